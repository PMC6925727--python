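"""Spectral shape distances between Steklov spectra.

Three weighting schemes are provided for the weighted l2 distance over the
first ``l`` nonzero eigenvalues (the shape-independent lambda_0 ~ 0 is
always excluded): uniform, Kac's 1/i, and the default curvature-histogram
scheme, which maps the area-weighted histogram of |Gaussian curvature| to
eigenvalue ranks — low-frequency eigenvalues carry the global geometry,
high-frequency ones the local detail, so detail-heavy surfaces up-weight
the high end of the spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bem import SteklovSpectrum
from .mesh import CurvatureField

DEFAULT_L = 50


@dataclass
class SpectralWeights:
    """Nonnegative weights w_1..w_l summing to one."""

    weights: np.ndarray
    scheme: str
    histogram_meta: dict = field(default_factory=dict)

    @property
    def l(self) -> int:
        return len(self.weights)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {s!r})")


@dataclass
class SSDResult:
    """A weighted Steklov-spectrum distance between two shapes."""

    value: float
    weights: SpectralWeights
    normalization: str
    spectrum_m: SteklovSpectrum = field(repr=False)
    spectrum_n: SteklovSpectrum = field(repr=False)

    def to_json(self) -> str:
        lm = self.weights.l
        return json.dumps(
            {
                "ssd": self.value,
                "l": lm,
                "scheme": self.weights.scheme,
                "normalization": self.normalization,
                "weights": list(map(float, self.weights.weights)),
                "eigenvalues_M": list(map(float, self.spectrum_m.eigenvalues[: lm + 1])),
                "eigenvalues_N": list(map(float, self.spectrum_n.eigenvalues[: lm + 1])),
            },
            indent=2,
        )


def euclidean_spectral_distance(lam, mu, l: int) -> float:
    """Plain l2 distance over eigenvalues 1..l (lambda_0 excluded)."""
    lam = np.asarray(lam, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if len(lam) < l + 1 or len(mu) < l + 1:
        raise ValueError(f"need at least {l + 1} eigenvalues in both sequences")
    return float(np.linalg.norm(lam[1 : l + 1] - mu[1 : l + 1]))


def curvature_histogram(
    field: CurvatureField,
    l: int,
    signed: bool = False,
    clip_percentile: float = 95.0,
) -> np.ndarray:
    """Area-weighted histogram of |K| over ``l`` bins; fractions sum to 1.

    Bins span [0, clip_percentile-th area-weighted percentile of |K|], the
    top bin absorbing the clipped tail — sliver triangles on scan-quality
    meshes produce unbounded curvature outliers otherwise.  ``signed=True``
    histograms K itself over a symmetric range instead.
    """
    if l < 2:
        raise ValueError("need at least 2 bins")
    k = field.K if signed else np.abs(field.K)
    a = field.area / field.area.sum()
    order = np.argsort(k)
    cdf = np.cumsum(a[order])
    hi = k[order][np.searchsorted(cdf, clip_percentile / 100.0, side="left").clip(0, len(k) - 1)]
    lo = -hi if signed else 0.0
    if hi <= lo:  # constant-curvature degenerate field: all mass in one bin
        hist = np.zeros(l)
        hist[0] = 1.0
        return hist
    edges = np.linspace(lo, hi, l + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, l - 1)  # top bin absorbs tail
    hist = np.zeros(l)
    np.add.at(hist, idx, a)
    return hist / hist.sum()


def eigenvalue_weights(
    hist_m: np.ndarray | None,
    hist_n: np.ndarray | None,
    l: int,
    scheme: str = "curvature-histogram",
) -> SpectralWeights:
    """Build weights for eigenvalue ranks 1..l from curvature histograms.

    ``uniform``: w_i = 1/l.  ``kac``: w_i proportional to 1/i.
    ``curvature-histogram``: w_i proportional to the symmetric average of
    the two histograms at bin i (ascending curvature mapped to ascending
    eigenvalue rank) plus a floor of 1/(10 l) that keeps every eigenvalue
    in play.
    """
    if scheme == "uniform":
        w = np.full(l, 1.0 / l)
        meta = {}
    elif scheme == "kac":
        w = 1.0 / np.arange(1, l + 1)
        w /= w.sum()
        meta = {}
    elif scheme == "curvature-histogram":
        if hist_m is None or hist_n is None:
            raise ValueError("curvature-histogram scheme requires both histograms")
        hist_m = np.asarray(hist_m, dtype=np.float64)
        hist_n = np.asarray(hist_n, dtype=np.float64)
        if len(hist_m) != l or len(hist_n) != l:
            raise ValueError(f"histograms must have length l={l}")
        w = 0.5 * (hist_m + hist_n) + 1.0 / (10.0 * l)
        w /= w.sum()
        meta = {
            "hist_m": list(map(float, hist_m)),
            "hist_n": list(map(float, hist_n)),
            "floor": 1.0 / (10.0 * l),
        }
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return SpectralWeights(weights=w, scheme=scheme, histogram_meta=meta)


def ssd(
    spec_m: SteklovSpectrum,
    spec_n: SteklovSpectrum,
    weights: SpectralWeights,
) -> SSDResult:
    """Weighted spectral distance sqrt(sum w_i (lambda_i - mu_i)^2), i >= 1."""
    if spec_m.normalization != spec_n.normalization:
        raise ValueError(
            "cannot compare spectra with different normalizations "
            f"({spec_m.normalization!r} vs {spec_n.normalization!r})"
        )
    l = weights.l
    if spec_m.m < l + 1 or spec_n.m < l + 1:
        raise ValueError(f"both spectra need at least {l + 1} eigenvalues")
    d = spec_m.eigenvalues[1 : l + 1] - spec_n.eigenvalues[1 : l + 1]
    value = float(np.sqrt(np.sum(weights.weights * d * d)))
    return SSDResult(
        value=value,
        weights=weights,
        normalization=spec_m.normalization,
        spectrum_m=spec_m,
        spectrum_n=spec_n,
    )


def ssd_curvature_weighted(
    spec_m: SteklovSpectrum,
    spec_n: SteklovSpectrum,
    l: int = DEFAULT_L,
    scheme: str = "curvature-histogram",
) -> SSDResult:
    """End-to-end SSD: curvature histograms of both meshes, weights, distance."""
    from .mesh import gaussian_curvature

    hist_m = hist_n = None
    if scheme == "curvature-histogram":
        if spec_m.mesh is None or spec_n.mesh is None:
            raise ValueError("curvature weighting requires mesh references")
        hist_m = curvature_histogram(gaussian_curvature(spec_m.mesh), l)
        hist_n = curvature_histogram(gaussian_curvature(spec_n.mesh), l)
    w = eigenvalue_weights(hist_m, hist_n, l, scheme)
    return ssd(spec_m, spec_n, w)
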