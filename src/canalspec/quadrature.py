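"""Quadrature rules for Galerkin boundary-element assembly.

Triangle rules are given in barycentric coordinates with weights summing
to one, so ``integral over T = area(T) * sum(w_q * f(x_q))``.  Singular
(coincident / edge-adjacent / vertex-adjacent) triangle-product integrals
use Sauter-Schwab regularizing coordinate transformations: the reference
quadrature points on (unit triangle)^2 and their weights are precomputed
once per case and order, so panel pairs evaluate fully vectorized.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# -- symmetric triangle rules (barycentric, weights sum to 1) ---------------

_RULES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _perm3(a: float) -> np.ndarray:
    b = 1.0 - 2.0 * a
    return np.array([[b, a, a], [a, b, a], [a, a, b]])


def _perm6(a: float, b: float) -> np.ndarray:
    c = 1.0 - a - b
    return np.array(
        [[a, b, c], [a, c, b], [b, a, c], [b, c, a], [c, a, b], [c, b, a]]
    )


_RULES[1] = (np.array([[1 / 3, 1 / 3, 1 / 3]]), np.array([1.0]))
_RULES[2] = (_perm3(1.0 / 6.0), np.full(3, 1.0 / 3.0))
_RULES[4] = (
    np.vstack([_perm3(0.445948490915965), _perm3(0.091576213509771)]),
    np.concatenate(
        [np.full(3, 0.223381589678011), np.full(3, 0.109951743655322)]
    ),
)
_RULES[6] = (
    np.vstack(
        [
            _perm3(0.249286745170910),
            _perm3(0.063089014491502),
            _perm6(0.310352451033785, 0.636502499121399),
        ]
    ),
    np.concatenate(
        [
            np.full(3, 0.116786275726379),
            np.full(3, 0.050844906370207),
            np.full(6, 0.082851075618374),
        ]
    ),
)


def triangle_rule(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Smallest stored symmetric rule exact to at least ``degree``.

    Returns (barycentric points (Q, 3), weights (Q,) summing to 1).
    """
    for d in sorted(_RULES):
        if d >= degree:
            return _RULES[d]
    return _RULES[max(_RULES)]


# -- Sauter-Schwab reference tables -----------------------------------------
#
# Reference triangle That = {(u, v): 0 <= v <= u <= 1}; a panel with corners
# (P0, P1, P2) is parameterized chi(u, v) = P0 + u (P1 - P0) + v (P2 - P1),
# i.e. barycentric hats (1 - u, u - v, v).  The tables below map tensor
# Gauss points on [0, 1]^4 to pairs of reference points with regularized
# Jacobians, following the classical relative-coordinate decompositions for
# kernels with an O(1/r) singularity.


def gauss01(k: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(k)
    return 0.5 * (x + 1.0), 0.5 * w


def _tensor4(k: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = gauss01(k)
    xi, e1, e2, e3 = np.meshgrid(x, x, x, x, indexing="ij")
    W = (
        w[:, None, None, None]
        * w[None, :, None, None]
        * w[None, None, :, None]
        * w[None, None, None, :]
    )
    return np.stack([a.ravel() for a in (xi, e1, e2, e3)]), W.ravel()


@lru_cache(maxsize=None)
def sauter_schwab_table(case: str, order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference quadrature for a singular panel pair.

    ``case`` is ``"coincident"``, ``"edge"`` or ``"vertex"``; ``order`` is
    the Gauss order per coordinate.  Returns ``(xhat, yhat, w)`` with
    ``xhat``/``yhat`` of shape (Q, 2) on the reference triangle and weights
    such that  integral over That x That  f(x, y)  = sum w_q f(xhat_q, yhat_q).
    """
    (xi, e1, e2, e3), w = _tensor4(order)
    xs, ys, ws = [], [], []

    def add(jac, x1, x2, y1, y2):
        xs.append(np.stack([x1, x2], axis=1))
        ys.append(np.stack([y1, y2], axis=1))
        ws.append(w * jac)

    if case == "coincident":
        jac = xi**3 * e1**2 * e2
        add(jac, xi, xi * (1 - e1 + e1 * e2), xi * (1 - e1 * e2 * e3), xi * (1 - e1))
        add(jac, xi * (1 - e1 * e2 * e3), xi * (1 - e1), xi, xi * (1 - e1 + e1 * e2))
        add(jac, xi, xi * e1 * (1 - e2 + e2 * e3), xi * (1 - e1 * e2), xi * e1 * (1 - e2))
        add(jac, xi * (1 - e1 * e2), xi * e1 * (1 - e2), xi, xi * e1 * (1 - e2 + e2 * e3))
        add(jac, xi * (1 - e1 * e2 * e3), xi * e1 * (1 - e2 * e3), xi, xi * e1 * (1 - e2))
        add(jac, xi, xi * e1 * (1 - e2), xi * (1 - e1 * e2 * e3), xi * e1 * (1 - e2 * e3))
    elif case == "edge":
        add(xi**3 * e1**2, xi, xi * e1 * e3, xi * (1 - e1 * e2), xi * e1 * (1 - e2))
        jac = xi**3 * e1**2 * e2
        add(jac, xi, xi * e1, xi * (1 - e1 * e2 * e3), xi * e1 * e2 * (1 - e3))
        add(jac, xi * (1 - e1 * e2), xi * e1 * (1 - e2), xi, xi * e1 * e2 * e3)
        add(jac, xi * (1 - e1 * e2 * e3), xi * e1 * e2 * (1 - e3), xi, xi * e1)
        add(jac, xi * (1 - e1 * e2 * e3), xi * e1 * (1 - e2 * e3), xi, xi * e1 * e2)
    elif case == "vertex":
        jac = xi**3 * e2
        add(jac, xi, xi * e1, xi * e2, xi * e2 * e3)
        add(jac, xi * e2, xi * e2 * e3, xi, xi * e1)
    else:
        raise ValueError(f"unknown singular case {case!r}")
    return np.vstack(xs), np.vstack(ys), np.concatenate(ws)


def refhat(uv: np.ndarray) -> np.ndarray:
    """Hat-function values (Q, 3) at reference points (Q, 2)."""
    u, v = uv[:, 0], uv[:, 1]
    return np.stack([1.0 - u, u - v, v], axis=1)
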