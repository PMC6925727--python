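"""Shared fixtures.  Expensive spectra are session-cached so acceptance and
unit tests reuse the same assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from canalspec import (
    SynthCanalParams,
    TriangleMesh,
    assemble_operators,
    compute_spectrum,
    make_icosphere,
    make_synthetic_canal,
    solve_steklov,
)


def tetrahedron() -> TriangleMesh:
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, name="tetra")


def unit_cube() -> TriangleMesh:
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    faces = []

    def quad(a, b, c, d):
        faces.extend([[a, b, c], [a, c, d]])

    quad(0, 1, 3, 2)
    quad(4, 6, 7, 5)
    quad(0, 4, 5, 1)
    quad(2, 3, 7, 6)
    quad(0, 2, 6, 4)
    quad(1, 5, 7, 3)
    return TriangleMesh(v, np.array(faces), name="cube")


@pytest.fixture
def tetra() -> TriangleMesh:
    return tetrahedron().validate()


@pytest.fixture
def cube() -> TriangleMesh:
    return unit_cube().validate()


@pytest.fixture(scope="session")
def ico2() -> TriangleMesh:
    return make_icosphere(1.0, 2).validate()


@pytest.fixture(scope="session")
def ico3() -> TriangleMesh:
    return make_icosphere(1.0, 3).validate()


_ops_cache: dict = {}
_spec_cache: dict = {}


def cached_operators(mesh: TriangleMesh, key: str, **kwargs):
    if key not in _ops_cache:
        _ops_cache[key] = assemble_operators(mesh, **kwargs)
    return _ops_cache[key]


def cached_spectrum(mesh: TriangleMesh, key: str, m: int, **kwargs):
    """Session-level spectrum cache; m must not exceed the first request's m."""
    if key not in _spec_cache:
        _spec_cache[key] = compute_spectrum(mesh, m=m, **kwargs)
    spec = _spec_cache[key]
    assert spec.m >= m, f"cached spectrum for {key} has m={spec.m} < {m}"
    return spec


@pytest.fixture(scope="session")
def ops_ico2(ico2):
    return cached_operators(ico2, "ico2")


@pytest.fixture(scope="session")
def spec_ico2(ops_ico2):
    if "ico2" not in _spec_cache:
        _spec_cache["ico2"] = solve_steklov(ops_ico2, m=20)
    return _spec_cache["ico2"]


@pytest.fixture(scope="session")
def spec_ico3(ico3):
    return cached_spectrum(ico3, "ico3", m=20)


def canal_params(**over) -> SynthCanalParams:
    base = dict(
        height=10.0,
        top_radius=1.5,
        bottom_radius=0.5,
        rings=16,
        layers=24,
        bump_count=5,
        seed=7,
    )
    base.update(over)
    return SynthCanalParams(**base)


@pytest.fixture(scope="session")
def bumpy_canal() -> TriangleMesh:
    return make_synthetic_canal(canal_params(bump_amplitude=0.35))
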