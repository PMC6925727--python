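# canalspec

Steklov-spectrum shape evaluation for root canal preparation.

`canalspec` computes the Dirichlet-to-Neumann (Steklov) spectrum of a
closed triangle surface mesh with a Galerkin boundary-element method,
constructs an "ideal" benchmark canal by key-cross-section lofting, and
scores a prepared canal against its ideal with a Gaussian-curvature-weighted
spectral distance (SSD).  The legacy slice-integration metrics (volume,
lateral area, centroid transportation) are included for comparison.  A
deterministic synthetic-canal generator makes the whole pipeline testable
without any imaging data.

## What is inside

| module | role |
| --- | --- |
| `canalspec.mesh` | mesh validation, Gaussian curvature (angle deficit), interior solid angles, areas/volumes, rigid/scale transforms |
| `canalspec.meshfile` | OFF / PLY (ascii + binary) / STL (ascii + binary) / OBJ readers and writers |
| `canalspec.bem` | Galerkin assembly of the single-layer `V`, double-layer `K`/`K*`, regularized hypersingular `D` and mass `G` matrices; the symmetric Steklov eigenproblem `(D + B^T V^-1 B) u = lambda G u` |
| `canalspec.iccg` | incomplete-Cholesky-preconditioned conjugate gradients |
| `canalspec.sections` | plane cross-sections, equal-area-circle deviation scoring, key-section selection, ideal-canal lofting |
| `canalspec.distance` | Euclidean / Kac / curvature-histogram-weighted spectral distances |
| `canalspec.legacy` | slice-stack volume, area and transportation metrics |
| `canalspec.synth` | icosphere / cylinder / cone fixtures and seeded synthetic canal (pre, post) pairs |
| `canalspec.cli` | `canalspec` command-line tool |

Singular panel integrals use Sauter–Schwab regularizing coordinates
(coincident, shared-edge, shared-vertex cases); the hypersingular operator
is assembled in its integration-by-parts weak form, so `D @ 1 = 0` holds to
rounding and the zero Steklov mode is reproduced at machine precision.
On a unit-ball mesh the computed spectrum matches the closed form
{0; 1 ×3; 2 ×5; 3 ×7; ...} mm⁻¹ to 1.4% / 0.33% / 0.05% at icosphere
subdivisions 2 / 3 / 4.

## CLI

```sh
# deterministic synthetic canal + JSON manifest
canalspec synth --seed 7 --bump-amplitude 0.3 --bump-count 5 --out canal.off

# Steklov spectrum (JSON to stdout; --csv for a CSV sidecar)
canalspec spectrum canal.off --l 30 --normalization area

# ideal benchmark canal + selection plan
canalspec ideal canal.off --out-mesh ideal.off --out-plan plan.json

# curvature-weighted Steklov spectrum distance between two meshes
canalspec ssd canal.off ideal.off --l 30

# full report: SSD vs the ideal + legacy volume/area/transportation
canalspec evaluate pre.off post.off --l 30 --out report.json

# legacy slice metrics only
canalspec legacy pre.off post.off --slices 100
```

All commands are deterministic given their `--seed`; logging goes to
stderr, machine output to stdout or files.  A TOML config file
(`canalspec --config cfg.toml ...`) can preset any option; explicit flags
win.

## Conventions

Coordinates are millimetres.  The canal axis is +z with the coronal (top)
end at larger z; depths are measured down from the top plane.  Meshes must
be closed, consistently oriented 2-manifolds (outward normals); a globally
inverted mesh is flipped with a warning at load.
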