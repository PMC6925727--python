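"""Reading and writing triangle meshes: OFF, PLY, STL, OBJ.

Only the plain geometry records of each dialect are supported: OFF
vertex/face lists, PLY ``vertex``/``face`` elements (ASCII and binary
little-endian, float or double coordinates), STL ASCII and binary (triangle
soup, duplicate vertices merged on load), and OBJ ``v``/``f`` records.
Coordinates are millimetres; ASCII writers emit 17 significant digits so
round-trips are bit-exact for double precision.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np

from .errors import MeshFormatError, MeshValidationError
from .mesh import TriangleMesh

FORMATS = ("off", "ply", "stl", "obj")

#: STL stores triangle soup; vertices within this distance (mm) are merged
STL_MERGE_TOL = 1e-9


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in FORMATS:
        return ext
    raise MeshFormatError(f"cannot auto-detect mesh format from '{path.name}'")


def read_mesh(path: str | os.PathLike, fmt: str | None = None, validate: bool = True) -> TriangleMesh:
    """Read a closed triangle mesh, validating the manifold contract.

    ``fmt`` is one of ``off``/``ply``/``stl``/``obj`` or ``None`` to
    auto-detect from the file extension.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = (fmt or _detect_format(path)).lower()
    if fmt == "off":
        mesh = _read_off(path)
    elif fmt == "ply":
        mesh = _read_ply(path)
    elif fmt == "stl":
        mesh = _read_stl(path)
    elif fmt == "obj":
        mesh = _read_obj(path)
    else:
        raise MeshFormatError(f"unknown mesh format {fmt!r}")
    mesh.name = path.stem
    if validate:
        mesh.validate()
    return mesh


def write_mesh(
    mesh: TriangleMesh,
    path: str | os.PathLike,
    fmt: str | None = None,
    binary: bool = False,
) -> None:
    """Write ``mesh`` so that :func:`read_mesh` reproduces it exactly.

    ASCII output carries 17 significant digits; binary PLY stores doubles
    (bit-exact round-trip), binary STL stores the format's mandated float32.
    """
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    path = Path(path)
    fmt = (fmt or _detect_format(path)).lower()
    try:
        if fmt == "off":
            _write_off(mesh, path)
        elif fmt == "ply":
            _write_ply(mesh, path, binary)
        elif fmt == "stl":
            _write_stl(mesh, path, binary)
        elif fmt == "obj":
            _write_obj(mesh, path)
        else:
            raise MeshFormatError(f"unknown mesh format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


# -- OFF ---------------------------------------------------------------------


def _tokens(path: Path) -> list[str]:
    out: list[str] = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            out.extend(line.split())
    return out


def _read_off(path: Path) -> TriangleMesh:
    toks = _tokens(path)
    if not toks or toks[0].upper() != "OFF":
        raise MeshFormatError(f"{path.name}: missing OFF header")
    try:
        nv, nf = int(toks[1]), int(toks[2])
        pos = 4  # skip edge count
        flat = np.array(toks[pos : pos + 3 * nv], dtype=np.float64)
        verts = flat.reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(toks[pos])
            if k != 3:
                raise MeshFormatError(f"{path.name}: non-triangular face (degree {k})")
            faces.append([int(t) for t in toks[pos + 1 : pos + 4]])
            pos += 1 + k
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path.name}: malformed OFF file: {exc}") from exc
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def _write_off(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- OBJ ---------------------------------------------------------------------


def _read_obj(path: Path) -> TriangleMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    try:
        with open(path, "r") as fh:
            for line in fh:
                parts = line.split("#", 1)[0].split()
                if not parts:
                    continue
                if parts[0] == "v":
                    verts.append([float(x) for x in parts[1:4]])
                elif parts[0] == "f":
                    idx = [int(p.split("/")[0]) for p in parts[1:]]
                    if len(idx) != 3:
                        raise MeshFormatError(f"{path.name}: non-triangular face")
                    faces.append([i - 1 if i > 0 else len(verts) + i for i in idx])
    except ValueError as exc:
        raise MeshFormatError(f"{path.name}: malformed OBJ file: {exc}") from exc
    if not verts or not faces:
        raise MeshFormatError(f"{path.name}: no v/f records found")
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# -- PLY ---------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> TriangleMesh:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise MeshFormatError(f"{path.name}: missing ply magic")
        fmt = None
        elements: list[tuple[str, int, list]] = []
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"{path.name}: unterminated PLY header")
            parts = line.decode("ascii", "replace").split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                elements.append((parts[1], int(parts[2]), []))
            elif parts[0] == "property":
                if not elements:
                    raise MeshFormatError(f"{path.name}: property before element")
                if parts[1] == "list":
                    elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
                else:
                    elements[-1][2].append(("scalar", parts[1], parts[2]))
            elif parts[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise MeshFormatError(f"{path.name}: unsupported PLY format {fmt!r}")
        verts = faces = None
        if fmt == "ascii":
            toks = fh.read().decode("ascii").split()
            pos = 0
            for name, count, props in elements:
                if name == "vertex":
                    width = len(props)
                    cols = {p[2]: k for k, p in enumerate(props) if p[0] == "scalar"}
                    arr = np.array(toks[pos : pos + width * count], dtype=np.float64)
                    arr = arr.reshape(count, width)
                    try:
                        verts = arr[:, [cols["x"], cols["y"], cols["z"]]]
                    except KeyError as exc:
                        raise MeshFormatError(f"{path.name}: vertex lacks x/y/z") from exc
                    pos += width * count
                elif name == "face":
                    faces = []
                    for _ in range(count):
                        k = int(toks[pos])
                        if k != 3:
                            raise MeshFormatError(f"{path.name}: non-triangular face")
                        faces.append([int(t) for t in toks[pos + 1 : pos + 4]])
                        pos += 1 + k
                    faces = np.array(faces, dtype=np.int64)
                else:  # skip unknown fixed-width ascii element
                    pos += count * len(props)
        else:
            for name, count, props in elements:
                if name == "vertex":
                    dt = np.dtype(
                        [(p[2], "<" + _PLY_TYPES[p[1]]) for p in props if p[0] == "scalar"]
                    )
                    raw = np.frombuffer(fh.read(dt.itemsize * count), dtype=dt)
                    verts = np.stack(
                        [raw["x"], raw["y"], raw["z"]], axis=1
                    ).astype(np.float64)
                elif name == "face":
                    (kind, ctype, itype, _), = (p for p in props if p[0] == "list")
                    cdt = np.dtype("<" + _PLY_TYPES[ctype])
                    idt = np.dtype("<" + _PLY_TYPES[itype])
                    faces = np.empty((count, 3), dtype=np.int64)
                    for i in range(count):
                        k = int(np.frombuffer(fh.read(cdt.itemsize), dtype=cdt)[0])
                        if k != 3:
                            raise MeshFormatError(f"{path.name}: non-triangular face")
                        faces[i] = np.frombuffer(fh.read(3 * idt.itemsize), dtype=idt)
                else:
                    for p in props:
                        if p[0] == "list":
                            raise MeshFormatError(
                                f"{path.name}: cannot skip binary list element {name!r}"
                            )
                    width = sum(np.dtype(_PLY_TYPES[p[1]]).itemsize for p in props)
                    fh.read(width * count)
    if verts is None or faces is None:
        raise MeshFormatError(f"{path.name}: missing vertex or face element")
    return TriangleMesh(verts, faces)


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        f"property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(mesh.vertices.astype("<f8").tobytes())
            rec = np.empty(
                mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", (3,))]
            )
            rec["n"] = 3
            rec["idx"] = mesh.faces
            fh.write(rec.tobytes())
        else:
            lines = [
                f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n" for v in mesh.vertices
            ] + [f"3 {f[0]} {f[1]} {f[2]}\n" for f in mesh.faces]
            fh.write("".join(lines).encode("ascii"))


# -- STL ---------------------------------------------------------------------


def _merge_soup(tris: np.ndarray) -> TriangleMesh:
    """Merge an (m, 3, 3) triangle soup into an indexed mesh (tol 1e-9 mm)."""
    pts = tris.reshape(-1, 3)
    # snap to a tolerance grid; exact duplicates from a common writer collapse
    key = np.round(pts / STL_MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # preserve first-appearance order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = pts[np.sort(first)]
    faces = rank[inverse].reshape(-1, 3)
    return TriangleMesh(verts, faces.astype(np.int64))


def _read_stl(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid"
    if is_ascii:
        # binary files sometimes start with "solid": cross-check the size
        if len(raw) >= 84:
            (nf,) = struct.unpack("<I", raw[80:84])
            if len(raw) == 84 + 50 * nf:
                is_ascii = False
    if is_ascii:
        toks = raw.decode("ascii", "replace").split()
        coords = []
        i = 0
        while i < len(toks):
            if toks[i] == "vertex":
                coords.extend(toks[i + 1 : i + 4])
                i += 4
            else:
                i += 1
        if not coords or len(coords) % 9:
            raise MeshFormatError(f"{path.name}: malformed ASCII STL")
        tris = np.array(coords, dtype=np.float64).reshape(-1, 3, 3)
    else:
        if len(raw) < 84:
            raise MeshFormatError(f"{path.name}: truncated binary STL")
        (nf,) = struct.unpack("<I", raw[80:84])
        if len(raw) < 84 + 50 * nf:
            raise MeshFormatError(f"{path.name}: truncated binary STL")
        rec = np.frombuffer(
            raw[84 : 84 + 50 * nf],
            dtype=[("n", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        )
        tris = rec["v"].astype(np.float64)
    return _merge_soup(tris)


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    a, b, c = mesh.face_corners()
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n, axis=1)[:, None]
    if binary:
        rec = np.zeros(
            mesh.n_faces, dtype=[("n", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        )
        rec["n"] = n
        rec["v"][:, 0], rec["v"][:, 1], rec["v"][:, 2] = a, b, c
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(f"solid {mesh.name or 'mesh'}\n")
            for k in range(mesh.n_faces):
                fh.write(f"  facet normal {n[k,0]:.17g} {n[k,1]:.17g} {n[k,2]:.17g}\n")
                fh.write("    outer loop\n")
                for p in (a[k], b[k], c[k]):
                    fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {mesh.name or 'mesh'}\n")
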