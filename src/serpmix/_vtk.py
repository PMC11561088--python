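"""Minimal legacy-VTK (ASCII, unstructured quad grid) writer/reader.

Covers exactly what the package exports: cell-centred scalars/vectors on the
structured quad mesh, written with 17 significant digits so a write/read
round trip is bit-exact.  The header's second line carries a format tag and
the logical grid shape.
"""

from __future__ import annotations

import numpy as np

FORMAT_TAG = "serpmix-fields-v1"


class VTKParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(message + loc)
        self.line = line


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_vtk(
    path,
    points: np.ndarray,
    quads: np.ndarray,
    cell_scalars: dict[str, np.ndarray] | None = None,
    cell_vectors: dict[str, np.ndarray] | None = None,
    shape: tuple[int, int] | None = None,
) -> None:
    """Write a quad mesh with cell data to a legacy VTK ASCII file.

    Refuses non-finite field values (a NaN in an exported field is always a
    bug upstream).
    """
    cell_scalars = cell_scalars or {}
    cell_vectors = cell_vectors or {}
    for name, arr in {**cell_scalars, **cell_vectors}.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"field {name!r} contains non-finite values; refusing to write")

    n_pts = len(points)
    n_cells = len(quads)
    shp = f" shape={shape[0]}x{shape[1]}" if shape is not None else ""
    lines = [
        "# vtk DataFile Version 3.0",
        f"{FORMAT_TAG}{shp}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_pts} double",
    ]
    for x, y in np.asarray(points, dtype=float):
        lines.append(f"{_fmt(x)} {_fmt(y)} 0")
    lines.append(f"CELLS {n_cells} {5 * n_cells}")
    for q in quads:
        lines.append("4 " + " ".join(str(int(i)) for i in q))
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["9"] * n_cells)
    if cell_scalars or cell_vectors:
        lines.append(f"CELL_DATA {n_cells}")
        for name, arr in cell_scalars.items():
            arr = np.asarray(arr, dtype=float).ravel()
            if len(arr) != n_cells:
                raise ValueError(f"scalar {name!r} has {len(arr)} values for {n_cells} cells")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(_fmt(v) for v in arr)
        for name, arr in cell_vectors.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 2)
            if len(arr) != n_cells:
                raise ValueError(f"vector {name!r} has {len(arr)} values for {n_cells} cells")
            lines.append(f"VECTORS {name} double")
            lines.extend(f"{_fmt(u)} {_fmt(v)} 0" for u, v in arr)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a file produced by :func:`write_vtk`.

    Returns (points, quads, cell_scalars, cell_vectors, shape).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0

    def expect(prefix: str):
        nonlocal k
        if k >= len(lines) or not lines[k].startswith(prefix):
            raise VTKParseError(f"expected {prefix!r}", k + 1)
        out = lines[k]
        k += 1
        return out

    expect("# vtk DataFile")
    header = expect(FORMAT_TAG)
    shape = None
    for tok in header.split():
        if tok.startswith("shape="):
            a, b = tok[6:].split("x")
            shape = (int(a), int(b))
    expect("ASCII")
    expect("DATASET UNSTRUCTURED_GRID")
    n_pts = int(expect("POINTS").split()[1])
    points = np.empty((n_pts, 2))
    for i in range(n_pts):
        parts = lines[k].split()
        points[i] = float(parts[0]), float(parts[1])
        k += 1
    n_cells = int(expect("CELLS").split()[1])
    quads = np.empty((n_cells, 4), dtype=int)
    for i in range(n_cells):
        parts = lines[k].split()
        if parts[0] != "4":
            raise VTKParseError("non-quad cell", k + 1)
        quads[i] = [int(p) for p in parts[1:5]]
        k += 1
    expect("CELL_TYPES")
    k += n_cells
    scalars: dict[str, np.ndarray] = {}
    vectors: dict[str, np.ndarray] = {}
    if k < len(lines) and lines[k].startswith("CELL_DATA"):
        k += 1
        while k < len(lines) and lines[k].strip():
            if lines[k].startswith("SCALARS"):
                name = lines[k].split()[1]
                k += 2  # skip LOOKUP_TABLE
                vals = np.array([float(lines[k + i]) for i in range(n_cells)])
                k += n_cells
                scalars[name] = vals
            elif lines[k].startswith("VECTORS"):
                name = lines[k].split()[1]
                k += 1
                vals = np.array(
                    [[float(x) for x in lines[k + i].split()[:2]] for i in range(n_cells)]
                )
                k += n_cells
                vectors[name] = vals
            else:
                raise VTKParseError(f"unexpected cell-data block {lines[k]!r}", k + 1)
    return points, quads, scalars, vectors, shape
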