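"""VTK legacy ASCII unstructured-grid I/O for tetrahedral LV meshes.

Only the dialect written by this package is supported on read:
DATASET UNSTRUCTURED_GRID, CELL_TYPES all 10 (tetrahedra), optional
POINT_DATA SCALARS blocks.  The scalar named ``MBF`` populates
``LVMesh.nodal_mbf``; other point scalars are returned alongside.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .model import LVMesh

VTK_TET = 10


class VTKParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"VTK parse error at line {line}: {msg}")
        self.line = line


class _Cursor:
    def __init__(self, lines):
        self.lines = lines
        self.i = 0

    def next_data_line(self) -> Tuple[str, int]:
        while self.i < len(self.lines):
            ln = self.lines[self.i]
            self.i += 1
            if ln.strip():
                return ln.strip(), self.i
        raise VTKParseError("unexpected end of file", len(self.lines))

    def peek(self) -> Optional[str]:
        j = self.i
        while j < len(self.lines):
            if self.lines[j].strip():
                return self.lines[j].strip()
            j += 1
        return None


def _read_floats(cur: _Cursor, count: int) -> np.ndarray:
    vals = []
    while len(vals) < count:
        ln, lineno = cur.next_data_line()
        try:
            vals.extend(float(t) for t in ln.split())
        except ValueError:
            raise VTKParseError(f"expected numeric data, got {ln!r}", lineno)
    if len(vals) != count:
        raise VTKParseError("data block has wrong length", cur.i)
    return np.array(vals)


def read_mesh(path) -> Tuple[LVMesh, Dict[str, np.ndarray]]:
    """Read a VTK legacy ASCII tet mesh.

    Returns ``(mesh, extra_point_fields)``.  A point scalar named ``MBF``
    is stored on the mesh itself; remaining scalars are returned in the
    dict.  Raises :class:`VTKParseError` on malformed input and
    ``ValueError`` on non-tet cells.
    """
    with open(path) as fh:
        cur = _Cursor(fh.readlines())
    ln, lineno = cur.next_data_line()
    if not ln.startswith("# vtk DataFile"):
        raise VTKParseError("missing '# vtk DataFile' header", lineno)
    cur.next_data_line()  # title
    ln, lineno = cur.next_data_line()
    if ln.upper() != "ASCII":
        raise VTKParseError("only ASCII VTK files are supported", lineno)
    ln, lineno = cur.next_data_line()
    if "UNSTRUCTURED_GRID" not in ln:
        raise VTKParseError("expected DATASET UNSTRUCTURED_GRID", lineno)

    ln, lineno = cur.next_data_line()
    if not ln.startswith("POINTS"):
        raise VTKParseError("expected POINTS block", lineno)
    n_pts = int(ln.split()[1])
    nodes = _read_floats(cur, 3 * n_pts).reshape(n_pts, 3)

    ln, lineno = cur.next_data_line()
    if not ln.startswith("CELLS"):
        raise VTKParseError("expected CELLS block", lineno)
    n_cells, n_ints = int(ln.split()[1]), int(ln.split()[2])
    raw = _read_floats(cur, n_ints).astype(np.int64)
    tets = np.empty((n_cells, 4), dtype=np.int64)
    pos = 0
    for c in range(n_cells):
        nper = raw[pos]
        if nper != 4:
            raise ValueError(
                f"unsupported cell with {nper} points (only tetrahedra supported)"
            )
        tets[c] = raw[pos + 1 : pos + 5]
        pos += 5

    ln, lineno = cur.next_data_line()
    if not ln.startswith("CELL_TYPES"):
        raise VTKParseError("expected CELL_TYPES block", lineno)
    types = _read_floats(cur, n_cells).astype(int)
    if np.any(types != VTK_TET):
        bad = sorted(set(types[types != VTK_TET].tolist()))
        raise ValueError(f"unsupported (non-tet) cell types present: {bad}")

    fields: Dict[str, np.ndarray] = {}
    if cur.peek() is not None:
        ln, lineno = cur.next_data_line()
        if not ln.startswith("POINT_DATA"):
            raise VTKParseError("expected POINT_DATA or end of file", lineno)
        n_pd = int(ln.split()[1])
        if n_pd != n_pts:
            raise VTKParseError("POINT_DATA count mismatch", lineno)
        while cur.peek() is not None:
            ln, lineno = cur.next_data_line()
            if not ln.startswith("SCALARS"):
                raise VTKParseError("expected SCALARS block", lineno)
            name = ln.split()[1]
            ln2, lineno2 = cur.next_data_line()
            if not ln2.startswith("LOOKUP_TABLE"):
                raise VTKParseError("expected LOOKUP_TABLE line", lineno2)
            fields[name] = _read_floats(cur, n_pts)

    mbf = fields.pop("MBF", None)
    mesh = LVMesh(nodes=nodes, tets=tets, nodal_mbf=mbf)
    return mesh, fields


def write_mesh(mesh: LVMesh, fields: Optional[Dict[str, np.ndarray]], path) -> None:
    """Write a tet mesh (plus named nodal scalar fields) as VTK legacy ASCII.

    ``mesh.nodal_mbf`` is written automatically as the ``MBF`` scalar.
    """
    fields = dict(fields or {})
    if mesh.nodal_mbf is not None and "MBF" not in fields:
        fields["MBF"] = mesh.nodal_mbf
    n = len(mesh.nodes)
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape != (n,):
            raise ValueError(
                f"field {name!r} has length {arr.shape}, expected ({n},)"
            )
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("myoperf LV mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        m = len(mesh.tets)
        fh.write(f"CELLS {m} {5 * m}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        for _ in range(m):
            fh.write("10\n")
        if fields:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in fields.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, dtype=float):
                    fh.write(f"{v:.17g}\n")
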