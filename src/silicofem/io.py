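"""Standard-format I/O: VTK unstructured grids (.vtu) and cohort CSV tables.

The VTU writer emits plain ASCII XML covering exactly what this package
produces — points, linear tetrahedra, element-wise cell data (``rho_app``,
``E``) and a ``landmarks`` field-data block — and the reader parses that
same layout back.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vtu",
    "read_vtu",
    "SchemaError",
    "COHORT_COLUMNS",
    "write_cohort",
    "read_cohort",
]

VTK_TETRA = 10


def _array_text(a: np.ndarray) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(repr(float(v)) for v in flat)


def write_vtu(
    path,
    node_coords: np.ndarray,
    tets: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    field_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a linear-tet mesh as an ASCII VTK XML unstructured grid."""
    node_coords = np.asarray(node_coords, dtype=float)
    tets = np.asarray(tets, dtype=int)
    n_pts, n_cells = len(node_coords), len(tets)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
    ]
    if field_data:
        lines.append("    <FieldData>")
        for name, arr in field_data.items():
            arr = np.asarray(arr, dtype=float)
            comps = arr.shape[1] if arr.ndim == 2 else 1
            lines.append(
                f'      <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{comps}" NumberOfTuples="{arr.shape[0]}" '
                f'format="ascii">{_array_text(arr)}</DataArray>'
            )
        lines.append("    </FieldData>")
    lines.append(f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">')
    lines.append("      <Points>")
    lines.append(
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">'
        f"{_array_text(node_coords)}</DataArray>"
    )
    lines.append("      </Points>")
    lines.append("      <Cells>")
    lines.append(
        '        <DataArray type="Int64" Name="connectivity" format="ascii">'
        f"{_array_text(tets)}</DataArray>"
    )
    offsets = 4 * np.arange(1, n_cells + 1)
    lines.append(
        '        <DataArray type="Int64" Name="offsets" format="ascii">'
        f"{_array_text(offsets)}</DataArray>"
    )
    types = np.full(n_cells, VTK_TETRA)
    lines.append(
        '        <DataArray type="UInt8" Name="types" format="ascii">'
        f"{_array_text(types)}</DataArray>"
    )
    lines.append("      </Cells>")
    if cell_data:
        lines.append("      <CellData>")
        for name, arr in cell_data.items():
            lines.append(
                f'        <DataArray type="Float64" Name="{name}" format="ascii">'
                f"{_array_text(np.asarray(arr, dtype=float))}</DataArray>"
            )
        lines.append("      </CellData>")
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtu(path):
    """Read a .vtu written by :func:`write_vtu`.

    Returns ``(node_coords, tets, cell_data, field_data)``.
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    coords = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=int)
    tets = conn.reshape(-1, 4)
    cell_data = {}
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.findall("DataArray"):
            cell_data[da.get("Name")] = np.fromstring(da.text, sep=" ")
    field_data = {}
    fd = root.find(".//FieldData")
    if fd is not None:
        for da in fd.findall("DataArray"):
            comps = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            field_data[da.get("Name")] = arr.reshape(-1, comps) if comps > 1 else arr
    return coords, tets, cell_data, field_data


# ---------------------------------------------------------------------------
# cohort tables


class SchemaError(ValueError):
    pass


COHORT_COLUMNS = (
    "subject_id",
    "pair_id",
    "label",
    "age",
    "height_cm",
    "weight_kg",
    "bmi",
    "abmd_neck",
    "t_score",
    "qc_status",
)


def write_cohort(path, table: pd.DataFrame) -> None:
    """Write a cohort table to CSV (floats at full round-trip precision)."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table lacks required column(s): {missing}")
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the required schema."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort CSV {path} lacks required column(s): {missing}")
    return table
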