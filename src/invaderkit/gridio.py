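"""TSV round-trip for pairwise invasibility grids.

Layout: comment header lines starting with '#' carrying parameters and the
seed, then a matrix whose first row holds the resident grid values and
first column the mutant grid values (the top-left cell is blank).  Values
are written with 12 significant digits so the round trip is lossless at
that precision.
"""

from __future__ import annotations

import numpy as np

from .games import PIPGrid

__all__ = ["write_grid", "read_grid"]


def write_grid(grid: PIPGrid, path, header: dict | None = None) -> None:
    """Write a PIPGrid as TSV; ``header`` entries become '# key: value' lines."""
    lam = np.asarray(grid.lam)
    if lam.size == 0:
        raise ValueError("refusing to write an empty grid")
    if not np.all(np.isfinite(lam)):
        raise ValueError("refusing to write a grid with non-finite entries")
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("\t" + "\t".join(_fmt(v) for v in grid.resident_values) + "\n")
        for i, mv in enumerate(grid.mutant_values):
            fh.write(_fmt(mv) + "\t" + "\t".join(_fmt(v) for v in lam[i]) + "\n")


def _fmt(v: float) -> str:
    return f"{v:.12g}"


def read_grid(path) -> tuple[PIPGrid, dict]:
    """Read a TSV grid written by :func:`write_grid`.

    Returns ``(grid, header)``; malformed rows raise with the line number.
    """
    header: dict = {}
    rows: list[list[str]] = []
    resident = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if resident is None:
                if parts[0].strip() != "":
                    raise ValueError(
                        f"{path}:{lineno}: first data row must start with an empty cell"
                    )
                try:
                    resident = np.array([float(v) for v in parts[1:]])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad resident grid value: {exc}") from exc
                continue
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric value: {exc}") from exc
            if len(parts) != len(resident) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(resident) + 1} columns, got {len(parts)}"
                )
    if resident is None or not rows:
        raise ValueError(f"{path}: no grid data found")
    arr = np.array(rows)
    return PIPGrid(resident, arr[:, 0], arr[:, 1:]), header
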