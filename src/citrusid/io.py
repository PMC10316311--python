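"""Genotype-table and marker-metadata I/O.

Two packaged fixtures ship with the library:

``table3_polymorphisms.tsv``
    Presence/absence of each published diagnostic fragment across the
    26 reference cultivars, in marker-rows layout with the assay's
    ○ (fragment present) / × (absent) symbols.  One marker (Cp0419-s)
    belongs to two kits and appears twice; loading deduplicates it to a
    single column after checking the duplicate rows agree.

``table2_markers.tsv``
    Per-kit marker metadata: source family, and amplicon size in bp.
    Sizes are keyed by (target cultivar, marker) because the same
    marker can be re-primed to a different amplicon size in different
    kits; the rbcL positive control (target ``*``) is shared by all.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix

PRESENT_ALIASES = {"1", "○", "o", "O", "present", "+"}
ABSENT_ALIASES = {"0", "×", "x", "X", "absent", "-"}

#: the eight published kits: target cultivar -> marker members
PUBLISHED_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "Asumi": ("Cp0419-s", "IND214-s"),
    "Rinoka": ("IND141-l",),
    "Mihaya": ("Tcs2-CL55_M", "Tcs1-P86"),
    "Asuki": ("Tcs2-CL25", "IND235-s"),
    "Ehimekashidai28go": ("Tcs2-CL68",),
    "Kanpei": ("Cp0419-s", "IND265-l", "IND44-l"),
    "Himekoharu": ("Tcs2-CL80",),
    "Ehimekashidai48go": ("Tcs2-CL55_E", "Tcs1-CL26"),
}


def _decode_cell(cell: str, row: str, col: str) -> int:
    token = str(cell).strip()
    if token in PRESENT_ALIASES:
        return 1
    if token in ABSENT_ALIASES:
        return 0
    raise ValueError(
        f"non-binary genotype cell {cell!r} at row {row!r}, column {col!r}")


def _infer_source(marker: str) -> str:
    if marker == "rbcL":
        return "positive_control"
    for family in ("CIRE1", "Tcs1", "Tcs2"):
        if marker.startswith(family):
            return family
    return "InDel"


def load_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Load a cultivars-x-markers TSV (header = marker ids, col 1 = cultivars).

    Cells may be 0/1 or the assay symbols ○/× (plus o/x aliases).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    raw.index = raw.index.astype(str)
    decoded = pd.DataFrame(
        [[_decode_cell(raw.iat[i, j], raw.index[i], raw.columns[j])
          for j in range(raw.shape[1])] for i in range(raw.shape[0])],
        index=raw.index, columns=raw.columns, dtype=np.int8)
    decoded.index.name = "cultivar"
    meta = pd.DataFrame({"source": [_infer_source(m) for m in decoded.columns],
                         "fragment_size": pd.NA},
                        index=pd.Index(decoded.columns, name="marker"))
    return GenotypeMatrix(decoded, meta)


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "cultivar"
    df.to_csv(path, sep="\t")


def _packaged(name: str):
    return resources.files("citrusid.data").joinpath(name)


def load_reference_genotypes(path: str | Path | None = None) -> GenotypeMatrix:
    """The packaged 26-cultivar reference panel (marker-rows layout).

    Duplicate marker rows (a marker reused across kits) are merged after
    verifying their genotype calls agree; the result has one column per
    unique marker.
    """
    source = Path(path) if path is not None else _packaged(
        "table3_polymorphisms.tsv")
    with (source.open("r", encoding="utf-8") if hasattr(source, "open")
          else open(source, encoding="utf-8")) as fh:
        raw = pd.read_csv(fh, sep="\t", dtype=str)
    cultivars = list(raw.columns[1:])
    columns: dict[str, list[int]] = {}
    order: list[str] = []
    for _, row in raw.iterrows():
        marker = str(row.iloc[0]).strip()
        values = [_decode_cell(row[c], marker, c) for c in cultivars]
        if marker in columns:
            if columns[marker] != values:
                raise ValueError(
                    f"duplicate marker {marker!r} with conflicting genotypes")
            continue
        columns[marker] = values
        order.append(marker)
    data = pd.DataFrame({m: columns[m] for m in order},
                        index=pd.Index(cultivars, name="cultivar"),
                        dtype=np.int8)
    meta = pd.DataFrame({"source": [_infer_source(m) for m in order],
                         "fragment_size": pd.NA},
                        index=pd.Index(order, name="marker"))
    return GenotypeMatrix(data, meta)


def load_marker_metadata(path: str | Path | None = None) -> pd.DataFrame:
    """Per-kit marker metadata: target, marker, source, fragment_size_bp."""
    source = Path(path) if path is not None else _packaged("table2_markers.tsv")
    with (source.open("r", encoding="utf-8") if hasattr(source, "open")
          else open(source, encoding="utf-8")) as fh:
        df = pd.read_csv(fh, sep="\t")
    df["fragment_size_bp"] = df["fragment_size_bp"].astype(int)
    return df


def kit_sizes(target: str, metadata: pd.DataFrame | None = None) -> dict[str, int]:
    """Amplicon sizes (bp) for one kit: the target's markers plus rbcL."""
    meta = load_marker_metadata() if metadata is None else metadata
    rows = meta[(meta["target"] == target) | (meta["target"] == "*")]
    if rows[rows["target"] == target].empty:
        raise KeyError(f"no published kit markers for target {target!r}")
    return dict(zip(rows["marker"], rows["fragment_size_bp"]))
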