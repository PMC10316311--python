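"""Presence/absence genotyping of insertion-site clusters.

Transposon-display markers are dominant: a cultivar either yields the
PCR fragment for an insertion site (1) or it does not (0).  A cluster's
read count is compared with the cultivar's total post-preprocessing read
count; clusters capturing less than ``threshold`` (default 0.1%) of a
cultivar's reads are called absent there — low-level read counts at a
site a cultivar does not carry arise from index hopping, PCR chimeras
and sequencing error, and the fractional threshold absorbs them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import InsertionClusterSet

logger = logging.getLogger(__name__)

#: marker ``source`` values with a defined meaning
MARKER_SOURCES = ("InDel", "CIRE1", "Tcs1", "Tcs2", "positive_control")

DEFAULT_ABSENCE_THRESHOLD = 0.001


@dataclass
class GenotypeMatrix:
    """Binary cultivars x markers matrix with per-marker metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by cultivar id with one 0/1 column per marker.
    metadata:
        DataFrame indexed by marker id with columns ``source`` (one of
        :data:`MARKER_SOURCES` or NA) and ``fragment_size`` (bp, NA when
        unknown).  Missing markers are filled with NA rows.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate marker ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1")
        self.data = self.data.astype(np.int8)
        meta = self.metadata
        if meta is None:
            meta = pd.DataFrame(index=pd.Index([], name="marker"),
                                columns=["source", "fragment_size"])
        meta = meta.reindex(self.data.columns)
        meta.index.name = "marker"
        self.metadata = meta
        for marker in self.positive_controls:
            col = self.data[marker]
            if self.n_cultivars and not (col == 1).all():
                raise ValueError(
                    f"positive control {marker!r} absent from some cultivars")

    # -- basic views ---------------------------------------------------
    @property
    def cultivar_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cultivars(self) -> int:
        return self.data.shape[0]

    @property
    def positive_controls(self) -> list[str]:
        src = self.metadata["source"]
        return list(src.index[src == "positive_control"])

    def informative_markers(self) -> list[str]:
        """Marker ids usable for discrimination (controls excluded)."""
        controls = set(self.positive_controls)
        return [m for m in self.marker_ids if m not in controls]

    def presence(self, cultivar: str, marker: str) -> int:
        return int(self.data.at[cultivar, marker])

    def carriers(self, marker: str) -> list[str]:
        """Cultivars possessing the marker fragment."""
        col = self.data[marker]
        return list(col.index[col == 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.data.equals(other.data)


def call_presence(clusters: InsertionClusterSet,
                  threshold: float = DEFAULT_ABSENCE_THRESHOLD) -> GenotypeMatrix:
    """Threshold cluster read counts into a presence/absence matrix.

    A cluster is called absent in a cultivar when its reads make up
    strictly less than ``threshold`` of that cultivar's total reads;
    a count exactly at the threshold is called present.  Cultivars whose
    library produced no reads at all receive an all-zero row and a
    warning, since no call can be made for them.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be a fraction in [0, 1]")
    cultivar_ids = list(clusters.totals)
    rows = []
    for cultivar in cultivar_ids:
        total = clusters.totals[cultivar]
        if total < 0:
            raise ValueError(f"negative read total for {cultivar!r}")
        if total == 0:
            logger.warning(
                "cultivar %r has no reads; emitting an all-absent row", cultivar)
            rows.append([0] * len(clusters.clusters))
            continue
        row = []
        for cl in clusters.clusters:
            count = cl.counts.get(cultivar, 0)
            if count < 0:
                raise ValueError(
                    f"negative count for cultivar {cultivar!r}, cluster {cl.cluster_id!r}")
            row.append(0 if count / total < threshold else 1)
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index(cultivar_ids, name="cultivar"),
                        columns=[cl.cluster_id for cl in clusters.clusters],
                        dtype=np.int8)
    return GenotypeMatrix(data)


def screen_specific(matrix: GenotypeMatrix) -> list[tuple[str, str]]:
    """Markers carried by exactly one cultivar, with that cultivar.

    These are the single-fragment cultivar diagnostics; positive-control
    markers are never reported.
    """
    out = []
    for marker in matrix.informative_markers():
        carriers = matrix.carriers(marker)
        if len(carriers) == 1:
            out.append((marker, carriers[0]))
    return out


def screen_polymorphic(matrix: GenotypeMatrix) -> list[str]:
    """Markers that vary across cultivars (neither all 0 nor all 1)."""
    out = []
    for marker in matrix.informative_markers():
        s = int(matrix.data[marker].sum())
        if 0 < s < matrix.n_cultivars:
            out.append(marker)
    return out
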