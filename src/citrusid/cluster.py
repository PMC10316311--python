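"""Greedy seeded-Hamming clustering of trimmed flank 50-mers.

Each retrotransposon insertion site contributes a distinct genomic
flanking sequence, so after preprocessing the distinct 50-mers fall into
tight groups: the true flank plus its sequencing-error satellites.  The
clusterer assigns every distinct sequence to a representative by a
greedy rule — process sequences in descending total multiplicity
(lexicographic tie-break) and join the earliest cluster whose
representative both shares at least one exact k-mer with the sequence
and lies within a small Hamming distance of it; otherwise found a new
cluster.  The defaults (8-mer seed, 2 mismatches) mirror the tile-size /
one-off intent of BLAT-style self-alignment clustering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

READ_LENGTH = 50


@dataclass(frozen=True)
class ClusterParams:
    seed_kmer: int = 8
    max_mismatch: int = 2
    min_cluster_reads: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.seed_kmer <= READ_LENGTH:
            raise ValueError("seed_kmer must be in [1, 50]")
        if not 0 <= self.max_mismatch <= 5:
            raise ValueError("max_mismatch must be in [0, 5]")
        if self.min_cluster_reads < 1:
            raise ValueError("min_cluster_reads must be >= 1")


@dataclass
class Cluster:
    cluster_id: str
    representative: str
    counts: dict[str, int] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class InsertionClusterSet:
    """Clusters plus the per-cultivar totals the 0.1% rule divides by."""

    clusters: list[Cluster]
    totals: dict[str, int]

    def __post_init__(self) -> None:
        per_cultivar: Counter[str] = Counter()
        for cl in self.clusters:
            per_cultivar.update(cl.counts)
        for cultivar, assigned in per_cultivar.items():
            if assigned > self.totals.get(cultivar, 0):
                raise ValueError(
                    f"cluster counts for {cultivar!r} exceed library total")

    def __len__(self) -> int:
        return len(self.clusters)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _ordered_sequences(reads_by_cultivar: Mapping[str, Mapping[str, int]]
                       ) -> tuple[list[str], dict[str, dict[str, int]]]:
    """Distinct sequences in processing order, plus per-sequence counts."""
    per_seq: dict[str, dict[str, int]] = {}
    for cultivar, counts in reads_by_cultivar.items():
        for seq, mult in counts.items():
            if len(seq) != READ_LENGTH:
                raise ValueError(
                    f"sequence of length {len(seq)} (expected {READ_LENGTH}): "
                    f"trim reads before clustering")
            if mult < 0:
                raise ValueError("negative multiplicity")
            per_seq.setdefault(seq, {})
            per_seq[seq][cultivar] = per_seq[seq].get(cultivar, 0) + mult
    order = sorted(per_seq, key=lambda s: (-sum(per_seq[s].values()), s))
    return order, per_seq


def cluster_reads(reads_by_cultivar: Mapping[str, Mapping[str, int]],
                  params: ClusterParams = ClusterParams()) -> InsertionClusterSet:
    """Cluster per-cultivar 50-mer multiplicity maps into insertion sites.

    ``reads_by_cultivar`` maps cultivar id -> {sequence: multiplicity},
    as produced by the duplicate-collapse step.  Totals are taken as
    each cultivar's summed multiplicities.  Determinism: the processing
    order (multiplicity-descending, then lexicographic) and the
    first-founded-cluster join rule make the output a pure function of
    the input multiset.
    """
    order, per_seq = _ordered_sequences(reads_by_cultivar)
    clusters: list[Cluster] = []
    kmer_index: dict[str, set[int]] = {}
    k = params.seed_kmer
    for seq in order:
        candidates: set[int] = set()
        for kmer in _kmers(seq, k):
            candidates.update(kmer_index.get(kmer, ()))
        chosen = None
        for idx in sorted(candidates):
            if hamming(seq, clusters[idx].representative) <= params.max_mismatch:
                chosen = clusters[idx]
                break
        if chosen is None:
            chosen = Cluster(cluster_id=f"site{len(clusters) + 1:04d}",
                             representative=seq)
            idx = len(clusters)
            clusters.append(chosen)
            for kmer in _kmers(seq, k):
                kmer_index.setdefault(kmer, set()).add(idx)
        chosen.members.append(seq)
        for cultivar, mult in per_seq[seq].items():
            chosen.counts[cultivar] = chosen.counts.get(cultivar, 0) + mult
    totals = {cultivar: sum(counts.values())
              for cultivar, counts in reads_by_cultivar.items()}
    kept = [cl for cl in clusters if cl.total >= params.min_cluster_reads]
    return InsertionClusterSet(clusters=kept, totals=totals)


def counts_from_reads(reads: Iterable[str]) -> dict[str, int]:
    """Convenience: fold an iterable of sequences into a multiplicity map."""
    return dict(Counter(reads))
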