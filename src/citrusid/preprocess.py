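"""Read filtering for transposon-display libraries.

The pipeline order is fixed and mirrors the analysis narrative:
strip the 5' element-end tag, trim the 3' ligation adapter, drop
low-quality reads (mean QV < 30), cut everything to a uniform 50 bp,
then collapse heavily duplicated sequences (>= 10 identical copies
become a single representative) so PCR amplification bias cannot
masquerade as read support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")

    @property
    def mean_qv(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0

    def slice(self, start: int, stop: int | None = None) -> "ReadRecord":
        return ReadRecord(self.id, self.sequence[start:stop],
                          self.qualities[start:stop])


@dataclass(frozen=True)
class PreprocessParams:
    adapter_sequence: str
    min_qv: int = 30
    trim_length: int = 50
    collapse_threshold: int = 10
    retro_tag: str | None = None
    tag_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.adapter_sequence:
            raise ValueError("adapter_sequence must be non-empty")
        if self.trim_length < 1:
            raise ValueError("trim_length must be >= 1")
        if self.collapse_threshold < 2:
            raise ValueError("collapse_threshold must be >= 2")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(rec.id, str(rec.seq).upper(),
                         tuple(rec.letter_annotations["phred_quality"]))


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def strip_tag(read: ReadRecord, retro_tag: str, max_mismatch: int = 1
              ) -> ReadRecord | None:
    """Remove the element-end tag prefix; None when the tag is absent.

    Reads not starting with the tag (within ``max_mismatch``
    substitutions) did not originate from element-anchored PCR and are
    dropped.
    """
    if len(read.sequence) < len(retro_tag):
        return None
    if _mismatches(read.sequence[:len(retro_tag)], retro_tag) > max_mismatch:
        return None
    return read.slice(len(retro_tag))


def trim_adapter(read: ReadRecord, adapter_sequence: str) -> ReadRecord:
    """Truncate at the leftmost adapter occurrence; no-op when absent.

    A match at position i covers L = min(len(adapter), len(read) - i)
    bases (an adapter running off the 3' end counts with its visible
    prefix).  Accepted when exact over the full adapter, or with at
    most one mismatch when L >= 8 — enough slack for simulated
    sequencing errors without full alignment.
    """
    if not adapter_sequence:
        raise ValueError("adapter_sequence must be non-empty")
    seq = read.sequence
    for i in range(len(seq)):
        overlap = min(len(adapter_sequence), len(seq) - i)
        window = seq[i:i + overlap]
        mm = _mismatches(window, adapter_sequence[:overlap])
        if (mm == 0 and overlap == len(adapter_sequence)) or (overlap >= 8 and mm <= 1):
            return read.slice(0, i)
    return read


def quality_filter(reads: Iterable[ReadRecord], min_qv: int = 30
                   ) -> list[ReadRecord]:
    """Keep reads whose mean QV is at least ``min_qv``."""
    if min_qv < 0:
        raise ValueError("min_qv must be >= 0")
    return [r for r in reads if r.mean_qv >= min_qv]


def fixed_length_trim(reads: Iterable[ReadRecord], trim_length: int = 50
                      ) -> list[ReadRecord]:
    """Cut every read to its ``trim_length`` prefix; discard shorter reads."""
    if trim_length < 1:
        raise ValueError("trim_length must be >= 1")
    return [r.slice(0, trim_length) for r in reads
            if len(r.sequence) >= trim_length]


def collapse_duplicates(reads: Iterable[ReadRecord] | Iterable[str],
                        collapse_threshold: int = 10) -> dict[str, int]:
    """Collapse identical sequences with >= threshold copies to one.

    Returns {sequence: multiplicity} with deterministic (lexicographic)
    key order.  Multiplicities below the threshold are preserved as-is;
    at or above it they are reduced to 1, removing PCR-duplication
    weight while keeping the sequence observed.
    """
    if collapse_threshold < 2:
        raise ValueError("collapse_threshold must be >= 2")
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"unequal read lengths {sorted(lengths)}: trim first")
    counts = Counter(seqs)
    return {seq: (1 if m >= collapse_threshold else m)
            for seq, m in sorted(counts.items())}


def preprocess_reads(reads: Iterable[ReadRecord],
                     params: PreprocessParams) -> dict[str, int]:
    """Full per-library pipeline -> {50-mer: multiplicity}."""
    stream: Iterable[ReadRecord] = reads
    if params.retro_tag:
        stripped = (strip_tag(r, params.retro_tag, params.tag_max_mismatch)
                    for r in stream)
        stream = [r for r in stripped if r is not None]
    stream = [trim_adapter(r, params.adapter_sequence) for r in stream]
    stream = quality_filter(stream, params.min_qv)
    stream = fixed_length_trim(stream, params.trim_length)
    return collapse_duplicates(stream, params.collapse_threshold)


def preprocess_fastq(path: str | Path, params: PreprocessParams) -> dict[str, int]:
    return preprocess_reads(read_fastq(path), params)


def write_collapsed_fasta(collapsed: dict[str, int], path: str | Path) -> None:
    """Collapsed reads as FASTA, multiplicity recorded in the header."""
    with Path(path).open("w") as fh:
        for i, (seq, mult) in enumerate(collapsed.items(), start=1):
            fh.write(f">seq{i:06d} multiplicity={mult}\n{seq}\n")
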