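"""Simulation of transposon-display sequencing with known ground truth.

A transposon-display library interrogates one retrotransposon family:
PCR anchored in the element's terminus amplifies outward into the
genomic flank, so read 1 of every on-target fragment begins with the
element-end tag followed by cultivar-dependent flanking sequence and,
when the insert is short, runs into the ligated adapter.  The simulator
draws an :class:`InsertionLandscape` — which cultivars carry which
insertion sites, and each site's flank — and then emits per-cultivar
FASTQ libraries plus a read-level truth table, so every downstream
stage (trimming, clustering, the 0.1% presence rule, marker screening)
can be scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

FAMILIES = ("CIRE1", "Tcs1", "Tcs2")
ALPHABET = "ACGT"

#: element-end tag carried at the 5' end of every on-target read (30 bp);
#: a stand-in for the retrotransposon LTR-terminus primer sequence.
DEFAULT_RETRO_TAG = "TGTTGGAATCCCATGGCATACGTGACTCGA"
#: ligated adapter encountered at the 3' end of short inserts (33 bp).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

BACKGROUND_SITE_ID = "background"


@dataclass(frozen=True)
class Site:
    site_id: str
    family: str
    flank: str


@dataclass
class InsertionLandscape:
    """Ground truth: cultivars x insertion sites with flank sequences."""

    cultivar_ids: list[str]
    sites: list[Site]
    truth: np.ndarray  # shape (n_cultivars, n_sites), dtype int8

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=np.int8)
        if self.truth.shape != (len(self.cultivar_ids), len(self.sites)):
            raise ValueError("truth matrix shape does not match labels")
        if self.truth.size and not np.isin(self.truth, (0, 1)).all():
            raise ValueError("truth entries must be 0/1")
        if self.truth.size and (self.truth.sum(axis=0) == 0).any():
            raise ValueError("every site must be present in at least one cultivar")

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivar_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def present_sites(self, cultivar: str) -> list[Site]:
        row = self.truth[self.cultivar_ids.index(cultivar)]
        return [site for site, bit in zip(self.sites, row) if bit]

    def specific_site_count(self) -> int:
        """Number of sites carried by exactly one cultivar."""
        return int((self.truth.sum(axis=0) == 1).sum())

    # -- serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "cultivar_ids": self.cultivar_ids,
            "sites": [asdict(s) for s in self.sites],
            "truth": self.truth.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "InsertionLandscape":
        payload = json.loads(Path(path).read_text())
        return cls(cultivar_ids=payload["cultivar_ids"],
                   sites=[Site(**s) for s in payload["sites"]],
                   truth=np.asarray(payload["truth"], dtype=np.int8))


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-emulation knobs.

    depth is the exact number of template reads emitted per present site
    per cultivar before duplicate amplification; duplicate_multiplier is
    an inclusive integer range (lo, hi) from which each template's copy
    number is drawn uniformly.  Qualities follow a two-point mixture: a
    read either passes (constant ``qv_pass`` per base) or fails
    (``qv_fail``), with failure probability ``qv_fail_rate`` — enough
    structure to exercise a mean-QV >= 30 filter without modelling
    per-cycle quality decay.
    """

    read_length: int = 150
    depth: int = 20
    error_rate: float = 0.0
    duplicate_multiplier: tuple[int, int] = (1, 3)
    adapter_sequence: str = DEFAULT_ADAPTER
    retro_tag: str = DEFAULT_RETRO_TAG
    seed: int = 0
    background_fraction: float = 0.0
    qv_pass: int = 38
    qv_fail: int = 20
    qv_fail_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.read_length < len(self.retro_tag) + 50:
            raise ValueError("read_length must cover the tag plus a 50 bp flank")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        lo, hi = self.duplicate_multiplier
        if not 1 <= lo <= hi:
            raise ValueError("duplicate_multiplier must be 1 <= lo <= hi")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if not 0 <= self.qv_fail_rate <= 1:
            raise ValueError("qv_fail_rate must be a probability")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def simulate_landscape(n_cultivars: int,
                       n_sites: int,
                       specific_fraction: float = 0.3,
                       seed: int = 0,
                       flank_length: int = 100,
                       family: str | None = None,
                       min_flank_distance: int = 5,
                       cultivar_ids: list[str] | None = None) -> InsertionLandscape:
    """Draw a ground-truth insertion landscape.

    Exactly ``round(specific_fraction * n_sites)`` sites are made
    cultivar-specific (present in one cultivar only); the rest are
    shared by at least two cultivars (or by the single cultivar when
    ``n_cultivars == 1``).  Flanks are rejection-sampled so that every
    pair differs at more than ``2 * max_mismatch`` positions over the
    first 50 bases (``min_flank_distance`` = 2*2 + 1 by default),
    keeping downstream clusters unambiguous.
    """
    if n_cultivars < 1 or n_sites < 1:
        raise ValueError("need at least one cultivar and one site")
    if not 0 <= specific_fraction <= 1:
        raise ValueError("specific_fraction must be in [0, 1]")
    if flank_length < 50:
        raise ValueError("flank_length must be >= 50")
    if family is not None and family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    rng = np.random.default_rng(seed)

    if cultivar_ids is None:
        cultivar_ids = [f"cv{i + 1:02d}" for i in range(n_cultivars)]

    # flanks: rejection sampling against the pairwise-distance invariant
    flanks: list[str] = []
    prefixes: list[str] = []
    attempts_cap = 200 * n_sites + 1000
    attempts = 0
    while len(flanks) < n_sites:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError(
                f"could not draw {n_sites} flanks of length {flank_length} with "
                f"pairwise 50-mer distance > {min_flank_distance - 1}: "
                "too many sites for this flank length/alphabet")
        cand = _random_seq(rng, flank_length)
        p = cand[:50]
        if all(hamming50(p, q) >= min_flank_distance for q in prefixes):
            flanks.append(cand)
            prefixes.append(p)

    families = ([family] * n_sites if family is not None
                else [FAMILIES[i] for i in rng.integers(0, len(FAMILIES), n_sites)])
    sites = [Site(site_id=f"{fam}-S{i + 1:04d}", family=fam, flank=fl)
             for i, (fam, fl) in enumerate(zip(families, flanks))]

    n_specific = round(specific_fraction * n_sites)
    truth = np.zeros((n_cultivars, n_sites), dtype=np.int8)
    specific_cols = rng.choice(n_sites, size=n_specific, replace=False)
    specific_set = set(int(c) for c in specific_cols)
    for col in range(n_sites):
        if col in specific_set:
            truth[rng.integers(0, n_cultivars), col] = 1
        elif n_cultivars == 1:
            truth[0, col] = 1
        else:
            # shared site: carried by >= 2 cultivars
            size = int(rng.integers(2, n_cultivars + 1))
            rows = rng.choice(n_cultivars, size=size, replace=False)
            truth[rows, col] = 1
    return InsertionLandscape(cultivar_ids=cultivar_ids, sites=sites, truth=truth)


def hamming50(a: str, b: str) -> int:
    """Mismatch count over the first 50 bases."""
    return sum(x != y for x, y in zip(a[:50], b[:50]))


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in ALPHABET if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _assemble(flank: str, config: SimConfig) -> str:
    """tag + flank + adapter remnant, truncated to read_length."""
    read = config.retro_tag + flank
    while len(read) < config.read_length:
        read += config.adapter_sequence
    return read[:config.read_length]


def generate_reads(landscape: InsertionLandscape,
                   config: SimConfig,
                   out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTQ per cultivar plus ``truth.tsv`` and ``landscape.json``.

    Returns a mapping cultivar id -> FASTQ path.  Deterministic for a
    fixed (landscape, config): byte-identical files on re-run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    fastq_paths: dict[str, Path] = {}
    truth_rows: list[tuple[str, str, str]] = []

    for cultivar in landscape.cultivar_ids:
        records: list[tuple[str, str, str]] = []  # (read_id, seq, site_id)
        serial = 0

        def emit(template: str, site_id: str) -> None:
            nonlocal serial
            n_copies = int(rng.integers(config.duplicate_multiplier[0],
                                        config.duplicate_multiplier[1] + 1))
            for _ in range(n_copies):
                serial += 1
                read_id = f"{cultivar}:r{serial:07d}"
                records.append((read_id, template, site_id))

        n_signal_templates = 0
        for site in landscape.present_sites(cultivar):
            base = _assemble(site.flank, config)
            for _ in range(config.depth):
                emit(_mutate(rng, base, config.error_rate), site.site_id)
                n_signal_templates += 1
        n_background = round(config.background_fraction * n_signal_templates
                             / max(1e-12, 1 - config.background_fraction))
        for _ in range(int(n_background)):
            junk = _assemble(_random_seq(rng, config.read_length), config)
            emit(_mutate(rng, junk, config.error_rate), BACKGROUND_SITE_ID)

        path = out_dir / f"{cultivar}.fastq"
        with path.open("w") as fh:
            for read_id, seq, site_id in records:
                qv = (config.qv_fail if rng.random() < config.qv_fail_rate
                      else config.qv_pass)
                qual = chr(qv + 33) * len(seq)
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
                truth_rows.append((read_id, site_id, cultivar))
        fastq_paths[cultivar] = path

    with (out_dir / "truth.tsv").open("w") as fh:
        fh.write("read_id\tsite_id\tcultivar\n")
        for read_id, site_id, cultivar in truth_rows:
            fh.write(f"{read_id}\t{site_id}\t{cultivar}\n")
    landscape.to_json(out_dir / "landscape.json")
    return fastq_paths
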