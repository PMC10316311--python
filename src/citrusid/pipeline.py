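"""End-to-end pipeline: simulate -> preprocess -> cluster -> genotype ->
marker selection -> kit design -> band prediction.

Every stage is a thin call into the corresponding module; this file only
wires them together, writes the output bundle, and records a manifest
with SHA-256 checksums so a re-run with the same configuration can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cluster as cluster_mod
from . import genotype as genotype_mod
from . import io as io_mod
from . import kitsim, landscape as landscape_mod, markerselect, preprocess

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulation block (ignored when fastq_dir or matrix_tsv is given)
    n_cultivars: int = 8
    n_sites: int = 40
    specific_fraction: float = 0.3
    depth: int = 20
    error_rate: float = 0.0
    background_fraction: float = 0.0
    # preprocessing / clustering / genotyping
    min_qv: int = 30
    trim_length: int = 50
    collapse_threshold: int = 10
    seed_kmer: int = 8
    max_mismatch: int = 2
    threshold: float = genotype_mod.DEFAULT_ABSENCE_THRESHOLD
    # marker selection / kit design
    max_k: int = markerselect.DEFAULT_MAX_K
    min_separation: int = kitsim.DEFAULT_MIN_SEPARATION
    targets: list[str] = field(default_factory=list)
    # alternative inputs
    fastq_dir: str | None = None
    matrix_tsv: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _genotype_from_fastq_dir(fastq_dir: Path, config: PipelineConfig,
                             sim: landscape_mod.SimConfig
                             ) -> genotype_mod.GenotypeMatrix:
    params = preprocess.PreprocessParams(
        adapter_sequence=sim.adapter_sequence,
        min_qv=config.min_qv,
        trim_length=config.trim_length,
        collapse_threshold=config.collapse_threshold,
        retro_tag=sim.retro_tag)
    collapsed = {}
    for path in sorted(fastq_dir.glob("*.fastq")):
        collapsed[path.stem] = preprocess.preprocess_fastq(path, params)
    clusters = cluster_mod.cluster_reads(
        collapsed, cluster_mod.ClusterParams(seed_kmer=config.seed_kmer,
                                             max_mismatch=config.max_mismatch))
    return genotype_mod.call_presence(clusters, config.threshold)


def _with_positive_control(matrix: genotype_mod.GenotypeMatrix
                           ) -> genotype_mod.GenotypeMatrix:
    """Append an all-present rbcL control column (simulated assays only)."""
    if "rbcL" in matrix.data.columns:
        return matrix
    data = matrix.data.copy()
    data["rbcL"] = 1
    meta = matrix.metadata.reindex(data.columns)
    meta.loc["rbcL", "source"] = "positive_control"
    meta.loc["rbcL", "fragment_size"] = 622
    return genotype_mod.GenotypeMatrix(data, meta)


def _pseudo_sizes(markers, start: int = 150, step: int = 35) -> dict[str, int]:
    """Deterministic well-separated amplicon sizes for simulated markers."""
    sizes = {"rbcL": 622}
    for i, m in enumerate(sorted(markers)):
        sizes[m] = start + step * i
    return sizes


def _matches_truth(matrix: genotype_mod.GenotypeMatrix,
                   truth: landscape_mod.InsertionLandscape) -> bool:
    """Called matrix equals the simulated truth up to column relabelling.

    Cluster ids are arbitrary, so columns are compared as multisets of
    cultivar-profiles with rows aligned on cultivar id.
    """
    if sorted(matrix.cultivar_ids) != sorted(truth.cultivar_ids):
        return False
    called = matrix.data.loc[truth.cultivar_ids].to_numpy()
    want = sorted(map(tuple, truth.truth.T.tolist()))
    got = sorted(map(tuple, called.T.tolist()))
    return want == got


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return a summary dict (also on disk).

    Outputs under ``config.out_dir``: genotype_matrix.tsv,
    specific_markers.tsv, marker_sets.json, kits.json,
    band_patterns.tsv, run_log.txt, manifest.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed}",
                 f"config={json.dumps(dataclasses.asdict(config), sort_keys=True)}"]

    sim = landscape_mod.SimConfig(depth=config.depth,
                                  error_rate=config.error_rate,
                                  background_fraction=config.background_fraction,
                                  seed=config.seed)
    truth = None
    if config.matrix_tsv is not None:
        matrix = io_mod.load_genotype_tsv(config.matrix_tsv)
        log_lines.append(f"stage=load matrix={config.matrix_tsv}")
    else:
        if config.fastq_dir is not None:
            fastq_dir = Path(config.fastq_dir)
            log_lines.append(f"stage=input fastq_dir={fastq_dir}")
        else:
            scape = landscape_mod.simulate_landscape(
                config.n_cultivars, config.n_sites,
                specific_fraction=config.specific_fraction, seed=config.seed)
            fastq_dir = out_dir / "reads"
            landscape_mod.generate_reads(scape, sim, fastq_dir)
            truth = scape
            log_lines.append(
                f"stage=simulate cultivars={scape.n_cultivars} sites={scape.n_sites}")
        matrix = _genotype_from_fastq_dir(fastq_dir, config, sim)
        log_lines.append(
            f"stage=genotype cultivars={matrix.n_cultivars} "
            f"markers={len(matrix.marker_ids)}")

    matrix_path = out_dir / "genotype_matrix.tsv"
    io_mod.write_genotype_tsv(matrix, matrix_path)

    specific = genotype_mod.screen_specific(matrix)
    with (out_dir / "specific_markers.tsv").open("w") as fh:
        fh.write("marker\tcultivar\n")
        for marker, cultivar in specific:
            fh.write(f"{marker}\t{cultivar}\n")

    kit_matrix = _with_positive_control(matrix)
    targets = config.targets or sorted({c for _, c in specific})
    sizes_known = config.matrix_tsv is None and config.fastq_dir is None
    sizes_all = _pseudo_sizes(matrix.marker_ids) if sizes_known else None

    sets_out, kits_out, band_rows = {}, {}, []
    for target in targets:
        mset = markerselect.minimal_and_set(kit_matrix, target, config.max_k)
        sets_out[target] = {"members": list(mset.members), "size": mset.size,
                            "unique": mset.unique}
        if not mset.unique:
            log_lines.append(f"stage=select target={target} unique=False")
            continue
        try:
            sizes = sizes_all if sizes_all is not None else io_mod.kit_sizes(target)
            kit = kitsim.design_kit(mset, sizes,
                                    min_separation=config.min_separation)
        except (KeyError, ValueError) as exc:
            log_lines.append(f"stage=kit target={target} skipped: {exc}")
            continue
        kits_out[target] = {"members": list(kit.members),
                            "lines": dict(kit.lines),
                            "fragment_sizes": dict(kit.fragment_sizes)}
        for sample in kit_matrix.cultivar_ids:
            pattern = kitsim.predict_bands(kit, kit_matrix, sample)
            band_rows.append((target, sample, pattern.band_count,
                              kitsim.diagnose(pattern)))

    (out_dir / "marker_sets.json").write_text(json.dumps(sets_out, indent=1))
    (out_dir / "kits.json").write_text(json.dumps(kits_out, indent=1))
    with (out_dir / "band_patterns.tsv").open("w") as fh:
        fh.write("kit_target\tsample\tband_count\tverdict\n")
        for row in band_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    summary = {
        "n_cultivars": matrix.n_cultivars,
        "n_markers": len(matrix.marker_ids),
        "n_specific_markers": len(specific),
        "targets": targets,
        "truth_recovered": (None if truth is None
                            else _matches_truth(matrix, truth)),
    }
    log_lines.append(f"summary={json.dumps(summary, sort_keys=True)}")
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    manifest = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
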