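"""Read filtering: tag strip, adapter trim, QV filter, trim, collapse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import citrusid as c
from citrusid.landscape import DEFAULT_ADAPTER, DEFAULT_RETRO_TAG
from citrusid.preprocess import preprocess_reads, read_fastq, strip_tag

def rec(seq: str, qv: int = 40, rid: str = "r") -> c.ReadRecord:
    return c.ReadRecord(rid, seq, tuple([qv] * len(seq)))


class TestTrimAdapter:
    def test_no_adapter_is_noop(self):
        r = rec("ACGT" * 10)
        assert c.trim_adapter(r, DEFAULT_ADAPTER) == r

    def test_full_adapter_suffix_removed(self):
        insert = "ACGTACGTACGTACGTACGT"
        r = rec(insert + DEFAULT_ADAPTER)
        trimmed = c.trim_adapter(r, DEFAULT_ADAPTER)
        assert trimmed.sequence == insert
        assert len(trimmed.qualities) == len(insert)

    def test_partial_suffix_with_one_mismatch(self):
        insert = "TTTTGGGGCCCCAAAA"
        remnant = list(DEFAULT_ADAPTER[:12])
        remnant[5] = "A" if remnant[5] != "A" else "C"
        r = rec(insert + "".join(remnant))
        assert c.trim_adapter(r, DEFAULT_ADAPTER).sequence == insert

    def test_short_remnant_not_trimmed(self):
        # a 5 bp adapter prefix is below the match-length floor
        insert = "TTTTGGGGCCCCAAAA"
        r = rec(insert + DEFAULT_ADAPTER[:5])
        assert c.trim_adapter(r, DEFAULT_ADAPTER) == r

    def test_simulated_offsets_recovered(self):
        """Adapters placed at known offsets come off at those offsets."""
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for _ in range(100):
            n = int(rng.integers(20, 80))
            insert = "".join(bases[i] for i in rng.integers(0, 4, n))
            read = rec((insert + DEFAULT_ADAPTER * 3)[:120])
            trimmed = c.trim_adapter(read, DEFAULT_ADAPTER)
            # guard against a chance internal adapter-like match
            if DEFAULT_ADAPTER[:8] not in insert:
                assert len(trimmed.sequence) == min(n, 120)


class TestStripTag:
    def test_exact_tag_removed(self):
        r = rec(DEFAULT_RETRO_TAG + "ACGT" * 20)
        out = strip_tag(r, DEFAULT_RETRO_TAG)
        assert out.sequence == "ACGT" * 20

    def test_offtarget_read_dropped(self):
        r = rec("T" * 150)
        assert strip_tag(r, DEFAULT_RETRO_TAG) is None


class TestQualityFilter:
    def test_pass_and_fail(self):
        keep = rec("ACGT" * 10, qv=40, rid="hi")
        drop = rec("ACGT" * 10, qv=20, rid="lo")
        out = c.quality_filter([keep, drop], 30)
        assert out == [keep]

    def test_empty_input(self):
        assert c.quality_filter([], 30) == []

    def test_mean_rule_on_mixed_qualities(self):
        # mean 30 exactly -> retained (>= threshold)
        r = c.ReadRecord("m", "ACGT", (20, 40, 20, 40))
        assert c.quality_filter([r], 30) == [r]

    def test_simulator_two_point_mixture(self, tmp_path):
        """Retained count equals the simulator's pass-QV draw count."""
        scape = c.simulate_landscape(2, 5, specific_fraction=0.2, seed=4)
        config = c.SimConfig(depth=30, qv_fail_rate=0.4, seed=4,
                             duplicate_multiplier=(1, 1))
        paths = c.generate_reads(scape, config, tmp_path)
        for path in paths.values():
            reads = list(read_fastq(path))
            n_pass_truth = sum(r.qualities[0] >= 30 for r in reads)
            assert len(c.quality_filter(reads, 30)) == n_pass_truth


class TestFixedLengthTrim:
    def test_prefix_of_150mer(self):
        r = rec("A" * 100 + "C" * 50)
        (out,) = c.fixed_length_trim([r], 50)
        assert out.sequence == "A" * 50

    def test_short_read_discarded(self):
        assert c.fixed_length_trim([rec("A" * 49)], 50) == []

    def test_output_lengths_point_mass(self):
        rng = np.random.default_rng(3)
        reads = [rec("A" * int(n)) for n in rng.integers(30, 200, 50)]
        out = c.fixed_length_trim(reads, 50)
        assert {len(r.sequence) for r in out} == {50}
        assert len(out) == sum(len(r.sequence) >= 50 for r in reads)


class TestCollapseDuplicates:
    def test_twelve_copies_become_one(self):
        out = c.collapse_duplicates(["A" * 50] * 12, 10)
        assert out == {"A" * 50: 1}

    def test_nine_copies_kept(self):
        out = c.collapse_duplicates(["C" * 50] * 9, 10)
        assert out == {"C" * 50: 9}

    def test_distinct_sequences_preserved(self):
        rng = np.random.default_rng(8)
        pool = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50))
                for _ in range(20)]
        reads = [pool[int(i)] for i in rng.integers(0, 20, 400)]
        out = c.collapse_duplicates(reads, 10)
        assert set(out) == set(reads)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="trim first"):
            c.collapse_duplicates(["AAAA", "AAA"], 10)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["AA", "AC", "AG", "AT", "CC"]),
                    max_size=60))
    def test_idempotent(self, seqs):
        once = c.collapse_duplicates(seqs, 10) if seqs else {}
        twice = (c.collapse_duplicates(
            [s for s, m in once.items() for _ in range(m)], 10)
            if once else {})
        assert once == twice


def test_pipeline_recovers_flank_prefixes(noisefree_sim):
    """Full preprocessing of an error-free library leaves exactly the
    flank 50-prefixes of the cultivar's present sites."""
    scape, config, out, paths = noisefree_sim
    params = c.PreprocessParams(adapter_sequence=config.adapter_sequence,
                                retro_tag=config.retro_tag)
    for cultivar, path in paths.items():
        collapsed = c.preprocess_fastq(path, params)
        expected = {site.flank[:50] for site in scape.present_sites(cultivar)}
        assert set(collapsed) == expected
        # depth 12 >= collapse threshold 10 -> every multiplicity reduced to 1
        assert set(collapsed.values()) == {1}


def test_quality_filter_never_alters_sequences(noisefree_sim):
    scape, config, out, paths = noisefree_sim
    reads = list(read_fastq(next(iter(paths.values()))))
    out_reads = c.quality_filter(reads, 30)
    assert all(r.sequence in {x.sequence for x in reads} for r in out_reads)
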