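"""Kit assembly, strip band prediction and three-way diagnosis."""

from itertools import chain, combinations

import pytest

import citrusid as c
from citrusid.kitsim import (BandPattern, NO_TEMPLATE_CONTROL, VERDICT_INVALID,
                             VERDICT_NON_TARGET, VERDICT_TARGET)


class TestDesignKit:
    def test_rinoka_two_line_kit(self, reference_matrix, published_kits):
        kit = published_kits["Rinoka"]
        assert kit.members == ("IND141-l",)
        assert kit.lines == {"rbcL": 1, "IND141-l": 2}

    def test_kanpei_sizes_separated(self, published_kits):
        kit = published_kits["Kanpei"]
        sizes = list(kit.fragment_sizes.values())
        gaps = [abs(a - b) for a, b in combinations(sizes, 2)]
        assert min(gaps) >= 30
        assert len(kit.lines) == 4

    def test_member_lines_ordered_by_size(self, published_kits):
        for kit in published_kits.values():
            ordered = sorted(kit.members,
                             key=lambda m: -kit.fragment_sizes[m])
            assert list(kit.members) == ordered
            assert [kit.lines[m] for m in kit.members] == \
                list(range(2, 2 + len(kit.members)))

    def test_four_members_exceed_strip(self):
        mset = c.MarkerSet(target="t", members=("a", "b", "c", "d"),
                           unique=True)
        sizes = {"rbcL": 622, "a": 100, "b": 200, "c": 300, "d": 400}
        with pytest.raises(ValueError, match="line"):
            c.design_kit(mset, sizes)

    def test_size_clash_names_pair(self):
        mset = c.MarkerSet(target="t", members=("a", "b"), unique=True)
        sizes = {"rbcL": 622, "a": 200, "b": 215}
        with pytest.raises(ValueError, match="a .* vs .*b"):
            c.design_kit(mset, sizes)

    def test_non_unique_set_rejected(self):
        mset = c.MarkerSet(target="t", members=("a",), unique=False)
        with pytest.raises(ValueError, match="not unique"):
            c.design_kit(mset, {"rbcL": 622, "a": 100})

    def test_missing_size_rejected(self):
        mset = c.MarkerSet(target="t", members=("a",), unique=True)
        with pytest.raises(KeyError):
            c.design_kit(mset, {"rbcL": 622})


class TestPredictBands:
    def test_kanpei_kit_on_kanpei_four_bands(self, reference_matrix,
                                             published_kits):
        pattern = c.predict_bands(published_kits["Kanpei"], reference_matrix,
                                  "Kanpei")
        assert pattern.band_count == 4

    def test_asumi_and_rinoka_target_bands(self, reference_matrix,
                                           published_kits):
        assert c.predict_bands(published_kits["Asumi"], reference_matrix,
                               "Asumi").band_count == 3
        assert c.predict_bands(published_kits["Rinoka"], reference_matrix,
                               "Rinoka").band_count == 2

    def test_no_template_control_zero_bands(self, reference_matrix,
                                            published_kits):
        pattern = c.predict_bands(published_kits["Kanpei"], reference_matrix,
                                  NO_TEMPLATE_CONTROL)
        assert pattern.band_count == 0

    def test_rinoka_kit_control_only_elsewhere(self, reference_matrix,
                                               published_kits):
        pattern = c.predict_bands(published_kits["Rinoka"], reference_matrix,
                                  "Miyagawa-wase")
        assert pattern.present_lines == frozenset({1})

    def test_kanpei_nontargets_at_most_three_bands(self, reference_matrix,
                                                   published_kits):
        kit = published_kits["Kanpei"]
        counts = [c.predict_bands(kit, reference_matrix, s).band_count
                  for s in reference_matrix.cultivar_ids if s != "Kanpei"]
        assert max(counts) == 3
        assert min(counts) >= 1  # rbcL always amplifies

    def test_band_count_monotone_in_genotype(self, reference_matrix,
                                             published_kits):
        """Adding a presence to a sample's row never removes a band."""
        kit = published_kits["Kanpei"]
        base = c.predict_bands(kit, reference_matrix, "Iyo")
        richer = reference_matrix.data.copy()
        richer.loc["Iyo", list(kit.members)] = 1
        m2 = c.GenotypeMatrix(richer, reference_matrix.metadata)
        grown = c.predict_bands(kit, m2, "Iyo")
        assert base.present_lines <= grown.present_lines


class TestDiagnose:
    def test_all_lines_is_target(self, reference_matrix, published_kits):
        kit = published_kits["Kanpei"]
        pattern = c.predict_bands(kit, reference_matrix, "Kanpei")
        assert c.diagnose(pattern) == VERDICT_TARGET

    def test_missing_control_is_invalid(self, published_kits):
        kit = published_kits["Kanpei"]
        pattern = BandPattern(kit=kit, sample="x",
                              present_lines=frozenset({2, 3}))
        assert c.diagnose(pattern) == VERDICT_INVALID

    def test_partial_members_is_non_target(self, published_kits):
        kit = published_kits["Kanpei"]
        pattern = BandPattern(kit=kit, sample="x",
                              present_lines=frozenset({1, 2}))
        assert c.diagnose(pattern) == VERDICT_NON_TARGET

    def test_verdict_partition_total_and_disjoint(self, published_kits):
        """Every possible line subset receives exactly one verdict."""
        kit = published_kits["Asumi"]
        lines = sorted(kit.lines.values())
        for subset in chain.from_iterable(
                combinations(lines, r) for r in range(len(lines) + 1)):
            verdict = c.diagnose(BandPattern(kit=kit, sample="x",
                                             present_lines=frozenset(subset)))
            assert verdict in {VERDICT_TARGET, VERDICT_NON_TARGET,
                               VERDICT_INVALID}
            if kit.control_line not in subset:
                assert verdict == VERDICT_INVALID
            elif set(kit.member_lines.values()) <= set(subset):
                assert verdict == VERDICT_TARGET
            else:
                assert verdict == VERDICT_NON_TARGET

    def test_all_kits_identify_exactly_their_target(self, reference_matrix,
                                                    published_kits):
        """26 cultivars x 8 kits: verdict is target iff sample == target."""
        for target, kit in published_kits.items():
            for sample in reference_matrix.cultivar_ids:
                verdict = c.diagnose(
                    c.predict_bands(kit, reference_matrix, sample))
                assert (verdict == VERDICT_TARGET) == (sample == target)

    def test_unknown_sample_raises(self, reference_matrix, published_kits):
        with pytest.raises(KeyError):
            c.predict_bands(published_kits["Asumi"], reference_matrix, "Yuzu")
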