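"""Segregation prefilter, single-cut filter, and group co-segregation filter."""

from __future__ import annotations

import math

import pytest

from capsmine.filters import (
    GroupSpec,
    SegregationParams,
    group_filter,
    segregation_filter,
    segregation_test,
    single_cut_filter,
)
from capsmine.mining import CapsMarker, MarkerAllele
from capsmine.v2c import Locus


def _locus(counts, missing=0, n_alt=1):
    """Bi-allelic locus with given (hom-ref, het, hom-alt) class counts."""
    gts = (
        [(0, 0)] * counts[0] + [(0, 1)] * counts[1] + [(1, 1)] * counts[2]
        + [(None, None)] * missing
    )
    samples = [f"s{i}" for i in range(len(gts))]
    return Locus("c1", 100, "A", ["G", "T"][:n_alt], gts, samples)


class TestSegregation:
    def test_perfect_ratio_retained(self):
        stat, p = segregation_test((25, 50, 25))
        assert stat == 0 and p == 1.0
        assert segregation_filter([_locus((25, 50, 25))]) != []

    def test_distorted_ratio_removed(self):
        """Counts (40,40,20): chi2 = 9+2+1 = 12, p = exp(-6) for df=2."""
        stat, p = segregation_test((40, 40, 20))
        assert stat == pytest.approx(12.0)
        assert p == pytest.approx(math.exp(-6.0), rel=1e-9)
        assert segregation_filter([_locus((40, 40, 20))]) == []

    def test_missing_cap(self):
        ok = _locus((25, 50, 25), missing=5)
        too_many = _locus((25, 50, 25), missing=6)
        kept = segregation_filter([ok, too_many])
        assert kept == [ok]

    def test_multiallelic_passes_through_with_warning(self, caplog):
        locus = _locus((40, 40, 20), n_alt=2)
        with caplog.at_level("WARNING"):
            kept = segregation_filter([locus])
        assert kept == [locus]
        assert "multi-allelic" in caplog.text

    def test_custom_ratio(self):
        # 3:1 dominant scoring
        params = SegregationParams(expected_ratio=(3.0, 1.0, 0.0001))
        stat, p = segregation_test((75, 25, 0), params.expected_ratio)
        assert p > 0.9

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SegregationParams(alpha=1.5)
        with pytest.raises(ValueError):
            SegregationParams(expected_ratio=(1, 0, 1))

    def test_idempotent(self):
        loci = [_locus((25, 50, 25)), _locus((40, 40, 20)),
                _locus((25, 50, 25), missing=7)]
        once = segregation_filter(loci)
        assert segregation_filter(once) == once


def _marker(ctx_ref, ctx_alt, gts=None, samples=None, site="T'CGA"):
    gts = gts if gts is not None else [(0, 0), (0, 1), (1, 1)]
    samples = samples or [f"s{i}" for i in range(len(gts))]
    return CapsMarker(
        "c1:100", ("TaqI",), site,
        [MarkerAllele("ref", 0, "T", True, ctx_ref),
         MarkerAllele("alt", 1, "G", False, ctx_alt)],
        samples, gts,
    )


class TestSingleCut:
    UP, DOWN = "g" * 80, "c" * 80

    def test_clean_marker_retained(self):
        m = _marker(self.UP + "TCGA" + self.DOWN, self.UP + "TGGA" + self.DOWN)
        assert single_cut_filter([m]) == [m]

    def test_second_constitutive_site_removed(self):
        up2 = "g" * 40 + "tcga" + "g" * 36  # extra TaqI site in the flank
        m = _marker(up2 + "TCGA" + self.DOWN, up2 + "TGGA" + self.DOWN)
        assert single_cut_filter([m]) == []

    def test_hit_on_undigested_allele_removed(self):
        # context disagrees with the recorded flag: treated as multi-cut
        m = _marker(self.UP + "TCGA" + self.DOWN, self.UP + "TCGA" + self.DOWN)
        assert single_cut_filter([m]) == []

    def test_minus_strand_hit_counts(self):
        # non-palindromic GACGC on the minus strand of the digested allele
        m = _marker(self.UP + "GCGTC" + self.DOWN, self.UP + "GGGTC" + self.DOWN,
                    site="GACGC")
        assert single_cut_filter([m]) == [m]
        up2 = "g" * 40 + "gacgc" + "g" * 35
        m2 = _marker(up2 + "GCGTC" + self.DOWN, up2 + "GGGTC" + self.DOWN,
                     site="GACGC")
        assert single_cut_filter([m2]) == []

    def test_subset_and_idempotent(self, small_fixture, enzyme_groups):
        from capsmine.mining import mine
        from capsmine.reference_io import build_fasta_index
        from capsmine.v2c import convert_vcf

        idx = build_fasta_index(small_fixture.reference_path)
        records, samples = convert_vcf(small_fixture.vcf_path, idx)
        markers = mine(records, enzyme_groups, samples, reference=idx)
        kept = single_cut_filter(markers)
        assert set(id(m) for m in kept) <= set(id(m) for m in markers)
        assert single_cut_filter(kept) == kept


def _cosegregating_marker(n1=10, n2=20, n1_wrong=0, hom="-/-"):
    """Group 1 carries `hom` homozygotes (n1_wrong of them heterozygous),
    group 2 carries the other classes."""
    g1 = [f"a{i}" for i in range(n1)]
    g2 = [f"b{i}" for i in range(n2)]
    hom_gt = (1, 1) if hom == "-/-" else (0, 0)
    gts = [hom_gt] * (n1 - n1_wrong) + [(0, 1)] * n1_wrong
    gts += [(0, 1) if i % 2 else ((0, 0) if hom == "-/-" else (1, 1))
            for i in range(n2)]
    return _marker("x", "y", gts=gts, samples=g1 + g2), g1, g2


class TestGroupFilter:
    def test_mode_a_perfect_three_groups(self):
        m, g1, g2 = _cosegregating_marker(n1=6, n2=12)
        hom_alt = [s for s, (gt, _) in m.sample_digestion().items() if gt == "1/1"]
        het = [s for s, (gt, _) in m.sample_digestion().items() if gt == "0/1"]
        hom_ref = [s for s, (gt, _) in m.sample_digestion().items() if gt == "0/0"]
        spec = GroupSpec(
            groups={"aa": hom_alt, "hh": het, "bb": hom_ref},
            thresholds={"aa": 0.0, "hh": 0.0, "bb": 0.0},
            mode="A",
        )
        assert group_filter([m], spec) == [m]

    def test_mode_a_fails_without_injective_assignment(self):
        # three groups but only two observed genotype classes
        m, g1, g2 = _cosegregating_marker(n1=6, n2=12)
        hom_alt = [s for s, (gt, _) in m.sample_digestion().items() if gt == "1/1"]
        rest = [s for s in m.sample_names if s not in hom_alt]
        spec = GroupSpec(
            groups={"g1": hom_alt, "g2": rest[:5], "g3": rest[5:]},
            thresholds={"g1": 0.0, "g2": 0.0, "g3": 0.0},
            mode="A",
        )
        assert group_filter([m], spec) == []

    def test_mode_b_one_of_ten_mismatch_passes_at_10_percent(self):
        m, g1, g2 = _cosegregating_marker(n1=10, n2=20, n1_wrong=1)
        spec = GroupSpec(groups={"g1": g1, "g2": g2},
                         thresholds={"g1": 0.10, "g2": 0.10}, mode="B")
        assert group_filter([m], spec) == [m]

    def test_mode_b_two_of_ten_mismatch_fails(self):
        m, g1, g2 = _cosegregating_marker(n1=10, n2=20, n1_wrong=2)
        spec = GroupSpec(groups={"g1": g1, "g2": g2},
                         thresholds={"g1": 0.10, "g2": 0.10}, mode="B")
        assert group_filter([m], spec) == []

    def test_mode_b_tries_both_homozygotes_and_labelings(self):
        m, g1, g2 = _cosegregating_marker(hom="+/+")
        # groups passed in the "wrong" order still pass
        spec = GroupSpec(groups={"g2": g2, "g1": g1},
                         thresholds={"g1": 0.0, "g2": 0.0}, mode="B")
        assert group_filter([m], spec) == [m]

    def test_mode_b_fixed_assignment_pins_search(self):
        m, g1, g2 = _cosegregating_marker(hom="-/-")
        spec = GroupSpec(groups={"g1": g1, "g2": g2},
                         thresholds={"g1": 0.0, "g2": 0.0}, mode="B")
        assert group_filter([m], spec, fixed_assignment=("-/-", "g1")) == [m]
        assert group_filter([m], spec, fixed_assignment=("+/+", "g1")) == []

    def test_missing_counts_as_inconsistent(self):
        m, g1, g2 = _cosegregating_marker(n1=10, n2=20)
        m.genotypes[0] = (None, None)  # one group-1 sample now ?/?
        spec0 = GroupSpec(groups={"g1": g1, "g2": g2},
                          thresholds={"g1": 0.0, "g2": 0.0}, mode="B")
        spec10 = GroupSpec(groups={"g1": g1, "g2": g2},
                           thresholds={"g1": 0.10, "g2": 0.10}, mode="B")
        assert group_filter([m], spec0) == []
        assert group_filter([m], spec10) == [m]

    def test_threshold_monotonicity(self):
        m, g1, g2 = _cosegregating_marker(n1=10, n2=20, n1_wrong=1)
        for t in (0.10, 0.2, 0.5, 1.0):
            spec = GroupSpec(groups={"g1": g1, "g2": g2},
                             thresholds={"g1": t, "g2": t}, mode="B")
            assert group_filter([m], spec) == [m]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GroupSpec(groups={"g1": ["a"], "g2": ["a", "b"]})

    def test_unknown_sample_rejected(self):
        m, g1, g2 = _cosegregating_marker()
        spec = GroupSpec(groups={"g1": g1 + ["ghost"], "g2": g2})
        with pytest.raises(ValueError, match="ghost"):
            group_filter([m], spec)

    def test_group_spec_json_round_trip(self, tmp_path):
        p = tmp_path / "groups.json"
        p.write_text(
            '{"mode": "B", "groups": {"g1": ["a"], "g2": ["b"]},'
            ' "thresholds": {"g1": 0.1}}'
        )
        spec = GroupSpec.from_file(p)
        assert spec.mode == "B"
        assert spec.threshold("g1") == 0.1
        assert spec.threshold("g2") == 0.10  # default
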