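"""Alignment mapping, substitution counts, and the exact-test oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkscan import evostats
from hkscan.evostats import (
    OrthologAlignment,
    constraint_tests,
    corresponding_residue_test,
    count_substitutions,
    enrichment,
    fisher_exact,
    ks_two_sample,
    map_reference_columns,
)
from hkscan.library import DomainRegion, Variant


def make_alignment(rows: dict[str, str], reference_id: str = "ref") -> OrthologAlignment:
    species = pd.DataFrame(
        {
            "species_id": [s for s in rows if s != reference_id],
            "has_RstBA": True,
            "has_CpxAR": True,
            "has_duplication": False,
        }
    ).set_index("species_id")
    return OrthologAlignment(sequences=rows, reference_id=reference_id, species=species)


class TestColumnMapping:
    def test_gapless_reference_is_identity_offset(self):
        region = DomainRegion("toy", 10, 13, "ACDE")
        aln = make_alignment({"ref": "ACDE", "s1": "AADE"})
        assert map_reference_columns(aln, region) == {10: 0, 11: 1, 12: 2, 13: 3}

    def test_reference_gaps_are_skipped(self):
        region = DomainRegion("toy", 1, 3, "ACD")
        aln = make_alignment({"ref": "A-CD", "s1": "AACD"})
        mapping = map_reference_columns(aln, region)
        assert mapping == {1: 0, 2: 2, 3: 3}
        for pos, col in mapping.items():
            assert aln.sequences["ref"][col] == region.aa_at(pos)

    def test_mismatching_reference_is_an_error(self):
        region = DomainRegion("toy", 1, 3, "ACD")
        aln = make_alignment({"ref": "AWD", "s1": "ACD"})
        with pytest.raises(ValueError):
            map_reference_columns(aln, region)


class TestCountSubstitutions:
    def test_reference_only_alignment_counts_nothing(self):
        region = DomainRegion("toy", 1, 2, "AC")
        aln = OrthologAlignment(
            sequences={"ref": "AC"}, reference_id="ref",
            species=pd.DataFrame(columns=["has_RstBA", "has_CpxAR", "has_duplication"],
                                 index=pd.Index([], name="species_id")),
        )
        counts = count_substitutions(aln, {1: 0, 2: 1},
                                     [Variant(1, "R", "A"), Variant(2, "D", "C")])
        assert (counts == 0).all()

    def test_direct_counting_and_gap_exclusion(self):
        region = DomainRegion("toy", 255, 255, "A")
        rows = {"ref": "A"}
        rows.update({f"s{i}": "R" for i in range(10)})
        rows["gapped"] = "-"
        aln = make_alignment(rows)
        counts = count_substitutions(
            aln, {255: 0}, [Variant(255, "R", "A"), Variant(255, "K", "A")]
        )
        assert counts["A255R"] == 10
        assert counts["A255K"] == 0

    def test_invariant_to_row_order_and_all_gap_columns(self):
        region = DomainRegion("toy", 1, 3, "ACD")
        variants = [Variant(1, "W", "A"), Variant(2, "Y", "C"), Variant(3, "A", "D")]
        rows = {"ref": "ACD", "s1": "WCD", "s2": "WYD", "s3": "ACA"}
        aln = make_alignment(rows)
        base = count_substitutions(aln, map_reference_columns(aln, region), variants)
        # reversed insertion order
        aln_rev = make_alignment(dict(reversed(list(rows.items()))))
        rev = count_substitutions(aln_rev, map_reference_columns(aln_rev, region), variants)
        pd.testing.assert_series_equal(base, rev)
        # an all-gap insertion column shifts mapping but not counts
        padded = {k: v[:1] + "-" + v[1:] for k, v in rows.items()}
        aln_pad = make_alignment(padded)
        pad = count_substitutions(aln_pad, map_reference_columns(aln_pad, region), variants)
        pd.testing.assert_series_equal(base, pad)


def ecdf_max_diff(x, y):
    """Brute-force D: scan the pooled support of both empirical CDFs."""
    pooled = sorted(set(x) | set(y))
    return max(
        abs(sum(v <= t for v in x) / len(x) - sum(v <= t for v in y) / len(y))
        for t in pooled
    )


class TestKSTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_enumerated_offset_samples(self):
        assert ks_two_sample([1, 2, 3], [2, 3, 4]).statistic == pytest.approx(1 / 3)

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0
        assert res.p_value < 0.2

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 12), min_size=1, max_size=12),
        y=st.lists(st.integers(0, 12), min_size=1, max_size=12),
    )
    def test_statistic_matches_ecdf_scan(self, x, y):
        assert ks_two_sample(x, y).statistic == pytest.approx(ecdf_max_diff(x, y))


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p: full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


class TestFisherExact:
    def test_balanced_table(self):
        res = fisher_exact([[1, 1], [1, 1]])
        assert res.statistic == 1.0
        assert res.p_value == 1.0

    def test_hand_enumerated_table(self):
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.statistic == pytest.approx(9.0)
        assert res.p_value == pytest.approx(34 / 70)

    def test_zero_cell_odds_ratio_is_flagged_infinite(self):
        res = fisher_exact([[5, 0], [2, 3]])
        assert np.isinf(res.statistic)
        assert "or_infinite" in res.flags

    def test_degenerate_margin(self):
        res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0
        assert "or_undefined" in res.flags

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    def test_p_matches_hypergeometric_enumeration(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        assert fisher_exact([[a, b], [c, d]]).p_value == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestEnrichment:
    def test_proportional_rates_give_zero(self):
        assert enrichment(5, 10, 50, 100) == 0.0

    def test_direct_formula(self):
        assert enrichment(10, 4, 50, 100) == pytest.approx(8.0)

    def test_no_with_species_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment(1, 1, 1, 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(rate=st.integers(1, 20), n_without=st.integers(1, 50), n_with=st.integers(1, 50))
    def test_scaling_identity(self, rate, n_without, n_with):
        """Zero whenever per-species rates match exactly."""
        assert enrichment(rate * n_without, rate * n_with, n_without, n_with) == pytest.approx(0.0)


class TestConstraintTests:
    def test_total_depletion_gives_zero_odds_ratio(self):
        counts = pd.Series({"A1W": 0, "A1Y": 0, "A1C": 7, "A1D": 3})
        is_ct = pd.Series({"A1W": True, "A1Y": True, "A1C": False, "A1D": False})
        ks, fisher = constraint_tests(counts, is_ct)
        assert fisher.statistic == 0.0
        assert ks.statistic == 1.0

    def test_empty_partition_is_an_error(self):
        counts = pd.Series({"A1W": 1})
        with pytest.raises(ValueError):
            constraint_tests(counts, pd.Series({"A1W": True}))


class TestCorrespondingResidue:
    def test_toy_perfect_association(self):
        region = DomainRegion("envz", 1, 2, "AC")
        other = DomainRegion("cpxa", 1, 2, "RC")
        calls = pd.Series({"A1R": True, "A1W": False, "C2D": False, "C2E": False})
        res = corresponding_residue_test({"CpxR": calls}, region, {"CpxR": other})
        # one matching substitution cross-talks; nothing else does
        assert np.isinf(res.statistic) and "or_infinite" in res.flags
        assert res.p_value == pytest.approx(fisher_oracle(1, 0, 0, 3))

    def test_no_crosstalk_calls_give_p_one(self):
        region = DomainRegion("envz", 1, 1, "A")
        other = DomainRegion("cpxa", 1, 1, "R")
        calls = pd.Series({"A1R": False, "A1W": False})
        res = corresponding_residue_test({"CpxR": calls}, region, {"CpxR": other})
        assert res.p_value == 1.0

    def test_pooling_over_two_reporters(self):
        region = DomainRegion("envz", 1, 1, "A")
        others = {"CpxR": DomainRegion("cpxa", 1, 1, "R"),
                  "RstA": DomainRegion("rstb", 1, 1, "K")}
        calls = {
            "CpxR": pd.Series({"A1R": True, "A1K": False, "A1W": False}),
            "RstA": pd.Series({"A1R": False, "A1K": True, "A1W": False}),
        }
        res = corresponding_residue_test(calls, region, others)
        # each reporter contributes its own match column: table [[2,0],[0,4]]
        assert res.table.tolist() == [[2, 0], [0, 4]]
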