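"""Characterization statistics: contingency tests, enrichment against an
enumeration oracle, signature scores, CIN calling, CGH region tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colotype.charact import (chi_squared_test, cin_call, cin_calls,
                              hypergeometric_enrichment,
                              region_frequency_test, score_signature,
                              subtype_marker_table, top_signature)
from colotype.sim import CGHProfile, SimConfig, default_genome_bins, simulate_cgh


class TestChiSquared:
    def test_proportional_rows_give_null(self):
        stat, df, p = chi_squared_test([[10, 20, 30], [20, 40, 60]],
                                       correction="none")
        assert stat == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_test([[0, 0], [1, 2]])

    def test_correction_modes(self):
        tab = [[12, 5], [7, 15]]
        s_none, _, _ = chi_squared_test(tab, "none")
        s_yates, _, _ = chi_squared_test(tab, "yates")
        s_auto, _, _ = chi_squared_test(tab, "auto")
        assert s_yates < s_none  # continuity correction shrinks the statistic
        assert s_auto == s_yates  # auto applies Yates on 2x2
        s3, _, _ = chi_squared_test([[5, 6, 7], [8, 9, 1]], "auto")
        s3n, _, _ = chi_squared_test([[5, 6, 7], [8, 9, 1]], "none")
        assert s3 == s3n  # and not on wider tables

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 60), min_size=4, max_size=4))
    def test_two_by_two_closed_form(self, cells):
        a, b, c, d = cells
        stat, _, _ = chi_squared_test([[a, b], [c, d]], correction="none")
        n = a + b + c + d
        expected = (n * (a * d - b * c) ** 2
                    / ((a + b) * (c + d) * (a + c) * (b + d)))
        assert stat == pytest.approx(expected, abs=1e-10)


def enumeration_overlap_tail(M, set_genes, n_sig, obs):
    """P(overlap >= obs) by exhaustive enumeration of all signatures."""
    hits = 0
    total = 0
    for sig in itertools.combinations(range(M), n_sig):
        total += 1
        if len(set(sig) & set_genes) >= obs:
            hits += 1
    return hits / total


class TestHypergeometricEnrichment:
    def test_perfect_overlap_small_universe(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"s": set(universe[:5])}
        res = hypergeometric_enrichment(universe[:5], sets, universe)[0]
        assert res.overlap == 5
        assert res.p == pytest.approx(1 / math.comb(20, 5))

    def test_partition_with_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"s": set(universe[:4])}
        res = hypergeometric_enrichment(universe[4:], sets, universe)[0]
        assert res.overlap == 0
        assert res.p == pytest.approx(1.0)

    def test_set_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = hypergeometric_enrichment(universe[:3], {"all": universe},
                                        universe)[0]
        assert res.overlap == 3
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("M,K,n_sig", [(12, 4, 5), (15, 6, 4), (25, 8, 6)])
    def test_matches_exhaustive_enumeration(self, M, K, n_sig):
        universe = [f"g{i}" for i in range(M)]
        gene_set = set(range(K))
        rng = np.random.default_rng(M)
        sig_idx = rng.choice(M, n_sig, replace=False)
        sets = {"s": {f"g{i}" for i in gene_set}}
        res = hypergeometric_enrichment([f"g{i}" for i in sig_idx], sets,
                                        universe)[0]
        oracle = enumeration_overlap_tail(M, gene_set, n_sig, res.overlap)
        assert res.p == pytest.approx(oracle, rel=1e-9)

    def test_signature_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["x"], {"s": {"a"}}, ["a", "b"])
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], {"s": {"a"}}, [])


class TestScoreSignature:
    def test_planted_extremes_score_positive(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 0.1, (20, 10)),
                            index=[f"G{i}" for i in range(20)])
        expr.iloc[:3, 0] += 5.0   # up genes high in sample 0
        expr.iloc[3:6, 0] -= 5.0  # down genes low in sample 0
        out = score_signature(expr, up_genes=["G0", "G1", "G2"],
                              down_genes=["G3", "G4", "G5"])
        assert out["score"].iloc[0] > 0
        assert bool(out["positive"].iloc[0])

    def test_score_local_to_signature_genes(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (20, 6)),
                            index=[f"G{i}" for i in range(20)])
        out1 = score_signature(expr, up_genes=["G0"], down_genes=["G1"])
        perturbed = expr.copy()
        perturbed.loc["G10"] += 100.0
        out2 = score_signature(perturbed, up_genes=["G0"], down_genes=["G1"])
        pd.testing.assert_series_equal(out1["score"], out2["score"])

    def test_no_genes_present_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G0"])
        with pytest.raises(ValueError):
            score_signature(expr, up_genes=["missing"])

    def test_top_signature_directions(self):
        tab = pd.DataFrame({"t_mod": [3.0, -2.0, 1.0, -4.0]},
                           index=list("abcd"))
        assert top_signature(tab, 2, "up") == ["a", "c"]
        assert top_signature(tab, 2, "down") == ["d", "b"]


class TestCinCall:
    def _profile(self, states):
        bins = default_genome_bins()
        return CGHProfile("s", bins, np.asarray(states))

    def test_all_neutral(self):
        p = self._profile(np.zeros(44, dtype=int))
        assert cin_call(p) == (0.0, False)

    def test_threshold_is_inclusive(self):
        # ten equal-length bins, exactly two gained: altered fraction 0.20
        bins = pd.DataFrame({"chrom": [str(i) for i in range(10)],
                             "arm": "p", "start": 1, "end": 100,
                             "length": 100})
        states = np.array([1, 1] + [0] * 8)
        frac, flag = cin_call(CGHProfile("s", bins, states), threshold=0.20)
        assert frac == pytest.approx(0.20)
        assert flag  # 'at least 20%' is CIN+

    def test_monotone_in_altered_bins(self):
        bins = default_genome_bins()
        states = np.zeros(len(bins), dtype=int)
        prev = 0.0
        for i in range(0, len(bins), 7):
            states[i] = -1
            frac, _ = cin_call(CGHProfile("s", bins, states))
            assert frac >= prev
            prev = frac

    def test_zero_length_rejected(self):
        bins = default_genome_bins().copy()
        bins["length"] = 0
        with pytest.raises(ValueError):
            cin_call(CGHProfile("s", bins, np.zeros(len(bins), dtype=int)))


class TestRegionFrequencyTest:
    def test_identical_patterns_are_non_significant(self):
        labels = pd.Series(["A"] * 30 + ["B"] * 30,
                           index=[f"S{i}" for i in range(60)])
        pattern = (("7p", 1, 0.7), ("18q", -1, 0.7))
        cfg = SimConfig(subtypes=("A", "B"), prevalences=(0.5, 0.5),
                        cgh_patterns={"A": pattern, "B": pattern},
                        cgh_background={"A": 0.0, "B": 0.0}, seed=0)
        cohort = simulate_cgh(labels, cfg)
        out = region_frequency_test(cohort, labels)
        assert len(out) > 0
        assert not out["significant"].any()

    def test_planted_subtype_specific_gain_detected(self):
        labels = pd.Series(["A"] * 50 + ["B"] * 50,
                           index=[f"S{i}" for i in range(100)])
        cfg = SimConfig(subtypes=("A", "B"), prevalences=(0.5, 0.5),
                        cgh_patterns={"A": (("13q", 1, 1.0),), "B": ()},
                        cgh_background={"A": 0.0, "B": 0.0}, seed=0)
        cohort = simulate_cgh(labels, cfg)
        out = region_frequency_test(cohort, labels)
        row = out[(out["bin"] == "13q") & (out["alteration"] == "gain")]
        assert len(row) == 1
        assert row["significant"].iloc[0]
        assert row["p_adj"].iloc[0] < 0.01

    def test_row_count_matches_testable_bins(self):
        labels = pd.Series(["A"] * 10 + ["B"] * 10,
                           index=[f"S{i}" for i in range(20)])
        cfg = SimConfig(subtypes=("A", "B"), prevalences=(0.5, 0.5),
                        cgh_patterns={"A": (("7p", 1, 1.0),),
                                      "B": (("8q", -1, 1.0),)},
                        cgh_background={"A": 0.0, "B": 0.0}, seed=0)
        cohort = simulate_cgh(labels, cfg)
        out = region_frequency_test(cohort, labels)
        # only 7p gain and 8q loss are testable (others have zero margins)
        assert len(out) == 2

    def test_marker_table_shape(self):
        annot = pd.DataFrame({"subtype": ["C1", "C1", "C2", "C2"],
                              "dMMR": [0, 1, 1, 1]})
        tab = subtype_marker_table(annot, "dMMR")
        assert tab.shape == (2, 2)
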