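"""Tests of the fold-change classifiers, presence filter and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistatrio import (ExpressionMatrix, ExprSimConfig, FilterParams,
                        average_replicates, classify_myb_response,
                        classify_myb_response_replicates,
                        collapse_probes_to_genes, direction_concordance,
                        kix_sensitivity, presence_filter, simulate_expression)


def matrix_from_means(means: dict[str, list[float]], n_rep: int = 1,
                      noise: np.ndarray | None = None) -> ExpressionMatrix:
    """Build a matrix whose per-condition means are given exactly."""
    genes = ["g%03d" % i for i in range(len(next(iter(means.values()))))]
    cols, rows = {}, []
    for cond, vals in means.items():
        genotype, treatment = cond.split(":")
        for r in range(1, n_rep + 1):
            sid = "%s_%s_r%d" % (genotype, treatment, r)
            cols[sid] = np.asarray(vals, dtype=float)
            rows.append((sid, genotype, treatment, r))
    samples = pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment",
                                          "replicate"]).set_index("sample_id")
    values = pd.DataFrame(cols, index=genes)
    if noise is not None:
        values = values + noise
    return ExpressionMatrix(values=values, samples=samples)


class TestAverageReplicates:
    def test_two_replicates_mean(self):
        m = matrix_from_means({"WT:ctrl": [4.0]}, n_rep=2)
        m.values.iloc[0, 0] = 4.0
        m.values.iloc[0, 1] = 6.0
        means, counts = average_replicates(m)
        assert means.loc["g000", "WT:ctrl"] == pytest.approx(5.0)
        assert counts["WT:ctrl"] == 2

    def test_single_replicate_identity(self):
        m = matrix_from_means({"WT:ctrl": [3.3, 7.1]}, n_rep=1)
        means, counts = average_replicates(m)
        assert np.allclose(means["WT:ctrl"], [3.3, 7.1])
        assert counts["WT:ctrl"] == 1

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        m = simulate_expression(ExprSimConfig(n_genes=20, n_replicates=3,
                                              noise_sd=0.5, seed=3))
        means, _ = average_replicates(m)
        for cond in means.columns:
            genotype, treatment = cond.split(":")
            samp = m.samples[(m.samples["genotype"] == genotype) &
                             (m.samples["treatment"] == treatment)].index
            manual = sum(m.values[s] for s in samp) / len(samp)
            assert np.allclose(means[cond], manual)


class TestPresenceFilter:
    def test_boundary_inclusive(self):
        means = pd.DataFrame({"a": [3.4, 3.3], "b": [5.0, 9.9]},
                             index=["keep", "drop"])
        kept = presence_filter(means, ["a", "b"], floor=3.4)
        assert list(kept) == ["keep"]

    def test_missing_condition_rejected(self):
        means = pd.DataFrame({"a": [5.0]}, index=["g"])
        with pytest.raises(KeyError, match="nope"):
            presence_filter(means, ["nope"])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        means = pd.DataFrame(rng.uniform(0, 10, size=(1000, 3)),
                             columns=["a", "b", "c"],
                             index=["g%04d" % i for i in range(1000)])
        kept = set(presence_filter(means, ["a", "c"], floor=3.4))
        brute = {g for g in means.index
                 if means.loc[g, "a"] >= 3.4 and means.loc[g, "c"] >= 3.4}
        assert kept == brute

    def test_lowering_floor_never_shrinks(self):
        rng = np.random.default_rng(3)
        means = pd.DataFrame({"a": rng.uniform(0, 10, 200)},
                             index=["g%03d" % i for i in range(200)])
        hi = set(presence_filter(means, ["a"], floor=5.0))
        lo = set(presence_filter(means, ["a"], floor=2.0))
        assert hi <= lo


class TestClassify:
    def test_exact_twofold_is_activated(self):
        means = pd.DataFrame({"c": [5.0, 5.0, 5.0], "t": [6.0, 5.9, 4.0]},
                             index=["two", "under", "half"])
        act, rep, ratio = classify_myb_response(means, "c", "t")
        assert list(act) == ["two"]        # ratio exactly 2 counts
        assert list(rep) == ["half"]       # ratio exactly 0.5 counts
        assert ratio["two"] == pytest.approx(2.0)

    def test_flat_matrix_empty_sets(self):
        means = pd.DataFrame({"c": [5.0, 6.0], "t": [5.0, 6.0]}, index=["a", "b"])
        act, rep, _ = classify_myb_response(means, "c", "t")
        assert len(act) == 0 and len(rep) == 0

    def test_identical_condition_names_rejected(self):
        means = pd.DataFrame({"c": [5.0]}, index=["a"])
        with pytest.raises(ValueError, match="identical"):
            classify_myb_response(means, "c", "c")

    def test_planted_truth_recovered_exactly(self, expr_matrix):
        means, _ = average_replicates(expr_matrix)
        present = presence_filter(means, ["WT:ctrl", "WT:myb"])
        act, rep, _ = classify_myb_response(means, "WT:ctrl", "WT:myb",
                                            genes=present)
        truth = expr_matrix.truth
        assert set(act) == set(truth.index[truth["status"] == "activated"])
        assert set(rep) == set(truth.index[truth["status"] == "repressed"])

    def test_recovery_degrades_with_noise(self):
        rates = []
        for noise in (0.5, 1.0, 1.5):
            m = simulate_expression(ExprSimConfig(n_genes=5000, noise_sd=noise,
                                                  seed=11))
            means, _ = average_replicates(m)
            act, _, _ = classify_myb_response(means, "WT:ctrl", "WT:myb")
            planted = m.truth.index[m.truth["status"] == "activated"]
            rates.append(len(act.intersection(planted)) / len(planted))
        assert rates[0] > rates[1] > rates[2]
        assert rates[0] > 0.9

    def test_high_noise_recovery_at_2fold_threshold(self):
        """At modest noise the 2-fold filter still recovers >=95% of truth."""
        m = simulate_expression(ExprSimConfig(n_genes=5000, noise_sd=0.3, seed=11))
        means, _ = average_replicates(m)
        act, _, _ = classify_myb_response(means, "WT:ctrl", "WT:myb")
        planted = m.truth.index[m.truth["status"] == "activated"]
        assert len(act.intersection(planted)) / len(planted) >= 0.95

    def test_replicate_mode_is_stricter(self):
        m = simulate_expression(ExprSimConfig(n_genes=500, n_replicates=3,
                                              noise_sd=0.6, seed=5))
        means, _ = average_replicates(m)
        act_avg, rep_avg, _ = classify_myb_response(means, "WT:ctrl", "WT:myb")
        ctrl = list(m.samples.index[(m.samples["genotype"] == "WT") &
                                    (m.samples["treatment"] == "ctrl")])
        trt = list(m.samples.index[(m.samples["genotype"] == "WT") &
                                   (m.samples["treatment"] == "myb")])
        act_rep, rep_rep = classify_myb_response_replicates(m, ctrl, trt)
        assert set(act_rep) <= set(act_avg)
        assert set(rep_rep) <= set(rep_avg)

    @given(st.floats(min_value=1.5, max_value=4.0),
           st.floats(min_value=2.0, max_value=8.0))
    @settings(max_examples=25, deadline=None)
    def test_monotonic_and_disjoint(self, low_thr, high_thr):
        rng = np.random.default_rng(17)
        means = pd.DataFrame({"c": rng.uniform(4, 9, 300),
                              "t": rng.uniform(4, 9, 300)},
                             index=["g%03d" % i for i in range(300)])
        lo = FilterParams(induce_ratio=min(low_thr, high_thr))
        hi = FilterParams(induce_ratio=max(low_thr, high_thr) + 1e-9)
        act_lo, rep_lo, _ = classify_myb_response(means, "c", "t", lo)
        act_hi, rep_hi, _ = classify_myb_response(means, "c", "t", hi)
        assert set(act_hi) <= set(act_lo)          # raising threshold shrinks
        assert not set(act_lo) & set(rep_lo)       # disjoint


class TestKixSensitivity:
    def test_boundary_inclusive(self):
        # wt - mut = log2(1.5) exactly, so the linear ratio is exactly 1.5
        means = pd.DataFrame(
            {"wt": [np.log2(1.5), 0.5], "mut": [0.0, 0.0]},
            index=["sens", "insens"])
        res = kix_sensitivity(pd.Index(["sens", "insens"]), pd.Index([]),
                              means, "wt", "mut")
        assert list(res.kix_sensitive_activated) == ["sens"]
        assert res.frac_sensitive_activated == pytest.approx(0.5)

    def test_identical_conditions_zero_sensitive(self):
        means = pd.DataFrame({"wt": [6.0, 7.0], "mut": [6.0, 7.0]},
                             index=["a", "b"])
        res = kix_sensitivity(pd.Index(["a"]), pd.Index(["b"]), means, "wt", "mut")
        assert res.frac_sensitive_activated == 0.0
        assert res.frac_sensitive_repressed == 0.0

    def test_empty_parent_fraction_absent(self):
        means = pd.DataFrame({"wt": [6.0], "mut": [5.0]}, index=["a"])
        res = kix_sensitivity(pd.Index([]), pd.Index([]), means, "wt", "mut")
        assert res.frac_sensitive_activated is None
        assert res.frac_sensitive_repressed is None

    def test_planted_fraction_exact(self, expr_matrix):
        means, _ = average_replicates(expr_matrix)
        act, rep, _ = classify_myb_response(means, "WT:ctrl", "WT:myb")
        res = kix_sensitivity(act, rep, means, "WT:myb", "KIX:myb")
        assert res.frac_sensitive_activated == pytest.approx(0.5)
        assert res.frac_sensitive_repressed == pytest.approx(0.5)
        truth = expr_matrix.truth
        want = set(truth.index[(truth["status"] == "activated") &
                               truth["kix_sensitive"]])
        assert set(res.kix_sensitive_activated) == want

    def test_subset_law(self, expr_matrix):
        means, _ = average_replicates(expr_matrix)
        act, rep, _ = classify_myb_response(means, "WT:ctrl", "WT:myb")
        res = kix_sensitivity(act, rep, means, "WT:myb", "KIX:myb")
        assert set(res.kix_sensitive_activated) <= set(act)
        assert set(res.kix_sensitive_repressed) <= set(rep)


class TestConcordance:
    def test_identity(self):
        a = pd.Series(["up", "down", "up"], index=["g1", "g2", "g3"])
        res = direction_concordance(a, a)
        assert res.n_overlap == res.n_same_direction == 3
        assert res.frac_of_overlap == 1.0

    def test_disjoint(self):
        a = pd.Series(["up"], index=["g1"])
        b = pd.Series(["down"], index=["g2"])
        res = direction_concordance(a, b)
        assert (res.n_overlap, res.n_same_direction) == (0, 0)
        assert res.frac_of_overlap is None

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        universe = ["g%03d" % i for i in range(100)]
        ids_a = rng.choice(universe, 50, replace=False)
        ids_b = rng.choice(universe, 80, replace=False)
        a = pd.Series(rng.choice(["up", "down"], 50), index=ids_a)
        b = pd.Series(rng.choice(["up", "down"], 80), index=ids_b)
        res = direction_concordance(a, b)
        n_ov = sum(1 for g in ids_a if g in set(ids_b))
        n_same = sum(1 for g in ids_a if g in set(ids_b) and a[g] == b[g])
        assert (res.n_overlap, res.n_same_direction) == (n_ov, n_same)

    def test_duplicate_ids_rejected(self):
        a = pd.Series(["up", "down"], index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate"):
            direction_concordance(a, a)


class TestCollapseProbes:
    def test_highest_mean_probe_kept_tie_lexicographic(self):
        values = pd.DataFrame(
            {"s1": [1.0, 5.0, 3.0, 3.0], "s2": [1.0, 5.0, 3.0, 3.0]},
            index=["p1", "p2", "p3", "p0"])
        mapping = pd.Series({"p1": "geneA", "p2": "geneA",
                             "p3": "geneB", "p0": "geneB"})
        out = collapse_probes_to_genes(values, mapping)
        assert out.loc["geneA", "s1"] == 5.0        # p2 wins on signal
        # p0 and p3 tie on signal; lexicographically smaller probe id wins
        assert list(out.index) == ["geneA", "geneB"]
        assert out.loc["geneB", "s1"] == 3.0
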