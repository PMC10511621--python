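"""ROC/AUC, Youden cut point, DeLong test, binormal closed form."""

import numpy as np
import pytest
from scipy.stats import norm

from patchwork3d.diagnostics import (
    binormal_auc,
    cohort_auc_experiment,
    delong_test,
    diagnostic_report,
    placement_auc,
    roc_auc,
    youden_cutpoint,
)
from patchwork3d.phantom import CohortConfig


def _pair_count_auc(volumes, is_msa):
    """Brute-force Mann-Whitney oracle (lower volume indicates MSA)."""
    v = np.asarray(volumes, float)
    y = np.asarray(is_msa, bool)
    pos, neg = v[y], v[~y]
    favorable = ties = 0
    for p in pos:
        for q in neg:
            if p < q:
                favorable += 1
            elif p == q:
                ties += 1
    return (favorable + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([2.0, 3.0, 4.0, 5.0], [True, True, False, False])
        assert auc == 1.0

    def test_one_tie(self):
        auc, _, _ = roc_auc([3.0, 4.0, 4.0, 5.0], [True, True, False, False])
        assert auc == pytest.approx(3.5 / 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_mann_whitney_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        v = np.round(rng.normal(4, 1, size=n), 1)  # rounding forces ties
        y = rng.random(n) > 0.6
        if y.all() or not y.any():
            y[0] = ~y[0]
        auc, _, _ = roc_auc(v, y)
        assert auc == pytest.approx(_pair_count_auc(v, y), abs=1e-12)

    def test_empirical_matches_binormal_closed_form(self):
        rng = np.random.default_rng(0)
        n = 500
        pos = rng.normal(2.62, 1.03, size=n)
        neg = rng.normal(4.34, 0.53, size=n)
        auc, _, _ = roc_auc(
            np.concatenate([pos, neg]),
            np.concatenate([np.ones(n, bool), np.zeros(n, bool)]),
        )
        expected = binormal_auc(2.62, 1.03, 4.34, 0.53)
        se = np.sqrt(expected * (1 - expected) * (n + n) / (n * n))  # coarse bound
        assert abs(auc - expected) <= 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestYoudenCutpoint:
    def test_perfect_split_midpoint(self):
        cut, sens, spec = youden_cutpoint([2.0, 3.0, 4.0, 5.0], [True, True, False, False])
        assert cut == pytest.approx(3.5)
        assert sens == 1.0 and spec == 1.0

    def test_fully_overlapping_distributions(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        y = [True, True, True, False, False, False]
        cut, sens, spec = youden_cutpoint(v, y)
        assert sens + spec - 1.0 == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 40))
        v = np.round(rng.normal(4, 1, size=n), 1)
        y = rng.random(n) > 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        _, sens, spec = youden_cutpoint(v, y)
        # oracle: try a fine sweep of thresholds
        best = max(
            (v[y] < t).mean() + (v[~y] >= t).mean() - 1.0
            for t in np.linspace(v.min() - 1, v.max() + 1, 4001)
        )
        assert sens + spec - 1.0 == pytest.approx(best, abs=1e-9)


class TestDelong:
    def test_identical_scores_degenerate(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = np.array([False, True, False, True, True, False])
        res = delong_test(scores, scores, labels)
        assert res["delta_auc"] == 0.0
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_placement_auc_equals_pair_count(self):
        rng = np.random.default_rng(3)
        v = np.round(rng.normal(0, 1, size=30), 1)
        y = rng.random(30) > 0.5
        y[0], y[1] = True, False
        auc, _, _ = placement_auc(-v, y)
        assert auc == pytest.approx(_pair_count_auc(v, y), abs=1e-12)

    def test_variance_nonnegative_and_p_valid(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 14
            y = np.concatenate([np.ones(6, bool), np.zeros(8, bool)])
            a = rng.normal(size=n) + y
            b = rng.normal(size=n) + 0.5 * y
            res = delong_test(a, b, y)
            assert res["var_delta"] >= 0.0
            assert 0.0 <= res["p"] <= 1.0

    def test_variance_matches_bootstrap_oracle(self):
        """DeLong variance of the AUC difference vs a stratified paired
        bootstrap over subjects (1e5 replicates)."""
        rng = np.random.default_rng(12)
        n_pos, n_neg = 12, 14
        y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
        a = rng.normal(size=y.size) + 1.2 * y
        b = 0.7 * a + rng.normal(scale=0.8, size=y.size)
        res = delong_test(a, b, y)

        reps = 100_000
        deltas = np.empty(reps)
        done = 0
        while done < reps:
            chunk = min(10_000, reps - done)
            pi = rng.integers(0, n_pos, size=(chunk, n_pos))
            ni = n_pos + rng.integers(0, n_neg, size=(chunk, n_neg))
            for arr, sign in ((a, 1.0), (b, -1.0)):
                pos = arr[pi][:, :, None]
                neg = arr[ni][:, None, :]
                auc = ((pos > neg) + 0.5 * (pos == neg)).mean(axis=(1, 2))
                if sign > 0:
                    deltas[done : done + chunk] = auc
                else:
                    deltas[done : done + chunk] -= auc
            done += chunk
        boot_var = deltas.var(ddof=1)
        assert res["var_delta"] == pytest.approx(boot_var, rel=0.10)


class TestBinormal:
    def test_equal_means_half(self):
        assert binormal_auc(3.0, 1.0, 3.0, 2.0) == pytest.approx(0.5)

    def test_printed_group_distributions(self):
        auc = binormal_auc(2.62, 1.03, 4.34, 0.53)
        assert auc == pytest.approx(norm.cdf(1.72 / np.hypot(1.03, 0.53)), abs=1e-12)
        assert auc == pytest.approx(0.931, abs=5e-4)

    def test_class_swap_symmetry(self):
        a = binormal_auc(2.0, 1.0, 4.0, 0.5)
        b = binormal_auc(4.0, 0.5, 2.0, 1.0)
        assert a + b == pytest.approx(1.0)

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            binormal_auc(2.0, 0.0, 4.0, 1.0)


class TestCohortExperiment:
    def test_exchangeable_groups_give_half(self):
        cc = CohortConfig(
            group_volumes_mL={"HC": (4.34, 0.53), "MSA": (4.34, 0.53), "PD": (4.34, 0.53)}
        )
        res = cohort_auc_experiment(cc, n_replicates=100, seed=1)
        assert abs(res["mean_auc"] - 0.5) < 0.03

    def test_auc_sd_shrinks_with_group_size(self):
        small = cohort_auc_experiment(CohortConfig(), n_replicates=100, seed=2)
        big_cfg = CohortConfig(group_sizes={"HC": 150, "MSA": 310, "PD": 740})
        big = cohort_auc_experiment(big_cfg, n_replicates=100, seed=2)
        assert big["sd_auc"] < small["sd_auc"]


class TestDiagnosticReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(2.6, 1.0, 31), rng.normal(4.4, 0.5, 89)])
        y = np.concatenate([np.ones(31, bool), np.zeros(89, bool)])
        rep = diagnostic_report(v, y)
        auc, _, _ = roc_auc(v, y)
        assert rep.auc == pytest.approx(auc, abs=1e-12)
        assert rep.ci95[0] <= rep.auc <= rep.ci95[1]
        assert 0 < rep.cutpoint_mL < 10
        assert rep.n_pos == 31 and rep.n_neg == 89
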