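"""Planned statistics: t tests, correlations, FDR, focused contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import tgpac as tg
from tgpac.stats import one_sample_t_cohend


class TestPairedT:
    def test_equal_samples_give_zero_t_and_d(self):
        a = np.arange(10.0)
        res = tg.paired_t_cohend(a, a)
        assert res.t == 0.0 and res.d == 0.0 and res.zero_variance

    def test_constant_nonzero_difference_is_flagged_infinite(self):
        res = tg.paired_t_cohend(np.array([2.0, 2.0, 2.0, 2.0]), np.ones(4))
        assert res.zero_variance and np.isinf(res.t) and res.t > 0

    def test_matches_textbook_formula(self, rng):
        d = rng.normal(0.5, 1.0, 60)
        res = tg.paired_t_cohend(d, np.zeros(60))
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(60))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 59)
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)
        assert res.df == 59


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = tg.pearson_r(x, 2 * x + 3)
        assert r == pytest.approx(1.0)

    def test_orthogonal_centered_fixture_gives_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])
        r, _ = tg.pearson_r(x, y)
        assert abs(r) < 1e-12

    def test_sampling_distribution_at_moderate_rho(self, rng):
        rho = 0.5
        x = rng.standard_normal(10_000)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(10_000)
        r, p = tg.pearson_r(x, y)
        assert 0.48 < r < 0.52
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tg.pearson_r(np.ones(5), np.arange(5.0))


def _brute_force_bh(p, q):
    """Independent step-up enumeration used as the FDR oracle."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k_max = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBHFDR:
    def test_hand_run_step_up_example(self):
        reject, _ = tg.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.2], q=0.05)
        assert reject.sum() == 4 and not reject[-1]

    def test_extremes(self):
        all_small, _ = tg.bh_fdr([0.001] * 6, q=0.05)
        assert all_small.all()
        none, _ = tg.bh_fdr([0.9, 0.95], q=0.05)
        assert not none.any()
        with pytest.raises(ValueError):
            tg.bh_fdr([])
        with pytest.raises(ValueError):
            tg.bh_fdr([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        p=st.lists(st.integers(0, 100).map(lambda v: v / 100.0),
                   min_size=1, max_size=6),
        q=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_agrees_with_brute_force_enumeration(self, p, q):
        reject, p_adj = tg.bh_fdr(p, q=q)
        np.testing.assert_array_equal(reject, _brute_force_bh(p, q))
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()


def _cells(values_by_cond, n_subjects=12, noise=0.0, rng=None):
    """Balanced subject x condition x window cell table."""
    rows = []
    for s in range(n_subjects):
        for cond, (pre, post) in values_by_cond.items():
            for w, v in (("pre", pre), ("post", post)):
                eps = rng.normal(0, noise) if rng is not None and noise else 0.0
                rows.append({"subject": s, "condition": cond, "window": w,
                             "cluster": "frontal", "band": "low",
                             "plv": v + eps})
    return pd.DataFrame(rows)


class TestFocusedContrast:
    CONDS = ["ActiveWM+", "ActiveWM-", "PassiveWM-"]

    def test_equal_conditions_yield_zero_task_contrast(self):
        cells = _cells({c: (0.1, 0.2) for c in self.CONDS})
        res = tg.focused_contrast_test(cells, conditions=self.CONDS)
        task = res[res.effect == "task"].iloc[0]
        assert task.t == 0.0 and task.zero_variance

    def test_inflated_wm_condition_scores_two_thirds_delta(self, rng):
        delta = 0.06
        vals = {c: (0.1, 0.2) for c in self.CONDS}
        vals["ActiveWM+"] = (0.1, 0.2 + 2 * delta)  # +delta averaged over windows
        cells = _cells(vals, n_subjects=400, noise=0.01, rng=rng)
        wide = cells.pivot_table(index="subject",
                                 columns=["condition", "window"], values="plv")
        scores = sum(
            w * wide[c].mean(axis=1)
            for w, c in zip(tg.WM_CONTRAST, self.CONDS)
        )
        assert scores.mean() == pytest.approx(2.0 / 3.0 * delta, abs=0.002)
        res = tg.focused_contrast_test(cells, conditions=self.CONDS)
        task = res[res.effect == "task"].iloc[0]
        assert task.p < 1e-6 and task.t > 0

    def test_window_effect_detected(self, rng):
        cells = _cells({c: (0.1, 0.25) for c in self.CONDS},
                       noise=0.02, rng=rng)
        res = tg.focused_contrast_test(cells, conditions=self.CONDS)
        win = res[res.effect == "window"].iloc[0]
        assert win.p < 1e-4 and win.t > 0

    def test_permuting_condition_labels_is_calibrated(self, rng):
        # under within-subject label exchange the task contrast rejects at
        # roughly the nominal rate
        base = _cells({c: (0.1, 0.2) for c in self.CONDS},
                      n_subjects=15, noise=0.03, rng=rng)
        rejections = 0
        n_perms = 300
        for _ in range(n_perms):
            permuted = base.copy()
            for s in range(15):
                mapping = dict(zip(self.CONDS, rng.permutation(self.CONDS)))
                mask = permuted.subject == s
                permuted.loc[mask, "condition"] = (
                    permuted.loc[mask, "condition"].map(mapping)
                )
            res = tg.focused_contrast_test(permuted, conditions=self.CONDS)
            rejections += res[res.effect == "task"].iloc[0].p < 0.05
        assert rejections / n_perms == pytest.approx(0.05, abs=0.035)

    def test_validation_errors(self):
        cells = _cells({c: (0.1, 0.2) for c in self.CONDS})
        with pytest.raises(ValueError, match="sum to 0"):
            tg.focused_contrast_test(cells, weights=(1.0, 0.0, 0.0),
                                     conditions=self.CONDS)
        with pytest.raises(ValueError, match="missing"):
            tg.focused_contrast_test(cells[cells.condition != "PassiveWM-"],
                                     conditions=self.CONDS)

    def test_one_sample_t_requires_three_observations(self):
        with pytest.raises(ValueError):
            one_sample_t_cohend(np.array([1.0, 2.0]))
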