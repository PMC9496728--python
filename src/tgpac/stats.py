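"""Inferential layer for the condition x window PLV tables.

The study design is fully within-subject (every subject contributes all three
task conditions in both analysis windows, per cluster and gamma band), so the
planned comparisons reduce to per-subject scores tested against zero:

* window effect: mean(post) - mean(pre) per subject, one-sample t;
* focused task contrast: sum of weights (2/3, -1/3, -1/3) x condition means
  per subject — the planned test that the working-memory condition exceeds
  the other two.  For a balanced design with a random subject intercept this
  per-subject contrast-score t test is algebraically the mixed-model contrast;
* window x condition interaction: the same contrast applied to each
  subject's (post - pre) differences.

Effect sizes are classical one-sample / paired Cohen's d (mean over SD of
the per-subject scores).  Exploratory families of tests are corrected with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "paired_t_cohend",
    "one_sample_t_cohend",
    "pearson_r",
    "bh_fdr",
    "focused_contrast_test",
    "WM_CONTRAST",
]

#: Planned contrast weights over (ActiveWM+, ActiveWM-, PassiveWM-).
WM_CONTRAST = (2.0 / 3.0, -1.0 / 3.0, -1.0 / 3.0)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    zero_variance: bool = False


def one_sample_t_cohend(x: np.ndarray, mu: float = 0.0,
                        one_sided: bool = False) -> TTestResult:
    """One-sample t test of ``x`` against ``mu`` with Cohen's d.

    Zero-variance input is flagged rather than raised: t is 0 when the mean
    equals ``mu`` and +/-inf otherwise (p of 1 or 0 accordingly).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    diffs = x - mu
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    df = x.size - 1
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
        d = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        return TTestResult(t=t, df=df, p=p, d=d, zero_variance=True)
    t = mean / (sd / np.sqrt(x.size))
    if one_sided:
        p = float(sps.t.sf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, d=float(mean / sd))


def paired_t_cohend(a: np.ndarray, b: np.ndarray,
                    one_sided: bool = False) -> TTestResult:
    """Paired t test (a vs b, paired by subject) with Cohen's d of differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t_cohend(a - b, mu=0.0, one_sided=one_sided)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone adjusted p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _check_balanced(cells: pd.DataFrame, conditions: list[str]) -> None:
    need = {"subject", "condition", "window", "plv"}
    missing = need - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns {sorted(missing)}")
    have = set(cells["condition"].unique())
    if not set(conditions) <= have:
        raise ValueError(f"missing conditions: {sorted(set(conditions) - have)}")


def focused_contrast_test(
    cells: pd.DataFrame,
    weights: tuple[float, ...] = WM_CONTRAST,
    conditions: list[str] | None = None,
    one_sided: bool = False,
) -> pd.DataFrame:
    """Planned-contrast tests on a balanced subject x condition x window table.

    ``cells`` needs columns subject, condition, window, plv and optionally
    cluster / band (tests are run per cluster x band group).  Three effects
    are reported per group: the window effect (post - pre), the focused task
    contrast (across windows), and the window x condition interaction (the
    contrast of post - pre differences).  Weights must sum to zero.
    """
    if abs(sum(weights)) > 1e-12:
        raise ValueError("contrast weights must sum to 0")
    if conditions is None:
        conditions = sorted(cells["condition"].unique())
    if len(weights) != len(conditions):
        raise ValueError("one weight per condition is required")
    _check_balanced(cells, conditions)

    group_keys = [c for c in ("cluster", "band") if c in cells.columns]
    groups = cells.groupby(group_keys, observed=True) if group_keys else [((), cells)]

    rows = []
    for gkey, grp in groups:
        wide = grp.pivot_table(
            index="subject", columns=["condition", "window"], values="plv"
        )
        if wide.isna().any().any():
            raise ValueError("unbalanced table: every subject needs every cell")
        per_cond = {c: wide[c].mean(axis=1) for c in conditions}
        post_minus_pre = {
            c: wide[(c, "post")] - wide[(c, "pre")] for c in conditions
        }

        window_scores = np.mean(
            [post_minus_pre[c].to_numpy() for c in conditions], axis=0
        )
        task_scores = sum(
            w * per_cond[c].to_numpy() for w, c in zip(weights, conditions)
        )
        inter_scores = sum(
            w * post_minus_pre[c].to_numpy() for w, c in zip(weights, conditions)
        )

        for effect, scores, sided in (
            ("window", window_scores, False),
            ("task", task_scores, one_sided),
            ("window_x_task", inter_scores, one_sided),
        ):
            res = one_sample_t_cohend(np.asarray(scores), one_sided=sided)
            row = {
                "effect": effect,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "d": res.d,
                "zero_variance": res.zero_variance,
            }
            if group_keys:
                key = gkey if isinstance(gkey, tuple) else (gkey,)
                row.update(dict(zip(group_keys, key)))
            rows.append(row)
    return pd.DataFrame(rows)
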