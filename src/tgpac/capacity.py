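"""Visual working-memory capacity (K) from change-detection trial tables.

Two classical estimators, matched to the test-array type:

* Pashler's K = S * (h - f) / (1 - f) — whole-display test arrays, where a
  false alarm means guessing "change" on an intact display;
* Cowan's  K = S * (h - f)           — single-probe test arrays.

S is the set size, h the hit rate and f the false-alarm rate at that set
size.  Both invert the high-threshold observer model exactly at population
rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CapacityEstimate", "k_formula", "estimate_capacity"]

_FORMULA_FOR_PARADIGM = {"whole-display": "pashler", "single-probe": "cowan"}


@dataclass
class CapacityEstimate:
    """Per-set-size rates and K, plus their summary.

    ``overall_K`` is the unweighted mean of K across the set sizes that
    entered the summary (by default those >= 2, since a one-item display
    saturates at ceiling for any realistic capacity).
    """

    per_set_size: pd.DataFrame  # columns: set_size, n_change, n_same, h, f, K
    overall_K: float
    formula: str


def k_formula(S: float, h: float, f: float, formula: str = "pashler") -> float:
    """Capacity from one set size's hit and false-alarm rates.

    Negative values are returned as computed (they are informative about
    below-chance responding); callers may clip.  Pashler's formula is
    undefined at f = 1.
    """
    if not (0.0 <= h <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if formula == "pashler":
        if f >= 1.0:
            raise ValueError("Pashler's K is undefined at a false-alarm rate of 1")
        return S * (h - f) / (1.0 - f)
    if formula == "cowan":
        return S * (h - f)
    raise ValueError(f"unknown formula {formula!r}")


def estimate_capacity(
    trials: pd.DataFrame,
    paradigm: str = "whole-display",
    min_set_size: int = 2,
) -> CapacityEstimate:
    """Estimate K from a trial table (set_size, change_present, response).

    ``response`` is True when the participant reported a change.  The
    formula follows the paradigm: whole-display -> Pashler, single-probe ->
    Cowan.  ``overall_K`` averages K over set sizes >= ``min_set_size``.
    """
    try:
        formula = _FORMULA_FOR_PARADIGM[paradigm]
    except KeyError:
        raise ValueError(f"unknown paradigm {paradigm!r}") from None
    required = {"set_size", "change_present", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")

    rows = []
    for S, grp in trials.groupby("set_size"):
        change = grp[grp["change_present"].astype(bool)]
        same = grp[~grp["change_present"].astype(bool)]
        if len(change) == 0 or len(same) == 0:
            raise ValueError(
                f"set size {S} needs at least one change and one no-change trial"
            )
        h = change["response"].astype(bool).mean()
        f = same["response"].astype(bool).mean()
        rows.append(
            {
                "set_size": int(S),
                "n_change": len(change),
                "n_same": len(same),
                "h": h,
                "f": f,
                "K": k_formula(S, h, f, formula),
            }
        )
    per = pd.DataFrame(rows).sort_values("set_size").reset_index(drop=True)
    used = per[per["set_size"] >= min_set_size]
    if used.empty:
        used = per
    return CapacityEstimate(
        per_set_size=per, overall_K=float(used["K"].mean()), formula=formula
    )
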