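"""Spearman associations between MGS abundance profiles and dietary nutrients.

Reproduces the diet-association surface: for every (MGS, nutrient) pair
a pairwise-complete Spearman rho with a two-sided p-value from the
t-approximation t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees
of freedom, flagged "+" at P < 0.05 and "*" at P < 0.01.  Raw p-values
are flagged (as in the source convention); a BH-adjusted column is
emitted alongside, clearly labelled as an extra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import AbundanceMatrix, NutrientTable

__all__ = ["diet_correlation"]

MIN_COMPLETE_PAIRS = 5


def _flag(p: float) -> str:
    if p < 0.01:
        return "*"
    if p < 0.05:
        return "+"
    return ""


def _permutation_p(x: np.ndarray, y: np.ndarray, rho: float, n_perm: int,
                   rng: np.random.Generator) -> float:
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    hits = 0
    for _ in range(n_perm):
        r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def diet_correlation(
    mgs_profiles: AbundanceMatrix,
    nutrients: NutrientTable,
    method: str = "t",
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(MGS, nutrient) Spearman rho, p and significance flags.

    Missing nutrient cells are excluded pairwise; a pair with fewer than
    5 complete samples is reported with NaN rho/p and a reason.  By
    default p comes from the t-approximation (``method="t"``);
    ``method="permutation"`` uses a seeded permutation null instead.
    Returns a long-format DataFrame with one row per pair, plus a
    BH-adjusted ``q_value`` column computed over the tested cells (not
    part of the source convention, provided for convenience).
    """
    shared = [s for s in mgs_profiles.sample_ids if s in set(nutrients.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between profiles and nutrients")
    prof = mgs_profiles.values[shared]
    nut = nutrients.values.loc[shared]
    rng = np.random.default_rng(seed)

    rows = []
    for mgs_id in prof.index:
        x_all = prof.loc[mgs_id].to_numpy(dtype=float)
        for nutrient in nut.columns:
            y_all = nut[nutrient].to_numpy(dtype=float)
            ok = ~np.isnan(x_all) & ~np.isnan(y_all)
            n = int(ok.sum())
            if n < MIN_COMPLETE_PAIRS:
                rows.append(
                    dict(mgs_id=mgs_id, nutrient_id=nutrient, n=n, rho=np.nan,
                         p_value=np.nan, flag="",
                         note=f"only {n} complete pairs (< {MIN_COMPLETE_PAIRS})")
                )
                continue
            x, y = x_all[ok], y_all[ok]
            res = stats.spearmanr(x, y)  # t-approximation p
            rho = float(res.statistic)
            if method == "t":
                p = float(res.pvalue)
            elif method == "permutation":
                p = _permutation_p(x, y, rho, n_perm, rng)
            else:
                raise ValueError(f"unknown method {method!r}")
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            rows.append(
                dict(mgs_id=mgs_id, nutrient_id=nutrient, n=n, rho=rho,
                     p_value=p, flag=_flag(p), note="")
            )
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["q_value"] = np.nan
    if tested.any():
        out.loc[tested, "q_value"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out
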