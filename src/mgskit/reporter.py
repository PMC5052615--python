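"""Reporter-score enrichment of KEGG modules from per-KO Z-scores.

Each KO gets a signed Z-score from its two-group rank-sum p-value,
z = Phi^-1(1 - p/2), positive when the KO is enriched in the focal
group.  A module's raw score aggregates its member-KO Z-scores as
z_raw = sum(z) / sqrt(k), and is standardised against random size-k KO
sets drawn from the scored universe:
z_reporter = (z_raw - mu_k) / sigma_k.  Modules with a reporter score
above 1.6 (in either direction; the negated scores score the other
group) are called differentially enriched.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import TIE, differential_features
from .io import AbundanceMatrix, AnnotationMap, CohortLabels

__all__ = ["ko_zscores", "reporter_scores", "enriched_modules"]

logger = logging.getLogger(__name__)

P_CLIP = 1e-15


def ko_zscores(
    ko_abund: AbundanceMatrix,
    labels: CohortLabels,
    focal_group: str | None = None,
) -> pd.Series:
    """Signed per-KO Z-scores from two-sided rank-sum p-values.

    z = Phi^-1(1 - p/2) with a positive sign when the KO's mean rank is
    higher in the focal group (default: the first group label).  p is
    clipped to [1e-15, 1 - 1e-15] before inversion; constant KOs get
    z = 0 with a warning.
    """
    g_a, g_b = labels.two_groups()
    focal = focal_group if focal_group is not None else g_a
    if focal not in (g_a, g_b):
        raise ValueError(f"focal group {focal!r} not among labels {g_a!r}, {g_b!r}")
    res = differential_features(ko_abund, labels, q_threshold=1.0)
    p = np.clip(res["p_value"].to_numpy(), P_CLIP, 1 - P_CLIP)
    z = stats.norm.ppf(1 - p / 2)
    sign = np.where(
        res["direction"] == focal, 1.0, np.where(res["direction"] == TIE, 0.0, -1.0)
    )
    n_const = int((res["direction"] == TIE).sum())
    if n_const:
        warnings.warn(f"{n_const} tied/constant KO(s) assigned z = 0", stacklevel=2)
    return pd.Series(z * sign, index=res.index, name="z")


def reporter_scores(
    ko_z: pd.Series,
    modules: AnnotationMap | dict[str, set[str]],
    n_background: int = 1000,
    seed: int = 0,
    threshold: float = 1.6,
    focal_group: str = "focal",
    other_group: str = "other",
) -> pd.DataFrame:
    """Background-corrected reporter scores for every KO module.

    For each module size k present, ``n_background`` random size-k KO
    sets are drawn (without replacement) from the scored universe to
    estimate mu_k and sigma_k of the raw score.  The background of the
    negated Z-scores is the exact mirror (mu flips sign, sigma is
    unchanged), so a single standardisation scores both directions: a
    module is enriched towards the focal group when z_reporter > 1.6
    and towards the other group when -z_reporter > 1.6.

    Returns a DataFrame indexed by module id with columns ``k``,
    ``z_raw``, ``z_reporter``, ``direction``, ``enriched``.  Modules
    with no member KO in the data are skipped (logged).
    """
    mod_map = modules.modules if isinstance(modules, AnnotationMap) else modules
    if not mod_map:
        raise ValueError("no modules given")
    universe = ko_z.index.to_numpy()
    z = ko_z.to_numpy(dtype=float)
    if universe.size < 2:
        raise ValueError("KO universe too small for background sampling")
    rng = np.random.default_rng(seed)

    present: dict[str, list[str]] = {}
    for mod, kos in sorted(mod_map.items()):
        hit = sorted(set(kos) & set(universe))
        if hit:
            present[mod] = hit
        else:
            logger.info("module %s has no scored KO; skipped", mod)

    if not present:
        return pd.DataFrame(
            columns=["k", "z_raw", "z_reporter", "direction", "enriched"],
            index=pd.Index([], name="module_id"),
        )

    sizes = sorted({len(kos) for kos in present.values()})
    bg: dict[int, tuple[float, float]] = {}
    for k in sizes:
        draws = np.empty(n_background)
        for b in range(n_background):
            idx = rng.choice(universe.size, size=k, replace=False)
            draws[b] = z[idx].sum() / np.sqrt(k)
        mu, sigma = draws.mean(), draws.std(ddof=0)
        if sigma <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(
                f"degenerate background (sigma = 0) for module size {k}; "
                "KO universe carries no score variation"
            )
        bg[k] = (float(mu), float(sigma))

    zmap = dict(zip(universe, z))
    rows = []
    for mod, kos in present.items():
        k = len(kos)
        z_raw = sum(zmap[ko] for ko in kos) / np.sqrt(k)
        mu, sigma = bg[k]
        z_rep = (z_raw - mu) / sigma
        direction = focal_group if z_rep >= 0 else other_group
        rows.append(
            {
                "module_id": mod,
                "k": k,
                "z_raw": z_raw,
                "z_reporter": z_rep,
                "direction": direction,
                "enriched": abs(z_rep) > threshold,
            }
        )
    return pd.DataFrame(rows).set_index("module_id")


def enriched_modules(results: pd.DataFrame, threshold: float = 1.6) -> pd.DataFrame:
    """Modules whose directional reporter score strictly exceeds threshold.

    Sorted by descending score magnitude.
    """
    score = results["z_reporter"].abs()
    out = results.loc[score > threshold].copy()
    return out.sort_values("z_reporter", key=lambda s: s.abs(), ascending=False)
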