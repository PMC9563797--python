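"""Direction-split over-representation analysis of significant CpGs.

Significant CpGs (p below a cutoff) are split by direction — hypo (less
methylation in patients, negative t) versus hyper — and each CpG category
(chromHMM state, TF binding, histone mark, island relation) is tested for
over-representation by the upper-tail hypergeometric test within a fixed
CpG universe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffmeth import adjust_bh

__all__ = ["select_cpgs", "ora", "exclusion_rerun"]


def select_cpgs(
    stats: pd.DataFrame, alpha: float = 0.01, direction: str = "hypo"
) -> set:
    """CpGs with p < alpha whose sign of t matches the direction.

    ``hypo`` means less methylation in patients (negative t/effect).
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    sign_ok = stats["t"] < 0 if direction == "hypo" else stats["t"] > 0
    sel = set(stats.index[(stats["p"] < alpha) & sign_ok])
    if not sel:
        warnings.warn(f"no CpGs selected for direction={direction}", stacklevel=2)
    return sel


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Sample odds ratio of the 2x2 overlap table, Haldane-corrected at zeros."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def ora(
    selected: set,
    category_db: dict,
    universe: set,
    min_gs: int = 4,
    max_gs: float = np.inf,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each category.

    Categories are intersected with the universe before the size filter;
    p = P(X >= k) for X ~ Hypergeom(N, K, n), BH-adjusted across the tested
    categories.
    """
    universe = set(universe)
    if not set(selected) <= universe:
        raise ValueError("selected CpGs must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for cat in sorted(category_db):
        members = set(category_db[cat]) & universe
        K = len(members)
        if K < min_gs or K > max_gs:
            continue
        k = len(members & set(selected))
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, N, K, n, k, _odds_ratio(k, K, n, N), min(p, 1.0)))
    res = pd.DataFrame(
        rows, columns=["category", "N", "K", "n", "k", "odds_ratio", "p"]
    ).set_index("category")
    if len(res):
        res["p_adj"] = adjust_bh(res["p"].values)
    else:
        res["p_adj"] = []
    return res


def exclusion_rerun(
    stats_reduced: pd.DataFrame,
    category_db: dict,
    alpha: float = 0.01,
    direction: str = "hypo",
    min_gs: int = 4,
    max_gs: float = np.inf,
) -> pd.DataFrame:
    """ORA on statistics recomputed on a reduced CpG universe.

    ``stats_reduced`` must come from re-running the t-stage with the masked
    region's CpGs removed; universe, selection and statistics are then all
    consistently restricted.
    """
    universe = set(stats_reduced.index)
    selected = select_cpgs(stats_reduced, alpha=alpha, direction=direction)
    return ora(selected, category_db, universe, min_gs=min_gs, max_gs=max_gs)
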