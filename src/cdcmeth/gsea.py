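"""Preranked gene-set enrichment engine used at two levels.

Level one integrates per-CpG moderated t-statistics into per-gene promoter
(or gene-body) enrichment: each gene's CpG set is tested against the full
CpG ranking with the weighted Kolmogorov-Smirnov running-sum statistic.  The
per-gene result is condensed into a signed score, sign(NES) * -log10(p.adj).
Level two ranks genes by that score and tests functional categories
(GO/disease-gene style sets) the same way.

The permutation null draws random same-size sets from the ranked list
(without replacement, seeded); NES normalises the observed ES by the mean
magnitude of same-sign null scores, and p-values carry a pseudocount so they
are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffmeth import adjust_bh

__all__ = [
    "RankedList",
    "rank_items",
    "es_score",
    "preranked_gsea",
    "promoter_enrichment",
    "chained_gsea",
    "leading_edge_genes",
    "region_map",
]

P_ADJ_FLOOR = 1e-16  # keeps sign(NES) * -log10(p.adj) finite


@dataclass
class RankedList:
    """Items in decreasing statistic order; ties broken by item id."""

    ids: np.ndarray
    stats: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.stats).all():
            raise ValueError("non-finite ranking statistics")

    def __len__(self) -> int:
        return len(self.ids)


def rank_items(stats: pd.Series, exclude_mask=None) -> RankedList:
    """Rank items by decreasing statistic; ties broken by id (ascending).

    ``stats`` maps item id -> statistic (a frame with a ``t`` column is also
    accepted).  ``exclude_mask`` removes the given ids before ranking; when
    the exclusion is genomic the caller is expected to re-run the t-stage on
    the reduced universe rather than just mask ranked output.
    """
    if isinstance(stats, pd.DataFrame):
        stats = stats["t"]
    if exclude_mask is not None:
        stats = stats.loc[~stats.index.isin(set(exclude_mask))]
    if len(stats) < 10:
        raise ValueError("fewer than 10 items after exclusion")
    ids = stats.index.to_numpy()
    vals = stats.to_numpy(dtype=float)
    order = np.lexsort((ids, -vals))
    return RankedList(ids[order], vals[order])


def _running_sum(ranked: RankedList, member_ids, weight_p: float) -> np.ndarray:
    N = len(ranked)
    hit = np.isin(ranked.ids, list(member_ids))
    m = int(hit.sum())
    if m == 0:
        raise ValueError("member set disjoint from ranked list")
    if m == N:
        # no misses: running sum climbs monotonically to 1
        w = np.abs(ranked.stats) ** weight_p
        tot = w.sum()
        return np.cumsum(w / tot) if tot > 0 else np.cumsum(np.full(N, 1.0 / N))
    inc = np.empty(N)
    w = np.abs(ranked.stats[hit]) ** weight_p
    tot = w.sum()
    inc[hit] = w / tot if tot > 0 else 1.0 / m
    inc[~hit] = -1.0 / (N - m)
    return np.cumsum(inc)


def es_score(
    ranked: RankedList, member_set, weight_p: float = 1.0
) -> tuple[float, list]:
    """Enrichment score and leading edge of one set against the ranking.

    Hits add ``|r|^p / sum_hits |r|^p`` to the running sum, misses subtract
    ``1/(N-m)``; ES is the extremum of largest magnitude (ties favour the
    positive side).  The leading edge holds the members at or before the
    extremum for positive ES, at or after it for negative ES.
    """
    run = _running_sum(ranked, member_set, weight_p)
    i_max = int(np.argmax(run))
    i_min = int(np.argmin(run))
    hit = np.isin(ranked.ids, list(member_set))
    if run[i_max] >= -run[i_min]:
        es = float(run[i_max])
        edge = ranked.ids[: i_max + 1][hit[: i_max + 1]]
    else:
        es = float(run[i_min])
        edge = ranked.ids[i_min:][hit[i_min:]]
    return es, list(edge)


def _null_es(absr_p: np.ndarray, size: int, nperm: int, seed: int) -> np.ndarray:
    """Vectorised null: ES of ``nperm`` random ``size``-subsets of the list.

    The running sum only changes slope at hit positions, so each null ES is
    computed from the sorted hit indices alone.
    """
    N = len(absr_p)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, size])
    r = rng.random((nperm, N))
    idx = np.argpartition(r, size - 1, axis=1)[:, :size]
    idx.sort(axis=1)
    w = absr_p[idx]
    tot = w.sum(axis=1, keepdims=True)
    uniform = np.full_like(w, 1.0 / size)
    w = np.where(tot > 0, w / np.where(tot == 0, 1.0, tot), uniform)
    miss = 1.0 / (N - size)
    offs = (idx - np.arange(size)[None, :]) * miss
    after = np.cumsum(w, axis=1) - offs  # value just after each hit
    before = after - w  # value just before each hit
    mx = after.max(axis=1)
    mn = before.min(axis=1)
    return np.where(np.abs(mx) >= np.abs(mn), mx, mn)


def preranked_gsea(
    ranked: RankedList,
    sets: dict,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA of every set against the ranking.

    Returns a frame indexed by set id with columns es, nes, p, p_adj, size
    and leading_edge; skipped (size-filtered) sets are listed in
    ``result.attrs["skipped"]``.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    universe = set(ranked.ids.tolist())
    tested, skipped = {}, []
    for set_id in sorted(sets):
        members = set(sets[set_id]) & universe
        if min_size <= len(members) <= max_size:
            tested[set_id] = members
        else:
            skipped.append(set_id)
    if not tested:
        raise ValueError("no set passes the size filter")

    absr_p = np.abs(ranked.stats) ** weight_p
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for set_id, members in tested.items():
        s = len(members)
        if s not in null_cache:
            null_cache[s] = _null_es(absr_p, s, nperm, seed)
        null = null_cache[s]
        es, edge = es_score(ranked, members, weight_p)
        if es >= 0:
            same = null[null >= 0]
            n_extreme = int((same >= es).sum())
        else:
            same = null[null < 0]
            n_extreme = int((same <= es).sum())
        p = (n_extreme + 1) / (len(same) + 1)
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        rows.append((set_id, es, nes, p, s, tuple(edge)))

    res = pd.DataFrame(
        rows, columns=["set_id", "es", "nes", "p", "size", "leading_edge"]
    ).set_index("set_id")
    res.insert(3, "p_adj", adjust_bh(res["p"].values))
    res.attrs["skipped"] = skipped
    res.attrs["nperm"] = nperm
    return res


def region_map(annotation: pd.DataFrame, region: str = "promoter") -> dict:
    """gene -> CpG-id set from the annotation's promoter/body gene columns."""
    col = {"promoter": "promoter_genes", "gene_body": "body_genes"}[region]
    out: dict = {}
    for probe, genes in annotation[col].items():
        if not isinstance(genes, str) or not genes:
            continue
        for g in genes.split(";"):
            out.setdefault(g, set()).add(probe)
    return out


def promoter_enrichment(
    ranked_cpgs: RankedList,
    gene_to_cpgs: dict,
    nperm: int = 1000,
    seed: int = 0,
    min_cpgs: int = 5,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Per-gene enrichment of its region CpGs in the CpG ranking.

    Adds the signed gene score sign(NES) * -log10(p.adj), with p.adj floored
    so the score stays finite.
    """
    res = preranked_gsea(
        ranked_cpgs,
        gene_to_cpgs,
        nperm=nperm,
        seed=seed,
        min_size=min_cpgs,
        max_size=10**9,
        weight_p=weight_p,
    )
    res["score"] = np.sign(res["nes"]) * -np.log10(res["p_adj"].clip(lower=P_ADJ_FLOOR))
    return res


def chained_gsea(
    gene_scores: pd.Series,
    gene_set_db: dict,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Second-level GSEA: functional categories against the gene-score ranking.

    Negative NES means less CpG methylation in patients for that category.
    """
    ranked = rank_items(gene_scores)
    res = preranked_gsea(
        ranked, gene_set_db, nperm=nperm, seed=seed,
        min_size=min_size, max_size=max_size, weight_p=weight_p,
    )
    if len(res) < 2:
        raise ValueError("need >= 2 categories passing the size filter")
    return res


def leading_edge_genes(
    results: pd.DataFrame, categories, min_membership: int = 2
) -> set:
    """Genes in the leading edge of >= ``min_membership`` of the categories."""
    missing = [c for c in categories if c not in results.index]
    if missing:
        raise KeyError(f"categories absent from results: {missing}")
    counts: dict = {}
    for c in categories:
        for g in set(results.loc[c, "leading_edge"]):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= min_membership}
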