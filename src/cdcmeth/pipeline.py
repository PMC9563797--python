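"""End-to-end orchestration: cohort -> filtered M values -> moderated t ->
two-level enrichment, with region-exclusion reruns.

Region exclusion follows the re-ranking rule: the t-stage is re-run on the
reduced CpG universe, per-gene promoter scores are recomputed from the
reduced ranking, and only then is the category-level GSEA repeated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import diffmeth, gsea, preprocess
from .containers import IntensityMatrix, MethylationMatrix, PairedDesign


@dataclass
class ChainedResult:
    stats: pd.DataFrame  # per-CpG moderated-t table
    promoter: pd.DataFrame  # per-gene enrichment + signed score
    categories: pd.DataFrame  # per-category enrichment


def cohort_m_values(
    intensities: IntensityMatrix,
    annotation: pd.DataFrame,
    detection_threshold: float = 0.01,
    offset: float = 100.0,
    clip_eps: float = 1e-6,
) -> tuple[MethylationMatrix, dict]:
    """Filter probes and convert to M values; returns (M, filter log)."""
    retained, log = preprocess.filter_probes(intensities, annotation, detection_threshold)
    sub = intensities.subset(retained)
    beta = preprocess.compute_beta(sub, offset=offset)
    return preprocess.compute_m(beta, clip_eps=clip_eps), log


def region_probe_ids(annotation: pd.DataFrame, chrom: str, start: float = 0,
                     end: float = float("inf")) -> set:
    """CpG ids falling in [start, end) on a chromosome."""
    sub = annotation.loc[
        (annotation["chrom"] == chrom)
        & (annotation["pos"] >= start)
        & (annotation["pos"] < end)
    ]
    return set(sub.index)


def chained_analysis(
    M: MethylationMatrix,
    design: PairedDesign,
    annotation: pd.DataFrame,
    gene_sets: dict,
    region: str = "promoter",
    covariates: list | None = None,
    exclude_probes: set | None = None,
    nperm: int = 1000,
    seed: int = 0,
    min_cpgs: int = 5,
    min_size: int = 10,
    max_size: int = 500,
) -> ChainedResult:
    """CpG t-statistics -> per-gene promoter scores -> category enrichment.

    ``exclude_probes`` removes CpGs *before* the t-stage so the whole chain
    runs on the reduced universe.
    """
    if exclude_probes:
        keep = M.values.index[~M.values.index.isin(exclude_probes)]
        M = MethylationMatrix(M.values.loc[keep], M.scale, M.provenance)
    stats = diffmeth.paired_stats(M, design, covariates=covariates)
    ranked = gsea.rank_items(stats["t"])
    gene_map = gsea.region_map(annotation.loc[annotation.index.isin(stats.index)], region)
    promoter = gsea.promoter_enrichment(
        ranked, gene_map, nperm=nperm, seed=seed, min_cpgs=min_cpgs
    )
    categories = gsea.chained_gsea(
        promoter["score"], gene_sets, nperm=nperm, seed=seed + 1,
        min_size=min_size, max_size=max_size,
    )
    return ChainedResult(stats, promoter, categories)
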