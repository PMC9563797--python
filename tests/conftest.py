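import pytest

from cdcmeth import SimConfig, make_annotation, simulate_cohort
from cdcmeth.pipeline import cohort_m_values


@pytest.fixture(scope="session")
def small_cohort():
    """Small paired cohort with one planted hypomethylated gene set."""
    cfg = SimConfig(
        n_cpgs=3000,
        n_genes=80,
        n_categories=10,
        genes_per_category=12,
        planted_sets=[("SET000", "hypo", 0.2)],
        seed=11,
    )
    bundle = make_annotation(cfg)
    intensities, design, truth = simulate_cohort(bundle, cfg)
    return cfg, bundle, intensities, design, truth


@pytest.fixture(scope="session")
def small_stats(small_cohort):
    """Filtered M values and the per-CpG moderated-t table for the cohort."""
    from cdcmeth import paired_stats

    _, bundle, intensities, design, _ = small_cohort
    M, log = cohort_m_values(intensities, bundle.annotation)
    stats = paired_stats(M, design)
    return M, stats, log
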