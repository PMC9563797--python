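"""Synthetic paired methylation cohort with planted truth.

Emulates the statistical structure the analysis assumes: paired
patient/control samples, bimodal beta baselines, lognormal total
intensities, hemizygous 5p intensity halving up to a per-patient
breakpoint, promoter hypo-/hyper-methylation planted in chosen gene sets
(preferentially on bivalent-marked CpGs), sporadic detection-p failures,
and recorded covariates.  Every draw flows from one seeded generator, so a
fixed seed reproduces the cohort byte for byte.

Coordinates are 1-based; intervals are half-open [start, end).  Promoters
span TSS-2000..TSS+500.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, PairSet, PairedDesign

CHR5_LENGTH = 181_538_259  # GRCh38 chromosome 5
CHR5_CENTROMERE = 48_800_000  # p-arm boundary

BIVALENT_MARKS = ("EZH2", "SUZ12", "H3K27me3", "H3K4me2", "H3K4me3")


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the modelled study: eight patient/control pairs,
    deletions spanning roughly 6-35 Mb of the 5p arm, lognormal array
    intensities, and small per-sample beta noise.
    """

    n_pairs: int = 8
    n_cpgs: int = 12000
    chrom_lengths: dict = field(
        default_factory=lambda: {
            "chr1": 248_000_000,
            "chr2": 242_000_000,
            "chr5": CHR5_LENGTH,
        }
    )
    chr5_centromere: float = float(CHR5_CENTROMERE)
    breakpoints: list | None = None  # bp per pair; 0 = no deletion; None -> uniform [6, 35] Mb
    intensity_log_sd: float = 0.2
    mean_intensity: float = 5000.0
    beta_noise_sd: float = 0.03
    background_effect_sd: float = 0.02  # per-gene inter-individual promoter drift
    beta_mix_a: float = 2.0  # Beta(a, b) low mode; high mode is its mirror
    beta_mix_b: float = 18.0
    planted_sets: list = field(default_factory=list)  # (set_id, "hypo"|"hyper", delta)
    frac_detection_fail: float = 0.001
    n_genes: int = 300
    min_cpgs_per_promoter: int = 5
    body_cpgs_per_gene: int = 3
    gene_body_length: int = 20000
    n_categories: int = 20
    genes_per_category: int = 20
    frac_snp_flagged: float = 0.0
    bivalent_frac: float = 0.10
    bivalent_cooccurrence: float = 0.8
    bivalent_background: float = 0.02
    planted_bivalent: bool = True
    confound_age: bool = False
    age_drift_per_year: float = 0.0
    multi_sample: dict = field(default_factory=dict)  # pair index -> (n_patient, n_control)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.n_cpgs < 100:
            raise ValueError("n_cpgs must be >= 100")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        if self.breakpoints is not None:
            if len(self.breakpoints) != self.n_pairs:
                raise ValueError("breakpoints must have one entry per pair")
            L = self.chrom_lengths.get("chr5", CHR5_LENGTH)
            if any(not 0 <= b <= L for b in self.breakpoints):
                raise ValueError("breakpoints must lie within chr5")
        for set_id, direction, delta in self.planted_sets:
            if direction not in ("hypo", "hyper"):
                raise ValueError(f"bad direction {direction!r} for {set_id}")
            if not 0 < delta < 1:
                raise ValueError("effect_delta_beta must be in (0, 1)")
        if not 0 <= self.frac_detection_fail <= 1:
            raise ValueError("frac_detection_fail must be in [0, 1]")


@dataclass
class AnnotationBundle:
    annotation: pd.DataFrame  # probe_id-indexed
    genes: pd.DataFrame  # gene-indexed: chrom, tss, promoter/body bounds
    gene_sets: dict  # category id -> list of genes
    mark_db: dict  # mark -> set of CpG ids


@dataclass
class TruthRecord:
    breakpoints: dict  # pair_id -> bp (0 = none)
    cpg_delta: pd.Series  # per-CpG planted patient-minus-control delta beta
    planted_genes: dict  # set_id -> list of genes
    planted_cpgs: dict  # set_id -> list of promoter CpGs
    sample_info: pd.DataFrame  # sample_id, pair_id, role, age, sex

    def to_frame(self) -> pd.DataFrame:
        out = self.cpg_delta.rename("delta").to_frame()
        out["planted_sets"] = ""
        for sid, cpgs in self.planted_cpgs.items():
            sub = out.index.isin(cpgs)
            out.loc[sub, "planted_sets"] = (
                out.loc[sub, "planted_sets"] + ";" + sid
            ).str.lstrip(";")
        return out


def make_annotation(config: SimConfig) -> AnnotationBundle:
    """Gene layout, CpG scatter, category/mark databases and gene sets."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)

    # genes per chromosome, proportional to length
    n_per = np.maximum(1, np.round(config.n_genes * lengths / lengths.sum())).astype(int)
    window = 2000 + 500 + config.gene_body_length
    gene_rows = []
    g_idx = 0
    for c, L, ng in zip(chroms, lengths, n_per):
        slot = int(L // ng)
        if slot < window + 2000:
            raise ValueError(f"too many genes for {c}: slot {slot} < window {window}")
        for i in range(ng):
            tss = i * slot + 2001 + int(rng.integers(0, slot - window - 2000))
            gene_rows.append(
                {
                    "gene": f"G{g_idx:04d}",
                    "chrom": c,
                    "tss": tss,
                    "promoter_start": tss - 2000,
                    "promoter_end": tss + 500,
                    "body_start": tss + 500,
                    "body_end": tss + 500 + config.gene_body_length,
                }
            )
            g_idx += 1
    genes = pd.DataFrame(gene_rows).set_index("gene")

    # CpGs: guaranteed promoter/body coverage, remainder scattered uniformly
    cpg_chrom, cpg_pos, prom_gene, body_gene = [], [], [], []
    for gene, row in genes.iterrows():
        ppos = rng.choice(
            np.arange(row.promoter_start, row.promoter_end),
            size=config.min_cpgs_per_promoter,
            replace=False,
        )
        for p in np.sort(ppos):
            cpg_chrom.append(row.chrom)
            cpg_pos.append(int(p))
            prom_gene.append(gene)
            body_gene.append("")
        bpos = rng.choice(
            np.arange(row.body_start, row.body_end),
            size=config.body_cpgs_per_gene,
            replace=False,
        )
        for p in np.sort(bpos):
            cpg_chrom.append(row.chrom)
            cpg_pos.append(int(p))
            prom_gene.append("")
            body_gene.append(gene)
    n_structured = len(cpg_pos)
    if config.n_cpgs < n_structured:
        raise ValueError(
            f"n_cpgs={config.n_cpgs} too small for {n_structured} gene-anchored CpGs"
        )
    n_free = config.n_cpgs - n_structured
    free_chrom_idx = rng.choice(len(chroms), size=n_free, p=lengths / lengths.sum())
    free_pos = (rng.random(n_free) * lengths[free_chrom_idx]).astype(int) + 1
    for ci, p in zip(free_chrom_idx, free_pos):
        cpg_chrom.append(chroms[ci])
        cpg_pos.append(int(p))
        prom_gene.append("")
        body_gene.append("")

    n = len(cpg_pos)
    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])
    in_promoter = np.array([g != "" for g in prom_gene])
    in_body = np.array([g != "" for g in body_gene])

    island = np.where(
        in_promoter,
        np.where(rng.random(n) < 0.8, "Island", "Shore"),
        np.where(rng.random(n) < 0.2, "Shore", "OpenSea"),
    )
    chromhmm = np.where(
        in_promoter,
        np.where(rng.random(n) < 0.7, "TssA", "EnhA"),
        np.where(in_body, "Tx", np.where(rng.random(n) < 0.7, "Quies", "Het")),
    )
    snp_flag = rng.random(n) < config.frac_snp_flagged

    annotation = pd.DataFrame(
        {
            "chrom": cpg_chrom,
            "pos": cpg_pos,
            "island": island,
            "chromhmm": chromhmm,
            "promoter_genes": prom_gene,
            "body_genes": body_gene,
            "snp_flag": snp_flag,
            "sex_flag": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # functional gene categories (GMT-style), deterministic order
    all_genes = genes.index.to_numpy()
    gene_sets = {
        f"SET{i:03d}": sorted(
            rng.choice(all_genes, size=min(config.genes_per_category, len(all_genes)),
                       replace=False)
        )
        for i in range(config.n_categories)
    }

    # bivalent marks: an EZH2-seeded promoter subset with tunable co-occurrence
    planted_gene_pool = {
        g for sid, _, _ in config.planted_sets for g in gene_sets.get(sid, [])
    }
    prom_gene_arr = np.asarray(prom_gene, dtype=object)
    seed_prob = np.where(
        in_promoter,
        np.where(
            np.isin(prom_gene_arr, sorted(planted_gene_pool)) & config.planted_bivalent,
            0.8,
            config.bivalent_frac,
        ),
        0.0,
    )
    is_seed = rng.random(n) < seed_prob
    mark_db: dict = {"EZH2": set(probe_ids[is_seed])}
    for mark in BIVALENT_MARKS[1:]:
        with_seed = is_seed & (rng.random(n) < config.bivalent_cooccurrence)
        background = ~is_seed & (rng.random(n) < config.bivalent_background)
        mark_db[mark] = set(probe_ids[with_seed | background])

    return AnnotationBundle(annotation, genes, gene_sets, mark_db)


def _sample_layout(config: SimConfig) -> list[tuple[str, list, list]]:
    layout = []
    for i in range(1, config.n_pairs + 1):
        n_pat, n_ctrl = config.multi_sample.get(i, (1, 1))
        pats = [f"p{i}"] if n_pat == 1 else [f"p{i}-{j + 1}" for j in range(n_pat)]
        ctrls = [f"c{i}"] if n_ctrl == 1 else [f"c{i}-{j + 1}" for j in range(n_ctrl)]
        layout.append((str(i), pats, ctrls))
    return layout


def simulate_cohort(
    bundle: AnnotationBundle, config: SimConfig
) -> tuple[IntensityMatrix, PairedDesign, TruthRecord]:
    """Draw intensities, design and truth for the configured cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    ann = bundle.annotation
    probes = ann.index
    n = len(probes)

    # breakpoints (bp on chr5; 0 = no deletion)
    if config.breakpoints is None:
        bps = rng.uniform(6e6, 35e6, size=config.n_pairs)
    else:
        bps = np.asarray(config.breakpoints, dtype=float)

    layout = _sample_layout(config)
    breakpoints = {pid: float(bp) for (pid, _, _), bp in zip(layout, bps)}

    # covariates
    ctrl_age = rng.uniform(1, 40, size=config.n_pairs)
    age_diff = rng.normal(0, 2, size=config.n_pairs)
    sex = rng.integers(0, 2, size=config.n_pairs)

    # planted promoter effects
    delta = np.zeros(n)
    planted_genes: dict = {}
    planted_cpgs: dict = {}
    prom = ann["promoter_genes"].to_numpy(dtype=object)
    for set_id, direction, eff in config.planted_sets:
        if set_id not in bundle.gene_sets:
            raise KeyError(f"planted set {set_id!r} not in the gene-set database")
        gset = bundle.gene_sets[set_id]
        mask = np.isin(prom, gset)
        delta[mask] = eff if direction == "hyper" else -eff
        planted_genes[set_id] = list(gset)
        planted_cpgs[set_id] = list(probes[mask])

    # baseline betas: bimodal mixture near 0.1 and 0.9
    a, b = config.beta_mix_a, config.beta_mix_b
    low = rng.beta(a, b, size=n)
    high = rng.beta(b, a, size=n)
    base = np.where(rng.random(n) < 0.5, low, high)
    # planted CpGs keep headroom for the full effect so the planted delta is
    # realised rather than truncated at the beta boundary
    margin = 4 * config.beta_noise_sd + 0.01
    for set_id, direction, eff in config.planted_sets:
        mask = np.isin(prom, bundle.gene_sets[set_id])
        if direction == "hypo":
            base[mask] = np.clip(base[mask], eff + margin, 1 - margin)
        else:
            base[mask] = np.clip(base[mask], margin, 1 - eff - margin)
    drift_dir = rng.normal(0, 1, size=n)  # per-CpG age-drift loading

    chrom = ann["chrom"].to_numpy()
    pos = ann["pos"].to_numpy(dtype=float)
    on_5p = (chrom == "chr5") & (pos < config.chr5_centromere)

    # background inter-individual promoter drift: a random patient-vs-control
    # shift per (gene, pair), shared by all CpGs of that promoter — gives the
    # gene-score ranking the continuum real cohorts show
    gene_list = bundle.genes.index.to_numpy()
    gene_idx = {g: i for i, g in enumerate(gene_list)}
    cpg_gene = np.array([gene_idx.get(g, -1) for g in prom], dtype=int)
    bg = (
        rng.normal(0, config.background_effect_sd, size=(len(gene_list), config.n_pairs))
        if config.background_effect_sd > 0
        else np.zeros((len(gene_list), config.n_pairs))
    )

    sets, meth_cols, unmeth_cols, detp_cols, info_rows = [], {}, {}, {}, []
    mean_age = float(np.mean(ctrl_age))
    for idx, (pid, pats, ctrls) in enumerate(layout):
        p_age = ctrl_age[idx] + age_diff[idx]
        eff_scale = 1.0 + age_diff[idx] / 5.0 if config.confound_age else 1.0
        for sid in pats + ctrls:
            is_patient = sid in pats
            age = p_age if is_patient else ctrl_age[idx]
            beta = base + (delta * eff_scale if is_patient else 0.0)
            if is_patient:
                beta = beta + np.where(cpg_gene >= 0, bg[cpg_gene, idx], 0.0)
            beta = beta + config.age_drift_per_year * (age - mean_age) * drift_dir
            if config.beta_noise_sd > 0:
                beta = beta + rng.normal(0, config.beta_noise_sd, size=n)
            beta = np.clip(beta, 1e-6, 1 - 1e-6)
            if config.intensity_log_sd > 0:
                T = config.mean_intensity * np.exp(
                    rng.normal(0, config.intensity_log_sd, size=n)
                )
            else:
                T = np.full(n, config.mean_intensity)
            if is_patient and breakpoints[pid] > 0:
                T = np.where(on_5p & (pos < breakpoints[pid]), T / 2.0, T)
            meth_cols[sid] = T * beta
            unmeth_cols[sid] = T * (1 - beta)
            detp_cols[sid] = rng.uniform(0, 0.005, size=n)
            info_rows.append(
                {
                    "sample_id": sid,
                    "pair_id": pid,
                    "role": "patient" if is_patient else "control",
                    "age": float(age),
                    "sex": int(sex[idx]),
                }
            )
        sets.append(
            PairSet(pid, pats, ctrls, {"age_diff": float(age_diff[idx]), "sex": int(sex[idx])})
        )

    meth = pd.DataFrame(meth_cols, index=probes)
    unmeth = pd.DataFrame(unmeth_cols, index=probes)
    detp = pd.DataFrame(detp_cols, index=probes)

    # planted detection failures: one random sample per failing CpG
    n_fail = int(round(config.frac_detection_fail * n))
    if n_fail:
        fail_idx = rng.choice(n, size=n_fail, replace=False)
        fail_col = rng.integers(0, detp.shape[1], size=n_fail)
        for fi, fc in zip(fail_idx, fail_col):
            detp.iloc[fi, fc] = rng.uniform(0.01, 0.5)

    design = PairedDesign(sets)
    truth = TruthRecord(
        breakpoints=breakpoints,
        cpg_delta=pd.Series(delta, index=probes),
        planted_genes=planted_genes,
        planted_cpgs=planted_cpgs,
        sample_info=pd.DataFrame(info_rows),
    )
    return IntensityMatrix(meth, unmeth, detp), design, truth


def write_cohort(outdir: str, bundle: AnnotationBundle, intensities, design, truth) -> None:
    """Write the full cohort in the pipeline's text dialects."""
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    cio.write_intensities(intensities, os.path.join(outdir, "intensities.tsv"))
    cio.write_annotation(bundle.annotation, os.path.join(outdir, "annotation.tsv"))
    cio.write_gene_bed(bundle.genes, os.path.join(outdir, "genes.bed"))
    cio.write_gmt(bundle.gene_sets, os.path.join(outdir, "gene_sets.gmt"))
    cio.write_gmt(bundle.mark_db, os.path.join(outdir, "marks.gmt"))
    cio.write_design(design, os.path.join(outdir, "design.tsv"))
    truth.to_frame().to_csv(os.path.join(outdir, "truth_cpgs.tsv"), sep="\t")
    pd.Series(truth.breakpoints, name="breakpoint").rename_axis("pair_id").to_csv(
        os.path.join(outdir, "truth_breakpoints.tsv"), sep="\t"
    )
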