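"""Downstream characterisations: bivalent-promoter scoring, top-CpG heatmap
matrix, external-signature correlation, linear epigenetic clocks,
reference-based cell deconvolution, and PCA-based QC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .containers import ClockModel, ExternalSignature, MethylationMatrix, PairedDesign
from .diffmeth import pair_differences
from .gsea import leading_edge_genes

BIVALENT_MARKS = ("EZH2", "SUZ12", "H3K27me3", "H3K4me2", "H3K4me3")


def count_bivalent(
    cpg_ids, mark_db: dict, marks=BIVALENT_MARKS
) -> tuple[pd.Series, dict]:
    """Per-CpG count of bivalent-promoter marks and a >=4/5, =5/5 summary.

    ``mark_db`` maps mark name -> set of CpG ids carrying the mark.
    """
    missing = [m for m in marks if m not in mark_db]
    if missing:
        raise KeyError(f"marks absent from database: {missing}")
    cpg_ids = list(cpg_ids)
    counts = pd.Series(
        [sum(c in mark_db[m] for m in marks) for c in cpg_ids],
        index=cpg_ids,
        dtype=int,
    )
    n = len(counts)
    summary = {
        "n": n,
        "ge4": int((counts >= 4).sum()),
        "eq5": int((counts == 5).sum()),
        "frac_ge4": float((counts >= 4).mean()) if n else np.nan,
        "frac_eq5": float((counts == 5).mean()) if n else np.nan,
    }
    return counts, summary


def heatmap_matrix(
    category_results: pd.DataFrame,
    categories,
    promoter_results: pd.DataFrame,
    stats: pd.DataFrame,
    M: MethylationMatrix,
    design: PairedDesign,
    top_n: int = 100,
    min_membership: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-pair delta-M matrix for the strongest CpG of each shared gene.

    Genes appearing in the leading edge of >= ``min_membership`` of the
    given categories are reduced to their most strongly changed
    promoter-leading-edge CpG (largest |t|, ties to the lower probe id);
    cell values are the per-pair patient-minus-control M differences,
    gene rows ordered by decreasing |t| and truncated to ``top_n``.
    """
    genes = leading_edge_genes(category_results, categories, min_membership)
    genes = [g for g in sorted(genes) if g in promoter_results.index]
    chosen = {}
    for g in genes:
        edge = [c for c in promoter_results.loc[g, "leading_edge"] if c in stats.index]
        if not edge:
            continue
        t_abs = stats.loc[edge, "t"].abs()
        best = t_abs[t_abs == t_abs.max()].index.min()
        chosen[g] = best
    if not chosen:
        raise ValueError("no genes with mapped leading-edge CpGs")
    order = sorted(
        chosen, key=lambda g: (-abs(stats.loc[chosen[g], "t"]), g)
    )[:top_n]
    cpgs = pd.Series({g: chosen[g] for g in order}, name="cpg")[order]
    dM = pair_differences(M, design)
    mat = dM.loc[cpgs.values]
    mat.index = order
    return mat, cpgs


def signature_correlation(
    own_deltas: pd.Series, signature: ExternalSignature | pd.Series
) -> tuple[float, int]:
    """Pearson correlation of this cohort's deltas with an external signature,
    over the overlapping CpGs."""
    sig = signature.deltas if isinstance(signature, ExternalSignature) else signature
    common = own_deltas.index.intersection(sig.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping CpGs (need >= 3)")
    r, _ = sps.pearsonr(own_deltas.loc[common], sig.loc[common])
    return float(r), len(common)


def apply_clock(
    beta: MethylationMatrix, clock: ClockModel, min_coverage: float = 0.95
) -> pd.Series:
    """Per-sample age from a linear clock on beta values.

    Missing clock CpGs (up to 1 - min_coverage of them) are imputed with the
    per-sample mean beta over the present clock CpGs; the linear predictor
    is inverted through the clock's age transform (identity, or the
    piecewise log-linear map anchored at adult_age).
    """
    if beta.scale != "beta":
        raise ValueError("clock requires beta values")
    coefs = clock.coefficients
    present = coefs.index.intersection(beta.values.index)
    coverage = len(present) / len(coefs)
    if coverage < min_coverage:
        raise ValueError(
            f"clock {clock.name}: only {coverage:.1%} of CpGs present"
        )
    b = beta.values.loc[present]
    m = clock.intercept + b.mul(coefs.loc[present], axis=0).sum(axis=0)
    n_missing = len(coefs) - len(present)
    if n_missing:
        warnings.warn(
            f"clock {clock.name}: imputing {n_missing} missing CpGs", stacklevel=2
        )
        m = m + b.mean(axis=0) * coefs.drop(present).sum()
    if clock.transform == "identity":
        age = m
    else:  # horvath piecewise anti-log
        a = clock.adult_age
        age = pd.Series(
            np.where(m < 0, (1 + a) * np.exp(m) - 1, m * (1 + a) + a),
            index=m.index,
        )
    age.name = clock.name
    return age


def encode_clock_betas(
    clock: ClockModel, ages: pd.Series, base_beta: float = 0.5
) -> pd.DataFrame:
    """Synthesise beta values that a linear clock decodes to the given ages.

    The target linear predictor is spread over the clock CpGs on top of a
    constant baseline; used to test exact clock inversion.
    """
    a = clock.adult_age
    if clock.transform == "identity":
        m = ages.astype(float)
    else:
        m = pd.Series(
            np.where(ages < a, np.log((ages + 1) / (1 + a)), (ages - a) / (1 + a)),
            index=ages.index,
        )
    coefs = clock.coefficients
    base_pred = clock.intercept + base_beta * coefs.sum()
    # put the whole adjustment on the first CpG
    first = coefs.index[0]
    betas = pd.DataFrame(base_beta, index=coefs.index, columns=ages.index)
    betas.loc[first] = base_beta + (m - base_pred) / coefs.iloc[0]
    return betas


def deconvolve_cells(
    beta_sample: pd.Series, reference: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Constrained least-squares cell-mixture estimate for one sample.

    Solves ``min ||b - A w||^2`` with ``w >= 0`` and ``sum(w) <= 1`` over the
    reference's discriminating CpGs; returns the proportions and the
    residual norm.
    """
    common = reference.index.intersection(beta_sample.index)
    if len(common) < reference.shape[1]:
        raise ValueError("too few reference CpGs present in the sample")
    A = reference.loc[common].values
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient reference profile")
    b = beta_sample.loc[common].values.astype(float)
    k = A.shape[1]
    w0, _ = optimize.nnls(A, b)
    if w0.sum() > 1:
        w0 = w0 / w0.sum()
    res = optimize.minimize(
        lambda w: 0.5 * np.sum((A @ w - b) ** 2),
        w0,
        jac=lambda w: A.T @ (A @ w - b),
        bounds=[(0, None)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum()}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0, None)
    resid = float(np.linalg.norm(A @ w - b))
    return pd.Series(w, index=reference.columns), resid


def pca_qc(
    M: MethylationMatrix,
    covariates: pd.DataFrame | None = None,
    n_top: int = 20000,
    n_pcs: int = 5,
) -> dict:
    """PCA of the top-variance CpGs for systematic-bias checks.

    Samples are projected on the principal components of the column-centred
    top-``n_top``-variance CpG submatrix.  Numeric covariates are scored by
    Pearson correlation with each PC, binary ones by a rank-sum test.
    """
    X = M.values
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    variances = X.var(axis=1)
    top = variances.sort_values(ascending=False).index[: min(n_top, len(variances))]
    data = X.loc[top].T.values  # samples x cpgs
    data = data - data.mean(axis=0)
    if not np.any(data):
        raise ValueError("constant matrix")
    U, S, _ = np.linalg.svd(data, full_matrices=False)
    n_pcs = min(n_pcs, len(S))
    scores = pd.DataFrame(
        U[:, :n_pcs] * S[:n_pcs],
        index=X.columns,
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    )
    var_frac = pd.Series(S**2 / (S**2).sum(), index=[f"PC{i + 1}" for i in range(len(S))])
    assoc = None
    if covariates is not None:
        rows = []
        for cov in covariates.columns:
            v = covariates.loc[scores.index, cov]
            binary = v.nunique() <= 2
            for pc in scores.columns:
                if binary:
                    grp = v == v.unique()[0]
                    if grp.all() or (~grp).any() is False:
                        continue
                    stat, p = sps.mannwhitneyu(
                        scores.loc[grp, pc], scores.loc[~grp, pc]
                    )
                else:
                    stat, p = sps.pearsonr(scores[pc], v.astype(float))
                rows.append((cov, pc, float(stat), float(p)))
        assoc = pd.DataFrame(rows, columns=["covariate", "pc", "stat", "p"])
    return {"scores": scores, "variance_fraction": var_frac, "associations": assoc}
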