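"""Probe filtering and conversion of raw intensities to beta/M values.

Filtering follows the standard EPIC-array QC rules: a probe is retained only
if its detection p-value beats the threshold in *every* sample, it is not
flagged as polymorphic/cross-reactive, and it does not sit on a sex
chromosome.  Beta values use the Illumina offset convention
``meth / (meth + unmeth + offset)``; M values are the (clipped) logit2 of
beta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, MethylationMatrix

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def filter_probes(
    intensities: IntensityMatrix,
    annotation: pd.DataFrame,
    detection_threshold: float = 0.01,
) -> tuple[pd.Index, dict]:
    """Apply detection-p, SNP/cross-reactive and sex-chromosome filters.

    Returns the retained probe ids (sorted) and a per-rule removal log.
    A probe must pass *all* rules; counts in the log are per rule on the
    annotated probes, so overlapping rules can sum to more than the total
    removed.
    """
    if not 0 < detection_threshold < 1 and detection_threshold != 1.0:
        raise ValueError("detection_threshold must be in (0, 1]")
    probes = intensities.probes
    annotated = probes.intersection(annotation.index)
    n_unannotated = len(probes) - len(annotated)

    detp = intensities.detection_p.loc[annotated]
    det_ok = (detp.values < detection_threshold).all(axis=1)

    ann = annotation.loc[annotated]
    snp_flag = ann["snp_flag"].astype(bool).values if "snp_flag" in ann else np.zeros(len(ann), bool)
    sex_flag = ann["chrom"].isin(SEX_CHROMS).values
    if "sex_flag" in ann:
        sex_flag = sex_flag | ann["sex_flag"].astype(bool).values

    keep = det_ok & ~snp_flag & ~sex_flag
    retained = annotated[keep].sort_values()
    log = {
        "n_input": len(probes),
        "removed_unannotated": n_unannotated,
        "removed_detection": int((~det_ok).sum()),
        "removed_snp": int(snp_flag.sum()),
        "removed_sex": int(sex_flag.sum()),
        "n_retained": len(retained),
    }
    if len(retained) == 0:
        raise ValueError(f"no probes retained after filtering: {log}")
    return retained, log


def compute_beta(intensities: IntensityMatrix, offset: float = 100.0) -> MethylationMatrix:
    """Beta = meth / (meth + unmeth + offset), elementwise."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    denom = intensities.meth + intensities.unmeth + offset
    if offset == 0 and (denom.values == 0).any():
        raise ValueError("meth + unmeth == 0 with offset 0")
    beta = intensities.meth / denom
    return MethylationMatrix(beta, "beta", {"offset": offset})


def compute_m(beta: MethylationMatrix, clip_eps: float = 1e-6) -> MethylationMatrix:
    """M = log2(b / (1 - b)) with b clipped to [clip_eps, 1 - clip_eps]."""
    if not 0 < clip_eps < 0.5:
        raise ValueError("clip_eps must be in (0, 0.5)")
    if beta.scale != "beta":
        raise ValueError("input must be on the beta scale")
    b = beta.values.clip(lower=clip_eps, upper=1 - clip_eps)
    m = np.log2(b / (1 - b))
    prov = dict(beta.provenance)
    prov["clip_eps"] = clip_eps
    return MethylationMatrix(m, "M", prov)


def inverse_m(m: MethylationMatrix) -> MethylationMatrix:
    """Inverse logit2: beta = 2^M / (1 + 2^M)."""
    e = np.exp2(m.values)
    return MethylationMatrix(e / (1 + e), "beta", dict(m.provenance))


def total_signal(intensities: IntensityMatrix) -> pd.DataFrame:
    """Per-probe per-sample total signal, meth + unmeth."""
    return intensities.meth + intensities.unmeth
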