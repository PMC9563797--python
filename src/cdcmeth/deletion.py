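"""5p deletion-breakpoint detection from total array intensity.

A hemizygous deletion halves the total (methylated + unmethylated) signal,
so the per-CpG log2 ratio of a patient's total signal to the mean control
total sits near -1 inside the deleted region and near 0 outside.  The track
is smoothed by degree-2 local regression (tricube neighbourhood weights,
span expressed as the fraction of points in each local fit) and the
breakpoint is called as the telomere-proximal-most position beyond a noise
guard (default 5 Mb) where the smoothed signal recovers above a threshold
(default -0.25, half-way to the single-copy level).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DeletionCall, PairedDesign, RatioTrack


class ZeroControlMeanError(ValueError):
    """Raised when the control mean is zero at some probes."""

    def __init__(self, probes):
        self.probes = list(probes)
        super().__init__(f"zero control mean at {len(self.probes)} probes")


def log_ratio_track(
    patient_sums: pd.Series,
    control_sums: pd.DataFrame,
    annotation: pd.DataFrame,
    chromosome: str,
    max_pos: float | None = None,
) -> RatioTrack:
    """log2(patient total / mean control total) per CpG along one chromosome.

    ``max_pos`` restricts to positions below it (e.g. the centromere, to keep
    only the p-arm).  Probes are taken in genomic order.
    """
    if control_sums.shape[1] < 1:
        raise ValueError("need >= 1 control sample")
    ann = annotation.loc[annotation["chrom"] == chromosome]
    if max_pos is not None:
        ann = ann.loc[ann["pos"] < max_pos]
    probes = ann.index.intersection(patient_sums.index)
    ann = ann.loc[probes].sort_values("pos")
    # collapse duplicate positions (strictly increasing required downstream)
    ann = ann.loc[~ann["pos"].duplicated()]
    ctrl_mean = control_sums.loc[ann.index].mean(axis=1)
    zero = ctrl_mean.index[ctrl_mean.values == 0]
    if len(zero):
        raise ZeroControlMeanError(zero)
    vals = np.log2(patient_sums.loc[ann.index].values / ctrl_mean.values)
    return RatioTrack(ann.index.values, ann["pos"].values.astype(float), vals)


def loess_smooth(track: RatioTrack, span: float = 0.05, degree: int = 2) -> RatioTrack:
    """Local polynomial regression of the ratio on position.

    For each CpG the ``ceil(span * N)`` nearest neighbours (contiguous in
    position) get tricube weights by distance, a degree-``degree`` polynomial
    is fit by weighted least squares, and the fit is evaluated at that CpG.
    """
    x, y = track.positions, track.values
    N = len(x)
    if N < 10:
        raise ValueError("need >= 10 points to smooth")
    k = int(np.ceil(span * N))
    if k < 4:
        raise ValueError(f"span * N = {span * N:.1f} gives < 4 points per fit")
    k = min(k, N)

    # nearest k neighbours of each point are a contiguous window in 1-D
    starts = np.empty(N, dtype=int)
    lo = 0
    for i in range(N):
        hi = lo + k - 1
        while hi + 1 < N and (x[hi + 1] - x[i]) < (x[i] - x[lo]):
            lo += 1
            hi += 1
        starts[i] = lo
    idx = starts[:, None] + np.arange(k)[None, :]  # N x k window indices

    xi = x[idx] - x[:, None]
    yi = y[idx]
    dmax = np.abs(xi).max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    u = np.clip(np.abs(xi) / dmax, 0.0, 1.0)
    w = (1 - u**3) ** 3

    # weighted least squares per point, batched normal equations; offsets are
    # rescaled by the window radius so the system is well conditioned
    powers = np.arange(degree + 1)
    xs = xi / dmax
    B = xs[:, :, None] ** powers[None, None, :]  # N x k x (deg+1)
    Bw = B * w[:, :, None]
    A = np.einsum("nkp,nkq->npq", Bw, B)
    b = np.einsum("nkp,nk->np", Bw, yi)
    # ridge jitter guards exactly singular windows (duplicate offsets)
    A += 1e-10 * np.eye(degree + 1)[None, :, :]
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    smoothed = coef[:, 0]  # polynomial evaluated at offset 0
    return RatioTrack(track.probes, x, y, span=span, smoothed=smoothed)


def call_breakpoint(
    track: RatioTrack,
    patient_id: str = "",
    min_pos: float = 5e6,
    threshold: float = -0.25,
) -> DeletionCall:
    """Breakpoint = lowest position > min_pos with smoothed signal > threshold.

    If no position qualifies the loss extends past the arm ("none detected").
    If the smoothed track never drops below the threshold at or before the
    called position the patient shows no deletion; the call is flagged rather
    than reported as a spurious ~min_pos-sized deletion.  Later transient
    dips below the threshold are logged, not re-called.
    """
    if track.smoothed is None:
        raise ValueError("track must be smoothed first")
    if len(track.positions) == 0:
        raise ValueError("empty track")
    pos, sm = track.positions, track.smoothed
    params = {"span": track.span, "min_pos": min_pos, "threshold": threshold}
    eligible = pos > min_pos
    above = sm > threshold
    cand = np.flatnonzero(eligible & above)
    if cand.size == 0:
        return DeletionCall(patient_id, None, None, False, params)
    i = cand[0]
    bp = float(pos[i])
    no_deletion = bool((sm[: i + 1] > threshold).all())
    later = [float(p) for p in pos[i:][sm[i:] <= threshold]]
    return DeletionCall(
        patient_id,
        bp,
        None if no_deletion else bp,
        no_deletion,
        params,
        later_dips=later,
    )


def call_patient_deletions(
    total: pd.DataFrame,
    design: PairedDesign,
    annotation: pd.DataFrame,
    chromosome: str = "chr5",
    centromere: float | None = None,
    span: float = 0.05,
    min_pos: float = 5e6,
    threshold: float = -0.25,
) -> tuple[list[DeletionCall], dict]:
    """Run the track/smooth/call chain for every patient sample vs all controls."""
    controls = [s for ps in design.sets for s in ps.controls]
    calls, tracks = [], {}
    for ps in design.sets:
        for pat in ps.patients:
            track = log_ratio_track(
                total[pat], total[controls], annotation, chromosome, max_pos=centromere
            )
            track = loess_smooth(track, span=span)
            calls.append(call_breakpoint(track, pat, min_pos, threshold))
            tracks[pat] = track
    return calls, tracks
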