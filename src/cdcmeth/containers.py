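"""Core data containers shared across the pipeline.

All per-probe matrices are pandas DataFrames indexed by probe id with one
column per sample.  Genomic coordinates are 1-based positions; intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "MethylationMatrix",
    "PairSet",
    "PairedDesign",
    "RatioTrack",
    "DeletionCall",
    "ClockModel",
    "ExternalSignature",
]


@dataclass
class IntensityMatrix:
    """Raw methylated/unmethylated signals plus detection p-values.

    ``meth``, ``unmeth`` and ``detection_p`` are probe x sample DataFrames
    with identical index and columns.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("unmeth", "detection_p"):
            other = getattr(self, name)
            if not self.meth.index.equals(other.index) or not self.meth.columns.equals(
                other.columns
            ):
                raise ValueError(f"{name} shape/labels differ from meth")
        if (self.meth.values < 0).any() or (self.unmeth.values < 0).any():
            raise ValueError("negative intensities are not allowed")

    @property
    def probes(self) -> pd.Index:
        return self.meth.index

    @property
    def samples(self) -> pd.Index:
        return self.meth.columns

    def subset(self, probes) -> "IntensityMatrix":
        return IntensityMatrix(
            self.meth.loc[probes], self.unmeth.loc[probes], self.detection_p.loc[probes]
        )


@dataclass
class MethylationMatrix:
    """Beta and/or M values with the conversion provenance recorded."""

    values: pd.DataFrame
    scale: str  # "beta" or "M"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")


@dataclass
class PairSet:
    """One patient/control comparison set.

    Multi-sample sets (several patient or control samples for the same
    comparison) are allowed and are averaged before differencing.
    """

    pair_id: str
    patients: list
    controls: list
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patients or not self.controls:
            raise ValueError(f"set {self.pair_id} needs >=1 patient and >=1 control")


@dataclass
class PairedDesign:
    sets: list

    def __post_init__(self) -> None:
        ids = [s.pair_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair ids")

    @property
    def pair_ids(self) -> list:
        return [s.pair_id for s in self.sets]

    @property
    def n_pairs(self) -> int:
        return len(self.sets)

    def all_samples(self) -> list:
        out = []
        for s in self.sets:
            out.extend(s.patients)
            out.extend(s.controls)
        return out

    def covariate_frame(self) -> pd.DataFrame:
        """Set-level covariates, one row per pair."""
        return pd.DataFrame(
            [s.covariates for s in self.sets], index=self.pair_ids
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sets:
            for sid in s.patients:
                rows.append({"sample_id": sid, "pair_id": s.pair_id, "role": "patient"})
            for sid in s.controls:
                rows.append({"sample_id": sid, "pair_id": s.pair_id, "role": "control"})
        frame = pd.DataFrame(rows)
        cov = self.covariate_frame()
        for col in cov.columns:
            frame[col] = frame["pair_id"].map(cov[col])
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairedDesign":
        sets = []
        cov_cols = [c for c in frame.columns if c not in ("sample_id", "pair_id", "role")]
        for pid, grp in frame.groupby("pair_id", sort=True):
            patients = grp.loc[grp["role"] == "patient", "sample_id"].tolist()
            controls = grp.loc[grp["role"] == "control", "sample_id"].tolist()
            cov = {c: grp[c].iloc[0] for c in cov_cols}
            sets.append(PairSet(str(pid), patients, controls, cov))
        return cls(sets)


@dataclass
class RatioTrack:
    """Ordered per-CpG log2 intensity ratios along one chromosome."""

    probes: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    span: float | None = None
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.positions) != len(self.values):
            raise ValueError("positions/values length mismatch")


@dataclass
class DeletionCall:
    patient_id: str
    breakpoint: float | None  # bp; None = none detected (loss past the arm)
    size: float | None  # deletion size = breakpoint (telomere at 0)
    no_deletion: bool  # track never dropped below threshold
    params: dict = field(default_factory=dict)
    later_dips: list = field(default_factory=list)


@dataclass
class ClockModel:
    """Linear epigenetic clock: age = transform^-1(intercept + sum coef*beta)."""

    name: str
    intercept: float
    coefficients: pd.Series  # indexed by CpG id
    transform: str = "identity"  # "identity" or "horvath"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "horvath"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not np.isfinite(self.coefficients.values).all():
            raise ValueError("non-finite clock coefficients")


@dataclass
class ExternalSignature:
    """External differential-methylation signature (CpG id -> delta)."""

    deltas: pd.Series
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.deltas.values).all():
            raise ValueError("non-finite signature deltas")
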