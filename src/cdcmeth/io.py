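"""Readers and writers for the tabular dialects used by the pipeline.

Intensities travel as long-format TSV (probe_id, sample_id, meth, unmeth,
detection_p); annotation as wide TSV plus BED for gene intervals; gene-set
and CpG-category databases as GMT.
"""

from __future__ import annotations

import os

import pandas as pd

from .containers import IntensityMatrix, PairedDesign, ClockModel


def write_gmt(sets: dict, path: str, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            desc = (descriptions or {}).get(set_id, "na")
            members = "\t".join(str(m) for m in sorted(sets[set_id]))
            fh.write(f"{set_id}\t{desc}\t{members}\n")


def read_gmt(path: str) -> dict:
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_intensities(intensities: IntensityMatrix, path: str) -> None:
    long = (
        intensities.meth.stack()
        .rename("meth")
        .to_frame()
        .join(intensities.unmeth.stack().rename("unmeth"))
        .join(intensities.detection_p.stack().rename("detection_p"))
    )
    long.index.names = ["probe_id", "sample_id"]
    long.reset_index().to_csv(path, sep="\t", index=False)


def read_intensities(path: str) -> IntensityMatrix:
    long = pd.read_csv(path, sep="\t")
    meth = long.pivot(index="probe_id", columns="sample_id", values="meth")
    unmeth = long.pivot(index="probe_id", columns="sample_id", values="unmeth")
    detp = long.pivot(index="probe_id", columns="sample_id", values="detection_p")
    return IntensityMatrix(meth, unmeth, detp)


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    annotation.to_csv(path, sep="\t", index=True, index_label="probe_id")


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="probe_id")
    for col in ("promoter_genes", "body_genes"):
        if col in ann.columns:
            ann[col] = ann[col].fillna("")
    return ann


def write_gene_bed(genes: pd.DataFrame, path: str) -> None:
    """Gene promoter/body intervals as BED (0-based half-open, per BED)."""
    with open(path, "w") as fh:
        for gene, row in genes.sort_values(["chrom", "promoter_start"]).iterrows():
            fh.write(
                f"{row.chrom}\t{int(row.promoter_start) - 1}\t{int(row.promoter_end) - 1}"
                f"\t{gene}_promoter\n"
            )
            fh.write(
                f"{row.chrom}\t{int(row.body_start) - 1}\t{int(row.body_end) - 1}"
                f"\t{gene}_body\n"
            )


def write_design(design: PairedDesign, path: str) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str) -> PairedDesign:
    return PairedDesign.from_frame(pd.read_csv(path, sep="\t"))


def read_clock(path: str) -> ClockModel:
    """Clock coefficient CSV: header rows ``#name=``, ``#intercept=``,
    ``#transform=`` followed by cpg_id,coefficient lines."""
    meta = {"name": os.path.basename(path), "intercept": 0.0, "transform": "identity"}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            elif not line.lower().startswith("cpg_id"):
                cpg, _, coef = line.partition(",")
                rows.append((cpg.strip(), float(coef)))
    coefs = pd.Series(dict(rows), dtype=float)
    return ClockModel(
        name=str(meta["name"]),
        intercept=float(meta["intercept"]),
        coefficients=coefs,
        transform=str(meta["transform"]),
    )


def read_signature(path: str) -> pd.Series:
    sig = pd.read_csv(path)
    return pd.Series(sig["delta"].values, index=sig["cpg_id"].values, dtype=float)
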