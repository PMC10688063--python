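"""Readers and writers for the pipeline's tabular artifacts.

Formats (all plain text, tab-separated unless stated otherwise):

* counts: first column ``locus``, one column per sample id;
* sample metadata: columns ``sample``, ``lineage``, ``condition``,
  ``generation``;
* intervals: BED6 (chrom, start, end, name, score, strand), 0-based
  half-open, score ignored;
* variants: columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``,
  ``vtype``, ``sample``;
* call/z matrices: first column ``locus``, one column per
  ``lineage:generation`` pair.

Reading then writing any artifact is lossless.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    IntervalRecord,
    LoadReport,
    SampleMeta,
    ValidationError,
    VariantRecord,
)


def read_sample_meta(meta_path: str | Path) -> list[SampleMeta]:
    meta = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
    required = {"sample", "lineage", "condition", "generation"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValidationError(f"metadata file missing columns: {sorted(missing_cols)}")
    samples = []
    for _, row in meta.iterrows():
        if pd.isna(row["generation"]) or str(row["generation"]).strip() == "":
            raise ValidationError(
                f"metadata missing generation for sample {row['sample']!r}"
            )
        samples.append(
            SampleMeta(
                sample_id=str(row["sample"]),
                lineage=str(row["lineage"]),
                condition=str(row["condition"]),
                generation=int(row["generation"]),
            )
        )
    return samples


def read_count_matrix(
    path: str | Path,
    meta_path: str | Path,
    locus_class: str = "gene",
    drop_unexpressed: bool = False,
) -> tuple[CountMatrix, LoadReport]:
    """Read a counts TSV plus its sample-metadata TSV.

    Returns the validated matrix together with a load report (loci,
    samples, number of all-zero loci dropped or flagged).
    """
    counts = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if counts.index.name != "locus":
        raise ValidationError(
            f"counts file must have first column 'locus', got {counts.index.name!r}"
        )
    samples = read_sample_meta(meta_path)
    by_id = {s.sample_id: s for s in samples}
    unknown = [c for c in counts.columns if c not in by_id]
    if unknown:
        raise ValidationError(f"unknown sample ids in counts header: {unknown}")
    ordered = [by_id[c] for c in counts.columns]
    for col in counts.columns:
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError(f"non-numeric counts in sample {col!r}")
        if (vals < 0).any():
            raise ValidationError(f"negative counts in sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"non-integer counts in sample {col!r}")
    cm = CountMatrix(counts.astype(np.int64), ordered, locus_class=locus_class)
    n_zero = len(cm.removable_loci)
    report = LoadReport(
        n_loci=cm.counts.shape[0], n_samples=cm.counts.shape[1], n_dropped=0
    )
    if drop_unexpressed:
        cm = cm.drop_unexpressed()
        report.n_dropped = n_zero
        report.n_loci = cm.counts.shape[0]
    elif n_zero:
        report.messages.append(f"{n_zero} all-zero loci flagged removable")
    return cm, report


def write_count_matrix(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "locus"
    out.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "sample": [s.sample_id for s in cm.samples],
            "lineage": [s.lineage for s in cm.samples],
            "condition": [s.condition for s in cm.samples],
            "generation": [s.generation for s in cm.samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


# -- BED6 ----------------------------------------------------------------


def read_bed(path: str | Path) -> list[IntervalRecord]:
    """Read a 6-column BED file; score column is ignored."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            records.append(
                IntervalRecord(
                    chrom=chrom, start=int(start), end=int(end), strand=strand, name=name
                )
            )
    return records


def write_bed(records: Iterable[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


# -- variants ------------------------------------------------------------


def read_variants(path: str | Path, meta_path: str | Path) -> list[VariantRecord]:
    samples = {s.sample_id: s for s in read_sample_meta(meta_path)}
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt", "vtype", "sample"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"variants file missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        sid = row["sample"]
        if sid not in samples:
            raise ValidationError(f"variant references unknown sample {sid!r}")
        records.append(
            VariantRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                vtype=row["vtype"],
                sample=samples[sid],
            )
        )
    return records


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "vtype", "sample"])
        for r in records:
            writer.writerow([r.chrom, r.pos, r.ref, r.alt, r.vtype, r.sample.sample_id])


# -- derived matrices ----------------------------------------------------


def write_keyed_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a loci x (lineage, generation) matrix with lineage:gen headers."""
    out = df.copy()
    out.columns = [f"{lin}:{gen}" for lin, gen in df.columns]
    out.index.name = "locus"
    out.to_csv(path, sep="\t")


def read_keyed_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for c in df.columns:
        lineage, gen = c.rsplit(":", 1)
        cols.append((lineage, int(gen)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["lineage", "generation"])
    return df


def write_size_factors(factors: pd.Series, path: str | Path) -> None:
    factors.rename("factor").rename_axis("sample").to_csv(path, sep="\t")


def read_size_factors(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["factor"]


# -- FASTA (plain, small synthetic sequences) ----------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is None:
                raise ValidationError("FASTA sequence before header")
            else:
                seqs[name].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
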