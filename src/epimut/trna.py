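"""tRNA-derived small-RNA fragment quantification.

Small-RNA alignments (18-36 nt intervals) are assigned to tRNA loci by
>= 1 bp overlap and converted to start positions in tRNA coordinates
(5'->3' along the tRNA, so a minus-strand locus counts from its genomic
end).  A fragment is a *3' half* when its start lies at or beyond the
locus midpoint, floor(length / 2).  Per-type 3'-half counts, normalized
by sample size factors, feed the same epimutation caller used for other
small-RNA classes.  The module also computes Argonaute-IP enrichment of
tRNA fragments and a mismatch-tolerant (ungapped Hamming) scan for
putative fragment targets in genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CountMatrix, IntervalRecord, SampleMeta, ValidationError
from . import calling, inheritance

MIN_READ_LEN = 18
MAX_READ_LEN = 36


@dataclass(frozen=True)
class TrnaLocus:
    interval: IntervalRecord
    trna_type: str

    def __post_init__(self) -> None:
        if len(self.interval) < 36:
            raise ValidationError(
                f"tRNA locus {self.trna_type!r} shorter than 36 bp cannot hold halves"
            )
        if not self.trna_type:
            raise ValidationError("tRNA type must be non-empty")

    @property
    def length(self) -> int:
        return len(self.interval)


def loci_from_bed(records: list[IntervalRecord]) -> list[TrnaLocus]:
    """Interpret BED names as tRNA types (e.g. ``GlyGCC``)."""
    return [TrnaLocus(r, r.name) for r in records]


@dataclass
class FragmentProfileSet:
    """Per-locus read-start histograms plus a read-accounting report."""

    profiles: dict[str, np.ndarray]  # locus name -> counts over tRNA positions
    loci: dict[str, TrnaLocus]
    n_assigned: int = 0
    n_dropped_length: int = 0
    n_dropped_clamped: int = 0
    n_unassigned: int = 0

    @property
    def n_input(self) -> int:
        return (
            self.n_assigned
            + self.n_dropped_length
            + self.n_dropped_clamped
            + self.n_unassigned
        )


def tRNA_start(read: IntervalRecord, locus: IntervalRecord) -> int:
    """Read start in tRNA 5'->3' coordinates."""
    if locus.strand == "+":
        return read.start - locus.start
    return locus.end - read.end


def assign_reads(
    reads: list[IntervalRecord], loci: list[TrnaLocus]
) -> FragmentProfileSet:
    """Assign reads to non-overlapping tRNA loci by >= 1 bp overlap.

    Reads outside 18-36 nt are dropped (counted); reads whose tRNA-space
    start falls outside [0, length) from a partial overlap are likewise
    dropped and counted.
    """
    for a, b in zip(sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start)),
                    sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start))[1:]):
        if a.interval.overlaps(b.interval):
            raise ValidationError(
                f"overlapping tRNA loci: {a.trna_type} and {b.trna_type}"
            )
    by_chrom: dict[str, list[TrnaLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.interval.chrom, []).append(locus)
    starts_by_chrom = {}
    for chrom, ls in by_chrom.items():
        ls.sort(key=lambda l: l.interval.start)
        starts_by_chrom[chrom] = np.array([l.interval.start for l in ls])

    out = FragmentProfileSet(
        profiles={l.interval.name: np.zeros(l.length, dtype=np.int64) for l in loci},
        loci={l.interval.name: l for l in loci},
    )
    for read in reads:
        if not MIN_READ_LEN <= len(read) <= MAX_READ_LEN:
            out.n_dropped_length += 1
            continue
        candidates = by_chrom.get(read.chrom)
        if not candidates:
            out.n_unassigned += 1
            continue
        starts = starts_by_chrom[read.chrom]
        # rightmost locus starting at or before the read end; loci are
        # non-overlapping so at most its two neighbours can overlap
        idx = int(np.searchsorted(starts, read.end, side="left")) - 1
        hit = None
        for k in (idx, idx + 1):
            if 0 <= k < len(candidates) and candidates[k].interval.overlaps(read):
                hit = candidates[k]
                break
        if hit is None:
            out.n_unassigned += 1
            continue
        s = tRNA_start(read, hit.interval)
        if not 0 <= s < hit.length:
            out.n_dropped_clamped += 1
            continue
        out.profiles[hit.interval.name][s] += 1
        out.n_assigned += 1
    return out


def three_prime_half_counts(
    profiles_by_sample: dict[str, FragmentProfileSet],
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalized 3'-half counts, tRNA type x sample.

    A read belongs to the 3' half when its tRNA-coordinate start is at
    or beyond floor(length / 2); counts are summed over loci of the same
    type and divided by the sample's size factor (1.0 when absent).
    """
    table: dict[str, dict[str, float]] = {}
    for sample_id, profset in profiles_by_sample.items():
        factor = 1.0
        if size_factors is not None:
            if sample_id not in size_factors.index:
                raise ValidationError(f"missing size factor for sample {sample_id!r}")
            factor = float(size_factors[sample_id])
        col: dict[str, float] = {}
        for name, profile in profset.profiles.items():
            locus = profset.loci[name]
            half = locus.length // 2
            col[locus.trna_type] = col.get(locus.trna_type, 0.0) + float(
                profile[half:].sum()
            )
        table[sample_id] = {k: v / factor for k, v in col.items()}
    df = pd.DataFrame(table).fillna(0.0)
    df.index.name = "trna_type"
    return df


def trna_epimutations(
    table: pd.DataFrame,
    samples: list[SampleMeta],
    cutoff: float = calling.DEFAULT_CUTOFF,
    pseudocount: float = 1.0,
):
    """Call epimutations on a type x sample 3'-half table (linear model).

    The table is already normalized, so the caller runs without the
    size-factor step.  Returns (z, calls, runs).
    """
    cm = CountMatrix(
        table[[s.sample_id for s in samples]],
        samples,
        locus_class="trna_half",
        require_int=False,
    )
    z, calls = calling.call_epimutations(
        cm, model="linear", cutoff=cutoff, pseudocount=pseudocount, prenormalized=True
    )
    runs = inheritance.detect_runs(calls, cm.available)
    return z, calls, runs


def ago_enrichment(
    ip_trna: pd.Series, ip_total: pd.Series, input_trna: pd.Series, input_total: pd.Series
) -> pd.Series:
    """Input-normalized tRNA-fragment enrichment per Argonaute IP.

    enrichment = (tRNA_IP / total_IP) / (tRNA_input / total_input).
    Upstream filtering must keep only reads strictly longer than 25 nt
    (so no 22G-RNA can contaminate the tRNA signal).  An AGO with zero
    tRNA reads in its paired input has undefined enrichment (NaN).
    """
    if (ip_total <= 0).any() or (input_total <= 0).any():
        raise ValidationError("total read counts must be positive")
    ip_share = ip_trna / ip_total
    input_share = input_trna / input_total
    out = ip_share / input_share.replace(0, np.nan)
    return out.rename("enrichment")


def filter_long_reads(reads: list[IntervalRecord], min_exclusive: int = 25):
    """Keep reads strictly longer than ``min_exclusive`` nt."""
    return [r for r in reads if len(r) > min_exclusive]


# -- mismatch-tolerant target search ------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, invalid_value: int = 0) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    # anything outside ACGT mismatches everything, including itself,
    # so probe and genome use different sentinel values
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[~valid] = invalid_value
    return arr


def find_targets(
    fragments: dict[str, tuple[str, str]],
    genome: dict[str, str],
    gene_bodies: list[IntervalRecord],
    max_mismatches: int = 3,
) -> pd.DataFrame:
    """Ungapped genome scan for near-matches of tRNA fragments.

    Parameters
    ----------
    fragments
        fragment id -> (trna_type, sequence); sequences must be >= 15 nt.
    genome
        chromosome name -> sequence.
    gene_bodies
        whole-gene intervals; a hit is reported once per overlapping gene.
    max_mismatches
        Hamming tolerance; every window of fragment length on both
        strands (reverse complement for minus) is tested.

    Returns a table with one row per (gene, hit):
    gene, trna_type, chrom, position, strand, mismatches.
    """
    if max_mismatches < 0:
        raise ValidationError("max_mismatches must be >= 0")
    rows = []
    genes_by_chrom: dict[str, list[IntervalRecord]] = {}
    for g in gene_bodies:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    encoded_genome = {c: _encode(s) for c, s in genome.items()}
    for frag_id, (trna_type, seq) in fragments.items():
        if len(seq) < 15:
            raise ValidationError(f"fragment {frag_id!r} shorter than 15 nt")
        m = len(seq)
        for strand, probe in (("+", seq), ("-", revcomp(seq))):
            penc = _encode(probe, invalid_value=1)
            for chrom, genc in encoded_genome.items():
                if genc.size < m:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(genc, m)
                mism = (windows != penc).sum(axis=1)
                for pos in np.flatnonzero(mism <= max_mismatches):
                    hit = (int(pos), int(pos) + m)
                    for gene in genes_by_chrom.get(chrom, []):
                        if gene.start < hit[1] and hit[0] < gene.end:
                            rows.append(
                                {
                                    "gene": gene.name,
                                    "trna_type": trna_type,
                                    "fragment": frag_id,
                                    "chrom": chrom,
                                    "position": hit[0],
                                    "strand": strand,
                                    "mismatches": int(mism[pos]),
                                }
                            )
    return pd.DataFrame(
        rows,
        columns=["gene", "trna_type", "fragment", "chrom", "position", "strand",
                 "mismatches"],
    )
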