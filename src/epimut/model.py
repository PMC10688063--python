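"""Core data model for multigenerational mutation-accumulation (MA) line data.

The experimental design this package analyses is a set of *C. elegans*
MA lines: independent lineages propagated through 2-worm bottlenecks,
sampled every two generations (0, 2, ..., 20), with lineages assigned to
a condition (control, low-dose or high-dose genotoxic exposure).  The
founder sample (generation 0) of each lineage is the reference every
later generation is compared against.

Coordinate conventions:

* genomic intervals are 0-based half-open (BED convention) everywhere
  internally;
* variant positions are 1-based on input (VarScan dialect) and converted
  once at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("control", "low_dose", "high_dose")

#: Lineage -> condition map of the reference study design (two lineages
#: per condition).  User-defined lineages are equally valid; condition is
#: always taken from sample metadata, never inferred from the name.
DEFAULT_LINEAGES: Mapping[str, str] = {
    "C1": "control",
    "C2": "control",
    "L1": "low_dose",
    "L2": "low_dose",
    "H1": "high_dose",
    "H2": "high_dose",
}

LOCUS_CLASSES = ("gene", "g22", "g26", "pirna", "mirna", "trna_half", "other")


class ValidationError(ValueError):
    """Raised when an input artifact violates a data-model invariant."""


@dataclass(frozen=True, order=True)
class SampleMeta:
    """Identity of one sequenced sample: a (lineage, generation) point."""

    sample_id: str
    lineage: str
    condition: str
    generation: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown condition {self.condition!r}; "
                f"expected one of {CONDITIONS}"
            )
        if self.generation < 0 or self.generation % 2 != 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: generation must be an even integer >= 0, "
                f"got {self.generation}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.lineage, self.generation)


@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval, 0-based half-open, stranded (BED6 semantics)."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval {self.name!r} on {self.chrom}: end ({self.end}) must be "
                f"> start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"interval {self.name!r}: malformed strand {self.strand!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "IntervalRecord") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class VariantRecord:
    """One variant observation in one sample (VarScan-style, 1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    sample: SampleMeta

    def __post_init__(self) -> None:
        if self.vtype not in ("SNP", "indel"):
            raise ValidationError(f"unknown variant type {self.vtype!r}")
        is_snp = len(self.ref) == 1 and len(self.alt) == 1
        if self.vtype == "SNP" and not is_snp:
            raise ValidationError(
                f"variant {self.chrom}:{self.pos} {self.ref}>{self.alt}: "
                "SNP requires single-base ref and alt"
            )
        if self.vtype == "indel" and is_snp:
            raise ValidationError(
                f"variant {self.chrom}:{self.pos} {self.ref}>{self.alt}: "
                "indel requires ref/alt of different length"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


class CountMatrix:
    """Raw counts, loci x samples, with per-sample MA-line metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by locus id with one column per sample id.
        Entries must be non-negative; integer for raw counts (real-valued
        matrices arise after normalization and are accepted when
        ``require_int=False``).
    samples
        One :class:`SampleMeta` per counts column, in column order.
    locus_class
        Class per locus (gene / small-RNA class).  A single string
        applies to all loci.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta],
        locus_class: str | Mapping[str, str] | pd.Series = "gene",
        require_int: bool = True,
    ) -> None:
        samples = list(samples)
        if list(counts.columns) != [s.sample_id for s in samples]:
            raise ValidationError(
                "counts columns do not match sample metadata ids: "
                f"{list(counts.columns)} vs {[s.sample_id for s in samples]}"
            )
        keys = [s.key for s in samples]
        dup = {k for k in keys if keys.count(k) > 1}
        if dup:
            raise ValidationError(f"duplicate (lineage, generation) pairs: {sorted(dup)}")
        for lineage in {s.lineage for s in samples}:
            founders = [s for s in samples if s.lineage == lineage and s.generation == 0]
            if len(founders) != 1:
                raise ValidationError(
                    f"lineage {lineage!r} must have exactly one generation-0 founder "
                    f"sample, found {len(founders)}"
                )
        arr = counts.to_numpy()
        if np.any(arr < 0):
            raise ValidationError("negative count values present")
        if require_int and not np.allclose(arr, np.round(arr)):
            raise ValidationError("non-integer count values present")
        self.counts = counts
        self.samples = samples
        if isinstance(locus_class, str):
            self.locus_class = pd.Series(locus_class, index=counts.index)
        else:
            self.locus_class = pd.Series(locus_class).reindex(counts.index)
            if self.locus_class.isna().any():
                missing = self.locus_class[self.locus_class.isna()].index.tolist()
                raise ValidationError(f"loci without class annotation: {missing[:5]}")
        self._by_key = {s.key: s for s in samples}

    # -- basic accessors ------------------------------------------------
    @property
    def loci(self) -> pd.Index:
        return self.counts.index

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.lineage, None)
        return list(seen)

    @property
    def available(self) -> set[tuple[str, int]]:
        """Set of (lineage, generation) pairs actually present."""
        return set(self._by_key)

    def condition_of(self, lineage: str) -> str:
        for s in self.samples:
            if s.lineage == lineage:
                return s.condition
        raise KeyError(lineage)

    def sample_at(self, lineage: str, generation: int) -> SampleMeta:
        return self._by_key[(lineage, generation)]

    def generations(self, lineage: str) -> list[int]:
        return sorted(s.generation for s in self.samples if s.lineage == lineage)

    def column(self, lineage: str, generation: int) -> pd.Series:
        return self.counts[self._by_key[(lineage, generation)].sample_id]

    # -- filtering ------------------------------------------------------
    @property
    def removable_loci(self) -> pd.Index:
        """Loci with zero counts in every sample (flagged for removal)."""
        return self.counts.index[(self.counts == 0).all(axis=1)]

    def drop_unexpressed(self) -> "CountMatrix":
        keep = self.counts.index.difference(self.removable_loci, sort=False)
        return CountMatrix(
            self.counts.loc[keep],
            self.samples,
            self.locus_class.loc[keep],
            require_int=False,
        )

    def __repr__(self) -> str:
        return (
            f"CountMatrix({self.counts.shape[0]} loci x {self.counts.shape[1]} "
            f"samples, lineages={self.lineages})"
        )


@dataclass
class LoadReport:
    """Summary returned alongside a freshly read :class:`CountMatrix`."""

    n_loci: int
    n_samples: int
    n_dropped: int = 0
    messages: list[str] = field(default_factory=list)


def available_map(available: Iterable[tuple[str, int]]) -> dict[str, list[int]]:
    """Group an available-(lineage, generation) set into sorted per-lineage lists."""
    out: dict[str, list[int]] = {}
    for lineage, gen in available:
        out.setdefault(lineage, []).append(gen)
    for gens in out.values():
        gens.sort()
    return out
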