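"""Mutation-accumulation fixation filtering.

A DNA variant counts as a fixed mutation of a lineage only when it
passes three rules: (1) variants already present in the founder (F0)
are baseline and discarded; (2) from its first observed generation
onwards it must be observed in every subsequently assayed generation
through the lineage's last available one; (3) variants first seen at
the last available generation are discarded because no later generation
can verify them.  Generations that were never assayed do not break
fixation - absence of evidence from an unsequenced sample is not
evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import IntervalRecord, ValidationError, VariantRecord, available_map


@dataclass
class FixedMutation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str
    lineage: str
    first_gen: int
    gene_hits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.first_gen <= 0:
            raise ValidationError("fixed mutation must first appear after generation 0")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    def span(self) -> tuple[int, int]:
        """0-based half-open genomic span: one base for SNPs, the ref
        span for indels."""
        start = self.pos - 1
        return start, start + max(1, len(self.ref))


def fixation_filter(
    variants: list[VariantRecord],
    available: set[tuple[str, int]],
    max_dropout: int = 0,
) -> list[FixedMutation]:
    """Apply the F0-baseline / fixation / last-generation filter.

    ``max_dropout`` available generations may be missing between the
    first observation and the end of the lineage before fixation is
    rejected (default 0: strict).
    """
    gens_by_lineage = available_map(available)
    observed: dict[tuple[str, tuple], dict] = {}
    for v in variants:
        lineage = v.sample.lineage
        if (lineage, v.sample.generation) not in available:
            raise ValidationError(
                f"variant observed in unlisted sample ({lineage}, {v.sample.generation})"
            )
        entry = observed.setdefault(
            (lineage, v.key), {"gens": set(), "vtype": v.vtype}
        )
        entry["gens"].add(v.sample.generation)

    fixed: list[FixedMutation] = []
    for (lineage, key), entry in observed.items():
        gens = entry["gens"]
        if 0 in gens:
            continue  # founder baseline
        avail = gens_by_lineage[lineage]
        last = avail[-1]
        first = min(gens)
        if first == last:
            continue  # unverifiable: first seen at the final generation
        required = [g for g in avail if g >= first]
        n_missing = sum(1 for g in required if g not in gens)
        if n_missing > max_dropout:
            continue
        chrom, pos, ref, alt = key
        fixed.append(
            FixedMutation(
                chrom=chrom, pos=pos, ref=ref, alt=alt, vtype=entry["vtype"],
                lineage=lineage, first_gen=first,
            )
        )
    fixed.sort(key=lambda m: (m.lineage, m.chrom, m.pos, m.ref, m.alt))
    return fixed


def per_generation_counts(
    fixed: list[FixedMutation], available: set[tuple[str, int]], vtype: str | None = None
) -> pd.DataFrame:
    """New fixed mutations per (lineage, generation), split by type."""
    gens_by_lineage = available_map((lin, g) for lin, g in available if g > 0)
    rows = []
    for lineage, gens in sorted(gens_by_lineage.items()):
        for g in gens:
            sel = [
                m for m in fixed
                if m.lineage == lineage and m.first_gen == g
                and (vtype is None or m.vtype == vtype)
            ]
            row = {"lineage": lineage, "generation": g, "new_mutations": len(sel)}
            if vtype is None:
                row["SNP"] = sum(m.vtype == "SNP" for m in sel)
                row["indel"] = sum(m.vtype == "indel" for m in sel)
            rows.append(row)
    return pd.DataFrame(rows)


def gene_overlap(
    fixed: list[FixedMutation], gene_bodies: list[IntervalRecord]
) -> list[FixedMutation]:
    """Annotate mutations with overlapping gene bodies (exons + introns).

    SNPs are points (1-based pos converted to a single 0-based base);
    indels use the reference-allele span.
    """
    by_chrom: dict[str, list[IntervalRecord]] = {}
    for g in gene_bodies:
        by_chrom.setdefault(g.chrom, []).append(g)
    for m in fixed:
        start, end = m.span()
        m.gene_hits = [
            g.name
            for g in by_chrom.get(m.chrom, [])
            if g.start < end and start < g.end
        ]
    return fixed


def mutation_expression_overlap(
    fixed_with_genes: list[FixedMutation], runs
) -> pd.DataFrame:
    """Cross gene-level fixed mutations with expression-change runs.

    One row per (gene, lineage) carrying both; ``simultaneous`` is True
    when any run generation falls at or after the mutation's first
    generation (the mutation persists once fixed).
    """
    runs_by_gene: dict[tuple[str, str], list] = {}
    for r in runs:
        runs_by_gene.setdefault((r.locus, r.lineage), []).append(r)
    rows = []
    for m in fixed_with_genes:
        for gene in m.gene_hits:
            gene_runs = runs_by_gene.get((gene, m.lineage))
            if not gene_runs:
                continue
            run_gens = sorted(
                {g for r in gene_runs for g in range(r.start_gen, r.end_gen + 1, 2)}
            )
            rows.append(
                {
                    "gene": gene,
                    "lineage": m.lineage,
                    "expression_generations": "_".join(map(str, run_gens)),
                    "mutation_first_gen": m.first_gen,
                    "simultaneous": any(g >= m.first_gen for g in run_gens),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "lineage", "expression_generations", "mutation_first_gen",
                 "simultaneous"],
    )
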