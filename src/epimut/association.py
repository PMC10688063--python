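"""Gene-centric association of expression changes with sRNA epimutations.

Every test in this module reduces to a 2x2 contingency table and a
Fisher exact test.  The two-sided p-value sums, over the hypergeometric
support at fixed margins, the probabilities of all tables no more
likely than the observed one; the sum is done in exact integer
arithmetic (binomial-coefficient numerators over a common denominator)
so ties at the probability boundary are handled exactly.  The reported
odds ratio is the sample cross-product ratio a*d / (b*c), with the
convention OR = +inf when b*c = 0 and a*d > 0 and undefined (NaN) when
both products vanish; the conditional-MLE estimate is available as a
secondary value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inheritance import EpimutationRun, bonferroni
from .model import ValidationError


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact hypergeometric tail summation."""
    r1, k, n = a + b, a + c, a + b + c + d
    lo = max(0, k - (c + d))
    hi = min(k, r1)
    num_obs = math.comb(r1, a) * math.comb(c + d, c)
    total = 0
    for x in range(lo, hi + 1):
        num = math.comb(r1, x) * math.comb(c + d, k - x)
        if num <= num_obs:
            total += num
    return min(1.0, total / math.comb(n, k))


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    ad, bc = a * d, b * c
    if bc > 0:
        return ad / bc
    return math.inf if ad > 0 else math.nan


def conditional_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional maximum-likelihood odds ratio (secondary estimate)."""
    from scipy.stats.contingency import odds_ratio as _cmle

    return float(_cmle([[a, b], [c, d]]).statistic)


@dataclass
class Assoc2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("case", "control")
    odds_ratio: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any((not isinstance(x, (int, np.integer))) or x < 0 for x in counts):
            raise ValidationError("2x2 counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValidationError("all-zero 2x2 table")
        self.odds_ratio = sample_odds_ratio(*counts)
        self.p = fisher_exact_p(*counts)

    @property
    def odds_ratio_cmle(self) -> float:
        return conditional_odds_ratio(self.a, self.b, self.c, self.d)

    def as_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio, "p": self.p,
        }


def fisher_2x2(a: int, b: int, c: int, d: int, **labels) -> Assoc2x2:
    """Fisher exact test of a 2x2 table; see module docstring for conventions."""
    return Assoc2x2(a, b, c, d, **labels)


# -- gene states ---------------------------------------------------------


@dataclass
class GeneState:
    """Per-gene, per-lineage record of expression and sRNA-class runs."""

    gene: str
    lineage: str
    expr_runs: list[EpimutationRun] = field(default_factory=list)
    srna_runs: dict[str, list[EpimutationRun]] = field(default_factory=dict)

    def has_expr(self) -> bool:
        return bool(self.expr_runs)

    def expr_inherited(self) -> bool:
        return any(r.inherited for r in self.expr_runs)

    def has_srna(self, srna_class: str) -> bool:
        return bool(self.srna_runs.get(srna_class))

    def simultaneous_pairs(self, srna_class: str):
        """(expr run, sRNA run) pairs sharing >= 1 sampled generation."""
        pairs = []
        for er in self.expr_runs:
            for sr in self.srna_runs.get(srna_class, []):
                if er.start_gen <= sr.end_gen and sr.start_gen <= er.end_gen:
                    pairs.append((er, sr))
        return pairs

    def has_simultaneous(self, srna_class: str) -> bool:
        return bool(self.simultaneous_pairs(srna_class))


def build_gene_states(
    expr_runs: list[EpimutationRun],
    srna_runs_by_class: dict[str, list[EpimutationRun]],
    trna_targets: pd.DataFrame | None = None,
    trna_class: str = "trna_half",
) -> dict[tuple[str, str], GeneState]:
    """Assemble gene-centric states from per-class run lists.

    Expression and gene-keyed sRNA runs (e.g. antisense 22G-RNAs) attach
    by locus id.  tRNA-fragment runs are keyed by tRNA type, so they
    attach to every gene the type putatively targets (``trna_targets``:
    output of :func:`epimut.trna.find_targets`); a gene's tRNA state is
    the union over targeting types.
    """
    states: dict[tuple[str, str], GeneState] = {}

    def get(gene: str, lineage: str) -> GeneState:
        return states.setdefault((gene, lineage), GeneState(gene, lineage))

    for r in expr_runs:
        get(r.locus, r.lineage).expr_runs.append(r)
    type_to_genes: dict[str, set[str]] = {}
    if trna_targets is not None and len(trna_targets):
        for _, row in trna_targets.iterrows():
            type_to_genes.setdefault(row["trna_type"], set()).add(row["gene"])
    for cls, runs in srna_runs_by_class.items():
        for r in runs:
            if cls == trna_class and trna_targets is not None:
                for gene in sorted(type_to_genes.get(r.locus, ())):
                    get(gene, r.lineage).srna_runs.setdefault(cls, []).append(r)
            else:
                get(r.locus, r.lineage).srna_runs.setdefault(cls, []).append(r)
    return states


def _gene_level(states) -> dict[str, list[GeneState]]:
    by_gene: dict[str, list[GeneState]] = {}
    for st in states.values() if isinstance(states, dict) else states:
        by_gene.setdefault(st.gene, []).append(st)
    return by_gene


def stepwise_association(
    states, srna_class: str, all_genes: list[str]
) -> dict[int, Assoc2x2 | None]:
    """The four-step association battery between expression changes and
    one sRNA class.

    1. has expression change x has sRNA epimutation, over all genes;
    2. expression change inherited x has sRNA epimutation, over genes
       with expression changes;
    3. expression change inherited x has *simultaneous* sRNA
       epimutation (same lineage, >= 1 shared generation), same
       background;
    4. as 3, over genes with both an expression change and an sRNA
       epimutation.

    A test whose table degenerates (an empty margin) is reported None.
    """
    by_gene = _gene_level(states)

    def flags(gene):
        sts = by_gene.get(gene, [])
        return {
            "expr": any(s.has_expr() for s in sts),
            "inherited": any(s.expr_inherited() for s in sts),
            "srna": any(s.has_srna(srna_class) for s in sts),
            "simul": any(s.has_simultaneous(srna_class) for s in sts),
        }

    table = {g: flags(g) for g in all_genes}

    def make(rows, row_key, col_key, labels):
        a = sum(1 for f in rows if f[row_key] and f[col_key])
        b = sum(1 for f in rows if f[row_key] and not f[col_key])
        c = sum(1 for f in rows if not f[row_key] and f[col_key])
        d = sum(1 for f in rows if not f[row_key] and not f[col_key])
        if a + b + c + d == 0:
            return None
        # empty margins yield OR = NaN / +inf per the stated conventions
        return Assoc2x2(a, b, c, d, row_labels=labels[0], col_labels=labels[1])

    every = list(table.values())
    with_expr = [f for f in every if f["expr"]]
    with_both = [f for f in every if f["expr"] and f["srna"]]
    return {
        1: make(every, "expr", "srna",
                (("expr change", "no expr change"), (f"{srna_class} epimutation", "none"))),
        2: make(with_expr, "inherited", "srna",
                (("inherited", "not inherited"), (f"{srna_class} epimutation", "none"))),
        3: make(with_expr, "inherited", "simul",
                (("inherited", "not inherited"), ("simultaneous", "not simultaneous"))),
        4: make(with_both, "inherited", "simul",
                (("inherited", "not inherited"), ("simultaneous", "not simultaneous"))),
    }


def concordance(states, srna_class: str) -> pd.DataFrame:
    """Concordant vs discordant simultaneous pairs.

    Among genes with both an expression change and an sRNA epimutation,
    genes with a direction-matched (concordant) or direction-unmatched
    (discordant) simultaneous pair are each tested against the
    non-simultaneous remainder of that background.
    """
    by_gene = _gene_level(states)
    conc, disc, nonsim = set(), set(), set()
    any_sim = False
    for gene, sts in by_gene.items():
        has_both = any(s.has_expr() for s in sts) and any(
            s.has_srna(srna_class) for s in sts
        )
        if not has_both:
            continue
        pairs = [p for s in sts for p in s.simultaneous_pairs(srna_class)]
        if pairs:
            any_sim = True
            if any(er.direction == sr.direction for er, sr in pairs):
                conc.add(gene)
            if any(er.direction != sr.direction for er, sr in pairs):
                disc.add(gene)
        else:
            nonsim.add(gene)
    if not any_sim:
        raise ValidationError(
            f"no simultaneous (expression, {srna_class}) pairs: concordance undefined"
        )
    n_background = len(conc | disc | nonsim)
    # odds of showing a class-X association versus the odds of showing no
    # simultaneous association at all, within the both-change background
    out = []
    for label, genes in (("concordant", conc), ("discordant", disc)):
        a = len(genes)
        c = len(nonsim)
        assoc = Assoc2x2(a, n_background - a, c, n_background - c)
        out.append(
            {"class": label, "n_class": a, "n_non_simultaneous": c,
             "odds_ratio": assoc.odds_ratio, "p": assoc.p}
        )
    return pd.DataFrame(out)


def simultaneity_breakdown(states, srna_class: str) -> pd.DataFrame:
    """Three-way percentage split of sRNA epimutation timing, per
    expression-inheritance stratum.

    Among genes carrying both an expression change and a (targeted)
    sRNA epimutation, each stratum (inherited vs non-inherited
    expression change) splits 100% into: simultaneous + inherited sRNA
    epimutation, simultaneous non-inherited, and non-simultaneous.
    """
    by_gene = _gene_level(states)
    strata = {True: [0, 0, 0], False: [0, 0, 0]}
    n_any = 0
    for gene, sts in by_gene.items():
        if not (any(s.has_expr() for s in sts) and any(s.has_srna(srna_class) for s in sts)):
            continue
        n_any += 1
        inherited = any(s.expr_inherited() for s in sts)
        pairs = [p for s in sts for p in s.simultaneous_pairs(srna_class)]
        if not pairs:
            strata[inherited][2] += 1
        elif any(sr.inherited for _, sr in pairs):
            strata[inherited][0] += 1
        else:
            strata[inherited][1] += 1
    if n_any == 0:
        raise ValidationError("no gene carries both change types")
    rows = []
    for inherited, counts in strata.items():
        total = sum(counts)
        pct = [100.0 * x / total if total else float("nan") for x in counts]
        rows.append(
            {
                "expr_inherited": inherited,
                "n_genes": total,
                "simultaneous_inherited_pct": pct[0],
                "simultaneous_non_inherited_pct": pct[1],
                "non_simultaneous_pct": pct[2],
            }
        )
    return pd.DataFrame(rows).sort_values("expr_inherited", ascending=False, ignore_index=True)


def class_comparison(states, class_a: str, class_b: str) -> Assoc2x2:
    """Odds of simultaneous association for one sRNA class versus another.

    Columns are the classes.  Each column counts the genes carrying both
    an expression change and a class-X epimutation, split into those
    where the two are simultaneous versus not: the odds ratio compares
    how tightly each class's epimutations track expression changes.
    """
    by_gene = _gene_level(states)
    counts = {}
    for cls in (class_a, class_b):
        with_sim = 0
        without = 0
        for gene, sts in by_gene.items():
            if not any(s.has_expr() for s in sts):
                continue
            if not any(s.has_srna(cls) for s in sts):
                continue
            if any(s.has_simultaneous(cls) for s in sts):
                with_sim += 1
            else:
                without += 1
        counts[cls] = (with_sim, without)
    (a, c), (b, d) = counts[class_a], counts[class_b]
    return Assoc2x2(
        a, b, c, d,
        row_labels=("expr change + simultaneous epimutation", "expr change only"),
        col_labels=(class_a, class_b),
    )


# -- term enrichment -----------------------------------------------------


def term_enrichment(
    test_genes,
    background_genes,
    annotation: dict[str, set[str]] | pd.DataFrame,
    min_genes: int = 5,
    correction: str = "bonferroni",
) -> tuple[pd.DataFrame, int]:
    """Fisher-based term enrichment of a test gene list.

    The background is the complement of the test list in the gene
    universe (genes without changes).  A term enters the analysis only
    if at least ``min_genes`` annotated genes occur in the test list or
    in the background list; the number of excluded terms is returned
    alongside the table.  ``correction`` is ``'bonferroni'`` (as used
    throughout) or ``'bh'``.
    """
    test = set(test_genes)
    background = set(background_genes)
    if test & background:
        raise ValidationError("test and background gene lists overlap")
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        for _, row in annotation.iterrows():
            ann.setdefault(row["gene"], set()).add(row["term"])
        annotation = ann
    terms: dict[str, set[str]] = {}
    for gene, ts in annotation.items():
        for t in ts:
            terms.setdefault(t, set()).add(gene)

    rows = []
    n_excluded = 0
    for term, genes in sorted(terms.items()):
        a = len(genes & test)
        c = len(genes & background)
        if a < min_genes and c < min_genes:
            n_excluded += 1
            continue
        b = len(test) - a
        d = len(background) - c
        assoc = Assoc2x2(a, b, c, d)
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": assoc.odds_ratio, "p": assoc.p}
        )
    table = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "p"])
    if len(table):
        if correction == "bonferroni":
            table["p_adj"] = bonferroni(table["p"])
        elif correction == "bh":
            from statsmodels.stats.multitest import multipletests

            table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        else:
            raise ValidationError(f"unknown correction {correction!r}")
    else:
        table["p_adj"] = []
    return table, n_excluded
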