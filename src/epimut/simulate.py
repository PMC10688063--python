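"""Synthetic multigenerational MA-line data with known ground truth.

The generator emulates the statistical structure of the study design it
is built for: six bottlenecked lineages (two per exposure condition),
embryos sampled every two generations from 0 to 20, with a single
founder sample per lineage and a handful of missing samples.

Counts model
------------
Each locus gets a founder log2 mean drawn uniformly from
``baseline_log2_mean_range``.  Per-sample counts are negative binomial
around ``2**(log2mean + effect)`` with a shared dispersion ``alpha``
(variance ``mu + alpha * mu**2``); overdispersed counts are the
realistic stress for a residual-based outlier statistic.  Epimutations
are born per locus/lineage/generation with probability
``epimutation_birth_rate``; each lasts a geometric number of sampled
generations (continuation probability ``persistence_p``), truncated at
the last generation, with direction +/-1 equiprobable.  While active, an
epimutation shifts the locus's log2 mean by
``direction * effect_size_sd * sigma_resid``, where ``sigma_resid`` is
the locus's expected regression-residual standard deviation (generation
noise plus founder noise, both approximated on the log2 scale by the
delta method).  Expressing the effect in residual-SD units makes the
injected signal directly comparable with the Z-score cutoff downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_LINEAGES, CountMatrix, IntervalRecord, SampleMeta, ValidationError

LN2 = float(np.log(2.0))

#: Missing samples of the reference RNA-seq design (insufficient yield).
DEFAULT_MISSING: tuple[tuple[str, int], ...] = (("C2", 12), ("H1", 20))

_TRNA_TYPES = (
    "GlyGCC", "GluCTC", "GlnTTG", "ValAAC", "SerCGA", "TrpCCA", "LeuAAG",
    "GlnCTG", "AspGTC", "AlaAGC", "ArgCCT", "LysTTT", "ProAGG", "ThrTGT",
    "IleAAT", "MetCAT", "PheGAA", "TyrGTA", "HisGTG", "CysGCA",
)


@dataclass(frozen=True)
class TrnaConfig:
    """Synthetic tRNA loci and positionally biased fragment reads."""

    n_loci: int = 20
    length_range: tuple[int, int] = (70, 90)
    bias: float = 0.8  # weight of the 3' half in read-start positions
    reads_per_locus: float = 200.0
    condition_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "low_dose": 1.5, "high_dose": 2.0}
    )
    # (trna_type, lineage, start_gen, end_gen, multiplier) count shifts
    injected_effects: tuple[tuple[str, str, int, int, float], ...] = ()
    chrom: str = "chrS"


@dataclass(frozen=True)
class VariantConfig:
    """Synthetic per-generation variant observations."""

    n_fixed: int = 10
    n_transient: int = 10
    n_f0_baseline: int = 5
    n_last_only: int = 3
    chrom: str = "chrS"
    chrom_length: int = 1_000_000


@dataclass(frozen=True)
class SimConfig:
    n_loci: int = 2000
    lineages: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGES))
    generations: tuple[int, ...] = tuple(range(0, 21, 2))
    baseline_log2_mean_range: tuple[float, float] = (6.0, 10.0)
    nb_dispersion: float = 0.05
    #: the founder is an expanded pre-bottleneck population, measured
    #: deeply: higher depth and no bottleneck overdispersion.  A noisy
    #: founder would leak the same sampling error into every
    #: generation's residual and fake inheritance under the null.
    founder_depth: float = 25.0
    founder_dispersion: float = 0.0
    epimutation_birth_rate: float = 1e-3
    persistence_p: float = 0.5
    effect_size_sd: float = 4.0
    missing_samples: tuple[tuple[str, int], ...] = DEFAULT_MISSING
    trna: TrnaConfig = field(default_factory=TrnaConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("epimutation_birth_rate", self.epimutation_birth_rate),
            ("persistence_p", self.persistence_p),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        gens = self.generations
        if list(gens) != sorted(set(gens)) or any(g % 2 or g < 0 for g in gens):
            raise ValidationError(
                "generations must be a strictly increasing grid of even integers"
            )
        if 0 not in gens:
            raise ValidationError("generation grid must include the founder (0)")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        lo, hi = self.baseline_log2_mean_range
        if not hi > lo:
            raise ValidationError("baseline_log2_mean_range must be a proper interval")

    def sample_grid(self) -> list[SampleMeta]:
        """All (lineage, generation) samples minus the configured missing ones."""
        missing = set(tuple(m) for m in self.missing_samples)
        out = []
        for lineage, condition in self.lineages.items():
            for g in self.generations:
                if (lineage, g) in missing and g != 0:
                    continue
                out.append(
                    SampleMeta(f"{lineage}_g{g}", lineage, condition, g)
                )
        return out


@dataclass(frozen=True)
class Episode:
    """One injected epimutation: a same-direction stretch on the sampled grid."""

    locus: str
    lineage: str
    direction: int
    start_gen: int
    end_gen: int

    def __post_init__(self) -> None:
        if self.end_gen < self.start_gen:
            raise ValidationError("episode end_gen must be >= start_gen")


@dataclass(frozen=True)
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    lineage: str
    first_gen: int
    category: str  # fixed / transient / f0_baseline / last_only


@dataclass
class GroundTruth:
    """Injected signal, recoverable only by tests and never by the pipeline."""

    episodes: list[Episode] = field(default_factory=list)
    variants: list[VariantTruth] = field(default_factory=list)
    trna_condition_multipliers: dict[str, float] = field(default_factory=dict)
    trna_injected: list[tuple[str, str, int, int, float]] = field(default_factory=list)

    def fixed_variants(self) -> list[VariantTruth]:
        return [v for v in self.variants if v.category == "fixed"]

    def to_json(self, path) -> None:
        payload = {
            "episodes": [asdict(e) for e in self.episodes],
            "variants": [asdict(v) for v in self.variants],
            "trna_condition_multipliers": self.trna_condition_multipliers,
            "trna_injected": [list(t) for t in self.trna_injected],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def residual_sd(
    log2_mean: np.ndarray,
    alpha: float,
    founder_depth: float = 25.0,
    founder_alpha: float = 0.0,
) -> np.ndarray:
    """Expected regression-residual SD on the log2 scale (delta method).

    One sampled generation regressed on the founder carries the
    generation sample's log2 noise plus the (much smaller) founder
    measurement noise; the residual variance is their sum (slope ~= 1
    for matched baselines).
    """
    mu = np.power(2.0, log2_mean)
    gen_var = (1.0 / mu + alpha) / (LN2**2)
    founder_var = (1.0 / (founder_depth * mu) + founder_alpha) / (LN2**2)
    return np.sqrt(gen_var + founder_var)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a locus x sample count matrix with injected epimutations."""
    rng = _rng(cfg.seed, 0)
    loci = [f"locus_{i:05d}" for i in range(cfg.n_loci)]
    lo, hi = cfg.baseline_log2_mean_range
    log2_mean = rng.uniform(lo, hi, size=cfg.n_loci)
    sigma = residual_sd(log2_mean, cfg.nb_dispersion, cfg.founder_depth,
                        cfg.founder_dispersion)

    truth = GroundTruth()
    samples = cfg.sample_grid()
    gens = [g for g in cfg.generations if g > 0]
    # shift[lineage] is an (n_loci, n_gens) matrix of active-direction values
    shift: dict[str, np.ndarray] = {}
    for lineage in cfg.lineages:
        active = np.zeros((cfg.n_loci, len(gens)), dtype=np.int8)
        remaining = np.zeros(cfg.n_loci, dtype=np.int64)  # sampled gens still active
        direction = np.zeros(cfg.n_loci, dtype=np.int8)
        for gi, g in enumerate(gens):
            fresh = (remaining == 0) & (
                rng.random(cfg.n_loci) < cfg.epimutation_birth_rate
            )
            idx = np.flatnonzero(fresh)
            if idx.size:
                if cfg.persistence_p >= 1.0:
                    dur = np.full(idx.size, len(gens) - gi)
                else:
                    dur = rng.geometric(1.0 - cfg.persistence_p, size=idx.size)
                dur = np.minimum(dur, len(gens) - gi)
                remaining[idx] = dur
                direction[idx] = rng.choice([-1, 1], size=idx.size)
                for j, d in zip(idx, dur):
                    truth.episodes.append(
                        Episode(
                            locus=loci[j],
                            lineage=lineage,
                            direction=int(direction[j]),
                            start_gen=g,
                            end_gen=gens[gi + int(d) - 1],
                        )
                    )
            live = remaining > 0
            active[live, gi] = direction[live]
            remaining[live] -= 1
        shift[lineage] = active

    columns = {}
    for s in samples:
        if s.generation == 0:
            mu = cfg.founder_depth * np.power(2.0, log2_mean)
            columns[s.sample_id] = _nb_draw(rng, mu, cfg.founder_dispersion)
        else:
            gi = gens.index(s.generation)
            eff = shift[s.lineage][:, gi] * cfg.effect_size_sd * sigma
            mu = np.power(2.0, log2_mean + eff)
            columns[s.sample_id] = _nb_draw(rng, mu, cfg.nb_dispersion)
    counts = pd.DataFrame(columns, index=pd.Index(loci, name="locus"))
    cm = CountMatrix(counts, samples, locus_class="gene")

    # episodes fully masked by missing samples are unobservable but kept:
    # ground truth describes the injected process, not its observability
    return cm, truth


def ground_truth_calls(
    truth: GroundTruth, loci: Sequence[str], samples: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Ternary call matrix implied directly by the injected episodes.

    Used by tests and calibration checks that exercise the run/survival
    machinery in isolation from the noisy caller.
    """
    cols = pd.MultiIndex.from_tuples(
        [(s.lineage, s.generation) for s in samples], names=["lineage", "generation"]
    )
    calls = pd.DataFrame(0, index=pd.Index(loci, name="locus"), columns=cols, dtype=np.int8)
    for ep in truth.episodes:
        for lineage, gen in calls.columns:
            if lineage == ep.lineage and ep.start_gen <= gen <= ep.end_gen:
                calls.loc[ep.locus, (lineage, gen)] = ep.direction
    return calls


# -- tRNA fragment reads -------------------------------------------------


def simulate_trna_reads(
    cfg: SimConfig,
) -> tuple[list[IntervalRecord], dict[str, list[IntervalRecord]], GroundTruth]:
    """Simulate tRNA loci plus per-sample fragment alignments.

    Loci are placed without overlap on a synthetic chromosome with
    alternating strands.  Read starts (in tRNA 5'->3' coordinates) fall
    in the 3' half with probability ``trna.bias``; read lengths are
    uniform on 18-36 nt.  Condition multipliers scale per-sample read
    depth, emulating the dose-dependent rise in 3' halves.
    """
    t = cfg.trna
    rng = _rng(cfg.seed, 1)
    if not 0.0 <= t.bias <= 1.0:
        raise ValidationError("trna bias must be in [0, 1]")

    loci: list[IntervalRecord] = []
    pos = 100
    for i in range(t.n_loci):
        length = int(rng.integers(t.length_range[0], t.length_range[1] + 1))
        if length < 36:
            raise ValidationError("tRNA locus length must be >= 36")
        strand = "+" if i % 2 == 0 else "-"
        name = _TRNA_TYPES[i % len(_TRNA_TYPES)]
        loci.append(IntervalRecord(t.chrom, pos, pos + length, strand, name))
        pos += length + int(rng.integers(60, 200))

    truth = GroundTruth(trna_condition_multipliers=dict(t.condition_multipliers),
                        trna_injected=list(t.injected_effects))
    reads_by_sample: dict[str, list[IntervalRecord]] = {}
    for s in cfg.sample_grid():
        mult = t.condition_multipliers.get(s.condition, 1.0)
        reads: list[IntervalRecord] = []
        for locus in loci:
            depth = t.reads_per_locus * mult
            for typ, lineage, g0, g1, m in t.injected_effects:
                if typ == locus.name and lineage == s.lineage and g0 <= s.generation <= g1:
                    depth *= m
            n_reads = rng.poisson(depth)
            length = len(locus)
            half = length // 2
            in_3p = rng.random(n_reads) < t.bias
            starts = np.where(
                in_3p,
                rng.integers(half, length, size=n_reads),
                rng.integers(0, half, size=n_reads),
            )
            read_lens = rng.integers(18, 37, size=n_reads)
            for k, (st, rl) in enumerate(zip(starts, read_lens)):
                if locus.strand == "+":
                    gstart = locus.start + int(st)
                    gend = gstart + int(rl)
                else:
                    gend = locus.end - int(st)
                    gstart = gend - int(rl)
                reads.append(
                    IntervalRecord(
                        locus.chrom, max(gstart, 0), gend, locus.strand,
                        f"{s.sample_id}|{locus.name}|{k}",
                    )
                )
        reads_by_sample[s.sample_id] = reads
    return loci, reads_by_sample, truth


# -- variants ------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def simulate_variants(cfg: SimConfig):
    """Simulate per-generation variant observations of four categories.

    ``fixed`` variants appear at ``first_gen`` and in every later
    sampled generation; ``transient`` ones violate fixation;
    ``f0_baseline`` are present from generation 0; ``last_only`` appear
    only at a lineage's final generation (unverifiable, to be discarded
    downstream).
    """
    from .model import VariantRecord, available_map

    v = cfg.variants
    rng = _rng(cfg.seed, 2)
    samples = cfg.sample_grid()
    by_key = {(s.lineage, s.generation): s for s in samples}
    avail = available_map(by_key.keys())
    lineages = list(cfg.lineages)

    n_total = v.n_fixed + v.n_transient + v.n_f0_baseline + v.n_last_only
    positions = rng.choice(
        np.arange(1, v.chrom_length), size=n_total, replace=False
    )
    categories = (
        ["fixed"] * v.n_fixed
        + ["transient"] * v.n_transient
        + ["f0_baseline"] * v.n_f0_baseline
        + ["last_only"] * v.n_last_only
    )

    truth = GroundTruth()
    records: list[VariantRecord] = []
    for pos, category in zip(positions, categories):
        lineage = lineages[int(rng.integers(len(lineages)))]
        gens = avail[lineage]
        last = gens[-1]
        ref = _BASES[int(rng.integers(4))]
        if rng.random() < 0.5:
            alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
            vtype = "SNP"
        else:
            alt = ref + _BASES[int(rng.integers(4))]
            vtype = "indel"

        if category == "fixed":
            # needs a first generation strictly between 0 and the last one
            eligible = [g for g in gens if 0 < g < last]
            first = int(eligible[int(rng.integers(len(eligible)))])
            observed = [g for g in gens if g >= first]
        elif category == "f0_baseline":
            first = 0
            observed = list(gens)
        elif category == "last_only":
            first = last
            observed = [last]
        else:  # transient: misses at least one generation after its first
            eligible = [g for g in gens if 0 < g < last]
            first = int(eligible[int(rng.integers(len(eligible)))])
            later = [g for g in gens if g > first]
            keep = [g for g in later if rng.random() < 0.5]
            if len(keep) == len(later):
                keep.remove(later[int(rng.integers(len(later)))])
            observed = [first] + keep

        truth.variants.append(
            VariantTruth(v.chrom, int(pos), ref, alt, vtype, lineage, first, category)
        )
        for g in observed:
            records.append(
                VariantRecord(v.chrom, int(pos), ref, alt, vtype, by_key[(lineage, g)])
            )
    order = rng.permutation(len(records))
    return [records[i] for i in order], truth
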