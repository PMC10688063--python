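"""Epimutation runs, rates and duration statistics.

A *run* is a maximal stretch of consecutive sampled generations in
which a locus carries a same-direction call within one lineage.  A
direction flip terminates the preceding run and starts a new one at the
same generation; a zero call terminates it.  Because embryos are
sampled every two generations, an epimutation present at generations 2
and 4 is taken to exist at the unsampled generation 3; by the same
logic a sampled-but-missing generation bridges a run only when both
flanking available generations carry the same direction.  Runs still
active at a lineage's last available generation are right-censored.

Durations are counted in sampled generations (``n_sampled``); one
sampled generation spans two organismal generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .model import ValidationError, available_map


@dataclass(frozen=True)
class EpimutationRun:
    locus: str
    lineage: str
    direction: int
    start_gen: int
    end_gen: int
    n_sampled: int
    censored: bool

    def __post_init__(self) -> None:
        if self.end_gen < self.start_gen:
            raise ValidationError("run end_gen must be >= start_gen")
        if self.direction not in (-1, 1):
            raise ValidationError("run direction must be +1 or -1")

    @property
    def inherited(self) -> bool:
        return self.n_sampled >= 2

    @property
    def organismal_generations(self) -> int:
        return 2 * self.n_sampled


def detect_runs(
    calls: pd.DataFrame,
    available: set[tuple[str, int]] | None = None,
    strict: bool = False,
) -> list[EpimutationRun]:
    """Scan a ternary call matrix into runs.

    Parameters
    ----------
    calls
        Loci x (lineage, generation) matrix of {-1, 0, +1}; columns are
        a MultiIndex.  Generation-0 columns, if present, are ignored
        (the founder defines the reference, not an epimutation).
    available
        The (lineage, generation) pairs that were actually assayed;
        defaults to the call matrix columns.  Must cover every column.
    strict
        If True, any gap in the sampled grid (a missing generation)
        closes runs instead of bridging same-direction flanks.
    """
    if available is None:
        available = set(calls.columns)
    if not set(calls.columns) <= set(available):
        raise ValidationError("available does not cover all call columns")
    runs: list[EpimutationRun] = []
    gens_by_lineage = available_map(
        (lin, g) for lin, g in available if g > 0
    )
    loci = calls.index
    for lineage, gens in sorted(gens_by_lineage.items()):
        last_gen = gens[-1]
        cols = [calls[(lineage, g)].to_numpy() for g in gens]
        matrix = np.column_stack(cols)  # loci x gens
        for li in range(matrix.shape[0]):
            row = matrix[li]
            cur_dir = 0
            start = end = 0
            count = 0
            prev_gen = None
            for gi, g in enumerate(gens):
                call = int(row[gi])
                gap_breaks = strict and prev_gen is not None and g - prev_gen > 2
                if cur_dir != 0 and call == cur_dir and not gap_breaks:
                    end = g
                    count += 1
                else:
                    if cur_dir != 0:
                        runs.append(
                            EpimutationRun(
                                locus=str(loci[li]), lineage=lineage,
                                direction=cur_dir, start_gen=start, end_gen=end,
                                n_sampled=count, censored=end == last_gen,
                            )
                        )
                    cur_dir = call
                    start = end = g
                    count = 1 if call != 0 else 0
                prev_gen = g
            if cur_dir != 0:
                runs.append(
                    EpimutationRun(
                        locus=str(loci[li]), lineage=lineage, direction=cur_dir,
                        start_gen=start, end_gen=end, n_sampled=count,
                        censored=end == last_gen,
                    )
                )
    return runs


def runs_to_frame(runs: list[EpimutationRun]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "locus": r.locus, "lineage": r.lineage, "direction": r.direction,
                "start_gen": r.start_gen, "end_gen": r.end_gen,
                "n_sampled": r.n_sampled, "organismal_generations": r.organismal_generations,
                "censored": r.censored,
            }
            for r in runs
        ]
    )
    if df.empty:
        df = pd.DataFrame(
            columns=["locus", "lineage", "direction", "start_gen", "end_gen",
                     "n_sampled", "organismal_generations", "censored"]
        )
    return df


def new_epimutation_rate(
    runs: list[EpimutationRun], available: set[tuple[str, int]]
) -> pd.DataFrame:
    """Runs starting at each (lineage, generation > 0)."""
    gens_by_lineage = available_map((lin, g) for lin, g in available if g > 0)
    index = [
        (lin, g) for lin, gens in sorted(gens_by_lineage.items()) for g in gens
    ]
    table = pd.Series(0, index=pd.MultiIndex.from_tuples(index, names=["lineage", "generation"]))
    for r in runs:
        table.loc[(r.lineage, r.start_gen)] += 1
    return table.rename("new_runs").reset_index()


def inherited_fraction(
    runs: list[EpimutationRun],
    available: set[tuple[str, int]],
    by: str | None = None,
    conditions: dict[str, str] | None = None,
):
    """Fraction of runs lasting >= 2 sampled generations.

    Runs starting at a lineage's final available generation are
    excluded from the denominator: their inheritance is unobservable.
    With ``by='lineage'`` or ``by='condition'`` returns a Series;
    ``by='generation'`` gives the per-start-generation decomposition.
    """
    gens_by_lineage = available_map((lin, g) for lin, g in available if g > 0)
    last = {lin: gens[-1] for lin, gens in gens_by_lineage.items()}
    eligible = [r for r in runs if r.start_gen < last[r.lineage]]
    if not eligible and by is None:
        raise ValidationError("no runs with observable inheritance")

    def frac(rs):
        return 100.0 * sum(r.inherited for r in rs) / len(rs) if rs else float("nan")

    if by is None:
        return frac(eligible)
    keys: dict[str, list[EpimutationRun]] = {}
    for r in eligible:
        if by == "lineage":
            key = r.lineage
        elif by == "condition":
            if conditions is None:
                raise ValidationError("by='condition' requires a lineage->condition map")
            key = conditions[r.lineage]
        elif by == "generation":
            key = r.start_gen
        else:
            raise ValidationError(f"unknown grouping {by!r}")
        keys.setdefault(key, []).append(r)
    return pd.Series({k: frac(v) for k, v in sorted(keys.items())}, name="inherited_pct")


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def s_at(self, t: float) -> float:
        """Right-continuous step evaluation of S(t); S(t<first event)=1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def mean_duration(self) -> float:
        """Restricted mean duration: sum of S(k) over the integer grid.

        For integer durations >= 1, E[T] = sum_{k>=0} P(T > k); the sum
        is truncated at the largest observed time.
        """
        kmax = int(np.ceil(self.times.max()))
        return float(sum(self.s_at(k) for k in range(kmax)))


def _km_inputs(runs: list[EpimutationRun]) -> tuple[np.ndarray, np.ndarray]:
    """Durations and event flags for product-limit estimation.

    A censored run observed for d sampled generations has survived the
    continuation trials 1..d-1 but its trial at d (presence at the next,
    never-assayed generation) is unobserved, so it leaves the risk set
    just before d; an uncensored run of duration d is an event at d.
    """
    durations = np.array(
        [r.n_sampled - 0.5 if r.censored else r.n_sampled for r in runs], dtype=float
    )
    observed = np.array([not r.censored for r in runs], dtype=bool)
    return durations, observed


def km_curve(runs: list[EpimutationRun]) -> SurvivalCurve:
    """Kaplan-Meier estimate of run duration (sampled generations)."""
    if not runs:
        raise ValidationError("need at least one run for a survival curve")
    durations, observed = _km_inputs(runs)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    return SurvivalCurve(
        times=times,
        survival=surv,
        n_at_risk=table["at_risk"].to_numpy(),
        n_events=table["observed"].to_numpy(),
        n_censored=table["censored"].to_numpy(),
    )


def logrank(groups: list[list[EpimutationRun]], labels=None):
    """k-sample log-rank test on run durations, honouring censoring."""
    if len(groups) < 2:
        raise ValidationError("log-rank test needs >= 2 groups")
    if labels is None:
        labels = list(range(len(groups)))
    durations, events, group_ids = [], [], []
    for label, runs in zip(labels, groups):
        d, obs = _km_inputs(runs)
        durations.extend(d)
        events.extend(obs)
        group_ids.extend([label] * len(runs))
    if not any(events):
        raise ValidationError("log-rank test needs >= 1 observed event")
    res = multivariate_logrank_test(durations, group_ids, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# -- rank-based group comparisons ---------------------------------------


def _conover_iman(groups: list[np.ndarray], labels) -> pd.DataFrame:
    """Conover-Iman post hoc: t-tests on rank means after Kruskal-Wallis."""
    pooled = np.concatenate(groups)
    n = pooled.size
    k = len(groups)
    ranks = stats.rankdata(pooled)
    split = np.split(ranks, np.cumsum([g.size for g in groups])[:-1])
    h = stats.kruskal(*groups).statistic
    # sample variance of the (possibly tied) ranks
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4) / (n - 1)
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(split), 2):
        diff = gi.mean() - gj.mean()
        se = np.sqrt(s2 * (n - 1 - h) / (n - k) * (1 / gi.size + 1 / gj.size))
        t = diff / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df=n - k)
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": t, "p": min(1.0, p)})
    return pd.DataFrame(rows)


def _pairwise_wilcoxon(groups: list[np.ndarray], labels) -> pd.DataFrame:
    rows = []
    pairs = list(combinations(range(len(groups)), 2))
    for i, j in pairs:
        u, p = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": u, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p"] = np.minimum(1.0, df["p_raw"] * len(pairs))  # Bonferroni
    return df


def rate_tests(
    groups: dict[str, list[float]] | list[list[float]],
    posthoc: str = "conover",
) -> dict:
    """Kruskal-Wallis across groups plus a selectable post hoc battery.

    ``posthoc`` is ``'conover'`` (Conover-Iman rank t-tests) or
    ``'wilcoxon'`` (pairwise Mann-Whitney with Bonferroni correction).
    """
    if isinstance(groups, dict):
        labels = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = list(range(len(groups)))
        arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and np.ptp(arrays[0]) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    if posthoc == "conover":
        table = _conover_iman(arrays, labels)
    elif posthoc == "wilcoxon":
        table = _pairwise_wilcoxon(arrays, labels)
    else:
        raise ValidationError(f"unknown posthoc {posthoc!r}")
    return {"H": float(h), "p": float(p), "posthoc": table}


def bonferroni(p_values):
    """Bonferroni adjustment: p * m, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


# -- Jonckheere-Terpstra ordered trend test ------------------------------


def _jt_statistic(values: np.ndarray, sizes: list[int]) -> float:
    """J = sum over ordered group pairs of #{x < y} + 0.5 #{x == y}."""
    bounds = np.cumsum([0] + sizes)
    j = 0.0
    for a in range(len(sizes)):
        ga = values[bounds[a]:bounds[a + 1]]
        for b in range(a + 1, len(sizes)):
            gb = values[bounds[b]:bounds[b + 1]]
            less = np.sum(ga[:, None] < gb[None, :])
            ties = np.sum(ga[:, None] == gb[None, :])
            j += less + 0.5 * ties
    return float(j)


def _jt_exact_p(values: np.ndarray, sizes: list[int], j_obs: float) -> float:
    """Exact one-sided p by enumerating all assignments of the pooled
    values to groups of the given sizes (multinomial enumeration)."""
    n = values.size
    count = [0, 0]  # (total, at least as extreme)

    def recurse(remaining: tuple[int, ...], sizes_left: list[int], acc: list[np.ndarray]):
        if not sizes_left:
            j = _jt_statistic(np.concatenate(acc), sizes)
            count[0] += 1
            if j >= j_obs - 1e-9:
                count[1] += 1
            return
        k = sizes_left[0]
        for picked in combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in set(picked))
            # indices are distinct so set-based removal is safe
            recurse(rest, sizes_left[1:], acc + [values[list(picked)]])

    recurse(tuple(range(n)), sizes, [])
    return count[1] / count[0]


def jonckheere(
    groups: list[list[float]],
    alternative: str = "increasing",
    exact_max_n: int = 12,
) -> tuple[float, float, float]:
    """Jonckheere-Terpstra test for an ordered-median alternative.

    Returns (J, z, one-sided p).  With total n <= ``exact_max_n`` the
    p-value is computed by exhaustive enumeration; otherwise by the
    tie-corrected normal approximation.  ``alternative='decreasing'``
    reverses the group order.
    """
    if len(groups) < 3:
        raise ValidationError("Jonckheere test needs >= 3 ordered groups")
    if alternative not in ("increasing", "decreasing"):
        raise ValidationError("alternative must be 'increasing' or 'decreasing'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if alternative == "decreasing":
        arrays = arrays[::-1]
    sizes = [a.size for a in arrays]
    if any(s == 0 for s in sizes):
        raise ValidationError("all groups must be non-empty")
    values = np.concatenate(arrays)
    n = values.size
    j = _jt_statistic(values, sizes)

    # tie-corrected null moments
    ni = np.array(sizes, dtype=float)
    _, tie_counts = np.unique(values, return_counts=True)
    tj = tie_counts.astype(float)
    mean_j = (n**2 - np.sum(ni**2)) / 4.0
    var_j = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(ni * (ni - 1) * (2 * ni + 5))
        - np.sum(tj * (tj - 1) * (2 * tj + 5))
    ) / 72.0
    if n > 2:
        var_j += (
            np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(tj * (tj - 1) * (tj - 2))
        ) / (36.0 * n * (n - 1) * (n - 2))
    var_j += (np.sum(ni * (ni - 1)) * np.sum(tj * (tj - 1))) / (8.0 * n * (n - 1))
    if var_j <= 0:
        # tie-saturated null: the statistic carries no information
        return j, 0.0, 0.5
    z = (j - mean_j) / np.sqrt(var_j)

    if n <= exact_max_n:
        p = _jt_exact_p(values, sizes, j)
    else:
        p = float(stats.norm.sf(z))
    return j, float(z), float(p)
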