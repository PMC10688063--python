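"""Residual Z-score epimutation calling.

For every lineage and sampled generation g > 0, the log2 normalized
counts at generation g are regressed on the log2 normalized counts of
that lineage's founder (generation 0).  Loci that deviate strongly from
the fit are candidate epimutations: residuals are standardised into
Z-scores (mean 0, SD 1 per column) and binarised at |Z| >= 2.25 into
+1 (up), -1 (down) or 0.

The regression is loess (locally weighted quadratic with tricube
weights) for gene expression, where the mean-dependent trend between
generations can be curved, and ordinary least squares for small-RNA
classes, whose per-class tables are smaller and noisier.  Both models
receive identical downstream treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CountMatrix, ValidationError
from .normalize import log2p, normalize, size_factors

DEFAULT_CUTOFF = 2.25
DEFAULT_SPAN = 0.75

#: above this size loess is evaluated at interpolation knots, like the
#: cell-based evaluation of reference implementations
_LOESS_EXACT_MAX = 1000
_LOESS_KNOTS = 401


class DegenerateColumnError(ValidationError):
    """Residuals have zero variance: Z-scores are undefined."""


@dataclass
class RegressionFit:
    """Fit of one (lineage, generation) column against the founder."""

    lineage: str
    generation: int
    model: str
    fitted: np.ndarray
    residuals: np.ndarray
    span: float | None = None


def loess(
    x: np.ndarray, y: np.ndarray, span: float = DEFAULT_SPAN, degree: int = 2
) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    Returns fitted values at every ``x``.  For large inputs the local
    fits are evaluated at quantile-spaced knots and linearly
    interpolated, which keeps the cost linear in the number of points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 0.0 < span <= 1.0:
        raise ValidationError(f"loess span must be in (0, 1], got {span}")
    k = max(degree + 1, int(np.ceil(span * n)))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    if n <= _LOESS_EXACT_MAX:
        targets = xs
    else:
        targets = np.quantile(xs, np.linspace(0.0, 1.0, _LOESS_KNOTS))

    fitted_t = np.empty(targets.size)
    lo = 0
    for i, x0 in enumerate(targets):
        # slide the k-nearest window along the sorted predictor
        while lo + k < n and xs[lo + k] - x0 < x0 - xs[lo]:
            lo += 1
        window = slice(lo, lo + k)
        xw, yw = xs[window], ys[window]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            fitted_t[i] = yw.mean()
            continue
        w = (1.0 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # weighted polynomial fit, centred for conditioning
        xc = xw - x0
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], yw * sw, rcond=None)
        fitted_t[i] = coef[0]

    if targets is xs:
        fitted_sorted = fitted_t
    else:
        fitted_sorted = np.interp(xs, targets, fitted_t)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def fit_generation(
    log2_founder: np.ndarray,
    log2_gen: np.ndarray,
    model: str = "loess",
    span: float = DEFAULT_SPAN,
    lineage: str = "",
    generation: int = 0,
) -> RegressionFit:
    """Regress one generation's log2 values on the founder's.

    The founder is the predictor; residuals are ``response - fitted``.
    """
    x = np.asarray(log2_founder, dtype=float)
    y = np.asarray(log2_gen, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(
            f"founder and generation vectors differ in length: {x.size} vs {y.size}"
        )
    if x.size < 10:
        raise ValidationError("need at least 10 loci to fit")
    if model == "linear":
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        return RegressionFit(lineage, generation, "linear", fitted, y - fitted)
    if model == "loess":
        if x.size < 30:
            raise ValidationError(
                "loess needs at least 30 loci; use model='linear' for small tables"
            )
        fitted = loess(x, y, span=span, degree=2)
        return RegressionFit(lineage, generation, "loess", fitted, y - fitted, span)
    raise ValidationError(f"unknown model {model!r}; expected 'loess' or 'linear'")


def zscores(fit: RegressionFit) -> np.ndarray:
    """Standardise residuals: z = (r - mean(r)) / sd(r), sd with n-1."""
    r = fit.residuals
    sd = np.std(r, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateColumnError(
            f"zero residual variance for {fit.lineage} generation {fit.generation}"
        )
    return (r - r.mean()) / sd


def binarize(z, cutoff: float = DEFAULT_CUTOFF):
    """Ternary calls: +1 where z >= cutoff, -1 where z <= -cutoff, else 0.

    The comparison is inclusive at the boundary.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    arr = np.asarray(z, dtype=float)
    calls = np.zeros(arr.shape, dtype=np.int8)
    calls[arr >= cutoff] = 1
    calls[arr <= -cutoff] = -1
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(calls, index=z.index, columns=z.columns)
    if isinstance(z, pd.Series):
        return pd.Series(calls, index=z.index)
    return calls


def zscore_matrix(
    cm: CountMatrix,
    model: str = "loess",
    span: float = DEFAULT_SPAN,
    pseudocount: float = 1.0,
    prenormalized: bool = False,
) -> pd.DataFrame:
    """Z-score matrix, loci x (lineage, generation>0), from raw counts.

    Applies median-of-ratios normalization (unless ``prenormalized``),
    log2 with pseudocount, then per-lineage regression of every sampled
    generation on that lineage's founder.
    """
    if prenormalized:
        norm = cm.counts
    else:
        norm = normalize(cm, size_factors(cm)).counts
    log2 = log2p(norm, pseudocount)
    cols: dict[tuple[str, int], np.ndarray] = {}
    for lineage in cm.lineages:
        founder = log2[cm.sample_at(lineage, 0).sample_id].to_numpy()
        for g in cm.generations(lineage):
            if g == 0:
                continue
            resp = log2[cm.sample_at(lineage, g).sample_id].to_numpy()
            fit = fit_generation(founder, resp, model=model, span=span,
                                 lineage=lineage, generation=g)
            cols[(lineage, g)] = zscores(fit)
    z = pd.DataFrame(cols, index=cm.loci)
    z.columns = pd.MultiIndex.from_tuples(z.columns, names=["lineage", "generation"])
    return z


def call_epimutations(
    cm: CountMatrix,
    model: str = "loess",
    cutoff: float = DEFAULT_CUTOFF,
    span: float = DEFAULT_SPAN,
    pseudocount: float = 1.0,
    prenormalized: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full caller: returns (z matrix, ternary call matrix)."""
    z = zscore_matrix(cm, model=model, span=span, pseudocount=pseudocount,
                      prenormalized=prenormalized)
    return z, binarize(z, cutoff)


# -- cutoff calibration --------------------------------------------------


def _next_column_pairs(columns: pd.MultiIndex) -> list[tuple[int, int]]:
    """Index pairs (col, next sampled col of the same lineage)."""
    pairs = []
    by_lineage: dict[str, list[tuple[int, int]]] = {}
    for idx, (lineage, gen) in enumerate(columns):
        by_lineage.setdefault(lineage, []).append((gen, idx))
    for entries in by_lineage.values():
        entries.sort()
        for (g0, i0), (g1, i1) in zip(entries, entries[1:]):
            pairs.append((i0, i1))
    return pairs


def _inherited_percent(calls: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    """Percent of nonzero calls recurring with the same direction at the
    next sampled generation of the same lineage.

    Calls in a lineage's final column have no successor and are excluded
    from the denominator.
    """
    num = 0
    den = 0
    for i0, i1 in pairs:
        c0 = calls[:, i0]
        nz = c0 != 0
        den += int(nz.sum())
        num += int((c0[nz] == calls[nz, i1]).sum())
    if den == 0:
        return float("nan")
    return 100.0 * num / den


def calibrate_cutoff(
    z: pd.DataFrame,
    grid,
    n_sim: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare observed vs chance inheritance across a cutoff grid.

    For each cutoff, ``observed_pct`` is the percentage of calls that
    recur (same direction) at the next sampled generation.  The null
    keeps each column's per-direction call rates but redraws calls
    independently per locus and generation; ``expected_pct`` is the
    mean over ``n_sim`` such datasets and ``p`` the one-sided
    Monte-Carlo probability that a null dataset is at least as
    inherited as the observed one.  The table's ``recommended``
    column marks the largest cutoff with p < ``alpha``.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("cutoff grid must be non-empty")
    if sorted(grid) != grid:
        raise ValidationError("cutoff grid must be sorted ascending")
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    zv = z.to_numpy()
    n_loci, n_cols = zv.shape
    pairs = _next_column_pairs(z.columns)
    if not pairs:
        raise ValidationError("need >= 2 sampled generations per lineage")
    rng = np.random.default_rng([seed, 3])

    rows = []
    for cutoff in grid:
        calls = np.zeros(zv.shape, dtype=np.int8)
        calls[zv >= cutoff] = 1
        calls[zv <= -cutoff] = -1
        observed = _inherited_percent(calls, pairs)
        rate_up = (calls == 1).mean(axis=0)
        rate_dn = (calls == -1).mean(axis=0)
        sims = np.empty(n_sim)
        for s in range(n_sim):
            u = rng.random((n_loci, n_cols))
            sim_calls = np.zeros_like(calls)
            sim_calls[u < rate_up] = 1
            sim_calls[(u >= rate_up) & (u < rate_up + rate_dn)] = -1
            sims[s] = _inherited_percent(sim_calls, pairs)
        expected = float(np.nanmean(sims))
        if np.isnan(observed):
            p = float("nan")
        else:
            p = (1.0 + np.sum(sims >= observed)) / (n_sim + 1.0)
        rows.append(
            {
                "cutoff": cutoff,
                "observed_pct": observed,
                "expected_pct": expected,
                "difference": observed - expected,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    significant = table["p"] < alpha
    table["recommended"] = False
    if significant.any():
        table.loc[significant[significant].index.max(), "recommended"] = True
    return table
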