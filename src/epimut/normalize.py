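"""Median-of-ratios library-size normalization and log2 transform.

The size factor of a sample is the median, over loci expressed in every
sample, of the ratio between the sample's count and the locus's
geometric mean across samples (the pseudo-reference).  Dividing a
sample's raw counts by its factor puts all samples on a common scale.
Loci with any zero count are excluded from the median because their
geometric mean is zero on the count scale; this is the standard dialect
of the method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CountMatrix, ValidationError


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Raises
    ------
    ValidationError
        If no locus has strictly positive counts in all samples, the
        pseudo-reference (and hence the factors) is undefined.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "size factors undefined: no locus has positive counts in all samples"
        )
    pos = counts[all_positive]
    # geometric mean via mean of logs; pos is strictly positive
    log_geomean = np.log(pos).mean(axis=1, keepdims=True)
    ratios = pos / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=cm.counts.columns, name="factor")


def normalize(cm: CountMatrix, factors: pd.Series) -> CountMatrix:
    """Divide each sample's raw counts by that sample's size factor."""
    missing = [c for c in cm.counts.columns if c not in factors.index]
    if missing:
        raise ValidationError(f"missing size factors for samples: {missing}")
    if (factors.loc[cm.counts.columns] <= 0).any():
        raise ValidationError("size factors must be positive")
    norm = cm.counts / factors.loc[cm.counts.columns]
    return CountMatrix(norm, cm.samples, cm.locus_class, require_int=False)


def log2p(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount).

    With the default pseudocount of 1, zero counts map to 0.  A
    pseudocount of 0 is allowed only when all values are positive.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (values.to_numpy() <= 0).any():
        raise ValidationError("zero values require a positive pseudocount")
    return np.log2(values + pseudocount)
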