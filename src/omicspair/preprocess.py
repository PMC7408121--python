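"""Feature filters and normalizations for both omics layers.

Every filter returns the reduced matrix together with a
:class:`FilterReport`, so the full feature funnel can be reconstructed
from logs.  All filters preserve input feature order and are idempotent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    stage: str
    features_in: int
    features_out: int
    removed_ids: list[str]

    def __post_init__(self) -> None:
        if self.features_out != self.features_in - len(self.removed_ids):
            raise ValueError("inconsistent filter report")
        if self.features_out < 0:
            raise ValueError("negative feature count")


def _apply_removal(matrix: OmicsMatrix, removed: list[str], stage: str,
                   layer: str | None = None) -> tuple[OmicsMatrix, FilterReport]:
    keep = [f for f in matrix.feature_ids if f not in set(removed)]
    report = FilterReport(stage, matrix.n_features, len(keep), removed)
    logger.info("%s: %d -> %d features (%d removed)",
                stage, report.features_in, report.features_out, len(removed))
    out = matrix.select_features(keep, layer=layer)
    return out, report


def filter_low_count_genes(counts: OmicsMatrix, threshold: float = 1.0,
                           per_sample_mean: bool = False) -> tuple[OmicsMatrix, FilterReport]:
    """Drop genes whose total (or mean, if ``per_sample_mean``) count falls below ``threshold``.

    With the default total-count reading and integer counts, threshold 1
    removes exactly the all-zero genes.
    """
    if counts.layer != "counts":
        raise UsageError(f"low-count filter expects a counts layer, got {counts.layer!r}")
    stat = counts.values.mean(axis=1) if per_sample_mean else counts.values.sum(axis=1)
    removed = [f for f, s in zip(counts.feature_ids, stat) if s < threshold]
    return _apply_removal(counts, removed, "low_count")


def normalize_counts(counts: OmicsMatrix) -> OmicsMatrix:
    """Median-of-ratios size factors followed by log2(count/size_factor + 1).

    The per-gene reference is the geometric mean across samples; genes
    containing a zero anywhere are excluded from the reference (their
    geometric mean is zero and would not yield a usable ratio).  This is
    a documented stand-in for a variance-stabilizing transform: it is
    monotone within each sample and flattens the count mean-variance
    relationship.
    """
    if counts.layer != "counts":
        raise UsageError(f"normalize_counts expects a counts layer, got {counts.layer!r}")
    col_sums = counts.values.sum(axis=0)
    if np.any(col_sums == 0):
        bad = counts.sample_ids[int(np.argmax(col_sums == 0))]
        raise UsageError(f"sample {bad!r} has all-zero counts; cannot compute a size factor")
    allpos = np.all(counts.values > 0, axis=1)
    if not allpos.any():
        raise UsageError("no gene has nonzero counts in every sample; "
                         "median-of-ratios reference is undefined")
    ref = np.exp(np.mean(np.log(counts.values[allpos]), axis=1))  # geometric mean per gene
    size_factors = np.median(counts.values[allpos] / ref[:, None], axis=0)
    logger.info("size factors: min %.4g, max %.4g", size_factors.min(), size_factors.max())
    values = np.log2(counts.values / size_factors[None, :] + 1.0)
    return OmicsMatrix(list(counts.feature_ids), list(counts.sample_ids), values, "normalized")


def rsd_filter(abundances: OmicsMatrix, threshold: float = 0.15) -> tuple[OmicsMatrix, FilterReport]:
    """Keep metabolites whose relative standard deviation (sd/mean, sample sd) exceeds ``threshold``."""
    if abundances.layer != "raw_abundance":
        raise UsageError(f"RSD filter expects raw abundances, got {abundances.layer!r}")
    means = abundances.values.mean(axis=1)
    if np.any(means == 0):
        bad = abundances.feature_ids[int(np.argmax(means == 0))]
        raise UsageError(f"metabolite {bad!r} has zero mean; RSD undefined")
    rsd = abundances.values.std(axis=1, ddof=1) / means
    removed = [f for f, r in zip(abundances.feature_ids, rsd) if not r > threshold]
    return _apply_removal(abundances, removed, "rsd")


def log_normalize_metabolites(abundances: OmicsMatrix) -> OmicsMatrix:
    """Natural-log transform of strictly positive abundances."""
    if np.any(abundances.values <= 0):
        i, j = np.argwhere(abundances.values <= 0)[0]
        raise UsageError(
            f"nonpositive abundance at metabolite {abundances.feature_ids[i]!r}, "
            f"sample {abundances.sample_ids[j]!r}; cannot log-transform"
        )
    return OmicsMatrix(list(abundances.feature_ids), list(abundances.sample_ids),
                       np.log(abundances.values), "log_abundance")


def variance_filter(matrix: OmicsMatrix, fraction: float = 0.05) -> tuple[OmicsMatrix, FilterReport]:
    """Remove the ``ceil(fraction * n)`` lowest-variance features.

    Ties are broken by lexical feature-ID order so the result is stable
    and platform-independent.  Retained count is always
    ``n - ceil(fraction * n)``.
    """
    if not 0 <= fraction < 1:
        raise UsageError(f"variance fraction must be in [0, 1), got {fraction}")
    n = matrix.n_features
    k = math.ceil(fraction * n)
    if k == 0:
        return _apply_removal(matrix, [], "variance")
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(range(n), key=lambda i: (var[i], matrix.feature_ids[i]))
    removed = [matrix.feature_ids[i] for i in order[:k]]
    return _apply_removal(matrix, removed, "variance")


def nonneg_filter(matrix: OmicsMatrix) -> tuple[OmicsMatrix, FilterReport]:
    """Remove every feature that has at least one negative value."""
    if matrix.layer not in ("normalized", "adjusted"):
        raise UsageError(f"nonneg filter expects a normalized or adjusted layer, got {matrix.layer!r}")
    has_neg = (matrix.values < 0).any(axis=1)
    removed = [f for f, b in zip(matrix.feature_ids, has_neg) if b]
    return _apply_removal(matrix, removed, "nonneg")


def classify_by_sd(values: pd.Series, strata: pd.Series | None = None,
                   k: float = 1.0) -> pd.Series:
    """Label samples low/high/excluded by a k-standard-deviation rule.

    Within each stratum (e.g. breed), values at or below ``mean - k*sd``
    are labeled ``low``, values at or above ``mean + k*sd`` are labeled
    ``high``, and everything else ``excluded``.  For feed conversion
    ratio, ``low`` means high feed efficiency.  A zero-variance stratum
    yields all ``excluded`` with a warning.
    """
    values = pd.Series(values)
    if strata is None:
        strata = pd.Series("all", index=values.index)
    labels = pd.Series("excluded", index=values.index, dtype=object)
    for name, grp in values.groupby(pd.Series(strata)):
        if len(grp) < 3:
            raise UsageError(f"stratum {name!r} has fewer than 3 samples")
        mean, sd = grp.mean(), grp.std(ddof=1)
        if sd == 0:
            logger.warning("stratum %r has zero variance; all samples excluded", name)
            continue
        labels[grp.index[grp <= mean - k * sd]] = "low"
        labels[grp.index[grp >= mean + k * sd]] = "high"
    return labels
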