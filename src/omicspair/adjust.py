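"""Per-feature fixed-effect covariate adjustment.

Each feature is regressed on a shared design matrix (intercept, one-hot
factors with a dropped reference level, numeric covariates) by QR least
squares; the adjusted value is the fitted intercept plus the residual,
which removes nuisance effects while keeping values on the original
scale.  Adjustment is a projection: applying it twice changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import UsageError
from .io import OmicsMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """Which metadata columns enter the adjustment design, and how."""

    fixed_factors: list[str]
    numeric_covariates: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = self.fixed_factors + self.numeric_covariates
        if len(set(cols)) != len(cols):
            dup = next(c for c in cols if cols.count(c) > 1)
            raise UsageError(f"column {dup!r} listed twice in design spec")


@dataclass
class AdjustedMatrix:
    matrix: OmicsMatrix
    residual_dof: int

    def __post_init__(self) -> None:
        if self.residual_dof <= 0:
            raise UsageError("design leaves no residual degrees of freedom")


#: Stock nuisance designs per analysis mode and omics layer.  The
#: phenotype under test never appears in its own adjustment: the breed
#: mode adjusts for FE group (and vice versa).
MODE_DESIGNS: dict[tuple[str, str], DesignSpec] = {
    ("breed", "genes"): DesignSpec(["fe_group", "pen"], ["rin", "slaughter_age_days"]),
    ("breed", "metabolites"): DesignSpec(["fe_group", "batch", "pen"], ["sampling_age_days"]),
    ("fe", "genes"): DesignSpec(["breed", "pen"], ["rin", "slaughter_age_days"]),
    ("fe", "metabolites"): DesignSpec(["breed", "batch", "pen"], ["sampling_age_days"]),
}


def design_for_mode(mode: str, layer: str) -> DesignSpec:
    try:
        return MODE_DESIGNS[(mode, layer)]
    except KeyError:
        raise UsageError(f"no stock design for mode={mode!r}, layer={layer!r}; "
                         "expected mode in {'breed','fe'} and layer in {'genes','metabolites'}") from None


def build_design(meta: SampleTable, spec: DesignSpec) -> pd.DataFrame:
    """Build the samples x coefficients design matrix.

    Columns: intercept, then one indicator per non-reference factor
    level (factors in spec order, levels lexically sorted), then numeric
    covariates in spec order.  Raises on single-level factors and on
    rank deficiency, naming the aliased columns.
    """
    n = len(meta.sample_ids)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for factor in spec.fixed_factors:
        series = meta.column(factor).astype(str)
        levels = sorted(series.unique())
        if len(levels) < 2:
            raise UsageError(f"factor {factor!r} has a single level among these samples")
        ref = spec.reference_levels.get(factor, levels[0])
        if ref not in levels:
            raise UsageError(f"reference level {ref!r} absent from factor {factor!r}")
        for level in levels:
            if level == ref:
                continue
            cols[f"{factor}[{level}]"] = (series == level).to_numpy(dtype=float)
    for cov in spec.numeric_covariates:
        vals = pd.to_numeric(meta.column(cov), errors="raise").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise UsageError(f"covariate {cov!r} has missing or non-finite values")
        cols[cov] = vals
    design = pd.DataFrame(cols, index=pd.Index(meta.sample_ids, name="sample_id"))
    _check_rank(design)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy()
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [design.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise UsageError(f"design is rank-deficient; aliased columns: {aliased}")


def adjust(matrix: OmicsMatrix, design: pd.DataFrame, keep: str = "mean") -> AdjustedMatrix:
    """OLS-adjust every feature against the design.

    ``design`` rows must match the matrix sample IDs in the same order;
    no silent reordering.  ``keep`` picks the level added back onto the
    residuals: ``"mean"`` (default) keeps each feature's grand mean so
    per-feature sample means are preserved exactly; ``"intercept"``
    keeps the fitted intercept (reference-level expectation, which
    shifts means when covariates are uncentered); ``"residual"`` keeps
    nothing.  All three are projections (idempotent).
    """
    if list(design.index) != list(matrix.sample_ids):
        raise UsageError(
            "design rows do not match matrix samples in order; "
            f"design={list(design.index)[:5]}..., matrix={matrix.sample_ids[:5]}..."
        )
    _check_rank(design)
    X = design.to_numpy()
    n, p = X.shape
    if n - p <= 0:
        raise UsageError(f"no residual degrees of freedom: {n} samples, {p} coefficients")
    if "intercept" not in design.columns:
        raise UsageError("design must contain an 'intercept' column")
    Y = matrix.values.T  # samples x features
    Q, R = np.linalg.qr(X)
    beta = scipy.linalg.solve_triangular(R, Q.T @ Y)
    resid = Y - X @ beta
    if keep == "mean":
        level = Y.mean(axis=0)
    elif keep == "intercept":
        icol = list(design.columns).index("intercept")
        level = beta[icol]
    elif keep == "residual":
        level = np.zeros(Y.shape[1])
    else:
        raise UsageError(f"keep must be 'mean', 'intercept' or 'residual', got {keep!r}")
    adjusted = (level[None, :] + resid).T  # features x samples
    logger.info("adjusted %d features on %d-column design (dof %d)",
                matrix.n_features, p, n - p)
    out = OmicsMatrix(list(matrix.feature_ids), list(matrix.sample_ids), adjusted, "adjusted")
    return AdjustedMatrix(out, residual_dof=n - p)
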