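"""Exhaustive gene-metabolite interaction modeling.

For every (gene, metabolite) pair the model

    m = b1 + b2*g + b3*p + b4*(g*p) + e

is fitted by least squares, where ``p`` is a 0/1 phenotype.  The
two-tailed t probability of the interaction coefficient ``b4`` (n - 4
degrees of freedom) flags pairs whose gene-metabolite slope differs
between phenotype groups.  Per-group Spearman correlations and their
signed difference (group1 - group0) provide the accompanying effect
size.  The engine is blocked and fully vectorized; results are
identical, bit for bit, for any block size, because each gene's
cross-products are computed independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .errors import UsageError
from .io import OmicsMatrix, SampleTable

logger = logging.getLogger(__name__)

#: Smallest representable positive double; p-values are capped here so
#: they stay in (0, 1] even for exact fits.
_P_FLOOR = float(np.finfo(float).smallest_subnormal)

RESULT_COLUMNS = [
    "metabolite_id", "gene_id", "beta1", "beta2", "beta3", "beta4",
    "se_beta4", "p_interaction", "fdr", "cor_group0", "cor_group1",
    "diff_corr", "abs_diff_corr", "significant", "cluster",
]


@dataclass
class PhenotypeCoding:
    """Binary phenotype contrast: ``level0`` codes 0, ``level1`` codes 1.

    For the two stock analyses group0 is Duroc (breed mode) or the
    high-FE group (FE mode), which makes ``diff_corr = cor_group1 -
    cor_group0`` the Landrace-minus-Duroc / low-minus-high convention.
    """

    column: str
    level0: str
    level1: str
    mode: str | None = None

    def encode(self, meta: SampleTable, sample_ids: list[str]) -> np.ndarray:
        labels = meta.subset(sample_ids).column(self.column).astype(str)
        extra = sorted(set(labels) - {self.level0, self.level1})
        if extra:
            raise UsageError(f"phenotype column {self.column!r} has unexpected levels: {extra}")
        p = (labels == self.level1).to_numpy(dtype=float)
        n0, n1 = int((p == 0).sum()), int((p == 1).sum())
        if n0 < 3 or n1 < 3:
            raise UsageError(
                f"each phenotype level needs >= 3 samples; got {self.level0}={n0}, {self.level1}={n1}"
            )
        return p

    def swapped(self) -> "PhenotypeCoding":
        return PhenotypeCoding(self.column, self.level1, self.level0, self.mode)


@dataclass
class PairResult:
    gene_id: str
    metabolite_id: str
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    se_beta4: float
    p_interaction: float
    cor_group0: float
    cor_group1: float
    diff_corr: float
    abs_diff_corr: float
    singular: bool = False
    fdr: float = float("nan")
    significant: bool = False
    cluster: str = "none"


def _validate_pair_inputs(g: np.ndarray, m: np.ndarray, p: np.ndarray) -> None:
    g, m, p = np.asarray(g, float), np.asarray(m, float), np.asarray(p, float)
    if not (g.shape == m.shape == p.shape) or g.ndim != 1:
        raise UsageError("g, m and p must be one-dimensional and equally sized")
    if g.size < 6:
        raise UsageError("pair model needs at least 6 samples")
    if not set(np.unique(p)) <= {0.0, 1.0}:
        raise UsageError("phenotype vector must be 0/1")
    if min((p == 0).sum(), (p == 1).sum()) < 3:
        raise UsageError("each phenotype group needs at least 3 samples")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(m))):
        raise UsageError("missing values are not allowed in the pair model")


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1 (tie-aware)."""
    return stats.rankdata(values, axis=1, method="average")


def _standardize_ranks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rank rows to unit norm; constant rows become zero.

    Returns (z, degenerate_mask); the dot product of two z-rows is the
    Spearman correlation.
    """
    r = _rank_rows(values)
    r = r - r.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(r, axis=1)
    degenerate = norms == 0
    norms[degenerate] = 1.0
    return r / norms[:, None], degenerate


def spearman_by_group(g: np.ndarray, m: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of (g, m) within each phenotype group.

    Ties get average ranks.  A constant vector within a group makes the
    correlation degenerate; it is reported as 0.0 with a log note.
    """
    g, m, p = np.asarray(g, float), np.asarray(m, float), np.asarray(p, float)
    out = []
    for level in (0.0, 1.0):
        mask = p == level
        if mask.sum() < 3:
            raise UsageError("each phenotype group needs at least 3 samples")
        zg, dg = _standardize_ranks(g[None, mask])
        zm, dm = _standardize_ranks(m[None, mask])
        if dg[0] or dm[0]:
            logger.debug("degenerate (constant) vector in group %d; correlation set to 0", int(level))
            out.append(0.0)
        else:
            out.append(float(zg[0] @ zm[0]))
    return out[0], out[1]


def correlation_difference(cor_group0: float, cor_group1: float) -> float:
    """Signed correlation difference, group1 minus group0."""
    return cor_group1 - cor_group0


def fit_pair(g: np.ndarray, m: np.ndarray, p: np.ndarray,
             gene_id: str = "gene", metabolite_id: str = "metabolite") -> PairResult:
    """Fit the interaction model for one pair.

    A rank-deficient design (e.g. a gene constant across all samples)
    is not an error: the pair is flagged singular and reported with
    ``p_interaction = 1``.
    """
    g, m, p = np.asarray(g, float), np.asarray(m, float), np.asarray(p, float)
    _validate_pair_inputs(g, m, p)
    n = g.size
    X = np.column_stack([np.ones(n), g, p, g * p])
    beta, _, rank, _ = np.linalg.lstsq(X, m, rcond=None)
    singular = rank < 4
    if singular:
        logger.warning("singular fit for pair (%s, %s); reporting p=1", gene_id, metabolite_id)
        b1 = b2 = b3 = b4 = se4 = float("nan")
        p_int = 1.0
    else:
        resid = m - X @ beta
        dof = n - 4
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se4 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
        if se4 == 0.0:
            p_int = _P_FLOOR
        else:
            t4 = beta[3] / se4
            p_int = max(2.0 * float(stats.t.sf(abs(t4), dof)), _P_FLOOR)
        b1, b2, b3, b4 = map(float, beta)
    c0, c1 = spearman_by_group(g, m, p)
    diff = correlation_difference(c0, c1)
    return PairResult(gene_id, metabolite_id, b1, b2, b3, b4, se4, p_int,
                      c0, c1, diff, abs(diff), singular=singular)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise UsageError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        bad = p[~((p > 0) & (p <= 1))][0]
        raise UsageError(f"p-value outside (0, 1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_all_pairs(genes: OmicsMatrix, metabolites: OmicsMatrix,
                  phenotype: np.ndarray, block_size: int = 2000,
                  count_only: bool = False) -> tuple[pd.DataFrame, int]:
    """Fit the interaction model for every gene x metabolite pair.

    Genes are processed in blocks of ``block_size`` to bound memory; the
    per-gene math is independent of the blocking, so results match the
    pair-at-a-time :func:`fit_pair` to floating-point noise.  With
    ``count_only`` the inputs are validated and the model grid
    enumerated without fitting (the returned frame is empty); this is
    the cheap way to report the size of the model family.

    Returns the result frame (one row per pair, genes outer, metabolites
    inner) and the model count ``n_genes * n_metabolites``.
    """
    if list(genes.sample_ids) != list(metabolites.sample_ids):
        only_g = sorted(set(genes.sample_ids) - set(metabolites.sample_ids))
        only_m = sorted(set(metabolites.sample_ids) - set(genes.sample_ids))
        raise UsageError(
            "gene and metabolite matrices must share identically ordered samples; "
            f"gene-only={only_g}, metabolite-only={only_m}"
        )
    p = np.asarray(phenotype, dtype=float)
    if p.shape != (genes.n_samples,):
        raise UsageError("phenotype vector length does not match sample count")
    if not set(np.unique(p)) <= {0.0, 1.0}:
        raise UsageError("phenotype vector must be 0/1")
    if block_size < 1:
        raise UsageError("block size must be >= 1")

    n = genes.n_samples
    n_genes, n_mets = genes.n_features, metabolites.n_features
    model_count = n_genes * n_mets
    logger.info("enumerating %d x %d = %d pair models", n_genes, n_mets, model_count)
    if count_only:
        return pd.DataFrame(columns=RESULT_COLUMNS), model_count
    if n < 6 or min((p == 0).sum(), (p == 1).sum()) < 3:
        raise UsageError("need >= 6 samples with >= 3 per phenotype group")

    M = metabolites.values  # mets x samples
    MT = M.T                # samples x mets
    dof = n - 4

    # per-group standardized ranks for Spearman correlations
    mask0, mask1 = p == 0, p == 1
    zm0, degm0 = _standardize_ranks(M[:, mask0])
    zm1, degm1 = _standardize_ranks(M[:, mask1])

    blocks: list[pd.DataFrame] = []
    met_ids = np.asarray(metabolites.feature_ids)
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        G = genes.values[start:stop]
        zg0, degg0 = _standardize_ranks(G[:, mask0])
        zg1, degg1 = _standardize_ranks(G[:, mask1])
        cor0 = zg0 @ zm0.T  # block_genes x mets
        cor1 = zg1 @ zm1.T
        cor0[degg0, :] = 0.0
        cor1[degg1, :] = 0.0
        cor0[:, degm0] = 0.0
        cor1[:, degm1] = 0.0

        nb = stop - start
        beta = np.empty((nb, 4, n_mets))
        se4 = np.empty((nb, n_mets))
        p_int = np.empty((nb, n_mets))
        for bi in range(nb):
            g = G[bi]
            X = np.column_stack([np.ones(n), g, p, g * p])
            Q, R = np.linalg.qr(X)
            rdiag = np.abs(np.diag(R))
            if rdiag.min() <= rdiag.max() * n * np.finfo(float).eps:
                logger.warning("singular fit for gene %r; reporting p=1",
                               genes.feature_ids[start + bi])
                beta[bi] = np.nan
                se4[bi] = np.nan
                p_int[bi] = 1.0
                continue
            b = scipy.linalg.solve_triangular(R, Q.T @ MT)  # 4 x mets
            resid = MT - X @ b
            sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
            rinv = scipy.linalg.solve_triangular(R, np.eye(4))
            xtx_inv33 = float((rinv[3] ** 2).sum())
            s = np.sqrt(sigma2 * xtx_inv33)
            beta[bi] = b
            se4[bi] = s
            with np.errstate(divide="ignore", invalid="ignore"):
                t4 = np.where(s > 0, b[3] / np.where(s > 0, s, 1.0), np.inf)
            p_int[bi] = np.maximum(2.0 * stats.t.sf(np.abs(t4), dof), _P_FLOOR)

        gene_ids = np.repeat(np.asarray(genes.feature_ids[start:stop]), n_mets)
        frame = pd.DataFrame({
            "metabolite_id": np.tile(met_ids, nb),
            "gene_id": gene_ids,
            "beta1": beta[:, 0, :].ravel(),
            "beta2": beta[:, 1, :].ravel(),
            "beta3": beta[:, 2, :].ravel(),
            "beta4": beta[:, 3, :].ravel(),
            "se_beta4": se4.ravel(),
            "p_interaction": p_int.ravel(),
            "cor_group0": cor0.ravel(),
            "cor_group1": cor1.ravel(),
        })
        blocks.append(frame)

    results = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(columns=RESULT_COLUMNS)
    results["diff_corr"] = results["cor_group1"] - results["cor_group0"]
    results["abs_diff_corr"] = results["diff_corr"].abs()
    results["fdr"] = bh_fdr(results["p_interaction"].to_numpy())
    results["significant"] = False
    results["cluster"] = "none"
    logger.info("fitted %d pair models", model_count)
    return results[RESULT_COLUMNS], model_count


def filter_significant(results: pd.DataFrame, fdr_max: float = 0.1,
                       min_abs_diff: float = 0.1,
                       raw_p_max: float | None = None) -> pd.DataFrame:
    """Apply the significance screens and return the surviving rows.

    Keeps pairs with ``fdr <= fdr_max`` and ``|diff_corr| > min_abs_diff``
    and, when set, ``p_interaction < raw_p_max``.  The raw-p screen is
    off by default.  The returned frame has ``significant`` set True.
    """
    for col in ("fdr", "diff_corr"):
        if col not in results.columns:
            raise UsageError(f"results frame lacks required column {col!r}")
    keep = (results["fdr"] <= fdr_max) & (results["diff_corr"].abs() > min_abs_diff)
    if raw_p_max is not None:
        keep &= results["p_interaction"] < raw_p_max
    logger.info("significance filter (fdr<=%g, |diff|>%g, raw_p<%s): %d -> %d pairs",
                fdr_max, min_abs_diff, raw_p_max, len(results), int(keep.sum()))
    out = results.loc[keep].copy()
    out["significant"] = True
    return out
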