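"""Sign-based clustering of significant pairs and display ordering.

Significant pairs split into two direction clusters keyed on the sign
of the correlation in a chosen reference group: pairs positively
correlated in the reference group versus pairs negatively correlated
there (and typically oppositely correlated in the other group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import UsageError

logger = logging.getLogger(__name__)

REF_CORRELATED = "ref_correlated"
REF_ANTICORRELATED = "ref_anticorrelated"
_CLUSTER_ORDER = {REF_CORRELATED: 0, REF_ANTICORRELATED: 1}


@dataclass
class ClusterSummary:
    cluster: str
    n_pairs: int
    unique_metabolites: list[str]
    unique_genes: list[str]


def assign_clusters(significant: pd.DataFrame, reference: str = "group0") -> pd.DataFrame:
    """Set the ``cluster`` column from the sign of the reference-group correlation.

    ``reference`` is ``"group0"`` or ``"group1"``.  Positive reference
    correlation puts the pair in ``ref_correlated``, negative in
    ``ref_anticorrelated``.  An exact zero is assigned to
    ``ref_anticorrelated`` with a warning (deterministic tie rule;
    never seen on continuous data).
    """
    if reference not in ("group0", "group1"):
        raise UsageError(f"reference must be 'group0' or 'group1', got {reference!r}")
    col = f"cor_{reference}"
    if col not in significant.columns:
        raise UsageError(f"results frame lacks column {col!r}")
    out = significant.copy()
    ref_cor = out[col]
    n_zero = int((ref_cor == 0).sum())
    if n_zero:
        logger.warning("%d pair(s) with exactly zero reference correlation "
                       "assigned to %s", n_zero, REF_ANTICORRELATED)
    out["cluster"] = [REF_CORRELATED if c > 0 else REF_ANTICORRELATED for c in ref_cor]
    return out


def summarize_cluster(pairs: pd.DataFrame, cluster: str | None = None) -> ClusterSummary:
    """Deduplicated, sorted unique gene and metabolite lists for one cluster."""
    label = cluster if cluster is not None else (
        str(pairs["cluster"].iloc[0]) if len(pairs) else "none")
    if len(pairs) == 0:
        return ClusterSummary(label, 0, [], [])
    return ClusterSummary(
        label,
        int(len(pairs)),
        sorted(pairs["metabolite_id"].unique()),
        sorted(pairs["gene_id"].unique()),
    )


def summarize_clusters(assigned: pd.DataFrame) -> list[ClusterSummary]:
    """One :class:`ClusterSummary` per emitted cluster, correlated first."""
    summaries = []
    for label in sorted(assigned["cluster"].unique(), key=lambda c: _CLUSTER_ORDER.get(c, 99)):
        summaries.append(summarize_cluster(assigned[assigned["cluster"] == label], label))
    return summaries


def order_for_heatmap(pairs: pd.DataFrame) -> pd.DataFrame:
    """Deterministic display order: by cluster, then descending |diff_corr|.

    Residual ties break on (gene_id, metabolite_id) so the order is
    reproducible across runs and platforms.
    """
    if len(pairs) == 0:
        return pairs.copy()
    out = pairs.copy()
    out["_corder"] = out["cluster"].map(lambda c: _CLUSTER_ORDER.get(c, 99))
    out = out.sort_values(
        ["_corder", "abs_diff_corr", "gene_id", "metabolite_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_corder")
    return out.reset_index(drop=True)


def summary_frame(summaries: list[ClusterSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cluster": s.cluster,
            "n_pairs": s.n_pairs,
            "n_unique_metabolites": len(s.unique_metabolites),
            "n_unique_genes": len(s.unique_genes),
            "unique_metabolites": ";".join(s.unique_metabolites),
            "unique_genes": ";".join(s.unique_genes),
        }
        for s in summaries
    ])
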