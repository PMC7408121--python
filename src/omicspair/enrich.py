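"""Hypergeometric over-representation and optional pathway topology impact.

The over-representation p-value is the upper tail P(X >= k) of a
hypergeometric draw — note ``>=``, not ``>``; the off-by-one here is a
classic silent bug, so the convention is fixed and tested.  Zero
overlap therefore gives p = 1 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import UsageError
from .integrate import bh_fdr
from .io import PathwayLibrary

logger = logging.getLogger(__name__)

ORA_COLUMNS = ["set_name", "set_size", "universe_size", "n_hits_total",
               "n_overlap", "p", "fdr", "impact"]


@dataclass
class OraResult:
    set_name: str
    set_size: int
    universe_size: int
    n_hits_total: int
    n_overlap: int
    p: float
    fdr: float = float("nan")
    impact: float | None = None


def hypergeom_upper_tail(n_overlap: int, universe_size: int,
                         set_size: int, n_hits: int) -> float:
    """P(X >= n_overlap) for X ~ Hypergeometric(universe, set, draws=hits)."""
    if n_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_overlap - 1, universe_size, set_size, n_hits))


def hypergeom_ora(hits: Iterable[str], universe: Iterable[str],
                  library: PathwayLibrary) -> pd.DataFrame:
    """Test each library set for over-representation of ``hits`` in ``universe``.

    Sets are intersected with the universe before testing; BH-FDR is
    computed across all tested sets.  Raises if any hit lies outside the
    universe.
    """
    hits = set(hits)
    universe = set(universe)
    strays = sorted(hits - universe)
    if strays:
        raise UsageError(f"hits outside the universe: {strays}")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in library.sets.items():
        in_universe = universe.intersection(members)
        k = len(hits.intersection(in_universe))
        p = hypergeom_upper_tail(k, M, len(in_universe), N)
        rows.append(OraResult(name, len(in_universe), M, N, k, p))
    frame = pd.DataFrame([vars(r) for r in rows], columns=ORA_COLUMNS)
    if len(frame):
        frame["fdr"] = bh_fdr(frame["p"].to_numpy())
        if library.graphs:
            frame["impact"] = [
                topology_impact(hits, library.graphs[name]) if name in library.graphs else None
                for name in frame["set_name"]
            ]
        frame = frame.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    logger.info("ORA: %d sets tested against %d hits in a universe of %d",
                len(frame), N, M)
    return frame


def topology_impact(hits: Iterable[str], edges: list[tuple[str, str]]) -> float:
    """Relative-betweenness impact of the hit nodes within one pathway graph.

    Exact betweenness centrality of every node is computed by
    shortest-path counting; the impact is the sum over hit nodes divided
    by the maximum betweenness in the graph.  Hits absent from the
    graph contribute 0.  A graph whose maximum betweenness is 0 (e.g.
    a single edge) has impact 0 by convention.
    """
    graph = nx.Graph()
    graph.add_edges_from(edges)
    if graph.number_of_nodes() == 0:
        raise UsageError("pathway graph is empty")
    bc = nx.betweenness_centrality(graph, normalized=True)
    max_bc = max(bc.values())
    if max_bc == 0:
        return 0.0
    total = 0.0
    for h in set(hits):
        if h in bc:
            total += bc[h]
        else:
            logger.debug("hit %r absent from pathway graph; contributes 0", h)
    return total / max_bc
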