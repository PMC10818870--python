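"""Network stability: removal robustness and community cohesion.

Robustness is the proportion of nodes that remain after a simulated removal
(random fraction or targeted module hubs) plus a secondary-extinction
cascade. Two cascade rules are available:

* ``degree_zero`` (default) — a surviving node goes secondarily extinct when
  it has lost every link.
* ``abundance_threshold`` — a surviving node goes extinct when the
  abundance-weighted sum of its surviving links falls below ``theta`` times
  its original value; iterated to a fixed point.

Cohesion follows the null-model approach of Herren & McMahon: a taxon's
connectedness is its average null-corrected positive (or negative) pairwise
correlation, where the null shuffles each taxon's abundances across samples
independently; a sample's positive (negative) cohesion is the
abundance-weighted sum of the taxa's positive (negative) connectedness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class RobustnessParams:
    removal_fraction: float = 0.5
    n_hubs_removed: int = 3
    replicates: int = 100
    cascade_rule: str = "degree_zero"   # or "abundance_threshold", "none"
    theta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.removal_fraction < 1:
            raise ValueError("removal_fraction must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cascade_rule not in ("degree_zero", "abundance_threshold", "none"):
            raise ValueError(f"unknown cascade rule {self.cascade_rule!r}")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")


@dataclass
class RobustnessResult:
    values: np.ndarray          # per-replicate remaining-node proportion
    mean: float
    sd: float
    removed: list = field(default_factory=list)  # targeted mode: nodes removed
    fallback_used: bool = False


def _graph_arrays(net: nx.Graph):
    nodes = list(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=float)
    for u, v, d in net.edges(data=True):
        w = abs(d.get("correlation", 1.0))
        adj[index[u], index[v]] = w
        adj[index[v], index[u]] = w
    ab = np.array([net.nodes[v].get("abundance", 1.0) for v in nodes])
    return nodes, adj, ab


def _cascade(alive: np.ndarray, adj: np.ndarray, ab: np.ndarray,
             rule: str, theta: float, base_strength: np.ndarray) -> np.ndarray:
    """Iterate secondary extinctions on the survivor mask until stable."""
    if rule == "none":
        return alive
    alive = alive.copy()
    binary = adj > 0
    while True:
        idx = alive.nonzero()[0]
        if rule == "degree_zero":
            deg = binary[np.ix_(idx, idx)].sum(axis=1)
            kill = idx[deg == 0]
        else:
            weighted = (adj[np.ix_(idx, idx)] * ab[idx][None, :]).sum(axis=1)
            kill = idx[weighted < theta * base_strength[idx]]
        if kill.size == 0:
            return alive
        alive[kill] = False


def robustness_random(net: nx.Graph, params: RobustnessParams | None = None
                      ) -> RobustnessResult:
    """Robustness under random removal of floor(fraction * N) nodes.

    Per replicate the removal set is drawn uniformly, the cascade applied,
    and robustness recorded as survivors / N. Deterministic under
    ``params.seed``.
    """
    params = params or RobustnessParams()
    nodes, adj, ab = _graph_arrays(net)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    n_remove = int(np.floor(params.removal_fraction * n))
    if n_remove < 1:
        raise ValueError("removal_fraction * N < 1: nothing to remove")
    base_strength = (adj * ab[None, :]).sum(axis=1)
    rng = np.random.default_rng(params.seed)
    values = np.empty(params.replicates)
    for rep in range(params.replicates):
        alive = np.ones(n, dtype=bool)
        alive[rng.choice(n, size=n_remove, replace=False)] = False
        alive = _cascade(alive, adj, ab, params.cascade_rule, params.theta,
                         base_strength)
        values[rep] = alive.sum() / n
    return RobustnessResult(values, float(values.mean()),
                            float(values.std(ddof=1)) if len(values) > 1 else 0.0)


def robustness_targeted(net: nx.Graph, zipi_table: pd.DataFrame,
                        params: RobustnessParams | None = None
                        ) -> RobustnessResult:
    """Robustness after deterministic removal of the top module hubs.

    Hubs are module-hub nodes ranked by Zi descending (ties: Pi ascending,
    then node id). When fewer module hubs exist than requested, the ranking
    falls back to all nodes by Zi, flagged in the result.
    """
    params = params or RobustnessParams()
    nodes, adj, ab = _graph_arrays(net)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    tab = zipi_table.copy()
    tab["_id"] = tab.index.astype(str)
    hubs = tab[tab["role"].isin(["module_hub", "network_hub"])]
    fallback = len(hubs) < params.n_hubs_removed
    pool = tab if fallback else hubs
    if fallback:
        logger.warning("only %d module hubs; falling back to top-Zi nodes",
                       len(hubs))
    ranked = pool.sort_values(["Zi", "Pi", "_id"],
                              ascending=[False, True, True])
    removed = ranked.index[:params.n_hubs_removed].tolist()
    if len(removed) < params.n_hubs_removed:
        raise ValueError("network smaller than n_hubs_removed")
    index = {v: i for i, v in enumerate(nodes)}
    alive = np.ones(n, dtype=bool)
    for v in removed:
        alive[index[v]] = False
    base_strength = (adj * ab[None, :]).sum(axis=1)
    alive = _cascade(alive, adj, ab, params.cascade_rule, params.theta,
                     base_strength)
    value = alive.sum() / n
    return RobustnessResult(np.array([value]), float(value), 0.0,
                            removed=removed, fallback_used=fallback)


@dataclass
class ConnectednessResult:
    """Per-taxon average null-corrected positive/negative correlation."""

    taxon_ids: list
    c_plus: np.ndarray     # >= 0
    c_minus: np.ndarray    # <= 0
    corrected: np.ndarray  # full null-corrected correlation matrix


def connectedness(reltable: AbundanceTable, null_reps: int = 200,
                  seed: int = 0) -> ConnectednessResult:
    """Null-corrected connectedness of every taxon.

    Observed pairwise Pearson correlations are computed on relative
    abundances; the null re-permutes each taxon's vector across samples
    independently per iteration. Corrected r = r_obs - mean(r_null).
    c_plus is the mean of a taxon's positive corrected correlations
    (0 if none), c_minus the mean of its negative ones.
    """
    if reltable.kind != "relative":
        raise ValueError("connectedness expects relative abundances")
    x = reltable.values()
    t, n = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("zero-variance taxa get zero connectedness: %s",
                    [reltable.taxon_ids[i] for i in np.flatnonzero(zero_var)])

    def _corr(m: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(m)
        r = np.asarray(r, dtype=float)
        r[np.isnan(r)] = 0.0
        return r

    r_obs = _corr(x)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(r_obs)
    for _ in range(null_reps):
        shuf = np.empty_like(x)
        for i in range(t):
            shuf[i] = x[i, rng.permutation(n)]
        null_sum += _corr(shuf)
    corrected = r_obs - null_sum / null_reps
    np.fill_diagonal(corrected, 0.0)
    corrected[zero_var, :] = 0.0
    corrected[:, zero_var] = 0.0
    c_plus = np.zeros(t)
    c_minus = np.zeros(t)
    for i in range(t):
        row = np.delete(corrected[i], i)
        pos = row[row > 0]
        neg = row[row < 0]
        c_plus[i] = pos.mean() if pos.size else 0.0
        c_minus[i] = neg.mean() if neg.size else 0.0
    return ConnectednessResult(reltable.taxon_ids, c_plus, c_minus, corrected)


def cohesion(reltable: AbundanceTable, conn: ConnectednessResult
             ) -> pd.DataFrame:
    """Per-sample positive and negative cohesion.

    C+_i = sum_j a_ij * c+_j and C-_i = sum_j a_ij * c-_j, with a_ij the
    relative abundance of taxon j in sample i. Returns a DataFrame indexed
    by sample with columns ``positive`` and ``negative``.
    """
    if reltable.kind != "relative":
        raise ValueError("cohesion expects relative abundances")
    if list(reltable.taxon_ids) != list(conn.taxon_ids):
        raise ValueError("taxa in table and connectedness result differ")
    a = reltable.values()   # taxa x samples
    out = pd.DataFrame({
        "positive": a.T @ conn.c_plus,
        "negative": a.T @ conn.c_minus,
    }, index=reltable.sample_ids)
    out.index.name = "sample_id"
    return out


def compare_stability(group_a, group_b, equal_var: bool = True
                      ) -> tuple[float, float]:
    """Two-sample Student's t-test (Welch optional) on stability values.

    Returns (t, two-sided p). Zero pooled variance with equal means gives
    t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
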