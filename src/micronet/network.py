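"""Correlation network inference with RMT-based threshold selection.

The co-occurrence graph is built from pairwise Pearson correlations of
log-transformed abundances. The edge cut-off is chosen by a random matrix
theory criterion: as the threshold rises, the nearest-neighbour spacing
distribution (NNSD) of the thresholded matrix's unfolded eigenvalues
transitions from Gaussian-orthogonal-ensemble (Wigner surmise) behaviour,
typical of correlated noise, to Poisson behaviour, typical of a system of
uncoupled modules. The selected threshold is the smallest grid value whose
spacing histogram is statistically consistent with Poisson and closer to
Poisson than to GOE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .io import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    taxon_ids: list
    matrix: np.ndarray
    zero_variance_taxa: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxon_ids,
                            columns=self.taxon_ids)


@dataclass
class NNSDResult:
    """Spacing histogram of unfolded eigenvalues with goodness-of-fit stats."""

    spacings: np.ndarray
    hist: np.ndarray
    bin_edges: np.ndarray
    chi2_poisson: float
    chi2_goe: float
    p_poisson: float
    n_eigenvalues: int


@dataclass
class RMTScanResult:
    """Per-threshold NNSD statistics and the selected cut-off.

    ``scan`` has one row per grid threshold with columns
    (threshold, nodes, chi2_poisson, chi2_goe, p_poisson).
    ``reliable`` is False when no threshold met the Poisson criterion or the
    surviving spectrum was smaller than ``min_eigs`` everywhere.
    """

    scan: pd.DataFrame
    selected_threshold: float
    reliable: bool


def pearson_matrix(logtable: pd.DataFrame | AbundanceTable) -> CorrelationResult:
    """Pairwise Pearson correlations between taxa (rows) across samples.

    Zero-variance taxa get r = 0 off-diagonal (they cannot enter a network)
    and are reported in ``zero_variance_taxa``.
    """
    df = logtable.data if isinstance(logtable, AbundanceTable) else logtable
    if df.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.asarray(r, dtype=float)
    r[np.isnan(r)] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    np.fill_diagonal(r, 1.0)
    if zero_var.size:
        logger.info("zero-variance taxa excluded from correlations: %s",
                    [df.index[i] for i in zero_var])
    return CorrelationResult(df.index.tolist(), r,
                             [df.index[i] for i in zero_var])


def _unfold(eigenvalues: np.ndarray, n_knots: int | None = None) -> np.ndarray:
    """Map eigenvalues through a smoothed empirical spectral CDF.

    A monotone piecewise-cubic (PCHIP) curve is fitted to a thinned set of
    knots on the cumulative spectral staircase; evaluating it at every
    eigenvalue yields an unfolded spectrum with near-uniform local density.
    The knot count scales as ~n/20 (capped at 25): the curve must track only
    the global eigenvalue density, not local fluctuations, or the spacing
    statistics are destroyed.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    uniq, counts = np.unique(lam, return_counts=True)
    cum = np.cumsum(counts).astype(float)
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct eigenvalues to unfold")
    if n_knots is None:
        n_knots = int(np.clip(lam.size // 20, 4, 25))
    k = min(n_knots, uniq.size)
    idx = np.unique(np.linspace(0, uniq.size - 1, k).round().astype(int))
    fit = PchipInterpolator(uniq[idx], cum[idx])
    return fit(lam)


def nnsd(eigenvalues, bins: int = 20, support: float = 3.0,
         n_knots: int | None = None) -> NNSDResult:
    """Nearest-neighbour spacing distribution of an unfolded spectrum.

    Spacings are normalized to unit mean, histogrammed on [0, ``support``]
    with ``bins`` equal bins, and compared by chi-square against the Poisson
    law P(d)=exp(-d) and the GOE Wigner surmise
    P(d)=(pi d/2) exp(-pi d^2/4), each truncated and renormalized to the
    histogram support.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if lam.size < 3:
        raise ValueError("need at least 3 eigenvalues")
    unfolded = _unfold(lam, n_knots=n_knots)
    d = np.diff(unfolded)
    mean = d.mean()
    if mean <= 0:
        raise ValueError("degenerate spectrum: zero mean spacing")
    d = d / mean
    edges = np.linspace(0.0, support, bins + 1)
    hist, _ = np.histogram(d, bins=edges)
    n_in = hist.sum()
    if n_in == 0:
        raise ValueError("no spacings inside the histogram support")

    def _chi2(cdf) -> tuple[float, int]:
        # pool adjacent bins (right to left) to expected counts >= 5 so the
        # chi-square null approximation stays valid for small spectra
        probs = np.diff(cdf(edges)) / cdf(np.array([support]))[0]
        expected = n_in * probs
        obs_pooled, exp_pooled = [], []
        o_acc = e_acc = 0.0
        for o, e in zip(hist[::-1], expected[::-1]):
            o_acc += o
            e_acc += e
            if e_acc >= 5.0:
                obs_pooled.append(o_acc)
                exp_pooled.append(e_acc)
                o_acc = e_acc = 0.0
        if e_acc > 0 or not exp_pooled:
            if exp_pooled:
                obs_pooled[-1] += o_acc
                exp_pooled[-1] += e_acc
            else:
                obs_pooled, exp_pooled = [o_acc], [e_acc]
        o = np.asarray(obs_pooled)
        e = np.asarray(exp_pooled)
        stat = float((((o - e) ** 2) / e).sum())
        return stat, len(e)

    poisson_cdf = lambda x: 1.0 - np.exp(-x)
    goe_cdf = lambda x: 1.0 - np.exp(-np.pi * np.asarray(x) ** 2 / 4.0)
    chi2_p, k_p = _chi2(poisson_cdf)
    chi2_g, _ = _chi2(goe_cdf)
    p_poisson = float(stats.chi2.sf(chi2_p, df=max(k_p - 1, 1)))
    return NNSDResult(d, hist, edges, chi2_p, chi2_g, p_poisson, lam.size)


def _threshold_matrix(r: np.ndarray, s: float) -> np.ndarray | None:
    """Zero sub-threshold entries, drop empty rows/cols; None if nothing survives."""
    a = np.where(np.abs(r) >= s, r, 0.0)
    np.fill_diagonal(a, 0.0)
    keep = np.flatnonzero((a != 0).any(axis=1))
    if keep.size == 0:
        return None
    a = a[np.ix_(keep, keep)]
    np.fill_diagonal(a, 1.0)
    return a


def select_threshold(corr: CorrelationResult,
                     grid=None,
                     min_eigs: int = 50,
                     bins: int = 20,
                     support: float = 3.0,
                     p_cut: float = 0.05,
                     strong_cut: float = 1e-3) -> RMTScanResult:
    """Scan candidate cut-offs and pick the RMT transition threshold.

    For each grid value s the correlation matrix is hard-thresholded at
    |r| >= s, empty rows/columns dropped, and the surviving spectrum's NNSD
    computed. Candidate thresholds are those above the last *strong*
    Poisson rejection (p < ``strong_cut``): with far more taxa than
    samples, sparse sub-percolation noise produces a spurious
    Poisson-consistent window below the correlated bulk's rejection hump,
    so the transition must be located after the spectrum last shows
    strongly non-Poisson statistics. Among candidates the selected
    threshold is the smallest s with Poisson goodness-of-fit p > ``p_cut``,
    GOE chi-square above Poisson chi-square, and at least ``min_eigs``
    surviving nodes. If none qualifies, the candidate minimizing the
    Poisson chi-square is returned with ``reliable=False``.
    """
    if grid is None:
        grid = np.round(np.arange(0.30, 0.95 + 1e-9, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    rows = []
    for s in grid:
        a = _threshold_matrix(corr.matrix, s)
        if a is None or a.shape[0] < 3:
            rows.append((s, 0 if a is None else a.shape[0],
                         np.nan, np.nan, np.nan))
            continue
        eigs = np.linalg.eigvalsh(a)
        try:
            res = nnsd(eigs, bins=bins, support=support)
        except ValueError:
            rows.append((s, a.shape[0], np.nan, np.nan, np.nan))
            continue
        rows.append((s, a.shape[0], res.chi2_poisson, res.chi2_goe,
                     res.p_poisson))
    scan = pd.DataFrame(rows, columns=["threshold", "nodes", "chi2_poisson",
                                       "chi2_goe", "p_poisson"])
    computable = scan["chi2_poisson"].notna()
    if not computable.any():
        logger.warning("no threshold left a usable spectrum; scan degenerate")
        return RMTScanResult(scan, float(grid[-1]), False)
    strong = computable & (scan["p_poisson"] < strong_cut)
    candidate = computable.copy()
    if strong.any():
        candidate &= scan.index > strong[strong].index[-1]
    if not candidate.any():
        logger.warning("entire grid strongly non-Poisson; scan degenerate")
        return RMTScanResult(scan, float(grid[-1]), False)
    ok = (candidate
          & (scan["p_poisson"] > p_cut)
          & (scan["chi2_goe"] > scan["chi2_poisson"])
          & (scan["nodes"] >= min_eigs))
    if ok.any():
        return RMTScanResult(scan, float(scan.loc[ok.idxmax(), "threshold"]),
                             True)
    sel = float(scan.loc[scan.loc[candidate, "chi2_poisson"].idxmin(),
                         "threshold"])
    logger.warning("no candidate threshold met the Poisson criterion; "
                   "returning chi2-minimizing threshold %.2f (degraded)", sel)
    return RMTScanResult(scan, sel, False)


def build_network(corr: CorrelationResult, threshold: float,
                  abundances: pd.Series | dict | None = None) -> nx.Graph:
    """Build the co-occurrence graph at a fixed cut-off.

    Edge (i, j) exists iff i != j and |r_ij| >= threshold; the signed r is
    stored as the ``correlation`` edge attribute. Isolated nodes are removed.
    ``abundances`` (mean relative abundance per taxon) becomes the
    ``abundance`` node attribute.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    r = corr.matrix
    ids = corr.taxon_ids
    g = nx.Graph()
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(r[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(ids[i], ids[j], correlation=float(r[i, j]))
    if abundances is not None:
        ab = pd.Series(abundances)
        for node in g.nodes:
            g.nodes[node]["abundance"] = float(ab.get(node, 0.0))
    return g
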