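"""Two-group and correlation statistics: Wilcoxon rank-sum with BH FDR,
Spearman screens against phenotypes, Bray-Curtis distances, and PERMANOVA."""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable

logger = logging.getLogger(__name__)

#: Largest combined sample size at which the exact rank-sum null is used
#: (ties force the tie-corrected normal approximation at any size).
EXACT_N_MAX = 12


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_test(x: np.ndarray, y: np.ndarray, exact_n_max: int = EXACT_N_MAX
                   ) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact two-sided p when the combined n <= ``exact_n_max`` and there are
    no ties; otherwise normal approximation with tie and continuity
    correction. Constant pooled data gives p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_n_max and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_fdr(table: pd.DataFrame | AbundanceTable, groups: pd.Series,
                 exact_n_max: int = EXACT_N_MAX) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum test with BH adjustment across features.

    ``table`` holds features in rows and samples in columns; ``groups`` maps
    sample id to one of exactly two labels. Returns a DataFrame with
    statistic, p and padj per feature.
    """
    df = table.data if isinstance(table, AbundanceTable) else table
    groups = pd.Series(groups)
    labels = pd.unique(groups.loc[df.columns])
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    a_cols = [s for s in df.columns if groups[s] == labels[0]]
    b_cols = [s for s in df.columns if groups[s] == labels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for feat in df.index:
        u, p = _rank_sum_test(df.loc[feat, a_cols].to_numpy(dtype=float),
                              df.loc[feat, b_cols].to_numpy(dtype=float),
                              exact_n_max)
        rows.append({"feature": feat, "statistic": u, "p": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def spearman_screen(features: pd.DataFrame | AbundanceTable,
                    phenotype: pd.Series,
                    min_prevalence: float = 0.5) -> pd.DataFrame:
    """Spearman correlation of each feature against a phenotype.

    Features present (nonzero) in fewer than ``min_prevalence`` of the
    samples are gated out before testing; samples with a missing phenotype
    are dropped pairwise; constant vectors are flagged and excluded from the
    returned table. Both raw p and BH-adjusted p are reported.
    """
    df = features.data if isinstance(features, AbundanceTable) else features
    phenotype = pd.Series(phenotype).reindex(df.columns)
    ok = phenotype.notna()
    if ok.sum() < 4:
        raise ValueError("need at least 4 paired observations")
    df = df.loc[:, ok]
    y = phenotype[ok].to_numpy(dtype=float)
    n = df.shape[1]
    prevalent = (df > 0).sum(axis=1) >= min_prevalence * n - 1e-9
    rows = []
    skipped = []
    for feat in df.index[prevalent]:
        x = df.loc[feat].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            skipped.append(feat)
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"feature": feat, "rho": float(rho), "p": float(p)})
    if skipped:
        logger.warning("excluded constant features: %s", skipped)
    out = pd.DataFrame(rows, columns=["feature", "rho", "p"]).set_index("feature")
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples."""
    x = table.values().T  # samples x taxa
    zero = np.flatnonzero(x.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample(s) make Bray-Curtis undefined: "
            f"{[table.sample_ids[i] for i in zero]}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's PERMANOVA pseudo-F from squared distances and labels."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, groups: pd.Series,
              permutations: int | str = 1000, seed: int = 0) -> dict:
    """One-way PERMANOVA on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (B + 1) under uniform label permutations.
    ``permutations="exact"`` enumerates every distinct assignment of samples
    to group sizes (feasible only for small n); p is then the exact fraction
    of assignments with F >= F_obs.
    """
    groups = pd.Series(groups).reindex(dm.ids)
    if groups.isna().any():
        raise ValueError("groups missing for some distance-matrix samples")
    labels = groups.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("singleton group")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels)
    n = len(labels)
    if permutations == "exact":
        if len(uniq) != 2:
            raise ValueError("exact enumeration implemented for two groups")
        n_a = counts[0]
        ge = 0
        total = 0
        for combo in itertools.combinations(range(n), int(n_a)):
            perm = np.full(n, uniq[1], dtype=object)
            perm[list(combo)] = uniq[0]
            total += 1
            if _pseudo_f(d2, perm) >= f_obs - 1e-12:
                ge += 1
        return {"pseudo_F": float(f_obs), "p": ge / total,
                "n_permutations": total}
    rng = np.random.default_rng(seed)
    b = int(permutations)
    ge = 0
    for _ in range(b):
        perm = labels[rng.permutation(n)]
        if _pseudo_f(d2, perm) >= f_obs - 1e-12:
            ge += 1
    return {"pseudo_F": float(f_obs), "p": (1 + ge) / (b + 1),
            "n_permutations": b}
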