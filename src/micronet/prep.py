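"""Post-denoising community preprocessing.

Prevalence filtering, rarefaction without replacement, relative abundance,
pseudocount log transform, and per-sample alpha diversity (Shannon, Chao1,
Good's coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _alpha

from .io import AbundanceTable

logger = logging.getLogger(__name__)

#: Rarefaction depth used throughout the study design this package emulates.
DEFAULT_RAREFACTION_DEPTH = 8509


@dataclass
class PrepParams:
    """Preprocessing knobs.

    prevalence_fraction : minimum fraction of samples a taxon must be
        detected in (inclusive boundary), default one third.
    rarefaction_depth : common subsampling depth; samples with fewer total
        reads are dropped.
    pseudocount_rule : "half_min_nonzero" (half the smallest nonzero relative
        abundance in the whole table) or a fixed float.
    """

    prevalence_fraction: float = 1.0 / 3.0
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    pseudocount_rule: object = "half_min_nonzero"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_fraction <= 1:
            raise ValueError("prevalence_fraction must be in (0, 1]")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")


def prevalence_filter(table: AbundanceTable, fraction: float = 1.0 / 3.0
                      ) -> AbundanceTable:
    """Keep taxa detected (count > 0) in at least ``fraction`` of samples.

    The boundary is inclusive: with 24 samples and fraction 1/3, presence in
    exactly 8 samples is retained.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = table.shape[1]
    present = (table.data > 0).sum(axis=1)
    # tolerance so that 8 >= 24 * (1/3) holds despite binary float fraction
    keep = present >= fraction * n - 1e-9
    return AbundanceTable(table.data.loc[keep].copy(), table.kind)


def rarefy(table: AbundanceTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning (QIIME2 convention). Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if table.kind != "counts":
        raise ValueError("rarefaction requires a counts table")
    rng = np.random.default_rng(seed)
    counts = np.rint(table.values()).astype(np.int64)
    out = {}
    for j, sample in enumerate(table.sample_ids):
        total = counts[:, j].sum()
        if total < depth:
            logger.warning("dropping sample %s: total %d < depth %d",
                           sample, total, depth)
            continue
        if total == depth:
            out[sample] = counts[:, j]
        else:
            out[sample] = rng.multivariate_hypergeometric(counts[:, j], depth)
    df = pd.DataFrame(out, index=table.taxon_ids)
    return AbundanceTable(df, kind="counts")


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to relative abundances (columns sum to 1)."""
    if table.kind == "relative":
        return table
    totals = table.data.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[(totals <= 0).argmax()]
        raise ValueError(f"sample {bad!r} has zero total count")
    return AbundanceTable(table.data / totals, kind="relative")


def log_transform(table: AbundanceTable, pseudocount: object = "half_min_nonzero"
                  ) -> AbundanceTable:
    """Natural log of (relative abundance + pseudocount).

    The default pseudocount is half the smallest nonzero relative abundance
    in the whole table, so zeros map strictly below every observed value and
    the rule is table-scale invariant. Returns a bare DataFrame (log values
    are negative, so the AbundanceTable non-negativity contract no longer
    applies).
    """
    if table.kind != "relative":
        raise ValueError("log_transform expects a relative-abundance table")
    values = table.values()
    if pseudocount == "half_min_nonzero":
        nz = values[values > 0]
        if nz.size == 0:
            raise ValueError("table has no nonzero entries")
        eps = 0.5 * nz.min()
    else:
        eps = float(pseudocount)
        if eps <= 0:
            raise ValueError("pseudocount must be positive")
    return pd.DataFrame(np.log(values + eps), index=table.taxon_ids,
                        columns=table.sample_ids)


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    return x


def shannon(counts, base: float = np.e) -> float:
    """Shannon diversity, -sum(p ln p), natural-log units by default."""
    x = _as_counts(counts)
    if x.sum() <= 0:
        raise ValueError("all-zero sample")
    return float(_alpha.shannon(np.rint(x).astype(np.int64), base=base))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1)/(2(F2+1))."""
    x = _as_counts(counts)
    if not np.allclose(x, np.rint(x)):
        raise ValueError("chao1 requires integer counts")
    return float(_alpha.chao1(x.astype(np.int64), bias_corrected=True))


def goods_coverage(counts) -> float:
    """Good's coverage, 1 - singletons/reads."""
    x = _as_counts(counts)
    if x.sum() <= 0:
        raise ValueError("empty sample")
    if not np.allclose(x, np.rint(x)):
        raise ValueError("goods_coverage requires integer counts")
    return float(_alpha.goods_coverage(x.astype(np.int64)))


def alpha_diversity(table: AbundanceTable, base: float = np.e) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and Good's coverage as a DataFrame."""
    if table.kind != "counts":
        raise ValueError("alpha diversity requires a counts table")
    rows = {}
    for sample in table.sample_ids:
        c = table.data[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(c, base=base),
            "chao1": chao1(c),
            "goods_coverage": goods_coverage(c),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
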