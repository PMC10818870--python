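"""Synthetic two-group community data with planted, recoverable structure.

Emulates a post-denoising ASV study: two groups of samples (default 12 + 12,
labelled LFS/HFS), compositional counts with a log-normal-like abundance
spread, planted positively-correlated taxon blocks, planted differential and
presence/absence taxa, and phenotype vectors built from chosen taxa.

The latent model is a multivariate Gaussian on the log scale with
exchangeable within-block correlation; log-abundances are softmax-closed to
a composition and counts realized by multinomial sampling at a per-sample
log-normal depth. Structural zeros are applied by masking after count
realization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import AbundanceTable


@dataclass
class SyntheticDesign:
    """Study-design knobs for the generator.

    Defaults mirror the emulated study: 12 samples per group and a
    sequencing-depth spread of 15623 +- 2217 reads; 300 taxa is the order of
    the networks' node counts.
    """

    n_per_group: int = 12
    n_taxa: int = 300
    n_blocks: int = 6
    block_size: int = 10
    block_rho: float = 0.8
    n_diff_taxa: int = 10
    effect_log2fc: float = 2.0
    n_absent_taxa: int = 2
    depth_mean: float = 15623.0
    depth_sd: float = 2217.0
    seed: int = 0
    group_labels: tuple = ("LFS", "HFS")
    base_log_sd: float = 1.5      # spread of taxon mean log-abundances
    taxon_log_sd: float = 0.6     # per-sample latent log-abundance sd
    diff_base_log: float = 1.0    # mean baseline log-abundance of planted
                                  # differential taxa (kept above the
                                  # detection limit so the signal is
                                  # recoverable by design)
    min_depth: int = 1000         # truncation floor for sampled depths

    def __post_init__(self) -> None:
        if min(self.n_per_group, self.n_taxa, self.block_size) < 1 \
                or min(self.n_blocks, self.n_diff_taxa, self.n_absent_taxa) < 0:
            raise ValueError("counts must be non-negative (sizes >= 1)")
        if self.n_blocks * self.block_size > self.n_taxa:
            raise ValueError(
                f"infeasible design: {self.n_blocks} blocks of "
                f"{self.block_size} overlap within {self.n_taxa} taxa")
        if not 0 <= self.block_rho <= 1:
            raise ValueError("block_rho must be in [0, 1]")
        reserved = self.n_blocks * self.block_size
        if reserved + self.n_diff_taxa + self.n_absent_taxa > self.n_taxa:
            raise ValueError("blocks, differential and absent taxa overlap")


@dataclass
class SyntheticTruth:
    """Planted structure: what downstream stages should recover."""

    block_membership: dict = field(default_factory=dict)   # taxon -> block
    differential_taxa: dict = field(default_factory=dict)  # taxon -> +1/-1
    absent_taxa: list = field(default_factory=list)        # zero in group A
    phenotype_loadings: dict = field(default_factory=dict) # phen -> {taxon: coef}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_ids(design: SyntheticDesign) -> list:
    a, b = design.group_labels
    return ([f"{a}_{i + 1:02d}" for i in range(design.n_per_group)]
            + [f"{b}_{i + 1:02d}" for i in range(design.n_per_group)])


def sample_groups(design: SyntheticDesign) -> pd.Series:
    ids = _sample_ids(design)
    a, b = design.group_labels
    return pd.Series([a] * design.n_per_group + [b] * design.n_per_group,
                     index=ids, name="group")


def generate_counts(design: SyntheticDesign
                    ) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw a taxa x samples count table with the planted structure.

    Bit-identical under a fixed ``design.seed``. Absent taxa are zero in the
    first group and guaranteed present somewhere in the second.
    """
    rng = np.random.default_rng(design.seed)
    t, n = design.n_taxa, 2 * design.n_per_group
    taxa = [f"ASV_{i + 1:04d}" for i in range(t)]
    samples = _sample_ids(design)
    a_label, b_label = design.group_labels

    # taxon layout: blocks first, then differential, then absent, then noise
    block_members: dict = {}
    pos = 0
    for b in range(design.n_blocks):
        for _ in range(design.block_size):
            block_members[taxa[pos]] = b
            pos += 1
    diff_taxa = {taxa[pos + i]: (1 if i % 2 == 0 else -1)
                 for i in range(design.n_diff_taxa)}
    pos += design.n_diff_taxa
    absent = [taxa[pos + i] for i in range(design.n_absent_taxa)]
    pos += design.n_absent_taxa

    mu = rng.normal(0.0, design.base_log_sd, size=t)
    if diff_taxa:
        diff_idx = [taxa.index(x) for x in diff_taxa]
        mu[diff_idx] = rng.normal(design.diff_base_log, 0.5, len(diff_idx))
    # group-B mean shift for differential taxa (direction alternates)
    shift = np.zeros(t)
    for taxon, direction in diff_taxa.items():
        shift[taxa.index(taxon)] = direction * design.effect_log2fc * np.log(2)

    # latent log-abundances: independent normals plus a shared block factor
    # gives exchangeable within-block correlation rho
    z = rng.normal(0.0, 1.0, size=(t, n))
    if design.block_rho > 0:
        rho = design.block_rho
        shared = rng.normal(0.0, 1.0, size=(design.n_blocks, n))
        for i, taxon in enumerate(taxa):
            if taxon in block_members:
                b = block_members[taxon]
                z[i] = np.sqrt(rho) * shared[b] + np.sqrt(1 - rho) * z[i]
    latent = mu[:, None] + design.taxon_log_sd * z
    latent[:, design.n_per_group:] += shift[:, None]

    # softmax closure to a composition, then multinomial counts per sample
    comp = np.exp(latent - latent.max(axis=0))
    comp /= comp.sum(axis=0)
    depths = np.maximum(
        rng.lognormal(mean=_lognormal_mu(design), sigma=_lognormal_sigma(design),
                      size=n),
        design.min_depth).astype(np.int64)
    counts = np.empty((t, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(depths[j], comp[:, j])

    # structural zeros: masked in group A after realization; ensure presence
    # in group B so the planted absence is detectable
    for taxon in absent:
        i = taxa.index(taxon)
        counts[i, :design.n_per_group] = 0
        if counts[i, design.n_per_group:].sum() == 0:
            j = design.n_per_group + int(rng.integers(design.n_per_group))
            counts[i, j] = 1

    table = AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples),
                           kind="counts")
    loadings = {}
    if diff_taxa:
        first = next(iter(diff_taxa))
        loadings["fecal_water_content"] = {first: 1.0}
    truth = SyntheticTruth(block_membership=block_members,
                           differential_taxa=diff_taxa,
                           absent_taxa=absent,
                           phenotype_loadings=loadings)
    return table, truth


def _lognormal_mu(design: SyntheticDesign) -> float:
    m, s = design.depth_mean, design.depth_sd
    return float(np.log(m ** 2 / np.sqrt(m ** 2 + s ** 2)))


def _lognormal_sigma(design: SyntheticDesign) -> float:
    m, s = design.depth_mean, design.depth_sd
    return float(np.sqrt(np.log(1 + (s / m) ** 2)))


def generate_phenotypes(table: AbundanceTable, truth: SyntheticTruth,
                        noise_sd: float = 0.1, seed: int = 0,
                        design: SyntheticDesign | None = None) -> pd.DataFrame:
    """Build sample metadata with phenotypes from the truth's loadings.

    Each phenotype is a linear combination of the loaded taxa's relative
    abundances plus Gaussian noise. Group labels are parsed from the sample
    naming scheme (``<group>_<number>``) used by :func:`generate_counts`.
    """
    for phen, loads in truth.phenotype_loadings.items():
        unknown = [t for t in loads if t not in table.taxon_ids]
        if unknown:
            raise ValueError(f"loadings reference unknown taxa: {unknown}")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=0)
    rel = table.data / totals.replace(0, np.nan)
    meta = pd.DataFrame(index=table.sample_ids)
    meta.index.name = "sample_id"
    meta["group"] = [s.rsplit("_", 1)[0] for s in table.sample_ids]
    for phen, loads in truth.phenotype_loadings.items():
        value = np.zeros(table.shape[1])
        for taxon, coef in loads.items():
            value += coef * rel.loc[taxon].fillna(0.0).to_numpy()
        meta[phen] = value + rng.normal(0.0, noise_sd, size=len(value))
    return meta


def generate_attd_inputs(seed: int = 0, n_records: int = 10) -> pd.DataFrame:
    """Marker/nutrient concentration records with known true digestibility.

    Built by algebraic inversion: a true ATTD and a fecal marker
    concentration factor k >= 1 are drawn, then Nf is set so that the
    marker-ratio formula recovers the chosen ATTD exactly. Columns:
    nutrient, Ad, Af, Nd, Nf, true_attd.
    """
    rng = np.random.default_rng(seed)
    nutrients = ["OM", "NDF", "ADF", "EE", "CP"]
    rows = []
    for i in range(n_records):
        true_attd = rng.uniform(30.0, 90.0)
        ad = rng.uniform(5.0, 15.0)
        k = rng.uniform(1.5, 4.0)   # marker concentrates in feces
        af = ad * k
        nd = rng.uniform(100.0, 600.0)
        nf = nd * k * (1.0 - true_attd / 100.0)
        rows.append({"nutrient": nutrients[i % len(nutrients)],
                     "Ad": ad, "Af": af, "Nd": nd, "Nf": nf,
                     "true_attd": true_attd})
    return pd.DataFrame(rows)
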