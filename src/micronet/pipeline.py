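"""End-to-end pipeline: simulate/load -> prep -> per-group networks ->
topology -> stability -> cohesion -> group statistics, driven by one config.

Every stage writes TSV/JSON artifacts to the output directory; a manifest
records parameters, per-stage seeds and a sha256 checksum of every output
file. Per-group networks are built from that group's samples only, with the
prevalence filter re-applied within each group.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .io import AbundanceTable
from .prep import PrepParams, prevalence_filter, rarefy, relative_abundance, \
    log_transform, alpha_diversity
from .network import pearson_matrix, select_threshold, build_network
from .topology import topology_summary, detect_modules, zipi
from .stability import RobustnessParams, robustness_random, \
    robustness_targeted, connectedness, cohesion, compare_stability
from .stats import wilcoxon_fdr, spearman_screen, bray_curtis, permanova
from .synthetic import SyntheticDesign, generate_counts, generate_phenotypes

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the global seed
_STAGE_OFFSETS = {"simulate": 0, "prep": 101, "network": 211,
                  "stability": 307, "cohesion": 401, "stats": 503}

_STAGES = ("simulate", "prep", "network", "topology", "stability",
           "cohesion", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat, YAML-serializable pipeline configuration.

    Either ``counts_path``/``metadata_path`` point at input TSVs, or
    ``simulate`` carries :class:`SyntheticDesign` keyword overrides.
    """

    outdir: str = "micronet_out"
    seed: int = 0
    counts_path: str | None = None
    metadata_path: str | None = None
    simulate: dict | None = field(default_factory=dict)
    group_column: str = "group"
    prep: dict = field(default_factory=dict)        # PrepParams overrides
    network: dict = field(default_factory=dict)     # select_threshold kwargs
    robustness: dict = field(default_factory=dict)  # RobustnessParams overrides
    cohesion_null_reps: int = 200
    permanova_permutations: int = 1000
    phenotypes: list = field(default_factory=list)  # columns to Spearman-screen

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        PrepParams(**self.prep)
        RobustnessParams(**self.robustness)
        if self.simulate is not None:
            SyntheticDesign(**{**self.simulate, "seed": 0})
        elif not self.counts_path or not self.metadata_path:
            raise ValueError("need counts_path and metadata_path, or simulate")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage. Reruns with the same config are byte-identical.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "params": asdict(config), "outputs": {}}
    results: dict = {}

    def _done(stage, **artifacts):
        logger.info("[%s] complete", stage)
        manifest["stages"].append(stage)
        for name, path in artifacts.items():
            manifest["outputs"][name] = {"path": str(path),
                                         "sha256": _sha256(Path(path))}

    # --- simulate or load ------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate is not None:
            design = SyntheticDesign(**{"seed": config.seed
                                        + _STAGE_OFFSETS["simulate"],
                                        **config.simulate})
            counts, truth = generate_counts(design)
            metadata = generate_phenotypes(
                counts, truth, seed=design.seed + 1, design=design)
            cp, mp, tp = (outdir / "counts.tsv", outdir / "metadata.tsv",
                          outdir / "truth.json")
            mio.write_abundance_table(counts, cp)
            mio.write_metadata(metadata, mp)
            truth.to_json(tp)
            _done(stage, counts=cp, metadata=mp, truth=tp)
        else:
            counts = mio.read_abundance_table(config.counts_path)
            metadata = mio.read_metadata(config.metadata_path)
            _done(stage)
    except Exception as exc:      # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    groups = metadata[config.group_column]
    group_labels = list(pd.unique(groups))

    # --- prep -------------------------------------------------------------
    stage = "prep"
    try:
        prep_params = PrepParams(**{"seed": config.seed + _STAGE_OFFSETS["prep"],
                                    **config.prep})
        rare = rarefy(counts, prep_params.rarefaction_depth, prep_params.seed)
        if rare.shape[1] < 4:
            raise ValueError(
                f"rarefaction at depth {prep_params.rarefaction_depth} kept "
                f"only {rare.shape[1]} samples")
        filtered = prevalence_filter(rare, prep_params.prevalence_fraction)
        alpha = alpha_diversity(rare)
        fp, ap = outdir / "filtered_counts.tsv", outdir / "alpha_diversity.tsv"
        mio.write_abundance_table(filtered, fp)
        alpha.to_csv(ap, sep="\t")
        _done(stage, filtered_counts=fp, alpha_diversity=ap)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- per-group networks ----------------------------------------------
    nets, zipis, scans = {}, {}, {}
    stage = "network"
    try:
        net_artifacts = {}
        for label in group_labels:
            samples = [s for s in filtered.sample_ids if groups.get(s) == label]
            sub = prevalence_filter(
                AbundanceTable(rare.data.loc[:, samples].copy(), "counts"),
                prep_params.prevalence_fraction)
            rel = relative_abundance(sub)
            logt = log_transform(rel, prep_params.pseudocount_rule)
            corr = pearson_matrix(logt)
            scan = select_threshold(corr, **config.network)
            net = build_network(corr, scan.selected_threshold,
                                abundances=rel.data.mean(axis=1))
            nets[label], scans[label] = net, scan
            sp = outdir / f"rmt_scan_{label}.tsv"
            scan.scan.to_csv(sp, sep="\t", index=False)
            np_ = outdir / f"network_{label}.graphml"
            gp = outdir / f"edges_{label}.tsv"
            net_artifacts[f"rmt_scan_{label}"] = sp
            if net.number_of_nodes():
                mio.write_network(net, np_, "graphml")
                mio.write_network(net, gp, "edgelist_tsv")
                net_artifacts.update({f"network_{label}": np_,
                                      f"edges_{label}": gp})
            results.setdefault("network", {})[label] = {
                "threshold": scan.selected_threshold,
                "reliable": scan.reliable,
                "nodes": net.number_of_nodes(),
                "edges": net.number_of_edges(),
            }
        _done(stage, **net_artifacts)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- topology ----------------------------------------------------------
    stage = "topology"
    try:
        topo_rows = []
        for label, net in nets.items():
            if net.number_of_nodes() == 0:
                logger.warning("[topology] empty network for %s", label)
                continue
            summary = topology_summary(net)
            partition, q = detect_modules(net, seed=config.seed)
            zt = zipi(net, partition)
            zipis[label] = zt
            zt.to_csv(outdir / f"zipi_{label}.tsv", sep="\t")
            row = asdict(summary)
            row.update({"group": label, "modularity": q,
                        "module_count": len(set(partition.values()))})
            topo_rows.append(row)
        topo = pd.DataFrame(topo_rows)
        tp = outdir / "topology.tsv"
        topo.to_csv(tp, sep="\t", index=False)
        results["topology"] = topo_rows
        _done(stage, topology=tp)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stability ----------------------------------------------------------
    stage = "stability"
    try:
        rob_params = RobustnessParams(
            **{"seed": config.seed + _STAGE_OFFSETS["stability"],
               **config.robustness})
        rob_rows = []
        rob_values = {}
        for label, net in nets.items():
            if net.number_of_nodes() == 0 or label not in zipis:
                continue
            rnd = robustness_random(net, rob_params)
            tgt = robustness_targeted(net, zipis[label], rob_params)
            rob_values[label] = rnd.values
            rob_rows.append({"group": label,
                             "random_mean": rnd.mean, "random_sd": rnd.sd,
                             "targeted": tgt.mean,
                             "targeted_removed": ";".join(map(str, tgt.removed)),
                             "hub_fallback": tgt.fallback_used})
        rob = pd.DataFrame(rob_rows)
        if len(rob_values) == 2:
            a, b = (rob_values[label] for label in group_labels)
            t, p = compare_stability(a, b)
            results["robustness_ttest"] = {"t": t, "p": p}
        rp = outdir / "robustness.tsv"
        rob.to_csv(rp, sep="\t", index=False)
        results["robustness"] = rob_rows
        _done(stage, robustness=rp)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- cohesion -----------------------------------------------------------
    stage = "cohesion"
    try:
        rel_all = relative_abundance(filtered)
        conn = connectedness(rel_all, null_reps=config.cohesion_null_reps,
                             seed=config.seed + _STAGE_OFFSETS["cohesion"])
        coh = cohesion(rel_all, conn)
        coh["group"] = [groups.get(s) for s in coh.index]
        cp2 = outdir / "cohesion.tsv"
        coh.to_csv(cp2, sep="\t")
        if len(group_labels) == 2:
            a = coh[coh["group"] == group_labels[0]]
            b = coh[coh["group"] == group_labels[1]]
            results["cohesion_ttest"] = {
                "positive": dict(zip(("t", "p"),
                                     compare_stability(a["positive"],
                                                       b["positive"]))),
                "negative": dict(zip(("t", "p"),
                                     compare_stability(a["negative"],
                                                       b["negative"]))),
            }
        _done(stage, cohesion=cp2)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- group statistics ----------------------------------------------------
    stage = "stats"
    try:
        rel_all = relative_abundance(filtered)
        wt = wilcoxon_fdr(rel_all, groups)
        wp = outdir / "wilcoxon.tsv"
        wt.to_csv(wp, sep="\t")
        artifacts = {"wilcoxon": wp}
        dm = bray_curtis(rel_all)
        dmp = outdir / "bray_curtis.tsv"
        mio.write_distance_matrix(dm, dmp)
        perm = permanova(dm, groups, config.permanova_permutations,
                         seed=config.seed + _STAGE_OFFSETS["stats"])
        results["permanova"] = perm
        artifacts["bray_curtis"] = dmp
        for phen in config.phenotypes:
            if phen not in metadata.columns:
                raise ValueError(f"phenotype {phen!r} not in metadata")
            sc = spearman_screen(rel_all, metadata[phen])
            scp = outdir / f"spearman_{phen}.tsv"
            sc.to_csv(scp, sep="\t")
            artifacts[f"spearman_{phen}"] = scp
        _done(stage, **artifacts)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["results"] = results
    mp = outdir / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
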