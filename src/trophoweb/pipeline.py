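"""End-to-end workflow orchestration with manifests and determinism.

A :class:`RunConfig` either points at existing input files or requests a
simulated study, then enables a subset of stages.  Stages run in
dependency order; each writes TSV/JSON outputs plus a manifest entry
recording its parameters, input hashes and derived seed.  Re-running the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta, diversity, enterotype, io, network, neutral, simulate, trophic, unique

log = logging.getLogger("trophoweb")

ALL_STAGES = (
    "filter",
    "partition",
    "betadiv",
    "enterotype",
    "ncm",
    "trophic",
    "unique",
    "darknet",
)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    min_otu_total: int = 100
    rarefaction_depth: int = 13551
    n_permutations: int = 999
    bin_width: float = 3.4
    network_rank: str = "genus"
    network_threshold: float = 0.35
    n_bootstrap: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    report: dict = {"seed": config.seed, "stages": {}}
    failed: set[str] = set()

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest.append(
            {
                "stage": stage,
                "parameters": params,
                "seed": _stage_seed(config.seed, stage),
                "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
            }
        )

    t0 = time.time()
    # --- inputs ---------------------------------------------------------
    if config.simulate:
        sim_cfg = simulate.SimConfig(seed=_stage_seed(config.seed, "simulate"), **config.sim)
        table, taxonomy, meta, tree, truth = simulate.simulate_foodweb_dataset(sim_cfg)
        io.write_otu_table(table, out / "otu_table.tsv")
        io.write_taxonomy(taxonomy, out / "taxonomy.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_tree(tree, out / "tree.nwk")
        truth.to_json(out / "ground_truth.json")
        record(
            "simulate",
            {"config": {k: v for k, v in sim_cfg.__dict__.items() if k != "groups"}},
            [out / "otu_table.tsv", out / "taxonomy.tsv", out / "metadata.tsv", out / "tree.nwk"],
        )
    else:
        table = io.read_otu_table(config.table_path)
        taxonomy = io.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
        meta = io.read_metadata(config.metadata_path)
        tree = io.read_tree(config.tree_path) if config.tree_path else None

    # --- global filtering ----------------------------------------------
    if "filter" in config.stages:
        table = io.filter_low_count_otus(table, config.min_otu_total)
        table, discarded = io.rarefy(
            table, config.rarefaction_depth, _stage_seed(config.seed, "rarefy")
        )
        meta = io.SampleMetadata(meta.frame.loc[table.sample_ids].copy())
        io.write_otu_table(table, out / "otu_table.rarefied.tsv")
        report["stages"]["filter"] = {
            "n_samples": table.n_samples,
            "n_otus": table.n_otus,
            "discarded_samples": discarded,
        }
        record(
            "filter",
            {"min_otu_total": config.min_otu_total, "depth": config.rarefaction_depth},
            [out / "otu_table.rarefied.tsv"],
        )

    def try_stage(name, fn):
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as exc:  # independent stages continue
            log.error("stage %s failed: %s", name, exc)
            failed.add(name)
            report["stages"][name] = {"error": str(exc)}

    # --- diversity partitioning ----------------------------------------
    def _partition():
        part = diversity.additive_partition(
            table,
            meta,
            ["sample_type"],
            n_perm=config.n_permutations,
            seed=_stage_seed(config.seed, "partition"),
            scheme="individuals_and_groups",
        )
        part.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
        report["stages"]["partition"] = {"gamma": part.gamma}
        record("partition", {"n_perm": config.n_permutations}, [out / "partition.tsv"])

    try_stage("partition", _partition)

    # --- beta diversity --------------------------------------------------
    def _betadiv():
        dist = (
            beta.weighted_unifrac(table, tree)
            if tree is not None
            else beta.jaccard_distance(table)
        )
        dist.to_frame().to_csv(out / "distances.tsv", sep="\t")
        ord_res = beta.pcoa(dist)
        ord_res.coordinates.iloc[:, :5].to_csv(out / "pcoa.tsv", sep="\t")
        labels = meta.frame.loc[dist.sample_ids, "sample_type"]
        res = beta.permanova(
            dist, labels, n_perm=config.n_permutations, seed=_stage_seed(config.seed, "permanova")
        )
        report["stages"]["betadiv"] = {
            "metric": dist.metric,
            "pseudo_F": res.pseudo_F,
            "p_value": res.p_value,
            "df": res.df,
        }
        record("betadiv", {"n_perm": config.n_permutations}, [out / "distances.tsv", out / "pcoa.tsv"])

    try_stage("betadiv", _betadiv)

    # --- enterotypes -----------------------------------------------------
    def _enterotype():
        rows = []
        for g in sorted(meta.frame["sample_type"].unique()):
            if g == "soil":
                continue
            gids = [s for s in table.sample_ids if meta.group_of(s) == g]
            if len(gids) < 6:
                continue
            res = enterotype.enterotype_group(
                table.select_samples(gids), taxonomy, group=g,
                seed=_stage_seed(config.seed, f"enterotype:{g}"),
            )
            for sid, label in res.assignment.items():
                rows.append(dict(sample_id=sid, group=g, enterotype=label, k=res.k))
        pd.DataFrame(rows).to_csv(out / "enterotypes.tsv", sep="\t", index=False)
        report["stages"]["enterotype"] = {"n_assigned": len(rows)}
        record("enterotype", {}, [out / "enterotypes.tsv"])

    try_stage("enterotype", _enterotype)

    # --- neutral model ---------------------------------------------------
    def _ncm():
        rows = []
        for g in sorted(meta.frame["sample_type"].unique()):
            gids = [s for s in table.sample_ids if meta.group_of(s) == g]
            if len(gids) < 10:
                continue
            sub = table.select_samples(gids)
            try:
                fit = neutral.fit_sloan_table(sub)
            except ValueError as exc:
                log.warning("NCM fit skipped for %s: %s", g, exc)
                continue
            rows.append(
                dict(
                    group=g, m=fit.m, Nm=fit.Nm, r_squared=fit.r_squared,
                    aic_neutral=fit.aic_neutral, aic_binomial=fit.aic_binomial,
                    fraction_within=fit.fraction_within,
                    fraction_above=fit.fraction_above,
                    fraction_below=fit.fraction_below,
                )
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "ncm.tsv", sep="\t", index=False)
        report["stages"]["ncm"] = df.set_index("group")["Nm"].to_dict() if len(df) else {}
        record("ncm", {}, [out / "ncm.tsv"])

    try_stage("ncm", _ncm)

    # --- trophic levels --------------------------------------------------
    def _trophic():
        tl = trophic.assign_from_metadata(meta, bin_width=config.bin_width)
        tl.to_csv(out / "trophic.tsv", sep="\t")
        shannon_per_sample = pd.Series(
            [diversity.shannon(table.counts[i]) for i in range(table.n_samples)],
            index=table.sample_ids,
        )
        fauna = [s for s in tl.index if s in shannon_per_sample.index]
        reg = trophic.regress_vs_trophic(
            tl.loc[fauna, "delta15N_adjusted"], shannon_per_sample[fauna]
        )
        report["stages"]["trophic"] = {
            "n_levels": int(tl["trophic_level"].max()),
            "diversity_slope": reg.slope,
            "diversity_r2": reg.r_squared,
            "diversity_p": reg.p_value,
        }
        record("trophic", {"bin_width": config.bin_width}, [out / "trophic.tsv"])

    try_stage("trophic", _trophic)

    # --- unique taxa -----------------------------------------------------
    def _unique():
        rep = unique.unique_otus(table, meta)
        rep.per_sample_counts.to_csv(out / "unique_counts.tsv", sep="\t")
        summary = {g: len(s) for g, s in rep.by_group.items()}
        report["stages"]["unique"] = summary
        record("unique", {}, [out / "unique_counts.tsv"])

    try_stage("unique", _unique)

    # --- dark-matter network --------------------------------------------
    def _darknet():
        agg, flags = network.aggregate_to_rank(table, taxonomy, config.network_rank)
        net = network.build_network(
            agg, flags, threshold=config.network_threshold, rank=config.network_rank
        )
        cent = network.centralities(net.graph)
        cent["hub_score"] = network.hub_scores(net)
        cent["unknown"] = [net.unknown_flags[n] for n in cent.index]
        cent.to_csv(out / "network_nodes.tsv", sep="\t")
        edges = nx_edges_frame(net)
        edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        pert = network.perturb_and_compare(
            net, B=config.n_bootstrap, seed=_stage_seed(config.seed, "darknet")
        )
        comp = {
            m: {f"{a}__vs__{b}": p for (a, b), p in pv.items()}
            for m, pv in pert.wilcoxon_p.items()
        }
        (out / "network_comparison.json").write_text(json.dumps(comp, indent=1))
        report["stages"]["darknet"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "top50_unknown_fraction": network.top_hub_unknown_fraction(net),
        }
        record(
            "darknet",
            {"rank": config.network_rank, "threshold": config.network_threshold, "B": config.n_bootstrap},
            [out / "network_nodes.tsv", out / "network_edges.tsv"],
        )

    try_stage("darknet", _darknet)

    report["elapsed_seconds"] = round(time.time() - t0, 2)
    report["failed_stages"] = sorted(failed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def nx_edges_frame(net: network.NetworkModel) -> pd.DataFrame:
    rows = [
        dict(node_a=a, node_b=b, weight=d.get("weight", 1.0))
        for a, b, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
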