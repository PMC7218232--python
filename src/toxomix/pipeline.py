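"""End-to-end orchestration: simulate -> preprocess -> contrasts -> NPA ->
factor model -> sGCCA -> network assembly -> PCSF -> clustering -> enrichment
-> report.

All randomness derives from one global seed via named per-stage substreams,
so inserting a stage never perturbs the others and identical config+seed
yields identical outputs (the report manifest records a content hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffabund, enrich, factors, netbuild, npa, pcsf, syndata
from ._utils import ConfigError, stage_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "toxomix_out"
    syndata: dict = field(default_factory=dict)
    diffabund: dict = field(default_factory=dict)
    npa: dict = field(default_factory=lambda: {"n_perm": 500, "n_networks": 2})
    factors: dict = field(default_factory=lambda: {"k_init": 10, "tol": 1e-6, "max_iter": 300})
    sgcca: dict = field(default_factory=lambda: {"keep": 30, "ncomp": 2})
    pcsf: dict = field(default_factory=lambda: {"mu": 0.0005, "omega": 0.6, "beta": 1000.0,
                                                "ensemble_runs": 10, "noise": 0.1, "grid": True})
    enrich: dict = field(default_factory=lambda: {"n_perm": 1000})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown config key {k!r}")
            if isinstance(getattr(cfg, k), dict) and isinstance(v, dict):
                merged = dict(getattr(cfg, k))
                merged.update(v)
                setattr(cfg, k, merged)
            else:
                setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self) -> syndata.SimConfig:
        kw = dict(self.syndata)
        kw.pop("seed", None)
        cfg = syndata.SimConfig(seed=stage_seed(self.seed, "simulate"), **kw)
        cfg.validate()
        return cfg


def validate_config(path) -> list[str]:
    """Schema and cross-field checks; returns a list of problems (empty = clean)."""
    problems: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except Exception as exc:
        return [f"unreadable config: {exc}"]
    try:
        cfg = PipelineConfig.from_dict(raw)
    except ConfigError as exc:
        return [str(exc)]
    if not isinstance(cfg.seed, int):
        problems.append("seed must be an integer")
    dims = cfg.syndata.get("modality_dims")
    if dims is not None:
        for m in syndata.MODALITIES:
            if m not in dims:
                problems.append(f"missing modality dim: {m}")
        for m, d in dims.items():
            if m not in syndata.MODALITIES:
                problems.append(f"unknown modality: {m}")
            elif not isinstance(d, int) or d <= 0:
                problems.append(f"non-positive dimension for {m}")
    groups = cfg.syndata.get("groups")
    if groups is not None:
        unknown = set(groups) - set(syndata.GROUPS)
        if unknown:
            problems.append(f"unknown groups: {sorted(unknown)}")
    for key in ("mu", "omega", "beta", "noise"):
        v = cfg.pcsf.get(key)
        if v is not None and v < 0:
            problems.append(f"negative pcsf.{key}")
    if cfg.npa.get("n_perm", 500) < 100:
        problems.append("npa.n_perm must be >= 100")
    try:
        cfg.sim_config()
    except ConfigError as exc:
        problems.append(str(exc))
    return problems


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    diff_counts: pd.DataFrame
    rbif: pd.DataFrame
    fc_correlation: pd.DataFrame
    variance_explained: pd.DataFrame
    factor_scores: pd.DataFrame
    enrichment_mrna: pd.DataFrame
    enrichment_protein: pd.DataFrame
    ora: pd.DataFrame
    covariate_correlation: dict
    cluster_profiles: pd.DataFrame
    grid_curve: pd.DataFrame
    network: "netbuild.MultiLayerNetwork"
    clusters: "pcsf.ClusteredNetwork"
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "diff_counts": self.diff_counts,
            "rbif": self.rbif,
            "fc_correlation": self.fc_correlation,
            "variance_explained": self.variance_explained,
            "factor_scores": self.factor_scores,
            "enrichment_mrna": self.enrichment_mrna,
            "enrichment_protein": self.enrichment_protein,
            "ora": self.ora,
            "cluster_profiles": self.cluster_profiles,
            "grid_curve": self.grid_curve,
        }

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name, t in sorted(self.tables().items()):
            h.update(name.encode())
            h.update(t.round(10).to_csv().encode())
        h.update(json.dumps(self.covariate_correlation, sort_keys=True).encode())
        return h.hexdigest()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, t in self.tables().items():
            t.to_csv(out / f"{name}.tsv", sep="\t")
        self.network.write_graphml(out / "final_network.graphml")
        self.network.write_sif(out / "final_network.sif", out / "final_network_edges.tsv")
        manifest = dict(self.manifest)
        manifest["content_hash"] = self.content_hash()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, write: bool = False) -> ReportBundle:
    seed = config.seed
    status: dict[str, str] = {}

    # -- simulate ----------------------------------------------------------
    study = syndata.simulate_study(config.sim_config())
    status["simulate"] = "ok"

    # -- preprocess --------------------------------------------------------
    prepped = [diffabund.preprocess_layer(ly, study.sheet) for ly in study.layers]
    status["preprocess"] = "ok"

    # -- contrasts ---------------------------------------------------------
    groups = [g for g in study.config.groups if g != "Sham"]
    contrasts: list[diffabund.ContrastTable] = []
    for ly in prepped:
        for g in groups:
            for tp in study.config.timepoints:
                ct = diffabund.fit_contrast(ly, study.sheet, g, tp)
                if ct.status == "ok":
                    contrasts.append(ct)
    counts = diffabund.count_significant(contrasts)
    status["diffexp"] = "ok" if contrasts else "no_contrasts"

    # -- cross-modal fold-change correlation ------------------------------
    fc_rows = []
    mrna_ct = {(c.group, c.timepoint): c for c in contrasts if c.modality == "mrna"}
    prot_ct = {(c.group, c.timepoint): c for c in contrasts if c.modality == "protein"}
    mrna_ann = study.layer("mrna").annotations if "mrna" in [l.modality for l in study.layers] else None
    for key in sorted(set(mrna_ct) & set(prot_ct)):
        if key[0] != "3R4F":
            continue
        r2, slope, n = diffabund.crossmodal_fc_correlation(
            mrna_ct[key], prot_ct[key], ann_a=mrna_ann, ann_b=study.layer("protein").annotations
        )
        fc_rows.append({"group": key[0], "timepoint": key[1], "r2": r2, "slope": slope, "n_pairs": n})
    fc_table = pd.DataFrame(fc_rows)

    # -- causal network perturbation (mRNA) --------------------------------
    npa_cfg = config.npa
    rbif_table = pd.DataFrame()
    if mrna_ct:
        gene_key = study.layer("mrna").annotations["gene"]
        results: dict[str, dict[str, npa.NpaResult]] = {}
        for i in range(int(npa_cfg.get("n_networks", 2))):
            model, _ = syndata.simulate_causal_network(
                study,
                n_backbone=int(npa_cfg.get("n_backbone", 20)),
                genes_per_node=int(npa_cfg.get("genes_per_node", 25)),
                seed=stage_seed(seed, f"causal_network_{i}"),
            )
            per_net = {}
            for (g, tp), ct in sorted(mrna_ct.items()):
                res = npa.npa_score(
                    model, ct, n_perm=int(npa_cfg.get("n_perm", 500)),
                    seed=stage_seed(seed, f"npa_{i}_{g}_{tp}"), gene_key=gene_key,
                )
                per_net[f"{g}@{tp}m"] = res
            results[f"network_{i + 1}"] = per_net
        rbif_table = npa.bif_aggregate(results).table
    status["npa"] = "ok" if len(rbif_table) else "no_contrasts"

    # -- latent factor model ----------------------------------------------
    fp = config.factors
    fac = factors.fit_mofa(
        prepped, study.sheet, k_init=int(fp.get("k_init", 10)), tol=float(fp.get("tol", 1e-6)),
        max_iter=int(fp.get("max_iter", 300)), seed=stage_seed(seed, "factors"),
    )
    ve = fac.variance_explained()
    status["factors"] = "ok"

    # -- sGCCA cross-check -------------------------------------------------
    sg = config.sgcca
    try:
        sgc = factors.fit_sgcca(prepped, study.sheet, keep=int(sg.get("keep", 30)),
                                ncomp=int(sg.get("ncomp", 2)), seed=stage_seed(seed, "sgcca"))
        status["sgcca"] = "ok"
    except ValueError as exc:
        sgc = None
        status["sgcca"] = f"skipped:{exc}"

    # -- aggregated network ------------------------------------------------
    interactions = syndata.simulate_interactions(study, seed=stage_seed(seed, "interactions"))
    filtered = netbuild.filter_interactions(interactions)
    network = netbuild.assign_edge_weights(filtered)
    node_map, unmapped = netbuild.harmonize_ids(prepped, network)
    status["netbuild"] = "ok"

    # -- terminals, grid search, ensemble PCSF, clustering -----------------
    pc = config.pcsf
    pcsf_cfg = pcsf.PcsfConfig(
        mu=float(pc.get("mu", 0.0005)), omega=float(pc.get("omega", 0.6)), beta=float(pc.get("beta", 1000.0)),
        ensemble_runs=int(pc.get("ensemble_runs", 10)), noise=float(pc.get("noise", 0.1)),
        seed=stage_seed(seed, "pcsf"),
    )
    terminals = pcsf.select_terminals(fac, 0, node_map)
    grid_curve = pd.DataFrame()
    if pc.get("grid", True) and len(terminals):
        pcsf_cfg, grid_curve = pcsf.grid_search(network, terminals, pcsf_cfg)
    final_net = pcsf.ensemble_solve(network, terminals, pcsf_cfg)
    clusters = pcsf.cluster_network(final_net)
    profiles = pcsf.cluster_profiles(clusters, contrasts, node_map)
    status["pcsf"] = "ok"

    # -- enrichment --------------------------------------------------------
    genesets = syndata.simulate_genesets(study, seed=stage_seed(seed, "genesets"))
    en = config.enrich
    mrna_w = fac.weights["mrna"].iloc[:, 0].copy()
    mrna_w.index = pd.Index(study.layer("mrna").annotations.loc[fac.weights["mrna"].index, "gene"])
    gsea_m = enrich.gsea_preranked(mrna_w, genesets, n_perm=int(en.get("n_perm", 1000)),
                                   seed=stage_seed(seed, "gsea_mrna"))
    prot_w = fac.weights["protein"].iloc[:, 0].copy()
    prot_w.index = pd.Index(study.layer("protein").annotations.loc[fac.weights["protein"].index, "gene"])
    prot_sets = {n: s & set(prot_w.index) for n, s in genesets.sets.items()}
    prot_sets = {n: s for n, s in prot_sets.items() if len(s) >= 2}
    gsea_p = enrich.gsea_preranked(prot_w, prot_sets, n_perm=int(en.get("n_perm", 1000)),
                                   seed=stage_seed(seed, "gsea_protein"), min_size=2)
    net_genes = {v for v in final_net.graph.nodes if final_net.graph.nodes[v].get("layer") == "gene"}
    universe = set(study.layer("mrna").annotations["gene"])
    sel = net_genes & universe
    ora = (
        enrich.fisher_ora(sel, universe, genesets).table
        if sel
        else pd.DataFrame()
    )
    status["enrich"] = "ok"

    # -- covariate correlation (factor 1 vs BALF immune cells) -------------
    cov_r2, cov_slope, cov_cells = factors.correlate_factor_covariate(fac, study.sheet)

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "status": status,
        "n_contrasts": len(contrasts),
        "n_terminals": len(terminals),
        "n_unmapped_features": len(unmapped),
        "pcsf_omega": pcsf_cfg.omega,
        "pcsf_beta": pcsf_cfg.beta,
        "sgcca": status["sgcca"],
    }
    bundle = ReportBundle(
        diff_counts=counts,
        rbif=rbif_table,
        fc_correlation=fc_table,
        variance_explained=ve,
        factor_scores=fac.scores,
        enrichment_mrna=gsea_m.table.drop(columns=["leading_edge"]),
        enrichment_protein=gsea_p.table.drop(columns=["leading_edge"]),
        ora=ora,
        covariate_correlation={"r2": cov_r2, "slope": cov_slope},
        cluster_profiles=profiles,
        grid_curve=grid_curve,
        network=final_net,
        clusters=clusters,
        manifest=manifest,
    )
    if write:
        outdir = Path(config.outdir)
        syndata.write_study(study, outdir / "study")
        counts.to_csv(outdir / "diff_counts.tsv", sep="\t", index=False)
        bundle.write(outdir / "report")
    return bundle
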