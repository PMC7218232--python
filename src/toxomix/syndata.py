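"""Synthetic multi-omics study generator.

Emulates a six-arm inhalation toxicology design measured across five
molecular layers (mRNA, miRNA, protein, metabolite, lipid) on shared
animals, at a reduced "desk" scale. Data are generated from a planted
linear latent-factor model Y_m = Z W_m' + eps_m per modality on its model
(log2) scale and then moved to each modality's native scale, with
designed missingness (no metabolomics at the 4-month time point, one
fewer proteomics replicate, sporadic QC dropouts). Planted truth (factor
scores, loadings, active feature sets, covariate slope) is always
emitted alongside the data so downstream recovery can be checked against
truth rather than against the data themselves.

Also generates the companion resources the downstream analyses need:
interaction tables shaped like KEGG metabolite/enzyme links, STRING
scored gene links and mirTarBase miRNA/gene links; gene-set collections;
and signed causal network models with a planted perturbation direction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ConfigError, stage_seed

GROUPS = ("Sham", "3R4F", "CHTP", "THS", "Cessation", "Switch")
TIMEPOINTS = (3, 4, 6)
MODALITIES = ("mrna", "mirna", "protein", "metabolite", "lipid")

#: exposure arms compared against Sham
EXPOSED_GROUPS = ("3R4F", "CHTP", "THS", "Cessation", "Switch")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


def _default_group_effect() -> dict[tuple[str, int], float]:
    """Planted factor-1 score means per (group, time point).

    Reference smoke is the extreme arm at every time point; cessation and
    switch arms sit at 50% of it at 3 months decaying to 25% at 6 months
    (partial reversal); sham and the two heated-tobacco arms are at zero.
    """
    eff: dict[tuple[str, int], float] = {}
    frac = {3: 0.5, 4: 0.375, 6: 0.25}
    for tp in TIMEPOINTS:
        eff[("Sham", tp)] = 0.0
        eff[("3R4F", tp)] = 3.0
        eff[("CHTP", tp)] = 0.0
        eff[("THS", tp)] = 0.0
        eff[("Cessation", tp)] = 3.0 * frac[tp]
        eff[("Switch", tp)] = 3.0 * frac[tp]
    return eff


@dataclass
class PlantedFactor:
    """One planted latent factor: score means per arm and loadings per view."""

    name: str
    group_effect: dict[tuple[str, int], float]
    modality_loading_scale: dict[str, float]
    active_fraction: dict[str, float]
    score_sd: float = 0.5
    mrna_protein_loading_corr: float = 0.75

    def validate(self) -> None:
        for v in self.group_effect.values():
            if not np.isfinite(v):
                raise ConfigError(f"factor {self.name}: non-finite group effect")
        for m, f in self.active_fraction.items():
            if not (0 < f <= 1):
                raise ConfigError(f"factor {self.name}: active_fraction for {m} not in (0,1]")
        if not (-1 <= self.mrna_protein_loading_corr <= 1):
            raise ConfigError("mrna_protein_loading_corr outside [-1,1]")


def default_factor_spec() -> list[PlantedFactor]:
    shared = PlantedFactor(
        name="factor1",
        group_effect=_default_group_effect(),
        modality_loading_scale={"mrna": 0.5, "mirna": 0.5, "protein": 0.5, "metabolite": 0.5, "lipid": 0.5},
        active_fraction={"mrna": 0.35, "mirna": 0.3, "protein": 0.4, "metabolite": 0.4, "lipid": 0.4},
    )
    zero_eff = {(g, t): 0.0 for g in GROUPS for t in TIMEPOINTS}
    # metabolite factor made a bit stronger than the lipid one so the
    # recovered ordering (by variance explained) is stable across seeds:
    # shared factor first, then metabolite-specific, then lipid-specific
    metab = PlantedFactor(
        name="factor2",
        group_effect=dict(zero_eff),
        modality_loading_scale={"metabolite": 0.7},
        active_fraction={"metabolite": 0.5},
        score_sd=1.0,
    )
    lipid = PlantedFactor(
        name="factor3",
        group_effect=dict(zero_eff),
        modality_loading_scale={"lipid": 0.55},
        active_fraction={"lipid": 0.5},
        score_sd=1.0,
    )
    return [shared, metab, lipid]


@dataclass
class SimConfig:
    """Study-level simulation settings (defaults are the desk-scale design)."""

    seed: int = 0
    n_per_group_modality: dict[str, int] = field(
        default_factory=lambda: {"mrna": 9, "mirna": 9, "protein": 8, "metabolite": 9, "lipid": 9}
    )
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[int, ...] = TIMEPOINTS
    modality_dims: dict[str, int] = field(
        default_factory=lambda: {"mrna": 2000, "protein": 500, "metabolite": 200, "lipid": 150, "mirna": 100}
    )
    factor_spec: list[PlantedFactor] = field(default_factory=default_factor_spec)
    dropout_rate: float = 0.02
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"mrna": 0.6, "mirna": 0.6, "protein": 0.5, "metabolite": 0.7, "lipid": 0.6}
    )
    #: per-entry low-abundance censoring rate for measured metabolite samples
    metabolite_censor_rate: float = 0.03

    def validate(self) -> None:
        if not self.groups or not self.timepoints:
            raise ConfigError("groups and timepoints must be nonempty")
        for m, d in self.modality_dims.items():
            if m not in MODALITIES:
                raise ConfigError(f"unknown modality {m!r}")
            if d <= 0:
                raise ConfigError(f"non-positive dimension for {m}")
        for m in self.modality_dims:
            if m not in self.n_per_group_modality:
                raise ConfigError(f"no replicate count for {m}")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0,1)")
        for f in self.factor_spec:
            f.validate()


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsLayer:
    """One modality's feature-by-sample abundance matrix.

    ``values`` holds NaN for missing entries (whole sample unavailable or
    entry-level QC/censoring); ``annotations`` is indexed by feature id with
    a ``gene`` column (mRNA/protein) and a ``node_id`` column for mapping
    onto the interaction network. ``scale`` is "log2" for mRNA/miRNA/protein
    and "native" for metabolite/lipid as generated.
    """

    modality: str
    values: pd.DataFrame
    annotations: pd.DataFrame
    scale: str = "log2"
    total_protein: pd.Series | None = None  # mg per sample; lipid layer only

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-entry mask (True = observed)."""
        return self.values.notna()

    def copy(self) -> "OmicsLayer":
        return OmicsLayer(
            modality=self.modality,
            values=self.values.copy(),
            annotations=self.annotations.copy(),
            scale=self.scale,
            total_protein=None if self.total_protein is None else self.total_protein.copy(),
        )


@dataclass
class SampleSheet:
    """One row per animal x time point, with per-modality availability flags."""

    table: pd.DataFrame

    def available(self, modality: str) -> list[str]:
        col = f"avail_{modality}"
        return list(self.table.index[self.table[col]])

    def arm(self, group: str, timepoint: int) -> list[str]:
        t = self.table
        return list(t.index[(t["group"] == group) & (t["timepoint"] == timepoint)])


@dataclass
class SimulatedStudy:
    layers: list[OmicsLayer]
    sheet: SampleSheet
    truth: dict
    config: SimConfig

    def layer(self, modality: str) -> OmicsLayer:
        for ly in self.layers:
            if ly.modality == modality:
                return ly
        raise KeyError(modality)


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


def _feature_ids(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Feature annotation frames per modality.

    Protein features map 1:1 onto the first genes of the mRNA universe so
    that cross-modal fold-change correlation and gene-node collapsing are
    exercised.
    """
    ann = {}
    n_mrna = config.modality_dims.get("mrna", 0)
    genes = [f"Gene{i + 1:05d}" for i in range(n_mrna)]
    ann["mrna"] = pd.DataFrame(
        {"gene": genes, "node_id": genes},
        index=pd.Index([f"MRNA{i + 1:05d}" for i in range(n_mrna)], name="feature_id"),
    )
    n_prot = config.modality_dims.get("protein", 0)
    if n_prot > n_mrna:
        raise ConfigError("protein universe larger than gene universe")
    ann["protein"] = pd.DataFrame(
        {"gene": genes[:n_prot], "node_id": genes[:n_prot]},
        index=pd.Index([f"PROT{i + 1:05d}" for i in range(n_prot)], name="feature_id"),
    )
    n_mir = config.modality_dims.get("mirna", 0)
    mir = [f"mmu-miR-{i + 1:04d}" for i in range(n_mir)]
    ann["mirna"] = pd.DataFrame({"gene": [""] * n_mir, "node_id": mir}, index=pd.Index(mir, name="feature_id"))
    n_met = config.modality_dims.get("metabolite", 0)
    met = [f"met_{i + 1:04d}" for i in range(n_met)]
    ann["metabolite"] = pd.DataFrame({"gene": [""] * n_met, "node_id": met}, index=pd.Index(met, name="feature_id"))
    n_lip = config.modality_dims.get("lipid", 0)
    lip = [f"lipid_{i + 1:04d}" for i in range(n_lip)]
    ann["lipid"] = pd.DataFrame(
        {"gene": [""] * n_lip, "node_id": [""] * n_lip}, index=pd.Index(lip, name="feature_id")
    )
    return {m: ann[m] for m in MODALITIES if m in config.modality_dims}


def _draw_loadings(config: SimConfig, ann: dict[str, pd.DataFrame], rng: np.random.Generator):
    """Per-modality loading matrices (features x factors) and active masks."""
    factors = config.factor_spec
    loadings: dict[str, pd.DataFrame] = {}
    active: dict[str, dict[str, list[str]]] = {m: {} for m in ann}
    for m, a in ann.items():
        loadings[m] = pd.DataFrame(0.0, index=a.index, columns=[f.name for f in factors])

    for f in factors:
        # mRNA/protein handled jointly so their loadings can be correlated
        mrna_dim = config.modality_dims.get("mrna", 0)
        prot_dim = config.modality_dims.get("protein", 0)
        joint = "mrna" in f.modality_loading_scale and "protein" in f.modality_loading_scale and prot_dim > 0
        if joint:
            n_prot_active = max(1, round(f.active_fraction.get("protein", 0) * prot_dim))
            prot_active_idx = np.sort(rng.choice(prot_dim, size=n_prot_active, replace=False))
            n_mrna_active = max(1, round(f.active_fraction.get("mrna", 0) * mrna_dim))
            extra_pool = np.setdiff1d(np.arange(mrna_dim), prot_active_idx)
            n_extra = max(0, n_mrna_active - n_prot_active)
            extra = rng.choice(extra_pool, size=min(n_extra, extra_pool.size), replace=False)
            mrna_active_idx = np.sort(np.concatenate([prot_active_idx, extra]))

            base = rng.normal(size=n_prot_active)
            rho = f.mrna_protein_loading_corr
            prot_load = rho * base + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n_prot_active)
            w_m = np.zeros(mrna_dim)
            w_m[prot_active_idx] = base
            w_m[extra] = rng.normal(size=extra.size)
            w_p = np.zeros(prot_dim)
            w_p[prot_active_idx] = prot_load
            loadings["mrna"][f.name] = w_m * f.modality_loading_scale["mrna"]
            loadings["protein"][f.name] = w_p * f.modality_loading_scale["protein"]
            active["mrna"][f.name] = list(ann["mrna"].index[mrna_active_idx])
            active["protein"][f.name] = list(ann["protein"].index[prot_active_idx])

        for m, scale in f.modality_loading_scale.items():
            if joint and m in ("mrna", "protein"):
                continue
            dim = config.modality_dims.get(m, 0)
            if dim == 0:
                continue
            n_active = max(1, round(f.active_fraction.get(m, 0) * dim))
            idx = np.sort(rng.choice(dim, size=n_active, replace=False))
            w = np.zeros(dim)
            w[idx] = rng.normal(size=n_active)
            loadings[m][f.name] = w * scale
            active[m][f.name] = list(ann[m].index[idx])
    return loadings, active


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate one synthetic multi-omics study (fully reproducible from seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _feature_ids(config)
    n_max = max(config.n_per_group_modality.values())

    # --- sample sheet -----------------------------------------------------
    rows = []
    for g in config.groups:
        for tp in config.timepoints:
            for i in range(n_max):
                animal = f"{g}_{tp}m_a{i + 1:02d}"
                rows.append({"sample_id": animal, "animal_id": animal, "group": g, "timepoint": tp, "rep": i + 1})
    sheet_df = pd.DataFrame(rows).set_index("sample_id")

    for m in ann:
        n_m = config.n_per_group_modality[m]
        avail = sheet_df["rep"] <= n_m
        if m == "metabolite":
            avail &= sheet_df["timepoint"] != 4
        # sporadic QC dropouts on top of the design
        drop = rng.random(len(sheet_df)) < config.dropout_rate
        sheet_df[f"avail_{m}"] = np.asarray(avail) & ~drop

    # --- factor scores ----------------------------------------------------
    factors = config.factor_spec
    z = np.zeros((len(sheet_df), len(factors)))
    for k, f in enumerate(factors):
        means = np.array([f.group_effect.get((g, t), 0.0) for g, t in zip(sheet_df["group"], sheet_df["timepoint"])])
        z[:, k] = means + rng.normal(0, f.score_sd, size=len(sheet_df))
    z_df = pd.DataFrame(z, index=sheet_df.index, columns=[f.name for f in factors])

    loadings, active = _draw_loadings(config, ann, rng)

    # --- BALF immune-cell covariate (affine in factor-1 score) ------------
    balf_slope, balf_intercept, balf_sd = 150.0, 200.0, 80.0
    balf = balf_intercept + balf_slope * z[:, 0] + rng.normal(0, balf_sd, size=len(sheet_df))
    sheet_df["balf_cells"] = np.maximum(balf, 0.0)

    # --- data matrices ----------------------------------------------------
    layers = []
    for m, a in ann.items():
        dim = config.modality_dims[m]
        baseline = rng.normal(7.0 if m in ("mrna", "mirna", "protein") else 4.0, 1.0, size=dim)
        W = loadings[m].to_numpy()
        signal = W @ z.T  # features x samples
        noise = rng.normal(0, config.noise_sd[m], size=signal.shape)
        y = baseline[:, None] + signal + noise  # model (log2) scale
        values = pd.DataFrame(y, index=a.index, columns=sheet_df.index)

        total_protein = None
        scale = "log2"
        if m in ("metabolite", "lipid"):
            values = 2.0**values
            scale = "native"
        if m == "lipid":
            total_protein = pd.Series(rng.uniform(1.5, 2.5, size=len(sheet_df)), index=sheet_df.index, name="total_protein_mg")
            values = values.mul(total_protein, axis=1)

        # blank out unavailable samples
        unavailable = ~sheet_df[f"avail_{m}"]
        values.loc[:, list(sheet_df.index[unavailable])] = np.nan

        if m == "metabolite" and config.metabolite_censor_rate > 0:
            # low-abundance censoring: entries below the per-feature 10th
            # percentile go missing at an elevated rate
            obs = values.to_numpy()
            with np.errstate(all="ignore"):
                q10 = np.nanquantile(obs, 0.10, axis=1, keepdims=True)
            low = obs <= q10
            hit = rng.random(obs.shape) < (config.metabolite_censor_rate / 0.10)
            obs[np.isfinite(obs) & low & hit] = np.nan
            values = pd.DataFrame(obs, index=values.index, columns=values.columns)

        layers.append(OmicsLayer(modality=m, values=values, annotations=a, scale=scale, total_protein=total_protein))

    truth = {
        "factor_scores": z_df,
        "group_effects": {f.name: f.group_effect for f in factors},
        "loadings": loadings,
        "active_features": active,
        "balf": {"intercept": balf_intercept, "slope": balf_slope, "noise_sd": balf_sd},
    }
    sheet = SampleSheet(table=sheet_df)
    return SimulatedStudy(layers=layers, sheet=sheet, truth=truth, config=config)


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

INTERACTION_COLUMNS = (
    "source_id",
    "target_id",
    "source_type",
    "target_type",
    "database",
    "combined_score",
    "n_publications",
    "n_nonhts_methods",
)


def simulate_interactions(
    study: SimulatedStudy,
    n_string_background: int = 800,
    n_kegg_background: int = 150,
    n_mirtarbase_background: int = 80,
    connectivity_enrichment: float = 1.0,
    n_signal_modules: int = 12,
    string_score_range: tuple[float, float] = (0.05, 0.95),
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a synthetic heterogeneous interaction table.

    Background links connect random features; when ``connectivity_enrichment``
    is positive, additional high-confidence links wire the factor-1-active
    features into ``n_signal_modules`` internally connected "signal" modules
    (functional clusters) so the downstream Steiner forest has recoverable
    structure. At 0 the planted features are wired exactly like background.
    """
    rng = np.random.default_rng(stage_seed(study.config.seed, "interactions") if seed is None else seed)
    ann = {ly.modality: ly.annotations for ly in study.layers}
    genes = list(ann["mrna"]["gene"]) if "mrna" in ann else []
    mets = list(ann["metabolite"].index) if "metabolite" in ann else []
    mirs = list(ann["mirna"].index) if "mirna" in ann else []
    if not genes:
        raise ConfigError("empty feature universe")

    lo, hi = string_score_range
    recs: list[tuple] = []

    # the factor-1 "signal" universe (used both for the planted wiring and,
    # when wiring is on, to keep background links from short-circuiting the
    # planted modules: distinct processes sit >=2 edges apart)
    sig_gene_set: set[str] = set()
    if connectivity_enrichment > 0:
        act = study.truth["active_features"]
        first = study.config.factor_spec[0].name
        sig_gene_set = set(ann["mrna"].loc[act.get("mrna", {}).get(first, []), "gene"])
        if "protein" in ann:
            sig_gene_set |= set(ann["protein"].loc[act.get("protein", {}).get(first, []), "gene"])

    def string_rec(a, b, score):
        recs.append((a, b, "gene", "gene", "string", float(score), 0, 0))

    def kegg_rec(met, gene):
        recs.append((met, gene, "metabolite", "gene", "kegg", np.nan, 0, 0))

    def mtb_rec(mir, gene, pubs, nonhts):
        recs.append((mir, gene, "mirna", "gene", "mirtarbase", np.nan, int(pubs), int(nonhts)))

    # background. Each metabolite/miRNA is used at most once so the
    # fixed-cost cross-layer links do not become cheap universal hubs; with
    # planted wiring on, background links never join two signal genes and
    # links touching a signal gene stay below high confidence, so planted
    # modules are separated by multi-edge paths rather than shortcuts.
    act = study.truth["active_features"] if connectivity_enrichment > 0 else {}
    first = study.config.factor_spec[0].name if study.config.factor_spec else ""
    sig_mets_set = set(act.get("metabolite", {}).get(first, []))
    sig_mirs_set = set(act.get("mirna", {}).get(first, []))
    for _ in range(n_string_background):
        for _attempt in range(20):
            a, b = rng.choice(len(genes), size=2, replace=False)
            if not (genes[a] in sig_gene_set and genes[b] in sig_gene_set):
                break
        touches_signal = genes[a] in sig_gene_set or genes[b] in sig_gene_set
        top = min(hi, 0.8) if touches_signal and connectivity_enrichment > 0 else hi
        string_rec(genes[a], genes[b], rng.uniform(lo, top))
    bg_mets = [m for m in mets if m not in sig_mets_set]
    if bg_mets:
        for mi in rng.choice(len(bg_mets), size=min(n_kegg_background, len(bg_mets)), replace=False):
            kegg_rec(bg_mets[mi], genes[rng.integers(len(genes))])
    bg_mirs = [m for m in mirs if m not in sig_mirs_set]
    if bg_mirs:
        for mi in rng.choice(len(bg_mirs), size=min(n_mirtarbase_background, len(bg_mirs)), replace=False):
            mtb_rec(bg_mirs[mi], genes[rng.integers(len(genes))], rng.integers(1, 6), rng.integers(0, 5))

    if connectivity_enrichment > 0:
        act = study.truth["active_features"]
        first = study.config.factor_spec[0].name
        sig_genes = sorted(sig_gene_set)
        sig_mets = act.get("metabolite", {}).get(first, [])
        sig_mirs = act.get("mirna", {}).get(first, [])
        # signal wiring sits in the high-confidence part of the requested range
        s_hi = hi
        s_lo = max(lo, min(0.85, hi))
        if len(sig_genes) >= 2:
            n_mod = max(1, min(n_signal_modules, len(sig_genes) // 4))
            module_of = rng.integers(n_mod, size=len(sig_genes))
            modules = [[i for i in range(len(sig_genes)) if module_of[i] == m] for m in range(n_mod)]
            modules = [m for m in modules if m]
            for mod in modules:
                order = rng.permutation(len(mod))
                for i in range(1, len(order)):  # random spanning tree per module
                    j = order[rng.integers(i)]
                    string_rec(sig_genes[mod[order[i]]], sig_genes[mod[order[j]]], rng.uniform(s_lo, s_hi))
                n_extra = int(connectivity_enrichment * 1.0 * len(mod))
                for _ in range(n_extra):
                    if len(mod) < 2:
                        break
                    a, b = rng.choice(len(mod), size=2, replace=False)
                    string_rec(sig_genes[mod[a]], sig_genes[mod[b]], rng.uniform(s_lo, s_hi))
            for met in sig_mets:
                mod = modules[rng.integers(len(modules))]
                kegg_rec(met, sig_genes[mod[rng.integers(len(mod))]])
            for mir in sig_mirs:
                mod = modules[rng.integers(len(modules))]
                mtb_rec(mir, sig_genes[mod[rng.integers(len(mod))]], rng.integers(2, 6), rng.integers(2, 5))

    df = pd.DataFrame(recs, columns=list(INTERACTION_COLUMNS))
    return df


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)


def simulate_genesets(
    study: SimulatedStudy,
    n_sets: int = 40,
    n_signal: int = 5,
    size_range: tuple[int, int] = (10, 200),
    signal_purity: float = 0.7,
    seed: int | None = None,
) -> GeneSetCollection:
    """Random gene sets over the mRNA gene universe, ``n_signal`` of which are
    enriched (fraction ``signal_purity``) in factor-1-active genes."""
    rng = np.random.default_rng(stage_seed(study.config.seed, "genesets") if seed is None else seed)
    ann = study.layer("mrna").annotations
    universe = list(ann["gene"])
    lo, hi = max(2, size_range[0]), size_range[1]
    if lo > len(universe):
        raise ConfigError("set size exceeds universe")
    first = study.config.factor_spec[0].name
    active = study.truth["active_features"]["mrna"][first]
    # signal sets are sign-coherent (genes moving together with the factor),
    # so they are detectable from the signed weight vector
    w1 = study.truth["loadings"]["mrna"][first]
    pos = [f for f in active if float(w1.get(f, 0.0)) > 0]
    sig_genes = sorted(set(ann.loc[pos if len(pos) >= 10 else active, "gene"]))

    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for i in range(n_sets):
        size = int(np.clip(rng.integers(size_range[0], size_range[1] + 1), lo, min(hi, len(universe))))
        if i < n_signal and sig_genes:
            n_sig = min(int(round(signal_purity * size)), len(sig_genes))
            members = set(rng.choice(sig_genes, size=n_sig, replace=False))
            pool = [g for g in universe if g not in members]
            members |= set(rng.choice(pool, size=size - n_sig, replace=False))
            name = f"SIGNAL_SET_{i + 1:02d}"
            desc[name] = "enriched in planted factor-1 genes"
        else:
            members = set(rng.choice(universe, size=size, replace=False))
            name = f"RANDOM_SET_{i + 1:02d}"
            desc[name] = "random background set"
        sets[name] = members
    return GeneSetCollection(sets=sets, universe=set(universe), descriptions=desc)


# ---------------------------------------------------------------------------
# causal network models
# ---------------------------------------------------------------------------


def simulate_causal_network(
    study: SimulatedStudy,
    n_backbone: int = 20,
    genes_per_node: int = 25,
    n_extra_edges: int = 10,
    seed: int | None = None,
):
    """Signed backbone + disjoint signed downstream gene layer.

    Each backbone node gets a planted perturbation direction d_i in {-1,+1}
    (emitted as truth); backbone edge signs are d_i*d_j (coherent) and
    downstream gene signs are d_i*sign(factor-1 loading) for active genes, so
    fold changes simulated from the planted factor produce a coherent
    perturbation.
    """
    from .npa import CausalNetworkModel  # local import to avoid a cycle

    rng = np.random.default_rng(stage_seed(study.config.seed, "causal_network") if seed is None else seed)
    mrna = study.layer("mrna")
    first = study.config.factor_spec[0].name
    need = n_backbone * genes_per_node
    if need > len(mrna.annotations):
        raise ConfigError("downstream demand exceeds mRNA universe")

    active = list(study.truth["active_features"]["mrna"][first])
    inactive = [f for f in mrna.annotations.index if f not in set(active)]
    pool = active + inactive  # prefer active genes
    chosen = pool[:need]
    chosen = list(rng.permutation(chosen))

    nodes = [f"BB{i + 1:02d}" for i in range(n_backbone)]
    direction = {n: int(d) for n, d in zip(nodes, rng.choice([-1, 1], size=n_backbone))}

    edges = []
    order = rng.permutation(n_backbone)
    for i in range(1, n_backbone):  # spanning tree -> connected backbone
        j = order[rng.integers(i)]
        a, b = nodes[order[i]], nodes[order[j]]
        edges.append((a, b, direction[a] * direction[b], 1.0))
    for _ in range(n_extra_edges):
        a, b = rng.choice(n_backbone, size=2, replace=False)
        edges.append((nodes[a], nodes[b], direction[nodes[a]] * direction[nodes[b]], 1.0))

    w1 = study.truth["loadings"]["mrna"][first]
    downstream: dict[str, dict[str, int]] = {}
    for i, node in enumerate(nodes):
        block = chosen[i * genes_per_node : (i + 1) * genes_per_node]
        signs = {}
        for feat in block:
            gene = mrna.annotations.loc[feat, "gene"]
            w = float(w1.get(feat, 0.0))
            s = direction[node] * (1 if w > 0 else -1) if w != 0 else int(rng.choice([-1, 1]))
            signs[gene] = s
        downstream[node] = signs

    model = CausalNetworkModel(nodes=nodes, edges=edges, downstream=downstream)
    model.validate()
    return model, {"direction": direction}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, outdir) -> None:
    """One TSV per modality (empty cell = missing), sample sheet, truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ly in study.layers:
        ly.values.to_csv(out / f"{ly.modality}.tsv", sep="\t", na_rep="")
        ly.annotations.to_csv(out / f"{ly.modality}_features.tsv", sep="\t")
        if ly.total_protein is not None:
            ly.total_protein.to_csv(out / "lipid_total_protein.tsv", sep="\t")
    study.sheet.table.to_csv(out / "sample_sheet.tsv", sep="\t")
    truth = study.truth
    payload = {
        "factor_scores": truth["factor_scores"].to_dict(orient="index"),
        "group_effects": {k: {f"{g}|{t}": v for (g, t), v in d.items()} for k, d in truth["group_effects"].items()},
        "active_features": truth["active_features"],
        "balf": truth["balf"],
        "loadings": {m: df.to_dict(orient="index") for m, df in truth["loadings"].items()},
        "config": {
            "seed": study.config.seed,
            "modality_dims": study.config.modality_dims,
            "dropout_rate": study.config.dropout_rate,
        },
    }
    (out / "truth.json").write_text(json.dumps(payload))


def read_study(indir) -> SimulatedStudy:
    """Read a study previously written by :func:`write_study`."""
    ind = Path(indir)
    sheet_df = pd.read_csv(ind / "sample_sheet.tsv", sep="\t", index_col=0)
    payload = json.loads((ind / "truth.json").read_text())
    cfg = SimConfig(seed=payload["config"]["seed"], modality_dims=payload["config"]["modality_dims"],
                    dropout_rate=payload["config"]["dropout_rate"])
    layers = []
    for m in MODALITIES:
        p = ind / f"{m}.tsv"
        if not p.exists():
            continue
        vals = pd.read_csv(p, sep="\t", index_col=0)
        ann = pd.read_csv(ind / f"{m}_features.tsv", sep="\t", index_col=0).fillna("")
        tp = None
        if m == "lipid" and (ind / "lipid_total_protein.tsv").exists():
            tp = pd.read_csv(ind / "lipid_total_protein.tsv", sep="\t", index_col=0).iloc[:, 0]
        layers.append(OmicsLayer(modality=m, values=vals, annotations=ann,
                                 scale="native" if m in ("metabolite", "lipid") else "log2",
                                 total_protein=tp))
    truth = {
        "factor_scores": pd.DataFrame.from_dict(payload["factor_scores"], orient="index"),
        "group_effects": {
            k: {(gk.split("|")[0], int(gk.split("|")[1])): v for gk, v in d.items()}
            for k, d in payload["group_effects"].items()
        },
        "active_features": payload["active_features"],
        "balf": payload["balf"],
        "loadings": {m: pd.DataFrame.from_dict(d, orient="index") for m, d in payload["loadings"].items()},
    }
    return SimulatedStudy(layers=layers, sheet=SampleSheet(table=sheet_df), truth=truth, config=cfg)


def write_causal_network(model, truth: dict, path) -> None:
    payload = {
        "nodes": model.nodes,
        "edges": [[a, b, s, w] for a, b, s, w in model.edges],
        "downstream": model.downstream,
        "truth": truth,
    }
    Path(path).write_text(json.dumps(payload))


def read_causal_network(path):
    from .npa import CausalNetworkModel

    payload = json.loads(Path(path).read_text())
    model = CausalNetworkModel(
        nodes=payload["nodes"],
        edges=[(a, b, int(s), float(w)) for a, b, s, w in payload["edges"]],
        downstream={n: {g: int(s) for g, s in d.items()} for n, d in payload["downstream"].items()},
    )
    return model, payload.get("truth", {})
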