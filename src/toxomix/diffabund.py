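"""Per-modality preprocessing and exposure-vs-Sham differential abundance.

Statistics follow the standard empirical-Bayes moderated t-statistic: per
feature, a two-group linear model (exposure arm vs the matching Sham arm at
the same time point) gives the log2 fold change and residual variance; the
residual variances are shrunk toward a pooled prior variance s0^2 with prior
degrees of freedom d0 estimated by moment matching on log variances
(trigamma inversion), and two-sided p-values come from a t distribution with
d0 + d_g degrees of freedom. Benjamini-Hochberg FDR adjustment is applied
within each (modality, contrast) family and features with adjusted p < 0.05
are flagged as differentially expressed/abundant.

Preprocessing: lipid abundances are normalized per mg of total protein and
log2 transformed; metabolite missing values (low-abundance censoring) are
imputed as the per-metabolite observed minimum before log2; mRNA/miRNA/
protein layers are already on log2 scale and pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .syndata import OmicsLayer, SampleSheet

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess_layer(layer: OmicsLayer, sheet: SampleSheet) -> OmicsLayer:
    """Move a layer onto its analysis (log2) scale.

    Only entries of samples marked available in the sheet are touched;
    designed-missing samples stay missing. Metabolites with no observed value
    are dropped with a warning (nothing to impute from).
    """
    out = layer.copy()
    avail = sheet.available(layer.modality)
    avail = [s for s in avail if s in out.values.columns]
    if layer.modality == "lipid":
        if out.total_protein is None:
            raise ValueError("lipid layer lacks total protein amounts")
        tp = out.total_protein.reindex(out.values.columns)
        if (tp.loc[avail] <= 0).any():
            raise ValueError("non-positive total protein amount")
        out.values = out.values.div(tp, axis=1)
        out.values = np.log2(out.values)
        out.scale = "log2"
    elif layer.modality == "metabolite":
        vals = out.values[avail]
        no_obs = vals.notna().sum(axis=1) == 0
        if no_obs.any():
            dropped = list(out.values.index[no_obs])
            logger.warning("dropping %d metabolites with no observed value: %s", len(dropped), dropped[:5])
            out.values = out.values.loc[~no_obs]
            out.annotations = out.annotations.loc[~no_obs]
            vals = vals.loc[~no_obs]
        row_min = vals.min(axis=1)
        filled = vals.apply(lambda col: col.fillna(row_min))
        out.values.loc[:, avail] = filled
        out.values = np.log2(out.values)
        out.scale = "log2"
    # mRNA / miRNA / protein: pass through unchanged
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes prior on residual variances
# ---------------------------------------------------------------------------


@dataclass
class EBayesPrior:
    """Shrinkage prior: d0 (may be inf) and s0^2 on residual variances."""

    d0: float
    s02: float

    def posterior_variance(self, s2: np.ndarray, d: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s02)
        return (self.d0 * self.s02 + d * np.asarray(s2, dtype=float)) / (self.d0 + d)


def _trigamma_inverse(target: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = target for x > 0 (monotone Newton iteration)."""
    if target <= 0:
        return np.inf
    x = 0.5 + 1.0 / target  # good starting value: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / target) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float, tol: float = 1e-8) -> EBayesPrior:
    """Moment-matching estimate of (d0, s0^2) from observed residual variances.

    Matches the first two moments of log s^2 under the scaled chi-square
    sampling model: var(log s^2) = trigamma(d/2) + trigamma(d0/2), so d0
    solves trigamma(d0/2) = max(0, var(log s2) - trigamma(d/2)). When the
    excess variance is at or below tolerance all shrinkage is used (d0 = inf).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError("need at least 10 finite positive variances")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if np.var(z, ddof=1) < 1e-15:
        # degenerate: identical variances carry no spread to match
        return EBayesPrior(d0=np.inf, s02=float(np.exp(np.mean(z))))
    target = np.var(z, ddof=1) - special.polygamma(1, d / 2.0)
    if target <= tol:
        return EBayesPrior(d0=np.inf, s02=float(np.exp(np.mean(e))))
    half_d0 = _trigamma_inverse(float(target), tol=tol)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return EBayesPrior(d0=d0, s02=s02)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastTable:
    """Per-feature differential statistics for one exposure-vs-Sham contrast."""

    table: pd.DataFrame  # feature_id -> logFC, s2, df, t, P.Value, adj.P.Val, significant
    group: str
    timepoint: int
    modality: str
    n_treat: int
    n_sham: int
    prior: EBayesPrior | None = None
    status: str = "ok"

    def summary(self) -> str:
        n_sig = int(self.table["significant"].sum()) if len(self.table) else 0
        lines = [
            f"Contrast: {self.group} vs Sham @ {self.timepoint} months [{self.modality}]",
            f"  n per arm: {self.n_treat} / {self.n_sham}; features tested: {len(self.table)}",
            f"  prior: d0={self.prior.d0:.3g}, s0^2={self.prior.s02:.3g}" if self.prior else "  prior: none",
            f"  significant at FDR<{FDR_THRESHOLD}: {n_sig}",
        ]
        return "\n".join(lines)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_contrast(
    layer: OmicsLayer,
    sheet: SampleSheet,
    group: str,
    timepoint: int,
    prior: EBayesPrior | None = None,
) -> ContrastTable:
    """Two-group moderated-t contrast of one exposure arm against Sham.

    Uses pairwise-complete observations per feature; features missing in more
    than half of either arm are excluded (logged). If no prior is supplied it
    is estimated from this contrast's residual variances.
    """
    if layer.scale != "log2":
        raise ValueError("layer must be preprocessed to log2 scale before testing")
    avail = set(sheet.available(layer.modality))
    treat = [s for s in sheet.arm(group, timepoint) if s in avail]
    sham = [s for s in sheet.arm("Sham", timepoint) if s in avail]
    if len(treat) < 2 or len(sham) < 2:
        logger.warning("contrast %s@%s [%s] skipped: arm too small", group, timepoint, layer.modality)
        return ContrastTable(
            table=pd.DataFrame(columns=["logFC", "s2", "df", "t", "P.Value", "adj.P.Val", "significant"]),
            group=group,
            timepoint=timepoint,
            modality=layer.modality,
            n_treat=len(treat),
            n_sham=len(sham),
            status="skipped:arm_too_small",
        )

    yt = layer.values[treat].to_numpy(dtype=float)
    ys = layer.values[sham].to_numpy(dtype=float)
    nt = np.isfinite(yt).sum(axis=1)
    ns = np.isfinite(ys).sum(axis=1)
    keep = (nt >= np.ceil(len(treat) / 2)) & (ns >= np.ceil(len(sham) / 2)) & (nt >= 2) & (ns >= 2)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("contrast %s@%s [%s]: excluding %d features with >50%% missing", group, timepoint, layer.modality, n_drop)
    idx = layer.values.index[keep]
    yt, ys, nt, ns = yt[keep], ys[keep], nt[keep], ns[keep]

    mt = np.nanmean(yt, axis=1)
    ms = np.nanmean(ys, axis=1)
    beta = mt - ms
    sst = np.nansum((yt - mt[:, None]) ** 2, axis=1)
    sss = np.nansum((ys - ms[:, None]) ** 2, axis=1)
    df = nt + ns - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (sst + sss) / df
    s2 = np.maximum(s2, 1e-12)

    if prior is None:
        # moment matching needs a common d; use the modal residual df
        d_common = float(np.median(df))
        prior = estimate_prior(s2, d_common)

    s2_post = prior.posterior_variance(s2, df) if prior.d0 > 0 else s2
    se = np.sqrt(s2_post * (1.0 / nt + 1.0 / ns))
    t = beta / se
    df_total = df + (prior.d0 if np.isfinite(prior.d0) else np.inf)
    if np.isinf(prior.d0):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "logFC": beta,
            "s2": s2,
            "df": df,
            "t": t,
            "P.Value": pvals,
            "adj.P.Val": adj,
            "significant": adj < FDR_THRESHOLD,
        },
        index=idx,
    )
    return ContrastTable(
        table=table,
        group=group,
        timepoint=timepoint,
        modality=layer.modality,
        n_treat=len(treat),
        n_sham=len(sham),
        prior=prior,
    )


def crossmodal_fc_correlation(a: ContrastTable, b: ContrastTable, gene_map: dict[str, str] | None = None,
                              ann_a: pd.DataFrame | None = None, ann_b: pd.DataFrame | None = None):
    """OLS of b's log2 fold changes on a's over gene-matched features.

    ``gene_map`` maps feature ids of a to feature ids of b; alternatively
    annotation frames with a ``gene`` column are matched on gene symbol.
    Returns (R^2, slope, n).
    """
    if gene_map is None:
        if ann_a is None or ann_b is None:
            raise ValueError("provide gene_map or both annotation frames")
        genes_b = {g: f for f, g in ann_b["gene"].items() if g}
        gene_map = {f: genes_b[g] for f, g in ann_a["gene"].items() if g in genes_b}
    pairs = [(fa, fb) for fa, fb in gene_map.items() if fa in a.table.index and fb in b.table.index]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 gene-matched pairs")
    x = a.table.loc[[p[0] for p in pairs], "logFC"].to_numpy()
    y = b.table.loc[[p[1] for p in pairs], "logFC"].to_numpy()
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), len(pairs)


def write_contrasts(tables: list[ContrastTable], path) -> None:
    """All contrasts as one long TSV (round-trips with read_contrasts)."""
    frames = []
    for ct in tables:
        t = ct.table.copy()
        t.insert(0, "feature_id", t.index)
        t["modality"], t["group"], t["timepoint"] = ct.modality, ct.group, ct.timepoint
        t["n_treat"], t["n_sham"] = ct.n_treat, ct.n_sham
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_contrasts(path) -> list[ContrastTable]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (m, g, tp), sub in df.groupby(["modality", "group", "timepoint"], sort=True):
        table = sub.set_index("feature_id")[["logFC", "s2", "df", "t", "P.Value", "adj.P.Val", "significant"]]
        out.append(
            ContrastTable(
                table=table,
                group=str(g),
                timepoint=int(tp),
                modality=str(m),
                n_treat=int(sub["n_treat"].iloc[0]),
                n_sham=int(sub["n_sham"].iloc[0]),
            )
        )
    return out


def count_significant(tables: list[ContrastTable]) -> pd.DataFrame:
    """Per (modality, group, timepoint) counts of FDR<0.05 features."""
    rows = []
    for ct in tables:
        rows.append(
            {
                "modality": ct.modality,
                "group": ct.group,
                "timepoint": ct.timepoint,
                "n_significant": int(ct.table["significant"].sum()) if len(ct.table) else 0,
                "n_tested": len(ct.table),
                "status": ct.status,
            }
        )
    return pd.DataFrame(rows)
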