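"""Unsupervised multi-omics integration.

``MultiOmicsFactorModel`` is a Bayesian group factor-analysis model in the
MOFA family: the five feature-by-sample matrices are decomposed into a
shared latent score matrix Z (samples x factors) and one weight matrix W_m
per modality, with automatic relevance determination (ARD) precisions
alpha_{m,k} switching off factors per view and a Gaussian likelihood with
per-view noise precision tau_m. Inference is variational EM with closed-form
coordinate updates; samples absent from a view simply contribute nothing to
that view's updates, so missing sample-modality blocks are handled exactly.
The evidence lower bound (ELBO) is tracked every iteration and is
non-decreasing under the exact updates.

``SparseGcca`` is a sparse generalized canonical correlation analysis
(block sparse PLS in canonical mode, fully connected design): per component
an alternating scheme a_m <- sum_{m'!=m} X_m' X_{m'} a_{m'}, hard-thresholded
to the ``keep`` largest absolute entries and renormalized, with canonical
deflation of each block by its own score.

Both follow the Model(data).fit() -> Results idiom; ``fit_mofa`` and
``fit_sgcca`` are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .syndata import OmicsLayer, SampleSheet

logger = logging.getLogger(__name__)

_TAU_MAX = 1e10


# ---------------------------------------------------------------------------
# MOFA-style latent factor model
# ---------------------------------------------------------------------------


@dataclass
class FactorResults:
    """Fitted latent factor model.

    Factors are ordered by total variance explained and signed so that the
    largest-magnitude weight entry of each factor is positive.
    """

    scores: pd.DataFrame  # samples x factors
    weights: dict[str, pd.DataFrame]  # modality -> features x factors
    alpha: pd.DataFrame  # modality x factor ARD precisions
    tau: dict[str, float]
    r2: pd.DataFrame  # modality x factor variance explained (fraction)
    elbo_trajectory: list[float]
    n_iter: int
    converged: bool

    @property
    def factor_names(self) -> list[str]:
        return list(self.scores.columns)

    def variance_explained(self) -> pd.DataFrame:
        """Per-(modality, factor) fraction of observed variance explained,
        plus a 'total' column per modality."""
        out = self.r2.copy()
        out["total"] = out.sum(axis=1)
        return out

    def summary(self) -> str:
        lines = ["Multi-omics latent factor model", "=" * 34]
        lines.append(f"factors retained: {len(self.factor_names)}; iterations: {self.n_iter} "
                     f"({'converged' if self.converged else 'max_iter reached'})")
        lines.append(f"final ELBO: {self.elbo_trajectory[-1]:.4f}")
        lines.append("")
        lines.append("Variance explained (%) per modality and factor:")
        ve = (100 * self.variance_explained()).round(2)
        lines.append(ve.to_string())
        return "\n".join(lines)


class MultiOmicsFactorModel:
    """Group factor analysis across omics views with ARD and missing blocks.

    Parameters
    ----------
    layers : list of OmicsLayer on log2 scale (preprocessed).
    sheet : SampleSheet giving per-view sample availability.
    k_init : initial number of factors (factors explaining less than
        ``drop_threshold`` variance in every view are dropped at convergence).
    tol : relative ELBO change declaring convergence.
    """

    def __init__(
        self,
        layers: list[OmicsLayer],
        sheet: SampleSheet,
        k_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        drop_threshold: float = 0.001,
    ):
        if len(layers) < 2:
            raise ValueError("need at least 2 modalities")
        self.sheet = sheet
        self.k_init = k_init
        self.tol = tol
        self.max_iter = max_iter
        self.drop_threshold = drop_threshold

        self.samples = list(sheet.table.index)
        n = len(self.samples)
        self.views: dict[str, dict] = {}
        for ly in layers:
            vals = ly.values.reindex(columns=self.samples)
            avail = np.array([s in set(sheet.available(ly.modality)) for s in self.samples])
            finite_frac = vals.notna().mean(axis=0).to_numpy()
            obs = avail & (finite_frac > 0)
            y = vals.to_numpy(dtype=float)[:, obs]
            mu = np.nanmean(y, axis=1, keepdims=True)
            y = y - mu
            y[~np.isfinite(y)] = 0.0  # entry-level holes: mean imputation after centering
            total_var = float(np.sum(np.var(y, axis=1))) or 1.0
            y = y / np.sqrt(total_var)  # each view carries unit total variance
            self.views[ly.modality] = {
                "y": y,
                "obs": np.where(obs)[0],
                "features": list(ly.values.index),
            }
        if k_init > min(min(v["y"].shape) for v in self.views.values()):
            raise ValueError("k_init exceeds smallest data dimension")
        any_obs = set()
        common = None
        for v in self.views.values():
            s = set(v["obs"])
            any_obs |= s
            common = s if common is None else (common & s)
        if not any_obs:
            raise ValueError("no observed samples in any view")

    # -- inference ----------------------------------------------------------

    def fit(self, seed: int = 0) -> FactorResults:
        rng = np.random.default_rng(seed)
        n = len(self.samples)
        k = self.k_init
        views = self.views

        # init scores from PCA of the concatenated (zero-filled) data
        stacked = np.zeros((n, sum(v["y"].shape[0] for v in views.values())))
        col = 0
        for v in views.values():
            f = v["y"].shape[0]
            stacked[v["obs"], col : col + f] = v["y"].T
            col += f
        u, s, _ = np.linalg.svd(stacked, full_matrices=False)
        m_z = u[:, :k] * s[:k]
        sd = m_z.std(axis=0)
        sd[sd == 0] = 1.0
        m_z = m_z / sd + 1e-6 * rng.standard_normal((n, k))

        # per-sample view pattern (which views observe the sample)
        names = list(views)
        in_view = {m: np.zeros(n, dtype=bool) for m in names}
        for m in names:
            in_view[m][views[m]["obs"]] = True
        patterns = {}
        pat_of = []
        for i in range(n):
            key = tuple(m for m in names if in_view[m][i])
            patterns.setdefault(key, []).append(i)
            pat_of.append(key)
        cov_zp = {key: np.eye(k) * 0.01 for key in patterns}

        alpha = {m: np.ones(k) for m in names}
        tau = {m: float(views[m]["y"].shape[0]) for m in names}
        u_w = {m: np.zeros((views[m]["y"].shape[0], k)) for m in names}
        c_w = {m: np.eye(k) / views[m]["y"].shape[0] for m in names}

        elbos: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # E-step W per view
            s_z = {}
            for m in names:
                obs = views[m]["obs"]
                sz = m_z[obs].T @ m_z[obs]
                for key, idx in patterns.items():
                    if m in key:
                        sz = sz + len(idx) * cov_zp[key]
                s_z[m] = sz
            for m in names:
                a_mat = tau[m] * s_z[m] + np.diag(alpha[m])
                c_w[m] = np.linalg.inv(a_mat)
                u_w[m] = tau[m] * (views[m]["y"] @ m_z[views[m]["obs"]]) @ c_w[m]

            # M-step alpha (ARD)
            for m in names:
                f = views[m]["y"].shape[0]
                ssq = np.sum(u_w[m] ** 2, axis=0) + f * np.diag(c_w[m])
                alpha[m] = np.minimum(f / np.maximum(ssq, 1e-300), 1e12)

            # E-step Z per missing pattern
            s_w = {m: u_w[m].T @ u_w[m] + views[m]["y"].shape[0] * c_w[m] for m in names}
            rhs = np.zeros((n, k))
            for m in names:
                obs = views[m]["obs"]
                rhs[obs] += tau[m] * (views[m]["y"].T @ u_w[m])
            for key, idx in patterns.items():
                prec = np.eye(k)
                for m in key:
                    prec = prec + tau[m] * s_w[m]
                cov = np.linalg.inv(prec)
                cov_zp[key] = cov
                m_z[idx] = rhs[idx] @ cov

            # M-step tau
            s_z = {}
            resid = {}
            for m in names:
                obs = views[m]["obs"]
                sz = m_z[obs].T @ m_z[obs]
                for key, idx in patterns.items():
                    if m in key:
                        sz += len(idx) * cov_zp[key]
                s_z[m] = sz
                y = views[m]["y"]
                cross = float(np.sum(y * (u_w[m] @ m_z[obs].T)))
                r = float(np.sum(y**2)) - 2 * cross + float(np.sum(s_w[m] * s_z[m]))
                resid[m] = max(r, 1e-12)
                n_entries = y.shape[0] * y.shape[1]
                tau[m] = min(n_entries / resid[m], _TAU_MAX)

            elbo = self._elbo(views, names, patterns, cov_zp, m_z, u_w, c_w, s_w, alpha, tau, resid, k)
            elbos.append(elbo)
            if len(elbos) > 1:
                denom = max(abs(elbos[-1]), 1.0)
                if (elbos[-1] - elbos[-2]) / denom < self.tol and elbos[-1] >= elbos[-2] - 1e-6 * denom:
                    converged = True
                    break

        return self._package(names, views, m_z, u_w, alpha, tau, elbos, it, converged)

    @staticmethod
    def _elbo(views, names, patterns, cov_zp, m_z, u_w, c_w, s_w, alpha, tau, resid, k):
        ll = 0.0
        for m in names:
            y = views[m]["y"]
            n_entries = y.shape[0] * y.shape[1]
            ll += 0.5 * n_entries * (np.log(tau[m]) - np.log(2 * np.pi)) - 0.5 * tau[m] * resid[m]
        p_w = 0.0
        ent_w = 0.0
        for m in names:
            f = views[m]["y"].shape[0]
            p_w += 0.5 * f * np.sum(np.log(alpha[m] / (2 * np.pi))) - 0.5 * float(np.sum(alpha[m] * np.diag(s_w[m])))
            sign, logdet = np.linalg.slogdet(c_w[m])
            ent_w += 0.5 * f * (k * np.log(2 * np.pi * np.e) + logdet)
        p_z = 0.0
        ent_z = 0.0
        n_tot = 0
        for key, idx in patterns.items():
            nn = len(idx)
            n_tot += nn
            tr = float(np.sum(m_z[idx] ** 2)) + nn * float(np.trace(cov_zp[key]))
            p_z += -0.5 * tr
            sign, logdet = np.linalg.slogdet(cov_zp[key])
            ent_z += 0.5 * nn * (k * np.log(2 * np.pi * np.e) + logdet)
        p_z += -0.5 * n_tot * k * np.log(2 * np.pi)
        return float(ll + p_w + ent_w + p_z + ent_z)

    def _package(self, names, views, m_z, u_w, alpha, tau, elbos, n_iter, converged) -> FactorResults:
        k = self.k_init
        # variance explained per (view, factor) on the training scale
        r2 = np.zeros((len(names), k))
        for vi, m in enumerate(names):
            y = views[m]["y"]
            obs = views[m]["obs"]
            ss_tot = float(np.sum(y**2)) or 1.0
            for kk in range(k):
                pred = np.outer(u_w[m][:, kk], m_z[obs, kk])
                r2[vi, kk] = max(0.0, 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot)
        keep = np.where(r2.max(axis=0) >= self.drop_threshold)[0]
        if keep.size == 0:
            keep = np.array([int(np.argmax(r2.sum(axis=0)))])
        order = keep[np.argsort(-r2[:, keep].sum(axis=0))]

        # sign convention: largest |weight| entry positive
        w_all = np.vstack([u_w[m] for m in names])
        signs = np.ones(len(order))
        for j, kk in enumerate(order):
            col = w_all[:, kk]
            if col[np.argmax(np.abs(col))] < 0:
                signs[j] = -1.0

        factor_names = [f"LF{j + 1}" for j in range(len(order))]
        scores = pd.DataFrame(m_z[:, order] * signs, index=self.samples, columns=factor_names)
        weights = {
            m: pd.DataFrame(u_w[m][:, order] * signs, index=views[m]["features"], columns=factor_names)
            for m in names
        }
        alpha_df = pd.DataFrame({fn: [alpha[m][kk] for m in names] for fn, kk in zip(factor_names, order)}, index=names)
        r2_df = pd.DataFrame(
            {fn: r2[:, kk] for fn, kk in zip(factor_names, order)}, index=names
        )
        return FactorResults(
            scores=scores,
            weights=weights,
            alpha=alpha_df,
            tau={m: tau[m] for m in names},
            r2=r2_df,
            elbo_trajectory=elbos,
            n_iter=n_iter,
            converged=converged,
        )


def fit_mofa(
    layers: list[OmicsLayer],
    sheet: SampleSheet,
    k_init: int = 10,
    tol: float = 1e-6,
    seed: int = 0,
    max_iter: int = 500,
    drop_threshold: float = 0.001,
) -> FactorResults:
    model = MultiOmicsFactorModel(layers, sheet, k_init=k_init, tol=tol, max_iter=max_iter, drop_threshold=drop_threshold)
    return model.fit(seed=seed)


def variance_explained(results: FactorResults) -> pd.DataFrame:
    return results.variance_explained()


# ---------------------------------------------------------------------------
# sparse generalized canonical correlation (block sparse PLS, canonical mode)
# ---------------------------------------------------------------------------


@dataclass
class SgccaResults:
    loadings: dict[str, pd.DataFrame]  # modality -> features x components
    scores: dict[str, pd.DataFrame]  # modality -> samples x components
    samples: list[str]
    n_dropped_samples: int

    def summary(self) -> str:
        mods = list(self.loadings)
        ncomp = self.loadings[mods[0]].shape[1]
        lines = [f"sGCCA model: {len(mods)} blocks, {ncomp} components, "
                 f"{len(self.samples)} complete-case samples ({self.n_dropped_samples} dropped)"]
        for m in mods:
            nz = int((self.loadings[m].iloc[:, 0] != 0).sum())
            lines.append(f"  {m}: {nz} nonzero loadings on component 1")
        return "\n".join(lines)


class SparseGcca:
    """Sparse GCCA with a fully connected design and hard top-k sparsity."""

    def __init__(self, layers: list[OmicsLayer], sheet: SampleSheet, keep: int = 30, ncomp: int = 2,
                 tol: float = 1e-6, max_iter: int = 200):
        self.keep = keep
        self.ncomp = ncomp
        self.tol = tol
        self.max_iter = max_iter
        avail = None
        for ly in layers:
            cols = set(sheet.available(ly.modality))
            cols &= set(ly.values.columns[ly.values.notna().any(axis=0)])
            avail = cols if avail is None else (avail & cols)
        self.samples = [s for s in sheet.table.index if s in (avail or set())]
        self.n_dropped = len(sheet.table) - len(self.samples)
        if len(self.samples) < 3:
            raise ValueError("fewer than 3 complete-case samples")
        logger.info("sGCCA: %d complete-case samples (%d dropped)", len(self.samples), self.n_dropped)
        self.blocks: dict[str, np.ndarray] = {}
        self.features: dict[str, list[str]] = {}
        for ly in layers:
            x = ly.values[self.samples].to_numpy(dtype=float).T  # samples x features
            mu = np.nanmean(x, axis=0)
            x = np.where(np.isfinite(x), x, mu)
            x = x - x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = x / sd
            if keep > x.shape[1]:
                raise ValueError(f"keep={keep} exceeds {ly.modality} feature count {x.shape[1]}")
            self.blocks[ly.modality] = x
            self.features[ly.modality] = list(ly.values.index)

    @staticmethod
    def _threshold(a: np.ndarray, keep: int) -> np.ndarray:
        if keep >= a.size:
            out = a.copy()
        else:
            # ties broken by feature index (stable order on (-|a|, index))
            order = np.lexsort((np.arange(a.size), -np.abs(a)))
            out = np.zeros_like(a)
            sel = order[:keep]
            out[sel] = a[sel]
        nrm = np.linalg.norm(out)
        return out / nrm if nrm > 0 else out

    def fit(self, seed: int = 0) -> SgccaResults:
        names = list(self.blocks)
        x = {m: self.blocks[m].copy() for m in names}
        load = {m: np.zeros((x[m].shape[1], self.ncomp)) for m in names}
        scor = {m: np.zeros((x[m].shape[0], self.ncomp)) for m in names}
        for comp in range(self.ncomp):
            a = {}
            for m in names:
                _, _, vt = np.linalg.svd(x[m], full_matrices=False)
                a[m] = self._threshold(vt[0], self.keep)
            for _ in range(self.max_iter):
                delta = 0.0
                for m in names:
                    grad = np.zeros(x[m].shape[1])
                    for m2 in names:
                        if m2 == m:
                            continue
                        grad += x[m].T @ (x[m2] @ a[m2])
                    new = self._threshold(grad, self.keep)
                    if new @ a[m] < 0:
                        new = -new
                    delta = max(delta, float(np.max(np.abs(new - a[m]))))
                    a[m] = new
                if delta < self.tol:
                    break
            for m in names:
                v = a[m]
                if v[np.argmax(np.abs(v))] < 0:
                    v = -v
                t = x[m] @ v
                load[m][:, comp] = v
                scor[m][:, comp] = t
                denom = float(t @ t)
                if denom > 0:  # canonical-mode deflation by the block's own score
                    x[m] = x[m] - np.outer(t, t @ x[m]) / denom
        comp_names = [f"comp{c + 1}" for c in range(self.ncomp)]
        return SgccaResults(
            loadings={m: pd.DataFrame(load[m], index=self.features[m], columns=comp_names) for m in names},
            scores={m: pd.DataFrame(scor[m], index=self.samples, columns=comp_names) for m in names},
            samples=self.samples,
            n_dropped_samples=self.n_dropped,
        )


def fit_sgcca(layers, sheet, keep: int = 30, ncomp: int = 2, seed: int = 0) -> SgccaResults:
    return SparseGcca(layers, sheet, keep=keep, ncomp=ncomp).fit(seed=seed)


# ---------------------------------------------------------------------------
# per-modality PCA and covariate correlation
# ---------------------------------------------------------------------------


def pca_layer(layer: OmicsLayer, n_components: int | None = None):
    """SVD-based PCA of one layer (samples as observations).

    Features with missing entries are mean-imputed for the PCA only.
    Returns (scores DataFrame, percent variance per component).
    """
    obs_cols = layer.values.columns[layer.values.notna().any(axis=0)]
    x = layer.values[obs_cols].to_numpy(dtype=float).T  # samples x features
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isfinite(x), x, mu)
    x = x - x.mean(axis=0)
    k = n_components or min(x.shape)
    k = min(k, min(x.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    pct = 100.0 * pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=obs_cols, columns=cols), pct


def correlate_factor_covariate(
    results: FactorResults, sheet: SampleSheet, covariate: str = "balf_cells", factor: str | int = 0
):
    """Regress per-(group, timepoint) mean factor scores on the covariate mean.

    Returns (R^2, slope, cell-level means DataFrame).
    """
    fname = results.factor_names[factor] if isinstance(factor, int) else factor
    t = sheet.table.copy()
    t["score"] = results.scores[fname].reindex(t.index)
    cells = t.groupby(["group", "timepoint"], observed=True).agg(
        mean_score=("score", "mean"), mean_covariate=(covariate, "mean")
    )
    cells = cells.dropna()
    if len(cells) < 3:
        raise ValueError("fewer than 3 group x timepoint cells with covariate")
    res = stats.linregress(cells["mean_covariate"], cells["mean_score"])
    return float(res.rvalue**2), float(res.slope), cells
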