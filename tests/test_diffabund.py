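"""Preprocessing and moderated-t differential abundance."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import toxomix as tx
from toxomix import diffabund as da
from toxomix import syndata as sd

from conftest import make_contrast


def tiny_sheet(n_per_group=4, modalities=("mrna", "metabolite", "lipid")):
    rows = []
    for g in ("Sham", "3R4F"):
        for i in range(n_per_group):
            rows.append({"sample_id": f"{g}_{i}", "group": g, "timepoint": 6, "animal_id": f"{g}_{i}"})
    t = pd.DataFrame(rows).set_index("sample_id")
    for m in sd.MODALITIES:
        t[f"avail_{m}"] = True
    return sd.SampleSheet(table=t)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def test_metabolite_missing_values_imputed_with_feature_minimum():
    sheet = tiny_sheet()
    samples = list(sheet.table.index)[:3]
    vals = pd.DataFrame([[2.0, np.nan, 5.0]], index=["met_1"], columns=samples)
    vals = vals.reindex(columns=sheet.table.index)
    sheet.table[f"avail_metabolite"] = sheet.table.index.isin(samples)
    layer = sd.OmicsLayer("metabolite", vals, pd.DataFrame(index=vals.index), scale="native")
    out = da.preprocess_layer(layer, sheet)
    np.testing.assert_allclose(out.values.loc["met_1", samples], np.log2([2.0, 2.0, 5.0]))


def test_lipid_normalized_per_total_protein_before_log2():
    sheet = tiny_sheet()
    cols = sheet.table.index
    vals = pd.DataFrame([[10.0] * len(cols)], index=["lipid_1"], columns=cols)
    tp = pd.Series(2.0, index=cols)
    layer = sd.OmicsLayer("lipid", vals, pd.DataFrame(index=vals.index), scale="native", total_protein=tp)
    out = da.preprocess_layer(layer, sheet)
    np.testing.assert_allclose(out.values.loc["lipid_1"], np.log2(5.0))
    with pytest.raises(ValueError):
        bad = sd.OmicsLayer("lipid", vals, pd.DataFrame(index=vals.index), scale="native",
                            total_protein=pd.Series(0.0, index=cols))
        da.preprocess_layer(bad, sheet)


def test_mrna_layer_passes_through_unchanged(default_study):
    layer = default_study.layer("mrna")
    out = da.preprocess_layer(layer, default_study.sheet)
    pd.testing.assert_frame_equal(out.values, layer.values)


def test_preprocess_touches_only_masked_entries_and_preserves_order(default_study):
    layer = default_study.layer("metabolite")
    out = da.preprocess_layer(layer, default_study.sheet)
    assert list(out.values.columns) == list(layer.values.columns)
    obs = layer.values.notna()
    # observed entries are exactly log2 of the originals
    a = layer.values.where(obs)
    b = out.values.where(obs)
    np.testing.assert_allclose(b.to_numpy(), np.log2(a.to_numpy()), equal_nan=True)


def test_metabolite_with_no_observed_value_is_dropped(caplog):
    sheet = tiny_sheet()
    cols = sheet.table.index
    vals = pd.DataFrame(
        [[np.nan] * len(cols), [1.0] * len(cols)], index=["met_empty", "met_ok"], columns=cols
    )
    layer = sd.OmicsLayer("metabolite", vals, pd.DataFrame(index=vals.index), scale="native")
    out = da.preprocess_layer(layer, sheet)
    assert list(out.values.index) == ["met_ok"]


# ---------------------------------------------------------------------------
# empirical-Bayes prior
# ---------------------------------------------------------------------------


def test_trigamma_inversion_recovers_known_point():
    # trigamma(1) = pi^2/6, so a target of pi^2/6 must invert to 1
    assert abs(da._trigamma_inverse(np.pi**2 / 6) - 1.0) < 1e-8


def test_identical_variances_give_infinite_prior_df():
    prior = da.estimate_prior(np.full(50, 0.3), d=6)
    assert np.isinf(prior.d0)
    assert abs(prior.s02 - 0.3) < 1e-12


def test_prior_df_recovered_from_simulated_variance_mixture():
    """s_g^2 ~ s0^2 * F-mixture with true d0=4, d=7: the moment-matching
    estimator recovers d0 with median in [3,5] over 20 seeds."""
    d0_true, d, s02 = 4.0, 7.0, 0.5
    est = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        true_var = s02 * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = true_var * rng.chisquare(d, size=5000) / d
        est.append(da.estimate_prior(s2, d).d0)
    assert 3.0 <= np.median(est) <= 5.0


def test_posterior_variance_lies_between_prior_and_observed():
    prior = da.EBayesPrior(d0=4.0, s02=1.0)
    s2 = np.array([0.1, 1.0, 10.0])
    post = prior.posterior_variance(s2, d=6)
    lo = np.minimum(s2, prior.s02)
    hi = np.maximum(s2, prior.s02)
    assert np.all(post >= lo) and np.all(post <= hi)


def test_estimate_prior_matches_limma_on_shared_data(tmp_path):
    """Independent oracle: limma's eBayes on the same matrix gives the same
    prior df, prior variance and moderated t."""
    rng = np.random.default_rng(3)
    n1 = n2 = 5
    scale = np.sqrt(rng.chisquare(4, size=300) / 4)
    y = rng.normal(0, 1, size=(300, n1 + n2)) * scale[:, None]
    y[:50, :n1] += 1.0
    pd.DataFrame(y).to_csv(tmp_path / "y.tsv", sep="\t", index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.delim("{tmp_path}/y.tsv"))
        design <- cbind(1, c(rep(1,{n1}), rep(0,{n2})))
        fit <- eBayes(lmFit(y, design))
        out <- data.frame(t=fit$t[,2], d0=fit$df.prior, s02=fit$s2.prior)
        write.table(out, "{tmp_path}/out.tsv", sep="\\t", row.names=FALSE)
    """)
    (tmp_path / "s.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "s.R")], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")

    m1, m2 = y[:, :n1].mean(1), y[:, n1:].mean(1)
    ss = ((y[:, :n1] - m1[:, None]) ** 2).sum(1) + ((y[:, n1:] - m2[:, None]) ** 2).sum(1)
    d = n1 + n2 - 2
    s2 = ss / d
    prior = da.estimate_prior(s2, d)
    assert abs(prior.d0 - ref["d0"][0]) < 1e-6 * ref["d0"][0]
    assert abs(prior.s02 - ref["s02"][0]) < 1e-6
    t_mod = (m1 - m2) / np.sqrt(prior.posterior_variance(s2, d) * (1 / n1 + 1 / n2))
    np.testing.assert_allclose(t_mod, ref["t"], atol=1e-9)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


def _layer_from_matrix(y, sheet, modality="mrna"):
    vals = pd.DataFrame(y, index=[f"f{i}" for i in range(y.shape[0])], columns=sheet.table.index)
    ann = pd.DataFrame({"gene": vals.index, "node_id": vals.index}, index=vals.index)
    return sd.OmicsLayer(modality, vals, ann, scale="log2")


def test_zero_prior_df_recovers_ordinary_two_sample_t():
    sheet = tiny_sheet()
    rng = np.random.default_rng(0)
    y = rng.normal(size=(100, 8))
    layer = _layer_from_matrix(y, sheet)
    prior = da.EBayesPrior(d0=0.0, s02=1.0)
    ct = da.fit_contrast(layer, sheet, "3R4F", 6, prior=prior)
    treat = [s for s in sheet.table.index if s.startswith("3R4F")]
    sham = [s for s in sheet.table.index if s.startswith("Sham")]
    ref = stats.ttest_ind(layer.values[treat], layer.values[sham], axis=1, equal_var=True)
    np.testing.assert_allclose(ct.table["t"], ref.statistic, atol=1e-10)
    np.testing.assert_allclose(ct.table["P.Value"], ref.pvalue, atol=1e-10)


def test_null_simulation_controls_false_discovery_rate():
    fracs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        sheet = tiny_sheet(n_per_group=5)
        layer = _layer_from_matrix(rng.normal(size=(400, 10)), sheet)
        ct = da.fit_contrast(layer, sheet, "3R4F", 6)
        fracs.append(ct.table["significant"].mean())
    assert np.mean(fracs) <= 0.05


def test_planted_features_are_preferentially_significant(default_study, prepped_layers, default_contrasts):
    ct = next(c for c in default_contrasts if c.modality == "mrna" and c.group == "3R4F" and c.timepoint == 6)
    active = set(default_study.truth["active_features"]["mrna"]["factor1"])
    sig = ct.table["significant"]
    frac_active = sig[sig.index.isin(active)].mean()
    frac_inactive = sig[~sig.index.isin(active)].mean()
    assert frac_active > frac_inactive


def test_contrast_with_tiny_arm_is_skipped():
    sheet = tiny_sheet(n_per_group=4)
    sheet.table.loc[sheet.table["group"] == "3R4F", "avail_mrna"] = [True, False, False, False]
    rng = np.random.default_rng(0)
    layer = _layer_from_matrix(rng.normal(size=(10, 8)), sheet)
    ct = da.fit_contrast(layer, sheet, "3R4F", 6)
    assert ct.status.startswith("skipped")
    assert len(ct.table) == 0


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """Direct step-up formula: p_(i)_adj = min_{j>=i} min(1, m/j * p_(j))."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m / rank * p[i])
        adj[i] = running
    return adj


def test_bh_matches_stepup_oracle_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(1, 21))
        p = rng.random(n)
        np.testing.assert_allclose(da.bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_hand_example_and_basic_properties():
    np.testing.assert_allclose(da.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(da.bh_adjust([0.37]), [0.37])
    rng = np.random.default_rng(2)
    p = rng.random(50)
    adj = da.bh_adjust(p)
    assert np.all(adj >= p) and np.all(adj <= 1)
    with pytest.raises(ValueError):
        da.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# cross-modal correlation and counting
# ---------------------------------------------------------------------------


def test_identical_fold_changes_give_perfect_r2():
    a = make_contrast([1.0, -0.5, 2.0, 0.3], modality="mrna")
    b = make_contrast([1.0, -0.5, 2.0, 0.3], modality="protein")
    r2, slope, n = da.crossmodal_fc_correlation(a, b, gene_map={f"g{i}": f"g{i}" for i in range(4)})
    assert abs(r2 - 1.0) < 1e-12 and abs(slope - 1.0) < 1e-12 and n == 4


def test_independent_fold_changes_give_near_zero_r2():
    r2s = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = make_contrast(rng.normal(size=1000))
        b = make_contrast(rng.normal(size=1000), modality="protein")
        r2, _, _ = da.crossmodal_fc_correlation(a, b, gene_map={f"g{i}": f"g{i}" for i in range(1000)})
        r2s.append(r2)
    assert np.mean(r2s) < 0.02


def test_crossmodal_requires_three_pairs():
    a = make_contrast([1.0, 2.0])
    b = make_contrast([1.0, 2.0], modality="protein")
    with pytest.raises(ValueError):
        da.crossmodal_fc_correlation(a, b, gene_map={"g0": "g0", "g1": "g1"})


def test_count_significant_equals_flag_totals(default_contrasts):
    counts = da.count_significant(default_contrasts)
    for ct in default_contrasts:
        row = counts[
            (counts["modality"] == ct.modality)
            & (counts["group"] == ct.group)
            & (counts["timepoint"] == ct.timepoint)
        ]
        assert int(row["n_significant"].iloc[0]) == int(ct.table["significant"].sum())


def test_mrna_count_exceeds_mirna_count_for_reference_smoke(default_contrasts):
    counts = da.count_significant(default_contrasts)
    c = counts[counts["group"] == "3R4F"].groupby("modality")["n_significant"].sum()
    assert c["mrna"] > c["mirna"]
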