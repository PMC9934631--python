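"""Interaction LMM, response-QTL calling, sharing and priming labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimqtl import qtl as mqtl
from stimqtl import response as mresp
from stimqtl.types import GenotypeMatrix


def _paired_data(rng, n_donors=40, donor_sd=0.3, beta_veh=0.5,
                 beta_inter=0.0):
    donors = np.repeat(np.arange(n_donors), 2)
    cond = np.tile([0.0, 1.0], n_donors)
    g_donor = rng.binomial(2, 0.3, size=n_donors).astype(float)
    g = g_donor[donors // 1][np.arange(2 * n_donors)]
    g = g_donor[np.repeat(np.arange(n_donors), 2)]
    u = rng.normal(0, donor_sd, size=n_donors)
    y = (beta_veh * g + beta_inter * g * cond + 0.3 * cond
         + u[np.repeat(np.arange(n_donors), 2)]
         + rng.normal(0, 0.5, size=2 * n_donors))
    donor_labels = np.array([f"d{i}" for i in np.repeat(
        np.arange(n_donors), 2)])
    return y, g, cond, donor_labels


def test_betas_satisfy_additivity(rng):
    y, g, cond, donors = _paired_data(rng, beta_veh=0.4, beta_inter=0.3)
    fit = mresp.fit_interaction_lmm(y, g, cond, donors)
    assert fit["beta_stim"] == pytest.approx(
        fit["beta_vehicle"] + fit["beta_interaction"])
    assert fit["lrt_chi2"] >= 0.0


def test_lmm_recovers_planted_interaction(rng):
    ps = []
    for rep in range(10):
        y, g, cond, donors = _paired_data(
            np.random.default_rng(rep), n_donors=80, beta_veh=0.5,
            beta_inter=0.5)
        ps.append(mresp.fit_interaction_lmm(y, g, cond, donors)
                  ["p_interaction"])
    assert np.median(ps) < 1e-3


def test_no_random_effect_mode_is_exact_ols_lrt(rng):
    """random_effect=False reproduces the plain OLS likelihood-ratio test."""
    y, g, cond, donors = _paired_data(rng, n_donors=60, donor_sd=0.0,
                                      beta_veh=0.4, beta_inter=0.2)
    ols = mresp.fit_interaction_lmm(y, g, cond, donors,
                                    random_effect=False, bartlett=False)
    n = len(y)

    def ols_ll(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)

    Xf = np.column_stack([np.ones(n), g, cond, g * cond])
    lrt = 2 * (ols_ll(Xf) - ols_ll(Xf[:, :3]))
    assert ols["lrt_chi2"] == pytest.approx(lrt, abs=1e-8)
    assert ols["p_interaction"] == pytest.approx(
        stats.chi2.sf(lrt, 1), abs=1e-10)


def test_lmm_matches_statsmodels_mixedlm(rng):
    """ML fit and interaction LRT agree with the statsmodels MixedLM oracle."""
    import statsmodels.api as sm
    y, g, cond, donors = _paired_data(rng, n_donors=50, donor_sd=0.4,
                                      beta_veh=0.5, beta_inter=0.3)
    fit = mresp.fit_interaction_lmm(y, g, cond, donors, bartlett=False)
    Xf = np.column_stack([np.ones_like(y), g, cond, g * cond])
    full = sm.MixedLM(y, Xf, groups=donors).fit(reml=False)
    red = sm.MixedLM(y, Xf[:, :3], groups=donors).fit(reml=False)
    lrt_ref = 2 * (full.llf - red.llf)
    assert fit["beta_vehicle"] == pytest.approx(full.params[1], abs=1e-4)
    assert fit["beta_interaction"] == pytest.approx(full.params[3],
                                                    abs=1e-4)
    assert fit["lrt_chi2"] == pytest.approx(lrt_ref, abs=1e-3)


def test_lmm_interaction_agrees_with_donor_fixed_effects(rng):
    """The interaction contrast survives within-donor demeaning, so a
    donor-fixed-effects fit gives near-identical interaction inference."""
    y, g, cond, donors = _paired_data(rng, n_donors=60, donor_sd=0.4,
                                      beta_veh=0.5, beta_inter=0.3)
    lmm = mresp.fit_interaction_lmm(y, g, cond, donors)
    # donor fixed effects: within-donor demeaning removes g and intercept
    df = pd.DataFrame({"y": y, "gc": g * cond, "c": cond, "d": donors})
    dem = df.groupby("d").transform(lambda s: s - s.mean())
    X = np.column_stack([dem["c"], dem["gc"]])
    beta, *_ = np.linalg.lstsq(X, dem["y"], rcond=None)
    assert lmm["beta_interaction"] == pytest.approx(beta[1], abs=0.05)


def test_constant_genotype_in_one_arm_skipped(rng):
    y, g, cond, donors = _paired_data(rng)
    g = np.zeros_like(g)
    fit = mresp.fit_interaction_lmm(y, g, cond, donors)
    assert fit["skip_reason"] != ""


def test_call_response_qtls_bh():
    recs = pd.DataFrame({"feature": ["a", "b", "c"],
                         "variant": ["v1", "v2", "v3"],
                         "p_interaction": [0.001, 0.5, 0.04]})
    out = mresp.call_response_qtls(recs, fdr=0.1)
    assert out.set_index("feature")["is_response"].tolist() == [
        True, False, True]
    single = mresp.call_response_qtls(recs.iloc[[2]], fdr=0.1)
    assert single["is_response"].iloc[0]  # p=0.04 with m=1
    empty = mresp.call_response_qtls(recs.iloc[0:0])
    assert len(empty) == 0


def test_sharing_membership_and_increment():
    sig = {"vehicle": {"A", "B"}, "stimA": {"A", "C"}, "stimB": {"A"}}
    table, increment = mresp.classify_sharing(sig, "vehicle")
    row = table.set_index("feature").loc["A"]
    assert bool(row["vehicle"]) and bool(row["stimA"]) and bool(row["stimB"])
    # stimulated-only = {C}; vehicle has 2 -> 50%
    assert increment == pytest.approx(50.0)
    with pytest.raises(ValueError):
        mresp.classify_sharing(sig, "missing_condition")


def _toy_qtl_result(condition, assay, sig_map, gm):
    """QTLResult with prescribed significant feature -> variant lists."""
    rows = []
    var_row = {v: i for i, v in enumerate(gm.variants["id"])}
    for feature, variants in sig_map.items():
        for v in variants:
            rows.append({"feature": feature, "variant": v,
                         "variant_row": var_row[v], "beta": 1.0, "se": 0.1,
                         "t": 10.0, "p": 1e-8, "tss_distance": 0})
    pairs = pd.DataFrame(rows, columns=["feature", "variant", "variant_row",
                                        "beta", "se", "t", "p",
                                        "tss_distance"])
    corr = pd.DataFrame({
        "feature": list(sig_map), "p_min_nominal": 1e-8, "m_eff": 1,
        "p_local": 1e-8, "method": "eigenmt",
        "p_global": 1e-7, "significant": True, "nominal_threshold": 1e-6})
    return mqtl.QTLResult(condition=condition, assay=assay, scan=pairs,
                          corrections=corr, significant_pairs=pairs,
                          signals=pairs.assign(tier="independent_index",
                                               signal_rank=0))


def _toy_panel(rng):
    shared = rng.binomial(2, 0.5, size=200).astype(float)
    other = rng.binomial(2, 0.5, size=200).astype(float)
    variants = pd.DataFrame({
        "chrom": "chr1", "pos": [500_000, 500_100],
        "id": ["caSNP", "otherSNP"], "ref": "A", "alt": "G"})
    return GenotypeMatrix(variants, [f"s{i}" for i in range(200)],
                          np.vstack([shared, other]))


def test_priming_toy_classification(rng):
    gm = _toy_panel(rng)
    peaks = pd.DataFrame({"feature_id": ["peak1"], "chrom": ["chr1"],
                          "start": [499_000], "end": [501_000]})
    genes = pd.DataFrame({"gene_id": ["gene1"], "chrom": ["chr1"],
                          "start": [600_000], "end": [620_000],
                          "strand": ["+"]})
    ca = {"stim": _toy_qtl_result("stim", "atac", {"peak1": ["caSNP"]}, gm),
          "veh": _toy_qtl_result("veh", "atac", {"peak1": ["caSNP"]}, gm)}
    eq = {"stim": _toy_qtl_result("stim", "rna", {"gene1": ["caSNP"]}, gm),
          "veh": _toy_qtl_result("veh", "rna", {}, gm)}
    calls = mresp.link_and_classify_priming(ca, eq, gm, peaks, genes,
                                            ("stim", "veh"))
    assert len(calls) == 1 and calls[0].label == "primed"

    # same topology but the eSNP is in low LD with the caSNP -> unlinked
    eq_low = {"stim": _toy_qtl_result("stim", "rna",
                                      {"gene1": ["otherSNP"]}, gm),
              "veh": _toy_qtl_result("veh", "rna", {}, gm)}
    calls = mresp.link_and_classify_priming(ca, eq_low, gm, peaks, genes,
                                            ("stim", "veh"))
    assert calls[0].label == "unlinked"
    assert calls[0].r2 < 0.8

    # caPeak stimulus-only with stimulus-only eGene -> stimulus_specific
    ca_stim = {"stim": _toy_qtl_result("stim", "atac",
                                       {"peak1": ["caSNP"]}, gm),
               "veh": _toy_qtl_result("veh", "atac", {}, gm)}
    calls = mresp.link_and_classify_priming(ca_stim, eq, gm, peaks, genes,
                                            ("stim", "veh"))
    assert calls[0].label == "stimulus_specific"

    # both assays in both conditions -> shared
    eq_both = {"stim": _toy_qtl_result("stim", "rna",
                                       {"gene1": ["caSNP"]}, gm),
               "veh": _toy_qtl_result("veh", "rna",
                                      {"gene1": ["caSNP"]}, gm)}
    calls = mresp.link_and_classify_priming(ca, eq_both, gm, peaks, genes,
                                            ("stim", "veh"))
    assert calls[0].label == "shared"


def test_priming_labels_are_a_partition(rng):
    gm = _toy_panel(rng)
    peaks = pd.DataFrame({"feature_id": ["peak1"], "chrom": ["chr1"],
                          "start": [499_000], "end": [501_000]})
    genes = pd.DataFrame({"gene_id": ["gene1", "gene2"],
                          "chrom": ["chr1", "chr1"],
                          "start": [600_000, 700_000],
                          "end": [620_000, 720_000],
                          "strand": ["+", "-"]})
    ca = {"stim": _toy_qtl_result("stim", "atac", {"peak1": ["caSNP"]}, gm),
          "veh": _toy_qtl_result("veh", "atac", {"peak1": ["caSNP"]}, gm)}
    eq = {"stim": _toy_qtl_result("stim", "rna", {"gene1": ["caSNP"],
                                                  "gene2": ["otherSNP"]}, gm),
          "veh": _toy_qtl_result("veh", "rna", {"gene2": ["otherSNP"]}, gm)}
    calls = mresp.link_and_classify_priming(ca, eq, gm, peaks, genes,
                                            ("stim", "veh"))
    seen = [(c.peak, c.gene) for c in calls]
    assert len(seen) == len(set(seen))  # one label per pair
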