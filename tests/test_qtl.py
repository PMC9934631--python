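"""cis pairing, association scan, local/global correction, secondary signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimqtl import qtl as mqtl
from stimqtl.normalize import NormalizedMatrix
from stimqtl.simulate import SimulationConfig, simulate_genotypes
from stimqtl.types import GenotypeMatrix


def _gm(dosage, positions=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=float)
    m, n = dosage.shape
    positions = positions if positions is not None else np.arange(1, m + 1)
    variants = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "id": [f"v{i}" for i in range(m)], "ref": "A", "alt": "G"})
    return GenotypeMatrix(variants, [f"s{i}" for i in range(n)], dosage)


# ---------------------------------------------------------------------------
# filters and cis windows

def test_variant_filters_maf_and_carriers(rng):
    n = 200
    common = rng.binomial(2, 0.3, size=n).astype(float)
    rare = np.zeros(n)
    rare[0] = 1.0                      # MAF 0.25%: fails MAF filter
    one_het = np.zeros(n)
    one_het[:4] = [1, 0, 0, 0]         # one carrier only
    two_het = np.zeros(n)
    two_het[:4] = [1, 1, 0, 0]         # two carriers, MAF 0.5% still fails
    gm = _gm(np.vstack([common, rare, one_het, two_het]))
    mask = mqtl.variant_filter_mask(gm, min_maf=0.001)
    assert mask.tolist() == [True, False, False, True]
    mask_default = mqtl.variant_filter_mask(gm)  # MAF >= 1%
    assert mask_default.tolist() == [True, False, False, False]


def test_cis_window_boundary_inclusive():
    features = pd.DataFrame({"feature_id": ["peak"], "chrom": ["chr1"],
                             "start": [100_000], "end": [101_000]})
    positions = np.array([100_000, 100_001, 126_000, 126_001, 75_000, 75_001])
    gm = _gm(np.tile([0.0, 1.0, 2.0, 1.0], (6, 50)), positions=positions)
    pairs = mqtl.build_cis_pairs(features, gm, window=25_000)
    got = set(pairs["variant"])
    # window = [start - w, end + w] with 1-based overlap: s - w < p <= e + w
    assert got == {"v0", "v1", "v2", "v5"}


def test_expressed_feature_filter():
    counts = np.array([[20] * 100, [3] * 100, [20] + [0] * 99])
    keep = mqtl.expressed_features(counts, np.ones(100), min_count=10,
                                   min_frac=0.01)
    assert keep.tolist() == [True, False, True]


# ---------------------------------------------------------------------------
# association scan

def _norm(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return NormalizedMatrix([f"f{i}" for i in range(values.shape[0])],
                            samples, values)


def test_scan_exact_linear_phenotype(rng):
    g = rng.binomial(2, 0.4, size=80).astype(float)
    gm = _gm(g[None, :])
    nm = _norm(0.5 * g[None, :])
    pairs = pd.DataFrame({"feature": ["f0"], "variant_row": [0],
                          "variant": ["v0"], "tss_distance": [0]})
    res = mqtl.assoc_scan(nm, gm, pairs)
    assert res["beta"].iloc[0] == pytest.approx(0.5)
    assert res["p"].iloc[0] < 1e-100


def test_scan_null_p_uniform(rng):
    cfg = SimulationConfig(n_donors=100, n_variants=500, n_peaks=1,
                           n_genes=1, seed=31)
    gm = simulate_genotypes(cfg)
    y = rng.normal(size=(20, 100))
    nm = _norm(y, samples=gm.samples)
    pairs = pd.DataFrame([
        {"feature": f"f{j}", "variant_row": i, "variant": f"v{i}",
         "tss_distance": 0}
        for j in range(20) for i in range(500)])
    res = mqtl.assoc_scan(nm, gm, pairs)
    ks = stats.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.001


def test_scan_skips_constant_genotype():
    gm = _gm(np.zeros((1, 30)))
    nm = _norm(np.random.default_rng(0).normal(size=(1, 30)))
    pairs = pd.DataFrame({"feature": ["f0"], "variant_row": [0],
                          "variant": ["v0"], "tss_distance": [0]})
    assert len(mqtl.assoc_scan(nm, gm, pairs)) == 0


# ---------------------------------------------------------------------------
# eigenMT-style local correction

def test_meff_one_for_rank_one_block(rng):
    base = rng.binomial(2, 0.5, size=300).astype(float)
    D = np.tile(base, (50, 1))
    rec = mqtl.eigenmt_local(np.full(50, 0.01), D, np.arange(50))
    assert rec["m_eff"] == 1
    assert rec["p_local"] == pytest.approx(0.01)


def test_meff_near_m_for_independent_variants(rng):
    D = rng.binomial(2, 0.5, size=(50, 500)).astype(float)
    rec = mqtl.eigenmt_local(np.full(50, 0.5), D, np.arange(50))
    assert 45 <= rec["m_eff"] <= 50


def test_meff_invariances(rng):
    cfg = SimulationConfig(n_donors=100, n_variants=60, n_peaks=1, n_genes=1,
                           seed=32)
    D = simulate_genotypes(cfg).dosage
    pos = np.arange(60)
    p = rng.uniform(size=60)
    base = mqtl.eigenmt_local(p, D, pos)
    scaled = mqtl.eigenmt_local(p, D * 3.7, pos)
    perm = rng.permutation(D.shape[1])
    permuted = mqtl.eigenmt_local(p, D[:, perm], pos)
    assert base["m_eff"] == scaled["m_eff"] == permuted["m_eff"]
    assert base["m_eff"] <= 60


# ---------------------------------------------------------------------------
# permutation-based local correction

def test_permutation_empirical_formula(rng):
    g = rng.binomial(2, 0.5, size=(5, 60)).astype(float)
    y = 2.0 * g[0] + rng.normal(0, 0.05, size=60)  # beats every permutation
    rec = mqtl.permutation_local(y, g, n_perm=1000,
                                 rng=np.random.default_rng(1))
    assert rec["p_empirical"] == pytest.approx(1.0 / 1001.0)


def test_permutation_single_variant_matches_nominal(rng):
    g = rng.binomial(2, 0.5, size=(1, 80)).astype(float)
    y = rng.normal(size=80) + 0.25 * g[0]
    rec = mqtl.permutation_local(y, g, n_perm=3000,
                                 rng=np.random.default_rng(2))
    assert rec["p_empirical"] == pytest.approx(rec["p_min_nominal"],
                                               abs=0.02)


def test_beta_approx_tracks_empirical(rng):
    cfg = SimulationConfig(n_donors=80, n_variants=40, n_peaks=1, n_genes=1,
                           seed=33)
    D = simulate_genotypes(cfg).dosage
    deltas = []
    for f in range(30):
        y = rng.normal(size=80)
        rec = mqtl.permutation_local(y, D, n_perm=1000,
                                     rng=np.random.default_rng(100 + f))
        if rec["p_empirical"] > 0.01:
            deltas.append(abs(rec["p_local"] - rec["p_empirical"]))
    assert max(deltas) < 0.05


# ---------------------------------------------------------------------------
# global correction

def test_global_correct_examples():
    ones = pd.DataFrame({"feature": ["a", "b"], "p_local": [1.0, 1.0],
                         "p_min_nominal": [0.9, 0.9], "m_eff": [1, 1],
                         "method": ["eigenmt"] * 2})
    out = mqtl.global_correct(ones)
    assert not out["significant"].any()
    single = pd.DataFrame({"feature": ["a"], "p_local": [0.05],
                           "p_min_nominal": [0.01], "m_eff": [5],
                           "method": ["eigenmt"]})
    out = mqtl.global_correct(single, fdr=0.1)
    assert out["significant"].iloc[0]


def test_nominal_threshold_backcalculation(rng):
    n_feat = 50
    m_eff = rng.integers(2, 30, size=n_feat)
    p_min = rng.uniform(1e-6, 0.05, size=n_feat)
    corr = pd.DataFrame({
        "feature": [f"f{i}" for i in range(n_feat)],
        "p_min_nominal": p_min, "m_eff": m_eff,
        "p_local": np.minimum(1.0, p_min * m_eff),
        "method": ["eigenmt"] * n_feat})
    out = mqtl.global_correct(corr, fdr=0.1)
    sig = out[out["significant"]]
    p_star = sig["p_local"].max()
    for row in sig.itertuples():
        # every variant flagged at the threshold satisfies p * m_eff <= p*
        thr = row.nominal_threshold
        assert thr * row.m_eff <= p_star + 1e-12 or \
            thr == pytest.approx(row.p_min_nominal)
        assert thr >= row.p_min_nominal - 1e-15


# ---------------------------------------------------------------------------
# independent signals

def test_prune_collapses_high_ld(rng):
    base = rng.binomial(2, 0.5, size=100).astype(float)
    noisy = base.copy()
    noisy[:3] = 2 - noisy[:3]          # r2 ~ 0.9
    indep = rng.binomial(2, 0.5, size=100).astype(float)
    gm = _gm(np.vstack([base, noisy, indep]))
    recs = pd.DataFrame({
        "feature": "f0", "variant_row": [0, 1, 2],
        "variant": ["v0", "v1", "v2"],
        "p": [1e-8, 1e-6, 1e-5], "beta": [1.0, 0.9, 0.5],
        "se": 0.1, "t": 5.0, "tss_distance": 0})
    out = mqtl.independent_signals(recs, gm, list(range(100)), mode="prune")
    assert out["variant"].tolist() == ["v0", "v2"]


def test_conditional_single_causal_rarely_finds_secondary():
    cfg = SimulationConfig(n_donors=90, n_variants=60, n_peaks=1, n_genes=1,
                           seed=34)
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        gm = simulate_genotypes(cfg, seed=200 + rep)
        rng = np.random.default_rng(rep)
        causal = 30
        y = 0.8 * gm.dosage[causal] + rng.normal(size=90)
        y = y - y.mean()
        D = gm.dosage - gm.dosage.mean(axis=1, keepdims=True)
        ssx = (D ** 2).sum(axis=1)
        beta = D @ y / np.where(ssx > 0, ssx, 1)
        rss = np.maximum(y @ y - beta ** 2 * ssx, 1e-12)
        se = np.sqrt(rss / 88 / np.where(ssx > 0, ssx, 1))
        p = 2 * stats.t.sf(np.abs(beta / se), 88)
        recs = pd.DataFrame({
            "feature": "f0", "variant_row": np.arange(60),
            "variant": [f"v{i}" for i in range(60)],
            "p": p, "beta": beta, "se": se, "t": beta / se,
            "tss_distance": 0})
        sig = recs[recs["p"] < 1e-3]
        if len(sig) == 0:
            continue
        out = mqtl.independent_signals(
            sig, gm, list(range(90)), mode="conditional",
            phenotype=y, nominal_threshold=1e-3)
        if (out["tier"] == "conditional_secondary").any():
            hits += 1
    assert hits <= 0.1 * n_rep
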