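"""Colocalization: candidate gates, conditional analysis, CLPP, salvage."""

import numpy as np
import pandas as pd
import pytest

from stimqtl import coloc as mcoloc
from stimqtl.simulate import SimulationConfig, simulate_coloc_locus, \
    simulate_genotypes
from stimqtl.types import GenotypeMatrix, GwasSumstats


def _gm(rng, m=20, n=100, positions=None):
    cfg = SimulationConfig(n_donors=n, n_variants=m, n_peaks=1, n_genes=1,
                           seed=int(rng.integers(1 << 20)))
    gm = simulate_genotypes(cfg)
    if positions is not None:
        gm.variants["pos"] = positions
    return gm


def _sumstats(gm, p_values, beta=0.1, se=0.02):
    t = pd.DataFrame({
        "id": gm.variants["id"], "chrom": gm.variants["chrom"],
        "pos": gm.variants["pos"], "effect_allele": gm.variants["alt"],
        "other_allele": gm.variants["ref"], "freq": gm.allele_freq(),
        "beta": beta, "se": se, "p": p_values, "n": 10_000})
    return GwasSumstats(t)


def test_candidate_requires_genomewide_significance(rng):
    gm = _gm(rng)
    p = np.full(gm.n_variants, 0.5)
    p[0] = 6e-8  # just above the genome-wide gate
    gwas = _sumstats(gm, p)
    idx = pd.DataFrame({"feature": ["f"], "variant": [gm.variants["id"][0]]})
    assert mcoloc.find_candidates(gwas, idx, gm) == []
    p[0] = 4e-8
    cands = mcoloc.find_candidates(_sumstats(gm, p), idx, gm)
    assert len(cands) == 1 and cands[0].index_r2 == pytest.approx(1.0)


def test_candidate_distance_boundary_inclusive(rng):
    positions = np.array([1_000_000, 2_000_000, 2_000_001])
    gm = _gm(rng, m=3, positions=positions)
    p = np.array([0.5, 1e-9, 1e-9])
    gwas = _sumstats(gm, p)
    idx = pd.DataFrame({"feature": ["f"], "variant": [gm.variants["id"][0]]})
    cands = mcoloc.find_candidates(gwas, idx, gm, r2_min=-1.0)
    # 2,000,000 is exactly 1 Mb away (included); 2,000,001 excluded
    assert len(cands) == 1 and cands[0].distance <= 1_000_000


def test_no_shared_variants_errors(rng):
    gm = _gm(rng)
    other = _gm(rng)
    other.variants["id"] = [f"x{i}" for i in range(other.n_variants)]
    gwas = _sumstats(other, np.full(other.n_variants, 1e-9))
    idx = pd.DataFrame({"feature": ["f"], "variant": [gm.variants["id"][0]]})
    with pytest.raises(ValueError, match="no shared variants"):
        mcoloc.find_candidates(gwas, idx, gm)


# ---------------------------------------------------------------------------
# approximate conditional analysis

def _locus_frame(gm, beta, se):
    return pd.DataFrame({
        "id": gm.variants["id"], "freq": gm.allele_freq(),
        "beta": beta, "se": se, "n": np.full(gm.n_variants, 10_000.0)})


def test_conditional_empty_set_is_identity(rng):
    gm = _gm(rng, m=10)
    ss = _locus_frame(gm, rng.normal(0, 0.05, 10), np.full(10, 0.02))
    out = mcoloc.approx_conditional(ss, gm.dosage, gm.allele_freq(), [])
    np.testing.assert_array_equal(out["beta_cond"], ss["beta"])
    np.testing.assert_array_equal(out["se_cond"], ss["se"])


def test_conditional_uncorrelated_target_unchanged(rng):
    cfg = SimulationConfig(n_donors=2000, n_variants=40,
                           within_block_copy_prob=0.0, n_peaks=1, n_genes=1,
                           seed=51)
    gm = simulate_genotypes(cfg)
    ss = _locus_frame(gm, rng.normal(0, 0.05, 40), np.full(40, 0.02))
    out = mcoloc.approx_conditional(ss, gm.dosage, gm.allele_freq(), [0])
    r = np.array([np.corrcoef(gm.dosage[j], gm.dosage[0])[0, 1]
                  for j in range(40)])
    nearly_indep = np.flatnonzero(np.abs(r) < 0.02)[1:]
    for t in nearly_indep:
        assert out.at[t, "beta_cond"] == pytest.approx(ss.at[t, "beta"],
                                                       abs=5e-3)


def test_conditional_masks_collinear_targets(rng):
    base = rng.binomial(2, 0.5, size=500).astype(float)
    proxy = base.copy()
    proxy[:10] = 2 - proxy[:10]
    indep = rng.binomial(2, 0.5, size=500).astype(float)
    variants = pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3],
                             "id": ["a", "b", "c"], "ref": "A", "alt": "G"})
    gm = GenotypeMatrix(variants, [f"s{i}" for i in range(500)],
                        np.vstack([base, proxy, indep]))
    ss = _locus_frame(gm, np.array([0.1, 0.09, 0.0]),
                      np.array([0.02, 0.02, 0.02]))
    out = mcoloc.approx_conditional(ss, gm.dosage, gm.allele_freq(), [0])
    assert bool(out.at[1, "masked"])        # r2 ~ 0.92 > 0.9
    assert not bool(out.at[2, "masked"])


def test_conditional_on_causal_abolishes_locus():
    # large reference panel so LD estimation noise does not dominate
    locus = simulate_coloc_locus(seed=5, flavor="shared", n_qtl=2000,
                                 gwas_var=0.01)
    gm = locus["genotypes"]
    gt = locus["gwas"].table
    crow = int(np.flatnonzero(gt["id"] == locus["gwas_causal"])[0])
    out = mcoloc.approx_conditional(gt, gm.dosage[gt.index.to_numpy()],
                                    gt["freq"].to_numpy(), [crow])
    z = (out["beta_cond"] / out["se_cond"]).abs().dropna()
    assert (z < 3).mean() > 0.95


def test_conditional_excludes_divergent_frequencies(rng):
    gm = _gm(rng, m=5)
    ss = _locus_frame(gm, rng.normal(0, 0.05, 5), np.full(5, 0.02))
    ref_freq = gm.allele_freq().copy()
    ref_freq[2] += 0.3
    out = mcoloc.approx_conditional(ss, gm.dosage, ref_freq, [0])
    assert bool(out.at[2, "excluded"])


# ---------------------------------------------------------------------------
# CLPP

def test_clpp_single_snp_is_one(rng):
    g = pd.DataFrame({"id": ["v"], "beta": [0.5], "se": [0.05], "p": [1e-9]})
    q = pd.DataFrame({"id": ["v"], "beta": [0.8], "se": [0.1], "p": [1e-6]})
    cl, snp, _ = mcoloc.clpp(g, q, {"v": rng.binomial(2, 0.5, 50).astype(float)})
    assert cl == pytest.approx(1.0)
    assert snp == "v"


def test_clpp_posteriors_and_duplication_invariance(rng):
    ids = [f"v{i}" for i in range(6)]
    g = pd.DataFrame({"id": ids, "beta": rng.normal(0.3, 0.1, 6),
                      "se": 0.05, "p": [1e-9, 1e-8, 1e-4, 0.01, 0.2, 0.6]})
    q = pd.DataFrame({"id": ids, "beta": rng.normal(0.3, 0.1, 6),
                      "se": 0.08, "p": [1e-5, 1e-4, 0.02, 0.03, 0.5, 0.9]})
    ref = {v: rng.binomial(2, 0.4, 60).astype(float) for v in ids}
    base = mcoloc.clpp(g, q, ref)
    # posteriors over the included set (p<0.05 in both) multiply to CLPP <= 1
    assert 0 < base[0] <= 1
    # adding SNPs outside the p<0.05 intersection changes nothing
    g2 = pd.concat([g, g.assign(id=[f"x{i}" for i in range(6)], p=0.9)],
                   ignore_index=True)
    q2 = pd.concat([q, q.assign(id=[f"x{i}" for i in range(6)], p=0.9)],
                   ignore_index=True)
    dup = mcoloc.clpp(g2, q2, ref)
    assert dup[0] == pytest.approx(base[0]) and dup[1] == base[1]


def test_clpp_empty_intersection(rng):
    g = pd.DataFrame({"id": ["v"], "beta": [0.5], "se": [0.05], "p": [1e-9]})
    q = pd.DataFrame({"id": ["v"], "beta": [0.0], "se": [0.1], "p": [0.8]})
    cl, snp, r2 = mcoloc.clpp(g, q, {})
    assert np.isnan(cl) and snp == ""


# ---------------------------------------------------------------------------
# salvage

def test_salvage_gates():
    cand = mcoloc.ColocCandidate("feat", "v", "v", 0, 1.0, 1.0)
    ok = mcoloc.ColocResult(candidate=cand, verdict="colocalized")
    calls = []

    def retest(cond):
        calls.append(cond)
        return mcoloc.ColocResult(candidate=cand, verdict="colocalized")

    out = mcoloc.salvage_condition_specific(
        {"vehicle": ok}, {"stimA": 5e-7, "stimB": 5e-6}, retest)
    assert list(out) == ["stimA"] and out["stimA"].salvage
    assert calls == ["stimA"]  # 5e-6 fails the p<1e-6 gate

    none = mcoloc.salvage_condition_specific(
        {"vehicle": mcoloc.ColocResult(candidate=cand)},
        {"stimA": 1e-9}, retest)
    assert none == {}  # not colocalized anywhere -> no salvage
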