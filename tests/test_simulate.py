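"""Generator statistical properties: LD, HWE, counts, GWAS, reproducibility."""

import json
import os

import numpy as np
import pytest
from scipy import stats

from stimqtl import io as sio
from stimqtl.normalize import hwe_exact_test
from stimqtl.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_dataset,
    simulate_features,
    simulate_genotypes,
    simulate_gwas,
    stage_rng,
    write_dataset,
)


def _pairwise_r(dosage, pairs, rng):
    rs = []
    for _ in range(pairs):
        i, j = rng.choice(len(dosage), size=2, replace=False)
        if dosage[i].std() == 0 or dosage[j].std() == 0:
            continue
        rs.append(np.corrcoef(dosage[i], dosage[j])[0, 1])
    return np.array(rs)


def test_full_ld_when_copy_prob_one():
    cfg = SimulationConfig(n_donors=40, n_variants=40, ld_block_size=20,
                           within_block_copy_prob=1.0, n_peaks=1, n_genes=1,
                           seed=1)
    g = simulate_genotypes(cfg)
    block = g.dosage[:20]
    for i in range(1, 20):
        assert np.corrcoef(block[0], block[i])[0, 1] ** 2 == pytest.approx(1.0)


def test_no_ld_when_copy_prob_zero():
    cfg = SimulationConfig(n_donors=80, n_variants=400,
                           within_block_copy_prob=0.0, n_peaks=1, n_genes=1,
                           seed=2)
    g = simulate_genotypes(cfg)
    rs = _pairwise_r(g.dosage, 100, np.random.default_rng(0))
    assert np.mean(np.abs(rs)) < 0.15


def test_realized_maf_near_target():
    cfg = SimulationConfig(n_donors=80, n_variants=500, n_peaks=1, n_genes=1,
                           seed=3)
    g = simulate_genotypes(cfg)
    # replay the stage stream to recover the per-block target frequencies
    draw = stage_rng("genotypes", 3).uniform(*cfg.maf_range,
                                             size=cfg.n_variants)
    anchor = (np.arange(cfg.n_variants) // cfg.ld_block_size) \
        * cfg.ld_block_size
    targets = draw[anchor]
    realized = g.allele_freq()
    dev = np.abs(realized - targets)
    # binomial sd at 160 alleles is <= 0.04: 0.1 is ~2.5 sigma per variant
    assert (dev <= 0.1).mean() > 0.98
    assert dev.max() <= 0.18  # ~4.5 sigma hard bound


def test_hwe_tail_calibration():
    """Exact-test rejection rates at HWE truth stay near (below) nominal.

    The p-value distribution is discrete and conservative, so uniformity is
    checked at the tails where the filter operates, not by a KS statistic.
    """
    cfg = SimulationConfig(n_donors=80, n_variants=1000, n_peaks=1,
                           n_genes=1, seed=4)
    g = simulate_genotypes(cfg)
    hard = np.round(g.dosage).astype(int)
    ps = np.array([
        hwe_exact_test(*[(row == k).sum() for k in (0, 1, 2)])
        for row in hard])
    for alpha in (0.01, 0.05, 0.1):
        rate = (ps < alpha).mean()
        assert rate <= alpha * 1.5 + 0.005
    assert ps.mean() > 0.5  # conservative, never anti-conservative


def test_counts_exchangeable_when_no_effects():
    cfg = SimulationConfig(n_donors=60, conditions=("vehicle", "stimA"),
                           n_variants=300, n_peaks=150, n_genes=10,
                           frac_wre=0, frac_deg=0, frac_caqtl=0, frac_eqtl=0,
                           scenario_mix={"null": 1.0}, donor_sd=0.0,
                           gc_effect_amplitude=0.0, libsize_lognormal_sd=0.0,
                           missing_rate=0.0, seed=5)
    g = simulate_genotypes(cfg)
    fs, truth = simulate_features(cfg, g)
    atac, _, _ = simulate_counts(g, fs, truth, cfg)
    mu = np.exp(truth.features.set_index("feature")
                .loc[atac.features, "baseline_log_mean"].to_numpy())
    n = atac.counts.shape[1]
    nb_var = mu + mu ** 2 / cfg.dispersion
    se = np.sqrt(nb_var / n)
    dev = np.abs(atac.counts.mean(axis=1) - mu) / se
    # per-feature mean within 4 SE (150 features, ~0.01 expected failures)
    assert (dev < 4).mean() > 0.97


def test_planted_condition_lfc_recovered():
    cfg = SimulationConfig(n_donors=80, conditions=("vehicle", "stimA"),
                           n_variants=300, n_peaks=200, n_genes=10,
                           frac_wre=0.5, lfc_log2=0.5, frac_caqtl=0,
                           frac_eqtl=0, scenario_mix={"null": 1.0},
                           missing_rate=0.0, seed=6)
    g = simulate_genotypes(cfg)
    fs, truth = simulate_features(cfg, g)
    atac, _, sheet = simulate_counts(g, fs, truth, cfg)
    tf = truth.features.set_index("feature")
    veh = [i for i, s in enumerate(atac.samples) if s.endswith("vehicle")]
    stim = [i for i, s in enumerate(atac.samples) if s.endswith("stimA")]
    # library-size normalize before estimating fold changes
    cpm = atac.counts / atac.counts.sum(axis=0, keepdims=True) * 1e6
    errs = []
    for j, feat in enumerate(atac.features):
        planted = tf.at[feat, "lfc_stimA"]
        if planted == 0:
            continue
        emp = (np.log2(cpm[j, stim].mean() + 0.5)
               - np.log2(cpm[j, veh].mean() + 0.5))
        errs.append(emp - planted)
    # a typical responsive peak recovers its planted fold change within
    # ±0.15; the NB noise floor at n=80 puts ~0.08 log2 units of sd on
    # each estimate, so the bound is checked at the 90th percentile
    assert np.quantile(np.abs(errs), 0.90) < 0.15
    assert abs(np.mean(errs)) < 0.05


def test_same_seed_identical_counts(tiny_dataset):
    cfg = tiny_dataset.config
    again = simulate_dataset(cfg)
    np.testing.assert_array_equal(again.atac.counts, tiny_dataset.atac.counts)
    np.testing.assert_array_equal(again.rna.counts, tiny_dataset.rna.counts)


def test_wiring_constraints(tiny_dataset):
    """Every wired pair's causal variant lies in peak ±25kb, gene within 1Mb."""
    ds = tiny_dataset
    pos_of = dict(zip(ds.genotypes.variants["id"],
                      ds.genotypes.variants["pos"]))
    peaks = {p.name: p for p in ds.features.peaks}
    genes = ds.features.genes.set_index("gene_id")
    for pair in ds.truth.pairs.itertuples():
        p = peaks[pair.peak_id]
        vpos = pos_of[pair.causal_variant]
        assert p.start - 25_000 < vpos <= p.end + 25_000
        grow = genes.loc[pair.gene_id]
        tss = grow.end if grow.strand == "-" else grow.start + 1
        assert min(abs(tss - p.end), abs(tss - p.start)) <= 1_000_000


def test_all_null_mix_has_no_wiring():
    cfg = SimulationConfig(n_donors=10, n_variants=200, n_peaks=20,
                           n_genes=10, scenario_mix={"null": 1.0},
                           frac_caqtl=0, frac_eqtl=0, seed=8)
    g = simulate_genotypes(cfg)
    _, truth = simulate_features(cfg, g)
    assert len(truth.pairs) == 0
    assert (truth.features["causal_variant"] == "").all()


def test_motif_rates_balanced_when_logor_zero():
    cfg = SimulationConfig(n_donors=10, n_variants=400, n_peaks=400,
                           n_genes=10, frac_wre=0.5, motif_logor=0.0,
                           n_motifs=10, seed=9)
    g = simulate_genotypes(cfg)
    fs, truth = simulate_features(cfg, g)
    is_resp = (truth.features.query("kind == 'peak'")
               .set_index("feature")["lfc_stimA"].abs() > 0)
    motifs = fs.motif_table.drop(columns=["width", "conserved_pct"])
    pooled_rate = motifs.to_numpy().mean()
    for col in motifs.columns:
        a = motifs.loc[is_resp[motifs.index], col].mean()
        b = motifs.loc[~is_resp[motifs.index], col].mean()
        # binomial 99.9% bound on the rate difference at ~200 peaks/class
        bound = 3.3 * np.sqrt(pooled_rate * (1 - pooled_rate) * 2 / 200)
        assert abs(a - b) < bound


def test_gwas_freq_matches_panel(tiny_dataset):
    """GWAS frequencies track the study panel's up to joint sampling noise
    (the panel has 24 donors, the cohort 500)."""
    ds = tiny_dataset
    panel = dict(zip(ds.genotypes.variants["id"], ds.genotypes.allele_freq()))
    gt = ds.gwas.table
    f = gt["freq"].to_numpy()
    pf = np.array([panel[v] for v in gt["id"]])
    se = np.sqrt(np.maximum(f * (1 - f), 0.01)
                 * (1 / (2 * 24) + 1 / (2 * 500)))
    standardized = np.abs(f - pf) / se
    assert (standardized < 4).mean() > 0.99


def test_gwas_null_has_no_genomewide_hits():
    cfg = SimulationConfig(n_donors=20, n_variants=500, n_peaks=5, n_genes=5,
                           frac_caqtl=0.4, frac_eqtl=0, n_gwas_loci=0,
                           gwas_n=2000, seed=10)
    g = simulate_genotypes(cfg)
    _, truth = simulate_features(cfg, g)
    ss = simulate_gwas(g, truth, cfg)
    assert ss.table["p"].min() > 5e-8


def test_write_dataset_manifest_reproducible(tmp_path):
    cfg = SimulationConfig(n_donors=8, n_variants=100, n_peaks=10, n_genes=6,
                           gwas_n=200, n_gwas_loci=2, seed=11)
    ds = simulate_dataset(cfg)
    m1 = write_dataset(ds, str(tmp_path / "d1"))
    m2 = write_dataset(simulate_dataset(cfg), str(tmp_path / "d2"))
    assert m1["checksums"] == m2["checksums"]
    with pytest.raises(FileExistsError):
        write_dataset(ds, str(tmp_path / "d1"))
    truth = open(tmp_path / "d1" / "truth_features.tsv").readlines()
    assert len(truth) - 1 == cfg.n_peaks + cfg.n_genes
    with open(tmp_path / "d1" / "manifest.json") as fh:
        assert json.load(fh)["seed"] == 11


def test_generated_dataset_passes_validators(tmp_path, tiny_dataset):
    out = str(tmp_path / "ds")
    write_dataset(tiny_dataset, out)
    gm = sio.read_vcf(os.path.join(out, "genotypes.vcf"))
    sheet = sio.read_sample_sheet(os.path.join(out, "samples.tsv"))
    atac = sio.read_counts(os.path.join(out, "atac_counts.tsv"))
    rna = sio.read_counts(os.path.join(out, "rna_counts.tsv"))
    sio.validate_dataset(gm, sheet, atac, rna)  # no hard errors


def test_config_validation():
    with pytest.raises(ValueError, match="n_donors"):
        SimulationConfig(n_donors=3)
    with pytest.raises(ValueError, match="scenario_mix"):
        SimulationConfig(scenario_mix={"shared": 0.9, "null": 0.9})
    with pytest.raises(ValueError, match="missing_rate"):
        SimulationConfig(missing_rate=1.5)
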