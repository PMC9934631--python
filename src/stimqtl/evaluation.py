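"""Simulation benchmarks: planted-truth recovery under the study conditions.

Each function generates data with the synthetic-data module, runs the
corresponding analysis path, and measures calibration / recovery against
the planted ground truth.  They are used by the test suite and the
reproduction script; problem sizes are arguments so callers can scale
replicate counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc as mcoloc
from . import differential as mdiff
from . import enrichment as menr
from . import normalize as mnorm
from . import qtl as mqtl
from . import response as mresp
from .simulate import (
    SimulationConfig,
    simulate_coloc_locus,
    simulate_counts,
    simulate_dataset,
    simulate_features,
    simulate_genotypes,
)

__all__ = [
    "interaction_null_calibration",
    "hierarchical_fdr_benchmark",
    "eigenmt_permutation_concordance",
    "effect_recovery",
    "priming_benchmark",
    "motif_benchmark",
    "clpp_benchmark",
    "differential_benchmark",
]


def _seed(base: int, k: int) -> int:
    return int((base * 1_000_003 + k) % (2 ** 31 - 1))


def _atac_normalized(ds_parts, n_pcs=10):
    g, fs, truth, atac, sheet = ds_parts
    sf = mnorm.size_factors(atac)
    gc = np.array([p.score for p in fs.peaks])
    off = mnorm.gc_normalize(atac, gc, factors=sf)
    return mnorm.vst_like(atac, sf, off)


def _simulate_atac(cfg, seed):
    g = simulate_genotypes(cfg, seed)
    fs, truth = simulate_features(cfg, g, seed)
    atac, _, sheet = simulate_counts(g, fs, truth, cfg, seed)
    return g, fs, truth, atac, sheet


def _peaks_frame(fs):
    return pd.DataFrame({
        "feature_id": [p.name for p in fs.peaks],
        "chrom": [p.chrom for p in fs.peaks],
        "start": [p.start for p in fs.peaks],
        "end": [p.end for p in fs.peaks]})


# ---------------------------------------------------------------------------

def interaction_null_calibration(seed: int, n_qtls: int = 1000,
                                 n_donors: int = 70) -> dict:
    """Null genotype x condition interactions (main effects present):
    rejection rate at p<0.05 and KS uniformity of the LRT p-values."""
    cfg = SimulationConfig(
        n_donors=n_donors, conditions=("vehicle", "stimA"),
        n_variants=max(1000, 4 * n_qtls), n_peaks=n_qtls, n_genes=8,
        frac_caqtl=1.0, frac_eqtl=0, frac_wre=0, frac_deg=0,
        scenario_mix={"null": 1.0}, qtl_var_frac=0.10, missing_rate=0.0,
        seed=_seed(seed, 1))
    parts = _simulate_atac(cfg, cfg.seed)
    g, fs, truth, atac, sheet = parts
    nm = _atac_normalized(parts)
    resid, _ = mnorm.pca_residualize(nm, 10)
    tf = truth.features.set_index("feature")
    idx = (tf[tf["kind"] == "peak"].reset_index()
           .rename(columns={"causal_variant": "variant"})
           [["feature", "variant"]])
    idx = idx[idx["variant"] != ""]
    recs = mresp.interaction_scan(resid, g, sheet, idx, ("stimA", "vehicle"))
    p = recs["p_interaction"].to_numpy()
    return {"rejection_rate": float((p < 0.05).mean()),
            "ks_uniform_p": float(stats.kstest(p, "uniform").pvalue),
            "n": int(len(p))}


def hierarchical_fdr_benchmark(seed: int, n_reps: int = 20,
                               n_peaks: int = 400, n_donors: int = 76,
                               frac_caqtl: float = 0.10,
                               var_frac: float = 0.08) -> dict:
    """Feature-level FDR and sensitivity of the full caQTL hierarchy."""
    tps = fps = fns = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_donors=n_donors, conditions=("vehicle",),
            reference_condition="vehicle", n_variants=4000, n_peaks=n_peaks,
            n_genes=8, frac_caqtl=frac_caqtl, frac_eqtl=0, frac_wre=0,
            frac_deg=0, scenario_mix={"null": 1.0}, qtl_var_frac=var_frac,
            missing_rate=0.0, seed=_seed(seed, 100 + rep))
        parts = _simulate_atac(cfg, cfg.seed)
        g, fs, truth, atac, sheet = parts
        nm = _atac_normalized(parts)
        resid, _ = mnorm.pca_residualize(nm, 10)
        res = mqtl.map_qtls(resid, g, _peaks_frame(fs), sheet, "vehicle",
                            "atac", 25_000, local_method="eigenmt",
                            seed=cfg.seed)
        tf = truth.features.set_index("feature")
        truth_set = set(tf[(tf["kind"] == "peak")
                           & (tf["beta_vehicle"].abs() > 0)].index)
        called = res.significant_features
        tps += len(called & truth_set)
        fps += len(called - truth_set)
        fns += len(truth_set - called)
    fdr = fps / max(tps + fps, 1)
    sens = tps / max(tps + fns, 1)
    return {"empirical_fdr": float(fdr), "sensitivity": float(sens),
            "n": int(n_reps)}


def eigenmt_permutation_concordance(seed: int, n_features: int = 50,
                                    n_variants: int = 100,
                                    n_samples: int = 150,
                                    n_perm: int = 10_000) -> dict:
    """Spearman correlation between eigenMT- and permutation-adjusted
    feature-level p-values on matched phenotypes."""
    rng = np.random.default_rng(_seed(seed, 2))
    e_vals, p_vals, meffs = [], [], []
    for f in range(n_features):
        cfg = SimulationConfig(n_donors=n_samples, n_variants=n_variants,
                               n_peaks=1, n_genes=1, seed=_seed(seed, 300 + f))
        gm = simulate_genotypes(cfg, cfg.seed)
        D = gm.dosage
        y = rng.normal(size=n_samples)
        if f % 3 == 0:  # sprinkle true effects to spread the p range
            j = int(rng.integers(n_variants))
            y = y + 0.35 * (D[j] - D[j].mean())
        Dc = D - D.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        ssx = (Dc ** 2).sum(axis=1)
        beta = Dc @ yc / np.where(ssx > 0, ssx, 1.0)
        rss = np.maximum(yc @ yc - beta ** 2 * ssx, 0.0)
        se = np.sqrt(rss / (n_samples - 2) / np.where(ssx > 0, ssx, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2 * stats.t.sf(np.abs(beta / se), n_samples - 2)
        e = mqtl.eigenmt_local(p, D, gm.variants["pos"].to_numpy())
        pm = mqtl.permutation_local(
            y, D, n_perm=n_perm, rng=np.random.default_rng(_seed(seed,
                                                                 600 + f)))
        e_vals.append(e["p_local"])
        p_vals.append(pm["p_local"])
        meffs.append(e["m_eff"])
    rho = stats.spearmanr(e_vals, p_vals).statistic
    return {"spearman_rho": float(rho), "max_m_eff": int(max(meffs)),
            "n": int(n_features)}


def effect_recovery(seed: int, n_qtls: int = 200, n_donors: int = 80,
                    var_frac: float = 0.10) -> dict:
    """Correlation and bias of estimated vs planted allelic effects (log2)."""
    cfg = SimulationConfig(
        n_donors=n_donors, conditions=("vehicle",),
        reference_condition="vehicle", n_variants=max(1000, 10 * n_qtls),
        n_peaks=n_qtls, n_genes=8, frac_caqtl=1.0, frac_eqtl=0, frac_wre=0,
        frac_deg=0, scenario_mix={"null": 1.0}, qtl_var_frac=var_frac,
        missing_rate=0.0, seed=_seed(seed, 3))
    parts = _simulate_atac(cfg, cfg.seed)
    g, fs, truth, atac, sheet = parts
    nm = _atac_normalized(parts)
    tf = truth.features.set_index("feature")
    dos = {v: g.dosage[i] for i, v in enumerate(g.variants["id"])}
    ln2 = float(np.log(2.0))
    true, est = [], []
    feat_row = {f: i for i, f in enumerate(nm.features)}
    for feat, row in tf[(tf["kind"] == "peak")
                        & (tf["causal_variant"] != "")].iterrows():
        y = nm.values[feat_row[feat]]
        y = y - y.mean()
        x = dos[row["causal_variant"]]
        xc = x - x.mean()
        true.append(row["beta_vehicle"] / ln2)
        est.append(float(xc @ y / (xc @ xc)))
    true, est = np.array(true), np.array(est)
    return {"correlation": float(np.corrcoef(true, est)[0, 1]),
            "mean_bias": float(np.mean(est - true)),
            "n": int(len(true))}


def priming_benchmark(seed: int, n_per_class: int = 50, n_donors: int = 80,
                      var_frac: float = 0.15, n_perm: int = 500) -> dict:
    """Recovery of planted primed / stimulus-specific / shared pairs."""
    n_pairs = 3 * n_per_class
    cfg = SimulationConfig(
        n_donors=n_donors, conditions=("vehicle", "stimA"), n_variants=3000,
        n_peaks=n_pairs, n_genes=n_pairs, frac_caqtl=0, frac_eqtl=0,
        frac_wre=0, frac_deg=0,
        scenario_mix={"shared": 1 / 3, "primed": 1 / 3,
                      "stimulus_specific": 1 / 3},
        qtl_var_frac=var_frac, mediation_gamma=1.0, missing_rate=0.0,
        seed=_seed(seed, 4))
    ds = simulate_dataset(cfg, with_gwas=False)
    peaks = _peaks_frame(ds.features)
    genes = ds.features.genes.rename(columns={"gene_id": "feature_id"})
    qtl_res = {}
    for assay, cm, feats, window, method in (
            ("atac", ds.atac, peaks, 25_000, "eigenmt"),
            ("rna", ds.rna, genes, 1_000_000, "permutation")):
        sf = mnorm.size_factors(cm)
        off = None
        if assay == "atac":
            gc = np.array([p.score for p in ds.features.peaks])
            off = mnorm.gc_normalize(cm, gc, factors=sf)
        nm = mnorm.vst_like(cm, sf, off)
        for cond in ("vehicle", "stimA"):
            samples = [s for s in ds.sheet.condition_samples(cond)
                       if s in set(nm.samples)]
            resid, _ = mnorm.pca_residualize(nm.subset_samples(samples), 10)
            qtl_res[(assay, cond)] = mqtl.map_qtls(
                resid, ds.genotypes, feats, ds.sheet, cond, assay, window,
                local_method=method, n_perm=n_perm, seed=cfg.seed)
    ca = {c: qtl_res[("atac", c)] for c in ("stimA", "vehicle")}
    eq = {c: qtl_res[("rna", c)] for c in ("stimA", "vehicle")}
    calls = mresp.link_and_classify_priming(
        ca, eq, ds.genotypes, peaks, ds.features.genes, ("stimA", "vehicle"))
    label_of = {(c.peak, c.gene): c.label for c in calls}
    out = {}
    shared_as_primed = 0
    n_shared = 0
    # recall conditional on the QTL significance patterns being detected
    cond_tp = {s: 0 for s in ("primed", "stimulus_specific", "shared")}
    cond_n = {s: 0 for s in ("primed", "stimulus_specific", "shared")}
    for scen in ("primed", "stimulus_specific", "shared"):
        pairs = ds.truth.pairs[ds.truth.pairs["scenario"] == scen]
        hit = sum(label_of.get((r.peak_id, r.gene_id)) == scen
                  for r in pairs.itertuples())
        out[f"recall_{scen}"] = float(hit / max(len(pairs), 1))
        if scen == "shared":
            n_shared = len(pairs)
            shared_as_primed = sum(
                label_of.get((r.peak_id, r.gene_id)) == "primed"
                for r in pairs.itertuples())
        for r in pairs.itertuples():
            ca_v = r.peak_id in ca["vehicle"].significant_features
            ca_s = r.peak_id in ca["stimA"].significant_features
            e_v = r.gene_id in eq["vehicle"].significant_features
            e_s = r.gene_id in eq["stimA"].significant_features
            pattern_ok = {
                "primed": ca_v and ca_s and e_s and not e_v,
                "stimulus_specific": ca_s and not ca_v and e_s and not e_v,
                "shared": ca_v and ca_s and e_v and e_s}[scen]
            if pattern_ok:
                cond_n[scen] += 1
                if label_of.get((r.peak_id, r.gene_id)) == scen:
                    cond_tp[scen] += 1
    for scen in cond_n:
        out[f"conditional_recall_{scen}"] = float(
            cond_tp[scen] / max(cond_n[scen], 1))
        out[f"n_detected_pattern_{scen}"] = int(cond_n[scen])
    out["shared_mislabeled_primed"] = float(
        shared_as_primed / max(n_shared, 1))
    out["n"] = int(n_pairs)
    return out


def motif_benchmark(seed: int, n_reps: int = 50, n_per_class: int = 2000,
                    base_rate: float = 0.2, logor: float = 1.0,
                    n_null_motifs: int = 200, null_reps: int = 5) -> dict:
    """Planted log-OR recovery and null-motif BH behaviour."""
    rng = np.random.default_rng(_seed(seed, 5))
    n = 2 * n_per_class
    labels = pd.Series(np.repeat([1, 0], n_per_class),
                       index=[f"p{i}" for i in range(n)])
    base_logit = np.log(base_rate / (1 - base_rate))
    within = 0
    for rep in range(n_reps):
        width = rng.integers(200, 2000, size=n)
        cons = rng.uniform(0, 0.5, size=n)
        prob = 1 / (1 + np.exp(-(base_logit + logor * labels.to_numpy())))
        y = (rng.random(n) < prob).astype(int)
        table = pd.DataFrame({"width": width, "conserved_pct": cons,
                              "m": y}, index=labels.index)
        res = menr.motif_glm(table, labels)
        if len(res) and abs(res["effect"].iloc[0] - logor) <= 0.3:
            within += 1
    null_sig = []
    for rep in range(null_reps):
        width = rng.integers(200, 2000, size=n)
        cons = rng.uniform(0, 0.5, size=n)
        cols = {
            f"m{j}": (rng.random(n) < base_rate).astype(int)
            for j in range(n_null_motifs)}
        table = pd.DataFrame({"width": width, "conserved_pct": cons, **cols},
                             index=labels.index)
        res = menr.motif_glm(table, labels, fdr=0.1)
        null_sig.append(int(res["significant"].sum()))
    return {"frac_estimates_within_0.3": float(within / n_reps),
            "null_bh_significant_mean": float(np.mean(null_sig)),
            "n": int(n_reps)}


def clpp_benchmark(seed: int, n_reps: int = 100, n_qtl: int = 80,
                   gwas_n: int = 20_000, qtl_var: float = 0.25,
                   gwas_var: float = 0.005) -> dict:
    """Colocalization rates for shared- vs distinct-causal loci."""
    rates = {}
    for flavor in ("shared", "distinct"):
        hits = 0
        for rep in range(n_reps):
            locus = simulate_coloc_locus(
                _seed(seed, 700 + rep), flavor, n_qtl=n_qtl, gwas_n=gwas_n,
                qtl_var=qtl_var, gwas_var=gwas_var)
            gm, qtl, gwas = locus["genotypes"], locus["qtl"], locus["gwas"]
            idx = pd.DataFrame({
                "feature": ["feat"],
                "variant": [qtl.loc[qtl["p"].idxmin(), "id"]]})
            try:
                cands = mcoloc.find_candidates(gwas, idx, gm)
            except ValueError:
                cands = []
            if cands:
                res = mcoloc.colocalize(cands[0], gwas, qtl, gm)
                hits += res.verdict == "colocalized"
        rates[flavor] = hits / n_reps
    return {"shared_coloc_rate": float(rates["shared"]),
            "distinct_coloc_rate": float(rates["distinct"]),
            "n": int(n_reps)}


def differential_benchmark(seed: int, n_features: int = 2000,
                           n_donors: int = 60, frac_true: float = 0.10,
                           lfc: float = 0.8) -> dict:
    """Sensitivity and FDR of the responsive-element caller."""
    cfg = SimulationConfig(
        n_donors=n_donors, conditions=("vehicle", "stimA"), n_variants=300,
        n_peaks=n_features, n_genes=8, frac_wre=frac_true, frac_deg=0,
        frac_caqtl=0, frac_eqtl=0, scenario_mix={"null": 1.0},
        lfc_log2=lfc, missing_rate=0.0, seed=_seed(seed, 6))
    parts = _simulate_atac(cfg, cfg.seed)
    g, fs, truth, atac, sheet = parts
    nm = _atac_normalized(parts)
    res = mdiff.paired_diff(nm, sheet, ("stimA", "vehicle"))
    res = mdiff.call_responsive(res, fdr=0.1, lfc_min=0.5)
    tf = truth.features.set_index("feature")
    truth_wre = tf.loc[[f for f in atac.features], "lfc_stimA"].abs() > 0
    called = (res.table.set_index("feature")["direction"] != "ns")
    called = called.loc[truth_wre.index]
    tp = int((called & truth_wre).sum())
    fp = int((called & ~truth_wre).sum())
    fn = int((~called & truth_wre).sum())
    return {"sensitivity": float(tp / max(tp + fn, 1)),
            "empirical_fdr": float(fp / max(tp + fp, 1)),
            "n": int(n_features)}
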