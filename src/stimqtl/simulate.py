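"""Synthetic paired-design dataset generator with recorded ground truth.

Emulates a stimulus-response regulatory-genomics study: ~80 donors cultured
under a vehicle condition and two stimulated conditions, assayed for
chromatin accessibility (peaks) and gene expression (genes), genotyped at
LD-structured biallelic variants in Hardy-Weinberg equilibrium.  Counts are
negative binomial with donor random intercepts, sample-specific library
sizes and GC biases, planted condition effects (responsive elements /
differential genes) and planted genetic effects:

* ``shared``              caQTL + eQTL active in every condition
* ``primed``              caQTL in all conditions, eQTL only under stimulus
* ``stimulus_specific``   caQTL and eQTL only under stimulus
* ``response_magnitude``  effect present everywhere but larger under stimulus
* ``null``                no genetic effect

Gene effects in wired peak-gene pairs are ``mediation_gamma`` times the
peak's per-condition allelic effect, so eQTL signals are peak-mediated by
construction.  An independent cohort drawn from the same LD process yields
GWAS summary statistics whose causal variants either coincide with planted
QTL variants ("shared" loci) or sit in low-LD neighbours ("distinct").

All randomness flows from a single master seed; each stage derives an
independent child stream keyed by (stage, seed) so stages can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .types import (
    CountMatrix,
    GenomicInterval,
    GenotypeMatrix,
    GwasSumstats,
    SampleSheet,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_features",
    "simulate_counts",
    "simulate_gwas",
    "simulate_coloc_locus",
    "simulate_dataset",
    "write_dataset",
]

_LN2 = float(np.log(2.0))

# fixed stage keys for child RNG streams
_STAGES = {"genotypes": 11, "features": 23, "counts": 37, "gwas": 53,
           "missing": 67}


def stage_rng(stage: str, seed: int) -> np.random.Generator:
    """Independent child stream for a pipeline stage under a master seed."""
    return np.random.default_rng(np.random.SeedSequence([_STAGES[stage],
                                                         int(seed)]))


@dataclass
class SimulationConfig:
    """Study-design and generative parameters.

    Effects are natural-log per-allele internally; condition log fold
    changes are specified in log2 (``lfc_log2``) and converted explicitly.
    """

    n_donors: int = 80
    conditions: tuple[str, ...] = ("vehicle", "stimA", "stimB")
    reference_condition: str = "vehicle"
    missing_rate: float = 0.05        # per condition x assay sample dropout
    n_variants: int = 3000
    n_peaks: int = 300
    n_genes: int = 150
    variant_spacing: int = 800        # bp between adjacent variants
    ld_block_size: int = 20
    within_block_copy_prob: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    dispersion: float = 10.0          # NB size parameter
    donor_sd: float = 0.3             # random intercept SD, natural log
    gc_effect_amplitude: float = 0.3  # SD of per-sample GC slope
    libsize_lognormal_sd: float = 0.3
    frac_wre: float = 0.1             # peaks with condition effects
    frac_deg: float = 0.1             # genes with condition effects
    frac_caqtl: float = 0.1           # unwired peaks with shared caQTLs
    frac_eqtl: float = 0.1            # unwired genes with shared eQTLs
    scenario_mix: dict = field(default_factory=lambda: {
        "shared": 0.05, "primed": 0.05, "stimulus_specific": 0.05,
        "response_magnitude": 0.0, "null": 0.85})
    lfc_log2: float = 0.8             # condition effect magnitude (log2)
    beta_ca: float = 0.6              # caQTL allelic effect (natural log)
    beta_e: float = 0.6               # unwired eQTL allelic effect
    beta_interaction: float = 0.6     # added under stimulus (response_magnitude)
    # when set, overrides the beta magnitudes: each planted effect explains
    # this fraction of the feature's predicted within-condition variance
    qtl_var_frac: float | None = None
    mediation_gamma: float = 1.0
    n_motifs: int = 50
    motif_base_rate: float = 0.2
    motif_logor: float = 1.0
    frac_motifs_enriched: float = 0.2
    annotation_counts: dict = field(default_factory=lambda: {
        "enhancer_state": 400, "haqer_like": 150, "har_like": 250})
    annotation_enrich_frac: float = 0.3  # fraction placed onto caQTL peaks
    gwas_n: int = 20000
    gwas_h2_per_locus: float = 0.0025
    n_gwas_loci: int = 10
    rin_mean: float = 8.0
    rin_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 4:
            raise ValueError("n_donors must be >= 4 (models unfittable below)")
        total = sum(self.scenario_mix.values())
        if total > 1 + 1e-9:
            raise ValueError("scenario_mix proportions must sum to <= 1")
        for name, val in (("missing_rate", self.missing_rate),
                          ("frac_wre", self.frac_wre),
                          ("frac_caqtl", self.frac_caqtl),
                          ("frac_eqtl", self.frac_eqtl)):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def genome_length(self) -> int:
        return (self.n_variants + 1) * self.variant_spacing

    @property
    def stim_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.reference_condition]


@dataclass
class GroundTruth:
    """Planted effects and scenario labels.

    ``features``: one row per peak/gene with baseline log-mean, per-condition
    log2 condition effect ``lfc_<cond>``, causal variant id (empty if none),
    per-condition allelic effect ``beta_<cond>`` (natural log).
    ``pairs``: wired caPeak-eGene pairs with scenario labels.
    ``motifs``: planted motif log-odds.  ``gwas_loci``: locus definitions.
    """

    features: pd.DataFrame
    pairs: pd.DataFrame
    motifs: pd.DataFrame
    gwas_loci: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class FeatureSet:
    peaks: list[GenomicInterval]
    genes: pd.DataFrame        # gene_id, chrom, start, end, strand
    motif_table: pd.DataFrame  # peak_id x motif columns + width, conserved_pct
    annotations: dict[str, list[GenomicInterval]]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    features: FeatureSet
    truth: GroundTruth
    atac: CountMatrix
    rna: CountMatrix
    sheet: SampleSheet
    gwas: GwasSumstats | None = None


# ---------------------------------------------------------------------------
# genotypes

def _haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                block_size: int, copy_prob: float) -> np.ndarray:
    """LD-block haplotypes: within a block each variant copies the previous
    one's allele per haplotype with ``copy_prob``, else draws fresh."""
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n_hap) < freqs[j]
        if j % block_size == 0:
            H[:, j] = fresh
        else:
            copy = rng.random(n_hap) < copy_prob
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_genotypes(config: SimulationConfig,
                       seed: int | None = None) -> GenotypeMatrix:
    """Biallelic HWE genotypes in decaying-LD blocks, deterministic per seed."""
    seed = config.seed if seed is None else seed
    rng = stage_rng("genotypes", seed)
    m = config.n_variants
    # one target frequency per LD block: the copy chain then preserves each
    # variant's marginal frequency exactly while correlation decays as
    # copy_prob^distance
    freqs = rng.uniform(*config.maf_range, size=m)
    block_anchor = (np.arange(m) // config.ld_block_size) \
        * config.ld_block_size
    freqs = freqs[block_anchor]
    H = _haplotypes(rng, 2 * config.n_donors, freqs,
                    config.ld_block_size, config.within_block_copy_prob)
    dosage = (H[0::2] + H[1::2]).T.astype(float)  # variants x donors
    donors = [f"D{i + 1:03d}" for i in range(config.n_donors)]
    variants = pd.DataFrame({
        "chrom": "chr1",
        "pos": (np.arange(m) + 1) * config.variant_spacing,
        "id": [f"rs{i + 1}" for i in range(m)],
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(variants, donors, dosage)


# ---------------------------------------------------------------------------
# features, wiring, motifs, annotations

def _place_gene_near(rng, anchor: int, genome: int) -> tuple[int, int, str]:
    """Gene body within ±0.8 Mb of ``anchor`` so TSS distance < 1 Mb."""
    length = int(rng.integers(5_000, 50_000))
    for _ in range(100):
        offset = int(rng.integers(-800_000, 800_000))
        start = anchor + offset
        if 0 <= start and start + length <= genome:
            strand = "+" if rng.random() < 0.5 else "-"
            return start, start + length, strand
    raise ValueError("genome too small to place a wired gene; "
                     "increase n_variants or variant_spacing")


def simulate_features(config: SimulationConfig,
                      genotypes: GenotypeMatrix,
                      seed: int | None = None,
                      ) -> tuple[FeatureSet, GroundTruth]:
    seed = config.seed if seed is None else seed
    rng = stage_rng("features", seed)
    genome = config.genome_length
    var_pos = genotypes.variants["pos"].to_numpy()
    var_ids = genotypes.variants["id"].to_numpy()
    stim = config.stim_conditions
    conds = list(config.conditions)

    # --- peaks -------------------------------------------------------------
    widths = rng.integers(200, 2001, size=config.n_peaks)
    gcs = rng.uniform(0.3, 0.7, size=config.n_peaks)
    starts = np.sort(rng.integers(0, genome - 2001, size=config.n_peaks))
    # GC content rides on the BED score slot
    peaks = [GenomicInterval("chr1", int(s), int(s + w), f"peak{i + 1:04d}",
                             float(g), ".")
             for i, (s, w, g) in enumerate(zip(starts, widths, gcs))]
    peak_ids = [p.name for p in peaks]
    peak_baseline = rng.uniform(np.log(20), np.log(500), size=config.n_peaks)

    dosage_of = {vid: genotypes.dosage[i]
                 for i, vid in enumerate(var_ids)}

    def _beta_mag(causal: str, baseline: float, default: float) -> float:
        """Allelic effect magnitude; calibrated to ``qtl_var_frac`` of the
        feature's predicted within-condition variance when configured.

        Predicted variance (natural-log scale): donor intercept variance +
        the delta-method NB log variance 1/size + 1/mean.
        """
        if config.qtl_var_frac is None:
            return default
        vg = float(np.nanvar(dosage_of[causal]))
        sigma2 = (config.donor_sd ** 2 + 1.0 / config.dispersion
                  + 1.0 / np.exp(baseline))
        h2 = config.qtl_var_frac
        return float(np.sqrt(h2 / (1 - h2) * sigma2 / max(vg, 1e-6)))

    # --- scenarios: wire one peak to one gene each --------------------------
    n_pairs_total = min(config.n_peaks, config.n_genes)
    scenario_counts = {s: int(round(frac * n_pairs_total))
                       for s, frac in config.scenario_mix.items()
                       if s != "null"}
    n_wired = sum(scenario_counts.values())
    if n_wired > n_pairs_total:
        raise ValueError("scenario_mix wires more pairs than features allow")
    wired_peaks = rng.choice(config.n_peaks, size=n_wired, replace=False)
    labels = [s for s, k in scenario_counts.items() for _ in range(k)]

    genes_rows = []
    pair_rows = []
    gene_effects: dict[str, dict] = {}
    peak_effects: dict[str, dict] = {}

    def _pick_causal(peak: GenomicInterval) -> str:
        lo, hi = peak.start - 25_000, peak.end + 25_000
        inside = np.flatnonzero((var_pos > lo) & (var_pos <= hi))
        if len(inside) == 0:
            raise ValueError("no variant within peak ±25kb; genome too sparse "
                             "(decrease variant_spacing)")
        return str(var_ids[rng.choice(inside)])

    for k, (pi, scen) in enumerate(zip(wired_peaks, labels)):
        peak = peaks[pi]
        causal = _pick_causal(peak)
        anchor = (peak.start + peak.end) // 2
        gstart, gend, gstrand = _place_gene_near(rng, anchor, genome)
        gid = f"gene{len(genes_rows) + 1:04d}"
        genes_rows.append((gid, "chr1", gstart, gend, gstrand))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        b = sign * _beta_mag(causal, peak_baseline[pi], config.beta_ca)
        if scen == "shared":
            beta_ca = {c: b for c in conds}
            beta_e = {c: config.mediation_gamma * b for c in conds}
        elif scen == "primed":
            beta_ca = {c: b for c in conds}
            beta_e = {c: (config.mediation_gamma * b if c in stim else 0.0)
                      for c in conds}
        elif scen == "stimulus_specific":
            beta_ca = {c: (b if c in stim else 0.0) for c in conds}
            beta_e = {c: (config.mediation_gamma * b if c in stim else 0.0)
                      for c in conds}
        elif scen == "response_magnitude":
            binter = sign * config.beta_interaction
            beta_ca = {c: (b + binter if c in stim else b) for c in conds}
            beta_e = {c: config.mediation_gamma * beta_ca[c] for c in conds}
        else:  # pragma: no cover - guarded by scenario_counts
            raise ValueError(f"unknown scenario {scen}")
        peak_effects[peak.name] = {"causal": causal, "beta": beta_ca,
                                   "scenario": scen}
        gene_effects[gid] = {"causal": causal, "beta": beta_e,
                             "scenario": scen}
        pair_rows.append((peak.name, gid, causal, scen))

    # --- remaining genes placed uniformly -----------------------------------
    while len(genes_rows) < config.n_genes:
        length = int(rng.integers(5_000, 50_000))
        gstart = int(rng.integers(0, genome - length))
        gstrand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{len(genes_rows) + 1:04d}"
        genes_rows.append((gid, "chr1", gstart, gstart + length, gstrand))
    genes = pd.DataFrame(genes_rows,
                         columns=["gene_id", "chrom", "start", "end",
                                  "strand"])

    # --- unwired shared QTLs on null features --------------------------------
    free_peaks = [i for i in range(config.n_peaks) if i not in set(wired_peaks)]
    n_extra_ca = int(round(config.frac_caqtl * config.n_peaks))
    for pi in rng.choice(free_peaks, size=min(n_extra_ca, len(free_peaks)),
                         replace=False):
        peak = peaks[pi]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        causal = _pick_causal(peak)
        b = sign * _beta_mag(causal, peak_baseline[pi], config.beta_ca)
        peak_effects[peak.name] = {
            "causal": causal,
            "beta": {c: b for c in conds},
            "scenario": "marginal"}
    gene_baseline = rng.uniform(np.log(20), np.log(500),
                                size=config.n_genes)
    gene_base_of = dict(zip(genes["gene_id"], gene_baseline))
    wired_gene_ids = set(gene_effects)
    free_genes = [g for g in genes["gene_id"] if g not in wired_gene_ids]
    n_extra_e = int(round(config.frac_eqtl * config.n_genes))
    gene_lookup = genes.set_index("gene_id")
    for gid in rng.choice(free_genes, size=min(n_extra_e, len(free_genes)),
                          replace=False):
        row = gene_lookup.loc[gid]
        lo, hi = row.start - 25_000, row.end + 25_000
        inside = np.flatnonzero((var_pos > lo) & (var_pos <= hi))
        if len(inside) == 0:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        causal = str(var_ids[rng.choice(inside)])
        b = sign * _beta_mag(causal, gene_base_of[gid], config.beta_e)
        gene_effects[gid] = {
            "causal": causal,
            "beta": {c: b for c in conds},
            "scenario": "marginal"}

    # --- condition effects (responsive peaks / genes) ------------------------
    def _condition_lfcs(n: int, frac: float) -> np.ndarray:
        lfc = np.zeros((n, len(conds)))
        chosen = rng.choice(n, size=int(round(frac * n)), replace=False)
        for i in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for c in stim:
                lfc[i, conds.index(c)] = sign * config.lfc_log2
        return lfc

    peak_lfc = _condition_lfcs(config.n_peaks, config.frac_wre)
    gene_lfc = _condition_lfcs(config.n_genes, config.frac_deg)

    # --- truth table ---------------------------------------------------------
    rows = []
    for i, p in enumerate(peaks):
        eff = peak_effects.get(p.name)
        row = {"feature": p.name, "kind": "peak",
               "baseline_log_mean": float(peak_baseline[i]),
               "causal_variant": eff["causal"] if eff else "",
               "scenario": eff["scenario"] if eff else "null"}
        for ci, c in enumerate(conds):
            row[f"lfc_{c}"] = peak_lfc[i, ci]
            row[f"beta_{c}"] = eff["beta"][c] if eff else 0.0
        rows.append(row)
    for i, gid in enumerate(genes["gene_id"]):
        eff = gene_effects.get(gid)
        row = {"feature": gid, "kind": "gene",
               "baseline_log_mean": float(gene_baseline[i]),
               "causal_variant": eff["causal"] if eff else "",
               "scenario": eff["scenario"] if eff else "null"}
        for ci, c in enumerate(conds):
            row[f"lfc_{c}"] = gene_lfc[i, ci]
            row[f"beta_{c}"] = eff["beta"][c] if eff else 0.0
        rows.append(row)
    truth_features = pd.DataFrame(rows)
    pairs = pd.DataFrame(pair_rows, columns=["peak_id", "gene_id",
                                             "causal_variant", "scenario"])

    # --- motifs --------------------------------------------------------------
    is_response = np.abs(peak_lfc).sum(axis=1) > 0
    n_enriched = int(round(config.frac_motifs_enriched * config.n_motifs))
    motif_logor = np.zeros(config.n_motifs)
    motif_logor[:n_enriched] = config.motif_logor
    base_logit = np.log(config.motif_base_rate / (1 - config.motif_base_rate))
    motif_cols = {}
    for mi in range(config.n_motifs):
        logit = base_logit + motif_logor[mi] * is_response.astype(float)
        prob = 1.0 / (1.0 + np.exp(-logit))
        motif_cols[f"motif{mi + 1:03d}"] = (
            rng.random(config.n_peaks) < prob).astype(int)
    motif_table = pd.DataFrame(motif_cols, index=peak_ids)
    motif_table.insert(0, "width", widths)
    motif_table.insert(1, "conserved_pct", rng.uniform(0, 0.5,
                                                       config.n_peaks))
    truth_motifs = pd.DataFrame({
        "motif": [f"motif{mi + 1:03d}" for mi in range(config.n_motifs)],
        "planted_log_or": motif_logor})

    # --- annotation tracks ---------------------------------------------------
    caqtl_peaks = [p for p in peaks if p.name in peak_effects]
    annotations: dict[str, list[GenomicInterval]] = {}
    for track, count in config.annotation_counts.items():
        ivs = []
        for k in range(count):
            width = int(rng.integers(200, 1500))
            if caqtl_peaks and rng.random() < config.annotation_enrich_frac:
                target = caqtl_peaks[rng.integers(len(caqtl_peaks))]
                center = (target.start + target.end) // 2
                start = max(0, center - width // 2)
            else:
                start = int(rng.integers(0, genome - width))
            ivs.append(GenomicInterval("chr1", start, start + width,
                                       f"{track}_{k + 1}"))
        ivs.sort(key=lambda iv: (iv.chrom, iv.start))
        annotations[track] = ivs

    fs = FeatureSet(peaks=peaks, genes=genes, motif_table=motif_table,
                    annotations=annotations)
    truth = GroundTruth(features=truth_features, pairs=pairs,
                        motifs=truth_motifs)
    return fs, truth


# ---------------------------------------------------------------------------
# counts

def simulate_counts(genotypes: GenotypeMatrix, features: FeatureSet,
                    truth: GroundTruth, config: SimulationConfig,
                    seed: int | None = None,
                    ) -> tuple[CountMatrix, CountMatrix, SampleSheet]:
    """NB counts with donor intercepts, library-size and GC biases.

    count_{js} ~ NB(mean = exp(logL_s + slope_s*(GC_j - mean GC) + a_j + u_d
    + ln2*lfc2_{jc} + beta_{jc} x_{d}), size = dispersion).
    """
    seed = config.seed if seed is None else seed
    rng = stage_rng("counts", seed)
    conds = list(config.conditions)
    donors = genotypes.samples
    n_d = len(donors)

    sample_ids = [f"{d}_{c}" for d in donors for c in conds]
    donor_idx = np.repeat(np.arange(n_d), len(conds))
    cond_idx = np.tile(np.arange(len(conds)), n_d)

    u = rng.normal(0.0, config.donor_sd, size=n_d)
    log_lib = rng.normal(0.0, config.libsize_lognormal_sd,
                         size=len(sample_ids))
    gc_slope = rng.normal(0.0, config.gc_effect_amplitude,
                          size=len(sample_ids))
    rin = rng.normal(config.rin_mean, config.rin_sd, size=n_d)

    tf = truth.features.set_index("feature")
    dosage_by_id = {vid: genotypes.dosage[i]
                    for i, vid in enumerate(genotypes.variants["id"])}

    def _simulate(feature_ids: list[str], gc: np.ndarray | None
                  ) -> CountMatrix:
        n_f = len(feature_ids)
        log_mu = np.tile(log_lib, (n_f, 1))
        if gc is not None:
            log_mu += np.outer(gc - gc.mean(), gc_slope)
        sub = tf.loc[feature_ids]
        a = sub["baseline_log_mean"].to_numpy()
        log_mu += a[:, None] + u[donor_idx][None, :]
        lfc = sub[[f"lfc_{c}" for c in conds]].to_numpy() * _LN2
        beta = sub[[f"beta_{c}" for c in conds]].to_numpy()
        log_mu += lfc[:, cond_idx]
        causal = sub["causal_variant"].to_numpy()
        for j in np.flatnonzero(causal != ""):
            x = dosage_by_id[causal[j]][donor_idx]
            log_mu[j] += beta[j, cond_idx] * x
        if log_mu.max() > 30:
            raise ValueError("NB log-mean exceeds 30; check effect sizes / "
                             "libsize settings in the simulation config")
        mu = np.exp(log_mu)
        size = config.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
        return CountMatrix(feature_ids, sample_ids, counts)

    peak_ids = [p.name for p in features.peaks]
    peak_gc = np.array([p.score if p.score is not None else 0.5
                        for p in features.peaks])
    atac = _simulate(peak_ids, peak_gc)
    rna = _simulate(features.genes["gene_id"].tolist(), None)

    # --- per-condition / assay missingness ----------------------------------
    mrng = stage_rng("missing", seed)
    keep_atac = mrng.random(len(sample_ids)) >= config.missing_rate
    keep_rna = mrng.random(len(sample_ids)) >= config.missing_rate
    atac = atac.subset_samples([s for s, k in zip(sample_ids, keep_atac) if k])
    rna = rna.subset_samples([s for s, k in zip(sample_ids, keep_rna) if k])

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "donor_id": [donors[i] for i in donor_idx],
        "condition": [conds[i] for i in cond_idx],
        "rin": rin[donor_idx],
    }), conditions=conds)
    return atac, rna, sheet


# ---------------------------------------------------------------------------
# GWAS cohort

def simulate_gwas(genotypes: GenotypeMatrix, truth: GroundTruth,
                  config: SimulationConfig, seed: int | None = None,
                  ) -> GwasSumstats:
    """Marginal GWAS over an independent cohort from the same LD process.

    Half the loci reuse a planted QTL causal variant ("shared"); half use a
    low-LD (r² < 0.1) neighbour within 1 Mb ("distinct").
    """
    seed = config.seed if seed is None else seed
    rng = stage_rng("gwas", seed)
    if config.gwas_n < 100:
        import warnings
        warnings.warn("gwas_n < 100: no genome-wide significant loci expected")

    variants = genotypes.variants
    var_pos = variants["pos"].to_numpy()
    var_ids = variants["id"].to_numpy()
    id_row = {v: i for i, v in enumerate(var_ids)}

    qtl_causals = [v for v in truth.features["causal_variant"].unique() if v]
    n_loci = min(config.n_gwas_loci, len(qtl_causals))
    chosen = list(rng.choice(qtl_causals, size=n_loci, replace=False))

    # cohort haplotypes: same per-variant frequencies as the study panel
    freqs = genotypes.allele_freq()
    H = _haplotypes(rng, 2 * config.gwas_n, freqs, config.ld_block_size,
                    config.within_block_copy_prob)
    X = (H[0::2] + H[1::2]).astype(np.float32)  # n x m
    del H

    loci = []
    causal_cols = []
    for k, qvar in enumerate(chosen):
        qrow = id_row[qvar]
        flavor = "shared" if k % 2 == 0 else "distinct"
        if flavor == "shared":
            crow = qrow
        else:
            near = np.flatnonzero(np.abs(var_pos - var_pos[qrow]) <= 1_000_000)
            xq = X[:, qrow]
            crow = None
            for cand in rng.permutation(near):
                if cand == qrow:
                    continue
                r = np.corrcoef(X[:, cand], xq)[0, 1]
                if r * r < 0.1:
                    crow = int(cand)
                    break
            if crow is None:
                continue
        causal_cols.append(crow)
        loci.append({"locus": f"L{k + 1}", "qtl_variant": qvar,
                     "causal_variant": str(var_ids[crow]), "flavor": flavor})

    n = config.gwas_n
    y = rng.normal(0.0, 1.0, size=n)
    for crow in causal_cols:
        x = X[:, crow]
        vx = x.var()
        if vx == 0:
            continue
        h2 = config.gwas_h2_per_locus
        b = np.sqrt(h2 / (1 - h2) / vx)
        y = y + b * (x - x.mean())

    # vectorized marginal regressions
    xm = X.mean(axis=0)
    yc = y - y.mean()
    ssx = ((X - xm) ** 2).sum(axis=0)
    sxy = X.T @ yc - 0.0  # X centered implicitly since yc sums to 0
    ok = ssx > 0
    beta = np.where(ok, sxy / np.where(ok, ssx, 1.0), 0.0)
    yy = float(yc @ yc)
    sigma2 = np.maximum(yy - beta * sxy, 0.0) / (n - 2)
    se = np.sqrt(np.where(ok, sigma2 / np.where(ok, ssx, 1.0), np.inf))
    from scipy import stats as sps
    z = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({
        "id": var_ids, "chrom": variants["chrom"], "pos": var_pos,
        "effect_allele": variants["alt"], "other_allele": variants["ref"],
        "freq": np.asarray(xm / 2.0, dtype=float),
        "beta": np.asarray(beta, dtype=float),
        "se": np.asarray(se, dtype=float), "p": p, "n": n,
    })
    table = table[ok].reset_index(drop=True)
    ss = GwasSumstats(table)
    truth.gwas_loci = pd.DataFrame(loci)
    return ss


def _marginal_stats(X: np.ndarray, y: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant simple regressions (columns of X on y)."""
    from scipy import stats as sps
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ssx = (Xc ** 2).sum(axis=0)
    ssx = np.where(ssx > 0, ssx, np.nan)
    beta = Xc.T @ yc / ssx
    rss = np.maximum(yc @ yc - beta ** 2 * ssx, 0.0)
    se = np.sqrt(rss / (n - 2) / ssx)
    p = np.clip(2 * sps.norm.sf(np.abs(beta / se)),
                np.finfo(float).tiny, 1.0)
    return beta, se, p


def simulate_coloc_locus(seed: int, flavor: str, n_qtl: int = 80,
                         gwas_n: int = 20_000, n_variants: int = 100,
                         qtl_var: float = 0.25, gwas_var: float = 0.005,
                         ) -> dict:
    """One locus for colocalization benchmarking: a QTL study panel and an
    independent well-powered GWAS cohort from the same LD process.

    ``flavor='shared'`` puts the GWAS causal effect on the QTL causal
    variant; ``'distinct'`` on a low-LD (r² < 0.1) variant at the same
    locus.  Returns the genotype panel, the QTL per-SNP summary statistics
    (mid-locus causal variant, ``qtl_var`` variance explained) and GWAS
    summary statistics (``gwas_var`` variance per locus).
    """
    if flavor not in ("shared", "distinct"):
        raise ValueError(f"flavor must be shared/distinct, got {flavor!r}")
    rng = np.random.default_rng(np.random.SeedSequence([83, int(seed)]))
    cfg = SimulationConfig(n_donors=n_qtl, n_variants=n_variants,
                           n_peaks=1, n_genes=1, seed=seed)
    gm = simulate_genotypes(cfg, seed=seed)
    D = gm.dosage
    causal_q = n_variants // 2
    if flavor == "shared":
        causal_g = causal_q
    else:
        xq = D[causal_q]
        r2 = np.array([
            np.corrcoef(D[j], xq)[0, 1] ** 2 if D[j].std() > 0 else 1.0
            for j in range(n_variants)])
        low = np.flatnonzero(r2 < 0.1)
        if len(low) == 0:
            raise ValueError("no low-LD variant available at this locus")
        causal_g = int(rng.choice(low))
    xq = D[causal_q]
    yq = (np.sqrt(qtl_var / (1 - qtl_var) / xq.var())
          * (xq - xq.mean()) + rng.normal(size=n_qtl))
    qb, qs, qp = _marginal_stats(D.T, yq)
    qtl = pd.DataFrame({"id": gm.variants["id"], "beta": qb,
                        "se": qs, "p": qp}).dropna(subset=["se"])

    freqs = gm.allele_freq()
    H = _haplotypes(rng, 2 * gwas_n, freqs, cfg.ld_block_size,
                    cfg.within_block_copy_prob)
    X = (H[0::2] + H[1::2]).astype(np.float32)
    xg = X[:, causal_g]
    yg = (np.sqrt(gwas_var / max(xg.var(), 1e-6))
          * (xg - xg.mean()) + rng.normal(size=gwas_n).astype(np.float32))
    gb, gs, gp = _marginal_stats(X, yg)
    gt = pd.DataFrame({
        "id": gm.variants["id"], "chrom": gm.variants["chrom"],
        "pos": gm.variants["pos"], "effect_allele": gm.variants["alt"],
        "other_allele": gm.variants["ref"], "freq": X.mean(axis=0) / 2.0,
        "beta": gb, "se": gs, "p": gp, "n": gwas_n,
    }).dropna(subset=["se"])
    return {"genotypes": gm, "qtl": qtl, "gwas": GwasSumstats(gt),
            "qtl_causal": str(gm.variants["id"].iloc[causal_q]),
            "gwas_causal": str(gm.variants["id"].iloc[causal_g])}


# ---------------------------------------------------------------------------
# orchestration + disk round trip

def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None,
                     with_gwas: bool = True) -> SimulatedDataset:
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    genotypes = simulate_genotypes(config, seed)
    features, truth = simulate_features(config, genotypes, seed)
    atac, rna, sheet = simulate_counts(genotypes, features, truth, config,
                                       seed)
    gwas = simulate_gwas(genotypes, truth, config, seed) if with_gwas else None
    return SimulatedDataset(config=config, genotypes=genotypes,
                            features=features, truth=truth, atac=atac,
                            rna=rna, sheet=sheet, gwas=gwas)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(ds: SimulatedDataset, outdir: str,
                  force: bool = False) -> dict:
    """Write every component plus ground truth and a reproducibility manifest."""
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "annotations"), exist_ok=True)
    paths = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    sio.write_vcf(ds.genotypes, _p("genotypes.vcf"))
    sio.write_bed(ds.features.peaks, _p("peaks.bed"))
    ds.features.genes.to_csv(_p("genes.tsv"), sep="\t", index=False)
    sio.write_counts(ds.atac, _p("atac_counts.tsv"))
    sio.write_counts(ds.rna, _p("rna_counts.tsv"))
    sio.write_sample_sheet(ds.sheet, _p("samples.tsv"))
    ds.features.motif_table.rename_axis("peak_id").to_csv(
        _p("motifs.tsv"), sep="\t")
    for track, ivs in ds.features.annotations.items():
        sio.write_bed(ivs, _p(os.path.join("annotations", f"{track}.bed")))
    if ds.gwas is not None:
        sio.write_sumstats(ds.gwas, _p("gwas_sumstats.tsv"))
    ds.truth.features.to_csv(_p("truth_features.tsv"), sep="\t", index=False)
    ds.truth.pairs.to_csv(_p("truth_pairs.tsv"), sep="\t", index=False)
    ds.truth.motifs.to_csv(_p("truth_motifs.tsv"), sep="\t", index=False)
    if len(ds.truth.gwas_loci):
        ds.truth.gwas_loci.to_csv(_p("truth_gwas_loci.tsv"), sep="\t",
                                  index=False)

    cfg = asdict(ds.config)
    cfg["conditions"] = list(cfg["conditions"])
    cfg["maf_range"] = list(cfg["maf_range"])
    manifest = {
        "config": cfg,
        "seed": ds.config.seed,
        "checksums": {name: _sha256(path) for name, path in paths.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
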