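"""Declarative pipeline: simulate -> normalize -> differential -> QTL ->
response -> priming -> enrichment -> colocalization -> report.

Every stage reads its inputs from the run directory, writes TSV outputs with
stable column order plus a provenance JSON (stage, parameters, seed, input
hashes), and is skipped on re-run when the provenance still matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import coloc as mcoloc
from . import differential as mdiff
from . import enrichment as menr
from . import io as sio
from . import normalize as mnorm
from . import qtl as mqtl
from . import response as mresp
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_stage", "run_all", "report",
           "STAGES"]


@dataclass
class RunConfig:
    outdir: str = "stimqtl_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    reference_condition: str = "vehicle"
    fdr: float = 0.1
    lfc_min: float = 0.5
    n_pcs: int = 10
    n_genotype_pcs: int = 10
    ca_window: int = 25_000
    e_window: int = 1_000_000
    n_perm: int = 1000
    motif_top_n: int = 2000
    clpp_prior_sd: float = 0.15
    use_kinship: bool = False
    force: bool = False

    def sim_config(self) -> SimulationConfig:
        kwargs = dict(self.simulate)
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        if "maf_range" in kwargs:
            kwargs["maf_range"] = tuple(kwargs["maf_range"])
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# provenance

def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance_path(outdir: str, stage: str) -> str:
    return os.path.join(outdir, stage, "provenance.json")


def _stage_fresh(cfg: RunConfig, stage: str, inputs: list[str],
                 params: dict) -> bool:
    path = _provenance_path(cfg.outdir, stage)
    if cfg.force or not os.path.exists(path):
        return False
    with open(path) as fh:
        prov = json.load(fh)
    if prov.get("params") != _jsonable(params):
        return False
    for f, digest in prov.get("inputs", {}).items():
        if not os.path.exists(f) or _hash_file(f) != digest:
            logger.info("stage %s stale: %s changed", stage, f)
            return False
    return True


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _write_provenance(cfg: RunConfig, stage: str, inputs: list[str],
                      params: dict, outputs: list[str]) -> None:
    prov = {
        "stage": stage,
        "seed": cfg.seed,
        "params": _jsonable(params),
        "inputs": {f: _hash_file(f) for f in inputs},
        "outputs": outputs,
    }
    with open(_provenance_path(cfg.outdir, stage), "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)


def _stage_dir(cfg: RunConfig, stage: str) -> str:
    d = os.path.join(cfg.outdir, stage)
    os.makedirs(d, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# dataset loading

@dataclass
class Dataset:
    genotypes: GenotypeMatrix
    peaks: pd.DataFrame
    peak_gc: np.ndarray
    genes: pd.DataFrame
    atac: "sio.CountMatrix"
    rna: "sio.CountMatrix"
    sheet: "sio.SampleSheet"
    motifs: pd.DataFrame
    annotations: dict
    gwas: "sio.GwasSumstats | None"
    truth: pd.DataFrame | None


def load_dataset(dataset_dir: str) -> Dataset:
    p = lambda name: os.path.join(dataset_dir, name)
    genotypes = sio.read_vcf(p("genotypes.vcf"))
    peak_ivs = sio.read_bed(p("peaks.bed"))
    peaks = pd.DataFrame({
        "feature_id": [iv.name for iv in peak_ivs],
        "chrom": [iv.chrom for iv in peak_ivs],
        "start": [iv.start for iv in peak_ivs],
        "end": [iv.end for iv in peak_ivs],
    })
    peak_gc = np.array([iv.score if iv.score is not None else 0.5
                        for iv in peak_ivs])
    genes = pd.read_csv(p("genes.tsv"), sep="\t")
    atac = sio.read_counts(p("atac_counts.tsv"))
    rna = sio.read_counts(p("rna_counts.tsv"))
    sheet = sio.read_sample_sheet(p("samples.tsv"))
    motifs = pd.read_csv(p("motifs.tsv"), sep="\t", index_col=0)
    annotations = {}
    ann_dir = p("annotations")
    if os.path.isdir(ann_dir):
        for f in sorted(os.listdir(ann_dir)):
            if f.endswith(".bed"):
                annotations[f[:-4]] = sio.read_bed(os.path.join(ann_dir, f))
    gwas = None
    if os.path.exists(p("gwas_sumstats.tsv")):
        gwas = sio.read_sumstats(p("gwas_sumstats.tsv"))
    truth = None
    if os.path.exists(p("truth_features.tsv")):
        truth = pd.read_csv(p("truth_features.tsv"), sep="\t")
    return Dataset(genotypes, peaks, peak_gc, genes, atac, rna, sheet,
                   motifs, annotations, gwas, truth)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> str:
    outdir = os.path.join(cfg.outdir, "dataset")
    params = {"simulate": cfg.simulate, "seed": cfg.seed}
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest_path = os.path.join(outdir, "manifest.json")
    if not cfg.force and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("seed") == cfg.seed:
            logger.info("dataset up to date")
            return outdir
    ds = simulate_dataset(cfg.sim_config())
    write_dataset(ds, outdir, force=True)
    return outdir


def _normalized(ds: Dataset, cfg: RunConfig, assay: str
                ) -> mnorm.NormalizedMatrix:
    cm = ds.atac if assay == "atac" else ds.rna
    factors = mnorm.size_factors(cm)
    gc_off = None
    if assay == "atac":
        gc_off = mnorm.gc_normalize(cm, ds.peak_gc, factors=factors)
    return mnorm.vst_like(cm, factors, gc_off)


def stage_normalize(cfg: RunConfig, ds: Dataset) -> dict:
    d = _stage_dir(cfg, "normalize")
    out = {}
    for assay in ("atac", "rna"):
        nm = _normalized(ds, cfg, assay)
        nm.to_frame().rename_axis("feature_id").to_csv(
            os.path.join(d, f"{assay}.tsv"), sep="\t")
        out[assay] = nm
    pcs, kinship = mnorm.genotype_pcs_and_kinship(ds.genotypes,
                                                  cfg.n_genotype_pcs)
    pcs.rename_axis("donor_id").to_csv(os.path.join(d, "genotype_pcs.tsv"),
                                       sep="\t")
    pd.DataFrame(kinship, index=ds.genotypes.samples,
                 columns=ds.genotypes.samples).to_csv(
        os.path.join(d, "kinship.tsv"), sep="\t")
    out["genotype_pcs"], out["kinship"] = pcs, kinship
    _write_provenance(cfg, "normalize", [], {"n_pcs": cfg.n_pcs},
                      ["atac.tsv", "rna.tsv"])
    return out


def stage_differential(cfg: RunConfig, ds: Dataset, norm: dict) -> dict:
    d = _stage_dir(cfg, "differential")
    ref = cfg.reference_condition
    stims = [c for c in ds.sheet.conditions if c != ref]
    out = {}
    for assay in ("atac", "rna"):
        covs = ["rin"] if (assay == "rna"
                           and "rin" in ds.sheet.covariate_names) else None
        for stim in stims:
            res = mdiff.paired_diff(norm[assay], ds.sheet, (stim, ref),
                                    covariates=covs)
            res = mdiff.call_responsive(res, fdr=cfg.fdr,
                                        lfc_min=cfg.lfc_min)
            res.table.to_csv(os.path.join(d, f"{assay}_{stim}_vs_{ref}.tsv"),
                             sep="\t", index=False)
            out[(assay, stim)] = res
    _write_provenance(cfg, "differential", [],
                      {"fdr": cfg.fdr, "lfc_min": cfg.lfc_min},
                      sorted(f"{a}_{s}_vs_{ref}.tsv" for a, s in out))
    return out


def _per_condition_residual(norm, sheet, condition, n_pcs):
    samples = [s for s in sheet.condition_samples(condition)
               if s in set(norm.samples)]
    sub = norm.subset_samples(samples)
    n_pcs = min(n_pcs, max(0, len(samples) - 2))
    resid, _ = mnorm.pca_residualize(sub, n_pcs)
    return resid


def stage_qtl(cfg: RunConfig, ds: Dataset, norm: dict) -> dict:
    d = _stage_dir(cfg, "qtl")
    gene_feats = ds.genes.rename(columns={"gene_id": "feature_id"})
    out = {}
    for assay, feats, window, method in (
            ("atac", ds.peaks, cfg.ca_window, "eigenmt"),
            ("rna", gene_feats, cfg.e_window, "permutation")):
        if assay == "rna":
            factors = mnorm.size_factors(ds.rna)
            keep = mqtl.expressed_features(ds.rna.counts, factors)
            feats = feats[feats["feature_id"].isin(
                np.array(ds.rna.features)[keep])]
        for cond in ds.sheet.conditions:
            resid = _per_condition_residual(norm[assay], ds.sheet, cond,
                                            cfg.n_pcs)
            res = mqtl.map_qtls(resid, ds.genotypes, feats, ds.sheet, cond,
                                assay, window, local_method=method,
                                fdr=cfg.fdr, n_perm=cfg.n_perm,
                                seed=cfg.seed)
            res.scan.to_csv(os.path.join(d, f"{assay}_{cond}_scan.tsv"),
                            sep="\t", index=False)
            res.corrections.to_csv(
                os.path.join(d, f"{assay}_{cond}_features.tsv"),
                sep="\t", index=False)
            res.signals.to_csv(os.path.join(d, f"{assay}_{cond}_signals.tsv"),
                               sep="\t", index=False)
            out[(assay, cond)] = res
    _write_provenance(cfg, "qtl", [],
                      {"fdr": cfg.fdr, "n_pcs": cfg.n_pcs,
                       "n_perm": cfg.n_perm},
                      sorted(f"{a}_{c}_scan.tsv" for a, c in out))
    return out


def _index_qtls(qtl_results: dict, assay: str, conditions: list[str]
                ) -> pd.DataFrame:
    """Union of index signals significant in any listed condition."""
    seen = {}
    for cond in conditions:
        res = qtl_results.get((assay, cond))
        if res is None or len(res.signals) == 0:
            continue
        idx = res.signals[res.signals["signal_rank"] == 0]
        for rec in idx.itertuples():
            seen.setdefault((rec.feature, rec.variant), True)
    return pd.DataFrame([{"feature": f, "variant": v} for f, v in seen])


def stage_response(cfg: RunConfig, ds: Dataset, norm: dict,
                   qtl_results: dict) -> dict:
    d = _stage_dir(cfg, "response")
    ref = cfg.reference_condition
    stims = [c for c in ds.sheet.conditions if c != ref]
    out = {"interactions": {}, "sharing": {}}
    for assay in ("atac", "rna"):
        nm = norm[assay]
        resid, _ = mnorm.pca_residualize(nm, min(cfg.n_pcs,
                                                 len(nm.samples) - 2))
        for stim in stims:
            idx = _index_qtls(qtl_results, assay, [stim, ref])
            if len(idx) == 0:
                recs = pd.DataFrame()
            else:
                recs = mresp.interaction_scan(resid, ds.genotypes, ds.sheet,
                                              idx, (stim, ref))
                recs = mresp.call_response_qtls(recs, fdr=cfg.fdr)
            recs.to_csv(os.path.join(d, f"{assay}_{stim}_vs_{ref}.tsv"),
                        sep="\t", index=False)
            out["interactions"][(assay, stim)] = recs
        sig = {c: qtl_results[(assay, c)].significant_features
               for c in ds.sheet.conditions}
        table, increment = mresp.classify_sharing(sig, ref)
        table.to_csv(os.path.join(d, f"{assay}_sharing.tsv"), sep="\t",
                     index=False)
        out["sharing"][assay] = (table, increment)
    _write_provenance(cfg, "response", [], {"fdr": cfg.fdr}, [])
    return out


def stage_prime(cfg: RunConfig, ds: Dataset, qtl_results: dict) -> dict:
    d = _stage_dir(cfg, "prime")
    ref = cfg.reference_condition
    stims = [c for c in ds.sheet.conditions if c != ref]
    out = {}
    for stim in stims:
        ca = {c: qtl_results[("atac", c)] for c in (stim, ref)}
        eq = {c: qtl_results[("rna", c)] for c in (stim, ref)}
        calls = mresp.link_and_classify_priming(
            ca, eq, ds.genotypes, ds.peaks, ds.genes, (stim, ref))
        table = pd.DataFrame([{
            "peak": c.peak, "gene": c.gene, "ca_snp": c.ca_snp,
            "e_snp": c.e_snp, "r2": c.r2, "label": c.label}
            for c in calls])
        table.to_csv(os.path.join(d, f"{stim}_vs_{ref}.tsv"), sep="\t",
                     index=False)
        out[stim] = table
    _write_provenance(cfg, "prime", [], {}, [])
    return out


def stage_enrich(cfg: RunConfig, ds: Dataset, diff_results: dict,
                 qtl_results: dict, response: dict) -> dict:
    d = _stage_dir(cfg, "enrich")
    ref = cfg.reference_condition
    stims = [c for c in ds.sheet.conditions if c != ref]
    out = {"motif": {}, "overlap": {}, "tss": {}}
    peak_ivs = {r.feature_id: r for r in ds.peaks.itertuples()}

    for stim in stims:
        diff = diff_results[("atac", stim)]
        opened = menr.select_top_peaks(diff.table, "open", cfg.motif_top_n)
        closed = menr.select_top_peaks(diff.table, "closed", cfg.motif_top_n)
        if opened and closed:
            sub = ds.motifs.loc[opened + closed]
            labels = pd.Series([1] * len(opened) + [0] * len(closed),
                               index=sub.index)
            res = menr.motif_glm(sub, labels, fdr=cfg.fdr)
            res.to_csv(os.path.join(d, f"motif_{stim}_vs_{ref}.tsv"),
                       sep="\t", index=False)
            out["motif"][stim] = res

    from .types import GenomicInterval
    all_peaks = [GenomicInterval(r.chrom, r.start, r.end, r.feature_id)
                 for r in ds.peaks.itertuples()]
    iv_of = {iv.name: iv for iv in all_peaks}
    rows = []
    for cond in ds.sheet.conditions:
        sig = qtl_results[("atac", cond)].significant_features
        query = [iv_of[f] for f in sig if f in iv_of]
        if not query:
            continue
        for track, ann in ds.annotations.items():
            rec = menr.overlap_binomial(query, ann, all_peaks,
                                        name=f"{cond}:{track}")
            rows.append({"condition": cond, "track": track,
                         "k": rec.k, "n": rec.n, "fold": rec.effect,
                         "p": rec.p})
            out["overlap"][(cond, track)] = rec
    pd.DataFrame(rows).to_csv(os.path.join(d, "overlap_enrichment.tsv"),
                              sep="\t", index=False)

    # TSS distance: response vs non-response eQTLs
    genes = ds.genes.copy()
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"],
                            genes["start"] + 1)
    tss_of = dict(zip(genes["gene_id"], genes["tss"]))
    pos_of = dict(zip(ds.genotypes.variants["id"],
                      ds.genotypes.variants["pos"]))
    for stim in stims:
        recs = response["interactions"].get(("rna", stim))
        if recs is None or len(recs) == 0 or "is_response" not in recs:
            continue
        dists = recs.apply(
            lambda r: abs(pos_of[r["variant"]] - tss_of[r["feature"]]),
            axis=1)
        comp = menr.tss_distance_compare(dists[recs["is_response"]],
                                         dists[~recs["is_response"]])
        out["tss"][stim] = comp
    with open(os.path.join(d, "tss_distance.json"), "w") as fh:
        json.dump(_jsonable(out["tss"]), fh, indent=2)
    _write_provenance(cfg, "enrich", [], {"top_n": cfg.motif_top_n}, [])
    return out


def stage_coloc(cfg: RunConfig, ds: Dataset, qtl_results: dict) -> pd.DataFrame:
    d = _stage_dir(cfg, "coloc")
    if ds.gwas is None:
        pd.DataFrame().to_csv(os.path.join(d, "coloc.tsv"), sep="\t")
        return pd.DataFrame()
    rows = []
    for (assay, cond), res in qtl_results.items():
        if len(res.signals) == 0:
            continue
        idx = res.signals[res.signals["signal_rank"] == 0][
            ["feature", "variant"]]
        try:
            cands = mcoloc.find_candidates(ds.gwas, idx, ds.genotypes)
        except ValueError:
            continue
        for cand in cands:
            locus = res.scan[res.scan["feature"] == cand.feature][
                ["variant", "beta", "se", "p"]].rename(
                columns={"variant": "id"})
            cres = mcoloc.colocalize(cand, ds.gwas, locus, ds.genotypes,
                                     prior_sd=cfg.clpp_prior_sd)
            rows.append({"assay": assay, "condition": cond,
                         "feature": cand.feature,
                         "qtl_index": cand.qtl_index,
                         "gwas_index": cand.gwas_index,
                         "index_r2": cand.index_r2,
                         "clpp_max": cres.clpp_max,
                         "clpp_snp": cres.clpp_snp,
                         "r2_to_gw_snp": cres.r2_to_gw_snp,
                         "conditional_pass": cres.conditional_pass,
                         "verdict": cres.verdict,
                         "salvage": cres.salvage})
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(d, "coloc.tsv"), sep="\t", index=False)
    _write_provenance(cfg, "coloc", [], {"prior_sd": cfg.clpp_prior_sd}, [])
    return table


def report(cfg: RunConfig, ds: Dataset, diff_results: dict,
           qtl_results: dict, response: dict, priming: dict,
           coloc_table: pd.DataFrame) -> dict:
    """Headline tabular summary; confusion matrices when truth is present."""
    ref = cfg.reference_condition
    stims = [c for c in ds.sheet.conditions if c != ref]
    rep: dict = {"conditions": list(ds.sheet.conditions)}
    rep["responsive"] = {
        f"{assay}_{stim}": int((diff_results[(assay, stim)]
                                .table["direction"] != "ns").sum())
        for assay in ("atac", "rna") for stim in stims
        if (assay, stim) in diff_results}
    rep["qtl_features"] = {
        f"{assay}_{cond}": len(res.significant_features)
        for (assay, cond), res in qtl_results.items()}
    rep["qtl_pairs"] = {
        f"{assay}_{cond}": int(len(res.significant_pairs))
        for (assay, cond), res in qtl_results.items()}
    rep["stimulated_only_increment_pct"] = {
        assay: response["sharing"][assay][1]
        for assay in response.get("sharing", {})}
    rep["response_qtls"] = {
        f"{assay}_{stim}": int(recs["is_response"].sum())
        for (assay, stim), recs in response.get("interactions", {}).items()
        if len(recs) and "is_response" in recs}
    rep["priming_calls"] = {
        stim: table["label"].value_counts().to_dict()
        for stim, table in priming.items() if len(table)}
    if len(coloc_table):
        rep["coloc_verdicts"] = (coloc_table["verdict"]
                                 .value_counts().to_dict())
    if ds.truth is not None:
        truth = ds.truth.set_index("feature")
        confusion = {}
        for (assay, cond), res in qtl_results.items():
            kind = "peak" if assay == "atac" else "gene"
            sub = truth[truth["kind"] == kind]
            has_qtl = sub[f"beta_{cond}"].abs() > 0
            called = sub.index.isin(res.significant_features)
            confusion[f"{assay}_{cond}"] = {
                "tp": int((has_qtl & called).sum()),
                "fp": int((~has_qtl & called).sum()),
                "fn": int((has_qtl & ~called).sum()),
                "tn": int((~has_qtl & ~called).sum()),
            }
        rep["truth_confusion"] = confusion
    path = os.path.join(cfg.outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(_jsonable(rep), fh, indent=2, sort_keys=True)
    return rep


STAGES = ["simulate", "normalize", "differential", "qtl", "response",
          "prime", "enrich", "coloc", "report"]


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order; returns the report dictionary."""
    return run_stage("report", cfg)


def run_stage(name: str, cfg: RunConfig) -> dict:
    """Run the pipeline up to and including ``name``.

    Prerequisite stages are recomputed in memory (the simulated dataset is
    reused from disk when its manifest matches the seed); only stages up to
    ``name`` have their outputs written.
    """
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r} (choose from {STAGES})")
    upto = STAGES.index(name)
    dataset_dir = stage_simulate(cfg)
    ds = load_dataset(dataset_dir)
    rep_val = sio.validate_dataset(ds.genotypes, ds.sheet, ds.atac, ds.rna)
    for w in rep_val.warnings:
        logger.info("validate: %s", w)
    out: dict = {"dataset_dir": dataset_dir}
    if upto < 1:
        return out
    norm = stage_normalize(cfg, ds)
    if upto < 2:
        return out
    diff_results = stage_differential(cfg, ds, norm)
    if upto < 3:
        return out
    qtl_results = stage_qtl(cfg, ds, norm)
    if upto < 4:
        return out
    resp = stage_response(cfg, ds, norm, qtl_results)
    if upto < 5:
        return out
    priming = stage_prime(cfg, ds, qtl_results)
    if upto < 6:
        return out
    stage_enrich(cfg, ds, diff_results, qtl_results, resp)
    if upto < 7:
        return out
    coloc_table = stage_coloc(cfg, ds, qtl_results)
    if upto < 8:
        return out
    return report(cfg, ds, diff_results, qtl_results, resp, priming,
                  coloc_table)
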