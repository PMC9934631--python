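"""Paired within-donor differential accessibility / expression.

Each feature is tested with a moderated one-sample t on within-donor
differences (stimulated minus vehicle) of normalized values.  Variances are
shrunk toward a common prior fitted across features by method of moments
(empirical Bayes), and log2 fold changes are shrunk with a normal prior
whose variance is the across-feature variance of the raw estimates.
Responsive elements/genes are called at BH FDR < 0.1 and |shrunken LFC| > 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix
from .types import SampleSheet

logger = logging.getLogger(__name__)

__all__ = ["DiffResult", "paired_diff", "call_responsive",
           "moderate_variances"]


@dataclass
class DiffResult:
    """Per-feature paired differential statistics (log2 scale)."""

    table: pd.DataFrame  # feature, lfc_raw, lfc_shrunk, se, t, p, padj, direction
    condition_pair: tuple[str, str]
    n_pairs: int


def moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance moderation.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the per-feature
    sample variances by method of moments and returns posterior variances
    s2_post = (d0*s0^2 + df*s2) / (d0 + df) together with (d0, s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.mean(s2))
    m = float(np.mean(s2[ok]))
    v = float(np.var(s2[ok], ddof=1))
    # Var(s2)/E[s2]^2 = 2/df + 2/d0 under the hierarchical model
    excess = v / (m * m) - 2.0 / df
    d0 = np.inf if excess <= 0 else 2.0 / excess
    s0_2 = m
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return s2_post, float(d0), s0_2


def paired_diff(norm: NormalizedMatrix, sheet: SampleSheet,
                condition_pair: tuple[str, str],
                covariates: list[str] | None = None,
                min_pairs: int = 4) -> DiffResult:
    """Moderated paired test of ``condition_pair = (stimulated, vehicle)``.

    Donors present in only one of the two conditions are dropped.  Numeric
    sample covariates (e.g. an RNA-integrity score) are regressed out of the
    normalized values across the paired samples before differencing.
    """
    stim, veh = condition_pair
    t = sheet.table
    t = t[t["sample_id"].isin(set(norm.samples))]
    by_cond = {
        c: t[t["condition"] == c].set_index("donor_id")["sample_id"]
        for c in (stim, veh)
    }
    donors = sorted(set(by_cond[stim].index) & set(by_cond[veh].index))
    dropped = (set(by_cond[stim].index) | set(by_cond[veh].index)) - set(donors)
    if dropped:
        logger.info("dropped %d donors present in only one condition",
                    len(dropped))
    if len(donors) < min_pairs:
        raise ValueError(
            f"only {len(donors)} complete donor pairs (< {min_pairs})")
    stim_samples = [by_cond[stim][d] for d in donors]
    veh_samples = [by_cond[veh][d] for d in donors]
    col = {s: i for i, s in enumerate(norm.samples)}
    X = norm.values
    xs = X[:, [col[s] for s in stim_samples]]
    xv = X[:, [col[s] for s in veh_samples]]

    if covariates:
        samples = stim_samples + veh_samples
        cov = (sheet.table.set_index("sample_id")
               .loc[samples, covariates].to_numpy(dtype=float))
        Z = np.column_stack([np.ones(len(samples)), cov])
        Y = np.concatenate([xs, xv], axis=1)
        beta, *_ = np.linalg.lstsq(Z, Y.T, rcond=None)
        Y = Y - (Z @ beta).T
        xs, xv = Y[:, :len(donors)], Y[:, len(donors):]

    d = xs - xv
    n = len(donors)
    lfc_raw = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1
    s2_post, d0, s0_2 = moderate_variances(s2, df)
    se = np.sqrt(s2_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, lfc_raw / se, np.where(lfc_raw == 0, 0.0,
                                                        np.inf * np.sign(lfc_raw)))
    df_total = df + (d0 if np.isfinite(d0) else 1e6)
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    # degenerate features: zero variance and zero mean difference
    degenerate = (s2 == 0) & (lfc_raw == 0)
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    s2_between = float(np.var(lfc_raw, ddof=1)) if len(lfc_raw) > 1 else 0.0
    shrink = s2_between / (s2_between + se ** 2) if s2_between > 0 else 0.0
    lfc_shrunk = lfc_raw * shrink

    table = pd.DataFrame({
        "feature": norm.features,
        "lfc_raw": lfc_raw,
        "lfc_shrunk": lfc_shrunk,
        "se": se,
        "t": tstat,
        "p": p,
        "padj": padj,
    })
    table["direction"] = "ns"
    return DiffResult(table=table, condition_pair=(stim, veh), n_pairs=n)


def call_responsive(result: DiffResult, fdr: float = 0.1,
                    lfc_min: float = 0.5,
                    use_shrunk: bool = True) -> DiffResult:
    """Call responsive features: BH padj < ``fdr`` and |LFC| > ``lfc_min``.

    Direction is ``open``/``closed`` (accessibility) a.k.a. up/down; a new
    DiffResult with the ``direction`` column filled is returned.
    """
    table = result.table.copy()
    lfc = table["lfc_shrunk"] if use_shrunk else table["lfc_raw"]
    sig = (table["padj"] < fdr) & (lfc.abs() > lfc_min)
    table["direction"] = np.where(~sig, "ns",
                                  np.where(lfc > 0, "open", "closed"))
    return DiffResult(table=table, condition_pair=result.condition_pair,
                      n_pairs=result.n_pairs)
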