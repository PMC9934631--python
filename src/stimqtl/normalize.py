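"""Count normalization and genotype summaries.

The normalized scale used throughout the pipeline is a shifted log2 of
size-factor-scaled counts with an optional per-sample GC offset removed,
followed by principal-component residualization.  Downstream association
models are linear on this scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "size_factors",
    "gc_normalize",
    "vst_like",
    "pca_residualize",
    "hwe_exact_test",
    "genotype_pcs_and_kinship",
]


@dataclass
class NormalizedMatrix:
    """Features x samples real-valued matrix with normalization provenance."""

    features: list[str]
    samples: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError("value shape does not match feature/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features,
                            columns=self.samples)

    def subset_samples(self, samples: list[str]) -> "NormalizedMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        cols = [idx[s] for s in samples]
        return NormalizedMatrix(list(self.features), list(samples),
                                self.values[:, cols], dict(self.provenance))


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios library-size factors, geometric mean rescaled to 1.

    Falls back to upper-quartile factors when no feature has all-positive
    counts.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples for size factors")
    positive = np.all(counts > 0, axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)  # log geometric mean
        factors = np.exp(np.median(logc - ref, axis=0))
    else:
        logger.warning("no feature with all-positive counts; "
                       "falling back to upper-quartile size factors")
        factors = np.percentile(counts, 75, axis=0)
        if np.any(factors <= 0):
            raise ValueError("upper-quartile size factor is zero")
    return factors / np.exp(np.mean(np.log(factors)))


def gc_normalize(cm: CountMatrix, gc: np.ndarray, n_bins: int = 20,
                 factors: np.ndarray | None = None,
                 pseudocount: float = 0.5) -> np.ndarray:
    """Per-sample GC-content offsets on the log2 scale.

    Features are binned by GC quantile; within each sample the offset curve
    is the bin median of the feature's log2 deviation from its cross-sample
    mean, linearly interpolated at each feature's GC.  Subtracting the
    returned matrix from log2-normalized values removes a smooth per-sample
    GC trend.  Constant GC yields all-zero offsets.
    """
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(cm.features):
        raise ValueError("gc vector length must match features")
    if factors is None:
        factors = size_factors(cm)
    logv = np.log2(cm.counts / factors[None, :] + pseudocount)
    resid = logv - logv.mean(axis=1, keepdims=True)
    if np.ptp(gc) == 0:
        return np.zeros_like(logv)
    edges = np.quantile(gc, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, gc, side="right") - 1,
                   0, len(edges) - 2)
    offsets = np.zeros_like(logv)
    centers, used = [], []
    for b in range(len(edges) - 1):
        mask = bins == b
        if mask.sum() == 0:
            continue
        centers.append(gc[mask].mean())
        used.append(mask)
    for s in range(logv.shape[1]):
        med = np.array([np.median(resid[m, s]) for m in used])
        offsets[:, s] = np.interp(gc, centers, med)
    return offsets


def vst_like(cm: CountMatrix, factors: np.ndarray,
             gc_offsets: np.ndarray | None = None,
             pseudocount: float = 0.5) -> NormalizedMatrix:
    """Shifted-log variance-stabilizing transform.

    value = log2(count / size_factor + pseudocount) - gc_offset.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    values = np.log2(cm.counts / factors[None, :] + pseudocount)
    if gc_offsets is not None:
        values = values - gc_offsets
    return NormalizedMatrix(
        list(cm.features), list(cm.samples), values,
        provenance={"size_factors": factors, "transform": "log2",
                    "pseudocount": pseudocount,
                    "gc_corrected": gc_offsets is not None})


def pca_residualize(nm: NormalizedMatrix, n_pcs: int = 10,
                    cap_fraction: float | None = 0.25,
                    return_pcs: bool = True,
                    ) -> tuple[NormalizedMatrix, np.ndarray]:
    """Remove the top sample-space principal components per feature.

    Features are row-centered, the top PCs of the sample covariance are
    computed by SVD, and every feature is regressed on them; residuals are
    returned together with the PC matrix (samples x n_pcs), which can be
    used as fixed covariates instead of residualizing.

    ``n_pcs`` defaults to 10 and is capped at ``cap_fraction * n_samples``
    (with a log line) so small runs keep degrees of freedom.
    """
    n_samples = len(nm.samples)
    if n_pcs >= n_samples:
        raise ValueError(f"n_pcs={n_pcs} must be < n_samples={n_samples}")
    if cap_fraction is not None:
        cap = max(1, int(n_samples * cap_fraction))
        if n_pcs > cap:
            logger.warning("capping n_pcs at %d (= %d samples x %.2f)",
                           cap, n_samples, cap_fraction)
            n_pcs = cap
    X = nm.values - nm.values.mean(axis=1, keepdims=True)
    if n_pcs == 0:
        pcs = np.empty((n_samples, 0))
        resid = X
    else:
        # right singular vectors = sample-space PCs
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        pcs = vt[:n_pcs].T
        resid = X - (X @ pcs) @ pcs.T
    out = NormalizedMatrix(list(nm.features), list(nm.samples), resid,
                           provenance={**nm.provenance,
                                       "n_pcs_removed": n_pcs})
    return out, pcs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, heterozygote counts follow
    the exact HWE distribution; the two-sided p-value sums the probability
    of all heterozygote counts whose probability does not exceed that of the
    observed count.  Computed with a stable recurrence on the heterozygote
    count.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible het counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized log probabilities via the exact conditional formula
    logp = np.empty(len(hets))
    # P(het) ∝ n! / (a! h! b!) * 2^h with a=(n_rare-h)/2, b=n-(n_rare+h)/2
    for i, h in enumerate(hets):
        a = (n_rare - h) // 2
        b = n - a - h
        logp[i] = (h * math.log(2.0)
                   - math.lgamma(a + 1) - math.lgamma(h + 1)
                   - math.lgamma(b + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = n_het
    if obs not in hets:
        raise ValueError(
            f"heterozygote count {obs} inconsistent with allele counts")
    p_obs = prob[np.searchsorted(hets, obs)]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def genotype_pcs_and_kinship(gm: GenotypeMatrix, n_pcs: int = 10,
                             ) -> tuple[pd.DataFrame, np.ndarray]:
    """Genomic-relationship kinship matrix and ancestry PCs.

    Dosages are mean-imputed, centered at 2f and scaled by sqrt(2f(1-f));
    K = Z'Z / M over donors.  PCs are K's leading eigenvectors scaled by
    the square roots of their eigenvalues (MDS-style coordinates).
    Monomorphic variants are excluded.
    """
    d = gm.dosage.copy()
    col_missing = np.isnan(d)
    if col_missing.any():
        means = np.nanmean(d, axis=1)
        d[col_missing] = np.broadcast_to(means[:, None], d.shape)[col_missing]
    f = d.mean(axis=1) / 2.0
    poly = (f > 0) & (f < 1)
    d, f = d[poly], f[poly]
    if len(d) == 0:
        raise ValueError("no polymorphic variants for kinship")
    z = (d - 2 * f[:, None]) / np.sqrt(2 * f * (1 - f))[:, None]
    K = z.T @ z / len(z)
    n_pcs = min(n_pcs, K.shape[0] - 1)
    w, v = np.linalg.eigh(K)
    order = np.argsort(w)[::-1][:n_pcs]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    pcs = pd.DataFrame(coords, index=gm.samples,
                       columns=[f"PC{i + 1}" for i in range(n_pcs)])
    return pcs, K
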