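"""Variant-level genotype QC, LD pruning, and genotype PCA.

Filters: call rate < 0.99, MAF < 0.01, or Hardy-Weinberg exact p < 1e-4
remove a variant (all strict comparisons).  Pruning is a 50-variant
window advanced by 5 with an r-squared threshold of 0.8.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix
from .errors import ConfigurationError, DomainError
from .exact import hwe_exact_p  # noqa: F401  (canonical home is exact.py)


@dataclass
class QcThresholds:
    min_call_rate: float = 0.99
    min_maf: float = 0.01
    min_hwe_p: float = 1e-4

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1)")


def call_rate(column: np.ndarray) -> float:
    """Fraction of samples with a non-missing call."""
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise DomainError("call rate undefined for zero samples")
    return float(np.isfinite(column).sum() / column.size)


def maf(column: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p) over non-missing samples."""
    column = np.asarray(column, dtype=float)
    mask = np.isfinite(column)
    n = int(mask.sum())
    if n == 0:
        raise DomainError("MAF undefined with no called samples")
    p = float(column[mask].sum()) / (2 * n)
    return min(p, 1.0 - p)


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts over non-missing samples."""
    column = np.asarray(column, dtype=float)
    g = column[np.isfinite(column)].astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square alternative to the exact test."""
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise DomainError("HWE test requires >= 1 sample")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QcReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    removed: pd.DataFrame = field(repr=False, default=None)


def variant_qc(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants failing call-rate, MAF, or HWE filters.

    A variant failing several filters is counted once per filter; removal
    reasons are recorded in the report for auditability.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    hwe_fn = {"exact": hwe_exact_p, "chisq": hwe_chisq_p}.get(hwe_method)
    if hwe_fn is None:
        raise ConfigurationError("hwe_method must be 'exact' or 'chisq'")

    keep = np.ones(matrix.n_variants, dtype=bool)
    reasons: list[tuple[str, str]] = []
    counts = {"call_rate": 0, "maf": 0, "hwe": 0}
    for j in range(matrix.n_variants):
        col = matrix.dosages[:, j]
        rsid = matrix.variants["rsid"].iat[j]
        fails = []
        if call_rate(col) < thresholds.min_call_rate:
            fails.append("call_rate")
        called = col[np.isfinite(col)]
        if called.size == 0 or maf(col) < thresholds.min_maf:
            fails.append("maf")
        if called.size and hwe_fn(*genotype_counts(col)) < thresholds.min_hwe_p:
            fails.append("hwe")
        if fails:
            keep[j] = False
            for f in fails:
                counts[f] += 1
                reasons.append((rsid, f))

    report = QcReport(
        n_input=matrix.n_variants,
        n_removed_call_rate=counts["call_rate"],
        n_removed_maf=counts["maf"],
        n_removed_hwe=counts["hwe"],
        n_retained=int(keep.sum()),
        removed=pd.DataFrame(reasons, columns=["rsid", "reason"]),
    )
    return matrix.subset_variants(keep), report


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over samples
    non-missing in both; 0 when either is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        return 0.0
    x, y = a[mask], b[mask]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return min(1.0, r * r)


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.8,
) -> list[str]:
    """Greedy sliding-window pruning; returns retained rsIDs in input order.

    Within each window, while any retained pair exceeds the threshold the
    member with the lower MAF is removed (ties: the later position).
    Windows never span chromosomes.
    """
    if window <= 0 or step <= 0 or window < step:
        raise ConfigurationError("require window >= step > 0")

    mafs = np.array([maf(matrix.dosages[:, j]) for j in range(matrix.n_variants)])
    retained = np.ones(matrix.n_variants, dtype=bool)

    for _, sub in matrix.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        start = 0
        while start < len(idx):
            win = idx[start:start + window]
            self_r2 = {}
            changed = True
            while changed:
                changed = False
                active = [j for j in win if retained[j]]
                for ii in range(len(active)):
                    for jj in range(ii + 1, len(active)):
                        a, b = active[ii], active[jj]
                        key = (a, b)
                        if key not in self_r2:
                            self_r2[key] = ld_r2(matrix.dosages[:, a],
                                                 matrix.dosages[:, b])
                        if self_r2[key] > r2_threshold:
                            if mafs[a] < mafs[b]:
                                drop = a
                            elif mafs[b] < mafs[a]:
                                drop = b
                            else:
                                drop = b  # equal MAF: drop the later position
                            retained[drop] = False
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= len(idx):
                break
            start += step

    return [matrix.variants["rsid"].iat[j] for j in range(matrix.n_variants)
            if retained[j]]


def genotype_pca(
    matrix: GenotypeMatrix, k: int = 3, outlier_sd: float = 6.0
) -> pd.DataFrame:
    """Top-k PCs of the column-standardized dosage matrix.

    Returns one row per sample with PC scores and an ``outlier`` flag set
    when any score exceeds ``outlier_sd`` standard deviations.
    """
    if k <= 0:
        raise ConfigurationError("k must be > 0")
    X = np.asarray(matrix.dosages, dtype=float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, mean)  # mean-impute the rare missing call
    X = X - mean
    sd = X.std(axis=0)
    X = X[:, sd > 0] / sd[sd > 0]
    k = min(k, min(X.shape))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    out = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    out.insert(0, "sample", matrix.samples)
    z = scores / scores.std(axis=0, ddof=1)
    out["outlier"] = (np.abs(z) > outlier_sd).any(axis=1)
    return out
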