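"""Additive-model pQTL scan with covariate adjustment.

Per (variant, protein) pair an OLS slope of protein level on alt-allele
dosage is fitted, adjusting for gender, ethnicity, and the top genotype
PCs; significance uses a single genome-wide threshold (alpha / number of
SNPs).  Variants within 1 Mb of the regulated gene body are classified
local, all others distant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ProteinMatrix
from .errors import ConfigurationError, InputValidationError
from .qc import genotype_pca, maf as _maf

logger = logging.getLogger(__name__)

LOCAL_DISTANCE = 1_000_000


@dataclass
class ScanConfig:
    threshold: float | None = None   # None: alpha / n_variants
    alpha: float = 0.05
    local_distance: int = LOCAL_DISTANCE
    min_quantified_frac: float = 0.90
    use_pcs: bool = True
    n_pcs: int = 3
    log10_transform: bool = False

    def validate(self) -> None:
        if self.threshold is not None and not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.local_distance < 0:
            raise ConfigurationError("local_distance must be >= 0")
        if not (0.0 <= self.min_quantified_frac < 1.0):
            raise ConfigurationError("min_quantified_frac must be in [0, 1)")


def significance_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """Genome-wide p-value threshold alpha / n_snps, reported at three
    significant figures (0.05 / 1,671,387 -> 2.99e-8)."""
    if n_snps <= 0:
        raise ConfigurationError("n_snps must be > 0")
    return float(f"{alpha / n_snps:.3g}")


def eligible_proteins(matrix: ProteinMatrix, min_frac: float = 0.90) -> list[str]:
    """Proteins quantified in strictly more than ``min_frac`` of samples."""
    frac = matrix.values.notna().mean(axis=1)
    return list(matrix.values.index[frac > min_frac])


def classify_local_distant(
    chrom: str, pos: int, gene_chrom: str, gene_start: int, gene_end: int,
    limit: int = LOCAL_DISTANCE,
) -> str:
    """'local' iff the variant is on the gene's chromosome and within
    ``limit`` bp of the gene body (inclusive; 0 inside the gene)."""
    if str(chrom) != str(gene_chrom):
        return "distant"
    if gene_start <= pos <= gene_end:
        return "local"
    dist = min(abs(pos - gene_start), abs(pos - gene_end))
    return "local" if dist <= limit else "distant"


def build_design(covariates: pd.DataFrame, pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dummy-code gender/ethnicity (largest group as reference) and attach
    PC columns; indexed by sample, no intercept column."""
    cov = covariates.set_index("sample")
    cols = {}
    for factor in ("gender", "ethnicity"):
        if factor not in cov.columns:
            continue
        levels = cov[factor].value_counts()
        for level in levels.index[1:]:  # largest level is the reference
            cols[f"{factor}_{level}"] = (cov[factor] == level).astype(float)
    design = pd.DataFrame(cols, index=cov.index)
    if pcs is not None:
        pc_cols = [c for c in pcs.columns if c.startswith("PC")]
        design = design.join(pcs.set_index("sample")[pc_cols])
    return design


@dataclass
class FitResult:
    beta: float
    se: float
    t: float
    p: float
    n: int


def fit_additive(
    dosage: np.ndarray, protein: np.ndarray, covariates: np.ndarray | None = None
) -> FitResult | None:
    """OLS slope of protein on dosage with optional covariate columns.

    Listwise-deletes incomplete cases; two-sided p from the t distribution
    with n - n_parameters degrees of freedom.  Returns None (caller logs
    and skips) when the dosage is constant after case deletion or there
    are too few complete cases.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(protein, dtype=float)
    if covariates is None:
        covariates = np.empty((len(g), 0))
    C = np.asarray(covariates, dtype=float)
    mask = np.isfinite(g) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    g, y, C = g[mask], y[mask], C[mask]
    n = len(g)
    n_par = 2 + C.shape[1]
    if n < n_par or np.ptp(g) == 0.0:
        return None
    X = np.column_stack([g, np.ones(n), C])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    beta = float(coef[0])
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return FitResult(beta=beta, se=se, t=t, p=max(p, np.nextafter(0, 1)), n=n)


def _fit_protein_all_variants(
    G: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """Vectorized OLS of one protein against every variant at once via
    residualization on the covariate design (Frisch-Waugh).

    Returns (beta, se, t, p, n, valid) arrays over variants.
    """
    mask = np.isfinite(y) & np.isfinite(C).all(axis=1) & np.isfinite(G).all(axis=1)
    Gm, ym, Cm = G[mask], y[mask], C[mask]
    n = int(mask.sum())
    X = np.column_stack([np.ones(n), Cm])
    q, _ = np.linalg.qr(X)
    y_r = ym - q @ (q.T @ ym)
    G_r = Gm - q @ (q.T @ Gm)
    gss = (G_r ** 2).sum(axis=0)
    valid = (gss > 1e-12) & (np.ptp(Gm, axis=0) > 0)
    gss_safe = np.where(valid, gss, 1.0)
    beta = (G_r * y_r[:, None]).sum(axis=0) / gss_safe
    rss = float(y_r @ y_r) - beta ** 2 * gss_safe
    df = n - X.shape[1] - 1
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / gss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return beta, se, t, p, n, valid


@dataclass
class ScanResult:
    records: pd.DataFrame                 # significant associations
    threshold: float
    n_tests: int
    summary: dict = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    all_p: pd.DataFrame | None = None     # proteins x variants, if kept


RECORD_COLUMNS = ["rsid", "chrom", "pos", "protein", "gene", "beta", "se", "t",
                  "p", "n", "class", "maf"]


def scan(
    genotypes: GenotypeMatrix,
    proteins: ProteinMatrix,
    covariates: pd.DataFrame,
    config: ScanConfig | None = None,
    pcs: pd.DataFrame | None = None,
    keep_all_p: bool = False,
) -> ScanResult:
    """Run the full variant x protein association scan.

    Sample IDs must agree across inputs (an error lists any mismatch).
    PCs are computed from the genotype matrix when requested and not
    supplied.
    """
    config = config or ScanConfig()
    config.validate()

    geno_samples = list(genotypes.samples)
    unmatched = (set(proteins.samples) ^ set(geno_samples)) | (
        set(covariates["sample"]) ^ set(geno_samples))
    if unmatched:
        raise InputValidationError(
            f"sample IDs differ across inputs: {sorted(unmatched)[:10]}")

    if config.use_pcs and pcs is None:
        pcs = genotype_pca(genotypes, k=config.n_pcs)
    design = build_design(covariates, pcs if config.use_pcs else None)
    C = design.loc[geno_samples].to_numpy(dtype=float)

    eligible = eligible_proteins(proteins, config.min_quantified_frac)
    values = proteins.values.loc[eligible, geno_samples]
    if config.log10_transform:
        values = np.log10(values)

    threshold = (config.threshold if config.threshold is not None
                 else significance_threshold(genotypes.n_variants, config.alpha))

    meta = proteins.meta_indexed()
    variants = genotypes.variants
    var_maf = np.array([_maf(genotypes.dosages[:, j])
                        for j in range(genotypes.n_variants)])

    rows: list[dict] = []
    skipped: list[tuple[str, str]] = []
    all_p = {} if keep_all_p else None
    n_tests = 0
    for prot in eligible:
        y = values.loc[prot].to_numpy(dtype=float)
        beta, se, t, p, n, valid = _fit_protein_all_variants(
            genotypes.dosages, y, C)
        n_tests += int(valid.sum())
        if keep_all_p:
            all_p[prot] = np.where(valid, p, np.nan)
        for j in np.flatnonzero(~valid):
            skipped.append((variants["rsid"].iat[j], prot))
        hits = np.flatnonzero(valid & (p < threshold))
        if len(hits) == 0:
            continue
        gmeta = meta.loc[prot]
        for j in hits:
            rows.append({
                "rsid": variants["rsid"].iat[j],
                "chrom": variants["chrom"].iat[j],
                "pos": int(variants["pos"].iat[j]),
                "protein": prot,
                "gene": gmeta["gene"],
                "beta": float(beta[j]), "se": float(se[j]),
                "t": float(t[j]), "p": float(p[j]), "n": n,
                "class": classify_local_distant(
                    variants["chrom"].iat[j], int(variants["pos"].iat[j]),
                    gmeta["chrom"], int(gmeta["start"]), int(gmeta["end"]),
                    config.local_distance),
                "maf": float(var_maf[j]),
            })
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if skipped:
        logger.info("skipped %d constant/collinear (variant, protein) fits",
                    len(skipped))

    result = ScanResult(
        records=records, threshold=threshold, n_tests=n_tests, skipped=skipped,
        all_p=(pd.DataFrame(all_p, index=variants["rsid"]).T
               if keep_all_p else None),
    )
    result.summary = summarize(result)
    return result


def _spearman(x: pd.Series, y: pd.Series) -> float:
    if len(x) < 3 or x.nunique() < 2 or y.nunique() < 2:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def summarize(result: ScanResult) -> dict:
    """Headline counts plus the |beta| vs MAF Spearman correlations,
    overall and stratified by local/distant class."""
    rec = result.records
    if rec.empty:
        return {"n_significant": 0, "n_variants": 0, "n_proteins": 0,
                "n_local": 0, "n_distant": 0}
    per_variant = rec.groupby("rsid")["protein"].nunique()
    per_protein = rec.groupby("protein")["rsid"].nunique()
    var_class = rec.groupby("rsid")["class"].agg(set)
    abs_beta = rec["beta"].abs()
    summary = {
        "n_significant": int(len(rec)),
        "n_variants": int(rec["rsid"].nunique()),
        "n_proteins": int(rec["protein"].nunique()),
        "n_local": int(sum(c == {"local"} for c in var_class)),
        "n_distant": int(sum(c == {"distant"} for c in var_class)),
        "n_both": int(sum(len(c) == 2 for c in var_class)),
        "median_variants_per_protein": float(per_protein.median()),
        "max_proteins_per_variant": int(per_variant.max()),
        "beta_maf_spearman": _spearman(abs_beta, rec["maf"]),
    }
    for cls in ("local", "distant"):
        sub = rec[rec["class"] == cls]
        summary[f"beta_maf_spearman_{cls}"] = _spearman(
            sub["beta"].abs(), sub["maf"])
    return summary
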