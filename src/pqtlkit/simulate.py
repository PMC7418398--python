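"""Synthetic genotype / proteome / annotation generator with known truth.

Every generator is a deterministic function of a :class:`SimulationConfig`
(seeded sub-streams per stage), so fixed seeds give bit-identical outputs
and downstream stages can be tested against planted ground truth without
any external download.

The genotype model is a Gaussian copula: within each LD block two latent
haplotype draws follow an AR(1) correlation ``ld_decay**|i-j|`` and are
thresholded at the allele-frequency quantile, which yields Hardy-Weinberg
genotypes with tunable block LD.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, GroundTruth, PeptideSignalTable, ProteinMatrix
from .errors import ConfigurationError

ETHNICITIES = ("EUR", "AFR", "EAS")
ETHNICITY_PROBS = (0.60, 0.25, 0.15)

#: Total MS2 signal per sample used when synthesising peptide tables.
#: 1e9 pg == 1 mg of input protein, so concentrations round-trip exactly.
TOTAL_SIGNAL = 1.0e9

BACKGROUND_PROTEIN = "BACKGROUND"
GENE_LENGTH = 20_000


@dataclass
class PlantedEffect:
    """One planted additive genetic effect on a protein."""

    variant: int
    protein: int
    beta: float
    kind: str = "local"  # "local" | "distant"


@dataclass
class CovariateEffect:
    """Per-protein covariate shifts: gender (added for males) and
    per-ethnicity mean offsets."""

    gender: float = 0.0
    ethnicity: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_samples: int = 287
    n_variants: int = 1000
    n_proteins: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 50
    ld_decay: float = 0.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    covariate_effects: dict[int, CovariateEffect] = field(default_factory=dict)
    noise_sd: float = 1.0
    shared_peptide_fraction: float = 0.0
    missing_protein_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 2
    variant_spacing: int = 100_000
    baseline_mean: float = 30.0
    abundance_distribution: str = "normal"  # or "lognormal"

    def validate(self) -> None:
        for name in ("n_samples", "n_variants", "n_proteins", "n_chromosomes",
                     "ld_block_size", "variant_spacing"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError("ld_decay must be in [0, 1)")
        if not (0.0 <= self.shared_peptide_fraction <= 1.0):
            raise ConfigurationError("shared_peptide_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_protein_rate <= 0.1):
            raise ConfigurationError("missing_protein_rate must be in [0, 0.1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if int(self.seed) < 0:
            raise ConfigurationError("seed must be >= 0")
        if self.abundance_distribution not in ("normal", "lognormal"):
            raise ConfigurationError("abundance_distribution must be normal|lognormal")
        for eff in self.planted_effects:
            if not (0 <= eff.variant < self.n_variants):
                raise ConfigurationError(
                    f"planted_effects: variant index {eff.variant} out of range")
            if not (0 <= eff.protein < self.n_proteins):
                raise ConfigurationError(
                    f"planted_effects: protein index {eff.protein} out of range")
            if eff.kind not in ("local", "distant"):
                raise ConfigurationError(
                    f"planted_effects: kind must be local|distant, got {eff.kind!r}")
        for p in self.covariate_effects:
            if not (0 <= p < self.n_proteins):
                raise ConfigurationError(
                    f"covariate_effects: protein index {p} out of range")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _chrom_sizes(config: SimulationConfig) -> list[int]:
    base, extra = divmod(config.n_variants, config.n_chromosomes)
    return [base + (1 if c < extra else 0) for c in range(config.n_chromosomes)]


def chromosome_length(config: SimulationConfig) -> int:
    """Nominal chromosome length (bp) used for annotation placement."""
    n_per = max(_chrom_sizes(config))
    return (n_per + 2) * config.variant_spacing + 2_000_000


def variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant metadata (chrom, pos, rsid, ref, alt)."""
    rows = []
    i = 0
    for c, size in enumerate(_chrom_sizes(config), start=1):
        for j in range(size):
            rows.append((str(c), (j + 1) * config.variant_spacing,
                         f"rs{1_000_000 + i}", "A", "G"))
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "ref", "alt"])


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(config.n_samples)]


def protein_ids(config: SimulationConfig) -> list[str]:
    return [f"P{i:04d}" for i in range(config.n_proteins)]


def protein_meta(config: SimulationConfig) -> pd.DataFrame:
    """Gene coordinates and molecular masses, consistent with planted
    local/distant classes (local genes placed near their variant, distant
    genes far away or on another chromosome)."""
    rng = _rng(config, 1)
    variants = variant_table(config)
    chrom_len = chromosome_length(config)
    ids = protein_ids(config)
    masses = rng.uniform(20_000.0, 150_000.0, config.n_proteins)

    first_effect: dict[int, PlantedEffect] = {}
    for eff in config.planted_effects:
        first_effect.setdefault(eff.protein, eff)

    chroms: list[str] = []
    starts: list[int] = []
    for p in range(config.n_proteins):
        eff = first_effect.get(p)
        if eff is None:
            chrom = str(rng.integers(1, config.n_chromosomes + 1))
            start = int(rng.integers(1, max(2, chrom_len - GENE_LENGTH)))
        else:
            vchrom = variants.at[eff.variant, "chrom"]
            vpos = int(variants.at[eff.variant, "pos"])
            if eff.kind == "local":
                chrom = vchrom
                start = max(1, vpos - GENE_LENGTH // 2)
            else:
                if config.n_chromosomes > 1:
                    others = [str(c) for c in range(1, config.n_chromosomes + 1)
                              if str(c) != vchrom]
                    chrom = others[int(rng.integers(len(others)))]
                    start = int(rng.integers(1, max(2, chrom_len - GENE_LENGTH)))
                else:
                    chrom = vchrom
                    start = vpos + 1_000_001 + GENE_LENGTH
        chroms.append(chrom)
        starts.append(int(start))

    return pd.DataFrame({
        "protein": ids,
        "gene": [f"GENE{p[1:]}" for p in ids],
        "chrom": chroms,
        "start": starts,
        "end": [s + GENE_LENGTH - 1 for s in starts],
        "mass": masses,
    })


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, 2)
    return pd.DataFrame({
        "sample": sample_ids(config),
        "gender": rng.choice(["F", "M"], config.n_samples),
        "ethnicity": rng.choice(ETHNICITIES, config.n_samples, p=ETHNICITY_PROBS),
    })


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a samples x variants dosage matrix under the block-AR(1)
    Gaussian-copula LD model."""
    config.validate()
    rng = _rng(config, 0)
    variants = variant_table(config)
    n, m = config.n_samples, config.n_variants
    dosages = np.empty((n, m), dtype=float)
    rho = config.ld_decay
    scale = np.sqrt(1.0 - rho * rho)

    col = 0
    for size in _chrom_sizes(config):
        for block_start in range(0, size, config.ld_block_size):
            bm = min(config.ld_block_size, size - block_start)
            mafs = rng.uniform(config.maf_range[0], config.maf_range[1], bm)
            thresholds = stats.norm.ppf(mafs)
            block = np.zeros((n, bm), dtype=float)
            for _hap in range(2):
                eps = rng.standard_normal((n, bm))
                z = np.empty_like(eps)
                z[:, 0] = eps[:, 0]
                for j in range(1, bm):
                    z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
                block += (z < thresholds).astype(float)
            dosages[:, col:col + bm] = block
            col += bm
    return GenotypeMatrix(samples=sample_ids(config), variants=variants,
                          dosages=dosages)


def simulate_proteome(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> tuple[ProteinMatrix, GroundTruth]:
    """Protein level = baseline + sum(beta * dosage) + covariate shifts +
    Gaussian noise; missingness injected completely at random."""
    config.validate()
    rng = _rng(config, 3)
    covariates = simulate_covariates(config)
    meta = protein_meta(config)
    samples = sample_ids(config)
    ids = protein_ids(config)
    n, p = config.n_samples, config.n_proteins

    trait = np.zeros((p, n))
    for eff in config.planted_effects:
        trait[eff.protein] += eff.beta * genotypes.dosages[:, eff.variant]
    male = (covariates["gender"] == "M").to_numpy(dtype=float)
    for prot, cov in config.covariate_effects.items():
        trait[prot] += cov.gender * male
        for level, shift in cov.ethnicity.items():
            trait[prot] += shift * (covariates["ethnicity"] == level).to_numpy(float)
    trait += rng.normal(0.0, config.noise_sd or 0.0, (p, n)) if config.noise_sd > 0 \
        else 0.0

    if config.abundance_distribution == "normal":
        conc = config.baseline_mean + trait
    else:
        conc = config.baseline_mean * np.exp(trait)
    full = pd.DataFrame(conc, index=ids, columns=samples)

    observed = full.copy()
    n_miss = int(config.missing_protein_rate * n)
    if n_miss and (n - n_miss) / n <= 0.9:
        n_miss = max(0, n - int(0.9 * n) - 1)
    if n_miss:
        obs = observed.to_numpy()
        for i in range(p):
            obs[i, rng.choice(n, size=n_miss, replace=False)] = np.nan
        observed = pd.DataFrame(obs, index=ids, columns=samples)

    clusters: dict[int, list[int]] = {}
    for eff in config.planted_effects:
        clusters.setdefault(eff.variant, []).append(eff.protein)
    clusters = {v: ps for v, ps in clusters.items() if len(ps) > 1}

    truth = GroundTruth(
        betas={(e.variant, e.protein): e.beta for e in config.planted_effects},
        concentrations=full, observed=observed, meta=meta,
        covariates=covariates, clusters=clusters,
    )
    matrix = ProteinMatrix(values=observed, meta=meta)
    return matrix, truth


def simulate_peptides(truth: GroundTruth, config: SimulationConfig) -> PeptideSignalTable:
    """Build a peptide table whose TPA quantification reproduces
    ``truth.observed`` exactly.

    Each protein gets two unique peptides; ``shared_peptide_fraction`` of
    proteins are paired up and share one peptide whose area is split in
    proportion to the partners' true signal (so redistribution by unique
    totals is exact).  A background peptide tops total signal up to
    :data:`TOTAL_SIGNAL` per sample, standing in for peptides of proteins
    that are not quantified.
    """
    config.validate()
    if truth.observed is None or truth.meta is None:
        raise ConfigurationError("truth must carry observed concentrations and meta")
    rng = _rng(config, 4)
    samples = list(truth.observed.columns)
    proteins = list(truth.observed.index)
    masses = truth.meta.set_index("protein")["mass"]

    # pg of each protein per mg input; this IS the required final MS2 signal
    required = truth.observed.to_numpy() * masses.loc[proteins].to_numpy()[:, None]
    totals = np.nansum(required, axis=0)
    if totals.max() >= 0.95 * TOTAL_SIGNAL:
        raise ConfigurationError(
            "implied protein mass exceeds input budget; lower baseline_mean or n_proteins")

    n_pairs = int(config.shared_peptide_fraction * len(proteins) / 2)
    order = rng.permutation(len(proteins))
    paired: dict[int, int] = {}
    for k in range(n_pairs):
        a, b = int(order[2 * k]), int(order[2 * k + 1])
        paired[a] = b

    alpha = 0.7  # fraction of a sharing protein's signal carried by unique peptides
    rows: list[tuple] = []
    areas: list[np.ndarray] = []
    frac = rng.uniform(0.3, 0.7, len(proteins))
    pep_no = 0

    def add(protein_ids: tuple[str, ...], area: np.ndarray) -> None:
        nonlocal pep_no
        rows.append((f"pep{pep_no:05d}", f"SEQ{pep_no:05d}K", protein_ids))
        areas.append(area)
        pep_no += 1

    shared_of = {**paired, **{b: a for a, b in paired.items()}}
    for i, prot in enumerate(proteins):
        sig = required[i].copy()
        scale = alpha if i in shared_of else 1.0
        add((prot,), scale * sig * frac[i])
        add((prot,), scale * sig * (1.0 - frac[i]))
    for a, b in paired.items():
        sa, sb = np.nan_to_num(required[a]), np.nan_to_num(required[b])
        shared = (1.0 - alpha) * (sa + sb)
        shared[np.isnan(required[a]) & np.isnan(required[b])] = np.nan
        add((proteins[a], proteins[b]), shared)

    assigned = np.nansum(np.array(areas), axis=0)
    add((BACKGROUND_PROTEIN,), TOTAL_SIGNAL - assigned)

    table = pd.DataFrame(rows, columns=["peptide_id", "sequence", "protein_ids"])
    area_mat = np.array(areas)
    area_mat[area_mat == 0.0] = np.nan  # zero-concentration == not detected
    table = pd.concat(
        [table, pd.DataFrame(area_mat, columns=samples)], axis=1)
    return PeptideSignalTable(table=table, samples=samples)


def write_study(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Simulate a full study and write every input file the pipeline
    consumes; returns the path mapping (keys match PipelineConfig)."""
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config)
    proteins, truth = simulate_proteome(config, genotypes)
    peptides = simulate_peptides(truth, config)
    bundle = simulate_annotations(config)

    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "peptides": str(out / "peptides.tsv"),
        "protein_meta": str(out / "protein_meta.tsv"),
        "covariates": str(out / "covariates.tsv"),
        "regulatory": str(out / "regulatory.bed"),
        "genes": str(out / "genes.gtf"),
        "traits": str(out / "traits.tsv"),
        "external_qtl": str(out / "external_qtl.tsv"),
    }
    io.write_vcf(genotypes, paths["vcf"])
    io.write_peptide_table(peptides, paths["peptides"])
    meta_with_background(truth.meta).to_csv(paths["protein_meta"], sep="\t",
                                            index=False)
    truth.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    io.write_bed(bundle.regulatory, paths["regulatory"])
    io.write_gtf(bundle.genes, paths["genes"])
    bundle.traits.to_csv(paths["traits"], sep="\t", index=False)
    bundle.external_qtl.to_csv(paths["external_qtl"], sep="\t", index=False)
    io.write_ground_truth(truth, out / "ground_truth.json")
    return paths


def meta_with_background(meta: pd.DataFrame) -> pd.DataFrame:
    """Append the synthetic background protein so that peptide tables
    emitted by :func:`simulate_peptides` can be quantified."""
    row = pd.DataFrame([{"protein": BACKGROUND_PROTEIN, "gene": "_background_",
                         "chrom": "1", "start": 1, "end": 2, "mass": 50_000.0}])
    return pd.concat([meta, row], ignore_index=True)


@dataclass
class AnnotationBundle:
    """Interval annotations and catalogs emitted by the simulator."""

    regulatory: pd.DataFrame  # chrom, start, end, feature (1-based inclusive)
    genes: pd.DataFrame       # gene, biotype, feature, chrom, start, end
    traits: pd.DataFrame      # rsid, trait, source
    external_qtl: pd.DataFrame  # rsid, gene, p


REGULATORY_CLASSES = (
    "promoter", "enhancer", "CTCF_binding_site",
    "open_chromatin", "promoter_flanking", "TF_binding_site",
)


def _gene_features(gene: str, biotype: str, chrom: str, start: int, end: int) -> list[tuple]:
    """Fixed three-exon gene model with terminal UTRs and interior CDS."""
    rows = [(gene, biotype, "gene", chrom, start, end)]
    e1 = (start, start + 2000)
    e2 = (start + 8000, start + 10_000)
    e3 = (end - 2000, end)
    for a, b in (e1, e2, e3):
        rows.append((gene, biotype, "exon", chrom, a, b))
    if biotype == "protein_coding":
        rows.append((gene, biotype, "UTR", chrom, start, start + 500))
        rows.append((gene, biotype, "CDS", chrom, start + 501, e1[1]))
        rows.append((gene, biotype, "CDS", chrom, e2[0], e2[1]))
        rows.append((gene, biotype, "CDS", chrom, e3[0], end - 501))
        rows.append((gene, biotype, "UTR", chrom, end - 500, end))
    return rows


def simulate_annotations(config: SimulationConfig) -> AnnotationBundle:
    """Regulatory intervals, gene models, a trait catalog keyed by
    simulated rsIDs, and an external QTL summary table seeded with the
    planted effects."""
    config.validate()
    rng = _rng(config, 5)
    variants = variant_table(config)
    meta = protein_meta(config)
    chrom_len = chromosome_length(config)

    reg_rows = []
    per_class = max(3, config.n_variants // (10 * config.n_chromosomes))
    for c in range(1, config.n_chromosomes + 1):
        for feature in REGULATORY_CLASSES:
            starts = rng.integers(1, chrom_len - 2001, per_class)
            lengths = rng.integers(200, 2001, per_class)
            for s, ln in zip(starts, lengths):
                reg_rows.append((str(c), int(s), int(s + ln - 1), feature))
    regulatory = pd.DataFrame(reg_rows, columns=["chrom", "start", "end", "feature"])
    regulatory = regulatory.sort_values(["chrom", "start"]).reset_index(drop=True)

    gene_rows: list[tuple] = []
    for rec in meta.itertuples():
        gene_rows.extend(_gene_features(rec.gene, "protein_coding", rec.chrom,
                                        int(rec.start), int(rec.end)))
    n_nc = max(1, config.n_proteins // 10)
    for k in range(n_nc):
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(1, chrom_len - GENE_LENGTH))
        gene_rows.extend(_gene_features(f"NCRNA{k:03d}", "non_coding", chrom,
                                        start, start + GENE_LENGTH - 1))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene", "biotype", "feature", "chrom", "start", "end"])

    trait_rows = []
    sources = ("gwas_catalog", "clinvar", "pharmgkb")
    for k, eff in enumerate(config.planted_effects):
        trait_rows.append((variants.at[eff.variant, "rsid"], f"trait_{k:03d}",
                           sources[k % 3]))
    n_random = max(5, config.n_variants // 50)
    for k, vi in enumerate(rng.choice(config.n_variants, n_random, replace=False)):
        trait_rows.append((variants.at[int(vi), "rsid"], f"rtrait_{k:03d}",
                           sources[int(rng.integers(3))]))
    traits = pd.DataFrame(trait_rows, columns=["rsid", "trait", "source"]) \
        .drop_duplicates().reset_index(drop=True)

    gene_of = meta.set_index("protein")["gene"]
    pids = protein_ids(config)
    qtl_rows = []
    for eff in config.planted_effects:
        qtl_rows.append((variants.at[eff.variant, "rsid"],
                         gene_of[pids[eff.protein]],
                         float(10 ** -rng.uniform(9, 14))))
    for vi in rng.choice(config.n_variants, n_random, replace=False):
        gi = int(rng.integers(config.n_proteins))
        qtl_rows.append((variants.at[int(vi), "rsid"], gene_of[pids[gi]],
                         float(rng.uniform(1e-6, 1.0))))
    external_qtl = pd.DataFrame(qtl_rows, columns=["rsid", "gene", "p"]) \
        .drop_duplicates(subset=["rsid", "gene"]).reset_index(drop=True)

    return AnnotationBundle(regulatory=regulatory, genes=genes, traits=traits,
                            external_qtl=external_qtl)
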