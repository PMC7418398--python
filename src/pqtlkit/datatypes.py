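"""Core in-memory containers passed between pipeline stages.

All coordinates are 1-based inclusive internally.  Dosages count alt
alleles (0/1/2) and are stored as floats so that missing entries can be
NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputValidationError

#: Column order for variant metadata tables.
VARIANT_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt"]

#: Column order for protein metadata tables.
META_COLUMNS = ["protein", "gene", "chrom", "start", "end", "mass"]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with variant metadata.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per row of ``dosages``.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, rsid, ref, alt``,
        sorted by position within each chromosome.
    dosages : numpy.ndarray, shape (n_samples, n_variants)
        Alt-allele counts in {0, 1, 2}; NaN marks a missing call.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise InputValidationError(
                f"dosage rows ({n}) != number of samples ({len(self.samples)})"
            )
        if m != len(self.variants):
            raise InputValidationError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if self.variants["rsid"].duplicated().any():
            dups = self.variants.loc[self.variants["rsid"].duplicated(), "rsid"]
            raise InputValidationError(f"duplicate rsIDs: {sorted(set(dups))[:5]}")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise InputValidationError(
                    f"positions not sorted on chromosome {sub['chrom'].iloc[0]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        """Return a copy restricted to the given variant mask/indexer."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
        )

    def column(self, rsid: str) -> np.ndarray:
        """Dosage vector for one variant by rsID."""
        hits = np.flatnonzero((self.variants["rsid"] == rsid).to_numpy())
        if len(hits) == 0:
            raise KeyError(rsid)
        return self.dosages[:, hits[0]]


@dataclass
class PeptideSignalTable:
    """Peptide-level MS2 peak areas with protein-group assignment.

    ``table`` has columns ``peptide_id``, ``sequence``, ``protein_ids``
    (tuple of protein IDs; length 1 means the peptide is unique), then
    one float column per sample (NaN = peptide not detected).
    """

    table: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        for col in ("peptide_id", "sequence", "protein_ids"):
            if col not in self.table.columns:
                raise InputValidationError(f"peptide table missing column {col!r}")
        missing = [s for s in self.samples if s not in self.table.columns]
        if missing:
            raise InputValidationError(f"peptide table missing sample columns: {missing}")
        if any(len(g) == 0 for g in self.table["protein_ids"]):
            raise InputValidationError("every peptide must map to >=1 protein")
        areas = self.table[self.samples].to_numpy(dtype=float)
        if np.nanmin(areas, initial=0.0) < 0:
            raise InputValidationError("negative MS2 peak area")

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for group in self.table["protein_ids"]:
            for p in group:
                seen.setdefault(p, None)
        return list(seen)

    def is_unique(self) -> np.ndarray:
        """Boolean mask: peptide assigned to exactly one protein."""
        return np.array([len(g) == 1 for g in self.table["protein_ids"]])


@dataclass
class ProteinMatrix:
    """Absolute protein concentrations (pmol per mg total input protein).

    Attributes
    ----------
    values : pandas.DataFrame
        proteins x samples concentrations; NaN = not quantified.
    meta : pandas.DataFrame
        One row per protein: ``protein, gene, chrom, start, end, mass``.
        ``mass`` is the molecular weight in g/mol; gene coordinates are
        1-based inclusive.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = set(self.values.index) - set(self.meta["protein"])
        if missing_meta:
            raise InputValidationError(
                f"proteins without metadata: {sorted(missing_meta)[:5]}"
            )
        if (self.meta["mass"] <= 0).any():
            raise InputValidationError("molecular mass must be > 0")
        if (self.meta["start"] > self.meta["end"]).any():
            raise InputValidationError("gene start > end")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise InputValidationError("negative concentration")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    def meta_indexed(self) -> pd.DataFrame:
        return self.meta.set_index("protein")


@dataclass
class GroundTruth:
    """Known quantities recorded by the simulator for downstream checks."""

    betas: dict[tuple[int, int], float] = field(default_factory=dict)
    concentrations: pd.DataFrame | None = None
    observed: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    clusters: dict[int, list[int]] = field(default_factory=dict)
    colocalized_pairs: list[tuple[str, str]] = field(default_factory=list)
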