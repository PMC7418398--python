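"""Variant-trait joining and LD/conditional-analysis colocalization.

Colocalization calls a pQTL and an external signal shared when the lead
pQTL variant and the external variant are in strong LD (r-squared > 0.8)
and the lead's association is no longer significant once the external
variant's dosage is added to the model as a covariate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import InputValidationError
from .qc import ld_r2
from .scan import fit_additive

logger = logging.getLogger(__name__)

TRAIT_SOURCES = ("gwas_catalog", "clinvar", "pharmgkb", "user")


def map_traits(records: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Inner join of significant associations with a trait catalog on
    rsID; returns deduplicated (rsid, protein, trait, source) triples."""
    for col in ("rsid", "trait"):
        if col not in catalog.columns:
            raise InputValidationError(f"trait catalog missing column {col!r}")
    if "source" not in catalog.columns:
        catalog = catalog.assign(source="user")
    triples = records[["rsid", "protein"]].drop_duplicates().merge(
        catalog[["rsid", "trait", "source"]].drop_duplicates(), on="rsid")
    return triples.drop_duplicates(subset=["rsid", "protein", "trait"]) \
        .reset_index(drop=True)


def trait_summary(triples: pd.DataFrame) -> dict:
    return {
        "n_triples": int(len(triples)),
        "n_variants": int(triples["rsid"].nunique()) if len(triples) else 0,
        "n_traits": int(triples["trait"].nunique()) if len(triples) else 0,
        "n_proteins": int(triples["protein"].nunique()) if len(triples) else 0,
    }


def lead_variant(records: pd.DataFrame) -> pd.Series:
    """The record with the smallest p (ties: smallest position, then
    lexicographic rsID) among one protein's associations."""
    if records.empty:
        raise InputValidationError("no records to choose a lead variant from")
    ordered = records.sort_values(["p", "pos", "rsid"],
                                  ascending=[True, True, True])
    return ordered.iloc[0]


@dataclass
class ConditionalResult:
    p_unconditional: float
    p_conditional: float
    collinear: bool = False


def conditional_test(
    protein_values: np.ndarray,
    lead_dosage: np.ndarray,
    candidate_dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    keep_covariates: bool = True,
) -> ConditionalResult:
    """p-value of the lead variant before and after conditioning on the
    candidate variant's dosage.

    Perfectly collinear candidate (r-squared == 1 with the lead) gives a
    conditional p of 1 with the ``collinear`` flag set.
    """
    C = covariates if keep_covariates else None
    base = fit_additive(lead_dosage, protein_values, C)
    if base is None:
        raise InputValidationError("lead variant fit failed (constant dosage?)")
    r2 = ld_r2(lead_dosage, candidate_dosage)
    if r2 >= 1.0 - 1e-12:
        return ConditionalResult(base.p, 1.0, collinear=True)
    cand = np.asarray(candidate_dosage, dtype=float)[:, None]
    C_aug = cand if C is None else np.column_stack([C, cand])
    cond = fit_additive(lead_dosage, protein_values, C_aug)
    if cond is None:  # residual collinearity after case deletion
        return ConditionalResult(base.p, 1.0, collinear=True)
    return ConditionalResult(base.p, cond.p, collinear=False)


@dataclass
class ColocResult:
    protein: str
    lead_rsid: str
    candidate_rsid: str
    r2: float
    p_unconditional: float
    p_conditional: float
    collinear: bool
    colocalized: bool


def colocalize(
    protein: str,
    protein_values: np.ndarray,
    records: pd.DataFrame,
    external: pd.DataFrame,
    genotypes: GenotypeMatrix,
    threshold: float,
    covariates: np.ndarray | None = None,
    r2_threshold: float = 0.8,
) -> tuple[list[ColocResult], int]:
    """Test every external variant in LD with the protein's lead pQTL.

    ``records`` are the protein's significant associations; ``external``
    needs an ``rsid`` column (eQTL or GWAS summary rows).  Colocalized
    iff r-squared > ``r2_threshold`` and the conditional p is >= the
    significance threshold.  Returns (results, n external variants
    skipped because they are not genotyped).
    """
    lead = lead_variant(records)
    lead_g = genotypes.column(lead["rsid"])
    known = set(genotypes.variants["rsid"])
    results: list[ColocResult] = []
    n_skipped = 0
    for rsid in pd.unique(external["rsid"]):
        if rsid not in known:
            n_skipped += 1
            continue
        cand_g = genotypes.column(rsid)
        r2 = ld_r2(lead_g, cand_g)
        if r2 <= r2_threshold:
            continue
        cond = conditional_test(protein_values, lead_g, cand_g, covariates)
        results.append(ColocResult(
            protein=protein, lead_rsid=str(lead["rsid"]), candidate_rsid=str(rsid),
            r2=r2, p_unconditional=cond.p_unconditional,
            p_conditional=cond.p_conditional, collinear=cond.collinear,
            colocalized=bool(cond.p_conditional >= threshold),
        ))
    if n_skipped:
        logger.warning("%s: %d external variant(s) not genotyped, skipped",
                       protein, n_skipped)
    return results, n_skipped


def coloc_table(results: list[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein": r.protein, "lead_rsid": r.lead_rsid,
        "candidate_rsid": r.candidate_rsid, "r2": r.r2,
        "p_uncond": r.p_unconditional, "p_cond": r.p_conditional,
        "collinear": r.collinear, "colocalized": r.colocalized,
    } for r in results], columns=["protein", "lead_rsid", "candidate_rsid",
                                  "r2", "p_uncond", "p_cond", "collinear",
                                  "colocalized"])
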