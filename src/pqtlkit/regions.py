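"""Mapping of variants to regulatory regions and gene features, plus
Fisher-exact regulator enrichment with Bonferroni control.

All intervals are 1-based inclusive internally (BED input is converted
at ingest); a variant hits an interval iff start <= pos <= end.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exact import fisher_exact_two_sided
from .errors import DomainError, InputValidationError

REGULATORY_VOCABULARY = frozenset({
    "promoter", "enhancer", "CTCF_binding_site",
    "open_chromatin", "promoter_flanking", "TF_binding_site",
})

GENE_FEATURES = ("UTR", "CDS", "exon", "intron")


def _overlap_hits(variants: pd.DataFrame, intervals: pd.DataFrame,
                  extra_cols: list[str]) -> pd.DataFrame:
    """Inner join of point positions against intervals, per chromosome."""
    out = []
    by_chrom = {c: g for c, g in intervals.groupby("chrom", sort=False)}
    for chrom, vsub in variants.groupby("chrom", sort=False):
        isub = by_chrom.get(chrom)
        if isub is None:
            continue
        pos = vsub["pos"].to_numpy()[:, None]
        inside = (pos >= isub["start"].to_numpy()) & (pos <= isub["end"].to_numpy())
        vi, ii = np.nonzero(inside)
        if len(vi) == 0:
            continue
        chunk = vsub.iloc[vi][["rsid", "chrom", "pos"]].reset_index(drop=True)
        for col in extra_cols + ["start", "end"]:
            chunk[col] = isub.iloc[ii][col].to_numpy()
        out.append(chunk)
    if not out:
        return pd.DataFrame(columns=["rsid", "chrom", "pos", *extra_cols,
                                     "start", "end"])
    return pd.concat(out, ignore_index=True)


def map_to_regulatory(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Per-variant regulatory-feature hits (multiple hits allowed).

    ``variants`` needs rsid/chrom/pos; ``regions`` needs
    chrom/start/end/feature with features from the fixed vocabulary.
    """
    bad = set(regions["feature"]) - REGULATORY_VOCABULARY
    if bad:
        raise InputValidationError(f"unknown regulatory feature classes: {sorted(bad)}")
    if (regions["start"] > regions["end"]).any():
        raise InputValidationError("regulatory interval with start > end")
    return _overlap_hits(variants, regions, ["feature"])


def map_to_gene_features(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Label each variant per overlapped gene: exon (plus CDS/UTR when
    inside those sub-intervals) or intron; a single ``intergenic`` row
    when no gene is overlapped.

    ``genes`` holds rows (gene, biotype, feature, chrom, start, end) with
    feature in {gene, exon, CDS, UTR}.
    """
    gene_spans = genes[genes["feature"] == "gene"]
    sub_feats = genes[genes["feature"].isin(["exon", "CDS", "UTR"])]

    in_gene = _overlap_hits(variants, gene_spans, ["gene", "biotype"])
    rows = []
    for rec in in_gene.itertuples():
        feats = sub_feats[(sub_feats["gene"] == rec.gene)
                          & (sub_feats["start"] <= rec.pos)
                          & (sub_feats["end"] >= rec.pos)]["feature"]
        labels = set(feats)
        if "exon" not in labels:
            labels = {"intron"}
        for lab in sorted(labels):
            rows.append((rec.rsid, rec.chrom, rec.pos, rec.gene, rec.biotype, lab))
    hit_rsids = set(in_gene["rsid"])
    for rec in variants.itertuples():
        if rec.rsid not in hit_rsids:
            rows.append((rec.rsid, rec.chrom, rec.pos, None, None, "intergenic"))
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "gene",
                                       "biotype", "feature"])


def regulator_enrichment(
    protein: str,
    pqtl_rsids: set[str],
    universe_rsids: set[str],
    gene_labels: pd.DataFrame,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (gene, feature) Fisher test of pQTL membership vs feature
    membership over the tested-SNP universe.

    ``gene_labels`` is the output of :func:`map_to_gene_features` for the
    universe.  ``n_tests`` is the Bonferroni divisor (defaults to the
    number of (gene, feature) tests performed here; pass the study-wide
    total when correcting across proteins).  A gene is a predicted
    regulator when adjusted p < alpha and the odds ratio exceeds 1.
    """
    if not universe_rsids:
        raise DomainError("empty variant universe")
    if not pqtl_rsids <= universe_rsids:
        raise InputValidationError("pQTL variants must be inside the universe")

    labs = gene_labels[gene_labels["gene"].notna()
                       & gene_labels["rsid"].isin(universe_rsids)]
    n_universe = len(universe_rsids)
    n_pqtl = len(pqtl_rsids)
    rows = []
    for (gene, feature), grp in labs.groupby(["gene", "feature"]):
        in_feat = set(grp["rsid"])
        a = len(pqtl_rsids & in_feat)
        b = n_pqtl - a
        c = len(in_feat) - a
        d = (n_universe - n_pqtl) - c
        odds, p = fisher_exact_two_sided(a, b, c, d)
        rows.append((protein, gene, feature, a, b, c, d, float(odds), float(p)))
    result = pd.DataFrame(rows, columns=["protein", "gene", "feature",
                                         "a", "b", "c", "d", "odds_ratio", "p"])
    divisor = n_tests if n_tests is not None else max(len(result), 1)
    result["p_adjusted"] = np.minimum(1.0, result["p"] * divisor)
    result["significant"] = (result["p_adjusted"] < alpha) & (result["odds_ratio"] > 1)
    return result.sort_values("p").reset_index(drop=True)


def local_distant_region_distribution(
    records: pd.DataFrame,
    gene_labels: pd.DataFrame,
    regulatory_hits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Counts of significant associations per (local/distant class,
    genomic region).

    Each association record contributes one count per region label of its
    variant relative to the regulated gene (so a variant associated with
    two proteins in different regions is counted twice); regulatory hits,
    when given, are keyed by rsid alone and added for every record of
    that variant.  Records with no label count as intergenic.
    """
    counts: dict[tuple[str, str], int] = {}
    gl = gene_labels[gene_labels["gene"].notna()]
    reg = regulatory_hits if regulatory_hits is not None else pd.DataFrame(
        columns=["rsid", "feature"])
    for _, rec in records.iterrows():
        labels = list(gl[(gl["rsid"] == rec["rsid"])
                         & (gl["gene"] == rec["gene"])]["feature"])
        labels += list(reg[reg["rsid"] == rec["rsid"]]["feature"])
        if not labels:
            labels = ["intergenic"]
        for lab in set(labels):
            key = (rec["class"], lab)
            counts[key] = counts.get(key, 0) + 1
    rows = [(cls, feat, cnt) for (cls, feat), cnt in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["class", "feature", "count"])
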