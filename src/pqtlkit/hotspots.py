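"""Protein co-expression correlation and QTL hotspot discovery.

A hotspot seed is a pair of neighboring QTL variants (position order,
same chromosome) associated with different proteins, less than 1 Mb
apart, with some cross-pair protein pair at |Spearman rho| > 0.5.  The
hotspot is then extended variant-by-variant while the candidate lies
within 1 Mb of the nearest member and correlates (|rho| > 0.5) with a
protein of that nearest member.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ProteinMatrix
from .exact import fisher_exact_two_sided
from .errors import ConfigurationError, InputValidationError

MAX_GAP = 1_000_000
MIN_ABS_RHO = 0.5


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho / p / sample-size matrices over proteins."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def summary(self, alpha: float = 0.05) -> dict:
        """Counts of strong pairs and the median rho among significant
        pairs (upper triangle only)."""
        mask = np.triu(np.ones(self.rho.shape, dtype=bool), k=1)
        rho = self.rho.to_numpy()[mask]
        p = self.p.to_numpy()[mask]
        sig = rho[p < alpha]
        return {
            "n_pairs": int(mask.sum()),
            "n_abs_rho_gt_0.5": int((np.abs(rho) > 0.5).sum()),
            "n_abs_rho_gt_0.8": int((np.abs(rho) > 0.8).sum()),
            "median_rho_significant": float(np.median(sig)) if len(sig) else float("nan"),
        }


def spearman_matrix(proteins: ProteinMatrix) -> CorrelationMatrix:
    """All-pairs Spearman correlation of protein levels across samples
    (average ranks for ties, pairwise-complete observations, p from the
    t approximation)."""
    values = proteins.values
    rho = values.T.corr(method="spearman")
    notna = values.notna().to_numpy().astype(float)
    n = pd.DataFrame(notna @ notna.T, index=values.index, columns=values.index)
    r = rho.to_numpy()
    nn = n.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((nn - 2) / np.clip(1.0 - r * r, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(nn - 2, 1))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        rho=rho,
        p=pd.DataFrame(p, index=values.index, columns=values.index),
        n=n,
    )


@dataclass
class Hotspot:
    id: str
    chrom: str
    start: int
    end: int
    variants: list[str]            # member rsIDs ordered by position
    positions: list[int]
    proteins: list[str]            # union of member-associated proteins
    annotations: set[str] = field(default_factory=set)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _variant_view(records: pd.DataFrame) -> pd.DataFrame:
    """One row per significant variant with its associated protein set."""
    grouped = records.groupby(["chrom", "pos", "rsid"])["protein"] \
        .agg(lambda s: frozenset(s)).reset_index()
    return grouped.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _pair_ok(prots_a: frozenset, prots_b: frozenset, rho: pd.DataFrame,
             min_abs_rho: float, require_distinct: bool) -> bool:
    for pa in prots_a:
        for pb in prots_b:
            if require_distinct and pa == pb:
                continue
            if abs(float(rho.at[pa, pb])) > min_abs_rho:
                return True
    return False


def find_hotspots(
    records: pd.DataFrame,
    corr: CorrelationMatrix,
    max_gap: int = MAX_GAP,
    min_abs_rho: float = MIN_ABS_RHO,
    seed_strict_gap: bool = True,
    direction: str = "both",
    id_prefix: str = "HS",
) -> list[Hotspot]:
    """Scan position-sorted significant QTL variants per chromosome for
    seed pairs and extend them while the adjacency rules hold.

    ``records`` needs columns rsid, chrom, pos, protein.  Seeds use a
    strict gap (< max_gap) and require a correlated pair of *different*
    proteins; extension is inclusive (<= max_gap) and accepts any
    correlated protein pair with the nearest member.  ``direction`` is
    "both" (default), "right", or "left".
    """
    if direction not in ("both", "left", "right"):
        raise ConfigurationError("direction must be both|left|right")
    if records.empty:
        return []
    missing = sorted(set(records["protein"]) - set(corr.rho.index))
    if missing:
        raise InputValidationError(
            f"proteins absent from correlation matrix: {missing}")

    view = _variant_view(records)
    rho = corr.rho
    hotspots: list[Hotspot] = []

    def seed_ok(i: int, j: int, sub: pd.DataFrame) -> bool:
        gap = int(sub["pos"].iat[j]) - int(sub["pos"].iat[i])
        gap_ok = gap < max_gap if seed_strict_gap else gap <= max_gap
        if not gap_ok:
            return False
        return _pair_ok(sub["protein"].iat[i], sub["protein"].iat[j], rho,
                        min_abs_rho, require_distinct=True)

    def ext_ok(cand: int, nearest: int, sub: pd.DataFrame) -> bool:
        if abs(int(sub["pos"].iat[cand]) - int(sub["pos"].iat[nearest])) > max_gap:
            return False
        return _pair_ok(sub["protein"].iat[cand], sub["protein"].iat[nearest],
                        rho, min_abs_rho, require_distinct=False)

    for chrom, sub in view.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        floor = 0  # first index not consumed by an earlier hotspot
        i = 0
        while i < len(sub) - 1:
            if not seed_ok(i, i + 1, sub):
                i += 1
                continue
            members = [i, i + 1]
            if direction in ("both", "right"):
                j = i + 2
                while j < len(sub) and ext_ok(j, members[-1], sub):
                    members.append(j)
                    j += 1
            if direction in ("both", "left"):
                k = i - 1
                while k >= floor and ext_ok(k, members[0], sub):
                    members.insert(0, k)
                    k -= 1
            rsids = [sub["rsid"].iat[m] for m in members]
            positions = [int(sub["pos"].iat[m]) for m in members]
            prots: list[str] = []
            for m in members:
                for pr in sorted(sub["protein"].iat[m]):
                    if pr not in prots:
                        prots.append(pr)
            hotspots.append(Hotspot(
                id=f"{id_prefix}{len(hotspots) + 1:03d}", chrom=str(chrom),
                start=positions[0], end=positions[-1],
                variants=rsids, positions=positions, proteins=prots,
            ))
            floor = members[-1] + 1
            i = floor
    return hotspots


def annotate_hotspot(hotspot: Hotspot, term_map: dict[str, set[str]]) -> set[str]:
    """Terms annotated to at least half (ceil) of the hotspot's proteins;
    a term carried by a single protein never qualifies."""
    n = len(hotspot.proteins)
    if n == 0:
        return set()
    need = max(2, (n + 1) // 2)
    counts: dict[str, int] = {}
    for prot in hotspot.proteins:
        for term in term_map.get(prot, set()):
            counts[term] = counts.get(term, 0) + 1
    terms = {t for t, c in counts.items() if c >= need}
    hotspot.annotations = terms
    return terms


def shared_hotspot_enrichment(
    corr: CorrelationMatrix,
    hotspots: list[Hotspot],
    proteins: list[str] | None = None,
    min_abs_rho: float = MIN_ABS_RHO,
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test of {highly correlated pair} x {pair shares a
    hotspot}; returns (odds ratio, two-sided p, 2x2 table)."""
    prots = proteins if proteins is not None else list(corr.rho.index)
    idx = {p: i for i, p in enumerate(prots)}
    m = len(prots)
    high = np.abs(corr.rho.loc[prots, prots].to_numpy()) > min_abs_rho
    shares = np.zeros((m, m), dtype=bool)
    for h in hotspots:
        members = [idx[p] for p in h.proteins if p in idx]
        for a in members:
            for b in members:
                shares[a, b] = True
    mask = np.triu(np.ones((m, m), dtype=bool), k=1)
    hi, sh = high[mask], shares[mask]
    table = np.array([
        [int((hi & sh).sum()), int((hi & ~sh).sum())],
        [int((~hi & sh).sum()), int((~hi & ~sh).sum())],
    ])
    odds, p = fisher_exact_two_sided(*table.ravel())
    return float(odds), float(p), table


def find_eqtl_hotspots(
    external: pd.DataFrame,
    variants: pd.DataFrame,
    meta: pd.DataFrame,
    corr: CorrelationMatrix,
    max_gap: int = MAX_GAP,
    min_abs_rho: float = MIN_ABS_RHO,
) -> list[Hotspot]:
    """Apply the hotspot algorithm to an external QTL summary table.

    Rows are first filtered to variants genotyped in this study (join on
    rsid against ``variants``) and genes with a quantified protein (join
    on gene against ``meta``); correlations are then taken from this
    study's protein matrix.
    """
    required = {"rsid", "gene"}
    if not required <= set(external.columns):
        raise InputValidationError(f"external table needs columns {sorted(required)}")
    if external.empty:
        return []
    joined = external.merge(variants[["rsid", "chrom", "pos"]], on="rsid") \
        .merge(meta[["protein", "gene"]], on="gene")
    if joined.empty:
        return []
    records = joined[["rsid", "chrom", "pos", "protein"]].drop_duplicates()
    return find_hotspots(records, corr, max_gap=max_gap,
                         min_abs_rho=min_abs_rho, id_prefix="EHS")
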