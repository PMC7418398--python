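import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlkit.datatypes import ProteinMatrix
from pqtlkit.errors import InputValidationError
from pqtlkit.hotspots import (CorrelationMatrix, Hotspot, annotate_hotspot,
                              find_eqtl_hotspots, find_hotspots,
                              shared_hotspot_enrichment, spearman_matrix)
from pqtlkit.simulate import (PlantedEffect, SimulationConfig, simulate_genotypes,
                              simulate_proteome, variant_table)
from pqtlkit.scan import ScanConfig, scan

from conftest import make_meta


def corr_from(rho_dict, proteins):
    """CorrelationMatrix from {(a, b): rho}; unspecified pairs are 0."""
    m = len(proteins)
    rho = pd.DataFrame(np.eye(m), index=proteins, columns=proteins)
    for (a, b), r in rho_dict.items():
        rho.at[a, b] = rho.at[b, a] = r
    p = pd.DataFrame(np.zeros((m, m)), index=proteins, columns=proteins)
    n = pd.DataFrame(np.full((m, m), 100.0), index=proteins, columns=proteins)
    return CorrelationMatrix(rho=rho, p=p, n=n)


def records_from(rows):
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "protein"])


def spearman_brute(x, y):
    """Average-rank Spearman via the Pearson-of-ranks definition."""
    def avg_rank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = avg_rank(x), avg_rank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearmanMatrix:
    def _matrix(self, rows, samples=5):
        df = pd.DataFrame(rows).T
        df.columns = [f"S{i}" for i in range(samples)]
        return ProteinMatrix(values=df, meta=make_meta({p: 5e4 for p in rows}))

    def test_monotone_pair(self):
        m = self._matrix({"A": [1, 2, 3, 4, 5], "B": [2, 4, 9, 12, 20]})
        assert spearman_matrix(m).rho.at["A", "B"] == pytest.approx(1.0)

    def test_reversed(self):
        m = self._matrix({"A": [1, 2, 3, 4, 5], "B": [5, 4, 3, 2, 1]})
        assert spearman_matrix(m).rho.at["A", "B"] == pytest.approx(-1.0)

    def test_ties_match_brute_force(self):
        a = [1.0, 2.0, 2.0, 3.0, 4.0]
        b = [3.0, 1.0, 4.0, 4.0, 5.0]
        m = self._matrix({"A": a, "B": b})
        assert spearman_matrix(m).rho.at["A", "B"] == \
            pytest.approx(spearman_brute(a, b), abs=1e-12)

    def test_p_matches_scipy(self, rng):
        a = rng.normal(size=30) + 10
        b = 0.5 * a + rng.normal(size=30) + 10
        m = self._matrix({"A": a, "B": b}, samples=30)
        res = stats.spearmanr(a, b)
        c = spearman_matrix(m)
        assert c.rho.at["A", "B"] == pytest.approx(res.statistic, abs=1e-12)
        assert c.p.at["A", "B"] == pytest.approx(res.pvalue, rel=1e-6)


def hotspot_oracle(records, corr, max_gap=1_000_000, min_abs_rho=0.5):
    """Exhaustive re-statement of the seeding/extension rules, written
    independently: enumerate chromosomes, walk every adjacency."""
    out = []
    view = records.groupby(["chrom", "pos", "rsid"])["protein"].agg(set).reset_index()
    for chrom in view["chrom"].unique():
        sub = view[view["chrom"] == chrom].sort_values("pos").reset_index(drop=True)
        consumed = set()
        i = 0
        while i + 1 < len(sub):
            if i in consumed:
                i += 1
                continue
            pa, pb = sub["protein"][i], sub["protein"][i + 1]
            gap = sub["pos"][i + 1] - sub["pos"][i]
            seed = gap < max_gap and any(
                x != y and abs(corr.rho.at[x, y]) > min_abs_rho
                for x in pa for y in pb)
            if not seed:
                i += 1
                continue
            members = [i, i + 1]
            grew = True
            while grew:
                grew = False
                for cand, nearest in ((members[-1] + 1, members[-1]),
                                      (members[0] - 1, members[0])):
                    if cand in consumed or cand < 0 or cand >= len(sub):
                        continue
                    if abs(sub["pos"][cand] - sub["pos"][nearest]) > max_gap:
                        continue
                    if any(abs(corr.rho.at[x, y]) > min_abs_rho
                           for x in sub["protein"][cand]
                           for y in sub["protein"][nearest]):
                        if cand > nearest:
                            members.append(cand)
                        else:
                            members.insert(0, cand)
                        grew = True
            consumed.update(members)
            out.append([sub["rsid"][m] for m in members])
            i = members[-1] + 1
    return out


class TestFindHotspots:
    def test_simple_seed(self):
        corr = corr_from({("P1", "P2"): 0.6}, ["P1", "P2"])
        recs = records_from([("v1", "2", 1_000_000, "P1"),
                             ("v2", "2", 1_500_000, "P2")])
        spots = find_hotspots(recs, corr)
        assert len(spots) == 1
        assert (spots[0].start, spots[0].end) == (1_000_000, 1_500_000)
        assert spots[0].proteins == ["P1", "P2"]

    def test_gap_too_large(self):
        corr = corr_from({("P1", "P2"): 0.6}, ["P1", "P2"])
        recs = records_from([("v1", "2", 1_000_000, "P1"),
                             ("v2", "2", 3_000_000, "P2")])
        assert find_hotspots(recs, corr) == []

    def test_low_correlation_no_seed(self):
        corr = corr_from({("P1", "P2"): 0.4}, ["P1", "P2"])
        recs = records_from([("v1", "2", 1_000_000, "P1"),
                             ("v2", "2", 1_500_000, "P2")])
        assert find_hotspots(recs, corr) == []

    def test_same_protein_never_seeds(self):
        corr = corr_from({}, ["P1"])
        recs = records_from([("v1", "2", 1_000_000, "P1"),
                             ("v2", "2", 1_200_000, "P1")])
        assert find_hotspots(recs, corr) == []

    def test_seed_gap_strict_extension_inclusive(self):
        corr = corr_from({("P1", "P2"): 0.9, ("P2", "P3"): 0.9}, ["P1", "P2", "P3"])
        # seed gap exactly 1 Mb -> NOT a seed (strict <)
        recs = records_from([("v1", "1", 1_000_000, "P1"),
                             ("v2", "1", 2_000_000, "P2")])
        assert find_hotspots(recs, corr) == []
        # extension gap exactly 1 Mb -> accepted (inclusive)
        recs = records_from([("v1", "1", 1_000_000, "P1"),
                             ("v2", "1", 1_500_000, "P2"),
                             ("v3", "1", 2_500_000, "P3")])
        spots = find_hotspots(recs, corr)
        assert len(spots) == 1 and spots[0].n_variants == 3

    def test_missing_protein_raises(self):
        corr = corr_from({}, ["P1"])
        recs = records_from([("v1", "1", 10, "P1"), ("v2", "1", 20, "PX")])
        with pytest.raises(InputValidationError, match="PX"):
            find_hotspots(recs, corr)

    def test_matches_oracle_on_toy_chromosome(self):
        prots = [f"P{i}" for i in range(6)]
        corr = corr_from({("P0", "P1"): 0.7, ("P1", "P2"): 0.55,
                          ("P3", "P4"): 0.9, ("P2", "P3"): 0.1,
                          ("P4", "P5"): -0.6}, prots)
        recs = records_from([
            ("v0", "1", 100_000, "P0"),
            ("v1", "1", 600_000, "P1"),
            ("v2", "1", 1_400_000, "P2"),
            ("v3", "1", 4_000_000, "P3"),
            ("v4", "1", 4_500_000, "P4"),
            ("v5", "1", 5_100_000, "P5"),
        ])
        spots = find_hotspots(recs, corr)
        assert [h.variants for h in spots] == hotspot_oracle(recs, corr)

    def test_matches_oracle_randomized(self, rng):
        prots = [f"P{i}" for i in range(8)]
        for trial in range(25):
            rho = {}
            for i in range(8):
                for j in range(i + 1, 8):
                    rho[(prots[i], prots[j])] = float(rng.uniform(-1, 1))
            corr = corr_from(rho, prots)
            n_var = int(rng.integers(3, 12))
            pos = np.sort(rng.choice(np.arange(1, 80) * 200_000, n_var,
                                     replace=False))
            recs = records_from([
                (f"v{k}", "1", int(pos[k]), prots[int(rng.integers(8))])
                for k in range(n_var)])
            spots = find_hotspots(recs, corr)
            assert [h.variants for h in spots] == hotspot_oracle(recs, corr), trial

    def test_members_disjoint(self, rng):
        prots = [f"P{i}" for i in range(5)]
        rho = {(a, b): 0.9 for i, a in enumerate(prots) for b in prots[i + 1:]}
        corr = corr_from(rho, prots)
        recs = records_from([(f"v{k}", "1", 400_000 * (k + 1),
                              prots[k % 5]) for k in range(12)])
        spots = find_hotspots(recs, corr)
        seen = []
        for h in spots:
            seen.extend(h.variants)
        assert len(seen) == len(set(seen))


class TestAnnotateHotspot:
    def _hs(self, proteins):
        return Hotspot(id="H1", chrom="1", start=1, end=2, variants=["v1", "v2"],
                       positions=[1, 2], proteins=proteins)

    def test_majority(self):
        terms = annotate_hotspot(self._hs(["P1", "P2", "P3"]),
                                 {"P1": {"ATP"}, "P2": {"ATP"},
                                  "P3": {"transport"}})
        assert terms == {"ATP"}

    def test_all_share(self):
        terms = annotate_hotspot(self._hs(["P1", "P2"]),
                                 {"P1": {"x"}, "P2": {"x"}})
        assert terms == {"x"}

    def test_none_shared(self):
        terms = annotate_hotspot(self._hs(["P1", "P2"]),
                                 {"P1": {"a"}, "P2": {"b"}})
        assert terms == set()


class TestSharedHotspotEnrichment:
    def test_perfect_association(self):
        # 5 proteins: A,B,C,D,E; hotspot covers A,B; high rho exactly A-B
        prots = list("ABCDE")
        corr = corr_from({("A", "B"): 0.9}, prots)
        hs = [Hotspot(id="H", chrom="1", start=1, end=2, variants=["v1", "v2"],
                      positions=[1, 2], proteins=["A", "B"])]
        odds, p, table = shared_hotspot_enrichment(corr, hs, prots)
        assert table.tolist() == [[1, 0], [0, 9]]
        # exact: only 1 of the 10 pairs is high-rho and it is the sharing one
        assert p == pytest.approx(0.1)

    def test_independence_gives_p_one(self):
        prots = list("ABCD")
        corr = corr_from({("A", "B"): 0.9, ("C", "D"): 0.9,
                          ("A", "C"): 0.9, ("B", "D"): 0.9,
                          ("A", "D"): 0.9, ("B", "C"): 0.9}, prots)
        hs = [Hotspot(id="H", chrom="1", start=1, end=2, variants=["v", "w"],
                      positions=[1, 2], proteins=["A", "B"])]
        _, p, table = shared_hotspot_enrichment(corr, hs, prots)
        assert p == 1.0  # all pairs high-rho: margins degenerate


class TestEqtlHotspots:
    def _study(self):
        cfg = SimulationConfig(
            n_samples=200, n_variants=60, n_proteins=9, seed=33,
            n_chromosomes=1, maf_range=(0.2, 0.5), noise_sd=0.4,
            planted_effects=[PlantedEffect(v, p, 1.5, "local")
                             for v in (10, 11, 12) for p in (0, 1, 2)])
        g = simulate_genotypes(cfg)
        pm, truth = simulate_proteome(cfg, g)
        res = scan(g, pm, truth.covariates,
                   ScanConfig(threshold=1e-8, use_pcs=False))
        corr = spearman_matrix(pm)
        return cfg, g, pm, truth, res, corr

    def test_same_table_same_hotspots(self):
        cfg, g, pm, truth, res, corr = self._study()
        own = find_hotspots(res.records, corr)
        gene_of = pm.meta.set_index("protein")["gene"]
        external = pd.DataFrame({
            "rsid": res.records["rsid"],
            "gene": [gene_of[p] for p in res.records["protein"]],
            "p": res.records["p"],
        })
        ext = find_eqtl_hotspots(external, g.variants, pm.meta, corr)
        assert [h.variants for h in ext] == [h.variants for h in own]

    def test_empty_external(self):
        cfg, g, pm, truth, res, corr = self._study()
        empty = pd.DataFrame(columns=["rsid", "gene", "p"])
        assert find_eqtl_hotspots(empty, g.variants, pm.meta, corr) == []

    def test_planted_cluster_found(self):
        cfg, g, pm, truth, res, corr = self._study()
        gene_of = pm.meta.set_index("protein")["gene"]
        rsids = [g.variants["rsid"].iat[v] for v in (10, 11, 12)]
        external = pd.DataFrame({
            "rsid": rsids * 3,
            "gene": [gene_of[pm.values.index[p]] for p in (0, 0, 0, 1, 1, 1, 2, 2, 2)],
            "p": 1e-12,
        })
        spots = find_eqtl_hotspots(external, g.variants, pm.meta, corr)
        assert len(spots) == 1
        assert set(spots[0].variants) == set(rsids)


class TestClusterRecovery:
    def test_k_clusters_recovered(self):
        hits = 0
        seeds = range(15)
        for seed in seeds:
            effects = []
            clusters = [(0, 1, 2), (20, 21, 22), (40, 41, 42)]
            for c, vs in enumerate(clusters):
                for v in vs:
                    for p in range(3 * c, 3 * c + 3):
                        effects.append(PlantedEffect(v, p, 1.2, "local"))
            cfg = SimulationConfig(
                n_samples=287, n_variants=60, n_proteins=12, seed=seed,
                n_chromosomes=1, maf_range=(0.2, 0.5), noise_sd=0.5,
                planted_effects=effects)
            g = simulate_genotypes(cfg)
            pm, truth = simulate_proteome(cfg, g)
            res = scan(g, pm, truth.covariates,
                       ScanConfig(threshold=2.99e-8, use_pcs=False))
            corr = spearman_matrix(pm)
            spots = find_hotspots(res.records, corr)
            hits += len(spots) == 3
        assert hits >= int(0.9 * len(seeds))
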