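"""Metagene profile, GBMR, rank classification, expression curve, clustering."""

import numpy as np
import pandas as pd
import pytest

from oystermeth import (
    MethylationCallSet,
    classify_genes_by_rank,
    cluster_samples,
    gene_body_methylation,
    linkage_to_newick,
    metagene_profile,
    methylation_by_expression_rank,
    rpkm,
    unite_positions,
)
from oystermeth.calling import UnitedMatrix, call_methylation
from oystermeth.characterize import first_split
from oystermeth.synthetic import GeneSet


def callset(rows, sample_id="s"):
    df = pd.DataFrame(
        rows, columns=["scaffold", "pos", "strand", "context", "coverage", "fraction"]
    )
    return MethylationCallSet(sample_id, 1, df)


def gene_set(*rows):
    return GeneSet(
        pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
    )


class TestMetagene:
    def test_uniform_methylome_is_flat(self):
        gs = gene_set(("g1", "s", 5000, 8000, "+"), ("g2", "s", 15000, 19000, "-"))
        rows = [("s", p, "+", "CpG", 20, 0.2) for p in range(1000, 23000, 10)]
        prof = metagene_profile(callset(rows), gs, flank=3000)
        filled = prof.dropna(subset=["mean_fraction"])
        np.testing.assert_allclose(filled["mean_fraction"], 0.2, rtol=0, atol=1e-12)

    def test_genic_enrichment_reproduces_mosaic_shape(self, small_dataset, small_config):
        cs = call_methylation(small_dataset.reports[0], 10)
        prof = metagene_profile(cs, small_dataset.gene_set, flank=small_config.flank)
        body = prof[prof["region"] == "body"]["mean_fraction"].mean()
        flanks = prof[prof["region"] != "body"]["mean_fraction"].mean()
        assert body > flanks

    def test_minus_strand_gradient_mirrors_plus_strand(self):
        # same 5'->3' gradient encoded on opposite strands
        gs_plus = gene_set(("g", "s", 4000, 5999, "+"))
        gs_minus = gene_set(("g", "s", 4000, 5999, "-"))
        rows_plus, rows_minus = [], []
        for p in range(1000, 9001, 10):
            rel = np.clip((p - 4000) / 2000, 0, 1)
            rows_plus.append(("s", p, "+", "CpG", 20, rel))
            rows_minus.append(("s", p, "+", "CpG", 20, 1 - rel))
        prof_p = metagene_profile(callset(rows_plus), gs_plus, flank=3000)
        prof_m = metagene_profile(callset(rows_minus), gs_minus, flank=3000)
        a = prof_p["mean_fraction"].to_numpy()
        b = prof_m["mean_fraction"].to_numpy()
        mask = ~np.isnan(a) & ~np.isnan(b)
        np.testing.assert_allclose(a[mask], b[mask], atol=0.01)

    def test_translation_equivariance(self):
        gs1 = gene_set(("g", "s", 4000, 6000, "+"))
        gs2 = gene_set(("g", "s", 4500, 6500, "+"))
        rows1 = [("s", p, "+", "CpG", 20, 0.1 + 0.2 * (p % 3 == 0))
                 for p in range(1000, 9001, 7)]
        rows2 = [("s", p + 500, st, c, cov, f) for (s, p, st, c, cov, f) in rows1]
        p1 = metagene_profile(callset(rows1), gs1, flank=3000)
        p2 = metagene_profile(callset(rows2), gs2, flank=3000)
        np.testing.assert_allclose(
            p1["mean_fraction"], p2["mean_fraction"], equal_nan=True
        )


class TestGbmr:
    def test_mean_of_member_sites(self):
        gs = gene_set(("g1", "s", 100, 200, "+"))
        cs = callset([("s", 120, "+", "CpG", 10, 0.1), ("s", 150, "-", "CpG", 10, 0.3)])
        out = gene_body_methylation(cs, gs)
        assert out.iloc[0]["gbmr"] == pytest.approx(0.2)

    def test_uncovered_gene_missing(self):
        gs = gene_set(("g1", "s", 100, 200, "+"), ("g2", "s", 300, 400, "+"))
        cs = callset([("s", 120, "+", "CpG", 10, 0.1)])
        out = gene_body_methylation(cs, gs)
        assert np.isnan(out.set_index("gene_id").loc["g2", "gbmr"])

    def test_overlapping_genes_share_sites(self):
        gs = gene_set(("g1", "s", 100, 200, "+"), ("g2", "s", 150, 250, "+"))
        cs = callset([("s", 170, "+", "CpG", 10, 0.4)])
        out = gene_body_methylation(cs, gs)
        assert (out["gbmr"] == 0.4).all()

    def test_brute_force_interval_oracle_on_synthetic_genome(self, small_dataset):
        cs = call_methylation(small_dataset.reports[0], 10)
        out = gene_body_methylation(cs, small_dataset.gene_set).set_index("gene_id")
        cpg = cs.data[cs.data["context"] == "CpG"]
        for g in small_dataset.gene_set.genes.itertuples(index=False):
            vals = [
                r.fraction
                for r in cpg.itertuples(index=False)
                if r.scaffold == g.scaffold and g.start <= r.pos <= g.end
            ]
            expected = np.mean(vals) if vals else np.nan
            got = out.loc[g.gene_id, "gbmr"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_gbmr_bounded_by_member_fractions(self, small_dataset):
        cs = call_methylation(small_dataset.reports[0], 10)
        out = gene_body_methylation(cs, small_dataset.gene_set)
        cpg = cs.data[cs.data["context"] == "CpG"]
        merged = out.dropna()
        assert (merged["gbmr"] >= cpg["fraction"].min() - 1e-12).all()
        assert (merged["gbmr"] <= cpg["fraction"].max() + 1e-12).all()


class TestClassification:
    def test_ten_increasing_genes_split_two_three_five(self):
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                           "gbmr": np.linspace(0.01, 0.4, 10)})
        out = classify_genes_by_rank(gm)
        counts = out["meth_class"].value_counts()
        assert counts.to_dict() == {"high": 5, "mid": 3, "low": 2}

    def test_all_tied_is_all_mid_with_warning(self):
        gm = pd.DataFrame({"gene_id": ["a", "b", "c"], "gbmr": [0.1, 0.1, 0.1]})
        with pytest.warns(UserWarning, match="tied"):
            out = classify_genes_by_rank(gm)
        assert (out["meth_class"] == "mid").all()

    def test_invariant_under_monotone_transform(self, rng):
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)],
                           "gbmr": rng.random(50)})
        a = classify_genes_by_rank(gm)["meth_class"]
        gm2 = gm.assign(gbmr=np.exp(5 * gm["gbmr"]))
        b = classify_genes_by_rank(gm2)["meth_class"]
        assert (a == b).all()

    def test_recovers_simulator_gene_classes(self, small_dataset):
        from oystermeth.calling import call_methylation

        cs = call_methylation(small_dataset.reports[0], 10)
        gbmr = gene_body_methylation(cs, small_dataset.gene_set)
        out = classify_genes_by_rank(gbmr).merge(
            small_dataset.gene_set.genes[["gene_id", "meth_class"]],
            on="gene_id", suffixes=("_pred", "_true"),
        )
        truth = out[out["meth_class_true"].isin(["low", "high"])]
        agree = (truth["meth_class_pred"] == truth["meth_class_true"]).mean()
        assert agree >= 0.95

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            classify_genes_by_rank(pd.DataFrame({"gene_id": ["a"], "gbmr": [0.1]}))


class TestRpkm:
    def test_formula(self):
        assert rpkm(10, 1000, 1_000_000)[()] == pytest.approx(10.0)

    def test_zero_counts(self):
        assert rpkm(0, 500, 10**6)[()] == 0.0

    def test_library_size_proportionality(self):
        assert rpkm(10, 1000, 2_000_000)[()] == pytest.approx(
            rpkm(10, 1000, 1_000_000)[()] / 2
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestExpressionCurve:
    def test_hump_coupling_maximal_in_moderate_band(self, small_dataset):
        from oystermeth.calling import call_methylation

        cs = call_methylation(small_dataset.reports[0], 10)
        gm = gene_body_methylation(cs, small_dataset.gene_set)
        curve, fixed = methylation_by_expression_rank(gm, small_dataset.expression)
        fixed = fixed.set_index("band")
        assert fixed.loc["100-1000", "mean_gbmr"] == fixed["mean_gbmr"].max()

    def test_single_bin_is_grand_mean(self):
        gm = pd.DataFrame({"gene_id": ["a", "b"], "gbmr": [0.1, 0.3]})
        expr = pd.DataFrame({"gene_id": ["a", "b"], "rpkm": [10.0, 20.0]})
        curve, _ = methylation_by_expression_rank(gm, expr, n_bins=1)
        assert len(curve) == 1
        assert curve.iloc[0]["mean_gbmr"] == pytest.approx(0.2)

    def test_disjoint_ids_rejected(self):
        gm = pd.DataFrame({"gene_id": ["a"], "gbmr": [0.1]})
        expr = pd.DataFrame({"gene_id": ["z"], "rpkm": [1.0]})
        with pytest.raises(ValueError):
            methylation_by_expression_rank(gm, expr)


def ward_oracle(dist: np.ndarray):
    """Brute-force Ward agglomeration via the Lance-Williams update."""
    n = dist.shape[0]
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(
            ((k, v) for k, v in d.items() if k[0] in active and k[1] in active),
            key=lambda kv: kv[1],
        )
        merges.append((i, j, h))
        for k in active - {i, j}:
            a, b, c = size[i], size[j], size[k]
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dij = d[(i, j)]
            new = np.sqrt(
                ((a + c) * dik**2 + (b + c) * djk**2 - c * dij**2) / (a + b + c)
            )
            d[tuple(sorted((nxt, k)))] = new
        size[nxt] = size[i] + size[j]
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return merges


class TestClustering:
    def _matrix(self, profiles, labels):
        n_sites = profiles.shape[1]
        data = {
            "scaffold": ["s"] * n_sites,
            "pos": np.arange(1, n_sites + 1),
            "strand": ["+"] * n_sites,
            "context": ["CpG"] * n_sites,
        }
        for lab, prof in zip(labels, profiles):
            m = np.round(prof * 100).astype(int)
            data[f"{lab}.M"] = m
            data[f"{lab}.U"] = 100 - m
        return UnitedMatrix(samples=list(labels), min_coverage=10,
                            data=pd.DataFrame(data))

    def test_first_split_separates_perfectly_correlated_groups(self, rng):
        base1 = rng.uniform(0.1, 0.9, 50)
        base2 = rng.permutation(base1)
        profiles = np.vstack([base1, base1 * 0.8 + 0.1, base2, base2 * 0.8 + 0.1])
        Z, labels = cluster_samples(self._matrix(profiles, ["a1", "a2", "b1", "b2"]))
        left, right = first_split(Z, ["a1", "a2", "b1", "b2"])
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"a1", "a2"}), frozenset({"b1", "b2"})
        }

    def test_linkage_matches_ward_oracle(self, rng):
        profiles = rng.uniform(0.05, 0.95, size=(4, 40))
        m = self._matrix(profiles, ["w", "x", "y", "z"])
        Z, _ = cluster_samples(m)
        mat = np.vstack([m.fractions(s) for s in m.samples])
        dist = 1 - np.corrcoef(mat)
        np.fill_diagonal(dist, 0)
        merges = ward_oracle(dist)
        np.testing.assert_allclose(Z[:, 2], [h for _, _, h in merges], rtol=1e-10)

    def test_constant_profile_rejected(self):
        profiles = np.vstack([np.full(20, 0.5), np.linspace(0.1, 0.9, 20),
                              np.linspace(0.9, 0.1, 20)])
        with pytest.raises(ValueError, match="constant"):
            cluster_samples(self._matrix(profiles, ["flat", "up", "down"]))

    def test_order_invariance(self, rng):
        profiles = rng.uniform(0.05, 0.95, size=(5, 30))
        labels = ["a", "b", "c", "d", "e"]
        m1 = self._matrix(profiles, labels)
        m2 = self._matrix(profiles[::-1], labels[::-1])
        Z1, _ = cluster_samples(m1)
        Z2, _ = cluster_samples(m2)
        np.testing.assert_allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_treatment_then_genotype_topology(self, small_dataset):
        from oystermeth.calling import call_methylation

        callsets = [call_methylation(r, 10) for r in small_dataset.reports]
        united = unite_positions(callsets, context_filter="CpG")
        Z, _ = cluster_samples(united)
        left, right = first_split(Z, united.samples)
        treat = lambda s: s[0]
        assert {frozenset(map(treat, left)), frozenset(map(treat, right))} == {
            frozenset("C"), frozenset("T")
        }

    def test_newick_roundtrip_has_all_leaves(self, rng):
        profiles = rng.uniform(0.05, 0.95, size=(4, 30))
        m = self._matrix(profiles, ["w", "x", "y", "z"])
        Z, _ = cluster_samples(m)
        nwk = linkage_to_newick(Z, m.samples)
        for leaf in m.samples:
            assert leaf in nwk
        assert nwk.endswith(";")
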