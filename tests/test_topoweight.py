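"""Topology catalog, outgroup-private SNP removal, SNP windows, NJ window
trees, exact weighting and loess smoothing."""

import itertools

import dendropy
import numpy as np
import pytest
from _util import make_table

from chelonia.topoweight import (
    WindowWeights,
    enumerate_topologies,
    infer_window_tree,
    remove_outgroup_private_snps,
    smooth_weights,
    topology_from_newick,
    weight_window,
    weight_windows,
    window_snp_blocks,
)

SPECIES = ("OL", "LL", "HH", "GG", "DC")
SMAP = {f"{s}__{k}": s for s in SPECIES for k in (0, 1)}


def get_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestEnumerate:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_double_factorial_counts(self, k, expected):
        taxa = [f"t{i}" for i in range(k)]
        cat = enumerate_topologies(taxa, "out")
        assert len(cat) == expected
        assert len(set(cat.topologies)) == expected  # canonical forms unique

    def test_three_taxa_match_brute_force(self):
        cat = enumerate_topologies(["A", "B", "C"], "O")
        assert set(cat.topologies) == {"((A,B),C)", "((A,C),B)", "((B,C),A)"}

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            enumerate_topologies(["A", "A", "B"], "O")


class TestOutgroupPrivate:
    def test_hand_classified_sites(self):
        # 4 samples, last is outgroup; 12 sites
        gt = np.zeros((12, 4, 2), dtype=np.int8)
        # sites 0-3: variation only in outgroup -> removed
        gt[0:4, 3, 0] = 1
        # sites 4-7: ingroup polymorphic -> retained
        gt[4:8, 1, :] = 1
        # sites 8-9: ingroup poly + outgroup carries alt -> retained
        gt[8:10, 0, :] = 1
        gt[8:10, 3, :] = 1
        # sites 10-11: everyone hom-alt (no ingroup polymorphism, outgroup same)
        gt[10:12, :, :] = 1
        g = make_table(np.arange(1, 13), gt, samples=["a", "b", "c", "og"])
        out = remove_outgroup_private_snps(g, "og")
        assert out.scaffolds["s"].pos.tolist() == [5, 6, 7, 8, 9, 10]

    def test_ingroup_variable_site_retained(self):
        gt = np.zeros((1, 3, 2), dtype=np.int8)
        gt[0, 0, 0] = 1
        g = make_table([1], gt, samples=["a", "b", "og"])
        out = remove_outgroup_private_snps(g, "og")
        assert out.scaffolds["s"].n_sites == 1


class TestSnpWindows:
    @pytest.mark.parametrize(
        "n_snps,expected_sizes",
        [
            (149, [50, 50, 49]),  # terminal 49 >= 45 kept
            (144, [50, 50]),  # terminal 44 dropped
            (10, []),
            (100, [50, 50]),
        ],
    )
    def test_block_rule(self, n_snps, expected_sizes):
        gt = np.zeros((n_snps, 1, 2), dtype=np.int8)
        g = make_table(np.arange(1, n_snps + 1), gt)
        blocks = window_snp_blocks(g, 50, 45)
        assert [len(idx) for _, idx in blocks] == expected_sizes


class TestWindowTree:
    def _haps_on_tree(self):
        # 6 haplotypes; (h0,h1), (h2,h3), (h4,h5) cherries with clear signal
        blocks = {
            ("h0", "h1"): [0, 1],
            ("h2", "h3"): [2, 3],
            ("h4", "h5"): [4, 5],
        }
        n_sites = 60
        h = np.zeros((n_sites, 6), dtype=np.int8)
        h[0:20, [0, 1]] = 1  # cherry 1 private alleles
        h[20:40, [2, 3]] = 1
        h[40:50, [0, 1, 2, 3]] = 1  # groups cherries 1+2 together
        rng = np.random.default_rng(0)
        h[50:60] = rng.integers(0, 2, size=(10, 6))
        return h

    def test_recovers_known_topology(self):
        h = self._haps_on_tree()
        labels = [f"h{i}" for i in range(6)]
        tree = infer_window_tree(h, labels)
        topo = topology_from_newick(tree.as_string(schema="newick", unquoted_underscores=True), "h5")
        # rooted on h5: ((h0,h1),(h2,h3)) with h4 attached below the root
        assert "(h0,h1)" in topo and "(h2,h3)" in topo

    def test_row_permutation_invariance(self):
        h = self._haps_on_tree()
        labels = [f"h{i}" for i in range(6)]
        t1 = infer_window_tree(h, labels)
        perm = np.random.default_rng(1).permutation(h.shape[0])
        t2 = infer_window_tree(h[perm], labels)
        topo1 = topology_from_newick(t1.as_string(schema="newick", unquoted_underscores=True), "h5")
        topo2 = topology_from_newick(t2.as_string(schema="newick", unquoted_underscores=True), "h5")
        assert topo1 == topo2

    def test_identical_haplotypes_star_rejected(self):
        h = np.zeros((30, 5), dtype=np.int8)
        with pytest.raises(ValueError, match="star"):
            infer_window_tree(h, [f"h{i}" for i in range(5)])


class TestWeightWindow:
    def test_monophyletic_species_weight_one(self):
        nwk = (
            "((((OL__0:1,OL__1:1):1,(LL__0:1,LL__1:1):1):1,"
            "((HH__0:1,HH__1:1):1,(GG__0:1,GG__1:1):1):1):1,(DC__0:1,DC__1:1):1);"
        )
        cat = enumerate_topologies(["OL", "LL", "HH", "GG"], "DC")
        w = weight_window(get_tree(nwk), SMAP, cat)
        assert w.sum() == pytest.approx(1.0)
        assert w.max() == pytest.approx(1.0)
        assert cat.topologies[int(np.argmax(w))] == "((GG,HH),(LL,OL))"

    def test_paraphyletic_matches_brute_force_extraction(self):
        nwk = (
            "(((OL__0:1,(LL__0:1,LL__1:1):1):1,(OL__1:1,(HH__0:1,HH__1:1):1):1):1,"
            "((GG__0:1,GG__1:1):1,(DC__0:1,DC__1:1):1):1);"
        )
        cat = enumerate_topologies(["OL", "LL", "HH", "GG"], "DC")
        w = weight_window(get_tree(nwk), SMAP, cat)
        counts = np.zeros(len(cat))
        by = {s: [f"{s}__0", f"{s}__1"] for s in SPECIES}
        for combo in itertools.product(*[by[s] for s in SPECIES]):
            t = get_tree(nwk)
            t.retain_taxa_with_labels(list(combo))
            canon = topology_from_newick(
                t.as_string(schema="newick", unquoted_underscores=True), combo[-1]
            )
            for s in SPECIES:
                canon = canon.replace(f"{s}__0", s).replace(f"{s}__1", s)
            counts[cat.index(canon)] += 1
        assert np.allclose(w, counts / counts.sum())

    def test_missing_haplotype_rejected(self):
        nwk = "((OL__0:1,LL__0:1):1,DC__0:1);"
        cat = enumerate_topologies(["OL", "LL"], "DC")
        with pytest.raises(ValueError, match="missing|no haplotype"):
            weight_window(get_tree(nwk), SMAP, cat)


class TestEndToEndWindows:
    def test_weights_sum_to_one_and_signature_direction(self, turtle_sim_migration):
        g = turtle_sim_migration.genotypes
        species_map = {f"{s}_0": s for s in SPECIES}
        g2 = remove_outgroup_private_snps(g, "DC_0")
        catalog, ws = weight_windows(g2, species_map, "DC")
        assert len(ws) > 50
        for w in ws[:20]:
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w.weights >= 0)
        mean = np.mean([w.weights for w in ws], axis=0)
        # with HH<->OL gene flow the discordant topology uniting HH and OL
        # must outweigh the other discordant resolution of the same clade
        i_mig = catalog.index("(((HH,OL),LL),GG)")
        i_other = catalog.index("(((HH,LL),OL),GG)")
        assert mean[i_mig] > mean[i_other]


class TestSmoothing:
    def _windows(self, values):
        return [
            WindowWeights("s", midpoint=float(i * 50_000), weights=np.array(v), n_snps=50)
            for i, v in enumerate(values)
        ]

    def test_constant_weights_unchanged(self):
        ws = self._windows([[0.6, 0.4]] * 30)
        x, S = smooth_weights(ws, span_bp=1_000_000)["s"]
        assert np.allclose(S[:, 0], 0.6) and np.allclose(S[:, 1], 0.4)

    def test_step_smooths_monotone_without_overshoot(self):
        ws = self._windows([[1.0, 0.0]] * 30 + [[0.0, 1.0]] * 30)
        _, S = smooth_weights(ws, span_bp=1_000_000)["s"]
        track = S[:, 0]
        assert np.all((track >= 0) & (track <= 1))
        assert track[0] > 0.9 and track[-1] < 0.1
        assert np.all(np.diff(track) <= 1e-9)  # monotone transition

    def test_renormalized_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        vals = rng.dirichlet([1, 1, 1], size=40)
        ws = self._windows(list(vals))
        _, S = smooth_weights(ws, span_bp=500_000)["s"]
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-9)

    def test_single_window_identity(self):
        ws = self._windows([[0.3, 0.7]])
        x, S = smooth_weights(ws)["s"]
        assert np.allclose(S, [[0.3, 0.7]])
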