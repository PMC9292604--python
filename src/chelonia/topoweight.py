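"""Exact topology weighting of per-window gene trees.

For k species with two haplotypes each and a designated outgroup, each
window's gene tree is reduced to species topologies by iterating over every
combination of one haplotype per species (2^k for diploids), pruning the tree
to that combination, rooting with the outgroup haplotype, and matching the
induced ingroup topology against the catalog of all rooted binary topologies.
Weights are the matched fractions, so they are exact (no subsampling) and sum
to one.

Window trees are built by neighbor joining on Jukes-Cantor-corrected
haplotype distances - deterministic and fast at the 50-SNP window scale; a
hook accepts externally computed newick trees per window instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeTable
from .diversity import jc_correct

__all__ = [
    "TopologyCatalog",
    "WindowWeights",
    "enumerate_topologies",
    "remove_outgroup_private_snps",
    "window_snp_blocks",
    "infer_window_tree",
    "weight_window",
    "weight_windows",
    "smooth_weights",
    "topology_from_newick",
]


# ---------------------------------------------------------------------------
# canonical rooted topologies

def _canon(node) -> str:
    """Canonical string of a nested-tuple/str rooted topology: children sorted
    by their canonical strings at every node."""
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(_canon(c) for c in node)) + ")"


def _all_rooted(taxa: tuple[str, ...]):
    """All rooted binary topologies on taxa, as nested tuples."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    for sub in _all_rooted(rest):
        yield from _attach_everywhere(sub, first)


def _attach_everywhere(node, leaf):
    # attach at the root
    yield (node, leaf)
    if not isinstance(node, str):
        a, b = node
        for na in _attach_everywhere(a, leaf):
            yield (na, b)
        for nb in _attach_everywhere(b, leaf):
            yield (a, nb)


@dataclass(frozen=True)
class TopologyCatalog:
    """Ordered canonical rooted topologies on the ingroup, outgroup fixed."""

    ingroup: tuple[str, ...]
    outgroup: str
    topologies: tuple[str, ...]  # canonical strings

    def index(self, canonical: str) -> int:
        return self.topologies.index(canonical)

    def __len__(self) -> int:
        return len(self.topologies)


def enumerate_topologies(ingroup, outgroup: str) -> TopologyCatalog:
    """Catalog of all distinct rooted binary ingroup topologies.

    For k ingroup taxa there are (2k-3)!! of them - 15 for four taxa.
    Deterministic order: sorted canonical strings.
    """
    ingroup = tuple(sorted(ingroup))
    if len(set(ingroup)) != len(ingroup) or outgroup in ingroup:
        raise ValueError("duplicate taxon names")
    if len(ingroup) < 2:
        raise ValueError("need at least 2 ingroup taxa")
    seen = {_canon(t) for t in _all_rooted(ingroup)}
    return TopologyCatalog(ingroup=ingroup, outgroup=outgroup, topologies=tuple(sorted(seen)))


# ---------------------------------------------------------------------------
# SNP preprocessing

def remove_outgroup_private_snps(g: GenotypeTable, outgroup: str) -> GenotypeTable:
    """Drop sites whose variation is private to the outgroup sample.

    A site is removed when every ingroup sample is homozygous for one allele
    and only the outgroup carries the other allele.
    """
    oi = g.sample_index(outgroup)
    keep = {}
    for name, sg in g.scaffolds.items():
        ingt = np.delete(sg.gt, oi, axis=1)
        called = ingt >= 0
        any0 = np.any((ingt == 0) & called, axis=(1, 2))
        any1 = np.any((ingt == 1) & called, axis=(1, 2))
        keep[name] = any0 & any1  # ingroup polymorphic -> retained
    return g.subset_sites(keep)


def window_snp_blocks(
    g: GenotypeTable, size_snps: int = 50, min_snps: int = 45
) -> list[tuple[str, np.ndarray]]:
    """Consecutive non-overlapping SNP-count windows per scaffold.

    Returns (scaffold, site-index array) pairs; the terminal block is kept
    only when it has at least ``min_snps`` SNPs.
    """
    blocks = []
    for name, sg in g.scaffolds.items():
        n = sg.n_sites
        for start in range(0, n, size_snps):
            idx = np.arange(start, min(start + size_snps, n))
            if len(idx) >= min_snps:
                blocks.append((name, idx))
    return blocks


# ---------------------------------------------------------------------------
# window trees

def infer_window_tree(haplotypes: np.ndarray, labels: list[str]):
    """Neighbor-joining tree on JC-corrected haplotype distances.

    ``haplotypes``: (n_sites, n_haplotypes) allele matrix for one window.
    Ties in the NJ criterion resolve deterministically in taxon-label order
    (dendropy's iteration order over the fixed taxon namespace).  Raises on
    all-identical haplotypes (star tree, window should be skipped).
    """
    import dendropy

    h = np.asarray(haplotypes)
    n = h.shape[1]
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (h[:, i] >= 0) & (h[:, j] >= 0)
            pij = float(np.mean(h[both, i] != h[both, j])) if both.any() else 0.0
            p[i, j] = p[j, i] = min(pij, 0.74)  # clamp below JC saturation
    if np.all(p == 0):
        raise ValueError("all haplotypes identical; star tree")
    d = np.vectorize(jc_correct)(p)
    np.fill_diagonal(d, 0.0)

    csv = "," + ",".join(labels) + "\n"
    for i, lab in enumerate(labels):
        csv += lab + "," + ",".join(f"{d[i, j]:.10f}" for j in range(n)) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv), delimiter=",")
    return pdm.nj_tree()


# ---------------------------------------------------------------------------
# exact weighting

def _ingroup_topology_from_clades(clades: set[frozenset], species: frozenset) -> str:
    """Canonical rooted ingroup topology from the set of rooted clades."""

    def build(ts: frozenset):
        if len(ts) == 1:
            return next(iter(ts))
        # largest proper sub-clade and its complement
        subs = [c for c in clades if c < ts and len(c) < len(ts)]
        best = max(subs, key=len)
        rest = ts - best
        if rest not in clades and len(rest) > 1:
            # complement must itself be a clade in a binary rooted tree
            raise ValueError("non-binary topology")
        return (build(best), build(rest))

    return _canon(build(species))


def topology_from_newick(newick: str, outgroup: str) -> str:
    """Canonical rooted ingroup topology of a (possibly unrooted) newick tree
    with one leaf per species, rooted at the outgroup leaf."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _topology_from_tree(tree, outgroup)


def _topology_from_tree(tree, outgroup: str) -> str:
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    ingroup = frozenset(labels - {outgroup})
    tree_b = tree.clone(depth=1)
    tree_b.encode_bipartitions()
    clades = set()
    for edge in tree_b.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in tree_b.taxon_namespace.bitmask_taxa_list(edge.bipartition.leafset_bitmask)
        )
        for s in (side & labels, labels - side):
            if outgroup not in s and 1 <= len(s):
                clades.add(frozenset(s))
    clades.add(ingroup)
    return _ingroup_topology_from_clades(clades, ingroup)


def weight_window(tree, species_map: dict[str, str], catalog: TopologyCatalog) -> np.ndarray:
    """Exact topology weights of one window tree.

    ``species_map``: haplotype label -> species.  Iterates over every
    combination of one haplotype per species, prunes the tree to it, roots
    with the outgroup haplotype and increments the matching catalog topology.
    Returns the normalized weight vector (sums to 1).
    """
    import itertools

    by_species: dict[str, list[str]] = {}
    tree_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    for hap, sp in species_map.items():
        if hap not in tree_leaves:
            raise ValueError(f"haplotype {hap!r} missing from tree")
        by_species.setdefault(sp, []).append(hap)
    species = list(catalog.ingroup) + [catalog.outgroup]
    for sp in species:
        if sp not in by_species:
            raise ValueError(f"species {sp!r} has no haplotype in the tree")

    # Precompute, per internal edge, the leaf set on each side; the induced
    # clade structure of a pruned subset follows by intersection, which is
    # much faster than 2^k dendropy tree extractions.
    tree_b = tree.clone(depth=1)
    tree_b.encode_bipartitions()
    all_labels = frozenset(tree_leaves)
    sides = []
    for edge in tree_b.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in tree_b.taxon_namespace.bitmask_taxa_list(edge.bipartition.leafset_bitmask)
        )
        sides.append(side)
        sides.append(all_labels - side)

    counts = np.zeros(len(catalog))
    combos = list(itertools.product(*[by_species[sp] for sp in species]))
    for combo in combos:
        chosen = frozenset(combo)
        out_hap = combo[-1]
        sp_of = dict(zip(species, combo))
        hap_to_sp = {h: s for s, h in sp_of.items()}
        clades = set()
        for side in sides:
            sub = side & chosen
            if out_hap not in sub and len(sub) >= 1:
                clades.add(frozenset(hap_to_sp[h] for h in sub))
        ingroup_set = frozenset(catalog.ingroup)
        clades.add(ingroup_set)
        canon = _ingroup_topology_from_clades(clades, ingroup_set)
        counts[catalog.index(canon)] += 1
    return counts / counts.sum()


@dataclass
class WindowWeights:
    scaffold: str
    midpoint: float  # mean of first/last SNP positions (bp)
    weights: np.ndarray
    n_snps: int


def weight_windows(
    g: GenotypeTable,
    species_map: dict[str, str],
    outgroup_species: str,
    size_snps: int = 50,
    min_snps: int = 45,
) -> tuple[TopologyCatalog, list[WindowWeights]]:
    """Infer NJ trees for 50-SNP windows and weight each against the catalog.

    ``species_map``: sample name -> species.  Haplotype labels are
    ``<sample>__<0|1>``.  Windows whose haplotypes are all identical are
    skipped (star trees carry no topology information).
    """
    species = sorted(set(species_map.values()))
    ingroup = [s for s in species if s != outgroup_species]
    catalog = enumerate_topologies(ingroup, outgroup_species)
    sample_idx = [g.sample_index(s) for s in species_map]
    hap_labels, hap_species = [], {}
    for s in species_map:
        for k in range(g.ploidy):
            lab = f"{s}__{k}"
            hap_labels.append(lab)
            hap_species[lab] = species_map[s]

    out = []
    for scaffold, idx in window_snp_blocks(g, size_snps, min_snps):
        sg = g.scaffolds[scaffold]
        h = sg.gt[np.ix_(idx, sample_idx)].reshape(len(idx), -1)
        try:
            tree = infer_window_tree(h, hap_labels)
        except ValueError:
            continue
        w = weight_window(tree, hap_species, catalog)
        mid = 0.5 * (float(sg.pos[idx[0]]) + float(sg.pos[idx[-1]]))
        out.append(WindowWeights(scaffold=scaffold, midpoint=mid, weights=w, n_snps=len(idx)))
    return catalog, out


# ---------------------------------------------------------------------------
# loess smoothing

def smooth_weights(
    windows: list[WindowWeights], span_bp: float = 1_000_000.0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Loess-smoothed weight tracks per scaffold.

    Tricube-weighted local *linear* fit with a physical bandwidth of
    ``span_bp`` (total span; half-width span_bp/2), evaluated at the window
    midpoints, then clipped to [0, 1] and renormalized across topologies at
    every evaluation point.  Returns scaffold -> (midpoints, smoothed array
    of shape (n_windows, n_topologies)).
    """
    out = {}
    half = span_bp / 2.0
    by_scaffold: dict[str, list[WindowWeights]] = {}
    for w in windows:
        by_scaffold.setdefault(w.scaffold, []).append(w)
    for scaffold, ws in by_scaffold.items():
        ws = sorted(ws, key=lambda w: w.midpoint)
        x = np.array([w.midpoint for w in ws])
        Y = np.stack([w.weights for w in ws])
        if len(ws) == 1:
            out[scaffold] = (x, Y.copy())
            continue
        S = np.empty_like(Y)
        for i, x0 in enumerate(x):
            d = np.abs(x - x0) / half
            w_tri = np.where(d < 1, (1 - d**3) ** 3, 0.0)
            if w_tri.sum() == 0 or np.count_nonzero(w_tri) == 1:
                S[i] = Y[i]
                continue
            xc = x - x0
            sw, swx, swxx = w_tri.sum(), (w_tri * xc).sum(), (w_tri * xc * xc).sum()
            det = sw * swxx - swx**2
            if det <= 0:
                S[i] = (w_tri[:, None] * Y).sum(axis=0) / sw
                continue
            # local linear fit evaluated at x0: intercept of centered fit
            a = (swxx * (w_tri[:, None] * Y).sum(axis=0) - swx * (w_tri[:, None] * xc[:, None] * Y).sum(axis=0)) / det
            S[i] = a
        S = np.clip(S, 0.0, 1.0)
        norm = S.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        out[scaffold] = (x, S / norm)
    return out


def weights_table(catalog: TopologyCatalog, windows: list[WindowWeights]) -> str:
    """Tab-separated weights table (window, midpoint, one column per topology)."""
    header = "scaffold\tmidpoint\tn_snps\t" + "\t".join(catalog.topologies)
    lines = [header]
    for w in windows:
        lines.append(
            f"{w.scaffold}\t{w.midpoint:.1f}\t{w.n_snps}\t"
            + "\t".join(f"{x:.6f}" for x in w.weights)
        )
    return "\n".join(lines) + "\n"
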