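"""Patterson's D (ABBA-BABA) from four single genomes with weighted block
jackknife standard errors, and a scan over all species-tree-consistent trios.

Convention, printed with every result: the arrangement is ``(((P1,P2),P3),O)``
and D = (nABBA - nBABA)/(nABBA + nBABA), so D > 0 indicates an excess of
derived-allele sharing between P2 and P3 (introgression or shared ancestry
beyond the species tree), D < 0 between P1 and P3.  Sites are polarized by a
single allele sampled from the outgroup; by default one allele is sampled
uniformly per diploid per site (seeded), with an allele-frequency-weighted
mode as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeTable, derive_seed

__all__ = [
    "DResult",
    "count_patterns",
    "d_statistic",
    "block_jackknife",
    "dstat_scan",
    "consistent_trios",
]

#: significance threshold on |Z|
Z_SIGNIFICANT = 3.0


@dataclass
class DResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    n_abba: float
    n_baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return np.isfinite(self.z) and abs(self.z) > Z_SIGNIFICANT

    @property
    def arrangement(self) -> str:
        return f"((({self.p1},{self.p2}),{self.p3}),{self.outgroup})"


def count_patterns(
    g: GenotypeTable,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    seed: int = 1,
    block_size: int = 5_000_000,
    min_block_sites: int = 100,
    mode: str = "sample",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (nABBA, nBABA) counts for one trio plus outgroup.

    Blocks are contiguous ``block_size``-bp spans per scaffold; blocks with
    fewer than ``min_block_sites`` informative sites are dropped.  In
    ``mode="sample"`` one allele is drawn per diploid per site (seeded); in
    ``mode="frequency"`` fractional pattern weights are accumulated from
    within-individual derived-allele frequencies.
    """
    if mode not in ("sample", "frequency"):
        raise ValueError("mode must be 'sample' or 'frequency'")
    names = (p1, p2, p3, outgroup)
    idx = [g.sample_index(s) for s in names]
    abba_blocks: dict[tuple, float] = {}
    baba_blocks: dict[tuple, float] = {}
    for name, sg in g.scaffolds.items():
        if sg.n_sites == 0:
            continue
        gt = sg.gt[:, idx, :]  # (sites, 4, ploidy)
        called = np.all(gt >= 0, axis=(1, 2))
        block_ids = sg.pos // block_size
        if mode == "sample":
            # one independent stream per sample so the drawn allele depends
            # only on (seed, sample, scaffold, site): swapping P1/P2 then
            # flips D's sign exactly
            choice = np.empty(gt.shape[:2], dtype=np.int64)
            for j, sample in enumerate(names):
                rng = np.random.default_rng(derive_seed(seed, "dstat", sample, name))
                choice[:, j] = rng.integers(0, gt.shape[2], size=sg.n_sites)
            alleles = np.take_along_axis(gt, choice[:, :, None], axis=2)[:, :, 0]
            anc = alleles[:, 3]
            b1 = alleles[:, 0] != anc
            b2 = alleles[:, 1] != anc
            b3 = alleles[:, 2] != anc
            abba = called & ~b1 & b2 & b3
            baba = called & b1 & ~b2 & b3
            for blk in np.unique(block_ids):
                m = block_ids == blk
                key = (name, int(blk))
                abba_blocks[key] = abba_blocks.get(key, 0.0) + float(abba[m].sum())
                baba_blocks[key] = baba_blocks.get(key, 0.0) + float(baba[m].sum())
        else:
            freq = gt.mean(axis=2)  # ALT-allele frequency per individual
            # polarize by the outgroup ALT frequency: derived freq d = |f - fO|
            # computed per site with the outgroup rounded to its major allele
            anc = (freq[:, 3] > 0.5).astype(float)
            d = np.abs(freq[:, :3] - anc[:, None])
            dO = np.abs(freq[:, 3] - anc)
            w_abba = (1 - d[:, 0]) * d[:, 1] * d[:, 2] * (1 - dO)
            w_baba = d[:, 0] * (1 - d[:, 1]) * d[:, 2] * (1 - dO)
            w_abba[~called] = 0.0
            w_baba[~called] = 0.0
            for blk in np.unique(block_ids):
                m = block_ids == blk
                key = (name, int(blk))
                abba_blocks[key] = abba_blocks.get(key, 0.0) + float(w_abba[m].sum())
                baba_blocks[key] = baba_blocks.get(key, 0.0) + float(w_baba[m].sum())
    keys = sorted(abba_blocks)
    abba = np.array([abba_blocks[k] for k in keys])
    baba = np.array([baba_blocks[k] for k in keys])
    keep = (abba + baba) >= min_block_sites
    abba, baba = abba[keep], baba[keep]
    if len(abba) < 2:
        raise ValueError("fewer than 2 blocks with informative sites")
    return abba, baba


def d_statistic(n_abba: float, n_baba: float) -> float:
    """D = (nABBA - nBABA)/(nABBA + nBABA)."""
    tot = n_abba + n_baba
    if tot <= 0:
        raise ValueError("D undefined: no informative sites")
    return (n_abba - n_baba) / tot


def block_jackknife(abba: np.ndarray, baba: np.ndarray) -> tuple[float, float, float]:
    """Weighted delete-one-block jackknife for D.

    Block weights are the informative-site counts (ABBA+BABA).  Uses the
    weighted jackknife variance of Busing et al. (unequal block sizes);
    returns (D, SE, Z).  When every delete-one estimate coincides the SE is
    exactly 0 and Z is NaN (degenerate, flagged by the caller).
    """
    abba = np.asarray(abba, dtype=float)
    baba = np.asarray(baba, dtype=float)
    m = abba + baba
    if len(m) < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    if np.any(m <= 0):
        raise ValueError("blocks without informative sites must be dropped first")
    n = m.sum()
    g = len(m)
    theta = d_statistic(abba.sum(), baba.sum())
    theta_del = np.array(
        [d_statistic(abba.sum() - a, baba.sum() - b) for a, b in zip(abba, baba)]
    )
    h = n / m
    theta_j = g * theta - np.sum((1 - m / n) * theta_del)
    pseudo = h * theta - (h - 1) * theta_del
    var = np.mean((pseudo - theta_j) ** 2 / (h - 1))
    se = float(np.sqrt(max(var, 0.0)))
    if se <= 1e-12 * (1.0 + abs(theta)):  # identical delete-one estimates
        se = 0.0
    z = theta / se if se > 0 else float("nan")
    return theta, se, z


def _trio_result(g, p1, p2, p3, outgroup, sample_map, seed, **kw) -> DResult:
    s = sample_map or {}
    abba, baba = count_patterns(
        g, s.get(p1, p1), s.get(p2, p2), s.get(p3, p3), s.get(outgroup, outgroup), seed=seed, **kw
    )
    d, se, z = block_jackknife(abba, baba)
    return DResult(
        p1=p1,
        p2=p2,
        p3=p3,
        outgroup=outgroup,
        n_abba=float(abba.sum()),
        n_baba=float(baba.sum()),
        d=d,
        se=se,
        z=z,
        n_blocks=len(abba),
        degenerate=(se == 0.0),
    )


def _clades_from_newick(newick: str) -> list[frozenset]:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    clades = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        clades.append(leaves)
        if not node.is_leaf() and len(node.child_nodes()) > 2:
            raise ValueError("species tree must be fully resolved (binary)")
    return clades


def consistent_trios(species_tree: str, outgroup: str) -> list[tuple[str, str, str]]:
    """Enumerate (P1, P2, P3) trios consistent with a rooted species tree.

    A trio is consistent when the MRCA of (P1, P2) is a strict descendant of
    the MRCA of the three taxa, i.e. (P1, P2) form a cherry or nested pair
    relative to P3.  P1/P2 order within the pair is alphabetical.
    """
    clades = _clades_from_newick(species_tree)
    taxa = sorted(max(clades, key=len))
    if outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not on the species tree")
    ingroup = [t for t in taxa if t != outgroup]

    def mrca(ts: set) -> frozenset:
        return min((c for c in clades if ts <= c), key=len)

    trios = []
    for i, a in enumerate(ingroup):
        for b in ingroup[i + 1 :]:
            for c in ingroup:
                if c in (a, b):
                    continue
                if len(mrca({a, b})) < len(mrca({a, b, c})):
                    trios.append((a, b, c))
    # drop duplicate (pair, P3) entries arising from symmetric pair order
    seen, out = set(), []
    for a, b, c in trios:
        key = (frozenset((a, b)), c)
        if key not in seen:
            seen.add(key)
            out.append((a, b, c))
    return out


def dstat_scan(
    g: GenotypeTable,
    species_tree: str,
    outgroup: str,
    sample_map: dict[str, str] | None = None,
    seed: int = 1,
    **kwargs,
) -> list[DResult]:
    """One :class:`DResult` per species-tree-consistent trio.

    ``species_tree`` is rooted newick over species names; ``sample_map``
    translates species to sample ids in the genotype table (identity by
    default).
    """
    return [
        _trio_result(g, p1, p2, p3, outgroup, sample_map, seed, **kwargs)
        for p1, p2, p3 in consistent_trios(species_tree, outgroup)
    ]


def dstat_table(results: list[DResult]) -> str:
    """Tab-separated table of D results (trio, counts, D, SE, Z, blocks)."""
    lines = ["arrangement\tnABBA\tnBABA\tD\tSE\tZ\tn_blocks\tsignificant"]
    for r in results:
        lines.append(
            f"{r.arrangement}\t{r.n_abba:.1f}\t{r.n_baba:.1f}\t{r.d:.4f}\t"
            f"{r.se:.4f}\t{r.z:.2f}\t{r.n_blocks}\t{r.significant}"
        )
    return "\n".join(lines) + "\n"
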