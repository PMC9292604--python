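"""Windowed diversity statistics and a distance-based strict-clock dating
surrogate.

Heterozygosity is reported both per window length (the headline figure,
matching the convention of windowed VCF tools) and per callable bp.  Species
divergence dating uses UPGMA on Jukes-Cantor-corrected distances with a
single calibrated node - a deliberately simple strict-clock surrogate whose
purpose is directional comparisons (e.g. nuclear vs mitochondrial node ages),
not posterior intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core import CallableMask, GenotypeTable, Window, derive_seed

__all__ = [
    "WindowStat",
    "GenerationTimeParams",
    "DatedTree",
    "windowed_heterozygosity",
    "tstv_ratio",
    "TsTvUndefinedError",
    "ibs_distance_matrix",
    "generation_time",
    "jc_distance",
    "jc_correct",
    "upgma_calibrated_ages",
    "pairwise_divergence_matrix",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class WindowStat:
    window: Window
    value: float  # per window-length
    value_callable: float  # per callable bp (nan if window fully masked)
    n_used: int


@dataclass(frozen=True)
class GenerationTimeParams:
    age_to_maturity: float  # years
    reproductive_longevity: float  # years

    def __post_init__(self):
        if self.age_to_maturity < 0 or self.reproductive_longevity < 0:
            raise ValueError("generation-time inputs must be non-negative")


def generation_time(p: GenerationTimeParams) -> float:
    """Generation time in years: age to maturity plus half the reproductive
    longevity."""
    return p.age_to_maturity + 0.5 * p.reproductive_longevity


def windowed_heterozygosity(
    g: GenotypeTable,
    mask: CallableMask,
    windows: list[Window],
    sample: str,
    min_depth: int = 5,
) -> list[WindowStat]:
    """Count heterozygous genotypes of one diploid per window.

    Sites contribute only when called (both alleles present) with depth at
    least ``min_depth``.  Values are heterozygous sites per bp of window
    length and per bp of callable span within the window.
    """
    si = g.sample_index(sample)
    out = []
    per_scaffold: dict[str, np.ndarray] = {}
    for name, sg in g.scaffolds.items():
        gt = sg.gt[:, si, :]
        called = np.all(gt >= 0, axis=1)
        if sg.depth is not None:
            called &= sg.depth[:, si] >= min_depth
        het = called & (gt[:, 0] != gt[:, 1])
        in_mask = mask.contains(name, sg.pos - 1)
        per_scaffold[name] = sg.pos[het & in_mask] - 1  # 0-based het positions
    for w in windows:
        hp = per_scaffold.get(w.scaffold, np.empty(0, dtype=np.int64))
        n = int(np.sum((hp >= w.start) & (hp < w.end)))
        callable_bp = mask.overlap_span(w.scaffold, w.start, w.end)
        out.append(
            WindowStat(
                window=Window(w.scaffold, w.start, w.end, n_callable=callable_bp, n_sites=n, partial=w.partial),
                value=n / w.span,
                value_callable=n / callable_bp if callable_bp else float("nan"),
                n_used=n,
            )
        )
    return out


class TsTvUndefinedError(ValueError):
    pass


def tstv_ratio(g: GenotypeTable) -> float:
    """Transition/transversion ratio over all variant sites.

    Transitions are A<->G and C<->T.  Raises :class:`TsTvUndefinedError`
    when the table contains no transversion.
    """
    n_ts = n_tv = 0
    for sg in g.scaffolds.values():
        for r, a in zip(sg.ref, sg.alt):
            if frozenset((r, a)) in _TRANSITIONS:
                n_ts += 1
            else:
                n_tv += 1
    if n_tv == 0:
        raise TsTvUndefinedError("no transversions observed; Ts/Tv undefined")
    return n_ts / n_tv


def ibs_distance_matrix(g: GenotypeTable, seed: int = 1) -> np.ndarray:
    """Pairwise identity-by-state distance using per-sample consensus alleles.

    Each diploid is reduced per site to its majority allele; heterozygous
    sites are ties broken by a seeded fair coin.  Distance is the proportion
    of co-called consensus sites that differ.  Sites absent from the table
    are monomorphic and contribute no difference (the matrix is relative).
    """
    n = len(g.samples)
    if n < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(derive_seed(seed, "ibs"))
    cons_all, called_all = [], []
    for sg in g.scaffolds.values():
        gt = sg.gt
        called = np.all(gt >= 0, axis=2)
        alt_count = np.where(called, gt.sum(axis=2), 0)
        if g.ploidy == 1:
            cons = alt_count
        else:
            coin = rng.integers(0, 2, size=alt_count.shape)
            cons = np.where(alt_count == 1, coin, (alt_count > 1).astype(np.int64))
        cons_all.append(cons)
        called_all.append(called)
    cons = np.concatenate(cons_all) if cons_all else np.zeros((0, n), dtype=int)
    called = np.concatenate(called_all) if called_all else np.zeros((0, n), dtype=bool)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no co-called sites for pair ({i}, {j})")
            d = np.mean(cons[both, i] != cons[both, j])
            dist[i, j] = dist[j, i] = d
    return dist


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance from a raw mismatch fraction p."""
    if p < 0:
        raise ValueError("negative mismatch fraction")
    if p >= 0.75:
        raise ValueError("mismatch fraction at or beyond JC saturation (p >= 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_distance(a, b) -> float:
    """JC-corrected substitutions/site between two equal-length sequences."""
    a = np.asarray(list(a) if isinstance(a, str) else a)
    b = np.asarray(list(b) if isinstance(b, str) else b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    if a.size == 0:
        raise ValueError("empty sequences")
    return jc_correct(float(np.mean(a != b)))


def pairwise_divergence_matrix(
    g: GenotypeTable, haplotype: int = 0, total_length: int | None = None, correct: bool = True
) -> np.ndarray:
    """JC-corrected per-site divergence between one haplotype per sample.

    Mismatch fractions are computed over ``total_length`` sites (default: the
    summed scaffold lengths), treating positions absent from the table as
    identical across samples.
    """
    n = len(g.samples)
    L = total_length or sum(g.scaffold_lengths.values())
    diff = np.zeros((n, n))
    for sg in g.scaffolds.values():
        h = sg.gt[:, :, min(haplotype, sg.gt.shape[2] - 1)]
        for i in range(n):
            for j in range(i + 1, n):
                d = int(np.sum((h[:, i] >= 0) & (h[:, j] >= 0) & (h[:, i] != h[:, j])))
                diff[i, j] += d
                diff[j, i] += d
    p = diff / L
    if not correct:
        return p
    out = np.zeros_like(p)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = jc_correct(p[i, j])
    return out


class CalibrationError(ValueError):
    pass


@dataclass
class DatedTree:
    """Ultrametric UPGMA tree with node ages linearly scaled to a calibration."""

    labels: list[str]
    children: list[tuple[int, int]]  # internal nodes; indices into labels+nodes
    heights_ma: list[float]  # per internal node, in Ma
    calibration: tuple[frozenset, float]

    def _leafsets(self) -> list[frozenset]:
        n = len(self.labels)
        sets = [frozenset([l]) for l in self.labels]
        for a, b in self.children:
            sets.append(sets[a] | sets[b])
        return sets[n:]

    def age(self, taxa) -> float:
        """Age in Ma of the node whose clade is exactly ``taxa``."""
        target = frozenset(taxa)
        for ls, h in zip(self._leafsets(), self.heights_ma):
            if ls == target:
                return h
        raise CalibrationError(f"no node with clade {sorted(target)}")

    @property
    def root_age(self) -> float:
        return max(self.heights_ma)

    def newick(self) -> str:
        n = len(self.labels)
        heights = [0.0] * n + list(self.heights_ma)

        def fmt(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b = self.children[i - n]
            bl_a = heights[i] - heights[a]
            bl_b = heights[i] - heights[b]
            return f"({fmt(a)}:{bl_a:.6f},{fmt(b)}:{bl_b:.6f})"

        return fmt(n + len(self.children) - 1) + ";"


def upgma_calibrated_ages(
    dist: np.ndarray, labels: list[str], calibration: tuple, age_ma: float
) -> DatedTree:
    """UPGMA tree with all node heights scaled so the calibration clade's age
    equals ``age_ma``.

    Raises :class:`CalibrationError` when the calibration clade is not a node
    of the UPGMA tree (no silent rescaling to a different node).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) or np.any(dist < 0):
        raise ValueError("distance matrix must be square, symmetric, non-negative")
    iu = np.triu_indices(n, 1)
    Z = linkage(dist[iu], method="average")
    children = [(int(a), int(b)) for a, b, *_ in Z]
    heights = [h / 2.0 for _, _, h, _ in Z]  # cophenetic distance -> height

    sets = [frozenset([l]) for l in labels]
    for a, b in children:
        sets.append(sets[a] | sets[b])
    target = frozenset(calibration)
    cal_height = None
    for i, h in enumerate(heights):
        if sets[n + i] == target:
            cal_height = h
            break
    if cal_height is None:
        raise CalibrationError(f"calibration clade {sorted(target)} not recovered by UPGMA")
    if cal_height <= 0:
        raise CalibrationError("calibration node has zero height; cannot scale")
    scale = age_ma / cal_height
    return DatedTree(
        labels=list(labels),
        children=children,
        heights_ma=[h * scale for h in heights],
        calibration=(target, age_ma),
    )
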