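"""Core in-memory containers shared across the pipeline.

Coordinate conventions, stated once and used everywhere:

* VCF / :class:`GenotypeTable` positions are 1-based inclusive.
* BED / :class:`CallableMask` / :class:`Window` intervals are 0-based
  half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScaffoldGenotypes",
    "GenotypeTable",
    "CallableMask",
    "Window",
    "derive_seed",
]


def derive_seed(seed: int, *tags) -> int:
    """Derive a deterministic child seed in ``[1, 2^31)`` from a master seed.

    Tags (strings or ints) identify the consuming stage so that independent
    stages never share a stream.
    """
    import zlib

    h = zlib.crc32(repr((int(seed),) + tuple(tags)).encode())
    return (h % (2**31 - 2)) + 1


@dataclass
class ScaffoldGenotypes:
    """Variant sites on one scaffold for all samples.

    ``gt`` has shape ``(n_sites, n_samples, ploidy)`` with allele indices
    (0 = REF, 1 = ALT, -1 = missing).  ``pos`` is 1-based and strictly
    increasing.  All sites are biallelic SNPs.
    """

    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray  # unicode length-1
    alt: np.ndarray
    gt: np.ndarray  # int8 (n_sites, n_samples, ploidy)
    depth: np.ndarray | None = None  # int32 (n_sites, n_samples)
    qual: np.ndarray | None = None  # float64 per-site

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.pos.size and not np.all(np.diff(self.pos) > 0):
            raise ValueError("site positions must be strictly increasing")
        if self.gt.ndim != 3:
            raise ValueError("gt must be (n_sites, n_samples, ploidy)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


@dataclass
class GenotypeTable:
    """Biallelic haplotype matrix over scaffolds; one entry per scaffold.

    ``ploidy`` is 2 for nuclear data, 1 for the mito-surrogate locus.
    """

    samples: list[str]
    scaffolds: dict[str, ScaffoldGenotypes]
    scaffold_lengths: dict[str, int]
    ploidy: int = 2
    phased: bool = True

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table") from None

    @property
    def n_sites(self) -> int:
        return sum(s.n_sites for s in self.scaffolds.values())

    def subset_sites(self, keep: dict[str, np.ndarray]) -> "GenotypeTable":
        """Return a new table keeping, per scaffold, the boolean-masked sites."""
        new = {}
        for name, sg in self.scaffolds.items():
            m = keep[name]
            new[name] = ScaffoldGenotypes(
                pos=sg.pos[m],
                ref=sg.ref[m],
                alt=sg.alt[m],
                gt=sg.gt[m],
                depth=None if sg.depth is None else sg.depth[m],
                qual=None if sg.qual is None else sg.qual[m],
            )
        return replace(self, scaffolds=new)


def _validate_intervals(iv: np.ndarray) -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if iv.size:
        if np.any(iv[:, 0] >= iv[:, 1]):
            raise ValueError("intervals must satisfy start < end")
        if np.any(np.diff(iv[:, 0]) < 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("intervals must be sorted and non-overlapping")
    return iv


@dataclass
class CallableMask:
    """Sorted, non-overlapping half-open callable intervals per scaffold."""

    intervals: dict[str, np.ndarray]  # name -> (k, 2) int64, 0-based half-open

    def __post_init__(self):
        self.intervals = {k: _validate_intervals(v) for k, v in self.intervals.items()}

    @classmethod
    def full(cls, scaffold_lengths: dict[str, int]) -> "CallableMask":
        return cls({n: np.array([[0, L]]) for n, L in scaffold_lengths.items()})

    def span(self, scaffold: str | None = None) -> int:
        if scaffold is not None:
            iv = self.intervals.get(scaffold)
            return 0 if iv is None or iv.size == 0 else int(np.sum(iv[:, 1] - iv[:, 0]))
        return sum(self.span(s) for s in self.intervals)

    def contains(self, scaffold: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions in the mask."""
        iv = self.intervals.get(scaffold)
        pos0 = np.asarray(pos0, dtype=np.int64)
        if iv is None or iv.size == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < iv[idx[ok], 1]
        return out

    def overlap_span(self, scaffold: str, start: int, end: int) -> int:
        """Callable bp within [start, end)."""
        iv = self.intervals.get(scaffold)
        if iv is None or iv.size == 0:
            return 0
        lo = np.maximum(iv[:, 0], start)
        hi = np.minimum(iv[:, 1], end)
        return int(np.sum(np.maximum(hi - lo, 0)))

    def copy(self) -> "CallableMask":
        return CallableMask({k: v.copy() for k, v in self.intervals.items()})


@dataclass(frozen=True)
class Window:
    """One genomic window, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    n_callable: int = 0
    n_sites: int = 0
    partial: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.n_callable > self.end - self.start:
            raise ValueError("n_callable exceeds window span")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)
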