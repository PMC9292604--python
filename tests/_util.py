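"""Shared helpers for building small in-memory genotype tables in tests."""

import numpy as np

from chelonia.core import GenotypeTable, ScaffoldGenotypes


def make_table(pos, gt, ref=None, alt=None, samples=None, length=1_000_000, depth=None, qual=None):
    """One-scaffold ('s') table from explicit positions and genotype array."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape[0], gt.shape[1]
    sg = ScaffoldGenotypes(
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype="U1"),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype="U1"),
        gt=gt,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        qual=None if qual is None else np.asarray(qual, dtype=float),
    )
    return GenotypeTable(
        samples=samples or [f"sm{i}" for i in range(n_samples)],
        scaffolds={"s": sg},
        scaffold_lengths={"s": length},
        ploidy=gt.shape[2],
        phased=True,
    )
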