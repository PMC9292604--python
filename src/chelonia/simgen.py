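"""Synthetic multi-species genomes under isolation-with-migration demographies.

This module is the ground-truth side of the pipeline: it simulates phased
diploid genomes for several species under a user-specified species tree with
post-split migration epochs, plus a haploid non-recombining mito-surrogate
locus, and emits the simulation truth (split times, gene-flow cessation
times) alongside.  Every downstream statistic in the package can therefore be
checked against a known history.

The coalescent-with-recombination engine is msprime; this module owns the
demographic-model validation, the genome layout, seeding, truth bookkeeping
and the conversion to the package's in-memory containers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import msprime
import numpy as np

from .core import CallableMask, GenotypeTable, ScaffoldGenotypes, derive_seed

__all__ = [
    "Split",
    "MigrationEpoch",
    "DemographicModel",
    "GenomeLayout",
    "TruthRecord",
    "SimResult",
    "build_demography",
    "ma_to_generations",
    "simulate_genotypes",
    "degrade_mask",
    "unphase",
    "turtle_like_model",
]

#: mutation rate per site per generation estimated for reptile genomes,
#: used as the package-wide default
DEFAULT_MU = 7.9e-9

#: recombination rate default; slightly below the mutation rate, as in
#: low-recombination reptile genome maps.  Keeps linkage blocks large enough
#: that megabase jackknife blocks are effectively independent at desk scale.
DEFAULT_R = 5.0e-9

#: transition/transversion bias of the HKY mutation model; kappa/2 is the
#: expected Ts/Tv ratio at equal base frequencies, so 4.3 targets ~2.15,
#: inside the 2.1-2.2 band typical of whole-genome animal data
DEFAULT_KAPPA = 4.3


def ma_to_generations(age_ma: float, gen_time_years: float) -> float:
    """Convert an age in millions of years to generations."""
    return age_ma * 1e6 / gen_time_years


@dataclass(frozen=True)
class Split:
    time: float  # generations before present
    derived: tuple[str, str]
    ancestral: str
    ne: float  # diploid Ne of the ancestral population


@dataclass(frozen=True)
class MigrationEpoch:
    """Gene flow between two populations over [start, end] generations ago.

    ``start`` is the more recent bound (the cessation time of gene flow),
    ``end`` the older bound.  ``direction`` is in forward time:
    ``"both"`` (symmetric), ``"AtoB"`` or ``"BtoA"`` with A, B the pair order.
    """

    pair: tuple[str, str]
    rate: float  # per-lineage per-generation migration probability
    start: float
    end: float
    direction: str = "both"

    def __post_init__(self):
        if self.direction not in ("both", "AtoB", "BtoA"):
            raise ValueError(f"unknown migration direction {self.direction!r}")


@dataclass
class DemographicModel:
    """Species tree with split times, per-population Ne and migration epochs.

    Times are in generations before present and increase toward the past.
    """

    populations: list[tuple[str, float]]
    splits: list[Split] = field(default_factory=list)
    migration_epochs: list[MigrationEpoch] = field(default_factory=list)
    mu: float = DEFAULT_MU
    r: float = DEFAULT_R
    generation_time_years: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def _lifespans(self) -> dict[str, tuple[float, float]]:
        """Map population -> (birth time, death time), death=inf if extant root."""
        spans = {name: (0.0, np.inf) for name, _ in self.populations}
        for s in sorted(self.splits, key=lambda s: s.time):
            for child in s.derived:
                if child not in spans:
                    raise ValueError(f"split references unknown population {child!r}")
                birth, death = spans[child]
                if not np.isinf(death):
                    raise ValueError(f"population {child!r} merged twice")
                if s.time <= birth:
                    raise ValueError("split times must increase toward the past")
                spans[child] = (birth, s.time)
            if s.ancestral in spans and not np.isinf(spans[s.ancestral][1]):
                raise ValueError(f"ancestral population {s.ancestral!r} reused after merge")
            spans.setdefault(s.ancestral, (s.time, np.inf))
        return spans

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("model must name at least one population")
        names = [n for n, _ in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for n, ne in self.populations:
            if ne <= 0:
                raise ValueError(f"non-positive Ne for population {n!r}")
        for s in self.splits:
            if s.time <= 0 or s.ne <= 0:
                raise ValueError("split time and ancestral Ne must be positive")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be non-negative")
        spans = self._lifespans()
        for ep in self.migration_epochs:
            if not (0 <= ep.start < ep.end):
                raise ValueError("epoch requires 0 <= start < end")
            if ep.rate < 0:
                raise ValueError("negative migration rate")
            for p in ep.pair:
                if p not in spans:
                    raise ValueError(f"migration epoch references unknown population {p!r}")
                birth, death = spans[p]
                if ep.start < birth or ep.end > death:
                    raise ValueError(
                        f"migration epoch on {ep.pair} spans [{ep.start}, {ep.end}] "
                        f"outside the lifetime [{birth}, {death}] of {p!r}"
                    )

    # -- derived truth ----------------------------------------------------
    def divergence_time(self, a: str, b: str) -> float:
        """Generations before present at which a and b first share a population."""
        comp = {n: n for n, _ in self.populations}
        for s in sorted(self.splits, key=lambda s: s.time):
            merged = {c for c, root in comp.items() if root in (*s.derived, s.ancestral)}
            for c in merged:
                comp[c] = s.ancestral
            comp[s.ancestral] = s.ancestral
            if comp.get(a) == comp.get(b):
                return s.time
        raise ValueError(f"populations {a!r} and {b!r} never merge")

    def cessation_time(self, a: str, b: str) -> float:
        """Most recent time gene flow occurred between a and b.

        Defined by migration epochs naming the pair directly; equals the
        divergence time when the pair has no post-split migration.
        """
        t_div = self.divergence_time(a, b)
        starts = [ep.start for ep in self.migration_epochs if set(ep.pair) == {a, b}]
        t = min(starts) if starts else t_div
        if t > t_div:
            raise ValueError("gene-flow cessation cannot predate the split")
        return t

    # -- msprime conversion ----------------------------------------------
    def to_msprime(self, ne_scale: float = 1.0, migration: bool = True) -> msprime.Demography:
        dem = msprime.Demography()
        for name, ne in self.populations:
            dem.add_population(name=name, initial_size=ne * ne_scale)
        for s in sorted(self.splits, key=lambda s: s.time):
            dem.add_population(name=s.ancestral, initial_size=s.ne * ne_scale)
            dem.add_population_split(time=s.time, derived=list(s.derived), ancestral=s.ancestral)
        if migration:
            for ep in self.migration_epochs:
                a, b = ep.pair
                # forward-time donor X -> recipient Y means lineages sampled in Y
                # trace back into X: backward rate is set on (source=Y, dest=X)
                backward = []
                if ep.direction in ("both", "AtoB"):
                    backward.append((b, a))
                if ep.direction in ("both", "BtoA"):
                    backward.append((a, b))
                for src, dst in backward:
                    dem.add_migration_rate_change(time=ep.start, rate=ep.rate, source=src, dest=dst)
                    dem.add_migration_rate_change(time=ep.end, rate=0.0, source=src, dest=dst)
        dem.sort_events()
        return dem

    def to_dict(self) -> dict:
        return {
            "populations": [[n, ne] for n, ne in self.populations],
            "splits": [
                {"time": s.time, "derived": list(s.derived), "ancestral": s.ancestral, "ne": s.ne}
                for s in self.splits
            ],
            "migration_epochs": [
                {
                    "pair": list(ep.pair),
                    "rate": ep.rate,
                    "start": ep.start,
                    "end": ep.end,
                    "direction": ep.direction,
                }
                for ep in self.migration_epochs
            ],
            "mu": self.mu,
            "r": self.r,
            "generation_time_years": dict(self.generation_time_years),
        }


@dataclass(frozen=True)
class GenomeLayout:
    """Scaffold names/lengths plus the mito-surrogate locus configuration."""

    scaffolds: tuple[tuple[str, int], ...]
    mito_length: int = 16_700
    mito_ne_scale: float = 0.25
    mito_migration: bool = True

    def __post_init__(self):
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        if any(L <= 0 for _, L in self.scaffolds) or self.mito_length <= 0:
            raise ValueError("scaffold lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(L for _, L in self.scaffolds)

    @classmethod
    def default(cls, n_scaffolds: int = 4, scaffold_length: int = 5_000_000) -> "GenomeLayout":
        return cls(tuple((f"scaffold_{i + 1}", scaffold_length) for i in range(n_scaffolds)))


@dataclass
class TruthRecord:
    """Echo of the simulated history for downstream verification."""

    model: dict
    pair_divergence: dict[str, float]  # "A|B" -> generations
    pair_cessation: dict[str, float]
    seed: int

    def __post_init__(self):
        for key, t_div in self.pair_divergence.items():
            if self.pair_cessation.get(key, t_div) > t_div:
                raise ValueError(f"cessation after split for pair {key}")

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "model": self.model,
                "pair_divergence": self.pair_divergence,
                "pair_cessation": self.pair_cessation,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class SimResult:
    """Bundle of simulate_genotypes outputs; unpacks as (genotypes, mask, truth)."""

    genotypes: GenotypeTable
    mask: CallableMask
    truth: TruthRecord
    mito: GenotypeTable | None = None

    def __iter__(self):
        return iter((self.genotypes, self.mask, self.truth))


def build_demography(config) -> DemographicModel:
    """Build and validate a :class:`DemographicModel` from structured config.

    ``config`` is a mapping (or YAML text parsing to one) with keys
    ``populations`` ([{name, ne}]), ``splits`` ([{time | time_ma, derived,
    ancestral, ne}]), ``migration_epochs``, ``mu``, ``r`` and
    ``generation_time_years``.  Split ages given as ``time_ma`` are converted
    with the split's own ``gen_time`` entry if present, else the mean of the
    model's generation times.
    """
    if isinstance(config, str):
        import yaml

        config = yaml.safe_load(config)
    gen_times = dict(config.get("generation_time_years", {}))
    mean_gt = float(np.mean(list(gen_times.values()))) if gen_times else None

    pops = [(p["name"], float(p["ne"])) for p in config["populations"]]
    splits = []
    for s in config.get("splits", []):
        if "time" in s:
            t = float(s["time"])
        else:
            gt = float(s.get("gen_time", mean_gt or 0.0))
            if gt <= 0:
                raise ValueError("time_ma split needs gen_time or generation_time_years")
            t = ma_to_generations(float(s["time_ma"]), gt)
        splits.append(Split(time=t, derived=tuple(s["derived"]), ancestral=s["ancestral"], ne=float(s["ne"])))
    epochs = [
        MigrationEpoch(
            pair=tuple(ep["pair"]),
            rate=float(ep["rate"]),
            start=float(ep["start"]),
            end=float(ep["end"]),
            direction=ep.get("direction", "both"),
        )
        for ep in config.get("migration_epochs", [])
    ]
    return DemographicModel(
        populations=pops,
        splits=splits,
        migration_epochs=epochs,
        mu=float(config.get("mu", DEFAULT_MU)),
        r=float(config.get("r", DEFAULT_R)),
        generation_time_years=gen_times,
    )


def _table_from_ts(ts, samples: list[str], ploidy: int, name: str, length: int) -> ScaffoldGenotypes:
    pos, ref, alt, gts = [], [], [], []
    for var in ts.variants():
        alleles = var.alleles
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            continue  # biallelic SNPs only
        p = int(np.floor(var.site.position)) + 1  # 1-based
        if pos and p <= pos[-1]:
            continue  # collapse rare same-bp collisions after flooring
        pos.append(p)
        ref.append(alleles[0])
        alt.append(alleles[1])
        gts.append(var.genotypes.astype(np.int8))
    n_ind = len(samples)
    if pos:
        gt = np.stack(gts).reshape(len(pos), n_ind, ploidy)
    else:
        gt = np.zeros((0, n_ind, ploidy), dtype=np.int8)
    return ScaffoldGenotypes(
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype="U1"),
        alt=np.array(alt, dtype="U1"),
        gt=gt,
    )


def simulate_genotypes(
    model: DemographicModel,
    layout: GenomeLayout,
    n_diploids_per_pop: int = 1,
    seed: int = 1,
    depth: int = 20,
    site_qual: float = 100.0,
    kappa: float = DEFAULT_KAPPA,
    include_mito: bool = True,
    record_trees: bool = False,
) -> SimResult:
    """Simulate phased diploid genomes plus the haploid mito-surrogate.

    Returns a :class:`SimResult` (unpackable as ``genotypes, mask, truth``)
    whose mask is initially fully callable; degrade it with
    :func:`degrade_mask` to emulate mappability/repeat gaps.  Same seed,
    same inputs -> bit-identical output.
    """
    if layout.total_length <= 0:
        raise ValueError("zero-length genome")
    leaf_pops = [n for n, _ in model.populations]
    samples = [f"{p}_{i}" for p in leaf_pops for i in range(n_diploids_per_pop)]
    mut_model = msprime.HKY(kappa=kappa)

    dem = model.to_msprime()
    scaffolds: dict[str, ScaffoldGenotypes] = {}
    tree_seqs = {}
    for name, length in layout.scaffolds:
        anc_seed = derive_seed(seed, "ancestry", name)
        mut_seed = derive_seed(seed, "mutations", name)
        ts = msprime.sim_ancestry(
            samples={p: n_diploids_per_pop for p in leaf_pops},
            demography=dem,
            sequence_length=length,
            recombination_rate=model.r,
            ploidy=2,
            random_seed=anc_seed,
        )
        ts = msprime.sim_mutations(ts, rate=model.mu, model=mut_model, random_seed=mut_seed)
        scaffolds[name] = _table_from_ts(ts, samples, 2, name, length)
        if record_trees:
            tree_seqs[name] = ts

    lengths = dict(layout.scaffolds)
    table = GenotypeTable(samples=samples, scaffolds=scaffolds, scaffold_lengths=lengths, ploidy=2, phased=True)
    for sg in table.scaffolds.values():
        n = sg.n_sites
        sg.depth = np.full((n, len(samples)), depth, dtype=np.int32)
        sg.qual = np.full(n, site_qual)

    mito = None
    if include_mito:
        dem_m = model.to_msprime(ne_scale=layout.mito_ne_scale, migration=layout.mito_migration)
        ts = msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(n_diploids_per_pop, population=p, ploidy=1) for p in leaf_pops
            ],
            demography=dem_m,
            sequence_length=layout.mito_length,
            recombination_rate=0.0,
            ploidy=2,
            random_seed=derive_seed(seed, "ancestry", "mito"),
        )
        ts = msprime.sim_mutations(
            ts, rate=model.mu, model=mut_model, random_seed=derive_seed(seed, "mutations", "mito")
        )
        mito = GenotypeTable(
            samples=samples,
            scaffolds={"mito": _table_from_ts(ts, samples, 1, "mito", layout.mito_length)},
            scaffold_lengths={"mito": layout.mito_length},
            ploidy=1,
            phased=True,
        )

    pairs_div, pairs_gf = {}, {}
    for i, a in enumerate(leaf_pops):
        for b in leaf_pops[i + 1 :]:
            key = f"{a}|{b}"
            try:
                pairs_div[key] = model.divergence_time(a, b)
                pairs_gf[key] = model.cessation_time(a, b)
            except ValueError:
                pass  # disconnected populations carry no pairwise truth
    truth = TruthRecord(model=model.to_dict(), pair_divergence=pairs_div, pair_cessation=pairs_gf, seed=seed)
    mask = CallableMask.full(lengths)
    res = SimResult(genotypes=table, mask=mask, truth=truth, mito=mito)
    if record_trees:
        res.tree_seqs = tree_seqs
    return res


def degrade_mask(
    mask: CallableMask, gap_fraction: float, seed: int, tile: int = 200
) -> CallableMask:
    """Remove ~``gap_fraction`` of the callable span as random gaps.

    The mask is tiled into ``tile``-bp pieces and whole tiles are deleted
    uniformly at random until the removed span reaches the target, so the
    realized gap fraction is within one tile of exact (far inside the +-1%
    contract for desk-scale masks).
    """
    if not (0 <= gap_fraction < 1):
        raise ValueError("gap_fraction must be in [0, 1)")
    if gap_fraction == 0:
        return mask.copy()
    rng = np.random.default_rng(derive_seed(seed, "degrade_mask"))
    out = {}
    for name, iv in mask.intervals.items():
        tiles = []
        for start, end in iv:
            edges = np.arange(start, end, tile)
            tiles.extend((int(e), int(min(e + tile, end))) for e in edges)
        tiles = np.array(tiles, dtype=np.int64).reshape(-1, 2)
        span = int(np.sum(tiles[:, 1] - tiles[:, 0]))
        target = gap_fraction * span
        order = rng.permutation(len(tiles))
        removed, drop = 0.0, np.zeros(len(tiles), dtype=bool)
        for idx in order:
            if removed >= target:
                break
            drop[idx] = True
            removed += tiles[idx, 1] - tiles[idx, 0]
        keep = tiles[~drop]
        # merge adjacent surviving tiles back into maximal intervals
        merged = []
        for s, e in keep:
            if merged and merged[-1][1] == s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out[name] = np.array(merged, dtype=np.int64).reshape(-1, 2)
    return CallableMask(out)


def unphase(g: GenotypeTable, seed: int) -> GenotypeTable:
    """Randomize within-individual allele order per site; genotypes preserved."""
    if not g.phased:
        raise ValueError("input table is already unphased")
    rng = np.random.default_rng(derive_seed(seed, "unphase"))
    new = {}
    for name, sg in g.scaffolds.items():
        gt = sg.gt.copy()
        if gt.shape[2] == 2:
            flip = rng.random(gt.shape[:2]) < 0.5
            a, b = gt[..., 0].copy(), gt[..., 1].copy()
            gt[..., 0] = np.where(flip, b, a)
            gt[..., 1] = np.where(flip, a, b)
        new[name] = ScaffoldGenotypes(pos=sg.pos, ref=sg.ref, alt=sg.alt, gt=gt, depth=sg.depth, qual=sg.qual)
    return GenotypeTable(
        samples=list(g.samples),
        scaffolds=new,
        scaffold_lengths=dict(g.scaffold_lengths),
        ploidy=g.ploidy,
        phased=False,
    )


def turtle_like_model(
    ne: float = 20_000,
    t1: float = 30_000,
    t2: float = 70_000,
    t3: float = 130_000,
    t_out: float = 250_000,
    migration: list[MigrationEpoch] | None = None,
    mu: float = DEFAULT_MU,
    r: float = DEFAULT_R,
) -> DemographicModel:
    """Five-population pectinate model mirroring the sea-turtle species tree.

    Leaves (most closely related first): OL and LL (the ridley/loggerhead
    cherry), HH, GG, and DC as the deep outgroup, i.e.
    ``((((OL,LL),HH),GG),DC)``.  Desk-scale defaults: 20k diploid Ne
    everywhere and internal branches of about one coalescent unit (2Ne
    generations), which yields substantial but not overwhelming incomplete
    lineage sorting - discordant gene trees are common, yet introgression
    signals remain separable from the ILS background in a few tens of Mb.
    """
    pops = [(p, ne) for p in ("OL", "LL", "HH", "GG", "DC")]
    splits = [
        Split(time=t1, derived=("OL", "LL"), ancestral="ANC1", ne=ne),
        Split(time=t2, derived=("ANC1", "HH"), ancestral="ANC2", ne=ne),
        Split(time=t3, derived=("ANC2", "GG"), ancestral="ANC3", ne=ne),
        Split(time=t_out, derived=("ANC3", "DC"), ancestral="ROOT", ne=ne),
    ]
    return DemographicModel(
        populations=pops,
        splits=splits,
        migration_epochs=migration or [],
        mu=mu,
        r=r,
        generation_time_years={"OL": 20.5, "LL": 24.0, "HH": 26.5, "GG": 33.0, "DC": 24.0},
    )
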