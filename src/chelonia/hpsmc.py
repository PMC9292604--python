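"""hPSMC: dating the cessation of gene flow from pseudo-F1 hybrid genomes.

An artificial F1 genome built from one pseudo-haploid genome of each of two
species cannot coalesce more recently than the last genetic exchange between
them.  Its apparent effective-size trajectory therefore explodes toward the
present at times more recent than that point, while at older times it tracks
the ancestral population size (the "plateau").  Comparing the empirical
pseudo-F1 trajectory against trajectories simulated under clean splits on a
grid of divergence times brackets the time gene flow ended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CallableMask, GenotypeTable, derive_seed
from .smc import BinSequence, SmcConfig, SmcTrajectory, binarize_positions, fit_smc, scale_trajectory

__all__ = [
    "PseudoHaploid",
    "PlateauError",
    "GeneFlowBracket",
    "pseudo_haploidize",
    "make_pseudo_f1",
    "fit_pseudo_f1",
    "estimate_plateau_ne",
    "simulate_divergence_grid",
    "bracket_gene_flow_end",
]


@dataclass
class PseudoHaploid:
    """One randomly picked allele per variant position of one sample.

    Positions absent from the table are implicitly the reference allele.
    Sites failing the depth/quality thresholds are missing.
    """

    sample: str
    seed: int
    positions: dict[str, np.ndarray]  # 1-based variant positions per scaffold
    alleles: dict[str, np.ndarray]  # int8; -1 = missing
    scaffold_lengths: dict[str, int]


def pseudo_haploidize(
    g: GenotypeTable,
    sample: str,
    min_depth: int = 5,
    min_qual: float = 30.0,
    seed: int = 1,
) -> PseudoHaploid:
    """Collapse a diploid to one uniformly chosen allele per site (seeded).

    Homozygous sites keep their allele; heterozygous sites pick either allele
    with probability 1/2; sites with depth < ``min_depth`` or site quality
    < ``min_qual`` become missing.
    """
    si = g.sample_index(sample)
    rng = np.random.default_rng(derive_seed(seed, "pseudohap", sample))
    positions, alleles = {}, {}
    for name, sg in g.scaffolds.items():
        gt = sg.gt[:, si, :]
        called = np.all(gt >= 0, axis=1)
        if sg.depth is not None:
            called &= sg.depth[:, si] >= min_depth
        if sg.qual is not None:
            called &= sg.qual >= min_qual
        pick = rng.integers(0, gt.shape[1], size=len(sg.pos))
        chosen = np.take_along_axis(gt, pick[:, None], axis=1)[:, 0].astype(np.int8)
        chosen[~called] = -1
        positions[name] = sg.pos.copy()
        alleles[name] = chosen
    return PseudoHaploid(
        sample=sample,
        seed=seed,
        positions=positions,
        alleles=alleles,
        scaffold_lengths=dict(g.scaffold_lengths),
    )


def make_pseudo_f1(a: PseudoHaploid, b: PseudoHaploid) -> dict[str, np.ndarray]:
    """Heterozygous-site positions of the artificial F1 of two pseudo-haploids.

    A position is heterozygous when both genomes are called there and their
    alleles differ; positions missing in either genome are dropped.  Returns
    1-based het positions per scaffold (feed to binarization with the
    callable mask).
    """
    common = set(a.positions) & set(b.positions)
    if not common and (a.positions or b.positions):
        raise ValueError("pseudo-haploids share no scaffolds")
    het: dict[str, np.ndarray] = {}
    for name in sorted(common):
        pa, pb = a.positions[name], b.positions[name]
        ia = {int(p): i for i, p in enumerate(pa)}
        out = []
        for i_b, p in enumerate(pb):
            i_a = ia.get(int(p))
            al_b = b.alleles[name][i_b]
            al_a = a.alleles[name][i_a] if i_a is not None else (0 if al_b >= 0 else -1)
            if al_a < 0 or al_b < 0:
                continue
            if al_a != al_b:
                out.append(int(p))
        # positions present only in a: b is implicitly reference (allele 0)
        pb_set = set(int(p) for p in pb)
        for i_a, p in enumerate(pa):
            if int(p) in pb_set:
                continue
            al_a = a.alleles[name][i_a]
            if al_a > 0:
                out.append(int(p))
        het[name] = np.array(sorted(out), dtype=np.int64)
    return het


def fit_pseudo_f1(
    het_positions: dict[str, np.ndarray],
    mask: CallableMask,
    scaffold_lengths: dict[str, int],
    cfg: SmcConfig | None = None,
) -> SmcTrajectory:
    """Binarize an F1 het track (default 10-bp bins) and fit the SMC HMM."""
    cfg = cfg or SmcConfig(bin_size=10)
    seqs = binarize_positions(het_positions, mask, scaffold_lengths, cfg.bin_size)
    return fit_smc(seqs, cfg)


class PlateauError(ValueError):
    pass


def estimate_plateau_ne(
    traj: SmcTrajectory, mu: float, support_mass: float = 0.995
) -> tuple[float, int | None]:
    """Pre-divergence (ancestral) Ne from the old-time flat region.

    Scanning from the oldest parameter group toward the present, the rise
    onset is the oldest group whose Ne is at least 1.5x the geometric mean of
    the three oldest groups; the plateau is the geometric mean of all groups
    older than the onset.  Groups beyond the data-supported time range
    (cumulative TMRCA prior mass under the fitted intensities above
    ``support_mass``) are excluded first: with essentially zero expected
    occupancy they retain initialization bias rather than signal.  Returns
    (plateau Ne, onset group index with 0 the most recent group; None when
    the trajectory never rises).  Raises :class:`PlateauError` when fewer
    than two groups precede the onset (monotone rise, no plateau to read).
    """
    from .smc import equilibrium_distribution

    if len(traj.groups) < 6:
        raise PlateauError("need at least 6 parameter groups")
    n0 = traj.n0(mu)
    _, lam_g = traj.group_values()
    ne = n0 / lam_g  # index 0 = most recent group
    pi = equilibrium_distribution(traj.boundaries, traj.lam)
    pi_g = np.array([pi[s].sum() for s in traj.group_slices()])
    cum = np.cumsum(pi_g)
    if cum[-1] >= support_mass:
        keep = int(np.argmax(cum >= support_mass)) + 1  # first group reaching the mass
        if keep >= 6:
            ne = ne[:keep]
    if np.all(np.diff(ne[::-1]) > 0):  # strict rise from oldest to most recent
        raise PlateauError("trajectory rises monotonically; no plateau to read")
    base = float(np.exp(np.mean(np.log(ne[-3:]))))
    onset = None
    for i in range(len(ne) - 1, -1, -1):  # oldest -> most recent
        if ne[i] >= 1.5 * base:
            onset = i
            break
    if onset is None:
        return float(np.exp(np.mean(np.log(ne)))), None
    older = ne[onset + 1 :]
    if len(older) < 2:
        raise PlateauError("trajectory rises across all old intervals; no plateau")
    return float(np.exp(np.mean(np.log(older)))), onset


def _simulate_clean_split_f1(
    ne: float,
    t_gens: float,
    genome_length: int,
    mu: float,
    r: float,
    seed: int,
    migration_rate: float = 0.0,
    migration_until_gens: float | None = None,
) -> dict[str, np.ndarray]:
    """Het positions of a pseudo-F1 from a two-population split.

    With ``migration_rate`` > 0, symmetric gene flow runs from the split
    until ``migration_until_gens`` before present (an isolation-with-
    migration history whose true gene-flow cessation is the latter)."""
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="X", initial_size=ne)
    dem.add_population(name="Y", initial_size=ne)
    dem.add_population(name="ANC", initial_size=ne)
    dem.add_population_split(time=t_gens, derived=["X", "Y"], ancestral="ANC")
    if migration_rate > 0:
        t_gf = 0.0 if migration_until_gens is None else migration_until_gens
        if t_gf >= t_gens:
            raise ValueError("gene-flow cessation must be more recent than the split")
        dem.add_symmetric_migration_rate_change(
            time=t_gf, populations=["X", "Y"], rate=migration_rate
        )
        dem.sort_events()
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(1, population=p, ploidy=1) for p in ("X", "Y")],
        demography=dem,
        sequence_length=genome_length,
        recombination_rate=r,
        ploidy=2,
        random_seed=derive_seed(seed, "grid_anc"),
    )
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=derive_seed(seed, "grid_mut"))
    het = []
    for var in ts.variants():
        gg = var.genotypes
        if gg[0] != gg[1]:
            het.append(int(np.floor(var.site.position)) + 1)
    return {"sim": np.unique(np.array(het, dtype=np.int64))}


def simulate_divergence_grid(
    plateau_ne: float,
    t_range_ma: tuple[float, float],
    mu: float,
    gen_time: float,
    genome_length: int = 5_000_000,
    step_ma: float = 1.0,
    r: float = 5e-9,
    cfg: SmcConfig | None = None,
    seed: int = 1,
) -> list[tuple[float, SmcTrajectory]]:
    """Pseudo-F1 trajectories for clean splits on a divergence-time grid.

    For each grid time T (Ma, inclusive ends, ``step_ma`` spacing) an
    ancestral population of size ``plateau_ne`` splits cleanly into two; one
    haploid genome per side forms the F1, which is fitted with the same
    :class:`SmcConfig` as the empirical pair.
    """
    lo, hi = t_range_ma
    if hi < lo or plateau_ne <= 0:
        raise ValueError("invalid grid range or plateau Ne")
    grid = np.arange(lo, hi + 0.5 * step_ma, step_ma)
    if len(grid) == 0:
        raise ValueError("empty grid")
    cfg = cfg or SmcConfig(bin_size=10)
    mask = CallableMask.full({"sim": genome_length})
    out = []
    for T in grid:
        t_gens = T * 1e6 / gen_time
        het = _simulate_clean_split_f1(
            plateau_ne, t_gens, genome_length, mu, r, derive_seed(seed, "grid", f"{T:.3f}")
        )
        traj = fit_pseudo_f1(het, mask, {"sim": genome_length}, cfg)
        out.append((float(T), traj))
    return out


@dataclass
class GeneFlowBracket:
    pair: tuple[str, str]
    grid_times_ma: list[float]
    lower_ma: float | None
    upper_ma: float | None
    lower_unbounded: bool
    upper_unbounded: bool
    plateau_ne: float
    window_years: tuple[float, float]
    frac_above: dict[float, float] = field(default_factory=dict)

    @property
    def midpoint_ma(self) -> float:
        lo = self.lower_ma if self.lower_ma is not None else min(self.grid_times_ma)
        hi = self.upper_ma if self.upper_ma is not None else max(self.grid_times_ma)
        return 0.5 * (lo + hi)


class BracketError(ValueError):
    pass


def _step_lookup(years: np.ndarray, left: np.ndarray, ne: np.ndarray) -> np.ndarray:
    """Piecewise-constant Ne(t) lookup; left boundaries ascending."""
    idx = np.clip(np.searchsorted(left, years, side="right") - 1, 0, len(ne) - 1)
    return ne[idx]


def bracket_gene_flow_end(
    empirical: SmcTrajectory,
    grid: list[tuple[float, SmcTrajectory]],
    plateau_ne: float,
    mu: float,
    gen_time: float,
    pair: tuple[str, str] = ("A", "B"),
    window: tuple[float, float] = (1.5, 10.0),
    decide_frac: float = 0.9,
) -> GeneFlowBracket:
    """Bracket the end of gene flow between the grid's divergence times.

    The comparison window is the span of years over which the empirical
    trajectory's Ne lies in ``window`` x plateau (the exponential-rise
    region); both curves are evaluated as step functions on a dense
    log-spaced grid of years across it.  A grid curve is "older" when its Ne
    exceeds the empirical at >= ``decide_frac`` of the points, "younger"
    when below at >= that fraction; the bracket is (largest younger T,
    smallest older T).  Classification must be monotone in T or
    :class:`BracketError` is raised.
    """
    if len(grid) < 2:
        raise BracketError("need at least 2 grid trajectories")
    emp = scale_trajectory(empirical, mu, gen_time)
    emp_left = emp.left_years.to_numpy()
    emp_right = emp.right_years.to_numpy()
    emp_ne = emp["Ne"].to_numpy()
    # The wall shoulder: scanning from the present into the past, apparent Ne
    # drops out of the divergence-driven explosion, crosses the window and
    # settles onto the plateau.  Only that contiguous run is compared; old-
    # time excursions of similar magnitude are fitting noise, not the wall.
    i = 0
    G = len(emp_ne)
    while i < G and emp_ne[i] > window[1] * plateau_ne:
        i += 1
    run = []
    while i < G and emp_ne[i] >= window[0] * plateau_ne:
        run.append(i)
        i += 1
    if not run:
        raise BracketError("empirical trajectory never crosses the comparison window")
    lo_y = max(float(emp_left[run[0]]), 1.0)
    hi_y = float(emp_right[run[-1]])
    pts = np.geomspace(lo_y, hi_y, 200)
    vals = _step_lookup(pts, emp_left, emp_ne)
    younger, older = [], []
    frac_above = {}
    for T, traj in sorted(grid, key=lambda x: x[0]):
        sc = scale_trajectory(traj, mu, gen_time)
        g_ne = _step_lookup(pts, sc.left_years.to_numpy(), sc["Ne"].to_numpy())
        fa = float(np.mean(g_ne > vals))
        frac_above[T] = fa
        if fa >= decide_frac:
            older.append(T)
        elif fa <= 1.0 - decide_frac:
            younger.append(T)
    if younger and older and max(younger) > min(older):
        raise BracketError(
            f"grid classification not monotone in T: younger {younger}, older {older}"
        )
    lower = max(younger) if younger else None
    upper = min(older) if older else None
    if lower is not None and upper is not None and lower >= upper:
        raise BracketError("degenerate bracket")
    return GeneFlowBracket(
        pair=tuple(pair),
        grid_times_ma=[T for T, _ in grid],
        lower_ma=lower,
        upper_ma=upper,
        lower_unbounded=lower is None,
        upper_unbounded=upper is None,
        plateau_ne=plateau_ne,
        window_years=(float(pts.min()), float(pts.max())),
        frac_above=frac_above,
    )
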