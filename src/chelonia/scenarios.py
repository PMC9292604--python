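"""Calibration scenarios: simulation studies with known truth.

Each function defines one frozen study condition (demography, genome size,
replicate count) and returns the measured quantities together with their
theoretical expectations.  They power both the validation test suite and the
reproduction script; sizes are desk-scale so each runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .core import CallableMask, derive_seed
from . import diversity, dstat, hpsmc, simgen, smc, topoweight

__all__ = [
    "snp_accumulation_bound",
    "dstat_calibration",
    "twisst_closed_form",
    "smc_constant_ne_recovery",
    "mito_nuclear_discordance",
    "hpsmc_bracket_study",
    "jackknife_validity",
]

MU = simgen.DEFAULT_MU
SPECIES_TREE = "((((OL,LL),HH),GG),DC);"
SAMPLE_MAP = {p: f"{p}_0" for p in ("OL", "LL", "HH", "GG", "DC")}


def snp_accumulation_bound(
    mu: float = MU,
    gen_time_years: float = 24.0,
    elapsed_years: float = 200_000.0,
    span_bp: float = 10_000.0,
) -> float:
    """Expected new SNPs per ``span_bp`` accumulated since a bottleneck.

    Heterozygous positions accrue on both chromosomes of a diploid at
    2*mu per site per generation, so the count over t years is
    2*mu*(t/g)*span.  With the package defaults this is ~1.32 SNPs per
    10 kb over 200 kyr - fewer than two, i.e. a genome retains barely any
    record of the post-bottleneck epoch.
    """
    return 2.0 * mu * (elapsed_years / gen_time_years) * span_bp


def _dstat_trio(g, seed, trio=("LL", "OL", "HH")):
    res = dstat.dstat_scan(
        g,
        SPECIES_TREE,
        "DC",
        sample_map=SAMPLE_MAP,
        seed=seed,
        block_size=1_000_000,
        min_block_sites=20,
    )
    for r in res:
        if (r.p1, r.p2, r.p3) == trio:
            return r, res
    raise AssertionError("trio missing from scan")


def dstat_calibration(
    n_reps: int = 20, genome_length: int = 10_000_000, seed: int = 1
) -> dict:
    """Null and power calibration of the D statistic.

    Null: the turtle-like species tree with no migration; incomplete lineage
    sorting alone must keep |Z| < 3.  Power: a pulse of gene flow from HH
    into OL with admixture fraction ~0.1 (the P3 -> P2 direction for the
    (LL, OL, HH) trio), which must give D > 0 with Z > 3.
    """
    lay = simgen.GenomeLayout((("s1", genome_length),))
    null_ok = 0
    null_total = 0
    power_ok = 0
    pulse = [
        simgen.MigrationEpoch(
            pair=("HH", "OL"), rate=1e-3, start=5_000, end=5_100, direction="AtoB"
        )
    ]
    z_null, z_power = [], []
    for rep in range(n_reps):
        model = simgen.turtle_like_model()
        res = simgen.simulate_genotypes(
            model, lay, seed=derive_seed(seed, "dnull", rep), include_mito=False
        )
        _, allres = _dstat_trio(res.genotypes, seed=derive_seed(seed, "dcount", rep))
        for r in allres:
            null_total += 1
            null_ok += abs(r.z) < 3
            z_null.append(r.z)

        model_m = simgen.turtle_like_model(migration=pulse)
        res_m = simgen.simulate_genotypes(
            model_m, lay, seed=derive_seed(seed, "dmig", rep), include_mito=False
        )
        r, _ = _dstat_trio(res_m.genotypes, seed=derive_seed(seed, "dcount2", rep))
        power_ok += (r.d > 0) and (r.z > 3)
        z_power.append(r.z)
    return {
        "null_frac_ok": null_ok / null_total,
        "power_frac_ok": power_ok / n_reps,
        "z_null_max_abs": float(np.max(np.abs(z_null))),
        "z_power_min": float(np.min(z_power)),
        "n_reps": n_reps,
    }


def twisst_closed_form(
    n_windows: int = 5_000, t_internal_units: float = 1.0, ne: float = 10_000, seed: int = 1
) -> dict:
    """Mean concordant topology weight vs the gene-tree frequency closed form.

    Three ingroup species with an internal branch of ``t_internal_units``
    coalescent units (2*Ne generations) and one haplotype per species: the
    species topology is matched by 1 - (2/3)exp(-t) of non-recombining
    windows, each discordant one by (1/3)exp(-t).
    """
    import dendropy
    import msprime

    t1 = 2 * ne  # (A,B) split
    t2 = t1 + t_internal_units * 2 * ne
    dem = msprime.Demography()
    for p in ("A", "B", "C", "O"):
        dem.add_population(name=p, initial_size=ne)
    dem.add_population(name="AB", initial_size=ne)
    dem.add_population(name="ABC", initial_size=ne)
    dem.add_population(name="ROOT", initial_size=ne)
    dem.add_population_split(time=t1, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=t2, derived=["AB", "C"], ancestral="ABC")
    dem.add_population_split(time=10 * t2, derived=["ABC", "O"], ancestral="ROOT")
    catalog = topoweight.enumerate_topologies(["A", "B", "C"], "O")
    concordant = catalog.index("((A,B),C)")
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(1, population=p, ploidy=1) for p in ("A", "B", "C", "O")],
        demography=dem,
        num_replicates=n_windows,
        random_seed=derive_seed(seed, "twisst"),
        ploidy=2,
    )
    relabel = {"n0": "A", "n1": "B", "n2": "C", "n3": "O"}
    total = np.zeros(len(catalog))
    smap = {p: p for p in ("A", "B", "C", "O")}
    for ts in reps:
        tree = dendropy.Tree.get(
            data=ts.first().as_newick(include_branch_lengths=False),
            schema="newick",
            preserve_underscores=True,
        )
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = relabel[leaf.taxon.label]
        total += topoweight.weight_window(tree, smap, catalog)
    mean = total / n_windows
    expected = 1.0 - (2.0 / 3.0) * np.exp(-t_internal_units)
    return {
        "concordant_mean": float(mean[concordant]),
        "expected": float(expected),
        "abs_error": float(abs(mean[concordant] - expected)),
        "discordant_means": [float(mean[i]) for i in range(len(catalog)) if i != concordant],
        "n_windows": n_windows,
    }


def smc_constant_ne_recovery(
    ne: float = 20_000, genome_length: int = 50_000_000, seed: int = 1, max_iters: int = 12
) -> dict:
    """Fit the coalescent HMM to a constant-Ne genome; report accuracy.

    The maximum relative Ne error is taken over parameter groups overlapping
    0.2-2 coalescent units, the well-constrained middle of the time grid.
    """
    half = genome_length // 2
    model = simgen.DemographicModel(populations=[("P", ne)], mu=MU, r=5e-9)
    lay = simgen.GenomeLayout((("s1", half), ("s2", genome_length - half)))
    res = simgen.simulate_genotypes(
        model, lay, seed=derive_seed(seed, "smcrec"), include_mito=False
    )
    seqs = smc.binarize(res.genotypes, "P_0", res.mask, bin_size=100)
    cfg = smc.SmcConfig(bin_size=100, max_iters=max_iters)
    traj = smc.fit_smc(seqs, cfg)
    sc = smc.scale_trajectory(traj, MU, 1.0)
    mid = sc[(sc.right_coal > 0.2) & (sc.left_coal < 2.0)]
    rel_err = np.abs(mid["Ne"].to_numpy() / ne - 1.0)
    ll = np.array(traj.loglik_trace)
    return {
        "max_rel_err": float(rel_err.max()),
        "mean_rel_err": float(rel_err.mean()),
        "ll_monotone": bool(np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))),
        "n_mid_groups": int(len(mid)),
        "theta": traj.theta,
    }


def mito_nuclear_discordance(
    n_reps: int = 20,
    ne: float = 20_000,
    t_split: float = 200_000,
    t_gf: float = 50_000,
    t_cal: float = 1_000_000,
    gen_time: float = 24.0,
    nuclear_length: int = 4_000_000,
    seed: int = 1,
) -> dict:
    """Direction of mito/nuclear divergence-date discordance under gene flow.

    Species A and B split ``t_split`` generations ago but exchange nuclear
    migrants (4*Ne*m = 4) until ``t_gf``; the mito-surrogate locus does not
    introgress.  Both matrices are dated by the UPGMA strict-clock surrogate
    calibrated at the root (the split with C).  Hybridization after
    divergence makes the nuclear (A,B) age younger than the mitochondrial
    one in nearly every replicate.
    """
    cal_ma = t_cal * gen_time / 1e6
    mig = [
        simgen.MigrationEpoch(
            pair=("A", "B"), rate=4 / (4 * ne), start=t_gf, end=t_split, direction="both"
        )
    ]
    model = simgen.DemographicModel(
        populations=[("A", ne), ("B", ne), ("C", ne)],
        splits=[
            simgen.Split(time=t_split, derived=("A", "B"), ancestral="AB", ne=ne),
            simgen.Split(time=t_cal, derived=("AB", "C"), ancestral="ABC", ne=ne),
        ],
        migration_epochs=mig,
        mu=MU,
        r=5e-9,
    )
    lay = simgen.GenomeLayout(
        (("s1", nuclear_length),), mito_length=16_700, mito_migration=False
    )
    labels = ["A", "B", "C"]
    younger = 0
    ages = []
    for rep in range(n_reps):
        res = simgen.simulate_genotypes(model, lay, seed=derive_seed(seed, "mitonuc", rep))
        d_nuc = diversity.pairwise_divergence_matrix(res.genotypes)
        d_mit = diversity.pairwise_divergence_matrix(res.mito)
        t_nuc = diversity.upgma_calibrated_ages(d_nuc, labels, set(labels), cal_ma)
        t_mit = diversity.upgma_calibrated_ages(d_mit, labels, set(labels), cal_ma)
        a_n, a_m = t_nuc.age({"A", "B"}), t_mit.age({"A", "B"})
        ages.append((a_n, a_m))
        younger += a_n < a_m
    return {
        "frac_nuclear_younger": younger / n_reps,
        "mean_nuclear_ma": float(np.mean([a for a, _ in ages])),
        "mean_mito_ma": float(np.mean([m for _, m in ages])),
        "true_split_ma": t_split * gen_time / 1e6,
        "n_reps": n_reps,
    }


HPSMC_CFG = dict(bin_size=10, pattern="2+14*2+2", t_max=15.0, max_iters=20, tol=1e-7)


def hpsmc_bracket_study(
    n_seeds: int = 10,
    plateau_ne: float = 110_000.0,
    t_split_ma: float = 12.0,
    t_gf_ma: float = 6.0,
    gen_time: float = 24.0,
    genome_length: int = 3_000_000,
    seed: int = 1,
    include_migration: bool = True,
) -> dict:
    """Bracket recovery for a clean split and displacement under gene flow.

    Clean split at ``t_split_ma`` analysed against a 10-15 Ma grid (the grid
    is simulated once, from the plateau estimated on the first replicate, and
    shared across replicates).  With symmetric migration continuing until
    ``t_gf_ma`` the bracket midpoint must move toward the cessation time.
    """
    cfg = smc.SmcConfig(**HPSMC_CFG)
    mask = CallableMask.full({"sim": genome_length})
    lengths = {"sim": genome_length}
    t_gens = t_split_ma * 1e6 / gen_time

    fits = []
    for rep in range(n_seeds):
        het = hpsmc._simulate_clean_split_f1(
            plateau_ne, t_gens, genome_length, MU, 5e-9, derive_seed(seed, "emp", rep)
        )
        fits.append(hpsmc.fit_pseudo_f1(het, mask, lengths, cfg))
    plateau0, _ = hpsmc.estimate_plateau_ne(fits[0], MU)
    grid = hpsmc.simulate_divergence_grid(
        plateau0, (10.0, 15.0), MU, gen_time,
        genome_length=genome_length, cfg=cfg, seed=derive_seed(seed, "grid"),
    )
    contained = contained_adj = 0
    brackets = []
    for traj in fits:
        plateau, _ = hpsmc.estimate_plateau_ne(traj, MU)
        try:
            br = hpsmc.bracket_gene_flow_end(traj, grid, plateau, MU, gen_time)
        except hpsmc.BracketError:
            brackets.append(None)
            continue
        lo = br.lower_ma if br.lower_ma is not None else 10.0 - 1.0
        hi = br.upper_ma if br.upper_ma is not None else 15.0 + 1.0
        brackets.append((lo, hi))
        contained += lo <= t_split_ma <= hi
        contained_adj += (lo - 1.0) <= t_split_ma <= (hi + 1.0)  # inside or adjacent
    out = {
        "contain_frac": contained / n_seeds,
        "contain_adjacent_frac": contained_adj / n_seeds,
        "brackets": brackets,
        "plateau_first": plateau0,
        "n_seeds": n_seeds,
    }
    if include_migration:
        het_m = hpsmc._simulate_clean_split_f1(
            plateau_ne, t_gens, genome_length, MU, 5e-9, derive_seed(seed, "mig"),
            migration_rate=2e-5, migration_until_gens=t_gf_ma * 1e6 / gen_time,
        )
        traj_m = hpsmc.fit_pseudo_f1(het_m, mask, lengths, cfg)
        plateau_m, _ = hpsmc.estimate_plateau_ne(traj_m, MU)
        grid_m = hpsmc.simulate_divergence_grid(
            plateau_m, (4.0, 14.0), MU, gen_time,
            genome_length=genome_length, step_ma=2.0, cfg=cfg, seed=derive_seed(seed, "gridm"),
        )
        br_m = hpsmc.bracket_gene_flow_end(traj_m, grid_m, plateau_m, MU, gen_time)
        out["migration_midpoint_ma"] = br_m.midpoint_ma
        out["migration_bracket"] = (br_m.lower_ma, br_m.upper_ma)
        out["t_gf_ma"] = t_gf_ma
        out["t_split_ma"] = t_split_ma
    return out


def jackknife_validity(n_reps: int = 50, genome_length: int = 5_000_000, seed: int = 1) -> dict:
    """Jackknife SE vs the empirical spread of D across replicates.

    A four-population model (trio plus outgroup, no migration) is simulated
    ``n_reps`` times; the weighted block jackknife SE from each replicate is
    compared with the standard deviation of D over replicates.
    """
    ne = 20_000
    model = simgen.DemographicModel(
        populations=[("P1", ne), ("P2", ne), ("P3", ne), ("O", ne)],
        splits=[
            simgen.Split(time=30_000, derived=("P1", "P2"), ancestral="A1", ne=ne),
            simgen.Split(time=70_000, derived=("A1", "P3"), ancestral="A2", ne=ne),
            simgen.Split(time=150_000, derived=("A2", "O"), ancestral="ROOT", ne=ne),
        ],
        mu=MU,
        r=5e-9,
    )
    lay = simgen.GenomeLayout((("s1", genome_length),))
    ds, ses = [], []
    for rep in range(n_reps):
        res = simgen.simulate_genotypes(
            model, lay, seed=derive_seed(seed, "jack", rep), include_mito=False
        )
        abba, baba = dstat.count_patterns(
            res.genotypes, "P1_0", "P2_0", "P3_0", "O_0",
            seed=derive_seed(seed, "jackcount", rep),
            block_size=500_000, min_block_sites=10,
        )
        d, se, _ = dstat.block_jackknife(abba, baba)
        ds.append(d)
        ses.append(se)
    sd = float(np.std(ds, ddof=1))
    return {
        "mean_jackknife_se": float(np.mean(ses)),
        "empirical_sd": sd,
        "ratio": float(np.mean(ses) / sd),
        "n_reps": n_reps,
    }
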