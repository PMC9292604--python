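"""Config-driven orchestration: simulate -> filter -> diversity -> dstat ->
topology weighting -> SMC trajectories -> hPSMC -> dating, with one global
seed, per-stage parameter blocks and a JSON run report.

A single seed deterministically derives per-stage seeds (stage-name
hashing), so one number reproduces every non-bootstrap output byte for byte.
Every output file carries a header line with the package version, the seed
and a digest of the stage parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import CallableMask, derive_seed
from . import simgen, variantio, diversity, dstat, topoweight, smc, hpsmc

logger = logging.getLogger("chelonia")

STAGES = ["simulate", "filter", "diversity", "dstat", "twisst", "smc", "hpsmc", "date"]

#: stage -> stages whose in-memory products it needs
_DEPS = {
    "simulate": [],
    "filter": ["simulate"],
    "diversity": ["filter"],
    "dstat": ["filter"],
    "twisst": ["filter"],
    "smc": ["filter"],
    "hpsmc": ["filter"],
    "date": ["filter"],
}

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "chelonia_run",
    "stages": {s: True for s in STAGES},
    "species": ["OL", "LL", "HH", "GG", "DC"],
    "outgroup": "DC",
    "species_tree": "((((OL,LL),HH),GG),DC);",
    "generation_time_years": {"OL": 20.5, "LL": 24.0, "HH": 26.5, "GG": 33.0, "DC": 24.0},
    "mu": simgen.DEFAULT_MU,
    "simulate": {
        "n_scaffolds": 2,
        "scaffold_length": 2_000_000,
        "mito_length": 16_700,
        "demography": None,  # falls back to the built-in turtle-like model
        "gap_fraction": 0.1,
    },
    "filter": {"thresholds": {}, "mode": "annotate"},
    "diversity": {"window_size": 100_000, "min_depth": 5, "min_scaffold": 500_000},
    "dstat": {"block_size": 1_000_000, "min_block_sites": 20},
    "twisst": {"size_snps": 50, "min_snps": 45, "loess_span": 1_000_000},
    "smc": {
        "bin_size": 100,
        "pattern": "4+25*2+4+6",
        "t_max": 15.0,
        "max_iters": 10,
        "min_bins": 10_000,
        "samples": None,  # default: one per species
    },
    "hpsmc": {
        "pair": ["HH", "LL"],
        "bin_size": 10,
        "pattern": "2+14*2+2",
        "t_max": 15.0,
        "max_iters": 12,
        "min_depth": 5,
        "min_qual": 30.0,
        "grid_ma": [10.0, 15.0],
        "grid_step_ma": 1.0,
        "grid_genome_length": 2_000_000,
        "plateau": "auto",
    },
    "date": {"calibration_age_ma": 68.4},
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.raw["outdir"])

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, "stage", stage)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.raw))


def _merge(defaults, override):
    if isinstance(defaults, dict) and isinstance(override, dict):
        out = dict(defaults)
        for k, v in override.items():
            out[k] = _merge(defaults.get(k), v) if k in defaults else v
        return out
    return defaults if override is None else override


def validate_config(config) -> RunConfig:
    """Expand a partial config against defaults and validate it.

    ``config`` may be a mapping, YAML text, or a path to a YAML file.  All
    problems are collected and reported together.  Idempotent: re-validating
    an expanded config returns an identical one.
    """
    if isinstance(config, (str, Path)):
        import yaml

        p = Path(config)
        text = p.read_text() if p.exists() else str(config)
        config = yaml.safe_load(text)
        if not isinstance(config, dict):
            raise ConfigError("config must parse to a mapping")
    cfg = _merge(DEFAULT_CONFIG, config or {})
    errors = []
    if not isinstance(cfg.get("seed"), int):
        errors.append("seed must be an integer")
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    species = cfg["species"]
    if cfg["outgroup"] not in species:
        errors.append(f"outgroup {cfg['outgroup']!r} not among species")
    for sp in cfg["hpsmc"]["pair"]:
        if sp not in species:
            errors.append(f"hpsmc pair member {sp!r} not among species")
    missing_gt = [s for s in species if s not in cfg["generation_time_years"]]
    if missing_gt:
        errors.append(f"generation times missing for {missing_gt}")
    enabled = {s for s in STAGES if cfg["stages"].get(s)}
    for s in enabled:
        for dep in _DEPS[s]:
            if dep not in enabled and not cfg.get("inputs", {}).get(dep):
                errors.append(f"stage {s!r} needs {dep!r} enabled or supplied via inputs")
    for key in ("vcf", "mask"):
        path = cfg.get("inputs", {}).get(key)
        if path and not Path(path).exists():
            errors.append(f"input file missing: {path}")
    try:
        smc.parse_interval_pattern(cfg["smc"]["pattern"])
        smc.parse_interval_pattern(cfg["hpsmc"]["pattern"])
    except ValueError as e:
        errors.append(str(e))
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(raw=cfg)


@dataclass
class RunReport:
    seed: int
    stages: dict[str, str] = field(default_factory=dict)  # status per stage
    outputs: dict[str, str] = field(default_factory=dict)
    key_numbers: dict[str, float] = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "seed": self.seed,
                "stages": self.stages,
                "outputs": self.outputs,
                "key_numbers": self.key_numbers,
                "wall_time_s": round(self.wall_time_s, 2),
                "version": __version__,
            },
            indent=2,
            sort_keys=True,
        )
        if path:
            Path(path).write_text(text + "\n")
        return text


def _param_digest(params: dict) -> str:
    return hashlib.md5(json.dumps(params, sort_keys=True).encode()).hexdigest()[:8]


def _header(cfg: RunConfig, stage: str) -> str:
    return (
        f"# chelonia v{__version__} seed={cfg.seed} stage={stage} "
        f"params={_param_digest(cfg.raw.get(stage, {}))}\n"
    )


def _write(path: Path, header: str, body: str) -> None:
    path.write_text(header + body)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, state: dict) -> None:
    p = cfg["simulate"]
    if p.get("demography"):
        model = simgen.build_demography(p["demography"])
    else:
        model = simgen.turtle_like_model(mu=cfg["mu"])
    layout = simgen.GenomeLayout(
        tuple((f"scaffold_{i+1}", int(p["scaffold_length"])) for i in range(int(p["n_scaffolds"]))),
        mito_length=int(p["mito_length"]),
    )
    res = simgen.simulate_genotypes(model, layout, seed=cfg.stage_seed("simulate"))
    mask = simgen.degrade_mask(res.mask, float(p["gap_fraction"]), cfg.stage_seed("simulate"))
    out = cfg.outdir
    variantio.write_genotype_table_vcf(res.genotypes, out / "nuclear.vcf")
    if res.mito is not None:
        variantio.write_genotype_table_vcf(res.mito, out / "mito.vcf")
    variantio.write_bed(mask, out / "callable.bed")
    res.truth.to_json(out / "truth.json")
    state.update(genotypes=res.genotypes, mito=res.mito, mask=mask, truth=res.truth, model=model)


def _load_inputs(cfg: RunConfig, state: dict) -> None:
    inputs = cfg.get("inputs", {})
    if "genotypes" not in state and inputs.get("vcf"):
        state["genotypes"] = variantio.read_genotype_table(inputs["vcf"])
    if "mask" not in state and inputs.get("mask"):
        state["mask"] = variantio.read_bed(inputs["mask"])
    if "mask" not in state and "genotypes" in state:
        state["mask"] = CallableMask.full(state["genotypes"].scaffold_lengths)


def _stage_filter(cfg: RunConfig, state: dict) -> None:
    g = state["genotypes"]
    records = variantio.genotype_table_to_records(g)
    kept = variantio.filter_records(records, cfg["filter"]["thresholds"], mode="annotate")
    variantio.write_vcf(
        cfg.outdir / "filtered.vcf",
        kept,
        g.samples,
        contigs=dict(g.scaffold_lengths),
        phased=g.phased,
    )
    keep = {}
    by_scaffold: dict[str, list[bool]] = {}
    for rec in kept:
        by_scaffold.setdefault(rec.scaffold, []).append(rec.filter == "PASS")
    for name, sg in g.scaffolds.items():
        flags = np.array(by_scaffold.get(name, []), dtype=bool)
        keep[name] = flags if len(flags) == sg.n_sites else np.ones(sg.n_sites, dtype=bool)
    state["genotypes"] = g.subset_sites(keep)
    state["n_pass"] = int(sum(sum(v) for v in keep.values()))


def _sample_of(cfg: RunConfig, species: str) -> str:
    return f"{species}_0"


def _stage_diversity(cfg: RunConfig, state: dict) -> None:
    g, mask = state["genotypes"], state["mask"]
    p = cfg["diversity"]
    windows = variantio.make_windows(
        dict(g.scaffold_lengths), int(p["window_size"]), int(p["min_scaffold"])
    )
    lines = ["scaffold\tstart\tend\tsample\thet_per_bp\thet_per_callable\tn_het"]
    means = {}
    for sp in cfg["species"]:
        sample = _sample_of(cfg, sp)
        stats = diversity.windowed_heterozygosity(g, mask, windows, sample, int(p["min_depth"]))
        for s in stats:
            lines.append(
                f"{s.window.scaffold}\t{s.window.start}\t{s.window.end}\t{sample}\t"
                f"{s.value:.6e}\t{s.value_callable:.6e}\t{s.n_used}"
            )
        means[sp] = float(np.mean([s.value for s in stats])) if stats else 0.0
    _write(cfg.outdir / "heterozygosity.tsv", _header(cfg, "diversity"), "\n".join(lines) + "\n")
    try:
        tstv = diversity.tstv_ratio(g)
    except diversity.TsTvUndefinedError:
        tstv = float("nan")
    ibs = diversity.ibs_distance_matrix(g, seed=cfg.stage_seed("diversity"))
    ibs_lines = ["\t".join(["sample"] + g.samples)]
    for i, s in enumerate(g.samples):
        ibs_lines.append(s + "\t" + "\t".join(f"{x:.6f}" for x in ibs[i]))
    _write(cfg.outdir / "ibs_distance.tsv", _header(cfg, "diversity"), "\n".join(ibs_lines) + "\n")
    state["het_means"] = means
    state["tstv"] = tstv


def _stage_dstat(cfg: RunConfig, state: dict) -> None:
    g = state["genotypes"]
    p = cfg["dstat"]
    sample_map = {sp: _sample_of(cfg, sp) for sp in cfg["species"]}
    results = dstat.dstat_scan(
        g,
        cfg["species_tree"],
        cfg["outgroup"],
        sample_map=sample_map,
        seed=cfg.stage_seed("dstat"),
        block_size=int(p["block_size"]),
        min_block_sites=int(p["min_block_sites"]),
    )
    _write(cfg.outdir / "dstat.tsv", _header(cfg, "dstat"), dstat.dstat_table(results))
    state["dstat"] = results


def _stage_twisst(cfg: RunConfig, state: dict) -> None:
    g = state["genotypes"]
    p = cfg["twisst"]
    species_map = {_sample_of(cfg, sp): sp for sp in cfg["species"]}
    g2 = topoweight.remove_outgroup_private_snps(g, _sample_of(cfg, cfg["outgroup"]))
    catalog, ws = topoweight.weight_windows(
        g2, species_map, cfg["outgroup"], int(p["size_snps"]), int(p["min_snps"])
    )
    _write(cfg.outdir / "topoweights.tsv", _header(cfg, "twisst"), topoweight.weights_table(catalog, ws))
    smoothed = topoweight.smooth_weights(ws, float(p["loess_span"]))
    lines = ["scaffold\tmidpoint\t" + "\t".join(catalog.topologies)]
    for scaffold, (x, S) in smoothed.items():
        for xi, row in zip(x, S):
            lines.append(f"{scaffold}\t{xi:.1f}\t" + "\t".join(f"{v:.6f}" for v in row))
    _write(cfg.outdir / "topoweights_smoothed.tsv", _header(cfg, "twisst"), "\n".join(lines) + "\n")
    if ws:
        state["weight_means"] = dict(
            zip(catalog.topologies, np.mean([w.weights for w in ws], axis=0))
        )
    state["catalog"] = catalog


def _stage_smc(cfg: RunConfig, state: dict) -> None:
    g, mask = state["genotypes"], state["mask"]
    p = cfg["smc"]
    config = smc.SmcConfig(
        bin_size=int(p["bin_size"]),
        pattern=p["pattern"],
        t_max=float(p["t_max"]),
        max_iters=int(p["max_iters"]),
        min_bins=int(p["min_bins"]),
    )
    species = p.get("samples") or cfg["species"]
    trajs = {}
    for sp in species:
        sample = _sample_of(cfg, sp)
        seqs = smc.binarize(g, sample, mask, config.bin_size)
        traj = smc.fit_smc(seqs, config)
        sc = smc.scale_trajectory(traj, cfg["mu"], cfg["generation_time_years"][sp])
        body = sc.to_csv(sep="\t", index=False)
        _write(cfg.outdir / f"smc_{sp}.tsv", _header(cfg, "smc"), body)
        trajs[sp] = traj
    state["smc_trajectories"] = trajs


def _stage_hpsmc(cfg: RunConfig, state: dict) -> None:
    g, mask = state["genotypes"], state["mask"]
    p = cfg["hpsmc"]
    a_sp, b_sp = p["pair"]
    config = smc.SmcConfig(
        bin_size=int(p["bin_size"]),
        pattern=p["pattern"],
        t_max=float(p["t_max"]),
        max_iters=int(p["max_iters"]),
    )
    seed = cfg.stage_seed("hpsmc")
    ph_a = hpsmc.pseudo_haploidize(g, _sample_of(cfg, a_sp), int(p["min_depth"]), float(p["min_qual"]), seed)
    ph_b = hpsmc.pseudo_haploidize(g, _sample_of(cfg, b_sp), int(p["min_depth"]), float(p["min_qual"]), seed + 1)
    het = hpsmc.make_pseudo_f1(ph_a, ph_b)
    traj = hpsmc.fit_pseudo_f1(het, mask, g.scaffold_lengths, config)
    gt_pair = 0.5 * (
        cfg["generation_time_years"][a_sp] + cfg["generation_time_years"][b_sp]
    )
    sc = smc.scale_trajectory(traj, cfg["mu"], gt_pair)
    _write(cfg.outdir / f"hpsmc_{a_sp}_{b_sp}.tsv", _header(cfg, "hpsmc"), sc.to_csv(sep="\t", index=False))
    if p["plateau"] == "auto":
        plateau, _onset = hpsmc.estimate_plateau_ne(traj, cfg["mu"])
    else:
        plateau = float(p["plateau"])
    lo, hi = (float(x) for x in p["grid_ma"])
    grid = hpsmc.simulate_divergence_grid(
        plateau,
        (lo, hi),
        cfg["mu"],
        gt_pair,
        genome_length=int(p["grid_genome_length"]),
        step_ma=float(p["grid_step_ma"]),
        cfg=config,
        seed=seed,
    )
    bracket = hpsmc.bracket_gene_flow_end(traj, grid, plateau, cfg["mu"], gt_pair, pair=(a_sp, b_sp))
    out = {
        "pair": [a_sp, b_sp],
        "plateau_ne": plateau,
        "lower_ma": bracket.lower_ma,
        "upper_ma": bracket.upper_ma,
        "frac_above": bracket.frac_above,
    }
    (cfg.outdir / "hpsmc_bracket.json").write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    state["hpsmc_bracket"] = bracket


def _stage_date(cfg: RunConfig, state: dict) -> None:
    g = state["genotypes"]
    p = cfg["date"]
    species = cfg["species"]
    samples = [_sample_of(cfg, sp) for sp in species]
    sub_idx = [g.sample_index(s) for s in samples]
    age = float(p["calibration_age_ma"])
    dist_nuc = diversity.pairwise_divergence_matrix(g)[np.ix_(sub_idx, sub_idx)]
    tree_nuc = diversity.upgma_calibrated_ages(dist_nuc, species, set(species), age)
    result = {"calibration_age_ma": age, "nuclear": {}, "mito": {}}
    ingroup = [sp for sp in species if sp != cfg["outgroup"]]
    for k in range(2, len(ingroup) + 1):
        clade = set(ingroup[:k])  # nested clades of the pectinate ingroup
        try:
            result["nuclear"][",".join(sorted(clade))] = tree_nuc.age(clade)
        except diversity.CalibrationError:
            pass
    (cfg.outdir / "dated_nuclear.nwk").write_text(tree_nuc.newick() + "\n")
    mito = state.get("mito")
    if mito is not None and mito.n_sites:
        dist_mt = diversity.pairwise_divergence_matrix(mito)[np.ix_(
            [mito.sample_index(s) for s in samples], [mito.sample_index(s) for s in samples]
        )]
        try:
            tree_mt = diversity.upgma_calibrated_ages(dist_mt, species, set(species), age)
            (cfg.outdir / "dated_mito.nwk").write_text(tree_mt.newick() + "\n")
            for k in range(2, len(ingroup) + 1):
                clade = set(ingroup[:k])
                try:
                    result["mito"][",".join(sorted(clade))] = tree_mt.age(clade)
                except diversity.CalibrationError:
                    pass
        except diversity.CalibrationError:
            result["mito"] = {"error": "calibration clade not recovered"}
    (cfg.outdir / "dated_nodes.json").write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
    state["dated"] = result


_STAGE_FN = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "diversity": _stage_diversity,
    "dstat": _stage_dstat,
    "twisst": _stage_twisst,
    "smc": _stage_smc,
    "hpsmc": _stage_hpsmc,
    "date": _stage_date,
}


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute enabled stages in dependency order; halt dependents on failure."""
    t0 = time.time()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    state: dict = {}
    failed: set[str] = set()
    _load_inputs(cfg, state)
    for stage in STAGES:
        if not cfg["stages"].get(stage):
            report.stages[stage] = "skipped"
            logger.info("stage %s skipped", stage)
            continue
        if any(d in failed or report.stages.get(d) == "blocked" for d in _DEPS[stage]):
            report.stages[stage] = "blocked"
            continue
        logger.info("stage %s starting (seed %d)", stage, cfg.stage_seed(stage))
        try:
            _STAGE_FN[stage](cfg, state)
            report.stages[stage] = "ok"
        except Exception as e:  # noqa: BLE001 - report records partial state
            logger.exception("stage %s failed", stage)
            report.stages[stage] = f"failed: {e}"
            failed.add(stage)
    for f in sorted(cfg.outdir.glob("*")):
        report.outputs[f.name] = str(f)
    if "tstv" in state and np.isfinite(state["tstv"]):
        report.key_numbers["tstv"] = round(float(state["tstv"]), 4)
    for r in state.get("dstat", []):
        report.key_numbers[f"D {r.arrangement}"] = round(r.d, 4)
    for topo, wmean in sorted(
        state.get("weight_means", {}).items(), key=lambda kv: -kv[1]
    )[:3]:
        report.key_numbers[f"weight {topo}"] = round(float(wmean), 4)
    br = state.get("hpsmc_bracket")
    if br is not None:
        report.key_numbers["hpsmc_bracket_midpoint_ma"] = br.midpoint_ma
    report.wall_time_s = time.time() - t0
    report.to_json(cfg.outdir / "report.json")
    return report
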