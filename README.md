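# chelonia

Genome-scale analysis of divergence, demography and ancient hybridization
from a handful of whole genomes — one diploid individual per species — aimed
at comparative and conservation genomicists working on sea turtles and
similar slow-evolving, hybridizing clades.

Given phased or unphased diploid genotypes (VCF) and callable-region masks
(BED), the package provides:

* **Variant hard filtering** — the GATK-style chain (biallelic SNPs only;
  QUAL < 60, FS > 60, QD < 2, MQ < 40, MQRankSum < −20,
  ReadPosRankSum < −8 dropped), ±4× coverage bounds, 5 bp indel proximity,
  and bedtools-style mask intersection.
* **Windowed diversity** — per-sample heterozygosity in 100 kb windows,
  Ts/Tv, consensus identity-by-state distance matrices.
* **Patterson's D (ABBA–BABA)** — `D = (nABBA − nBABA)/(nABBA + nBABA)`
  under the arrangement `(((P1,P2),P3),O)`, with weighted block-jackknife
  standard errors, Z-scores (|Z| > 3 significant) and a scan over all
  species-tree-consistent trios.
* **Exact topology weighting** — neighbor-joining trees in 50-SNP windows,
  exact enumeration of all one-haplotype-per-species subtrees against the
  catalog of 15 rooted topologies (4 ingroup taxa + outgroup), with 1 Mb
  physical-bandwidth loess smoothing.
* **PSMC'-style coalescent HMM** — effective-size trajectories `Ne(t)` from
  one diploid via Baum–Welch EM over a discretized TMRCA grid
  (`"4+25*2+4+6"` atomic intervals), with block bootstrap and real-unit
  scaling (`μ = 7.9e-9`/site/generation; generation time = age to maturity
  + ½ reproductive longevity).
* **hPSMC** — pseudo-F1 genomes from two species' pseudo-haploids; the
  apparent-Ne explosion dates the *cessation of gene flow*, bracketed
  against clean-split simulations on a 1 Myr divergence-time grid.
* **Coalescent simulation with ground truth** — five-species
  isolation-with-migration genomes (msprime-backed), plus a haploid
  mito-surrogate locus, so every stage above is testable without any
  external data.

## Worked example

Simulate 10 Mb of five-species genomes where HH donated ~10% of OL's genome
shortly after their ancestors split, then scan for introgression:

```python
from chelonia import simgen, dstat, topoweight
import numpy as np

mig = [simgen.MigrationEpoch(pair=("HH", "OL"), rate=1e-3,
                             start=5_000, end=5_100, direction="AtoB")]
model = simgen.turtle_like_model(migration=mig)
layout = simgen.GenomeLayout((("scaffold_1", 10_000_000),))
genotypes, mask, truth = simgen.simulate_genotypes(model, layout, seed=42)

samples = {sp: f"{sp}_0" for sp in ("OL", "LL", "HH", "GG", "DC")}
results = dstat.dstat_scan(genotypes, "((((OL,LL),HH),GG),DC);", "DC",
                           sample_map=samples, block_size=1_000_000,
                           min_block_sites=20)
print(dstat.dstat_table(results))
```

```
arrangement        nABBA  nBABA  D        SE      Z      n_blocks  significant
(((HH,LL),GG),DC)  213.0  236.0  -0.0512  0.0280  -1.83  10        False
(((HH,OL),GG),DC)  188.0  260.0  -0.1607  0.0342  -4.70  10        True
(((LL,OL),GG),DC)  53.0   87.0   -0.2429  0.0621  -3.91  6         True
(((LL,OL),HH),DC)  655.0  388.0  0.2560   0.0675  3.79   10        True
```

The `(((LL,OL),HH),DC)` trio shows D = +0.26 with Z = 3.8: an excess of
derived-allele sharing between P2 = OL and P3 = HH, exactly the simulated
gene-flow direction (positive D means P2–P3 sharing under the printed
arrangement; the other significant rows are the same signal re-expressed in
trios that place OL or HH elsewhere). Topology weighting localizes the same
signal:

```python
g = topoweight.remove_outgroup_private_snps(genotypes, "DC_0")
catalog, windows = topoweight.weight_windows(
    g, {f"{sp}_0": sp for sp in samples}, "DC")
mean = np.mean([w.weights for w in windows], axis=0)
for i in np.argsort(mean)[::-1][:3]:
    print(f"{catalog.topologies[i]}  mean weight {mean[i]:.3f}")
```

```
(((LL,OL),HH),GG)  mean weight 0.643
(((HH,OL),LL),GG)  mean weight 0.163
(((HH,LL),OL),GG)  mean weight 0.106
```

The species topology dominates (0.643), but the discordant topology uniting
the migrating pair HH+OL (0.163) clearly exceeds the other discordant
resolution (0.106) — the asymmetry that distinguishes introgression from
incomplete lineage sorting, which would leave the two balanced.

## Command line

A config-driven pipeline runs all stages end to end with one seed:

```sh
chelonia all --config run.yaml --seed 7 --outdir results/
chelonia dstat --seed 7 --outdir results/   # just simulate+filter+dstat
```

Outputs are headered TSV/VCF/BED/JSON files plus a `report.json` with
per-stage status and key numbers; the same config and seed reproduce every
non-bootstrap output byte for byte.

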