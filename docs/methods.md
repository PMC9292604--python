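# Methods

`chelonia` reconstructs histories of divergence, demography and
hybridization from a handful of whole genomes — one diploid individual per
species — and verifies every stage against coalescent simulations with known
truth. This note documents the models, the numerical choices, the synthetic
data generator, and the limits of what the bundled validation studies show.

## Synthetic genomes (`simgen`)

Genomes are simulated with msprime under a user-specified
isolation-with-migration demography: a species tree with split times (in
generations before present), piecewise-constant diploid `Ne` per population,
and migration epochs `(pair, rate, start, end)` where `start` is the more
recent bound — the gene-flow cessation time. Mutations use an HKY model with
κ = 4.3, so the expected Ts/Tv ratio is ≈2.15, matching the 2.1–2.2 range
typical of whole-genome animal data. Only biallelic SNPs are retained.

A haploid, non-recombining mito-surrogate locus (default 16.7 kb) is
simulated under the same demography with all `Ne` scaled by ¼ (one
maternally inherited copy per diploid pair); migration is on by default so
mitochondrial capture is possible, and can be disabled to emulate species
with nuclear-only introgression.

Desk-scale defaults, chosen once at design time:

| parameter | default | why |
|---|---|---|
| μ | 7.9e-9 /site/gen | reptile whole-genome estimate used throughout |
| r | 5e-9 /site/gen | below μ, as in slow-recombining reptile maps; LD block length (~1/(4·Ne·r) ≈ 2.5 kb at Ne 2e4) stays far below the 1 Mb jackknife blocks, and coalescent simulation stays affordable |
| Ne | 20,000 diploids | gives per-site heterozygosity 4·Ne·μ ≈ 6.3e-4, a realistic vertebrate value |
| five-species tree | splits at 30k/70k/130k/250k generations | internal branches ≈1 coalescent unit: substantial incomplete lineage sorting without drowning introgression signals |

The truth record stores, per species pair, the split time and the gene-flow
cessation time (the most recent migration-epoch bound; equal to the split
when there is no migration), asserting cessation ≤ split.

`degrade_mask` deletes random 200-bp tiles until a target fraction of the
callable span is gone, emulating the ~10% loss to mappability/repeat
filters; `unphase` randomizes within-individual allele order so phase-free
methods can be tested on both representations.

What the generator does **not** emulate: sequencing errors, read-level
artifacts, reference bias from mapping, indels (beyond hand-written filter
fixtures), selection, or population structure within species. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated coalescent models, not robustness to raw-data pathologies.

## Variant filtering (`variantio`)

The hard-filter chain drops sites that are not biallelic SNPs or that fail
QUAL < 60, FS > 60, QD < 2, MQ < 40, MQRankSum < −20 or
ReadPosRankSum < −8. Two deliberate readings:

* An absent INFO annotation never fires its criterion — upstream callers
  emit the rank-sum annotations only at heterozygous sites, and dropping all
  homozygous records would be catastrophic.
* MQRankSum < −20 is kept as the default threshold even though −12.5 is the
  more common community cut; both are configurable.

Coverage filtering excludes bases with depth above k·mean or below mean/k
(default k = 4; symmetric on the log scale). SNPs within 5 bp of an indel
called with QUAL > 60 are removed. All criteria are independent, so the kept
set does not depend on evaluation order (property-tested). Coordinates: VCF
1-based inclusive; BED/masks/windows 0-based half-open.

## Diversity and dating (`diversity`)

Windowed heterozygosity counts heterozygous genotypes with depth ≥ 5 in
100 kb windows, reported per window length (headline, matching windowed-VCF
tool conventions) and per callable bp. Trailing partial windows are kept and
flagged rather than discarded.

The pairwise distance matrix follows the consensus identity-by-state idea:
each diploid is collapsed to its majority allele per site, ties broken by a
seeded coin, distance = fraction of differing consensus sites.

Divergence dating uses a deliberately minimal strict-clock surrogate: UPGMA
(scipy average linkage) on Jukes–Cantor-corrected distances, with all node
heights scaled linearly so one calibration node has a fixed age. If the
calibration clade is not a UPGMA node the run fails loudly — no silent
rescaling. This supports directional comparisons (nuclear vs mitochondrial
node ages); it does not produce credible intervals and is not a substitute
for full Bayesian dating, which is out of scope.

## Patterson's D (`dstat`)

Arrangement fixed and printed as `(((P1,P2),P3),O)`; sites are polarized by
one allele sampled from the outgroup, one allele is sampled per diploid per
site (a frequency-weighted mode is available). The per-sample sampling
streams depend only on (seed, sample, scaffold), so swapping P1 and P2 flips
D's sign exactly, and relabelling REF/ALT changes nothing.

Standard errors come from a weighted delete-one-block jackknife (Busing's
formulation) over 5 Mb physical blocks by default, weights = informative
sites per block; blocks under the informative-site floor are dropped. |Z|>3
flags significance. The trio scan enumerates every trio whose (P1,P2) pair
is a cherry or nested pair relative to P3 on the rooted species tree — four
trios for the pectinate four-species ingroup.

## Topology weighting (`topoweight`)

For five species × two haplotypes, each 50-SNP window (minimum 45 at
scaffold ends) gets a neighbor-joining tree on JC-corrected haplotype
distances. NJ replaces a full ML tree search: at ten leaves and 50 SNPs the
two virtually always agree on topology, NJ is deterministic, and a hook
accepts externally computed newick trees per window for exact parity with
other tools. Sites private to the outgroup are removed first.

Weighting is exact: all 2⁵ combinations of one haplotype per species are
enumerated; each pruned subtree is rooted with the outgroup haplotype and
matched against the canonical catalog (15 rooted topologies for four ingroup
taxa). Pruning is implemented by intersecting the precomputed leaf sets of
every tree edge with the chosen haplotype set, which is algebraically
identical to extract-and-reroot but ~50× faster.

Smoothing is a tricube-weighted local *linear* fit with a physical 1 Mb
bandwidth (±500 kb) evaluated at window midpoints (midpoint = mean of first
and last SNP positions), then clipped to [0,1] and renormalized across
topologies per point. A fraction-of-points loess would confound physical
distance with SNP density, which is exactly what windowed introgression
scans must not do.

## The coalescent HMM (`smc`)

A PSMC'-style pairwise sequentially-Markovian-coalescent HMM on one
haplotype pair — a diploid's phase-free heterozygosity track or a pseudo-F1.

* **Time grid.** Atomic interval boundaries are log-spaced,
  `b_i = α(exp(i/n·log(1+t_max/α)) − 1)` with α = 0.1, `b_n = t_max`
  (default 15 coalescent units of 2·N₀ generations); the last interval is
  open-ended for coalescence. Intervals are tied into parameter groups via
  patterns like `"4+25*2+4+6"` (64 atomic intervals, 28 free intensities).
* **Emission.** P(het | TMRCA t) = 1 − exp(−θt) per bin (default 100 bp
  within species, 10 bp for pseudo-F1 runs, where divergence-scale
  heterozygosity would otherwise saturate). Missing bins (majority of the
  bin outside the callable mask) emit probability 1 for every state: they
  carry no information but preserve the Markov chain, verified against
  explicit matrix-power bridging.
* **Transition.** With probability exp(−ρt) the TMRCA persists; otherwise a
  recombination at u ~ Uniform(0, t) detaches a lineage that re-coalesces at
  the piecewise-constant hazard λ(s) for s > u (single-partner SMC kernel).
  The double integral over u and s is evaluated in closed form per interval
  pair, so transition rows sum to 1 to machine precision.
* **EM.** Baum–Welch with scaled forward/backward (numba-compiled; results
  independent of the scaling scheme to 1e-8). θ is re-estimated each
  iteration by 1-D maximization; ρ is fixed after initialization (θ/2 by
  default) — re-estimating ρ jointly is known to be poorly identified in
  this model family. The group intensities are updated by L-BFGS-B on the
  expected complete log-likelihood, falling back to the incumbent point if
  the optimizer fails to improve it, so every iteration is a generalized
  EM step. Per-interval representative times (conditional TMRCA means) are
  computed under the flat initial intensities and then *fixed*: updating
  them each iteration changes the model mid-fit and can break likelihood
  monotonicity, which the suite asserts.
* **Initialization.** λ ≡ 1; θ₀ = h/(1−h) from the genome-wide het-bin
  fraction.
* **Scaling.** N₀ = θ/(4μ·bin); time = t·2N₀·g years; Ne(t) = N₀/λ(t).

Bootstrap: the genome is cut into 5 Mb segments, resampled with replacement
to the original count (each resampled segment is its own sequence — no fake
junction transitions), 20 replicates by default.

Validation: on 50 Mb at constant Ne = 20,000 the fitted Ne is within ~6%
(bound 20%) of truth across every group overlapping 0.2–2 coalescent units;
the tiny-instance forward likelihood matches exhaustive hidden-path
enumeration to 1e-8.

## hPSMC (`hpsmc`)

Each species' diploid is pseudo-haploidized (one uniformly drawn allele per
site; depth < 5 or site quality < 30 → missing). The pseudo-F1 of two
species is heterozygous exactly where the two pseudo-haploids differ and is
binned at 10 bp. Because an F1's two genomes cannot coalesce more recently
than the last genetic exchange between the species, the fitted trajectory
shows a plateau at the ancestral Ne and an explosion of apparent Ne toward
the present, starting at the cessation of gene flow.

* **Plateau rule** (replacing by-eye estimation): groups beyond the
  data-supported range (cumulative TMRCA prior mass > 99.5% under the fitted
  intensities) are excluded — with essentially zero expected occupancy they
  retain initialization bias, not signal. Scanning old → recent, the rise
  onset is the oldest group with Ne ≥ 1.5× the geometric mean of the three
  oldest supported groups; the plateau is the geometric mean of everything
  older. Monotone rises and too-short plateaus are signalled, and a manual
  override is available.
* **Grid comparison.** Clean-split pseudo-F1 genomes are simulated at 1 Myr
  steps with the estimated plateau Ne and fitted with the same
  configuration. The comparison window is the contiguous "wall shoulder"
  where the empirical Ne sits in [1.5, 10]× plateau — old-time excursions of
  similar magnitude are fitting noise and are excluded. Both curves are
  evaluated as step functions on 200 log-spaced year points across the
  window; a grid curve is *older* if above the empirical at ≥90% of points,
  *younger* if below at ≥90%, and the bracket is (largest younger T,
  smallest older T). Non-monotone classifications raise.
* **Per-pair TMRCA caps**: 15 coalescent units for the closest pair
  (hawksbill/loggerhead-like), 5 for hawksbill/green-like, 10 otherwise —
  configurable defaults. Grid simulations use the mean generation time of
  the pair.

Validation (3 Mb pseudo-F1 genomes, 32 atomic intervals in 18 groups,
20 EM iterations): a clean split at 12 Ma is bracketed by the 10–15 Ma grid
in 10/10 seeds, and with symmetric migration continuing until 6 Ma the
bracket midpoint (8 Ma, bracket 6–10) moves decisively toward the cessation
time — the core behaviour that makes hPSMC a gene-flow clock rather than a
divergence clock. The estimated plateau runs ~20–25% above the simulated
ancestral Ne at these desk-scale sizes (old intervals converge slowly from a
flat initialization); since empirical and grid curves share the bias, the
brackets are unaffected.

## Calibration studies (`scenarios`)

Frozen study conditions used by both the test suite and
`scripts/acceptance.py` (sizes in parentheses):

* SNP-accumulation bound: 2μ·(200,000/24)·10,000 ≈ 1.32 < 2 (analytic).
* D null/power: 10 Mb genomes, 20 replicates each; ILS-only must give
  |Z| < 3 (observed 97.5% of trio×replicate tests), a 10% pulse must give
  D > 0, Z > 3 (observed 100%).
* Topology weighting: 5,000 non-recombining windows, internal branch t = 1;
  mean concordant weight within 0.03 of 1 − (2/3)e⁻¹ ≈ 0.755.
* SMC recovery: 50 Mb, constant Ne 20,000 (above).
* Mito/nuclear discordance: splits at 4.8/24 Ma, nuclear migration until
  1.2 Ma, 4 Mb nuclear + 16.7 kb mito, 20 replicates; nuclear (A,B) age
  younger than mitochondrial in ≥90% (observed 95%).
* Jackknife validity: 50 replicates of a 5 Mb trio genome; mean jackknife SE
  within 30% of the across-replicate SD of D (observed ratio 1.06).
* hPSMC bracketing (above).
* Filter chain: 30-record toy VCF with hand-enumerated truth, including
  boundary values at every threshold.

`scripts/acceptance.py` reports the same quantities with slightly smaller
replicate counts (10 D/discordance replicates, 25 jackknife replicates,
3 hPSMC seeds) so a full reproduction stays under ten minutes on one CPU;
the test suite uses the full sizes above.

## Known limitations

* The SMC transition kernel is SMC (single-partner re-coalescence), not
  SMC'; at these recombination/mutation ratios the practical difference is
  absorbed into the fixed ρ, but very recent Ne estimates inherit the usual
  PSMC-family unreliability.
* The discretized time grid is fixed, not adapted to the data; trajectories
  outside ~0.05–5 coalescent units of the fitted N₀ are weakly constrained.
* UPGMA dating assumes a strict clock and ultrametric distances; it is a
  directional instrument only.
* IBS and divergence matrices are computed on variant tables, so absolute
  distances depend on the table being complete for the compared samples
  (true for simulated data; real callsets need consistent joint calling).
* The exact-weighting cost grows as 2^k combinations per window for k
  diploid species; fine for 5 species, not for 20.
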