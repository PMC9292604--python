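"""PSMC'-style coalescent hidden Markov model on one haplotype pair.

The hidden state at each genomic bin is the local TMRCA of the pair,
discretized on a log-spaced grid of atomic intervals; the emission is the
per-bin heterozygosity indicator.  Fitting is by Baum-Welch EM over tied
interval groups, yielding a piecewise-constant coalescence-intensity
trajectory convertible to diploid Ne against real time.  The same engine
serves within-species effective-size trajectories (one diploid = two
haplotypes) and pseudo-F1 hybrid genomes (hPSMC).

Model details
-------------
Time is in coalescent units of 2*N0 generations, N0 being the effective size
implied by the fitted per-bin theta.  With boundaries 0 = b_0 < ... < b_K
(the last interval open-ended) and intensity lambda_k on interval k:

* prior: P(state k) follows the exponential race across intervals;
* emission: P(het | t) = 1 - exp(-theta*t); missing bins emit 1 for every
  state, contributing no information while preserving the Markov chain;
* transition: with probability exp(-rho*t) the TMRCA is unchanged; otherwise
  a recombination at u ~ Uniform(0, t) detaches a lineage that re-coalesces
  at hazard lambda(s) for s > u (single-partner sequentially-Markov kernel),
  integrated exactly over the discretization.

Per-interval representative times are the conditional expectations of the
TMRCA under the *initial* intensities and stay fixed through EM, which makes
the EM log-likelihood provably non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import CallableMask, GenotypeTable

__all__ = [
    "SmcConfig",
    "BinSequence",
    "SmcTrajectory",
    "parse_interval_pattern",
    "time_boundaries",
    "binarize",
    "binarize_positions",
    "fit_smc",
    "scale_trajectory",
    "bootstrap",
]

HOM, HET, MISSING = 0, 1, 2


def parse_interval_pattern(pattern: str) -> tuple[int, list[int]]:
    """Parse an atomic-interval pattern like ``"4+25*2+4+6"``.

    Terms are ``n`` (one parameter group spanning n atomic intervals) or
    ``n*m`` (n groups of m atomic intervals each).  Returns
    (n_atomic, group sizes); the example yields 64 atomic intervals in
    28 groups.
    """
    groups: list[int] = []
    for term in pattern.replace(" ", "").split("+"):
        if not term:
            raise ValueError(f"malformed pattern {pattern!r}")
        if "*" in term:
            n_s, m_s = term.split("*", 1)
            n, m = int(n_s), int(m_s)
            if n <= 0 or m <= 0:
                raise ValueError(f"malformed pattern term {term!r}")
            groups.extend([m] * n)
        else:
            n = int(term)
            if n <= 0:
                raise ValueError(f"malformed pattern term {term!r}")
            groups.append(n)
    n_atomic = sum(groups)
    if n_atomic < 2:
        raise ValueError("pattern must define at least 2 atomic intervals")
    return n_atomic, groups


def time_boundaries(n_atomic: int, t_max: float, alpha: float = 0.1) -> np.ndarray:
    """Log-spaced atomic interval boundaries on (0, t_max].

    b_i = alpha * (exp(i/n * log(1 + t_max/alpha)) - 1); b_0 = 0 and
    b_n = t_max exactly.  The final interval is treated as open-ended for
    coalescence.
    """
    i = np.arange(n_atomic + 1)
    b = alpha * (np.exp(i / n_atomic * np.log1p(t_max / alpha)) - 1.0)
    b[0], b[-1] = 0.0, t_max
    return b


@dataclass
class SmcConfig:
    bin_size: int = 100
    pattern: str = "4+25*2+4+6"
    t_max: float = 15.0
    theta_init: float | None = None  # per-bin; estimated from het fraction if None
    rho_init: float | None = None  # per-bin; theta/2 if None
    max_iters: int = 20
    tol: float = 1e-6  # relative log-likelihood improvement
    min_bins: int = 10_000

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        parse_interval_pattern(self.pattern)


@dataclass
class BinSequence:
    """Per-scaffold symbol sequences over fixed-size bins."""

    symbols: dict[str, np.ndarray]  # int8 arrays of HOM/HET/MISSING
    bin_size: int

    def __post_init__(self):
        for name, s in self.symbols.items():
            s = np.asarray(s, dtype=np.int8)
            if s.size and (s.min() < 0 or s.max() > 2):
                raise ValueError("symbols must be 0 (hom), 1 (het) or 2 (missing)")
            self.symbols[name] = s

    @property
    def n_bins(self) -> int:
        return sum(len(s) for s in self.symbols.values())

    def het_fraction(self) -> float:
        n_het = n_obs = 0
        for s in self.symbols.values():
            n_het += int(np.sum(s == HET))
            n_obs += int(np.sum(s != MISSING))
        return n_het / n_obs if n_obs else 0.0


def binarize_positions(
    het_positions: dict[str, np.ndarray],
    mask: CallableMask,
    scaffold_lengths: dict[str, int],
    bin_size: int,
) -> BinSequence:
    """Bin per-scaffold 1-based heterozygous-site positions.

    A bin is HET when it contains at least one het site, MISSING when more
    than half of it lies outside the callable mask, else HOM.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    symbols = {}
    for name, length in scaffold_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        sym = np.zeros(n_bins, dtype=np.int8)
        hp = np.asarray(het_positions.get(name, ()), dtype=np.int64)
        if hp.size:
            sym[np.minimum((hp - 1) // bin_size, n_bins - 1)] = HET
        # callable bp per bin via cumulative coverage of the mask
        cov = np.zeros(n_bins)
        for start, end in mask.intervals.get(name, np.zeros((0, 2), dtype=np.int64)):
            b0, b1 = start // bin_size, (end - 1) // bin_size
            if b0 == b1:
                cov[b0] += end - start
                continue
            cov[b0] += (b0 + 1) * bin_size - start
            cov[b1] += end - b1 * bin_size
            if b1 > b0 + 1:
                cov[b0 + 1 : b1] += bin_size
        spans = np.full(n_bins, bin_size, dtype=np.int64)
        spans[-1] = length - (n_bins - 1) * bin_size
        sym[cov <= 0.5 * spans] = MISSING
        symbols[name] = sym
    return BinSequence(symbols=symbols, bin_size=bin_size)


def binarize(
    g: GenotypeTable,
    sample: str,
    mask: CallableMask,
    bin_size: int = 100,
    min_depth: int = 0,
) -> BinSequence:
    """Binarize one diploid's heterozygosity track (phase-free)."""
    si = g.sample_index(sample)
    het = {}
    for name, sg in g.scaffolds.items():
        gt = sg.gt[:, si, :]
        ok = np.all(gt >= 0, axis=1)
        if min_depth and sg.depth is not None:
            ok &= sg.depth[:, si] >= min_depth
        is_het = ok & (gt.min(axis=1) != gt.max(axis=1))
        in_mask = mask.contains(name, sg.pos - 1)
        het[name] = sg.pos[is_het & in_mask]
    return binarize_positions(het, mask, g.scaffold_lengths, bin_size)


_SYMBOL_CHARS = np.array(["0", "1", "."])  # hom, het, missing


def write_bin_sequence(seqs: BinSequence, path) -> None:
    """Plain-text BinSequence: per scaffold a ``>name`` header then one
    symbol character per bin ('0' hom, '1' het, '.' missing)."""
    with open(path, "w") as fh:
        fh.write(f"#bin_size={seqs.bin_size}\n")
        for name, sym in seqs.symbols.items():
            fh.write(f">{name}\n")
            fh.write("".join(_SYMBOL_CHARS[sym]) + "\n")


def read_bin_sequence(path) -> BinSequence:
    decode = {"0": HOM, "1": HET, ".": MISSING}
    bin_size = None
    symbols: dict[str, np.ndarray] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#bin_size="):
                bin_size = int(line.split("=", 1)[1])
            elif line.startswith(">"):
                name = line[1:]
            elif name is not None:
                symbols[name] = np.array([decode[c] for c in line], dtype=np.int8)
    if bin_size is None:
        raise ValueError("missing #bin_size header")
    return BinSequence(symbols=symbols, bin_size=bin_size)


# ---------------------------------------------------------------------------
# HMM internals


@njit(cache=True)
def _forward(sym, pi, A, E):
    T = sym.shape[0]
    K = pi.shape[0]
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * E[sym[0]]
    s = a.sum()
    alpha[0] = a / s
    c[0] = s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * E[sym[t]]
        s = a.sum()
        alpha[t] = a / s
        c[t] = s
    return alpha, c


@njit(cache=True)
def _backward(sym, A, E, c):
    T = sym.shape[0]
    K = A.shape[0]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (E[sym[t + 1]] * beta[t + 1])) / c[t + 1]
    return beta


def _hazard_cumsum(b: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Cumulative hazard at boundaries; H[-1] = inf (open last interval)."""
    K = len(lam)
    H = np.zeros(K + 1)
    H[1:K] = np.cumsum(lam[: K - 1] * np.diff(b)[: K - 1])
    H[K] = np.inf
    return H


def equilibrium_distribution(b: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P(TMRCA in interval k) under piecewise-constant intensities."""
    K = len(lam)
    H = _hazard_cumsum(b, lam)
    d = np.diff(b)
    pi = np.empty(K)
    pi[: K - 1] = np.exp(-H[: K - 1]) * -np.expm1(-lam[: K - 1] * d[: K - 1])
    pi[K - 1] = np.exp(-H[K - 1])
    return pi


def representative_times(b: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Conditional mean TMRCA within each interval, last interval open."""
    K = len(lam)
    d = np.diff(b)
    t = np.empty(K)
    for k in range(K - 1):
        ld = lam[k] * d[k]
        t[k] = b[k] + 1.0 / lam[k] - d[k] * np.exp(-ld) / -np.expm1(-ld)
    t[K - 1] = b[K - 1] + 1.0 / lam[K - 1]
    return t


def build_transition(
    b: np.ndarray, lam: np.ndarray, rho: float, t_rep: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized transition matrix and prior; rows sum to 1.

    Conditional on a recombination at u ~ U(0, t_k), the floating lineage
    re-coalesces at piecewise-exponential hazard lambda(s), s > u; the
    integrals over u within each interval are closed-form.
    """
    K = len(lam)
    d = np.diff(b).astype(float)
    H = _hazard_cumsum(b, lam)
    pi = equilibrium_distribution(b, lam)

    # S[j, l] = P(survive from b_{j+1} to b_l, then coalesce in interval l), l > j
    coal_in = np.empty(K)
    coal_in[: K - 1] = -np.expm1(-lam[: K - 1] * d[: K - 1])
    coal_in[K - 1] = 1.0
    upper = np.arange(K)[None, :] > np.arange(K)[:, None]
    with np.errstate(invalid="ignore", over="ignore"):
        M = H[None, :K] - H[1:, None]  # H[l] - H[j+1]; >= 0 where l > j
        S = np.where(upper, np.exp(-np.where(upper, M, 0.0)) * coal_in[None, :], 0.0)

    # u-integrals per start state k (rows) and start interval j (cols)
    c = np.minimum(b[None, 1:], t_rep[:, None])
    w = np.maximum(c - b[None, :-1], 0.0)
    active = w > 0
    lam_row = lam[None, :]
    with np.errstate(over="ignore"):
        E = (np.exp(-lam_row * (b[None, 1:] - c)) - np.exp(-lam_row * d[None, :])) / lam_row
    E[:, K - 1] = 0.0  # survival past the open-ended last interval is 0
    E = np.where(active, E, 0.0)
    R = (w - E) * active + E @ S
    R /= t_rep[:, None]
    p_stay = np.exp(-rho * t_rep)
    A = np.diag(p_stay) + (1.0 - p_stay)[:, None] * R
    return A, pi


@dataclass
class SmcTrajectory:
    """Fitted discretized coalescence-intensity trajectory."""

    boundaries: np.ndarray  # K+1 boundaries in coalescent units (2*N0 gens)
    lam: np.ndarray  # per atomic interval
    groups: list[int]
    theta: float  # per-bin
    rho: float  # per-bin
    bin_size: int
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.lam <= 0):
            raise ValueError("coalescence intensities must be positive")

    def n0(self, mu: float) -> float:
        if self.theta <= 0:
            raise ValueError("zero theta; cannot scale")
        return self.theta / (4.0 * mu * self.bin_size)

    def group_slices(self) -> list[slice]:
        out, i = [], 0
        for gsize in self.groups:
            out.append(slice(i, i + gsize))
            i += gsize
        return out

    def group_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(left boundary per group, lambda per group)."""
        sl = self.group_slices()
        left = np.array([self.boundaries[s.start] for s in sl])
        lam = np.array([self.lam[s.start] for s in sl])
        return left, lam


def scale_trajectory(traj: SmcTrajectory, mu: float, gen_time: float):
    """Scale to real units: columns left/right time (years) and diploid Ne.

    N0 = theta/(4*mu*bin_size); time_years = t_coal * 2*N0 * gen_time;
    Ne(t) = N0 / lambda(t).  One row per parameter group.
    """
    import pandas as pd

    if mu <= 0 or gen_time <= 0:
        raise ValueError("mu and gen_time must be positive")
    n0 = traj.n0(mu)
    sl = traj.group_slices()
    left = np.array([traj.boundaries[s.start] for s in sl])
    right = np.array([traj.boundaries[s.stop] for s in sl])
    lam = np.array([traj.lam[s.start] for s in sl])
    return pd.DataFrame(
        {
            "left_years": left * 2 * n0 * gen_time,
            "right_years": right * 2 * n0 * gen_time,
            "left_coal": left,
            "right_coal": right,
            "lambda": lam,
            "Ne": n0 / lam,
        }
    )


def _expand(groups: list[int], lam_g: np.ndarray) -> np.ndarray:
    return np.repeat(lam_g, groups)


def _estep(seqs: list[np.ndarray], pi, A, E):
    """Forward-backward sufficient statistics summed over sequences."""
    K = A.shape[0]
    ll = 0.0
    c0 = np.zeros(K)
    C = np.zeros((K, K))
    counts = np.zeros((3, K))
    for sym in seqs:
        if len(sym) == 0:
            continue
        alpha, c = _forward(sym, pi, A, E)
        beta = _backward(sym, A, E, c)
        ll += float(np.sum(np.log(c)))
        gamma = alpha * beta
        c0 += gamma[0]
        for s in (HOM, HET):
            m = sym == s
            if m.any():
                counts[s] += gamma[m].sum(axis=0)
        X = alpha[:-1]
        Y = (E[sym[1:]] * beta[1:]) / c[1:, None]
        C += (X.T @ Y) * A
    return ll, c0, C, counts


def _mstep_theta(counts: np.ndarray, t_rep: np.ndarray, theta: float) -> float:
    from scipy.optimize import minimize_scalar

    H, N = counts[HET], counts[HOM]

    def neg(logth):
        th = np.exp(logth)
        p = -np.expm1(-th * t_rep)
        return -(np.sum(H * np.log(np.maximum(p, 1e-300))) - th * np.sum(N * t_rep))

    res = minimize_scalar(neg, bounds=(np.log(theta) - 3, np.log(theta) + 3), method="bounded")
    return float(np.exp(res.x))


def _mstep_lambda(b, groups, lam_g, rho, t_rep, c0, C) -> np.ndarray:
    from scipy.optimize import minimize

    def neg(x):
        lam = _expand(groups, np.exp(x))
        A, pi = build_transition(b, lam, rho, t_rep)
        with np.errstate(divide="ignore"):
            q = np.sum(c0 * np.log(np.maximum(pi, 1e-300)))
            q += np.sum(C * np.log(np.maximum(A, 1e-300)))
        return -q

    x0 = np.log(lam_g)
    res = minimize(
        neg, x0, method="L-BFGS-B", bounds=[(-6, 6)] * len(lam_g), options={"maxiter": 40}
    )
    # EM requires a non-decreasing Q; fall back to the current point if the
    # optimizer terminated somewhere worse (can happen at bound corners)
    if neg(res.x) > neg(x0):
        return lam_g
    return np.exp(res.x)


def fit_smc(
    seqs: BinSequence, cfg: SmcConfig | None = None, seed: int | None = None
) -> SmcTrajectory:
    """Fit the coalescent HMM by Baum-Welch EM.

    Deterministic given inputs (the seed is accepted for interface symmetry
    but the fit involves no randomness).  Raises on inputs with too few
    usable bins or no heterozygous bin at all.
    """
    cfg = cfg or SmcConfig()
    if seqs.bin_size != cfg.bin_size:
        raise ValueError("BinSequence bin_size disagrees with config")
    n_obs = sum(int(np.sum(s != MISSING)) for s in seqs.symbols.values())
    if n_obs < cfg.min_bins:
        raise ValueError(f"only {n_obs} non-missing bins; need >= {cfg.min_bins}")
    hf = seqs.het_fraction()
    if hf == 0:
        raise ValueError("no heterozygous bins; degenerate input")

    n_atomic, groups = parse_interval_pattern(cfg.pattern)
    b = time_boundaries(n_atomic, cfg.t_max)
    theta = cfg.theta_init if cfg.theta_init is not None else hf / (1.0 - hf)
    rho = cfg.rho_init if cfg.rho_init is not None else 0.5 * theta
    lam_g = np.ones(len(groups))
    lam = _expand(groups, lam_g)
    t_rep = representative_times(b, lam)  # fixed through EM

    sym_list = [s for s in seqs.symbols.values() if len(s)]
    trace: list[float] = []
    for _ in range(cfg.max_iters):
        A, pi = build_transition(b, lam, rho, t_rep)
        E = np.empty((3, n_atomic))
        E[HOM] = np.exp(-theta * t_rep)
        E[HET] = -np.expm1(-theta * t_rep)
        E[MISSING] = 1.0
        ll, c0, C, counts = _estep(sym_list, pi, A, E)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol * abs(trace[-2]):
            break
        theta = _mstep_theta(counts, t_rep, theta)
        lam_g = _mstep_lambda(b, groups, lam_g, rho, t_rep, c0, C)
        lam = _expand(groups, lam_g)

    return SmcTrajectory(
        boundaries=b,
        lam=lam,
        groups=groups,
        theta=theta,
        rho=rho,
        bin_size=cfg.bin_size,
        loglik_trace=trace,
    )


def bootstrap(
    seqs: BinSequence,
    cfg: SmcConfig | None = None,
    n_reps: int = 20,
    segment: int = 5_000_000,
    seed: int = 1,
    resample: bool = True,
) -> list[SmcTrajectory]:
    """Block bootstrap: resample fixed-length segments with replacement.

    The genome is cut into ``segment``-bp pieces (each becoming its own
    sequence, so no artificial junction transitions are introduced) and
    resampled to the original piece count; one fit per replicate.
    With ``resample=False`` each replicate fits the original data.
    """
    from .core import derive_seed

    cfg = cfg or SmcConfig()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seg_bins = max(1, segment // cfg.bin_size)
    pieces = []
    for s in seqs.symbols.values():
        for i in range(0, len(s), seg_bins):
            pieces.append(s[i : i + seg_bins])
    if not pieces:
        raise ValueError("no data to resample")
    if segment // cfg.bin_size > sum(len(s) for s in seqs.symbols.values()):
        raise ValueError("segment longer than the genome")
    out = []
    for rep in range(n_reps):
        if resample:
            rng = np.random.default_rng(derive_seed(seed, "bootstrap", rep))
            idx = rng.integers(0, len(pieces), size=len(pieces))
            rep_seq = BinSequence(
                symbols={f"seg{j}": pieces[i] for j, i in enumerate(idx)}, bin_size=cfg.bin_size
            )
        else:
            rep_seq = seqs
        out.append(fit_smc(rep_seq, cfg))
    return out
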