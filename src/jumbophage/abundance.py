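"""Coverage-based abundance and the SparCC-style co-abundance network.

Per genome and sample, abundance is the mean read depth, zeroed when breadth
of coverage (fraction of positions with depth ≥ 1) is ≤ 0.25 — i.e. when
the sample covers < 1× across ≥ 75 % of the genome.  Basis correlations are
inferred from the compositional count matrix with the SparCC procedure
(log-ratio variances, basis-variance linear system, iterative strong-pair
exclusion, median over Dirichlet resamples); significance comes from a
permutation bootstrap (default 1,000 iterations) and only pairs with
p < 0.001 enter the signed network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .io import CoverageTrack


@dataclass
class AbundanceMatrix:
    genome_ids: list[str]
    sample_ids: list[str]
    mean_depth: np.ndarray     # zero-ruled means, genomes × samples
    breadth: np.ndarray
    zeroed: np.ndarray         # boolean


@dataclass
class CorrelationNetwork:
    pairs: list[tuple[int, int, float, float, int]]  # (i, j, rho, p, sign)
    n_positive: int
    n_negative: int


def compute_abundance(track: CoverageTrack,
                      config: RunConfig = DEFAULT_CONFIG
                      ) -> tuple[float, float, bool]:
    """(mean depth, breadth, zeroed) for one genome in one sample.

    Zeroed iff breadth ≤ 0.25 (boundary inclusive: exactly 75 % uncovered
    still zeroes); the reported mean depth is then 0.
    """
    d = track.depth
    if d.size == 0:
        raise ValueError("empty coverage vector")
    breadth = float((d >= 1).mean())
    zeroed = breadth <= config.breadth_zero_max
    mean_depth = 0.0 if zeroed else float(d.mean())
    return mean_depth, breadth, zeroed


def abundance_matrix(tracks: list[CoverageTrack],
                     config: RunConfig = DEFAULT_CONFIG) -> AbundanceMatrix:
    """Assemble the zero-ruled genome × sample mean-depth matrix."""
    genomes = sorted({t.genome_id for t in tracks})
    samples = sorted({t.sample_id for t in tracks})
    gi = {g: i for i, g in enumerate(genomes)}
    si = {s: i for i, s in enumerate(samples)}
    mean = np.zeros((len(genomes), len(samples)))
    breadth = np.zeros_like(mean)
    zeroed = np.ones(mean.shape, dtype=bool)
    for t in tracks:
        m, b, z = compute_abundance(t, config)
        mean[gi[t.genome_id], si[t.sample_id]] = m
        breadth[gi[t.genome_id], si[t.sample_id]] = b
        zeroed[gi[t.genome_id], si[t.sample_id]] = z
    return AbundanceMatrix(genomes, samples, mean, breadth, zeroed)


def to_pseudocounts(mean_depth: np.ndarray,
                    config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Scale the zero-ruled mean-depth matrix to integer pseudo-counts so
    Dirichlet resampling is defined (×100, rounded)."""
    return np.rint(np.asarray(mean_depth) *
                   config.abundance_pseudocount_scale).astype(np.int64)


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var(log(x_i / x_j)) over samples; fractions is samples × taxa."""
    logf = np.log(fractions)
    d = logf.shape[1]
    v = np.var(logf, axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False, ddof=1)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _basis_correlations(t: np.ndarray, exclusion_threshold: float,
                        exclusion_rounds: int) -> np.ndarray:
    """Solve the basis-variance system and iteratively exclude the strongest
    correlated pair above the threshold, re-solving each round."""
    d = t.shape[0]
    included = np.ones((d, d), dtype=bool)
    np.fill_diagonal(included, False)

    def solve() -> np.ndarray:
        m = included.astype(float)
        np.fill_diagonal(m, included.sum(axis=1))
        rhs = (t * included).sum(axis=1)
        omega = np.linalg.lstsq(m, rhs, rcond=None)[0]
        omega = np.maximum(omega, 1e-12)
        rho = (omega[:, None] + omega[None, :] - t) / \
            (2.0 * np.sqrt(omega[:, None] * omega[None, :]))
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = solve()
    for _ in range(exclusion_rounds):
        masked = np.where(np.triu(included, 1), np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        if included.sum(axis=1).min() <= 2:   # keep the system solvable
            break
        included[i, j] = included[j, i] = False
        rho = solve()
    return rho


def sparcc_correlations(counts: np.ndarray,
                        n_estimation_iters: int | None = None,
                        exclusion_threshold: float | None = None,
                        seed: int | None = None,
                        config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """SparCC basis correlation matrix (taxa × taxa) from a count matrix
    (taxa × samples).

    Per estimation iteration, sample-wise fractions are drawn from a
    Dirichlet(counts + 1) posterior; the final ρ is the element-wise median
    over iterations.  Taxa with identical counts in every sample carry no
    compositional signal; their correlations are reported as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    d, s = counts.shape
    if d < 3:
        raise ValueError("correlation inference needs >= 3 taxa")
    if s < 3:
        raise ValueError("correlation inference needs >= 3 samples")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    iters = n_estimation_iters or config.sparcc_estimation_iters
    thr = exclusion_threshold if exclusion_threshold is not None \
        else config.sparcc_exclusion_threshold
    rng = np.random.default_rng(config.seed if seed is None else seed)
    constant = np.array([np.ptp(row) == 0 for row in counts])
    rhos = np.empty((iters, d, d))
    for it in range(iters):
        fractions = _dirichlet_fractions(counts, rng)
        t = _log_ratio_variances(fractions)
        rhos[it] = _basis_correlations(t, thr, config.sparcc_exclusion_rounds)
    rho = np.median(rhos, axis=0)
    if constant.any():
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
        np.fill_diagonal(rho, 1.0)
    return rho


def _dirichlet_fractions(counts: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-sample Dirichlet(counts + 1) draw → samples × taxa fractions."""
    gamma = rng.gamma(shape=counts.T + 1.0)    # samples × taxa
    return gamma / gamma.sum(axis=1, keepdims=True)


def bootstrap_pvalues(counts: np.ndarray, observed_rho: np.ndarray,
                      n_boot: int | None = None, seed: int | None = None,
                      config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Permutation bootstrap: each taxon's counts are shuffled independently
    across samples, ρ is recomputed (single estimation iteration) and
    p_ij = #{|ρ_boot| ≥ |ρ_obs|} / n_boot.

    With the default strict estimator, p < 0.001 at n_boot = 1000 requires
    zero exceedances; the (count+1)/(n+1) estimator is available via
    ``config.pvalue_add_one``.  The diagonal is NaN (undefined).
    """
    counts = np.asarray(counts, dtype=float)
    n_boot = config.n_bootstrap if n_boot is None else n_boot
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    d, s = counts.shape
    rng = np.random.default_rng(config.seed if seed is None else seed)
    exceed = np.zeros((d, d))
    obs = np.abs(observed_rho)
    for _ in range(n_boot):
        perm = np.empty_like(counts)
        for i in range(d):
            perm[i] = counts[i, rng.permutation(s)]
        fractions = _dirichlet_fractions(perm, rng)
        t = _log_ratio_variances(fractions)
        rho_b = _basis_correlations(t, config.sparcc_exclusion_threshold,
                                    config.sparcc_exclusion_rounds)
        exceed += (np.abs(rho_b) >= obs)
    if config.pvalue_add_one:
        p = (exceed + 1.0) / (n_boot + 1.0)
    else:
        p = exceed / n_boot
    np.fill_diagonal(p, np.nan)
    return p


def build_coabundance_network(rho: np.ndarray, p: np.ndarray,
                              cutoff: float | None = None,
                              config: RunConfig = DEFAULT_CONFIG
                              ) -> CorrelationNetwork:
    """Retain pairs with p < cutoff (default 0.001); sign by ρ."""
    cutoff = config.p_cutoff if cutoff is None else cutoff
    d = rho.shape[0]
    pairs = []
    n_pos = n_neg = 0
    for i in range(d):
        for j in range(i + 1, d):
            if np.isnan(p[i, j]) or np.isnan(rho[i, j]):
                continue
            if p[i, j] < cutoff:
                sign = 1 if rho[i, j] > 0 else -1
                pairs.append((i, j, float(rho[i, j]), float(p[i, j]), sign))
                if sign > 0:
                    n_pos += 1
                else:
                    n_neg += 1
    return CorrelationNetwork(pairs=pairs, n_positive=n_pos, n_negative=n_neg)
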