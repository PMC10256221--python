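"""Independent mutation-rate estimators and the two-locus epistasis check.

These single-locus baselines validate the joint genotype-class inference:

* the premature-stop-codon bound — under mutation-selection balance the
  frequency of lethal variants equals their mutation rate, so the observed
  premature-stop frequency (inflated by sequencing errors) upper-bounds the
  rate;
* a single-locus neutral rejection-sampling estimator applied to synonymous
  SNV trajectories, assuming neutrality and Wright-Fisher dynamics;
* a two-locus bi-allelic Wright-Fisher simulation used to ask whether the
  scarcity of double mutants among strongly beneficial SNVs can be explained
  without epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import PosteriorSamples
from .model import ParameterError


# ---------------------------------------------------------------------------
# premature stop codons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StopCodonCensus:
    """Counts entering the premature-stop-codon mutation-rate bound."""

    n_reads: int
    n_premature_stop_observations: int  # summed over reads and sites
    n_possible_stop_snvs: int           # (site, alt) pairs creating a premature stop
    genome_length: int

    def __post_init__(self):
        if min(self.n_reads, self.n_premature_stop_observations,
               self.n_possible_stop_snvs, self.genome_length) < 0:
            raise ParameterError("census counts must be non-negative")


def premature_stop_upper_bound(census: StopCodonCensus) -> float:
    """Upper bound on the genome-wide mutation rate from premature stops.

    The mean frequency per possible stop-creating SNV is
    stops / (reads * possible-stop SNVs); scaled by the genome length this
    bounds the genome-wide rate.  It is an upper bound because sequencing
    errors are indistinguishable from genuine premature stops.
    """
    if census.n_reads < 1:
        raise ParameterError("need at least one read")
    if census.n_possible_stop_snvs == 0:
        raise ParameterError("no possible premature-stop SNVs in a coding genome")
    per_site = census.n_premature_stop_observations / (
        census.n_reads * census.n_possible_stop_snvs)
    return per_site * census.genome_length


def simulate_stop_codon_census(
    n_reads: int,
    n_possible_stop_snvs: int,
    genome_length: int,
    snv_error_rate: float,
    seed,
    per_snv_mutant_frequency: float = 0.0,
) -> StopCodonCensus:
    """Synthetic census for validating the stop-codon bound.

    Each possible stop-creating SNV appears on a read independently with
    probability ``snv_error_rate`` (per-read, per possible SNV — the chance a
    site is misread as that specific alternative base) plus any genuine
    population frequency ``per_snv_mutant_frequency``.
    """
    rng = np.random.default_rng(seed)
    p = min(1.0, snv_error_rate + per_snv_mutant_frequency)
    stops = int(rng.binomial(n_reads * n_possible_stop_snvs, p))
    return StopCodonCensus(n_reads, stops, n_possible_stop_snvs, genome_length)


# ---------------------------------------------------------------------------
# single-locus neutral estimator (rejection sampling over per-site rates)
# ---------------------------------------------------------------------------

def simulate_neutral_trajectories(
    mu: float, N: int, passages, n_loci: int, rng,
    generations_per_passage: int = 1,
) -> np.ndarray:
    """Neutral single-locus Wright-Fisher trajectories (derived-allele freq).

    Starts from frequency 0 at every locus; each replication cycle the
    derived-allele frequency moves to Binomial(N, f + mu (1 - f)) / N (forward
    mutation only, no selection).  Returns an (n_loci, len(passages)) matrix
    of frequencies at the requested passages.
    """
    passages = sorted(passages)
    f = np.zeros(n_loci)
    out = np.empty((n_loci, len(passages)))
    j = 0
    for t in range(1, passages[-1] + 1):
        for _ in range(generations_per_passage):
            p = f + mu * (1.0 - f)
            f = rng.binomial(N, p) / N
        if t == passages[j]:
            out[:, j] = f
            j += 1
    return out


def single_locus_neutral_estimator(
    trajectories: np.ndarray,
    passages,
    N: int,
    rate_log10_bounds: tuple = (-8.0, -2.0),
    n_sims: int = 2000,
    epsilon: float = 0.01,
    seed=0,
    genome_length: int = 3569,
    pool_loci: bool = True,
) -> PosteriorSamples:
    """Rejection-sampling posterior for the mutation rate from neutral loci.

    Candidate per-site rates are drawn log10-uniformly from
    ``rate_log10_bounds``; for each candidate, neutral single-locus
    trajectories are simulated for every locus and compared to the observed
    ``trajectories`` (loci x passages frequency matrix) by RMSE pooled over
    loci and passages.  The lowest ``epsilon`` fraction of candidates is
    accepted.  Returned draws are genome-wide rates (per-site rate times
    ``genome_length``) under the parameter name "U".

    With ``pool_loci=False`` the distance is computed per locus and a
    candidate is accepted if it falls in the lowest epsilon-percentile for
    the median locus — a coarser, per-locus pooling alternative.
    """
    trajectories = np.atleast_2d(np.asarray(trajectories, float))
    n_loci = trajectories.shape[0]
    if n_loci < 1:
        raise ValueError("need at least one trajectory")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rate_rng = np.random.default_rng(ss.spawn(1)[0])
    mus = 10.0 ** rate_rng.uniform(*rate_log10_bounds, size=n_sims)
    children = ss.spawn(n_sims)
    dists = np.empty(n_sims)
    for i, mu in enumerate(mus):
        sim = simulate_neutral_trajectories(
            mu, N, passages, n_loci, np.random.default_rng(children[i]))
        err2 = (sim - trajectories) ** 2
        if pool_loci:
            dists[i] = np.sqrt(err2.mean())
        else:
            dists[i] = np.median(np.sqrt(err2.mean(axis=1)))
    n_accept = max(1, int(round(epsilon * n_sims)))
    accepted = np.argsort(dists, kind="stable")[:n_accept]
    return PosteriorSamples(
        (mus[accepted] * genome_length)[:, None], ("U",),
        provenance={"method": "single-locus-neutral", "n_sims": n_sims,
                    "epsilon": epsilon, "n_loci": n_loci},
    )


# ---------------------------------------------------------------------------
# lethal mutation-selection balance
# ---------------------------------------------------------------------------

def lethal_balance_frequencies(mu: float, N: int, n_generations: int, seed) -> np.ndarray:
    """Observed lethal-allele frequency per generation at mutation-selection balance.

    Lethal carriers leave no offspring, so each generation's parents are all
    wildtype; new offspring carry the lethal allele with probability ``mu``.
    The censused (pre-selection) frequency therefore fluctuates around mu —
    the equality underpinning the stop-codon bound.
    """
    rng = np.random.default_rng(seed)
    return rng.binomial(N, mu, size=n_generations) / N


# ---------------------------------------------------------------------------
# two-locus bi-allelic check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoLocusConfig:
    """Two-locus bi-allelic Wright-Fisher model without epistasis."""

    N: int = 20_000_000
    mu: float = 5.6e-5            # per-locus, per-replication-cycle
    s1: float = 0.8               # selection coefficient of beneficial allele 1
    s2: float = 0.8
    n_generations: int = 10
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.mu <= 1):
            raise ParameterError("mutation rate must be in [0, 1]")
        if self.N < 1:
            raise ParameterError("N must be >= 1")


@dataclass
class TwoLocusReport:
    """Distribution of the double-mutant haplotype frequency without epistasis."""

    double_mutant_freqs: np.ndarray      # final-generation x11 across replicates
    observed_pair_frequency: float
    observed_quantile: float             # P(simulated x11 <= observed)
    mean_double: float
    mean_product_of_singles: float       # E[F(X) F(Y)] at the final generation


def _two_locus_generation(x: np.ndarray, cfg: TwoLocusConfig, rng) -> np.ndarray:
    """One generation for haplotype frequencies x = (x00, x01, x10, x11) batched."""
    mu = cfg.mu
    x00, x01, x10, x11 = x.T
    # forward mutation at each wildtype allele, independent across loci
    y00 = x00 * (1 - mu) ** 2
    y01 = x01 * (1 - mu) + x00 * (1 - mu) * mu
    y10 = x10 * (1 - mu) + x00 * mu * (1 - mu)
    y11 = x11 + x01 * mu + x10 * mu + x00 * mu * mu
    y = np.stack([y00, y01, y10, y11], axis=1)
    w = np.array([1.0, 1.0 + cfg.s2, 1.0 + cfg.s1, (1.0 + cfg.s1) * (1.0 + cfg.s2)])
    y = y * w
    y /= y.sum(axis=1, keepdims=True)
    counts = rng.multinomial(cfg.N, y)
    return counts / cfg.N


def two_locus_deterministic(cfg: TwoLocusConfig) -> np.ndarray:
    """Infinite-N recursion (mutation + selection, no drift) — an exact oracle."""
    x = np.array([[1.0, 0.0, 0.0, 0.0]])
    w = np.array([1.0, 1.0 + cfg.s2, 1.0 + cfg.s1, (1.0 + cfg.s1) * (1.0 + cfg.s2)])
    mu = cfg.mu
    for _ in range(cfg.n_generations):
        x00, x01, x10, x11 = x[0]
        y = np.array([[
            x00 * (1 - mu) ** 2,
            x01 * (1 - mu) + x00 * (1 - mu) * mu,
            x10 * (1 - mu) + x00 * mu * (1 - mu),
            x11 + x01 * mu + x10 * mu + x00 * mu * mu,
        ]])
        y = y * w
        x = y / y.sum()
    return x[0]


def two_locus_no_epistasis_check(
    config: TwoLocusConfig, observed_pair_frequency: float,
) -> TwoLocusReport:
    """Can drift + strong selection alone explain the observed double-mutant rarity?

    Simulates ``n_reps`` replicate populations of the no-epistasis two-locus
    model and reports where the observed double-mutant haplotype frequency
    falls in the simulated final-generation distribution.
    """
    rng = np.random.default_rng(config.seed)
    x = np.zeros((config.n_reps, 4))
    x[:, 0] = 1.0
    for _ in range(config.n_generations):
        x = _two_locus_generation(x, config, rng)
    x11 = x[:, 3]
    f1 = x[:, 2] + x[:, 3]   # F(X): allele-1 frequency
    f2 = x[:, 1] + x[:, 3]   # F(Y)
    return TwoLocusReport(
        double_mutant_freqs=x11,
        observed_pair_frequency=observed_pair_frequency,
        observed_quantile=float((x11 <= observed_pair_frequency).mean()),
        mean_double=float(x11.mean()),
        mean_product_of_singles=float((f1 * f2).mean()),
    )
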