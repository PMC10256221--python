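"""Genotype-class Wright-Fisher model for a serially passaged virus population.

Genomes are grouped into *genotype classes*: 6-tuples

    k = (k_Is, k_Ins, k_s, k_ns, k_bs, k_bns)

counting founder synonymous, founder non-synonymous, de-novo non-beneficial
synonymous, de-novo non-beneficial non-synonymous, beneficial synonymous and
beneficial non-synonymous SNVs carried by a genome.  SNVs of the same type are
exchangeable and share a fitness effect, so the population state is a frequency
vector over classes rather than over the ~4^3500 possible haplotypes.

One generation is: mutation (convolution with a truncated Poisson-multinomial
kernel), selection (multiplicative fitness with an epistasis exponent acting on
genomes carrying >= 2 beneficial SNVs), and drift (multinomial resampling of N
virions).  Sequenced passages additionally pass through an observation layer:
a sequencing-error kernel of the same Poisson-multinomial form followed by
multinomial read sampling at the passage coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: number of components in a genotype-class tuple
N_CLASS_COMPONENTS = 6
#: bits per component in the packed integer encoding of a class tuple
_KEY_BITS = 8
# big-endian packing: sorting packed keys == lexicographic order of the tuples
_KEY_STRIDES = (np.int64(1) << (_KEY_BITS * np.arange(N_CLASS_COMPONENTS - 1, -1, -1,
                                                      dtype=np.int64)))


class ParameterError(ValueError):
    """Raised when model parameters violate their constraints."""


class DegeneratePopulationError(RuntimeError):
    """Raised when the population mean fitness collapses to zero."""


@dataclass(frozen=True)
class ModelParams:
    """The ten inferred model parameters.

    Parameters
    ----------
    w_s, w_ns
        Fitness multiplier per non-beneficial synonymous / non-synonymous SNV.
    w_b
        Fitness multiplier per beneficial SNV (synonymous or not).
    p_bs, p_bns
        Probability that a new SNV is beneficial-synonymous / beneficial-
        non-synonymous.
    M_s, M_ns
        Mean number of synonymous / non-synonymous SNVs per genome in the
        plaque-derived founder population.
    delta
        Correlation of founder-SNV log-fitness with the experimental
        log-fitness: 0 means founder SNVs are neutral in the experiment,
        1 means they behave like de-novo non-beneficial SNVs.
    eta
        Epistasis exponent applied to the beneficial-SNV count of genomes
        carrying at least two beneficial SNVs; eta < 0 is reciprocal sign
        epistasis (the combination is deleterious).
    U
        Genome-wide mutation rate, mutations per genome per replication cycle.
    """

    w_s: float
    w_ns: float
    w_b: float
    p_bs: float
    p_bns: float
    M_s: float
    M_ns: float
    delta: float
    eta: float
    U: float

    def validate(self, p_s: float) -> None:
        if min(self.w_s, self.w_ns, self.w_b) <= 0:
            raise ParameterError("fitness multipliers must be positive")
        if not (0 <= self.p_bs <= p_s):
            raise ParameterError(f"require 0 <= p_bs <= p_s; got p_bs={self.p_bs}")
        if not (0 <= self.p_bns <= 1 - p_s):
            raise ParameterError(f"require 0 <= p_bns <= 1 - p_s; got p_bns={self.p_bns}")
        if self.U < 0:
            raise ParameterError("mutation rate U must be non-negative")
        if self.M_s < 0 or self.M_ns < 0:
            raise ParameterError("founder SNV means must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_s, self.w_ns, self.w_b, self.p_bs, self.p_bns,
             self.M_s, self.M_ns, self.delta, self.eta, self.U]
        )

    @classmethod
    def from_array(cls, a) -> "ModelParams":
        return cls(*(float(x) for x in a))


PARAM_NAMES = ("w_s", "w_ns", "w_b", "p_bs", "p_bns", "M_s", "M_ns", "delta", "eta", "U")

#: parameters of a neutral, mutation-free model — handy in tests and checks
NEUTRAL_PARAMS = ModelParams(
    w_s=1.0, w_ns=1.0, w_b=1.0, p_bs=0.0, p_bns=0.0,
    M_s=0.0, M_ns=0.0, delta=0.0, eta=1.0, U=0.0,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fixed experimental conditions of a serial-passage run.

    Defaults follow the MS2 passaging experiment: population size N = 2e7
    virions, ten passages with passages 3, 7 and 10 sequenced, probability
    p_s = 0.28 that a random SNV is synonymous, and a long-read error rate
    of 5e-5 per base.  ``generations_per_passage`` defaults to one
    replication cycle per 120-minute passage.

    ``err_mean_mode`` selects the mean of the per-genome sequencing-error
    count: "as-printed" uses coverage * err_seq; "per-genome" uses
    genome_length * err_seq.
    """

    N: int = 20_000_000
    coverage: dict = field(default_factory=lambda: {3: 2589, 7: 2589, 10: 2589})
    p_s: float = 0.28
    err_seq: float = 5e-5
    n_passages: int = 10
    sequenced_passages: tuple = (3, 7, 10)
    generations_per_passage: int = 1
    err_mean_mode: str = "as-printed"
    genome_length: int = 3569
    max_snvs_per_component: int = 25

    def validate(self) -> None:
        if self.N < 1:
            raise ParameterError("population size N must be >= 1")
        if not (0 < self.p_s < 1):
            raise ParameterError("p_s must be in (0, 1)")
        if self.err_seq < 0:
            raise ParameterError("err_seq must be non-negative")
        if not set(self.sequenced_passages) <= set(range(1, self.n_passages + 1)):
            raise ParameterError("sequenced passages must be within 1..n_passages")
        for t in self.sequenced_passages:
            if self.coverage_at(t) < 1:
                raise ParameterError("coverage must be >= 1 at each sequenced passage")
        if self.err_mean_mode not in ("as-printed", "per-genome"):
            raise ParameterError(f"unknown err_mean_mode {self.err_mean_mode!r}")

    def coverage_at(self, passage: int) -> int:
        if isinstance(self.coverage, dict):
            return int(self.coverage[passage])
        return int(self.coverage)

    def error_mean(self, passage: int) -> float:
        """Mean per-genome sequencing-error count at a sequenced passage."""
        if self.err_mean_mode == "as-printed":
            return self.coverage_at(passage) * self.err_seq
        return self.genome_length * self.err_seq


def p_delta_vector(params: ModelParams, p_s: float) -> np.ndarray:
    """Mutation-type split p_Delta = (p_s - p_bs, p_ns - p_bns, p_bs, p_bns)."""
    v = np.array([p_s - params.p_bs, (1 - p_s) - params.p_bns, params.p_bs, params.p_bns])
    if (v < -1e-12).any():
        raise ParameterError("beneficial probabilities exceed their type probability")
    return np.clip(v, 0.0, None)


# ---------------------------------------------------------------------------
# class distributions
# ---------------------------------------------------------------------------

@dataclass
class ClassDistribution:
    """A frequency vector over genotype classes.

    ``classes`` is an (n, 6) integer array of class tuples and ``freq`` the
    matching frequencies.  ``mean_fitness`` is populated by the selection
    step.  Class tuples are unique within a distribution.
    """

    classes: np.ndarray
    freq: np.ndarray
    mean_fitness: float | None = None

    def __post_init__(self):
        self.classes = np.atleast_2d(np.asarray(self.classes, dtype=np.int64))
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.classes.shape != (self.freq.size, N_CLASS_COMPONENTS):
            raise ValueError("classes must be (n, 6) matching freq length")
        if (self.freq < 0).any():
            raise ValueError("frequencies must be non-negative")

    @classmethod
    def point_mass(cls, k=(0, 0, 0, 0, 0, 0)) -> "ClassDistribution":
        return cls(np.array([k], dtype=np.int64), np.array([1.0]))

    @classmethod
    def from_dict(cls, d: dict) -> "ClassDistribution":
        ks = np.array(sorted(d), dtype=np.int64)
        return cls(ks, np.array([d[tuple(k)] for k in ks.tolist()]))

    def as_dict(self) -> dict:
        return {tuple(k): float(f) for k, f in zip(self.classes.tolist(), self.freq)}

    def total(self) -> float:
        return float(self.freq.sum())

    def get(self, k) -> float:
        key = _encode(np.asarray(k, dtype=np.int64)[None, :])[0]
        hit = _encode(self.classes) == key
        return float(self.freq[hit].sum())

    def normalized(self) -> "ClassDistribution":
        s = self.freq.sum()
        if s <= 0:
            raise DegeneratePopulationError("distribution has zero total mass")
        return ClassDistribution(self.classes, self.freq / s, self.mean_fitness)

    def pruned(self, threshold: float = 0.0) -> "ClassDistribution":
        keep = self.freq > threshold
        return ClassDistribution(self.classes[keep], self.freq[keep], self.mean_fitness)


def _encode(classes: np.ndarray) -> np.ndarray:
    return classes.astype(np.int64) @ _KEY_STRIDES


def _decode(keys: np.ndarray) -> np.ndarray:
    out = np.empty((keys.size, N_CLASS_COMPONENTS), dtype=np.int64)
    for i in range(N_CLASS_COMPONENTS):
        shift = _KEY_BITS * (N_CLASS_COMPONENTS - 1 - i)
        out[:, i] = (keys >> shift) & ((1 << _KEY_BITS) - 1)
    return out


def _aggregate(keys: np.ndarray, mass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(keys, return_inverse=True)
    return _decode(uniq), np.bincount(inv, weights=mass, minlength=uniq.size)


# ---------------------------------------------------------------------------
# founder population
# ---------------------------------------------------------------------------

def founder_distribution(params: ModelParams, trunc: float = 1e-10) -> ClassDistribution:
    """Distribution of founder classes (k_Is, k_Ins, 0, 0, 0, 0).

    The founder SNV count is M ~ Poisson(M_s + M_ns) split binomially into
    synonymous and non-synonymous SNVs, which is equivalent to independent
    Poisson counts with means M_s and M_ns.  The founder population carries
    no beneficial SNVs.  Probabilities below ``trunc`` are dropped and the
    remainder renormalized.
    """
    if params.M_s < 0 or params.M_ns < 0:
        raise ParameterError("founder SNV means must be non-negative")
    ps = _truncated_poisson_pmf(params.M_s, trunc)
    pns = _truncated_poisson_pmf(params.M_ns, trunc)
    joint = np.outer(ps, pns)
    kis, kins = np.nonzero(joint >= trunc) if joint.size > 1 else (np.array([0]), np.array([0]))
    mass = joint[kis, kins]
    if mass.size == 0:  # pathological trunc; keep the modal class
        kis, kins = np.array([0]), np.array([0])
        mass = joint[:1, 0]
    classes = np.zeros((mass.size, N_CLASS_COMPONENTS), dtype=np.int64)
    classes[:, 0] = kis
    classes[:, 1] = kins
    return ClassDistribution(classes, mass / mass.sum())


def _truncated_poisson_pmf(mean: float, trunc: float) -> np.ndarray:
    if mean == 0:
        return np.ones(1)
    kmax = int(stats.poisson.isf(min(trunc, 0.1) / 10, mean)) + 2
    return stats.poisson.pmf(np.arange(kmax + 1), mean)


# ---------------------------------------------------------------------------
# mutation kernel
# ---------------------------------------------------------------------------

def mutation_kernel_mass(delta, U: float, p_delta, N: int) -> float:
    """Probability of a mutation-count increment Delta = (ds, dns, dbs, dbns).

    The total number of new SNVs is Poisson(U) and is split multinomially with
    probabilities p_Delta, so the joint mass factorizes into independent
    Poisson masses with means U * p_Delta_i.  Masses below 1/(100 N) are
    truncated to exactly zero.
    """
    delta = np.asarray(delta)
    p_delta = np.asarray(p_delta, dtype=float)
    if U < 0:
        raise ParameterError("U must be non-negative")
    if abs(p_delta.sum() - 1.0) > 1e-9:
        raise ParameterError("p_delta must sum to 1")
    mass = float(np.prod(stats.poisson.pmf(delta, U * p_delta)))
    return mass if mass >= 1.0 / (100 * N) else 0.0


def build_mutation_kernel(U: float, p_delta, threshold: float):
    """All increments Delta with untruncated mass >= threshold.

    Returns ``(deltas, mass)`` with deltas an (m, 4) integer array.  Built by
    progressively crossing the four independent Poisson components and
    filtering at ``threshold`` after each cross; exact because each factor is
    at most 1, so every prefix product of a surviving tuple also clears the
    threshold.
    """
    p_delta = np.asarray(p_delta, dtype=float)
    means = U * p_delta
    deltas = np.zeros((1, 0), dtype=np.int64)
    mass = np.ones(1)
    for m in means:
        pm = _poisson_upto(m, threshold)
        new_mass = (mass[:, None] * pm[None, :]).ravel()
        keep = new_mass >= threshold
        vals = np.arange(pm.size, dtype=np.int64)
        new_deltas = np.concatenate(
            [np.repeat(deltas, pm.size, axis=0),
             np.tile(vals, deltas.shape[0])[:, None]], axis=1)
        deltas, mass = new_deltas[keep], new_mass[keep]
    if mass.size == 0:  # threshold above the modal mass: keep the mode
        deltas = np.floor(means)[None, :].astype(np.int64)
        mass = np.array([float(np.prod(stats.poisson.pmf(deltas[0], means)))])
    return deltas, mass


def _poisson_upto(mean: float, threshold: float) -> np.ndarray:
    if mean == 0:
        return np.ones(1)
    kmax = max(int(stats.poisson.isf(min(threshold, 0.5) / 4, mean)) + 2, 1)
    pm = stats.poisson.pmf(np.arange(kmax + 1), mean)
    last = np.nonzero(pm >= threshold)[0]
    return pm[: last[-1] + 1] if last.size else pm[:1]


def apply_mutation(
    dist: ClassDistribution,
    params: ModelParams,
    config: ExperimentConfig,
    kernel=None,
) -> ClassDistribution:
    """One round of mutation: convolve with the truncated Poisson-multinomial kernel.

    Mutation only increases the de-novo components (k_s, k_ns, k_bs, k_bns);
    founder counts are untouched.  Mass lost to kernel truncation is
    redistributed by renormalization and logged.  Components are capped at
    ``config.max_snvs_per_component`` (classes beyond the cap are merged into
    the cap, with a warning).
    """
    if params.U == 0:
        return ClassDistribution(dist.classes, dist.freq.copy())
    threshold = 1.0 / (100 * config.N)
    if kernel is None:
        kernel = build_mutation_kernel(params.U, p_delta_vector(params, config.p_s), threshold)
    deltas, kmass = kernel
    delta6 = np.zeros((deltas.shape[0], N_CLASS_COMPONENTS), dtype=np.int64)
    delta6[:, 2:] = deltas
    cap = config.max_snvs_per_component
    overflow = (dist.classes[:, 2:].max(axis=0, initial=0)
                + deltas.max(axis=0, initial=0) > cap).any()
    if overflow:
        logger.warning("genotype-class components exceeded the cap of %d; clipping", cap)
        new_classes = np.minimum(dist.classes[:, None, :] + delta6[None, :, :], cap)
        keys = _encode(new_classes.reshape(-1, N_CLASS_COMPONENTS))
    else:
        keys = (_encode(dist.classes)[:, None] + _encode(delta6)[None, :]).ravel()
    mass = (dist.freq[:, None] * kmass[None, :]).ravel()
    classes, freq = _aggregate(keys, mass)
    lost = 1.0 - freq.sum()
    if lost > 1e-12:
        logger.debug("mutation kernel truncation lost %.3e probability mass", lost)
    out = ClassDistribution(classes, freq).normalized()
    # same truncation rule applied to the class distribution itself: classes
    # below 1/(100N) have expected multinomial count < 0.01 at the drift step
    out = out.pruned(threshold).normalized()
    return out


# ---------------------------------------------------------------------------
# selection and drift
# ---------------------------------------------------------------------------

def class_fitness(k, params: ModelParams) -> np.ndarray | float:
    """Multiplicative fitness of genotype class(es) ``k``.

    w = w_s^(delta*k_Is + k_s) * w_ns^(delta*k_Ins + k_ns) * w_b^(e*(k_bs+k_bns))
    with e = eta when k_bs + k_bns >= 2 and e = 1 otherwise.
    """
    k = np.asarray(k, dtype=np.float64)
    scalar = k.ndim == 1
    k = np.atleast_2d(k)
    nb = k[:, 4] + k[:, 5]
    e = np.where(nb >= 2, params.eta, 1.0)
    w = (
        params.w_s ** (params.delta * k[:, 0] + k[:, 2])
        * params.w_ns ** (params.delta * k[:, 1] + k[:, 3])
        * params.w_b ** (e * nb)
    )
    return float(w[0]) if scalar else w


def apply_selection(dist: ClassDistribution, params: ModelParams) -> ClassDistribution:
    """Reweight class frequencies by fitness: f_k <- w_k f_k / w_bar."""
    w = class_fitness(dist.classes, params)
    wbar = float(w @ dist.freq)
    if wbar <= 0:
        raise DegeneratePopulationError("population mean fitness is zero")
    return ClassDistribution(dist.classes, w * dist.freq / wbar, mean_fitness=wbar)


def drift_sample(dist: ClassDistribution, N: int, rng) -> ClassDistribution:
    """Multinomial resampling of N virions; classes drawn to zero are dropped."""
    if N < 1:
        raise ParameterError("N must be >= 1")
    rng = _as_rng(rng)
    p = dist.freq / dist.freq.sum()
    counts = rng.multinomial(int(N), p)
    keep = counts > 0
    return ClassDistribution(dist.classes[keep], counts[keep] / float(N))


def sequencing_step(
    dist: ClassDistribution,
    N_s: int,
    err_seq: float,
    p_delta,
    config: ExperimentConfig,
    rng,
    error_mean: float | None = None,
) -> ClassDistribution:
    """Observation layer: sequencing errors plus finite-coverage read sampling.

    Errors enter through the same Poisson-multinomial kernel as true mutations
    (adding only to the de-novo components, with the same type split p_Delta);
    the per-genome error mean follows ``config.err_mean_mode`` unless
    ``error_mean`` overrides it.  N_s reads are then drawn multinomially and
    observed frequencies n_k / N_s returned.
    """
    if N_s < 1:
        raise ParameterError("coverage must be >= 1")
    rng = _as_rng(rng)
    if error_mean is None:
        error_mean = N_s * err_seq if config.err_mean_mode == "as-printed" \
            else config.genome_length * err_seq
    if error_mean > 0:
        threshold = 1.0 / (100 * N_s)
        deltas, kmass = build_mutation_kernel(error_mean, np.asarray(p_delta), threshold)
        delta6 = np.zeros((deltas.shape[0], N_CLASS_COMPONENTS), dtype=np.int64)
        delta6[:, 2:] = deltas
        keys = (_encode(dist.classes)[:, None] + _encode(delta6)[None, :]).ravel()
        mass = (dist.freq[:, None] * kmass[None, :]).ravel()
        classes, freq = _aggregate(keys, mass)
        dist = ClassDistribution(classes, freq).normalized()
    counts = rng.multinomial(int(N_s), dist.freq / dist.freq.sum())
    keep = counts > 0
    return ClassDistribution(dist.classes[keep], counts[keep] / float(N_s))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Observed (and optionally latent) class distributions of one run."""

    observed: dict  # passage -> ClassDistribution (post sequencing layer)
    latent: dict | None = None  # passage -> ClassDistribution (pre sequencing)
    params: ModelParams | None = None
    config: ExperimentConfig | None = None
    seed: int | None = None


def simulate_experiment(
    params: ModelParams,
    config: ExperimentConfig,
    rng_seed,
    keep_latent: bool = False,
) -> SimulationResult:
    """Simulate one serial-passage run and return the sequenced observations.

    Initializes from the founder distribution, iterates mutation, selection
    and drift for ``generations_per_passage`` replication cycles per passage,
    and applies the sequencing layer at each sequenced passage.  All
    randomness derives from ``rng_seed``: per-passage streams are spawned
    deterministically so trajectories are reproducible.
    """
    params.validate(config.p_s)
    config.validate()
    ss = np.random.SeedSequence(rng_seed) if not isinstance(rng_seed, np.random.SeedSequence) \
        else rng_seed
    drift_rng = np.random.default_rng(ss.spawn(1)[0])
    threshold = 1.0 / (100 * config.N)
    p_delta = p_delta_vector(params, config.p_s)
    kernel = (
        build_mutation_kernel(params.U, p_delta, threshold) if params.U > 0 else None
    )
    dist = founder_distribution(params, trunc=threshold)
    observed: dict = {}
    latent: dict = {}
    seq_streams = {t: np.random.default_rng(s)
                   for t, s in zip(config.sequenced_passages,
                                   ss.spawn(len(config.sequenced_passages)))}
    for passage in range(1, config.n_passages + 1):
        for _ in range(config.generations_per_passage):
            dist = apply_mutation(dist, params, config, kernel=kernel)
            dist = apply_selection(dist, params)
            dist = drift_sample(dist, config.N, drift_rng)
        if passage in config.sequenced_passages:
            if keep_latent:
                latent[passage] = dist
            observed[passage] = sequencing_step(
                dist, config.coverage_at(passage), config.err_seq,
                p_delta, config, seq_streams[passage],
            )
    return SimulationResult(
        observed=observed, latent=latent if keep_latent else None,
        params=params, config=config, seed=rng_seed if np.isscalar(rng_seed) else None,
    )


def trajectory_frame(result: SimulationResult):
    """Tabulate a simulation as (passage, class tuple, frequency, layer) rows."""
    import pandas as pd

    rows = []
    layers = [("observed", result.observed)]
    if result.latent:
        layers.append(("latent", result.latent))
    for layer, dists in layers:
        for passage in sorted(dists):
            d = dists[passage]
            for k, f in zip(d.classes.tolist(), d.freq):
                rows.append({
                    "passage": passage, "layer": layer,
                    "k_Is": k[0], "k_Ins": k[1], "k_s": k[2],
                    "k_ns": k[3], "k_bs": k[4], "k_bns": k[5],
                    "frequency": float(f),
                })
    return pd.DataFrame(rows)
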