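"""Likelihood-free Bayesian inference for the genotype-class model.

Two routes to a posterior over the ten model parameters:

* **Rejection ABC**: draw parameters from the prior, simulate, accept the
  parameter sets whose summaries are closest to the observation (root mean
  square error on per-entry standardized summaries).
* **Neural posterior estimation (NPE)**: train a conditional density
  estimator (a mixture-density network, :mod:`phagepop.mdn`) on prior-drawn
  (parameter, summary) pairs.  Training on prior draws makes the estimated
  conditional density a direct, amortized posterior approximation — one
  network serves any observation without retraining.  An *ensemble* averages
  the posteriors of several estimators trained on non-overlapping subsets,
  which improves calibration over a single estimator.

Plus the standard posterior diagnostics: marginal MAP (modal bin of a
100-bin histogram), highest density intervals, coverage, Kullback-Leibler
information gain over the prior, and posterior predictive checks.

Parameters live on their natural scale everywhere outside the estimator;
internally they are mapped to an unbounded space by a logit of the
prior-normalized coordinate, with the mutation rate U handled on the log10
scale matching its prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mdn import ConditionalMDN, MDNSpec, TrainingError
from .model import PARAM_NAMES, ExperimentConfig, ModelParams, simulate_experiment
from .summaries import SummaryVector, summarize

logger = logging.getLogger(__name__)


def _as_seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)

__all__ = [
    "PriorSpec", "PosteriorSamples", "ABCConfig", "sample_prior", "rej_abc",
    "train_npe", "ensemble_posterior", "average_over_replicas", "map_estimate",
    "hdi", "coverage", "kl_information_gain", "posterior_predictive_check",
    "simulate_training_set", "NeuralPosterior", "MDNSpec",
]

# Table of default prior bounds.  U's bounds are exponents: U = 10^x with
# x ~ Uniform(-4, 0.3).
_DEFAULT_BOUNDS = {
    "w_s": (0.1, 1.0),
    "w_ns": (0.1, 1.0),
    "w_b": (1.0, 3.0),
    "p_bs": (0.0, 0.01),
    "p_bns": (0.0, 0.01),
    "M_s": (0.4, 0.6),
    "M_ns": (0.7, 0.9),
    "delta": (0.0, 2.0),
    "eta": (-1.0, 3.0),
    "U": (-4.0, 0.3),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors; U is log10-uniform (bounds are exponents).

    ``names`` defaults to the full ten-parameter model but may be any subset
    (e.g. a mutation-rate-only prior for toy studies and single-locus
    baselines).
    """

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    log10_params: frozenset = frozenset({"U"})
    names: tuple = PARAM_NAMES

    def lo_hi(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        return lo, hi

    def is_log10(self) -> np.ndarray:
        return np.array([n in self.log10_params for n in self.names])

    def to_internal(self, theta: np.ndarray) -> np.ndarray:
        """Natural scale -> uniform-prior scale (log10 where applicable)."""
        theta = np.atleast_2d(np.asarray(theta, float)).copy()
        islog = self.is_log10()
        theta[:, islog] = np.log10(theta[:, islog])
        return theta

    def from_internal(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float)).copy()
        islog = self.is_log10()
        x[:, islog] = 10.0 ** x[:, islog]
        return x

    def contains(self, theta: np.ndarray) -> np.ndarray:
        x = self.to_internal(theta)
        lo, hi = self.lo_hi()
        return ((x >= lo - 1e-12) & (x <= hi + 1e-12)).all(axis=1)


def sample_prior(spec: PriorSpec, n: int, seed) -> np.ndarray:
    """n independent prior draws, natural scale, shape (n, 10)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spec.lo_hi()
    x = rng.uniform(lo, hi, size=(n, lo.size))
    return spec.from_internal(x)


@dataclass
class PosteriorSamples:
    """Draws from an estimated posterior plus provenance."""

    samples: np.ndarray  # (n_draws, 10)
    param_names: tuple = PARAM_NAMES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.samples.shape[1] != len(self.param_names):
            raise ValueError("sample matrix width must match parameter names")

    def marginal(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]

    def map_estimate(self, name: str) -> float:
        return map_estimate(self.marginal(name))

    def hdi(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return hdi(self.marginal(name), mass)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.samples, columns=list(self.param_names))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation plumbing
# ---------------------------------------------------------------------------

def summarize_run(params: ModelParams, config: ExperimentConfig, seed, kind: str) -> SummaryVector:
    """Simulate one experiment and summarize its sequenced passages."""
    result = simulate_experiment(params, config, seed)
    return summarize(result.observed, kind, passages=sorted(config.sequenced_passages))


def simulate_training_set(
    prior: PriorSpec, n: int, config: ExperimentConfig, kind: str, seed,
    progress: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Prior draws plus their simulated summaries: ((n, 10), (n, L))."""
    ss = _as_seedseq(seed)
    theta_seed, sim_seed = ss.spawn(2)
    theta = sample_prior(prior, n, theta_seed)
    sims = []
    children = sim_seed.spawn(n)
    iterator = range(n)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="simulating")
        except ImportError:  # pragma: no cover
            pass
    for i in iterator:
        sv = summarize_run(ModelParams.from_array(theta[i]), config, children[i], kind)
        sims.append(sv.values)
    return theta, np.array(sims)


# ---------------------------------------------------------------------------
# rejection ABC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ABCConfig:
    """Rejection-ABC settings.

    The distance is the root mean square error over summary entries, taken on
    the raw summary scale by default.  ``standardize=True`` switches to
    per-entry z-scaled entries (scaler fit on the simulated set), which gives
    every entry equal leverage but is a departure from the plain RMSE.
    """

    acceptance_rate: float = 0.01
    distance: str = "rmse"
    standardize: bool = False

    def __post_init__(self):
        if not (0 < self.acceptance_rate <= 1):
            raise ValueError("acceptance rate must be in (0, 1]")


def rej_abc(
    observed, theta: np.ndarray, summaries: np.ndarray, config: ABCConfig,
    param_names: tuple = PARAM_NAMES,
) -> PosteriorSamples:
    """Accept the parameter sets with the smallest summary distances.

    Distances are root mean square errors over summary entries (optionally
    after per-entry standardization fit on the simulated set, in which case
    entries constant across simulations are ignored).  The lowest
    ``acceptance_rate`` fraction of parameter sets is returned as posterior
    draws.
    """
    obs = observed.values if isinstance(observed, SummaryVector) else np.asarray(observed, float)
    summaries = np.asarray(summaries, float)
    if obs.size != summaries.shape[1]:
        raise ValueError(
            f"observed summary has {obs.size} entries but simulations have "
            f"{summaries.shape[1]}")
    if config.standardize:
        mean = summaries.mean(axis=0)
        sd = summaries.std(axis=0)
        keep = sd > 0
        z_sims = (summaries[:, keep] - mean[keep]) / sd[keep]
        z_obs = (obs[keep] - mean[keep]) / sd[keep]
    else:
        z_sims, z_obs = summaries, obs
    dist = np.sqrt(((z_sims - z_obs) ** 2).mean(axis=1))
    n_accept = max(1, int(round(config.acceptance_rate * len(dist))))
    accepted = np.argsort(dist, kind="stable")[:n_accept]
    return PosteriorSamples(
        theta[accepted], param_names,
        provenance={"method": "rej-abc", "epsilon": config.acceptance_rate,
                    "n_sims": len(dist), "n_accepted": n_accept},
    )


# ---------------------------------------------------------------------------
# neural posterior estimation
# ---------------------------------------------------------------------------

class NeuralPosterior:
    """Amortized posterior: an MDN over logit-transformed parameters.

    Holds the feature scaler (fit on the training summaries) and the
    parameter-support transform, so ``sample`` and ``log_density`` work on the
    natural parameter scale and on raw summary vectors for any observation.
    """

    #: summaries with more informative entries than this are reduced to the
    #: entries most correlated with the parameters (an embedding choice that
    #: keeps training cheap; the cut is fit on the training set only)
    MAX_FEATURES = 256

    def __init__(self, prior: PriorSpec, spec: MDNSpec, seed):
        self.prior = prior
        self.spec = spec
        self._ss = _as_seedseq(seed)
        self.mdn: ConditionalMDN | None = None

    # -- support transform ----------------------------------------------------

    def _to_z(self, theta: np.ndarray) -> np.ndarray:
        x = self.prior.to_internal(theta)
        lo, hi = self.prior.lo_hi()
        u = np.clip((x - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        return np.log(u / (1 - u))

    def _from_z(self, z: np.ndarray) -> np.ndarray:
        lo, hi = self.prior.lo_hi()
        u = 1.0 / (1.0 + np.exp(-z))
        return self.prior.from_internal(lo + u * (hi - lo))

    def _log_jacobian(self, theta: np.ndarray) -> np.ndarray:
        """log |dz/dtheta| summed over parameters, for density on natural scale."""
        x = self.prior.to_internal(theta)
        lo, hi = self.prior.lo_hi()
        u = np.clip((x - lo) / (hi - lo), 1e-12, 1 - 1e-12)
        log_j = -np.log(u) - np.log1p(-u) - np.log(hi - lo)
        islog = self.prior.is_log10()
        th = np.atleast_2d(np.asarray(theta, float))
        log_j[:, islog] -= np.log(th[:, islog] * np.log(10.0))
        return log_j.sum(axis=1)

    # -- features ---------------------------------------------------------------

    def _fit_scaler(self, summaries: np.ndarray, theta_z: np.ndarray) -> None:
        mean, sd = summaries.mean(axis=0), summaries.std(axis=0)
        informative = np.nonzero(sd > 0)[0]
        if informative.size == 0:
            raise TrainingError("summaries are constant; cannot condition on them")
        if informative.size > self.MAX_FEATURES:
            z = (summaries[:, informative] - mean[informative]) / sd[informative]
            tz = (theta_z - theta_z.mean(0)) / (theta_z.std(0) + 1e-12)
            corr = np.abs(z.T @ tz) / len(z)  # (n_feat, n_params)
            score = corr.max(axis=1)
            top = np.argsort(score, kind="stable")[::-1][: self.MAX_FEATURES]
            informative = np.sort(informative[top])
        self._feat_idx = informative
        self._feat_mean = mean[informative]
        self._feat_sd = sd[informative]

    def _featurize(self, summaries: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(summaries, float))
        return (s[:, self._feat_idx] - self._feat_mean) / self._feat_sd

    # -- training / inference ---------------------------------------------------

    def fit(self, theta: np.ndarray, summaries: np.ndarray) -> "NeuralPosterior":
        theta = np.atleast_2d(np.asarray(theta, float))
        summaries = np.atleast_2d(np.asarray(summaries, float))
        Z = self._to_z(theta)
        self._fit_scaler(summaries, Z)
        X = self._featurize(summaries)
        init_seed, fit_seed = self._ss.spawn(2)
        self.mdn = ConditionalMDN(X.shape[1], Z.shape[1], self.spec,
                                  np.random.default_rng(init_seed))
        self.mdn.fit(Z, X, np.random.default_rng(fit_seed))
        self.n_training = theta.shape[0]
        return self

    def sample(self, n: int, observed_summary, seed) -> PosteriorSamples:
        obs = observed_summary.values if isinstance(observed_summary, SummaryVector) \
            else observed_summary
        x = self._featurize(obs)[0]
        z = self.mdn.sample(n, x, np.random.default_rng(seed))
        return PosteriorSamples(
            self._from_z(z), self.prior.names,
            provenance={"method": "npe-mdn", "n_training": self.n_training},
        )

    def log_density(self, theta, observed_summary) -> np.ndarray:
        """Posterior log density on the natural parameter scale."""
        obs = observed_summary.values if isinstance(observed_summary, SummaryVector) \
            else observed_summary
        theta = np.atleast_2d(np.asarray(theta, float))
        x = np.repeat(self._featurize(obs), theta.shape[0], axis=0)
        return self.mdn.log_prob(self._to_z(theta), x) + self._log_jacobian(theta)

    @property
    def loss_trajectory(self) -> list:
        return self.mdn.loss_trajectory if self.mdn else []


def train_npe(
    theta: np.ndarray, summaries: np.ndarray,
    prior: PriorSpec | None = None,
    density_estimator_spec: MDNSpec | None = None,
    seed=0,
    min_pairs: int = 50,
) -> NeuralPosterior:
    """Train one amortized neural posterior on (parameter, summary) pairs."""
    theta = np.atleast_2d(np.asarray(theta, float))
    if theta.shape[0] < min_pairs:
        raise TrainingError(f"need at least {min_pairs} training pairs, got {theta.shape[0]}")
    est = NeuralPosterior(prior or PriorSpec(), density_estimator_spec or MDNSpec(), seed)
    return est.fit(theta, summaries)


def train_ensemble(
    theta: np.ndarray, summaries: np.ndarray, n_members: int,
    prior: PriorSpec | None = None,
    density_estimator_spec: MDNSpec | None = None,
    seed=0,
) -> list[NeuralPosterior]:
    """Train ``n_members`` estimators on non-overlapping slices of the pairs."""
    n = theta.shape[0]
    per = n // n_members
    if per < 1:
        raise TrainingError("fewer training pairs than ensemble members")
    seeds = _as_seedseq(seed).spawn(n_members)
    members = []
    for j in range(n_members):
        sl = slice(j * per, (j + 1) * per)
        members.append(train_npe(theta[sl], summaries[sl], prior,
                                 density_estimator_spec, seeds[j]))
    return members


def ensemble_posterior(
    estimators: list, observed, n_draws: int, seed,
) -> PosteriorSamples:
    """Sample the uniform mixture of member posteriors.

    Each member contributes ``n_draws // len(estimators)`` draws; the
    remainder is assigned one extra draw per member, starting from the first.
    """
    if not estimators:
        raise ValueError("need at least one estimator")
    m = len(estimators)
    base, extra = divmod(n_draws, m)
    seeds = _as_seedseq(seed).spawn(m)
    parts = []
    for j, est in enumerate(estimators):
        nj = base + (1 if j < extra else 0)
        if nj > 0:
            parts.append(est.sample(nj, observed, seeds[j]).samples)
    samples = np.vstack(parts)
    names = getattr(getattr(estimators[0], "prior", None), "names", PARAM_NAMES)
    return PosteriorSamples(
        samples, names,
        provenance={"method": "ensemble-npe", "ensemble_size": m,
                    "n_training_each": getattr(estimators[0], "n_training", None)},
    )


def average_over_replicas(posteriors: list[PosteriorSamples]) -> PosteriorSamples:
    """Uniform mixture over replica posteriors (equal draws from each)."""
    if not posteriors:
        raise ValueError("need at least one posterior")
    if len(posteriors) == 1:
        return posteriors[0]
    names = posteriors[0].param_names
    if any(p.param_names != names for p in posteriors):
        raise ValueError("posteriors are over different parameter spaces")
    n = min(p.samples.shape[0] for p in posteriors)
    samples = np.vstack([p.samples[:n] for p in posteriors])
    return PosteriorSamples(samples, names,
                            provenance={"method": "replica-average",
                                        "n_replicas": len(posteriors)})


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def map_estimate(samples: np.ndarray, n_bins: int = 100) -> float:
    """Marginal MAP: center of the modal bin of a histogram over the sample range.

    Ties between equally full bins resolve to the lower-valued bin.
    """
    samples = np.asarray(samples, float).ravel()
    if samples.size == 0:
        raise ValueError("empty sample")
    lo, hi = samples.min(), samples.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax takes the first (lower) bin on ties
    return float(0.5 * (edges[i] + edges[i + 1]))


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws (via arviz)."""
    samples = np.sort(np.asarray(samples, float).ravel())
    n = samples.size
    if n < 2:
        if n == 1:
            return float(samples[0]), float(samples[0])
        raise ValueError("need at least one draw")
    if mass >= 1 or samples[0] == samples[-1]:
        return float(samples[0]), float(samples[-1])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        lo, hi = az.hdi(samples, hdi_prob=float(mass))
    return float(lo), float(hi)


def coverage(true_values, posteriors: list[PosteriorSamples] | list[np.ndarray],
             mass: float = 0.95, param: str | None = None) -> float:
    """Fraction of cases whose ``mass``-HDI contains the true value."""
    if len(true_values) != len(posteriors):
        raise ValueError("true values and posteriors must be paired")
    hits = 0
    for truth, post in zip(true_values, posteriors):
        draws = post.marginal(param) if isinstance(post, PosteriorSamples) else np.asarray(post)
        lo, hi = hdi(draws, mass)
        hits += lo <= truth <= hi
    return hits / len(true_values)


def kl_information_gain(
    posterior: PosteriorSamples, prior: PriorSpec, n_bins: int = 50,
) -> dict:
    """Monte-Carlo KL(marginal posterior || marginal prior) per parameter.

    The posterior marginal is a histogram density over the prior support
    (log10 scale for U, where the prior is uniform); the prior density is the
    exact uniform.  Draws outside the prior support raise an error.
    """
    if not prior.contains(posterior.samples).all():
        raise ValueError("posterior draws fall outside the prior support")
    x = prior.to_internal(posterior.samples)
    lo, hi = prior.lo_hi()
    out = {}
    for j, name in enumerate(prior.names):
        counts, edges = np.histogram(x[:, j], bins=n_bins, range=(lo[j], hi[j]))
        p = counts / counts.sum()
        width = edges[1] - edges[0]
        q = width / (hi[j] - lo[j])  # uniform prior mass per bin
        nz = p > 0
        out[name] = float((p[nz] * np.log(p[nz] / q)).sum())
    return out


@dataclass
class PPCReport:
    """Posterior predictive bands and the observation's membership in them."""

    band_lo: np.ndarray
    band_hi: np.ndarray
    predictive: np.ndarray  # (n_rep, L) simulated summaries
    observed: np.ndarray
    membership_fraction: float


def posterior_predictive_check(
    samples: PosteriorSamples, config: ExperimentConfig, observed,
    n_rep: int, seed, kind: str = "L-LR", band_mass: float = 0.95,
) -> PPCReport:
    """Simulate at posterior draws and compare predictive bands to the data."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    obs = observed.values if isinstance(observed, SummaryVector) else np.asarray(observed, float)
    ss = _as_seedseq(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    idx = pick_rng.integers(0, samples.samples.shape[0], size=n_rep)
    children = ss.spawn(n_rep)
    preds = []
    for i in range(n_rep):
        p = ModelParams.from_array(samples.samples[idx[i]])
        preds.append(summarize_run(p, config, children[i], kind).values)
    preds = np.array(preds)
    alpha = (1 - band_mass) / 2
    lo = np.quantile(preds, alpha, axis=0)
    hi = np.quantile(preds, 1 - alpha, axis=0)
    inside = (obs >= lo) & (obs <= hi)
    return PPCReport(lo, hi, preds, obs, float(inside.mean()))
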