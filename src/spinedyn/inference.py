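"""Simulation-based inference of plasticity parameters.

Six free parameters of the weight-dynamics simulator — the proportion of
stimulated inputs, the multiplicative and additive noise strengths, the
STDP timescale, and the potentiation/depression rates — are inferred
from six summary features: the (mu, sigma) of the lognormal fit to the
final weight distribution under each of the silent, 10 Hz control and
200 Hz HFS protocols.  Simulated weights are first rescaled to match the
observed mean size per protocol, so the features carry shape rather than
absolute-scale information.

The engine is sequential rejection ABC: each round simulates a batch of
candidates, keeps the fraction closest to the observed features under a
standardized Euclidean distance, and proposes the next round by
Gaussian perturbation of the survivors truncated to the prior box.  The
simulator is an injectable callable, so a neural posterior-estimation
backend can be slotted in behind the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import distfit
from .errors import ConfigurationError, NumericalError
from .simulator import NoiseParams, STDPParams, SimulationConfig, run_protocol_suite

PARAM_NAMES = (
    "stim_proportion",
    "mult_strength",
    "add_strength",
    "tau_stdp",
    "pot_rate",
    "dep_rate_rel",
)

PROTOCOL_ORDER = ("silent", "control", "hfs")


@dataclass
class ParameterVector:
    stim_proportion: float
    mult_strength: float
    add_strength: float
    tau_stdp: float  # ms
    pot_rate: float  # c_p analogue, pS
    dep_rate_rel: float  # c_d analogue, dimensionless

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ParameterVector":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(a, dtype=float))))


@dataclass
class PriorBox:
    """Independent uniform prior per parameter."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or not (self.lower < self.upper).all():
            raise ConfigurationError("prior bounds must satisfy lower < upper elementwise")

    @property
    def ndim(self) -> int:
        return self.lower.size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.ndim))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        t = np.atleast_2d(theta)
        return ((t >= self.lower) & (t <= self.upper)).all(axis=1)


def default_prior() -> PriorBox:
    """Illustrative prior spanning plausible decades for each parameter."""
    return PriorBox(
        lower=[0.05, 0.02, 0.0, 0.1, 0.001, 0.0005],
        upper=[0.50, 0.50, 0.02, 5.0, 0.020, 0.0100],
    )


@dataclass
class SummaryFeatures:
    """(mu, sigma) of the lognormal fit per protocol, in protocol order."""

    values: np.ndarray  # length 6: mu_silent, sigma_silent, mu_control, ...
    valid: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6,):
            raise ConfigurationError("summary features must have length 6")
        if not np.isfinite(self.values).all():
            self.valid = False


@dataclass
class PosteriorSamples:
    draws: np.ndarray  # (n, ndim)
    map: np.ndarray
    rounds_run: int
    sims_per_round: int
    survivors: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# features


def summarize(
    results: dict, target_means: dict | None = None, n_bins: int | None = None
) -> SummaryFeatures:
    """Lognormal (mu, sigma) per protocol after mean normalization.

    Each protocol's positive final weights are rescaled to the observed
    mean spine size for that protocol (identity if ``target_means`` is
    None), then binned, normalized and fitted.  A failed fit marks the
    whole feature vector invalid.
    """
    feats = []
    for name in PROTOCOL_ORDER:
        res = results[name]
        w = res.final_weights.ravel() if hasattr(res, "final_weights") else np.ravel(res)
        w = w[w > 0]
        if w.size < 100:
            return SummaryFeatures(np.full(6, np.nan), valid=False)
        if target_means is not None:
            w = w * (float(target_means[name]) / w.mean())
        init = distfit.log_moments(w)
        fit = distfit.fit_lognormal(distfit.bin_and_normalize(w, n_bins), init, n=w.size)
        if not fit.converged or fit.sigma <= 0:
            return SummaryFeatures(np.full(6, np.nan), valid=False)
        feats.extend([fit.mu, fit.sigma])
    return SummaryFeatures(np.asarray(feats))


def make_suite_simulator(
    template: SimulationConfig, target_means: dict | None = None, n_bins: int | None = None
):
    """Build theta -> SummaryFeatures by running the protocol suite.

    ``template`` fixes population size, duration and numerical settings;
    the six inferable parameters are overridden per candidate.
    """

    def simulate(theta: np.ndarray, seed: int) -> SummaryFeatures:
        p = ParameterVector.from_array(theta)
        cfg = replace(
            template,
            stdp=STDPParams(c_p=p.pot_rate, c_d=p.dep_rate_rel, tau_stdp=p.tau_stdp),
            noise=NoiseParams(p.mult_strength, p.add_strength),
            protocol=replace(template.protocol, stim_proportion=p.stim_proportion),
            seed=int(seed),
        )
        try:
            return summarize(run_protocol_suite(cfg), target_means, n_bins)
        except Exception:
            return SummaryFeatures(np.full(6, np.nan), valid=False)

    return simulate


def inference_template(
    n_neurons: int = 100,
    n_inputs: int = 100,
    duration: float = 0.5,
    noise_interval: float = 0.02,
) -> SimulationConfig:
    """Reduced-population configuration used per ABC candidate."""
    from .simulator import NeuronParams

    return SimulationConfig(
        neuron=NeuronParams(n_neurons=n_neurons, n_inputs=n_inputs),
        duration=duration,
        noise_interval=noise_interval,
    )


# ---------------------------------------------------------------------------
# sequential ABC


def sequential_infer(
    observed,
    prior: PriorBox,
    simulator,
    rounds: int = 5,
    sims_per_round: int = 3200,
    seed: int = 0,
    epsilon: float = 0.1,
    n_posterior: int = 10000,
) -> PosteriorSamples:
    """Sequential rejection ABC with Gaussian perturbation kernels.

    Round 1 samples the prior; every round keeps the fraction ``epsilon``
    of candidates whose features are closest to ``observed`` (Euclidean
    distance standardized by the round-1 feature spread) and perturbs the
    survivors to propose the next round.  The final survivors are
    resampled with replacement to ``n_posterior`` draws.
    """
    if rounds < 1 or sims_per_round < 2:
        raise ConfigurationError("require rounds >= 1 and sims_per_round >= 2")
    if not 0 < epsilon <= 1:
        raise ConfigurationError("epsilon must lie in (0, 1]")
    obs = observed.values if isinstance(observed, SummaryFeatures) else np.asarray(observed)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seeds = iter(ss.generate_state(rounds * sims_per_round + 16) % (2**31 - 1))

    survivors = None
    feat_scale = None
    n_keep = max(1, int(math.floor(epsilon * sims_per_round)))

    for rnd in range(rounds):
        if rnd == 0:
            thetas = prior.sample(sims_per_round, rng)
        else:
            width = prior.upper - prior.lower
            if survivors.shape[0] > 1:
                sd = survivors.std(axis=0, ddof=1)
                sd = np.where(sd > 0, sd, 1e-3 * width)
            else:
                sd = 1e-3 * width
            picks = survivors[rng.integers(0, survivors.shape[0], sims_per_round)]
            thetas = picks + rng.standard_normal(picks.shape) * sd
            # truncate the perturbation kernel to the prior box
            for _ in range(100):
                bad = ~prior.contains(thetas)
                if not bad.any():
                    break
                redraw = survivors[rng.integers(0, survivors.shape[0], int(bad.sum()))]
                thetas[bad] = redraw + rng.standard_normal(redraw.shape) * sd
            thetas = np.clip(thetas, prior.lower, prior.upper)

        feats = np.empty((sims_per_round, obs.size))
        ok = np.zeros(sims_per_round, dtype=bool)
        for i in range(sims_per_round):
            f = simulator(thetas[i], int(next(sim_seeds)))
            if isinstance(f, SummaryFeatures):
                ok[i] = f.valid
                feats[i] = f.values
            else:
                feats[i] = np.asarray(f, dtype=float)
                ok[i] = np.isfinite(feats[i]).all()
        if not ok.any():
            raise NumericalError("all simulations in a round produced invalid features")
        if feat_scale is None:
            feat_scale = feats[ok].std(axis=0, ddof=0)
            feat_scale[feat_scale <= 0] = 1.0
        dist = np.full(sims_per_round, np.inf)
        dist[ok] = np.sqrt((((feats[ok] - obs) / feat_scale) ** 2).sum(axis=1))
        keep = np.argsort(dist, kind="stable")[:n_keep]
        keep = keep[np.isfinite(dist[keep])]
        survivors = thetas[keep]

    draws = survivors[rng.integers(0, survivors.shape[0], n_posterior)]
    return PosteriorSamples(
        draws=draws,
        map=map_estimate(draws),
        rounds_run=rounds,
        sims_per_round=sims_per_round,
        survivors=survivors,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def map_estimate(posterior) -> np.ndarray:
    """Mode of a Gaussian-KDE density over the posterior draws.

    Degenerate (zero-variance) dimensions are held at their value.  The
    KDE (Silverman bandwidth) is evaluated at the draws and the mode is
    refined locally as the density-weighted centroid of the top-density
    shell, which is far more stable under sampling noise than the raw
    argmax.  If the draw covariance is singular (e.g. very few unique
    survivors) the most frequent draw is returned.
    """
    draws = posterior.draws if isinstance(posterior, PosteriorSamples) else np.asarray(posterior)
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws.reshape(-1, 1)
    n, d = draws.shape
    if n < 2:
        return draws[0].copy()
    mode = draws.mean(axis=0)
    live = draws.std(axis=0) > 0
    if not live.any():
        return draws[0].copy()
    sub = draws[:, live]
    uniq, counts = np.unique(sub, axis=0, return_counts=True)
    if uniq.shape[0] < 2:
        mode[live] = uniq[0]
        return mode
    try:
        kde = stats.gaussian_kde(sub.T, bw_method="silverman")
        eval_pts = sub
        if eval_pts.shape[0] > 20_000:
            idx = np.random.default_rng(0).choice(eval_pts.shape[0], 20_000, replace=False)
            eval_pts = eval_pts[idx]
        dens = kde(eval_pts.T)
        k = max(10, int(0.05 * eval_pts.shape[0]))
        top = np.argsort(dens)[-k:]
        mode[live] = np.average(eval_pts[top], axis=0, weights=dens[top])
    except np.linalg.LinAlgError:
        mode[live] = uniq[int(np.argmax(counts))]
    return mode


@dataclass
class MarginalGrids:
    one_d: dict  # name -> (edges, density)
    two_d: dict  # (name_i, name_j) -> (edges_i, edges_j, density)


def marginals(posterior, bins: int = 30, names=PARAM_NAMES) -> MarginalGrids:
    """Normalized 1-D and pairwise 2-D histogram marginals of the draws."""
    draws = posterior.draws if isinstance(posterior, PosteriorSamples) else np.asarray(posterior)
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws.reshape(-1, 1)
    d = draws.shape[1]
    names = list(names)[:d]
    one = {}
    for j in range(d):
        dens, edges = np.histogram(draws[:, j], bins=bins, density=True)
        if not np.isfinite(dens).all():  # zero-width support
            dens = np.zeros_like(dens)
        one[names[j]] = (edges, dens)
    two = {}
    for i in range(d):
        for j in range(i + 1, d):
            H, ei, ej = np.histogram2d(draws[:, i], draws[:, j], bins=bins, density=True)
            two[(names[i], names[j])] = (ei, ej, H)
    return MarginalGrids(one_d=one, two_d=two)


def credible_interval(draws: np.ndarray, level: float = 0.9) -> np.ndarray:
    """Central credible interval per dimension: (ndim, 2) array."""
    lo = (1.0 - level) / 2.0
    d = np.asarray(draws, dtype=float)
    if d.ndim == 1:
        d = d.reshape(-1, 1)
    return np.quantile(d, [lo, 1.0 - lo], axis=0).T


def simulate_map_and_compare(
    map_theta,
    observed_weights: dict,
    template: SimulationConfig,
    seed: int = 0,
    n_bins: int = 30,
) -> dict:
    """Re-simulate at the MAP and score the overlap with observed samples.

    For each protocol, the MAP-simulated positive weights are rescaled to
    the observed mean and binned on the observed sample's bin edges; the
    r^2 between the two normalized densities measures the match.
    """
    theta = map_theta.to_array() if isinstance(map_theta, ParameterVector) else np.asarray(map_theta)
    p = ParameterVector.from_array(theta)
    cfg = replace(
        template,
        stdp=STDPParams(c_p=p.pot_rate, c_d=p.dep_rate_rel, tau_stdp=p.tau_stdp),
        noise=NoiseParams(p.mult_strength, p.add_strength),
        protocol=replace(template.protocol, stim_proportion=p.stim_proportion),
        seed=int(seed),
    )
    results = run_protocol_suite(cfg)
    out = {}
    for name in PROTOCOL_ORDER:
        obs = np.ravel(observed_weights[name])
        obs = obs[obs > 0]
        simw = results[name].final_weights.ravel()
        simw = simw[simw > 0]
        simw = simw * (obs.mean() / simw.mean())
        binned_obs = distfit.bin_and_normalize(obs, n_bins)
        edges = binned_obs.bin_edges
        counts, _ = np.histogram(simw, bins=edges)
        widths = np.diff(edges)
        total = counts @ widths
        sim_density = counts / total if total > 0 else np.zeros_like(widths)
        out[name] = {
            "r2": distfit.r_squared(binned_obs.density, sim_density),
            "edges": edges,
            "observed_density": binned_obs.density,
            "map_density": sim_density,
        }
    return out
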