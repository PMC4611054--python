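"""Likelihood-free inference: ABC-SMC fitting and Bayesian model selection.

Sequential Monte Carlo ABC with an adaptive epsilon schedule (quantile of
the previous population's distances), component-wise uniform perturbation
kernels (log10 space for log-scale parameters) and standard importance
weights.  Model selection samples a model indicator jointly with the
parameters; the per-population model probability is the weighted fraction
of accepted particles per model, and the scheme runs until one model
reaches probability one (or the population budget is exhausted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelDefinition
from .params import ParameterSet
from .simulate import observable_product, simulate_time_course
from .synthetic import TimeCourseDataset

__all__ = ["Prior", "PriorSet", "Posterior", "ModelSelectionResult",
           "abc_distance", "abc_smc", "abc_smc_fit", "abc_smc_model_select",
           "iterative_selection_scheme", "posterior_compare",
           "default_priors"]


# ---------------------------------------------------------------------- priors
@dataclass(frozen=True)
class Prior:
    """One marginal prior: uniform, log-uniform or normal."""

    family: str
    a: float
    b: float

    def __post_init__(self):
        if self.family not in ("uniform", "loguniform", "normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family in ("uniform", "loguniform") and not (self.a < self.b):
            raise ValueError("bounds must satisfy a < b")
        if self.family == "loguniform" and self.a <= 0:
            raise ValueError("log-uniform bounds must be positive")
        if self.family == "normal" and self.b <= 0:
            raise ValueError("normal prior needs scale > 0")

    @property
    def log_scale(self) -> bool:
        return self.family == "loguniform"

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            return rng.uniform(self.a, self.b)
        if self.family == "loguniform":
            return 10 ** rng.uniform(np.log10(self.a), np.log10(self.b))
        return rng.normal(self.a, self.b)

    def pdf(self, x: float) -> float:
        if self.family == "uniform":
            return 1.0 / (self.b - self.a) if self.a <= x <= self.b else 0.0
        if self.family == "loguniform":
            if not (self.a <= x <= self.b):
                return 0.0
            return 1.0 / (x * (np.log(self.b) - np.log(self.a)))
        z = (x - self.a) / self.b
        return np.exp(-0.5 * z * z) / (self.b * np.sqrt(2 * np.pi))

    def transform(self, x: float) -> float:
        return np.log10(x) if self.log_scale else x

    def untransform(self, u: float) -> float:
        return 10 ** u if self.log_scale else u


class PriorSet(dict):
    """Ordered mapping parameter name -> :class:`Prior`."""

    @property
    def names(self) -> list:
        return list(self.keys())

    def sample(self, rng: np.random.Generator) -> dict:
        return {k: p.sample(rng) for k, p in self.items()}

    def pdf(self, theta: dict) -> float:
        out = 1.0
        for k, p in self.items():
            out *= p.pdf(theta[k])
        return out


def default_priors(names: Sequence[str], fixture: ParameterSet,
                   decades: float = 2.0) -> PriorSet:
    """Log-uniform priors spanning ``2*decades`` orders around fixture values.

    The chamber capacity C gets a uniform prior on [10, 1000] molecules.
    """
    ps = PriorSet()
    for nm in names:
        if nm == "C":
            ps[nm] = Prior("uniform", 10.0, 1000.0)
        else:
            v = getattr(fixture, nm)
            if v <= 0:
                raise ValueError(f"cannot build log prior around {nm}={v}")
            ps[nm] = Prior("loguniform", v / 10**decades, v * 10**decades)
    return ps


# ------------------------------------------------------------------- distance
def abc_distance(simulated: TimeCourseDataset, observed: TimeCourseDataset) -> float:
    """Root-mean-square difference over design cells, per-series normalised.

    Each (concentration, time) cell is compared on replicate means and
    normalised by the maximum observed product of its concentration
    series.  Both datasets must cover the same design cells.
    """
    sim = simulated.pivot()
    obs = observed.pivot()
    missing = [(c, t) for c in obs.index for t in obs.columns
               if c not in sim.index or t not in sim.columns
               or pd.isna(sim.loc[c, t])]
    if missing:
        raise ValueError(f"design mismatch; simulated dataset lacks cells {missing}")
    sim = sim.loc[obs.index, obs.columns]
    return _distance_matrices(sim.to_numpy(), obs.to_numpy())


def _distance_matrices(sim: np.ndarray, obs: np.ndarray) -> float:
    norms = np.abs(obs).max(axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    d = (sim - obs) / norms
    return float(np.sqrt(np.mean(d * d)))


# ------------------------------------------------------------------ posterior
@dataclass
class Posterior:
    """Weighted particles of the final ABC-SMC population plus diagnostics."""

    particles: pd.DataFrame          # one column per parameter
    weights: np.ndarray
    distances: np.ndarray
    epsilons: list
    acceptance_rates: list
    seed: int
    distance_id: str = "normalised-rms"
    converged: bool = True
    populations: list = field(default_factory=list)   # per-population copies

    @property
    def names(self) -> list:
        return list(self.particles.columns)

    def quantile(self, name: str, q) -> np.ndarray:
        return _weighted_quantile(self.particles[name].to_numpy(),
                                  self.weights, np.atleast_1d(q))

    def median(self, name: str) -> float:
        return float(self.quantile(name, 0.5)[0])

    def interval(self, name: str, lo: float = 0.05, hi: float = 0.95) -> tuple:
        q = self.quantile(name, [lo, hi])
        return float(q[0]), float(q[1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for nm in self.names:
            lo, hi = self.interval(nm)
            rows.append((nm, self.median(nm), lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "median", "q05", "q95"])


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= w.sum()
    return np.interp(q, cdf, x)


# ------------------------------------------------------------------- core SMC
def _kernel_widths(values: np.ndarray, priors: PriorSet,
                   scale: float) -> np.ndarray:
    """Per-parameter half-widths of the uniform perturbation kernel."""
    widths = np.empty(values.shape[1])
    for i, nm in enumerate(priors.names):
        col = values[:, i]
        t = np.array([priors[nm].transform(v) for v in col])
        rng_ = t.max() - t.min()
        widths[i] = max(scale * rng_, 1e-8)
    return widths


def abc_smc(priors: PriorSet, simulate: Callable, distance: Callable,
            observed, n_particles: int = 200, seed: int = 0,
            eps_quantile: float = 0.3, max_populations: int = 8,
            eps_floor: float = 0.0, kernel_scale: float = 0.5,
            max_proposals_per_population: Optional[int] = None) -> Posterior:
    """Generic ABC-SMC sampler.

    ``simulate(theta_dict, rng)`` returns a synthetic dataset,
    ``distance(sim, observed)`` a non-negative scalar.  Failures inside
    ``simulate`` count as infinite distance.  Fully reproducible from
    ``seed``.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    rng = np.random.default_rng(seed)
    names = priors.names
    cap = max_proposals_per_population or 50 * n_particles

    # population 0: sample from the prior, accept everything
    theta = np.empty((n_particles, len(names)))
    dist = np.empty(n_particles)
    for i in range(n_particles):
        th = priors.sample(rng)
        theta[i] = [th[k] for k in names]
        dist[i] = _safe_distance(simulate, distance, th, observed, rng)
    w = np.full(n_particles, 1.0 / n_particles)
    epsilons, acc_rates = [float("inf")], [1.0]
    populations = [(theta.copy(), w.copy(), dist.copy())]
    converged = True

    for t in range(1, max_populations):
        finite = dist[np.isfinite(dist)]
        if finite.size == 0:
            converged = False
            break
        eps = float(np.quantile(finite, eps_quantile))
        if eps <= eps_floor or eps >= epsilons[-1] and epsilons[-1] != float("inf"):
            break
        widths = _kernel_widths(theta, priors, kernel_scale)
        new_theta = np.empty_like(theta)
        new_dist = np.empty(n_particles)
        new_w = np.empty(n_particles)
        accepted = 0
        proposals = 0
        while accepted < n_particles and proposals < cap:
            proposals += 1
            j = rng.choice(n_particles, p=w)
            cand = {}
            ok = True
            for i, nm in enumerate(names):
                u = priors[nm].transform(theta[j, i]) + widths[i] * rng.uniform(-1, 1)
                cand[nm] = priors[nm].untransform(u)
            prior_pdf = priors.pdf(cand)
            if prior_pdf == 0:
                continue
            d = _safe_distance(simulate, distance, cand, observed, rng)
            if d > eps:
                continue
            vec = np.array([cand[k] for k in names])
            denom = _kernel_mixture_density(vec, theta, w, priors, widths)
            if denom == 0:
                continue
            new_theta[accepted] = vec
            new_dist[accepted] = d
            new_w[accepted] = prior_pdf / denom
            accepted += 1
        if accepted < n_particles:
            warnings.warn("ABC-SMC stopped early: population could not be "
                          f"filled within {cap} proposals")
            converged = False
            break
        theta, dist = new_theta, new_dist
        w = new_w / new_w.sum()
        epsilons.append(eps)
        acc_rates.append(n_particles / proposals)
        populations.append((theta.copy(), w.copy(), dist.copy()))
        ess = 1.0 / np.sum(w * w)
        if ess < 1.5:
            warnings.warn("degenerate ABC-SMC population (ESS < 1.5); stopping")
            converged = False
            break

    return Posterior(pd.DataFrame(theta, columns=names), w, dist,
                     epsilons, acc_rates, seed, converged=converged,
                     populations=populations)


def _safe_distance(simulate, distance, theta, observed, rng) -> float:
    try:
        sim = simulate(theta, rng)
        d = distance(sim, observed)
        return d if np.isfinite(d) else float("inf")
    except (RuntimeError, FloatingPointError, ValueError, OverflowError):
        return float("inf")


def _kernel_mixture_density(vec, theta, w, priors: PriorSet, widths) -> float:
    names = priors.names
    t_vec = np.array([priors[nm].transform(v) for nm, v in zip(names, vec)])
    dens = np.zeros(theta.shape[0])
    inside = np.ones(theta.shape[0], dtype=bool)
    for i, nm in enumerate(names):
        t_col = np.array([priors[nm].transform(v) for v in theta[:, i]])
        inside &= np.abs(t_vec[i] - t_col) <= widths[i] + 1e-15
    dens[inside] = 1.0
    for i in range(len(names)):
        dens[inside] /= 2.0 * widths[i]
    return float(np.sum(w * dens))


# ---------------------------------------------------------- model-based layer
def _dataset_matrices(dataset: TimeCourseDataset):
    piv = dataset.pivot()
    return (np.asarray(piv.index, dtype=float),
            np.asarray(piv.columns, dtype=float), piv.to_numpy())


def _make_model_simulator(model: ModelDefinition, base: ParameterSet,
                          concentrations: np.ndarray, times: np.ndarray,
                          solver_opts: Optional[dict] = None) -> Callable:
    """Fast simulator: theta dict -> product matrix (nM), rows=concentrations."""
    solver_opts = solver_opts or {"rtol": 1e-6, "atol": 1e-9}

    def simulate(theta: dict, rng=None) -> np.ndarray:
        p = base.with_(**theta)
        out = np.empty((concentrations.size, times.size))
        for i, s0 in enumerate(concentrations):
            traj = simulate_time_course(model, p, float(s0), times,
                                        **solver_opts)
            out[i] = observable_product(traj) * 1e3
        return out

    return simulate


def abc_smc_fit(model: ModelDefinition, dataset: TimeCourseDataset,
                priors: PriorSet, base_params: ParameterSet,
                n_particles: int = 200, seed: int = 0,
                eps_quantile: float = 0.3, max_populations: int = 8,
                eps_floor: float = 0.0,
                solver_opts: Optional[dict] = None) -> Posterior:
    """Fit a model to a time-course dataset by ABC-SMC.

    Fitting targets the replicate mean of each design cell; the distance
    is the per-series-normalised RMS.  Parameters not covered by
    ``priors`` stay at their ``base_params`` values.
    """
    if n_particles < 50:
        raise ValueError("n_particles must be >= 50")
    conc, times, obs = _dataset_matrices(dataset)
    if conc.size < 2:
        raise ValueError("dataset must cover at least two concentrations")
    for nm in priors.names:
        if not hasattr(base_params, nm):
            raise ValueError(f"prior parameter {nm} unknown to the model family")
    sim = _make_model_simulator(model, base_params, conc, times, solver_opts)
    post = abc_smc(priors, sim, lambda s, o: _distance_matrices(s, o), obs,
                   n_particles=n_particles, seed=seed,
                   eps_quantile=eps_quantile, max_populations=max_populations,
                   eps_floor=eps_floor)
    return post


# -------------------------------------------------------------- model choice
@dataclass
class ModelSelectionResult:
    """Per-population model probabilities and the comparison outcome."""

    probabilities: pd.DataFrame      # rows = populations, cols = model ids
    winner: str
    epsilons: list
    seed: int
    history: list = field(default_factory=list)

    @property
    def final_probabilities(self) -> dict:
        return self.probabilities.iloc[-1].to_dict()


def abc_smc_model_select(problems: Dict[str, tuple], observed,
                         distance: Callable, n_particles: int = 100,
                         seed: int = 0, eps_quantile: float = 0.3,
                         max_populations: int = 8,
                         model_switch_prob: float = 0.25,
                         max_proposals_per_population: Optional[int] = None,
                         ) -> ModelSelectionResult:
    """Joint (model, parameter) ABC-SMC model selection.

    ``problems`` maps model id -> (PriorSet, simulate callable).  The
    prior model probability is uniform (0.5 pairwise, 0.25 for a
    four-model comparison).  Runs until one model has probability 1 or
    the population budget is exhausted.
    """
    if len(problems) < 2:
        raise ValueError("need at least two models to compare")
    rng = np.random.default_rng(seed)
    ids = list(problems.keys())
    cap = max_proposals_per_population or 50 * n_particles

    recs = []        # per particle: (model_idx, theta dict, weight, distance)
    for i in range(n_particles):
        m = rng.integers(len(ids))
        pri, simf = problems[ids[m]]
        th = pri.sample(rng)
        d = _safe_distance(simf, distance, th, observed, rng)
        recs.append([m, th, 1.0 / n_particles, d])
    prob_rows = [_model_probs(recs, len(ids))]
    epsilons = [float("inf")]

    for t in range(1, max_populations):
        finite = np.array([r[3] for r in recs if np.isfinite(r[3])])
        if finite.size == 0:
            break
        eps = float(np.quantile(finite, eps_quantile))
        if eps >= epsilons[-1] and np.isfinite(epsilons[-1]):
            break
        marg = prob_rows[-1]
        # per-model kernel widths from the previous population
        widths = {}
        for m, mid in enumerate(ids):
            vals = [r[1] for r in recs if r[0] == m]
            if vals:
                arr = np.array([[v[k] for k in problems[mid][0].names]
                                for v in vals])
                widths[m] = _kernel_widths(arr, problems[mid][0], 0.5)
        new_recs = []
        proposals = 0
        weights = np.array([r[2] for r in recs])
        weights = weights / weights.sum()
        while len(new_recs) < n_particles and proposals < cap:
            proposals += 1
            # model kernel: resample a model from the marginal, maybe switch
            m = int(np.searchsorted(np.cumsum(marg), rng.uniform()))
            m = min(m, len(ids) - 1)
            if marg[m] == 0:
                continue
            if len(ids) > 1 and rng.uniform() < model_switch_prob:
                others = [k for k in range(len(ids)) if k != m]
                m = others[rng.integers(len(others))]
            if marg[m] == 0 or m not in widths:
                continue
            pri, simf = problems[ids[m]]
            names = pri.names
            cond_w = np.array([r[2] if r[0] == m else 0.0 for r in recs])
            cond_w = cond_w / cond_w.sum()
            j = rng.choice(len(recs), p=cond_w)
            base = recs[j][1]
            cand = {}
            for i, nm in enumerate(names):
                u = pri[nm].transform(base[nm]) + widths[m][i] * rng.uniform(-1, 1)
                cand[nm] = pri[nm].untransform(u)
            prior_pdf = pri.pdf(cand)
            if prior_pdf == 0:
                continue
            d = _safe_distance(simf, distance, cand, observed, rng)
            if d > eps:
                continue
            vec = np.array([cand[k] for k in names])
            arr = np.array([[r[1][k] for k in names] for r in recs if r[0] == m])
            w_arr = np.array([r[2] for r in recs if r[0] == m])
            denom_theta = _kernel_mixture_density(vec, arr, w_arr / w_arr.sum(),
                                                  pri, widths[m])
            km = sum(marg[mp] * (_model_kernel(mp, m, len(ids),
                                               model_switch_prob))
                     for mp in range(len(ids)))
            if denom_theta == 0 or km == 0:
                continue
            w_new = (1.0 / len(ids)) * prior_pdf / (km * denom_theta)
            new_recs.append([m, cand, w_new, d])
        if len(new_recs) < n_particles:
            warnings.warn("model selection stopped early: population "
                          f"unfilled within {cap} proposals")
            break
        tot = sum(r[2] for r in new_recs)
        for r in new_recs:
            r[2] /= tot
        recs = new_recs
        epsilons.append(eps)
        prob_rows.append(_model_probs(recs, len(ids)))
        if max(prob_rows[-1]) >= 1.0:
            break

    probs = pd.DataFrame(prob_rows, columns=ids)
    winner = probs.iloc[-1].idxmax()
    return ModelSelectionResult(probs, winner, epsilons, seed)


def _model_probs(recs, n_models) -> list:
    p = np.zeros(n_models)
    for m, _, w, _ in recs:
        p[m] += w
    s = p.sum()
    return list(p / s if s > 0 else p)


def _model_kernel(m_from: int, m_to: int, n: int, switch: float) -> float:
    if n == 1:
        return 1.0
    if m_from == m_to:
        return 1.0 - switch
    return switch / (n - 1)


def iterative_selection_scheme(make_problem: Callable, observed,
                               distance: Callable, seed: int = 0,
                               n_particles: int = 100,
                               max_populations: int = 6,
                               final_retest: bool = True, **kwargs):
    """The staged comparison ladder over the nine-model family.

    Stage 1 compares the four non-compartmental models jointly (prior
    probability 0.25 each); the winner is then compared pairwise against
    the compartmental models in order of increasing complexity, each
    winner advancing; the overall winner is finally re-tested against
    every other model.  ``make_problem(model_id)`` must return a
    ``(PriorSet, simulate)`` tuple.

    Returns ``(winner, history)`` where history is a list of
    ``(label, ModelSelectionResult)``.
    """
    history = []
    stage1 = {mid: make_problem(mid) for mid in ("M1", "M2", "M3", "M4")}
    res = abc_smc_model_select(stage1, observed, distance,
                               n_particles=n_particles, seed=seed,
                               max_populations=max_populations, **kwargs)
    history.append(("stage1:M1-M4", res))
    winner = res.winner
    for rung, mid in enumerate(("M5", "M6", "M7", "M8", "M9")):
        pair = {winner: make_problem(winner), mid: make_problem(mid)}
        res = abc_smc_model_select(pair, observed, distance,
                                   n_particles=n_particles,
                                   seed=seed + rung + 1,
                                   max_populations=max_populations, **kwargs)
        history.append((f"pair:{winner}-vs-{mid}", res))
        winner = res.winner
    if final_retest:
        for rung, mid in enumerate(m for m in
                                   ("M1", "M2", "M3", "M4", "M5", "M6",
                                    "M7", "M8", "M9") if m != winner):
            pair = {winner: make_problem(winner), mid: make_problem(mid)}
            res = abc_smc_model_select(pair, observed, distance,
                                       n_particles=n_particles,
                                       seed=seed + 100 + rung,
                                       max_populations=max_populations,
                                       **kwargs)
            history.append((f"retest:{winner}-vs-{mid}", res))
            if res.winner != winner:
                winner = res.winner
    return winner, history


# ------------------------------------------------------------------ posterior
def posterior_compare(post_a: Posterior, post_b: Posterior,
                      lo: float = 0.05, hi: float = 0.95,
                      overlap_threshold: float = 0.05) -> pd.DataFrame:
    """Per-parameter marginal comparison of two posteriors.

    Overlap score: length of the intersection of the two central
    credible intervals divided by the length of the shorter interval
    (1 = nested/identical, 0 = disjoint).  Parameters with overlap below
    ``overlap_threshold`` are flagged as showing evidence for a
    difference.
    """
    if list(post_a.names) != list(post_b.names):
        raise ValueError("posteriors have different parameterisations")
    rows = []
    for nm in post_a.names:
        a_lo, a_hi = post_a.interval(nm, lo, hi)
        b_lo, b_hi = post_b.interval(nm, lo, hi)
        inter = max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))
        shorter = max(min(a_hi - a_lo, b_hi - b_lo), 0.0)
        overlap = 1.0 if shorter == 0 and inter >= 0 and a_lo <= b_hi and b_lo <= a_hi \
            else (inter / shorter if shorter > 0 else 0.0)
        rows.append((nm, post_a.median(nm), a_lo, a_hi,
                     post_b.median(nm), b_lo, b_hi, overlap,
                     overlap < overlap_threshold))
    return pd.DataFrame(rows, columns=["parameter", "median_a", "a_q05",
                                       "a_q95", "median_b", "b_q05", "b_q95",
                                       "overlap", "flagged"])
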