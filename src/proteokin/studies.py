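"""Canonical study configurations at desk scale.

Every quantitative exercise of the pipeline (conservation suite,
integrator cross-check, Michaelis-Menten limit, qualitative-phenomenon
fixtures, model-selection and parameter-recovery experiments, the
conjugate ABC toy) is defined here once, so the analysis scripts, the
test suite and the acceptance script all run the same computations.

Problem sizes are deliberately small (hundreds of particles, a handful
of concentrations) so a full pipeline pass runs on a single CPU in
minutes; docs/methods.md records the sizes.
"""

from __future__ import annotations

import numpy as np

from .inference import (Prior, PriorSet, _distance_matrices, _make_model_simulator,
                        abc_smc, abc_smc_fit, abc_smc_model_select,
                        default_priors)
from .models import MODEL_IDS, build_model, make_engine
from .params import ParameterSet
from .simulate import (observable_product, reaction_velocity,
                       simulate_time_course)
from .synthetic import (AssayDesign, default_designs, fixture_parameters,
                        generate_assay_dataset)

__all__ = ["random_conservation_fixture", "conservation_drift",
           "mm_limit_setup", "mm_limit_max_deviation",
           "gaussian_toy", "make_selection_problems",
           "selection_stage1_study", "selection_m9_vs_m5_study",
           "recovery_study"]


# ------------------------------------------------------------- conservation
def random_conservation_fixture(model_id: str, rng: np.random.Generator):
    """Random parameter set and random (conservation-consistent) state."""
    fix = fixture_parameters("LLVY")
    jitter = {nm: getattr(fix, nm) * 10 ** rng.uniform(-1, 1)
              for nm in ("kon", "koff", "vin", "vout", "tau", "kp",
                         "KaS", "KaP", "KiS", "KiP", "Ron", "Roff",
                         "Ion", "Ioff")}
    p = fix.with_(C=rng.uniform(50, 500), Xenh=rng.uniform(0, 15),
                  Yinh=rng.uniform(0, 10), h=float(rng.integers(1, 4)),
                  na=rng.uniform(1, 2), ni=rng.uniform(1, 2),
                  alpha=rng.uniform(0.1, 1.0), beta=rng.uniform(0.01, 1.0),
                  eps_bind=rng.uniform(0, 5), eps_hyd=rng.uniform(0, 5),
                  vmax=rng.uniform(0.001, 0.1), KM=rng.uniform(10, 500),
                  **jitter)
    model = build_model(model_id)
    if not model.compartmentalised:
        state = np.array([rng.uniform(0, 500), rng.uniform(0, 50)])
        return model, p, state
    eng = make_engine(model, p)
    y = np.zeros(eng.dim)
    for k in range(eng.n):
        y[4 * k] = rng.uniform(0, 300)        # outer pools
        y[4 * k + 2] = rng.uniform(0, p.E0 * p.C / 2)
    names = eng.state_names()
    for tot, free, bound in (
            (p.G1_tot, "G1", ("G1Sout", "G1Pout")),
            (p.G2_tot, "G2", ("G2S", "G2P")),
            (p.Ereg_tot, "Ereg", ("EregS", "EregP")),
            (p.I0, "Ifree", ("IS", "IP"))):
        if free not in names:
            continue
        split = rng.dirichlet(np.ones(3)) * tot
        y[names.index(free)] = split[0]
        for b, v in zip(bound, split[1:]):
            y[names.index(b)] = v
    return model, p, y


def conservation_drift(model, p, state, t_end: float = 360.0,
                       rtol: float = 1e-8, atol: float = 1e-10):
    """(max relative drift of conserved totals, min species value)."""
    from scipy.integrate import odeint
    if not model.compartmentalised:
        def rhs(t, y):
            from .models import _noncompartmental_rate
            v = _noncompartmental_rate(model, y[0], y[1], p)
            return np.array([-v, v])
        sol = odeint(rhs, state, [0.0, t_end], tfirst=True,
                     rtol=rtol, atol=atol, mxstep=200000)
        tot0, totE = state.sum(), sol[-1].sum()
        return abs(totE - tot0) / max(abs(tot0), 1e-12), float(sol.min())
    eng = make_engine(model, p)
    sol = odeint(eng.rhs, state, [0.0, t_end], tfirst=True,
                 rtol=rtol, atol=atol, mxstep=200000)
    ref = eng.conservation_totals(np.asarray(state, float))
    end = eng.conservation_totals(sol[-1])
    drift = max(abs(end[k] - ref[k]) / max(abs(ref[k]), 1e-12) for k in ref)
    return drift, float(sol.min())


# ------------------------------------------------------------------ MM limit
def mm_limit_setup():
    """M9 in the fast-transport / no-regulation / no-inhibition regime.

    Transport constants sit >= 1e3 x kp, modifier and product affinities
    at 1e12 (numerically infinite), na = 1; gate site totals are small so
    the gate-bound pools carry negligible peptide, and the capacity is
    far above the largest assay concentration.  The matched reference is
    M1 with vmax = na*kp*E0 and KM = KaS.
    """
    kp = 1e-4
    m9_params = ParameterSet(
        E0=1.0, C=1e4, kon=1000.0, koff=1.0, vin=1e6, vout=0.1, tau=0.1,
        kp=kp, KaS=100.0, KaP=1e12, KiS=1e12, KiP=1e12, na=1.0, ni=1.0,
        alpha=1.0, beta=1.0, Ron=0.0, Roff=0.0, Xenh=0.0,
        Ion=0.0, Ioff=0.0, h=1.0, Yinh=0.0,
        G1_tot=1e-3, G2_tot=1e-3)
    m1_params = ParameterSet(vmax=m9_params.na * kp * m9_params.E0,
                             KM=m9_params.KaS, E0=m9_params.E0)
    return m9_params, m1_params


def mm_limit_max_deviation(concentrations=(20, 40, 80, 160, 320, 480, 640),
                           rtol: float = 1e-10, atol: float = 1e-14) -> float:
    """Max relative initial-velocity deviation of limiting M9 vs M1 (%)."""
    m9p, m1p = mm_limit_setup()
    m9, m1 = build_model("M9"), build_model("M1")
    times = [15.0, 30.0, 45.0, 60.0]
    worst = 0.0
    for s0 in concentrations:
        v9 = reaction_velocity(times, observable_product(
            simulate_time_course(m9, m9p, float(s0), times,
                                 rtol=rtol, atol=atol)))
        v1 = reaction_velocity(times, observable_product(
            simulate_time_course(m1, m1p, float(s0), times,
                                 rtol=rtol, atol=atol)))
        worst = max(worst, abs(v9 - v1) / v1)
    return 100.0 * worst


# -------------------------------------------------------------- Gaussian toy
def gaussian_toy(seed: int = 0, n_obs: int = 50, prior_sd: float = 2.0,
                 noise_sd: float = 1.0, true_mean: float = 1.0,
                 n_particles: int = 300):
    """Conjugate Gaussian-mean problem solved by ABC-SMC.

    Returns (abc posterior mean, analytic posterior mean, MC standard
    error of the weighted mean).
    """
    rng = np.random.default_rng(seed)
    data = rng.normal(true_mean, noise_sd, n_obs)
    ybar = data.mean()
    post_var = 1.0 / (1.0 / prior_sd**2 + n_obs / noise_sd**2)
    analytic_mean = post_var * (n_obs * ybar / noise_sd**2)

    priors = PriorSet(mu=Prior("normal", 0.0, prior_sd))

    def simulate(theta, rng_):
        return rng_.normal(theta["mu"], noise_sd, n_obs).mean()

    # stop near the Monte-Carlo noise floor of the sample mean
    post = abc_smc(priors, simulate, lambda s, o: abs(s - o), ybar,
                   n_particles=n_particles, seed=seed + 1,
                   eps_quantile=0.3, max_populations=8,
                   eps_floor=0.3 * noise_sd / np.sqrt(n_obs))
    mu = post.particles["mu"].to_numpy()
    w = post.weights
    abc_mean = float(np.sum(w * mu))
    ess = 1.0 / np.sum(w**2)
    abc_sd = float(np.sqrt(np.sum(w * (mu - abc_mean) ** 2)))
    mcse = abc_sd / np.sqrt(ess)
    return abc_mean, analytic_mean, mcse


# ----------------------------------------------------------- model selection
_SELECTION_TIMES = np.array([15.0, 30.0, 60.0, 120.0, 240.0, 360.0])
_SELECTION_CONCS = np.array([40.0, 160.0, 640.0])
_SOLVER = {"rtol": 1e-6, "atol": 1e-9}


def _selection_priors(model_id: str, fixture: ParameterSet) -> PriorSet:
    """Reduced free-parameter sets for the scaled-down comparisons."""
    if model_id == "M1":
        return PriorSet(vmax=Prior("loguniform", 1e-4, 1.0),
                        KM=Prior("loguniform", 1.0, 1e4))
    if model_id in ("M2", "M3", "M4"):
        ps = PriorSet(kp=Prior("loguniform", 1e-2, 1e3),
                      KaS=Prior("loguniform", 1.0, 1e4),
                      KiS=Prior("loguniform", 1.0, 1e5))
        if model_id == "M3":
            ps["eps_bind"] = Prior("loguniform", 1e-2, 1e2)
        if model_id == "M4":
            ps["eps_hyd"] = Prior("loguniform", 1e-2, 1e2)
        return ps
    ps = PriorSet(vin=Prior("loguniform", fixture.vin / 100, fixture.vin * 100),
                  kp=Prior("loguniform", fixture.kp / 100, fixture.kp * 100))
    if model_id in ("M6", "M7", "M8", "M9"):
        ps["Xenh"] = Prior("loguniform", 0.01, 100.0)
    if model_id in ("M8", "M9"):
        ps["Yinh"] = Prior("loguniform", 0.01, 100.0)
    return ps


def make_selection_problems(observed_matrix, fixture: ParameterSet,
                            model_ids, concentrations=_SELECTION_CONCS,
                            times=_SELECTION_TIMES):
    """(PriorSet, simulate) problems on the shared reduced design."""
    problems = {}
    for mid in model_ids:
        model = build_model(mid)
        base = fixture
        sim = _make_model_simulator(model, base, concentrations, times,
                                    solver_opts=_SOLVER)
        problems[mid] = (_selection_priors(mid, fixture), sim)
    return problems


def _strong_regulation_fixture() -> ParameterSet:
    """M9 fixture with pronounced enhancer and inhibitor action."""
    return fixture_parameters("LLVY").with_(Xenh=15.0, Yinh=8.0)


def selection_stage1_study(seed: int = 0, n_particles: int = 100,
                           max_populations: int = 6):
    """Recover M1 from Michaelis-Menten data in the joint M1-M4 comparison."""
    rng = np.random.default_rng(seed)
    m1 = build_model("M1")
    truth = ParameterSet(vmax=0.02, KM=150.0)
    sim = _make_model_simulator(m1, truth, _SELECTION_CONCS, _SELECTION_TIMES,
                                solver_opts=_SOLVER)
    obs = sim({}, rng)
    obs = obs * np.exp(0.05 * rng.standard_normal(obs.shape))
    problems = make_selection_problems(obs, fixture_parameters("LLVY"),
                                       ("M1", "M2", "M3", "M4"))
    res = abc_smc_model_select(problems, obs,
                               lambda s, o: _distance_matrices(s, o),
                               n_particles=n_particles, seed=seed,
                               max_populations=max_populations)
    return res


def selection_m9_vs_m5_study(seed: int = 0, n_particles: int = 100,
                             max_populations: int = 7):
    """Recover M9 against M5 from strongly regulated M9 data."""
    rng = np.random.default_rng(seed)
    truth = _strong_regulation_fixture()
    m9 = build_model("M9")
    sim = _make_model_simulator(m9, truth, _SELECTION_CONCS, _SELECTION_TIMES,
                                solver_opts=_SOLVER)
    obs = sim({}, rng)
    obs = obs * np.exp(0.05 * rng.standard_normal(obs.shape))
    problems = make_selection_problems(obs, truth, ("M5", "M9"))
    res = abc_smc_model_select(problems, obs,
                               lambda s, o: _distance_matrices(s, o),
                               n_particles=n_particles, seed=seed,
                               max_populations=max_populations)
    return res


# --------------------------------------------------------- parameter recovery
def recovery_study(seed: int = 0, n_particles: int = 200,
                   max_populations: int = 6, noise_sd: float = 0.05):
    """Fit M9 to its own synthetic six-concentration dataset.

    Free parameters: vin, kp and the chamber capacity C; all others stay
    at the generating fixture values.  The six-point time grid keeps a
    full fit within minutes on one CPU.  Returns (posterior, truth dict).
    """
    truth = fixture_parameters("LLE", "human-s")
    design = AssayDesign("LLE", "human-s",
                         (20.0, 40.0, 80.0, 160.0, 320.0, 640.0),
                         tuple(_SELECTION_TIMES), enzyme_ug=0.5)
    m9 = build_model("M9")
    data = generate_assay_dataset(m9, truth, design, noise_sd=noise_sd,
                                  seed=seed, **_SOLVER)
    priors = default_priors(["vin", "kp", "C"], truth, decades=2.0)
    post = abc_smc_fit(m9, data, priors, truth, n_particles=n_particles,
                       seed=seed + 1, max_populations=max_populations,
                       solver_opts=_SOLVER)
    return post, {"vin": truth.vin, "kp": truth.kp, "C": truth.C}
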