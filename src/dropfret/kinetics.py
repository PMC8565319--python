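"""Mass-action kinetic schemes for protein-promoted strand annealing.

Two schemes are supported.  In the two-step scheme the labelled stem-loop
SL binds the complementary strand P to form a single intermediate complex
that converts irreversibly-ish into the extended duplex ED:

    SL + P  <-> IC1   (k1 association, k_m1 dissociation)
    IC1      -> ED    (kf)

The three-step scheme inserts a second intermediate:

    SL + P  <-> IC1   (k1 / k_m1)
    IC1     <-> IC2   (k2 / k_m2)
    IC2      -> ED    (kf)

Concentrations are handled in uM internally; second-order rate constants
are accepted and reported in M^-1 s^-1 (conversion factor 1e-6).

Both the species-concentration trajectories (time-resolved detection) and
stopped-flow intensity traces (brightness-weighted sums over species) can
be fitted globally across experiments with shared rate constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import DataError, FitError, IntegrationError, InvalidParameterError

__all__ = [
    "KineticParameters",
    "InitialConditions",
    "ConcentrationTrajectory",
    "ObservedTrajectory",
    "BrightnessVector",
    "IntensityTrace",
    "simulate_scheme",
    "fit_concentration_trajectories",
    "predict_intensity",
    "fit_intensity_traces",
    "derived_constants",
    "TrajectoryFitResult",
    "IntensityFitResult",
]

#: uM per M
UM_PER_M = 1e-6

SCHEMES = ("two_step", "three_step")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the annealing schemes.

    ``k1`` is in M^-1 s^-1; all first-order rates in s^-1.  ``k2``/``k_m2``
    are only meaningful for the three-step scheme.
    """

    k1: float
    k_m1: float
    kf: float
    k2: float = 0.0
    k_m2: float = 0.0
    scheme: str = "two_step"

    def __post_init__(self):
        for name in ("k1", "k_m1", "kf", "k2", "k_m2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        if self.scheme not in SCHEMES:
            raise InvalidParameterError(f"scheme must be one of {SCHEMES}")

    @property
    def k1_um(self) -> float:
        """Association rate in uM^-1 s^-1."""
        return self.k1 * UM_PER_M


@dataclass(frozen=True)
class InitialConditions:
    """Total strand concentrations (uM) at the mixing event (T = 0)."""

    sl0: float
    p0: float

    def __post_init__(self):
        if not (np.isfinite(self.sl0) and self.sl0 > 0):
            raise InvalidParameterError(f"sl0 must be > 0, got {self.sl0}")
        if not (np.isfinite(self.p0) and self.p0 > 0):
            raise InvalidParameterError(f"p0 must be > 0, got {self.p0}")


@dataclass
class ConcentrationTrajectory:
    """Species concentrations (uM) along reaction time (s)."""

    times: np.ndarray
    sl: np.ndarray
    ic1: np.ndarray
    ic2: np.ndarray
    ed: np.ndarray
    p: np.ndarray
    init: InitialConditions
    scheme: str = "two_step"
    experiment_id: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("sl", "ic1", "ic2", "ed", "p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def total_ic(self) -> np.ndarray:
        return self.ic1 + self.ic2

    def conservation_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        """Deviation of the two strand balances from the initial totals (uM)."""
        labeled = self.sl + self.ic1 + self.ic2 + self.ed - self.init.sl0
        complement = self.p + self.ic1 + self.ic2 + self.ed - self.init.p0
        return labeled, complement


@dataclass
class ObservedTrajectory:
    """Measured (or decomposed) species concentrations vs reaction time.

    ``ic`` is the observed intermediate pool and ``ed`` the observed duplex
    pool; in the three-step scheme the second intermediate is counted with
    the duplex (they are spectroscopically indistinguishable in the decay
    domain).
    """

    times: np.ndarray
    sl: np.ndarray
    ic: np.ndarray
    ed: np.ndarray
    init: InitialConditions
    errors: dict | None = None
    experiment_id: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.sl = np.asarray(self.sl, dtype=float)
        self.ic = np.asarray(self.ic, dtype=float)
        self.ed = np.asarray(self.ed, dtype=float)
        n = self.times.size
        if not (self.sl.size == self.ic.size == self.ed.size == n):
            raise DataError("trajectory arrays must share one length")


@dataclass
class BrightnessVector:
    """Relative fluorescence intensities per species (duplex fixed at 1)."""

    i_sl: float
    i_ic1: float
    i_ic2: float = 0.0
    i_ed: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        for name in ("i_sl", "i_ic1", "i_ic2", "i_ed", "scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class IntensityTrace:
    """Stopped-flow intensity trace (arbitrary units) for one design."""

    times: np.ndarray
    intensity: np.ndarray
    design: InitialConditions
    experiment_id: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise DataError("times and intensity must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("trace times must be strictly increasing")
        if np.any(~np.isfinite(self.intensity)):
            raise DataError("intensity must be finite")


# ---------------------------------------------------------------------------
# simulation


def _rhs(t, y, ku, k_m1, k2, k_m2, kf, scheme, p_fixed):
    sl, ic1, ic2, ed, p = y
    p_eff = p_fixed if p_fixed is not None else p
    assoc = ku * sl * p_eff
    if scheme == "two_step":
        dsl = -assoc + k_m1 * ic1
        dic1 = assoc - (k_m1 + kf) * ic1
        dic2 = 0.0
        ded = kf * ic1
    else:
        dsl = -assoc + k_m1 * ic1
        dic1 = assoc - (k_m1 + k2) * ic1 + k_m2 * ic2
        dic2 = k2 * ic1 - (k_m2 + kf) * ic2
        ded = kf * ic2
    dp = 0.0 if p_fixed is not None else dsl
    return [dsl, dic1, dic2, ded, dp]


def simulate_scheme(params: KineticParameters, init: InitialConditions, times,
                    *, rtol: float = 1e-8, atol: float = 1e-12,
                    pseudo_first_order: bool = False,
                    experiment_id: str | None = None) -> ConcentrationTrajectory:
    """Integrate the selected scheme on a time grid (stiff-capable solver).

    With ``pseudo_first_order=True`` the complementary strand is frozen at
    its initial concentration, making the system exactly linear (used to
    cross-check the integrator against a matrix-exponential solution).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise InvalidParameterError("times must be >= 0")
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing")
    y0 = [init.sl0, 0.0, 0.0, 0.0, init.p0]
    p_fixed = init.p0 if pseudo_first_order else None
    t_end = float(times[-1]) if times[-1] > 0 else 1e-12
    sol = solve_ivp(
        _rhs, (0.0, t_end), y0, t_eval=times, method="LSODA",
        rtol=rtol, atol=atol,
        args=(params.k1_um, params.k_m1, params.k2, params.k_m2, params.kf,
              params.scheme, p_fixed))
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    y = np.where((sol.y > -1e-9) & (sol.y < 0), 0.0, sol.y)
    return ConcentrationTrajectory(
        times=times, sl=y[0], ic1=y[1], ic2=y[2], ed=y[3], p=y[4],
        init=init, scheme=params.scheme, experiment_id=experiment_id)


# ---------------------------------------------------------------------------
# trajectory fitting (time-resolved detection mode)


@dataclass
class TrajectoryFitResult:
    params: KineticParameters
    stderr: dict[str, float]
    K: float
    K_stderr: float
    chi2: float
    n_points: int
    k1_lower_bound: bool
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scheme": self.params.scheme,
            "k1_M_s": self.params.k1,
            "k_m1_s": self.params.k_m1,
            "k2_s": self.params.k2,
            "k_m2_s": self.params.k_m2,
            "kf_s": self.params.kf,
            "K_M": self.K,
            "K_stderr_M": self.K_stderr,
            "stderr": self.stderr,
            "chi2": self.chi2,
            "n_points": self.n_points,
            "k1_lower_bound": self.k1_lower_bound,
            "flags": self.flags,
        }


def _observed_pools(traj: ConcentrationTrajectory, scheme: str):
    """Map simulated species onto the observed (SL, IC, ED) pools."""
    if scheme == "two_step":
        return traj.sl, traj.ic1, traj.ed
    # decay-domain observation: IC2 is indistinguishable from ED
    return traj.sl, traj.ic1, traj.ic2 + traj.ed


def fit_concentration_trajectories(
        observed: list[ObservedTrajectory], scheme: str = "two_step", *,
        init_guess: KineticParameters | None = None,
        weighting: str = "absolute",
        flatness_threshold: float = 0.02) -> TrajectoryFitResult:
    """Global fit of shared rate constants to species trajectories.

    Residuals are absolute (uM) by default, matching the typical dispersion
    of decomposed concentrations; ``weighting='relative'`` divides by the
    observation magnitude.  Reports K = k1/k_m1 and flags k1 as a lower
    bound when the objective is flat in the k1 direction (at fixed K).
    """
    if scheme not in SCHEMES:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")
    if not observed:
        raise DataError("no trajectories supplied")
    for obs in observed:
        if obs.times.size < 3:
            raise DataError("each trajectory needs at least 3 informative time points")
    if init_guess is None:
        init_guess = KineticParameters(k1=1e4, k_m1=1.0, kf=1.0, k2=1.0,
                                       k_m2=0.0, scheme=scheme)

    three = scheme == "three_step"
    names = ["k1", "k_m1", "kf"] + (["k2", "k_m2"] if three else [])

    def params_from(x):
        vals = dict(zip(["k1", "k_m1", "kf"], np.exp(x[:3])))
        if three:
            vals["k2"] = float(np.exp(x[3]))
            vals["k_m2"] = float(x[4])
        return KineticParameters(scheme=scheme, **vals)

    def resid(x):
        p = params_from(x)
        out = []
        for obs in observed:
            traj = simulate_scheme(p, obs.init, obs.times)
            sl, ic, ed = _observed_pools(traj, scheme)
            for sim, data in ((sl, obs.sl), (ic, obs.ic), (ed, obs.ed)):
                r = sim - data
                if weighting == "relative":
                    r = r / np.maximum(np.abs(data), 1e-3)
                out.append(r)
        return np.concatenate(out)

    x0 = np.log([init_guess.k1, init_guess.k_m1, init_guess.kf])
    lb = np.full(3, -50.0)
    ub = np.full(3, 50.0)
    if three:
        x0 = np.concatenate([x0, [np.log(max(init_guess.k2, 1e-6)), init_guess.k_m2]])
        lb = np.concatenate([lb, [-50.0, 0.0]])
        ub = np.concatenate([ub, [50.0, np.inf]])

    res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12)
    if not res.success and res.cost > 1e-20:
        raise FitError(f"trajectory fit did not converge: {res.message}",
                       best_attempt=res)
    params = params_from(res.x)
    n_points = sum(3 * obs.times.size for obs in observed)
    dof = max(n_points - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
        se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = None
        se_x = np.full(res.x.size, np.nan)
    stderr = {}
    vals = [params.k1, params.k_m1, params.kf] + ([params.k2, params.k_m2] if three else [])
    for i, (name, v) in enumerate(zip(names, vals)):
        # log-parameters: se(log v) -> se(v) = v * se(log v); k_m2 is linear
        stderr[name] = float(se_x[i] * (1.0 if (three and name == "k_m2") else v))

    K = params.k1 / params.k_m1 if params.k_m1 > 0 else np.inf
    if cov is not None and np.isfinite(K):
        var_logK = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        K_stderr = float(K * np.sqrt(max(var_logK, 0.0)))
    else:
        K_stderr = np.nan

    # flatness probe along k1 at fixed K and kf
    cost0 = res.cost
    x_probe = res.x.copy()
    x_probe[0] += np.log(10.0)
    x_probe[1] += np.log(10.0)
    cost_probe = 0.5 * float(np.sum(resid(x_probe) ** 2))
    k1_lower_bound = bool(cost_probe - cost0 <= flatness_threshold * max(cost0, 1e-30))

    flags = []
    if k1_lower_bound:
        flags.append("objective flat in k1 at fixed K: k1 is a lower bound")
    if three and params.k_m2 <= 1e-12:
        flags.append("k_m2 at zero boundary: report as an upper bound")
    return TrajectoryFitResult(
        params=params, stderr=stderr, K=K, K_stderr=K_stderr,
        chi2=2.0 * res.cost, n_points=n_points,
        k1_lower_bound=k1_lower_bound, covariance=cov, flags=flags)


# ---------------------------------------------------------------------------
# intensity traces (stopped-flow mode)


def predict_intensity(trajectory: ConcentrationTrajectory,
                      brightness: BrightnessVector,
                      experiment_id: str | None = None) -> IntensityTrace:
    """Brightness-weighted sum over species concentrations."""
    intensity = brightness.scale * (
        brightness.i_sl * trajectory.sl
        + brightness.i_ic1 * trajectory.ic1
        + brightness.i_ic2 * trajectory.ic2
        + brightness.i_ed * trajectory.ed)
    return IntensityTrace(times=trajectory.times, intensity=intensity,
                          design=trajectory.init,
                          experiment_id=experiment_id or trajectory.experiment_id)


@dataclass
class IntensityFitResult:
    params: KineticParameters
    brightness: BrightnessVector
    scales: list[float]
    stderr: dict[str, float]
    chi2: float
    n_points: int
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scheme": self.params.scheme,
            "k1_M_s": self.params.k1,
            "k_m1_s": self.params.k_m1,
            "k2_s": self.params.k2,
            "k_m2_s": self.params.k_m2,
            "kf_s": self.params.kf,
            "i_sl": self.brightness.i_sl,
            "i_ic1": self.brightness.i_ic1,
            "i_ic2": self.brightness.i_ic2,
            "scales": self.scales,
            "stderr": self.stderr,
            "chi2": self.chi2,
            "n_points": self.n_points,
            "flags": self.flags,
        }


def fit_intensity_traces(traces: list[IntensityTrace], scheme: str = "two_step",
                         *, fixed: dict | None = None,
                         init_guess: dict | None = None,
                         n_starts: int = 3, seed: int = 0,
                         solver_rtol: float = 1e-8) -> IntensityFitResult:
    """Global fit of shared rates and brightnesses to intensity traces.

    The duplex brightness is the unit reference; each trace carries a free
    overall scale.  Any brightness can be pinned via ``fixed`` (e.g.
    ``{"i_ic1": 0.01}`` for the nearly dark first intermediate).  Residuals
    are relative, matching multiplicative detection noise.
    """
    if scheme not in SCHEMES:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")
    if not traces:
        raise DataError("no traces supplied")
    fixed = dict(fixed or {})
    three = scheme == "three_step"
    if len(traces) < 2 and not fixed:
        warnings.warn("single trace with free brightnesses: k1 is weakly "
                      "identifiable; expect wide covariances", stacklevel=2)

    rate_names = ["k1", "k_m1", "kf"] + (["k2", "k_m2"] if three else [])
    bright_names = ["i_sl", "i_ic1"] + (["i_ic2"] if three else [])
    free_bright = [b for b in bright_names if b not in fixed]
    n_rates = len(rate_names)
    n_b = len(free_bright)
    m = len(traces)

    defaults = {"k1": 1e4, "k_m1": 0.01, "kf": 0.02, "k2": 1.0, "k_m2": 0.0,
                "i_sl": 0.3, "i_ic1": 0.5, "i_ic2": 0.5}
    defaults.update(init_guess or {})
    scale0 = [max(tr.intensity.max(), 1e-12) / tr.design.sl0 for tr in traces]

    def unpack(x):
        vals = {}
        for i, name in enumerate(rate_names):
            vals[name] = float(x[i]) if name == "k_m2" else float(np.exp(x[i]))
        params = KineticParameters(scheme=scheme,
                                   k1=vals["k1"], k_m1=vals["k_m1"], kf=vals["kf"],
                                   k2=vals.get("k2", 0.0), k_m2=vals.get("k_m2", 0.0))
        bvals = {"i_ed": 1.0}
        for j, name in enumerate(free_bright):
            bvals[name] = float(x[n_rates + j])
        for name in bright_names:
            if name in fixed:
                bvals[name] = float(fixed[name])
        bvals.setdefault("i_ic2", 0.0)
        brightness = BrightnessVector(i_sl=bvals["i_sl"], i_ic1=bvals["i_ic1"],
                                      i_ic2=bvals["i_ic2"], i_ed=1.0)
        scales = np.exp(x[n_rates + n_b:])
        return params, brightness, scales

    def resid(x):
        params, brightness, scales = unpack(x)
        out = []
        for tr, s in zip(traces, scales):
            traj = simulate_scheme(params, tr.design, tr.times, rtol=solver_rtol)
            pred = s * (brightness.i_sl * traj.sl + brightness.i_ic1 * traj.ic1
                        + brightness.i_ic2 * traj.ic2 + traj.ed)
            out.append((pred - tr.intensity) / np.maximum(np.abs(tr.intensity), 1e-12))
        return np.concatenate(out)

    def build_x0(rng=None):
        xr = []
        for name in rate_names:
            v = defaults[name]
            if rng is not None and name != "k_m2":
                v = v * np.exp(rng.normal(0.0, 1.0))
            xr.append(v if name == "k_m2" else np.log(max(v, 1e-12)))
        xb = [defaults[name] for name in free_bright]
        return np.concatenate([xr, xb, np.log(scale0)])

    lb = np.concatenate([
        [0.0 if n == "k_m2" else -50.0 for n in rate_names],
        np.zeros(n_b), np.full(m, -50.0)])
    ub = np.concatenate([
        [np.inf if n == "k_m2" else 50.0 for n in rate_names],
        np.full(n_b, 50.0), np.full(m, 50.0)])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        x0 = build_x0(rng if start > 0 else None)
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12,
                                max_nfev=2000)
        except (IntegrationError, FitError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("intensity-trace fit failed for all starts")

    params, brightness, scales = unpack(best.x)
    n_points = sum(tr.times.size for tr in traces)
    dof = max(n_points - best.x.size, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov, se = None, np.full(best.x.size, np.nan)
    stderr = {}
    for i, name in enumerate(rate_names):
        v = getattr(params, name)
        stderr[name] = float(se[i] * (1.0 if name == "k_m2" else v))
    for j, name in enumerate(free_bright):
        stderr[name] = float(se[n_rates + j])

    flags = []
    if three and params.k_m2 <= 1e-12:
        flags.append("k_m2 at zero boundary: report as an upper bound")
    return IntensityFitResult(
        params=params, brightness=brightness, scales=[float(s) for s in scales],
        stderr=stderr, chi2=2.0 * best.cost, n_points=n_points,
        covariance=cov, flags=flags)


# ---------------------------------------------------------------------------
# derived constants


def derived_constants(params: KineticParameters) -> dict:
    """Equilibrium constant K = k1/k_m1 and, when a conversion step exists,
    the effective second-order rate k_eff = k1 * k2 / k_m1 (fast
    pre-equilibrium of the first intermediate)."""
    if params.k_m1 <= 0:
        raise InvalidParameterError("K undefined: k_m1 must be > 0")
    out = {"K": params.k1 / params.k_m1}
    if params.k2 > 0:
        out["k_eff"] = params.k1 * params.k2 / params.k_m1
    return out
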