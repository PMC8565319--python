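"""Gaussian-IRF reconvolved multiexponential decay model and fitting.

The physical model is a sum of exponential decays switched on at the time
origin ``t0`` and convolved with a Gaussian instrument response of standard
deviation ``sigma``.  The convolution has a closed form,

    A(t) = C + sum_i (A_i/2) exp(sigma^2 / 2 tau_i^2) exp(-(t-t0)/tau_i)
                 * [1 + erf((t - t0 - sigma^2/tau_i) / (sigma sqrt(2)))],

which is evaluated here in an overflow-safe form based on the scaled
complementary error function.

Goodness of fit is the photon-counting weighted chi-square
``sum_i (y_i - f_i)^2 / max(y_i, floor)`` (Poisson variance, with a
configurable variance floor for empty bins), reported reduced by the number
of degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf, erfcx

from .errors import DataError, FitError, InvalidParameterError, StitchError

__all__ = [
    "InstrumentResponse",
    "DecayComponent",
    "MultiExponentialModel",
    "DecayCurve",
    "DecayFitResult",
    "model_decay",
    "weighted_chi2",
    "reduced_chi2",
    "fit_decay",
    "average_lifetime",
    "stitch_windows",
    "sigma_for_window",
]

_SQRT2 = math.sqrt(2.0)

#: Gaussian IRF standard deviation at the reference (shortest) window, in ns.
SIGMA_REF_NS = 0.010
#: Reference window span in ns for the linear sigma scaling.
WINDOW_REF_NS = 1.0


def sigma_for_window(window_ns: float, sigma_ref: float = SIGMA_REF_NS,
                     window_ref: float = WINDOW_REF_NS) -> float:
    """IRF width for an acquisition window: sigma scales linearly with span."""
    if window_ns <= 0:
        raise InvalidParameterError(f"window must be positive, got {window_ns}")
    return sigma_ref * (window_ns / window_ref)


@dataclass(frozen=True)
class InstrumentResponse:
    """Gaussian instrument response: standard deviation and time origin (ns)."""

    sigma: float
    t0: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be finite and > 0, got {self.sigma}")
        if not np.isfinite(self.t0):
            raise InvalidParameterError(f"t0 must be finite, got {self.t0}")


@dataclass(frozen=True)
class DecayComponent:
    """One exponential component: dimensionless amplitude, lifetime in ns."""

    amplitude: float
    lifetime: float

    def __post_init__(self):
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise InvalidParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if not np.isfinite(self.lifetime) or self.lifetime <= 0:
            raise InvalidParameterError(f"lifetime must be > 0, got {self.lifetime}")


@dataclass(frozen=True)
class MultiExponentialModel:
    """Sum of exponential components plus a constant dark-count offset.

    Components are stored in canonical order (increasing lifetime,
    ties broken by amplitude) so that fits are directly comparable.
    """

    components: tuple[DecayComponent, ...]
    offset: float = 0.0

    def __post_init__(self):
        if len(self.components) < 1:
            raise InvalidParameterError("model needs at least one component")
        if not np.isfinite(self.offset) or self.offset < 0:
            raise InvalidParameterError(f"offset must be >= 0, got {self.offset}")
        ordered = tuple(sorted(self.components, key=lambda c: (c.lifetime, c.amplitude)))
        object.__setattr__(self, "components", ordered)

    @classmethod
    def from_arrays(cls, amplitudes, lifetimes, offset: float = 0.0) -> "MultiExponentialModel":
        amplitudes = np.asarray(amplitudes, dtype=float)
        lifetimes = np.asarray(lifetimes, dtype=float)
        if amplitudes.shape != lifetimes.shape:
            raise InvalidParameterError("amplitudes and lifetimes must have equal length")
        comps = tuple(DecayComponent(a, t) for a, t in zip(amplitudes, lifetimes))
        return cls(comps, offset)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([c.lifetime for c in self.components])

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class DecayCurve:
    """Binned photon counts for one acquisition window.

    ``propagation_time`` is the reaction time T in seconds; reference curves
    (pre-mix stem-loop, equilibrated duplex) carry ``tag`` instead.
    ``sigma_bins`` optionally stores the per-bin IRF sigma (ns), which is how
    stitched multi-window traces remember the resolution of each segment.
    """

    times: np.ndarray
    counts: np.ndarray
    window: float
    propagation_time: float | None = None
    tag: str | None = None
    sigma_bins: np.ndarray | None = None
    experiment_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise DataError("times and counts must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise DataError("a decay curve needs at least two bins")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise DataError("counts must be finite and nonnegative")
        if self.window < self.times[-1] - 1e-12:
            raise DataError(
                f"window ({self.window} ns) smaller than max time ({self.times[-1]} ns)")
        if self.sigma_bins is not None:
            self.sigma_bins = np.asarray(self.sigma_bins, dtype=float)
            if self.sigma_bins.shape != self.times.shape:
                raise DataError("sigma_bins must match times in length")

    @property
    def n_bins(self) -> int:
        return self.times.size

    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class DecayFitResult:
    """Outcome of a reconvolution fit of a single decay curve."""

    model: MultiExponentialModel
    irf: InstrumentResponse
    chi2_reduced: float
    chi2_raw: float
    n_free: int
    uncertainties: dict[str, float]
    n_points: int
    selection_trace: list[tuple[int, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.chi2_reduced < 0:
            raise InvalidParameterError("chi2_reduced must be >= 0")
        if self.n_free < 1:
            raise InvalidParameterError("n_free must be >= 1")

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.model.amplitudes.tolist(),
            "lifetimes_ns": self.model.lifetimes.tolist(),
            "offset": self.model.offset,
            "t0_ns": self.irf.t0,
            "sigma_ns": self.irf.sigma,
            "chi2_reduced": self.chi2_reduced,
            "chi2_raw": self.chi2_raw,
            "n_free": self.n_free,
            "n_points": self.n_points,
            "uncertainties": self.uncertainties,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# model evaluation


def _reconvolved_components(times, t0, sigma, amplitudes, lifetimes):
    """Per-component reconvolved decay, shape (k, n).

    Overflow-safe: using z = (u - sigma^2/tau) / (sigma sqrt(2)) with
    u = t - t0, the closed form factors as
    (A/2) erfcx(-z) exp(-u^2 / 2 sigma^2), because the total exponent
    -u/tau + sigma^2/2tau^2 + z^2 equals u^2/2sigma^2.  For large z the
    erfcx argument would overflow, but there the plain expression
    (A/2) exp(sigma^2/2tau^2 - u/tau) (1 + erf z) is itself safe (its
    exponent is provably negative once z > 4).
    """
    u = np.asarray(times, dtype=float) - t0
    sigma = np.asarray(sigma, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)[:, None]
    lifetimes = np.asarray(lifetimes, dtype=float)[:, None]
    z = (u - sigma**2 / lifetimes) / (sigma * _SQRT2)
    safe = z < 4.0
    with np.errstate(over="ignore", under="ignore"):
        stable = 0.5 * erfcx(np.where(safe, -z, 0.0)) * np.exp(-(u**2) / (2.0 * sigma**2))
        expo = sigma**2 / (2.0 * lifetimes**2) - u / lifetimes
        plain = 0.5 * np.exp(np.where(safe, 0.0, expo)) * (1.0 + erf(z))
    return amplitudes * np.where(safe, stable, plain)


def model_decay(model: MultiExponentialModel, irf: InstrumentResponse, times,
                sigma=None) -> np.ndarray:
    """Expected counts per bin for a reconvolved multiexponential model.

    Parameters
    ----------
    sigma : float or array, optional
        Overrides ``irf.sigma``; an array gives a per-bin IRF width
        (stitched multi-window traces).
    """
    times = np.asarray(times, dtype=float)
    if np.any(~np.isfinite(times)):
        raise InvalidParameterError("times must be finite")
    if sigma is None:
        sigma = irf.sigma
    sigma = np.asarray(sigma, dtype=float)
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise InvalidParameterError("sigma must be finite and > 0")
    comps = _reconvolved_components(times, irf.t0, sigma,
                                    model.amplitudes, model.lifetimes)
    return model.offset + comps.sum(axis=0)


def model_decay_curve(model: MultiExponentialModel, irf: InstrumentResponse,
                      curve: DecayCurve) -> np.ndarray:
    """Evaluate the model on a curve's grid, honouring per-bin sigma metadata."""
    sigma = curve.sigma_bins if curve.sigma_bins is not None else None
    return model_decay(model, irf, curve.times, sigma=sigma)


# ---------------------------------------------------------------------------
# goodness of fit


def weighted_chi2(counts, predicted, variance_floor: float = 1.0) -> float:
    """Poisson-weighted chi-square: sum (y - f)^2 / max(y, floor).

    The variance floor handles empty bins, whose Poisson variance estimate
    would otherwise vanish.
    """
    counts = np.asarray(counts, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if counts.shape != predicted.shape:
        raise DataError(
            f"shape mismatch: counts {counts.shape} vs predicted {predicted.shape}")
    var = np.maximum(counts, variance_floor)
    return float(np.sum((counts - predicted) ** 2 / var))


def reduced_chi2(curve: DecayCurve, predicted, n_free: int,
                 variance_floor: float = 1.0) -> float:
    """Weighted chi-square divided by (number of bins - n_free)."""
    if n_free >= curve.n_bins:
        raise DataError("n_free must be smaller than the number of bins")
    raw = weighted_chi2(curve.counts, predicted, variance_floor)
    return raw / (curve.n_bins - n_free)


def average_lifetime(model: MultiExponentialModel) -> float:
    """Amplitude-weighted mean lifetime, sum(A_i tau_i) / sum(A_i), in ns."""
    amps = model.amplitudes
    total = amps.sum()
    if total <= 0:
        raise InvalidParameterError("average lifetime undefined for all-zero amplitudes")
    return float(np.dot(amps, model.lifetimes) / total)


# ---------------------------------------------------------------------------
# single-curve fitting


def _initial_guess(curve, irf_init, k, rng=None):
    y = curve.counts
    t = curve.times
    c0 = max(float(np.percentile(y, 2)), 0.0)
    peak = max(float(y.max() - c0), 1e-6)
    t_peak = float(t[int(np.argmax(y))])
    span = float(t[-1] - t[0])
    dt = float(np.median(np.diff(t)))
    taus = np.geomspace(max(2 * dt, span * 2e-3), span / 3.0, k)
    amps = np.full(k, peak / k)
    t0 = t_peak
    sigma = irf_init.sigma
    if rng is not None:
        taus = taus * np.exp(rng.normal(0.0, 0.7, size=k))
        taus = np.clip(taus, dt / 10, span * 5)
        t0 = t0 + rng.normal(0.0, 2.0 * sigma)
    return amps, np.sort(taus), c0, t0, sigma


def _fit_k_components(curve, irf_init, k, *, variance_floor, rng, n_starts,
                      fit_sigma=True, fit_t0=True):
    """Bounded LM-style fit (trust-region reflective) with multi-start."""
    t = curve.times
    y = curve.counts
    w = 1.0 / np.sqrt(np.maximum(y, variance_floor))
    dt = float(np.median(np.diff(t)))
    span = float(t[-1] - t[0])
    sigma0 = irf_init.sigma

    def unpack(x):
        amps = x[:k]
        taus = np.exp(x[k:2 * k])
        c = x[2 * k]
        t0 = x[2 * k + 1] if fit_t0 else irf_init.t0
        sig = np.exp(x[2 * k + 2]) if fit_sigma else sigma0
        return amps, taus, c, t0, sig

    def resid(x):
        amps, taus, c, t0, sig = unpack(x)
        f = c + _reconvolved_components(t, t0, sig, amps, taus).sum(axis=0)
        return (f - y) * w

    lb = np.concatenate([np.zeros(k), np.full(k, math.log(dt / 100)),
                         [0.0, t[0] - span / 10, math.log(sigma0 / 30)]])
    ub = np.concatenate([np.full(k, np.inf), np.full(k, math.log(span * 10)),
                         [np.inf, t[-1], math.log(sigma0 * 30)]])

    best = None
    for start in range(n_starts):
        start_rng = rng if start > 0 else None
        amps0, taus0, c0, t00, sig0 = _initial_guess(curve, irf_init, k, start_rng)
        x0 = np.concatenate([amps0, np.log(taus0), [c0, np.clip(t00, lb[2 * k + 1], ub[2 * k + 1]), math.log(sig0)]])
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14,
                                max_nfev=4000)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"fit with {k} components failed to converge")
    amps, taus, c, t0, sig = unpack(best.x)
    return best, (amps, taus, c, t0, sig)


def _uncertainties_from_fit(res, k, amps, taus, sig, fit_sigma, fit_t0):
    """Standard errors from the weighted Jacobian; log-parameters rescaled."""
    J = res.jac
    try:
        cov = np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(J.shape[1], np.nan)
    unc = {}
    order = np.argsort(taus, kind="stable")
    for rank, idx in enumerate(order):
        unc[f"amplitude_{rank}"] = float(se[idx])
        unc[f"lifetime_{rank}"] = float(se[k + idx] * taus[idx])
    unc["offset"] = float(se[2 * k])
    if fit_t0:
        unc["t0"] = float(se[2 * k + 1])
    if fit_sigma:
        unc["sigma"] = float(se[2 * k + 2] * sig)
    return unc


def fit_decay(curve: DecayCurve, irf_init: InstrumentResponse,
              max_components: int = 4, *, improvement_threshold: float = 0.02,
              n_starts: int = 5, seed: int = 0, variance_floor: float = 1.0,
              fit_sigma: bool = True, fit_t0: bool = True) -> DecayFitResult:
    """Reconvolution fit with automatic selection of the component count.

    Components are added one at a time starting from one, until the reduced
    chi-square improves by less than ``improvement_threshold``.  Each
    candidate model is fitted by bounded least squares (lifetimes and sigma
    in log space, amplitudes and offset bounded below at zero) from
    ``n_starts`` seeded initialisations.
    """
    if curve.counts.sum() <= 0:
        raise DataError("degenerate curve: all counts are zero")
    largest = 2 * max_components + 3
    if curve.n_bins < 10 * largest:
        raise DataError(
            f"curve has {curve.n_bins} bins; need >= {10 * largest} for "
            f"max_components={max_components}")
    rng = np.random.default_rng(seed)

    selection = []
    chosen = None
    prev_red = None
    for k in range(1, max_components + 1):
        n_free = 2 * k + 1 + int(fit_t0) + int(fit_sigma)
        res, (amps, taus, c, t0, sig) = _fit_k_components(
            curve, irf_init, k, variance_floor=variance_floor, rng=rng,
            n_starts=n_starts, fit_sigma=fit_sigma, fit_t0=fit_t0)
        raw = 2.0 * res.cost
        red = raw / (curve.n_bins - n_free)
        selection.append((k, red))
        cand = (res, amps, taus, c, t0, sig, raw, red, n_free, k)
        if prev_red is not None and prev_red - red < improvement_threshold:
            break
        chosen = cand
        prev_red = red
        if red < improvement_threshold:  # essentially perfect fit already
            break
    if chosen is None:  # pragma: no cover - first fit always accepted
        raise FitError("no candidate model accepted", best_attempt=selection)

    res, amps, taus, c, t0, sig, raw, red, n_free, k = chosen
    keep = amps > 0  # drop exactly-zero components only if at least one remains
    if keep.sum() == 0:
        keep = np.ones_like(keep, dtype=bool)
    model = MultiExponentialModel.from_arrays(amps[keep], taus[keep], offset=c)
    unc = _uncertainties_from_fit(res, k, amps, taus, sig, fit_sigma, fit_t0)
    flags = []
    if not res.success:
        flags.append("optimizer did not report clean convergence")
    return DecayFitResult(
        model=model, irf=InstrumentResponse(sigma=sig, t0=t0),
        chi2_reduced=red, chi2_raw=raw, n_free=n_free,
        uncertainties=unc, n_points=curve.n_bins,
        selection_trace=selection, flags=flags)


# ---------------------------------------------------------------------------
# window stitching


def stitch_windows(curves, *, min_overlap_bins: int = 3) -> DecayCurve:
    """Append multi-window acquisitions of one decay into a single trace.

    The shortest window supplies the segment [0, w1]; each longer window
    supplies its bins beyond the previous span, rescaled by the ratio of
    summed counts over the overlap region against the already-stitched
    trace (the stitched trace is sampled at the longer window's bin centres
    by interpolation).  Per-bin IRF sigma metadata is carried along from
    the source window.
    """
    curves = sorted(curves, key=lambda c: c.window)
    if len(curves) < 2:
        raise StitchError("need at least two windows to stitch")
    windows = [c.window for c in curves]
    if len(set(windows)) != len(windows):
        raise StitchError(f"duplicate windows in {windows}")
    ref = curves[0]
    for c in curves[1:]:
        same_time = (c.propagation_time == ref.propagation_time) or (
            c.propagation_time is not None and ref.propagation_time is not None
            and np.isclose(c.propagation_time, ref.propagation_time))
        if not (same_time and c.tag == ref.tag):
            raise StitchError("curves to stitch must share propagation time / tag")

    def sig_of(c):
        if c.sigma_bins is not None:
            return c.sigma_bins
        return np.full(c.n_bins, sigma_for_window(c.window))

    times = ref.times.copy()
    counts = ref.counts.astype(float).copy()
    sigmas = sig_of(ref).copy()
    scales = {ref.window: 1.0}
    prev_span = ref.window
    for cur in curves[1:]:
        overlap = (cur.times >= times[0]) & (cur.times <= prev_span)
        if overlap.sum() < min_overlap_bins:
            raise StitchError(
                f"empty overlap between {prev_span} ns and {cur.window} ns windows")
        stitched_at = np.interp(cur.times[overlap], times, counts)
        denom = cur.counts[overlap].sum()
        if denom <= 0:
            raise StitchError("overlap region of longer window has zero counts")
        scale = float(stitched_at.sum() / denom)
        scales[cur.window] = scale
        tail = cur.times > prev_span
        times = np.concatenate([times, cur.times[tail]])
        counts = np.concatenate([counts, cur.counts[tail] * scale])
        sigmas = np.concatenate([sigmas, sig_of(cur)[tail]])
        prev_span = cur.window

    meta = dict(ref.meta)
    meta["stitch_scales"] = scales
    meta["source_windows"] = windows
    return DecayCurve(times=times, counts=counts, window=max(windows),
                      propagation_time=ref.propagation_time, tag=ref.tag,
                      sigma_bins=sigmas, experiment_id=ref.experiment_id,
                      meta=meta)
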