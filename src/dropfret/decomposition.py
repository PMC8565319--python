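"""Global three-species decomposition of mixture decay curves.

Reference measurements fix the decay signatures of the free stem-loop
(triexponential, amplitudes summing to one) and of the equilibrated duplex
(monoexponential, unit amplitude).  Each mixture curve recorded at reaction
time T is then modelled as

    F(t, T) = (1 - alpha - beta) F_SL(t) + beta exp(-t / tau_IC) + alpha F_ED(t)

convolved with the instrument response, with per-curve fractions
(alpha = duplex, beta = intermediate), a free overall scale and dark-count
offset, and one intermediate lifetime tau_IC shared by every curve of every
experiment.  Because the model is linear in the species coefficients at
fixed tau_IC, the global fit is solved by variable projection: weighted
nonnegative least squares per curve inside a one-dimensional search over
tau_IC.  Nonnegative coefficients automatically keep (alpha, beta) on the
simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar, nnls

from .decay import (DecayCurve, InstrumentResponse, MultiExponentialModel,
                    _reconvolved_components)
from .errors import DataError, FitError, InvalidParameterError
from .kinetics import InitialConditions, ObservedTrajectory

__all__ = [
    "SpeciesSignatureSet",
    "DecompositionResult",
    "fit_signatures",
    "decompose_one_step",
    "decompose_two_step_global",
    "to_concentrations",
]


@dataclass
class SpeciesSignatureSet:
    """Fixed per-species decay laws used as the decomposition basis."""

    sl_amplitudes: np.ndarray
    sl_lifetimes: np.ndarray
    ed_lifetime: float
    tau_ic: float | None = None
    fit_info: dict | None = None

    def __post_init__(self):
        self.sl_amplitudes = np.asarray(self.sl_amplitudes, dtype=float)
        self.sl_lifetimes = np.asarray(self.sl_lifetimes, dtype=float)
        if self.sl_amplitudes.shape != self.sl_lifetimes.shape:
            raise InvalidParameterError("SL amplitudes and lifetimes must match")
        if np.any(self.sl_amplitudes < 0):
            raise InvalidParameterError("SL amplitudes must be >= 0")
        if abs(self.sl_amplitudes.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("SL amplitudes must sum to 1")
        if np.any(self.sl_lifetimes <= 0):
            raise InvalidParameterError("SL lifetimes must be > 0")
        if self.ed_lifetime <= 0:
            raise InvalidParameterError("ED lifetime must be > 0")
        if self.tau_ic is not None and self.tau_ic <= 0:
            raise InvalidParameterError("tau_IC must be > 0 when present")
        order = np.argsort(self.sl_lifetimes)
        self.sl_lifetimes = self.sl_lifetimes[order]
        self.sl_amplitudes = self.sl_amplitudes[order]

    def with_tau_ic(self, tau_ic: float) -> "SpeciesSignatureSet":
        return SpeciesSignatureSet(self.sl_amplitudes.copy(), self.sl_lifetimes.copy(),
                                   self.ed_lifetime, tau_ic, self.fit_info)

    def sl_model(self) -> MultiExponentialModel:
        return MultiExponentialModel.from_arrays(self.sl_amplitudes, self.sl_lifetimes)

    def ed_model(self) -> MultiExponentialModel:
        return MultiExponentialModel.from_arrays([1.0], [self.ed_lifetime])

    def to_dict(self) -> dict:
        return {
            "sl_amplitudes": self.sl_amplitudes.tolist(),
            "sl_lifetimes_ns": self.sl_lifetimes.tolist(),
            "ed_lifetime_ns": self.ed_lifetime,
            "tau_ic_ns": self.tau_ic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesSignatureSet":
        return cls(np.asarray(d["sl_amplitudes"]), np.asarray(d["sl_lifetimes_ns"]),
                   float(d["ed_lifetime_ns"]),
                   None if d.get("tau_ic_ns") is None else float(d["tau_ic_ns"]))


@dataclass
class DecompositionResult:
    """Per-curve species fractions plus the shared intermediate lifetime.

    ``table`` has one row per mixture curve: experiment_id, T_s, frac_sl,
    frac_ic (beta), frac_ed (alpha), their standard errors, the per-curve
    scale and offset, and the per-curve reduced chi-square.
    """

    table: pd.DataFrame
    tau_ic: float
    tau_ic_stderr: float
    tau_ic_at_bound: bool
    chi2_reduced: float
    chi2_raw: float
    n_free: int

    def to_summary_dict(self) -> dict:
        return {
            "tau_ic_ns": self.tau_ic,
            "tau_ic_stderr_ns": self.tau_ic_stderr,
            "tau_ic_at_bound": self.tau_ic_at_bound,
            "chi2_reduced": self.chi2_reduced,
            "chi2_raw": self.chi2_raw,
            "n_free": self.n_free,
            "n_curves": int(len(self.table)),
        }


# ---------------------------------------------------------------------------
# basis evaluation


def _curve_sigma(curve: DecayCurve, irf: InstrumentResponse):
    return curve.sigma_bins if curve.sigma_bins is not None else irf.sigma


def _basis_column(curve, irf, amplitudes, lifetimes):
    sigma = _curve_sigma(curve, irf)
    return _reconvolved_components(curve.times, irf.t0, sigma,
                                   amplitudes, lifetimes).sum(axis=0)


def _design_matrix(curve, signatures, irf, tau_ic=None, include_ic=True):
    cols = [_basis_column(curve, irf, signatures.sl_amplitudes, signatures.sl_lifetimes)]
    if include_ic:
        if tau_ic is None:
            raise InvalidParameterError("tau_ic required for the three-species basis")
        cols.append(_basis_column(curve, irf, [1.0], [tau_ic]))
    cols.append(_basis_column(curve, irf, [1.0], [signatures.ed_lifetime]))
    cols.append(np.ones(curve.n_bins))
    return np.column_stack(cols)


def _weighted_nnls(A, y, variance_floor=1.0):
    w = 1.0 / np.sqrt(np.maximum(y, variance_floor))
    coef, _ = nnls(A * w[:, None], y * w)
    resid = (A @ coef - y) * w
    chi2 = float(np.dot(resid, resid))
    return coef, chi2, w


def _coef_errors(A, w, coef):
    """Delta-method errors on fractions from the WLS covariance at the solution."""
    Aw = A * w[:, None]
    try:
        cov = np.linalg.pinv(Aw.T @ Aw)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    return cov


def _fractions_from_coef(coef, cov, include_ic=True):
    """Species fractions (and errors) from nonnegative basis coefficients.

    coef layout: [c_sl, (c_ic,) c_ed, offset]; the species columns all carry
    unit total amplitude, so fractions are coefficient ratios.
    """
    if include_ic:
        c_sl, c_ic, c_ed = coef[0], coef[1], coef[2]
    else:
        c_sl, c_ic, c_ed = coef[0], 0.0, coef[1]
    scale = c_sl + c_ic + c_ed
    if scale <= 0:
        raise FitError("decomposition degenerate: zero total species amplitude")
    alpha = c_ed / scale
    beta = c_ic / scale
    errs = {"alpha": np.nan, "beta": np.nan}
    if cov is not None:
        # gradient of alpha = c_ed/S and beta = c_ic/S w.r.t. the species coefs
        idx = [0, 1, 2] if include_ic else [0, 1]
        sub = cov[np.ix_(idx, idx)]
        if include_ic:
            g_a = np.array([-alpha, -alpha, 1.0 - alpha]) / scale
            g_b = np.array([-beta, 1.0 - beta, -beta]) / scale
        else:
            g_a = np.array([-alpha, 1.0 - alpha]) / scale
            g_b = np.zeros(2)
        errs["alpha"] = float(np.sqrt(max(g_a @ sub @ g_a, 0.0)))
        errs["beta"] = float(np.sqrt(max(g_b @ sub @ g_b, 0.0)))
    return alpha, beta, scale, errs


# ---------------------------------------------------------------------------
# signature fitting


def _softmax(logits):
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def fit_signatures(sl_curves: list[DecayCurve], ed_curves: list[DecayCurve],
                   irf: InstrumentResponse, *, n_sl_components: int = 3,
                   improvement_threshold: float = 0.02,
                   variance_floor: float = 1.0) -> SpeciesSignatureSet:
    """Fit the reference stem-loop and duplex signatures globally.

    All stem-loop curves share one triexponential law (amplitudes summing
    to one via a softmax parameterisation) and all duplex curves share one
    monoexponential lifetime; each curve keeps a free scale and offset.
    The time origin is fitted shared per species; per-bin sigma metadata
    (or ``irf.sigma``) is taken as known.
    """
    if not sl_curves or not ed_curves:
        raise DataError("need at least one stem-loop and one duplex reference curve")

    def global_multi_fit(curves, k):
        nc = len(curves)
        # x = [logits (k-1), log taus (k), t0, log scale per curve, offset per curve]
        spans = [float(c.times[-1] - c.times[0]) for c in curves]
        span = max(spans)
        tau0 = np.geomspace(span * 5e-3, span / 4.0, k)
        scale0 = [max(c.counts.max(), 1.0) for c in curves]

        def unpack(x):
            amps = _softmax(x[:k - 1]) if k > 1 else np.array([1.0])
            taus = np.exp(x[k - 1:2 * k - 1])
            t0 = x[2 * k - 1]
            scales = np.exp(x[2 * k:2 * k + nc])
            offsets = x[2 * k + nc:]
            return amps, taus, t0, scales, offsets

        def resid(x):
            amps, taus, t0, scales, offsets = unpack(x)
            out = []
            for c, s, off in zip(curves, scales, offsets):
                sigma = _curve_sigma(c, irf)
                f = off + s * _reconvolved_components(
                    c.times, t0, sigma, amps, taus).sum(axis=0)
                w = 1.0 / np.sqrt(np.maximum(c.counts, variance_floor))
                out.append((f - c.counts) * w)
            return np.concatenate(out)

        x0 = np.concatenate([np.zeros(k - 1), np.log(tau0), [irf.t0],
                             np.log(scale0), np.zeros(nc)])
        lb = np.concatenate([np.full(k - 1, -20.0), np.full(k, np.log(span * 1e-5)),
                             [irf.t0 - span / 10], np.full(nc, -50.0), np.zeros(nc)])
        ub = np.concatenate([np.full(k - 1, 20.0), np.full(k, np.log(span * 10)),
                             [irf.t0 + span / 10], np.full(nc, 80.0),
                             np.full(nc, np.inf)])
        res = least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub),
                            method="trf", x_scale="jac",
                            ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=6000)
        amps, taus, t0, scales, offsets = unpack(res.x)
        n_pts = sum(c.n_bins for c in curves)
        n_free = res.x.size
        red = 2.0 * res.cost / max(n_pts - n_free, 1)
        return amps, taus, t0, scales, offsets, red

    amps3, taus3, t0_sl, sl_scales, sl_offsets, red3 = global_multi_fit(
        sl_curves, n_sl_components)
    if n_sl_components >= 3:
        _, _, _, _, _, red2 = global_multi_fit(sl_curves, n_sl_components - 1)
        if red2 - red3 < improvement_threshold:
            warnings.warn(
                "three stem-loop components do not improve the fit beyond the "
                "threshold; returning the three-component signature anyway",
                stacklevel=2)

    amps1, taus1, t0_ed, ed_scales, ed_offsets, red_ed = global_multi_fit(ed_curves, 1)

    order = np.argsort(taus3)
    info = {
        "sl_chi2_reduced": red3,
        "ed_chi2_reduced": red_ed,
        "sl_t0": float(t0_sl),
        "ed_t0": float(t0_ed),
        "sl_scales": [float(s) for s in sl_scales],
        "ed_scales": [float(s) for s in ed_scales],
    }
    return SpeciesSignatureSet(sl_amplitudes=amps3[order], sl_lifetimes=taus3[order],
                               ed_lifetime=float(taus1[0]), tau_ic=None,
                               fit_info=info)


# ---------------------------------------------------------------------------
# decomposition


def _mixture_curves(curves):
    """Keep only curves that belong to the reaction (drop pre-mix references)."""
    out = []
    for c in curves:
        if c.tag is not None:
            continue
        if c.propagation_time is None or c.propagation_time < 0:
            continue
        out.append(c)
    return out


def decompose_one_step(curves: list[DecayCurve], signatures: SpeciesSignatureSet,
                       irf: InstrumentResponse, *,
                       variance_floor: float = 1.0) -> pd.DataFrame:
    """Two-species (stem-loop + duplex) decomposition, one alpha per curve."""
    rows = []
    for c in _mixture_curves(curves):
        A = _design_matrix(c, signatures, irf, include_ic=False)
        coef, chi2, w = _weighted_nnls(A, c.counts, variance_floor)
        cov = _coef_errors(A, w, coef)
        alpha, _, scale, errs = _fractions_from_coef(coef, cov, include_ic=False)
        n_free = 3
        rows.append({
            "experiment_id": c.experiment_id, "T_s": c.propagation_time,
            "alpha": alpha, "alpha_err": errs["alpha"], "scale": scale,
            "offset": coef[-1],
            "chi2_reduced": chi2 / max(c.n_bins - n_free, 1),
        })
    if not rows:
        raise DataError("no mixture curves to decompose")
    return pd.DataFrame(rows)


def decompose_two_step_global(curve_sets, signatures: SpeciesSignatureSet,
                              irf: InstrumentResponse, *,
                              tau_bounds: tuple[float, float] = (0.005, 2.0),
                              variance_floor: float = 1.0,
                              beta_zero: bool = False) -> DecompositionResult:
    """Three-species decomposition with one shared intermediate lifetime.

    ``curve_sets`` is either a flat list of curves or a list of lists (one
    per experiment).  Signatures are frozen; only the species coefficients,
    per-curve scale/offset and the shared tau_IC are fitted.  With
    ``beta_zero=True`` the intermediate column is dropped, reproducing the
    two-species decomposition.
    """
    if curve_sets and isinstance(curve_sets[0], DecayCurve):
        curve_sets = [curve_sets]
    curves = [c for group in curve_sets for c in _mixture_curves(group)]
    if not curves:
        raise DataError("no mixture curves to decompose")

    include_ic = not beta_zero
    n_bins_total = sum(c.n_bins for c in curves)

    def total_chi2(tau_ic):
        total = 0.0
        for c in curves:
            A = _design_matrix(c, signatures, irf,
                               tau_ic=tau_ic if include_ic else None,
                               include_ic=include_ic)
            _, chi2, _ = _weighted_nnls(A, c.counts, variance_floor)
            total += chi2
        return total

    if include_ic:
        lo, hi = np.log(tau_bounds[0]), np.log(tau_bounds[1])
        opt = minimize_scalar(lambda x: total_chi2(np.exp(x)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        tau_ic = float(np.exp(opt.x))
        at_bound = (np.log(tau_ic) - lo < 1e-3) or (hi - np.log(tau_ic) < 1e-3)
        # curvature of the total chi2 w.r.t. tau_IC for a standard error
        h = max(tau_ic * 1e-3, 1e-6)
        c0, cp, cm = total_chi2(tau_ic), total_chi2(tau_ic + h), total_chi2(tau_ic - h)
        curv = (cp + cm - 2.0 * c0) / h**2
        tau_stderr = float(np.sqrt(2.0 / curv)) if curv > 0 else np.nan
    else:
        tau_ic, tau_stderr, at_bound = np.nan, np.nan, False

    rows = []
    chi2_raw = 0.0
    for c in curves:
        A = _design_matrix(c, signatures, irf,
                           tau_ic=tau_ic if include_ic else None,
                           include_ic=include_ic)
        coef, chi2, w = _weighted_nnls(A, c.counts, variance_floor)
        cov = _coef_errors(A, w, coef)
        alpha, beta, scale, errs = _fractions_from_coef(coef, cov, include_ic)
        chi2_raw += chi2
        rows.append({
            "experiment_id": c.experiment_id, "T_s": c.propagation_time,
            "frac_sl": 1.0 - alpha - beta, "frac_ic": beta, "frac_ed": alpha,
            "frac_ic_err": errs["beta"], "frac_ed_err": errs["alpha"],
            "scale": scale, "offset": coef[-1],
            "chi2_reduced": chi2 / max(c.n_bins - (4 if include_ic else 3), 1),
        })
    table = pd.DataFrame(rows).sort_values(["experiment_id", "T_s"]).reset_index(drop=True)
    n_free = (1 if include_ic else 0) + (4 if include_ic else 3) * len(curves)
    return DecompositionResult(
        table=table, tau_ic=tau_ic, tau_ic_stderr=tau_stderr,
        tau_ic_at_bound=bool(at_bound),
        chi2_reduced=chi2_raw / max(n_bins_total - n_free, 1),
        chi2_raw=chi2_raw, n_free=n_free)


def to_concentrations(result: DecompositionResult, totals: dict) -> list[ObservedTrajectory]:
    """Rescale fractions to concentrations (uM) per experiment.

    ``totals`` maps experiment_id -> (total labelled concentration,
    complementary concentration), both in uM.
    """
    out = []
    for exp_id, group in result.table.groupby("experiment_id", dropna=False):
        if exp_id not in totals:
            raise InvalidParameterError(f"no totals provided for experiment {exp_id!r}")
        sl0, p0 = totals[exp_id]
        if sl0 <= 0 or p0 <= 0:
            raise InvalidParameterError("total concentrations must be positive")
        g = group.sort_values("T_s")
        errors = {
            "ic": (g["frac_ic_err"] * sl0).to_numpy(),
            "ed": (g["frac_ed_err"] * sl0).to_numpy(),
        }
        out.append(ObservedTrajectory(
            times=g["T_s"].to_numpy(),
            sl=(g["frac_sl"] * sl0).to_numpy(),
            ic=(g["frac_ic"] * sl0).to_numpy(),
            ed=(g["frac_ed"] * sl0).to_numpy(),
            init=InitialConditions(sl0=sl0, p0=p0),
            errors=errors, experiment_id=exp_id))
    return out
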