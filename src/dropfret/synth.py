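"""Synthetic-data generation: every input the analysis pipeline consumes.

Emulates the droplet instrument (three stitchable acquisition windows with
window-scaled Gaussian IRF, Poisson photon noise, dark counts), species
concentrations evolving under the kinetic schemes, and stopped-flow
intensity traces with per-species brightness.  All stochastic output is
driven by an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import (DecayCurve, InstrumentResponse, MultiExponentialModel,
                    model_decay, sigma_for_window, stitch_windows)
from .decomposition import SpeciesSignatureSet
from .errors import InvalidParameterError
from .kinetics import (BrightnessVector, InitialConditions, KineticParameters,
                       predict_intensity, simulate_scheme)

__all__ = [
    "ExperimentDesign",
    "default_signatures",
    "propagation_times",
    "generate_decay_curves",
    "generate_reference_curves",
    "generate_trf_experiment",
    "generate_trfi_traces",
    "TrfExperiment",
]

#: Published reference signatures of the labelled hairpin (triexponential),
#: the equilibrated duplex (monoexponential) and the short-lived
#: intermediate used as generator defaults.
SL_AMPLITUDES = (0.46, 0.44, 0.10)
SL_LIFETIMES_NS = (0.11, 0.71, 2.66)
ED_LIFETIME_NS = 4.19
TAU_IC_NS = 0.045

#: Droplet speed range supported by the instrument (mm/s).
SPEED_RANGE_MM_S = (7.0, 80.0)


def default_signatures(tau_ic: float | None = TAU_IC_NS) -> SpeciesSignatureSet:
    """Reference species signatures used by the synthetic generator."""
    return SpeciesSignatureSet(
        sl_amplitudes=np.array(SL_AMPLITUDES), sl_lifetimes=np.array(SL_LIFETIMES_NS),
        ed_lifetime=ED_LIFETIME_NS, tau_ic=tau_ic)


@dataclass
class ExperimentDesign:
    """Concentrations, droplet timing and instrument settings for one run."""

    sl0: float
    p0: float
    nc_ratio: float = 1.0
    positions_mm: np.ndarray | None = None
    speed_mm_s: float | None = None
    windows: tuple[float, ...] = (1.0, 5.0, 20.0)
    n_bins: int = 1000
    counts_per_curve: float = 1e6
    dark_counts_per_bin: float = 1.0
    t0_ns: float = 0.1
    seed: int = 0
    experiment_id: str = "exp"

    def __post_init__(self):
        if self.sl0 <= 0 or self.p0 <= 0:
            raise InvalidParameterError("concentrations must be positive")
        if self.speed_mm_s is not None:
            lo, hi = SPEED_RANGE_MM_S
            if not (lo <= self.speed_mm_s <= hi):
                raise InvalidParameterError(
                    f"droplet speed {self.speed_mm_s} mm/s outside the "
                    f"instrument range {SPEED_RANGE_MM_S}")
        if self.positions_mm is not None:
            self.positions_mm = np.asarray(self.positions_mm, dtype=float)
            if np.any(self.positions_mm < 0):
                raise InvalidParameterError("channel positions must be >= 0")

    @property
    def init(self) -> InitialConditions:
        return InitialConditions(sl0=self.sl0, p0=self.p0)

    def irf_for_window(self, window: float) -> InstrumentResponse:
        return InstrumentResponse(sigma=sigma_for_window(window), t0=self.t0_ns)


def propagation_times(positions_mm, speed_mm_s: float) -> np.ndarray:
    """Reaction times (s) from channel positions (mm) and droplet speed (mm/s)."""
    if speed_mm_s <= 0:
        raise InvalidParameterError(f"speed must be > 0, got {speed_mm_s}")
    positions = np.asarray(positions_mm, dtype=float)
    if np.any(positions < 0):
        raise InvalidParameterError("positions must be >= 0")
    return positions / speed_mm_s


def _window_times(window: float, n_bins: int) -> np.ndarray:
    """Bin centres of a uniform grid covering [0, window]."""
    return (np.arange(n_bins) + 0.5) * (window / n_bins)


def _mixture_model(fractions, signatures: SpeciesSignatureSet) -> MultiExponentialModel:
    f_sl, f_ic, f_ed = fractions
    amps, taus = [], []
    if f_sl > 0:
        amps.extend(f_sl * signatures.sl_amplitudes)
        taus.extend(signatures.sl_lifetimes)
    if f_ic > 0:
        if signatures.tau_ic is None:
            raise InvalidParameterError("signatures lack tau_IC for a nonzero IC fraction")
        amps.append(f_ic)
        taus.append(signatures.tau_ic)
    if f_ed > 0:
        amps.append(f_ed)
        taus.append(signatures.ed_lifetime)
    if not amps:
        raise InvalidParameterError("all species fractions are zero")
    return MultiExponentialModel.from_arrays(amps, taus)


def _check_simplex(fractions, tol=1e-9):
    f = np.asarray(fractions, dtype=float)
    if np.any(f < -tol) or f.sum() > 1.0 + tol:
        raise InvalidParameterError(f"fractions {fractions} outside the simplex")


def generate_decay_curves(fractions, signatures: SpeciesSignatureSet,
                          design: ExperimentDesign, *, rng=None,
                          poisson: bool = True, stitch: bool = False):
    """Generate per-window decay curves for a list of (T, fractions) points.

    ``fractions`` is a sequence of ``(T_seconds, (f_sl, f_ic, f_ed))``.  For
    every reaction time and acquisition window, the species mixture is
    reconvolved with the window-scaled IRF, scaled to the configured photon
    budget, offset by the dark-count level, and Poisson-sampled.

    Returns a list per reaction time; each entry is either the list of
    window curves or (``stitch=True``) the stitched single trace.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    out = []
    for T, frac in fractions:
        _check_simplex(frac)
        model = _mixture_model(frac, signatures)
        window_curves = []
        for w in design.windows:
            irf = design.irf_for_window(w)
            t = _window_times(w, design.n_bins)
            shape = model_decay(model, irf, t)
            total = shape.sum()
            expected = shape * (design.counts_per_curve / total) + design.dark_counts_per_bin
            counts = rng.poisson(expected).astype(float) if poisson else expected
            window_curves.append(DecayCurve(
                times=t, counts=counts, window=w, propagation_time=T,
                sigma_bins=np.full(design.n_bins, irf.sigma),
                experiment_id=design.experiment_id))
        out.append(stitch_windows(window_curves) if stitch else window_curves)
    return out


def generate_reference_curves(design: ExperimentDesign,
                              signatures: SpeciesSignatureSet, kind: str, *,
                              n_replicates: int = 1, rng=None,
                              poisson: bool = True):
    """Pure-species reference curves, tagged pre-mix 'SL' or equilibrated 'ED'.

    Pre-mix curves carry a negative propagation time by convention.
    """
    if kind not in ("SL", "ED"):
        raise InvalidParameterError("kind must be 'SL' or 'ED'")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    frac = (1.0, 0.0, 0.0) if kind == "SL" else (0.0, 0.0, 1.0)
    T = -1.0 if kind == "SL" else None
    out = []
    for _ in range(n_replicates):
        sets = generate_decay_curves([(0.0, frac)], signatures, design,
                                     rng=rng, poisson=poisson)
        for c in sets[0]:
            c.tag = kind
            c.propagation_time = T
        out.append(sets[0])
    return out


@dataclass
class TrfExperiment:
    """Simulated droplet experiment: curves plus the generating truth."""

    design: ExperimentDesign
    mixture_curves: list        # one list of window curves per reaction time
    sl_references: list
    ed_references: list
    truth: dict = field(default_factory=dict)


def generate_trf_experiment(design: ExperimentDesign, params: KineticParameters,
                            signatures: SpeciesSignatureSet, *,
                            n_times: int = 10, t_range=(0.1, 10.0),
                            n_reference_replicates: int = 2,
                            seed: int | None = None,
                            poisson: bool = True,
                            ic2_as: str = "ed") -> TrfExperiment:
    """Simulate one full droplet mixing experiment.

    Reaction times are taken from the design's channel positions and
    droplet speed when present, otherwise log-spaced over ``t_range``.
    Species concentrations come from the kinetic scheme; in the three-step
    scheme the second intermediate contributes to the duplex signature by
    default (``ic2_as='ed'``: its lifetime is experimentally
    indistinguishable from the duplex), or to the intermediate signature
    with ``ic2_as='ic'`` for identifiability studies.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    if design.positions_mm is not None and design.speed_mm_s is not None:
        T = propagation_times(design.positions_mm, design.speed_mm_s)
    else:
        T = np.geomspace(t_range[0], t_range[1], n_times)
    traj = simulate_scheme(params, design.init, T)
    f_sl = traj.sl / design.sl0
    f_ic = traj.ic1 / design.sl0
    f_ed = traj.ed / design.sl0
    if params.scheme == "three_step":
        if ic2_as == "ed":
            f_ed = f_ed + traj.ic2 / design.sl0
        elif ic2_as == "ic":
            f_ic = f_ic + traj.ic2 / design.sl0
        else:
            raise InvalidParameterError("ic2_as must be 'ed' or 'ic'")
    fractions = [(float(t), (float(a), float(b), float(c)))
                 for t, a, b, c in zip(T, f_sl, f_ic, f_ed)]
    mixtures = generate_decay_curves(fractions, signatures, design,
                                     rng=rng, poisson=poisson)
    sl_refs = generate_reference_curves(design, signatures, "SL",
                                        n_replicates=n_reference_replicates,
                                        rng=rng, poisson=poisson)
    ed_refs = generate_reference_curves(design, signatures, "ED",
                                        n_replicates=n_reference_replicates,
                                        rng=rng, poisson=poisson)
    truth = {"params": params, "trajectory": traj, "fractions": fractions,
             "signatures": signatures}
    return TrfExperiment(design=design, mixture_curves=mixtures,
                         sl_references=sl_refs, ed_references=ed_refs, truth=truth)


def generate_trfi_traces(designs, params: KineticParameters,
                         brightness: BrightnessVector, noise: float, *,
                         time_grid=None, seed: int = 0):
    """Simulate stopped-flow intensity traces with relative Gaussian noise.

    Returns ``(traces, truth)`` where truth records the generating
    parameters and noiseless trajectories.
    """
    if noise < 0:
        raise InvalidParameterError(f"noise must be >= 0, got {noise}")
    rng = np.random.default_rng(seed)
    if time_grid is None:
        time_grid = np.geomspace(0.01, 150.0, 150)
    traces, clean = [], []
    for i, design in enumerate(designs):
        init = design.init if isinstance(design, ExperimentDesign) else design
        exp_id = (design.experiment_id if isinstance(design, ExperimentDesign)
                  else f"trace_{i}")
        traj = simulate_scheme(params, init, time_grid, experiment_id=exp_id)
        trace = predict_intensity(traj, brightness, experiment_id=exp_id)
        clean.append(trace.intensity.copy())
        if noise > 0:
            trace.intensity = trace.intensity * (
                1.0 + rng.normal(0.0, noise, size=trace.intensity.size))
        traces.append(trace)
    truth = {"params": params, "brightness": brightness, "noise": noise,
             "clean_intensity": clean}
    return traces, truth
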