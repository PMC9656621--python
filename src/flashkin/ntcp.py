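"""Peroxyl-radical exposure metrics and the NTCP dose-response model.

The biological-damage surrogate is the area under the peroxyl-radical
concentration curve,

    AUC-ROO = integral of [ROO](t) dt        (uM s),

normalised between two fixed anchor simulations (a high-exposure continuous
delivery and a minimal two-pulse delivery) and mapped to a normal-tissue
complication probability by a logistic response

    NTCP = 1 / (1 + exp(-gamma (AUC_norm - AUC50))).

The shipped default parameters are gamma = 1000 and AUC50 = 0.1682 (murine
brain model, low-LET electrons).  D50 is the dose at which a dose-response
curve crosses NTCP = 0.5; the FLASH modifying factor is the ratio of the
ultra-high-dose-rate D50 to the conventional-dose-rate D50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

from .beam import BeamSchedule, GValueSet, pulses_for
from .homo import KineticsTrace, simulate
from .reaction_network import ReactionSystem

__all__ = [
    "NTCPModel",
    "FitError",
    "NTCPFit",
    "ScheduleTemplate",
    "DoseResponseCurve",
    "auc_roo",
    "normalize_auc",
    "ntcp",
    "fit_ntcp",
    "compute_anchors",
    "dose_response",
    "flash_modifying_factor",
]

#: Default fitted slope of the logistic response (dimensionless).
DEFAULT_GAMMA = 1000.0
#: Default normalised AUC at 50 % complication probability.
DEFAULT_AUC50 = 0.1682


class FitError(RuntimeError):
    """The sigmoid fit is degenerate or non-identifiable."""


@dataclass(frozen=True)
class NTCPModel:
    """Logistic (gamma, AUC50) response plus AUC normalisation anchors."""

    gamma: float = DEFAULT_GAMMA
    auc50: float = DEFAULT_AUC50
    auc_high: float | None = None     # uM s, high-exposure anchor
    auc_low: float | None = None      # uM s, minimal-exposure anchor

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.auc_high is not None and self.auc_low is not None:
            if not self.auc_high > self.auc_low > 0:
                raise ValueError("anchors must satisfy auc_high > auc_low > 0")

    def with_anchors(self, auc_high: float, auc_low: float) -> "NTCPModel":
        return replace(self, auc_high=auc_high, auc_low=auc_low)


def auc_roo(trace: KineticsTrace, t_end: float | None = None) -> float:
    """Trapezoidal integral of [ROO] over the trace grid, in uM s."""
    c = trace.species("ROO")  # KeyError if absent
    t = trace.t
    if t_end is not None:
        keep = t <= t_end
        t, c = t[keep], c[keep]
    return float(np.trapezoid(c, t) * 1e6)


def normalize_auc(auc: float, model: NTCPModel, eps: float = 0.05) -> float:
    """Min-max scaling of a raw AUC (uM s) between the model anchors."""
    if model.auc_high is None or model.auc_low is None:
        raise ValueError("normalisation anchors have not been computed")
    x = (auc - model.auc_low) / (model.auc_high - model.auc_low)
    if x < 0 or x > 1 + eps:
        warnings.warn(
            f"normalised AUC {x:.3f} outside [0, 1+{eps}]", stacklevel=2
        )
    return float(np.clip(x, 0.0, 1.0 + eps))

def ntcp(model: NTCPModel, auc_norm: float | np.ndarray):
    """Logistic complication probability for a normalised AUC."""
    z = model.gamma * (np.asarray(auc_norm, dtype=float) - model.auc50)
    out = 1.0 / (1.0 + np.exp(-z))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# anchors and dose-response curves
# ---------------------------------------------------------------------------

#: Anchor prescriptions: AUC_high from a 30 Gy delivery at 0.03 Gy/s
#: (continuous; at such rates pulse structure is irrelevant), AUC_low from
#: the minimal two-pulse train delivering 1 Gy at 100 Gy/s and 100 Hz.
ANCHOR_HIGH = {"dose": 30.0, "dose_rate": 0.03}
ANCHOR_LOW = {"dose": 1.0, "dose_rate": 100.0, "frequency": 100.0,
              "pulse_width": 1.8e-6}


def compute_anchors(
    system: ReactionSystem,
    g: GValueSet | None = None,
    o2_percent: float = 3.8,
    t_end_tail: float = 300.0,
    **sim_kwargs,
) -> tuple[float, float]:
    """Simulate the two normalisation anchors; returns (auc_high, auc_low)."""
    sched_hi = BeamSchedule.continuous(ANCHOR_HIGH["dose"], ANCHOR_HIGH["dose_rate"])
    tr_hi = simulate(
        system, sched_hi, g=g, o2_percent=o2_percent,
        t_end=sched_hi.t_irr + t_end_tail, **sim_kwargs,
    )
    sched_lo = pulses_for(
        ANCHOR_LOW["dose_rate"], ANCHOR_LOW["dose"],
        ANCHOR_LOW["frequency"], ANCHOR_LOW["pulse_width"],
    )
    tr_lo = simulate(
        system, sched_lo, g=g, o2_percent=o2_percent,
        t_end=sched_lo.duration + t_end_tail, **sim_kwargs,
    )
    return auc_roo(tr_hi), auc_roo(tr_lo)


@dataclass(frozen=True)
class ScheduleTemplate:
    """Pulse structure reused across a dose grid (accelerator fingerprint)."""

    mode: str = "continuous"           # continuous | pulsed | semi_continuous
    frequency: float = 0.0             # Hz, pulsed mode
    pulse_width: float = 0.0           # s

    def build(self, dose: float, mean_dose_rate: float) -> BeamSchedule:
        if self.mode == "continuous":
            return BeamSchedule.continuous(dose, mean_dose_rate)
        if self.mode == "semi_continuous":
            return BeamSchedule.semi_continuous(dose, mean_dose_rate,
                                                self.pulse_width or 1.8e-6)
        return pulses_for(mean_dose_rate, dose, self.frequency, self.pulse_width)


@dataclass
class DoseResponseCurve:
    doses: np.ndarray
    auc: np.ndarray          # uM s
    auc_norm: np.ndarray
    ntcp: np.ndarray
    dose_rate: float
    d50: float


def _d50(doses: np.ndarray, auc_norm: np.ndarray, model: NTCPModel) -> float:
    """Dose at NTCP = 0.5, i.e. where AUC_norm crosses AUC50.

    Monotone piecewise-cubic interpolation of the (smooth) AUC_norm(D)
    curve avoids oscillation in the steep sigmoid region; for any gamma the
    logistic crosses 0.5 exactly at AUC_norm = AUC50.
    """
    lo, hi = float(np.min(auc_norm)), float(np.max(auc_norm))
    if not lo <= model.auc50 <= hi:
        raise ValueError(
            f"response does not cross NTCP=0.5 on the grid: AUC_norm spans "
            f"[{lo:.4f}, {hi:.4f}], AUC50={model.auc50:.4f}"
        )
    interp = PchipInterpolator(doses, auc_norm)
    return float(brentq(lambda d: interp(d) - model.auc50,
                        doses[0], doses[-1], xtol=1e-6))


def dose_response(
    model: NTCPModel,
    system: ReactionSystem,
    doses: Sequence[float],
    mean_dose_rate: float,
    template: ScheduleTemplate | None = None,
    o2_percent: float = 3.8,
    g: GValueSet | None = None,
    t_end_tail: float = 300.0,
    **sim_kwargs,
) -> DoseResponseCurve:
    """NTCP(D) curve at a fixed mean dose rate and pulse structure."""
    template = template or ScheduleTemplate()
    doses = np.asarray(sorted(doses), dtype=float)
    aucs = np.empty_like(doses)
    for i, dose in enumerate(doses):
        sched = template.build(float(dose), mean_dose_rate)
        tr = simulate(
            system, sched, g=g, o2_percent=o2_percent,
            t_end=sched.duration + t_end_tail, **sim_kwargs,
        )
        aucs[i] = auc_roo(tr)
    auc_norm = np.array([normalize_auc(a, model) for a in aucs])
    probs = ntcp(model, auc_norm)
    return DoseResponseCurve(
        doses=doses, auc=aucs, auc_norm=auc_norm, ntcp=probs,
        dose_rate=mean_dose_rate, d50=_d50(doses, auc_norm, model),
    )


def flash_modifying_factor(
    conv: DoseResponseCurve, flash: DoseResponseCurve
) -> float:
    """Isoeffect dose ratio D50(UHDR) / D50(conventional)."""
    return flash.d50 / conv.d50


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class NTCPFit:
    model: NTCPModel
    gamma_sd: float
    auc50_sd: float


def fit_ntcp(
    points: Sequence[tuple[float, float, float]],
    simulator: Callable[[float, float], float],
) -> NTCPFit:
    """Least-squares fit of (gamma, AUC50) to observed complication data.

    Parameters
    ----------
    points:
        ``(dose, dose_rate, observed_probability)`` triples spanning the
        response transition.
    simulator:
        Callable mapping ``(dose, dose_rate)`` to the normalised AUC for
        that delivery (typically a closure over :func:`dose_response`
        machinery, or an analytic surrogate in tests).
    """
    if len(points) < 3:
        raise FitError("need at least three points to fit the sigmoid")
    x = np.array([simulator(d, r) for d, r, _ in points], dtype=float)
    p = np.array([obs for _, _, obs in points], dtype=float)
    if np.ptp(x) < 1e-12:
        raise FitError("degenerate points: all deliveries give the same AUC")
    if p.max() < 0.5 or p.min() > 0.5:
        raise FitError(
            "non-identifiable: observed probabilities all on one side of 0.5"
        )

    def logistic(xv, gamma, auc50):
        return 1.0 / (1.0 + np.exp(-gamma * (xv - auc50)))

    span = max(np.ptp(x), 1e-6)
    p0 = (4.0 / span, float(np.median(x)))
    popt, pcov = curve_fit(logistic, x, p, p0=p0, maxfev=20000)
    gamma, auc50 = popt
    if gamma <= 0:
        raise FitError(f"fit collapsed to non-positive slope gamma={gamma}")
    sds = np.sqrt(np.diag(pcov))
    return NTCPFit(
        model=NTCPModel(gamma=float(gamma), auc50=float(auc50)),
        gamma_sd=float(sds[0]),
        auc50_sd=float(sds[1]),
    )
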