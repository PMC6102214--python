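"""Enzyme kinetics: Michaelis-Menten fits, efficiencies, and progress-curve readings.

Covers the quantitative analysis applied to formaldehyde-reduction data:

* nonlinear least-squares fit of v = Vmax*S/(Km+S) to initial-rate data,
  with kcat = Vmax / [E] when the enzyme concentration is supplied;
* catalytic efficiency kcat/Km and fold-change relative to wild type
  (rounded half-up to one decimal, matching how such tables are printed);
* the time for a decaying progress curve (e.g. NADH absorbance) to reach half
  its initial value, read off the curve by linear interpolation rather than by
  fitting a model;
* the time at which an OD600 growth curve resumes growth after a toxic
  treatment, defined as the first sample exceeding the OD at treatment by a
  relative threshold and not decreasing for a persistence window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import HalfDecayNotReachedError, KineticsDesignError


@dataclass
class RateDataset:
    """Paired substrate concentrations (mM) and initial rates.

    ``enzyme_conc`` (same molar units as Vmax per time) enables kcat; ``truth``
    is free-form provenance metadata (e.g. generator parameters).
    """

    substrate_conc: np.ndarray
    initial_rate: np.ndarray
    enzyme_conc: float | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.initial_rate = np.asarray(self.initial_rate, dtype=float)
        if self.substrate_conc.shape != self.initial_rate.shape:
            raise KineticsDesignError("substrate and rate arrays must be paired")
        if self.substrate_conc.size < 3:
            raise KineticsDesignError("need at least 3 rate measurements")
        if np.any(self.substrate_conc < 0):
            raise KineticsDesignError("substrate concentrations must be non-negative")
        if np.unique(self.substrate_conc).size < 3:
            raise KineticsDesignError("need at least 3 distinct substrate concentrations")


@dataclass
class MMFitResult:
    Km: float  # mM
    Vmax: float  # rate units of the input
    kcat: float | None  # 1/hr, only when enzyme_conc was given
    efficiency: float | None  # kcat/Km, 1/(hr mM)
    residual_sse: float
    converged: bool


@dataclass
class ProgressCurve:
    """A time series (strictly increasing time) of NADH concentration or OD600."""

    time: np.ndarray
    value: np.ndarray
    time_unit: str = "min"
    value_name: str = "value"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.size < 2:
            raise ValueError("time and value must be paired with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def michaelis_menten(s, vmax: float, km: float):
    return vmax * np.asarray(s, dtype=float) / (km + np.asarray(s, dtype=float))


def _initial_km_guess(s: np.ndarray, v: np.ndarray, vmax0: float) -> float:
    """S at half-max rate, linearly interpolated along increasing S."""
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    half = vmax0 / 2.0
    above = np.nonzero(v_sorted >= half)[0]
    if above.size == 0:
        return float(s_sorted[-1])
    i = int(above[0])
    if i == 0:
        return max(float(s_sorted[0]) / 2.0, 1e-6)
    s0, s1 = s_sorted[i - 1], s_sorted[i]
    v0, v1 = v_sorted[i - 1], v_sorted[i]
    if v1 == v0:
        return float(s1)
    return max(float(s0 + (half - v0) * (s1 - s0) / (v1 - v0)), 1e-6)


def fit_michaelis_menten(data: RateDataset, weighting: str = "relative") -> MMFitResult:
    """Least-squares Michaelis-Menten fit with positivity enforced.

    ``weighting="relative"`` (default) minimises relative residuals
    (sigma proportional to the observed rate), the appropriate variance model
    for initial-rate assays whose error scales with the signal (constant CV);
    ``"absolute"`` minimises plain residuals. Initialisation: Vmax0 = max
    observed rate, Km0 = S at half-max (interpolated). Non-convergence is
    reported through the ``converged`` flag, not an exception.
    """
    if weighting not in ("relative", "absolute"):
        raise ValueError(f"weighting must be 'relative' or 'absolute', got {weighting!r}")
    s, v = data.substrate_conc, data.initial_rate
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        vmax0 = 1e-6
    km0 = _initial_km_guess(s, v, vmax0)
    sigma = None
    if weighting == "relative":
        sigma = np.maximum(np.abs(v), 1e-3 * vmax0)
    try:
        popt, _ = curve_fit(
            michaelis_menten,
            s,
            v,
            p0=[vmax0, km0],
            sigma=sigma,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=10000,
        )
        vmax, km = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        vmax, km, converged = vmax0, km0, False
    sse = float(np.sum((v - michaelis_menten(s, vmax, km)) ** 2))
    kcat = eff = None
    if data.enzyme_conc is not None and converged:
        kcat = vmax / data.enzyme_conc
        eff = kcat / km if km > 0 else None
    return MMFitResult(Km=km, Vmax=vmax, kcat=kcat, efficiency=eff,
                       residual_sse=sse, converged=converged)


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/Km in 1/(hr mM); Km must be positive."""
    if km <= 0:
        raise ValueError(f"Km must be positive, got {km}")
    return kcat / km


def relative_efficiency(
    eff_mutant: float, eff_wildtype: float, decimals: int = 1
) -> float:
    """Mutant catalytic efficiency over wild-type, rounded half-up to ``decimals``."""
    if eff_wildtype <= 0:
        raise ValueError(f"wild-type efficiency must be positive, got {eff_wildtype}")
    ratio = Decimal(repr(eff_mutant)) / Decimal(repr(eff_wildtype))
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def half_decay_time(curve: ProgressCurve) -> float:
    """First time the curve falls to half its initial value (linear interpolation).

    Raises :class:`HalfDecayNotReachedError` (carrying the final fraction of
    the initial value) when the curve never reaches half.
    """
    t, v = curve.time, curve.value
    v0 = float(v[0])
    if v0 <= 0:
        raise ValueError("initial value must be positive")
    target = v0 / 2.0
    below = np.nonzero(v <= target)[0]
    if below.size == 0:
        raise HalfDecayNotReachedError(
            f"curve never reaches half of its initial value "
            f"(final fraction {v[-1] / v0:.3f})",
            final_fraction=float(v[-1] / v0),
        )
    i = int(below[0])
    if i == 0:  # cannot happen for v0 > 0, but keep the guard explicit
        return float(t[0])
    t0, t1, va, vb = t[i - 1], t[i], v[i - 1], v[i]
    if vb == va:
        return float(t1)
    return float(t0 + (va - target) * (t1 - t0) / (va - vb))


#: sentinel return of growth_resumption_time when growth never resumes
NO_RESUMPTION = None


def growth_resumption_time(
    curve: ProgressCurve,
    treatment_time: float,
    delta: float = 0.2,
    persistence: int = 2,
) -> float | None:
    """Earliest post-treatment sample showing sustained growth, or None.

    A sample at t > treatment_time qualifies when its value is at least
    (1+delta) times the value at treatment (linearly interpolated) and the
    following up-to-``persistence`` samples are non-decreasing; sustained
    growth cannot be claimed from a lone final point, so when persistence > 0
    at least one later sample must exist. Returns ``NO_RESUMPTION`` (None)
    when no sample qualifies — the culture never escaped arrest within the
    observation window.
    """
    t, v = curve.time, curve.value
    if not (t[0] <= treatment_time <= t[-1]):
        raise ValueError(
            f"treatment time {treatment_time} outside curve range [{t[0]}, {t[-1]}]"
        )
    threshold = (1.0 + delta) * float(np.interp(treatment_time, t, v))
    for i in range(len(t)):
        if t[i] <= treatment_time or v[i] < threshold:
            continue
        window = v[i : i + persistence + 1]
        if persistence > 0 and window.size < 2:
            continue
        if np.all(np.diff(window) >= 0):
            return float(t[i])
    return NO_RESUMPTION
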