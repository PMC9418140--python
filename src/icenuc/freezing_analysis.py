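"""Frozen-fraction curves, T50 estimation, and heterogeneous/homogeneous splits.

The frozen fraction f_ice(T) is the cumulative fraction of droplets frozen at
or above temperature T during a cooling ramp.  Curves are step functions over
discrete freeze events; ties at one temperature merge into a single step.
Censored droplets (never froze before the ramp end) inflate the denominator
only, so terminal f_ice can sit below 1.

T50 uses the step-function convention: the temperature of the freeze event
that first brings f_ice to at least 0.5.  With no censoring this equals the
ceil(N/2)-th order statistic of freeze temperatures taken in descending order.
No interpolation between events is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assay_io import DropletAssay, ValidationError

__all__ = [
    "FreezingCurve",
    "T50Estimate",
    "build_freezing_curve",
    "estimate_t50",
    "t50_bootstrap_ci",
    "heterogeneous_fraction",
    "DEFAULT_SPLIT_TEMPS",
]

#: Default heterogeneous/homogeneous split temperatures per apparatus context,
#: midway between the homogeneous background and the coldest heterogeneous
#: modes seen on each instrument.  Overridable everywhere they are used.
DEFAULT_SPLIT_TEMPS = {"WISDOM": -30.0, "BINARY": -26.0, "GENERIC": -30.0}


@dataclass(frozen=True)
class FreezingCurve:
    """Empirical cumulative frozen fraction versus temperature (step function).

    ``temps`` is strictly decreasing; ``f_ice[i]`` is the cumulative fraction
    frozen at or above ``temps[i]``.
    """

    temps: tuple[float, ...]
    f_ice: tuple[float, ...]
    n_droplets: int
    n_censored: int

    def __post_init__(self) -> None:
        t = np.asarray(self.temps)
        f = np.asarray(self.f_ice)
        if np.any(np.diff(t) >= 0):
            raise ValidationError("temps must be strictly decreasing")
        if np.any(np.diff(f) < 0):
            raise ValidationError("f_ice must be non-decreasing with cooling")
        if len(f) and (f[0] < 0 or f[-1] > 1):
            raise ValidationError("f_ice must lie in [0, 1]")

    @property
    def terminal_f_ice(self) -> float:
        return self.f_ice[-1] if self.f_ice else 0.0

    def to_table(self) -> list[tuple[float, float]]:
        return list(zip(self.temps, self.f_ice))


@dataclass(frozen=True)
class T50Estimate:
    t50: float
    ci_low: float
    ci_high: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not (self.ci_low <= self.t50 <= self.ci_high):
            raise ValidationError("T50 confidence interval must bracket t50")


def build_freezing_curve(assay: DropletAssay) -> FreezingCurve:
    """Collapse per-droplet freeze events into a cumulative step function."""
    included = assay.included
    if not included:
        raise ValidationError("all droplets excluded; no curve to build")
    n_total = len(included)
    temps = sorted(assay.freeze_temps(), reverse=True)
    n_censored = n_total - len(temps)

    step_temps: list[float] = []
    step_f: list[float] = []
    frozen = 0
    for t in temps:
        frozen += 1
        if step_temps and step_temps[-1] == t:
            step_f[-1] = frozen / n_total
        else:
            step_temps.append(t)
            step_f.append(frozen / n_total)
    return FreezingCurve(tuple(step_temps), tuple(step_f), n_total, n_censored)


def estimate_t50(curve: FreezingCurve) -> T50Estimate:
    """Step-convention T50: the event temperature where f_ice first >= 0.5.

    Returns ``defined=False`` when the terminal frozen fraction never reaches
    one half (heavy censoring), with ``t50`` set to NaN.
    """
    for t, f in zip(curve.temps, curve.f_ice):
        if f >= 0.5:
            return T50Estimate(t50=t, ci_low=t, ci_high=t, defined=True)
    return T50Estimate(math.nan, math.nan, math.nan, defined=False)


def t50_bootstrap_ci(
    assay: DropletAssay,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    temp_uncertainty: float = 0.3,
) -> T50Estimate:
    """Percentile bootstrap CI for T50 over droplet resamples.

    The reported interval is never narrower than the instrument temperature
    uncertainty (default ±0.3 °C): when the bootstrap half-width falls below
    that floor the interval is widened symmetrically around the point T50.
    Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    point = estimate_t50(build_freezing_curve(assay))
    if not point.defined:
        raise ValidationError("T50 undefined on the full sample")

    included = assay.included
    temps = np.array(
        [d.freeze_temp if d.freeze_temp is not None else np.nan for d in included]
    )
    n = len(temps)
    rng = np.random.default_rng(seed)
    boot = np.full(n_boot, np.nan)
    for b in range(n_boot):
        sample = temps[rng.integers(0, n, size=n)]
        events = np.sort(sample[~np.isnan(sample)])[::-1]
        k = math.ceil(n / 2)  # index of the event reaching f_ice >= 0.5
        if len(events) >= k:
            boot[b] = events[k - 1]
    boot = boot[~np.isnan(boot)]
    if len(boot) == 0:
        raise ValidationError("T50 undefined in every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    if (hi - lo) / 2.0 < temp_uncertainty:
        lo = point.t50 - temp_uncertainty
        hi = point.t50 + temp_uncertainty
    lo = min(lo, point.t50)
    hi = max(hi, point.t50)
    return T50Estimate(point.t50, float(lo), float(hi), defined=True)


def heterogeneous_fraction(curve: FreezingCurve, split_temp: float) -> float:
    """Fraction of droplets frozen strictly above ``split_temp``.

    Censored droplets count in the denominator but never in the numerator;
    monotone non-increasing in ``split_temp``.
    """
    frac = 0.0
    for t, f in zip(curve.temps, curve.f_ice):
        if t > split_temp:
            frac = f
        else:
            break
    return frac


def t50_significantly_different(
    a: T50Estimate, b: T50Estimate, temp_uncertainty: float = 0.3
) -> bool:
    """Whether two T50s differ by more than their combined uncertainty.

    Combined uncertainty is the quadrature sum of each bootstrap half-width
    with the instrument floor applied to each side.
    """
    if not (a.defined and b.defined):
        raise ValidationError("both T50 estimates must be defined")
    half_a = max((a.ci_high - a.ci_low) / 2.0, temp_uncertainty)
    half_b = max((b.ci_high - b.ci_low) / 2.0, temp_uncertainty)
    return abs(a.t50 - b.t50) > math.hypot(half_a, half_b)
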