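"""Cumulative ice-nucleator concentration spectra from frozen-fraction curves.

Uses the standard cumulative-spectrum relation K(T) = -ln(1 - f_ice(T)) / V,
with Nm(T) = K(T) / cell mass concentration giving nucleators per gram of
cells.  Saturated points (f_ice = 1) are kept as explicit lower bounds using
the (n - 0.5)/n continuity substitute rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assay_io import DropletAssay, ValidationError
from .freezing_analysis import FreezingCurve, build_freezing_curve

__all__ = [
    "NucleationSpectrum",
    "cumulative_spectrum",
    "spectrum_from_dilution_series",
]


@dataclass(frozen=True)
class NucleationSpectrum:
    """Cumulative nucleators per litre (K) and per gram of cells (Nm).

    ``temps`` descend; K is non-decreasing with cooling.  ``saturated`` marks
    grid points where every droplet had frozen, so K and Nm there are lower
    bounds.  ``Nm`` entries are NaN when the mass concentration is unknown.
    """

    temps: tuple[float, ...]
    K: tuple[float, ...]
    Nm: tuple[float, ...]
    saturated: tuple[bool, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.K)
        if np.any(k < 0):
            raise ValidationError("K must be non-negative")
        if np.any(np.diff(k) < -1e-9 * np.maximum(k[:-1], 1.0)):
            raise ValidationError("K must be non-decreasing with cooling")


def cumulative_spectrum(
    curve: FreezingCurve, volume: float, mass_conc: float = 0.0
) -> NucleationSpectrum:
    """Convert a frozen-fraction step curve into a cumulative spectrum.

    Parameters
    ----------
    curve : empirical frozen-fraction curve.
    volume : droplet volume in litres.
    mass_conc : cell mass concentration in g/L; 0 leaves Nm undefined (NaN).
    """
    if volume <= 0:
        raise ValidationError("droplet volume must be positive")
    n = curve.n_droplets
    temps, K, Nm, sat = [], [], [], []
    for t, f in zip(curve.temps, curve.f_ice):
        saturated = f >= 1.0
        f_eff = (n - 0.5) / n if saturated else f
        k = -math.log(1.0 - f_eff) / volume
        temps.append(t)
        K.append(k)
        Nm.append(k / mass_conc if mass_conc > 0 else math.nan)
        sat.append(saturated)
    return NucleationSpectrum(tuple(temps), tuple(K), tuple(Nm), tuple(sat))


def _step_lookup(temps: np.ndarray, values: np.ndarray, query: float) -> float:
    """Value of a descending-temperature step function at ``query``.

    Returns the value at the coldest event temperature >= query, or 0 when the
    query sits above all events.
    """
    idx = np.nonzero(temps >= query)[0]
    if len(idx) == 0:
        return 0.0
    return float(values[idx[-1]])


def spectrum_from_dilution_series(
    assays: list[DropletAssay],
) -> NucleationSpectrum:
    """Merge assays of one sample at distinct dilutions onto one Nm axis.

    Each assay's per-gram spectrum is rescaled by 1/dilution_factor onto the
    undiluted-sample axis; where temperature ranges overlap, values are
    averaged with droplet-count weights.  K is reported on the same merged
    axis (per litre of undiluted-equivalent suspension).
    """
    if not assays:
        raise ValidationError("no assays supplied")
    labels = {a.sample_label for a in assays}
    apparatuses = {a.apparatus for a in assays}
    if len(labels) > 1 or len(apparatuses) > 1:
        raise ValidationError("assays must share sample_label and apparatus")
    dilutions = [a.dilution_factor for a in assays]
    if len(set(dilutions)) != len(dilutions):
        raise ValidationError("duplicated dilution_factor in series")

    per_assay = []
    for a in assays:
        spec = cumulative_spectrum(
            build_freezing_curve(a), a.droplet_volume, a.cell_mass_concentration
        )
        temps = np.asarray(spec.temps)
        scale = 1.0 / a.dilution_factor
        per_assay.append(
            (
                temps,
                np.asarray(spec.K) * scale,
                np.asarray(spec.Nm) * scale,
                np.asarray(spec.saturated),
                a.n_droplets,
            )
        )

    grid = np.unique(np.concatenate([t for t, *_ in per_assay]))[::-1]
    K_out, Nm_out, sat_out = [], [], []
    for t in grid:
        k_vals, nm_vals, weights, sat_here = [], [], [], False
        for temps, K, Nm, sat, n in per_assay:
            if len(temps) == 0 or t < temps[-1] or t > temps[0]:
                continue  # outside this assay's observed range
            k_vals.append(_step_lookup(temps, K, t))
            nm_vals.append(_step_lookup(temps, Nm, t))
            weights.append(n)
            idx = np.nonzero(temps >= t)[0]
            if len(idx) and sat[idx[-1]]:
                sat_here = True
        if not weights:
            # Temperature seen by exactly one assay at its range edge.
            for temps, K, Nm, sat, n in per_assay:
                if t in temps:
                    j = int(np.nonzero(temps == t)[0][0])
                    k_vals.append(float(K[j]))
                    nm_vals.append(float(Nm[j]))
                    weights.append(n)
                    sat_here = sat_here or bool(sat[j])
        w = np.asarray(weights, dtype=float)
        K_out.append(float(np.average(k_vals, weights=w)))
        nm_arr = np.asarray(nm_vals)
        if np.all(np.isnan(nm_arr)):
            Nm_out.append(math.nan)
        else:
            ok = ~np.isnan(nm_arr)
            Nm_out.append(float(np.average(nm_arr[ok], weights=w[ok])))
        sat_out.append(sat_here)

    # Weighted averaging across assays can break monotonicity at range
    # boundaries; enforce the cumulative property explicitly.
    K_mono = np.maximum.accumulate(K_out)
    Nm_arr = np.asarray(Nm_out)
    if not np.all(np.isnan(Nm_arr)):
        filled = np.where(np.isnan(Nm_arr), -np.inf, Nm_arr)
        Nm_arr = np.where(np.isnan(Nm_arr), np.nan, np.maximum.accumulate(filled))
    return NucleationSpectrum(
        tuple(float(t) for t in grid),
        tuple(float(k) for k in K_mono),
        tuple(float(v) for v in Nm_arr),
        tuple(sat_out),
    )
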