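"""Zero-truncated Poisson inference for dilution-to-single-nucleator assays.

When droplets either freeze heterogeneously (they contain at least one
nucleator) or only at the homogeneous point (they contain none), the empty
fraction f_hom estimates exp(-lambda) for the mean nucleator count per
droplet.  Conditioning on occupancy gives the zero-truncated Poisson mass

    P(K = k | K >= 1) = lambda^k e^{-lambda} / (k! (1 - e^{-lambda})),

e.g. lambda = -ln(0.60) puts ~76.6% of occupied droplets at exactly one
nucleator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assay_io import ValidationError

__all__ = [
    "TruncatedPoissonEstimate",
    "DilutionSeriesFit",
    "estimate_lambda",
    "prob_k_given_present",
    "dilution_series_fit",
    "expected_cells_per_droplet",
]


def _wilson_interval(count: int, nobs: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if nobs <= 0:
        raise ValidationError("n_droplets must be positive")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = count / nobs
    denom = 1.0 + z * z / nobs
    centre = (p + z * z / (2 * nobs)) / denom
    half = z * math.sqrt(p * (1 - p) / nobs + z * z / (4 * nobs * nobs)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass(frozen=True)
class TruncatedPoissonEstimate:
    """Mean nucleators per droplet plus occupancy probabilities."""

    lambda_hat: float
    f_hom: float
    n_droplets: int
    ci: tuple[float, float]
    level: float = 0.95
    p_k_given_present: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lambda_hat < 0:
            raise ValidationError("lambda_hat must be non-negative")


def estimate_lambda(
    f_hom: float, n_droplets: int, level: float = 0.95, k_max: int = 50
) -> TruncatedPoissonEstimate:
    """Estimate mean nucleators per droplet from the homogeneous-only fraction.

    ``lambda_hat = -ln(f_hom)``.  The CI maps the Wilson binomial interval on
    f_hom through -ln; note the mapping reverses interval endpoints.
    """
    if f_hom < 0 or f_hom > 1:
        raise ValidationError("f_hom must lie in [0, 1]")
    if f_hom == 0:
        raise ValidationError("f_hom = 0: lambda is unbounded")
    lam = -math.log(f_hom)
    count = round(f_hom * n_droplets)
    lo_f, hi_f = _wilson_interval(count, n_droplets, level)
    ci = (-math.log(hi_f) if hi_f > 0 else 0.0,
          -math.log(lo_f) if lo_f > 0 else math.inf)
    pk = {}
    if lam > 0:
        pk = {k: prob_k_given_present(lam, k, k_max=k_max) for k in range(1, 11)}
    return TruncatedPoissonEstimate(lam, f_hom, n_droplets, ci, level, pk)


def prob_k_given_present(lam: float, k: int, k_max: int = 50) -> float:
    """Zero-truncated Poisson mass at ``k`` (k >= 1).

    ``k_max`` is accepted for signature compatibility with brute-force
    normalization checks; the closed form needs no truncation.
    """
    if k < 1:
        raise ValidationError("k must be at least 1 (zero is truncated away)")
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    # expm1 keeps the denominator accurate as lambda -> 0+.
    return float(stats.poisson.pmf(k, lam) / -math.expm1(-lam))


@dataclass(frozen=True)
class DilutionSeriesFit:
    lambda_at_unit_dilution: float
    dilutions: tuple[float, ...]
    lambda_hats: tuple[float, ...]
    predicted: tuple[float, ...]
    standardized_deviation: tuple[float, ...]
    non_poisson: bool


def dilution_series_fit(
    observations: list[tuple[float, float, int]],
    flag_threshold: float = 3.0,
) -> DilutionSeriesFit:
    """Fit lambda_d = lambda0 * d across a dilution series.

    ``observations`` holds (dilution_factor, f_hom, n_droplets) triples.  The
    fit is a weighted mean of log(lambda_d) - log(d) with inverse-variance
    weights from binomial error on f_hom; per-dilution standardized deviations
    above ``flag_threshold`` mark non-Poisson behaviour such as a potent
    subpopulation inflating the warm tail.
    """
    usable = [(d, f, n) for d, f, n in observations if 0 < f < 1]
    if all(f >= 1 for _, f, _ in observations):
        raise ValidationError("all f_hom = 1: no heterogeneous signal to fit")
    if len(usable) < 2:
        raise ValidationError("need at least 2 dilutions with 0 < f_hom < 1")

    ds = np.array([d for d, _, _ in usable])
    fs = np.array([f for _, f, _ in usable])
    ns = np.array([n for _, _, n in usable], dtype=float)
    lams = -np.log(fs)
    # var(lambda_hat) = var(f)/f^2 by the delta method.
    var_lam = fs * (1 - fs) / ns / fs**2
    var_log_lam = var_lam / lams**2
    weights = 1.0 / var_log_lam
    log_lam0 = float(np.average(np.log(lams) - np.log(ds), weights=weights))
    lam0 = math.exp(log_lam0)

    predicted = lam0 * ds
    z = (lams - predicted) / np.sqrt(var_lam)
    return DilutionSeriesFit(
        lam0,
        tuple(float(d) for d in ds),
        tuple(float(v) for v in lams),
        tuple(float(v) for v in predicted),
        tuple(float(v) for v in z),
        bool(np.any(np.abs(z) > flag_threshold)),
    )


def expected_cells_per_droplet(
    cfu_conc: float, volume: float, dilution: float = 1.0
) -> float:
    """Expected cell count per droplet: CFU/L x volume (L) x dilution."""
    if cfu_conc <= 0 or volume <= 0 or dilution <= 0:
        raise ValidationError("cfu_conc, volume and dilution must be positive")
    return cfu_conc * volume * dilution
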