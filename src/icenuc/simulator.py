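"""Stochastic droplet-assay simulator and synthetic repeat-gene generator.

The droplet model follows the singular approximation: nucleators carry
characteristic freezing temperatures, each droplet loads a Poisson number of
nucleators, and a droplet freezes at the warmer of its heterogeneous
characteristic temperature and its homogeneous-background draw.  Because the
assays show that one nucleator in a droplet freezes it at the same
temperature as hundreds (nucleation is set by the construct, not the dose),
the heterogeneous temperature is drawn once per occupied droplet rather than
independently per nucleator; a rare potent subpopulation is still applied at
the per-nucleator level through a binomial thinning.

The gene generator emits consensus-derived water-organizing coils with
tunable divergence (motif positions protected), divergent C-terminal R-coil
tails, random flanks, and silent restriction-site pairs engineered at
matching coil phases so their spacing is a multiple of 48 bp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .assay_io import Apparatus, Droplet, DropletAssay, ValidationError
from .construct_ops import (
    COIL_BASES,
    SYNONYMOUS,
    Coil,
    ConstructSpec,
    backtranslate,
    translate,
)
from .repeat_analysis import CONSENSUS, REPEAT_LEN, AMINO_ACIDS, CoilClass

__all__ = [
    "SimulationConfig",
    "CalibrationMap",
    "INACTIVE",
    "simulate_assay",
    "calibrated_mu",
    "generate_repeat_gene",
    "WISDOM_CALIBRATION",
    "BINARY_CALIBRATION",
    "RCOIL_TEMPLATE",
]

#: Sentinel for constructs below the minimum active repeat count.
INACTIVE = None


@dataclass(frozen=True)
class CalibrationMap:
    """Monotone n_repeats -> characteristic T50 anchors for one apparatus.

    Anchors come from measured per-construct T50 values; queries between
    anchors use monotone piecewise-linear interpolation, queries above the
    largest anchor clamp to it, and queries below ``min_active_repeats``
    return :data:`INACTIVE` (homogeneous-only freezing).  Queries between
    ``min_active_repeats`` and the smallest anchor extrapolate the first
    segment's slope.
    """

    anchors: dict[int, float]
    min_active_repeats: int = 13

    def __post_init__(self) -> None:
        n = sorted(self.anchors)
        mus = [self.anchors[k] for k in n]
        if any(b < a for a, b in zip(mus, mus[1:])):
            raise ValidationError("anchor T50s must be non-decreasing in n_rep")

    def mu(self, n_rep: int) -> float | None:
        if n_rep < self.min_active_repeats:
            return INACTIVE
        ns = sorted(self.anchors)
        mus = [self.anchors[k] for k in ns]
        if n_rep <= ns[0]:
            slope = (mus[1] - mus[0]) / (ns[1] - ns[0]) if len(ns) > 1 else 0.0
            return mus[0] - slope * (ns[0] - n_rep)
        return float(np.interp(n_rep, ns, mus))


#: Default anchors per apparatus (measured construct T50s).
WISDOM_CALIBRATION = CalibrationMap(
    {15: -23.4, 16: -21.3, 17: -19.8, 18: -17.5, 29: -10.0, 33: -9.2, 65: -8.0}
)
BINARY_CALIBRATION = CalibrationMap(
    {15: -22.9, 16: -22.5, 17: -19.4, 18: -17.4, 33: -9.0, 65: -7.1}
)

_CALIBRATIONS = {
    Apparatus.WISDOM: WISDOM_CALIBRATION,
    Apparatus.BINARY: BINARY_CALIBRATION,
    Apparatus.GENERIC: WISDOM_CALIBRATION,
}

#: Homogeneous-background (mu, sigma) per apparatus: WISDOM in LB, BINARY in
#: PBS.  Sigma 0.4 degC reproduces the sharp background step.
_HOM_DEFAULTS = {
    Apparatus.WISDOM: (-38.7, 0.4),
    Apparatus.BINARY: (-29.7, 0.4),
    Apparatus.GENERIC: (-38.7, 0.4),
}

_RAMP_END_DEFAULTS = {
    Apparatus.WISDOM: -40.0,
    Apparatus.BINARY: -32.0,
    Apparatus.GENERIC: -40.0,
}


def calibrated_mu(n_rep: int, apparatus: Apparatus | str) -> float | None:
    """Characteristic freezing temperature for an n-repeat construct.

    Returns :data:`INACTIVE` (None) below the minimum active repeat count.
    """
    if n_rep < 0:
        raise ValidationError("n_rep must be non-negative")
    apparatus = Apparatus(apparatus)
    return _CALIBRATIONS[apparatus].mu(n_rep)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated droplet assay.

    ``lambda_per_droplet`` may be given directly or derived via
    cfu_conc x droplet_volume x dilution_factor.  The construct sigma
    default of 0.5 degC makes an active plate freeze over a one-to-two
    degree window.
    """

    seed: int
    apparatus: Apparatus = Apparatus.WISDOM
    n_droplets: int = 120
    n_replicates: int = 1
    lambda_per_droplet: float | None = None
    cfu_conc: float | None = None  # CFU per litre
    construct_mu: float | None = None  # None => inactive (homogeneous only)
    construct_sigma: float = 0.5
    hom_mu: float | None = None
    hom_sigma: float | None = None
    potent_fraction: float = 0.0
    potent_mu: float | None = None
    potent_sigma: float = 0.5
    droplet_volume: float = 3.8e-10  # sphere of ~90 um diameter, litres
    dilution_factor: float = 1.0
    cell_mass_concentration: float = 1.0  # g/L (assay convention: 1 mg/mL)
    cooling_rate: float = 1.0
    ramp_end_temp: float | None = None
    sample_label: str = "simulated"

    def __post_init__(self) -> None:
        if self.construct_sigma <= 0 or self.potent_sigma <= 0:
            raise ValidationError("sigmas must be positive")
        if not (0.0 <= self.potent_fraction <= 1.0):
            raise ValidationError("potent_fraction must be in [0, 1]")
        for mu in (self.construct_mu, self.hom_mu, self.potent_mu):
            if mu is not None and mu >= 0:
                raise ValidationError("characteristic means must be below 0 degC")

    @property
    def effective_lambda(self) -> float:
        if self.lambda_per_droplet is not None:
            return self.lambda_per_droplet
        if self.cfu_conc is not None:
            return self.cfu_conc * self.droplet_volume * self.dilution_factor
        return 0.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        kwargs = dict(mapping)
        if "apparatus" in kwargs:
            kwargs["apparatus"] = Apparatus(kwargs["apparatus"])
        return cls(**kwargs)


def simulate_assay(config: SimulationConfig) -> DropletAssay:
    """Simulate one droplet-freezing ramp; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    app = config.apparatus
    hom_mu, hom_sigma = _HOM_DEFAULTS[app]
    if config.hom_mu is not None:
        hom_mu = config.hom_mu
    if config.hom_sigma is not None:
        hom_sigma = config.hom_sigma
    ramp_end = (
        config.ramp_end_temp
        if config.ramp_end_temp is not None
        else _RAMP_END_DEFAULTS[app]
    )

    n = config.n_droplets
    lam = config.effective_lambda
    k = rng.poisson(lam, size=n) if lam > 0 else np.zeros(n, dtype=int)
    hom = rng.normal(hom_mu, hom_sigma, size=n)

    temps = hom.copy()
    if config.construct_mu is not None:
        het = rng.normal(config.construct_mu, config.construct_sigma, size=n)
        if config.potent_fraction > 0 and config.potent_mu is not None:
            n_potent = rng.binomial(k, config.potent_fraction)
            potent = rng.normal(config.potent_mu, config.potent_sigma, size=n)
            het = np.where(n_potent > 0, np.maximum(het, potent), het)
        temps = np.where(k > 0, np.maximum(het, hom), hom)
    temps = np.minimum(temps, 0.0)  # characteristic distributions truncate at 0

    droplets = []
    for i in range(n):
        if temps[i] < ramp_end:
            droplets.append(Droplet(f"d{i + 1}", None))
        else:
            droplets.append(Droplet(f"d{i + 1}", float(temps[i])))
    return DropletAssay(
        assay_id=f"{config.sample_label}-seed{config.seed}",
        droplets=tuple(droplets),
        apparatus=app,
        droplet_volume=config.droplet_volume,
        cooling_rate=config.cooling_rate,
        ramp_end_temp=ramp_end,
        dilution_factor=config.dilution_factor,
        cell_mass_concentration=config.cell_mass_concentration,
        sample_label=config.sample_label,
    )


# ---------------------------------------------------------------------------
# Synthetic repeat genes
# ---------------------------------------------------------------------------

#: R-coil template: R at position 12, water-organizing motifs ablated,
#: 11/16 identity to the consensus.
RCOIL_TEMPLATE = "AGHGSAQVAGERSSLN"

#: Coil positions (1-based) never touched by random divergence.
_PROTECTED_WATER = {3, 4, 5, 6, 8, 14, 15, 16}
_PROTECTED_RCOIL = {3, 6, 8, 12, 16}


def _diverge(coil: str, protected: set[int], divergence: float,
             rng: np.random.Generator) -> str:
    out = list(coil)
    for pos in range(1, REPEAT_LEN + 1):
        if pos in protected:
            continue
        if rng.random() < divergence:
            choices = [aa for aa in AMINO_ACIDS if aa != out[pos - 1]]
            out[pos - 1] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(
        AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))] for _ in range(length)
    )


#: Site-anchor slack, in bases, around the nominal cut point.  The same
#: delta must apply at both members of a pair so spacing stays 0 mod 48.
_SITE_DELTAS = (0, 1, 2, -1, -2)


def _engineer_site_in_coil(
    coil_dna: str, recognition: str, phase: int, delta: int
) -> str | None:
    """Silently place ``recognition`` near the cut phase of a 48-bp coil.

    The site start is anchored at the post-residue-``phase`` cut point
    (base offset phase*3) shifted by ``delta`` bases; synonymous codons of
    the residues under the site are searched exhaustively.  Returns the
    re-coded coil DNA, or None when no silent combination exists here.
    """
    offset = phase * 3 + delta
    m = len(recognition)
    if offset < 0 or offset + m > COIL_BASES:
        return None
    protein = translate(coil_dna)
    first_res = offset // 3
    last_res = (offset + m - 1) // 3
    residues = protein[first_res:last_res + 1]
    for combo in itertools.product(*(SYNONYMOUS[aa] for aa in residues)):
        segment = "".join(combo)
        window = coil_dna[:first_res * 3] + segment + coil_dna[(last_res + 1) * 3:]
        if window[offset:offset + m] == recognition:
            return window
    return None


def generate_repeat_gene(
    n_water: int,
    n_rcoil: int,
    divergence: float = 0.0,
    site_plan: list[tuple[str, str, int, int, int]] | None = None,
    seed: int = 0,
    flank5_len: int = 20,
    flank3_len: int = 20,
) -> tuple[ConstructSpec, str]:
    """Generate a synthetic tandem-repeat gene and its protein.

    Parameters
    ----------
    n_water, n_rcoil : counts of consensus-derived water-organizing coils and
        C-terminal R-coils.
    divergence : per-residue substitution probability at unprotected coil
        positions (must be < 0.5).
    site_plan : optional list of (enzyme_name, recognition, repeat_i,
        repeat_j, phase) silent restriction-site pairs to engineer; raises
        naming the pair when no silent re-coding exists.
    flank5_len, flank3_len : random flank lengths in residues.

    Returns (construct, protein sequence).  Deterministic for a given seed.
    """
    if not (0.0 <= divergence < 0.5):
        raise ValidationError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(seed)

    coil_proteins = [
        _diverge(CONSENSUS, _PROTECTED_WATER, divergence, rng)
        for _ in range(n_water)
    ]
    classes = [CoilClass.WATER_ORGANIZING] * n_water
    coil_proteins += [
        _diverge(RCOIL_TEMPLATE, _PROTECTED_RCOIL, divergence, rng)
        for _ in range(n_rcoil)
    ]
    classes += [CoilClass.R_COIL] * n_rcoil

    flank5 = _random_protein(flank5_len, rng)
    flank3 = _random_protein(flank3_len, rng)
    coils = [
        Coil(backtranslate(p), cls) for p, cls in zip(coil_proteins, classes)
    ]

    for plan in site_plan or []:
        name, recognition, repeat_i, repeat_j, phase = plan
        recognition = recognition.upper()
        n_total = len(coils)
        if not (1 <= repeat_i < repeat_j <= n_total):
            raise ValidationError(f"site pair {name}: bad repeat indices")
        new_i = new_j = None
        for delta in _SITE_DELTAS:
            cand_i = _engineer_site_in_coil(
                coils[repeat_i - 1].dna, recognition, phase, delta
            )
            cand_j = _engineer_site_in_coil(
                coils[repeat_j - 1].dna, recognition, phase, delta
            )
            if cand_i is not None and cand_j is not None:
                new_i, new_j = cand_i, cand_j
                break
        if new_i is None or new_j is None:
            raise ValidationError(
                f"site pair {name} at phase {phase} cannot be introduced "
                "silently"
            )
        coils[repeat_i - 1] = replace(coils[repeat_i - 1], dna=new_i)
        coils[repeat_j - 1] = replace(coils[repeat_j - 1], dna=new_j)

    construct = ConstructSpec(
        backtranslate(flank5),
        tuple(coils),
        backtranslate(flank3),
        label=f"synthetic-{n_water}w{n_rcoil}r",
    )
    return construct, construct.protein
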