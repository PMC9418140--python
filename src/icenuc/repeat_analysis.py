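"""Tandem-repeat consensus profiling and coil classification for solenoid INPs.

A repeat protein is scanned as consecutive 16-residue windows against a
consensus coil.  Identity is exact-match Hamming (matches out of 16), the
same metric as a pairwise "number of differences" count subtracted from the
window length.  Flank windows (three before the repeat region, two after)
quantify how sharply the repeat signal drops at the domain boundaries.

Coils carry outward-facing motifs at fixed 1-based positions within the coil:
TxT (T6/T8), SLT (S14, L or I 15, T16), YGS (Y3 G4 S5), and the R-coil marker
arginine at position 12.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay_io import ValidationError

__all__ = [
    "CONSENSUS",
    "REPEAT_LEN",
    "CoilClass",
    "CoilFlags",
    "RepeatProfile",
    "LogoMatrix",
    "consensus_match_profile",
    "detect_repeat_frame",
    "build_logo",
    "classify_coils",
    "coil_flags",
    "hamming_matches",
]

#: Consensus 16-residue solenoid coil.
CONSENSUS = "AGYGSTQTAGEESSLT"
REPEAT_LEN = 16

#: 1-based motif positions within a coil.
MOTIF_POSITIONS = {"TxT": (6, 8), "SLT": (14, 15, 16), "YGS": (3, 4, 5)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class CoilClass(str, enum.Enum):
    WATER_ORGANIZING = "WATER_ORGANIZING"
    R_COIL = "R_COIL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class CoilFlags:
    has_TxT: bool
    has_SLT: bool
    has_YGS: bool
    has_R12: bool


def hamming_matches(window: str, consensus: str) -> int:
    """Number of identical positions between two equal-length strings."""
    if len(window) != len(consensus):
        raise ValidationError("window and consensus lengths differ")
    return sum(a == b for a, b in zip(window, consensus))


def coil_flags(coil: str) -> CoilFlags:
    """Motif flags for one 16-residue coil (positions are 1-based)."""
    if len(coil) != REPEAT_LEN:
        raise ValidationError(f"coil must be {REPEAT_LEN} residues")
    return CoilFlags(
        has_TxT=coil[5] == "T" and coil[7] == "T",
        has_SLT=coil[13] == "S" and coil[14] in "LI" and coil[15] == "T",
        has_YGS=coil[2] == "Y" and coil[3] == "G" and coil[4] == "S",
        has_R12=coil[11] == "R",
    )


@dataclass(frozen=True)
class RepeatProfile:
    """Per-repeat consensus identity for a repeat region plus flank windows.

    ``match_counts`` maps user-facing 1-based repeat index -> matches out of
    16; flank windows use indices -3..-1 (N-terminal side) and n+1, n+2
    (C-terminal side) and are present only where the sequence extends far
    enough.
    """

    sequence_id: str
    frame_start: int  # 0-based residue index of repeat 1, position 1
    repeat_len: int
    n_repeats: int
    consensus: str
    match_counts: dict[int, int]
    repeats: tuple[str, ...]

    def repeat_matches(self) -> list[int]:
        """Match counts of genuine repeats 1..n, in order."""
        return [self.match_counts[i] for i in range(1, self.n_repeats + 1)]


def consensus_match_profile(
    seq: str,
    frame_start: int,
    n_repeats: int,
    consensus: str = CONSENSUS,
    sequence_id: str = "",
) -> RepeatProfile:
    """Score every repeat window (and in-bounds flank windows) by identity."""
    L = len(consensus)
    if L != REPEAT_LEN:
        raise ValidationError(f"consensus must be {REPEAT_LEN} residues")
    if frame_start < 0 or frame_start + n_repeats * L > len(seq):
        raise ValidationError("repeat windows do not fit inside the sequence")

    match_counts: dict[int, int] = {}
    repeats: list[str] = []
    for i in range(1, n_repeats + 1):
        s = frame_start + (i - 1) * L
        window = seq[s:s + L]
        repeats.append(window)
        match_counts[i] = hamming_matches(window, consensus)
    for i in (-3, -2, -1):
        s = frame_start + i * L
        if s >= 0:
            match_counts[i] = hamming_matches(seq[s:s + L], consensus)
    for i in (n_repeats + 1, n_repeats + 2):
        s = frame_start + (i - 1) * L
        if s + L <= len(seq):
            match_counts[i] = hamming_matches(seq[s:s + L], consensus)
    return RepeatProfile(
        sequence_id, frame_start, L, n_repeats, consensus, match_counts,
        tuple(repeats),
    )


def detect_repeat_frame(
    seq: str, consensus: str = CONSENSUS, min_match: int = 6
) -> tuple[int, int]:
    """Locate the tandem-repeat region by maximizing the contiguous run of
    windows scoring at least ``min_match`` against the consensus.

    All 16 phases are scanned; ties go to the smallest frame_start.  Returns
    (frame_start, n_repeats).  Raises when no window reaches the threshold.
    """
    L = len(consensus)
    if len(seq) < 2 * L:
        raise ValidationError("sequence shorter than two repeat units")

    best: tuple[int, int] | None = None  # (frame_start, run_length)
    for phase in range(L):
        n_windows = (len(seq) - phase) // L
        scores = [
            hamming_matches(seq[phase + w * L: phase + (w + 1) * L], consensus)
            for w in range(n_windows)
        ]
        run_start = run_len = 0
        cur_start = cur_len = 0
        for w, sc in enumerate(scores):
            if sc >= min_match:
                if cur_len == 0:
                    cur_start = w
                cur_len += 1
                if cur_len > run_len:
                    run_start, run_len = cur_start, cur_len
            else:
                cur_len = 0
        if run_len == 0:
            continue
        start = phase + run_start * L
        if (
            best is None
            or run_len > best[1]
            or (run_len == best[1] and start < best[0])
        ):
            best = (start, run_len)
    if best is None:
        raise ValidationError("no repeat region: no window reaches min_match")
    return best


@dataclass(frozen=True)
class LogoMatrix:
    """Position frequency matrix with per-position information content.

    ``frequencies`` is a (positions x 20) DataFrame whose rows sum to 1;
    ``bits`` holds log2(20) minus the Shannon entropy of each column, with no
    small-sample correction (declared).
    """

    frequencies: pd.DataFrame
    bits: tuple[float, ...]

    def modal_residue(self, position_1based: int) -> str:
        return str(self.frequencies.iloc[position_1based - 1].idxmax())


def build_logo(repeats: list[str]) -> LogoMatrix:
    """Relative-frequency logo matrix from equal-length repeat windows."""
    if not repeats:
        raise ValidationError("need at least one repeat")
    L = len(repeats[0])
    if any(len(r) != L for r in repeats):
        raise ValidationError("repeat windows must be of uniform length")

    counts = np.zeros((L, len(AMINO_ACIDS)))
    aa_index = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for rep in repeats:
        for pos, aa in enumerate(rep):
            if aa not in aa_index:
                raise ValidationError(f"non-standard residue {aa!r}")
            counts[pos, aa_index[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)

    max_bits = math.log2(len(AMINO_ACIDS))
    bits = []
    for pos in range(L):
        p = freqs[pos][freqs[pos] > 0]
        entropy = float(-(p * np.log2(p)).sum())
        bits.append(max_bits - entropy)
    frame = pd.DataFrame(
        freqs, index=range(1, L + 1), columns=list(AMINO_ACIDS)
    )
    return LogoMatrix(frame, tuple(bits))


def classify_coils(
    repeats: list[str],
    consensus: str = CONSENSUS,
    water_match_threshold: int = 12,
    motif_only: bool = False,
) -> list[CoilClass]:
    """Classify each coil as water-organizing, R-coil, or other.

    Default rule: R_COIL iff the coil has R at position 12 and lacks the TxT
    motif; WATER_ORGANIZING iff it has TxT or its consensus identity reaches
    ``water_match_threshold``; everything else is OTHER.  ``motif_only``
    drops the identity fallback for analyses of divergent orthologs.
    """
    classes = []
    for coil in repeats:
        flags = coil_flags(coil)
        if flags.has_R12 and not flags.has_TxT:
            classes.append(CoilClass.R_COIL)
        elif flags.has_TxT or (
            not motif_only
            and hamming_matches(coil, consensus) >= water_match_threshold
        ):
            classes.append(CoilClass.WATER_ORGANIZING)
        else:
            classes.append(CoilClass.OTHER)
    return classes
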