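"""In-silico engineering of tandem-repeat genes.

A construct is modeled as an ordered central region of 48-bp repeat units
(coils) and non-repeat insert blocks, between two flanking DNA segments.
Paired same-phase excision, block replacement, and motif mutation all keep
the reading frame (every DNA length change is a multiple of 3, asserted) and
keep the repeat region's 48-bp periodicity.

Repeat indices are 1-based at the API surface ("repeats 10 to 57"); DNA
coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .assay_io import ValidationError
from .repeat_analysis import (
    MOTIF_POSITIONS,
    REPEAT_LEN,
    CoilClass,
    classify_coils,
)

__all__ = [
    "Coil",
    "Insert",
    "ConstructSpec",
    "SitePairReport",
    "EnzymeReport",
    "build_construct",
    "backtranslate",
    "excise_between_paired_sites",
    "insert_block",
    "apply_motif_mutations",
    "verify_site_pairs",
    "count_coil_classes",
    "uninterrupted_runs",
]

#: Fixed back-translation table (common E. coli codons); one codon per residue
#: so protein -> DNA is deterministic and DNA -> protein inverts it.
CODON_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: Synonymous codons per residue, for silent restriction-site engineering.
SYNONYMOUS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("CTG", "CTC", "CTT", "CTA", "TTA", "TTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCG", "CCA", "CCT", "CCC"),
    "Q": ("CAG", "CAA"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("AGC", "AGT", "TCT", "TCC", "TCA", "TCG"),
    "T": ("ACC", "ACT", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COIL_BASES = REPEAT_LEN * 3  # 48


def backtranslate(protein: str) -> str:
    """Deterministic protein -> DNA using the fixed codon table."""
    try:
        return "".join(CODON_TABLE[aa] for aa in protein)
    except KeyError as exc:
        raise ValidationError(f"cannot backtranslate residue {exc}") from exc


def translate(dna: str) -> str:
    if len(dna) % 3:
        raise ValidationError("DNA length not a multiple of 3")
    return str(Seq(dna).translate())


@dataclass(frozen=True)
class Coil:
    """One intact 48-bp repeat unit of the central domain."""

    dna: str
    cls: CoilClass
    mutated: bool = False

    def __post_init__(self) -> None:
        if len(self.dna) != COIL_BASES:
            raise ValidationError(f"coil DNA must be {COIL_BASES} bp")

    @property
    def protein(self) -> str:
        return translate(self.dna)


@dataclass(frozen=True)
class Insert:
    """A non-repeat block occupying space inside the central region."""

    dna: str
    label: str

    def __post_init__(self) -> None:
        if len(self.dna) % 3:
            raise ValidationError("insert DNA must preserve reading frame")


@dataclass(frozen=True)
class ConstructSpec:
    """Repeat-array state of a gene after deletions/insertions/mutations."""

    flank5: str
    elements: tuple[Coil | Insert, ...]
    flank3: str
    label: str = "construct"

    def __post_init__(self) -> None:
        if len(self.flank5) % 3 or len(self.flank3) % 3:
            raise ValidationError("flanks must preserve reading frame")

    # -- derived views -----------------------------------------------------
    @property
    def dna(self) -> str:
        return self.flank5 + "".join(e.dna for e in self.elements) + self.flank3

    @property
    def protein(self) -> str:
        return translate(self.dna)

    @property
    def repeat_region(self) -> tuple[int, int]:
        """Base interval spanning the central region (0-based half-open)."""
        start = len(self.flank5)
        end = len(self.dna) - len(self.flank3)
        return start, end

    @property
    def coils(self) -> tuple[Coil, ...]:
        return tuple(e for e in self.elements if isinstance(e, Coil))

    @property
    def n_repeats(self) -> int:
        return len(self.coils)

    @property
    def coil_classes(self) -> tuple[CoilClass, ...]:
        return tuple(c.cls for c in self.coils)

    @property
    def interruptions(self) -> tuple[tuple[int, int], ...]:
        """Half-open intervals (element indices) of inserts/mutated coils."""
        out, start = [], None
        for i, e in enumerate(self.elements):
            broken = isinstance(e, Insert) or (isinstance(e, Coil) and e.mutated)
            if broken and start is None:
                start = i
            elif not broken and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.elements)))
        return tuple(out)

    def coil_element_index(self, repeat_1based: int) -> int:
        """Element index of the n-th intact coil (1-based repeat numbering)."""
        if not (1 <= repeat_1based <= self.n_repeats):
            raise ValidationError(
                f"repeat {repeat_1based} outside 1..{self.n_repeats}"
            )
        seen = 0
        for i, e in enumerate(self.elements):
            if isinstance(e, Coil):
                seen += 1
                if seen == repeat_1based:
                    return i
        raise AssertionError("unreachable")

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "label": self.label,
            "flank5": self.flank5,
            "flank3": self.flank3,
            "elements": [
                {"kind": "coil", "dna": e.dna, "class": e.cls.value,
                 "mutated": e.mutated}
                if isinstance(e, Coil)
                else {"kind": "insert", "dna": e.dna, "label": e.label}
                for e in self.elements
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ConstructSpec":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text(encoding="utf-8")
        payload = json.loads(source)
        elements: list[Coil | Insert] = []
        for e in payload["elements"]:
            if e["kind"] == "coil":
                elements.append(
                    Coil(e["dna"], CoilClass(e["class"]), e.get("mutated", False))
                )
            else:
                elements.append(Insert(e["dna"], e.get("label", "insert")))
        return cls(
            payload["flank5"], tuple(elements), payload["flank3"],
            payload.get("label", "construct"),
        )


def build_construct(
    coil_proteins: Sequence[str],
    classes: Sequence[CoilClass] | None = None,
    flank5_protein: str = "",
    flank3_protein: str = "",
    label: str = "construct",
) -> ConstructSpec:
    """Assemble a construct from 16-residue coil proteins and flanks.

    Classes default to sequence-derived classification.
    """
    if classes is None:
        classes = classify_coils(list(coil_proteins))
    if len(classes) != len(coil_proteins):
        raise ValidationError("classes and coil_proteins lengths differ")
    coils = tuple(
        Coil(backtranslate(p), c) for p, c in zip(coil_proteins, classes)
    )
    return ConstructSpec(
        backtranslate(flank5_protein), coils, backtranslate(flank3_protein),
        label,
    )


def _assert_frame(before: ConstructSpec, after: ConstructSpec) -> None:
    delta = len(after.dna) - len(before.dna)
    assert delta % 3 == 0, "edit broke the reading frame"


def uninterrupted_runs(c: ConstructSpec) -> list[int]:
    """Lengths of maximal runs of intact, unmutated coils, in order."""
    runs, cur = [], 0
    for e in c.elements:
        if isinstance(e, Coil) and not e.mutated:
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------

def excise_between_paired_sites(
    c: ConstructSpec, repeat_i: int, repeat_j: int, phase: int
) -> ConstructSpec:
    """Excise between same-phase cut points in repeats i and j and religate.

    The cut in each repeat falls after coil residue ``phase`` (1-16), so the
    religated chimeric coil carries residues 1..phase of repeat i fused to
    residues phase+1..16 of repeat j; repeat count drops by exactly j - i.
    The chimera keeps the class its two parents share; with mixed parentage
    it inherits the upstream (repeat i) parent's class, matching how short
    excision products are conventionally tallied.
    """
    if not (1 <= phase <= REPEAT_LEN):
        raise ValidationError(f"phase must be in 1..{REPEAT_LEN}")
    if repeat_j > c.n_repeats:
        raise ValidationError(f"repeat_j={repeat_j} exceeds n_repeats={c.n_repeats}")
    if not (1 <= repeat_i <= repeat_j):
        raise ValidationError("need 1 <= repeat_i <= repeat_j")
    if repeat_i == repeat_j:
        return c

    ei = c.coil_element_index(repeat_i)
    ej = c.coil_element_index(repeat_j)
    if any(isinstance(e, Insert) for e in c.elements[ei:ej + 1]):
        raise ValidationError("cannot excise across an insert block")
    parent_i: Coil = c.elements[ei]  # type: ignore[assignment]
    parent_j: Coil = c.elements[ej]  # type: ignore[assignment]
    cut = phase * 3
    chimera_dna = parent_i.dna[:cut] + parent_j.dna[cut:]
    # Shared class when parents agree; upstream parent's class otherwise.
    chimera_cls = parent_i.cls
    chimera = Coil(chimera_dna, chimera_cls, parent_i.mutated or parent_j.mutated)
    elements = c.elements[:ei] + (chimera,) + c.elements[ej + 1:]
    out = replace(c, elements=elements)
    _assert_frame(c, out)
    assert out.n_repeats == c.n_repeats - (repeat_j - repeat_i)
    return out


#: Deterministic in-frame filler used when no insert DNA is supplied
#: (a generic bulky-domain stand-in; 711 bp = 237 codons).
_DEFAULT_INSERT = ("ATG" + "GCTGGTAGC" * 78 + "AAA")


def insert_block(
    c: ConstructSpec,
    start_repeat: int,
    n_replaced: int,
    insert_label: str = "insert",
    insert_dna: str | None = None,
) -> tuple[ConstructSpec, list[int], int]:
    """Replace ``n_replaced`` repeats from ``start_repeat`` with one block.

    Returns (construct, uninterrupted section lengths, longest run).
    """
    if n_replaced < 1:
        raise ValidationError("n_replaced must be at least 1")
    if start_repeat < 1 or start_repeat + n_replaced - 1 > c.n_repeats:
        raise ValidationError(
            f"block [{start_repeat}, {start_repeat + n_replaced - 1}] outside "
            f"1..{c.n_repeats}"
        )
    dna = _DEFAULT_INSERT if insert_dna is None else insert_dna.upper()
    e_start = c.coil_element_index(start_repeat)
    e_end = c.coil_element_index(start_repeat + n_replaced - 1)
    if any(isinstance(e, Insert) for e in c.elements[e_start:e_end + 1]):
        raise ValidationError("replacement range overlaps an existing insert")
    elements = (
        c.elements[:e_start] + (Insert(dna, insert_label),) + c.elements[e_end + 1:]
    )
    out = replace(c, elements=elements)
    _assert_frame(c, out)
    runs = uninterrupted_runs(out)
    return out, runs, max(runs, default=0)


def apply_motif_mutations(
    c: ConstructSpec,
    repeat_range: tuple[int, int],
    motif: str,
    substitutions: Mapping[int, str | Sequence[str]],
) -> tuple[ConstructSpec, list[int]]:
    """Mutate motif positions within an inclusive 1-based repeat range.

    ``substitutions`` maps a coil position (1-based, restricted to the
    motif's positions) to the replacement residue(s); with several candidate
    residues they are cycled across the mutated coils so adjacent coils get
    different replacements.  Mutated coils are marked as interruptions for
    run accounting.  Returns (construct, lengths of unmutated runs).
    """
    if motif not in MOTIF_POSITIONS:
        raise ValidationError(f"unknown motif {motif!r}")
    allowed = set(MOTIF_POSITIONS[motif])
    for pos in substitutions:
        if pos not in allowed:
            raise ValidationError(
                f"position {pos} outside {motif} motif positions {sorted(allowed)}"
            )
    lo, hi = repeat_range
    if not (1 <= lo <= hi <= c.n_repeats):
        raise ValidationError(f"repeat_range {repeat_range} outside construct")
    if not substitutions:
        return c, uninterrupted_runs(c)

    subs = {
        pos: ([res] if isinstance(res, str) else list(res))
        for pos, res in substitutions.items()
    }
    elements = list(c.elements)
    for n, rep in enumerate(range(lo, hi + 1)):
        idx = c.coil_element_index(rep)
        coil = elements[idx]
        assert isinstance(coil, Coil)
        dna = coil.dna
        for pos, residues in subs.items():
            new_aa = residues[n % len(residues)]
            codon_at = (pos - 1) * 3
            dna = dna[:codon_at] + CODON_TABLE[new_aa] + dna[codon_at + 3:]
        elements[idx] = Coil(dna, coil.cls, mutated=True)
    out = replace(c, elements=tuple(elements))
    _assert_frame(c, out)
    return out, uninterrupted_runs(out)


# ---------------------------------------------------------------------------
# Restriction-site reporting
# ---------------------------------------------------------------------------

def _iupac_regex(recognition: str) -> re.Pattern[str]:
    try:
        return re.compile(
            "".join(
                b if len(IUPAC_DNA[b]) == 1 else f"[{IUPAC_DNA[b]}]"
                for b in recognition.upper()
            )
        )
    except KeyError as exc:
        raise ValidationError(f"bad IUPAC base {exc} in {recognition!r}") from exc


def _revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _scan(dna: str, recognition: str) -> list[int]:
    """Overlapping occurrences of an IUPAC recognition sequence (fwd strand)."""
    pat = _iupac_regex(recognition)
    return [m.start() for m in re.finditer(f"(?={pat.pattern})", dna)]


@dataclass(frozen=True)
class EnzymeReport:
    name: str
    recognition: str
    positions: tuple[int, ...]  # forward-strand site starts, both strands
    is_unique_pair: bool
    spacing: int | None
    spacing_mod48: int | None
    in_frame: bool | None


@dataclass(frozen=True)
class SitePairReport:
    enzymes: tuple[EnzymeReport, ...]

    def __getitem__(self, name: str) -> EnzymeReport:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)


def verify_site_pairs(
    c: ConstructSpec, enzymes: Iterable[tuple[str, str]]
) -> SitePairReport:
    """Locate each enzyme's recognition sites and check pair uniqueness.

    Non-palindromic sites are also searched on the reverse complement (their
    positions reported in forward-strand coordinates).  A pair is unique iff
    the site occurs exactly twice; spacing is between site starts, with
    mod-48 periodicity and mod-3 frame preservation of the excision junction
    reported alongside.
    """
    dna = c.dna
    reports = []
    for name, recognition in enzymes:
        recognition = recognition.upper()
        positions = _scan(dna, recognition)
        if _revcomp(recognition) != recognition:
            m = len(recognition)
            rc_hits = [
                len(dna) - p - m for p in _scan(_revcomp(dna), recognition)
            ]
            positions = sorted(set(positions) | set(rc_hits))
        unique_pair = len(positions) == 2
        spacing = positions[1] - positions[0] if unique_pair else None
        reports.append(
            EnzymeReport(
                name,
                recognition,
                tuple(positions),
                unique_pair,
                spacing,
                spacing % 48 if spacing is not None else None,
                spacing % 3 == 0 if spacing is not None else None,
            )
        )
    return SitePairReport(tuple(reports))


def count_coil_classes(c: ConstructSpec) -> tuple[int, int, int]:
    """(n_water_organizing, n_r_coil, n_other) over remaining coils."""
    classes = c.coil_classes
    return (
        sum(cls is CoilClass.WATER_ORGANIZING for cls in classes),
        sum(cls is CoilClass.R_COIL for cls in classes),
        sum(cls is CoilClass.OTHER for cls in classes),
    )
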