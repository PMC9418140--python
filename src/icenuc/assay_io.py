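"""Input/output for droplet-freezing assay tables, sequence files, and configs.

Droplet tables are UTF-8 delimited text with a header row.  Assay metadata
travels in ``#meta`` comment lines at the top of the file, each holding one
``key: value`` pair (YAML scalar syntax), so a table remains grep-able while
staying fully machine-readable.  Temperatures are degrees Celsius everywhere,
negative when supercooled; there is no Kelvin anywhere in this package.

Sequence coordinates follow the usual split convention: 0-based half-open
internally, 1-based inclusive at user-facing boundaries (GenBank locations,
repeat indices).  Conversion happens only in this module.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

__all__ = [
    "CENSORED",
    "Apparatus",
    "ApparatusParams",
    "Droplet",
    "DropletAssay",
    "SequenceRecord",
    "SchemaError",
    "ValidationError",
    "read_droplet_table",
    "write_droplet_table",
    "read_sequence",
    "write_fasta",
    "read_config",
    "genbank_to_internal",
    "internal_to_genbank",
]

#: Token used in droplet tables for droplets that never froze before the ramp
#: reached its end temperature.  Such droplets still count in denominators.
CENSORED = "CENSORED"


class SchemaError(ValueError):
    """A droplet table does not match the documented schema."""


class ValidationError(ValueError):
    """A value parsed fine but violates a domain invariant."""


class Apparatus(str, enum.Enum):
    WISDOM = "WISDOM"
    BINARY = "BINARY"
    GENERIC = "GENERIC"


@dataclass(frozen=True)
class ApparatusParams:
    """Instrument-level constants used for uncertainty floors and backgrounds.

    Defaults: both instruments carry a ±0.3 °C temperature uncertainty;
    background (no-nucleator) T50s are −38.7 °C for WISDOM in LB,
    −29.7 °C for BINARY in PBS and −29.5 °C for BINARY in pure water;
    homogeneous freezing of pure water on WISDOM sets in below −35 °C.
    """

    name: Apparatus = Apparatus.GENERIC
    temp_uncertainty: float = 0.3
    background_t50: float = -38.7
    homogeneous_onset: float = -35.0

    def __post_init__(self) -> None:
        if self.temp_uncertainty <= 0:
            raise ValidationError("temp_uncertainty must be positive")
        if self.background_t50 >= 0:
            raise ValidationError("background_t50 must be below 0 degC")


#: Ready-made parameter sets for the two instruments (buffer backgrounds).
WISDOM_PARAMS = ApparatusParams(Apparatus.WISDOM, 0.3, -38.7, -35.0)
BINARY_PARAMS = ApparatusParams(Apparatus.BINARY, 0.3, -29.7, -29.5)
BINARY_WATER_PARAMS = ApparatusParams(Apparatus.BINARY, 0.3, -29.5, -29.5)


@dataclass(frozen=True)
class Droplet:
    droplet_id: str
    freeze_temp: float | None  # None encodes CENSORED (never froze on ramp)
    excluded: bool = False

    @property
    def censored(self) -> bool:
        return self.freeze_temp is None


@dataclass(frozen=True)
class DropletAssay:
    """One droplet-freezing run: per-droplet events plus assay metadata."""

    assay_id: str
    droplets: tuple[Droplet, ...]
    apparatus: Apparatus = Apparatus.GENERIC
    droplet_volume: float = 1e-9  # litres
    cooling_rate: float = 1.0  # degC per minute
    ramp_end_temp: float = -40.0
    dilution_factor: float = 1.0
    cell_mass_concentration: float = 0.0  # grams per litre; 0 = unknown
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValidationError("droplet_volume must be positive")
        if not (0.0 < self.dilution_factor <= 1.0):
            raise ValidationError("dilution_factor must be in (0, 1]")
        for d in self.droplets:
            if d.freeze_temp is None:
                continue
            if not (-80.0 < d.freeze_temp <= 0.0):
                raise ValidationError(
                    f"droplet {d.droplet_id}: freeze_temp {d.freeze_temp} "
                    "outside (-80, 0] degC"
                )
            if d.freeze_temp < self.ramp_end_temp:
                raise ValidationError(
                    f"droplet {d.droplet_id}: freeze_temp below ramp_end_temp"
                )

    @property
    def included(self) -> tuple[Droplet, ...]:
        """Droplets that enter statistics (e.g. spacer-contact ones do not)."""
        return tuple(d for d in self.droplets if not d.excluded)

    @property
    def n_droplets(self) -> int:
        return len(self.included)

    @property
    def n_censored(self) -> int:
        return sum(1 for d in self.included if d.censored)

    def freeze_temps(self) -> list[float]:
        """Freeze temperatures of included, non-censored droplets (file order)."""
        return [d.freeze_temp for d in self.included if d.freeze_temp is not None]

    def with_droplets(self, droplets: Iterable[Droplet]) -> "DropletAssay":
        return replace(self, droplets=tuple(droplets))


# ---------------------------------------------------------------------------
# Droplet tables
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ("droplet_id", "freeze_temp_C")

_META_FIELDS = {
    "assay_id": str,
    "apparatus": str,
    "droplet_volume_L": float,
    "cooling_rate_C_per_min": float,
    "ramp_end_temp_C": float,
    "dilution_factor": float,
    "cell_mass_concentration_g_per_L": float,
    "sample_label": str,
}


def _parse_meta(lines: list[str]) -> dict:
    raw = "\n".join(line[len("#meta"):].strip() for line in lines)
    meta = yaml.safe_load(raw) if raw.strip() else {}
    if not isinstance(meta, dict):
        raise SchemaError("#meta lines must form a YAML mapping")
    return meta


def read_droplet_table(path: str | Path, schema_version: str = "1") -> DropletAssay:
    """Read a delimited droplet table into a validated :class:`DropletAssay`.

    Row order is preserved; excluded droplets are retained but flagged.
    """
    if schema_version != "1":
        raise SchemaError(f"unknown schema version {schema_version!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta_lines = [ln for ln in text.splitlines() if ln.startswith("#meta")]
    data_lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not data_lines:
        raise SchemaError(f"{path}: no header row")
    delim = "\t" if "\t" in data_lines[0] else ","
    header = [h.strip() for h in data_lines[0].split(delim)]
    for col in _MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    idx = {name: i for i, name in enumerate(header)}
    rows = data_lines[1:]
    if not rows:
        raise SchemaError(f"{path}: table has a header but no droplet rows")

    droplets: list[Droplet] = []
    for lineno, row in enumerate(rows, start=2):
        fields = [f.strip() for f in row.split(delim)]
        if len(fields) < len(_MANDATORY_COLUMNS):
            raise SchemaError(f"{path}:{lineno}: too few fields")
        did = fields[idx["droplet_id"]]
        raw_t = fields[idx["freeze_temp_C"]]
        if raw_t.upper() == CENSORED:
            temp: float | None = None
        else:
            try:
                temp = float(raw_t)
            except ValueError as exc:
                raise SchemaError(
                    f"{path}:{lineno}: freeze_temp_C {raw_t!r} is neither a "
                    f"number nor {CENSORED!r}"
                ) from exc
            if not math.isfinite(temp):
                raise ValidationError(f"{path}:{lineno}: non-finite temperature")
            if temp > 0:
                raise ValidationError(
                    f"{path}:{lineno}: freeze temperature {temp} degC is above 0"
                )
        excluded = False
        if "excluded" in idx and len(fields) > idx["excluded"]:
            excluded = fields[idx["excluded"]] in ("1", "true", "True")
        droplets.append(Droplet(did, temp, excluded))

    meta = _parse_meta(meta_lines)
    for key in meta:
        if key not in _META_FIELDS:
            raise SchemaError(f"{path}: unknown #meta key {key!r}")
    kwargs = {}
    if "assay_id" in meta:
        kwargs["assay_id"] = str(meta["assay_id"])
    else:
        kwargs["assay_id"] = path.stem
    if "apparatus" in meta:
        kwargs["apparatus"] = Apparatus(meta["apparatus"])
    if "droplet_volume_L" in meta:
        kwargs["droplet_volume"] = float(meta["droplet_volume_L"])
    if "cooling_rate_C_per_min" in meta:
        kwargs["cooling_rate"] = float(meta["cooling_rate_C_per_min"])
    if "ramp_end_temp_C" in meta:
        kwargs["ramp_end_temp"] = float(meta["ramp_end_temp_C"])
    if "dilution_factor" in meta:
        kwargs["dilution_factor"] = float(meta["dilution_factor"])
    if "cell_mass_concentration_g_per_L" in meta:
        kwargs["cell_mass_concentration"] = float(
            meta["cell_mass_concentration_g_per_L"]
        )
    if "sample_label" in meta:
        kwargs["sample_label"] = str(meta["sample_label"])
    return DropletAssay(droplets=tuple(droplets), **kwargs)


def write_droplet_table(assay: DropletAssay, path: str | Path) -> None:
    """Write ``assay`` so that :func:`read_droplet_table` round-trips it."""
    path = Path(path)
    buf = io.StringIO()
    meta = {
        "assay_id": assay.assay_id,
        "apparatus": assay.apparatus.value,
        "droplet_volume_L": assay.droplet_volume,
        "cooling_rate_C_per_min": assay.cooling_rate,
        "ramp_end_temp_C": assay.ramp_end_temp,
        "dilution_factor": assay.dilution_factor,
        "cell_mass_concentration_g_per_L": assay.cell_mass_concentration,
        "sample_label": assay.sample_label,
    }
    for key, value in meta.items():
        buf.write(f"#meta {key}: {value!r}\n" if isinstance(value, str)
                  else f"#meta {key}: {value}\n")
    buf.write("droplet_id,freeze_temp_C,excluded\n")
    for d in assay.droplets:
        temp = CENSORED if d.freeze_temp is None else repr(d.freeze_temp)
        buf.write(f"{d.droplet_id},{temp},{int(d.excluded)}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_IUPAC_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
_IUPAC_DNA = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """A parsed sequence with features in internal 0-based half-open coords."""

    id: str
    sequence: str
    features: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def genbank_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive (GenBank) -> 0-based half-open (internal)."""
    return start_1based - 1, end_1based


def internal_to_genbank(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (internal) -> 1-based inclusive (GenBank)."""
    return start + 1, end


def read_sequence(path: str | Path, format: str = "FASTA") -> list[SequenceRecord]:
    """Read FASTA or GenBank records, uppercased, with validated alphabets.

    GenBank feature locations are converted from the file's 1-based inclusive
    convention into the internal 0-based half-open one.
    """
    fmt = format.upper()
    if fmt not in ("FASTA", "GENBANK"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    bio_fmt = "fasta" if fmt == "FASTA" else "genbank"
    try:
        bio_records = list(SeqIO.parse(str(path), bio_fmt))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    if not bio_records:
        raise ValueError(f"{path}: no {fmt} records found")

    records: list[SequenceRecord] = []
    for rec in bio_records:
        seq = str(rec.seq).upper()
        is_protein = bool(set(seq) - _IUPAC_DNA)
        alphabet = _IUPAC_PROTEIN if is_protein else _IUPAC_DNA
        bad = set(seq) - alphabet
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id}: non-IUPAC characters {sorted(bad)}"
            )
        features = []
        for feat in getattr(rec, "features", []):
            # Biopython already exposes 0-based half-open coordinates.
            features.append(
                (feat.type, int(feat.location.start), int(feat.location.end))
            )
        records.append(
            SequenceRecord(rec.id, seq, tuple(features), rec.description)
        )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_config(path: str | Path) -> dict:
    """Read a YAML (or JSON, a YAML subset) configuration mapping."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
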