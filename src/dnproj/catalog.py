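"""Descending-neuron catalog: data model, validation, and tabular I/O.

A catalog is a list of DN (descending neuron) cell-type records annotated
against two neuropil atlases — one for the brain, one for the ventral nerve
cord (VNC).  Each record carries the soma cluster, the number of bilateral
pairs, laterality of the descending axon, the descending tract, and a
per-neuropil polarity annotation (smooth = putative postsynaptic input,
varicose = putative presynaptic output).

File formats
------------
Catalog CSV columns are ``type_id, soma_group, kind, n_pairs, laterality,
tract`` followed by one column per brain neuropil and one per VNC neuropil,
in atlas order.  Polarity cells hold a single code character — ``N`` none,
``S`` smooth, ``V`` varicose, ``B`` both — optionally followed by an ordinal
intensity digit (``0`` absent, ``1`` sparse, ``2`` dense), e.g. ``V2``.
An equivalent JSON encoding stores one object per record.  Atlases are YAML
lists of ``[abbreviation, full name, group]`` triples.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Polarity",
    "NeuropilAtlas",
    "DNRecord",
    "DNCatalog",
    "DNName",
    "CatalogError",
    "validate_dn_name",
    "parse_catalog",
    "write_catalog",
    "load_default_atlases",
    "load_atlas",
    "write_atlas",
    "SOMA_GROUPS",
    "TRACTS",
    "LATERALITIES",
]

SOMA_GROUPS = ("a", "b", "c", "d", "g", "p", "x")
#: Seven named descending tracts; the eighth tract in the original material
#: is unnamed, so records may carry "other" (identified but unnamed) or
#: "unknown" (not determined).
TRACTS = ("DLT", "MDA", "MTD", "ITD", "VLT", "DLV", "VTV", "other", "unknown")
LATERALITIES = ("ipsilateral", "contralateral", "unknown")

_POLARITY_VALUES = ("none", "smooth", "varicose", "both")
_CODE_TO_VALUE = {"N": "none", "S": "smooth", "V": "varicose", "B": "both"}
_VALUE_TO_CODE = {v: k for k, v in _CODE_TO_VALUE.items()}
_INTENSITY_NAMES = {0: "absent", 1: "sparse", 2: "dense"}


class CatalogError(ValueError):
    """Raised for schema violations in catalogs, atlases, or name grammar."""


@dataclass(frozen=True)
class Polarity:
    """Polarity annotation of one DN type in one neuropil.

    ``value`` is the neurite morphology class: ``smooth`` (postsynaptic),
    ``varicose`` (presynaptic), ``both``, or ``none``.  ``intensity`` is an
    optional ordinal level (0 absent / 1 sparse / 2 dense) used for
    graded annotations such as optic-glomerulus innervation.
    """

    value: str = "none"
    intensity: int | None = None

    def __post_init__(self) -> None:
        if self.value not in _POLARITY_VALUES:
            raise CatalogError(f"unknown polarity value {self.value!r}")
        if self.intensity is not None:
            if self.intensity not in (0, 1, 2):
                raise CatalogError(f"intensity must be 0, 1 or 2, got {self.intensity!r}")
            if (self.value == "none") != (self.intensity == 0):
                raise CatalogError(
                    f"polarity {self.value!r} inconsistent with intensity "
                    f"{_INTENSITY_NAMES[self.intensity]!r}"
                )

    @property
    def innervates(self) -> bool:
        return self.value != "none"

    def effective_intensity(self) -> int:
        """Ordinal level used for thresholding; un-annotated innervation counts as dense."""
        if self.intensity is not None:
            return self.intensity
        return 0 if self.value == "none" else 2

    def code(self) -> str:
        c = _VALUE_TO_CODE[self.value]
        return c if self.intensity is None else f"{c}{self.intensity}"

    @classmethod
    def from_code(cls, code: str) -> "Polarity":
        code = code.strip()
        if code == "" or code.lower() == "nan":
            return cls("none")
        m = re.fullmatch(r"([NSVB])([012])?", code)
        if not m:
            raise CatalogError(f"unknown polarity code {code!r}")
        value = _CODE_TO_VALUE[m.group(1)]
        intensity = int(m.group(2)) if m.group(2) is not None else None
        return cls(value, intensity)


NONE_POLARITY = Polarity("none")


@dataclass(frozen=True)
class DNName:
    """Parsed DN type name: soma-group letter and two-digit index."""

    group: str
    index: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"DN{self.group}{self.index}"


def validate_dn_name(name: str) -> DNName:
    """Validate a DN type name against the nomenclature grammar.

    Names are ``DN`` + one soma-group letter (a, b, c, d, g, p, x — the
    cell-body cluster on the brain surface) + a two-digit index, e.g.
    ``DNp01``.  Returns the parsed parts or raises :class:`CatalogError`
    with a description of the violation.
    """
    if not isinstance(name, str):
        raise CatalogError(f"DN name must be a string, got {type(name).__name__}")
    if not name.startswith("DN"):
        raise CatalogError(f"{name!r}: DN names start with the prefix 'DN'")
    rest = name[2:]
    if not rest or rest[0] not in SOMA_GROUPS:
        raise CatalogError(
            f"{name!r}: soma-group letter must be one of {''.join(SOMA_GROUPS)}"
        )
    index = rest[1:]
    if not re.fullmatch(r"[0-9]{2}", index):
        raise CatalogError(f"{name!r}: type index must be exactly two digits")
    return DNName(group=rest[0], index=index)


@dataclass(frozen=True)
class NeuropilAtlas:
    """Ordered list of neuropil compartments with group labels.

    ``compartments`` is a tuple of ``(abbreviation, full_name, group)``.
    Groups partition the compartments (e.g. the VNC grouping into dorsal,
    tectulum, lower tectulum, leg, and other regions).
    """

    side: str  # brain | vnc | custom
    compartments: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        abbrevs = [c[0] for c in self.compartments]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise CatalogError(f"duplicate atlas abbreviations: {dupes}")

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.compartments)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.abbreviations

    def __len__(self) -> int:
        return len(self.compartments)

    def group(self, abbrev: str) -> str:
        for a, _, g in self.compartments:
            if a == abbrev:
                return g
        raise KeyError(f"{abbrev!r} not in {self.side} atlas")

    def full_name(self, abbrev: str) -> str:
        for a, n, _ in self.compartments:
            if a == abbrev:
                return n
        raise KeyError(f"{abbrev!r} not in {self.side} atlas")

    @property
    def groups(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for a, _, g in self.compartments:
            out.setdefault(g, []).append(a)
        return {g: tuple(v) for g, v in out.items()}

    def members(self, group: str) -> tuple[str, ...]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"no group {group!r} in {self.side} atlas") from None


@dataclass(frozen=True)
class DNRecord:
    """One DN cell type with its anatomical annotation."""

    type_id: str
    soma_group: str
    kind: str  # unique | population
    n_pairs: int
    laterality: str
    tract: str
    brain_innervation: Mapping[str, Polarity] = field(default_factory=dict)
    vnc_innervation: Mapping[str, Polarity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parsed = validate_dn_name(self.type_id)
        if self.soma_group not in SOMA_GROUPS:
            raise CatalogError(f"{self.type_id}: bad soma group {self.soma_group!r}")
        if parsed.group != self.soma_group:
            raise CatalogError(
                f"{self.type_id}: name encodes group {parsed.group!r} but record "
                f"says {self.soma_group!r}"
            )
        if self.kind not in ("unique", "population"):
            raise CatalogError(f"{self.type_id}: kind must be unique or population")
        if not (isinstance(self.n_pairs, int) and self.n_pairs >= 1):
            raise CatalogError(f"{self.type_id}: n_pairs must be a positive integer")
        if self.kind == "unique" and self.n_pairs != 1:
            raise CatalogError(f"{self.type_id}: unique types have exactly 1 pair")
        if self.laterality not in LATERALITIES:
            raise CatalogError(f"{self.type_id}: bad laterality {self.laterality!r}")
        if self.tract not in TRACTS:
            raise CatalogError(f"{self.type_id}: unknown tract {self.tract!r}")
        object.__setattr__(self, "brain_innervation", dict(self.brain_innervation))
        object.__setattr__(self, "vnc_innervation", dict(self.vnc_innervation))

    def polarity(self, side: str, neuropil: str) -> Polarity:
        ann = self.brain_innervation if side == "brain" else self.vnc_innervation
        return ann.get(neuropil, NONE_POLARITY)


@dataclass
class DNCatalog:
    """A validated collection of DN records plus the atlases they refer to."""

    records: list[DNRecord]
    brain_atlas: NeuropilAtlas
    vnc_atlas: NeuropilAtlas
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.type_id in seen:
                raise CatalogError(f"duplicate type_id {rec.type_id!r}")
            seen.add(rec.type_id)
            for np_abbrev in rec.brain_innervation:
                if np_abbrev not in self.brain_atlas:
                    raise CatalogError(
                        f"{rec.type_id}: {np_abbrev!r} not in the brain atlas"
                    )
            for np_abbrev in rec.vnc_innervation:
                if np_abbrev not in self.vnc_atlas:
                    raise CatalogError(
                        f"{rec.type_id}: {np_abbrev!r} not in the VNC atlas"
                    )
            for np_abbrev, pol in rec.vnc_innervation.items():
                if pol.value == "smooth":
                    logger.warning(
                        "%s: smooth (input-type) process annotated in VNC neuropil %s; "
                        "VNC innervation is expected to be varicose",
                        rec.type_id,
                        np_abbrev,
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def type_ids(self) -> list[str]:
        return [r.type_id for r in self.records]

    def get(self, type_id: str) -> DNRecord:
        for r in self.records:
            if r.type_id == type_id:
                return r
        raise KeyError(type_id)

    def sorted(self) -> "DNCatalog":
        """Canonical copy with records ordered by type_id."""
        recs = sorted(self.records, key=lambda r: r.type_id)
        return replace(self, records=recs)


# --------------------------------------------------------------------------
# Default atlases
# --------------------------------------------------------------------------

# Standard insect-brain nomenclature: 41 named neuropils of the cerebral
# ganglia plus the gnathal ganglia (GNG).  Group labels follow the standard
# supercategories (optic lobe, mushroom body, central complex, ...).
_BRAIN_COMPARTMENTS: tuple[tuple[str, str, str], ...] = (
    ("LA", "lamina", "optic_lobe"),
    ("ME", "medulla", "optic_lobe"),
    ("AME", "accessory medulla", "optic_lobe"),
    ("LO", "lobula", "optic_lobe"),
    ("LOP", "lobula plate", "optic_lobe"),
    ("CA", "mushroom body calyx", "mushroom_body"),
    ("PED", "pedunculus", "mushroom_body"),
    ("VL", "vertical lobe", "mushroom_body"),
    ("ML", "medial lobe", "mushroom_body"),
    ("LH", "lateral horn", "lateral_horn"),
    ("SLP", "superior lateral protocerebrum", "superior_neuropils"),
    ("SIP", "superior intermediate protocerebrum", "superior_neuropils"),
    ("SMP", "superior medial protocerebrum", "superior_neuropils"),
    ("CRE", "crepine", "inferior_neuropils"),
    ("SCL", "superior clamp", "inferior_neuropils"),
    ("ICL", "inferior clamp", "inferior_neuropils"),
    ("IB", "inferior bridge", "inferior_neuropils"),
    ("ATL", "antler", "inferior_neuropils"),
    ("AL", "antennal lobe", "antennal_lobe"),
    ("AOTU", "anterior optic tubercle", "ventrolateral_neuropils"),
    ("AVLP", "anterior ventrolateral protocerebrum", "ventrolateral_neuropils"),
    ("PVLP", "posterior ventrolateral protocerebrum", "ventrolateral_neuropils"),
    ("PLP", "posterior lateral protocerebrum", "ventrolateral_neuropils"),
    ("WED", "wedge", "ventrolateral_neuropils"),
    ("VES", "vest", "ventromedial_neuropils"),
    ("EPA", "epaulette", "ventromedial_neuropils"),
    ("GOR", "gorget", "ventromedial_neuropils"),
    ("SPS", "superior posterior slope", "ventromedial_neuropils"),
    ("IPS", "inferior posterior slope", "ventromedial_neuropils"),
    ("SAD", "saddle", "periesophageal_neuropils"),
    ("AMMC", "antennal mechanosensory and motor center", "periesophageal_neuropils"),
    ("FLA", "flange", "periesophageal_neuropils"),
    ("CAN", "cantle", "periesophageal_neuropils"),
    ("PRW", "prow", "periesophageal_neuropils"),
    ("FB", "fan-shaped body", "central_complex"),
    ("EB", "ellipsoid body", "central_complex"),
    ("PB", "protocerebral bridge", "central_complex"),
    ("NO", "noduli", "central_complex"),
    ("BU", "bulb", "lateral_complex"),
    ("LAL", "lateral accessory lobe", "lateral_complex"),
    ("GA", "gall", "lateral_complex"),
    ("GNG", "gnathal ganglia", "gnathal"),
)

# VNC compartments explicitly derivable from the figure grouping: dorsal
# (neck/wing/haltere motor neuropils), tectulum, lower tectulum, the three
# leg neuromeres, and the remaining small regions.  User-extensible.
_VNC_COMPARTMENTS: tuple[tuple[str, str, str], ...] = (
    ("neck", "neck motor neuropil", "dorsal"),
    ("wing", "wing motor neuropil", "dorsal"),
    ("haltere", "haltere motor neuropil", "dorsal"),
    ("tectulum", "tectulum", "tectulum"),
    ("lower_tectulum", "lower tectulum", "lower_tectulum"),
    ("foreleg", "prothoracic leg neuropil", "leg"),
    ("middle_leg", "mesothoracic leg neuropil", "leg"),
    ("hindleg", "metathoracic leg neuropil", "leg"),
    ("AMN", "accessory mesothoracic neuropil", "other"),
    ("AS", "abdominal segments", "other"),
    ("VAC", "ventral association center", "other"),
    ("mVAC", "medial ventral association center", "other"),
)


def load_default_atlases() -> tuple[NeuropilAtlas, NeuropilAtlas]:
    """Return the default (brain, VNC) atlases."""
    return (
        NeuropilAtlas("brain", _BRAIN_COMPARTMENTS),
        NeuropilAtlas("vnc", _VNC_COMPARTMENTS),
    )


def load_atlas(path: str | Path, side: str = "custom") -> NeuropilAtlas:
    """Read an atlas from a YAML list of ``[abbrev, name, group]`` triples."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    comps = tuple((str(a), str(n), str(g)) for a, n, g in raw)
    return NeuropilAtlas(side, comps)


def write_atlas(atlas: NeuropilAtlas, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([list(c) for c in atlas.compartments], fh)


# --------------------------------------------------------------------------
# Catalog I/O
# --------------------------------------------------------------------------

_META_COLUMNS = ["type_id", "soma_group", "kind", "n_pairs", "laterality", "tract"]


def _record_to_row(rec: DNRecord, brain: NeuropilAtlas, vnc: NeuropilAtlas) -> dict:
    row = {
        "type_id": rec.type_id,
        "soma_group": rec.soma_group,
        "kind": rec.kind,
        "n_pairs": rec.n_pairs,
        "laterality": rec.laterality,
        "tract": rec.tract,
    }
    for a in brain.abbreviations:
        row[a] = rec.polarity("brain", a).code()
    for a in vnc.abbreviations:
        row[a] = rec.polarity("vnc", a).code()
    return row


def _row_to_record(row: Mapping, brain: NeuropilAtlas, vnc: NeuropilAtlas) -> DNRecord:
    brain_ann = {}
    for a in brain.abbreviations:
        if a in row:
            pol = Polarity.from_code(str(row[a]))
            if pol.innervates or pol.intensity is not None:
                brain_ann[a] = pol
    vnc_ann = {}
    for a in vnc.abbreviations:
        if a in row:
            pol = Polarity.from_code(str(row[a]))
            if pol.innervates or pol.intensity is not None:
                vnc_ann[a] = pol
    return DNRecord(
        type_id=str(row["type_id"]),
        soma_group=str(row["soma_group"]),
        kind=str(row["kind"]),
        n_pairs=int(row["n_pairs"]),
        laterality=str(row["laterality"]),
        tract=str(row["tract"]),
        brain_innervation=brain_ann,
        vnc_innervation=vnc_ann,
    )


def parse_catalog(
    path: str | Path,
    brain_atlas: NeuropilAtlas | None = None,
    vnc_atlas: NeuropilAtlas | None = None,
) -> DNCatalog:
    """Read a catalog from CSV or JSON (by file extension).

    Unknown neuropil columns and duplicate ``type_id`` values raise
    :class:`CatalogError`.  Atlases default to :func:`load_default_atlases`.
    """
    if brain_atlas is None or vnc_atlas is None:
        b, v = load_default_atlases()
        brain_atlas = brain_atlas or b
        vnc_atlas = vnc_atlas or v
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        rows = payload["records"] if isinstance(payload, dict) else payload
        provenance = payload.get("provenance", "") if isinstance(payload, dict) else ""
        for row in rows:
            _check_columns(row.keys(), brain_atlas, vnc_atlas)
        records = [_row_to_record(r, brain_atlas, vnc_atlas) for r in rows]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _check_columns(df.columns, brain_atlas, vnc_atlas)
        records = [
            _row_to_record(row, brain_atlas, vnc_atlas)
            for row in df.to_dict(orient="records")
        ]
        provenance = ""
    return DNCatalog(records, brain_atlas, vnc_atlas, provenance=provenance)


def _check_columns(cols: Iterable[str], brain: NeuropilAtlas, vnc: NeuropilAtlas) -> None:
    cols = list(cols)
    for c in _META_COLUMNS:
        if c not in cols:
            raise CatalogError(f"missing mandatory column {c!r}")
    known = set(_META_COLUMNS) | set(brain.abbreviations) | set(vnc.abbreviations)
    unknown = [c for c in cols if c not in known]
    if unknown:
        raise CatalogError(f"unknown neuropil columns: {unknown}")


def write_catalog(catalog: DNCatalog, path: str | Path, fmt: str | None = None) -> None:
    """Write a catalog to CSV or JSON with canonical row/column ordering.

    Rows are sorted by ``type_id``; columns follow atlas order.  Lossless
    with respect to :func:`parse_catalog`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    cat = catalog.sorted()
    rows = [_record_to_row(r, cat.brain_atlas, cat.vnc_atlas) for r in cat.records]
    cols = (
        _META_COLUMNS
        + list(cat.brain_atlas.abbreviations)
        + list(cat.vnc_atlas.abbreviations)
    )
    if fmt == "json":
        payload = {"provenance": cat.provenance, "records": rows}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    elif fmt == "csv":
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, index=False)
    else:
        raise CatalogError(f"unknown catalog format {fmt!r}")
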