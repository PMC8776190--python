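"""Additive Hazard Index screening for occupational chemical mixtures.

Workers are routinely exposed to several airborne chemicals at once.  The
standard single-substance check — compare each measured concentration C with
the substance's occupational exposure limit (OEL) — misses situations where
several substances below their individual limits attack the same target
organ.  The screening convention recommended by ACGIH and the EPA is
additivity: for every toxicological class (target organ or mode of action)
shared by the mixture components, compute a Hazard Index

    HI = (C1/OEL1 + C2/OEL2 + ... + Cn/OELn) x 100

and flag the class as risky when HI exceeds 100%.  For a handful of classes
(carcinogenicity/mutagenicity, sensitization, endocrine disruption,
reproductive and developmental toxicity) additivity is not a meaningful
model; any exposure at all triggers an alert instead of a summed index.

This module provides, in the order an analysis runs:

1.  the built-in taxonomy of 24 toxicological classes with their
    additive/alert status and associated toxic effects;
2.  the substance database model (CAS-keyed substances with jurisdictional
    OEL sets and class links), with JSON/CSV readers and writers, CAS
    check-digit validation, 8 h OEL selection, and ppm <-> mg/m3 conversion;
3.  the mixture engine: per-class HI under additivity, alert detection,
    quantitative and qualitative analysis, ranked reporting;
4.  report rendering (deterministic text and JSON) and report round-trip;
5.  synthetic fixture generators standing in for the unpublished 700+
    substance regulatory corpus, plus a packaged four-solvent
    printing-workshop case study.
"""

from __future__ import annotations

import csv
import io
import json
import math
import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

__all__ = [
    # constants
    "MOLAR_VOLUME_L_PER_MOL",
    "RISK_THRESHOLD_PERCENT",
    # errors
    "HazmixError",
    "DatabaseError",
    "ScenarioError",
    "UnitConversionError",
    "NoUsableOELError",
    # taxonomy
    "ToxClass",
    "ToxClassRegistry",
    "load_builtin_taxonomy",
    # database
    "OELValue",
    "SelectedOEL",
    "Substance",
    "SubstanceDatabase",
    "validate_cas",
    "validate_database",
    "parse_substance_db",
    "write_substance_db",
    "select_oel",
    "convert_concentration",
    # scenarios
    "ExposureRecord",
    "MixtureScenario",
    "parse_scenario",
    # engine
    "Contribution",
    "ClassHIResult",
    "QualitativeClassResult",
    "AlertFinding",
    "AnalysisReport",
    "exposure_ratio",
    "compute_class_hi",
    "detect_alerts",
    "analyze_quantitative",
    "analyze_qualitative",
    "rank_results",
    # reporting
    "render_report",
    "report_to_dict",
    "report_from_dict",
    "report_from_json",
    "ALERT_MESSAGES",
    # fixtures
    "GeneratorSpec",
    "generate_substance_db",
    "generate_scenario",
    "case_study_fixture",
]

# --------------------------------------------------------------------------
# Configuration constants
# --------------------------------------------------------------------------

#: Molar volume of an ideal gas at 25 degC and 101.325 kPa, litres per mole.
#: Industrial-hygiene convention for ppm <-> mg/m3 conversion.
MOLAR_VOLUME_L_PER_MOL = 24.45

#: A class is risky when its Hazard Index strictly exceeds this percentage.
RISK_THRESHOLD_PERCENT = 100.0

OELKind = Literal["eight_hour", "short_term", "ceiling"]
Unit = Literal["mg_per_m3", "ppm", "fibers_per_cm3"]

OEL_KINDS: tuple[str, ...] = ("eight_hour", "short_term", "ceiling")
UNITS: tuple[str, ...] = ("mg_per_m3", "ppm", "fibers_per_cm3")

#: Fallback precedence when no 8 h OEL exists: ceiling, then short-term.
#: Conservative screening beats refusing the analysis; every fallback is
#: reported as a machine-readable warning so the choice stays auditable.
OEL_PRECEDENCE: tuple[str, ...] = ("eight_hour", "ceiling", "short_term")

UNIT_SYMBOLS = {"mg_per_m3": "mg/m3", "ppm": "ppm", "fibers_per_cm3": "f/cm3"}


class HazmixError(Exception):
    """Base class for all errors raised by this package."""


class DatabaseError(HazmixError):
    """Malformed or invalid substance database, or unresolvable CAS."""


class ScenarioError(HazmixError):
    """Malformed or invalid mixture scenario."""


class UnitConversionError(HazmixError):
    """Concentration units cannot be reconciled (e.g. missing molecular weight)."""


class NoUsableOELError(HazmixError):
    """Substance carries no OEL of any kind."""


# --------------------------------------------------------------------------
# Taxonomy: the 24 toxicological classes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ToxClass:
    """One toxicological class: a target organ or mode of action.

    ``additive=False`` marks an *alert class*: additivity is not applicable
    (carcinogens, sensitizers, endocrine disrupters, reproductive and
    developmental toxicants) and any exposure triggers a warning instead of
    a Hazard Index.
    """

    class_id: str
    name: str
    additive: bool
    effects: tuple[str, ...]


@dataclass(frozen=True)
class ToxClassRegistry:
    """The fixed, ordered collection of toxicological classes."""

    classes: tuple[ToxClass, ...]

    def __post_init__(self) -> None:
        ids = [c.class_id for c in self.classes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate class_id in registry")
        object.__setattr__(self, "_by_id", {c.class_id: c for c in self.classes})

    def __iter__(self):
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self._by_id  # type: ignore[attr-defined]

    def __getitem__(self, class_id: str) -> ToxClass:
        try:
            return self._by_id[class_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown toxicological class: {class_id!r}") from None

    @property
    def class_ids(self) -> tuple[str, ...]:
        return tuple(c.class_id for c in self.classes)

    @property
    def alert_class_ids(self) -> tuple[str, ...]:
        return tuple(c.class_id for c in self.classes if not c.additive)

    @property
    def additive_class_ids(self) -> tuple[str, ...]:
        return tuple(c.class_id for c in self.classes if c.additive)


# (class_id, display name, additive, effects).  The six non-additive entries
# are the alert classes.  "Stimulation of basal metabolism" genuinely lists
# no associated effects and is kept as an empty-effects class.
_BUILTIN_TAXONOMY: tuple[tuple[str, str, bool, tuple[str, ...]], ...] = (
    ("ocular_damage", "Ocular damage", True,
     ("Cataract", "Eye irritation", "Corneal edema", "Corneal necrosis")),
    ("cardiovascular_damage", "Cardiovascular damage", True,
     ("Cardiac damage", "Vascular system impairment", "Vasoconstriction",
      "Vasodilatation", "Other cardiovascular damage")),
    ("upper_airway_damage", "Upper airway damage", True,
     ("Upper airway irritation", "Perforation of the nasal septum",
      "Other upper airway damage")),
    ("autonomic_nervous_system_damage", "Autonomic nervous system damage", True,
     ("Cholinesterase inhibition", "Muscular stimulation",
      "Other autonomic nervous system damage")),
    ("lower_airway_damage", "Lower airway damage", True,
     ("Berylliosis", "Bronchitis", "Bronchopneumonia", "Pulmonary emphysema",
      "Pulmonary fibrosis", "Brazier's disease", "Lower airway irritation",
      "Pulmonary edema", "Pneumoconiosis", "Other lower airway damage")),
    ("disruption_of_oxygen_transport", "Disruption of oxygen transport", True,
     ("Anemia", "Asphyxia", "Carboxyhemoglobinemia",
      "Blood-forming system disorder", "Hemolysis",
      "Cytochrome oxidase inhibition", "Heme synthesis inhibition",
      "Methemoglobinemia")),
    ("central_nervous_system_damage", "Central nervous system damage", True,
     ("Central nervous system convulsion", "Central nervous system depression",
      "Other central nervous system damage")),
    ("peripheral_nervous_system_damage", "Peripheral nervous system damage", True,
     ("Peripheral neuropathy", "Other peripheral nervous system damage")),
    ("hematopoietic_system_disruption", "Hematopoietic system disruption", True,
     ("Agranulocytosis", "Anemia", "Medullar aplasia", "Leukopenia",
      "Neutropenia", "Pancytopenia", "Thrombocytosis", "Thrombopenia",
      "Blood coagulation disorder")),
    ("ototoxicity", "Ototoxicity", True,
     ("Cochlear damage", "Auditory nerve damage", "Vestibular damage",
      "Hyperacusis")),
    ("metabolic_acidosis", "Metabolic acidosis", True,
     ("Metabolic acidosis",)),
    ("stimulation_of_basal_metabolism", "Stimulation of basal metabolism", True,
     ()),
    ("dental_or_bone_damage", "Dental or bone damage", True,
     ("Bone damage", "Skeletal fluorosis", "Dental erosion",
      "Other dental or bone damage")),
    ("skin_damage", "Skin damage", True,
     ("Alopecia", "Chloracne", "Skin irritation",
      "Other skin damage (except sensitization)")),
    ("endocrine_disrupter", "Endocrine disrupter", False,
     ("Antithyroid effect", "Other endocrine disrupter effect")),
    ("male_reproductive_system_damage", "Male reproductive system damage", False,
     ("Testicular damage", "Impairment of male fertility",
      "Other male reproductive system damage")),
    ("immune_system_damage", "Immune system damage", True,
     ("Immune system damage",)),
    ("female_reproductive_system_damage", "Female reproductive system damage", False,
     ("Ovarian damage", "Impairment of female fertility",
      "Other female reproductive system damage")),
    ("hepatic_damage", "Hepatic damage", True,
     ("Liver necrosis", "Other hepatic damage")),
    ("spleen_damage", "Spleen damage", True,
     ("Spleen damage",)),
    ("developmental_damage", "Developmental damage", False,
     ("Embryonic damage", "Fetal damage", "Teratogenic effect",
      "Effect on offspring", "Mutagenic effect on germ cells",
      "Effect on offspring behavior", "Other developmental damage")),
    ("carcinogenicity_mutagenicity", "Carcinogenicity and/or mutagenicity", False,
     ("Bladder cancer", "Blood vessel cancer", "Laryngeal cancer", "Leukemia",
      "Liver cancer", "Lung cancer", "Mesothelioma", "Nasal cancer",
      "Nasopharyngeal cancer", "Prostate cancer", "Renal cancer",
      "Stomach cancer", "Sinonasal cancer", "Skin cancer", "Testicular cancer",
      "Upper respiratory tract cancer", "Mutagenic effect")),
    ("kidney_damage", "Kidney damage", True,
     ("Glomerular damage", "Tubular damage", "Bladder damage",
      "Other kidney damage")),
    ("sensitization", "Sensitization (skin or respiratory)", False,
     ("Asthma", "Respiratory sensitization", "Contact dermatitis",
      "Skin sensitization")),
)

_REGISTRY_SINGLETON: Optional[ToxClassRegistry] = None


def load_builtin_taxonomy() -> ToxClassRegistry:
    """Return the built-in registry of 24 toxicological classes.

    The registry is embedded in the package and identical across calls.
    Six classes are non-additive alert classes: endocrine disrupter, male
    and female reproductive system damage, developmental damage,
    carcinogenicity and/or mutagenicity, and sensitization.
    """
    global _REGISTRY_SINGLETON
    if _REGISTRY_SINGLETON is None:
        _REGISTRY_SINGLETON = ToxClassRegistry(
            tuple(ToxClass(cid, name, additive, effects)
                  for cid, name, additive, effects in _BUILTIN_TAXONOMY)
        )
    return _REGISTRY_SINGLETON


# --------------------------------------------------------------------------
# Substance database model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OELValue:
    """One occupational exposure limit: kind, magnitude, and explicit unit.

    ``eight_hour`` is the full-shift limit (VLEP-8h in France, VEMP in
    Quebec); ``short_term`` is the 15 min limit; ``ceiling`` must never be
    exceeded.  The unit is always recorded, never implied.
    """

    kind: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.kind not in OEL_KINDS:
            raise ValueError(f"unknown OEL kind: {self.kind!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown concentration unit: {self.unit!r}")
        if not (self.value > 0):
            raise ValueError(f"OEL value must be strictly positive, got {self.value}")


@dataclass(frozen=True)
class SelectedOEL:
    """Result of OEL selection: the limit used plus an optional fallback warning."""

    oel: OELValue
    fallback_warning: Optional[str] = None


@dataclass(frozen=True)
class Substance:
    """A chemical with its identifiers, OEL set, and toxicological class links.

    ``synthetic=True`` flags generated fixture entries whose CAS-shaped
    identifier is not claimed to exist in the real registry (the check
    digit is still valid).  ``evidence_notes`` is free-text provenance
    metadata (e.g. effects observed in humans within 5x the OEL, or in
    animals within 100x) and plays no computational role.
    """

    cas: str
    name: str
    oels: Mapping[str, OELValue] = field(default_factory=dict)
    class_ids: frozenset[str] = field(default_factory=frozenset)
    molecular_weight: Optional[float] = None
    synthetic: bool = False
    evidence_notes: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "oels", dict(self.oels))
        object.__setattr__(self, "class_ids", frozenset(self.class_ids))
        for kind, oel in self.oels.items():
            if oel.kind != kind:
                raise ValueError(
                    f"{self.cas}: OEL keyed {kind!r} has kind {oel.kind!r}")
        if self.molecular_weight is not None and not (self.molecular_weight > 0):
            raise ValueError(f"{self.cas}: molecular weight must be positive")


@dataclass
class SubstanceDatabase:
    """A jurisdiction's substance/OEL corpus, keyed by CAS number."""

    jurisdiction: str
    oel_name: str
    substances: dict[str, Substance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cas, s in self.substances.items():
            if s.cas != cas:
                raise DatabaseError(f"substance keyed {cas!r} carries cas {s.cas!r}")
        if not self.jurisdiction:
            raise DatabaseError("jurisdiction must be non-empty")

    def __len__(self) -> int:
        return len(self.substances)

    def __contains__(self, cas: str) -> bool:
        return cas in self.substances

    def __getitem__(self, cas: str) -> Substance:
        try:
            return self.substances[cas]
        except KeyError:
            raise DatabaseError(f"unknown CAS number: {cas!r}") from None


_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number's format and modulo-10 check digit.

    Format is 2-7 digits, 2 digits, 1 check digit, hyphen-separated.  The
    check digit equals the sum of the other digits weighted 1..n from the
    rightmost non-check digit, modulo 10.  Malformed strings return False.
    """
    if not isinstance(cas, str):
        return False
    m = _CAS_RE.match(cas)
    if not m:
        return False
    body = m.group(1) + m.group(2)
    check = int(m.group(3))
    total = sum(w * int(d) for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


def select_oel(substance: Substance) -> SelectedOEL:
    """Pick the OEL to use for Hazard Index calculation.

    The 8 h full-shift OEL is always chosen when available.  Otherwise the
    ceiling value, then the short-term value, is used — each with a
    machine-readable ``oel_fallback:`` warning, since a screening ratio
    against a non-shift-average limit is conservative but not equivalent.

    Raises :class:`NoUsableOELError` when the substance lists no OEL.
    """
    for kind in OEL_PRECEDENCE:
        oel = substance.oels.get(kind)
        if oel is not None:
            warning = None
            if kind != "eight_hour":
                warning = (f"oel_fallback:{substance.cas}:{kind}:"
                           "no 8 h OEL listed; using "
                           f"{kind.replace('_', '-')} value")
            return SelectedOEL(oel=oel, fallback_warning=warning)
    raise NoUsableOELError(f"{substance.cas} ({substance.name}): no usable OEL")


def convert_concentration(
    value: float,
    from_unit: str,
    to_unit: str,
    molecular_weight: Optional[float] = None,
    *,
    substance: str = "",
) -> float:
    """Convert a concentration between ppm and mg/m3.

    Uses mg/m3 = ppm x MW / 24.45 (molar volume at 25 degC, 101.325 kPa).
    Identity when units are equal (any unit, including fibers/cm3).
    Converting between differing units requires the molecular weight;
    fibre counts cannot be converted to mass or volume units at all.
    """
    for u in (from_unit, to_unit):
        if u not in UNITS:
            raise UnitConversionError(f"unknown concentration unit: {u!r}")
    if from_unit == to_unit:
        return value
    who = f" for {substance}" if substance else ""
    if "fibers_per_cm3" in (from_unit, to_unit):
        raise UnitConversionError(
            f"cannot convert between {from_unit} and {to_unit}{who}")
    if molecular_weight is None:
        raise UnitConversionError(
            f"molecular weight required to convert {from_unit} to {to_unit}{who}")
    if from_unit == "ppm":  # -> mg/m3
        return value * molecular_weight / MOLAR_VOLUME_L_PER_MOL
    return value * MOLAR_VOLUME_L_PER_MOL / molecular_weight  # mg/m3 -> ppm


# --------------------------------------------------------------------------
# Database validation and I/O (JSON canonical; two-file CSV dialect)
# --------------------------------------------------------------------------


def validate_database(
    db: SubstanceDatabase,
    registry: Optional[ToxClassRegistry] = None,
) -> list[str]:
    """Run full validation; return a list of human-readable diagnostics.

    An empty list means the database is valid.  Checks: CAS check digits
    (skipped for entries flagged synthetic), class links resolving in the
    registry, OEL well-formedness (enforced at construction), and at most
    one OEL per kind (guaranteed by the mapping representation).
    """
    registry = registry or load_builtin_taxonomy()
    diagnostics: list[str] = []
    for cas in sorted(db.substances):
        s = db.substances[cas]
        if not s.synthetic and not validate_cas(cas):
            diagnostics.append(f"{cas}: invalid CAS number (check digit or format)")
        for cid in sorted(s.class_ids):
            if cid not in registry:
                diagnostics.append(f"{cas}: unknown class_id {cid!r}")
        if not s.name:
            diagnostics.append(f"{cas}: empty substance name")
    return diagnostics


def _substance_to_dict(s: Substance) -> dict:
    d: dict = {"cas": s.cas, "name": s.name}
    if s.molecular_weight is not None:
        d["molecular_weight"] = s.molecular_weight
    if s.synthetic:
        d["synthetic"] = True
    d["oels"] = {
        kind: {"value": oel.value, "unit": oel.unit}
        for kind, oel in sorted(s.oels.items())
    }
    d["class_ids"] = sorted(s.class_ids)
    if s.evidence_notes is not None:
        d["evidence_notes"] = s.evidence_notes
    return d


def _substance_from_dict(d: dict, where: str) -> Substance:
    if not isinstance(d, dict):
        raise DatabaseError(f"{where}: substance record must be an object")
    for key in ("cas", "name"):
        if key not in d:
            raise DatabaseError(f"{where}: substance record missing {key!r}")
    unknown = set(d) - {"cas", "name", "molecular_weight", "synthetic",
                        "oels", "class_ids", "evidence_notes"}
    if unknown:
        raise DatabaseError(f"{where}: unknown substance fields {sorted(unknown)}")
    oels = {}
    for kind, spec in (d.get("oels") or {}).items():
        if kind not in OEL_KINDS:
            raise DatabaseError(f"{where}: unknown OEL kind {kind!r}")
        try:
            oels[kind] = OELValue(kind=kind, value=float(spec["value"]),
                                  unit=spec["unit"])
        except (KeyError, TypeError, ValueError) as e:
            raise DatabaseError(f"{where}: bad OEL {kind!r}: {e}") from e
    try:
        return Substance(
            cas=str(d["cas"]),
            name=str(d["name"]),
            oels=oels,
            class_ids=frozenset(d.get("class_ids") or ()),
            molecular_weight=(float(d["molecular_weight"])
                              if d.get("molecular_weight") is not None else None),
            synthetic=bool(d.get("synthetic", False)),
            evidence_notes=d.get("evidence_notes"),
        )
    except ValueError as e:
        raise DatabaseError(f"{where}: {e}") from e


def _finalize_db(jurisdiction, oel_name, substances: list[Substance],
                 registry: Optional[ToxClassRegistry]) -> SubstanceDatabase:
    seen: dict[str, Substance] = {}
    for s in substances:
        if s.cas in seen:
            raise DatabaseError(f"duplicate CAS number: {s.cas}")
        seen[s.cas] = s
    db = SubstanceDatabase(jurisdiction=str(jurisdiction), oel_name=str(oel_name),
                           substances=seen)
    diagnostics = validate_database(db, registry)
    if diagnostics:
        raise DatabaseError("invalid substance database:\n  "
                            + "\n  ".join(diagnostics))
    return db


def parse_substance_db(
    path: Union[str, Path],
    format: Optional[str] = None,
    registry: Optional[ToxClassRegistry] = None,
) -> SubstanceDatabase:
    """Load and validate a substance database.

    ``format`` is ``"json"`` (canonical single file) or ``"csv"`` (a
    directory holding ``substances.csv`` and ``classes.csv``); when omitted
    it is inferred from the path (directories are CSV).  Raises
    :class:`DatabaseError` naming the offending record on any malformed
    content, unknown class link, or duplicate CAS.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "json"
    if format == "json":
        return _parse_db_json(path, registry)
    if format == "csv":
        return _parse_db_csv(path, registry)
    raise ValueError(f"unknown database format: {format!r}")


def _parse_db_json(path: Path, registry) -> SubstanceDatabase:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise DatabaseError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
    if not isinstance(doc, dict):
        raise DatabaseError(f"{path}: top level must be an object")
    for key in ("jurisdiction", "oel_name", "substances"):
        if key not in doc:
            raise DatabaseError(f"{path}: missing top-level key {key!r}")
    if not isinstance(doc["substances"], list):
        raise DatabaseError(f"{path}: 'substances' must be an array")
    substances = [
        _substance_from_dict(rec, f"{path} substances[{i}]")
        for i, rec in enumerate(doc["substances"])
    ]
    return _finalize_db(doc["jurisdiction"], doc["oel_name"], substances, registry)


_CSV_SUBSTANCE_HEADER = ["cas", "name", "molecular_weight", "synthetic",
                         "evidence_notes", "oel_kind", "oel_value", "oel_unit"]
_CSV_LINK_HEADER = ["cas", "class_id"]


def _read_csv_rows(path: Path, expected_header: list[str]):
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
            else:
                lines.append(line)
    reader = csv.reader(io.StringIO("".join(lines)))
    rows = list(reader)
    if not rows or rows[0] != expected_header:
        raise DatabaseError(
            f"{path}: expected header {','.join(expected_header)}")
    return meta, rows[1:]


def _parse_db_csv(dirpath: Path, registry) -> SubstanceDatabase:
    sub_path = dirpath / "substances.csv"
    link_path = dirpath / "classes.csv"
    for p in (sub_path, link_path):
        if not p.exists():
            raise DatabaseError(f"CSV database requires {p.name} in {dirpath}")
    meta, sub_rows = _read_csv_rows(sub_path, _CSV_SUBSTANCE_HEADER)
    _, link_rows = _read_csv_rows(link_path, _CSV_LINK_HEADER)
    for key in ("jurisdiction", "oel_name"):
        if key not in meta:
            raise DatabaseError(f"{sub_path}: missing '#{key}=' metadata line")

    links: dict[str, set[str]] = {}
    for i, row in enumerate(link_rows, start=2):
        if len(row) != 2:
            raise DatabaseError(f"{link_path}: line {i}: expected 2 fields")
        links.setdefault(row[0], set()).add(row[1])

    # One row per OEL; a substance without OELs has a single row with empty
    # oel_* fields.  Descriptive fields must agree across a substance's rows.
    by_cas: dict[str, dict] = {}
    for i, row in enumerate(sub_rows, start=2):
        if len(row) != len(_CSV_SUBSTANCE_HEADER):
            raise DatabaseError(
                f"{sub_path}: line {i}: expected "
                f"{len(_CSV_SUBSTANCE_HEADER)} fields, got {len(row)}")
        cas, name, mw, synthetic, notes, okind, oval, ounit = row
        desc = {
            "name": name,
            "molecular_weight": float(mw) if mw else None,
            "synthetic": synthetic == "true",
            "evidence_notes": notes or None,
        }
        entry = by_cas.setdefault(cas, {**desc, "oels": {}})
        if {k: entry[k] for k in desc} != desc:
            raise DatabaseError(
                f"{sub_path}: line {i}: conflicting descriptive fields for {cas}")
        if okind or oval or ounit:
            if okind in entry["oels"]:
                raise DatabaseError(
                    f"{sub_path}: line {i}: duplicate OEL kind {okind!r} for {cas}")
            try:
                entry["oels"][okind] = OELValue(kind=okind, value=float(oval),
                                                unit=ounit)
            except ValueError as e:
                raise DatabaseError(f"{sub_path}: line {i}: {e}") from e

    substances = [
        Substance(cas=cas, name=entry["name"], oels=entry["oels"],
                  class_ids=frozenset(links.pop(cas, set())),
                  molecular_weight=entry["molecular_weight"],
                  synthetic=entry["synthetic"],
                  evidence_notes=entry["evidence_notes"])
        for cas, entry in by_cas.items()
    ]
    if links:
        raise DatabaseError(
            f"{link_path}: class links for CAS not in substances.csv: "
            f"{sorted(links)}")
    return _finalize_db(meta["jurisdiction"], meta["oel_name"], substances, registry)


def write_substance_db(
    db: SubstanceDatabase,
    path: Union[str, Path],
    format: str = "json",
) -> None:
    """Write a database canonically: sorted keys, so output is byte-stable.

    JSON writes one file; CSV writes ``substances.csv`` and ``classes.csv``
    into the directory ``path`` (created if absent).  ``parse_substance_db``
    of the output reconstructs an equal database.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "jurisdiction": db.jurisdiction,
            "oel_name": db.oel_name,
            "substances": [_substance_to_dict(db.substances[cas])
                           for cas in sorted(db.substances)],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown database format: {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    sub_buf = io.StringIO()
    sub_buf.write(f"#jurisdiction={db.jurisdiction}\n#oel_name={db.oel_name}\n")
    sw = csv.writer(sub_buf, lineterminator="\n")
    sw.writerow(_CSV_SUBSTANCE_HEADER)
    link_buf = io.StringIO()
    lw = csv.writer(link_buf, lineterminator="\n")
    lw.writerow(_CSV_LINK_HEADER)
    for cas in sorted(db.substances):
        s = db.substances[cas]
        desc = [cas, s.name,
                repr(s.molecular_weight) if s.molecular_weight is not None else "",
                "true" if s.synthetic else "",
                s.evidence_notes or ""]
        if s.oels:
            for kind in sorted(s.oels):
                oel = s.oels[kind]
                sw.writerow(desc + [kind, repr(oel.value), oel.unit])
        else:
            sw.writerow(desc + ["", "", ""])
        for cid in sorted(s.class_ids):
            lw.writerow([cas, cid])
    (path / "substances.csv").write_text(sub_buf.getvalue(), encoding="utf-8")
    (path / "classes.csv").write_text(link_buf.getvalue(), encoding="utf-8")


# --------------------------------------------------------------------------
# Mixture scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureRecord:
    """One substance in a work situation, with an optional measured concentration."""

    cas: str
    concentration: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.concentration is not None:
            if self.unit is None:
                raise ScenarioError(
                    f"{self.cas}: concentration given without a unit")
            if self.unit not in UNITS:
                raise ScenarioError(f"{self.cas}: unknown unit {self.unit!r}")
            if self.concentration < 0:
                raise ScenarioError(
                    f"{self.cas}: concentration must be >= 0")


@dataclass(frozen=True)
class MixtureScenario:
    """The substances a worker is co-exposed to.

    ``quantitative`` mode carries measured atmospheric concentrations and
    yields Hazard Indexes; ``qualitative`` mode has no concentrations and
    yields class activation and sharing only.
    """

    records: tuple[ExposureRecord, ...]
    mode: str = "quantitative"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.mode not in ("quantitative", "qualitative"):
            raise ScenarioError(f"unknown scenario mode: {self.mode!r}")
        if not self.records:
            raise ScenarioError("scenario must contain at least one substance")
        cas_values = [r.cas for r in self.records]
        dupes = sorted({c for c in cas_values if cas_values.count(c) > 1})
        if dupes:
            raise ScenarioError(f"duplicate CAS in scenario: {dupes}")

    @property
    def cas_list(self) -> tuple[str, ...]:
        return tuple(r.cas for r in self.records)


def parse_scenario(
    path: Union[str, Path],
    format: Optional[str] = None,
    mode: Optional[str] = None,
) -> MixtureScenario:
    """Load a scenario from CSV (``cas,concentration,unit``) or JSON.

    The mode is inferred — quantitative when every record carries a
    concentration, qualitative otherwise — unless ``mode`` overrides it.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    records: list[ExposureRecord] = []
    if format == "json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise ScenarioError(
                f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
        recs = doc.get("records") if isinstance(doc, dict) else doc
        if not isinstance(recs, list):
            raise ScenarioError(f"{path}: expected a list of exposure records")
        for i, rec in enumerate(recs):
            try:
                records.append(ExposureRecord(
                    cas=str(rec["cas"]),
                    concentration=(float(rec["concentration"])
                                   if rec.get("concentration") is not None else None),
                    unit=rec.get("unit")))
            except (KeyError, TypeError, ValueError) as e:
                raise ScenarioError(f"{path} records[{i}]: {e}") from e
        if mode is None and isinstance(doc, dict):
            mode = doc.get("mode")
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows or rows[0][:1] != ["cas"]:
            raise ScenarioError(f"{path}: expected header starting with 'cas'")
        for i, row in enumerate(rows[1:], start=2):
            row = row + [""] * (3 - len(row))
            cas, conc, unit = row[0], row[1], row[2]
            try:
                records.append(ExposureRecord(
                    cas=cas,
                    concentration=float(conc) if conc else None,
                    unit=unit or None))
            except ValueError as e:
                raise ScenarioError(f"{path}: line {i}: {e}") from e
    else:
        raise ValueError(f"unknown scenario format: {format!r}")
    if mode is None:
        mode = ("quantitative"
                if records and all(r.concentration is not None for r in records)
                else "qualitative")
    return MixtureScenario(records=tuple(records), mode=mode)


# --------------------------------------------------------------------------
# Mixture engine
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Contribution:
    """One substance's exposure ratio, 100 * C/OEL, within a class.

    The ratio is a property of the substance alone (same OEL for every
    class it activates), so it is identical across classes.
    """

    cas: str
    ratio_percent: float
    oel_used: OELValue
    fallback_warning: Optional[str] = None


@dataclass(frozen=True)
class ClassHIResult:
    """Per-class quantitative result.

    For additive classes ``hi_percent`` is the Hazard Index (sum of the
    contributions' ratios) and ``risky`` is True iff it strictly exceeds
    100%.  For alert classes additivity is suppressed: ``hi_percent`` is
    None (rendered "N.A."), contributions are empty, and ``risky`` is never
    derived from an index.
    """

    class_id: str
    additive: bool
    hi_percent: Optional[float]
    contributions: tuple[Contribution, ...]
    cas_list: tuple[str, ...]
    risky: bool


@dataclass(frozen=True)
class QualitativeClassResult:
    """Per-class qualitative result: which and how many substances activate it."""

    class_id: str
    additive: bool
    substance_count: int
    cas_list: tuple[str, ...]
    shared: bool


@dataclass(frozen=True)
class AlertFinding:
    """A warning message attached to the report.

    Non-informational findings correspond to activated alert (non-additive)
    classes.  The single informational finding mirrors the combined
    "CMR and/or ototoxic" banner: ototoxicity is additive and keeps its
    Hazard Index, but noise co-exposure makes its mere presence worth
    flagging.
    """

    class_id: str
    cas_list: tuple[str, ...]
    message_key: str
    informational: bool = False


ALERT_MESSAGE_KEYS: dict[str, str] = {
    "carcinogenicity_mutagenicity": "cmr_present",
    "sensitization": "sensitizer_present",
    "developmental_damage": "developmental_toxicant_present",
    "endocrine_disrupter": "endocrine_disrupter_present",
    "male_reproductive_system_damage": "male_reprotoxicant_present",
    "female_reproductive_system_damage": "female_reprotoxicant_present",
}

#: Display text per message key (the extension point for other languages).
ALERT_MESSAGES: dict[str, str] = {
    "cmr_present": ("Carcinogenic and/or mutagenic substance(s) present. "
                    "Additivity is not applicable: minimize exposure "
                    "regardless of measured levels."),
    "sensitizer_present": ("Sensitizing substance(s) present (skin or "
                           "respiratory). Additivity is not applicable."),
    "developmental_toxicant_present": (
        "Substance(s) presenting a risk to the development of the foetus, "
        "embryo and/or child present. Additivity is not applicable."),
    "endocrine_disrupter_present": ("Endocrine-disrupting substance(s) "
                                    "present. Additivity is not applicable."),
    "male_reprotoxicant_present": ("Substance(s) toxic to the male "
                                   "reproductive system present. Additivity "
                                   "is not applicable."),
    "female_reprotoxicant_present": ("Substance(s) toxic to the female "
                                     "reproductive system present. Additivity "
                                     "is not applicable."),
    "ototoxicant_present": ("Ototoxic substance(s) present: combined "
                            "exposure with noise may aggravate hearing "
                            "damage (informational)."),
}


@dataclass(frozen=True)
class AnalysisReport:
    """Ranked analysis of a work situation.

    ``class_results`` holds :class:`ClassHIResult` (quantitative) or
    :class:`QualitativeClassResult` (qualitative) entries, alert classes
    first, then additive classes by decreasing Hazard Index or substance
    count, ties broken alphabetically by class id.  ``any_risk`` is True
    iff some additive class has HI > 100% (quantitative mode only);
    activated alert classes are reported separately in ``alert_findings``
    rather than folded into a composite flag.
    """

    mode: str
    scenario: MixtureScenario
    alert_findings: tuple[AlertFinding, ...]
    class_results: tuple[Union[ClassHIResult, QualitativeClassResult], ...]
    warnings: tuple[str, ...]
    any_risk: bool


def exposure_ratio(record: ExposureRecord, substance: Substance) -> Contribution:
    """Compute 100 * C/OEL for one substance, reconciling units.

    The concentration is converted to the unit of the selected OEL when
    they differ (via the molecular weight); the ratio is dimensionless so
    the result does not depend on which side is converted.
    """
    if record.concentration is None:
        raise ScenarioError(f"{record.cas}: no concentration to form a ratio")
    selected = select_oel(substance)
    oel = selected.oel
    conc = convert_concentration(record.concentration, record.unit, oel.unit,
                                 substance.molecular_weight,
                                 substance=f"{substance.cas} ({substance.name})")
    return Contribution(
        cas=record.cas,
        ratio_percent=100.0 * conc / oel.value,
        oel_used=oel,
        fallback_warning=selected.fallback_warning,
    )


def _resolve(scenario: MixtureScenario, db: SubstanceDatabase) -> list[Substance]:
    unknown = sorted(c for c in scenario.cas_list if c not in db)
    if unknown:
        raise DatabaseError(f"scenario CAS not in database: {unknown}")
    return [db.substances[r.cas] for r in scenario.records]


def compute_class_hi(
    scenario: MixtureScenario,
    class_id: str,
    db: SubstanceDatabase,
    registry: Optional[ToxClassRegistry] = None,
) -> ClassHIResult:
    """Hazard Index of one additive class for a quantitative scenario.

    Sums 100 * C/OEL over the scenario substances that activate the class;
    substances not activating it contribute nothing.  Raises
    :class:`HazmixError` for an alert class (additivity suppressed), a
    non-quantitative scenario, or a class no scenario substance activates.
    """
    registry = registry or load_builtin_taxonomy()
    toxclass = registry[class_id]
    if not toxclass.additive:
        raise HazmixError(
            f"{class_id} is an alert class: the Hazard Index is not applicable")
    if scenario.mode != "quantitative":
        raise ScenarioError("Hazard Index requires a quantitative scenario")
    substances = _resolve(scenario, db)
    contribs = [
        exposure_ratio(record, substance)
        for record, substance in zip(scenario.records, substances)
        if class_id in substance.class_ids
    ]
    if not contribs:
        raise HazmixError(f"no scenario substance activates {class_id}")
    contribs.sort(key=lambda c: (-c.ratio_percent, c.cas))
    hi = math.fsum(c.ratio_percent for c in contribs)
    return ClassHIResult(
        class_id=class_id,
        additive=True,
        hi_percent=hi,
        contributions=tuple(contribs),
        cas_list=tuple(c.cas for c in contribs),
        risky=hi > RISK_THRESHOLD_PERCENT,
    )


def detect_alerts(
    scenario: MixtureScenario,
    db: SubstanceDatabase,
    registry: Optional[ToxClassRegistry] = None,
) -> list[AlertFinding]:
    """Find activated alert classes, plus the ototoxicity informational note.

    Works identically in both modes — alert detection needs no
    concentrations.  One finding per non-additive class activated by at
    least one scenario substance, listing the activating CAS numbers in
    scenario order; ototoxicity (an additive class) additionally yields an
    informational finding when activated, mirroring the combined
    "CMR and/or ototoxic" warning banner.
    """
    registry = registry or load_builtin_taxonomy()
    substances = _resolve(scenario, db)
    findings: list[AlertFinding] = []
    for toxclass in registry:
        if toxclass.additive and toxclass.class_id != "ototoxicity":
            continue
        activating = tuple(s.cas for s in substances
                           if toxclass.class_id in s.class_ids)
        if not activating:
            continue
        if toxclass.additive:
            findings.append(AlertFinding(
                class_id=toxclass.class_id, cas_list=activating,
                message_key="ototoxicant_present", informational=True))
        else:
            findings.append(AlertFinding(
                class_id=toxclass.class_id, cas_list=activating,
                message_key=ALERT_MESSAGE_KEYS[toxclass.class_id]))
    findings.sort(key=lambda f: (f.informational, f.class_id))
    return findings


def rank_results(
    results: Iterable[Union[ClassHIResult, QualitativeClassResult]],
) -> list[Union[ClassHIResult, QualitativeClassResult]]:
    """Order class results for display.

    Alert classes come first (additivity not calculated, shown as N.A.),
    then additive classes in decreasing order of Hazard Index
    (quantitative) or substance count (qualitative); ties break
    alphabetically by class id.  Alert classes rank among themselves by
    number of activating substances.
    """
    def key(r):
        if isinstance(r, QualitativeClassResult):
            magnitude = float(r.substance_count)
        else:
            magnitude = (r.hi_percent if r.hi_percent is not None
                         else float(len(r.cas_list)))
        return (r.additive, -magnitude, r.class_id)

    return sorted(results, key=key)


def _activation_map(
    substances: Sequence[Substance],
    registry: ToxClassRegistry,
) -> dict[str, list[str]]:
    """class_id -> activating CAS numbers (scenario order), activated classes only."""
    activation: dict[str, list[str]] = {}
    for s in substances:
        for cid in s.class_ids:
            activation.setdefault(cid, []).append(s.cas)
    # deterministic: registry declaration order, scenario order within
    return {cid: activation[cid] for cid in registry.class_ids if cid in activation}


def analyze_quantitative(
    scenario: MixtureScenario,
    db: SubstanceDatabase,
    registry: Optional[ToxClassRegistry] = None,
    *,
    allow_missing: bool = False,
) -> AnalysisReport:
    """Full quantitative analysis of a work situation.

    Produces alert findings, a Hazard Index for every additive class
    activated by at least one substance (classes nobody activates are
    omitted, not printed as 0% rows), alert classes listed first with a
    not-applicable index, and warnings for every OEL fallback and every
    substance excluded from the sums.

    Substances with no usable OEL are excluded from all Hazard Index sums
    with a warning but still count for class activation and alert
    findings — the qualitative information remains valid.  Missing
    concentrations are a hard error unless ``allow_missing`` is set, in
    which case the offending substances are dropped to warnings and every
    index is a lower bound.
    """
    if scenario.mode != "quantitative":
        raise ScenarioError("analyze_quantitative requires a quantitative scenario")
    registry = registry or load_builtin_taxonomy()
    substances = _resolve(scenario, db)
    warnings: list[str] = []

    missing = [r.cas for r in scenario.records if r.concentration is None]
    if missing and not allow_missing:
        raise ScenarioError(
            f"quantitative scenario lacks concentrations for: {missing} "
            "(pass allow_missing to drop them with a warning)")
    for cas in missing:
        warnings.append(f"missing_concentration:{cas}:"
                        "dropped from Hazard Index sums; indexes are lower bounds")

    # One contribution per substance; identical across the classes it activates.
    contribution_by_cas: dict[str, Contribution] = {}
    for record, substance in zip(scenario.records, substances):
        if record.concentration is None:
            continue
        try:
            contrib = exposure_ratio(record, substance)
        except NoUsableOELError:
            warnings.append(
                f"excluded_no_oel:{record.cas}:no usable OEL; excluded from "
                "Hazard Index sums (still considered for class activation "
                "and alerts)")
            continue
        if contrib.fallback_warning:
            warnings.append(contrib.fallback_warning)
        contribution_by_cas[record.cas] = contrib

    activation = _activation_map(substances, registry)
    results: list[ClassHIResult] = []
    for class_id, cas_list in activation.items():
        if registry[class_id].additive:
            # excluded substances (no OEL / dropped concentration) still
            # count as activating the class; the index sums what is known
            contribs = sorted(
                (contribution_by_cas[cas] for cas in cas_list
                 if cas in contribution_by_cas),
                key=lambda c: (-c.ratio_percent, c.cas))
            hi = math.fsum(c.ratio_percent for c in contribs)
            ordered = tuple(c.cas for c in contribs) + tuple(
                cas for cas in cas_list if cas not in contribution_by_cas)
            results.append(ClassHIResult(
                class_id=class_id, additive=True, hi_percent=hi,
                contributions=tuple(contribs), cas_list=ordered,
                risky=hi > RISK_THRESHOLD_PERCENT))
        else:
            results.append(ClassHIResult(
                class_id=class_id, additive=False, hi_percent=None,
                contributions=(), cas_list=tuple(cas_list), risky=False))

    ranked = tuple(rank_results(results))
    return AnalysisReport(
        mode="quantitative",
        scenario=scenario,
        alert_findings=tuple(detect_alerts(scenario, db, registry)),
        class_results=ranked,
        warnings=tuple(warnings),
        any_risk=any(r.risky for r in ranked),
    )


def analyze_qualitative(
    scenario: MixtureScenario,
    db: SubstanceDatabase,
    registry: Optional[ToxClassRegistry] = None,
) -> AnalysisReport:
    """Qualitative analysis: class activation and sharing, no concentrations.

    Every class activated by at least one substance appears with its
    substance count; classes shared by two or more substances are flagged,
    on the principle that the risk to an organ grows with the number of
    substances attacking it.  Concentrations, if present, are ignored.
    """
    registry = registry or load_builtin_taxonomy()
    substances = _resolve(scenario, db)
    activation = _activation_map(substances, registry)
    results = [
        QualitativeClassResult(
            class_id=class_id,
            additive=registry[class_id].additive,
            substance_count=len(cas_list),
            cas_list=tuple(cas_list),
            shared=len(cas_list) >= 2)
        for class_id, cas_list in activation.items()
    ]
    return AnalysisReport(
        mode="qualitative",
        scenario=replace(scenario, mode="qualitative"),
        alert_findings=tuple(detect_alerts(scenario, db, registry)),
        class_results=tuple(rank_results(results)),
        warnings=(),
        any_risk=False,
    )


# --------------------------------------------------------------------------
# Report rendering
# --------------------------------------------------------------------------

_REPORT_SCHEMA_VERSION = 1


def report_to_dict(report: AnalysisReport) -> dict:
    """Serialize a report to plain JSON-compatible types, full precision."""
    def contribution(c: Contribution) -> dict:
        return {"cas": c.cas, "ratio_percent": c.ratio_percent,
                "oel_used": {"kind": c.oel_used.kind, "value": c.oel_used.value,
                             "unit": c.oel_used.unit},
                "fallback_warning": c.fallback_warning}

    def result(r) -> dict:
        if isinstance(r, ClassHIResult):
            return {"kind": "hi", "class_id": r.class_id, "additive": r.additive,
                    "hi_percent": r.hi_percent,
                    "contributions": [contribution(c) for c in r.contributions],
                    "cas_list": list(r.cas_list), "risky": r.risky}
        return {"kind": "qualitative", "class_id": r.class_id,
                "additive": r.additive, "substance_count": r.substance_count,
                "cas_list": list(r.cas_list), "shared": r.shared}

    return {
        "schema_version": _REPORT_SCHEMA_VERSION,
        "mode": report.mode,
        "scenario": {
            "mode": report.scenario.mode,
            "records": [{"cas": r.cas, "concentration": r.concentration,
                         "unit": r.unit} for r in report.scenario.records],
        },
        "alert_findings": [
            {"class_id": f.class_id, "cas_list": list(f.cas_list),
             "message_key": f.message_key, "informational": f.informational}
            for f in report.alert_findings],
        "class_results": [result(r) for r in report.class_results],
        "warnings": list(report.warnings),
        "any_risk": report.any_risk,
    }


def report_from_dict(doc: dict) -> AnalysisReport:
    """Reconstruct an :class:`AnalysisReport` from its JSON form."""
    def result(d):
        if d["kind"] == "hi":
            return ClassHIResult(
                class_id=d["class_id"], additive=d["additive"],
                hi_percent=d["hi_percent"],
                contributions=tuple(
                    Contribution(cas=c["cas"], ratio_percent=c["ratio_percent"],
                                 oel_used=OELValue(**c["oel_used"]),
                                 fallback_warning=c["fallback_warning"])
                    for c in d["contributions"]),
                cas_list=tuple(d["cas_list"]), risky=d["risky"])
        return QualitativeClassResult(
            class_id=d["class_id"], additive=d["additive"],
            substance_count=d["substance_count"],
            cas_list=tuple(d["cas_list"]), shared=d["shared"])

    scenario = MixtureScenario(
        records=tuple(ExposureRecord(**r) for r in doc["scenario"]["records"]),
        mode=doc["scenario"]["mode"])
    return AnalysisReport(
        mode=doc["mode"],
        scenario=scenario,
        alert_findings=tuple(AlertFinding(
            class_id=f["class_id"], cas_list=tuple(f["cas_list"]),
            message_key=f["message_key"], informational=f["informational"])
            for f in doc["alert_findings"]),
        class_results=tuple(result(r) for r in doc["class_results"]),
        warnings=tuple(doc["warnings"]),
        any_risk=doc["any_risk"],
    )


def report_from_json(text: str) -> AnalysisReport:
    return report_from_dict(json.loads(text))


def render_report(
    report: AnalysisReport,
    format: str = "text",
    registry: Optional[ToxClassRegistry] = None,
) -> str:
    """Render a report as a deterministic plain-text table or as JSON.

    Text format: alert messages first, then the ranked class table with
    Hazard Indexes to one decimal, "N.A." for alert classes, and risky
    rows (HI > 100%) marked.  JSON carries full precision and round-trips
    through :func:`report_from_json`.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    if format != "text":
        raise ValueError(f"unknown report format: {format!r}")
    registry = registry or load_builtin_taxonomy()
    lines: list[str] = []
    n = len(report.scenario.records)
    lines.append(f"Mixture analysis ({report.mode} mode, {n} substances)")
    lines.append("=" * lines[0].__len__())
    if report.alert_findings:
        lines.append("")
        lines.append("Alerts:")
        for f in report.alert_findings:
            text = ALERT_MESSAGES.get(f.message_key, f.message_key)
            lines.append(f"  [{f.message_key}] {text}")
            lines.append(f"      substances: {', '.join(f.cas_list)}")
    if report.warnings:
        lines.append("")
        lines.append("Warnings:")
        for w in report.warnings:
            lines.append(f"  - {w}")
    lines.append("")
    if report.mode == "quantitative":
        lines.append(f"{'Toxicological class':40s} {'HI %':>10s}  Substances")
        for r in report.class_results:
            name = registry[r.class_id].name if r.class_id in registry else r.class_id
            if r.hi_percent is None:
                hi_cell, marker = "N.A.", ""
            else:
                hi_cell = f"{r.hi_percent:.1f}"
                marker = "  ** >100%" if r.risky else ""
            lines.append(f"{name:40s} {hi_cell:>10s}  "
                         f"{', '.join(r.cas_list)}{marker}")
        lines.append("")
        lines.append("Multiple-exposure risk (any HI > 100%): "
                     + ("YES" if report.any_risk else "no"))
    else:
        lines.append(f"{'Toxicological class':40s} {'HI %':>10s} "
                     f"{'n':>3s}  Substances")
        for r in report.class_results:
            name = registry[r.class_id].name if r.class_id in registry else r.class_id
            # indexes and per-substance ratios are not calculated without
            # concentrations: ">0%" for additive classes, "N.A." for alerts
            hi_cell = ">0%" if r.additive else "N.A."
            marker = "  ** shared" if r.shared else ""
            lines.append(f"{name:40s} {hi_cell:>10s} {r.substance_count:>3d}  "
                         f"{', '.join(r.cas_list)}{marker}")
    lines.append("")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# Synthetic fixtures: stand-ins for the unpublished regulatory corpus
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for synthetic database generation.

    Defaults emulate the shape of a regulatory OEL corpus: most substances
    carry a full-shift OEL, activate a couple of additive classes, and
    only occasionally an alert class.  ``class_density`` /
    ``alert_density`` are per-class Bernoulli probabilities;
    ``oel_range`` gives [min, max] of the 8 h OEL per unit;
    ``concentration_regime`` is the uniform [lo, hi] range the scenario
    generator draws C/OEL targets from (spanning below and above the
    limit so risky and safe situations both occur).
    """

    n_substances: int = 30
    seed: int = 0
    class_density: float = 0.15
    alert_density: float = 0.05
    oel_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ppm": (1.0, 500.0), "mg_per_m3": (0.1, 100.0)})
    p_missing_oel: float = 0.05
    p_missing_mw: float = 0.10
    concentration_regime: tuple[float, float] = (0.0, 1.5)

    def __post_init__(self) -> None:
        for p in (self.class_density, self.alert_density,
                  self.p_missing_oel, self.p_missing_mw):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in self.oel_range.values():
            if not (0 < lo <= hi):
                raise ValueError("oel_range bounds must be positive and ordered")
        if self.n_substances < 1:
            raise ValueError("n_substances must be >= 1")


def _synthetic_cas(rng: random.Random, taken: set[str]) -> str:
    """A CAS-shaped identifier with a valid check digit, from a high range
    unlikely to collide with assigned registry numbers."""
    while True:
        body = f"{rng.randint(2_000_000, 9_999_999)}{rng.randint(10, 99)}"
        check = sum(w * int(d)
                    for w, d in enumerate(reversed(body), start=1)) % 10
        cas = f"{body[:7]}-{body[7:]}-{check}"
        if cas not in taken:
            taken.add(cas)
            return cas


def generate_substance_db(spec: GeneratorSpec) -> SubstanceDatabase:
    """Generate a valid synthetic substance database.

    Substances are flagged synthetic, carry CAS-shaped identifiers with
    correct check digits, and draw class memberships independently per
    class (``class_density`` for additive classes, ``alert_density`` for
    alert classes).  Output is reproducible: the same spec (including
    seed) yields an identical database.
    """
    rng = random.Random(spec.seed)
    registry = load_builtin_taxonomy()
    taken: set[str] = set()
    substances: dict[str, Substance] = {}
    for i in range(spec.n_substances):
        cas = _synthetic_cas(rng, taken)
        mw = None if rng.random() < spec.p_missing_mw else rng.uniform(20.0, 300.0)
        unit = rng.choice(sorted(spec.oel_range))
        lo, hi = spec.oel_range[unit]
        oels: dict[str, OELValue] = {}
        if rng.random() >= spec.p_missing_oel:
            value = rng.uniform(lo, hi)
            oels["eight_hour"] = OELValue("eight_hour", value, unit)
            if rng.random() < 0.30:
                oels["short_term"] = OELValue("short_term",
                                              value * rng.uniform(2.0, 4.0), unit)
            if rng.random() < 0.15:
                oels["ceiling"] = OELValue("ceiling",
                                           value * rng.uniform(3.0, 6.0), unit)
        else:
            # no full-shift limit: sometimes a ceiling or short-term value
            # remains (exercises the fallback path), sometimes nothing at all
            if rng.random() < 0.5:
                kind = rng.choice(["ceiling", "short_term"])
                oels[kind] = OELValue(kind, rng.uniform(lo, hi), unit)
        class_ids = set()
        for cid in registry.additive_class_ids:
            if rng.random() < spec.class_density:
                class_ids.add(cid)
        for cid in registry.alert_class_ids:
            if rng.random() < spec.alert_density:
                class_ids.add(cid)
        substances[cas] = Substance(
            cas=cas, name=f"Synthetic substance {i + 1:03d}", oels=oels,
            class_ids=frozenset(class_ids), molecular_weight=mw, synthetic=True)
    return SubstanceDatabase(jurisdiction="synthetic",
                             oel_name="synthetic 8 h OEL",
                             substances=substances)


def generate_scenario(
    db: SubstanceDatabase,
    n_selected: int,
    regime: Optional[tuple[float, float]] = None,
    seed: int = 0,
) -> MixtureScenario:
    """Draw a scenario from a database, without replacement.

    With a ``regime`` (lo, hi), each selected substance gets a
    concentration such that C/OEL is uniform on [lo, hi], expressed in the
    unit of its selected OEL (so only substances with a usable OEL are
    eligible).  Without a regime, a qualitative scenario with no
    concentrations is produced.  Reproducible under ``seed``.
    """
    rng = random.Random(seed)
    if n_selected > len(db):
        raise ValueError(
            f"cannot select {n_selected} substances from a database of {len(db)}")
    if regime is None:
        chosen = rng.sample(sorted(db.substances), n_selected)
        return MixtureScenario(
            records=tuple(ExposureRecord(cas=c) for c in chosen),
            mode="qualitative")
    eligible = sorted(cas for cas, s in db.substances.items() if s.oels)
    if n_selected > len(eligible):
        raise ValueError(
            f"only {len(eligible)} substances carry an OEL; cannot select "
            f"{n_selected} for a quantitative scenario")
    chosen = rng.sample(eligible, n_selected)
    lo, hi = regime
    records = []
    for cas in chosen:
        oel = select_oel(db.substances[cas]).oel
        ratio = rng.uniform(lo, hi)
        records.append(ExposureRecord(cas=cas, concentration=ratio * oel.value,
                                      unit=oel.unit))
    return MixtureScenario(records=tuple(records), mode="quantitative")


def case_study_fixture() -> tuple[SubstanceDatabase, MixtureScenario]:
    """A reconstructed four-solvent printing-workshop co-exposure.

    Industrial hygienists measuring maintenance operations in the printing
    industry find methyl ethyl ketone (MEK), methyl isobutyl ketone
    (MIBK), toluene and trichloroethylene together.  All four depress the
    central nervous system and irritate eyes and skin, and all four are
    ototoxic; MEK and toluene additionally threaten foetal development
    (alert class), while MIBK and trichloroethylene are possible
    carcinogens (alert class).

    The OELs and concentrations here are illustrative reconstructions —
    plausible magnitudes, not regulatory values.  Each substance sits at
    40% of its own limit, so single-substance screening sees no problem;
    the four shared additive classes each sum to a Hazard Index of 160%.
    """
    note = ("synthetic reconstruction: OEL and concentration values are "
            "illustrative, not regulatory")
    classes_all = frozenset({"central_nervous_system_damage", "ocular_damage",
                             "skin_damage", "ototoxicity"})
    spec = [
        # (cas, name, MW g/mol, 8h OEL ppm, extra alert class)
        ("78-93-3", "Methyl ethyl ketone (MEK)", 72.11, 200.0,
         "developmental_damage"),
        ("108-10-1", "Methyl isobutyl ketone (MIBK)", 100.16, 20.0,
         "carcinogenicity_mutagenicity"),
        ("108-88-3", "Toluene", 92.14, 20.0, "developmental_damage"),
        ("79-01-6", "Trichloroethylene", 131.39, 10.0,
         "carcinogenicity_mutagenicity"),
    ]
    substances = {
        cas: Substance(
            cas=cas, name=name,
            oels={"eight_hour": OELValue("eight_hour", oel, "ppm")},
            class_ids=classes_all | {alert},
            molecular_weight=mw, synthetic=False, evidence_notes=note)
        for cas, name, mw, oel, alert in spec
    }
    db = SubstanceDatabase(jurisdiction="synthetic",
                           oel_name="synthetic 8 h OEL", substances=substances)
    # every substance at 40% of its own OEL: no individual exceedance,
    # every shared additive class at HI = 4 x 40 = 160%
    scenario = MixtureScenario(
        records=tuple(ExposureRecord(cas=cas, concentration=0.4 * oel, unit="ppm")
                      for cas, _, _, oel, _ in spec),
        mode="quantitative")
    return db, scenario
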