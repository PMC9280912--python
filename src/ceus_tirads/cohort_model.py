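"""Domain types, validation and CSV I/O for thyroid-nodule cohorts.

A cohort is an ordered collection of per-nodule records.  Each record
carries patient covariates (age, sex, nodule size), the six conventional
ultrasound (US) features of the C-TIRADS counting method, the six
qualitative contrast-enhanced ultrasound (CEUS) features, and an optional
pathology label.  All enumerations are closed; enum tokens are
lower-snake-case and parsed case-insensitively.

CSV layout
----------
One header row, comma-separated, UTF-8.  Boolean cells are ``true``/``false``,
empty cells are absent optional values.  C-TIRADS categories are written in
clinical notation (``2``, ``3``, ``4a``, ``4b``, ``4c``, ``5``).  Column
names may be remapped through a *schema* dictionary (canonical name →
actual column name), e.g. loaded from a YAML config.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence, TextIO


class CohortError(Exception):
    """Base class for cohort parsing/validation failures."""


class ParseError(CohortError):
    """A cell could not be parsed; names the row and column."""

    def __init__(self, row: int, column: str, message: str):
        super().__init__(f"row {row}, column '{column}': {message}")
        self.row = row
        self.column = column


class SchemaError(CohortError):
    """A required column is missing from the header."""


class ValidationError(CohortError):
    """A structurally invalid record or cohort."""


class Pathology(enum.Enum):
    """Histopathological ground truth for a nodule."""

    BENIGN = "benign"
    MALIGNANT = "malignant"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class Category(enum.Enum):
    """Ordinal C-TIRADS / CEUS-TIRADS malignancy-risk category.

    The six levels 2 < 3 < 4a < 4b < 4c < 5 form a total order; ``rank``
    is the 0-based position on that scale, so category arithmetic
    (shifting one level up or down) is rank arithmetic.
    """

    C2 = "2"
    C3 = "3"
    C4A = "4a"
    C4B = "4b"
    C4C = "4c"
    C5 = "5"

    @property
    def rank(self) -> int:
        return _CATEGORY_ORDER.index(self)

    @classmethod
    def from_rank(cls, rank: int) -> "Category":
        if not 0 <= rank < len(_CATEGORY_ORDER):
            raise ValueError(f"category rank out of range: {rank}")
        return _CATEGORY_ORDER[rank]

    def shifted(self, delta: int, clamp: bool = True) -> "Category":
        """Category ``delta`` levels away; clamped to the scale ends."""
        r = self.rank + delta
        if clamp:
            r = min(max(r, 0), len(_CATEGORY_ORDER) - 1)
        return Category.from_rank(r)

    def __lt__(self, other: "Category") -> bool:
        return self.rank < other.rank

    def __le__(self, other: "Category") -> bool:
        return self.rank <= other.rank

    def __gt__(self, other: "Category") -> bool:
        return self.rank > other.rank

    def __ge__(self, other: "Category") -> bool:
        return self.rank >= other.rank

    def __str__(self) -> str:
        return self.value


_CATEGORY_ORDER = [Category.C2, Category.C3, Category.C4A, Category.C4B, Category.C4C, Category.C5]


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class EnhancementDegree(enum.Enum):
    """Contrast intensity relative to the surrounding parenchyma."""

    ABSENT = "absent"
    HYPO = "hypo"
    ISO = "iso"
    HYPER = "hyper"


class Arrival(enum.Enum):
    """Contrast arrival time relative to the thyroid tissue."""

    LATER = "later"
    EQUAL_OR_EARLIER = "equal_or_earlier"


class Homogeneity(enum.Enum):
    HOMOGENEOUS = "homogeneous"
    HETEROGENEOUS = "heterogeneous"


class Pattern(enum.Enum):
    """Filling direction: centripetal (rim → centre) or diffuse."""

    CENTRIPETAL = "centripetal"
    DIFFUSE = "diffuse"


class Washout(enum.Enum):
    """Washout time relative to the parenchyma (excluded from the score)."""

    EARLIER = "earlier"
    LATER_OR_EQUAL = "later_or_equal"


@dataclass(frozen=True)
class USFeatureSet:
    """The six C-TIRADS conventional-US features.

    Five suspicious signs each add one point; the comet-tail artifact is the
    single benign sign and subtracts one.  Extrathyroidal extension is
    folded into the irregular/ill-defined-margin flag.
    """

    solid: bool = False
    markedly_hypoechoic: bool = False
    vertical_orientation: bool = False
    microcalcifications: bool = False
    irregular_or_illdefined_margin: bool = False
    comet_tail: bool = False

    MALIGNANT_FLAGS = (
        "solid",
        "markedly_hypoechoic",
        "vertical_orientation",
        "microcalcifications",
        "irregular_or_illdefined_margin",
    )


@dataclass(frozen=True)
class CEUSFeatureSet:
    """The six qualitative CEUS descriptors of one nodule.

    When ``enhancement_degree`` is ``absent`` the nodule takes up no
    contrast, so the remaining enhancement descriptors are not applicable
    and must be left as ``None``; the scoring layer treats such nodules
    through the absent-enhancement benign override instead of the score.
    """

    enhancement_degree: EnhancementDegree
    arrival: Optional[Arrival] = None
    homogeneity: Optional[Homogeneity] = None
    pattern: Optional[Pattern] = None
    washout: Optional[Washout] = None
    peripheral_ring: bool = False

    @property
    def enhancing(self) -> bool:
        return self.enhancement_degree is not EnhancementDegree.ABSENT


#: Names of the CEUSFeatureSet descriptors meaningless under absent enhancement.
_DESCRIPTORS = ("arrival", "homogeneity", "pattern", "washout")


@dataclass(frozen=True)
class NoduleRecord:
    """One nodule: covariates, feature panels, optional ground truth.

    At least one of ``us`` / ``ctirads_category`` must be present; when both
    are, the category must equal the one graded from the US features.
    """

    id: str
    ceus: CEUSFeatureSet
    us: Optional[USFeatureSet] = None
    ctirads_category: Optional[Category] = None
    age: Optional[float] = None
    sex: Optional[Sex] = None
    size_mm: Optional[float] = None
    pathology: Optional[Pathology] = None


@dataclass
class Cohort:
    """An ordered, uniquely-identified collection of nodule records."""

    records: list[NoduleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("cohort is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def validate_record(record: NoduleRecord) -> list[str]:
    """Return human-readable invariant violations (empty list iff valid)."""
    violations: list[str] = []
    if record.us is None and record.ctirads_category is None:
        violations.append("us/ctirads_category: at least one of the US feature set or the C-TIRADS category must be present")
    if record.us is not None and record.ctirads_category is not None:
        # deferred import: grading depends on these types
        from ceus_tirads.ctirads_grading import category_from_score, us_score

        implied = category_from_score(us_score(record.us))
        if implied is not record.ctirads_category:
            violations.append(
                f"ctirads_category: stated category {record.ctirads_category} inconsistent "
                f"with category {implied} graded from the US features"
            )
    ceus = record.ceus
    if ceus.enhancing:
        for name in _DESCRIPTORS:
            if getattr(ceus, name) is None:
                violations.append(f"{name}: required for enhancing nodules (model cannot score a partial CEUS panel)")
    else:
        for name in _DESCRIPTORS:
            if getattr(ceus, name) is not None:
                violations.append(f"{name}: descriptor not applicable under absent enhancement")
    if record.age is not None and record.age < 0:
        violations.append("age: must be >= 0")
    if record.size_mm is not None and record.size_mm <= 0:
        violations.append("size_mm: must be > 0")
    return violations


# ---------------------------------------------------------------------------
# CSV serialization

#: Canonical column order (deterministic writes).
COLUMNS = (
    "id",
    "age",
    "sex",
    "size_mm",
    "solid",
    "markedly_hypoechoic",
    "vertical_orientation",
    "microcalcifications",
    "irregular_or_illdefined_margin",
    "comet_tail",
    "ctirads_category",
    "enhancement_degree",
    "arrival",
    "homogeneity",
    "pattern",
    "washout",
    "peripheral_ring",
    "pathology",
)

_REQUIRED = ("id", "enhancement_degree")

_ENUMS: dict[str, type[enum.Enum]] = {
    "sex": Sex,
    "ctirads_category": Category,
    "enhancement_degree": EnhancementDegree,
    "arrival": Arrival,
    "homogeneity": Homogeneity,
    "pattern": Pattern,
    "washout": Washout,
    "pathology": Pathology,
}

_US_FLAGS = USFeatureSet.MALIGNANT_FLAGS + ("comet_tail",)


def _parse_enum(token: str, kind: type[enum.Enum], row: int, column: str) -> enum.Enum:
    try:
        return kind(token.strip().lower())
    except ValueError:
        allowed = ", ".join(m.value for m in kind)
        raise ParseError(row, column, f"unknown token {token!r}; expected one of: {allowed}") from None


def _parse_bool(token: str, row: int, column: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ParseError(row, column, f"unknown boolean token {token!r}")


def read_cohort(
    source: TextIO | str,
    schema: Optional[Mapping[str, str]] = None,
    provenance: str = "",
) -> Cohort:
    """Read a cohort from a CSV stream (or string of CSV text).

    Parameters
    ----------
    source:
        Open text stream or a CSV string.
    schema:
        Optional column remapping, canonical name → actual header name
        (renaming only; vocabulary and semantics are fixed).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    schema = dict(schema or {})
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise SchemaError("empty input: no header row")
    colname = {canon: schema.get(canon, canon) for canon in COLUMNS}
    for canon in _REQUIRED:
        if colname[canon] not in reader.fieldnames:
            raise SchemaError(f"missing required column: {colname[canon]!r}")

    records: list[NoduleRecord] = []
    for rownum, row in enumerate(reader, start=2):  # 1-based; row 1 is the header
        def cell(canon: str) -> str:
            return (row.get(colname[canon]) or "").strip()

        rid = cell("id")
        if not rid:
            raise ParseError(rownum, colname["id"], "empty id")

        us: Optional[USFeatureSet] = None
        flag_cells = {name: cell(name) for name in _US_FLAGS}
        if any(flag_cells.values()):
            missing = [n for n, v in flag_cells.items() if not v]
            if missing:
                raise ParseError(rownum, colname[missing[0]], "US feature flags must be all present or all absent")
            us = USFeatureSet(**{n: _parse_bool(v, rownum, colname[n]) for n, v in flag_cells.items()})

        def opt_enum(canon: str) -> Optional[enum.Enum]:
            tok = cell(canon)
            return _parse_enum(tok, _ENUMS[canon], rownum, colname[canon]) if tok else None

        def opt_float(canon: str) -> Optional[float]:
            tok = cell(canon)
            if not tok:
                return None
            try:
                return float(tok)
            except ValueError:
                raise ParseError(rownum, colname[canon], f"not a number: {tok!r}") from None

        degree = _parse_enum(cell("enhancement_degree"), EnhancementDegree, rownum, colname["enhancement_degree"])
        ring_tok = cell("peripheral_ring")
        ceus = CEUSFeatureSet(
            enhancement_degree=degree,
            arrival=opt_enum("arrival"),
            homogeneity=opt_enum("homogeneity"),
            pattern=opt_enum("pattern"),
            washout=opt_enum("washout"),
            peripheral_ring=_parse_bool(ring_tok, rownum, colname["peripheral_ring"]) if ring_tok else False,
        )
        records.append(
            NoduleRecord(
                id=rid,
                ceus=ceus,
                us=us,
                ctirads_category=opt_enum("ctirads_category"),
                age=opt_float("age"),
                sex=opt_enum("sex"),
                size_mm=opt_float("size_mm"),
                pathology=opt_enum("pathology"),
            )
        )
    cohort = Cohort(records=records, provenance=provenance)
    problems = [f"{rec.id}: {v}" for rec in records for v in validate_record(rec)]
    if problems:
        raise ValidationError("; ".join(problems))
    return cohort


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def record_to_row(rec: NoduleRecord) -> dict[str, str]:
    """Flatten a record into the canonical CSV cell mapping."""
    row = {c: "" for c in COLUMNS}
    row["id"] = rec.id
    row["age"] = _fmt(rec.age)
    row["sex"] = _fmt(rec.sex)
    row["size_mm"] = _fmt(rec.size_mm)
    if rec.us is not None:
        for name in _US_FLAGS:
            row[name] = _fmt(getattr(rec.us, name))
    row["ctirads_category"] = _fmt(rec.ctirads_category)
    row["enhancement_degree"] = rec.ceus.enhancement_degree.value
    for name in _DESCRIPTORS:
        row[name] = _fmt(getattr(rec.ceus, name))
    row["peripheral_ring"] = _fmt(rec.ceus.peripheral_ring)
    row["pathology"] = _fmt(rec.pathology)
    return row


def write_cohort(cohort: Cohort, sink: TextIO) -> None:
    """Write a cohort as canonical CSV (deterministic, byte-stable)."""
    writer = csv.DictWriter(sink, fieldnames=list(COLUMNS), lineterminator="\n")
    writer.writeheader()
    for rec in cohort:
        writer.writerow(record_to_row(rec))
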