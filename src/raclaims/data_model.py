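"""Domain types and delimited-text I/O for claims and registry event streams.

The package operates on four event streams extracted from administrative
claims plus a clinical registry:

* pharmacy fills (oral and self-injected drugs, with days supply),
* infusion administrations (infused biologics, with dose in mg),
* procedure events (glucocorticoid joint injections),
* registry visits (28-joint counts, ESR, patient/physician globals).

All files are comma-separated UTF-8 with a mandatory header row; dates are
ISO-8601 calendar dates.  Oral glucocorticoid strengths are assumed to be
already expressed in prednisone-equivalent milligrams.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence


class Drug(str, enum.Enum):
    """RA drugs the algorithm knows about.

    ``OTHER_ORAL`` is a catch-all for non-RA oral medications; it exists only
    so the active-user eligibility check (any oral fill 6-12 months before
    the index date) can be evaluated.
    """

    ABATACEPT = "abatacept"
    ADALIMUMAB = "adalimumab"
    ETANERCEPT = "etanercept"
    INFLIXIMAB = "infliximab"
    RITUXIMAB = "rituximab"
    METHOTREXATE = "methotrexate"
    SULFASALAZINE = "sulfasalazine"
    LEFLUNOMIDE = "leflunomide"
    HYDROXYCHLOROQUINE = "hydroxychloroquine"
    ORAL_GLUCOCORTICOID = "oral_glucocorticoid"
    OTHER_ORAL = "other_oral"


#: Biologic agents; switch/add and dose-escalation rules apply to these.
BIOLOGICS = frozenset(
    {Drug.ABATACEPT, Drug.ADALIMUMAB, Drug.ETANERCEPT, Drug.INFLIXIMAB, Drug.RITUXIMAB}
)
#: Biologics administered by infusion (adherence counted in infusions).
INFUSED_BIOLOGICS = frozenset({Drug.INFLIXIMAB, Drug.ABATACEPT, Drug.RITUXIMAB})
#: Nonbiologic DMARDs covered by the new-DMARD prohibition.
DMARDS = frozenset(
    {Drug.METHOTREXATE, Drug.SULFASALAZINE, Drug.LEFLUNOMIDE, Drug.HYDROXYCHLOROQUINE}
)
#: Drugs whose adherence is a pharmacy-fill medication possession ratio.
MPR_DRUGS = frozenset(Drug) - INFUSED_BIOLOGICS


class Route(str, enum.Enum):
    ORAL = "oral"
    SUBCUTANEOUS = "subcutaneous"


class EpisodeClass(str, enum.Enum):
    BIOLOGIC = "biologic"
    DMARD = "dmard"


class Flag(str, enum.Enum):
    """Reasons an episode fails the claims-based effectiveness rule."""

    NONADHERENT_OR_SWITCH = "nonadherent_or_switch"
    BIOLOGIC_SWITCH_OR_ADD = "biologic_switch_or_add"
    NEW_DMARD_ADDED = "new_dmard_added"
    BIOLOGIC_DOSE_ESCALATION = "biologic_dose_escalation"
    EXCESS_JOINT_INJECTIONS = "excess_joint_injections"
    GC_INITIATION = "gc_initiation"
    GC_DOSE_INCREASE = "gc_dose_increase"


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


class RowError(ValueError):
    """A data row failed type or invariant validation."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


def _parse_date(text: str) -> date:
    return datetime.strptime(text.strip(), "%Y-%m-%d").date()


@dataclass(frozen=True)
class PharmacyFill:
    patient_id: str
    drug: Drug
    fill_date: date
    days_supply: int
    strength_mg: float
    quantity: float
    route: Route

    def __post_init__(self) -> None:
        if self.days_supply < 0:
            raise ValueError("days_supply must be >= 0")
        if self.strength_mg < 0:
            raise ValueError("strength_mg must be >= 0")
        if self.quantity < 0:
            raise ValueError("quantity must be >= 0")

    @property
    def total_mg(self) -> float:
        """Total dispensed amount, in mg (prednisone-equivalent for GCs)."""
        return self.strength_mg * self.quantity

    @property
    def daily_dose_mg(self) -> float:
        """Mean daily dose implied by the dispensing, 0 for zero-day supply."""
        return self.total_mg / self.days_supply if self.days_supply > 0 else 0.0


@dataclass(frozen=True)
class InfusionEvent:
    patient_id: str
    drug: Drug
    date: date
    dose_mg: float

    def __post_init__(self) -> None:
        if self.drug not in INFUSED_BIOLOGICS:
            raise ValueError(f"{self.drug.value} is not an infused biologic")
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be > 0")


@dataclass(frozen=True)
class ProcedureEvent:
    patient_id: str
    date: date
    kind: str = "glucocorticoid_injection"

    def __post_init__(self) -> None:
        if self.kind != "glucocorticoid_injection":
            raise ValueError(f"unknown procedure kind {self.kind!r}")


@dataclass(frozen=True)
class RegistryVisit:
    patient_id: str
    date: date
    tjc28: int
    sjc28: int
    esr_mm_hr: float
    patient_global: float
    physician_global: float

    def __post_init__(self) -> None:
        if not 0 <= self.tjc28 <= 28:
            raise ValueError("tjc28 must be in [0, 28]")
        if not 0 <= self.sjc28 <= 28:
            raise ValueError("sjc28 must be in [0, 28]")
        if self.esr_mm_hr < 0:
            raise ValueError("esr_mm_hr must be >= 0")
        for name in ("patient_global", "physician_global"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must be in [0, 100]")


@dataclass(frozen=True)
class TreatmentEpisode:
    """A new-user drug course: index drug/date plus visit anchors.

    The outcome visit sits 10-14 calendar months after the index date; when
    present, the baseline visit is within 31 days of the index date.
    """

    patient_id: str
    index_drug: Drug
    index_date: date
    episode_class: EpisodeClass
    outcome_visit: RegistryVisit
    baseline_visit: RegistryVisit | None = None

    def __post_init__(self) -> None:
        from dateutil.relativedelta import relativedelta

        lo = self.index_date + relativedelta(months=10)
        hi = self.index_date + relativedelta(months=14)
        if not lo <= self.outcome_visit.date <= hi:
            raise ValueError(
                f"outcome visit {self.outcome_visit.date} outside "
                f"[{lo}, {hi}] for index {self.index_date}"
            )
        if self.baseline_visit is not None:
            if abs((self.baseline_visit.date - self.index_date).days) > 31:
                raise ValueError("baseline visit more than 31 days from index")

    @property
    def outcome_date(self) -> date:
        return self.outcome_visit.date


@dataclass(frozen=True)
class AlgorithmResult:
    episode: TreatmentEpisode
    effective: bool
    flags: frozenset[Flag] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.effective != (len(self.flags) == 0):
            raise ValueError("effective must be True exactly when flags is empty")


@dataclass(frozen=True)
class GoldStandardResult:
    episode: TreatmentEpisode
    effective: bool
    das28_outcome: float
    reached_lda: bool
    improved_gt_1_2: bool
    adherent: bool
    das28_baseline: float | None = None


@dataclass(frozen=True)
class ConfusionMatrix:
    """Algorithm vs gold standard 2x2 table (gold standard is truth)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    point: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.point <= self.ci_upper <= 1.0):
            raise ValueError("CI must satisfy 0 <= lower <= point <= upper <= 1")


@dataclass(frozen=True)
class PerformanceMetrics:
    ppv: MetricWithCI | None
    npv: MetricWithCI | None
    se: MetricWithCI | None
    sp: MetricWithCI | None


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------

FILL_COLUMNS = (
    "patient_id",
    "drug",
    "fill_date",
    "days_supply",
    "strength_mg",
    "quantity",
    "route",
)
INFUSION_COLUMNS = ("patient_id", "drug", "date", "dose_mg")
PROCEDURE_COLUMNS = ("patient_id", "date", "kind")
VISIT_COLUMNS = (
    "patient_id",
    "date",
    "tjc28",
    "sjc28",
    "esr_mm_hr",
    "patient_global",
    "physician_global",
)
COMORBIDITY_COLUMNS = ("patient_id", "condition", "flag")
EPISODE_COLUMNS = (
    "patient_id",
    "index_drug",
    "index_date",
    "episode_class",
    "baseline_date",
    "outcome_date",
)
RESULT_COLUMNS = ("patient_id", "index_drug", "index_date", "effective", "flags")

#: Delimiter used when serializing a set of flags into one CSV field.
FLAG_DELIMITER = "|"

_SCHEMAS: dict[str, Sequence[str]] = {
    "fills": FILL_COLUMNS,
    "infusions": INFUSION_COLUMNS,
    "procedures": PROCEDURE_COLUMNS,
    "visits": VISIT_COLUMNS,
    "comorbidities": COMORBIDITY_COLUMNS,
}


def _build_fill(row: dict[str, str]) -> PharmacyFill:
    return PharmacyFill(
        patient_id=row["patient_id"],
        drug=Drug(row["drug"]),
        fill_date=_parse_date(row["fill_date"]),
        days_supply=int(row["days_supply"]),
        strength_mg=float(row["strength_mg"]),
        quantity=float(row["quantity"]),
        route=Route(row["route"]),
    )


def _build_infusion(row: dict[str, str]) -> InfusionEvent:
    return InfusionEvent(
        patient_id=row["patient_id"],
        drug=Drug(row["drug"]),
        date=_parse_date(row["date"]),
        dose_mg=float(row["dose_mg"]),
    )


def _build_procedure(row: dict[str, str]) -> ProcedureEvent:
    return ProcedureEvent(
        patient_id=row["patient_id"], date=_parse_date(row["date"]), kind=row["kind"]
    )


def _build_visit(row: dict[str, str]) -> RegistryVisit:
    return RegistryVisit(
        patient_id=row["patient_id"],
        date=_parse_date(row["date"]),
        tjc28=int(row["tjc28"]),
        sjc28=int(row["sjc28"]),
        esr_mm_hr=float(row["esr_mm_hr"]),
        patient_global=float(row["patient_global"]),
        physician_global=float(row["physician_global"]),
    )


_BUILDERS = {
    "fills": _build_fill,
    "infusions": _build_infusion,
    "procedures": _build_procedure,
    "visits": _build_visit,
}


def read_claims(path, schema: str) -> list:
    """Read one event stream from a CSV file.

    Parameters
    ----------
    path:
        CSV file with the documented header for `schema`.
    schema:
        One of ``fills``, ``infusions``, ``procedures``, ``visits``,
        ``comorbidities``.

    Raises
    ------
    SchemaError
        If the header is missing a required column.
    RowError
        On the first malformed row, citing the 1-based data row number and
        the offending field.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    expected = _SCHEMAS[schema]
    records = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in expected if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        if schema == "comorbidities":
            for i, row in enumerate(reader, start=1):
                try:
                    records.append(
                        (row["patient_id"], row["condition"], _parse_bool(row["flag"]))
                    )
                except (ValueError, KeyError) as exc:
                    raise RowError(i, str(exc)) from exc
            return records
        build = _BUILDERS[schema]
        for i, row in enumerate(reader, start=1):
            try:
                records.append(build(row))
            except (ValueError, KeyError) as exc:
                raise RowError(i, str(exc)) from exc
    return records


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {text!r}")


def write_stream(records: Iterable, path, schema: str) -> None:
    """Write an event stream back to CSV (inverse of `read_claims`)."""
    columns = _SCHEMAS[schema]
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for rec in records:
            writer.writerow([_serialize_field(getattr(rec, c)) for c in columns])


def _serialize_field(value) -> str:
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, date):
        return value.isoformat()
    if isinstance(value, float) and math.isfinite(value) and value == int(value):
        return str(int(value))
    return str(value)


def write_episodes(episodes: Iterable[TreatmentEpisode], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EPISODE_COLUMNS)
        for ep in episodes:
            writer.writerow(
                [
                    ep.patient_id,
                    ep.index_drug.value,
                    ep.index_date.isoformat(),
                    ep.episode_class.value,
                    ep.baseline_visit.date.isoformat() if ep.baseline_visit else "",
                    ep.outcome_visit.date.isoformat(),
                ]
            )


def write_results(results: Iterable[AlgorithmResult], path) -> None:
    """Write algorithm classifications; flags joined with a stable delimiter.

    Flags are serialized sorted and `|`-joined so files compare byte-equal
    across runs; `read_results` restores the flag set.
    """
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(RESULT_COLUMNS)
        for res in results:
            ep = res.episode
            writer.writerow(
                [
                    ep.patient_id,
                    ep.index_drug.value,
                    ep.index_date.isoformat(),
                    str(res.effective).lower(),
                    FLAG_DELIMITER.join(sorted(f.value for f in res.flags)),
                ]
            )


def read_episodes(path, visits: Sequence[RegistryVisit]) -> list[TreatmentEpisode]:
    """Re-hydrate episodes from episodes.csv, resolving visit references
    against the visits stream by (patient_id, date)."""
    by_key = {(v.patient_id, v.date): v for v in visits}
    episodes = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in EPISODE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                pid = row["patient_id"]
                outcome = by_key[(pid, _parse_date(row["outcome_date"]))]
                baseline = None
                if row["baseline_date"]:
                    baseline = by_key[(pid, _parse_date(row["baseline_date"]))]
                episodes.append(
                    TreatmentEpisode(
                        patient_id=pid,
                        index_drug=Drug(row["index_drug"]),
                        index_date=_parse_date(row["index_date"]),
                        episode_class=EpisodeClass(row["episode_class"]),
                        outcome_visit=outcome,
                        baseline_visit=baseline,
                    )
                )
            except KeyError as exc:
                raise RowError(i, f"no registry visit matches {exc}") from exc
            except ValueError as exc:
                raise RowError(i, str(exc)) from exc
    return episodes


def read_results(path) -> list[dict]:
    """Read an algorithm-results file into plain dicts keyed like the header."""
    rows = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in RESULT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                flags = frozenset(
                    Flag(f) for f in row["flags"].split(FLAG_DELIMITER) if f
                )
                rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "index_drug": Drug(row["index_drug"]),
                        "index_date": _parse_date(row["index_date"]),
                        "effective": _parse_bool(row["effective"]),
                        "flags": flags,
                    }
                )
            except (ValueError, KeyError) as exc:
                raise RowError(i, str(exc)) from exc
    return rows
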