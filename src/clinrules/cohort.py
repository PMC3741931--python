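"""Patient-level cohort ingestion, discretization, and transaction encoding.

The analysis operates on an operation-centric oral squamous cell carcinoma
(OSCC) cohort: every retained patient was treated primarily by surgical
operation (OP), optionally followed by chemo- and/or radiotherapy.  Raw
clinical attributes (age in years, tumor sizes in cm, integer stage and
grade codes, the treatment sequence, survival in months) are discretized
into the categorical bins the analysis uses throughout, survival is
dichotomized at 36 months, and selected attributes are encoded as
market-basket style transactions of ``attribute=value`` items ready for
frequent-itemset mining.

The discretized cohort is held as a plain :class:`pandas.DataFrame` (one row
per patient, one column per categorical attribute) so that the usual pandas
idioms — filtering, cross-tabulation, CSV round trips — apply directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .apriori import TransactionDB

logger = logging.getLogger(__name__)

#: Explicit marker for a missing categorical value (never an empty string).
MISSING = "missing"

#: Treatment modality tokens; "+" inside a token marks concurrent modalities.
MODALITY_TOKENS = ("OP", "IA", "CT", "IV", "RT")

#: Post-operative continuations that define surgical-modality group "03"
#: (surgery followed by chemo/radiotherapy in any of the recorded patterns).
OP_GROUP_03_TAILS = frozenset(
    {
        ("CT",),
        ("CT+IV",),
        ("CT", "RT"),
        ("IA", "RT"),
        ("IV",),
        ("IV", "RT"),
        ("RT",),
        ("RT+CT",),
        ("RT+IV",),
        ("RT", "CT"),
        ("RT", "IA"),
        ("RT", "IV"),
    }
)

#: Canonical display order for ordered category schemes (binned attributes).
CATEGORY_ORDER = {
    "age_group": ("<30", "30~50", "50~70", ">70"),
    "nodes_group": ("<5", "5~10", ">10"),
    "clinical_size_group": ("<2 cm", "2~4 cm", ">4 cm"),
    "pathology_size_group": ("<2 cm", "2~4 cm", ">4 cm"),
    "clinical_stage_group": ("early", "late"),
    "pathologic_stage_group": ("early", "late"),
}

#: Columns of the discretized cohort table.
COHORT_COLUMNS = (
    "patient_id",
    "age_group",
    "primary_site",
    "laterality",
    "grade",
    "nodes_group",
    "clinical_stage_group",
    "pathologic_stage_group",
    "clinical_size_group",
    "pathology_size_group",
    "op_group",
    "group",
    "survived_gt36",
    "five_year_survivor",
)


@dataclass
class PatientRecord:
    """One patient of the operation-centric cohort, at raw (undiscretized) level.

    ``None`` encodes a genuinely missing clinical value (tumor sizes, stages
    and node counts are incomplete in registry data); mandatory fields (age,
    grade, laterality, survival, vital status, treatment sequence) must be
    present for the record to be retained by :func:`read_cohort`.
    """

    patient_id: str
    age: float
    primary_site: str
    laterality: int
    grade: int
    nodes_examined: int | None
    clinical_stage: int | None
    pathologic_stage: int | None
    clinical_tumor_size: float | None
    pathology_tumor_size: float | None
    treatment_sequence: tuple[str, ...]
    survival_months: float
    vital_status: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age: {self.age}")
        if self.laterality not in range(5):
            raise ValueError(f"laterality code out of range 0-4: {self.laterality}")
        if self.grade not in (1, 2, 3, 4, 9):
            raise ValueError(f"grade code not in {{1,2,3,4,9}}: {self.grade}")
        for name in ("clinical_stage", "pathologic_stage"):
            value = getattr(self, name)
            if value is not None and value not in range(5):
                raise ValueError(f"{name} out of range 0-4: {value}")
        if self.survival_months < 0:
            raise ValueError(f"negative survival: {self.survival_months}")
        if self.vital_status not in ("alive", "dead"):
            raise ValueError(f"vital_status must be alive|dead: {self.vital_status}")
        if not self.treatment_sequence or self.treatment_sequence[0] != "OP":
            raise ValueError(
                "operation-centric cohort: treatment_sequence must start with OP, "
                f"got {self.treatment_sequence!r}"
            )

    def five_year_survivor(self) -> bool | None:
        """True beyond 60 months, False if dead by 60 months, None if censored."""
        if self.survival_months > 60:
            return True
        if self.vital_status == "dead":
            return False
        return None


def stage_group(stage: int) -> str:
    """Collapse an AJCC-style stage code 0-4 into the early/late dichotomy.

    Stages 0 through 3 count as ``early``; stage 4 as ``late``.
    """
    if stage not in range(5):
        raise ValueError(f"stage code out of range 0-4: {stage}")
    return "late" if stage == 4 else "early"


@dataclass(frozen=True)
class DiscretizationScheme:
    """Bin boundaries for the continuous clinical attributes.

    Interior bins are closed on both ends ([30, 50] years, [2, 4] cm,
    [5, 10] nodes); values strictly below or above fall in the open outer
    bins.  The defaults are the bins used for the reference OSCC cohort.
    """

    age_edges: tuple[float, float] = (30.0, 50.0, 70.0)
    size_edges: tuple[float, float] = (2.0, 4.0)
    nodes_edges: tuple[int, int] = (5, 10)

    def age_group(self, age: float) -> str:
        lo, mid, hi = self.age_edges
        if age < lo:
            return "<30"
        if age <= mid:
            return "30~50"
        if age <= hi:
            return "50~70"
        return ">70"

    def size_group(self, size_cm: float | None) -> str:
        if size_cm is None:
            return MISSING
        lo, hi = self.size_edges
        if size_cm < lo:
            return "<2 cm"
        if size_cm <= hi:
            return "2~4 cm"
        return ">4 cm"

    def nodes_group(self, n: int | None) -> str:
        if n is None:
            return MISSING
        lo, hi = self.nodes_edges
        if n < lo:
            return "<5"
        if n <= hi:
            return "5~10"
        return ">10"


DEFAULT_SCHEME = DiscretizationScheme()


def op_group(treatment_sequence: Sequence[str]) -> str:
    """Surgical-modality group code: 01 surgery only, 02 surgery then
    intra-arterial chemotherapy, 03 surgery followed by any other recorded
    chemo/radiotherapy pattern.

    Sequences outside the recorded patterns map to the missing marker (the
    record is excluded from modality analyses but retained elsewhere).
    """
    seq = tuple(treatment_sequence)
    if seq == ("OP",):
        return "01"
    if seq == ("OP", "IA"):
        return "02"
    if seq and seq[0] == "OP" and seq[1:] in OP_GROUP_03_TAILS:
        return "03"
    logger.warning("unmapped treatment sequence %r; op_group set to missing", seq)
    return MISSING


def discretize(
    records: Iterable[PatientRecord],
    scheme: DiscretizationScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Map raw patient records to the categorical cohort table.

    Returns a DataFrame with one row per record and the columns in
    :data:`COHORT_COLUMNS`.  Every categorical cell holds either a category
    label of its attribute or :data:`MISSING`.  ``survived_gt36`` is True
    iff survival exceeded 36 months.  ``five_year_survivor`` is ``True`` for
    survival beyond 60 months, ``False`` for death at or before 60 months,
    and :data:`MISSING` for patients alive but censored before 60 months.
    """
    rows = []
    for rec in records:
        if rec.five_year_survivor() is None:
            five_year: object = MISSING
        else:
            five_year = rec.five_year_survivor()
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age_group": scheme.age_group(rec.age),
                "primary_site": rec.primary_site if rec.primary_site else MISSING,
                "laterality": f"{rec.laterality:02d}",
                "grade": f"{rec.grade:02d}",
                "nodes_group": scheme.nodes_group(rec.nodes_examined),
                "clinical_stage_group": (
                    MISSING if rec.clinical_stage is None else stage_group(rec.clinical_stage)
                ),
                "pathologic_stage_group": (
                    MISSING if rec.pathologic_stage is None else stage_group(rec.pathologic_stage)
                ),
                "clinical_size_group": scheme.size_group(rec.clinical_tumor_size),
                "pathology_size_group": scheme.size_group(rec.pathology_tumor_size),
                "op_group": op_group(rec.treatment_sequence),
                "group": "OP" if rec.treatment_sequence[:1] == ("OP",) else "non-OP",
                "survived_gt36": rec.survival_months > 36,
                "five_year_survivor": five_year,
            }
        )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def filter_population(cohort: pd.DataFrame, predicate: str) -> pd.DataFrame:
    """Select the mining population: ``survived_gt36``, ``not_survived_gt36``
    or ``all``.  Record order is preserved; the resulting size is logged."""
    if predicate == "all":
        out = cohort
    elif predicate == "survived_gt36":
        out = cohort[cohort["survived_gt36"]]
    elif predicate == "not_survived_gt36":
        out = cohort[~cohort["survived_gt36"]]
    else:
        raise ValueError(f"unknown population predicate: {predicate!r}")
    logger.info("population %s: %d of %d records", predicate, len(out), len(cohort))
    return out.reset_index(drop=True)


def encode_transactions(cohort: pd.DataFrame, attributes: Sequence[str]) -> TransactionDB:
    """Encode each cohort record as a transaction of ``attribute=value`` items.

    Records missing any selected attribute are dropped (listwise, logged).
    Item ids are assigned deterministically: attributes in the order given,
    values of each attribute in lexicographic order.  The id order therefore
    fixes the canonical within-itemset item order used for rule enumeration.
    """
    if not list(attributes):
        raise ValueError("empty attribute list")
    missing_cols = [a for a in attributes if a not in cohort.columns]
    if missing_cols:
        raise KeyError(f"attributes not in cohort table: {missing_cols}")
    sub = cohort[list(attributes)].astype(object)
    keep = sub.notna().all(axis=1) & (sub != MISSING).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("encode_transactions: dropped %d records with missing values", n_dropped)
    sub = sub[keep]

    id_to_item: list[str] = []
    for attr in attributes:
        for value in sorted(map(str, sub[attr].unique())):
            id_to_item.append(f"{attr}={value}")
    item_to_id = {item: i for i, item in enumerate(id_to_item)}

    transactions = [
        frozenset(item_to_id[f"{attr}={row[attr]}"] for attr in attributes)
        for row in sub.to_dict("records")
    ]
    return TransactionDB(transactions=transactions, id_to_item=tuple(id_to_item))


# ---------------------------------------------------------------------------
# file I/O


#: Canonical column names of the raw patient table.
RAW_COLUMNS = tuple(f.name for f in fields(PatientRecord))

_MANDATORY = (
    "patient_id",
    "age",
    "primary_site",
    "laterality",
    "grade",
    "treatment_sequence",
    "survival_months",
    "vital_status",
)

_OPTIONAL_NUMERIC = {
    "nodes_examined": int,
    "clinical_stage": int,
    "pathologic_stage": int,
    "clinical_tumor_size": float,
    "pathology_tumor_size": float,
}


def parse_treatment_sequence(text: str) -> tuple[str, ...]:
    """Parse ``"OP->RT+CT"`` (ASCII arrow) or ``"OP→RT+CT"`` into tokens."""
    text = text.replace("→", "->")
    tokens = tuple(tok.strip() for tok in text.split("->") if tok.strip())
    for tok in tokens:
        for part in tok.split("+"):
            if part.strip() not in MODALITY_TOKENS:
                raise ValueError(f"unknown modality token {part!r} in {text!r}")
    return tokens


def format_treatment_sequence(seq: Sequence[str]) -> str:
    return "->".join(seq)


def read_schema(path: str | Path) -> dict[str, str]:
    """Read a plain ``field = column`` mapping file (``#`` starts a comment)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    return mapping


def read_cohort(
    path: str | Path,
    schema: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> list[PatientRecord]:
    """Read a delimited patient table into validated records.

    ``schema`` maps canonical field names to column names in the file (an
    identity mapping by default).  Rows whose mandatory fields cannot be
    parsed, or that fail record validation, are dropped; the exclusion count
    is logged.  A missing file or a missing mandatory column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    schema = schema or {}
    colmap = {f: schema.get(f, f) for f in RAW_COLUMNS}
    for f in _MANDATORY:
        if colmap[f] not in df.columns:
            raise ValueError(f"mandatory column missing: {colmap[f]!r} (field {f})")

    records: list[PatientRecord] = []
    n_excluded = 0
    for idx, row in enumerate(df.to_dict("records")):
        try:
            kwargs: dict[str, object] = {
                "patient_id": str(row[colmap["patient_id"]]),
                "age": float(row[colmap["age"]]),
                "primary_site": str(row[colmap["primary_site"]]).strip(),
                "laterality": int(row[colmap["laterality"]]),
                "grade": int(row[colmap["grade"]]),
                "treatment_sequence": parse_treatment_sequence(
                    str(row[colmap["treatment_sequence"]])
                ),
                "survival_months": float(row[colmap["survival_months"]]),
                "vital_status": str(row[colmap["vital_status"]]).strip().lower(),
            }
            for f, cast in _OPTIONAL_NUMERIC.items():
                col = colmap[f]
                raw = str(row.get(col, "")).strip()
                kwargs[f] = cast(float(raw)) if raw not in ("", "NA", "nan") else None
            records.append(PatientRecord(**kwargs))
        except (ValueError, KeyError) as exc:
            n_excluded += 1
            logger.warning("dropping row %d: %s", idx + 1, exc)
    if n_excluded:
        logger.info("read_cohort: %d rows excluded, %d retained", n_excluded, len(records))
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write raw patient records as CSV (inverse of :func:`read_cohort`)."""
    rows = []
    for rec in records:
        row = {f: getattr(rec, f) for f in RAW_COLUMNS}
        row["treatment_sequence"] = format_treatment_sequence(rec.treatment_sequence)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(RAW_COLUMNS))
    df.to_csv(path, index=False)
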