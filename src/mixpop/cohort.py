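"""Core cohort containers and tabular I/O.

The analysis operates on two tables: a genes-by-patients matrix of
log2-transformed expression intensities, and a clinical table of survival
outcomes and treatment arms. Both are plain tab-separated text. Source
vocabularies (month-based survival columns, site-specific outcome codes)
are translated into the canonical fields through a :class:`ClinicalMapping`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ER_STATUSES = frozenset({"positive", "negative", "unknown"})
TREATMENTS = frozenset({"none", "hormone_only", "chemo_only", "other"})
OUTCOMES = frozenset(
    {"died_of_disease", "died_other_cause", "alive_at_last_followup", "unknown"}
)

DEFAULT_INDEX_GENE = "NAT1"


class CohortError(ValueError):
    """Invalid cohort table or record."""


@dataclass
class ExpressionMatrix:
    """Genes x patients matrix of log2 expression values.

    Rows are genes, columns are patients. All values must be finite;
    missing expression is rejected rather than imputed.
    """

    gene_ids: list[str]
    patient_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise CohortError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.patient_ids)} patients"
            )
        for label, ids in (("gene", self.gene_ids), ("patient", self.patient_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise CohortError(f"duplicate {label} identifier: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            g, p = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite expression value for gene {self.gene_ids[g]!r}, "
                f"patient {self.patient_ids[p]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def row(self, gene: str) -> np.ndarray:
        """Expression vector for one gene, in patient order."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.patient_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class PatientRecord:
    """One patient's clinical covariates and overall-survival outcome.

    ``survival_time`` is years since diagnosis. ``outcome`` distinguishes
    disease deaths from other-cause deaths and censoring so downstream
    stages can apply their own event definitions.
    """

    patient_id: str
    er_status: str = "unknown"
    treatment: str = "other"
    survival_time: float = 0.0
    outcome: str = "unknown"
    age_at_diagnosis: float | None = None
    tumor_size: float | None = None

    def __post_init__(self) -> None:
        self.patient_id = str(self.patient_id)
        if self.er_status not in ER_STATUSES:
            raise CohortError(f"invalid ER status {self.er_status!r}")
        if self.treatment not in TREATMENTS:
            raise CohortError(f"invalid treatment {self.treatment!r}")
        if self.outcome not in OUTCOMES:
            raise CohortError(f"invalid outcome {self.outcome!r}")
        self.survival_time = float(self.survival_time)
        if not np.isfinite(self.survival_time) or self.survival_time < 0:
            raise CohortError(
                f"negative or non-finite survival time for {self.patient_id!r}: "
                f"{self.survival_time}"
            )


@dataclass
class Cohort:
    """Expression matrix plus clinical records, tied by patient id."""

    expression: ExpressionMatrix
    clinical: list[PatientRecord]
    index_gene: str = DEFAULT_INDEX_GENE

    def __post_init__(self) -> None:
        known = set(self.expression.patient_ids)
        ids: set[str] = set()
        for rec in self.clinical:
            if rec.patient_id in ids:
                raise CohortError(f"duplicate clinical patient id {rec.patient_id!r}")
            ids.add(rec.patient_id)
            if rec.patient_id not in known:
                raise CohortError(
                    f"clinical patient {rec.patient_id!r} absent from expression matrix"
                )
        if self.index_gene not in self.expression.gene_ids:
            raise CohortError(f"index gene {self.index_gene!r} not in expression matrix")

    def index_values(self) -> np.ndarray:
        """Index-gene expression aligned to the clinical record order."""
        row = self.expression.row(self.index_gene)
        pos = {p: i for i, p in enumerate(self.expression.patient_ids)}
        return row[[pos[r.patient_id] for r in self.clinical]]

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.clinical],
                "er_status": [r.er_status for r in self.clinical],
                "treatment": [r.treatment for r in self.clinical],
                "survival_time": [r.survival_time for r in self.clinical],
                "outcome": [r.outcome for r in self.clinical],
                "age_at_diagnosis": [r.age_at_diagnosis for r in self.clinical],
                "tumor_size": [r.tumor_size for r in self.clinical],
            }
        )


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table into an :class:`ExpressionMatrix`.

    The first column holds row identifiers and the header row holds column
    identifiers. ``orientation`` states whether rows are genes or patients;
    the returned matrix is always genes x patients.
    """
    if orientation not in {"genes_in_rows", "patients_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    for axis, ids in (("row", df.index), ("column", df.columns)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortError(f"duplicate {axis} identifier: {dup[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise CohortError(f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    if orientation == "patients_in_rows":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical I/O


@dataclass
class ClinicalMapping:
    """Translation from a source clinical table to canonical fields.

    ``columns`` maps canonical names to source column names. The treatment
    arm is derived from two boolean therapy columns (hormone therapy and
    chemotherapy), yielding none / hormone_only / chemo_only / other.
    ``survival_unit`` converts month-based follow-up columns to years.
    Category codes absent from the code maps become ``unknown`` with a
    logged warning rather than failing the read.
    """

    columns: dict = field(
        default_factory=lambda: {
            "patient_id": "patient_id",
            "er_status": "er_status",
            "hormone_therapy": "hormone_therapy",
            "chemotherapy": "chemotherapy",
            "survival_time": "survival_time",
            "outcome": "outcome",
            "age_at_diagnosis": "age_at_diagnosis",
            "tumor_size": "tumor_size",
        }
    )
    survival_unit: str = "years"
    er_codes: dict = field(
        default_factory=lambda: {"positive": "positive", "negative": "negative"}
    )
    outcome_codes: dict = field(
        default_factory=lambda: {
            "died_of_disease": "died_of_disease",
            "died_other_cause": "died_other_cause",
            "alive_at_last_followup": "alive_at_last_followup",
        }
    )
    true_codes: frozenset = frozenset({"1", "yes", "true", "y"})

    def __post_init__(self) -> None:
        if self.survival_unit not in {"years", "months"}:
            raise ValueError(f"unsupported survival unit {self.survival_unit!r}")


def _as_bool(raw, mapping: ClinicalMapping) -> bool:
    return str(raw).strip().lower() in mapping.true_codes


def read_clinical(path, mapping: ClinicalMapping | None = None) -> list[PatientRecord]:
    """Read a TSV clinical table into canonical :class:`PatientRecord`s."""
    mapping = mapping or ClinicalMapping()
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = mapping.columns
    for canonical in ("patient_id", "survival_time", "outcome"):
        if cols[canonical] not in df.columns:
            raise CohortError(f"clinical table missing column {cols[canonical]!r}")
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        pid = row[cols["patient_id"]]
        time = float(row[cols["survival_time"]])
        if mapping.survival_unit == "months":
            time /= 12.0
        if time < 0:
            raise CohortError(f"negative survival time for patient {pid!r}")

        raw_outcome = str(row[cols["outcome"]]).strip()
        outcome = mapping.outcome_codes.get(raw_outcome)
        if outcome is None:
            logger.warning(
                "patient %s: unmapped outcome code %r -> unknown", pid, raw_outcome
            )
            outcome = "unknown"

        er = "unknown"
        if cols.get("er_status") in df.columns:
            raw_er = str(row[cols["er_status"]]).strip()
            er = mapping.er_codes.get(raw_er, "unknown")
            if er == "unknown" and raw_er not in {"", "nan", "unknown"}:
                logger.warning("patient %s: unmapped ER code %r -> unknown", pid, raw_er)

        hormone = cols.get("hormone_therapy") in df.columns and _as_bool(
            row[cols["hormone_therapy"]], mapping
        )
        chemo = cols.get("chemotherapy") in df.columns and _as_bool(
            row[cols["chemotherapy"]], mapping
        )
        if not hormone and not chemo:
            treatment = "none"
        elif hormone and not chemo:
            treatment = "hormone_only"
        elif chemo and not hormone:
            treatment = "chemo_only"
        else:
            treatment = "other"

        def _opt(name: str) -> float | None:
            col = cols.get(name)
            if col not in df.columns:
                return None
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() in {"", "NA", "nan"}:
                return None
            return float(raw)

        records.append(
            PatientRecord(
                patient_id=pid,
                er_status=er,
                treatment=treatment,
                survival_time=time,
                outcome=outcome,
                age_at_diagnosis=_opt("age_at_diagnosis"),
                tumor_size=_opt("tumor_size"),
            )
        )
    return records


def write_clinical(records: list[PatientRecord], path) -> None:
    """Write records as a TSV readable back with the default mapping."""
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "er_status": [r.er_status for r in records],
            "hormone_therapy": [
                int(r.treatment in {"hormone_only", "other"}) for r in records
            ],
            "chemotherapy": [
                int(r.treatment in {"chemo_only", "other"}) for r in records
            ],
            "survival_time": [r.survival_time for r in records],
            "outcome": [r.outcome for r in records],
            "age_at_diagnosis": [r.age_at_diagnosis for r in records],
            "tumor_size": [r.tumor_size for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def log2_transform(raw_values) -> np.ndarray:
    """Elementwise base-2 log of positive raw intensities."""
    arr = np.asarray(raw_values, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise CohortError("log2_transform requires strictly positive finite values")
    return np.log2(arr)
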