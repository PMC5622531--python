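"""The EHR bundle and cohort inclusion rules.

The cohort substrate is five flat tables (patients, encounters, documents,
coded diagnoses, prescriptions).  Inclusion follows a registry-union-CDW
design: members of a department-maintained disease registry are included
outright, and the clinical data warehouse contributes every patient who
jointly satisfies four criteria — an encounter within the study window, a
billing code for the index disease, an encounter in the index department,
and a free-text document mentioning the index disease.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._text import fold_text
from .errors import CohortError, ParseError
from .terminology import IcdPattern, TermPattern, icd_matches

__all__ = ["EhrBundle", "select_cohort", "describe_cohort", "TABLE_SCHEMAS"]

TABLE_SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "age_years", "registry_member"],
    "encounters": ["patient_id", "date", "department", "setting"],
    "documents": ["doc_id", "patient_id", "date", "text", "doc_type"],
    "diagnoses": ["patient_id", "encounter_ref", "code", "date"],
    "prescriptions": ["patient_id", "date", "code"],
}


@dataclass
class EhrBundle:
    """Five pandas tables plus referential-integrity validation."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    documents: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame

    def validate(self) -> "EhrBundle":
        for name, cols in TABLE_SCHEMAS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ParseError(f"table {name!r} missing column(s) {missing}")
        ids = set(self.patients["patient_id"])
        if len(ids) != len(self.patients):
            raise ParseError("duplicate patient_id in patients table")
        for name in ("encounters", "documents", "diagnoses", "prescriptions"):
            df = getattr(self, name)
            orphans = set(df["patient_id"]) - ids
            if orphans:
                raise ParseError(
                    f"table {name!r} references unknown patient(s): {sorted(orphans)[:5]}"
                )
        return self

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in TABLE_SCHEMAS:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "EhrBundle":
        path = Path(path)
        tables = {}
        for name in TABLE_SCHEMAS:
            f = path / f"{name}.csv"
            if not f.exists():
                raise ParseError(f"bundle table not found: {f}")
            tables[name] = pd.read_csv(f, dtype={"patient_id": str, "code": str}, keep_default_na=False)
        return cls(**tables).validate()


def _parse_date(d) -> dt.date:
    if isinstance(d, dt.date):
        return d
    return dt.date.fromisoformat(str(d)[:10])


def select_cohort(
    bundle: EhrBundle,
    index_icd: IcdPattern,
    index_terms: Sequence[TermPattern],
    dept_filter: str,
    window: tuple[dt.date | str, dt.date | str],
) -> set[str]:
    """Registry members UNION patients meeting all four CDW criteria.

    CDW criteria (all required): at least one encounter with a date inside
    *window* (closed interval); at least one coded diagnosis matching
    *index_icd*; at least one encounter in *dept_filter*; at least one
    document whose folded text matches any of *index_terms*.
    """
    bundle.validate()
    start, end = (_parse_date(window[0]), _parse_date(window[1]))
    if start > end:
        raise CohortError(f"empty study window: {start} > {end}")

    registry = set(
        bundle.patients.loc[
            bundle.patients["registry_member"].astype(str).str.lower().isin(["true", "1"]),
            "patient_id",
        ]
    )

    enc = bundle.encounters
    enc_dates = pd.to_datetime(enc["date"]).dt.date
    in_window = set(enc.loc[(enc_dates >= start) & (enc_dates <= end), "patient_id"])

    diag = bundle.diagnoses
    has_code = set(
        diag.loc[[icd_matches(index_icd, c) for c in diag["code"]], "patient_id"]
    ) if len(diag) else set()

    in_dept = set(enc.loc[enc["department"] == dept_filter, "patient_id"])

    compiled = [t.compiled() for t in index_terms]
    doc_hit: set[str] = set()
    for row in bundle.documents.itertuples(index=False):
        if row.patient_id in doc_hit:
            continue
        folded, _ = fold_text(str(row.text))
        if any(rx.search(folded) for rx in compiled):
            doc_hit.add(row.patient_id)

    cdw = in_window & has_code & in_dept & doc_hit
    return registry | cdw


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.quantile(arr, 0.25)),
        float(np.quantile(arr, 0.75)),
    )


def describe_cohort(
    bundle: EhrBundle,
    cohort: set[str],
    index_icd: IcdPattern | None = None,
) -> dict:
    """Descriptive summary: demographics, utilization, follow-up, coding depth.

    Follow-up per patient is the span in years between first and last
    encounter (0 for single-encounter patients).  Distinct ICD-code counts
    exclude codes matching *index_icd* (the index disease does not count as
    a comorbidity code).
    """
    if not cohort:
        raise CohortError("cohort is empty")
    pts = bundle.patients[bundle.patients["patient_id"].isin(cohort)]
    enc = bundle.encounters[bundle.encounters["patient_id"].isin(cohort)].copy()
    docs = bundle.documents[bundle.documents["patient_id"].isin(cohort)]
    diag = bundle.diagnoses[bundle.diagnoses["patient_id"].isin(cohort)]

    n = len(pts)
    sex = pts["sex"].value_counts().to_dict()
    ages = pts["age_years"].astype(float)

    enc["date"] = pd.to_datetime(enc["date"])
    per_pat = enc.groupby("patient_id")["date"]
    n_enc = per_pat.size().reindex(pts["patient_id"], fill_value=0)
    span_years = (per_pat.max() - per_pat.min()).dt.days / 365.25
    span_years = span_years.reindex(pts["patient_id"], fill_value=0.0)

    single = int((n_enc <= 1).sum())
    fu_strata = {
        "0 (single encounter)": single,
        "0-1": int(((n_enc > 1) & (span_years <= 1)).sum()),
        "1-2": int(((span_years > 1) & (span_years <= 2)).sum()),
        "2-5": int(((span_years > 2) & (span_years <= 5)).sum()),
        ">5": int((span_years > 5).sum()),
    }

    n_docs = docs.groupby("patient_id").size().reindex(pts["patient_id"], fill_value=0)

    if index_icd is not None and len(diag):
        keep = [not icd_matches(index_icd, c) for c in diag["code"]]
        diag = diag.loc[keep]
    n_codes = (
        diag.assign(code=[c for c in diag["code"]])
        .groupby("patient_id")["code"]
        .nunique()
        .reindex(pts["patient_id"], fill_value=0)
    )
    code_strata = {
        "0": int((n_codes == 0).sum()),
        "1": int((n_codes == 1).sum()),
        "2-5": int(((n_codes >= 2) & (n_codes <= 5)).sum()),
        ">=6": int((n_codes >= 6).sum()),
    }

    med_d, q1_d, q3_d = _median_iqr(n_docs)
    med_e, q1_e, q3_e = _median_iqr(n_enc)
    return {
        "n": n,
        "sex_counts": sex,
        "sex_proportions": {k: v / n for k, v in sex.items()},
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if n > 1 else 0.0,
        "documents_per_patient": {"median": med_d, "iqr": (q1_d, q3_d), "max": int(n_docs.max())},
        "encounters_per_patient": {"median": med_e, "iqr": (q1_e, q3_e), "max": int(n_enc.max())},
        "followup_strata": fu_strata,
        "distinct_icd_strata": code_strata,
    }
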