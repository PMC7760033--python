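"""Clinical endpoints: iRECIST-based response labelling, TTF/OS summaries.

Two labelling rules are implemented for anti-PD-1-treated cohorts:

``first_RA``   responder iff the first radiological assessment is a complete
               response (iCR), partial response (iPR) or stable disease (iSD).
               Death before the first assessment (hyper-progression) is a
               non-responder.

``second_RA``  responder iff therapy continued to a third or later
               radiological assessment; subjects who discontinued at or
               before the second assessment (confirmed progression,
               hyper-progression or death) are non-responders. This rule
               tolerates pseudo-progression — apparent early radiological
               growth from immune infiltration — which the first-assessment
               rule misreads as failure.

Time-to-treatment-failure (TTF) and overall survival (OS) are summarised per
labelled group. Ongoing/alive ("+") values are treated as observed at their
recorded week for medians and rank tests (this is the convention needed to
reproduce the published cohort medians); a Kaplan-Meier median is available
separately as :func:`km_median_endpoint`.

The nivolumab (34 subjects) and pembrolizumab (19 subjects) cohort tables are
shipped as packaged CSV fixtures transcribed from the published study tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord",
    "ResponseLabel",
    "RULES",
    "classify_first_ra",
    "classify_second_ra",
    "classify",
    "group_counts",
    "median_endpoint",
    "km_median_endpoint",
    "compare_endpoint",
    "load_clinical_csv",
    "records_to_csv",
    "load_table1",
    "load_table2",
    "labels_frame",
]

RESPONDER, NONRESPONDER = "responder", "non-responder"
RULES = ("first_RA", "second_RA")

# iRECIST codes considered a favourable assessment under the first-RA rule.
_FAVOURABLE = {"iCR", "iPR", "iSD"}
# Accepted synonyms found in printed tables -> canonical iRECIST code.
_SYNONYMS = {
    "HP": "iHP", "NA (HP)": "iHP", "NA(HP)": "iHP",
    "PD": "iPD", "CR": "iCR", "PR": "iPR", "SD": "iSD",
    "UPD": "iUPD", "CPD": "iCPD",
}
_KNOWN = {"iCR", "iPR", "iSD", "iUPD", "iCPD", "iPD", "iHP"}


def _canon(code: str) -> str:
    c = code.strip()
    up = c.upper()
    if up in _SYNONYMS:
        return _SYNONYMS[up]
    for k in _KNOWN:
        if up == k.upper():
            return k
    raise ValueError(f"unrecognized radiological assessment code: {code!r}")


def _components(code: str) -> list[str]:
    """Split composite codes like 'iSD/PR' into canonical components."""
    return [_canon(p) for p in code.split("/")]


@dataclass(frozen=True)
class ClinicalRecord:
    """One cohort-table row.

    ttf_weeks / os_weeks may be NaN when the printed table leaves them blank;
    ra_codes is the ordered tuple of radiological assessment codes (possibly
    empty when the subject died before the first assessment).
    """

    subject_id: str
    arm: str = ""
    histology: str = "NA"
    cycles: int = 0
    ttf_weeks: float = math.nan
    ttf_ongoing: bool = False
    os_weeks: float = math.nan
    os_alive: bool = False
    ra_codes: tuple[str, ...] = ()
    pdl1_tps: float = math.nan

    def __post_init__(self) -> None:
        if (self.ttf_weeks < 0) or (self.os_weeks < 0):
            raise ValueError(f"{self.subject_id}: negative endpoint weeks")
        for code in self.ra_codes:
            _components(code)  # validate eagerly


@dataclass(frozen=True)
class ResponseLabel:
    subject_id: str
    rule: str
    label: str


def classify_first_ra(record: ClinicalRecord) -> ResponseLabel:
    """Responder iff the first assessment is iCR/iPR/iSD.

    Composite codes ("iSD/PR") count as responder when any component is
    favourable; hyper-progression variants and an empty assessment list are
    non-responders.
    """
    if not record.ra_codes:
        label = NONRESPONDER
    else:
        first = _components(record.ra_codes[0])
        label = RESPONDER if any(c in _FAVOURABLE for c in first) else NONRESPONDER
    return ResponseLabel(record.subject_id, "first_RA", label)


def classify_second_ra(record: ClinicalRecord) -> ResponseLabel:
    """Responder iff therapy reached a third or later radiological assessment."""
    label = RESPONDER if len(record.ra_codes) >= 3 else NONRESPONDER
    return ResponseLabel(record.subject_id, "second_RA", label)


def classify(record: ClinicalRecord, rule: str) -> ResponseLabel:
    if rule == "first_RA":
        return classify_first_ra(record)
    if rule == "second_RA":
        return classify_second_ra(record)
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


def group_counts(records: list[ClinicalRecord], rule: str = "second_RA") -> tuple[int, int]:
    """(n_responders, n_nonresponders) under the chosen rule."""
    if not records:
        raise ValueError("no records")
    labels = [classify(r, rule).label for r in records]
    return labels.count(RESPONDER), labels.count(NONRESPONDER)


def _endpoint_values(records: list[ClinicalRecord], rule: str, endpoint: str,
                     group: str) -> np.ndarray:
    if endpoint not in ("TTF", "OS"):
        raise ValueError("endpoint must be 'TTF' or 'OS'")
    attr = "ttf_weeks" if endpoint == "TTF" else "os_weeks"
    vals = [getattr(r, attr) for r in records if classify(r, rule).label == group]
    arr = np.array([v for v in vals if not math.isnan(v)], float)
    if arr.size == 0:
        raise ValueError(f"no {endpoint} values in group {group!r}")
    return arr


def median_endpoint(records: list[ClinicalRecord], rule: str, endpoint: str,
                    group: str) -> float:
    """Plain sample median of TTF or OS (weeks) in the labelled group.

    Censored ("+") values enter at their recorded week; rows with a missing
    endpoint are dropped.
    """
    return float(np.median(_endpoint_values(records, rule, endpoint, group)))


def km_median_endpoint(records: list[ClinicalRecord], rule: str, endpoint: str,
                       group: str) -> float:
    """Kaplan-Meier median honouring the censor flags (may be inf)."""
    from lifelines import KaplanMeierFitter

    attr = "ttf_weeks" if endpoint == "TTF" else "os_weeks"
    flag = "ttf_ongoing" if endpoint == "TTF" else "os_alive"
    rows = [(getattr(r, attr), not getattr(r, flag)) for r in records
            if classify(r, rule).label == group and not math.isnan(getattr(r, attr))]
    if not rows:
        raise ValueError(f"no {endpoint} values in group {group!r}")
    t, observed = zip(*rows)
    kmf = KaplanMeierFitter().fit(np.asarray(t, float), np.asarray(observed, bool))
    return float(kmf.median_survival_time_)


def compare_endpoint(records: list[ClinicalRecord], rule: str, endpoint: str) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p for responder vs non-responder weeks."""
    a = _endpoint_values(records, rule, endpoint, RESPONDER)
    b = _endpoint_values(records, rule, endpoint, NONRESPONDER)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    from .univariate import wilcoxon_rank_sum

    _, p = wilcoxon_rank_sum(a, b)
    return p


# ---------------------------------------------------------------------------
# CSV schema:
# subject_id, arm, histology, cycles, ttf_weeks, ttf_ongoing, os_weeks,
# os_alive, pdl1_tps, ra_codes (semicolon-separated ordered list)

def load_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"subject_id", "ttf_weeks", "os_weeks", "ra_codes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        codes = tuple(c for c in str(row["ra_codes"]).split(";") if c.strip())
        records.append(ClinicalRecord(
            subject_id=row["subject_id"],
            arm=row.get("arm", ""),
            histology=row.get("histology", "NA") or "NA",
            cycles=int(float(row["cycles"])) if row.get("cycles", "") else 0,
            ttf_weeks=float(row["ttf_weeks"]) if row["ttf_weeks"] else math.nan,
            ttf_ongoing=row.get("ttf_ongoing", "") in ("1", "True", "true"),
            os_weeks=float(row["os_weeks"]) if row["os_weeks"] else math.nan,
            os_alive=row.get("os_alive", "") in ("1", "True", "true"),
            ra_codes=codes,
            pdl1_tps=float(row["pdl1_tps"]) if row.get("pdl1_tps", "") else math.nan,
        ))
    return records


def records_to_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = [{
        "subject_id": r.subject_id, "arm": r.arm, "histology": r.histology,
        "cycles": r.cycles,
        "ttf_weeks": "" if math.isnan(r.ttf_weeks) else f"{r.ttf_weeks:g}",
        "ttf_ongoing": int(r.ttf_ongoing),
        "os_weeks": "" if math.isnan(r.os_weeks) else f"{r.os_weeks:g}",
        "os_alive": int(r.os_alive),
        "pdl1_tps": "" if math.isnan(r.pdl1_tps) else f"{r.pdl1_tps:g}",
        "ra_codes": ";".join(r.ra_codes),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def _load_packaged(name: str) -> list[ClinicalRecord]:
    with resources.as_file(resources.files("nmrfinger.data") / name) as p:
        return load_clinical_csv(p)


def load_table1() -> list[ClinicalRecord]:
    """Nivolumab cohort (34 subjects), transcribed from the published table."""
    return _load_packaged("nivolumab_cohort.csv")


def load_table2() -> list[ClinicalRecord]:
    """Pembrolizumab cohort (19 subjects), transcribed from the published table."""
    return _load_packaged("pembrolizumab_cohort.csv")


def labels_frame(records: list[ClinicalRecord], rule: str = "second_RA") -> pd.DataFrame:
    """Per-subject labels plus +/-1 class coding (responder positive)."""
    labs = [classify(r, rule) for r in records]
    return pd.DataFrame({
        "subject_id": [l.subject_id for l in labs],
        "label": [l.label for l in labs],
        "y": [+1 if l.label == RESPONDER else -1 for l in labs],
    }).set_index("subject_id")
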