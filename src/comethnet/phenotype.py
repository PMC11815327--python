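"""Clinical case-ascertainment rules for AD psychosis phenotyping.

Dementia is called from cognition (MMSE < 24 or last CDR >= 1); AD from
neuropathology (CERAD neuritic plaque score >= 2 and Braak NFT stage >= III,
or Braak >= V when CERAD is unavailable).  Psychosis is harmonized across
two rating instruments by symptom *frequency* over the past month: the CERAD
Behavioral Rating Scale (BRS) codes times-per-month, with >= 3 counting as
recurrent; the Neuropsychiatric Inventory (NPI) codes an ordinal frequency
where level 2 ("about once a week") and above counts as recurrent (NPI
severity is ignored so the two instruments match).  AD donors with recurrent
delusions or hallucinations at any assessment are AD+P; donors scoring zero
on both symptoms at every available assessment are AD-P; symptomatic but
never recurrent donors are indeterminate and excluded from group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "Assessment",
    "ClinicalRecord",
    "classify_dementia",
    "classify_ad",
    "classify_psychosis",
    "classify_record",
    "harmonize_sample_sheet",
    "AD_P_PLUS",
    "AD_P_MINUS",
    "INDETERMINATE",
    "NOT_AD",
]

AD_P_PLUS = "AD_P_plus"
AD_P_MINUS = "AD_P_minus"
INDETERMINATE = "indeterminate"
NOT_AD = "not_ad"

# instrument-specific recurrence thresholds on the frequency rating
_RECURRENT_THRESHOLD = {
    "BRS": 3,  # at least 3 times in the past month
    "NPI": 2,  # ordinal level "about once a week" or more frequent
}


@dataclass
class Assessment:
    """One neuropsychiatric assessment time point."""

    instrument: str  # "BRS" or "NPI"
    delusion_freq: int
    hallucination_freq: int

    def __post_init__(self) -> None:
        if self.instrument not in _RECURRENT_THRESHOLD:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if self.delusion_freq < 0 or self.hallucination_freq < 0:
            raise ValueError("symptom frequencies must be non-negative")

    @property
    def recurrent(self) -> bool:
        thr = _RECURRENT_THRESHOLD[self.instrument]
        return self.delusion_freq >= thr or self.hallucination_freq >= thr

    @property
    def asymptomatic(self) -> bool:
        return self.delusion_freq == 0 and self.hallucination_freq == 0


@dataclass
class ClinicalRecord:
    """Clinical scores needed to call dementia / AD / psychosis status."""

    mmse: int | None = None
    cdr_last: float | None = None
    cerad: int | None = None
    braak: int = 0
    assessments: list[Assessment] = field(default_factory=list)


def classify_dementia(rec: ClinicalRecord) -> bool:
    """Dementia iff MMSE < 24 or last CDR >= 1 (a missing score counts false)."""
    if rec.mmse is None and rec.cdr_last is None:
        raise ValueError("cannot call dementia: both MMSE and CDR missing")
    by_mmse = rec.mmse is not None and rec.mmse < 24
    by_cdr = rec.cdr_last is not None and rec.cdr_last >= 1
    return by_mmse or by_cdr


def classify_ad(rec: ClinicalRecord, dementia: bool) -> bool:
    """AD iff dementia with CERAD >= 2 and Braak >= III, or Braak >= V when
    CERAD is unavailable."""
    if not dementia:
        return False
    if rec.cerad is not None:
        return rec.cerad >= 2 and rec.braak >= 3
    return rec.braak >= 5


def classify_psychosis(rec: ClinicalRecord, ad: bool) -> str:
    """Label AD donors AD+P / AD-P / indeterminate from symptom frequencies.

    AD+P: any assessment reaches the instrument's recurrence threshold.
    AD-P: every assessment scores 0 on both delusions and hallucinations.
    Otherwise indeterminate (symptomatic but never recurrent).
    """
    if not ad:
        return NOT_AD
    if not rec.assessments:
        raise ValueError("cannot call psychosis without assessments")
    if any(a.recurrent for a in rec.assessments):
        return AD_P_PLUS
    if all(a.asymptomatic for a in rec.assessments):
        return AD_P_MINUS
    return INDETERMINATE


def classify_record(rec: ClinicalRecord) -> dict:
    """Full phenotype call for one record: dementia, AD, psychosis label."""
    dementia = classify_dementia(rec)
    ad = classify_ad(rec, dementia)
    psychosis = classify_psychosis(rec, ad) if (ad and rec.assessments) else (
        NOT_AD if not ad else INDETERMINATE if not rec.assessments else None
    )
    if psychosis is None:  # pragma: no cover - unreachable
        psychosis = INDETERMINATE
    return {"dementia": dementia, "ad": ad, "psychosis": psychosis}


def _record_from_row(row: pd.Series) -> ClinicalRecord:
    def _opt(name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and pd.isna(v)) else v

    instrument = row["instrument"]
    assessments = []
    i = 1
    while f"delusion_freq_{i}" in row.index:
        d, h = row.get(f"delusion_freq_{i}"), row.get(f"hallucination_freq_{i}")
        if pd.notna(d) and pd.notna(h):
            assessments.append(Assessment(instrument, int(d), int(h)))
        i += 1
    mmse = _opt("mmse")
    cdr = _opt("cdr_last")
    cerad = _opt("cerad")
    return ClinicalRecord(
        mmse=None if mmse is None else int(mmse),
        cdr_last=None if cdr is None else float(cdr),
        cerad=None if cerad is None else int(cerad),
        braak=int(row["braak"]),
        assessments=assessments,
    )


def harmonize_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Apply the classification rules to a sample sheet.

    Expects columns ``mmse``, ``cdr_last``, ``cerad``, ``braak``,
    ``instrument`` and wide assessment columns ``delusion_freq_<i>`` /
    ``hallucination_freq_<i>``.  Returns a copy with ``dementia``, ``ad``
    and ``psychosis_status`` columns appended.
    """
    out = sheet.copy()
    calls = [classify_record(_record_from_row(row)) for _, row in sheet.iterrows()]
    out["dementia"] = [c["dementia"] for c in calls]
    out["ad"] = [c["ad"] for c in calls]
    out["psychosis_status"] = [c["psychosis"] for c in calls]
    return out


def psychosis_indicator(labels: Iterable[str]) -> pd.Series:
    """Map labels to a 0/1 trait (AD+P=1, AD-P=0, others NA)."""
    mapping = {AD_P_PLUS: 1, AD_P_MINUS: 0}
    return pd.Series([mapping.get(l, pd.NA) for l in labels], dtype="Int64")
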