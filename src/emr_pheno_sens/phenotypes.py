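"""Five HDL-C phenotype definitions over longitudinal lab data.

For each subject the adult (age >= 18 at draw) labs are summarized five
ways: the median of all values ("all"), the earliest and latest values
("first"/"last"), and medians of the strata before and from the first dated
evidence of lipid-lowering medication ("premed"/"postmed"). A subject with
no drug evidence contributes all adult labs to the pre-medication stratum
and none to the post stratum. A lab drawn the same day as the first
medication mention is classified post-medication, since it cannot be
confirmed medication-naive. Even-count medians are the mean of the two
middle order statistics; same-date first/last ties resolve to the minimum
value for "first" and the maximum for "last", because intraday ordering is
not reliable in clinical records.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from ._dates import eighteenth_birthday
from .lexicon import first_medication_date
from .types import LabMeasurement, MedicationMention

DEFINITIONS = ("all", "first", "last", "premed", "postmed")


def filter_adult_labs(
    labs: list[LabMeasurement], birth_date: date
) -> list[LabMeasurement]:
    """Keep labs drawn on or after the 18th birthday.

    A lab dated before birth indicates corrupted records and raises.
    """
    cutoff = eighteenth_birthday(birth_date)
    for lab in labs:
        if lab.lab_date < birth_date:
            raise ValueError(
                f"{lab.subject_id}: lab dated {lab.lab_date} precedes birth {birth_date}"
            )
    return [lab for lab in labs if lab.lab_date >= cutoff]


def all_hdl(labs: list[LabMeasurement]) -> float | None:
    """Median of all values; None on an empty set."""
    if not labs:
        return None
    return float(np.median([lab.value for lab in labs]))


def first_last_hdl(labs: list[LabMeasurement]) -> tuple[float | None, float | None]:
    if not labs:
        return None, None
    first_date = min(lab.lab_date for lab in labs)
    last_date = max(lab.lab_date for lab in labs)
    first = min(lab.value for lab in labs if lab.lab_date == first_date)
    last = max(lab.value for lab in labs if lab.lab_date == last_date)
    return float(first), float(last)


def pre_post_hdl(
    labs: list[LabMeasurement], med_start: date | None
) -> tuple[float | None, float | None]:
    """Medians of the pre- and post-medication strata.

    With no medication evidence the whole history is pre-medication.
    Same-day labs fall in the post stratum.
    """
    if med_start is None:
        return all_hdl(labs), None
    pre = [lab for lab in labs if lab.lab_date < med_start]
    post = [lab for lab in labs if lab.lab_date >= med_start]
    return all_hdl(pre), all_hdl(post)


def build_phenotype_table(
    demographics: pd.DataFrame,
    labs: pd.DataFrame,
    mentions: list[MedicationMention] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject phenotype table across the five definitions.

    Parameters
    ----------
    demographics : columns subject_id, sex, birth_date
    labs : columns subject_id, date, value (analyte/units ignored)
    mentions : medication mentions (list or frame from the note scan)

    Returns a frame indexed like demographics with columns all_hdl,
    first_hdl, last_hdl, premed_hdl, postmed_hdl and eligible-lab counts
    n_labs_all, n_labs_pre, n_labs_post. Subjects without adult labs keep
    every definition as missing.
    """
    med_dates = _first_mention_dates(mentions)
    known = set(demographics["subject_id"].astype(str))
    if unknown := set(med_dates) - known:
        raise ValueError(f"mentions reference unknown subject_ids: {sorted(unknown)[:5]}")

    labs = labs.copy()
    labs["subject_id"] = labs["subject_id"].astype(str)
    by_subject: dict[str, list[LabMeasurement]] = {}
    for row in labs.itertuples(index=False):
        by_subject.setdefault(row.subject_id, []).append(
            LabMeasurement(row.subject_id, _as_date(row.date), float(row.value))
        )

    rows = []
    for rec in demographics.itertuples(index=False):
        sid = str(rec.subject_id)
        adult = filter_adult_labs(by_subject.get(sid, []), _as_date(rec.birth_date))
        med_start = med_dates.get(sid)
        first, last = first_last_hdl(adult)
        pre, post = pre_post_hdl(adult, med_start)
        n_pre = (
            len(adult)
            if med_start is None
            else sum(lab.lab_date < med_start for lab in adult)
        )
        rows.append(
            {
                "subject_id": sid,
                "all_hdl": all_hdl(adult),
                "first_hdl": first,
                "last_hdl": last,
                "premed_hdl": pre,
                "postmed_hdl": post,
                "n_labs_all": len(adult),
                "n_labs_pre": n_pre,
                "n_labs_post": len(adult) - n_pre,
            }
        )
    table = pd.DataFrame(rows)
    value_cols = [f"{d}_hdl" for d in DEFINITIONS]
    table[value_cols] = table[value_cols].astype(float)
    return table


def _first_mention_dates(
    mentions: list[MedicationMention] | pd.DataFrame,
) -> dict[str, date]:
    if isinstance(mentions, pd.DataFrame):
        if mentions.empty:
            return {}
        df = mentions.assign(
            subject_id=mentions["subject_id"].astype(str),
            mention_date=mentions["mention_date"].map(_as_date),
        )
        return df.groupby("subject_id")["mention_date"].min().to_dict()
    out: dict[str, date] = {}
    for sid in {m.subject_id for m in mentions}:
        out[sid] = first_medication_date(mentions, sid)
    return out


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value)[:10])
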