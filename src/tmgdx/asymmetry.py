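"""Bilateral symmetric percentage differences and group summaries.

For a bilateral pair of parameter values (a, b) the asymmetry statistic is
the average of the two one-sided absolute percentage differences::

    diff% = ( |a − b| / b · 100  +  |b − a| / a · 100 ) / 2

In injured subjects the pair is (injured leg, contralateral leg); in
non-injured subjects it is (left, right).  The same statistic is applied to
Tc, Td and Dm.  Because the two one-sided percentages are averaged, the
statistic is symmetric in its arguments and invariant to a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PARAM_NAMES, SubjectRecord

__all__ = [
    "AsymmetryRecord",
    "symmetric_pct_diff",
    "subject_asymmetries",
    "cohort_asymmetries",
    "summarize_diffs",
]


@dataclass(frozen=True)
class AsymmetryRecord:
    """Per-subject symmetric percentage differences for Tc, Td and Dm."""

    subject_id: str
    group: str
    sex: str
    diff_td: float
    diff_tc: float
    diff_dm: float

    def __post_init__(self) -> None:
        for name in ("diff_td", "diff_tc", "diff_dm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def symmetric_pct_diff(a: float, b: float) -> float:
    """Average of the two one-sided absolute percentage differences.

    Requires a > 0 and b > 0.  Symmetric in (a, b), zero iff a == b, and
    invariant under a common positive rescaling of both arguments.
    """
    a = float(a)
    b = float(b)
    if not (a > 0 and b > 0) or not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError(f"inputs must be finite and positive, got ({a!r}, {b!r})")
    d = abs(a - b)
    return (d / b * 100.0 + d / a * 100.0) / 2.0


def subject_asymmetries(record: SubjectRecord) -> AsymmetryRecord:
    """Asymmetry statistics of one subject.

    Injured subjects pair the injured leg with the contralateral leg;
    non-injured subjects pair left with right.
    """
    if record.group == "injured":
        a, b = record.injured_leg, record.contralateral_leg
    else:
        a, b = record.left, record.right
    return AsymmetryRecord(
        subject_id=record.subject_id,
        group=record.group,
        sex=record.sex,
        diff_td=symmetric_pct_diff(a.td, b.td),
        diff_tc=symmetric_pct_diff(a.tc, b.tc),
        diff_dm=symmetric_pct_diff(a.dm, b.dm),
    )


def cohort_asymmetries(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-subject asymmetry table (subject_id, group, sex, diff_td/tc/dm)."""
    recs = [subject_asymmetries(r) for r in cohort]
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id, "group": r.group, "sex": r.sex,
                "diff_td": r.diff_td, "diff_tc": r.diff_tc, "diff_dm": r.diff_dm,
            }
            for r in recs
        ]
    )


def _kruskal(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal–Wallis H (mid-ranks, tie-corrected) and its chi-square p."""
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and len(set(
            map(len, groups))) == 1:
        # scipy raises on all-identical data; H is 0 by definition then
        if all((g == groups[0][0]).all() for g in groups):
            return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def summarize_diffs(diffs: pd.DataFrame) -> pd.DataFrame:
    """Group summary of asymmetry statistics with between-group tests.

    For each parameter and stratum (all subjects, males, females) the mean
    diff% of the injured and non-injured groups is reported with a
    Kruskal–Wallis comparison (H is asymptotically chi-square with
    df = groups − 1).  A final block compares female vs male injured
    subjects.  Returns a tidy frame with columns
    ``stratum, parameter, mean_injured, mean_noninjured, H, p``
    (the sex-contrast block reports female/male means in the two mean
    columns).

    Strata with fewer than two subjects in a compared cell are skipped with
    a warning.
    """
    rows = []
    strata = [("all", diffs), ("M", diffs[diffs["sex"] == "M"]),
              ("F", diffs[diffs["sex"] == "F"])]
    for label, sub in strata:
        inj = sub[sub["group"] == "injured"]
        non = sub[sub["group"] == "non_injured"]
        if len(inj) < 2 or len(non) < 2:
            warnings.warn(f"stratum {label!r} skipped: fewer than 2 subjects per group",
                          stacklevel=2)
            continue
        for p_name in PARAM_NAMES:
            col = f"diff_{p_name}"
            h, p = _kruskal(inj[col].to_numpy(), non[col].to_numpy())
            rows.append({
                "stratum": label, "parameter": p_name,
                "mean_injured": float(inj[col].mean()),
                "mean_noninjured": float(non[col].mean()),
                "H": h, "p": p,
            })
    # female vs male within the injured group
    inj = diffs[diffs["group"] == "injured"]
    f, m = inj[inj["sex"] == "F"], inj[inj["sex"] == "M"]
    if len(f) >= 2 and len(m) >= 2:
        for p_name in PARAM_NAMES:
            col = f"diff_{p_name}"
            h, p = _kruskal(f[col].to_numpy(), m[col].to_numpy())
            rows.append({
                "stratum": "injured_F_vs_M", "parameter": p_name,
                "mean_injured": float(f[col].mean()),
                "mean_noninjured": float(m[col].mean()),
                "H": h, "p": p,
            })
    else:
        warnings.warn("sex contrast skipped: fewer than 2 injured subjects per sex",
                      stacklevel=2)
    return pd.DataFrame(rows)
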