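"""Descriptive summaries of male-infant interaction data.

Covers the headline rates a field report quotes: how many male-infant
affiliations were observed, what share infants initiated, the
affiliative vs aggressive split, the average number of scans an infant
spent near a male with and without its mother (and the rounded ratio of
the two), the mirror-image ratio for time near the mother with and
without a male, and the share of fathers still resident when their
offspring turned one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def initiated_share(n_initiated: float, n_total: float) -> float:
    """Percentage share, rounded to one decimal (e.g. 63.5)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_initiated / n_total, 1)


def rounded_ratio(numerator: float, denominator: float) -> int:
    """Ratio of two means rounded to the nearest integer."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(round(numerator / denominator))


def summarize(
    interactions: pd.DataFrame,
    scans: pd.DataFrame,
    roster: pd.DataFrame,
    paternity: pd.DataFrame | None = None,
    memberships: pd.DataFrame | None = None,
) -> dict:
    """Compute the descriptive report from event and scan tables."""
    cls = roster.set_index("id")["cls"].to_dict()

    def is_mi(a: str, b: str) -> bool:
        ca, cb = cls.get(str(a)), cls.get(str(b))
        return {ca, cb} == {"adult_male", "infant"}

    mask = np.fromiter(
        (
            is_mi(a, b)
            for a, b in zip(interactions["initiator"], interactions["recipient"])
        ),
        dtype=bool,
        count=len(interactions),
    )
    mi = interactions[mask]
    aff = mi[mi["behavior_class"] == "affiliative"]
    n_total = len(aff)
    n_infant = int(
        sum(cls.get(str(i)) == "infant" for i in aff["initiator"])
    )
    out: dict = {
        "n_male_infant_affiliations": n_total,
        "n_infant_initiated": n_infant,
        "infant_initiated_share_pct": (
            initiated_share(n_infant, n_total) if n_total else np.nan
        ),
        "affiliative_share_pct": (
            round(100.0 * len(aff) / len(mi), 1) if len(mi) else np.nan
        ),
    }

    # per-infant scan totals (day-level columns are repeated per male row)
    daily = scans.drop_duplicates(subset=["infant", "day"])
    per_infant = daily.groupby("infant").agg(
        near_male_mother_present=("mother_any_male_scans", "sum"),
        near_male_total=("any_male_scans", "sum"),
        mother_total=("mother_scans", "sum"),
    )
    per_infant["near_male_mother_absent"] = (
        per_infant["near_male_total"] - per_infant["near_male_mother_present"]
    )
    per_infant["near_mother_male_absent"] = (
        per_infant["mother_total"] - per_infant["near_male_mother_present"]
    )
    mp = float(per_infant["near_male_mother_present"].mean())
    ma = float(per_infant["near_male_mother_absent"].mean())
    nm_p = float(per_infant["near_male_mother_present"].mean())
    nm_a = float(per_infant["near_mother_male_absent"].mean())
    out.update(
        {
            "mean_scans_near_male_mother_present": mp,
            "mean_scans_near_male_mother_absent": ma,
            "mother_absent_present_ratio": ma / mp if mp > 0 else np.nan,
            "mother_absent_present_ratio_rounded": (
                rounded_ratio(ma, mp) if mp > 0 else None
            ),
            "mean_scans_near_mother_male_present": nm_p,
            "mean_scans_near_mother_male_absent": nm_a,
            "male_absent_present_ratio": nm_a / nm_p if nm_p > 0 else np.nan,
            "male_absent_present_ratio_rounded": (
                rounded_ratio(nm_a, nm_p) if nm_p > 0 else None
            ),
        }
    )

    if paternity is not None and memberships is not None:
        birth = roster.set_index("id")["birth_day"].to_dict()
        group_of = roster.set_index("id")["group"].to_dict()
        present = total = 0
        for r in paternity.itertuples(index=False):
            if r.sire is None or (isinstance(r.sire, float) and np.isnan(r.sire)):
                continue
            day1 = birth.get(str(r.offspring), 0) + 365
            grp = group_of.get(str(r.offspring))
            spans = memberships[
                (memberships["id"] == r.sire) & (memberships["group"] == grp)
            ]
            total += 1
            if any(
                int(s.entry_day) <= day1 <= int(s.exit_day)
                for s in spans.itertuples(index=False)
            ):
                present += 1
        out["father_present_at_one_year_pct"] = (
            round(100.0 * present / total, 1) if total else np.nan
        )
    return out
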