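"""Assembly of the daily dyad-level analysis table.

The unit of analysis is one (male, infant) dyad on one focal-follow
day.  For each direction the binary response records whether at least
one qualifying affiliative event was initiated that day by the infant
(infant model) or by the male (male model).  Predictors are determined
daily: standardized male and mother dominance rank, the number of scans
with the mother within 2.5 m (log(x+1)-transformed), the running
proportion of mother-male affiliation out of their co-presence scans,
paternity, presence of the male at the infant's conception (male model
only), plus controls (infant sex and age, number of adult males,
seasonal sine/cosine of date, male tenure) and the log number of scans
that day as an offset.  All continuous predictors are z-scored over the
assembled table.

Focal days of an infant after its assigned sire left the group are
omitted, as are infants without an assigned sire.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nigra.errors import DataError

CONTINUOUS_PREDICTORS = {
    "male_rank": "z_male_rank",
    "mother_rank": "z_mother_rank",
    "log_mother_presence": "z_mother_presence",
    "mother_male_affiliation": "z_mother_male_affiliation",
    "infant_age": "z_infant_age",
    "n_males": "z_n_males",
    "tenure": "z_tenure",
}


def daily_response(
    interactions: pd.DataFrame, direction: str
) -> set[tuple[str, str, int]]:
    """Set of (infant, male, day) with >= 1 affiliative event in ``direction``.

    ``direction`` = ``"infant"`` keeps infant-initiated events,
    ``"male"`` male-initiated ones.  Only rows with
    ``behavior_class == "affiliative"`` qualify.
    """
    aff = interactions[interactions["behavior_class"] == "affiliative"]
    out = set()
    for row in aff.itertuples(index=False):
        if direction == "infant":
            out.add((str(row.initiator), str(row.recipient), int(row.day)))
        else:
            out.add((str(row.recipient), str(row.initiator), int(row.day)))
    return out


def running_bond(scans: pd.DataFrame) -> pd.Series:
    """Running mother-male affiliation proportion per (infant, male).

    Numerator: cumulative count (study start through the row's day,
    inclusive) of scans with an observed mother-male affiliation;
    denominator: cumulative count of scans with mother and male both
    within 2.5 m of the focal infant.  0 while the denominator is 0.
    """
    s = scans.sort_values(["infant", "male", "day"], kind="stable")
    g = s.groupby(["infant", "male"], sort=False)
    num = g["mm_affil_scans"].cumsum()
    den = g["mm_co_scans"].cumsum()
    prop = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return pd.Series(prop, index=s.index).reindex(scans.index)


def conception_presence(
    male: str,
    infant: str,
    memberships: pd.DataFrame,
    conceptions: pd.DataFrame,
) -> int:
    """1 iff the male's residence overlaps the infant's conception window
    in the mother's group."""
    row = conceptions[conceptions["infant"] == infant]
    if row.empty:
        return 0
    ws = int(row["window_start"].iloc[0])
    we = int(row["window_end"].iloc[0])
    grp = row["group"].iloc[0]
    mem = memberships[
        (memberships["id"] == male) & (memberships["group"] == grp)
    ]
    for r in mem.itertuples(index=False):
        if int(r.entry_day) <= we and int(r.exit_day) >= ws:
            return 1
    return 0


def assemble(
    direction: str,
    scans: pd.DataFrame,
    interactions: pd.DataFrame,
    ranks: pd.DataFrame,
    roster: pd.DataFrame,
    memberships: pd.DataFrame,
    conceptions: pd.DataFrame,
    paternity: pd.DataFrame,
    bond_window: str = "cumulative",
    constant_policy: str = "error",
) -> pd.DataFrame:
    """Build the dyad-day model table for one direction.

    Parameters
    ----------
    direction : "infant" or "male"
        Whose initiations form the response.  ``present_at_conception``
        is attached only for the male direction.
    paternity : DataFrame with columns ``offspring, sire``
        Assigned sires; infants with no assigned sire are dropped, and
        an infant's rows after its sire's emigration are omitted.
    bond_window : "cumulative" (default) or "daily"
        Aggregation of the mother-male affiliation proportion.
    constant_policy : "error" or "drop"
        What to do when a continuous predictor is constant study-wide
        (z-scoring undefined).
    """
    if direction not in ("infant", "male"):
        raise ValueError("direction must be 'infant' or 'male'")
    sire_of = {
        str(r.offspring): str(r.sire)
        for r in paternity.itertuples(index=False)
        if r.sire is not None and not (isinstance(r.sire, float) and np.isnan(r.sire))
    }
    roster_ix = roster.set_index("id")
    sex_of = roster_ix["sex"].to_dict()
    mother_of = roster_ix["mother_id"].to_dict()
    birth_of = roster_ix["birth_day"].to_dict()

    # sire residence end (in the infant's group) per infant
    father_until: dict[str, int] = {}
    for inf, sire in sire_of.items():
        grp = roster_ix.loc[inf, "group"]
        spans = memberships[
            (memberships["id"] == sire) & (memberships["group"] == grp)
        ]
        if not spans.empty:
            father_until[inf] = int(spans["exit_day"].max())
        else:
            father_until[inf] = -1

    rank_lookup = {
        (str(r.id), int(r.day)): float(r.standardized)
        for r in ranks.itertuples(index=False)
    }

    # adult males per (group, day) count and tenure spans
    cls = roster_ix["cls"].to_dict()
    male_mem = memberships[
        memberships["id"].map(lambda i: cls.get(str(i)) == "adult_male")
    ]
    spans_of: dict[str, list[tuple[str, int, int]]] = {}
    for r in male_mem.itertuples(index=False):
        spans_of.setdefault(str(r.id), []).append(
            (r.group, int(r.entry_day), int(r.exit_day))
        )

    def n_males_on(group: str, day: int) -> int:
        return sum(
            1
            for spans in spans_of.values()
            for g, lo, hi in spans
            if g == group and lo <= day <= hi
        )

    def tenure_on(male: str, group: str, day: int) -> float:
        for g, lo, hi in spans_of.get(male, ()):
            if g == group and lo <= day <= hi:
                return float(day - lo)
        return np.nan

    events = daily_response(interactions, direction)

    sc = scans.copy()
    if bond_window == "cumulative":
        sc["bond_prop"] = running_bond(sc)
    elif bond_window == "daily":
        sc["bond_prop"] = np.where(
            sc["mm_co_scans"] > 0, sc["mm_affil_scans"] / sc["mm_co_scans"], 0.0
        )
    else:
        raise ValueError("bond_window must be 'cumulative' or 'daily'")

    conc_cache: dict[tuple[str, str], int] = {}
    rows = []
    n_males_cache: dict[tuple[str, int], int] = {}
    for r in sc.itertuples(index=False):
        inf, male, day, grp = str(r.infant), str(r.male), int(r.day), r.group
        sire = sire_of.get(inf)
        if sire is None:
            continue  # paternity unresolved: infant excluded
        if day > father_until.get(inf, -1):
            continue  # father no longer in the group
        mrank = rank_lookup.get((male, day))
        mother = mother_of.get(inf)
        morank = rank_lookup.get((str(mother), day))
        if mrank is None or morank is None:
            continue
        key = (inf, male)
        if key not in conc_cache:
            conc_cache[key] = conception_presence(male, inf, memberships, conceptions)
        nm_key = (grp, day)
        if nm_key not in n_males_cache:
            n_males_cache[nm_key] = n_males_on(grp, day)
        doy = day % 365
        rows.append(
            {
                "infant": inf, "male": male, "dyad": f"{inf}|{male}", "day": day,
                "group": grp,
                "response": int((inf, male, day) in events),
                "male_rank": mrank, "mother_rank": morank,
                "mother_presence": int(r.mother_scans),
                "log_mother_presence": float(np.log1p(r.mother_scans)),
                "mother_male_affiliation": float(r.bond_prop),
                "paternity": int(male == sire),
                "conception": conc_cache[key],
                "infant_sex_male": int(sex_of.get(inf) == "M"),
                "infant_age": float(day - birth_of.get(inf, day)),
                "n_males": n_males_cache[nm_key],
                "season_sin": math_sin(doy),
                "season_cos": math_cos(doy),
                "tenure": tenure_on(male, grp, day),
                "obs_scans": int(r.obs_scans),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise DataError("assembled table is empty")
    table = table[table["obs_scans"] >= 1].reset_index(drop=True)
    table["log_obs"] = np.log(table["obs_scans"].astype(float))

    for raw, zname in CONTINUOUS_PREDICTORS.items():
        col = table[raw].astype(float)
        sd = col.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            if constant_policy == "error":
                raise DataError(
                    f"predictor {raw!r} is constant study-wide; cannot z-transform"
                )
            # "drop": omit the z column entirely; model specs filter on
            # column availability
            continue
        else:
            table[zname] = (col - col.mean()) / sd
    if direction == "infant":
        table = table.drop(columns=["conception"])
    return table


def math_sin(doy: int) -> float:
    return float(np.sin(2 * np.pi * doy / 365.25))


def math_cos(doy: int) -> float:
    return float(np.cos(2 * np.pi * doy / 365.25))
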