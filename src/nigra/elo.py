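"""Sequential Elo dominance ratings and daily within-sex standardization.

Dominance hierarchies are derived from dated decided agonistic
interactions (displacements, dyadic aggression with a clear winner).
Each individual starts at ``start_rating``; after every interaction the
winner gains ``k * (1 - p_win)`` points and the loser loses the same
amount, where ``p_win`` is the winner's expected score given the two
pre-interaction ratings.  Updates are therefore zero-sum: the total
rating mass of the population is conserved.

Because ratings drift over a study and males usually outrank all
females, raw scores are standardized per day, separately for each
(group, sex) stratum, to the range [0, 1] (min-max within stratum).
The standardized value is the dominance-rank covariate used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nigra.errors import DataError


@dataclass(frozen=True)
class EloConfig:
    """Update constants of the sequential Elo scheme.

    The conventional defaults of the animal-dominance Elo literature are
    used: everyone starts at 1000, k = 100, and the expected score is the
    base-10 logistic with scale 400.
    """

    start_rating: float = 1000.0
    k_factor: float = 100.0
    logistic_scale: float = 400.0

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise ValueError("k_factor must be > 0")
        if self.logistic_scale <= 0:
            raise ValueError("logistic_scale must be > 0")


def expected_score(r_a: float, r_b: float, config: EloConfig = EloConfig()) -> float:
    """Probability that the individual rated ``r_a`` beats ``r_b``.

    ``1 / (1 + 10**((r_b - r_a) / scale))``; symmetric so that
    ``expected_score(a, b) + expected_score(b, a) == 1``.
    """
    return 1.0 / (1.0 + 10.0 ** ((r_b - r_a) / config.logistic_scale))


def update_ratings(
    events: pd.DataFrame,
    memberships: pd.DataFrame,
    config: EloConfig = EloConfig(),
    validate_residence: bool = True,
) -> pd.DataFrame:
    """Process dated agonistic events into an event-level rating timeline.

    Parameters
    ----------
    events : DataFrame with columns ``day, group, winner, loser``
        Decided agonistic interactions.  Processed in ``day`` order;
        ties within a day are broken by input order.
    memberships : DataFrame with columns ``id, group, entry_day, exit_day``
        Residence intervals (inclusive).  Used to check that contestants
        were co-resident in the stated group on the event day.

    Returns
    -------
    DataFrame with one row per event: ``day, group, winner, loser,
    winner_pre, loser_pre, winner_post, loser_post``.
    """
    required = {"day", "group", "winner", "loser"}
    missing = required - set(events.columns)
    if missing:
        raise DataError(f"events table missing columns: {sorted(missing)}")

    if validate_residence:
        _check_residence(events, memberships)

    ev = events.sort_values("day", kind="stable").reset_index(drop=True)
    ratings: dict[str, float] = {}
    rows = []
    for day, group, winner, loser in zip(ev["day"], ev["group"], ev["winner"], ev["loser"]):
        rw = ratings.get(winner, config.start_rating)
        rl = ratings.get(loser, config.start_rating)
        p_win = expected_score(rw, rl, config)
        delta = config.k_factor * (1.0 - p_win)
        ratings[winner] = rw + delta
        ratings[loser] = rl - delta
        rows.append((day, group, winner, loser, rw, rl, ratings[winner], ratings[loser]))
    return pd.DataFrame(
        rows,
        columns=[
            "day", "group", "winner", "loser",
            "winner_pre", "loser_pre", "winner_post", "loser_post",
        ],
    )


def _check_residence(events: pd.DataFrame, memberships: pd.DataFrame) -> None:
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for row in memberships.itertuples(index=False):
        intervals.setdefault(str(row.id), []).append(
            (row.group, int(row.entry_day), int(row.exit_day))
        )

    def resident(ind: str, group: str, day: int) -> bool:
        return any(
            g == group and lo <= day <= hi for g, lo, hi in intervals.get(str(ind), ())
        )

    bad = [
        i
        for i, row in enumerate(events.itertuples(index=False))
        if not (resident(row.winner, row.group, int(row.day))
                and resident(row.loser, row.group, int(row.day)))
    ]
    if bad:
        raise DataError(
            f"{len(bad)} event(s) involve individuals not co-resident in the "
            f"stated group on the event day; offending row indices: {bad[:20]}"
        )


def rating_on_days(
    timeline: pd.DataFrame,
    memberships: pd.DataFrame,
    roster: pd.DataFrame,
    days: np.ndarray | None = None,
    config: EloConfig = EloConfig(),
    adult_only: bool = True,
) -> pd.DataFrame:
    """Expand an event timeline to one raw rating per (individual, day).

    An individual's rating changes only on days it has an event and is
    carried forward between events; individuals carry ``start_rating``
    from their entry day until their first event.  Rows are emitted only
    for days within the individual's residence.

    Returns a DataFrame ``id, day, group, sex, rating``.
    """
    sex = roster.set_index("id")["sex"].to_dict()
    cls = roster.set_index("id")["cls"].to_dict()

    # last post-event rating per individual per day
    per_ind: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    updates: dict[str, list[tuple[int, float]]] = {}
    for row in timeline.itertuples(index=False):
        updates.setdefault(str(row.winner), []).append((int(row.day), row.winner_post))
        updates.setdefault(str(row.loser), []).append((int(row.day), row.loser_post))
    for ind, ups in updates.items():
        d = np.array([u[0] for u in ups])
        r = np.array([u[1] for u in ups])
        per_ind[ind] = (d, r)

    out_id, out_day, out_group, out_sex, out_rating = [], [], [], [], []
    for row in memberships.itertuples(index=False):
        ind = str(row.id)
        if adult_only and cls.get(ind) not in ("adult_male", "adult_female"):
            continue
        lo, hi = int(row.entry_day), int(row.exit_day)
        span = np.arange(lo, hi + 1)
        if days is not None:
            span = span[np.isin(span, days)]
        if span.size == 0:
            continue
        if ind in per_ind:
            ud, ur = per_ind[ind]
            idx = np.searchsorted(ud, span, side="right") - 1
            ratings = np.where(idx >= 0, ur[np.clip(idx, 0, None)], config.start_rating)
        else:
            ratings = np.full(span.size, config.start_rating)
        out_id.extend([ind] * span.size)
        out_day.extend(span.tolist())
        out_group.extend([row.group] * span.size)
        out_sex.extend([sex.get(ind, "unknown")] * span.size)
        out_rating.extend(ratings.tolist())
    return pd.DataFrame(
        {"id": out_id, "day": out_day, "group": out_group, "sex": out_sex,
         "rating": out_rating}
    )


def standardize_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Min-max standardize raw ratings within each (group, sex, day) stratum.

    On each stratum with at least two distinct ratings the lowest-rated
    individual maps to 0 and the highest to 1.  Degenerate strata (a
    single resident, or all ratings tied) map to 0.5: the midpoint avoids
    manufacturing spuriously extreme ranks out of no information.
    """
    out = daily.copy()
    grp = out.groupby(["group", "sex", "day"])["rating"]
    lo = grp.transform("min")
    hi = grp.transform("max")
    span = hi - lo
    std = np.where(span > 0, (out["rating"] - lo) / np.where(span > 0, span, 1.0), 0.5)
    out["standardized"] = std
    return out


def daily_ranks(
    events: pd.DataFrame,
    memberships: pd.DataFrame,
    roster: pd.DataFrame,
    config: EloConfig = EloConfig(),
    days: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full Elo stage: events -> per-day standardized ranks for all adults."""
    timeline = update_ratings(events, memberships, config)
    daily = rating_on_days(timeline, memberships, roster, days=days, config=config)
    return standardize_daily(daily)
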