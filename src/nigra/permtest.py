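"""Dyadic permutation tests for non-random partner preference.

For each group and each direction (infant-initiated or male-initiated)
the affiliative interaction events are cross-tabulated into a
contingency table of initiators x recipients, restricted to adult males
present for the entire study period.  The chi-square statistic of the
observed table is compared with its permutation null distribution,
obtained by shuffling the initiator labels across events (which
preserves every initiator's and every recipient's event total).  The
observed data count as one permutation, so the p-value is bounded below
by ``1 / n_perm``.

Because the chi-square statistic is non-directional, counting the upper
tail (permuted chi-square at least as large as observed) is the
two-sided test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nigra.errors import DataError


@dataclass
class DyadTable:
    group: str
    direction: str  # "infant" (infant->male) or "male" (male->infant)
    rows: list[str]  # initiator ids
    cols: list[str]  # recipient ids
    counts: np.ndarray  # (n_rows, n_cols) integer counts
    events: pd.DataFrame = field(repr=False, default=None)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PermutationResult:
    table: DyadTable
    observed_chi2: float
    n_permutations: int
    p_value: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray


def full_period_males(
    memberships: pd.DataFrame, roster: pd.DataFrame, group: str,
    study_start: int, study_end: int,
) -> set[str]:
    """Adult males resident in ``group`` over the whole study period."""
    cls = roster.set_index("id")["cls"].to_dict()
    out = set()
    for row in memberships.itertuples(index=False):
        if (
            row.group == group
            and cls.get(str(row.id)) == "adult_male"
            and int(row.entry_day) <= study_start
            and int(row.exit_day) >= study_end
        ):
            out.add(str(row.id))
    return out


def build_table(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    memberships: pd.DataFrame,
    group: str,
    direction: str,
    study_start: int,
    study_end: int,
    affiliative_only: bool = True,
) -> DyadTable:
    """Cross-tabulate affiliative events for one group and direction.

    ``events`` columns: ``day, group, initiator, recipient, behavior,
    behavior_class``.  ``direction`` selects which side initiates:
    ``"infant"`` keeps infant-initiated events (rows = infants,
    columns = males), ``"male"`` the reverse.  Adult males not present
    for the entire study period are excluded.
    """
    if direction not in ("infant", "male"):
        raise ValueError("direction must be 'infant' or 'male'")
    cls = roster.set_index("id")["cls"].to_dict()
    sub = events[events["group"] == group]
    if affiliative_only and "behavior_class" in sub.columns:
        sub = sub[sub["behavior_class"] == "affiliative"]

    males = full_period_males(memberships, roster, group, study_start, study_end)

    def is_infant(x: str) -> bool:
        return cls.get(str(x)) == "infant"

    if direction == "infant":
        keep = sub[
            sub["initiator"].map(is_infant) & sub["recipient"].astype(str).isin(males)
        ]
        row_ids = sorted(keep["initiator"].astype(str).unique())
        col_ids = sorted(males)
    else:
        keep = sub[
            sub["initiator"].astype(str).isin(males) & sub["recipient"].map(is_infant)
        ]
        row_ids = sorted(males)
        col_ids = sorted(keep["recipient"].astype(str).unique())

    if keep.empty:
        raise DataError(
            f"no qualifying events for group={group!r} direction={direction!r} "
            "after the full-presence filter"
        )
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: i for i, c in enumerate(col_ids)}
    counts = np.zeros((len(row_ids), len(col_ids)), dtype=np.int64)
    np.add.at(
        counts,
        (
            keep["initiator"].astype(str).map(ri).to_numpy(),
            keep["recipient"].astype(str).map(ci).to_numpy(),
        ),
        1,
    )
    return DyadTable(group, direction, row_ids, col_ids, counts, events=keep)


def _drop_empty(counts: np.ndarray) -> np.ndarray:
    """Drop all-zero rows/columns (individuals with no events)."""
    counts = counts[counts.sum(axis=1) > 0]
    counts = counts[:, counts.sum(axis=0) > 0]
    return counts


def chi_square(counts: np.ndarray) -> float:
    """Pearson chi-square of a contingency table against independence.

    All-zero rows and columns are dropped first; expected counts come
    from the row/column marginals.
    """
    counts = _drop_empty(np.asarray(counts, dtype=float))
    n = counts.sum()
    if n < 1:
        raise DataError("empty table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    return float(np.sum((counts - expected) ** 2 / expected))


def permutation_test(
    table: DyadTable,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Initiator-label permutation test of the dyadic table.

    Each permutation shuffles the initiator column of the event list
    (preserving every initiator total and every recipient total) and
    recomputes the chi-square; the observed data count as one of the
    ``n_perm`` permutations, so
    ``p = #(chi2_perm >= chi2_obs) / n_perm >= 1 / n_perm``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
    rng = np.random.default_rng(seed) if rng is None else rng

    ev = table.events
    init = ev["initiator"].astype(str).to_numpy()
    recip = ev["recipient"].astype(str).to_numpy()
    init_ids, i_idx = np.unique(init, return_inverse=True)
    recip_ids, r_idx = np.unique(recip, return_inverse=True)
    nr, nc = len(init_ids), len(recip_ids)
    if nr < 2 or nc < 2:
        raise DataError("degenerate table: need >= 2 initiators and >= 2 recipients")

    def table_from(ii: np.ndarray) -> np.ndarray:
        return np.bincount(ii * nc + r_idx, minlength=nr * nc).reshape(nr, nc)

    counts = table_from(i_idx).astype(float)
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n
    observed = float(np.sum((counts - expected) ** 2 / expected))

    # marginals are invariant under initiator shuffles, so E is fixed
    at_least = 1  # the original data
    for _ in range(n_perm - 1):
        perm_counts = table_from(rng.permutation(i_idx)).astype(float)
        stat = float(np.sum((perm_counts - expected) ** 2 / expected))
        if stat >= observed - 1e-12:
            at_least += 1
    p = at_least / n_perm

    row_prop = row / n
    col_prop = col / n
    denom = np.sqrt(expected * np.outer(1 - row_prop, 1 - col_prop))
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(denom > 0, (counts - expected) / denom, 0.0)

    # map back into the full table layout (rows/cols with zero events kept at 0)
    full_exp = np.zeros_like(table.counts, dtype=float)
    full_adj = np.zeros_like(table.counts, dtype=float)
    rmap = {r: i for i, r in enumerate(table.rows)}
    cmap = {c: i for i, c in enumerate(table.cols)}
    for a, rid in enumerate(init_ids):
        for b, cid in enumerate(recip_ids):
            if rid in rmap and cid in cmap:
                full_exp[rmap[rid], cmap[cid]] = expected[a, b]
                full_adj[rmap[rid], cmap[cid]] = adj[a, b]

    return PermutationResult(
        table=table, observed_chi2=observed, n_permutations=n_perm,
        p_value=p, expected=full_exp, adjusted_residuals=full_adj,
    )


def preferred_partners(
    result: PermutationResult, z_threshold: float = 1.96
) -> pd.DataFrame:
    """Flag dyads whose adjusted standardized residual exceeds ``z_threshold``.

    Returns one row per (initiator, recipient) cell with the residual
    and a ``preferred`` flag.  Only meaningful when the permutation test
    itself is significant.
    """
    tab = result.table
    rows = []
    for i, rid in enumerate(tab.rows):
        for j, cid in enumerate(tab.cols):
            z = result.adjusted_residuals[i, j]
            rows.append(
                (rid, cid, int(tab.counts[i, j]), result.expected[i, j], z,
                 bool(z > z_threshold))
            )
    return pd.DataFrame(
        rows,
        columns=["initiator", "recipient", "observed", "expected",
                 "adjusted_residual", "preferred"],
    )
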