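"""Multi-tube consensus genotyping and microsatellite locus statistics.

Genotypes from non-invasive (fecal) DNA are unreliable in any single
PCR because of allelic dropout and misprints, so each individual x locus
is amplified in several independent replicates and a consensus call is
accepted only under conservative confirmation rules:

- *heterozygote*: both alleles confirmed in at least two replicates
  each, with at least four replicates run in total;
- *homozygote*: a single allele seen in at least six independent
  replicates while no second allele was ever confirmed twice;
- conflicting patterns are taken to replication extension (up to 11
  replicates); after extension the same two rules are applied in
  priority order -- heterozygote if two alleles each reach two
  confirmations, else homozygote if the majority allele reaches six
  confirmations and any minority allele was seen only once -- otherwise
  the call is left unresolved.

From the accepted calls the module computes per-locus allele
frequencies (gene counting), observed heterozygosity, polymorphic
information content (PIC), a Monte-Carlo exact Hardy-Weinberg test,
a null-allele index, and the (sibling) probability of identity used to
decide how many loci are needed for reliable individual identification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nigra.errors import ContaminationError, InsufficientDataError


@dataclass(frozen=True)
class ConsensusGenotype:
    individual: str
    locus: str
    call: tuple[str, str] | None  # unordered pair, sorted; None if missing
    status: str  # het_confirmed | hom_confirmed | unresolved

    @property
    def is_het(self) -> bool:
        return self.call is not None and self.call[0] != self.call[1]


@dataclass
class LocusStats:
    locus: str
    freqs: dict[str, float]
    n_called: int
    n_alleles: int
    ho: float
    he: float
    pic: float
    hwe_p: float | None = None
    null_allele: float | None = None
    pid: float = field(default=np.nan)
    pidsib: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def call_consensus(
    replicates: list[tuple[str, ...] | frozenset | set | list],
    min_het_reps: int = 2,
    min_total_het: int = 4,
    min_hom_reps: int = 6,
) -> tuple[tuple[str, str] | None, str]:
    """Call one individual x locus from its replicate PCR allele sets.

    Each replicate is a set of 1 or 2 allele labels.  Returns
    ``(call, status)``; ``call`` is a sorted allele pair or ``None``.

    Raises
    ------
    ContaminationError
        if more than two distinct alleles are each confirmed (seen in
        >= ``min_het_reps`` replicates).
    """
    if not replicates:
        raise InsufficientDataError("no replicates supplied")
    counts: Counter[str] = Counter()
    for rep in replicates:
        alleles = set(rep)
        if not 1 <= len(alleles) <= 2:
            raise ValueError(f"replicate must carry 1 or 2 alleles, got {sorted(alleles)}")
        for a in alleles:
            counts[a] += 1

    confirmed = [a for a, c in counts.items() if c >= min_het_reps]
    if len(confirmed) > 2:
        raise ContaminationError(
            f"{len(confirmed)} alleles each confirmed >= {min_het_reps} times: "
            f"{sorted(confirmed)}"
        )

    n_reps = len(replicates)
    if len(confirmed) == 2 and n_reps >= min_total_het:
        a, b = sorted(confirmed)
        return (a, b), "het_confirmed"
    if len(confirmed) == 1:
        a = confirmed[0]
        others_max = max((c for al, c in counts.items() if al != a), default=0)
        if counts[a] >= min_hom_reps and others_max <= 1:
            return (a, a), "hom_confirmed"
    return None, "unresolved"


def call_all(
    pcr: pd.DataFrame,
    min_het_reps: int = 2,
    min_total_het: int = 4,
    min_hom_reps: int = 6,
    on_contamination: str = "raise",
) -> pd.DataFrame:
    """Consensus-call every (individual, locus) in a replicate table.

    ``pcr`` columns: ``individual, locus, replicate, allele1, allele2``
    (allele2 may equal allele1 or be empty/NaN for single-allele
    replicates).  Returns ``individual, locus, allele1, allele2, status``
    with NaN alleles for unresolved calls.
    """
    rows = []
    for (ind, locus), sub in pcr.groupby(["individual", "locus"], sort=True):
        reps = []
        for r in sub.itertuples(index=False):
            alleles = {str(r.allele1)}
            a2 = getattr(r, "allele2", None)
            if a2 is not None and not (isinstance(a2, float) and np.isnan(a2)) and str(a2) != "":
                alleles.add(str(a2))
            reps.append(alleles)
        try:
            call, status = call_consensus(reps, min_het_reps, min_total_het, min_hom_reps)
        except ContaminationError:
            if on_contamination == "raise":
                raise
            call, status = None, "contaminated"
        a1, a2 = (call if call is not None else (None, None))
        rows.append((ind, locus, a1, a2, status))
    return pd.DataFrame(rows, columns=["individual", "locus", "allele1", "allele2", "status"])


# ---------------------------------------------------------------------------
# locus statistics
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Gene-count allele frequencies per locus from called genotypes.

    Each called individual contributes two allele copies.  Loci with no
    calls are excluded.  ``genotypes`` needs columns
    ``locus, allele1, allele2`` (rows with missing alleles are skipped).
    """
    out: dict[str, dict[str, float]] = {}
    called = genotypes.dropna(subset=["allele1", "allele2"])
    for locus, sub in called.groupby("locus", sort=True):
        counts: Counter[str] = Counter()
        for a1, a2 in zip(sub["allele1"], sub["allele2"]):
            counts[str(a1)] += 1
            counts[str(a2)] += 1
        total = sum(counts.values())
        if total:
            out[locus] = {a: c / total for a, c in sorted(counts.items())}
    return out


def pic_from_freqs(p: np.ndarray) -> float:
    """Polymorphic information content: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(p, dtype=float)
    sum_p2 = float(np.sum(p**2))
    sum_p4 = float(np.sum(p**4))
    cross = (sum_p2**2 - sum_p4)  # = sum_{i != j} p_i^2 p_j^2
    return 1.0 - sum_p2 - cross


def null_allele_index(ho: float, he: float) -> float | None:
    """(He - Ho) / (He + Ho); positive values flag possible null alleles.

    Undefined (returns None) for He = 0.
    """
    if he == 0:
        return None
    return (he - ho) / (he + ho)


def pid_locus(p: np.ndarray) -> tuple[float, float]:
    """Per-locus probability of identity for unrelated pairs and full sibs.

    PID      = 2 (sum p_i^2)^2 - sum p_i^4
    PIDsib   = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4
    """
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    pid = 2.0 * s2**2 - s4
    pidsib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return pid, pidsib


def pid(freqs: dict[str, dict[str, float]], loci: list[str] | None = None) -> tuple[float, float]:
    """Multi-locus PID and PIDsib: products of the per-locus values."""
    loci = list(freqs) if loci is None else loci
    pid_total, sib_total = 1.0, 1.0
    for locus in loci:
        p = np.array(list(freqs[locus].values()))
        a, b = pid_locus(p)
        pid_total *= a
        sib_total *= b
    return pid_total, sib_total


def min_loci_for_identity(
    freqs: dict[str, dict[str, float]], threshold: float
) -> tuple[int, float, bool]:
    """Smallest number of loci whose combined PIDsib falls below ``threshold``.

    Loci are taken most-informative first (smallest per-locus PIDsib).
    Returns ``(k, cumulative_pidsib, attained)``; when the threshold is
    unattainable even with all loci, ``k`` is the total locus count and
    ``attained`` is False.
    """
    sibs = sorted(
        pid_locus(np.array(list(f.values())))[1] for f in freqs.values()
    )
    cum = 1.0
    for k, s in enumerate(sibs, start=1):
        cum *= s
        if cum <= threshold:
            return k, cum, True
    return len(sibs), cum, False


def hwe_test(
    genotypes: pd.DataFrame,
    locus: str,
    n_shuffles: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one locus.

    The statistic is the chi-square distance between observed genotype
    counts and the Hardy-Weinberg expectation computed from the sample
    allele frequencies.  The null distribution is generated by shuffling
    the 2N allele copies among individuals and re-pairing them; the
    observed arrangement counts as one arrangement, so p is in (0, 1].
    Monomorphic loci return p = 1 by convention.
    """
    rng = np.random.default_rng() if rng is None else rng
    sub = genotypes[(genotypes["locus"] == locus)].dropna(subset=["allele1", "allele2"])
    n = len(sub)
    if n < 5:
        raise InsufficientDataError(f"locus {locus}: {n} called genotypes (< 5)")
    alleles = sorted(set(sub["allele1"].astype(str)) | set(sub["allele2"].astype(str)))
    if len(alleles) == 1:
        return 1.0
    idx = {a: i for i, a in enumerate(alleles)}
    a1 = np.array([idx[str(a)] for a in sub["allele1"]])
    a2 = np.array([idx[str(a)] for a in sub["allele2"]])
    k = len(alleles)

    def stat(x1: np.ndarray, x2: np.ndarray) -> float:
        lo = np.minimum(x1, x2)
        hi = np.maximum(x1, x2)
        obs = np.zeros((k, k))
        np.add.at(obs, (lo, hi), 1.0)
        counts = np.bincount(np.concatenate([x1, x2]), minlength=k).astype(float)
        p = counts / counts.sum()
        exp = np.zeros((k, k))
        for i in range(k):
            exp[i, i] = n * p[i] ** 2
            for j in range(i + 1, k):
                exp[i, j] = 2 * n * p[i] * p[j]
        mask = exp > 0
        return float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))

    observed = stat(a1, a2)
    pool = np.concatenate([a1, a2])
    count = 1  # the observed arrangement
    for _ in range(n_shuffles):
        perm = rng.permutation(pool)
        if stat(perm[:n], perm[n:]) >= observed - 1e-12:
            count += 1
    return count / (n_shuffles + 1)


def locus_summary(
    genotypes: pd.DataFrame,
    hwe_shuffles: int = 2000,
    rng: np.random.Generator | None = None,
    run_hwe: bool = True,
) -> list[LocusStats]:
    """Per-locus statistics from a called genotype table."""
    rng = np.random.default_rng() if rng is None else rng
    freqs = allele_frequencies(genotypes)
    called = genotypes.dropna(subset=["allele1", "allele2"])
    out = []
    for locus, fr in freqs.items():
        sub = called[called["locus"] == locus]
        p = np.array(list(fr.values()))
        ho = float(np.mean(sub["allele1"].astype(str).values != sub["allele2"].astype(str).values))
        he = 1.0 - float(np.sum(p**2))
        pic = pic_from_freqs(p)
        pid_l, pidsib_l = pid_locus(p)
        hwe_p = None
        if run_hwe and len(sub) >= 5:
            hwe_p = hwe_test(genotypes, locus, n_shuffles=hwe_shuffles, rng=rng)
        out.append(
            LocusStats(
                locus=locus, freqs=fr, n_called=len(sub), n_alleles=len(fr),
                ho=ho, he=he, pic=pic, hwe_p=hwe_p,
                null_allele=null_allele_index(ho, he),
                pid=pid_l, pidsib=pidsib_l,
            )
        )
    return out


def locus_summary_frame(stats: list[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [s.locus for s in stats],
            "n_called": [s.n_called for s in stats],
            "n_alleles": [s.n_alleles for s in stats],
            "ho": [s.ho for s in stats],
            "he": [s.he for s in stats],
            "pic": [s.pic for s in stats],
            "hwe_p": [s.hwe_p for s in stats],
            "null_allele": [s.null_allele for s in stats],
            "pid": [s.pid for s in stats],
            "pidsib": [s.pidsib for s in stats],
        }
    )
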