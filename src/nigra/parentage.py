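"""Exclusion-based paternity assignment with likelihood (LOD) support.

Maternity (known from the field) is first verified genetically: mother
and offspring must share at least one allele at every locus compared,
over a minimum of eight jointly called loci.  Candidate sires are then
screened locus by locus against the mother-offspring pair: at each
locus the offspring's paternal allele set is deduced (the offspring
alleles not explainable by the mother; ambiguous when both offspring
alleles occur in the mother), and a candidate that carries none of the
possible paternal alleles accrues one mismatch.

Assignment categories, in order of precedence:

- ``strict``    -- a single zero-mismatch candidate, all others excluded
  at two or more loci;
- ``standard``  -- a single zero-mismatch candidate, all others excluded
  at one or more loci;
- ``relaxed``   -- no zero-mismatch candidate, exactly one candidate
  with a single mismatch and all others at two or more;
- ``tiebreak_conception`` -- several zero-mismatch candidates, exactly
  one of which was resident in the offspring's group during the
  conception window;
- ``unresolved`` otherwise.

Each assignment is additionally supported by a LOD score -- the natural
log ratio of the probability of the offspring genotype given the
candidate as sire over its probability given a random sire drawn from
the population allele frequencies -- computed under a simple
per-genotype error model, and by a simulation-based confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nigra.errors import InsufficientDataError

Genotype = dict[str, tuple[str, str]]  # locus -> sorted allele pair


@dataclass
class MismatchProfile:
    offspring: str
    candidate: str
    loci_compared: int
    mismatches: int
    mismatching_loci: list[str] = field(default_factory=list)


@dataclass
class PaternityAssignment:
    offspring: str
    sire: str | None
    category: str
    lod: float | None = None
    confidence: float | None = None
    profiles: list[MismatchProfile] = field(default_factory=list)


def genotype_table_to_dict(genotypes: pd.DataFrame) -> dict[str, Genotype]:
    """``genotypes.csv`` frame -> {individual: {locus: (a1, a2)}}."""
    out: dict[str, Genotype] = {}
    called = genotypes.dropna(subset=["allele1", "allele2"])
    for row in called.itertuples(index=False):
        pair = tuple(sorted((str(row.allele1), str(row.allele2))))
        out.setdefault(str(row.individual), {})[str(row.locus)] = pair
    return out


# ---------------------------------------------------------------------------
# exclusion
# ---------------------------------------------------------------------------

def confirm_maternity(
    mother: Genotype, offspring: Genotype, min_shared_loci: int = 8
) -> tuple[bool, list[str]]:
    """True iff mother and offspring share >= 1 allele at every shared locus.

    Loci missing in either genotype are skipped and do not count as
    compared.  Raises if fewer than ``min_shared_loci`` loci are jointly
    called.
    """
    shared = sorted(set(mother) & set(offspring))
    if len(shared) < min_shared_loci:
        raise InsufficientDataError(
            f"only {len(shared)} jointly called loci (< {min_shared_loci})"
        )
    bad = [loc for loc in shared if not set(mother[loc]) & set(offspring[loc])]
    return (not bad), bad


def _locus_mismatch(mother: tuple[str, str], off: tuple[str, str],
                    cand: tuple[str, str]) -> bool:
    """True iff the candidate is Mendelian-incompatible at this locus.

    The paternal allele must complete the offspring genotype given a
    maternal contribution: compatible iff some (maternal allele m in
    mother, paternal allele f in candidate) has {m, f} == offspring pair
    as a multiset.
    """
    off_sorted = tuple(sorted(off))
    for m in set(mother):
        for f in set(cand):
            if tuple(sorted((m, f))) == off_sorted:
                return False
    return True


def paternal_mismatches(
    mother: Genotype, offspring: Genotype, candidate: Genotype,
    offspring_id: str = "", candidate_id: str = "",
) -> MismatchProfile:
    """Count loci at which a candidate male is excluded as the sire.

    Loci with a missing genotype in mother, offspring or candidate are
    skipped and not counted as compared.
    """
    shared = sorted(set(mother) & set(offspring) & set(candidate))
    bad = [
        loc for loc in shared
        if _locus_mismatch(mother[loc], offspring[loc], candidate[loc])
    ]
    return MismatchProfile(
        offspring=offspring_id, candidate=candidate_id,
        loci_compared=len(shared), mismatches=len(bad), mismatching_loci=bad,
    )


def assign_paternity(
    profiles: list[MismatchProfile],
    present_at_conception: dict[str, bool] | None = None,
) -> PaternityAssignment:
    """Assign a sire from candidate mismatch profiles.

    ``present_at_conception`` maps candidate id -> whether the male was
    resident in the offspring's group during the conception window; it
    is only consulted to break ties among zero-mismatch candidates.
    """
    if not profiles:
        raise InsufficientDataError("no candidate profiles")
    offspring = profiles[0].offspring
    zero = [p for p in profiles if p.mismatches == 0]
    one = [p for p in profiles if p.mismatches == 1]

    if len(zero) == 1:
        others = [p for p in profiles if p is not zero[0]]
        if all(p.mismatches >= 2 for p in others):
            cat = "strict"
        elif all(p.mismatches >= 1 for p in others):
            cat = "standard"
        else:  # unreachable: others have >= 1 mismatch by construction
            cat = "standard"
        return PaternityAssignment(offspring, zero[0].candidate, cat, profiles=profiles)

    if len(zero) == 0 and len(one) == 1:
        others = [p for p in profiles if p is not one[0]]
        if all(p.mismatches >= 2 for p in others):
            return PaternityAssignment(
                offspring, one[0].candidate, "relaxed", profiles=profiles
            )

    if len(zero) >= 2 and present_at_conception is not None:
        present = [p for p in zero if present_at_conception.get(p.candidate, False)]
        if len(present) == 1:
            return PaternityAssignment(
                offspring, present[0].candidate, "tiebreak_conception",
                profiles=profiles,
            )

    return PaternityAssignment(offspring, None, "unresolved", profiles=profiles)


# ---------------------------------------------------------------------------
# likelihood (LOD) support
# ---------------------------------------------------------------------------

def _trans_prob(
    off: tuple[str, str],
    mother: tuple[str, str] | None,
    father: tuple[str, str] | None,
    freqs: dict[str, float],
) -> float:
    """P(offspring pair | parental genotypes), unknown parents drawn from HW.

    ``None`` for a parent means a random Hardy-Weinberg parent, i.e. its
    transmitted allele is drawn from the allele frequencies.
    """
    def contrib(parent: tuple[str, str] | None) -> dict[str, float]:
        if parent is None:
            return dict(freqs)
        out: dict[str, float] = {}
        for a in parent:
            out[a] = out.get(a, 0.0) + 0.5
        return out

    pm = contrib(mother)
    pf = contrib(father)
    a, b = off
    p = pm.get(a, 0.0) * pf.get(b, 0.0)
    if a != b:
        p += pm.get(b, 0.0) * pf.get(a, 0.0)
    return p


def _hw_prob(off: tuple[str, str], freqs: dict[str, float]) -> float:
    a, b = off
    pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
    return pa * pb * (2.0 if a != b else 1.0)


def lod_score(
    mother: Genotype,
    offspring: Genotype,
    candidate: Genotype,
    freqs: dict[str, dict[str, float]],
    error_rate: float = 0.01,
) -> float:
    """Natural-log likelihood ratio: candidate-as-sire vs random sire.

    Each observed genotype is treated as correct with probability
    ``1 - e`` and as an independent Hardy-Weinberg draw with probability
    ``e`` (a single per-locus genotyping error rate).  Summed over the
    loci called in all three individuals.  At ``e = 0`` an incompatible
    candidate yields ``-inf``.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    e = error_rate
    total = 0.0
    for loc in sorted(set(mother) & set(offspring) & set(candidate)):
        f = freqs[loc]
        o, m, c = offspring[loc], mother[loc], candidate[loc]
        hw = _hw_prob(o, f)
        # mother/candidate genotypes each correct w.p. (1-e), random otherwise;
        # the offspring genotype itself is a random HW draw w.p. e.
        t_mc = _trans_prob(o, m, c, f)
        t_m = _trans_prob(o, m, None, f)
        t_c = _trans_prob(o, None, c, f)
        num = (1 - e) * ((1 - e) ** 2 * t_mc + (1 - e) * e * t_m
                         + e * (1 - e) * t_c + e * e * hw) + e * hw
        den = (1 - e) * ((1 - e) * t_m + e * hw) + e * hw
        if den == 0:
            continue  # impossible under both hypotheses: uninformative
        if num == 0:
            return -np.inf
        total += np.log(num / den)
    return total


def _sample_genotype(freqs: dict[str, float], rng: np.random.Generator) -> tuple[str, str]:
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles])
    p = p / p.sum()
    pick = rng.choice(len(alleles), size=2, p=p)
    return tuple(sorted((alleles[pick[0]], alleles[pick[1]])))


def _mendelian_child(
    mother: tuple[str, str], father: tuple[str, str], rng: np.random.Generator
) -> tuple[str, str]:
    return tuple(sorted((mother[rng.integers(2)], father[rng.integers(2)])))


def delta_confidence(
    mother: Genotype,
    offspring: Genotype,
    candidates: dict[str, Genotype],
    assigned: str,
    freqs: dict[str, dict[str, float]],
    n_sim: int = 1000,
    error_rate: float = 0.01,
    seed: int = 0,
) -> float:
    """Simulation-based confidence of an assignment's Delta criterion.

    Delta is the LOD gap between the best and second-best candidate.
    ``n_sim`` offspring are simulated from the observed mother with the
    assigned candidate as the true sire, and another ``n_sim`` with a
    sire drawn from the allele frequencies.  The confidence is the
    proportion, among all simulations whose Delta meets the observed
    Delta, that come from the true-sire scenario with the assigned
    candidate on top -- i.e. the estimated probability that an
    assignment as strong as the observed one is correct.
    """
    rng = np.random.default_rng(seed)
    loci = sorted(set(mother) & set(offspring) & set(freqs))

    def delta_for(off: Genotype) -> tuple[float, str | None]:
        lods = {
            cid: lod_score(mother, off, g, freqs, error_rate)
            for cid, g in candidates.items()
        }
        order = sorted(lods, key=lambda k: lods[k], reverse=True)
        best = order[0]
        gap = lods[best] - (lods[order[1]] if len(order) > 1 else 0.0)
        if len(order) > 1 and gap <= 1e-12:
            best = None  # tie: no candidate is singled out
        return gap, best

    obs_delta, _ = delta_for(offspring)

    hits_true = 0
    hits_any = 0
    for scenario in ("true", "random"):
        for _ in range(n_sim):
            if scenario == "true":
                sire_g = candidates[assigned]
            else:
                sire_g = {loc: _sample_genotype(freqs[loc], rng) for loc in loci}
            sim_off = {
                loc: _mendelian_child(mother[loc], sire_g[loc], rng) for loc in loci
            }
            gap, best = delta_for(sim_off)
            if gap >= obs_delta - 1e-12:
                hits_any += 1
                if scenario == "true" and best == assigned:
                    hits_true += 1
    if hits_any == 0:
        return 0.0
    return hits_true / hits_any


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------

def assign_all(
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    conception_presence: dict[str, dict[str, bool]] | None = None,
    candidate_ids: list[str] | None = None,
    error_rate: float = 0.01,
    n_sim: int = 0,
    seed: int = 0,
    min_shared_loci: int = 8,
) -> pd.DataFrame:
    """Run maternity confirmation + paternity assignment for a cohort.

    ``pedigree`` needs columns ``infant, mother`` (field-observed
    maternity).  ``candidate_ids`` defaults to every genotyped
    individual that appears neither as infant nor mother.  Returns a
    frame ``offspring, sire, category, mismatches_of_sire, lod,
    confidence``.
    """
    gdict = genotype_table_to_dict(genotypes)
    freqs = _freqs_from_table(genotypes)
    if candidate_ids is None:
        non_candidates = set(pedigree["infant"].astype(str)) | set(
            pedigree["mother"].astype(str)
        )
        candidate_ids = sorted(set(gdict) - non_candidates)
    rows = []
    for rec in pedigree.itertuples(index=False):
        infant, mother_id = str(rec.infant), str(rec.mother)
        if infant not in gdict or mother_id not in gdict:
            rows.append((infant, None, "ungenotyped", None, None, None))
            continue
        try:
            ok, bad = confirm_maternity(
                gdict[mother_id], gdict[infant], min_shared_loci=min_shared_loci
            )
        except InsufficientDataError:
            rows.append((infant, None, "insufficient_loci", None, None, None))
            continue
        if not ok:
            rows.append((infant, None, "maternity_mismatch", None, None, None))
            continue
        profiles = [
            paternal_mismatches(
                gdict[mother_id], gdict[infant], gdict[c], infant, c
            )
            for c in candidate_ids
            if c in gdict
        ]
        presence = (conception_presence or {}).get(infant)
        assignment = assign_paternity(profiles, presence)
        lod = conf = mm = None
        if assignment.sire is not None:
            lod = lod_score(
                gdict[mother_id], gdict[infant], gdict[assignment.sire],
                freqs, error_rate,
            )
            mm = next(
                p.mismatches for p in profiles if p.candidate == assignment.sire
            )
            if n_sim > 0:
                conf = delta_confidence(
                    gdict[mother_id], gdict[infant],
                    {c: gdict[c] for c in candidate_ids if c in gdict},
                    assignment.sire, freqs, n_sim=n_sim,
                    error_rate=error_rate, seed=seed,
                )
        rows.append((infant, assignment.sire, assignment.category, mm, lod, conf))
    return pd.DataFrame(
        rows,
        columns=["offspring", "sire", "category", "mismatches", "lod", "confidence"],
    )


def _freqs_from_table(genotypes: pd.DataFrame) -> dict[str, dict[str, float]]:
    from nigra.genotyping import allele_frequencies

    return allele_frequencies(genotypes)
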