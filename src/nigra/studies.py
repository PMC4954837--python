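"""Canned simulation studies validating each pipeline stage.

Each function generates its own synthetic inputs under a caller-supplied
seed, runs the relevant stage(s) of the package, and returns the summary
quantity a validation report cares about: recovery correlations,
error-rate calibrations, assignment accuracy, likelihood gains, sign
recovery.  They are used both by the test suite and by the
reproducibility script, at the problem sizes given by their defaults.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

from nigra import acglmm, elo, genotyping, parentage, permtest
from nigra.errors import DataError
from nigra.modeltable import assemble
from nigra.synth import SimulationConfig, generate, simulate_agonistic, simulate_population

# ---------------------------------------------------------------------------
# Elo
# ---------------------------------------------------------------------------

def elo_strength_recovery(seed: int = 0, min_resident_days: int = 180) -> float:
    """Spearman correlation between latent strength and end-of-study Elo.

    Agonistic events are generated at the default study scale (three
    groups, two years of ad libitum observation) and processed by the
    Elo stage.  The correlation is computed over all adults resident for
    at least ``min_resident_days`` (short-tenured immigrants have too
    few decided interactions for their rating to leave the start value).
    """
    cfg = SimulationConfig(seed=seed, birth_rate=0.0)
    pop = simulate_population(cfg)
    events = simulate_agonistic(pop)
    timeline = elo.update_ratings(events, pop.memberships)
    final: dict[str, float] = {}
    for r in timeline.itertuples(index=False):
        final[r.winner] = r.winner_post
        final[r.loser] = r.loser_post
    mem = pop.memberships
    resident_days = (
        mem.assign(
            days=np.minimum(mem["exit_day"], cfg.study_days - 1)
            - np.maximum(mem["entry_day"], 0)
            + 1
        )
        .groupby("id")["days"]
        .sum()
    )
    keep = sorted(
        i for i in final if resident_days.get(i, 0) >= min_resident_days
    )
    rho = scipy.stats.spearmanr(
        [final[i] for i in keep], [pop.latent_strength[i] for i in keep]
    ).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _random_events(
    rng: np.random.Generator, n_events: int, n_init: int, n_recip: int,
    assortative: bool = False,
) -> pd.DataFrame:
    init = rng.integers(0, n_init, n_events)
    if assortative:
        recip = init % n_recip
    else:
        recip = rng.integers(0, n_recip, n_events)
    recip = np.asarray(recip)
    return pd.DataFrame(
        {
            "initiator": [f"I{i}" for i in init],
            "recipient": [f"M{j}" for j in recip],
        }
    )


def _perm_result(events: pd.DataFrame, n_perm: int, seed: int):
    tab = permtest.DyadTable(
        group="G", direction="infant",
        rows=sorted(events["initiator"].unique()),
        cols=sorted(events["recipient"].unique()),
        counts=pd.crosstab(events["initiator"], events["recipient"]).to_numpy(),
        events=events,
    )
    return permtest.permutation_test(tab, n_perm=n_perm, seed=seed)


def permtest_type1_error(
    seed: int = 0,
    n_datasets: int = 500,
    n_events: int = 60,
    n_perm: int = 400,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the permutation test under independent pairing."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_datasets):
        events = _random_events(rng, n_events, 5, 4)
        if events["initiator"].nunique() < 2 or events["recipient"].nunique() < 2:
            continue
        res = _perm_result(events, n_perm, seed=(seed + 1000 + k) % (2**31 - 1))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_datasets


def permtest_exact_agreement(
    seed: int = 0, n_events: int = 7, n_perm: int = 4000
) -> dict[str, float]:
    """Monte-Carlo p vs exact enumeration on a tiny event list.

    All orderings of the initiator label multiset are enumerated
    (uniform over permutations); returns both p-values and the
    Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)

    def draw() -> pd.DataFrame:
        # half the events follow a partner preference, half are random,
        # so the exact p lands in the interior of (0, 1]
        init = rng.integers(0, 3, n_events)
        pref = rng.random(n_events) < 0.5
        recip = np.where(pref, init % 2, rng.integers(0, 2, n_events))
        return pd.DataFrame(
            {
                "initiator": [f"I{i}" for i in init],
                "recipient": [f"M{j}" for j in recip],
            }
        )

    events = draw()
    while events["initiator"].nunique() < 2 or events["recipient"].nunique() < 2:
        events = draw()
    res = _perm_result(events, n_perm, seed=seed + 1)

    init = events["initiator"].to_numpy()
    recip = events["recipient"].to_numpy()
    r_ids, r_idx = np.unique(recip, return_inverse=True)
    i_ids, i_idx = np.unique(init, return_inverse=True)
    nr, nc = len(i_ids), len(r_ids)

    def chi2_of(order: tuple[int, ...]) -> float:
        ii = i_idx[list(order)]
        counts = np.bincount(ii * nc + r_idx, minlength=nr * nc).reshape(nr, nc)
        counts = counts.astype(float)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        return float(np.sum((counts - expected) ** 2 / expected))

    observed = chi2_of(tuple(range(n_events)))
    hits = total = 0
    for order in itertools.permutations(range(n_events)):
        total += 1
        if chi2_of(order) >= observed - 1e-12:
            hits += 1
    p_exact = hits / total
    mc_se = float(np.sqrt(p_exact * (1 - p_exact) / n_perm))
    return {"p_mc": res.p_value, "p_exact": p_exact, "mc_se": mc_se}


# ---------------------------------------------------------------------------
# parentage
# ---------------------------------------------------------------------------

def _simulate_parentage_cohort(
    rng: np.random.Generator,
    n_offspring: int,
    n_candidates: int,
    n_loci: int,
    n_alleles: int,
    dropout: float,
    misprint: float = 0.0,
    equifrequent: bool = True,
    n_replicates: int = 6,
):
    loci = [f"L{i:02d}" for i in range(n_loci)]
    labels = [[str(100 + 2 * a) for a in range(n_alleles)] for _ in loci]
    freqs = [
        np.full(n_alleles, 1.0 / n_alleles)
        if equifrequent
        else rng.dirichlet(np.ones(n_alleles))
        for _ in loci
    ]

    def draw(li: int) -> tuple[str, str]:
        picks = rng.choice(n_alleles, size=2, p=freqs[li])
        return tuple(sorted((labels[li][picks[0]], labels[li][picks[1]])))

    males = {f"M{i:02d}": {loci[li]: draw(li) for li in range(len(loci))}
             for i in range(n_candidates)}
    mothers = {f"F{i:02d}": {loci[li]: draw(li) for li in range(len(loci))}
               for i in range(n_offspring)}
    truth: dict[str, str] = {}
    offspring = {}
    male_ids = sorted(males)
    for i, mid in enumerate(sorted(mothers)):
        sire = male_ids[rng.integers(n_candidates)]
        oid = f"O{i:02d}"
        truth[oid] = sire
        offspring[oid] = {
            loc: tuple(sorted((
                mothers[mid][loc][rng.integers(2)],
                males[sire][loc][rng.integers(2)],
            )))
            for loc in loci
        }

    rows = []
    everyone = {**males, **mothers, **offspring}
    for ind, g in everyone.items():
        for li, loc in enumerate(loci):
            a, b = g[loc]
            for rep in range(n_replicates):
                if a != b:
                    copies = [x for x in (a, b) if rng.random() >= dropout]
                    if not copies:
                        copies = [(a, b)[rng.integers(2)]]
                else:
                    copies = [a, b]
                out = []
                for c in copies:
                    if rng.random() < misprint:
                        c = labels[li][rng.integers(n_alleles)]
                    out.append(c)
                seen = sorted(set(out))
                rows.append((ind, loc, rep + 1, seen[0],
                             seen[1] if len(seen) > 1 else ""))
    pcr = pd.DataFrame(
        rows, columns=["individual", "locus", "replicate", "allele1", "allele2"]
    )
    pedigree = pd.DataFrame(
        {"infant": sorted(offspring), "mother": sorted(mothers)}
    )
    return pcr, pedigree, truth, male_ids


def sire_recovery(
    seed: int = 0,
    n_offspring: int = 30,
    n_candidates: int = 20,
    n_loci: int = 12,
    n_alleles: int = 6,
    dropout: float = 0.05,
    n_replicates: int = 8,
) -> dict[str, float]:
    """End-to-end paternity recovery on a synthetic cohort.

    Replicate PCRs with allelic dropout are consensus-called and fed to
    exclusion assignment.  Returns the fraction of offspring assigned to
    the true sire, the fraction of *strict* assignments that name a
    wrong male, and the assignment-rate.
    """
    rng = np.random.default_rng(seed)
    pcr, pedigree, truth, male_ids = _simulate_parentage_cohort(
        rng, n_offspring, n_candidates, n_loci, n_alleles, dropout,
        n_replicates=n_replicates,
    )
    gt = genotyping.call_all(pcr, on_contamination="mark")
    result = parentage.assign_all(
        gt, pedigree, candidate_ids=male_ids, min_shared_loci=min(8, n_loci)
    )
    result["true"] = result["offspring"].map(truth)
    assigned = result[result["sire"].notna()]
    correct = (assigned["sire"] == assigned["true"]).mean() if len(assigned) else 0.0
    strict = assigned[assigned["category"] == "strict"]
    wrong_strict = (
        (strict["sire"] != strict["true"]).mean() if len(strict) else 0.0
    )
    true_recovered = (
        (result["sire"] == result["true"]).sum() / n_offspring
    )
    return {
        "true_sire_recovery": float(true_recovered),
        "wrong_strict_rate": float(wrong_strict),
        "assignment_rate": float(len(assigned) / n_offspring),
        "correct_among_assigned": float(correct),
    }


def mendelian_split_oracle(
    mother: tuple[str, str], off: tuple[str, str], cand: tuple[str, str]
) -> bool:
    """Locus-level exclusion by enumerating (maternal, paternal) splits.

    The offspring pair (o1, o2) can split as (maternal=o1, paternal=o2)
    or (maternal=o2, paternal=o1); the candidate is compatible iff some
    split has its maternal allele in the mother and its paternal allele
    in the candidate.  Returns True when the candidate is EXCLUDED.
    """
    o1, o2 = off
    for ma, pa in ((o1, o2), (o2, o1)):
        if ma in mother and pa in cand:
            return False
    return True


def mismatch_oracle_agreement(seed: int = 0, n_trios: int = 1000) -> float:
    """Fraction of random trios where exclusion counts match the split oracle."""
    rng = np.random.default_rng(seed)
    alleles = [str(100 + 2 * a) for a in range(6)]
    agree = 0
    for _ in range(n_trios):
        n_loci = int(rng.integers(4, 13))
        loci = [f"L{i}" for i in range(n_loci)]

        def g() -> dict[str, tuple[str, str]]:
            return {
                loc: tuple(sorted(rng.choice(alleles, size=2)))
                for loc in loci
            }

        m, o, c = g(), g(), g()
        prof = parentage.paternal_mismatches(m, o, c)
        oracle = sum(mendelian_split_oracle(m[l], o[l], c[l]) for l in loci)
        if prof.mismatches == oracle:
            agree += 1
    return agree / n_trios


# ---------------------------------------------------------------------------
# AC-GLMM studies
# ---------------------------------------------------------------------------

def _small_study_config(seed: int, **overrides) -> SimulationConfig:
    """A desk-scale single-group study used by the model validation runs."""
    params = dict(
        n_groups=1, females_per_group=10, males_per_group=6,
        study_days=180, birth_rate=0.006, msat_loci=8,
        scans_per_day=25.0, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def _assembled_table(config: SimulationConfig, direction: str = "infant") -> pd.DataFrame:
    data = generate(config)
    pop = data.population
    gt = genotyping.call_all(data.pcr, on_contamination="mark")
    pat = parentage.assign_all(
        gt, pop.conceptions[["infant", "mother"]],
        min_shared_loci=min(8, config.msat_loci),
    )
    # fall back to true sires for unresolved infants so model rows survive
    sire_truth = pop.roster.set_index("id")["sire_id"].to_dict()
    pat["sire"] = [
        s if isinstance(s, str) else sire_truth.get(o)
        for o, s in zip(pat["offspring"], pat["sire"])
    ]
    ranks = elo.daily_ranks(
        data.agonistic, pop.memberships, pop.roster,
        days=np.arange(config.study_days),
    )
    return assemble(
        direction, data.scans, data.interactions, ranks, pop.roster,
        pop.memberships, pop.conceptions, pat, constant_policy="drop",
    )


def _varying(table: pd.DataFrame, term: str) -> bool:
    cols = term.split(":")
    if any(c not in table.columns for c in cols):
        return False
    prod = np.ones(len(table))
    for c in cols:
        prod = prod * table[c].to_numpy(dtype=float)
    return bool(np.ptp(prod) > 0)


def _glm_spec(table: pd.DataFrame, direction: str = "infant") -> acglmm.ModelSpec:
    return acglmm.ModelSpec(
        test_terms=[
            t for t in acglmm.full_test_terms(direction) if _varying(table, t)
        ],
        control_terms=[c for c in acglmm.CONTROL_TERMS if _varying(table, c)],
        random_terms=[],
    )


def ac_likelihood_gain_rate(
    seed: int = 0, n_sims: int = 50, ar1_rho: float = 0.9, ar1_sd: float = 1.0
) -> float:
    """Share of simulations where the optimized-sigma AC model beats the
    no-AC model's likelihood, under an AR(1) dyadic latent process."""
    wins = done = 0
    for k in range(n_sims):
        cfg = _small_study_config((seed * 10_000 + k) % (2**31 - 1),
                                  ar1_rho=ar1_rho, ar1_sd=ar1_sd,
                                  study_days=140, females_per_group=8,
                                  males_per_group=5)
        try:
            table = _assembled_table(cfg)
        except DataError:  # a rare simulated study with no focal infants
            continue
        spec = _glm_spec(table)
        base = acglmm.fit_glmm(table, spec)
        fit, _ = acglmm.fit_with_ac(table, spec)
        done += 1
        if fit.loglik > base.loglik:
            wins += 1
    return wins / max(done, 1)


def sign_recovery_rates(
    seed: int = 0,
    n_sims: int = 100,
    effects: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-effect sign recovery of the planted fixed effects.

    For each simulation a small study is generated, assembled, and fit;
    the estimate's sign is compared with the planted log-odds effect.
    Returns the recovery rate per effect name (model-table column).
    """
    if effects is None:
        effects = {
            "z_mother_presence": -0.2,
            "z_male_rank": 0.15,
            "z_mother_male_affiliation": 0.1,
        }
    hits = {k: 0 for k in effects}
    done = 0
    for k in range(n_sims):
        cfg = _small_study_config(
            (seed * 10_000 + 5000 + k) % (2**31 - 1),
            study_days=240, females_per_group=14, males_per_group=8,
        )
        try:
            table = _assembled_table(cfg)
            fit = acglmm.fit_glmm(table, _glm_spec(table))
        except DataError:
            continue
        done += 1
        for name, true_val in effects.items():
            if name in fit.params.index and np.sign(fit.params[name]) == np.sign(true_val):
                hits[name] += 1
    return {k: v / max(done, 1) for k, v in hits.items()}
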