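"""Seeded synthetic field and lab data with the structure the analysis assumes.

The generator emulates a multi-group macaque study: stable resident
females, males immigrating and emigrating with Gamma-distributed
tenures, rank-skewed paternity (sires sampled among males present in
the conception window with probability proportional to standardized
latent strength raised to a skew exponent), ad libitum agonistic events
whose outcome is a logistic function of latent-strength difference,
daily focal follows of infants with scan-sampled proximity of the
mother and of adult males, dyadic affiliation whose daily log-odds
follow a configurable linear predictor plus a per-dyad AR(1) latent
process (so the autocorrelation machinery downstream has signal to
detect), and replicate microsatellite PCRs with allelic dropout and
misprints.

Everything is driven by a single :class:`SimulationConfig` and a single
seed; the same seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.special

from nigra.dates import DEFAULT_BASE_DATE, days_to_iso
from nigra.errors import ConfigurationError


def _default_effects() -> dict[str, float]:
    # log-odds effects of the z-scored / binary predictors on daily
    # dyadic affiliation; magnitudes in the range reported for dyadic
    # affiliation models in wild macaques
    return {
        "intercept": -2.5,
        "male_rank": 0.15,
        "mother_rank": 0.0,
        "mother_presence": -0.2,
        "mother_male_affiliation": 0.1,
        "paternity": 0.0,
        "conception": 0.0,  # male->infant direction only
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generator.

    Defaults mirror the field study being emulated: three groups of
    50-80 animals with 13-25 reproducing females and 4-11 adult males
    each, a two-year horizon, male tenures with mean 766.5 d and SD
    396.7 d, 12 microsatellite loci, and strongly rank-skewed paternity.
    """

    n_groups: int = 3
    females_per_group: int = 18
    males_per_group: int = 8
    study_days: int = 730
    male_mean_tenure_days: float = 766.5
    male_sd_tenure_days: float = 396.7
    birth_rate: float = 0.0008  # births per female-day
    msat_loci: int = 12
    alleles_per_locus: int = 6
    dropout_rate: float = 0.05
    misprint_rate: float = 0.01
    paternity_skew: float = 8.0
    true_effects: dict[str, float] = field(default_factory=_default_effects)
    ar1_rho: float = 0.9
    ar1_sd: float = 1.0
    infant_initiated_share: float = 0.635
    scans_per_day: float = 30.0
    agonistic_per_group_day: float = 3.0
    # decided agonistic outcomes in macaque dominance hierarchies are
    # strongly unidirectional; 0.5 gives ~0.88 win probability for a
    # 1 SD latent-strength gap
    strength_scale: float = 0.5
    gestation_days: int = 165  # conception window ends this many days pre-birth
    conception_window_days: int = 14
    n_replicates: int = 6
    base_date: str = DEFAULT_BASE_DATE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "females_per_group", "males_per_group",
                     "study_days", "msat_loci", "alleles_per_locus",
                     "conception_window_days", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("dropout_rate", "misprint_rate", "birth_rate",
                     "infant_initiated_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ConfigurationError("ar1_rho must be in [0, 1)")
        if self.ar1_sd < 0:
            raise ConfigurationError("ar1_sd must be >= 0")
        if self.male_mean_tenure_days <= 0 or self.male_sd_tenure_days <= 0:
            raise ConfigurationError("tenure parameters must be positive")
        if self.paternity_skew < 0:
            raise ConfigurationError("paternity_skew must be >= 0")


@dataclass
class PopulationState:
    roster: pd.DataFrame       # id, sex, cls, birth_day, mother_id, sire_id, group
    memberships: pd.DataFrame  # id, group, entry_day, exit_day
    latent_strength: dict[str, float]
    conceptions: pd.DataFrame  # infant, mother, group, window_start, window_end, birth_day
    config: SimulationConfig


@dataclass
class SyntheticData:
    population: PopulationState
    agonistic: pd.DataFrame
    scans: pd.DataFrame          # daily per (infant, day, male) aggregation
    interactions: pd.DataFrame
    pcr: pd.DataFrame
    truth: pd.DataFrame          # dyad-day generating covariates and responses

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all CSV products (ISO-8601 dates) and return their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base = self.population.config.base_date
        paths = {}

        def _write(name: str, df: pd.DataFrame, day_cols: tuple[str, ...]) -> None:
            out = df.copy()
            for c in day_cols:
                out[c.replace("day", "date") if c.endswith("day") else c + "_date"] = (
                    days_to_iso(out[c], base)
                )
            p = outdir / name
            out.to_csv(p, index=False)
            paths[name] = p

        _write("roster.csv", self.population.roster, ())
        _write("memberships.csv", self.population.memberships, ())
        _write("agonistic.csv", self.agonistic, ("day",))
        _write("scans.csv", self.scans, ("day",))
        _write("interactions.csv", self.interactions, ("day",))
        _write("pcr_replicates.csv", self.pcr, ())
        _write("conceptions.csv", self.population.conceptions, ())
        return paths


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PopulationState:
    """Generate demography: groups, male migration, births, true sires."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.males_per_group < 1:
        raise ConfigurationError("need at least one male per group")

    mean, sd = config.male_mean_tenure_days, config.male_sd_tenure_days
    shape = (mean / sd) ** 2
    scale = sd**2 / mean

    rows = []          # roster
    members = []       # memberships
    strength: dict[str, float] = {}
    pre_study = config.gestation_days + config.conception_window_days + 1
    male_counter = 0

    male_pool: dict[str, list[tuple[str, int, int]]] = {}
    for g in range(config.n_groups):
        group = f"G{g + 1}"
        male_pool[group] = []
        for _ in range(config.females_per_group):
            fid = f"{group}F{len([r for r in rows if r[6] == group and r[1] == 'F']) + 1:02d}"
            rows.append((fid, "F", "adult_female", -3650, None, None, group))
            members.append((fid, group, -pre_study, config.study_days - 1))
            strength[fid] = float(rng.normal())
        # initial males enter before the study so early conception windows
        # have resident candidates
        entries = [-pre_study] * config.males_per_group
        while entries:
            entry = entries.pop()
            male_counter += 1
            mid = f"M{male_counter:03d}"
            tenure = max(1, int(round(rng.gamma(shape, scale))))
            exit_day = entry + tenure - 1
            rows.append((mid, "M", "adult_male", -3650, None, None, group))
            members.append((mid, group, entry, exit_day))
            strength[mid] = float(rng.normal())
            male_pool[group].append((mid, entry, exit_day))
            if exit_day < config.study_days - 1:
                entries.append(exit_day + 1)  # replacement immigrant

    roster = pd.DataFrame(
        rows,
        columns=["id", "sex", "cls", "birth_day", "mother_id", "sire_id", "group"],
    )
    memberships = pd.DataFrame(
        members, columns=["id", "group", "entry_day", "exit_day"]
    )

    # births with rank-skewed paternity
    conc_rows = []
    infant_rows = []
    infant_members = []
    infant_counter = 0
    for g in range(config.n_groups):
        group = f"G{g + 1}"
        females = roster[(roster["group"] == group) & (roster["cls"] == "adult_female")]
        males = male_pool[group]
        for fid in females["id"]:
            next_allowed = 0
            day = 0
            while day < config.study_days:
                if day >= next_allowed and rng.random() < config.birth_rate:
                    w_end = day - config.gestation_days
                    w_start = w_end - (config.conception_window_days - 1)
                    cands = [
                        (m, s, e) for m, s, e in males if s <= w_end and e >= w_start
                    ]
                    if cands:
                        sire = _sample_sire(
                            cands, strength, config.paternity_skew, rng
                        )
                        infant_counter += 1
                        iid = f"I{infant_counter:03d}"
                        sex = "M" if rng.random() < 0.5 else "F"
                        infant_rows.append(
                            (iid, sex, "infant", day, fid, sire, group)
                        )
                        infant_members.append(
                            (iid, group, day, config.study_days - 1)
                        )
                        conc_rows.append((iid, fid, group, w_start, w_end, day))
                        next_allowed = day + 365
                day += 1

    roster = pd.concat(
        [roster, pd.DataFrame(infant_rows, columns=roster.columns)],
        ignore_index=True,
    )
    memberships = pd.concat(
        [memberships, pd.DataFrame(infant_members, columns=memberships.columns)],
        ignore_index=True,
    )
    conceptions = pd.DataFrame(
        conc_rows,
        columns=["infant", "mother", "group", "window_start", "window_end", "birth_day"],
    )
    return PopulationState(roster, memberships, strength, conceptions, config)


def _sample_sire(
    candidates: list[tuple[str, int, int]],
    strength: dict[str, float],
    skew: float,
    rng: np.random.Generator,
) -> str:
    ids = [c[0] for c in candidates]
    s = np.array([strength[i] for i in ids], dtype=float)
    if len(ids) == 1:
        return ids[0]
    lo, hi = s.min(), s.max()
    std = (s - lo) / (hi - lo) if hi > lo else np.ones_like(s)
    if not math.isfinite(skew):
        return ids[int(np.argmax(std))]
    with np.errstate(invalid="ignore"):
        w = std**skew
    w = np.where(np.isfinite(w), w, 0.0)
    if w.sum() == 0:
        w = np.ones_like(w)
    return ids[int(rng.choice(len(ids), p=w / w.sum()))]


# ---------------------------------------------------------------------------
# agonistic events
# ---------------------------------------------------------------------------

def simulate_agonistic(
    pop: PopulationState, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Dated decided agonistic events among co-resident same-sex adults.

    P(i beats j) is a logistic function of the latent strength
    difference, scaled by ``strength_scale``.
    """
    config = pop.config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    adults = pop.roster[pop.roster["cls"].isin(["adult_male", "adult_female"])]
    mem = pop.memberships.set_index("id")
    rows = []
    for group in sorted(adults["group"].unique()):
        for sex in ("M", "F"):
            ids = adults[(adults["group"] == group) & (adults["sex"] == sex)][
                "id"
            ].tolist()
            spans = {
                i: (int(mem.loc[i, "entry_day"]), int(mem.loc[i, "exit_day"]))
                for i in ids
            }
            s = {i: pop.latent_strength[i] for i in ids}
            for day in range(config.study_days):
                present = [i for i in ids if spans[i][0] <= day <= spans[i][1]]
                if len(present) < 2:
                    continue
                n_ev = rng.poisson(config.agonistic_per_group_day / 2.0)
                for _ in range(n_ev):
                    a, b = rng.choice(len(present), size=2, replace=False)
                    ia, ib = present[a], present[b]
                    p_a = float(
                        scipy.special.expit((s[ia] - s[ib]) / config.strength_scale)
                    )
                    if rng.random() < p_a:
                        rows.append((day, group, ia, ib))
                    else:
                        rows.append((day, group, ib, ia))
    return pd.DataFrame(rows, columns=["day", "group", "winner", "loser"])


# ---------------------------------------------------------------------------
# focal follows
# ---------------------------------------------------------------------------

def _percentile_rank(values: np.ndarray) -> np.ndarray:
    """Min-max standardized rank in [0, 1]; 0.5 for a single value."""
    if values.size == 1:
        return np.array([0.5])
    order = values.argsort().argsort().astype(float)
    return order / (values.size - 1)


def simulate_focal_data(
    pop: PopulationState, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Daily focal-follow products: scan aggregates, events, and truth table.

    Returns ``(scans, interactions, truth)``:

    - ``scans`` -- one row per (infant, day, co-resident male):
      ``obs_scans`` 1-min scans that day, ``mother_scans`` with the
      mother within 2.5 m, ``male_near_scans`` with the male within
      2.5 m, ``mm_co_scans`` with both, ``mm_affil_scans`` with both and
      an observed mother-male affiliation;
    - ``interactions`` -- dated events ``(day, group, initiator,
      recipient, behavior, behavior_class)``;
    - ``truth`` -- dyad-day generating state: covariates on the
      generator's scale, AR(1) latent values, and both binary responses.

    The daily log-odds of affiliation in each direction follow the
    configured ``true_effects`` linear predictor (z-scored continuous
    covariates), plus ``ln(obs_scans / scans_per_day)`` as an
    observation-effort offset and a stationary per-dyad AR(1) latent
    term with correlation ``ar1_rho`` and marginal SD ``ar1_sd``.
    """
    config = pop.config
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    infants = pop.roster[pop.roster["cls"] == "infant"]
    mem = pop.memberships.set_index("id")
    males_by_group: dict[str, list[str]] = {}
    females_by_group: dict[str, list[str]] = {}
    for group in sorted(pop.roster["group"].unique()):
        males_by_group[group] = pop.roster[
            (pop.roster["group"] == group) & (pop.roster["cls"] == "adult_male")
        ]["id"].tolist()
        females_by_group[group] = pop.roster[
            (pop.roster["group"] == group) & (pop.roster["cls"] == "adult_female")
        ]["id"].tolist()

    # mother-male bond propensities (per mother-male pair, logit scale)
    bond: dict[tuple[str, str], float] = {}

    def bond_of(mother: str, male: str) -> float:
        key = (mother, male)
        if key not in bond:
            bond[key] = float(rng.normal(-1.0, 0.8))
        return bond[key]

    records = []  # raw covariates before z-scoring
    scan_rows = []
    for inf in infants.itertuples(index=False):
        iid, group, mother, sire = inf.id, inf.group, inf.mother_id, inf.sire_id
        birth = int(inf.birth_day)
        d0 = max(0, birth)
        d1 = min(birth + 364, config.study_days - 1)
        if d1 < d0:
            continue
        group_males = males_by_group[group]
        spans = {
            m: (int(mem.loc[m, "entry_day"]), int(mem.loc[m, "exit_day"]))
            for m in group_males
        }
        fem_strength = np.array(
            [pop.latent_strength[f] for f in females_by_group[group]]
        )
        fem_rank = dict(
            zip(females_by_group[group], _percentile_rank(fem_strength))
        )
        mother_rank = fem_rank[mother]

        # AR(1) latent per dyad-direction over the focal span
        n_days = d1 - d0 + 1
        ar: dict[tuple[str, str], np.ndarray] = {}

        def ar_series() -> np.ndarray:
            if config.ar1_sd == 0:
                return np.zeros(n_days)
            x = np.empty(n_days)
            x[0] = rng.normal(0.0, config.ar1_sd)
            innov_sd = config.ar1_sd * math.sqrt(1 - config.ar1_rho**2)
            for t in range(1, n_days):
                x[t] = config.ar1_rho * x[t - 1] + rng.normal(0.0, innov_sd)
            return x

        for day in range(d0, d1 + 1):
            present = [m for m in group_males if spans[m][0] <= day <= spans[m][1]]
            if not present:
                continue
            obs = 1 + rng.poisson(max(config.scans_per_day - 1, 0))
            age = day - birth
            p_mom = 1.0 / (1.0 + np.exp(-(1.2 - 2.9 * age / 365.0)))
            mother_scans = int(rng.binomial(obs, p_mom))
            mother_flag = np.zeros(obs, dtype=bool)
            mother_flag[:mother_scans] = True
            rng.shuffle(mother_flag)
            strengths = np.array([pop.latent_strength[m] for m in present])
            ranks = _percentile_rank(strengths)
            # per-scan proximity of each male (2.5 m radius)
            p_near = 0.12
            near = rng.random((obs, len(present))) < p_near
            bonds = np.array([bond_of(mother, m) for m in present])
            bond_p = 1.0 / (1.0 + np.exp(-bonds))
            co = near & mother_flag[:, None]
            affil = co & (rng.random((obs, len(present))) < bond_p[None, :])
            any_male = int(near.any(axis=1).sum())
            mother_any_male = int((near.any(axis=1) & mother_flag).sum())
            for j, (m, mrank) in enumerate(zip(present, ranks)):
                key_i = (m, "infant")
                key_m = (m, "male")
                if key_i not in ar:
                    ar[key_i] = ar_series()
                    ar[key_m] = ar_series()
                scan_rows.append(
                    (iid, day, group, m, obs, mother_scans,
                     int(near[:, j].sum()), int(co[:, j].sum()),
                     int(affil[:, j].sum()), any_male, mother_any_male)
                )
                records.append(
                    {
                        "infant": iid, "male": m, "day": day, "group": group,
                        "mother": mother, "age": age, "obs": obs,
                        "mother_scans": mother_scans,
                        "male_rank": float(mrank), "mother_rank": float(mother_rank),
                        "bond": float(scipy.special.expit(bonds[j])),
                        "paternity": float(m == sire),
                        "conception": float(_conception_overlap(pop, iid, m, spans)),
                        "ar_infant": float(ar[key_i][day - d0]),
                        "ar_male": float(ar[key_m][day - d0]),
                    }
                )

    truth = pd.DataFrame(records)
    scans = pd.DataFrame(
        scan_rows,
        columns=["infant", "day", "group", "male", "obs_scans", "mother_scans",
                 "male_near_scans", "mm_co_scans", "mm_affil_scans",
                 "any_male_scans", "mother_any_male_scans"],
    )
    if truth.empty:
        return scans, pd.DataFrame(
            columns=["day", "group", "initiator", "recipient", "behavior",
                     "behavior_class"]
        ), truth

    # z-score the generator's continuous covariates, build linear predictors
    eff = dict(_default_effects())
    eff.update(pop.config.true_effects)

    def z(col: np.ndarray) -> np.ndarray:
        sd = col.std()
        return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    z_rank = z(truth["male_rank"].to_numpy())
    z_mrank = z(truth["mother_rank"].to_numpy())
    z_pres = z(np.log1p(truth["mother_scans"].to_numpy()))
    z_bond = z(truth["bond"].to_numpy())
    offset = np.log(truth["obs"].to_numpy() / config.scans_per_day)

    base_lp = (
        eff["intercept"]
        + eff["male_rank"] * z_rank
        + eff["mother_rank"] * z_mrank
        + eff["mother_presence"] * z_pres
        + eff["mother_male_affiliation"] * z_bond
        + eff["paternity"] * truth["paternity"].to_numpy()
        + offset
    )
    lp_inf = base_lp + truth["ar_infant"].to_numpy()
    lp_male = (
        base_lp
        + eff["conception"] * truth["conception"].to_numpy()
        + truth["ar_male"].to_numpy()
    )
    truth["p_infant"] = 1.0 / (1.0 + np.exp(-lp_inf))
    truth["p_male"] = 1.0 / (1.0 + np.exp(-lp_male))
    truth["y_infant"] = (rng.random(len(truth)) < truth["p_infant"]).astype(int)
    truth["y_male"] = (rng.random(len(truth)) < truth["p_male"]).astype(int)

    interactions = _emit_events(truth, config, rng)
    return scans, interactions, truth


def _conception_overlap(
    pop: PopulationState, infant: str, male: str,
    spans: dict[str, tuple[int, int]],
) -> bool:
    conc = pop.conceptions
    row = conc[conc["infant"] == infant]
    if row.empty or male not in spans:
        return False
    ws, we = int(row["window_start"].iloc[0]), int(row["window_end"].iloc[0])
    s, e = spans[male]
    return s <= we and e >= ws


def _emit_events(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Turn positive dyad-days into interaction events.

    Event multiplicities are tuned so the realized infant-initiated
    share of affiliations matches ``infant_initiated_share``; a light
    sprinkling of aggressive events exercises the affiliative filter
    downstream.
    """
    n_inf_days = int(truth["y_infant"].sum())
    n_male_days = int(truth["y_male"].sum())
    mu_male = 1.0
    share = config.infant_initiated_share
    if n_inf_days > 0 and share < 1:
        target_inf = share / (1 - share) * n_male_days * (1 + mu_male)
        mu_inf = max(0.0, target_inf / n_inf_days - 1.0)
    else:
        mu_inf = 1.0
    behaviors = ["approach", "groom", "lipsmack", "follow"]
    b_probs = np.array([0.92, 0.02, 0.03, 0.03])
    b_probs = b_probs / b_probs.sum()
    rows = []
    for rec in truth.itertuples(index=False):
        if rec.y_infant:
            for _ in range(1 + rng.poisson(mu_inf)):
                rows.append(
                    (rec.day, rec.group, rec.infant, rec.male,
                     behaviors[rng.choice(4, p=b_probs)], "affiliative")
                )
        if rec.y_male:
            for _ in range(1 + rng.poisson(mu_male)):
                rows.append(
                    (rec.day, rec.group, rec.male, rec.infant,
                     behaviors[rng.choice(4, p=b_probs)], "affiliative")
                )
        if rng.random() < 0.01:  # occasional aggression
            pair = (
                (rec.male, rec.infant) if rng.random() < 0.7 else (rec.infant, rec.male)
            )
            rows.append((rec.day, rec.group, pair[0], pair[1], "threat", "aggressive"))
    return pd.DataFrame(
        rows,
        columns=["day", "group", "initiator", "recipient", "behavior",
                 "behavior_class"],
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pop: PopulationState,
    rng: np.random.Generator | None = None,
    allele_freqs: list[np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, tuple[str, str]]]]:
    """Replicate PCR calls for every individual at every locus.

    Founder genotypes are drawn from per-locus allele frequencies
    (Dirichlet(1, ..., 1) by default); offspring inherit one maternal
    and one paternal allele.  Each replicate of a heterozygote drops
    each allele independently with ``dropout_rate`` (a replicate whose
    two copies both drop re-amplifies a random one of them); every
    surviving allele copy is replaced by a random allele of the locus
    with ``misprint_rate``.

    Returns ``(pcr_table, true_genotypes)`` where ``true_genotypes``
    maps individual -> locus -> sorted allele pair.
    """
    config = pop.config
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    loci = [f"L{i + 1:02d}" for i in range(config.msat_loci)]
    if allele_freqs is None:
        allele_freqs = [
            rng.dirichlet(np.ones(config.alleles_per_locus)) for _ in loci
        ]
    labels = [
        [str(100 + 2 * a) for a in range(len(f))] for f in allele_freqs
    ]

    roster = pop.roster
    truth: dict[str, dict[str, tuple[str, str]]] = {}
    # founders first (parents unknown), then infants in birth order
    founders = roster[roster["mother_id"].isnull()]
    for ind in founders["id"]:
        g: dict[str, tuple[str, str]] = {}
        for li, locus in enumerate(loci):
            picks = rng.choice(len(allele_freqs[li]), size=2, p=allele_freqs[li])
            g[locus] = tuple(sorted((labels[li][picks[0]], labels[li][picks[1]])))
        truth[ind] = g
    infants = roster[roster["mother_id"].notnull()].sort_values("birth_day")
    for ind in infants.itertuples(index=False):
        g = {}
        for locus in loci:
            ma = truth[ind.mother_id][locus][rng.integers(2)]
            pa = truth[ind.sire_id][locus][rng.integers(2)]
            g[locus] = tuple(sorted((ma, pa)))
        truth[ind.id] = g

    rows = []
    for ind in sorted(truth):
        for li, locus in enumerate(loci):
            a, b = truth[ind][locus]
            for rep in range(config.n_replicates):
                seen = _replicate(a, b, labels[li], config, rng)
                a1 = seen[0]
                a2 = seen[1] if len(seen) > 1 else ""
                rows.append((ind, locus, rep + 1, a1, a2))
    pcr = pd.DataFrame(
        rows, columns=["individual", "locus", "replicate", "allele1", "allele2"]
    )
    return pcr, truth


def _replicate(
    a: str, b: str, alphabet: list[str], config: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    if a != b:
        copies = [x for x in (a, b) if rng.random() >= config.dropout_rate]
        if not copies:
            copies = [(a, b)[rng.integers(2)]]
    else:
        copies = [a, b]
    out = []
    for c in copies:
        if rng.random() < config.misprint_rate:
            c = alphabet[rng.integers(len(alphabet))]
        out.append(c)
    return sorted(set(out))


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def generate(config: SimulationConfig) -> SyntheticData:
    """Run every simulator under one seed chain."""
    pop = simulate_population(config)
    agonistic = simulate_agonistic(pop)
    scans, interactions, truth = simulate_focal_data(pop)
    pcr, _ = simulate_genotypes(pop)
    return SyntheticData(pop, agonistic, scans, interactions, pcr, truth)
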