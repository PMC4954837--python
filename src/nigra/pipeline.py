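"""End-to-end orchestration: synth -> elo -> genotype -> paternity ->
permtest -> table -> fit -> report.

A run is configured by a :class:`RunConfig` (loadable from YAML),
executed stage by stage in dependency order; every stage validates its
input schema before computing, and every written artifact is hashed
into ``manifest.json`` so reruns with the same seed can be verified to
be byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nigra import acglmm, descriptives, elo, genotyping, modeltable, parentage, permtest
from nigra.errors import ConfigurationError, DataError
from nigra.synth import SimulationConfig, SyntheticData, generate


@dataclass
class RunConfig:
    outdir: str = "nigra_run"
    seed: int = 0
    synth: dict = field(default_factory=dict)
    elo_params: dict = field(default_factory=dict)       # start, k, scale
    genotype_params: dict = field(default_factory=dict)  # min_het_reps, ...
    paternity_params: dict = field(default_factory=dict)  # error_rate, nsim
    permtest_params: dict = field(default_factory=dict)  # nperm, alpha
    table_params: dict = field(default_factory=dict)     # bond_window, constant_policy
    fit_params: dict = field(default_factory=dict)       # slopes, directions, stability

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "outdir", "seed", "synth", "elo_params", "genotype_params",
            "paternity_params", "permtest_params", "table_params", "fit_params",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require(df: pd.DataFrame, cols: set[str], stage: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise DataError(f"stage {stage}: input missing columns {sorted(missing)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, data: SyntheticData | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    When ``data`` is None a synthetic dataset is generated from
    ``config.synth`` under ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if data is None:
        synth_cfg = SimulationConfig(**{"seed": config.seed, **config.synth})
        data = generate(synth_cfg)
    cfg = data.population.config
    paths = data.write(outdir)

    pop = data.population
    study_days = cfg.study_days

    # --- elo ---------------------------------------------------------------
    _require(data.agonistic, {"day", "group", "winner", "loser"}, "elo")
    elo_cfg = elo.EloConfig(
        start_rating=config.elo_params.get("start", 1000.0),
        k_factor=config.elo_params.get("k", 100.0),
        logistic_scale=config.elo_params.get("scale", 400.0),
    )
    ranks = elo.daily_ranks(
        data.agonistic, pop.memberships, pop.roster, elo_cfg,
        days=np.arange(0, study_days),
    )
    ranks.to_csv(outdir / "daily_ranks.csv", index=False)

    # --- genotyping --------------------------------------------------------
    _require(
        data.pcr, {"individual", "locus", "replicate", "allele1"}, "genotype"
    )
    gt = genotyping.call_all(
        data.pcr,
        min_het_reps=config.genotype_params.get("min_het_reps", 2),
        min_total_het=config.genotype_params.get("min_total_het", 4),
        min_hom_reps=config.genotype_params.get("min_hom_reps", 6),
        on_contamination="mark",
    )
    gt.to_csv(outdir / "genotypes.csv", index=False)
    stats = genotyping.locus_summary(
        gt,
        hwe_shuffles=config.genotype_params.get("hwe_shuffles", 2000),
        rng=np.random.default_rng(config.seed + 10),
    )
    genotyping.locus_summary_frame(stats).to_csv(
        outdir / "locus_stats.csv", index=False
    )

    # --- paternity ---------------------------------------------------------
    pedigree = pop.conceptions.rename(columns={"infant": "infant"})[
        ["infant", "mother"]
    ]
    conc_presence = {
        str(r.infant): {
            m: bool(
                modeltable.conception_presence(
                    m, str(r.infant), pop.memberships, pop.conceptions
                )
            )
            for m in pop.roster[pop.roster["cls"] == "adult_male"]["id"]
        }
        for r in pop.conceptions.itertuples(index=False)
    }
    paternity = parentage.assign_all(
        gt, pedigree, conc_presence,
        error_rate=config.paternity_params.get("error_rate", 0.01),
        n_sim=config.paternity_params.get("nsim", 0),
        seed=config.seed + 20,
        min_shared_loci=config.paternity_params.get("min_shared_loci", 8),
    )
    paternity.to_csv(outdir / "paternity.csv", index=False)

    # --- permutation tests --------------------------------------------------
    perm_rows = []
    pref_frames = []
    nperm = config.permtest_params.get("nperm", 10_000)
    for group in sorted(pop.roster["group"].unique()):
        for direction in ("male", "infant"):
            try:
                tab = permtest.build_table(
                    data.interactions, pop.roster, pop.memberships,
                    group, direction, 0, study_days - 1,
                )
                res = permtest.permutation_test(
                    tab, n_perm=nperm, seed=config.seed + 30
                )
            except DataError:
                continue
            perm_rows.append(
                (group, direction, tab.total, res.observed_chi2, res.p_value)
            )
            prefs = permtest.preferred_partners(res)
            prefs.insert(0, "direction", direction)
            prefs.insert(0, "group", group)
            pref_frames.append(prefs)
    pd.DataFrame(
        perm_rows, columns=["group", "direction", "n", "chi2", "p"]
    ).to_csv(outdir / "permtest.csv", index=False)
    if pref_frames:
        pd.concat(pref_frames, ignore_index=True).to_csv(
            outdir / "preferences.csv", index=False
        )

    # --- model tables and fits ----------------------------------------------
    fit_summaries = {}
    vif_rows = []
    directions = config.fit_params.get("directions", ["infant", "male"])
    slopes = config.fit_params.get("slopes", "reduced")
    for direction in directions:
        table = modeltable.assemble(
            direction, data.scans, data.interactions, ranks, pop.roster,
            pop.memberships, pop.conceptions, paternity,
            bond_window=config.table_params.get("bond_window", "cumulative"),
            constant_policy=config.table_params.get("constant_policy", "drop"),
        )
        table.to_csv(outdir / f"model_table_{direction}.csv", index=False)
        table["response"] = table["response"].astype(float)
        spec = acglmm.ModelSpec(
            test_terms=[
                t
                for t in acglmm.full_test_terms(direction)
                if all(p in table.columns for p in t.split(":"))
            ],
            control_terms=[c for c in acglmm.CONTROL_TERMS if c in table.columns],
            random_terms=acglmm.default_random_terms(slopes),
        )
        fit, work = acglmm.fit_with_ac(table, spec)
        null = acglmm.fit_glmm(work, fit.spec.null_spec())
        chi2, df, p = acglmm.lrt(fit, null)
        final_spec, prune_log = acglmm.prune_interactions(work, fit.spec)
        vif_table = acglmm.vif(work, [t for t in spec.test_terms if ":" not in t]
                               + spec.control_terms)
        vif_rows += [(direction, term, v) for term, v in vif_table.items()]
        summary = {
            "direction": direction,
            "estimates": fit.params.to_dict(),
            "se": fit.se.to_dict(),
            "loglik": fit.loglik,
            "vc": fit.vc,
            "ac_sigmas": fit.ac_sigmas,
            "full_vs_null": {"chi2": chi2, "df": df, "p": p},
            "pruning": prune_log.to_dict(orient="records"),
            "final_test_terms": final_spec.test_terms,
            "vif": vif_table.to_dict(),
            "method": fit.method,
            "converged": fit.converged,
            "n_rows": fit.n,
        }
        if config.fit_params.get("stability", False):
            stab = acglmm.stability_check(work, final_spec)
            stab.to_csv(outdir / f"stability_{direction}.csv", index=False)
            summary["max_stability_delta"] = (
                float(stab["max_abs_delta"].max()) if len(stab) else None
            )
        with open(outdir / f"fit_{direction}.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        fit_summaries[direction] = summary

    if vif_rows:
        pd.DataFrame(vif_rows, columns=["direction", "term", "vif"]).to_csv(
            outdir / "vif.csv", index=False
        )

    # --- descriptive report -------------------------------------------------
    report = descriptives.summarize(
        data.interactions, data.scans, pop.roster, paternity, pop.memberships
    )
    with open(outdir / "descriptives.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "synth": {k: v for k, v in vars(cfg).items() if k != "true_effects"}
        | {"true_effects": dict(cfg.true_effects)},
        "stages": ["synth", "elo", "genotype", "paternity", "permtest",
                   "table", "fit", "report"],
        "files": {},
    }
    for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if p.name == "manifest.json":
            continue
        manifest["files"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
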