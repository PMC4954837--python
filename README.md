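# nigra

Analysis pipeline for **male-infant affiliation in wild crested
macaques** (*Macaca nigra*) — and, more generally, for dyadic
male-infant association studies in multi-male primate groups that
combine behavioral observation with non-invasive microsatellite
parentage.

In promiscuous primates it is unclear why adult males and infants
affiliate at all: males could be investing in their own offspring
(paternal investment), courting the mother (care-then-mate), or simply
tolerating infants; infants may actively seek male protectors.
Answering this requires stitching together several analyses that are
rarely packaged together:

1. **Dominance** — sequential Elo ratings from dated agonistic events,
   standardized daily within sex and group to [0, 1]:
   winner gains `k (1 - p)` with `p = 1 / (1 + 10^((R_loser - R_winner)/400))`.
2. **Parentage** — multi-tube consensus genotyping of replicate PCRs
   (het: both alleles ≥2×, ≥4 PCRs; hom: one allele 6×, extension to
   11), locus statistics (Ho, PIC, Monte-Carlo HWE, null-allele index,
   P(ID), P(ID)sib = ¼ + ½Σp² + ½(Σp²)² − ¼Σp⁴), and exclusion-based
   sire assignment with LOD support and simulation-based confidence.
3. **Partner preference** — permutation tests on initiator × recipient
   contingency tables (initiator labels shuffled across events, the
   observed data counted as one of 10,000 permutations).
4. **Daily dyad models** — binomial GLMMs of whether an infant (or a
   male) initiated an affiliation on a given day, with z-scored social
   predictors, an observation-effort offset, random intercepts and
   slopes, and two Gaussian-kernel **temporal autocorrelation terms**
   (kernel-weighted means of other rows' residuals keyed on the infant
   and on the male, kernel SDs chosen by profile likelihood).

Because raw field data of this kind are not deposited, the package
ships a first-class synthetic-data module (`nigra.synth`) that
emulates the whole data-generating process — male migration with
Gamma tenures, rank-skewed paternity, allelic dropout, AR(1)-correlated
dyadic affiliation — so every stage is validated by parameter recovery.
See `docs/methods.md` for the full model descriptions and assumptions.

## Worked example

```python
import numpy as np
from nigra.synth import SimulationConfig, generate
from nigra import elo, genotyping, parentage, modeltable, acglmm

cfg = SimulationConfig(n_groups=1, females_per_group=10, males_per_group=5,
                       study_days=240, birth_rate=0.004, seed=1)
data = generate(cfg)
pop = data.population

# dominance
ranks = elo.daily_ranks(data.agonistic, pop.memberships, pop.roster,
                        days=np.arange(cfg.study_days))

# parentage
calls = genotyping.call_all(data.pcr, on_contamination="mark")
paternity = parentage.assign_all(calls, pop.conceptions[["infant", "mother"]])
print(paternity[["offspring", "sire", "category"]].head())

# dyad-day model with autocorrelation terms
table = modeltable.assemble("infant", data.scans, data.interactions, ranks,
                            pop.roster, pop.memberships, pop.conceptions,
                            paternity, constant_policy="drop")
spec = acglmm.ModelSpec(
    test_terms=[t for t in acglmm.full_test_terms("infant")
                if all(p in table.columns for p in t.split(":"))],
    control_terms=[c for c in acglmm.CONTROL_TERMS if c in table.columns],
    random_terms=[],
)
fit, work = acglmm.fit_with_ac(table, spec)
print({k: round(v, 1) for k, v in fit.ac_sigmas.items()},
      round(fit.params["z_mother_presence"], 3))
```

Output:

```
  offspring  sire category
0      I001  M002   strict
1      I002  M002   strict
2      I003  M002   strict
3      I004  M002   strict
4      I005  M002   strict
{'infant': 9.1, 'male': 4.2} -0.21
```

All five infants are assigned to the same sire under the strict
exclusion category — the generator's paternity skew concentrates
conceptions on the top-ranked male — and the fitted infant model
recovers the planted negative mother-presence effect of -0.2 (infants
initiate more affiliations towards males when the mother is away); the
two autocorrelation kernels settle on SDs of a few days, consistent
with the generator's AR(1) dyadic process.

The same workflow runs from the shell:

```bash
nigra all --outdir run --seed 0        # synth → elo → genotype → paternity
                                       #   → permtest → table → fit → report
nigra synth --outdir run --seed 0      # or stage by stage
nigra elo --workdir run
nigra report --workdir run
```

Every run writes a `manifest.json` with SHA-256 hashes of all
artifacts; reruns with the same seed are byte-identical.

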