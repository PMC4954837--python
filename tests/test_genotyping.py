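"""Consensus calling rules and locus statistics."""

import numpy as np
import pandas as pd
import pytest

from nigra import genotyping as gt
from nigra.errors import ContaminationError
from nigra.synth import SimulationConfig, simulate_genotypes, simulate_population


class TestConsensusRules:
    @pytest.mark.parametrize(
        "reps,call,status",
        [
            # het: both alleles confirmed twice within >= 4 replicates
            ([{"A", "B"}, {"A", "B"}, {"A"}, {"B"}], ("A", "B"), "het_confirmed"),
            # hom: one allele in six independent PCRs
            ([{"A"}] * 6, ("A", "A"), "hom_confirmed"),
            # extension: single het replicate never reconfirmed in 11 reps
            ([{"A"}] * 5 + [{"A", "B"}] + [{"A"}] * 5, ("A", "A"), "hom_confirmed"),
            # too few replicates for a hom call
            ([{"A"}] * 5, None, "unresolved"),
            # second allele confirmed twice blocks the hom call, and the
            # het needs both alleles twice
            ([{"A"}] * 6 + [{"A", "B"}, {"B"}], ("A", "B"), "het_confirmed"),
            ([{"A"}, {"B"}, {"A"}], None, "unresolved"),
        ],
    )
    def test_rule_table(self, reps, call, status):
        got_call, got_status = gt.call_consensus(reps)
        assert got_status == status
        assert got_call == call

    def test_three_confirmed_alleles_is_contamination(self):
        reps = [{"A", "B"}, {"A", "C"}, {"B", "C"}, {"A"}, {"B"}, {"C"}]
        with pytest.raises(ContaminationError):
            gt.call_consensus(reps)

    def test_order_invariance(self):
        reps = [{"A"}] * 5 + [{"A", "B"}] + [{"A"}] * 5
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = [reps[i] for i in rng.permutation(len(reps))]
            assert gt.call_consensus(perm) == gt.call_consensus(reps)

    def test_noiseless_replicates_recover_truth(self):
        cfg = SimulationConfig(
            n_groups=1, females_per_group=6, males_per_group=4,
            study_days=200, birth_rate=0.004, dropout_rate=0.0,
            misprint_rate=0.0, msat_loci=5, seed=7,
        )
        pop = simulate_population(cfg)
        pcr, truth = simulate_genotypes(pop)
        calls = gt.call_all(pcr)
        for row in calls.itertuples(index=False):
            assert row.status in ("het_confirmed", "hom_confirmed")
            assert (row.allele1, row.allele2) == truth[row.individual][row.locus]

    def test_dropout_single_allele_fraction(self):
        # each het replicate shows one allele w.p. 1 - (1-d)^2
        d = 0.2
        cfg = SimulationConfig(
            n_groups=1, females_per_group=4, males_per_group=3,
            study_days=30, birth_rate=0.0, dropout_rate=d, misprint_rate=0.0,
            msat_loci=6, alleles_per_locus=2, n_replicates=40, seed=3,
        )
        pop = simulate_population(cfg)
        pcr, truth = simulate_genotypes(pop)
        singles = totals = 0
        for (ind, locus), sub in pcr.groupby(["individual", "locus"]):
            if truth[ind][locus][0] != truth[ind][locus][1]:
                totals += len(sub)
                singles += (sub["allele2"].fillna("") == "").sum()
        frac = singles / totals
        expected = 1 - (1 - d) ** 2
        se = np.sqrt(expected * (1 - expected) / totals)
        assert abs(frac - expected) < 4 * se


class TestLocusStatistics:
    def _geno(self, pairs, locus="L1"):
        return pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(len(pairs))],
                "locus": locus,
                "allele1": [p[0] for p in pairs],
                "allele2": [p[1] for p in pairs],
                "status": "het_confirmed",
            }
        )

    def test_gene_count_frequencies(self):
        freqs = gt.allele_frequencies(self._geno([("A", "A"), ("A", "B")]))
        assert freqs["L1"] == {"A": 0.75, "B": 0.25}

    def test_frequencies_order_invariant(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "A"), ("C", "C")]
        f1 = gt.allele_frequencies(self._geno(pairs))
        f2 = gt.allele_frequencies(self._geno(pairs[::-1]))
        assert f1 == f2

    @pytest.mark.parametrize(
        "p,expected",
        [
            (np.array([0.5, 0.5]), 0.375),
            (np.array([1.0]), 0.0),
        ],
    )
    def test_pic(self, p, expected):
        assert gt.pic_from_freqs(p) == pytest.approx(expected)

    def test_summary_ho(self):
        stats = gt.locus_summary(
            self._geno([("A", "B"), ("A", "B"), ("A", "B")]), run_hwe=False
        )
        assert stats[0].ho == 1.0
        stats = gt.locus_summary(self._geno([("A", "A")] * 5), run_hwe=False)
        assert stats[0].ho == 0.0
        assert stats[0].pic == 0.0

    @pytest.mark.parametrize(
        "ho,he,expected",
        [(0.5, 0.5, 0.0), (0.0, 0.5, 1.0), (0.6, 0.5, -1 / 11)],
    )
    def test_null_allele_index(self, ho, he, expected):
        assert gt.null_allele_index(ho, he) == pytest.approx(expected)

    def test_null_allele_undefined_at_he_zero(self):
        assert gt.null_allele_index(0.0, 0.0) is None


class TestHardyWeinberg:
    def test_proportions_at_hwe_give_large_p(self):
        # 25 AA, 50 AB, 25 BB: exactly Hardy-Weinberg at p = 0.5
        pairs = [("A", "A")] * 25 + [("A", "B")] * 50 + [("B", "B")] * 25
        df = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(100)],
                "locus": "L1",
                "allele1": [p[0] for p in pairs],
                "allele2": [p[1] for p in pairs],
            }
        )
        p = gt.hwe_test(df, "L1", n_shuffles=500, rng=np.random.default_rng(0))
        assert p > 0.5

    def test_all_heterozygotes_rejected(self):
        df = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(50)],
                "locus": "L1",
                "allele1": "A",
                "allele2": "B",
            }
        )
        p = gt.hwe_test(df, "L1", n_shuffles=2000, rng=np.random.default_rng(0))
        assert p < 0.01

    def test_monomorphic_convention(self):
        df = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(10)],
                "locus": "L1",
                "allele1": "A",
                "allele2": "A",
            }
        )
        assert gt.hwe_test(df, "L1", rng=np.random.default_rng(0)) == 1.0

    def test_type1_calibration(self):
        # genotypes drawn from HWE should reject at roughly alpha
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 120
        for k in range(n_rep):
            alleles = rng.choice(["A", "B", "C"], size=(40, 2), p=[0.5, 0.3, 0.2])
            df = pd.DataFrame(
                {
                    "individual": [f"i{j}" for j in range(40)],
                    "locus": "L1",
                    "allele1": alleles[:, 0],
                    "allele2": alleles[:, 1],
                }
            )
            if gt.hwe_test(df, "L1", n_shuffles=400, rng=rng) <= 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.0 <= rate <= 0.12  # 0.05 +/- Monte-Carlo error


class TestProbabilityOfIdentity:
    @pytest.mark.parametrize(
        "p,pid,pidsib",
        [
            (np.array([0.5, 0.5]), 0.375, 0.59375),
            (np.array([0.25] * 4), 0.109375, 0.40234375),
        ],
    )
    def test_closed_forms(self, p, pid, pidsib):
        got_pid, got_sib = gt.pid_locus(p)
        assert got_pid == pytest.approx(pid)
        assert got_sib == pytest.approx(pidsib)

    def test_sib_dominates_and_products_decrease(self):
        rng = np.random.default_rng(0)
        freqs = {
            f"L{k}": dict(
                zip("abcdef", rng.dirichlet(np.ones(6)))
            )
            for k in range(8)
        }
        prev_pid, prev_sib = 1.0, 1.0
        loci = list(freqs)
        for k in range(1, len(loci) + 1):
            pid_k, sib_k = gt.pid(freqs, loci[:k])
            assert sib_k >= pid_k
            assert pid_k <= prev_pid and sib_k <= prev_sib
            prev_pid, prev_sib = pid_k, sib_k

    def test_min_loci_threshold_one(self):
        freqs = {"L1": {"A": 0.5, "B": 0.5}}
        assert gt.min_loci_for_identity(freqs, 1.0)[0] == 1

    def test_min_loci_identical_loci(self):
        # PIDsib = 0.59375 per locus -> need ceil(log .001 / log .59375) = 14
        freqs = {f"L{k}": {"A": 0.5, "B": 0.5} for k in range(20)}
        k, cum, attained = gt.min_loci_for_identity(freqs, 1e-3)
        assert attained
        assert cum <= 1e-3
        assert k == int(np.ceil(np.log(1e-3) / np.log(0.59375)))

    def test_min_loci_unattainable_flagged(self):
        freqs = {f"L{k}": {"A": 0.5, "B": 0.5} for k in range(3)}
        k, cum, attained = gt.min_loci_for_identity(freqs, 1e-6)
        assert not attained and k == 3

    def test_min_loci_non_increasing_in_locus_count(self):
        rng = np.random.default_rng(1)
        freqs = {
            f"L{k}": dict(zip("abcdef", rng.dirichlet(np.ones(6))))
            for k in range(12)
        }
        loci = list(freqs)
        prev = None
        for n_avail in range(6, 13):
            k, _, attained = gt.min_loci_for_identity(
                {l: freqs[l] for l in loci[:n_avail]}, 1e-3
            )
            if attained and prev is not None:
                assert k <= prev
            prev = k if attained else prev
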