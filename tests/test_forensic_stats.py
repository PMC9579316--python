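"""Forensic battery: frozen examples plus independent enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from mhkit import forensic_stats as fs
from mhkit import simdata
from mhkit.simdata import SimConfig


def _geno_df(rows):
    """rows: (sample, locus, allele1, allele2) with '' allele2 for homozygotes."""
    return pd.DataFrame(
        [
            {"sample": s, "locus": l, "allele1": a1, "allele2": a2,
             "doc": 100, "balance": "", "qc": "PASS"}
            for s, l, a1, a2 in rows
        ]
    )


class TestAlleleFrequencies:
    def test_hand_counted_two_samples(self):
        ft = fs.allele_frequencies(_geno_df([("S1", "L", "A", ""), ("S2", "L", "A", "B")]))
        assert ft.freqs["L"] == pytest.approx({"A": 0.75, "B": 0.25})
        assert ft.n["L"] == 2

    def test_single_homozygote(self):
        ft = fs.allele_frequencies(_geno_df([("S1", "L", "A", "")]))
        assert ft.freqs["L"]["A"] == 1.0

    def test_rare_allele_in_92_samples(self):
        # an allele carried by 3 heterozygotes among 92 diploids: 3/184
        rows = [(f"S{i}", "L", "AACC", "AATG") for i in range(3)]
        rows += [(f"S{i}", "L", "AATG", "") for i in range(3, 92)]
        ft = fs.allele_frequencies(_geno_df(rows))
        assert ft.freqs["L"]["AACC"] == pytest.approx(3 / 184)
        assert round(ft.freqs["L"]["AACC"], 3) == 0.016

    def test_no_call_reduces_n(self):
        df = _geno_df([("S1", "L", "A", "B"), ("S2", "L", "A", "")])
        df.loc[1, "qc"] = "NO_CALL"
        df.loc[1, "allele1"] = ""
        ft = fs.allele_frequencies(df)
        assert ft.n["L"] == 1

    def test_frequency_table_round_trip(self, tmp_path, small_freqs):
        path = tmp_path / "f.csv"
        small_freqs.to_csv(path)
        back = fs.FrequencyTable.from_csv(path)
        assert back.population == small_freqs.population
        for locus in small_freqs.freqs:
            assert back.freqs[locus] == pytest.approx(small_freqs.freqs[locus])


class TestAe:
    def test_monomorphic_is_one(self):
        assert fs.ae([1.0]) == pytest.approx(1.0)

    def test_uniform_equals_allele_count(self):
        assert fs.ae([0.25] * 4) == pytest.approx(4.0)

    def test_skewed_vector(self):
        assert fs.ae([0.5, 0.25, 0.25]) == pytest.approx(1 / 0.375)

    def test_relabeling_invariant_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(k))
            a = fs.ae(p)
            assert a == pytest.approx(fs.ae(p[rng.permutation(k)]))
            assert 1.0 - 1e-12 <= a <= k + 1e-12


class TestHeTpi:
    def test_he_and_tpi_printed_pairs(self):
        # 69 heterozygotes of 92 -> He 0.7500, TPI 2.0000
        rows = [(f"S{i}", "L", "A", "B") for i in range(69)]
        rows += [(f"S{i}", "L", "A", "") for i in range(69, 92)]
        he = fs.observed_heterozygosity(_geno_df(rows), "L")
        assert he == pytest.approx(69 / 92)
        assert round(fs.tpi(he), 4) == 2.0000

    def test_tpi_uses_full_precision_counts(self):
        # 80/92 = 0.869565...; rounding He to 0.8696 first would give 3.8344
        assert round(fs.tpi(80 / 92), 4) == 3.8333

    def test_all_homozygous(self):
        rows = [(f"S{i}", "L", "A", "") for i in range(5)]
        assert fs.observed_heterozygosity(_geno_df(rows), "L") == 0.0
        assert fs.tpi(0.0) == 0.5

    def test_he_of_one_warns_and_returns_inf(self):
        with pytest.warns(UserWarning):
            assert math.isinf(fs.tpi(1.0))


class TestMatchProbability:
    def test_single_class(self):
        mp, pd_ = fs.match_probability(_geno_df([("S1", "L", "A", "B"), ("S2", "L", "A", "B")]), "L")
        assert (mp, pd_) == (1.0, 0.0)

    def test_two_equal_classes(self):
        mp, pd_ = fs.match_probability(
            _geno_df([("S1", "L", "A", "B"), ("S2", "L", "A", "")]), "L"
        )
        assert mp == pytest.approx(0.5)

    def test_matches_brute_force_pair_rate(self, small_genotypes):
        """MP equals the ordered-pair (with replacement) genotype match rate."""
        locus = small_genotypes["locus"].iloc[0]
        rows = small_genotypes[small_genotypes["locus"] == locus]
        gts = [tuple(sorted((r.allele1, r.allele2 or r.allele1))) for r in rows.itertuples()]
        n = len(gts)
        brute = sum(g1 == g2 for g1 in gts for g2 in gts) / n**2
        mp, pd_ = fs.match_probability(small_genotypes, locus)
        assert mp == pytest.approx(brute, abs=1e-12)
        assert pd_ == pytest.approx(1 - brute, abs=1e-12)


# ---------------------------------------------------------------------------
# exclusion-power oracles: exhaustive enumeration under HWE

from tests_oracles import pe_duo_enum, pe_trio_enum  # noqa: E402


class TestExclusionPowers:
    def test_biallelic_half_spot_values(self):
        assert fs.pe_duo([0.5, 0.5]) == pytest.approx(0.125, abs=1e-15)
        assert fs.pe_trio([0.5, 0.5]) == pytest.approx(0.1875, abs=1e-15)

    def test_monomorphic_zero(self):
        assert fs.pe_duo([1.0]) == pytest.approx(0.0, abs=1e-12)
        assert fs.pe_trio([1.0]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_formulas_match_enumeration(self, k):
        rng = np.random.default_rng(k)
        for _ in range(25):
            p = rng.dirichlet(np.ones(k))
            assert fs.pe_duo(p) == pytest.approx(pe_duo_enum(p), abs=1e-12)
            assert fs.pe_trio(p) == pytest.approx(pe_trio_enum(p), abs=1e-12)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_enum(counts):
    """Exact conditional p-value by exhausting biallelic heterozygote counts."""
    n = sum(counts.values())
    alleles = sorted({a for pair in counts for a in pair})
    assert len(alleles) == 2
    a, b = alleles
    na = sum(c * ((a1 == a) + (a2 == a)) for (a1, a2), c in counts.items())

    def logprob(nab):
        naa = (na - nab) // 2
        nbb = n - naa - nab
        return (
            nab * math.log(2)
            - gammaln(naa + 1)
            - gammaln(nab + 1)
            - gammaln(nbb + 1)
        )

    obs = counts.get((a, b), 0)
    support = [h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)]
    probs = {h: logprob(h) for h in support}
    log_z = max(probs.values())
    weights = {h: math.exp(v - log_z) for h, v in probs.items()}
    z = sum(weights.values())
    return sum(w for h, w in weights.items() if probs[h] <= probs[obs] + 1e-12) / z


class TestHWE:
    def test_monomorphic_is_one(self):
        assert fs.hwe_exact_test({("A", "A"): 30}) == 1.0

    def test_seed_reproducibility(self):
        counts = {("A", "A"): 10, ("A", "B"): 5, ("B", "B"): 10}
        p1 = fs.hwe_exact_test(counts, n_perm=2000, seed=3)
        p2 = fs.hwe_exact_test(counts, n_perm=2000, seed=3)
        assert p1 == p2

    @pytest.mark.parametrize(
        "counts",
        [
            {("A", "A"): 4, ("A", "B"): 2, ("B", "B"): 4},  # het deficit, 2n = 20
            {("A", "A"): 1, ("A", "B"): 8, ("B", "B"): 1},  # het excess
            {("A", "A"): 3, ("A", "B"): 5, ("B", "B"): 2},
        ],
    )
    def test_mc_matches_exact_enumeration(self, counts):
        exact = hwe_exact_enum(counts)
        mc = fs.hwe_exact_test(counts, n_perm=20000, seed=11)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_extreme_disequilibrium_rejected(self):
        # all heterozygotes at a balanced biallelic locus: p must be tiny
        counts = {("A", "B"): 40}
        assert fs.hwe_exact_test(counts, n_perm=5000, seed=1) < 0.01


class TestCombinedPowers:
    def test_single_locus_equals_per_locus(self):
        cp = fs.combined_powers([0.2], [0.3], [0.4])
        assert cp.cpd == pytest.approx(0.8)
        assert cp.cped == pytest.approx(0.3)
        assert cp.cpet == pytest.approx(0.4)

    def test_log_space_matches_naive_product(self):
        rng = np.random.default_rng(5)
        mp = rng.uniform(0.05, 0.3, size=12)
        ped = rng.uniform(0.2, 0.5, size=12)
        pet = rng.uniform(0.4, 0.7, size=12)
        cp = fs.combined_powers(mp, ped, pet)
        assert 10**cp.log10_comp_cpd == pytest.approx(np.prod(mp), rel=1e-10)
        assert 10**cp.log10_comp_cped == pytest.approx(np.prod(1 - ped), rel=1e-10)
        assert 10**cp.log10_comp_cpet == pytest.approx(np.prod(1 - pet), rel=1e-10)

    def test_adding_a_locus_never_decreases_power(self):
        cp1 = fs.combined_powers([0.2, 0.3], [0.3, 0.2], [0.4, 0.1])
        cp2 = fs.combined_powers([0.2, 0.3, 0.9], [0.3, 0.2, 0.01], [0.4, 0.1, 0.01])
        assert cp2.cpd >= cp1.cpd and cp2.cped >= cp1.cped and cp2.cpet >= cp1.cpet


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _df_from_pairs(pairs_a, pairs_b):
    rows = []
    for i, ((a1, a2), (b1, b2)) in enumerate(zip(pairs_a, pairs_b)):
        rows.append((f"S{i}", "LA", *sorted((a1, a2))))
        rows.append((f"S{i}", "LB", *sorted((b1, b2))))
    return _geno_df([(s, l, x, y if y != x else "") for s, l, x, y in rows])


class TestLD:
    def test_complete_coupling_is_one(self):
        # haplotypes AB and ab only, each at 1/2: r2 = 1
        pairs_a = [("A", "A"), ("a", "a"), ("A", "a")] * 10
        pairs_b = [("B", "B"), ("b", "b"), ("B", "b")] * 10
        res = fs.ld_r2(_df_from_pairs(pairs_a, pairs_b), "LA", "LB")
        assert res.r2 == pytest.approx(1.0, abs=1e-6)

    def test_biallelic_unambiguous_matches_phased_oracle(self):
        """Without double heterozygotes the EM equals direct phased counting."""
        rng = np.random.default_rng(7)
        haps = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
        hw = np.array([0.4, 0.1, 0.2, 0.3])
        pairs_a, pairs_b, kept = [], [], []
        while len(kept) < 200:
            h1, h2 = rng.choice(4, size=2, p=hw)
            # keep phase-unambiguous individuals only
            if haps[h1][0] != haps[h2][0] and haps[h1][1] != haps[h2][1]:
                continue
            kept.append((h1, h2))
            pairs_a.append((haps[h1][0], haps[h2][0]))
            pairs_b.append((haps[h1][1], haps[h2][1]))
        flat = [haps[h] for pair in kept for h in pair]
        pa = sum(h[0] == "A" for h in flat) / len(flat)
        qb = sum(h[1] == "B" for h in flat) / len(flat)
        hab = sum(h == ("A", "B") for h in flat) / len(flat)
        d = hab - pa * qb
        oracle = d * d / (pa * (1 - pa) * qb * (1 - qb))
        res = fs.ld_r2(_df_from_pairs(pairs_a, pairs_b), "LA", "LB")
        assert res.converged
        assert res.r2 == pytest.approx(oracle, abs=1e-6)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(13)
        n = 500
        pairs_a = [tuple(rng.choice(["A", "a"], size=2, p=[0.6, 0.4])) for _ in range(n)]
        pairs_b = [tuple(rng.choice(["B", "b"], size=2, p=[0.3, 0.7])) for _ in range(n)]
        res = fs.ld_r2(_df_from_pairs(pairs_a, pairs_b), "LA", "LB")
        assert res.r2 < 0.05

    def test_too_few_shared_samples_raises(self):
        pairs_a = [("A", "a")] * 4
        pairs_b = [("B", "b")] * 4
        with pytest.raises(ValueError, match="shared callable"):
            fs.ld_r2(_df_from_pairs(pairs_a, pairs_b), "LA", "LB")


class TestStatsTable:
    def test_battery_on_synthetic_panel(self, small_genotypes):
        df = fs.stats_table(small_genotypes, hwe_perms=500, seed=2)
        assert set(df["locus"]) == set(small_genotypes["locus"])
        assert ((df["ae"] >= 1) & (df["ae"] <= df["k"])).all()
        assert df["pd"].between(0, 1).all()
        assert (df["mp"] + df["pd"]).round(12).eq(1).all()
        assert df["ped"].between(0, 1).all() and df["pet"].between(0, 1).all()
        # TPI consistency with He on every row
        finite = df[df["he"] < 1]
        assert np.allclose(finite["tpi"], 1 / (2 * (1 - finite["he"])))

    def test_ae_min_filters_subpanel(self, small_genotypes):
        full = fs.stats_table(small_genotypes, hwe_perms=200, seed=2)
        sub = fs.stats_table(small_genotypes, hwe_perms=200, seed=2, ae_min=2.0)
        assert set(sub["locus"]) == set(full[full["ae"] >= 2.0]["locus"])
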