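"""Per-locus and combined forensic parameters for MH panels.

Given a long-format genotype table (sample, locus, allele1, allele2, qc)
this module computes the standard forensic identification battery:

* allele frequencies (gene-counting over QC-passing diploid calls),
* Ae, the effective number of alleles, ``1 / sum(p_i^2)``,
* observed heterozygosity He and expected heterozygosity ``1 - sum(p^2)``,
* match probability MP = ``sum(g_j^2)`` over observed genotype
  frequencies and its complement the power of discrimination PD,
* powers of exclusion for motherless duos (PED) and full trios (PET)
  from allele frequencies (Garber-Morris formulas),
* typical paternity index TPI = ``1 / (2 (1 - He))``,
* a Monte-Carlo exact test for Hardy-Weinberg equilibrium that permutes
  the 2n gene copies into n diploids and compares conditional genotype
  probabilities (Guo-Thompson style),
* combined powers over a locus set with complements accumulated in
  log10 space (CPD, CPED, CPET),
* pairwise linkage disequilibrium between MH loci as a multi-allelic
  r-squared from EM-estimated two-locus haplotype frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "FrequencyTable",
    "LocusStats",
    "CombinedPowers",
    "allele_frequencies",
    "ae",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "tpi",
    "match_probability",
    "pe_duo",
    "pe_trio",
    "genotype_counts",
    "hwe_exact_test",
    "locus_stats",
    "stats_table",
    "combined_powers",
    "ld_r2",
]


# ---------------------------------------------------------------------------
# frequency table


@dataclass
class FrequencyTable:
    """Per-locus allele frequency vectors for one population.

    ``freqs[locus]`` maps allele label -> frequency (summing to 1);
    ``n[locus]`` is the number of diploid individuals the locus was
    estimated from (2n gene copies).
    """

    population: str
    freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)

    def loci(self) -> list[str]:
        return list(self.freqs)

    def vector(self, locus: str) -> np.ndarray:
        return np.array(list(self.freqs[locus].values()), dtype=float)

    def validate(self, tol: float = 1e-9) -> None:
        for locus, fr in self.freqs.items():
            p = np.array(list(fr.values()))
            if abs(p.sum() - 1.0) > tol:
                raise ValueError(f"{locus}: frequencies sum to {p.sum()}, not 1")
            if np.any(p <= 0) or np.any(p > 1):
                raise ValueError(f"{locus}: frequencies must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": self.population, "locus": loc, "allele": a, "freq": f, "n": self.n[loc]}
            for loc, fr in self.freqs.items()
            for a, f in fr.items()
        ]
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "freq", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencyTable":
        pops = df["population"].unique()
        if len(pops) != 1:
            raise ValueError("expected a single population per table")
        ft = cls(population=str(pops[0]))
        for locus, grp in df.groupby("locus", sort=False):
            ft.freqs[str(locus)] = dict(zip(grp["allele"].astype(str), grp["freq"].astype(float)))
            ft.n[str(locus)] = int(grp["n"].iloc[0])
        return ft

    @classmethod
    def from_csv(cls, path) -> "FrequencyTable":
        return cls.from_frame(pd.read_csv(path, dtype={"allele": str}, keep_default_na=False))


def _callable_rows(genotypes: pd.DataFrame, locus: Optional[str] = None) -> pd.DataFrame:
    sub = genotypes if locus is None else genotypes[genotypes["locus"] == locus]
    return sub[(sub["qc"] == "PASS") & (sub["allele1"] != "")]


def allele_frequencies(genotypes: pd.DataFrame, population: str = "POP") -> FrequencyTable:
    """Gene-counting allele frequencies from QC-passing diploid calls.

    Homozygotes contribute two copies of their allele; loci with no-call
    samples use that locus's reduced n.  Loci with zero callable samples
    are omitted with a warning.
    """
    ft = FrequencyTable(population=population)
    for locus in genotypes["locus"].unique():
        rows = _callable_rows(genotypes, locus)
        n = len(rows)
        if n == 0:
            warnings.warn(f"locus {locus}: no callable samples, omitted")
            continue
        counts: dict[str, int] = {}
        for a1, a2 in zip(rows["allele1"], rows["allele2"]):
            a2 = a2 if a2 else a1  # homozygote serialized with one allele
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
        ft.freqs[locus] = {a: c / (2 * n) for a, c in sorted(counts.items())}
        ft.n[locus] = n
    return ft


# ---------------------------------------------------------------------------
# per-locus statistics


def ae(freqs: Sequence[float] | Mapping[str, float]) -> float:
    """Effective number of alleles, 1 / sum(p_i^2); 1.0 iff monomorphic."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    return float(1.0 / np.sum(p**2))


def observed_heterozygosity(genotypes: pd.DataFrame, locus: str) -> float:
    """Fraction of callable individuals heterozygous at ``locus``."""
    rows = _callable_rows(genotypes, locus)
    if len(rows) == 0:
        raise ValueError(f"locus {locus}: no callable samples")
    het = (rows["allele2"] != "") & (rows["allele1"] != rows["allele2"])
    return float(het.mean())


def expected_heterozygosity(freqs) -> float:
    """HWE-expected heterozygosity, 1 - sum(p_i^2)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    return float(1.0 - np.sum(p**2))


def tpi(he: float) -> float:
    """Typical paternity index, 1 / (2 (1 - He)), from observed He."""
    if he >= 1.0:
        warnings.warn("He = 1: TPI is unbounded")
        return math.inf
    return 1.0 / (2.0 * (1.0 - he))


def match_probability(genotypes: pd.DataFrame, locus: str) -> tuple[float, float]:
    """(MP, PD) from observed genotype class frequencies.

    MP is the probability that two individuals drawn with replacement from
    the sample share a genotype: ``sum(g_j^2)``; PD = 1 - MP.
    """
    rows = _callable_rows(genotypes, locus)
    n = len(rows)
    if n == 0:
        raise ValueError(f"locus {locus}: no callable samples")
    classes: dict[tuple[str, str], int] = {}
    for a1, a2 in zip(rows["allele1"], rows["allele2"]):
        a2 = a2 if a2 else a1
        key = (a1, a2) if a1 <= a2 else (a2, a1)
        classes[key] = classes.get(key, 0) + 1
    g = np.array(list(classes.values()), dtype=float) / n
    mp = float(np.sum(g**2))
    return mp, 1.0 - mp


def pe_duo(freqs) -> float:
    """Power of exclusion for a motherless duo from allele frequencies.

    Probability that a random non-father shares no allele with the child
    (Garber-Morris): 1 - 4*S2 + 4*S3 - 3*S4 + 2*S2^2 with Sk = sum(p^k).
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    s2, s3, s4 = np.sum(p**2), np.sum(p**3), np.sum(p**4)
    return float(1 - 4 * s2 + 4 * s3 - 3 * s4 + 2 * s2**2)


def pe_trio(freqs) -> float:
    """Power of exclusion for a mother-child-man trio (Garber-Morris).

    1 - 2*S2 + S3 + 2*S4 - 3*S5 - 2*S2^2 + 3*S2*S3 with Sk = sum(p^k).
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    s2, s3, s4, s5 = np.sum(p**2), np.sum(p**3), np.sum(p**4), np.sum(p**5)
    return float(1 - 2 * s2 + s3 + 2 * s4 - 3 * s5 - 2 * s2**2 + 3 * s2 * s3)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo)


def genotype_counts(genotypes: pd.DataFrame, locus: str) -> dict[tuple[str, str], int]:
    """Observed genotype class counts (unordered allele pairs) at a locus."""
    rows = _callable_rows(genotypes, locus)
    out: dict[tuple[str, str], int] = {}
    for a1, a2 in zip(rows["allele1"], rows["allele2"]):
        a2 = a2 if a2 else a1
        key = (a1, a2) if a1 <= a2 else (a2, a1)
        out[key] = out.get(key, 0) + 1
    return out


def hwe_exact_test(
    counts: Mapping[tuple[str, str], int],
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test for Hardy-Weinberg equilibrium.

    Permutes the 2n observed gene copies into n random diploids and
    compares the conditional probability of each permuted genotype array
    (given the allele counts) to the observed one:
    ``p = (1 + #{perm prob <= observed prob}) / (1 + n_perm)``.
    Monomorphic loci return p = 1 by convention.  Reproducible under a
    fixed seed.
    """
    alleles = sorted({a for pair in counts for a in pair})
    k = len(alleles)
    if k <= 1:
        return 1.0
    idx = {a: i for i, a in enumerate(alleles)}
    n = sum(counts.values())
    copies = np.empty(2 * n, dtype=np.int64)
    pos = 0
    for (a1, a2), c in counts.items():
        copies[pos : pos + c] = idx[a1]
        pos += c
        copies[pos : pos + c] = idx[a2]
        pos += c

    def stat(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """log conditional probability up to a permutation-invariant constant.

        T = (#het) * log 2 - sum_g log(count_g!) over genotype classes g.
        """
        het = (lo != hi).sum(axis=-1)
        codes = lo * k + hi
        nrow = codes.shape[0]
        flat = codes + (np.arange(nrow) * k * k)[:, None]
        cnt = np.bincount(flat.ravel(), minlength=nrow * k * k).reshape(nrow, k * k)
        return het * math.log(2.0) - gammaln(cnt + 1.0).sum(axis=1)

    h_obs = sum(c for (a1, a2), c in counts.items() if a1 != a2)
    t_obs = h_obs * math.log(2.0) - float(
        sum(gammaln(c + 1.0) for c in counts.values())
    )

    rng = np.random.default_rng(seed)
    # vectorized permutations: argsort of uniforms is a uniform random permutation
    perms = np.argsort(rng.random((n_perm, 2 * n)), axis=1)
    shuffled = copies[perms].reshape(n_perm, n, 2)
    lo = np.minimum(shuffled[..., 0], shuffled[..., 1])
    hi = np.maximum(shuffled[..., 0], shuffled[..., 1])
    t_perm = stat(lo, hi)
    hits = int(np.sum(t_perm <= t_obs + 1e-9))
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class LocusStats:
    """The per-locus forensic battery (one panel-report row)."""

    locus: str
    n: int
    k: int
    ae: float
    he: float
    he_exp: float
    mp: float
    pd: float
    ped: float
    pet: float
    tpi: float
    hwe_p: float


def locus_stats(
    genotypes: pd.DataFrame,
    locus: str,
    freqs: Optional[Mapping[str, float]] = None,
    hwe_perms: int = 10000,
    seed: int = 0,
) -> LocusStats:
    """Compute the full battery at one locus from a genotype table."""
    if freqs is None:
        ft = allele_frequencies(genotypes[genotypes["locus"] == locus])
        freqs = ft.freqs[locus]
    he = observed_heterozygosity(genotypes, locus)
    mp, pd_ = match_probability(genotypes, locus)
    return LocusStats(
        locus=locus,
        n=len(_callable_rows(genotypes, locus)),
        k=len(freqs),
        ae=ae(freqs),
        he=he,
        he_exp=expected_heterozygosity(freqs),
        mp=mp,
        pd=pd_,
        ped=pe_duo(freqs),
        pet=pe_trio(freqs),
        tpi=tpi(he),
        hwe_p=hwe_exact_test(genotype_counts(genotypes, locus), hwe_perms, seed),
    )


def stats_table(
    genotypes: pd.DataFrame,
    hwe_perms: int = 10000,
    seed: int = 0,
    ae_min: Optional[float] = None,
) -> pd.DataFrame:
    """Per-locus stats for every locus in a genotype table.

    ``ae_min`` keeps only loci with Ae >= the cutoff (subpanel selection,
    e.g. an identification panel at Ae >= 3.0).
    """
    ft = allele_frequencies(genotypes)
    rows = []
    for i, locus in enumerate(ft.loci()):
        st = locus_stats(genotypes, locus, ft.freqs[locus], hwe_perms, seed + i)
        rows.append(vars(st))
    df = pd.DataFrame(rows)
    if ae_min is not None:
        df = df[df["ae"] >= ae_min].reset_index(drop=True)
    return df


@dataclass
class CombinedPowers:
    """Combined discrimination / exclusion powers over a locus set.

    Complements are accumulated in log10 space; ``*_mantissa`` and
    ``*_exponent`` report the complement as mantissa x 10^exponent, so the
    combined power itself is ``1 - mantissa x 10^exponent``.
    """

    n_loci: int
    log10_comp_cpd: float
    log10_comp_cped: float
    log10_comp_cpet: float

    @staticmethod
    def _split(log10c: float) -> tuple[float, int]:
        exp = math.floor(log10c)
        return 10 ** (log10c - exp), exp

    @property
    def cpd_complement(self) -> tuple[float, int]:
        return self._split(self.log10_comp_cpd)

    @property
    def cped_complement(self) -> tuple[float, int]:
        return self._split(self.log10_comp_cped)

    @property
    def cpet_complement(self) -> tuple[float, int]:
        return self._split(self.log10_comp_cpet)

    @property
    def cpd(self) -> float:
        return 1.0 - 10**self.log10_comp_cpd

    @property
    def cped(self) -> float:
        return 1.0 - 10**self.log10_comp_cped

    @property
    def cpet(self) -> float:
        return 1.0 - 10**self.log10_comp_cpet


def combined_powers(
    mp: Iterable[float], ped: Iterable[float], pet: Iterable[float]
) -> CombinedPowers:
    """Combine per-locus MP/PED/PET across a panel.

    CPD = 1 - prod(MP_i); CPED = 1 - prod(1 - PED_i);
    CPET = 1 - prod(1 - PET_i).  Products are accumulated as sums of
    log10 so 48-locus complements around 1e-44 stay exact.
    """
    mp = list(mp)
    ped = list(ped)
    pet = list(pet)
    if not mp:
        raise ValueError("need at least one locus")
    return CombinedPowers(
        n_loci=len(mp),
        log10_comp_cpd=float(np.sum(np.log10(mp))),
        log10_comp_cped=float(np.sum(np.log10(1.0 - np.asarray(ped, dtype=float)))),
        log10_comp_cpet=float(np.sum(np.log10(1.0 - np.asarray(pet, dtype=float)))),
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDResult:
    r2: float
    converged: bool
    n_iter: int
    loglik: float
    hap_freqs: dict[tuple[str, str], float]


def _em_haplotype_freqs(
    pairs_a: list[tuple[str, str]],
    pairs_b: list[tuple[str, str]],
    tol: float,
    max_iter: int,
) -> tuple[dict[tuple[str, str], float], bool, int, float]:
    alleles_a = sorted({a for p in pairs_a for a in p})
    alleles_b = sorted({b for p in pairs_b for b in p})
    ia = {a: i for i, a in enumerate(alleles_a)}
    ib = {b: i for i, b in enumerate(alleles_b)}
    ka, kb = len(alleles_a), len(alleles_b)
    n = len(pairs_a)

    # initialize at linkage equilibrium from allele marginals
    pa = np.zeros(ka)
    pb = np.zeros(kb)
    for (a1, a2), (b1, b2) in zip(pairs_a, pairs_b):
        pa[ia[a1]] += 1
        pa[ia[a2]] += 1
        pb[ib[b1]] += 1
        pb[ib[b2]] += 1
    pa /= 2 * n
    pb /= 2 * n
    h = np.outer(pa, pb)

    # each individual: one or two phase configurations of two haplotypes
    configs = []
    for (a1, a2), (b1, b2) in zip(pairs_a, pairs_b):
        c1 = ((ia[a1], ib[b1]), (ia[a2], ib[b2]))
        if a1 == a2 or b1 == b2:
            configs.append((c1,))
        else:
            c2 = ((ia[a1], ib[b2]), (ia[a2], ib[b1]))
            configs.append((c1, c2))

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros_like(h)
        ll = 0.0
        for cfgs in configs:
            probs = np.array([h[h1] * h[h2] for h1, h2 in cfgs])
            tot = probs.sum()
            if tot <= 0:
                probs = np.full(len(cfgs), 1.0 / len(cfgs))
                tot = 1.0
            else:
                probs = probs / tot
            ll += math.log(max(tot, 1e-300))
            for w, (h1, h2) in zip(probs, cfgs):
                new[h1] += w
                new[h2] += w
        h = new / (2 * n)
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    haps = {
        (alleles_a[i], alleles_b[j]): float(h[i, j])
        for i in range(ka)
        for j in range(kb)
        if h[i, j] > 0
    }
    return haps, converged, it, prev_ll


def ld_r2(
    genotypes: pd.DataFrame,
    locus_a: str,
    locus_b: str,
    em_tol: float = 1e-9,
    max_iter: int = 1000,
    min_shared: int = 10,
) -> LDResult:
    """Multi-allelic LD r-squared between two MH loci.

    Two-locus haplotype frequencies are estimated by EM from unphased
    diploid genotypes (double heterozygotes have two phase
    configurations); then
    ``r2 = sum_ij D_ij^2 / ((1 - sum p_i^2)(1 - sum q_j^2))`` with
    ``D_ij = h_ij - p_i q_j``.  Reduces to the classic biallelic r^2.
    Non-convergence is flagged, returning the last iterate.
    """
    ra = _callable_rows(genotypes, locus_a).set_index("sample")
    rb = _callable_rows(genotypes, locus_b).set_index("sample")
    shared = ra.index.intersection(rb.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"{locus_a} x {locus_b}: only {len(shared)} shared callable samples "
            f"(need >= {min_shared})"
        )

    def pairs(rows: pd.DataFrame) -> list[tuple[str, str]]:
        out = []
        for a1, a2 in zip(rows["allele1"], rows["allele2"]):
            out.append((a1, a2 if a2 else a1))
        return out

    pa = pairs(ra.loc[shared])
    pb = pairs(rb.loc[shared])
    haps, converged, n_iter, ll = _em_haplotype_freqs(pa, pb, em_tol, max_iter)

    p: dict[str, float] = {}
    q: dict[str, float] = {}
    for (a, b), f in haps.items():
        p[a] = p.get(a, 0.0) + f
        q[b] = q.get(b, 0.0) + f
    denom = (1.0 - sum(v**2 for v in p.values())) * (1.0 - sum(v**2 for v in q.values()))
    if denom <= 0:  # one or both loci monomorphic in the shared samples
        r2 = 0.0
    else:
        num = 0.0
        for a, pv in p.items():
            for b, qv in q.items():
                d = haps.get((a, b), 0.0) - pv * qv
                num += d * d
        r2 = min(num / denom, 1.0)
    if not converged:
        warnings.warn(f"{locus_a} x {locus_b}: EM did not converge in {max_iter} iterations")
    return LDResult(r2=r2, converged=converged, n_iter=n_iter, loglik=ll, hap_freqs=haps)
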