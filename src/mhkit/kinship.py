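"""Paternity likelihood ratios and simulated LR distributions.

For a duo (alleged father AF, child CH) or trio (with the mother), the
likelihood ratio compares H1 "AF is the biological father" against H2
"AF is unrelated to CH".  Per-locus LRs follow Mendelian transmission
with Hardy-Weinberg genotype priors and no mutation model (a genotype
incompatibility yields LR = 0); the combined LR is the product over loci.

The simulator reproduces the standard validation experiment: a cohort of
true father-child pairs (H1) and a cohort of unrelated pairs (H2), each
scored with the combined duo LR, summarized as log10(LR) distributions.
Exclusions (LR = 0) are kept as a -infinity point mass, not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from mhkit.forensic_stats import FrequencyTable

Genotype = tuple[str, str]


@dataclass
class KinshipCase:
    """One duo/trio case: genotypes plus the frequency table they live in."""

    child: dict[str, Genotype]
    alleged_father: dict[str, Genotype]
    freqs: FrequencyTable
    mother: Optional[dict[str, Genotype]] = None


def _freq(freqs: Mapping[str, float], allele: str) -> float:
    try:
        f = freqs[allele]
    except KeyError:
        raise ValueError(f"allele {allele!r} missing from frequency table") from None
    if f <= 0:
        raise ValueError(f"allele {allele!r} has non-positive frequency")
    return f


def _transmission(genotype: Genotype, allele: str) -> float:
    """P(parent with ``genotype`` transmits ``allele``), no mutation."""
    return (0.5 * (genotype[0] == allele)) + (0.5 * (genotype[1] == allele))


def _hwe_prob(genotype: Genotype, freqs: Mapping[str, float]) -> float:
    a, b = genotype
    pa, pb = _freq(freqs, a), _freq(freqs, b)
    return pa * pa if a == b else 2 * pa * pb


def duo_lr(child: Genotype, af: Genotype, freqs: Mapping[str, float]) -> float:
    """Single-locus motherless paternity LR.

    X = P(child | AF is father) summed over paternal transmissions with the
    maternal allele drawn from the population; Y = HWE probability of the
    child's genotype.  Classic closed forms fall out: AF=aa, CH=ab gives
    1/(2 p_a); AF=ab, CH=ab gives (p_a + p_b)/(4 p_a p_b).
    """
    a, b = child
    pa, pb = _freq(freqs, a), _freq(freqs, b)
    if a == b:
        x = _transmission(af, a) * pa
        y = pa * pa
    else:
        x = _transmission(af, a) * pb + _transmission(af, b) * pa
        y = 2 * pa * pb
    return x / y


def trio_lr(
    child: Genotype, af: Genotype, mother: Genotype, freqs: Mapping[str, float]
) -> float:
    """Single-locus trio paternity LR, conditioning on the mother.

    Numerator: P(child | mother, AF); denominator: P(child | mother,
    random man from the population).  Both sum over maternal transmission
    (1/2 each) and the paternal allele completing the child.
    """

    def p_child_given(mother_gt: Genotype, paternal_prob) -> float:
        total = 0.0
        for m_allele in mother_gt:
            for f_allele in set(child):
                gt = tuple(sorted((m_allele, f_allele)))
                if gt == tuple(sorted(child)):
                    total += 0.5 * paternal_prob(f_allele)
        return total

    num = p_child_given(mother, lambda f: _transmission(af, f))
    den = p_child_given(mother, lambda f: _freq(freqs, f))
    if den == 0:
        raise ValueError("child incompatible with mother (mutation not modelled)")
    return num / den


def paternity_lr(case: KinshipCase) -> tuple[dict[str, float], float]:
    """Per-locus and combined paternity LR for a duo or trio case.

    Returns ``(per_locus, combined)``; the combined LR is the product over
    loci (0 if any locus excludes).
    """
    per_locus: dict[str, float] = {}
    combined = 1.0
    for locus, child_gt in case.child.items():
        fr = case.freqs.freqs[locus]
        af_gt = case.alleged_father[locus]
        if case.mother is not None:
            lr = trio_lr(child_gt, af_gt, case.mother[locus], fr)
        else:
            lr = duo_lr(child_gt, af_gt, fr)
        per_locus[locus] = lr
        combined *= lr
    return per_locus, combined


@dataclass
class LRDistribution:
    """Combined log10(LR) cohorts for true pairs (H1) and unrelated (H2).

    Exclusions (combined LR = 0) appear as -inf entries; ``finite`` views
    drop them for plotting/summaries.
    """

    log10_h1: np.ndarray
    log10_h2: np.ndarray
    n: int
    seed: int

    @property
    def h2_exclusion_fraction(self) -> float:
        return float(np.mean(np.isinf(self.log10_h2)))

    def overlap(self) -> bool:
        """True if the H1 support overlaps the finite H2 support."""
        finite_h2 = self.log10_h2[np.isfinite(self.log10_h2)]
        if finite_h2.size == 0:
            return False
        return float(self.log10_h1.min()) <= float(finite_h2.max())


def _sample_genotype_indices(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n HWE genotypes as (n, 2) allele indices."""
    k = len(p)
    return rng.choice(k, size=(n, 2), p=p)


def simulate_lr_distributions(
    freqs: FrequencyTable,
    n: int = 10000,
    seed: int = 0,
    loci: Optional[Sequence[str]] = None,
) -> LRDistribution:
    """Simulate combined duo log10(LR) for true and unrelated father-child pairs.

    H1: father drawn from HWE; the child receives one paternal allele
    (1/2 each) and one population allele.  H2: the alleged father is an
    independent HWE genotype while the child remains a true child of an
    unknown father (so the child distribution is HWE in both cohorts).
    Vectorized per locus; reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    use_loci = list(loci) if loci is not None else freqs.loci()
    log_h1 = np.zeros(n)
    log_h2 = np.zeros(n)
    excl_h2 = np.zeros(n, dtype=bool)
    for locus in use_loci:
        alleles = list(freqs.freqs[locus])
        p = np.array([freqs.freqs[locus][a] for a in alleles])
        p = p / p.sum()
        k = len(p)

        father = _sample_genotype_indices(p, n, rng)
        paternal = father[np.arange(n), rng.integers(0, 2, size=n)]
        maternal = rng.choice(k, size=n, p=p)
        child = np.stack([paternal, maternal], axis=1)
        af_unrelated = _sample_genotype_indices(p, n, rng)

        def locus_lr(child_idx: np.ndarray, af_idx: np.ndarray) -> np.ndarray:
            ca, cb = child_idx[:, 0], child_idx[:, 1]
            pa, pb = p[ca], p[cb]
            trans_a = 0.5 * (af_idx[:, 0] == ca) + 0.5 * (af_idx[:, 1] == ca)
            trans_b = 0.5 * (af_idx[:, 0] == cb) + 0.5 * (af_idx[:, 1] == cb)
            hom = ca == cb
            x = np.where(hom, trans_a * pa, trans_a * pb + trans_b * pa)
            y = np.where(hom, pa * pa, 2 * pa * pb)
            return x / y

        lr1 = locus_lr(child, father)
        lr2 = locus_lr(child, af_unrelated)
        with np.errstate(divide="ignore"):
            log_h1 += np.log10(lr1)  # true fathers never exclude without mutation
            excl_h2 |= lr2 == 0
            log_h2 += np.where(lr2 > 0, np.log10(np.where(lr2 > 0, lr2, 1.0)), 0.0)
    log_h2[excl_h2] = -np.inf
    return LRDistribution(log10_h1=log_h1, log10_h2=log_h2, n=n, seed=seed)
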