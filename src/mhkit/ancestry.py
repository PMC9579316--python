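"""Ancestry informativeness and population-structure summaries.

Three statistics from multi-population allele-frequency data:

* Rosenberg's informativeness for assignment, In, per locus — the
  expected mutual information (natural log) between an allele copy and
  its population of origin; the conventional screen for ancestry-
  informative markers flags loci with In > 0.185.
* Pairwise Fst between populations as Nei's Gst averaged over loci.
* A neighbor-joining tree over the Fst matrix, emitted as Newick.

A converter is included to build MH genotypes from phased SNP genotype
tables by concatenating phased alleles per haplotype.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from mhkit.forensic_stats import FrequencyTable

IN_AIM_THRESHOLD = 0.185  # conventional screen for ancestry-informative loci


@dataclass
class MultiPopFrequencies:
    """Per-locus K x (alleles) frequency matrices across populations.

    ``freqs[locus]`` is a DataFrame with populations as rows and allele
    labels as columns; rows sum to 1 (alleles absent from a population
    have frequency 0).
    """

    populations: list[str]
    freqs: dict[str, pd.DataFrame] = field(default_factory=dict)
    sample_sizes: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_tables(cls, tables: Sequence[FrequencyTable]) -> "MultiPopFrequencies":
        pops = [t.population for t in tables]
        if len(set(pops)) != len(pops):
            raise ValueError("duplicate population labels")
        mpf = cls(populations=pops, sample_sizes={})
        loci = sorted(set().union(*(set(t.freqs) for t in tables)))
        for locus in loci:
            alleles = sorted(set().union(*(set(t.freqs.get(locus, {})) for t in tables)))
            mat = pd.DataFrame(0.0, index=pops, columns=alleles)
            for t in tables:
                for a, f in t.freqs.get(locus, {}).items():
                    mat.loc[t.population, a] = f
            mpf.freqs[locus] = mat
        for t in tables:
            mpf.sample_sizes[t.population] = max(t.n.values(), default=0)
        return mpf

    def loci(self) -> list[str]:
        return list(self.freqs)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def informativeness(mpf: MultiPopFrequencies, locus: str) -> float:
    """Rosenberg's In for one locus across K populations.

    In = sum_j [ -pbar_j ln pbar_j + (1/K) sum_i p_ij ln p_ij ] with
    pbar_j the unweighted mean allele frequency across populations and
    0 ln 0 = 0.  Zero iff all populations share identical frequency
    vectors; ln K when K populations are each fixed for distinct alleles.
    """
    mat = mpf.freqs[locus].to_numpy(dtype=float)
    k = mat.shape[0]
    if k < 2:
        raise ValueError("informativeness needs K >= 2 populations")
    pbar = mat.mean(axis=0)

    def xlogx(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log(x[nz])
        return out

    val = float(np.sum(-xlogx(pbar) + xlogx(mat).sum(axis=0) / k))
    return max(val, 0.0)  # clip tiny negative rounding residue


def informativeness_table(mpf: MultiPopFrequencies, threshold: float = IN_AIM_THRESHOLD) -> pd.DataFrame:
    """In per locus with the ancestry-informative flag (In > threshold)."""
    rows = [
        {"locus": loc, "In": informativeness(mpf, loc)}
        for loc in mpf.loci()
    ]
    df = pd.DataFrame(rows)
    df["ancestry_informative"] = df["In"] > threshold
    return df


def _gst_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Nei's Gst for one locus between two populations; negatives -> 0."""
    hs = 0.5 * ((1 - np.sum(a**2)) + (1 - np.sum(b**2)))
    pbar = 0.5 * (a + b)
    ht = 1 - np.sum(pbar**2)
    if ht <= 0:
        return np.nan  # monomorphic in the pooled pair: uninformative
    return max((ht - hs) / ht, 0.0)


def pairwise_fst(mpf: MultiPopFrequencies) -> DistanceMatrix:
    """Pairwise Fst (Nei's Gst averaged over loci) between populations.

    Per pair and locus Gst = (Ht - Hs)/Ht with Hs the mean within-pair
    expected heterozygosity and Ht that of the mean frequencies; per-locus
    negatives are truncated at 0, loci monomorphic in the pooled pair are
    skipped.  An everywhere-monomorphic locus set yields a zero matrix
    with a warning.
    """
    import warnings

    pops = mpf.populations
    k = len(pops)
    if k < 2:
        raise ValueError("need K >= 2 populations")
    out = np.zeros((k, k))
    any_poly = False
    for i in range(k):
        for j in range(i + 1, k):
            vals = []
            for locus in mpf.loci():
                mat = mpf.freqs[locus].to_numpy(dtype=float)
                g = _gst_pair(mat[i], mat[j])
                if not np.isnan(g):
                    vals.append(g)
            if vals:
                any_poly = True
                out[i, j] = out[j, i] = float(np.mean(vals))
    if not any_poly:
        warnings.warn("all loci monomorphic: zero Fst matrix")
    return DistanceMatrix(tuple(pops), out)


def nj_tree(dist: DistanceMatrix) -> str:
    """Neighbor-joining (Saitou-Nei) tree over a distance matrix, as Newick.

    Unrooted; negative branch lengths are clamped at zero.  Requires at
    least three taxa.
    """
    if len(dist.labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dm = _SkbioDM(dist.values, ids=list(dist.labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def phased_snps_to_mh(
    phased: pd.DataFrame, snp_columns_per_locus: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Build MH genotypes from phased SNP genotypes by per-haplotype concatenation.

    ``phased`` is long-per-sample with one column per SNP holding phased
    genotypes like ``A|G`` plus a ``sample`` column; for each MH locus the
    listed SNP columns are concatenated left-allele-with-left-allele to
    form the two haplotype alleles.  Returns a genotype table in the
    caller's long format (qc = PASS).
    """
    rows = []
    for _, rec in phased.iterrows():
        for locus, cols in snp_columns_per_locus.items():
            hap1 = []
            hap2 = []
            for c in cols:
                a, b = str(rec[c]).split("|")
                hap1.append(a)
                hap2.append(b)
            a1, a2 = "".join(hap1), "".join(hap2)
            if a2 < a1:
                a1, a2 = a2, a1
            rows.append(
                {
                    "sample": rec["sample"],
                    "locus": locus,
                    "allele1": a1,
                    "allele2": a2 if a2 != a1 else "",
                    "doc": 0,
                    "balance": "",
                    "qc": "PASS",
                }
            )
    return pd.DataFrame(
        rows, columns=["sample", "locus", "allele1", "allele2", "doc", "balance", "qc"]
    )
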