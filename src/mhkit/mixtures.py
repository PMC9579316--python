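"""Planning, simulation and scoring of multi-person DNA mixtures.

A mixture is specified by 2-5 single-source contributor profiles and a
ratio vector (e.g. 19:1).  Under a mass-proportional model each allele's
expected read fraction at a locus is the weight-average of contributor
dosages; read counts are simulated multinomially with a per-SNP error
channel.  Scoring partitions the union of contributor alleles into the
major contributor's alleles and minor-unique alleles (carried by at least
one minor contributor and absent from the major) and reports detection
counts and percentage rates per partition — the standard deconvolution
report schema for unbalanced-mixture studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mhkit.hapcall import HaplotypeCounts
from mhkit.panel_io import Panel, PanelLocus

REPORT_COLUMNS = [
    "n_contributors",
    "ratio",
    "max_alleles",
    "detected_alleles",
    "detection_rate",
    "major_alleles",
    "major_detected",
    "major_rate",
    "minor_alleles",
    "minor_detected",
    "minor_rate",
]


def round_rate(detected: int, expected: int) -> float:
    """Percentage rate 100*detected/expected, rounded half-up to 2 decimals."""
    if expected == 0:
        return 0.0
    pct = Decimal(100 * detected) / Decimal(expected)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MixtureSpec:
    """Contributors with genotype profiles and positive mixing weights.

    ``profiles[label][locus]`` is the contributor's allele pair (tuple of
    two haplotype strings, equal when homozygous).  The major contributor
    is the one with the largest weight.
    """

    labels: list[str]
    weights: list[float]
    profiles: dict[str, dict[str, tuple[str, str]]]
    dna_mass: str = "1 ng"

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a mixture needs >= 2 contributors")
        if len(self.weights) != len(self.labels):
            raise ValueError("one weight per contributor")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        locus_sets = {frozenset(self.profiles[l]) for l in self.labels}
        if len(locus_sets) != 1:
            raise ValueError("contributor profiles must cover the same locus set")

    @property
    def ratio_label(self) -> str:
        def fmt(w: float) -> str:
            return str(int(w)) if float(w).is_integer() else str(w)

        return ":".join(fmt(w) for w in self.weights)

    @property
    def major(self) -> str:
        return self.labels[int(np.argmax(self.weights))]

    @property
    def minors(self) -> list[str]:
        return [l for l in self.labels if l != self.major]

    def loci(self) -> list[str]:
        return sorted(self.profiles[self.labels[0]])

    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels,
            "weights": self.weights,
            "dna_mass": self.dna_mass,
            "profiles": {
                lab: {loc: list(gt) for loc, gt in prof.items()}
                for lab, prof in self.profiles.items()
            },
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MixtureSpec":
        with open(path, "rt", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            labels=d["labels"],
            weights=d["weights"],
            dna_mass=d.get("dna_mass", "1 ng"),
            profiles={
                lab: {loc: (gt[0], gt[1]) for loc, gt in prof.items()}
                for lab, prof in d["profiles"].items()
            },
        )


def expected_allele_fractions(spec: MixtureSpec, locus: str) -> dict[str, float]:
    """Expected read fraction per allele under the mass-proportional model.

    fraction(a) = sum_c w_c * dosage_c(a) / 2 with dosage in {0, 1, 2};
    fractions sum to 1 per locus.
    """
    w = spec.normalized_weights()
    out: dict[str, float] = {}
    for weight, label in zip(w, spec.labels):
        a1, a2 = spec.profiles[label][locus]
        out[a1] = out.get(a1, 0.0) + weight * 0.5
        out[a2] = out.get(a2, 0.0) + weight * 0.5
    return out


def _mutate_haplotypes(
    haps: np.ndarray, error_rate: float, alphabet: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Per-read per-SNP substitution channel over haplotype strings."""
    if error_rate <= 0 or haps.size == 0:
        return haps
    L = len(haps[0])
    arr = haps.view("U1").reshape(len(haps), L).copy()
    hit = rng.random(arr.shape) < error_rate
    if hit.any():
        alpha = np.array(list(alphabet))
        idx = np.argwhere(hit)
        for i, j in idx:
            choices = alpha[alpha != arr[i, j]]
            arr[i, j] = rng.choice(choices)
    return arr.view(f"U{L}").ravel()


def simulate_mixture_counts(
    spec: MixtureSpec,
    locus_depths: Mapping[str, int],
    error_rate: float = 0.0,
    seed: int = 0,
    alphabet: Sequence[str] = "ACGT",
) -> dict[str, HaplotypeCounts]:
    """Multinomial read-count simulation of a mixture at each locus.

    Draws each locus's total depth over the expected allele fractions,
    then pushes every read through an independent per-SNP substitution
    error channel at ``error_rate``.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, HaplotypeCounts] = {}
    for locus in spec.loci():
        depth = int(locus_depths.get(locus, 0))
        hc = HaplotypeCounts(locus=locus)
        if depth > 0:
            fracs = expected_allele_fractions(spec, locus)
            alleles = list(fracs)
            draws = rng.multinomial(depth, [fracs[a] for a in alleles])
            reads = np.repeat(np.array(alleles), draws)
            reads = _mutate_haplotypes(reads, error_rate, alphabet, rng)
            uniq, cnt = np.unique(reads, return_counts=True)
            hc.counts = {str(a): int(c) for a, c in zip(uniq, cnt)}
        out[locus] = hc
    return out


def _allele_partition(spec: MixtureSpec, locus: str) -> tuple[set[str], set[str]]:
    """(major alleles, minor-unique alleles) at a locus.

    Minor-unique alleles are carried by >= 1 minor contributor and absent
    from the major; alleles shared with the major count toward the major
    only, so the two sets partition the union of contributor alleles.
    """
    major = set(spec.profiles[spec.major][locus])
    minor = set()
    for m in spec.minors:
        minor.update(spec.profiles[m][locus])
    return major, minor - major


@dataclass
class DetectionReport:
    """One deconvolution report row (per mixture, summed over loci)."""

    n_contributors: int
    ratio: str
    max_alleles: int
    detected_alleles: int
    major_alleles: int
    major_detected: int
    minor_alleles: int
    minor_detected: int

    def __post_init__(self) -> None:
        if self.major_alleles + self.minor_alleles != self.max_alleles:
            raise ValueError("major + minor-unique alleles must equal the maximum allele number")
        if self.detected_alleles > self.max_alleles:
            raise ValueError("detected cannot exceed expected")

    @property
    def detection_rate(self) -> float:
        return round_rate(self.detected_alleles, self.max_alleles)

    @property
    def major_rate(self) -> float:
        return round_rate(self.major_detected, self.major_alleles)

    @property
    def minor_rate(self) -> float:
        return round_rate(self.minor_detected, self.minor_alleles)

    def to_row(self) -> dict:
        return {
            "n_contributors": self.n_contributors,
            "ratio": self.ratio,
            "max_alleles": self.max_alleles,
            "detected_alleles": self.detected_alleles,
            "detection_rate": self.detection_rate,
            "major_alleles": self.major_alleles,
            "major_detected": self.major_detected,
            "major_rate": self.major_rate,
            "minor_alleles": self.minor_alleles,
            "minor_detected": self.minor_detected,
            "minor_rate": self.minor_rate,
        }


def score_deconvolution(
    detected: Mapping[str, set[str] | Sequence[str]], spec: MixtureSpec
) -> DetectionReport:
    """Score detected allele sets per locus against the known truth profiles.

    ``detected`` maps locus -> alleles called in the mixture.  Counts the
    union of contributor alleles per locus, partitioned into major and
    minor-unique, and how many of each were detected.  A detected locus
    absent from the spec is an error.
    """
    unknown = set(detected) - set(spec.loci())
    if unknown:
        raise ValueError(f"detected loci absent from mixture spec: {sorted(unknown)}")
    max_n = det_n = maj_n = maj_det = min_n = min_det = 0
    for locus in spec.loci():
        major, minor_unique = _allele_partition(spec, locus)
        expected = major | minor_unique
        got = set(detected.get(locus, ())) & expected
        max_n += len(expected)
        det_n += len(got)
        maj_n += len(major)
        maj_det += len(got & major)
        min_n += len(minor_unique)
        min_det += len(got & minor_unique)
    return DetectionReport(
        n_contributors=len(spec.labels),
        ratio=spec.ratio_label,
        max_alleles=max_n,
        detected_alleles=det_n,
        major_alleles=maj_n,
        major_detected=maj_det,
        minor_alleles=min_n,
        minor_detected=min_det,
    )


def report_table(reports: Sequence[DetectionReport]) -> pd.DataFrame:
    """Stack report rows into the standard deconvolution table layout."""
    return pd.DataFrame([r.to_row() for r in reports], columns=REPORT_COLUMNS)


def locus_diagram_data(
    counts: HaplotypeCounts,
    spec: MixtureSpec,
    locus: str,
    min_doc: int = 30,
) -> pd.DataFrame:
    """Per-allele DoC with contributor attribution for bar-diagram rendering.

    One row per observed or expected allele: depth of coverage, the
    contributors carrying it (all donors listed for shared alleles), and
    whether it clears the ``min_doc`` detection threshold.
    """
    donors: dict[str, list[str]] = {}
    for label in spec.labels:
        for a in spec.profiles[label][locus]:
            donors.setdefault(a, [])
            if label not in donors[a]:
                donors[a].append(label)
    alleles = sorted(set(donors) | set(counts.counts), key=lambda a: (-counts.counts.get(a, 0), a))
    rows = [
        {
            "locus": locus,
            "allele": a,
            "doc": counts.counts.get(a, 0),
            "contributors": ",".join(donors.get(a, [])),
            "above_threshold": counts.counts.get(a, 0) >= min_doc,
        }
        for a in alleles
    ]
    return pd.DataFrame(rows, columns=["locus", "allele", "doc", "contributors", "above_threshold"])
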