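"""MH genotype calling from aligned amplicon reads.

The caller phases the constituent SNP bases of each MH locus within a
sequenced fragment (a read pair sharing a name): a fragment contributes one
haplotype string — one base per SNP position, in order — only if it covers
every SNP of the locus with base quality at or above the threshold.
Haplotype counts are then reduced to a genotype call with the standard
massively-parallel-sequencing analytical thresholds: locus depth of
coverage >= 30x and heterozygote allele balance (minor/major depth) above
0.15, plus a per-locus noise fraction below which haplotypes are treated
as sequencing artifacts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from mhkit.panel_io import PanelLocus

DELETION_CODE = "-"

GENOTYPE_COLUMNS = ["sample", "locus", "allele1", "allele2", "doc", "balance", "qc"]


class QCFlag(str, enum.Enum):
    PASS = "PASS"
    LOW_DOC = "LOW_DOC"
    IMBALANCED = "IMBALANCED"
    EXCESS_ALLELES = "EXCESS_ALLELES"
    NO_CALL = "NO_CALL"

    def __str__(self) -> str:  # serialize as the bare label
        return self.value


@dataclass(frozen=True)
class CallerThresholds:
    """Analytical thresholds applied by the genotype caller.

    min_doc: minimum locus / per-allele depth of coverage (reads).
    min_balance: minimum heterozygote allele balance (minor/major depth).
    noise_fraction: haplotypes below this fraction of locus depth are noise.
    min_base_quality: minimum Phred base quality at a SNP position.
    """

    min_doc: int = 30
    min_balance: float = 0.15
    noise_fraction: float = 0.02
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_doc < 0 or self.min_base_quality < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_balance < 1:
            raise ValueError("min_balance must be in [0, 1)")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")


@dataclass
class HaplotypeCounts:
    """Observed haplotype strings and read counts at one locus in one sample."""

    locus: str
    counts: dict[str, int] = field(default_factory=dict)
    discarded: int = 0

    @property
    def total_depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MHCall:
    """A sample x locus MH genotype call.

    ``alleles`` holds one (homozygous) or two (heterozygous) haplotype
    strings sorted by descending depth; ``doc`` is the total locus depth
    before noise filtering; ``balance`` is minor/major depth for
    two-allele situations (also recorded on IMBALANCED calls where the
    minor allele was demoted).
    """

    locus: str
    alleles: tuple[str, ...]
    depths: tuple[int, ...]
    doc: int
    balance: Optional[float]
    qc_flag: QCFlag

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2


@dataclass(frozen=True)
class MixtureAlleles:
    """All alleles detected at a locus in mixture mode (no diploid cap)."""

    locus: str
    detected: dict[str, int]
    sub_threshold: dict[str, int]
    noise: dict[str, int]


def _fragment_bases(
    reads: Iterable[pysam.AlignedSegment], snp_positions: tuple[int, ...]
) -> dict[int, tuple[str, int]]:
    """Best (base, quality) per SNP position across the mates of a fragment.

    On mate disagreement the higher-quality base wins.  Soft-clipped or
    deleted-through positions: a deletion over a SNP maps to the deletion
    code; soft clips do not cover the position.
    """
    wanted = set(snp_positions)
    best: dict[int, tuple[str, int]] = {}
    for read in reads:
        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None:
            continue
        for qpos, rpos in read.get_aligned_pairs():
            if rpos not in wanted:
                continue
            if qpos is None:  # deletion in the read over the SNP
                base, qual = DELETION_CODE, 93
            else:
                base = seq[qpos]
                qual = quals[qpos] if quals is not None else 93
            prev = best.get(rpos)
            if prev is None or qual > prev[1]:
                best[rpos] = (base, qual)
    return best


def extract_haplotype_counts(
    alignments,
    locus: PanelLocus,
    thresholds: CallerThresholds = CallerThresholds(),
) -> HaplotypeCounts:
    """Count phased haplotype strings at ``locus`` from aligned reads.

    ``alignments`` is a pysam.AlignmentFile (SAM or indexed BAM) or a path
    to one.  Each fragment (reads sharing a query name) contributes at most
    one haplotype; fragments that do not cover all SNP positions, or whose
    best base at any SNP is below ``min_base_quality``, are tallied in
    ``discarded``.  Raises ``KeyError`` if the locus contig is absent from
    the alignment header.
    """
    own = False
    reopened = None
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        if locus.chrom not in alignments.references:
            raise KeyError(f"contig {locus.chrom!r} absent from alignment header")
        if alignments.has_index():
            it = alignments.fetch(locus.chrom, locus.amplicon_start, locus.amplicon_end)
        else:  # plain SAM: filter a fresh full pass
            reopened = pysam.AlignmentFile(alignments.filename)
            it = (
                r
                for r in reopened
                if r.reference_name == locus.chrom
                and r.reference_start is not None
                and r.reference_start < locus.amplicon_end
                and (r.reference_end or 0) > locus.amplicon_start
            )
        fragments: dict[str, list[pysam.AlignedSegment]] = {}
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            fragments.setdefault(read.query_name, []).append(read)
    finally:
        if reopened is not None:
            reopened.close()
        if own:
            alignments.close()

    counts = HaplotypeCounts(locus=locus.name)
    minq = thresholds.min_base_quality
    for reads in fragments.values():
        best = _fragment_bases(reads, locus.snp_positions)
        if len(best) < len(locus.snp_positions) or any(
            best[p][1] < minq for p in locus.snp_positions
        ):
            counts.discarded += 1
            continue
        hap = "".join(best[p][0] for p in locus.snp_positions)
        counts.counts[hap] = counts.counts.get(hap, 0) + 1
    return counts


def extract_all_haplotype_counts(
    alignments,
    panel,
    thresholds: CallerThresholds = CallerThresholds(),
) -> dict[str, HaplotypeCounts]:
    """Single-pass haplotype extraction for every panel locus.

    Equivalent to calling :func:`extract_haplotype_counts` per locus but
    reads the alignment file once, binning each fragment to the amplicon
    it overlaps (panel amplicons are assumed disjoint).  Preferred for
    plain (unindexed) SAM input.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    by_chrom: dict[str, list[PanelLocus]] = {}
    for locus in panel:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for loci in by_chrom.values():
        loci.sort(key=lambda l: l.amplicon_start)
    try:
        missing = [c for c in by_chrom if c not in alignments.references]
        if missing:
            raise KeyError(f"contigs absent from alignment header: {missing}")
        fragments: dict[str, dict[str, list[pysam.AlignedSegment]]] = {
            l.name: {} for l in panel
        }
        import bisect

        starts = {c: [l.amplicon_start for l in loci] for c, loci in by_chrom.items()}
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            loci = by_chrom.get(chrom)
            if not loci:
                continue
            i = bisect.bisect_right(starts[chrom], read.reference_start)
            for locus in loci[max(i - 1, 0) : i + 1]:
                if (
                    read.reference_start < locus.amplicon_end
                    and (read.reference_end or 0) > locus.amplicon_start
                ):
                    fragments[locus.name].setdefault(read.query_name, []).append(read)
                    break
    finally:
        if own:
            alignments.close()

    out: dict[str, HaplotypeCounts] = {}
    minq = thresholds.min_base_quality
    for locus in panel:
        counts = HaplotypeCounts(locus=locus.name)
        for reads in fragments[locus.name].values():
            best = _fragment_bases(reads, locus.snp_positions)
            if len(best) < len(locus.snp_positions) or any(
                best[p][1] < minq for p in locus.snp_positions
            ):
                counts.discarded += 1
                continue
            hap = "".join(best[p][0] for p in locus.snp_positions)
            counts.counts[hap] = counts.counts.get(hap, 0) + 1
        out[locus.name] = counts
    return out


def call_sample(
    alignments,
    panel,
    thresholds: CallerThresholds = CallerThresholds(),
) -> dict[str, MHCall]:
    """Call the full panel for one single-source sample in one pass."""
    counts = extract_all_haplotype_counts(alignments, panel, thresholds)
    return {locus: call_genotype(c, thresholds) for locus, c in counts.items()}


def _split_noise(
    counts: HaplotypeCounts, noise_fraction: float
) -> tuple[list[tuple[str, int]], dict[str, int]]:
    total = counts.total_depth
    cutoff = noise_fraction * total
    kept = [(h, c) for h, c in counts.counts.items() if c >= cutoff]
    noise = {h: c for h, c in counts.counts.items() if c < cutoff}
    # deterministic: depth-descending, haplotype string as tie-break
    kept.sort(key=lambda hc: (-hc[1], hc[0]))
    return kept, noise


def call_genotype(
    counts: HaplotypeCounts, thresholds: CallerThresholds = CallerThresholds()
) -> MHCall:
    """Reduce single-source haplotype counts to a diploid MH genotype call.

    Haplotypes below ``noise_fraction`` of locus depth are dropped; calls
    with passing depth below ``min_doc`` are no-calls (LOW_DOC); two-allele
    calls with balance below ``min_balance`` demote the minor allele and
    are flagged IMBALANCED; more than two above-noise haplotypes flag
    EXCESS_ALLELES (possible mixture).  Never raises on empty counts.
    """
    doc = counts.total_depth
    if doc == 0:
        return MHCall(counts.locus, (), (), 0, None, QCFlag.NO_CALL)
    kept, _ = _split_noise(counts, thresholds.noise_fraction)
    passing_depth = sum(c for _, c in kept)
    if passing_depth < thresholds.min_doc:
        return MHCall(counts.locus, (), (), doc, None, QCFlag.LOW_DOC)
    if len(kept) > 2:
        top = kept[:2]
        balance = top[1][1] / top[0][1]
        return MHCall(
            counts.locus,
            tuple(h for h, _ in top),
            tuple(c for _, c in top),
            doc,
            balance,
            QCFlag.EXCESS_ALLELES,
        )
    if len(kept) == 2:
        (major, cmaj), (minor, cmin) = kept
        balance = cmin / cmaj
        if balance < thresholds.min_balance:
            return MHCall(counts.locus, (major,), (cmaj,), doc, balance, QCFlag.IMBALANCED)
        return MHCall(counts.locus, (major, minor), (cmaj, cmin), doc, balance, QCFlag.PASS)
    (hap, c) = kept[0]
    return MHCall(counts.locus, (hap,), (c,), doc, None, QCFlag.PASS)


def call_mixture_alleles(
    counts: HaplotypeCounts, thresholds: CallerThresholds = CallerThresholds()
) -> MixtureAlleles:
    """Report every allele at a (possibly) mixed locus, with per-allele DoC.

    All haplotypes above the noise fraction with per-allele depth >=
    ``min_doc`` are detected (no diploid cap); above-noise haplotypes below
    ``min_doc`` are reported separately as sub-threshold.
    """
    kept, noise = _split_noise(counts, thresholds.noise_fraction)
    detected = {h: c for h, c in kept if c >= thresholds.min_doc}
    sub = {h: c for h, c in kept if c < thresholds.min_doc}
    return MixtureAlleles(counts.locus, detected, sub, noise)


def genotype_table(calls: Iterable[tuple[str, MHCall]]) -> pd.DataFrame:
    """Long-format genotype table from (sample, call) pairs.

    One row per sample x locus (duplicates are an error); NO_CALL rows get
    empty allele fields.  Serializes losslessly through
    :func:`write_genotype_table` / :func:`read_genotype_table`.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for sample, call in calls:
        key = (sample, call.locus)
        if key in seen:
            raise ValueError(f"duplicate genotype row for sample={sample!r} locus={call.locus!r}")
        seen.add(key)
        a1 = call.alleles[0] if len(call.alleles) >= 1 else ""
        a2 = call.alleles[1] if len(call.alleles) >= 2 else ""
        rows.append(
            {
                "sample": sample,
                "locus": call.locus,
                "allele1": a1,
                "allele2": a2,
                "doc": call.doc,
                "balance": "" if call.balance is None else f"{call.balance:.4f}",
                "qc": str(call.qc_flag),
            }
        )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    df["doc"] = df["doc"].astype(int)
    return df[GENOTYPE_COLUMNS]
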