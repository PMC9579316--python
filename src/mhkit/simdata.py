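"""Synthetic inputs for every other module: panels, frequencies, genotypes, reads.

The generator emulates a targeted MH amplicon experiment: loci of 2-6
SNPs inside amplicons of at most 300 bp, population allele (haplotype)
frequencies drawn from a Dirichlet prior, Hardy-Weinberg genotypes,
K populations diverged from a common base by a Balding-Nichols style
drift parameter, and 2 x 150 bp paired reads at configurable depth with
a per-base substitution error channel.  Reads are emitted pre-aligned
(sorted SAM with truth positions and simple CIGARs) so the toolkit never
depends on an external aligner; a paired FASTQ mirror is available for
external-aligner workflows.  Every stochastic operation takes or derives
a seed and is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from mhkit.forensic_stats import FrequencyTable
from mhkit.hapcall import GENOTYPE_COLUMNS, HaplotypeCounts
from mhkit.panel_io import Panel, PanelLocus

BASES = "ACGT"


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic generator.

    Defaults emulate a 163-locus panel typed in 92 diploid individuals
    with 2 x 150 bp paired reads at a mean locus depth of ~2,300x.
    """

    n_loci: int = 163
    snps_min: int = 2
    snps_max: int = 6
    amplicon_len: int = 280
    dirichlet_concentration: float = 1.6
    n_populations: int = 1
    divergence: float = 0.0
    n_samples: int = 92
    read_len: int = 150
    error_rate: float = 0.0
    depth_mean: float = 2301.0
    depth_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.snps_min <= self.snps_max <= 6:
            raise ValueError("snps per locus must lie in 2..6")
        if self.amplicon_len > 300:
            raise ValueError("amplicon length must be <= 300 bp")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")


# ---------------------------------------------------------------------------
# panel


def generate_panel(cfg: SimConfig, lab_code: str = "SY") -> Panel:
    """A valid synthetic panel: loci spread over chromosomes 1-22.

    Locus i sits at a fixed 1 kb stride on its chromosome so amplicons
    never overlap; SNP positions are drawn uniformly inside the amplicon.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.snps_max > cfg.amplicon_len:
        raise ValueError("more SNPs than amplicon positions")
    loci = []
    serial: dict[int, int] = {}
    for i in range(cfg.n_loci):
        chrom_num = (i % 22) + 1
        serial[chrom_num] = serial.get(chrom_num, 0) + 1
        stride = i // 22
        start = 1000 + stride * 1000
        end = start + cfg.amplicon_len
        s = int(rng.integers(cfg.snps_min, cfg.snps_max + 1))
        pos = np.sort(rng.choice(np.arange(start, end), size=s, replace=False))
        alleles = []
        for _ in range(s):
            pair = rng.choice(list(BASES), size=2, replace=False)
            alleles.append(frozenset(pair.tolist()))
        loci.append(
            PanelLocus(
                name=f"MH{chrom_num:02d}{lab_code}{serial[chrom_num]:03d}",
                chrom=str(chrom_num),
                amplicon_start=start,
                amplicon_end=end,
                snp_positions=tuple(int(p) for p in pos),
                alleles_per_snp=tuple(alleles),
            )
        )
    return Panel(reference_build="synthetic", loci=tuple(loci)).sorted()


def locus_haplotype_space(locus: PanelLocus) -> list[str]:
    """All haplotype strings the locus's permitted per-SNP symbols allow."""
    sets = [sorted(s) for s in locus.alleles_per_snp]
    return ["".join(combo) for combo in itertools.product(*sets)]


# ---------------------------------------------------------------------------
# frequencies


def _draw_locus_freqs(
    space: list[str],
    rng: np.random.Generator,
    concentration: float,
    min_freq: float = 0.01,
    ae_range: Optional[tuple[float, float]] = None,
    max_tries: int = 1000,
) -> dict[str, float]:
    # total concentration split across the haplotype space keeps the
    # effective allele count roughly independent of 2^s (Ae ~ 1 + c)
    alpha = concentration / len(space)
    for _ in range(max_tries):
        p = rng.dirichlet(np.full(len(space), alpha))
        keep = p >= min_freq
        if keep.sum() < 2:
            keep = np.zeros_like(keep)
            keep[np.argsort(p)[-2:]] = True
        q = p[keep] / p[keep].sum()
        if ae_range is not None:
            a = 1.0 / np.sum(q**2)
            if not ae_range[0] <= a <= ae_range[1]:
                continue
        labels = [h for h, k in zip(space, keep) if k]
        return dict(zip(labels, q.tolist()))
    raise RuntimeError("could not draw frequencies in the requested Ae range")


def generate_frequency_table(
    panel: Panel,
    cfg: SimConfig,
    population: str = "POP",
    ae_range: Optional[tuple[float, float]] = None,
    seed: Optional[int] = None,
) -> FrequencyTable:
    """Base-population haplotype frequencies per locus.

    Dirichlet(alpha) over the locus's haplotype space, truncated at 1%
    and renormalized (so the observed allele count resembles the 2-7
    effective alleles typical of real MH panels).  ``ae_range`` rejection-
    samples each locus until its Ae lands in the range (e.g. (3, 7) for a
    high-polymorphism identification panel).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ft = FrequencyTable(population=population)
    for locus in panel:
        space = locus_haplotype_space(locus)
        ft.freqs[locus.name] = _draw_locus_freqs(
            space, rng, cfg.dirichlet_concentration, ae_range=ae_range
        )
        ft.n[locus.name] = cfg.n_samples
    return ft


def generate_population_freqs(panel: Panel, cfg: SimConfig) -> list[FrequencyTable]:
    """K populations diverged from a common base.

    Each population's per-locus frequencies are drawn
    Dirichlet(base * (1 - F)/F) around the base vector (Balding-Nichols),
    so the drift parameter F (``cfg.divergence``) sets the expected Fst;
    F = 0 returns identical copies of the base.
    """
    rng = np.random.default_rng(cfg.seed)
    base = generate_frequency_table(panel, cfg, population="BASE", seed=cfg.seed + 1)
    tables = []
    f = cfg.divergence
    for k in range(cfg.n_populations):
        ft = FrequencyTable(population=f"POP{k + 1}")
        for locus, fr in base.freqs.items():
            labels = list(fr)
            p = np.array([fr[a] for a in labels])
            if f <= 0:
                q = p
            else:
                q = rng.dirichlet(p * (1 - f) / f)
                q = np.maximum(q, 1e-6)
                q = q / q.sum()
            ft.freqs[locus] = dict(zip(labels, q.tolist()))
            ft.n[locus] = cfg.n_samples
        tables.append(ft)
    return tables


# ---------------------------------------------------------------------------
# genotypes


def sample_genotypes(
    freqs: FrequencyTable, n: int, seed: int = 0, doc: int = 1000
) -> pd.DataFrame:
    """HWE random-mating genotypes as a long-format genotype table.

    Samples two independent allele copies per individual and locus.
    Returns the caller's table schema with qc = PASS (``doc`` is a nominal
    fill value); use :func:`truth_genotypes` for the dict form read
    simulation consumes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    samples = [f"S{i + 1:03d}" for i in range(n)]
    for locus, fr in freqs.freqs.items():
        labels = list(fr)
        p = np.array([fr[a] for a in labels])
        p = p / p.sum()
        picks = rng.choice(len(labels), size=(n, 2), p=p)
        for s, (i1, i2) in zip(samples, picks):
            a1, a2 = sorted((labels[i1], labels[i2]))
            rows.append(
                {
                    "sample": s,
                    "locus": locus,
                    "allele1": a1,
                    "allele2": a2 if a2 != a1 else "",
                    "doc": doc,
                    "balance": "",
                    "qc": "PASS",
                }
            )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def truth_genotypes(table: pd.DataFrame) -> dict[str, dict[str, tuple[str, str]]]:
    """Genotype table -> {sample: {locus: (allele1, allele2)}} truth dict."""
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for row in table.itertuples(index=False):
        a2 = row.allele2 if row.allele2 else row.allele1
        out.setdefault(row.sample, {})[row.locus] = (row.allele1, a2)
    return out


# ---------------------------------------------------------------------------
# reads


def generate_reference(panel: Panel, seed: int = 0) -> dict[str, str]:
    """Random reference sequence per contig, long enough for all amplicons."""
    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    for locus in panel:
        lengths[locus.chrom] = max(lengths.get(locus.chrom, 0), locus.amplicon_end + 100)
    return {
        chrom: "".join(rng.choice(list(BASES), size=length))
        for chrom, length in sorted(lengths.items(), key=lambda kv: kv[0])
    }


def _draw_depth(cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.depth_mean <= 0:
        return 0
    if cfg.depth_dispersion <= 0:
        return int(round(cfg.depth_mean))
    shape = 1.0 / cfg.depth_dispersion
    lam = rng.gamma(shape, cfg.depth_mean / shape)
    return int(rng.poisson(lam))


def _haplotype_fragment_counts(
    genotype: tuple[str, str], depth: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    a1, a2 = genotype
    if a1 == a2:
        return [(a1, depth)]
    n1 = int(rng.binomial(depth, 0.5))
    return [(a1, n1), (a2, depth - n1)]


def generate_reads(
    sample_haplotypes: Mapping[str, Sequence[tuple[str, int]]],
    panel: Panel,
    cfg: SimConfig,
    out_sam,
    reference: Optional[dict[str, str]] = None,
    sample_name: str = "S001",
    seed: int = 0,
    out_fastq_prefix: Optional[str] = None,
) -> None:
    """Emit sorted, truth-aligned paired reads for one sample as SAM.

    ``sample_haplotypes`` maps locus -> [(haplotype string, fragment
    count), ...]; use :func:`fragments_from_genotypes` or mixture counts
    to build it.  Each fragment yields a 2 x ``read_len`` proper pair
    spanning the amplicon; per-base substitution errors at
    ``cfg.error_rate``.  With ``out_fastq_prefix`` a paired FASTQ mirror
    (_R1/_R2, Phred+33) is written as well.
    """
    rng = np.random.default_rng(seed)
    reference = reference if reference is not None else generate_reference(panel, cfg.seed)
    chroms = sorted(reference, key=lambda c: (len(c), c))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
            "RG": [{"ID": sample_name, "SM": sample_name}],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}

    records = []
    fastq1: list[tuple[str, str]] = []
    fastq2: list[tuple[str, str]] = []
    for locus in panel.sorted():
        haps = sample_haplotypes.get(locus.name)
        if not haps:
            continue
        amp = list(reference[locus.chrom][locus.amplicon_start : locus.amplicon_end])
        offsets = [p - locus.amplicon_start for p in locus.snp_positions]
        alen = len(amp)
        rlen = min(cfg.read_len, alen)
        r2_start = locus.amplicon_start + alen - rlen
        frag_i = 0
        for hap, count in haps:
            template = amp.copy()
            for off, base in zip(offsets, hap):
                template[off] = base
            for _ in range(count):
                frag_i += 1
                seq = np.array(template)
                if cfg.error_rate > 0:
                    hit = rng.random(alen) < cfg.error_rate
                    for j in np.flatnonzero(hit):
                        choices = [b for b in BASES if b != seq[j]]
                        seq[j] = choices[rng.integers(0, 3)]
                full = "".join(seq)
                r1 = full[:rlen]
                r2 = full[alen - rlen :]
                qname = f"{sample_name}:{locus.name}:{frag_i}"
                records.append(
                    _make_pair(
                        qname, tid[locus.chrom], locus.amplicon_start, r2_start, r1, r2, alen, header
                    )
                )
                if out_fastq_prefix is not None:
                    fastq1.append((qname, r1))
                    fastq2.append((qname, _revcomp(r2)))
    flat = [r for pair in records for r in pair]
    flat.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.is_read2))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
        for rec in flat:
            fh.write(rec)
    if out_fastq_prefix is not None:
        for suffix, items in (("_R1.fastq", fastq1), ("_R2.fastq", fastq2)):
            with open(f"{out_fastq_prefix}{suffix}", "wt", encoding="utf-8") as fq:
                for qname, seq in items:
                    fq.write(f"@{qname}\n{seq}\n+\n{'F' * len(seq)}\n")


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp.get(b, "N") for b in reversed(seq))


def _make_pair(qname, tid, start1, start2, seq1, seq2, frag_len, header):
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.query_sequence = seq1
    a.flag = 99  # paired, proper, mate reverse, first in pair
    a.reference_id = tid
    a.reference_start = start1
    a.mapping_quality = 60
    a.cigarstring = f"{len(seq1)}M"
    a.next_reference_id = tid
    a.next_reference_start = start2
    a.template_length = frag_len
    a.query_qualities = pysam.qualitystring_to_array("F" * len(seq1))
    a.set_tag("RG", header.to_dict()["RG"][0]["ID"])

    b = pysam.AlignedSegment(header)
    b.query_name = qname
    b.query_sequence = seq2
    b.flag = 147  # paired, proper, reverse, second in pair
    b.reference_id = tid
    b.reference_start = start2
    b.mapping_quality = 60
    b.cigarstring = f"{len(seq2)}M"
    b.next_reference_id = tid
    b.next_reference_start = start1
    b.template_length = -frag_len
    b.query_qualities = pysam.qualitystring_to_array("F" * len(seq2))
    b.set_tag("RG", header.to_dict()["RG"][0]["ID"])
    return a, b


def fragments_from_genotypes(
    genotypes: Mapping[str, tuple[str, str]],
    panel: Panel,
    cfg: SimConfig,
    seed: int = 0,
) -> dict[str, list[tuple[str, int]]]:
    """Per-locus (haplotype, fragment count) lists for one diploid sample.

    Locus depth is Gamma-Poisson around ``cfg.depth_mean`` (dispersion 0
    makes it deterministic); heterozygote fragments split Binomial(1/2)
    between the two alleles.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[str, int]]] = {}
    for locus in panel:
        gt = genotypes.get(locus.name)
        if gt is None:
            continue
        depth = _draw_depth(cfg, rng)
        out[locus.name] = [(h, c) for h, c in _haplotype_fragment_counts(gt, depth, rng) if c > 0]
    return out


def fragments_from_counts(counts: Mapping[str, HaplotypeCounts]) -> dict[str, list[tuple[str, int]]]:
    """Adapter: mixture HaplotypeCounts -> the generate_reads input form."""
    return {locus: sorted(hc.counts.items()) for locus, hc in counts.items()}
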