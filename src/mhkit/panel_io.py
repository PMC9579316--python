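"""Microhaplotype panel definitions: types, validation, TSV round-trip.

A panel lists MH loci: for each locus the amplicon interval on a reference
build and the genomic positions of its constituent SNPs (2-6 per locus,
all inside an amplicon of at most 300 bp).  Panel files use 1-based
inclusive coordinates (the VCF convention); internally everything is
0-based half-open.  Locus names follow the standard MH nomenclature:
``MH`` + two-digit chromosome number (01-22) + uppercase lab abbreviation
+ serial digits, e.g. ``MH13KK218``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

MAX_AMPLICON_LEN = 300
MIN_SNPS = 2
MAX_SNPS = 6

_NAME_RE = re.compile(r"^MH(\d{2})([A-Z]+)(\d+)$")

PANEL_COLUMNS = ["name", "chrom", "build", "amplicon_start", "amplicon_end", "snp_positions"]


class PanelValidationError(ValueError):
    """A locus or panel violates a structural invariant."""


class PanelParseError(ValueError):
    """A panel file row cannot be parsed."""


def validate_mh_name(name: str) -> tuple[bool, Optional[int]]:
    """Check a locus name against the standard MH nomenclature.

    Valid names are ``MH`` + two-digit chromosome (01-22) + an uppercase
    laboratory abbreviation + one or more serial digits.  Returns
    ``(valid, chromosome)``; never raises.

    >>> validate_mh_name("MH13KK218")
    (True, 13)
    >>> validate_mh_name("mh05kk170")
    (False, None)
    """
    m = _NAME_RE.match(name)
    if not m:
        return False, None
    chrom = int(m.group(1))
    if not 1 <= chrom <= 22:
        return False, None
    return True, chrom


@dataclass(frozen=True)
class PanelLocus:
    """One MH marker: its amplicon and the SNP positions phased into alleles.

    Coordinates are 0-based half-open (``amplicon_start`` inclusive,
    ``amplicon_end`` exclusive); ``snp_positions`` are 0-based reference
    positions, strictly increasing, all within the amplicon.
    ``alleles_per_snp`` gives the permitted symbols at each position
    (single-character codes; a ``-`` code may represent a single-base
    deletion).
    """

    name: str
    chrom: str
    amplicon_start: int
    amplicon_end: int
    snp_positions: tuple[int, ...]
    alleles_per_snp: tuple[frozenset[str], ...] = field(default=())

    def __post_init__(self) -> None:
        valid, _ = validate_mh_name(self.name)
        if not valid:
            raise PanelValidationError(
                f"locus {self.name!r}: name fails MH nomenclature "
                "(MH + chromosome 01-22 + uppercase lab code + serial digits)"
            )
        n = len(self.snp_positions)
        if not MIN_SNPS <= n <= MAX_SNPS:
            raise PanelValidationError(
                f"locus {self.name}: {n} SNP positions, must be {MIN_SNPS}-{MAX_SNPS}"
            )
        length = self.amplicon_end - self.amplicon_start
        if length <= 0:
            raise PanelValidationError(f"locus {self.name}: empty amplicon interval")
        if length > MAX_AMPLICON_LEN:
            raise PanelValidationError(
                f"locus {self.name}: amplicon {length} bp exceeds {MAX_AMPLICON_LEN} bp"
            )
        if any(b <= a for a, b in zip(self.snp_positions, self.snp_positions[1:])):
            raise PanelValidationError(
                f"locus {self.name}: SNP positions must be strictly increasing"
            )
        if self.snp_positions and (
            self.snp_positions[0] < self.amplicon_start
            or self.snp_positions[-1] >= self.amplicon_end
        ):
            raise PanelValidationError(
                f"locus {self.name}: SNP positions fall outside the amplicon"
            )
        if self.alleles_per_snp and len(self.alleles_per_snp) != n:
            raise PanelValidationError(
                f"locus {self.name}: alleles_per_snp length != number of SNPs"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start


@dataclass(frozen=True)
class Panel:
    """An ordered collection of uniquely-named MH loci on one reference build."""

    reference_build: str
    loci: tuple[PanelLocus, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate locus names: {dupes}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> PanelLocus:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise KeyError(name)

    def sorted(self) -> "Panel":
        """Loci ordered by (chromosome, amplicon start); the on-disk order."""
        return Panel(
            self.reference_build,
            tuple(sorted(self.loci, key=lambda l: (_chrom_key(l.chrom), l.amplicon_start))),
        )


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (int(c), "") if c.isdigit() else (99, c)


def read_panel(path) -> Panel:
    """Read a panel TSV (1-based inclusive coordinates) into a :class:`Panel`.

    Expected header columns: name, chrom, build, amplicon_start,
    amplicon_end, snp_positions (comma-separated 1-based positions).
    Lines starting with ``#`` are comments.  Raises
    :class:`PanelParseError` naming the offending line on malformed rows
    and :class:`PanelValidationError` naming the locus on invariant
    violations.
    """
    loci: list[PanelLocus] = []
    build = ""
    with open(path, "rt", encoding="utf-8") as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in PANEL_COLUMNS if c not in header]
                if missing:
                    raise PanelParseError(f"line {lineno}: missing columns {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                name = row["name"]
                chrom = row["chrom"]
                build = row["build"]
                start1 = int(row["amplicon_start"])
                end1 = int(row["amplicon_end"])
                snps1 = [int(x) for x in row["snp_positions"].split(",") if x]
                alleles_raw = row.get("alleles_per_snp", "")
            except (KeyError, ValueError) as exc:
                raise PanelParseError(f"line {lineno}: {exc}") from exc
            alleles: tuple[frozenset[str], ...] = ()
            if alleles_raw:
                alleles = tuple(frozenset(grp) for grp in alleles_raw.split(";"))
            loci.append(
                PanelLocus(
                    name=name,
                    chrom=chrom,
                    amplicon_start=start1 - 1,
                    amplicon_end=end1,
                    snp_positions=tuple(p - 1 for p in snps1),
                    alleles_per_snp=alleles,
                )
            )
    return Panel(reference_build=build, loci=tuple(loci)).sorted()


def write_panel(panel: Panel, path) -> None:
    """Write a panel TSV (1-based inclusive coordinates); read_panel inverse."""
    panel = panel.sorted()
    with open(path, "wt", encoding="utf-8") as fh:
        cols = PANEL_COLUMNS + ["alleles_per_snp"]
        fh.write("\t".join(cols) + "\n")
        for locus in panel:
            alleles = ";".join("".join(sorted(s)) for s in locus.alleles_per_snp)
            fh.write(
                "\t".join(
                    [
                        locus.name,
                        locus.chrom,
                        panel.reference_build,
                        str(locus.amplicon_start + 1),
                        str(locus.amplicon_end),
                        ",".join(str(p + 1) for p in locus.snp_positions),
                        alleles,
                    ]
                )
                + "\n"
            )


def write_bed(panel: Panel, path) -> None:
    """Export amplicon intervals as BED (0-based half-open) for interop."""
    with open(path, "wt", encoding="utf-8") as fh:
        for locus in panel.sorted():
            fh.write(f"{locus.chrom}\t{locus.amplicon_start}\t{locus.amplicon_end}\t{locus.name}\n")
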