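"""ORF prediction and catalogue statistics under baculoviral conventions.

An ORF here is a maximal start-to-stop reading frame: the first start codon
after the previous in-frame stop, through the next in-frame stop (inclusive).
Both strands and all six frames are scanned; on circular genomes ORFs may
wrap through the origin, in which case their footprint is reported with
``start > end``. Orientation (clockwise / anticlockwise) is defined relative
to the polh strand, which is '+' once the genome has been rotated to the
polh start codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_io import (
    GenomeRecord,
    GenomeValidationError,
    SequenceInterval,
    reverse_complement,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
DEFAULT_MIN_AA = 50  # common baculovirus annotation convention


@dataclass(frozen=True)
class OrfFeature:
    orf_id: str
    interval: SequenceInterval
    aa_length: int
    product: str = ""

    @property
    def orientation(self) -> str:
        return "clockwise" if self.interval.strand == "+" else "anticlockwise"


@dataclass
class OrfCatalog:
    """Ordered ORF catalogue, sorted by start coordinate (polh-anchored maps
    therefore start at the polh ORF)."""

    genome_id: str
    orfs: list[OrfFeature] = field(default_factory=list)

    @property
    def n_orfs(self) -> int:
        return len(self.orfs)

    def sort(self) -> None:
        self.orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.interval.strand))

    def renumber(self, prefix: str = "ORF") -> None:
        self.sort()
        self.orfs = [
            OrfFeature(f"{prefix}{i}", o.interval, o.aa_length, o.product)
            for i, o in enumerate(self.orfs, start=1)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "orf_id": o.orf_id,
                    "start": o.interval.start,
                    "end": o.interval.end,
                    "strand": o.interval.strand,
                    "aa_length": o.aa_length,
                    "orientation": o.orientation,
                    "product": o.product,
                }
                for o in self.orfs
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _scan_strand(seq: str, circular: bool, min_nt: int, start_codons: frozenset[str]):
    """Yield maximal ORFs on one strand as 0-based (start, length) in strand coords.

    On circular sequences the walk runs over the doubled string and only
    records ORFs once an upstream in-frame stop has been seen, so wrapping
    ORFs get their true maximal start.
    """
    L = len(seq)
    scan = seq + seq if circular else seq
    seen: set[tuple[int, int]] = set()
    for frame in range(3):
        first_start: int | None = None
        # linear sequences have a natural upstream boundary at position 0
        context_known = not circular
        for p in range(frame, len(scan) - 2, 3):
            codon = scan[p : p + 3]
            if codon in STOP_CODONS:
                if context_known and first_start is not None:
                    length = p + 3 - first_start
                    if length >= min_nt and length <= L:
                        key = (first_start % L, length)
                        if key not in seen:
                            seen.add(key)
                            yield first_start % L, length
                first_start = None
                context_known = True
            elif first_start is None and codon in start_codons:
                first_start = p


def find_orfs(
    record: GenomeRecord,
    min_aa: int = DEFAULT_MIN_AA,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    allow_wrap: bool = True,
) -> OrfCatalog:
    """Predict all maximal ORFs of at least ``min_aa`` residues on both strands.

    ``aa_length`` counts translated residues (span/3 - 1; the stop codon is
    part of the span but not of the protein).
    """
    if min_aa < 1:
        raise ValueError(f"min_aa must be >= 1, got {min_aa}")
    L = record.length
    circular = record.topology == "circular" and allow_wrap
    min_nt = 3 * (min_aa + 1)
    orfs: list[OrfFeature] = []

    for strand, sseq in (("+", record.seq), ("-", reverse_complement(record.seq))):
        for s0, length in _scan_strand(sseq, circular, min_nt, start_codons):
            e0 = s0 + length - 1  # strand-local 0-based inclusive
            if strand == "+":
                start = s0 % L + 1
                end = e0 % L + 1
            else:
                # strand-local index i maps to plus-strand position L - (i % L)
                start = L - (e0 % L)
                end = L - (s0 % L)
            iv = SequenceInterval(start, end, strand)
            orfs.append(OrfFeature("", iv, length // 3 - 1))

    catalog = OrfCatalog(genome_id=record.id, orfs=orfs)
    catalog.renumber()
    return catalog


def translate_orf(record: GenomeRecord, orf: OrfFeature) -> str:
    """Translate an ORF's coding sequence (stop codon dropped)."""
    from Bio.Seq import Seq

    from .genome_io import subsequence

    cds = subsequence(record, orf.interval)
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def orientation_stats(catalog: OrfCatalog, polh_strand: str = "+") -> dict:
    """Clockwise/anticlockwise counts relative to the polh strand.

    The ratio is anticlockwise:clockwise, rounded to two decimals (the usual
    way the 1:1.06-style orientation ratio is quoted); it is None when no ORF
    lies on the polh strand.
    """
    if catalog.n_orfs == 0:
        raise GenomeValidationError("orientation undefined on an empty catalogue")
    n_cw = sum(1 for o in catalog.orfs if o.interval.strand == polh_strand)
    n_acw = catalog.n_orfs - n_cw
    ratio = round(n_acw / n_cw, 2) if n_cw else None
    return {"n_clockwise": n_cw, "n_anticlockwise": n_acw, "ratio": ratio}


def _overlap_bp(a: SequenceInterval, b: SequenceInterval, genome_length: int) -> int:
    total = 0
    for s1, e1 in a.segments(genome_length):
        for s2, e2 in b.segments(genome_length):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def overlap_stats(catalog: OrfCatalog, genome_length: int) -> dict:
    """Pairwise ORF overlap statistics, circular adjacency included.

    An ORF counts as overlapping if it shares at least 1 bp with any other
    ORF, on either strand. Amino-acid overlaps are reported as
    floor(overlap_bp / 3) alongside the bp value.
    """
    pairs = []
    overlapping: set[str] = set()
    orfs = catalog.orfs
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            bp = _overlap_bp(orfs[i].interval, orfs[j].interval, genome_length)
            if bp > 0:
                rel = (
                    "same"
                    if orfs[i].interval.strand == orfs[j].interval.strand
                    else "opposite"
                )
                pairs.append(
                    {
                        "orf_a": orfs[i].orf_id,
                        "orf_b": orfs[j].orf_id,
                        "overlap_bp": bp,
                        "overlap_aa": bp // 3,
                        "relative_orientation": rel,
                    }
                )
                overlapping.add(orfs[i].orf_id)
                overlapping.add(orfs[j].orf_id)
    lengths = [p["overlap_bp"] for p in pairs]
    n = len(overlapping)
    return {
        "n_overlapping_orfs": n,
        "pct_overlapping": (n / catalog.n_orfs * 100.0) if catalog.n_orfs else 0.0,
        "min_overlap_bp": min(lengths) if lengths else 0,
        "max_overlap_bp": max(lengths) if lengths else 0,
        "pairs": pairs,
    }


def genome_density(catalog: OrfCatalog, genome_length: int, other_density: float | None = None) -> dict:
    """ORFs per kb of genome; optionally the ratio against another density."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    density = catalog.n_orfs / (genome_length / 1000.0)
    out = {"orfs_per_kb": density}
    if other_density is not None:
        out["density_ratio_vs"] = density / other_density
    return out
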