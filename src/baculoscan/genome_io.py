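"""Genome record I/O and coordinate utilities.

Baculovirus genome maps are conventionally circular, numbered from the A of
the polyhedrin (polh) start codon, with 1-based inclusive coordinates. This
module owns that coordinate dialect: every other stage works on the
:class:`GenomeRecord` / :class:`SequenceInterval` types defined here and never
re-derives coordinates itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Topology = Literal["circular", "linear"]


class GenomeValidationError(ValueError):
    """Raised when a record or interval violates the coordinate contract."""


class CoordinateError(GenomeValidationError):
    """Raised for out-of-range or illegally wrapping coordinates."""


class CompositionError(GenomeValidationError):
    """Raised when base composition is undefined (empty or all-N input)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceInterval:
    """1-based inclusive genomic interval.

    ``start > end`` denotes an interval wrapping through the origin and is
    only meaningful on circular records. ``strand`` follows the usual +/-
    convention; minus-strand extraction returns the reverse complement of the
    plus-strand footprint.
    """

    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"coordinates are 1-based: ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"invalid strand {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError("wrapping interval length needs the genome length")
        return self.end - self.start + 1 + genome_length

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """Plus-strand footprint as 1 or 2 non-wrapping (start, end) pieces."""
        if self.wraps:
            return [(self.start, genome_length), (1, self.end)]
        return [(self.start, self.end)]


@dataclass
class GenomeRecord:
    """A genome sequence with features, in 1-based inclusive coordinates."""

    id: str
    seq: str
    topology: Topology = "circular"
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        if not self.seq:
            raise GenomeValidationError(f"record {self.id!r} has zero-length sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeValidationError(f"invalid topology {self.topology!r}")
        for feat in self.features:
            iv = getattr(feat, "interval", feat)
            if isinstance(iv, SequenceInterval):
                self._check_interval(iv)

    def _check_interval(self, interval: SequenceInterval) -> None:
        if interval.start > self.length or interval.end > self.length:
            raise CoordinateError(
                f"interval ({interval.start}, {interval.end}) outside [1, {self.length}]"
            )
        if interval.wraps and self.topology != "circular":
            raise CoordinateError("wrapping interval on a linear record")

    @property
    def length(self) -> int:
        return len(self.seq)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any non-ACGT residue (IUPAC ambiguity etc.) to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    return "".join(c if c in _VALID_BASES else "N" for c in seq)


def subsequence(record: GenomeRecord, interval: SequenceInterval) -> str:
    """Extract an interval's sequence; minus strand returns the reverse complement."""
    record._check_interval(interval)
    if interval.wraps:
        out = record.seq[interval.start - 1 :] + record.seq[: interval.end]
    else:
        out = record.seq[interval.start - 1 : interval.end]
    if interval.strand == "-":
        out = reverse_complement(out)
    return out


def rotate_to_anchor(record: GenomeRecord, anchor_start: int) -> GenomeRecord:
    """Renumber a circular genome so the base at ``anchor_start`` becomes position 1.

    Used to place the A of the polh start codon at position 1, the standard
    baculovirus map convention. Feature coordinates are remapped modulo the
    genome length; content and feature count are unchanged.
    """
    if record.topology != "circular":
        raise GenomeValidationError("rotation is only defined on circular records")
    if not 1 <= anchor_start <= record.length:
        raise CoordinateError(f"anchor {anchor_start} outside [1, {record.length}]")
    shift = anchor_start - 1
    newseq = record.seq[shift:] + record.seq[:shift]

    def remap(pos: int) -> int:
        return (pos - 1 - shift) % record.length + 1

    new_features = []
    for feat in record.features:
        iv = getattr(feat, "interval", None)
        if isinstance(iv, SequenceInterval):
            new_iv = replace(iv, start=remap(iv.start), end=remap(iv.end))
            new_features.append(replace(feat, interval=new_iv))
        else:
            new_features.append(feat)
    return GenomeRecord(id=record.id, seq=newseq, topology=record.topology, features=new_features)


def base_composition(seq: str) -> dict[str, float]:
    """GC and AT percentages over called (non-N) bases."""
    seq = normalize_sequence(seq)
    called = sum(seq.count(b) for b in "ACGT")
    if called == 0:
        raise CompositionError("composition undefined: no called bases")
    gc = seq.count("G") + seq.count("C")
    gc_pct = gc / called * 100.0
    return {"gc_percent": gc_pct, "at_percent": 100.0 - gc_pct}


# --- file formats -----------------------------------------------------------

@dataclass(frozen=True)
class RegionFeature:
    """Generic non-ORF feature (hr, CNE, ...) carried on a record."""

    label: str
    interval: SequenceInterval
    kind: str = "misc_feature"


def _features_from_seqrecord(seqrec) -> list:
    from .orf_annotation import OrfFeature  # local import to avoid a cycle

    feats = []
    length = len(seqrec.seq)
    for f in seqrec.features:
        if f.type != "CDS":
            if f.type not in ("source", "gene"):
                logger.warning("ignoring feature of type %r", f.type)
            continue
        start = int(f.location.start) + 1  # Biopython is 0-based half-open
        end = int(f.location.end)
        strand = "-" if f.location.strand == -1 else "+"
        product = f.qualifiers.get("product", [""])[0]
        locus = f.qualifiers.get("locus_tag", f.qualifiers.get("gene", [""]))[0]
        span = end - start + 1
        if span % 3:
            logger.warning("CDS %s span %d not divisible by 3; keeping as-is", locus, span)
        feats.append(
            OrfFeature(
                orf_id=locus or f"cds_{start}",
                interval=SequenceInterval(start, end, strand),
                aa_length=max(span // 3 - 1, 0),
                product=product,
            )
        )
        if end > length:
            raise CoordinateError(f"CDS {locus} end {end} beyond sequence length {length}")
    return feats


def read_genome(
    path: str | Path,
    format: str = "genbank",
    features_path: str | Path | None = None,
    topology: Topology = "circular",
) -> GenomeRecord:
    """Read a genome from a GenBank flat file or FASTA (+ optional feature TSV).

    The TSV companion format has columns ``id, start, end, strand, product``
    with 1-based inclusive coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        try:
            seqrec = next(SeqIO.parse(str(path), "genbank"))
        except (StopIteration, ValueError) as exc:
            raise GenomeValidationError(f"could not parse GenBank record from {path}: {exc}") from exc
        topo = seqrec.annotations.get("topology", topology)
        return GenomeRecord(
            id=seqrec.id,
            seq=str(seqrec.seq),
            topology="circular" if topo == "circular" else "linear",
            features=_features_from_seqrecord(seqrec),
        )
    if format in ("fasta", "fasta+tsv"):
        try:
            seqrec = next(SeqIO.parse(str(path), "fasta"))
        except (StopIteration, ValueError) as exc:
            raise GenomeValidationError(f"could not parse FASTA record from {path}: {exc}") from exc
        features = []
        if features_path is not None:
            features = read_feature_tsv(features_path)
        return GenomeRecord(id=seqrec.id, seq=str(seqrec.seq), topology=topology, features=features)
    raise ValueError(f"unknown format {format!r}")


def read_feature_tsv(path: str | Path) -> list:
    from .orf_annotation import OrfFeature

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "product": str})
    if df.empty:
        return []
    required = {"id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeValidationError(f"feature TSV missing columns: {sorted(missing)}")
    feats = []
    for row in df.itertuples(index=False):
        iv = SequenceInterval(int(row.start), int(row.end), str(row.strand))
        feats.append(
            OrfFeature(
                orf_id=str(row.id),
                interval=iv,
                aa_length=getattr(row, "aa_length", 0) or 0,
                product=str(getattr(row, "product", "") or ""),
            )
        )
    return feats


def write_genome(record: GenomeRecord, fasta_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write sequence as FASTA and features as TSV (id, start, end, strand, aa_length, product)."""
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(record.seq), id=record.id, description=record.topology)],
        str(fasta_path),
        "fasta",
    )
    if tsv_path is not None:
        rows = []
        for feat in record.features:
            iv = feat.interval
            rows.append(
                {
                    "id": getattr(feat, "orf_id", getattr(feat, "label", "")),
                    "start": iv.start,
                    "end": iv.end,
                    "strand": iv.strand,
                    "aa_length": getattr(feat, "aa_length", ""),
                    "product": getattr(feat, "product", getattr(feat, "kind", "")),
                }
            )
        pd.DataFrame(rows, columns=["id", "start", "end", "strand", "aa_length", "product"]).to_csv(
            tsv_path, sep="\t", index=False
        )
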