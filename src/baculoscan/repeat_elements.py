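"""Homologous-region (hr) detection, degenerate consensus motifs, CNE scan.

Baculovirus hrs are clusters of imperfect ~30-bp palindromes flanked by
direct repeats; they act as replication origins and transcriptional
enhancers. Detection here is windowed palindromicity: a window is a hit when
at most ``max_mismatch`` of its (i, L+1-i) base pairs fail to be
Watson-Crick complementary. Hits are clustered into hr regions by genomic
gap, and a per-column IUPAC degenerate consensus is derived over the
repeats.

The CNE (conserved non-coding element) is a ~156-bp alphabaculovirus
element with seven conserved nucleotide clusters (C1-C7) arranged in three
dyad-symmetry elements (DSl/DSc/DSr), each carrying an inverted repeat; the
scanner locates the best match of a reference CNE on either strand and then
checks the cluster/dyad structure inside the match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import edlib
import numpy as np

from .genome_io import (
    GenomeRecord,
    GenomeValidationError,
    SequenceInterval,
    normalize_sequence,
    reverse_complement,
    subsequence,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

# IUPAC degenerate codes by base set
IUPAC_CODE = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_SET = {code: bases for bases, code in IUPAC_CODE.items()}

DEFAULT_WORD_LENGTH = 30
DEFAULT_MAX_MISMATCH = 3
DEFAULT_MAX_GAP = 500
DEFAULT_MIN_REPEATS = 1
DEFAULT_INCLUSION_THRESHOLD = 0.125


@dataclass
class PalindromeHit:
    interval: SequenceInterval
    seq: str
    self_complementary_pairs: int
    mismatches_to_consensus: int | None = None

    @property
    def mismatched_pairs(self) -> int:
        return len(self.seq) // 2 - self.self_complementary_pairs


@dataclass
class HrRegion:
    hr_id: str
    interval: SequenceInterval
    repeats: list[PalindromeHit]

    @property
    def repeat_count(self) -> int:
        return len(self.repeats)


@dataclass
class ConsensusMotif:
    iupac: str
    counts: np.ndarray  # shape (L, 4), columns A,C,G,T

    @property
    def unambiguous_positions(self) -> int:
        return sum(1 for c in self.iupac if c in "ACGT")


@dataclass
class CneMatch:
    interval: SequenceInterval
    identity_pct: float
    cluster_hits: dict[str, bool] = field(default_factory=dict)
    ds_elements: dict[str, SequenceInterval] = field(default_factory=dict)
    ir_pairs: list[dict] = field(default_factory=list)


def _pair_mismatches(window: str) -> int:
    """Number of (i, L+1-i) pairs that are not Watson-Crick complementary.

    Mismatch is counted per pair, not per base; a central base of an
    odd-length window belongs to no pair.
    """
    L = len(window)
    bad = 0
    for i in range(L // 2):
        a, b = window[i], window[L - 1 - i]
        if _COMP.get(a) != b:
            bad += 1
    return bad


def find_palindromes(
    seq: str,
    word_length: int = DEFAULT_WORD_LENGTH,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[PalindromeHit]:
    """Slide a window and keep near-palindromic windows; overlapping hits are
    merged to the best-scoring (fewest mismatched pairs, then leftmost) one."""
    seq = normalize_sequence(seq)
    if word_length > len(seq):
        raise ValueError(f"word_length {word_length} exceeds sequence length {len(seq)}")
    if max_mismatch >= word_length / 2:
        raise ValueError("max_mismatch must be < word_length/2")
    n_pairs = word_length // 2

    raw: list[tuple[int, int]] = []  # (0-based start, mismatched pairs)
    for s in range(len(seq) - word_length + 1):
        bad = _pair_mismatches(seq[s : s + word_length])
        if bad <= max_mismatch:
            raw.append((s, bad))

    hits: list[PalindromeHit] = []
    group: list[tuple[int, int]] = []

    def flush() -> None:
        if not group:
            return
        s, bad = min(group, key=lambda t: (t[1], t[0]))
        hits.append(
            PalindromeHit(
                interval=SequenceInterval(s + 1, s + word_length),
                seq=seq[s : s + word_length],
                self_complementary_pairs=n_pairs - bad,
            )
        )
        group.clear()

    for s, bad in raw:
        if group and s >= group[-1][0] + word_length:
            flush()
        group.append((s, bad))
    flush()
    return hits


def cluster_into_hrs(
    hits: list[PalindromeHit],
    max_gap: int = DEFAULT_MAX_GAP,
    min_repeats: int = DEFAULT_MIN_REPEATS,
) -> list[HrRegion]:
    """Cluster palindrome hits into hr regions by inter-hit gap; hr ids are
    assigned in genome order starting at hr1."""
    hits = sorted(hits, key=lambda h: h.interval.start)
    clusters: list[list[PalindromeHit]] = []
    for hit in hits:
        if clusters and hit.interval.start - clusters[-1][-1].interval.end - 1 <= max_gap:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    regions = []
    for cluster in clusters:
        if len(cluster) < min_repeats:
            continue
        iv = SequenceInterval(cluster[0].interval.start, cluster[-1].interval.end)
        regions.append(HrRegion(hr_id=f"hr{len(regions) + 1}", interval=iv, repeats=cluster))
    return regions


def build_consensus(
    repeats: list[str],
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD,
) -> ConsensusMotif:
    """Per-column IUPAC degenerate consensus over equal-length repeats.

    A base enters the position's code when its column frequency reaches
    ``inclusion_threshold``; the majority base is always included. The
    default threshold admits any base clearly above sequencing/mutation
    noise, so rare variants widen the code rather than vanish.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeats to build a consensus")
    repeats = [normalize_sequence(r) for r in repeats]
    L = len(repeats[0])
    if any(len(r) != L for r in repeats):
        raise GenomeValidationError("repeats must be pre-aligned to equal length")
    order = "ACGT"
    counts = np.zeros((L, 4), dtype=int)
    for r in repeats:
        for i, b in enumerate(r):
            if b in _COMP:
                counts[i, order.index(b)] += 1
    codes = []
    for i in range(L):
        col = counts[i]
        total = col.sum()
        if total == 0:
            codes.append("N")
            continue
        included = {order[k] for k in range(4) if col[k] / total >= inclusion_threshold}
        included.add(order[int(col.argmax())])
        codes.append(IUPAC_CODE[frozenset(included)])
    return ConsensusMotif(iupac="".join(codes), counts=counts)


def consensus_stats(motif: ConsensusMotif | str) -> dict:
    """Length, invariant-position count and complement-compatible pair count
    of an IUPAC consensus.

    A pair (i, L+1-i) is complement-compatible when some base allowed at i
    can Watson-Crick pair with some base allowed at the mirror position.
    """
    iupac = motif.iupac if isinstance(motif, ConsensusMotif) else motif
    iupac = iupac.upper()
    for c in iupac:
        if c not in IUPAC_SET:
            raise GenomeValidationError(f"invalid IUPAC code {c!r}")
    L = len(iupac)
    unambiguous = sum(1 for c in iupac if c in "ACGT")
    compatible = 0
    for i in range(L // 2):
        left = IUPAC_SET[iupac[i]]
        right_complement = frozenset(_COMP[b] for b in IUPAC_SET[iupac[L - 1 - i]])
        if left & right_complement:
            compatible += 1
    return {
        "length": L,
        "unambiguous_positions": unambiguous,
        "complementary_pairs": compatible,
    }


def annotate_consensus_mismatches(hrs: list[HrRegion], motif: ConsensusMotif) -> None:
    """Fill each repeat's mismatch count against the consensus (IUPAC-aware)."""
    for hr in hrs:
        for rep in hr.repeats:
            if len(rep.seq) != len(motif.iupac):
                continue
            rep.mismatches_to_consensus = sum(
                1 for b, c in zip(rep.seq, motif.iupac) if b not in IUPAC_SET[c]
            )


def hr_genome_fraction(hrs: list[HrRegion], genome_length: int) -> float:
    """Percentage of the genome occupied by hr palindromic repeats.

    The numerator is summed repeat bp, not whole-region spans, so spacer
    sequence between repeats does not count.
    """
    spans = sorted((hr.interval.start, hr.interval.end) for hr in hrs)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise GenomeValidationError("hr regions overlap")
    total = sum(len(rep.seq) for hr in hrs for rep in hr.repeats)
    return total / genome_length * 100.0


# --- CNE --------------------------------------------------------------------

def load_reference_cne() -> tuple[str, dict]:
    """Packaged reference CNE sequence and its C1-C7/DS/IR annotation.

    The packaged reference is a synthetic stand-in with the canonical
    architecture (seven conserved clusters in three dyad-symmetry elements
    with inverted repeats), not a sequence from any deposited genome.
    """
    data = resources.files("baculoscan").joinpath("data")
    seq = ""
    for line in data.joinpath("cne_reference_synthetic.fasta").read_text().splitlines():
        if not line.startswith(">"):
            seq += line.strip()
    annotation = json.loads(data.joinpath("cne_annotation_synthetic.json").read_text())
    return normalize_sequence(seq), annotation


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """Percent identity and column count from an extended-CIGAR string."""
    import re

    matches = columns = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return (matches / columns * 100.0 if columns else 0.0), columns


def _find_submotif(region: str, motif: str, max_mismatch: int = 1) -> int | None:
    """0-based start of the best <=max_mismatch occurrence of motif, else None."""
    best = None
    for s in range(len(region) - len(motif) + 1):
        mm = sum(1 for a, b in zip(region[s : s + len(motif)], motif) if a != b)
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (s, mm)
    return best[0] if best else None


def scan_cne(
    record: GenomeRecord,
    reference_cne: str | None = None,
    min_identity: float = 80.0,
    annotation: dict | None = None,
) -> CneMatch | None:
    """Locate the best CNE match on either strand; None below ``min_identity``.

    Cluster hits (C1-C7) are searched as exact/1-mismatch submotifs of the
    reference inside the matched region; dyad-symmetry elements are reported
    with their inverted-repeat pairs when both arms are found.
    """
    if reference_cne is None:
        reference_cne, packaged = load_reference_cne()
        if annotation is None:
            annotation = packaged
    reference_cne = normalize_sequence(reference_cne)
    if len(reference_cne) < 100:
        raise ValueError("reference CNE must be at least 100 bp")

    best = None
    max_dist = int(len(reference_cne) * (1 - min_identity / 100.0)) + 1
    for strand, target in (("+", record.seq), ("-", reverse_complement(record.seq))):
        res = edlib.align(reference_cne, target, mode="HW", task="path", k=max_dist)
        if res["editDistance"] < 0:
            continue
        identity, _ = _cigar_identity(res["cigar"])
        loc = res["locations"][0]
        if best is None or identity > best[0]:
            best = (identity, strand, loc)
    if best is None or best[0] < min_identity:
        return None
    identity, strand, (a0, b0) = best
    L = record.length
    if strand == "+":
        iv = SequenceInterval(a0 + 1, b0 + 1, "+")
    else:
        iv = SequenceInterval(L - b0, L - a0, "-")
    region = subsequence(record, iv)

    cluster_hits: dict[str, bool] = {}
    ds_elements: dict[str, SequenceInterval] = {}
    ir_pairs: list[dict] = []
    if annotation:
        for name, (s, e) in annotation.get("clusters", {}).items():
            motif = reference_cne[s - 1 : e]
            cluster_hits[name] = _find_submotif(region, motif) is not None
        for ds, info in annotation.get("dyads", {}).items():
            s, e = info["span"]
            ds_elements[ds] = SequenceInterval(s, e)
            (ls, le), (rs, re_) = info["ir"]
            left = region[ls - 1 : le] if le <= len(region) else ""
            right = region[rs - 1 : re_] if re_ <= len(region) else ""
            mm = (
                sum(1 for a, b in zip(left, reverse_complement(right)) if a != b)
                if left and len(left) == len(right)
                else None
            )
            ir_pairs.append(
                {"ds": ds, "left": (ls, le), "right": (rs, re_), "arm_mismatches": mm}
            )
    return CneMatch(
        interval=iv,
        identity_pct=identity,
        cluster_hits=cluster_hits,
        ds_elements=ds_elements,
        ir_pairs=ir_pairs,
    )


def write_hr_tsv(hrs: list[HrRegion], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for hr in hrs:
        for rep in hr.repeats:
            rows.append(
                {
                    "hr_id": hr.hr_id,
                    "hr_start": hr.interval.start,
                    "hr_end": hr.interval.end,
                    "repeat_start": rep.interval.start,
                    "repeat_end": rep.interval.end,
                    "repeat_seq": rep.seq,
                    "self_complementary_pairs": rep.self_complementary_pairs,
                    "mismatches_to_consensus": rep.mismatches_to_consensus,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "hr_id", "hr_start", "hr_end", "repeat_start", "repeat_end",
            "repeat_seq", "self_complementary_pairs", "mismatches_to_consensus",
        ],
    ).to_csv(path, sep="\t", index=False)
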