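"""Cross-genome ortholog mapping and comparative statistics.

Orthologs are called by reciprocal best hit (RBH) over global protein
alignments, with a shared k-mer prefilter to keep the all-vs-all dynamic
programming tractable. Downstream statistics mirror the standard
comparative-genomics toolkit for baculoviruses: shared-ORF counts, mean
amino-acid identity, gene parity plots (rank-vs-rank collinearity) and
per-pair amino-acid length differences, plus an in silico restriction
digest (RFLP fingerprint) of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iproduct
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, reverse_complement
from .orf_annotation import OrfCatalog

DEFAULT_MIN_IDENTITY = 25.0
DEFAULT_KMER_SIZE = 5
DEFAULT_TOP_CANDIDATES = 10

_IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class OrthologPair:
    query_orf: str
    subject_orf: str
    identity_pct: float
    aln_length: int
    aa_length_diff: int  # query - subject, residues
    possible_fusion: str | None = None  # runner-up subject sharing the best score


@dataclass
class ComparisonReport:
    n_shared: int
    mean_identity: float
    parity_points: list[tuple[int, int]]
    length_diffs: list[tuple[str, int]]
    unmatched_query: list[str]
    unmatched_subject: list[str]


@dataclass
class RestrictionFragmentSet:
    enzyme: str
    site: str
    cut_positions: list[int]  # 1-based position of the first base of each site
    fragment_lengths: list[int]


def _aligner(scoring: str = "blosum62", gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.upper())
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_proteins(
    a: str,
    b: str,
    scoring: str = "blosum62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> dict:
    """Global protein alignment; identity over all alignment columns.

    The identity denominator includes gap columns, so unaligned overhangs
    count against identity.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _aligner(scoring, gap_open, gap_extend)
    aln = next(iter(aligner.align(a, b)))
    sa, sb = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    columns = len(sa)
    return {
        "identity_pct": identical / columns * 100.0,
        "aln_length": columns,
        "score": aln.score,
    }


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _best_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    subject_rank: dict[str, int],
    k: int,
    top_n: int,
    aligner_kwargs: dict,
) -> dict[str, tuple[str, float, float, int, str | None]]:
    """Best subject per query: id, score, identity, aln_length, runner-up id."""
    subj_kmers = {sid: _kmers(s, k) for sid, s in subjects.items()}
    out = {}
    for qid, q in queries.items():
        qk = _kmers(q, k)
        ranked = sorted(
            subjects,
            key=lambda sid: (-len(qk & subj_kmers[sid]), subject_rank[sid]),
        )[:top_n]
        scored = []
        for sid in ranked:
            res = align_proteins(q, subjects[sid], **aligner_kwargs)
            scored.append((sid, res["score"], res["identity_pct"], res["aln_length"]))
        if not scored:
            continue
        # ties: higher identity, then lower subject catalogue rank
        scored.sort(key=lambda t: (-t[1], -t[2], subject_rank[t[0]]))
        best = scored[0]
        runner = None
        if len(scored) > 1 and scored[1][1] == best[1]:
            runner = scored[1][0]
        out[qid] = (best[0], best[1], best[2], best[3], runner)
    return out


def map_orthologs(
    cat_a: OrfCatalog,
    proteins_a: dict[str, str],
    cat_b: OrfCatalog,
    proteins_b: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    kmer_size: int = DEFAULT_KMER_SIZE,
    top_candidates: int = DEFAULT_TOP_CANDIDATES,
    **aligner_kwargs,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two ORF catalogues.

    One-to-one by construction; a one-to-two case (e.g. a fused ORF matching
    two neighbours equally well) keeps the single best hit and records the
    runner-up as a possible fusion.
    """
    rank_a = {o.orf_id: i for i, o in enumerate(cat_a.orfs)}
    rank_b = {o.orf_id: i for i, o in enumerate(cat_b.orfs)}
    fwd = _best_hits(proteins_a, proteins_b, rank_b, kmer_size, top_candidates, aligner_kwargs)
    rev = _best_hits(proteins_b, proteins_a, rank_a, kmer_size, top_candidates, aligner_kwargs)
    pairs = []
    for qid, (sid, _score, identity, aln_len, runner) in fwd.items():
        if rev.get(sid, (None,))[0] != qid:
            continue
        if identity < min_identity:
            continue
        pairs.append(
            OrthologPair(
                query_orf=qid,
                subject_orf=sid,
                identity_pct=identity,
                aln_length=aln_len,
                aa_length_diff=len(proteins_a[qid]) - len(proteins_b[sid]),
                possible_fusion=runner,
            )
        )
    pairs.sort(key=lambda p: rank_a[p.query_orf])
    return pairs


def comparison_report(pairs: list[OrthologPair], cat_a: OrfCatalog, cat_b: OrfCatalog) -> ComparisonReport:
    """Shared-ORF summary with gene-parity points (1-based catalogue ranks)."""
    rank_a = {o.orf_id: i + 1 for i, o in enumerate(cat_a.orfs)}
    rank_b = {o.orf_id: i + 1 for i, o in enumerate(cat_b.orfs)}
    parity = [(rank_a[p.query_orf], rank_b[p.subject_orf]) for p in pairs]
    matched_a = {p.query_orf for p in pairs}
    matched_b = {p.subject_orf for p in pairs}
    mean_identity = sum(p.identity_pct for p in pairs) / len(pairs) if pairs else 0.0
    return ComparisonReport(
        n_shared=len(pairs),
        mean_identity=mean_identity,
        parity_points=parity,
        length_diffs=[(p.query_orf, p.aa_length_diff) for p in pairs],
        unmatched_query=[o.orf_id for o in cat_a.orfs if o.orf_id not in matched_a],
        unmatched_subject=[o.orf_id for o in cat_b.orfs if o.orf_id not in matched_b],
    )


def _expand_iupac(site: str) -> list[str]:
    site = site.upper()
    for c in site:
        if c not in _IUPAC_DNA:
            raise ValueError(f"invalid IUPAC code {c!r} in site")
    return ["".join(p) for p in iproduct(*(_IUPAC_DNA[c] for c in site))]


def _site_positions(seq: str, site: str, circular: bool) -> list[int]:
    """1-based start positions of every occurrence, wrapping occurrences included."""
    L = len(seq)
    hay = seq + seq[: len(site) - 1] if circular else seq
    positions = []
    start = 0
    while True:
        i = hay.find(site, start)
        if i < 0 or i >= L:
            break
        positions.append(i + 1)
        start = i + 1
    return positions


def insilico_rflp(record: GenomeRecord, site: str = "GGATCC", enzyme: str = "BamHI") -> RestrictionFragmentSet:
    """In silico restriction digest; on circular genomes fragments run between
    successive cut positions and wrap once, so their lengths always sum to
    the genome length. An uncut circle yields one full-length fragment.

    A palindromic site (like BamHI's GGATCC) is searched on one strand only;
    a non-palindromic site is additionally searched as its reverse
    complement.
    """
    if len(site) < 4:
        raise ValueError("recognition site must be at least 4 bp")
    circular = record.topology == "circular"
    variants = set(_expand_iupac(site))
    extra = {reverse_complement(v) for v in variants} - variants
    cuts: set[int] = set()
    for v in sorted(variants | extra):
        cuts.update(_site_positions(record.seq, v, circular))
    cut_positions = sorted(cuts)
    L = record.length
    if not cut_positions:
        fragments = [L]
    elif circular:
        fragments = [
            (b - a) % L or L
            for a, b in zip(cut_positions, cut_positions[1:] + cut_positions[:1])
        ]
    else:
        bounds = [1] + cut_positions + [L + 1]
        fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return RestrictionFragmentSet(
        enzyme=enzyme, site=site.upper(), cut_positions=cut_positions, fragment_lengths=fragments
    )


def write_pairs_tsv(pairs: list[OrthologPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "query": p.query_orf,
                "subject": p.subject_orf,
                "identity_pct": p.identity_pct,
                "aln_length": p.aln_length,
                "aa_length_diff": p.aa_length_diff,
                "possible_fusion": p.possible_fusion or "",
            }
            for p in pairs
        ],
        columns=["query", "subject", "identity_pct", "aln_length", "aa_length_diff", "possible_fusion"],
    ).to_csv(path, sep="\t", index=False)


def write_parity_csv(report: ComparisonReport, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"query_rank": q, "subject_rank": s, "aa_length_diff": d}
            for (q, s), (_orf, d) in zip(report.parity_points, report.length_diffs)
        ],
        columns=["query_rank", "subject_rank", "aa_length_diff"],
    ).to_csv(path, index=False)
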