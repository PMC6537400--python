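"""Seeded generator of baculovirus-like genomes with exact ground truth.

The generator emulates the structure of an alphabaculovirus genome: a
circular, AT-rich (~60%) sequence of 50-130 kb carrying 100-150 ORFs on both
strands (including controlled overlapping pairs and a wrapping ORF),
several hr clusters of a shared ~30-bp near-palindrome with per-copy
mutations, and one CNE copy. Every planted feature is bookkept, and the
genome is post-processed so that *exactly* the planted features satisfy the
package's detection criteria: spurious open reading frames are broken by
single-codon edits, spurious near-palindromic windows by single-base edits,
always outside fixed (planted) positions and never introducing a stop codon
into a planted reading frame. Detection on a generated genome is therefore
closed over the ground truth: ORF count, hr count, repeat total and CNE
site reported downstream equal the bookkept plants.

All randomness flows through one seeded NumPy generator; regeneration from
(spec, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeRecord, SequenceInterval, reverse_complement, rotate_to_anchor
from .orf_annotation import STOP_CODONS, OrfCatalog, OrfFeature, find_orfs
from .repeat_elements import find_palindromes

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]


class SpecError(ValueError):
    """Raised when a synthetic spec cannot be realized."""


@dataclass(frozen=True)
class PlantedOrf:
    start: int  # 1-based plus-strand footprint, start <= end at design time
    end: int
    strand: str
    aa_length: int


@dataclass(frozen=True)
class PlantedHr:
    repeat_starts: tuple[int, ...]
    motif: str
    n_mutations: tuple[int, ...]


@dataclass(frozen=True)
class PlantedCne:
    start: int
    reference: str
    n_substitutions: int


@dataclass
class SyntheticSpec:
    seed: int
    genome_length: int
    gc_fraction: float = 0.40
    orfs: list[PlantedOrf] = field(default_factory=list)
    hrs: list[PlantedHr] = field(default_factory=list)
    cne: PlantedCne | None = None
    min_aa: int = 50
    palindrome_word: int = 30
    palindrome_max_mismatch: int = 3
    wrap_anchor: int | None = None  # rotate the finished genome to this base
    genome_id: str = "synthetic"


@dataclass
class GroundTruth:
    orfs: list[OrfFeature]
    hr_repeats: list[dict]
    n_hrs: int
    n_repeats: int
    repeat_total_bp: int
    cne_interval: SequenceInterval | None
    cne_identity_pct: float | None

    @property
    def catalog(self) -> OrfCatalog:
        cat = OrfCatalog(genome_id="ground_truth", orfs=list(self.orfs))
        cat.renumber()
        return cat


# --- low-level sequence sampling -------------------------------------------

def random_dna(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def mutate_sequence(
    seq: str,
    transition_rate: float,
    transversion_rate: float,
    seed: int | np.random.Generator,
) -> tuple[str, float, float]:
    """Per-site independent substitution under a transition/transversion model.

    Returns the mutated sequence and the exactly bookkept realized transition
    and transversion proportions (P, Q) over all sites.
    """
    if transition_rate < 0 or transversion_rate < 0:
        raise ValueError("rates must be non-negative")
    if transition_rate + transversion_rate > 1:
        raise ValueError("per-site rate sum exceeds 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(len(seq))
    pick = rng.integers(0, 2, size=len(seq))
    out = list(seq)
    n_ts = n_tv = 0
    for i, base in enumerate(seq):
        if base not in _COMP:
            continue
        if u[i] < transition_rate:
            out[i] = _TRANSITION[base]
            n_ts += 1
        elif u[i] < transition_rate + transversion_rate:
            out[i] = _TRANSVERSIONS[base][pick[i]]
            n_tv += 1
    n = len(seq)
    return "".join(out), n_ts / n, n_tv / n


def evolve_k2p(
    seq: str,
    transitions_per_site: float,
    transversions_per_site: float,
    seed: int | np.random.Generator,
) -> tuple[str, float]:
    """Evolve a sequence under a continuous-time Kimura 2-parameter process.

    Each site receives a Poisson number of substitution events with mean
    ``transitions_per_site + transversions_per_site`` (the expected number of
    substitutions per site, i.e. the true evolutionary distance d); each
    event is a transition or a transversion in proportion to the rates and
    is applied to the current base, so multiple hits and back-substitutions
    occur as in the model. Returns the evolved sequence and the exactly
    bookkept realized substitutions/site (event count over sites).
    """
    if transitions_per_site < 0 or transversions_per_site < 0:
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = transitions_per_site + transversions_per_site
    p_ts = transitions_per_site / total if total > 0 else 0.0
    n_events = rng.poisson(total, size=len(seq))
    out = list(seq)
    realized = 0
    for i, k in enumerate(n_events):
        if out[i] not in _COMP:
            continue
        for _ in range(k):
            if rng.random() < p_ts:
                out[i] = _TRANSITION[out[i]]
            else:
                out[i] = _TRANSVERSIONS[out[i]][rng.integers(0, 2)]
            realized += 1
    return "".join(out), realized / len(seq)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = aa.replace(out[i], "") if out[i] in aa else aa
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def make_near_palindrome(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    """A perfectly self-complementary motif of the given (even) length."""
    half = random_dna(length // 2, gc_fraction, rng)
    return half + reverse_complement(half)


# --- the generator ----------------------------------------------------------

class _Assembly:
    """Mutable genome under construction: sequence, fixed positions, and
    no-stop frame constraints for every planted coding span."""

    def __init__(self, spec: SyntheticSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.L = spec.genome_length
        self.seq = list(random_dna(self.L, spec.gc_fraction, rng))
        self.fixed = np.zeros(self.L, dtype=bool)
        self.constraints: list[tuple[int, int, str]] = []  # 0-based coding spans
        self._pos_index: dict[int, list[int]] = {}
        gc = spec.gc_fraction
        base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
        w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in _NONSTOP_CODONS])
        self._codon_p = w / w.sum()

    # -- writing plants
    def set_fixed(self, pos0: int, text: str) -> None:
        for k, b in enumerate(text):
            p = (pos0 + k) % self.L
            self.seq[p] = b
            self.fixed[p] = True

    def random_codon(self) -> str:
        return _NONSTOP_CODONS[self.rng.choice(len(_NONSTOP_CODONS), p=self._codon_p)]

    def add_constraint(self, a0: int, b0: int, strand: str) -> None:
        idx = len(self.constraints)
        self.constraints.append((a0, b0, strand))
        for s, e in self._segments(a0, b0):
            for p in range(s, e + 1):
                self._pos_index.setdefault(p, []).append(idx)

    def _segments(self, a0: int, b0: int):
        if a0 <= b0:
            return [(a0, b0)]
        return [(a0, self.L - 1), (0, b0)]

    # -- codon geometry
    def _triplets(self, a0: int, b0: int, strand: str):
        """Coding-order list of plus-position triples (each ascending in
        coding direction for '+', descending for '-')."""
        n = (b0 - a0) % self.L + 1
        out = []
        if strand == "+":
            for k in range(n // 3):
                base = (a0 + 3 * k) % self.L
                out.append(((base) % self.L, (base + 1) % self.L, (base + 2) % self.L))
        else:
            for k in range(n // 3):
                base = (b0 - 3 * k) % self.L
                out.append((base % self.L, (base - 1) % self.L, (base - 2) % self.L))
        return out

    def _codon(self, triplet, strand: str) -> str:
        if strand == "+":
            return "".join(self.seq[p] for p in triplet)
        return "".join(_COMP[self.seq[p]] for p in triplet)

    def _violations(self, ci: int):
        a0, b0, strand = self.constraints[ci]
        trips = self._triplets(a0, b0, strand)
        return [
            t
            for t in trips[:-1]  # final codon is the designated stop
            if self._codon(t, strand) in STOP_CODONS
        ]

    def _ok_locally(self, changed: list[int]) -> bool:
        """No planted frame gains an internal stop at codons covering changed positions."""
        cis = {ci for p in changed for ci in self._pos_index.get(p, [])}
        for ci in cis:
            a0, b0, strand = self.constraints[ci]
            trips = self._triplets(a0, b0, strand)
            for t in trips[:-1]:
                if any(p in t for p in changed) and self._codon(t, strand) in STOP_CODONS:
                    return False
        return True

    # -- repairs
    def repair_frame_violations(self, max_rounds: int = 500) -> None:
        for _ in range(max_rounds):
            dirty = False
            for ci in range(len(self.constraints)):
                for t in self._violations(ci):
                    free = [p for p in t if not self.fixed[p]]
                    if not free:
                        raise SpecError("planted frames conflict at fixed positions")
                    if not self._resample_codon(t, free):
                        raise SpecError("could not clear a stop in a planted frame")
                    dirty = True
            if not dirty:
                return
        raise SpecError("frame repair did not converge")

    def _resample_codon(self, triplet, free: list[int], tries: int = 200) -> bool:
        a0b0s = [self.constraints[ci] for p in triplet for ci in self._pos_index.get(p, [])]
        del a0b0s
        old = {p: self.seq[p] for p in free}
        for _ in range(tries):
            for p in free:
                self.seq[p] = _BASES[self.rng.integers(0, 4)]
            if self._ok_locally(list(triplet)):
                return True
        for p, b in old.items():
            self.seq[p] = b
        return False

    def place_stop(self, triplet, strand: str) -> bool:
        """Try to make this codon a stop without breaking planted frames."""
        free = [p for p in triplet if not self.fixed[p]]
        if not free:
            return False
        old = {p: self.seq[p] for p in triplet}
        stops = list(STOP_CODONS)
        self.rng.shuffle(stops)
        for stop in stops:
            want = stop if strand == "+" else None
            for i, p in enumerate(triplet):
                b = stop[i] if strand == "+" else _COMP[stop[i]]
                if self.fixed[p] and self.seq[p] != b:
                    break
            else:
                for i, p in enumerate(triplet):
                    self.seq[p] = stop[i] if strand == "+" else _COMP[stop[i]]
                if self._ok_locally(list(triplet)):
                    # freeze the repair so later repairs cannot revive the ORF
                    for p in triplet:
                        self.fixed[p] = True
                    return True
                for p, b in old.items():
                    self.seq[p] = b
            del want
        return False


def _plant_orfs(asm: _Assembly) -> None:
    for orf in asm.spec.orfs:
        a0, b0 = orf.start - 1, orf.end - 1
        span = b0 - a0 + 1
        if span != 3 * (orf.aa_length + 1):
            raise SpecError(f"ORF span {span} inconsistent with aa_length {orf.aa_length}")
        if orf.strand == "+":
            asm.set_fixed((a0 - 3) % asm.L, "TAA")  # upstream in-frame guard stop
            asm.set_fixed(a0, "ATG")
            asm.set_fixed(b0 - 2, "TAA")
            for k in range(1, span // 3 - 1):
                p = a0 + 3 * k
                if not any(asm.fixed[(p + j) % asm.L] for j in range(3)):
                    codon = asm.random_codon()
                    for j in range(3):
                        asm.seq[(p + j) % asm.L] = codon[j]
        else:
            asm.set_fixed((b0 + 1) % asm.L, "TTA")  # guard stop, minus frame
            asm.set_fixed(b0 - 2, "CAT")  # ATG on the minus strand
            asm.set_fixed(a0, "TTA")  # stop on the minus strand
            for k in range(1, span // 3 - 1):
                p = b0 - 3 * k - 2
                if not any(asm.fixed[(p + j) % asm.L] for j in range(3)):
                    codon = reverse_complement(asm.random_codon())
                    for j in range(3):
                        asm.seq[(p + j) % asm.L] = codon[j]
        asm.add_constraint(a0, b0, orf.strand)


def _mutate_motif(motif: str, n_mut: int, max_mismatch: int, rng: np.random.Generator) -> str:
    """Apply n_mut substitutions, re-drawing until the copy stays detectable."""
    for _ in range(100):
        out = list(motif)
        for p in rng.choice(len(motif), size=n_mut, replace=False):
            out[p] = _BASES[(rng.integers(1, 4) + _BASES.index(out[p])) % 4]
        bad = sum(
            1
            for i in range(len(out) // 2)
            if _COMP[out[i]] != out[len(out) - 1 - i]
        )
        if bad <= max_mismatch:
            return "".join(out)
    raise SpecError("could not mutate a repeat while keeping it detectable")


def _plant_hrs(asm: _Assembly) -> list[dict]:
    records = []
    for hi, hr in enumerate(asm.spec.hrs, start=1):
        for start, n_mut in zip(hr.repeat_starts, hr.n_mutations):
            copy = _mutate_motif(
                hr.motif, n_mut, asm.spec.palindrome_max_mismatch, asm.rng
            )
            asm.set_fixed(start - 1, copy)
            records.append(
                {
                    "hr_index": hi,
                    "start": start,
                    "end": start + len(copy) - 1,
                    "seq": copy,
                    "n_mutations": n_mut,
                }
            )
    return records


def _plant_cne(asm: _Assembly) -> tuple[SequenceInterval, float] | None:
    cne = asm.spec.cne
    if cne is None:
        return None
    copy = list(cne.reference)
    if cne.n_substitutions:
        for p in asm.rng.choice(len(copy), size=cne.n_substitutions, replace=False):
            copy[p] = _BASES[(asm.rng.integers(1, 4) + _BASES.index(copy[p])) % 4]
    asm.set_fixed(cne.start - 1, "".join(copy))
    identity = (len(copy) - cne.n_substitutions) / len(copy) * 100.0
    return SequenceInterval(cne.start, cne.start + len(copy) - 1), identity


def _planted_footprints(spec: SyntheticSpec) -> set[tuple[int, int, str]]:
    return {(o.start, o.end, o.strand) for o in spec.orfs}


def _break_orf(asm: _Assembly, orf: OrfFeature) -> None:
    """Kill a spurious ORF by planting stops so no stop-free run >= min_aa remains."""
    iv = orf.interval
    a0 = iv.start - 1
    b0 = iv.end - 1
    strand = iv.strand
    trips = asm._triplets(a0, b0, strand)
    step = max(asm.spec.min_aa - 5, 10)
    targets = list(range(2, len(trips) - 1, step)) or [max(len(trips) // 2, 1)]
    placed = 0
    for k in targets:
        done = False
        for dk in range(0, 15):
            for kk in (k + dk, k - dk):
                if 0 < kk < len(trips) - 1 and asm.place_stop(trips[kk], strand):
                    done = True
                    break
            if done:
                break
        placed += done
    if placed == 0:
        raise SpecError(
            f"could not break spurious ORF at ({iv.start}, {iv.end}, {strand})"
        )


def _break_palindrome(asm: _Assembly, start1: int) -> None:
    """Push a spurious near-palindromic window past the mismatch threshold."""
    w = asm.spec.palindrome_word
    s0 = start1 - 1
    window = [s0 + k for k in range(w)]
    need = asm.spec.palindrome_max_mismatch + 1
    bad = sum(
        1
        for i in range(w // 2)
        if _COMP.get(asm.seq[window[i]]) != asm.seq[window[w - 1 - i]]
    )
    pairs = [
        (window[i], window[w - 1 - i])
        for i in range(w // 2)
        if _COMP.get(asm.seq[window[i]]) == asm.seq[window[w - 1 - i]]
    ]
    asm.rng.shuffle(pairs)
    for p, q in pairs:
        if bad >= need:
            return
        for pos in (p, q):
            if asm.fixed[pos]:
                continue
            old = asm.seq[pos]
            partner = q if pos == p else p
            choices = [b for b in _BASES if b != old and _COMP[b] != asm.seq[partner]]
            asm.rng.shuffle(choices)
            broken = False
            for b in choices:
                asm.seq[pos] = b
                if asm._ok_locally([pos]):
                    asm.fixed[pos] = True  # freeze so ORF repairs keep the break
                    bad += 1
                    broken = True
                    break
                asm.seq[pos] = old
            if broken:
                break
    if bad < need:
        raise SpecError(f"could not break spurious palindrome at {start1}")


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Generate a genome realizing the spec, with exact ground truth.

    Raises :class:`SpecError` if the plants cannot be packed or the cleanup
    loops fail to converge (e.g. features denser than the genome allows).
    """
    if spec.genome_length <= 0:
        raise SpecError("genome_length must be positive")
    for orf in spec.orfs:
        if not (1 <= orf.start < orf.end <= spec.genome_length):
            raise SpecError(f"planted ORF ({orf.start}, {orf.end}) outside the genome")
    rng = np.random.default_rng(spec.seed)
    asm = _Assembly(spec, rng)
    _plant_orfs(asm)
    hr_records = _plant_hrs(asm)
    cne_result = _plant_cne(asm)
    asm.repair_frame_violations()

    planted = _planted_footprints(spec)
    planted_repeat_starts = {r["start"] for r in hr_records}

    for round_ in range(40):
        seq = "".join(asm.seq)
        record = GenomeRecord(id=spec.genome_id, seq=seq, topology="circular")
        clean = True
        if spec.orfs:
            found = find_orfs(record, min_aa=spec.min_aa, allow_wrap=True)
            fp = {
                (o.interval.start, o.interval.end, o.interval.strand) for o in found.orfs
            }
            missing = planted - fp
            if missing:
                raise SpecError(f"planted ORFs lost during assembly: {sorted(missing)[:3]}")
            for orf in found.orfs:
                key = (orf.interval.start, orf.interval.end, orf.interval.strand)
                if key not in planted:
                    _break_orf(asm, orf)
                    clean = False
        hits = find_palindromes(
            "".join(asm.seq), spec.palindrome_word, spec.palindrome_max_mismatch
        )
        for hit in hits:
            if hit.interval.start not in planted_repeat_starts:
                _break_palindrome(asm, hit.interval.start)
                clean = False
        if clean:
            break
    else:
        raise SpecError("cleanup did not converge after 40 rounds")

    record = GenomeRecord(id=spec.genome_id, seq="".join(asm.seq), topology="circular")

    truth_orfs = [
        OrfFeature(
            orf_id="",
            interval=SequenceInterval(o.start, o.end, o.strand),
            aa_length=o.aa_length,
        )
        for o in spec.orfs
    ]

    if spec.wrap_anchor is not None:
        L = spec.genome_length

        def remap(p: int) -> int:
            return (p - spec.wrap_anchor) % L + 1

        record = rotate_to_anchor(record, spec.wrap_anchor)
        truth_orfs = [
            OrfFeature(
                o.orf_id,
                SequenceInterval(remap(o.interval.start), remap(o.interval.end), o.interval.strand),
                o.aa_length,
            )
            for o in truth_orfs
        ]
        for r in hr_records:
            r["start"], r["end"] = remap(r["start"]), remap(r["end"])
        if cne_result is not None:
            iv, ident = cne_result
            cne_result = (SequenceInterval(remap(iv.start), remap(iv.end)), ident)

    truth = GroundTruth(
        orfs=truth_orfs,
        hr_repeats=hr_records,
        n_hrs=len(spec.hrs),
        n_repeats=len(hr_records),
        repeat_total_bp=sum(len(r["seq"]) for r in hr_records),
        cne_interval=cne_result[0] if cne_result else None,
        cne_identity_pct=cne_result[1] if cne_result else None,
    )
    record.features = list(truth.catalog.orfs)
    return record, truth


# --- study-scale layout -----------------------------------------------------

def design_spec(
    seed: int,
    genome_length: int = 125_477,
    n_orfs: int = 144,
    n_plus: int = 70,
    hr_cluster_sizes: tuple[int, ...] = (8, 7, 5, 4, 3, 1, 1, 1),
    n_overlap_pairs: int = 4,
    with_cne: bool = True,
    wrap_last_orf: bool = True,
    gc_fraction: float = 0.40,
    aa_range: tuple[int, int] = (60, 420),
    min_aa: int = 50,
) -> SyntheticSpec:
    """Lay out a study-scale genome: the defaults mirror a ~125-kb circular
    alphabaculovirus map with 144 ORFs (70 clockwise / 74 anticlockwise, four
    opposite-strand overlapping pairs, one wrapping through the origin),
    eight hr clusters totalling 30 near-palindromic repeats, and one CNE copy.
    """
    rng = np.random.default_rng(seed)
    if n_orfs < 1 or n_plus > n_orfs:
        raise SpecError("invalid ORF counts")

    strands = ["+"] * n_plus + ["-"] * (n_orfs - n_plus)
    rng.shuffle(strands)
    aa_lengths = rng.integers(aa_range[0], aa_range[1] + 1, size=n_orfs)
    spans = 3 * (aa_lengths + 1)

    motif = make_near_palindrome(30, gc_fraction, rng)
    n_repeats_total = int(sum(hr_cluster_sizes))

    # budget: ORF cassettes (guard + breathing room on both sides), hr
    # repeats + worst-case spacers, CNE, then inter-feature gaps
    overhead = 8
    hr_bp = sum(size * 30 + (size - 1) * 60 + 2 for size in hr_cluster_sizes)
    cne_bp = 170 if with_cne else 0
    for _ in range(50):
        fixed_bp = int(spans.sum()) + n_orfs * overhead + hr_bp + cne_bp
        slack = genome_length - fixed_bp - 30
        if slack >= 15 * (n_orfs + len(hr_cluster_sizes) + 2):
            break
        aa_lengths = rng.integers(aa_range[0], aa_range[1] + 1, size=n_orfs)
        spans = 3 * (aa_lengths + 1)
    else:
        raise SpecError("features exceed the genome: reduce counts or lengths")

    # interleave: hrs after roughly every n_orfs / n_hrs ORFs, CNE near the end
    n_slots = n_orfs + len(hr_cluster_sizes) + (1 if with_cne else 0)
    gap_weights = rng.dirichlet(np.ones(n_slots + 1))
    gaps = np.maximum((gap_weights * slack * 0.9).astype(int), 12)

    hr_after = {
        int(round((i + 1) * n_orfs / (len(hr_cluster_sizes) + 1)))
        for i in range(len(hr_cluster_sizes))
    }
    overlap_at = set()
    if n_overlap_pairs:
        candidates = [
            i
            for i in range(1, n_orfs - 1)
            if i not in hr_after
            and (i + 1) not in hr_after
            and strands[i - 1] == "+"
            and strands[i] == "-"
        ]
        rng.shuffle(candidates)
        chosen: list[int] = []
        for c in candidates:
            if all(abs(c - o) > 1 for o in chosen):
                chosen.append(c)
            if len(chosen) == n_overlap_pairs:
                break
        overlap_at = set(chosen)
    overlap_lengths = iter([158, 141, 108, 51] + [60] * max(0, n_overlap_pairs - 4))

    orfs: list[PlantedOrf] = []
    hrs: list[PlantedHr] = []
    cne = None
    pos = 10  # leave the origin clear until the final rotation
    gi = 0
    hr_iter = iter(hr_cluster_sizes)
    mut_budget = iter(rng.integers(0, 3, size=n_repeats_total))

    for i in range(n_orfs):
        pos += int(gaps[gi]); gi += 1
        span = int(spans[i])
        if i in overlap_at:
            ov = min(next(overlap_lengths), span - 12, orfs[-1].end - orfs[-1].start - 12)
            start = orfs[-1].end - ov + 1
            orfs.append(PlantedOrf(start, start + span - 1, "-", int(aa_lengths[i])))
            pos = start + span - 1 + 4  # past the minus-strand guard
        else:
            strand = strands[i]
            start = pos + 4  # room for the guard stop
            orfs.append(PlantedOrf(start, start + span - 1, strand, int(aa_lengths[i])))
            pos = start + span - 1 + 4
        if (i + 1) in hr_after:
            size = next(hr_iter)
            pos += int(gaps[gi]); gi += 1
            starts = []
            muts = []
            for _ in range(size):
                starts.append(pos + 1)
                muts.append(int(next(mut_budget)))
                pos += 30 + int(rng.integers(40, 61))
            hrs.append(PlantedHr(tuple(starts), motif, tuple(muts)))

    if with_cne:
        pos += int(gaps[gi]); gi += 1
        from .repeat_elements import load_reference_cne

        reference, _ = load_reference_cne()
        cne = PlantedCne(pos + 1, reference, n_substitutions=6)
        pos += len(reference) + 2

    if pos >= genome_length - 10:
        raise SpecError("layout overflow: features exceed the genome")

    wrap_anchor = None
    if wrap_last_orf:
        last = orfs[-1]
        wrap_anchor = (last.start + last.end) // 2

    return SyntheticSpec(
        seed=seed,
        genome_length=genome_length,
        gc_fraction=gc_fraction,
        orfs=orfs,
        hrs=hrs,
        cne=cne,
        min_aa=min_aa,
        wrap_anchor=wrap_anchor,
        genome_id=f"synthetic_{seed}",
    )


def study_scale_spec(seed: int = 1) -> SyntheticSpec:
    """The study-scale default layout (125,477 bp, 144 ORFs 70/74, 8 hrs with
    30 repeats, 1 CNE, one wrapping ORF, four overlapping pairs)."""
    return design_spec(seed)
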