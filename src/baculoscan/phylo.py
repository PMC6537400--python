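"""Kimura 2-parameter distances, neighbor-joining trees, and the
baculovirus species-demarcation rule.

The K2P model separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) and corrects for multiple hits:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Species demarcation follows the paired-distance rule used for baculovirus
taxonomy on polh/lef-8/lef-9: pairwise K2P distance below ~0.015
substitutions/site indicates the same species, above ~0.050 a distinct
species, and the band in between is ambiguous. Trees are built by classic
neighbor joining with bootstrap support from column resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
_DNA = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: too many substitutions for the correction."""


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # substitutions/site
    n_sites: int
    se: float = float("nan")  # large-sample standard error of d


@dataclass(frozen=True)
class SpeciesThresholds:
    same_species_max: float = 0.015
    distinct_species_min: float = 0.050

    def __post_init__(self) -> None:
        if not 0 < self.same_species_max < self.distinct_species_min:
            raise ValueError("require 0 < same_species_max < distinct_species_min")


def k2p_distance(a: str, b: str) -> K2PResult:
    """Kimura 2-parameter distance between two aligned nucleotide sequences.

    Columns where either sequence has a gap or ambiguous base are excluded
    pairwise (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _DNA or y not in _DNA:
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P correction undefined (P={P:.4f}, Q={Q:.4f})")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    if d == 0:
        d = 0.0  # avoid IEEE -0.0 from log(1)
    # delta-method variance (Kimura): c1 = 1/w1, c2 = 1/w2, c3 = (c1+c2)/2
    c1, c2 = 1.0 / w1, 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n
    return K2PResult(P=P, Q=Q, d=d, n_sites=n, se=math.sqrt(max(var, 0.0)))


def p_distance(a: str, b: str, alphabet: frozenset | None = None) -> float:
    """Proportion of differing sites (pairwise deletion of non-standard chars)."""
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    n = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-.*?X" or y in "-.*?X":
            continue
        n += 1
        diff += x != y
    if n == 0:
        raise ValueError("no comparable sites")
    return diff / n


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and non-negative")

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.taxa, columns=self.taxa).to_csv(path, sep="\t")


# --- trees ------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_newick(self, support: dict[frozenset, float] | None = None, _root: bool = True) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c.to_newick(support, _root=False) for c in self.children)
        label = ""
        if support is not None and not _root:
            clade = frozenset(l.name for l in self.leaves())
            if clade in support:
                label = f"{support[clade]:.0f}"
        if _root:
            return f"({inner}){label};"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class PhyloTree:
    root: TreeNode
    support: dict[frozenset, float] | None = None

    @property
    def taxa(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def to_newick(self) -> str:
        return self.root.to_newick(self.support)

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, each as the frozenset of leaf names on
        the child side (normalised to the smaller/lexicographic side)."""
        all_taxa = frozenset(self.taxa)
        parts: set[frozenset] = set()

        def walk(node: TreeNode, is_root: bool) -> None:
            for child in node.children:
                if child.children:
                    side = frozenset(l.name for l in child.leaves())
                    parts.add(_canonical_side(side, all_taxa))
                walk(child, False)

        walk(self.root, True)
        # root trifurcation edges are covered by their child clades; drop the
        # trivial full-set partition if present
        parts.discard(_canonical_side(all_taxa, all_taxa))
        return parts

    def leaf_path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def path_to(node: TreeNode, target: str) -> list[TreeNode] | None:
            if not node.children:
                return [node] if node.name == target else None
            for c in node.children:
                sub = path_to(c, target)
                if sub is not None:
                    return [node] + sub
            return None

        pa = path_to(self.root, a)
        pb = path_to(self.root, b)
        i = 0
        while i < min(len(pa), len(pb)) and pa[i] is pb[i]:
            i += 1
        return sum(n.length for n in pa[i:]) + sum(n.length for n in pb[i:])


def _canonical_side(side: frozenset, all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining (Saitou & Nei agglomeration).

    Deterministic: ties in the Q criterion break on the smallest index pair.
    Negative branch lengths are clamped to zero with the deficit moved onto
    the sister branch, preserving the pair's summed length.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negative branch to 0, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ai, aj = active[i], active[j]
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length, child_j.length = li, max(lj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for k_idx in range(m):
            if k_idx in (i, j):
                continue
            ak = active[k_idx]
            new_row[ak] = 0.5 * (D[ai, ak] + D[aj, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # final three nodes joined at an unrooted trifurcation
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


# --- supermatrix + bootstrap ------------------------------------------------

@dataclass
class Supermatrix:
    """Per-taxon concatenated aligned sequences with gene boundaries."""

    taxa: list[str]
    sequences: dict[str, str]
    gene_names: list[str]
    boundaries: list[int]  # cumulative end column (1-based) of each gene but the last

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values())))


def concat_core_genes(
    gene_sets: dict[str, dict[str, str]],
    core_list: list[str],
    missing_policy: str | None = None,
) -> Supermatrix:
    """Concatenate aligned core genes per taxon in canonical core_list order.

    Baculovirus phylogeny is conventionally built on the 37 core genes shared
    by all sequenced baculovirus genomes; any canonical gene list works here.
    With ``missing_policy='gap'`` a missing gene is padded with gaps;
    otherwise a missing gene is an error naming the taxon and gene.
    """
    taxa = sorted(gene_sets)
    if not taxa:
        raise ValueError("no taxa supplied")
    gene_lengths: dict[str, int] = {}
    for gene in core_list:
        for taxon in taxa:
            seq = gene_sets[taxon].get(gene)
            if seq is None:
                continue
            if gene in gene_lengths and len(seq) != gene_lengths[gene]:
                raise ValueError(
                    f"gene {gene!r} alignment width differs for taxon {taxon!r}"
                )
            gene_lengths.setdefault(gene, len(seq))
        if gene not in gene_lengths:
            raise ValueError(f"gene {gene!r} missing from every taxon")
    sequences = {}
    for taxon in taxa:
        parts = []
        for gene in core_list:
            seq = gene_sets[taxon].get(gene)
            if seq is None:
                if missing_policy == "gap":
                    seq = "-" * gene_lengths[gene]
                else:
                    raise ValueError(f"taxon {taxon!r} is missing core gene {gene!r}")
            parts.append(seq)
        sequences[taxon] = "".join(parts)
    cum = np.cumsum([gene_lengths[g] for g in core_list])
    return Supermatrix(
        taxa=taxa,
        sequences=sequences,
        gene_names=list(core_list),
        boundaries=[int(x) for x in cum[:-1]],
    )


def distance_matrix_from_supermatrix(
    sm: Supermatrix, metric: str = "p"
) -> DistanceMatrix:
    """Pairwise distance matrix over a supermatrix; metric 'p' (proportion of
    differing sites, suitable for amino acids) or 'k2p' (nucleotides)."""
    n = len(sm.taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sm.sequences[sm.taxa[i]], sm.sequences[sm.taxa[j]]
            d = k2p_distance(a, b).d if metric == "k2p" else p_distance(a, b)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(taxa=list(sm.taxa), values=vals)


def bootstrap_support(
    sm: Supermatrix,
    n_replicates: int = 100,
    seed: int = 0,
    metric: str = "p",
) -> PhyloTree:
    """NJ tree from the full supermatrix with per-edge bootstrap support.

    Alignment columns are resampled with replacement; support for each
    internal bipartition of the full-data tree is the percentage of
    replicate trees containing it. Deterministic under a fixed seed and
    invariant to taxon order (taxa are sorted internally).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(distance_matrix_from_supermatrix(sm, metric))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    width = sm.width
    cols = {t: np.frombuffer(sm.sequences[t].encode(), dtype="S1") for t in sm.taxa}
    for _ in range(n_replicates):
        idx = rng.integers(0, width, size=width)
        resampled = Supermatrix(
            taxa=list(sm.taxa),
            sequences={t: cols[t][idx].tobytes().decode() for t in sm.taxa},
            gene_names=sm.gene_names,
            boundaries=sm.boundaries,
        )
        try:
            rep = nj_tree(distance_matrix_from_supermatrix(resampled, metric))
        except (SaturationError, ValueError):
            continue
        found = rep.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    tree.support = {bp: c / n_replicates * 100.0 for bp, c in counts.items()}
    return tree


# --- demarcation ------------------------------------------------------------

def classify_species(
    d_single: dict[str, K2PResult | None],
    d_concat: K2PResult | None,
    thresholds: SpeciesThresholds = SpeciesThresholds(),
    saturated: bool = False,
) -> dict:
    """Species-demarcation verdict from per-gene and concatenated distances.

    The overall verdict follows the concatenated polh/lef-8/lef-9 distance;
    per-gene verdicts are reported for transparency. A saturated distance is
    classified distinct_species with a flag (divergence beyond the model's
    correctable range can only mean a distinct species).
    """

    def verdict(d: float) -> str:
        if d < thresholds.same_species_max:
            return "same_species"
        if d > thresholds.distinct_species_min:
            return "distinct_species"
        return "ambiguous"

    per_gene = {
        gene: (verdict(res.d) if res is not None else "saturated:distinct_species")
        for gene, res in d_single.items()
    }
    if saturated or d_concat is None:
        overall = "distinct_species"
        flag = True
    else:
        overall = verdict(d_concat.d)
        flag = False
    return {
        "verdict": overall,
        "saturation_flag": flag,
        "d_concat": None if d_concat is None else d_concat.d,
        "per_gene": per_gene,
        "thresholds": {
            "same_species_max": thresholds.same_species_max,
            "distinct_species_min": thresholds.distinct_species_min,
        },
    }
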