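"""End-to-end characterization runs: configuration, stage orchestration and
report-bundle assembly.

A run takes one genome (file or synthetic spec), annotates ORFs, detects hr
regions and derives their consensus, scans for the CNE, digests the genome
in silico, and — when reference genomes are supplied — maps orthologs and
computes comparative statistics. Outputs are plain-text TSV/JSON so runs
diff cleanly; a manifest records every parameter and seed so a run can be
re-derived from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .comparative import (
    comparison_report,
    insilico_rflp,
    map_orthologs,
    write_pairs_tsv,
    write_parity_csv,
)
from .genome_io import GenomeRecord, base_composition, read_genome, write_genome
from .orf_annotation import (
    OrfCatalog,
    find_orfs,
    genome_density,
    orientation_stats,
    overlap_stats,
    translate_orf,
)
from .repeat_elements import (
    annotate_consensus_mismatches,
    build_consensus,
    cluster_into_hrs,
    consensus_stats,
    find_palindromes,
    hr_genome_fraction,
    scan_cne,
    write_hr_tsv,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Every stage parameter with its documented default; JSON round-trip safe."""

    genome_path: str | None = None
    genome_format: str = "genbank"
    features_path: str | None = None
    reference_paths: list[str] = field(default_factory=list)
    output_dir: str = "baculoscan_out"
    min_aa: int = 50
    palindrome_word: int = 30
    palindrome_max_mismatch: int = 3
    hr_max_gap: int = 500
    hr_min_repeats: int = 1
    consensus_inclusion_threshold: float = 0.125
    cne_min_identity: float = 80.0
    rbh_min_identity: float = 25.0
    rbh_kmer_size: int = 5
    rflp_site: str = "GGATCC"
    rflp_enzyme: str = "BamHI"
    seed: int = 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _catalog_and_proteins(record: GenomeRecord, min_aa: int) -> tuple[OrfCatalog, dict[str, str]]:
    catalog = find_orfs(record, min_aa=min_aa)
    proteins = {o.orf_id: translate_orf(record, o) for o in catalog.orfs}
    return catalog, proteins


def run_characterize(
    config: RunConfig,
    record: GenomeRecord | None = None,
    references: list[GenomeRecord] | None = None,
) -> dict:
    """Run the full characterization and write the report bundle.

    ``record``/``references`` may be passed directly (e.g. synthetic
    genomes); otherwise they are read from the paths in ``config``. Returns
    the summary dict that is also written as ``summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "setup"
    try:
        if record is None:
            if config.genome_path is None:
                raise ValueError("no genome supplied (path or record)")
            record = read_genome(
                config.genome_path, config.genome_format, config.features_path
            )
        if references is None:
            references = [
                read_genome(p, config.genome_format) for p in config.reference_paths
            ]

        stage = "composition"
        comp = base_composition(record.seq)
        summary["genome"] = {
            "id": record.id,
            "length_bp": record.length,
            "topology": record.topology,
            **{k: round(v, 2) for k, v in comp.items()},
        }

        stage = "annotate"
        catalog, proteins = _catalog_and_proteins(record, config.min_aa)
        catalog.write_tsv(out / "orf_catalog.tsv")
        orient = orientation_stats(catalog)
        ov = overlap_stats(catalog, record.length)
        dens = genome_density(catalog, record.length)
        logger.info("annotate: %d ORFs (%d clockwise / %d anticlockwise)",
                    catalog.n_orfs, orient["n_clockwise"], orient["n_anticlockwise"])
        summary["orfs"] = {
            "n_orfs": catalog.n_orfs,
            **orient,
            "n_overlapping_orfs": ov["n_overlapping_orfs"],
            "pct_overlapping": round(ov["pct_overlapping"], 2),
            "max_overlap_bp": ov["max_overlap_bp"],
            "orfs_per_kb": round(dens["orfs_per_kb"], 4),
        }

        stage = "hrscan"
        hits = find_palindromes(
            record.seq, config.palindrome_word, config.palindrome_max_mismatch
        )
        hrs = cluster_into_hrs(hits, config.hr_max_gap, config.hr_min_repeats)
        n_repeats = sum(h.repeat_count for h in hrs)
        logger.info("hrscan: %d hr regions, %d repeats", len(hrs), n_repeats)
        consensus = None
        if n_repeats >= 2:
            consensus = build_consensus(
                [rep.seq for hr in hrs for rep in hr.repeats],
                config.consensus_inclusion_threshold,
            )
            annotate_consensus_mismatches(hrs, consensus)
            (out / "hr_consensus.fasta").write_text(
                f">hr_palindrome_consensus\n{consensus.iupac}\n"
            )
        write_hr_tsv(hrs, out / "hr_regions.tsv")
        summary["hrs"] = {
            "n_hrs": len(hrs),
            "n_repeats": n_repeats,
            "genome_fraction_pct": round(hr_genome_fraction(hrs, record.length), 3),
            "consensus": consensus.iupac if consensus else None,
            **(consensus_stats(consensus) if consensus else {}),
        }

        stage = "cne"
        match = scan_cne(record, min_identity=config.cne_min_identity)
        cne_report = None
        if match is not None:
            cne_report = {
                "start": match.interval.start,
                "end": match.interval.end,
                "strand": match.interval.strand,
                "identity_pct": round(match.identity_pct, 2),
                "clusters_found": sum(match.cluster_hits.values()),
                "cluster_hits": match.cluster_hits,
            }
        (out / "cne_report.json").write_text(json.dumps(cne_report, indent=1))
        summary["cne"] = cne_report

        stage = "rflp"
        frags = insilico_rflp(record, config.rflp_site, config.rflp_enzyme)
        (out / "rflp_fragments.tsv").write_text(
            "fragment_bp\n" + "\n".join(str(x) for x in sorted(frags.fragment_lengths, reverse=True)) + "\n"
        )
        summary["rflp"] = {
            "enzyme": frags.enzyme,
            "n_fragments": len(frags.fragment_lengths),
            "fragments_sum_bp": sum(frags.fragment_lengths),
        }

        stage = "compare"
        summary["comparisons"] = []
        for ref in references:
            ref_cat, ref_prot = _catalog_and_proteins(ref, config.min_aa)
            pairs = map_orthologs(
                catalog, proteins, ref_cat, ref_prot,
                min_identity=config.rbh_min_identity,
                kmer_size=config.rbh_kmer_size,
            )
            rep = comparison_report(pairs, catalog, ref_cat)
            write_pairs_tsv(pairs, out / f"orthologs_{ref.id}.tsv")
            write_parity_csv(rep, out / f"parity_{ref.id}.csv")
            logger.info("compare vs %s: %d shared ORFs, mean identity %.2f%%",
                        ref.id, rep.n_shared, rep.mean_identity)
            summary["comparisons"].append(
                {
                    "reference": ref.id,
                    "n_shared": rep.n_shared,
                    "mean_identity_pct": round(rep.mean_identity, 2),
                    "genome_size_diff_bp": record.length - ref.length,
                }
            )

        stage = "bundle"
        write_genome(record, out / "genome.fasta", out / "features.tsv")
        manifest = {
            "package": "baculoscan",
            "version": __version__,
            "config": asdict(config),
            "genome_id": record.id,
            "reference_ids": [r.id for r in references],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    except Exception as exc:  # partial outputs stay on disk for inspection
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return summary
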