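"""End-to-end pipeline orchestration and report assembly.

``run_pipeline`` chains the stages — annotation, classification/naming,
tandem detection, Ks dating, expression analysis — from a single flat
config, writes per-stage TSV tables plus a JSON report, and logs a run
manifest (config hash, seed, package versions). Any stage error aborts with
the stage name and removes partial outputs. Reports are deterministic:
identical inputs and config give byte-identical files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import sys
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping

from . import __version__, annotation_io, domain_classify, duplication, expression_analysis
from .models import DatingConfig, HomoeologPair, ValidationError


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run; defaults per docs/methods.md."""

    gff: str | None = None
    proteins: str | None = None
    domtbl: str | None = None
    synteny: str | None = None
    expr_tissue: str | None = None
    expr_stress: str | None = None
    out_dir: str = "polyfam_out"
    prefix: str = "Gr"
    subgenome: bool = False
    seed: int = 0
    fpkm_threshold: float = 1.0
    pseudocount: float = 0.1
    bias_log2: float = 1.0
    tandem_window_bp: int = 100_000
    tandem_max_intervening: int = 5
    ks_recent_lo: float = 0.45
    ks_recent_hi: float = 1.08
    ks_ancient_lo: float = 1.50
    ks_ancient_hi: float = 2.45
    lambda_rate: float = 5.4e-9
    kde_bandwidth: float = 0.08
    similarity_floor: float | None = None

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; unknown keys are errors."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(pathlib.Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"config line {lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValidationError(f"config line {lineno}: unknown key {key!r}")
            ftype = fields[key].type
            if raw.lower() in ("none", ""):
                kwargs[key] = None
            elif "bool" in str(ftype):
                kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
            elif "int" in str(ftype):
                kwargs[key] = int(raw)
            elif "float" in str(ftype):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw

        return cls(**kwargs)

    def dating_config(self) -> DatingConfig:
        return DatingConfig(
            lambda_rate=self.lambda_rate,
            recent_window=(self.ks_recent_lo, self.ks_recent_hi),
            ancient_window=(self.ks_ancient_lo, self.ks_ancient_hi),
            kde_bandwidth=self.kde_bandwidth,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# internal-consistency arithmetic (used by verify_report and by tests)
# ---------------------------------------------------------------------------

def counts_total(counts: Mapping[str, int]) -> int:
    """Sum of a count table (e.g. per-subfamily or per-subgenome sizes)."""
    return int(sum(counts.values()))


def recent_pair_count(total_pairs: int, ancient_pairs: int) -> int:
    """Recent-event pairs as the complement of the ancient ones."""
    return total_pairs - ancient_pairs


def group_share_percent(group_count: int, family_count: int) -> int:
    """A group's share of its subfamily, as a whole percentage."""
    if family_count <= 0:
        raise ValidationError("family_count must be positive")
    return round(100.0 * group_count / family_count)


def verify_report(report: Mapping) -> None:
    """Assert the cross-module count invariants of a pipeline report."""
    cls = report.get("classification")
    if cls:
        if counts_total(cls["subfamily_counts"]) != cls["n_family"]:
            raise ValidationError("subfamily counts do not sum to family total")
    tandem = report.get("tandem")
    if tandem:
        if sum(tandem["cluster_sizes"]) != tandem["n_tandem_genes"]:
            raise ValidationError("tandem cluster sizes do not sum to tandem gene count")
    ks = report.get("ks")
    if ks:
        ev = ks["event_counts"]
        if ev.get("recent_wgd", 0) + ev.get("ancient_hexaploidy", 0) + ev.get("unassigned", 0) != ks["n_pairs"]:
            raise ValidationError("event counts do not partition the pairs")
    stress = report.get("stress")
    if stress:
        per = [v for k, v in stress["induced"].items() if k != "union"]
        union = stress["induced"]["union"]
        if per and not (max(per) <= union <= sum(per)):
            raise ValidationError("stress union count outside [max, sum] of per-stress counts")
    expression = report.get("expression")
    if expression and "fate_counts" in expression:
        if counts_total(expression["fate_counts"]) != expression["n_pairs"]:
            raise ValidationError("fate counts do not partition the pairs")


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _write_tsv(path: pathlib.Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage enabled by the config; return (and write) the report."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    # the config digest (which hashes input paths) lives in the manifest only,
    # keeping report.json byte-identical across relocated but equivalent runs
    report: dict = {"seed": config.seed}

    def emit_tsv(name: str, header: list[str], rows: list[list]) -> None:
        path = out / name
        _write_tsv(path, header, rows)
        written.append(path)

    try:
        stage = "annotation"
        if not config.gff or not config.proteins:
            raise ValidationError("gff and proteins inputs are required")
        genes = annotation_io.parse_gff3(config.gff)
        gene_index = {g.gene_id: g for g in genes}
        proteins = annotation_io.read_fasta_proteins(config.proteins)
        report[stage] = {"n_genes": len(genes), "n_proteins": len(proteins)}

        stage = "classification"
        hits_by_protein = None
        if config.domtbl:
            hits = annotation_io.parse_domtbl(pathlib.Path(config.domtbl).read_text())
            hits_by_protein = defaultdict(list)
            for h in hits:
                hits_by_protein[h.protein_id].append(h)
        assignments, _ = domain_classify.classify_proteins(
            proteins,
            hits_by_protein=hits_by_protein,
            similarity_floor=config.similarity_floor,
        )
        named = domain_classify.name_genes(
            assignments, gene_index, config.prefix, subgenome_tag=config.subgenome
        )
        subfam_counts = Counter(a.subfamily for a in named)
        group_counts = Counter(a.group for a in named if a.group != "none")
        emit_tsv(
            "family.tsv",
            ["gene_id", "subfamily", "group", "name"],
            [[a.gene_id, a.subfamily, a.group, a.name or ""] for a in
             sorted(named, key=lambda a: a.gene_id)],
        )
        report[stage] = {
            "n_family": len(named),
            "subfamily_counts": dict(sorted(subfam_counts.items())),
            "group_counts": dict(sorted(group_counts.items())),
            "n_named": sum(1 for a in named if a.name),
        }

        stage = "tandem"
        family_ids = [a.gene_id for a in named if a.gene_id in gene_index]
        clusters = duplication.find_tandem_clusters(
            family_ids,
            gene_index,
            window_bp=config.tandem_window_bp,
            max_intervening=config.tandem_max_intervening,
        )
        emit_tsv(
            "tandem_clusters.tsv",
            ["chrom", "n_members", "span_bp", "members"],
            [[c.chrom, len(c.members), c.span_bp, ",".join(c.members)] for c in clusters],
        )
        report[stage] = {
            "n_clusters": len(clusters),
            "n_tandem_genes": sum(len(c.members) for c in clusters),
            "cluster_sizes": sorted((len(c.members) for c in clusters), reverse=True),
        }

        if config.synteny:
            stage = "ksdate"
            pairs = annotation_io.read_synteny_table(config.synteny)
            dating = config.dating_config()
            pairs = duplication.assign_events(pairs, dating)
            modes = (
                duplication.detect_ks_peaks(
                    [p.ks for p in pairs], bandwidth=config.kde_bandwidth
                )
                if len(pairs) >= 10
                else []
            )
            subfam_of = {a.gene_id: a.subfamily for a in named}
            by_subfam = duplication.count_pairs_by_subfamily(pairs, subfam_of)
            emit_tsv(
                "synteny_events.tsv",
                ["gene_a", "gene_b", "block_id", "ks", "event"],
                [[p.gene_a, p.gene_b, p.block_id, f"{p.ks:.6g}", p.event] for p in pairs],
            )
            report[stage.replace("ksdate", "ks")] = {
                "n_pairs": len(pairs),
                "n_blocks": len({p.block_id for p in pairs}),
                "modes": [round(m, 4) for m in modes[:5]],
                "mode_times_mya": [
                    round(duplication.ks_to_time(m, dating.lambda_rate), 1) for m in modes[:5]
                ],
                "event_counts": {
                    e: sum(1 for p in pairs if p.event == e)
                    for e in ("recent_wgd", "ancient_hexaploidy", "unassigned")
                },
                "pairs_by_subfamily": dict(sorted(by_subfam["total"].items())),
            }

        tissue = stress_calls = None
        if config.expr_tissue:
            stage = "expression"
            tissue = annotation_io.read_expression_matrix(config.expr_tissue)
        if config.expr_stress:
            stage = "stress"
            stress_matrix = annotation_io.read_expression_matrix(config.expr_stress)
            stress_calls = expression_analysis.call_stress_matrix(
                stress_matrix, pseudocount=config.pseudocount
            )
            by_course = defaultdict(list)
            for c in stress_calls:
                by_course[(c.gene_id, c.stress)].append(c)
            patterns = [
                expression_analysis.classify_temporal_pattern(calls)
                for calls in by_course.values()
            ]
            emit_tsv(
                "stress_calls.tsv",
                ["gene_id", "stress", "timepoint", "call", "log2fc", "testable"],
                [[c.gene_id, c.stress, c.timepoint, c.call, f"{c.log2fc:.4f}", c.testable]
                 for c in stress_calls],
            )
            emit_tsv(
                "temporal_patterns.tsv",
                ["gene_id", "stress", "pattern"],
                [[p.gene_id, p.stress, p.pattern]
                 for p in sorted(patterns, key=lambda p: (p.gene_id, p.stress))],
            )
            report["stress"] = {
                "induced": expression_analysis.summarize_stress(stress_calls),
                "pattern_counts": dict(
                    sorted(Counter(p.pattern for p in patterns).items())
                ),
            }

        if tissue is not None:
            stage = "expression"
            n_expressed = sum(
                1
                for g in tissue.genes
                if any(
                    expression_analysis.call_expressed(v, config.fpkm_threshold)
                    for v in tissue.df.loc[g]
                )
            )
            named_for_pairing = [a for a in named if a.name] or list(tissue.genes)
            pairs_h, unpaired = expression_analysis.pair_homoeologs(named_for_pairing)
            # fall back to matrix row names when the annotation holds no A/D names
            if not pairs_h:
                pairs_h, unpaired = expression_analysis.pair_homoeologs(list(tissue.genes))
            pairs_h = [p for p in pairs_h if p.a_gene in tissue.df.index and p.d_gene in tissue.df.index]
            fated = expression_analysis.classify_fates(
                pairs_h, tissue, stress_calls or []
            )
            emit_tsv(
                "homoeolog_fates.tsv",
                ["base_id", "a_gene", "d_gene", "fate"],
                [[p.base_id, p.a_gene, p.d_gene, p.fate] for p in fated],
            )
            report["expression"] = {
                "n_expressed": n_expressed,
                "n_pairs": len(fated),
                "n_unpaired": len(unpaired),
                "fate_counts": dict(sorted(Counter(p.fate for p in fated).items())),
            }

        stage = "report"
        verify_report(report)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
        written.append(report_path)
        manifest = {
            "polyfam_version": __version__,
            "python_version": sys.version.split()[0],
            "config": dataclasses.asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
        }
        manifest_path = out / "run_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return report
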