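"""Tandem-cluster detection, Ks-distribution analysis and duplication dating.

Tandem rule: two family genes are tandem-linked iff they lie on the same
chromosome, are separated by at most five intervening annotated genes
(genome-wide rank difference minus one), and their start coordinates are at
most 100 kb apart (both thresholds inclusive). Clusters are the connected
components of this relation; chains can therefore grow past pairwise limits.

Segmental pairs arrive as precomputed syntenic anchors with Ks values. The
Ks density typically shows two modes — a recent lineage whole-genome
duplication (Ks around 0.65, roughly 60 Mya at the default clock) and the
eudicot-shared paleohexaploidy (Ks around 1.9) — detected here by a Gaussian
kernel density estimate with a fixed evaluation grid.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import gaussian_kde

from .models import (
    DatingConfig,
    FamilyAssignment,
    GeneModel,
    SyntenyPair,
    TandemCluster,
    ValidationError,
)

TANDEM_WINDOW_BP = 100_000
TANDEM_MAX_INTERVENING = 5

#: chromosome-name prefixes treated as unplaced scaffolds, excluded from
#: tandem analysis (rank context is undefined off-chromosome)
SCAFFOLD_PREFIXES = ("scaffold", "contig", "unplaced")


def is_placed(chrom: str) -> bool:
    return not chrom.lower().startswith(SCAFFOLD_PREFIXES)


def tandem_linked(
    a: GeneModel,
    b: GeneModel,
    window_bp: int = TANDEM_WINDOW_BP,
    max_intervening: int = TANDEM_MAX_INTERVENING,
) -> bool:
    """The pairwise tandem rule (strand-agnostic, start-to-start distance)."""
    if a.chrom != b.chrom:
        return False
    if a.rank is None or b.rank is None:
        raise ValidationError(f"{a.gene_id}/{b.gene_id}: genes lack rank indices")
    return (abs(a.rank - b.rank) - 1) <= max_intervening and abs(a.start - b.start) <= window_bp


def find_tandem_clusters(
    family_genes: Sequence[GeneModel],
    genome_index: Mapping[str, GeneModel] | Sequence[GeneModel],
    window_bp: int = TANDEM_WINDOW_BP,
    max_intervening: int = TANDEM_MAX_INTERVENING,
) -> list[TandemCluster]:
    """Connected components of the tandem relation among family genes.

    ``genome_index`` must hold *all* annotated genes with ranks computed
    genome-wide (intervening-gene counts refer to any annotated gene, not
    only family members). Genes on unplaced scaffolds are skipped.
    Singletons are discarded; clusters come back sorted by (chrom, start),
    members in start order.
    """
    if not isinstance(genome_index, Mapping):
        genome_index = {g.gene_id: g for g in genome_index}
    located: list[GeneModel] = []
    for g in family_genes:
        gid = g if isinstance(g, str) else g.gene_id
        model = genome_index.get(gid)
        if model is None:
            raise ValidationError(f"family gene {gid!r} absent from genome index")
        if model.rank is None:
            raise ValidationError(f"{model.gene_id}: genome index lacks ranks")
        if is_placed(model.chrom):
            located.append(model)

    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in located)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in located:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.rank)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if (b.rank - a.rank) - 1 > max_intervening:
                    break  # ranks ascending: no later gene can satisfy the rule
                if tandem_linked(a, b, window_bp, max_intervening):
                    graph.add_edge(a.gene_id, b.gene_id)

    model_of = {g.gene_id: g for g in located}
    clusters = []
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        members = sorted(component, key=lambda gid: model_of[gid].start)
        starts = [model_of[m].start for m in members]
        clusters.append(
            TandemCluster(
                chrom=model_of[members[0]].chrom,
                members=tuple(members),
                span_bp=max(starts) - min(starts),
            )
        )
    clusters.sort(key=lambda c: (c.chrom, model_of[c.members[0]].start))
    return clusters


def detect_ks_peaks(
    ks_values: Sequence[float],
    bandwidth: float = 0.08,
    grid_step: float = 0.01,
) -> list[float]:
    """Mode locations of the Ks kernel density estimate, densest first.

    Gaussian KDE with an absolute bandwidth on the Ks axis, evaluated on a
    fixed grid over [0, max(ks)]. Local maxima (including grid endpoints)
    are returned in order of descending density. Deterministic for fixed
    input. Requires at least 10 values; below that a histogram should be
    inspected by eye instead.
    """
    values = np.asarray(ks_values, dtype=float)
    if values.size < 10:
        raise ValidationError(
            f"need >= 10 Ks values for density estimation (got {values.size}); "
            "inspect a histogram instead"
        )
    std = values.std(ddof=1)
    if std == 0:
        return [float(values[0])]
    kde = gaussian_kde(values, bw_method=bandwidth / std)
    grid = np.arange(0.0, values.max() + grid_step, grid_step)
    density = kde(grid)
    is_max = np.ones(len(grid), dtype=bool)
    is_max[1:] &= density[1:] > density[:-1]
    is_max[:-1] &= density[:-1] > density[1:]
    modes = grid[is_max]
    order = np.argsort(-density[is_max], kind="stable")
    return [float(m) for m in modes[order]]


def assign_event(pair: SyntenyPair, config: DatingConfig = DatingConfig()) -> str:
    """Duplication event from the pair's Ks value (window edges inclusive)."""
    lo, hi = config.recent_window
    if lo <= pair.ks <= hi:
        return "recent_wgd"
    lo, hi = config.ancient_window
    if lo <= pair.ks <= hi:
        return "ancient_hexaploidy"
    return "unassigned"


def assign_events(pairs: Iterable[SyntenyPair], config: DatingConfig = DatingConfig()) -> list[SyntenyPair]:
    out = []
    for p in pairs:
        out.append(SyntenyPair(p.gene_a, p.gene_b, p.block_id, p.ks, assign_event(p, config)))
    return out


def ks_to_time(ks: float, lambda_rate: float = 5.4e-9) -> float:
    """Divergence time in Mya: T = Ks / (2 lambda) / 1e6.

    ``lambda_rate`` is the synonymous substitution rate per site per year;
    the default maps Ks = 0.648 to 60 Mya.
    """
    if ks < 0:
        raise ValidationError(f"ks must be >= 0, got {ks}")
    if lambda_rate <= 0:
        raise ValidationError(f"lambda_rate must be > 0, got {lambda_rate}")
    return ks / (2.0 * lambda_rate) / 1e6


def count_pairs_by_subfamily(
    pairs: Iterable[SyntenyPair],
    assignments: Mapping[str, str] | Sequence[FamilyAssignment],
) -> dict[str, Counter]:
    """Pair counts per subfamily, overall and per event.

    A pair whose two genes belong to different subfamilies counts under
    ``mixed``; a pair with a gene lacking an assignment counts under
    ``unknown``. Returns {"total": Counter, "<event>": Counter, ...}; counts
    in "total" sum to the number of pairs.
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.gene_id: a.subfamily for a in assignments}
    tables: dict[str, Counter] = {"total": Counter()}
    for p in pairs:
        sa, sb = assignments.get(p.gene_a), assignments.get(p.gene_b)
        if sa is None or sb is None:
            label = "unknown"
        elif sa == sb:
            label = sa
        else:
            label = "mixed"
        tables["total"][label] += 1
        tables.setdefault(p.event, Counter())[label] += 1
    return tables
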