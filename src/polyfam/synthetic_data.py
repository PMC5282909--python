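"""Synthetic pipeline inputs with planted ground truth.

Everything downstream of raw data can be exercised offline: the generator
emits a multi-chromosome gene annotation with planted family members and
tandem clusters, proteins carrying 0-2 AP2 domains (and optional B3) with
controlled residues at the diagnostic domain columns, Ks values from a
two-component mixture (modes near 0.65 and 1.9, mirroring the recent
lineage WGD and the eudicot paleohexaploidy), and homoeolog FPKM matrices
with planted fates and stress time-courses.

All outputs are deterministic functions of the seed, and every emitted
entity is recorded in the accompanying :class:`SimTruth`.
"""
from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation_io
from .domain_classify import (
    AP2_CONSENSUS_DREB,
    AP2_CONSENSUS_ERF,
    B3_CONSENSUS,
    default_exemplars,
)
from .models import (
    AMINO_ACIDS,
    STRESS_TIMEPOINTS,
    ExpressionMatrix,
    FATES,
    GeneModel,
    ProteinRecord,
    SyntenyPair,
    ValidationError,
)

#: subfamily composition of planted (non-tandem) family genes; proportions
#: follow the relative subfamily sizes of a diploid cotton AP2/EREBP census
#: (AP2 32 : RAV 11 : DREB 80 : ERF 142)
DEFAULT_COMPOSITION = {"AP2": 0.121, "RAV": 0.042, "DREB": 0.302, "ERF": 0.535}

#: ERF group weights; B3 dominates (44% of ERFs), as in the census
ERF_GROUP_WEIGHTS = {"B1": 0.08, "B2": 0.08, "B3": 0.44, "B4": 0.10, "B5": 0.10, "B6": 0.12, "B7": 0.08}
DREB_GROUPS = ("A1", "A2", "A3", "A4", "A5", "A6")

#: default planted tandem clusters: (cluster size, subfamily); the largest
#: mirrors the eight-gene tandem run, most members sit in ERF group B3 and
#: one pair is a RAV tandem
DEFAULT_TANDEM_SPEC: tuple[tuple[int, str], ...] = (
    (8, "ERF"), (3, "ERF"), (3, "ERF"), (2, "ERF"), (2, "ERF"), (2, "RAV"),
)

DEFAULT_TISSUES = (
    "root", "stem", "leaf",
    "ovule_m3dpa", "ovule_0dpa", "ovule_3dpa",
    "fiber_5dpa", "fiber_10dpa", "fiber_20dpa", "fiber_25dpa",
)

STRESSES = ("cold", "heat", "drought")

# non-diagnostic AP2 columns untouched by any group's exemplar block
# (0-based; exemplar blocks occupy indices 20..54, diagnostics are 13 and 18)
_SAFE_AP2_POSITIONS = [i for i in range(20) if i not in (13, 18)]


@dataclass
class SimTruth:
    """Planted ground truth for one simulation; identical seed, identical outputs."""

    seed: int
    family_members: list[str] = field(default_factory=list)
    subfamily: dict[str, str] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)
    tandem_clusters: list[list[str]] = field(default_factory=list)
    ks_components: dict = field(default_factory=dict)
    pair_component: dict[str, int] = field(default_factory=dict)
    pair_subfamily: dict[str, str] = field(default_factory=dict)
    pair_fates: dict[str, str] = field(default_factory=dict)
    temporal_patterns: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def merged_with(self, other: "SimTruth") -> "SimTruth":
        out = SimTruth(seed=self.seed)
        for f in dataclasses.fields(SimTruth):
            if f.name == "seed":
                continue
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, list):
                setattr(out, f.name, a + b)
            else:
                setattr(out, f.name, {**a, **b})
        return out


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, length)])


def _mutated(rng: np.random.Generator, seq: str, n_subs: int, positions: Sequence[int]) -> str:
    out = list(seq)
    if n_subs:
        for i in rng.choice(np.asarray(positions), size=n_subs, replace=False):
            alternatives = [aa for aa in AMINO_ACIDS if aa != out[i]]
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _planted_domain(rng: np.random.Generator, subfamily: str, group: str) -> str:
    """A detectable AP2 domain carrying the planted diagnostic residues.

    DREB/ERF domains start from the matching group exemplar prototype so the
    nearest-group rule can recover the planted group; substitutions are
    confined to columns no group block touches, keeping hits above
    threshold (<= 2 substitutions of ~5 bits each against a >200-bit
    consensus score and a far lower threshold).
    """
    if subfamily in ("DREB", "ERF") and group != "none":
        base = default_exemplars()[subfamily][group][0]
    elif subfamily == "DREB":
        base = AP2_CONSENSUS_DREB
    else:
        base = AP2_CONSENSUS_ERF
    return _mutated(rng, base, int(rng.integers(0, 3)), _SAFE_AP2_POSITIONS)


def _family_protein(rng: np.random.Generator, subfamily: str, group: str) -> str:
    flank = lambda: _random_protein(rng, int(rng.integers(30, 81)))
    if subfamily == "AP2":
        d1 = _mutated(rng, AP2_CONSENSUS_ERF, int(rng.integers(0, 3)), _SAFE_AP2_POSITIONS)
        d2 = _mutated(rng, AP2_CONSENSUS_ERF, int(rng.integers(0, 3)), _SAFE_AP2_POSITIONS)
        return flank() + d1 + _random_protein(rng, int(rng.integers(40, 61))) + d2 + flank()
    if subfamily == "RAV":
        ap2 = _planted_domain(rng, "DREB", "none")
        b3 = _mutated(rng, B3_CONSENSUS, int(rng.integers(0, 3)), range(len(B3_CONSENSUS)))
        return flank() + ap2 + _random_protein(rng, int(rng.integers(30, 51))) + b3 + flank()
    return flank() + _planted_domain(rng, subfamily, group) + flank()


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    labels = sorted(weights)
    probs = np.array([weights[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def simulate_genome(
    n_chrom: int = 13,
    genes_per_chrom: int = 160,
    family_fraction: float = 0.05,
    tandem_spec: Sequence[tuple[int, str]] = DEFAULT_TANDEM_SPEC,
    seed: int = 0,
    composition: Mapping[str, float] = DEFAULT_COMPOSITION,
) -> tuple[list[GeneModel], list[ProteinRecord], SimTruth]:
    """Simulate a genome annotation and proteome with planted family genes.

    Background genes are spaced 20-40 kb apart so that any two family genes
    at least 8 ranks apart violate both tandem thresholds; planted singles
    are laid on a rank grid of step >= 9 and tandem clusters occupy
    consecutive ranks, so the planted clusters are exactly the tandem
    components of the emitted annotation. Tandem clusters count toward the
    family total. Family proteins carry their planted domain architecture;
    AP2-subfamily genes get 6-10 exons, other family genes 1-3 (mostly 1),
    mirroring the intron-poor structure of single-domain subfamilies.
    """
    rng = np.random.default_rng(seed)
    n_family = int(round(n_chrom * genes_per_chrom * family_fraction))
    n_tandem = sum(size for size, _ in tandem_spec)
    if n_tandem > n_family:
        raise ValidationError("tandem_spec exceeds the family budget")
    if len(tandem_spec) > n_chrom:
        raise ValidationError("more tandem clusters than chromosomes")
    for size, _ in tandem_spec:
        if size + 20 > genes_per_chrom:
            raise ValidationError("tandem cluster does not fit on a chromosome")

    # subfamily specs for non-tandem family genes
    n_single = n_family - n_tandem
    singles: list[tuple[str, str]] = []
    quota = {s: int(round(n_single * w)) for s, w in composition.items()}
    while sum(quota.values()) < n_single:
        quota["ERF"] += 1
    while sum(quota.values()) > n_single:
        quota[max(quota, key=quota.get)] -= 1
    for subfam, n in sorted(quota.items()):
        for _ in range(n):
            if subfam == "DREB":
                group = DREB_GROUPS[rng.integers(len(DREB_GROUPS))]
            elif subfam == "ERF":
                group = _weighted_choice(rng, ERF_GROUP_WEIGHTS)
            else:
                group = "none"
            singles.append((subfam, group))
    rng.shuffle(singles)

    truth = SimTruth(seed=seed)
    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    single_queue = list(singles)

    for c in range(n_chrom):
        chrom = f"Chr{c + 1:02d}"
        cluster = tandem_spec[c] if c < len(tandem_spec) else None
        cluster_start_idx = genes_per_chrom // 2
        cluster_idx = (
            set(range(cluster_start_idx, cluster_start_idx + cluster[0])) if cluster else set()
        )
        single_idx = []
        i = 4
        while i < genes_per_chrom:
            if not cluster_idx or min(abs(i - j) for j in cluster_idx) >= 8:
                single_idx.append(i)
            i += 9
        cluster_members: list[str] = []
        pos = 1
        for idx in range(genes_per_chrom):
            in_cluster = idx in cluster_idx
            gene_len = int(rng.integers(1000, 5001))
            gid = f"Sim{chrom}g{idx + 1:04d}"
            start, end = pos, pos + gene_len - 1
            if in_cluster:
                subfam, group = cluster[1], ("B3" if cluster[1] == "ERF" else "none")
            elif idx in single_idx and single_queue:
                subfam, group = single_queue.pop()
            else:
                subfam = None

            if subfam is None:
                n_exons = int(rng.integers(1, 9))
                seq = _random_protein(rng, int(rng.integers(150, 401)))
            else:
                n_exons = int(rng.integers(6, 11)) if subfam == "AP2" else int(rng.integers(1, 3))
                seq = _family_protein(rng, subfam, group)
                truth.family_members.append(gid)
                truth.subfamily[gid] = subfam
                truth.group[gid] = group
                if in_cluster:
                    cluster_members.append(gid)

            # partition the gene span into n_exons disjoint exons
            bounds = sorted(rng.choice(np.arange(1, gene_len), size=2 * n_exons - 2, replace=False)) if n_exons > 1 else []
            coords = [0] + [int(b) for b in bounds] + [gene_len - 1]
            exons = tuple(
                (start + coords[2 * k], start + coords[2 * k + 1]) for k in range(n_exons)
            )
            genes.append(GeneModel(gid, chrom, start, end, "+" if rng.random() < 0.5 else "-", exons))
            proteins.append(ProteinRecord(gid, gid, seq))
            gap = int(rng.integers(3000, 10001)) if in_cluster else int(rng.integers(20000, 40001))
            pos = end + 1 + gap
        if cluster_members:
            truth.tandem_clusters.append(cluster_members)

    return annotation_io.assign_ranks(genes), proteins, truth


def simulate_proteome(
    n_proteins: int = 300,
    seed: int = 0,
    composition: Mapping[str, float] = DEFAULT_COMPOSITION,
) -> tuple[list[ProteinRecord], SimTruth]:
    """Family proteins only (no genome), with planted subfamily/group truth.

    Useful for exercising the classifier at a chosen sample size without the
    cost of a full genome simulation.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed)
    labels = sorted(composition)
    probs = np.array([composition[l] for l in labels], dtype=float)
    probs /= probs.sum()
    proteins = []
    for i in range(n_proteins):
        subfam = labels[rng.choice(len(labels), p=probs)]
        if subfam == "DREB":
            group = DREB_GROUPS[rng.integers(len(DREB_GROUPS))]
        elif subfam == "ERF":
            group = _weighted_choice(rng, ERF_GROUP_WEIGHTS)
        else:
            group = "none"
        pid = f"simprot{i:04d}"
        proteins.append(ProteinRecord(pid, pid, _family_protein(rng, subfam, group)))
        truth.family_members.append(pid)
        truth.subfamily[pid] = subfam
        truth.group[pid] = group
    return proteins, truth


def simulate_ks(
    n_pairs: int = 221,
    means: tuple[float, float] = (0.65, 1.9),
    sds: tuple[float, float] = (0.12, 0.12),
    weights: tuple[float, float] = (157 / 221, 64 / 221),
    seed: int = 0,
    subfamily_weights: Mapping[str, float] | None = None,
) -> tuple[list[SyntenyPair], SimTruth]:
    """Syntenic pairs with Ks drawn from a two-component normal mixture.

    Values are truncated at zero by redrawing. The pair:block ratio follows
    the census (221 pairs in 185 blocks). Truth records the component and a
    planted subfamily per pair (default subfamily mix DREB 83 : ERF 112 :
    AP2 22 : RAV 4).
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValidationError(f"mixture weights must sum to 1, got {weights}")
    if subfamily_weights is None:
        subfamily_weights = {"DREB": 83, "ERF": 112, "AP2": 22, "RAV": 4}
    rng = np.random.default_rng(seed)
    truth = SimTruth(
        seed=seed,
        ks_components={"means": list(means), "sds": list(sds), "weights": list(weights)},
    )
    pairs: list[SyntenyPair] = []
    n_blocks = max(1, int(round(n_pairs * 185 / 221)))
    for i in range(n_pairs):
        comp = int(rng.choice(len(weights), p=np.asarray(weights) / sum(weights)))
        ks = float(rng.normal(means[comp], sds[comp]))
        while ks < 0:
            ks = float(rng.normal(means[comp], sds[comp]))
        a, b = f"ksA{i:04d}", f"ksB{i:04d}"
        block = f"block{(i * n_blocks) // max(n_pairs, 1):04d}"
        pair = SyntenyPair(gene_a=a, gene_b=b, block_id=block, ks=ks)
        pairs.append(pair)
        key = f"{pair.gene_a}|{pair.gene_b}"
        truth.pair_component[key] = comp
        subfam = _weighted_choice(rng, subfamily_weights)
        truth.pair_subfamily[pair.gene_a] = subfam
        truth.pair_subfamily[pair.gene_b] = subfam
    return pairs, truth


# --- expression archetypes -------------------------------------------------

_VEGETATIVE = ("root", "stem", "leaf")

#: stress time-course archetypes (FPKM at 1,3,6,12,24 h); responsive shapes
#: start from a control of 2.0, while stress-unresponsive genes sit below the
#: expressed threshold (0.5) so the fold-change rule's testability guard
#: applies to them, as it does to non-induced family members in real data
_COURSES = {
    "early_peak": (20.0, 14.0, 8.0, 3.0, 2.0),
    "late_peak": (2.0, 2.5, 4.0, 10.0, 24.0),
    "biphasic": (16.0, 3.0, 2.5, 6.0, 18.0),
    "flat": (0.5, 0.5, 0.5, 0.5, 0.5),
}
_RESPONSIVE_CONTROL_FPKM = 2.0
_FLAT_FPKM = 0.5


def _tissue_profile(fate: str, member: str, tissues: Sequence[str]) -> list[float]:
    is_veg = [t.startswith(_VEGETATIVE) for t in tissues]
    if fate == "non_functionalization":
        return [10.0] * len(tissues) if member == "A" else [0.0] * len(tissues)
    if fate == "dominance":
        hi, lo = (20.0, 2.0)
        return [hi if v == (member == "A") else lo for v in is_veg]
    if fate == "sub_functionalization":
        return [10.0 if v == (member == "A") else 0.0 for v in is_veg]
    return [10.0] * len(tissues)  # conserved, neo_functionalization


def simulate_expression(
    n_pairs_per_fate: int = 50,
    fates: Sequence[str] = FATES,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    noise_sigma: float = 0.0,
    seed: int = 0,
    stresses: Sequence[str] = STRESSES,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Homoeolog tissue and stress matrices with planted fates.

    One archetype per fate: silenced member (non_functionalization),
    complementary tissue occupancy (sub), class-switched bias (dominance),
    single-member stress induction (neo) and a uniform conserved profile.
    Neo-functionalized A copies cycle through the early / late / biphasic
    response shapes under a cycling stress; truth records each planted
    pattern. Noise is multiplicative lognormal (zeros stay zero).
    """
    for fate in fates:
        if fate not in FATES:
            raise ValidationError(f"unknown fate label {fate!r}")
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed)
    tissue_rows: dict[str, list[float]] = {}
    stress_rows: dict[str, list[float]] = {}
    stress_cols = [f"{s}:{t}" for s in stresses for t in (0,) + tuple(STRESS_TIMEPOINTS)]
    patterns = ("early_peak", "late_peak", "biphasic")

    for f_idx, fate in enumerate(fates):
        for i in range(n_pairs_per_fate):
            base = f"SimP{f_idx}{i:03d}"
            truth.pair_fates[base] = fate
            for member in ("A", "D"):
                gid = base + member
                tissue_rows[gid] = _tissue_profile(fate, member, tissues)
                row: list[float] = []
                for s_idx, stress in enumerate(stresses):
                    if (
                        fate == "neo_functionalization"
                        and member == "A"
                        and s_idx == i % len(stresses)
                    ):
                        shape = patterns[i % len(patterns)]
                        truth.temporal_patterns[f"{gid}|{stress}"] = shape
                    else:
                        shape = "flat"
                    if fate == "non_functionalization" and member == "D":
                        control, course = 0.0, (0.0,) * 5
                    else:
                        control = (
                            _RESPONSIVE_CONTROL_FPKM if shape != "flat" else _FLAT_FPKM
                        )
                        course = _COURSES[shape]
                    row.extend([control, *course])
                stress_rows[gid] = row
                truth.family_members.append(gid)

    def noisy(df: pd.DataFrame) -> pd.DataFrame:
        if noise_sigma == 0:
            return df
        factors = np.exp(rng.normal(0.0, noise_sigma, size=df.shape))
        return df * factors  # zeros stay zero under multiplicative noise

    tissue_df = pd.DataFrame.from_dict(tissue_rows, orient="index", columns=list(tissues))
    stress_df = pd.DataFrame.from_dict(stress_rows, orient="index", columns=stress_cols)
    return ExpressionMatrix(noisy(tissue_df)), ExpressionMatrix(noisy(stress_df)), truth


def write_simulation(
    out_dir: str | pathlib.Path,
    seed: int = 0,
    genome_kwargs: Mapping | None = None,
    ks_kwargs: Mapping | None = None,
    expression_kwargs: Mapping | None = None,
) -> SimTruth:
    """Run all three simulators and write a full input directory.

    Writes genome.gff3, proteins.fasta, synteny.tsv, expr_tissue.tsv,
    expr_stress.tsv and truth.json; returns the merged truth.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, proteins, t1 = simulate_genome(seed=seed, **(genome_kwargs or {}))
    pairs, t2 = simulate_ks(seed=seed, **(ks_kwargs or {}))
    tissue, stress, t3 = simulate_expression(seed=seed, **(expression_kwargs or {}))
    with open(out / "genome.gff3", "w") as fh:
        annotation_io.write_gff3(genes, fh)
    with open(out / "proteins.fasta", "w") as fh:
        annotation_io.write_fasta_proteins(proteins, fh)
    with open(out / "synteny.tsv", "w") as fh:
        annotation_io.write_synteny_table(pairs, fh)
    with open(out / "expr_tissue.tsv", "w") as fh:
        annotation_io.write_expression_matrix(tissue, fh)
    with open(out / "expr_stress.tsv", "w") as fh:
        annotation_io.write_expression_matrix(stress, fh)
    truth = t1.merged_with(t2).merged_with(t3)
    (out / "truth.json").write_text(truth.to_json())
    return truth
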