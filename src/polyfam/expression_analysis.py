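"""Expression calling, homoeolog bias, gene fates and stress responses.

A gene is *expressed* when FPKM > 1 (strict). Stress responses use the
twofold rule on pseudocounted FPKM ratios: r = (treatment + pc)/(control +
pc); r >= 2 is up-regulated, r < 0.5 down-regulated. Homoeolog pairs (A- and
D-subgenome copies sharing a base name) are classified per tissue as A- or
D-biased (|log2 ratio| >= 1), balanced, or silent, and each pair receives one
of five fates via a fixed decision ladder:

1. non_functionalization — exactly one member expressed anywhere;
2. neo_functionalization — both expressed, exactly one stress-induced;
3. dominance — both expressed in both tissue classes, bias direction flips
   between the vegetative and reproductive class;
4. sub_functionalization — both expressed, tissue occupancy complementary
   (each member has a tissue the other lacks);
5. conserved otherwise.
"""
from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .models import (
    STRESS_TIMEPOINTS,
    ExpressionMatrix,
    FamilyAssignment,
    HomoeologPair,
    StressCall,
    TemporalPattern,
    ValidationError,
)

EXPRESSED_FPKM = 1.0
PSEUDOCOUNT = 0.1
BIAS_LOG2 = 1.0
FOLD_UP = 2.0
FOLD_DOWN = 0.5

#: default tissue-class map for the dominance rule (configurable); tissue
#: labels are matched by prefix so staged labels like ``ovule_-3dpa`` work
DEFAULT_TISSUE_CLASSES = {
    "vegetative": ("root", "stem", "leaf"),
    "reproductive": ("ovule", "fiber"),
}


def call_expressed(fpkm: float, threshold: float = EXPRESSED_FPKM) -> bool:
    """True iff FPKM is strictly above the expression threshold."""
    if fpkm < 0:
        raise ValidationError(f"negative FPKM {fpkm}")
    return fpkm > threshold


def pair_homoeologs(
    assignments: Iterable[FamilyAssignment | str],
) -> tuple[list[HomoeologPair], list[str]]:
    """Match A/D-suffixed names into homoeolog pairs.

    Accepts named assignments or bare names. Returns (pairs, unpaired_names);
    unpaired names are the lost homoeologs. Duplicate (base, subgenome)
    names raise.
    """
    by_base: dict[str, dict[str, str]] = defaultdict(dict)
    for a in assignments:
        name = a if isinstance(a, str) else a.name
        gene_id = a if isinstance(a, str) else a.gene_id
        if not name or name[-1] not in ("A", "D") or len(name) < 2:
            continue
        base, sub = name[:-1], name[-1]
        if sub in by_base[base]:
            raise ValidationError(f"duplicate name {name!r} in subgenome {sub}")
        by_base[base][sub] = gene_id
    pairs, unpaired = [], []
    for base in sorted(by_base):
        copies = by_base[base]
        if "A" in copies and "D" in copies:
            pairs.append(HomoeologPair(base_id=base, a_gene=copies["A"], d_gene=copies["D"]))
        else:
            sub, gid = next(iter(copies.items()))
            unpaired.append(base + sub)
    return pairs, unpaired


def _fpkm(matrix: ExpressionMatrix, gene: str, condition: str) -> float:
    if gene not in matrix.df.index:
        raise ValidationError(f"gene {gene!r} missing from expression matrix")
    return matrix.value(gene, condition)


def classify_bias(
    pair: HomoeologPair,
    matrix: ExpressionMatrix,
    tissue: str,
    pseudocount: float = PSEUDOCOUNT,
    bias_log2: float = BIAS_LOG2,
) -> str:
    """Per-tissue homoeolog bias: 'A', 'D', 'balanced' or 'silent'."""
    a = _fpkm(matrix, pair.a_gene, tissue)
    d = _fpkm(matrix, pair.d_gene, tissue)
    if not call_expressed(a) and not call_expressed(d):
        return "silent"
    ratio = math.log2((a + pseudocount) / (d + pseudocount))
    if ratio >= bias_log2:
        return "A"
    if ratio <= -bias_log2:
        return "D"
    return "balanced"


def call_stress_response(
    control_fpkm: float,
    treatment_fpkm: float,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[str, float, bool]:
    """(call, log2fc, testable) for one control/treatment FPKM pair.

    r = (t + pc)/(c + pc); r >= 2 -> 'up', r < 0.5 -> 'down', else
    'unchanged'. If the gene is expressed (FPKM > 1) in neither condition
    the call is 'unchanged' and testable is False.
    """
    if control_fpkm < 0 or treatment_fpkm < 0:
        raise ValidationError("FPKM values must be >= 0")
    ratio = (treatment_fpkm + pseudocount) / (control_fpkm + pseudocount)
    log2fc = math.log2(ratio)
    if not call_expressed(control_fpkm) and not call_expressed(treatment_fpkm):
        return "unchanged", log2fc, False
    if ratio >= FOLD_UP:
        return "up", log2fc, True
    if ratio < FOLD_DOWN:
        return "down", log2fc, True
    return "unchanged", log2fc, True


def call_stress_matrix(
    matrix: ExpressionMatrix,
    stresses: Sequence[str] = ("cold", "heat", "drought"),
    timepoints: Sequence[int] = STRESS_TIMEPOINTS,
    pseudocount: float = PSEUDOCOUNT,
    sep: str = ":",
) -> list[StressCall]:
    """Fold-change calls for every gene x stress x timepoint in a matrix.

    Columns are labelled ``<stress>:<hours>`` with the 0-hour column as the
    unstressed control for that stress.
    """
    calls = []
    for gene in matrix.genes:
        for stress in stresses:
            control_col = f"{stress}{sep}0"
            if control_col not in matrix.df.columns:
                raise ValidationError(f"missing control column {control_col!r}")
            control = matrix.value(gene, control_col)
            for t in timepoints:
                col = f"{stress}{sep}{t}"
                if col not in matrix.df.columns:
                    raise ValidationError(f"missing timepoint column {col!r}")
                call, log2fc, testable = call_stress_response(
                    control, matrix.value(gene, col), pseudocount
                )
                calls.append(StressCall(gene, stress, t, call, log2fc, testable))
    return calls


def _local_maxima(values: Sequence[float]) -> list[int]:
    idx = []
    for i, v in enumerate(values):
        left = values[i - 1] if i > 0 else -math.inf
        right = values[i + 1] if i < len(values) - 1 else -math.inf
        if v > left and v > right:
            idx.append(i)
    return idx


def classify_temporal_pattern(
    calls: Sequence[StressCall],
    dip_log2: float = 0.5,
    timepoints: Sequence[int] = STRESS_TIMEPOINTS,
) -> TemporalPattern:
    """Shape label of one gene x stress time-course.

    Ladder: unresponsive (no up/down call) -> constitutive (up at every
    timepoint) -> biphasic (two local |log2fc| maxima separated by a dip of
    >= 0.5 log2 units) -> early_peak (|log2fc| argmax at 1/3/6 h) ->
    late_peak (argmax at 12/24 h). Biphasic precedes the peak-position
    rules because a second peak moves the argmax.
    """
    by_time = {c.timepoint: c for c in calls}
    missing = [t for t in timepoints if t not in by_time]
    if missing:
        raise ValidationError(f"missing timepoints {missing}")
    gene = calls[0].gene_id
    stress = calls[0].stress
    ordered = [by_time[t] for t in timepoints]
    mags = [abs(c.log2fc) for c in ordered]

    if all(c.call == "unchanged" for c in ordered):
        pattern = "unresponsive"
    elif all(c.call == "up" for c in ordered):
        pattern = "constitutive"
    else:
        maxima = _local_maxima(mags)
        biphasic = False
        for i, m1 in enumerate(maxima):
            for m2 in maxima[i + 1:]:
                dip = min(mags[m1 + 1:m2])
                if min(mags[m1], mags[m2]) - dip >= dip_log2:
                    biphasic = True
        if biphasic:
            pattern = "biphasic"
        elif timepoints[mags.index(max(mags))] in (1, 3, 6):
            pattern = "early_peak"
        else:
            pattern = "late_peak"
    return TemporalPattern(gene_id=gene, stress=stress, pattern=pattern)


def summarize_stress(calls: Iterable[StressCall]) -> dict[str, int]:
    """Per-stress counts of genes with >= 1 'up' call, plus their union."""
    genes_by_stress: dict[str, set[str]] = {}
    for c in calls:
        genes_by_stress.setdefault(c.stress, set())
        if c.call == "up":
            genes_by_stress[c.stress].add(c.gene_id)
    summary = {stress: len(genes) for stress, genes in sorted(genes_by_stress.items())}
    summary["union"] = (
        len(set().union(*genes_by_stress.values())) if genes_by_stress else 0
    )
    return summary


def _class_means(
    gene: str,
    matrix: ExpressionMatrix,
    tissue_classes: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    means = {}
    for cls, prefixes in tissue_classes.items():
        cols = [c for c in matrix.conditions if c.lower().startswith(tuple(prefixes))]
        if not cols:
            raise ValidationError(f"tissue class {cls!r} matches no tissue column")
        means[cls] = sum(matrix.value(gene, c) for c in cols) / len(cols)
    return means


def classify_fate(
    pair: HomoeologPair,
    tissue_matrix: ExpressionMatrix,
    stress_calls: Iterable[StressCall] = (),
    tissue_classes: Mapping[str, Sequence[str]] = DEFAULT_TISSUE_CLASSES,
    pseudocount: float = PSEUDOCOUNT,
    bias_log2: float = BIAS_LOG2,
) -> str:
    """Fate of one homoeolog pair; first matching rung of the ladder wins."""
    tissues = tissue_matrix.conditions
    a_on = {t for t in tissues if call_expressed(_fpkm(tissue_matrix, pair.a_gene, t))}
    d_on = {t for t in tissues if call_expressed(_fpkm(tissue_matrix, pair.d_gene, t))}

    # 1. one member silenced everywhere, the other functional
    if bool(a_on) != bool(d_on):
        return "non_functionalization"
    if not a_on and not d_on:
        return "conserved"  # both silent: no evidence of divergence

    # 2. exactly one member stress-induced
    up_genes = {c.gene_id for c in stress_calls if c.call == "up"}
    if (pair.a_gene in up_genes) != (pair.d_gene in up_genes):
        return "neo_functionalization"

    # 3. expression-level dominance flips between tissue classes
    a_means = _class_means(pair.a_gene, tissue_matrix, tissue_classes)
    d_means = _class_means(pair.d_gene, tissue_matrix, tissue_classes)
    both_on_everywhere = all(
        call_expressed(a_means[cls]) and call_expressed(d_means[cls]) for cls in tissue_classes
    )
    if both_on_everywhere:
        direction = {}
        for cls in tissue_classes:
            ratio = math.log2((a_means[cls] + pseudocount) / (d_means[cls] + pseudocount))
            direction[cls] = "A" if ratio >= bias_log2 else ("D" if ratio <= -bias_log2 else "=")
        dirs = set(direction.values())
        if dirs == {"A", "D"}:
            return "dominance"

    # 4. complementary tissue occupancy
    if (a_on - d_on) and (d_on - a_on):
        return "sub_functionalization"

    return "conserved"


def classify_fates(
    pairs: Iterable[HomoeologPair],
    tissue_matrix: ExpressionMatrix,
    stress_calls: Iterable[StressCall] = (),
    tissue_classes: Mapping[str, Sequence[str]] = DEFAULT_TISSUE_CLASSES,
) -> list[HomoeologPair]:
    """Fate-annotated copies of the pairs, with per-tissue bias filled in."""
    stress_calls = list(stress_calls)
    out = []
    for pair in pairs:
        bias = {
            t: classify_bias(pair, tissue_matrix, t) for t in tissue_matrix.conditions
        }
        fate = classify_fate(pair, tissue_matrix, stress_calls, tissue_classes)
        out.append(
            HomoeologPair(
                base_id=pair.base_id,
                a_gene=pair.a_gene,
                d_gene=pair.d_gene,
                bias_by_tissue=bias,
                fate=fate,
            )
        )
    return out
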