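"""AP2/B3 domain detection and AP2/EREBP subfamily classification.

The AP2 DNA-binding domain (~60 aa) defines the superfamily. Architecture
determines the subfamily: two complete AP2 domains -> AP2 subfamily; one AP2
plus a B3 domain -> RAV; a single AP2 domain -> DREB or ERF, split by the
diagnostic residues at aligned domain columns 14 and 19 (valine-14 marks
DREB; alanine-14 with aspartate-19 marks ERF). Anything else is binned as
an "outsider".

Detection uses a position-specific scoring matrix (PSSM) derived from the
packaged seed alignments (synthetic stand-ins built around a plausible
AP2/ERF-domain consensus; see ``data/``), scored over ungapped windows with a
calibrated score threshold. Precomputed domain-table hits can be substituted
via :func:`polyfam.annotation_io.parse_domtbl`.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .models import (
    AMINO_ACIDS,
    DomainHit,
    FamilyAssignment,
    GeneModel,
    ProteinRecord,
    ValidationError,
)

#: index of each residue in the PSSM columns; X maps to a neutral extra column
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_INDEX["X"] = len(AMINO_ACIDS)

#: 1-based diagnostic columns of the aligned AP2 domain
DIAGNOSTIC_COL_14 = 14
DIAGNOSTIC_COL_19 = 19

# Synthetic AP2/ERF-domain consensus (60 columns, ERF flavour: A14/D19).
# Built around the canonical YRG and RAYD elements of the domain; it is a
# constructed stand-in, not a curated Pfam consensus.
AP2_CONSENSUS_ERF = (
    "YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAARAMYGPRARTNFPVN"
)
#: DREB flavour of the same consensus: V at column 14, E at column 19
AP2_CONSENSUS_DREB = (
    AP2_CONSENSUS_ERF[:13] + "V" + AP2_CONSENSUS_ERF[14:18] + "E" + AP2_CONSENSUS_ERF[19:]
)

# Synthetic B3-domain consensus (50 columns), distinct composition from AP2.
B3_CONSENSUS = "FKVLTPSDVSKRLRLPEKFVRNYGDELSDTVTLEVPSGRTWHVELTKSDG"

AP2_PROFILE_LENGTH = len(AP2_CONSENSUS_ERF)
B3_PROFILE_LENGTH = len(B3_CONSENSUS)


@dataclass(frozen=True)
class DomainProfile:
    """A per-column log-odds scoring matrix for one domain type.

    ``matrix`` has shape (length, 21): one log2-odds score per column per
    amino acid, plus a neutral (zero) column for X.
    """

    name: str
    matrix: np.ndarray
    score_threshold: float

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(AMINO_ACIDS) + 1:
            raise ValidationError("PSSM must have one score per residue per column")
        if self.matrix.shape[0] == 0:
            raise ValidationError("empty profile")
        if not math.isfinite(self.score_threshold):
            raise ValidationError("threshold must be finite")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])


def build_pssm(aligned_sequences: Sequence[str], pseudocount: float = 1.0) -> np.ndarray:
    """Log2-odds PSSM from an ungapped alignment against a uniform background."""
    if not aligned_sequences:
        raise ValidationError("need at least one aligned sequence")
    length = len(aligned_sequences[0])
    if any(len(s) != length for s in aligned_sequences):
        raise ValidationError("aligned sequences must have equal length")
    counts = np.zeros((length, len(AMINO_ACIDS)))
    for seq in aligned_sequences:
        for j, aa in enumerate(seq.upper()):
            if aa in _AA_INDEX and aa != "X":
                counts[j, _AA_INDEX[aa]] += 1
    n = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (n + 20.0 * pseudocount)
    logodds = np.log2(probs / (1.0 / 20.0))
    # neutral column for X
    return np.hstack([logodds, np.zeros((length, 1))])


def _encode(sequence: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, len(AMINO_ACIDS)) for aa in sequence.upper()], dtype=np.int64)


def window_scores(sequence: str, matrix: np.ndarray) -> np.ndarray:
    """PSSM score of every ungapped window of profile length in the sequence."""
    L = matrix.shape[0]
    idx = _encode(sequence)
    n_windows = len(idx) - L + 1
    if n_windows <= 0:
        return np.zeros(0)
    scores = np.zeros(n_windows)
    for j in range(L):
        scores += matrix[j, idx[j:j + n_windows]]
    return scores


def calibrate_threshold(
    matrix: np.ndarray, n_windows: int = 10_000, seed: int = 0, margin: float = 20.0
) -> float:
    """Score threshold above the empirical null of random windows.

    Draws ``n_windows`` uniform-random windows of profile length, scores
    them, and returns the maximum observed score plus a safety margin (in
    bits). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    L = matrix.shape[0]
    draws = rng.integers(0, len(AMINO_ACIDS), size=(n_windows, L))
    scores = matrix[np.arange(L), draws].sum(axis=1)
    return float(scores.max() + margin)


def _read_packaged_alignment(filename: str) -> list[str]:
    with resources.files("polyfam.data").joinpath(filename).open() as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fasta")]


@lru_cache(maxsize=None)
def default_profiles() -> tuple[DomainProfile, ...]:
    """AP2 and B3 profiles built from the packaged synthetic seed alignments."""
    profiles = []
    for name, filename in (("AP2", "ap2_seed_synthetic.afa"), ("B3", "b3_seed_synthetic.afa")):
        matrix = build_pssm(_read_packaged_alignment(filename))
        profiles.append(
            DomainProfile(name=name, matrix=matrix, score_threshold=calibrate_threshold(matrix))
        )
    return tuple(profiles)


def scan_domains(
    protein: ProteinRecord, profiles: Sequence[DomainProfile] | None = None
) -> list[DomainHit]:
    """All non-overlapping above-threshold domain hits on one protein.

    Windows scoring at or above each profile's threshold are pooled across
    profiles and selected greedily by descending score (ties: leftmost
    first); a candidate overlapping an accepted hit is discarded. Each hit
    carries its aligned (window) string. A sequence shorter than every
    profile yields an empty list.
    """
    if profiles is None:
        profiles = default_profiles()
    candidates: list[DomainHit] = []
    for profile in profiles:
        scores = window_scores(protein.sequence, profile.matrix)
        for w in np.nonzero(scores >= profile.score_threshold)[0]:
            start = int(w) + 1
            end = start + profile.length - 1
            candidates.append(
                DomainHit(
                    protein_id=protein.protein_id,
                    domain=profile.name,
                    start=start,
                    end=end,
                    score=float(scores[w]),
                    aligned=protein.sequence[start - 1:end],
                )
            )
    candidates.sort(key=lambda h: (-h.score, h.start, h.domain))
    accepted: list[DomainHit] = []
    for hit in candidates:
        if all(hit.end < a.start or hit.start > a.end for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: h.start)
    return accepted


def is_complete(hit: DomainHit, profile_length: int, min_coverage: float = 0.9) -> bool:
    """A 'complete' domain covers >= 90% of the profile columns."""
    return hit.length >= math.ceil(min_coverage * profile_length)


def classify_subfamily(
    hits: Sequence[DomainHit],
    profile_lengths: Mapping[str, int] | None = None,
    min_coverage: float = 0.9,
) -> str:
    """Subfamily from the domain architecture of one protein.

    Two complete AP2 domains -> ``AP2``; one complete AP2 plus >= 1 B3 ->
    ``RAV``; exactly one complete AP2 and no B3 -> ``DREB_or_ERF`` (pending
    the residue split); any other retained-hit architecture -> ``outsider``.
    Total function: never raises on a hit list.
    """
    if profile_lengths is None:
        profile_lengths = {p.name: p.length for p in default_profiles()}
    n_ap2 = sum(
        1
        for h in hits
        if h.domain == "AP2" and is_complete(h, profile_lengths.get("AP2", h.length), min_coverage)
    )
    n_b3 = sum(1 for h in hits if h.domain == "B3")
    if n_ap2 == 2 and n_b3 == 0:
        return "AP2"
    if n_ap2 == 1 and n_b3 >= 1:
        return "RAV"
    if n_ap2 == 1 and n_b3 == 0:
        return "DREB_or_ERF"
    return "outsider"


def split_dreb_erf(aligned: str, profile_length: int = AP2_PROFILE_LENGTH) -> str:
    """DREB/ERF split by the diagnostic residues of the aligned AP2 domain.

    Valine at column 14 -> DREB regardless of column 19 (V14 is invariant in
    DREB proteins while E19 is not); alanine at 14 -> ERF (D19 typical but
    not required); any other residue at column 14 -> ``ambiguous``.
    Columns are 1-based over profile columns.
    """
    if len(aligned) != profile_length:
        raise ValidationError(
            f"aligned string length {len(aligned)} != profile length {profile_length}"
        )
    res14 = aligned[DIAGNOSTIC_COL_14 - 1].upper()
    if res14 == "V":
        return "DREB"
    if res14 == "A":
        return "ERF"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Group assignment (reference-guided nearest group)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def assign_group(
    aligned: str,
    exemplars: Mapping[str, Sequence[str]],
    similarity_floor: float | None = None,
) -> str:
    """Group whose exemplar domains are globally most similar to the query.

    Similarity is the mean global-alignment score (BLOSUM62, gap open -10 /
    extend -0.5) against each group's exemplars; ties break to the
    lexicographically smallest group label. If ``similarity_floor`` is set
    and the best mean score falls below it, returns ``"none"`` (the query
    cannot be allocated to an existing group).
    """
    if not exemplars:
        raise ValidationError("empty exemplar set")
    aligner = _aligner()
    best_group, best_score = None, -math.inf
    for group in sorted(exemplars):
        seqs = exemplars[group]
        if not seqs:
            raise ValidationError(f"group {group!r} has no exemplars")
        mean_score = sum(aligner.score(aligned, s) for s in seqs) / len(seqs)
        if mean_score > best_score:
            best_group, best_score = group, mean_score
    if similarity_floor is not None and best_score < similarity_floor:
        return "none"
    return best_group


@lru_cache(maxsize=None)
def default_exemplars() -> dict[str, dict[str, tuple[str, ...]]]:
    """Packaged synthetic group exemplars keyed by subfamily then group."""
    out: dict[str, dict[str, list[str]]] = {"DREB": {}, "ERF": {}}
    with resources.files("polyfam.data").joinpath("exemplars_synthetic.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            meta = dict(
                token.split("=", 1) for token in rec.description.split()[1:] if "=" in token
            )
            out[meta["subfamily"]].setdefault(meta["group"], []).append(str(rec.seq))
    return {
        subfam: {g: tuple(seqs) for g, seqs in groups.items()} for subfam, groups in out.items()
    }


# ---------------------------------------------------------------------------
# Whole-proteome classification and naming
# ---------------------------------------------------------------------------

def classify_proteins(
    proteins: Iterable[ProteinRecord],
    profiles: Sequence[DomainProfile] | None = None,
    hits_by_protein: Mapping[str, Sequence[DomainHit]] | None = None,
    exemplars: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    similarity_floor: float | None = None,
) -> tuple[list[FamilyAssignment], dict[str, list[DomainHit]]]:
    """Scan, confirm and classify a proteome.

    Proteins without any retained domain hit are not family members and are
    omitted. When ``hits_by_protein`` is given (e.g. parsed from an external
    domain table), scanning is skipped and group assignment / DREB-ERF
    splitting fall back to 'ambiguous' where no aligned string is available.
    """
    if profiles is None:
        profiles = default_profiles()
    profile_lengths = {p.name: p.length for p in profiles}
    if exemplars is None:
        exemplars = default_exemplars()

    assignments: list[FamilyAssignment] = []
    all_hits: dict[str, list[DomainHit]] = {}
    for protein in proteins:
        if hits_by_protein is not None:
            hits = list(hits_by_protein.get(protein.protein_id, []))
        else:
            hits = scan_domains(protein, profiles)
        if not hits:
            continue
        all_hits[protein.protein_id] = hits
        subfamily = classify_subfamily(hits, profile_lengths)
        group = "none"
        if subfamily == "DREB_or_ERF":
            ap2_hits = [h for h in hits if h.domain == "AP2"]
            aligned = ap2_hits[0].aligned
            subfamily = split_dreb_erf(aligned, profile_lengths["AP2"]) if aligned else "ambiguous"
            if subfamily in ("DREB", "ERF") and aligned and exemplars.get(subfamily):
                group = assign_group(aligned, exemplars[subfamily], similarity_floor)
        assignments.append(
            FamilyAssignment(gene_id=protein.gene_id, subfamily=subfamily, group=group)
        )
    return assignments, all_hits


def _natural_key(label: str) -> tuple:
    return tuple(int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", label))


_NAME_INFIX = {"AP2": "AP2-", "RAV": "RAV", "DREB": "DREB", "ERF": "ERF"}


def name_genes(
    assignments: Sequence[FamilyAssignment],
    gene_models: Mapping[str, GeneModel],
    species_prefix: str,
    subgenome_tag: bool = False,
) -> list[FamilyAssignment]:
    """Assign chromosome-ordered names within each subfamily.

    Ordinals 1..n follow chromosome label (natural sort) then start
    coordinate. With ``subgenome_tag`` on, ordinals are computed per
    subgenome (chromosome names starting with A or D) and the subgenome
    letter is appended, so homoeologs get the same base name with an A/D
    suffix. Outsiders and ambiguous proteins keep name=None. Genes without
    a gene model sort last, with a warning.
    """
    named: list[FamilyAssignment] = []
    buckets: dict[tuple, list[FamilyAssignment]] = {}
    for a in assignments:
        if a.subfamily not in _NAME_INFIX:
            named.append(FamilyAssignment(a.gene_id, a.subfamily, a.group, None))
            continue
        tag = ""
        if subgenome_tag:
            model = gene_models.get(a.gene_id)
            if model is not None and model.chrom[:1].upper() in ("A", "D"):
                tag = model.chrom[:1].upper()
        buckets.setdefault((a.subfamily, tag), []).append(a)

    for (subfamily, tag), members in buckets.items():
        def sort_key(a: FamilyAssignment):
            model = gene_models.get(a.gene_id)
            if model is None:
                warnings.warn(f"{a.gene_id}: no gene model; named last", stacklevel=2)
                return (1, (), 0, a.gene_id)
            return (0, _natural_key(model.chrom), model.start, a.gene_id)

        for ordinal, a in enumerate(sorted(members, key=sort_key), start=1):
            name = f"{species_prefix}{_NAME_INFIX[subfamily]}{ordinal}{tag}"
            named.append(FamilyAssignment(a.gene_id, a.subfamily, a.group, name))

    names = [a.name for a in named if a.name]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate gene names generated")
    return named
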