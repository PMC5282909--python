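"""Regenerate the packaged synthetic seed alignments and group exemplars.

The fixtures under src/polyfam/data/ are synthetic stand-ins constructed
around the package's AP2/ERF- and B3-domain consensus strings; this script
rebuilds them deterministically (fixed seed). Run from the repository root:

    python scripts/build_seed_fixtures.py
"""
from __future__ import annotations

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from polyfam.domain_classify import (  # noqa: E402
    AP2_CONSENSUS_DREB,
    AP2_CONSENSUS_ERF,
    B3_CONSENSUS,
)
from polyfam.models import AMINO_ACIDS  # noqa: E402

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "polyfam" / "data"
SEED = 20170131  # fixed; fixtures are committed, this script only regenerates them

# 0-based indices of the diagnostic AP2 columns (14 and 19, 1-based)
DIAG = (13, 18)


def mutate(rng: np.random.Generator, seq: str, n_subs: int, exclude: tuple[int, ...]) -> str:
    positions = [i for i in range(len(seq)) if i not in exclude]
    chosen = rng.choice(positions, size=n_subs, replace=False)
    out = list(seq)
    for i in chosen:
        alternatives = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def write_fasta(path: pathlib.Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def build_ap2_seed(rng: np.random.Generator) -> list[tuple[str, str]]:
    records = []
    dreb_19 = ["E", "E", "A", "L"]  # V14 is invariant in DREB; E19 is not
    for i in range(20):
        records.append((f"ap2_seed_erf_{i+1}", mutate(rng, AP2_CONSENSUS_ERF, 6, DIAG)))
    for i in range(20):
        seq = list(mutate(rng, AP2_CONSENSUS_DREB, 6, DIAG))
        seq[18] = dreb_19[i % len(dreb_19)]
        records.append((f"ap2_seed_dreb_{i+1}", "".join(seq)))
    return records


def build_b3_seed(rng: np.random.Generator) -> list[tuple[str, str]]:
    return [(f"b3_seed_{i+1}", mutate(rng, B3_CONSENSUS, 5, ())) for i in range(30)]


def build_exemplars(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Three exemplar domains per group; groups differ at 5 dedicated columns.

    Each group's prototype mutates a disjoint 5-column block (columns 21+,
    clear of the diagnostic columns), so prototypes of different groups are
    >= 10 substitutions apart; within-group variants add one extra
    substitution each.
    """
    records = []
    specs = [("DREB", AP2_CONSENSUS_DREB, [f"A{i}" for i in range(1, 7)]),
             ("ERF", AP2_CONSENSUS_ERF, [f"B{i}" for i in range(1, 8)])]
    for subfamily, consensus, groups in specs:
        for k, group in enumerate(groups):
            block = range(20 + 5 * k, 20 + 5 * k + 5)
            proto = list(consensus)
            for i in block:
                alternatives = [aa for aa in AMINO_ACIDS if aa != proto[i]]
                proto[i] = alternatives[rng.integers(len(alternatives))]
            proto = "".join(proto)
            records.append((f"{group}_1 subfamily={subfamily} group={group}", proto))
            for j in (2, 3):
                extra = [i for i in range(55, 60) if i not in DIAG]
                pos = extra[(k + j) % len(extra)]
                variant = list(proto)
                alternatives = [aa for aa in AMINO_ACIDS if aa != variant[pos]]
                variant[pos] = alternatives[rng.integers(len(alternatives))]
                records.append(
                    (f"{group}_{j} subfamily={subfamily} group={group}", "".join(variant))
                )
    return records


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    write_fasta(DATA / "ap2_seed_synthetic.afa", build_ap2_seed(rng))
    write_fasta(DATA / "b3_seed_synthetic.afa", build_b3_seed(rng))
    write_fasta(DATA / "exemplars_synthetic.fasta", build_exemplars(rng))
    print(f"fixtures written to {DATA}")


if __name__ == "__main__":
    main()
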