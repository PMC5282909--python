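"""Classify the simulated proteome into AP2/EREBP subfamilies and groups.

Scans every protein for AP2 and B3 domains, applies the architecture rules
(two AP2 -> AP2 subfamily; AP2 + B3 -> RAV; single AP2 split into DREB/ERF
by the V14/A14 diagnostic residue), assigns nearest-exemplar groups, and
names genes in chromosome order. Writes results/family.tsv.
"""
import pathlib
import sys
from collections import Counter

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from polyfam import annotation_io, domain_classify  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "results" / "sim"
    genes = {g.gene_id: g for g in annotation_io.parse_gff3(str(sim / "genome.gff3"))}
    proteins = annotation_io.read_fasta_proteins(str(sim / "proteins.fasta"))
    assignments, hits = domain_classify.classify_proteins(proteins)
    named = domain_classify.name_genes(assignments, genes, species_prefix="Sim")

    out = ROOT / "results" / "family.tsv"
    with open(out, "w") as fh:
        fh.write("gene_id\tsubfamily\tgroup\tname\tn_domains\n")
        for a in sorted(named, key=lambda a: a.gene_id):
            fh.write(f"{a.gene_id}\t{a.subfamily}\t{a.group}\t{a.name or ''}\t"
                     f"{len(hits.get(a.gene_id, []))}\n")

    counts = Counter(a.subfamily for a in named)
    groups = Counter(a.group for a in named if a.group != "none")
    print(f"{len(proteins)} proteins scanned; {len(named)} family members confirmed")
    print(f"  subfamilies: {dict(sorted(counts.items()))} (sum {sum(counts.values())})")
    b3 = groups.get("B3", 0)
    print(f"  largest ERF group is B3 with {b3} genes "
          f"({100 * b3 / max(counts['ERF'], 1):.0f}% of ERFs)")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
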