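"""Call stress responses and temporal patterns over the time-courses.

Applies the twofold rule at each of 1, 3, 6, 12 and 24 h against the 0 h
control for cold, heat and drought, summarizes per-stress induced gene
counts with their union, and labels each responsive time-course as
early-peak, late-peak, biphasic or constitutive. Writes
results/stress_calls.tsv and results/temporal_patterns.tsv.
"""
import pathlib
import sys
from collections import Counter, defaultdict

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from polyfam import annotation_io, expression_analysis as ea  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "results" / "sim"
    stress = annotation_io.read_expression_matrix(str(sim / "expr_stress.tsv"))
    calls = ea.call_stress_matrix(stress)

    out1 = ROOT / "results" / "stress_calls.tsv"
    with open(out1, "w") as fh:
        fh.write("gene_id\tstress\ttimepoint\tcall\tlog2fc\ttestable\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.stress}\t{c.timepoint}\t{c.call}\t"
                     f"{c.log2fc:.4f}\t{c.testable}\n")

    by_course = defaultdict(list)
    for c in calls:
        by_course[(c.gene_id, c.stress)].append(c)
    patterns = [ea.classify_temporal_pattern(v) for v in by_course.values()]
    out2 = ROOT / "results" / "temporal_patterns.tsv"
    with open(out2, "w") as fh:
        fh.write("gene_id\tstress\tpattern\n")
        for p in sorted(patterns, key=lambda p: (p.gene_id, p.stress)):
            fh.write(f"{p.gene_id}\t{p.stress}\t{p.pattern}\n")

    summary = ea.summarize_stress(calls)
    responsive = Counter(p.pattern for p in patterns if p.pattern != "unresponsive")
    print(f"induced genes: {summary}")
    print(f"responsive time-course shapes: {dict(sorted(responsive.items()))}")
    print(f"wrote {out1.relative_to(ROOT)}, {out2.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
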