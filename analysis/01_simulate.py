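"""Generate the default synthetic study inputs.

Writes a 13-chromosome annotation (160 genes each, 5% planted AP2/EREBP
family members, six tandem clusters up to eight genes), a 221-pair syntenic
table with two-component Ks values, and homoeolog tissue/stress FPKM
matrices (50 pairs per fate class) under results/sim/.
"""
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from polyfam.synthetic_data import write_simulation  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    out = ROOT / "results" / "sim"
    truth = write_simulation(out, seed=SEED)
    n_clusters = len(truth.tandem_clusters)
    print(f"wrote {out.relative_to(ROOT)} (seed {SEED})")
    print(f"  planted family genes : {len([g for g in truth.subfamily])}")
    print(f"  planted tandem runs  : {n_clusters} "
          f"(sizes {sorted((len(c) for c in truth.tandem_clusters), reverse=True)})")
    print(f"  syntenic pairs       : {len(truth.pair_component)}")
    print(f"  homoeolog pairs      : {len(truth.pair_fates)} (5 fate classes)")


if __name__ == "__main__":
    main()
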