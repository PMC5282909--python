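# polyfam

Genome-wide analysis of AP2/EREBP-like transcription-factor superfamilies in
plant genomes, with a focus on polyploids: domain-architecture
classification, duplication-driven family expansion, and homoeolog
expression divergence under abiotic stress.

The package is aimed at comparative genomicists studying gene-family
expansion in diploid/allotetraploid species pairs (the motivating system is
*Gossypium*: the diploid D-genome and the allotetraploid A/D genome of
upland cotton). Every stage can be exercised offline on synthetic inputs
with planted ground truth.

## What it computes

**Family classification.** Proteins are scanned for the ~60-aa AP2
DNA-binding domain and the B3 domain with packaged PSSMs (ungapped window
scoring against a calibrated null threshold); precomputed HMMER-style domain
tables are accepted as an alternative. Architecture sets the subfamily:

| architecture | subfamily |
|---|---|
| 2 complete AP2 | AP2 |
| 1 AP2 + B3 | RAV |
| 1 AP2 | DREB or ERF |
| anything else | outsider |

Single-domain proteins are split by the diagnostic residues of the aligned
domain: valine at column 14 marks DREB (V14 is invariant there, E19 is
not); alanine-14 (typically with aspartate-19) marks ERF. DREB genes are
then placed into groups A1–A6 and ERF genes into B1–B7 by highest mean
global-alignment similarity to packaged group exemplars, and genes are named
in chromosome order (`GrDREB1…`, with an A/D suffix per subgenome in
allotetraploid mode).

**Duplication analysis.** Two family genes are *tandem duplicates* when they
lie on one chromosome with at most 5 intervening annotated genes and at most
100 kb between starts (both inclusive); clusters are connected components of
this relation, so chains of eight genes can form. Segmental (syntenic)
paralog pairs arrive with Ks values; the pipeline finds Ks density modes by
Gaussian KDE, assigns each pair to the recent whole-genome duplication
(Ks ∈ [0.45, 1.08]) or the ancient eudicot hexaploidy (Ks ∈ [1.50, 2.45]),
and dates events with the molecular clock T = Ks/(2λ), λ = 5.4×10⁻⁹
substitutions · site⁻¹ · yr⁻¹ by default (Ks ≈ 0.65 → ≈ 60 Mya).

**Expression analysis.** A gene is expressed when FPKM > 1. Stress
responses use the twofold rule on pseudocounted ratios
r = (t + 0.1)/(c + 0.1): r ≥ 2 is up, r < 0.5 is down, with time-courses
over 1, 3, 6, 12 and 24 h labelled early-peak, late-peak, biphasic,
constitutive or unresponsive. A/D homoeolog pairs get per-tissue bias calls
(|log₂ ratio| ≥ 1) and one of five fates through a fixed ladder:
non-functionalization (one copy silenced) → neo-functionalization (one copy
stress-induced) → expression-level dominance (bias flips between vegetative
and reproductive tissue classes) → sub-functionalization (complementary
tissue occupancy) → conserved.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated data
(`python analysis/01_simulate.py` through `05_stress_response.py`), writing
tables under `results/`. Equivalently from the shell:

```
polyfam simulate --out sim --seed 1
polyfam classify --proteins sim/proteins.fasta --gff sim/genome.gff3 --prefix Sim --out family.tsv
polyfam tandem   --gff sim/genome.gff3 --family family.tsv --out tandem.tsv
```

On the default study (13 chromosomes × 160 genes, seed 1) the drivers print:

```
2080 proteins scanned; 104 family members confirmed
  subfamilies: {'AP2': 10, 'DREB': 25, 'ERF': 63, 'RAV': 6} (sum 104)
tandem: 20 genes in 6 clusters (largest 8)
segmental: 221 pairs in 185 blocks
  Ks modes at 0.65, 1.94 -> 60 Mya, 180 Mya
  events: {'recent_wgd': 151, 'ancient_hexaploidy': 68, 'unassigned': 2}
250 homoeolog pairs (0 unpaired)
  planted-fate recovery: 250/250
induced genes: {'cold': 17, 'drought': 16, 'heat': 17, 'union': 50}
```

Reading: all 104 planted family members are confirmed and correctly
subclassified from sequence alone; the six planted tandem runs are recovered
exactly; the two Ks modes sit at the planted mixture means, and the recent
mode dates to ~60 Mya under the default clock; every planted homoeolog fate
is recalled on the noise-free panel; and per-stress induced counts never
exceed their union, which never exceeds their sum.

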