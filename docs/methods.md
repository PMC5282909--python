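# Methods

This note documents the models and procedures implemented in polyfam, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices that keep every run deterministic.

## Domain detection and family confirmation

Family membership is decided by presence of the AP2 DNA-binding domain
(~60 aa). Detection uses a position-specific scoring matrix per domain type
(AP2, B3): log₂-odds of per-column residue frequencies against a uniform
background, with +1 pseudocounts. The matrices are derived at load time from
the seed alignments packaged under `src/polyfam/data/`. These seed
alignments are **synthetic stand-ins**: forty 60-column AP2 sequences (half
ERF-flavoured with A14/D19, half DREB-flavoured with V14 and a variable
column 19) and thirty 50-column B3 sequences, generated as controlled
mutants of a constructed consensus built around the canonical YRG and RAYD
elements of the domain. They are not a curated Pfam alignment, and
classification of real proteomes should substitute a real seed alignment (or
supply precomputed HMMER-style domain-table hits, which the pipeline accepts
directly).

Scoring is ungapped: every window of profile length is scored and windows at
or above the profile threshold become candidate hits, selected greedily by
descending score with overlaps discarded. The aligned string of a hit is the
window itself, which makes profile-column indexing (needed for the
diagnostic residues) trivial and exact. A gapped refinement was considered
and rejected: on domains without long indels it changes no call, and it
would complicate the column-14/19 mapping that the DREB/ERF split depends
on.

The score threshold is calibrated, per profile, as the maximum score of
10,000 uniform-random windows (fixed calibration seed 0) plus a 20-bit
safety margin. The consensus scores ≈ 215 bits and each planted substitution
costs ≈ 5 bits, so planted domains with up to ~25 substitutions stay
detectable while the empirical null (max ≈ −24 bits for AP2) is cleared by a
wide margin; the margin makes false positives on megabase-scale proteomes
vanishingly unlikely.

A domain is *complete* when its hit covers ≥ 90% of profile columns; the
completeness bar matters only for externally supplied (possibly truncated)
hits, since internal hits are full windows. Architecture rules: two complete
AP2 → AP2 subfamily; one complete AP2 plus any B3 → RAV; exactly one
complete AP2 → DREB/ERF, split by residues at aligned columns 14 and 19
(1-based over profile columns): V14 → DREB regardless of column 19, A14 →
ERF, anything else → ambiguous (reported, never silently binned). Any other
architecture is an "outsider".

## Group assignment

The reference analysis places DREB genes into groups A1–A6 and ERF genes
into B1–B7 with a phylogeny; polyfam replaces this with a deterministic
nearest-group rule: mean global-alignment score (BLOSUM62, gap open −10,
extend −0.5) against each group's exemplar domains, highest mean wins, ties
broken to the lexicographically smallest label. The packaged exemplars are
synthetic (three per group, each group's prototype mutated at a dedicated
5-column block, so prototypes are ≥ 10 substitutions apart). An optional
similarity floor returns "none" for queries that match no group well — the
analogue of the unallocatable-gene problem that motivated group B7 — but no
default floor is set because no principled value exists without a reference
phylogeny.

## Tandem duplication

Two family genes are tandem-linked iff they are on the same chromosome,
separated by ≤ 5 intervening annotated genes, and ≤ 100,000 bp apart.
Numerical choices: distance is start-to-start and both thresholds are
inclusive; intervening genes are counted on the genome-wide rank order (all
annotated genes, not just family members), with ranks assigned per
chromosome by ascending start, ties broken by end then gene id. Clusters
are connected components of the link relation, which is what allows runs of
eight genes even though no single pair spans them. Genes on unplaced
scaffolds are parsed but excluded from tandem analysis, since rank context
is undefined there. The pairwise scan breaks out of the inner loop as soon
as the rank gap alone exceeds the limit, giving near-linear behaviour per
chromosome; tests verify equivalence against a brute-force all-pairs oracle.

## Ks analysis and dating

Mode detection uses a Gaussian KDE with an absolute bandwidth of 0.08 on the
Ks axis (passed to `scipy.stats.gaussian_kde` as a factor of the sample
standard deviation), evaluated on a fixed grid of step 0.01 over
[0, max Ks]; local maxima (including grid endpoints) are returned in
descending density order. The bandwidth/grid pair resolves two modes
separated by ~1.2 Ks units with component sd ≈ 0.12, the structure of the
motivating dataset, while suppressing sampling wiggles at n ≈ 200–1000. At
least 10 values are required; below that the estimator refuses and advises
histogram inspection.

Event windows default to Ks ∈ [0.45, 1.08] for the recent lineage WGD and
[1.50, 2.45] for the eudicot-shared paleohexaploidy, edges inclusive;
everything else is unassigned. Dating is T = Ks/(2λ)/10⁶ Mya. The default
λ = 5.4×10⁻⁹ substitutions·site⁻¹·yr⁻¹ maps the recent-peak midpoint
(Ks ≈ 0.65) to ≈ 60 Mya. No single λ reproduces both a 60-Mya recent peak
and a ~131-Mya ancient peak from these Ks ranges, so λ is exposed per call
and per config rather than hidden.

## Expression rules

Expressed means FPKM strictly > 1. All FPKM ratios add a pseudocount of 0.1
to numerator and denominator — division by a zero control is otherwise
undefined — and the twofold rule is evaluated on the pseudocounted ratio:
r ≥ 2 up (boundary inclusive), r < 0.5 down. Consequences worth knowing:
with the pseudocount, a 2→4 FPKM change is r = 1.95 and is *not* called up;
the up/down thresholds are exact reciprocals only at pseudocount 0 (a
property the tests verify there). Calls on genes expressed in neither
condition are returned as unchanged with a `testable=False` flag rather than
dropped, so downstream tallies can audit them.

Temporal patterns are a total function of the five-point time-course
(1, 3, 6, 12, 24 h): unresponsive (no call anywhere) → constitutive (up at
all five) → biphasic (two local |log₂FC| maxima separated by a dip ≥ 0.5
log₂ units) → early peak (argmax at 1–6 h) → late peak (argmax at 12–24 h).
Biphasic is tested before the peak-position rules because a second peak
moves the argmax; with that order each course receives exactly one label.

Homoeolog bias per tissue: A if log₂((a+0.1)/(d+0.1)) ≥ 1, D if ≤ −1,
silent if neither copy is expressed, balanced otherwise.

## The fate ladder

Fates are assigned by the first matching rung: (1) non-functionalization —
exactly one copy expressed in at least one tissue, the other in none;
(2) neo-functionalization — both copies tissue-expressed and exactly one
has ≥ 1 up-regulation call in the stress panel; (3) dominance — both copies
expressed in both tissue classes (vegetative = root/stem/leaf,
reproductive = ovule*/fiber*, configurable) and the class-level bias
direction flips between classes; (4) sub-functionalization — both copies
expressed, each in at least one tissue where the other is not;
(5) conserved. Two deliberate choices: the dominance rung requires both
copies expressed in *both* classes — without that, any complementary
(sub-functionalized) pair would flip class-level bias trivially and rung 4
would be unreachable; and "partitioned ancestral function" is
operationalized as complementary tissue occupancy rather than a 0.5
expression ratio, because occupancy is robust to sequencing depth. Pairs
silent everywhere fall through to conserved: absence of expression is no
evidence of divergence.

## Synthetic data

The generator plants truth for every stage and is fully determined by its
seed.

*Genome* (defaults: 13 chromosomes × 160 genes, 5% family genes): gene
spacing is drawn uniformly from 20–40 kb, so two family genes ≥ 8 ranks
apart always violate both tandem thresholds; planted singles sit on a rank
grid of step 9 and tandem clusters occupy consecutive ranks with 3–10 kb
spacing. The planted clusters are therefore *provably* the exact tandem
components of the emitted annotation — recovery failures indicate bugs, not
bad luck. The default cluster spec (8+3+3+2+2 ERF/B3 genes plus one RAV
pair) mirrors the observed pattern that tandem expansion concentrates in
ERF group B3 with a small RAV contribution. Family proteins embed their
planted domains (mutants of the group exemplar, ≤ 2 substitutions confined
to columns no group block uses) in random flanks; AP2-subfamily genes get
6–10 exons and other family genes 1–2, reproducing the intron-rich AP2 /
intron-poor DREB-ERF-RAV contrast. Subfamily composition follows the
relative sizes of the motivating census (AP2 32 : RAV 11 : DREB 80 :
ERF 142, scaled).

*Ks* (default 221 pairs in ~185 blocks): two-component normal mixture with
means 0.65 and 1.9, sd 0.12, weights 157:64, truncated at zero by
redrawing — the recent:ancient pair ratio and mode positions of the
motivating dataset.

*Expression* (default 50 pairs per fate class, 10 tissues, 3 stresses ×
{0,1,3,6,12,24} h): one archetype per fate (silenced copy; complementary
occupancy; class-switched 20-vs-2 bias; single-copy stress induction
cycling through early/late/biphasic course shapes with control FPKM 2).
Stress-unresponsive genes are set to FPKM 0.5 — below the expressed
threshold — so the testability guard covers them, as it does for the many
non-induced family members in real stress RNA-seq. Noise is multiplicative
lognormal (zeros stay zero).

What the simulation does **not** emulate: real sequence evolution (no codon
models or indels), annotation noise (no split/merged gene models),
unplaced scaffolds, mapping or quantification error beyond lognormal FPKM
noise, and genuinely ambiguous domain architectures. Passing the recovery
suites therefore demonstrates that the rules are implemented exactly as
specified and are robust to moderate expression noise — not that the
pipeline's thresholds are optimal for any particular real genome.

## Problem sizes and determinism

Default scales (2,080 genes, 221–1,000 Ks pairs, 250 homoeolog pairs) keep
the full test suite and the acceptance script within seconds on one CPU
while leaving every statistical structure detectable; they are scaled-down
analogues of the motivating genome, not attempts to reproduce its absolute
counts, which depend on external genome and RNA-seq resources. All
randomness flows through `numpy.random.default_rng(seed)`; KDE grids, tie
breaks (lexicographic), and sort orders (chromosome natural order, then
start, then id) are fixed, so identical seeds give byte-identical outputs
end to end.

## Known limitations

- The PSSM scorer is ungapped; a domain interrupted by a long insertion
  would be missed or scored as incomplete. Supplying external domain-table
  hits is the supported path for such proteins.
- Group assignment is only as good as the exemplar set; with the packaged
  synthetic exemplars it validates the rule, not real group biology.
- The B7-style "no existing group" decision needs a similarity floor that
  only a reference phylogeny can justify; none is set by default.
- Subgenome tagging keys on the first letter of the chromosome name
  (A*/D*); other naming schemes need renaming upstream.
- The fate ladder is evidence-priority-ordered and deterministic; pairs with
  genuinely mixed evidence (e.g. dominance *and* private stress induction)
  take the earlier rung by construction.
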