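# Methods

`talclone` reconstructs the subclonal architecture of *STIL-TAL1*+
T-cell acute lymphoblastic leukaemia from single-cell measurements.
This note documents the models, the tunable parameters, what the
synthetic-data generator does and does not emulate, the numerical
choices, and the known limitations.

## Character model and clone trees

Every tracked lesion is an ordered, irreversible character:

* sequence markers (fusion, SNV, indel) step wild type → heterozygous →
  homozygous (states 0 → 1 → 2), one unit of evolutionary change per
  step;
* copy-number markers step 2 → 1 → 0 retained copies, one unit per
  lost copy.

Internally states are mapped to *change units* (distance from the
germline state), making irreversibility a monotonicity condition along
every root-to-leaf path. Reversals carry infinite cost — back-mutation
of an indel or re-gain of a deleted allele is biologically implausible
in this setting — while independent parallel origins of lesions in the
same gene on divergent branches are allowed, which is how reiterative
driver inactivation (e.g. multiple PTEN indels) is represented.

Maximum parsimony trees are found by exhaustive search over rooted
binary topologies on the observed subclones (feasible because cases
carry at most ~8 subclones; the implementation refuses more than 10).
For a fixed topology the optimal ancestral genotypes under this cost
model are unique: each internal node takes the component-wise minimum
(in units) of its children. Zero-change edges are then contracted, so
observed genotypes may sit at internal positions and *inferred*
ancestors (unobserved genotypes) appear only where they reduce the
score. All co-optimal trees are kept, deduplicated by their multiset of
(parent-genotype, child-genotype) edges and returned in canonical sort
order; equally parsimonious histories are a real feature of these data
(the 6116-style configuration yields exactly two). Branch lengths equal
the number of changes on the edge, and their sum equals the tree's
parsimony score by construction.

An independent oracle, `brute_force_min_score`, enumerates topologies
through a different recursion (leaf-set bipartition rather than
stepwise insertion) and scores each with a generic Sankoff dynamic
program over all ancestral states; it is used only for cross-checking
(≤ 7 subclones).

### Bootstrap

Supports are computed by resampling **cells** with replacement,
re-collapsing and re-inferring per replicate; a node's support is the
percentage of replicates whose best tree contains a clade with the
same set of observed genotypes. Cells rather than markers are
resampled because panels are small (5–10 markers, which would make
character resampling degenerate) and the dominant sampling noise is in
clone frequencies.

## qPCR simulation and genotype calling

Each assay runs in duplicate wells. The generative model is a standard
ΔCt description: a diploid well amplifies at `ct_baseline` (default 24
cycles), each halving of template adds `ct_per_copy_shift` cycles
(default 1.0), Gaussian well noise has `ct_sd` cycles (default 0 in
the noise-free configuration, 0.15 in the realistic one), and zero
template yields a no-amplification sentinel. Allelic dropout is a
per-cell, per-allele loss (rate `allelic_dropout_rate`) applied before
amplification — both duplicates share the surviving alleles because
dropout happens at lysis/capture — while amplification failure (rate
`assay_failure_rate`) is independent per well.

Calling is conservative:

* mutation-specific assays: positive only when **both** duplicates
  amplify below `ct_max` (default 38 cycles), negative when neither
  does, *missing* when they disagree;
* copy number: mean ΔCt versus a diploid control, banded by
  `delta_ct_bands` (default 0.5, 1.5 — matched to the 1-cycle-per-
  halving response); both locus wells silent with passing controls is
  bi-allelic loss; control failure or a discordant locus duplicate is
  NA;
* zygosity of a sequence marker is heterozygous on a positive
  mutant-specific assay and upgraded to homozygous only when a paired
  wild-type-allele assay is present and negative. This abstracts
  zygosity resolution by single-cell Sanger sequencing as an optional
  extra assay column; without it zygosity is capped at het.
* a cell whose control wells fail is entirely uncallable (all NA) and
  removed in QC, together with cells missing more than
  `max_missing_frac` of their calls (default 0.3).

## Subclone detection and dropout shadows

Identical complete genotype rows merge into subclones; rows with NA
are assigned to a subclone when exactly one candidate matches all
their non-NA calls, otherwise counted as unassigned. Genotypes below
`min_cells` (default 2) are reported as below the level of reliable
detection, never silently dropped; all counts reconcile with the input.

Allelic dropout creates a characteristic artefact: a heterozygous
marker whose single mutant allele drops out reads confidently wild
type in both duplicates, so a clone at dropout rate ε sheds ~ε of its
cells per het marker into *shadow* genotypes — strict sub-genotypes of
the source. Shadows cannot be separated from genuine small subclones
by any fixed count threshold when deep clones are themselves eroded.
`collapse_subclones` therefore offers optional shadow absorption
(`absorb_dropout_shadows`, default off): a genotype is merged into a
clone when it is a strict sub-genotype (component-wise, in units) of a
genotype with more than `1/ratio` times its cell count. The ratio test
uses pre-absorption counts throughout, so a clone inflated by absorbed
shadows cannot in turn swallow a genuine ancestor (subclone chains are
nested genotypes). The rationale: shadows occur at ~ε of their source
clone, whereas a genuine ancestor is sampled at a count commensurate
with its own frequency, so a ratio well above ε (0.5 is used by the
recovery pipeline) separates the two.

### The standard recovery pipeline

The benchmark pipeline used by the evaluation helpers and the
acceptance script chains: QC (controls + ≤50% missing), shadow
absorption at ratio 0.5, and a detection threshold of 5% of kept cells
(at least 2). The threshold must exceed the residual artefact band
(~2–3% of all cells for shadows of a dominant clone) while staying
below what an eroded genuine subclone retains (a 20%-frequency clone
keeps ≳8% of cells after dropout and QC losses at dropout 0.1).
Topology recovery is judged by the strictest criterion: exact equality
of the genotype-labelled edge multiset of the best tree with the
generating truth.

## What the generator emulates — and what it does not

`make_truth` produces 1–8 subclones with a truncal first clone
(fusion heterozygous, truncal copy-number losses bi-allelic), uniform
random parent attachment for later clones, non-truncal markers dealt
evenly over the subclonal edges, and uniform clone frequencies unless
a vector is given. Reiterative lesions are extra markers of one gene
placed on pairwise non-ancestral clones. Defaults for the realistic
noise condition are dropout 0.1, well failure 0.05, Ct noise 0.15 —
treated as free simulation parameters of the emulated study design,
not estimates of any real study's rates.

Not emulated: cell doublets, normal-cell contamination, read-level
sequencing noise, FISH hybridisation images (only signal-count
tables), relapse samples, and copy-number events distinguishable only
by breakpoint (multiple CDKN2A deletions collapse to one copy-number
state, as small qPCR assays cannot tell them apart). Passing the
simulation benchmarks therefore demonstrates correctness of the
algorithms under the modelled noise processes, not robustness to every
artefact of real single-cell data.

## FISH containment ordering

FISH patterns are per-cell signal-count tuples; a fusion-indicator
probe pair counts intact co-localised red–green pairs (2 normal, 1
with the fusion), locus probes count retained copies. Distinct tuples
with the same lesion interpretation merge. Patterns are ordered by
lesion containment under the same irreversible model; the diagram is
built in two passes: the node set is first closed under *meets*
(component-wise least-severe states) wherever a pattern has several
incomparable maximal ancestors, then each node's parent is its unique
maximal strict ancestor or that meet — incomparable patterns become
siblings under their meet. Signal counts above the diploid state are
rejected rather than silently ordered, as gains cannot be placed under
a loss-only model.

## RSS scoring

A candidate RSS is heptamer (consensus `CACAGTG`) + spacer (12 or 23
bp) + nonamer (consensus `ACAAAAACC`). Heptamer and nonamer windows
are scored by a position weight matrix whose columns are maximal at
the consensus base; the spacer contributes only a length-deviation
penalty (its base composition is ignored), default 1.0 per base with
at most ±1 bp deviation considered. The default matrix weights the
first three heptamer bases (the CAC strictly required for cleavage) at
±1 and all other positions at ±0.5, so a perfect RSS at canonical
spacer scores 9.5. `N` bases score the column minimum (conservative).
Scanning is exhaustive over placements, spacer lengths and both
strands; minus-strand coordinates are mapped back to the forward
sequence, all coordinates 0-based half-open. Reports record which
matrix produced the scores; published matrices can be substituted, and
the 8.55 reference threshold (the score level reported at genuinely
RAG-driven breakpoints in B-cell-precursor ALL) classifies summaries
into "RAG motif support" / "no RAG support".

## Cohort grid

The packaged 20-sample driver grid
(`data/cohort_table_synthetic.csv`) is a constructed stand-in: the
printed table body was not available, so the grid was built to
reproduce the reported cohort marginals exactly — PTEN inactivation
(exon 7 mutation or copy loss) 8/20, 9p21.3 loss 19/20, 6q loss 6/20 —
together with the per-case driver facts stated in the text. The three
marginals serve as transcription checks in the tests. The PTEN
predicate is fixed as (exon 7 mutation OR copy-number loss); sequencing
of other exons suggests this undercounts, hence the frequency is
interpreted as a lower bound.

## Problem sizes and numerical choices

The test suite and acceptance script use: 200 random instances (≤ 7
subclones, ≤ 10 markers) for oracle equivalence; 50 simulations of 5
clones × 300 cells at dropout 0.1 / failure 0.05 for topology
recovery; 1,000 cells for the noise-free round trip; 100 sequences per
condition for the RSS properties; 400 cells per compartment for the
zygosity contrast. Ties everywhere are broken deterministically
(canonical sorts of genotypes and edge multisets); all randomness
flows through explicit integer seeds; NA is serialised as the literal
`NA`; trees are written as Newick (branch lengths = change counts,
bootstrap supports as node labels) with a JSON sidecar carrying
genotypes and flags.

## Limitations

* Exhaustive search scales as (2k−3)!! in the subclone count k;
  beyond ~9 subclones it is impractical, and the implementation
  refuses k > 10. Likelihood-based single-cell phylogenetics with
  explicit error models is out of scope.
* The irreversibility assumption is structural: genuine reversals
  (e.g. copy-neutral LOH restoring a signal) would be mis-explained as
  parallel events.
* Shadow absorption assumes dropout is the dominant source of
  sub-genotype artefacts and that genuine ancestors are not much rarer
  than half their descendants' counts; very rare true ancestors are
  indistinguishable from shadows by counts alone.
* Bootstrap supports quantify sampling stability of clades under the
  chosen collapse parameters, not genotyping error.
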