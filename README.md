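# talclone

Single-cell clonal architecture of *STIL-TAL1*+ T-cell acute
lymphoblastic leukaemia (T-ALL).

In this leukaemia subtype an interstitial 1p33 deletion fuses *STIL*
to *TAL1*; the subtype's natural history is a branching clonal
expansion in which the fusion and bi-allelic *CDKN2A* (9p21.3) loss
are truncal while drivers such as *NOTCH1* and *PTEN* arise later,
subclonally, and often reiteratively (several independent lesions of
the same gene on divergent branches). `talclone` is a library for
reconstructing that architecture from single-cell measurements:

* **Genotype calling** from duplicated multiplex single-cell qPCR Ct
  matrices (mutation-specific and ΔCt copy-number assays, duplicate
  concordance rules, per-cell QC).
* **Clone trees** by maximum parsimony under an ordered irreversible
  character model: sequence markers 0→1→2 (wt→het→hom), copy numbers
  2→1→0, unit cost per step, reversals forbidden, parallel origins
  allowed. The search is exhaustive over rooted topologies with
  optimal ancestral genotypes (component-wise minima in change units),
  returns *all* co-optimal trees with inferred ancestors flagged,
  branch lengths equal to change counts, and cell-resampling bootstrap
  supports.
* **Multicolour-FISH** pattern tabulation and containment-ordered
  evolutionary diagrams.
* **RSS scanning**: weighted-matrix scoring of cryptic recombination
  signal sequences (heptamer–spacer–nonamer) and fixed-motif searches
  (`CACAGTG`, `ACAAAAACC`, `CACA`) at deletion breakpoints, to assess
  RAG recombinase involvement.
* **Cohort summaries** (driver frequencies with explicit numerators)
  and **diagnosis-versus-xenograft comparison** (which subclones "read
  out" in transplants — T-status — frequency shifts, zygosity
  fractions).
* A **synthetic-data generator** that emulates the study design
  (clonal truths, allelic dropout, well failure, xenograft
  bottlenecks, breakpoint sequences with planted motifs) so the whole
  pipeline is testable against known truth.

See `docs/methods.md` for the models, parameters and limitations.

## Worked example

`examples/02_clone_tree_cooptimal.py` simulates 308 cells from the
four-subclone case-6116 structure, calls genotypes, collapses
subclones and infers the parsimony trees:

```
subclones: 4  (cells per clone: [98, 96, 70, 44])
co-optimal trees: 2
  tree 1: ((C1:1,(C4:2)C3:1)C2:3)N;
    latest clone C4 descends from C3 (mutated genes: ['CDKN2A', 'PIK3CD', 'STIL_TAL1'])
  tree 2: (((C4:2)C1:1,C3:1)C2:3)N;
    latest clone C4 descends from C1 (mutated genes: ['CDKN2A', 'FREM2', 'STIL_TAL1'])
bootstrap supports: {'C2': 100.0, 'C1': 100.0, 'C3': 100.0, 'C4': 100.0}
```

The root edge carries three changes (the fusion plus both *CDKN2A*
copy losses — the truncal lesions); both trees explain the data with
seven changes, and they differ only in whether the double-mutant
latest clone descends from the *FREM2*- or the *PIK3CD*-mutant clone —
an ambiguity the data genuinely cannot resolve. Bootstrap values are
the percentage of cell-resampling replicates in which each clade
reappears.

The other scripts in `examples/` cover genotype calling under noise
(01), FISH containment diagrams (03), RSS scanning (04) and cohort /
xenograft comparison (05); each prints its numbers with a line on what
they mean. A thin CLI mirrors the stages
(`talclone simulate|genotype|tree|fish|rss|cohort|compare`, see
`talclone --help`).

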