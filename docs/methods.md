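# Methods

## Model and assumptions

The unit of evidence is the occupancy probability *P(x, g, s)* that
transcription factor *x* binds at least once in the upstream promoter region
of gene *g* in species *s*.  Rewiring is framed as a contrast across one
branch of a fixed, rooted species phylogeny: the branch partitions the
species into a clade *M* and its complement *M\**, and the pairwise skew

    skew(x, g) = mean_{s in M, present} P(x,g,s) − mean_{s in M*, present} P(x,g,s)

is an unweighted arithmetic mean difference.  Species that lack an ortholog
of *g* are excluded from both means; a gene with no present ortholog on one
side has undefined skew and is dropped from the candidate pool *for that
branch* before any optimisation.  Team and block scores are grand means of
pairwise skews, so averaging first over genes or first over factors is the
same number (this identity is asserted to 1e−12 in the tests).  Because all
probabilities lie in [0, 1], |skew(x, g)| ≤ 1 and block scores lie in
[−2, 2].

The two reporting quantities Dif(M) and Dif(M\*) are *pooled* means over all
present (factor, gene, species) triples on one side.  On a complete tensor
Dif(M) − Dif(M\*) equals the block score exactly; with missing orthologs the
pooled means weight genes by their number of present species, so the
identity is only approximate — this is a property of the definitions, not a
numerical artefact.

## The search

Ping-pong is a block-coordinate ascent at fixed shape (m, m\*, m_G).  Step
TF rebuilds both teams from *all* factors given the genes; Step G rebuilds
the gene set from *all* usable module genes given the teams.  Each step
replaces a set by the optimal set of the same size, so the score never
decreases and the loop terminates on a finite space; on termination no
single-element substitution can improve the block (checked exhaustively by
`verify_max_block`, and against full enumeration on tiny instances in the
tests).  The loop stops as soon as the rounded score fails to increase, or
earlier when the gene set reproduces itself exactly — at that point both
steps are provably idempotent.

Team membership is sign-constrained: T is filled only from factors with
positive (rounded) skew and T\* only from negative ones; a factor scoring
exactly zero counts for neither side.  If a sign runs short *inside* a run,
the run ends early with the last valid block.  The outer search
(`find_block`) starts from G0 = all usable module genes with team sizes
equal to the positive/negative sign counts, and before every restart clamps
m and m\* to the currently available sign counts — deleting a gene can flip
a near-zero factor's sign, and shrinking the teams to fit (rather than
aborting) is what lets the attrition trajectory run to completion.  Only a
side with no signed factors at all stops the search, flagged via
`stop_reason`.

Attrition deletes the globally least-important element each round:
importance is skew(x, G) relative to the strongest member of T, skew(y, G)
relative to the most-negative member of T\* (a ratio of two negatives), and
the per-gene contrast relative to the strongest gene.  Deleting a class's
weakest member can only raise that class's mean, so the re-converged score
is monotone along the trajectory (asserted in tests).  The stop threshold
defaults to 0.5; 0.25 yields larger blocks, 0.75 smaller ones, and a
threshold of 1.0 drives the block down to (1, 1, 1).

## Determinism and precision

All probabilities are stored at eight decimal digits (decimal half-to-even
on parse), every score comparison uses values rounded to eight digits, and
rounded ties break alphabetically — first by element name, then by class
order T, T\*, G when a tie spans classes.  There is no randomness anywhere
in the core: identical inputs give byte-identical trajectories and reports.
The iteration cap (10 000) is a pure safety guard; the monotonicity argument
makes reaching it impossible short of a bug, and hitting it raises an
internal error rather than returning a result.

## Occupancy model

The exact estimator behind the originally published probability table is
not public in full detail, so the package ships its own documented model, isolated behind `site_probability` so a different per-window
estimator can be swapped in without touching callers.  Per window *w* of
PWM width: q(w) = p·L(w) / (p·L(w) + (1−p)·B(w)), with L the PWM likelihood
under pseudocount-regularised frequencies (0.5 per cell), B the background
likelihood, and prior p = 1/600 — one expected site per full-length
promoter.  Backgrounds default to each species' pooled promoter base
composition.  Occupancy is 1 − Π(1 − q(w)) over every window on both
strands; windows containing an ambiguous base contribute zero.  Consequences
worth knowing: occupancy is monotone non-decreasing as sequence is appended,
invariant under reverse complement, and for a consensus-only PWM the
per-site posterior approaches 4^width·p/(4^width·p + 1 − p) as the
pseudocount vanishes — close to 1 only for motifs long enough that the
likelihood ratio swamps the prior.

## Synthetic fixtures

`plant_tensor` emulates the structure of a rewiring event, not yeast
biology: cell probabilities are truncated-normal noise around block-wise
means (truncation keeps values in [0, 1] without clipping mass onto the
endpoints), and the planted block's expected score has the closed form
Δ = (t_on_M − t_on_M\*) − (t\*_on_M − t\*_on_M\*).  Defaults scale the real
study down — 20 factors × 40 genes × 23 species, a 10-species clade, a
planted (3, 1, 19)-block, Δ = 1.0, noise 0.05, no missing orthologs — sizes
chosen so a full search trajectory (~30 attrition rounds) completes in tens
of milliseconds while keeping the species dimension realistic.  The fixture
tree is a nested-ladder topology in which all study-style branch labels
(prefix clades, and the interior clades used for three-digit labels) are
genuine clades.  `plant_promoters` implants PWM consensus sites only on the
appropriate branch side, which exercises the occupancy stage end to end.

What passing on these fixtures does *not* show: real binding probabilities
are neither Gaussian around two levels nor independent across species
(phylogenetic correlation), module boundaries are noisy, and real signals
are far weaker than Δ = 1.  The fixtures validate the machinery —
correctness of the statistics, convergence, determinism, recoverability of
a strong planted signal — not detection power on real data.

## Design choices on open points

* **Binding-table dialect** — the published probability database is plain
  text of unspecified layout; the package fixes a 4-column TSV (tf, gene,
  species, probability) with a header.  A (gene, species) pair must either
  carry all factors or be absent entirely; partial coverage is an error,
  and duplicate triples are a hard error (paralogs must be resolved
  upstream).
* **Branch labels** — one/two-digit labels expand to "the first k species
  in tree leaf order"; three-digit labels must be given explicitly in the
  branch config, since only some of their memberships are defined in prose.
  A branch must be a clade, or have a clade as complement (a split at the
  root), unless clade checking is disabled.
* **Ties that stall the score** — the loop stops on any non-increase, so a
  score-preserving membership change (possible only with an exact 8-digit
  tie) terminates rather than cycles.
* **Undefined pairs** — genes undefined for a branch are excluded per
  branch rather than per average, keeping every reported mean over a fixed
  species set.
* **Reportable blocks** — screening discards blocks in which any T\* member
  has non-negative skew (`require_negative_t_star=False` disables this);
  with sign-constrained Step TF this filter is a belt-and-braces check.
* **Near-duplicate branches** — optional screening dedup collapses rows of
  one module whose block gene sets have Jaccard similarity > 0.8, keeping
  the higher skew; "differs only slightly" is informal, and 0.8 is the
  package's concretisation.
* **Histogram** — bins are floor(skew·100)/100 (truncation toward −∞, with
  a 1e−9 epsilon guarding exact hundredths against float representation);
  the smoothing is a centered 7-bin moving average truncated at the edges.

## Limitations

* No significance model: a max block always exists, and its score carries
  no p-value.  Ranking and the histogram's tail are the only guidance.
* The occupancy model is a documented stand-in for the original
  supplementary estimator; absolute probabilities from `build_tensor` are
  not comparable to the published table, though the downstream statistics
  are estimator-agnostic.
* The "expanding" attrition variant (grow G from a single gene) and
  gene-turnover contrasts are out of scope.
* `build_tensor` loops over promoters in Python; it is sized for fixtures
  and moderate genome subsets, not for millions of promoters.
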