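# Methods

This note records the models, conventions and operational choices behind the
package, in the spirit of a simulation-study methods section: what is
computed, under which assumptions, and where a definition in the literature
left room that we had to close ourselves.

## Trees and metrics

All metrics operate on a rooted phylogeny with non-negative branch lengths
carried on the child node of each edge; a root edge in the input is ignored.
Tips are addressed in sorted-label order everywhere, and the newick writer
emits children sorted by smallest descendant label so that identical trees
serialise identically.  Ultrametricity (all root-to-tip depths equal) is
assumed by the isolation literature; we check it with a relative tolerance
of 1e-6 of tree depth and *warn* rather than refuse on non-ultrametric
input, since most of the metrics remain well defined.  Zero-length internal
edges are permitted and their nodes count as real nodes in the node-count
metrics.

Conventions the original descriptions do not pin down:

- **VW / MVW** count interior nodes on the root path root-inclusively and
  tip-exclusively.  This makes MVW = VW/2 exactly on bifurcating trees,
  consistent with a bifurcating node contributing 2 daughters.
- **NWU** marks a root-path clade with 1 when it is strictly larger than
  *every* sister clade, and scores 1/(1 + Σ marks).  The +1 keeps the score
  defined when no comparison fires; a maximally isolated tip (never on the
  larger side) then scores exactly 1.
- **NWW** sums descendant counts over root-path nodes, root included, tip
  excluded (the tip would add 1 uniformly).
- **SV** is the Shapley value of the *unrooted* spanning-length game (a
  bifurcating root is suppressed).  The rooted game would make SV collapse
  onto ED exactly; the unrooted game reproduces the observed
  nearly-but-not-exactly-ED behaviour.  The closed form
  Σ_e l_e (N−a_e)/(N a_e) is verified against subset enumeration with
  factorial Shapley weights on every tree with ≤ 8 tips we throw at it.
- **QE** maximises Rao's quadratic entropy over the probability simplex via
  an active-set scheme: solve D p = c·1 on the current support, drop tips
  whose weight falls below −1e-12 (they score 0), re-solve.  On the final
  support the stationarity certificate ‖D p − c·1‖∞ < 1e-8 is enforced in
  tests, and the solution is checked against a brute-force simplex grid
  search on 3–4-tip trees.  Zeros genuinely occur, mainly on
  non-ultrametric trees.
- **CHR** is a deterministic expectation, not a character simulation.
  Characters arise at rate ν per unit branch length on the edge above each
  root-path node k and survive each subsequent edge with probability ρ; a
  character's rarity is the expected fraction of the *whole tree's* species
  lacking it (species outside k's clade can never carry it), giving
  CHR(i) = Σ_k ν l_k ρ^m(k,i) (1 − f_k/N) with f_k = Σ_{j below k} ρ^m(k,j).
  ν is a pure scale factor and disappears under standardisation.  ρ is the
  one consequential parameter: the score's published behaviour is its
  near-redundancy with APD, and we calibrate the default ρ = 0.995 to
  reproduce exactly that (rank correlation ≈ 0.99 with APD on 100-tip
  birth–death trees; normalised inter-metric distance ≈ 0.12).  Smaller ρ
  progressively shifts weight toward shallow clades and breaks the
  redundancy — worth knowing before trusting CHR with "reasonable" rates on
  empirical trees.

## The simulated study conditions

Test trees are homogeneous birth–death phylogenies: birth rate λ = 0.5 per
lineage per unit time, death rates µ ∈ {0, 0.125, 0.25, 0.4}, 100 extant
tips (50–500 in the size-scaling experiments), 1000 replicates per
condition.  Simulation is forward in continuous time from two crown
lineages; the clock stops the first time the extant count reaches the
target and the tree is truncated one further exponential waiting time later
(just before the next event would fire), so pendant edges are never zero.
Extinct lineages are pruned, unifurcations suppressed; whole-tree
extinction triggers a fresh attempt (cap 1000).  All draws come from one
seeded NumPy generator, so a seed determines every output byte.

What the generator emulates: the tree-shape gradient the study varies —
from pure-birth trees with long pendant edges to near-parity trees whose
survivors sit close together (mean pendant/depth falls from ≈ 0.15 at µ = 0
to ≈ 0.07 at µ = 0.4).  What it does not emulate: conditioning details of
any particular simulator (e.g. generalised sampling of survival times),
rate variation across lineages or time, incomplete taxon sampling, and any
phylogenetic signal in threat status (threat categories for EDGE exercises
are i.i.d. draws).  Passing tests therefore say the *metrics and pipeline*
behave as documented on trees of these shapes — not that any particular
empirical tree will show the same constants.

## Comparing the metrics

Per tree, every metric is standardised by its mean over tips.  The
inter-metric distance is the Euclidean distance between score vectors after
centring each metric and scaling it to unit variance, and the 11×11 matrix
is then normalised so its mean off-diagonal entry is 1.  The unit-variance
step matters: it makes the distance a monotone function of the Pearson
correlation between metrics, so two metrics that are linear transforms of
each other (VW and MVW) sit at distance 0 regardless of their spread.  This
is the scaling under which the study's reported distances and groupings
reproduce; distances taken directly on mean-standardised vectors are
instead dominated by differences in relative spread (APD varies a few
percent around its mean, PE varies several-fold) and are available as
`scale="mean"`.

Dendrograms use average-linkage agglomeration (deterministic given the
canonical metric order; average linkage cannot invert heights).  The
majority-rule consensus keeps clades present in strictly more than half of
the per-tree dendrograms — such clades are pairwise compatible, so they
nest into a single rooted tree — with supports equal to occurrence
proportions, re-checked in tests by independent recounting.

**Captured variation.**  "Fraction of total variation captured by a metric
subset" is not a standard quantity; we implement two definitions.  The
default *variance-share* definition takes the total variation of a tree's
score set to be the sum of the 11 per-metric variances (after mean
standardisation) and credits a subset with the variance of its members;
this is the definition under which the published captured-variation curve
(≈ 51/67/78/86 % for the best 2–5 metrics, ≈ 14 % left in the other six)
reproduces, and under it greedy forward selection reduces to picking
metrics by variance share.  The alternative *regression* definition credits
a subset with the variance-weighted mean R² of all 11 metrics regressed on
the subset (OLS with intercept, pseudo-inverse when collinear); it measures
predictive redundancy instead of raw spread, saturates much faster (two
well-chosen metrics already explain > 90 %), and is the right definition
for questions like "does VW add anything once MVW is chosen?".  Both are
monotone in subset inclusion.  The "major groups" used by the one-per-group
selector are obtained by cutting the average-linkage tree of the pooled
(replicate-mean) distance matrix into k clusters.

## Uniqueness and originality

Per tree we correlate (Spearman, average ranks — essential for the heavily
tied node-count metrics) each non-redundant metric's scores with the
pendant-edge scores (uniqueness) and with APD (originality); FP, VW and CHR
are dropped as duplicates of ED/SV, MVW and APD, leaving 8 metrics with PE
and APD anchoring the two ends at self-correlation 1.  The per-tree
trade-off line is OLS of the uniqueness correlations on the originality
correlations — the orientation is a genuine free choice (the source
analysis does not state it) and this one reproduces the reported slope
magnitude (≈ −1); the opposite orientation is available via
`response="rho_orig"` and gives a shallower slope (≈ −0.7) because the
regression direction matters when R² < 1.  Adjusted R² uses the
simple-regression (n−1)/(n−2) correction.  A constant score vector has no
rank correlation; it is recorded as missing with a warning and the fit
proceeds on the remaining points (at least 3 required).

Known gap: our per-tree fits average adjusted R² ≈ 0.73 with slope s.d.
≈ 0.25 across replicate trees, a wider spread than the study reports; the
between-tree variance depends on simulator conditioning details that are
not published, and we chose not to reverse-engineer them.

## EDGE lists

EDGE = ln(1 + isolation) + GE·ln 2 with the isolation score standardised by
its mean and GE the ordinal threat code LC = 0 … CR = 4; one category step
exactly doubles the implied weight.  Lists are ranked by descending EDGE
with average ranks on ties.  Top-k comparisons report the overlap of top-k
sets, the Spearman correlation of both lists' full ranks restricted to the
*reference's* top-k species (not the union — comparisons are anchored to a
reference list), and the number of distinct isolation values in the other
list, which exposes how coarse the node-count metrics are (a 250-tip tree
yields ≈ 165 distinct ED scores but ≈ 14 distinct NWU scores).

## Problem sizes and numerics

The test suite runs the whole pipeline at reduced scale — 120–200 trees per
death rate, chosen so the Monte-Carlo standard error is comfortably inside
each assertion's tolerance and the suite finishes in about half a minute.
The acceptance script runs the full 1000 replicates per condition (a few
minutes on one CPU).  Floating-point output is written at 10 significant
digits; newick branch lengths use shortest-round-trip representation, so
parse → write → parse is the identity.  Ties inside metrics are never
broken arbitrarily (exchangeable tips receive exactly equal scores);
ranking ties are resolved by average ranks downstream.

## Limitations

- Unrooted trees and networks are out of scope; every metric here presumes
  a root (only SV is naturally root-free).
- CHR is only as meaningful as its retention parameter; we document its
  calibration rather than claim canonical input values.
- The captured-variation and trade-off analyses are operationalisations of
  informally described quantities; both definitions are shipped and the
  defaults are the ones that reproduce the published summaries.
- Threat categories in the EDGE exercises carry no phylogenetic signal, so
  EDGE-list overlap statistics on simulated data describe the metrics, not
  real red-list structure.
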