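# Methods

## Scope and data flow

`sinaphy` analyses a protein family with one ancestral (invertebrate-like)
lineage and several vertebrate paralog lineages. Inputs are aligned or
unaligned FASTA protein sequences plus a domain-coordinate annotation for
one reference sequence per alignment; the homology search that produces
candidate sequences, and the construction of multiple alignments, are
upstream of the package (alignments are inputs; the simulator emits true
alignments). The stages run curate → trim → (tree + metrics) and
(profile + consensus), each usable on its own.

All residue and column coordinates are 1-based inclusive. The sequence
alphabet is the 20 standard amino acids plus `X` (ambiguity) and `-` (gap);
rare one-letter codes (U, B, Z, J, O) are mapped to `X` with a logged
warning. Every trimming operation carries a `column_map` from current to
original columns, and trims compose: trimming twice yields the same map as
the equivalent single trim.

## Curation

Two filters reproduce a candidate-selection protocol downstream of a
remote homology search (the search itself, with its E-value cutoff of
1e-60, is retained only as provenance metadata):

* **Length** — keep sequences strictly longer than a threshold (defaults:
  240 residues; 200 for the fast-evolving SIAH3-style search). The
  inequalities are strict, as printed in the protocol being reproduced.
* **Domain-region coverage** — the original criterion ("produced an
  alignment with the functional domain-containing region") was a manual
  judgment. We quantify it: the candidate is globally aligned to the
  reference (BLOSUM62, gap open −11 / extend −1, fixed so results are
  reproducible) and kept if its non-gap characters cover at least a
  configurable fraction (default 0.5) of the reference span from the first
  domain's start to the last domain's end. This proxy is a design choice,
  not a published rule, and is flagged as such here.

## Trimming

* **Coverage trim** removes a column iff its gap fraction strictly exceeds
  the threshold (default 0.70, i.e. keep columns with ≥ 30% coverage). A
  column with exactly 70% gaps is kept.
* **Reference trim** removes columns that are gaps in a designated
  reference row. Columns inside the functional domains are protected by
  default (in-domain reference gaps survive), and the trim can be
  restricted to a column region — used for ancestral-family alignments
  where only the region upstream of the reference's RING-domain start is
  trimmed. We protect domains uniformly across all reference trims; for
  references without in-domain gaps this is unobservable either way.
* **Overhang removal** deletes a maximal terminal run of columns in which
  at most one record is non-gap (a single-species extension).

All three are idempotent and leave the reference's ungapped residue
content unchanged.

## Substitution model

Published exchangeabilities and frequencies for Dayhoff, JTT, WAG, and LG
ship as text assets in the conventional ARNDCQEGHILKMFPSTWYV order. The
rate matrix Q_ij = s_ij π_j is scaled so −Σ π_i Q_ii = 1; transition
matrices come from the symmetric eigendecomposition of
D^{1/2} Q D^{-1/2}, exact for reversible models. `+F` frequencies are
counted from the analyzed alignment, excluding gaps and `X`, with no
pseudocounts.

Among-site rate variation uses the common discrete-gamma convention:
k equal-probability categories (default 4) whose rates are the exact
conditional means of a mean-1 gamma within each quantile (computed from
the regularized incomplete gamma function), so the mean rate is exactly 1.

## Likelihood and tree search

Felsenstein pruning over compressed site patterns, 20 states × k
categories, with per-node scaling against underflow; `-`/`X` contribute a
partial likelihood of 1 in every state. Branch lengths are optimized by
per-branch Brent steps against cached "outer" partial likelihoods, swept
in preorder with partials refreshed in place, iterated to a relative
improvement below 1e-6 (bounds 1e-8 to 20 substitutions/site); the gamma
shape is optimized the same way on a log scale, alternating with branch
sweeps. The likelihood never decreases along a sweep; optimizing an
already-optimal configuration is a fixed point.

Starting trees come from Neighbor-Joining and BioNJ on pairwise ML
distances under a one-parameter JTT model without gamma (distances are
capped at 10 substitutions/site; columns with `-`/`X` in either sequence
are dropped); the start with the better likelihood is kept. NJ is exact on
additive matrices. The SPR search interprets "level" as a regraft radius:
only edges within that many edges of the pruning point are candidate
regraft sites. Moves are scored after Brent-optimizing the branches at the
new junction only; the first improving move is accepted (greedy
first-improvement), branch lengths are re-optimized globally, and the scan
restarts until no move improves the likelihood. Candidate topologies
identical to the current one (which some seam-adjacent regrafts recreate)
are skipped.

The nonparametric bootstrap resamples columns with replacement, infers a
tree per replicate, and annotates each internal edge of the main tree with
the percentage of replicates containing its bipartition. Replicate-level
search effort is configurable (distance tree only, SPR at a reduced level,
or the full search); internal edges shorter than 1e-7 substitutions/site
are treated as unresolved and carry no support — with zero phylogenetic
signal, supports are reported as absent rather than as artifacts of
deterministic tie-breaking.

Model selection fits each candidate of {Dayhoff, JTT, WAG, LG} × (+G) ×
(±F) on a fixed topology and ranks by AICc with sample size n = number of
alignment columns (a convention choice; tools differ here) and parameter
count k = branch lengths + gamma shape + 19 frequencies when +F.
Candidates with n ≤ k + 1 are flagged non-computable.

Rooting places the root on the edge separating the smallest clade that
contains all outgroup taxa, splitting that edge's length equally; if the
outgroup is not separable in the unrooted topology, the edge maximizing
outgroup-side purity is used, with a warning. Rooting does not change the
unrooted topology.

## Post-inference metrics

The root-to-tip distance of a paralog subtree starts at the node adjacent
to the subtree's root — concretely, the subtree root's child on the focal
tip's path — and ends at the focal tip; the subtree root's incoming edge
and its first focal-side edge are thereby excluded, and a focal tip that
is itself a child of the subtree root has distance 0. This is the only
reading under which the path "starts" at a node adjacent to the root.
Rate ratios are plain quotients of these distances; note that ratios of
rounded published distances can differ from ratios of exact ones (e.g.
2.58/0.07 ≈ 36.9, which prints as "34-fold" only if the inputs were
rounded). Distances are computed on the best (maximum-likelihood) tree,
not on a bootstrap consensus.

## Conservation profiling and consensus

Percent identity against a reference is "not excluding gaps": every column
in the span counts in the denominator, and `-`/`X` never match anything —
including themselves. An incomplete database sequence can be designated so
that columns where *it* is gapped leave the denominator for all
comparisons (otherwise truncation masquerades as divergence).

Column classes: *identical* iff all records share one amino acid (no
gaps/X in the column); *similar* iff not identical but all non-gap
residues fall in one strong-similarity group — the grouping
({I,L,V,M}, {F,W,Y}, {K,R,H}, {D,E}, {N,Q}, {S,T}, {A,G}, {C}, {P}) is a
fixed published-style default, configurable, since rendering tools do not
document their palettes; everything else is *divergent*. The three classes
partition every span.

Consensus: per column, count amino-acid frequencies ignoring gaps; emit
the unique maximal residue, or `X` when two or more residues tie at the
top; gap-only columns are dropped but each consensus position remembers
its source column, so consensuses of subsets of one alignment remain
mutually aligned without re-alignment. Consensus *comparison* (the
identity matrix of paralog consensuses against the ancestral-family
consensus) is computed in the reference consensus's own coordinates —
columns where the reference row is gapped leave the denominator — with
strict character equality, so a consensus is 100% identical to itself by
construction while an `X` against a resolved residue is a mismatch. This
differs deliberately from the sequence-level identity rule above: the
published identity matrix defines its reference row as 100%.

Default domain coordinates for the human SIAH paralogs and the
*B. floridae* SINA reference ship as
`data/default_domain_maps.synthetic.tsv`. They are reconstructed from
printed constraints (core spans, domain column counts, domain order), not
taken from the primary database entries, and the filename marks them as
synthetic; replace them with database coordinates for real-data work.

## Synthetic families

The simulator generates the structure the analysis assumes:

* a species tree (default: 8 ingroup species plus one outgroup) onto which
  duplications are grafted — each duplication splits a lineage on a named
  species-tree edge into two labeled paralog lineages, successive events
  spaced evenly along the edge;
* per-paralog rate multipliers scaling every gene-tree branch (defaults
  10 : 2 : 1 for the SIAH3- / SIAH2- / SIAH1-like lineages, the ordering
  the real family shows, with the outgroup lineage at 1);
* a domain architecture (N-terminal region 80, RING 36, SZF 60, SBS 25,
  DIMER 48 residues) with per-domain multipliers (defaults: N-term 2.0,
  RING 0.5, SZF 0.8, SBS 0.2, DIMER 0.6 — the substrate-binding site
  coldest, the N-terminus fast). A multiplier of 0 freezes a domain
  entirely, a useful control;
* LG substitution with discrete-gamma site rates (default shape 0.5852,
  4 categories — the shape estimated for the real family), each site
  assigned a category once at the root;
* indels confined to the N-terminal region: Poisson insertion/deletion
  events per unit branch length (default 0.25 each) with geometric lengths
  (mean 12), which at the default tree depth produces leaf N-terminal
  lengths varying by several tens of residues, emulating the large
  N-terminal length variance of real families (tens to ~150 residues).

All randomness flows from one seed; identical configurations are
byte-identical on disk. The simulator does **not** emulate alignment
error (true alignments are emitted), lineage-specific gene loss,
heterotachy, or compositional drift across the tree — so passing recovery
tests demonstrates correctness of the estimators under the model's own
assumptions, not robustness to real-data misspecification.

## Verification strategy and problem sizes

Every numerical component is checked against an independent oracle:
pruning against explicit summation over internal-node states (≤ 5 taxa,
≤ 4 sites, tol 1e-10); NJ against random additive matrices (n ≤ 12, exact
recovery) and a second implementation (scikit-bio); gamma category rates
against numerical quadrature (tol 1e-6); consensus against a per-column
recount; root-to-tip distances against leaf-to-leaf path sums via the
three-point formula; trimming against brute-force gap recounts. Recovery
experiments use deliberately desk-scale problem sizes — 6–8 taxa and
300–5,000 sites for branch-length/shape/topology recovery, ~1,000-site
families and 20 replicates for the rate-ranking experiment, 3,000 sites
for model selection — chosen so the full suite runs in a few minutes on
one CPU while leaving comfortable statistical margins. Bootstrap counts
in pipeline runs default to 10 with the distance-tree replicate search;
the count and search depth are configuration knobs, and a full-search
100-replicate bootstrap is the setting a production analysis would use.

## Known limitations

* Exact numerical parity with specific GUI phylogenetics programs is not
  promised: gamma discretization, +F counting, and the AICc sample-size
  convention vary between tools, so likelihoods and shape estimates agree
  to tolerance, not digit-for-digit.
* The SPR search is a greedy hill-climb; on large families it can stop in
  local optima that a stochastic or exhaustive search would escape.
* BioNJ shares NJ's agglomeration and differs only in variance-weighted
  distance updates; on clean (additive) inputs the two coincide.
* The curation coverage filter is a stated proxy for a manual judgment;
  its default threshold (0.5) is a convention, not a fitted value.
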