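# Methods

This note records the models, parameter choices and numerical decisions
behind `t2pks`, and what the synthetic test conditions do and do not
establish about real genomes.

## Sequence comparison

All pairwise comparison is Smith–Waterman local alignment with affine
gaps (biotite's C kernel), BLOSUM62 with gap open 11 / extend 1 by
default. Identity is computed over aligned columns of the optimal local
alignment; coverage is aligned columns divided by the shorter sequence
length. Ambiguity codes (B, Z, J, U, O, \*) are retained in I/O but
masked to X for scoring, because substitution matrices define X.

Where an E-value is needed — the homology fallback for tiny subfamilies
and the chemotype homolog vote — it is derived from the raw score with
the Karlin–Altschul formula `E = K·m·n·exp(−λS)` using the published
gapped BLOSUM62/11/1 constants (λ = 0.267, K = 0.041). This
approximates what SSEARCH/BLAST report and is used only for
thresholding (default cutoff 1e−10, configurable); it is not a
significance claim.

## Subfamily clustering and threshold calibration

Classes are partitioned by single-linkage clustering: sequences are
linked when percent identity ≥ min_identity **and** coverage ≥
min_coverage, and clusters are connected components (transitive
closure), reported deterministically (descending size, then smallest
member id; labels a, b, c… follow that order). Single linkage is the
right relation here because subfamily membership is defined by chains
of homology, not by tight centroids.

The thresholds are not method constants. They are calibrated by a grid
scan (identity 25–70 % in steps of 5, coverage 0.5–0.9 in steps of 0.1)
choosing the first pair that reproduces the reference partition's
per-class cluster-size multisets, falling back to the best mean Rand
index against the labeled partition. The calibrated pair is stored with
the resulting table. Note that the curated collection's own labels are
not size-ordered in one class (the largest CYC subfamily is labeled c,
not a); size-ordered labels are a convention of the clustering summary
only — subfamily identity used by classifiers and chemotype rules
always comes from the labeled reference set.

## Profile HMM classifiers

Each subfamily's members are aligned progressively (biotite
`align_multiple`, deterministic for fixed input order) and a profile
HMM is built with pyhmmer (HMMER 3). Queries are scored with the
standard HMMER search pipeline (Z = 1, so the reported E-value is the
per-sequence p-value).

The positive-call threshold is gathering-style: half the minimum
training-member self-score, and never above that minimum minus a
10-bit margin. Rationale: an unseen family member scores like another
draw from the member self-score distribution, so a cutoff pinned a few
bits under the observed minimum misclassifies legitimate members in
held-out evaluation (subsample ranges underestimate population
dispersion), whereas true non-members either fail the HMMER filter
pipeline outright or land hundreds of bits lower. Setting the cutoff
far below the family's own scores — as Pfam gathering thresholds do —
costs nothing in specificity at these separations; discrimination
between *related* profiles is the job of competitive call selection
(below), not of the per-profile cutoff.

## Alignment-feature SVM classifiers

The SVM feature vector of a query is its Smith–Waterman score against
each member of the subfamily panel, each component divided by that
panel member's self-score (removing length bias; features ≈ [0, 1]).
The panel and scaling constants are fixed at training time. The RBF
kernel's C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and width r ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} are
grid-searched to maximize the cross-validated product SN × SP, with
ties broken toward smaller C then smaller r; the winner is refit on all
data. The trained decision function is stored as plain arrays (support
vectors, dual coefficients, intercept), so a saved model bank is pure
text and reloads without pickles.

Negatives are members of other PKS classes plus residue-shuffled
positives, 1:1 with the positives, seeded — reproducible without any
external database, and covering both "wrong family" and "right
composition, no signal" error modes.

## Cross-validation protocol

4-fold when a subfamily has ≥ 20 members, leave-one-out otherwise;
metrics are averaged over 10 repeats and per-repeat values are kept for
dispersion. In LOO mode each positive is held out in turn while the
negatives are scored once per repeat by the model trained on all
positives (negatives are resampled 1:1 per repeat when the pool is
larger); how LOO handles negatives is a protocol choice this package
makes explicitly. SVM features for CV are computed once against the
full positive panel and row-sliced per fold — the panel is treated as a
fixed feature definition, not as part of the fold's training data. The
comparison harness reports both classifiers' metrics per subfamily and
the winner by SN × SP product, ties going to the HMM.

## Domain calls per protein

Type II PKS proteins carry at most two domains, so at most two calls
are retained per protein. Candidates from all subfamily models are
ranked — calls carrying E-values (HMM, homology) first by ascending
E-value, SVM-only calls after them by decision value (the two score
types are not commensurable) — and accepted greedily unless a
candidate's span overlaps an accepted call's span by more than 20 % of
the shorter span. HMM spans are alignment envelopes; SVM calls span the
whole protein; homology spans are the query's aligned region.
Subfamilies with fewer than five members (KSIII a/b, AL, MCAT, TE) are
handled by best-homolog assignment under the E-value cutoff.

## Cluster chaining and validation

The gap between two genes is the intervening base pairs between gene
bodies (`next.start − prev.end − 1`, measured from the rightmost end
seen so far, which equals the naive rule whenever genes do not
overlap); genes join a cluster iff gap < 15,000, strictly, taken
transitively. Strand is ignored (real type II PKS clusters mix
strands) and chaining does not cross the origin of circular genomes by
default. A cluster is valid iff it contains ≥ 1 KS call and ≥ 1 CLF
call; invalid clusters are retained in reports but excluded from
chemotype prediction and headline counts (both tallies are available).
Plain protein FASTA input has no coordinates, so genes are laid out
synthetically (1,000 bp spacing by default) and all downstream
coordinates are flagged synthetic.

## Chemotype rules

The embedded table has 11 ARO/CYC combinations over six chemotypes;
uniqueness flags are recomputed at load and asserted against the stored
column. Signature matching is exact-set equality by default — the table
enumerates complete combinations, so supersets and subsets fall to
Unclassified; a relaxed mode (match if the signature contains a
combination; most specific rule wins) is available for real clusters
with extra gene copies. Overlapped combinations are resolved by a
homolog vote: every ARO/CYC domain call contributes *all* reference
ARO/CYC homologs under the E-value cutoff (not only the best hit), and
the majority label wins; exact ties are reported as ambiguous rather
than resolved arbitrarily.

## Taxonomic summaries

The taxonomic PKS group ratio of a suborder is 100 × (genomes with ≥ 1
valid cluster) / (sequenced genomes), rounded half-up to two decimals.
Lineages come from GenBank ORGANISM blocks (suborders recognised by the
-ineae suffix), overridable by a user lineage table; no network
taxonomy lookups. The published 319-genome survey's per-suborder counts
ship as input data for ratio checks and comparison.

## Synthetic study conditions

`t2pks.synthetic` defines the conditions everything is tested under:

* **Families**: descendants of a random ancestor with per-site
  substitution rate 0.08 and no indels by default (≈ 85–90 % pairwise
  identity — a well-conserved protein subfamily), deterministic per
  seed.
* **Reference set**: one independent family per subfamily with exactly
  the curated sizes and mean lengths (20 subfamilies, 308 domains, 280
  proteins); ARO a/b members are paired into didomain proteins as in
  the curated didomain aromatases. ARO/CYC members carry chemotype
  labels in fixed proportions chosen so each overlapped rule
  combination has an unambiguous majority.
* **Negatives**: uniform-composition random proteins (Robinson–Robinson
  composition by flag) and residue shuffles of positives.
* **Planted genomes**: clusters of family-member proteins placed at
  exact coordinates with specified intergenic gaps, decoy genes 50 kb
  away, alternating strands; GenBank serialization back-translates with
  a fixed codon table so files are byte-reproducible. The standard
  suite (12 genomes) covers every distinct rule combination, a
  KS+CLF-only (Unclassified) cluster, and both sides of the 15 kb
  boundary (14,999 joins, 15,000 splits). Planted proteins are verbatim
  family members: detection of members is what the calibrated
  classifiers guarantee, so the truth table is exact rather than
  probabilistic. Expected chemotypes for overlapped combinations are
  derived at planting time from the reference label census (at these
  divergences every within-subfamily member is a homolog under the
  cutoff), independent of the mining code path.

What passing these conditions does **not** show: robustness to the
lower within-subfamily identities, shared ancestry between classes
(real KS and CLF are homologous; synthetic families are mutually
unrelated), horizontal transfer mosaics, fragmented assemblies, or
mis-called ORFs in real genomes. The classifiers' behaviour on real
data depends on the real reference collection, which is not
redistributed with this package; the loaders accept it in the same
TSV + FASTA form whenever available.

## Problem sizes and determinism

Default test and reproduction scales: the full 308-domain synthetic
reference set for bookkeeping, calibration and bank training; 24-member
families for cross-validation (4-fold branch) with 10 repeats; 100
random instances for the chaining oracle; 1,000 random confusion tables
for the metric oracle; 12 planted genomes end to end. Every stochastic
step takes an explicit seed (default 42 in the library; the
reproduction script derives all of its seeds from `--seed`), and
generators are deterministic given the seed.
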