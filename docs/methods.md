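# Methods

This note documents the models, statistics, and numerical choices behind
`integronhgt`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## HGT detection by exact sequence sharing

A cross-species horizontal transfer event is an unordered pair of
cassettes from different `species_label`s whose nucleotide sequences are
identical over the full length of the shorter one: equal, or an exact
substring of the longer, on the forward or reverse-complement strand.
This is the exact-matching formulation of an all-vs-all nucleotide
search with 100 % identity and 100 % query-cover cutoffs, and it is
deterministic — no alignment heuristics, no e-value dependence.

Choices that matter:

- **Within-species pairs are excluded**, so identical cassettes carried
  by strains of one species (vertical transmission) never count.
- **Events are counted per cassette pair**, not per species pair; a
  cassette shared by three species yields three events.
- **The ambiguity code N never matches.** A shorter sequence containing
  N cannot achieve full-cover identity and is skipped — conservative
  calling rather than optimistic wildcard matching.
- **Strand and match kind** (`equal`/`substring`) are recorded per event;
  reverse-complement matches count because a strand-agnostic search
  would report them.
- The detector is quadratic in cassette count with an exact-equality
  fast path; the test suite holds it equal to an independent brute-force
  pair enumeration on every instance up to 200 cassettes.

## The proportional (squared-fraction) null for site enrichment

Under the null of no site effect on transfer, both partners of an event
are drawn independently in proportion to per-site cassette abundance.
A site holding fraction *f* of all cassettes (computed over *all*
cassettes, including those with no announced isolation site) therefore
expects

    E_within(site) = N_events × f²

within-site events. The squared form is the defensible reading of
"proportional to cassette abundance" for a *pair* statistic: with 620
events and a 33.6 % cassette share it gives 620 × 0.336² ≈ 70, whereas a
linear reading would give ≈ 208 — only the squared form matches the
worked value this expectation is anchored to.

Observed vs expected counts enter a 2×2 table
`[[observed_within, observed_elsewhere], [round(E_within), round(E_elsewhere)]]`
tested with the two-sided Fisher exact test; the constructed table is
logged for audit, since contingency construction for an
observed-vs-expected comparison is a modelling choice, not a given.
Significance is flagged at p < 0.001 by default. The Fisher p-value is
computed from the hypergeometric distribution: the sum of point
probabilities of all tables with the observed margins whose probability
does not exceed the observed table's (relative tolerance 1e-7, so
floating-point noise cannot drop ties). An all-zero table returns p = 1.

Category-proportion tests between habitats use the same primitive per
category; stars follow the conventional raw-p thresholds (0.05, 0.01,
0.001), with Benjamini–Hochberg adjusted p-values reported alongside —
panels of this kind are conventionally starred on raw p, but the
adjusted values belong in the record.

## Annotation re-categorisation rules

Toxin–antitoxin (TA) components are detected by case-insensitive plain
substring match of the description against a fixed term list ("toxin",
"antitoxin", "addiction module", "plasmid maintenance system killer",
"plasmid stabilization", "antidote", "TA system", "antitox",
"post-segregation"); fragments such as "antitox" only make sense as
substrings, and "toxin" deliberately covers all its derivatives.
Descriptions containing "transposase" are re-categorised as
"Transposases"; when both rules fire, transposase wins with a logged
warning (precedence is not canonical — it is a documented choice).
Otherwise the first COG letter's standard category name is used (COG S →
"Function unknown"; no COG → "Unannotated"); multi-letter COG strings use
the first letter, logged. The re-categorisation is idempotent and
conserves record counts.

Remaining rules are pure filters: IS-family assignment takes the
maximum-bit-score hit per query (ties: lexicographically smallest
subject id, logged); PGPT screening retains KO hits scoring *strictly*
above the model-specific threshold, restricted to a supplied KO list and
the six plant-interaction subclasses; effector calls require agreement
of both predictors (absence from either table counts as a negative);
homology filtering keeps hits at or above identity/cover cutoffs
(95/95 for integrase assignment).

## attC structure comparison

*attC* sites are recognised by integrases in their folded single-stranded
form, so relatedness is assessed on secondary structure. The chain is
deliberately simple, deterministic, and exactly testable:

1. **Folding** maximises the number of nested base pairs (Nussinov
   dynamic programme) over AU/GC plus GU wobble (disable with
   `allow_gu=False`), with a minimum hairpin loop of 3 unpaired bases.
   Among co-optimal structures the traceback pairs the smallest 5'
   index first and takes the largest span for it — a fixed rule, so
   folds are identical across platforms. The suite holds the DP equal
   to an exhaustive enumeration over all nested structures for
   sequences up to 18 nt. Maximum pairing is a combinatorial stand-in
   for thermodynamic folding: it preserves gross hairpin geometry,
   which is what the downstream metric consumes, and nothing else.
2. **Distance** is a normalised mountain metric: the height profile
   h(k) = #pairs enclosing position k, divided by sequence length, is
   sampled at 100 evenly spaced relative positions x = (t + 0.5)/100
   (index ⌊x·L⌋), and the distance is the mean absolute difference of
   the sampled vectors. This is a pseudo-metric (non-negative,
   symmetric, triangle inequality on the common sample grid) and is
   **scale-free in both axes**: a perfect hairpin's profile is a
   triangle with unit slopes and a plateau at stem/length, so two
   hairpins are distinguished by their *paired fraction* and pairing
   layout, not their absolute size. Consequences: structures of
   different lengths are comparable, but geometrically similar folds of
   different sizes are deliberately close.
3. **Representatives**: within each clade, structures are first
   deduplicated by exact sequence + dot-bracket equality, then the k
   (default 10) members with the smallest summed distance to all clade
   members are kept (medoid centrality; ties by id). This discards
   unrepresentative outliers the same way covariance-model scoring
   does in alignment-based pipelines, at a fraction of the machinery.
4. **WPGMA** (McQuitty linkage) merges the closest pair of clusters at
   height d/2; the merged cluster's distance to any other is the plain
   mean of its two constituents' distances. Ties are broken by the
   lexicographically smallest pair of cluster keys (a cluster's key is
   its smallest leaf label), logged. The output is rooted and
   ultrametric, and reproduces cophenetic distances exactly on
   ultrametric input; heights agree with SciPy's `weighted` linkage.

This chain intentionally replaces sequence–structure alignment
(LocARNA/Infernal-style) with a fully specified, oracle-testable
pipeline. Topology-level conclusions — which clades separate — are
meaningful; per-branch detail is not comparable to alignment-based
trees.

## Tree incongruence (nPH85)

Non-trivial bipartitions are extracted per internal edge and stored
canonically as the lexicographically smaller side, making the extraction
independent of rooting. For binary n-leaf trees this yields exactly
n − 3 splits, and |A Δ B| equals the classical Robinson–Foulds distance
(cross-checked against an independent implementation). The normalisation

    nPH85 = |A Δ B| / (|A| + |B|)

is 0 for identical topologies, 1 for split-disjoint trees, handles
multifurcations, and is defined as 0 when both split sets are empty
(two star trees are identical). Branch lengths are ignored throughout.

Significance uses a label-permutation randomisation: both topologies
are held fixed and one tree's leaf labels are permuted uniformly
(n_rand = 10,000 by default), giving the one-sided, +1-smoothed p-value
p = (1 + #{nPH85_perm ≤ nPH85_obs}) / (n_rand + 1) — small when the
trees are more congruent than chance. An alternative scheme redrawing
the second topology uniformly at random is available behind a flag.
Because nPH85 is discrete and concentrates at 1 for unrelated trees,
this p-value is *conservative* (super-uniform) under the null:
P(p ≤ α) ≤ α holds, but the p-value distribution is far from uniform —
most replicates sit at p = 1. The calibration experiments therefore
check validity (no anti-conservatism, one-sided KS plus direct
rejection-rate bounds), which is the property a user of the test relies
on; exact uniformity is unattainable for any discrete permutation
statistic and is not claimed.

## Synthetic data: what it emulates, and what it does not

**Communities.** Default draws use 12 species × 2 genomes × 8 cassettes
(192 cassettes, lengths 60–200 nt uniform over {A,C,G,T}) with site
fractions mirroring a plant-isolate screen (33.6 % rhizosphere, 15.4 %
phyllosphere, 5 % spermosphere, rest unannounced) apportioned by largest
remainder, so realised fractions are within 1/N of the request. Planted
transfer truth is a set of disjoint cross-species cassette pairs sharing
a verbatim fresh random sequence; a configurable fraction spans two
sites, and `planted_within_site` can confine within-site events to one
site to emulate habitat-specific transfer. Background sequences are
collision-checked (including reverse complements), so the zero-HGT null
is exact, and all draws descend from one seeded generator. These
communities reproduce the *statistical structure* of a screen —
abundance-weighted sites, planted identical pairs — not genome
biology: no gene content, no shared ancestry, no near-identical (<100 %)
homologs, and background collisions of biological origin cannot occur.
Exact recovery of planted truth therefore demonstrates correctness of
the detector, not robustness to borderline homology, which the method
excludes by design.

**attC sites.** A clade template is a conserved stem, a poly-A spacer
loop, and a per-base mutation rate: sequence = stem + spacer +
reverse-complement(stem), then each base mutates with the given
probability. The spacer is poly-A (not random) because under
maximum-pairing folding a random loop pairs with itself or the stem and
destroys the designed geometry; an unpairable spacer emulates the
extrahelical central spacer of real *attC* hairpins and makes the
zero-mutation case fold to exactly |stem| pairs. The default pair of
templates (20 bp stem / 4 nt loop vs 8 bp stem / 14 nt loop, GC-only
stems, 1 %/base divergence) was designed around the metric's
scale-freeness: clades must differ in *paired fraction* to be
separable, and within-clade conservation must dominate the displacement
a stem mutation causes on a short stem. With 25 sites per clade and
k = 10 medoids, the deepest WPGMA split recovers the two clades in
≈ 99 % of seeds; the residual failures are single heavily mutated
variants whose displaced profiles fracture the root split — an honest
property of average-linkage clustering on a profile metric. Real *attC*
clades differ in far more than paired fraction; these simulations test
the clustering machinery, not the biological claim that clades have
distinct structures.

**Tree pairs** with an exact shared-split count are produced by
rejection sampling over random binary topologies (uniform sequential
joins), verified by bipartition intersection before return; the budget
(20,000 draws) fails loudly with a suggestion to lower the target.

## Problem sizes and determinism

Test and reproduction runs use deliberately small instances — ≤ 200
cassettes per community, sequences ≤ 18 nt for exhaustive fold
enumeration, 8–16-leaf trees, 25–50 replicate simulations — chosen so
that every check has an exact or brute-force oracle and the whole suite
runs in well under a minute of CPU per module. Every stochastic
component takes an explicit seed; identical seeds give byte-identical
outputs (the CLI demo is regression-tested for this), and the CLI
writes a manifest (versions, parameters, input checksums) sufficient to
reproduce any run.

## Known limitations

- Exact matching cannot see transfer older than the most recent mutation
  in either copy; the method is by construction a lower bound on HGT.
- The squared-fraction null treats events as independent draws; linked
  transfers (one conjugation moving several cassettes) violate it.
- Maximum-pairing folding ignores thermodynamics; stems with GU wobble
  are as good as GC, and co-optimal structures are resolved by a fixed
  rule rather than by energy.
- The mountain metric is insensitive to sequence identity: clades with
  similar hairpin proportions but unrelated sequences are close. This
  is intended (structure, not sequence, mediates recombination) but
  means the tree should not be read as a sequence phylogeny.
- WPGMA assumes rate constancy across lineages (ultrametricity); it is
  a clustering of distances, not an evolutionary model.
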