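# Methods

## The data model

A DN catalog holds one record per descending-neuron *type*. A type is
either *unique* (a single identifiable bilateral pair, `n_pairs = 1`) or a
*population* (a small group of morphologically near-identical cells,
`n_pairs ≥ 1`, counted as the largest number labeled in a single driver
line). All "cell-level" statistics therefore weight a type by `n_pairs`;
"type-level" statistics count it once. Records never store per-side cells:
the bilateral pair is the counting unit throughout.

Polarity annotations encode light-microscopy morphology as a proxy for
synaptic polarity: *smooth* neurites are treated as postsynaptic (input),
*varicose* ones as presynaptic (output), `both` as both. An optional
ordinal intensity (0 absent / 1 sparse / 2 dense) supports graded
annotations such as optic-glomerulus innervation; the default threshold
counts any non-absent level as innervation, with a dense-only switch.
Innervation without an ordinal annotation is treated as dense for
thresholding, so raising the threshold never spuriously removes
binary-annotated entries.

Atlases: the brain atlas carries the 41 standard named neuropils of the
insect cerebral ganglia plus the gnathal ganglia (GNG); since no complete
compartment list for the VNC is fixed by convention, the default VNC atlas
carries the 12 compartments that are unambiguous from the figure grouping
(neck, wing, haltere = dorsal; tectulum; lower tectulum; three leg
neuromeres; AMN, AS, VAC, mVAC = other) and is user-extensible via YAML.

Design choices surfaced rather than silently resolved: `both` polarity
matches both the smooth and the varicose filter; smooth VNC annotations
are accepted but logged (descending outputs are expected varicose);
records with unknown laterality or tract are excluded from the relevant
percentages and reported.

## Clustering

The clustering core is written from the definition rather than delegated,
because the exact metric, linkage, and tie behavior are the point:

- distance `d = 1 − r` with `r` the sample Pearson coefficient (on binary
  profiles this is the phi coefficient), giving `d ∈ [0, 2]`;
- unweighted average linkage (UPGMA): merge the pair of clusters with the
  smallest mean pairwise dissimilarity, at a height equal to that mean,
  maintained by the size-weighted Lance–Williams update;
- ties broken by the lexicographically least pair of minimum leaf indices,
  so output is identical across platforms;
- zero-variance profiles (uninnervated or ubiquitously innervated labels)
  are excluded by default and reported, since their correlation is
  undefined; a `max` policy instead pins them at distance 2.

Average linkage on a dissimilarity is monotone, and the dendrogram
constructor enforces non-decreasing merge heights. The test suite checks
the implementation two independent ways: an O(n³) oracle that recomputes
every cluster-average from the original matrix at each step, and scipy's
`linkage(..., method="average")` as a cross-library check. scipy is never
the implementation path.

## Pathways

The connectivity matrix counts DNs with an input-type (default smooth)
process in brain neuropil *b* and an output-type (default varicose)
process in VNC neuropil *v*; both filters are configurable because the
polarity convention for such maps is a modeling choice. A DN innervating
several VNC targets contributes to every target's grouped map
(non-exclusive grouping, logged), so grouped totals may exceed the catalog
size. The convergence index of a VNC target is the Shannon entropy
(natural log, `0·log 0 ≡ 0`) of its brain-source distribution, normalized
by `log` of the number of brain compartments with any nonzero count in the
matrix: 0 = single source, 1 = uniform over active sources.

## Census arithmetic

Percentages use half-up rounding (`percent_round`), not banker's rounding;
this is the convention that reproduces the published worked fractions
(e.g. 46/131 → 35%, 121/190 → 64%). Coverage against a photoactivation
census maps soma groups to clusters as anterior = {a, b, c, d},
posterior = {p}, GNG = {g}; group x (soma outside the brain) is excluded
because a brain-surface census cannot contain it.

## Axis profiles

A labeled volume is reduced to counts of neurite voxels per half-open bin
`[k·w, (k+1)·w)` µm from the volume origin, default `w = 1` µm, along the
anterior–posterior axis; soma- and axon-labeled voxels are excluded. How
those labels were produced is an input contract, not something the package
infers. The center of mass is the count-weighted mean bin position on
*raw* counts — max-normalization is for display only and would not change
the COM anyway, being a uniform per-profile rescaling. The two-class
comparison (dorsal- vs leg-projecting) is a Wilcoxon rank-sum on COMs with
an exact permutation p-value when the number of assignments is ≤ 20 000,
Monte-Carlo (seeded, 10 000 draws) otherwise; the statistic reports which
class sits more posterior. This test is an extension beyond a purely
graphical trend and is labeled as such in results.

## Synthetic generator

The generator emulates the coarse, published architecture of the DN
projectome, not any real innervation table:

- ~98 types split across four classes: 30 dorsal-direct (IPS/SPS →
  neck/wing/haltere, soma biased to the posterior p-group, MTD-heavy
  tracts), 30 leg-direct (GNG → the three leg neuromeres, g-group,
  ITD-heavy), 20 convergent (6 sources drawn from a broad 16-neuropil pool
  → tectulum/lower tectulum), 18 unstructured;
- block innervation Bernoulli(p_in = 0.9), background Bernoulli(p_bg =
  0.05); brain entries are smooth, VNC entries varicose;
- 64% ipsilateral laterality; 20% population types with pair counts
  uniform on 2–10 (so a default catalog carries roughly 190–200 pairs);
- all draws come from per-class substreams spawned from one seed in config
  order, so appending a pathway class never changes earlier classes'
  records.

What the generator does *not* emulate: correlated innervation within a
type beyond the block structure, sub-neuropil geometry, polarity mixtures
(`both` codes), soma-position/pathway correlations beyond a coarse bias,
or the empirical breadth distribution. Tests passing on synthetic data
therefore certify the *pipeline* (that planted structure of the stated
strength is recovered), not any claim about real anatomy.

Nomenclature caps a soma group at 99 types; configurations exceeding that
are rejected as infeasible rather than silently renamed. Marginal
convergence checks (e.g. the 64% ipsilateral fraction against a 99%
binomial interval) therefore aggregate across seeds instead of generating
one huge catalog.

Recovery is scored with the adjusted Rand index computed from its
contingency-table definition (cross-checked against scikit-learn in
tests). The benchmark condition — 30+30 direct-pathway types, p_in = 0.9,
p_bg = 0.05, VNC-output matrix, correlation distance over type rows, UPGMA
cut at k = 2 — attains ARI ≥ 0.9 against the planted labels in ≥ 95 of
100 seeds, and the two largest (brain group → VNC group) aggregate blocks
are the planted posterior-slope→dorsal and GNG→leg pathways at the same
rate.

## Problem sizes and numerics

The validation suite uses the sizes at which exhaustive oracles are
practical: naive-UPGMA equivalence on 200 random matrices with n ≤ 12,
recovery rates over 100 seeds of 60-type catalogs, bipartite consistency
over 100 random 10-type catalogs, and 5000-voxel masks for axis profiles.
Floating-point comparisons in the clustering path use absolute tolerances
of 1e-9–1e-12; correlation values are clipped to [−1, 1] against rounding
spill. All randomness flows from explicit integer seeds.

## Real-annotation statistics

Summary statistics of the deposited per-type annotation table (mean brain
input breadth 2.7, mean VNC output breadth 1.9, 78% of types with varicose
GNG processes, 6% with wing-plus-leg projections) are implemented and run
against a transcription of that table placed at `data/supp1_catalog.csv`
in the catalog CSV schema. The table is not redistributed with the
package, so the corresponding acceptance test fails with a pointer until a
transcription is supplied; every other check runs self-contained.
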