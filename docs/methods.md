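# Methods

This note documents the models, default parameters and design decisions
behind `topostrat`, and what the synthetic test bed does and does not
establish about behavior on real data.

## Clinical cohort model

Subjects carry six clinical features in fixed order: ADHD index,
inattentive score, hyperactive/impulsive score, full-scale IQ, verbal IQ,
performance IQ. The synthetic generator draws, per latent group, the five
*primitive* features (two symptom subscales, three IQ scales) from a
multivariate normal with configurable within-block correlations — default
0.5 between the symptom subscales and 0.6 among IQ scales, with the two
blocks independent — scaled to the group's marginal mean/SD. The ADHD
index is then computed as the **exact sum** of the two subscales, matching
the arithmetic structure of the rating instrument (the published group
summaries are consistent with this identity up to rounding: one group
prints an index mean of 44.1 against subscales summing to 44.2). Two
consequences are deliberate:

* the preset's index-mean and index-SD slots are informational — the
  realized index distribution is implied by the subscales and the symptom
  correlation (e.g. subscale SDs 1.9/2.1 with r = 0.5 imply an index SD
  near 3.5, not the printed 2.9);
* setting all SDs to zero collapses every subject onto the group mean and
  the index identity holds exactly, which the tests exploit.

Default presets (`principal_cohort_specs`) carry the published per-group
summaries for typically developing controls (TDC), a mild-symptom group
(mADHD) and a severe-symptom group (sADHD). Cohort sizes default to
15/15/15 (matching the published F_{2,42} analyses); topology-recovery
experiments use 60/30/30, since the TDC arm of the real sample was about
twice the size of each patient subgroup. Age is drawn normally per group
and carried into the phenotype table as the default ANCOVA covariate.

## Patient-patient network (Mapper)

Normalization uses the **population** SD (divide by N) over the reference
rows; "variance normalization" intends a z-score and a single reference
subject is rejected (zero scale). Distances are Euclidean over all six
z-scored features; the lens is L-infinity centrality (row maximum of the
distance matrix). The pipeline is deterministic throughout — no random
seeds enter the topology.

The cover places `n_intervals` uniform-width intervals over the lens
range, each widened symmetrically so adjacent intervals overlap by
`overlap_frac` of their widened width. Within an interval, subjects are
clustered by single linkage; the dendrogram is cut at the **first gap** in
a `cluster_bins`-bin histogram of merge heights — the first empty bin
after the populated region begins. Leading empty bins must not trigger a
cut (they only indicate that the smallest merge is not tiny; cutting there
would shatter the preimage into singletons). Singleton clusters produced
by a cut are reattached to the nearest multi-member cluster: a lone
subject at the edge of a blob is an outlier of that blob, not a subgroup.

Defaults: `n_intervals = 4`, `overlap_frac = 0.45`, `cluster_bins = 3`.
These are deliberately coarse. On reference-normalized clinical data the
relevant scales separate cleanly — within-blob single-linkage heights run
to about 3 z-units while between-blob distances run 4–20 z-units — and a
three-bin histogram makes the cut fire only on order-of-magnitude jumps
(distinct blobs sharing an interval) while tolerating the tail of
within-blob merge heights. Wide intervals matter for the junction: the
three groups' lens ranges overlap only in a narrow band (patients with
mild symptoms sit at the lens minimum; controls and severe-symptom
patients both reach the maximum), and the Y-shaped topology forms only
when one interval contains enough members of all three groups for
single-linkage chaining to produce the mixed junction node. Finer covers
(10–12 narrow intervals, 10 histogram bins) fragment this data into
dozens of components and recover the three-branch structure in none of 50
synthetic cohorts; the shipped defaults recover it in 49/50 (and 96–98 of
100 held-out cohorts). All three parameters remain configurable.

Flares are the connected components left after deleting junction nodes
(degree ≥ 3); a component without a junction is one flare. Each flare's
majority group label breaks ties alphabetically. Peripheral selection
takes the k (default 15) members at the branch's **outward** end: a branch
that climbs in lens value away from its junction is ranked by largest
lens value, one that descends by smallest (`direction="auto"` in the
pipeline compares the tip and attachment nodes; the standalone operation
defaults to "high"). Extreme lens values sit at branch tips at *both* ends
of the lens range — for the mild-symptom branch, which occupies the lens
minimum, the largest-lens members would be the junction-adjacent, least
typical ones.

## Connectome arm

Scrubbing removes exactly the frames with framewise displacement strictly
above threshold (default 1 mm), no neighbor augmentation; a frame at
exactly the threshold is kept. FD is consumed as given (the upstream
preprocessing pipeline ships it); a Power-style helper (`power_fd`,
rotations × 50 mm) exists for completeness. Pearson networks set the
diagonal to 1 and refuse zero-variance ROIs by name.

Centralities and modularity operate on the positive part of `R` (negative
off-diagonal entries dropped, no self-loops); group-representative
networks are the elementwise mean of subject matrices on the raw r scale
(Fisher-z averaging available behind a flag but not default — group
matrices feed modularity, where the raw mean is the observed convention).
Betweenness uses the 1/weight length transform (stronger correlation =
shorter path) on weighted graphs, unnormalized fractional counting;
PageRank treats each undirected edge as two arcs, damping α = 0.85,
uniform teleportation; strength is the weighted degree.

FCD deliberately uses the **signed** matrix: between-network coupling is
often negative and the sign is the finding. Intra-module FCD of a
single-ROI module is undefined and reported as missing. Module partitions
are estimated on group-mean graphs; per-subject FCD is computed against
one reference group's partition (the mild-symptom group in the original
analysis; a flag in the CLI).

Consensus Louvain runs `n_runs` (default 1000) seeded optimizations and
returns the run maximizing mean pairwise NMI (arithmetic-mean
normalization; geometric/min variants selectable) against all other runs,
ties broken by higher Q then lower seed. Identical partitions are pooled
before the quadratic NMI stage, which keeps 1000 runs cheap on
well-modular graphs. The Louvain resolution is fixed at 1.

## Synthetic time-series model

ROI series are i.i.d. frames from a block correlation matrix: one target
correlation per module (intra) and per module pair (inter), validated
positive semi-definite at construction. The default layout plants five
networks over 90 ROIs — DMN 22, ECN 20, SN 16, VN 14, BGN 18 — a
synthetic stand-in parcellation (module identities are assigned by
construction, not anatomical lookup). Default scan length is 236 frames,
the resting-state run length of the emulated acquisition. The fixed
default targets reproduce the observed module-connectivity pattern (intra
0.28–0.39; inter −0.20 to +0.06); a jittering sampler draws targets
uniformly from the observed ranges (intra 0.24–0.40, inter −0.20–0.07),
rejecting configurations that are either non-PSD or **not modular in
expectation** — if a sampled between-module correlation is positive and
comparable to the intra values, merging those modules has higher expected
modularity than the planted split, and no Q-maximizer can (or should)
return the planted labels. Planting such a structure would test the
optimizer against a wrong answer.

What the generator does *not* emulate: temporal autocorrelation of BOLD,
hemodynamics, spatial smoothness, physiological noise, site effects, or
real anatomical module boundaries. Passing recovery tests therefore show
that the pipeline's inference machinery is correct under its own model
assumptions, not that five networks are recoverable from any real scan.
Motion injection adds white spikes (scale 5 SD by default) to frames
flagged in a supplied FD profile, so scrub-then-correlate can be checked
against the clean run.

## Statistics

`anova_from_summary` reconstructs the one-way F from per-group mean,
sample SD (ddof = 1) and n: SS_between = Σ n_g(m_g − grand)², SS_within =
Σ (n_g − 1)SD_g². It agrees exactly with the raw-data F whenever the raw
sample carries those moments, which is what makes published summary
tables checkable (to the precision their rounding allows — the shipped
checks use ±5%). ANCOVA is the nested-OLS extra-sum-of-squares F with
covariates always retained (default covariate: age); collinear covariate
matrices are rejected by rank check. Post-hoc tests are pooled-variance
Student t with the p-value multiplied by the number of pairs (capped at
1). BH correction is the standard step-up procedure over one measure
family at a time — the 15 FCD measures, or all ROIs within one centrality
measure.

Calibration facts the suite verifies by simulation: the omnibus ANOVA
type-I error at α = 0.05 lies in 0.05 ± 0.01 over 10,000 null replicates;
under the global null the BH false-discovery proportion is an indicator
(all discoveries false), its expectation equals q exactly, so the check
allows the three-sigma Monte Carlo margin above q rather than pretending
the boundary value sits strictly below it.

## Numerical choices and edge cases

* Mapper interval membership is boundary-inclusive; empty intervals are
  skipped; a zero-range lens yields a single interval.
* Single-linkage heights of exactly 0 (duplicate subjects) yield one
  cluster without histogramming.
* NMI is clipped into [0, 1] (floating error in the sklearn backend can
  overshoot 1 by ~1e-16, which would break exact `== 1` recovery checks).
* PageRank non-convergence raises rather than returning a partial vector.
* Modularity on an empty or zero-weight graph raises.
* Flare ordering from a junction is breadth-first from the attachment
  nodes, ties by node key; peripheral ties break by subject id.

## Known limitations

* The flare definition (junction = degree ≥ 3) is an operationalization;
  the original branch reading was partly visual. Graphs whose arms touch
  in two places (cycles) can merge flares.
* Cover defaults are tuned to reference-normalized clinical data where
  between-group separations are several z-units; data without that scale
  separation will need different `CoverConfig` values.
* The three-branch recovery rate is a property of the preset effect sizes
  (very large symptom separations); cohorts with weaker separation will
  fragment or merge branches.
* Group-level centrality statistics operate on per-subject graphs, not
  the group-mean graph (the mean graph only anchors module partitions).
* No overlapping communities, no resolution sweep, no negative-weight
  graph analytics.
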