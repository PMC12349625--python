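# Methods

## Data model

A dataset is a set of diploid individuals, each assigned to exactly one
population, typed at L codominant SSR loci. A call is an unordered pair
of allele labels (canonically integer fragment sizes in base pairs);
the label 0 — or an empty cell — is the missing sentinel and never
counts as an allele. Half-calls (one allele present, one missing) are
rejected rather than silently coerced to missing, because they usually
indicate a genotyping or transcription error worth surfacing. Allele
labels are compared after integer normalization ("150" equals 150); no
fragment-size binning is performed — binning belongs upstream, in the
allele-calling software. Population order is the order of first
appearance in the input and locus order is column order; all reports
preserve both.

## Diversity indices

For one population at one locus, frequencies are simple counts over the
`2·N_l` observed gene copies, where `N_l` is the number of individuals
with a non-missing call there. The realized `N_l` — not the nominal
population size — enters `Ho` and the unbiased correction
`uHe = (2N_l/(2N_l−1))·He`, as unbiased estimation requires. The
Shannon index uses natural logarithms, with `p ln p = 0` at `p = 0`.
The indices obey the Hill-number ordering `Ne ≤ e^I ≤ Na` in every
cell; this is asserted as a property test.

The fixation index `F = (He − Ho)/He` is 0/0 at a fixed locus and is
therefore reported as undefined there; a population's mean F averages
only the loci where F is defined, rather than counting fixed loci as
zero. (This matches the convention of the widely used spreadsheet
packages for SSR data, and it is why a tabulated mean F can differ from
`(He̅ − Ho̅)/He̅`.) The percentage of polymorphic loci counts loci with
at least two observed alleles, over all L loci — a locus with no data
in a population counts as non-polymorphic for that population. Grand
means across populations are unweighted means of the per-population
means, with the sample-size column averaged the same way.

Rendered tables round half-away-from-zero to 3 decimals; all TSV
outputs also exist at full precision, because 3-decimal tables are for
reading, not for computing.

## F-statistics and gene flow

Per locus, over the populations with data there (populations with
`N_l = 0` are dropped from that locus and the count used is recorded):
`Hi` and `Hs` are unweighted population means of `Ho` and `He`, and
`Ht = 1 − Σp̄²` with `p̄` the unweighted mean of the per-population
frequency vectors. Then `Fis = (Hs − Hi)/Hs`, `Fit = (Ht − Hi)/Ht`,
`Fst = (Ht − Hs)/Ht`. This is the gene-diversity (Nei 1977) family
with unweighted means and no small-sample correction of Hs or Ht — the
convention of the standard SSR spreadsheet software — rather than the
Weir–Cockerham variance-components estimator. Two consequences are
asserted in tests: the partition identity `(1−Fit) = (1−Fis)(1−Fst)`
holds to 1e-9, and `Ht ≥ Hs` (concavity of `1 − Σp²` under frequency
averaging) so `Fst ∈ [0, 1]`. Because Hs and Ht are uncorrected plug-in
estimates, Fst is biased upward at small sample sizes; the parameter-
recovery test at N = 20 per population absorbs this in its ±0.05 band,
and hierarchical scenarios show it more strongly.

`Fis` is undefined when `Hs = 0`, and all three are undefined at a
locus that is monomorphic overall (`Ht = 0`). Gene flow is the
island-model estimate `Nm = (1 − Fst)/(4·Fst)`, undefined at
`Fst = 0` and 0 at `Fst = 1`. Table aggregation reports the unweighted
column mean and the standard error (sample SD over √n of the defined
values); undefined cells are excluded with a logged warning, and a
single-row table has SE 0 by convention.

## Nei's unbiased distance

Per shared locus, `J_AB = Σ xᵢyᵢ` and the unbiased within-population
identities `Ĵ = (2N·Σp² − 1)/(2N − 1)`; the distance is
`D = −ln(J̄_AB/√(J̄_A·J̄_B))` with arithmetic means over the shared
loci. Loci missing in either population are excluded pairwise (not
listwise), maximizing data use. Three edge cases:

- the unbiased correction can push D slightly negative for very similar
  populations; such values are clamped to 0 with a warning, since the
  downstream clustering needs a dissimilarity and small negatives are
  sampling noise;
- `J̄_AB = 0` (no shared allele anywhere) gives `D = +∞`; the written
  matrix preserves `inf`, and a finite sentinel (10× the largest finite
  entry) is substituted only for clustering, so the singularity is not
  hidden;
- a single-individual population heterozygous at every shared locus has
  `Ĵ = 0` everywhere — the unbiased estimator has no anchor — and the
  pair is reported as an error naming the populations rather than a
  number.

## UPGMA and tree cutting

True average linkage (UPGMA, not WPGMA): on merging, distances update
by the cluster-size-weighted rule, equivalent to the mean of all
original inter-leaf distances. Merge height is half the merged
distance, so cophenetic distance between two leaves is twice the height
of their lowest common merge; the output is ultrametric with
non-decreasing heights. Ties on the minimal distance are broken by the
lexicographically smallest pair of cluster representative labels
(representative = smallest contained leaf label), making the merge
history deterministic across platforms. Newick serialization writes
branch lengths as height differences, orders each node's children by
their smallest contained leaf in input order, and single-quotes labels
containing spaces. The k-cluster cut undoes the last k−1 merges; if the
cut falls inside a run of tied heights the result is still
deterministic (merge order decides) and a warning is logged.

## Synthetic data generator

The generator emulates the sampling regime of a multi-gorge wild-stand
survey: per locus an ancestral frequency vector is drawn from a
symmetric Dirichlet(1), and each population's vector from a Dirichlet
with that mean and concentration `(1−θ)/θ` (Balding–Nichols), so θ is
directly the target Fst. Genotypes are drawn with inbreeding f:
for `f ≥ 0`, `P(hom i) = pᵢ² + f·pᵢ(1−pᵢ)` and
`P(het ij) = 2pᵢpⱼ(1−f)`; for `f < 0`, heterozygote probabilities are
inflated by `(1−f)` over Hardy–Weinberg homozygote terms and the vector
renormalized. The renormalization attenuates the realized fixation
index to `1 − (1−f)/(1 − f·He)` per locus, so realized |F| is smaller
than |f| (about −0.1 at f = −0.3, He = 0.6); the direction, not the
magnitude, of heterozygote excess is the modeled feature. Calls are
masked missing independently at the configured rate; everything is
reproducible from the seed.

Defaults mirror the study design the package is aimed at: 11
populations with sizes (3, 18, 1, 6, 5, 1, 3, 6, 3, 4, 4) — 54
individuals — and 13 loci. The gorge scenario groups these into three
geographic clusters (Pop1–4, Pop8–10, Pop5–7+Pop11) with between-gorge
θ = 0.25 and within-gorge θ = 0.05. Its free parameters were fixed
once at 6 alleles per locus and f = −0.3, matching the observed regime
of up to ~5.8 alleles per population and a negative mean fixation
index. The single-individual fixture builder creates the exact
configuration implied by a published N = 1 summary row: one individual
heterozygous at a chosen number of loci, from which every index follows
in closed form (e.g. mean I = h·ln 2/L, mean Na = (L + h)/L).

What the generator does **not** emulate: stepwise mutation (allele
identities are abstract; the statistics use identity-in-state only),
linkage between loci, coalescent genealogies, and spatial continuity
within gorges. Passing tests therefore demonstrate estimator
correctness and structural recovery under the stated frequency model,
not robustness to those real-data features.

## Problem sizes and numerical choices

Property suites run on small random datasets (≤5 populations, ≤6 loci,
≤10 individuals, 4-allele pool) with seeded generators; parameter
recovery uses 10 seeds of 11 populations × 20 individuals × 13 loci at
θ = 0.2 (±0.05 band on the mean Fst), 10 seeds of the gorge scenario
(3-cluster recovery required in ≥9 of 10), and 500-individual
single-population draws for the random-mating check (mean F within
±0.05 of 0). These sizes keep the whole suite a few seconds long while
leaving the Monte-Carlo bands comfortably wide. Frequencies sum to 1
to 1e-12 by construction; the partition identity is asserted to 1e-9;
UPGMA oracle agreement to 1e-10.

## NDVI

`(NIR − RED)/(NIR + RED)` as pure array arithmetic over co-registered
reflectance bands, with zero-signal pixels (NIR + RED = 0) masked
invalid and an input validity mask propagated. Bounded in [−1, 1] and
invariant to common positive rescaling of both bands. No
georeferencing, raster file parsing or orthophoto processing: plot-level
NDVI values from a specific survey depend on imagery this package does
not ship, so only the formula's guarantees are testable.

## Known limitations

- The F-statistics are the uncorrected gene-diversity estimators;
  comparisons with variance-components Fst (Weir–Cockerham) will differ,
  especially with unbalanced small samples.
- Distances involving near-singleton populations are noisy, and the
  clamp-to-zero rule flattens very small distances among close
  populations, which can make within-cluster branching arbitrary even
  when between-cluster structure is recovered reliably.
- Mean F over populations of wildly different sizes is an unweighted
  mean, by design; it is not an estimate of a global inbreeding
  coefficient.
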