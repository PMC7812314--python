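# Methods

This note records the models, parameter choices and limitations behind
`maldimatch`, in the order the pipeline runs.

## Problem setting

Two tissue conditions (a control and a diseased/transgenic "case") are
measured twice: by MALDI-TOF imaging mass spectrometry (IMS) of in-situ
tryptic peptides on one section (singly charged ions, 600–3,200 Da,
centroided, mass accuracy about ±0.1 Da, 25 μm pixel pitch), and by
shotgun LC–MS/MS of serial sections quantified as a peptide table with 3
replicates per condition. The goal is to assign each deisotoped IMS mass
to the parent protein of the shotgun peptide it most likely represents.

Two working assumptions carry the identification step: peptides of
relatively higher shotgun abundance are preferentially detected by
MALDI-TOF imaging, and a spatial cluster that occurs in the tissue of one
condition should be searched only against peptides classified to that
condition.

## Isotope model

Peptide isotope patterns are predicted from mass alone with the averagine
composition (C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da).
Relative isotopologue abundances are Poisson with rate λ = c·M, where
c ≈ 5.36·10⁻⁴/Da is the summed +1-isotope abundance of the scaled
composition. The isotope spacing is 1.00235 Da — the averagine average
for 1+ peptides, deliberately not the pure ¹³C–¹²C difference
(1.00335 Da). The test suite checks this approximation against an exact
per-element isotope convolution; both place the point where the second
isotope peak overtakes the monoisotopic peak between 1.8 and 1.9 kDa, so
the "monoisotopic peak is the maximum below 1,800 Da" rule holds in both.

## Segmentation

Spectra are binned into half-open 0.1 Da bins (left-inclusive: a peak on
a boundary belongs to the higher bin), TIC-normalized to the dataset mean
total ion current (keeping the acquisition scale), square-root
variance-stabilized, and clustered with Ward linkage on Euclidean
distances. Neither linkage nor normalization is dictated by the problem;
Ward/Euclidean with TIC is the common imaging-MS default and both are
exposed as parameters. Bins occupied in under 1% of pixels are dropped
before computing distances — sporadic single-pixel noise bins triple the
column count while carrying no clustering signal. For datasets above
5,000 pixels the dendrogram is built on a seeded random subsample and the
remaining pixels are assigned to the nearest cluster centroid; exact mode
is a parameter away. The number of clusters is a user choice: in real
tissue the cut is chosen by comparing cluster maps with histology, a
judgment the software does not automate.

Cluster-discriminative masses use the ROC criterion: per bin, the AUC of
in-cluster vs out-of-cluster per-pixel intensities (equal to the
Mann–Whitney statistic over n₁·n₂, ties one half), reported at AUC ≥ 0.7,
one-sided — a bin depleted in the cluster is not a marker of it. Ties in
the ranking break by ascending m/z.

## Deisotoping

Cluster-level peaks are built from the raw per-pixel centroids of the
cluster's pixels: pooled, sorted, split into groups wherever consecutive
m/z values differ by more than 0.02 Da, and further split where a group
is multimodal (weighted 1-D 2-means, accepted when the component means
separate by at least 2.5× the 0.04 Da centroid scatter, recursively).
Groups present in fewer than 5% of the cluster's pixels are discarded as
noise. Each group yields one peak: intensity-weighted mean m/z, mean
per-pixel intensity, and an ion-image vector over the cluster pixels.

Envelope assembly is greedy, ascending in m/z, with no peak reuse. Peak q
joins the envelope anchored at mono mass m when (i) it lies within
±0.15 Da of the next expected isotope position m + k·1.00235; (ii) its
intensity is within ±50% (relative) of the averagine-expected intensity
for isotope k — the tolerance is interpreted against the averagine
prediction, since "within 50%" needs a reference, and this choice is
configurable; (iii) its ion image correlates with the anchor's at Pearson
r ≥ 0.7. A zero-variance image counts as not co-localized. Singleton
peaks become their own monoisotopic entries. An exhaustive
partition-search mode exists for small instances and is used in tests to
confirm the greedy result. Per-cluster lists are pooled into a unique
list deduplicated at ±0.1 Da. Co-localization can alternatively be
declared by cluster co-membership (`coloc_mode="co-membership"`);
explicit image correlation is the default.

Known limitation: two peptides of the same region closer than ~0.1 Da
(2.5× the centroid scatter) cannot be separated at this mass accuracy;
they merge into one entry whose centroid lies between them. No
least-squares decomposition of overlapped envelope intensities is
attempted — overlaps are separated spatially or not at all.

## Shotgun statistics

All tests run on log₂ intensities; a zero intensity in the MaxQuant-style
table means missing. Missing values are drawn per sample column from
Normal(mean − 1.8·sd, (0.3·sd)²) over that column's observed values —
the conventional down-shifted imputation for censoring below the
detection limit. Observed cells are never altered; a column with fewer
than 3 observed values is an error.

The moderated t-test shrinks each peptide's pooled within-group variance
s² (d = n₁+n₂−2 df) toward a prior s₀² with d₀ prior df:
s̃² = (d₀s₀² + d·s²)/(d₀ + d), t = Δmean/(s̃·√(1/n₁+1/n₂)), p from a t
distribution on d₀ + d df. The prior is estimated by moment matching on
log variances: e = log s² − ψ(d/2) + log(d/2) has variance
ψ′(d/2) + ψ′(d₀/2), so d₀ comes from inverting the trigamma function and
s₀² from the mean of e. Setting d₀ = 0 reproduces the ordinary pooled
t-test exactly; homoscedastic data drive d₀ → ∞ and the statistic becomes
a z-score against s₀². The implementation is cross-checked in the test
suite against Bioconductor limma on the same matrix (prior, t and p agree
to ≤10⁻⁴ relative). p-values are floored at 10⁻³⁰⁰ so downstream ratios
stay finite.

Fold change is computed on the linear scale after back-transforming:
log₂FC = log₂(μ_case/μ_control) of the group means, positive → case,
negative → control, zero or non-positive means → unclassified. The means
enter after imputation (the alternative is a documented open choice).

Protein-level filters: a protein is present in a condition when at least
one unique peptide is observed (not imputed) in ≥2 of 3 replicates of
that condition, giving the shared/exclusive partition of the two
proteomes; a shared protein is enriched when its per-animal ratio exceeds
4 (strictly) in ≥2 of 3 animals. Because the animals of the two
conditions are distinct individuals, the default compares each case
animal with the mean of the control group; pairing by replicate index is
available (`paired=True`). Over-representation uses the upper-tail
hypergeometric p = P(X ≥ k) with X ~ Hypergeom(N, K, n), term sets
intersected with the universe first, Benjamini–Hochberg adjusted
(the only multiplicity correction shipped).

## τ-search and MLP score

A deisotoped IMS mass matches a peptide when
|m/z − (neutral mass + 1.007276)| ≤ τ, τ = 0.1 Da by default, restricted
to peptides whose condition label equals the cluster's declared
condition. The cluster→condition declaration is a user input, mirroring
the histology judgment; the simulation harness derives it from the
planted truth by majority overlap.

The MLP score is μ·|log₂FC|/p. Two readings of the formula were possible
and both are implemented: the ratio in p (default — a more confident
peptide must score higher, which requires p in the denominator) and the
absolute value of the fold change (default — the score must be positively
oriented for both conditions inside the group-restricted search space; a
`signed` mode evaluates the formula literally). μ is the peptide's mean
linear-scale intensity over the replicates of its own condition, and p is
the unadjusted moderated p-value; both are configurable. Ties break by
larger μ, then smaller |mass delta|, then lexicographic accession. An
assignment whose runner-up scores within 2× of the winner is flagged
ambiguous; the flag never changes the winner.

## Synthetic data generator

The generator's defaults are the emulated study conditions: 700 proteins
with 2–5 tryptic peptides each, 20% of proteins differential at
log₂FC = ±3 (a proteome is mostly unchanged between conditions; the
differential set is a minority), base abundances log₂ ~ Normal(25, 2),
replicate noise SD 0.5, two conditions × 3 replicates. Missingness is
logistic in log₂ intensity around the 10% detection-limit quantile
(steepness 1.5 log₂ units), which yields missing-not-at-random censoring
of low-abundance peptides at an overall rate near 15%.

The IMS side renders 300 of the differential peptides — those whose
planted direction matches their region's condition, with a +2 log₂
abundance boost reflecting abundance-biased MALDI detection — on a 64×64
grid partitioned into 3 contiguous Voronoi regions. Each peptide appears
in every pixel of its region as a 4-peak averagine envelope at
MH⁺ = mass + 1.007276, with per-peak centroid error Normal(0, 0.04 Da)
(±0.1 Da ≈ 2.5σ), a log-normal per-pixel gain (σ = 0.3, exercising TIC
normalization), a log-normal spatial abundance texture per peptide and
pixel shared by all of its isotope peaks (σ = 0.5) — the signal
co-localization relies on — and independent per-peak detection noise
(σ = 0.15). Five uniform-m/z baseline noise peaks per pixel are added.
Each imaged peptide gets 3 decoy rows in the shotgun table: near-isobaric
(within ±0.07 Da of the target), 3–4 log₂ units less abundant, with fold
changes drawn like any other protein — the ambiguity the MLP score must
resolve. All outputs are a deterministic function of the seed.

What the generator does not emulate: chemical background structure,
spatially smooth (autocorrelated) texture, charge states above 1+,
retention-time or fragmentation information, peptide sequences consistent
with a real proteome digest (sequences are decorative K/R-terminated
strings; the mass column is authoritative), and shared peptides between
proteins beyond a 10% non-unique flag rate. Passing tests therefore
demonstrate the pipeline's correctness under the stated noise and design,
not instrument-level performance on real tissue.

## Numerical choices

- Bin boundaries, τ windows and isotope windows are compared with a 10⁻⁹
  epsilon so values sitting exactly on a boundary behave as documented
  despite float rounding.
- The trigamma inverse is solved by bracketed root finding on
  [10⁻⁹, 10⁹]; a non-positive moment target means no excess variance and
  d₀ = ∞.
- MLP scores that overflow double precision (floored p with extreme μ)
  are capped at the largest finite double.
- Pipeline outputs contain no timestamps; a re-run with the same config
  and inputs is byte-identical, and the manifest (input hashes, all
  parameters, seeds, version) suffices to reproduce a run.

## Problem sizes used in the checks

The self-checks run the default 64×64-grid scenario (300 imaged
peptides), 10,000-peptide null calibrations, 10 segmentation seeds, and a
5,000-peptide τ-search oracle — sizes chosen so the full suite and the
acceptance script each complete in minutes on a single CPU while keeping
every rate estimate's sampling error well below the margins being tested.
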