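# Methods

This note documents the models, statistical procedures and numerical choices
behind `caphier`, and what the bundled synthetic data do and do not establish
about real resting-state fMRI.

## The analysis model

A preprocessed, motion-censored BOLD series is reduced to a matrix of
retained volumes by in-mask voxels. Each voxel's time series is z-normalized
**within subject** over retained volumes (sample SD, `n−1` denominator;
`ddof=0` is available as a switch since the convention is not universal).
Zero-variance voxels are set to 0 and flagged rather than dropped, so every
subject shares one voxel space. "Zero variance" is detected relative to the
voxel's magnitude (SD ≤ 1e−8 × max |value|): normalizing a voxel whose
variation is at floating-point rounding level would amplify that jitter to
order one.

Volumes are compared by cosine distance `1 − cos`, which ignores global
scaling of a volume and places anticorrelated patterns at the maximal
distance 2 (the standard conversion; correlation-based alternatives would
also ignore additive offsets, which acts like implicit global-signal
regression). The full N × N matrix is required by exact Ward linkage; it is
computed in row blocks so transient memory beyond the result stays bounded,
and the O(N²) result itself is the practical ceiling (~1.1 GB at N ≈ 12,000
in double precision; the synthetic presets stay well below that).

Ward agglomeration follows the ward.D2 convention — Lance–Williams updates
applied to squared dissimilarities, merge heights reported on the original
scale. `scipy.cluster.hierarchy.linkage(method="ward")` on a precomputed
condensed matrix implements exactly this; the test suite pins it against a
frozen `hclust(method="ward.D2")` run and against a brute-force oracle that
recomputes cluster variance sums from raw coordinates. Tie-breaking between
equal-height candidate merges follows scipy's nearest-neighbour chain order;
ties have probability zero on continuous data and are not otherwise
canonicalized.

Cutting the tree at every level L ∈ [2, 30] yields nested partitions; a
binary tree with distinct heights contributes exactly two new member-sets
per additional level, hence 2 + 2·28 = 58 distinct CAPs for the default
range. CAP labels are `LL-OO` where the ordinal numbers clusters by first
appearance in dendrogram leaf order. That ordering convention is a free
choice (any within-level numbering is valid); the label-to-member-set
registry and the `label_alias` table let users remap published numberings
manually.

### CAP z maps

Per CAP and voxel: mean over member volumes, `SE = SD/√n` (sample SD;
population-SD switch available), `z = mean/SE`. Singleton CAPs and zero-SE
voxels are flagged undefined, not errors — singletons legitimately occur at
high cut levels. Two properties worth knowing:

- Mean maps are exactly linear along the cladogram: a parent's mean is the
  member-count-weighted average of its children's means.
- Because each subject's normalized series sums to zero, the members of a
  CAP holding a fraction *f* of a subject's volumes are negatively
  correlated within subject, and the CAP-mean SD at signal-free voxels
  shrinks by ≈ √(1−f). z maps of the large low-level CAPs are therefore
  conservatively scaled relative to a nominal N(0, 1); the effect is
  negligible for small CAPs and irrelevant to the permutation inference,
  which never uses the t reference distribution.
- The familiar |z| ∈ [3.5, 20] display window is a rendering convention and
  appears only in the plotting helper, never in analysis.

### Group occupancy

Occupancy counts volumes per subject per CAP. Within any single level the
counts partition each subject's retained total. Group location is summarized
by medians with percentile-bootstrap CIs (default 95%, 10,000 resamples,
subjects resampled with replacement within group). Group tests are two-sided
Mann–Whitney: exact enumeration when both groups have ≤ 8 subjects (cheap
and exact; note the exact method does not tie-correct), the tie-corrected
normal approximation otherwise; BH FDR is applied across the whole CAP
family. Raw counts are the default test variable; per-subject fractions are
available since censoring rates can differ by group.

### Voxel-wise group contrasts

The design at level L has one column per CAP × group cell; each volume is
one-hot. The observed statistic is a pooled-variance two-sample t treating
member volumes as observations — deliberately so, because the validity of
inference comes from the permutation scheme, not from the t reference
distribution: group labels are permuted **at the subject level**, all
volumes of a subject moving together, the only scheme consistent with
subjects as exchangeability blocks. When the number of distinct label
assignments C(S, n_A) − 1 does not exceed the requested permutation count,
all of them are enumerated (so 3-vs-3 subjects gives p values on a 1/20
grid); otherwise assignments are sampled uniformly. p = (1 + #{perm ≥
obs}) / (1 + n_perm) never returns zero. A permuted assignment that leaves a
group with fewer than two member volumes yields an undefined statistic and
is counted as exceeding the observed value (conservative). Perfectly
separated voxels give infinite t; these are capped at ±1e10 before TFCE,
which requires finite input.

TFCE enhances each direction's positive part:
`TFCE(v) = Σ_h e(v, h)^E · h^H · dh` with E = 0.5, H = 2, dh = max/100 and
26-connected components — the standard parameter set of the method. The
permuted TFCE value at each voxel forms that voxel's null (per-voxel
uncorrected p), not a max-statistic FWE correction. Closed forms used as
oracles: an isolated voxel of height h0 integrates to h0³/3, and scaling the
map by c scales the output by c³ exactly when dh scales proportionally.

Uncorrected p maps from every CAP × direction contrast are pooled into one
BH family; the reported `fdr_threshold` is the largest p(i) ≤ i·q/m.
Significance masks threshold at that pooled cutoff — the family already
contains both directions, so halving again would double-correct — while the
halved per-tail value is computed and logged because two-tailed results are
conventionally reported that way (a pooled cutoff of .004 is quoted as
p < .002 per tail). The A>B and B>A masks are disjoint by construction.

### Network-level summaries

The atlas arrives as K network z maps; each in-mask voxel is assigned to the
network with the highest |z| (ties to the lowest index, counted), voxels
with all-zero |z| stay unassigned. The networks × CAPs mean-z matrix is
biclustered for display with the same cosine/Ward machinery (zero-norm rows
or columns cannot enter a cosine distance and are appended at the end).
Percent-significant matrices divide significant voxels in a network by the
network's voxel count; the highest-decile highlight takes the 90th
percentile of *nonzero* entries pooled over both directions — including the
zeros would degenerate the decile whenever results are sparse. The ranked
report counts 26-connected components of each significant mask and formats
cells as `"57% (1298/2259)"`.

## The synthetic generator

`SynthConfig` defaults emulate a two-group resting-state study: 27 subjects
per group, 250 volumes each, 14 networks, 13.2% of volumes censored, unit
noise SD. Networks are isotropic Gaussian blobs (σ = 2 voxels, peak exactly
1 at an integer-voxel center, pairwise center separation ≥ 2.5σ) — the
smallest structure that makes max-|z| assignment and TFCE meaningful. The
analysis mask is the union of blob supports at ≥ 0.25 of peak, mirroring the
fact that network atlases in this setting are thresholded cores (a z ≈ 3.5
display floor against peaks around 14) rather than unthresholded maps.

Brain state is a two-state first-order Markov chain (symmetric stay
probability by default; an asymmetric preset reproduces a 61/39 occupancy
split), refined by sub-states drawn uniformly at each dwell onset. Sub-state
amplitude rows alternate the sign of their modulation across networks so
that no two sub-states are collinear — cosine distance can then separate
them in the noiseless limit. The group effect adds a signed offset to chosen
networks' amplitudes whenever the designated macro-state is active (with the
default table, "reduced deactivation"). Censoring is i.i.d. Bernoulli per
volume. Everything derives from one seed via spawned generators, so a config
determines its dataset bit-for-bit.

Presets: `study_preset` (the study-scale conditions), `effect_preset`
(6+6 subjects, 100 volumes, 8 networks, delta = 1 noise SD in 2 networks
during the deactivation state — a small power-analysis configuration) and
`null_preset` (its effect-free twin with a single sub-state per macro-state,
so that under the null the only between-volume variation at a voxel is
i.i.d. noise).

### What the generator does not emulate

No hemodynamic response, temporal autocorrelation, physiological or motion
noise, scanner drift, or bursty censoring; blobs are not realistic network
topographies. Consequences worth stating plainly:

- Passing tests show the *machinery* is correct (normalization, linkage
  semantics, permutation validity, TFCE arithmetic, FDR bookkeeping), not
  that clinical-versus-control differences in real data would be detected at
  these sizes.
- Per-subject normalization redistributes a state-specific amplitude offset:
  roughly half of it appears (with opposite sign) in the other macro-state's
  CAP, and within-state effect size is reduced accordingly. This is a
  property of the pipeline itself, not of the simulator.
- With few subjects per group, subject-block permutation granularity bounds
  attainable significance: with 6 per group the closest non-identity
  assignments retain two-thirds of any true effect, so only voxels with very
  large observed t can beat every permutation, and voxel-level recovery of a
  1-noise-SD amplitude offset is sparse. Detecting such effects at
  conventional FDR levels needs either more subjects or stronger effects;
  the bundled effect preset documents this regime honestly rather than
  inflating the simulated effect.

## Calibration checks

Permutation p validity is checked two ways: marginally (multi-seed average
of P(p ≤ α) under the state-bearing null stays at or below α) and
distributionally (KS uniformity at the 1% level on a signal-free null, where
voxels are independent — state-bearing nulls share per-subject normalization
offsets across voxels, so pooling their p values into one KS test would
test that dependence, not the machinery). Mann–Whitney occupancy rejections
under the null are checked against binomial bounds across the 58-CAP family.

## Defaults

| parameter | default | note |
| --- | --- | --- |
| cut levels | 2..30 | 58-CAP registry |
| permutations | 10,000 (500 in small presets) | full enumeration when cheaper |
| q (FDR) | 0.05 | pooled across all contrasts |
| TFCE | E=0.5, H=2, dh=max/100, 26-conn | standard parameters |
| bootstrap | 10,000 resamples, 95% CI | percentile method |
| exact Mann–Whitney | both groups ≤ 8 | tie-corrected normal otherwise |
| noise SD / amplitude | 1.0 / 1.0 | matched signal-to-noise |
| censoring | 13.2% i.i.d. | flagged, not deleted |
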