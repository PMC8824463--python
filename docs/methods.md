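# Methods

## Problem and model

Two independent perturbations of the same kinase pathway — an acute
small-molecule inhibitor and a tissue-specific genetic knockout of an
upstream activator — are each profiled by TMT sixplex phosphoproteomics
(3 treated + 3 control channels per run, one run per biological replicate).
A phosphosite that loses signal under *both* perturbations is a
high-confidence pathway-dependent event; sites responding to only one axis
reflect perturbation-specific (e.g. pleiotropic or kinetic) effects. The
pipeline formalizes this as a geometric classification in the plane of the
two mean log2 fold changes.

## Quantification

Per replicate, each record's ratio is
`log2(median(observed treated intensities) / median(observed control
intensities))`. Medians (midpoint rule for even counts) are robust to a
single aberrant channel. A record is eliminated when either arm has no
observed channel at all: such a record cannot yield a ratio. Zero, empty and
non-numeric intensity cells are all treated as non-detections, since an
isobaric zero readout is a missing measurement, not a measured zero.

Ratios are computed at the clustered-site level: within one replicate, the
reporter intensities of all spectra mapping to the same site cluster are
summed per channel before the median, so repeatedly sampled sites are not
double counted. Each replicate's log2 ratios are then median-centered
(normalization method was an open choice; median-centering is the standard
correction for loading differences in isobaric data and is idempotent).

## Localization clustering

Localization engines split one phosphate's probability across neighbouring
acceptor residues. Sites of a record localized to *adjacent phosphorylatable
residues* — consecutive protein positions that are each S/T/Y with no other
residue between them — are merged into one cluster; member probabilities are
summed, and clusters are retained only when the cumulative probability is
strictly above the threshold (default 0.85). "Adjacent" is read literally as
a contiguous S/T/Y run; a "within k residues" gap rule would merge
biologically distinct sites. The representative coordinate is the
highest-probability member, ties broken toward the smaller position.

Across replicates (and spectra), member sets of the same true site can
differ with the ambiguity pattern, so replicate-level aggregation and
cross-replicate matching key on the representative position; member sets are
unioned for reporting. Keying on exact member sets first and reconciling
later can create two ratios for one (site, replicate), which the merge
rejects — representative keying is the only self-consistent reading.

## Merge and region classification

Sites quantified in at least `min_replicates_per_axis` (default 2)
independent replicates on *each* axis are merged; the per-axis unweighted
mean log2 fold changes (x = inhibitor, y = knockout) are the scatter
coordinates. The replicate rule is enforced per axis because both axis means
must be supported.

Geometry (all in log2 units):

- **CENTER**: `hypot(x, y) <= center_radius` (default 0.7). A fold-change
  radius only makes sense on the log scale, where "0.7-fold change" is a
  symmetric distance about the origin.
- **Bow-tie wedge**: `sign(x) = sign(y)` and `1/F <= y/x <= F` with
  `F = bowtie_fold` (default 5) — the two log2 fold changes agree within a
  fivefold interval of correlation. Q2 = wedge with both negative,
  Q4 = wedge with both positive.
- **Q1** (knockout-dominant decrease): `y < 0` and (`x >= 0` or `y/x > F`).
- **Q3** (inhibitor-dominant decrease): `x < 0` and (`y >= 0` or
  `0 < y/x < 1/F`).
- **UNCLASSIFIED**: the rest (increases outside the wedge and borderline
  non-negative points). Up-moving off-wedge points are not forced into
  Q1/Q3 because those labels denote *dependence* (decrease) categories.

Boundary conventions are fixed for determinism: the circle and the wedge
lines are inclusive; `x = 0, y < 0` is Q1 and `y = 0, x < 0` is Q3. The
exact published wedge labeling is not recoverable from prose, so the
geometry is fully parameterized (`center_radius`, `bowtie_fold`) and the
adopted variant reproduces the stated Q1/Q2/Q3 semantics; an independent
predicate oracle over a 100×100 grid guards the implementation.

**Consistency filter.** Within a quadrant, each sign-constrained axis
(both for Q2/Q4; the dominant axis for Q1/Q3) must not contain a
per-replicate ratio of opposite sign with magnitude ≥ `inversion_magnitude`
(default 0.25). Offending replicates are reported per site. The filter is a
verdict on fixed inputs, hence trivially idempotent.

## Motif analysis

±`motif_flank` (default 6) windows around representative positions are
padded with `-` past the termini. Classes are mutually exclusive: S/T-Q
(+1 = Q); S/T-P-X-K (+1 = P and +3 = K, taking precedence over the remaining
S/T-P); centers other than S/T are OTHER. The composite "STP" class
(S/T-P-X-K ∪ S/T-P-other) is also reported, matching how "S/T-P percentage"
is conventionally quoted. Enrichment of a class in a foreground set
(default: consistency-passing Q2 sites) versus background (CENTER sites
surviving the same localization and replicate rules) uses the two-sided
Fisher exact test on the 2×2 table with BH adjustment across the classes of
one batch; the test is an addition of this package — the original analysis
reported raw percentages. Degenerate tables (an empty margin) are flagged
rather than smoothed. Frequency matrices exclude pads from denominators;
relative-proportion matrices use a pseudo-count of 0.5 per residue so
disjoint residue usage stays finite (identical sets give exact ones).

## Synthetic data: the stated world

Defaults mirror the motivating study design: 5 inhibitor-axis and 3
knockout-axis experiments, 3+3 channels, 1000 sites on 150 random proteins
(length 300–800, drawn from a vertebrate-like residue background). Class mix
is 60% CENTER, 16% Q2 and 8% each Q1/Q3/Q4 (the doubly dependent class is
about twice each single-axis class, as observed in such screens). Effects in
log2 units: Q2 ~ N(−1.5, 0.3) on both axes, Q1/Q3 ~ N(−1.5, 0.3) on the
dominant axis and N(0, 0.1) on the other, Q4 mirrored positive, CENTER
N(0, 0.05). Intensities are `base · 2^(effect·[treated] + ε)` with
`base ~ exp(N(11.5, 1))` per site and run and per-channel noise
ε ~ N(0, 0.2); channels drop out independently at 5%. Sites are spaced ≥ 16
residues so ±6 windows never collide. With probability 0.2 a site's
localization mass (0.9 + 0.1·Beta(2,2)) is split with the adjacent −1
residue (true site keeps the 0.55–0.9 share), exercising clustering without
changing the representative. Motif rates: Q2 windows get S/T-Q at 15%,
S/T-P-X-K at 15% and other S/T-P at 27% (≈ 42% total S/T-P); all other
classes 5%/3%/22% — the Q2-vs-CENTER contrasts the motif stage is meant to
recover.

**Geometric self-consistency of planted classes.** Unbounded Gaussian
effects occasionally land a site of one class inside another class's region
(a "Q3" draw inside the center circle), which would make perfect zero-noise
recovery impossible by construction rather than by pipeline defect. Planted
effects are therefore rejection-sampled until the true effect point and a
0.15 log2-unit margin box around it classify to the planted region under the
default geometry. The margin absorbs the small shift introduced by
median-centering. This is a definition of what "planting a class" means,
fixed before any test was frozen.

Optional knobs plant sub-threshold localization (`low_confidence_fraction`)
and one inverted inhibitor replicate on Q2 sites
(`inverted_replicate_fraction`) to exercise the localization and consistency
filters; both default to 0.

**What the generator does not emulate:** protein-abundance confounding,
peptide-level missingness correlated with intensity, isotope-impurity
leakage between channels, retention-time or fractionation structure, and
real phosphoproteome sequence biases beyond the planted motif rates. A green
recovery test therefore establishes the correctness of the pipeline's
arithmetic and logic on data matching its assumptions, not performance on
the real deposit.

## Numerical choices and limitations

- Ratios and thresholds are float64; medians use the midpoint rule; result
  tables serialize floats with 6 decimals (round-trip exact to 1e-6) and
  generated intensities with 4 decimals.
- Determinism: one integer seed drives three spawned RNG streams (proteome,
  effects, noise); all outputs are byte-identical across runs at a fixed
  seed, verified by hashing.
- Peptides shared between protein isoforms keep one row per mapping; site
  keys are per protein.
- The headline counts of the motivating study derive from its deposited
  tables and are not reproduced at desk scale; the package's claims are the
  property-based recoveries documented in the test suite.
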