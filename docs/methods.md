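# Methods

## The analysis problem

A two-channel droplet digital PCR (ddPCR) well partitions a reaction into
roughly 20 000 nanolitre droplets, each of which is thermocycled
independently and read out in two fluorescence channels (two fluorochromes,
e.g. a mutant-specific and a wild-type-specific probe). Data analysis has
two stages: **gating** — assign every droplet to one of the four
positivity classes NN, NP, PN, PP (first letter = Channel 1, second =
Channel 2), setting aside ambiguous droplets ("rain") — and
**quantification** — convert the gated counts into concentrations via
Poisson occupancy statistics. The motivating application is rare-mutant
detection in circulating free DNA, where the mutant (Channel 1 by
convention) may be a few percent of total template, so small gating errors
translate directly into allelic-fraction errors.

## Gating

Three classifiers are provided, in increasing order of robustness to the
cluster distortions ("lean" of the PN cluster, "lift" of the NP cluster)
seen in noisy cfDNA data:

* **Linear thresholds** (`threshold_classify`): one gate per channel;
  a droplet is positive iff its amplitude is ≥ the gate. The boundary
  counts as positive — a closed decision rule chosen so the gating is a
  partition; which way the boundary goes is immaterial in practice because
  amplitudes are continuous.
* **Four-centre k-means** (`kmeans_classify`): standard Lloyd iteration on
  raw amplitudes (Euclidean metric, no per-channel standardisation, so the
  clusters the algorithm sees are the clusters a scatter plot shows;
  standardisation is a flag). Iteration stops when the largest absolute
  centre movement falls below `tol` (default 1e-6 amplitude units — far
  below fluorescence noise, so effectively "to convergence") or after
  `max_iter` = 100 rounds. An empty cluster is an error naming the
  offending initial centre rather than a silent re-seed: on this data an
  empty cluster almost always means the seeding does not match the plate.
* **k-nearest neighbour** (`knn_classify`): majority vote among the k
  nearest droplets of a labelled training well (defaults k = 1,
  `min_vote_fraction` = 0.51). A droplet whose winning vote fraction falls
  below `min_vote_fraction` is left Unclassified. Distance ties are broken
  by training-row order, making the classifier fully deterministic.

Cluster → class naming (`assign_centres_to_classes`) is geometric: NN is
the centre with the smallest coordinate rank-sum, PP the largest, and of
the remaining two the one with larger Channel 1 amplitude is PN. Rank sums
rather than raw sums make the rule scale-free; exact ties are an error
that asks for a manual mapping instead of guessing.

**Seeding.** The default initial centres are the four corner points of the
per-channel 10th/90th amplitude percentiles — deterministic (no RNG) and
effective whenever all four clusters hold an appreciable share of
droplets. For designs where one class is rare (a low-fraction mutant
titration has almost no Channel-1-positive droplets in low-input wells),
percentile corners all land inside the populated clusters and the
partition is meaningless; in that situation centres should be supplied
explicitly, e.g. from a control well or the known assay geometry, which is
what the end-to-end tests and the acceptance script do.

**Plate-level gating.** `kmeans_classify_plate` pools all wells, fits
once, and distributes labels back. Wells of the same assay share
fluorescence geometry, and pooling lets sparse wells borrow it.

## Rain refinement

Rain droplets — intermediate fluorescence, typically partial
amplification — must be excluded from counting. Two single-pass filters
relabel droplets from {NN, NP, PN, PP} to Rain (never the reverse, and
never class → other class):

* `sd_rain`: per cluster, a droplet further than `n_sd` (default 5)
  sample standard deviations from the cluster mean *in either channel* is
  Rain. Axis-aligned by construction.
* `mahalanobis_rain`: per cluster c, droplets with squared Mahalanobis
  distance d²(x) = (x − μ_c)ᵀ Σ_c⁻¹ (x − μ_c) above a radius m_c become
  Rain. Because the sample covariance Σ_c enters, the acceptance region is
  an ellipse that follows cluster rotation, which is what separates NP
  from PP when those clusters lean into each other.

Conventions that the literature leaves ambiguous, fixed here: the distance
uses the **inverse** covariance (the only form that is scale-invariant and
reduces to Euclidean distance under identity covariance — the version
sometimes printed without the inverse is not a distance), and m_c bounds
the **squared** distance, so for a bivariate Gaussian cluster m_c is
directly a χ² quantile with 2 df. The default m_c = 30 (χ²₂ tail mass
~3 × 10⁻⁷) is deliberately permissive and **requires manual adjustment
per assay**: small enough ellipses shed the rain, large enough keep the
class. For the synthetic geometry below, m_c = 12 (the 99.75% χ²₂
quantile) is the adjusted value used in the end-to-end checks.

Cluster statistics are estimated once from the incoming labels; the filter
is a single refinement pass, not an iterated re-estimation (re-estimating
after removal would shrink the ellipses progressively and has no natural
stopping point). Classes with fewer than 3 droplets (no invertible sample
covariance; fewer than 2 for `sd_rain`) are left untouched rather than
erroring, so a nearly-empty PP class in a low-input well does not abort a
plate. Covariances with condition number above 1e10 raise an error naming
the class instead of being silently regularised.

## Quantification

Target molecules are Poisson-distributed across droplets, so with P
positive droplets among R accepted droplets of volume V µl each, the
per-channel concentration estimate is

    ĉ = −ln(1 − P/R) / V    [copies/µl],   V = 8.5 × 10⁻⁴ µl by default,

the exact inversion of the occupancy probability P/R = 1 − e^(−cV) (the
−ln(1−·) corrects for droplets holding more than one copy; at occupancy
≤ 1% it differs from the naive P/(R·V) by < 0.6%). Implemented as
`-log1p(-P/R)/V` for accuracy at small occupancy. Edge cases are explicit
errors: P = R (saturation; the estimate is unbounded and the well needs
dilution) and R = 0 (empty well).

Rain and Unclassified droplets are **excluded from both P and R** by
default: they are ambiguous, not negative. Counting them as negatives
(`exclude_rain=False` / `--include-rain-as-negative`) biases
concentrations downward; both readings are offered because instrument
software differs on this point.

Fractional abundance (mutant allelic fraction) is reported as
conc_ch1 / (conc_ch1 + conc_ch2), Channel 1 = mutant by convention; it is
undefined (None/NaN) when both concentrations are zero. Point estimates
only — no confidence intervals are computed. Summary CSVs print
concentrations to 4 significant figures; full precision is kept in memory.

## Synthetic data generator

The generator (`simulate_well`, `simulate_kras_series`) is the exact
statistical mirror of the analysis model, which is what makes recovery
tests meaningful: each droplet's true class is drawn from the independent
two-channel Poisson occupancy probabilities, amplitudes are drawn from
per-class bivariate Gaussians, and a small share of droplets is replaced
by rain placed uniformly along the segment between two randomly chosen
distinct class means with Gaussian jitter orthogonal to the segment
(rain is observed to lie *between* the main clusters).

Defaults, chosen once to resemble a realistic well-optimised duplex assay
and frozen:

| parameter | default | rationale |
|---|---|---|
| n_droplets | 20 000 | typical accepted-droplet count per well |
| droplet volume | 0.85 nl | platform default |
| cluster means | NN (2000,1500), PN (9000,1800), NP (2500,7500), PP (9500,8000) | typical amplitude-plot geometry; PN slightly raised, PP right-shifted |
| cluster sd | 300 per channel, axis-aligned | well-separated but visibly noisy clusters |
| lean/lift shear | 0 (off) | opt-in distortion of PN/NP covariances; phenomenological, not a chemistry model |
| rain_fraction | 0.001 | a few tens of ambiguous droplets per well — the sprinkle seen between clusters in a good assay |
| rain jitter sd | 150 | half the cluster sd: rain tracks the inter-cluster segments |
| copies series | 15, 60, 240, 960 copies/µl | stands for 1/4/16/64 ng of human gDNA: ~330 haploid copies per ng into a 20 µl reaction ≈ 15 copies/µl per ng |

`simulate_kras_series` (default mutant fraction 0.05, 3 replicates × 4
levels = 12 wells) reproduces a mutant-titration design: per well,
conc_ch1 = fraction × total, conc_ch2 = (1 − fraction) × total, wells
seeded as `seed + well_index` so they are independent and the plate is
bit-reproducible. Ground truth (true class per droplet, true
concentrations) travels in `plate.metadata`.

What the generator does **not** emulate: PCR efficiency/kinetics, probe
cross-hybridisation chemistry (lean/lift is a covariance shear, not a
mechanism), droplet-volume variability, or correlated rain from a common
failure mode. Passing recovery tests therefore show the pipeline is
correct and unbiased *under the model's own assumptions*; they do not
certify performance on pathological real plates, where the manual
adjustment of thresholds, centres and m_c remains the operator's job.

A known, quantifiable interaction: simulated rain near a cluster end is
absorbed by k-means and kept by the Mahalanobis ellipse, inflating both
channels' positives by a few droplets per well. At the lowest input level
(~13 true mutant-positive droplets) this raises the per-well allelic
fraction noticeably, which is exactly the regime where the real method
also needs tight, manually tuned ellipses — hence the adjusted m_c = 12
in the end-to-end checks.

## Numerical and design choices

* Amplitudes are float64 throughout; CSV parsing converts each cell with
  correctly-rounded `float()`, so write → parse round-trips amplitudes
  exactly (pandas' fast CSV float path is not correctly rounded and is
  deliberately bypassed).
* Vendor `Cluster` code map defaults to 1→NN, 2→PN, 3→NP, 4→PP, anything
  else → Unclassified, and is overridable — the vendor semantics are a
  convention, not a documented fact.
* Well names are canonicalised to zero-padded form (A1 → A01); plates
  reject duplicate wells.
* k-means and k-NN agree bit-for-bit with naive loop-based reference
  implementations on random instances (same tie-break conventions:
  argmin's lowest index, stable sort by training row).
* Problem sizes in the test-suite and acceptance checks: 200 replicate
  wells × 20 000 droplets for estimator consistency; 12 wells × 20 000
  droplets for the titration pipeline; ≥ 20 random instances ≤ 500
  droplets for oracle equivalence — sizes at which the statistical checks
  are already decisive.

## Limitations

* Two channels, four clusters only; no QX600-style multi-plex gating.
* No confidence intervals on concentrations or allelic fraction.
* Mahalanobis refinement assumes roughly Gaussian clusters;
  heavy-tailed amplitude noise will push m_c tuning toward larger values.
* The mass → concentration conversion for input series is left to the
  user (the generator speaks copies/µl, not nanograms).
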