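# Methods

This note records the scientific model behind `ganospec`, the parameter
choices that matter, what the synthetic scene generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Problem setting

Thirty-two *Ganoderma lucidum* specimens, each imaged as an intact cap and
as pressed powder, three photographs per sample, in two spectral ranges
(VNIR 385–1009 nm, SWIR 899–1695 nm). Each photograph yields a three-pixel
region of interest whose mean spectrum represents the sample; replicate
photographs are averaged. Reference chemistry (polysaccharide % by the
phenol-sulfuric assay, ergosterol % by HPLC, each reported as the mean of
three assay replicates) provides the regression targets. Enumerating
sample × form × range gives the 128 modeling records, randomly divided
115:13 into training and prediction sets (proportionally for other sizes,
train = round(n·115/128), clamped to leave at least one record per side).

## Reflectance calibration

`R = (I_raw − I_dark) / (I_white − I_dark)` element-wise. Two policies are
deliberate:

- pixels where the white frame fails to exceed the dark frame in any band
  are masked with a validity plane rather than propagated as NaN, so ROI
  extraction can reject them by name;
- reflectance outside [0, 1] is retained, not clipped; the affected
  fraction is recorded in cube metadata. Downstream models are
  scale-tolerant and clipping would bias bright-specimen spectra.

Cubes are held in memory as (row, col, band) with 0-based row-major pixel
coordinates; ENVI interleaves (BSQ/BIL/BIP) are converted on read so only
one axis convention exists internally.

## Synthetic scene generator

The generator emulates the statistical structure the analysis assumes, not
the radiometry of the instrument:

- **Concentration panel** — polysaccharide ~ U(0.5, 3.5) %, ergosterol
  ~ U(0.01, 0.30) %. These ranges bracket the reported regional means
  (producing areas with < 1 % polysaccharide at the low end).
- **Spectrum model** — a Beer-Lambert-style reflectance proxy:
  `R(λ) = baseline_form(λ) · scatter(λ) · 10^(−Σ strength·conc·G(λ))` with
  Gaussian absorption features. Ergosterol drives the 1200 nm trough
  (σ = 15 nm, 0.36 absorbance per %); polysaccharide drives C-H/O-H
  overtone features at 1300, 1430 and 1520 nm (0.022/0.032/0.024 per %);
  a concentration-independent matrix band sits at 1100 nm; VNIR analogues
  at 840 (polysaccharide), 880 (ergosterol) and 680 nm (pigment). The
  polysaccharide SWIR signature is therefore exactly three planted
  informative features, the ground truth for recovery experiments.
- **Scatter** — each physical specimen carries a broadband gain
  (σ = 1.5 %) times a smooth Legendre tilt (coefficient σ 1.2 %/0.8 %/
  0.5 %/0.3 % for degrees 1–4), shared across its three replicate
  photographs. This is the dominant nuisance of diffuse-reflectance
  imaging; it is what makes unsupervised PCA compression lossy for the
  analyte signal while leaving wrapper selection effective. The magnitudes
  were chosen so that a full-spectrum ELM lands in the low-0.9 prediction-R²
  regime the study reports for original spectra.
- **Form effect** — the cap baseline is strictly above the powder baseline
  at equal composition, and cap patches carry larger pixel-to-pixel
  brightness jitter (σ 2 % vs 0.5 %), mimicking surface texture. The
  source material is internally inconsistent about the sign of the
  pulverization effect; the generator follows the spectral-characterization
  reading (cap above powder) and exposes the sign as configuration.
- **Noise** — i.i.d. Gaussian per pixel-band, σ = 0.005 reflectance units;
  assay replicates have a 2 % coefficient of variation.
- **Grids** — VNIR 312 bands at 2 nm from 385 nm; SWIR 200 bands at 4 nm
  from 899 nm. Band counts are not documented for the instrument; these
  are configurable defaults with the documented spectral coverage.

Raw cubes are emitted by inverting the calibration equation with synthetic
white (≈ 0.95, slight spatial ripple and band profile) and dark (≈ 0.03)
frames, so calibration is genuinely exercised: at zero noise, calibrating a
generated cube recovers the planted reflectance to ≈ 1e−15.

**What the generator does not emulate:** stray light, spectral smile and
keystone, detector nonlinearity, moisture and temperature effects,
inter-analyte chemical correlation, and real absorption line shapes.
Passing recovery tests therefore demonstrates that the pipeline identifies
and exploits localized, monotone concentration–absorbance structure under
multiplicative scatter — not that it would reach the same accuracy on real
specimens.

## Wavelength selection

A chromosome is a binary inclusion mask over the grid (all-zero masks are
repaired to one random bit). Operators follow the classical generational
scheme: roulette-wheel parent selection, single-point crossover
(probability 0.8), independent bitwise mutation (probability 0.05), one
elite per generation. Defaults: population 40, 50 generations.

- **Fitness** is the cross-validated R² of a small ELM (20 hidden neurons)
  on the masked bands, averaged over 4 folds (`n_splits=1` reproduces a
  single 80/20 hold-out). The fold assignment is fixed per run; the ELM's
  hidden layer is seeded from the run seed plus the mask bytes, so a mask's
  score is deterministic regardless of evaluation order. This enables
  memoization and exact comparison against exhaustive search; fold
  averaging smooths the fitness landscape so independent runs agree on
  genuinely informative bands rather than on hold-out idiosyncrasies.
- **Roulette probabilities** are proportional to raw fitness when all
  values are positive; when zero or negative values occur the vector is
  shifted by `min + 1e−6`, preserving order.
- **Iterative selection** runs nested rounds (default 3): each round
  searches only the previous round's selected set, with a parsimony
  penalty λ·(selected fraction), λ = 0.05, so counts genuinely shrink.
  Selected sets are nested by construction. The three rounds can equally
  be read as three independent runs; both usages are a seed/config choice.
- **Voting selection** accumulates independent GA runs until 50 of them
  reach best raw validation R² > 0.7 (runs below the bar are discarded; a
  hard cap of 4×50 runs raises an error carrying the partial tally). All
  runs under one configuration share a single fixed fitness objective
  (one fold assignment per dataset), so run-to-run variation is exactly
  the GA's own randomness — initial population, crossover, mutation —
  which is what the vote aggregates over; this also lets the runs share
  one fitness cache. The constituent runs start sparse (initial inclusion
  probability 0.1) and carry a parsimony pressure (λ = 0.2, i.e. 0.2/L
  per band): without it, bitwise mutation drifts masks toward 50 %
  density, where the heavily collinear spectrum makes membership
  irrelevant and vote counts uninformative; much stronger pressure makes
  runs drop the weaker of several jointly informative features.
  Qualification always uses the raw, unpenalized score. The number of
  wavelengths kept defaults to the iterative run's final count; ties at
  rank k break toward the lower wavelength index so output is
  deterministic.
- **PCA baseline** — column-centered PCA keeping the first five
  components, components sign-fixed (largest-magnitude loading positive),
  truncated with a warning below rank.

## Regressors

- **ELM** (authored here): hidden weights and biases drawn uniform on
  [−1, 1]; hidden output `H = g(X Wᵀ + b)` with logistic sigmoid by default
  (tanh available); output weights as the minimum-norm least-squares
  solution of `H β = y` (LAPACK SVD with machine-epsilon rank cutoff — no
  explicit inverse, so rank-deficient H is handled). No output bias, per
  the classical formulation. Default 50 hidden neurons, kept below the
  ~115-record training size so the network does not trivially interpolate.
- **BPNN**: scikit-learn `MLPRegressor`, one hidden layer of 100 tanh
  neurons, lbfgs solver, 1000 iterations, initial learning rate 0.01 (kept
  in the configuration although lbfgs does not consume it).
  Non-convergence surfaces as a warning, not an error.
- **DT**: scikit-learn `DecisionTreeRegressor`; depth and split minimums
  are configuration (none are documented for the study).

## Evaluation protocol

`evaluate_model` refits the estimator with `n_repeats` (default 10)
distinct sub-seeds and reports the mean training R², prediction R² and
MSEP with the per-repeat values. Estimators whose `random_state` is left
unset are reseeded per repeat; an explicitly fixed seed makes repeats
identical. MSEP is computed on the prediction set (the pairing with
verification performance makes the train-set reading implausible). Failed
repeats are excluded with a warning and `n_effective` reports survivors.
R² = 1 − SS_res/SS_tot about the mean of the reference values; it is
undefined (an error) for constant references. Grades: > 0.90 excellent,
(0.81, 0.90] good, [0.60, 0.81] usable, < 0.60 inadequate — the published
band edges leave (0.80, 0.81] and the boundaries open; these closures are
fixed here for determinism.

## Recovery experiment

`ganospec.pipeline.recovery_experiment` is the package's summary
experiment: for each master seed it generates the default 32-sample scene,
runs calibration and extraction, splits 115:13-proportionally, and compares
full-spectrum ELM, voting-GA + ELM (k from an iterative run) and PCA(5) +
ELM on SWIR polysaccharide. A planted feature counts as recovered when a
selected wavelength lies within one Gaussian width of its center (adjacent
bands within a feature are near-collinear, so demanding the exact center
band would be arbitrary). The experiment uses population 20 / 30
generations, a desk-scale setting of the package's GA defaults (40 × 50),
and a 25-neuron evaluation ELM scaled to its ~58-record training tables;
the experiment grid and tests use smaller scenes and populations where
only interface behavior is at stake.

## Numerical choices and degenerate inputs

- One master seed drives every stage through named, independent
  substreams (concentrations, scatter, pixels, references, assay, split,
  GA population/crossover/mutation/fitness), so campaigns are reproducible
  byte-for-byte on a fixed floating-point environment.
- Chromosome length 1 cannot cross over (children are parent copies);
  length-2 crossover always cuts at 1.
- `split_train_test` uses Python's round (banker's) on n·115/128 and
  clamps so both sides are non-empty.
- Experiment-grid cell failures are recorded in-row (`error` column) and
  the run continues; grid completeness is the requested combination count
  minus logged failures.
- The leakage-safe split variant (`group_by_sample`) keeps all records of
  a physical sample on one side; the default per-record split matches the
  pooled 115:13 protocol and is the documented deviation-prone choice.

## Known limitations

- Synthetic-only validation; no instrument data accompanies the package.
- The ELM fitness makes GA selection an order of magnitude more expensive
  than filter methods; no parallelism is attempted.
- Voting's parsimony pressure and sparse initialization are package
  choices where the published description is silent; with a flat (dense)
  GA the voting tally is demonstrably uninformative on collinear spectra.
- BPNN training at 100 hidden neurons on ~60-record tables is slow and
  prone to overfitting warnings; it is included for protocol fidelity, not
  as the recommended model.
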