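# Methods

`simpull_stoich` measures the subunit stoichiometry of bait:prey protein
complexes captured by single-molecule pulldown (SiMPull) and imaged by
two-channel TIRF microscopy. A complex carries one GFP-tagged bait
(green, 488 nm) and zero or more dye-labeled prey copies (far-red,
647 nm). Under continuous excitation each fluorophore photobleaches
once, so the number of discrete, irreversible intensity drops in a
spot's trace counts the fluorophores — and hence the bound subunits —
in that complex. The quantity of interest is the oligomeric fraction:
among complexes whose green trace shows exactly one bleaching step
(a single bait), the percentage whose far-red trace shows two or more
steps (multiple prey copies).

## Synthetic acquisitions

No raw single-molecule data are bundled; every analysis stage is
validated against a generator that emulates the acquisition and carries
full ground truth.

Model and defaults:

- Imaging: 20 frames/s, 1000 frames per channel (~50 s continuous
  dual excitation), 108 nm pixels, Gaussian PSF with sigma 1.3 px.
- Photophysics: each fluorophore bleaches after an exponential waiting
  time with half-time expressed as a fraction of the movie — 1/5 of the
  total imaging time for far-red, 1/10 for green, matching how
  excitation power is tuned in practice. Realized bleach times may
  exceed the movie (the event is then censored); they are stored
  uncapped in the ground-truth table.
- Intensities: per-fluorophore step amplitudes are lognormal with mean
  120 and SD 24 camera counts, constant over the fluorophore's lifetime
  so steps are sustained; the camera adds a 200-count electronic
  baseline and 8 counts RMS Gaussian read noise. A trace-level step
  therefore has SNR ~15, which keeps a 25-count step criterion
  meaningful.
- Blinking: re-appearance of a previously bleached fluorophore at a
  uniform random time for a geometric-duration interval (mean 20
  frames), at a default rate of 0.05 upward-step events per trace per
  movie. This is why step counting must stop at the first upward step.
- Stoichiometry: one green fluorophore per complex; far-red counts
  default to P(1)=0.6, P(2)=0.3, P(3)=0.1 — a 40% oligomeric fraction,
  the regime the analysis is designed to resolve. A labeling-efficiency
  parameter thins far-red counts binomially; it defaults to 1 because
  no measured dye efficiency is available, which makes every reported
  stoichiometry a lower bound on true copy number. No efficiency
  correction is applied downstream, matching standard practice.
- Rendering: spots are pixel-integrated 2-D Gaussians scaled per frame
  by the complex's noise-free signal; Poisson shot noise applies to
  signal photons, after which the baseline offset and Gaussian read
  noise are added (the offset is electronic, not photon flux). Each
  simulated field ships with a fiducial-bead image pair related by the
  same channel-offset affine as the data.

What the generator does not emulate: evanescent-field depth, drift,
uneven illumination, EM-gain noise statistics, dye maturation, and
aggregation. Passing tests therefore demonstrate correctness of the
algorithms under idealized but realistic photophysics, not robustness
to every artifact of real acquisitions.

## Spot detection and colocalization

Detection runs on temporal-mean snapshots of the first 3, 5, 10, 20 and
50 frames. Each snapshot is band-passed with a difference of Gaussians
(sigma and 2 sigma) and local maxima above the snapshot's median plus
4.5 robust standard deviations (MAD/0.6745) become candidates; subpixel
positions are intensity-weighted centroids in a 5x5 window, and
candidates from all scales within 2 sigma of a stronger one are merged.
The multi-scale ladder exists because the two failure modes of a single
snapshot are complementary: fluorophores that bleach in the first few
frames vanish from long averages, while dim spots need long averages to
rise above noise. With one 50-frame snapshot, round-trip recovery of
dual-labeled complexes saturates near 90%; the ladder reaches ~97% with
no false pairs in seeded experiments.

A field is flagged (status `rejected`, spots still returned) when the
spot count exceeds a density cap defaulting to the physical field area
in nm^2 divided by 3e5 — about 2500 spots for a 256x256 field at 108
nm/px, i.e. a guard against aggregated or over-concentrated samples.
The cap is exposed as `max_spots`.

Channel registration fits a least-squares affine mapping far-red bead
centroids onto green ones (nearest-neighbor matching within 10 px,
>= 3 non-collinear beads required; RMS residual > 1 px raises a warning
flag). Colocalization maps far-red centroids through the registration
and pairs spots that are mutual nearest neighbors within 2 px, with
ties broken by distance then spot id; mutual-nearest pairing makes the
result symmetric in channel order and unambiguous in dense fields.

Traces are background-corrected integrated counts: per frame, the 5x5
window sum around the rounded centroid minus 25x the median of the
9x9-minus-5x5 ring. The ring median (not mean) resists bias from
neighboring spots. Spots without a full 9x9 neighborhood are flagged
and excluded downstream.

## Step counting (rule-based oracle)

Step counting runs on raw camera counts; classifier inputs are
separately Z-scored (zero mean, unit population SD over the whole
trace — population SD so the transform is deterministic and
length-independent).

Traces are segmented into piecewise-constant levels by iterative binary
changepoint splitting under a squared-error cost. A split must leave
segments of at least `min_duration` frames (default 5, i.e. 0.25 s at
20 fps — the operational meaning of "sustained") and change the segment
mean by more than 3x a robust noise SD estimated from successive
differences. Changepoints are then read in time order: a downward mean
change greater than 25 counts is one photobleaching step; the first
upward change greater than 25 counts terminates counting (blinking or
re-binding makes later downward steps unattributable). A trace whose
post-fit residual SD exceeds half the median accepted step size is
marked too noisy — the algorithmic stand-in for a human rejecting a
trace whose variability prevents seeing discrete drops.

Classes: far-red traces bin to rejected / 1-step / 2-step /
3-and-higher (too-noisy or zero-step traces are rejected); green traces
bin to 1-step only when exactly one accepted step is found, otherwise
rejected. Because counting can stop early, counts are "at least x";
binning uses the truncated count as observed.

The bleach half-time is survival-based: survival(t) is the fraction of
traces whose first accepted step falls after frame t (traces with no
accepted step are right-censored), and the half-time is the linearly
interpolated median. With mixed stoichiometries the first-step
half-time lies below the single-fluorophore half-time (minimum of
several exponentials), which is the expected behavior of ensemble
bleach curves.

## CNN step classifiers

Two 1-D CNNs classify Z-scored traces: CNN-Green (2 classes) selects
complexes with a single bait, CNN-FarRed (4 classes) counts prey steps.
The network engine is a compact, fully seeded numpy implementation
(Conv1d blocks with ReLU and max pooling, dense head, Adam, softmax
cross-entropy); at these input lengths (1000 samples) and model sizes
(~10^5 parameters) CPU matmuls train a model in minutes and every run
is bit-reproducible given its seeds.

Class imbalance is handled by inverse class frequency weighting,
w_c = N / (K * n_c), which satisfies sum(n_c * w_c) = N and gives the
rarest class the largest weight. Training uses stratified, randomized
80/20 train-validation splits; model selection trains each architecture
in a grid once on such a split, ranks by validation accuracy (ties:
macro-F1, then fewer parameters), forwards the top five to stratified
5-fold cross-validation, and picks the best mean CV accuracy. The demo
grid spans 39 configurations over kernel size {5, 9, 15}, filter count
{8, 16, 32}, dense layout {(32), (64), (64, 32)} and two learning
rates. The default architecture (two conv blocks 16/32 filters, kernel
9, pool 5, dense 64) reaches ~0.95 held-out macro-F1 on default-SNR
synthetic far-red traces; synthetic performance does not transfer to a
claim about manually labeled real traces.

Inputs are fixed at the acquisition length (1000 frames); shorter
traces are zero-padded and longer ones truncated, both with an explicit
warning. Inference is deterministic and batch-size invariant.

## Stoichiometry and statistics

The five-step pipeline: (1) Z-score far-red traces of colocalized
pairs; (2) classify them; (3) Z-score green traces; (4) classify them;
(5) retain only pairs with a 1-step green trace and a non-rejected
far-red trace. Orphan pairs (missing or border-flagged traces) are
excluded and counted; every filtering stage satisfies
input = retained + rejected + orphaned.

Summaries report far-red class percentages among retained pairs at
three levels: per technical replicate; per biological replicate (both
pooling conventions are emitted — pooled technical counts, and the mean
of technical percentages — because either is defensible); and per
genotype as mean ± SEM over biological replicates. The oligomeric
fraction is (2-step + 3-and-higher) / total retained x 100.

Genotypes are compared with a nested one-way ANOVA on
technical-replicate values with biological replicate as the error
stratum: F = MS(genotype) / MS(bio within genotype). For balanced
designs this is algebraically identical to a one-way ANOVA on
biological-replicate means (verified in tests to 1e-9). Tukey's HSD on
biological-replicate means provides adjusted pairwise comparisons.
Genotypes with fewer than two biological replicates are an error, and
F = 0 (p = 1) is returned when the between-genotype mean square
vanishes.

## Reproducibility and problem sizes

One global seed derives all per-stage seeds through
`numpy.random.SeedSequence` (CRC-stable tokens, values < 2^31), so a
full run is byte-reproducible and any stage can be re-run standalone.
Test and acceptance problem sizes — 8000 training traces, 2000-pair
stoichiometry recovery, five 128x128 round-trip fields, 200
colocalization fields, 5000-trace half-time estimates — were chosen so
Monte-Carlo error sits well inside the asserted tolerances while a full
run completes in minutes on one CPU.

## Known limitations

- Step counts are lower bounds: early stopping truncates counts, and
  unlabeled prey (efficiency < 1) is invisible. No binomial
  deconvolution of true copy number is attempted.
- Near-coincident bleach events (within `min_duration`) merge into one
  step; fluorophores surviving the whole movie contribute no step. Both
  bias multi-step classes downward by a few percent at the default
  half-times; the effect is visible in the oracle's ~93% class accuracy
  on 1-3 fluorophore traces.
- Movie-extracted traces sum 25 pixels of read noise, so step counting
  from rendered movies needs brighter steps or lower read noise than
  the trace-level defaults (the demo uses read noise 2); quantitative
  step classification is therefore validated at the trace level.
- The rule-based labels that train the CNNs come from ground-truth
  fluorophore counts, not human annotation; real training data will
  contain label noise the synthetic study conditions do not model.
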