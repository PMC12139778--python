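# simpull-stoich

Photobleaching-step stoichiometry analysis for two-channel
single-molecule pulldown (SiMPull) TIRF microscopy.

In SiMPull, protein complexes are immunoprecipitated from lysate onto a
passivated coverslip and imaged by total internal reflection
fluorescence microscopy, so each captured complex appears as a
diffraction-limited spot. With a GFP-tagged bait in the green channel
and a dye-labeled prey in the far-red channel, the number of discrete,
irreversible intensity drops ("photobleaching steps") in a spot's trace
counts the fluorophores — and therefore the protein copies — in that
complex. This package answers the question: *among complexes containing
exactly one bait molecule, what fraction contains two or more prey
molecules?* That percentage is the **oligomeric fraction**

```
oligomeric % = 100 * (#2-step + #3-and-higher far-red traces)
                    / (#retained bait:prey pairs)
```

computed over colocalized spot pairs whose green trace shows exactly
one bleaching step and whose far-red trace is not rejected.

It is written for single-molecule biophysicists who have two-channel
TIRF movie stacks (TIFF), a fiducial-bead registration image pair, and
a biological/technical replicate structure — and for anyone who wants
to study the estimator itself on fully synthetic, ground-truth-annotated
data, which the package generates.

## What's inside

| module | role |
| --- | --- |
| `simpull_stoich.simulate` | synthetic two-channel acquisitions: ground-truth complexes, exponential photobleaching (half-time as a fraction of the movie), blinking, pixel-integrated Gaussian PSF rendering, bead registration pairs |
| `simpull_stoich.detect` | multi-scale spot detection, affine bead registration, mutual-nearest-neighbor colocalization at 2 px, background-corrected trace extraction |
| `simpull_stoich.steps` | Z-score normalization, rule-based step counting (sustained >25-count drops, early stop on upward steps), class binning, survival-based bleach half-time |
| `simpull_stoich.classifier` | seeded numpy 1-D CNNs (CNN-Green: 2 classes, CNN-FarRed: 4 classes), inverse-class-frequency loss weighting, stratified splits, 5-fold CV, 39-configuration architecture search |
| `simpull_stoich.stoich` | the five-step filter pipeline, per-replicate class percentages, nested one-way ANOVA + Tukey HSD across genotypes |
| `simpull_stoich.pipeline` | seeded end-to-end runs with a JSON config and an auditable count manifest |

`docs/methods.md` describes the model, defaults and numerical choices.

## Worked example

Simulate a small acquisition, run every stage, and summarize:

```python
import simpull_stoich as ss

config = ss.demo_config("demo_out", seed=7)
manifest = ss.run_all(config)
print(manifest["stages"]["totals"])
print(manifest["stages"]["bleach_half_time"])
```

prints

```
{'complexes': 100, 'green_spots': 100, 'farred_spots': 100, 'pairs': 100,
 'traces_flagged': 0, 'orphaned': 0, 'classified': 100, 'retained': 96,
 'rejected_by_filter': 4}
{'farred_frames': 53.0, 'farred_seconds': 2.65}
```

All 100 simulated complexes were detected in both channels and paired;
96 pairs survived the filter (1-step green + non-rejected far-red). The
far-red first-step half-time (53 frames) sits below the
single-fluorophore half-time (80 frames for this 400-frame demo)
because multi-copy complexes bleach their first fluorophore sooner —
the expected behavior of a survival-based estimate over mixed
stoichiometries. `demo_out/summary_technical.csv` then holds
per-replicate class percentages and `oligomeric_pct`.

The same stages are available from the shell:

```bash
simpull-stoich simulate --out field0 --seed 1 --n-complexes 100
simpull-stoich detect --green field0/green.tif --farred field0/farred.tif \
    --beads-green field0/beads_green.tif --beads-farred field0/beads_farred.tif \
    --coloc-distance 2 --out field0/analysis
simpull-stoich label --traces field0/analysis/traces_farred.csv \
    --channel farred --step-threshold 25 --out field0/labels.csv
simpull-stoich run --config run.json
```

Training and applying the CNNs programmatically:

```python
import simpull_stoich as ss
import numpy as np

traces, labels = ss.make_labeled_traces(8000, "farred", seed=1)
z = (traces - traces.mean(1, keepdims=True)) / traces.std(1, keepdims=True)
data = ss.LabeledTraceSet(z, labels, channel="farred")
model, metrics = ss.train(data, ss.ModelConfig(), seed=5)
```

On held-out synthetic traces at default SNR this model classifies
far-red traces with ~0.95 macro-F1.

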