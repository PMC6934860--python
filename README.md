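# mcsmdr

Multidrug-resistance (MDR) profiling of head-and-neck cancer cells from
multicellular tumor spheroid (MCS) assays.

Cancer cells that overexpress ATP-binding-cassette efflux transporters
(P-gp/MDR1, MRP1, BCRP) pump chemotherapeutics — and fluorescent reporter
dyes — back out of the cell. This package turns three in-vitro readouts of
that behaviour into a per-cell-line resistance call
(*sensitive / moderately resistant / highly resistant*):

1. **Time-lapse fluorescence kinetics.** Spheroids incubated with
   calcein-AM accumulate fluorescent calcein; efflux-competent lines expel
   it, so retained fluorescence over 12 h separates phenotypes. A dilated
   fully convolutional network segments the spheroid in every phase-contrast
   frame; the mean green fluorescence over the mask, integrated over time
   (trapezoid, a.u.·h), is the "accumulated calcein" summary. DCFDA/ROS
   stacks reuse the same machinery with a decay test
   (linear slope < 0, p < 0.05).
2. **MTS dose–response plates.** Blank-corrected A490−A650 absorbances give
   % viability; a four-parameter logistic
   `V(c) = bottom + (top − bottom) / (1 + (c/IC50)^h)`
   is fitted per (line, drug, culture mode) with multi-start least squares
   and a profile-likelihood CI for the IC50.
3. **Flow cytometry with transporter inhibitors.** Events are gated to the
   PI-negative (live) population at the KDE valley of the PI distribution;
   the median green fluorescence intensity (MFI) per tube gives the
   retention ratio MFI(inhibitor)/MFI(control) per transporter
   (verapamil → MDR1, MK-571 → MRP1, novobiocin → BCRP) and a transporter
   involvement ranking.

A weighted evidence score (accumulated calcein, cohort IC50 rank, ROS
decay, mean retention ratio) produces the final ordinal class. A seeded
synthetic-data module generates all three input kinds with known ground
truth — spheroid geometry with intensity inhomogeneity and soft
boundaries, saturating uptake/efflux kinetics
`C(t) = (u/e)(1 − e^{−et})`, 4PL viability plates and bimodal live/dead
flow events — so every stage is testable end to end.

## Worked example

```python
from mcsmdr.profile import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, segmentation="ground_truth")
report = run_pipeline(cfg)
for label, sub in report["subjects"].items():
    print(label, sub["phenotype"], f"acc={sub['accumulated_calcein']:.0f}",
          "ros", sub["ros_decay"], "->", sub["profile"]["class"],
          f"(score {sub['profile']['score']:.3f})")
```

prints

```
MCS_02 moderate acc=49371 ros False -> moderately_resistant (score 0.517)
MCS_08 resistant acc=1653 ros False -> highly_resistant (score 1.000)
MCS_17 sensitive acc=74901 ros True -> sensitive (score 0.000)
```

`acc` is the accumulated calcein (a.u.·h over 12 h): the sensitive line
retains ~45× more dye than the resistant one, whose fluorescence stays
confined to the spheroid rim. The score combines the four evidence
streams (weights logged in each profile's rationale); thresholds at 1/3
and 2/3 give the three classes.

The same stages are available as numbered analysis drivers
(`analysis/01_simulate_inputs.py` … `analysis/06_profile_resistance.py`)
and as a CLI (`mcsmdr simulate|train-seg|segment|quantify|ic50|flow|profile`);
each driver writes its tables under `results/`.

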