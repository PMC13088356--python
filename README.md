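# filamap

Nanoscale mapping of protein distributions along filamentous structures in
super-resolution fluorescence images.

Neutrophil extracellular traps (NETs) are extracellular DNA filaments
decorated with proteins; whether a protein sits on the filament
periodically (like nucleosomes or neutrophil elastase) or at random (like
cathepsin G), and whether two proteins share binding sites, is a nanoscale
question that SIM, STED and SMLM imaging can answer — given an automated,
unbiased analysis of thousands of filament stretches.  `filamap` provides
that analysis:

* **detect** single thin DNA-labeled filaments: segmentation of the DNA
  channel, skeletonization into a junction/chain graph, extraction of
  non-branching paths, cutting into equal 1.5 µm fragments;
* **quantify periodicity**: per-fragment intensity line profiles, the
  normalized autocorrelogram
  `r(k) = Σᵢ (xᵢ − x̄)(xᵢ₊ₖ − x̄) / Σᵢ (xᵢ − x̄)²`,
  the lag of its first qualifying peak, pooled into periodicity
  histograms, with maximum-likelihood Gaussian-mixture fits (K = 1 vs 2,
  EM) compared by AIC = 2(3K − 1) − 2 log L;
* **quantify colocalization**: zero-lag normalized cross-correlation
  between channels, restricted to double-labeled fragments (robust SNR
  rule), summarized as median ± quartiles and a double-labeled fraction;
* **simulate** ground-truthed multichannel images — curved filaments with
  periodic or Poisson-placed puncta, Gaussian PSF at SIM/STED/SMLM scales,
  shot noise, read noise, background — so the whole chain is testable
  without microscope data.

It is aimed at microscopists and image analysts working with filamentous
scaffolds (NETs, cytoskeleton, chromatin fibers) who need repeat-distance
and colocalization statistics from calibrated TIFF images or SMLM
localization tables.

## Worked example

Simulate a SIM-like dataset with a known 0.37 µm repeat, then analyze it:

```sh
filamap simulate --preset sim --out run/sim --seed 3 --n-filaments 6
filamap analyze run/sim/image_seed3.tif --out run/ana --seed 3
filamap report run/ana
```

The report prints:

```
run: analyze  seed: 3
profiles analyzed: 17
  protein1: K=1 periodicity center(s): 368 nm
```

i.e. from one image (6 filaments, 17 analyzable 1.5 µm fragments) the
AIC-selected one-component fit centers at 368 nm — the generator's 370 nm
repeat recovered to within one sampling step.  `run/ana/` also contains
per-channel first-peak CSVs, histogram CSVs, fitted-mixture parameters in
`manifest.json`, and a rendered histogram+fit PNG.

The same works from Python:

```python
from filamap import SimulationConfig, pipeline
from filamap.synthetic_data import simulate_stack

cfg = SimulationConfig.from_preset("sim", n_filaments=6, seed=3)
stack, truth = simulate_stack(cfg)
det = pipeline.run_detection(stack, pipeline.DetectionParams())
res = pipeline.run_analysis(det, pipeline.AnalysisParams(seed=3))
print(res.fits["protein1"]["selected"].dominant_mean)  # 0.368
```

Real data enter through `filamap.read_stack` (calibrated multipage TIFF;
`--pixel-size` overrides metadata) or `filamap.read_localizations` +
`render_localizations` for SMLM tables
(`x_nm,y_nm,precision_nm,frame,channel` CSV).

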