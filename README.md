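# deltaosc

Analysis of Delta-gene expression patterning and dynamics in developing
forebrain tissue: quantification of in-situ-hybridisation (ISH) signal,
spatial point-pattern statistics of Delta-positive cells, single-cell
reporter-trace oscillation analysis, and clustering of oscillator
robustness — with a synthetic-data module that emulates the microscopy
inputs with known ground truth.

## The scientific problem

Notch signalling patterns neurogenesis through the ligand Delta (Dll1 in
mammals, dlc in zebrafish). Two competing regimes leave different spatial
and temporal signatures:

* **Lateral inhibition** predicts an *ordered* salt-and-pepper pattern —
  the distance between neighbouring Delta-positive cells is nearly constant,
  so the coefficient of variation (CV) of their relative spacing is small.
* **Oscillatory expression** predicts an *irregular* pattern — which cells
  are "on" changes over time, spacing varies, and single-cell reporter
  traces rise and fall with a period of tens of minutes.

`deltaosc` implements the measurements that discriminate the two:

1. **ISH area quantification** (`deltaosc.imaging.quantify_ish`): invert,
   blur (3–5 µm), subtract, threshold, count particles; reports the ratio of
   positive signal area to the region of interest.
2. **Cell detection and positive calling** (`detect_cells`,
   `measure_and_call`): difference-of-Gaussians blob detection, per-cell
   Delta/DAPI intensity ratio, Otsu or fixed threshold.
3. **Spatial statistics** (`deltaosc.spatial`): per-cell relative
   nearest-neighbour distances and their CV; Ripley's K and its
   linearisation L(r) = sqrt(K(r)/π) with *random-relabelling* simulation
   envelopes (default 80 simulations, 99% pointwise bounds, 100 radii), and
   a per-radius classification into clustered / random / regular.
4. **Trace analysis** (`deltaosc.oscillation`): normalize mCherry by GFP,
   subtract a 100-min moving-mean trend, smooth with a 20-min moving mean,
   call peaks with prominence ≥ 0.1 × dynamic range, autocorrelate (59 lags
   from 60 time points), and extract five robustness features: completed
   cycles, mean squared ACF, ACF range, mean peak-to-peak interval, mean
   amplitude.
5. **Clustering** (`deltaosc.clustering`): z-score the features, k-means
   (Lloyd, 50 epochs, 10 restarts) with the group count chosen by the elbow
   (maximal second difference of the inertia curve).

## Worked example

```sh
deltaosc simulate-spatial --mode random --seed 1 --out demo
deltaosc spatial --cells demo/cells.csv --seed 1 --out demo
deltaosc simulate-traces --n-cells 60 --seed 1 --out demo
deltaosc traces --in demo/traces.csv --out demo
deltaosc cluster --features demo/features.csv --seed 1 --out demo
```

prints

```
wrote demo/cells.csv (200 cells, 40 positive, random)
relative-distance cv = 0.9825
classification fractions: clustered=0.01, random=0.94, regular=0.05
wrote demo/traces.csv (60 cells)
featurized 60 cells (9 without peaks)
k-means: k=3, inertia=22.436
  group 0: n=10, centroid=[-1.936 -1.303 -1.451 -2.086 -1.395]
  group 1: n=20, centroid=[-0.048  1.281  1.208  0.733  1.289]
  group 2: n=30, centroid=[ 0.677 -0.42  -0.322  0.207 -0.394]
  inertia curve (k=1..6): [295.   128.85  22.44  14.24  11.    10.06]
  second differences (k=2..): [59.74 98.22  4.95  2.31]
```

Reading the output: the randomly relabelled pattern stays inside the 99%
envelope at 94% of radii (it is correctly called random), and the trace
population — generated as a hidden mixture of 20 robust oscillators, 30
noisy oscillators, and 10 non-oscillatory cells — is recovered as exactly
those three groups: group 1 (n=20) has high ACF power and amplitude (the
robust oscillators), group 2 (n=30) has high cycle counts but weak ACF (the
noisy fast oscillators), and group 0 (n=10) is flat. The elbow lands on
k = 3 because the second difference of the inertia curve peaks there
(98.2 vs 59.7 at k = 2).

Every command writes a `manifest.json` with parameters, seeds, and output
checksums; identical configurations reproduce byte-identical numeric
outputs.

## Library use

```python
import numpy as np
from deltaosc import (Window, gen_cell_field, label_positives, envelope,
                      gen_population, standardize, select_k_elbow)
from deltaosc.oscillation import featurize_trace
from deltaosc.clustering import features_to_matrix

w = Window(0, 100, 0, 100)
cells = label_positives(gen_cell_field(200, w, seed=1), 40, "max_cluster", seed=2)
env = envelope(cells, w, n_sim=80, level=0.99, seed=3)
print(env.fraction("clustered"))          # > 0: clustering detected

traces, truth = gen_population("mixed_default", 60, seed=1)
feats = [featurize_trace(t)[1] for t in traces]
z, _ = standardize(features_to_matrix(feats))
print(select_k_elbow(z, seed=1).k)        # 3
```

See `docs/methods.md` for the statistical methods, parameter defaults, and
known limitations.
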