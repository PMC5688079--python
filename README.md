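# wiringcost

Resting-state intracranial EEG (iEEG/ECoG) connectivity analysis centred on
a distance-weighted **wiring cost** statistic and a **threshold filtration**
over network densities, built to contrast the two canonical baseline
conditions of neurophysiology: eyes closed (EC) and eyes open (EO).

## Who this is for

Electrophysiologists and network neuroscientists who want to ask whether
eyes-closed and eyes-open resting states are electrophysiologically
equivalent baselines — and more generally anyone contrasting two
conditions of a multichannel recording through functional connectivity,
without committing to a single arbitrary network threshold.  Clinical
iEEG of this kind is rarely shareable, so the package includes a synthetic
two-condition cohort generator that reproduces the statistical structure
the analysis assumes (alpha-band oscillations over 1/f noise, with
condition-dependent inter-channel coupling), making the entire chain
testable end to end.

## The analysis

1. **Preprocess** — 0.5–70 Hz zero-phase band-pass plus 60 Hz notch.
2. **Decompose** — convolution with complex Morlet wavelets (7 cycles,
   support ±1 s) gives instantaneous power |z(t)|² and phase arg z(t) per
   channel and frequency; the alpha band is 8–12 Hz.
3. **Connectivity** — three pairwise estimators assembled into a symmetric
   channel × channel matrix **F**:
   - windowed **Spearman power correlation** (rank-transform each 5 s
     window, Pearson-correlate, average windows),
   - **intersite phase clustering** ISPC = |n⁻¹ Σₜ exp(i(φₓ(t) − φᵧ(t)))|,
   - **phase-lag index** PLI = |n⁻¹ Σₜ sgn(imag Sₓᵧ(t))| with
     Sₓᵧ = zₓ·z̄ᵧ, insensitive to zero-lag (volume-conducted) coupling.
4. **Wiring cost** — **W = D ∘ F**, the elementwise product of the
   inter-electrode Euclidean distance matrix (mm) and the connectivity
   matrix: the further apart and the more strongly coupled two contacts,
   the more the observed pattern "costs".
5. **Networks** — binarise F at τ = μ + σ of its pair values and compute a
   14-metric battery (density, clustering, transitivity, components,
   modularity, assortativity, core/periphery, path length, centralities,
   topological overlap, matching index, degree); compare conditions by the
   per-subject EC − EO metric difference.
6. **Filtration** — instead of one threshold, sweep *every* value the
   matrix takes: under the sublevel rule the binary networks nest from the
   empty to the complete graph, and density, clustering, characteristic
   path length and total wiring cost become curves over the threshold
   axis.  EC − EO difference curves are formed on the union grid; by
   construction the density and clustering differences end at exactly 0.
7. **Statistics** — within-subject permutation tests that exchange 5 s
   windows between conditions: a per-channel test on mean connectivity to
   all other channels, and a curve test on the area between condition
   filtration curves.  Stars follow `*` p < 0.05, `**` p < 0.001.

## Worked example

A six-contact temporal strip (10 mm spacing), two simulated 3-minute
conditions with the default contrast (alpha coupling 0.8 eyes closed vs
0.2 eyes open):

```python
import numpy as np
from wiringcost.synthetic import SyntheticConfig, simulate_recording, make_layout, LayoutSpec
from wiringcost.preprocessing import bandpass_notch
from wiringcost.spectral import decompose
from wiringcost.connectivity import connectivity_matrix, windowed_connectivity_matrices
from wiringcost.wiring import distance_matrix, wiring_cost, total_wiring_cost
from wiringcost.graph_metrics import threshold_fixed, compute_metrics, condition_difference
from wiringcost.stats import curve_condition_test

layout = make_layout(LayoutSpec("strip", 6, 10.0, region="T", laterality="L"))
D = distance_matrix(layout)
cfg = SyntheticConfig(n_channels=6, fs=250.0, duration_s=180.0, seed=0)
results = {}
for cond in ("EC", "EO"):
    rec = simulate_recording(cfg, cond)
    rec.channels = list(layout.labels)   # adopt the strip's contact labels
    dec = decompose(bandpass_notch(rec), np.arange(8.0, 13.0))
    F = connectivity_matrix(dec, "spearman_power", band=(8, 12))
    W = wiring_cost(D, F, labels=layout.labels)
    results[cond] = dict(F=F, dec=dec,
                         metrics=compute_metrics(threshold_fixed(F)))
    print(f"{cond}: mean alpha power correlation "
          f"{F.offdiag().mean():.3f}, total wiring cost {total_wiring_cost(W):.1f}")
diff = condition_difference(results["EC"]["metrics"], results["EO"]["metrics"])
print(f"EC - EO density difference at the mu+sigma threshold: {diff['density']:+.3f}")
wm = {c: windowed_connectivity_matrices(results[c]["dec"], "spearman_power")
      for c in ("EC", "EO")}
test = curve_condition_test(wm["EC"], wm["EO"], D, n_perm=199, seed=0)
print(test[["metric", "statistic", "p_value", "stars"]].to_string(index=False))
```

prints

```
EC: mean alpha power correlation 0.410, total wiring cost 143.1
EO: mean alpha power correlation 0.052, total wiring cost 19.2
EC - EO density difference at the mu+sigma threshold: -0.133
          metric  statistic  p_value stars
      clustering   7.874058    0.005     *
         density   7.802933    0.005     *
char_path_length  11.495201    0.005     *
     wiring_cost 892.055788    0.005     *
```

Eyes closed carries far stronger alpha power coupling (0.410 vs 0.052),
an order of magnitude more wiring cost (143 vs 19, in mm × correlation
units), and every filtration-curve permutation test rejects at its
resolution floor (p = 1/200 at 199 permutations).  The fixed-threshold
density difference is *negative* despite the stronger coupling — a nice
illustration of why the filtration, not any single threshold, is the
robust comparison: μ + σ adapts to each condition's own value
distribution.

## Command line

```bash
wiringcost simulate --subjects 3 --fs 500 --duration-s 180 --seed 7 --out data/
wiringcost connectivity data/S01/EC.edf F_ec.tsv --measure spearman_power --band 8:12
wiringcost run --out results/ --seed 7         # full pipeline on a simulated cohort
```

`wiringcost run` writes, per subject and condition: connectivity and
wiring-cost matrices (TSV + JSON sidecars), fixed-threshold metric
vectors, filtration curves and EC − EO difference curves, and cohort-level
permutation-test tables.  A `manifest.json` records the seed and every
parameter; a rerun with the same seed reproduces every numeric table
byte for byte.

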