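# mupool — motor-unit pool analysis from high-density surface EMG

`mupool` is a tested, reusable implementation of the analysis chain used
to characterise the rate coding of motor-unit pools from high-density
surface electromyography (HD-EMG), exercised end to end on simulated
recordings with known ground truth. It is aimed at motor-control and
EMG-methods researchers who want a transparent, scriptable version of
this pipeline whose every stage can be validated against a simulation
oracle.

The chain comprises:

1. **Synthetic HD-EMG generation** — trapezoidal force-matching
   contractions (ramps at 5 %MVC·s⁻¹), a motoneuron pool obeying the
   size principle whose units fire at f(F) = a·ln(F) + b pps above
   their recruitment threshold, unique spatial action-potential
   signatures on 13×5 electrode grids, linear superposition plus white
   noise at a prescribed SNR.
2. **Decomposition** — convolutive blind source separation: channel
   extension to 1000 extended channels, spatial whitening, fixed-point
   iteration on the log-cosh contrast with deflation, discharge
   detection by two-class peak clustering, acceptance at silhouette
   ≥ 0.9, duplicate removal (≥30% common discharges within 0.5 ms).
3. **Tracking** — the same physical unit is followed across contraction
   levels by reprojecting separation vectors between recordings and
   matching discharge trains (>30% common).
4. **Waveform validation** — spike-triggered action-potential templates
   on the 236-channel single-differential montage, synthetic-EMG
   reconstruction and explained-power ratio, and a waveform-uniqueness
   audit of tracked units (50 ms, 102-sample template matrices).
5. **Rate coding** — per unit, three candidate rate–force models
   (linear, rising exponential, natural logarithm) compared by
   BIC = n·ln(sse/n) + p·ln(n); initial firing-rate acceleration a/rt
   at recruitment; plateau rates and their increments per 10 %MVC;
   recruitment–derecruitment hysteresis.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

The standing validation scenario is ten well-separated units (thresholds
2–25 %MVC) recorded at 20 dB on a 64-electrode grid during contractions
at 10, 20 and 30 %MVC. The numbered scripts under `analysis/` run it
stage by stage (artifacts under `scratch/run/`, tables under
`results/`):

```sh
python analysis/01_simulate.py 1      # seed 1
python analysis/02_decompose.py 1
python analysis/03_track.py 1
python analysis/04_validate_waveforms.py 1
python analysis/05_rate_coding.py 1
```

or equivalently, as a library / CLI:

```python
from mupool.evaluation import run_validation_study

s = run_validation_study(seed=1)
print("recovered", s.n_recovered, "of", s.n_truth_units)
print("yields", [round(y, 3) for y in s.tracking_yields])
print("power", round(s.explained_power, 3), "ceiling", round(s.explained_power_ceiling, 3))
print("unique", s.fraction_unique, "assessable", s.n_assessable, "registry", s.registry_size)
```

```sh
mupool all --seed 1 --workdir scratch/run
```

With seed 1 the snippet prints:

```
recovered 10 of 10
yields [0.833, 0.875]
power 0.922 ceiling 0.99
unique 1.0 assessable 8 registry 10
```

Reading: all ten simulated units are recovered by the decomposition with
a rate of agreement of at least 0.90 against the true discharge times
(here all at 1.00); 83% and 88% of the units identified at one level are
tracked into the next; the synthetic EMG reconstructed from the
estimated units explains 92.2% of the recorded signal power over the
force plateau, against a 99.0% ceiling set by the 20 dB simulation
noise; all eight units tracked over two or more levels pass the
waveform-uniqueness audit; and the tracking registry contains exactly
ten unique units. The rate-coding stage then fits each tracked unit —
e.g. `bic(sse=100, n=100, p=2)` evaluates to 9.210, and a unit fitted
with a = 5 pps recruited at 10 %MVC has an initial acceleration of
0.5 pps/%MVC, i.e. 2.5 pps·s⁻¹ at the 5 %MVC·s⁻¹ ramp.

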