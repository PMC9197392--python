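# cerebellopipe

Analysis pipeline for optogenetically evoked cerebello-thalamo-cortical
responses and rodent motor behavior, built for studies of cerebellar
output in dystonia models (e.g. *Gnal*-haploinsufficient mice) but
applicable to any stimulation-plus-recording design of the same shape.

The pipeline covers, end to end:

* **Evoked-response quantification** — peristimulus time histograms
  (10 ms bins, 300 ms baseline), a 4×SD responsiveness criterion, the
  evoked rate change ΔFR = ⟨FR_stim⟩ − ⟨FR_base⟩, region-specific 10 ms
  afferent-volley windows (DN 0–10 ms, thalamus 4–14 ms, cortex
  7–17 ms), mean firing rate, CV of the interspike interval, a 6 Hz
  slow/fast-spiking split of striatal units, and early/late stability
  checks.
* **Spike sorting** — PCA of waveform snippets + k-means, with a
  silhouette sweep for the cluster count (also available as a
  scikit-learn estimator, `WaveformSorter`).
* **Plasticity and group statistics** — paired Wilcoxon for pre vs
  post θ-burst, Mann–Whitney for genotype contrasts, Kruskal–Wallis
  with Dunn/Holm–Šidák post-hocs, two-way state × genotype ANOVA with
  interaction (type-II), and the 1.5 × IQR boxplot convention.
* **Behavior** — the five footprint gait parameters plus stride length
  and hind-base width; open-field video tracking
  (threshold → bilateral + Gaussian smoothing → Canny → largest
  contour → centroid) with distance, 1 s window speeds, occupancy,
  thigmotaxis and center time; active-wake percentage; and dystonia
  score aggregation per 10-min block.
* **Synthetic data** — generators for every input the pipeline
  consumes (piecewise-constant-rate Poisson spike trains with
  stimulus-locked increments, waveform mixtures, footprint patterns,
  arena trajectories, video frame stacks), each returning its ground
  truth so every stage is testable by parameter recovery.

See `docs/methods.md` for the models, conventions and default
parameters.

## Worked example

Simulate a 40-unit thalamic cohort probed with 150 DN pulses before and
after a θ-burst with a 1.5× evoked gain, then test the plasticity:

```python
from cerebellopipe import (EphysSimConfig, compare_pre_post, compute_psth,
                           evoked_delta_rate, gen_evoked_train, gen_protocol,
                           summarize_response)

proto = gen_protocol("low_freq", 600.0)   # 150 pulses, 100 ms @ 0.25 Hz
pre, post = [], []
for u in range(40):
    cfg_pre = EphysSimConfig(seed=100 + u)
    cfg_post = EphysSimConfig(plasticity_gain=1.5, seed=5100 + u)
    tr_pre, _ = gen_evoked_train(cfg_pre, proto, "VAL", 600.0)
    tr_post, _ = gen_evoked_train(cfg_post, proto, "VAL", 600.0)
    pre.append(evoked_delta_rate(compute_psth(tr_pre, proto)))
    post.append(evoked_delta_rate(compute_psth(tr_post, proto)))

summ = summarize_response(tr_pre, proto)
print(f"unit: responsive={summ.responsive}, evoked {summ.delta_rate:+.2f} Hz, "
      f"volley {summ.volley_rate_delta:+.2f} Hz, "
      f"baseline {summ.baseline_rate:.2f} Hz, CV_isi {summ.cv_isi:.2f}")
res = compare_pre_post(pre, post)
print(f"theta-burst effect: median post-pre = {res.effect:+.2f} Hz, "
      f"Wilcoxon p = {res.p_value:.2e}")
```

prints

```
unit: responsive=True, evoked +13.78 Hz, volley +21.51 Hz, baseline 11.16 Hz, CV_isi 1.01
theta-burst effect: median post-pre = +7.20 Hz, Wilcoxon p = 3.71e-08
```

The unit is flagged responsive (a stimulation bin clears 4 baseline
SDs), its evoked rate change of ≈14 Hz matches the configured 15 Hz
increment (the 4 ms onset latency trims the 100 ms analysis window),
the volley is the stronger early component, and the CV_isi ≈ 1 reflects
the Poisson baseline. Across the cohort the 1.5× gain appears as a
+7.2 Hz median paired difference, decisively significant.

The same stages are available from the shell:

```sh
cerebellopipe simulate --seed 1 --out data/
cerebellopipe analyze-ephys --spikes data/spikes.csv --events data/events.csv --out responses.csv
cerebellopipe analyze-gait --footprints data/footprints.csv --out gait.json
cerebellopipe analyze-openfield --trajectory data/trajectory.csv --out openfield.json
cerebellopipe run --seed 1 --out report/     # full pipeline + statistics
```

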