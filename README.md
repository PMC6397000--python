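# placecode

Spatial and temporal coding-resolution analysis for hippocampal
recordings on virtual linear tracks.

Head-fixed rodents running back and forth on a virtual 200 cm track give
CA1 recordings in which the *resolution* of the hippocampal spatial code
— how many cells carry place fields, how sharp, stable and informative
those fields are, and how well the population decodes position — depends
on the visual cues in the environment. `placecode` implements the full
analysis chain needed to quantify this, for experimentalists with
trajectory + spike + LFP data and for modelers who want a tested
reference implementation:

* **Rate maps & cell classes** — per-trial firing-rate vectors on a
  100 × 2 cm bin grid (Gaussian-smoothed, occupancy-normalized,
  locomotion-gated), putative pyramidal/interneuron and active/silent
  classification.
* **Place-field detection** — per-bin bootstrap against trial-wise
  homogeneous Poisson surrogates (p < 0.01, > 3 contiguous bins, merge /
  extend / size rules, trial-stability criterion), per-lap fields, and
  field metrics: width (30% threshold crossings), lap dispersion
  PFD = (L/N)·√(Σ(C−Cᵢ)²/M), out/in-field ratio, End-Track vs On-Track,
  object-responsive cells.
* **Spatial metrics** — pairwise-trial stability index, Skaggs spatial
  information SI = Σᵢ (FRᵢ/FR)(OTᵢ/OT_T) log₂(FRᵢ/FR), surrogate-
  normalized mutual information, even/odd local stability, a trimmed-SD
  bootstrap test of field-position uniformity, and map similarity across
  condition switches.
* **Position decoding** — memoryless Bayesian decoder
  P(x|n) ∝ Πᵢ fᵢ(x)^{nᵢ} exp(−τ Σᵢ fᵢ(x)) with leave-one-out tuning
  curves (τ = 150 ms), firing-rate-vector decoding, the drop-cell
  subset procedure, and confusion/accuracy summaries by track zone.
* **Theta / temporal coding** — Hilbert and waveform theta phase,
  phase locking, circular-linear phase-precession fits with exact
  permutation tests (pooled and single-lap), the spike/LFP multitaper
  spectral shift, speed modulation of theta frequency and amplitude,
  and theta-timescale cross-correlogram offsets for overlapping-field
  pairs.
* **Synthetic sessions** — a generator producing trajectories, theta
  LFP and inhomogeneous-Poisson spike trains with known place tuning,
  trial jitter and phase precession, so every stage is testable against
  ground truth without external data.

## Worked example

Simulate a cue-rich session and run the whole stack:

```python
from placecode.pipeline import build_condition_session, analyze_session

session = build_condition_session("OT-like", n_trials=20, seed=42,
                                  n_cells_scale=0.5)
res = analyze_session(session, seed=42, n_boot=500, lap_fields=False)
row = res["session"]
print(f"{row['n_neurons']} cells: {row['n_active']} active, "
      f"{row['n_place']} place cells ({row['pct_place']:.0f}% of active)")
```

prints

```
22 cells: 15 active, 11 place cells (73% of active)
stability index     0.90
spatial information 0.28 bits/spike
out/in field ratio  0.31
decoding error      18 cm (accuracy 0.023, chance 0.0125)
precessing fields   73% (mean slope -3.17 rad/U)
```

73% of active cells are place cells and the Bayesian decoder reaches an
18 cm median error — far above the 1/80 chance accuracy — while the
same pipeline on the cue-poor preset (`"NT-like"`) finds ~20% place
cells, near-zero spatial information and ~45 cm decoding error: the
qualitative contrast the analysis chain is built to measure.
`res["cells"]` and `res["fields"]` are tidy per-cell / per-field
DataFrames.

The same stages are available from the shell:

```bash
placecode simulate --preset OT-like --trials 20 --out sess/ --seed 42
placecode fields   --session sess/ --seed 1 --out fields.csv
placecode decode   --session sess/ --out decode.csv
placecode report   --config conditions.yaml --seed 1 --out report/
```

Sessions on disk are plain text (manifest.json, trajectory.csv,
spikes.csv, cells.csv, lfp.csv), so recorded data can be dropped into
the same layout.

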