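# rhinoflow

Nasal-resistance measurement from two-channel (pressure + flow) respiratory
recordings. The package segments respiratory cycles from raw 100 Hz signals,
classifies each cycle as effective or ineffective with combined FFT
(dominant-frequency) and peak-to-peak amplitude thresholds, resamples
effective cycles onto a fixed 2000-point grid with a natural cubic spline,
and computes four nasal-resistance indicators per breathing phase:

- **mean resistance** — flow interpolated at the ±150 Pa reference pressure,
- **vertex resistance** — pressure/flow at the flow peak,
- **effective resistance** — RMS pressure over RMS flow,
- **Broms resistance** — tangent of the polar angle where the scaled
  pressure–flow curve crosses the radius-2 circle (least-squares angle fit).

It also ships a seeded synthetic breath simulator (effective cycles plus
three interference paradigms: saturated/weak, not-worn-properly, multiple
breaths), an exhaustive six-threshold grid search over labeled cycle sets,
and a within-group standard-deviation stability analysis comparing filtered
vs unfiltered preprocessing.

## Library overview

| module | contents |
| --- | --- |
| `rhinoflow.signal_io` | CSV recordings (`time_s,pressure_pa,flow_cm3s`), labeled cycle sets (CSV + JSON manifest), threshold JSON |
| `rhinoflow.synthetic_breaths` | `SyntheticSpec`, effective/ineffective cycle generators, recording concatenation with ground-truth boundaries |
| `rhinoflow.segmentation` | DC removal, sum-of-five start rule, sign-alternation end rule, streaming cycle extraction |
| `rhinoflow.cycle_validation` | dominant frequency (zero-padded FFT), peak-to-peak, the four-clause effectiveness decision |
| `rhinoflow.resampling` | hand-rolled natural cubic spline, 2000-point resampling, cycle averaging |
| `rhinoflow.resistance` | phase splitting and the four indicators; severity interpretation at the 0.75 cutoff |
| `rhinoflow.threshold_search` | confusion-matrix metrics, per-scenario accuracy, cached-feature grid search |
| `rhinoflow.evaluation` | within-group SD summaries (median/IQR) and the filtered-vs-unfiltered stability report |
| `rhinoflow.pipeline` / `rhinoflow.cli` | end-to-end pipeline and the `rhinoflow` command |

```python
import rhinoflow as rf

spec = rf.SyntheticSpec(frequency_hz=0.3, pressure_amp_pa=250, flow_amp_cm3s=450, seed=1)
rec, labeled, bounds = rf.generate_recording([spec] * 4, gap_s=0.2, seed=1)
result = rf.run_pipeline(rf.PipelineConfig(), rec)
print(result["group_resistance"]["vertex_ins"])
```

## Command line

```sh
rhinoflow simulate --n-cycles 4 --seed 1 --out-recording rec.csv --out-cycles cycles/
rhinoflow segment  --input rec.csv --min-cycle 0.5 --out segs/
rhinoflow validate --cycles segs/ --max-count 4
rhinoflow resample --cycles segs/ --average --out avg.csv
rhinoflow resistance --cycles segs/ --out result.json
rhinoflow search   --labeled cycles/manifest.json --top 1000 --out ranking.csv
rhinoflow stability --groups g1/manifest.json --groups g2/manifest.json --out stability.json
rhinoflow run      --input rec.csv --out result.json
```

Exit codes: `0` success, `2` no effective cycles after validation,
`3` input format error. Default thresholds are the grid-search optimum
(0.12–0.6 Hz; 300–1000 Pa; 100–1650 cm³/s); override with
`--thresholds t.json`.

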