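# lungdce

Radial UTE sliding-window DCE-MRI reconstruction and model-free lung
enhancement analysis for preclinical (rat) lung imaging, with a synthetic
dynamic phantom providing ground truth for every stage.

## The problem

Dynamic contrast-enhanced (DCE) MRI of rodent lungs at high field is hard:
lung signal decays in well under a millisecond, the circulation is too fast
for quantitative first-passage imaging in 3D, and continuous radial
scanning trades temporal independence for coverage.  A practical recipe is
continuous 2D multi-slice ultra-short-echo-time (UTE) acquisition with
tiny-golden-angle radial spokes, sliding-window reconstruction of
overlapping frames, and a *model-free* analysis of relative enhancement:
per-pixel signal change normalized to the pre-injection baseline, corrected
for the time-varying background artefact level, and binned into discrete
enhancement classes whose volumes characterize inflammatory (day-7) and
fibrotic (day-28) stages of bleomycin-induced lung injury.

`lungdce` implements that whole pipeline as a tested Python library plus a
CLI — for MR physicists and image-analysis researchers who want to study,
reproduce, or extend the method without access to the original scanner
data.

## What is inside

- **trajectory** — tiny golden angles ψ_N = 180°/(φ+N−1) (ψ₇ = 23.63°),
  center-out radial coordinates, ramp density-compensation weights
  w = |k|/k_max with an area-consistent floor at DC.
- **recon** — Kaiser-Bessel gridding (exact adjoint NUFFT pair, width 4,
  1.5× oversampling), sliding-window frame assembly (window 90 / step 60
  profiles: 10.2 s frames every 6.8 s at TR_eff = 114 ms), and an
  l1/l2-regularized FISTA solver,
  `argmin ‖W½(Ax−y)‖² + 0.00536‖Ψx‖₁ + 0.0016‖x‖²`, with an orthogonal
  Daubechies-4 wavelet (or TV) as Ψ.
- **synthetic** — dynamic rat-lung phantoms: SPGR signal model
  S = PD·sinα(1−E1)/(1−cosα·E1) with uptake×washout enhancement courses,
  exact direct-summation nonuniform DFT as the forward model, seeded noise
  and global drift; presets `control`, `bleo_d7`, `bleo_d28` calibrated to
  the study's group-mean volumes and enhancement fractions, plus synthetic
  histology sections with known tissue fraction.
- **dce** — baseline (frames 1–50), relative enhancement (S−S0)/S0,
  corner-ROI background trace and drift correction, 7-class binning at
  thresholds {1, 2, 3, 4, 8, 12}, bin/lung volumes and group curves.
- **morphometry** — histogram lesion volume on the 3000-spoke baseline,
  histology tissue/air fraction at the 900 threshold, Rayleigh-corrected
  SNR estimation.
- **pipeline / cli** — YAML config, NIfTI/CSV/JSON I/O, and the `lungdce`
  command with subcommands `simulate`, `recon`, `dce`, `lesion`, `histo`,
  `run`.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate the day-28 fibrotic preset, reconstruct the sliding-window series,
and run the full analysis:

```sh
lungdce run --preset bleo_d28 --seed 1 --out run_d28
```

prints (exactly; the pipeline is deterministic for a given config and seed)

```json
{
  "config_hash": "15274b19c6cd",
  "lesion_volume_ml": 1.673,
  "low_enhancement_fraction_pct": 72.4,
  "low_enhancement_volume_ml": 4.708,
  "lung_volume_ml": 6.499,
  "snr": 96.33
}
```

Reading these numbers: the segmented lung volume is 6.5 ml (the day-28
preset's calibration target; controls are 4.4 ml, so the fibrotic lung has
grown by 2.1 ml).  72.4% of that volume — 4.7 ml — shows a peak relative
enhancement below 3 after contrast injection, recovering the phantom's
ground-truth low-enhancement fraction of 73.8% and mirroring the fibrotic
pattern in which low-enhancing bins roughly double versus controls (~61%).
The baseline histogram analysis finds 1.67 ml of hyperintense tissue
(vessels + lesion; ground truth 1.70 ml).  `run_d28/report.json` holds the
full report including per-class bin volumes and the ground-truth block;
`curves.csv` the mean enhancement and background traces; `bin_map.nii.gz`
and `bin_overlay.png` the enhancement-class map.

The same stages are available as library calls:

```python
import lungdce as L

spec = L.desk_preset("bleo_d28", seed=1)          # matrix 64, 4 slices
traj = L.build_trajectory(5000, 64, matrix_size=64)
k, truth = L.simulate_kspace(spec, traj)           # radial k-space + oracle
plan = L.plan_sliding_window(k.n_profiles, 90, 60, k.meta.tr_eff_s)
series = L.reconstruct_series(k, plan, zero_fill=1)
roi = L.LungROI(truth.lung_mask, spec.pixel_spacing_mm, spec.slice_thickness_mm)
result = L.analyze_series(series, roi, injection_time_s=spec.injection_time_s)
print(result.low_enhancement_fraction())           # ~0.72 vs truth 0.738
```

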