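# stimwave

Tools for studying how electrical stimulation during cardiac differentiation
shapes the function of hiPSC-derived cardiomyocytes (hiPSC-CMs), from the
stimulation side and from the optical-readout side:

* **A digital twin of the stimulation signal generator** — charge-balanced
  biphasic, monophasic, and alternating-monophasic pulse trains; static
  schedules and *ramped* regimens whose frequency or pulse duration increases
  linearly over days (e.g. 1 → 2 Hz over 10 days = 6.94 × 10⁻⁵ Hz/min);
  waveform sampling and oscilloscope-style fidelity assessment (cathodic,
  anodic, and total pulse duration, percent error against nominal).
* **An analysis pipeline for GCaMP calcium movies** — ΔF/F0 trace
  extraction on an ROI grid; per-beat **FWHM** (calcium cycle duration) and
  exponential **decay constant τ** (reuptake rate); beating synchronicity via
  the **TPA-MAD** (median absolute deviation of the time of peak arrival
  across regions); and calcium-wave velocimetry with **Horn–Schunck optical
  flow** summarized as mean vector magnitude (μm/s), **circular variance**
  of the vector phase (0 = unidirectional, 1 = isotropic), and polar rose
  histograms.
* **Contractility velocimetry for phase-contrast movies** — whole-frame
  pixel-velocity traces and average peak contraction / relaxation speeds.
* **A synthetic-movie generator** providing exact ground truth for every
  stage: plane-wave, source, sink, and synchronous calcium patterns built
  from a linear-rise / exponential-decay transient kernel (closed-form
  FWHM = rise/2 + τ·ln 2), jittered ROI beat trains, and radially beating
  texture movies.

Because the quantities above are estimated from sampled, noisy movies, every
estimator here is validated by recovering the known parameters of the
synthetic inputs rather than against fixed constants.

## The statistics in brief

For a ΔF/F0 transient peaking at height *A*:

* FWHM is the time between the two half-height (*A*/2) crossings bracketing
  the peak, located by linear interpolation.
* τ is the decay constant of a least-squares fit of *A*·exp(−t/τ) + *c* on
  the window from the peak to the next beat.
* TPA-MAD for one beat with arrival times *tᵢ* across ROIs is
  median(|tᵢ − median(tᵢ)|), in ms, with no Gaussian consistency factor;
  the reported statistic is the median over beats.
* For pooled flow vectors with phases θⱼ, circular variance is
  1 − |⟨exp(iθ)⟩| and velocity is the mean vector magnitude scaled to μm/s.

## Worked example

```python
import math
from stimwave.regimen import PulseSpec, build_schedule
from stimwave.synthetic import TransientKernel, generate_trace_set, generate_wave_movie
from stimwave.transients import detect_peaks, transient_metrics, tpa_mad
from stimwave.flow import preprocess_movie, compute_flow_sequence, flow_summary

# a ramped-frequency regimen: 1 -> 2 Hz over 10 days
start = PulseSpec("biphasic", voltage=4.0, phase_duration_ms=4.0, frequency_hz=1.0)
end = PulseSpec("biphasic", voltage=4.0, phase_duration_ms=4.0, frequency_hz=2.0)
ramp = build_schedule("ramped_frequency", start, end, duration_days=10.0)
print(f"ramp rate: {ramp.rate_per_minute('frequency_hz'):.3e} Hz/min "
      f"({ramp.rate_per_day('frequency_hz'):.1f} Hz/day)")

# jittered GCaMP beat trains: recover FWHM, tau, and synchronicity
kernel = TransientKernel(rise_ms=100.0, tau_ms=400.0, amplitude=1.0)
traces, truth = generate_trace_set(n_rois=16, n_beats=8, period_ms=2000.0,
                                   kernel=kernel, jitter_sd_ms=40.0,
                                   noise_sd=0.05, frame_rate=20.0, seed=42)
peaks = detect_peaks(traces, min_prominence_dff=0.5)
metrics = transient_metrics(traces, peaks)
sync = tpa_mad(traces, peaks)
print(f"median FWHM: {metrics['fwhm_ms'].median():.1f} ms "
      f"(closed form {kernel.fwhm_ms:.1f} ms)")
print(f"median tau:  {metrics['tau_ms'].median():.1f} ms (true {kernel.tau_ms:.0f} ms)")
print(f"TPA-MAD:     {sync.tpa_mad_ms:.1f} ms (injected jitter SD 40 ms)")

# a propagating calcium plane wave: recover speed and directionality
movie, _ = generate_wave_movie(h=128, w=128, pixel_size=2.0, frame_rate=20.0,
                               n_frames=120, pattern="plane_wave", speed=10.0,
                               direction=0.0, period_ms=2000.0, kernel=kernel,
                               noise_sd=0.02, seed=42)
fields = compute_flow_sequence(preprocess_movie(movie))
summary = flow_summary(fields, movie.pixel_size, movie.frame_rate)
print(f"calcium flow: {summary.mean_magnitude_um_s:.1f} um/s toward "
      f"{math.degrees(summary.mean_direction_rad):.1f} deg, "
      f"circular variance {summary.circular_variance:.3f} "
      f"(true: 10 um/s along 0 deg)")
```

Output:

```
ramp rate: 6.944e-05 Hz/min (0.1 Hz/day)
median FWHM: 345.5 ms (closed form 327.3 ms)
median tau:  403.4 ms (true 400 ms)
TPA-MAD:     25.0 ms (injected jitter SD 40 ms)
calcium flow: 11.0 um/s toward 0.1 deg, circular variance 0.029 (true: 10 um/s along 0 deg)
```

The FWHM median sits within one 50 ms frame of the closed form; τ is within
1%. TPA-MAD ≈ 25 ms is what a 40 ms Gaussian jitter implies: the MAD of a
normal sample is ≈ 0.67σ ≈ 27 ms, quantized to the 50 ms frame grid. The
flow summary recovers the wave speed within 10% and its direction within a
fraction of a degree, with near-zero phase dispersion — a source or sink
pattern instead yields circular variance near 1.

## Command line

Every stage is also a subcommand over TIFF/CSV/JSON artifacts:

```bash
stimwave regimen    --config regimen.json --out out/        # schedule log, waveform, fidelity
stimwave simulate   --config run.json --seed 1 --out out/   # synthetic movies/traces
stimwave transients --movie movie.tif --out out/            # FWHM, tau, TPA-MAD
stimwave flow       --movie movie.tif --out out/            # velocimetry + rose
stimwave contract   --movie beats.tif --out out/            # contraction/relaxation
stimwave run        --config run.json --seed 1 --out out/   # end-to-end, one report row per condition
```

Movies travel as multi-page TIFF with a JSON sidecar (`frame_rate`,
`pixel_size_um`); traces, schedule logs, and summaries are plain CSV/JSON.

## Scope

The package models the computational analyses only: no device firmware or
electronics, no RNA-seq or immunostaining quantification, no group
statistics. `docs/methods.md` documents the models, estimator choices,
defaults, and known limitations.
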