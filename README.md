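# ebmd — Empirical Blaschke Mode Decomposition

Periodic pulse trains — heartbeats in an ECG, epileptiform spikes in an EEG,
fault transients in a gearbox vibration record — concentrate their spectral
energy in a few compact, mutually separated frequency bands. `ebmd`
decomposes a uniformly sampled 1-D signal into *intrinsic mode functions*
(IMFs), each carrying one such periodic-pulse constituent, by chaining four
stages:

1. an **adaptive Blaschke transform**: greedy expansion of the signal's
   analytic extension in the Takenaka–Malmquist rational orthonormal system
   `B_n(z) = √(1−|a_n|²)/(1−ā_n z) · Π_{k<n} (z−a_k)/(1−ā_k z)`, with each
   disk parameter `a_k` chosen from a dictionary by a quasi-periodicity
   score (the summed autocorrelation `|Σ_m R(m)|/N` of the candidate
   component). With all `a_k = 0` this is exactly the one-sided Fourier
   series; the per-order mean power `BS(k)` is the *Blaschke spectrum*;
2. **a-contrario unimodal pre-segmentation** of that spectrum: the trend
   (mean truncation + maximum filter) is cut into statistically unimodal
   intervals using a number-of-false-alarms test,
   `NFA = L(L+1)/2 · B(N, NQ, P) ≤ δ`, against Grenander
   (pool-adjacent-violators) monotone estimates — each interval's partial
   reconstruction is a mono-component;
3. **group sparse filtering**: per-bin energy detection
   (`keep bin i iff |c_i|² ≥ λ w_i`, the separable minimiser of
   `‖c − c∘f‖₂² + λ‖f‖₀,w`) followed by gap-filling and short-run removal;
   each compact group inverts to one *fundamental mode*;
4. **envelope-signature fusion**: modes whose Hilbert-envelope spectra
   overlap (Jaccard > `thr`) and share a dominant envelope frequency (the
   pulse repetition rate, within one bin) are summed into one IMF,
   undoing the over-decomposition of step 3.

The library is written for signal-processing practitioners; the estimator
classes (`EBMD`, `BlaschkeDecomposer`) follow the fit/transform convention
and expose `get_params`/`set_params`, and every stage is also available as a
plain function (`blaschke_transform`, `presegment`, `pointwise_mask`,
`fuse`, ...).

## Worked example

```python
import numpy as np
from ebmd import EBMD, EbmdConfig, ebmd
from ebmd.synthgen import gear_fault_mixture, make_mixture

# 125 Hz fault pulse train ringing a 2 kHz resonance + 40 Hz shaft tone,
# 64 fault periods at 8 kHz, white noise at exactly -5 dB SNR
spec = gear_fault_mixture(seed=0)
signal, parts, noise = make_mixture(spec)

est = EBMD(sample_rate=spec.sample_rate, max_order=1300,
           radii=(0.1, 0.3, 0.5), phase_count=16,
           trend_window=31, min_gap=70)
imfs = est.fit_transform(signal)

pulse = parts[0]
corrs = [abs(np.corrcoef(imf.samples, pulse)[0, 1]) for imf in est.imfs_]
best = est.imfs_[int(np.argmax(corrs))]
print(f"{est.n_imfs_} IMFs; pulse IMF corr {max(corrs):.2f}; "
      f"envelope peak {best.signature.dominant_freq:.0f} Hz")
```

prints (seed 0):

```
4 IMFs; pulse IMF corr 0.84; envelope peak 125 Hz
```

Even at −5 dB the fused pulse mode's envelope spectrum peaks at exactly the
125 Hz repetition rate — the quantity a fault analyst reads off. `est.result_.diagnostics` holds the Blaschke spectrum, the
segment boundaries with their NFA values, the filter groups in Hz, and the
fusion trace; `ebmd.write_result` serialises IMFs to CSV and diagnostics to
JSON.

A command-line interface wraps the same pipeline:

```bash
ebmd simulate --case ecg --seed 1 --out sim        # signal + ground truth CSV
ebmd decompose sim.csv --rate 250 --out-dir out --plots
ebmd inspect out
```

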