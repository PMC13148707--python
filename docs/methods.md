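# Methods

`ebmd` decomposes a uniformly sampled real signal into *intrinsic mode
functions* (IMFs), each intended to carry one coherent periodic-pulse
constituent (a fault transient train, a QRS train, a tonal line). This note
records the model, the discretisation and numerical choices, the defaults and
why, what the synthetic generators do and do not emulate, and the known
limitations.

## Pipeline overview

1. **Analytic lift.** The real signal `x` (length `N`) becomes its one-sided
   analytic extension, read as boundary values of a Hardy-space function on
   the uniform circle grid `z_t = exp(i 2π t/N)`.
2. **Adaptive Blaschke transform.** Greedy expansion in a Takenaka–Malmquist
   rational orthonormal system with parameters `a_k` chosen from a finite
   disk dictionary; per-order mean power defines the *Blaschke spectrum*
   `BS(k)`.
3. **Unimodal pre-segmentation.** The spectrum axis is smoothed into a trend
   (mean truncation + maximum filter) and cut into statistically unimodal
   intervals by an a-contrario test (number of false alarms, NFA, against the
   Grenander nearest-monotone estimate). Each interval's partial
   reconstruction is a *mono-component*.
4. **Group sparse filtering.** Each mono-component's one-sided Fourier
   spectrum is masked by per-bin energy detection (`keep iff |c_i|² ≥ λ w_i`,
   the separable minimiser of `‖c − c∘f‖² + λ‖f‖₀,w`), then structured:
   gaps shorter than `min_gap` are filled, runs shorter than `min_group_len`
   dropped. **Each remaining group is inverted separately**, producing one
   *fundamental mode* per compact band. This is the "filter bank" reading: a
   single pulse train deliberately over-decomposes into its carrier band and
   sideband clusters, which the next stage re-assembles.
5. **Envelope-signature fusion.** Each fundamental mode's Hilbert envelope
   spectrum yields an *active band* (bins above the spectrum mean) and a
   *dominant frequency* (argmax — the pulse repetition rate). Modes merge
   when their bands' Jaccard overlap exceeds `thr` and dominant bins agree
   within `freq_tol_bins`; the merged signature is recomputed before further
   comparisons. Fusion is an exact partition: IMFs sum bit-near to the
   fundamental modes.

Reconstruction accounting: `x = Σ IMFs + filtered-out + unsegmented-orders +
transform tail` holds as a floating-point identity; its realised error is
stored in the diagnostics and is ≤ 1e−8 whenever the filters are all-pass.

## The transform in detail

The order-`n` basis function is
`B_n(z) = √(1−|a_n|²)/(1−ā_n z) · Π_{k<n} (z−a_k)/(1−ā_k z)`,
which reduces to `z^{n−1}` when all parameters vanish; in that limit the
transform *is* the one-sided FFT (verified to 1e−8 in the validation suite).
Inner products are discretised as means over the grid. Two numerical
choices make the recursion exact rather than asymptotic:

- the Szegő kernels used inside the recursion are re-normalised to exactly
  unit *discrete* norm (the analytic norm differs by O(|a|^N));
- the Blaschke factors are unimodular at the grid points in exact arithmetic,
  so dividing by them preserves the discrete norm.

Consequently `‖f_k‖² = |c_k|² + ‖f_{k+1}‖²` holds to machine precision at
every order, and `Σ components + residual` reproduces the analytic input
exactly. Because each recursion step divides by a degree-one Blaschke
factor, content at frequency bin `j` only becomes capturable around order
`k ≈ j`: **the transform order must reach the highest active bin**, exactly
as a Fourier series must. Study configurations size `max_order` accordingly
(e.g. 1300 orders for a resonance band near bin 1100).

### Parameter selection

Each order maximises the quasi-periodicity score of the candidate component
`c(a)·ê_a`: the magnitude of the summed lag autocorrelation,
`|Σ_{m≥1} R(m)|/N`. The lag sum telescopes: for samples `g`,
`Σ_m Σ_t g_{t+m} ḡ_t = Σ_s g_s · conj(Σ_{t<s} g_t)`, an O(N) cumulative-sum
identity, and for a candidate `c·ê_a` it equals `|c|²·T_a` with a per-atom
constant `T_a` precomputed once per (dictionary, N). Selection is therefore
`argmax_a |c(a)|² |T_a|`, one matrix–vector product per order. Ties break to
the smallest dictionary index; everything is deterministic.

Behavioural notes, measured and worth knowing:

- `|T_a|/N² ≈ (1−|a|²)/2` to first order, so the score is radius-biased: it
  favours small-radius (near-Fourier) atoms over large-radius ones capturing
  the same energy, and the flat atom `a = 0` whenever a strong DC component
  is present — which reproduces the `B_1 = 1` first-order convention.
- It is *not* a matched filter. A component planted at a high-radius atom can
  be out-scored by a smaller-radius atom along the same ray. Recovery of a
  planted atom is guaranteed in practice for same-radius dictionaries and
  moderate radii; the tests exercise exactly that regime.

The default dictionary is a polar grid (radii 0.1…0.9 × 64 phases, plus the
origin; 577 atoms). The study configurations use a coarser grid
(radii {0.1, 0.3, 0.5} × 16 phases): past selection behaviour is dominated by
the radius bias, the angular refinement contributes little, and the coarse
grid keeps a 1200-order transform around three seconds.

## Pre-segmentation in detail

The trend is `z(n) = max` over a centred width-`M` window (clipped at the
boundaries) of the spectrum with sub-mean values zeroed. The trend is read
as a histogram with `N = Σ z(i)` "samples" over `L` bins. For an interval
with observed mass fraction `Q` against a reference law mass `P`,
`NFA = L(L+1)/2 · B(N, NQ, P)` (upper binomial tail, mirrored when `Q < P`),
with the tail extended to real arguments through the regularized incomplete
beta `I_p(k, n−k+1)` — the continuous extension that coincides with the
direct sum at integers (checked to 1e−12). A slice is *statistically
monotone* when no sub-interval achieves `NFA ≤ δ` against the slice's
Grenander estimate; the Grenander estimate itself is pool-adjacent-violators
(the averaging D-transformation iterated to its fixed point), which is
simultaneously the least-squares and the minimum-KL monotone projection.
Unimodal representatives scan all mode positions and keep the minimum-KL
concatenation of an increasing and a decreasing fit.

Segmentation: strictly monotone runs of the trend are merged fine-to-coarse —
at each step the admissible merge with the *largest* min-NFA (the least
meaningful rejection) is applied, a deterministic order the description
"attempt merging all adjacent monotonic intervals" leaves open — then each
increasing run pairs with the following decreasing run into one unimodal
segment. Adjacent runs share their extremum index; segments are made
disjoint by convention (the shared index goes to the earlier segment).

Two practical caveats, both inherent to the amplitude-as-counts model:

- the test's power scales with the spectrum's absolute amplitude (a histogram
  test is sensitive to its sample count); signals of order unity give small
  `N` and hence liberal merging;
- mean truncation discards bands whose per-bin energy sits below the global
  spectrum mean. When one component dominates total energy (e.g. baseline
  drift against millivolt pulse trains), the weak bands vanish from the
  trend. For that regime the pipeline offers `segment_axis="fourier"`,
  which segments the one-sided Fourier *magnitude* spectrum and cuts
  mono-components as frequency bands (the text describing the method speaks
  of an inverse Fourier transform at exactly this step, so both readings are
  defensible); `"blaschke"` (default) and `"blaschke_rms"` (per-order RMS
  amplitudes, compressing dynamic range) stay on the order axis.

For segments with more than 50 000 sub-intervals the exact beta tails are
evaluated only on the 2000 intervals with the largest Chernoff exponent
`N·KL(q‖p)` (the first-order tail magnitude); below that size every interval
is evaluated exactly. Pair scores in the merge loop are cached; only pairs
adjacent to the last merge are re-scored.

## Filtering and fusion defaults

| parameter | default | why |
|---|---|---|
| `kappa` (λ = κ·median bin energy) | 10 | an exponential noise floor has P(E > 10·median) ≈ 2⁻¹⁰: isolated noise bins essentially never survive |
| median over | occupied bins | bins below 1e−12 of the peak are numerically empty (a band-limited mono-component leaves most of the transform length blank) and would drag the median to zero |
| `min_group_len` | 3 bins | an isolated super-threshold bin is noise, not a band |
| `min_gap` | 2 bins | sub-`min_gap` gaps inside one band are detector dropouts; study configs raise it to the sideband spacing so one carrier band forms one group |
| `thr` (fusion overlap) | 0.5 | majority band overlap; never stated in the reference experiments, engineering choice |
| `freq_tol_bins` | 1 | exact float equality of two argmax frequencies is meaningless |
| `mode_energy_floor` | 1e−6 | modes below this fraction of the strongest mode's energy are transform-leakage slivers; they return to the filtered-out remainder |
| `delta`, `epsilon` | 0.5 | the stated pre-segmentation threshold; the NFA meaningfulness constant read as ≤ 1/2 |
| `trend_window` | 9 (odd, clamped to the axis length) | the reference per-case windows (≈100 and ≈50, shipped as presets `case1`/`eeg`, made odd for a centred filter) presume a much longer spectrum axis than the default 64 orders |

If the length/gap constraints empty a segment's filter although the energy
detector kept bins, the raw detection runs are used — an on-bin tone is a
single-bin line and must survive filtering.

## Synthetic generators

All generators are pure functions of (spec, seed); mixtures return their
ground-truth parts, and `signal == Σ parts + noise` holds exactly. Noise is
drawn once and *rescaled* so the realised SNR matches the target to machine
precision — no Monte-Carlo slack in stated noise levels.

- **Gearbox-like study** (`gear_fault_mixture`): a 125 Hz fault-rate impulse
  train through a 2 kHz resonance with ring-down 200 s⁻¹ (Q ≈ 31), plus the
  40 Hz shaft line at half amplitude, 0.512 s (64 whole fault periods, so
  the repetition rate and its harmonics sit on the envelope-spectrum grid,
  as in order analysis) at 8 kHz, −5 dB white noise.
  The fault rate, shaft rate and noise level are the reference scenario's;
  duration, carrier and damping are fixture choices. The damping is chosen
  so the clean envelope's *fundamental* dominates its harmonics — with very
  short bursts (duty ≪ 1) the envelope spectrum's argmax genuinely sits on a
  harmonic, and the generator's contract (clean envelope argmax at f₀ ± 1
  bin) fails regardless of any analysis.
- **ECG-like study** (`ecg_like_mixture`): maternal-like (1.2 Hz, 16 Hz
  carrier, damping 10 s⁻¹) and fetal-like (2.2 Hz, 60 Hz carrier, damping
  15 s⁻¹) trains plus baseline drift below 0.4 Hz, 10 s at 250 Hz,
  noiseless. The ring-downs are chosen so the two trains occupy disjoint
  spectral bands — the separation claim under test concerns band-separable
  trains; with broad overlapping kernels not even an oracle band filter
  reaches 0.95 correlation. Drift harmonics lie on the analysis grid
  (window-periodic): off-grid truncated sinusoids add `1/Δbin` leakage
  across the whole axis, a window-boundary artifact of the finite fixture
  rather than a property of baseline wander; real drift would additionally
  require detrending.
- **EEG-like signal** (`eeg_like_signal`): seeded 1/√f-shaped band (0.5–40
  Hz) plus −2 dB noise.

What passing these fixtures does *not* show: robustness to physiological
pulse morphology (the kernels are damped sines, not QRS complexes), to
heart-rate variability beyond small timing jitter, to non-stationary noise,
or to components whose spectral bands genuinely interleave (two line spectra
at incommensurate repetition rates occupying one band cannot be separated by
any union-of-bands mask, this method's included).

## Known limitations

- The transform costs O(K·|dict|·N) and K must reach the highest active
  frequency bin; high sample rates want decimation first.
- Selection is phase- and radius-biased (see above); it is the stated
  functional, not an optimal matched pursuit.
- Segmentation inherits the counts interpretation's amplitude sensitivity;
  rescaling the input rescales the test's power.
- Fusion compares dominant envelope frequencies within ±1 bin; two pulse
  trains whose rates differ by less than an envelope bin will merge.
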