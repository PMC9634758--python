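# Methods

This note documents the model assumptions, parameter choices, numerical
conventions and known limitations of `vcgdelin`.  Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Signal model and conventions

A record is three equal-length orthogonal leads X, Y, Z sampled at a
common rate.  The working rate is 1000 Hz: records at other rates are
polyphase-resampled on ingestion, because every sample-denominated
constant of the algorithm (gap rules, search windows) is defined at
1000 Hz.  Amplitudes are kept in GAIN·mV with GAIN = 2000 — the native
integer scale of PTB-style recordings — so the one amplitude-denominated
threshold (THSLOPE = 10 per sample) operates on its original scale.

Sample indices are 0-based in memory (idiomatic numpy).  On-disk fiducial
files carry each index both as a 0-based sample column and in
milliseconds (index × 1000/fs), which makes the base convention
self-describing without duplicated 1-based columns.

## Preprocessing

*Baseline wander*: linear-phase FIR high-pass, passband edge 1 Hz
(±0.5 dB), stopband edge 0.5 Hz (≤ −61 dB).  The template fixes only the
band edges; the order (7949 taps at 1000 Hz) follows from the Kaiser
design rule with a 4 dB margin, and the measured response is asserted in
the tests.  The symmetric impulse response is applied centred on each
sample (edge-value padding), so the group delay is exactly compensated —
an impulse's energy centroid does not move — and fiducial indices are
unbiased.  Edge-value padding rather than zero extension avoids a step
transient at the record ends; the first/last ~4 s remain partially
settled, which is harmless because beats within 200 samples of the edges
are excluded anyway and all synthetic records keep beats ≥ 0.6 s from
the edges.

*Powerline*: second-order recursive notch (−3 dB width 0.17 Hz at 50 or
60 Hz) run forward-backward, cancelling its phase response and doubling
the attenuation (> 60 dB at f0).  Whether to apply it is decided from the
Welch spectrum: power in f0 ± 0.5 Hz greater than 4× the mean of the
flanking bands (f0 ∓ 1–3 Hz).  The 4× ratio is a design choice; the
decision can be forced either way.

## Wavelet engine

The CWT is discretised as a Riemann sum over the wavelet's compact
support at the signal rate,
`W(a,b) = a^(-1/2) Σ_m f(b+m) ψ(m/a)`, with zero extension beyond the
record.  ψ is the biorthogonal 2.2 decomposition wavelet tabulated by
PyWavelets and centred on its symmetry point — which sits half a grid
step off the tabulation midpoint; centring there keeps the transform of a
symmetric pulse symmetric to ~1e−9.  A brute-force per-sample evaluation
of the same sum serves as the oracle in the tests (agreement < 1e−6
relative).

The central frequency is estimated the way the classic wavelet toolboxes
do: magnitude FFT of the raw tabulation (level 8, no padding), dominant
non-DC bin, frequency = bin index / grid span.  This reproduces the
conventional printed value for bior2.2, 1.0008 Hz.  The true spectral
peak of the wavelet — dense tabulation with parabolic refinement,
available behind the `refine` flag — is 0.9255 Hz; the conventional
estimator is the default because the scale↔frequency table everyone
quotes (f_a = f_c/(a·Δ): 100, 33.4, 20, 14.3, 8.3 Hz for
a = 10…120) is built on it.

Scalogram energy is the squared coefficient over the grand sum of squares
per lead, ×100; only energy *ratios* enter the algorithm, so the
normalisation constant never matters downstream.

## Delineation logic

Parameters (all at 1000 Hz): RATIO_O = RATIO_A = 0.7, TTG = TTE = 200,
ε = 10, TTLS = 150, RATIO_LS = 0.3, TTSN = 10, TTLN = 25,
TT1LS = TT2LS = TT3LS = 200, ε1 = 16, ε2 = 24, TTAR = 50, TW = 10,
START = 30, STOP = 0, DELTA = 2, THSLOPE = 10, TTBS = 80, TW1 = 20,
START1 = 50, STOP1 = 10, DELTA1 = 2.  All are exposed in
`PipelineConfig`.

Points where the written rules underdetermine behaviour, and the choices
made:

* **Interval forgiveness (TTSN).**  A short (< TTSN) unsuitable interval
  is treated as suitable only when the *next* interval is suitable
  (sandwich rule).  Forgiving every short interval lets the
  zero-crossing chatter of band-limited noise (lobe lengths mostly
  < TTSN) carry the scan arbitrarily far from the QRS; with the sandwich
  rule the onset error on the noisy low-amplitude preset drops from
  ~76 ms to ~3 ms.
* **Virtual tail interval.**  When W30 stops crossing zero inside the
  ±TTLS window (typical right of the QRS, where the T-wave rise keeps
  W30 one-signed), the stretch from the outermost zero to the window
  edge is treated as one more interval, classified by the same
  threshold.  A trailing unsuitable interval can then form a stopping
  pair; without this, ends run systematically to the window edge.
* **Fine trace.**  Inside the interval just outward of the stopping zero
  point, the boundary is the last crossing of |W30| through
  γ·THLS (γ = 0.05) on the inward traversal — i.e. where residual
  activity finally dies away next to the zero point.  Degenerate cases:
  all-below extends to the interval's outer end, all-above (γ = 0) stays
  at the zero point.
* **Wide-QRS trigger.**  A boundary is *wide* when scalogram energy at
  scale 120 over the TT1LS/TT2LS window centred on it reaches 2× the
  scale-70 energy (the "double energy" ratio, config
  `wide_energy_ratio`), vetoed when any near-zone cell (±ε1/ε2) reaches
  0.5 of the window's maximum cell (config `wide_energy_near_ratio`) —
  energy packed against the boundary means a sharp, already
  well-delineated transition.  The veto fraction is a design choice; the
  ratio is not.
* **Slope adjustment.**  Ten-sample windows march toward the QRS across
  [q−START, q+STOP] (mirrored after the end).  The window slope is taken
  from its endpoints only, |f(end)−f(start)|/(TW−1).  If a window with
  accumulated shift > 3·DELTA exceeds THSLOPE, the boundary retreats to
  the QRS-side edge of the nearest *preceding* flat window, or to
  fid ∓ START when the whole zone is steep.  A flat zone (the normal
  case) leaves the boundary untouched.
* **Rounding.**  Interpolated zero crossings round to the nearest
  sample; synthesised candidates and alignment means round half away
  from zero; argmax ties resolve to the earliest sample.

Order of operations per beat and lead: W30 delineation → wide test and
possible W70 re-delineation per side → slope adjustment → inter-lead
alignment (spread > TTBS moves the farthest lead onto the mean of the
other two) → a final guard enforcing q < R < s.

## PQ window, loop boundaries, alignment

The PQ search slides 20-sample windows across [q−START1, q+STOP1] in
2-sample steps and keeps the window with the minimum absolute
least-squares slope (ties to the earliest window, which lies farther from
QRS energy).  ISO is the mean of f over the window's strict interior.
boundL uses the window *begin* (the whole isoelectric window lies inside
the loop); medians over beats use the mean-of-central-pair convention for
even counts, rounded.  Loops crossing a record edge are dropped with a
warning.

## Synthetic data

Beats are sums of Gaussian wave atoms (amplitude, centre, width per
wave), shared across leads up to per-lead gains (1.0, 0.7, −0.9), placed
at anchors with RR uniform in mean ± jitter.  Truth conventions: QRS
onset/end are the first/last samples where the summed absolute QRS-atom
envelope exceeds 1% of the R amplitude (`TRUTH_ENVELOPE_FRACTION`,
config-exposed); P end likewise for the P atom; the R peak is the
extremum of the clean lead inside the QRS; the isoelectric level is the
clean-signal mean between P end and onset.  Noise (white Gaussian —
optionally specified as SNR against the clean-signal rms — sinusoidal
baseline wander, powerline) is added after the truth is recorded.

Presets: `hc` — narrow QRS (~82 ms), dominant 1.1 mV R;
`mi_low_amp` — narrow QRS with small R (0.35 mV) against prominent P/T
and extra wideband noise; `bbb_wide` — slurred two-lobe complex
(σ = 15 ms each, opposite signs, ~150 ms at the 1% envelope), dominated
by sub-15 Hz content as wide complexes are.

What the generator does *not* emulate: real conduction-system morphology
(atoms are Gaussians), beat-to-beat morphology variation, ectopy,
arrhythmia, electrode artefacts, or amplitude asymmetry between
morphologically distinct leads.  Passing tests therefore demonstrate the
algorithmic contract — not clinical-grade accuracy on pathological
recordings.

## Accuracy characteristics and limitations

On the 20-record validation suite (60 s records, seeds 1–20, 20 dB SNR)
the pipeline finds every beat with no false positives (Se = P⁺ = 100%,
n ≈ 1315 pooled beats).

Boundary accuracy against the 1%-envelope truth is preset-dependent.
Narrow morphologies: onset MAE 4.3–4.8 ms, end MAE 7.6–8.7 ms.  The wide
preset carries a systematic offset (onset ≈ −29 ms, i.e. early): the
scale-70 zero-crossing boundary of a smooth wide complex sits one wavelet
side-lobe outside the 1% envelope point, which itself is far below
anything visible at realistic noise levels.  The two wide-QRS
requirements pull against each other — edges crisp enough for tight
1%-envelope delineation would remove the low-frequency dominance the
scale-switching trigger keys on — so the wide preset's boundaries should
be read as *consistent* (low spread within a record) rather than
*unbiased* against the 1% convention.

The PQ window lies strictly between the true P end and the true QRS
onset for 100% of beats on noise-free records.  At 20 dB SNR ~6% of
windows touch or cross the onset: at the true onset the signal equals 1%
of the R amplitude ≈ 0.7 of the noise standard deviation, and the search
range deliberately extends STOP1 = 10 samples past the detected onset,
so the flattest window occasionally lands there.  This is a property of
the truth convention under noise, not of the search itself.

Further limitations: P- and T-wave delineation is out of scope; there is
no search-back for missed beats nor RR-regularity heuristics; thresholds
are record-global (very long records with drifting amplitude would need
segmentation); the WFDB reader supports storage format 16 only.
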