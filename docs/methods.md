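# Methods

## Signal model and montage

The pipeline operates on 10–20 scalp EEG sampled at ≥ 1 kHz (reference
setting: 21 recorded electrodes, 1024 Hz). Analysis is performed on the
bipolar neighbour montage: every pair of adjacent electrodes of the 19
scalp positions, where adjacency is 8-connectivity on the standard 5-row
10–20 grid plus the physically adjacent Fp1–Fp2 and O1–O2 pairs. This rule
yields exactly 52 derivations and contains all diagonal derivations that
appear as highest-rate channels in published scalp-ripple tables (T5-C3,
F3-Cz, P4-Cz, Pz-O2, T3-F3, …). The pair list ships as
`data/montage_pairs.tsv`; a test re-derives it from the grid so file and
rule cannot drift. Pair names accept both electrode orders on input
("T3-F3" ≡ "F3-T3") and are canonicalized anterior-first/left-first; the
derived signal is anode − cathode. Every lateral derivation has a unique
left–right mirror (homologue); midline-only pairs and the self-mirroring
Fp1-Fp2 / O1-O2 have none and are exempt from the bilateral rejection rule.

Sample indices are 0-based and event spans half-open `[onset, offset)`.
Sleep-stage annotations are consumed, never computed: N3 spans within the
first 3 h after sleep onset (start of the first non-wake epoch) are tiled
into 300-s intervals, each N3 span from its own start, discarding residuals
shorter than 300 s and all annotated artifact spans. Analyses require at
least two intervals; a warning is emitted below three.

## Detector

**Stage I (baseline and thresholding).** The channel is band-passed to
80–250 Hz with a zero-phase FIR filter (Hamming, ~fs/4 taps, applied
forward–backward; an in-band tone is preserved within 2 %, a 10 Hz tone
attenuated > 80 dB). The Stockwell transform of each 1-s window gives a
time-averaged ripple-band power spectrum whose Shannon entropy is high when
the spectrum is flat (no oscillation). Windows with entropy at or above the
0.75 quantile form the baseline. Detection operates on the Hilbert envelope
of the band-passed trace smoothed by a 20-ms moving average; the detection
threshold is baseline mean + 5.5 SD of the smoothed envelope. Each
suprathreshold excursion is then delimited by walking outward on the
*unsmoothed* envelope down to baseline mean + 1 SD (detect high, delimit
low). Runs closer than 10 ms merge; runs shorter than 30 ms or with fewer
than 3 band-passed crests are dropped — noise excursions that cross the
threshold are predominantly shorter than 30 ms with ripple-like spectra, so
the duration floor does most of the false-positive rejection, at the cost
of blindness to the shortest (< ~35 ms) events.

The smoothing/threshold pair was chosen by measuring false-positive rates
on noise-only synthetic records against recall of 15 µV ripples: the raw
envelope at lower multipliers admits tens of accepted noise events per
minute across 52 channels, while the chosen point leaves well under one
accepted noise event per minute over the full montage at recall 0.8–1.0
for 15 µV / 60 ms events across seeds. Note
the threshold is baseline-relative (scale-invariant); only the Stage-III
40 µV and SNR rules are absolute.

**Stage II (isolated peak).** The S-transform power profile, averaged over
the event span within a ≥ 0.5-s context, must show a ripple-band peak
separated from the low-frequency (≤ 40 Hz) maximum by a trough whose power
is at most `stage2_trough_ratio` (default 0.5) of the ripple peak, boundary
inclusive. A filtered sharp transient has a monotonically decaying profile
— no trough — and is rejected.

**Stage III (scalp-specific rejection).** An event is rejected when its
band-passed peak-to-peak amplitude is ≥ 40 µV, its SNR is < 4, or an event
on the homologous derivation overlaps it in time (≥ 1 shared instant on
half-open spans; both partners are rejected). Precedence follows that
order. Events whose ±0.5-s SNR flanks are truncated below 0.25 s per side
by an interval edge get a distinct `rejected_edge` status. Boundary
semantics: amplitude exactly 40 µV is rejected, SNR exactly 4 is accepted.

Stage order is I → II → III; Stage-I/II constants live in
`DetectorConfig` and are implementation choices, the Stage-III constants
are the validated scalp criteria.

## Event and patient characteristics

* **Frequency** — reciprocal of the mean crest-to-crest interval of the
  band-passed event (crests: positive local maxima). The detector applies a
  relative height floor (25 % of the segment maximum) because noise crests
  in the low-amplitude tapers otherwise bias the estimate upward. An
  FFT-peak estimator is available (`method="fft"`) for sensitivity
  analysis. Results are clipped to 80–250 Hz.
* **Duration** — time the envelope stays above the delimitation threshold.
* **Amplitude** — largest |crest − trough| over adjacent extrema. This
  extreme-value statistic is upward-biased by background noise: at the
  default 1.5 µV background the bias is ~4–6 µV for 20–34 µV events
  (+15–25 %), shrinking proportionally with background RMS. Recovery of
  injected amplitudes to ±10 % therefore holds in the quiet high-SNR
  regime; at the default background the frequency (±5 Hz) and duration
  (±10 ms) means still recover.
* **SNR** — mean band-passed power inside the event over the mean power of
  the concatenated 0.5-s flanks; silent flanks yield an infinite-SNR
  sentinel with a warning.
* **Rate** — accepted events per channel divided by analyzed minutes
  (5 × number of intervals), so rate × minutes is integral.
* **Patient summary** — means of frequency/duration/amplitude/SNR over the
  accepted events on the top-rate channel (ties: higher count, then
  lexicographic name). Morphology means require more than 3 accepted
  events. RBA is the mean over intervals of the per-interval band-passed
  RMS of the top channel.

## Reliability

Consecutive non-overlapping groups of 5-min intervals form blocks (two per
block for the standard 10-min analysis, which requires > 20 min of data;
5-min blocks are the intervals themselves). The HFO area of a block is its
top-rate channel (empty blocks carry a none-sentinel that agrees only with
itself); reliability is the percentage of unordered block pairs with equal
areas. Because single-label agreement is transitive, attainable values are
restricted to sums of within-group pair counts — published intermediate
percentages produced by other profile-similarity definitions are not all
reproducible; the formula is isolated in one function so alternatives can
be swapped.

## Cohort statistics

Distributions are summarized by median and interquartile range (linear
interpolation between order statistics). Group comparisons use the
Wilcoxon rank-sum (Mann–Whitney, normal approximation with continuity and
tie correction) and signed-rank tests; correlations use tie-corrected
Spearman rank correlation. The HFO rate model is ordinary least squares on
an intercept, a CSWS indicator, an older-age indicator (age ≥ 7 years),
log10 seizure frequency (base 10 chosen so that one seizure per month maps
to 0, matching the intercept's interpretation; base e available), and RBA.
Age-trend correlations of morphology and detectability features are
computed over the patients with valid morphology (> 3 events, 29 of 30 in
the reference table) — these reproduce the published coefficients to
within table rounding, whereas the all-30 versions do not; the RBA–SNR
correlation uses all patients. p-values from rank tests are asserted only
as bounds because the upstream implementations (exact vs approximate
variants) are not specified.

## Synthetic data

The generator emulates the N3 analysis substrate, not full-night EEG: per
electrode, 1/f-weighted Gaussian noise (exponent 1) rescaled so the
ripple-band RMS equals `background_rms_uv` (default 1.5 µV), plus 0.5–2 Hz
slow waves (40 µV) and 1-s spindle bursts (11–15 Hz, 10 µV) that carry
negligible ripple-band power. Ripples are Tukey(0.5)-windowed sinusoids
specified at a bipolar derivation (+w/2 on the anode, −w/2 on the cathode,
so the derivation sees the stated peak-to-peak); this necessarily leaks
half-amplitude copies onto derivations sharing an electrode, which the
overlap-based evaluation credits to the same ground-truth event. Default
event parameters span the published scalp-ripple ranges (24–85 ms,
frequencies in band, amplitudes 10–34 µV straddling the SNR-4
detectability boundary). Decoy kinds: high-amplitude artifacts (80–120 µV,
so even half-amplitude leakage stays at or above the 40 µV limit) and
bilateral artifacts (40–80 µV on homologous pairs, large enough that their
leakage is detected on both sides and caught by the mirror rule).

The cohort generator draws ages uniformly over 0.7–17.4 years and imposes
rate = 4.5·exp(−age/5.5) HFO/min with lognormal noise (σ = 0.4) and
background RMS = 1.9 − 0.05·age µV (σ = 0.08, floor 0.8), roughly matching
published younger/older rate medians and RBA ranges; event frequency
centers drift downward with age. What passing tests on this material show:
the detector recovers known in-band events and rejects the modeled
artifact classes on a stationary Gaussian-background; they do not certify
behaviour on real EEG nonstationarities (arousals, electrode pops, EMG
bursts with in-band peaks) or on volume-conducted scalp topographies,
which the simulator intentionally does not model.

## Problem sizes and runtime

Full-scale runs (5-min, 52 channels) are used for the headline detection
quantities (~1.5 min each on one CPU). Unit and property tests use 60-s
records and a 10-electrode induced sub-montage (10 derivations); the
synthetic cohort in the acceptance script uses 10 patients × 2 min on that
sub-montage, which is sufficient for the sign of the rate–age trend. The
S-transform is computed per 1-s window restricted to the ripple band,
vectorized over frequency voices.

## Known limitations

* Stage-I/II constants are calibrated on the synthetic background; real
  recordings with different noise spectra may need retuning
  (`DetectorConfig` exposes all of them).
* The amplitude statistic's noise inflation (above) also applies to real
  data; reported amplitudes are upper-biased for low-SNR events.
* EDF writing uses 1-s records and truncates to whole seconds; annotations
  travel in a TSV sidecar rather than EDF+ annotation channels.
* Reliability is defined on the single top channel; multi-channel "area"
  definitions are not implemented (hook provided).
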