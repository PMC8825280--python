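# Methods

This note documents the models and procedures each module implements, the
parameters that matter (with defaults and units), the design choices made
where the underlying protocols leave the analysis open, what the synthetic
generators do and do not emulate, and the numerical conventions.

## Electrophysiology (`ephys`)

Whole-nerve vagal recordings are compound multiunit signals; no spike
sorting is attempted and all supra-threshold events are pooled.

**Spike detection.** The threshold is k × RMS of the voltage trace. k is
not dictated by the recording protocol, so it is configurable with a
default of 4.0, the common extracellular practice. RMS is computed over the
whole trace by default; a `rms_window_s` argument restricts it to an
initial (quiescent) segment, since either convention is defensible. A spike
is the time of the absolute-amplitude extremum of each contiguous
excursion of |v| above threshold; excursions beginning within the
refractory period (default 1 ms) of the previous spike are merged into it.
An all-zero trace has zero RMS and yields an empty train rather than an
error. Detection is amplitude-scale invariant because the threshold scales
with the trace.

**Rate estimation.** r(t) = Σᵢ N(t − tᵢ; σ) evaluated at the centers of a
regular grid (bin width 0.2 s). The kernel width σ is not dictated either;
the default is σ = 0.2 s (equal to the bin width) and it is configurable —
response-window summaries in the tests use σ = 2–3 s, where the
peak-of-a-noisy-estimate bias is small. No edge padding is applied: the
integral of the rate equals the spike count only for spikes a few σ inside
the window (mass conservation is guaranteed, and tested, to 1e-6 for
interior spikes).

**Normalization and metrics.** Each trial serves as its own control: the
rate is divided by its mean over the first 2 min (ratio normalization,
i.e. fold of baseline, matching how response traces are displayed;
subtraction is available via `mode="subtract"`). A zero baseline mean makes
the ratio undefined and raises with instructions to use raw rates. Response
metrics over [onset, window_end] (window_end defaults to onset + 360 s,
the minimum spacing between infusions): peak normalized rate, time from
onset to that peak, and the trapezoidal integral of (normalized − 1). The
AUC is signed by default — whether the original analysis integrated the
positive part only is not documented — with a `positive_part_auc` flag.

## Calcium imaging (`calcium`)

**Ratiometric (in vitro).** R = Fluo-4/Fura Red per frame (Fura Red must be
strictly positive; a non-positive frame is reported by index). A response
to a stimulus window is a fractional increase of R strictly greater than
10% over baseline. The re-baselining rule for later stimuli is explicit in
the protocol (five frames immediately before application); the baseline for
the *first* stimulus is defined the same way — the mean of the five frames
preceding the first window — mirroring that rule; the frame count is
configurable. ">10%" is implemented strictly: exactly 10% is not a
response. The terminal 50 mM KCl window applies the same rule as a
viability gate; non-viable cells carry no stimulus calls. Peak increases
can be normalized to the KCl peak.

**Single-channel (in vivo).** ΔF/F = (F − F̄)/F̄ with F̄ the mean over the
entire run, so the ΔF/F series has mean exactly zero. Because that
definition leaves "baseline" unspecified, the >20% response criterion is
applied against the mean ΔF/F of the pre-stimulus frames (all frames before
onset by default, configurable via `pre_window`).

**Overlap summaries.** venn_summary partitions viable units into a-only /
b-only / both / neither and reports percentages over responders (the
dissociated-cell and coculture convention) and over all viable units (the
in vivo convention), since both denominators are used. Populations with
zero responders are flagged rather than erroring. Coculture
electrophysiology responders (excitatory current present/absent) enter as
externally supplied boolean calls through the same summary.

## Single-cell RT–qPCR (`qpcr`)

Quality control sets wells below the 0.65 quality threshold (inclusive at
exactly 0.65) to undetected, then drops cells with no detected transcript
for either housekeeping gene (*Gapdh*, *Actb1*), reporting each dropped
cell and reason; the filter is idempotent. Control wells (0/10/100-cell
calibration wells) are assumed excluded before analysis.

RQ = 2^(34 − Cq) for detected wells and 0.5 for undetected ones; log₂ RQ is
exactly 34 − Cq. Heat-map normalization z-scores log₂ RQ per gene using the
population s.d. (ddof = 0), so a two-cell gene maps to (−1, +1);
zero-variance genes become zero columns with a warning.

Differential expression: per-gene two-tailed two-sample t-tests on log₂ RQ —
Welch by default, pooled-variance behind `equal_var=True` — with
Benjamini–Hochberg q-values across the panel (the open equivalent of the
commercial q-value used originally) and significance at q ≤ 0.05. Genes
identical and constant in both groups have an undefined t statistic and are
assigned p = 1 (no evidence). Fold change is the ratio of group means of
linear RQ; 2^(Δ mean log₂) is available behind `fold_change_basis="log2"`.
Printed fold changes from the original cell populations (e.g. 81.6) are not
recoverable without the underlying matrix and are not targets here.

Receptor classes: a gene is "expressed" in a cell iff detected after QC —
the semantics implied by the 0.5 substitution — not by an RQ magnitude
threshold. Percentages are computed within each mouse and summarized as
mean ± s.e.m. (s.d./√n across mice, ddof = 1); with a single mouse the
s.e.m. is reported as absent.

## Behavior (`behavior`)

Cleaning applies the carry-forward rule literally, left to right: a reading
lower than its (already corrected) predecessor is replaced by that most
recent value. This enforces monotonicity, never decreases a reading, is
idempotent, and preserves final intakes when dips revert within a tick.
Intakes are referenced to the session-start reading of each stream, not
absolute zero. Preference = 100 × sucrose/(sucrose + sucralose) at the
session end (60 min default); zero total intake flags the preference as
undefined instead of dividing by zero.

The stability rule is two consecutive tests both strictly above 66% with an
absolute difference of at most 15 percentage points ("15%" is read as
percentage points, not relative).

Schedules: the periodic program tiles the session with a period of
on + off minutes starting laser-on (1 on / 2 off, 40 Hz, 20% duty, 5 V by
default; pulse width = duty/frequency = 5 ms); a final partial on-interval
is truncated at the session end. The intake-triggered program emits one
5-s on-interval per 0.01 g quantum at the tick where the quantum appears;
overlapping or simultaneous intervals are merged into a single extended
interval because the hardware cannot double-fire, while the trigger count
(floor of total intake / quantum) is reported separately. The cage
firmware's internal smoothing/ADC parameters are not modeled — only their
downstream effect (quantized, occasionally dipping cumulative readings).

## Fiber optics and closed forms (`biophys`)

Cut-back analysis converts powers to attenuation in dB relative to the
shortest length, −10·log₁₀(P(L)/P(Lmin)), and fits α as the ordinary
least-squares slope versus (L − Lmin) — the conventional cut-back method;
fitting in the dB domain is equivalent up to transform to fitting percent
transmission, and a Theil–Sen option (`robust=True`) is provided. Only
power ratios matter, so the fit is invariant to uniform rescaling.

Tip power density divides output power by the fiber-core cross-section
(default 230 µm diameter, area π·0.115² ≈ 0.0415 mm²), the documented
assumption for reported optical intensities. Gallbladder volume uses the
ellipsoid approximation l·w·d·π/6 (µl from mm); emptying is the percent
change pre→post. Gastric emptying is percent volume remaining,
100·post/pre. Membrane capacitance C_m = τ·I₀/ΔE (ms·pA/mV = pF), and
maximum currents are normalized to C_m. Glutamate assays average the nine
reads per well, subtract the no-enzyme control mean, and interpolate on a
straight least-squares line through the kit standards (no 4-parameter
logistic); corrected absorbances outside the standard range are flagged as
extrapolated.

## Synthetic data (`synthetic`)

The generators emulate the *statistics of the measurements*, not the cell
biology: there is no receptor or neurotransmitter model, and no attempt to
match real noise spectra. Identical parameters and seed reproduce
byte-identical output, and every generator's labels are recoverable by its
analysis stage under the default (margin-safe) settings — which is what
passing tests demonstrate: correctness of the analysis rules, not
robustness to real-data artifacts such as drift, motion, bursting units or
correlated sensor noise.

Choices made where the protocols specify none:

* **Voltage.** Additive Gaussian noise (default 3 µV s.d.); spikes are a
  stereotyped biphasic 1-ms sine-cycle template (negative lobe first)
  scaled to the requested amplitude (default 60 µV), at times drawn from a
  piecewise-constant-rate Poisson process. Overlapping templates sum, so at
  high designed rates a few percent of spikes merge below the refractory
  period — the reason pipeline-recovery checks use moderate rates
  (20 Hz baseline, 3× epochs).
* **Calcium.** Triangular transients with designed peak fractional
  increases (defaults: responders 25%, non-responders 5%, KCl 15%, with
  0.2% frame noise) on the in vitro timeline (210 s at 1.5-s frames, 15-s
  stimuli with 30-s buffer, terminal KCl). Designs within ±1% of the 10%
  threshold are rejected as ambiguous. The in vivo generator uses the
  683-ms frame interval, 2-min baseline and 60-s stimuli, with 60% peaks
  so calls survive the run-mean ΔF/F re-referencing.
* **Cq matrices.** Detected Cq ~ Normal(26 − effect, 0.5) truncated below
  the cutoff of 34; the modest 0.5-cycle spread keeps planted effects
  decision-theoretically unambiguous at the design sample sizes (60 vs 30
  cells), per the construction-margin principle. Dropout is Bernoulli per
  non-housekeeping well; designed QC casualties lack both housekeeping
  genes. A companion generator draws receptor-class cells per mouse from
  designed multinomial fractions.
* **Intake.** Final intakes split total grams by the true preference,
  quantized to 0.01 g; quanta are scattered uniformly over ticks; sensor
  dips subtract a fixed magnitude for exactly one tick. Recovery of the
  designed preference is limited only by the 0.01-g quantization.
* **Optics.** power(L) = p0·10^(−α(L−Lmin)/10) times mean-1 lognormal noise
  with the requested coefficient of variation, so fits are unbiased.

## Problem sizes

The validation suite runs on desk-scale versions of the study designs: the
printed population sizes are reproduced exactly where they are the point
(47/59/54-cell imaging fixtures, 60 vs 30 qPCR cells, 1–10 cm cut-back
series), while Monte-Carlo checks use 10 seeds (electrophysiology
pipeline), 20 seeds (differential expression), 100 seeds (cut-back bias)
and 200 sessions (preference recovery) — sizes chosen so the whole suite
completes in well under a minute of compute apiece while the sampling error
of each check stays far below its tolerance.

## Known limitations

* Group-level animal statistics from the original recordings (peak-response
  comparisons across stimuli, the 58.9%/90.8% behavioral preferences, gene
  fold changes like 81.6) require the raw data and are out of scope; the
  package reproduces the rule-based classification layer and validates it
  on designed fixtures.
* The droplet single-cell RNA-seq workflow (alignment, integration,
  clustering, UMAP) is standard external tooling and is not re-implemented.
* Spike detection pools all units (no sorting) and applies no artifact or
  movement rejection; calcium analysis starts from extracted per-ROI
  traces (no image processing); amplification efficiency is not modeled in
  qPCR.
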