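# neuropod

Analysis toolkit for gut–brain sensory-transduction experiments: how duodenal
neuropod cells — enteroendocrine epithelial cells that synapse with vagal
afferents — transduce luminal sugar and sweetener stimuli to the vagus nerve
and steer an animal's preference for sugar over sweetener.

The package re-implements the complete quantification stack such a study
runs, as a tested, reusable library with a CLI, and pairs every stage with a
seeded synthetic-data generator carrying ground-truth labels, so each
pipeline can be exercised and validated end to end without raw recordings.

## What it computes

**Vagal electrophysiology** (`neuropod.ephys`). Whole-nerve extracellular
voltage → multiunit spike train via an RMS-threshold detector
(threshold = k·RMS, default k = 4; spike = extremum of each supra-threshold
excursion) → firing rate r(t) = Σᵢ N(t − tᵢ; σ) on a 200-ms bin grid →
normalization to the pre-stimulus baseline (first 2 min) → response metrics
per infusion: peak (fold of baseline), time to peak, and trapezoidal AUC of
(normalized rate − 1).

**Calcium response calling** (`neuropod.calcium`). In vitro ratiometric
traces: R = Fluo-4/Fura Red; a response is a ratio increase > 10% over the
mean of the five frames preceding the stimulus window (with re-baselining
before each subsequent stimulus); cells whose terminal 50 mM KCl transient
stays ≤ 10% are excluded as non-viable; peaks can be normalized to the KCl
peak. In vivo single-channel traces: ΔF/F = (F − F̄)/F̄ over the whole run,
with a > 20% response threshold against the pre-stimulus ΔF/F level.
Responder overlap between two stimuli is summarized as an a-only / b-only /
both / neither partition with percentages over responders and over all
viable units.

**Single-cell RT–qPCR** (`neuropod.qpcr`). Per-well quality control
(threshold 0.65) and exclusion of cells lacking both housekeeping genes
(*Gapdh*, *Actb1*); relative quantities RQ = 2^(34 − Cq) with RQ = 0.5 for
undetected wells; per-gene z-scoring of log₂ RQ; two-group Welch t-tests on
log₂ RQ with Benjamini–Hochberg q-values (cutoff 0.05) and linear
group-mean fold changes; receptor-coexpression classes (*Slc5a1* × *Tas1r3*)
as per-mouse percentages, mean ± s.e.m. across mice.

**Two-bottle behavior** (`neuropod.behavior`). Cage sensor streams
(cumulative grams every 5 s, 0.01 g resolution) cleaned by the carry-forward
rule (any reading below its predecessor is replaced by the most recent
value), binned at 1 min; preference = 100 × sucrose/(sucrose + sucralose);
the stable-preference admission rule (> 66% in two consecutive tests,
differing by ≤ 15 points); and the two laser programs — periodic 1 min on /
2 min off (40 Hz, 5 V, 20% duty → 5-ms pulses) and intake-triggered (5 s of
stimulation per 0.01 g consumed, overlapping triggers merged).

**Fiber optics & closed forms** (`neuropod.biophys`). Cut-back attenuation:
dB loss relative to the shortest length regressed on length, yielding α in
dB/cm; bend transmission; tip power density; gallbladder volume
(l·w·d·π/6) and emptying; gastric emptying (% remaining = 100·post/pre);
membrane capacitance C_m = τ·I₀/ΔE; glutamate concentrations from a plate
standard curve.

**Synthetic data** (`neuropod.synthetic`). Seeded generators for every
modality above, each returning the data plus a `GroundTruth` record (exact
spike times, designed responder classes, planted log₂ effects, true
preference, true α).

## Worked example

Simulate a dissociated-cell imaging session with a designed population —
21 KCl-only cells, 14 glucose-only, 4 sucralose-only and 8 dual responders —
then classify it:

```bash
neuropod simulate calcium --seed 1 --out sim
neuropod calcium sim/traces.tsv --windows sim/windows.yaml --out calls
```

which prints

```
47 viable, 26 responders (14/4/8 glucose-only/sucralose-only/both)
```

i.e. all 47 cells pass the KCl viability gate, 26 respond to at least one
stimulus, and the responder split is 53.8% glucose-only / 15.4%
sucralose-only / 30.8% both (written with the full summary to
`calls/venn.tsv`). The same goes for the library API; for example, the
electrophysiology pipeline on a simulated recording with a designed 3×
firing-rate response:

```python
from neuropod import synthetic, ephys

trace, truth = synthetic.gen_vagal_recording(
    duration_s=300, baseline_rate_hz=20, response_profile=[(120, 60, 3.0)], seed=1)
train, rate, baseline, metrics = ephys.analyze_recording(
    trace, [ephys.InfusionEvent("sucrose", 120, window_end=240)], kernel_sigma_s=3.0)
```

detects 8219 spikes, a 20.0 Hz baseline and a peak of 3.01× baseline at
+45.7 s after infusion onset — the designed multiplier recovered from raw
voltage.

Every output file carries a provenance header (`# version/seed/params`), and
reruns with the same seed are byte-identical.

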