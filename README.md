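# gazeseg

Denoising, segmentation and event classification for eye-tracking
recordings.

Gaze position signals are, to a good approximation, piecewise linear in
time: fixations are flat, smooth pursuits are slow ramps, saccades are
steep ramps, and post-saccadic oscillations (PSOs) are short segments with
near-180° direction reversals.  `gazeseg` exploits this structure
directly.  Instead of the traditional pre-filter → detect → segment
pipeline, it *first* fits a continuous piecewise-linear function to the
raw 2-D gaze trace — which simultaneously denoises and segments the signal
— and then classifies each linear segment as fixation, saccade, PSO or
smooth pursuit with a hidden Markov model.

## The model

Observed gaze $\vec{x}_i \in \mathbb{R}^2$ at times $t_i$ is modelled as

$$\vec{x}_i = \vec{g}(t_i) + \vec{\varepsilon}_i, \qquad
  \vec{\varepsilon}_i \sim \mathcal{N}(0, \sigma^2 I),$$

with $\vec g$ continuous and piecewise linear.  Segmentation maximizes the
penalized Gaussian log-likelihood

$$\sum_{\text{segments}} -\frac{\mathrm{SSE}}{2\sigma^2} \;-\; \lambda \cdot \#\text{splits}$$

by a forward dynamic program over split hypotheses with pruning in the
style of PELT (Pruned Exact Linear Time changepoint search).  Continuity
is enforced greedily — each new segment must start at the previous
segment's predicted value — which preserves optimal substructure; the
final reconstruction is then re-fitted as an exact continuous
least-squares linear spline over the found breakpoints.

The two parameters are handled automatically: the noise level $\sigma$ is
estimated by fixed-point iteration on the residual standard deviation
(plus a small "structural error", default 0.1°, absorbing tremor and
micro-movements), and the split penalty $\lambda$ comes from a shipped
table calibrated by simulation over eye-movement scenarios (saccade
amplitude $a^*$, slow-phase duration $d^*$ and speed $v^*$, tracker rate).

Classification operates per segment on two features — log mean speed and
the Fisher-transformed cosine of the angle to the previous segment — with
class-conditional Gaussian emissions estimated from labelled data and a
fixed transition matrix encoding oculomotor structure (PSOs only after
saccades, no saccade directly after a PSO, and a 2:1 labelling inertia for
fixation/pursuit runs).  Decoding is exact Viterbi; samples inherit their
segment's class.

The package also contains the supporting apparatus: a seeded eye-movement
simulator (jump/slow-phase target driving a damped-oscillator eye,
$\ddot{\vec x} = K(\vec x' - \vec x) - D\dot{\vec x}$ with $K=6000$,
$D=90$), the penalty calibration, and a benchmarking harness (ISNR, a
truth-informed Wiener reference filter, Cohen's kappa).

## Worked example

```sh
# 1. simulate a 20 s recording at 250 Hz with 0.5 deg noise
gazeseg simulate --seed 7 --duration 20 --sigma 0.5 --out-rate 250 measured.csv

# 2. denoise and segment it, estimating the noise level from the data
gazeseg denoise --sigma auto measured.csv segments.csv reconstruction.csv
```

The first command reports `wrote 5001 samples at 250.0 Hz (38 fast
phases)`; the second prints

```
76 segments, sigma=0.5969 deg, penalty=10
```

meaning: the trace was partitioned into 76 linear segments; the blind
noise estimate (≈0.50 deg estimated from the data + 0.1 deg structural
error) came out at 0.60 deg; and the split penalty 10 was looked up from
the shipped calibration table for the default scenario at 250 Hz.
`segments.csv` holds one row per segment (times, sample indices, endpoint
positions, mean speed); `reconstruction.csv` holds the denoised trace with
a segment id per sample.  Each output has a `.provenance.json` sidecar
with the resolved parameters.

From Python:

```python
from gazeseg import ScenarioParams, SegmentationConfig, simulate_recording, segment_gaze

sim = simulate_recording(ScenarioParams(duration=20.0, sigma=0.5, out_rate=250.0, seed=7))
seg = segment_gaze(sim.measured, SegmentationConfig())   # sigma and penalty automatic
print(seg.n_segments, seg.sigma_used)                    # 76 segments, 0.597 deg
recon = seg.reconstruct(sim.measured.t)                  # denoised positions, (n, 2)
```

To train and apply the event classifier you need per-sample labels
(`fixation|saccade|pso|pursuit|blink|other`) on some traces:

```sh
gazeseg train-classifier labeled1.csv labeled2.csv --out model.json
gazeseg classify --model model.json measured.csv out_segments.csv out_samples.csv
gazeseg agreement out_samples.csv coder1.csv coder2.csv --classes binary
```

## Data formats

Trace CSV: columns `t` (s, strictly increasing), `x`, `y` (degrees of
visual angle), optional `valid` (0/1) and `label`.  Comma-separated,
header row, `.` decimal separator, UTF-8.  Recordings from published
datasets can be used by converting them to this layout (time to seconds,
positions to degrees, outlier/blink flags to `valid=0`); no native parsers
for vendor formats are included.
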