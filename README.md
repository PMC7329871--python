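# echogaze

Analysis pipeline for the acoustic gaze and flight behaviour of
echolocating horseshoe bats (*Rhinolophus ferrumequinum nippon*) flying
repeated S-shaped obstacle courses under two acoustic conditions:
**permeable** walls built from hanging chains, which ultrasound passes
through, and **reflective** acrylic boards, which hide the space behind
them.  It is aimed at behavioural bioacousticians who want to study how
spatial learning reshapes sonar and flight control, and at anyone who
needs a tested microphone-array direction-reconstruction and
mixed-model stack for similar experiments.

Because the underlying raw recordings (on-animal telemetry audio,
20-channel array audio, stereo video) are not publicly deposited, the
package ships a first-class synthetic-data generator whose defaults are
calibrated to the study conditions, so every stage of the analysis is
runnable and testable from scratch.

## What it computes

**Array direction reconstruction.**  For each emitted pulse, the
received sound-pressure level on microphone channel *ch* at range
*r* is corrected for propagation and sensitivity,

    L_corr = L_raw + 20 log10(r / 1 m) + alpha r − s_ch,

with atmospheric absorption alpha = 2.4 dB/m at 65 kHz and per-channel
offsets *s_ch* from a 107 dB / 65 kHz / 1 m loudspeaker calibration.
A Gaussian directivity pattern with free baseline,

    L(theta) = b + A exp(−(theta − mu)² / (2 sigma²)),

is least-squares fitted over microphone bearing theta, and the
horizontal pulse direction is the fitted peak mu.  On noise-free
synthetic emissions across the accurate 2–5 m measurement band the
maximum reconstruction error is far below the 3° system error bound.

**Gaze and kinematics.**  Acoustic gaze angle (pulse direction minus
flight direction), Δpulse direction (absolute change between successive
pulses), acoustic gaze points (ray intersection with the axis of the
immediate obstacle wall), in-wall gaze rates, per-section gaze-point
histograms, 125-Hz speed profiles, maximum flight speed up to the third
wall, and the meandering width Δd of the S-shaped path.

**Strobe groups.**  Pulse trains are partitioned by the 40-ms rule:
runs of consecutive pulses with inter-pulse intervals all below 40 ms
form one strobe group — single, doublet, or multiple (triplet or more).

**Mixed models.**  Per-flight responses are modelled with a bat-ID
random intercept throughout: Gaussian LMM for maximum flight speed
(via statsmodels MixedLM) and Poisson log-link GLMMs for pulse counts,
fitted by adaptive Gauss–Hermite maximum likelihood (validated against
lme4::glmer in the test suite).  The battery includes estimated
marginal means with 95% CIs and Tukey-adjusted pairwise contrasts,
type-II Wald chi-square tests, AICc model selection, a collinearity
screen (which splits the speed model when |rho| > 0.5, as between
meandering width and flight number), Nakagawa marginal/conditional R²,
overdispersion checks, and a seeded parametric-bootstrap test against
null models.

## Worked example

```python
import numpy as np, pandas as pd
from echogaze import (SimulationConfig, simulate_cohort, count_by_type,
                      PoissonGLMM, in_wall_rate)
from echogaze.gaze import gaze_records

config = SimulationConfig(condition="permeable")   # 7 bats, flights 1 and 12
flights = simulate_cohort(config, np.random.default_rng(0))

pulses = pd.concat([f.pulses for f in flights], ignore_index=True)
counts = count_by_type(pulses)
res = PoissonGLMM.from_dataframe(counts, "total_pulses", ["flight_number"]).fit()
print(res.marginal_means("flight_number").to_string(index=False))

layout = config.layout()
recs = pd.concat([gaze_records(f.pulses.rename(
    columns={"true_direction_deg": "direction_deg"}), layout)
    for f in flights if f.flight_number == 12], ignore_index=True)
pct, k, n = in_wall_rate(recs)
print(f"12th-flight in-wall gaze rate: {pct}% ({k}/{n} pulses)")
```

prints

```
 flight_number    emmean  se_link  ci_lower  ci_upper
             1 50.714755 0.053076 44.538073 57.748040
            12 30.428832 0.068520 25.731816 35.983229
12th-flight in-wall gaze rate: 19% (40/213 pulses)
```

The estimated marginal means are the GLMM's fitted per-flight pulse
counts on the response scale: this seeded cohort emitted ~51 pulses per
flight before learning the course and ~30 after, with the expected drop
between the 1st and 12th flight, and roughly a fifth of the
12th-flight pulses aimed inside the (permeable) wall the bat was
approaching.

## Command-line pipeline

```sh
echogaze simulate --condition permeable --seed 1 --levels --out run/
echogaze localize --pulses run/pulses.csv --levels run/levels.csv \
                  --arena run/arena.yaml --out run/
echogaze metrics  --trajectories run/trajectories.csv \
                  --pulses run/localized_pulses.csv --arena run/arena.yaml --out run/
echogaze stats    --metrics run/flight_metrics.csv --seed 2 --out run/
echogaze report   --stats-json run/model_summaries.json \
                  --metrics run/flight_metrics.csv --out run/
```

`echogaze detect` turns telemetry WAV audio (fs = 500 kHz) into a pulse
table; supplying `--pulses` instead of `--audio` engages the
feature-level bypass so the downstream stages run without audio.  Every
stage writes a manifest (config hash, seed, input hashes) and re-runs
byte-identically under a fixed seed.

## Layout

| module | contents |
| --- | --- |
| `echogaze.arena` | chamber/wall/microphone geometry, sections, config I/O |
| `echogaze.simulate` | calibrated synthetic flights, schedules, gaze, levels, audio |
| `echogaze.signalproc` | spectrograms, pulse detection, tFM2 onsets, IPIs |
| `echogaze.localization` | propagation correction, calibration, directivity fits |
| `echogaze.gaze` | gaze angles, gaze points, in-wall rates, histograms |
| `echogaze.kinematics` | speed profiles, meandering width, strobe grouping |
| `echogaze.glmm` | Poisson GLMM / Gaussian LMM model & results objects |
| `echogaze.pipeline`, `echogaze.cli` | stage orchestration and the `echogaze` CLI |
| `echogaze.plotting` | flight-path, EMM and gaze-histogram figures |

See `docs/methods.md` for the modelling assumptions, calibration
choices and known limitations.
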