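# dyadsync

Dyadic cardiac synchrony analysis: second-by-second respiratory sinus
arrhythmia (RSA) estimation, pre-whitened lagged cross-correlation of
interbeat-interval (IBI) and RSA series between two interacting
partners, exhaustive shuffled-pair surrogate nulls, lagged affect
regression-out, and cohort-level inference — plus a synthetic
coupled-dyad generator with ground truth.

## Who this is for

Psychophysiology researchers studying interpersonal autonomic
coupling (e.g. mother–child dyads during cooperative play) who have
per-participant R-peak event times and, optionally, second-by-second
behavioral codings, and who want the full protocol — signal
extraction, pre-whitening, surrogate control, affect attribution,
group statistics — as one tested, scriptable pipeline.

## The statistic

For each dyad, condition and signal, both partners' per-second series
are pre-whitened (order-2 polynomial detrend, then ARIMA(1,1,1)
innovations without constant) and correlated at integer lags:

    r(k) = corr( mother[t], child[t+k] ),   k ∈ {−3, …, +3} s

Positive k: the mother's signal precedes the child's ("mother
leads"); negative k: the child leads. IBI series are 10-Hz resampled
interbeat intervals averaged into 1-s epochs; RSA series are the
natural log of multitaper (Slepian bank) spectral power of the 4-Hz
spline-interpolated IBI series in the 0.12–0.40 Hz respiration band,
from 32-s windows sliding in 1-s steps. Task-driven similarity is
controlled by a dyad-specific surrogate: the mean r(k) over all
cross-dyad pairings in the same condition. The contribution of
positive affect is measured by regressing 21 lagged copies of a
binary affect series out of the raw ANS series and recomputing
synchrony. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 6-dyad cohort whose interactive conditions carry latent
coupling with the child leading by 2 s, then run the full pipeline:

```
dyadsync simulate --out cohort --seed 7 --n-dyads 6 --preset coupled
dyadsync run-all --manifest cohort/manifest.csv --out results --signal ibi
```

or in Python:

```python
import numpy as np
from dyadsync import SimulationConfig, simulate_dyad, compute_synchrony

cfg = SimulationConfig(coupling_lag_s=-2, seed=11)
dyad, truth = simulate_dyad(cfg, "La1", np.random.SeedSequence(11))
profile = compute_synchrony(dyad, source="ibi")
for lag, r in zip(profile.lags, profile.r):
    print(f"lag {lag:+d} s   r = {r:+.3f}")
print("argmax lag:", profile.argmax_lag())
```

prints

```
lag -3 s   r = +0.011
lag -2 s   r = +0.199
lag -1 s   r = +0.009
lag +0 s   r = +0.009
lag +1 s   r = -0.062
lag +2 s   r = +0.053
lag +3 s   r = -0.034
argmax lag: -2
```

The profile peaks at lag −2 s — the injected child-leads coupling —
at r ≈ 0.20, while the remaining lags fluctuate around zero as the
pre-whitening intends. `run-all` writes per-dyad profiles, surrogate
comparisons, affect-cleaned profiles, paired-test / mirrored-lag /
mixed-model tables, and an across-dyad correlation matrix as CSV,
together with the effective YAML configuration.

## Layout

```
src/dyadsync/
  simulate.py    coupled-dyad generator (OU latent, Markov affect, IPFM beats)
  ibi.py         10-Hz IBI resampling, 1-s epoch means
  rsa.py         spline interpolation, sliding multitaper band power, ln RSA
  synchrony.py   detrend, ARIMA pre-whitening, lagged cross-correlation
  surrogate.py   exhaustive shuffled-pair surrogate profiles
  affect.py      affect binarization, lagged regression-out, shuffled controls
  stats.py       paired tests, FDR, random-intercept LMM (Satterthwaite), correlations
  io.py          CSV formats, cohort manifest
  pipeline.py    stage orchestration
  cli.py         `dyadsync` subcommands (simulate, preprocess, rsa, sync,
                 surrogate, clean, stats, run-all)
```
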