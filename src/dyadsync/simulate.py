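"""Coupled-dyad generator: paired cardiac and affect series with ground truth.

The generator produces, per dyad and condition, mother and child R-peak
series plus per-second binary positive-affect series, with the
statistical structure the synchrony analysis assumes:

* a shared latent Ornstein-Uhlenbeck process (timescale ~10 s) drives
  both partners' instantaneous heart period, with a configurable lead
  lag — negative lag means the child receives the latent first ("child
  leads") — and gain; coupling is active only in the interactive
  conditions (La1, La2), zero at Rest and during Single play;
* a respiration-band sinusoidal heart-period oscillation (distinct
  adult and child respiration frequencies) whose amplitude is what the
  RSA estimator measures; positive affect can scale this amplitude
  multiplicatively and shift the heart period additively;
* sparse positive-affect episodes from a two-state Markov chain at
  1 Hz, with an imitation mechanism letting the child's episodes lead
  the mother's by the coupling lag;
* beats generated from the instantaneous heart-period function m(t) by
  the forward recursion t_{i+1} = t_i + m(t_i)/1000 (an integral-pulse
  style beat generator).

Every random stream derives from one seed via `numpy` SeedSequence
spawning, so a cohort is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .errors import ParameterError
from .series import (AffectSeries, Cohort, CONDITIONS, DyadRecord,
                     INTERACTIVE_CONDITIONS, RPeakSeries)


@dataclass
class SimulationConfig:
    """Generator parameters (the study conditions of every simulation).

    Heart periods default to typical adult (850 ms) and school-age
    child (700 ms) values; respiration sits in the analysis band
    (0.12-0.40 Hz) for both; affect occupies 4-14% of task time in
    short (~6 s) episodes. ``coupling_lag_s`` is signed: negative means
    the child's signal leads the mother's. The reference coupling gain
    is calibrated so that pipeline lag-0 IBI synchrony of an
    interactive condition lands near the 0.1-0.2 range typical of
    mother-child play, strong enough that the injected lag is
    recoverable from a single 300-s dyad.
    """

    n_dyads: int = 10
    duration_s: float = 300.0
    mean_rr_adult_ms: float = 850.0
    mean_rr_child_ms: float = 700.0
    resp_freq_hz: tuple[float, float] = (0.25, 0.30)   # (adult, child)
    resp_freq_jitter_hz: float = 0.02    # per-participant uniform jitter
    resp_random_phase: bool = True
    rsa_mod_depth_ms: float = 25.0
    coupling_gain: float = 40.0       # ms per unit latent (unit-variance OU)
    coupling_lag_s: int = -2
    latent_timescale_s: float = 10.0
    affect_rate: float = 0.10
    affect_mean_bout_s: float = 6.0
    affect_imitation_prob: float = 0.0
    affect_rr_effect_ms: float = 0.0
    affect_rsa_gain: float = 0.0
    noise_sd_ms: float = 12.0
    seed: int = 0

    def __post_init__(self):
        self.resp_freq_hz = tuple(self.resp_freq_hz)
        if min(self.mean_rr_adult_ms, self.mean_rr_child_ms) <= 0:
            raise ParameterError("heart periods must be positive")
        if not 0 <= self.affect_rate < 1:
            raise ParameterError("affect_rate must be in [0, 1)")
        if self.affect_mean_bout_s < 1:
            raise ParameterError("mean bout length must be >= 1 s")
        if abs(self.coupling_lag_s) > 3:
            raise ParameterError("|coupling_lag_s| must be <= 3 s")
        if self.latent_timescale_s <= 0 or self.duration_s < 1:
            raise ParameterError("timescale and duration must be positive")


@dataclass
class GroundTruth:
    """What the generator injected, for downstream verification."""

    coupling_lag_s: int
    coupling_gain: float
    seed: int
    latent: dict = field(default_factory=dict)    # (dyad, condition) -> array
    affect: dict = field(default_factory=dict)    # (dyad, role, condition) -> array
    dyad_seeds: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {"coupling_lag_s": self.coupling_lag_s,
                "coupling_gain": self.coupling_gain, "seed": self.seed}


def ou_latent(n: int, timescale_s: float, rng: np.random.Generator
              ) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck process sampled at 1 Hz.

    Exact discretisation x[t+1] = a x[t] + sqrt(1-a^2) z with
    a = exp(-1/timescale); initialised from the stationary law.
    """
    a = np.exp(-1.0 / timescale_s)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = np.sqrt(1 - a * a) * rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = a * x[t - 1] + innov[t - 1]
    return x


def _markov_binary(n: int, rate: float, mean_bout_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Stationary two-state chain at 1 Hz: P(on) = rate, mean on-run =
    mean_bout_s."""
    if rate == 0:
        return np.zeros(n, dtype=int)
    q_off = 1.0 / mean_bout_s                      # on -> off
    q_on = rate * q_off / (1.0 - rate)             # off -> on
    if q_on > 1:
        raise ParameterError(
            f"affect_rate {rate} with mean bout {mean_bout_s}s implies "
            f"off->on probability {q_on:.3f} > 1")
    x = np.empty(n, dtype=int)
    x[0] = int(rng.random() < rate)
    u = rng.random(n - 1)
    for t in range(1, n):
        if x[t - 1]:
            x[t] = 0 if u[t - 1] < q_off else 1
        else:
            x[t] = 1 if u[t - 1] < q_on else 0
    return x


def _shift_binary(x: np.ndarray, shift: int) -> np.ndarray:
    """x delayed by ``shift`` s (zeros fill the exposed edge)."""
    out = np.zeros_like(x)
    if shift == 0:
        out[:] = x
    elif shift > 0:
        out[shift:] = x[:-shift]
    else:
        out[:shift] = x[-shift:]
    return out


def simulate_affect(cfg: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[AffectSeries, AffectSeries]:
    """Mother and child binary positive-affect series at 1 Hz.

    The child's series is a stationary two-state Markov chain. With
    imitation probability 1 the mother's series is exactly the child's
    delayed by |coupling_lag_s| s; with probability 0 it is an
    independent chain; in between, each child episode is copied
    (delayed) into the mother's otherwise independent series with the
    given probability.
    """
    n = int(np.floor(cfg.duration_s))
    if n < 1:
        raise ParameterError("duration must be >= 1 s")
    child = _markov_binary(n, cfg.affect_rate, cfg.affect_mean_bout_s, rng)
    delay = abs(cfg.coupling_lag_s)
    if cfg.affect_imitation_prob >= 1.0:
        mother = _shift_binary(child, delay)
    else:
        mother = _markov_binary(n, cfg.affect_rate, cfg.affect_mean_bout_s,
                                rng)
        if cfg.affect_imitation_prob > 0:
            shifted = _shift_binary(child, delay)
            edges = np.flatnonzero(np.diff(np.concatenate(([0], shifted))) == 1)
            runs = np.flatnonzero(np.diff(np.concatenate((shifted, [0]))) == -1)
            for start, stop in zip(edges, runs):
                if rng.random() < cfg.affect_imitation_prob:
                    mother[start:stop + 1] = 1
    return (AffectSeries(mother, role="mother"),
            AffectSeries(child, role="child"))


def simulate_rr_target(cfg: SimulationConfig, role: str,
                       affect: np.ndarray, latent: np.ndarray,
                       rng: np.random.Generator):
    """Instantaneous heart-period function m(t) in ms for one partner.

    m(t) = mean_rr + gain * latent(t - role_delay)
         + depth * (1 + rsa_gain * affect(t)) * sin(2 pi f_resp t + phase)
         + rr_effect * affect(t) + noise(t)

    The latent and the noise (white at 1 Hz) are linearly interpolated
    between their 1-s samples; affect is zero-order held per second.
    The role delay places the latent lead on the configured partner:
    with a negative coupling lag the mother is delayed (child leads).

    Each participant breathes at their own phase and at a frequency
    jittered around the role's nominal rate: two people never share a
    deterministic phase-locked oscillation, and an uncoupled pair must
    show no systematic covariation.
    """
    adult = role == "mother"
    mean_rr = cfg.mean_rr_adult_ms if adult else cfg.mean_rr_child_ms
    f_nominal = cfg.resp_freq_hz[0] if adult else cfg.resp_freq_hz[1]
    f_resp = f_nominal + rng.uniform(-1, 1) * cfg.resp_freq_jitter_hz
    phase = rng.uniform(0, 2 * np.pi) if cfg.resp_random_phase else 0.0
    if cfg.coupling_lag_s <= 0:
        delay = -cfg.coupling_lag_s if adult else 0
    else:
        delay = 0 if adult else cfg.coupling_lag_s
    n = latent.size
    t_grid = np.arange(n, dtype=float)
    noise = rng.standard_normal(n) * cfg.noise_sd_ms
    aff = np.asarray(affect, dtype=float)

    def m(t):
        t = np.asarray(t, dtype=float)
        lat = np.interp(t - delay, t_grid, latent)
        eps = np.interp(t, t_grid, noise)
        a = aff[np.clip(t.astype(int), 0, aff.size - 1)] if aff.size else 0.0
        depth = cfg.rsa_mod_depth_ms * (1.0 + cfg.affect_rsa_gain * a)
        return (mean_rr + cfg.coupling_gain * lat
                + depth * np.sin(2 * np.pi * f_resp * t + phase)
                + cfg.affect_rr_effect_ms * a + eps)

    probe = m(np.arange(0, cfg.duration_s, 0.25))
    if np.any(probe <= 200.0):
        raise ParameterError(
            "instantaneous heart period fell below 200 ms; "
            "reduce gains/depths or noise")
    return m


def rr_target_to_rpeaks(m, duration_s: float) -> RPeakSeries:
    """Generate beats from a heart-period function by forward recursion.

    First beat at t = 0; each next beat follows after the current
    instantaneous period, t_{i+1} = t_i + m(t_i)/1000; generation stops
    at the recording duration.
    """
    times = [0.0]
    t = 0.0
    while True:
        step = float(m(t)) / 1000.0
        if step <= 0.2:
            raise ParameterError("nonphysiological heart period < 200 ms")
        t = t + step
        if t > duration_s + 1e-12:
            break
        times.append(t)
    return RPeakSeries(np.asarray(times), duration_s=duration_s)


def _condition_config(cfg: SimulationConfig, condition: str
                      ) -> SimulationConfig:
    """Interactive conditions keep coupling and imitation; Rest/Single
    are uncoupled (independent partners) and have no coded affect."""
    if condition in INTERACTIVE_CONDITIONS:
        return cfg
    return replace(cfg, coupling_gain=0.0, affect_imitation_prob=0.0,
                   affect_rate=0.0, affect_rr_effect_ms=0.0,
                   affect_rsa_gain=0.0)


def simulate_dyad(cfg: SimulationConfig, condition: str,
                  seed_seq: np.random.SeedSequence,
                  dyad_id: str = "d00") -> tuple[DyadRecord, dict]:
    """One dyad's mother+child recordings for one condition."""
    ccfg = _condition_config(cfg, condition)
    streams = seed_seq.spawn(4)
    rng_latent, rng_affect, rng_m, rng_c = map(np.random.default_rng, streams)
    n = int(np.floor(ccfg.duration_s))
    latent = ou_latent(n, ccfg.latent_timescale_s, rng_latent)
    mother_aff, child_aff = simulate_affect(ccfg, rng_affect)
    m_mother = simulate_rr_target(ccfg, "mother", mother_aff.values, latent,
                                  rng_m)
    m_child = simulate_rr_target(ccfg, "child", child_aff.values, latent,
                                 rng_c)
    rec = DyadRecord(
        dyad_id=dyad_id, condition=condition,
        mother_rpeaks=rr_target_to_rpeaks(m_mother, ccfg.duration_s),
        child_rpeaks=rr_target_to_rpeaks(m_child, ccfg.duration_s),
        mother_affect=mother_aff if condition in INTERACTIVE_CONDITIONS
        else None,
        child_affect=child_aff if condition in INTERACTIVE_CONDITIONS
        else None)
    truth = {"latent": latent, "mother_affect": mother_aff.values,
             "child_affect": child_aff.values}
    return rec, truth


def simulate_cohort(cfg: SimulationConfig,
                    conditions=CONDITIONS) -> tuple[Cohort, GroundTruth]:
    """A full cohort: n_dyads x {Rest, Single, La1, La2}.

    Coupling and affect imitation are active only in the interactive
    conditions. Each dyad draws from an independent substream of the
    seed, so adding dyads never perturbs existing ones.
    """
    cohort = Cohort()
    truth = GroundTruth(coupling_lag_s=cfg.coupling_lag_s,
                        coupling_gain=cfg.coupling_gain, seed=cfg.seed)
    for i in range(cfg.n_dyads):
        dyad_id = f"d{i:03d}"
        truth.dyad_seeds[dyad_id] = (cfg.seed, i)
        for j, condition in enumerate(conditions):
            dseq = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i, j))
            rec, t = simulate_dyad(cfg, condition, dseq, dyad_id=dyad_id)
            cohort.add(rec)
            truth.latent[(dyad_id, condition)] = t["latent"]
            if condition in INTERACTIVE_CONDITIONS:
                truth.affect[(dyad_id, "mother", condition)] = \
                    t["mother_affect"]
                truth.affect[(dyad_id, "child", condition)] = \
                    t["child_affect"]
    return cohort, truth


def null_config(**overrides) -> SimulationConfig:
    """Uncoupled partners everywhere (coupling gain 0, no imitation)."""
    base = dict(coupling_gain=0.0, affect_imitation_prob=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


def coupled_config(**overrides) -> SimulationConfig:
    """Reference latent-coupled cohort (child leads by 2 s in La1/La2)."""
    return SimulationConfig(**overrides)


def affect_driven_config(**overrides) -> SimulationConfig:
    """Coupling carried by shared affect, not by a latent process.

    The child's affect episodes are imitated by the mother at lag 0 and
    shift both partners' heart period; the latent gain is off, so any
    synchrony is attributable to affect — the regime the affect
    regression-out is designed to detect.
    """
    base = dict(coupling_gain=0.0, coupling_lag_s=0,
                affect_imitation_prob=1.0, affect_rr_effect_ms=40.0,
                affect_rsa_gain=0.5, affect_rate=0.12,
                affect_mean_bout_s=8.0)
    base.update(overrides)
    return SimulationConfig(**base)


def config_as_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["resp_freq_hz"] = list(cfg.resp_freq_hz)
    return d
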