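"""Pipeline configuration: spectral, pre-whitening and lag parameters.

One flat YAML document on disk; every default is overridable and the
effective configuration is echoed into the output directory so a run can
be reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Analysis parameters.

    Defaults follow the standard dyadic-synchrony protocol: IBI resampled
    at 10 Hz and averaged into 1-s epochs; RSA from a cubic-spline 4 Hz
    IBI series via 32-s multitaper windows sliding in 1-s steps (31 s
    overlap) over the 0.12-0.40 Hz respiration band; quadratic detrend
    plus ARIMA(1,1,1) pre-whitening; cross-correlation at lags -3..+3 s;
    affect regression-out at lags -10..+10 s.
    """

    epoch_s: float = 1.0
    resample_hz: int = 10
    rsa_interp_hz: int = 4
    rsa_window_s: int = 32
    rsa_overlap_s: int = 31
    rsa_band_hz: tuple[float, float] = (0.12, 0.40)
    rsa_n_tapers: int = 3
    rsa_time_bandwidth: float = 2.5
    sync_max_lag_s: int = 3
    clean_max_lag_s: int = 10
    arima_order: tuple[int, int, int] = (1, 1, 1)
    detrend_order: int = 2
    fisher_z_average: bool = False      # average surrogate r on z scale
    clean_use_both_individual: bool = False  # both partners' affect as predictors
    effect_size: str = "dz"             # dz | dav for paired tests
    fdr_alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rsa_band_hz = tuple(self.rsa_band_hz)
        self.arima_order = tuple(self.arima_order)
        self.validate()

    def validate(self) -> None:
        low, high = self.rsa_band_hz
        if not (0 < low < high < self.rsa_interp_hz / 2):
            raise ParameterError(
                f"band {self.rsa_band_hz} must satisfy "
                f"0 < low < high < Nyquist ({self.rsa_interp_hz / 2} Hz)")
        if not self.rsa_overlap_s < self.rsa_window_s:
            raise ParameterError("rsa_overlap_s must be < rsa_window_s")
        if self.sync_max_lag_s < 0 or self.clean_max_lag_s < 0:
            raise ParameterError("lag ranges must be symmetric about 0 "
                                 "(max lag >= 0)")
        if not self.resample_hz * self.epoch_s == int(self.resample_hz * self.epoch_s):
            raise ParameterError("resample_hz * epoch_s must be integral")
        if not 0 < self.fdr_alpha < 1:
            raise ParameterError("fdr_alpha must be in (0, 1)")
        if self.effect_size not in ("dz", "dav"):
            raise ParameterError("effect_size must be 'dz' or 'dav'")

    @property
    def sync_lags(self) -> list[int]:
        k = self.sync_max_lag_s
        return list(range(-k, k + 1))

    @property
    def clean_lags(self) -> list[int]:
        k = self.clean_max_lag_s
        return list(range(-k, k + 1))

    def to_yaml(self) -> str:
        d = asdict(self)
        d["rsa_band_hz"] = list(self.rsa_band_hz)
        d["arima_order"] = list(self.arima_order)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
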