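"""Default loop configuration and config-file handling.

Every tunable of the inner PD+IFB loop, the SAFE layer and the DRB tuner
lives in :class:`LoopConfig`; the defaults are the published tuning of the
control stack (Kp = TDI/2250 U/min per mg/dl, Td = 90 min, G_r = 100 mg/dl,
gamma = 0.42, W = 350 mg/dl, tau = 10 min, lambda = 0.1 min^-1,
K_DIA = 0.013 min^-1, trigger/release thresholds 150/140 mg/dl, K_IOB 1.3
by day and 1.1 by night).  Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass(frozen=True)
class LoopConfig:
    # inner loop
    kp: float | None = None        # U/min per mg/dl; None -> TDI/2250
    td: float = 90.0               # derivative time, min
    g_r: float = 100.0             # glucose setpoint, mg/dl
    gamma: float = 0.42            # insulin-feedback gain
    # SAFE layer
    tau: float = 10.0              # sliding time constant, min
    w: float = 350.0               # switching amplitude, mg/dl
    lam: float = 0.1               # reference-filter rate, 1/min
    # IOB estimator
    k_dia: float = 0.013           # elimination rate, 1/min
    iob_method: str = "heun"       # "heun" or "exact"
    # DRB tuner
    g_trigger: float = 150.0       # raise threshold, mg/dl
    g_release: float = 140.0       # release threshold, mg/dl
    t_iob_slope: float = 1.5       # evaluation delay, min per announced gram
    k_iob_day: float = 1.3
    k_iob_night: float = 1.1
    day_start: str = "06:00"
    night_start: str = "23:00"
    # timing / sensing
    sample_period: float = 5.0     # controller & CGM period, min
    plant_dt: float = 1.0          # internal plant step, min
    cgm_noise_sd: float = 0.0      # mg/dl
    smooth_derivative: bool = False  # 3-point moving average on dG/dt

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LoopConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "LoopConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
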