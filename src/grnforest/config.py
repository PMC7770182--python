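"""Flat run configuration with the recommended defaults.

Defaults follow the published recommendations for the inference forest
(1000 trees, n_test = ceil((N-1)/3), height cap 32, log-beta search range
[-10, 5]) and for the feature-selection stage (100 replicate ensembles of
100 trees, significance level 0.01, VR-Trees alpha 0.5, mixing parameter
p = 0.9); measurement weights default to 1.0 (time-series) and 1.1
(static). A configuration file is a flat YAML/key-value mapping; explicit
flags override file values, which override defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .exceptions import ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # smoothing
    span: float = 0.3
    kernel: str = "tricube"
    # inference ensemble
    n_tree: int = 1000
    n_test: int | None = None  # None -> ceil(n_inputs / 3)
    h_max: int = 32
    min_node: int = 2
    importance: str = "variance"
    # beta search
    log_beta_lo: float = -10.0
    log_beta_hi: float = 5.0
    gss_tol: float = 0.01
    beta_exponent: int = -1
    search_n_tree: int | None = None  # None -> same as n_tree
    # feature selection
    enable_fs: bool = True
    n_rf: int = 100
    fs_trees: int = 100
    alpha_s: float = 0.01
    vr_alpha: float = 0.5
    fs_confidence: str = "win_rate"
    # combination
    p: float = 0.9
    # execution
    seed: int = 0
    workers: int = 1

    def validate(self) -> "RunConfig":
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p={self.p} outside [0, 1]")
        if not (0.0 < self.span <= 1.0):
            raise ValidationError(f"span={self.span} outside (0, 1]")
        if self.kernel not in ("tricube", "uniform"):
            raise ValidationError(f"unknown kernel: {self.kernel!r}")
        if not (0.0 < self.alpha_s < 1.0):
            raise ValidationError(f"alpha_s={self.alpha_s} outside (0, 1)")
        if not (0.0 <= self.vr_alpha <= 1.0):
            raise ValidationError(f"vr_alpha={self.vr_alpha} outside [0, 1]")
        if self.n_tree < 1 or self.fs_trees < 1 or self.n_rf < 1:
            raise ValidationError("tree/replicate counts must be >= 1")
        if self.gss_tol <= 0:
            raise ValidationError("gss_tol must be positive")
        if not self.log_beta_lo < self.log_beta_hi:
            raise ValidationError("log-beta range must satisfy lo < hi")
        if self.beta_exponent not in (-2, -1, 1):
            raise ValidationError("beta_exponent must be one of -2, -1, 1")
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")
        if self.importance not in ("variance", "literal"):
            raise ValidationError(f"unknown importance mode: {self.importance!r}")
        if self.fs_confidence not in ("win_rate", "printed"):
            raise ValidationError(f"unknown fs_confidence: {self.fs_confidence!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig: defaults <- config file <- explicit overrides.

    Unknown keys are rejected with the offending name; ``None`` overrides
    are ignored (unset flags).
    """
    known = {f.name for f in fields(RunConfig)}
    merged: dict = {}
    if path is not None:
        with open(str(path)) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a flat key-value mapping")
        for key in data:
            if key not in known:
                raise ValidationError(f"{path}: unknown configuration key {key!r}")
        merged.update(data)
    for key, val in overrides.items():
        if key not in known:
            raise ValidationError(f"unknown configuration key {key!r}")
        if val is not None:
            merged[key] = val
    return RunConfig(**merged).validate()
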