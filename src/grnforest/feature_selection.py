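"""Permutation-copy relevance testing of candidate regulators.

Each input column is paired with a shadow column holding a random
permutation of its values, the doubled matrix is fitted by a tree ensemble,
and the input scores a *win* when its importance strictly exceeds its
shadow's (ties count as losses). Repeating this over ``n_rf`` independent
permutation/ensemble replicates gives a win count C_i per input; under the
null (input irrelevant, hence exchangeable with its shadow) C_i is
Binomial(n_rf, 1/2), and the input is declared irrelevant when

    z_i = (C_i - n_rf/2) / sqrt(n_rf/4)

falls at or below the lower alpha_s-quantile of the standard normal, i.e.
when it loses to its own shadow significantly often. With alpha_s = 0.01
the cut is z <= -2.3263 (C_i <= 38 at n_rf = 100).

Three ensemble backends are used: a random forest with paired candidate
sampling (each sampled original brings its shadow into the candidate set,
giving both even chances of being chosen), and unmodified Extra-Trees and
VR-Trees over all doubled columns.

The per-input confidence D_i defaults to the win rate C_i / n_rf, so that
min over backends is the *worst* (least supported) estimate fed to the
confidence mixing step; the complementary form 1 - C_i / n_rf is available
as ``fs_confidence="printed"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._rng import as_seed_sequence, generator
from .ensembles import EnsembleConfig, fit_ensemble
from .exceptions import ValidationError

__all__ = ["FSConfig", "FSResult", "permute_augment", "relevance_test", "run_fs"]

FS_BACKENDS = ("rf_paired", "extra", "vr")


@dataclass
class FSConfig:
    """Replicates, trees per replicate, test level and backend choice."""

    n_rf: int = 100
    trees_per_ensemble: int = 100
    alpha_s: float = 0.01
    method: str = "rf_paired"
    fs_confidence: str = "win_rate"
    h_max: int = 32
    min_node: int = 2
    vr_alpha: float = 0.5
    importance: str = "variance"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rf < 1:
            raise ValidationError("n_rf must be >= 1")
        if not (0.0 < self.alpha_s < 1.0):
            raise ValidationError("alpha_s must lie in (0, 1)")
        if self.method not in FS_BACKENDS:
            raise ValidationError(f"unknown FS backend: {self.method!r}")
        if self.fs_confidence not in ("win_rate", "printed"):
            raise ValidationError(f"unknown fs_confidence: {self.fs_confidence!r}")


@dataclass
class FSResult:
    """Per-input outcome of one backend's relevance test."""

    method: str
    n_rf: int
    wins: np.ndarray  # C_i
    z: np.ndarray
    relevant: np.ndarray
    D: np.ndarray


def permute_augment(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Append one independently permuted shadow column per input column."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, m = X.shape
    if n < 1:
        raise ValidationError("need at least one row")
    shadow = np.empty_like(X)
    for i in range(m):
        shadow[:, i] = X[rng.permutation(n), i]
    return np.hstack([X, shadow])


def relevance_test(wins: int, n_rf: int, alpha_s: float) -> tuple[float, bool]:
    """Normal-approximation test of C_i against the Binomial(n_rf, 1/2) null."""
    if not (0 <= wins <= n_rf):
        raise ValidationError(f"win count {wins} outside [0, {n_rf}]")
    z = (wins - n_rf / 2.0) / math.sqrt(n_rf / 4.0)
    return z, bool(z > norm.ppf(alpha_s))


def _backend_config(fs: FSConfig, n_inputs_orig: int) -> EnsembleConfig:
    """Ensemble configuration of one FS backend over 2*M doubled columns."""
    base = dict(
        n_tree=fs.trees_per_ensemble,
        h_max=fs.h_max,
        min_node=fs.min_node,
        importance=fs.importance,
    )
    if fs.method == "rf_paired":
        # doubled candidate count so each sampled original brings its shadow
        return EnsembleConfig(
            method="rf_paired",
            n_test=2 * max(1, math.ceil(n_inputs_orig / 3)),
            bootstrap=True,
            **base,
        )
    if fs.method == "extra":
        return EnsembleConfig(method="extra", n_test=2 * n_inputs_orig, bootstrap=False, **base)
    return EnsembleConfig(
        method="vr",
        n_test=2 * n_inputs_orig,
        vr_alpha=fs.vr_alpha,
        bootstrap=False,
        **base,
    )


def run_fs(X, y, w=None, ts_mask=None, fs_config: FSConfig | None = None, seed=None) -> FSResult:
    """Run the full permutation relevance test with one backend.

    For each of ``n_rf`` replicates: draw fresh shadow permutations, train
    one ensemble of the configured method on the doubled matrix with the
    measurement weights, and record per input whether the original column's
    importance strictly exceeds its shadow's.
    """
    fs = fs_config or FSConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_rows, m = X.shape
    ss = as_seed_sequence(seed if seed is not None else fs.seed)
    cfg = _backend_config(fs, m)
    wins = np.zeros(m, dtype=int)
    for _ in range(fs.n_rf):
        perm_ss, ens_ss = ss.spawn(2)
        Z = permute_augment(X, generator(perm_ss))
        ens = fit_ensemble(Z, y, w, ts_mask, cfg, ens_ss)
        imp = ens.importances_
        wins += imp[:m] > imp[m:]
    z = (wins - fs.n_rf / 2.0) / math.sqrt(fs.n_rf / 4.0)
    relevant = z > norm.ppf(fs.alpha_s)
    if fs.fs_confidence == "win_rate":
        D = wins / fs.n_rf
    else:
        D = 1.0 - wins / fs.n_rf
    return FSResult(
        method=fs.method,
        n_rf=fs.n_rf,
        wins=wins,
        z=z,
        relevant=relevant,
        D=D,
    )
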