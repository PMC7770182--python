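"""Synthetic gene-network simulator producing DREAM-style datasets.

A network of N genes evolves by dX_n/dt = F_n(X_{-n}) - beta_n X_n. Two
regulation forms are provided:

* ``linear`` (default): F_n = max(0, b_n + sum_m a_{nm} X_m) - analytically
  tractable (empty networks have the closed-form steady state b_n/beta_n);
* ``sigmoid``: F_n = b_n * sigma(sum_m a_{nm} X_m), a saturating response.

Edge strengths a_{nm} are drawn uniformly in magnitude [0.3, 1.0] with 60%
activating sign, basal rates b_n in [0.5, 1.5] and decay rates beta_n in
[0.5, 1.5]; parameter sets whose unperturbed system fails to reach a
finite, nonnegative steady state are resampled. Trajectories are integrated
by fixed-step RK4; observation noise is additive Gaussian (floored at 0) on
the measurements only - the dynamics themselves are deterministic.

The simulator emits the exact artifacts the inference pipeline consumes:
time-series experiments from random or transiently-perturbed initial
conditions, and wild-type / single-gene knockout / single-gene knockdown
steady-state rows (knockout clamps the gene to exactly 0; knockdown halves
its basal transcription).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._rng import generator
from .datasets import (
    ExpressionDataset,
    GoldStandardNetwork,
    StaticLabel,
    StaticMeasurement,
    TimeSeriesExperiment,
)
from .exceptions import ValidationError

__all__ = [
    "NetworkModel",
    "generate_network",
    "simulate_timeseries",
    "simulate_static",
    "make_dataset",
]


@dataclass
class NetworkModel:
    """A ground-truth network with kinetic parameters.

    ``A[n, m]`` is the strength of the regulation m -> n (0 if absent);
    ``b`` are basal production rates, ``beta`` first-order decay rates.
    """

    names: list[str]
    gold: GoldStandardNetwork
    A: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    form: str = "linear"
    noise_sd: float = 0.05
    seed: int | None = None
    steady_state: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return len(self.names)

    def production(self, X: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
        """F_n(X_{-n}) for every gene (diagonal of A is zero by construction)."""
        b = self.b if b is None else b
        drive = self.A @ X
        if self.form == "linear":
            return np.maximum(b + drive, 0.0)
        return b * expit(drive)

    def velocity(self, X: np.ndarray, b: np.ndarray | None = None, clamp: int | None = None) -> np.ndarray:
        v = self.production(X, b) - self.beta * X
        if clamp is not None:
            v[clamp] = 0.0
        return v


def _rk4(model: NetworkModel, X: np.ndarray, h: float, b=None, clamp=None) -> np.ndarray:
    k1 = model.velocity(X, b, clamp)
    k2 = model.velocity(X + 0.5 * h * k1, b, clamp)
    k3 = model.velocity(X + 0.5 * h * k2, b, clamp)
    k4 = model.velocity(X + h * k3, b, clamp)
    out = X + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if clamp is not None:
        out[clamp] = 0.0
    return np.maximum(out, 0.0)


def _steady_state(model: NetworkModel, X0, b=None, clamp=None, t_max=200.0, h=0.05):
    """Integrate to equilibrium; returns None on divergence/non-convergence."""
    X = np.array(X0, dtype=float)
    if clamp is not None:
        X[clamp] = 0.0
    steps = int(t_max / h)
    check = max(1, int(2.0 / h))
    for step in range(steps):
        X = _rk4(model, X, h, b, clamp)
        if not np.all(np.isfinite(X)) or X.max() > 1e6:
            return None
        if step % check == 0 and np.max(np.abs(model.velocity(X, b, clamp))) < 1e-9:
            return X
    v = model.velocity(X, b, clamp)
    if np.max(np.abs(v)) > 1e-6:
        return None
    return X


def generate_network(n_genes: int, n_edges: int, seed=None, form: str = "linear", noise_sd: float = 0.05) -> NetworkModel:
    """Sample a random stable network with ``n_edges`` directed regulations."""
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    max_edges = n_genes * (n_genes - 1)
    if not (0 <= n_edges <= max_edges):
        raise ValidationError(
            f"n_edges={n_edges} infeasible for {n_genes} genes (max {max_edges})"
        )
    if form not in ("linear", "sigmoid"):
        raise ValidationError(f"unknown regulation form: {form!r}")
    rng = generator(seed)
    names = [f"G{i + 1}" for i in range(n_genes)]
    pairs = [(t, r) for t in range(n_genes) for r in range(n_genes) if t != r]
    for attempt in range(500):
        if attempt % 40 == 0:
            sel = rng.choice(len(pairs), size=n_edges, replace=False)
            topo = [pairs[int(i)] for i in sel]
        A = np.zeros((n_genes, n_genes))
        for tgt, reg in topo:
            sign = 1.0 if rng.random() < 0.6 else -1.0
            A[tgt, reg] = sign * rng.uniform(0.3, 1.0)
        b = rng.uniform(0.5, 1.5, n_genes)
        beta = rng.uniform(0.5, 1.5, n_genes)
        model = NetworkModel(
            names=names,
            gold=GoldStandardNetwork(
                frozenset((names[reg], names[tgt]) for tgt, reg in topo)
            ),
            A=A,
            b=b,
            beta=beta,
            form=form,
            noise_sd=noise_sd,
            seed=seed if isinstance(seed, int) else None,
        )
        ss = _steady_state(model, b / beta)
        if ss is None or not np.all(ss >= 0) or ss.max() <= 1e-3:
            continue
        # every perturbation condition must also reach a steady state
        # (knockouts can turn a stable rectified-linear system oscillatory)
        ok = True
        for gidx in range(n_genes):
            if _steady_state(model, ss, clamp=gidx) is None:
                ok = False
                break
            b_kd = b.copy()
            b_kd[gidx] *= 0.5
            if _steady_state(model, ss, b=b_kd) is None:
                ok = False
                break
        if ok:
            model.steady_state = ss
            return model
    raise ValidationError(
        f"could not sample a stable {n_genes}-gene network with {n_edges} edges"
    )


def simulate_timeseries(
    model: NetworkModel,
    n_experiments: int,
    n_timepoints: int = 21,
    dt: float = 0.01,
    init: str = "random",
    rng=None,
    obs_interval: float = 0.5,
) -> list[TimeSeriesExperiment]:
    """Integrate noisy time-courses observed every ``obs_interval`` time units.

    ``dt`` is the RK4 integration step. ``init="random"`` starts each
    experiment from steady state scaled elementwise by Uniform(0.25, 1.75);
    ``init="perturbed"`` starts at steady state, multiplies the basal rates
    of a random third of the genes by Uniform(1.5, 4) for the first half of
    the observations, then restores them (the transient-perturbation design
    the indicator elements describe).
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if init not in ("random", "perturbed"):
        raise ValidationError(f"unknown init mode: {init!r}")
    rng = rng if isinstance(rng, np.random.Generator) else generator(rng)
    if model.steady_state is None:
        model.steady_state = _steady_state(model, model.b / model.beta)
        if model.steady_state is None:
            raise ValidationError("model has no stable steady state")
    substeps = max(1, round(obs_interval / dt))
    h = obs_interval / substeps
    experiments = []
    for _ in range(n_experiments):
        if init == "random":
            X = model.steady_state * rng.uniform(0.25, 1.75, model.n_genes)
            b_active = model.b
            release_at = None
        else:
            X = model.steady_state.copy()
            k_pert = max(1, model.n_genes // 3)
            genes = rng.choice(model.n_genes, size=k_pert, replace=False)
            b_active = model.b.copy()
            b_active[genes] *= rng.uniform(1.5, 4.0, k_pert)
            release_at = n_timepoints // 2
        rows = [X.copy()]
        for k in range(1, n_timepoints):
            if release_at is not None and k == release_at:
                b_active = model.b
            for _ in range(substeps):
                X = _rk4(model, X, h, b_active)
                if not np.all(np.isfinite(X)) or X.max() > 1e6:
                    worst = model.names[int(np.nanargmax(X))]
                    raise ValidationError(f"trajectory diverged at gene {worst}")
            rows.append(X.copy())
        values = np.array(rows)
        if model.noise_sd > 0:
            values = values + rng.normal(0.0, model.noise_sd, values.shape)
            values = np.maximum(values, 0.0)
        experiments.append(
            TimeSeriesExperiment(
                times=obs_interval * np.arange(n_timepoints), values=values
            )
        )
    return experiments


def simulate_static(model: NetworkModel, rng=None) -> list[StaticMeasurement]:
    """Wild-type plus every single-gene knockout and knockdown steady state.

    Knockout clamps the gene to exactly 0 (its column stays 0, noise-free,
    as the condition is definitional, not measured); knockdown halves the
    gene's basal transcription rate.
    """
    rng = rng if isinstance(rng, np.random.Generator) else generator(rng)
    if model.steady_state is None:
        model.steady_state = _steady_state(model, model.b / model.beta)
    if model.steady_state is None:
        raise ValidationError("model has no stable steady state")

    def noisy(x, keep_zero: int | None = None):
        if model.noise_sd <= 0:
            return x
        out = np.maximum(x + rng.normal(0.0, model.noise_sd, len(x)), 0.0)
        if keep_zero is not None:
            out[keep_zero] = 0.0
        return out

    statics = [
        StaticMeasurement(values=noisy(model.steady_state), label=StaticLabel("wild-type"))
    ]
    for g in range(model.n_genes):
        ss = _steady_state(model, model.steady_state, clamp=g)
        if ss is None:
            raise ValidationError(f"knockout of {model.names[g]} diverged")
        statics.append(
            StaticMeasurement(
                values=noisy(ss, keep_zero=g),
                label=StaticLabel("knockout", model.names[g]),
            )
        )
    for g in range(model.n_genes):
        b_kd = model.b.copy()
        b_kd[g] *= 0.5
        ss = _steady_state(model, model.steady_state, b=b_kd)
        if ss is None:
            raise ValidationError(f"knockdown of {model.names[g]} diverged")
        statics.append(
            StaticMeasurement(values=noisy(ss), label=StaticLabel("knockdown", model.names[g]))
        )
    return statics


def make_dataset(
    model: NetworkModel,
    n_experiments: int = 10,
    n_timepoints: int = 21,
    init: str = "random",
    include_statics: bool = True,
    seed=None,
    obs_interval: float = 0.5,
    dt: float = 0.01,
) -> ExpressionDataset:
    """Convenience: a full DREAM-style dataset from one model."""
    rng = generator(seed)
    experiments = simulate_timeseries(
        model,
        n_experiments,
        n_timepoints,
        dt=dt,
        init=init,
        rng=rng,
        obs_interval=obs_interval,
    )
    statics = simulate_static(model, rng) if include_statics else []
    return ExpressionDataset(
        element_names=list(model.names), experiments=experiments, statics=statics
    )
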