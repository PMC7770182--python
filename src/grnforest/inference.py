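"""Per-gene subproblem: decay-rate optimization and confidence computation.

The network model is dX_n/dt = F_n(X_{-n}) - beta_n X_n with an arbitrary
regulation function F_n and a first-order degradation rate beta_n > 0. For a
candidate beta_n the regression targets are

    y_tk = dX_n/dt|t_k + beta_n X_n|t_k   (time-series rows)
    y_sk =      0      + beta_n X_n|s_k   (steady-state rows; derivative 0)

and F_n is approximated by a weighted tree ensemble on the remaining
columns. The scalar objective

    S_n(beta_n) = beta_n^e * sum_k w_k [y_k - F_hat(x_k)]^2,   e = -1

is minimized over log beta_n in [-10, 5] by golden-section search, with
out-of-bag residuals so that S_n measures held-out error (in-sample
residuals of a deep forest are near zero for every beta). The 1/beta factor
(``beta_exponent=-1``) gives an interior minimum: for large beta the
residuals grow like beta so the objective grows ~beta; as beta -> 0 the
targets degenerate to the derivative alone and the factor diverges.

The confidence of regulation m -> n is the normalized total importance of
column m in the ensemble refitted at the optimal beta*:

    C_{n,m} = raw_importance(m) / (Sq_w0 * N_tree),

where Sq_w0 is the weighted sum of squared deviations of the targets around
their weighted mean. Under the variance gain this keeps sum_m C_{n,m} in
[0, 1] (telescoping of split gains down each tree).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from ._rng import as_seed_sequence
from .datasets import ExpressionDataset
from .ensembles import Ensemble, EnsembleConfig, fit_ensemble
from .exceptions import ValidationError

__all__ = [
    "TrainingData",
    "SubproblemFit",
    "build_training_data",
    "objective_sn",
    "golden_section_search",
    "fit_subproblem",
    "confidence_row",
]

logger = logging.getLogger(__name__)

LOG_BETA_RANGE = (-10.0, 5.0)
GSS_TOL = 0.01


@dataclass
class TrainingData:
    """Input-output pairs for one gene's subproblem at a given beta."""

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    ts_mask: np.ndarray
    input_names: list[str]
    target: int
    beta: float


@dataclass
class SubproblemFit:
    """Result of one gene's subproblem."""

    gene: int
    gene_name: str
    beta_star: float
    ensemble: Ensemble
    objective_value: float
    training: TrainingData

    @property
    def y_targets(self) -> np.ndarray:
        return self.training.y


def build_training_data(dataset: ExpressionDataset, n: int, beta: float) -> TrainingData:
    """Assemble (X_{-n}, y, w) over all time-series and static measurements.

    Requires derivatives (see :func:`grnforest.smoothing.smooth_dataset`);
    smoothed levels are used where available. Statics of gene ``n``'s own
    knockout/knockdown should already have been excluded by the caller.
    """
    if not (0 <= n < dataset.n_elements):
        raise ValidationError(f"gene index {n} out of range")
    if beta <= 0:
        raise ValidationError("beta must be positive")
    cols = [m for m in range(dataset.n_elements) if m != n]
    names = [dataset.element_names[m] for m in cols]
    xs, ys, ws, ts = [], [], [], []
    for exp in dataset.experiments:
        if exp.derivatives is None:
            raise ValidationError(
                "experiments carry no derivative estimates; smooth the dataset first"
            )
        vals = exp.smoothed if exp.smoothed is not None else exp.values
        xs.append(vals[:, cols])
        ys.append(exp.derivatives[:, n] + beta * vals[:, n])
        ws.append(exp.weights)
        ts.append(np.ones(exp.n_timepoints, dtype=bool))
    for s in dataset.statics:
        xs.append(s.values[cols][None, :])
        ys.append(np.array([beta * s.values[n]]))  # steady state: dX/dt = 0
        ws.append(np.array([s.weight]))
        ts.append(np.array([False]))
    return TrainingData(
        X=np.ascontiguousarray(np.vstack(xs)),
        y=np.concatenate(ys),
        w=np.concatenate(ws),
        ts_mask=np.concatenate(ts),
        input_names=names,
        target=n,
        beta=float(beta),
    )


def _ensemble_objective(td: TrainingData, ens: Ensemble, beta_exponent: int) -> float:
    if ens.config.bootstrap:
        pred, _ = ens.oob_predict(td.X)
    else:
        pred = ens.predict(td.X)
    r = td.y - pred
    return float(td.beta**beta_exponent * np.sum(td.w * r * r))


def objective_sn(
    dataset: ExpressionDataset,
    n: int,
    beta: float,
    ens_config: EnsembleConfig | None = None,
    seed=None,
    beta_exponent: int = -1,
) -> float:
    """S_n(beta): weighted held-out squared error of the trained ensemble."""
    td = build_training_data(dataset, n, beta)
    ens = fit_ensemble(td.X, td.y, td.w, td.ts_mask, ens_config, seed)
    return _ensemble_objective(td, ens, beta_exponent)


def golden_section_search(f, lo: float, hi: float, tol: float) -> float:
    """Minimize a unimodal scalar function on [lo, hi]; returns the midpoint
    of the final bracket once it is narrower than ``tol``."""
    if tol <= 0:
        raise ValidationError("tolerance must be positive")
    if not lo < hi:
        raise ValidationError("need lo < hi")
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = f(c)
    fd = f(d)
    while b - a > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def fit_subproblem(
    dataset: ExpressionDataset,
    n: int,
    ens_config: EnsembleConfig | None = None,
    log_beta_range: tuple[float, float] = LOG_BETA_RANGE,
    gss_tol: float = GSS_TOL,
    beta_exponent: int = -1,
    search_n_tree: int | None = None,
    seed=None,
) -> SubproblemFit:
    """Optimize beta_n over log-space and refit the final ensemble at beta*.

    Every objective evaluation during the search reuses one fixed seed, so
    the searched function is a deterministic function of beta. A cheaper
    search forest may be requested via ``search_n_tree``; the final ensemble
    always uses the full configuration.
    """
    ens_config = ens_config or EnsembleConfig()
    ss = as_seed_sequence(seed)
    search_ss, final_ss = ss.spawn(2)
    search_cfg = ens_config
    if search_n_tree is not None:
        search_cfg = replace(ens_config, n_tree=int(search_n_tree))
        logger.debug(
            "gene %d: beta search uses %d trees, final refit %d",
            n,
            search_cfg.n_tree,
            ens_config.n_tree,
        )

    def g(u: float) -> float:
        return objective_sn(dataset, n, math.exp(u), search_cfg, search_ss, beta_exponent)

    u_star = golden_section_search(g, log_beta_range[0], log_beta_range[1], gss_tol)
    beta_star = math.exp(u_star)
    td = build_training_data(dataset, n, beta_star)
    ens = fit_ensemble(td.X, td.y, td.w, td.ts_mask, ens_config, final_ss)
    obj = _ensemble_objective(td, ens, beta_exponent)
    return SubproblemFit(
        gene=n,
        gene_name=dataset.element_names[n],
        beta_star=beta_star,
        ensemble=ens,
        objective_value=obj,
        training=td,
    )


def confidence_row(fit: SubproblemFit) -> tuple[list[str], np.ndarray]:
    """Normalized importances C_{n,m} for all candidate regulators of gene n.

    Each tree contributes the fraction of its root dispersion explained by
    splits on m; the ensemble confidence is the mean over trees,

        C_{n,m} = (1/N_tree) sum_i [sum_{nodes on m} I(nu)] / Sq_w(root_i).

    For trees grown on the full sample Sq_w(root) is exactly the global
    Sq_w0 of the targets; for bootstrapped trees the per-tree denominator
    keeps the telescoping bound sum_m C_{n,m} <= 1 exact, which a global
    denominator only satisfies in expectation.

    Returns (input names, confidences). A constant-target subproblem
    (Sq_w0 = 0) carries no splittable signal; the row is all zeros.
    """
    y = fit.training.y
    w = fit.training.w
    nw0 = w.sum()
    ybar0 = float((w * y).sum() / nw0)
    sqw0 = float((w * (y - ybar0) ** 2).sum())
    n_inputs = len(fit.training.input_names)
    if sqw0 <= 0:
        logger.warning(
            "gene %s: constant regression targets; confidence row set to zero",
            fit.gene_name,
        )
        return fit.training.input_names, np.zeros(n_inputs)
    ens = fit.ensemble
    root_sq = ens.sqs[:, 0]  # per-tree root dispersion
    ok = root_sq > 0
    c = np.zeros(n_inputs)
    if ok.any():
        c = (ens.per_tree_importances_[ok] / root_sq[ok, None]).sum(axis=0) / ens.n_tree
    return fit.training.input_names, c
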