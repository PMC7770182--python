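"""The combined inference algorithm.

For every target gene n:

1. exclude gene n's own knockout/knockdown statics;
2. optimize beta_n and fit the final forest (:mod:`grnforest.inference`),
   giving the confidence row C_{n,m};
3. build the training pairs at beta_n* once and hand the same matrix to the
   three feature-selection backends (paired random forest, Extra-Trees,
   VR-Trees), which also see the measurement weights;
4. zero C_{n,m} whenever at least one backend concludes that element m does
   not regulate gene n, and otherwise blend

       C_{n,m} <- p C_{n,m} + (1 - p) min(D_rf, D_et, D_vt),

   the worst (least supported) of the three feature-selection confidences.

Indicator elements act as candidate regulators but never as targets. With
``enable_fs`` off and p = 1 the output is bit-for-bit the plain
random-forest-based method: the per-gene inference seed stream does not
depend on the feature-selection stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_seed_sequence
from .config import RunConfig
from .datasets import ExpressionDataset, exclude_static_for_gene
from .ensembles import EnsembleConfig
from .exceptions import ValidationError
from .feature_selection import FS_BACKENDS, FSConfig, FSResult, run_fs
from .inference import confidence_row, fit_subproblem
from .smoothing import smooth_dataset

__all__ = ["ConfidenceMatrix", "combine_row", "infer_network"]

logger = logging.getLogger(__name__)


@dataclass
class ConfidenceMatrix:
    """Confidence values C_{n,m} for all ordered candidate regulations.

    ``values[i, m]`` is the confidence that element ``m`` regulates the
    ``i``-th target gene (zero encodes "removed" or "self");``raw_values``
    holds the pre-adjustment confidences of the plain method. ``removed``
    marks pairs zeroed by feature selection, ``relevant_by`` the per-backend
    relevance verdicts.
    """

    element_names: list[str]
    is_gene: np.ndarray
    target_indices: np.ndarray
    values: np.ndarray
    raw_values: np.ndarray
    removed: np.ndarray
    relevant_by: dict
    beta_star: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def target_names(self) -> list[str]:
        return [self.element_names[i] for i in self.target_indices]

    @property
    def n_candidates(self) -> int:
        return len(self.target_indices) * (len(self.element_names) - 1)

    def to_edges(self, include_zeros: bool = True, genes_only: bool = False):
        """(regulator, target, confidence) triples for all candidate pairs."""
        out = []
        for i, n in enumerate(self.target_indices):
            tgt = self.element_names[n]
            for m, reg in enumerate(self.element_names):
                if m == n:
                    continue
                if genes_only and not self.is_gene[m]:
                    continue
                c = float(self.values[i, m])
                if c <= 0 and not include_zeros:
                    continue
                out.append((reg, tgt, c))
        return out

    def gene_pair_scores(self) -> dict:
        """Gene-to-gene candidate scores (indicator regulators excluded)."""
        return {
            (reg, tgt): c for reg, tgt, c in self.to_edges(genes_only=True)
        }

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.target_names, columns=self.element_names
        )
        df.index.name = "target"
        return df

    def removal_report(self) -> pd.DataFrame:
        """One row per removed pair with the backends that rejected it."""
        rows = []
        for i, n in enumerate(self.target_indices):
            for m, reg in enumerate(self.element_names):
                if m == n or not self.removed[i, m]:
                    continue
                rejected = [
                    b for b in FS_BACKENDS if not self.relevant_by[b][i, m]
                ]
                rows.append(
                    {
                        "regulator": reg,
                        "target": self.element_names[n],
                        "rejected_by": ",".join(rejected),
                    }
                )
        return pd.DataFrame(rows, columns=["regulator", "target", "rejected_by"])


def combine_row(
    c_row: np.ndarray,
    fs_rf: FSResult,
    fs_et: FSResult,
    fs_vt: FSResult,
    p: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust one confidence row with the three backends' verdicts.

    Entry m is zeroed iff any backend marks m not relevant; surviving
    entries blend toward the worst (minimum) backend confidence.
    Returns (adjusted row, removed mask).
    """
    c_row = np.asarray(c_row, dtype=float)
    m = len(c_row)
    for res in (fs_rf, fs_et, fs_vt):
        if len(res.relevant) != m:
            raise ValidationError(
                f"feature-selection result covers {len(res.relevant)} inputs, "
                f"confidence row has {m}"
            )
    removed = ~(fs_rf.relevant & fs_et.relevant & fs_vt.relevant)
    d_min = np.minimum(np.minimum(fs_rf.D, fs_et.D), fs_vt.D)
    adjusted = np.where(removed, 0.0, p * c_row + (1.0 - p) * d_min)
    return adjusted, removed


def _gene_worker(dataset, n, cfg: RunConfig, gene_ss):
    """Solve one gene's subproblem; returns everything the matrix needs."""
    infer_ss, rf_ss, et_ss, vt_ss = gene_ss.spawn(4)
    ds_n = exclude_static_for_gene(dataset, int(n))
    ens_cfg = EnsembleConfig(
        n_tree=cfg.n_tree,
        n_test=cfg.n_test,
        h_max=cfg.h_max,
        min_node=cfg.min_node,
        importance=cfg.importance,
        method="rf",
    )
    fit = fit_subproblem(
        ds_n,
        int(n),
        ens_cfg,
        log_beta_range=(cfg.log_beta_lo, cfg.log_beta_hi),
        gss_tol=cfg.gss_tol,
        beta_exponent=cfg.beta_exponent,
        search_n_tree=cfg.search_n_tree,
        seed=infer_ss,
    )
    names, raw = confidence_row(fit)
    if not cfg.enable_fs:
        return fit, names, raw, raw.copy(), np.zeros(len(raw), bool), {}
    td = fit.training
    fs_results = {}
    for method, mss in zip(FS_BACKENDS, (rf_ss, et_ss, vt_ss)):
        fscfg = FSConfig(
            n_rf=cfg.n_rf,
            trees_per_ensemble=cfg.fs_trees,
            alpha_s=cfg.alpha_s,
            method=method,
            fs_confidence=cfg.fs_confidence,
            h_max=cfg.h_max,
            min_node=cfg.min_node,
            vr_alpha=cfg.vr_alpha,
            importance=cfg.importance,
        )
        fs_results[method] = run_fs(td.X, td.y, td.w, td.ts_mask, fscfg, mss)
    adjusted, removed = combine_row(
        raw, fs_results["rf_paired"], fs_results["extra"], fs_results["vr"], cfg.p
    )
    relevant_by = {b: fs_results[b].relevant for b in FS_BACKENDS}
    return fit, names, raw, adjusted, removed, relevant_by


def infer_network(
    dataset: ExpressionDataset,
    config: RunConfig | None = None,
    seed=None,
    n_jobs: int = 1,
) -> ConfidenceMatrix:
    """Run the full combined method over every target gene.

    ``seed`` overrides ``config.seed``; per-gene seed streams are spawned
    from the master seed in gene order, so serial and parallel execution
    (``n_jobs`` > 1) give identical results.
    """
    cfg = (config or RunConfig()).validate()
    if seed is None:
        seed = cfg.seed
    master = as_seed_sequence(seed)
    if not any(e.derivatives is not None for e in dataset.experiments):
        dataset = smooth_dataset(dataset, span=cfg.span, kernel=cfg.kernel)
    targets = dataset.gene_indices
    n_el = dataset.n_elements
    gene_seeds = master.spawn(len(targets))

    def run_one(pos):
        n = targets[pos]
        try:
            return _gene_worker(dataset, n, cfg, gene_seeds[pos])
        except Exception as exc:  # re-raise with the gene named
            raise RuntimeError(
                f"subproblem for gene {dataset.element_names[n]!r} failed: {exc}"
            ) from exc

    if n_jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(run_one)(pos) for pos in range(len(targets))
        )
    else:
        results = [run_one(pos) for pos in range(len(targets))]

    values = np.zeros((len(targets), n_el))
    raw_values = np.zeros((len(targets), n_el))
    removed = np.zeros((len(targets), n_el), dtype=bool)
    relevant_by = {b: np.ones((len(targets), n_el), dtype=bool) for b in FS_BACKENDS}
    betas = np.zeros(len(targets))
    for pos, (fit, names, raw, adjusted, rem, gene_relevant) in enumerate(results):
        n = targets[pos]
        cols = [m for m in range(n_el) if m != n]
        values[pos, cols] = adjusted
        raw_values[pos, cols] = raw
        removed[pos, cols] = rem
        if gene_relevant:
            for b in FS_BACKENDS:
                relevant_by[b][pos, cols] = gene_relevant[b]
        betas[pos] = fit.beta_star
        logger.info(
            "gene %s: beta*=%.4g, objective=%.4g, removed %d/%d candidates",
            dataset.element_names[n],
            fit.beta_star,
            fit.objective_value,
            int(rem.sum()),
            len(cols),
        )
    meta = {
        "config": cfg.to_dict(),
        "seed": getattr(master, "entropy", None),
        "objective_values": [r[0].objective_value for r in results],
    }
    return ConfidenceMatrix(
        element_names=list(dataset.element_names),
        is_gene=dataset.is_gene.copy(),
        target_indices=targets.copy(),
        values=values,
        raw_values=raw_values,
        removed=removed,
        relevant_by=relevant_by,
        beta_star=betas,
        meta=meta,
    )
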