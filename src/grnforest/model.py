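"""High-level modelling interface.

:class:`GeneNetworkModel` wraps an :class:`~grnforest.datasets.ExpressionDataset`
together with a :class:`~grnforest.config.RunConfig`; ``fit()`` runs the
combined inference and returns a :class:`GeneNetworkResults` carrying the
confidence matrix, the per-gene decay estimates, removal diagnostics and a
``summary()`` table. Evaluation and plotting hang off the results object.

Example
-------
>>> from grnforest import generate_network, make_dataset, GeneNetworkModel
>>> net = generate_network(n_genes=5, n_edges=6, seed=7)
>>> data = make_dataset(net, n_experiments=5, seed=7)
>>> res = GeneNetworkModel(data, gold=net.gold, n_tree=100, n_rf=20,
...                        fs_trees=20).fit(seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .combine import ConfidenceMatrix, infer_network
from .config import RunConfig, load_config
from .datasets import (
    ExpressionDataset,
    GoldStandardNetwork,
    load_dataset,
    read_gold,
    write_edge_list,
)
from .evaluation import aurpc, pr_curve
from .exceptions import ValidationError

__all__ = ["GeneNetworkModel", "GeneNetworkResults"]


class GeneNetworkModel:
    """Combined random-forest + feature-selection network inference model."""

    def __init__(
        self,
        dataset: ExpressionDataset,
        gold: GoldStandardNetwork | None = None,
        config: RunConfig | None = None,
        **overrides,
    ):
        if config is None:
            config = load_config(**overrides)
        elif overrides:
            config = replace(config, **overrides).validate()
        self.dataset = dataset
        self.gold = gold
        self.config = config

    @classmethod
    def from_files(
        cls,
        timeseries,
        statics=None,
        gold=None,
        config_file=None,
        ts_weights=None,
        static_weights=None,
        indicator_cols=(),
        **overrides,
    ) -> "GeneNetworkModel":
        """Build the model from the TSV formats.

        ``indicator_cols`` names columns that are stimulus/perturbation
        indicators rather than genes (candidate regulators, never targets).
        """
        dataset = load_dataset(timeseries, statics, ts_weights, static_weights)
        if indicator_cols:
            is_gene = dataset.is_gene.copy()
            for name in indicator_cols:
                is_gene[dataset.index(name)] = False
            dataset = ExpressionDataset(
                element_names=dataset.element_names,
                experiments=dataset.experiments,
                statics=dataset.statics,
                is_gene=is_gene,
            )
        gold_net = read_gold(gold) if gold is not None else None
        config = load_config(config_file, **overrides)
        return cls(dataset, gold=gold_net, config=config)

    def fit(self, seed=None, n_jobs: int = 1) -> "GeneNetworkResults":
        matrix = infer_network(self.dataset, self.config, seed=seed, n_jobs=n_jobs)
        return GeneNetworkResults(self, matrix)


class GeneNetworkResults:
    """Fitted confidences, decay estimates and diagnostics."""

    def __init__(self, model: GeneNetworkModel, matrix: ConfidenceMatrix):
        self.model = model
        self.matrix = matrix

    # -- accessors ----------------------------------------------------------
    @property
    def confidences(self) -> pd.DataFrame:
        """Targets x elements confidence matrix (0 = self or removed)."""
        return self.matrix.to_dataframe()

    @property
    def raw_confidences(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix.raw_values,
            index=self.matrix.target_names,
            columns=self.matrix.element_names,
        )
        df.index.name = "target"
        return df

    @property
    def betas(self) -> pd.Series:
        """Estimated degradation rates beta*_n per target gene."""
        return pd.Series(
            self.matrix.beta_star, index=self.matrix.target_names, name="beta_star"
        )

    @property
    def removed_count(self) -> int:
        return int(self.matrix.removed.sum())

    def top_edges(self, k: int = 10) -> pd.DataFrame:
        edges = sorted(self.matrix.to_edges(include_zeros=False), key=lambda e: -e[2])
        return pd.DataFrame(edges[:k], columns=["regulator", "target", "confidence"])

    # -- output -------------------------------------------------------------
    def to_edge_list(self, path, include_zeros: bool = True) -> None:
        write_edge_list(self.matrix, path, include_zeros=include_zeros)

    def removal_report(self) -> pd.DataFrame:
        return self.matrix.removal_report()

    def evaluate(self, gold: GoldStandardNetwork | None = None) -> dict:
        """AURPC and the recall-precision curve against a gold standard."""
        gold = gold or self.model.gold
        if gold is None:
            raise ValidationError("no gold-standard network available")
        points = pr_curve(self.matrix, gold)
        curve = pd.DataFrame(
            [(p.threshold, p.tp, p.fp, p.fn, p.recall, p.precision) for p in points],
            columns=["threshold", "tp", "fp", "fn", "recall", "precision"],
        )
        return {"aurpc": aurpc(self.matrix, gold), "curve": curve}

    def plot_pr(self, gold: GoldStandardNetwork | None = None, ax=None):
        """Recall-precision curve plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        res = self.evaluate(gold)
        if ax is None:
            _, ax = plt.subplots()
        ax.step(res["curve"]["recall"], res["curve"]["precision"], where="post")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        ax.set_title(f"AURPC = {res['aurpc']:.4f}")
        return ax

    def summary(self) -> str:
        m = self.matrix
        ds = self.model.dataset
        cfg = self.model.config
        n_ind = int((~ds.is_gene).sum())
        n_cand = m.n_candidates
        lines = []
        bar = "=" * 64
        thin = "-" * 64
        lines.append(bar)
        lines.append("Gene Network Inference Results".center(64))
        lines.append(bar)
        lines.append(
            f"Elements: {ds.n_elements} ({len(m.target_indices)} genes, {n_ind} indicators)"
        )
        lines.append(f"Measurements: K_T = {ds.K_T} time-series, K_S = {ds.K_S} static")
        lines.append(
            f"Candidate regulations: {n_cand}   removed by feature selection: "
            f"{self.removed_count} ({100.0 * self.removed_count / max(n_cand, 1):.1f}%)"
        )
        fs = "on" if cfg.enable_fs else "off"
        lines.append(
            f"Forest: {cfg.n_tree} trees, h_max={cfg.h_max}; FS {fs} "
            f"(N_RF={cfg.n_rf}, {cfg.fs_trees} trees, alpha_s={cfg.alpha_s}); p={cfg.p}"
        )
        lines.append(thin)
        lines.append(f"{'target':<12}{'beta*':>12}{'sum(C)':>12}{'removed':>10}")
        for i, name in enumerate(m.target_names):
            lines.append(
                f"{name:<12}{m.beta_star[i]:>12.4g}"
                f"{m.values[i].sum():>12.4f}{int(m.removed[i].sum()):>10d}"
            )
        lines.append(thin)
        top = self.top_edges(5)
        lines.append("Top regulations (regulator -> target, confidence):")
        for _, row in top.iterrows():
            lines.append(
                f"  {row.regulator} -> {row.target}  {row.confidence:.4f}"
            )
        lines.append(bar)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<GeneNetworkResults: {len(self.matrix.target_indices)} genes, "
            f"{self.removed_count} removed>"
        )
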