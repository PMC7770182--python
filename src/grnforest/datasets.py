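"""Data model and I/O for expression data, measurement weights and networks.

The on-disk formats follow the DREAM in-silico challenge conventions:

* time-series TSV: a ``Time`` column followed by one column per element,
  with independent experiments separated by blank lines;
* static TSV: one row per steady-state measurement (wild-type, single-gene
  knockout/knockdown, or unlabelled), with an optional leading ``label``
  column;
* edge lists: ``regulator<TAB>target<TAB>value`` rows.

Element indexing is 0-based internally; files always use element names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ParseError, ValidationError

__all__ = [
    "TimeSeriesExperiment",
    "StaticLabel",
    "StaticMeasurement",
    "ExpressionDataset",
    "GoldStandardNetwork",
    "Indicator",
    "read_timeseries",
    "parse_timeseries",
    "write_timeseries",
    "read_static",
    "parse_static",
    "write_static",
    "read_weights",
    "exclude_static_for_gene",
    "add_indicator_elements",
    "write_edge_list",
    "read_edge_list",
    "read_gold",
    "write_gold",
    "load_dataset",
]

DEFAULT_TS_WEIGHT = 1.0
DEFAULT_STATIC_WEIGHT = 1.1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesExperiment:
    """One time-course: expression levels of all elements at successive times.

    ``values[k, m]`` is the level of element ``m`` at time ``times[k]``;
    ``weights[k]`` is the per-measurement weight w_k^T. ``smoothed`` and
    ``derivatives`` are filled in by :mod:`grnforest.smoothing` and carry the
    denoised levels and the estimated d/dt at each time point.
    """

    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    derivatives: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.weights is None:
            self.weights = np.full(len(self.times), DEFAULT_TS_WEIGHT)
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.times)
        if self.values.shape[0] != k or len(self.weights) != k:
            raise ValidationError(
                f"time-series experiment is inconsistent: {k} times, "
                f"{self.values.shape[0]} value rows, {len(self.weights)} weights"
            )
        if k >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("measurement times must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValidationError("time-series weights must be positive")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]


_LABEL_RE = re.compile(r"^(knockout|knockdown)\((.+)\)$")


@dataclass(frozen=True)
class StaticLabel:
    """Condition label of a steady-state row.

    ``kind`` is one of ``wild-type``, ``knockout``, ``knockdown``, ``other``;
    ``gene`` names the perturbed gene for knockout/knockdown rows.
    """

    kind: str
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("wild-type", "knockout", "knockdown", "other"):
            raise ValidationError(f"unknown static label kind: {self.kind!r}")
        if self.kind in ("knockout", "knockdown") and not self.gene:
            raise ValidationError(f"{self.kind} label requires a gene name")

    @classmethod
    def parse(cls, text: str) -> "StaticLabel":
        text = text.strip()
        if text in ("wild-type", "other"):
            return cls(text)
        m = _LABEL_RE.match(text)
        if m:
            return cls(m.group(1), m.group(2))
        raise ValidationError(f"unknown static label: {text!r}")

    def __str__(self) -> str:
        if self.gene is not None:
            return f"{self.kind}({self.gene})"
        return self.kind


@dataclass
class StaticMeasurement:
    """One steady-state measurement row with weight w_k^S."""

    values: np.ndarray
    weight: float = DEFAULT_STATIC_WEIGHT
    label: StaticLabel = field(default_factory=lambda: StaticLabel("other"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.weight <= 0:
            raise ValidationError("static measurement weight must be positive")
        if isinstance(self.label, str):
            self.label = StaticLabel.parse(self.label)


@dataclass
class ExpressionDataset:
    """Time-series experiments plus static measurements over named elements.

    ``is_gene`` is False for indicator (stimulus/perturbation) elements,
    which may act as candidate regulators but are never inference targets.
    """

    element_names: list[str]
    experiments: list[TimeSeriesExperiment]
    statics: list[StaticMeasurement] = field(default_factory=list)
    is_gene: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.element_names = list(self.element_names)
        if len(set(self.element_names)) != len(self.element_names):
            raise ValidationError("element names must be unique")
        n = len(self.element_names)
        if self.is_gene is None:
            self.is_gene = np.ones(n, dtype=bool)
        self.is_gene = np.asarray(self.is_gene, dtype=bool)
        if len(self.is_gene) != n:
            raise ValidationError("is_gene length must match element_names")
        for i, exp in enumerate(self.experiments):
            if exp.n_elements != n:
                raise ValidationError(
                    f"experiment {i} has {exp.n_elements} columns, expected {n}"
                )
        for i, s in enumerate(self.statics):
            if len(s.values) != n:
                raise ValidationError(
                    f"static row {i} has {len(s.values)} columns, expected {n}"
                )
        if self.K_T < 2:
            raise ValidationError("a dataset needs at least two time-series points")

    # -- derived sizes ------------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.element_names)

    @property
    def K_T(self) -> int:
        """Total number of time-series measurements across experiments."""
        return sum(e.n_timepoints for e in self.experiments)

    @property
    def K_S(self) -> int:
        """Number of steady-state measurements."""
        return len(self.statics)

    @property
    def gene_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_gene)

    @property
    def gene_names(self) -> list[str]:
        return [self.element_names[i] for i in self.gene_indices]

    def index(self, name: str) -> int:
        try:
            return self.element_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown element name: {name!r}") from None

    def n_candidate_regulations(self) -> int:
        """Ordered candidate pairs: every element m regulating every gene n, m != n."""
        n_genes = int(self.is_gene.sum())
        return n_genes * (self.n_elements - 1)


@dataclass(frozen=True)
class GoldStandardNetwork:
    """Ground-truth directed regulations used for evaluation."""

    edges: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValidationError(f"gold standard contains self-edge {reg!r}")

    @property
    def genes(self) -> set:
        out = set()
        for reg, tgt in self.edges:
            out.add(reg)
            out.add(tgt)
        return out

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# time-series I/O
# ---------------------------------------------------------------------------


def _parse_float(cell: str, lineno: int, path: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric cell {cell!r} on line {lineno}"
        ) from None


def parse_timeseries(path) -> tuple[list[str], list[TimeSeriesExperiment]]:
    """Parse a DREAM-style time-series TSV; returns (element names, experiments)."""
    path = str(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: list[str] | None = None
    names: list[str] = []
    blocks: list[list[tuple[int, list[str]]]] = []
    current: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            if len(header) < 2 or header[0].strip().lower() != "time":
                raise ParseError(
                    f"{path}: header must start with a Time column, got {header[:1]}"
                )
            names = [c.strip() for c in header[1:]]
            continue
        if cells == header:  # repeated header at the start of a block
            continue
        current.append((lineno, cells))
    if current:
        blocks.append(current)
    if header is None:
        raise ParseError(f"{path}: empty file")

    experiments = []
    ncol = len(header)
    for block in blocks:
        times, rows = [], []
        for lineno, cells in block:
            if len(cells) != ncol:
                raise ParseError(
                    f"{path}: expected {ncol} columns but found {len(cells)} "
                    f"on line {lineno}"
                )
            times.append(_parse_float(cells[0], lineno, path))
            rows.append([_parse_float(c, lineno, path) for c in cells[1:]])
        t = np.array(times)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"{path}: times are not strictly increasing in the block ending "
                f"on line {block[-1][0]}"
            )
        experiments.append(TimeSeriesExperiment(times=t, values=np.array(rows)))
    return names, experiments


def read_timeseries(path) -> list[TimeSeriesExperiment]:
    """Read blank-line-separated time-series experiments from a DREAM TSV."""
    return parse_timeseries(path)[1]


def write_timeseries(path, names: Sequence[str], experiments: Iterable[TimeSeriesExperiment]) -> None:
    with open(str(path), "w") as fh:
        fh.write("Time\t" + "\t".join(names) + "\n")
        for bi, exp in enumerate(experiments):
            if bi:
                fh.write("\n")
            for k in range(exp.n_timepoints):
                row = [repr(float(exp.times[k]))]
                row += [repr(float(v)) for v in exp.values[k]]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# static I/O
# ---------------------------------------------------------------------------


def parse_static(path) -> tuple[list[str], list[StaticMeasurement]]:
    """Parse a static TSV; returns (element names, measurements)."""
    path = str(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    has_label = header[0].strip().lower() == "label"
    names = [c.strip() for c in (header[1:] if has_label else header)]
    statics = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: expected {len(header)} columns but found {len(cells)} "
                f"on line {lineno}"
            )
        if has_label:
            label = StaticLabel.parse(cells[0])
            vals = cells[1:]
        else:
            label = StaticLabel("other")
            vals = cells
        values = [_parse_float(c, lineno, path) for c in vals]
        statics.append(StaticMeasurement(values=np.array(values), label=label))
    return names, statics


def read_static(path) -> list[StaticMeasurement]:
    """Read steady-state rows; weights initialize to the 1.1 default."""
    return parse_static(path)[1]


def write_static(path, names: Sequence[str], statics: Iterable[StaticMeasurement]) -> None:
    with open(str(path), "w") as fh:
        fh.write("label\t" + "\t".join(names) + "\n")
        for s in statics:
            fh.write(str(s.label) + "\t" + "\t".join(repr(float(v)) for v in s.values) + "\n")


def read_weights(path) -> np.ndarray:
    """Read one positive weight per line (measurement order of the data file)."""
    path = str(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            w = _parse_float(line.strip(), lineno, path)
            if w <= 0:
                raise ValidationError(f"{path}: weight on line {lineno} is not positive")
            out.append(w)
    return np.array(out)


def load_dataset(ts_path, static_path=None, ts_weights=None, static_weights=None) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from the TSV formats.

    Optional weight vectors override the 1.0 / 1.1 defaults; a time-series
    weight file holds one weight per measurement row, concatenated across
    experiments in file order.
    """
    names, experiments = parse_timeseries(ts_path)
    statics: list[StaticMeasurement] = []
    if static_path is not None:
        snames, statics = parse_static(static_path)
        if snames != names:
            raise ValidationError(
                "static and time-series files name different elements"
            )
    if ts_weights is not None:
        w = np.asarray(read_weights(ts_weights) if isinstance(ts_weights, (str,)) or hasattr(ts_weights, "__fspath__") else ts_weights, dtype=float)
        total = sum(e.n_timepoints for e in experiments)
        if len(w) != total:
            raise ValidationError(
                f"time-series weight vector has {len(w)} entries for {total} measurements"
            )
        ofs = 0
        for exp in experiments:
            exp.weights = w[ofs:ofs + exp.n_timepoints].copy()
            ofs += exp.n_timepoints
    if static_weights is not None:
        w = np.asarray(read_weights(static_weights) if isinstance(static_weights, (str,)) or hasattr(static_weights, "__fspath__") else static_weights, dtype=float)
        if len(w) != len(statics):
            raise ValidationError(
                f"static weight vector has {len(w)} entries for {len(statics)} rows"
            )
        for s, wk in zip(statics, w):
            s.weight = float(wk)
    return ExpressionDataset(element_names=names, experiments=experiments, statics=statics)


# ---------------------------------------------------------------------------
# dataset transforms
# ---------------------------------------------------------------------------


def exclude_static_for_gene(dataset: ExpressionDataset, n) -> ExpressionDataset:
    """Drop the knockout and knockdown rows of gene ``n`` (index or name).

    Used when solving gene ``n``'s subproblem: its own perturbation rows do
    not describe the unperturbed dynamics of that gene.
    """
    idx = dataset.index(n) if isinstance(n, str) else int(n)
    if idx < 0 or idx >= dataset.n_elements:
        raise ValidationError(f"element index {idx} out of range")
    if not dataset.is_gene[idx]:
        raise ValidationError(
            f"element {dataset.element_names[idx]!r} is an indicator, not a gene"
        )
    name = dataset.element_names[idx]
    kept = [
        s
        for s in dataset.statics
        if not (s.label.kind in ("knockout", "knockdown") and s.label.gene == name)
    ]
    return ExpressionDataset(
        element_names=list(dataset.element_names),
        experiments=list(dataset.experiments),
        statics=kept,
        is_gene=dataset.is_gene.copy(),
    )


@dataclass(frozen=True)
class Indicator:
    """Definition of one stimulus/perturbation indicator element.

    ``experiments`` lists the experiment indices in which the stimulus was
    applied; the stimulus starts at time-point index ``start`` (0-based) and,
    in binary mode, stays on through index ``stop`` (inclusive; None = last).
    """

    name: str
    experiments: tuple
    start: int = 0
    stop: int | None = None

    def __post_init__(self) -> None:
        exps = self.experiments
        if isinstance(exps, int):
            exps = (exps,)
        object.__setattr__(self, "experiments", tuple(int(e) for e in exps))


def add_indicator_elements(
    dataset: ExpressionDataset,
    indicators: Sequence[Indicator],
    mode: str = "binary",
    base: float = 0.9,
    scale: float = 48.0,
) -> ExpressionDataset:
    """Append indicator columns encoding external stimuli.

    ``binary`` sets 1 inside the active time-point range and 0 elsewhere
    (including all statics). ``decay`` models compound decomposition: the
    column takes ``base**((t - t_start)/scale)`` from the stimulation onward
    within the stimulated experiments (time units as in the Time column,
    minutes for the 0.9/48 defaults) and 0 elsewhere. Existing columns are
    never modified.
    """
    if mode not in ("binary", "decay"):
        raise ValidationError(f"unknown indicator mode: {mode!r}")
    names = list(dataset.element_names)
    for ind in indicators:
        if ind.name in names:
            raise ValidationError(f"duplicate indicator name: {ind.name!r}")
        names.append(ind.name)
    n_new = len(indicators)
    new_exps = []
    for ei, exp in enumerate(dataset.experiments):
        cols = np.zeros((exp.n_timepoints, n_new))
        for j, ind in enumerate(indicators):
            if ei not in ind.experiments:
                continue
            k = exp.n_timepoints
            start = ind.start
            stop = k - 1 if ind.stop is None else ind.stop
            if not (0 <= start < k) or not (start <= stop < k):
                raise ValidationError(
                    f"indicator {ind.name!r}: range [{start}, {stop}] outside "
                    f"experiment {ei} with {k} time points"
                )
            if mode == "binary":
                cols[start:stop + 1, j] = 1.0
            else:
                t0 = exp.times[start]
                t = exp.times[start:]
                cols[start:, j] = base ** ((t - t0) / scale)
        new_exps.append(
            TimeSeriesExperiment(
                times=exp.times.copy(),
                values=np.hstack([exp.values, cols]),
                weights=exp.weights.copy(),
                smoothed=None if exp.smoothed is None else np.hstack([exp.smoothed, cols]),
                derivatives=None
                if exp.derivatives is None
                else np.hstack([exp.derivatives, np.zeros_like(cols)]),
            )
        )
    new_statics = [
        StaticMeasurement(
            values=np.concatenate([s.values, np.zeros(n_new)]),
            weight=s.weight,
            label=s.label,
        )
        for s in dataset.statics
    ]
    return ExpressionDataset(
        element_names=names,
        experiments=new_exps,
        statics=new_statics,
        is_gene=np.concatenate([dataset.is_gene, np.zeros(n_new, dtype=bool)]),
    )


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def write_edge_list(edges, path, include_zeros: bool = True) -> None:
    """Write ``regulator TAB target TAB confidence`` rows.

    ``edges`` is either an iterable of (regulator, target, confidence) or an
    object with a ``to_edges()`` method (a ConfidenceMatrix). Rows are sorted
    by confidence descending, ties lexicographically by (regulator, target);
    zero-confidence (removed) pairs go last, or are omitted when
    ``include_zeros`` is False.
    """
    if hasattr(edges, "to_edges"):
        edges = edges.to_edges()
    edges = [(str(r), str(t), float(c)) for r, t, c in edges]
    pos = sorted((e for e in edges if e[2] > 0), key=lambda e: (-e[2], e[0], e[1]))
    zero = sorted((e for e in edges if e[2] <= 0), key=lambda e: (e[0], e[1]))
    with open(str(path), "w") as fh:
        for reg, tgt, c in pos:
            fh.write(f"{reg}\t{tgt}\t{repr(c)}\n")
        if include_zeros:
            for reg, tgt, c in zero:
                fh.write(f"{reg}\t{tgt}\t0.0\n")


def read_edge_list(path) -> dict:
    """Read a prediction edge list into a {(regulator, target): confidence} map."""
    path = str(path)
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise ParseError(f"{path}: expected 3 columns on line {lineno}")
            out[(cells[0], cells[1])] = _parse_float(cells[2], lineno, path)
    return out


def read_gold(path) -> GoldStandardNetwork:
    """Read a gold-standard edge list (third column 1 = edge, 0 = non-edge)."""
    path = str(path)
    edges = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) not in (2, 3):
                raise ParseError(f"{path}: expected 2 or 3 columns on line {lineno}")
            flag = 1.0 if len(cells) == 2 else _parse_float(cells[2], lineno, path)
            if flag:
                edges.add((cells[0], cells[1]))
    return GoldStandardNetwork(edges=frozenset(edges))


def write_gold(gold: GoldStandardNetwork, path) -> None:
    with open(str(path), "w") as fh:
        for reg, tgt in sorted(gold.edges):
            fh.write(f"{reg}\t{tgt}\t1\n")
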