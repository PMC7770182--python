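"""Expression data model, TSV dialects, indicators and edge lists."""

import numpy as np
import pytest

from grnforest import (
    ExpressionDataset,
    GoldStandardNetwork,
    Indicator,
    ParseError,
    StaticLabel,
    StaticMeasurement,
    TimeSeriesExperiment,
    ValidationError,
    add_indicator_elements,
    exclude_static_for_gene,
    read_edge_list,
    read_gold,
    read_static,
    read_timeseries,
    write_edge_list,
    write_gold,
)
from grnforest.datasets import (
    load_dataset,
    parse_static,
    parse_timeseries,
    write_static,
    write_timeseries,
)


def _make_dataset(n_genes=3, n_statics=0, n_tp=4):
    names = [f"G{i+1}" for i in range(n_genes)]
    exp = TimeSeriesExperiment(
        times=np.arange(n_tp, dtype=float),
        values=np.arange(n_tp * n_genes, dtype=float).reshape(n_tp, n_genes),
    )
    statics = [
        StaticMeasurement(values=np.full(n_genes, float(k)), label=StaticLabel("other"))
        for k in range(n_statics)
    ]
    return ExpressionDataset(element_names=names, experiments=[exp], statics=statics)


# ---------------------------------------------------------------------------
# time-series parsing
# ---------------------------------------------------------------------------


def test_read_timeseries_single_block(tmp_path):
    path = tmp_path / "ts.tsv"
    path.write_text("Time\tG1\tG2\n0\t1.5\t2.5\n10\t3.5\t4.5\n")
    exps = read_timeseries(path)
    assert len(exps) == 1
    assert exps[0].values.shape == (2, 2)
    assert list(exps[0].times) == [0.0, 10.0]
    assert list(exps[0].weights) == [1.0, 1.0]


def test_read_timeseries_blocks_and_counts(tmp_path):
    # 46 blocks x 21 rows -> K_T = 966, the DREAM3 bookkeeping
    names = ["G1", "G2", "G3"]
    exps = [
        TimeSeriesExperiment(
            times=10.0 * np.arange(21), values=np.random.default_rng(i).random((21, 3))
        )
        for i in range(46)
    ]
    path = tmp_path / "ts.tsv"
    write_timeseries(path, names, exps)
    parsed_names, parsed = parse_timeseries(path)
    assert parsed_names == names
    assert len(parsed) == 46
    ds = ExpressionDataset(element_names=names, experiments=parsed)
    assert ds.K_T == 46 * 21 == 966


@pytest.mark.parametrize(
    "body,err,match",
    [
        ("Time\tG1\n0\t1\n5\t2\t3\n", ParseError, "line 3"),
        ("Time\tG1\n0\tabc\n1\t2\n", ParseError, "abc"),
        ("Time\tG1\n5\t1\n5\t2\n", ValidationError, "increasing"),
    ],
)
def test_read_timeseries_errors(tmp_path, body, err, match):
    path = tmp_path / "bad.tsv"
    path.write_text(body)
    with pytest.raises(err, match=match):
        read_timeseries(path)


def test_timeseries_roundtrip_exact(tmp_path, small_dataset):
    path = tmp_path / "rt.tsv"
    write_timeseries(path, small_dataset.element_names, small_dataset.experiments)
    names, exps = parse_timeseries(path)
    assert names == small_dataset.element_names
    for orig, back in zip(small_dataset.experiments, exps):
        np.testing.assert_array_equal(orig.times, back.times)
        np.testing.assert_array_equal(orig.values, back.values)


# ---------------------------------------------------------------------------
# static parsing
# ---------------------------------------------------------------------------


def test_read_static_counts_and_labels(tmp_path):
    names = [f"G{i+1}" for i in range(5)]
    rows = [StaticMeasurement(values=np.ones(5), label=StaticLabel("wild-type"))]
    for g in names:
        rows.append(StaticMeasurement(values=np.ones(5), label=StaticLabel("knockout", g)))
        rows.append(StaticMeasurement(values=np.ones(5), label=StaticLabel("knockdown", g)))
    path = tmp_path / "static.tsv"
    write_static(path, names, rows)
    parsed = read_static(path)
    assert len(parsed) == 11
    assert all(s.weight == 1.1 for s in parsed)
    ko = [s for s in parsed if s.label.kind == "knockout"]
    assert {s.label.gene for s in ko} == set(names)


def test_read_static_empty_body(tmp_path):
    path = tmp_path / "static.tsv"
    path.write_text("label\tG1\tG2\n")
    assert read_static(path) == []


def test_static_label_parse():
    lab = StaticLabel.parse("knockout(G5)")
    assert lab.kind == "knockout" and lab.gene == "G5"
    with pytest.raises(ValidationError):
        StaticLabel.parse("smashed(G1)")


def test_static_roundtrip_exact(tmp_path, small_dataset):
    path = tmp_path / "st.tsv"
    write_static(path, small_dataset.element_names, small_dataset.statics)
    names, back = parse_static(path)
    assert names == small_dataset.element_names
    for orig, b in zip(small_dataset.statics, back):
        np.testing.assert_array_equal(orig.values, b.values)
        assert str(orig.label) == str(b.label)


def test_load_dataset_weight_overrides(tmp_path, small_dataset):
    ts = tmp_path / "ts.tsv"
    st = tmp_path / "st.tsv"
    write_timeseries(ts, small_dataset.element_names, small_dataset.experiments)
    write_static(st, small_dataset.element_names, small_dataset.statics)
    k_t = small_dataset.K_T
    wfile = tmp_path / "w.txt"
    wfile.write_text("\n".join(["0.5"] * k_t))
    ds = load_dataset(ts, st, ts_weights=wfile)
    assert all(np.all(e.weights == 0.5) for e in ds.experiments)
    assert all(s.weight == 1.1 for s in ds.statics)


# ---------------------------------------------------------------------------
# exclusion of a gene's own perturbation rows
# ---------------------------------------------------------------------------


def test_exclude_static_for_gene_dream_arithmetic():
    # 1 WT + 100 KO + 100 KD rows over 100 genes -> 199 after excluding gene n
    n = 100
    names = [f"G{i+1}" for i in range(n)]
    exp = TimeSeriesExperiment(times=np.array([0.0, 1.0]), values=np.zeros((2, n)))
    statics = [StaticMeasurement(values=np.zeros(n), label=StaticLabel("wild-type"))]
    for g in names:
        statics.append(StaticMeasurement(values=np.zeros(n), label=StaticLabel("knockout", g)))
        statics.append(StaticMeasurement(values=np.zeros(n), label=StaticLabel("knockdown", g)))
    ds = ExpressionDataset(element_names=names, experiments=[exp], statics=statics)
    assert ds.K_S == 201
    reduced = exclude_static_for_gene(ds, 7)
    assert reduced.K_S == 1 + 100 + 100 - 2 == 199
    # untouched genes keep their rows; excluding twice is a no-op
    again = exclude_static_for_gene(reduced, 7)
    assert again.K_S == 199


def test_exclude_static_duplicates_and_errors():
    names = ["G1", "G2"]
    exp = TimeSeriesExperiment(times=np.array([0.0, 1.0]), values=np.zeros((2, 2)))
    statics = [
        StaticMeasurement(values=np.zeros(2), label=StaticLabel("knockout", "G1")),
        StaticMeasurement(values=np.zeros(2), label=StaticLabel("knockout", "G1")),
        StaticMeasurement(values=np.zeros(2), label=StaticLabel("wild-type")),
    ]
    ds = ExpressionDataset(element_names=names, experiments=[exp], statics=statics)
    assert exclude_static_for_gene(ds, "G1").K_S == 1  # both KO rows removed
    ind = add_indicator_elements(ds, [Indicator("S1", experiments=0)])
    with pytest.raises(ValidationError, match="indicator"):
        exclude_static_for_gene(ind, "S1")


# ---------------------------------------------------------------------------
# indicator elements
# ---------------------------------------------------------------------------


def test_indicator_binary_pattern():
    names = ["G1", "G2"]
    exps = [
        TimeSeriesExperiment(times=np.arange(21.0), values=np.ones((21, 2)))
        for _ in range(2)
    ]
    statics = [StaticMeasurement(values=np.ones(2))]
    ds = ExpressionDataset(element_names=names, experiments=exps, statics=statics)
    out = add_indicator_elements(
        ds, [Indicator("P1", experiments=0, start=0, stop=9)], mode="binary"
    )
    assert out.n_elements == 3
    assert not out.is_gene[2]
    col = out.experiments[0].values[:, 2]
    np.testing.assert_array_equal(col[:10], 1.0)
    np.testing.assert_array_equal(col[10:], 0.0)
    np.testing.assert_array_equal(out.experiments[1].values[:, 2], 0.0)
    assert out.statics[0].values[2] == 0.0
    # existing columns bitwise untouched
    for old, new in zip(ds.experiments, out.experiments):
        np.testing.assert_array_equal(old.values, new.values[:, :2])


def test_indicator_decay_values():
    # 0.9**(t/48): 1.0 at t=0, 0.81 at t=96
    names = ["G1"]
    exp = TimeSeriesExperiment(times=np.array([0.0, 48.0, 96.0]), values=np.ones((3, 1)))
    ds = ExpressionDataset(element_names=names, experiments=[exp])
    out = add_indicator_elements(
        ds, [Indicator("S", experiments=0)], mode="decay", base=0.9, scale=48.0
    )
    col = out.experiments[0].values[:, 1]
    assert col[0] == pytest.approx(1.0)
    assert col[1] == pytest.approx(0.9)
    assert col[2] == pytest.approx(0.81)


def test_indicator_duplicate_name_rejected(small_dataset):
    with pytest.raises(ValidationError, match="duplicate"):
        add_indicator_elements(
            small_dataset,
            [Indicator("S", experiments=0), Indicator("S", experiments=1)],
        )


# ---------------------------------------------------------------------------
# edge lists and gold standards
# ---------------------------------------------------------------------------


def test_write_edge_list_ordering(tmp_path):
    path = tmp_path / "edges.tsv"
    write_edge_list(
        [("G2", "G1", 0.5), ("G1", "G2", 0.9), ("G1", "G3", 0.5), ("G3", "G1", 0.0)],
        path,
    )
    lines = path.read_text().splitlines()
    assert lines[0].startswith("G1\tG2")  # largest first
    assert lines[1].startswith("G1\tG3")  # tie at 0.5: lexicographic
    assert lines[2].startswith("G2\tG1")
    assert lines[3] == "G3\tG1\t0.0"  # zeros last


def test_write_edge_list_omit_zeros(tmp_path):
    path = tmp_path / "edges.tsv"
    write_edge_list([("A", "B", 0.0)], path, include_zeros=False)
    assert path.read_text() == ""
    scores = read_edge_list(path)
    assert scores == {}


def test_gold_roundtrip_and_validation(tmp_path):
    gold = GoldStandardNetwork(frozenset({("G1", "G2"), ("G3", "G1")}))
    path = tmp_path / "gold.tsv"
    write_gold(gold, path)
    back = read_gold(path)
    assert back.edges == gold.edges
    with pytest.raises(ValidationError, match="self-edge"):
        GoldStandardNetwork(frozenset({("G1", "G1")}))


def test_candidate_regulation_counts():
    ds = _make_dataset(n_genes=4)
    assert ds.n_candidate_regulations() == 4 * 3
    out = add_indicator_elements(ds, [Indicator("S1", 0), Indicator("S2", 0)])
    assert out.n_candidate_regulations() == 4 * 5
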