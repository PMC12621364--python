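"""Windowed differential methylation: geometry, the test, calling, sets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmeth import dma
from panmeth.config import HAPLOTYPES
from panmeth.graph import SequenceGraph, _infer_edges
from panmeth.methio import united_profiles


def _graph(nodes, paths):
    g = SequenceGraph(nodes=dict(nodes), paths={k: list(v) for k, v in paths.items()})
    _infer_edges(g)
    return g


def _profile(rows, clones=("c1",)):
    """rows: (pos, context, m, u) applied to every clone."""
    data = {
        "chrom": ["chr1"] * len(rows),
        "pos": [r[0] for r in rows],
        "strand": ["+"] * len(rows),
        "context": [r[1] for r in rows],
    }
    for c in clones:
        data[f"m_{c}"] = [r[2] for r in rows]
        data[f"u_{c}"] = [r[3] for r in rows]
    return pd.DataFrame(data)


# -- window geometry -----------------------------------------------------


@pytest.mark.parametrize(
    "length,win,step,expected",
    [(1000, 200, 200, 5), (1030, 200, 200, 5), (1000, 200, 100, 9)],
)
def test_reference_window_tiling(length, win, step, expected):
    g = _graph({"1": "A" * length}, {"CSCF": [("1", "+")]})
    windows = dma.make_reference_windows(g, ["CSCF"], win, step)
    assert len(windows) == expected
    assert all(150 <= w.length <= 250 for w in windows)


def test_terminal_window_kept_when_long_enough():
    g = _graph({"1": "A" * 1180}, {"CSCF": [("1", "+")]})
    windows = dma.make_reference_windows(g, ["CSCF"], 200, 200)
    assert len(windows) == 6 and windows[-1].length == 180


def test_projected_insertion_window_dropped():
    """A 60 bp target-private insertion inflates the projection to 260 bp."""
    ins = "ACGT" * 15
    shared1, shared2 = "A" * 100, "G" * 100
    g = _graph(
        {"1": shared1, "I": ins, "2": shared2},
        {
            "CSCF": [("1", "+"), ("2", "+")],
            "T": [("1", "+"), ("I", "+"), ("2", "+")],
        },
    )
    rows = [(p, "CHH", 5, 5) for p in range(1, 201, 10)]
    profiles = {"CSCF": _profile(rows), "T": _profile(rows)}
    windows = dma.make_reference_windows(g, ["CSCF"], 200, 200)
    kept, drops = dma.project_windows(g, windows, ["T"], profiles)
    assert kept == [] and drops["length"] == 1


def test_window_with_too_few_cytosines_dropped():
    g = _graph({"1": "A" * 200}, {"CSCF": [("1", "+")], "T": [("1", "+")]})
    profiles = {
        "CSCF": _profile([(10, "CG", 5, 5), (50, "CG", 5, 5), (90, "CG", 5, 5)]),
        "T": _profile([(10, "CG", 5, 5), (50, "CG", 5, 5)]),  # only 2 sites
    }
    windows = dma.make_reference_windows(g, ["CSCF"], 200, 200)
    kept, drops = dma.project_windows(g, windows, ["T"], profiles)
    assert kept == [] and drops["cytosines"] == 1


def test_duplicate_node_ranges_deduplicated(small_trio, small_profiles):
    from panmeth.graph import chop_nodes

    _, truth, _ = small_trio
    g, _ = chop_nodes(truth.graphs["chr1"], 200)
    windows, drops = dma.build_windows(g, small_profiles)
    assert drops["duplicate"] > 0
    assert len({w.window_id for w in windows}) == len(windows)


# -- aggregation ---------------------------------------------------------


def test_aggregate_sums_sites_per_clone():
    g = _graph({"1": "A" * 200}, {"A": [("1", "+")], "B": [("1", "+")]})
    rows = [(10, "CG", 8, 2), (20, "CG", 2, 8), (30, "CG", 5, 5)]
    profiles = {"A": _profile(rows, ("c1", "c2")), "B": _profile(rows, ("c1", "c2"))}
    w = dma.ComparableWindow("w", None, {"A": (0, 200), "B": (0, 200)})
    ga, gb = dma.aggregate_window_counts(w, profiles, ["A"], ["B"], "CG")
    assert ga == [(15, 30), (15, 30)]


def test_aggregate_pools_two_haplotypes():
    g = _graph({"1": "A" * 100}, {})
    rows = [(10, "CG", 4, 6)]
    profiles = {
        "H1": _profile(rows, ("c1",)),
        "H2": _profile([(10, "CG", 6, 4)], ("c1",)),
        "B": _profile(rows, ("c1",)),
    }
    w = dma.ComparableWindow("w", None, {"H1": (0, 100), "H2": (0, 100), "B": (0, 100)})
    ga, _ = dma.aggregate_window_counts(w, profiles, ["H1", "H2"], ["B"], "CG")
    assert ga == [(10, 20)]


def test_aggregate_zero_coverage_raises():
    w = dma.ComparableWindow("w", None, {"A": (0, 100), "B": (0, 100)})
    profiles = {"A": _profile([(10, "CG", 0, 0)]), "B": _profile([(10, "CG", 1, 1)])}
    with pytest.raises(ValueError, match="zero total coverage"):
        dma.aggregate_window_counts(w, profiles, ["A"], ["B"], "CG")


# -- the test ------------------------------------------------------------


def test_identical_groups_null_result():
    diff, p = dma.test_window([(10, 20), (5, 20)], [(10, 20), (5, 20)])
    assert diff == 0.0 and p == 1.0


def test_full_separation():
    diff, p = dma.test_window([(30, 30)] * 3, [(0, 30)] * 3)
    assert diff == 100.0 and p < 1e-10


def test_matches_independent_likelihood_oracle():
    """The deviance/overdispersion machinery equals a brute-force
    evaluation via binomial log-pmfs on random count configurations."""
    from oracles import lrt_oracle, random_count_groups

    rng = np.random.default_rng(2024)
    for _ in range(300):
        ga, gb = random_count_groups(rng)
        d1, p1 = dma.test_window(ga, gb)
        d2, p2 = lrt_oracle(ga, gb)
        assert abs(d1 - d2) < 1e-10
        assert abs(p1 - p2) < 1e-10


def test_antisymmetry_under_group_swap():
    rng = np.random.default_rng(7)
    for _ in range(50):
        ga = [(int(rng.integers(0, n + 1)), int(n)) for n in rng.integers(1, 60, 3)]
        gb = [(int(rng.integers(0, n + 1)), int(n)) for n in rng.integers(1, 60, 3)]
        d1, p1 = dma.test_window(ga, gb)
        d2, p2 = dma.test_window(gb, ga)
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        dma.test_window([(1, 2)], [(1, 2), (1, 2)])


# -- calling -------------------------------------------------------------


def _results(rows):
    return pd.DataFrame(
        rows, columns=["window_id", "comparison", "context", "meth_diff", "p_value"]
    )


def test_calls_respect_context_thresholds():
    res = _results(
        [
            ("w1", "CFvSB", "CG", 15.0, 1e-9),  # below the 20-point CG rule
            ("w2", "CFvSB", "CHH", -12.0, 1e-9),  # above the 10-point CHH rule
            ("w3", "CFvSB", "CG", 45.0, 1e-9),
        ]
    )
    called = dma.adjust_and_call(res).set_index("window_id")
    assert called.loc["w1", "call"] == "ns"
    assert called.loc["w2", "call"] == "hypo"
    assert called.loc["w3", "call"] == "hyper"


def test_all_flat_pvalues_never_called():
    res = _results([(f"w{i}", "CFvSB", "CG", 50.0, 1.0) for i in range(20)])
    called = dma.adjust_and_call(res)
    assert (called["call"] == "ns").all()
    assert (called["q_value"] == 1.0).all()


def test_q_values_are_bh():
    rng = np.random.default_rng(1)
    ps = rng.random(40)
    res = _results([(f"w{i}", "X", "CG", 0.0, p) for i, p in enumerate(ps)])
    called = dma.adjust_and_call(res)
    expected = stats.false_discovery_control(ps, method="bh")
    assert np.allclose(called["q_value"], expected)


# -- inherited sets and concordance -------------------------------------


def _called(rows):
    return pd.DataFrame(rows, columns=["window_id", "comparison", "context", "call"])


def test_inherited_sets_sign_logic():
    dmrs = _called(
        [
            ("w1", "CSvSB", "CG", "hyper"),
            ("w1", "CFvSB", "CG", "hyper"),  # -> iCF hyper
            ("w2", "CSvSB", "CG", "hyper"),
            ("w2", "CFvSB", "CG", "hypo"),  # sign mismatch -> excluded
            ("w3", "CSvCF", "CG", "hypo"),
            ("w3", "SBvCF", "CG", "hypo"),  # -> iSB hypo
            ("w1", "CSvCF", "CG", "ns"),
            ("w1", "SBvCF", "CG", "ns"),
        ]
    )
    sets_ = dma.inherited_dmr_sets(dmrs)
    assert list(sets_["iCF"]["window_id"]) == ["w1"]
    assert list(sets_["iCF"]["call"]) == ["hyper"]
    assert list(sets_["iSB"]["window_id"]) == ["w3"]


def test_inherited_sets_missing_comparison_raises():
    dmrs = _called([("w1", "CSvSB", "CG", "hyper")])
    with pytest.raises(ValueError, match="missing comparisons"):
        dma.inherited_dmr_sets(dmrs)


def test_concordance_examples():
    parent = pd.DataFrame(
        {
            "window_id": ["w1", "w2"],
            "comparison": "CF1:CF2",
            "context": "CG",
            "level_a": [82.0, 90.0],
            "level_b": [5.0, 5.0],
            "call": ["hyper", "hyper"],
        }
    )
    cs = pd.DataFrame(
        {"window_id": ["w1", "w2"], "context": "CG", "level": [80.0, 50.0]}
    )
    frac, records = dma.intra_cultivar_concordance(parent, cs)
    by_id = records.set_index("window_id")
    assert bool(by_id.loc["w1", "concordant"]) is True  # delta 2 < 20
    assert bool(by_id.loc["w2", "concordant"]) is False  # min delta 40
    assert frac == 0.5


def test_concordance_missing_cs_window_excluded():
    parent = pd.DataFrame(
        {
            "window_id": ["w1"],
            "comparison": "x",
            "context": "CG",
            "level_a": [80.0],
            "level_b": [0.0],
            "call": ["hyper"],
        }
    )
    cs = pd.DataFrame({"window_id": [], "context": [], "level": []})
    frac, records = dma.intra_cultivar_concordance(parent, cs)
    assert np.isnan(frac) and records.empty


# -- sweep ---------------------------------------------------------------


def test_sweep_monotonicity(small_trio, small_profiles):
    from panmeth.graph import chop_nodes

    _, truth, _ = small_trio
    g, _ = chop_nodes(truth.graphs["chr1"], 200)
    sweep = dma.sweep_parameters(
        g,
        small_profiles,
        win_sizes=(200,),
        cov_bases=(1, 3, 6),
        diff_mins=(5.0, 25.0),
        contexts=("CG",),
    )
    # stricter differential never yields more DMRs
    for cov in (1, 3, 6):
        sub = sweep[sweep["cov_bases"] == cov].set_index("diff_min")
        assert sub.loc[25.0, "n_dmrs"] <= sub.loc[5.0, "n_dmrs"]
    # more required cytosines never yields more windows
    n_win = sweep.groupby("cov_bases")["n_windows"].first()
    assert n_win.loc[3] <= n_win.loc[1]
    assert n_win.loc[6] <= n_win.loc[3]


def test_single_cell_sweep_matches_direct_run(small_trio, small_profiles):
    from panmeth.graph import chop_nodes

    _, truth, _ = small_trio
    g, _ = chop_nodes(truth.graphs["chr1"], 200)
    sweep = dma.sweep_parameters(
        g,
        small_profiles,
        win_sizes=(200,),
        cov_bases=(3,),
        diff_mins=(20.0,),
        contexts=("CG",),
    )
    th = dma.DMAThresholds()
    windows, _ = dma.build_windows(g, small_profiles, th)
    res = dma.run_comparison(windows, small_profiles, "CFvSB", ("CG",), chrom="chr1")
    called = dma.adjust_and_call(res, th)
    direct = int(
        ((called["q_value"] < 0.01) & (called["meth_diff"].abs() >= 20)).sum()
    )
    assert int(sweep["n_dmrs"].iloc[0]) == direct
    assert int(sweep["n_windows"].iloc[0]) == len(called)
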