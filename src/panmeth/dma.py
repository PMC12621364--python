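"""Graph-window differential methylation analysis (DMA).

Windows are tiled on the two CS haplotypes (the hybrid's phased genome),
projected through the graph onto every other haplotype, and filtered to
projected lengths of 150-250 bp with at least 3 united cytosines on every
haplotype.  Counts are pooled per clone within each cultivar's projected
intervals (clones are the samples, 3 vs 3) and compared with a binomial
logistic likelihood-ratio test; the statistic is deflated by the Pearson
overdispersion estimate when it exceeds 1 (McCullagh-Nelder scaling).
Benjamini-Hochberg q-values are computed per comparison and context, and
windows are called hyper-/hypo-methylated at q < 0.01 with
context-specific differentials (CG/CHG 20, CHH 10 percentage points).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .config import HAPS_OF_CULTIVAR
from .graph import PathInterval, SequenceGraph, project_interval

__all__ = [
    "DMAThresholds",
    "ComparableWindow",
    "build_windows",
    "make_reference_windows",
    "project_windows",
    "aggregate_window_counts",
    "test_window",
    "test_windows_bulk",
    "run_comparison",
    "adjust_and_call",
    "inherited_dmr_sets",
    "intra_cultivar_concordance",
    "window_levels",
    "sweep_parameters",
]

COMPARISONS = {
    "CSvSB": ("CS", "SB"),
    "CFvSB": ("CF", "SB"),
    "CSvCF": ("CS", "CF"),
    "SBvCF": ("SB", "CF"),
}


@dataclass
class DMAThresholds:
    """Calling thresholds: q-value cut-off, context-specific methylation
    differentials (percentage points), window geometry and filters."""

    q_max: float = 0.01
    diff_min: dict[str, float] = field(
        default_factory=lambda: {"CG": 20.0, "CHG": 20.0, "CHH": 10.0}
    )
    win: int = 200
    step: int = 200
    min_cytosines: int = 3
    min_len: int = 150
    max_len: int = 250

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.diff_min.values()):
            raise ValueError("diff_min thresholds must be positive")


@dataclass
class ComparableWindow:
    """A reference window plus its projected interval on every haplotype.

    ``intervals`` maps haplotype -> 0-based half-open (start, end),
    including the reference haplotype itself.
    """

    window_id: str
    ref: PathInterval
    intervals: dict[str, tuple[int, int]]


def make_reference_windows(
    graph: SequenceGraph,
    ref_paths: list[str],
    win: int = 200,
    step: int = 200,
    min_len: int = 150,
) -> list[PathInterval]:
    """Tile [0, L) of each reference path; a short terminal window is
    kept only when it reaches ``min_len``."""
    if win < 1 or step < 1:
        raise ValueError("win and step must be >= 1")
    windows = []
    for path in ref_paths:
        L = graph.path_length(path)
        for start in range(0, L, step):
            end = min(start + win, L)
            if end - start >= min_len:
                windows.append(PathInterval(path, start, end))
    return windows


def _node_range_key(graph: SequenceGraph, iv: PathInterval) -> tuple:
    idx = graph._index(iv.path_name)
    s0 = idx.step_at(iv.start)
    s1 = idx.step_at(iv.end - 1)
    return tuple(nid for nid, _o in idx.steps[s0 : s1 + 1])


def _cytosine_counter(profiles: dict[str, pd.DataFrame], chrom: str | None):
    """hap -> sorted site position array (for interval counting)."""
    pos_by_hap = {}
    for hap, prof in profiles.items():
        sub = prof if chrom is None else prof[prof["chrom"] == chrom]
        pos_by_hap[hap] = np.sort(sub["pos"].to_numpy() - 1)
    return pos_by_hap


def project_windows(
    graph: SequenceGraph,
    windows: list[PathInterval],
    targets: list[str],
    profiles: dict[str, pd.DataFrame],
    thresholds: DMAThresholds | None = None,
) -> tuple[list[ComparableWindow], Counter]:
    """Project windows onto target haplotypes and apply the retention
    filters (projected length 150-250 bp, >= 3 cytosines everywhere).

    Windows anchored on both CS haplotypes that cover the same node range
    are deduplicated.  Returns the retained windows and a tally of drop
    reasons.
    """
    thresholds = thresholds or DMAThresholds()
    drops: Counter = Counter()
    pos_by_hap = _cytosine_counter(profiles, graph.name)
    seen_ranges: set[tuple] = set()
    retained: list[ComparableWindow] = []
    for w in windows:
        key = _node_range_key(graph, w)
        if key in seen_ranges:
            drops["duplicate"] += 1
            continue
        intervals: dict[str, tuple[int, int]] = {w.path_name: (w.start, w.end)}
        ok = True
        for target in targets:
            if target == w.path_name:
                continue
            piv = project_interval(graph, w, target)
            if piv is None:
                drops["unprojectable"] += 1
                ok = False
                break
            if not (thresholds.min_len <= piv.length <= thresholds.max_len):
                drops["length"] += 1
                ok = False
                break
            intervals[target] = (piv.start, piv.end)
        if not ok:
            continue
        for hap, (s, e) in intervals.items():
            pos = pos_by_hap.get(hap)
            if pos is None:
                continue
            n_cyt = np.searchsorted(pos, e) - np.searchsorted(pos, s)
            if n_cyt < thresholds.min_cytosines:
                drops["cytosines"] += 1
                ok = False
                break
        if not ok:
            continue
        seen_ranges.add(key)
        wid = f"{w.path_name}:{w.start}-{w.end}"
        retained.append(ComparableWindow(wid, w, intervals))
    return retained, drops


def build_windows(
    graph: SequenceGraph,
    profiles: dict[str, pd.DataFrame],
    thresholds: DMAThresholds | None = None,
    ref_paths: tuple[str, ...] = ("CSCF", "CSSB"),
    targets: tuple[str, ...] | None = None,
) -> tuple[list[ComparableWindow], Counter]:
    """Standard window set: tile the CS haplotypes and project onto all
    haplotypes (convenience wrapper)."""
    thresholds = thresholds or DMAThresholds()
    targets = targets or tuple(graph.paths)
    raw = make_reference_windows(
        graph,
        [p for p in ref_paths if p in graph.paths],
        thresholds.win,
        thresholds.step,
        thresholds.min_len,
    )
    return project_windows(graph, raw, list(targets), profiles, thresholds)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


class _CumulativeCounts:
    """Per-haplotype, per-context cumulative clone counts for O(log n)
    interval sums."""

    def __init__(self, profiles: dict[str, pd.DataFrame], chrom: str | None):
        self.data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.clones: dict[str, list[str]] = {}
        for hap, prof in profiles.items():
            sub = prof if chrom is None else prof[prof["chrom"] == chrom]
            clones = [c[2:] for c in sub.columns if c.startswith("m_")]
            self.clones[hap] = clones
            for ctx, csub in sub.groupby("context", observed=True, sort=False):
                csub = csub.sort_values("pos", kind="stable")
                pos0 = csub["pos"].to_numpy() - 1
                m = csub[[f"m_{c}" for c in clones]].to_numpy(dtype=np.int64)
                u = csub[[f"u_{c}" for c in clones]].to_numpy(dtype=np.int64)
                cm = np.vstack([np.zeros((1, len(clones)), dtype=np.int64), m.cumsum(0)])
                cn = np.vstack(
                    [np.zeros((1, len(clones)), dtype=np.int64), (m + u).cumsum(0)]
                )
                self.data[(hap, str(ctx))] = (pos0, cm, cn)

    def interval_sums(
        self, hap: str, context: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(m, n) clone-count sums for each interval; shape (W, clones)."""
        entry = self.data.get((hap, context))
        n_clones = len(self.clones.get(hap, [])) or 1
        if entry is None:
            z = np.zeros((len(starts), n_clones), dtype=np.int64)
            return z, z.copy()
        pos0, cm, cn = entry
        lo = np.searchsorted(pos0, starts)
        hi = np.searchsorted(pos0, ends)
        return cm[hi] - cm[lo], cn[hi] - cn[lo]


def _group_counts(
    windows: list[ComparableWindow],
    cum: _CumulativeCounts,
    haps: list[str],
    context: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool counts per clone across a group's haplotype intervals."""
    total_m = total_n = None
    for hap in haps:
        starts = np.array([w.intervals[hap][0] for w in windows], dtype=np.int64)
        ends = np.array([w.intervals[hap][1] for w in windows], dtype=np.int64)
        m, n = cum.interval_sums(hap, context, starts, ends)
        total_m = m if total_m is None else total_m + m
        total_n = n if total_n is None else total_n + n
    return total_m, total_n


def aggregate_window_counts(
    window: ComparableWindow,
    profiles: dict[str, pd.DataFrame],
    group_a: list[str],
    group_b: list[str],
    context: str,
    chrom: str | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Per-clone (m, n) pairs for the two groups of one window.

    Counts are summed over all cytosines of ``context`` inside the
    group's projected interval(s); a cultivar group pools its two
    haplotypes per clone.  Raises ``ValueError`` when a sample has zero
    coverage.
    """
    cum = _CumulativeCounts(profiles, chrom)
    out = []
    for haps in (group_a, group_b):
        m, n = _group_counts([window], cum, haps, context)
        if (n[0] == 0).any():
            raise ValueError(
                f"zero total coverage in window {window.window_id} for group {haps}"
            )
        out.append(list(zip(m[0].tolist(), n[0].tolist())))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------


def test_windows_bulk(
    m_a: np.ndarray, n_a: np.ndarray, m_b: np.ndarray, n_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized likelihood-ratio test over windows.

    Inputs are (windows x clones) count matrices.  Returns
    ``(meth_diff, p_value)`` where meth_diff is the pooled-proportion
    difference A - B in percentage points.  The binomial deviance
    against the pooled null is scaled by the Pearson overdispersion
    estimate when it exceeds 1, and referred to chi-square with 1 df.
    """
    m_a, n_a, m_b, n_b = (np.asarray(x, dtype=float) for x in (m_a, n_a, m_b, n_b))
    sm_a, sn_a = m_a.sum(1), n_a.sum(1)
    sm_b, sn_b = m_b.sum(1), n_b.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(sn_a > 0, sm_a / np.maximum(sn_a, 1), 0.0)
        p_b = np.where(sn_b > 0, sm_b / np.maximum(sn_b, 1), 0.0)
        p_0 = (sm_a + sm_b) / np.maximum(sn_a + sn_b, 1)
    meth_diff = 100.0 * (p_a - p_b)

    def _loglik(m, n, p):
        return xlogy(m, p).sum(1) + xlogy(n - m, 1.0 - p).sum(1)

    ll_full = _loglik(m_a, n_a, p_a[:, None]) + _loglik(m_b, n_b, p_b[:, None])
    ll_null = _loglik(m_a, n_a, p_0[:, None]) + _loglik(m_b, n_b, p_0[:, None])
    deviance = np.maximum(2.0 * (ll_full - ll_null), 0.0)

    # Pearson overdispersion under the fitted (group) proportions
    def _pearson(m, n, p):
        num = (m - n * p) ** 2
        den = n * p * (1.0 - p)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0).sum(1)

    n_samples = m_a.shape[1] + m_b.shape[1]
    phi = (_pearson(m_a, n_a, p_a[:, None]) + _pearson(m_b, n_b, p_b[:, None])) / max(
        n_samples - 2, 1
    )
    scaled = np.where(phi > 1.0, deviance / np.maximum(phi, 1.0), deviance)
    p_value = stats.chi2.sf(scaled, df=1)
    return meth_diff, p_value


def test_window(
    group_a: list[tuple[int, int]], group_b: list[tuple[int, int]]
) -> tuple[float, float]:
    """Overdispersion-corrected binomial LRT for one window (scalar API).

    ``group_a``/``group_b`` are per-sample (methylated, total) pairs;
    requires >= 2 samples per group and a non-zero total per group.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    m_a = np.array([[m for m, _ in group_a]])
    n_a = np.array([[n for _, n in group_a]])
    m_b = np.array([[m for m, _ in group_b]])
    n_b = np.array([[n for _, n in group_b]])
    if n_a.sum() == 0 or n_b.sum() == 0:
        raise ValueError("a group has zero total coverage")
    diff, p = test_windows_bulk(m_a, n_a, m_b, n_b)
    return float(diff[0]), float(p[0])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_comparison(
    windows: list[ComparableWindow],
    profiles: dict[str, pd.DataFrame],
    comparison: str,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
    chrom: str | None = None,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Test every window for one pairwise comparison (A vs B; B is the
    reference).  ``comparison`` is a key of :data:`COMPARISONS` or
    "X:Y" with explicit group names; ``groups`` may override the
    cultivar -> haplotypes mapping (e.g. single-haplotype groups for the
    intra-cultivar mode).  Windows where any clone has zero coverage for
    a context are skipped for that context.
    """
    groups = groups or HAPS_OF_CULTIVAR
    if comparison in COMPARISONS:
        name_a, name_b = COMPARISONS[comparison]
    elif ":" in comparison:
        name_a, name_b = comparison.split(":", 1)
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    haps_a, haps_b = list(groups[name_a]), list(groups[name_b])
    cum = _CumulativeCounts(profiles, chrom)
    rows = []
    if not windows:
        return pd.DataFrame(
            columns=[
                "window_id",
                "comparison",
                "context",
                "level_a",
                "level_b",
                "meth_diff",
                "p_value",
            ]
        )
    for context in contexts:
        m_a, n_a = _group_counts(windows, cum, haps_a, context)
        m_b, n_b = _group_counts(windows, cum, haps_b, context)
        valid = (n_a > 0).all(1) & (n_b > 0).all(1)
        if not valid.any():
            continue
        diff, p = test_windows_bulk(m_a[valid], n_a[valid], m_b[valid], n_b[valid])
        level_a = 100.0 * m_a[valid].sum(1) / n_a[valid].sum(1)
        level_b = 100.0 * m_b[valid].sum(1) / n_b[valid].sum(1)
        ids = [w.window_id for w, v in zip(windows, valid.tolist()) if v]
        rows.append(
            pd.DataFrame(
                {
                    "window_id": ids,
                    "comparison": comparison,
                    "context": context,
                    "level_a": level_a,
                    "level_b": level_b,
                    "meth_diff": diff,
                    "p_value": p,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "window_id",
                "comparison",
                "context",
                "level_a",
                "level_b",
                "meth_diff",
                "p_value",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def adjust_and_call(
    results: pd.DataFrame, thresholds: DMAThresholds | None = None
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values per comparison and context, then the
    hyper/hypo/ns call at q < q_max and the context differential."""
    thresholds = thresholds or DMAThresholds()
    out = results.copy()
    out["q_value"] = np.nan
    for (_, _), idx in out.groupby(["comparison", "context"], observed=True).groups.items():
        ps = out.loc[idx, "p_value"].to_numpy()
        out.loc[idx, "q_value"] = stats.false_discovery_control(ps, method="bh")
    diff_min = out["context"].map(thresholds.diff_min).to_numpy(dtype=float)
    sig = out["q_value"].to_numpy() < thresholds.q_max
    diff = out["meth_diff"].to_numpy()
    call = np.where(
        sig & (diff >= diff_min),
        "hyper",
        np.where(sig & (diff <= -diff_min), "hypo", "ns"),
    )
    out["call"] = call
    return out


def inherited_dmr_sets(dmrs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Inherited DMR sets from the four cultivar comparisons.

    iCF: windows with the same differential sign in CSvSB and CFvSB
    (pattern shared by the hybrid and CF); iSB: same sign in CSvCF and
    SBvCF.  Hyper and hypo are kept separate.
    """
    have = set(dmrs["comparison"].unique())
    needed = {"CSvSB", "CFvSB", "CSvCF", "SBvCF"}
    if not needed <= have:
        raise ValueError(f"missing comparisons: {sorted(needed - have)}")
    out = {}
    for set_name, (comp1, comp2) in {
        "iCF": ("CSvSB", "CFvSB"),
        "iSB": ("CSvCF", "SBvCF"),
    }.items():
        a = dmrs[(dmrs["comparison"] == comp1) & (dmrs["call"] != "ns")]
        b = dmrs[(dmrs["comparison"] == comp2) & (dmrs["call"] != "ns")]
        merged = a.merge(
            b[["window_id", "context", "call"]],
            on=["window_id", "context"],
            suffixes=("", "_parent"),
        )
        merged = merged[merged["call"] == merged["call_parent"]]
        out[set_name] = merged[["window_id", "context", "call"]].reset_index(drop=True)
    return out


def window_levels(
    windows: list[ComparableWindow],
    profiles: dict[str, pd.DataFrame],
    haps: list[str],
    context: str,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Pooled methylation level (%) per window over the given haplotype
    intervals (summed over clones and haplotypes)."""
    cum = _CumulativeCounts(profiles, chrom)
    m, n = _group_counts(windows, cum, haps, context)
    sm, sn = m.sum(1), n.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(sn > 0, 100.0 * sm / np.maximum(sn, 1), np.nan)
    return pd.DataFrame(
        {"window_id": [w.window_id for w in windows], "context": context, "level": level}
    )


def intra_cultivar_concordance(
    parent_dmrs: pd.DataFrame,
    cs_levels: pd.DataFrame,
    thresholds: DMAThresholds | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of intra-cultivar DMRs where the hybrid matches at least
    one parental haplotype.

    ``parent_dmrs`` must carry ``level_a``/``level_b`` (the two parental
    haplotype levels) for windows called hyper or hypo; ``cs_levels``
    the CS level per (window_id, context).  A DMR is concordant when
    min(|CS - hap1|, |CS - hap2|) is below the context differential
    threshold; DMRs without a homologous CS window are excluded.
    """
    thresholds = thresholds or DMAThresholds()
    sig = parent_dmrs[parent_dmrs["call"] != "ns"]
    merged = sig.merge(
        cs_levels.rename(columns={"level": "level_cs"}),
        on=["window_id", "context"],
        how="left",
    )
    excluded = merged["level_cs"].isna()
    merged = merged[~excluded].copy()
    delta1 = (merged["level_cs"] - merged["level_a"]).abs()
    delta2 = (merged["level_cs"] - merged["level_b"]).abs()
    diff_min = merged["context"].map(thresholds.diff_min)
    merged["delta_min"] = np.minimum(delta1, delta2)
    merged["concordant"] = merged["delta_min"] < diff_min
    frac = float(merged["concordant"].mean()) if len(merged) else float("nan")
    return frac, merged


def sweep_parameters(
    graph: SequenceGraph,
    profiles: dict[str, pd.DataFrame],
    comparison: str = "CFvSB",
    ref_paths: tuple[str, ...] = ("CSCF", "CSSB"),
    targets: tuple[str, ...] = ("CF1", "CF2", "SB1", "SB2", "CSCF", "CSSB"),
    win_sizes: tuple[int, ...] = (100, 200, 400),
    step_sizes: tuple[int, ...] | None = None,
    cov_bases: tuple[int, ...] = (1, 3, 5),
    diff_mins: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0),
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Parameter grid for threshold selection: DMR counts per
    (win, step, cov_bases, diff_min, context)."""
    rows = []
    for win in win_sizes:
        for step in step_sizes or (win,):
            for cov in cov_bases:
                thresholds = DMAThresholds(
                    win=win,
                    step=step,
                    min_cytosines=cov,
                    min_len=max(1, win - 50),
                    max_len=win + 50,
                )
                raw = make_reference_windows(
                    graph, list(ref_paths), win, step, thresholds.min_len
                )
                windows, _ = project_windows(
                    graph, raw, list(targets), profiles, thresholds
                )
                res = run_comparison(
                    windows, profiles, comparison, contexts, chrom=graph.name
                )
                if res.empty:
                    continue
                called = adjust_and_call(res, thresholds)
                for diff_min in diff_mins:
                    for context in contexts:
                        sub = called[called["context"] == context]
                        sig = (sub["q_value"] < thresholds.q_max) & (
                            sub["meth_diff"].abs() >= diff_min
                        )
                        rows.append(
                            {
                                "win": win,
                                "step": step,
                                "cov_bases": cov,
                                "diff_min": diff_min,
                                "context": context,
                                "n_windows": len(sub),
                                "n_dmrs": int(sig.sum()),
                            }
                        )
    return pd.DataFrame(rows)
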