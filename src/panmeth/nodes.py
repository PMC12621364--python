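"""Pan-methylome node classification.

Methylation profiles are projected onto the chopped graph: every united
site lands in exactly one node of its own haplotype path.  Nodes
containing cytosines are then classified by which haplotypes share them
— either by mere presence on the path, or restricted to haplotypes in
which the node is methylated (>= 1 cytosine with mean-across-clones
level over the threshold), the methylation-aware sharing that exposes
parent-progeny inheritance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CULTIVAR_OF
from .graph import SequenceGraph
from .methio import clone_names, level_matrix

__all__ = [
    "NodeMethylationMatrix",
    "assign_sites_to_nodes",
    "classify_nodes",
    "node_class_summary",
]


@dataclass
class NodeMethylationMatrix:
    """Per-node, per-haplotype presence and methylation flags.

    ``presence[node]`` is the set of haplotypes whose path contains the
    node; ``site_counts``/``meth_counts`` give, per node and haplotype,
    the number of united cytosines and how many of them are methylated.
    """

    haplotypes: list[str]
    presence: dict[str, set[str]]
    site_counts: dict[str, dict[str, int]]
    meth_counts: dict[str, dict[str, int]]

    def contains_cytosine(self, node: str, hap: str) -> bool:
        return self.site_counts.get(node, {}).get(hap, 0) > 0

    def methylated(self, node: str, hap: str) -> bool:
        return self.meth_counts.get(node, {}).get(hap, 0) > 0

    def cytosine_nodes(self) -> list[str]:
        return [n for n, c in self.site_counts.items() if any(c.values())]


def assign_sites_to_nodes(
    graph: SequenceGraph,
    profiles: dict[str, pd.DataFrame],
    meth_threshold: float = 20.0,
) -> NodeMethylationMatrix:
    """Bin every united site into the node covering it on its own path.

    ``profiles`` maps haplotype (path name) to a united profile whose
    positions are 1-based path coordinates.  Raises ``ValueError`` for a
    site beyond the path length.
    """
    haps = list(profiles)
    presence: dict[str, set[str]] = {}
    for hap in graph.paths:
        for nid, _o in graph.paths[hap]:
            presence.setdefault(nid, set()).add(hap)

    site_counts: dict[str, dict[str, int]] = {}
    meth_counts: dict[str, dict[str, int]] = {}
    for hap, profile in profiles.items():
        starts = np.asarray(graph.node_step_starts(hap))
        steps = graph.paths[hap]
        plen = graph.path_length(hap)
        if profile.empty:
            continue
        chrom_col = profile["chrom"].to_numpy()
        if graph.name is not None:
            keep = chrom_col == graph.name
            profile = profile[keep]
            if profile.empty:
                continue
        pos0 = profile["pos"].to_numpy() - 1
        if pos0.min() < 0 or pos0.max() >= plen:
            bad = pos0.max() if pos0.max() >= plen else pos0.min()
            raise ValueError(
                f"site position {bad + 1} outside path {hap} (length {plen})"
            )
        level_mean = level_matrix(profile, clone_names(profile)).mean(axis=1)
        meth = level_mean >= meth_threshold
        step_idx = np.searchsorted(starts, pos0, side="right") - 1
        for si, is_m in zip(step_idx.tolist(), meth.tolist()):
            nid = steps[si][0]
            site_counts.setdefault(nid, {}).setdefault(hap, 0)
            site_counts[nid][hap] += 1
            if is_m:
                meth_counts.setdefault(nid, {}).setdefault(hap, 0)
                meth_counts[nid][hap] += 1
    return NodeMethylationMatrix(haps, presence, site_counts, meth_counts)


def _classify_sharing(sharing: frozenset[str]) -> tuple[str, str]:
    """(presence_class, cultivar_class) of a haplotype sharing set.

    core = all six haplotypes; private = haplotypes of a single cultivar;
    dispensable = shared more widely without reaching all six.  The
    cultivar classes follow the all / intra / inter legend: all six
    haplotypes, one cultivar only, or several cultivars but not all.
    """
    cultivars = {CULTIVAR_OF[h] for h in sharing}
    n_haps = len(sharing)
    if n_haps == 6:
        return "core", "all"
    if len(cultivars) == 1:
        return "private", "intra"
    return "dispensable", "inter"


def classify_nodes(
    matrix: NodeMethylationMatrix, mode: str = "presence"
) -> pd.DataFrame:
    """Classify cytosine-containing nodes by their haplotype sharing set.

    ``mode='presence'`` shares a node among all haplotypes whose path
    contains it; ``mode='methylation'`` restricts the set to haplotypes
    where the node is methylated.  Nodes with an empty (restricted) set
    are excluded and reported with class ``excluded``.
    """
    if mode not in ("presence", "methylation"):
        raise ValueError("mode must be 'presence' or 'methylation'")
    rows = []
    for node in matrix.cytosine_nodes():
        if mode == "presence":
            sharing = frozenset(matrix.presence.get(node, set()))
        else:
            sharing = frozenset(
                h for h in matrix.presence.get(node, set()) if matrix.methylated(node, h)
            )
        if not sharing:
            rows.append(
                {
                    "node": node,
                    "combination": "",
                    "presence_class": "excluded",
                    "cultivar_class": "excluded",
                    "cultivar_combination": "",
                }
            )
            continue
        presence_class, cultivar_class = _classify_sharing(sharing)
        rows.append(
            {
                "node": node,
                "combination": "+".join(sorted(sharing)),
                "presence_class": presence_class,
                "cultivar_class": cultivar_class,
                "cultivar_combination": "+".join(
                    sorted({CULTIVAR_OF[h] for h in sharing})
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "node",
            "combination",
            "presence_class",
            "cultivar_class",
            "cultivar_combination",
        ],
    )


def node_class_summary(
    classifications: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Upset-style summary: counts per haplotype combination (ranked
    descending, stable lexicographic tie-break) and per cultivar class."""
    cls = classifications[classifications["presence_class"] != "excluded"]
    counts = Counter(cls["combination"])
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    by_comb = pd.DataFrame(rows, columns=["combination", "n_nodes"])
    comb_to_class = dict(
        zip(cls["combination"], zip(cls["presence_class"], cls["cultivar_class"]))
    )
    by_comb["presence_class"] = [comb_to_class[c][0] for c in by_comb["combination"]]
    by_comb["cultivar_class"] = [comb_to_class[c][1] for c in by_comb["combination"]]
    by_class = (
        cls.groupby(["presence_class", "cultivar_class"])
        .size()
        .rename("n_nodes")
        .reset_index()
    )
    return {"combinations": by_comb, "classes": by_class}
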