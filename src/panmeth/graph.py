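"""Haplotype sequence graph: data model, GFA v1 I/O, chopping, projection.

A :class:`SequenceGraph` stores node sequences, edges, and named haplotype
paths.  Each path is an ordered, oriented walk over nodes spelling one
haplotype.  All cross-haplotype coordinate arithmetic (window projection,
homologous-chunk pairing, variant extraction) goes through this module.

Coordinates are 0-based half-open everywhere inside the package; the
1-based conventions of CX reports and GFF are converted at I/O boundaries.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field

__all__ = [
    "SequenceGraph",
    "PathInterval",
    "PathVariant",
    "reverse_complement",
    "read_gfa",
    "write_gfa",
    "path_sequence",
    "chop_nodes",
    "project_position",
    "project_interval",
    "extract_path_variants",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GFAError(ValueError):
    """Malformed GFA input or inconsistent graph."""


@dataclass
class PathInterval:
    """Half-open interval ``[start, end)`` on a named path, in bp."""

    path_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PathVariant:
    """A bubble between two paths, anchored on flanking shared nodes.

    ``pos_a``/``pos_b`` are the 0-based start of the alternative allele on
    each path (the insertion point when the allele is empty).  ``type`` is
    one of SNP / INDEL / MNP / OTHER; ``length`` is the allele length for
    SNP/MNP and the length difference for INDELs.
    """

    path_a: str
    path_b: str
    pos_a: int
    pos_b: int
    allele_a: str
    allele_b: str
    type: str
    length: int

    @property
    def is_sv(self) -> bool:
        """Structural variant: insertion/deletion of at least 50 bp."""
        return self.type == "INDEL" and self.length >= 50


@dataclass
class SequenceGraph:
    """Bidirected sequence graph with named haplotype paths.

    nodes
        node id -> DNA sequence (non-empty, alphabet ACGTN).
    edges
        set of ``(node_a, orient_a, node_b, orient_b)`` links.
    paths
        path name -> ordered list of ``(node_id, orient)`` steps.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    paths: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        self._index_cache: dict[str, "_PathIndex"] = {}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for nid, seq in self.nodes.items():
            if not seq:
                raise GFAError(f"node {nid} has empty sequence")
            if not set(seq.upper()) <= _ALPHABET:
                raise GFAError(f"node {nid} has non-ACGTN characters")
        for name, steps in self.paths.items():
            if not steps:
                raise GFAError(f"path {name} is empty")
            for nid, _ in steps:
                if nid not in self.nodes:
                    raise GFAError(f"path {name} references unknown node {nid}")

    # -- path indexing ---------------------------------------------------
    def _index(self, path_name: str) -> "_PathIndex":
        if path_name not in self.paths:
            raise KeyError(f"unknown path {path_name!r}")
        idx = self._index_cache.get(path_name)
        if idx is None:
            idx = _PathIndex(self, path_name)
            self._index_cache[path_name] = idx
        return idx

    def invalidate_indexes(self) -> None:
        """Call after mutating nodes/paths in place."""
        self._index_cache.clear()

    def path_length(self, path_name: str) -> int:
        return self._index(path_name).length

    def node_step_starts(self, path_name: str) -> list[int]:
        """Start offset of each step along the path (for binning sites)."""
        return self._index(path_name).starts


class _PathIndex:
    """Per-path step offsets and node occurrence lookup."""

    def __init__(self, graph: SequenceGraph, path_name: str):
        steps = graph.paths[path_name]
        self.steps = steps
        self.starts: list[int] = []
        self.occurrences: dict[str, list[int]] = {}
        off = 0
        for i, (nid, _orient) in enumerate(steps):
            self.starts.append(off)
            off += len(graph.nodes[nid])
            self.occurrences.setdefault(nid, []).append(i)
        self.length = off

    def step_at(self, pos: int) -> int:
        """Index of the step containing position ``pos``."""
        if not (0 <= pos < self.length):
            raise IndexError(f"position {pos} outside path (length {self.length})")
        return bisect_right(self.starts, pos) - 1


# -- GFA I/O -------------------------------------------------------------


def read_gfa(path) -> SequenceGraph:
    """Read GFA v1 (S/L/P lines; GFA 1.1 W lines normalized to paths)."""
    graph = SequenceGraph()
    pending_paths: list[tuple[int, str, list[tuple[str, str]]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "S":
                    graph.nodes[fields[1]] = fields[2].upper()
                elif tag == "L":
                    graph.edges.add((fields[1], fields[2], fields[3], fields[4]))
                elif tag == "P":
                    steps = [(s[:-1], s[-1]) for s in fields[2].split(",")]
                    pending_paths.append((lineno, fields[1], steps))
                elif tag == "W":
                    name = "#".join(fields[1:4])
                    steps = _parse_walk(fields[6])
                    pending_paths.append((lineno, name, steps))
                # H and other records are ignored
            except (IndexError, ValueError) as exc:
                raise GFAError(f"malformed GFA line {lineno}: {line!r}") from exc
    for lineno, name, steps in pending_paths:
        for nid, orient in steps:
            if nid not in graph.nodes:
                raise GFAError(f"line {lineno}: path {name} references unknown node {nid}")
            if orient not in "+-":
                raise GFAError(f"line {lineno}: bad orientation {orient!r}")
        graph.paths[name] = steps
    if not graph.edges:
        _infer_edges(graph)
    return graph


def _parse_walk(walk: str) -> list[tuple[str, str]]:
    steps = []
    token = ""
    orient = None
    for ch in walk:
        if ch in "><":
            if orient is not None:
                steps.append((token, "+" if orient == ">" else "-"))
            orient, token = ch, ""
        else:
            token += ch
    if orient is None:
        raise ValueError(f"bad walk {walk!r}")
    steps.append((token, "+" if orient == ">" else "-"))
    return steps


def _infer_edges(graph: SequenceGraph) -> None:
    for steps in graph.paths.values():
        for (a, oa), (b, ob) in itertools.pairwise(steps):
            graph.edges.add((a, oa, b, ob))


def write_gfa(graph: SequenceGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes, key=_node_sort_key):
            fh.write(f"S\t{nid}\t{graph.nodes[nid]}\n")
        for a, oa, b, ob in sorted(graph.edges):
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")
        for name, steps in graph.paths.items():
            walk = ",".join(f"{nid}{o}" for nid, o in steps)
            fh.write(f"P\t{name}\t{walk}\t*\n")


def _node_sort_key(nid: str):
    return (0, int(nid)) if nid.isdigit() else (1, nid)


# -- core operations -----------------------------------------------------


def path_sequence(graph: SequenceGraph, path_name: str) -> str:
    """Spell the haplotype: concatenate oriented node sequences."""
    if path_name not in graph.paths:
        raise KeyError(f"unknown path {path_name!r}")
    parts = []
    for nid, orient in graph.paths[path_name]:
        seq = graph.nodes[nid]
        parts.append(seq if orient == "+" else reverse_complement(seq))
    return "".join(parts)


def chop_nodes(
    graph: SequenceGraph, max_len: int = 200
) -> tuple[SequenceGraph, dict[str, list[str]]]:
    """Split nodes longer than ``max_len`` into consecutive pieces.

    Pieces are emitted 5'->3' in node-forward order and named
    ``<old>.<i>``.  Path sequences are preserved exactly.  Returns the
    chopped graph and a provenance map old id -> ordered new ids.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    provenance: dict[str, list[str]] = {}
    new_nodes: dict[str, str] = {}
    for nid, seq in graph.nodes.items():
        if len(seq) <= max_len:
            provenance[nid] = [nid]
            new_nodes[nid] = seq
        else:
            pieces = [seq[i : i + max_len] for i in range(0, len(seq), max_len)]
            ids = [f"{nid}.{k}" for k in range(len(pieces))]
            provenance[nid] = ids
            new_nodes.update(zip(ids, pieces))

    chopped = SequenceGraph(nodes=new_nodes, name=graph.name)
    for name, steps in graph.paths.items():
        new_steps: list[tuple[str, str]] = []
        for nid, orient in steps:
            ids = provenance[nid]
            if orient == "+":
                new_steps.extend((i, "+") for i in ids)
            else:
                new_steps.extend((i, "-") for i in reversed(ids))
        chopped.paths[name] = new_steps
    # intra-node chain edges
    for ids in provenance.values():
        for a, b in itertools.pairwise(ids):
            chopped.edges.add((a, "+", b, "+"))
    # original edges reattached to the boundary pieces
    for a, oa, b, ob in graph.edges:
        pa = provenance.get(a, [a])
        pb = provenance.get(b, [b])
        na = pa[-1] if oa == "+" else pa[0]
        nb = pb[0] if ob == "+" else pb[-1]
        chopped.edges.add((na, oa, nb, ob))
    return chopped, provenance


def project_position(
    graph: SequenceGraph, source: str, pos: int, target: str
) -> int | None:
    """Map a 0-based position from one path to another through the graph.

    The node containing ``pos`` on the source path must occur exactly once
    on the target path; the within-node offset is carried over, mirrored
    when the two occurrences have opposite orientation.  Returns ``None``
    for nodes absent from the target or occurring more than once
    (ambiguous mapping).
    """
    sidx = graph._index(source)
    tidx = graph._index(target)
    step = sidx.step_at(pos)
    nid, sorient = sidx.steps[step]
    occ = tidx.occurrences.get(nid)
    if occ is None or len(occ) != 1:
        return None
    node_len = len(graph.nodes[nid])
    off = pos - sidx.starts[step]
    fwd_off = off if sorient == "+" else node_len - 1 - off
    tstep = occ[0]
    _, torient = tidx.steps[tstep]
    toff = fwd_off if torient == "+" else node_len - 1 - fwd_off
    return tidx.starts[tstep] + toff


def project_interval(
    graph: SequenceGraph, interval: PathInterval, target: str
) -> PathInterval | None:
    """Project a half-open interval by mapping both end bases.

    Returns ``None`` when either endpoint does not project.  The result is
    normalized (start < end) so it is valid when the target path traverses
    the region in the opposite orientation.
    """
    a = project_position(graph, interval.path_name, interval.start, target)
    b = project_position(graph, interval.path_name, interval.end - 1, target)
    if a is None or b is None:
        return None
    lo, hi = (a, b) if a <= b else (b, a)
    return PathInterval(target, lo, hi + 1)


def extract_path_variants(
    graph: SequenceGraph, path_a: str, path_b: str
) -> list[PathVariant]:
    """Pairwise bubble deconstruction between two haplotype paths.

    Nodes occurring exactly once on both paths act as anchors; maximal
    runs of steps between consecutive anchors become variant records.
    Bubbles whose interior still contains nodes shared by both paths
    (nested variation) are reported as OTHER rather than decomposed.
    Sites where both alleles are identical are discarded.
    """
    aidx = graph._index(path_a)
    bidx = graph._index(path_b)
    anchors = [
        (i, bidx.occurrences[nid][0])
        for i, (nid, _o) in enumerate(aidx.steps)
        if len(aidx.occurrences[nid]) == 1
        and len(bidx.occurrences.get(nid, ())) == 1
    ]
    if not anchors:
        raise ValueError(f"paths {path_a!r} and {path_b!r} share no anchor nodes")
    # keep anchors collinear on both paths (greedy increasing b-index)
    collinear: list[tuple[int, int]] = []
    last_b = -1
    for ia, ib in anchors:
        if ib > last_b:
            collinear.append((ia, ib))
            last_b = ib

    def _allele(idx: _PathIndex, lo: int, hi: int) -> str:
        parts = []
        for nid, orient in idx.steps[lo + 1 : hi]:
            seq = graph.nodes[nid]
            parts.append(seq if orient == "+" else reverse_complement(seq))
        return "".join(parts)

    variants: list[PathVariant] = []
    bnodes = set(bidx.occurrences)
    for (a0, b0), (a1, b1) in itertools.pairwise(collinear):
        if a1 == a0 + 1 and b1 == b0 + 1:
            continue
        allele_a = _allele(aidx, a0, a1)
        allele_b = _allele(bidx, b0, b1)
        if allele_a == allele_b:
            continue  # same genotype on both paths
        interior_shared = any(
            nid in bnodes for nid, _o in aidx.steps[a0 + 1 : a1]
        )
        la, lb = len(allele_a), len(allele_b)
        if interior_shared:
            vtype, length = "OTHER", max(la, lb)
        elif la == lb == 1:
            vtype, length = "SNP", 1
        elif la != lb:
            vtype, length = "INDEL", abs(la - lb)
        else:
            vtype, length = "MNP", la
        anchor_node_a, _ = aidx.steps[a0]
        pos_a = aidx.starts[a0] + len(graph.nodes[anchor_node_a])
        anchor_node_b, _ = bidx.steps[b0]
        pos_b = bidx.starts[b0] + len(graph.nodes[anchor_node_b])
        variants.append(
            PathVariant(path_a, path_b, pos_a, pos_b, allele_a, allele_b, vtype, length)
        )
    return variants
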