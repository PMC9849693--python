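"""Protein structure networks and EF-hand communication robustness.

A trajectory's non-bonded contacts (H-bonds, electrostatic and
hydrophobic interactions) are condensed into a static graph: residues
are nodes, and a pair becomes an edge when its interaction persists in
at least a fraction pT of the frames.  pT itself is chosen from the
dissolution profile of the largest hydrophobic cluster.  On the
resulting network, hub degree and the Communication Robustness (CR)
index between the four EF-hand Ca²⁺-binding loops — represented by
their bidentate glutamates E31 (EF1), E67 (EF2), E104 (EF3) and
E140 (EF4) — quantify how mutations rewire allosteric communication.

Residue identifiers use mature-protein numbering (no initiator Met);
peptide nodes carry channel numbering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

INTERACTION_CLASSES = ("hbond", "electrostatic", "hydrophobic")

#: Bidentate glutamate representing each EF-hand Ca²⁺-binding loop.
DEFAULT_EF_MAP = {"EF1": "E31", "EF2": "E67", "EF3": "E104", "EF4": "E140"}

#: CR at or above this is deemed robust communication.
CR_ROBUST_THRESHOLD = 0.1

#: pT used when the hydrophobic-cluster curve gives no usable knee.
DEFAULT_PT = 0.2


@dataclass(frozen=True)
class InteractionRecord:
    """One frame-wise non-bonded contact between two residues."""

    frame: int
    residue_i: str
    residue_j: str
    interaction_class: str

    def __post_init__(self) -> None:
        if self.residue_i == self.residue_j:
            raise ValueError("self-interactions are not allowed")
        if self.interaction_class not in INTERACTION_CLASSES:
            raise ValueError(f"unknown interaction class {self.interaction_class!r}")
        # canonical unordered storage
        a, b = sorted((self.residue_i, self.residue_j))
        object.__setattr__(self, "residue_i", a)
        object.__setattr__(self, "residue_j", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.residue_i, self.residue_j)


@dataclass(frozen=True)
class PersistenceMatrix:
    """Fraction of frames each residue pair interacts, per class.

    ``values`` maps interaction class → {(i, j): fraction in [0, 1]}
    with pairs stored canonically (i < j).
    """

    values: dict[str, dict[tuple[str, str], float]]
    n_frames: int

    def __post_init__(self) -> None:
        for cls, pairs in self.values.items():
            for (i, j), p in pairs.items():
                if i >= j:
                    raise ValueError(f"pair {(i, j)} not canonical")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"persistence {p} outside [0, 1]")

    def merged(self, how: str = "max") -> dict[tuple[str, str], float]:
        """Collapse interaction classes into one persistence per pair."""
        out: dict[tuple[str, str], float] = {}
        for pairs in self.values.values():
            for pair, p in pairs.items():
                if how == "max":
                    out[pair] = max(out.get(pair, 0.0), p)
                elif how == "sum":
                    out[pair] = min(out.get(pair, 0.0) + p, 1.0)
                else:
                    raise ValueError(f"unknown merge mode {how!r}")
        return out

    def only(self, interaction_class: str) -> "PersistenceMatrix":
        return PersistenceMatrix(
            values={interaction_class: dict(self.values.get(interaction_class, {}))},
            n_frames=self.n_frames)

    def to_frame(self) -> pd.DataFrame:
        rows = [(cls, i, j, p)
                for cls, pairs in self.values.items()
                for (i, j), p in sorted(pairs.items())]
        return pd.DataFrame(rows, columns=["class", "residue_i", "residue_j",
                                           "persistence"])


def persistence_from_records(records, n_frames: int) -> PersistenceMatrix:
    """Per-pair occupancy fraction from frame-wise interaction records.

    Duplicate records for the same (pair, class, frame) count once.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    seen: dict[str, dict[tuple[str, str], set[int]]] = {}
    for rec in records:
        if not 0 <= rec.frame < n_frames:
            raise ValueError(f"frame index {rec.frame} out of range [0, {n_frames})")
        seen.setdefault(rec.interaction_class, {}).setdefault(rec.pair, set()).add(rec.frame)
    values = {cls: {pair: len(frames) / n_frames for pair, frames in pairs.items()}
              for cls, pairs in seen.items()}
    return PersistenceMatrix(values=values, n_frames=n_frames)


def largest_cluster_profile(hydrophobic: PersistenceMatrix,
                            grid) -> list[tuple[float, int]]:
    """Size of the largest hydrophobic connected component at each pT."""
    pairs = hydrophobic.merged("max")
    profile = []
    for pt in grid:
        g = nx.Graph((i, j) for (i, j), p in pairs.items() if p >= pt)
        size = max((len(c) for c in nx.connected_components(g)), default=0)
        profile.append((float(pt), size))
    return profile


def select_pt(hydrophobic: PersistenceMatrix, scan_grid=None) -> float:
    """Persistence threshold from the hydrophobic-cluster dissolution knee.

    Scans pT over the grid, tracking the size of the largest connected
    component of the hydrophobic-only network, and returns the grid
    point just before the steepest drop of that curve (ties resolve to
    the smaller pT, keeping the network more inclusive).  A flat curve
    falls back to 0.2 with a warning.
    """
    if scan_grid is None:
        scan_grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
    grid = np.asarray(sorted(scan_grid), dtype=float)
    if grid.size < 10:
        raise ValueError("scan grid needs at least 10 points")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("scan grid must lie strictly inside (0, 1)")

    pairs = hydrophobic.merged("max")
    if not pairs:
        warnings.warn("empty hydrophobic network; falling back to pT = "
                      f"{DEFAULT_PT}", RuntimeWarning, stacklevel=2)
        return DEFAULT_PT

    profile = largest_cluster_profile(hydrophobic, grid)
    sizes = np.array([s for _, s in profile])
    drops = sizes[:-1] - sizes[1:]
    if drops.size == 0 or drops.max() <= 0:
        warnings.warn("flat hydrophobic-cluster curve; falling back to pT = "
                      f"{DEFAULT_PT}", RuntimeWarning, stacklevel=2)
        return DEFAULT_PT
    knee = int(np.argmax(drops))  # argmax takes the first (smallest pT) on ties
    return float(grid[knee])


@dataclass(frozen=True)
class PSNGraph:
    """Persistence-filtered residue interaction network."""

    graph: nx.Graph
    pt: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pt < 1.0:
            raise ValueError("pt must lie in (0, 1)")
        for _, _, data in self.graph.edges(data=True):
            if data.get("persistence", 1.0) < self.pt:
                raise ValueError("edge below the persistence threshold")

    @property
    def nodes(self):
        return self.graph.nodes

    def degree(self, node=None):
        return self.graph.degree(node) if node is not None else dict(self.graph.degree())


def build_psn(persistence: PersistenceMatrix, pt: float,
              merge: str = "max", extra_nodes=()) -> PSNGraph:
    """Graph with an edge wherever merged persistence ≥ pT.

    Interaction classes merge by maximum persistence by default
    (``merge="sum"`` caps the sum at 1).  ``extra_nodes`` adds known
    residues that end up isolated, so path queries on them return
    "disconnected" rather than "unknown".
    """
    if not 0.0 < pt < 1.0:
        raise ValueError("pt must lie in (0, 1)")
    merged = persistence.merged(merge)
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    for (i, j), p in merged.items():
        g.add_node(i)
        g.add_node(j)
        if p >= pt:
            g.add_edge(i, j, persistence=p)
    return PSNGraph(graph=g, pt=pt)


def hubs(psn: PSNGraph, min_degree: int = 4) -> dict[str, int]:
    """Nodes with strictly more than ``min_degree`` edges, with degrees."""
    return {n: d for n, d in psn.graph.degree() if d > min_degree}


def report_hubs(psns: list[PSNGraph], report_degree: int = 6) -> set[str]:
    """Comparative reporting set: nodes reaching ``report_degree`` in ≥1 graph."""
    out: set[str] = set()
    for psn in psns:
        out.update(n for n, d in psn.graph.degree() if d >= report_degree)
    return out


def delta_degree(variant_psn: PSNGraph, wt_psn: PSNGraph,
                 node_set=None) -> tuple[dict[str, int], int]:
    """Per-node and total degree change, variant − WT.

    Nodes absent from one graph count as degree 0 (with a notice).
    """
    if node_set is None:
        node_set = set(variant_psn.graph.nodes) | set(wt_psn.graph.nodes)
    per_node: dict[str, int] = {}
    for node in node_set:
        missing = []
        if node not in variant_psn.graph:
            missing.append("variant")
        if node not in wt_psn.graph:
            missing.append("WT")
        if missing:
            warnings.warn(f"node {node!r} absent from {'/'.join(missing)} graph; "
                          "treated as degree 0", RuntimeWarning, stacklevel=2)
        dv = variant_psn.graph.degree(node) if node in variant_psn.graph else 0
        dw = wt_psn.graph.degree(node) if node in wt_psn.graph else 0
        per_node[node] = dv - dw
    return per_node, sum(per_node.values())


def shortest_paths(psn: PSNGraph, x: str, y: str
                   ) -> tuple[float, int, list[list[str]]]:
    """Unweighted shortest-path length l, count n_XY, and the paths.

    Counts distinct shortest *node sequences* between x and y.  A
    disconnected pair returns (inf, 0, []).
    """
    g = psn.graph
    for node in (x, y):
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
    if x == y:
        raise ValueError("x and y must differ")
    if not nx.has_path(g, x, y):
        return math.inf, 0, []
    paths = list(nx.all_shortest_paths(g, x, y))
    return float(len(paths[0]) - 1), len(paths), paths


def cr_index(psn: PSNGraph, x: str, y: str, form: str = "n_pt_over_l") -> float:
    """Communication Robustness between two residues.

    Combines the number n of shortest paths, their length l and the
    persistence threshold pT of the network.  ``n_pt_over_l`` (default)
    evaluates (n·pT)/l; ``n_pt_pow_l`` evaluates n·pT^l.  Disconnected
    pairs score 0.
    """
    l, n, _ = shortest_paths(psn, x, y)
    if n == 0:
        return 0.0
    if form == "n_pt_over_l":
        return n * psn.pt / l
    if form == "n_pt_pow_l":
        return n * psn.pt ** l
    raise ValueError(f"unknown CR form {form!r}")


@dataclass(frozen=True)
class CRMatrix:
    """Pairwise CR between EF-hand representative residues."""

    values: pd.DataFrame  # symmetric, EF labels as index/columns
    pt: float
    form: str
    robust_threshold: float = CR_ROBUST_THRESHOLD

    @property
    def robust(self) -> pd.DataFrame:
        return self.values >= self.robust_threshold

    def pair(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def is_robust(self, a: str, b: str) -> bool:
        return bool(self.robust.loc[a, b])


def ef_hand_cr(psn: PSNGraph, ef_map: dict[str, str] | None = None,
               form: str = "n_pt_over_l",
               robust_threshold: float = CR_ROBUST_THRESHOLD) -> CRMatrix:
    """CR matrix over all six EF-hand pairs, with robustness flags.

    Pairs at CR ≥ ``robust_threshold`` (default 0.1) are flagged as
    supporting robust intramolecular communication.
    """
    ef_map = dict(DEFAULT_EF_MAP if ef_map is None else ef_map)
    for ef, node in ef_map.items():
        if node not in psn.graph:
            raise KeyError(f"EF-hand representative {node!r} ({ef}) not in graph")
    labels = list(ef_map)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            cr = cr_index(psn, ef_map[a], ef_map[b], form=form)
            mat.loc[a, b] = mat.loc[b, a] = cr
    return CRMatrix(values=mat, pt=psn.pt, form=form,
                    robust_threshold=robust_threshold)
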