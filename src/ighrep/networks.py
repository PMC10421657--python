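"""Hamming-distance similarity networks over CDR3 amino-acid sequences.

Nodes are (sample, CDR3-aa) pairs; two nodes are connected when their
sequences have equal length and Hamming distance at most ``max_distance``
(distance 0 links identical sequences shared by different samples —
sequences of unequal length are never compared). Connected components are
the candidate clonal clusters; a component is *relevant* when it spans at
least ``min_samples`` distinct samples (optionally counted within a
restriction set, e.g. patients only), and *patient-exclusive* when every
member node comes from a patient group. Each component carries a
position-frequency matrix and consensus string (one vote per node,
per-position argmax, alphabetical tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .records import AA_ALPHABET, PATIENT_GROUPS, Cohort


def hamming(seq_a: str, seq_b: str) -> Optional[int]:
    """Positionwise mismatch count; None (no edge) for unequal lengths."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) != len(seq_b):
        return None
    return sum(a != b for a, b in zip(seq_a, seq_b))


@dataclass
class NetworkComponent:
    nodes: Tuple[Tuple[str, str], ...]  # (sample_id, cdr3_aa)
    sample_set: frozenset
    group_set: frozenset
    cdr3_length: int
    exclusivity: str  # "patient_exclusive" | "mixed"
    consensus: str
    pfm: pd.DataFrame  # positions x residues, rows sum to 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class ClonalNetwork:
    graph: nx.Graph
    isotype: str
    max_distance: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def components(self) -> List[NetworkComponent]:
        out = [
            _make_component(self.graph, nodes)
            for nodes in nx.connected_components(self.graph)
        ]
        # deterministic report order: size desc, then lexicographic first node
        out.sort(key=lambda c: (-c.n_nodes, c.nodes[0]))
        return out

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_a": a[0], "cdr3_a": a[1],
                "sample_b": b[0], "cdr3_b": b[1],
                "distance": d,
            }
            for a, b, d in sorted(
                (tuple(sorted((u, v))) + (w["distance"],) for u, v, w in self.graph.edges(data=True))
            )
        ]
        return pd.DataFrame(rows, columns=["sample_a", "cdr3_a", "sample_b", "cdr3_b", "distance"])


def consensus_matrix(sequences: Iterable[str]) -> Tuple[str, pd.DataFrame]:
    """Position-frequency matrix and consensus of equal-length sequences.

    One vote per sequence; the consensus letter at each position is the
    most frequent residue, ties broken alphabetically.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((L, len(AA_ALPHABET)))
    index = {a: i for i, a in enumerate(AA_ALPHABET)}
    for s in seqs:
        for pos, ch in enumerate(s):
            counts[pos, index[ch]] += 1
    pfm = pd.DataFrame(counts / len(seqs), columns=list(AA_ALPHABET))
    pfm.index.name = "position"
    # argmax over alphabetical column order breaks ties alphabetically
    consensus = "".join(AA_ALPHABET[i] for i in np.argmax(pfm.to_numpy(), axis=1))
    return consensus, pfm


def _make_component(graph: nx.Graph, node_set) -> NetworkComponent:
    nodes = tuple(sorted(node_set))
    lengths = {len(seq) for _, seq in nodes}
    assert len(lengths) == 1, "components must be length-homogeneous"
    samples = frozenset(s for s, _ in nodes)
    groups = frozenset(graph.nodes[n]["group"] for n in nodes)
    exclusivity = (
        "patient_exclusive" if groups <= set(PATIENT_GROUPS) else "mixed"
    )
    cons, pfm = consensus_matrix([seq for _, seq in nodes])
    return NetworkComponent(
        nodes=nodes,
        sample_set=samples,
        group_set=groups,
        cdr3_length=lengths.pop(),
        exclusivity=exclusivity,
        consensus=cons,
        pfm=pfm,
    )


def _pairwise_edges(seq_arr: np.ndarray, max_distance: int) -> List[Tuple[int, int, int]]:
    """All index pairs with Hamming distance <= max_distance (equal-length block)."""
    k = seq_arr.shape[0]
    edges = []
    chunk = max(1, int(2_000_000 // max(1, k * seq_arr.shape[1])))
    for start in range(0, k, chunk):
        block = seq_arr[start : start + chunk]
        dist = (block[:, None, :] != seq_arr[None, :, :]).sum(axis=2)
        for bi, j in zip(*np.where(dist <= max_distance)):
            i = start + int(bi)
            if i < j:
                edges.append((i, int(j), int(dist[bi, j])))
    return edges


def build_network(
    cohort: Cohort,
    isotype: str = "IGHG",
    max_distance: int = 2,
    sample_ids: Optional[Iterable[str]] = None,
) -> ClonalNetwork:
    """Build the clonal similarity network for one isotype.

    One node per (sample, unique CDR3-aa); edges between equal-length
    sequences with Hamming distance <= ``max_distance``. ``sample_ids``
    restricts which samples contribute nodes (e.g. the endemic area only).
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    wanted = set(sample_ids) if sample_ids is not None else None
    graph = nx.Graph()
    node_info: List[Tuple[str, str]] = []
    for s in cohort.by_isotype(isotype):
        if wanted is not None and s.sample_id not in wanted:
            continue
        freq = s.df.groupby("cdr3_aa")["frequency"].sum()
        for seq, f in freq.items():
            node = (s.sample_id, seq)
            graph.add_node(node, group=s.group, frequency=float(f))
            node_info.append(node)

    by_length: Dict[int, List[Tuple[str, str]]] = {}
    for node in node_info:
        by_length.setdefault(len(node[1]), []).append(node)
    for length, nodes in by_length.items():
        nodes = sorted(nodes)
        arr = np.frombuffer(
            "".join(seq for _, seq in nodes).encode("ascii"), dtype=np.uint8
        ).reshape(len(nodes), length)
        for i, j, d in _pairwise_edges(arr, max_distance):
            graph.add_edge(nodes[i], nodes[j], distance=d)
    return ClonalNetwork(graph, isotype, max_distance)


def extract_relevant(
    network: ClonalNetwork,
    min_samples: int = 4,
    restrict_to: Optional[Iterable[str]] = None,
) -> List[NetworkComponent]:
    """Components spanning >= ``min_samples`` distinct samples.

    When ``restrict_to`` is given only samples in that set are counted
    toward the threshold (e.g. count patients only); membership and
    exclusivity still reflect every node in the component.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    restrict = set(restrict_to) if restrict_to is not None else None
    out = []
    for comp in network.components():
        counted = comp.sample_set if restrict is None else comp.sample_set & restrict
        if len(counted) >= min_samples:
            out.append(comp)
    return out


def component_report(components: List[NetworkComponent]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(components):
        rows.append(
            {
                "component_id": i,
                "cdr3_length": c.cdr3_length,
                "n_nodes": c.n_nodes,
                "n_samples": len(c.sample_set),
                "samples": ",".join(sorted(c.sample_set)),
                "groups": ",".join(sorted(c.group_set)),
                "exclusivity": c.exclusivity,
                "consensus": c.consensus,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "component_id", "cdr3_length", "n_nodes", "n_samples",
            "samples", "groups", "exclusivity", "consensus",
        ],
    )
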