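"""Alpha and beta diversity of CDR3 repertoires on a phylogenetic substrate.

The tree over CDR3 amino-acid sequences is built internally from pairwise
normalized edit distances (unit-cost global alignment) by neighbor joining,
rooted at the midpoint of the longest leaf-to-leaf path; an externally
inferred newick tree can be supplied instead wherever a tree is accepted.

Alpha diversity: Shannon entropy of clonotype frequencies (in nats) and
Faith's phylogenetic diversity (root-inclusive: the branch length of the
minimal subtree connecting the observed leaves and the root). Beta
diversity: normalized weighted UniFrac between per-sample abundance
vectors mapped onto a pooled per-isotype tree, embedded by classical PCoA
and tested with PERMANOVA under label permutation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import inf, lgamma
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .airr_io import filter_by_frequency
from .records import _AA_SET, Cohort, RepertoireSample
from .tree import PhyloTree, midpoint_root


# ---------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="label"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy(float))


def pairwise_cdr3_distance(sequences: Sequence[str]) -> DistanceMatrix:
    """Normalized global-alignment edit distance between CDR3 sequences.

    d(i, j) = (unit-cost Needleman-Wunsch distance) / max(len_i, len_j),
    so d is in [0, 1] with d(i, i) = 0. Sequences must be unique (they
    label the matrix) and drawn from the 20-letter amino-acid alphabet.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    if len(set(seqs)) != len(seqs):
        raise ValueError("sequences must be unique to label a distance matrix")
    for i, s in enumerate(seqs):
        for pos, ch in enumerate(s):
            if ch not in _AA_SET:
                raise ValueError(
                    f"invalid residue {ch!r} at position {pos} of sequence {i} ({s!r})"
                )
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], task="distance")["editDistance"]
            values[i, j] = values[j, i] = d / max(len(seqs[i]), len(seqs[j]))
    return DistanceMatrix(tuple(seqs), values)


# ---------------------------------------------------------------------------
# neighbor joining

def build_nj_tree(distances: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining, midpoint-rooted.

    Negative branch-length estimates are clamped to zero with the deficit
    moved onto the sibling edge (the pair's total d(i, j) is preserved).
    Requires at least three labels; for fewer, connect the leaves directly
    to a star-center root instead.
    """
    n = len(distances.labels)
    if n < 3:
        raise ValueError(
            "neighbor joining needs >= 3 labels; build a trivial star tree instead"
        )
    D = distances.values.astype(float).copy()
    nodes: List[object] = list(distances.labels)
    edges: List[tuple] = []
    next_internal = itertools.count()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        if lj < 0:
            li, lj = D[i, j], 0.0
        new_id = ("_nj", next(next_internal))
        edges.append((new_id, nodes[i], li))
        edges.append((new_id, nodes[j], lj))
        d_new = np.maximum(0.0, 0.5 * (D[i, :] + D[j, :] - D[i, j]))
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new_id]

    # three-point termination
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = ("_nj", next(next_internal))
    edges.append((center, a, max(0.0, (dab + dac - dbc) / 2.0)))
    edges.append((center, b, max(0.0, (dab + dbc - dac) / 2.0)))
    edges.append((center, c, max(0.0, (dac + dbc - dab) / 2.0)))

    return midpoint_root(edges, list(distances.labels))


# ---------------------------------------------------------------------------
# alpha diversity

def shannon_index(sample: RepertoireSample) -> float:
    """Shannon entropy of clonotype frequencies, in nats."""
    f = sample.frequencies
    if len(f) == 0:
        warnings.warn(f"empty repertoire {sample.key}; Shannon index 0", stacklevel=2)
        return 0.0
    f = f / f.sum()
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def faith_pd(tree: PhyloTree, observed_leaves: Iterable[str]) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    The sum of branch lengths of the minimal subtree spanning the observed
    leaves *and* the root, so a single observed leaf contributes its full
    root-to-leaf path.
    """
    observed = set(observed_leaves)
    if not observed:
        raise ValueError("observed_leaves must be non-empty")
    names = set(tree.leaf_names)
    unknown = observed - names
    if unknown:
        raise KeyError(f"leaf label(s) not in tree: {sorted(unknown)[:5]}")
    keep: Dict[int, bool] = {}
    total = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            keep[id(node)] = node.name in observed
        else:
            keep[id(node)] = any(keep[id(c)] for c in node.children)
        if node is not tree.root and keep[id(node)]:
            total += node.length
    return total


def weighted_unifrac(
    tree: PhyloTree,
    abundance_a: Dict[str, float],
    abundance_b: Dict[str, float],
) -> float:
    """Normalized weighted UniFrac between two leaf-abundance vectors.

    u = sum_b l_b |p_A(b) - p_B(b)| over branches, scaled by
    sum_j d_j (p_Aj + p_Bj) with d_j the root-to-leaf distance, so u is in
    [0, 1]. Abundances must each sum to 1 over the tree's leaves (missing
    leaves count as zero).
    """
    names = set(tree.leaf_names)
    for label, abund in (("a", abundance_a), ("b", abundance_b)):
        unknown = set(abund) - names
        if unknown:
            raise KeyError(f"abundance_{label} has labels not in tree: {sorted(unknown)[:5]}")
        if any(v < 0 for v in abund.values()):
            raise ValueError(f"abundance_{label} has negative entries")
        total = sum(abund.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance_{label} sums to {total}, expected 1")

    pa: Dict[int, float] = {}
    pb: Dict[int, float] = {}
    numerator = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            pa[id(node)] = abundance_a.get(node.name, 0.0)
            pb[id(node)] = abundance_b.get(node.name, 0.0)
        else:
            pa[id(node)] = sum(pa[id(c)] for c in node.children)
            pb[id(node)] = sum(pb[id(c)] for c in node.children)
        if node is not tree.root:
            numerator += node.length * abs(pa[id(node)] - pb[id(node)])

    depths = tree.leaf_depths()
    scale = sum(
        d * (abundance_a.get(name, 0.0) + abundance_b.get(name, 0.0))
        for name, d in depths.items()
    )
    if scale == 0.0:
        # all observed mass sits at zero distance from the root
        return 0.0
    return numerator / scale


# ---------------------------------------------------------------------------
# ordination and PERMANOVA

@dataclass
class PCoAResult:
    labels: Tuple[str, ...]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(distances: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical (Gower) principal coordinate analysis.

    Eigendecomposition of the double-centered squared-distance matrix;
    axes are ordered by descending eigenvalue, negative eigenvalues are
    reported but their axes dropped, and each axis has a deterministic
    sign (largest-magnitude coordinate positive).
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    D2 = distances.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, abs(eigval[0]) if n else 1.0)
    positive = eigval > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
    k = min(n_axes, n_pos)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for ax in range(k):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    pos_sum = eigval[positive].sum()
    prop = eigval[:n_pos] / pos_sum if pos_sum > 0 else np.zeros(n_pos)
    return PCoAResult(distances.labels, coords, eigval, prop)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "exhaustive" or "sampled"


def _log_multinomial(counts: Sequence[int]) -> float:
    n = sum(counts)
    return lgamma(n + 1) - sum(lgamma(c + 1) for c in counts)


def _multiset_permutations(codes: np.ndarray):
    """All distinct permutations of a code array, lexicographic order."""
    arr = sorted(codes.tolist())
    n = len(arr)
    while True:
        yield np.array(arr)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and arr[i] >= arr[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while arr[j] <= arr[i]:
            j -= 1
        arr[i], arr[j] = arr[j], arr[i]
        arr[i + 1:] = reversed(arr[i + 1:])


def _permanova_f_batch(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for each row of a (P x N) label-code matrix."""
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = np.zeros(codes.shape[0])
    for g in range(n_groups):
        mask = (codes == g).astype(float)
        n_g = mask.sum(axis=1)
        quad = np.einsum("pi,ij,pj->p", mask, D2, mask) / 2.0
        ss_within += quad / n_g
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    f[ss_within == 0] = inf
    return f


def permanova(
    distances: DistanceMatrix,
    grouping: Dict[str, str],
    n_permutations: int = 99999,
    seed: int = 0,
    method: str = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) under label permutation.

    With ``method="auto"``, when the number of distinct label permutations
    is at most ``n_permutations`` the null distribution is enumerated
    exhaustively (p = fraction of distinct labelings, including the observed
    one, with F >= F_obs); otherwise ``n_permutations`` random permutations
    are drawn and p uses the (1 + hits) / (1 + permutations) correction.
    ``method="exhaustive"`` / ``"sampled"`` force one path.
    """
    if method not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    labels = distances.labels
    missing = [l for l in labels if l not in grouping]
    if missing:
        raise KeyError(f"grouping missing labels {missing[:5]}")
    group_names = sorted(set(grouping[l] for l in labels))
    if len(group_names) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    codes = np.array([group_names.index(grouping[l]) for l in labels])
    counts = [int((codes == g).sum()) for g in range(len(group_names))]
    if min(counts) < 2:
        raise ValueError("every group needs at least two samples")
    D2 = distances.values ** 2
    if D2.sum() == 0:
        raise ValueError("all distances are zero; pseudo-F undefined")

    f_obs = float(_permanova_f_batch(D2, codes[None, :], len(group_names))[0])

    log_distinct = _log_multinomial(counts)
    exhaustive = method == "exhaustive" or (
        method == "auto" and log_distinct <= np.log(max(n_permutations, 1)) + 1e-12
    )
    if exhaustive:
        if _log_multinomial(counts) > np.log(5e6):
            raise ValueError("too many distinct permutations to enumerate exhaustively")
        perms = np.array(list(_multiset_permutations(codes)))
        f_perm = _permanova_f_batch(D2, perms, len(group_names))
        p = float((f_perm >= f_obs - 1e-12).mean())
        return PermanovaResult(f_obs, p, len(perms), "exhaustive")

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 20000
    done = 0
    while done < n_permutations:
        size = min(chunk, n_permutations - done)
        perm_codes = np.array([rng.permutation(codes) for _ in range(size)])
        f_perm = _permanova_f_batch(D2, perm_codes, len(group_names))
        hits += int((f_perm >= f_obs - 1e-12).sum())
        done += size
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(f_obs, float(p), n_permutations, "sampled")


# ---------------------------------------------------------------------------
# cohort-level drivers

def weighted_unifrac_matrix(
    tree: PhyloTree,
    abundances: Sequence[Dict[str, float]],
) -> np.ndarray:
    """Pairwise normalized weighted UniFrac for many abundance vectors.

    Equivalent to calling :func:`weighted_unifrac` on every pair but with
    the branch-wise descendant masses accumulated once per sample.
    """
    nodes = [n for n in tree.postorder()]
    index = {id(n): i for i, n in enumerate(nodes)}
    lengths = np.array([n.length if n is not tree.root else 0.0 for n in nodes])
    k = len(abundances)
    P = np.zeros((k, len(nodes)))
    for si, abund in enumerate(abundances):
        total = sum(abund.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance {si} sums to {total}, expected 1")
        for node in nodes:
            i = index[id(node)]
            if node.is_leaf:
                P[si, i] = abund.get(node.name, 0.0)
            else:
                P[si, i] = sum(P[si, index[id(c)]] for c in node.children)
    depths = tree.leaf_depths()
    leaf_depth = np.array(
        [depths[n.name] if n.is_leaf else 0.0 for n in nodes]
    )
    is_leaf = np.array([n.is_leaf for n in nodes])
    per_sample_depth = (P[:, is_leaf] * leaf_depth[is_leaf]).sum(axis=1)
    out = np.zeros((k, k))
    for i in range(k):
        diff = np.abs(P[i] - P[i + 1:]) @ lengths
        scale = per_sample_depth[i] + per_sample_depth[i + 1:]
        vals = np.divide(diff, scale, out=np.zeros_like(diff), where=scale > 0)
        out[i, i + 1:] = vals
        out[i + 1:, i] = vals
    return out


def _sample_abundance(sample: RepertoireSample) -> Dict[str, float]:
    """Per-CDR3-aa abundance (frequencies summed over V/J variants), renormalized."""
    agg = sample.df.groupby("cdr3_aa")["frequency"].sum()
    total = float(agg.sum())
    return {seq: float(v) / total for seq, v in agg.items()}


def pooled_cdr3_tree(samples: Sequence[RepertoireSample]) -> PhyloTree:
    """Neighbor-joining tree over the pooled unique CDR3 set of the samples."""
    pooled = sorted({seq for s in samples for seq in s.df["cdr3_aa"]})
    if len(pooled) < 3:
        raise ValueError("need at least 3 distinct CDR3 sequences to build a tree")
    return build_nj_tree(pairwise_cdr3_distance(pooled))


def alpha_diversity(
    cohort: Cohort,
    isotype: str,
    tree: Optional[PhyloTree] = None,
) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Faith's PD for one isotype.

    Faith's PD is evaluated against a pooled per-isotype tree (built
    internally unless an external tree covering every CDR3 is supplied).
    """
    samples = cohort.by_isotype(isotype)
    if not samples:
        raise ValueError(f"no samples with isotype {isotype}")
    if tree is None:
        tree = pooled_cdr3_tree(samples)
    rows = []
    for s in samples:
        observed = set(s.df["cdr3_aa"])
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "isotype": isotype,
                "metric": "shannon",
                "value": shannon_index(s),
            }
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "isotype": isotype,
                "metric": "faith_pd",
                "value": faith_pd(tree, observed),
            }
        )
    return pd.DataFrame(rows)


def beta_diversity(
    cohort: Cohort,
    isotype: str,
    min_frequency: Optional[float] = None,
    tree: Optional[PhyloTree] = None,
) -> Tuple[DistanceMatrix, PhyloTree]:
    """Weighted-UniFrac distance matrix between samples of one isotype.

    Clonotypes are optionally filtered to frequency > ``min_frequency``
    first (the IGHG convention; IGHM uses all clonotypes), the retained
    frequencies are renormalized per sample, and every sample's abundance
    vector is mapped onto the shared pooled tree (absent leaves get zero).
    """
    samples = cohort.by_isotype(isotype)
    if min_frequency is not None:
        samples = [filter_by_frequency(s, min_frequency, renormalize=True) for s in samples]
        samples = [s for s in samples if s.n_clonotypes > 0]
    if len(samples) < 2:
        raise ValueError("beta diversity needs at least two non-empty samples")
    if tree is None:
        tree = pooled_cdr3_tree(samples)
    abundances = [_sample_abundance(s) for s in samples]
    ids = [s.sample_id for s in samples]
    values = weighted_unifrac_matrix(tree, abundances)
    return DistanceMatrix(tuple(ids), values), tree
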