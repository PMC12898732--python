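"""Barcode phylogenetic cross-validation.

Pairwise distances (p-distance or Kimura two-parameter), neighbor-
joining tree construction with deterministic tie-breaking, column-
resampling bootstrap supports, and clade-membership checks. K2P is the
default distance, the convention for plant barcoding loci; columns with
gaps or ambiguity codes are excluded pairwise.

Trees are Bio.Phylo objects so they serialize to Newick directly;
bootstrap supports land on ``clade.confidence`` as integer percents.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "clade_check",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = {0, 2}


class DistanceMatrix:
    """Symmetric non-negative taxon distance matrix with zero diagonal."""

    def __init__(self, ids: Sequence[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        if d.shape != (len(ids), len(ids)):
            raise ValueError("distance matrix shape does not match taxon count")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        self.ids = list(ids)
        self.d = d

    def __len__(self) -> int:
        return len(self.ids)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, -1) for c in seq.upper()), dtype=np.int8,
                       count=len(seq))


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Transition/transversion proportions over pairwise-valid columns."""
    valid = (a >= 0) & (b >= 0)
    nvalid = int(valid.sum())
    if nvalid == 0:
        raise ValueError("no valid (gap- and ambiguity-free) columns shared by the pair")
    av, bv = a[valid], b[valid]
    diff = av != bv
    both_purine = np.isin(av, (0, 2)) & np.isin(bv, (0, 2))
    both_pyrimidine = np.isin(av, (1, 3)) & np.isin(bv, (1, 3))
    transitions = int((diff & (both_purine | both_pyrimidine)).sum())
    transversions = int(diff.sum()) - transitions
    return transitions / nvalid, transversions / nvalid, nvalid


def pairwise_distance(a: str, b: str, model: str = "k2p") -> float:
    """Evolutionary distance between two aligned sequences.

    ``p``: observed mismatch proportion. ``k2p``: Kimura's two-parameter
    correction, −½·ln((1−2P−Q)·√(1−2Q)) with transition proportion P
    and transversion proportion Q.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ea, eb = _encode(a), _encode(b)
    p_trs, q_trv, _ = _pq(ea, eb)
    if model == "p":
        return p_trs + q_trv
    if model.lower() == "k2p":
        w1 = 1.0 - 2.0 * p_trs - q_trv
        w2 = 1.0 - 2.0 * q_trv
        if w1 <= 0 or w2 <= 0:
            raise ValueError("K2P distance undefined: sequences too divergent (saturation)")
        return -0.5 * math.log(w1 * math.sqrt(w2))
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(
    ids: Sequence[str], seqs: Sequence[str], model: str = "k2p"
) -> DistanceMatrix:
    if len(ids) != len(seqs):
        raise ValueError("ids and sequences differ in number")
    enc = [_encode(s) for s in seqs]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p_trs, q_trv, _ = _pq(enc[i], enc[j])
        if model == "p":
            dist = p_trs + q_trv
        else:
            w1 = 1.0 - 2.0 * p_trs - q_trv
            w2 = 1.0 - 2.0 * q_trv
            if w1 <= 0 or w2 <= 0:
                raise ValueError(
                    f"K2P distance undefined for pair ({ids[i]}, {ids[j]}): saturation"
                )
            dist = -0.5 * math.log(w1 * math.sqrt(w2))
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion resolve to the smallest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit moved
    to the sister branch. The root is the final trifurcation (unrooted
    convention).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("nj_tree: need at least 3 taxa")
    nodes: list[Clade] = [Clade(name=taxon) for taxon in dm.ids]
    active = list(range(n))
    d = dm.d.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = Clade(clades=[nodes[i], nodes[j]])
        # Reuse slot i for the new node; distances by the reduction formula.
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].branch_length = max(la, 0.0)
    nodes[j].branch_length = max(lb, 0.0)
    nodes[k].branch_length = max(lc, 0.0)
    root = Clade(clades=[nodes[i], nodes[j], nodes[k]])
    return Tree(root=root, rooted=False)


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the leaf set on the
    side not containing the alphabetically first taxon."""
    leaves = frozenset(l.name for l in tree.get_terminals())
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        below = frozenset(l.name for l in clade.get_terminals())
        side = below if anchor not in below else leaves - below
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


def clade_check(tree: Tree, group_map: Mapping[str, set[str]]) -> dict[str, bool]:
    """Monophyly per group: true iff some edge separates exactly that taxon
    set (singletons are monophyletic by convention)."""
    leaves = frozenset(l.name for l in tree.get_terminals())
    for label, taxa in group_map.items():
        unknown = set(taxa) - leaves
        if unknown:
            raise ValueError(f"group {label!r} contains unknown taxa {sorted(unknown)}")
    anchor = min(leaves)
    splits = bipartitions(tree)
    out: dict[str, bool] = {}
    for label, taxa in group_map.items():
        taxa = frozenset(taxa)
        # Singletons, leaf-complements and the full leaf set are trivially
        # separated by an edge on any unrooted tree.
        if len(taxa) <= 1 or len(taxa) >= len(leaves) - 1:
            out[label] = True
            continue
        side = taxa if anchor not in taxa else leaves - taxa
        out[label] = side in splits
    return out


def bootstrap_support(
    ids: Sequence[str],
    seqs: Sequence[str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "k2p",
) -> Tree:
    """NJ tree from the full alignment with column-resampling bootstrap.

    Each replicate resamples alignment columns with replacement,
    rebuilds the NJ tree and records its bipartitions; supports are the
    percent of replicates containing each original bipartition,
    attached as integer ``clade.confidence``.
    """
    if len(ids) < 4:
        raise ValueError("bootstrap_support: need at least 4 taxa")
    if n_reps < 1:
        raise ValueError("bootstrap_support: n_reps must be >= 1")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned to equal length")
    ncol = lengths.pop()

    tree = nj_tree(distance_matrix(ids, seqs, model=model))
    original = bipartitions(tree)
    counts = {split: 0 for split in original}

    arr = np.stack([_encode(s) for s in seqs])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        sub = arr[:, cols]
        sub_seqs = ["".join("ACGT-"[c] if c >= 0 else "-" for c in row) for row in sub]
        try:
            rep_tree = nj_tree(distance_matrix(ids, sub_seqs, model=model))
        except ValueError:
            continue  # saturated/degenerate replicate contributes no support
        rep_splits = bipartitions(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    leaves = frozenset(ids)
    anchor = min(leaves)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        below = frozenset(l.name for l in clade.get_terminals())
        side = below if anchor not in below else leaves - below
        if side in counts:
            clade.confidence = int(round(100.0 * counts[side] / n_reps))
    return tree
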