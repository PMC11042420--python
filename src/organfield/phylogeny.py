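"""Hamming distances and maximum-parsimony clonal trees.

Samples are leaves; an extra leaf ``node0`` carries the all-zero ancestral
state and roots the tree. Characters are binary presence/absence calls and
are scored with Fitch's algorithm, bit-packed so all characters of a node
are processed in one big-integer operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .organ_io import VafMatrix

ROOT_NAME = "node0"


@dataclass
class CharacterMatrix:
    """Binary samples x mutations matrix (presence at a VAF threshold)."""

    matrix: np.ndarray
    sample_ids: list[str]
    mutation_ids: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (len(self.sample_ids), len(self.mutation_ids)):
            raise ValidationError("character matrix shape mismatch")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("character states must be 0/1")
        if self.matrix.shape[1] and (self.matrix.sum(axis=0) == 0).any():
            raise ValidationError("all-zero mutation columns must be dropped")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_characters(self) -> int:
        return self.matrix.shape[1]

    def row_bits(self) -> list[int]:
        """Pack each sample's characters into one big integer."""
        out = []
        for row in self.matrix:
            bits = 0
            for c in np.flatnonzero(row):
                bits |= 1 << int(c)
            out.append(bits)
        return out


@dataclass
class CladeTree:
    """Rooted clonal tree; ``node0`` is the all-zero ancestral root."""

    children: dict[str, list[str]]
    parent: dict[str, str]
    edge_changes: dict[str, int]  # changes on the edge above each non-root node
    score: int
    sample_ids: list[str]

    @property
    def nodes(self) -> list[str]:
        return [ROOT_NAME] + list(self.parent)

    def newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children.get(node, [])
            label = node if (node in self.sample_ids or node == ROOT_NAME) else ""
            inner = f"({','.join(rec(k) for k in kids)})" if kids else ""
            length = f":{self.edge_changes[node]}" if node in self.edge_changes else ""
            return f"{inner}{label}{length}"

        return rec(ROOT_NAME) + ";"


# ---------------------------------------------------------------------------
# character matrix construction
# ---------------------------------------------------------------------------


def binarize(vafs: VafMatrix, threshold: float = 0.01) -> CharacterMatrix:
    """Presence iff VAF >= threshold; all-absent mutation columns dropped."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    present = ((vafs.values >= threshold) & vafs.mask).T.astype(np.uint8)
    keep = present.sum(axis=0) > 0
    return CharacterMatrix(
        matrix=present[:, keep],
        sample_ids=list(vafs.field_ids),
        mutation_ids=[m for m, k in zip(vafs.mutation_ids, keep) if k],
        n_dropped=int((~keep).sum()),
    )


def hamming_matrix(chars: CharacterMatrix) -> pd.DataFrame:
    """Symmetric matrix of pairwise Hamming distances (character counts)."""
    if chars.n_samples < 2:
        raise ValidationError("need at least two samples")
    X = chars.matrix.astype(int)
    d = (X[:, None, :] != X[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=chars.sample_ids, columns=chars.sample_ids)


# ---------------------------------------------------------------------------
# Fitch machinery on unrooted trees (leaf 0 = ancestral all-zero "node0")
# ---------------------------------------------------------------------------
# Trees during search are adjacency dicts {node: [neighbours]} over leaf ids
# 0..L-1 and internal ids -1, -2, ...; leaf 0 is the all-zero root leaf.


def _leaf_sets(bits: int, mask: int) -> tuple[int, int]:
    return (~bits) & mask, bits


def _fitch_post(
    adj: dict[int, list[int]], node: int, parent: int, leaf_bits: dict[int, int], mask: int
) -> tuple[int, int, int]:
    """Return (zero_ok, one_ok, changes) for the subtree below ``node``."""
    kids = [n for n in adj[node] if n != parent]
    if not kids:
        A, B = _leaf_sets(leaf_bits[node], mask)
        return A, B, 0
    accA = accB = None
    changes = 0
    for k in kids:
        A2, B2, ch = _fitch_post(adj, k, node, leaf_bits, mask)
        changes += ch
        if accA is None:
            accA, accB = A2, B2
            continue
        IA, IB = accA & A2, accB & B2
        E = mask & ~(IA | IB)
        changes += E.bit_count()
        accA = IA | (E & (accA | A2))
        accB = IB | (E & (accB | B2))
    return accA, accB, changes


def _score_unrooted(adj: dict[int, list[int]], leaf_bits: dict[int, int], mask: int) -> int:
    """Parsimony score with leaf 0 fixed at the all-zero state."""
    neigh = adj[0][0]
    A, _B, changes = _fitch_post(adj, neigh, 0, leaf_bits, mask)
    return changes + (mask & ~A).bit_count()


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    out = []
    seen = set()
    for u, vs in adj.items():
        for v in vs:
            if (v, u) not in seen:
                seen.add((u, v))
                out.append((u, v))
    return out


def _copy_adj(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {k: list(v) for k, v in adj.items()}


def _insert_leaf(adj: dict[int, list[int]], edge: tuple[int, int], leaf: int, new_internal: int) -> None:
    """Subdivide ``edge`` with ``new_internal`` and hang ``leaf`` off it (in place)."""
    u, v = edge
    adj[u][adj[u].index(v)] = new_internal
    adj[v][adj[v].index(u)] = new_internal
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def _all_topologies(n_leaves: int) -> Iterator[dict[int, list[int]]]:
    """All unrooted binary topologies over leaves 0..n_leaves-1."""
    if n_leaves < 3:
        raise ValidationError("topology enumeration needs >= 3 leaves")
    base = {0: [-1], 1: [-1], 2: [-1], -1: [0, 1, 2]}

    def rec(adj: dict[int, list[int]], next_leaf: int) -> Iterator[dict[int, list[int]]]:
        if next_leaf == n_leaves:
            yield adj
            return
        for edge in _edges(adj):
            new = _copy_adj(adj)
            _insert_leaf(new, edge, next_leaf, -(next_leaf - 1))
            yield from rec(new, next_leaf + 1)

    yield from rec(base, 3)


def _stepwise_tree(
    order: Sequence[int], leaf_bits: dict[int, int], mask: int
) -> tuple[dict[int, list[int]], int]:
    """Greedy stepwise addition following ``order`` (must start with leaf 0)."""
    adj = {order[0]: [-1], order[1]: [-1], order[2]: [-1], -1: [order[0], order[1], order[2]]}
    next_internal = -2
    for leaf in order[3:]:
        best = None
        for edge in _edges(adj):
            cand = _copy_adj(adj)
            _insert_leaf(cand, edge, leaf, next_internal)
            s = _score_unrooted(cand, leaf_bits, mask)
            if best is None or s < best[0]:
                best = (s, cand)
        adj = best[1]
        next_internal -= 1
    return adj, _score_unrooted(adj, leaf_bits, mask)


def _nni_moves(adj: dict[int, list[int]], edge: tuple[int, int]):
    """The two nearest-neighbour interchanges around an internal edge."""
    u, v = edge
    if u >= 0 or v >= 0:
        return
    u_sub = [n for n in adj[u] if n != v]
    v_sub = [n for n in adj[v] if n != u]
    # swap u_sub[1] <-> v_sub[0] and u_sub[1] <-> v_sub[1]
    for vs in v_sub:
        new = _copy_adj(adj)
        a = u_sub[1]
        new[u][new[u].index(a)] = vs
        new[v][new[v].index(vs)] = a
        new[a][new[a].index(u)] = v
        new[vs][new[vs].index(v)] = u
        yield new


def _nni_hill_climb(
    adj: dict[int, list[int]], leaf_bits: dict[int, int], mask: int
) -> tuple[dict[int, list[int]], int]:
    score = _score_unrooted(adj, leaf_bits, mask)
    improved = True
    while improved:
        improved = False
        for edge in _edges(adj):
            for cand in _nni_moves(adj, edge):
                s = _score_unrooted(cand, leaf_bits, mask)
                if s < score:
                    adj, score = cand, s
                    improved = True
                    break
            if improved:
                break
    return adj, score


# ---------------------------------------------------------------------------
# rooted tree construction with edge lengths
# ---------------------------------------------------------------------------


def _build_clade_tree(
    adj: dict[int, list[int]],
    leaf_bits: dict[int, int],
    mask: int,
    sample_ids: Sequence[str],
    score: int,
) -> CladeTree:
    """Root at leaf 0 and assign per-edge change counts via Fitch up-pass."""
    names: dict[int, str] = {0: ROOT_NAME}
    for i, s in enumerate(sample_ids, start=1):
        names[i] = s
    n_int = 0
    for n in adj:
        if n < 0:
            n_int += 1
            names[n] = f"n{n_int}"

    prelim: dict[int, tuple[int, int]] = {}

    def post(node: int, par: int) -> tuple[int, int]:
        kids = [n for n in adj[node] if n != par]
        if not kids:
            res = _leaf_sets(leaf_bits[node], mask)
        else:
            accA = accB = None
            for k in kids:
                A2, B2 = post(k, node)
                if accA is None:
                    accA, accB = A2, B2
                    continue
                IA, IB = accA & A2, accB & B2
                E = mask & ~(IA | IB)
                accA = IA | (E & (accA | A2))
                accB = IB | (E & (accB | B2))
            res = (accA, accB)
        prelim[node] = res
        return res

    children: dict[str, list[str]] = {}
    parent: dict[str, str] = {}
    edge_changes: dict[str, int] = {}
    final1: dict[int, int] = {0: 0}

    if len(adj) > 1:
        root_neigh = adj[0][0]
        post(root_neigh, 0)

        def pre(node: int, par: int) -> None:
            A, B = prelim[node]
            P1 = final1[par]
            # keep the parent state where allowed, else the forced state
            f1 = (P1 & B) | (~P1 & mask & ~A)
            final1[node] = f1
            pn, nn = names[par], names[node]
            parent[nn] = pn
            children.setdefault(pn, []).append(nn)
            edge_changes[nn] = (f1 ^ final1[par]).bit_count()
            for k in adj[node]:
                if k != par:
                    pre(k, node)

        pre(root_neigh, 0)

    return CladeTree(
        children=children,
        parent=parent,
        edge_changes=edge_changes,
        score=score,
        sample_ids=list(sample_ids),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

EXHAUSTIVE_MAX_SAMPLES = 7


def parsimony_tree(
    chars: CharacterMatrix,
    method: str = "auto",
    seed: int | None = 0,
    n_restarts: int = 25,
) -> CladeTree:
    """Maximum-parsimony tree rooted at the all-zero ancestral state.

    ``method='exhaustive'`` enumerates every unrooted topology (global
    optimum; feasible for small sample counts). ``method='heuristic'`` runs
    seeded random-order stepwise addition with NNI hill climbing over
    ``n_restarts`` restarts. ``method='auto'`` picks exhaustive for up to
    7 samples.
    """
    L = chars.n_samples + 1  # + ancestral leaf
    mask = (1 << chars.n_characters) - 1
    leaf_bits = {0: 0}
    for i, bits in enumerate(chars.row_bits(), start=1):
        leaf_bits[i] = bits

    if chars.n_samples < 2:
        # degenerate: root plus at most one sample
        if chars.n_samples == 0:
            return CladeTree({}, {}, {}, 0, [])
        sid = chars.sample_ids[0]
        ch = leaf_bits[1].bit_count()
        return CladeTree(
            children={ROOT_NAME: [sid]},
            parent={sid: ROOT_NAME},
            edge_changes={sid: ch},
            score=ch,
            sample_ids=list(chars.sample_ids),
        )

    if method == "auto":
        method = "exhaustive" if chars.n_samples <= EXHAUSTIVE_MAX_SAMPLES else "heuristic"
    if method == "exhaustive":
        best = None
        for adj in _all_topologies(L):
            s = _score_unrooted(adj, leaf_bits, mask)
            if best is None or s < best[0]:
                best = (s, adj)
        score, adj = best
    elif method == "heuristic":
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(max(1, n_restarts)):
            order = [0] + list(rng.permutation(np.arange(1, L)))
            adj, _s = _stepwise_tree(order, leaf_bits, mask)
            adj, s = _nni_hill_climb(adj, leaf_bits, mask)
            if best is None or s < best[0]:
                best = (s, adj)
        score, adj = best
    else:
        raise ValueError(f"unknown method {method!r}")

    return _build_clade_tree(adj, leaf_bits, mask, chars.sample_ids, score)


def fitch_character_score(chars: CharacterMatrix, adj: dict[int, list[int]]) -> int:
    """Score an explicit unrooted topology (testing hook)."""
    mask = (1 << chars.n_characters) - 1
    leaf_bits = {0: 0}
    for i, bits in enumerate(chars.row_bits(), start=1):
        leaf_bits[i] = bits
    return _score_unrooted(adj, leaf_bits, mask)


def tree_sample_order(tree: CladeTree) -> list[str]:
    """Deterministic depth-first leaf order for heat-map display.

    Children are visited smaller-subtree first, ties broken by label.
    """
    sample_set = set(tree.sample_ids)

    def subtree_size(node: str) -> int:
        return 1 + sum(subtree_size(k) for k in tree.children.get(node, []))

    order: list[str] = []

    def dfs(node: str) -> None:
        if node in sample_set:
            order.append(node)
        for k in sorted(tree.children.get(node, []), key=lambda n: (subtree_size(n), n)):
            dfs(k)

    dfs(ROOT_NAME)
    return order
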