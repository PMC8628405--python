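"""Distance-based tree inference and clade assignment.

The stage stack is: filter alignment columns by occupancy, Poisson-corrected
distances (d = -ln(1 - p)), neighbor joining (Saitou-Nei Q criterion with
Studier-Keppler updates), outgroup rooting, and a rule-based query-to-clade
assignment whose uncertainty is quantified by a plain nonparametric bootstrap
over alignment columns.

This is a desk-scale, fully deterministic stand-in for heavy ML/Bayesian
inference; reports produced downstream always label the method so its
supports are not confused with published ML bootstrap values or posterior
probabilities.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .align import GAP, MSA, _EXT_INDEX
from .errors import TreeError

log = logging.getLogger(__name__)

#: p-distances are capped here before the -ln(1 - p) correction so that
#: saturated pairs stay finite.
P_CAP = 0.95

OUTGROUP_LABEL = "outgroup"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances (substitutions/site) over labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=np.float64)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise TreeError("duplicate labels in distance matrix")
        if d.shape != (n, n):
            raise TreeError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise TreeError("non-finite distances")
        if not np.allclose(d, d.T):
            raise TreeError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise TreeError("nonzero diagonal")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class CladeMap:
    """Reference leaves per clade label, plus a disjoint outgroup set."""

    clades: dict[str, frozenset[str]]
    outgroup: frozenset[str]

    def __post_init__(self):
        if not self.outgroup:
            raise TreeError("outgroup set must be nonempty")
        seen: set[str] = set(self.outgroup)
        for label, members in self.clades.items():
            if not members:
                raise TreeError(f"clade {label!r} has no members")
            overlap = seen & members
            if overlap:
                raise TreeError(f"leaves in multiple groups: {sorted(overlap)}")
            seen |= members

    @property
    def references(self) -> dict[str, str]:
        """leaf id -> clade label for every reference leaf."""
        return {m: c for c, members in self.clades.items() for m in members}

    @classmethod
    def from_tsv(cls, path) -> "CladeMap":
        """Two-column TSV (leaf_id, clade_label); 'outgroup' is reserved."""
        clades: dict[str, set[str]] = {}
        outgroup: set[str] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TreeError(f"{path}: line {lineno}: expected 2 columns")
                leaf, label = parts
                if lineno == 1 and (leaf, label) == ("leaf_id", "clade_label"):
                    continue  # tolerate a header row
                if label == OUTGROUP_LABEL:
                    outgroup.add(leaf)
                else:
                    clades.setdefault(label, set()).add(leaf)
        return cls(
            clades={c: frozenset(m) for c, m in clades.items()},
            outgroup=frozenset(outgroup),
        )


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    assigned: str
    support: float
    n_successful_reps: int

    def __post_init__(self):
        if not 0.0 <= self.support <= 1.0:
            raise TreeError("support must lie in [0, 1]")


def filter_columns(msa: MSA, min_occupancy: float = 0.5) -> MSA:
    """Keep columns whose non-gap fraction is >= *min_occupancy*."""
    if not 0.0 < min_occupancy <= 1.0:
        raise TreeError("min_occupancy must lie in (0, 1]")
    n = len(msa.rows)
    keep = [
        j
        for j in range(msa.column_count)
        if sum(r[j] != GAP for _, r in msa.rows) / n >= min_occupancy
    ]
    if not keep:
        raise TreeError("no columns left after occupancy filtering")
    return MSA(rows=[(sid, "".join(r[j] for j in keep)) for sid, r in msa.rows])


def _msa_to_ints(msa: MSA) -> np.ndarray:
    return np.array(
        [[_EXT_INDEX[c] for c in row] for _, row in msa.rows], dtype=np.int16
    )


_GAP_CODE = _EXT_INDEX[GAP]


def _p_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise p-distances over shared non-gap columns; NaN where no column
    is shared."""
    nongap = codes != _GAP_CODE
    shared = (nongap[:, None, :] & nongap[None, :, :])
    mism = shared & (codes[:, None, :] != codes[None, :, :])
    ns = shared.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ns > 0, mism.sum(axis=2) / np.maximum(ns, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    return p


def _poisson_correct(p: np.ndarray, warn: bool = True) -> np.ndarray:
    capped = p > P_CAP
    if warn and np.any(capped):
        log.warning(
            "%d saturated p-distances capped at %.2f before Poisson correction",
            int(np.sum(capped)) // 2,
            P_CAP,
        )
    return -np.log1p(-np.minimum(p, P_CAP))


def poisson_distance(msa: MSA) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) between all MSA rows.

    p is capped at 0.95 (with a logged warning) so distances stay finite.
    """
    codes = _msa_to_ints(msa)
    p = _p_matrix(codes)
    if np.any(np.isnan(p)):
        bad = np.argwhere(np.isnan(p))
        i, j = bad[0]
        raise TreeError(
            f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no non-gap columns"
        )
    return DistanceMatrix(labels=tuple(msa.ids), d=_poisson_correct(p))


# ---------------------------------------------------------------------------
# Neighbor joining


def _nj_core(
    labels: Sequence[str], D: np.ndarray
) -> tuple[list[tuple[int, int, float]], int, dict[int, str]]:
    """Neighbor joining on a distance matrix.

    Returns (edges, center, leaf_labels): an undirected edge list
    ``(node_u, node_v, branch_length)``, the id of the final trifurcating
    center node, and the map of leaf node ids (0..n-1, input order) to labels.

    Determinism: node sums and the Q scan follow the lexicographic order of
    cluster representative labels, and exact Q ties are broken by the
    lexicographically smallest representative pair, so the result does not
    depend on input row order.
    """
    n = len(labels)
    if n < 3:
        raise TreeError("neighbor joining requires >= 3 labels")
    dist: dict[int, dict[int, float]] = {
        i: {j: float(D[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    rep = {i: labels[i] for i in range(n)}
    active = sorted(range(n), key=lambda i: rep[i])
    edges: list[tuple[int, int, float]] = []
    next_id = n

    while len(active) > 3:
        N = len(active)
        r = {i: sum(dist[i][k] for k in active if k != i) for i in active}
        best_q = math.inf
        best_pair: tuple[int, int] | None = None
        best_key: tuple[str, str] | None = None
        for ai in range(N):
            for aj in range(ai + 1, N):
                i, j = active[ai], active[aj]
                q = (N - 2) * dist[i][j] - r[i] - r[j]
                key = tuple(sorted((rep[i], rep[j])))
                tol = 1e-10 * max(1.0, abs(best_q) if best_q < math.inf else 1.0)
                if q < best_q - tol or (
                    abs(q - best_q) <= tol and (best_key is None or key < best_key)
                ):
                    best_q = q
                    best_pair = (i, j)
                    best_key = key
        i, j = best_pair  # type: ignore[misc]
        dij = dist[i][j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = dij - li
        # Clamp a negative estimate to zero, moving the deficit to the sister
        # branch so the path length through the new node is preserved.
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        u = next_id
        next_id += 1
        edges.append((u, i, li))
        edges.append((u, j, lj))
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = max((dist[i][k] + dist[j][k] - dij) / 2.0, 0.0)
            dist[u][k] = duk
            dist[k][u] = duk
        for k in active:
            dist[k].pop(i, None)
            dist[k].pop(j, None)
        del dist[i], dist[j]
        rep[u] = min(rep[i], rep[j])
        active = sorted(
            [a for a in active if a not in (i, j)] + [u], key=lambda a: rep[a]
        )

    a, b, c = active
    dab, dac, dbc = dist[a][b], dist[a][c], dist[b][c]
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    center = next_id
    edges.append((center, a, la))
    edges.append((center, b, lb))
    edges.append((center, c, lc))
    leaf_labels = {i: labels[i] for i in range(n)}
    return edges, center, leaf_labels


def neighbor_joining(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """NJ tree as an unrooted dendropy Tree with branch lengths."""
    edges, center, leaf_labels = _nj_core(dm.labels, dm.d)
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, length in edges:
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    def attach(node_id: int, parent_id: int, parent_node: dendropy.Node):
        for child_id, length in adj[node_id]:
            if child_id == parent_id:
                continue
            child = dendropy.Node()
            if child_id in leaf_labels:
                child.taxon = tns.require_taxon(label=leaf_labels[child_id])
            parent_node.add_child(child)
            child.edge.length = length
            attach(child_id, node_id, child)

    attach(center, -1, tree.seed_node)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                real_value_format_specifier=".10g",
                suppress_rooting=True,
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# Clade assignment


def _tree_to_edges(
    tree: dendropy.Tree,
) -> tuple[list[tuple[int, int, float]], int, dict[int, str]]:
    """Flatten a dendropy tree into the edge-list form used internally."""
    ids: dict[dendropy.Node, int] = {}
    leaf_labels: dict[int, str] = {}
    edges: list[tuple[int, int, float]] = []
    for node in tree.preorder_node_iter():
        ids[node] = len(ids)
        if node.taxon is not None:
            leaf_labels[ids[node]] = node.taxon.label
        elif node.is_leaf():
            raise TreeError("leaf without a taxon label")
        if node.parent_node is not None:
            edges.append(
                (ids[node.parent_node], ids[node], node.edge.length or 0.0)
            )
    return edges, ids[tree.seed_node], leaf_labels


def _assign_on_edges(
    edges: list[tuple[int, int, float]],
    leaf_labels: dict[int, str],
    clade_map: CladeMap,
    query_id: str,
) -> str:
    """Root on the outgroup edge and apply the clade-purity rule.

    The root edge is the edge whose one side contains the most outgroup
    leaves, ties broken by fewest non-outgroup leaves on that side (this is
    the outgroup MRCA edge whenever the outgroup is monophyletic), further
    ties by the lexicographic label list of that side.  The query is assigned
    to clade C iff the smallest rooted clade containing the query and at
    least one reference contains only references of C besides the query.
    """
    adj: dict[int, list[int]] = {}
    for u, v, _l in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    nodes = set(adj)
    label_of = leaf_labels
    refs = clade_map.references
    og = set(clade_map.outgroup)

    # Leaf sets below each directed edge (u -> v): labels on the v side.
    below: dict[tuple[int, int], frozenset[str]] = {}

    def collect(v: int, u: int) -> frozenset[str]:
        key = (u, v)
        if key in below:
            return below[key]
        acc: set[str] = set()
        if v in label_of:
            acc.add(label_of[v])
        for w in adj[v]:
            if w != u:
                acc |= collect(w, v)
        out = frozenset(acc)
        below[key] = out
        return out

    best = None
    for u, v, _l in edges:
        for side_top, other in ((v, u), (u, v)):
            side = collect(side_top, other)
            n_og = len(side & og)
            n_other = len(side) - n_og
            key = (-n_og, n_other, tuple(sorted(side)))
            if best is None or key < best[0]:
                best = (key, side_top, other)
    if best is None:
        raise TreeError("tree has no edges")
    og_top, in_top = best[1], best[2]

    # Rooted orientation: virtual root with children og_top and in_top.
    parent: dict[int, int | None] = {og_top: None, in_top: None}
    order: list[int] = []
    for start, came_from in ((og_top, in_top), (in_top, og_top)):
        stack = [(start, came_from)]
        while stack:
            node, par = stack.pop()
            order.append(node)
            for w in adj[node]:
                if w != par:
                    parent[w] = node
                    stack.append((w, node))
    # leaf sets below each rooted node
    below_node: dict[int, set[str]] = {nid: set() for nid in nodes}
    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    for nid, par in parent.items():
        if par is not None:
            children[par].append(nid)
    def fill(nid: int) -> set[str]:
        acc = {label_of[nid]} if nid in label_of else set()
        for ch in children[nid]:
            acc |= fill(ch)
        below_node[nid] = acc
        return acc

    fill(og_top)
    fill(in_top)

    query_node = next(
        (nid for nid, lab in label_of.items() if lab == query_id), None
    )
    if query_node is None:
        raise TreeError(f"query {query_id!r} not in tree")
    node = query_node
    while node is not None:
        members = below_node[node] - {query_id}
        ref_members = {m for m in members if m in refs}
        if ref_members:
            if members != ref_members:
                return "unassigned"
            clades_hit = {refs[m] for m in ref_members}
            return clades_hit.pop() if len(clades_hit) == 1 else "unassigned"
        node = parent[node]
    return "unassigned"


def assign_clade(
    tree: dendropy.Tree, clade_map: CladeMap, query_id: str
) -> str:
    """Assign *query_id* to a labeled clade, or "unassigned".

    The tree is rooted on the edge leading to the outgroup's MRCA; the query
    is assigned clade C iff the smallest rooted clade containing it and at
    least one reference leaf contains only C references besides the query.
    """
    edges, _root, leaf_labels = _tree_to_edges(tree)
    present = set(leaf_labels.values())
    needed = {query_id} | set(clade_map.outgroup) | set(clade_map.references)
    missing = sorted(needed - present)
    if missing:
        raise TreeError(f"leaves missing from tree: {missing}")
    return _assign_on_edges(edges, leaf_labels, clade_map, query_id)


def bootstrap_clade_support(
    msa: MSA,
    clade_map: CladeMap,
    query_id: str,
    n_reps: int = 100,
    seed: int | None = None,
) -> CladeAssignment:
    """Nonparametric bootstrap over alignment columns for clade assignment.

    Each replicate resamples columns with replacement, recomputes Poisson
    distances, rebuilds the NJ tree and re-applies :func:`assign_clade`.  The
    assignment is the modal label over successful replicates (ties give
    "unassigned") and the support is the modal label's replicate fraction.
    Replicates in which some pair shares no non-gap column are recorded and
    excluded.
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    if seed is None:
        raise TreeError("a seed is required for the bootstrap")
    ids = msa.ids
    needed = {query_id} | set(clade_map.outgroup) | set(clade_map.references)
    missing = sorted(needed - set(ids))
    if missing:
        raise TreeError(f"leaves missing from MSA: {missing}")
    codes = _msa_to_ints(msa)
    ncols = codes.shape[1]
    rng = np.random.default_rng(seed)
    votes: Counter[str] = Counter()
    n_failed = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        p = _p_matrix(codes[:, cols])
        if np.any(np.isnan(p)):
            n_failed += 1
            continue
        d = _poisson_correct(p, warn=False)
        edges, _center, leaf_labels = _nj_core(ids, d)
        # _nj_core returns leaf ids 0..n-1; treat as labels directly
        votes[_assign_on_edges(edges, leaf_labels, clade_map, query_id)] += 1
    n_ok = n_reps - n_failed
    if n_ok == 0:
        return CladeAssignment(query_id, "unassigned", 0.0, 0)
    top = votes.most_common()
    best_count = top[0][1]
    tied = sorted(lab for lab, cnt in top if cnt == best_count)
    assigned = tied[0] if len(tied) == 1 else "unassigned"
    return CladeAssignment(query_id, assigned, best_count / n_ok, n_ok)


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree (labels sorted)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels=tuple(labels), d=d)
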