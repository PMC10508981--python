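"""Distance phylogenetics with bootstrap support, lineage filtering, and
minimal-change ancestral reconstruction.

Trees are built by canonical neighbor-joining on p-distances from pairwise
or progressive alignments; internal-edge support comes from a Felsenstein
column bootstrap.  Clusters with support at or above the credibility
threshold (default 95) feed the two-of-three lineage-removal filter, and a
generalized Fitch pass reconstructs the minimal number of structural-state
changes on a rooted species tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._seq import AA_ALPHABET, AA_INDEX

logger = logging.getLogger(__name__)

GAP_PENALTY = -4.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: 21x21 substitution scores indexed by AA_INDEX, last row/col = unknown -> 0
SUBST = np.zeros((21, 21))
for _a in AA_ALPHABET:
    for _b in AA_ALPHABET:
        SUBST[AA_INDEX[_a], AA_INDEX[_b]] = _BLOSUM62[_a][_b]


# ---------------------------------------------------------------------------
# alignment

@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]
    partition_boundary: int | None = None  # column index where a concatenated block starts

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("ragged alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _nw_trace(M: np.ndarray, gap: float) -> list[tuple[int | None, int | None]]:
    """Global alignment over a precomputed column-score matrix; linear gaps.

    Returns aligned index pairs (None = gap).  Traceback prefers diagonal,
    then up, for determinism.
    """
    n, m = M.shape
    dp = np.empty((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    dp[0] = gap * np.arange(m + 1)
    dp[:, 0] = gap * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, n + 1):
        diag = dp[i - 1, :-1] + M[i - 1]
        up = dp[i - 1, 1:] + gap
        cand = np.maximum(diag, up)
        ptr[i, 1:] = np.where(diag >= up, 0, 1)
        row = dp[i]
        best = row[0]
        for j in range(1, m + 1):
            left = best + gap
            if cand[j - 1] >= left:
                row[j] = cand[j - 1]
            else:
                row[j] = left
                ptr[i, j] = 2
            best = row[j]
    out = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            out.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and (p == 1 or j == 0):
            out.append((i - 1, None))
            i -= 1
        else:
            out.append((None, j - 1))
            j -= 1
    out.reverse()
    return out


def _codes(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX.get(c, 20) for c in seq), dtype=np.int64, count=len(seq))


def align_pair(a: str, b: str, gap: float = GAP_PENALTY) -> tuple[str, str]:
    """Needleman-Wunsch with BLOSUM62 and linear gaps; returns gapped rows."""
    M = SUBST[np.ix_(_codes(a), _codes(b))]
    trace = _nw_trace(M, gap)
    ra = "".join("-" if i is None else a[i] for i, _ in trace)
    rb = "".join("-" if j is None else b[j] for _, j in trace)
    return ra, rb


def _profile_freqs(rows: tuple[str, ...]) -> np.ndarray:
    """Per-column residue frequencies over non-gap characters (L x 21)."""
    L = len(rows[0])
    F = np.zeros((L, 21))
    for r in rows:
        for i, c in enumerate(r):
            if c != "-":
                F[i, AA_INDEX.get(c, 20)] += 1
    totals = F.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    return F / totals


def _merge_alignments(a: MultipleAlignment, b: MultipleAlignment, gap: float) -> MultipleAlignment:
    M = _profile_freqs(a.rows) @ SUBST @ _profile_freqs(b.rows).T
    trace = _nw_trace(M, gap)
    new_rows = []
    for r in a.rows:
        new_rows.append("".join("-" if i is None else r[i] for i, _ in trace))
    for r in b.rows:
        new_rows.append("".join("-" if j is None else r[j] for _, j in trace))
    return MultipleAlignment(ids=a.ids + b.ids, rows=tuple(new_rows))


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(0, len(a) - k + 1))}
    kb = {b[i : i + k] for i in range(max(0, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_align(seqs: dict[str, str], gap: float = GAP_PENALTY) -> MultipleAlignment:
    """Deterministic progressive alignment along a k-mer UPGMA guide tree."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = sorted(seqs)
    clusters: dict[str, MultipleAlignment] = {
        i: MultipleAlignment(ids=(i,), rows=(seqs[i],)) for i in ids
    }
    dist: dict[tuple[str, str], float] = {}
    for x in ids:
        for y in ids:
            if x < y:
                dist[(x, y)] = _kmer_distance(seqs[x], seqs[y])
    sizes = {i: 1 for i in ids}
    while len(clusters) > 1:
        (x, y), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = _merge_alignments(clusters[x], clusters[y], gap)
        for pair in list(dist):
            if x in pair or y in pair:
                del dist[pair]
        del clusters[x], clusters[y]
        new = x  # keep lexicographically stable key
        # average linkage over member sequences (UPGMA-equivalent)
        for z, other in clusters.items():
            key = (min(z, new), max(z, new))
            vals = [
                _kmer_distance(seqs[p], seqs[q])
                for p in merged.ids
                for q in other.ids
            ]
            dist[key] = float(np.mean(vals))
        clusters[new] = merged
        sizes[new] = sizes.pop(x) + sizes.pop(y)
    aln = next(iter(clusters.values()))
    # restore sorted id order for determinism
    order = sorted(range(len(aln.ids)), key=lambda i: aln.ids[i])
    return MultipleAlignment(
        ids=tuple(aln.ids[i] for i in order), rows=tuple(aln.rows[i] for i in order)
    )


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over columns where neither row is a gap; 0 if none."""
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    cols = matches = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            cols += 1
            matches += x == y
    return 100.0 * matches / cols if cols else 0.0


def distance_matrix(aln: MultipleAlignment, poisson_correct: bool = False) -> np.ndarray:
    """Pairwise p-distance matrix (optionally Poisson-corrected).

    Pairs without comparable columns get max observed + 0.1 with a warning.
    """
    n = len(aln.ids)
    if n < 3:
        raise ValueError("need >= 3 rows")
    D = np.zeros((n, n))
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            comparable = any(
                x != "-" and y != "-" for x, y in zip(aln.rows[i], aln.rows[j])
            )
            if not comparable:
                missing.append((i, j))
                continue
            D[i, j] = D[j, i] = 1.0 - pairwise_identity(aln.rows[i], aln.rows[j]) / 100.0
    if missing:
        fill = D.max() + 0.1
        for i, j in missing:
            logger.warning("no comparable columns for %s / %s; distance set to %.3f",
                           aln.ids[i], aln.ids[j], fill)
            D[i, j] = D[j, i] = fill
    if poisson_correct:
        D = -np.log(np.clip(1.0 - D, 1e-12, None))
        np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# trees

@dataclass(eq=False)
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def tip_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.postorder() if n.is_leaf)


@dataclass
class SupportedTree:
    """Unrooted tree stored with an arbitrary (multifurcating) root; internal
    edges may carry bootstrap support percentages."""

    root: TreeNode

    def tips(self) -> frozenset[str]:
        return self.root.tip_names()

    def _canon(self, side: frozenset[str]) -> frozenset[str]:
        all_tips = self.tips()
        anchor = min(all_tips)
        return all_tips - side if anchor in side else side

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions keyed canonically (side without the
        lexicographically smallest tip), mapped to the node below the edge."""
        all_tips = self.tips()
        out: dict[frozenset[str], TreeNode] = {}
        def walk(node: TreeNode, is_root: bool) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for c in node.children:
                below |= walk(c, False)
            if not is_root and 1 < len(below) < len(all_tips) - 1:
                out[self._canon(below)] = node
            return below
        walk(self.root, True)
        return out

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def parse_newick(text: str) -> SupportedTree:
    """Parse newick via dendropy; numeric internal labels become supports."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        label = getattr(dnode, "label", None)
        if label is not None and not dnode.is_leaf():
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return SupportedTree(root=convert(dtree.seed_node))


def nj_tree(D: np.ndarray, taxa: list[str]) -> SupportedTree:
    """Canonical neighbor-joining.

    Q-matrix criterion with deterministic lexicographic tie-breaking;
    negative branch lengths clamped to 0; the returned tree is rooted at the
    final trifurcation (or cherry for 2 taxa).
    """
    D = np.asarray(D, dtype=float)
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("matrix/taxa size mismatch")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    labels = list(taxa)  # smallest tip name per cluster, for tie-breaking
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                q = (m - 2) * sub[ai, bi] - r[ai] - r[bi]
                key = (q, tuple(sorted((labels[active[ai]], labels[active[bi]]))))
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = dij / 2 + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, li)
        child_j.length = max(0.0, lj)
        new = TreeNode(children=[child_i, child_j])
        # distances to the new node
        newrow = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = (D[i, k] + D[j, k] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    order = sorted(zip((a, b, c), (la, lb, lc)), key=lambda t: labels[t[0]])
    root = TreeNode()
    for idx, ln in order:
        nodes[idx].length = max(0.0, ln)
        root.children.append(nodes[idx])
    return SupportedTree(root=root)


def nj_from_alignment(aln: MultipleAlignment, poisson_correct: bool = False) -> SupportedTree:
    order = sorted(range(len(aln.ids)), key=lambda i: aln.ids[i])
    sorted_aln = MultipleAlignment(
        ids=tuple(aln.ids[i] for i in order), rows=tuple(aln.rows[i] for i in order)
    )
    D = distance_matrix(sorted_aln, poisson_correct=poisson_correct)
    return nj_tree(D, list(sorted_aln.ids))


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    poisson_correct: bool = False,
) -> SupportedTree:
    """Felsenstein column bootstrap: support = % of replicate NJ trees
    containing each internal bipartition of the full-data tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_from_alignment(aln, poisson_correct=poisson_correct)
    biparts = tree.bipartitions()
    counts = {key: 0 for key in biparts}
    order = sorted(range(len(aln.ids)), key=lambda i: aln.ids[i])
    ids = tuple(aln.ids[i] for i in order)
    rows = [aln.rows[i] for i in order]
    arr = np.array([list(r) for r in rows])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
        rep_rows = tuple("".join(row) for row in arr[:, cols])
        rep_aln = MultipleAlignment(ids=ids, rows=rep_rows)
        rep_tree = nj_from_alignment(rep_aln, poisson_correct=poisson_correct)
        rep_biparts = set(rep_tree.bipartitions())
        for key in counts:
            counts[key] += key in rep_biparts
    for key, node in biparts.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


def credible_clusters(tree: SupportedTree, threshold: float = 95.0) -> list[frozenset[str]]:
    """Tip sets (smaller bipartition side) with support >= threshold."""
    all_tips = tree.tips()
    out = []
    for key, node in sorted(tree.bipartitions().items(), key=lambda kv: sorted(kv[0])):
        if node.support is None or node.support < threshold:
            continue
        side = key if len(key) <= len(all_tips) - len(key) else all_tips - key
        out.append(side)
    return out


def test_monophyly(tree: SupportedTree, tips: set[str] | frozenset[str]) -> tuple[bool, float | None]:
    """Whether ``tips`` forms one side of some edge; returns (bool, support)."""
    tips = frozenset(tips)
    all_tips = tree.tips()
    if not tips or not tips < all_tips:
        raise ValueError("tips must be a proper non-empty subset of tree tips")
    if len(tips) == 1 or len(tips) == len(all_tips) - 1:
        return True, None  # trivial edge
    biparts = tree.bipartitions()
    node = biparts.get(tree._canon(tips))
    if node is None:
        return False, None
    return True, node.support


def concat_alignment(a1: MultipleAlignment, a2: MultipleAlignment) -> MultipleAlignment:
    """Concatenate on the id intersection (a1 order), recording the boundary."""
    ids = tuple(i for i in a1.ids if i in set(a2.ids))
    if not ids:
        raise ValueError("no shared ids")
    rows = tuple(a1.row(i) + a2.row(i) for i in ids)
    return MultipleAlignment(ids=ids, rows=rows, partition_boundary=a1.n_cols)


# ---------------------------------------------------------------------------
# lineage filtering

@dataclass
class LineageFlags:
    lineage_id: str
    c1_discordant_clustering: bool
    c2_unique_structure: bool
    c3_whole_contig_or_no_ltr: bool

    @property
    def removed(self) -> bool:
        return (self.c1_discordant_clustering + self.c2_unique_structure
                + self.c3_whole_contig_or_no_ltr) >= 2


def filter_lineages(flags: list[LineageFlags]) -> tuple[list[LineageFlags], list[LineageFlags]]:
    """Remove a lineage iff it meets at least two of the three criteria."""
    retained = [f for f in flags if not f.removed]
    removed = [f for f in flags if f.removed]
    return retained, removed


def compute_lineage_flags(
    lineage_ids: list[str],
    clusters: list[frozenset[str]],
    taxon_group: dict[str, str],
    structures: dict[str, str],
    artifact_flags: dict[str, bool],
) -> list[LineageFlags]:
    """Derive the three criteria from pipeline outputs.

    c1: no credible cluster contains the lineage together with another
    lineage of its taxon group (vacuously False when it is the only member
    of its group); c2: its structure label occurs exactly once in the
    cohort; c3: miner edge-truncation / missing-LTR flag.
    """
    from collections import Counter

    structure_counts = Counter(structures.get(i) for i in lineage_ids)
    group_sizes = Counter(taxon_group.get(i) for i in lineage_ids)
    out = []
    for lid in lineage_ids:
        grp = taxon_group.get(lid)
        if group_sizes[grp] <= 1:
            c1 = False
        else:
            c1 = not any(
                lid in cl and any(o != lid and taxon_group.get(o) == grp for o in cl)
                for cl in clusters
            )
        c2 = structure_counts[structures.get(lid)] == 1
        c3 = bool(artifact_flags.get(lid, False))
        out.append(LineageFlags(lid, c1, c2, c3))
    return out


# ---------------------------------------------------------------------------
# ancestral reconstruction

def fitch_parsimony(
    tree: SupportedTree | TreeNode,
    tip_states: dict[str, set[str] | frozenset[str]],
) -> tuple[int, dict[TreeNode, frozenset[str]]]:
    """Generalized Fitch pass on a rooted tree with set-valued tips.

    Bottom-up: child sets are folded pairwise by intersection when non-empty,
    else union with one counted change.  Returns (minimum changes, per-node
    state sets).  Exact for binary trees.
    """
    root = tree.root if isinstance(tree, SupportedTree) else tree
    states: dict[TreeNode, frozenset[str]] = {}
    changes = 0
    for node in root.postorder():
        if node.is_leaf:
            if node.name not in tip_states or not tip_states[node.name]:
                raise ValueError(f"tip {node.name!r} has no state")
            states[node] = frozenset(tip_states[node.name])
        else:
            acc = states[node.children[0]]
            for child in node.children[1:]:
                inter = acc & states[child]
                if inter:
                    acc = inter
                else:
                    acc = acc | states[child]
                    changes += 1
            states[node] = acc
    return changes, states
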