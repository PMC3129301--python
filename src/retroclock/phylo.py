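"""Distance phylogenetics for retroelement families.

K2P distance matrices from a multiple alignment, neighbor-joining (Saitou-Nei
agglomeration with the Studier-Keppler Q-criterion), column-resampling
bootstrap supports, and classification of clades into genome-specific groups
(e.g. the B-, D- and A-subgenomes of allopolyploid wheat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import Alignment
from .k2p_dating import SaturationError, SitePatternCounts, k2p_distance

_PURINE = {"A": True, "G": True, "C": False, "T": False}


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(d < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)


class TreeNode:
    """Node of an (unrooted) tree, held as a rooted structure whose root is the
    trifurcation left by the final NJ join."""

    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.support: float | None = None

    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: TreeNode

    def tips(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_tip()]

    def tip_names(self) -> set[str]:
        return {n.name for n in self.tips()}

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge splits, each canonicalised as the smaller side
        (ties broken by sorted tip names)."""
        all_tips = frozenset(self.tip_names())
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_tip():
                continue
            below = frozenset(n.name for n in node.walk() if n.is_tip())
            out.add(_canon_split(below, all_tips))
        return out

    def clades(self):
        """(node, tip-set-below) for every internal non-root node."""
        for node in self.root.walk():
            if node is self.root or node.is_tip():
                continue
            yield node, frozenset(n.name for n in node.walk() if n.is_tip())

    def path_lengths(self) -> DistanceMatrix:
        """Tip-to-tip distances along the tree."""
        tips = sorted(self.tips(), key=lambda t: t.name)
        labels = tuple(t.name for t in tips)
        # root-to-node distances + LCA via parent chains
        depth: dict[TreeNode, float] = {}
        for node in self.root.walk():
            depth[node] = (depth[node.parent] if node.parent else 0.0) + (
                node.length if node.parent else 0.0
            )
        n = len(tips)
        d = np.zeros((n, n))
        for i in range(n):
            anc_i = _ancestors(tips[i])
            for j in range(i + 1, n):
                lca = next(a for a in _ancestors(tips[j]) if a in anc_i)
                d[i, j] = d[j, i] = depth[tips[i]] + depth[tips[j]] - 2 * depth[lca]
        return DistanceMatrix(labels, d)


def _ancestors(node: TreeNode) -> list[TreeNode]:
    out = []
    while node is not None:
        out.append(node)
        node = node.parent
    return out


def _canon_split(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min((side, other), key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def _pattern_counts(row_a: np.ndarray, row_b: np.ndarray, usable: np.ndarray):
    use = usable
    n = int(use.sum())
    if n == 0:
        return None
    a, b = row_a[use], row_b[use]
    diff = a != b
    ts = int(np.sum(diff & (_IS_PURINE[a] == _IS_PURINE[b])))
    tv = int(np.sum(diff) - ts)
    return SitePatternCounts(n, ts / n, tv / n)


# byte-code lookup: A=65 C=67 G=71 T=84; purine flag per code
_IS_PURINE = np.zeros(256, dtype=bool)
_IS_PURINE[ord("A")] = _IS_PURINE[ord("G")] = True
_USABLE = np.zeros(256, dtype=bool)
for _c in "ACGT":
    _USABLE[ord(_c)] = True


def _encode(aln: Alignment) -> np.ndarray:
    return np.vstack([
        np.frombuffer(res.encode(), dtype=np.uint8) for _, res in aln.rows
    ])


def k2p_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise K2P distances over an alignment.

    ``pairwise`` deletion drops gap/N columns per compared pair; ``complete``
    drops columns with a gap/N in any row, so all pairs share the same columns.
    Saturated or incomparable pairs abort with an error naming them.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion option {deletion!r}")
    if len(aln.rows) < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    mat = _encode(aln)
    usable_site = _USABLE[mat]  # rows x cols
    labels = aln.ids
    n = len(labels)
    d = np.zeros((n, n))
    if deletion == "complete":
        shared = usable_site.all(axis=0)
    bad: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            use = shared if deletion == "complete" else (usable_site[i] & usable_site[j])
            counts = _pattern_counts(mat[i], mat[j], use)
            if counts is None:
                bad.append(f"{labels[i]}/{labels[j]}: no comparable sites")
                continue
            try:
                d[i, j] = d[j, i] = k2p_distance(counts).D
            except SaturationError:
                bad.append(f"{labels[i]}/{labels[j]}: saturated "
                           f"(P={counts.P:.3f}, Q={counts.Q:.3f})")
    if bad:
        raise ValueError("cannot build distance matrix: " + "; ".join(bad))
    return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Q(i, j) = (N - 2) d(i, j) - R_i - R_j with R the row sums; the pair with
    minimal Q is joined, ties broken by the smallest (i, j) in label-sorted
    order.  Negative branch-length estimates are clamped to zero with the
    deficit moved to the sister branch, so path lengths are preserved.
    """
    if m.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = np.argsort(np.array(m.labels))
    labels = [m.labels[i] for i in order]
    d = m.d[np.ix_(order, order)].astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    active = list(range(len(labels)))

    while len(active) > 3:
        N = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (N - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current (label-sorted) order
        besti = bestj = -1
        bestq = np.inf
        for x in range(N):
            for y in range(x + 1, N):
                if Q[x, y] < bestq:
                    bestq = Q[x, y]
                    besti, bestj = x, y
        i, j = active[besti], active[bestj]
        dij = d[i, j]
        li = 0.5 * dij + (R[besti] - R[bestj]) / (2 * (N - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances to the new node
        new = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : new.size - 1] = new[:-1]
        d[: new.size - 1, -1] = new[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final trifurcation
    i, j, k = active
    root = TreeNode()
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].length = max(v, 0.0)
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: Alignment, n_reps: int = 500, seed: int = 0,
                      deletion: str = "pairwise") -> Tree:
    """Point-estimate NJ tree with column-resampling bootstrap supports.

    Each replicate resamples ``n_cols`` columns with replacement, rebuilds the
    K2P matrix and NJ tree, and records its bipartitions; support is the
    percentage of usable replicates containing each internal split.  Replicates
    whose matrix is saturated/incomparable are skipped; more than half skipped
    is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = neighbor_joining(k2p_matrix(aln, deletion))
    rng = np.random.default_rng(seed)
    mat = _encode(aln)
    ids = aln.ids
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    used = skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        sub = mat[:, cols]
        rows = tuple(
            (ids[k], sub[k].tobytes().decode("ascii")) for k in range(len(ids))
        )
        try:
            rep_tree = neighbor_joining(k2p_matrix(Alignment(rows), deletion))
        except ValueError:
            skipped += 1
            continue
        used += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped > n_reps / 2:
        raise ValueError(
            f"bootstrap failed: {skipped}/{n_reps} replicates saturated"
        )
    all_tips = frozenset(point.tip_names())
    for node in point.root.walk():
        if node is point.root or node.is_tip():
            continue
        below = frozenset(n.name for n in node.walk() if n.is_tip())
        node.support = round(100.0 * counts[_canon_split(below, all_tips)] / used)
    return point


# ---------------------------------------------------------------------------
# genome-group classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeGroup:
    """A set of tree tips called genome-specific (or left mixed)."""

    group_label: str  # e.g. "B-specific", "mixed"
    members: frozenset[str]
    purity: float
    size: int


def classify_genome_groups(tree: Tree, labels: Mapping[str, str],
                           purity_threshold: float = 0.90,
                           min_size: int = 5) -> list[GenomeGroup]:
    """Partition tips into maximal genome-specific clades plus mixed remainder.

    Every side of every internal edge is a candidate clade; a side is
    genome-specific for genome G when at least ``purity_threshold`` of its
    labelled tips carry G and it holds at least ``min_size`` tips.  Maximal
    non-nested genome-specific clades are reported; all remaining tips form
    mixed groups by connectivity in the pruned tree.
    """
    all_tips = frozenset(tree.tip_names())
    candidates: list[tuple[frozenset[str], str, float]] = []
    sides: set[frozenset[str]] = set()
    for _, below in tree.clades():
        sides.add(below)
        sides.add(all_tips - below)
    for side in sides:
        lab = [labels[t] for t in side if t in labels and labels[t]]
        if len(side) < min_size or not lab:
            continue
        best_g, best_n = max(
            ((g, lab.count(g)) for g in set(lab)), key=lambda x: (x[1], x[0])
        )
        purity = best_n / len(lab)
        if purity >= purity_threshold:
            candidates.append((side, best_g, purity))

    candidates.sort(key=lambda c: (-len(c[0]), tuple(sorted(c[0]))))
    accepted: list[tuple[frozenset[str], str, float]] = []
    for side, g, purity in candidates:
        if any(side & a_side for a_side, _, _ in accepted):
            continue  # nested or overlapping a larger accepted clade
        accepted.append((side, g, purity))

    groups = [
        GenomeGroup(f"{g}-specific", side, purity, len(side))
        for side, g, purity in accepted
    ]
    leftover = all_tips - frozenset().union(*[s for s, _, _ in accepted]) \
        if accepted else all_tips
    if leftover:
        # each accepted side is one component of the tree minus a single edge,
        # so pruning them leaves the remaining tips in one connected residue
        lab = [labels[t] for t in leftover if t in labels and labels[t]]
        purity = (max(lab.count(g) for g in set(lab)) / len(lab)) if lab else 0.0
        groups.append(GenomeGroup("mixed", frozenset(leftover), purity, len(leftover)))
    groups.sort(key=lambda g: (-g.size, g.group_label))
    return groups
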