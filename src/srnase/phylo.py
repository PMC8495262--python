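"""Distance-based phylogeny: column masking, gamma-corrected amino-acid
distances, neighbor-joining with deterministic tie-breaking, bootstrap
bipartition support, and Newick output.

Distances are expressed as amino-acid substitutions per site.  Rate variation
among sites is modelled with a gamma distribution (shape ``alpha``), giving
the corrected distance d = alpha * ((1 - p)^(-1/alpha) - 1) for proportion p
of differing sites.  The "jtt-gamma" model additionally calibrates the
correction with the JTT equilibrium frequencies (an equal-input-style
saturation bound), which tracks the matrix-based distances used by common
tree software closely enough for topology work; exact ML pairwise JTT
distances are out of scope.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# JTT (Jones-Taylor-Thornton 1992) equilibrium amino-acid frequencies
_JTT_FREQS = {
    "A": 0.077, "R": 0.051, "N": 0.043, "D": 0.052, "C": 0.020,
    "Q": 0.041, "E": 0.062, "G": 0.074, "H": 0.023, "I": 0.053,
    "L": 0.091, "K": 0.059, "M": 0.024, "F": 0.040, "P": 0.051,
    "S": 0.069, "T": 0.059, "W": 0.014, "Y": 0.032, "V": 0.066,
}
_JTT_B = 1.0 - sum(f * f for f in _JTT_FREQS.values())

_MISSING = set("-X.?*")


@dataclass
class MaskedAlignment:
    ids: list[str]
    rows: list[str]
    kept_columns: list[int]
    threshold: float

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class DistanceModel:
    model: str = "jtt-gamma"  # p-distance | poisson-gamma | jtt-gamma
    gamma_shape: float = 0.8
    ceiling: float = 10.0

    def __post_init__(self) -> None:
        if self.model not in ("p-distance", "poisson-gamma", "jtt-gamma"):
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


def mask_low_coverage_columns(
    ids: Sequence[str], rows: Sequence[str], threshold: float = 0.95
) -> MaskedAlignment:
    """Drop alignment columns whose residue coverage falls below ``threshold``
    (gaps, missing data and ambiguous residues all count against coverage)."""
    rows = [r.upper() for r in rows]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment must be rectangular")
    n = len(rows)
    kept = []
    for j in range(len(rows[0]) if rows else 0):
        ok = sum(1 for r in rows if r[j] not in _MISSING)
        if ok / n >= threshold:
            kept.append(j)
    if rows and not kept:
        raise ValueError("all columns removed by the coverage mask")
    masked_rows = ["".join(r[j] for j in kept) for r in rows]
    return MaskedAlignment(ids=list(ids), rows=masked_rows, kept_columns=kept, threshold=threshold)


def gamma_corrected_distance(p: float, alpha: float, b: float = 1.0, ceiling: float = 10.0) -> float:
    """d = b * alpha * ((1 - p/b)^(-1/alpha) - 1); saturates at ``ceiling``."""
    if p <= 0:
        return 0.0
    if p >= b:
        return ceiling
    return b * alpha * ((1.0 - p / b) ** (-1.0 / alpha) - 1.0)


def compute_distances(masked: MaskedAlignment, model: Optional[DistanceModel] = None) -> pd.DataFrame:
    """Pairwise distance matrix under the chosen model (symmetric, zero diagonal).

    p is computed over columns where both sequences carry an unambiguous
    residue; saturated pairs are set to the model ceiling.
    """
    model = model or DistanceModel()
    ids = masked.ids
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    m = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b_id = ids[j]
            ra, rb = masked.rows[i], masked.rows[j]
            compared = differing = 0
            for ca, cb in zip(ra, rb):
                if ca in _MISSING or cb in _MISSING:
                    continue
                compared += 1
                if ca != cb:
                    differing += 1
            if compared == 0:
                raise ValueError(f"no comparable columns between {a} and {b_id}")
            p = differing / compared
            if model.model == "p-distance":
                d = p
            elif model.model == "poisson-gamma":
                d = gamma_corrected_distance(p, model.gamma_shape, 1.0, model.ceiling)
            else:
                d = gamma_corrected_distance(p, model.gamma_shape, _JTT_B, model.ceiling)
            m.loc[a, b_id] = m.loc[b_id, a] = d
    return m


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str = ""
    length: float = 0.0
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: Node

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side not containing
        the lexicographically first leaf."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        splits = set()
        for node in _internal_nodes(self.root):
            side = frozenset(l.name for l in node.leaves())
            if anchor in side:
                side = frozenset(all_leaves - side)
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits


def _internal_nodes(root: Node) -> list[Node]:
    out = []
    stack = list(root.children)
    while stack:
        n = stack.pop()
        if not n.is_leaf:
            out.append(n)
            stack.extend(n.children)
    return out


def nj_tree(distance_matrix: pd.DataFrame) -> PhyloTree:
    """Standard neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest pair of
    node labels; negative branch lengths are clamped to zero with the deficit
    moved onto the sibling branch.
    """
    ids = list(distance_matrix.index)
    if len(ids) < 3:
        raise ValueError("need at least three taxa")
    arr = distance_matrix.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    nodes: dict[str, Node] = {i: Node(name=i) for i in ids}
    d: dict[frozenset, float] = {
        frozenset((a, b)): float(distance_matrix.loc[a, b])
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    }
    active = sorted(ids)
    counter = 0
    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        new_label = f"@{counter}"
        counter += 1
        nodes[new_label] = Node(name="", children=[child_a, child_b])
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[frozenset((a, c))] + d[frozenset((b, c))] - dab)
            d[frozenset((new_label, c))] = max(dc, 0.0)
        active = sorted(x for x in active if x not in (a, b)) + [new_label]
        active.sort()

    a, b = active
    na, nb = nodes[a], nodes[b]
    tail = max(d[frozenset((a, b))], 0.0)
    # root along the final edge: attach one side under the other
    if na.is_leaf and not nb.is_leaf:
        na, nb = nb, na
    na.children.append(nb)
    nb.length = tail
    return PhyloTree(root=na)


def leaf_distances(tree: PhyloTree) -> dict[str, dict[str, float]]:
    """Patristic (branch-length-sum) distances between all leaf pairs."""
    paths: dict[str, dict[str, float]] = {}

    def walk(node: Node, ancestors: list[tuple[Node, float]]):
        here = ancestors + [(node, ancestors[-1][1] + node.length if ancestors else 0.0)]
        if node.is_leaf:
            paths[node.name] = {id(n): depth for (n, depth) in here}  # type: ignore[misc]
        for c in node.children:
            walk(c, here)

    walk(tree.root, [])
    names = list(paths)
    out: dict[str, dict[str, float]] = {n: {} for n in names}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            shared = set(paths[x]) & set(paths[y])
            deepest = max(paths[x][s] for s in shared)
            dist = (max(paths[x].values()) - deepest) + (max(paths[y].values()) - deepest)
            out[x][y] = out[y][x] = dist
    return out


def bootstrap_support(
    masked: MaskedAlignment,
    model: Optional[DistanceModel] = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap support (%) on internal branches.

    Columns are resampled with replacement per replicate; support for an
    internal branch is the percentage of replicate trees containing the same
    leaf bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model = model or DistanceModel()
    tree = nj_tree(compute_distances(masked, model))
    counts: dict[frozenset, int] = {split: 0 for split in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    ncols = masked.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rows = ["".join(r[j] for j in cols) for r in masked.rows]
        replicate = MaskedAlignment(masked.ids, rows, list(cols), masked.threshold)
        try:
            rep_tree = nj_tree(compute_distances(replicate, model))
        except ValueError:
            continue
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    all_leaves = set(tree.leaf_names())
    anchor = min(all_leaves)
    for node in _internal_nodes(tree.root):
        side = frozenset(l.name for l in node.leaves())
        if anchor in side:
            side = frozenset(all_leaves - side)
        if side in counts:
            node.support = 100.0 * counts[side] / n_replicates
    return tree


# ---------------------------------------------------------------------------
# Newick / multiple alignment helpers
# ---------------------------------------------------------------------------

def to_newick(tree: PhyloTree) -> str:
    def render(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(render(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:.0f}"
        return f"({inner}){label}:{node.length:.6f}"

    root = tree.root
    inner = ",".join(render(c) for c in root.children)
    label = root.name or ("" if root.support is None else f"{root.support:.0f}")
    return f"({inner}){label};"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def align_proteins(sequences: dict[str, str]) -> MaskedAlignment:
    """Multiple protein alignment via MAFFT (progressive, deterministic),
    returned unmasked (every column kept)."""
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as handle:
            for name, seq in sequences.items():
                handle.write(f">{name}\n{seq}\n")
        result = subprocess.run(
            ["mafft", "--retree", "2", "--maxiterate", "0", "--quiet", "--amino", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    ids: list[str] = []
    rows: list[str] = []
    for chunk in result.stdout.split(">")[1:]:
        lines = chunk.splitlines()
        ids.append(lines[0].split()[0])
        rows.append("".join(lines[1:]).upper())
    order = {name: i for i, name in enumerate(sequences)}
    paired = sorted(zip(ids, rows), key=lambda t: order.get(t[0], len(order)))
    ids = [p[0] for p in paired]
    rows = [p[1] for p in paired]
    return MaskedAlignment(ids=ids, rows=rows, kept_columns=list(range(len(rows[0]) if rows else 0)), threshold=0.0)
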