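"""Independent oracles and stochastic validation experiments.

These utilities deliberately avoid the implementation paths they check:

* :func:`exhaustive_alignment` enumerates every global alignment of two short
  sequences and scores it directly (affine gap runs scored open +
  (L-1)*extend), providing a brute-force reference for the dynamic-programming
  aligner.
* :func:`random_additive_case` builds a random unrooted binary tree, reads its
  path-length (additive) distance matrix, and returns the generating splits,
  against which neighbor-joining consistency is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align as _align


# ---------------------------------------------------------------------------
# exhaustive alignment oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExhaustiveResult:
    best_score: float
    identities: frozenset[float]  # identity % of every co-optimal alignment


def exhaustive_alignment(seq_a: str, seq_b: str) -> ExhaustiveResult:
    """Enumerate all global alignments (DNA scoring) and return the optimal
    score plus the identity percentages achieved by co-optimal alignments."""
    match = _align.DNA_PARAMS["match"]
    mismatch = _align.DNA_PARAMS["mismatch"]
    open_ = _align.DNA_PARAMS["open"]
    extend = _align.DNA_PARAMS["extend"]
    best: list[float] = [float("-inf")]
    identities: set[float] = set()
    na, nb = len(seq_a), len(seq_b)

    # state: i, j, last op ('M'|'D'|'I'|start), score, matches, columns
    def walk(i: int, j: int, last: str, score: float, matches: int, columns: int) -> None:
        if i == na and j == nb:
            if score > best[0] + 1e-9:
                best[0] = score
                identities.clear()
            if abs(score - best[0]) <= 1e-9:
                identities.add(100.0 * matches / columns)
            return
        if i < na and j < nb:
            pair = match if seq_a[i] == seq_b[j] else mismatch
            walk(i + 1, j + 1, "M", score + pair, matches + (seq_a[i] == seq_b[j]), columns + 1)
        if i < na:  # gap in B
            cost = extend if last == "D" else open_
            walk(i + 1, j, "D", score + cost, matches, columns + 1)
        if j < nb:  # gap in A
            cost = extend if last == "I" else open_
            walk(i, j + 1, "I", score + cost, matches, columns + 1)

    walk(0, 0, "S", 0.0, 0, 0)
    return ExhaustiveResult(best_score=best[0], identities=frozenset(identities))


def identity_oracle_agreement(seed: int, n_pairs: int = 200, max_len: int = 8) -> float:
    """Fraction of random short DNA pairs on which the affine aligner's score
    equals the exhaustive optimum and its identity is achieved by a co-optimal
    alignment."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        a = "".join(rng.choice(list("ACGT"), size=la))
        b = "".join(rng.choice(list("ACGT"), size=lb))
        oracle = exhaustive_alignment(a, b)
        alignment = _align.pairwise_align(a, b, mode="dna")
        ident = _align.identity_percent(alignment)
        score_ok = abs(float(alignment.score) - oracle.best_score) <= 1e-6
        ident_ok = any(abs(ident - x) <= 1e-6 for x in oracle.identities)
        agree += score_ok and ident_ok
    return agree / n_pairs


# ---------------------------------------------------------------------------
# additive-matrix NJ consistency
# ---------------------------------------------------------------------------

def random_additive_case(
    rng: np.random.Generator, n_taxa: int
) -> tuple[pd.DataFrame, set[frozenset]]:
    """Random unrooted binary tree with uniform(0.1, 1.0) branch lengths;
    returns its additive distance matrix and the generating bipartitions."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for a non-trivial split")
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, weight); leaves are labels, internals ints
    adjacency: dict = {}
    nxt = [0]

    def connect(u, v, w):
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))

    def new_internal():
        nxt[0] += 1
        return -nxt[0]

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = new_internal()
    for leaf in labels[:3]:
        connect(leaf, center, blen())
    edges = [(leaf, center) for leaf in labels[:3]]
    for leaf in labels[3:]:
        u, v = edges[int(rng.integers(len(edges)))]
        w = next(wt for x, wt in adjacency[u] if x == v)
        adjacency[u] = [(x, wt) for x, wt in adjacency[u] if x != v]
        adjacency[v] = [(x, wt) for x, wt in adjacency[v] if x != u]
        mid = new_internal()
        split = float(rng.uniform(0.25, 0.75))
        connect(u, mid, w * split)
        connect(v, mid, w * (1 - split))
        connect(leaf, mid, blen())
        edges = [e for e in edges if set(e) != {u, v}]
        edges.extend([(u, mid), (v, mid), (leaf, mid)])

    def distances_from(start):
        seen = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adjacency[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen

    m = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        d = distances_from(a)
        for b in labels:
            m.loc[a, b] = d[b]

    anchor = min(labels)
    splits: set[frozenset] = set()
    for u in adjacency:
        for v, _ in adjacency[u]:
            if not (isinstance(u, int) and isinstance(v, int)):
                continue
            # leaves on v's side of edge (u, v)
            side = set()
            stack = [v]
            seen = {u, v}
            while stack:
                x = stack.pop()
                if isinstance(x, str):
                    side.add(x)
                for y, _w in adjacency[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if anchor in side:
                side = set(labels) - side
            if 2 <= len(side) <= n_taxa - 2:
                splits.add(frozenset(side))
    return m, splits


def nj_additive_consistency(seed: int, n_instances: int = 100, max_taxa: int = 6) -> float:
    """Fraction of random additive matrices whose generating topology is
    recovered exactly by neighbor-joining."""
    from .phylo import nj_tree

    rng = np.random.default_rng(seed)
    recovered = 0
    for k in range(n_instances):
        n_taxa = 4 + k % (max_taxa - 3)
        matrix, true_splits = random_additive_case(rng, n_taxa)
        tree = nj_tree(matrix)
        recovered += tree.bipartitions() == true_splits
    return recovered / n_instances


# ---------------------------------------------------------------------------
# truth-recovery metrics on synthetic families
# ---------------------------------------------------------------------------

def structure_recovery_fraction(sim, annotations) -> float:
    """Fraction of non-LOF alleles whose exon/intron spans are recovered
    exactly (both boundaries and frame)."""
    lof_ids = {e.allele_id for e in sim.truth.lof_events}
    ids = [i for i in sim.truth.structures if i not in lof_ids and i in annotations]
    exact = 0
    for allele_id in ids:
        found = annotations[allele_id].structure
        planted = sim.truth.structures[allele_id]
        exact += (
            found.exon2 == planted.exon2
            and found.intron2 == planted.intron2
            and found.exon3 == planted.exon3
            and found.frame_offset == planted.frame_offset
        )
    return exact / len(ids) if ids else 0.0


def recovered_lof_class(annotation) -> str | None:
    """Map a functional call back onto the planted loss-of-function class."""
    call = annotation.call
    if call is None:
        return None
    if call.status == "splice-defect":
        return "splice3-AG-to-GG"
    if call.status in ("frameshift-truncated", "premature-stop"):
        missing = set(call.missing_regions)
        if {"C3", "RC4", "C5"} <= missing or len(annotation.protein) < 40:
            return "frameshift-after-C2"
        if missing == {"C5"}:
            return "frameshift-upstream-C5"
    return None


def planted_lof_recall(sim, annotations) -> float:
    events = sim.truth.lof_events
    if not events:
        return 1.0
    hits = sum(
        1
        for e in events
        if e.allele_id in annotations
        and recovered_lof_class(annotations[e.allele_id]) == e.lof_type
    )
    return hits / len(events)


def trans_classification_metrics(sim, annotations, matrices, tree=None) -> tuple[float, float]:
    """(precision, recall) of the supported-verdict set against the planted
    trans-specific pairs, evaluated over functional alleles and homologs."""
    from .identity import classify_trans_specific

    functional = {
        aid: ann
        for aid, ann in annotations.items()
        if ann.call is None or ann.call.status == "putative-functional"
    }
    calls = classify_trans_specific(matrices, functional, tree=tree)
    supported = {tuple(sorted(c.pair)) for c in calls if c.verdict == "supported"}
    planted = {tuple(sorted(p)) for p in sim.truth.trans_pairs}
    if not supported or not planted:
        return (0.0, 0.0)
    precision = len(supported & planted) / len(supported)
    recall = len(supported & planted) / len(planted)
    return precision, recall
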