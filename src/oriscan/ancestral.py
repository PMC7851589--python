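"""Joint ancestral reconstruction of nucleotides and genomic positions.

Two characters are reconstructed at every internal node of a rooted
phylogeny:

* the **nucleotide** at each alignment column, by marginal maximum
  likelihood under HKY (empirical base frequencies, transition/transversion
  ratio fitted by 1-D likelihood maximization) using Felsenstein's pruning
  algorithm and a standard down/up pass for per-node marginal posteriors;

* the **genomic position** of each homologous block, treated as a
  categorical character over the (start, strand) labels observed at the
  leaves, by small parsimony (Sankoff with unit change cost).  Where several
  minimum-change assignments exist, the tie is broken by maximizing a simple
  likelihood in which a label change on a branch of length ``t`` has
  probability ``1 − exp(−ρt)`` for a single rearrangement rate ρ (fitted
  from the parsimony change count per unit tree length).

A substitution event is a branch on which the max-posterior parent and child
nucleotides differ.  Each event carries both the parent node's reconstructed
genomic position (the ancestral position, used for spatial mapping) and the
child's.  Multiple hits at one column on different branches are separate
events.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .blocks import AlignedBlock, GeneSegment, GAP

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = -1


# ---------------------------------------------------------------------------
# phylogeny


@dataclass
class _Node:
    id: int
    parent: Optional[int]
    children: List[int]
    length: float  # edge length to parent (expected substitutions/site)
    taxon: Optional[str]  # leaf name, None for internal nodes


class Phylogeny:
    """A rooted tree flattened to postorder-indexed arrays.

    Node ids are postorder indices (root last).  Multifurcations are resolved
    arbitrarily (zero-length edges) and logged; leaf names must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        if any(len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()):
            logger.info("resolving multifurcations arbitrarily")
            tree.resolve_polytomies()
        self._dendropy = tree
        self.nodes: List[_Node] = []
        index: Dict[int, int] = {}
        for nd in tree.postorder_node_iter():
            nid = len(self.nodes)
            index[id(nd)] = nid
            children = [index[id(c)] for c in nd.child_nodes()]
            taxon = nd.taxon.label if nd.taxon is not None else None
            length = nd.edge.length if nd.edge.length is not None else 0.0
            self.nodes.append(_Node(nid, None, children, float(length), taxon))
        for n in self.nodes:
            for c in n.children:
                self.nodes[c].parent = n.id
        self.root = len(self.nodes) - 1
        self.leaves = [n.id for n in self.nodes if not n.children]
        names = [self.nodes[i].taxon for i in self.leaves]
        if len(set(names)) != len(names) or None in names:
            raise ValueError("leaf names must be present and unique")
        self.leaf_by_name = {self.nodes[i].taxon: i for i in self.leaves}

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
        return cls(tree)

    @property
    def taxa(self) -> List[str]:
        return [self.nodes[i].taxon for i in self.leaves]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent is not None)

    def postorder(self) -> Sequence[_Node]:
        return self.nodes

    def preorder(self) -> Sequence[_Node]:
        return self.nodes[::-1]

    def branches(self) -> List[Tuple[int, int]]:
        """(parent, child) pairs; no branch is assigned above the root."""
        return [(n.parent, n.id) for n in self.nodes if n.parent is not None]

    def prune_taxon(self, name: str) -> "Phylogeny":
        """Remove one leaf, merging the branch through its former parent."""
        if name not in self.leaf_by_name:
            raise KeyError(f"taxon {name!r} not in tree")
        tree = self._dendropy.clone(depth=1)
        keep = [t for t in tree.taxon_namespace if t.label != name]
        tree.retain_taxa(keep)
        return Phylogeny(tree)

    def newick(self) -> str:
        return self._dendropy.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# HKY substitution model


def hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix normalized to one expected substitution per unit time."""
    pi = np.asarray(pi, dtype=float)
    Q = np.tile(pi, (4, 1)).astype(float)
    transitions = [(0, 2), (2, 0), (1, 3), (3, 1)]  # A<->G, C<->T
    for i, j in transitions:
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    return Q / rate


def hky_transition_probs(t: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    return expm(hky_rate_matrix(kappa, pi) * max(t, 0.0))


@dataclass
class NodeStateTable:
    """Reconstructed nucleotide states for one segment over all tree nodes.

    ``states[node_id, col]`` is the max-posterior base index (A=0..T=3) or
    ``MISSING``; ``posterior`` holds the corresponding posterior weight
    (1.0 at leaves).  Ties in posteriors are broken by the fixed base order
    A < C < G < T and flagged in ``tied``.
    """

    segment_id: str
    states: np.ndarray
    posterior: np.ndarray
    tied: np.ndarray
    kappa: float
    log_likelihood: float


def encode_alignment(seqs: Dict[str, str]) -> Dict[str, np.ndarray]:
    out = {}
    for t, s in seqs.items():
        arr = np.full(len(s), MISSING, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            arr[np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)] = i
        out[t] = arr
    return out


def _leaf_partials(codes: np.ndarray) -> np.ndarray:
    """(4, ncols) indicator partials; missing bases are all-ones (uninformative)."""
    ncols = codes.shape[0]
    L = np.zeros((4, ncols))
    ok = codes >= 0
    L[:, ~ok] = 1.0
    L[codes[ok], np.nonzero(ok)[0]] = 1.0
    return L


def _pruning_pass(
    tree: Phylogeny, leaf_codes: Dict[str, np.ndarray], kappa: float, pi: np.ndarray
):
    """Postorder partial likelihoods with per-column scaling.

    Returns (partials per node, per-branch P matrices, total log-likelihood).
    """
    ncols = next(iter(leaf_codes.values())).shape[0]
    partials: List[Optional[np.ndarray]] = [None] * tree.n_nodes
    P: List[Optional[np.ndarray]] = [None] * tree.n_nodes  # P for edge above node
    logscale = np.zeros(ncols)
    for node in tree.postorder():
        if not node.children:
            partials[node.id] = _leaf_partials(leaf_codes[node.taxon])
        else:
            L = np.ones((4, ncols))
            for c in node.children:
                if P[c] is None:
                    P[c] = hky_transition_probs(tree.nodes[c].length, kappa, pi)
                L = L * (P[c] @ partials[c])
            scale = L.max(axis=0)
            scale[scale == 0] = 1.0
            L = L / scale
            logscale += np.log(scale)
            partials[node.id] = L
    root_like = pi @ partials[tree.root]
    with np.errstate(divide="ignore"):
        loglik = float(np.sum(np.log(root_like) + logscale))
    return partials, P, loglik


def fit_kappa(
    leaf_codes: Dict[str, np.ndarray], tree: Phylogeny, pi: np.ndarray
) -> float:
    """1-D ML fit of the HKY transition/transversion ratio."""

    def neg_ll(log_kappa: float) -> float:
        _, _, ll = _pruning_pass(tree, leaf_codes, math.exp(log_kappa), pi)
        return -ll

    res = minimize_scalar(neg_ll, bounds=(math.log(0.2), math.log(50.0)), method="bounded")
    return float(math.exp(res.x))


def empirical_base_frequencies(seqs: Dict[str, str]) -> np.ndarray:
    counts = np.ones(4)  # +1 pseudocount keeps frequencies strictly positive
    for s in seqs.values():
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for b, i in _BASE_INDEX.items():
            counts[i] += int((arr == ord(b)).sum())
    return counts / counts.sum()


def reconstruct_nucleotides(
    segment: GeneSegment,
    tree: Phylogeny,
    kappa: Optional[float] = None,
    pi: Optional[np.ndarray] = None,
) -> NodeStateTable:
    """Marginal ML reconstruction of every column at every node.

    Columns where any leaf has a missing base are categorized as missing
    data and excluded (states ``MISSING`` at internal nodes).
    """
    missing = [t for t in tree.taxa if t not in segment.seqs]
    if missing:
        raise KeyError(f"segment {segment.id}: no sequence for taxa {missing}")
    codes = encode_alignment({t: segment.seqs[t] for t in tree.taxa})
    ncols = segment.length
    if ncols == 0:
        empty = np.zeros((tree.n_nodes, 0))
        return NodeStateTable(segment.id, empty.astype(np.int8), empty, empty.astype(bool), 1.0, 0.0)
    if pi is None:
        pi = empirical_base_frequencies(segment.seqs)
    if kappa is None:
        kappa = fit_kappa(codes, tree, pi)

    partials, P, loglik = _pruning_pass(tree, codes, kappa, pi)
    if not np.isfinite(loglik):
        raise FloatingPointError(f"segment {segment.id}: non-finite likelihood")

    complete = np.ones(ncols, dtype=bool)
    for t in tree.taxa:
        complete &= codes[t] >= 0

    states = np.full((tree.n_nodes, ncols), MISSING, dtype=np.int8)
    posterior = np.zeros((tree.n_nodes, ncols))
    tied = np.zeros((tree.n_nodes, ncols), dtype=bool)

    # downward ("above") vectors for marginal posteriors
    above: List[Optional[np.ndarray]] = [None] * tree.n_nodes
    above[tree.root] = np.tile(pi[:, None], (1, ncols))
    for node in tree.preorder():
        if not node.children:
            continue
        down = {c: P[c] @ partials[c] for c in node.children}
        for c in node.children:
            M = above[node.id].copy()
            for w in node.children:
                if w != c:
                    M = M * down[w]
            A = P[c].T @ M
            norm = A.max(axis=0)
            norm[norm == 0] = 1.0
            above[c] = A / norm

    for node in tree.postorder():
        if not node.children:
            states[node.id] = codes[node.taxon]
            posterior[node.id] = 1.0
            continue
        post = above[node.id] * partials[node.id]
        total = post.sum(axis=0)
        total[total == 0] = 1.0
        post = post / total
        best = post.argmax(axis=0)  # argmax takes the first max: A < C < G < T
        states[node.id] = best
        posterior[node.id] = post[best, np.arange(ncols)]
        tied[node.id] = (np.isclose(post, post.max(axis=0), rtol=0, atol=1e-12).sum(axis=0)) > 1
    states[:, ~complete] = MISSING
    for i in tree.leaves:  # leaves keep their observed states even if others missing
        states[i] = codes[tree.nodes[i].taxon]
    return NodeStateTable(segment.id, states, posterior, tied, float(kappa), loglik)


# ---------------------------------------------------------------------------
# genomic-position reconstruction (Sankoff + likelihood tie-break)


PositionLabel = Tuple[int, str]  # (block start in that genome, strand)


@dataclass
class PositionReconstruction:
    """Per-node block-position labels.

    ``labels[node_id]`` is a (start, strand) label drawn from the labels
    observed at the leaves; ``donors[node_id]`` names a leaf taxon carrying
    that label, whose per-column position map stands in for the node's.
    """

    block_id: str
    labels: Dict[int, PositionLabel]
    donors: Dict[int, str]
    changes: int
    rho: float


def fitted_rearrangement_rate(changes: int, tree: Phylogeny) -> float:
    """Rearrangement rate for tie-breaking: parsimony changes per unit tree length."""
    total = tree.total_length
    if total <= 0:
        return 1.0
    return max(changes, 1) / total


def reconstruct_positions(
    leaf_labels: Dict[str, PositionLabel],
    tree: Phylogeny,
    rho: Optional[float] = None,
    block_id: str = "",
) -> PositionReconstruction:
    """Minimum-change ancestral block positions with likelihood tie-breaking.

    Sankoff dynamic programming over the observed labels with unit change
    cost finds all minimum-change assignments; among those, the assignment
    maximizing the product of per-branch probabilities (stay ``exp(−ρt)``,
    change ``(1 − exp(−ρt))/(K−1)``) is chosen.  Remaining exact ties break
    on label sort order, for determinism.
    """
    for t in tree.taxa:
        if t not in leaf_labels:
            raise KeyError(f"block {block_id}: no position label for leaf {t!r}")
    labels = sorted(set(leaf_labels.values()))
    K = len(labels)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    donors: Dict[PositionLabel, str] = {}
    for t in tree.taxa:  # first taxon exhibiting a label donates its map
        donors.setdefault(leaf_labels[t], t)

    INF = (10**9, 0.0)
    # cost[node][label] = (min changes, min −log-likelihood) lexicographic
    cost = np.zeros((tree.n_nodes, K, 2))
    if rho is None:
        # preliminary pass with a nominal rate just to count changes
        prelim = reconstruct_positions(leaf_labels, tree, rho=1.0, block_id=block_id)
        rho = fitted_rearrangement_rate(prelim.changes, tree)

    def branch_penalties(length: float) -> Tuple[float, float]:
        t = max(length, 1e-9)
        p_stay = math.exp(-rho * t)
        p_change = (1.0 - p_stay) / max(K - 1, 1)
        return -math.log(max(p_stay, 1e-300)), -math.log(max(p_change, 1e-300))

    for node in tree.postorder():
        if not node.children:
            obs = lab_index[leaf_labels[node.taxon]]
            for k in range(K):
                cost[node.id, k] = (0.0, 0.0) if k == obs else INF
            continue
        for k in range(K):
            tot_changes, tot_nll = 0.0, 0.0
            for c in tree.nodes[node.id].children:
                stay_nll, change_nll = branch_penalties(tree.nodes[c].length)
                best = None
                for y in range(K):
                    ch = cost[c, y, 0] + (0 if y == k else 1)
                    nll = cost[c, y, 1] + (stay_nll if y == k else change_nll)
                    cand = (ch, nll, y)
                    if best is None or cand < best:
                        best = cand
                tot_changes += best[0]
                tot_nll += best[1]
            cost[node.id, k] = (tot_changes, tot_nll)

    # choose root label, then backtrack top-down
    assignment: Dict[int, int] = {}
    root_best = min(range(K), key=lambda k: (cost[tree.root, k, 0], cost[tree.root, k, 1], k))
    assignment[tree.root] = root_best
    for node in tree.preorder():
        k = assignment[node.id]
        for c in node.children:
            stay_nll, change_nll = branch_penalties(tree.nodes[c].length)
            best = min(
                range(K),
                key=lambda y: (
                    cost[c, y, 0] + (0 if y == k else 1),
                    cost[c, y, 1] + (stay_nll if y == k else change_nll),
                    y,
                ),
            )
            assignment[c] = best

    changes = sum(
        1 for p, c in tree.branches() if assignment[p] != assignment[c]
    )
    node_labels = {nid: labels[k] for nid, k in assignment.items()}
    return PositionReconstruction(
        block_id=block_id,
        labels=node_labels,
        donors={nid: donors[lab] for nid, lab in node_labels.items()},
        changes=changes,
        rho=float(rho),
    )


def leaf_block_labels(block: AlignedBlock) -> Dict[str, PositionLabel]:
    return {r.taxon: (r.start, r.strand) for r in block.rows}


# ---------------------------------------------------------------------------
# substitution events


@dataclass
class SubstitutionEvent:
    """One inferred nucleotide change on one branch at one alignment column.

    ``parent_position`` is the ancestral genomic position (the parent node's
    position reconstruction) used for spatial mapping; ``child_position`` is
    retained for sensitivity analysis.  ``distance`` is filled downstream by
    the origin-relative transform.
    """

    parent_node: int
    child_node: int
    child_taxon: Optional[str]
    segment_id: str
    column: int
    parent_base: str
    child_base: str
    parent_position: int
    child_position: int
    distance: Optional[int] = None


def extract_substitutions(
    states: NodeStateTable,
    tree: Phylogeny,
    positions: PositionReconstruction,
    segment: GeneSegment,
) -> List[SubstitutionEvent]:
    """Emit one event per (branch, column) where parent and child states differ.

    Positions at each node come from the node's donor leaf's per-column map
    for this segment; multiple hits at one column across branches all count.
    """
    events: List[SubstitutionEvent] = []
    for p, c in tree.branches():
        diff = np.nonzero(
            (states.states[p] != states.states[c])
            & (states.states[p] != MISSING)
            & (states.states[c] != MISSING)
        )[0]
        if diff.size == 0:
            continue
        pmap = segment.position_maps[positions.donors[p]]
        cmap = segment.position_maps[positions.donors[c]]
        for col in diff:
            events.append(
                SubstitutionEvent(
                    parent_node=p,
                    child_node=c,
                    child_taxon=tree.nodes[c].taxon,
                    segment_id=segment.id,
                    column=int(col),
                    parent_base=BASES[states.states[p, col]],
                    child_base=BASES[states.states[c, col]],
                    parent_position=int(pmap[col]),
                    child_position=int(cmap[col]),
                )
            )
    return events


def events_to_rows(events: Sequence[SubstitutionEvent]) -> List[dict]:
    return [
        {
            "parent_node": e.parent_node,
            "child_node": e.child_node,
            "child_taxon": e.child_taxon or "",
            "segment": e.segment_id,
            "column": e.column,
            "parent_base": e.parent_base,
            "child_base": e.child_base,
            "parent_position": e.parent_position,
            "child_position": e.child_position,
        }
        for e in events
    ]
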