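"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the library's own algorithms: parsimony scores are
found by exhaustive enumeration over internal-node label assignments, and
codon difference counts by explicit mutation-path enumeration.
"""

from itertools import permutations, product
from typing import Dict, List, Sequence, Tuple


def all_rooted_binary_topologies(leaves: Sequence[str]) -> List:
    """All rooted binary leaf-labelled tree shapes, as nested tuples."""
    if len(leaves) == 1:
        return [leaves[0]]
    trees = []

    def splits(items):
        n = len(items)
        for mask in range(1, 2 ** (n - 1)):  # avoid mirror duplicates
            left = [items[i] for i in range(n) if mask >> i & 1]
            right = [items[i] for i in range(n) if not mask >> i & 1]
            yield left, right

    all_leaves = list(leaves)
    for left, right in splits(all_leaves):
        for lt in all_rooted_binary_topologies(left):
            for rt in all_rooted_binary_topologies(right):
                trees.append((lt, rt))
    return trees


def topology_to_newick(tree, branch_length: float = 1.0) -> str:
    def fmt(node):
        if isinstance(node, str):
            return f"{node}:{branch_length}"
        return f"({fmt(node[0])},{fmt(node[1])}):{branch_length}"

    return fmt(tree) + ";"


def _edges(tree, counter=None):
    """(parent_index, child_index_or_leaf) edge list with internal indexing."""
    internal = []
    edges = []

    def walk(node):
        if isinstance(node, str):
            return ("leaf", node)
        idx = len(internal)
        internal.append(node)
        left = walk(node[0])
        right = walk(node[1])
        edges.append((idx, left))
        edges.append((idx, right))
        return ("internal", idx)

    walk(tree)
    return len(internal), edges


def brute_force_min_changes(tree, leaf_labels: Dict[str, object], labels: Sequence[object]) -> int:
    """Minimum label changes over all internal assignments, by enumeration."""
    n_internal, edges = _edges(tree)
    best = None
    for assignment in product(labels, repeat=n_internal):
        changes = 0
        for parent_idx, child in edges:
            pa = assignment[parent_idx]
            ch = leaf_labels[child[1]] if child[0] == "leaf" else assignment[child[1]]
            if pa != ch:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best


def set_partitions(items: Sequence[str], max_groups: int) -> List[List[List[str]]]:
    """All set partitions of `items` into at most `max_groups` blocks."""
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for part in set_partitions(rest, max_groups):
        for i in range(len(part)):
            out.append(part[:i] + [part[i] + [first]] + part[i + 1 :])
        if len(part) < max_groups:
            out.append(part + [[first]])
    return out


# --- codon path enumeration -------------------------------------------------


def enumerate_codon_paths(c1: str, c2: str, codon_table: Dict[str, str]):
    """(syn, nonsyn) steps averaged over stop-free shortest mutation paths.

    Shortest paths are found by recursive search over codon space (one base
    toward the target per step), independent of the implementation's
    position-permutation bookkeeping.  Falls back to all shortest paths when
    every one passes through a stop codon.
    """

    def search(cur: str) -> List[List[Tuple[str, str]]]:
        if cur == c2:
            return [[]]
        paths = []
        for i in range(3):
            if cur[i] != c2[i]:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                for tail in search(nxt):
                    paths.append([(cur, nxt)] + tail)
        return paths

    paths = search(c1)
    if not paths:
        return 0.0, 0.0
    clean = [
        p for p in paths if all(codon_table[b] != "*" for _, b in p[:-1])
    ] or paths
    syn = nonsyn = 0.0
    for p in clean:
        for a, b in p:
            if codon_table[a] == codon_table[b]:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(clean), nonsyn / len(clean)
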