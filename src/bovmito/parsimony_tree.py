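"""Most-parsimonious haplotype trees with mutation-annotated branches.

Haplotypes are sets of differences from a reference; a tree explains them as
an accumulation of mutations from a supplied ancestral (root) profile, with
inferred internal node profiles playing the role of Steiner points in the
hamming space of variant presence/absence.  Small inputs are solved exactly
by branch-and-bound over leaf-labelled binary topologies with bit-parallel
Fitch scoring; larger inputs fall back to a greedy agglomeration that factors
shared mutations into internal nodes.

Each edge carries the ordered list of mutations it implies.  A change away
from the ancestral state is a gain; a change back is flagged as a back
mutation (the ``@`` of the field notation), and any position hit on more than
one edge is flagged recurrent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .reference_variants import (
    HaplotypeProfile,
    Region,
    VariantCall,
    VariantKind,
)

__all__ = [
    "AnnotatedTree",
    "TreeNode",
    "EdgeMutation",
    "build_tree",
    "root_distance",
    "mark_recurrences",
]

# exhaustive topology search is worst-case (2n-3)!! in the number of distinct
# haplotypes; 8 (i.e. 9 leaves with the root) keeps it around 1e5 topologies
DEFAULT_EXACT_MAX = 8


@dataclass
class EdgeMutation:
    call: VariantCall  # back_mutation=True encodes a loss (reversion)
    recurrent: bool = False

    @property
    def gained(self) -> bool:
        return not self.call.back_mutation

    @property
    def position(self) -> int:
        return self.call.position

    def label(self) -> str:
        return self.call.label()


@dataclass(eq=False)  # identity semantics: nodes are unique tree positions
class TreeNode:
    id: int
    profile: FrozenSet  # variant keys present at this node
    sample_ids: Tuple[str, ...] = ()
    parent: Optional["TreeNode"] = None
    children: List["TreeNode"] = field(default_factory=list)
    edge_mutations: List[EdgeMutation] = field(default_factory=list)  # edge to parent

    @property
    def is_tip(self) -> bool:
        return bool(self.sample_ids)

    @property
    def multiplicity(self) -> int:
        return len(self.sample_ids)

    @property
    def name(self) -> str:
        return "/".join(self.sample_ids) if self.sample_ids else f"node{self.id}"


class CladeError(ValueError):
    pass


class AnnotatedTree:
    """A rooted haplotype tree whose edges carry mutation lists."""

    def __init__(self, root: TreeNode, variant_index: Dict[object, VariantCall]):
        self.root = root
        self.variant_index = dict(variant_index)
        self.clade_index: Dict[str, int] = {}
        self._nodes: Dict[int, TreeNode] = {}
        for node in self.walk():
            self._nodes[node.id] = node

    # -- traversal ---------------------------------------------------------
    def walk(self, start: Optional[TreeNode] = None):
        stack = [start or self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def node(self, node_id: int) -> TreeNode:
        return self._nodes[node_id]

    def tips(self, clade_root: Optional[TreeNode] = None) -> List[TreeNode]:
        return [n for n in self.walk(clade_root) if n.is_tip]

    def n_tips(self, clade_root: Optional[TreeNode] = None) -> int:
        """Multiplicity-weighted tip count."""
        return sum(n.multiplicity for n in self.tips(clade_root))

    def find_tip(self, sample_id: str) -> TreeNode:
        for n in self.walk():
            if sample_id in n.sample_ids:
                return n
        raise KeyError(sample_id)

    @property
    def length(self) -> int:
        """Total number of mutations over all edges (the parsimony score)."""
        return sum(len(n.edge_mutations) for n in self.walk())

    def path_from(self, ancestor: TreeNode, node: TreeNode) -> List[TreeNode]:
        """Nodes from (excl.) ``ancestor`` down to (incl.) ``node``."""
        chain = []
        cur: Optional[TreeNode] = node
        while cur is not None and cur is not ancestor:
            chain.append(cur)
            cur = cur.parent
        if cur is None:
            raise CladeError(
                f"node {node.name!r} is not within the clade rooted at {ancestor.name!r}"
            )
        return list(reversed(chain))

    def mrca(self, nodes: Sequence[TreeNode]) -> TreeNode:
        if not nodes:
            raise CladeError("mrca of an empty node set")
        paths = []
        for n in nodes:
            chain = []
            cur: Optional[TreeNode] = n
            while cur is not None:
                chain.append(cur)
                cur = cur.parent
            paths.append(list(reversed(chain)))
        mrca = paths[0][0]
        for level in zip(*paths):
            if all(x is level[0] for x in level):
                mrca = level[0]
            else:
                break
        return mrca

    def register_clade(self, name: str, clade_root: TreeNode) -> None:
        self.clade_index[name] = clade_root.id

    def clade_root(self, name: str) -> TreeNode:
        return self.node(self.clade_index[name])

    # -- output ------------------------------------------------------------
    def newick(self, include_mutations: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.name if node.is_tip else ""
            comment = ""
            if include_mutations and node.edge_mutations:
                muts = " ".join(m.label() + ("!" if m.recurrent else "") for m in node.edge_mutations)
                comment = f"[&mutations={muts}]"
            blen = f":{len(node.edge_mutations)}"
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner}){label}{blen}{comment}"
            return f"{label}{blen}{comment}"

        return fmt(self.root) + ";"

    def edge_table(self):
        import pandas as pd

        rows = []
        for node in self.walk():
            if node.parent is None:
                continue
            rows.append(
                {
                    "parent": node.parent.name,
                    "child": node.name,
                    "mutations": ",".join(m.label() for m in node.edge_mutations),
                    "n_mutations": len(node.edge_mutations),
                    "recurrent": ",".join(
                        m.label() for m in node.edge_mutations if m.recurrent
                    ),
                    "is_tip": node.is_tip,
                    "multiplicity": node.multiplicity,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "parent",
                "child",
                "mutations",
                "n_mutations",
                "recurrent",
                "is_tip",
                "multiplicity",
            ],
        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def _variant_key_sort(key) -> Tuple:
    return (key[0], key[1], key[2] or "")


def build_tree(
    profiles: Sequence[HaplotypeProfile],
    root_profile: Optional[HaplotypeProfile] = None,
    exact_max_haplotypes: int = DEFAULT_EXACT_MAX,
) -> AnnotatedTree:
    """Build a most-parsimonious tree connecting ``profiles`` to a root.

    ``root_profile`` is the ancestral haplotype (defaults to an empty profile,
    i.e. the reference itself).  Identical haplotypes collapse to a single tip
    whose multiplicity is the number of samples carrying it.  With at most
    ``exact_max_haplotypes`` distinct haplotypes the search is exact
    (branch-and-bound over topologies); above, a greedy agglomeration with
    shared-mutation factoring is used.
    """
    if not profiles:
        raise ValueError("build_tree needs at least one profile")
    root_keys: FrozenSet = frozenset(
        v.key for v in (root_profile.variants if root_profile else ())
    )

    variant_index: Dict[object, VariantCall] = {}
    for p in list(profiles) + ([root_profile] if root_profile else []):
        for v in p.variants:
            variant_index.setdefault(v.key, replace(v, back_mutation=False, heteroplasmic=False))

    # collapse identical haplotypes (multiplicity-weighted tips)
    grouped: Dict[FrozenSet, List[str]] = {}
    for p in sorted(profiles, key=lambda p: p.sample_id):
        grouped.setdefault(frozenset(v.key for v in p.variants), []).append(p.sample_id)
    haplotypes = sorted(
        grouped.items(),
        key=lambda kv: (len(kv[0] ^ root_keys), kv[1][0]),
    )

    chars = sorted(
        set().union(root_keys, *[h for h, _ in haplotypes]),
        key=_variant_key_sort,
    )
    if len(haplotypes) <= max(exact_max_haplotypes, 1):
        root, nodes = _build_exact(haplotypes, root_keys, chars)
    else:
        root, nodes = _build_greedy(haplotypes, root_keys)

    tree = AnnotatedTree(root, variant_index)
    _annotate_edges(tree)
    mark_recurrences(tree)
    return tree


# -- exact search -----------------------------------------------------------


def _states_to_masks(states: Sequence[int]) -> Tuple[int, int]:
    can0 = can1 = 0
    for i, s in enumerate(states):
        if s:
            can1 |= 1 << i
        else:
            can0 |= 1 << i
    return can0, can1


def _fitch_cost(adj, leaf_masks, full_mask, root_leaf=0):
    """Parsimony length of an unrooted topology by bit-parallel Fitch."""
    start = next(iter(adj[root_leaf]))
    cost = 0
    sets: Dict[int, Tuple[int, int]] = {}
    stack = [(start, root_leaf, False)]
    while stack:
        node, parent, processed = stack.pop()
        if node in leaf_masks:
            sets[node] = leaf_masks[node]
            continue
        if not processed:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
            continue
        c0 = c1 = full_mask
        u0 = u1 = 0
        for nb in adj[node]:
            if nb == parent:
                continue
            a0, a1 = sets[nb]
            c0 &= a0
            c1 &= a1
            u0 |= a0
            u1 |= a1
        empty = full_mask & ~(c0 | c1)
        cost += empty.bit_count()
        sets[node] = (c0 | (empty & u0), c1 | (empty & u1))
    r0, r1 = leaf_masks[root_leaf]
    s0, s1 = sets[start]
    cost += (full_mask & ~((r0 & s0) | (r1 & s1))).bit_count()
    return cost


def _build_exact(haplotypes, root_keys, chars):
    """Branch-and-bound over leaf-labelled topologies; exact Steiner length."""
    char_index = {c: i for i, c in enumerate(chars)}
    nchars = len(chars)
    full_mask = (1 << nchars) - 1 if nchars else 0

    # leaf 0 is the ancestral profile; haplotypes follow in deterministic order
    leaf_profiles = [root_keys] + [h for h, _ in haplotypes]
    leaf_masks = {
        i: _states_to_masks([1 if c in prof else 0 for c in chars])
        for i, prof in enumerate(leaf_profiles)
    }
    n_leaves = len(leaf_profiles)

    if n_leaves == 1:
        adj_best = {0: set()}
    elif n_leaves == 2:
        adj_best = {0: {1}, 1: {0}}
    else:
        best = {"cost": None, "adj": None}
        next_internal = [n_leaves]

        def recurse(adj, edges, next_leaf):
            cost = _fitch_cost(adj, leaf_masks, full_mask)
            if best["cost"] is not None and cost >= best["cost"]:
                return
            if next_leaf == n_leaves:
                best["cost"] = cost
                best["adj"] = {k: set(v) for k, v in adj.items()}
                return
            for (u, v) in list(edges):
                w = next_internal[0]
                next_internal[0] += 1
                adj[u].discard(v)
                adj[v].discard(u)
                adj[w] = {u, v, next_leaf}
                adj[u].add(w)
                adj[v].add(w)
                adj[next_leaf] = {w}
                edges.remove((u, v))
                new_edges = [(u, w), (w, v), (w, next_leaf)]
                edges.extend(new_edges)

                recurse(adj, edges, next_leaf + 1)

                for e in new_edges:
                    edges.remove(e)
                edges.append((u, v))
                del adj[w], adj[next_leaf]
                adj[u].discard(w)
                adj[v].discard(w)
                adj[u].add(v)
                adj[v].add(u)
                next_internal[0] -= 1

        # initial topology: the single unrooted tree on the first 3 leaves
        first = n_leaves
        adj0 = {0: {first}, 1: {first}, 2: {first}, first: {0, 1, 2}}
        edges0 = [(0, first), (1, first), (2, first)]
        next_internal[0] = first + 1
        recurse(adj0, edges0, 3)
        adj_best = best["adj"]

    # assign internal states rooted at the ancestral leaf (Fitch backtrace,
    # ties resolved toward the parent state for a deterministic MP labelling)
    profiles_by_node: Dict[int, FrozenSet] = {}
    sets: Dict[int, List[int]] = {}

    def downpass(node, parent):
        if node < n_leaves:
            m0, m1 = leaf_masks[node]
            sets[node] = (m0, m1)
            return
        for nb in adj_best[node]:
            if nb != parent:
                downpass(nb, node)
        c0 = c1 = full_mask
        u0 = u1 = 0
        for nb in adj_best[node]:
            if nb == parent:
                continue
            a0, a1 = sets[nb]
            c0 &= a0
            c1 &= a1
            u0 |= a0
            u1 |= a1
        empty = full_mask & ~(c0 | c1)
        sets[node] = (c0 | (empty & u0), c1 | (empty & u1))

    states: Dict[int, int] = {}  # node -> bitmask of present chars

    def uppass(node, parent_state):
        if node < n_leaves:
            m0, m1 = leaf_masks[node]
            states[node] = m1
            return
        s0, s1 = sets[node]
        both = s0 & s1
        forced1 = s1 & ~s0
        chosen = forced1 | (both & parent_state)
        states[node] = chosen

    root_state = leaf_masks[0][1]
    if n_leaves > 1:
        start = next(iter(adj_best[0]))
        order = []
        stack = [(start, 0)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in adj_best.get(node, ()):
                if nb != parent:
                    stack.append((nb, node))
        downpass(start, 0)
        states[0] = root_state
        for node, parent in order:
            uppass(node, states[parent])
    else:
        states[0] = root_state

    def mask_to_profile(mask: int) -> FrozenSet:
        return frozenset(c for c, i in char_index.items() if mask >> i & 1)

    # convert to rooted TreeNode structure (root = ancestral leaf's position)
    counter = itertools.count(0)
    root_node = TreeNode(next(counter), mask_to_profile(root_state))
    nodes = [root_node]

    def attach(node_id, parent_id, parent_node):
        tn = TreeNode(next(counter), mask_to_profile(states[node_id]), parent=parent_node)
        if 1 <= node_id < n_leaves:
            tn.sample_ids = tuple(haplotypes[node_id - 1][1])
        parent_node.children.append(tn)
        nodes.append(tn)
        for nb in sorted(adj_best.get(node_id, ())):
            if nb != parent_id:
                attach(nb, node_id, tn)
        return tn

    if n_leaves > 1:
        attach(next(iter(adj_best[0])), 0, root_node)

    _collapse_silent_internals(root_node)
    return root_node, nodes


def _collapse_silent_internals(root: TreeNode) -> None:
    """Merge internal nodes whose profile equals their parent's (zero edges)."""
    changed = True
    while changed:
        changed = False
        stack = [root]
        while stack:
            node = stack.pop()
            for child in list(node.children):
                if not child.is_tip and child.profile == node.profile:
                    node.children.remove(child)
                    for gc in child.children:
                        gc.parent = node
                        node.children.append(gc)
                    changed = True
            stack.extend(node.children)
    # drop internal nodes left with no children (cannot represent anything)
    stack = [root]
    while stack:
        node = stack.pop()
        node.children = [
            c for c in node.children if c.is_tip or c.children
        ]
        stack.extend(node.children)


# -- greedy agglomeration ---------------------------------------------------


def _build_greedy(haplotypes, root_keys):
    counter = itertools.count(0)
    root = TreeNode(next(counter), frozenset(root_keys))
    nodes = [root]
    for keys, sample_ids in haplotypes:
        best_node = min(nodes, key=lambda n: (len(keys ^ n.profile), n.id))
        tip = TreeNode(next(counter), keys, tuple(sample_ids), parent=best_node)
        best_node.children.append(tip)
        nodes.append(tip)

    # factor mutations shared by >=2 children of a node into internal nodes
    work = [root]
    while work:
        node = work.pop()
        while True:
            deltas = {
                c: _signed_delta(node.profile, c.profile) for c in node.children
            }
            shared: Dict[Tuple, List[TreeNode]] = {}
            for child, delta in deltas.items():
                for ch in delta:
                    shared.setdefault(ch, []).append(child)
            candidates = {ch: cs for ch, cs in shared.items() if len(cs) >= 2}
            if not candidates:
                break
            ch_key = max(
                candidates,
                key=lambda ch: (len(candidates[ch]), _signed_sort(ch)),
            )
            group = candidates[ch_key]
            common = set.intersection(*[deltas[c] for c in group])
            mid_profile = _apply_signed(node.profile, common)
            mid = TreeNode(next(counter), frozenset(mid_profile), parent=node)
            node.children = [c for c in node.children if c not in group]
            node.children.append(mid)
            for c in group:
                c.parent = mid
                mid.children.append(c)
            nodes.append(mid)
            work.append(mid)
    return root, nodes


def _signed_delta(parent_profile, child_profile):
    gains = {(k, True) for k in child_profile - parent_profile}
    losses = {(k, False) for k in parent_profile - child_profile}
    return gains | losses


def _signed_sort(signed_key):
    key, gained = signed_key
    return (-key[0], key[1], key[2] or "", gained)


def _apply_signed(profile, signed_changes):
    out = set(profile)
    for key, gained in signed_changes:
        if gained:
            out.add(key)
        else:
            out.discard(key)
    return out


# -- annotation -------------------------------------------------------------


def _annotate_edges(tree: AnnotatedTree) -> None:
    for node in tree.walk():
        if node.parent is None:
            node.edge_mutations = []
            continue
        mutations = []
        for key in sorted(node.profile - node.parent.profile, key=_variant_key_sort):
            mutations.append(EdgeMutation(replace(tree.variant_index[key], back_mutation=False)))
        for key in sorted(node.parent.profile - node.profile, key=_variant_key_sort):
            mutations.append(EdgeMutation(replace(tree.variant_index[key], back_mutation=True)))
        mutations.sort(key=lambda m: (m.position, m.label()))
        node.edge_mutations = mutations


def mark_recurrences(tree: AnnotatedTree) -> AnnotatedTree:
    """Flag positions mutating on more than one edge as recurrent."""
    position_edges: Dict[int, int] = {}
    for node in tree.walk():
        for m in node.edge_mutations:
            position_edges[m.position] = position_edges.get(m.position, 0) + 1
    for node in tree.walk():
        for m in node.edge_mutations:
            m.recurrent = position_edges[m.position] > 1
    return tree


def root_distance(
    tree: AnnotatedTree,
    tip: TreeNode,
    clade_root: Optional[TreeNode] = None,
    region: Optional[Region] = None,
    substitutions_only: bool = True,
) -> int:
    """Count qualifying mutations on the path clade-root -> tip.

    With ``substitutions_only`` indels are skipped; a back mutation of a
    substitution is itself a substitution event and counts.  ``region``
    restricts counting to positions inside it (e.g. the coding region).
    """
    clade_root = clade_root or tree.root
    total = 0
    for node in tree.path_from(clade_root, tip):
        for m in node.edge_mutations:
            if substitutions_only and not m.call.kind.is_substitution:
                continue
            if region is not None and m.position not in region:
                continue
            total += 1
    return total
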