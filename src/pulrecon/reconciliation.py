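"""Event-cost parsimony reconciliation of gene trees against a species tree.

Embeds a rooted binary gene tree into a rooted binary species tree by a
minimum-cost combination of speciations (free), duplications, transfers
(horizontal gene transfer between non-ancestral species branches) and
losses, via dynamic programming over (gene node x species branch) in the
undated model.  One optimal history is returned with deterministic
tie-breaking (speciation preferred over duplication over transfer, then
lowest species-branch id); the number of co-optimal histories can also be
counted.

Default event costs: loss 1.0, duplication 2.0, transfer 3.0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "EventCosts",
    "Event",
    "ReconciliationResult",
    "reconcile",
    "root_search",
    "classify_family_history",
]

INF = math.inf
_TOL = 1e-9


class PhyloTree:
    """Rooted tree stored as parallel arrays in postorder (root last).

    ``children[i]`` is a tuple of child indices (empty for leaves);
    ``labels[i]`` is the leaf label (internal nodes may be unlabeled).
    """

    def __init__(self, children: list[tuple[int, ...]], labels: list[str | None]):
        self.children = children
        self.labels = labels
        self.n = len(children)
        self.root = self.n - 1
        self.parent: list[int | None] = [None] * self.n
        for i, kids in enumerate(children):
            for k in kids:
                self.parent[k] = i
        self.leaves = [i for i in range(self.n) if not children[i]]
        leaf_labels = [labels[i] for i in self.leaves]
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError("duplicate leaf labels")
        self.leaf_index = {labels[i]: i for i in self.leaves}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, require_binary: bool = True) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree, require_binary=require_binary)

    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree", require_binary: bool = True) -> "PhyloTree":
        children: list[tuple[int, ...]] = []
        labels: list[str | None] = []

        def build(node) -> int:
            kids = node.child_nodes()
            if require_binary and len(kids) not in (0, 2):
                raise ValueError(
                    f"non-binary node with {len(kids)} children; tree must be strictly bifurcating"
                )
            idxs = tuple(build(k) for k in kids)
            children.append(idxs)
            label = None
            if node.taxon is not None:
                label = node.taxon.label.replace(" ", "_")
            elif node.label and not kids:
                label = node.label
            labels.append(label)
            return len(children) - 1

        build(tree.seed_node)
        return cls(children, labels)

    # -- queries ------------------------------------------------------------

    def is_binary(self) -> bool:
        return all(len(k) in (0, 2) for k in self.children)

    def postorder(self) -> range:
        return range(self.n)

    def subtree_leaves(self, i: int) -> list[int]:
        if not self.children[i]:
            return [i]
        out: list[int] = []
        stack = [i]
        while stack:
            j = stack.pop()
            if self.children[j]:
                stack.extend(self.children[j])
            else:
                out.append(j)
        return out

    def newick(self, node: int | None = None) -> str:
        node = self.root if node is None else node
        if not self.children[node]:
            return self.labels[node] or f"n{node}"
        inner = ",".join(self.newick(k) for k in self.children[node])
        return f"({inner})"

    def newick_string(self) -> str:
        return self.newick() + ";"

    def node_name(self, i: int) -> str:
        return self.labels[i] or f"N{i}"


@dataclass(frozen=True)
class EventCosts:
    loss: float = 1.0
    duplication: float = 2.0
    transfer: float = 3.0

    def __post_init__(self) -> None:
        if min(self.loss, self.duplication, self.transfer) < 0:
            raise ValueError("event costs must be >= 0")


@dataclass(frozen=True)
class Event:
    type: str  # speciation | duplication | transfer | loss
    gene_node: str
    species_branch: str
    donor: str | None = None
    recipient: str | None = None


@dataclass
class ReconciliationResult:
    total_cost: float
    events: list[Event]
    mapping: dict[str, str]  # gene node name -> species branch name
    n_optima: int | None = None

    def counts(self) -> dict[str, int]:
        out = {"speciation": 0, "duplication": 0, "transfer": 0, "loss": 0}
        for e in self.events:
            out[e.type] += 1
        return out


def _species_arrays(species: PhyloTree):
    n = species.n
    anc = [[False] * n for _ in range(n)]  # anc[x][y]: x ancestor-or-equal of y
    dist = [[0] * n for _ in range(n)]
    for y in range(n):
        x: int | None = y
        d = 0
        while x is not None:
            anc[x][y] = True
            dist[x][y] = d
            x = species.parent[x]
            d += 1
    incomp = [
        [not anc[x][y] and not anc[y][x] for y in range(n)] for x in range(n)
    ]
    return anc, dist, incomp


def reconcile(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: Mapping[str, str],
    costs: EventCosts | None = None,
    count_optima: bool = False,
) -> ReconciliationResult:
    """Minimum-cost duplication-transfer-loss embedding of a gene tree.

    ``leaf_map`` maps every gene-tree leaf label to a species-tree leaf
    label.  Transfers are allowed between any two species branches not in an
    ancestor-descendant relation (undated model); losses are charged per
    species branch skipped during a descent.
    """
    costs = costs or EventCosts()
    if not gene_tree.is_binary() or not species_tree.is_binary():
        raise ValueError("both trees must be strictly bifurcating")
    G, S = gene_tree, species_tree
    nS = S.n
    anc, dist, incomp = _species_arrays(S)
    L, D, T = costs.loss, costs.duplication, costs.transfer

    # DP tables: per gene node, over species nodes
    c: list[list[float]] = [[INF] * nS for _ in range(G.n)]
    inn: list[list[float]] = [[INF] * nS for _ in range(G.n)]
    # backtracking stores
    choice: list[list[tuple | None]] = [[None] * nS for _ in range(G.n)]
    in_from: list[list[int]] = [[-1] * nS for _ in range(G.n)]  # species node achieving inn
    out_from: list[list[int]] = [[-1] * nS for _ in range(G.n)]
    out: list[list[float]] = [[INF] * nS for _ in range(G.n)]
    # counting tables
    cnt_c = [[0] * nS for _ in range(G.n)] if count_optima else None
    cnt_in = [[0] * nS for _ in range(G.n)] if count_optima else None
    cnt_out = [[0] * nS for _ in range(G.n)] if count_optima else None

    for u in G.postorder():
        if not G.children[u]:
            label = G.labels[u]
            if label not in leaf_map:
                raise ValueError(f"gene leaf {label!r} missing from leaf map")
            sp_label = leaf_map[label]
            if sp_label not in S.leaf_index:
                raise ValueError(f"species {sp_label!r} not in species tree")
            c[u][S.leaf_index[sp_label]] = 0.0
            if count_optima:
                cnt_c[u][S.leaf_index[sp_label]] = 1
        else:
            a, b = G.children[u]
            for x in range(nS):
                options: list[tuple[float, int, tuple]] = []
                if S.children[x]:
                    x1, x2 = S.children[x]
                    s1 = inn[a][x1] + inn[b][x2]
                    s2 = inn[a][x2] + inn[b][x1]
                    options.append((s1, 0, ("spec", a, x1, b, x2)))
                    options.append((s2, 0, ("spec", a, x2, b, x1)))
                options.append((D + inn[a][x] + inn[b][x], 1, ("dup", a, b)))
                options.append((T + inn[a][x] + out[b][x], 2, ("transfer", a, b, x)))
                options.append((T + inn[b][x] + out[a][x], 2, ("transfer", b, a, x)))
                best = min(o[0] for o in options)
                c[u][x] = best
                if best < INF:
                    # deterministic preference: speciation > duplication > transfer
                    chosen = min(
                        (o for o in options if o[0] <= best + _TOL),
                        key=lambda o: o[1],
                    )
                    choice[u][x] = chosen[2]
                    if count_optima:
                        total = 0
                        for cost_o, _pref, det in options:
                            if cost_o > best + _TOL or cost_o == INF:
                                continue
                            if det[0] == "spec":
                                _, ca, xa, cb, xb = det
                                total += cnt_in[ca][xa] * cnt_in[cb][xb]
                            elif det[0] == "dup":
                                total += cnt_in[a][x] * cnt_in[b][x]
                            else:
                                _, stay, move, _x = det
                                total += cnt_in[stay][x] * cnt_out[move][x]
                        cnt_c[u][x] = total

        # inn[u]: min over descendants-or-self with loss per skipped branch
        for x in S.postorder():  # postorder: children before parents
            best = c[u][x]
            src = x if best < INF else -1
            for k in S.children[x]:
                cand = inn[u][k] + L
                if cand >= INF:
                    continue
                if cand < best - _TOL:
                    best, src = cand, in_from[u][k]
                elif cand <= best + _TOL and (src == -1 or in_from[u][k] < src):
                    src = in_from[u][k]  # tie: prefer lowest species node id
            inn[u][x] = best
            in_from[u][x] = src
            if count_optima:
                total = cnt_c[u][x] if c[u][x] <= best + _TOL else 0
                for k in S.children[x]:
                    if inn[u][k] + L <= best + _TOL:
                        total += cnt_in[u][k]
                cnt_in[u][x] = total

        # out[u][x]: best inn over branches incomparable with x
        for x in range(nS):
            best = INF
            src = -1
            for y in range(nS):
                if incomp[x][y] and inn[u][y] < best - _TOL:
                    best = inn[u][y]
                    src = y
            out[u][x] = best
            out_from[u][x] = src
            if count_optima:
                cnt_out[u][x] = sum(
                    cnt_in[u][y]
                    for y in range(nS)
                    if incomp[x][y] and inn[u][y] <= best + _TOL
                )

    root = G.root
    total = min(c[root])
    if total == INF:
        raise ValueError("no valid reconciliation (check leaf map)")
    root_x = min(x for x in range(nS) if c[root][x] <= total + _TOL)

    # ---- backtracking -----------------------------------------------------
    events: list[Event] = []
    mapping: dict[str, str] = {}

    def resolve_in(u: int, x: int) -> None:
        """Descend from x to the species node where c[u] is realised, charging losses."""
        target = in_from[u][x]
        z = x
        while z != target:
            nxt = next(k for k in S.children[z] if anc[k][target])
            sibling = next(k for k in S.children[z] if k != nxt)
            events.append(
                Event("loss", G.node_name(u), S.node_name(sibling))
            )
            z = nxt
        embed(u, z)

    def embed(u: int, x: int) -> None:
        mapping[G.node_name(u)] = S.node_name(x)
        if not G.children[u]:
            return
        det = choice[u][x]
        if det[0] == "spec":
            _, ca, xa, cb, xb = det
            events.append(Event("speciation", G.node_name(u), S.node_name(x)))
            resolve_in(ca, xa)
            resolve_in(cb, xb)
        elif det[0] == "dup":
            _, ca, cb = det
            events.append(Event("duplication", G.node_name(u), S.node_name(x)))
            resolve_in(ca, x)
            resolve_in(cb, x)
        else:
            _, stay, move, donor = det
            y = out_from[move][x]
            events.append(
                Event(
                    "transfer",
                    G.node_name(u),
                    S.node_name(x),
                    donor=S.node_name(donor),
                    recipient=S.node_name(y),
                )
            )
            resolve_in(stay, x)
            resolve_in(move, y)

    embed(root, root_x)

    result = ReconciliationResult(total_cost=total, events=events, mapping=mapping)
    counts = result.counts()
    recon_cost = (
        L * counts["loss"] + D * counts["duplication"] + T * counts["transfer"]
    )
    if abs(recon_cost - total) > 1e-6:
        raise AssertionError(
            f"backtracked event costs {recon_cost} != DP total {total}"
        )
    if count_optima:
        result.n_optima = sum(
            cnt_c[root][x] for x in range(nS) if c[root][x] <= total + _TOL
        )
    return result


# ---------------------------------------------------------------------------
# rooting search for unrooted gene trees
# ---------------------------------------------------------------------------

def _unrooted_adjacency(newick: str) -> tuple[dict[int, list[int]], dict[int, str], int]:
    """Adjacency map of an unrooted tree read from Newick (trifurcating root)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    ids: dict[object, int] = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
            adj[ids[node]] = []
        return ids[node]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = nid(edge.tail_node), nid(edge.head_node)
        adj[a].append(b)
        adj[b].append(a)
    for node in tree:
        i = nid(node)
        if node.taxon is not None:
            labels[i] = node.taxon.label.replace(" ", "_")
    # the dendropy seed node of an unrooted newick has 3 neighbours (or 2 if
    # it was written rooted; then we suppress it)
    seed = ids[tree.seed_node]
    if len(adj[seed]) == 2:
        a, b = adj[seed]
        adj[a] = [x for x in adj[a] if x != seed] + [b]
        adj[b] = [x for x in adj[b] if x != seed] + [a]
        del adj[seed]
    n_leaves = sum(1 for i in adj if len(adj[i]) == 1)
    for i, neigh in adj.items():
        if len(neigh) not in (1, 3):
            raise ValueError("unrooted gene tree must be binary (degree 1 or 3)")
    return adj, labels, n_leaves


def _root_on_edge(
    adj: Mapping[int, list[int]], labels: Mapping[int, str], a: int, b: int
) -> PhyloTree:
    children: list[tuple[int, ...]] = []
    out_labels: list[str | None] = []

    def build(node: int, parent: int) -> int:
        kids = [x for x in adj[node] if x != parent]
        idxs = tuple(build(k, node) for k in kids)
        children.append(idxs)
        out_labels.append(labels.get(node))
        return len(children) - 1

    ia = build(a, b)
    ib = build(b, a)
    children.append((ia, ib))
    out_labels.append(None)
    return PhyloTree(children, out_labels)


def root_search(
    unrooted_newick: str,
    species_tree: PhyloTree,
    leaf_map: Mapping[str, str],
    costs: EventCosts | None = None,
) -> tuple[PhyloTree, ReconciliationResult]:
    """Try every rooting of an unrooted binary gene tree; return the cheapest.

    Ties are broken by the smallest Newick string of the rooted tree.
    """
    adj, labels, n_leaves = _unrooted_adjacency(unrooted_newick)
    if n_leaves < 3:
        raise ValueError("root_search requires >= 3 leaves")
    edges = sorted(
        {tuple(sorted((a, b))) for a in adj for b in adj[a]}
    )
    best: tuple[float, str, PhyloTree, ReconciliationResult] | None = None
    for a, b in edges:
        rooted = _root_on_edge(adj, labels, a, b)
        res = reconcile(rooted, species_tree, leaf_map, costs)
        key = (res.total_cost, rooted.newick_string())
        if best is None or key < (best[0], best[1]):
            best = (res.total_cost, rooted.newick_string(), rooted, res)
    assert best is not None
    return best[2], best[3]


def classify_family_history(
    result: ReconciliationResult, costs: EventCosts | None = None
) -> dict:
    """Summarise a reconciliation into a vertical / HGT-dominated / mixed verdict.

    ``vertical`` iff no transfers; ``HGT-dominated`` iff the transfer cost
    share exceeds half the total cost; otherwise ``mixed``.
    """
    costs = costs or EventCosts()
    counts = result.counts()
    transfers = [e for e in result.events if e.type == "transfer"]
    if counts["transfer"] == 0:
        verdict = "vertical"
    else:
        transfer_cost = costs.transfer * counts["transfer"]
        verdict = "HGT-dominated" if transfer_cost > 0.5 * result.total_cost else "mixed"
    return {
        "n_speciations": counts["speciation"],
        "n_duplications": counts["duplication"],
        "n_transfers": counts["transfer"],
        "n_losses": counts["loss"],
        "transfers": [(e.donor, e.recipient) for e in transfers],
        "verdict": verdict,
    }
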