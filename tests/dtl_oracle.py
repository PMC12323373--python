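"""Independent oracles for reconciliation tests.

Kept deliberately separate from the package: the brute force enumerates
every mapping of gene-tree nodes to species-tree nodes and costs each
mapping by local event rules, instead of running the package's dynamic
program.  Also provides exhaustive rooted-topology enumeration, random tree
generation, and the closed-form duplication-loss cost of the classical LCA
mapping.
"""

from __future__ import annotations

import itertools

import numpy as np

from pulrecon.reconciliation import EventCosts, PhyloTree


def species_arrays(tree: PhyloTree):
    n = tree.n
    anc = np.zeros((n, n), dtype=bool)
    dist = np.zeros((n, n), dtype=np.int64)
    for y in range(n):
        x, d = y, 0
        while x is not None:
            anc[x, y] = True
            dist[x, y] = d
            x = tree.parent[x]
            d += 1
    incomp = ~anc & ~anc.T
    return anc, dist, incomp


def brute_force_min_cost(
    gene: PhyloTree,
    species: PhyloTree,
    leaf_map: dict[str, str],
    costs: EventCosts,
    precomputed=None,
) -> float:
    """Minimum DTL cost by exhaustive enumeration of node mappings.

    For each assignment of every gene internal node to a species node the
    cost decomposes over gene nodes: speciation (children separated into the
    two child subtrees, losses per skipped branch), duplication (both
    children at-or-below, D plus per-edge losses), or transfer (one child
    at-or-below, the other on an incomparable branch, T plus stay-side
    losses).  Invalid assignments cost infinity.
    """
    anc, dist, incomp = precomputed if precomputed is not None else species_arrays(species)
    nS = species.n
    L, D, T = costs.loss, costs.duplication, costs.transfer
    child1 = np.zeros(nS, dtype=np.int64)
    child2 = np.zeros(nS, dtype=np.int64)
    has_kids = np.zeros(nS, dtype=bool)
    for x in range(nS):
        if species.children[x]:
            child1[x], child2[x] = species.children[x]
            has_kids[x] = True

    fixed = {
        i: species.leaf_index[leaf_map[gene.labels[i]]] for i in gene.leaves
    }
    internal = [i for i in range(gene.n) if gene.children[i]]
    pos = {u: j for j, u in enumerate(internal)}
    k = len(internal)
    if k == 0:  # single-leaf gene tree: no events possible
        return 0.0
    grids = np.meshgrid(*([np.arange(nS)] * k), indexing="ij")
    assign = np.stack([g.ravel() for g in grids], axis=1)
    M = assign.shape[0]
    total = np.zeros(M)
    for u in internal:
        a, b = gene.children[u]
        xu = assign[:, pos[u]]
        xa = np.full(M, fixed[a]) if a in fixed else assign[:, pos[a]]
        xb = np.full(M, fixed[b]) if b in fixed else assign[:, pos[b]]
        hk = has_kids[xu]
        x1 = np.where(hk, child1[xu], 0)
        x2 = np.where(hk, child2[xu], 0)
        best = np.full(M, np.inf)
        # speciation, both child orders
        for ca, cb in ((x1, x2), (x2, x1)):
            ok = hk & anc[ca, xa] & anc[cb, xb]
            cost = np.where(ok, L * (dist[ca, xa] + dist[cb, xb]), np.inf)
            best = np.minimum(best, cost)
        # duplication
        ok = anc[xu, xa] & anc[xu, xb]
        best = np.minimum(
            best, np.where(ok, D + L * (dist[xu, xa] + dist[xu, xb]), np.inf)
        )
        # transfer, either child moves
        for stay, move in ((xa, xb), (xb, xa)):
            ok = anc[xu, stay] & incomp[xu, move]
            best = np.minimum(best, np.where(ok, T + L * dist[xu, stay], np.inf))
        total += best
    return float(total.min())


def enumerate_topologies(labels: list[str]) -> list[PhyloTree]:
    """All rooted binary labeled topologies on the given leaf labels.

    Counts follow (2n-3)!!: 1, 1, 3, 15, 105 for n = 1..5.
    """

    def grow(structures, label):
        out = []
        for s in structures:
            out.extend(_insert_everywhere(s, label))
        return out

    def _insert_everywhere(s, label):
        results = [(s, label)]  # new root above everything
        if isinstance(s, tuple):
            left, right = s
            results.extend((l2, right) for l2 in _insert_everywhere(left, label))
            results.extend((left, r2) for r2 in _insert_everywhere(right, label))
        return results

    structures = [labels[0]]
    for label in labels[1:]:
        structures = grow(structures, label)

    def to_tree(s) -> PhyloTree:
        children: list[tuple[int, ...]] = []
        labs: list[str | None] = []

        def build(node) -> int:
            if isinstance(node, tuple):
                idxs = tuple(build(k) for k in node)
                children.append(idxs)
                labs.append(None)
            else:
                children.append(())
                labs.append(node)
            return len(children) - 1

        build(s)
        return PhyloTree(children, labs)

    return [to_tree(s) for s in structures]


def random_topology(labels: list[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform random rooted binary topology by random sequential insertion."""
    structure = labels[0]

    def edges(s):
        yield ()
        if isinstance(s, tuple):
            for i, sub in enumerate(s):
                for path in edges(sub):
                    yield (i,) + path

    def insert(s, path, label):
        if not path:
            return (s, label)
        i = path[0]
        parts = list(s)
        parts[i] = insert(s[i], path[1:], label)
        return tuple(parts)

    for label in labels[1:]:
        all_edges = list(edges(structure))
        path = all_edges[int(rng.integers(0, len(all_edges)))]
        structure = insert(structure, path, label)

    children: list[tuple[int, ...]] = []
    labs: list[str | None] = []

    def build(node) -> int:
        if isinstance(node, tuple):
            idxs = tuple(build(k) for k in node)
            children.append(idxs)
            labs.append(None)
        else:
            children.append(())
            labs.append(node)
        return len(children) - 1

    build(structure)
    return PhyloTree(children, labs)


def dl_cost_closed_form(
    gene: PhyloTree, species: PhyloTree, leaf_map: dict[str, str],
    dup_cost: float, loss_cost: float,
) -> float:
    """Duplication-loss cost of the classical LCA mapping (no transfers).

    m(u) = LCA of the children's mappings; u is a duplication iff m(u)
    equals a child's mapping; losses are depth differences (minus one per
    child at a speciation).
    """
    anc, dist, _ = species_arrays(species)

    def lca(x: int, y: int) -> int:
        z = x
        while not (anc[z, x] and anc[z, y]):
            z = species.parent[z]
        return z

    m: dict[int, int] = {}
    ndup = nloss = 0
    for u in gene.postorder():
        if not gene.children[u]:
            m[u] = species.leaf_index[leaf_map[gene.labels[u]]]
            continue
        a, b = gene.children[u]
        m[u] = lca(m[a], m[b])
        if m[u] == m[a] or m[u] == m[b]:
            ndup += 1
            nloss += dist[m[u], m[a]] + dist[m[u], m[b]]
        else:
            nloss += (dist[m[u], m[a]] - 1) + (dist[m[u], m[b]] - 1)
    return dup_cost * ndup + loss_cost * nloss
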