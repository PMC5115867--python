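"""Independent reference implementations used as test oracles.

These deliberately re-derive each quantity with plain loops and a
different code path from the package implementation.
"""

import itertools

import numpy as np


def mcl_reference(graph, nodes, inflation=2.0, max_iter=100, tol=1e-6):
    """Plain-loop Markov clustering with the same update rules."""
    names = sorted(nodes)
    idx = {g: i for i, g in enumerate(names)}
    n = len(names)
    M = [[0.0] * n for _ in range(n)]
    for (a, b), e in graph.items():
        w = min(200.0, -np.log10(max(e, 1e-300)))
        M[idx[a]][idx[b]] = M[idx[b]][idx[a]] = max(w, 0.0)
    for i in range(n):
        col_max = max(M[j][i] for j in range(n))
        M[i][i] = col_max if col_max > 0 else 1.0

    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] /= s

    normalize(M)
    for _ in range(max_iter):
        exp = [[sum(M[i][k] * M[k][j] for k in range(n))
                for j in range(n)] for i in range(n)]
        inf = [[exp[i][j] ** inflation for j in range(n)]
               for i in range(n)]
        normalize(inf)
        for i in range(n):
            for j in range(n):
                if inf[i][j] < 1e-12:
                    inf[i][j] = 0.0
        normalize(inf)
        change = max(abs(inf[i][j] - M[i][j])
                     for i in range(n) for j in range(n))
        M = inf
        if change < tol:
            break
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if M[i][j] > 1e-8 or M[j][i] > 1e-8:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        seen.add(s)
        while stack:
            u = stack.pop()
            comp.add(names[u])
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(comp)
    return sorted((sorted(c) for c in comps), key=lambda c: (-len(c), c))


def naive_reconcile(gene_tree, stree):
    """Quadratic LCA oracle: every internal node maps to the LCA of all
    leaf species below it, found by root-path intersection."""

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    mapping, events = {}, {}
    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            sp = node.taxon.label.split("|")[0]
            mapping[id(node)] = stree.leaf_node(sp)
            continue
        species_below = {lf.taxon.label.split("|")[0]
                         for lf in node.leaf_iter()}
        paths = [root_path(stree.leaf_node(sp)) for sp in species_below]
        common = set(id(x) for x in paths[0])
        for p in paths[1:]:
            common &= {id(x) for x in p}
        lca = next(x for x in paths[0] if id(x) in common)
        mapping[id(node)] = lca
        events[id(node)] = "duplication" if any(
            mapping[id(c)] is lca for c in node.child_nodes()) \
            else "speciation"
    return mapping, events


def naive_calls(gene_tree, stree, support_min=0.9):
    """Most-recent-duplication calls derived from the quadratic oracle."""
    from edsnet.trees import GeneTree

    mapping, events = naive_reconcile(gene_tree, stree)
    out = {}
    for leaf in gene_tree.tree.leaf_node_iter():
        node, branch = leaf.parent_node, None
        while node is not None:
            if events.get(id(node)) == "duplication":
                branch = stree.branch_label(mapping[id(node)])
                break
            node = node.parent_node
        out[leaf.taxon.label] = branch
    return out


def codon_pathway_subs(c1, c2, table):
    """Average syn/nonsyn steps over stop-free minimal pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, steps, blocked = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*":
                blocked = True
            steps.append(table[cur] == table[nxt])
            cur = nxt
        paths.append((blocked, steps))
    ok = [s for blocked, s in paths if not blocked]
    if not ok:
        ok = [s for _, s in paths]
    syn = sum(sum(s) for s in ok) / len(ok)
    return syn, len(diff) - syn
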