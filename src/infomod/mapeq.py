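"""Map-equation community detection on undirected weighted networks.

For an undirected walk the stationary visit rate of node i is
``p_i = s_i / 2W`` (strength over twice the total edge weight), so no
teleportation enters the codelength.  With ``f(x) = x log2 x`` and module
exit rates ``q_m`` (boundary flow), the two-level map equation is

    L = f(q) - 2 sum_m f(q_m) + sum_m f(q_m + P_m) - sum_i f(p_i)

with ``q = sum_m q_m`` and ``P_m`` the total visit rate inside m — an
algebraic rearrangement of the index-codebook entropy plus the per-module
codebook entropies.  The hierarchical form recurses: an internal module
contributes an index codebook over its own exit rate and its children's
enter rates, and leaf modules contribute the within-module term.

The optimizer is greedy node aggregation with seeded restarts: local moves
from a singleton start, then aggregation of modules into super-nodes,
repeated until no move helps.  Only inter-module flows affect the
objective, so the ``sum_i f(p_i)`` term is a constant carried through the
aggregation levels.

PageRank (with uniform teleportation) is computed separately and used only
to label modules by their highest-ranking member gene.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "ModuleTree",
    "connected_components",
    "visit_rates",
    "codelength",
    "optimize_two_level",
    "build_hierarchy",
    "pagerank",
    "label_modules",
    "write_tree_file",
    "read_tree_file",
    "tree_to_json",
    "tree_from_json",
]

_EPS_BITS = 1e-10  # a split must beat this to count as a real improvement


def _f(x: float) -> float:
    """x * log2(x), continuously extended with f(0) = 0."""
    return x * math.log2(x) if x > 0.0 else 0.0


@dataclass
class ModuleTree:
    """One node of a nested partition: a module, submodule, ... of genes.

    ``path`` is the 1-based colon-separated address ("1:2"); the root has
    path "".  Leaf modules have no children.  ``codelength`` is the module's
    own codebook contribution in bits; on the root it is the total
    hierarchical codelength of the tree.
    """

    path: str
    genes: frozenset
    children: list["ModuleTree"] = field(default_factory=list)
    label: str | None = None
    codelength: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        return len(self.genes)

    def walk(self):
        """Yield every module node, pre-order."""
        yield self
        for child in self.children:
            yield from child.walk()

    def modules_at_depth(self, depth: int) -> list["ModuleTree"]:
        """Modules whose path has exactly ``depth`` components (root = 0)."""
        return [m for m in self.walk() if m.path and m.path.count(":") == depth - 1]

    def max_depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.max_depth() for c in self.children)

    def leaf_assignment(self) -> dict:
        """gene -> path of the finest module containing it."""
        out = {}
        for m in self.walk():
            if m.is_leaf:
                for g in m.genes:
                    out[g] = m.path or "1"
        return out

    def validate(self) -> None:
        for m in self.walk():
            if not m.is_leaf:
                union: set = set()
                total = 0
                for c in m.children:
                    union |= c.genes
                    total += len(c.genes)
                if total != len(union) or union != set(m.genes):
                    raise ValueError(f"children of module '{m.path}' do not partition it")


# -- components and flows ----------------------------------------------------


def connected_components(net: nx.Graph) -> list[frozenset]:
    """Components sorted by size descending, ties by smallest member id."""
    comps = [frozenset(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def _component_flows(net: nx.Graph, component) -> tuple[list, dict, dict]:
    """Nodes (sorted), visit rates, and normalized edge flows w/2W of the
    induced subgraph."""
    nodes = sorted(component)
    sub = net.subgraph(nodes)
    if len(nodes) > 1 and not nx.is_connected(sub):
        raise ValueError("component is not connected in the network")
    strength = {u: 0.0 for u in nodes}
    for u, v, d in sub.edges(data=True):
        w = float(d.get("weight", 1.0))
        if w <= 0:
            raise ValueError("edge weights must be positive")
        if u == v:
            strength[u] += 2.0 * w  # self-loop counts twice, walk convention
        else:
            strength[u] += w
            strength[v] += w
    two_w = sum(strength.values())
    if two_w == 0.0:  # single isolated node
        rates = {u: 1.0 for u in nodes}
        return nodes, rates, {}
    rates = {u: strength[u] / two_w for u in nodes}
    flows = {}
    for u, v, d in sub.edges(data=True):
        if u == v:
            continue  # self-flow never crosses a boundary
        a, b = (u, v) if u <= v else (v, u)
        flows[(a, b)] = float(d.get("weight", 1.0)) / two_w
    return nodes, rates, flows


def visit_rates(net: nx.Graph, component) -> dict:
    """Stationary visit rate p_i = s_i / 2W on the component's subgraph."""
    _, rates, _ = _component_flows(net, component)
    return rates


# -- codelength ---------------------------------------------------------------


def _exit_flow(genes: frozenset, flows: dict) -> float:
    return sum(w for (a, b), w in flows.items() if (a in genes) != (b in genes))


def _tree_codelength(tree: ModuleTree, rates: dict, flows: dict) -> float:
    """Hierarchical map-equation value in bits, from first principles."""

    def module_exit(m: ModuleTree) -> float:
        return _exit_flow(m.genes, flows)

    def contribution(m: ModuleTree, exit_rate: float) -> float:
        if m.is_leaf:
            terms = [exit_rate] + [rates[g] for g in m.genes]
        else:
            terms = [exit_rate] + [module_exit(c) for c in m.children]
        total = sum(terms)
        return _f(total) - sum(_f(t) for t in terms)

    bits = 0.0
    for m in tree.walk():
        if m.is_leaf and m is not tree and m.size == 0:
            continue
        exit_rate = 0.0 if m is tree else module_exit(m)
        if m.is_leaf or m.children:
            bits += contribution(m, exit_rate)
    return bits


def codelength(net: nx.Graph, tree: ModuleTree) -> float:
    """Codelength (bits) of a partition hierarchy over one component.

    A depth-1 tree gives the two-level value; deeper trees the hierarchical
    one.  The tree must partition the component at every level.
    """
    tree.validate()
    nodes, rates, flows = _component_flows(net, tree.genes)
    if set(nodes) != set(tree.genes):
        raise ValueError("tree does not cover the component")
    return _tree_codelength(tree, rates, flows)


# -- two-level optimizer ------------------------------------------------------


class _Level:
    """One aggregation level: super-nodes with flows and inter-node flows."""

    __slots__ = ("p", "adj", "n")

    def __init__(self, p: np.ndarray, adj: list[dict]):
        self.p = p
        self.adj = adj  # adj[i] = {j: flow}, i != j, symmetric
        self.n = len(p)

    def ext(self, i: int) -> float:
        return sum(self.adj[i].values())


def _local_moves(level: _Level, module_of: np.ndarray, rng: np.random.Generator) -> bool:
    """Sweep nodes in random order, applying the best improving move.

    Module bookkeeping: Q (exit flow), P (flow sum), q = sum Q.  Returns
    True if any move was applied.
    """
    n = level.n
    n_mod = int(module_of.max()) + 1
    Q = np.zeros(n_mod)
    P = np.zeros(n_mod)
    for i in range(n):
        P[module_of[i]] += level.p[i]
    for i in range(n):
        mi = module_of[i]
        for j, w in level.adj[i].items():
            if module_of[j] != mi:
                Q[mi] += w
    q_total = float(Q.sum())

    moved_any = False
    improved = True
    sweeps = 0
    while improved and sweeps < 100:
        improved = False
        sweeps += 1
        for i in rng.permutation(n):
            a = module_of[i]
            ext_i = level.ext(i)
            w_to: dict[int, float] = {}
            for j, w in level.adj[i].items():
                w_to[module_of[j]] = w_to.get(module_of[j], 0.0) + w
            w_ia = w_to.get(a, 0.0)

            qa_new = Q[a] - ext_i + 2.0 * w_ia
            pa_new = P[a] - level.p[i]
            if pa_new <= 1e-15:
                qa_new, pa_new = 0.0, 0.0
            base_removed = (
                -2.0 * (_f(qa_new) - _f(Q[a]))
                + (_f(qa_new + pa_new) - _f(Q[a] + P[a]))
            )

            best_delta = -1e-16
            best_b = a
            candidates = [b for b in w_to if b != a]
            if P[a] > level.p[i] + 1e-15:
                candidates.append(-1)  # split out into a fresh singleton module
            for b in candidates:
                qb, pb, w_ib = (0.0, 0.0, 0.0) if b == -1 else (Q[b], P[b], w_to.get(b, 0.0))
                qb_new = qb + ext_i - 2.0 * w_ib
                pb_new = pb + level.p[i]
                q_new = q_total - Q[a] - qb + qa_new + qb_new
                delta = (
                    (_f(q_new) - _f(q_total))
                    + base_removed
                    - 2.0 * (_f(qb_new) - _f(qb))
                    + (_f(qb_new + pb_new) - _f(qb + pb))
                )
                if delta < best_delta - 1e-15:
                    best_delta = delta
                    best_b = b
            if best_b != a:
                b = best_b
                if b == -1:
                    b = n_mod
                    n_mod += 1
                    Q = np.append(Q, 0.0)
                    P = np.append(P, 0.0)
                w_ib = w_to.get(b, 0.0)
                q_total += -Q[a] - Q[b] + (Q[a] - ext_i + 2.0 * w_ia) + (
                    Q[b] + ext_i - 2.0 * w_ib
                )
                Q[a] = Q[a] - ext_i + 2.0 * w_ia
                P[a] -= level.p[i]
                if P[a] <= 1e-15:
                    Q[a], P[a] = 0.0, 0.0
                Q[b] = Q[b] + ext_i - 2.0 * w_ib
                P[b] += level.p[i]
                module_of[i] = b
                improved = True
                moved_any = True
    return moved_any


def _aggregate(level: _Level, module_of: np.ndarray) -> tuple[_Level, np.ndarray]:
    """Collapse modules into super-nodes; returns new level and the map
    old-node -> new-node."""
    mods = sorted(set(int(m) for m in module_of))
    remap = {m: k for k, m in enumerate(mods)}
    node_map = np.array([remap[int(m)] for m in module_of])
    p = np.zeros(len(mods))
    for i in range(level.n):
        p[node_map[i]] += level.p[i]
    adj: list[dict] = [dict() for _ in mods]
    for i in range(level.n):
        a = node_map[i]
        for j, w in level.adj[i].items():
            if j < i:
                continue
            b = node_map[j]
            if a == b:
                continue
            adj[a][b] = adj[a].get(b, 0.0) + w
            adj[b][a] = adj[b].get(a, 0.0) + w
    return _Level(p, adj), node_map


def _two_level_bits(level: _Level, module_of: np.ndarray, const: float) -> float:
    n_mod = int(module_of.max()) + 1
    Q = np.zeros(n_mod)
    P = np.zeros(n_mod)
    for i in range(level.n):
        P[module_of[i]] += level.p[i]
        mi = module_of[i]
        for j, w in level.adj[i].items():
            if module_of[j] != mi:
                Q[mi] += w
    q = float(Q.sum())
    return (
        _f(q)
        - 2.0 * sum(_f(x) for x in Q)
        + sum(_f(Q[m] + P[m]) for m in range(n_mod) if P[m] > 0)
        + const
    )


def _optimize_partition(
    nodes: list, rates: dict, flows: dict, trials: int, seed: int
) -> tuple[list[frozenset], float]:
    """Best two-level partition over seeded greedy-aggregation trials."""
    index = {u: i for i, u in enumerate(nodes)}
    p0 = np.array([rates[u] for u in nodes])
    adj0: list[dict] = [dict() for _ in nodes]
    for (a, b), w in flows.items():
        ia, ib = index[a], index[b]
        adj0[ia][ib] = adj0[ia].get(ib, 0.0) + w
        adj0[ib][ia] = adj0[ib].get(ia, 0.0) + w
    const = -sum(_f(x) for x in p0)
    base = _Level(p0, adj0)

    one_module = np.zeros(len(nodes), dtype=int)
    best_bits = _two_level_bits(base, one_module, const)
    best_assign = one_module

    seeds = np.random.SeedSequence(seed).spawn(max(1, trials))
    for trial_seed in seeds:
        rng = np.random.default_rng(trial_seed)
        level = base
        assign = np.arange(len(nodes))  # original node -> module at current level
        module_of = np.arange(level.n)
        while True:
            moved = _local_moves(level, module_of, rng)
            n_mods = len(set(int(m) for m in module_of))
            if not moved or n_mods == level.n:
                break
            level, node_map = _aggregate(level, module_of)
            assign = node_map[assign]
            module_of = np.arange(level.n)
        final = np.array([module_of[a] for a in assign])
        bits = _two_level_bits(base, _renumber(final), const)
        if bits < best_bits - _EPS_BITS:
            best_bits = bits
            best_assign = _renumber(final)

    groups: dict[int, set] = {}
    for u, m in zip(nodes, best_assign):
        groups.setdefault(int(m), set()).add(u)
    modules = sorted((frozenset(g) for g in groups.values()), key=lambda s: (-len(s), min(s)))
    return modules, best_bits


def _renumber(assign: np.ndarray) -> np.ndarray:
    remap: dict[int, int] = {}
    out = np.empty_like(assign)
    for i, m in enumerate(assign):
        out[i] = remap.setdefault(int(m), len(remap))
    return out


def optimize_two_level(
    net: nx.Graph, component, trials: int = 10, seed: int = 0
) -> ModuleTree:
    """Minimum-codelength flat partition of one connected component.

    Greedy node aggregation from a singleton start with ``trials`` seeded
    restarts; the best trial wins.  The result never exceeds the one-module
    codelength (the one-module partition is always a candidate).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not component:
        raise ValueError("empty component")
    nodes, rates, flows = _component_flows(net, component)
    modules, bits = _optimize_partition(nodes, rates, flows, trials, seed)
    root = ModuleTree(path="", genes=frozenset(nodes), codelength=bits)
    root.children = [
        ModuleTree(path=str(k), genes=m) for k, m in enumerate(modules, start=1)
    ]
    for child in root.children:
        child.codelength = _module_contribution(child.genes, rates, flows)
    return root


def _module_contribution(genes: frozenset, rates: dict, flows: dict) -> float:
    """Within-module codebook bits of a leaf module."""
    q = _exit_flow(genes, flows)
    terms = [q] + [rates[g] for g in genes]
    return _f(sum(terms)) - sum(_f(t) for t in terms)


# -- hierarchy ----------------------------------------------------------------


def build_hierarchy(
    net: nx.Graph,
    component,
    trials: int = 10,
    seed: int = 0,
    max_depth: int = 5,
    min_split: int = 3,
) -> ModuleTree:
    """Nested partition minimizing the hierarchical codelength.

    Starts from the best flat partition, then searches in both directions:
    downward, re-partitioning each module's induced subgraph; and upward,
    clustering the module graph into supermodules (extra index-codebook
    levels).  Either refinement is kept only when it strictly lowers the
    hierarchical codelength of the whole tree (tolerance 1e-10 bits).
    Recursion stops at ``max_depth``, below ``min_split`` genes, or when no
    change helps.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if min_split < 2:
        raise ValueError("min_split must be >= 2")
    nodes, rates, flows = _component_flows(net, component)
    seq_flat, seq_down, seq_up = np.random.SeedSequence(seed).spawn(3)
    modules, _ = _optimize_partition(nodes, rates, flows, trials, int(seq_flat.generate_state(1)[0]))
    tree = ModuleTree(path="", genes=frozenset(nodes))
    tree.children = [ModuleTree(path=str(k), genes=m) for k, m in enumerate(modules, start=1)]

    def split(module: ModuleTree, depth: int, seed_seq: np.random.SeedSequence) -> None:
        if depth >= max_depth or module.size < min_split:
            return
        sub_nodes, sub_rates, sub_flows = _component_flows(net, module.genes)
        if len(sub_flows) == 0:
            return
        candidates, _ = _optimize_partition(
            sub_nodes, sub_rates, sub_flows, trials, int(seed_seq.generate_state(1)[0])
        )
        if len(candidates) < 2:
            return
        # hierarchical contribution of this module, before vs after the split,
        # in the component-level flow normalization
        exit_rate = _exit_flow(module.genes, flows)
        before = _module_contribution(module.genes, rates, flows)
        child_exits = [_exit_flow(c, flows) for c in candidates]
        index_terms = [exit_rate] + child_exits
        after = (
            _f(sum(index_terms))
            - sum(_f(t) for t in index_terms)
            + sum(_module_contribution(c, rates, flows) for c in candidates)
        )
        if after >= before - _EPS_BITS:
            return
        module.children = [ModuleTree(path="", genes=c) for c in candidates]
        for child, cs in zip(module.children, seed_seq.spawn(len(module.children))):
            split(child, depth + 1, cs)

    for child, cs in zip(tree.children, seq_down.spawn(max(1, len(tree.children)))):
        split(child, 1, cs)

    # upward pass: cluster the current top-level modules into supermodules,
    # one extra index level at a time, while the codelength keeps dropping
    bits = _tree_codelength(tree, rates, flows)
    up_seqs = iter(seq_up.spawn(max_depth))
    while len(tree.children) > 2 and tree.max_depth() < max_depth:
        top = tree.children
        # On the module graph the hierarchical index objective IS the
        # two-level map equation with node flow = the module's enter rate
        # (boundary flow), since a supermodule codebook only re-describes
        # module entries, not node visits.
        agg_rates = {i: _exit_flow(m.genes, flows) for i, m in enumerate(top)}
        member_of = {g: i for i, m in enumerate(top) for g in m.genes}
        agg_flows: dict[tuple[int, int], float] = {}
        for (a, b), w in flows.items():
            ia, ib = member_of[a], member_of[b]
            if ia == ib:
                continue
            key = (min(ia, ib), max(ia, ib))
            agg_flows[key] = agg_flows.get(key, 0.0) + w
        groups, _ = _optimize_partition(
            list(range(len(top))), agg_rates, agg_flows, trials,
            int(next(up_seqs).generate_state(1)[0]),
        )
        if len(groups) < 2 or len(groups) >= len(top):
            break
        supers = []
        for members in groups:
            children = [top[i] for i in sorted(members)]
            if len(children) == 1:  # no point wrapping a lone module
                supers.append(children[0])
                continue
            genes = frozenset().union(*(c.genes for c in children))
            supers.append(ModuleTree(path="", genes=genes, children=children))
        candidate = ModuleTree(path="", genes=tree.genes, children=supers)
        cand_bits = _tree_codelength(candidate, rates, flows)
        if cand_bits >= bits - _EPS_BITS:
            break
        tree, bits = candidate, cand_bits

    _finalize_tree(tree, rates, flows)
    return tree


def _finalize_tree(tree: ModuleTree, rates: dict, flows: dict) -> None:
    """Assign deterministic paths and per-module codelength contributions."""

    def address(m: ModuleTree, prefix: str) -> None:
        m.children.sort(key=lambda c: (-c.size, min(c.genes)))
        for k, c in enumerate(m.children, start=1):
            c.path = f"{prefix}{k}"
            address(c, c.path + ":")
    tree.path = ""
    address(tree, "")

    for m in tree.walk():
        if m is tree:
            continue
        exit_rate = _exit_flow(m.genes, flows)
        if m.is_leaf:
            m.codelength = _module_contribution(m.genes, rates, flows)
        else:
            terms = [exit_rate] + [_exit_flow(c.genes, flows) for c in m.children]
            m.codelength = _f(sum(terms)) - sum(_f(t) for t in terms)
    tree.codelength = _tree_codelength(tree, rates, flows)


# -- PageRank and labeling ----------------------------------------------------


def pagerank(
    net: nx.Graph,
    component,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict:
    """Weighted PageRank with uniform teleportation, by power iteration."""
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must lie in (0, 1)")
    nodes = sorted(component)
    n = len(nodes)
    if n == 1:
        return {nodes[0]: 1.0}
    sub = net.subgraph(nodes)
    if not nx.is_connected(sub):
        raise ValueError("component is not connected in the network")
    index = {u: i for i, u in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in sub.edges(data=True):
        w = float(d.get("weight", 1.0))
        W[index[u], index[v]] += w
        if u != v:
            W[index[v], index[u]] += w
    out = W.sum(axis=1)
    T = W / out[:, None]  # row-stochastic transition matrix
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = (1.0 - damping) / n + damping * (x @ T)
        if np.abs(x_new - x).sum() < tol:
            return {u: float(x_new[index[u]]) for u in nodes}
        x = x_new
    raise RuntimeError(f"PageRank did not converge in {max_iter} iterations")


def label_modules(tree: ModuleTree, scores: dict) -> ModuleTree:
    """Label every module by its highest-PageRank member gene (ties:
    lexicographically smaller id).  Mutates and returns the tree."""
    for m in tree.walk():
        missing = [g for g in m.genes if g not in scores]
        if missing:
            raise ValueError(f"no PageRank score for gene(s): {sorted(missing)[:5]}")
        m.label = min(m.genes, key=lambda g: (-scores[g], g))
    return tree


# -- interchange --------------------------------------------------------------


def write_tree_file(tree: ModuleTree, rates: dict, path: str | Path) -> None:
    """Infomap-style .tree: ``path flow "gene" node_index`` per gene."""
    nodes = sorted(tree.genes)
    index = {g: i + 1 for i, g in enumerate(nodes)}
    lines = [
        "# path flow name node_index",
        f"# codelength {tree.codelength:.10f} bits",
    ]
    def emit(m: ModuleTree) -> None:
        if m.is_leaf:
            members = sorted(m.genes, key=lambda g: (-rates[g], g))
            prefix = f"{m.path}:" if m.path else ""
            for k, g in enumerate(members, start=1):
                lines.append(f'{prefix}{k} {rates[g]:.8f} "{g}" {index[g]}')
        else:
            for c in m.children:
                emit(c)
    emit(tree)
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree_file(path: str | Path) -> dict:
    """gene -> module path (leaf position stripped) from a .tree file."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        addr, _flow, name, _idx = line.split(" ", 3)
        gene = name.strip('"')
        out[gene] = addr.rsplit(":", 1)[0] if ":" in addr else addr
    return out


def tree_to_json(tree: ModuleTree, path: str | Path | None = None) -> dict:
    """Nested JSON dump with labels and per-module codelength."""
    def encode(m: ModuleTree) -> dict:
        node = {
            "path": m.path or "root",
            "size": m.size,
            "label": m.label,
            "codelength_bits": round(m.codelength, 10),
        }
        if m.is_leaf:
            node["genes"] = sorted(m.genes)
        else:
            node["children"] = [encode(c) for c in m.children]
        return node
    payload = encode(tree)
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def tree_from_json(payload: dict | str | Path) -> ModuleTree:
    """Inverse of :func:`tree_to_json`."""
    if not isinstance(payload, dict):
        payload = json.loads(Path(payload).read_text())

    def decode(node: dict) -> ModuleTree:
        path = "" if node["path"] == "root" else node["path"]
        if "children" in node:
            children = [decode(c) for c in node["children"]]
            genes = frozenset().union(*(c.genes for c in children))
        else:
            children = []
            genes = frozenset(node["genes"])
        return ModuleTree(
            path=path,
            genes=genes,
            children=children,
            label=node.get("label"),
            codelength=float(node.get("codelength_bits", 0.0)),
        )

    return decode(payload)
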