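"""Light-weight unrooted binary trees for likelihood computation and MCMC.

Trees are stored rooted at an internal node purely as a computational
convenience (time-reversible likelihoods are invariant to the root choice).
Leaves are nodes ``0..n_leaves-1`` in the order of ``taxa``; every internal
node has two children except the designated root, which may have three
(the standard representation of an unrooted binary tree).  Branch lengths
are expected substitutions per site and live on the child end of each edge.

Newick interchange goes through dendropy.
"""

from __future__ import annotations

import numpy as np

import dendropy


class Tree:
    __slots__ = ("taxa", "parent", "children", "blen", "root", "_postorder",
                 "_flat")

    def __init__(self, taxa, parent, children, blen, root):
        self.taxa = tuple(taxa)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.blen = np.asarray(blen, dtype=float)
        self.root = int(root)
        self._postorder = None
        self._flat = None

    # -- construction ------------------------------------------------------

    @classmethod
    def random_topology(cls, taxa, rng: np.random.Generator,
                        branch_lengths=0.1) -> "Tree":
        """Random unrooted binary topology via stepwise addition."""
        n = len(taxa)
        if n < 3:
            raise ValueError("need at least 3 taxa")
        n_nodes = 2 * n - 2
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        root = n  # first internal node
        order = list(rng.permutation(n))
        a, b, c = order[0], order[1], order[2]
        children[root] = [a, b, c]
        parent[[a, b, c]] = root
        edges = [a, b, c]  # node ids identify the edge above them
        next_internal = n + 1
        for leaf in order[3:]:
            e = edges[int(rng.integers(len(edges)))]
            p = parent[e]
            mid = next_internal
            next_internal += 1
            children[p][children[p].index(e)] = mid
            parent[mid] = p
            children[mid] = [e, leaf]
            parent[e] = mid
            parent[leaf] = mid
            edges.extend([leaf, mid])
        if np.isscalar(branch_lengths):
            blen = np.full(n_nodes, float(branch_lengths))
        else:
            blen = np.asarray(branch_lengths, dtype=float)
        blen = blen.copy()
        blen[root] = 0.0
        return cls(taxa, parent, children, blen, root)

    def copy(self) -> "Tree":
        return Tree(self.taxa, self.parent.copy(),
                    [list(c) for c in self.children], self.blen.copy(), self.root)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, v: int) -> bool:
        return v < self.n_leaves

    def edges(self) -> list[int]:
        """Node ids carrying an edge (everything except the root)."""
        return [v for v in range(self.n_nodes) if v != self.root]

    @property
    def total_length(self) -> float:
        return float(sum(self.blen[v] for v in self.edges()))

    def invalidate(self) -> None:
        self._postorder = None
        self._flat = None

    def postorder(self) -> np.ndarray:
        if self._postorder is None:
            out = []
            stack = [self.root]
            seen = []
            while stack:
                v = stack.pop()
                seen.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(seen[::-1], dtype=np.int64)
        return self._postorder

    def flat_children(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (ptr, idx) arrays of the children lists (cached)."""
        if self._flat is None:
            ptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            for v in range(self.n_nodes):
                ptr[v + 1] = ptr[v] + len(self.children[v])
            idx = np.empty(ptr[-1], dtype=np.int64)
            for v in range(self.n_nodes):
                idx[ptr[v]:ptr[v + 1]] = self.children[v]
            self._flat = (ptr, idx)
        return self._flat

    def is_ancestor(self, a: int, d: int) -> bool:
        while d != -1:
            if d == a:
                return True
            d = self.parent[d]
        return False

    # -- splits ------------------------------------------------------------

    def leaf_masks(self) -> np.ndarray:
        """Bitmask of leaves below each node."""
        masks = np.zeros(self.n_nodes, dtype=object)
        for v in self.postorder():
            if self.is_leaf(v):
                masks[v] = 1 << int(v)
            else:
                m = 0
                for c in self.children[v]:
                    m |= masks[c]
                masks[v] = m
        return masks

    def splits(self, with_lengths: bool = False):
        """Non-trivial splits as normalised bitmasks (side without leaf 0)."""
        full = (1 << self.n_leaves) - 1
        masks = self.leaf_masks()
        out = {} if with_lengths else set()
        for v in self.edges():
            if self.is_leaf(v):
                continue
            m = int(masks[v])
            if m & 1:
                m = full ^ m
            if bin(m).count("1") < 2:
                continue
            if with_lengths:
                out[m] = self.blen[v]
            else:
                out.add(m)
        return out

    def leaf_lengths(self) -> np.ndarray:
        return self.blen[: self.n_leaves].copy()

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_leaf(v):
                return f"{self.taxa[v]}:{self.blen[v]:.10g}"
            inner = ",".join(rec(c) for c in self.children[v])
            if v == self.root:
                return f"({inner});"
            return f"({inner}):{self.blen[v]:.10g}"

        return rec(self.root)

    @classmethod
    def from_newick(cls, newick: str, taxa=None) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        return cls.from_dendropy(dt, taxa=taxa)

    @classmethod
    def from_dendropy(cls, dt: "dendropy.Tree", taxa=None) -> "Tree":
        """Convert (and unroot, suppressing any degree-2 root)."""
        dt = dt.clone(depth=1)
        dt.suppress_unifurcations()
        if len(dt.seed_node.child_nodes()) == 2:
            # merge the two root edges: unrooted representation
            a, b = dt.seed_node.child_nodes()
            keep, fold = (a, b) if not a.is_leaf() else (b, a)
            if keep.is_leaf():
                raise ValueError("tree too small to unroot")
            fold.edge.length = (fold.edge.length or 0.0) + (keep.edge.length or 0.0)
            dt.seed_node.remove_child(keep)
            for ch in list(keep.child_nodes()):
                keep.remove_child(ch)
                dt.seed_node.add_child(ch)
        leaves = [lf.taxon.label for lf in dt.leaf_node_iter()]
        if taxa is None:
            taxa = sorted(leaves)
        index = {lab: i for i, lab in enumerate(taxa)}
        n = len(taxa)
        n_nodes = 2 * n - 2
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        blen = np.zeros(n_nodes)
        next_internal = [n]

        def rec(node) -> int:
            if node.is_leaf():
                v = index[node.taxon.label]
            else:
                v = next_internal[0]
                next_internal[0] += 1
                for ch in node.child_nodes():
                    c = rec(ch)
                    parent[c] = v
                    children[v].append(c)
            blen[v] = node.edge.length or 0.0
            return v

        root = rec(dt.seed_node)
        blen[root] = 0.0  # no stem edge in the unrooted representation
        return cls(taxa, parent, children, blen, root)

    def to_dendropy(self, taxon_namespace=None) -> "dendropy.Tree":
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            preserve_underscores=True, taxon_namespace=taxon_namespace,
        )

    # -- rerooting (for invariance checks) ---------------------------------

    def rerooted(self, new_root: int) -> "Tree":
        """Same unrooted tree, computationally rooted at ``new_root``.

        ``new_root`` must be an internal node.  Edge lengths are preserved;
        the edge that previously pointed root-ward is reversed.
        """
        if self.is_leaf(new_root):
            raise ValueError("root must be internal")
        t = self.copy()
        path = []
        v = new_root
        while v != t.root:
            path.append(v)
            v = int(t.parent[v])
        path.append(t.root)
        old_blen = {v: t.blen[v] for v in path}
        for child, par in zip(path[:-1], path[1:]):
            t.children[par].remove(child)
            t.children[child].append(par)
            t.blen[par] = old_blen[child]
        for child, par in zip(path[:-1], path[1:]):
            t.parent[par] = child
        t.parent[new_root] = -1
        t.blen[new_root] = 0.0
        t.root = new_root
        t.invalidate()
        return t
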