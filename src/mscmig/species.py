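"""Rooted species trees for the multispecies coalescent with migration.

A species tree defines the populations of the MSC-M model: every node
(tip or internal) is a population with its own mutation-scaled size theta,
and every internal node has a divergence time tau.  Time runs from 0 at the
present into the past and is measured in expected mutations per site.  A
population labelled ``j`` is extant on the half-open interval
``[tau_j, tau_parent(j))`` (tips are born at 0; the root population never
dies).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpeciesTree"]


@dataclass
class SpeciesTree:
    """Rooted binary species tree with labelled populations.

    Nodes are indexed ``0 .. 2S-2`` with the ``S`` tips first (in the order
    they appear in the Newick string) and the root last.  Divergence times
    and population sizes are carried separately in a :class:`ParamSet`; the
    tree only fixes the topology and the labels.
    """

    labels: list[str]
    parent: np.ndarray  # int, -1 for the root
    children: np.ndarray  # (n_nodes, 2) int, -1 for tips
    n_tips: int

    label_to_node: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_to_node:
            self.label_to_node = {lab: i for i, lab in enumerate(self.labels)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        """Parse a rooted binary Newick string with labelled internal nodes.

        Branch lengths, if present, are ignored: divergence times are model
        parameters, not tree annotations.  Example: ``"((A, B)S, C)R;"``.
        """
        import dendropy

        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
        tips = [lf for lf in tree.leaf_node_iter()]
        n_tips = len(tips)
        n_nodes = 2 * n_tips - 1

        def node_label(nd) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return str(nd.taxon.label).replace(" ", "_")
            if nd.label:
                return str(nd.label).replace(" ", "_")
            raise ValueError("every species-tree node needs a label")

        labels: list[str] = [""] * n_nodes
        index: dict[int, int] = {}
        i_tip = 0
        i_int = n_tips
        # tips in newick order, then internals in postorder (root last)
        for nd in tree.postorder_node_iter():
            pass
        for nd in tree.leaf_node_iter():
            index[id(nd)] = i_tip
            labels[i_tip] = node_label(nd)
            i_tip += 1
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            kids = nd.child_nodes()
            if len(kids) != 2:
                raise ValueError("species tree must be binary")
            index[id(nd)] = i_int
            labels[i_int] = node_label(nd)
            i_int += 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children = np.full((n_nodes, 2), -1, dtype=np.int64)
        for nd in tree.postorder_node_iter():
            i = index[id(nd)]
            if not nd.is_leaf():
                kids = nd.child_nodes()
                children[i, 0] = index[id(kids[0])]
                children[i, 1] = index[id(kids[1])]
                for k in kids:
                    parent[index[id(k)]] = i
        if len(set(labels)) != n_nodes:
            raise ValueError("species-tree labels must be unique")
        return cls(labels=labels, parent=parent, children=children, n_tips=n_tips)

    def to_newick(self) -> str:
        out = _io.StringIO()

        def rec(i: int) -> None:
            if self.children[i, 0] >= 0:
                out.write("(")
                rec(self.children[i, 0])
                out.write(", ")
                rec(self.children[i, 1])
                out.write(")")
            out.write(self.labels[i])

        rec(self.root)
        out.write(";")
        return out.getvalue()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def internal_nodes(self) -> range:
        return range(self.n_tips, self.n_nodes)

    def node(self, label: str) -> int:
        try:
            return self.label_to_node[label]
        except KeyError:
            raise KeyError(f"unknown population label {label!r}") from None

    def is_ancestor(self, anc: int, node: int) -> bool:
        while node != -1:
            if node == anc:
                return True
            node = int(self.parent[node])
        return False

    def mrca(self, a: int, b: int) -> int:
        seen = set()
        while a != -1:
            seen.add(a)
            a = int(self.parent[a])
        while b not in seen:
            b = int(self.parent[b])
        return b

    # -- time-dependent queries (tau passed explicitly) --------------------

    def lifespan(self, pop: int, tau: np.ndarray) -> tuple[float, float]:
        """Half-open extant interval ``[start, end)`` of a population."""
        start = float(tau[pop])
        p = int(self.parent[pop])
        end = np.inf if p == -1 else float(tau[p])
        return start, end

    def ancestor_at(self, pop: int, t: float, tau: np.ndarray) -> int:
        """The population containing lineage ancestry of `pop` at time t>=tau[pop]."""
        p = int(self.parent[pop])
        while p != -1 and t >= tau[p]:
            pop = p
            p = int(self.parent[pop])
        return pop

    def validate_tau(self, tau: np.ndarray) -> list[str]:
        """Check tau is 0 at tips, positive at internals, child < parent."""
        problems = []
        for i in range(self.n_tips):
            if tau[i] != 0.0:
                problems.append(f"tip {self.labels[i]} must have time 0")
        for i in self.internal_nodes:
            if not tau[i] > 0.0:
                problems.append(f"internal node {self.labels[i]} needs tau > 0")
            for c in self.children[i]:
                if tau[c] >= tau[i]:
                    problems.append(
                        f"node {self.labels[i]}: child {self.labels[c]} age "
                        f"{tau[c]} >= parent age {tau[i]}"
                    )
        return problems
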