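"""Haplogroup trees, binary-marker panels and tree-based Y-chromosome calling.

A haplogroup tree is a rooted tree whose nodes are haplogroup labels; each
non-root node may be defined by one or more binary markers (SNPs on the
non-recombining Y, or control/coding-region substitutions for mtDNA).  An
individual genotyped for a panel of such markers is assigned to the deepest
node whose path from the root is supported by derived alleles, with the
paragroup convention: a carrier that is ancestral for every typed
downstream marker belongs to the paragroup of that node and is rendered
with a star suffix (e.g. ``C*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConflictError, InputError

ANCESTRAL = "ancestral"
DERIVED = "derived"
MISSING = "missing"


@dataclass(frozen=True)
class Marker:
    """A binary marker defining a haplogroup node.

    Parameters
    ----------
    name : str
        Marker identifier, e.g. ``"M9"`` or ``"RPS4Y"``.
    node : str
        Haplogroup label the derived allele defines.
    ancestral_allele, derived_allele : str
        Single-letter nucleotide states; must differ.
    """

    name: str
    node: str
    ancestral_allele: str
    derived_allele: str

    def __post_init__(self):
        if self.ancestral_allele == self.derived_allele:
            raise InputError(
                f"marker {self.name}: ancestral and derived alleles are equal"
            )


class HaploTree:
    """Rooted haplogroup tree with marker-annotated nodes.

    Parameters
    ----------
    parent : dict
        Map node -> parent label; exactly one node (the root) maps to ``None``.
    markers : iterable of Marker, optional
        Panel of markers; every marker's node must be present in the tree.
    """

    def __init__(self, parent, markers=()):
        self.parent = dict(parent)
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise InputError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise InputError(f"node {node!r} has unknown parent {par!r}")
        # depth doubles as a cycle/reachability check
        self._depth = {}
        for node in self.parent:
            seen = []
            cur = node
            while cur is not None and cur not in self._depth:
                seen.append(cur)
                cur = self.parent[cur]
                if len(seen) > len(self.parent):
                    raise InputError("cycle detected in haplogroup tree")
            base = -1 if cur is None else self._depth[cur]
            for i, n in enumerate(reversed(seen)):
                self._depth[n] = base + 1 + i

        self.children = {n: [] for n in self.parent}
        for node, par in self.parent.items():
            if par is not None:
                self.children[par].append(node)

        self.markers = {n: [] for n in self.parent}
        self.marker_by_name = {}
        for m in markers:
            if m.node not in self.parent:
                raise InputError(f"marker {m.name} names unknown node {m.node!r}")
            self.markers[m.node].append(m)
            self.marker_by_name[m.name] = m

    @property
    def nodes(self):
        return list(self.parent)

    def depth(self, node):
        return self._depth[node]

    def path(self, node):
        """Root-to-node path, inclusive."""
        out = []
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out[::-1]

    def is_ancestor(self, anc, node):
        """True if ``anc`` lies on the root path of ``node`` (or equals it)."""
        return anc in self.path(node)

    def node_for_marker(self, marker_name):
        """Haplogroup label defined by a marker, e.g. ``"M95" -> "O2a1"``."""
        return self.marker_by_name[marker_name].node


@dataclass
class YGenotype:
    """Binary-marker genotype for one male sample.

    ``states`` maps marker name to one of ``"ancestral"``, ``"derived"``,
    ``"missing"``.
    """

    sample_id: str
    population: str
    states: dict = field(default_factory=dict)

    def typed(self):
        return {m: s for m, s in self.states.items() if s != MISSING}


@dataclass(frozen=True)
class YAssignment:
    """Result of tree-based Y calling: node label plus paragroup status."""

    node: str
    paragroup: bool

    @property
    def rendered_label(self):
        return self.node + "*" if self.paragroup else self.node


def call_y_haplogroup(genotype: YGenotype, tree: HaploTree) -> YAssignment:
    """Assign a Y haplogroup from binary marker states on a SNP tree.

    The call is the deepest node with a typed derived path-defining marker
    such that no typed marker on the root path is ancestral and no derived
    marker sits on an incompatible branch.  Missing markers on the accepted
    path are tolerated when a deeper typed derived marker supports the call.
    The paragroup flag is set when at least one child-defining marker was
    typed and every typed child-defining marker is ancestral.

    Raises
    ------
    InputError
        All markers missing, or no typed marker belongs to the tree panel.
    ConflictError
        Derived states on two incompatible branches, or an ancestral state
        upstream of a derived one.
    """
    typed = {
        m: s for m, s in genotype.states.items()
        if s != MISSING and m in tree.marker_by_name
    }
    if not typed:
        raise InputError(
            f"sample {genotype.sample_id}: no typed marker overlaps the panel"
        )

    derived_nodes = {}
    for mname, state in typed.items():
        if state == DERIVED:
            derived_nodes.setdefault(tree.node_for_marker(mname), mname)

    if not derived_nodes:
        node = tree.root
    else:
        # all derived nodes must lie on a single root path
        deepest = max(derived_nodes, key=tree.depth)
        for other, mname in derived_nodes.items():
            if not tree.is_ancestor(other, deepest):
                raise ConflictError(
                    f"sample {genotype.sample_id}: derived alleles at "
                    f"{derived_nodes[deepest]} ({deepest}) and {mname} ({other}) "
                    "lie on incompatible branches",
                    markers=(derived_nodes[deepest], mname),
                )
        # typed markers on the accepted path must not be ancestral
        for pnode in tree.path(deepest):
            for m in tree.markers[pnode]:
                if typed.get(m.name) == ANCESTRAL:
                    raise ConflictError(
                        f"sample {genotype.sample_id}: marker {m.name} ({pnode}) "
                        f"is ancestral upstream of derived "
                        f"{derived_nodes[deepest]} ({deepest})",
                        markers=(m.name, derived_nodes[deepest]),
                    )
        node = deepest

    child_marker_states = [
        typed[m.name]
        for child in tree.children[node]
        for m in tree.markers[child]
        if m.name in typed
    ]
    paragroup = bool(child_marker_states) and all(
        s == ANCESTRAL for s in child_marker_states
    )
    return YAssignment(node=node, paragroup=paragroup)
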