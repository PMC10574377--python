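"""SMILES to labeled rooted DAG encoding for graph machines.

A molecule is encoded as a hydrogen-suppressed labeled graph: every node is
a heavy atom carrying its element symbol, a *degree label* (the sum of
kekulized bond orders to heavy neighbours, so an olefinic CHCl carbon has
degree 3) and optional stereochemical labels:

* ``iso1``/``iso2`` encode double-bond configuration — an E bond labels
  both sp2 atoms ``{iso1, iso1}``, a Z bond ``{iso1, iso2}``;
* ``chi1``/``chi2`` encode *relative* tetrahedral configuration: a
  canonical reference centre receives ``chi1`` and every other centre
  ``chi1`` ("like" the reference) or ``chi2`` ("unlike"), so enantiomers
  receive identical labels while diastereomers differ.

A molecule with a single tetrahedral stereocentre is a potential enantiomer
whose mirror image has the same physical properties, so its chi label is
discarded (:func:`strip_single_stereocenter`).

Rings are opened (one edge removed per independent cycle, degree labels
kept frozen so the disconnection stays visible) and all remaining edges are
oriented toward a *root* node whose output carries the property estimate.
The root may be forced with atom map 1 in the SMILES (``[C:1]1=NN=CC=C1``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import rdCIPLabeler

RDLogger.DisableLog("rdApp.warning")

#: Heavy-atom alphabet of the reference model (16 atom types counting H).
DEFAULT_ALPHABET: tuple[str, ...] = (
    "B", "C", "N", "O", "F", "Si", "P", "S", "Cl",
    "Ti", "Ge", "Se", "Br", "Sn", "I",
)

STEREO_LABELS: tuple[str, ...] = ("iso1", "iso2", "chi1", "chi2")


class SmilesError(ValueError):
    """The SMILES string could not be parsed into a molecule."""


class MixtureError(SmilesError):
    """Multi-component SMILES: a mixture is not a well-defined structure."""


class DisconnectedGraphError(ValueError):
    """The molecular graph is not a single connected component."""


class UnknownElementWarning(UserWarning):
    """An element outside the configured alphabet was encountered.

    Such atoms are kept in the graph; their atom-type indicator is all-zero
    so the corresponding label weights contribute nothing to the model.
    """


@dataclass(frozen=True)
class AtomNode:
    """One heavy atom: element, degree label and stereo labels."""

    atom_type: str
    degree_label: int
    stereo_labels: frozenset[str] = frozenset()
    root_override: bool = False

    def __post_init__(self) -> None:
        if self.degree_label < 0:
            raise ValueError("degree_label must be >= 0")
        bad = set(self.stereo_labels) - set(STEREO_LABELS)
        if bad:
            raise ValueError(f"unknown stereo labels: {sorted(bad)}")
        if {"iso1", "iso2"} <= self.stereo_labels:
            raise ValueError("at most one iso label per node")
        if {"chi1", "chi2"} <= self.stereo_labels:
            raise ValueError("at most one chi label per node")


@dataclass
class MolGraph:
    """Hydrogen-suppressed labeled molecular graph."""

    nodes: list[AtomNode]
    edges: list[tuple[int, int, int]]  # (u, v, bond order), u < v
    source_smiles: str
    unknown_elements: tuple[str, ...] = ()
    # RDKit molecule and canonical ranks kept for stereo perception and
    # deterministic tie-breaking; not part of the graph's value semantics.
    rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)
    canon_ranks: tuple[int, ...] = field(default=(), repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degree_sum(self) -> int:
        return sum(n.degree_label for n in self.nodes)


@dataclass
class RootedDAG:
    """Acyclic directed computation graph with a single root/output node.

    ``children[v]`` lists the tree children of ``v`` in canonical order
    (sorted by canonical subtree key); every non-root node's single
    outgoing edge points to ``parent[v]``.  ``broken_edges`` records the
    ring bonds removed during cycle opening; degree labels are those of the
    source molecule, *not* decremented by the removal.
    """

    nodes: tuple[AtomNode, ...]
    root: int
    parent: tuple[int, ...]  # parent[root] == -1
    children: tuple[tuple[int, ...], ...]
    broken_edges: tuple[tuple[int, int], ...]
    source_smiles: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def topological_order(self) -> list[int]:
        """Nodes ordered leaves-first (every child before its parent)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order


def _prepare_rdmol(smiles: str) -> Chem.Mol:
    if "." in smiles:
        raise MixtureError(
            f"multi-component SMILES {smiles!r}: mixtures are not "
            "well-defined structures"
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"could not parse SMILES {smiles!r}")
    mol = Chem.RemoveHs(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    rdCIPLabeler.AssignCIPLabels(mol)
    return mol


def _canonical_ranks(mol: Chem.Mol) -> tuple[int, ...]:
    # Ranks must be enantiomer-invariant (no chirality) and independent of
    # atom maps, which are only a root-override transport.
    clean = Chem.Mol(mol)
    for atom in clean.GetAtoms():
        atom.SetAtomMapNum(0)
    return tuple(Chem.CanonicalRankAtoms(clean, includeChirality=False))


def parse_smiles(
    smiles: str, alphabet: Sequence[str] = DEFAULT_ALPHABET
) -> MolGraph:
    """Parse a single-component SMILES into a hydrogen-suppressed graph.

    Each node's degree label is the sum of kekulized bond orders to its
    heavy neighbours.  Elements outside ``alphabet`` raise
    :class:`UnknownElementWarning` and are recorded on the graph; their
    label weights are treated as zero downstream.  Stereo labels are *not*
    assigned here — see :func:`assign_stereo_labels`.
    """
    mol = _prepare_rdmol(smiles)
    ranks = _canonical_ranks(mol)

    override_seen = False
    nodes: list[AtomNode] = []
    unknown: set[str] = set()
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol == "H":
            raise SmilesError(f"explicit hydrogen node survived in {smiles!r}")
        if symbol not in alphabet:
            unknown.add(symbol)
        degree = sum(
            int(round(bond.GetBondTypeAsDouble())) for bond in atom.GetBonds()
        )
        is_root = atom.GetAtomMapNum() == 1
        if is_root:
            if override_seen:
                raise SmilesError("atom map 1 used on more than one atom")
            override_seen = True
        nodes.append(AtomNode(symbol, degree, frozenset(), is_root))

    if unknown:
        warnings.warn(
            f"elements outside the alphabet in {smiles!r}: {sorted(unknown)}; "
            "their atom-type weights will be zero",
            UnknownElementWarning,
            stacklevel=2,
        )

    edges = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = int(round(bond.GetBondTypeAsDouble()))
        edges.append((min(u, v), max(u, v), order))
    edges.sort()

    return MolGraph(
        nodes=nodes,
        edges=edges,
        source_smiles=smiles,
        unknown_elements=tuple(sorted(unknown)),
        rdmol=mol,
        canon_ranks=ranks,
    )


def _add_label(node: AtomNode, label: str) -> AtomNode:
    kind = label[:3]
    if any(lab.startswith(kind) for lab in node.stereo_labels):
        return node  # at most one iso and one chi label per node
    return replace(node, stereo_labels=node.stereo_labels | {label})


def assign_stereo_labels(graph: MolGraph) -> MolGraph:
    """Attach iso (E/Z) and chi (relative R/S) labels to the graph nodes.

    E double bonds label both sp2 atoms ``iso1``; Z bonds give ``iso1`` to
    the lower-canonical-rank atom and ``iso2`` to the other.  Tetrahedral
    centres are labeled *relative* to the centre of lowest canonical rank:
    that reference gets ``chi1``, every other centre ``chi1`` if its CIP
    descriptor equals the reference's ("like") and ``chi2`` otherwise, so
    mirror images map to identical graphs.  Unlabeled stereo elements
    simply contribute no labels.
    """
    mol = graph.rdmol
    if mol is None:
        raise ValueError("MolGraph lacks its RDKit molecule; re-parse first")
    ranks = graph.canon_ranks
    nodes = list(graph.nodes)

    stereo_bonds = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        if not bond.HasProp("_CIPCode"):
            continue
        code = bond.GetProp("_CIPCode")
        if code not in ("E", "Z"):
            continue
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        stereo_bonds.append((min((ranks[u], u), (ranks[v], v)), code, u, v))
    for _, code, u, v in sorted(stereo_bonds):
        lo, hi = sorted((u, v), key=lambda i: (ranks[i], i))
        if code == "E":
            nodes[lo] = _add_label(nodes[lo], "iso1")
            nodes[hi] = _add_label(nodes[hi], "iso1")
        else:
            nodes[lo] = _add_label(nodes[lo], "iso1")
            nodes[hi] = _add_label(nodes[hi], "iso2")

    centers = []
    for atom in mol.GetAtoms():
        if atom.HasProp("_CIPCode"):
            code = atom.GetProp("_CIPCode")
            if code in ("R", "S"):
                centers.append((atom.GetIdx(), code))
    if centers:
        ref_idx, ref_code = min(centers, key=lambda c: (ranks[c[0]], c[0]))
        for idx, code in centers:
            nodes[idx] = _add_label(
                nodes[idx], "chi1" if code == ref_code else "chi2"
            )

    return replace(graph, nodes=nodes)


def strip_single_stereocenter(graph: MolGraph) -> MolGraph:
    """Drop chi labels when the molecule has exactly one stereocentre.

    A compound with a single tetrahedral stereocentre and no stereo double
    bond is a potential enantiomer; mirror images share their physical
    properties, so the label carries no information and is removed.  All
    other graphs pass through unchanged.
    """
    chi_nodes = [
        i for i, n in enumerate(graph.nodes)
        if n.stereo_labels & {"chi1", "chi2"}
    ]
    has_iso = any(
        n.stereo_labels & {"iso1", "iso2"} for n in graph.nodes
    )
    if len(chi_nodes) != 1 or has_iso:
        return graph
    nodes = list(graph.nodes)
    i = chi_nodes[0]
    nodes[i] = replace(
        nodes[i], stereo_labels=nodes[i].stereo_labels - {"chi1", "chi2"}
    )
    return replace(graph, nodes=nodes)


def _subtree_keys(
    nodes: Sequence[AtomNode], children: list[list[int]], root: int
) -> dict[int, tuple]:
    """Canonical subtree key per node (atom, degree, labels, child keys)."""
    keys: dict[int, tuple] = {}

    def key(v: int) -> tuple:
        if v in keys:
            return keys[v]
        child_keys = sorted(key(c) for c in children[v])
        n = nodes[v]
        keys[v] = (
            n.atom_type,
            n.degree_label,
            tuple(sorted(n.stereo_labels)),
            tuple(child_keys),
        )
        return keys[v]

    key(root)
    return keys


def to_rooted_dag(
    graph: MolGraph, root_override: Optional[int] = None
) -> RootedDAG:
    """Open rings and orient the graph toward a root node.

    The root is, in order of precedence: the ``root_override`` argument, a
    node flagged by atom map 1 in the SMILES, or the default — a node of
    minimal eccentricity (graph centre), ties broken by lowest canonical
    rank then atom index.  One edge is removed per independent cycle (the
    edge of the cycle whose endpoints lie jointly farthest from the root);
    degree labels are *not* decremented, so the disconnection remains
    encoded.  Children of each node are ordered by canonical subtree key.
    """
    n = graph.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for u, v, _order in graph.edges:
        G.add_edge(u, v)
    if n == 0:
        raise ValueError("empty molecular graph")
    if not nx.is_connected(G):
        raise DisconnectedGraphError(
            f"molecular graph of {graph.source_smiles!r} is disconnected"
        )

    ranks = graph.canon_ranks or tuple(range(n))
    if root_override is not None:
        if not 0 <= root_override < n:
            raise ValueError(f"root_override {root_override} out of range")
        root = root_override
    else:
        flagged = [i for i, nd in enumerate(graph.nodes) if nd.root_override]
        if flagged:
            root = flagged[0]
        else:
            ecc = nx.eccentricity(G)
            root = min(range(n), key=lambda i: (ecc[i], ranks[i], i))

    dist = nx.single_source_shortest_path_length(G, root)
    broken: list[tuple[int, int]] = []
    while True:
        cycles = nx.cycle_basis(G)
        if not cycles:
            break
        cycles.sort(key=lambda c: tuple(sorted(c)))
        cyc = cycles[0]
        cyc_edges = [
            tuple(sorted((cyc[i], cyc[(i + 1) % len(cyc)])))
            for i in range(len(cyc))
        ]
        best = max(
            cyc_edges,
            key=lambda e: (
                dist[e[0]] + dist[e[1]],
                max(dist[e[0]], dist[e[1]]),
                tuple(sorted(((ranks[e[0]], e[0]), (ranks[e[1]], e[1])))),
            ),
        )
        G.remove_edge(*best)
        broken.append(best)

    parent = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for child, par in nx.bfs_predecessors(G, root):
        parent[child] = par
        children[par].append(child)

    keys = _subtree_keys(graph.nodes, children, root)
    for v in range(n):
        children[v].sort(key=lambda c: (keys[c], ranks[c], c))

    return RootedDAG(
        nodes=tuple(graph.nodes),
        root=root,
        parent=tuple(parent),
        children=tuple(tuple(c) for c in children),
        broken_edges=tuple(sorted(broken)),
        source_smiles=graph.source_smiles,
    )


def smiles_to_dag(
    smiles: str,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    root_override: Optional[int] = None,
    strip: bool = True,
    label_stereo: bool = True,
) -> RootedDAG:
    """Full encoding pipeline: parse, label, strip, open rings, root.

    With ``label_stereo=False`` the stereo-labeling step is skipped
    entirely, yielding the encoding an unspecified (mixture) SMILES of the
    same skeleton would receive.
    """
    graph = parse_smiles(smiles, alphabet)
    if label_stereo:
        graph = assign_stereo_labels(graph)
        if strip:
            graph = strip_single_stereocenter(graph)
    return to_rooted_dag(graph, root_override=root_override)


def _node_dict(dag: RootedDAG, v: int, cuts: dict[int, int]) -> dict:
    d = {
        "a": dag.nodes[v].atom_type,
        "d": dag.nodes[v].degree_label,
        "s": sorted(dag.nodes[v].stereo_labels),
        "c": [_node_dict(dag, c, cuts) for c in dag.children[v]],
    }
    if cuts.get(v):
        d["x"] = cuts[v]
    return d


def canonical_serialization(dag: RootedDAG) -> str:
    """Byte-stable JSON of the rooted DAG (labels, structure, ring cuts).

    Two molecules receive identical serializations exactly when their
    labeled rooted DAGs are isomorphic, so this string doubles as the
    deduplication key for the curation rules.
    """
    cuts: dict[int, int] = {}
    for u, v in dag.broken_edges:
        cuts[u] = cuts.get(u, 0) + 1
        cuts[v] = cuts.get(v, 0) + 1
    payload = {
        "root": _node_dict(dag, dag.root, cuts),
        "n_broken": len(dag.broken_edges),
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))
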