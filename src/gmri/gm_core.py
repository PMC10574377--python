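"""The shared node function and its composition along a rooted DAG.

A graph machine instantiates one *shared* single-hidden-layer feed-forward
unit (tanh hidden neurons, linear output) at every heavy atom of a
molecule's rooted DAG.  Each instance receives the outputs of the node's
children in fixed canonical slots (zero-padded) together with indicator
inputs for the node's labels — atom type, degree, iso/chi stereo labels —
realized as bias units whose weights are selected by the active labels.
The root instance's scalar output is the property estimate.

Because the same parameter vector θ is shared by every node of every
graph, the model's size is that of the node function alone, and the
gradient of a prediction with respect to θ sums the contributions of all
node instances (weight sharing).

Parameter layout (flat vector θ)::

    n_hidden > 0: [W (n_hidden × n_features), b_hidden (n_hidden),
                   w_out (n_hidden), b_out]
    n_hidden = 0: [w (n_features), b_out]            # linear node function

so ``parameter_count = n_hidden*(n_features+1) + n_hidden + 1`` with an
output bias, and ``n_features + 1`` in the degenerate linear case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .chem_graph import DEFAULT_ALPHABET, STEREO_LABELS, RootedDAG


class ArityError(ValueError):
    """A node has more children than the architecture provides slots for."""


@dataclass(frozen=True)
class Architecture:
    """Hyper-structure of the shared node function.

    ``n_features`` counts the trainable input lines: child slots, one-hot
    atom type, one-hot degree (D0..Dmax) and the four stereo indicators.
    The constant bias unit of each neuron is carried as an explicit bias
    parameter rather than an always-1 input column, which keeps the
    n_hidden = 0 linear case full-rank (single intercept).
    """

    n_hidden: int = 8
    n_child_slots: int = 4
    atom_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    max_degree: int = 6
    output_bias: bool = True

    def __post_init__(self) -> None:
        if self.n_hidden < 0:
            raise ValueError("n_hidden must be >= 0")
        if not 1 <= self.n_child_slots <= 6:
            raise ValueError("n_child_slots must be in 1..6")
        if self.max_degree < 0:
            raise ValueError("max_degree must be >= 0")

    @property
    def n_features(self) -> int:
        return (
            self.n_child_slots
            + len(self.atom_alphabet)
            + (self.max_degree + 1)
            + len(STEREO_LABELS)
        )

    @property
    def n_inputs(self) -> int:
        """Input dimensionality counting the constant bias unit."""
        return self.n_features + 1

    # feature-column offsets
    @property
    def _atom_off(self) -> int:
        return self.n_child_slots

    @property
    def _deg_off(self) -> int:
        return self._atom_off + len(self.atom_alphabet)

    @property
    def _stereo_off(self) -> int:
        return self._deg_off + self.max_degree + 1


def parameter_count(arch: Architecture) -> int:
    """Number of trainable parameters implied by the layout."""
    nf = arch.n_features
    bias = 1 if arch.output_bias else 0
    if arch.n_hidden == 0:
        return nf + bias
    return arch.n_hidden * (nf + 1) + arch.n_hidden + bias


def _unpack(theta: np.ndarray, arch: Architecture):
    h, nf = arch.n_hidden, arch.n_features
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (parameter_count(arch),):
        raise ValueError(
            f"theta has length {theta.size}, expected {parameter_count(arch)}"
        )
    if h == 0:
        w = theta[:nf]
        b_out = theta[nf] if arch.output_bias else 0.0
        return w, b_out
    W = theta[: h * nf].reshape(h, nf)
    b_h = theta[h * nf : h * nf + h]
    w_out = theta[h * nf + h : h * nf + 2 * h]
    b_out = theta[-1] if arch.output_bias else 0.0
    return W, b_h, w_out, b_out


def node_features(dag: RootedDAG, v: int, arch: Architecture) -> np.ndarray:
    """Label part of node ``v``'s input vector (child slots left zero)."""
    x = np.zeros(arch.n_features)
    node = dag.nodes[v]
    try:
        x[arch._atom_off + arch.atom_alphabet.index(node.atom_type)] = 1.0
    except ValueError:
        pass  # element outside the alphabet: zero-weight handling
    if node.degree_label > arch.max_degree:
        raise ValueError(
            f"degree label {node.degree_label} exceeds max_degree "
            f"{arch.max_degree}"
        )
    x[arch._deg_off + node.degree_label] = 1.0
    for k, lab in enumerate(STEREO_LABELS):
        if lab in node.stereo_labels:
            x[arch._stereo_off + k] = 1.0
    return x


def _check_arity(dag: RootedDAG, arch: Architecture) -> None:
    for v in range(dag.n_nodes):
        if len(dag.children[v]) > arch.n_child_slots:
            raise ArityError(
                f"node {v} of {dag.source_smiles!r} has "
                f"{len(dag.children[v])} children, architecture provides "
                f"{arch.n_child_slots} slots"
            )


def evaluate(dag: RootedDAG, theta: np.ndarray, arch: Architecture) -> float:
    """Forward pass: compose the node function leaves-first, return root."""
    _check_arity(dag, arch)
    params = _unpack(theta, arch)
    out = np.zeros(dag.n_nodes)
    for v in dag.topological_order():
        x = node_features(dag, v, arch)
        for s, c in enumerate(dag.children[v]):
            x[s] = out[c]
        if arch.n_hidden == 0:
            w, b_out = params
            out[v] = float(w @ x) + b_out
        else:
            W, b_h, w_out, b_out = params
            z = np.tanh(W @ x + b_h)
            out[v] = float(w_out @ z) + b_out
    return float(out[dag.root])


def gradient(dag: RootedDAG, theta: np.ndarray, arch: Architecture) -> np.ndarray:
    """Exact gradient of the root output w.r.t. the shared parameters.

    Contributions of every node instance are summed (weight sharing);
    verified against central finite differences in the test suite.
    """
    _check_arity(dag, arch)
    params = _unpack(theta, arch)
    h, nf = arch.n_hidden, arch.n_features
    order = dag.topological_order()

    xs = np.zeros((dag.n_nodes, nf))
    zs = np.zeros((dag.n_nodes, h)) if h else None
    out = np.zeros(dag.n_nodes)
    for v in order:
        x = node_features(dag, v, arch)
        for s, c in enumerate(dag.children[v]):
            x[s] = out[c]
        xs[v] = x
        if h == 0:
            w, b_out = params
            out[v] = float(w @ x) + b_out
        else:
            W, b_h, w_out, b_out = params
            z = np.tanh(W @ x + b_h)
            zs[v] = z
            out[v] = float(w_out @ z) + b_out

    grad = np.zeros(parameter_count(arch))
    adj = np.zeros(dag.n_nodes)
    adj[dag.root] = 1.0
    for v in reversed(order):
        a = adj[v]
        if a == 0.0:
            continue
        if h == 0:
            w, _ = params
            grad[:nf] += a * xs[v]
            if arch.output_bias:
                grad[nf] += a
            for s, c in enumerate(dag.children[v]):
                adj[c] += a * w[s]
        else:
            W, b_h, w_out, _ = params
            dpre = w_out * (1.0 - zs[v] ** 2)  # d out / d preactivation
            grad[: h * nf] += a * np.outer(dpre, xs[v]).ravel()
            grad[h * nf : h * nf + h] += a * dpre
            grad[h * nf + h : h * nf + 2 * h] += a * zs[v]
            if arch.output_bias:
                grad[-1] += a
            for s, c in enumerate(dag.children[v]):
                adj[c] += a * float(dpre @ W[:, s])
    return grad


class GraphBatch:
    """Level-vectorized forward/Jacobian engine over a set of DAGs.

    All nodes of all molecules are flattened into shared arrays and
    processed level by level (a node's level is 1 + max level of its
    children), so each level is a single matrix operation.  Produces
    bit-identical outputs to :func:`evaluate` / :func:`gradient`, which the
    test suite cross-checks; training uses this engine for speed.
    """

    def __init__(self, dags: Sequence[RootedDAG], arch: Architecture):
        self.arch = arch
        self.n_examples = len(dags)
        feats = []
        example_id = []
        level = []
        links = []  # (parent_global, slot, child_global)
        roots = []
        offset = 0
        for e, dag in enumerate(dags):
            _check_arity(dag, arch)
            lev = {}
            for v in dag.topological_order():
                lev[v] = 1 + max((lev[c] for c in dag.children[v]), default=-1)
                feats.append(node_features(dag, v, arch))
                example_id.append(e)
            # topological order visits nodes in stack order; map local
            # index -> global index via a per-dag table
            base = offset
            local_order = dag.topological_order()
            gidx = {v: base + i for i, v in enumerate(local_order)}
            for v in local_order:
                for s, c in enumerate(dag.children[v]):
                    links.append((gidx[v], s, gidx[c]))
                level.append(lev[v])
            roots.append(gidx[dag.root])
            offset += dag.n_nodes

        self.n_nodes = offset
        self.X0 = np.asarray(feats)
        self.example_id = np.asarray(example_id, dtype=np.intp)
        self.level = np.asarray(level, dtype=np.intp)
        self.roots = np.asarray(roots, dtype=np.intp)
        links_arr = (
            np.asarray(links, dtype=np.intp)
            if links
            else np.empty((0, 3), dtype=np.intp)
        )
        # group links by the level of the parent node
        self.max_level = int(self.level.max()) if offset else 0
        self.links_by_level = []
        for ell in range(self.max_level + 1):
            mask = (
                self.level[links_arr[:, 0]] == ell
                if len(links_arr)
                else np.zeros(0, bool)
            )
            self.links_by_level.append(links_arr[mask])
        self.nodes_by_level = [
            np.nonzero(self.level == ell)[0] for ell in range(self.max_level + 1)
        ]

    def forward(self, theta: np.ndarray, want_grad_state: bool = False):
        arch = self.arch
        params = _unpack(theta, arch)
        h = arch.n_hidden
        X = self.X0.copy()
        out = np.zeros(self.n_nodes)
        Z = np.zeros((self.n_nodes, h)) if h else None
        for ell in range(self.max_level + 1):
            ln = self.links_by_level[ell]
            if len(ln):
                X[ln[:, 0], ln[:, 1]] = out[ln[:, 2]]
            idx = self.nodes_by_level[ell]
            if h == 0:
                w, b_out = params
                out[idx] = X[idx] @ w + b_out
            else:
                W, b_h, w_out, b_out = params
                z = np.tanh(X[idx] @ W.T + b_h)
                Z[idx] = z
                out[idx] = z @ w_out + b_out
        preds = out[self.roots]
        if want_grad_state:
            return preds, (X, Z, out)
        return preds

    def outputs(self, theta: np.ndarray) -> np.ndarray:
        """Model output g_i(θ) per example."""
        return self.forward(theta)

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Matrix Z with Z[i, :] = ∂g_i/∂θ (one row per example)."""
        arch = self.arch
        h, nf = arch.n_hidden, arch.n_features
        p = parameter_count(arch)
        _, (X, Z, _out) = self.forward(theta, want_grad_state=True)
        params = _unpack(theta, arch)

        adj = np.zeros(self.n_nodes)
        adj[self.roots] = 1.0
        if h:
            W, _, w_out, _ = params
            dpre = (1.0 - Z**2) * w_out  # (n_nodes, h)
        for ell in range(self.max_level, -1, -1):
            ln = self.links_by_level[ell]
            if not len(ln):
                continue
            pidx, slots, cidx = ln[:, 0], ln[:, 1], ln[:, 2]
            if h == 0:
                w, _ = params
                np.add.at(adj, cidx, adj[pidx] * w[slots])
            else:
                contrib = adj[pidx] * np.einsum(
                    "lh,lh->l", dpre[pidx], W[:, slots].T
                )
                np.add.at(adj, cidx, contrib)

        J = np.zeros((self.n_examples, p))
        if h == 0:
            w_grad = adj[:, None] * X
            np.add.at(J[:, :nf], self.example_id, w_grad)
            if arch.output_bias:
                np.add.at(J[:, nf], self.example_id, adj)
        else:
            gW = np.einsum("n,nh,nf->nhf", adj, dpre, X).reshape(
                self.n_nodes, h * nf
            )
            np.add.at(J[:, : h * nf], self.example_id, gW)
            np.add.at(J[:, h * nf : h * nf + h], self.example_id,
                      adj[:, None] * dpre)
            np.add.at(J[:, h * nf + h : h * nf + 2 * h], self.example_id,
                      adj[:, None] * Z)
            if arch.output_bias:
                np.add.at(J[:, -1], self.example_id, adj)
        return J


def save_model(
    path: Union[str, Path],
    arch: Architecture,
    theta: np.ndarray,
    metadata: dict | None = None,
) -> None:
    """Serialize architecture + θ (+ provenance) to JSON, bit-exactly."""
    payload = {
        "architecture": asdict(arch),
        "theta_hex": [float.hex(float(t)) for t in np.asarray(theta).ravel()],
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: Union[str, Path]):
    """Inverse of :func:`save_model`; returns (arch, theta, metadata)."""
    payload = json.loads(Path(path).read_text())
    d = payload["architecture"]
    d["atom_alphabet"] = tuple(d["atom_alphabet"])
    arch = Architecture(**d)
    theta = np.array([float.fromhex(t) for t in payload["theta_hex"]])
    return arch, theta, payload.get("metadata", {})
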