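"""A graph-isomorphism-style neural encoder for molecules, in NumPy.

Message passing follows the GIN update: each layer sums the feature vectors
of a node's neighbours, adds the node's own features, and transforms the
result with a two-hidden-layer ReLU + batch-norm perceptron. The graph-level
representation is the component-wise maximum over the atom vectors of the
final layer (max-pool readout), which is invariant to atom order.

For feature extraction the encoder is first trained end-to-end with a single
linear head mapping the pooled representation to the activity label; the
head is then discarded and the frozen encoder used as a static featuriser.
The end-to-end variant keeps a full MLP head instead.

Atom features (the inputs of the first layer): one-hot element type, degree,
formal charge, aromaticity flag and attached-hydrogen count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .nn import (
    AdamW,
    BatchNorm,
    Linear,
    ReLU,
    Sequential,
    TrainConfig,
    TrainingDivergedError,
    iterate_minibatches,
    make_mlp,
)

_ELEMENTS = (6, 7, 8, 9, 15, 16, 17, 35, 53)  # C N O F P S Cl Br I; else "other"
_MAX_DEGREE = 5
_MAX_H = 4

ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 3 + 1 + (_MAX_H + 1)


def atom_features(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM)
    try:
        v[_ELEMENTS.index(atom.GetAtomicNum())] = 1.0
    except ValueError:
        v[len(_ELEMENTS)] = 1.0
    off = len(_ELEMENTS) + 1
    v[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    v[off + min(max(atom.GetFormalCharge(), -1), 1) + 1] = 1.0
    off += 3
    v[off] = float(atom.GetIsAromatic())
    off += 1
    v[off + min(atom.GetTotalNumHs(), _MAX_H)] = 1.0
    return v


@dataclass
class MolGraph:
    """One molecular graph: atom feature matrix + directed edge list (both
    directions of every bond)."""

    x: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM)
    edges: np.ndarray      # (2, n_directed_edges)

    @property
    def n_atoms(self) -> int:
        return self.x.shape[0]


def mol_graph(smiles: str) -> MolGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    x = np.stack([atom_features(a) for a in mol.GetAtoms()]) if mol.GetNumAtoms() else np.zeros((0, ATOM_FEATURE_DIM))
    src, dst = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
    return MolGraph(x=x, edges=np.array([src, dst], dtype=int).reshape(2, -1))


@dataclass
class GraphBatch:
    """Several graphs packed into one node matrix with contiguous segments."""

    x: np.ndarray
    edges: np.ndarray
    starts: np.ndarray     # first node index of each graph
    graph_idx: np.ndarray  # node -> graph

    @classmethod
    def from_graphs(cls, graphs: list[MolGraph]) -> "GraphBatch":
        starts, offset = [], 0
        xs, srcs, dsts, gidx = [], [], [], []
        for g, graph in enumerate(graphs):
            starts.append(offset)
            xs.append(graph.x)
            srcs.append(graph.edges[0] + offset)
            dsts.append(graph.edges[1] + offset)
            gidx.append(np.full(graph.n_atoms, g))
            offset += graph.n_atoms
        return cls(
            x=np.concatenate(xs, axis=0),
            edges=np.array([np.concatenate(srcs), np.concatenate(dsts)], dtype=int),
            starts=np.array(starts, dtype=int),
            graph_idx=np.concatenate(gidx).astype(int),
        )


def _scatter_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, index, values)
    return out


class GINLayer:
    """h' = MLP((1 + eps) * h + sum_neighbours h), eps fixed at 0."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.mlp = Sequential(
            [
                Linear(n_in, n_hidden, rng),
                BatchNorm(n_hidden),
                ReLU(),
                Linear(n_hidden, n_hidden, rng),
                BatchNorm(n_hidden),
                ReLU(),
            ]
        )

    @property
    def params(self):
        return self.mlp.params

    @property
    def grads(self):
        return self.mlp.grads

    def forward(self, h: np.ndarray, edges: np.ndarray, training: bool) -> np.ndarray:
        self._edges = edges
        self._n = h.shape[0]
        agg = h + _scatter_sum(h[edges[0]], edges[1], h.shape[0])
        return self.mlp.forward(agg, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g_agg = self.mlp.backward(grad)
        out = g_agg.copy()
        np.add.at(out, self._edges[0], g_agg[self._edges[1]])
        return out


def _segment_max(h: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.maximum.reduceat(h, starts, axis=0)


class GINEncoder:
    """Stack of GIN layers with max-pool readout; embedding dim = hidden_dim."""

    def __init__(self, n_layers: int = 2, hidden_dim: int = 64, seed: int = 0):
        if n_layers < 1:
            raise ValueError("need at least one graph convolutional layer")
        rng = np.random.default_rng(seed)
        self.hidden_dim = hidden_dim
        self.layers = [
            GINLayer(ATOM_FEATURE_DIM if i == 0 else hidden_dim, hidden_dim, rng)
            for i in range(n_layers)
        ]
        self.frozen = False

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, batch: GraphBatch, training: bool) -> np.ndarray:
        if self.frozen:
            training = False
        h = batch.x
        for layer in self.layers:
            h = layer.forward(h, batch.edges, training)
        self._h_final = h
        self._batch = batch
        pooled = _segment_max(h, batch.starts)
        # tie-aware max-pool cache: route gradient to (all) argmax atoms
        self._max_mask = h == pooled[batch.graph_idx]
        self._tie_counts = _scatter_sum(self._max_mask.astype(float), batch.graph_idx, len(batch.starts))
        return pooled

    def backward(self, grad_pooled: np.ndarray) -> None:
        share = grad_pooled / np.maximum(self._tie_counts, 1.0)
        grad_h = self._max_mask * share[self._batch.graph_idx]
        for layer in reversed(self.layers):
            grad_h = layer.backward(grad_h)

    def embed(self, graphs: list[MolGraph]) -> np.ndarray:
        """Inference-mode graph embeddings (deterministic once trained)."""
        if not graphs:
            return np.zeros((0, self.hidden_dim))
        return self.forward(GraphBatch.from_graphs(graphs), training=False)


@dataclass
class GraphEncoderConfig:
    """Architecture of the graph encoder."""

    n_conv_layers: int = 2
    hidden_dim: int = 64


class _Head:
    """Linear or MLP projection head on top of the pooled representation."""

    def __init__(self, kind: str, n_in: int, config: TrainConfig, rng: np.random.Generator):
        if kind == "linear":
            self.net = Sequential([Linear(n_in, 1, rng)])
        elif kind == "mlp":
            self.net = make_mlp(n_in, config.hidden, 1, rng, dropout=config.dropout)
        else:
            raise ValueError(f"unknown head kind {kind!r}")


def train_gin(
    graphs: list[MolGraph],
    y: np.ndarray,
    encoder_config: GraphEncoderConfig,
    train_config: TrainConfig,
    head: str = "linear",
) -> tuple[GINEncoder, Sequential, list[float]]:
    """Train encoder + head end-to-end under the MSE loss.

    Returns (encoder, head network, per-epoch losses). The encoder is NOT yet
    frozen; call ``encoder.frozen = True`` (see :func:`train_gin_features`)
    to use it as a static feature extractor.
    """
    if len(graphs) < 1:
        raise ValueError("no training data")
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    encoder = GINEncoder(
        n_layers=encoder_config.n_conv_layers,
        hidden_dim=encoder_config.hidden_dim,
        seed=train_config.seed,
    )
    rng = np.random.default_rng(train_config.seed + 1)
    head_net = _Head(head, encoder_config.hidden_dim, train_config, rng).net
    params = encoder.params + head_net.params
    opt = AdamW(
        params,
        lr=train_config.lr,
        weight_decay=train_config.weight_decay,
        lr_decay=train_config.lr_decay,
    )
    losses: list[float] = []
    for _ in range(train_config.epochs):
        epoch_loss, n_seen = 0.0, 0
        for idx in iterate_minibatches(len(graphs), train_config.batch_size, rng):
            batch = GraphBatch.from_graphs([graphs[i] for i in idx])
            pooled = encoder.forward(batch, training=True)
            pred = head_net.forward(pooled, training=True)
            diff = pred - y[idx]
            loss = float((diff**2).mean())
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at step {opt.t}")
            grad = 2.0 * diff / diff.shape[0]
            encoder.backward(head_net.backward(grad))
            opt.step(encoder.grads + head_net.grads)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        opt.end_epoch()
        losses.append(epoch_loss / n_seen)
    return encoder, head_net, losses


def train_gin_features(
    graphs: list[MolGraph],
    y: np.ndarray,
    encoder_config: GraphEncoderConfig,
    train_config: TrainConfig,
) -> tuple[GINEncoder, list[float]]:
    """Linear-head pretraining for static feature extraction: the head is
    discarded and the returned encoder frozen."""
    encoder, _, losses = train_gin(graphs, y, encoder_config, train_config, head="linear")
    encoder.frozen = True
    return encoder, losses


class GINModel:
    """End-to-end graph encoder + MLP head exposed as predict(graphs)."""

    def __init__(self, encoder: GINEncoder, head_net: Sequential):
        self.encoder = encoder
        self.head_net = head_net

    def predict(self, graphs: list[MolGraph]) -> np.ndarray:
        pooled = self.encoder.embed(graphs)
        return self.head_net.forward(pooled, training=False).ravel()
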