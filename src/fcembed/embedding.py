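"""node2vec graph embedding: biased random walks and skip-gram training.

The walk is second-order: standing at node ``v`` having arrived from ``t``,
the unnormalized probability of stepping to neighbor ``x`` is
``pi_vx = alpha_pq(t, x) * w_vx`` where the search bias is

    alpha_pq(t, x) = 1/p  if d(t, x) = 0   (return)
                     1    if d(t, x) = 1   (stay local)
                     1/q  if d(t, x) = 2   (move outward)

with ``d`` the shortest-path distance between ``t`` and ``x`` (necessarily
in {0, 1, 2} for a candidate ``x`` adjacent to ``v``).  Small ``p`` and
``q`` > 1 bias walks toward revisiting and local exploration.

The walk corpus trains a one-hidden-layer skip-gram network with an exact
softmax over the node vocabulary (the vocabulary is at most a few hundred
ROIs, so exact gradients are cheap, deterministic and testable).  The
hidden-layer weight matrix is the embedding.  One fixed-length subject
feature vector is the row-wise concatenation of the embedding in atlas
node order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import STAGE_SKIPGRAM, STAGE_WALKS, seed_sequence
from .connectivity import WeightedGraph

__all__ = [
    "Node2vecParams", "WalkCorpus", "NodeEmbedding",
    "search_bias", "transition_distribution", "simulate_walks",
    "context_pairs", "skipgram_objective", "train_skipgram",
    "subject_feature_vector", "embed_subject",
]


@dataclass(frozen=True)
class Node2vecParams:
    """All knobs of the sampling + training stage.

    Defaults follow the reference operating point for connectome-scale
    graphs: strongly local walks (p = 0.1, q = 1.6), short walks
    (length 10), 200 walks per node, 32-dimensional embeddings.
    """

    p: float = 0.1
    q: float = 1.6
    walk_length: int = 10
    num_walks: int = 200
    dim: int = 32
    window: int = 10
    epochs: int = 5
    learning_rate: float = 0.5
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if min(self.walk_length, self.num_walks, self.dim, self.window,
               self.epochs, self.batch_size) < 1:
            raise ValueError("walk_length, num_walks, dim, window, epochs and "
                             "batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class WalkCorpus:
    """Sampled node sequences plus provenance."""

    walks: list[list[int]]
    n_nodes: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class NodeEmbedding:
    """V x dim embedding matrix, rows in graph node order."""

    matrix: np.ndarray
    node_names: list[str]
    trained_mask: np.ndarray  # False rows kept their (flagged) initialization
    loglik_history: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def search_bias(d_tx: int, p: float, q: float) -> float:
    """Second-order bias alpha_pq(t, x) as a function of d(t, x)."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ValueError(f"d_tx must be in {{0, 1, 2}}, got {d_tx}")


def transition_distribution(g: WeightedGraph, t: int | None, v: int,
                            p: float = 1.0, q: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic next-step distribution from state (t, v).

    Returns ``(neighbors, probabilities)``.  ``t is None`` (or ``t == v``)
    marks the first step of a walk, where probabilities are proportional to
    the static weights alone.  A neighborless ``v`` yields empty arrays
    (the walk terminates).
    """
    nbrs = g.neighbors(v)
    if nbrs.size == 0:
        return nbrs, np.empty(0)
    w = g.weights[v, nbrs]
    if t is None or t == v:
        probs = w / w.sum()
        return nbrs, probs
    if g.weights[t, v] <= 0:
        raise ValueError(f"previous node {t} is not adjacent to current node {v}")
    alpha = np.where(g.adjacency[t, nbrs], 1.0, 1.0 / q)
    alpha[nbrs == t] = 1.0 / p
    unnorm = alpha * w
    return nbrs, unnorm / unnorm.sum()


def _step_batch(g: WeightedGraph, prev: np.ndarray, cur: np.ndarray,
                rng: np.random.Generator, p: float, q: float) -> np.ndarray:
    """Sample one biased step for a batch of walks; -1 marks a dead walk.

    ``prev[i] == -1`` means walk i has no predecessor (first step).
    This is the production sampler: tests compare its empirical
    frequencies against :func:`transition_distribution`.
    """
    w = g.weights
    adj = g.adjacency
    pi = w[cur].copy()                              # (B, N) static weights
    has_prev = prev >= 0
    if np.any(has_prev):
        tp = prev[has_prev]
        alpha = np.where(adj[tp], 1.0, 1.0 / q)     # d(t,x) == 1 vs 2
        alpha[np.arange(tp.size), tp] = 1.0 / p     # d(t,x) == 0
        pi[has_prev] *= alpha
    csum = np.cumsum(pi, axis=1)
    total = csum[:, -1]
    nxt = np.full(cur.size, -1, dtype=np.int64)
    alive = total > 0
    if np.any(alive):
        r = rng.random(cur.size) * total
        idx = (csum[alive] < r[alive, None]).sum(axis=1)
        nxt[alive] = np.minimum(idx, g.n_nodes - 1)
    return nxt


def simulate_walks(g: WeightedGraph, params: Node2vecParams,
                   rng: np.random.Generator | None = None) -> WalkCorpus:
    """num_walks biased walks per start node, fully seeded.

    Start-node order is shuffled once per round by the seeded generator.
    Walks from neighborless nodes are single-node sequences.
    """
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    if rng is None:
        rng = np.random.default_rng(seed_sequence(params.seed, STAGE_WALKS))
    n = g.n_nodes
    length = params.walk_length
    all_walks: list[list[int]] = []
    for _ in range(params.num_walks):
        starts = rng.permutation(n)
        seq = np.full((n, length), -1, dtype=np.int64)
        seq[:, 0] = starts
        prev = np.full(n, -1, dtype=np.int64)
        cur = starts.copy()
        for step in range(1, length):
            alive = cur >= 0
            if not np.any(alive):
                break
            nxt = np.full(n, -1, dtype=np.int64)
            nxt[alive] = _step_batch(g, prev[alive], cur[alive], rng,
                                     params.p, params.q)
            seq[:, step] = nxt
            prev, cur = cur, nxt
        for row in seq:
            all_walks.append([int(x) for x in row[row >= 0]])
    return WalkCorpus(all_walks, n, provenance={
        "p": params.p, "q": params.q, "walk_length": params.walk_length,
        "num_walks": params.num_walks, "seed": params.seed,
        "negative_policy": g.negative_policy})


def context_pairs(corpus: WalkCorpus, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within the sliding window."""
    centers, contexts = [], []
    for walk in corpus.walks:
        arr = np.asarray(walk, dtype=np.int64)
        L = arr.size
        for off in range(1, min(window, L - 1) + 1):
            centers.append(arr[:-off])
            contexts.append(arr[off:])
            centers.append(arr[off:])
            contexts.append(arr[:-off])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def skipgram_objective(w_in: np.ndarray, w_out: np.ndarray,
                       centers: np.ndarray, contexts: np.ndarray,
                       with_grads: bool = False):
    """Mean log-probability of contexts under the exact-softmax skip-gram.

    Optionally returns analytic gradients (d mean-logp / d weights) for the
    finite-difference check.
    """
    h = w_in[centers]                       # (B, dim)
    scores = h @ w_out                      # (B, V)
    scores -= scores.max(axis=1, keepdims=True)
    exp = np.exp(scores)
    probs = exp / exp.sum(axis=1, keepdims=True)
    b = centers.size
    logp = float(np.mean(np.log(probs[np.arange(b), contexts] + 1e-300)))
    if not with_grads:
        return logp
    delta = probs
    delta[np.arange(b), contexts] -= 1.0    # d(-logp)/d scores
    g_out = h.T @ delta / b
    g_h = delta @ w_out.T / b
    g_in = np.zeros_like(w_in)
    np.add.at(g_in, centers, g_h)
    return logp, -g_in, -g_out              # gradients of the *mean log-lik*


def train_skipgram(corpus: WalkCorpus, params: Node2vecParams,
                   node_names: list[str] | None = None) -> NodeEmbedding:
    """Mini-batch SGD on the exact-softmax skip-gram objective.

    Initialization and batch shuffling draw from generators derived from
    ``params.seed`` only, never from the corpus, so identical graphs (hence
    identical corpora) produce identical embeddings across subjects.
    Nodes absent from the corpus keep their initialization row and are
    flagged in ``trained_mask``.
    """
    if not corpus.walks:
        raise ValueError("corpus is empty")
    v = corpus.n_nodes
    dim = params.dim
    init_rng = np.random.default_rng(seed_sequence(params.seed, STAGE_SKIPGRAM, 0))
    shuffle_rng = np.random.default_rng(seed_sequence(params.seed, STAGE_SKIPGRAM, 1))
    w_in = (init_rng.random((v, dim)) - 0.5) / dim
    w_out = (init_rng.random((dim, v)) - 0.5) / dim

    centers, contexts = context_pairs(corpus, params.window)
    if centers.size == 0:
        # degenerate corpus of single-node walks: nothing to train on
        mask = np.zeros(v, dtype=bool)
        names = node_names or [f"ROI{i + 1:03d}" for i in range(v)]
        return NodeEmbedding(w_in, names, mask, [])

    n_pairs = centers.size
    n_batches_total = params.epochs * max(1, -(-n_pairs // params.batch_size))
    history: list[float] = []
    batch_counter = 0
    for _ in range(params.epochs):
        order = shuffle_rng.permutation(n_pairs)
        epoch_logp = 0.0
        for lo in range(0, n_pairs, params.batch_size):
            sel = order[lo:lo + params.batch_size]
            c, o = centers[sel], contexts[sel]
            frac = batch_counter / n_batches_total
            lr = params.learning_rate * max(1.0 - frac, 0.01)
            logp, g_in, g_out = skipgram_objective(w_in, w_out, c, o,
                                                   with_grads=True)
            w_in += lr * g_in               # gradient *ascent* on mean log-lik
            w_out += lr * g_out
            epoch_logp += logp * sel.size
            batch_counter += 1
        history.append(epoch_logp / n_pairs)

    mask = np.zeros(v, dtype=bool)
    mask[np.unique(centers)] = True
    names = node_names or [f"ROI{i + 1:03d}" for i in range(v)]
    return NodeEmbedding(w_in, names, mask, history)


def subject_feature_vector(emb: NodeEmbedding, node_order: list[str]) -> np.ndarray:
    """Concatenate embedding rows in fixed atlas order -> length V*dim."""
    if list(emb.node_names) != list(node_order):
        raise ValueError("embedding node order does not match the requested "
                         "ROI order")
    return emb.matrix.ravel()


def embed_subject(g: WeightedGraph, params: Node2vecParams,
                  walk_rng: np.random.Generator | None = None) -> np.ndarray:
    """Walks + skip-gram + concatenation for one subject graph."""
    corpus = simulate_walks(g, params, rng=walk_rng)
    emb = train_skipgram(corpus, params, node_names=g.node_names)
    return subject_feature_vector(emb, g.node_names)
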