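"""Graph autoencoder for site-disease link prediction.

A 3-layer GNN encoder (GIN, GCN or GraphSAGE message passing) maps the
heterogeneous graph to latent embeddings H = [H_S; H_D]; the decoder scores
every (site, disease) pair as sigma(<h_s, h_d>); training minimises a
weighted cross-entropy over the labelled pairs, optionally augmented with
FGM adversarial perturbations of intermediate layer embeddings.

Everything here is dense NumPy with hand-derived gradients: the graphs are
small (hundreds of nodes), so explicit forward/backward passes are simple,
fast and exactly reproducible.  Layer formulations:

    GCN :  H' = act( D^{-1/2} (X+I) D^{-1/2} H W + b )
    SAGE:  H' = act( H W1 + mean_{u in N(v)} H_u W2 + b )   (empty
           neighbourhoods aggregate to the zero vector)
    GIN :  H' = act( MLP( (1+eps_gin) H_v + sum_{u in N(v)} H_u ) ),
           MLP = 2-layer with batch normalisation before the internal ReLU
           (the canonical GIN form; without it the sum aggregation saturates
           on dense similarity blocks).  Training is full batch, so the
           normalisation statistics are deterministic and identical between
           training and scoring.

ReLU is applied between layers; the final encoder layer is linear so latent
coordinates may take either sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import expit

from .core_io import AssociationTable, ValidationError
from .hetgraph import HeteroGraph

_CLAMP = 1e-7  # score clamp inside the loss; Eq. is undefined at 0/1


class EncoderVariant(str, Enum):
    GIN = "gin"
    GCN = "gcn"
    SAGE = "sage"


@dataclass
class EncoderConfig:
    variant: EncoderVariant = EncoderVariant.GIN
    layers: int = 3
    hidden_dim: int = 64
    activation: str = "relu"
    gin_eps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.variant = EncoderVariant(self.variant)
        if self.layers < 1:
            raise ValidationError("layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValidationError("hidden_dim must be >= 1")
        if self.activation != "relu":
            raise ValidationError("only relu is supported between layers")


@dataclass
class AdvConfig:
    enabled: bool = True
    epsilon: float = 0.1
    target_layers: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        self.target_layers = tuple(self.target_layers)
        if self.enabled and self.epsilon <= 0:
            raise ValidationError("epsilon must be positive when adversarial training is on")
        if any(l < 1 for l in self.target_layers):
            raise ValidationError("target layers are 1-based layer indices")


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    init: str = "xavier"
    neg_ratio_train: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValidationError("only adam is supported")
        if self.init != "xavier":
            raise ValidationError("only xavier init is supported")


@dataclass
class LatentEmbedding:
    H: np.ndarray
    m: int

    @property
    def H_S(self) -> np.ndarray:
        return self.H[: self.m]

    @property
    def H_D(self) -> np.ndarray:
        return self.H[self.m :]


@dataclass
class ScoreMatrix:
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all((self.values > 0.0) & (self.values < 1.0)):
            raise ValidationError("scores must lie strictly in (0,1)")


@dataclass
class TrainedModel:
    params: list[dict[str, np.ndarray]]
    encoder: EncoderConfig
    adversarial: AdvConfig
    training: TrainConfig
    loss_history: dict[str, list[float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# graph operators and parameter initialisation
# ---------------------------------------------------------------------------

def _graph_operator(graph: HeteroGraph, variant: EncoderVariant, gin_eps: float) -> np.ndarray:
    X = graph.adjacency
    t = X.shape[0]
    if variant is EncoderVariant.GCN:
        Xh = X + np.eye(t)
        d = Xh.sum(axis=1)
        dinv = 1.0 / np.sqrt(d)
        return (dinv[:, None] * Xh) * dinv[None, :]
    if variant is EncoderVariant.SAGE:
        d = X.sum(axis=1)
        M = np.zeros_like(X)
        nz = d > 0
        M[nz] = X[nz] / d[nz, None]
        return M
    # GIN: (1+eps) I + X, so B @ H performs the injective sum aggregation
    return (1.0 + gin_eps) * np.eye(t) + X


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(
    variant: EncoderVariant, in_dim: int, hidden_dim: int, layers: int, seed: int
) -> list[dict[str, np.ndarray]]:
    """Xavier-uniform initialisation of all layer weights, seeded."""
    rng = np.random.default_rng(seed)
    params = []
    d_in = in_dim
    for _ in range(layers):
        d_out = hidden_dim
        if variant is EncoderVariant.GCN:
            p = {"W": _xavier(rng, d_in, d_out), "b": np.zeros(d_out)}
        elif variant is EncoderVariant.SAGE:
            p = {
                "W1": _xavier(rng, d_in, d_out),
                "W2": _xavier(rng, d_in, d_out),
                "b": np.zeros(d_out),
            }
        else:
            p = {
                "W1": _xavier(rng, d_in, d_out),
                "b1": np.zeros(d_out),
                "gamma": np.ones(d_out),
                "beta": np.zeros(d_out),
                "W2": _xavier(rng, d_out, d_out),
                "b2": np.zeros(d_out),
            }
        params.append(p)
        d_in = d_out
    return params


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

_BN_EPS = 1e-5


def _act(Z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(Z, 0.0) if kind == "relu" else Z


def _bn_forward(Z, gamma, beta):
    mu = Z.mean(axis=0)
    var = Z.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    Zhat = (Z - mu) * inv_std
    return gamma * Zhat + beta, (Zhat, inv_std)


def _bn_backward(dout, cache, gamma):
    Zhat, inv_std = cache
    N = Zhat.shape[0]
    dgamma = (dout * Zhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dZhat = dout * gamma
    dZ = (inv_std / N) * (
        N * dZhat - dZhat.sum(axis=0) - Zhat * (dZhat * Zhat).sum(axis=0)
    )
    return dZ, dgamma, dbeta


def _layer_forward(op, H, p, variant, act):
    if variant is EncoderVariant.GCN:
        P = op @ H
        Z = P @ p["W"] + p["b"]
        return _act(Z, act), {"P": P, "Z": Z}
    if variant is EncoderVariant.SAGE:
        N = op @ H
        Z = H @ p["W1"] + N @ p["W2"] + p["b"]
        return _act(Z, act), {"H": H, "N": N, "Z": Z}
    Agg = op @ H
    Z1 = Agg @ p["W1"] + p["b1"]
    if "gamma" in p:
        B1, bn_cache = _bn_forward(Z1, p["gamma"], p["beta"])
    else:  # identity-MLP toys may omit the normalisation parameters
        B1, bn_cache = Z1, None
    A1 = np.maximum(B1, 0.0)
    Z2 = A1 @ p["W2"] + p["b2"]
    return _act(Z2, act), {"Agg": Agg, "B1": B1, "A1": A1, "Z": Z2, "bn": bn_cache}


def _layer_backward(op, dout, cache, p, variant, act):
    dZ = dout * (cache["Z"] > 0) if act == "relu" else dout
    if variant is EncoderVariant.GCN:
        grads = {"W": cache["P"].T @ dZ, "b": dZ.sum(axis=0)}
        dH = op.T @ (dZ @ p["W"].T)
        return dH, grads
    if variant is EncoderVariant.SAGE:
        grads = {
            "W1": cache["H"].T @ dZ,
            "W2": cache["N"].T @ dZ,
            "b": dZ.sum(axis=0),
        }
        dH = dZ @ p["W1"].T + op.T @ (dZ @ p["W2"].T)
        return dH, grads
    dZ2 = dZ
    grads = {"W2": cache["A1"].T @ dZ2, "b2": dZ2.sum(axis=0)}
    dA1 = dZ2 @ p["W2"].T
    dB1 = dA1 * (cache["B1"] > 0)
    if cache["bn"] is not None:
        dZ1, dgamma, dbeta = _bn_backward(dB1, cache["bn"], p["gamma"])
        grads["gamma"] = dgamma
        grads["beta"] = dbeta
    else:
        dZ1 = dB1
    grads["W1"] = cache["Agg"].T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    dH = op.T @ (dZ1 @ p["W1"].T)
    return dH, grads


def gnn_forward(
    graph: HeteroGraph,
    H_in: np.ndarray,
    layer_params: dict[str, np.ndarray],
    variant: EncoderVariant | str,
    gin_eps: float = 0.0,
    activation: str = "relu",
) -> np.ndarray:
    """One message-passing layer (public single-layer surface)."""
    variant = EncoderVariant(variant)
    op = _graph_operator(graph, variant, gin_eps)
    out, _ = _layer_forward(op, H_in, layer_params, variant, activation)
    if not np.all(np.isfinite(out)):
        raise ValidationError("non-finite activations in gnn_forward")
    return out


def _forward_all(op, H0, params, variant, layers):
    """All layers: ReLU between layers, linear last.  Returns Hs and caches."""
    Hs, caches = [H0], []
    H = H0
    for l in range(layers):
        act = "relu" if l < layers - 1 else "identity"
        H, cache = _layer_forward(op, H, params[l], variant, act)
        Hs.append(H)
        caches.append(cache)
    return Hs, caches


def encode(
    graph: HeteroGraph, config: EncoderConfig, params: list[dict[str, np.ndarray]]
) -> LatentEmbedding:
    op = _graph_operator(graph, config.variant, config.gin_eps)
    Hs, _ = _forward_all(op, graph.node_features, params, config.variant, config.layers)
    H = Hs[-1]
    if not np.all(np.isfinite(H)):
        for l, Hl in enumerate(Hs[1:], start=1):
            if not np.all(np.isfinite(Hl)):
                raise ValidationError(f"non-finite activations at encoder layer {l}")
    return LatentEmbedding(H=H, m=graph.m)


def decode(H_S: np.ndarray, H_D: np.ndarray) -> ScoreMatrix:
    """Bilinear logistic decoder: score(i,j) = sigma(<h_s_i, h_d_j>)."""
    if H_S.shape[1] != H_D.shape[1]:
        raise ValidationError(
            f"latent dims differ: {H_S.shape[1]} vs {H_D.shape[1]}"
        )
    Z = H_S @ H_D.T
    S = expit(Z)
    return ScoreMatrix(np.clip(S, 1e-12, 1.0 - 1e-12))


def wce_loss(scores: ScoreMatrix | np.ndarray, assoc: AssociationTable) -> float:
    """Weighted cross-entropy over the labelled pairs (Ω+ weighted |Ω-|/|Ω+|)."""
    X = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    if not assoc.positives:
        raise ValidationError("weighted cross-entropy undefined without positives")
    pos = assoc.pair_indices(sorted(assoc.positives))
    neg = assoc.pair_indices(sorted(assoc.negatives))
    return _wce_from_scores(X, pos, neg, X.shape[0], X.shape[1])


def _wce_from_scores(X, pos_idx, neg_idx, m, n) -> float:
    Xc = np.clip(X, _CLAMP, 1.0 - _CLAMP)
    w = len(neg_idx) / len(pos_idx)
    total = w * np.log(Xc[pos_idx[:, 0], pos_idx[:, 1]]).sum()
    if len(neg_idx):
        total += np.log(1.0 - Xc[neg_idx[:, 0], neg_idx[:, 1]]).sum()
    return float(-total / (m * n))


def fgm_perturbation(grad: np.ndarray, epsilon: float) -> tuple[np.ndarray, bool]:
    """FGM step: r_adv = eps * g / ||g||_2 (global norm); zero gradient skips."""
    norm = float(np.linalg.norm(grad))
    if norm == 0.0:
        return np.zeros_like(grad), True
    return epsilon * grad / norm, False


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, mm, vv in zip(params, grads, self.m, self.v):
            for k in p:
                mm[k] = self.b1 * mm[k] + (1 - self.b1) * g[k]
                vv[k] = self.b2 * vv[k] + (1 - self.b2) * g[k] ** 2
                p[k] -= self.lr * (mm[k] / bc1) / (np.sqrt(vv[k] / bc2) + self.eps)


def _loss_and_grad_z(Z, pos_idx, neg_idx, m, n):
    """WCE loss and its gradient w.r.t. the decoder logits (sparse support)."""
    X = expit(Z)
    loss = _wce_from_scores(X, pos_idx, neg_idx, m, n)
    w = len(neg_idx) / len(pos_idx)
    G = np.zeros_like(Z)
    xp = X[pos_idx[:, 0], pos_idx[:, 1]]
    G[pos_idx[:, 0], pos_idx[:, 1]] = -w * (1.0 - xp) / (m * n)
    if len(neg_idx):
        xn = X[neg_idx[:, 0], neg_idx[:, 1]]
        G[neg_idx[:, 0], neg_idx[:, 1]] += xn / (m * n)
    return loss, G


def _zero_grads(params):
    return [{k: np.zeros_like(v) for k, v in p.items()} for p in params]


def _accumulate(total, extra):
    for t, e in zip(total, extra):
        for k in t:
            t[k] += e[k]


def _loss_pass(op, Hs, caches, params, variant, layers, m, pos_idx, neg_idx, n,
               start_layer=0, prefix_caches=None):
    """Backward pass from the decoder to layer 1.

    ``Hs``/``caches`` describe the forward pass from ``start_layer`` on; when
    re-running a perturbed suffix, ``prefix_caches`` supplies the clean caches
    for the layers below the perturbation.
    """
    H = Hs[-1]
    HS, HD = H[:m], H[m:]
    Z = HS @ HD.T
    loss, G = _loss_and_grad_z(Z, pos_idx, neg_idx, m, n)
    dH = np.vstack([G @ HD, G.T @ HS])
    grads = _zero_grads(params)
    dH_at = {}
    all_caches = (prefix_caches or []) + caches
    for l in range(layers, 0, -1):
        dH_at[l] = dH
        act = "relu" if l < layers else "identity"
        dH, g = _layer_backward(op, dH, all_caches[l - 1], params[l - 1], variant, act)
        for k in grads[l - 1]:
            grads[l - 1][k] += g[k]
    return loss, grads, dH_at


def train(
    graph: HeteroGraph,
    assoc: AssociationTable,
    enc: EncoderConfig | None = None,
    adv: AdvConfig | None = None,
    tr: TrainConfig | None = None,
) -> TrainedModel:
    """Full-batch training with optional FGM adversarial regularisation.

    Each epoch: (1) clean forward + weighted cross-entropy, gradients captured
    at every layer embedding; (2) for each target layer, the FGM perturbation
    r = eps * g/||g|| is added to that layer's embedding and the forward pass
    re-run from there (earlier layers reused) to get an adversarial loss;
    (3) one Adam step on the sum of the clean and adversarial losses.
    """
    enc = enc or EncoderConfig()
    adv = adv or AdvConfig()
    tr = tr or TrainConfig()
    if not assoc.positives:
        raise ValidationError("cannot train without positive pairs")
    if any(l > enc.layers for l in adv.target_layers):
        raise ValidationError("adversarial target layer beyond encoder depth")

    m, n = graph.m, graph.n
    pos_idx = assoc.pair_indices(sorted(assoc.positives))
    neg_idx = assoc.pair_indices(sorted(assoc.negatives))
    op = _graph_operator(graph, enc.variant, enc.gin_eps)
    params = init_params(
        enc.variant, graph.node_features.shape[1], enc.hidden_dim, enc.layers, enc.seed
    )
    optimizer = _Adam(params, tr.learning_rate)
    history: dict[str, list[float]] = {"clean": [], "adv": []}

    for epoch in range(tr.epochs):
        Hs, caches = _forward_all(op, graph.node_features, params, enc.variant, enc.layers)
        clean_loss, grads, dH_at = _loss_pass(
            op, Hs, caches, params, enc.variant, enc.layers, m, pos_idx, neg_idx, n
        )
        adv_loss = clean_loss
        if adv.enabled:
            adv_loss = 0.0
            for l in adv.target_layers:
                r_adv, skipped = fgm_perturbation(dH_at[l], adv.epsilon)
                H_pert = Hs[l] + r_adv
                sub_Hs, sub_caches = [H_pert], []
                Hc = H_pert
                for ll in range(l, enc.layers):
                    act = "relu" if ll < enc.layers - 1 else "identity"
                    Hc, cache = _layer_forward(op, Hc, params[ll], enc.variant, act)
                    sub_Hs.append(Hc)
                    sub_caches.append(cache)
                loss_l, grads_l, _ = _loss_pass(
                    op, sub_Hs, sub_caches, params, enc.variant, enc.layers,
                    m, pos_idx, neg_idx, n,
                    start_layer=l, prefix_caches=caches[:l],
                )
                adv_loss += loss_l
                _accumulate(grads, grads_l)
        if not (np.isfinite(clean_loss) and np.isfinite(adv_loss)):
            raise ValidationError(f"training diverged at epoch {epoch}")
        optimizer.step(params, grads)
        history["clean"].append(clean_loss)
        history["adv"].append(adv_loss)

    return TrainedModel(params=params, encoder=enc, adversarial=adv, training=tr,
                        loss_history=history)


def score_matrix(model: TrainedModel, graph: HeteroGraph) -> ScoreMatrix:
    emb = encode(graph, model.encoder, model.params)
    return decode(emb.H_S, emb.H_D)


def save_model(model: TrainedModel, outdir) -> None:
    """Checkpoint: one TSV per named weight array plus a YAML of the configs."""
    import dataclasses
    from pathlib import Path

    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for l, p in enumerate(model.params, start=1):
        for k, arr in p.items():
            name = f"layer{l}_{k}"
            names.append(name)
            np.savetxt(outdir / f"{name}.tsv", np.atleast_2d(arr), delimiter="\t")
    meta = {
        "encoder": dataclasses.asdict(model.encoder),
        "adversarial": dataclasses.asdict(model.adversarial),
        "training": dataclasses.asdict(model.training),
        "weights": names,
        "loss_history": {k: [float(x) for x in v] for k, v in model.loss_history.items()},
    }
    meta["encoder"]["variant"] = model.encoder.variant.value
    meta["adversarial"]["target_layers"] = list(model.adversarial.target_layers)
    with open(outdir / "model.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_model(outdir) -> TrainedModel:
    from pathlib import Path

    import yaml

    outdir = Path(outdir)
    with open(outdir / "model.yaml") as fh:
        meta = yaml.safe_load(fh)
    enc = EncoderConfig(**meta["encoder"])
    adv = AdvConfig(**meta["adversarial"])
    tr = TrainConfig(**meta["training"])
    params: list[dict[str, np.ndarray]] = [{} for _ in range(enc.layers)]
    template = init_params(enc.variant, 1, 1, enc.layers, 0)
    for name in meta["weights"]:
        layer_tag, key = name.split("_", 1)
        l = int(layer_tag.removeprefix("layer"))
        arr = np.loadtxt(outdir / f"{name}.tsv", delimiter="\t", ndmin=2)
        if template[l - 1][key].ndim == 1:
            arr = arr.ravel()
        params[l - 1][key] = arr
    return TrainedModel(params=params, encoder=enc, adversarial=adv, training=tr,
                        loss_history=meta.get("loss_history", {}))


def predict(
    model: TrainedModel, graph: HeteroGraph, pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Scores for (site_id, disease_id) pairs via one forward pass."""
    if not pairs:
        return np.empty(0)
    scores = score_matrix(model, graph).values
    srow = {s: i for i, s in enumerate(graph.site_index)}
    dcol = {d: j for j, d in enumerate(graph.disease_index)}
    out = np.empty(len(pairs))
    for k, (s, d) in enumerate(pairs):
        if s not in srow:
            raise ValidationError(f"unknown site id {s!r}")
        if d not in dcol:
            raise ValidationError(f"unknown disease id {d!r}")
        out[k] = scores[srow[s], dcol[d]]
    return out
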