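"""Single-layer, single-head self-attention encoder for multi-label
protein-abundance classification.

Each gene is one token: a learned per-gene identity embedding (which doubles
as the positional signal, since genes have no meaningful order) plus a linear
projection of the pair (normalized expression, TF flag).  Tokens pass through
a self-attention encoder layer with a position-wise feed-forward block, each
token is read out to a scalar, and a classification head maps the per-token
scalars to one logit per protein.  Training minimizes independent per-protein
binary cross-entropy (multi-label) against soft targets that encode the
distance of each normalized abundance from the labeling threshold, with an
L1 penalty on the head's token read-out weights to keep per-protein
attributions sparse, and selects the best of several random restarts by
validation loss.

The network is implemented directly in NumPy with hand-derived gradients and
an Adam optimizer; at desk scale (hundreds of gene tokens, embedding width
~8) a full fit takes on the order of a minute on one CPU, and every step is
deterministic under the configured seed.
"""

from __future__ import annotations

import copy
import json
import warnings
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .exceptions import ConfigError, ContractError, DomainError, LeakageError
from .preprocess import ModelInputTensor, ProteinLabelMatrix

CHECKPOINT_SCHEMA = 1

#: the blind-test stage: never allowed inside train()
HELDOUT_TIMEPOINT = "dpc2.5"
TRAIN_TIMEPOINTS = ("estrus", "dpc0.5", "dpc1.5")


@dataclass
class ModelConfig:
    d_model: int = 8
    n_layers: int = 1
    n_heads: int = 1
    ffn_hidden: int = 16
    mlp_hidden: int = 0  # 0 -> linear read-out head; >0 -> one hidden ReLU layer
    tau: float = 0.6
    learning_rate: float = 3e-3
    max_epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    early_stop_patience: int = 40
    val_fraction: float = 0.2
    l1_head: float = 3e-2
    jitter_sd: float = 0.01
    n_aug: int = 64
    #: independent re-initializations per fit; the restart with the lowest
    #: validation loss wins.  Sparse heads have distinct optimization basins
    #: and validation loss reliably separates them.
    n_restarts: int = 3
    #: soft-label slope: when > 0, training targets are
    #: clip(0.5 + gamma * (normalized_value - tau), 0, 1) instead of hard 0/1,
    #: so the loss sees how far each protein sits from the labeling threshold;
    #: the 0.5 probability cut still reproduces the hard label
    soft_label_gamma: float = 2.0
    #: restrict the classification head's token read-out to TF tokens;
    #: non-TF genes still shape predictions through the attention mixing
    tf_readout_only: bool = False
    top_variance_genes: int = 0  # 0 = keep all genes as tokens

    def validate(self) -> None:
        if self.d_model < 2:
            raise ConfigError("d_model must be >= 2")
        if self.d_model % self.n_heads != 0:
            raise ConfigError("d_model must be divisible by n_heads")
        if self.n_layers != 1 or self.n_heads != 1:
            warnings.warn(
                f"architecture deviates from the single-layer single-head "
                f"reference (n_layers={self.n_layers}, n_heads={self.n_heads})",
                stacklevel=2,
            )
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError("val_fraction must lie in (0, 1)")


@dataclass
class Dataset:
    """Paired expression tensor and protein labels with sample timepoints."""

    tensor: ModelInputTensor
    labels: ProteinLabelMatrix
    timepoints: list[str]

    def __post_init__(self) -> None:
        if self.tensor.sample_ids != self.labels.sample_ids:
            raise ContractError("expression and label sample ids differ")
        if len(self.timepoints) != self.tensor.n_samples:
            raise ContractError("one timepoint per sample required")

    @property
    def sample_ids(self) -> list[str]:
        return self.tensor.sample_ids

    def subset(self, idx: np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        ids = [self.sample_ids[i] for i in idx]
        tensor = ModelInputTensor(
            list(self.tensor.gene_ids), ids, self.tensor.expression[:, idx], self.tensor.tf_flag
        )
        labels = ProteinLabelMatrix(
            list(self.labels.protein_ids), ids, self.labels.labels[:, idx],
            self.labels.tau, self.labels.normalized_values[:, idx],
        )
        return Dataset(tensor, labels, [self.timepoints[i] for i in idx])


@dataclass
class TrainedModel:
    params: dict[str, np.ndarray]
    config: ModelConfig
    gene_ids: list[str]
    protein_ids: list[str]
    tf_flag: np.ndarray
    history: list[dict] = field(default_factory=list)
    trained_sample_ids: list[str] = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return bool(self.history)


@dataclass
class EvaluationReport:
    protein_ids: list[str]
    per_protein: dict[str, dict[str, float]]  # accuracy/precision/recall/f1
    micro: dict[str, float]
    macro: dict[str, float]
    confusion: dict[str, int]  # tp/fp/fn/tn over all protein-sample pairs
    split_description: str

    @property
    def accuracy(self) -> float:
        return self.micro["accuracy"]


# ---------------------------------------------------------------------------
# parameter construction and the forward/backward passes


def build_model(config: ModelConfig, gene_ids: list[str], protein_ids: list[str],
                tf_flag: np.ndarray) -> TrainedModel:
    """Initialize all parameters deterministically under ``config.seed``."""
    config.validate()
    n_genes, n_proteins = len(gene_ids), len(protein_ids)
    if n_genes < 1 or n_proteins < 1:
        raise ConfigError("need at least one gene and one protein")
    params = _init_params(config, n_genes, n_proteins, config.seed)
    return TrainedModel(params, config, list(gene_ids), list(protein_ids),
                        np.asarray(tf_flag, float))


def _init_params(config: ModelConfig, n_genes: int, n_proteins: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    d, dff = config.d_model, config.ffn_hidden

    def glorot(*shape):
        fan = sum(shape)
        return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

    params: dict[str, np.ndarray] = {
        "E": rng.normal(0.0, 0.1, size=(n_genes, d)),
        "W_in": glorot(2, d),
    }
    for l in range(config.n_layers):
        params[f"Wq{l}"] = glorot(d, d)
        params[f"Wk{l}"] = glorot(d, d)
        params[f"Wv{l}"] = glorot(d, d)
        params[f"Wo{l}"] = glorot(d, d)
        params[f"Wf1_{l}"] = glorot(d, dff)
        params[f"bf1_{l}"] = np.zeros(dff)
        params[f"Wf2_{l}"] = glorot(dff, d)
        params[f"bf2_{l}"] = np.zeros(d)
        params[f"ln1g{l}"] = np.ones(d)
        params[f"ln1b{l}"] = np.zeros(d)
        params[f"ln2g{l}"] = np.ones(d)
        params[f"ln2b{l}"] = np.zeros(d)
    params["w_tok"] = glorot(d)
    params["b_tok"] = np.zeros(1)
    # learned skip from each gene's expression straight to its token scalar;
    # starts at gain 1 so every gene enters the head with the same sensitivity
    params["w_skip"] = np.ones(1)
    if config.mlp_hidden > 0:
        params["W1"] = glorot(config.mlp_hidden, n_genes)
        params["b1"] = np.zeros(config.mlp_hidden)
        params["W2"] = glorot(n_proteins, config.mlp_hidden)
        params["b2"] = np.zeros(n_proteins)
    else:
        params["W1"] = glorot(n_proteins, n_genes)
        params["b1"] = np.zeros(n_proteins)
    return params


def _features(tensor: ModelInputTensor) -> np.ndarray:
    """Stack (expression, tf_flag) into the (samples, genes, 2) input array."""
    expr = tensor.expression.T  # (S, G)
    flags = np.broadcast_to(tensor.tf_flag, expr.shape)
    return np.stack([expr, flags], axis=-1)


def tokenize(model: TrainedModel, tensor: ModelInputTensor) -> np.ndarray:
    """Embed each gene: identity embedding + linear projection of (expr, flag).

    Returns the (samples, genes, d_model) token array fed to the encoder.
    """
    tensor = align_genes(tensor, model.gene_ids)
    F = _features(tensor)
    return model.params["E"][None] + F @ model.params["W_in"]


def align_genes(tensor: ModelInputTensor, gene_ids: list[str]) -> ModelInputTensor:
    """Reorder a tensor's genes into the model's canonical order."""
    if tensor.gene_ids == gene_ids:
        return tensor
    if set(tensor.gene_ids) != set(gene_ids):
        raise ContractError("gene set differs from the model's training genes")
    pos = {g: i for i, g in enumerate(tensor.gene_ids)}
    idx = np.array([pos[g] for g in gene_ids])
    return ModelInputTensor(list(gene_ids), list(tensor.sample_ids),
                            tensor.expression[idx], tensor.tf_flag[idx])


_LN_EPS = 1e-5


def _ln_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, xhat, inv


def _ln_backward(dy: np.ndarray, g: np.ndarray, xhat: np.ndarray, inv: np.ndarray):
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _forward(params: dict, config: ModelConfig, F: np.ndarray, want_cache: bool = True):
    B, G, _ = F.shape
    h = config.n_heads
    dh = config.d_model // h
    X = params["E"][None] + F @ params["W_in"]
    cache = {"F": F, "X0": X, "layers": []}
    for l in range(config.n_layers):
        Xin = X
        N1, xh1, inv1 = _ln_forward(X, params[f"ln1g{l}"], params[f"ln1b{l}"])
        Q = N1 @ params[f"Wq{l}"]
        K = N1 @ params[f"Wk{l}"]
        V = N1 @ params[f"Wv{l}"]
        Qh = Q.reshape(B, G, h, dh).transpose(0, 2, 1, 3)
        Kh = K.reshape(B, G, h, dh).transpose(0, 2, 1, 3)
        Vh = V.reshape(B, G, h, dh).transpose(0, 2, 1, 3)
        S = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
        S -= S.max(axis=-1, keepdims=True)
        A = np.exp(S)
        A /= A.sum(axis=-1, keepdims=True)
        C = A @ Vh
        Cc = C.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        X1 = Xin + Cc @ params[f"Wo{l}"]
        N2, xh2, inv2 = _ln_forward(X1, params[f"ln2g{l}"], params[f"ln2b{l}"])
        U = N2 @ params[f"Wf1_{l}"] + params[f"bf1_{l}"]
        R = np.maximum(U, 0.0)
        X = X1 + R @ params[f"Wf2_{l}"] + params[f"bf2_{l}"]
        if want_cache:
            cache["layers"].append(
                {"Xin": Xin, "A": A, "Qh": Qh, "Kh": Kh, "Vh": Vh, "Cc": Cc,
                 "X1": X1, "U": U, "R": R, "N1": N1, "xh1": xh1, "inv1": inv1,
                 "N2": N2, "xh2": xh2, "inv2": inv2}
            )
    # no normalization before read-out: the pre-LN residual trunk carries each
    # gene's expression with one shared gain, which keeps the per-gene head
    # weights directly comparable across genes; the skip term guarantees that
    # gain is nonzero from the first step
    z = X @ params["w_tok"] + params["w_skip"] * F[:, :, 0] + params["b_tok"]
    cache["Xout"] = X
    cache["z"] = z
    if config.mlp_hidden > 0:
        M = z @ params["W1"].T + params["b1"]
        Rm = np.maximum(M, 0.0)
        logits = Rm @ params["W2"].T + params["b2"]
        cache["M"], cache["Rm"] = M, Rm
    else:
        logits = z @ params["W1"].T + params["b1"]
    cache["logits"] = logits
    return logits, cache


def _backward(params: dict, config: ModelConfig, cache: dict, dlogits: np.ndarray) -> dict:
    B, G, _ = cache["F"].shape
    h = config.n_heads
    dh = config.d_model // h
    g: dict[str, np.ndarray] = {}
    z, X = cache["z"], cache["Xout"]
    if config.mlp_hidden > 0:
        Rm, M = cache["Rm"], cache["M"]
        g["W2"] = dlogits.T @ Rm
        g["b2"] = dlogits.sum(0)
        dM = (dlogits @ params["W2"]) * (M > 0)
        g["W1"] = dM.T @ z
        g["b1"] = dM.sum(0)
        dz = dM @ params["W1"]
    else:
        g["W1"] = dlogits.T @ z
        g["b1"] = dlogits.sum(0)
        dz = dlogits @ params["W1"]
    dX = dz[:, :, None] * params["w_tok"][None, None, :]
    g["w_tok"] = np.einsum("bg,bgd->d", dz, cache["Xout"])
    g["b_tok"] = np.array([dz.sum()])
    g["w_skip"] = np.array([(dz * cache["F"][:, :, 0]).sum()])
    for l in reversed(range(config.n_layers)):
        c = cache["layers"][l]
        dX1 = dX.copy()
        dR = dX @ params[f"Wf2_{l}"].T
        g[f"Wf2_{l}"] = np.einsum("bgf,bgd->fd", c["R"], dX)
        g[f"bf2_{l}"] = dX.sum((0, 1))
        dU = dR * (c["U"] > 0)
        g[f"Wf1_{l}"] = np.einsum("bgd,bgf->df", c["N2"], dU)
        g[f"bf1_{l}"] = dU.sum((0, 1))
        dN2 = dU @ params[f"Wf1_{l}"].T
        dX1_ln, g[f"ln2g{l}"], g[f"ln2b{l}"] = _ln_backward(
            dN2, params[f"ln2g{l}"], c["xh2"], c["inv2"])
        dX1 += dX1_ln
        dXin = dX1.copy()
        dCc = dX1 @ params[f"Wo{l}"].T
        g[f"Wo{l}"] = np.einsum("bgd,bge->de", c["Cc"], dX1)
        dC = dCc.reshape(B, G, h, dh).transpose(0, 2, 1, 3)
        A, Qh, Kh, Vh = c["A"], c["Qh"], c["Kh"], c["Vh"]
        dA = dC @ Vh.transpose(0, 1, 3, 2)
        dVh = A.transpose(0, 1, 3, 2) @ dC
        dS = A * (dA - (dA * A).sum(-1, keepdims=True))
        dQh = dS @ Kh / np.sqrt(dh)
        dKh = dS.transpose(0, 1, 3, 2) @ Qh / np.sqrt(dh)
        dQ = dQh.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        dK = dKh.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        dV = dVh.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        N1 = c["N1"]
        g[f"Wq{l}"] = np.einsum("bgd,bge->de", N1, dQ)
        g[f"Wk{l}"] = np.einsum("bgd,bge->de", N1, dK)
        g[f"Wv{l}"] = np.einsum("bgd,bge->de", N1, dV)
        dN1 = dQ @ params[f"Wq{l}"].T + dK @ params[f"Wk{l}"].T + dV @ params[f"Wv{l}"].T
        dX_ln, g[f"ln1g{l}"], g[f"ln1b{l}"] = _ln_backward(
            dN1, params[f"ln1g{l}"], c["xh1"], c["inv1"])
        dXin += dX_ln
        dX = dXin
    g["E"] = dX.sum(0)
    g["W_in"] = np.einsum("bgt,bgd->td", cache["F"], dX)
    return g


def _bce_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits, and its gradient."""
    # log(1 + e^x) computed stably
    softplus = np.logaddexp(0.0, logits)
    loss = float(np.mean(softplus - y * logits))
    probs = 1.0 / (1.0 + np.exp(-logits))
    return loss, (probs - y) / y.size


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, p in params.items():
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training / prediction / evaluation


def _check_no_heldout(timepoints: list[str]) -> None:
    leaked = [t for t in timepoints if t == HELDOUT_TIMEPOINT]
    if leaked:
        raise LeakageError(
            f"{len(leaked)} sample(s) from the blind-test timepoint "
            f"{HELDOUT_TIMEPOINT!r} reached the training set"
        )


def train(model: TrainedModel, dataset: Dataset,
          val_fraction: float | None = None, seed: int | None = None) -> TrainedModel:
    """Fit on estrus/0.5/1.5-dpc samples with a stratified validation split.

    The validation split is made on the *original* samples, stratified by
    timepoint, before augmentation; jittered copies are generated only from
    the training portion, so validation loss measures generalization to
    unseen animals rather than to perturbed copies of seen ones.  Hard-fails
    with :class:`LeakageError` if any sample carries the held-out timepoint.
    Early-stops on validation loss and returns the model at its best
    validation epoch.  Fully deterministic under ``seed``.
    """
    from .preprocess import augment  # local import to avoid cycle at module load

    cfg = model.config
    val_fraction = cfg.val_fraction if val_fraction is None else val_fraction
    seed = cfg.seed if seed is None else seed
    _check_no_heldout(dataset.timepoints)
    n = dataset.tensor.n_samples
    if n < 2:
        raise DomainError("need at least 2 samples to train and validate")
    if dataset.tensor.gene_ids != model.gene_ids:
        raise ContractError("dataset gene order differs from the model")
    if dataset.labels.protein_ids != model.protein_ids:
        raise ContractError("dataset protein order differs from the model")

    rng = np.random.default_rng(seed)
    # stratified split by timepoint: at least one validation sample per stratum
    val_idx: list[int] = []
    for tp in sorted(set(dataset.timepoints)):
        members = [i for i, t in enumerate(dataset.timepoints) if t == tp]
        k = max(1, int(round(val_fraction * len(members))))
        val_idx.extend(rng.choice(members, size=min(k, max(len(members) - 1, 1)),
                                  replace=False))
    val_mask = np.zeros(n, bool)
    val_mask[val_idx] = True
    if val_mask.all():
        val_mask[int(rng.integers(n))] = False
    train_split = dataset.subset(np.flatnonzero(~val_mask))
    val_split = dataset.subset(np.flatnonzero(val_mask))
    aug = augment(train_split.tensor, train_split.labels, cfg.n_aug,
                  int(rng.integers(2**31)), jitter_sd=cfg.jitter_sd)
    F_tr = _features(aug.tensor)
    F_va = _features(val_split.tensor)
    if cfg.soft_label_gamma > 0:
        def soft(lbl):
            return np.clip(
                0.5 + cfg.soft_label_gamma * (lbl.normalized_values - lbl.tau), 0.0, 1.0
            ).T
        y_tr, y_va = soft(aug.labels), soft(val_split.labels)
    else:
        y_tr = aug.labels.labels.T  # (S, P)
        y_va = val_split.labels.labels.T

    n_genes, n_proteins = len(model.gene_ids), len(model.protein_ids)
    readout_mask = None
    if cfg.tf_readout_only:
        readout_mask = model.tf_flag[None, :] > 0  # W1 columns are gene tokens

    overall_val = np.inf
    overall_params = model.params
    overall_history: list[dict] = []
    for restart in range(max(cfg.n_restarts, 1)):
        if restart == 0:
            params = model.params  # the init the caller built (cfg.seed)
        else:
            params = _init_params(cfg, n_genes, n_proteins,
                                  (seed + 7919 * restart) % 2**31)
        if readout_mask is not None:
            params["W1"] = params["W1"] * readout_mask
        rng_r = np.random.default_rng((seed + 104729 * restart + 1) % 2**31)
        opt = _Adam(params, cfg.learning_rate)
        best_val = np.inf
        best_params = copy.deepcopy(params)
        best_epoch = -1
        history: list[dict] = []
        n_tr = F_tr.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng_r.permutation(n_tr)
            for start in range(0, n_tr, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits, cache = _forward(params, cfg, F_tr[idx])
                _, dlogits = _bce_loss(logits, y_tr[idx])
                grads = _backward(params, cfg, cache, dlogits)
                if cfg.l1_head > 0:
                    grads["W1"] = grads["W1"] + cfg.l1_head * np.sign(params["W1"])
                opt.step(params, grads)
                if readout_mask is not None:
                    params["W1"] *= readout_mask
            tr_logits, _ = _forward(params, cfg, F_tr, want_cache=False)
            tr_loss, _ = _bce_loss(tr_logits, y_tr)
            va_logits, _ = _forward(params, cfg, F_va, want_cache=False)
            va_loss, _ = _bce_loss(va_logits, y_va)
            history.append({
                "restart": restart,
                "epoch": epoch,
                "train_loss": tr_loss,
                "val_loss": va_loss,
                "train_acc": float(((tr_logits >= 0) == (y_tr >= 0.5)).mean()),
                "val_acc": float(((va_logits >= 0) == (y_va >= 0.5)).mean()),
            })
            if va_loss < best_val - 1e-9:
                best_val = va_loss
                best_params = copy.deepcopy(params)
                best_epoch = epoch
            elif epoch - best_epoch >= cfg.early_stop_patience:
                break
        overall_history.extend(history)
        if best_val < overall_val:
            overall_val = best_val
            overall_params = best_params
    model.params = overall_params
    model.history = overall_history
    model.trained_sample_ids = list(dataset.sample_ids)
    return model


def predict(model: TrainedModel, tensor: ModelInputTensor) -> np.ndarray:
    """Per-protein abundance probabilities, shape (n_proteins, n_samples)."""
    if not model.is_trained:
        warnings.warn("predicting with an untrained model", stacklevel=2)
    tensor = align_genes(tensor, model.gene_ids)
    logits, _ = _forward(model.params, model.config, _features(tensor), want_cache=False)
    return (1.0 / (1.0 + np.exp(-logits))).T


def predict_labels(model: TrainedModel, tensor: ModelInputTensor) -> np.ndarray:
    return (predict(model, tensor) >= 0.5).astype(float)


def attention_maps(model: TrainedModel, tensor: ModelInputTensor) -> np.ndarray:
    """Row-normalized attention of the final encoder layer, averaged over
    heads: shape (n_samples, n_genes, n_genes); entry [s, i, j] is how much
    token i attends to gene j in sample s."""
    tensor = align_genes(tensor, model.gene_ids)
    _, cache = _forward(model.params, model.config, _features(tensor))
    return cache["layers"][-1]["A"].mean(axis=1)


def input_saliency(model: TrainedModel, tensor: ModelInputTensor) -> np.ndarray:
    """|d logit_p / d expression_g| averaged over samples, shape (P, G).

    Exact first-order attribution through every path of the network —
    embedding, residual, attention mixing and the classification head — via
    one vector-Jacobian (backward) pass per protein.
    """
    tensor = align_genes(tensor, model.gene_ids)
    cfg = model.config
    params = model.params
    F = _features(tensor)
    _, cache = _forward(params, cfg, F)
    B, G, _ = F.shape
    P = len(model.protein_ids)
    sal = np.empty((P, G))
    for p in range(P):
        if cfg.mlp_hidden > 0:
            # d logit_p / d z through the hidden ReLU layer, per sample
            gate = (cache["M"] > 0).astype(float)  # (B, H)
            dz = (params["W2"][p][None, :] * gate) @ params["W1"]  # (B, G)
        else:
            dz = np.broadcast_to(params["W1"][p], (B, G)).copy()
        dF = _input_gradient(params, cfg, cache, dz)
        sal[p] = np.abs(dF[:, :, 0]).mean(axis=0)  # expression channel
    return sal


def _input_gradient(params: dict, config: ModelConfig, cache: dict, dz: np.ndarray) -> np.ndarray:
    """Back-propagate a gradient on the token scalars z to the input features."""
    dX = dz[:, :, None] * params["w_tok"][None, None, :]
    B, G, _ = cache["F"].shape
    h = config.n_heads
    dh = config.d_model // h
    for l in reversed(range(config.n_layers)):
        c = cache["layers"][l]
        dX1 = dX.copy()
        dR = dX @ params[f"Wf2_{l}"].T
        dU = dR * (c["U"] > 0)
        dN2 = dU @ params[f"Wf1_{l}"].T
        dX1_ln, _, _ = _ln_backward(dN2, params[f"ln2g{l}"], c["xh2"], c["inv2"])
        dX1 += dX1_ln
        dXin = dX1.copy()
        dCc = dX1 @ params[f"Wo{l}"].T
        dC = dCc.reshape(B, G, h, dh).transpose(0, 2, 1, 3)
        A, Qh, Kh, Vh = c["A"], c["Qh"], c["Kh"], c["Vh"]
        dA = dC @ Vh.transpose(0, 1, 3, 2)
        dVh = A.transpose(0, 1, 3, 2) @ dC
        dS = A * (dA - (dA * A).sum(-1, keepdims=True))
        dQh = dS @ Kh / np.sqrt(dh)
        dKh = dS.transpose(0, 1, 3, 2) @ Qh / np.sqrt(dh)
        dQ = dQh.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        dK = dKh.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        dV = dVh.transpose(0, 2, 1, 3).reshape(B, G, config.d_model)
        dN1 = dQ @ params[f"Wq{l}"].T + dK @ params[f"Wk{l}"].T + dV @ params[f"Wv{l}"].T
        dX_ln, _, _ = _ln_backward(dN1, params[f"ln1g{l}"], c["xh1"], c["inv1"])
        dXin += dX_ln
        dX = dXin
    dF = dX @ params["W_in"].T
    dF[:, :, 0] += dz * params["w_skip"]
    return dF


def head_readout_magnitude(model: TrainedModel) -> np.ndarray:
    """|read-out| of each gene token by each protein's output, (P, G).

    Linear head: the absolute weight matrix itself.  MLP head: magnitudes
    composed through the hidden layer, |W2| @ |W1|.
    """
    if model.config.mlp_hidden > 0:
        return np.abs(model.params["W2"]) @ np.abs(model.params["W1"])
    return np.abs(model.params["W1"])


def evaluate_heldout(model: TrainedModel, dataset: Dataset) -> EvaluationReport:
    """Blind evaluation on held-out-timepoint samples only."""
    wrong = [t for t in dataset.timepoints if t != HELDOUT_TIMEPOINT]
    if wrong:
        raise DomainError(
            f"held-out evaluation accepts only {HELDOUT_TIMEPOINT!r} samples; "
            f"found {sorted(set(wrong))}"
        )
    overlap = set(dataset.sample_ids) & set(model.trained_sample_ids)
    if overlap:
        raise LeakageError(f"samples {sorted(overlap)} were seen during training")
    y_true = dataset.labels.labels  # (P, S)
    y_pred = predict_labels(model, dataset.tensor)
    per_protein: dict[str, dict[str, float]] = {}
    for i, pid in enumerate(model.protein_ids):
        t, p = y_true[i], y_pred[i]
        prec, rec, f1, _ = precision_recall_fscore_support(
            t, p, average="binary", zero_division=0.0
        )
        per_protein[pid] = {
            "accuracy": float((t == p).mean()),
            "precision": float(prec), "recall": float(rec), "f1": float(f1),
        }
    tflat, pflat = y_true.ravel(), y_pred.ravel()
    tp = int(((tflat == 1) & (pflat == 1)).sum())
    fp = int(((tflat == 0) & (pflat == 1)).sum())
    fn = int(((tflat == 1) & (pflat == 0)).sum())
    tn = int(((tflat == 0) & (pflat == 0)).sum())
    mprec, mrec, mf1, _ = precision_recall_fscore_support(
        tflat, pflat, average="binary", zero_division=0.0
    )
    micro = {"accuracy": float((tflat == pflat).mean()),
             "precision": float(mprec), "recall": float(mrec), "f1": float(mf1)}
    macro = {k: float(np.mean([d[k] for d in per_protein.values()]))
             for k in ("accuracy", "precision", "recall", "f1")}
    return EvaluationReport(
        protein_ids=list(model.protein_ids),
        per_protein=per_protein,
        micro=micro,
        macro=macro,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        split_description=f"blind test on held-out timepoint {HELDOUT_TIMEPOINT}",
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Write parameters + config + id lists into one zip container."""
    path = Path(path)
    meta = {
        "schema_version": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "gene_ids": model.gene_ids,
        "protein_ids": model.protein_ids,
        "history": model.history,
        "trained_sample_ids": model.trained_sample_ids,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        import io as _io

        buf = _io.BytesIO()
        np.savez(buf, tf_flag=model.tf_flag,
                 **{f"param_{k}": v for k, v in model.params.items()})
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema_version") != CHECKPOINT_SCHEMA:
            raise ContractError(
                f"checkpoint schema {meta.get('schema_version')} is not supported"
            )
        import io as _io

        arrays = np.load(_io.BytesIO(zf.read("arrays.npz")))
        params = {k[len("param_"):]: arrays[k] for k in arrays.files if k.startswith("param_")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            config = ModelConfig(**meta["config"])
        return TrainedModel(
            params=params,
            config=config,
            gene_ids=meta["gene_ids"],
            protein_ids=meta["protein_ids"],
            tf_flag=arrays["tf_flag"],
            history=meta["history"],
            trained_sample_ids=meta["trained_sample_ids"],
        )
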