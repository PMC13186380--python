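"""The six-architecture model family, class-weighted training and random
search.

All architectures share the same branch vocabulary: a decoder-only (causal)
transformer with rotary positional embeddings over the per-second sequence —
with the 24 coarse 5-minute context rows linearly projected and prepended as
tokens, rotary positions continuing across both — plus feed-forward branches
over the baseline vector and the 768-d diagnosis embedding. Branch outputs are
concatenated into a feed-forward head emitting one event probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor, causal_attention, concat, dropout, layer_norm
from .evaluation import auroc

ARCHITECTURES = (
    "baseline_only_ff",
    "combined_ff",
    "vitals_only_transformer",
    "combined_transformer_onehot_reduced",
    "combined_transformer_vector_reduced",
    "combined_transformer_vector_full",
)

#: Which branches each architecture wires together. The one-hot-diagnosis
#: variant carries the diagnosis one-hot inside the baseline vector, so it has
#: no separate embedding branch.
_ARCH_BRANCHES = {
    "baseline_only_ff": {"transformer": False, "fine_ff": False, "baseline": "full", "dx": True},
    "combined_ff": {"transformer": False, "fine_ff": True, "baseline": "reduced", "dx": True},
    "vitals_only_transformer": {"transformer": True, "fine_ff": False, "baseline": None, "dx": False},
    "combined_transformer_onehot_reduced": {"transformer": True, "fine_ff": False, "baseline": "reduced", "dx": False},
    "combined_transformer_vector_reduced": {"transformer": True, "fine_ff": False, "baseline": "reduced", "dx": True},
    "combined_transformer_vector_full": {"transformer": True, "fine_ff": False, "baseline": "full", "dx": True},
}


class ConstructionError(ValueError):
    """Model/branch dimensions inconsistent with the windowing outputs."""


@dataclass
class HyperParams:
    """Training and architecture hyperparameters (desk-scale defaults)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 5
    hidden_dim: int = 64  # feed-forward branch width
    model_width: int = 64  # transformer width
    transformer_layers: int = 2
    attention_heads: int = 4
    ff_mult: int = 2
    dropout: float = 0.1
    l2_weight: float = 0.0
    max_norm: float | None = None
    batch_norm: bool = False  # per-branch layer normalisation toggle
    positional_weighting: bool = False  # recency scaling of token embeddings
    class_weight: str = "inverse_prevalence"  # or "none"
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "epochs", "hidden_dim",
                     "model_width", "transformer_layers", "attention_heads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.model_width % self.attention_heads != 0:
            raise ValueError("attention_heads must divide model_width")


@dataclass
class FeatureDims:
    fine: int = 36
    context: int = 21
    baseline: int = 0
    dx: int = 768


def _rotary_tables(n_pos: int, dh: int) -> tuple[np.ndarray, np.ndarray]:
    half = dh // 2
    inv_freq = 10000.0 ** (-np.arange(half) / half)
    ang = np.arange(n_pos)[:, None] * inv_freq[None, :]
    return np.cos(ang).astype(np.float32), np.sin(ang).astype(np.float32)


def _apply_rotary(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Rotate query/key features pairwise by position-dependent angles.

    ``x`` is (B, H, T, dh); split-half convention, fused forward/backward
    (the rotation is orthogonal, so the backward pass is the inverse
    rotation applied to the gradient)."""
    half = x.shape[-1] // 2
    c, s = cos[None, None], sin[None, None]
    x1, x2 = x.data[..., :half], x.data[..., half:]
    out_data = np.concatenate([x1 * c - x2 * s, x1 * s + x2 * c], axis=-1)

    def bw(g):
        g1, g2 = g[..., :half], g[..., half:]
        x._accumulate(
            np.concatenate([g1 * c + g2 * s, -g1 * s + g2 * c], axis=-1)
        )

    return Tensor._node(out_data, (x,), bw)


class Model:
    """One architecture instance: parameter store + differentiable forward."""

    def __init__(self, arch: str, hp: HyperParams, dims: FeatureDims):
        if arch not in ARCHITECTURES:
            raise ConstructionError(f"unknown architecture {arch!r}")
        if dims.fine != 36:
            raise ConstructionError(
                f"fine branch: expected 36-wide input, got {dims.fine}"
            )
        if dims.dx != 768:
            raise ConstructionError(
                f"diagnosis branch: expected 768-d embedding, got {dims.dx}"
            )
        self.arch = arch
        self.hp = hp
        self.dims = dims
        self.branches = _ARCH_BRANCHES[arch]
        if self.branches["baseline"] and dims.baseline <= 0:
            raise ConstructionError(
                "baseline branch: baseline dimension must be positive"
            )
        self.params: dict[str, Tensor] = {}
        self.history: list[dict] = []
        self._rng = np.random.default_rng(hp.seed)
        self._build()

    # -- construction --------------------------------------------------------

    def _linear(
        self, name: str, fan_in: int, fan_out: int,
        zero: bool = False, bias_scale: float = 0.0,
    ):
        scale = 0.0 if zero else np.sqrt(2.0 / (fan_in + fan_out))
        self.params[f"{name}.W"] = Tensor(
            self._rng.normal(0, scale, (fan_in, fan_out)).astype(np.float32),
            requires_grad=True,
        )
        bias = (
            self._rng.normal(0, bias_scale, fan_out)
            if bias_scale
            else np.zeros(fan_out)
        )
        self.params[f"{name}.b"] = Tensor(
            bias.astype(np.float32), requires_grad=True
        )

    def _ln(self, name: str, dim: int):
        self.params[f"{name}.g"] = Tensor(
            np.ones(dim, dtype=np.float32), requires_grad=True
        )
        self.params[f"{name}.B"] = Tensor(
            np.zeros(dim, dtype=np.float32), requires_grad=True
        )

    def _build(self):
        hp, dims = self.hp, self.dims
        head_in = 0
        if self.branches["transformer"]:
            d = hp.model_width
            # non-zero projection biases keep the token embedding of an
            # all-zero ("fully imputed") input away from layer-norm's
            # degenerate point, so attribution paths from the zero baseline
            # stay smooth
            self._linear("fine_proj", dims.fine, d, bias_scale=0.3)
            self._linear("ctx_proj", dims.context, d, bias_scale=0.3)
            for l in range(hp.transformer_layers):
                p = f"layer{l}"
                self._ln(f"{p}.ln1", d)
                self._linear(f"{p}.q", d, d)
                self._linear(f"{p}.k", d, d)
                self._linear(f"{p}.v", d, d)
                self._linear(f"{p}.o", d, d)
                self._ln(f"{p}.ln2", d)
                self._linear(f"{p}.ff1", d, hp.ff_mult * d)
                self._linear(f"{p}.ff2", hp.ff_mult * d, d)
            self._ln("final_ln", d)
            head_in += d
        if self.branches["fine_ff"]:
            self._linear("ff_fine", dims.fine, hp.hidden_dim)
            self._linear("ff_ctx", dims.context, hp.hidden_dim)
            self._linear("ff_pool", 2 * hp.hidden_dim, hp.hidden_dim)
            head_in += hp.hidden_dim
        if self.branches["baseline"]:
            self._linear("base1", dims.baseline, hp.hidden_dim)
            self._linear("base2", hp.hidden_dim, hp.hidden_dim)
            if hp.batch_norm:
                self._ln("base_norm", hp.hidden_dim)
            head_in += hp.hidden_dim
        if self.branches["dx"]:
            self._linear("dx1", dims.dx, hp.hidden_dim)
            self._linear("dx2", hp.hidden_dim, hp.hidden_dim)
            if hp.batch_norm:
                self._ln("dx_norm", hp.hidden_dim)
            head_in += hp.hidden_dim
        self._linear("head1", head_in, hp.hidden_dim)
        self._linear("head2", hp.hidden_dim, 1, zero=True)

    # -- forward --------------------------------------------------------------

    def _lin(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _lnorm(self, name: str, x: Tensor) -> Tensor:
        return layer_norm(x, self.params[f"{name}.g"], self.params[f"{name}.B"])

    def _transformer(self, fine: Tensor, ctx: Tensor, rng) -> Tensor:
        hp = self.hp
        d, H = hp.model_width, hp.attention_heads
        dh = d // H
        xc = self._lin("ctx_proj", ctx)
        xf = self._lin("fine_proj", fine)
        x = concat([xc, xf], axis=1)  # (B, 24+T, d)
        B, T, _ = x.shape
        if hp.positional_weighting:
            w = np.linspace(0.5, 1.5, T)[None, :, None]
            x = x * Tensor(w)
        cos, sin = _rotary_tables(T, dh)
        mask = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)[None, None]
        for l in range(hp.transformer_layers):
            p = f"layer{l}"
            h = self._lnorm(f"{p}.ln1", x)
            q = self._lin(f"{p}.q", h).reshape(B, T, H, dh).swapaxes(1, 2)
            k = self._lin(f"{p}.k", h).reshape(B, T, H, dh).swapaxes(1, 2)
            v = self._lin(f"{p}.v", h).reshape(B, T, H, dh).swapaxes(1, 2)
            q = _apply_rotary(q, cos, sin)
            k = _apply_rotary(k, cos, sin)
            o = causal_attention(q, k, v, mask).swapaxes(1, 2).reshape(B, T, d)
            o = dropout(o, self.hp.dropout, rng)
            x = x + self._lin(f"{p}.o", o)
            h = self._lnorm(f"{p}.ln2", x)
            h = self._lin(f"{p}.ff1", h).gelu()
            h = dropout(h, self.hp.dropout, rng)
            x = x + self._lin(f"{p}.ff2", h)
        x = self._lnorm("final_ln", x)
        return x[:, -1, :]

    def forward(self, batch: dict, rng: np.random.Generator | None = None) -> Tensor:
        """Probability of an event in the label window, per sample.

        ``batch`` values may be ndarrays or Tensors (Tensors with
        ``requires_grad`` receive input gradients, used by attribution).
        """
        t = {
            k: (
                v
                if isinstance(v, Tensor)
                else Tensor(np.asarray(v, dtype=np.float32))
            )
            for k, v in batch.items()
        }
        if t["fine"].shape[-1] != self.dims.fine:
            raise ConstructionError("fine branch: input width mismatch")
        if self.branches["baseline"] and t["baseline"].shape[-1] != self.dims.baseline:
            raise ConstructionError(
                f"baseline branch: expected width {self.dims.baseline}, got "
                f"{t['baseline'].shape[-1]} (configuration mismatch)"
            )
        outs: list[Tensor] = []
        if self.branches["transformer"]:
            outs.append(self._transformer(t["fine"], t["context"], rng))
        if self.branches["fine_ff"]:
            hf = self._lin("ff_fine", t["fine"]).relu().mean(axis=1)
            hc = self._lin("ff_ctx", t["context"]).relu().mean(axis=1)
            outs.append(self._lin("ff_pool", concat([hf, hc], axis=-1)).relu())
        if self.branches["baseline"]:
            h = self._lin("base1", t["baseline"]).relu()
            h = self._lin("base2", h).relu()
            if self.hp.batch_norm:
                h = self._lnorm("base_norm", h)
            outs.append(h)
        if self.branches["dx"]:
            h = self._lin("dx1", t["dx"]).relu()
            h = self._lin("dx2", h).relu()
            if self.hp.batch_norm:
                h = self._lnorm("dx_norm", h)
            outs.append(h)
        h = concat(outs, axis=-1) if len(outs) > 1 else outs[0]
        h = dropout(h, self.hp.dropout, rng)
        h = self._lin("head1", h).relu()
        logit = self._lin("head2", h)
        return logit.reshape(logit.shape[0]).sigmoid()

    def token_states(self, batch: dict) -> np.ndarray:
        """Hidden states of all transformer token positions (for causality
        checks); (B, 24+T, d)."""
        if not self.branches["transformer"]:
            raise ConstructionError(f"{self.arch} has no transformer branch")
        t = {k: Tensor(np.asarray(v)) for k, v in batch.items()}
        hp = self.hp
        d, H = hp.model_width, hp.attention_heads
        dh = d // H
        xc = self._lin("ctx_proj", t["context"])
        xf = self._lin("fine_proj", t["fine"])
        x = concat([xc, xf], axis=1)
        B, T, _ = x.shape
        cos, sin = _rotary_tables(T, dh)
        mask = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)[None, None]
        for l in range(hp.transformer_layers):
            p = f"layer{l}"
            h = self._lnorm(f"{p}.ln1", x)
            q = self._lin(f"{p}.q", h).reshape(B, T, H, dh).swapaxes(1, 2)
            k = self._lin(f"{p}.k", h).reshape(B, T, H, dh).swapaxes(1, 2)
            v = self._lin(f"{p}.v", h).reshape(B, T, H, dh).swapaxes(1, 2)
            q = _apply_rotary(q, cos, sin)
            k = _apply_rotary(k, cos, sin)
            o = causal_attention(q, k, v, mask).swapaxes(1, 2).reshape(B, T, d)
            x = x + self._lin(f"{p}.o", o)
            h = self._lnorm(f"{p}.ln2", x)
            x = x + self._lin(f"{p}.ff2", self._lin(f"{p}.ff1", h).gelu())
        return self._lnorm("final_ln", x).data

    # -- prediction / utilities ----------------------------------------------

    def predict(self, data: dict, batch_size: int = 256) -> np.ndarray:
        """Per-window probabilities in [0, 1]; batch-size invariant."""
        n = len(data["fine"])
        out = np.empty(n)
        for i in range(0, n, batch_size):
            batch = {k: data[k][i : i + batch_size] for k in
                     ("fine", "context", "baseline", "dx") if k in data}
            out[i : i + batch_size] = self.forward(batch).data
        return out

    def parameter_list(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k].data = v.copy()


def build_model(arch: str, hp: HyperParams, dims: FeatureDims) -> Model:
    """Construct one of the six architectures (wiring per branch table)."""
    return Model(arch, hp, dims)


def count_parameters(model: Model) -> int:
    """Total trainable scalar parameters (invariant to training)."""
    return int(sum(p.data.size for p in model.params.values()))


def class_weight(y: np.ndarray, mode: str = "inverse_prevalence") -> float:
    """Positive-class loss weight; inverse prevalence = n_neg / n_pos."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if mode == "none":
        return 1.0
    if n_pos == 0:
        raise ValueError("degenerate training labels: no positive class")
    return n_neg / n_pos


def train(
    model: Model,
    train_data: dict,
    tune_data: dict,
    task: str = "respiratory",
    verbose: bool = False,
) -> Model:
    """Class-weighted binary cross-entropy training with Adam.

    Seeded initialisation and shuffling; the epoch with the best tuning-set
    AUROC is restored at the end. Training history (per-epoch loss and tune
    AUROC) is recorded on ``model.history``.
    """
    hp = model.hp
    y = train_data[f"y_{task}"].astype(float)
    y_tune = tune_data[f"y_{task}"].astype(float)
    if y.min() == y.max():
        raise ValueError("degenerate single-class training labels")
    w_pos = class_weight(y, hp.class_weight)
    opt = Adam(
        model.parameter_list(), lr=hp.learning_rate,
        weight_decay=hp.l2_weight, max_norm=hp.max_norm,
    )
    rng = np.random.default_rng(hp.seed + 1)
    n = len(y)
    best = (-np.inf, None)
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        drop_rng = np.random.default_rng(hp.seed + 1000 + epoch)
        losses = []
        for i in range(0, n, hp.batch_size):
            idx = order[i : i + hp.batch_size]
            batch = {k: train_data[k][idx] for k in
                     ("fine", "context", "baseline", "dx")}
            yb = y[idx]
            p = model.forward(batch, rng=drop_rng)
            pc = p * (1 - 2e-7) + 1e-7  # clamp away from {0,1}
            wt = Tensor(np.where(yb == 1, w_pos, 1.0))
            yb_t = Tensor(yb)
            loss = -(
                wt * (yb_t * pc.log() + (1.0 - yb_t) * (1.0 - pc).log())
            ).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        scores = model.predict(tune_data)
        tune_auroc = auroc(scores, y_tune) if y_tune.min() != y_tune.max() else np.nan
        model.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "tune_auroc": tune_auroc}
        )
        if verbose:
            print(f"epoch {epoch}: loss {np.mean(losses):.4f} tune AUROC {tune_auroc:.3f}")
        if np.isfinite(tune_auroc) and tune_auroc > best[0]:
            best = (tune_auroc, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model


DEFAULT_SEARCH_SPACE = {
    "learning_rate": [3e-4, 1e-3, 3e-3],
    "batch_size": [32, 64],
    "epochs": [3, 5],
    "hidden_dim": [32, 64],
    "model_width": [32, 64],
    "transformer_layers": [1, 2],
    "attention_heads": [2, 4],
    "dropout": [0.0, 0.1, 0.2],
    "l2_weight": [0.0, 1e-4],
    "max_norm": [None, 3.0],
    "batch_norm": [False, True],
    "positional_weighting": [False, True],
}


def random_search(
    arch: str,
    dims: FeatureDims,
    train_data: dict,
    tune_data: dict,
    task: str = "respiratory",
    space: dict | None = None,
    budget: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, list[dict]]:
    """Random-search hyperparameter optimisation by tuning-set AUROC.

    Draws ``budget`` configurations from the space with the given seed, trains
    each, and returns the best hyperparameters plus the full leaderboard.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    leaderboard = []
    best = (-np.inf, None)
    for trial in range(budget):
        draw = {k: v[rng.integers(len(v))] for k, v in space.items()}
        while draw.get("model_width", 64) % draw.get("attention_heads", 4) != 0:
            draw["attention_heads"] = space["attention_heads"][
                rng.integers(len(space["attention_heads"]))
            ]
        hp = HyperParams(seed=seed + trial, **draw)
        model = build_model(arch, hp, dims)
        train(model, train_data, tune_data, task)
        score = max(h["tune_auroc"] for h in model.history)
        leaderboard.append({"trial": trial, "tune_auroc": score, "hp": asdict(hp)})
        if score > best[0]:
            best = (score, hp)
    return best[1], leaderboard
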