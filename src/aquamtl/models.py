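"""The four multi-task sharing structures and their tower heads.

Every structure follows the shared-bottom template: per-indicator
encoders (one dense + ReLU each, never weight-shared across
indicators), an optional jointly maintained hidden block, an optional
gating mechanism, and one task-specific tower per indicator that emits
the station-vector prediction through a ReLU output head.

* ``hard`` — the towers all consume the concatenation of the four
  encoder outputs.
* ``soft`` — a two-layer hidden block over all indicators' raw inputs
  produces a shared vector that is concatenated to each task's own
  encoder output before its tower.
* ``gate`` — per task, a softmax gate over the four encoder outputs
  produces mixture weights; a weight-tied linear map turns each
  encoder output into a candidate vector and the tower consumes their
  convex combination (a mixture-of-experts-style fusion).
* ``gh`` — gated-hidden: combines the soft hidden block with a
  two-way gate per task that arbitrates between the task's own mapped
  representation and a projection of the shared hidden vector.

Two reference structures are included for comparisons: ``single_task``
(an independent encoder + tower per indicator, seeing only its own
history) and ``linear_baseline`` (one affine map per indicator).

Forward passes are written against ``autograd.numpy`` so the training
loop can differentiate the joint loss automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np

from .errors import ConfigError, DataError
from .panel import DEFAULT_INDICATORS

STRUCTURES = ("hard", "soft", "gate", "gh", "single_task", "linear_baseline")
TOWER_TYPES = ("mlp", "lstm", "gru", "cnn", "attention")

#: Task-specific tower depths (number of hidden dense+ReLU layers).
DEFAULT_TOWER_DEPTHS = {"pH": 3, "DO": 3, "CODMn": 2, "NH3N": 2}

#: Subtracted from the min-max-scaled inputs before the encoder and
#: hidden-block layers: [0,1]-scaled features are all positive, which
#: conditions first-layer learning badly; shifting them to [-1/2, 1/2]
#: centers the pre-activations without changing the data contract.
INPUT_CENTER = 0.5


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def relu(x):
    """Elementwise max(x, 0)."""
    return anp.maximum(x, 0.0)


def softmax(logits):
    """Exp-normalize along the last axis, stabilized by max subtraction."""
    z = logits - anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=-1, keepdims=True)


def dense_layer(x, W, b, activation: bool = True):
    """Affine map z = xW + b, optionally followed by ReLU.

    ``x`` is (batch, n_in) or (n_in,); ``W`` is (n_in, n_out).
    """
    if anp.shape(x)[-1] != anp.shape(W)[0]:
        raise DataError(
            f"dense dimension mismatch: input {anp.shape(x)[-1]} vs weight {anp.shape(W)[0]}"
        )
    z = anp.dot(x, W) + b
    return relu(z) if activation else z


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureConfig:
    """Which sharing structure / towers to build and at what widths."""

    structure: str = "gh"
    tower_type: str = "mlp"
    tasks: tuple[str, ...] = DEFAULT_INDICATORS
    hidden_width: int = 64
    tower_depths: dict = field(default_factory=lambda: dict(DEFAULT_TOWER_DEPTHS))
    gh_literal_fusion: bool = False
    tower_seq_len: int = 5

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ConfigError(f"unknown structure {self.structure!r}; pick from {STRUCTURES}")
        if self.tower_type not in TOWER_TYPES:
            raise ConfigError(f"unknown tower_type {self.tower_type!r}; pick from {TOWER_TYPES}")
        if not self.tasks:
            raise ConfigError("task subset must be non-empty")
        if len(set(self.tasks)) != len(self.tasks):
            raise ConfigError("task subset contains duplicates")
        if self.hidden_width < 1:
            raise ConfigError("hidden_width must be >= 1")
        if self.tower_seq_len < 1:
            raise ConfigError("tower_seq_len must be >= 1")

    def depth(self, task: str) -> int:
        d = self.tower_depths.get(task, 2)
        if d < 1:
            raise ConfigError(f"tower depth for {task} must be >= 1")
        return d


@dataclass(frozen=True)
class ModelDims:
    """Problem dimensions the layer shapes derive from."""

    lookback: int
    n_stations: int

    @property
    def input_dim(self) -> int:
        return self.lookback * self.n_stations


@dataclass
class ActivationBundle:
    """Intermediate vectors of one forward pass (for inspection/tests)."""

    outs: dict = field(default_factory=dict)           # encoder outputs per task
    out_shared: np.ndarray | None = None               # hard: concatenated encoders
    hidden_shared: np.ndarray | None = None            # soft/gh hidden block output
    hiddens: dict = field(default_factory=dict)        # gate/gh mapped candidates
    gate_weights: dict = field(default_factory=dict)   # softmax weights per task
    v: dict = field(default_factory=dict)              # tower inputs per task


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_dense(rng: np.random.Generator, n_in: int, n_out: int,
                bias: float = 0.0) -> dict:
    limit = np.sqrt(6.0 / n_in)
    return {
        "W": rng.uniform(-limit, limit, size=(n_in, n_out)),
        "b": np.full(n_out, float(bias)),
    }


def _tower_input_dim(config: StructureConfig, dims: ModelDims) -> int:
    h = config.hidden_width
    return {
        "hard": h * len(config.tasks),
        "soft": 2 * h,
        "gate": h,
        "gh": h,
        "single_task": h,
    }[config.structure]


def _init_tower(rng, config: StructureConfig, task: str, n_in: int, n_stations: int) -> dict:
    h = config.hidden_width
    if config.tower_type == "mlp":
        layers = []
        d = n_in
        for _ in range(config.depth(task)):
            layers.append(_init_dense(rng, d, h))
            d = h
        # head bias starts mid-range of the [0,1]-scaled targets so no
        # output unit is born on the dead side of its ReLU
        layers.append(_init_dense(rng, d, n_stations, bias=0.5))
        return {"layers": layers}
    # sequence towers: reshape v to (seq_len, feat), one canonical layer, dense head
    seq = config.tower_seq_len
    feat = -(-n_in // seq)  # ceil
    if config.tower_type == "lstm":
        core = {
            "Wx": _init_dense(rng, feat, 4 * h)["W"],
            "Wh": _init_dense(rng, h, 4 * h)["W"],
            "b": np.zeros(4 * h),
        }
    elif config.tower_type == "gru":
        core = {
            "Wx": _init_dense(rng, feat, 3 * h)["W"],
            "Wh": _init_dense(rng, h, 3 * h)["W"],
            "b": np.zeros(3 * h),
        }
    elif config.tower_type == "cnn":
        limit = np.sqrt(6.0 / (3 * feat))
        core = {
            "K": rng.uniform(-limit, limit, size=(3, feat, h)),
            "b": np.zeros(h),
        }
    else:  # attention
        core = {
            "Wq": _init_dense(rng, feat, h)["W"],
            "Wk": _init_dense(rng, feat, h)["W"],
            "Wv": _init_dense(rng, feat, h)["W"],
        }
    return {"core": core, "head": _init_dense(rng, h, n_stations, bias=0.5)}


def build_model(config: StructureConfig, dims: ModelDims, seed: int = 0) -> dict:
    """Allocate all layer parameters with He-style fan-in uniform init.

    The same config, dims and seed always give identical parameters.
    """
    if dims.lookback < 1 or dims.n_stations < 1:
        raise ConfigError("lookback and n_stations must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    h = config.hidden_width
    D = dims.input_dim
    S = dims.n_stations
    tasks = config.tasks
    params: dict = {}

    if config.structure == "linear_baseline":
        params["towers"] = {t: {"layer": _init_dense(rng, D, S)} for t in tasks}
        return params

    params["encoders"] = {t: _init_dense(rng, D, h) for t in tasks}

    if config.structure in ("soft", "gh"):
        # two dense+ReLU layers over the concatenation of all task inputs
        params["hidden"] = [
            _init_dense(rng, D * len(tasks), h),
            _init_dense(rng, h, h),
        ]
    if config.structure == "gate":
        params["gates"] = {t: _init_dense(rng, h * len(tasks), len(tasks)) for t in tasks}
        params["hidden_map"] = _init_dense(rng, h, h)  # tied across indicators
    if config.structure == "gh":
        params["gates"] = {t: _init_dense(rng, 2 * h, 2) for t in tasks}
        params["hidden_map"] = _init_dense(rng, 2 * h, h)  # tied across tasks
        params["proj"] = _init_dense(rng, h, h)  # shared-hidden projection for fusion

    n_in = _tower_input_dim(config, dims)
    params["towers"] = {t: _init_tower(rng, config, t, n_in, S) for t in tasks}
    return params


def count_params(params) -> int:
    """Total scalar parameter count of a (possibly nested) parameter tree."""
    if isinstance(params, dict):
        return sum(count_params(v) for v in params.values())
    if isinstance(params, (list, tuple)):
        return sum(count_params(v) for v in params)
    return int(np.size(params))


# ---------------------------------------------------------------------------
# towers
# ---------------------------------------------------------------------------

def tower_forward(v, tower: dict, kind: str = "mlp", seq_len: int = 5):
    """Run one task's tower on its fused input ``v`` (batch, n_in).

    The MLP tower is a stack of dense+ReLU layers ending in a
    station-sized ReLU head.  Sequence towers reshape ``v`` to
    (seq_len, feat) — zero-padded if needed — apply one canonical
    layer of the named kind, and finish with the same dense ReLU head.
    ``kind='affine'`` is the linear baseline: a single affine map.
    """
    if kind == "affine":
        lay = tower["layer"]
        return dense_layer(v, lay["W"], lay["b"], activation=False)
    if kind == "mlp":
        x = v
        for lay in tower["layers"]:
            x = dense_layer(x, lay["W"], lay["b"], activation=True)
        return x
    if kind not in TOWER_TYPES:
        raise ConfigError(f"unknown tower kind {kind!r}")

    core = tower["core"]
    feat = core["K"].shape[1] if kind == "cnn" else (
        core["Wq"].shape[0] if kind == "attention" else core["Wx"].shape[0]
    )
    n = anp.shape(v)[0]
    total = seq_len * feat
    pad = total - anp.shape(v)[1]
    if pad < 0:
        raise DataError("tower input longer than seq_len * feat")
    if pad > 0:
        v = anp.concatenate([v, anp.zeros((n, pad))], axis=1)
    x = anp.reshape(v, (n, seq_len, feat))

    if kind == "lstm":
        h_dim = core["Wh"].shape[0]
        h = anp.zeros((n, h_dim))
        c = anp.zeros((n, h_dim))
        for t in range(seq_len):
            g = anp.dot(x[:, t, :], core["Wx"]) + anp.dot(h, core["Wh"]) + core["b"]
            i, f, o, u = (g[:, :h_dim], g[:, h_dim:2 * h_dim],
                          g[:, 2 * h_dim:3 * h_dim], g[:, 3 * h_dim:])
            c = _sigmoid(f) * c + _sigmoid(i) * anp.tanh(u)
            h = _sigmoid(o) * anp.tanh(c)
        pooled = h
    elif kind == "gru":
        h_dim = core["Wh"].shape[0]
        h = anp.zeros((n, h_dim))
        for t in range(seq_len):
            g = anp.dot(x[:, t, :], core["Wx"]) + anp.dot(h, core["Wh"]) + core["b"]
            r = _sigmoid(g[:, :h_dim])
            z = _sigmoid(g[:, h_dim:2 * h_dim])
            cand = anp.tanh(
                anp.dot(x[:, t, :], core["Wx"][:, 2 * h_dim:])
                + anp.dot(r * h, core["Wh"][:, 2 * h_dim:])
                + core["b"][2 * h_dim:]
            )
            h = (1.0 - z) * h + z * cand
        pooled = h
    elif kind == "cnn":
        # width-3 'same' convolution along the sequence axis, then mean pool
        xp = anp.concatenate(
            [anp.zeros((n, 1, feat)), x, anp.zeros((n, 1, feat))], axis=1
        )
        conv = [
            anp.dot(xp[:, t, :], core["K"][0])
            + anp.dot(xp[:, t + 1, :], core["K"][1])
            + anp.dot(xp[:, t + 2, :], core["K"][2])
            + core["b"]
            for t in range(seq_len)
        ]
        pooled = anp.mean(anp.stack([relu(cv) for cv in conv], axis=1), axis=1)
    else:  # attention: single-head scaled dot-product self-attention, mean pool
        q = anp.einsum("ntf,fh->nth", x, core["Wq"])
        k = anp.einsum("ntf,fh->nth", x, core["Wk"])
        vv = anp.einsum("ntf,fh->nth", x, core["Wv"])
        scores = anp.einsum("nth,nsh->nts", q, k) / anp.sqrt(float(core["Wq"].shape[1]))
        att = softmax(scores)
        pooled = anp.mean(anp.einsum("nts,nsh->nth", att, vv), axis=1)

    head = tower["head"]
    return dense_layer(pooled, head["W"], head["b"], activation=True)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _check_inputs(config: StructureConfig, inputs: dict) -> None:
    missing = [t for t in config.tasks if t not in inputs]
    if missing:
        raise DataError(f"inputs missing task(s) {missing}; model tasks are {config.tasks}")


def encode_indicators(inputs: dict, params: dict, config: StructureConfig) -> dict:
    """One dense+ReLU encoder per indicator, no weight sharing across them.

    Inputs are shifted by ``INPUT_CENTER`` before the dense layer (see
    the constant's note).
    """
    _check_inputs(config, inputs)
    outs = {}
    for t in config.tasks:
        enc = params["encoders"][t]
        outs[t] = dense_layer(inputs[t] - INPUT_CENTER, enc["W"], enc["b"],
                              activation=True)
    return outs


def _run_hidden_block(inputs: dict, params: dict, config: StructureConfig):
    x = anp.concatenate([inputs[t] for t in config.tasks], axis=1) - INPUT_CENTER
    for lay in params["hidden"]:
        x = dense_layer(x, lay["W"], lay["b"], activation=True)
    return x


def forward_hard(params: dict, config: StructureConfig, inputs: dict,
                 return_activations: bool = False):
    """Hard sharing: all towers consume the concatenated encoder outputs."""
    outs = encode_indicators(inputs, params, config)
    out_shared = anp.concatenate([outs[t] for t in config.tasks], axis=1)
    preds = {t: tower_forward(out_shared, params["towers"][t], config.tower_type, config.tower_seq_len)
             for t in config.tasks}
    if return_activations:
        return preds, ActivationBundle(outs=outs, out_shared=out_shared,
                                       v={t: out_shared for t in config.tasks})
    return preds


def forward_soft(params: dict, config: StructureConfig, inputs: dict,
                 return_activations: bool = False):
    """Soft sharing: each tower sees [own encoder output, shared hidden vector]."""
    outs = encode_indicators(inputs, params, config)
    hidden_shared = _run_hidden_block(inputs, params, config)
    v = {t: anp.concatenate([outs[t], hidden_shared], axis=1) for t in config.tasks}
    preds = {t: tower_forward(v[t], params["towers"][t], config.tower_type, config.tower_seq_len)
             for t in config.tasks}
    if return_activations:
        return preds, ActivationBundle(outs=outs, hidden_shared=hidden_shared, v=v)
    return preds


def forward_gate(params: dict, config: StructureConfig, inputs: dict,
                 return_activations: bool = False):
    """Gated sharing: per-task softmax weights fuse the mapped encoder outputs."""
    outs = encode_indicators(inputs, params, config)
    cat = anp.concatenate([outs[t] for t in config.tasks], axis=1)
    hm = params["hidden_map"]
    # one weight-tied linear map turns each encoder output into a candidate
    hiddens = {t: dense_layer(outs[t], hm["W"], hm["b"], activation=False)
               for t in config.tasks}
    gate_weights, v, preds = {}, {}, {}
    for t in config.tasks:
        g = params["gates"][t]
        w = softmax(dense_layer(cat, g["W"], g["b"], activation=False))
        gate_weights[t] = w
        fused = sum(w[:, i:i + 1] * hiddens[s] for i, s in enumerate(config.tasks))
        v[t] = fused
        preds[t] = tower_forward(fused, params["towers"][t], config.tower_type, config.tower_seq_len)
    if return_activations:
        return preds, ActivationBundle(outs=outs, hiddens=hiddens,
                                       gate_weights=gate_weights, v=v)
    return preds


def forward_gh(params: dict, config: StructureConfig, inputs: dict,
               return_activations: bool = False):
    """Gated-hidden sharing: a two-way gate arbitrates between the task's own
    mapped representation and a projection of the shared hidden vector."""
    outs = encode_indicators(inputs, params, config)
    hidden_shared = _run_hidden_block(inputs, params, config)
    hm = params["hidden_map"]
    pj = params["proj"]
    proj = dense_layer(hidden_shared, pj["W"], pj["b"], activation=False)
    gate_weights, hiddens, v, preds = {}, {}, {}, {}
    for t in config.tasks:
        g_in = anp.concatenate([outs[t], hidden_shared], axis=1)
        w = softmax(dense_layer(g_in, params["gates"][t]["W"],
                                params["gates"][t]["b"], activation=False))
        gate_weights[t] = w
        h_t = dense_layer(g_in, hm["W"], hm["b"], activation=True)
        hiddens[t] = h_t
        second = h_t if config.gh_literal_fusion else proj
        v[t] = w[:, 0:1] * h_t + w[:, 1:2] * second
        preds[t] = tower_forward(v[t], params["towers"][t], config.tower_type, config.tower_seq_len)
    if return_activations:
        return preds, ActivationBundle(outs=outs, hidden_shared=hidden_shared,
                                       hiddens=hiddens, gate_weights=gate_weights, v=v)
    return preds


def forward_single_task(params: dict, config: StructureConfig, inputs: dict,
                        return_activations: bool = False):
    """Independent encoder + tower per indicator; no cross-task pathway."""
    outs = encode_indicators(inputs, params, config)
    preds = {t: tower_forward(outs[t], params["towers"][t], config.tower_type, config.tower_seq_len)
             for t in config.tasks}
    if return_activations:
        return preds, ActivationBundle(outs=outs, v=outs)
    return preds


def forward_linear(params: dict, config: StructureConfig, inputs: dict,
                   return_activations: bool = False):
    """One affine map per indicator from its flattened window to the stations."""
    _check_inputs(config, inputs)
    preds = {t: tower_forward(inputs[t], params["towers"][t], "affine") for t in config.tasks}
    if return_activations:
        return preds, ActivationBundle(v=dict(inputs))
    return preds


_FORWARDS = {
    "hard": forward_hard,
    "soft": forward_soft,
    "gate": forward_gate,
    "gh": forward_gh,
    "single_task": forward_single_task,
    "linear_baseline": forward_linear,
}


def forward(params: dict, config: StructureConfig, inputs: dict,
            return_activations: bool = False):
    """Dispatch to the configured structure's forward pass."""
    return _FORWARDS[config.structure](params, config, inputs, return_activations)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _flatten_tree(tree, prefix="", out=None):
    if out is None:
        out = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            _flatten_tree(v, f"{prefix}{k}/", out)
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            _flatten_tree(v, f"{prefix}{i}/", out)
    else:
        out[prefix[:-1]] = tree
    return out


def save_checkpoint(path, params: dict, config: StructureConfig, dims: ModelDims,
                    extra: dict | None = None) -> None:
    """Write parameters + config to a single .npz archive (round-trips bit-exact)."""
    flat = _flatten_tree(params)
    arrays = {k: np.asarray(v) for k, v in flat.items() if isinstance(v, np.ndarray)}
    scalars = {k: v for k, v in flat.items() if not isinstance(v, np.ndarray)}
    meta = {
        "config": asdict(config),
        "dims": asdict(dims),
        "scalars": scalars,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (params, config, dims, extra)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        flat = {k: z[k] for k in z.files if k != "__meta__"}
    flat.update(meta["scalars"])
    params: dict = {}
    for key, arr in flat.items():
        parts = key.split("/")
        node = params
        for i, p in enumerate(parts[:-1]):
            nxt = parts[i + 1]
            if p.isdigit():
                p = int(p)
            default: dict | list = [] if nxt.isdigit() else {}
            if isinstance(node, list):
                while len(node) <= p:
                    node.append(None)
                if node[p] is None:
                    node[p] = default
                node = node[p]
            else:
                node = node.setdefault(p, default)
        leaf = parts[-1]
        if isinstance(node, list):
            idx = int(leaf)
            while len(node) <= idx:
                node.append(None)
            node[idx] = arr
        else:
            node[leaf] = arr
    cfg_d = meta["config"]
    cfg_d["tasks"] = tuple(cfg_d["tasks"])
    config = StructureConfig(**cfg_d)
    dims = ModelDims(**meta["dims"])
    return params, config, dims, meta["extra"]
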