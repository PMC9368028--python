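"""Independent straight-line transcriptions of the four forward passes.

These operate on ONE sample at a time with explicit per-step numpy
arithmetic (no shared code with the package's batched forwards) and
serve as oracles for the structure equivalence tests.  They read the
same parameter dictionaries the package builds, but every computation
is re-derived step by step.
"""

import numpy as np


def _relu(v):
    return np.where(v > 0, v, 0.0)


def _softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def _mlp_tower(v, layers):
    h = v
    for lay in layers:
        h = _relu(h @ lay["W"] + lay["b"])
    return h


def _encode(params, tasks, x):
    outs = {}
    for t in tasks:
        enc = params["encoders"][t]
        outs[t] = _relu((x[t] - 0.5) @ enc["W"] + enc["b"])  # centered inputs
    return outs


def _hidden_block(params, tasks, x):
    h = np.concatenate([x[t] for t in tasks]) - 0.5
    for lay in params["hidden"]:
        h = _relu(h @ lay["W"] + lay["b"])
    return h


def oracle_hard(params, tasks, x):
    outs = _encode(params, tasks, x)
    out_shared = np.concatenate([outs[t] for t in tasks])
    return {t: _mlp_tower(out_shared, params["towers"][t]["layers"]) for t in tasks}


def oracle_soft(params, tasks, x):
    outs = _encode(params, tasks, x)
    hidden_shared = _hidden_block(params, tasks, x)
    preds = {}
    for t in tasks:
        v = np.concatenate([outs[t], hidden_shared])
        preds[t] = _mlp_tower(v, params["towers"][t]["layers"])
    return preds


def oracle_gate(params, tasks, x, return_weights=False):
    outs = _encode(params, tasks, x)
    cat = np.concatenate([outs[t] for t in tasks])
    hm = params["hidden_map"]
    hiddens = {t: outs[t] @ hm["W"] + hm["b"] for t in tasks}  # linear mapping
    preds, weights = {}, {}
    for t in tasks:
        g = params["gates"][t]
        w = _softmax(cat @ g["W"] + g["b"])
        weights[t] = w
        v = np.zeros_like(hiddens[t])
        for i, s in enumerate(tasks):
            v = v + w[i] * hiddens[s]
        preds[t] = _mlp_tower(v, params["towers"][t]["layers"])
    if return_weights:
        return preds, weights
    return preds


def oracle_gh(params, tasks, x, literal=False, return_weights=False):
    outs = _encode(params, tasks, x)
    hidden_shared = _hidden_block(params, tasks, x)
    hm = params["hidden_map"]
    pj = params["proj"]
    proj = hidden_shared @ pj["W"] + pj["b"]
    preds, weights = {}, {}
    for t in tasks:
        g_in = np.concatenate([outs[t], hidden_shared])
        g = params["gates"][t]
        w = _softmax(g_in @ g["W"] + g["b"])
        weights[t] = w
        h_t = _relu(g_in @ hm["W"] + hm["b"])
        second = h_t if literal else proj
        v = w[0] * h_t + w[1] * second
        preds[t] = _mlp_tower(v, params["towers"][t]["layers"])
    if return_weights:
        return preds, weights
    return preds


ORACLES = {
    "hard": oracle_hard,
    "soft": oracle_soft,
    "gate": oracle_gate,
    "gh": oracle_gh,
}
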