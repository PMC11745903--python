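"""Hypergraph convolution with gated residual connections.

One refinement layer convolves the stacked node features with the
degree-normalized incidence operator,

    C = act( D^-1 H W_e E^-1 H^T X W6 ),

then blends the result back through a sigmoid gate.  In the default
("literal") mode the layer returns ``X + gate ⊙ X`` with
``gate = sigmoid(C W7^T + b7)``; in the alternative ("conv") mode it
returns ``X + gate ⊙ C``.  Either way, initializing the gate bias to a
sufficiently negative value (equilibrium bias initialization, EBI) makes
every layer start as a near-identity map, which is what lets deep stacks
avoid over-smoothing: the network opens each gate only as far as training
finds useful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _autodiff as ad
from .hypergraph import Hypergraph
from .mol_graph import _resolve_activation, _t

__all__ = [
    "HgnnLayerParams", "hgnn_convolve", "gated_residual_layer",
    "init_gate_bias_ebi", "refine", "EBI_DEFAULT_BIAS",
]

EBI_DEFAULT_BIAS = -5.0

RESIDUAL_MODES = ("gated", "plain_residual", "no_residual")
GATE_MODES = ("literal", "conv")


@dataclass
class HgnnLayerParams:
    """One refinement layer: convolution weight W6 and gate (W7, b7)."""

    conv_weight: object            # in x out (W6)
    gate_weight: object            # dim x dim (W7)
    gate_bias: object              # dim (b7)
    conv_activation: str = "relu"
    gate_mode: str = "literal"

    def __post_init__(self):
        if self.gate_mode not in GATE_MODES:
            raise ValueError(f"unknown gate mode {self.gate_mode!r}")


def _data(x):
    return x.data if isinstance(x, ad.Tensor) else np.asarray(x)


def hgnn_convolve(X, hg: Hypergraph, W6, activation="relu",
                  operator: np.ndarray | None = None):
    """Degree-normalized hypergraph convolution ``act(S X W6)``.

    ``S = D^-1 H W_e E^-1 H^T`` may be passed precomputed via ``operator``
    (it is constant across layers and epochs for a fixed hypergraph).
    Zero-degree nodes receive an all-zero convolved row.
    """
    Xd = _data(X)
    if Xd.shape[0] != hg.n_nodes:
        raise ValueError(
            f"feature matrix has {Xd.shape[0]} rows, hypergraph has "
            f"{hg.n_nodes} nodes")
    W6d = _data(W6)
    if W6d.shape[0] != Xd.shape[1]:
        raise ValueError(
            f"W6 expects input dim {W6d.shape[0]}, features have {Xd.shape[1]}")
    S = hg.normalized_operator() if operator is None else operator
    act = _resolve_activation(activation)
    return act(ad.matmul(S, ad.matmul(X, W6)))


def gated_residual_layer(X, hg: Hypergraph, params: HgnnLayerParams,
                         operator: np.ndarray | None = None):
    """One gated-residual refinement layer.

    literal mode: ``X + sigmoid(C W7^T + b7) ⊙ X``
    conv mode:    ``X + sigmoid(C W7^T + b7) ⊙ C``
    with ``C = act(S X W6)``.  Requires W6 to be square (the residual path
    needs matching shapes).
    """
    W6d = _data(params.conv_weight)
    if W6d.shape[0] != W6d.shape[1]:
        raise ValueError("gated residual layer requires square W6 "
                         f"(got {W6d.shape})")
    C = hgnn_convolve(X, hg, params.conv_weight, params.conv_activation,
                      operator=operator)
    pre = ad.add(ad.matmul(C, _t(params.gate_weight)), params.gate_bias)
    gate = ad.sigmoid(pre)
    carrier = X if params.gate_mode == "literal" else C
    return ad.add(X, ad.mul(gate, carrier))


def init_gate_bias_ebi(params: HgnnLayerParams,
                       b0: float = EBI_DEFAULT_BIAS) -> HgnnLayerParams:
    """Equilibrium bias initialization: fill the gate bias with ``b0``.

    With the default ``b0 = -5`` the gate opens to sigmoid(-5) ≈ 0.0067, so
    an untrained layer is a near-identity map.
    """
    bias = params.gate_bias
    new_bias = np.full_like(_data(bias), float(b0))
    if isinstance(bias, ad.Tensor):
        bias.data[...] = float(b0)
        return params
    return replace(params, gate_bias=new_bias)


def refine(X, hg: Hypergraph, layers: list[HgnnLayerParams],
           mode: str = "gated", operator: np.ndarray | None = None,
           dropout_rate: float = 0.0,
           rng: np.random.Generator | None = None):
    """Apply the refinement stack sequentially.

    ``mode`` selects the residual scheme: ``gated`` (default), or the
    ablations ``plain_residual`` (X + C) and ``no_residual`` (C only).
    Dropout, when requested (training only), is applied to the features
    entering each layer with inverted scaling.
    """
    if mode not in RESIDUAL_MODES:
        raise ValueError(f"unknown residual mode {mode!r}")
    if operator is None and layers:
        operator = hg.normalized_operator()
    out = X
    for params in layers:
        if dropout_rate > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            keep = (rng.random(_data(out).shape) >= dropout_rate)
            out = ad.mul(out, keep / (1.0 - dropout_rate))
        if mode == "gated":
            out = gated_residual_layer(out, hg, params, operator=operator)
        elif mode == "plain_residual":
            out = ad.add(out, hgnn_convolve(out, hg, params.conv_weight,
                                            params.conv_activation,
                                            operator=operator))
        else:
            out = hgnn_convolve(out, hg, params.conv_weight,
                                params.conv_activation, operator=operator)
    return out
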