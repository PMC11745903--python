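"""MLP encoders mapping cell lines and diseases into the common feature space.

Drug vectors come out of the graph-transformer encoder at the common
dimensionality; cell lines (preprocessed expression rows) and diseases
(precomputed language-model embedding rows) are each projected into that
same space by a single affine layer with a nonlinearity, so that all three
entity types can share one hypergraph feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .data_io import DiseaseEmbeddingTable, ExpressionMatrix
from .mol_graph import _resolve_activation, _t

__all__ = ["MlpParams", "encode_rows", "encode_cell_lines", "encode_diseases"]


@dataclass
class MlpParams:
    weight: object          # out x in
    bias: object            # out
    activation: str = "relu"

    def in_dim(self) -> int:
        w = self.weight.data if isinstance(self.weight, ad.Tensor) else self.weight
        return w.shape[1]


def encode_rows(rows, params: MlpParams):
    """Apply ``activation(W @ row + b)`` to every row of a matrix."""
    act = _resolve_activation(params.activation)
    data = rows.data if isinstance(rows, ad.Tensor) else np.asarray(rows)
    if data.shape[1] != params.in_dim():
        raise ValueError(
            f"encoder expects input dim {params.in_dim()}, got {data.shape[1]}")
    return act(ad.add(ad.matmul(rows, _t(params.weight)), params.bias))


def encode_cell_lines(expr: ExpressionMatrix | np.ndarray,
                      params: MlpParams):
    """Project preprocessed expression rows into the common feature space."""
    rows = expr.values if isinstance(expr, ExpressionMatrix) else expr
    return encode_rows(rows, params)


def encode_diseases(embeddings: DiseaseEmbeddingTable | np.ndarray,
                    params: MlpParams):
    """Project disease embedding rows into the common feature space."""
    rows = embeddings.vectors if isinstance(embeddings, DiseaseEmbeddingTable) \
        else embeddings
    return encode_rows(rows, params)
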