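"""The dual-relationship hypergraph over drugs, cell lines and diseases.

Nodes are all drugs, then all cell lines, then all diseases (block order is
fixed so that the stacked feature matrix aligns with the incidence matrix).
Two hyperedge families exist:

* **triplet** hyperedges — one per unique unordered synergistic
  (drug_a, drug_b, cell_line) combination (third-order interactions),
  weight 1;
* **indication** hyperedges — one per unique (drug, disease) pair
  (ordinary pairwise edges), weighted by the ``interaction_weight``
  hyperparameter.  Weight 0 removes their influence on the convolution
  entirely, which is the "without disease knowledge" ablation.

Node degrees are weighted (sum of incident hyperedge weights); hyperedge
degrees are plain cardinalities.  The degree-normalized convolution
operator ``D^-1 H W_e E^-1 H^T`` is row-stochastic wherever a node has
positive degree; zero-degree nodes get an all-zero row (they rely on the
residual path downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .data_io import DataError, IndicationPair, SynergySample, binarize_synergy

__all__ = ["NodeIndex", "Hypergraph", "build_node_index", "build_hypergraph"]


@dataclass
class NodeIndex:
    """Global node positions: drugs first, then cell lines, then diseases."""

    drugs: list[str]
    cell_lines: list[str]
    diseases: list[str]
    position: dict[tuple[str, str], int] = field(init=False)

    def __post_init__(self):
        for kind, ids in (("drug", self.drugs), ("cell_line", self.cell_lines),
                          ("disease", self.diseases)):
            if len(ids) != len(set(ids)):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise DataError(f"duplicate {kind} id {dup!r} in node index")
        self.position = {}
        pos = 0
        for kind, ids in (("drug", self.drugs), ("cell_line", self.cell_lines),
                          ("disease", self.diseases)):
            for i in ids:
                self.position[(kind, i)] = pos
                pos += 1

    @property
    def n_nodes(self) -> int:
        return len(self.drugs) + len(self.cell_lines) + len(self.diseases)

    def drug(self, drug_id: str) -> int:
        return self._get("drug", drug_id)

    def cell_line(self, cell_id: str) -> int:
        return self._get("cell_line", cell_id)

    def disease(self, disease_id: str) -> int:
        return self._get("disease", disease_id)

    def _get(self, kind: str, ident: str) -> int:
        try:
            return self.position[(kind, ident)]
        except KeyError:
            raise KeyError(f"unknown {kind} id {ident!r}") from None


def build_node_index(drugs: list[str], cell_lines: list[str],
                     diseases: list[str] | None = None) -> NodeIndex:
    """Deterministic node ordering; input order is preserved per block."""
    return NodeIndex(list(drugs), list(cell_lines), list(diseases or []))


@dataclass
class Hypergraph:
    incidence: sp.csr_matrix          # nodes x hyperedges, binary
    edge_weights: np.ndarray          # per-hyperedge positive weight
    edge_kinds: list[str]             # "triplet" | "indication"
    node_degrees: np.ndarray = field(init=False)
    edge_degrees: np.ndarray = field(init=False)

    def __post_init__(self):
        self.incidence = sp.csr_matrix(self.incidence)
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64)
        H = self.incidence
        if H.nnz and not np.isin(H.data, (0.0, 1.0)).all():
            raise DataError("incidence matrix must be binary")
        self.edge_degrees = np.asarray(H.sum(axis=0)).ravel()
        self.node_degrees = np.asarray(H @ self.edge_weights).ravel()

    @property
    def n_nodes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    def normalized_operator(self) -> np.ndarray:
        """Dense ``D^-1 H W_e E^-1 H^T`` with 1/0 treated as 0."""
        H = self.incidence
        d_inv = _safe_reciprocal(self.node_degrees)
        e_inv = _safe_reciprocal(self.edge_degrees)
        right = H.multiply(self.edge_weights * e_inv).tocsr()  # H W_e E^-1
        S = (right @ H.T).toarray()
        return d_inv[:, None] * S

    def dump_text(self, path: str | Path) -> None:
        """Coordinate-list debug dump: node, hyperedge, weight, kind."""
        coo = self.incidence.tocoo()
        with open(path, "w") as fh:
            fh.write("node\thyperedge\tweight\tkind\n")
            for v, e in sorted(zip(coo.row, coo.col)):
                fh.write(f"{v}\t{e}\t{self.edge_weights[e]!r}\t"
                         f"{self.edge_kinds[e]}\n")


def _safe_reciprocal(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=np.float64)
    nz = x != 0
    out[nz] = 1.0 / x[nz]
    return out


def build_hypergraph(samples: list[SynergySample],
                     pairs: list[IndicationPair],
                     index: NodeIndex,
                     interaction_weight: float = 0.02,
                     positives_only: bool = True) -> Hypergraph:
    """Assemble the incidence structure from training-fold data.

    By default only positive-label (synergistic) samples contribute triplet
    hyperedges; ``positives_only=False`` admits every training triplet (a
    sensitivity-analysis mode).  Duplicate triplets and pairs collapse to a
    single hyperedge.
    """
    if interaction_weight < 0:
        raise ValueError("interaction_weight must be >= 0")
    triplet_keys: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for s in samples:
        if s.drug_a == s.drug_b:
            raise DataError(
                f"triplet with identical drugs rejected: "
                f"({s.drug_a}, {s.drug_b}, {s.cell_line})")
        if positives_only:
            label = s.label if s.label is not None else binarize_synergy(s.score)
            if label != 1:
                continue
        key = (min(s.drug_a, s.drug_b), max(s.drug_a, s.drug_b), s.cell_line)
        if key in seen:
            continue
        seen.add(key)
        triplet_keys.append(key)

    pair_keys: list[tuple[str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    for p in pairs:
        key = (p.drug_id, p.disease_id)
        if key not in seen_pairs:
            seen_pairs.add(key)
            pair_keys.append(key)

    rows: list[int] = []
    cols: list[int] = []
    weights: list[float] = []
    kinds: list[str] = []
    for e, (da, db, cl) in enumerate(triplet_keys):
        rows += [index.drug(da), index.drug(db), index.cell_line(cl)]
        cols += [e, e, e]
        weights.append(1.0)
        kinds.append("triplet")
    off = len(triplet_keys)
    for e, (dr, dis) in enumerate(pair_keys):
        rows += [index.drug(dr), index.disease(dis)]
        cols += [off + e, off + e]
        weights.append(float(interaction_weight))
        kinds.append("indication")

    n_edges = len(weights)
    H = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(index.n_nodes, n_edges),
    )
    return Hypergraph(H, np.array(weights), kinds)
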