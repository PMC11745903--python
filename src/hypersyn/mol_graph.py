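"""Molecular graphs and the graph-transformer (GTN) drug encoder.

A drug's SMILES string is parsed into a heavy-atom graph: one node per
non-hydrogen atom, one undirected edge per chemical bond.  Atom features
follow a fixed 75-length layout (scheme id ``convmol-75``) mirroring the
widely used convolutional featurizer convention:

====================  ======  =========================================
block                 length  content
====================  ======  =========================================
element               44      one-hot over a fixed symbol list (+ other)
degree                11      one-hot over 0..10
implicit valence      7       one-hot over 0..6
formal charge         1       integer value
radical electrons     1       integer value
hybridization         5       one-hot over SP, SP2, SP3, SP3D, SP3D2
aromatic              1       flag
total hydrogens       5       one-hot over 0..4
====================  ======  =========================================

Atom features are refined by stacked multi-head graph-transformer layers:
each atom attends over its bonded neighbours with scaled dot-product
attention, and the per-head attention-weighted neighbour messages are
averaged across heads before being combined with the atom's own linear
term.  The drug-level vector is the columnwise maximum over refined atom
features (permutation invariant, robust to varying atom counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

__all__ = [
    "ATOM_FEATURE_DIM", "FEATURE_SCHEME", "MolecularGraph", "GtnLayerParams",
    "smiles_to_graph", "attention_coefficients", "gtn_layer", "gtn_forward",
    "neighbor_mean_forward", "readout_max", "graph_to_text", "graph_from_text",
]

FEATURE_SCHEME = "convmol-75"
ATOM_FEATURE_DIM = 75

_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]


class SmilesParseError(ValueError):
    """The SMILES string does not describe a valid molecule."""


@dataclass
class MolecularGraph:
    atom_features: np.ndarray      # atoms x feature dim
    bonds: list[tuple[int, int]]   # undirected atom-index pairs
    n_atoms: int
    scheme: str = FEATURE_SCHEME

    def __post_init__(self):
        self.atom_features = np.asarray(self.atom_features, dtype=np.float64)
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < self.n_atoms and 0 <= b < self.n_atoms):
                raise ValueError(f"bond ({a},{b}) out of range for "
                                 f"{self.n_atoms} atoms")

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) arrays with each undirected bond listed both ways."""
        if not self.bonds:
            e = np.empty(0, dtype=np.intp)
            return e, e
        a = np.array([b[0] for b in self.bonds], dtype=np.intp)
        b = np.array([b[1] for b in self.bonds], dtype=np.intp)
        return np.concatenate([a, b]), np.concatenate([b, a])

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


@dataclass
class GtnLayerParams:
    """Weights of one graph-transformer layer.

    ``W1`` maps the atom's own feature, ``W2`` the attended neighbour
    messages; ``W3``/``W4`` project query/key vectors for ``heads`` attention
    heads of ``d`` latent dimensions each (their row count is heads*d).
    """

    W1: object  # out x in
    W2: object  # out x in
    W3: object  # heads*d x in
    W4: object  # heads*d x in
    heads: int
    d: int

    def __post_init__(self):
        for name in ("W3", "W4"):
            w = getattr(self, name)
            rows = w.shape[0]
            if rows != self.heads * self.d:
                raise ValueError(
                    f"{name} has {rows} rows, expected heads*d = "
                    f"{self.heads * self.d}")


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def _atom_features(atom) -> list[float]:
    symbol = atom.GetSymbol()
    feats = _one_hot(symbol if symbol in _SYMBOLS else "other",
                     _SYMBOLS + ["other"])
    feats += _one_hot(min(atom.GetDegree(), 10), list(range(11)))
    feats += _one_hot(min(atom.GetImplicitValence(), 6), list(range(7)))
    feats.append(float(atom.GetFormalCharge()))
    feats.append(float(atom.GetNumRadicalElectrons()))
    feats += _one_hot(str(atom.GetHybridization()), _HYBRIDIZATIONS)
    feats.append(1.0 if atom.GetIsAromatic() else 0.0)
    feats += _one_hot(min(atom.GetTotalNumHs(), 4), list(range(5)))
    return feats


def smiles_to_graph(smiles: str, scheme: str = FEATURE_SCHEME,
                    drug_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`."""
    from rdkit import Chem

    if scheme != FEATURE_SCHEME:
        raise ValueError(f"unknown atom-feature scheme {scheme!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" (drug {drug_id!r})" if drug_id else ""
        raise SmilesParseError(f"invalid SMILES {smiles!r}{who}")
    feats = np.array([_atom_features(a) for a in mol.GetAtoms()],
                     dtype=np.float64)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MolecularGraph(feats, bonds, mol.GetNumAtoms(), scheme)


# ---------------------------------------------------------------------------
# graph-transformer layer

_ACTIVATIONS = {
    "relu": ad.relu,
    "identity": lambda x: x,
    "sigmoid": ad.sigmoid,
}


def _resolve_activation(activation):
    if callable(activation):
        return activation
    try:
        return _ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None


def attention_coefficients(graph: MolecularGraph, i: int,
                           params: GtnLayerParams) -> np.ndarray:
    """Per-head attention of atom ``i`` over its neighbours.

    Returns a (heads, |N(i)|) array; neighbours are ordered by atom index.
    Each row is the softmax over j in N(i) of (W3 a_i)^T (W4 a_j) / sqrt(d)
    restricted to that head's slice.
    """
    nbrs = graph.neighbors(i)
    if not nbrs:
        raise ValueError(f"atom {i} has no neighbours")
    A = graph.atom_features
    W3 = params.W3.data if isinstance(params.W3, ad.Tensor) else params.W3
    W4 = params.W4.data if isinstance(params.W4, ad.Tensor) else params.W4
    q = (W3 @ A[i]).reshape(params.heads, params.d)
    keys = (A[nbrs] @ W4.T).reshape(len(nbrs), params.heads, params.d)
    logits = np.einsum("hd,nhd->hn", q, keys) / np.sqrt(params.d)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def gtn_forward(features, src: np.ndarray, dst: np.ndarray, n_atoms: int,
                params: GtnLayerParams, activation="relu"):
    """One graph-transformer layer on explicit edge arrays.

    ``features`` may be a NumPy array or an autodiff tensor; the result has
    the same flavour.  Atoms with no incident edge receive only their own
    linear term (empty neighbour sum).
    """
    act = _resolve_activation(activation)
    heads, d = params.heads, params.d
    self_term = ad.matmul(features, _t(params.W1))
    if len(src) == 0:
        return act(self_term)
    Q = ad.matmul(features, _t(params.W3))      # n x heads*d
    K = ad.matmul(features, _t(params.W4))
    Qe = ad.take_rows(Q, dst)                   # query = centre atom
    Ke = ad.take_rows(K, src)                   # key = neighbour
    prod = ad.reshape(ad.mul(Qe, Ke), (len(src), heads, d))
    logits = ad.div(ad.tsum(prod, axis=2), float(np.sqrt(d)))  # E x heads
    # segment softmax over edges sharing a centre atom, per head
    logits_data = logits.data if isinstance(logits, ad.Tensor) else logits
    seg_max = np.full((n_atoms, heads), -np.inf)
    np.maximum.at(seg_max, dst, logits_data)
    shifted = ad.sub(logits, seg_max[dst])
    e = ad.exp(shifted)
    denom = ad.segment_sum(e, dst, n_atoms)
    alpha = ad.div(e, ad.take_rows(denom, dst))        # E x heads
    alpha_mean = ad.tmean(alpha, axis=1, keepdims=True)  # heads averaged
    V = ad.matmul(features, _t(params.W2))
    msg = ad.mul(ad.take_rows(V, src), alpha_mean)
    agg = ad.segment_sum(msg, dst, n_atoms)
    return act(ad.add(self_term, agg))


def _t(w):
    """Transpose a weight that may be an ndarray or a Tensor."""
    if isinstance(w, ad.Tensor):
        return _transpose(w)
    return np.asarray(w).T


def _transpose(w: ad.Tensor) -> ad.Tensor:
    out = ad.Tensor(w.data.T, parents=(w,))

    def bwd(g):
        if w.grad is None:
            w.grad = np.zeros_like(w.data)
        w.grad += g.T

    out._backward = bwd
    return out


def gtn_layer(graph: MolecularGraph, params: GtnLayerParams,
              activation="relu") -> np.ndarray:
    """Refine a molecular graph's atom features with one GTN layer."""
    in_dim = graph.atom_features.shape[1]
    W1 = params.W1.data if isinstance(params.W1, ad.Tensor) else params.W1
    if W1.shape[1] != in_dim:
        raise ValueError(
            f"W1 expects input dim {W1.shape[1]}, atom features have {in_dim}")
    src, dst = graph.directed_edges()
    return gtn_forward(graph.atom_features, src, dst, graph.n_atoms,
                       params, activation)


def neighbor_mean_forward(features, src: np.ndarray, dst: np.ndarray,
                          n_atoms: int, W1, W2, activation="relu"):
    """Attention-free variant: neighbours contribute with uniform weights.

    Used when the transformer is ablated; each atom receives the mean of its
    neighbours' ``W2`` messages instead of an attention-weighted sum.
    """
    act = _resolve_activation(activation)
    self_term = ad.matmul(features, _t(W1))
    if len(src) == 0:
        return act(self_term)
    deg = np.bincount(dst, minlength=n_atoms).astype(np.float64)
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    V = ad.matmul(features, _t(W2))
    agg = ad.segment_sum(ad.take_rows(V, src), dst, n_atoms)
    agg = ad.mul(agg, inv[:, None])
    return act(ad.add(self_term, agg))


def readout_max(atom_features):
    """Drug-level vector: elementwise maximum over atom feature rows."""
    data = atom_features.data if isinstance(atom_features, ad.Tensor) \
        else np.asarray(atom_features)
    if data.shape[0] == 0:
        raise ValueError("cannot max-pool an empty molecule")
    return ad.max_over_rows(atom_features)


# ---------------------------------------------------------------------------
# deterministic text dump (fixture-friendly)


def graph_to_text(graph: MolecularGraph) -> str:
    lines = [f"# scheme={graph.scheme} atoms={graph.n_atoms}"]
    for row in graph.atom_features:
        lines.append("\t".join(repr(float(v)) for v in row))
    lines.append("# bonds")
    for a, b in graph.bonds:
        lines.append(f"{a}\t{b}")
    return "\n".join(lines) + "\n"


def graph_from_text(text: str) -> MolecularGraph:
    lines = [ln for ln in text.strip().splitlines()]
    header = lines[0]
    scheme = header.split("scheme=")[1].split()[0]
    n_atoms = int(header.split("atoms=")[1])
    split = lines.index("# bonds")
    feats = np.array([[float(v) for v in ln.split("\t")]
                      for ln in lines[1:split]])
    bonds = [tuple(int(v) for v in ln.split("\t")) for ln in lines[split + 1:]]
    return MolecularGraph(feats, [(a, b) for a, b in bonds], n_atoms, scheme)
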