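"""End-to-end synergy classifier: assembly, scoring, training, checkpoints.

The full pipeline is: molecular graphs through the graph-transformer
encoder (drugs), MLP encoders (cell lines, diseases), vertical stacking
into one node-feature matrix, refinement over the dual-relationship
hypergraph built from training-fold synergistic triplets, and a sigmoid
predictor over the concatenated (drug_a, drug_b, cell_line) rows.  Training
minimizes binary cross-entropy with AdamW, pairwise symmetric permutation
augmentation of the training fold, dropout between refinement layers,
weight decay and early stopping on validation AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from . import _autodiff as ad
from .data_io import (Cohort, DataError, DiseaseEmbeddingTable,
                      ExpressionMatrix, SynergySample, preprocess_expression)
from .entity_encoders import MlpParams, encode_rows
from .hgnn import (EBI_DEFAULT_BIAS, HgnnLayerParams, refine)
from .hypergraph import Hypergraph, NodeIndex, build_hypergraph, build_node_index
from .mol_graph import (ATOM_FEATURE_DIM, GtnLayerParams, MolecularGraph,
                        _resolve_activation, _t, gtn_forward,
                        neighbor_mean_forward, readout_max, smiles_to_graph)

__all__ = [
    "PredictorParams", "TrainConfig", "TrainReport", "Checkpoint",
    "SynergyModel", "assemble_features", "predict_synergy",
    "augment_symmetric", "bce_loss", "train",
]

BCE_EPS = 1e-7


# ---------------------------------------------------------------------------
# predictor


@dataclass
class PredictorParams:
    """MLP scoring head; last layer has a single sigmoid output unit.

    ``layers`` is a list of (weight, bias) pairs; all but the last are
    followed by the hidden activation.  The minimal configuration is a
    single affine layer (weight shape 1 x 3*common_dim).
    """

    layers: list[tuple[object, object]]
    hidden_activation: str = "relu"

    def in_dim(self) -> int:
        w = self.layers[0][0]
        return (w.data if isinstance(w, ad.Tensor) else w).shape[1]

    def logits(self, features):
        """Apply the stack up to (not including) the output sigmoid."""
        act = _resolve_activation(self.hidden_activation)
        out = features
        for i, (w, b) in enumerate(self.layers):
            out = ad.add(ad.matmul(out, _t(w)), b)
            if i < len(self.layers) - 1:
                out = act(out)
        return ad.reshape(out, (-1,))


def assemble_features(x_drug, x_cell, x_dis=None):
    """Stack per-entity feature blocks vertically in node-index order."""
    blocks = [x_drug, x_cell] if x_dis is None or _n_rows(x_dis) == 0 \
        else [x_drug, x_cell, x_dis]
    dims = {_n_cols(b) for b in blocks}
    if len(dims) != 1:
        raise ValueError(f"feature blocks disagree on dimensionality: {dims}")
    return ad.concat(blocks, axis=0)


def _n_rows(x) -> int:
    return (x.data if isinstance(x, ad.Tensor) else np.asarray(x)).shape[0]


def _n_cols(x) -> int:
    return (x.data if isinstance(x, ad.Tensor) else np.asarray(x)).shape[1]


def predict_synergy(refined, triplet: tuple[str, str, str], index: NodeIndex,
                    params: PredictorParams) -> float:
    """Score one (drug_a, drug_b, cell_line) triplet from refined features.

    Concatenates the three refined node rows in the stored orientation and
    applies the predictor; returns a probability in (0, 1).  Architecture is
    order-sensitive — symmetry is acquired through training augmentation,
    not imposed here.
    """
    drug_a, drug_b, cell_line = triplet
    data = refined.data if isinstance(refined, ad.Tensor) else np.asarray(refined)
    if not np.isfinite(data).all():
        raise ValueError("refined feature matrix contains non-finite values")
    row = np.concatenate([data[index.drug(drug_a)], data[index.drug(drug_b)],
                          data[index.cell_line(cell_line)]])
    z = params.logits(row[None, :])
    z = z.data if isinstance(z, ad.Tensor) else z
    return float(ad.sigmoid(z[0]))


def augment_symmetric(samples: list[SynergySample]) -> list[SynergySample]:
    """Add the drug-swapped twin of every sample with distinct drugs."""
    out = []
    for s in samples:
        out.append(s)
        if s.drug_a != s.drug_b:
            out.append(SynergySample(s.drug_b, s.drug_a, s.cell_line,
                                     s.score, s.label))
    return out


def bce_loss(labels, probabilities) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} "
                         "probabilities")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainConfig:
    """Hyperparameters; numeric defaults follow the tuned grid-search values
    (learning rate 2e-4, weight decay 1e-2, 4 attention heads, 3 refinement
    layers, indication hyperedge weight 0.02)."""

    learning_rate: float = 2e-4
    weight_decay: float = 1e-2
    attention_heads: int = 4
    refinement_layers: int = 3
    interaction_weight: float = 0.02
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    dropout_rate: float = 0.2
    seed: int = 0
    common_dim: int = 64
    gtn_layers: int = 3
    predictor_hidden: tuple[int, ...] = (64,)
    gate_mode: str = "literal"           # Eq-literal gate carrier, or "conv"
    residual_mode: str = "gated"         # gated | plain_residual | no_residual
    lr_schedule: str = "constant"        # constant | cosine
    paired_orientation_batches: bool = False
    use_transformer: bool = True
    use_disease: bool = True
    augment: bool = True
    positives_only_hyperedges: bool = True
    ebi_bias: float = EBI_DEFAULT_BIAS

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if isinstance(self.predictor_hidden, list):
            self.predictor_hidden = tuple(self.predictor_hidden)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predictor_hidden"] = list(self.predictor_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def desk_scale_config(seed: int = 0, **overrides) -> TrainConfig:
    """Configuration scaled to desk-size cohorts (~2000 samples, ~20 drugs).

    Relative to the full-scale defaults this narrows the common space to 32
    dimensions, uses 2 refinement layers, and adapts the optimization to the
    much smaller step budget (batch 32, learning rate 2e-3, at most 200
    epochs with early-stop patience 20): at this scale an epoch is only a
    few dozen optimizer steps, so the full-scale learning rate would never
    converge within the epoch budget.
    """
    fields = dict(common_dim=32, refinement_layers=2, predictor_hidden=(128,),
                  learning_rate=2e-3, batch_size=32, max_epochs=200,
                  patience=20, lr_schedule="cosine", weight_decay=1e-1,
                  seed=seed)
    fields.update(overrides)
    return TrainConfig(**fields)


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_auroc: float = float("nan")
    stopping_reason: str = ""

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# model


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class SynergyModel:
    """Holds all trainable parameters and runs the end-to-end forward pass.

    The hypergraph (and its precomputed normalized operator) is attached
    separately via :meth:`set_hypergraph` because it is fold-specific: it is
    built from the training fold's synergistic triplets only.
    """

    def __init__(self, index: NodeIndex, drug_graphs: dict[str, MolecularGraph],
                 expr_pre: ExpressionMatrix,
                 embeddings: DiseaseEmbeddingTable | None,
                 config: TrainConfig, rng: np.random.Generator):
        self.index = index
        self.config = config
        self.expr_values = expr_pre.values  # preprocessed, row-aligned
        if list(expr_pre.cell_line_ids) != list(index.cell_lines):
            raise ValueError("expression rows not aligned with node index")
        self.disease_vectors = None
        if config.use_disease and embeddings is not None and index.diseases:
            if list(embeddings.disease_ids) != list(index.diseases):
                raise ValueError("embedding rows not aligned with node index")
            self.disease_vectors = embeddings.vectors
        self._build_molecule_union([drug_graphs[d] for d in index.drugs])
        self._init_params(rng)
        self.hypergraph: Hypergraph | None = None
        self._operator: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    def _build_molecule_union(self, graphs: list[MolecularGraph]) -> None:
        """Concatenate all drug graphs into one disjoint union graph."""
        feats, srcs, dsts, slices = [], [], [], []
        offset = 0
        for g in graphs:
            feats.append(g.atom_features)
            s, d = g.directed_edges()
            srcs.append(s + offset)
            dsts.append(d + offset)
            slices.append((offset, offset + g.n_atoms))
            offset += g.n_atoms
        self.atom_features = np.concatenate(feats, axis=0)
        self.edge_src = np.concatenate(srcs) if srcs else np.empty(0, np.intp)
        self.edge_dst = np.concatenate(dsts) if dsts else np.empty(0, np.intp)
        self.n_atoms_total = offset
        self.mol_slices = slices

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        dim = cfg.common_dim
        heads = cfg.attention_heads
        self.params: dict[str, ad.Tensor] = {}

        def param(name, array):
            t = ad.Tensor(array)
            self.params[name] = t
            return t

        self.gtn_stack: list[GtnLayerParams] = []
        in_dim = ATOM_FEATURE_DIM
        for i in range(cfg.gtn_layers):
            d_head = max(1, dim // heads)
            layer = GtnLayerParams(
                W1=param(f"gtn{i}.W1", _glorot(rng, dim, in_dim)),
                W2=param(f"gtn{i}.W2", _glorot(rng, dim, in_dim)),
                W3=param(f"gtn{i}.W3", _glorot(rng, heads * d_head, in_dim)),
                W4=param(f"gtn{i}.W4", _glorot(rng, heads * d_head, in_dim)),
                heads=heads, d=d_head)
            self.gtn_stack.append(layer)
            in_dim = dim

        self.cell_encoder = MlpParams(
            weight=param("cell.W", _glorot(rng, dim, self.expr_values.shape[1])),
            bias=param("cell.b", np.zeros(dim)))
        if self.disease_vectors is not None:
            self.disease_encoder = MlpParams(
                weight=param("dis.W",
                             _glorot(rng, dim, self.disease_vectors.shape[1])),
                bias=param("dis.b", np.zeros(dim)))
        else:
            self.disease_encoder = None

        self.hgnn_stack: list[HgnnLayerParams] = []
        for i in range(cfg.refinement_layers):
            self.hgnn_stack.append(HgnnLayerParams(
                conv_weight=param(f"hgnn{i}.W6", _glorot(rng, dim, dim).T),
                gate_weight=param(f"hgnn{i}.W7", _glorot(rng, dim, dim)),
                gate_bias=param(f"hgnn{i}.b7", np.full(dim, cfg.ebi_bias)),
                gate_mode=cfg.gate_mode))

        sizes = (3 * dim,) + tuple(cfg.predictor_hidden) + (1,)
        layers = []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            layers.append((param(f"pred{i}.W", _glorot(rng, n_out, n_in)),
                           param(f"pred{i}.b", np.zeros(n_out))))
        # The two drug slots of the first scoring layer start identical, so
        # the head is exchange-symmetric at initialization; symmetric
        # (augmented, twin-paired) training preserves this, while training
        # without augmentation lets the slots drift apart.
        w0 = layers[0][0]
        w0.data[:, dim:2 * dim] = w0.data[:, :dim]
        self.predictor = PredictorParams(layers)

        self._no_decay = {id(t) for name, t in self.params.items()
                          if name.endswith((".b", ".b7"))}

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    # -- hypergraph --------------------------------------------------------

    def set_hypergraph(self, hg: Hypergraph) -> None:
        if hg.n_nodes != self.index.n_nodes:
            raise ValueError("hypergraph node count does not match index")
        self.hypergraph = hg
        self._operator = hg.normalized_operator()

    def build_fold_hypergraph(self, train_samples: list[SynergySample],
                              pairs) -> Hypergraph:
        cfg = self.config
        use_pairs = pairs if (cfg.use_disease and self.index.diseases) else []
        hg = build_hypergraph(train_samples, use_pairs, self.index,
                              interaction_weight=cfg.interaction_weight,
                              positives_only=cfg.positives_only_hyperedges)
        self.set_hypergraph(hg)
        return hg

    # -- forward -----------------------------------------------------------

    def _encode_drugs(self):
        x = self.atom_features
        for layer in self.gtn_stack:
            if self.config.use_transformer:
                x = gtn_forward(x, self.edge_src, self.edge_dst,
                                self.n_atoms_total, layer)
            else:
                x = neighbor_mean_forward(x, self.edge_src, self.edge_dst,
                                          self.n_atoms_total,
                                          layer.W1, layer.W2)
        pooled = [ad.reshape(readout_max(ad.take_rows(x, np.arange(lo, hi))),
                             (1, -1))
                  for lo, hi in self.mol_slices]
        return ad.concat(pooled, axis=0)

    def refined_features(self, training: bool = False,
                         rng: np.random.Generator | None = None):
        if self.hypergraph is None:
            raise RuntimeError("no hypergraph attached; call set_hypergraph")
        x_drug = self._encode_drugs()
        x_cell = encode_rows(self.expr_values, self.cell_encoder)
        x_dis = None
        if self.disease_encoder is not None:
            x_dis = encode_rows(self.disease_vectors, self.disease_encoder)
        X = assemble_features(x_drug, x_cell, x_dis)
        rate = self.config.dropout_rate if training else 0.0
        return refine(X, self.hypergraph, self.hgnn_stack,
                      mode=self.config.residual_mode, operator=self._operator,
                      dropout_rate=rate, rng=rng)

    def triplet_indices(self, samples: list[SynergySample]) -> tuple[np.ndarray, ...]:
        ia = np.array([self.index.drug(s.drug_a) for s in samples], dtype=np.intp)
        ib = np.array([self.index.drug(s.drug_b) for s in samples], dtype=np.intp)
        ic = np.array([self.index.cell_line(s.cell_line) for s in samples],
                      dtype=np.intp)
        return ia, ib, ic

    def batch_logits(self, refined, ia, ib, ic):
        F = ad.concat([ad.take_rows(refined, ia), ad.take_rows(refined, ib),
                       ad.take_rows(refined, ic)], axis=1)
        return self.predictor.logits(F)

    def predict_proba(self, samples: list[SynergySample]) -> np.ndarray:
        """Score samples with the current parameters (no dropout)."""
        refined = self.refined_features(training=False)
        ia, ib, ic = self.triplet_indices(samples)
        z = self.batch_logits(refined, ia, ib, ic)
        z = z.data if isinstance(z, ad.Tensor) else z
        return ad.sigmoid(z)

    # -- parameter snapshots ----------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data[...] = state[k]


def _orientation_groups(samples: list[SynergySample]) -> list[np.ndarray]:
    """Indices of adjacent drug-swapped twins in an augmented sample list."""
    groups, i = [], 0
    while i < len(samples):
        s = samples[i]
        if (i + 1 < len(samples) and s.drug_a != s.drug_b
                and samples[i + 1] == SynergySample(s.drug_b, s.drug_a,
                                                    s.cell_line, s.score,
                                                    s.label)):
            groups.append(np.array([i, i + 1]))
            i += 2
        else:
            groups.append(np.array([i]))
            i += 1
    return groups


def _bce_from_logits(logits, labels: np.ndarray):
    """Mean of softplus(z) - y*z, the stable form of binary cross-entropy."""
    return ad.tmean(ad.sub(ad.softplus(logits), ad.mul(logits, labels)))


# ---------------------------------------------------------------------------
# training


def build_model(cohort: Cohort, config: TrainConfig,
                rng: np.random.Generator | None = None) -> SynergyModel:
    """Construct an untrained model over a (filtered) cohort's entities."""
    rng = rng or np.random.default_rng(config.seed)
    drug_ids = [d.drug_id for d in cohort.drugs]
    diseases = list(cohort.embeddings.disease_ids) \
        if (config.use_disease and cohort.embeddings is not None) else []
    index = build_node_index(drug_ids, list(cohort.expr.cell_line_ids), diseases)
    graphs = {d.drug_id: smiles_to_graph(d.smiles, drug_id=d.drug_id)
              for d in cohort.drugs}
    expr_pre = preprocess_expression(cohort.expr)
    emb = cohort.embeddings if config.use_disease else None
    return SynergyModel(index, graphs, expr_pre, emb, config, rng)


def train(cohort: Cohort, fold: tuple, config: TrainConfig,
          ) -> tuple["Checkpoint", TrainReport]:
    """Train one model on a cross-validation fold.

    ``fold`` is ``(train_indices, val_indices)`` into ``cohort.samples``.
    The training fold is symmetrically augmented; validation AUROC is
    monitored every epoch and training stops once it fails to improve for
    ``config.patience`` consecutive epochs.  Fully reproducible given
    ``config.seed``.
    """
    train_idx, val_idx = fold
    train_idx = list(train_idx)
    val_idx = list(val_idx)
    if set(train_idx) & set(val_idx):
        raise ValueError("train and validation folds overlap")
    if not val_idx:
        raise DataError("validation fold is empty")

    labeled = cohort.labeled_samples()
    train_samples = [labeled[i] for i in train_idx]
    val_samples = [labeled[i] for i in val_idx]
    val_labels = np.array([s.label for s in val_samples], dtype=np.float64)
    if len(set(val_labels.tolist())) < 2:
        raise DataError("validation fold contains a single class")

    rng = np.random.default_rng(config.seed)
    model = build_model(cohort, config, rng)
    model.build_fold_hypergraph(train_samples, cohort.pairs)

    fit_samples = augment_symmetric(train_samples) if config.augment \
        else list(train_samples)
    ia, ib, ic = model.triplet_indices(fit_samples)
    y = np.array([s.label for s in fit_samples], dtype=np.float64)

    opt = ad.AdamW(model.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay,
                   no_decay=model._no_decay)
    report = TrainReport()
    best_state = model.state_dict()
    best_auroc = -np.inf
    since_improve = 0
    n = len(fit_samples)

    groups = None
    if config.paired_orientation_batches and config.augment:
        groups = _orientation_groups(fit_samples)

    base_lr = config.learning_rate
    for epoch in range(1, config.max_epochs + 1):
        if config.lr_schedule == "cosine":
            frac = (epoch - 1) / max(1, config.max_epochs - 1)
            opt.lr = base_lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
        if groups is None:
            order = rng.permutation(n)
        else:
            order = np.concatenate(
                [groups[g] for g in rng.permutation(len(groups))])
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            refined = model.refined_features(training=True, rng=rng)
            logits = model.batch_logits(refined, ia[sel], ib[sel], ic[sel])
            loss = _bce_from_logits(logits, y[sel])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        report.train_loss.append(float(np.mean(losses)))

        val_scores = model.predict_proba(val_samples)
        auroc = float(roc_auc_score(val_labels, val_scores))
        report.val_auroc.append(auroc)

        if auroc > best_auroc:
            best_auroc = auroc
            best_state = model.state_dict()
            report.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                report.stopping_reason = (
                    f"no validation improvement for {config.patience} epochs")
                break
    else:
        report.stopping_reason = "reached max_epochs"

    report.best_val_auroc = float(best_auroc)
    model.load_state_dict(best_state)
    ckpt = Checkpoint.from_model(model, cohort)
    return ckpt, report


# ---------------------------------------------------------------------------
# checkpointing


@dataclass
class Checkpoint:
    """Self-describing snapshot: parameters, config, indices and the data
    needed to rebuild the scoring pipeline (SMILES, preprocessed expression,
    disease embeddings, and the training-fold hypergraph)."""

    state: dict[str, np.ndarray]
    config: TrainConfig
    drugs: list[tuple[str, str]]            # (drug_id, smiles)
    cell_lines: list[str]
    diseases: list[str]
    expr_pre: np.ndarray                    # preprocessed expression rows
    gene_ids: list[str]
    disease_vectors: np.ndarray | None
    hg_coo: tuple[np.ndarray, np.ndarray]   # (rows, cols) of incidence
    hg_shape: tuple[int, int]
    hg_weights: np.ndarray
    hg_kinds: list[str]

    @classmethod
    def from_model(cls, model: SynergyModel, cohort: Cohort) -> "Checkpoint":
        hg = model.hypergraph
        coo = hg.incidence.tocoo()
        smiles = {d.drug_id: d.smiles for d in cohort.drugs}
        return cls(
            state=model.state_dict(),
            config=model.config,
            drugs=[(d, smiles[d]) for d in model.index.drugs],
            cell_lines=list(model.index.cell_lines),
            diseases=list(model.index.diseases),
            expr_pre=model.expr_values.copy(),
            gene_ids=list(cohort.expr.gene_ids),
            disease_vectors=(None if model.disease_vectors is None
                             else model.disease_vectors.copy()),
            hg_coo=(coo.row.copy(), coo.col.copy()),
            hg_shape=hg.incidence.shape,
            hg_weights=hg.edge_weights.copy(),
            hg_kinds=list(hg.edge_kinds),
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "hypersyn-checkpoint-1",
            "config": self.config.to_dict(),
            "drugs": self.drugs,
            "cell_lines": self.cell_lines,
            "diseases": self.diseases,
            "gene_ids": self.gene_ids,
            "hg_kinds": self.hg_kinds,
            "hg_shape": list(self.hg_shape),
            "has_disease_vectors": self.disease_vectors is not None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays = {f"param::{k}": v for k, v in self.state.items()}
        arrays["expr_pre"] = self.expr_pre
        arrays["hg_rows"] = self.hg_coo[0]
        arrays["hg_cols"] = self.hg_coo[1]
        arrays["hg_weights"] = self.hg_weights
        if self.disease_vectors is not None:
            arrays["disease_vectors"] = self.disease_vectors
        np.savez(directory / "arrays.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "Checkpoint":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with np.load(directory / "arrays.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        state = {k.split("::", 1)[1]: v for k, v in arrays.items()
                 if k.startswith("param::")}
        return cls(
            state=state,
            config=TrainConfig.from_dict(manifest["config"]),
            drugs=[tuple(d) for d in manifest["drugs"]],
            cell_lines=manifest["cell_lines"],
            diseases=manifest["diseases"],
            expr_pre=arrays["expr_pre"],
            gene_ids=manifest["gene_ids"],
            disease_vectors=arrays.get("disease_vectors"),
            hg_coo=(arrays["hg_rows"], arrays["hg_cols"]),
            hg_shape=tuple(manifest["hg_shape"]),
            hg_weights=arrays["hg_weights"],
            hg_kinds=manifest["hg_kinds"],
        )

    def to_model(self) -> SynergyModel:
        """Rebuild a scoring-ready model from the stored snapshot."""
        index = build_node_index([d for d, _ in self.drugs], self.cell_lines,
                                 self.diseases)
        graphs = {d: smiles_to_graph(smi, drug_id=d) for d, smi in self.drugs}
        expr = ExpressionMatrix(self.cell_lines, self.gene_ids, self.expr_pre)
        emb = None
        if self.disease_vectors is not None:
            emb = DiseaseEmbeddingTable(self.diseases, self.disease_vectors)
        model = SynergyModel.__new__(SynergyModel)
        model.index = index
        model.config = self.config
        model.expr_values = self.expr_pre
        model.disease_vectors = self.disease_vectors
        model._build_molecule_union([graphs[d] for d, _ in self.drugs])
        model._init_params(np.random.default_rng(0))
        model.load_state_dict(self.state)
        rows, cols = self.hg_coo
        H = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=self.hg_shape)
        model.set_hypergraph(Hypergraph(H, self.hg_weights, self.hg_kinds))
        return model

    def predict(self, samples: list[SynergySample]) -> np.ndarray:
        return self.to_model().predict_proba(samples)
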