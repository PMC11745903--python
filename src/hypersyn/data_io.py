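"""Reading, validation and preprocessing of the five cohort tables.

The pipeline consumes five delimited-text tables (CSV or TSV, header row,
UTF-8):

* synergy samples      — columns ``drug_a, drug_b, cell_line, score``
* drugs                — columns ``drug_id, smiles``
* expression matrix    — wide: first column ``cell_line``, one column per gene
* indication pairs     — columns ``drug_id, disease_id``
* disease embeddings   — wide: first column ``disease_id``, one column per
  embedding dimension (precomputed language-model vectors, consumed as-is)

Preprocessing follows the screening-panel convention: raw expression is
``log2(x + 1)`` transformed and each gene is z-scored across cell lines
(population standard deviation).  Continuous synergy scores (Loewe scores or
ComboScores) are binarized at a strict threshold of 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError", "DataError", "DrugRecord", "SynergySample",
    "ExpressionMatrix", "DiseaseEmbeddingTable", "IndicationPair",
    "FilterReport", "read_synergy_table", "read_drug_table",
    "read_expression_matrix", "read_indication_pairs",
    "read_disease_embeddings", "write_synergy_table", "write_drug_table",
    "write_expression_matrix", "write_indication_pairs",
    "write_disease_embeddings", "filter_entities", "preprocess_expression",
    "binarize_synergy", "Cohort", "load_cohort", "SYNERGY_THRESHOLD",
]

SYNERGY_THRESHOLD = 30.0

SYNERGY_COLUMNS = ("drug_a", "drug_b", "cell_line", "score")
DRUG_COLUMNS = ("drug_id", "smiles")
INDICATION_COLUMNS = ("drug_id", "disease_id")


class SchemaError(ValueError):
    """A table is missing a required column or is structurally malformed."""


class DataError(ValueError):
    """A table row or value violates its contract."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class SynergySample:
    """One measured (drug_a, drug_b, cell_line) combination.

    ``label`` is None until the score has been binarized; when set it must
    equal ``binarize_synergy(score)``.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    score: float
    label: int | None = None

    def with_label(self, threshold: float = SYNERGY_THRESHOLD) -> "SynergySample":
        return replace(self, label=binarize_synergy(self.score, threshold))


@dataclass
class ExpressionMatrix:
    cell_line_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # cell lines x genes

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_line_ids), len(self.gene_ids)):
            raise SchemaError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.cell_line_ids)} cell lines x {len(self.gene_ids)} genes")
        if not np.isfinite(self.values).all():
            raise DataError("expression matrix contains missing/non-finite values")

    def row(self, cell_line: str) -> np.ndarray:
        return self.values[self.cell_line_ids.index(cell_line)]


@dataclass
class DiseaseEmbeddingTable:
    disease_ids: list[str]
    vectors: np.ndarray  # diseases x embedding dim

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if len(self.disease_ids) != len(set(self.disease_ids)):
            raise DataError("duplicate disease ids in embedding table")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.disease_ids):
            raise SchemaError("embedding table shape does not match disease ids")


@dataclass(frozen=True)
class IndicationPair:
    drug_id: str
    disease_id: str


@dataclass
class FilterReport:
    """Counts of records removed by each consistency rule."""

    drugs_without_smiles: int = 0
    samples_missing_drug: int = 0
    samples_missing_cell_line: int = 0
    drugs_unreferenced: int = 0
    cell_lines_unreferenced: int = 0
    pairs_missing_drug: int = 0
    pairs_missing_embedding: int = 0
    diseases_unreferenced: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _read_table(path: str | Path, required: tuple[str, ...],
                dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def read_synergy_table(path: str | Path,
                       dialect: str | None = None) -> list[SynergySample]:
    """Parse the synergy table; scores become floats, labels stay unset.

    The reader is lossless: duplicate rows are retained (deduplication, if
    any, is a modelling decision taken downstream).
    """
    df = _read_table(path, SYNERGY_COLUMNS, dialect)
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            score = float(row.score)
        except (TypeError, ValueError) as err:
            raise DataError(
                f"{Path(path).name} line {i + 2}: unparseable score "
                f"{row.score!r}") from err
        samples.append(SynergySample(str(row.drug_a), str(row.drug_b),
                                     str(row.cell_line), score))
    return samples


def read_drug_table(path: str | Path,
                    dialect: str | None = None) -> list[DrugRecord]:
    df = _read_table(path, DRUG_COLUMNS, dialect)
    ids = df["drug_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataError(f"duplicate drug_id {dup!r} in drug table")
    smiles = df["smiles"].fillna("")
    return [DrugRecord(str(d), str(s)) for d, s in zip(ids, smiles)]


def read_expression_matrix(path: str | Path,
                           dialect: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect),
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise SchemaError(f"{path.name}: expression matrix needs id + gene columns")
    id_col = df.columns[0]
    cells = df[id_col].astype(str).tolist()
    genes = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise DataError(f"{path.name}: missing value for cell line "
                        f"{cells[r]!r}, gene {genes[c]!r}")
    return ExpressionMatrix(cells, genes, values)


def read_indication_pairs(path: str | Path,
                          dialect: str | None = None) -> list[IndicationPair]:
    df = _read_table(path, INDICATION_COLUMNS, dialect)
    seen: set[tuple[str, str]] = set()
    pairs = []
    for row in df.itertuples(index=False):
        key = (str(row.drug_id), str(row.disease_id))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(IndicationPair(*key))
    return pairs


def read_disease_embeddings(path: str | Path,
                            dialect: str | None = None) -> DiseaseEmbeddingTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect),
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise SchemaError(f"{path.name}: embedding table needs id + vector columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    vectors = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    if np.isnan(vectors).any():
        raise DataError(f"{path.name}: missing embedding value")
    return DiseaseEmbeddingTable(ids, vectors)


def write_synergy_table(samples: list[SynergySample], path: str | Path) -> None:
    df = pd.DataFrame([(s.drug_a, s.drug_b, s.cell_line, repr(s.score))
                       for s in samples], columns=SYNERGY_COLUMNS)
    df.to_csv(path, sep=_sep_for(path, None), index=False)


def write_drug_table(drugs: list[DrugRecord], path: str | Path) -> None:
    pd.DataFrame([(d.drug_id, d.smiles) for d in drugs],
                 columns=DRUG_COLUMNS).to_csv(path, sep=_sep_for(path, None),
                                              index=False)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.gene_ids)
    df.insert(0, "cell_line", expr.cell_line_ids)
    df.to_csv(path, sep=_sep_for(path, None), index=False)


def write_indication_pairs(pairs: list[IndicationPair], path: str | Path) -> None:
    pd.DataFrame([(p.drug_id, p.disease_id) for p in pairs],
                 columns=INDICATION_COLUMNS).to_csv(
                     path, sep=_sep_for(path, None), index=False)


def write_disease_embeddings(emb: DiseaseEmbeddingTable, path: str | Path) -> None:
    df = pd.DataFrame(emb.vectors,
                      columns=[f"e{i}" for i in range(emb.vectors.shape[1])])
    df.insert(0, "disease_id", emb.disease_ids)
    df.to_csv(path, sep=_sep_for(path, None), index=False)


# ---------------------------------------------------------------------------
# filtering and preprocessing


def filter_entities(samples: list[SynergySample],
                    drugs: list[DrugRecord],
                    expr: ExpressionMatrix,
                    pairs: list[IndicationPair] | None = None,
                    embeddings: DiseaseEmbeddingTable | None = None,
                    ):
    """Apply the cross-table consistency rules and report what was removed.

    Rules, in order: drugs without a SMILES string are dropped; synergy
    samples referencing a dropped drug or a cell line absent from the
    expression matrix are dropped; drugs and cell lines no longer referenced
    by any surviving sample are dropped; indication pairs whose drug did not
    survive or whose disease has no embedding are dropped; embeddings of
    diseases no longer referenced by any pair are dropped.

    The operation is idempotent.  Raises :class:`DataError` if no synergy
    sample survives.
    """
    pairs = pairs or []
    report = FilterReport()

    with_smiles = [d for d in drugs if d.smiles.strip()]
    report.drugs_without_smiles = len(drugs) - len(with_smiles)
    drug_ids = {d.drug_id for d in with_smiles}
    cell_ids = set(expr.cell_line_ids)

    kept_samples = []
    for s in samples:
        if s.drug_a not in drug_ids or s.drug_b not in drug_ids:
            report.samples_missing_drug += 1
        elif s.cell_line not in cell_ids:
            report.samples_missing_cell_line += 1
        else:
            kept_samples.append(s)
    if not kept_samples:
        raise DataError("no synergy samples survive entity filtering")

    used_drugs = {s.drug_a for s in kept_samples} | {s.drug_b for s in kept_samples}
    used_cells = {s.cell_line for s in kept_samples}
    kept_drugs = [d for d in with_smiles if d.drug_id in used_drugs]
    report.drugs_unreferenced = len(with_smiles) - len(kept_drugs)

    keep_rows = [i for i, c in enumerate(expr.cell_line_ids) if c in used_cells]
    report.cell_lines_unreferenced = len(expr.cell_line_ids) - len(keep_rows)
    kept_expr = ExpressionMatrix(
        [expr.cell_line_ids[i] for i in keep_rows],
        list(expr.gene_ids),
        expr.values[keep_rows],
    )

    emb_ids = set(embeddings.disease_ids) if embeddings is not None else set()
    kept_drug_ids = {d.drug_id for d in kept_drugs}
    kept_pairs = []
    for p in pairs:
        if p.drug_id not in kept_drug_ids:
            report.pairs_missing_drug += 1
        elif p.disease_id not in emb_ids:
            report.pairs_missing_embedding += 1
        else:
            kept_pairs.append(p)

    kept_emb = embeddings
    if embeddings is not None:
        used_dis = {p.disease_id for p in kept_pairs}
        keep = [i for i, d in enumerate(embeddings.disease_ids) if d in used_dis]
        report.diseases_unreferenced = len(embeddings.disease_ids) - len(keep)
        kept_emb = DiseaseEmbeddingTable(
            [embeddings.disease_ids[i] for i in keep],
            embeddings.vectors[keep] if keep else
            np.empty((0, embeddings.vectors.shape[1])),
        )

    return kept_samples, kept_drugs, kept_expr, kept_pairs, kept_emb, report


def preprocess_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1) transform then per-gene z-score (population std).

    Constant gene columns are mapped to all zeros so the matrix stays finite.
    Raw values must be non-negative.
    """
    if (expr.values < 0).any():
        r, c = np.argwhere(expr.values < 0)[0]
        raise DataError(
            f"negative expression value for gene {expr.gene_ids[c]!r}, "
            f"cell line {expr.cell_line_ids[r]!r}")
    logged = np.log2(expr.values + 1.0)
    mean = logged.mean(axis=0)
    std = logged.std(axis=0)  # population (divide-by-N) std
    # a column is constant when its spread is at rounding level relative to
    # its magnitude (the float mean of identical values is not always exact)
    keep = std > 1e-12 * np.maximum(1.0, np.abs(mean))
    centered = logged - mean
    out = np.where(keep, centered / np.where(keep, std, 1.0), 0.0)
    return ExpressionMatrix(list(expr.cell_line_ids), list(expr.gene_ids), out)


def binarize_synergy(score: float, threshold: float = SYNERGY_THRESHOLD) -> int:
    """1 if the continuous synergy score strictly exceeds the threshold."""
    if not math.isfinite(score):
        raise DataError(f"non-finite synergy score {score!r}")
    return 1 if score > threshold else 0


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class Cohort:
    """The five tables of one study cohort, kept together.

    ``expr`` holds raw (non-negative) expression; model code preprocesses it.
    ``pairs``/``embeddings`` may be empty/None for disease-free cohorts.
    """

    samples: list[SynergySample]
    drugs: list[DrugRecord]
    expr: ExpressionMatrix
    pairs: list[IndicationPair] = field(default_factory=list)
    embeddings: DiseaseEmbeddingTable | None = None

    def labeled_samples(self,
                        threshold: float = SYNERGY_THRESHOLD) -> list[SynergySample]:
        return [s.with_label(threshold) for s in self.samples]

    def filtered(self) -> tuple["Cohort", FilterReport]:
        samples, drugs, expr, pairs, emb, report = filter_entities(
            self.samples, self.drugs, self.expr, self.pairs, self.embeddings)
        return Cohort(samples, drugs, expr, pairs, emb), report

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_synergy_table(self.samples, directory / "synergy.csv")
        write_drug_table(self.drugs, directory / "drugs.csv")
        write_expression_matrix(self.expr, directory / "expression.csv")
        write_indication_pairs(self.pairs, directory / "indications.csv")
        if self.embeddings is not None:
            write_disease_embeddings(self.embeddings,
                                     directory / "disease_embeddings.csv")


def load_cohort(synergy: str | Path, drugs: str | Path, expr: str | Path,
                indications: str | Path | None = None,
                disease_embeddings: str | Path | None = None,
                dialect: str | None = None) -> Cohort:
    """Read the five tables from disk into a :class:`Cohort`."""
    return Cohort(
        samples=read_synergy_table(synergy, dialect),
        drugs=read_drug_table(drugs, dialect),
        expr=read_expression_matrix(expr, dialect),
        pairs=read_indication_pairs(indications, dialect) if indications else [],
        embeddings=(read_disease_embeddings(disease_embeddings, dialect)
                    if disease_embeddings else None),
    )
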