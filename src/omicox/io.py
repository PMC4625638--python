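"""Containers and file I/O for multi-omic survival cohorts.

The on-disk dialect is plain TSV throughout: feature-by-patient matrices
with a ``feature_id`` header column, a three-column clinical table
(``patient_id``, ``time``, ``event``), two-column edge lists for the
interaction network, and two-column (mirna_id, gene_id) target maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

SOURCES = ("EXPR", "MIRNA", "CNA", "MUT")
CONTINUOUS_SOURCES = ("EXPR", "MIRNA", "CNA")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class OmicsMatrix:
    """One data source's feature-by-patient matrix.

    Parameters
    ----------
    source:
        One of ``EXPR``, ``MIRNA``, ``CNA`` (continuous) or ``MUT``
        (strictly 0/1).
    df:
        ``features x patients`` DataFrame; index = feature ids,
        columns = patient ids.
    """

    source: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if self.df.index.has_duplicates:
            raise ValidationError(f"{self.source}: duplicate feature ids")
        if self.df.columns.has_duplicates:
            raise ValidationError(f"{self.source}: duplicate patient ids")
        values = self.df.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError(f"{self.source}: non-finite or missing values")
        if self.source == "MUT" and values.size:
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValidationError("MUT matrix must be strictly 0/1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def source_of(self, feature_id: str) -> str:
        if feature_id not in self.df.index:
            raise KeyError(feature_id)
        return self.source

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.source, self.df.loc[list(feature_ids)])

    def subset_patients(self, patient_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.source, self.df[list(patient_ids)])


@dataclass
class SurvivalData:
    """Per-patient follow-up time (positive, abstract units) and event flag."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = list(self.patient_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.patient_ids) != len(set(self.patient_ids)):
            raise ValidationError("duplicate patient ids in survival data")
        if not (len(self.patient_ids) == self.time.size == self.event.size):
            raise ValidationError("survival fields have unequal lengths")
        if self.time.size and self.time.min() <= 0:
            raise ValidationError("follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, patient_ids) -> "SurvivalData":
        idx = pd.Index(self.patient_ids)
        pos = idx.get_indexer(list(patient_ids))
        if (pos < 0).any():
            raise KeyError("unknown patient id in subset request")
        return SurvivalData(
            [self.patient_ids[i] for i in pos], self.time[pos], self.event[pos]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event},
            index=pd.Index(self.patient_ids, name="patient_id"),
        )


@dataclass
class InteractionNetwork:
    """Undirected feature graph (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(cls, edges) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    def degree(self, node) -> int:
        return self.graph.degree(node) if node in self.graph else 0

    def neighbors(self, node):
        return list(self.graph.neighbors(node)) if node in self.graph else []

    def has_node(self, node) -> bool:
        return node in self.graph

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return list(self.graph.edges)


@dataclass
class MirnaTargetMap:
    """Mapping miRNA id -> non-empty set of target gene ids."""

    targets: dict

    def __post_init__(self) -> None:
        clean = {}
        for mirna, genes in self.targets.items():
            genes = set(genes)
            if not genes:
                raise ValidationError(f"empty target set for {mirna}")
            if not all(isinstance(g, str) for g in genes):
                raise ValidationError(f"non-string gene id for {mirna}")
            clean[str(mirna)] = genes
        self.targets = clean

    def __getitem__(self, mirna: str) -> set:
        return self.targets[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def items(self):
        return self.targets.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path, source: str) -> OmicsMatrix:
    """Read a feature-by-patient TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return OmicsMatrix(source, df)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    df = matrix.df.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_clinical(path) -> SurvivalData:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return SurvivalData(df["patient_id"].tolist(), df["time"], df["event"])


def write_clinical(survival: SurvivalData, path) -> None:
    survival.to_frame().to_csv(path, sep="\t")


def read_edge_list(path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return InteractionNetwork.from_edges(df.itertuples(index=False, name=None))


def write_edge_list(network: InteractionNetwork, path) -> None:
    pd.DataFrame(network.edges).to_csv(path, sep="\t", header=False, index=False)


def read_target_map(path) -> MirnaTargetMap:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    targets: dict = {}
    for mirna, gene in df.itertuples(index=False, name=None):
        targets.setdefault(mirna, set()).add(gene)
    return MirnaTargetMap(targets)


def write_target_map(target_map: MirnaTargetMap, path) -> None:
    rows = [
        (m, g) for m, genes in sorted(target_map.items()) for g in sorted(genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# alignment and normalization


def align_cohort(matrices: dict, survival: SurvivalData):
    """Restrict all matrices and the survival table to their common patients.

    The common ids are ordered lexicographically so the result does not
    depend on file order.  Raises on an empty intersection.
    """
    common = set(survival.patient_ids)
    for m in matrices.values():
        common &= set(m.patient_ids)
    if not common:
        raise ValidationError("no patients shared by all matrices and survival")
    order = sorted(common)
    aligned = {src: m.subset_patients(order) for src, m in matrices.items()}
    return aligned, survival.subset(order)


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Quantile-normalize patients (columns) to the mean order statistics.

    After normalization every patient holds the identical sorted value
    multiset.  Tied values within a patient receive the mean of the order
    statistics they span.
    """
    if matrix.source == "MUT":
        raise ValidationError("quantile normalization is undefined for MUT data")
    values = matrix.values
    n_feat = values.shape[0]
    if n_feat == 0:
        return matrix
    # mean order-statistic vector across patients
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_feat)
        assigned[order] = mean_sorted
        # average order statistics over tied values
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(col).transform("mean").to_numpy()
    return OmicsMatrix(
        matrix.source,
        pd.DataFrame(out, index=matrix.df.index, columns=matrix.df.columns),
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
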