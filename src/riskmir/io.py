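"""Readers and writers for the external formats the pipeline touches.

Expression matrices are tab-separated, features in rows and samples in
columns (header row = sample ids, first column = feature/probe ids, the
missing-value token is ``NA``).  Loading applies the standard microarray
preprocessing rules: features with missing values are screened out and
rows that share a feature id (multiple probes per gene) are averaged into
a unique value.  Values are assumed to be already log2-scale, normalized
intensities; raw-array (CEL) processing is out of scope.

Also here: GMT gene-set collections, two-column miRNA-target interaction
tables, protein-protein interaction edge lists, and SIF/GraphML network
export.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DesignError, LabelingError, ParseError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """One labeled case/control feature x sample matrix (mRNA or miRNA).

    ``values`` holds log-scale intensities with shape
    ``(len(feature_ids), len(sample_ids))``; ``labels`` holds ``"case"`` or
    ``"control"`` per sample, aligned with ``sample_ids``.
    """

    study_id: str
    platform: str  # "mRNA" | "miRNA"
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.platform not in ("mRNA", "miRNA"):
            raise ParseError(f"unknown platform {self.platform!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ParseError("feature ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("sample ids are not unique")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ParseError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ParseError("expression matrix contains missing values after loading")
        bad = set(self.labels) - {CASE, CONTROL}
        if bad:
            raise LabelingError(f"unknown sample labels: {sorted(bad)}")
        if self.n_case < 2 or self.n_control < 2:
            raise DesignError(
                f"study {self.study_id!r} needs >=2 case and >=2 control samples "
                f"(got {self.n_case} case, {self.n_control} control)"
            )

    # -- convenience views --------------------------------------------------

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == CONTROL

    @property
    def n_case(self) -> int:
        return int(np.sum(self.labels == CASE))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.labels == CONTROL))

    @property
    def labels_dict(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def case_values(self) -> np.ndarray:
        return self.values[:, self.case_mask]

    def control_values(self) -> np.ndarray:
        return self.values[:, self.control_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def feature_values(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (
            self.platform == other.platform
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and list(self.labels) == list(other.labels)
            and np.allclose(self.values, other.values)
        )


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets (a pathway collection)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ParseError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names if n in self.sets}, self.source)


@dataclass
class TargetMap:
    """Unique (miRNA, gene) interaction pairs with per-miRNA target counts."""

    pairs: frozenset[tuple[str, str]]
    provenance: str = "validated"

    def __post_init__(self) -> None:
        self.pairs = frozenset((str(m), str(g)) for m, g in self.pairs)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return frozenset(g for m, g in self.pairs if m == mirna)

    @property
    def target_counts(self) -> dict[str, int]:
        """K_i: number of distinct genes targeted by each miRNA."""
        counts: dict[str, int] = {}
        for m, _ in self.pairs:
            counts[m] = counts.get(m, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.pairs)

    def by_mirna(self) -> dict[str, frozenset[str]]:
        acc: dict[str, set[str]] = {}
        for m, g in self.pairs:
            acc.setdefault(m, set()).add(g)
        return {m: frozenset(gs) for m, gs in acc.items()}


@dataclass
class PpiNetwork:
    """Undirected protein-protein interaction network (no self-loops)."""

    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                continue
            canon.add((a, b) if a <= b else (b, a))
        self.edges = frozenset(canon)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def degree(self, gene: str) -> int:
        return sum(1 for a, b in self.edges if gene in (a, b))

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    def subgraph_edges(self, genes: Iterable[str]) -> frozenset[tuple[str, str]]:
        keep = set(genes)
        return frozenset((a, b) for a, b in self.edges if a in keep and b in keep)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path,
    labels: Mapping[str, str],
    platform: str,
    *,
    study_id: str | None = None,
    missing_token: str = MISSING_TOKEN,
    max_missing_fraction: float = 0.0,
) -> ExpressionStudy:
    """Load a TSV expression matrix, applying the preprocessing rules.

    Rows sharing a feature id are averaged element-wise into a unique value;
    features whose fraction of missing cells exceeds ``max_missing_fraction``
    (default 0: any missing value) are dropped; any missing cells that
    survive the screen are imputed with the feature's mean.

    Parameters
    ----------
    labels : mapping of sample id -> "case" | "control"; every sample in the
        header must be labeled.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.isnull().any():
        raise ParseError(f"{path}: missing feature id")
    unlabeled = [s for s in raw.columns if s not in labels]
    if unlabeled:
        raise LabelingError(f"{path}: unlabeled samples: {unlabeled}")

    masked = raw.replace(missing_token, np.nan)
    try:
        values = masked.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric cell that is not the missing token: {exc}") from exc

    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= max_missing_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d features failing the missing-value screen", path, n_dropped)
    values = values.loc[keep]
    if values.isna().any().any():
        # tolerated missing cells (max_missing_fraction > 0): impute feature mean
        values = values.T.fillna(values.mean(axis=1)).T

    # probe combination: average duplicate feature ids (first-occurrence order)
    n_before = len(values)
    values = values.groupby(level=0, sort=False).mean()
    if len(values) != n_before:
        logger.info("%s: averaged %d probe rows into %d unique features", path, n_before, len(values))

    sample_ids = list(values.columns)
    study = ExpressionStudy(
        study_id=study_id or str(path),
        platform=platform,
        feature_ids=list(values.index),
        sample_ids=sample_ids,
        values=values.to_numpy(dtype=float),
        labels=np.array([labels[s] for s in sample_ids], dtype=object),
    )
    return study


def write_expression_matrix(study: ExpressionStudy, path) -> None:
    study.to_frame().to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, ``name<TAB>desc<TAB>members...``."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, source if source is not None else str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction tables and edge lists
# ---------------------------------------------------------------------------


def _read_two_column_tsv(path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}: line {lineno}: malformed {what} row")
            rows.append((fields[0], fields[1]))
    return rows


def read_interaction_table(path, provenance: str = "validated") -> TargetMap:
    """Read a two-column miRNA-id<TAB>gene-id table into a TargetMap."""
    return TargetMap(frozenset(_read_two_column_tsv(path, "interaction")), provenance)


def write_interaction_table(targets: TargetMap, path) -> None:
    with open(path, "w") as fh:
        for m, g in sorted(targets.pairs):
            fh.write(f"{m}\t{g}\n")


def read_edge_list(path) -> PpiNetwork:
    """Read a two-column gene-gene edge list; drops self-loops, collapses duplicates."""
    return PpiNetwork(frozenset(_read_two_column_tsv(path, "edge")))


def write_edge_list(ppi: PpiNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def write_network(net: nx.Graph, path, dialect: str = "SIF") -> None:
    """Export a typed regulatory network as SIF or GraphML.

    SIF rows are ``source<TAB>interaction<TAB>target`` using the edge
    ``edge_type`` attribute ("targets", "member_of", "ppi"); isolated nodes
    are written as single-token lines.  GraphML carries node attributes
    (``node_type``, ``direction``) and edge attributes (``edge_type``) and
    round-trips the node/edge sets exactly.
    """
    dialect = dialect.upper()
    if dialect == "SIF":
        with open(path, "w") as fh:
            seen: set[str] = set()
            for u, v, data in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{data.get('edge_type', 'interacts')}\t{v}\n")
                seen.add(u)
                seen.add(v)
            for node in sorted(set(net.nodes) - seen):
                fh.write(f"{node}\n")
    elif dialect == "GRAPHML":
        out = nx.Graph()
        for n, data in net.nodes(data=True):
            out.add_node(n, **{k: str(v) for k, v in data.items()})
        for u, v, data in net.edges(data=True):
            out.add_edge(u, v, **{k: str(v) for k, v in data.items()})
        nx.write_graphml(out, path)
    else:
        raise ParseError(f"unknown network dialect {dialect!r} (use SIF or GraphML)")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
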