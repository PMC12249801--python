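"""Antigen-specificity cluster database.

A specificity cluster is a set of convergent TCRbeta clonotypes — CDR3
sequences of equal length differing by one amino acid — that expand
together after vaccination with a given peptide. The databases handled
here are flat TSV files, one CDR3 per row, with an antigen label and a
cluster identifier; the column layout is configurable and defaults to
the VDJdb-chunk-style ``cdr3`` / ``v.segm`` / ``antigen.epitope`` /
``cluster.id`` naming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .repertoire import is_valid_cdr3

# Database-derived clusters are expected in this size range; outside it
# the file is still read but a warning is emitted.
CLUSTER_SIZE_RANGE = (4, 200)


@dataclass
class ClusterColumnMap:
    """Column names used when reading a cluster database TSV."""

    cdr3: str = "cdr3"
    v_call: str = "v.segm"
    antigen: str = "antigen.epitope"
    cluster_id: str = "cluster.id"


@dataclass
class SpecificityCluster:
    """Named set of antigen-specific CDR3 amino-acid sequences."""

    cluster_id: str
    antigen: str
    members: frozenset[str]
    member_v_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")
        bad = [m for m in self.members if not is_valid_cdr3(m)]
        if bad:
            raise ValueError(
                f"cluster {self.cluster_id!r}: invalid CDR3 members {bad[:3]!r}"
            )
        lo, hi = CLUSTER_SIZE_RANGE
        if not lo <= len(self.members) <= hi:
            warnings.warn(
                f"cluster {self.cluster_id} has {len(self.members)} members, "
                f"outside the expected {lo}-{hi} range for database clusters",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterDB:
    """Container of specificity clusters keyed by cluster id."""

    clusters: list[SpecificityCluster]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate cluster ids in database")
        self._by_id = {c.cluster_id: c for c in self.clusters}

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, cluster_id: str) -> SpecificityCluster:
        return self._by_id[cluster_id]

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self._by_id

    @property
    def cluster_ids(self) -> list[str]:
        return [c.cluster_id for c in self.clusters]

    @property
    def n_members(self) -> int:
        return sum(len(c) for c in self.clusters)


def read_cluster_db(
    path: str | Path,
    columns: ClusterColumnMap | None = None,
) -> ClusterDB:
    """Read a specificity-cluster database from a TSV file.

    Rows are grouped by cluster identifier; duplicate CDR3s within a
    cluster are collapsed; rows with invalid CDR3s are dropped (a cluster
    left empty by filtering is dropped with a warning).
    """
    columns = columns or ClusterColumnMap()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"cluster database {path} is empty") from None
    if df.empty:
        raise ValueError(f"cluster database {path} has no rows")

    required = [columns.cdr3, columns.cluster_id]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"cluster database {path} lacks required column(s) {missing}; "
            f"available: {list(df.columns)}; adjust the ClusterColumnMap"
        )

    has_antigen = columns.antigen in df.columns
    has_v = columns.v_call in df.columns

    clusters: list[SpecificityCluster] = []
    for cid, grp in df.groupby(columns.cluster_id, sort=True):
        members: dict[str, str] = {}
        for _, row in grp.iterrows():
            cdr3 = str(row[columns.cdr3]).strip().upper()
            if not is_valid_cdr3(cdr3):
                continue
            v = str(row[columns.v_call]).strip() if has_v else ""
            members.setdefault(cdr3, v if v != "nan" else "")
        if not members:
            warnings.warn(
                f"cluster {cid} has no valid CDR3 members after filtering; dropped",
                stacklevel=2,
            )
            continue
        antigen = ""
        if has_antigen:
            antigen = str(grp[columns.antigen].iloc[0])
        clusters.append(
            SpecificityCluster(
                cluster_id=str(cid),
                antigen=antigen,
                members=frozenset(members),
                member_v_calls=members,
            )
        )
    if not clusters:
        raise ValueError(f"cluster database {path}: no usable clusters")
    return ClusterDB(clusters=clusters, source=str(path))


def load_builtin_cluster_db() -> ClusterDB:
    """Load the packaged nine-cluster p30 specificity database.

    This is a synthetic stand-in for the published p30 cluster set: nine
    clusters of convergent equal-length CDR3s differing by single amino
    acids, seeded around the printed public C14/C22 sequences. It matches
    the structural properties of the real database (cluster count, size
    range, one-mismatch convergence) but not its exact sequences.
    """
    ref = resources.files("neotrack.data").joinpath("p30_clusters_synthetic.tsv")
    with resources.as_file(ref) as path:
        db = read_cluster_db(path)
    db.source = "builtin:p30_clusters_synthetic"
    return db
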