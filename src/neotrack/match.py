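"""Fuzzy matching of repertoire CDR3s against specificity clusters.

The quantification at the heart of the pipeline: every clonotype whose
CDR3 lies within edit distance 1 (substitution, insertion or deletion)
of any cluster member is counted as specific for that cluster,
regardless of its TRBV call, and the frequencies of matched clonotypes
are summed per cluster and once overall (the union).

Lookup uses a symmetric-deletion neighbourhood index: every cluster
member is stored under itself and all of its single-character deletions;
a query probes the same neighbourhood of itself and candidate hits are
verified with the exact capped Levenshtein distance. For two strings
within distance ``d`` the depth-``d`` deletion neighbourhoods always
intersect, so the index returns exactly the hits a brute-force scan over
all members would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clusters import ClusterDB
from .distance import bounded_levenshtein, deletion_variants
from .repertoire import Repertoire


@dataclass(frozen=True)
class MatchResult:
    """One (clonotype, cluster) hit with its best member-wise distance."""

    clonotype_cdr3: str
    v_call: str
    j_call: str
    cluster_id: str
    best_distance: int
    matched_member: str
    frequency: float


@dataclass
class SampleQuantification:
    """Per-cluster and union summed frequencies for one sample."""

    sample_id: str
    per_cluster_frequency: dict[str, float]
    union_frequency: float
    matches: list[MatchResult] = field(default_factory=list)
    mouse_id: str = ""
    tissue: str = ""
    subset: str = ""

    def matched_clonotypes(self, cluster_id: str) -> list[MatchResult]:
        return [m for m in self.matches if m.cluster_id == cluster_id]


def _deletion_neighbourhood(s: str, depth: int) -> set[str]:
    """All strings reachable from ``s`` by up to ``depth`` deletions."""
    out = {s}
    frontier = {s}
    for _ in range(depth):
        nxt = set()
        for t in frontier:
            if len(t) > 1:
                nxt.update(deletion_variants(t))
        nxt -= out
        out |= nxt
        frontier = nxt
    return out


class MatchIndex:
    """Deletion-neighbourhood index over a cluster database.

    ``max_distance`` 0, 1 or 2. Querying returns, per cluster, the best
    (distance, member) pair among members within the cap — identical to
    a brute-force member-wise scan.
    """

    def __init__(self, db: ClusterDB, max_distance: int = 1) -> None:
        if len(db) == 0:
            raise ValueError("empty cluster database")
        if max_distance not in (0, 1, 2):
            raise ValueError("max_distance must be 0, 1 or 2")
        self.db = db
        self.max_distance = max_distance
        # key -> list of (cluster_id, member)
        self._table: dict[str, list[tuple[str, str]]] = {}
        for cluster in db.clusters:
            for member in cluster.members:
                for key in _deletion_neighbourhood(member, max_distance):
                    self._table.setdefault(key, []).append(
                        (cluster.cluster_id, member)
                    )

    @property
    def member_keys(self) -> frozenset[str]:
        """All index keys; useful for fast collision screens."""
        return frozenset(self._table)

    def query(self, cdr3: str) -> dict[str, tuple[int, str]]:
        """Map cluster_id -> (best distance, matched member) for ``cdr3``."""
        candidates: set[tuple[str, str]] = set()
        for key in _deletion_neighbourhood(cdr3, self.max_distance):
            hits = self._table.get(key)
            if hits:
                candidates.update(hits)
        best: dict[str, tuple[int, str]] = {}
        for cluster_id, member in candidates:
            d = bounded_levenshtein(cdr3, member, cap=self.max_distance)
            if d is None:
                continue
            cur = best.get(cluster_id)
            # tie-break on member string for determinism
            if cur is None or (d, member) < cur:
                best[cluster_id] = (d, member)
        return best

    def query_brute_force(self, cdr3: str) -> dict[str, tuple[int, str]]:
        """Reference scan over every member; used for verification."""
        best: dict[str, tuple[int, str]] = {}
        for cluster in self.db.clusters:
            for member in sorted(cluster.members):
                d = bounded_levenshtein(cdr3, member, cap=self.max_distance)
                if d is None:
                    continue
                cur = best.get(cluster.cluster_id)
                if cur is None or (d, member) < cur:
                    best[cluster.cluster_id] = (d, member)
        return best


def match_repertoire(
    repertoire: Repertoire,
    db: ClusterDB | MatchIndex,
    max_distance: int = 1,
) -> list[MatchResult]:
    """All (clonotype, cluster) pairs within ``max_distance`` edits.

    V and J calls are ignored during matching (they are carried through
    for inspection only). Each qualifying pair is reported once with the
    best member-wise distance.
    """
    index = db if isinstance(db, MatchIndex) else MatchIndex(db, max_distance)
    if index.max_distance != max_distance:
        index = MatchIndex(index.db, max_distance)
    results: list[MatchResult] = []
    for clon in repertoire.clonotypes:
        for cluster_id, (d, member) in sorted(index.query(clon.cdr3_aa).items()):
            results.append(
                MatchResult(
                    clonotype_cdr3=clon.cdr3_aa,
                    v_call=clon.v_call,
                    j_call=clon.j_call,
                    cluster_id=cluster_id,
                    best_distance=d,
                    matched_member=member,
                    frequency=clon.frequency,
                )
            )
    return results


def quantify(
    repertoire: Repertoire,
    db: ClusterDB | MatchIndex,
    max_distance: int = 1,
) -> SampleQuantification:
    """Sum matched clonotype frequencies per cluster and as a union.

    A clonotype matching several clusters contributes its frequency to
    each of them but only once to the union, so the union frequency never
    exceeds 1. Clusters without matches report an exact 0 (any display
    floor for log-scale plots is presentation-only).
    """
    index = db if isinstance(db, MatchIndex) else MatchIndex(db, max_distance)
    if index.max_distance != max_distance:
        index = MatchIndex(index.db, max_distance)
    per_cluster = {cid: 0.0 for cid in index.db.cluster_ids}
    union = 0.0
    matches: list[MatchResult] = []
    for clon in repertoire.clonotypes:
        hits = index.query(clon.cdr3_aa)
        if not hits:
            continue
        union += clon.frequency
        for cluster_id, (d, member) in sorted(hits.items()):
            per_cluster[cluster_id] += clon.frequency
            matches.append(
                MatchResult(
                    clonotype_cdr3=clon.cdr3_aa,
                    v_call=clon.v_call,
                    j_call=clon.j_call,
                    cluster_id=cluster_id,
                    best_distance=d,
                    matched_member=member,
                    frequency=clon.frequency,
                )
            )
    return SampleQuantification(
        sample_id=repertoire.sample_id,
        per_cluster_frequency=per_cluster,
        union_frequency=union,
        matches=matches,
        mouse_id=repertoire.mouse_id,
        tissue=repertoire.tissue,
        subset=repertoire.subset,
    )


def neighbourhood_size(length: int, alphabet_size: int = 20) -> int:
    """Exact size of the distance-1 Levenshtein neighbourhood of a string.

    For a string of length L over an alphabet of size k (excluding the
    string itself): L*(k-1) substitutions, (L+1)*k - L distinct
    insertions, and at most L deletions; deletions and insertions of
    repeated runs collapse, so this is an upper bound reached only by
    strings with no repeated adjacent characters. Used to sanity-check
    variant generation requests.
    """
    subs = length * (alphabet_size - 1)
    ins = (length + 1) * alphabet_size - length
    dels = length
    return subs + ins + dels


def distinct_distance1_variants(s: str, alphabet: str) -> set[str]:
    """Enumerate the exact distance-1 neighbourhood of ``s`` (excluding it)."""
    out: set[str] = set()
    for i in range(len(s)):
        for c in alphabet:
            t = s[:i] + c + s[i + 1 :]
            if t != s:
                out.add(t)
        if len(s) > 1:
            out.add(s[:i] + s[i + 1 :])
    for i in range(len(s) + 1):
        for c in alphabet:
            out.add(s[:i] + c + s[i:])
    out.discard(s)
    return out
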