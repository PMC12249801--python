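"""Core containers for bulk TCRbeta clonotype data.

A *clonotype* is a group of T cells sharing the same rearranged receptor,
identified here by the CDR3 amino-acid sequence plus the TRBV gene call.
A *repertoire* is the clonotype list of one sorted, sequenced sample
(one mouse, one tissue, one T-cell subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

TISSUES = ("tdLN", "cfa_plaque", "tumor")
SUBSETS = ("Th", "Treg", "CD8")

FREQ_TOL = 1e-9


def is_valid_cdr3(seq: str) -> bool:
    """True if ``seq`` is a non-empty string over the 20 standard amino acids.

    Out-of-frame junctions exported by upstream tools carry stop ('*'),
    frameshift ('_') or ambiguous ('X') symbols and are rejected.
    """
    return bool(seq) and all(c in _AA_SET for c in seq)


@dataclass(frozen=True)
class Clonotype:
    """One TCRbeta clone: CDR3 amino acids, gene calls, abundance."""

    cdr3_aa: str
    v_call: str = ""
    j_call: str = ""
    count: int = 1
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("clonotype CDR3 must be non-empty")
        if self.count < 0:
            raise ValueError("clonotype count must be non-negative")


@dataclass
class Repertoire:
    """One sorted sample's clonotypes plus sample-level metadata.

    ``flags`` records provenance marks set by pipeline stages, e.g.
    ``not_downsampled`` when a sample was already below the rarefaction
    target.
    """

    sample_id: str
    clonotypes: list[Clonotype]
    mouse_id: str = ""
    tissue: str = ""
    subset: str = "Th"
    flags: dict = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def richness(self) -> int:
        """Number of distinct clonotypes."""
        return len(self.clonotypes)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self):
        return iter(self.clonotypes)


def aggregate_clonotypes(clonotypes: list[Clonotype]) -> list[Clonotype]:
    """Merge entries sharing (cdr3_aa, v_call), summing counts.

    Output order follows first appearance, so aggregation commutes with any
    permutation of the input up to that canonical order.
    """
    merged: dict[tuple[str, str], int] = {}
    j_calls: dict[tuple[str, str], str] = {}
    for c in clonotypes:
        key = (c.cdr3_aa, c.v_call)
        merged[key] = merged.get(key, 0) + c.count
        j_calls.setdefault(key, c.j_call)
    out = [
        Clonotype(cdr3_aa=k[0], v_call=k[1], j_call=j_calls[k], count=n)
        for k, n in sorted(merged.items())
    ]
    return out


def recompute_frequencies(repertoire: Repertoire) -> Repertoire:
    """Return a copy with frequency_i = count_i / sum(counts)."""
    total = repertoire.total_count
    if total <= 0:
        raise ValueError(
            f"sample {repertoire.sample_id!r}: total count is zero, "
            "frequencies undefined"
        )
    clons = [replace(c, frequency=c.count / total) for c in repertoire.clonotypes]
    return replace_clonotypes(repertoire, clons)


def replace_clonotypes(repertoire: Repertoire, clonotypes: list[Clonotype]) -> Repertoire:
    return Repertoire(
        sample_id=repertoire.sample_id,
        clonotypes=clonotypes,
        mouse_id=repertoire.mouse_id,
        tissue=repertoire.tissue,
        subset=repertoire.subset,
        flags=dict(repertoire.flags),
    )


@dataclass
class ValidationReport:
    """Outcome of non-mutating invariant checks on a repertoire."""

    sample_id: str
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_repertoire(repertoire: Repertoire) -> ValidationReport:
    """Check repertoire invariants; never mutates.

    Violations: frequency sum off unity, duplicate (CDR3, V) keys, empty
    clonotype list. Warnings: lowercase or non-standard CDR3 characters.
    """
    report = ValidationReport(sample_id=repertoire.sample_id)
    if not repertoire.clonotypes:
        report.violations.append("repertoire has no clonotypes")
        return report

    freq_sum = sum(c.frequency for c in repertoire.clonotypes)
    if abs(freq_sum - 1.0) > FREQ_TOL:
        report.violations.append(
            f"frequencies sum to {freq_sum:.6g}, expected 1 within {FREQ_TOL:g}"
        )

    seen: set[tuple[str, str]] = set()
    for c in repertoire.clonotypes:
        key = (c.cdr3_aa, c.v_call)
        if key in seen:
            report.violations.append(
                f"duplicate clonotype key {key!r} (aggregate before use)"
            )
        seen.add(key)
        if c.cdr3_aa != c.cdr3_aa.upper():
            report.warnings.append(
                f"CDR3 {c.cdr3_aa!r} is not uppercase; normalize on read"
            )
        elif not is_valid_cdr3(c.cdr3_aa):
            report.warnings.append(
                f"CDR3 {c.cdr3_aa!r} contains non-standard amino-acid symbols"
            )
    return report
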