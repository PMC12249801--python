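"""Reading and writing clonotype tables.

Two TSV dialects are supported:

* ``airr`` — AIRR Rearrangement style, columns ``junction_aa``, ``v_call``,
  ``j_call``, ``duplicate_count``;
* ``mixcr`` — MiXCR export style, columns ``aaSeqCDR3``,
  ``bestVGene``/``allVHitsWithScore``, ``bestJGene``, ``cloneCount``,
  ``cloneFraction``.

Reading always uppercases CDR3s, drops rows whose junction leaves the
20-letter amino-acid alphabet (out-of-frame '_' or '*', ambiguous 'X'),
aggregates duplicate (CDR3, V) rows by summing counts, and recomputes
frequencies, so a freshly read repertoire always satisfies the container
invariants regardless of how the upstream tool wrote the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .repertoire import (
    Clonotype,
    Repertoire,
    aggregate_clonotypes,
    recompute_frequencies,
)
from .repertoire import is_valid_cdr3

DIALECTS = ("airr", "mixcr")

_AIRR_REQUIRED = ("junction_aa", "v_call", "duplicate_count")
_MIXCR_REQUIRED = ("aaSeqCDR3", "cloneCount")


class DialectError(ValueError):
    """A required column for the requested dialect is missing."""


class EmptyRepertoireError(ValueError):
    """No usable clonotype rows after filtering."""


@dataclass
class ReadReport:
    """Row-level accounting for one table read."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_invalid_cdr3: int = 0
    n_aggregated_duplicates: int = 0
    dropped_examples: list[str] = field(default_factory=list)


def _best_hit(raw: str) -> str:
    """First gene of a MiXCR 'allVHitsWithScore' field, score stripped.

    e.g. ``"TRBV13-1*00(1200),TRBV13-2*00(900)"`` -> ``"TRBV13-1"``.
    """
    if not raw or raw == "nan":
        return ""
    first = raw.split(",")[0]
    first = first.split("(")[0]
    return first.split("*")[0].strip()


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    sample_id: str | None = None,
) -> tuple[Repertoire, ReadReport]:
    """Read one clonotype TSV into a validated :class:`Repertoire`.

    Returns the repertoire and a :class:`ReadReport` counting dropped and
    aggregated rows. Sample metadata (mouse, tissue, subset) is taken from
    optional ``mouse_id`` / ``tissue`` / ``subset`` columns when present,
    otherwise left blank for the caller to fill from a metadata table.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path}: file is empty") from None

    required = _AIRR_REQUIRED if dialect == "airr" else _MIXCR_REQUIRED
    if dialect == "mixcr" and "aaSeqCDR3" in df.columns:
        # V column may come as bestVGene or allVHitsWithScore
        if "bestVGene" not in df.columns and "allVHitsWithScore" not in df.columns:
            raise DialectError(
                f"{path}: mixcr dialect needs column 'bestVGene' or "
                "'allVHitsWithScore'"
            )
    for col in required:
        if col not in df.columns:
            raise DialectError(
                f"{path}: column {col!r} required by the {dialect!r} dialect "
                "is missing"
            )

    report = ReadReport(path=str(path), n_rows=len(df))
    clonotypes: list[Clonotype] = []
    for _, row in df.iterrows():
        if dialect == "airr":
            raw = row["junction_aa"]
            cdr3 = "" if pd.isna(raw) else str(raw).strip().upper()
            v = str(row.get("v_call", "") or "").strip()
            j = str(row.get("j_call", "") or "").strip()
            count_raw = row["duplicate_count"]
        else:
            raw = row["aaSeqCDR3"]
            cdr3 = "" if pd.isna(raw) else str(raw).strip().upper()
            if "bestVGene" in df.columns and str(row.get("bestVGene", "")) not in ("", "nan"):
                v = str(row["bestVGene"]).strip()
            else:
                v = _best_hit(str(row.get("allVHitsWithScore", "")))
            j = str(row.get("bestJGene", "") or "").strip()
            count_raw = row["cloneCount"]
        v = "" if v == "nan" else v
        j = "" if j == "nan" else j
        if not is_valid_cdr3(cdr3):
            report.n_dropped_invalid_cdr3 += 1
            if len(report.dropped_examples) < 5:
                report.dropped_examples.append(cdr3)
            continue
        try:
            count = int(float(count_raw))
        except (TypeError, ValueError):
            report.n_dropped_invalid_cdr3 += 1
            continue
        if count < 1:
            report.n_dropped_invalid_cdr3 += 1
            continue
        clonotypes.append(Clonotype(cdr3_aa=cdr3, v_call=v, j_call=j, count=count))

    if not clonotypes:
        raise EmptyRepertoireError(f"{path}: zero usable clonotype rows")

    aggregated = aggregate_clonotypes(clonotypes)
    report.n_aggregated_duplicates = len(clonotypes) - len(aggregated)
    report.n_kept = len(aggregated)

    meta = {}
    for key in ("mouse_id", "tissue", "subset"):
        if key in df.columns and len(df[key].dropna()):
            meta[key] = str(df[key].dropna().iloc[0])
    rep = Repertoire(
        sample_id=sample_id or path.stem,
        clonotypes=aggregated,
        mouse_id=meta.get("mouse_id", ""),
        tissue=meta.get("tissue", ""),
        subset=meta.get("subset", "Th"),
    )
    return recompute_frequencies(rep), report


def write_clonotype_table(
    repertoire: Repertoire,
    path: str | Path,
    dialect: str = "airr",
) -> None:
    """Write a repertoire as a TSV in the requested dialect.

    Round trip through :func:`read_clonotype_table` reproduces CDR3s, gene
    calls and counts exactly.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not repertoire.clonotypes:
        raise EmptyRepertoireError(
            f"refusing to write empty repertoire {repertoire.sample_id!r}"
        )
    total = repertoire.total_count
    if dialect == "airr":
        df = pd.DataFrame(
            {
                "junction_aa": [c.cdr3_aa for c in repertoire.clonotypes],
                "v_call": [c.v_call for c in repertoire.clonotypes],
                "j_call": [c.j_call for c in repertoire.clonotypes],
                "duplicate_count": [c.count for c in repertoire.clonotypes],
            }
        )
    else:
        df = pd.DataFrame(
            {
                "aaSeqCDR3": [c.cdr3_aa for c in repertoire.clonotypes],
                "bestVGene": [c.v_call for c in repertoire.clonotypes],
                "bestJGene": [c.j_call for c in repertoire.clonotypes],
                "cloneCount": [c.count for c in repertoire.clonotypes],
                "cloneFraction": [c.count / total for c in repertoire.clonotypes],
            }
        )
    df.to_csv(path, sep="\t", index=False)
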