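"""Sample-size normalisation by rarefaction.

Bulk repertoires from different tissues differ in sequencing depth by
orders of magnitude (draining lymph nodes yield ~50x more sorted cells
than adjuvant plaques). To keep summed clone frequencies comparable,
every sample is downsampled to a common number of distinct clonotypes
(1000 by default) before any specificity matching.

Two interpretations of "downsample to N clonotypes" are provided:

* ``rarefy_reads_until_richness`` (default) — reads are drawn without
  replacement in uniformly random order until the number of distinct
  clonotypes first reaches the target; the drawn reads form the new
  repertoire. This preserves relative abundances stochastically and is
  unbiased at the clone level.
* ``top_n_by_count`` — the N most abundant clonotypes are kept (ties
  broken lexicographically by CDR3) and frequencies renormalised. This
  is deterministic but biased toward large clones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .repertoire import Repertoire, recompute_frequencies, replace_clonotypes

MODES = ("rarefy_reads_until_richness", "top_n_by_count")

DEFAULT_TARGET = 1000


@dataclass(frozen=True)
class DownsampleSpec:
    """Parameters of the rarefaction step; recorded in output provenance."""

    target_clonotypes: int = DEFAULT_TARGET
    mode: str = "rarefy_reads_until_richness"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_clonotypes < 1:
            raise ValueError("target_clonotypes must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def downsample(repertoire: Repertoire, spec: DownsampleSpec) -> Repertoire:
    """Downsample a repertoire to ``spec.target_clonotypes`` distinct clones.

    A repertoire already at or below the target is returned unchanged
    apart from a ``not_downsampled`` flag. Deterministic given
    ``spec.seed``. Never introduces clonotypes absent from the input.
    """
    if repertoire.richness <= spec.target_clonotypes:
        out = replace_clonotypes(repertoire, list(repertoire.clonotypes))
        out.flags["not_downsampled"] = True
        out.flags["downsample"] = _provenance(spec)
        return recompute_frequencies(out)

    if spec.mode == "top_n_by_count":
        ranked = sorted(
            repertoire.clonotypes, key=lambda c: (-c.count, c.cdr3_aa, c.v_call)
        )
        kept = ranked[: spec.target_clonotypes]
        out = replace_clonotypes(repertoire, kept)
    else:
        out = _rarefy(repertoire, spec)
    out.flags["downsample"] = _provenance(spec)
    return recompute_frequencies(out)


def _rarefy(repertoire: Repertoire, spec: DownsampleSpec) -> Repertoire:
    rng = np.random.default_rng(spec.seed)
    counts = np.array([c.count for c in repertoire.clonotypes], dtype=np.int64)
    # one entry per read, labelled by clonotype index, in random order
    reads = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(reads)
    # mark the first occurrence of each label in the shuffled order, then
    # cut the prefix at the read that brings in the target-th distinct clone
    first_mask = np.zeros(len(reads), dtype=bool)
    _, idx = np.unique(reads, return_index=True)
    first_mask[idx] = True
    distinct_so_far = np.cumsum(first_mask)
    stop = int(np.searchsorted(distinct_so_far, spec.target_clonotypes, side="left"))
    prefix = reads[: stop + 1]
    new_counts = np.bincount(prefix, minlength=len(counts))
    kept = [
        replace(c, count=int(n))
        for c, n in zip(repertoire.clonotypes, new_counts)
        if n > 0
    ]
    return replace_clonotypes(repertoire, kept)


def _provenance(spec: DownsampleSpec) -> dict:
    return {
        "target_clonotypes": spec.target_clonotypes,
        "mode": spec.mode,
        "seed": spec.seed,
    }
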