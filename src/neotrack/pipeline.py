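"""End-to-end orchestration: ingest/simulate -> rarefy -> match -> correlate.

A run takes a directory of clonotype tables plus a sample metadata TSV
(or a simulation config), downsample every sample to a common clonotype
count, quantifies specificity-cluster frequencies, correlates them with
day-14 tumor volume per tissue, and writes every intermediate as TSV so
each stage can be audited and re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clusters import ClusterDB, load_builtin_cluster_db, read_cluster_db
from .io import read_clonotype_table
from .match import MatchIndex, SampleQuantification, quantify
from .preprocess import DownsampleSpec, downsample
from .repertoire import Repertoire
from .simulate import VACCINATED, Cohort, CohortConfig, simulate_cohort
from .stats import UNION, correlate_clusters, group_contrast

log = logging.getLogger("neotrack")


class StageError(RuntimeError):
    """Fatal pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path
    input_dir: str | Path | None = None          # cohort dir; None => simulate
    simulation: CohortConfig | None = None
    cluster_db: str | Path | None = None         # None => packaged p30 set
    dialect: str = "airr"
    downsample_spec: DownsampleSpec = field(default_factory=DownsampleSpec)
    max_distance: int = 1
    correlation_groups: tuple[str, ...] = VACCINATED
    correlation_tissues: tuple[str, ...] = ("tdLN", "cfa_plaque", "tumor")
    volume_range: tuple[float, float] | None = None
    bh_correct: bool = False
    min_clonotypes: int | None = None            # optional pre-filter, off
    seed: int = 0


@dataclass
class RunReport:
    out_dir: Path
    quantifications: list[SampleQuantification]
    correlations: pd.DataFrame
    contrasts: pd.DataFrame
    summary_text: str
    n_samples: int


def _load_cohort(config: RunConfig) -> tuple[list[Repertoire], pd.DataFrame, ClusterDB]:
    try:
        if config.cluster_db is not None:
            db = read_cluster_db(config.cluster_db)
        else:
            db = load_builtin_cluster_db()
    except (OSError, ValueError) as e:
        raise StageError("cluster_match", f"cannot load cluster database: {e}")

    if config.input_dir is not None:
        in_dir = Path(config.input_dir)
        meta_path = in_dir / "metadata.tsv"
        if not meta_path.exists():
            raise StageError("ingest", f"metadata table {meta_path} not found")
        meta = pd.read_csv(meta_path, sep="\t")
        reps = []
        for _, row in meta.iterrows():
            path = in_dir / "repertoires" / f"{row['sample_id']}.tsv"
            try:
                rep, _report = read_clonotype_table(
                    path, dialect=config.dialect, sample_id=str(row["sample_id"]))
            except (OSError, ValueError) as e:
                raise StageError("ingest", str(e))
            rep.mouse_id = str(row["mouse_id"])
            rep.tissue = str(row["tissue"])
            rep.subset = str(row.get("subset", "Th"))
            reps.append(rep)
        return reps, meta, db

    sim = config.simulation or CohortConfig(seed=config.seed)
    cohort: Cohort = simulate_cohort(sim, level="repertoire", seed=config.seed, db=db)
    return cohort.repertoires, cohort.sample_metadata(), db


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reps, meta, db = _load_cohort(config)
    if config.min_clonotypes:
        before = len(reps)
        reps = [r for r in reps if r.richness >= config.min_clonotypes]
        log.info("min-clonotype filter: %d -> %d samples", before, len(reps))
    if not reps:
        raise StageError("ingest", "no samples to process")

    # rarefaction — one derived seed per sample, deterministic in run seed
    downsampled = []
    for i, rep in enumerate(reps):
        spec = DownsampleSpec(
            target_clonotypes=config.downsample_spec.target_clonotypes,
            mode=config.downsample_spec.mode,
            seed=(config.seed * 100003 + i) % (2**31),
        )
        downsampled.append(downsample(rep, spec))

    index = MatchIndex(db, max_distance=config.max_distance)
    quants = [quantify(r, index, config.max_distance) for r in downsampled]

    wide = _quant_table(quants, db)
    wide.to_csv(out / "quantification.tsv", sep="\t")
    _match_table(quants).to_csv(out / "matches.tsv", sep="\t", index=False)

    vols_by_mouse = meta.drop_duplicates("mouse_id").set_index("mouse_id")[
        "volume_day14_mm3"]
    groups = meta.drop_duplicates("mouse_id").set_index("mouse_id")["group"]

    corr_rows = []
    for tissue in config.correlation_tissues:
        sel = [
            q for q in quants
            if q.tissue == tissue and groups.get(q.mouse_id) in config.correlation_groups
        ]
        if len(sel) < 3:
            continue
        volumes = {q.sample_id: float(vols_by_mouse[q.mouse_id]) for q in sel}
        for r in correlate_clusters(
            sel, volumes, volume_range=config.volume_range,
            bh_correct=config.bh_correct,
        ):
            corr_rows.append({
                "tissue": tissue, "cluster_id": r.cluster_id, "rho": r.rho,
                "p_two_sided": r.p_two_sided, "n": r.n,
                "significant": r.significant, "note": r.note,
            })
    correlations = pd.DataFrame(
        corr_rows, columns=["tissue", "cluster_id", "rho", "p_two_sided",
                            "n", "significant", "note"])
    correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)

    contrast_frames = []
    for tissue in config.correlation_tissues:
        sel = [q for q in quants if q.tissue == tissue]
        labels = {q.sample_id: groups[q.mouse_id] for q in sel}
        if len(set(labels.values())) >= 2:
            gdf = group_contrast(sel, labels)
            gdf.insert(0, "tissue", tissue)
            contrast_frames.append(gdf)
    contrasts = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames else pd.DataFrame()
    )
    contrasts.to_csv(out / "group_contrast.tsv", sep="\t", index=False)

    _write_provenance(config, out, n_samples=len(quants))
    summary = report(quants, correlations, contrasts, config)
    (out / "summary.txt").write_text(summary)

    return RunReport(
        out_dir=out, quantifications=quants, correlations=correlations,
        contrasts=contrasts, summary_text=summary, n_samples=len(quants),
    )


def _quant_table(quants: list[SampleQuantification], db: ClusterDB) -> pd.DataFrame:
    rows = {}
    for q in quants:
        row = {cid: q.per_cluster_frequency.get(cid, 0.0) for cid in db.cluster_ids}
        row[UNION] = q.union_frequency
        row["mouse_id"] = q.mouse_id
        row["tissue"] = q.tissue
        row["subset"] = q.subset
        rows[q.sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def _match_table(quants: list[SampleQuantification]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": q.sample_id, "cdr3_aa": m.clonotype_cdr3,
            "v_call": m.v_call, "j_call": m.j_call, "cluster_id": m.cluster_id,
            "distance": m.best_distance, "matched_member": m.matched_member,
            "frequency": m.frequency,
        }
        for q in quants for m in q.matches
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "cdr3_aa", "v_call", "j_call",
                       "cluster_id", "distance", "matched_member", "frequency"])


def _write_provenance(config: RunConfig, out: Path, n_samples: int) -> None:
    prov = {
        "neotrack_version": __version__,
        "seed": config.seed,
        "n_samples": n_samples,
        "downsample": {
            "target_clonotypes": config.downsample_spec.target_clonotypes,
            "mode": config.downsample_spec.mode,
        },
        "max_distance": config.max_distance,
        "cluster_db": str(config.cluster_db or "builtin:p30_synthetic"),
        "correlation_groups": list(config.correlation_groups),
        "volume_range": list(config.volume_range) if config.volume_range else None,
        "bh_correct": config.bh_correct,
        "input": str(config.input_dir) if config.input_dir else "simulated",
    }
    (out / "provenance.yaml").write_text(yaml.safe_dump(prov, sort_keys=False))


def report(
    quants: list[SampleQuantification],
    correlations: pd.DataFrame,
    contrasts: pd.DataFrame,
    config: RunConfig,
) -> str:
    """Plain-text run summary; regeneration from the same inputs is idempotent."""
    lines = [
        "neotrack run summary",
        "====================",
        f"samples quantified: {len(quants)}",
        f"rarefaction: {config.downsample_spec.mode} to "
        f"{config.downsample_spec.target_clonotypes} clonotypes",
        f"match radius: {config.max_distance} amino-acid edit(s), TRBV-agnostic",
        f"multiple-testing correction: "
        f"{'Benjamini-Hochberg' if config.bh_correct else 'none'}",
        "",
    ]
    if correlations.empty:
        lines.append("no testable clusters (fewer than 3 complete "
                     "frequency/volume pairs in every tissue)")
    else:
        lines.append("cluster frequency vs day-14 tumor volume (Spearman):")
        for _, r in correlations.iterrows():
            flag = " *significant*" if r["significant"] else ""
            rho = "nan" if pd.isna(r["rho"]) else f"{r['rho']:+.3f}"
            p = "nan" if pd.isna(r["p_two_sided"]) else f"{r['p_two_sided']:.4g}"
            lines.append(
                f"  {r['tissue']:<11}{r['cluster_id']:<8}rho={rho}  "
                f"p={p}  n={int(r['n'])}{flag}")
    if not contrasts.empty:
        lines.append("")
        lines.append("group medians (log10 fold vs reference group):")
        for _, r in contrasts.iterrows():
            lines.append(
                f"  {r['tissue']:<11}{r['group']:<15}{r['cluster_id']:<8}"
                f"median={r['median']:.3g}  "
                f"log10 fold={r['log10_fold_vs_ref']:+.2f}")
    return "\n".join(lines) + "\n"
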