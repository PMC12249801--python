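"""Synthetic cohort generator.

Emulates the statistical structure of a neoepitope-vaccination study on
a transplantable mouse tumor so every pipeline stage can be exercised
and calibrated without animal data:

* three treatment groups (adjuvant only, peptide vaccine, vaccine plus
  checkpoint blockade) with 10/9/21 mice;
* per mouse, bulk CD4 repertoires from the draining lymph node, the
  adjuvant plaque and the tumor, with power-law clone sizes and ~50x
  higher read depth in the lymph node than the plaque;
* antigen-specific clonotypes spiked in as cluster members or their
  one-mismatch variants, with group/tissue-dependent lognormal
  frequencies (vaccinated lymph nodes around a few percent summed mass,
  adjuvant-only several orders lower);
* exponential tumor growth with a bimodal (tolerant/susceptible) rate
  mixture, caliper measurements emitted as (a, b) pairs;
* a programmable rank coupling between a cluster's lymph-node frequency
  and the day-14 tumor volume, implemented through a Gaussian copula so
  the programmed value is the population Spearman correlation whatever
  the growth-model marginal looks like.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .clusters import ClusterDB, SpecificityCluster
from .distance import deletion_variants
from .io import write_clonotype_table
from .match import MatchIndex, distinct_distance1_variants
from .repertoire import (
    AA_ALPHABET,
    Clonotype,
    Repertoire,
    aggregate_clonotypes,
    recompute_frequencies,
)
from .stats import TumorMeasurement

GROUPS = ("adjuvant_only", "p30_PBS", "p30_aCTLA4")
DEFAULT_N_MICE = {"adjuvant_only": 10, "p30_PBS": 9, "p30_aCTLA4": 21}
VACCINATED = ("p30_PBS", "p30_aCTLA4")

_TRBV_POOL = [
    "TRBV1", "TRBV2", "TRBV3", "TRBV4", "TRBV5", "TRBV12-1", "TRBV12-2",
    "TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV14", "TRBV15", "TRBV16",
    "TRBV17", "TRBV19", "TRBV20", "TRBV23", "TRBV26", "TRBV29", "TRBV31",
]
_TRBJ_POOL = [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 6)]


# --------------------------------------------------------------------------
# configuration

@dataclass
class TumorGrowthParams:
    """Exponential growth V(t) = V0 * exp(g t) with lognormal rate noise.

    The per-mouse rate g (1/day) is drawn from a lognormal, optionally a
    two-component mixture reproducing the tolerant/susceptible split in
    individual growth curves. Calipers read the larger/smaller lateral
    dimensions with multiplicative noise; recorded volumes come back
    through V = a*b^2/2.
    """

    inoculum_volume: float = 2.0          # mm^3 at day 0
    rate_mean: float = 0.32               # median growth rate, 1/day
    rate_log_sd: float = 0.25
    bimodal: bool = True
    slow_fraction: float = 0.35           # share of tumor-tolerant... resistant mice
    slow_rate_factor: float = 0.5
    measure_days: tuple[int, ...] = (3, 5, 7, 10, 12, 14)
    caliper_noise_sd: float = 0.04        # multiplicative, on a and b
    aspect_ratio: float = 1.25            # a / b

    def rate_components(self) -> list[tuple[float, float, float]]:
        """(weight, mean of ln g, sd of ln g) per mixture component."""
        m = math.log(self.rate_mean)
        s = self.rate_log_sd
        if not self.bimodal or self.slow_fraction <= 0:
            return [(1.0, m, s)]
        return [
            (self.slow_fraction, m + math.log(self.slow_rate_factor), s),
            (1.0 - self.slow_fraction, m, s),
        ]


def default_specific_targets() -> dict:
    """(mean frequency, lognormal sigma) per group, tissue and cluster.

    Vaccinated lymph nodes carry ~3% total specific mass dominated by
    three clusters; adjuvant-only lymph nodes and plaques sit three
    orders of magnitude lower; tumors carry comparable specific mass in
    all groups but with higher dispersion.
    """
    vac_lymphoid = {
        "C14": (0.006, 1.0), "C25": (0.012, 1.3), "C26": (0.005, 1.0),
        "C22": (0.002, 1.0), "C3": (0.0008, 1.0), "C8": (0.0008, 1.0),
        "C11": (0.0008, 1.0), "C19": (0.0008, 1.0), "C30": (0.0008, 1.0),
    }
    vac_plaque = dict(vac_lymphoid)
    vac_plaque["C26"] = (0.0015, 1.0)  # lymph-node enriched cluster
    tumor = {
        "C14": (0.005, 1.5), "C25": (0.008, 1.5), "C26": (0.004, 1.5),
        "C22": (0.001, 1.5), "C3": (0.0004, 1.5), "C8": (0.0004, 1.5),
        "C11": (0.0004, 1.5), "C19": (0.0004, 1.5), "C30": (0.0004, 1.5),
    }
    adj_lymphoid = {c: (m * 1e-3, s) for c, (m, s) in vac_lymphoid.items()}
    adj_plaque = {c: (m * 1e-3, s) for c, (m, s) in vac_plaque.items()}
    targets = {
        "adjuvant_only": {"tdLN": adj_lymphoid, "cfa_plaque": adj_plaque,
                          "tumor": dict(tumor)},
    }
    for g in VACCINATED:
        targets[g] = {"tdLN": dict(vac_lymphoid), "cfa_plaque": dict(vac_plaque),
                      "tumor": dict(tumor)}
    return targets


@dataclass
class CohortConfig:
    """Knobs of the synthetic study; defaults reproduce the study layout."""

    n_mice: dict = field(default_factory=lambda: dict(DEFAULT_N_MICE))
    tissues: tuple[str, ...] = ("tdLN", "cfa_plaque", "tumor")
    richness: dict = field(default_factory=lambda: {
        "tdLN": 5000, "cfa_plaque": 2500, "tumor": 3000})
    reads: dict = field(default_factory=lambda: {
        "tdLN": 300_000, "cfa_plaque": 6_000, "tumor": 30_000})
    powerlaw_exponent: float = 2.0        # clone-size density exponent
    size_log_noise_sd: float = 0.5
    cdr3_len_mean: float = 14.5
    cdr3_len_sd: float = 1.3
    cdr3_len_range: tuple[int, int] = (10, 20)
    specific_targets: dict = field(default_factory=default_specific_targets)
    coupling: dict = field(default_factory=lambda: {"C14": -0.65})
    growth: TumorGrowthParams = field(default_factory=TumorGrowthParams)
    include_treg: bool = False
    treg_scale: float = 1.0 / 2.5
    max_cluster_frequency: float = 0.25
    max_specific_mass: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_mice.items():
            if n < 1:
                raise ValueError(f"n_mice[{g!r}] must be >= 1")
        for c, rho in self.coupling.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"coupling[{c!r}] must lie in [-1, 1]")


# --------------------------------------------------------------------------
# background repertoires

def _random_cdr3s(n: int, config: CohortConfig, rng: np.random.Generator,
                  forbidden_keys: frozenset[str] | None = None) -> list[str]:
    """n distinct random CDR3s with C...F anchors, Gaussian length law.

    ``forbidden_keys`` is a symmetric-deletion key set (members plus
    their single deletions); any candidate whose own deletion
    neighbourhood touches it is rejected, which over-rejects slightly
    (the screen admits some distance-2 pairs) but guarantees no
    accidental specificity matches.
    """
    letters = np.array(list(AA_ALPHABET))
    lo, hi = config.cdr3_len_range
    out: set[str] = set()
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 200:
            raise RuntimeError("CDR3 rejection sampling failed to converge")
        need = n - len(out)
        lens = np.clip(
            np.rint(rng.normal(config.cdr3_len_mean, config.cdr3_len_sd, need)),
            lo, hi,
        ).astype(int)
        for length in np.unique(lens):
            k = int(np.sum(lens == length))
            mat = letters[rng.integers(0, len(letters), size=(k, length - 2))]
            for row in mat:
                s = "C" + "".join(row) + "F"
                if s in out:
                    continue
                if forbidden_keys is not None:
                    if s in forbidden_keys or any(
                        v in forbidden_keys for v in deletion_variants(s)
                    ):
                        continue
                out.add(s)
                if len(out) == n:
                    break
            if len(out) == n:
                break
    return sorted(out)


def _clone_sizes(n: int, reads: int, config: CohortConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Integer clone sizes: power-law with lognormal noise, scaled to depth."""
    gamma = config.powerlaw_exponent
    u = rng.random(n)
    x = u ** (-1.0 / max(gamma - 1.0, 1e-6))
    x *= np.exp(rng.normal(0.0, config.size_log_noise_sd, n))
    x = np.minimum(x, 0.05 * reads)  # no single background clone above 5%
    x = x / x.sum() * reads
    return np.maximum(1, np.rint(x)).astype(np.int64)


def sample_background(
    config: CohortConfig,
    seed: int,
    tissue: str = "tdLN",
    sample_id: str = "background",
    avoid: MatchIndex | None = None,
) -> Repertoire:
    """One background repertoire with no antigen-specific clonotypes.

    Richness and read depth follow the per-tissue config; when ``avoid``
    is given, CDR3s within one edit of any cluster member are rejected.
    """
    rng = np.random.default_rng(seed)
    n = config.richness[tissue]
    reads = config.reads[tissue]
    forbidden = avoid.member_keys if avoid is not None else None
    cdr3s = _random_cdr3s(n, config, rng, forbidden)
    rng.shuffle(cdr3s)
    sizes = _clone_sizes(n, reads, config, rng)
    vs = rng.choice(_TRBV_POOL, n)
    js = rng.choice(_TRBJ_POOL, n)
    clons = [
        Clonotype(cdr3_aa=s, v_call=v, j_call=j, count=int(c))
        for s, v, j, c in zip(cdr3s, vs, js, sizes)
    ]
    rep = Repertoire(sample_id=sample_id, clonotypes=clons, tissue=tissue)
    return recompute_frequencies(rep)


# --------------------------------------------------------------------------
# specific spike-in

def make_cluster_variants(member_cdr3: str, k: int, seed: int) -> list[str]:
    """``k`` distinct CDR3s at edit distance exactly 1 from ``member_cdr3``.

    Each variant is a single substitution, insertion or deletion chosen
    uniformly from the exact distance-1 neighbourhood; raises if ``k``
    exceeds the neighbourhood size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    pool = sorted(distinct_distance1_variants(member_cdr3, AA_ALPHABET))
    if k > len(pool):
        raise ValueError(
            f"requested {k} variants but the distance-1 neighbourhood of "
            f"{member_cdr3!r} holds only {len(pool)} strings"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` into integer parts proportional to weights, each >=1."""
    m = len(weights)
    total = max(total, m)
    ideal = weights / weights.sum() * (total - m)
    base = np.floor(ideal).astype(np.int64)
    rem = total - m - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:rem]] += 1
    return base + 1


def spike_specific(
    repertoire: Repertoire,
    db: ClusterDB,
    targets: dict[str, float],
    seed: int,
) -> tuple[Repertoire, dict[str, float]]:
    """Add specific clonotypes so each targeted cluster sums near its target.

    For each cluster with a positive target, 1–10 clonotypes are added
    whose CDR3s are cluster members or their distance-1 variants; counts
    are chosen so the realised summed frequency lands within rounding
    error of the target (background renormalises implicitly). Returns
    the spiked repertoire and the realised per-cluster frequencies.
    """
    targets = {c: t for c, t in targets.items() if t > 0}
    if not targets:
        return repertoire, {}
    total_target = sum(targets.values())
    if total_target >= 0.5:
        raise ValueError(
            f"infeasible spike: total specific mass {total_target:.3f} >= 0.5"
        )
    rng = np.random.default_rng(seed)
    background = repertoire.total_count
    new_clons = list(repertoire.clonotypes)
    cluster_counts: dict[str, int] = {}
    for cid in sorted(targets):
        t = targets[cid]
        ideal = t / (1.0 - total_target) * background
        c_total = max(1, int(round(ideal)))
        cluster = db[cid]
        members = sorted(cluster.members)
        m = int(min(rng.integers(1, 11), c_total, 4 * len(members)))
        weights = rng.dirichlet(np.ones(m))
        counts = _apportion(c_total, weights)
        v_call = cluster.member_v_calls.get(members[0], "") or str(
            rng.choice(_TRBV_POOL))
        used: set[str] = set()
        for i in range(m):
            base = members[int(rng.integers(0, len(members)))]
            if rng.random() < 0.5:
                seq = base
            else:
                seq = make_cluster_variants(base, 1, int(rng.integers(2**31)))[0]
            if seq in used:
                seq = base
            used.add(seq)
            new_clons.append(
                Clonotype(cdr3_aa=seq, v_call=v_call,
                          j_call=str(rng.choice(_TRBJ_POOL)),
                          count=int(counts[i]))
            )
        cluster_counts[cid] = int(counts.sum())
    out = Repertoire(
        sample_id=repertoire.sample_id,
        clonotypes=aggregate_clonotypes(new_clons),
        mouse_id=repertoire.mouse_id,
        tissue=repertoire.tissue,
        subset=repertoire.subset,
        flags=dict(repertoire.flags),
    )
    out = recompute_frequencies(out)
    grand_total = out.total_count
    realized = {c: n / grand_total for c, n in cluster_counts.items()}
    return out, realized


def realized_frequencies(
    background_reads: int, targets: dict[str, float]
) -> dict[str, float]:
    """Frequencies the spike's count discretisation would realise.

    Mirrors the integer rounding in :func:`spike_specific` without
    materialising sequences; used by the fast cohort level.
    """
    targets = {c: t for c, t in targets.items() if t > 0}
    total_target = sum(targets.values())
    if not targets:
        return {}
    counts = {
        c: max(1, int(round(t / (1.0 - total_target) * background_reads)))
        for c, t in sorted(targets.items())
    }
    grand = background_reads + sum(counts.values())
    return {c: n / grand for c, n in counts.items()}


# --------------------------------------------------------------------------
# tumor growth

def _pearson_for_spearman(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter giving Spearman ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _rate_quantile(u: np.ndarray, params: TumorGrowthParams) -> np.ndarray:
    """Inverse CDF of the (possibly bimodal) lognormal growth-rate mixture."""
    comps = params.rate_components()
    if len(comps) == 1:
        _, m, s = comps[0]
        return np.exp(m + s * norm.ppf(u))
    lo = min(m for _, m, _ in comps) - 8 * max(s for *_, s in comps)
    hi = max(m for _, m, _ in comps) + 8 * max(s for *_, s in comps)

    def cdf(lng: float) -> float:
        return sum(w * norm.cdf((lng - m) / s) for w, m, s in comps)

    out = np.empty_like(u, dtype=float)
    for i, ui in np.ndenumerate(u):
        ui = min(max(ui, 1e-12), 1 - 1e-12)
        out[i] = math.exp(brentq(lambda g: cdf(g) - ui, lo, hi, xtol=1e-12))
    return out


def _measurements_from_rate(
    rate: float, params: TumorGrowthParams, rng: np.random.Generator
) -> list[TumorMeasurement]:
    out = []
    for day in params.measure_days:
        v = params.inoculum_volume * math.exp(rate * day)
        b = (2.0 * v / params.aspect_ratio) ** (1.0 / 3.0)
        a = params.aspect_ratio * b
        if params.caliper_noise_sd > 0:
            a *= math.exp(rng.normal(0.0, params.caliper_noise_sd))
            b *= math.exp(rng.normal(0.0, params.caliper_noise_sd))
        hi, lo_ = max(a, b), min(a, b)
        out.append(TumorMeasurement(day=day, a=hi, b=lo_))
    return out


def simulate_tumor(
    group: str,
    specific_frequency: float,
    coupling: float,
    params: TumorGrowthParams,
    seed: int,
    freq_log_mean: float = math.log(0.006),
    freq_log_sd: float = 1.0,
) -> list[TumorMeasurement]:
    """Growth curve for one mouse, rank-coupled to its specific frequency.

    The mouse's standardised log frequency z enters a Gaussian copula
    with Pearson parameter 2*sin(pi*coupling/6); the copula quantile is
    mapped through the growth-rate mixture, so across mice the Spearman
    correlation between frequency and day-14 volume equals ``coupling``
    (up to caliper noise). ``coupling`` 0 makes growth independent of
    frequency.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z = (math.log(max(specific_frequency, 1e-300)) - freq_log_mean) / freq_log_sd
    r = _pearson_for_spearman(coupling)
    latent = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * rng.normal()
    u = norm.cdf(latent)
    rate = float(_rate_quantile(np.array([u]), params)[0])
    return _measurements_from_rate(rate, params, rng)


# --------------------------------------------------------------------------
# cohort assembly

@dataclass
class MouseRecord:
    mouse_id: str
    group: str
    measurements: list[TumorMeasurement]

    @property
    def volume_day14(self) -> float:
        last = max(self.measurements, key=lambda m: m.day)
        return last.volume


@dataclass
class Cohort:
    """Simulated cohort: mice, repertoires (optional) and ground truth."""

    config: CohortConfig
    mice: list[MouseRecord]
    repertoires: list[Repertoire]
    ground_truth: pd.DataFrame  # mouse_id, tissue, cluster_id, target, realized
    db: ClusterDB

    @property
    def volumes(self) -> pd.Series:
        """Day-14 tumor volume (mm^3) per mouse id."""
        return pd.Series({m.mouse_id: m.volume_day14 for m in self.mice})

    @property
    def groups(self) -> dict[str, str]:
        return {m.mouse_id: m.group for m in self.mice}

    def sample_metadata(self) -> pd.DataFrame:
        vols = self.volumes
        groups = self.groups
        rows = [
            {
                "sample_id": r.sample_id,
                "mouse_id": r.mouse_id,
                "group": groups[r.mouse_id],
                "tissue": r.tissue,
                "subset": r.subset,
                "volume_day14_mm3": vols[r.mouse_id],
            }
            for r in self.repertoires
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, dialect: str = "airr") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep_dir = out / "repertoires"
        rep_dir.mkdir(exist_ok=True)
        for r in self.repertoires:
            write_clonotype_table(r, rep_dir / f"{r.sample_id}.tsv", dialect)
        self.sample_metadata().to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        meas = [
            {"mouse_id": m.mouse_id, "group": m.group, "day": t.day,
             "a_mm": t.a, "b_mm": t.b, "volume_mm3": t.volume}
            for m in self.mice for t in m.measurements
        ]
        pd.DataFrame(meas).to_csv(out / "measurements.tsv", sep="\t", index=False)


def _mouse_frequencies(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Per-tissue target frequencies for one mouse, plus the latent z's.

    One standard-normal latent per cluster is shared across tissues (the
    same expanded clones seed every compartment), so tissue profiles are
    correlated within a mouse, as they are in real cohorts.
    """
    tissue_targets = config.specific_targets[group]
    cluster_ids = sorted({c for t in tissue_targets.values() for c in t})
    z = {c: float(rng.normal()) for c in cluster_ids}
    out: dict[str, dict[str, float]] = {}
    for tissue in config.tissues:
        targets = {}
        per = tissue_targets.get(tissue, {})
        for c, (mean, sigma) in per.items():
            f = mean * math.exp(sigma * z[c] - sigma * sigma / 2.0)
            targets[c] = min(f, config.max_cluster_frequency)
        mass = sum(targets.values())
        if mass >= config.max_specific_mass:
            scale = (config.max_specific_mass * 0.98) / mass
            targets = {c: f * scale for c, f in targets.items()}
        out[tissue] = targets
    return out, z


def simulate_cohort(
    config: CohortConfig | None = None,
    level: str = "repertoire",
    seed: int | None = None,
    db: ClusterDB | None = None,
) -> Cohort:
    """Simulate a full cohort.

    ``level="repertoire"`` materialises background + spiked clonotype
    tables for every mouse and tissue. ``level="frequency"`` runs the
    identical frequency, count-discretisation and tumor-growth code but
    skips sequence materialisation — ground truth and volumes only, for
    large calibration sweeps.
    """
    if level not in ("repertoire", "frequency"):
        raise ValueError("level must be 'repertoire' or 'frequency'")
    config = config or CohortConfig()
    if db is None:
        from .clusters import load_builtin_cluster_db

        db = load_builtin_cluster_db()
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    index = MatchIndex(db, max_distance=1) if level == "repertoire" else None

    mice: list[MouseRecord] = []
    repertoires: list[Repertoire] = []
    truth_rows: list[dict] = []

    coupled = {c: r for c, r in config.coupling.items() if r != 0.0}
    r_coefs = {c: _pearson_for_spearman(r) for c, r in coupled.items()}
    resid = max(0.0, 1.0 - sum(v * v for v in r_coefs.values()))

    idx = 0
    for group in sorted(config.n_mice):
        for k in range(config.n_mice[group]):
            idx += 1
            mouse_id = f"m{idx:03d}_{group}"
            child = np.random.SeedSequence(entropy=root_seed,
                                           spawn_key=(idx,))
            rng = np.random.default_rng(child)
            targets_by_tissue, z = _mouse_frequencies(config, group, rng)

            latent = sum(r_coefs[c] * z[c] for c in r_coefs) + \
                math.sqrt(resid) * rng.normal()
            u = norm.cdf(latent)
            rate = float(_rate_quantile(np.array([u]), config.growth)[0])
            measurements = _measurements_from_rate(rate, config.growth, rng)
            mice.append(MouseRecord(mouse_id=mouse_id, group=group,
                                    measurements=measurements))

            for tissue in config.tissues:
                targets = targets_by_tissue[tissue]
                sample_id = f"{mouse_id}_{tissue}"
                if level == "repertoire":
                    bg = sample_background(
                        config, seed=int(rng.integers(2**31)), tissue=tissue,
                        sample_id=sample_id, avoid=index)
                    bg.mouse_id = mouse_id
                    rep, realized = spike_specific(
                        bg, db, targets, seed=int(rng.integers(2**31)))
                    repertoires.append(rep)
                else:
                    realized = realized_frequencies(
                        config.reads[tissue], targets)
                for c in sorted(targets):
                    truth_rows.append({
                        "mouse_id": mouse_id, "group": group, "tissue": tissue,
                        "cluster_id": c, "target_frequency": targets[c],
                        "realized_frequency": realized.get(c, 0.0),
                    })

    truth = pd.DataFrame(truth_rows)
    return Cohort(config=config, mice=mice, repertoires=repertoires,
                  ground_truth=truth, db=db)


# --------------------------------------------------------------------------
# synthetic cluster database

_DB_SIZES = {
    "C3": 6, "C8": 5, "C11": 9, "C14": 24, "C19": 7,
    "C22": 12, "C25": 30, "C26": 18, "C30": 4,
}
_DB_SEED_SEQUENCES = {
    # printed public C14/C22 homologues anchor those two clusters
    "C14": ["CASSFGRQNTLYF", "CASSFGSQNTLYF"],
    "C22": ["CGARGTGNTGQLYF"],
}
_DB_V_CALLS = {
    "C3": "TRBV5", "C8": "TRBV2", "C11": "TRBV16", "C14": "TRBV13-1",
    "C19": "TRBV12-2", "C22": "TRBV31", "C25": "TRBV13-3", "C26": "TRBV19",
    "C30": "TRBV4",
}


def build_synthetic_cluster_db(seed: int = 20240516) -> ClusterDB:
    """Build the packaged nine-cluster synthetic p30 database.

    Each cluster is a connected set of equal-length CDR3s related by
    single substitutions (one TRBV per cluster), sized 4–30 members.
    Deterministic; regenerating with the default seed reproduces the
    packaged TSV exactly.
    """
    rng = np.random.default_rng(seed)
    letters = list(AA_ALPHABET)
    clusters = []
    for cid in sorted(_DB_SIZES, key=lambda c: int(c[1:])):
        size = _DB_SIZES[cid]
        seeds = _DB_SEED_SEQUENCES.get(cid)
        if seeds is None:
            length = int(rng.integers(12, 16))
            core = "".join(rng.choice(letters, length - 2))
            seeds = ["C" + core + "F"]
        members = set(seeds)
        guard = 0
        while len(members) < size:
            guard += 1
            if guard > 10_000:
                raise RuntimeError("cluster growth stalled")
            base = sorted(members)[int(rng.integers(0, len(members)))]
            pos = int(rng.integers(1, len(base) - 1))
            sub = letters[int(rng.integers(0, len(letters)))]
            cand = base[:pos] + sub + base[pos + 1:]
            if cand != base:
                members.add(cand)
        clusters.append(
            SpecificityCluster(
                cluster_id=cid, antigen="p30", members=frozenset(members),
                member_v_calls={m: _DB_V_CALLS[cid] for m in members},
            )
        )
    return ClusterDB(clusters=clusters, source="synthetic")


def write_cluster_db(db: ClusterDB, path: str | Path) -> None:
    """Write a cluster database in the default TSV column layout."""
    rows = [
        {"cdr3": m, "v.segm": c.member_v_calls.get(m, ""),
         "antigen.epitope": c.antigen, "cluster.id": c.cluster_id}
        for c in db.clusters for m in sorted(c.members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# re-exported for callers composing custom spikes
__all__ = [
    "CohortConfig", "TumorGrowthParams", "Cohort", "MouseRecord",
    "sample_background", "make_cluster_variants", "spike_specific",
    "realized_frequencies", "simulate_tumor", "simulate_cohort",
    "build_synthetic_cluster_db", "write_cluster_db",
    "default_specific_targets", "GROUPS", "VACCINATED",
]
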