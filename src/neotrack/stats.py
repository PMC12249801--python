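"""Tumor burden statistics: volume formula, rank correlation, contrasts.

The study design correlates, across mice, the summed frequency of each
specificity cluster in a tissue with the caliper-derived tumor volume at
day 14, using nonparametric Spearman correlation with two-sided p
values; a cluster is called significant when p < 0.05. Group contrasts
(vaccinated vs adjuvant-only) are descriptive — medians and fold
differences on a floored log scale — with no attached test.

The correlation stage is exposed statsmodels-style: build a
:class:`ClusterTumorBurdenModel` from per-sample quantifications and a
volume table, call :meth:`~ClusterTumorBurdenModel.fit`, and read the
per-cluster estimates off the returned
:class:`ClusterTumorBurdenResults` (or print ``summary()``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .match import SampleQuantification

UNION = "union"

#: sample-size threshold at or below which the exact permutation null is used
EXACT_PERMUTATION_MAX_N = 9


def tumor_volume(a: float, b: float) -> float:
    """Ellipsoid-style caliper volume V = a*b^2/2 in mm^3.

    ``a`` and ``b`` are the larger and smaller lateral dimensions in mm;
    if given in the wrong order they are swapped with a warning (the
    formula is not symmetric, so order matters).
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"tumor dimensions must be positive, got a={a}, b={b}")
    if b > a:
        warnings.warn(
            f"tumor dimensions swapped: a={a} < b={b}; using a={b}, b={a}",
            stacklevel=2,
        )
        a, b = b, a
    return a * b * b / 2.0


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper reading: day, larger (a) and smaller (b) lateral mm."""

    day: int
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b > self.a:
            raise ValueError(f"expected a >= b, got a={self.a}, b={self.b}")
        if self.b <= 0:
            raise ValueError("dimensions must be positive")

    @property
    def volume(self) -> float:
        """Caliper volume a*b^2/2 in mm^3."""
        return tumor_volume(self.a, self.b)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact" | "t-approx" | "degenerate"


def spearman(x, y, *, exact_max_n: int = EXACT_PERMUTATION_MAX_N) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p value.

    Ranks use midranks for ties. For n <= ``exact_max_n`` the p value is
    the exact two-sided permutation probability (share of the n!
    permutations of one margin whose |rho| reaches the observed |rho|);
    for larger n the usual t approximation with n-2 degrees of freedom
    is used. Constant input yields a degenerate result with NaN rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=math.nan, p_value=math.nan, n=n, method="degenerate")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    if n <= exact_max_n:
        p = _exact_permutation_p(rx, ry, rho)
        return SpearmanResult(rho=rho, p_value=p, n=n, method="exact")

    if abs(rho) == 1.0:
        p = float(np.nextafter(0, 1))
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=min(p, 1.0), n=n, method="t-approx")


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p, conditioning on observed midranks."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    mx, my = rx.mean(), ry.mean()
    sx = math.sqrt(np.sum((rx - mx) ** 2))
    sy = math.sqrt(np.sum((ry - my) ** 2))
    rhos = (perms - my) @ (rx - mx) / (sx * sy)
    hits = np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12)
    return float(hits / len(perms))


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of one cluster's frequency with tumor volume."""

    cluster_id: str
    rho: float
    p_two_sided: float
    n: int
    significant: bool
    note: str = ""


class ClusterTumorBurdenModel:
    """Rank-correlation model of cluster frequencies against tumor burden.

    Parameters
    ----------
    frequencies : DataFrame
        samples x clusters table of summed specific frequencies; a
        ``union`` column is treated as one more quantity to test.
    volumes : Series
        day-14 tumor volume (mm^3) indexed by sample id; samples missing
        from either table are excluded pairwise, per cluster.
    """

    def __init__(self, frequencies: pd.DataFrame, volumes: pd.Series) -> None:
        self.frequencies = frequencies.astype(float)
        self.volumes = volumes.astype(float).dropna()
        self.cluster_ids = list(frequencies.columns)

    @classmethod
    def from_quantifications(
        cls,
        quantifications: list[SampleQuantification],
        volumes: dict[str, float] | pd.Series,
    ) -> "ClusterTumorBurdenModel":
        rows = {}
        for q in quantifications:
            row = dict(q.per_cluster_frequency)
            row[UNION] = q.union_frequency
            rows[q.sample_id] = row
        freq = pd.DataFrame.from_dict(rows, orient="index")
        return cls(freq, pd.Series(volumes))

    def fit(
        self,
        alpha: float = 0.05,
        volume_range: tuple[float, float] | None = None,
        bh_correct: bool = False,
    ) -> "ClusterTumorBurdenResults":
        """Correlate every cluster (and the union) with tumor volume.

        ``volume_range`` optionally restricts the fit to tumors within
        (min, max] mm^3, e.g. ``(0, 200)`` for the small-tumor sub-range.
        ``bh_correct`` applies Benjamini–Hochberg across clusters before
        the significance call (off by default; the primary analysis
        tests nine clusters uncorrected).
        """
        vols = self.volumes
        if volume_range is not None:
            lo, hi = volume_range
            vols = vols[(vols > lo) & (vols <= hi)]
        results: list[CorrelationResult] = []
        pvals: list[float] = []
        for cid in self.cluster_ids:
            col = self.frequencies[cid].dropna()
            common = col.index.intersection(vols.index)
            x = col.loc[common].to_numpy()
            y = vols.loc[common].to_numpy()
            n = len(common)
            if n < 3:
                results.append(
                    CorrelationResult(cid, math.nan, math.nan, n, False,
                                      note="fewer than 3 complete pairs"))
                pvals.append(math.nan)
                continue
            r = spearman(x, y)
            if r.method == "degenerate":
                results.append(
                    CorrelationResult(cid, math.nan, math.nan, n, False,
                                      note="constant vector"))
                pvals.append(math.nan)
                continue
            results.append(
                CorrelationResult(cid, r.rho, r.p_value, n, r.p_value < alpha,
                                  note=r.method))
            pvals.append(r.p_value)

        if bh_correct:
            adj = _benjamini_hochberg(pvals)
            results = [
                CorrelationResult(r.cluster_id, r.rho, p_adj, r.n,
                                  (not math.isnan(p_adj)) and p_adj < alpha,
                                  note=(r.note + ";BH").strip(";"))
                for r, p_adj in zip(results, adj)
            ]
        return ClusterTumorBurdenResults(
            model=self, results=results, alpha=alpha,
            volume_range=volume_range, bh_corrected=bh_correct,
        )


def _benjamini_hochberg(pvals: list[float]) -> list[float]:
    ps = np.array(pvals, dtype=float)
    ok = ~np.isnan(ps)
    adj = np.full_like(ps, np.nan)
    p = ps[ok]
    m = len(p)
    if m:
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[ok] = out
    return adj.tolist()


@dataclass
class ClusterTumorBurdenResults:
    """Per-cluster correlation estimates with a text summary."""

    model: ClusterTumorBurdenModel
    results: list[CorrelationResult]
    alpha: float = 0.05
    volume_range: tuple[float, float] | None = None
    bh_corrected: bool = False

    def __iter__(self):
        return iter(self.results)

    @property
    def significant(self) -> list[CorrelationResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": r.cluster_id,
                    "rho": r.rho,
                    "p_two_sided": r.p_two_sided,
                    "n": r.n,
                    "significant": r.significant,
                    "note": r.note,
                }
                for r in self.results
            ]
        ).set_index("cluster_id")

    def summary(self) -> str:
        lines = [
            "Cluster frequency vs tumor volume — Spearman rank correlation",
            f"significance rule: two-sided p < {self.alpha:g}"
            + (", Benjamini-Hochberg adjusted" if self.bh_corrected else
               " (no multiple-testing correction)"),
        ]
        if self.volume_range is not None:
            lines.append(f"volume range filter: {self.volume_range} mm^3")
        lines.append("")
        lines.append(f"{'cluster':<10}{'rho':>8}{'p':>12}{'n':>5}  flag")
        for r in self.results:
            rho = "nan" if math.isnan(r.rho) else f"{r.rho:.3f}"
            p = "nan" if math.isnan(r.p_two_sided) else f"{r.p_two_sided:.4g}"
            flag = "*" if r.significant else (r.note if math.isnan(r.rho) else "")
            lines.append(f"{r.cluster_id:<10}{rho:>8}{p:>12}{r.n:>5}  {flag}")
        return "\n".join(lines)

    def plot(self, cluster_id: str, ax=None, floor: float = 1e-5):
        """Scatter of one cluster's frequency (log, floored) vs volume."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        col = self.model.frequencies[cluster_id].dropna()
        common = col.index.intersection(self.model.volumes.index)
        ax.scatter(self.model.volumes.loc[common],
                   np.maximum(col.loc[common], floor))
        ax.set_yscale("log")
        ax.set_xlabel("tumor volume, mm$^3$")
        ax.set_ylabel(f"{cluster_id} summed frequency")
        return ax


def correlate_clusters(
    quantifications: list[SampleQuantification],
    volumes: dict[str, float] | pd.Series,
    cluster_ids: list[str] | None = None,
    alpha: float = 0.05,
    volume_range: tuple[float, float] | None = None,
    bh_correct: bool = False,
) -> list[CorrelationResult]:
    """Functional wrapper over :class:`ClusterTumorBurdenModel`.

    One :class:`CorrelationResult` per cluster plus one for the union.
    """
    model = ClusterTumorBurdenModel.from_quantifications(quantifications, volumes)
    if cluster_ids is not None:
        keep = [c for c in cluster_ids if c in model.frequencies.columns]
        model.cluster_ids = keep + ([UNION] if UNION in model.frequencies else [])
    res = model.fit(alpha=alpha, volume_range=volume_range, bh_correct=bh_correct)
    return res.results


def group_contrast(
    quantifications: list[SampleQuantification],
    groups: dict[str, str],
    reference: str | None = None,
    floor: float = 1e-5,
) -> pd.DataFrame:
    """Descriptive per-cluster group summary: median, IQR, log10 fold.

    ``groups`` maps sample_id -> group label. The fold difference of
    medians is taken on a floored log10 scale (zeros clamped to
    ``floor``) against the ``reference`` group (default: first label in
    sorted order). No hypothesis test is attached.
    """
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("group_contrast needs at least 2 groups")
    reference = reference or labels[0]
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not among {labels}")

    rows = {}
    for q in quantifications:
        row = dict(q.per_cluster_frequency)
        row[UNION] = q.union_frequency
        rows[q.sample_id] = row
    freq = pd.DataFrame.from_dict(rows, orient="index")
    freq["__group"] = pd.Series(groups).reindex(freq.index)
    if freq["__group"].isna().any():
        missing = freq.index[freq["__group"].isna()].tolist()
        raise ValueError(f"samples without a group label: {missing[:5]}")
    for g in labels:
        if not (freq["__group"] == g).any():
            raise ValueError(f"group {g!r} has no samples")

    out = []
    clusters = [c for c in freq.columns if c != "__group"]
    med = freq.groupby("__group")[clusters].median()
    q1 = freq.groupby("__group")[clusters].quantile(0.25)
    q3 = freq.groupby("__group")[clusters].quantile(0.75)
    ref_logmed = np.log10(np.maximum(med.loc[reference], floor))
    for g in labels:
        for c in clusters:
            out.append(
                {
                    "group": g,
                    "cluster_id": c,
                    "median": med.loc[g, c],
                    "iqr_low": q1.loc[g, c],
                    "iqr_high": q3.loc[g, c],
                    "log10_fold_vs_ref": float(
                        np.log10(max(med.loc[g, c], floor)) - ref_logmed[c]
                    ),
                    "reference": reference,
                }
            )
    return pd.DataFrame(out)
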