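"""Tumor volume, Spearman correlation (exact and approximate), contrasts."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from neotrack.match import SampleQuantification
from neotrack.stats import (
    ClusterTumorBurdenModel,
    TumorMeasurement,
    correlate_clusters,
    group_contrast,
    spearman,
    tumor_volume,
)


def exact_permutation_p(x, y) -> float:
    """Brute-force two-sided permutation p for Spearman rho (oracle)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    perms = list(itertools.permutations(ry))
    for p in perms:
        if abs(np.corrcoef(rx, np.array(p))[0, 1]) >= obs - 1e-12:
            hits += 1
    return hits / len(perms)


# --- tumor volume ----------------------------------------------------------

def test_volume_formula_direct():
    assert tumor_volume(10, 6) == pytest.approx(180.0)


def test_volume_sphere_like_case():
    b = 7.3
    assert tumor_volume(b, b) == pytest.approx(b**3 / 2)


def test_volume_swaps_misordered_arguments():
    with pytest.warns(UserWarning, match="swapped"):
        assert tumor_volume(6, 10) == pytest.approx(180.0)


def test_volume_rejects_nonpositive():
    for a, b in [(0, 1), (5, -2)]:
        with pytest.raises(ValueError):
            tumor_volume(a, b)


def test_volume_cubic_scaling():
    assert tumor_volume(12, 8) == pytest.approx(8 * tumor_volume(6, 4))


def test_measurement_requires_ordered_dimensions():
    m = TumorMeasurement(day=14, a=10, b=6)
    assert m.volume == pytest.approx(180.0)
    with pytest.raises(ValueError):
        TumorMeasurement(day=14, a=6, b=10)


# --- spearman --------------------------------------------------------------

def test_perfect_antitone():
    r = spearman([1, 2, 3], [3, 2, 1])
    assert r.rho == pytest.approx(-1.0)


def test_hand_rank_case_n4():
    r = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert r.rho == pytest.approx(0.8)
    assert r.p_value == pytest.approx(exact_permutation_p([1, 2, 3, 4],
                                                          [1, 3, 2, 4]))


def test_exact_p_for_antitone_n4():
    # all 24 permutations of 4 ranks: only the two monotone ones reach |rho|=1
    r = spearman([1, 2, 3, 4], [9, 7, 5, 3])
    assert r.method == "exact"
    assert r.p_value == pytest.approx(2 / 24)


def test_exact_branch_matches_enumeration_oracle(rng):
    for n in (3, 4, 5, 6, 7):
        for _ in range(8):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties
                x[: n // 2] = x[0]
            r = spearman(x, y)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(exact_permutation_p(x, y))


def test_large_n_matches_scipy_t_approximation(rng):
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    r = spearman(x, y)
    ref_rho, ref_p = sps.spearmanr(x, y)
    assert r.rho == pytest.approx(ref_rho)
    assert r.p_value == pytest.approx(ref_p, rel=1e-6)


def test_self_correlation_identities(rng):
    x = rng.permutation(20).astype(float)
    assert spearman(x, x).rho == pytest.approx(1.0)
    assert spearman(x, -x).rho == pytest.approx(-1.0)


def test_constant_vector_flagged():
    r = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
    assert r.method == "degenerate"
    assert math.isnan(r.rho)


# --- model / correlate_clusters -------------------------------------------

def _quant(sample_id, freqs, union=None, **meta):
    return SampleQuantification(
        sample_id=sample_id, per_cluster_frequency=freqs,
        union_frequency=union if union is not None else sum(freqs.values()),
        **meta)


def test_programmed_antitone_sign_recovered(rng):
    quants, volumes = [], {}
    for i in range(20):
        f = float(np.exp(rng.normal(-4, 1)))
        quants.append(_quant(f"s{i}", {"C14": f, "C25": 0.001}))
        volumes[f"s{i}"] = 500.0 / (1 + 50 * f) * float(np.exp(rng.normal(0, 0.1)))
    res = correlate_clusters(quants, volumes)
    by_id = {r.cluster_id: r for r in res}
    assert by_id["C14"].rho < -0.5
    assert by_id["C14"].significant
    assert by_id["C25"].note == "constant vector"
    assert {r.cluster_id for r in res} == {"C14", "C25", "union"}


def test_null_volumes_rarely_significant(rng):
    fp = 0
    trials = 120
    for _ in range(trials):
        quants = [_quant(f"s{i}", {"A": float(np.exp(rng.normal(-4, 1)))})
                  for i in range(60)]
        volumes = {f"s{i}": float(rng.lognormal(5, 0.6)) for i in range(60)}
        res = {r.cluster_id: r for r in correlate_clusters(quants, volumes)}
        fp += res["A"].significant
    assert fp / trials < 0.12  # two-sided 5% test; generous sampling margin


def test_pairwise_deletion_counts_complete_pairs():
    quants = [_quant(f"s{i}", {"A": 0.01 * (i + 1)}) for i in range(6)]
    volumes = {"s0": 10.0, "s1": 20.0, "s2": 15.0, "s3": 40.0}  # 2 missing
    res = {r.cluster_id: r for r in correlate_clusters(quants, volumes)}
    assert res["A"].n == 4


def test_too_few_pairs_flagged_not_fatal():
    quants = [_quant(f"s{i}", {"A": 0.01}) for i in range(2)]
    res = correlate_clusters(quants, {"s0": 1.0, "s1": 2.0})
    assert all("fewer than 3" in r.note for r in res)


def test_volume_range_filter_restricts_fit():
    quants = [_quant(f"s{i}", {"A": float(i)}) for i in range(10)]
    volumes = {f"s{i}": 50.0 * (i + 1) for i in range(10)}  # 50..500
    model = ClusterTumorBurdenModel.from_quantifications(quants, volumes)
    full = model.fit()
    small = model.fit(volume_range=(0, 200))
    assert {r.n for r in full.results} == {10}
    assert {r.n for r in small.results} == {4}


def test_bh_correction_is_monotone_and_flagged():
    quants, volumes = [], {}
    rng = np.random.default_rng(5)
    for i in range(30):
        f = float(np.exp(rng.normal(-4, 1)))
        quants.append(_quant(f"s{i}", {"A": f, "B": float(rng.random())}))
        volumes[f"s{i}"] = 400 / (1 + 100 * f)
    model = ClusterTumorBurdenModel.from_quantifications(quants, volumes)
    raw = {r.cluster_id: r for r in model.fit().results}
    adj = {r.cluster_id: r for r in model.fit(bh_correct=True).results}
    for cid in raw:
        assert adj[cid].p_two_sided >= raw[cid].p_two_sided - 1e-12
        assert "BH" in adj[cid].note


def test_results_summary_mentions_rule():
    quants = [_quant(f"s{i}", {"A": 0.01 * i}) for i in range(5)]
    model = ClusterTumorBurdenModel.from_quantifications(
        quants, {f"s{i}": float(i + 1) for i in range(5)})
    text = model.fit().summary()
    assert "p < 0.05" in text
    assert "A" in text


# --- group contrast --------------------------------------------------------

def test_group_contrast_log_fold():
    quants = (
        [_quant(f"v{i}", {"A": 0.03}, mouse_id=f"v{i}") for i in range(5)]
        + [_quant(f"a{i}", {"A": 1e-5}, mouse_id=f"a{i}") for i in range(5)]
    )
    groups = {f"v{i}": "vaccinated" for i in range(5)}
    groups.update({f"a{i}": "adjuvant" for i in range(5)})
    df = group_contrast(quants, groups, reference="adjuvant")
    row = df[(df.group == "vaccinated") & (df.cluster_id == "A")].iloc[0]
    assert row["log10_fold_vs_ref"] == pytest.approx(
        math.log10(0.03) - math.log10(1e-5), abs=1e-9)


def test_group_contrast_identical_groups_zero_fold():
    quants = [_quant(f"s{i}", {"A": 0.02}) for i in range(6)]
    groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
    df = group_contrast(quants, groups)
    assert df["log10_fold_vs_ref"].abs().max() == pytest.approx(0.0)


def test_group_contrast_empty_group_is_error():
    quants = [_quant("s0", {"A": 0.02})]
    with pytest.raises(ValueError):
        group_contrast(quants, {"s0": "only_group"})
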