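"""Synthetic cohort generator: spike-in fidelity, growth, determinism."""

import math

import numpy as np
import pytest

from neotrack.match import quantify
from neotrack.simulate import (
    CohortConfig,
    TumorGrowthParams,
    build_synthetic_cluster_db,
    make_cluster_variants,
    realized_frequencies,
    sample_background,
    simulate_cohort,
    simulate_tumor,
    spike_specific,
)
from neotrack.stats import spearman

from conftest import wagner_fischer


def small_config(**kw) -> CohortConfig:
    defaults = dict(
        n_mice={"adjuvant_only": 2, "p30_PBS": 2, "p30_aCTLA4": 2},
        richness={"tdLN": 400, "cfa_plaque": 200, "tumor": 250},
        reads={"tdLN": 20_000, "cfa_plaque": 400, "tumor": 2_000},
        seed=3,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


# --- background ------------------------------------------------------------

def test_background_contract(builtin_db):
    cfg = small_config()
    rep = sample_background(cfg, seed=5, tissue="tdLN")
    assert rep.richness == 400
    assert abs(sum(c.frequency for c in rep) - 1.0) < 1e-9
    assert len({c.cdr3_aa for c in rep}) == 400


def test_background_determinism():
    cfg = small_config()
    a = sample_background(cfg, seed=9)
    b = sample_background(cfg, seed=9)
    c = sample_background(cfg, seed=10)
    key = lambda r: [(x.cdr3_aa, x.count) for x in r]
    assert key(a) == key(b)
    assert key(a) != key(c)


def test_background_avoids_cluster_members(builtin_db):
    from neotrack.match import MatchIndex

    cfg = small_config()
    index = MatchIndex(builtin_db, max_distance=1)
    rep = sample_background(cfg, seed=2, avoid=index)
    assert all(not index.query(c.cdr3_aa) for c in rep)


def test_powerlaw_head_dominates():
    cfg = small_config(richness={"tdLN": 2000, "cfa_plaque": 200, "tumor": 250},
                       reads={"tdLN": 60_000, "cfa_plaque": 400, "tumor": 2_000})
    rep = sample_background(cfg, seed=4, tissue="tdLN")
    counts = np.sort([c.count for c in rep])[::-1]
    top10 = counts[:10].sum()
    deciles = [counts[i:i + 200].sum() for i in range(200, 1800, 200)]
    assert all(top10 > d for d in deciles)


# --- variants --------------------------------------------------------------

def test_variants_at_distance_one_by_oracle():
    out = make_cluster_variants("CASSF", k=3, seed=1)
    assert len(set(out)) == 3
    for v in out:
        assert v != "CASSF"
        assert wagner_fischer(v, "CASSF") == 1


def test_variant_request_beyond_neighbourhood_errors():
    with pytest.raises(ValueError, match="neighbourhood"):
        make_cluster_variants("CA", k=500, seed=0)


# --- spike-in --------------------------------------------------------------

def test_spike_recovered_by_quantifier(builtin_db):
    from neotrack.match import MatchIndex

    cfg = small_config()
    index = MatchIndex(builtin_db, max_distance=1)
    bg = sample_background(cfg, seed=11, avoid=index)
    rep, realized = spike_specific(bg, builtin_db, {"C25": 0.10}, seed=12)
    q = quantify(rep, index, max_distance=1)
    assert 0.09 <= q.per_cluster_frequency["C25"] <= 0.11
    assert q.per_cluster_frequency["C25"] == pytest.approx(realized["C25"])


def test_spike_multiple_targets_independent(builtin_db):
    from neotrack.match import MatchIndex

    cfg = small_config()
    index = MatchIndex(builtin_db, max_distance=1)
    bg = sample_background(cfg, seed=21, avoid=index)
    targets = {"C14": 0.02, "C25": 0.10}
    rep, _ = spike_specific(bg, builtin_db, targets, seed=22)
    q = quantify(rep, index, max_distance=1)
    for cid, t in targets.items():
        assert abs(q.per_cluster_frequency[cid] - t) / t < 0.1


def test_spike_zero_target_noop(builtin_db):
    cfg = small_config()
    bg = sample_background(cfg, seed=31)
    rep, realized = spike_specific(bg, builtin_db, {"C14": 0.0}, seed=32)
    assert realized == {}
    assert [(c.cdr3_aa, c.count) for c in rep] == \
        [(c.cdr3_aa, c.count) for c in bg]


def test_spike_infeasible_mass_errors(builtin_db):
    bg = sample_background(small_config(), seed=41)
    with pytest.raises(ValueError, match="infeasible"):
        spike_specific(bg, builtin_db, {"C14": 0.3, "C25": 0.3}, seed=42)


def test_realized_frequencies_mirror_spike_arithmetic():
    out = realized_frequencies(10_000, {"C14": 0.02, "C25": 0.1})
    assert out["C25"] == pytest.approx(0.1, rel=0.01)
    assert out["C14"] == pytest.approx(0.02, rel=0.01)


# --- tumor growth ----------------------------------------------------------

def test_tumor_volume_nondecreasing_without_noise():
    params = TumorGrowthParams(caliper_noise_sd=0.0)
    meas = simulate_tumor("p30_PBS", 0.01, coupling=-0.65, params=params, seed=5)
    vols = [m.volume for m in meas]
    assert vols == sorted(vols)
    assert [m.day for m in meas] == list(params.measure_days)


def test_tumor_coupling_zero_is_null():
    params = TumorGrowthParams(caliper_noise_sd=0.0, bimodal=False)
    rng = np.random.default_rng(0)
    freqs = np.exp(rng.normal(math.log(0.006), 1.0, size=200))
    vols = [simulate_tumor("g", f, 0.0, params, seed=i)[-1].volume
            for i, f in enumerate(freqs)]
    r = spearman(freqs, vols)
    assert abs(r.rho) < 0.15
    assert r.p_value > 0.01


def test_tumor_coupling_negative_recovered_across_mice():
    params = TumorGrowthParams(caliper_noise_sd=0.0)
    rng = np.random.default_rng(1)
    freqs = np.exp(rng.normal(math.log(0.006), 1.0, size=300))
    vols = [simulate_tumor("g", f, -0.65, params, seed=1000 + i)[-1].volume
            for i, f in enumerate(freqs)]
    r = spearman(freqs, vols)
    assert -0.8 < r.rho < -0.5


def test_tumor_determinism():
    params = TumorGrowthParams()
    a = simulate_tumor("g", 0.01, -0.5, params, seed=7)
    b = simulate_tumor("g", 0.01, -0.5, params, seed=7)
    assert [(m.a, m.b) for m in a] == [(m.a, m.b) for m in b]


# --- cohort ----------------------------------------------------------------

def test_default_layout_matches_study_design():
    cfg = CohortConfig()
    assert cfg.n_mice == {"adjuvant_only": 10, "p30_PBS": 9, "p30_aCTLA4": 21}
    assert sum(cfg.n_mice.values()) == 40
    assert cfg.tissues == ("tdLN", "cfa_plaque", "tumor")
    assert cfg.reads["tdLN"] == 50 * cfg.reads["cfa_plaque"]
    assert cfg.coupling == {"C14": -0.65}


def test_cohort_structure_and_files(tmp_path):
    cohort = simulate_cohort(small_config(), level="repertoire", seed=8)
    assert len(cohort.mice) == 6
    assert len(cohort.repertoires) == 18  # 6 mice x 3 tissues
    cohort.write(tmp_path / "cohort")
    reps = sorted((tmp_path / "cohort" / "repertoires").glob("*.tsv"))
    assert len(reps) == 18
    assert (tmp_path / "cohort" / "metadata.tsv").exists()
    assert (tmp_path / "cohort" / "ground_truth.tsv").exists()
    meta = cohort.sample_metadata()
    assert set(meta["tissue"]) == {"tdLN", "cfa_plaque", "tumor"}


def test_adjuvant_only_orders_of_magnitude_lower():
    cohort = simulate_cohort(small_config(), level="frequency", seed=13)
    gt = cohort.ground_truth
    sel = gt[(gt.tissue == "tdLN")]
    vac = sel[sel.group != "adjuvant_only"].groupby("cluster_id")[
        "target_frequency"].mean()
    adj = sel[sel.group == "adjuvant_only"].groupby("cluster_id")[
        "target_frequency"].mean()
    ratio = (vac / adj).dropna()
    assert (ratio > 100).all()  # programmed three orders, allow dispersion


def test_cohort_byte_identical_given_seed(tmp_path):
    for d in ("a", "b"):
        simulate_cohort(small_config(), level="repertoire", seed=17).write(
            tmp_path / d)
    for name in ["metadata.tsv", "ground_truth.tsv", "measurements.tsv"]:
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()
    a_reps = sorted((tmp_path / "a" / "repertoires").glob("*.tsv"))
    b_reps = sorted((tmp_path / "b" / "repertoires").glob("*.tsv"))
    assert [p.name for p in a_reps] == [p.name for p in b_reps]
    for pa, pb in zip(a_reps, b_reps):
        assert pa.read_bytes() == pb.read_bytes()


def test_frequency_level_skips_repertoires():
    cohort = simulate_cohort(small_config(), level="frequency", seed=19)
    assert cohort.repertoires == []
    assert not cohort.ground_truth.empty
    assert len(cohort.volumes) == 6
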