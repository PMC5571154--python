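import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immigratio import (
    ArgumentError,
    InvariantError,
    SimConfig,
    evaluate_recovery,
    make_dataset,
    sample_reads,
    simulate_digester_profile,
    simulate_stream_profiles,
)
from immigratio.immigration import RatioTable
from immigratio.synthetic import SimTruth
from immigratio.tables_io import write_count_table

from conftest import SMALL_SIM


def _small_cfg(**kw):
    return dataclasses.replace(SMALL_SIM, **kw)


# ---------- stream profiles ----------------------------------------------

def test_stream_profiles_deterministic_under_seed():
    a1, b1 = simulate_stream_profiles(_small_cfg())
    a2, b2 = simulate_stream_profiles(_small_cfg())
    pd.testing.assert_series_equal(a1, a2)
    pd.testing.assert_series_equal(b1, b2)
    a3, _ = simulate_stream_profiles(_small_cfg(seed=99))
    assert not a1.equals(a3)


def test_stream_profiles_partial_overlap_and_normalization():
    prim, surp = simulate_stream_profiles(_small_cfg())
    assert prim.sum() == pytest.approx(1.0) and surp.sum() == pytest.approx(1.0)
    in_prim, in_surp = prim > 0, surp > 0
    assert (in_prim & in_surp).any()      # shared members
    assert (in_prim & ~in_surp).any()     # stream-specific members
    assert (~in_prim & ~in_surp).any()    # OTUs absent from both streams


def test_stream_profiles_sigma_zero_limit_is_uniform():
    prim, _ = simulate_stream_profiles(_small_cfg(lognormal_sigma=1e-12))
    nz = prim[prim > 0]
    assert nz.max() / nz.min() == pytest.approx(1.0, abs=1e-6)


def test_stream_rank_abundance_matches_lognormal_quantiles():
    cfg = SimConfig(n_otus=2000, seed=4)
    prim, _ = simulate_stream_profiles(cfg)
    logvals = np.log(np.sort(prim[prim > 0].to_numpy()))
    theo = stats.norm.ppf((np.arange(len(logvals)) + 0.5) / len(logvals),
                          scale=cfg.lognormal_sigma)
    r = np.corrcoef(logvals, theo)[0, 1]
    assert r > 0.995


def test_stream_profiles_reject_tiny_universe():
    with pytest.raises(ArgumentError):
        SimConfig(n_otus=5)


# ---------- digester profiles --------------------------------------------

def test_pure_immigration_with_full_survival_conserves_composition():
    cfg = _small_cfg(grower_fraction=0.0, survival_range=(1.0, 1.0))
    streams = simulate_stream_profiles(cfg)
    comp, truth = simulate_digester_profile(streams, cfg)
    feed = (streams[0] + streams[1]) / 2
    member = feed > 0
    assert np.allclose(truth.loc[member.to_numpy(), "expected_ratio"], 1.0)
    pd.testing.assert_series_equal(comp, feed, check_names=False)


def test_immigrant_expected_ratio_equals_survival_exactly():
    cfg = _small_cfg()
    streams = simulate_stream_profiles(cfg)
    _, truth = simulate_digester_profile(streams, cfg)
    feed = (streams[0] + streams[1]) / 2
    immigrants = (~truth.is_grower) & (feed > 0)
    assert np.allclose(truth.loc[immigrants.to_numpy(), "expected_ratio"],
                       truth.loc[immigrants.to_numpy(), "survival"], atol=1e-12)
    assert (truth.loc[immigrants.to_numpy(), "expected_ratio"] <= 1.0).all()


def test_grower_absent_from_streams_has_infinite_expected_ratio():
    cfg = _small_cfg()
    streams = simulate_stream_profiles(cfg)
    _, truth = simulate_digester_profile(streams, cfg)
    feed = (streams[0] + streams[1]) / 2
    orphan_growers = truth.is_grower & (feed == 0) & (truth.digester_fraction > 0)
    assert orphan_growers.any()
    assert np.isinf(truth.loc[orphan_growers.to_numpy(), "expected_ratio"]).all()
    reg = truth.loc[orphan_growers.to_numpy(), "expected_ratio_reg"]
    assert np.isfinite(reg).all() and (reg > 0).all()


def test_expected_ratio_vector_matches_direct_recomputation():
    cfg = _small_cfg(n_otus=100)
    streams = simulate_stream_profiles(cfg)
    comp, truth = simulate_digester_profile(streams, cfg)
    feed = ((streams[0] + streams[1]) / 2).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        expect = np.where(feed > 0, comp.to_numpy() / feed,
                          np.where(comp.to_numpy() > 0, np.inf, 0.0))
    assert np.array_equal(truth.expected_ratio.to_numpy(), expect)


def test_thp_mode_requires_growers():
    cfg = _small_cfg(grower_fraction=0.0)
    streams = simulate_stream_profiles(cfg)
    with pytest.raises(InvariantError):
        simulate_digester_profile(streams, cfg, mode="thp")


# ---------- read sampling -------------------------------------------------

def test_sample_reads_column_sums_equal_depth():
    cfg = _small_cfg()
    comp, _ = simulate_digester_profile(simulate_stream_profiles(cfg), cfg)
    block = sample_reads(comp, cfg, 15)
    assert (block.sum(axis=0) == cfg.depth).all()
    assert block.shape == (cfg.n_otus, 15)


def test_sample_reads_concentrated_limit_recovers_truth():
    cfg = _small_cfg(n_otus=50, depth=1_000_000,
                     dirichlet_concentration=1_000_000.0)
    comp, _ = simulate_digester_profile(simulate_stream_profiles(cfg), cfg)
    block = sample_reads(comp, cfg, 1)
    frac = block.iloc[:, 0] / cfg.depth
    assert np.abs(frac - comp).max() < 1e-2


def test_sample_reads_mean_counts_match_multinomial_moments():
    cfg = _small_cfg(n_otus=12, depth=500)
    rng = np.random.default_rng(8)
    comp = pd.Series(rng.dirichlet(np.ones(12) * 3),
                     index=[f"OTU_{i}" for i in range(12)])
    n_rep = 5000
    block = sample_reads(comp, cfg, n_rep, rng=np.random.default_rng(21))
    means = block.mean(axis=1)
    # empirical SE of the replicate mean (covers the Dirichlet overdispersion)
    se = block.std(axis=1, ddof=1) / np.sqrt(n_rep)
    assert (np.abs(means - cfg.depth * comp) < 3.5 * se).all()


# ---------- make_dataset / evaluate_recovery ------------------------------

def test_make_dataset_shapes_and_groups(small_sim):
    ds, truth = small_sim
    cfg = SMALL_SIM
    n_samples = (cfg.primary_samples + cfg.surplus_samples
                 + 3 * cfg.digester_samples_per_group)
    assert ds.counts.counts.shape == (cfg.n_otus, n_samples)
    assert set(truth.groups) == {"mesophilic", "thermophilic", "thp"}
    assert set(ds.samples.process_type) == {"na", "mesophilic", "thermophilic", "thp"}
    assert (ds.counts.counts.sum(axis=0) == cfg.depth).all()


def test_make_dataset_same_seed_reproduces_identical_tsv(tmp_path, small_sim):
    ds1, _ = small_sim
    ds2, _ = make_dataset(SMALL_SIM)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_count_table(ds1.counts, p1)
    write_count_table(ds2.counts, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_seed_sweep_gives_distinct_valid_datasets():
    seen = set()
    for seed in range(5):
        ds, _ = make_dataset(_small_cfg(seed=seed, n_otus=60,
                                        digester_samples_per_group=4,
                                        primary_samples=3, surplus_samples=3,
                                        depth=500))
        seen.add(ds.counts.counts.to_numpy().tobytes())
    assert len(seen) == 5


def test_thp_digesters_share_almost_no_mass_with_immigrant_otus(small_sim):
    _, truth = small_sim
    thp = truth.groups["thp"]
    feed = (truth.stream_primary + truth.stream_surplus) / 2
    immigrant_otus = (~thp.is_grower) & (feed > 0)
    assert thp.loc[immigrant_otus.to_numpy(), "digester_fraction"].sum() < 0.01


def _truth_for(otus, is_grower):
    df = pd.DataFrame({
        "is_grower": is_grower,
        "survival": 0.0, "grower_mass": 0.0,
        "digester_fraction": np.linspace(0.1, 0.2, len(otus)),
        "expected_ratio": np.where(is_grower, 100.0, 0.5),
        "expected_ratio_reg": np.where(is_grower, 100.0, 0.5),
    }, index=pd.Index(otus, name="otu_id"))
    return SimTruth(stream_primary=pd.Series(dtype=float),
                    stream_surplus=pd.Series(dtype=float),
                    groups={"mesophilic": df})


def _classified_table(otus, classes, group="mesophilic"):
    frame = pd.DataFrame(
        {"mean_primary": 0.0, "mean_surplus": 0.0, "mean_influent": 0.0,
         "mean_digester": 0.1, "ratio": 1.0, "weight": 0.1,
         "growth_class": classes}, index=pd.Index(otus, name="otu_id"))
    return RatioTable(frame=frame, group=group)


def test_evaluate_recovery_perfect_classification():
    otus = [f"o{i}" for i in range(10)]
    grower = np.arange(10) < 4
    truth = _truth_for(otus, grower)
    classes = ["growing" if g else "non_growing" for g in grower]
    fixed = type("S", (), {"bimodal": False, "split": 10.0})()
    metrics = evaluate_recovery(_classified_table(otus, classes), truth, split=fixed)
    assert metrics["balanced_accuracy"] == 1.0
    assert metrics["confusion"].loc["grower", "growing"] == 4


def test_evaluate_recovery_random_labels_score_half():
    rng = np.random.default_rng(0)
    otus = [f"o{i}" for i in range(40)]
    grower = np.arange(40) < 20
    truth = _truth_for(otus, grower)
    fixed = type("S", (), {"bimodal": False, "split": 10.0})()
    accs = []
    for _ in range(100):
        classes = rng.permutation(
            ["growing"] * 20 + ["non_growing"] * 20).tolist()
        accs.append(evaluate_recovery(_classified_table(otus, classes), truth,
                                      split=fixed)["balanced_accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.05


def test_evaluate_recovery_rejects_unknown_otus():
    truth = _truth_for(["o0"], np.array([True]))
    table = _classified_table(["o0", "alien"], ["growing", "growing"])
    with pytest.raises(InvariantError, match="alien"):
        evaluate_recovery(table, truth, split=type("S", (), {"bimodal": False})())
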