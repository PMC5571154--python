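import numpy as np
import pandas as pd
import pytest

from immigratio import (
    ArgumentError,
    EmptyResultError,
    InvariantError,
    abundant_core,
    classify_growth,
    compute_ratios,
    core_growth_summary,
    detect_split,
    to_relative,
    weighted_ratio_distribution,
)
from immigratio.immigration import RatioTable


@pytest.fixture
def toy_ratios(toy_counts, toy_meta):
    return compute_ratios(to_relative(toy_counts), toy_meta, "mesophilic",
                          pseudo=5e-5)


# ---------- compute_ratios ------------------------------------------------

def test_compute_ratios_frozen_examples(toy_ratios):
    f = toy_ratios.frame
    # 0.05 digester vs (0.004 + 0.006)/2 influent -> ratio 10
    assert f.loc["OTU_A", "mean_influent"] == pytest.approx(0.005)
    assert f.loc["OTU_A", "ratio"] == pytest.approx(10.0)
    # absent from influent: denominator is the pseudo-abundance 5e-5
    assert f.loc["OTU_B", "ratio"] == pytest.approx(0.01 / 5e-5)  # = 200
    # absent from digesters: ratio and weight are 0
    assert f.loc["OTU_C", "ratio"] == 0.0
    assert f.loc["OTU_C", "weight"] == 0.0
    assert (f.weight == f.mean_digester).all()


def test_compute_ratios_matches_spreadsheet_oracle(small_sim):
    ds, _ = small_sim
    at = to_relative(ds.counts)
    rt = compute_ratios(at, ds.samples, "mesophilic", pseudo=5e-5)
    meta = ds.samples
    dig = meta.loc[(meta.sample_type == "digester")
                   & (meta.process_type == "mesophilic"), "sample_id"]
    prim = meta.loc[meta.sample_type == "primary", "sample_id"]
    surp = meta.loc[meta.sample_type == "surplus", "sample_id"]
    a = at.abund
    expect_dig = a[list(dig)].mean(axis=1)
    expect_inf = (a[list(prim)].mean(axis=1) + a[list(surp)].mean(axis=1)) / 2
    expect_ratio = expect_dig / np.maximum(expect_inf, 5e-5)
    assert np.allclose(rt.frame.mean_digester, expect_dig, atol=1e-15)
    assert np.allclose(rt.frame.ratio, expect_ratio, atol=1e-12)


def test_compute_ratios_pooled_influent(toy_counts, toy_meta):
    rt = compute_ratios(to_relative(toy_counts), toy_meta, "mesophilic",
                        influent_combine="pooled")
    # equal primary/surplus sample counts: pooled mean = mean over 4 samples
    assert rt.frame.loc["OTU_A", "mean_influent"] == pytest.approx(
        (0.004 + 0.004 + 0.006 + 0.006) / 4)


def test_compute_ratios_errors(toy_counts, toy_meta):
    at = to_relative(toy_counts)
    with pytest.raises(EmptyResultError, match="thermophilic"):
        compute_ratios(at, toy_meta, "thermophilic")
    with pytest.raises(ArgumentError):
        compute_ratios(at, toy_meta, "mesophilic", pseudo=0.0)
    with pytest.raises(ArgumentError):
        compute_ratios(at, toy_meta, "lagoon")


def test_ratio_label_permutation_equivariance(toy_counts, toy_meta):
    at = to_relative(toy_counts)
    base = compute_ratios(at, toy_meta, "mesophilic").frame.ratio
    perm = ["OTU_C", "OTU_A", "OTU_D", "OTU_B"]
    permuted_at = type(at)(at.abund.loc[perm], at.depth, at.domain, at.normalized)
    out = compute_ratios(permuted_at, toy_meta, "mesophilic").frame.ratio
    assert np.allclose(out.loc[base.index], base)


def test_ratio_invariant_to_replicated_digester_samples(toy_counts, toy_meta):
    at = to_relative(toy_counts)
    base = compute_ratios(at, toy_meta, "mesophilic").frame.ratio
    # triplicate D1/D2 columns with identical compositions
    reps = pd.concat([at.abund] + [at.abund[["D1", "D2"]].add_suffix(f"_{i}")
                                   for i in (1, 2)], axis=1)
    meta = pd.concat(
        [toy_meta]
        + [toy_meta[toy_meta.sample_id.isin(["D1", "D2"])].assign(
            sample_id=lambda d: d.sample_id + f"_{i}") for i in (1, 2)],
        ignore_index=True)
    rep_at = type(at)(reps, at.depth, at.domain, False)
    out = compute_ratios(rep_at, meta, "mesophilic").frame.ratio
    assert np.allclose(out.loc[base.index], base)


# ---------- weighted_ratio_distribution ----------------------------------

def _ratio_table(ratios, weights, group="mesophilic"):
    idx = [f"o{i}" for i in range(len(ratios))]
    frame = pd.DataFrame(
        {"mean_primary": 0.0, "mean_surplus": 0.0, "mean_influent": 0.0,
         "mean_digester": weights, "ratio": ratios, "weight": weights,
         "growth_class": ""}, index=idx)
    return RatioTable(frame=frame, group=group)


def test_weighted_hist_single_otu_and_two_otu_masses():
    single = weighted_ratio_distribution(_ratio_table([5.0], [0.2]), n_bins=10)
    assert single.mass.sum() == pytest.approx(1.0)
    assert (single.mass > 0).sum() == 1
    two = weighted_ratio_distribution(_ratio_table([0.5, 100.0], [0.03, 0.01]),
                                      n_bins=20)
    nonzero = np.sort(two.mass[two.mass > 0])[::-1]
    assert nonzero == pytest.approx([0.75, 0.25])


def test_weighted_hist_matches_brute_force_binning():
    rng = np.random.default_rng(17)
    ratios = 10 ** rng.uniform(-2, 3, size=1000)
    weights = rng.dirichlet(np.ones(1000))
    hist = weighted_ratio_distribution(_ratio_table(ratios, weights), n_bins=40)
    logr = np.log10(ratios)
    brute = np.zeros(len(hist.mass))
    for lr, w in zip(logr, weights):
        # right-inclusive last bin, matching numpy's histogram convention
        j = np.searchsorted(hist.bin_edges, lr, side="right") - 1
        j = min(j, len(brute) - 1)
        brute[j] += w
    brute /= brute.sum()
    assert np.allclose(hist.mass, brute, atol=1e-12)
    assert hist.bin_edges[0] <= logr.min() and hist.bin_edges[-1] >= logr.max()


def test_weighted_hist_ignores_zero_weight_otus():
    base = weighted_ratio_distribution(_ratio_table([0.5, 100.0], [0.03, 0.01]))
    padded = weighted_ratio_distribution(
        _ratio_table([0.5, 100.0, 7.0], [0.03, 0.01, 0.0]))
    assert np.allclose(base.mass, padded.mass)
    with pytest.raises(EmptyResultError):
        weighted_ratio_distribution(_ratio_table([1.0], [0.0]))


# ---------- detect_split --------------------------------------------------

def _bimodal_table(seed, n=400, immigrant_ratio=0.7, grower_ratio=150.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    logr = np.concatenate([
        rng.normal(np.log10(immigrant_ratio), 0.25, size=half),
        rng.normal(np.log10(grower_ratio), 0.35, size=n - half),
    ])
    weights = rng.dirichlet(np.ones(n) * 5)
    # equal mass in the two modes
    weights[:half] *= 0.5 / weights[:half].sum()
    weights[half:] *= 0.5 / weights[half:].sum()
    return _ratio_table(10.0**logr, weights)


@pytest.mark.parametrize("seed", range(20))
def test_split_recovered_between_modes(seed):
    rt = _bimodal_table(seed)
    res = detect_split(rt, seed=seed)
    assert res.bimodal
    assert 2.0 <= res.split <= 30.0


def test_split_crossing_agrees_with_grid_oracle():
    from immigratio._mixture import WeightedGMM2

    rt = _bimodal_table(1)
    logr = np.log10(rt.frame.ratio.to_numpy())
    gmm = WeightedGMM2(random_state=1).fit(logr, rt.frame.weight.to_numpy())
    analytic = gmm.equal_posterior_point()
    grid = gmm.grid_split()
    assert analytic == pytest.approx(grid, abs=1e-3)


def test_split_unimodal_falls_back_with_warning(caplog):
    rng = np.random.default_rng(3)
    ratios = 10 ** rng.normal(1.6, 0.25, size=300)  # single mode above 10
    rt = _ratio_table(ratios, rng.dirichlet(np.ones(300)))
    with caplog.at_level("WARNING", logger="immigratio"):
        res = detect_split(rt, seed=0)
    assert not res.bimodal
    assert res.fallback_used and res.split == 10.0
    assert res.mode_ratio > 10.0
    assert any("falling back" in r.message for r in caplog.records)


def test_split_fixed_method_and_input_guards():
    rt = _bimodal_table(2)
    assert detect_split(rt, method="fixed", fixed_value=10.0).split == 10.0
    tiny = _ratio_table([0.5, 100.0], [0.03, 0.01])
    with pytest.raises(ArgumentError, match="10 OTUs"):
        detect_split(tiny)
    same = _ratio_table([5.0] * 12, [1.0 / 12] * 12)
    with pytest.raises(ArgumentError, match="distinct"):
        detect_split(same)


# ---------- classify_growth / core_growth_summary -------------------------

def test_classify_growth_thresholds_inclusive_at_one():
    rt = _ratio_table([200.0, 1.0, 5.0, 10.0, 0.2], [0.1] * 5)
    out = classify_growth(rt).frame.growth_class.tolist()
    assert out == ["growing", "non_growing", "intermediate", "intermediate",
                   "non_growing"]
    with pytest.raises(ArgumentError):
        classify_growth(rt, grow_threshold=1.0, die_threshold=1.0)


def test_core_growth_summary_counts_and_percentages():
    rt = classify_growth(_ratio_table([200.0, 50.0, 0.5, 12.0],
                                      [0.4, 0.3, 0.2, 0.1]))
    from immigratio.structure import CoreResult

    core = CoreResult(ranked_otus=["o0", "o1", "o2", "o3"],
                      mean_abund=np.array([0.4, 0.3, 0.2, 0.1]),
                      cum_frac=np.array([0.4, 0.7, 0.9, 1.0]),
                      core_size=4, threshold=1.0)
    summ = core_growth_summary(core, rt)
    assert summ.loc["growing", "n_otus"] == 3
    assert summ.loc["non_growing", "n_otus"] == 1
    assert summ.loc["growing", "pct_of_core"] == pytest.approx(75.0)
    assert summ.loc["non_growing", "core_read_mass_frac"] == pytest.approx(0.2)


def test_core_growth_summary_requires_matching_scope():
    rt = classify_growth(_ratio_table([5.0, 2.0], [0.5, 0.5]))
    from immigratio.structure import CoreResult

    core = CoreResult(ranked_otus=["o0", "ghost"], mean_abund=np.array([0.5, 0.5]),
                      cum_frac=np.array([0.5, 1.0]), core_size=2, threshold=1.0)
    with pytest.raises(InvariantError, match="ghost"):
        core_growth_summary(core, rt)


def test_core_tally_matches_brute_force_on_synthetic_core(default_run):
    manifest = default_run["_manifest"]
    rt = manifest["ratio_tables"]["mesophilic"]
    core = manifest["core"]
    summ = core_growth_summary(core, rt)
    top = core.ranked_otus[: core.core_size]
    brute = rt.frame.loc[top, "growth_class"].value_counts()
    for cls in ("growing", "non_growing", "intermediate"):
        assert summ.loc[cls, "n_otus"] == int(brute.get(cls, 0))
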