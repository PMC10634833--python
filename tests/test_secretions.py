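"""Metabolomics peak filtering, gating, profiles and by-product similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commassembly import (
    AnalysisError,
    PeakTable,
    build_profiles,
    byproduct_correlation,
    cluster_substrates,
    filter_control_peaks,
    growth_gate,
    simulate_peak_table,
    targeted_similarity,
)
from commassembly.secretions import cut_clusters
from commassembly.synth import GeneratorConfig


def _table(heights: dict, meta: dict) -> PeakTable:
    h = pd.DataFrame(heights).T  # rows metabolites
    m = pd.DataFrame(meta).T
    return PeakTable(heights=h[list(m.index)], meta=m)


@pytest.fixture
def tiny_table():
    heights = {
        "m1": {"s1": 100.0, "s2": 50.0, "ctrl": 0.0},
        "m2": {"s1": 200.0, "s2": 100.0, "ctrl": 50.0},  # control-contaminated
        "m3": {"s1": 0.0, "s2": 80.0, "ctrl": 1.0},      # 1.25% of max -> kept
    }
    meta = {
        "s1": {"strain": "k", "carbon_source": "glc", "replicate": 1,
               "is_control": False, "od": 0.5},
        "s2": {"strain": "k", "carbon_source": "ace", "replicate": 1,
               "is_control": False, "od": 0.5},
        "ctrl": {"strain": "k", "carbon_source": "none", "replicate": 1,
                 "is_control": True, "od": 0.01},
    }
    return _table(heights, meta)


def test_control_filter_relative_rule(tiny_table):
    filtered, removed = filter_control_peaks(tiny_table)
    assert removed == ["m2"]
    assert list(filtered.heights.index) == ["m1", "m3"]


def test_control_filter_zero_fraction_boundary(tiny_table):
    _, removed = filter_control_peaks(tiny_table, fraction=0.0)
    assert set(removed) == {"m2", "m3"}  # any nonzero control signal


def test_control_filter_requires_controls(tiny_table):
    no_ctrl = tiny_table.subset_samples(["s1", "s2"])
    with pytest.raises(AnalysisError):
        filter_control_peaks(no_ctrl)


def test_paper_scale_fixture_retains_55():
    pt = simulate_peak_table(GeneratorConfig(seed=0, n_substrates=16))
    assert pt.heights.shape[0] == 69
    filtered, removed = filter_control_peaks(pt)
    assert len(removed) == 14
    assert filtered.heights.shape[0] == 55


@settings(max_examples=25, deadline=None)
@given(
    f1=st.floats(0.0, 1.0),
    f2=st.floats(0.0, 1.0),
    seed=st.integers(0, 10_000),
)
def test_control_filter_monotone_in_threshold(f1, f2, seed):
    rng = np.random.default_rng(seed)
    n_met, n_s = 12, 5
    heights = rng.uniform(0, 100, (n_met, n_s))
    cols = [f"s{i}" for i in range(n_s - 1)] + ["ctrl"]
    h = pd.DataFrame(heights, index=[f"m{i}" for i in range(n_met)], columns=cols)
    meta = pd.DataFrame(
        {
            "strain": "k",
            "carbon_source": [f"c{i}" for i in range(n_s - 1)] + ["none"],
            "replicate": 1,
            "is_control": [False] * (n_s - 1) + [True],
            "od": 0.5,
        },
        index=cols,
    )
    pt = PeakTable(heights=h, meta=meta)
    lo, hi = sorted((f1, f2))
    kept_hi, _ = filter_control_peaks(pt, fraction=hi)
    kept_lo, _ = filter_control_peaks(pt, fraction=lo)
    assert set(kept_lo.heights.index) <= set(kept_hi.heights.index)


def test_growth_gate_all_replicate_rule():
    heights = {"m1": {"a1": 1.0, "a2": 1.0, "a3": 1.0, "b1": 1.0, "ctrl": 0.0}}
    meta = {
        "a1": {"strain": "k", "carbon_source": "glc", "replicate": 1,
               "is_control": False, "od": 0.5},
        "a2": {"strain": "k", "carbon_source": "glc", "replicate": 2,
               "is_control": False, "od": 0.5},
        "a3": {"strain": "k", "carbon_source": "glc", "replicate": 3,
               "is_control": False, "od": 0.03},  # one failed replicate
        "b1": {"strain": "k", "carbon_source": "ace", "replicate": 1,
               "is_control": False, "od": 0.5},
        "ctrl": {"strain": "k", "carbon_source": "none", "replicate": 1,
                 "is_control": True, "od": 0.01},
    }
    gated = growth_gate(_table(heights, meta))
    sources = set(gated.meta["carbon_source"])
    assert sources == {"ace", "none"}  # glc dropped entirely, control kept
    unchanged = growth_gate(_table(heights, meta), od_threshold=0.0)
    assert set(unchanged.meta.index) == set(meta)


def test_build_profiles_replicate_mean_then_zscore():
    heights = {
        "m1": {"g1": 10.0, "g2": 12.0, "g3": 14.0, "a1": 20.0, "a2": 20.0,
               "a3": 20.0, "f1": 30.0, "f2": 30.0, "f3": 36.0, "ctrl": 0.0},
    }
    meta = {}
    for i, s in enumerate(["g1", "g2", "g3", "a1", "a2", "a3", "f1", "f2", "f3"]):
        src = {"g": "glc", "a": "ace", "f": "fru"}[s[0]]
        meta[s] = {"strain": "k", "carbon_source": src, "replicate": i % 3 + 1,
                   "is_control": False, "od": 0.5}
    meta["ctrl"] = {"strain": "k", "carbon_source": "none", "replicate": 1,
                    "is_control": True, "od": 0.01}
    prof = build_profiles(_table(heights, meta))
    # replicate means (12, 20, 96/3=32) -> z-scores over (12, 20, 32)
    row = prof.profiles.loc["m1"]
    vals = np.array([row["glc"], row["ace"], row["fru"]])
    expected = (np.array([12.0, 20.0, 32.0]) - 64 / 3) / np.std([12, 20, 32], ddof=1)
    assert vals == pytest.approx(expected)
    assert abs(row.mean()) < 1e-12


def test_build_profiles_constant_metabolite_flagged():
    heights = {"m1": {"s1": 5.0, "s2": 5.0, "ctrl": 0.0}}
    meta = {
        "s1": {"strain": "k", "carbon_source": "glc", "replicate": 1,
               "is_control": False, "od": 0.5},
        "s2": {"strain": "k", "carbon_source": "ace", "replicate": 1,
               "is_control": False, "od": 0.5},
        "ctrl": {"strain": "k", "carbon_source": "none", "replicate": 1,
                 "is_control": True, "od": 0.01},
    }
    prof = build_profiles(_table(heights, meta))
    assert prof.flagged_constant == ["m1"]
    assert (prof.profiles.loc["m1"] == 0).all()


def test_byproduct_correlation_extremes():
    profiles = pd.DataFrame(
        {"glc": [1.0, -0.5, 0.2], "fru": [1.0, -0.5, 0.2], "ace": [-1.0, 0.5, -0.2]},
        index=["m1", "m2", "m3"],
    )
    from commassembly.secretions import SecretionProfileMatrix

    corr = byproduct_correlation(SecretionProfileMatrix(profiles, "zscore_across_sources"))
    assert corr.loc["glc", "fru"] == pytest.approx(1.0)
    assert corr.loc["glc", "ace"] == pytest.approx(-1.0)
    assert np.allclose(corr.values, corr.values.T)


def test_block_structure_separates_correlations():
    cfg = GeneratorConfig(seed=4, n_substrates=12)
    pt = simulate_peak_table(cfg)
    filtered, _ = filter_control_peaks(pt)
    prof = build_profiles(growth_gate(filtered))
    corr = byproduct_correlation(prof)
    subs = sorted(corr.columns)
    block = {s: (0 if i < 6 else 1) for i, s in enumerate(subs)}
    within, between = [], []
    for i, a in enumerate(subs):
        for b in subs[i + 1:]:
            (within if block[a] == block[b] else between).append(corr.loc[a, b])
    assert np.mean(within) - np.mean(between) > 0.3


def test_cluster_recovers_planted_blocks():
    cfg = GeneratorConfig(seed=9, n_substrates=10)
    pt = simulate_peak_table(cfg)
    filtered, _ = filter_control_peaks(pt)
    corr = byproduct_correlation(build_profiles(growth_gate(filtered)))
    linkage, order = cluster_substrates(corr)
    assignment = cut_clusters(linkage, list(corr.columns), k=2)
    subs = sorted(corr.columns)
    planted = {s: (0 if i < 5 else 1) for i, s in enumerate(subs)}
    groups = {}
    for s, c in assignment.items():
        groups.setdefault(c, set()).add(planted[s])
    assert all(len(v) == 1 for v in groups.values())


def test_cluster_identical_pair_merges_first():
    corr = pd.DataFrame(
        [[1.0, 1.0, -0.8], [1.0, 1.0, -0.8], [-0.8, -0.8, 1.0]],
        index=list("abc"), columns=list("abc"),
    )
    linkage, order = cluster_substrates(corr)
    assert linkage[0, 2] == pytest.approx(0.0)  # first merge at distance 0
    assert {order.index("a"), order.index("b")} == {0, 1} or \
           {order.index("a"), order.index("b")} == {1, 2}


def test_targeted_similarity_reference_and_flags():
    heights = {
        "m1": {"g": 10.0, "f": 10.0, "z": 0.0},
        "m2": {"g": 5.0, "f": 5.0, "z": 0.0},
        "m3": {"g": 1.0, "f": 1.0, "z": 0.0},
    }
    meta = {
        s: {"strain": "e", "carbon_source": src, "replicate": 1,
            "is_control": False, "od": 0.5, "time_hr": 16.0}
        for s, src in [("g", "glc"), ("f", "fru"), ("z", "pyr")]
    }
    res = targeted_similarity(_table(heights, meta), reference="glc", timepoint=16.0)
    res = res.set_index("carbon_source")
    assert res.loc["fru", "r"] == pytest.approx(1.0)
    assert np.isnan(res.loc["pyr", "r"])  # all-zero vector flagged
    with pytest.raises(AnalysisError):
        targeted_similarity(_table(heights, meta), reference="glc", timepoint=28.0)


def test_gate_and_filter_commute(rng):
    cfg = GeneratorConfig(seed=13, n_substrates=8)
    pt = simulate_peak_table(cfg)
    # plant one failed replicate
    victim = pt.meta.index[pt.meta["carbon_source"] == sorted(
        set(pt.meta["carbon_source"]) - {"none"})[0]][0]
    pt.meta.loc[victim, "od"] = 0.01
    a = growth_gate(filter_control_peaks(pt)[0])
    b = filter_control_peaks(growth_gate(pt))[0]
    assert list(a.heights.index) == list(b.heights.index)
    assert list(a.heights.columns) == list(b.heights.columns)
    assert np.allclose(a.heights.to_numpy(), b.heights.to_numpy())
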