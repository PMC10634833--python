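"""Rarefaction, taxonomy aggregation, Renkonen similarity, variance partition."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from commassembly import (
    AnalysisError,
    CommunityTable,
    TaxonomyMap,
    aggregate_taxonomy,
    community_similarity_matrix,
    generations,
    rarefy,
    renkonen,
    similarity_vs_metabolic,
    simulate_communities,
    variance_partition,
)
from commassembly.community import clade_of_family, per_inoculum_renkonen
from commassembly.synth import GeneratorConfig


def _ct(counts: dict, meta: dict | None = None, **kwargs) -> CommunityTable:
    df = pd.DataFrame(counts).T
    if meta is None:
        meta = pd.DataFrame(index=df.index)
    else:
        meta = pd.DataFrame(meta).T.loc[df.index]
    return CommunityTable(counts=df, meta=meta, **kwargs)


@pytest.fixture
def tax():
    return TaxonomyMap(
        lineage=pd.DataFrame(
            {
                "genus": ["Klebsiella", "Enterobacter", "Pseudomonas", "Acinetobacter", "Delftia"],
                "family": [
                    "Enterobacteriaceae",
                    "Enterobacteriaceae",
                    "Pseudomonadaceae",
                    "Moraxellaceae",
                    "Comamonadaceae",
                ],
            },
            index=["e1", "e2", "e3", "e4", "e5"],
        )
    )


def test_serial_passage_generation_arithmetic():
    assert generations(125, 12) == pytest.approx(12 * np.log2(125))
    assert round(generations(125, 12)) == 84
    assert round(generations(125, 10)) == 70


def test_clade_table():
    assert clade_of_family("Enterobacteriaceae") == "E+"
    assert clade_of_family("Yersiniaceae") == "E+"
    assert clade_of_family("Moraxellaceae") == "P+"
    assert clade_of_family("Comamonadaceae") == "Other"


def test_rarefy_exact_depth_and_determinism():
    ct = _ct({"s1": {"e1": 3000, "e2": 2000}, "s2": {"e1": 1000, "e2": 1800}})
    r1 = rarefy(ct, depth=2733, seed=42)
    r2 = rarefy(ct, depth=2733, seed=42)
    assert (r1.counts.sum(axis=1) == 2733).all()
    assert r1.counts.equals(r2.counts)
    assert set(r1.counts.index) == {"s1", "s2"}
    shallow = rarefy(ct, depth=2900, seed=0)
    assert list(shallow.counts.index) == ["s1"]  # s2 (2800 reads) dropped


def test_rarefy_row_at_exact_total_unchanged():
    ct = _ct({"s1": {"e1": 60, "e2": 40}})
    out = rarefy(ct, depth=100, seed=0)
    assert out.counts.loc["s1"].tolist() == [60, 40]


def test_rarefy_preserves_expected_proportions():
    ct = _ct({"s1": {"e1": 700, "e2": 200, "e3": 100}})
    props = []
    for seed in range(500):
        out = rarefy(ct, depth=200, seed=seed)
        props.append(out.counts.loc["s1"].to_numpy() / 200)
    mean = np.mean(props, axis=0)
    sd = np.std(props, axis=0) / np.sqrt(500)
    parent = np.array([0.7, 0.2, 0.1])
    assert np.all(np.abs(mean - parent) < 2 * np.maximum(sd, 1e-4) + 2e-3)


def test_rarefy_rejects_bad_depth():
    ct = _ct({"s1": {"e1": 10, "e2": 10}})
    with pytest.raises(AnalysisError):
        rarefy(ct, depth=0, seed=0)


def test_aggregate_family_and_clade(tax):
    ct = _ct({"s1": {"e1": 10, "e2": 5, "e3": 7, "e4": 3, "e5": 2}})
    fam = aggregate_taxonomy(ct, tax, "Family")
    assert fam.counts.loc["s1", "Enterobacteriaceae"] == 15
    clade = aggregate_taxonomy(ct, tax, "Clade")
    assert clade.counts.loc["s1", "E+"] == 15
    assert clade.counts.loc["s1", "P+"] == 10  # Pseudomonadaceae + Moraxellaceae
    assert clade.counts.loc["s1", "Other"] == 2
    assert clade.counts.sum(axis=1).tolist() == ct.counts.sum(axis=1).tolist()
    ident = aggregate_taxonomy(ct, tax, "ESV")
    assert ident.counts.equals(ct.counts)


def test_aggregate_unmapped_taxa(tax):
    ct = _ct({"s1": {"e1": 5, "mystery": 5}})
    gen = aggregate_taxonomy(ct, tax, "Genus")
    assert gen.counts.loc["s1", "unassigned"] == 5
    clade = aggregate_taxonomy(ct, tax, "Clade")
    assert clade.counts.loc["s1", "Other"] == 5


def test_renkonen_worked_values():
    assert renkonen([0.5, 0.5, 0.0], [0.25, 0.5, 0.25]) == pytest.approx(0.75)
    assert renkonen([1.0, 0.0], [1.0, 0.0]) == pytest.approx(1.0)
    assert renkonen([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)
    with pytest.raises(AnalysisError, match="not normalized"):
        renkonen([0.5, 0.1], [0.5, 0.5])


def test_renkonen_equals_one_minus_bray_curtis(rng):
    """Independent oracle: scipy's Bray-Curtis on 100 random profile pairs."""
    from scipy.spatial.distance import braycurtis

    for _ in range(100):
        x = rng.dirichlet(np.ones(12))
        y = rng.dirichlet(np.ones(12))
        assert renkonen(x, y) == pytest.approx(1.0 - braycurtis(x, y), abs=1e-12)


def test_similarity_matrix_duplicated_sample():
    ct = _ct(
        {"s1": {"e1": 10, "e2": 30}, "s2": {"e1": 10, "e2": 30}},
    )
    sim = community_similarity_matrix(ct)
    assert sim.loc["s1", "s2"] == pytest.approx(1.0)
    assert np.allclose(np.diag(sim.values), 1.0)


def test_coarsening_never_decreases_similarity(tax, rng):
    esvs = list(tax.lineage.index)
    for _ in range(100):
        counts = {
            "s1": dict(zip(esvs, rng.integers(0, 50, len(esvs)))),
            "s2": dict(zip(esvs, rng.integers(0, 50, len(esvs)))),
        }
        counts["s1"]["e1"] += 1  # avoid empty samples
        counts["s2"]["e2"] += 1
        ct = _ct(counts)
        prev = None
        for level in ("ESV", "Genus", "Family", "Clade"):
            agg = aggregate_taxonomy(ct, tax, level)
            sim = community_similarity_matrix(agg).loc["s1", "s2"]
            if prev is not None:
                assert sim >= prev - 1e-12
            prev = sim


def test_similarity_vs_metabolic_planted_and_null(branched20):
    model, envs, sim = branched20
    cfg = GeneratorConfig(seed=21, n_taxa=30, n_substrates=20, n_inocula=2)
    ct, tax, _ = simulate_communities(cfg, model, envs)
    comm = per_inoculum_renkonen(rarefy(ct, seed=0), "inoc1")
    res = similarity_vs_metabolic(comm, sim.labels, sim.values, n_perm=999, seed=3)
    assert res["pearson_r"] > 0
    assert res["mantel_p"] <= 0.05


def test_variance_partition_carbon_dominates():
    rng = np.random.default_rng(2)
    inocs, sources = [f"i{k}" for k in range(2)], [f"c{k}" for k in range(25)]
    rows, meta = {}, {}
    base = {c: rng.dirichlet(np.ones(6)) for c in sources}
    for i in inocs:
        for c in sources:
            s = f"{i}_{c}"
            p = base[c] + rng.normal(0, 0.002, 6)
            p = np.clip(p, 1e-6, None)
            rows[s] = dict(zip(range(6), p / p.sum()))
            meta[s] = {"inoculum": i, "carbon_source": c, "replicate": 1}
    ct = CommunityTable(
        counts=pd.DataFrame(rows).T,
        meta=pd.DataFrame(meta).T.loc[list(rows)],
        relative=True,
    )
    frac = variance_partition(ct)
    assert abs(frac["frac_carbon_source"] - 1.0) < 0.05
    assert abs(frac["frac_inoculum"]) < 0.05


def test_variance_partition_pure_noise_near_zero():
    rng = np.random.default_rng(3)
    rows, meta = {}, {}
    for k in range(40):
        s = f"s{k}"
        rows[s] = dict(zip(range(8), rng.dirichlet(np.ones(8))))
        meta[s] = {"inoculum": f"i{k % 4}", "carbon_source": f"c{k % 10}", "replicate": 1}
    ct = CommunityTable(
        counts=pd.DataFrame(rows).T,
        meta=pd.DataFrame(meta).T.loc[list(rows)],
        relative=True,
    )
    frac = variance_partition(ct)
    for key in ("frac_inoculum", "frac_carbon_source"):
        assert abs(frac[key]) < 0.05


def test_variance_partition_swapping_factors_swaps_fractions():
    rng = np.random.default_rng(4)
    rows, meta = {}, {}
    for i in range(3):
        for c in range(5):
            s = f"s{i}_{c}"
            rows[s] = dict(zip(range(5), rng.dirichlet(np.ones(5))))
            meta[s] = {"inoculum": f"i{i}", "carbon_source": f"c{c}", "replicate": 1}
    ct = CommunityTable(
        counts=pd.DataFrame(rows).T,
        meta=pd.DataFrame(meta).T.loc[list(rows)],
        relative=True,
    )
    a = variance_partition(ct, factors=("inoculum", "carbon_source"))
    b = variance_partition(ct, factors=("carbon_source", "inoculum"))
    assert a["frac_inoculum"] == pytest.approx(b["frac_inoculum"], abs=1e-12)
    assert a["frac_carbon_source"] == pytest.approx(b["frac_carbon_source"], abs=1e-12)
    assert a["frac_shared"] == pytest.approx(b["frac_shared"], abs=1e-12)


def test_variance_partition_fractions_sum_to_one():
    rng = np.random.default_rng(5)
    rows, meta = {}, {}
    for i in range(3):
        for c in range(6):
            s = f"s{i}_{c}"
            rows[s] = dict(zip(range(6), rng.dirichlet(np.ones(6))))
            meta[s] = {"inoculum": f"i{i}", "carbon_source": f"c{c}", "replicate": 1}
    ct = CommunityTable(
        counts=pd.DataFrame(rows).T,
        meta=pd.DataFrame(meta).T.loc[list(rows)],
        relative=True,
    )
    frac = variance_partition(ct)
    total = sum(frac.values())
    assert total == pytest.approx(1.0, abs=1e-9)


def test_variance_partition_matches_vegan(tmp_path):
    """Cross-check adjusted-R2 fractions against R vegan's varpart."""
    if subprocess.run(["which", "Rscript"], capture_output=True).returncode != 0:
        pytest.skip("Rscript unavailable")
    rng = np.random.default_rng(6)
    rows, meta = {}, {}
    base = {c: rng.dirichlet(np.ones(5)) for c in range(4)}
    shift = {i: rng.normal(0, 0.05, 5) for i in range(3)}
    for i in range(3):
        for c in range(4):
            s = f"s{i}_{c}"
            p = np.clip(base[c] + shift[i] + rng.normal(0, 0.02, 5), 1e-4, None)
            rows[s] = dict(zip(range(5), p / p.sum()))
            meta[s] = {"inoculum": f"i{i}", "carbon_source": f"c{c}", "replicate": 1}
    counts = pd.DataFrame(rows).T
    metadf = pd.DataFrame(meta).T.loc[counts.index]
    ct = CommunityTable(counts=counts, meta=metadf, relative=True)
    ours = variance_partition(ct)
    counts.to_csv(tmp_path / "y.csv")
    metadf.to_csv(tmp_path / "m.csv")
    rscript = textwrap.dedent(
        f"""
        suppressMessages(library(vegan))
        y <- read.csv("{tmp_path}/y.csv", row.names=1)
        m <- read.csv("{tmp_path}/m.csv", row.names=1)
        vp <- varpart(y, ~ inoculum, ~ carbon_source, data=m)
        f <- vp$part$indfract$Adj.R.square
        cat(sprintf("%.10f %.10f %.10f %.10f", f[1], f[2], f[3], f[4]))
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    a, b, c, d = map(float, out.stdout.split())
    # vegan's individual fractions: [a]=pure X1, [b]=pure X2, [c]=shared, [d]=residual
    assert ours["frac_inoculum"] == pytest.approx(a, abs=1e-6)
    assert ours["frac_carbon_source"] == pytest.approx(b, abs=1e-6)
    assert ours["frac_shared"] == pytest.approx(c, abs=1e-6)
    assert ours["frac_residual"] == pytest.approx(d, abs=1e-6)
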