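import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from steatoreg.errors import UndefinedCallError, ValidationError
from steatoreg.methylation import (
    bh_adjust, classify_locus, clock_loci, concordance, coverage_mask,
    differential_cpgs, methylation_index, normalize_index, select_aging_loci,
    site_statistics, snupe_site_statistics,
)
from steatoreg.synthetic import SyntheticConfig, generate_methylation_tables


# ---------------------------------------------------------------------------
# methylation index
# ---------------------------------------------------------------------------

def test_index_symmetric():
    assert methylation_index(3.2, 3.2) == 0.5


def test_index_boundaries():
    assert methylation_index(0.0, 2.0) == 0.0
    assert methylation_index(2.0, 0.0) == 1.0


def test_index_arithmetic():
    assert methylation_index(3.0, 1.0) == 0.75


def test_index_undefined():
    with pytest.raises(UndefinedCallError):
        methylation_index(0.0, 0.0)


def test_index_negative_rejected():
    with pytest.raises(ValidationError):
        methylation_index(-1.0, 2.0)


@given(h_m=st.floats(0.001, 1e6), h_um=st.floats(0.001, 1e6),
       scale=st.floats(0.001, 1e3))
@settings(max_examples=50, deadline=None)
def test_index_scale_invariant(h_m, h_um, scale):
    assert methylation_index(h_m * scale, h_um * scale) == pytest.approx(
        methylation_index(h_m, h_um), rel=1e-9)


# ---------------------------------------------------------------------------
# normalize_index
# ---------------------------------------------------------------------------

def test_normalize_two_points():
    np.testing.assert_allclose(normalize_index([0.2, 0.7]), [0.0, 100.0])


def test_normalize_linear():
    np.testing.assert_allclose(normalize_index([0.1, 0.3, 0.5]), [0.0, 50.0, 100.0])


def test_normalize_affine_invariant(rng):
    vals = rng.random(10)
    np.testing.assert_allclose(normalize_index(vals),
                               normalize_index(0.3 * vals + 0.2), atol=1e-9)


def test_normalize_constant_warns(caplog):
    with caplog.at_level("WARNING"):
        out = normalize_index([0.4, 0.4, 0.4])
    assert (out == 0).all()
    assert "constant" in caplog.text


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_matches_oracle(rng):
    for _ in range(100):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), oracles.bh_adjust(list(p)), atol=1e-12)


def test_bh_with_ties():
    p = np.array([0.01, 0.01, 0.5, 0.5, 1.0])
    np.testing.assert_allclose(bh_adjust(p), oracles.bh_adjust(list(p)), atol=1e-12)


def test_bh_monotone_in_p(rng):
    p = np.sort(rng.random(20))
    adj = bh_adjust(p)
    assert (np.diff(adj) >= -1e-12).all()


# ---------------------------------------------------------------------------
# RRBS table ops
# ---------------------------------------------------------------------------

def rrbs_rows(site, betas_by_group, depth=50):
    rows = []
    for group, betas in betas_by_group.items():
        for i, b in enumerate(betas):
            rows.append((site, "chr1", 100, f"{group}_{i + 1}", group,
                         int(round(b * depth)), depth))
    return rows


def rrbs_frame(rows):
    return pd.DataFrame(rows, columns=["site", "chrom", "pos", "sample", "group",
                                       "meth_reads", "total_reads"])


def test_coverage_mask_boundaries():
    rows = [("s1", "chr1", 1, "a_1", "a", 1, 2), ("s1", "chr1", 1, "b_1", "b", 5, 10),
            ("s2", "chr1", 2, "a_1", "a", 2, 3), ("s2", "chr1", 2, "b_1", "b", 2, 3)]
    assert coverage_mask(rrbs_frame(rows), min_reads=3) == ["s1"]


def test_coverage_mask_matches_brute_force(rng):
    rows = []
    for s in range(20):
        for g, grp in enumerate(["a", "b"]):
            for i in range(3):
                tot = int(rng.integers(0, 12))
                rows.append((f"s{s:02d}", "chr1", s, f"{grp}_{i}", grp,
                             min(tot, int(rng.integers(0, 12))), tot))
    df = rrbs_frame([r for r in rows if r[5] <= r[6]])
    got = coverage_mask(df, min_reads=3)
    want = sorted({r[0] for r in rows if r[5] <= r[6]} -
                  {s for s in {r[0] for r in rows}
                   if min(r[6] for r in rows if r[0] == s) >= 3})
    assert got == want


def test_differential_cpgs_clear_signal_kept():
    rows = (rrbs_rows("hit", {"a": [0.2, 0.22, 0.21, 0.19], "b": [0.5, 0.52, 0.49, 0.51]},
                      depth=100)
            + rrbs_rows("null", {"a": [0.4, 0.41, 0.39, 0.4], "b": [0.4, 0.39, 0.41, 0.4]},
                        depth=100))
    out = differential_cpgs(rrbs_frame(rows), "a", "b")
    assert bool(out.loc["hit", "passes"])
    assert not bool(out.loc["null", "passes"])


def test_differential_cpgs_variance_gate():
    rows = rrbs_rows("v", {"a": [0.1, 0.1, 0.1, 0.1], "b": [0.1, 0.9, 0.1, 0.9]}, depth=100)
    out = differential_cpgs(rrbs_frame(rows), "a", "b")
    assert bool(out.loc["v", "passes_diff"])
    assert not bool(out.loc["v", "passes_var"])
    assert not bool(out.loc["v", "passes"])


def test_differential_cpgs_coverage_gate():
    rows = rrbs_rows("c", {"a": [0.2] * 2, "b": [0.8] * 2}, depth=4)
    out = differential_cpgs(rrbs_frame(rows), "a", "b")
    assert not bool(out.loc["c", "covered"])
    assert not bool(out.loc["c", "passes"])


def test_differential_cpgs_group_needs_two_samples():
    rows = rrbs_rows("s", {"a": [0.2], "b": [0.8, 0.7]}, depth=50)
    with pytest.raises(ValidationError):
        differential_cpgs(rrbs_frame(rows), "a", "b")


def test_differential_cpgs_nesting_in_min_diff(rng):
    cfg = SyntheticConfig(seed=3, n_cpgs=60, n_aging_cpgs=15, n_diet_cpgs=10,
                          n_opposite_cpgs=5)
    rrbs, _, _ = generate_methylation_tables(cfg)
    loose = differential_cpgs(rrbs, "young", "aged", min_diff=0.05)
    tight = differential_cpgs(rrbs, "young", "aged", min_diff=0.2)
    assert set(tight.index[tight["passes"]]) <= set(loose.index[loose["passes"]])
    strict_alpha = differential_cpgs(rrbs, "young", "aged", alpha=0.01)
    assert set(strict_alpha.index[strict_alpha["passes"]]) <= set(loose.index[loose["passes"]])


def test_differential_cpgs_plant_recovery():
    recovered, fp_frac = [], []
    for seed in range(20):
        cfg = SyntheticConfig(seed=seed, n_cpgs=200, n_aging_cpgs=20, n_diet_cpgs=20,
                              n_opposite_cpgs=10, aging_delta=-0.4, rrbs_depth=100)
        rrbs, _, truth = generate_methylation_tables(cfg)
        out = differential_cpgs(rrbs, "young", "aged")
        planted = {d["site"] for d in truth.dm_cpgs if d["age_direction"] != 0}
        flagged = set(out.index[out["passes"]])
        recovered.append(len(planted & flagged) >= 18)
        fp_frac.append(len(flagged - planted) / (cfg.n_cpgs - len(planted)))
    assert sum(recovered) >= 18
    assert np.mean(fp_frac) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 20)


# ---------------------------------------------------------------------------
# aging loci selection
# ---------------------------------------------------------------------------

def stats_frame(rows):
    return pd.DataFrame(rows, columns=["site", "delta_beta", "padj"]).set_index("site")


def test_aging_exact_boundary_excluded():
    out = select_aging_loci(stats_frame([("s", 0.30, 0.01)]))
    assert out == []  # strictly more than 0.30 required


def test_aging_included():
    assert select_aging_loci(stats_frame([("s", 0.45, 0.02)])) == ["s"]
    assert select_aging_loci(stats_frame([("s", -0.45, 0.02)])) == ["s"]


def test_aging_fdr_boundary_excluded():
    assert select_aging_loci(stats_frame([("s", 0.5, 0.1)])) == []


def test_aging_plant_recovery():
    cfg = SyntheticConfig(seed=5, n_cpgs=120, n_aging_cpgs=12, n_diet_cpgs=12,
                          n_opposite_cpgs=6, aging_delta=-0.4, rrbs_depth=100)
    rrbs, _, truth = generate_methylation_tables(cfg)
    stats = site_statistics(rrbs, "young", "aged")
    got = set(select_aging_loci(stats))
    planted = {d["site"] for d in truth.dm_cpgs if d["age_direction"] != 0}
    assert planted <= got
    assert len(got - planted) <= 3


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_classify_discordant():
    assert classify_locus(-0.4, True, 0.2, True) == "discordant"


def test_classify_age_only():
    assert classify_locus(-0.4, True, 0.2, False) == "age_only"


def test_classify_all_classes():
    assert classify_locus(0.3, True, 0.2, True) == "concordant"
    assert classify_locus(0.0, False, 0.4, True) == "diet_only"
    assert classify_locus(0.0, False, 0.0, False) == "neither"


def test_concordance_planted_opposites_discordant():
    cfg = SyntheticConfig(seed=9, n_cpgs=80, n_aging_cpgs=10, n_diet_cpgs=10,
                          n_opposite_cpgs=10, aging_delta=-0.4, diet_delta=0.3,
                          rrbs_depth=100)
    rrbs, _, truth = generate_methylation_tables(cfg)
    age = site_statistics(rrbs, "young", "aged")
    diet = site_statistics(rrbs, "Co", "LDC")
    conc = concordance(age, diet)
    opposite = [d["site"] for d in truth.dm_cpgs
                if d["age_direction"] * d["diet_direction"] == -1]
    assert opposite
    assert (conc.loc[opposite, "class"] == "discordant").all()
    assert not (conc["class"] == "concordant").any()


def test_concordance_skips_missing_locus(caplog):
    age = stats_frame([("s1", -0.4, 0.001)]).assign(pvalue=0.001)
    diet = stats_frame([("s2", 0.4, 0.001)]).assign(pvalue=0.001)
    with caplog.at_level("WARNING"):
        out = concordance(age, diet, loci=["s1", "s2"])
    assert len(out) == 0
    assert "missing" in caplog.text


def test_snupe_engine_agrees_with_planted_direction():
    cfg = SyntheticConfig(seed=11, n_cpgs=60, n_aging_cpgs=8, n_diet_cpgs=8,
                          n_opposite_cpgs=4, aging_delta=-0.4, diet_delta=0.3)
    _, snupe, truth = generate_methylation_tables(cfg)
    stats = snupe_site_statistics(snupe, "young", "aged", technology="SNuPE")
    for d in truth.dm_cpgs:
        if d["age_direction"] != 0 and d["site"] in stats.index:
            assert np.sign(stats.loc[d["site"], "delta_beta"]) == d["age_direction"]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def test_clock_loci_fixture_round_trip(tmp_path):
    from steatoreg.io import read_bed, write_bed

    loci = clock_loci()
    assert len(loci) == 13
    assert {"Fgfr3", "Tns1", "Ndrg2", "Smarca2", "Inpp5a"} <= set(loci["name"])
    assert ((loci["end"] - loci["start"]) == 2).all()
    p = tmp_path / "loci.bed"
    write_bed(loci, p)
    pd.testing.assert_frame_equal(read_bed(p), loci)
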