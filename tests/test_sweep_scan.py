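"""Weir–Cockerham components against a scalar oracle, zFST, pi-ratio,
outlier-window merging, background contrast and gene annotation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popscan.core_io import PopscanError
from popscan.sweep_scan import (
    annotate_regions,
    background_contrast,
    call_sweep_regions,
    flag_outlier_windows,
    genome_fst,
    log2_pi_ratio,
    shared_gene_counts,
    weir_cockerham_components,
    weir_cockerham_fst,
    zfst_transform,
)
from popscan.synthetic_data import ScenarioConfig, simulate_cohort
from popscan.windowed_stats import WindowSpec, make_windows, window_diversity

from conftest import build_matrix


def wc_oracle(p1, h1, n1, p2, h2, n2):
    """Independent scalar Weir–Cockerham two-population components from
    allele frequency p, heterozygote proportion h, and diploid count n."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def two_pop_matrix(genos_a, genos_b):
    d = np.array([list(genos_a) + list(genos_b)], dtype=np.int8)
    m = build_matrix(d, positions=[100])
    pop_a = m.sample_ids[: len(genos_a)]
    pop_b = m.sample_ids[len(genos_a):]
    return m, pop_a, pop_b


def test_fixed_difference_gives_theta_one():
    m, a, b = two_pop_matrix([2] * 5, [0] * 5)
    per_site = weir_cockerham_components(m, a, b)
    assert per_site.loc[0, "theta_hat"] == pytest.approx(1.0)


def test_identical_allele_counts_give_nonpositive_theta():
    # 10 vs 10 diploids with the same genotype composition (3 hom-alt,
    # 4 het, 3 hom-ref in each): no among-population variance
    genos = [2] * 3 + [1] * 4 + [0] * 3
    m, a, b = two_pop_matrix(genos, genos)
    per_site = weir_cockerham_components(m, a, b)
    th = per_site.loc[0, "theta_hat"]
    assert th <= 0
    ao, bo, co = wc_oracle(0.5, 0.4, 10, 0.5, 0.4, 10)
    assert per_site.loc[0, "a"] == pytest.approx(ao, abs=1e-12)
    assert th == pytest.approx(ao / (ao + bo + co), abs=1e-12)


def test_asymmetric_example_matches_scalar_oracle():
    # pop1: 3 hom-alt, 4 het, 3 hom-ref; pop2: 1 hom-alt, 2 het, 7 hom-ref
    m, a, b = two_pop_matrix([2, 2, 2, 1, 1, 1, 1, 0, 0, 0],
                             [2, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    per_site = weir_cockerham_components(m, a, b)
    ao, bo, co = wc_oracle(0.5, 0.4, 10, 0.2, 0.2, 10)
    assert per_site.loc[0, "a"] == pytest.approx(ao, abs=1e-12)
    assert per_site.loc[0, "b"] == pytest.approx(bo, abs=1e-12)
    assert per_site.loc[0, "c"] == pytest.approx(co, abs=1e-12)
    assert per_site.loc[0, "theta_hat"] == pytest.approx(
        ao / (ao + bo + co), abs=1e-12
    )


def test_overlapping_populations_rejected():
    m, a, b = two_pop_matrix([0, 1], [1, 2])
    with pytest.raises(PopscanError, match="overlap"):
        weir_cockerham_components(m, a, a)


def test_balding_nichols_scenario_recovers_f():
    cfg = ScenarioConfig(
        contigs=[("chr1", 10_000_000)],
        pop_sizes={"popA": 50, "popB": 50},
        fst=0.1,
        seed=0,
    )
    co = simulate_cohort(cfg)
    m = co.matrix
    f = genome_fst(m, co.manifest.samples_of("popA"), co.manifest.samples_of("popB"))
    assert f == pytest.approx(0.10, abs=0.02)


def test_window_fst_is_ratio_of_sums_not_mean_of_ratios():
    # two sites in one window: a fixed difference and a shared-polymorphism
    # site; ratio-of-sums differs from averaging per-site theta
    d = np.array(
        [[2, 2, 0, 0],  # fixed difference
         [1, 1, 1, 1]],  # identical frequencies
        dtype=np.int8,
    )
    m = build_matrix(d, positions=[100, 200])
    a, b = m.sample_ids[:2], m.sample_ids[2:]
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    per_site, wtab = weir_cockerham_fst(m, a, b, w)
    num = per_site["a"].sum()
    den = (per_site["a"] + per_site["b"] + per_site["c"]).sum()
    assert wtab.loc[0, "fst"] == pytest.approx(num / den)
    assert wtab.loc[0, "fst"] != pytest.approx(per_site["theta_hat"].mean())


# -- zFST -------------------------------------------------------------------

def test_zfst_two_values_closed_form():
    z = zfst_transform(np.array([0.1, 0.3]))
    assert z == pytest.approx([-0.70710678, 0.70710678], abs=1e-6)


def test_zfst_constant_vector_raises():
    with pytest.raises(PopscanError, match="sd = 0"):
        zfst_transform(np.array([0.2, 0.2, 0.2]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=3, max_size=60)
)
def test_zfst_output_standardized(values):
    x = np.asarray(values)
    if np.ptp(x) < 1e-9:
        return
    z = zfst_transform(x)
    assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
    assert np.nanstd(z, ddof=1) == pytest.approx(1.0, rel=1e-9)


def test_zfst_propagates_missing():
    z = zfst_transform(np.array([0.1, np.nan, 0.3]))
    assert np.isnan(z[1]) and not np.isnan(z[0])


# -- log2 pi ratio ----------------------------------------------------------

def _pi_frame(vals):
    n = len(vals)
    return pd.DataFrame(
        {
            "contig": "c",
            "start": np.arange(n) * 100,
            "end": np.arange(1, n + 1) * 100,
            "theta_pi": vals,
        }
    )


def test_pi_ratio_closed_forms_and_zero_target_reason():
    ref = _pi_frame([2.0, 4.0, 1.0])
    tgt = _pi_frame([2.0, 1.0, 0.0])
    out = log2_pi_ratio(ref, tgt)
    assert out.loc[0, "log2_pi_ratio"] == 0.0
    assert out.loc[1, "log2_pi_ratio"] == pytest.approx(2.0)  # log2(4)
    assert np.isnan(out.loc[2, "log2_pi_ratio"])
    assert out.loc[2, "reason"] == "zero_target_pi"


def test_pi_ratio_mismatched_frames_rejected():
    ref = _pi_frame([1.0])
    tgt = _pi_frame([1.0, 2.0])
    with pytest.raises(Exception):
        log2_pi_ratio(ref, tgt)


# -- outlier calling --------------------------------------------------------

def _window_frame(fst_vals, ratio_vals, step=20_000, size=40_000):
    n = len(fst_vals)
    starts = np.arange(n) * step
    base = pd.DataFrame(
        {
            "contig": "c",
            "start": starts,
            "end": starts + size,
            "truncated": False,
        }
    )
    fst = base.copy()
    fst["fst"] = fst_vals
    ratio = base.copy()
    ratio["log2_pi_ratio"] = ratio_vals
    return fst, ratio


def test_two_flagged_windows_sharing_20kb_merge_to_60kb_region():
    n = 40
    fst_vals = np.linspace(0.01, 0.2, n)
    ratio_vals = np.linspace(0.0, 1.0, n)
    # top-2 windows (adjacent, overlapping by 20 kb) pass both criteria
    fst, ratio = _window_frame(fst_vals, ratio_vals)
    regions = call_sweep_regions(fst, ratio, quantile=0.95)
    assert len(regions) == 1
    reg = regions.iloc[0]
    assert reg["end"] - reg["start"] == 60_000
    assert reg["n_windows"] == 2


def test_flagged_fraction_bounded_by_quantile():
    rng = np.random.default_rng(0)
    fst, ratio = _window_frame(rng.random(500), rng.random(500))
    flags, _ = flag_outlier_windows(fst, ratio, quantile=0.95)
    # each criterion alone keeps at most 5%; the intersection is smaller
    assert flags["outlier"].mean() <= 0.05


def test_region_calling_idempotent_on_called_windows():
    rng = np.random.default_rng(1)
    fst_vals = rng.random(300)
    ratio_vals = fst_vals + rng.normal(0, 0.05, 300)  # correlated criteria
    fst, ratio = _window_frame(fst_vals, ratio_vals)
    first = call_sweep_regions(fst, ratio, quantile=0.9)
    again = call_sweep_regions(fst, ratio, quantile=0.9)
    pd.testing.assert_frame_equal(first, again)


def test_too_few_windows_for_quantiles_rejected():
    fst, ratio = _window_frame(np.arange(10) / 10, np.arange(10) / 10)
    with pytest.raises(PopscanError, match="usable windows"):
        call_sweep_regions(fst, ratio)


def test_background_contrast_top_windows_significant_and_all_windows_null():
    rng = np.random.default_rng(2)
    fst_vals = rng.random(400)
    ratio_vals = fst_vals + rng.normal(0, 0.02, 400)
    fst, ratio = _window_frame(fst_vals, ratio_vals)
    regions = call_sweep_regions(fst, ratio, quantile=0.95)
    rep = background_contrast(regions, fst, ratio)
    assert (rep["p_value"] < 0.05).all()
    # regions spanning every window: in-region == background, p ~ 1
    whole = pd.DataFrame(
        {"contig": ["c"], "start": [0], "end": [fst["end"].max()]}
    )
    rep2 = background_contrast(whole, fst, ratio)
    assert (rep2["p_value"] > 0.99).all()


def test_single_window_region_valid_small_sample_path():
    rng = np.random.default_rng(3)
    fst, ratio = _window_frame(rng.random(100), rng.random(100))
    one = pd.DataFrame({"contig": ["c"], "start": [0], "end": [40_000]})
    rep = background_contrast(one, fst, ratio)
    assert ((rep["p_value"] >= 0) & (rep["p_value"] <= 1)).all()


def test_empty_region_set_rejected():
    fst, ratio = _window_frame(np.arange(30) / 30, np.arange(30) / 30)
    with pytest.raises(PopscanError, match="empty"):
        background_contrast(pd.DataFrame(columns=["contig", "start", "end"]), fst, ratio)


# -- gene annotation --------------------------------------------------------

GENES = pd.DataFrame(
    {
        "contig": ["c", "c", "c"],
        "start": [1_000, 50_000, 100_000],
        "end": [2_000, 70_000, 110_000],
        "gene_id": ["inside", "straddle", "abutting"],
    }
)


def test_gene_overlap_half_open_convention():
    regions = pd.DataFrame({"contig": ["c"], "start": [0], "end": [100_000]})
    out = annotate_regions(regions, GENES)
    joined = out.loc[0, "genes"].split(",")
    assert "inside" in joined and "straddle" in joined
    assert "abutting" not in joined  # starts exactly at region end


def test_shared_gene_counts_across_population_scans():
    r1 = pd.DataFrame({"genes": ["g1,g2"]})
    r2 = pd.DataFrame({"genes": ["g1"]})
    r3 = pd.DataFrame({"genes": ["g1,g3"]})
    counts = shared_gene_counts({"p1": r1, "p2": r2, "p3": r3})
    lookup = dict(zip(counts["gene_id"], counts["n_populations"]))
    assert lookup == {"g1": 3, "g2": 1, "g3": 1}


def test_malformed_gene_intervals_rejected():
    bad = pd.DataFrame(
        {"contig": ["c"], "start": [100], "end": [100], "gene_id": ["x"]}
    )
    regions = pd.DataFrame({"contig": ["c"], "start": [0], "end": [1000]})
    with pytest.raises(PopscanError, match="end <= start"):
        annotate_regions(regions, bad)
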