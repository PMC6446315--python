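"""Window arithmetic, diversity statistics against hand oracles, Z-vs-autosome
contrasts and window-size selection."""
from fractions import Fraction

import numpy as np
import pytest

from popscan.core_io import MISSING, PopscanError
from popscan.synthetic_data import ScenarioConfig, simulate_cohort
from popscan.windowed_stats import (
    WindowSpec,
    compare_chromosome_groups,
    make_windows,
    select_window_size,
    tajima_constants,
    tajimas_d_from_summary,
    window_diversity,
)

from conftest import build_matrix


# -- window tiling ----------------------------------------------------------

def test_sliding_windows_tile_with_truncated_tail():
    w = make_windows([("c", 100_000)], WindowSpec(40_000, 20_000))
    assert list(w["start"]) == [0, 20_000, 40_000, 60_000, 80_000]
    assert list(w["end"])[-1] == 100_000
    assert list(w["truncated"]) == [False, False, False, False, True]


def test_step_equals_size_gives_nonoverlapping_tiling():
    w = make_windows([("c", 100_000)], WindowSpec(25_000, 25_000))
    assert list(w["start"]) == [0, 25_000, 50_000, 75_000]
    assert not w["truncated"].any()


def test_contig_shorter_than_window_yields_single_truncated_window():
    w = make_windows([("c", 9_000)], WindowSpec(40_000, 20_000))
    assert len(w) == 1 and w.loc[0, "end"] == 9_000 and bool(w.loc[0, "truncated"])


def test_bad_window_spec_rejected():
    with pytest.raises(PopscanError):
        WindowSpec(0, 1)
    with pytest.raises(PopscanError):
        WindowSpec(100, 200)


# -- diversity statistics ---------------------------------------------------

def exact_tajimas_d(s, pi, n):
    """Independent oracle: textbook constants computed in exact rationals."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (pi - s / a1) / float(var) ** 0.5


def test_tajimas_d_matches_exact_constants_oracle():
    """4 chromosomes, derived counts {1,1,2} over 3 sites: pi = 5/3,
    thetaW = 18/11, D ~ +0.168."""
    n, s = 4, 3
    pi = float(Fraction(5, 3))
    expected = exact_tajimas_d(s, Fraction(5, 3), n)
    got = tajimas_d_from_summary(s, pi, n)
    assert got == pytest.approx(expected, abs=1e-6)
    assert got == pytest.approx(0.168, abs=5e-4)


@pytest.mark.parametrize("n", [4, 9, 25, 60])
def test_tajima_constants_match_rational_oracle(n):
    k = tajima_constants(n)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    assert k["a1"] == pytest.approx(float(a1), abs=1e-12)
    assert k["a2"] == pytest.approx(float(a2), abs=1e-12)
    b1 = Fraction(n + 1, 3 * (n - 1))
    c1 = b1 - 1 / a1
    assert k["e1"] == pytest.approx(float(c1 / a1), abs=1e-12)


def test_window_theta_pi_on_hand_example():
    # 2 diploids = 4 chromosomes; derived counts 1, 1, 2 across 3 sites
    m = build_matrix([[1, 0], [0, 1], [1, 1]], positions=[100, 200, 300])
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    t = window_diversity(m, m.sample_ids, w, "theta_pi", min_snps=0)
    assert t.loc[0, "theta_pi"] == pytest.approx(5 / 3, abs=1e-12)
    d = window_diversity(m, m.sample_ids, w, "tajimas_d", min_snps=0)
    assert d.loc[0, "tajimas_d"] == pytest.approx(0.168, abs=5e-4)


def test_monomorphic_window_has_zero_theta_pi():
    m = build_matrix([[0, 0, 0], [2, 2, 2]], positions=[100, 200])
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    t = window_diversity(m, m.sample_ids, w, "theta_pi", min_snps=0)
    assert t.loc[0, "theta_pi"] == 0.0
    assert t.loc[0, "n_snps"] == 0


def test_het_count_per_sample_and_pooled_consistency():
    m = build_matrix(
        [[1, 0], [1, 2], [1, 1], [1, MISSING], [1, 0]],
        positions=[100, 200, 300, 400, 500],
    )
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    t = window_diversity(m, m.sample_ids, w, "het_count", per_sample=True)
    assert t.loc[0, "het_count"] == 6
    assert t.loc[0, "het:s0"] == 5  # one sample 0/1 at 5 sites
    assert t.loc[0, "het:s1"] == 1
    assert t.loc[0, "het_count"] == t.loc[0, "het:s0"] + t.loc[0, "het:s1"]


def test_per_site_n_uses_nonmissing_chromosomes():
    # site with one missing diploid: n = 2 chromosomes, p = 1/2 -> pi = 2pq*n/(n-1) = 1
    m = build_matrix([[1, MISSING]], positions=[100])
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    t = window_diversity(m, m.sample_ids, w, "theta_pi", min_snps=0)
    assert t.loc[0, "theta_pi"] == pytest.approx(1.0)


def test_low_snp_windows_flagged_with_missing_statistic():
    m = build_matrix([[1, 0]], positions=[100])
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    t = window_diversity(m, m.sample_ids, w, "theta_pi", min_snps=20)
    assert bool(t.loc[0, "low_snp"]) and np.isnan(t.loc[0, "theta_pi"])


def test_unknown_stat_and_tiny_pop_rejected():
    m = build_matrix([[0, 1]])
    w = make_windows(m.contigs, WindowSpec(1000, 1000))
    with pytest.raises(PopscanError, match="unknown statistic"):
        window_diversity(m, m.sample_ids, w, "dxy")
    with pytest.raises(PopscanError, match="2 diploid"):
        window_diversity(m, m.sample_ids[:1], w, "theta_pi")


# -- Z vs autosome contrast -------------------------------------------------

def test_identical_groups_give_p_one_under_mann_whitney_ties():
    import pandas as pd

    het = pd.DataFrame(
        {"contig": ["chrZ"] * 5 + ["chr1"] * 5, "het_count": [3.0] * 10}
    )
    res = compare_chromosome_groups(het, ["chrZ"], test="mann_whitney")
    pooled = res[res["autosome"] == "all_autosomes"].iloc[0]
    assert pooled["p_value"] == pytest.approx(1.0)


def test_z_contig_low_diversity_detected_by_pooled_test():
    """With the Z simulated at half theta, the pooled Z-vs-autosome contrast
    on 500-kb heterozygosity windows is significant."""
    detected = 0
    for seed in range(5):
        cfg = ScenarioConfig(
            contigs=[("chr1", 25_000_000), ("chrZ", 25_000_000)],
            z_contigs=("chrZ",),
            pop_sizes={"popA": 10},
            n_outgroup=0,
            fst=0.1,
            seed=seed,
        )
        co = simulate_cohort(cfg)
        m = co.matrix
        w = make_windows(m.contigs, WindowSpec(500_000, 500_000, 0))
        het = window_diversity(m, m.sample_ids, w, "het_count", min_snps=0)
        res = compare_chromosome_groups(het, ["chrZ"], test="t_two_tailed")
        pooled = res[res["autosome"] == "all_autosomes"].iloc[0]
        assert pooled["median_z"] < pooled["median_autosome"]
        detected += pooled["p_value"] < 0.05
    assert detected >= 4


def test_absent_z_contig_errors():
    import pandas as pd

    het = pd.DataFrame({"contig": ["chr1"] * 4, "het_count": [1.0, 2, 3, 4]})
    with pytest.raises(PopscanError, match="absent"):
        compare_chromosome_groups(het, ["chrZ"])


# -- window-size selection --------------------------------------------------

def test_uniform_density_ties_break_to_smaller_size():
    # 1 SNP per kb exactly: every 10-kb and 40-kb window holds >= 20? No:
    # 10-kb window holds 10 SNPs; use min_snps=5 so both tie at proportion 1
    m = build_matrix(
        np.ones((200, 2), dtype=np.int8),
        positions=np.arange(200) * 1000 + 500,
        length=200_000,
    )
    chosen, table = select_window_size(m, [10_000, 40_000], min_snps=5)
    assert table["proportion_ok"].tolist() == [1.0, 1.0]
    assert chosen == 10_000


def test_sparse_density_forces_larger_window():
    """0.5 SNP/kb: 10-kb windows expect 5 SNPs (<20) while 40-kb windows
    expect 20, so the 40-kb size wins."""
    cfg = ScenarioConfig(
        contigs=[("chr1", 4_000_000)],
        pop_sizes={"popA": 10},
        n_outgroup=0,
        fst=0.05,
        site_density=0.0006,
        seed=2,
    )
    m = simulate_cohort(cfg).matrix
    chosen, table = select_window_size(m, [10_000, 40_000], min_snps=20)
    assert chosen == 40_000
    t10 = table.set_index("size").loc[10_000, "proportion_ok"]
    assert t10 < 0.05


def test_single_candidate_returned_unchanged():
    m = build_matrix([[1, 1]], positions=[100])
    chosen, _ = select_window_size(m, [12_345], min_snps=0)
    assert chosen == 12_345


def test_empty_matrix_rejected():
    m = build_matrix(np.zeros((0, 2), dtype=np.int8), positions=[])
    with pytest.raises(PopscanError, match="empty"):
        select_window_size(m, [10_000])
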