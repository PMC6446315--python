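"""Sliding/tiling-window diversity statistics and window-size selection.

All windows are 0-based half-open.  Frequency statistics use the per-site
count of non-missing chromosomes ``n``; for a window's Tajima's D constants
``n`` is summarized by the window median (configurable to the per-site
values' harmonic mean).  Windows with fewer SNPs than the ``min_snps``
threshold keep their counts but have their statistic set to missing and are
flagged, as are truncated terminal windows; downstream quantile-based
steps exclude both.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import MISSING, GenotypeMatrix, PopscanError

STATS = ("theta_pi", "tajimas_d", "het_count", "snp_count")


@dataclass
class WindowSpec:
    size: int = 40_000
    step: int = 20_000
    min_snps: int = 20

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise PopscanError("window size must be positive")
        if self.step <= 0 or self.step > self.size:
            raise PopscanError("window step must satisfy 0 < step <= size")


def make_windows(contigs: Sequence[tuple[str, int]], spec: WindowSpec) -> pd.DataFrame:
    """Tile each contig with half-open windows; a truncated final window is
    kept and flagged ``truncated``."""
    rows = []
    for contig, length in contigs:
        for start in range(0, length, spec.step):
            end = min(start + spec.size, length)
            rows.append((contig, start, end, end - start < spec.size))
            if spec.step >= spec.size and end == length:
                break
    return pd.DataFrame(rows, columns=["contig", "start", "end", "truncated"])


# ---------------------------------------------------------------------------
# Per-site building blocks
# ---------------------------------------------------------------------------

def _per_site_arrays(matrix: GenotypeMatrix, samples: Sequence[str]):
    alt, n = matrix.allele_counts(samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    # unbiased per-site pairwise diversity 2 p q n/(n-1)
    pi = np.where(n > 1, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1), 0.0)
    seg = (alt > 0) & (alt < n)
    return alt, n, pi, seg


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1, a2, b1, b2, c1, c2, e1, e2 for n sampled chromosomes."""
    if n < 2:
        raise PopscanError("Tajima's D needs at least 2 chromosomes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_summary(s: int, pi: float, n: int) -> float:
    """D from segregating-site count S, pairwise-difference sum pi, and n
    chromosomes; NaN when S = 0 or n < 4."""
    if s == 0 or n < 4:
        return float("nan")
    k = tajima_constants(n)
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (pi - theta_w) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def window_diversity(
    matrix: GenotypeMatrix,
    samples: Sequence[str],
    windows: pd.DataFrame,
    stat: str,
    *,
    min_snps: int = 20,
    n_convention: str = "median",
    per_sample: bool = False,
) -> pd.DataFrame:
    """Compute one statistic per window for a population sample set.

    ``stat`` is one of ``theta_pi`` (window sum of per-site 2pqn/(n-1), plus
    a per-bp column), ``tajimas_d``, ``het_count`` (pooled heterozygous
    genotype count; per-sample columns with ``per_sample=True``) or
    ``snp_count``.  ``n_snps`` counts sites segregating in the sample set.
    """
    if stat not in STATS:
        raise PopscanError(f"unknown statistic {stat!r}; choose from {STATS}")
    if not samples:
        raise PopscanError("empty sample set")
    if stat == "theta_pi" and len(samples) < 2:
        raise PopscanError("theta_pi needs at least 2 diploid samples")

    alt, n, pi_site, seg = _per_site_arrays(matrix, samples)
    d = matrix.dosages[:, matrix.sample_indices(samples)]
    het_site = (d == 1).sum(axis=1)

    out = windows.copy().reset_index(drop=True)
    n_snps = np.zeros(len(out), dtype=int)
    values = np.full(len(out), np.nan)
    pi_bp = np.full(len(out), np.nan)
    het_cols = np.zeros((len(out), len(samples)), dtype=int) if per_sample else None

    pos_by_contig = {
        c: (grp.index.to_numpy(), grp["pos"].to_numpy() - 1)
        for c, grp in matrix.sites.groupby("contig", sort=False)
    }
    for w, row in out.iterrows():
        got = pos_by_contig.get(row["contig"])
        if got is None:
            continue
        idx, pos0 = got
        lo, hi = np.searchsorted(pos0, [row["start"], row["end"]])
        sel = idx[lo:hi]
        n_snps[w] = int(seg[sel].sum())
        if stat == "snp_count":
            values[w] = n_snps[w]
            continue
        if stat == "het_count":
            values[w] = float(het_site[sel].sum())
            if per_sample:
                het_cols[w] = (d[sel] == 1).sum(axis=0)
            continue
        if n_snps[w] < min_snps:
            continue  # flagged below; statistic stays missing
        if stat == "theta_pi":
            values[w] = float(pi_site[sel].sum())
            pi_bp[w] = values[w] / (row["end"] - row["start"])
        elif stat == "tajimas_d":
            seg_sel = sel[seg[sel]]
            if len(seg_sel) == 0:
                continue  # no segregating sites: D undefined
            n_local = n[seg_sel]
            if n_convention == "median":
                n_win = int(np.median(n_local))
            elif n_convention == "harmonic":
                n_win = int(round(len(n_local) / np.sum(1.0 / n_local)))
            else:
                raise PopscanError(f"unknown n_convention {n_convention!r}")
            values[w] = tajimas_d_from_summary(
                len(seg_sel), float(pi_site[seg_sel].sum()), n_win
            )

    out["n_snps"] = n_snps
    out["low_snp"] = n_snps < min_snps if stat in ("theta_pi", "tajimas_d") else False
    out[stat] = values
    if stat == "theta_pi":
        out["theta_pi_per_bp"] = pi_bp
    if per_sample and stat == "het_count":
        for j, s in enumerate(samples):
            out[f"het:{s}"] = het_cols[:, j]
    return out


def compare_chromosome_groups(
    het_windows: pd.DataFrame,
    z_contig_names: Sequence[str],
    test: str = "t_two_tailed",
    value_col: str = "het_count",
) -> pd.DataFrame:
    """Contrast per-window values on the Z contig(s) against each autosome
    and against all autosomes pooled (two-sided)."""
    if test not in ("t_two_tailed", "mann_whitney"):
        raise PopscanError(f"unknown test {test!r}")
    z_set = set(z_contig_names)
    in_table = set(het_windows["contig"])
    if not z_set & in_table:
        raise PopscanError(f"Z contigs {sorted(z_set)} absent from window table")
    z_vals = het_windows.loc[het_windows["contig"].isin(z_set), value_col].dropna().to_numpy()
    rows = []
    autosomes = [c for c in het_windows["contig"].unique() if c not in z_set]
    groups = [(a, het_windows.loc[het_windows["contig"] == a, value_col].dropna().to_numpy())
              for a in autosomes]
    groups.append(
        ("all_autosomes",
         het_windows.loc[~het_windows["contig"].isin(z_set), value_col].dropna().to_numpy())
    )
    for name, vals in groups:
        if len(vals) < 2 or len(z_vals) < 2:
            raise PopscanError("each group needs at least 2 windows")
        if test == "t_two_tailed":
            stat, p = sps.ttest_ind(z_vals, vals, equal_var=False)
        else:
            stat, p = sps.mannwhitneyu(z_vals, vals, alternative="two-sided")
        rows.append(
            {
                "autosome": name,
                "test": test,
                "statistic": float(stat),
                "p_value": float(p),
                "median_z": float(np.median(z_vals)),
                "median_autosome": float(np.median(vals)),
            }
        )
    return pd.DataFrame(rows)


def select_window_size(
    matrix: GenotypeMatrix,
    candidate_sizes: Sequence[int],
    min_snps: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Pick the window size whose non-overlapping tiling maximizes the
    proportion of windows holding >= ``min_snps`` SNPs; ties go to the
    smaller size (better resolution for short sweeps)."""
    if not candidate_sizes:
        raise PopscanError("no candidate sizes")
    if matrix.n_sites == 0:
        raise PopscanError("empty matrix")
    rows = []
    for size in sorted(candidate_sizes):
        spec = WindowSpec(size=size, step=size, min_snps=min_snps)
        windows = make_windows(matrix.contigs, spec)
        counts = np.zeros(len(windows), dtype=int)
        for w, row in windows.reset_index(drop=True).iterrows():
            grp = matrix.sites[matrix.sites["contig"] == row["contig"]]
            pos0 = grp["pos"].to_numpy() - 1
            lo, hi = np.searchsorted(pos0, [row["start"], row["end"]])
            counts[w] = hi - lo
        ok = int((counts >= min_snps).sum())
        rows.append(
            {
                "size": size,
                "n_windows": len(windows),
                "n_ok": ok,
                "proportion_ok": ok / len(windows) if len(windows) else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    best = table["proportion_ok"].max()
    chosen = int(table.loc[table["proportion_ok"] == best, "size"].min())
    return chosen, table
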