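"""Selective-sweep calling from windowed differentiation and diversity loss.

The scan flags windows that are simultaneously in the upper tail of
(1) windowed Weir–Cockerham FST between a target and a reference population
and (2) the log2 diversity ratio ``log2(pi_reference / pi_target)``, merges
overlapping/abutting flagged windows into regions, contrasts region windows
against the genome-wide background (Mann-Whitney U), and joins overlapping
gene intervals.

Window FST is the ratio of summed Weir–Cockerham variance components
``sum(a) / sum(a + b + c)`` over polymorphic sites — not a mean of per-site
ratios — and negative per-site components are retained unclamped so the
sums stay unbiased.  zFST standardizes window FST over autosomal windows
with the n-1 standard deviation.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import MISSING, GenotypeMatrix, PopscanError, WINDOW_KEY


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components (two populations, diploid)
# ---------------------------------------------------------------------------

def weir_cockerham_components(
    matrix: GenotypeMatrix,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
) -> pd.DataFrame:
    """Per-site a (among-population), b (among-individual) and c
    (within-individual) components and theta_hat = a/(a+b+c).

    Sites monomorphic across both populations, or with fewer than 2 genotyped
    diploids in either population, are returned with NaN components and
    excluded from window sums.
    """
    if set(pop_a) & set(pop_b):
        raise PopscanError("populations overlap")
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise PopscanError("each population needs >= 2 diploids")
    r = 2
    comps = []
    for pop in (pop_a, pop_b):
        d = matrix.dosages[:, matrix.sample_indices(pop)]
        miss = d == MISSING
        n_i = (~miss).sum(axis=1).astype(float)
        alt = np.where(miss, 0, d).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(n_i > 0, alt / (2.0 * n_i), np.nan)
            h_i = np.where(n_i > 0, (d == 1).sum(axis=1) / n_i, np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    valid = (n1 >= 2) & (n2 >= 2)
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)

    poly = valid & (pbar > 0) & (pbar < 1)
    for arr in (a, b, c, theta):
        arr[~poly] = np.nan
    return pd.DataFrame(
        {
            "contig": matrix.sites["contig"],
            "pos": matrix.sites["pos"],
            "a": a,
            "b": b,
            "c": c,
            "theta_hat": theta,
            "polymorphic": poly,
        }
    )


def weir_cockerham_fst(
    matrix: GenotypeMatrix,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    windows: pd.DataFrame | None = None,
    min_snps: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-site components plus, when ``windows`` is given, a window table
    with ratio-of-sums FST (``fst``) and the count of contributing sites.

    Windows with fewer than ``min_snps`` polymorphic sites get a missing
    FST and a ``low_snp`` flag (the SNP-count gate uses sites polymorphic
    across the two populations jointly, so sweep-fixed windows are not
    dropped for being monomorphic in one population alone).
    """
    per_site = weir_cockerham_components(matrix, pop_a, pop_b)
    if windows is None:
        return per_site, None
    wtab = windows.copy().reset_index(drop=True)
    fst = np.full(len(wtab), np.nan)
    used = np.zeros(len(wtab), dtype=int)
    by_contig = {
        cname: grp for cname, grp in per_site.groupby("contig", sort=False)
    }
    for w, row in wtab.iterrows():
        grp = by_contig.get(row["contig"])
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        lo, hi = np.searchsorted(pos0, [row["start"], row["end"]])
        sel = grp.iloc[lo:hi]
        sel = sel[sel["polymorphic"]]
        used[w] = len(sel)
        if len(sel) == 0:
            continue
        denom = (sel["a"] + sel["b"] + sel["c"]).sum()
        if denom != 0:
            fst[w] = sel["a"].sum() / denom
    low = used < min_snps
    fst[low] = np.nan
    wtab["fst"] = fst
    wtab["n_fst_sites"] = used
    wtab["low_snp"] = low
    return per_site, wtab


def genome_fst(matrix: GenotypeMatrix, pop_a, pop_b) -> float:
    """Genome-wide ratio-of-sums Weir–Cockerham FST estimate."""
    per_site = weir_cockerham_components(matrix, pop_a, pop_b)
    sel = per_site[per_site["polymorphic"]]
    denom = (sel["a"] + sel["b"] + sel["c"]).sum()
    if denom == 0:
        raise PopscanError("no polymorphic sites")
    return float(sel["a"].sum() / denom)


# ---------------------------------------------------------------------------
# zFST and diversity ratio
# ---------------------------------------------------------------------------

def zfst_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Standardize window FST: z = (x - mean)/sd with the n-1 sd, over
    non-missing entries (missing in -> missing out).  Callers restrict the
    input to autosomal windows."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise PopscanError("zFST needs >= 2 non-missing values")
    if np.all(x[ok] == x[ok][np.argmax(ok)]) or np.ptp(x[ok]) == 0:
        raise PopscanError("zFST undefined: constant FST vector (sd = 0)")
    sd = float(np.std(x[ok], ddof=1))
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - float(np.mean(x[ok]))) / sd
    return out


def log2_pi_ratio(
    pi_reference: pd.DataFrame,
    pi_target: pd.DataFrame,
    value_col: str = "theta_pi",
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Per-window ``log2(pi_ref / pi_target)`` on matched window frames.

    High values mark diversity loss in the target population.  Windows where
    either diversity is missing, or the target diversity is 0 (unless an
    ``epsilon`` pseudo-floor is supplied), carry a missing ratio and a reason
    code.
    """
    for col in WINDOW_KEY:
        if not pi_reference[col].reset_index(drop=True).equals(
            pi_target[col].reset_index(drop=True)
        ):
            raise PopscanError("mismatched window frames between pi tables")
    out = pi_reference[WINDOW_KEY + [c for c in ("truncated", "n_snps") if c in pi_reference.columns]].copy()
    ref = pi_reference[value_col].to_numpy(dtype=float)
    tgt = pi_target[value_col].to_numpy(dtype=float)
    ratio = np.full(len(out), np.nan)
    reason = np.array([""] * len(out), dtype=object)
    missing = np.isnan(ref) | np.isnan(tgt)
    reason[missing] = "missing_pi"
    zero_t = (~missing) & (tgt == 0)
    if epsilon is not None:
        tgt = np.where(zero_t, epsilon, tgt)
        zero_t[:] = False
    else:
        reason[zero_t] = "zero_target_pi"
    ok = ~missing & ~zero_t & (ref > 0)
    zero_r = (~missing) & (~zero_t) & (ref == 0)
    reason[zero_r] = "zero_reference_pi"
    with np.errstate(divide="ignore"):
        ratio[ok] = np.log2(ref[ok] / tgt[ok])
    out["log2_pi_ratio"] = ratio
    out["reason"] = reason
    return out


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def flag_outlier_windows(
    fst_table: pd.DataFrame,
    ratio_table: pd.DataFrame,
    quantile: float = 0.95,
    z_contigs: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """Mark windows in the top tail of both FST and log2 pi-ratio.

    Quantile thresholds use the ``higher`` interpolation over non-missing,
    non-truncated autosomal windows, so each criterion alone flags at most
    ``1 - quantile`` of windows even under ties.
    """
    if not 0.5 < quantile < 1:
        raise PopscanError("quantile must be in (0.5, 1)")
    for col in WINDOW_KEY:
        if not fst_table[col].reset_index(drop=True).equals(
            ratio_table[col].reset_index(drop=True)
        ):
            raise PopscanError("FST and ratio tables on different window frames")
    merged = fst_table[WINDOW_KEY].copy().reset_index(drop=True)
    merged["truncated"] = (
        fst_table["truncated"].to_numpy()
        if "truncated" in fst_table.columns
        else np.zeros(len(merged), dtype=bool)
    )
    merged["fst"] = fst_table["fst"].to_numpy(dtype=float)
    merged["log2_pi_ratio"] = ratio_table["log2_pi_ratio"].to_numpy(dtype=float)
    autosomal = ~merged["contig"].isin(set(z_contigs))
    eligible = (
        autosomal
        & ~merged["truncated"]
        & ~merged["fst"].isna()
        & ~merged["log2_pi_ratio"].isna()
    )
    if eligible.sum() < 20:
        raise PopscanError(
            f"only {int(eligible.sum())} usable windows; quantile thresholds unstable"
        )
    def upper_cut(values: pd.Series) -> float:
        # smallest order statistic with at most (1-q) * n values >= it,
        # so each criterion alone flags at most that fraction of windows
        x = np.sort(values.to_numpy())
        k = min(int(np.ceil(quantile * len(x))), len(x) - 1)
        return float(x[k])

    fst_cut = upper_cut(merged.loc[eligible, "fst"])
    ratio_cut = upper_cut(merged.loc[eligible, "log2_pi_ratio"])
    merged["outlier"] = (
        eligible & (merged["fst"] >= fst_cut) & (merged["log2_pi_ratio"] >= ratio_cut)
    )
    thresholds = {"fst": fst_cut, "log2_pi_ratio": ratio_cut, "quantile": quantile,
                  "n_eligible": int(eligible.sum())}
    return merged, thresholds


def call_sweep_regions(
    fst_table: pd.DataFrame,
    ratio_table: pd.DataFrame,
    d_target: pd.DataFrame | None = None,
    d_reference: pd.DataFrame | None = None,
    quantile: float = 0.95,
    z_contigs: Sequence[str] = (),
) -> pd.DataFrame:
    """Merge doubly-outlying windows into candidate sweep regions.

    Adjacent flagged windows that overlap or abut are merged (with a
    size-step overlapping tiling, neighbouring flagged windows always
    merge).  Each region reports window count, max/mean FST, max zFST
    (standardized over autosomal windows), mean log2 pi-ratio and — when
    Tajima's D tables for both populations are supplied — the mean absolute
    D difference, carried as annotation only.
    """
    flagged, thresholds = flag_outlier_windows(fst_table, ratio_table, quantile, z_contigs)
    autosomal = ~flagged["contig"].isin(set(z_contigs))
    zfst = np.full(len(flagged), np.nan)
    zfst[autosomal.to_numpy()] = zfst_transform(flagged.loc[autosomal, "fst"])
    flagged = flagged.assign(zfst=zfst)

    dd = None
    if d_target is not None and d_reference is not None:
        dd = np.abs(
            d_target["tajimas_d"].to_numpy(dtype=float)
            - d_reference["tajimas_d"].to_numpy(dtype=float)
        )

    regions = []
    for contig, grp in flagged.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        hit = grp[grp["outlier"]]
        if hit.empty:
            continue
        cur_start = cur_end = None
        members: list[int] = []

        def _close():
            rows = flagged.loc[members]
            rec = {
                "contig": contig,
                "start": int(cur_start),
                "end": int(cur_end),
                "n_windows": len(members),
                "fst_max": float(rows["fst"].max()),
                "fst_mean": float(rows["fst"].mean()),
                "zfst_max": float(np.nanmax(rows["zfst"])) if rows["zfst"].notna().any() else float("nan"),
                "log2_pi_ratio_mean": float(rows["log2_pi_ratio"].mean()),
            }
            rec["abs_tajimas_d_diff_mean"] = (
                float(np.nanmean(dd[members])) if dd is not None else float("nan")
            )
            regions.append(rec)

        for idx, row in hit.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = row["start"], row["end"], [idx]
            elif row["start"] <= cur_end:  # overlap or abut
                cur_end = max(cur_end, row["end"])
                members.append(idx)
            else:
                _close()
                cur_start, cur_end, members = row["start"], row["end"], [idx]
        _close()
    cols = [
        "contig", "start", "end", "n_windows", "fst_max", "fst_mean",
        "zfst_max", "log2_pi_ratio_mean", "abs_tajimas_d_diff_mean",
    ]
    out = pd.DataFrame(regions, columns=cols)
    out.attrs["thresholds"] = thresholds
    return out


def background_contrast(
    regions: pd.DataFrame,
    fst_table: pd.DataFrame,
    ratio_table: pd.DataFrame,
    z_contigs: Sequence[str] = (),
) -> pd.DataFrame:
    """Mann-Whitney U (two-sided) of in-region window values against the
    genome-wide window background, for zFST and the log2 pi-ratio."""
    if regions.empty:
        raise PopscanError("empty region set")
    autosomal = ~fst_table["contig"].isin(set(z_contigs))
    zfst = np.full(len(fst_table), np.nan)
    zfst[autosomal.to_numpy()] = zfst_transform(fst_table.loc[autosomal, "fst"])

    in_region = np.zeros(len(fst_table), dtype=bool)
    starts = fst_table["start"].to_numpy()
    ends = fst_table["end"].to_numpy()
    contigs = fst_table["contig"].to_numpy()
    for _, reg in regions.iterrows():
        in_region |= (
            (contigs == reg["contig"]) & (starts < reg["end"]) & (ends > reg["start"])
        )
    rows = []
    for name, vals in (
        ("zfst", zfst),
        ("log2_pi_ratio", ratio_table["log2_pi_ratio"].to_numpy(dtype=float)),
    ):
        a = vals[in_region & ~np.isnan(vals)]
        b = vals[~np.isnan(vals)]
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"statistic_name": name, "u": float(stat), "p_value": float(p),
                     "n_region_windows": int(len(a)), "n_background_windows": int(len(b))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def annotate_regions(regions: pd.DataFrame, gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Join genes overlapping each region by >= 1 bp (half-open intervals:
    a gene starting exactly at the region end is not joined)."""
    for col in ("contig", "start", "end", "gene_id"):
        if col not in gene_intervals.columns:
            raise PopscanError(f"gene intervals missing column {col!r}")
    if (gene_intervals["end"] <= gene_intervals["start"]).any():
        raise PopscanError("malformed gene interval with end <= start")
    out = regions.copy()
    genes_col = []
    for _, reg in out.iterrows():
        hit = gene_intervals[
            (gene_intervals["contig"] == reg["contig"])
            & (gene_intervals["start"] < reg["end"])
            & (gene_intervals["end"] > reg["start"])
        ]
        genes_col.append(",".join(hit["gene_id"].astype(str)))
    out["genes"] = genes_col
    return out


def shared_gene_counts(regions_by_population: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Count, for every gene, the number of population scans whose annotated
    regions contain it (the 'shared selected gene' tally)."""
    counts: dict[str, int] = {}
    for _, regions in regions_by_population.items():
        seen: set[str] = set()
        for g in regions.get("genes", pd.Series(dtype=str)).fillna(""):
            seen.update(x for x in str(g).split(",") if x)
        for g in seen:
            counts[g] = counts.get(g, 0) + 1
    return (
        pd.DataFrame(
            {"gene_id": list(counts), "n_populations": list(counts.values())}
        )
        .sort_values(["n_populations", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
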