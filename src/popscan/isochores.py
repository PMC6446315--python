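"""Isochore segmentation of a reference genome and variant-GC correlation.

The genome is tiled into fixed windows, each window classified into one of
the five canonical isochore families by its GC fraction over non-N bases
(left-closed bins, boundaries from the isochore literature):

    L1 < 37%  <= L2 < 41% <= H1 < 46% <= H2 < 53% <= H3

Consecutive same-family windows merge into segments whose GC is the
base-weighted mean; windows that are >= 50% N become unclassified ``gap``
segments, so segments always tile the contig exactly.  This is a
transparent classify-and-merge segmenter validated on constructed
references, standing in for heavier isochore segmentation tools; the family
thresholds are overridable.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import GenotypeMatrix, PopscanError, ReferenceGenome

#: family -> [low, high) GC bounds (left-closed; H3 is right-closed at 1)
DEFAULT_FAMILY_BOUNDS: dict[str, tuple[float, float]] = {
    "L1": (0.0, 0.37),
    "L2": (0.37, 0.41),
    "H1": (0.41, 0.46),
    "H2": (0.46, 0.53),
    "H3": (0.53, 1.0 + 1e-9),
}

GAP = "gap"


def classify_family(gc: float, bounds: Mapping[str, tuple[float, float]] = DEFAULT_FAMILY_BOUNDS) -> str:
    """Family label for a GC fraction; NaN (no informative bases) -> gap."""
    if np.isnan(gc):
        return GAP
    for fam, (lo, hi) in bounds.items():
        if lo <= gc < hi:
            return fam
    raise PopscanError(f"GC fraction {gc} outside [0,1]")


def _window_base_counts(reference: ReferenceGenome, contig: str, window_size: int):
    """Per-window (gc_bases, informative_bases, total_bases) via cumsums."""
    arr = reference.base_array(contig)
    is_gc = np.isin(arr, (ord("G"), ord("C")))
    is_acgt = np.isin(arr, (ord("A"), ord("C"), ord("G"), ord("T")))
    cg = np.concatenate(([0], np.cumsum(is_gc)))
    ci = np.concatenate(([0], np.cumsum(is_acgt)))
    length = len(arr)
    starts = np.arange(0, length, window_size)
    ends = np.minimum(starts + window_size, length)
    return starts, ends, cg[ends] - cg[starts], ci[ends] - ci[starts]


def segment_isochores(
    reference: ReferenceGenome,
    window_size: int,
    family_bounds: Mapping[str, tuple[float, float]] = DEFAULT_FAMILY_BOUNDS,
    max_n_fraction: float = 0.5,
) -> pd.DataFrame:
    """Classify fixed windows and merge same-family runs into segments.

    Returns a frame with ``contig, start, end, gc, family, n_windows``;
    segments tile each contig without gaps or overlaps, with ``gap``
    segments covering N-dominated stretches.
    """
    if window_size < 1:
        raise PopscanError("window_size must be positive")
    if not reference.sequences:
        raise PopscanError("empty reference")
    rows = []
    for contig, _ in reference.contigs:
        starts, ends, gc_b, inf_b = _window_base_counts(reference, contig, window_size)
        tot_b = ends - starts
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(inf_b > 0, gc_b / np.maximum(inf_b, 1), np.nan)
        n_frac = 1.0 - inf_b / tot_b
        fams = [
            GAP if n_frac[i] >= max_n_fraction else classify_family(gc[i], family_bounds)
            for i in range(len(starts))
        ]
        # run-length merge over consecutive same-family windows
        i = 0
        while i < len(starts):
            j = i
            while j + 1 < len(starts) and fams[j + 1] == fams[i]:
                j += 1
            seg_gc_b = int(gc_b[i : j + 1].sum())
            seg_inf_b = int(inf_b[i : j + 1].sum())
            rows.append(
                {
                    "contig": contig,
                    "start": int(starts[i]),
                    "end": int(ends[j]),
                    "gc": seg_gc_b / seg_inf_b if seg_inf_b else float("nan"),
                    "family": fams[i],
                    "n_windows": j - i + 1,
                }
            )
            i = j + 1
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gc", "family", "n_windows"])


def choose_gc_window(
    reference: ReferenceGenome,
    candidate_sizes: Sequence[int] = (10_000, 20_000, 50_000, 100_000, 200_000, 500_000, 750_000),
    tolerance: float = 0.05,
    min_segment_windows: int = 4,
) -> tuple[int, pd.DataFrame]:
    """Pick the smallest window size at which the GC-SD curve plateaus.

    For each candidate size the SD (n-1) of per-window GC is computed over
    windows belonging to segments of at least ``min_segment_windows``
    windows.  The chosen size is the smallest whose relative SD decrease to
    the next larger size falls below ``tolerance``; if the curve never
    plateaus the largest candidate is returned.
    """
    sizes = sorted(set(int(s) for s in candidate_sizes))
    if len(sizes) == 0:
        raise PopscanError("no candidate sizes")
    min_len = min(length for _, length in reference.contigs)
    if min_len < sizes[0]:
        raise PopscanError("contig shorter than the smallest candidate window")
    sds = []
    for size in sizes:
        vals = []
        for contig, _ in reference.contigs:
            starts, ends, gc_b, inf_b = _window_base_counts(reference, contig, size)
            with np.errstate(divide="ignore", invalid="ignore"):
                gc = np.where(inf_b > 0, gc_b / np.maximum(inf_b, 1), np.nan)
            n_frac = 1.0 - inf_b / (ends - starts)
            fams = np.array(
                [
                    GAP if n_frac[i] >= 0.5 else classify_family(gc[i])
                    for i in range(len(starts))
                ],
                dtype=object,
            )
            # keep windows inside runs of >= min_segment_windows same-family windows
            i = 0
            while i < len(fams):
                j = i
                while j + 1 < len(fams) and fams[j + 1] == fams[i]:
                    j += 1
                if j - i + 1 >= min_segment_windows and fams[i] != GAP:
                    vals.extend(gc[i : j + 1][~np.isnan(gc[i : j + 1])])
                i = j + 1
        sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"))
    table = pd.DataFrame({"size": sizes, "gc_sd": sds})
    if len(sizes) == 1:
        return sizes[0], table
    chosen = sizes[-1]
    for k in range(len(sizes) - 1):
        s0, s1 = sds[k], sds[k + 1]
        if np.isnan(s0) or np.isnan(s1) or s0 == 0:
            continue
        if (s0 - s1) / s0 < tolerance:
            chosen = sizes[k]
            break
    return chosen, table


def variant_gc_correlation(
    segments: pd.DataFrame,
    matrix: GenotypeMatrix,
    variant_class: str = "snp",
) -> dict:
    """Pearson correlation between segment GC and variant density.

    Counts SNPs and indels per classified segment, computes densities per
    Mb, and reports Pearson r/p of (GC, density) for the requested class
    plus the per-family share of classified variants.
    """
    if variant_class not in ("snp", "indel"):
        raise PopscanError("variant_class must be 'snp' or 'indel'")
    seg = segments[segments["family"] != GAP].reset_index(drop=True)
    if len(seg) < 3:
        raise PopscanError("need >= 3 classified segments for a correlation")
    is_indel = matrix.sites["is_indel"].to_numpy(dtype=bool)
    pos0 = matrix.sites["pos"].to_numpy() - 1
    contigs = matrix.sites["contig"].to_numpy()
    n_snp = np.zeros(len(seg), dtype=int)
    n_indel = np.zeros(len(seg), dtype=int)
    for i, row in seg.iterrows():
        inside = (contigs == row["contig"]) & (pos0 >= row["start"]) & (pos0 < row["end"])
        n_snp[i] = int((inside & ~is_indel).sum())
        n_indel[i] = int((inside & is_indel).sum())
    seg = seg.assign(n_snps=n_snp, n_indels=n_indel)
    length_mb = (seg["end"] - seg["start"]) / 1e6
    seg["snp_per_mb"] = seg["n_snps"] / length_mb
    seg["indel_per_mb"] = seg["n_indels"] / length_mb

    dens = seg["snp_per_mb"] if variant_class == "snp" else seg["indel_per_mb"]
    r, p = sps.pearsonr(seg["gc"], dens)

    counts = seg.groupby("family")[["n_snps", "n_indels"]].sum()
    col = "n_snps" if variant_class == "snp" else "n_indels"
    total = counts[col].sum()
    shares = {
        fam: 100.0 * counts.loc[fam, col] / total if total else float("nan")
        for fam in counts.index
    }
    return {
        "variant_class": variant_class,
        "pearson_r": float(r),
        "p_value": float(p),
        "segments": seg,
        "family_share_percent": shares,
    }
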