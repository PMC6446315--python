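"""Pairwise linkage disequilibrium r^2 within a distance cap and the
genome-averaged decay curve.

For phased haplotypes r^2 is the textbook haplotype-frequency form
``(p_AB - p_A p_B)^2 / (p_A q_A p_B q_B)``.  For unphased diploid dosages
the squared Pearson correlation of dosages is used as a documented
surrogate and flagged in the output metadata.  Sites below a minor-allele
frequency floor (default 0.05) are excluded to stabilize denominators.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import MISSING, PopscanError


def pairwise_r2(
    data: np.ndarray,
    positions: np.ndarray,
    contigs: np.ndarray | None = None,
    *,
    phased: bool,
    max_dist: int = 40_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """r^2 for all same-contig site pairs within ``max_dist`` bp.

    ``data`` is sites x haplotypes (0/1) when ``phased`` else sites x
    samples dosages (0/1/2, MISSING allowed).  Returns columns
    ``contig, pos_i, pos_j, dist, r2`` with ``phased`` recorded in
    ``DataFrame.attrs``.
    """
    data = np.asarray(data)
    positions = np.asarray(positions)
    if data.shape[0] != len(positions):
        raise PopscanError("data rows must match positions")
    if phased and data.shape[1] < 4:
        raise PopscanError("phased path needs >= 4 haplotypes")
    if not phased and data.shape[1] < 5:
        raise PopscanError("unphased path needs >= 5 diploids")
    if contigs is None:
        contigs = np.zeros(len(positions), dtype=int)
    contigs = np.asarray(contigs)

    rows = []
    for contig in pd.unique(contigs):
        m = contigs == contig
        pos = positions[m]
        block = data[m]
        order = np.argsort(pos)
        pos, block = pos[order], block[order]

        if phased:
            freq = block.mean(axis=1)
        else:
            miss = block == MISSING
            with np.errstate(invalid="ignore"):
                freq = np.where(miss, 0, block).sum(axis=1) / np.maximum(
                    2.0 * (~miss).sum(axis=1), 1
                )
        keep = np.minimum(freq, 1 - freq) >= maf_min
        pos, block, freq = pos[keep], block[keep], freq[keep]

        for i in range(len(pos)):
            j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            for j in range(i + 1, j_hi):
                if phased:
                    p_ab = float((block[i] & block[j]).mean())
                    denom = freq[i] * (1 - freq[i]) * freq[j] * (1 - freq[j])
                    r2 = (p_ab - freq[i] * freq[j]) ** 2 / denom
                else:
                    xi, xj = block[i].astype(float), block[j].astype(float)
                    ok = (block[i] != MISSING) & (block[j] != MISSING)
                    if ok.sum() < 3:
                        continue
                    with np.errstate(invalid="ignore"):
                        r = np.corrcoef(xi[ok], xj[ok])[0, 1]
                    if np.isnan(r):
                        continue
                    r2 = float(r) ** 2
                rows.append((contig, int(pos[i]), int(pos[j]), int(pos[j] - pos[i]), float(r2)))
    out = pd.DataFrame(rows, columns=["contig", "pos_i", "pos_j", "dist", "r2"])
    out.attrs["phased"] = phased
    out.attrs["max_dist"] = max_dist
    out.attrs["maf_min"] = maf_min
    return out


def decay_curve(
    pairs: pd.DataFrame,
    bin_width: int = 1_000,
    max_dist: int | None = None,
) -> pd.DataFrame:
    """Mean r^2 per distance bin; empty bins carry a missing mean, not 0."""
    if bin_width <= 0:
        raise PopscanError("bin_width must be positive")
    if pairs.empty:
        raise PopscanError("no pairs to bin")
    top = int(max_dist if max_dist is not None else pairs.attrs.get("max_dist", pairs["dist"].max()))
    edges = np.arange(0, top + bin_width, bin_width)
    idx = np.clip(np.digitize(pairs["dist"], edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=pairs["r2"], minlength=len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
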