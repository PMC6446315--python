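"""Allele-frequency-differential screen between two sample groups.

A site is a hit when the alternate-allele frequency (over non-missing
chromosomes) is above ``hi`` in one group and below ``lo`` in the other
(strict inequalities; defaults 0.8 / 0.2), and Pearson's chi-squared test
on the 2x2 allele-count table (no continuity correction by default) gives
``p < p_max``.  Benjamini–Hochberg q-values over the frequency-passing
candidates are reported alongside, but the raw-p filter is the default
decision rule.  Consequence annotations (synonymous / missense / nonsense /
noncoding ...) are consumed from an external table, never computed here.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import GenotypeMatrix, PopscanError

UNANNOTATED = "unannotated"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def screen_differential(
    matrix: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    hi: float = 0.8,
    lo: float = 0.2,
    p_max: float = 0.001,
    yates: bool = False,
) -> pd.DataFrame:
    """Flag near-fixed allele-frequency differences between two groups.

    Returns one row per hit with both group frequencies, the 2x2 allele
    counts, the chi-squared statistic, raw p and BH q (computed across all
    frequency-rule candidates), and the direction of the difference.
    """
    if hi <= lo:
        raise PopscanError("hi threshold must exceed lo")
    if set(group_a) & set(group_b):
        raise PopscanError("groups overlap")
    if len(group_a) < 5 or len(group_b) < 5:
        raise PopscanError("each group needs >= 5 diploids")

    alt_a, n_a = matrix.allele_counts(group_a)
    alt_b, n_b = matrix.allele_counts(group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.where(n_a > 0, alt_a / np.maximum(n_a, 1), np.nan)
        fb = np.where(n_b > 0, alt_b / np.maximum(n_b, 1), np.nan)
    up = (fa > hi) & (fb < lo)
    down = (fa < lo) & (fb > hi)
    cand = np.flatnonzero((up | down) & (n_a > 0) & (n_b > 0))

    rows = []
    for i in cand:
        table = np.array(
            [[alt_a[i], n_a[i] - alt_a[i]], [alt_b[i], n_b[i] - alt_b[i]]]
        )
        chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
        site = matrix.sites.iloc[i]
        rows.append(
            {
                "contig": site["contig"],
                "pos": int(site["pos"]),
                "ref": site["ref"],
                "alt": site["alt"],
                "freq_a": float(fa[i]),
                "freq_b": float(fb[i]),
                "alt_a": int(alt_a[i]),
                "ref_a": int(n_a[i] - alt_a[i]),
                "alt_b": int(alt_b[i]),
                "ref_b": int(n_b[i] - alt_b[i]),
                "chi2": float(chi2),
                "p_value": float(p),
                "direction": "a_high" if up[i] else "b_high",
            }
        )
    hits = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "freq_a", "freq_b",
            "alt_a", "ref_a", "alt_b", "ref_b", "chi2", "p_value", "direction",
        ],
    )
    if len(hits):
        hits["q_value"] = _bh_adjust(hits["p_value"].to_numpy())
        hits = hits[hits["p_value"] < p_max].reset_index(drop=True)
    else:
        hits["q_value"] = pd.Series(dtype=float)
    return hits


def read_annotations(path) -> pd.DataFrame:
    """Consequence annotations keyed by (contig, pos, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "alt": str})
    needed = {"contig", "pos", "alt", "consequence"}
    if not needed.issubset(df.columns):
        raise PopscanError(f"annotation table must provide columns {sorted(needed)}")
    return df


def join_consequences(
    hits: pd.DataFrame,
    annotations: pd.DataFrame,
    keep_classes: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """Join consequence classes onto hits and optionally filter.

    Unmatched hits are labeled ``unannotated`` and retained unless
    ``keep_classes`` is non-empty and excludes them.  Conflicting duplicate
    annotation keys are an error.
    """
    key_cols = ["contig", "pos", "alt"]
    ann = annotations.drop_duplicates(subset=key_cols + ["consequence"])
    if ann.duplicated(subset=key_cols).any():
        dup = ann[ann.duplicated(subset=key_cols, keep=False)]
        raise PopscanError(
            "conflicting consequence classes for keys: "
            + ", ".join(
                f"{r.contig}:{r.pos}:{r.alt}" for r in dup.drop_duplicates(key_cols).itertuples()
            )
        )
    out = hits.merge(ann[key_cols + ["consequence"]], on=key_cols, how="left")
    out["consequence"] = out["consequence"].fillna(UNANNOTATED)
    report = {
        "n_hits": len(out),
        "n_annotated": int((out["consequence"] != UNANNOTATED).sum()),
        "n_unannotated": int((out["consequence"] == UNANNOTATED).sum()),
    }
    if keep_classes:
        keep = set(keep_classes)
        kept = out[out["consequence"].isin(keep)].reset_index(drop=True)
        report["n_kept"] = len(kept)
        report["n_filtered_out"] = len(out) - len(kept)
        return kept, report
    report["n_kept"] = len(out)
    report["n_filtered_out"] = 0
    return out, report
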