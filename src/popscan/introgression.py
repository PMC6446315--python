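"""ABBA-BABA introgression tests and IBD tract summaries.

The D-statistic is computed from population derived-allele frequencies:

    D = sum[(1 - p1) p2 p3 - p1 (1 - p2) p3]
        / sum[(1 - p1) p2 p3 + p1 (1 - p2) p3]

over sites polarized against an outgroup that is fixed at each kept site
(the outgroup enters only through polarization; its frequency does not
appear in the sums).  A positive D indicates excess derived-allele sharing
between P2 and P3 — gene flow between them, if P1 and P2 are sister
populations.  Significance uses a delete-one block jackknife over
contiguous genomic blocks (default 1 Mb), an addition documented as such:
the estimator itself carries no analytic variance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, PopulationManifest, PopscanError


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize_alleles(
    matrix: GenotypeMatrix,
    outgroup: Sequence[str],
    populations: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, dict]:
    """Derived-allele frequencies per population at outgroup-fixed sites.

    A site is kept when the outgroup's non-missing chromosomes are fixed;
    the derived allele is the one absent from the outgroup.  Returns a frame
    with ``contig, pos`` and one ``p:<name>`` column per population, plus a
    report of dropped-site counts.
    """
    if not outgroup:
        raise PopscanError("empty outgroup")
    og_alt, og_n = matrix.allele_counts(outgroup)
    fixed_ref = (og_n > 0) & (og_alt == 0)
    fixed_alt = (og_n > 0) & (og_alt == og_n)
    keep = fixed_ref | fixed_alt
    report = {
        "n_sites": matrix.n_sites,
        "n_kept": int(keep.sum()),
        "n_outgroup_polymorphic": int((~keep & (og_n > 0)).sum()),
        "n_outgroup_missing": int((og_n == 0).sum()),
    }
    out = matrix.sites.loc[keep, ["contig", "pos"]].reset_index(drop=True)
    for name, samples in populations.items():
        alt, n = matrix.allele_counts(samples)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_alt = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        derived = np.where(fixed_alt, 1.0 - p_alt, p_alt)
        out[f"p:{name}"] = derived[keep]
    return out, report


# ---------------------------------------------------------------------------
# D-statistic
# ---------------------------------------------------------------------------

@dataclass
class DStatResult:
    d: float
    abba: float
    baba: float
    n_sites: int  # informative sites (nonzero ABBA+BABA weight)
    se: float
    z: float
    n_blocks: int
    se_reliable: bool

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.d <= 1.0 + 1e-12

    def summary(self) -> str:
        flag = "" if self.se_reliable else " (SE unreliable: <5 blocks)"
        return (
            f"D = {self.d:+.4f}  ABBA = {self.abba:.2f}  BABA = {self.baba:.2f}  "
            f"informative sites = {self.n_sites}  "
            f"jackknife SE = {self.se:.4f}  Z = {self.z:+.2f} "
            f"[{self.n_blocks} blocks]{flag}"
        )


def d_statistic(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    positions: np.ndarray | None = None,
    contigs: np.ndarray | None = None,
    block_size: int = 1_000_000,
) -> DStatResult:
    """Frequency-based ABBA-BABA D with delete-one block-jackknife SE.

    ``p1, p2, p3`` are aligned derived-allele frequency vectors at polarized
    sites.  When ``positions`` (1-based) are given, jackknife blocks are
    contiguous genomic intervals of ``block_size`` bp (per contig);
    otherwise sites are blocked by index.
    """
    p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p1, p2, p3))
    if not (len(p1) == len(p2) == len(p3)):
        raise PopscanError("frequency vectors of unequal length")
    if block_size <= 0:
        raise PopscanError("block_size must be positive")
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3))
    abba = (1.0 - p1) * p2 * p3
    baba = p1 * (1.0 - p2) * p3
    abba[~ok] = 0.0
    baba[~ok] = 0.0
    num = abba - baba
    den = abba + baba
    total_den = float(den.sum())
    if total_den == 0:
        raise PopscanError("no informative sites: ABBA + BABA = 0 everywhere")
    d_full = float(num.sum()) / total_den

    if positions is not None:
        positions = np.asarray(positions)
        if contigs is None:
            contigs = np.zeros(len(positions), dtype=int)
        contigs = np.asarray(contigs)
        keys = pd.factorize(
            pd.Series(contigs).astype(str) + ":" + pd.Series(positions // block_size).astype(str)
        )[0]
    else:
        keys = np.arange(len(p1)) // max(1, block_size)

    num_b = np.bincount(keys, weights=num)
    den_b = np.bincount(keys, weights=den)
    nonempty = den_b != 0
    g = int(nonempty.sum())
    num_b, den_b = num_b[nonempty], den_b[nonempty]
    if g < 2:
        se, z, reliable = float("nan"), float("nan"), False
    else:
        d_loo = (num.sum() - num_b) / (den.sum() - den_b)
        se = float(np.sqrt((g - 1) / g * ((d_loo - d_loo.mean()) ** 2).sum()))
        z = 0.0 if se == 0 and d_full == 0 else (d_full / se if se > 0 else float("inf"))
        reliable = g >= 5
    return DStatResult(
        d=d_full,
        abba=float(abba.sum()),
        baba=float(baba.sum()),
        n_sites=int((den > 0).sum()),
        se=se,
        z=float(z),
        n_blocks=g,
        se_reliable=reliable,
    )


def d_statistic_from_matrix(
    matrix: GenotypeMatrix,
    p1_samples: Sequence[str],
    p2_samples: Sequence[str],
    p3_samples: Sequence[str],
    outgroup: Sequence[str],
    block_size: int = 1_000_000,
) -> tuple[DStatResult, dict]:
    """Polarize against the outgroup and compute D(P1, P2, P3, outgroup)."""
    freqs, report = polarize_alleles(
        matrix, outgroup, {"P1": p1_samples, "P2": p2_samples, "P3": p3_samples}
    )
    res = d_statistic(
        freqs["p:P1"].to_numpy(),
        freqs["p:P2"].to_numpy(),
        freqs["p:P3"].to_numpy(),
        positions=freqs["pos"].to_numpy(),
        contigs=freqs["contig"].to_numpy(),
        block_size=block_size,
    )
    return res, report


# ---------------------------------------------------------------------------
# IBD tract summaries
# ---------------------------------------------------------------------------

IBD_COLUMNS = ["sample1", "sample2", "contig", "start", "end", "score"]


def read_ibd_tracts(path) -> pd.DataFrame:
    """BEAGLE-style IBD tract TSV: sample1, sample2, contig, start, end[, score]."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    rename = {cols[c]: c for c in IBD_COLUMNS if c in cols}
    df = df.rename(columns=rename)
    if "score" not in df.columns:
        df["score"] = np.nan
    missing = [c for c in IBD_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise PopscanError(f"IBD tract table missing columns {missing}")
    return df[IBD_COLUMNS]


def ibd_summary(
    tracts: pd.DataFrame,
    manifest: PopulationManifest,
    normalize_by: str = "pair",
) -> pd.DataFrame:
    """Per-population-pair tract counts and length statistics.

    ``normalize_by`` controls the 'average number of IBDs' column: ``pair``
    divides the tract count by the number of cross-population sample pairs,
    ``second`` by the number of samples in the pair's second population
    (tracts per recipient sample).
    """
    if len(tracts) and (tracts["end"] <= tracts["start"]).any():
        raise PopscanError("IBD tract with end <= start")
    pop_of = manifest.populations
    pop_sizes: dict[str, int] = {}
    for p in pop_of.values():
        pop_sizes[p] = pop_sizes.get(p, 0) + 1

    rows: dict[tuple[str, str], dict] = {}
    for _, t in tracts.iterrows():
        try:
            pa, pb = pop_of[t["sample1"]], pop_of[t["sample2"]]
        except KeyError as exc:
            raise PopscanError(f"tract sample {exc} absent from manifest") from exc
        key = tuple(sorted((pa, pb)))
        rec = rows.setdefault(key, {"n_tracts": 0, "total_bp": 0})
        rec["n_tracts"] += 1
        rec["total_bp"] += int(t["end"] - t["start"])

    out = []
    for (pa, pb), rec in sorted(rows.items()):
        na, nb = pop_sizes[pa], pop_sizes[pb]
        n_pairs = na * nb if pa != pb else na * (na - 1) // 2
        denom = n_pairs if normalize_by == "pair" else nb
        out.append(
            {
                "population_a": pa,
                "population_b": pb,
                "n_tracts": rec["n_tracts"],
                "total_length_bp": rec["total_bp"],
                "mean_length_bp": rec["total_bp"] / rec["n_tracts"],
                "n_sample_pairs": n_pairs,
                "tracts_per_unit": rec["n_tracts"] / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "population_a", "population_b", "n_tracts", "total_length_bp",
            "mean_length_bp", "n_sample_pairs", "tracts_per_unit",
        ],
    )
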