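"""Shared data model and readers/writers for the formats the pipeline touches.

Coordinate conventions, stated once and used everywhere:

* variant sites are 1-based, as printed in a VCF ``POS`` column;
* windows, sweep regions, isochore segments and all BED output are 0-based
  half-open ``[start, end)``.

The central container is :class:`GenotypeMatrix`, a site x sample matrix of
diploid alternate-allele dosages (0, 1, 2 or missing) with contig and site
metadata, alongside a :class:`PopulationManifest` mapping samples to
populations and analysis roles.  Window-level results are plain
:class:`pandas.DataFrame` objects with a documented schema (columns
``contig, start, end, n_snps, truncated`` plus one column per statistic).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid dosage.
MISSING = -1

SITE_COLUMNS = ["contig", "pos", "ref", "alt", "is_indel"]
WINDOW_KEY = ["contig", "start", "end"]


class PopscanError(ValueError):
    """Raised on contract violations (bad inputs, malformed files)."""


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic variant sites with per-sample diploid dosages.

    Parameters
    ----------
    contigs
        Ordered ``(name, length_bp)`` pairs for every contig referenced.
    sites
        DataFrame with columns ``contig, pos, ref, alt, is_indel``;
        ``pos`` is 1-based and strictly increasing within each contig.
    dosages
        ``(n_sites, n_samples)`` int8 array of alternate-allele counts per
        diploid genotype; :data:`MISSING` marks a missing call.
    sample_ids
        Ordered sample names matching the dosage columns.
    """

    contigs: list[tuple[str, int]]
    sites: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.sample_ids)):
            raise PopscanError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise PopscanError("dosages must be in {0,1,2} or MISSING")
        known = {name for name, _ in self.contigs}
        if not set(self.sites["contig"]).issubset(known):
            raise PopscanError("sites reference contigs absent from the contig list")
        for name, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos"].to_numpy()
            # ties are allowed only for split multi-allelics (distinct alts)
            if len(pos) > 1 and not (np.diff(pos) >= 0).all():
                raise PopscanError(f"positions not sorted on {name}")
            if grp.duplicated(subset=["pos", "alt"]).any():
                raise PopscanError(f"duplicate (pos, alt) site on {name}")

    # -- basic views ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise PopscanError(f"samples absent from matrix: {sorted(missing)}")
        return np.array([lookup[s] for s in samples], dtype=int)

    # -- per-site summaries ----------------------------------------------

    def allele_counts(self, samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, non-missing chromosome count) in a sample set."""
        d = self.dosages[:, self.sample_indices(samples)]
        miss = d == MISSING
        alt = np.where(miss, 0, d).sum(axis=1)
        n_chrom = 2 * (d.shape[1] - miss.sum(axis=1))
        return alt.astype(np.int64), n_chrom.astype(np.int64)

    def het_counts(self, samples: Sequence[str]) -> np.ndarray:
        """Per-site count of heterozygous genotypes in a sample set."""
        d = self.dosages[:, self.sample_indices(samples)]
        return (d == 1).sum(axis=1).astype(np.int64)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            contigs=list(self.contigs),
            sites=self.sites.loc[np.asarray(mask)],
            dosages=self.dosages[np.asarray(mask)],
            sample_ids=list(self.sample_ids),
        )


# ---------------------------------------------------------------------------
# Population manifest
# ---------------------------------------------------------------------------

@dataclass
class PopulationManifest:
    """Sample -> population labels plus optional per-sample analysis roles.

    Roles are free-form strings (``sweep_target``, ``P1`` .. ``P3``,
    ``outgroup``, ``groupA``/``groupB``, ...) used to wire samples into the
    pipeline stages.
    """

    populations: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.populations)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        out = [s for s, p in self.populations.items() if p == population]
        if not out:
            raise PopscanError(f"no samples in population {population!r}")
        return out

    def samples_with_role(self, role: str) -> list[str]:
        out = [s for s, r in self.roles.items() if r == role]
        if not out:
            raise PopscanError(f"no samples with role {role!r}")
        return out

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = sorted(set(self.populations) - set(matrix.sample_ids))
        if missing:
            raise PopscanError(
                f"manifest samples absent from variant data: {missing}"
            )


def read_manifest(path: str | Path) -> PopulationManifest:
    """Read a TSV with header ``sample_id<TAB>population[<TAB>role]``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise PopscanError(f"manifest missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise PopscanError(f"duplicate manifest samples: {dups}")
    pops = dict(zip(df["sample_id"], df["population"]))
    roles: dict[str, str] = {}
    if "role" in df.columns:
        for s, r in zip(df["sample_id"], df["role"]):
            if isinstance(r, str) and r and r.lower() != "nan":
                roles[s] = r
    return PopulationManifest(populations=pops, roles=roles)


def write_manifest(manifest: PopulationManifest, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s,
            "population": p,
            "role": manifest.roles.get(s, ""),
        }
        for s, p in manifest.populations.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_variants(
    vcf_path: str | Path,
    manifest_path: str | Path | None = None,
    *,
    drop_multiallelic: bool = True,
    split_multiallelic: bool = False,
    max_missing: float = 0.2,
) -> tuple[GenotypeMatrix, PopulationManifest | None]:
    """Read biallelic diploid calls from a sorted VCF into a GenotypeMatrix.

    Dosage is the alternate-allele count of the GT field; any genotype with
    a missing allele becomes :data:`MISSING`.  Multi-allelic records are
    dropped by default or split into one biallelic site per alternate allele
    when ``split_multiallelic`` is set.  Sites whose missing-genotype
    fraction exceeds ``max_missing`` are dropped (set ``max_missing=1`` to
    keep everything).
    """
    from cyvcf2 import VCF

    if drop_multiallelic and split_multiallelic:
        drop_multiallelic = False
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)

    header_lengths = dict(zip(vcf.seqnames, vcf.seqlens or [])) if vcf.seqnames else {}

    rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    seen_contigs: list[str] = []
    last_pos: dict[str, int] = {}
    for v in vcf:
        if v.CHROM not in last_pos:
            if v.CHROM in seen_contigs:
                raise PopscanError(f"unsorted VCF: contig {v.CHROM} appears twice")
            seen_contigs.append(v.CHROM)
        elif v.POS < last_pos[v.CHROM]:
            raise PopscanError(
                f"unsorted VCF: {v.CHROM}:{v.POS} after {last_pos[v.CHROM]}"
            )
        last_pos[v.CHROM] = v.POS

        alts = v.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1:
            if drop_multiallelic and not split_multiallelic:
                continue
            gts = np.array([g[:2] for g in v.genotypes], dtype=int)
            for ai, alt in enumerate(alts, start=1):
                dos = (gts == ai).sum(axis=1).astype(np.int8)
                dos[(gts < 0).any(axis=1)] = MISSING
                rows.append(
                    (v.CHROM, v.POS, v.REF, alt, len(v.REF) != 1 or len(alt) != 1)
                )
                dosage_rows.append(dos)
            continue
        # gts012 gives 0/1/2 dosage directly, 3 = missing
        dos = v.gt_types.astype(np.int8)
        dos[dos == 3] = MISSING
        rows.append(
            (v.CHROM, v.POS, v.REF, alts[0], len(v.REF) != 1 or len(alts[0]) != 1)
        )
        dosage_rows.append(dos)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosages = (
        np.vstack(dosage_rows)
        if dosage_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    if max_missing < 1 and len(sites):
        frac = (dosages == MISSING).mean(axis=1)
        keep = frac <= max_missing
        sites, dosages = sites.loc[keep], dosages[keep]

    contigs = [
        (c, int(header_lengths.get(c, last_pos.get(c, 0)))) for c in seen_contigs
    ]
    # retain header contigs even if empty of sites, in header order
    if header_lengths:
        contigs = [(c, int(l)) for c, l in header_lengths.items()]
    matrix = GenotypeMatrix(contigs, sites, dosages, samples)

    manifest = None
    if manifest_path is not None:
        manifest = read_manifest(manifest_path)
        manifest.validate_against(matrix)
    return matrix, manifest


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_variants(
    matrix: GenotypeMatrix,
    path: str | Path,
    *,
    haplotypes: np.ndarray | None = None,
) -> None:
    """Write a minimal VCF 4.2.  With ``haplotypes`` (site x 2*n_samples,
    sample i owning columns 2i, 2i+1) genotypes are written phased."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=popscan\n')
        for name, length in matrix.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        sites = matrix.sites
        for i in range(matrix.n_sites):
            row = sites.iloc[i]
            if haplotypes is not None:
                gts = [
                    f"{haplotypes[i, 2 * j]}|{haplotypes[i, 2 * j + 1]}"
                    if matrix.dosages[i, j] != MISSING
                    else ".|."
                    for j in range(matrix.n_samples)
                ]
            else:
                gts = [_DOSAGE_TO_GT[int(d)] for d in matrix.dosages[i]]
            fh.write(
                f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Uppercased reference sequences with per-contig lengths; N's retained."""

    sequences: dict[str, str]

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    def base_array(self, contig: str) -> np.ndarray:
        return np.frombuffer(self.sequences[contig].encode("ascii"), dtype=np.uint8)

    def gc_fraction(self, contig: str, start: int = 0, end: int | None = None) -> float:
        """GC over non-N bases in ``[start, end)``; NaN when no informative base."""
        arr = self.base_array(contig)[start:end]
        gc = np.isin(arr, (ord("G"), ord("C"))).sum()
        informative = np.isin(arr, (ord("A"), ord("C"), ord("G"), ord("T"))).sum()
        return float(gc) / informative if informative else float("nan")


def read_reference(path: str | Path) -> ReferenceGenome:
    from pyfaidx import Fasta

    try:
        fa = Fasta(str(path), sequence_always_upper=True, duplicate_action="stop")
    except ValueError as exc:
        raise PopscanError(f"bad reference FASTA: {exc}") from exc
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return ReferenceGenome(sequences=seqs)


def write_reference(reference: ReferenceGenome | Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seqs = reference.sequences if isinstance(reference, ReferenceGenome) else reference
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping | None = None) -> None:
    """TSV with optional ``# key=value`` comment lines above the header."""
    with open(path, "w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_regions_bed(regions: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """BED (0-based half-open) from any table with contig/start/end columns."""
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            name = str(row[name_col]) if name_col and name_col in regions.columns else "."
            fh.write(f"{row['contig']}\t{int(row['start'])}\t{int(row['end'])}\t{name}\n")


def write_tables(objects: Mapping[str, pd.DataFrame], out_dir: str | Path,
                 metadata: Mapping | None = None) -> list[Path]:
    """Write each named table as ``<name>.tsv``; tables with region
    coordinates additionally as ``<name>.bed``.  Returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in objects.items():
        p = out / f"{name}.tsv"
        write_table(df, p, metadata)
        written.append(p)
        if {"contig", "start", "end"}.issubset(df.columns):
            b = out / f"{name}.bed"
            write_regions_bed(df, b)
            written.append(b)
    return written


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (contig,start,end,name) or TSV with a header."""
    first = open(path).readline()
    if first.lower().startswith(("contig", "chrom", "#contig", "#chrom")):
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        cols = {c.lower(): c for c in df.columns}
        rename = {}
        for want, aliases in {
            "contig": ("contig", "chrom", "chromosome"),
            "start": ("start",),
            "end": ("end", "stop"),
            "gene_id": ("gene_id", "gene", "name", "id"),
        }.items():
            for a in aliases:
                if a in cols:
                    rename[cols[a]] = want
                    break
        df = df.rename(columns=rename)
    else:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["contig", "start", "end", "gene_id"],
        )
    needed = {"contig", "start", "end", "gene_id"}
    if not needed.issubset(df.columns):
        raise PopscanError(f"gene interval table must provide columns {sorted(needed)}")
    df = df[["contig", "start", "end", "gene_id"]].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise PopscanError("gene interval with end <= start")
    return df


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
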