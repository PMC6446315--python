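"""Synthetic cohorts with known truth for every pipeline stage.

The generator emulates, structurally, a multi-population diploid resequencing
cohort with a diverged outgroup: ancestral allele frequencies are drawn from
a neutral (~1/i) or uniform spectrum, population frequencies follow the
Balding–Nichols model ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` whose expected
Weir–Cockerham FST is the divergence parameter ``F``, haplotypes are either
independent Bernoulli draws or mosaics of ``K`` founder haplotypes with a
per-bp recombination switch rate (giving distance-decaying LD), and the
outgroup is emitted fixed for the ancestral (reference) allele at every site
so that polarization is exact.

Selective sweeps are implanted by driving segregating sites inside a target
interval to fixation with a given probability (depressing diversity and
inflating differentiation); introgression is implanted by copying
geometric-length tracts from donor haplotypes into a fraction of recipient
haplotypes.  Every randomization is recorded in a truth record so recovery
tests can compare calls against the implanted signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    GenotypeMatrix,
    PopulationManifest,
    PopscanError,
    ReferenceGenome,
    write_json,
    write_manifest,
    write_reference,
    write_variants,
)

OUTGROUP = "outgroup"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """Locally fix segregating sites in one population's haplotypes."""

    contig: str
    start: int  # 0-based half-open interval on the contig
    end: int
    target_pop: str
    fixation_prob: float = 0.9


@dataclass
class IntrogressionSpec:
    """Copy donor tracts into a fraction of recipient haplotypes.

    ``fraction`` is the share of recipient haplotypes that carry donor
    ancestry.  A carrier haplotype is tiled with introgressed tracts of
    geometrically distributed length (mean ``tract_mean_bp``), each copied
    from an independently chosen donor haplotype; with ``coverage`` < 1,
    resident gaps alternate with the tracts so carriers average that much
    donor ancestry instead of being fully donor-derived.
    """

    donor_pop: str
    recipient_pop: str
    fraction: float
    tract_mean_bp: float = 50_000.0
    coverage: float = 1.0


@dataclass
class ScenarioConfig:
    """Complete description of one synthetic cohort.

    Defaults mirror the study-scale design the pipeline targets: tens of
    diploids per population, ~2 variant sites per kb, moderate divergence
    (F = 0.1), a fixed-ancestral outgroup, and an optional low-diversity
    "Z" contig with site density scaled by ``z_theta_scale``.
    """

    contigs: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 10_000_000)])
    pop_sizes: dict[str, int] = field(default_factory=lambda: {"popA": 25, "popB": 25})
    fst: float | dict[str, float] = 0.1
    n_outgroup: int = 2
    site_density: float = 0.002  # sites per bp
    sfs_mode: str = "neutral"  # "neutral" (~1/i) or "uniform" (U(0.05, 0.95))
    sfs_panel: int = 500  # notional panel size for the 1/i spectrum
    founder_haplotypes: int = 0  # 0 = independent haplotypes (no mosaic LD)
    recomb_rate: float = 1e-6  # per-bp founder-switch rate in mosaic mode
    z_contigs: tuple[str, ...] = ()
    z_theta_scale: float = 0.5
    sweeps: list[SweepSpec] = field(default_factory=list)
    introgressions: list[IntrogressionSpec] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)  # population -> role
    seed: int = 0

    def pop_f(self, pop: str) -> float:
        f = self.fst[pop] if isinstance(self.fst, dict) else self.fst
        if not 0.0 < f < 1.0:
            raise PopscanError(f"divergence F for {pop!r} must be in (0,1), got {f}")
        return float(f)

    def validate(self) -> None:
        if self.seed is None:
            raise PopscanError("a seed is mandatory for reproducibility")
        lengths = dict(self.contigs)
        for sw in self.sweeps:
            if sw.contig not in lengths or not 0 <= sw.start < sw.end <= lengths[sw.contig]:
                raise PopscanError(f"sweep interval outside contig bounds: {sw}")
            if not 0.0 <= sw.fixation_prob <= 1.0:
                raise PopscanError("fixation_prob must be in [0,1]")
            if sw.target_pop not in self.pop_sizes:
                raise PopscanError(f"sweep target {sw.target_pop!r} not a population")
        for ig in self.introgressions:
            if ig.donor_pop == ig.recipient_pop:
                raise PopscanError("introgression donor must differ from recipient")
            if not 0.0 <= ig.fraction <= 1.0:
                raise PopscanError("introgression fraction must be in [0,1]")
        for pop in self.pop_sizes:
            self.pop_f(pop)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Phased haplotypes plus derived genotype matrix, manifest and truth."""

    config: ScenarioConfig
    sites: pd.DataFrame  # contig, pos, ref, alt, is_indel
    haplotypes: np.ndarray  # (n_sites, 2 * n_diploids) int8 in {0,1}
    sample_ids: list[str]
    manifest: PopulationManifest
    truth: dict

    @property
    def matrix(self) -> GenotypeMatrix:
        dos = (self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]).astype(np.int8)
        return GenotypeMatrix(
            contigs=list(self.config.contigs),
            sites=self.sites,
            dosages=dos,
            sample_ids=list(self.sample_ids),
        )

    def haplotype_columns(self, pop: str) -> np.ndarray:
        cols = []
        for j, s in enumerate(self.sample_ids):
            if self.manifest.populations[s] == pop:
                cols.extend((2 * j, 2 * j + 1))
        if not cols:
            raise PopscanError(f"population {pop!r} has no samples")
        return np.array(cols, dtype=int)

    def site_mask(self, contig: str, start: int | None = None, end: int | None = None) -> np.ndarray:
        m = (self.sites["contig"] == contig).to_numpy()
        if start is not None:
            m &= (self.sites["pos"].to_numpy() - 1) >= start
        if end is not None:
            m &= (self.sites["pos"].to_numpy() - 1) < end
        return m

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "manifest": out / "manifest.tsv",
            "truth": out / "truth.json",
        }
        write_variants(self.matrix, paths["vcf"], haplotypes=self.haplotypes)
        write_manifest(self.manifest, paths["manifest"])
        truth = dict(self.truth)
        truth["seed"] = self.config.seed
        write_json(truth, paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Frequency and haplotype machinery
# ---------------------------------------------------------------------------

def _ancestral_frequencies(n: int, config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    if config.sfs_mode == "uniform":
        return rng.uniform(0.05, 0.95, size=n)
    if config.sfs_mode != "neutral":
        raise PopscanError(f"unknown sfs_mode {config.sfs_mode!r}")
    i = np.arange(1, config.sfs_panel)
    w = 1.0 / i
    counts = rng.choice(i, size=n, p=w / w.sum())
    return counts / config.sfs_panel


def _population_frequencies(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw; E = p, Var = F p (1-p), hence E(FST) = F."""
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def _mosaic_haplotypes(
    freqs: np.ndarray,
    positions: np.ndarray,
    n_hap: int,
    k_founders: int,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotypes as founder mosaics; K=0 or K>=n_hap means independent draws."""
    n_sites = len(freqs)
    if k_founders <= 0 or k_founders >= n_hap:
        return (rng.random((n_sites, n_hap)) < freqs[:, None]).astype(np.int8)
    founders = (rng.random((n_sites, k_founders)) < freqs[:, None]).astype(np.int8)
    gaps = np.diff(positions.astype(float))
    p_switch = 1.0 - np.exp(-rho * gaps)
    haps = np.empty((n_sites, n_hap), dtype=np.int8)
    for h in range(n_hap):
        idx = np.empty(n_sites, dtype=int)
        cur = rng.integers(k_founders)
        idx[0] = cur
        switches = rng.random(n_sites - 1) < p_switch
        for s in range(1, n_sites):
            if switches[s - 1]:
                cur = rng.integers(k_founders)
            idx[s] = cur
        haps[:, h] = founders[np.arange(n_sites), idx]
    return haps


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def simulate_cohort(config: ScenarioConfig) -> SimulatedCohort:
    """Draw a full cohort (sites, phased haplotypes, manifest, truth record)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    pops = list(config.pop_sizes)
    sample_ids: list[str] = []
    populations: dict[str, str] = {}
    for pop in pops:
        for i in range(config.pop_sizes[pop]):
            s = f"{pop}_{i:03d}"
            sample_ids.append(s)
            populations[s] = pop
    for i in range(config.n_outgroup):
        s = f"{OUTGROUP}_{i:03d}"
        sample_ids.append(s)
        populations[s] = OUTGROUP

    roles = {}
    for s, pop in populations.items():
        role = config.roles.get(pop)
        if pop == OUTGROUP and role is None:
            role = OUTGROUP
        if role:
            roles[s] = role
    manifest = PopulationManifest(populations=populations, roles=roles)

    site_frames = []
    hap_blocks = []
    truth_freqs: dict[str, dict] = {}
    for contig, length in config.contigs:
        density = config.site_density
        if contig in config.z_contigs:
            # a low-diversity sex chromosome: theta scaled via site density
            density *= config.z_theta_scale
        n_sites = rng.binomial(length, density)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        anc = _ancestral_frequencies(n_sites, config, rng)

        pop_haps = []
        contig_truth = {"ancestral": anc, "pops": {}}
        for pop in pops:
            pf = _population_frequencies(anc, config.pop_f(pop), rng)
            contig_truth["pops"][pop] = pf
            pop_haps.append(
                _mosaic_haplotypes(
                    pf, positions, 2 * config.pop_sizes[pop],
                    config.founder_haplotypes, config.recomb_rate, rng,
                )
            )
        # outgroup fixed for the ancestral (= reference) allele
        pop_haps.append(np.zeros((n_sites, 2 * config.n_outgroup), dtype=np.int8))
        hap_blocks.append(np.hstack(pop_haps))
        truth_freqs[contig] = contig_truth
        site_frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": positions,
                    "ref": "A",
                    "alt": "G",
                    "is_indel": False,
                }
            )
        )

    cohort = SimulatedCohort(
        config=config,
        sites=pd.concat(site_frames, ignore_index=True),
        haplotypes=np.vstack(hap_blocks),
        sample_ids=sample_ids,
        manifest=manifest,
        truth={
            "frequencies": {
                c: {
                    "ancestral": t["ancestral"],
                    **{f"pop:{p}": f for p, f in t["pops"].items()},
                }
                for c, t in truth_freqs.items()
            },
            "sweeps": [],
            "introgression_tracts": [],
        },
    )
    for sw in config.sweeps:
        implant_sweep(cohort, sw, rng)
    for ig in config.introgressions:
        implant_introgression(cohort, ig, rng)
    return cohort


def implant_sweep(cohort: SimulatedCohort, spec: SweepSpec, rng: np.random.Generator | None = None) -> dict:
    """Drive segregating sites in the interval to fixation in the target pop.

    Each site segregating among the target population's haplotypes is, with
    probability ``fixation_prob``, set to its current major allele on every
    target haplotype (ties resolved to the ancestral allele), so diversity
    collapses inside the interval while differentiation rises.
    """
    if spec.target_pop not in cohort.config.pop_sizes:
        raise PopscanError(f"sweep target {spec.target_pop!r} not in manifest")
    rng = rng if rng is not None else np.random.default_rng(cohort.config.seed + 1)
    cols = cohort.haplotype_columns(spec.target_pop)
    mask = cohort.site_mask(spec.contig, spec.start, spec.end)
    idx = np.flatnonzero(mask)
    block = cohort.haplotypes[np.ix_(idx, cols)]
    freq = block.mean(axis=1)
    seg = (freq > 0) & (freq < 1)
    hit = seg & (rng.random(len(idx)) < spec.fixation_prob)
    major = (freq > 0.5).astype(np.int8)
    block[hit, :] = major[hit, None]
    cohort.haplotypes[np.ix_(idx, cols)] = block
    record = {
        "contig": spec.contig,
        "start": spec.start,
        "end": spec.end,
        "target_pop": spec.target_pop,
        "fixation_prob": spec.fixation_prob,
        "n_sites_fixed": int(hit.sum()),
    }
    cohort.truth["sweeps"].append(record)
    return record


def implant_introgression(
    cohort: SimulatedCohort,
    spec: IntrogressionSpec,
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Copy geometric-length donor tracts into recipient haplotypes."""
    if not 0.0 <= spec.fraction <= 1.0:
        raise PopscanError("introgression fraction outside [0,1]")
    if spec.donor_pop == spec.recipient_pop:
        raise PopscanError("donor and recipient populations must differ")
    rng = rng if rng is not None else np.random.default_rng(cohort.config.seed + 2)
    donor_cols = cohort.haplotype_columns(spec.donor_pop)
    recip_cols = cohort.haplotype_columns(spec.recipient_pop)
    n_carriers = int(round(spec.fraction * len(recip_cols)))
    carriers = rng.choice(recip_cols, size=n_carriers, replace=False)
    cov = min(max(spec.coverage, 1e-9), 1.0)
    gap_mean = spec.tract_mean_bp * (1.0 - cov) / cov
    tracts: list[dict] = []
    for contig, length in cohort.config.contigs:
        cmask = cohort.site_mask(contig)
        pos0 = cohort.sites.loc[cmask, "pos"].to_numpy() - 1
        base = np.flatnonzero(cmask)
        for hap in carriers:
            x = rng.exponential(gap_mean) if gap_mean > 0 else 0.0
            while x < length:
                t_len = rng.exponential(spec.tract_mean_bp)
                t_start, t_end = int(x), int(min(x + t_len, length))
                if t_end > t_start:
                    donor = int(rng.choice(donor_cols))
                    sel = base[(pos0 >= t_start) & (pos0 < t_end)]
                    cohort.haplotypes[sel, hap] = cohort.haplotypes[sel, donor]
                    tracts.append(
                        {
                            "contig": contig,
                            "start": t_start,
                            "end": t_end,
                            "recipient_hap": int(hap),
                            "donor_hap": donor,
                        }
                    )
                x = x + t_len + (rng.exponential(gap_mean) if gap_mean > 0 else 0.0)
    cohort.truth["introgression_tracts"].extend(tracts)
    return tracts


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    gc_block_plan: dict[str, Sequence[tuple[int, int, float]]],
    seed: int = 0,
) -> ReferenceGenome:
    """Reference with i.i.d. bases at per-block GC probabilities.

    ``gc_block_plan`` maps contig name to ``(start, end, gc)`` blocks that
    must tile the contig contiguously from 0 with no overlaps.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for contig, blocks in gc_block_plan.items():
        blocks = sorted(blocks)
        expected = 0
        parts: list[np.ndarray] = []
        for start, end, gc in blocks:
            if start != expected:
                raise PopscanError(
                    f"blocks on {contig} overlap or leave a gap at {expected}"
                )
            if not 0.0 <= gc <= 1.0:
                raise PopscanError("block GC outside [0,1]")
            expected = end
            n = end - start
            is_gc = rng.random(n) < gc
            strong = rng.integers(0, 2, n)  # G vs C
            weak = rng.integers(0, 2, n)  # A vs T
            bases = np.where(is_gc, np.where(strong == 0, ord("G"), ord("C")),
                             np.where(weak == 0, ord("A"), ord("T"))).astype(np.uint8)
            parts.append(bases)
        seqs[contig] = np.concatenate(parts).tobytes().decode("ascii")
    return ReferenceGenome(sequences=seqs)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    return cohort.write(out_dir)
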