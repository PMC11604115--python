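"""Seeded generators of structured SNP genotype data.

Two generative models cover the statistical structure the analysis consumes:

* **Balding-Nichols metapopulation** — each subpopulation's allele frequency
  at a locus is a Beta draw around an ancestral frequency p0 with variance
  F p0 (1 - p0), so F plays the role of a per-subpopulation differentiation
  (FST-like) parameter; genotypes are binomial(2, p) with completely-at-random
  missingness, and an optional large admixed outgroup pool is genotyped from
  the mean of the subpopulation frequencies.

* **Forward Wright-Fisher** — an individual-based population of N diploids
  under random union of gametes (selfing allowed, so census = effective
  size), unlinked loci; used as the truth harness for the effective-size
  estimators, whose drift signal (inter-locus association carried by the
  finite parental pool) only exists in an individual-based simulation.

Two fixture editors plant a subpopulation-private allele or convert a locus
into a (partially) null-allele locus by recoding heterozygotes.

All generators are seed-deterministic: the same config yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, Locus, SubpopulationMap

__all__ = [
    "MetapopSimConfig",
    "WrightFisherConfig",
    "simulate_metapopulation",
    "simulate_wright_fisher",
    "plant_private_allele",
    "inject_null_allele_locus",
]


@dataclass
class MetapopSimConfig:
    n_subpops: int = 6
    sizes: list[int] | None = None          # default: spread over 6..60
    n_loci: int = 1000
    F: float = 0.1                          # differentiation parameter
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.01
    seed: int = 0
    outgroup_size: int | None = 100
    n_chromosomes: int = 18

    def __post_init__(self) -> None:
        if self.n_subpops < 2:
            raise ValueError("need at least 2 subpopulations")
        if self.sizes is None:
            # unequal sizes spanning small to large samples
            self.sizes = [
                int(round(6 + (60 - 6) * k / max(self.n_subpops - 1, 1)))
                for k in range(self.n_subpops)
            ]
        if len(self.sizes) != self.n_subpops:
            raise ValueError("sizes length must equal n_subpops")
        if min(self.sizes) < 1:
            raise ValueError("subpopulation sizes must be >= 1")
        if not (0 <= self.F < 1):
            raise ValueError("F must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class WrightFisherConfig:
    N_true: int = 50                        # diploid census = effective size
    n_loci: int = 2000
    generations: int = 20
    init_freq: tuple[float, float] = (0.2, 0.8)
    sample_size: int = 50
    seed: int = 0
    n_chromosomes: int = 18

    def __post_init__(self) -> None:
        if self.sample_size > self.N_true:
            raise ValueError("sample_size cannot exceed N_true")
        if self.generations < 1:
            raise ValueError("need at least 1 generation")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _make_loci(n_loci: int, n_chromosomes: int) -> list[Locus]:
    per = -(-n_loci // n_chromosomes)
    loci = []
    for l in range(n_loci):
        chrom = l // per + 1
        pos = (l % per + 1) * 1000
        loci.append(Locus(f"snp{l:05d}", str(chrom), pos, ("A", "B")))
    return loci


def simulate_metapopulation(
    cfg: MetapopSimConfig,
) -> tuple[GenotypeMatrix, SubpopulationMap, dict]:
    """Balding-Nichols metapopulation with an optional admixed outgroup pool.

    Returns the genotype matrix, the subpopulation map (outgroup flagged) and
    a truth record holding the drawn ancestral and per-subpopulation
    frequencies, from which expected HS/DG are exactly recomputable.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=L)
    if cfg.F > 0:
        a = p0 * (1 - cfg.F) / cfg.F
        b = (1 - p0) * (1 - cfg.F) / cfg.F
        freqs = rng.beta(a, b, size=(cfg.n_subpops, L))
    else:
        freqs = np.tile(p0, (cfg.n_subpops, 1))

    blocks, ids, assignment = [], [], {}
    labels = [f"subpop{k + 1:02d}" for k in range(cfg.n_subpops)]
    for k, (label, n_k) in enumerate(zip(labels, cfg.sizes)):
        dose = rng.binomial(2, freqs[k], size=(n_k, L)).astype(np.int8)
        blocks.append(dose)
        for i in range(n_k):
            iid = f"{label}_ind{i + 1:03d}"
            ids.append(iid)
            assignment[iid] = label
    outgroup = None
    if cfg.outgroup_size:
        outgroup = "outgroup"
        p_out = freqs.mean(axis=0)  # admixed pool around the metapopulation mean
        dose = rng.binomial(2, p_out, size=(cfg.outgroup_size, L)).astype(np.int8)
        blocks.append(dose)
        for i in range(cfg.outgroup_size):
            iid = f"outgroup_ind{i + 1:03d}"
            ids.append(iid)
            assignment[iid] = outgroup
    dose = np.vstack(blocks)
    if cfg.missing_rate > 0:
        miss = rng.random(dose.shape) < cfg.missing_rate
        dose = np.where(miss, MISSING, dose)
    gm = GenotypeMatrix(ids, _make_loci(L, cfg.n_chromosomes), dose)
    subs = SubpopulationMap(assignment, outgroup)
    truth = {
        "p0": p0,
        "subpop_freqs": freqs,
        "labels": labels,
        "outgroup_freq": freqs.mean(axis=0) if cfg.outgroup_size else None,
        "F": cfg.F,
    }
    return gm, subs, truth


def simulate_wright_fisher(cfg: WrightFisherConfig) -> GenotypeMatrix:
    """Individual-based forward Wright-Fisher simulation, unlinked loci.

    Each generation every offspring draws two parents uniformly at random
    (random union of gametes; selfing allowed) and receives one allele per
    locus from each parent.  The final generation is sampled without
    replacement.
    """
    rng = np.random.default_rng(cfg.seed)
    N, L = cfg.N_true, cfg.n_loci
    p_init = rng.uniform(*cfg.init_freq, size=L)
    dose = rng.binomial(2, p_init, size=(N, L)).astype(np.int8)
    for _ in range(cfg.generations):
        pa = rng.integers(0, N, size=N)
        pb = rng.integers(0, N, size=N)
        gam_a = rng.random((N, L)) < dose[pa] / 2.0
        gam_b = rng.random((N, L)) < dose[pb] / 2.0
        dose = (gam_a.astype(np.int8) + gam_b.astype(np.int8))
    sample = rng.choice(N, size=cfg.sample_size, replace=False)
    ids = [f"wf_ind{i + 1:04d}" for i in range(cfg.sample_size)]
    return GenotypeMatrix(ids, _make_loci(L, cfg.n_chromosomes), dose[sample])


def plant_private_allele(
    gm: GenotypeMatrix,
    subs: SubpopulationMap,
    target: str,
    frequency: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Append a locus whose alternate allele segregates at ``frequency`` in
    ``target`` and is absent everywhere else (a planted private allele)."""
    if not (0 < frequency <= 1):
        raise ValueError("frequency must lie in (0, 1]")
    if target not in subs.subpopulations():
        raise ValueError(f"unknown target subpopulation {target!r}")
    rng = np.random.default_rng(seed)
    col = np.full((gm.n_individuals, 1), 2, dtype=np.int8)  # dose 2 = no alt copies
    members = set(subs.members(target))
    for k, iid in enumerate(gm.individual_ids):
        if iid in members:
            col[k, 0] = 2 - rng.binomial(2, frequency)
    last = gm.loci[-1]
    new_locus = Locus("snp_private", last.chromosome, last.position + 1000, ("A", "B"))
    return GenotypeMatrix(
        list(gm.individual_ids), list(gm.loci) + [new_locus],
        np.hstack([gm.dose, col]),
    )


def inject_null_allele_locus(
    gm: GenotypeMatrix, locus_id: str, beta: float, seed: int = 0
) -> GenotypeMatrix:
    """Recode each heterozygote at ``locus_id`` as a homozygote (random side)
    with probability ``beta`` — mimics a (partially) null allele."""
    if not (0 <= beta <= 1):
        raise ValueError("beta must lie in [0, 1]")
    if locus_id not in gm.locus_ids:
        raise ValueError(f"unknown locus {locus_id!r}")
    l = gm.locus_ids.index(locus_id)
    rng = np.random.default_rng(seed)
    dose = gm.dose.copy()
    het = np.flatnonzero(dose[:, l] == 1)
    hit = het[rng.random(len(het)) < beta]
    dose[hit, l] = rng.choice(np.array([0, 2], dtype=np.int8), size=len(hit))
    return GenotypeMatrix(list(gm.individual_ids), list(gm.loci), dose)
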