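"""Shared fixtures: small hand-built genotype objects and the (expensive)
Wright-Fisher effective-size recovery harness, run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from metapopdiv.genotypes import (
    AlleleCounts,
    GenotypeMatrix,
    Locus,
    SubpopulationMap,
)
from metapopdiv.ne import ne_ld
from metapopdiv.simulate import (
    MetapopSimConfig,
    WrightFisherConfig,
    simulate_metapopulation,
    simulate_wright_fisher,
)


def make_gm(dose, chrom=None):
    """GenotypeMatrix from a dose array; one chromosome unless given."""
    dose = np.asarray(dose, dtype=np.int8)
    n, L = dose.shape
    chrom = chrom or ["1"] * L
    loci = [Locus(f"snp{j}", chrom[j], (j + 1) * 1000, ("A", "B")) for j in range(L)]
    return GenotypeMatrix([f"ind{i}" for i in range(n)], loci, dose)


def make_counts(ref, tot, labels=None, locus_ids=None):
    """AlleleCounts from reference-copy and total-copy integer arrays."""
    ref = np.asarray(ref, dtype=np.int64)
    tot = np.asarray(tot, dtype=np.int64)
    labels = labels or [f"pop{i}" for i in range(ref.shape[0])]
    locus_ids = locus_ids or [f"snp{j}" for j in range(ref.shape[1])]
    return AlleleCounts(labels, locus_ids, ref, tot)


def random_counts(rng, n_subpops=4, n_loci=12, max_n=12, polymorphic=True):
    """Random fully-observed biallelic counts; every locus usable everywhere."""
    n_ind = rng.integers(3, max_n + 1, size=n_subpops)
    tot = np.tile((2 * n_ind)[:, None], (1, n_loci))
    ref = rng.integers(0, tot + 1)
    if polymorphic:
        # Force at least one copy of each allele somewhere per locus.
        ref[0] = np.clip(ref[0], 1, tot[0] - 1)
    return make_counts(ref, tot)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_metapop():
    cfg = MetapopSimConfig(
        n_subpops=4,
        sizes=[8, 10, 12, 15],
        n_loci=120,
        F=0.15,
        missing_rate=0.02,
        outgroup_size=20,
        seed=42,
    )
    return simulate_metapopulation(cfg)


def _wf_recovery():
    """LD-Ne recovery under Wright-Fisher truth: the study design the package
    is calibrated for (sample size S equal to true Ne, 2,000 unlinked loci).

    The simulated loci are unlinked by construction, so no pruning is applied:
    pruning would truncate the upper tail of the drift r^2 distribution and
    bias the estimate upward (it exists to enforce quasi-independence on real
    linked panels, which the estimator's input contract assumes).
    """
    out = {}
    for ne_true in (25, 50, 100):
        points, covered = [], 0
        for rep in range(30):
            cfg = WrightFisherConfig(
                N_true=ne_true,
                n_loci=2000,
                generations=20,
                sample_size=ne_true,
                seed=10_000 * ne_true + rep,
            )
            gm = simulate_wright_fisher(cfg)
            est = ne_ld(gm, pcrit=0.05, jackknife=True)
            points.append(est.point)
            if est.ci_low <= ne_true <= est.ci_high:
                covered += 1
        out[ne_true] = {
            "median": float(np.median(points)),
            "coverage": covered / 30,
            "points": points,
        }
    return out


@pytest.fixture(scope="session")
def wf_recovery():
    return _wf_recovery()
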