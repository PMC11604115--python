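"""Genotype container, PED/MAP I/O, counting and cohort filters."""

import numpy as np
import pandas as pd
import pytest

from metapopdiv.genotypes import (
    MISSING,
    GenotypeMatrix,
    Locus,
    PedParseError,
    SubpopulationMap,
    count_alleles,
    filter_null_allele_loci,
    filter_small_subpopulations,
    locus_fis,
    merge_subpopulations,
    read_ped_map,
    write_ped_map,
)
from metapopdiv.simulate import (
    MetapopSimConfig,
    inject_null_allele_locus,
    simulate_metapopulation,
)

from conftest import make_gm


def _subs(gm, labels):
    return SubpopulationMap(dict(zip(gm.individual_ids, labels)))


# -------------------------------------------------------------- I/O ----------


def test_ped_map_round_trip(tmp_path, small_metapop):
    gm, subs, _ = small_metapop
    ped, mp = tmp_path / "a.ped", tmp_path / "a.map"
    write_ped_map(gm, subs, ped, mp)
    gm2, subs2 = read_ped_map(ped, mp)
    assert gm2.individual_ids == gm.individual_ids
    assert gm2.locus_ids == gm.locus_ids
    assert [l.chromosome for l in gm2.loci] == [l.chromosome for l in gm.loci]
    assert subs2.assignment == subs.assignment
    # Dose values round-trip up to the reference-allele convention (first
    # allele seen in PED order); all downstream statistics are invariant, and
    # the genotype itself (unordered allele pair) must be preserved exactly.
    same_ref = gm2.dose == gm.dose
    flipped = (gm2.dose == 2 - gm.dose) & (gm.dose >= 0)
    missing = gm.dose == MISSING
    assert np.all(same_ref | flipped | missing)
    assert np.array_equal(gm2.dose == MISSING, missing)


def test_read_ped_map_missing_and_ref_convention(tmp_path):
    (tmp_path / "b.map").write_text("1\tsnp1\t0\t100\n1\tsnp2\t0\t200\n")
    (tmp_path / "b.ped").write_text(
        "popA i1 0 0 0 0 A A G T\n"
        "popA i2 0 0 0 0 A C 0 0\n"
        "popB i3 0 0 0 0 C C T T\n"
    )
    gm, subs = read_ped_map(tmp_path / "b.ped", tmp_path / "b.map")
    # snp1: ref = A (first seen); snp2: ref = G.
    assert gm.dose.tolist() == [[2, 1], [1, MISSING], [0, 0]]
    assert subs.assignment == {"i1": "popA", "i2": "popA", "i3": "popB"}


def test_read_ped_map_rejects_ragged_and_triallelic(tmp_path):
    (tmp_path / "c.map").write_text("1\tsnp1\t0\t100\n")
    (tmp_path / "c.ped").write_text("p i1 0 0 0 0 A A G\n")
    with pytest.raises(PedParseError):
        read_ped_map(tmp_path / "c.ped", tmp_path / "c.map")
    (tmp_path / "c.ped").write_text("p i1 0 0 0 0 A C\np i2 0 0 0 0 G G\n")
    with pytest.raises(PedParseError):
        read_ped_map(tmp_path / "c.ped", tmp_path / "c.map")


def test_read_ped_map_rejects_duplicate_individuals(tmp_path):
    (tmp_path / "d.map").write_text("1\tsnp1\t0\t100\n")
    (tmp_path / "d.ped").write_text("p i1 0 0 0 0 A A\np i1 0 0 0 0 A C\n")
    with pytest.raises(PedParseError):
        read_ped_map(tmp_path / "d.ped", tmp_path / "d.map")


# ------------------------------------------------------- counting ------------


def test_count_alleles_hand_example():
    gm = make_gm([[2, 1], [1, MISSING], [0, 0], [2, 2]])
    subs = _subs(gm, ["A", "A", "B", "B"])
    counts = count_alleles(gm, subs)
    assert counts.ref.tolist() == [[3, 1], [2, 2]]
    assert counts.tot.tolist() == [[4, 2], [4, 4]]
    f = counts.freq
    assert f[0, 0] == pytest.approx(0.75)
    assert f[0, 1] == pytest.approx(0.5)


def test_count_alleles_unobserved_gives_nan_freq():
    gm = make_gm([[MISSING], [MISSING], [1]])
    counts = count_alleles(gm, _subs(gm, ["A", "A", "B"]))
    assert counts.tot[0, 0] == 0
    assert np.isnan(counts.freq[0, 0])
    assert counts.freq[1, 0] == pytest.approx(0.5)


def test_count_alleles_invariant_to_individual_order(rng):
    dose = rng.integers(-1, 3, size=(12, 8)).astype(np.int8)
    gm = make_gm(dose)
    labels = ["A"] * 6 + ["B"] * 6
    counts = count_alleles(gm, _subs(gm, labels))
    perm = rng.permutation(12)
    gm2 = GenotypeMatrix(
        [gm.individual_ids[k] for k in perm], list(gm.loci), dose[perm]
    )
    subs2 = SubpopulationMap(
        {gm.individual_ids[k]: labels[k] for k in perm}
    )
    counts2 = count_alleles(gm2, subs2, labels=["A", "B"])
    assert np.array_equal(counts.ref, counts2.ref)
    assert np.array_equal(counts.tot, counts2.tot)


# ------------------------------------------------------------ FIS ------------


def test_locus_fis_hand_examples():
    # doses (0, 0, 1, 1): p = 0.25, He = 0.375, Ho = 0.5 -> FIS = -1/3.
    gm = make_gm([[0, 0, 1], [0, 2, 1], [1, 2, 2], [1, 2, 0]])
    fis = locus_fis(gm, _subs(gm, ["A"] * 4))
    assert fis.loc["A", "snp0"] == pytest.approx(-1 / 3)
    # Second locus: doses (0,2,2,2) all homozygous -> FIS = 1 exactly.
    assert fis.loc["A", "snp1"] == pytest.approx(1.0)
    # Third locus: doses (1,1,2,0), p = 0.5, Ho = 0.5, He = 0.5 -> FIS = 0.
    assert fis.loc["A", "snp2"] == pytest.approx(0.0)


def test_locus_fis_nan_when_monomorphic():
    gm = make_gm([[2], [2], [2]])
    fis = locus_fis(gm, _subs(gm, ["A"] * 3))
    assert np.isnan(fis.loc["A", "snp0"])


# -------------------------------------------------------- filters ------------


def test_null_allele_filter_removes_injected_locus(small_metapop):
    gm, subs, _ = small_metapop
    bad = inject_null_allele_locus(gm, "snp00007", beta=1.0, seed=5)
    kept, report = filter_null_allele_loci(bad, subs, threshold=0.9)
    assert "snp00007" in report["locus"].tolist()
    assert "snp00007" not in kept.locus_ids


def test_null_allele_filter_retains_hw_loci():
    # Under Hardy-Weinberg sampling FIS fluctuates around 0; across 100 seeded
    # simulated cohorts the 0.9 threshold should essentially never fire.
    removed = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, size=30)
        dose = rng.binomial(2, p, size=(40, 30)).astype(np.int8)
        gm = make_gm(dose)
        _, report = filter_null_allele_loci(gm, _subs(gm, ["A"] * 40))
        removed += len(report)
    assert removed == 0


def test_filter_monotone_in_threshold(small_metapop, rng):
    gm, subs, _ = small_metapop
    bad = gm
    for j, b in (("snp00003", 0.95), ("snp00010", 0.7), ("snp00020", 0.5)):
        bad = inject_null_allele_locus(bad, j, beta=b, seed=int(b * 100))
    strict, rep_strict = filter_null_allele_loci(bad, subs, threshold=0.5)
    loose, rep_loose = filter_null_allele_loci(bad, subs, threshold=0.95)
    assert set(loose.locus_ids) >= set(strict.locus_ids)
    assert len(rep_strict) >= len(rep_loose)


def test_small_subpopulation_filter_and_outgroup_exemption():
    dose = np.ones((12, 3), dtype=np.int8)
    gm = make_gm(dose)
    labels = ["A"] * 6 + ["B"] * 3 + ["OUT"] * 3
    subs = SubpopulationMap(dict(zip(gm.individual_ids, labels)), outgroup="OUT")
    kept, subs2, report = filter_small_subpopulations(gm, subs, min_n=6)
    assert set(subs2.subpopulations()) == {"A", "OUT"}
    assert report["subpopulation"].tolist() == ["B"]
    assert kept.n_individuals == 9
    # Without the exemption the outgroup would fall too.
    _, subs3, _ = filter_small_subpopulations(gm, subs, min_n=6, exempt_outgroup=False)
    assert set(subs3.subpopulations()) == {"A"}


def test_merge_subpopulations_pools_counts():
    gm = make_gm(np.array([[0], [1], [2], [2]], dtype=np.int8))
    subs = _subs(gm, ["A", "A", "B", "C"])
    merged = merge_subpopulations(subs, {"B": "BC", "C": "BC"})
    counts = count_alleles(gm, merged)
    i = counts.index_of("BC")
    assert counts.ref[i, 0] == 4 and counts.tot[i, 0] == 4


def test_merge_refuses_outgroup_mix():
    gm = make_gm(np.zeros((3, 1), dtype=np.int8))
    subs = SubpopulationMap(
        dict(zip(gm.individual_ids, ["A", "B", "OUT"])), outgroup="OUT"
    )
    with pytest.raises(ValueError):
        merge_subpopulations(subs, {"OUT": "X", "A": "X"})


def test_subpopulation_map_rejects_unassigned_outgroup():
    with pytest.raises(ValueError):
        SubpopulationMap({"i1": "A"}, outgroup="OUT")
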