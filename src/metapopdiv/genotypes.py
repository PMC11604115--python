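"""Genotype data model, PLINK text PED/MAP I/O, allele counting and cohort filters.

The single substrate for every downstream statistic is a dose-coded biallelic
genotype matrix (individuals x loci, counting copies of the reference allele,
with explicit missingness) plus an assignment of individuals to named
subpopulations.  Frequencies are always computed over observed gene copies
only (complete case per locus per subpopulation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


class PedParseError(ValueError):
    """Malformed PED/MAP input (ragged row, >2 alleles at a locus, ...)."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: id, chromosome, 1-based physical position, allele pair.

    ``alleles`` is ordered (reference, alternate); dose counts copies of the
    reference allele.  Positions are carried through untouched.
    """

    id: str
    chromosome: str
    position: int
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"locus {self.id}: negative position")
        if len(self.alleles) != 2:
            raise ValueError(f"locus {self.id}: need exactly two allele labels")


@dataclass
class GenotypeMatrix:
    """Individuals x loci dose matrix with values in {0, 1, 2, MISSING=-1}."""

    individual_ids: list[str]
    loci: list[Locus]
    dose: np.ndarray  # int8, shape (n_individuals, n_loci)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.int8)
        n, L = len(self.individual_ids), len(self.loci)
        if n < 1 or L < 1:
            raise ValueError("GenotypeMatrix needs at least 1 individual and 1 locus")
        if self.dose.shape != (n, L):
            raise ValueError(
                f"dose shape {self.dose.shape} inconsistent with "
                f"{n} individuals x {L} loci"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != L:
            raise ValueError("duplicate locus ids")
        bad = (self.dose < -1) | (self.dose > 2)
        if bad.any():
            raise ValueError("dose values outside {0,1,2,MISSING}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def subset_individuals(self, keep: list[str]) -> "GenotypeMatrix":
        idx = {iid: k for k, iid in enumerate(self.individual_ids)}
        rows = [idx[i] for i in keep]
        return GenotypeMatrix(list(keep), list(self.loci), self.dose[rows, :])

    def subset_loci(self, keep_ids: list[str]) -> "GenotypeMatrix":
        idx = {lid: k for k, lid in enumerate(self.locus_ids)}
        cols = [idx[i] for i in keep_ids]
        return GenotypeMatrix(
            list(self.individual_ids), [self.loci[c] for c in cols], self.dose[:, cols]
        )


@dataclass
class SubpopulationMap:
    """Assignment of individuals to named subpopulations.

    ``outgroup`` names the (at most one) pooled reference population that is
    always retained in leave-one-out analyses.  ``group`` / ``continent`` carry
    optional descriptive labels used by the group-level summaries.
    """

    assignment: dict[str, str]
    outgroup: str | None = None
    group: dict[str, str] = field(default_factory=dict)
    continent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outgroup is not None and self.outgroup not in set(self.assignment.values()):
            raise ValueError(f"outgroup label {self.outgroup!r} assigned to no individual")

    def subpopulations(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignment.values():
            seen.setdefault(label, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [i for i, s in self.assignment.items() if s == label]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.assignment.values():
            out[label] = out.get(label, 0) + 1
        return out

    def is_outgroup(self, label: str) -> bool:
        return label == self.outgroup

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [i for i in gm.individual_ids if i not in self.assignment]
        if missing:
            raise ValueError(f"{len(missing)} individuals unassigned, e.g. {missing[0]!r}")

    def restricted_to(self, individuals: list[str]) -> "SubpopulationMap":
        keep = set(individuals)
        asg = {i: s for i, s in self.assignment.items() if i in keep}
        og = self.outgroup if self.outgroup in set(asg.values()) else None
        return SubpopulationMap(asg, og, dict(self.group), dict(self.continent))


@dataclass
class AlleleCounts:
    """Reference-allele copy counts per (subpopulation, locus).

    ``ref[s, l]`` counts observed reference-allele copies, ``tot[s, l]`` the
    observed gene copies (2 x non-missing individuals).  Frequencies are
    undefined (NaN) wherever ``tot == 0``.
    """

    subpop_labels: list[str]
    locus_ids: list[str]
    ref: np.ndarray  # int64 (S, L)
    tot: np.ndarray  # int64 (S, L)

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.tot = np.asarray(self.tot, dtype=np.int64)
        if self.ref.shape != self.tot.shape:
            raise ValueError("ref/tot shape mismatch")
        if (self.ref > self.tot).any() or (self.ref < 0).any():
            raise ValueError("copies_ref must lie in [0, copies_total]")
        if (self.tot % 2 != 0).any():
            raise ValueError("copies_total must be even (diploid gene copies)")

    @property
    def freq(self) -> np.ndarray:
        """Reference-allele frequency, NaN where no copies were observed."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.tot > 0, self.ref / np.maximum(self.tot, 1), np.nan)

    def index_of(self, label: str) -> int:
        return self.subpop_labels.index(label)

    def restricted_to(self, labels: list[str]) -> "AlleleCounts":
        rows = [self.index_of(s) for s in labels]
        return AlleleCounts(list(labels), list(self.locus_ids), self.ref[rows], self.tot[rows])


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------
# PLINK text dialect: PED columns are family (= subpopulation label),
# individual id, father (0), mother (0), sex (0), phenotype (-9), then two
# allele fields per locus; "0" is the missing allele code.  MAP columns are
# chromosome, id, genetic distance (0), position.


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, SubpopulationMap]:
    """Read a PED/MAP pair into a dose matrix plus subpopulation assignment.

    The reference allele at each locus is the first allele label encountered
    in PED file order (deterministic); every statistic downstream is invariant
    to this choice.  "0 0" genotype pairs become MISSING.
    """
    loci_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PedParseError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom, lid, _gd, pos = parts
            loci_rows.append((lid, chrom, int(pos)))
    L = len(loci_rows)
    if L == 0:
        raise PedParseError(f"{map_path}: no loci")

    individual_ids: list[str] = []
    assignment: dict[str, str] = {}
    alleles: list[list[str]] = [[] for _ in range(L)]  # observed labels in order
    dose_rows: list[np.ndarray] = []
    raw_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * L:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * L} fields "
                    f"({L} loci), found {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            if iid in assignment:
                raise PedParseError(f"{ped_path}:{lineno}: duplicate individual id {iid!r}")
            individual_ids.append(iid)
            assignment[iid] = fam
            raw_rows.append(parts[6:])

    for row in raw_rows:
        for l in range(L):
            for a in (row[2 * l], row[2 * l + 1]):
                if a != "0" and a not in alleles[l]:
                    alleles[l].append(a)
                    if len(alleles[l]) > 2:
                        raise PedParseError(
                            f"locus {loci_rows[l][0]}: more than 2 alleles observed"
                        )

    for row in raw_rows:
        d = np.empty(L, dtype=np.int8)
        for l in range(L):
            a1, a2 = row[2 * l], row[2 * l + 1]
            if a1 == "0" or a2 == "0":
                d[l] = MISSING
            else:
                ref = alleles[l][0]
                d[l] = int(a1 == ref) + int(a2 == ref)
        dose_rows.append(d)

    loci = []
    for l, (lid, chrom, pos) in enumerate(loci_rows):
        obs = alleles[l]
        pair = (obs + ["A", "B"])[:2]  # pad monomorphic / all-missing loci
        loci.append(Locus(lid, chrom, pos, (pair[0], pair[1])))
    gm = GenotypeMatrix(individual_ids, loci, np.vstack(dose_rows))
    return gm, SubpopulationMap(assignment)


def write_ped_map(gm: GenotypeMatrix, subs: SubpopulationMap, ped_path, map_path) -> None:
    """Write a PED/MAP pair readable by :func:`read_ped_map` (round-trip exact)."""
    if gm.n_loci == 0:
        raise ValueError("refusing to write a PED/MAP pair with no loci")
    subs.validate_against(gm)
    with open(map_path, "w") as fh:
        for loc in gm.loci:
            fh.write(f"{loc.chromosome}\t{loc.id}\t0\t{loc.position}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            fam = subs.assignment[iid]
            fields = [fam, iid, "0", "0", "0", "-9"]
            for l, loc in enumerate(gm.loci):
                d = gm.dose[i, l]
                ref, alt = loc.alleles
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [ref, ref]
                elif d == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Allele counting and per-locus statistics
# ---------------------------------------------------------------------------


def _subpop_rows(gm: GenotypeMatrix, subs: SubpopulationMap) -> dict[str, np.ndarray]:
    subs.validate_against(gm)
    idx: dict[str, list[int]] = {}
    for k, iid in enumerate(gm.individual_ids):
        idx.setdefault(subs.assignment[iid], []).append(k)
    return {s: np.asarray(rows, dtype=np.intp) for s, rows in idx.items()}


def count_alleles(
    gm: GenotypeMatrix, subs: SubpopulationMap, labels: list[str] | None = None
) -> AlleleCounts:
    """Count observed reference-allele copies per (subpopulation, locus)."""
    rows = _subpop_rows(gm, subs)
    if labels is None:
        labels = subs.subpopulations()
    ref = np.zeros((len(labels), gm.n_loci), dtype=np.int64)
    tot = np.zeros_like(ref)
    for s, label in enumerate(labels):
        block = gm.dose[rows[label], :]
        obs = block >= 0
        ref[s] = np.where(obs, block, 0).sum(axis=0)
        tot[s] = 2 * obs.sum(axis=0)
    return AlleleCounts(list(labels), gm.locus_ids, ref, tot)


def locus_fis(gm: GenotypeMatrix, subs: SubpopulationMap) -> pd.DataFrame:
    """Per (subpopulation, locus) heterozygote-deficit statistic FIS = 1 - Ho/He.

    Ho is the observed heterozygote proportion among non-missing individuals,
    He = 2 p(1-p) from the observed allele frequency.  NaN where the locus is
    unobserved or monomorphic in that subpopulation (FIS undefined there and
    never filtered on).
    """
    rows = _subpop_rows(gm, subs)
    labels = subs.subpopulations()
    out = np.full((len(labels), gm.n_loci), np.nan)
    for s, label in enumerate(labels):
        block = gm.dose[rows[label], :]
        obs = block >= 0
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, block, 0).sum(axis=0) / np.maximum(2 * n, 1)
            ho = (block == 1).sum(axis=0) / np.maximum(n, 1)
            he = 2 * p * (1 - p)
            fis = 1 - ho / he
        fis[(n == 0) | (he <= 0)] = np.nan
        out[s] = fis
    return pd.DataFrame(out, index=labels, columns=gm.locus_ids)


# ---------------------------------------------------------------------------
# Cohort-assembly filters
# ---------------------------------------------------------------------------


def filter_null_allele_loci(
    gm: GenotypeMatrix,
    subs: SubpopulationMap,
    threshold: float = 0.9,
    assess_subpops: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci whose FIS exceeds ``threshold`` in any assessed subpopulation.

    Screens for null and partially null alleles (technical heterozygote
    deficit).  Returns the filtered matrix and a report naming each removed
    locus with the first triggering subpopulation and its FIS.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    fis = locus_fis(gm, subs)
    if assess_subpops is not None:
        fis = fis.loc[assess_subpops]
    exceed = fis.to_numpy() > threshold  # NaN compares False
    drop_cols = np.flatnonzero(exceed.any(axis=0))
    records = []
    for c in drop_cols:
        s = int(np.argmax(exceed[:, c]))
        records.append(
            {
                "locus": gm.locus_ids[c],
                "subpopulation": fis.index[s],
                "fis": float(fis.iloc[s, c]),
                "reason": f"FIS > {threshold}",
            }
        )
    report = pd.DataFrame(records, columns=["locus", "subpopulation", "fis", "reason"])
    keep = [lid for k, lid in enumerate(gm.locus_ids) if k not in set(drop_cols)]
    if not keep:
        raise ValueError("null-allele filter removed every locus")
    return gm.subset_loci(keep), report


def filter_small_subpopulations(
    gm: GenotypeMatrix,
    subs: SubpopulationMap,
    min_n: int = 6,
    exempt_outgroup: bool = True,
) -> tuple[GenotypeMatrix, SubpopulationMap, pd.DataFrame]:
    """Remove subpopulations sampled below ``min_n`` individuals (outgroup exempt)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    subs.validate_against(gm)
    sizes = subs.sizes()
    removed = []
    keep_labels = []
    for label, n in sizes.items():
        if n < min_n and not (exempt_outgroup and subs.is_outgroup(label)):
            removed.append({"subpopulation": label, "n": n, "reason": f"n < {min_n}"})
        else:
            keep_labels.append(label)
    if not keep_labels:
        raise ValueError("no subpopulations remain after the minimum-size filter")
    keep_set = set(keep_labels)
    keep_inds = [i for i in gm.individual_ids if subs.assignment[i] in keep_set]
    gm2 = gm.subset_individuals(keep_inds)
    subs2 = subs.restricted_to(keep_inds)
    report = pd.DataFrame(removed, columns=["subpopulation", "n", "reason"])
    return gm2, subs2, report


def merge_subpopulations(
    subs: SubpopulationMap, merge_spec: dict[str, str]
) -> SubpopulationMap:
    """Rewrite assignments merging old labels into new ones.

    A pool containing the outgroup inherits the outgroup role; merging the
    outgroup with a non-outgroup subpopulation is refused as ambiguous.
    """
    existing = set(subs.assignment.values())
    absent = [s for s in merge_spec if s not in existing]
    if absent:
        raise ValueError(f"merge_spec names absent subpopulations: {absent}")
    if subs.outgroup is not None and subs.outgroup in merge_spec:
        target = merge_spec[subs.outgroup]
        partners = {s for s, t in merge_spec.items() if t == target}
        if partners != {subs.outgroup}:
            raise ValueError("refusing to merge the outgroup with non-outgroup pools")
    asg = {i: merge_spec.get(s, s) for i, s in subs.assignment.items()}
    og = subs.outgroup
    if og is not None:
        og = merge_spec.get(og, og)
    group = {merge_spec.get(s, s): g for s, g in subs.group.items()}
    continent = {merge_spec.get(s, s): c for s, c in subs.continent.items()}
    return SubpopulationMap(asg, og, group, continent)
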