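"""Metapopulation diversity partitions and leave-one-out contributions.

Total gene diversity is decomposed as HT = HS + DG, where HS is the mean
within-subpopulation expected heterozygosity and DG the mean pairwise Nei
minimum genetic distance over all n^2 ordered subpopulation pairs (self-pairs
contribute zero).  Under this equal-weight convention HT equals the gene
diversity of the pooled (equal-weight) frequency vector exactly.

Analogously, total allelic diversity is AT = AS + DA: AS is the mean rarefied
allelic richness minus one (expected segregating alleles in a standardized
sample of g gene copies), and DA the mean pairwise rarefied count of alleles
expected in one subpopulation's sample but absent from the other's.  Private
allele richness extends the pairwise "absent elsewhere" count to all other
subpopulations jointly.

The marginal contribution of a subpopulation to each component is the signed
percent change of the full-metapopulation total caused by removing it, with
the rarefaction size g (and the usable-locus set) frozen at the full-set
values so that totals are comparable across removals.  Positive means the
subpopulation contributes favorably (its removal loses diversity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import AlleleCounts

__all__ = [
    "GeneDiversityPartition",
    "AllelicRichnessPartition",
    "gene_diversity_within",
    "nei_minimum_distance_matrix",
    "gene_diversity_partition",
    "choose_rarefaction_size",
    "rarefacted_allele_count",
    "rarefacted_absent_count",
    "allelic_richness_partition",
    "private_allele_richness",
    "marginal_contributions",
    "group_level_partition",
]


@dataclass
class GeneDiversityPartition:
    subpops: list[str]
    HS_i: np.ndarray          # per-subpopulation mean gene diversity
    D: np.ndarray             # pairwise Nei minimum distance, zero diagonal
    HS: float
    DG: float
    HT: float


@dataclass
class AllelicRichnessPartition:
    subpops: list[str]
    g: int                    # rarefaction size in gene copies
    AS_i: np.ndarray          # rarefied richness minus one, per subpopulation
    d: np.ndarray             # pairwise rarefied allelic distance, zero diagonal
    AS: float
    DA: float
    AT: float
    P_i: np.ndarray           # private allele richness per subpopulation
    n_loci_used: int = 0


# ---------------------------------------------------------------------------
# Gene-diversity partition
# ---------------------------------------------------------------------------


def gene_diversity_within(counts: AlleleCounts) -> pd.Series:
    """Mean expected heterozygosity 1 - sum_a p_a^2 per subpopulation.

    Loci with no observed copies in a subpopulation are excluded from that
    subpopulation's mean.
    """
    p = counts.freq
    het = 1.0 - (p**2 + (1.0 - p) ** 2)
    usable = counts.tot > 0
    if not usable.any(axis=1).all():
        bad = [s for k, s in enumerate(counts.subpop_labels) if not usable[k].any()]
        raise ValueError(f"subpopulations with no usable loci: {bad}")
    with np.errstate(invalid="ignore"):
        hs = np.nansum(np.where(usable, het, np.nan), axis=1) / usable.sum(axis=1)
    return pd.Series(hs, index=counts.subpop_labels, name="HS_i")


def nei_minimum_distance_matrix(counts: AlleleCounts) -> np.ndarray:
    """Pairwise Nei minimum distance: mean over shared usable loci of
    (1/2) sum_a (p_ia - p_ja)^2, which for biallelic loci is (p_i - p_j)^2.
    """
    p = counts.freq
    usable = counts.tot > 0
    S = p.shape[0]
    D = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            both = usable[i] & usable[j]
            if not both.any():
                raise ValueError(
                    f"no shared usable locus between "
                    f"{counts.subpop_labels[i]!r} and {counts.subpop_labels[j]!r}"
                )
            diff = p[i, both] - p[j, both]
            D[i, j] = D[j, i] = float(np.mean(diff**2))
    return D


def gene_diversity_partition(
    counts: AlleleCounts, included: list[str] | None = None
) -> GeneDiversityPartition:
    """HT = HS + DG with equal subpopulation weights.

    HS = mean of HS_i; DG = (1/n^2) sum_ij D_ij over all ordered pairs
    including zero self-pairs.  Equal weights make HT identical to the gene
    diversity of the equal-weight pooled frequency vector.
    """
    if included is not None:
        counts = counts.restricted_to(included)
    n = len(counts.subpop_labels)
    if n < 2:
        raise ValueError("gene-diversity partition needs >= 2 subpopulations")
    hs_i = gene_diversity_within(counts).to_numpy()
    D = nei_minimum_distance_matrix(counts)
    HS = float(hs_i.mean())
    DG = float(D.sum() / n**2)
    return GeneDiversityPartition(list(counts.subpop_labels), hs_i, D, HS, DG, HS + DG)


# ---------------------------------------------------------------------------
# Rarefaction machinery
# ---------------------------------------------------------------------------


def _log_comb(n: np.ndarray, k: int | np.ndarray) -> np.ndarray:
    """log C(n, k), -inf where n < k (empty binomial)."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def unseen_probability(tot: np.ndarray, count: np.ndarray, g: int) -> np.ndarray:
    """Q = C(N - N_a, g) / C(N, g): probability an allele with ``count`` copies
    among ``tot`` is absent from a random g-copy sample (hypergeometric)."""
    tot = np.asarray(tot, dtype=float)
    count = np.asarray(count, dtype=float)
    logq = _log_comb(tot - count, g) - _log_comb(tot, g)
    return np.exp(logq)


def rarefacted_allele_count(copies: np.ndarray, N: int, g: int) -> float:
    """Expected number of distinct alleles in a random sample of g of N copies.

    ``copies`` holds per-allele copy numbers summing to N.  Computed in
    log-space for numerical safety; exact for any allele number.
    """
    copies = np.asarray(copies, dtype=np.int64)
    if copies.sum() != N:
        raise ValueError("allele copies must sum to N")
    if not (2 <= g <= N):
        raise ValueError(f"rarefaction size g={g} outside [2, N={N}]")
    q = unseen_probability(np.full_like(copies, N), copies, g)
    return float(np.sum(1.0 - q))


def rarefacted_absent_count(
    copies_i: np.ndarray, N_i: int, copies_j: np.ndarray, N_j: int, g: int
) -> float:
    """Expected alleles present in a g-copy sample from i and absent from an
    independent g-copy sample from j: sum_a (1 - Q_ia) Q_ja."""
    copies_i = np.asarray(copies_i, dtype=np.int64)
    copies_j = np.asarray(copies_j, dtype=np.int64)
    if g > N_i or g > N_j:
        raise ValueError("g exceeds a subpopulation's observed copies")
    qi = unseen_probability(np.full_like(copies_i, N_i), copies_i, g)
    qj = unseen_probability(np.full_like(copies_j, N_j), copies_j, g)
    return float(np.sum((1.0 - qi) * qj))


def choose_rarefaction_size(
    counts: AlleleCounts, included: list[str] | None = None, override: int | None = None
) -> int:
    """Global rarefaction size: minimum observed copy count over included
    subpopulation-loci with at least 2 copies everywhere; config-overridable."""
    if included is not None:
        counts = counts.restricted_to(included)
    if override is not None:
        if override < 2:
            raise ValueError("rarefaction size must be >= 2")
        return int(override)
    usable = (counts.tot >= 2).all(axis=0)
    if not usable.any():
        raise ValueError("no locus observed with >= 2 copies in every subpopulation")
    g = int(counts.tot[:, usable].min())
    if g < 2:
        raise ValueError("rarefaction size below 2")
    return g


def _usable_allelic(counts: AlleleCounts, g: int) -> np.ndarray:
    """Loci at which every subpopulation has at least g observed copies."""
    return (counts.tot >= g).all(axis=0)


def _q_matrices(counts: AlleleCounts, g: int, usable: np.ndarray):
    """Unseen probabilities for the reference and alternate allele, (S, Lu)."""
    tot = counts.tot[:, usable]
    ref = counts.ref[:, usable]
    q_ref = unseen_probability(tot, ref, g)
    q_alt = unseen_probability(tot, tot - ref, g)
    return q_ref, q_alt


def allelic_richness_partition(
    counts: AlleleCounts,
    included: list[str] | None = None,
    g: int | None = None,
    locus_mask: np.ndarray | None = None,
) -> AllelicRichnessPartition:
    """AT = AS + DA from rarefied allele counts at a common size g.

    AS_i = mean over usable loci of (rarefied allele count - 1);
    d_ij symmetrizes the directed "present in i, absent in j" counts;
    DA = (1/n^2) sum_ij d_ij with zero diagonal.  ``locus_mask`` freezes an
    externally chosen usable-locus set (used by leave-one-out re-evaluation).
    """
    if included is not None:
        counts = counts.restricted_to(included)
    n = len(counts.subpop_labels)
    if n < 2:
        raise ValueError("allelic-richness partition needs >= 2 subpopulations")
    if g is None:
        g = choose_rarefaction_size(counts)
    usable = _usable_allelic(counts, g)
    if locus_mask is not None:
        usable = usable & locus_mask
    if not usable.any():
        raise ValueError("no locus usable at the chosen rarefaction size")
    q_ref, q_alt = _q_matrices(counts, g, usable)

    pres_ref, pres_alt = 1.0 - q_ref, 1.0 - q_alt
    as_i = (pres_ref + pres_alt - 1.0).mean(axis=1)

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v_ij = np.mean(pres_ref[i] * q_ref[j] + pres_alt[i] * q_alt[j])
            v_ji = np.mean(pres_ref[j] * q_ref[i] + pres_alt[j] * q_alt[i])
            d[i, j] = d[j, i] = 0.5 * (v_ij + v_ji)

    # private richness: seen in i's sample, unseen in every other sample
    with np.errstate(divide="ignore"):
        log_q_ref = np.log(q_ref)
        log_q_alt = np.log(q_alt)
    tot_log_ref = log_q_ref.sum(axis=0)
    tot_log_alt = log_q_alt.sum(axis=0)
    P_i = np.empty(n)
    for i in range(n):
        with np.errstate(invalid="ignore"):
            others_ref = np.exp(tot_log_ref - log_q_ref[i])
            others_alt = np.exp(tot_log_alt - log_q_alt[i])
        # q == 0 rows make the log-sum trick ill-defined; recompute exactly
        if np.isnan(others_ref).any() or np.isnan(others_alt).any():
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            others_ref = q_ref[mask].prod(axis=0)
            others_alt = q_alt[mask].prod(axis=0)
        P_i[i] = np.mean(pres_ref[i] * others_ref + pres_alt[i] * others_alt)

    AS = float(as_i.mean())
    DA = float(d.sum() / n**2)
    return AllelicRichnessPartition(
        list(counts.subpop_labels), int(g), as_i, d, AS, DA, AS + DA, P_i,
        n_loci_used=int(usable.sum()),
    )


def private_allele_richness(
    counts: AlleleCounts, included: list[str] | None = None, g: int | None = None
) -> pd.Series:
    """Expected rarefied count of alleles seen only in each subpopulation."""
    part = allelic_richness_partition(counts, included, g)
    return pd.Series(part.P_i, index=part.subpops, name="P_i")


# ---------------------------------------------------------------------------
# Leave-one-out contributions
# ---------------------------------------------------------------------------


def marginal_contributions(
    counts: AlleleCounts,
    targets: list[str] | None = None,
    outgroup: str | None = None,
    g: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out percent contributions to each diversity component.

    For target k: cHT_k = 100 (HT_full - HT_without_k) / HT_full, and cHS/cDG
    use the same HT_full denominator so cHS + cDG = cHT; identically for
    cAS/cDA/cAT over AT_full.  The rarefaction size g and the usable-locus set
    are frozen at their full-set values across removals.  The outgroup is
    always retained and is not a default target.
    """
    labels = list(counts.subpop_labels)
    if len(labels) < 3:
        raise ValueError("leave-one-out contributions need >= 3 subpopulations")
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among subpopulations")
    if targets is None:
        targets = [s for s in labels if s != outgroup]
    for t in targets:
        if t not in labels:
            raise ValueError(f"target {t!r} not among subpopulations")
        if len(labels) - 1 < 2:
            raise ValueError("removal would leave fewer than 2 subpopulations")

    full_gd = gene_diversity_partition(counts)
    if g is None:
        g = choose_rarefaction_size(counts)
    full_mask = _usable_allelic(counts, g)
    full_ar = allelic_richness_partition(counts, g=g, locus_mask=full_mask)

    ht0, at0 = full_gd.HT, full_ar.AT
    sizes_tot = counts.tot.max(axis=1)  # 2 x individuals per subpop (no-missing cap)
    rows = []
    for k in targets:
        rest = [s for s in labels if s != k]
        gd = gene_diversity_partition(counts, rest)
        ar = allelic_richness_partition(counts, rest, g=g, locus_mask=full_mask)
        if ht0 != 0:
            chs = 100.0 * (full_gd.HS - gd.HS) / ht0
            cdg = 100.0 * (full_gd.DG - gd.DG) / ht0
            cht = 100.0 * (ht0 - gd.HT) / ht0
        else:
            chs = cdg = cht = np.nan
        if at0 != 0:
            cas = 100.0 * (full_ar.AS - ar.AS) / at0
            cda = 100.0 * (full_ar.DA - ar.DA) / at0
            cat = 100.0 * (at0 - ar.AT) / at0
        else:
            cas = cda = cat = np.nan
        ki = labels.index(k)
        rows.append(
            {
                "subpopulation": k,
                "n": int(sizes_tot[ki] // 2),
                "HS_i": full_gd.HS_i[ki],
                "AS_i": full_ar.AS_i[ki],
                "P_i": full_ar.P_i[ki],
                "cHS": chs,
                "cDG": cdg,
                "cHT": cht,
                "cAS": cas,
                "cDA": cda,
                "cAT": cat,
                "g": int(g),
            }
        )
    return pd.DataFrame(rows).set_index("subpopulation")


def group_level_partition(
    counts: AlleleCounts,
    group_of: dict[str, str],
    outgroup: str | None = None,
) -> pd.DataFrame:
    """Descriptive group-level analysis: pool each group's subpopulations into
    one subpopulation, then recompute the leave-one-out contributions over
    groups.  Pooling is acceptable for description only (rarefaction is a
    subpopulation-level concept); the per-group summary mirrors the
    N / gene diversity / allelic richness / contribution columns.
    """
    labels = list(counts.subpop_labels)
    for s in labels:
        if s not in group_of:
            raise ValueError(f"subpopulation {s!r} has no group label")
    groups: dict[str, list[int]] = {}
    for k, s in enumerate(labels):
        groups.setdefault(group_of[s], []).append(k)
    glabels = list(groups)
    ref = np.vstack([counts.ref[rows].sum(axis=0) for rows in groups.values()])
    tot = np.vstack([counts.tot[rows].sum(axis=0) for rows in groups.values()])
    if (tot.min(axis=1) < 2).any():
        small = [g for g, t in zip(glabels, tot.min(axis=1)) if t < 2]
        raise ValueError(f"groups with fewer than 2 observed copies: {small}")
    gcounts = AlleleCounts(glabels, list(counts.locus_ids), ref, tot)
    og_group = group_of.get(outgroup) if outgroup is not None else None
    contrib = marginal_contributions(gcounts, outgroup=og_group)

    g = choose_rarefaction_size(gcounts)
    usable = _usable_allelic(gcounts, g)
    q_ref, q_alt = _q_matrices(gcounts, g, usable)
    richness = ((1.0 - q_ref) + (1.0 - q_alt)).mean(axis=1)
    hs = gene_diversity_within(gcounts)
    out = contrib.copy()
    out.insert(0, "n_subpopulations", [len(groups[g_]) for g_ in out.index])
    out.insert(1, "gene_diversity", [hs[g_] for g_ in out.index])
    out.insert(2, "allelic_richness", [richness[glabels.index(g_)] for g_ in out.index])
    return out
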