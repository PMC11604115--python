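"""Stage 5: structure summary and downstream association statistics.

Runs a genotype PCA (per-subpopulation mean eigenvectors), cross-classifies
contribution signs against sample-size classes, applies the generalized CMH
test to the resulting crosstab, and correlates the gene-diversity and
allelic-richness contribution components.

Usage: python analysis/05_structure_and_associations.py [--out results/analysis]
"""

import argparse
from pathlib import Path

import pandas as pd

from metapopdiv.genotypes import read_ped_map
from metapopdiv.popstats import (
    classify_signs,
    cmh_test,
    paired_correlations,
    pca_genotypes,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    gm, subs = read_ped_map(args.out / "filtered.ped", args.out / "filtered.map")
    subs.outgroup = "outgroup" if "outgroup" in subs.subpopulations() else None

    pca = pca_genotypes(gm, m=4, subs=subs)
    pca.eigenvectors.to_csv(args.out / "pca_eigenvectors.tsv", sep="\t")
    if pca.subpop_means is not None:
        pca.subpop_means.to_csv(args.out / "pca_subpop_means.tsv", sep="\t")
    pv = ", ".join(f"{100 * v:.2f}%" for v in pca.proportion_variance)
    print(f"PCA variance explained: {pv}")

    contrib = pd.read_csv(args.out / "contributions.tsv", sep="\t", index_col=0)
    labels, crosstab = classify_signs(contrib, size_scheme="lt10")
    labels.to_csv(args.out / "sign_classes.tsv", sep="\t")
    print(crosstab.to_string())

    rows = []
    if crosstab.shape[0] >= 2 and crosstab.shape[1] >= 2:
        q, df, p = cmh_test([crosstab.to_numpy()])
        rows.append({"test": "CMH size x sign", "statistic": q, "df": df, "p": p})
    for a, b in (("cHS", "cAS"), ("cDG", "cDA"), ("cHT", "cAT")):
        cr = paired_correlations(contrib[a], contrib[b])
        rows.append(
            {
                "test": f"corr {a}~{b}",
                "pearson": cr.pearson_r,
                "spearman": cr.spearman_r,
                "p_spearman": cr.spearman_p,
                "n": cr.n_used,
            }
        )
    stats = pd.DataFrame(rows)
    stats.to_csv(args.out / "association_stats.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
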