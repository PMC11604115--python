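"""Stage 2: cohort-assembly filters.

Removes subpopulations sampled below 6 individuals (the outgroup is exempt)
and loci whose within-subpopulation heterozygote deficit FIS exceeds 0.9 in
any subpopulation (null-allele screen); writes the filtered PED/MAP and the
removal reports.

Usage: python analysis/02_cohort_filters.py [--out results/analysis]
"""

import argparse
from pathlib import Path

from metapopdiv.genotypes import (
    filter_null_allele_loci,
    filter_small_subpopulations,
    read_ped_map,
    write_ped_map,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--min-n", type=int, default=6)
    ap.add_argument("--fis-threshold", type=float, default=0.9)
    args = ap.parse_args()

    gm, subs = read_ped_map(args.out / "cohort.ped", args.out / "cohort.map")
    subs.outgroup = "outgroup" if "outgroup" in subs.subpopulations() else None
    gm, subs, size_rep = filter_small_subpopulations(gm, subs, args.min_n)
    gm, fis_rep = filter_null_allele_loci(gm, subs, args.fis_threshold)
    size_rep.to_csv(args.out / "removed_subpopulations.tsv", sep="\t", index=False)
    fis_rep.to_csv(args.out / "removed_loci.tsv", sep="\t", index=False)
    write_ped_map(gm, subs, args.out / "filtered.ped", args.out / "filtered.map")
    print(
        f"removed {len(size_rep)} subpopulations and {len(fis_rep)} loci; "
        f"kept {gm.n_individuals} individuals x {gm.n_loci} loci"
    )


if __name__ == "__main__":
    main()
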