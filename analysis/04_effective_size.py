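"""Stage 4: per-subpopulation effective population size.

LD-prunes the panel (window 50, step 10, r^2 <= 0.2), then estimates Ne per
subpopulation by the LD method (Pcrit = 0.05, delete-one-individual jackknife
CI) and the molecular-coancestry method (delete-one-locus jackknife CI).

Usage: python analysis/04_effective_size.py [--out results/analysis]
"""

import argparse
from pathlib import Path

from metapopdiv.genotypes import read_ped_map
from metapopdiv.ne import ld_prune, ne_by_subpopulation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--no-jackknife", action="store_true")
    args = ap.parse_args()

    gm, subs = read_ped_map(args.out / "filtered.ped", args.out / "filtered.map")
    subs.outgroup = "outgroup" if "outgroup" in subs.subpopulations() else None
    panel = ld_prune(gm, window=50, step=10, r2max=0.2)
    tab = ne_by_subpopulation(
        gm, subs, panel, pcrit=0.05, jackknife=not args.no_jackknife
    )
    tab.to_csv(args.out / "ne_estimates.tsv", sep="\t", index=False)
    print(f"pruned panel: {len(panel.retained)} / {gm.n_loci} loci retained")
    print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
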