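"""End-to-end orchestration: filters -> diversity partitions -> leave-one-out
contributions (whole set and configured subsets, outgroup always retained) ->
LD pruning -> effective sizes -> structure and association statistics.

Every stage writes a TSV; a JSON manifest records the config hash, seed and
per-stage bookkeeping (counts before/after each filter).  Reruns with the same
config and seed produce identical numerical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    GenotypeMatrix,
    SubpopulationMap,
    count_alleles,
    filter_null_allele_loci,
    filter_small_subpopulations,
    read_ped_map,
)
from .diversity import group_level_partition, marginal_contributions
from .ne import ld_prune, ne_by_subpopulation
from .popstats import classify_signs, cmh_test, paired_correlations, pca_genotypes


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    ped_path: str | None = None
    map_path: str | None = None
    outgroup: str | None = None
    subsets: dict[str, list[str]] = field(default_factory=dict)
    min_n: int = 6
    fis_threshold: float = 0.9
    pcrit: float = 0.05
    prune_window: int = 50
    prune_step: int = 10
    prune_r2max: float = 0.2
    run_ne: bool = True
    jackknife: bool = True
    pca_components: int = 4
    size_scheme: str = "lt10"
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate_subsets(cfg: AnalysisConfig, subs: SubpopulationMap) -> None:
    known = set(subs.subpopulations())
    for name, members in cfg.subsets.items():
        unknown = [s for s in members if s not in known]
        if unknown:
            raise ValueError(f"subset {name!r} references unknown subpopulations: {unknown}")
        if cfg.outgroup is not None and cfg.outgroup not in members:
            raise ValueError(
                f"subset {name!r} must retain the outgroup {cfg.outgroup!r}"
            )


def run_full_analysis(
    cfg: AnalysisConfig,
    gm: GenotypeMatrix | None = None,
    subs: SubpopulationMap | None = None,
) -> dict:
    """Run the whole analysis; returns the result bundle and writes TSVs.

    ``gm``/``subs`` may be passed directly (e.g. from the simulators); else
    they are read from the configured PED/MAP pair.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}
    stage = "load"
    try:
        if gm is None:
            if cfg.ped_path is None or cfg.map_path is None:
                raise ValueError("no genotypes passed and no PED/MAP configured")
            gm, subs_read = read_ped_map(cfg.ped_path, cfg.map_path)
            if subs is None:
                subs = subs_read
                subs.outgroup = cfg.outgroup
        assert subs is not None
        _validate_subsets(cfg, subs)
        manifest["stages"][stage] = {
            "individuals": gm.n_individuals,
            "loci": gm.n_loci,
            "subpopulations": len(subs.subpopulations()),
        }

        stage = "filter"
        gm, subs, size_report = filter_small_subpopulations(gm, subs, cfg.min_n)
        gm, fis_report = filter_null_allele_loci(gm, subs, cfg.fis_threshold)
        size_report.to_csv(out / "removed_subpopulations.tsv", sep="\t", index=False)
        fis_report.to_csv(out / "removed_loci.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "individuals_after": gm.n_individuals,
            "loci_after": gm.n_loci,
            "subpopulations_removed": len(size_report),
            "loci_removed": len(fis_report),
        }

        stage = "contributions"
        analyses = {"whole": subs.subpopulations()}
        analyses.update(cfg.subsets)
        contrib_tables: dict[str, pd.DataFrame] = {}
        for name, members in analyses.items():
            counts = count_alleles(gm, subs, members)
            tab = marginal_contributions(counts, outgroup=subs.outgroup)
            tab.to_csv(out / f"contributions_{name}.tsv", sep="\t")
            contrib_tables[name] = tab
        bundle["contributions"] = contrib_tables
        manifest["stages"][stage] = {name: len(t) for name, t in contrib_tables.items()}

        if subs.group:
            stage = "groups"
            counts = count_alleles(gm, subs)
            group_of = {
                s: subs.group.get(s, s) for s in subs.subpopulations()
            }
            gtab = group_level_partition(counts, group_of, subs.outgroup)
            gtab.to_csv(out / "group_contributions.tsv", sep="\t")
            bundle["groups"] = gtab

        if cfg.run_ne:
            stage = "ne"
            panel = ld_prune(gm, cfg.prune_window, cfg.prune_step, cfg.prune_r2max)
            ne_tab = ne_by_subpopulation(
                gm, subs, panel, cfg.pcrit, jackknife=cfg.jackknife
            )
            ne_tab.to_csv(out / "ne_estimates.tsv", sep="\t", index=False)
            bundle["ne"] = ne_tab
            manifest["stages"][stage] = {
                "pruned_loci": len(panel.retained), "rows": len(ne_tab)
            }

        stage = "pca"
        pca = pca_genotypes(gm, cfg.pca_components, subs)
        pca.eigenvectors.to_csv(out / "pca_eigenvectors.tsv", sep="\t")
        if pca.subpop_means is not None:
            pca.subpop_means.to_csv(out / "pca_subpop_means.tsv", sep="\t")
        bundle["pca"] = pca
        manifest["stages"][stage] = {
            "proportion_variance": [float(v) for v in pca.proportion_variance]
        }

        stage = "stats"
        whole = contrib_tables["whole"]
        labels, tab = classify_signs(whole, cfg.size_scheme)
        labels.to_csv(out / "sign_classes.tsv", sep="\t")
        stats_rows = []
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            q, df, p = cmh_test([tab.to_numpy()])
            stats_rows.append({"test": "CMH size x sign", "statistic": q, "df": df, "p": p})
        for pair in (("cHS", "cAS"), ("cDG", "cDA"), ("cHT", "cAT")):
            cr = paired_correlations(whole[pair[0]], whole[pair[1]])
            stats_rows.append(
                {
                    "test": f"corr {pair[0]}~{pair[1]}",
                    "pearson": cr.pearson_r,
                    "spearman": cr.spearman_r,
                    "p_pearson": cr.pearson_p,
                    "p_spearman": cr.spearman_p,
                    "n": cr.n_used,
                }
            )
        stats_tab = pd.DataFrame(stats_rows)
        stats_tab.to_csv(out / "association_stats.tsv", sep="\t", index=False)
        bundle["stats"] = stats_tab
        bundle["sign_classes"] = labels
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def consistency_report(
    whole: pd.DataFrame, subset: pd.DataFrame
) -> pd.DataFrame:
    """Rank/product-moment agreement of contributions between the whole-set
    analysis and a subset analysis, over common target subpopulations."""
    common = [s for s in whole.index if s in set(subset.index)]
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping target subpopulations")
    rows = []
    for col in ("cHT", "cAT"):
        cr = paired_correlations(
            whole.loc[common, col].to_numpy(), subset.loc[common, col].to_numpy()
        )
        rows.append(
            {
                "component": col,
                "spearman": cr.spearman_r,
                "pearson": cr.pearson_r,
                "n": cr.n_used,
            }
        )
    return pd.DataFrame(rows)
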