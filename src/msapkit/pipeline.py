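"""End-to-end MSAP analysis: score -> classify -> diversity -> differentiation.

One call reproduces the full analysis of a band-matrix pair: methylation
state scoring, MSL/NML locus classification, global methylation levels,
per-locus Shannon diversity with the MSL-vs-NML Wilcoxon comparison,
global and pairwise AMOVA/PhiST for the MSL, NML and all-loci (AFLP mode)
partitions, PCoA ordinations, and the group mean/median statistics
battery.  The bundle is a pure function of (inputs, config, seed):
identical runs give identical numeric outputs.
"""

from __future__ import annotations


import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differentiation import (
    amova,
    aflp_mode_phist,
    pairwise_distance,
    pairwise_phist,
    pcoa,
)
from .diversity import group_battery, shannon_per_locus, wilcoxon_rank_sum
from .io_formats import BandMatrixPair, MsapError, SampleSheet, read_msap_table
from .scoring import (
    ScoringConfig,
    binarize_msl,
    binarize_nml,
    classify_loci,
    classify_states,
    methylation_level,
    state_proportions,
)

logger = logging.getLogger("msapkit")


def configure_logging(level: str = "INFO", quiet: bool = False) -> None:
    """Stage logging to stderr; ``quiet`` suppresses all but errors."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.ERROR if quiet else getattr(logging, level.upper(), logging.INFO))


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one full-analysis run."""

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    missing_policy: str = "pairwise"
    n_perm: int = 10_000
    seed: int | None = None
    outliers_removed: tuple[str, ...] = ()
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.n_perm > 0 and self.seed is None:
            raise MsapError("a seed is required when n_perm > 0 (reproducibility)")


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run (in-memory; optionally on disk)."""

    state_proportions: pd.DataFrame
    locus_summary: pd.DataFrame
    shannon_summary: pd.DataFrame
    shannon_per_locus: pd.DataFrame
    amova_tables: dict[str, pd.DataFrame]
    phist_pairwise: dict[str, pd.DataFrame]
    pcoa_coordinates: dict[str, pd.DataFrame]
    pcoa_eigenvalues: dict[str, pd.DataFrame]
    stats_battery: dict[str, object]
    methylation_individual: pd.DataFrame
    methylation_population: pd.DataFrame
    manifest: dict


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_full_analysis(
    pair: BandMatrixPair,
    sheet: SampleSheet,
    config: PipelineConfig,
) -> ReportBundle:
    """Run the complete MSAP analysis on one band-matrix pair."""
    t0 = _stage("classify_states")
    groups = sheet.groups(pair.individuals)
    states = classify_states(pair, populations=groups)

    _stage("classify_loci")
    classes = classify_loci(states, config.scoring)
    locus_summary = pd.DataFrame(
        {
            "partition": ["MSL", "NML", "total"],
            "n_loci": [classes.n_msl, classes.n_nml, len(classes.loci)],
            "n_polymorphic": [
                classes.n_msl_polymorphic,
                classes.n_nml_polymorphic,
                classes.n_msl_polymorphic + classes.n_nml_polymorphic,
            ],
        }
    )
    locus_summary["percent_polymorphic"] = (
        100.0 * locus_summary["n_polymorphic"] / locus_summary["n_loci"]
    )

    # Methylation levels and state proportions are read off the MSL
    # partition: at NML loci the band pattern is genetic, so including
    # them would dilute the (II+III)/(I+II+III) proportion.
    _stage("methylation_level")
    msl_states = states.subset_loci(classes.is_msl)
    levels = methylation_level(msl_states)
    props = state_proportions(msl_states)

    _stage("binarize")
    msl_mat, msl_loci = binarize_msl(states, classes, config.scoring)
    nml_mat, nml_loci = binarize_nml(states, classes, config.scoring)

    _stage("shannon")
    sh_msl = shannon_per_locus(msl_mat, msl_loci, partition="MSL")
    sh_nml = shannon_per_locus(nml_mat, nml_loci, partition="NML")
    W, w_p = wilcoxon_rank_sum(sh_msl.values, sh_nml.values)
    shannon_summary = pd.DataFrame(
        {
            "partition": ["MSL", "NML"],
            "n_loci": [len(sh_msl.values), len(sh_nml.values)],
            "mean_shannon_i": [sh_msl.mean, sh_nml.mean],
            "sd_shannon_i": [sh_msl.sd, sh_nml.sd],
            "wilcoxon_w": [W, np.nan],
            "wilcoxon_p": [w_p, np.nan],
        }
    )
    shannon_long = pd.concat([sh_msl.to_frame(), sh_nml.to_frame()], ignore_index=True)

    ids = list(pair.individuals)
    seeds = {}
    if config.seed is not None:
        for i, name in enumerate(("MSL", "NML", "AFLP")):
            ss = np.random.SeedSequence(config.seed, spawn_key=(100 + i,))
            seeds[name] = int(ss.generate_state(1)[0] % (2**31))

    amova_tables: dict[str, pd.DataFrame] = {}
    phist_tables: dict[str, pd.DataFrame] = {}
    pcoa_coords: dict[str, pd.DataFrame] = {}
    pcoa_eigs: dict[str, pd.DataFrame] = {}
    for name, mat in (("MSL", msl_mat), ("NML", nml_mat)):
        _stage(f"differentiation[{name}]")
        dist = pairwise_distance(mat, ids=ids, missing_policy=config.missing_policy)
        res = amova(dist, groups, n_perm=config.n_perm, seed=seeds.get(name))
        tab = res.to_frame()
        tab["phi_st"] = [res.phi_st, np.nan]
        tab["p_value"] = [res.p_value, np.nan]
        amova_tables[name] = tab
        phist_tables[name] = pairwise_phist(
            mat, ids, groups, n_perm=config.n_perm, seed=seeds.get(name),
            missing_policy=config.missing_policy,
        )
        ordination = pcoa(dist)
        pcoa_coords[name] = ordination.to_frame()
        pcoa_eigs[name] = pd.DataFrame(
            {
                "axis": np.arange(1, len(ordination.eigenvalues) + 1),
                "eigenvalue": ordination.eigenvalues,
                "percent_variance": ordination.percent_variance,
            }
        )

    _stage("differentiation[AFLP]")
    aflp_global, aflp_pairs = aflp_mode_phist(
        pair, groups, n_perm=config.n_perm, seed=seeds.get("AFLP")
    )
    tab = aflp_global.to_frame()
    tab["phi_st"] = [aflp_global.phi_st, np.nan]
    tab["p_value"] = [aflp_global.p_value, np.nan]
    amova_tables["AFLP"] = tab
    phist_tables["AFLP"] = aflp_pairs

    _stage("group_battery")
    ind = levels.individual_levels.set_index("individual")
    battery = group_battery(
        ind["proportion"],
        ind["population"],
        outliers_removed=list(config.outliers_removed),
    )
    battery_dict = {
        "shapiro": {
            "statistic": battery.shapiro_statistic,
            "p": battery.shapiro_p,
            "interpretable": battery.shapiro_interpretable,
        },
        "means_test": battery.means_test,
        "means_F": battery.means_F,
        "means_df": battery.means_df,
        "means_p": battery.means_p,
        "kruskal": {"H": battery.kruskal_H, "Hc": battery.kruskal_Hc, "p": battery.kruskal_p},
        "tukey_q": battery.tukey_q,
        "tukey_p": battery.tukey_p,
        "mannwhitney_p": battery.mannwhitney_p,
        "group_summary": battery.group_summary,
        "outliers_removed": battery.outliers_removed,
    }

    manifest = {
        "msapkit_version": __version__,
        "n_individuals": pair.n_individuals,
        "n_loci": pair.n_loci,
        "populations": {p: int((groups == p).sum()) for p in pd.unique(groups)},
        "config": {
            "ert": config.scoring.ert,
            "type_iv_policy": config.scoring.type_iv_policy.value,
            "nml_presence": config.scoring.nml_presence.value,
            "missing_policy": config.missing_policy,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "outliers_removed": list(config.outliers_removed),
        },
    }
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)

    bundle = ReportBundle(
        state_proportions=props,
        locus_summary=locus_summary,
        shannon_summary=shannon_summary,
        shannon_per_locus=shannon_long,
        amova_tables=amova_tables,
        phist_pairwise=phist_tables,
        pcoa_coordinates=pcoa_coords,
        pcoa_eigenvalues=pcoa_eigs,
        stats_battery=battery_dict,
        methylation_individual=levels.individual_levels,
        methylation_population=levels.population_levels,
        manifest=manifest,
    )
    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> Path:
    """Write every bundle artifact as TSV (manifest as JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(outdir / name, sep="\t", index=index, float_format="%.10g")

    tsv(bundle.state_proportions, "state_proportions.tsv")
    tsv(bundle.locus_summary, "locus_classification.tsv")
    tsv(bundle.shannon_summary, "shannon_summary.tsv")
    tsv(bundle.shannon_per_locus, "shannon_per_locus.tsv")
    tsv(bundle.methylation_individual, "methylation_individual.tsv")
    tsv(bundle.methylation_population, "methylation_population.tsv")
    for name in bundle.amova_tables:
        tsv(bundle.amova_tables[name], f"amova_{name.lower()}.tsv")
        tsv(bundle.phist_pairwise[name], f"phist_pairwise_{name.lower()}.tsv")
    for name in bundle.pcoa_coordinates:
        tsv(bundle.pcoa_coordinates[name], f"pcoa_coords_{name.lower()}.tsv")
        tsv(bundle.pcoa_eigenvalues[name], f"pcoa_eigenvalues_{name.lower()}.tsv")

    battery = bundle.stats_battery
    tsv(battery["tukey_q"], "battery_tukey_q.tsv", index=True)
    tsv(battery["tukey_p"], "battery_tukey_p.tsv", index=True)
    tsv(battery["mannwhitney_p"], "battery_mannwhitney_p.tsv", index=True)
    tsv(battery["group_summary"], "battery_group_summary.tsv")
    scalars = {
        k: battery[k] for k in ("shapiro", "means_test", "means_F", "means_df", "means_p", "kruskal", "outliers_removed")
    }
    (outdir / "battery_tests.json").write_text(json.dumps(scalars, indent=2, default=str))
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    return outdir


def analyze_file(path: str | Path, config: PipelineConfig) -> ReportBundle:
    """Read an msap-dialect CSV and run the full analysis."""
    pair, sheet = read_msap_table(path)
    return run_full_analysis(pair, sheet, config)
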