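"""End-to-end orchestration of the dysbiosis analysis.

Stage order mirrors the study workflow: depth normalization -> alpha
diversity with per-timepoint Wilcoxon -> generalized UniFrac + PCoA +
pairwise PERMANOVA -> per-level association testing -> representative-taxon
selection -> MCPI with per-timepoint ANOVA -> LME margins for the
representative taxa. Every stage logs shapes and surviving counts; outputs
are plain TSV/JSON, reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import LEVELS, aggregate_all_levels
from .association import associate, select_representatives
from .containers import DEFAULT_TIMEPOINTS, AbundanceTable, CohortMetadata
from .diversity import generalized_unifrac, normalize_to_max_depth, pcoa, shannon_by_sample
from .io import check_tree_covers_table, write_distance_tsv
from .longitudinal import LmeSpec, fit_lme, predictive_margins
from .mcpi import MCPIConfig, compare_mcpi_by_timepoint, compute_mcpi
from .simulate import CohortDesign, PlantedEffect, default_planted_effect, simulate_cohort
from .stats import DEFAULT_SEED, permanova, permanova_pairwise, wilcoxon_rank_sum

logger = logging.getLogger("rtdysbiosis")

__all__ = ["RunConfig", "run_all", "simulate_and_run"]


@dataclass
class RunConfig:
    """Tunable parameters of a full pipeline run."""

    timepoint_order: tuple = DEFAULT_TIMEPOINTS
    unifrac_alpha: float = 0.5
    abundance_cutoff: float = 0.01
    q_threshold: float = 0.05
    mcpi_epsilon: float = 1e-8
    mcpi_pseudocount: float = 1e-6
    #: 'mixed' scores MCPI on the three-level representative sets; 'family'
    #: restricts to the family-level representatives only
    mcpi_mode: str = "mixed"
    n_permutations: int = 999
    seed: int = DEFAULT_SEED
    lme_group: str = "toxicity"
    lme_grid: tuple | None = None
    normalization: str = "max-depth"  # or 'rarefy'

    def __post_init__(self) -> None:
        if self.mcpi_mode not in ("mixed", "family"):
            raise ValueError("mcpi_mode must be 'mixed' or 'family'")
        if not 0.0 <= self.unifrac_alpha <= 1.0:
            raise ValueError("unifrac_alpha must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("alpha-diversity")
def _alpha_stage(rel_species, metadata, config):
    shannon = shannon_by_sample(rel_species)
    meta = metadata.indexed()
    rows = []
    for tp in config.timepoint_order:
        at = meta[meta["timepoint"] == tp]
        tox = shannon[at.loc[at["toxicity"] == 1, "sample_id"]].to_numpy()
        notox = shannon[at.loc[at["toxicity"] == 0, "sample_id"]].to_numpy()
        if tox.size == 0 or notox.size == 0:
            continue
        res = wilcoxon_rank_sum(tox, notox, mode="normal")
        rows.append(
            {
                "timepoint": tp,
                "mean_shannon_tox": float(tox.mean()),
                "mean_shannon_notox": float(notox.mean()),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_tox": tox.size,
                "n_notox": notox.size,
            }
        )
    alpha_df = pd.DataFrame(rows)
    logger.info("alpha diversity: %d timepoints tested", len(alpha_df))
    return shannon, alpha_df


@_stage("beta-diversity")
def _beta_stage(rel_species, metadata, tree, config):
    check_tree_covers_table(tree, rel_species)
    dm = generalized_unifrac(rel_species, tree, alpha=config.unifrac_alpha)
    ordination = pcoa(dm, n_components=2)
    meta = metadata.align(rel_species).frame
    overall = permanova(
        dm,
        meta["toxicity"].to_numpy(),
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    overall_df = pd.DataFrame(
        [
            {
                "comparison": "toxicity_vs_no_toxicity",
                "pseudo_F": overall.pseudo_f,
                "p_value": overall.p_value,
                "n_permutations": overall.n_permutations,
            }
        ]
    )
    # pairwise timepoints within each toxicity stratum
    rows = []
    for tox_flag, name in ((1, "toxicity"), (0, "no_toxicity")):
        mask = meta["toxicity"].to_numpy() == tox_flag
        ids = meta.loc[mask, "sample_id"].tolist()
        sub = dm.filter(ids)
        labels = meta.set_index("sample_id").loc[list(sub.ids), "timepoint"].to_numpy()
        for res in permanova_pairwise(
            sub, labels, n_permutations=config.n_permutations, seed=config.seed
        ):
            rows.append(
                {
                    "stratum": name,
                    "group_a": res.groups[0],
                    "group_b": res.groups[1],
                    "pseudo_F": res.pseudo_f,
                    "p_value": res.p_value,
                    "q_value": res.q_value,
                }
            )
    pairwise_df = pd.DataFrame(rows)
    logger.info("beta diversity: %d pairwise PERMANOVA tests", len(pairwise_df))
    return dm, ordination, overall_df, pairwise_df


@_stage("association")
def _association_stage(rel_by_level, metadata, config):
    results = {}
    for level in LEVELS:
        res = associate(
            rel_by_level[level], metadata, level=level, cutoff=config.abundance_cutoff
        )
        results[level] = res
        logger.info(
            "association %s: %d taxa tested, %d at q<%g",
            level, len(res), int((res["q_value"] < config.q_threshold).sum()),
            config.q_threshold,
        )
    return results


@_stage("mcpi")
def _mcpi_stage(rel_by_level, metadata, reps, config):
    if config.mcpi_mode == "family":
        if "family" not in reps.T or "family" not in reps.N:
            logger.warning("family-level representatives incomplete; MCPI skipped")
            return None, None, None
        mcpi_cfg = MCPIConfig(
            T=[reps.T["family"]],
            N=[reps.N["family"]],
            epsilon=config.mcpi_epsilon,
            pseudocount=config.mcpi_pseudocount,
        )
        series = compute_mcpi(rel_by_level["family"], mcpi_cfg, metadata)
    else:
        if not reps.T or not reps.N:
            logger.warning("representative sets incomplete; MCPI skipped")
            return None, None, None
        mcpi_cfg = MCPIConfig(
            T=[(lvl, tax) for lvl, tax in reps.T.items()],
            N=[(lvl, tax) for lvl, tax in reps.N.items()],
            epsilon=config.mcpi_epsilon,
            pseudocount=config.mcpi_pseudocount,
        )
        series = compute_mcpi(rel_by_level, mcpi_cfg, metadata)
    comparison = compare_mcpi_by_timepoint(series, config.timepoint_order)
    return mcpi_cfg, series, comparison


@_stage("lme")
def _lme_stage(rel_by_level, metadata, reps, config):
    grid = (
        list(config.lme_grid)
        if config.lme_grid is not None
        else sorted({int(d) for d in metadata.frame["days"]})
    )
    rows = []
    for side, mapping in (("T", reps.T), ("N", reps.N)):
        for level, taxon in mapping.items():
            spec = LmeSpec(response=taxon, group=config.lme_group)
            model = fit_lme(rel_by_level[level], metadata, spec)
            margins = predictive_margins(model, grid)
            df = margins.frame.copy()
            df.insert(0, "taxon_id", taxon)
            df.insert(1, "level", level)
            df.insert(2, "set", side)
            df.insert(3, "converged", model.converged_)
            rows.append(df)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    logger.info("lme: margins for %d representative taxa", len(rows))
    return out


def run_all(
    tables: dict,
    metadata: CohortMetadata,
    tree,
    config: RunConfig | None = None,
    outdir=None,
) -> dict:
    """Execute the full analysis.

    Parameters
    ----------
    tables
        Mapping level -> count :class:`AbundanceTable` (at least 'species';
        missing levels are skipped in association).
    metadata, tree
        Cohort covariates and the rooted phylogeny over species-level taxa.
    config
        Run parameters; defaults to :class:`RunConfig()`.
    outdir
        If given, all result tables plus a manifest are written there as TSV
        and JSON.

    Returns a dict of result objects keyed by stage.
    """
    config = config or RunConfig()
    if "species" not in tables:
        raise ValueError("tables must include the 'species' level")
    if tree is None:
        raise ValueError("a phylogenetic tree is required for UniFrac")
    check_tree_covers_table(tree, tables["species"])

    norm_by_level = {}
    for level, tab in tables.items():
        norm = normalize_to_max_depth(tab) if tab.unit == "counts" else tab
        norm_by_level[level] = norm
    rel_by_level = {lvl: t.relative_abundance() for lvl, t in norm_by_level.items()}
    rel_species = rel_by_level["species"]
    metadata = metadata.align(rel_species)
    logger.info(
        "inputs: %d taxa x %d samples, %d patients",
        *rel_species.shape, len(metadata.patient_ids),
    )

    shannon, alpha_df = _alpha_stage(rel_species, metadata, config)
    dm, ordination, permanova_df, permanova_pairwise_df = _beta_stage(
        rel_species, metadata, tree, config
    )
    assoc = _association_stage(
        {lvl: rel_by_level[lvl] for lvl in LEVELS if lvl in rel_by_level},
        metadata,
        config,
    )
    reps = select_representatives(assoc, q_threshold=config.q_threshold)
    mcpi_cfg, mcpi_series, mcpi_comparison = _mcpi_stage(
        rel_by_level, metadata, reps, config
    )
    lme_df = _lme_stage(rel_by_level, metadata, reps, config)

    results = {
        "config": config,
        "shannon": shannon,
        "alpha_tests": alpha_df,
        "distance_matrix": dm,
        "ordination": ordination,
        "permanova": permanova_df,
        "permanova_pairwise": permanova_pairwise_df,
        "association": assoc,
        "representatives": reps,
        "mcpi_config": mcpi_cfg,
        "mcpi": mcpi_series,
        "mcpi_tests": mcpi_comparison,
        "lme_margins": lme_df,
    }
    if outdir is not None:
        _write_bundle(results, metadata, Path(outdir))
    return results


def _write_bundle(results, metadata, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    config = results["config"]
    results["shannon"].rename_axis("sample_id").reset_index().to_csv(
        outdir / "shannon.tsv", sep="\t", index=False, float_format=fmt
    )
    results["alpha_tests"].to_csv(
        outdir / "alpha_tests.tsv", sep="\t", index=False, float_format=fmt
    )
    write_distance_tsv(results["distance_matrix"], outdir / "unifrac_distance.tsv")
    ords = results["ordination"]
    ords.coordinates.rename_axis("sample_id").reset_index().to_csv(
        outdir / "pcoa_coordinates.tsv", sep="\t", index=False, float_format=fmt
    )
    pd.DataFrame(
        {
            "eigenvalue": ords.eigenvalues,
            "proportion_explained": ords.proportion_explained,
        }
    ).to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t", index=False, float_format=fmt)
    results["permanova"].to_csv(
        outdir / "permanova.tsv", sep="\t", index=False, float_format=fmt
    )
    results["permanova_pairwise"].to_csv(
        outdir / "permanova_pairwise.tsv", sep="\t", index=False, float_format=fmt
    )
    for level, df in results["association"].items():
        df.to_csv(
            outdir / f"association_{level}.tsv", sep="\t", index=False, float_format=fmt
        )
    reps = results["representatives"]
    if reps.provenance is not None and len(reps.provenance):
        reps.provenance.to_csv(
            outdir / "representatives.tsv", sep="\t", index=False, float_format=fmt
        )
    if results["mcpi"] is not None:
        results["mcpi"].to_csv(
            outdir / "mcpi.tsv", sep="\t", index=False, float_format=fmt
        )
        results["mcpi_tests"].to_csv(
            outdir / "mcpi_tests.tsv", sep="\t", index=False, float_format=fmt
        )
        cfg = results["mcpi_config"]
        (outdir / "mcpi_config.json").write_text(
            json.dumps(
                {
                    "T": [list(t) if isinstance(t, tuple) else t for t in cfg.T],
                    "N": [list(t) if isinstance(t, tuple) else t for t in cfg.N],
                    "epsilon": cfg.epsilon,
                    "pseudocount": cfg.pseudocount,
                },
                indent=2,
                sort_keys=True,
            )
        )
    if len(results["lme_margins"]):
        results["lme_margins"].to_csv(
            outdir / "lme_margins.tsv", sep="\t", index=False, float_format=fmt
        )
    manifest = {
        "package": "rtdysbiosis",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_samples": len(metadata.frame),
        "n_patients": len(metadata.patient_ids),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )


def simulate_and_run(
    design: CohortDesign | None = None,
    effect: PlantedEffect | None = None,
    config: RunConfig | None = None,
    outdir=None,
) -> dict:
    """Simulate a cohort, run the full pipeline, and compare against truth.

    Adds a ``truth_comparison`` DataFrame (planted vs recovered
    representatives per level and side) and the cohort's ``truth`` record to
    the result bundle.
    """
    design = design or CohortDesign()
    effect = effect if effect is not None else default_planted_effect(design)
    config = config or RunConfig(timepoint_order=design.timepoint_labels)
    cohort = simulate_cohort(design, effect)
    tables = aggregate_all_levels(cohort.table, cohort.lineage)
    results = run_all(tables, cohort.metadata, cohort.tree, config, outdir=outdir)

    reps = results["representatives"]
    planted = cohort.truth["planted_by_level"]
    rows = []
    for side, mapping, key in (("T", reps.T, "tox"), ("N", reps.N, "notox")):
        for level in LEVELS:
            found = mapping.get(level)
            rows.append(
                {
                    "set": side,
                    "level": level,
                    "planted": ";".join(planted[level][key]),
                    "recovered": found if found is not None else "",
                    "correct": found in planted[level][key],
                }
            )
    truth_df = pd.DataFrame(rows)
    results["truth"] = cohort.truth
    results["truth_comparison"] = truth_df
    results["cohort"] = cohort
    if outdir is not None:
        truth_df.to_csv(
            Path(outdir) / "truth_comparison.tsv", sep="\t", index=False
        )
    return results
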