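"""End-to-end pipeline runner: simulate -> preprocess -> statistics.

Runs the full chain on a synthetic experiment defined by a
:class:`~phenolome.config.PipelineConfig`, writing every intermediate
table as TSV plus a machine-readable run manifest.  Every stage is
seeded from the config seed, so a rerun with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import chromproc, effects, io, phenocorr, simdata
from .config import PipelineConfig

__all__ = ["default_trait_specs", "run_pipeline"]

logger = logging.getLogger(__name__)


def default_trait_specs(n_traits: int = 15) -> list[simdata.TraitSpec]:
    """The standard simulated trait panel.

    Mirrors a maturity assessment: most traits respond uniformly and
    negatively to drought (D), a few carry variety-specific deviations
    (VD), and one is left unaffected.
    """
    specs = []
    for i in range(1, n_traits + 1):
        name = f"F{i}"
        if i == 5:  # an unaffected trait (e.g. 1000-grain weight)
            specs.append(simdata.TraitSpec(name, baseline=45.0, baseline_variety_sd=2.0))
        elif i in (2, 3, 13, 14, 15):  # variety-specific responders
            specs.append(
                simdata.TraitSpec(
                    name,
                    baseline=25.0,
                    baseline_variety_sd=2.0,
                    common_effects={"I": -5.0, "II": -3.0, "I+II": -5.0},
                    perturbation_sd=3.0,
                )
            )
        else:  # uniform responders
            specs.append(
                simdata.TraitSpec(
                    name,
                    baseline=30.0,
                    baseline_variety_sd=2.0,
                    common_effects={"I": -6.0, "II": -3.0, "I+II": -6.0},
                )
            )
    return specs


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    design = _stage("simulate")(simdata.make_design)(
        n_varieties=config.n_varieties,
        treatments=tuple(config.treatments),
        n_reps=config.n_reps,
        seed=config.seed,
    )
    chromset, truth = _stage("simulate")(simdata.simulate_experiment)(
        design,
        n_metabolites=config.n_metabolites,
        effect_size=config.effect_size,
        warp_magnitude=config.warp_magnitude,
        noise_sd=config.noise_sd,
        seed=config.seed,
        n_points=config.n_points,
    )
    linked_met = next(
        (m for m, c in truth.categories.items() if c in ("VD", "VD_TD", "VTD")),
        None,
    )
    link = {"F3": (linked_met, -2.0)} if linked_met else {}
    pheno, truth = _stage("simulate")(simdata.simulate_phenotypes)(
        design,
        default_trait_specs(),
        link=link,
        ground_truth=truth,
        n_reps=config.pheno_reps,
        noise_sd=config.pheno_noise_sd,
        seed=config.seed + 1,
    )
    io.write_chromatogram_set(out / "chromatograms", chromset)
    io.write_ground_truth(out / "ground_truth.json", truth)
    io.write_table(out / "phenotypes.tsv", pheno)
    config.to_yaml(out / "config.yaml")
    manifest["stages"]["simulate"] = {
        "n_samples": len(design),
        "n_chromatograms": len(chromset),
        "n_metabolites": config.n_metabolites,
        "n_phenotype_rows": len(pheno),
    }

    # --- preprocess -------------------------------------------------------
    prep = _stage("preprocess")(chromproc.run_preprocessing)(config, chromset)
    io.write_table(out / "metabolite_table.tsv", prep.table)
    io.write_table(out / "common_peaks.tsv", prep.peak_meta)
    manifest["stages"]["preprocess"] = dict(prep.counts)

    # --- effects ----------------------------------------------------------
    table = _stage("effects")(effects.log_transform)(prep.table)
    classification = _stage("effects")(effects.classify_effects)(
        table, alpha_fwer=config.fwer_alpha
    )
    eff = _stage("effects")(effects.compute_effects)(table)
    cat_tab = effects.category_table(classification)
    chi2, p_perm = effects.permutation_chisq(
        cat_tab, n_perm=config.n_permutations, seed=config.seed + 2
    )
    io.write_table(out / "classification.tsv", classification.categories, index=True)
    io.write_table(out / "family_pvalues.tsv", classification.pvalues)
    io.write_table(out / "effects.tsv", eff)
    io.write_table(out / "category_table.tsv", cat_tab, index=True)
    manifest["stages"]["effects"] = {
        "category_table": {t: cat_tab.loc[t].to_dict() for t in cat_tab.index},
        "chi2": chi2,
        "permutation_p": p_perm,
    }

    cluster_rows = []
    for trt in cat_tab.index:
        time_dep = classification.categories.index[
            classification.categories[trt].isin(["TD", "VD_TD", "VTD"])
        ].tolist()
        if len(time_dep) < config.cluster_k:
            continue
        prof = effects.time_profiles(eff, trt, time_dep)
        res = effects.cluster_time_profiles(
            prof,
            k=config.cluster_k,
            n_restarts=config.cluster_restarts,
            seed=config.seed + 3,
        )
        dist = effects.mahalanobis_between_clusters(res)
        for met, lab in res.assignment.items():
            cluster_rows.append({"treatment": trt, "metabolite": met, "cluster": lab})
        manifest["stages"].setdefault("clustering", {})[trt] = {
            "n_profiles": len(prof),
            "within_ss": res.within_ss,
            "between_ss": res.between_ss,
            "method": res.method,
            "max_mahalanobis": float(np.nanmax(dist.to_numpy())),
        }
    if cluster_rows:
        io.write_table(out / "clusters.tsv", pd.DataFrame(cluster_rows))

    # --- phenotypes -------------------------------------------------------
    trait_class = _stage("phenocorr")(phenocorr.classify_trait_effects)(
        pheno, alpha=config.pheno_alpha
    )
    eff_mean_pct = phenocorr.trait_effects(pheno, as_percent_of_control=True)
    eff_var = phenocorr.trait_effects(pheno, per_variety=True)
    io.write_table(out / "trait_classification.tsv", trait_class, index=True)
    io.write_table(out / "trait_effects_percent.tsv", eff_mean_pct)
    io.write_table(out / "trait_effects_by_variety.tsv", eff_var)
    manifest["stages"]["phenocorr"] = {
        "trait_classes": {
            trt: trait_class[trt].value_counts().to_dict()
            for trt in trait_class.columns
        }
    }

    biplot_rows = []
    for trt in trait_class.columns:
        vd_traits = trait_class.index[trait_class[trt] == "VD"].tolist()
        if len(vd_traits) < 2:
            continue
        mat = (
            eff_var[(eff_var["treatment"] == trt) & eff_var["trait"].isin(vd_traits)]
            .pivot(index="variety", columns="trait", values="effect")
        )
        bp = phenocorr.biplot_coords(mat)
        for v, row in bp.scores.iterrows():
            biplot_rows.append(
                {"treatment": trt, "kind": "score", "name": v,
                 "axis1": row["axis1"], "axis2": row["axis2"]}
            )
        for t, row in bp.loadings.iterrows():
            biplot_rows.append(
                {"treatment": trt, "kind": "loading", "name": t,
                 "axis1": row["axis1"], "axis2": row["axis2"]}
            )
    if biplot_rows:
        io.write_table(out / "biplot_coords.tsv", pd.DataFrame(biplot_rows))

    variety_specific = classification.categories.index[
        classification.categories.isin(["VD", "VD_TD", "VTD"]).any(axis=1)
    ].tolist()
    if variety_specific and pheno["variety"].nunique() >= 3:
        met_var_eff = (
            eff[eff["metabolite"].isin(variety_specific)]
            .groupby(["treatment", "metabolite", "variety"], as_index=False)["effect"]
            .mean()
        )
        corr = _stage("phenocorr")(phenocorr.correlate_effects)(met_var_eff, eff_var)
        io.write_table(out / "correlations.tsv", corr)
        manifest["stages"]["phenocorr"]["n_correlations"] = len(corr)
        manifest["stages"]["phenocorr"]["n_sig05"] = int(corr["sig05"].sum())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline complete; outputs in %s", out)
    return manifest
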