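"""Phenotype analysis and metabolite-phenotype correlation.

Traits measured at plant maturity (tillering, biomass, main/lateral
spike characteristics) are classified per treatment by a two-way
variety x drought ANOVA: a significant interaction (p < 0.01) marks a
variety-specific drought effect (VD), a significant main drought
effect without interaction marks a uniform effect (D).  Treatment
effects are reported raw and as percent of the control mean; rank-2
SVD biplots summarize variety similarities and trait correlations; and
variety-specific metabolite effects are screened against
variety-specific trait effects by Pearson correlation at the 0.01 and
0.05 levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import balanced_factorial_anova

__all__ = [
    "trait_columns",
    "classify_trait_effects",
    "trait_effects",
    "BiplotCoords",
    "biplot_coords",
    "correlate_effects",
]

_PHENO_META = ("variety", "treatment", "replicate")


def trait_columns(pheno: pd.DataFrame) -> list[str]:
    return [c for c in pheno.columns if c not in _PHENO_META]


def _treatment_subset(pheno: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Control rows plus the given treatment's rows, with a condition factor."""
    sub = pheno[pheno["treatment"].isin(["control", treatment])].copy()
    if not (sub["treatment"] == "control").any():
        raise ValueError("missing control rows in phenotype table")
    sub["condition"] = np.where(sub["treatment"] == "control", "control", "drought")
    return sub


def classify_trait_effects(
    pheno: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Classify each trait per treatment as VD, D or none.

    Per treatment, the fixed model variety * drought is fitted against
    the control subset; VD if the interaction F-test has p < ``alpha``,
    else D if the main drought effect has p < ``alpha``, else none.
    Returns a DataFrame traits x treatments of labels.
    """
    traits = trait_columns(pheno)
    treatments = [t for t in pheno["treatment"].unique() if t != "control"]
    out = {}
    for trt in sorted(treatments):
        sub = _treatment_subset(pheno, trt)
        res = balanced_factorial_anova(sub, ["variety", "condition"], traits)
        p_int = res.p.loc["variety:condition"].to_numpy()
        p_d = res.p.loc["condition"].to_numpy()
        out[trt] = np.where(p_int < alpha, "VD", np.where(p_d < alpha, "D", "none"))
    table = pd.DataFrame(out, index=traits)
    table.index.name = "trait"
    return table


def trait_effects(
    pheno: pd.DataFrame,
    as_percent_of_control: bool = False,
    per_variety: bool = False,
) -> pd.DataFrame:
    """Drought-minus-control trait effects.

    Returns a long DataFrame (trait, treatment[, variety], effect).
    With ``as_percent_of_control`` the effect is scaled to percent of
    the corresponding control mean (which must be nonzero).
    """
    traits = trait_columns(pheno)
    treatments = sorted(t for t in pheno["treatment"].unique() if t != "control")
    group = ["variety"] if per_variety else []
    control = pheno[pheno["treatment"] == "control"]
    rows = []
    for trt in treatments:
        drought = pheno[pheno["treatment"] == trt]
        if per_variety:
            cm = control.groupby("variety")[traits].mean()
            dm = drought.groupby("variety")[traits].mean()
            for v in cm.index:
                for tr in traits:
                    eff = dm.loc[v, tr] - cm.loc[v, tr]
                    if as_percent_of_control:
                        if cm.loc[v, tr] == 0:
                            raise ZeroDivisionError(
                                f"zero control mean for trait {tr!r}, variety {v!r}"
                            )
                        eff = 100.0 * eff / cm.loc[v, tr]
                    rows.append(
                        {"trait": tr, "treatment": trt, "variety": v, "effect": eff}
                    )
        else:
            cm = control[traits].mean()
            dm = drought[traits].mean()
            for tr in traits:
                eff = dm[tr] - cm[tr]
                if as_percent_of_control:
                    if cm[tr] == 0:
                        raise ZeroDivisionError(f"zero control mean for trait {tr!r}")
                    eff = 100.0 * eff / cm[tr]
                rows.append({"trait": tr, "treatment": trt, "effect": eff})
    return pd.DataFrame(rows)


@dataclass
class BiplotCoords:
    """Rank-2 principal-component biplot of an effect matrix."""

    scores: pd.DataFrame  # varieties x 2, left factors scaled by singular values
    loadings: pd.DataFrame  # traits x 2, right factors
    variance_explained: np.ndarray  # length-2, fractions of total variance


def biplot_coords(effect_matrix: pd.DataFrame) -> BiplotCoords:
    """Principal-component biplot coordinates (varieties x traits input).

    The matrix is column-centered, decomposed by SVD, and truncated to
    rank 2; scores carry the singular values, loadings are unit right
    singular vectors.
    """
    x = effect_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 varieties and 2 traits")
    xc = x - x.mean(axis=0, keepdims=True)
    total = float((xc**2).sum())
    if total == 0:
        raise ValueError("zero-variance effect matrix")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :2] * s[:2]
    loadings = vt[:2].T
    var_exp = (s[:2] ** 2) / float((s**2).sum())
    return BiplotCoords(
        scores=pd.DataFrame(
            scores, index=effect_matrix.index, columns=["axis1", "axis2"]
        ),
        loadings=pd.DataFrame(
            loadings, index=effect_matrix.columns, columns=["axis1", "axis2"]
        ),
        variance_explained=var_exp,
    )


def correlate_effects(
    metabolite_effects: pd.DataFrame,
    trait_effects_table: pd.DataFrame,
    levels: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Pearson correlation of variety-specific treatment effects.

    Both inputs are long tables with columns (``metabolite`` or
    ``trait``, ``treatment``, ``variety``, ``effect``).  For every
    (metabolite, trait) pair within each treatment the cross-variety
    Pearson r is computed with a two-sided p from the t transform on
    n-2 degrees of freedom, flagged at both significance levels.
    Pairs where either vector has zero variance get an undefined r.
    """
    lv1, lv2 = sorted(levels)
    rows = []
    met_piv = metabolite_effects.pivot_table(
        index=["treatment", "variety"], columns="metabolite", values="effect"
    )
    tr_piv = trait_effects_table.pivot_table(
        index=["treatment", "variety"], columns="trait", values="effect"
    )
    treatments = sorted(
        set(met_piv.index.get_level_values(0)) & set(tr_piv.index.get_level_values(0))
    )
    for trt in treatments:
        mv = met_piv.loc[trt]
        tv = tr_piv.loc[trt]
        common = mv.index.intersection(tv.index)
        n = len(common)
        if n < 3:
            raise ValueError(f"need >= 3 shared varieties, got {n}")
        mv = mv.loc[common]
        tv = tv.loc[common]
        for met in mv.columns:
            a = mv[met].to_numpy(dtype=float)
            for trait in tv.columns:
                b = tv[trait].to_numpy(dtype=float)
                if np.std(a) == 0 or np.std(b) == 0:
                    r, p = np.nan, np.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                    r_cl = min(max(r, -1.0), 1.0)
                    if abs(r_cl) == 1.0:
                        p = 0.0
                    else:
                        t = r_cl * np.sqrt((n - 2) / (1.0 - r_cl**2))
                        p = 2.0 * stats.t.sf(abs(t), n - 2)
                rows.append(
                    {
                        "metabolite": met,
                        "trait": trait,
                        "treatment": trt,
                        "n": n,
                        "r": r,
                        "p": p,
                        f"sig{str(lv1).split('.')[1]}": bool(p < lv1)
                        if np.isfinite(p)
                        else False,
                        f"sig{str(lv2).split('.')[1]}": bool(p < lv2)
                        if np.isfinite(p)
                        else False,
                    }
                )
    return pd.DataFrame(rows)
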