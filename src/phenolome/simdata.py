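"""Synthetic UPLC-PDA experiments with known ground truth.

Emulates a factorial drought study on spring barley: eight varieties,
three water-deficit treatments (I at the three-leaf stage, II at the
flag leaf stage, I+II combined), sampling days 3/6/10 (plus day 1 for
I+II), four replicates, and dual-wavelength UV detection (280/330 nm).
Each "metabolite" is a chromatographic peak at a fixed latent retention
time whose area responds to drought according to a planted effect
category; traces sit on drifting baselines, are shifted by smooth
monotone retention-time warps and carry additive Gaussian noise.

Planted effect categories mirror the ANOVA families used downstream:

``D``
    drought effect constant over varieties and days,
``VD`` / ``TD``
    effect varies with variety only / day only,
``VD_TD``
    additive variety and day components,
``VTD``
    non-additive variety x day interaction,
``NoEffect``
    all zeros.

Effects are multiplicative on peak area (``area_drought =
2**effect * area_control``), i.e. additive on the log2 scale on which
the statistics are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Chromatogram, ChromatogramSet

__all__ = [
    "CATEGORIES",
    "DEFAULT_VARIETIES",
    "PeakSpec",
    "PiecewiseLinearWarp",
    "GroundTruth",
    "TraitSpec",
    "make_design",
    "make_random_warp",
    "simulate_chromatogram",
    "simulate_experiment",
    "simulate_phenotypes",
    "default_benchmark",
]

#: Drought-response categories, in the conventional reporting order.
CATEGORIES = ("NoEffect", "D", "VD", "TD", "VD_TD", "VTD")

#: The eight barley varieties of the reference design.
DEFAULT_VARIETIES = (
    "Georgie", "Maresi", "Sebastian", "Lubuski",
    "Stratus", "CamB1CI", "Harmal", "MDingo",
)

#: Sampling days per treatment: I+II additionally samples day 1.
DEFAULT_DAYS = {"I": (3, 6, 10), "II": (3, 6, 10), "I+II": (1, 3, 6, 10)}


# ---------------------------------------------------------------------------
# design table


def make_design(
    n_varieties: int = 8,
    treatments: tuple[str, ...] = ("I", "II", "I+II"),
    days_per_treatment: dict[str, tuple[int, ...]] | None = None,
    n_reps: int = 4,
    mass_range: tuple[float, float] = (80.0, 120.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Build a balanced factorial design table.

    Every treatment gets a full factorial over
    variety x {control, drought} x day x replicate, so each drought cell
    has a matched control harvested on the same day.  Sample masses (mg)
    are drawn uniformly from ``mass_range``.
    """
    if len(treatments) == 0:
        raise ValueError("treatments must be non-empty")
    if n_varieties < 2:
        raise ValueError("need at least 2 varieties")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    if not (0 < mass_range[0] <= mass_range[1]):
        raise ValueError(f"invalid mass_range {mass_range}")
    if days_per_treatment is None:
        days_per_treatment = {t: DEFAULT_DAYS.get(t, (3, 6, 10)) for t in treatments}
    for t in treatments:
        if t not in days_per_treatment or len(days_per_treatment[t]) == 0:
            raise ValueError(f"no sampling days for treatment {t!r}")

    if n_varieties <= len(DEFAULT_VARIETIES):
        varieties = DEFAULT_VARIETIES[:n_varieties]
    else:
        varieties = tuple(f"V{i + 1}" for i in range(n_varieties))

    rng = np.random.default_rng(seed)
    rows = []
    for trt in treatments:
        for variety in varieties:
            for cond in ("control", "drought"):
                for day in days_per_treatment[trt]:
                    for rep in range(1, n_reps + 1):
                        rows.append((variety, trt, cond, int(day), rep))
    design = pd.DataFrame(
        rows, columns=["variety", "treatment", "condition", "day", "replicate"]
    )
    design.insert(
        0,
        "sample_id",
        [
            f"{v}_{t}_{c}_d{d}_r{r}".replace("+", "")
            for v, t, c, d, r in rows
        ],
    )
    design["sample_mass"] = rng.uniform(mass_range[0], mass_range[1], len(design))
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id generated")
    return design


# ---------------------------------------------------------------------------
# peak shapes and warps


@dataclass(frozen=True)
class PeakSpec:
    """One chromatographic peak: EMG with Gaussian as the tau=0 case.

    ``amplitude`` is the height of the tau=0 Gaussian; the peak area is
    ``amplitude * width * sqrt(2*pi)`` for every tau, so scaling
    amplitude scales area proportionally.
    """

    apex_rt: float
    width: float
    amplitude: float
    shape: str = "gaussian"
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.shape not in ("gaussian", "emg"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the peak profile on retention times ``t`` (minutes)."""
        t = np.asarray(t, dtype=float)
        if self.shape == "gaussian" or self.tau == 0.0:
            return self.amplitude * np.exp(
                -0.5 * ((t - self.apex_rt) / self.width) ** 2
            )
        # exponentially modified Gaussian: Gaussian convolved with an
        # exponential tail of time constant tau; area preserved.
        area = self.amplitude * self.width * np.sqrt(2.0 * np.pi)
        k = self.tau / self.width
        return area * stats.exponnorm.pdf(
            t, K=k, loc=self.apex_rt, scale=self.width
        )

    @property
    def area(self) -> float:
        return float(self.amplitude * self.width * np.sqrt(2.0 * np.pi))


class PiecewiseLinearWarp:
    """Monotone piecewise-linear retention-time warp fixing the endpoints.

    Maps observed retention time to latent retention time: a peak with
    latent apex ``a`` appears at the observed time ``w^-1(a)``.
    """

    def __init__(self, nodes: np.ndarray, values: np.ndarray):
        nodes = np.asarray(nodes, dtype=float)
        values = np.asarray(values, dtype=float)
        if nodes.shape != values.shape or nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("nodes/values must be equal-length 1-D, size >= 2")
        if not (np.all(np.diff(nodes) > 0) and np.all(np.diff(values) > 0)):
            raise ValueError("warp must be strictly monotone")
        if not (values[0] == nodes[0] and values[-1] == nodes[-1]):
            raise ValueError("warp must fix both endpoints")
        self.nodes = nodes
        self.values = values

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.nodes, self.values)

    @classmethod
    def identity(cls, lo: float, hi: float) -> "PiecewiseLinearWarp":
        return cls(np.array([lo, hi]), np.array([lo, hi]))

    @property
    def max_displacement(self) -> float:
        return float(np.max(np.abs(self.values - self.nodes)))

    def to_dict(self) -> dict:
        return {"nodes": self.nodes.tolist(), "values": self.values.tolist()}


def make_random_warp(
    lo: float,
    hi: float,
    magnitude: float,
    n_nodes: int = 7,
    rng: np.random.Generator | None = None,
) -> PiecewiseLinearWarp:
    """Random smooth warp: interior node displacements ~ U(-magnitude, magnitude)."""
    rng = np.random.default_rng() if rng is None else rng
    nodes = np.linspace(lo, hi, n_nodes)
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude >= 0.5 * (nodes[1] - nodes[0]):
        raise ValueError("warp magnitude too large for node spacing")
    disp = rng.uniform(-magnitude, magnitude, n_nodes)
    disp[0] = disp[-1] = 0.0
    return PiecewiseLinearWarp(nodes, nodes + disp)


def simulate_chromatogram(
    grid: np.ndarray,
    peaks: list[PeakSpec],
    baseline_coeffs: tuple[float, ...] = (0.0,),
    warp: PiecewiseLinearWarp | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render one trace: peaks (at warped retention times) + polynomial baseline + noise.

    ``baseline_coeffs`` are polynomial coefficients in ``numpy.polyval``
    order (highest power first) in raw AU vs. minutes.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    t = grid if warp is None else warp(grid)
    if warp is not None and not np.all(np.diff(t) > 0):
        raise ValueError("warp is not monotone on the grid")
    y = np.polyval(baseline_coeffs, grid)
    y = np.broadcast_to(y, grid.shape).astype(float).copy()
    for p in peaks:
        y += p.evaluate(t)
    if noise_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        y += rng.normal(0.0, noise_sd, grid.size)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite intensity produced")
    return y


# ---------------------------------------------------------------------------
# ground truth and full experiments


@dataclass
class GroundTruth:
    """Planted structure of a synthetic experiment."""

    categories: dict[str, str] = field(default_factory=dict)
    #: metabolite -> DataFrame (varieties x days) of log2 drought effects
    effect_maps: dict[str, pd.DataFrame] = field(default_factory=dict)
    #: metabolite -> latent retention time (minutes; EMG Gaussian center)
    latent_rt: dict[str, float] = field(default_factory=dict)
    #: metabolite -> observable apex (mode of the peak shape, minutes);
    #: differs from latent_rt for tailed peaks
    apex_rt: dict[str, float] = field(default_factory=dict)
    #: metabolite -> {wavelength: base amplitude}
    amplitudes: dict[str, dict[int, float]] = field(default_factory=dict)
    #: sample_id -> warp applied to that sample
    warps: dict[str, PiecewiseLinearWarp] = field(default_factory=dict)
    #: long table (trait, variety, treatment) -> planted phenotype effect
    phenotype_effects: pd.DataFrame | None = None

    def validate(self) -> None:
        """Check category/effect-map consistency."""
        for m, cat in self.categories.items():
            em = self.effect_maps[m]
            if cat == "NoEffect" and not np.allclose(em.values, 0):
                raise ValueError(f"{m}: NoEffect but nonzero effects")
            if cat == "D":
                if not np.allclose(em.values, em.values.flat[0]):
                    raise ValueError(f"{m}: D effect must be constant")


def _planted_effect_map(
    category: str,
    varieties: list[str],
    days: list[int],
    effect_size: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a (variety x day) log2 effect map consistent with ``category``."""
    nv, nd = len(varieties), len(days)
    if category == "NoEffect":
        vals = np.zeros((nv, nd))
    elif category == "D":
        vals = np.full((nv, nd), effect_size)
    elif category == "VD":
        per_v = effect_size * rng.choice([-1.0, 1.0], nv) * rng.uniform(0.5, 1.5, nv)
        vals = np.repeat(per_v[:, None], nd, axis=1)
    elif category == "TD":
        per_d = effect_size * rng.choice([-1.0, 1.0], nd) * rng.uniform(0.5, 1.5, nd)
        vals = np.repeat(per_d[None, :], nv, axis=0)
    elif category == "VD_TD":
        per_v = effect_size * rng.choice([-1.0, 1.0], nv) * rng.uniform(0.5, 1.5, nv)
        per_d = effect_size * rng.choice([-1.0, 1.0], nd) * rng.uniform(0.5, 1.5, nd)
        vals = per_v[:, None] + per_d[None, :]
    elif category == "VTD":
        u = rng.choice([-1.0, 1.0], nv) * rng.uniform(0.5, 1.5, nv)
        w = rng.choice([-1.0, 1.0], nd) * rng.uniform(0.5, 1.5, nd)
        vals = effect_size * np.outer(u, w)
    else:
        raise ValueError(f"unknown category {category!r}")
    return pd.DataFrame(vals, index=varieties, columns=days)


def simulate_experiment(
    design: pd.DataFrame,
    n_metabolites: int = 20,
    category_assignment: dict[str, float] | list[str] | None = None,
    effect_size: float = 2.0,
    warp_magnitude: float = 0.05,
    noise_sd: float = 0.01,
    seed: int = 0,
    n_points: int = 1500,
    rt_range: tuple[float, float] = (0.0, 30.0),
    amplitude_range: tuple[float, float] = (2.0, 6.0),
    width_range: tuple[float, float] = (0.08, 0.15),
    tau_max: float = 0.04,
    wavelengths: tuple[int, ...] = (280, 330),
    baseline_slope_range: tuple[float, float] = (-0.02, 0.02),
) -> tuple[ChromatogramSet, GroundTruth]:
    """Simulate the dual-wavelength chromatogram set for a design.

    ``category_assignment`` is either an explicit list of categories of
    length ``n_metabolites`` or a dict of category proportions (summing
    to 1) from which assignments are drawn.  Drought samples have each
    metabolite's amplitude multiplied by ``2**effect`` for that
    (variety, day) cell; every sample receives its own random monotone
    warp of magnitude <= ``warp_magnitude`` minutes and iid Gaussian
    noise of ``noise_sd`` raw AU.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    rng = np.random.default_rng(seed)
    varieties = sorted(design["variety"].unique().tolist())
    days = sorted(int(d) for d in design["day"].unique())

    if category_assignment is None:
        category_assignment = {
            "NoEffect": 0.3, "D": 0.25, "VD": 0.05,
            "TD": 0.2, "VD_TD": 0.05, "VTD": 0.15,
        }
    if isinstance(category_assignment, dict):
        probs = np.array([category_assignment.get(c, 0.0) for c in CATEGORIES])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("category proportions must sum to 1")
        cats = list(rng.choice(CATEGORIES, size=n_metabolites, p=probs))
    else:
        cats = list(category_assignment)
        if len(cats) != n_metabolites:
            raise ValueError("category list length != n_metabolites")

    grid = np.linspace(rt_range[0], rt_range[1], n_points)
    lo = rt_range[0] + 0.06 * (rt_range[1] - rt_range[0])
    hi = rt_range[1] - 0.06 * (rt_range[1] - rt_range[0])
    # latent apexes: jittered even spacing keeps peaks resolvable
    base = np.linspace(lo, hi, n_metabolites)
    jitter_amp = 0.15 * (base[1] - base[0]) if n_metabolites > 1 else 0.3
    latent = base + rng.uniform(-jitter_amp, jitter_amp, n_metabolites)

    truth = GroundTruth()
    met_ids = [f"M{i + 1:03d}" for i in range(n_metabolites)]
    widths = rng.uniform(width_range[0], width_range[1], n_metabolites)
    taus = rng.uniform(0.0, tau_max, n_metabolites)
    for i, m in enumerate(met_ids):
        truth.categories[m] = cats[i]
        truth.effect_maps[m] = _planted_effect_map(
            cats[i], varieties, days, effect_size, rng
        )
        truth.latent_rt[m] = float(latent[i])
        shape = PeakSpec(
            apex_rt=float(latent[i]), width=float(widths[i]), amplitude=1.0,
            shape="emg" if taus[i] > 0 else "gaussian", tau=float(taus[i]),
        )
        truth.apex_rt[m] = float(grid[int(np.argmax(shape.evaluate(grid)))])
        amp280 = rng.uniform(amplitude_range[0], amplitude_range[1])
        truth.amplitudes[m] = {
            wl: float(amp280 if j == 0 else amp280 * rng.uniform(0.4, 1.0))
            for j, wl in enumerate(wavelengths)
        }
    truth.validate()

    chroms: list[Chromatogram] = []
    for row in design.itertuples(index=False):
        if warp_magnitude > 0:
            warp = make_random_warp(
                rt_range[0], rt_range[1], warp_magnitude, rng=rng
            )
        else:
            warp = PiecewiseLinearWarp.identity(rt_range[0], rt_range[1])
        truth.warps[row.sample_id] = warp
        b1 = rng.uniform(baseline_slope_range[0], baseline_slope_range[1])
        b0 = rng.uniform(0.5, 2.0)
        for wl in wavelengths:
            peaks = []
            for i, m in enumerate(met_ids):
                amp = truth.amplitudes[m][wl]
                if row.condition == "drought":
                    amp *= 2.0 ** truth.effect_maps[m].loc[row.variety, row.day]
                peaks.append(
                    PeakSpec(
                        apex_rt=truth.latent_rt[m],
                        width=float(widths[i]),
                        amplitude=float(amp),
                        shape="emg" if taus[i] > 0 else "gaussian",
                        tau=float(taus[i]),
                    )
                )
            y = simulate_chromatogram(
                grid, peaks, (b1, b0), warp, noise_sd, seed=rng
            )
            chroms.append(
                Chromatogram(
                    rt=grid,
                    intensity=y,
                    wavelength=wl,
                    sample_id=row.sample_id,
                    sample_mass=float(row.sample_mass),
                )
            )
    return ChromatogramSet(chroms, design.copy()), truth


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class TraitSpec:
    """One phenotypic trait of the maturity assessment.

    ``common_effects`` gives the drought effect shared by all varieties
    per treatment (trait units); ``perturbation_sd`` adds a
    variety-specific deviation around it (creating VD structure when
    nonzero).
    """

    name: str
    baseline: float
    baseline_variety_sd: float = 0.0
    common_effects: dict[str, float] = field(default_factory=dict)
    perturbation_sd: float = 0.0


def simulate_phenotypes(
    design: pd.DataFrame,
    trait_specs: list[TraitSpec],
    link: dict[str, tuple[str, float]] | None = None,
    ground_truth: GroundTruth | None = None,
    n_reps: int = 2,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the maturity phenotype table.

    Trait value = variety baseline + treatment effect + iid noise.  For
    traits named in ``link`` (trait -> (metabolite_id, slope)), the
    variety-specific treatment effect is
    ``slope * mean-over-days(metabolite effect for that variety)`` plus
    the trait's perturbation, so a cross-variety Pearson correlation
    between metabolite and phenotype effects is planted by construction.
    """
    rng = np.random.default_rng(seed)
    link = link or {}
    varieties = sorted(design["variety"].unique().tolist())
    treatments = sorted(design["treatment"].unique().tolist())
    if link and ground_truth is None:
        raise ValueError("link requires the metabolite GroundTruth")
    for trait, (met, _slope) in link.items():
        if ground_truth is None or met not in ground_truth.effect_maps:
            raise KeyError(f"link for {trait!r} names unknown metabolite {met!r}")

    truth = ground_truth if ground_truth is not None else GroundTruth()
    eff_rows = []
    effects: dict[tuple[str, str, str], float] = {}
    for spec in trait_specs:
        for trt in treatments:
            common = spec.common_effects.get(trt, 0.0)
            for v in varieties:
                if spec.name in link:
                    met, slope = link[spec.name]
                    met_eff = float(truth.effect_maps[met].loc[v].mean())
                    e = slope * met_eff
                else:
                    e = common
                e += rng.normal(0.0, spec.perturbation_sd) if spec.perturbation_sd else 0.0
                effects[(spec.name, v, trt)] = e
                eff_rows.append((spec.name, v, trt, e))
    truth.phenotype_effects = pd.DataFrame(
        eff_rows, columns=["trait", "variety", "treatment", "effect"]
    )

    baselines = {
        (spec.name, v): spec.baseline
        + (rng.normal(0.0, spec.baseline_variety_sd) if spec.baseline_variety_sd else 0.0)
        for spec in trait_specs
        for v in varieties
    }
    rows = []
    for v in varieties:
        for trt in ["control"] + treatments:
            for rep in range(1, n_reps + 1):
                vals = {}
                for spec in trait_specs:
                    y = baselines[(spec.name, v)]
                    if trt != "control":
                        y += effects[(spec.name, v, trt)]
                    if noise_sd > 0:
                        y += rng.normal(0.0, noise_sd)
                    vals[spec.name] = y
                rows.append({"variety": v, "treatment": trt, "replicate": rep, **vals})
    pheno = pd.DataFrame(rows)
    return pheno, truth


# ---------------------------------------------------------------------------
# canonical benchmark


def default_benchmark(
    seed: int = 0,
    n_metabolites: int = 20,
    n_varieties: int = 2,
    n_reps: int = 2,
) -> tuple[ChromatogramSet, GroundTruth]:
    """The standard planted-peak benchmark: 20 well-separated peaks,
    high SNR, warps within the default alignment slack, one treatment.

    Small variety/replicate counts keep the chromatogram count modest;
    peak-recovery performance depends on the per-trace signal model, not
    on the design width.
    """
    design = make_design(
        n_varieties=n_varieties,
        treatments=("I",),
        days_per_treatment={"I": (3, 6, 10)},
        n_reps=n_reps,
        seed=seed,
    )
    return simulate_experiment(design, n_metabolites=n_metabolites, seed=seed)
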