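"""Seeded synthetic cohorts with known ground truth.

The generator emulates the statistical structure of per-cell tables exported
by a supervised multiplex-IHC image-analysis system, plus the matched
expression and survival data the downstream analyses consume:

* **Tissue geometry** — each patient contributes one image tile per region
  of interest (core / edge / margin / adjacent normal). Tumor-nest regions
  are unions of random discs (lognormal radii, ~150 µm mean) inside the
  tumor tiles; the tissue compartment label (tumor_nest vs stroma) comes
  from that disc mask, so every cell's label agrees with the generating
  geometry by construction.
* **Cell placement** — tumor cells follow a homogeneous Poisson process
  restricted to the nests. Each macrophage population follows a Poisson
  process whose count has mean rate x tile area and whose positions honour a
  population-specific preferred distance to the nearest tumor cell
  (Gamma-shaped distance kernel), so orderings such as "IRF8+ macrophages
  proximal, triple-positive macrophages distal" are injected as ground
  truth. Non-macrophage "Other" cells are uniform.
* **Marker intensities** — lognormal per marker per phenotype, with widely
  separated positive / negative components so the gate is recoverable, and
  optionally modulated across the tumor-nest/stroma interface (logistic
  ramp, half-rise a configurable onset distance before the interface). The
  gradient covariate is the same signed nearest-opposite-compartment
  distance the analysis modules measure.
* **Expression** — linked genes are monotone transforms (normal scores) of
  a population's per-patient density plus Gaussian noise calibrated so the
  expected Spearman correlation hits the configured target; unlinked genes
  are independent noise.
* **Survival** — exponential event times with per-patient hazard
  baseline x exp(coefficient x standardized density of a chosen
  population), with independent exponential censoring.

All randomness flows from ``SimulationConfig.seed`` through one stream per
patient, split by purpose (placement / intensity / expression / survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit
from scipy.stats import gamma as gamma_dist, norm, rankdata

from .errors import ConfigError, DataError
from .gradient import signed_interface_distance
from .phenotype import (
    ALL_LABELS,
    GATING_MARKERS,
    HIGH_MARKERS,
    MARKERS,
    OTHER_LABEL,
    TAM_LABELS,
    TUMOR_LABEL,
    GatingConfig,
)

ROIS: tuple[str, ...] = ("core", "edge", "margin", "normal")

#: tile dimensions in µm — a 2x2 microscope stamp (1338 x 1000 µm) for the
#: core/edge/normal regions and a 1x1 stamp (669 x 500 µm) for the margin
DEFAULT_TILES_UM: dict[str, tuple[float, float]] = {
    "core": (1338.0, 1000.0),
    "edge": (1338.0, 1000.0),
    "margin": (669.0, 500.0),
    "normal": (1338.0, 1000.0),
}

GAMMA_SHAPE = 2.0  # shape of the distance-to-nearest-tumor-cell kernel


def _gamma_scale_for_median(median_um: float, shape: float = GAMMA_SHAPE) -> float:
    return median_um / gamma_dist.ppf(0.5, shape)


#: preferred median distance (µm) to the nearest tumor cell; None = uniform
DEFAULT_PLACEMENT_UM: dict[str, float | None] = {
    "CD68+IRF8+": 12.0,
    "CD68+CD206+": 14.0,
    "CD68++CD163+": 16.0,
    "CD68+CD163+": 18.0,
    "CD68+": 20.0,
    "CD68+CD206++": 22.0,
    "CD68+CD163+CD206+": 26.0,
    OTHER_LABEL: None,
}

#: cells/mm² of tile per population per ROI; the tumor entry is the density
#: within the nest mask. Absolute levels are free parameters chosen to give
#: realistic per-tile cell counts (~2-5 x 10^3 per 1.3 mm² tile); the ROI
#: contrasts encode the qualitative enrichment patterns of the study system
#: (IRF8+ macrophages toward the core, triple-positives toward the margin).
DEFAULT_RATES: dict[str, dict[str, float]] = {
    TUMOR_LABEL: {"core": 1500.0, "edge": 1500.0, "margin": 1500.0, "normal": 0.0},
    "CD68+": {"core": 60.0, "edge": 60.0, "margin": 60.0, "normal": 70.0},
    "CD68+IRF8+": {"core": 70.0, "edge": 50.0, "margin": 25.0, "normal": 8.0},
    "CD68+CD163+": {"core": 50.0, "edge": 45.0, "margin": 40.0, "normal": 15.0},
    "CD68++CD163+": {"core": 35.0, "edge": 30.0, "margin": 25.0, "normal": 10.0},
    "CD68+CD206+": {"core": 45.0, "edge": 40.0, "margin": 35.0, "normal": 15.0},
    "CD68+CD206++": {"core": 40.0, "edge": 40.0, "margin": 45.0, "normal": 50.0},
    "CD68+CD163+CD206+": {"core": 55.0, "edge": 60.0, "margin": 80.0, "normal": 40.0},
    OTHER_LABEL: {"core": 700.0, "edge": 700.0, "margin": 700.0, "normal": 700.0},
}

_NEG = 0.0  # log-intensity location of a negative marker component
_POS = 2.0  # positive component
_HIGH = 3.8  # "++" component
_SIGMA = 0.30  # log-intensity scale (>=6 sigma positive/negative separation)


def _intensity_row(**over: float) -> dict[str, tuple[float, float]]:
    row = {m: (_NEG, _SIGMA) for m in MARKERS}
    for m, mu in over.items():
        row[m] = (mu, _SIGMA)
    return row


#: per phenotype, per marker (log-location, log-scale) of staining intensity.
#: PDL1 levels mirror the study system qualitatively: highest on the
#: CD68+CD206+ population, elevated on CD68-only and CD206++ macrophages,
#: tumor cells near the cohort positivity threshold.
DEFAULT_INTENSITY: dict[str, dict[str, tuple[float, float]]] = {
    TUMOR_LABEL: _intensity_row(AE1AE3=2.5, PDL1=1.0),
    "CD68+IRF8+": _intensity_row(CD68=_POS, IRF8=2.2, PDL1=0.3),
    "CD68+": _intensity_row(CD68=_POS, PDL1=0.9),
    "CD68+CD163+": _intensity_row(CD68=_POS, CD163=2.2, PDL1=0.5),
    "CD68++CD163+": _intensity_row(CD68=_HIGH, CD163=2.2, PDL1=0.5),
    "CD68+CD206+": _intensity_row(CD68=_POS, CD206=_POS, PDL1=1.5),
    "CD68+CD206++": _intensity_row(CD68=_POS, CD206=_HIGH, PDL1=1.2),
    "CD68+CD163+CD206+": _intensity_row(CD68=_POS, CD163=2.2, CD206=2.2, PDL1=0.6),
    OTHER_LABEL: _intensity_row(PDL1=0.2),
}


@dataclass(frozen=True)
class GradientSpec:
    """One marker's intensity change across the TS interface.

    The lognormal location is multiplied by
    ``1 + (fold - 1) * expit((s + onset_um) / ramp_um)`` where ``s`` is the
    signed interface distance, so the multiplier half-rises exactly
    ``onset_um`` before the interface (stroma side) and plateaus at *fold*
    inside the nest.
    """

    marker: str
    fold: float = 2.0
    onset_um: float = 25.0
    ramp_um: float = 4.0
    populations: tuple[str, ...] | None = None  # None = every TAM population

    def multiplier(self, signed_um: np.ndarray) -> np.ndarray:
        return 1.0 + (self.fold - 1.0) * expit((signed_um + self.onset_um) / self.ramp_um)


#: a twofold CD68 increase with ~25 µm onset on the CD163+ and IRF8+
#: macrophages, and nest-side PDL1 up-regulation on every macrophage
DEFAULT_GRADIENTS: tuple[GradientSpec, ...] = (
    GradientSpec(
        marker="CD68",
        fold=2.0,
        onset_um=25.0,
        populations=("CD68+CD163+", "CD68++CD163+", "CD68+CD163+CD206+", "CD68+IRF8+"),
    ),
    GradientSpec(marker="PDL1", fold=2.0, onset_um=10.0, populations=None),
)


@dataclass
class ExpressionParams:
    n_genes: int = 2000
    n_linked_per_population: int = 50
    linked_populations: tuple[str, ...] = TAM_LABELS
    target_rho: float = 0.8
    noise_scale: float = 1.0  # 0 disables noise -> Spearman rho = 1 exactly
    unlinked_sd: float = 1.0
    roi: str = "core"


@dataclass
class SurvivalParams:
    baseline_hazard: float = 0.02  # events per month
    log_hazard_coef: float = -0.6  # per SD of density (negative = protective)
    censoring_rate: float = 0.2
    population: str = "CD68++CD163+"
    roi: str = "core"


@dataclass
class SimulationConfig:
    """Full description of one synthetic study; identical config + seed give
    byte-identical output."""

    n_patients: int = 35
    seed: int = 0
    roi_tiles_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TILES_UM)
    )
    n_images: dict[str, int] = field(default_factory=lambda: {r: 1 for r in ROIS})
    population_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(r) for p, r in DEFAULT_RATES.items()}
    )
    placement_profiles: dict[str, float | None] = field(
        default_factory=lambda: dict(DEFAULT_PLACEMENT_UM)
    )
    intensity_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {p: dict(r) for p, r in DEFAULT_INTENSITY.items()}
    )
    interface_gradients: tuple[GradientSpec, ...] = DEFAULT_GRADIENTS
    exposure: dict[str, float] = field(default_factory=lambda: {m: 1.0 for m in MARKERS})
    nest_mean_per_mm2: float = 2.0
    nest_radius_mean_um: float = 150.0
    nest_radius_log_sd: float = 0.3
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for roi, (w, h) in self.roi_tiles_um.items():
            if w <= 0 or h <= 0:
                raise ConfigError(f"tile dimensions for {roi!r} must be positive")
        bad = set(self.population_rates) - set(ALL_LABELS)
        if bad:
            raise ConfigError(f"population_rates has unknown labels: {sorted(bad)}")
        total = 0.0
        for pop, per_roi in self.population_rates.items():
            for roi, rate in per_roi.items():
                if rate < 0:
                    raise ConfigError(f"negative rate for {pop} in {roi}")
                total += rate
        if total == 0:
            raise ConfigError("all population rates are zero")
        for m, sc in self.intensity_model.get(TUMOR_LABEL, {}).items():
            if sc[1] <= 0:
                raise ConfigError(f"non-positive intensity scale for {m}")
        if self.expression.n_linked_per_population * len(
            self.expression.linked_populations
        ) > self.expression.n_genes:
            raise ConfigError("more linked genes requested than n_genes")
        if self.survival.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be positive")
        if not np.isfinite(self.survival.log_hazard_coef):
            raise ConfigError("log-hazard coefficient must be finite")
        if not 0 <= self.survival.censoring_rate < 1:
            raise ConfigError("censoring_rate must lie in [0, 1)")

    def tile_area_mm2(self, roi: str) -> float:
        w, h = self.roi_tiles_um[roi]
        return (w * h) / 1e6

    def patient_ids(self) -> list[str]:
        return [f"P{i:03d}" for i in range(self.n_patients)]

    def without_gradients(self) -> "SimulationConfig":
        return replace(self, interface_gradients=())

    def true_gating(self) -> GatingConfig:
        """Gating thresholds at the log-midpoints of the generating mixture.

        For each gated marker the positivity threshold sits halfway (in log
        space) between the highest negative and the lowest positive
        component location; the CD68/CD206 high thresholds sit between the
        "+" and "++" locations.
        """
        positivity: dict[str, float] = {}
        high: dict[str, float] = {}
        for m in GATING_MARKERS:
            mus = sorted({model[m][0] for model in self.intensity_model.values()})
            if len(mus) < 2:
                raise ConfigError(f"marker {m} has a single component; no threshold")
            positivity[m] = float(np.exp(0.5 * (mus[0] + mus[1])))
            if m in HIGH_MARKERS:
                # the "++" component is the top level; split it from the
                # next-lower positive level
                if len(mus) >= 3:
                    high[m] = float(np.exp(0.5 * (mus[-2] + mus[-1])))
                else:
                    high[m] = float(np.exp(mus[1] + 1.0))
        mode = "raw" if all(v == 1.0 for v in self.exposure.values()) else "exposure_normalized"
        return GatingConfig(positivity=positivity, high=high, normalization=mode)


@dataclass
class GroundTruth:
    """Per-cell, per-gene and per-patient generating truth."""

    phenotype: pd.Series  # cell_id -> true label
    gene_linkage: pd.DataFrame | None = None  # gene, population, target_rho
    survival_density: pd.Series | None = None  # patient_id -> density in hazard
    nest_discs: dict | None = None  # image_id -> (centers (k,2), radii (k,)) in µm


def _patient_streams(config: SimulationConfig, patient_index: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(patient_index,))
    children = root.spawn(4)
    names = ("placement", "intensity", "expression", "survival")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _sample_nests(
    config: SimulationConfig, roi: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disc centers (k, 2) and radii (k,) of the tumor-nest mask."""
    if roi == "normal":
        return np.empty((0, 2)), np.empty(0)
    w, h = config.roi_tiles_um[roi]
    area = config.tile_area_mm2(roi)
    k = max(1, int(rng.poisson(config.nest_mean_per_mm2 * area)))
    centers = rng.uniform((0.0, 0.0), (w, h), size=(k, 2))
    sigma = config.nest_radius_log_sd
    mu = np.log(config.nest_radius_mean_um) - 0.5 * sigma**2
    radii = np.exp(rng.normal(mu, sigma, size=k))
    return centers, radii


def _in_nest(xy: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    if len(centers) == 0 or len(xy) == 0:
        return np.zeros(len(xy), dtype=bool)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= radii[None, :] ** 2).any(axis=1)


def _place_near_tumor(
    n: int,
    median_um: float,
    tumor_xy: np.ndarray,
    tile_wh: tuple[float, float],
    rng: np.random.Generator,
    tol: float = 0.25,
    max_iter: int = 150,
) -> np.ndarray:
    """Place n cells so distance to the *nearest* tumor cell follows the
    Gamma kernel with the given median.

    Each cell draws its target distance d once; rejection sampling then
    searches for a location (random tumor-cell anchor, random direction,
    step d) whose realized nearest-tumor distance is within a relative
    tolerance of d (plus a 2 µm absolute slack) and inside the tile.
    Keeping d fixed across retries leaves the realized distance distribution
    unbiased. Remaining cells after max_iter keep their last in-tile
    proposal.
    """
    if n == 0:
        return np.empty((0, 2))
    w, h = tile_wh
    scale = _gamma_scale_for_median(median_um)
    tree = cKDTree(tumor_xy)
    out = np.empty((n, 2))
    d_target = rng.gamma(GAMMA_SHAPE, scale, size=n)
    todo = np.arange(n)
    fallback: dict[int, np.ndarray] = {}
    for it in range(max_iter):
        if todo.size == 0:
            break
        m = todo.size
        d = d_target[todo]
        anchors = tumor_xy[rng.integers(0, len(tumor_xy), size=m)]
        theta = rng.uniform(0, 2 * np.pi, size=m)
        prop = anchors + d[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        inside = (prop[:, 0] >= 0) & (prop[:, 0] <= w) & (prop[:, 1] >= 0) & (prop[:, 1] <= h)
        nearest, _ = tree.query(prop, k=1)
        ok = inside & (np.abs(nearest - d) <= tol * d + 2.0)
        out[todo[ok]] = prop[ok]
        for j in np.nonzero(inside & ~ok)[0]:
            fallback[int(todo[j])] = prop[j]
        todo = todo[~ok]
    for i in todo:  # rare: keep an in-tile proposal or fall back to uniform
        out[i] = fallback.get(
            int(i), rng.uniform((0.0, 0.0), (w, h))
        )
    return out


def generate_cell_table(
    config: SimulationConfig, patient_index: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one patient's per-cell table plus ground-truth labels.

    Returns a frame in the package's cell-table dialect (coordinates in µm,
    per-tile frame) and a :class:`GroundTruth` with one true phenotype per
    cell.
    """
    streams = _patient_streams(config, patient_index)
    rng_p = streams["placement"]
    rng_i = streams["intensity"]
    patient_id = f"P{patient_index:03d}"

    frames = []
    nest_discs: dict = {}
    for roi in ROIS:
        if roi not in config.roi_tiles_um:
            continue
        w, h = config.roi_tiles_um[roi]
        area = config.tile_area_mm2(roi)
        for img_idx in range(config.n_images.get(roi, 1)):
            image_id = f"{patient_id}_{roi}_{img_idx}"
            centers, radii = _sample_nests(config, roi, rng_p)
            nest_discs[image_id] = (centers, radii)

            # tumor cells: homogeneous Poisson on the tile, thinned to nests
            tumor_rate = config.population_rates.get(TUMOR_LABEL, {}).get(roi, 0.0)
            tumor_xy = np.empty((0, 2))
            if tumor_rate > 0 and len(centers):
                n_cand = rng_p.poisson(tumor_rate * area)
                cand = rng_p.uniform((0.0, 0.0), (w, h), size=(n_cand, 2))
                tumor_xy = cand[_in_nest(cand, centers, radii)]

            xs, labels = [tumor_xy], [np.full(len(tumor_xy), TUMOR_LABEL, dtype=object)]
            for pop in list(TAM_LABELS) + [OTHER_LABEL]:
                rate = config.population_rates.get(pop, {}).get(roi, 0.0)
                if rate <= 0:
                    continue
                n = rng_p.poisson(rate * area)
                median = config.placement_profiles.get(pop)
                if median is not None and len(tumor_xy) > 0:
                    xy = _place_near_tumor(n, median, tumor_xy, (w, h), rng_p)
                else:
                    xy = rng_p.uniform((0.0, 0.0), (w, h), size=(n, 2))
                xs.append(xy)
                labels.append(np.full(n, pop, dtype=object))

            xy = np.concatenate(xs)
            lab = np.concatenate(labels)
            df = pd.DataFrame(
                {
                    "patient_id": patient_id,
                    "image_id": image_id,
                    "roi": roi,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
            df["compartment"] = np.where(
                _in_nest(xy, centers, radii), "tumor_nest", "stroma"
            )
            df["true_phenotype"] = lab
            frames.append(df)

    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", [f"{patient_id}_c{i:06d}" for i in range(len(cells))])

    # gradient covariate: signed nearest-opposite-compartment distance,
    # computed per image on the full cell complement
    signed = pd.Series(np.nan, index=cells.index)
    for _, img in cells.groupby("image_id", sort=False):
        comps = img["compartment"].unique()
        if len(comps) == 2:
            signed.loc[img.index] = signed_interface_distance(img).to_numpy()
    cells["signed_distance_um"] = signed.to_numpy()

    # marker intensities: lognormal per phenotype, gradient-modulated
    n = len(cells)
    lab = cells["true_phenotype"].to_numpy()
    s = cells["signed_distance_um"].to_numpy()
    for m in MARKERS:
        mu = np.empty(n)
        sd = np.empty(n)
        for pop, model in config.intensity_model.items():
            mask = lab == pop
            mu[mask], sd[mask] = model[m]
        mult = np.ones(n)
        for spec in config.interface_gradients:
            if spec.marker != m:
                continue
            pops = spec.populations if spec.populations is not None else TAM_LABELS
            affected = np.isin(lab, list(pops)) & np.isfinite(s)
            mult[affected] *= spec.multiplier(s[affected])
        cells[m] = np.exp(rng_i.normal(mu, sd)) * mult * config.exposure[m]
    for m in MARKERS:
        cells[f"exposure_{m}"] = config.exposure[m]

    truth = GroundTruth(
        phenotype=pd.Series(
            cells["true_phenotype"].to_numpy(), index=cells["cell_id"], name="true_phenotype"
        ),
        nest_discs=nest_discs,
    )
    return cells, truth


@dataclass
class CohortData:
    """Everything one synthetic study produces."""

    cells: pd.DataFrame
    truth: GroundTruth
    image_areas: dict[str, float]
    config: SimulationConfig


def generate_cohort(config: SimulationConfig) -> CohortData:
    """Generate every patient's cell table; see :func:`generate_cell_table`."""
    frames, truths, nests = [], [], {}
    for i in range(config.n_patients):
        cells, truth = generate_cell_table(config, i)
        frames.append(cells)
        truths.append(truth.phenotype)
        nests.update(truth.nest_discs or {})
    cells = pd.concat(frames, ignore_index=True)
    image_areas = {
        img: config.tile_area_mm2(roi)
        for img, roi in cells[["image_id", "roi"]].drop_duplicates().to_numpy()
    }
    return CohortData(
        cells=cells,
        truth=GroundTruth(phenotype=pd.concat(truths), nest_discs=nests),
        image_areas=image_areas,
        config=config,
    )


def _density_vector(
    density_table: pd.DataFrame, population: str, roi: str
) -> pd.Series:
    sub = density_table[
        (density_table["population"] == population)
        & (density_table["roi"] == roi)
        & (density_table["compartment"] == "all")
    ]
    return sub.set_index("patient_id")["density"].sort_index()


def generate_expression(
    density_table: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x samples expression matrix with density-linked genes.

    Linked genes for a population are the normal scores of that population's
    per-patient density rank plus Gaussian noise whose scale is calibrated so
    the expected Spearman correlation equals ``expression.target_rho``
    (``noise_scale`` rescales it; 0 gives rho = 1 exactly). Unlinked genes
    are independent Gaussian noise. Returns ``(matrix, linkage)`` where
    linkage records each gene's true population (or "none").
    """
    params = config.expression
    patients = sorted(density_table["patient_id"].unique())
    n = len(patients)
    if n < 3:
        raise DataError(f"expression generation needs >=3 patients, got {n}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000,))
    )
    if params.target_rho <= 0 or params.target_rho >= 1:
        raise ConfigError("target_rho must lie in (0, 1)")
    r_pearson = 2.0 * np.sin(np.pi * params.target_rho / 6.0)
    sigma = params.noise_scale * np.sqrt(1.0 / r_pearson**2 - 1.0)

    genes, rows, linkage = [], [], []
    g = 0
    for pop in params.linked_populations:
        dens = _density_vector(density_table, pop, params.roi).reindex(patients)
        if dens.isna().any():
            raise DataError(f"density table lacks {pop} in {params.roi} for some patients")
        ranks = rankdata(dens.to_numpy(), method="average")
        score = norm.ppf(np.clip((ranks - 0.5) / n, 1e-9, 1 - 1e-9))
        for _ in range(params.n_linked_per_population):
            rows.append(score + sigma * rng.standard_normal(n))
            genes.append(f"gene{g:05d}")
            linkage.append({"gene": genes[-1], "population": pop, "target_rho": params.target_rho})
            g += 1
    while g < params.n_genes:
        rows.append(params.unlinked_sd * rng.standard_normal(n))
        genes.append(f"gene{g:05d}")
        linkage.append({"gene": genes[-1], "population": "none", "target_rho": 0.0})
        g += 1
    expr = pd.DataFrame(np.asarray(rows), index=pd.Index(genes, name="gene"), columns=patients)
    return expr, pd.DataFrame(linkage)


def generate_survival(
    density_table: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient exponential survival driven by a population's density.

    hazard_i = baseline x exp(coef x z_i) with z the standardized density of
    the configured population/ROI; censoring is an independent exponential
    calibrated so each patient is censored with probability
    ``censoring_rate``. Returns ``(records, density_used)``.
    """
    params = config.survival
    dens = _density_vector(density_table, params.population, params.roi)
    if dens.empty:
        raise DataError(f"no densities for {params.population} in {params.roi}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(20_000,))
    )
    d = dens.to_numpy(dtype=float)
    z = (d - d.mean()) / d.std() if d.std() > 0 else np.zeros_like(d)
    hazard = params.baseline_hazard * np.exp(params.log_hazard_coef * z)
    t_event = rng.exponential(1.0 / hazard)
    cr = params.censoring_rate
    if cr > 0:
        t_cens = rng.exponential(1.0 / (hazard * cr / (1.0 - cr)))
    else:
        t_cens = np.full_like(t_event, np.inf)
    records = pd.DataFrame(
        {
            "patient_id": dens.index,
            "time": np.minimum(t_event, t_cens),
            "event": t_event <= t_cens,
        }
    )
    return records, dens
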