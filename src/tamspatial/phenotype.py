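"""Marker-intensity gating of segmented cells into macrophage populations.

Cells arrive as a tidy table (one row per segmented cell) carrying mean
intensities for six markers: CD68 (pan-macrophage), CD163 (scavenger
receptor), CD206 (mannose receptor), IRF8 (M1-associated transcription
factor), PDL1 (immune checkpoint) and AE1AE3 (pan-cytokeratin, tumor cells).
A fixed-priority gate assigns each cell to Tumor, one of seven
tumor-associated macrophage (TAM) populations, or Other.

The seven TAM populations and their M1-like / M2-like grouping:

==================  ========
label               class
==================  ========
CD68+IRF8+          M1-like
CD68+               M1-like
CD68+CD163+         M2-like
CD68++CD163+        M2-like
CD68+CD206+         M2-like
CD68+CD206++        M2-like
CD68+CD163+CD206+   M2-like
==================  ========

A macrophage is any CD68-positive, AE1AE3-negative cell; "++" denotes a
second, higher intensity threshold on CD68 or CD206.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import ConfigError, DataError

MARKERS: tuple[str, ...] = ("CD68", "CD163", "CD206", "IRF8", "PDL1", "AE1AE3")

#: markers consulted by the gate (PDL1 is analyzed downstream, not gated on)
GATING_MARKERS: tuple[str, ...] = ("CD68", "CD163", "CD206", "IRF8", "AE1AE3")

#: markers with an additional "high" (++) threshold
HIGH_MARKERS: tuple[str, ...] = ("CD68", "CD206")

TUMOR_LABEL = "Tumor"
OTHER_LABEL = "Other"

M1_LABELS: tuple[str, ...] = ("CD68+IRF8+", "CD68+")
M2_LABELS: tuple[str, ...] = (
    "CD68+CD163+",
    "CD68++CD163+",
    "CD68+CD206+",
    "CD68+CD206++",
    "CD68+CD163+CD206+",
)
TAM_LABELS: tuple[str, ...] = M1_LABELS + M2_LABELS

#: the full nine-label vocabulary every cell maps into
ALL_LABELS: tuple[str, ...] = (TUMOR_LABEL,) + TAM_LABELS + (OTHER_LABEL,)


def m_class(label: str) -> str:
    """Return the polarization class ('M1like' / 'M2like' / 'none') of a label."""
    if label in M1_LABELS:
        return "M1like"
    if label in M2_LABELS:
        return "M2like"
    if label in ALL_LABELS:
        return "none"
    raise ValueError(f"unknown phenotype label: {label!r}")


@dataclass
class GatingConfig:
    """Thresholds driving the population gate.

    Parameters
    ----------
    positivity:
        Per-marker positivity threshold on the (normalized) intensity scale.
        Must cover every marker in :data:`GATING_MARKERS`.
    high:
        Second, higher threshold for CD68 and CD206 used for the "++" calls.
    normalization:
        ``"raw"`` or ``"exposure_normalized"`` — records which intensity scale
        the thresholds refer to.
    """

    positivity: dict[str, float]
    high: dict[str, float]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        missing = [m for m in GATING_MARKERS if m not in self.positivity]
        if missing:
            raise ConfigError(f"positivity thresholds missing for {missing}")
        for m in HIGH_MARKERS:
            if m not in self.high:
                raise ConfigError(f"high threshold missing for {m}")
            if not self.high[m] > self.positivity[m]:
                raise ConfigError(
                    f"high threshold for {m} ({self.high[m]}) must exceed the "
                    f"positivity threshold ({self.positivity[m]})"
                )
        if self.normalization not in ("raw", "exposure_normalized"):
            raise ConfigError(f"unknown normalization mode {self.normalization!r}")

    def to_dict(self) -> dict:
        return {
            "positivity": {k: float(v) for k, v in self.positivity.items()},
            "high": {k: float(v) for k, v in self.high.items()},
            "normalization": self.normalization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingConfig":
        return cls(
            positivity=dict(d["positivity"]),
            high=dict(d["high"]),
            normalization=d.get("normalization", "raw"),
        )


def normalize_intensity(cells: pd.DataFrame, mode: str = "raw") -> pd.DataFrame:
    """Return a copy of *cells* with intensities on the requested scale.

    Under ``exposure_normalized`` each marker intensity is divided by its
    per-cell exposure time (column ``exposure_<marker>``), putting images
    acquired at different exposures on a common scale. Under ``raw`` the
    table is returned unchanged (a copy).
    """
    if mode == "raw":
        return cells.copy()
    if mode != "exposure_normalized":
        raise ConfigError(f"unknown normalization mode {mode!r}")
    out = cells.copy()
    for m in MARKERS:
        col = f"exposure_{m}"
        if col not in out.columns:
            raise DataError(f"exposure column {col!r} required for normalization")
        exp = out[col].to_numpy(dtype=float)
        bad = ~(exp > 0)
        if bad.any():
            first = out.index[bad][0]
            raise DataError(
                f"non-positive exposure for marker {m} at cell "
                f"{out.loc[first, 'cell_id'] if 'cell_id' in out else first}"
            )
        out[m] = out[m].to_numpy(dtype=float) / exp
    return out


def _gmm2_threshold(values: np.ndarray, seed: int = 0) -> tuple[float, float] | None:
    """Two-component mixture split of one marker's log1p intensities.

    Returns ``(positivity, upper_component_mean)`` on the intensity scale, or
    ``None`` when the fit is degenerate (collapsed components).
    """
    x = np.log1p(values).reshape(-1, 1)
    if np.ptp(x) < 1e-12:
        return None
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed)
    try:
        gm.fit(x)
    except Exception:  # pragma: no cover - sklearn failure path
        return None
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(mu)
    if (mu[hi] - mu[lo]) < 0.5 * (sd[lo] + sd[hi]) or (mu[hi] - mu[lo]) < 1e-6:
        return None
    # equal-posterior crossing between the two component means
    grid = np.linspace(mu[lo], mu[hi], 2001)
    post = gm.predict_proba(grid.reshape(-1, 1))
    diff = post[:, hi] - post[:, lo]
    cross = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    t_log = grid[cross[0]] if len(cross) else 0.5 * (mu[lo] + mu[hi])
    return float(np.expm1(t_log)), float(np.expm1(mu[hi]))


def estimate_thresholds(
    cells: pd.DataFrame,
    method: str = "gmm2",
    positivity_quantile: float = 0.70,
    high_quantile: float = 0.90,
    seed: int = 0,
) -> GatingConfig:
    """Estimate cohort-wide gating thresholds from the pooled intensity table.

    ``gmm2`` fits a two-component Gaussian mixture per marker on log1p
    intensity; the positivity threshold is the equal-posterior point between
    the components and the CD68/CD206 high thresholds sit at the upper
    component's mean. Markers with a degenerate fit fall back to the
    ``percentile`` rule (positivity and high quantiles of the raw intensity),
    with a warning.
    """
    if len(cells) < 100:
        raise DataError(f"need at least 100 cells to estimate thresholds, got {len(cells)}")
    if method not in ("gmm2", "percentile"):
        raise ConfigError(f"unknown threshold method {method!r}")
    positivity: dict[str, float] = {}
    high: dict[str, float] = {}
    for m in GATING_MARKERS:
        vals = cells[m].to_numpy(dtype=float)
        fit = None
        if method == "gmm2":
            fit = _gmm2_threshold(vals, seed=seed)
            if fit is None:
                warnings.warn(
                    f"degenerate mixture fit for marker {m}; falling back to percentile",
                    stacklevel=2,
                )
        if fit is not None:
            positivity[m] = fit[0]
            if m in HIGH_MARKERS:
                high[m] = fit[1]
        else:
            positivity[m] = float(np.quantile(vals, positivity_quantile))
            if m in HIGH_MARKERS:
                h = float(np.quantile(vals, high_quantile))
                high[m] = h if h > positivity[m] else positivity[m] * 1.5 + 1e-9
    return GatingConfig(positivity=positivity, high=high)


def classify_cells(cells: pd.DataFrame, config: GatingConfig) -> pd.Series:
    """Vectorized population gate; returns one label per cell.

    Decision order (first match wins):

    1. AE1AE3 positive                      -> Tumor
    2. CD68 negative                        -> Other
    3. CD163+ and CD206+                    -> CD68+CD163+CD206+
    4. CD163+                               -> CD68++CD163+ if CD68 high
                                               else CD68+CD163+
    5. CD206+                               -> CD68+CD206++ if CD206 high
                                               else CD68+CD206+
    6. IRF8+                                -> CD68+IRF8+
    7. otherwise                            -> CD68+

    Scavenger/mannose positivity takes priority over IRF8, which only splits
    the CD163-/CD206- branch; this yields exactly seven TAM labels.
    """
    pos = config.positivity
    cd68 = cells["CD68"].to_numpy(dtype=float)
    cd163 = cells["CD163"].to_numpy(dtype=float)
    cd206 = cells["CD206"].to_numpy(dtype=float)
    irf8 = cells["IRF8"].to_numpy(dtype=float)
    ae = cells["AE1AE3"].to_numpy(dtype=float)

    p163 = cd163 >= pos["CD163"]
    p206 = cd206 >= pos["CD206"]
    conditions = [
        ae >= pos["AE1AE3"],
        cd68 < pos["CD68"],
        p163 & p206,
        p163 & (cd68 >= config.high["CD68"]),
        p163,
        p206 & (cd206 >= config.high["CD206"]),
        p206,
        irf8 >= pos["IRF8"],
    ]
    choices = [
        TUMOR_LABEL,
        OTHER_LABEL,
        "CD68+CD163+CD206+",
        "CD68++CD163+",
        "CD68+CD163+",
        "CD68+CD206++",
        "CD68+CD206+",
        "CD68+IRF8+",
    ]
    labels = np.select(conditions, choices, default="CD68+")
    return pd.Series(labels, index=cells.index, name="phenotype")


def classify_cell(cell: pd.Series | dict, config: GatingConfig) -> str:
    """Gate a single cell; see :func:`classify_cells`."""
    row = pd.DataFrame([dict(cell)])
    return str(classify_cells(row, config).iloc[0])


def population_signature(
    cells: pd.DataFrame,
    populations: tuple[str, ...] | None = None,
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Mean marker-intensity vector per labelled population.

    Returns a populations x markers frame; requested populations with no
    cells are omitted with a warning.
    """
    if "phenotype" not in cells.columns:
        raise DataError("cells must carry a 'phenotype' column; run classify_cells first")
    if populations is None:
        populations = tuple(cells["phenotype"].unique())
    present = []
    for p in populations:
        if (cells["phenotype"] == p).any():
            present.append(p)
        else:
            warnings.warn(f"population {p!r} has no cells; omitted from signature", stacklevel=2)
    sig = (
        cells[cells["phenotype"].isin(present)]
        .groupby("phenotype", sort=False)[list(markers)]
        .mean()
    )
    return sig.loc[[p for p in present]]
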