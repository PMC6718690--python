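"""Marker-intensity gradients across the tumor-nest / stroma (TS) interface.

The TS interface is taken as point zero of a signed distance axis: positive
distances lie on the tumor-nest side, negative distances in the stroma. A
cell's signed distance is the Euclidean distance from its nucleus to the
nearest nucleus of the opposite compartment, signed by its own compartment.
This nucleus-based proxy stands in for the segmentation-mask boundary (cell
tables carry no pixel masks) and converges to it as cell density grows.

Profiles are built from compartment-balanced samples (equal cell numbers per
side per patient) so that neither side dominates the bin means, then binned
along the signed axis with a confidence band. A threshold on the marker
splits each side into positive/negative, yielding the four interface
quadrants:

=========  ==========  ========
quadrant   side        marker
=========  ==========  ========
I          tumor-nest  positive
II         stroma      positive
III        stroma      negative
IV         tumor-nest  negative
=========  ==========  ========
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.isotonic import IsotonicRegression

from .errors import DataError


def sample_balanced(
    cells: pd.DataFrame,
    n_per_side: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample exactly *n_per_side* cells per compartment, without replacement.

    Operates on one patient's cells (one ROI). Raises :class:`DataError`
    when either compartment has fewer than *n_per_side* cells; cohort-level
    exclusion / quota reduction lives in :func:`sample_balanced_cohort`.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for comp in ("tumor_nest", "stroma"):
        side = cells[cells["compartment"] == comp]
        if len(side) < n_per_side:
            raise DataError(
                f"compartment {comp!r} has {len(side)} cells, fewer than "
                f"n_per_side={n_per_side}"
            )
        take = rng.choice(len(side), size=n_per_side, replace=False)
        parts.append(side.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def sample_balanced_cohort(
    cells: pd.DataFrame,
    n_per_side: int = 500,
    seed: int = 0,
    mode: str = "strict",
) -> pd.DataFrame:
    """Balanced per-patient sampling across a cohort.

    ``strict`` excludes (with a warning) patients lacking *n_per_side* cells
    on either side; ``min_available`` instead reduces the per-side quota to
    the minimum available across the cohort, so every patient contributes the
    same number of cells per side.
    """
    if mode not in ("strict", "min_available"):
        raise DataError(f"unknown balanced-sampling mode {mode!r}")
    counts = cells.groupby(["patient_id", "compartment"], sort=False).size()
    if mode == "min_available":
        n_per_side = min(n_per_side, int(counts.min())) if len(counts) else n_per_side
    out = []
    rng_seeds = {}
    for i, (pid, pat) in enumerate(cells.groupby("patient_id", sort=False)):
        rng_seeds[pid] = seed + i
        try:
            out.append(sample_balanced(pat, n_per_side=n_per_side, seed=rng_seeds[pid]))
        except DataError:
            warnings.warn(
                f"patient {pid} lacks {n_per_side} cells per compartment; excluded",
                stacklevel=2,
            )
    if not out:
        raise DataError("no patient has enough cells on both sides")
    return pd.concat(out, ignore_index=True)


def signed_interface_distance(cells: pd.DataFrame) -> pd.Series:
    """Signed distance (µm) to the TS interface for every cell of one image.

    Magnitude: distance to the nearest nucleus of the opposite compartment.
    Sign: positive in the tumor nest, negative in the stroma.
    """
    comp = cells["compartment"].to_numpy()
    in_nest = comp == "tumor_nest"
    if in_nest.all() or (~in_nest).all():
        raise DataError("image contains a single compartment; interface undefined")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    d = np.empty(len(cells), dtype=float)
    nest_tree = cKDTree(xy[in_nest])
    stroma_tree = cKDTree(xy[~in_nest])
    d[in_nest], _ = stroma_tree.query(xy[in_nest], k=1)
    d[~in_nest], _ = nest_tree.query(xy[~in_nest], k=1)
    d[~in_nest] *= -1.0
    return pd.Series(d, index=cells.index, name="signed_distance_um")


def signed_interface_distance_by_image(cells: pd.DataFrame) -> pd.Series:
    """Apply :func:`signed_interface_distance` image by image.

    Single-compartment images are skipped with a warning; their cells get
    NaN.
    """
    out = pd.Series(np.nan, index=cells.index, name="signed_distance_um")
    for image_id, img in cells.groupby("image_id", sort=False):
        try:
            out.loc[img.index] = signed_interface_distance(img)
        except DataError:
            warnings.warn(f"image {image_id} has one compartment; skipped", stacklevel=2)
    return out


def gradient_profile(
    cells: pd.DataFrame,
    marker: str,
    population: str | None = None,
    bin_width: float = 10.0,
    band: str = "ci95_t",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned mean-intensity profile along the signed interface axis.

    *cells* must carry ``signed_distance_um`` (see
    :func:`signed_interface_distance_by_image`). Cells of *population* (all
    cells when None) are binned by signed distance into half-open
    ``[k*w, (k+1)*w)`` bins; bins with fewer than 2 cells are suppressed.
    The confidence band is a per-bin 95% t-interval, or a seeded percentile
    bootstrap of the bin mean (``band="bootstrap"``).
    """
    if bin_width <= 0:
        raise DataError("bin_width must be positive")
    if band not in ("ci95_t", "bootstrap"):
        raise DataError(f"unknown band method {band!r}")
    sub = cells if population is None else cells[cells["phenotype"] == population]
    sub = sub.dropna(subset=["signed_distance_um"])
    if len(sub) == 0:
        warnings.warn(f"no cells for population {population!r}; empty profile", stacklevel=2)
        return pd.DataFrame(
            columns=["marker", "population", "bin_center_um", "n", "mean", "lower", "upper"]
        )
    s = sub["signed_distance_um"].to_numpy(dtype=float)
    y = sub[marker].to_numpy(dtype=float)
    k = np.floor(s / bin_width).astype(int)
    rng = np.random.default_rng(seed)
    rows = []
    for kk in np.unique(k):
        vals = y[k == kk]
        if vals.size < 2:
            continue
        m = float(vals.mean())
        if band == "ci95_t":
            sd = float(vals.std(ddof=1))
            half = stats.t.ppf(0.975, vals.size - 1) * sd / np.sqrt(vals.size)
            lo, hi = m - half, m + half
        else:
            boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "marker": marker,
                "population": population if population is not None else "all",
                "bin_center_um": (kk + 0.5) * bin_width,
                "n": int(vals.size),
                "mean": m,
                "lower": float(lo),
                "upper": float(hi),
            }
        )
    return pd.DataFrame(rows).sort_values("bin_center_um", ignore_index=True)


def quadrant_classify(profile: pd.DataFrame, threshold: float) -> dict[str, str]:
    """Assign the interface quadrant for each side of a profile.

    A side is positive when its cell-weighted mean intensity strictly
    exceeds *threshold*. Sides without any bins are reported as
    ``"indeterminate"``.
    """
    out: dict[str, str] = {}
    for side, name in ((profile["bin_center_um"] > 0, "tumor_nest"),
                       (profile["bin_center_um"] < 0, "stroma")):
        sub = profile[side]
        if len(sub) == 0:
            out[name] = "indeterminate"
            continue
        mean = float(np.average(sub["mean"], weights=sub["n"]))
        positive = mean > threshold
        if name == "tumor_nest":
            out[name] = "I" if positive else "IV"
        else:
            out[name] = "II" if positive else "III"
    return out


def estimate_half_rise(profile: pd.DataFrame) -> float:
    """Signed position where a rising profile crosses half of its total rise.

    A cell-weighted isotonic (monotone non-decreasing) fit smooths the bin
    means — sparse far-stroma bins are noisy and would otherwise trigger
    spurious early crossings. The baseline and plateau are the fit's
    extreme levels; the half-rise position is linearly interpolated between
    the last bin below and the first bin at or above the midpoint level.
    Raises :class:`DataError` when the profile has no rise.
    """
    prof = profile.sort_values("bin_center_um")
    centers = prof["bin_center_um"].to_numpy(dtype=float)
    weights = prof["n"].to_numpy(dtype=float)
    if (centers < 0).sum() < 2 or (centers > 0).sum() < 1:
        raise DataError("profile does not span both sides of the interface")
    iso = IsotonicRegression(increasing=True).fit_transform(
        centers, prof["mean"].to_numpy(dtype=float), sample_weight=weights
    )
    baseline, plateau = iso[0], iso[-1]
    if plateau <= baseline:
        raise DataError("profile has no rise across the interface")
    half = 0.5 * (baseline + plateau)
    above = iso >= half
    i = int(np.argmax(above))
    if i == 0:
        return float(centers[0])
    if iso[i] == iso[i - 1]:
        return float(0.5 * (centers[i - 1] + centers[i]))
    frac = (half - iso[i - 1]) / (iso[i] - iso[i - 1])
    return float(centers[i - 1] + frac * (centers[i] - centers[i - 1]))
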