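"""Nearest-cell distance analysis between phenotype pairs.

Every cell of a reference phenotype (RC) is paired with the closest cell of
a target phenotype (NC), nucleus to nucleus, within one image. From the
resulting per-cell distances the module derives:

* **median distance** — per patient (x ROI), the empirical median of the
  RC-to-nearest-NC distances;
* **effective percentage** — the proportion of RCs whose nearest NC falls in
  a given distance bin (default 10 µm increments), and its cumulative form;
* **effective density** — the number of RCs with an NC within the contact
  radius (default 10 µm, an estimated direct nucleus-to-nucleus contact
  distance), normalized to tissue area (cells/mm²);
* per-patient density tables by ROI and tissue compartment with the
  M1-like:M2-like count ratio;
* population co-localization (pairwise Spearman correlation of densities
  across patients).

Distances are only defined within a single image: coordinates live in
per-tile frames, so cross-image pairing is never performed.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

from .errors import DataError
from .phenotype import ALL_LABELS, M1_LABELS, M2_LABELS, TAM_LABELS


def _coords(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_um", "y_um"]].to_numpy(dtype=float)


def nearest_distance(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    exclude_same_cell: bool = True,
) -> np.ndarray:
    """Distance from each reference cell to the nearest target cell (µm).

    Cells are matched by Euclidean nucleus-to-nucleus distance. When a cell
    appears in both sets (same ``cell_id``) it never pairs with itself.
    Both frames must come from the same image; the caller is responsible for
    restricting them (see :func:`distance_result`).
    """
    if len(target) == 0:
        raise DataError("target set is empty; nearest distances are undefined")
    if len(reference) == 0:
        return np.empty(0, dtype=float)
    ref_xy = _coords(reference)
    tgt_xy = _coords(target)
    tree = cKDTree(tgt_xy)

    check_self = (
        exclude_same_cell
        and "cell_id" in reference.columns
        and "cell_id" in target.columns
        and bool(set(reference["cell_id"]) & set(target["cell_id"]))
    )
    if not check_self:
        d, _ = tree.query(ref_xy, k=1)
        return np.asarray(d, dtype=float)

    if len(target) < 2:
        raise DataError("target contains only the reference cell itself")
    d2, i2 = tree.query(ref_xy, k=2)
    ref_ids = reference["cell_id"].to_numpy()
    tgt_ids = target["cell_id"].to_numpy()
    self_hit = tgt_ids[i2[:, 0]] == ref_ids
    out = np.where(self_hit, d2[:, 1], d2[:, 0])
    return np.asarray(out, dtype=float)


def nearest_distances_by_image(
    cells: pd.DataFrame,
    reference_population: str,
    target_population: str,
) -> pd.DataFrame:
    """Per-cell nearest distances computed image by image.

    Returns one row per reference cell (patient_id, roi, image_id, cell_id,
    distance_um). Images lacking target cells are skipped with a warning, as
    the distance is undefined there.
    """
    rows = []
    for image_id, img in cells.groupby("image_id", sort=False):
        ref = img[img["phenotype"] == reference_population]
        tgt = img[img["phenotype"] == target_population]
        if len(ref) == 0:
            continue
        if len(tgt) == 0 or (reference_population == target_population and len(tgt) < 2):
            warnings.warn(
                f"image {image_id}: no {target_population} target cells; "
                f"{len(ref)} reference cells skipped",
                stacklevel=2,
            )
            continue
        d = nearest_distance(ref, tgt)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": ref["patient_id"].to_numpy(),
                    "roi": ref["roi"].to_numpy(),
                    "image_id": image_id,
                    "cell_id": ref["cell_id"].to_numpy(),
                    "distance_um": d,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "roi", "image_id", "cell_id", "distance_um"]
        )
    return pd.concat(rows, ignore_index=True)


def median_distance(distances: Iterable[float]) -> float:
    """Empirical median (midpoint convention for even counts) of distances."""
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise DataError("no reference cells; median distance undefined")
    return float(np.median(arr))


def median_distance_table(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Median nearest distance per patient x ROI from per-cell distances."""
    if per_cell.empty:
        warnings.warn("no reference cells in any image; empty median table", stacklevel=2)
        return pd.DataFrame(columns=["patient_id", "roi", "n_reference", "median_um"])
    out = (
        per_cell.groupby(["patient_id", "roi"], sort=False)["distance_um"]
        .agg(n_reference="size", median_um="median")
        .reset_index()
    )
    return out


def effective_percentage(
    distances: Iterable[float],
    bin_width: float = 10.0,
    max_distance: float | None = None,
) -> pd.DataFrame:
    """Per-bin fraction of reference cells whose nearest target lies in the bin.

    Bins are half-open ``[k*w, (k+1)*w)``. Fractions are relative to the
    *total* reference count, so they sum to 1 as ``max_distance`` grows to
    cover every cell. A ``cumulative`` column gives the fraction within
    ``[0, upper_edge]``.
    """
    if bin_width <= 0:
        raise DataError("bin_width must be positive")
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise DataError("no reference cells; effective percentage undefined")
    if max_distance is None:
        max_distance = float(arr.max()) + bin_width
    n_bins = int(np.ceil(max_distance / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(arr / bin_width).astype(int)
    counts = np.bincount(idx[idx < n_bins], minlength=n_bins)
    frac = counts / arr.size
    cumulative = np.cumsum(frac)
    return pd.DataFrame(
        {
            "bin_lower_um": edges[:-1],
            "bin_upper_um": edges[1:],
            "n": counts,
            "fraction": frac,
            "cumulative": cumulative,
        }
    )


def cumulative_effective_percentage(distances: Iterable[float], radius: float) -> float:
    """Fraction of reference cells with nearest target within ``[0, radius]``."""
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise DataError("no reference cells")
    return float(np.mean(arr <= radius))


def effective_density(
    distances: Iterable[float],
    area_mm2: float,
    contact_radius: float = 10.0,
) -> float:
    """Reference cells with a target within the contact radius, per mm².

    The contact criterion is inclusive (nearest distance <= radius). The
    identity ``effective_density = cumulative_effective_percentage(radius) *
    reference_density`` holds exactly.
    """
    if not area_mm2 > 0:
        raise DataError("area must be positive")
    arr = np.asarray(list(distances), dtype=float)
    return float(np.sum(arr <= contact_radius) / area_mm2)


def density_table(
    cells: pd.DataFrame,
    image_areas: dict[str, float],
    by_compartment: bool = False,
    populations: tuple[str, ...] = ALL_LABELS,
) -> pd.DataFrame:
    """Cell densities per patient x ROI (x compartment) x population.

    Counts from all images of a stratum are pooled and normalized by the
    summed area of those images (cells/mm²); populations absent from a
    stratum appear with count 0. The M1-like:M2-like count ratio is appended
    per stratum (0 when no M1-like cells; +inf when M1-like cells face zero
    M2-like cells).

    Compartment strata are normalized by the same total imaged area as the
    whole stratum: per-compartment mask areas are not recoverable from a
    cell table.
    """
    unknown = set(cells["image_id"].unique()) - set(image_areas)
    if unknown:
        raise DataError(f"unknown image area for image(s): {sorted(unknown)}")
    if "phenotype" not in cells.columns:
        raise DataError("cells must carry a 'phenotype' column")

    img_area = pd.Series(image_areas, name="area_mm2")
    strata_area = (
        cells[["patient_id", "roi", "image_id"]]
        .drop_duplicates()
        .assign(area_mm2=lambda d: d["image_id"].map(img_area))
        .groupby(["patient_id", "roi"], sort=False)["area_mm2"]
        .sum()
    )

    group_cols = ["patient_id", "roi"] + (["compartment"] if by_compartment else [])
    counts = (
        cells.groupby(group_cols + ["phenotype"], sort=False, observed=True)
        .size()
        .rename("cell_count")
    )
    # complete the population index with zeros
    strata = cells[group_cols].drop_duplicates()
    full = strata.merge(pd.DataFrame({"phenotype": list(populations)}), how="cross")
    out = full.merge(counts.reset_index(), on=group_cols + ["phenotype"], how="left")
    out["cell_count"] = out["cell_count"].fillna(0).astype(int)
    if not by_compartment:
        out["compartment"] = "all"
    out["area_mm2"] = out.set_index(["patient_id", "roi"]).index.map(strata_area)
    out["density"] = out["cell_count"] / out["area_mm2"]

    m1 = (
        out[out["phenotype"].isin(M1_LABELS)]
        .groupby(group_cols, sort=False)["cell_count"]
        .sum()
    )
    m2 = (
        out[out["phenotype"].isin(M2_LABELS)]
        .groupby(group_cols, sort=False)["cell_count"]
        .sum()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = m1.to_numpy(dtype=float) / m2.to_numpy(dtype=float)
    ratio = pd.Series(
        np.where(m1.to_numpy() == 0, 0.0, raw), index=m1.index, name="m1_m2_ratio"
    )
    out = out.merge(ratio.reset_index(), on=group_cols, how="left")
    out = out.rename(columns={"phenotype": "population"})
    cols = ["patient_id", "roi", "compartment", "population", "cell_count", "area_mm2", "density", "m1_m2_ratio"]
    return out[cols]


def colocalization_matrix(
    densities: pd.DataFrame,
    roi: str = "core",
    populations: tuple[str, ...] = TAM_LABELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of population densities across patients.

    Operates on one ROI of a :func:`density_table` output (compartment
    'all'). Returns (rho, p) matrices, symmetric with unit diagonal; pairs
    involving a constant density vector are reported as missing (NaN).
    """
    sub = densities[(densities["roi"] == roi) & (densities["compartment"] == "all")]
    wide = sub.pivot_table(
        index="patient_id", columns="population", values="density"
    ).reindex(columns=list(populations))
    if len(wide) < 5:
        raise DataError(f"need >=5 patients for co-localization, got {len(wide)}")
    k = wide.shape[1]
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    x = wide.to_numpy(dtype=float)
    const = np.nanstd(x, axis=0) == 0
    for i in range(k):
        rho[i, i] = np.nan if const[i] else 1.0
        pval[i, i] = np.nan if const[i] else 0.0
        for j in range(i + 1, k):
            if const[i] or const[j]:
                continue
            r, p = stats.spearmanr(x[:, i], x[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(populations, name="population")
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pval, index=idx, columns=idx),
    )
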