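"""Cohort-level statistics: PDL1 positivity, environmental gene signatures,
survival stratification, and phenotyping robustness.

PDL1 analysis pools an equal number of randomly selected cells per patient
(all ROIs, all cell types) into subsampling cohorts, so patients with more
imaged tissue do not dominate; positivity is defined against the cohort's
mean PDL1 intensity, and patients are called PDL1-high when any of their
macrophages reaches the cohort's top percentile.

An environmental gene signature of a macrophage population is the set of
genes whose whole-tissue expression correlates (Spearman) with that
population's per-patient density; the "refined" signature keeps only genes
at p < 0.001. Benjamini-Hochberg adjusted values are reported alongside raw
p-values but do not drive membership.

Survival stratification follows the study design: patients split into
density terciles (upper vs lower compared) or above/below the median of a
signature score, compared with Kaplan-Meier curves and the Mantel-Cox
log-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .phenotype import MARKERS, TAM_LABELS

# ---------------------------------------------------------------------------
# PDL1 subsampling cohorts and positivity


def build_pdl1_cohorts(
    cells: pd.DataFrame,
    n_per_patient: int = 10_000,
    n_cohorts: int = 5,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Independent subsampling cohorts with equal cell numbers per patient.

    Each cohort pools exactly *n_per_patient* cells per patient (all ROIs,
    irrespective of cell type), sampled without replacement; patients with
    fewer cells are sampled with replacement to reach the quota and flagged
    in a ``resampled`` column.
    """
    counts = cells.groupby("patient_id", sort=False).size()
    if (counts == 0).any() or len(counts) == 0:
        raise DataError("every patient must contribute at least one cell")
    rng = np.random.default_rng(seed)
    cohorts = []
    for _ in range(n_cohorts):
        parts = []
        for pid, pat in cells.groupby("patient_id", sort=False):
            replace = len(pat) < n_per_patient
            idx = rng.choice(len(pat), size=n_per_patient, replace=replace)
            part = pat.iloc[idx].copy()
            part["resampled"] = replace
            parts.append(part)
        cohorts.append(pd.concat(parts, ignore_index=True))
    return cohorts


def pdl1_positivity(cohort: pd.DataFrame) -> tuple[float, pd.Series, float]:
    """Mean-intensity PDL1 positivity over a subsampling cohort.

    The threshold is the arithmetic mean PDL1 intensity across the cohort's
    cells; a cell is positive iff its intensity strictly exceeds it. Returns
    ``(threshold, per-cell flags, positive fraction)``.
    """
    if len(cohort) == 0:
        raise DataError("cohort is empty")
    x = cohort["PDL1"].to_numpy(dtype=float)
    threshold = float(x.mean())
    flags = pd.Series(x > threshold, index=cohort.index, name="pdl1_positive")
    return threshold, flags, float(flags.mean())


def pdl1_top_percent(cohort: pd.DataFrame, percent: float) -> pd.Series:
    """Flags for cells in the top *percent* of the cohort's PDL1 intensities."""
    if not 0 < percent < 100:
        raise DataError(f"percent must lie in (0, 100), got {percent}")
    x = cohort["PDL1"].to_numpy(dtype=float)
    cut = np.quantile(x, 1.0 - percent / 100.0)
    return pd.Series(x > cut, index=cohort.index, name=f"pdl1_top{percent:g}")


def classify_pdl1_high_patients(cohort: pd.DataFrame, flags: pd.Series) -> pd.DataFrame:
    """Patient-level PDL1-high calls from top-percentile cell flags.

    A patient is PDL1-high when at least one of their *macrophage* cells is
    flagged (tumor or other flagged cells do not count). Also reports, per
    patient, the macrophage population attaining the highest PDL1 intensity.
    """
    if "phenotype" not in cohort.columns:
        raise DataError("cohort must carry a 'phenotype' column")
    is_tam = cohort["phenotype"].isin(TAM_LABELS)
    rows = []
    for pid, pat in cohort.groupby("patient_id", sort=False):
        tam = pat[is_tam.loc[pat.index]]
        high = bool(flags.loc[tam.index].any()) if len(tam) else False
        top_pop = (
            tam.loc[tam["PDL1"].idxmax(), "phenotype"] if len(tam) else None
        )
        rows.append({"patient_id": pid, "pdl1_high": high, "top_tam_population": top_pop})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n p-values


@lru_cache(maxsize=8)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """All n! Spearman rho values of one fixed ranking against every
    permutation of the other (exact null distribution, n <= 9)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1)
    rhos = [
        1.0 - 6.0 * float(((base - np.asarray(perm, dtype=float)) ** 2).sum()) / denom
        for perm in itertools.permutations(range(1, n + 1))
    ]
    return np.sort(np.asarray(rhos))


def spearman_with_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation p for n <= *exact_max_n* (valid for tie-free data),
    the usual t-approximation otherwise. Returns (nan, nan) when either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return (np.nan, np.nan)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        dist = _exact_rho_distribution(n)
        p = float(np.mean(np.abs(dist) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(stats.spearmanr(x, y).pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignatureResult:
    """Per-population environmental gene signature."""

    population: str
    table: pd.DataFrame  # gene, rho, p, fdr, in_signature, in_refined
    alpha: float
    alpha_refined: float

    @property
    def signature_genes(self) -> list[str]:
        return self.table.loc[self.table["in_signature"], "gene"].tolist()

    @property
    def refined_genes(self) -> list[str]:
        return self.table.loc[self.table["in_refined"], "gene"].tolist()


def environmental_signature(
    density_table: pd.DataFrame,
    expression: pd.DataFrame,
    population: str,
    alpha: float = 0.05,
    alpha_refined: float = 0.001,
    roi: str = "core",
) -> SignatureResult:
    """Genes whose expression tracks a population's density across patients.

    Densities (one ROI, compartments pooled) are matched to expression
    samples by patient id; each gene's Spearman rho and two-sided p against
    the density vector define the signature (p < alpha) and refined
    signature (p < alpha_refined). BH-FDR is reported per gene. Genes or
    densities with zero variance yield missing correlations and never enter
    a signature.
    """
    sub = density_table[
        (density_table["population"] == population)
        & (density_table["roi"] == roi)
        & (density_table["compartment"] == "all")
    ].set_index("patient_id")["density"]
    common = [p for p in expression.columns if p in sub.index]
    if len(common) < 5:
        raise DataError(f"need >=5 matched samples, got {len(common)}")
    dens = sub.loc[common].to_numpy(dtype=float)
    mat = expression[common].to_numpy(dtype=float)
    n = len(common)

    if np.std(dens) == 0:
        rho = np.full(mat.shape[0], np.nan)
        pval = np.full(mat.shape[0], np.nan)
    elif n <= 9:
        rho = np.empty(mat.shape[0])
        pval = np.empty(mat.shape[0])
        for i in range(mat.shape[0]):
            rho[i], pval[i] = spearman_with_p(mat[i], dens)
    else:
        # vectorized rank correlation with t-approximation p-values
        const = mat.std(axis=1) == 0
        rg = stats.rankdata(mat, axis=1).astype(float)
        dg = stats.rankdata(dens).astype(float)
        rg = (rg - rg.mean(axis=1, keepdims=True)) / np.where(
            rg.std(axis=1, keepdims=True) == 0, 1.0, rg.std(axis=1, keepdims=True)
        )
        dgz = (dg - dg.mean()) / dg.std()
        rho = rg @ dgz / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pval = np.where(np.abs(rho) >= 1.0, 0.0, pval)
        rho[const] = np.nan
        pval[const] = np.nan

    fdr = np.full_like(pval, np.nan)
    ok = np.isfinite(pval)
    if ok.any():
        fdr[ok] = bh_fdr(pval[ok])
    table = pd.DataFrame(
        {
            "gene": expression.index,
            "rho": rho,
            "p": pval,
            "fdr": fdr,
            "in_signature": ok & (pval < alpha),
            "in_refined": ok & (pval < alpha_refined),
        }
    )
    return SignatureResult(population=population, table=table, alpha=alpha, alpha_refined=alpha_refined)


def signature_score_and_split(
    expression: pd.DataFrame, gene_set
) -> tuple[pd.Series, pd.Series]:
    """Per-sample signature score (mean z-scored expression) and median split.

    Samples scoring strictly above the cohort median are 'high', the rest
    'low'. Raises when no signature gene is present in the matrix.
    """
    genes = [g for g in gene_set if g in expression.index]
    if not genes:
        raise DataError("no signature gene found in the expression matrix")
    sub = expression.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    score = pd.Series(z.mean(axis=0), index=expression.columns, name="signature_score")
    groups = pd.Series(
        np.where(score > score.median(), "high", "low"), index=score.index, name="group"
    )
    return score, groups


def cluster_samples(expression: pd.DataFrame, gene_set, k: int = 2) -> pd.Series:
    """Agglomerative sample grouping (average linkage, correlation distance).

    Deterministic alternative to the median split for heat-map style
    grouping of samples on a gene set.
    """
    genes = [g for g in gene_set if g in expression.index]
    if len(genes) < 2:
        raise DataError("need >=2 signature genes for correlation-distance clustering")
    x = expression.loc[genes].to_numpy(dtype=float).T  # samples x genes
    link = hierarchy.linkage(x, method="average", metric="correlation")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
    return pd.Series(labels, index=expression.columns, name="cluster")


# ---------------------------------------------------------------------------
# Survival


def tercile_stratify(values: pd.Series) -> pd.Series:
    """Upper / middle / lower tercile labels per patient.

    Upper = strictly above the 2/3 empirical quantile; lower = at or below
    the 1/3 quantile; remainder middle. Heavy ties can empty a group, which
    is reported as-is with a warning.
    """
    v = pd.Series(values).astype(float)
    if len(v) < 3:
        raise DataError(f"tercile stratification needs >=3 patients, got {len(v)}")
    q1, q2 = np.quantile(v.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    labels = pd.Series(
        np.where(v > q2, "upper", np.where(v <= q1, "lower", "middle")),
        index=v.index,
        name="tercile",
    )
    for grp in ("upper", "lower"):
        if (labels == grp).sum() == 0:
            warnings.warn(f"tercile group {grp!r} is empty (heavy ties)", stacklevel=2)
    return labels


def km_logrank(
    records: pd.DataFrame, groups: pd.Series, labels: tuple[str, str]
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves and Mantel-Cox log-rank test for two groups.

    *records* needs ``patient_id``, ``time``, ``event``; *groups* maps
    patient_id to a stratum label. Returns ``(curves, chi2, p)`` where
    curves maps each label to its product-limit estimate (columns
    ``time``, ``survival``).
    """
    df = records.set_index("patient_id")
    curves: dict[str, pd.DataFrame] = {}
    sets = {}
    for lab in labels:
        pids = groups.index[groups == lab]
        sub = df.loc[df.index.intersection(pids)]
        if len(sub) == 0:
            raise DataError(f"group {lab!r} has no subjects")
        sets[lab] = sub
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[lab] = sf
    a, b = sets[labels[0]], sets[labels[1]]
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Phenotyping robustness


def subsample_stability(
    cells: pd.DataFrame,
    population: str,
    n_draws: int = 2000,
    n_cells: int = 100,
    seed: int = 0,
    markers: tuple[str, ...] = MARKERS,
) -> dict:
    """Stability of a population's combined-marker signature under subsampling.

    Repeatedly draws *n_cells* cells of the population (without replacement)
    and correlates (Pearson) the subsample's mean marker vector with the
    bulk population's. Draws whose marker vector has zero variance are
    skipped and counted. Returns the r distribution with its mean +- SD.
    """
    sub = cells[cells["phenotype"] == population]
    if len(sub) < n_cells:
        warnings.warn(
            f"population {population!r} has {len(sub)} cells < n_cells={n_cells}; skipped",
            stacklevel=2,
        )
        return {"population": population, "r": np.empty(0), "mean": np.nan, "sd": np.nan, "n_skipped": 0}
    x = sub[list(markers)].to_numpy(dtype=float)
    bulk = x.mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = np.stack([rng.choice(len(x), size=n_cells, replace=False) for _ in range(n_draws)])
    means = x[idx].mean(axis=1)  # n_draws x markers
    bz = bulk - bulk.mean()
    mz = means - means.mean(axis=1, keepdims=True)
    denom = np.sqrt((mz**2).sum(axis=1) * (bz**2).sum())
    valid = denom > 0
    r = np.full(n_draws, np.nan)
    r[valid] = (mz @ bz)[valid] / denom[valid]
    rs = r[valid]
    return {
        "population": population,
        "r": rs,
        "mean": float(rs.mean()) if rs.size else np.nan,
        "sd": float(rs.std(ddof=1)) if rs.size > 1 else np.nan,
        "n_skipped": int(n_draws - valid.sum()),
    }


def kmeans_population_check(
    cells: pd.DataFrame,
    k_range=range(2, 11),
    seed: int = 0,
    markers: tuple[str, ...] = MARKERS,
    ari_k: int = 7,
) -> pd.DataFrame:
    """K-means sweep over the number of macrophage populations.

    Clusters z-scored marker vectors of macrophage-labelled cells for each k
    (10 restarts, seeded), reporting within-cluster sum of squares and the
    silhouette coefficient, plus the adjusted Rand agreement between the
    k = *ari_k* clustering and the gate labels.
    """
    tam = cells[cells["phenotype"].isin(TAM_LABELS)]
    kmax = max(k_range)
    if len(tam) < kmax:
        raise ConfigError(f"k up to {kmax} requested but only {len(tam)} macrophages present")
    x = np.log1p(tam[list(markers)].to_numpy(dtype=float))
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    rows = []
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        sil = float(silhouette_score(x, km.labels_)) if 1 < k < len(x) else np.nan
        ari = (
            float(adjusted_rand_score(tam["phenotype"].to_numpy(), km.labels_))
            if k == ari_k
            else np.nan
        )
        rows.append({"k": k, "inertia": float(km.inertia_), "silhouette": sil, "ari_vs_gate": ari})
    return pd.DataFrame(rows)
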