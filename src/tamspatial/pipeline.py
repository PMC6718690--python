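"""Stage-chained analysis pipeline with a reproducibility manifest.

Stages run in dependency order::

    simulate -> phenotype -> density -> distance -> gradient -> pdl1
             -> signature -> survive

Inputs come either from a synthetic study (``synthetic:`` block, a
:class:`~tamspatial.simulate.SimulationConfig` override mapping) or from
files (``inputs:`` block with cell-table / expression / survival paths).
Every requested stage writes tidy CSV artifacts into the output directory;
a ``manifest.json`` records the package version, seed, a hash of the
resolved configuration and the SHA-256 of every artifact, so two runs with
the same configuration and seed are byte-identical.

All randomness flows from the single configured seed; no stage reads
ambient entropy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DependencyError
from . import cohort as cohort_mod
from . import gradient as gradient_mod
from . import io_tables
from . import phenotype as phenotype_mod
from . import simulate as simulate_mod
from . import spatial as spatial_mod

STAGES: tuple[str, ...] = (
    "simulate",
    "phenotype",
    "density",
    "distance",
    "gradient",
    "pdl1",
    "signature",
    "survive",
)

DEFAULT_PARAMS: dict = {
    "contact_radius": 10.0,
    "bin_width": 10.0,
    "max_distance": 100.0,
    "n_per_side": 500,
    "alpha": 0.05,
    "alpha_refined": 0.001,
    "n_per_patient": 10_000,
    "n_cohorts": 5,
    "top_percent": 1.0,
    "gradient_markers": ["CD68", "CD163", "CD206", "PDL1"],
    "distance_target": "Tumor",
    "roi": "core",
    "threshold_method": "gmm2",
}


def simulation_config_from_dict(d: dict) -> simulate_mod.SimulationConfig:
    """Build a SimulationConfig from a plain override mapping."""
    d = dict(d)
    if "expression" in d and isinstance(d["expression"], dict):
        d["expression"] = simulate_mod.ExpressionParams(**d["expression"])
    if "survival" in d and isinstance(d["survival"], dict):
        d["survival"] = simulate_mod.SurvivalParams(**d["survival"])
    if "interface_gradients" in d:
        d["interface_gradients"] = tuple(
            g if isinstance(g, simulate_mod.GradientSpec) else simulate_mod.GradientSpec(**g)
            for g in d["interface_gradients"]
        )
    valid = {f.name for f in dataclasses.fields(simulate_mod.SimulationConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigError(f"unknown synthetic config key(s): {sorted(unknown)}")
    return simulate_mod.SimulationConfig(**d)


def _canonical_config(config: dict) -> str:
    return json.dumps(config, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the requested stages and return the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    stages = config.get("stages", ["all"])
    if stages == ["all"] or stages == "all":
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    synthetic = config.get("synthetic")
    inputs = config.get("inputs", {})
    artifacts: list[Path] = []
    log: list[str] = []

    cells = None
    image_areas: dict[str, float] | None = None
    expression = None
    survival_records = None
    sim_config = None
    density_all = None
    density_comp = None

    if synthetic is not None:
        syn = dict(synthetic)
        syn.setdefault("seed", seed)
        sim_config = simulation_config_from_dict(syn)
    if "simulate" in stages:
        if sim_config is None:
            raise DependencyError("stage 'simulate' requires a 'synthetic' config block")
        data = simulate_mod.generate_cohort(sim_config)
        cells, image_areas = data.cells, data.image_areas
        path = out / "cells.csv"
        io_tables.write_cell_table(cells, path)
        artifacts.append(path)
        areas = pd.DataFrame(
            sorted(image_areas.items()), columns=["image_id", "area_mm2"]
        )
        path = out / "image_areas.csv"
        areas.to_csv(path, index=False)
        artifacts.append(path)
        log.append(f"simulate: {len(cells)} cells, {cells['patient_id'].nunique()} patients")
    elif any(s in stages for s in STAGES[1:]):
        if "cells" not in inputs:
            raise DependencyError("downstream stages need 'inputs: cells' or a simulate stage")
        cells = io_tables.read_cell_table(inputs["cells"])
        if "image_areas" in inputs:
            areas = pd.read_csv(inputs["image_areas"])
            image_areas = dict(zip(areas["image_id"], areas["area_mm2"].astype(float)))
        log.append(f"load: {len(cells)} cells from {inputs['cells']}")

    if "phenotype" in stages:
        if cells is None:
            raise DependencyError("stage 'phenotype' requires cells")
        norm_mode = "raw"
        work = phenotype_mod.normalize_intensity(cells, norm_mode)
        gating = phenotype_mod.estimate_thresholds(
            work, method=params["threshold_method"], seed=seed
        )
        cells = cells.copy()
        cells["phenotype"] = phenotype_mod.classify_cells(work, gating).to_numpy()
        path = out / "cells_labelled.csv"
        io_tables.write_cell_table(cells, path)
        artifacts.append(path)
        path = out / "gating.yaml"
        path.write_text(yaml.safe_dump(gating.to_dict(), sort_keys=True))
        artifacts.append(path)
        sig = phenotype_mod.population_signature(cells)
        path = out / "population_signature.csv"
        sig.to_csv(path)
        artifacts.append(path)
        log.append(
            "phenotype: " + ", ".join(
                f"{k}={v}" for k, v in cells["phenotype"].value_counts().items()
            )
        )

    need_labels = [s for s in ("density", "distance", "gradient", "pdl1", "signature", "survive") if s in stages]
    if need_labels and (cells is None or "phenotype" not in cells.columns):
        raise DependencyError(f"stage(s) {need_labels} require labelled cells (run 'phenotype')")

    if any(s in stages for s in ("density", "signature", "survive")):
        if image_areas is None:
            raise DependencyError("density computation requires image areas")
        density_all = spatial_mod.density_table(cells, image_areas, by_compartment=False)
        density_comp = spatial_mod.density_table(cells, image_areas, by_compartment=True)
    if "density" in stages:
        path = out / "density.csv"
        density_all.to_csv(path, index=False)
        artifacts.append(path)
        path = out / "density_by_compartment.csv"
        density_comp.to_csv(path, index=False)
        artifacts.append(path)
        log.append(f"density: {len(density_all)} strata rows")

    if "distance" in stages:
        target = params["distance_target"]
        med_rows, ep_rows, ed_rows = [], [], []
        core = cells[cells["roi"] == params["roi"]]
        patient_area = (
            core[["patient_id", "image_id"]].drop_duplicates()
            .assign(a=lambda d: d["image_id"].map(image_areas))
            .groupby("patient_id")["a"].sum()
            if image_areas
            else None
        )
        for pop in phenotype_mod.TAM_LABELS:
            per_cell = spatial_mod.nearest_distances_by_image(core, pop, target)
            if per_cell.empty:
                continue
            med = spatial_mod.median_distance_table(per_cell)
            med.insert(0, "population", pop)
            med_rows.append(med)
            for pid, grp in per_cell.groupby("patient_id", sort=False):
                ep = spatial_mod.effective_percentage(
                    grp["distance_um"], bin_width=params["bin_width"],
                    max_distance=params["max_distance"],
                )
                ep.insert(0, "population", pop)
                ep.insert(0, "patient_id", pid)
                ep_rows.append(ep)
                if patient_area is not None:
                    ed_rows.append(
                        {
                            "patient_id": pid,
                            "population": pop,
                            "effective_density": spatial_mod.effective_density(
                                grp["distance_um"],
                                area_mm2=float(patient_area.loc[pid]),
                                contact_radius=params["contact_radius"],
                            ),
                        }
                    )
        for name, frame in (
            ("median_distance.csv", pd.concat(med_rows, ignore_index=True) if med_rows else pd.DataFrame()),
            ("effective_percentage.csv", pd.concat(ep_rows, ignore_index=True) if ep_rows else pd.DataFrame()),
            ("effective_density.csv", pd.DataFrame(ed_rows)),
        ):
            path = out / name
            frame.to_csv(path, index=False)
            artifacts.append(path)
        log.append(f"distance: {sum(len(m) for m in med_rows)} patient medians vs {target}")

    if "gradient" in stages:
        core = cells[cells["roi"] == params["roi"]].copy()
        core["signed_distance_um"] = gradient_mod.signed_interface_distance_by_image(core)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            balanced = gradient_mod.sample_balanced_cohort(
                core.dropna(subset=["signed_distance_um"]),
                n_per_side=params["n_per_side"], seed=seed, mode="min_available",
            )
        profs = []
        for marker in params["gradient_markers"]:
            for pop in phenotype_mod.TAM_LABELS:
                prof = gradient_mod.gradient_profile(
                    balanced, marker, population=pop, bin_width=params["bin_width"]
                )
                if len(prof):
                    profs.append(prof)
        path = out / "gradient_profiles.csv"
        pd.concat(profs, ignore_index=True).to_csv(path, index=False)
        artifacts.append(path)
        log.append(f"gradient: {len(balanced)} balanced cells, {len(profs)} profiles")

    if "pdl1" in stages:
        cohorts = cohort_mod.build_pdl1_cohorts(
            cells, n_per_patient=params["n_per_patient"],
            n_cohorts=params["n_cohorts"], seed=seed,
        )
        rows, pat_rows = [], []
        for i, c in enumerate(cohorts):
            thr, _, frac = cohort_mod.pdl1_positivity(c)
            rows.append({"cohort": i, "threshold": thr, "fraction_positive": frac})
            flags = cohort_mod.pdl1_top_percent(c, params["top_percent"])
            pats = cohort_mod.classify_pdl1_high_patients(c, flags)
            pats.insert(0, "cohort", i)
            pat_rows.append(pats)
        path = out / "pdl1_positivity.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        artifacts.append(path)
        path = out / "pdl1_patients.csv"
        pd.concat(pat_rows, ignore_index=True).to_csv(path, index=False)
        artifacts.append(path)
        log.append(f"pdl1: {len(cohorts)} cohorts of {params['n_per_patient']} cells/patient")

    if "signature" in stages or "survive" in stages:
        if sim_config is not None:
            expression, linkage = simulate_mod.generate_expression(density_all, sim_config)
            path = out / "expression.tsv"
            io_tables.write_expression(expression, path)
            artifacts.append(path)
            path = out / "gene_linkage.csv"
            linkage.to_csv(path, index=False)
            artifacts.append(path)
        elif "expression" in inputs:
            expression = io_tables.read_expression(inputs["expression"])
        elif "signature" in stages:
            raise DependencyError("stage 'signature' requires expression input or a synthetic block")

    if "signature" in stages:
        sig_pops = (
            [sim_config.survival.population]
            if sim_config is not None
            else list(phenotype_mod.TAM_LABELS)
        )
        tables = []
        for pop in sig_pops:
            res = cohort_mod.environmental_signature(
                density_all, expression, pop,
                alpha=params["alpha"], alpha_refined=params["alpha_refined"],
                roi=params["roi"],
            )
            t = res.table.copy()
            t.insert(0, "population", pop)
            tables.append(t)
        path = out / "signatures.csv"
        pd.concat(tables, ignore_index=True).to_csv(path, index=False)
        artifacts.append(path)
        log.append(
            "signature: " + ", ".join(
                f"{t['population'].iloc[0]}:{int(t['in_signature'].sum())}" for t in tables
            )
        )

    if "survive" in stages:
        if sim_config is not None:
            survival_records, dens_used = simulate_mod.generate_survival(density_all, sim_config)
            sv_pop, sv_roi = sim_config.survival.population, sim_config.survival.roi
        elif "survival" in inputs:
            survival_records = io_tables.read_survival(inputs["survival"])
            sv_pop, sv_roi = params.get("survival_population", "CD68++CD163+"), params["roi"]
            dens_used = simulate_mod._density_vector(density_all, sv_pop, sv_roi)
        else:
            raise DependencyError("stage 'survive' requires survival input or a synthetic block")
        path = out / "survival.csv"
        io_tables.write_survival(survival_records, path)
        artifacts.append(path)
        terciles = cohort_mod.tercile_stratify(dens_used)
        curves, chi2, p = cohort_mod.km_logrank(survival_records, terciles, ("upper", "lower"))
        grp = terciles.rename("tercile").reset_index().rename(columns={"index": "patient_id"})
        path = out / "survival_groups.csv"
        grp.to_csv(path, index=False)
        artifacts.append(path)
        km = pd.concat(
            [c.assign(group=lab) for lab, c in curves.items()], ignore_index=True
        )
        path = out / "km_curves.csv"
        km.to_csv(path, index=False)
        artifacts.append(path)
        path = out / "logrank.csv"
        pd.DataFrame(
            [{"population": sv_pop, "roi": sv_roi, "chi2": chi2, "p": p}]
        ).to_csv(path, index=False)
        artifacts.append(path)
        log.append(f"survive: log-rank chi2={chi2:.3f} p={p:.4f} ({sv_pop}, upper vs lower tercile)")

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config_sha256": hashlib.sha256(_canonical_config(config).encode()).hexdigest(),
        "params": {k: params[k] for k in sorted(params)},
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
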