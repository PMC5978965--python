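"""File formats: cohort manifests, model JSON, curation logs, reports.

Everything is plain text — JSON for structured data, CSV/TSV for curves and
tables — and every file embeds a schema version and the digest of the
configuration that produced it, so runs are diffable and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .curation import CurationLog
from .dvh import write_dvh_csv
from .geometry import RegionThresholds
from .regression import LinearFit
from .simulate import (CohortConfig, OutlierSpec, QualityModel, RegimeSpec,
                       StructureSpec, SyntheticPlan, generate_cohort,
                       inject_outliers)
from .training import OverlapModel, PCABasis, StructureModel, TrainingDiagnostics
from .validation import ValidationReport

SCHEMA_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _dump(payload: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(payload), fh, sort_keys=True, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Cohort config round-trip
# ---------------------------------------------------------------------------

def cohort_config_to_dict(cfg: CohortConfig) -> dict:
    return _jsonable(cfg)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(
        n_plans=d["n_plans"], rx_gy=d["rx_gy"],
        target_volume_cc=d["target_volume_cc"],
        structures=tuple(StructureSpec(**s) for s in d["structures"]),
        regimes=tuple(RegimeSpec(**r) for r in d["regimes"]),
        quality=QualityModel(**d["quality"]),
        noise_sd=d["noise_sd"], falloff_sigma_mm=d["falloff_sigma_mm"],
        sparing_sigma_mm=d["sparing_sigma_mm"],
        sparing_floor=d["sparing_floor"],
        thresholds=RegionThresholds(**d["thresholds"]),
        seed=d["seed"], min_plans=d.get("min_plans", 20))


def outlier_spec_from_dict(d: dict) -> OutlierSpec:
    d = dict(d)
    for key in ("overlap_range", "bump_level_range"):
        if key in d:
            d[key] = tuple(d[key])
    return OutlierSpec(**d)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def write_cohort(out_dir, cohort_cfg: CohortConfig, run_cfg: RunConfig,
                 outlier_spec: OutlierSpec | None = None,
                 validation_fraction: float = 0.0) -> Path:
    """Simulate a cohort and write manifest + DVH CSVs + truth labels.

    Truth labels go to a separate file so the curation pipeline cannot
    peek; the manifest embeds the generator provenance (config + spec +
    seed) which is what ``load_cohort`` uses to rebuild voxel data.
    Returns the manifest path.
    """
    from .curation import make_grid
    from .dvh import dvh_from_doses_on_grid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plans = generate_cohort(cohort_cfg)
    if outlier_spec is not None and outlier_spec.total() > 0:
        plans = inject_outliers(plans, outlier_spec, cohort_cfg)
    grid = make_grid(cohort_cfg, run_cfg)

    n_val = int(round(validation_fraction * len(plans)))
    splits = {p.plan_id: ("validation" if i >= len(plans) - n_val else "training")
              for i, p in enumerate(plans)}

    entries = []
    for p in plans:
        structs = {}
        for name, ss in p.structures.items():
            csv_name = f"dvh_{p.plan_id}_{name}.csv"
            write_dvh_csv(out_dir / csv_name,
                          dvh_from_doses_on_grid(ss.achieved_dose_gy, grid))
            from .geometry import (compute_scalar_features, expected_dose,
                                   partition_regions)
            geom = ss.geometry(cohort_cfg)
            e = expected_dose(geom, cohort_cfg.falloff_sigma_mm,
                              cohort_cfg.thresholds)
            part = partition_regions(e, geom.in_target, cohort_cfg.rx_gy,
                                     cohort_cfg.thresholds)
            feats = compute_scalar_features(geom, part)
            structs[name] = {"dvh_csv": csv_name,
                             "features": feats.as_dict(),
                             "region_fractions": part.fractions}
        entries.append({"plan_id": p.plan_id, "rx_gy": p.rx_gy,
                        "split": splits[p.plan_id], "structures": structs})

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_digest": run_cfg.digest(),
        "cohort_config": cohort_config_to_dict(cohort_cfg),
        "outlier_spec": _jsonable(outlier_spec) if outlier_spec else None,
        "plans": entries,
    }
    _dump(manifest, out_dir / "manifest.json")
    _dump({"schema_version": SCHEMA_VERSION,
           "labels": {p.plan_id: {"outlier_category": p.outlier_category,
                                  "cluster_id": p.cluster_id,
                                  "quality": p.q}
                      for p in plans}},
          out_dir / "truth_labels.json")
    return out_dir / "manifest.json"


def load_cohort(manifest_path):
    """Load a cohort manifest; returns (cohort_cfg, plans, split dict).

    Voxel-level data are rebuilt deterministically from the embedded
    generator provenance; the manifest's files and invariants (unique plan
    ids, referenced CSVs present) are validated first.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        m = json.load(fh)
    for field in ("schema_version", "cohort_config", "plans"):
        if field not in m:
            raise ValueError(f"manifest missing required field '{field}'")
    ids = [p["plan_id"] for p in m["plans"]]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate plan_id in manifest: {dup}")
    base = manifest_path.parent
    for p in m["plans"]:
        if "split" not in p:
            raise ValueError(f"plan {p['plan_id']}: missing 'split'")
        for name, s in p["structures"].items():
            path = base / s["dvh_csv"]
            if not path.exists():
                raise FileNotFoundError(f"referenced DVH CSV missing: {path}")
    cohort_cfg = cohort_config_from_dict(m["cohort_config"])
    plans = generate_cohort(cohort_cfg)
    if m.get("outlier_spec"):
        plans = inject_outliers(plans, outlier_spec_from_dict(m["outlier_spec"]),
                                cohort_cfg)
    split = {p["plan_id"]: p["split"] for p in m["plans"]}
    keep = set(split)
    plans = [p for p in plans if p.plan_id in keep]
    return cohort_cfg, plans, split


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

def _basis_payload(b: PCABasis, n_rows: int) -> dict:
    return {"mean": b.mean, "eigenvectors": b.eigenvectors[:n_rows],
            "eigenvalues": b.eigenvalues, "n_components": b.n_components}


def _basis_from(d: dict) -> PCABasis:
    return PCABasis(mean=np.array(d["mean"]),
                    eigenvectors=np.array(d["eigenvectors"]),
                    eigenvalues=np.array(d["eigenvalues"]),
                    n_components=int(d["n_components"]))


def save_model(model: StructureModel, path, run_cfg: RunConfig | None = None) -> None:
    from .training import _ged_candidate_count

    fits = []
    for f in model.pc_fits:
        fits.append({"terms": f.terms, "coef": f.coef, "s2": f.s2,
                     "sse": f.sse, "sst": f.sst, "n": f.n, "p": f.p,
                     "xtx_inv": f.xtx_inv,
                     "flagged_terms": f.flagged_terms})
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": run_cfg.as_dict() if run_cfg else None,
        "config_digest": run_cfg.digest() if run_cfg else None,
        "structure": model.structure,
        "grid": {"bin_width_gy": float(model.grid[1] - model.grid[0]),
                 "n_bins": int(model.grid.size)},
        "dvh_basis": _basis_payload(model.dvh_basis, model.dvh_basis.n_components),
        "ged_basis": _basis_payload(model.ged_basis,
                                    _ged_candidate_count(model.ged_basis)),
        "overlap_model": ({"mean_curve": model.overlap_model.mean_curve,
                           "sd_curve": model.overlap_model.sd_curve}
                          if model.overlap_model else None),
        "pc_fits": fits,
        "predictor_names": model.predictor_names,
        "predictor_matrix": model.predictor_matrix,
        "dvh_scores": model.dvh_scores,
        "case_ids": model.case_ids,
        "transmission_dose_gy": model.transmission_dose_gy,
        "rx_gy": model.rx_gy,
        "diagnostics": {"r_squared": model.diagnostics.r_squared,
                        "chi_squared": model.diagnostics.chi_squared},
    }
    _dump(payload, path)


def load_model(path) -> StructureModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema_version {d.get('schema_version')}")
    g = d["grid"]
    grid = np.arange(g["n_bins"], dtype=float) * g["bin_width_gy"]
    fits = []
    for f in d["pc_fits"]:
        n = int(f["n"])
        fits.append(LinearFit(
            terms=list(f["terms"]), coef=np.array(f["coef"]),
            fitted=np.zeros(n), residuals=np.zeros(n),
            hat_diag=np.zeros(n), s2=float(f["s2"]), sse=float(f["sse"]),
            sst=float(f["sst"]), n=n, p=int(f["p"]),
            xtx_inv=np.array(f["xtx_inv"]),
            flagged_terms=list(f.get("flagged_terms", []))))
    om = d.get("overlap_model")
    n_cases = len(d["case_ids"])
    k = int(d["dvh_basis"]["n_components"])
    diag = TrainingDiagnostics(
        case_ids=list(d["case_ids"]),
        r_squared=float(d["diagnostics"]["r_squared"]),
        chi_squared=float(d["diagnostics"]["chi_squared"]),
        per_pc_r_squared=[], per_pc_chi_squared=[],
        cooks=np.zeros((n_cases, k)), studentized=np.zeros((n_cases, k)),
        leverage=np.zeros((n_cases, k)))
    return StructureModel(
        structure=d["structure"], grid=grid,
        dvh_basis=_basis_from(d["dvh_basis"]),
        ged_basis=_basis_from(d["ged_basis"]),
        overlap_model=(OverlapModel(mean_curve=np.array(om["mean_curve"]),
                                    sd_curve=np.array(om["sd_curve"]))
                       if om else None),
        pc_fits=fits, predictor_names=list(d["predictor_names"]),
        predictor_matrix=np.array(d["predictor_matrix"]),
        dvh_scores=np.array(d["dvh_scores"]), case_ids=list(d["case_ids"]),
        diagnostics=diag,
        transmission_dose_gy=float(d["transmission_dose_gy"]),
        rx_gy=float(d["rx_gy"]))


# ---------------------------------------------------------------------------
# Curation log, reports, scatter export
# ---------------------------------------------------------------------------

def save_curation_log(log: CurationLog, path, run_cfg: RunConfig | None = None) -> None:
    payload = {"schema_version": SCHEMA_VERSION,
               "config": run_cfg.as_dict() if run_cfg else None,
               "config_digest": run_cfg.digest() if run_cfg else None,
               "structure": log.structure,
               "cluster_k": log.cluster_k,
               "cluster_policy": log.cluster_policy,
               "warnings": log.warnings,
               "iterations": log.iterations}
    _dump(payload, path)


def format_curation_report(log_payload: dict) -> str:
    """Human-readable text rendering of a curation-log JSON payload."""
    lines = [f"Curation report — structure: {log_payload['structure']}",
             f"cluster check: k={log_payload['cluster_k']} "
             f"(policy: {log_payload['cluster_policy']})"]
    for w in log_payload.get("warnings", []):
        lines.append(f"warning: {w}")
    for it in log_payload["iterations"]:
        lines.append(
            f"iteration {it['iteration']}: n={it['n_cases']} "
            f"R2={it['r_squared']:.3f} chi2={it['chi_squared']:.3f} "
            f"maxCook={it['max_cooks']:.2f} flags={it['n_flags']}")
        for a in it.get("actions", []):
            lines.append(f"  {a['plan_id']}: {a['category'] or 'none'} -> "
                         f"{a['action']} ({a['rationale']})")
    return "\n".join(lines) + "\n"


def write_validation_report(report: ValidationReport, csv_path, json_path=None) -> None:
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write("structure,metric,mean,sem,n,frac_within_6,frac_within_10\n")
        for metric in report.mean:
            fh.write(f"{report.structure},{metric},{report.mean[metric]:.6g},"
                     f"{report.sem[metric]:.6g},{report.n},"
                     f"{report.frac_within_6:.6g},{report.frac_within_10:.6g}\n")
    if json_path:
        _dump({"schema_version": SCHEMA_VERSION, **report.as_dict()}, json_path)


def write_scatter_tsvs(model: StructureModel, out_dir) -> list:
    """One TSV per (PC, predictor): points plus line and SD-band parameters."""
    from .training import export_scatter_data

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sc in export_scatter_data(model):
        name = f"scatter_{model.structure}_pc{sc['pc']}_{sc['predictor']}.tsv"
        path = out_dir / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# slope={sc['slope']!r} intercept={sc['intercept']!r} "
                     f"sd={sc['sd']!r} flagged={sc['flagged']}\n")
            fh.write("case_id\tx\ty\tfitted\n")
            for cid, x, y in zip(sc["case_ids"], sc["x"], sc["y"]):
                fitted = sc["intercept"] + sc["slope"] * x
                fh.write(f"{cid}\t{x!r}\t{y!r}\t{fitted!r}\n")
        paths.append(path)
    return paths
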