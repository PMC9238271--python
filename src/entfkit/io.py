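"""Typed CSV readers/writers, run configuration, and the pipeline driver.

CSV dialect: comma-separated, dot decimals, one header row.  Numbers
with locale decimal commas are rejected with the offending row and
column named.  Residue positions are 1-based everywhere in I/O.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import alascan, alignment, detection, kinetics, peptides, qpcr, synthetic
from .defaults import DEFAULTS

__all__ = [
    "SchemaError",
    "read_timecourses",
    "write_timecourses",
    "read_blots",
    "write_blots",
    "read_records",
    "write_records",
    "read_cq",
    "write_cq",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("entfkit")


class SchemaError(ValueError):
    """A table does not match the expected schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _to_float(df: pd.DataFrame, column: str, path) -> np.ndarray:
    out = np.empty(len(df), dtype=float)
    for i, v in enumerate(df[column]):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            raise SchemaError(
                f"{path}: row {i + 1}, column {column!r}: "
                f"malformed number {v!r} (dot-decimal required)"
            ) from None
    return out


def read_timecourses(path: str | Path) -> list[kinetics.TimeCourse]:
    """Read time courses (columns: replicate, time_min, value, unit)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["replicate", "time_min", "value", "unit"], path)
    df = df.assign(
        time_min=_to_float(df, "time_min", path), value=_to_float(df, "value", path)
    )
    out = []
    for (rep, unit), grp in df.groupby(["replicate", "unit"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(kinetics.TimeCourse(
            tuple(grp["time_min"]), tuple(grp["value"]),
            unit=str(unit), replicate=str(rep),
        ))
    return out


def write_timecourses(tcs: Sequence[kinetics.TimeCourse], path: str | Path) -> None:
    rows = [
        {"replicate": tc.replicate, "time_min": t, "value": v, "unit": tc.unit}
        for tc in tcs
        for t, v in zip(tc.times, tc.responses)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_blots(path: str | Path) -> list[alascan.BlotMeasurement]:
    """Read blot lanes (columns: group, intensity, total_protein)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["group", "intensity", "total_protein"], path)
    inten = _to_float(df, "intensity", path)
    prot = _to_float(df, "total_protein", path)
    return [
        alascan.BlotMeasurement(group=str(g), intensity=i, total_protein=p)
        for g, i, p in zip(df["group"], inten, prot)
    ]


def write_blots(blots: Sequence[alascan.BlotMeasurement], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(b) for b in blots]).to_csv(path, index=False)


_RECORD_COLUMNS = [
    "method", "rt_min", "quantifier_area", "qualifier_area",
    "quantifier_sn", "qualifier_sn", "concentration_pm",
    "daughter_mzs", "isotope_mzs",
]


def _parse_mz_list(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(float(x) for x in str(cell).split(";"))


def read_records(path: str | Path) -> list[detection.ChromFeatureRecord]:
    """Read detection records; m/z lists are semicolon-separated cells."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["method", "rt_min"], path)
    records = []
    for i, row in df.iterrows():
        def num(col, default=0.0):
            if col not in df.columns or pd.isna(row[col]) or row[col] == "":
                return default
            try:
                return float(row[col])
            except ValueError:
                raise SchemaError(
                    f"{path}: row {i + 1}, column {col!r}: malformed number {row[col]!r}"
                ) from None
        records.append(detection.ChromFeatureRecord(
            method=str(row["method"]), retention_time=num("rt_min"),
            quantifier_area=num("quantifier_area"),
            qualifier_area=num("qualifier_area"),
            quantifier_sn=num("quantifier_sn"), qualifier_sn=num("qualifier_sn"),
            concentration_pm=num("concentration_pm", default=None),
            daughter_mzs=_parse_mz_list(row.get("daughter_mzs")),
            isotope_mzs=_parse_mz_list(row.get("isotope_mzs")),
        ))
    return records


def write_records(
    records: Sequence[detection.ChromFeatureRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["rt_min"] = d.pop("retention_time")
        d["daughter_mzs"] = ";".join(f"{m:.5f}" for m in r.daughter_mzs)
        d["isotope_mzs"] = ";".join(f"{m:.5f}" for m in r.isotope_mzs)
        rows.append(d)
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)


def read_cq(path: str | Path) -> list[qpcr.CqObservation]:
    """Read qPCR replicates (columns: sample, replicate, value, detected, lod)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["sample", "replicate", "value", "detected", "lod"], path)
    out = []
    for i, row in df.iterrows():
        detected = str(row["detected"]).strip().lower() in ("1", "true", "yes")
        lod = float(row["lod"])
        if detected:
            try:
                val = float(row["value"])
            except ValueError:
                raise SchemaError(
                    f"{path}: row {i + 1}, column 'value': malformed number"
                ) from None
            out.append(qpcr.CqObservation(cq=val, censored=False,
                                          lod_log10_copies=lod))
        else:
            out.append(qpcr.CqObservation(cq=None, censored=True,
                                          lod_log10_copies=lod))
    return out


def write_cq(obs: Sequence[qpcr.CqObservation], path: str | Path,
             sample: str = "sample1") -> None:
    rows = [
        {
            "sample": sample, "replicate": i + 1,
            "value": "" if o.censored else o.cq,
            "detected": not o.censored, "lod": o.lod_log10_copies,
        }
        for i, o in enumerate(obs)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline driver


@dataclass
class RunConfig:
    """Seed, output directory, stage list, and method-constant overrides."""

    seed: int = 0
    out_dir: str = "entfkit_run"
    stages: tuple[str, ...] = (
        "fragments", "detection", "formation", "papp", "exposure",
        "alascan", "qpcr",
    )
    constants: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULTS)))
    input_paths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**{k: v for k, v in data.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise SchemaError(f"unknown stage(s): {sorted(unknown)}")
        for name, p in self.input_paths.items():
            if not Path(p).exists():
                raise SchemaError(f"input path for {name!r} does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_fragments(cfg: RunConfig, out: Path) -> dict:
    pep = peptides.ENTF_STAR
    ions = {
        f"{series}{idx}": round(peptides.fragment_mz(pep, series, idx), 2)
        for series, idx in (("b", 2), ("b", 3), ("y", 11), ("y", 12))
    }
    (out / "fragments.json").write_text(json.dumps(ions, indent=2))
    return {"peptide": pep.name, "ions": ions}


def _stage_detection(cfg: RunConfig, out: Path) -> dict:
    if "records" in cfg.input_paths:
        records = read_records(cfg.input_paths["records"])
    else:
        records = synthetic.gen_chrom_records(cfg.seed, n=20, method="LC1MS1")
    results = [detection.classify_lowres(r) if r.method in detection.LOWRES_METHODS
               else detection.classify_highres(
                   r, reference_daughters=synthetic._entfstar_reference_ions()[0],
                   reference_isotopes=synthetic._entfstar_reference_ions()[1])
               for r in records]
    rows = [
        {"index": i, "method": r.method, "positive": res.positive,
         "failed_rules": ";".join(sorted(res.failed_rules))}
        for i, (r, res) in enumerate(zip(records, results))
    ]
    pd.DataFrame(rows).to_csv(out / "verdicts.csv", index=False)
    return {"n_records": len(records),
            "n_positive": sum(r.positive for r in results)}


def _stage_formation(cfg: RunConfig, out: Path) -> dict:
    if "formation" in cfg.input_paths:
        tcs = read_timecourses(cfg.input_paths["formation"])
    else:
        tcs = synthetic.gen_metabolization(cfg.seed)
    rates = [kinetics.fit_formation(tc).rate for tc in tcs]
    write_timecourses(tcs, out / "formation_timecourses.csv")
    return {"n": len(rates), "mean_rate_pct_per_min": float(np.mean(rates)),
            "sem": float(np.std(rates, ddof=1) / np.sqrt(len(rates)))}


def _stage_papp(cfg: RunConfig, out: Path) -> dict:
    kc = cfg.constants["kinetics"]
    if "transwell" in cfg.input_paths:
        tcs = read_timecourses(cfg.input_paths["transwell"])
    else:
        tcs = synthetic.gen_transwell(cfg.seed)
    papps = [
        kinetics.fit_papp(
            tc, area_cm2=kc["transwell_area_cm2"],
            c0_mol_per_cm3=kc["donor_conc_mol_per_cm3"],
            sample_volume_ul=kc["sample_volume_ul"],
            receiver_volume_ul=kc["receiver_volume_ul"],
        ).papp
        for tc in tcs
    ]
    write_timecourses(tcs, out / "transwell_timecourses.csv")
    return {"n": len(papps), "mean_papp_cm_per_s": float(np.mean(papps))}


def _stage_exposure(cfg: RunConfig, out: Path) -> dict:
    kc = cfg.constants["kinetics"]
    tc = (read_timecourses(cfg.input_paths["pk"])[0]
          if "pk" in cfg.input_paths else synthetic.gen_pk_profile(cfg.seed))
    profile = kinetics.fit_biexponential(tc, breakpoint=kc["pk_breakpoint_min"])
    expo = kinetics.exposure(profile, kc["exposure_window_min"])
    ratio = kinetics.exposure_ratio(
        profile, kc["endogenous_conc_nm"], kc["exposure_window_min"]
    )
    write_timecourses([tc], out / "pk_timecourse.csv")
    return {"exposure_nm_min": expo, "fold_over_endogenous": ratio}


def _stage_alascan(cfg: RunConfig, out: Path) -> dict:
    blots = (read_blots(cfg.input_paths["blots"])
             if "blots" in cfg.input_paths else synthetic.gen_blots(cfg.seed))
    ac = cfg.constants["alascan"]
    ranking = alascan.scan_pipeline(blots, k=ac["k_classes"], scale=ac["scale"])
    payload = {
        "scores": {str(p): s for p, s in ranking.scores.items()},
        "classes": {str(p): c for p, c in ranking.classes.items()},
        "multipliers": {str(p): m for p, m in ranking.multipliers.items()},
        "jenks_disagreement": list(ranking.jenks_disagreement),
    }
    (out / "ranking.json").write_text(json.dumps(payload, indent=2))
    return {"class1": sorted(ranking.positions_in_class(1)),
            "class2": sorted(ranking.positions_in_class(2))}


def _stage_qpcr(cfg: RunConfig, out: Path) -> dict:
    obs = (read_cq(cfg.input_paths["cq"])
           if "cq" in cfg.input_paths else synthetic.gen_cq(cfg.seed, n=24))
    fit = qpcr.censored_ml(obs)
    return {"mean_log10_copies": fit.mean, "sd_log10_copies": fit.sd,
            "n_censored": fit.n_censored, "converged": fit.converged}


_STAGES = {
    "fragments": _stage_fragments,
    "detection": _stage_detection,
    "formation": _stage_formation,
    "papp": _stage_papp,
    "exposure": _stage_exposure,
    "alascan": _stage_alascan,
    "qpcr": _stage_qpcr,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Pre-flight validates the config (unknown stages, missing inputs)
    before any stage runs; a stage failure aborts with the failing stage
    named.  Identical configs give identical numeric outputs.
    """
    from importlib.metadata import version

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "package_version": version("entfkit"),
        "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                   for k, p in cfg.input_paths.items()},
        "stages": {},
        "complete": False,
    }
    for stage in cfg.stages:
        logger.info("stage %s: start", stage)
        try:
            manifest["stages"][stage] = _STAGES[stage](cfg, out)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done", stage)
    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
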