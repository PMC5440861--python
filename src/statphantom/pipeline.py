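"""Study orchestration: template -> series -> deformation -> transport -> stats.

A study is a grid of (phantom x beam) cells driven by one YAML config and
one master seed.  Stage seeds are derived by hashing (master seed, stage
name, index), so e.g. adding beam energies never perturbs the phantom
geometry.  Results are flushed per cell and a study can resume from its
own partial results file; re-running an identical config reproduces
byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import grid as g
from . import io as vio
from . import materials as mat
from . import stats as st
from . import transport as tr
from .deform import DeformationPolicy, build_statistical_phantom
from .series import MassDistribution, plan_series, series_to_frame, spec_for_mass
from .template import TemplateConfig, build_template, validate_template

_FLOAT_FMT = "%.9g"


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


@dataclass
class BeamSection:
    energies: list[float] = field(default_factory=lambda: [1.0])
    geometries: list[str] = field(default_factory=lambda: ["AP"])
    histories: int = 100_000
    margin_cm: float = 5.0

    def __post_init__(self):
        for geom in self.geometries:
            if geom not in tr.GEOMETRIES:
                raise ValueError(f"unknown geometry {geom!r}; expected one of {tr.GEOMETRIES}")
        for e in self.energies:
            if not (0.01 <= e <= 20.0):
                raise ValueError(f"beam energy {e} MeV outside [0.01, 20]")
        if self.histories < 1:
            raise ValueError("histories must be >= 1")


@dataclass
class StudyConfig:
    seed: int = 0
    output_dir: str = "study_out"
    checkpoint: bool = True
    write_phantoms: bool = False
    template: TemplateConfig = field(default_factory=TemplateConfig)
    population: MassDistribution = field(default_factory=MassDistribution)
    policy: DeformationPolicy = field(default_factory=DeformationPolicy)
    beam: BeamSection = field(default_factory=BeamSection)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        known = {"seed", "output_dir", "checkpoint", "write_phantoms",
                 "template", "population", "deformation", "beam"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)} "
                             f"(expected a subset of {sorted(known)})")
        seed = int(data.get("seed", 0))
        tpl_kw = dict(data.get("template", {}))
        if "spacing" in tpl_kw:
            tpl_kw["spacing"] = tuple(tpl_kw["spacing"])
        tpl_kw.setdefault("seed", derive_seed(seed, "template"))
        pop_kw = dict(data.get("population", {}))
        pop_kw.setdefault("seed", derive_seed(seed, "population"))
        try:
            return cls(
                seed=seed,
                output_dir=str(data.get("output_dir", "study_out")),
                checkpoint=bool(data.get("checkpoint", True)),
                write_phantoms=bool(data.get("write_phantoms", False)),
                template=TemplateConfig(**tpl_kw),
                population=MassDistribution(**pop_kw),
                policy=DeformationPolicy(**data.get("deformation", {})),
                beam=BeamSection(**data.get("beam", {})),
            )
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def canonical(self) -> str:
        payload = {
            "seed": self.seed,
            "template": asdict(self.template),
            "population": asdict(self.population),
            "deformation": asdict(self.policy),
            "beam": asdict(self.beam),
        }
        return json.dumps(payload, sort_keys=True, default=str)


def _beam_seed(cfg: StudyConfig, geometry: str, energy: float, index: int) -> int:
    return derive_seed(cfg.seed, f"beam:{geometry}:{energy!r}", index)


@dataclass
class StudyResult:
    output_dir: Path
    results: pd.DataFrame
    reports: pd.DataFrame
    manifest: dict


def run_study(config: StudyConfig, materials: mat.MaterialTable | None = None,
              progress: bool = False) -> StudyResult:
    """Execute the full study grid and write all result artifacts."""
    materials = materials or mat.default_materials()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "master_seed": config.seed,
        "template_seed": config.template.seed,
        "population_seed": config.population.seed,
        "n_phantoms": config.population.n,
        "cells_per_phantom": len(config.beam.energies) * len(config.beam.geometries),
    }

    template = build_template(config.template, materials)
    validation = validate_template(template, config.template, materials)
    validation.to_frame().to_csv(out / "template_validation.csv", index=False,
                                 float_format=_FLOAT_FMT)
    if not validation.passed:
        raise RuntimeError("template validation failed; see template_validation.csv")
    if config.write_phantoms:
        vio.write_volume(template, out / "template.nrrd")

    specs = plan_series(config.population)
    series_to_frame(specs).to_csv(out / "series_plan.csv", index=False,
                                  float_format=_FLOAT_FMT)

    results_path = out / "results.csv"
    columns = ["phantom_index", "geometry", "energy_MeV", "ladf_pGy_cm2",
               "rel_err", "lung_mass_g", "beam_seed"]
    done = set()
    rows = []
    if config.checkpoint and results_path.exists():
        prior = pd.read_csv(results_path)
        if list(prior.columns) == columns:
            rows = prior.to_dict("records")
            done = {(int(r["phantom_index"]), r["geometry"], float(r["energy_MeV"]))
                    for r in rows}

    prov_path = out / "provenance.jsonl"
    prov_records = []
    for spec in specs:
        cells = [(geom, e) for geom in config.beam.geometries
                 for e in config.beam.energies]
        todo = [(geom, e) for geom, e in cells
                if (spec.index, geom, e) not in done]
        if not todo:
            continue
        try:
            phantom, prov = build_statistical_phantom(template, spec,
                                                      config.policy, materials)
        except Exception as exc:  # noqa: BLE001 - stage failures are logged
            prov_records.append({"index": spec.index, "error": str(exc)})
            continue
        prov_records.append(prov.to_dict())
        if config.write_phantoms:
            vio.write_volume(phantom, out / f"phantom_{spec.index:03d}.nrrd")
        lung_mass = g.mass_of(phantom, g.LUNG_LABELS, materials)
        for geom, e in todo:
            seed = _beam_seed(config, geom, e, spec.index)
            beam = tr.BeamConfig(geometry=geom, energy_mev=e,
                                 histories=config.beam.histories, seed=seed,
                                 margin_cm=config.beam.margin_cm)
            res = tr.transport(phantom, materials, beam)
            rows.append({
                "phantom_index": spec.index, "geometry": geom, "energy_MeV": e,
                "ladf_pGy_cm2": res.lung_ladf, "rel_err": res.lung_rel_err,
                "lung_mass_g": lung_mass, "beam_seed": seed,
            })
            pd.DataFrame(rows, columns=columns).sort_values(
                ["phantom_index", "geometry", "energy_MeV"]).to_csv(
                results_path, index=False, float_format=_FLOAT_FMT)
        if progress:
            print(f"phantom {spec.index}: {len(todo)} cell(s) done")

    with open(prov_path, "w") as fh:
        for rec in prov_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    results = pd.read_csv(results_path) if results_path.exists() else pd.DataFrame(columns=columns)
    reports = []
    hist_rows = []
    for (geom, e), grp in results.groupby(["geometry", "energy_MeV"]):
        grp = grp.sort_values("phantom_index")
        doses = st.SeriesDoses(e, geom, grp["ladf_pGy_cm2"].to_numpy(),
                               grp["rel_err"].to_numpy())
        rep = st.summarize_series(doses)
        reports.append(rep)
        for lo, hi, c in zip(rep.hist_edges[:-1], rep.hist_edges[1:], rep.hist_counts):
            hist_rows.append({"geometry": geom, "energy_MeV": e,
                              "bin_lo": lo, "bin_hi": hi, "count": c})
    report_frame = st.reports_to_frame(reports)
    report_frame.to_csv(out / "uncertainty_report.csv", index=False,
                        float_format=_FLOAT_FMT)
    pd.DataFrame(hist_rows).to_csv(out / "histograms.csv", index=False,
                                   float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return StudyResult(out, results, report_frame, manifest)


def compare_modes(config: StudyConfig, mode_a: str = "organ_wins",
                  mode_b: str = "lung_wins",
                  materials: mat.MaterialTable | None = None) -> pd.DataFrame:
    """Largest-lung phantom under both overlap modes, identical beams.

    The largest lung is the population mean + 3 SD.  Returns one row per
    (geometry, energy) with both doses and the relative difference in
    percent of their mean.
    """
    materials = materials or mat.default_materials()
    template = build_template(config.template, materials)
    spec = spec_for_mass(config.population.mean_g + 3.0 * config.population.sd_g,
                         config.population)
    phantoms = {}
    for mode in (mode_a, mode_b):
        policy = DeformationPolicy(
            overlap_mode=mode, volume_tol=config.policy.volume_tol,
            max_iter=config.policy.max_iter,
            rib_coupling=config.policy.rib_coupling,
            vessel_adjustment=config.policy.vessel_adjustment)
        phantoms[mode], _ = build_statistical_phantom(template, spec, policy, materials)
    rows = []
    for geom in config.beam.geometries:
        for e in config.beam.energies:
            seed = _beam_seed(config, geom, e, spec.index)
            beam = tr.BeamConfig(geometry=geom, energy_mev=e,
                                 histories=config.beam.histories, seed=seed,
                                 margin_cm=config.beam.margin_cm)
            doses = {mode: tr.transport(ph, materials, beam).lung_ladf
                     for mode, ph in phantoms.items()}
            da, db = doses[mode_a], doses[mode_b]
            rows.append({
                "geometry": geom, "energy_MeV": e,
                f"ladf_{mode_a}": da, f"ladf_{mode_b}": db,
                "rel_diff_pct": 200.0 * abs(da - db) / (da + db),
            })
    return pd.DataFrame(rows)


def relabel_heart_liver(phantom: g.LabeledVolume) -> g.LabeledVolume:
    """Replace all heart and liver voxels with residual tissue."""
    out = phantom.copy()
    out.labels[np.isin(out.labels, [g.L_HEART, g.L_LIVER])] = g.L_RESIDUAL
    return out


def heart_liver_ablation(config: StudyConfig,
                         materials: mat.MaterialTable | None = None) -> pd.DataFrame:
    """Lung dose change when heart and liver become residual tissue.

    Runs the template with and without heart/liver under identical beams
    (same seed, for correlated sampling) and reports the relative change.
    """
    materials = materials or mat.default_materials()
    template = build_template(config.template, materials)
    ablated = relabel_heart_liver(template)
    rows = []
    for geom in config.beam.geometries:
        for e in config.beam.energies:
            seed = _beam_seed(config, geom, e, 0)
            beam = tr.BeamConfig(geometry=geom, energy_mev=e,
                                 histories=config.beam.histories, seed=seed,
                                 margin_cm=config.beam.margin_cm)
            d_with = tr.transport(template, materials, beam).lung_ladf
            d_without = tr.transport(ablated, materials, beam).lung_ladf
            rows.append({
                "geometry": geom, "energy_MeV": e,
                "ladf_with": d_with, "ladf_without": d_without,
                "rel_change_pct": 100.0 * abs(d_without - d_with) / d_with,
            })
    return pd.DataFrame(rows)
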