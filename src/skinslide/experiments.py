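"""End-to-end experiment drivers: single runs, the 12-run COF x skin-stiffness
sweep, the mesh-convergence study, and the dry-vs-wet factorial reduction.

A single simulation is configured by a :class:`RunConfig`; the sweep varies
the skin-mattress coefficient of friction over four levels (0.2, 0.4, 0.6,
0.8 — dry through wet interface) and the skin elastic modulus over three
(15.2, 50, 100 kPa — compliant young skin through stiff aged/diabetic skin),
a full 4 x 3 cross of 12 simulations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contact import ContactPair, ContactParams
from .fe import (FEModel, PlaneStrainMaterial, PlaneStressMaterial,
                 SolverSettings, solve_quasi_static)
from .geometry import (MaterialProps, MeshDensitySpec, RoiGeometry,
                       build_roi_mesh)
from .loading import BoundaryConditionSet, LoadCase
from .postprocess import extract_interface, extract_midline, summarize

__all__ = [
    "RunConfig",
    "TaguchiDesign",
    "ConvergenceReport",
    "FactorialReport",
    "run_simulation",
    "run_taguchi",
    "mesh_convergence_study",
    "factorial_effects",
    "load_config",
    "dump_config",
]

#: reference material table (skin modulus is the swept parameter)
SKIN_NU = 0.49
SKIN_DENSITY = 1100.0
SUBCUTIS = MaterialProps(elastic_modulus=2.0, poisson_ratio=0.48, density=971.0)
MATTRESS = MaterialProps(elastic_modulus=10.0, poisson_ratio=0.3, density=30.0)

COF_LEVELS = (0.2, 0.4, 0.6, 0.8)
E_SKIN_LEVELS = (15.2, 50.0, 100.0)

#: fraction of the skin thickness admitted as maximum penalty penetration
PENETRATION_FRACTION = 0.02


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one repositioning simulation."""

    mu: float = 0.2
    E_skin: float = 15.2
    geometry: RoiGeometry = field(default_factory=RoiGeometry)
    density: MeshDensitySpec = field(default_factory=MeshDensitySpec)
    load_case: LoadCase = field(default_factory=LoadCase)
    solver: SolverSettings = field(default_factory=SolverSettings)
    formulation: str = "plane_stress"  # or "plane_strain"

    def __post_init__(self) -> None:
        if self.formulation not in ("plane_stress", "plane_strain"):
            raise ValueError("formulation must be plane_stress or plane_strain")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TaguchiDesign:
    """The 12-run full cross of COF and skin-modulus levels.

    Rows are ordered COF-major (all three moduli at COF 0.2 first), the
    four COF levels being the reference 0.4 varied by -50%, +50% and +100%.
    """

    cof_levels: tuple = COF_LEVELS
    e_skin_levels: tuple = E_SKIN_LEVELS

    @property
    def runs(self) -> list[tuple[float, float]]:
        return [(mu, e) for mu in self.cof_levels for e in self.e_skin_levels]


@dataclass
class ConvergenceReport:
    levels: list[dict]  # per level: density label, skin elements, max stress
    converged: bool
    converged_level: int | None  # index into ``levels`` (the finer of the pair)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels)


@dataclass
class FactorialReport:
    """Dry (COF 0.2) vs wet (COF 0.8) interface shear, per skin modulus."""

    e_skin: list
    dry_shear: list
    wet_shear: list
    wet_dry_difference: list
    wet_dry_ratio: list
    difference_grows_with_stiffness: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "E_skin": self.e_skin, "dry_shear": self.dry_shear,
            "wet_shear": self.wet_shear,
            "wet_dry_difference": self.wet_dry_difference,
            "wet_dry_ratio": self.wet_dry_ratio,
        })


def _materials(config: RunConfig) -> dict[str, PlaneStressMaterial]:
    t = config.geometry.out_of_plane_thickness
    cls = (PlaneStrainMaterial if config.formulation == "plane_strain"
           else PlaneStressMaterial)
    return {
        "skin": cls(config.E_skin, SKIN_NU, t),
        "subcutis": cls(SUBCUTIS.elastic_modulus, SUBCUTIS.poisson_ratio, t),
        "mattress": cls(MATTRESS.elastic_modulus, MATTRESS.poisson_ratio, t),
    }


def _contact_params(config: RunConfig) -> ContactParams:
    # 25 x the softest contacting modulus per mm keeps penalty penetration
    # far below the admissible bound at this problem's kPa-scale contact
    # pressures while keeping the Newton iteration well-behaved; the
    # penetration check below raises it automatically if ever insufficient
    softest = min(config.E_skin, MATTRESS.elastic_modulus)
    kn = config.solver.penalty_normal or 25.0 * softest  # kPa per mm gap
    kt = config.solver.penalty_tangent or kn
    return ContactParams(
        penalty_normal=kn, penalty_tangent=kt,
        max_penetration_check=PENETRATION_FRACTION * config.geometry.skin_thickness,
    )


def _times(case: LoadCase, settings: SolverSettings) -> np.ndarray:
    t1 = np.linspace(0.0, case.t_phase1_end, settings.n_increments_phase1 + 1)[1:]
    t2 = np.linspace(case.t_phase1_end, case.t_end,
                     settings.n_increments_phase2 + 1)[1:]
    return np.concatenate([t1, t2])


def run_simulation(config: RunConfig, outdir: str | Path | None = None,
                   keep_history: bool = False):
    """Build the mesh, run both loading phases, and post-process.

    Returns ``(record, artifacts)``; ``artifacts`` holds the mesh, the final
    state, the midline/interface profiles, and the contact pair.  If the
    converged penalty penetration exceeds the admissible fraction of the
    skin thickness, the penalties are raised and the run repeated.
    """
    mesh = build_roi_mesh(config.geometry, config.density)
    model = FEModel(mesh, _materials(config))
    bcs = BoundaryConditionSet(mesh, config.load_case,
                               thickness=config.geometry.out_of_plane_thickness)
    times = _times(config.load_case, config.solver)
    params = _contact_params(config)

    for attempt in range(3):
        pair = ContactPair(
            mesh, mesh.node_sets["skin_bottom_boundary"],
            mesh.node_sets["mattress_top_edge"], config.mu, params,
            thickness=config.geometry.out_of_plane_thickness)
        result = solve_quasi_static(
            model, bcs.at_time, times, contact=pair, settings=config.solver,
            keep_history=keep_history)
        final = result[0] if keep_history else result
        pen = pair.max_penetration()
        if (params.max_penetration_check is None
                or pen <= params.max_penetration_check):
            break
        factor = max(2.0, 1.5 * pen / params.max_penetration_check)
        params = replace(params,
                         penalty_normal=params.penalty_normal * factor,
                         penalty_tangent=params.penalty_tangent * factor)
    record = summarize(final, mesh, config.mu, config.E_skin)
    record.extras["penalty_normal"] = params.penalty_normal
    record.extras["max_penetration"] = pen
    record.extras["n_elements"] = mesh.n_elements
    artifacts = {
        "mesh": mesh,
        "model": model,
        "final_state": final,
        "midline": extract_midline(final, mesh),
        "interface": extract_interface(final, mesh),
        "contact": pair,
    }
    if keep_history:
        artifacts["history"] = result[1]
    if outdir is not None:
        _write_run_artifacts(config, record, artifacts, Path(outdir))
    return record, artifacts


def _write_run_artifacts(config, record, artifacts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"mu{config.mu:g}_E{config.E_skin:g}"
    artifacts["midline"].to_frame().to_csv(
        outdir / f"midline_{tag}.csv", index=False)
    artifacts["interface"].to_frame().to_csv(
        outdir / f"interface_{tag}.csv", index=False)
    with open(outdir / f"summary_{tag}.json", "w") as f:
        json.dump(record.as_dict(), f, indent=1)


def run_taguchi(base: RunConfig, outdir: str | Path | None = None,
                cache_dir: str | Path | None = None,
                progress=None) -> pd.DataFrame:
    """Run the 12-simulation sweep; one row per run, in design order.

    Completed runs found in ``cache_dir`` (keyed by config hash) are reused.
    Failed runs are recorded with NaN maxima and an ``error`` note; the
    remaining runs continue.
    """
    design = TaguchiDesign()
    rows = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for k, (mu, e) in enumerate(design.runs, start=1):
        config = replace(base, mu=mu, E_skin=e)
        cfile = cache / f"{config.config_hash()}.json" if cache else None
        if cfile is not None and cfile.exists():
            row = json.loads(cfile.read_text())
        else:
            try:
                record, _ = run_simulation(config, outdir=outdir)
                row = record.as_dict()
            except Exception as exc:  # keep sweeping, report at the end
                row = {"mu": mu, "E_skin": e, "error": str(exc),
                       "max_skin_effective": np.nan,
                       "max_subcutis_effective": np.nan,
                       "max_interface_shear": np.nan,
                       "max_interface_effective": np.nan,
                       "extracted_at_time": np.nan}
            if cfile is not None and "error" not in row:
                cfile.write_text(json.dumps(row))
        row["simulation"] = k
        rows.append(row)
        if progress is not None:
            progress(k, len(design.runs), row)
    df = pd.DataFrame(rows)
    cols = ["simulation", "mu", "E_skin", "max_skin_effective",
            "max_subcutis_effective", "max_interface_shear",
            "max_interface_effective", "extracted_at_time"]
    df = df[cols + [c for c in df.columns if c not in cols]]
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(outdir) / "results.csv", index=False)
    return df


def density_ladder(n_levels: int = 3, finest: MeshDensitySpec = None
                   ) -> list[MeshDensitySpec]:
    """Dyadic ladder of density specs ending at ``finest`` (default: the
    production density), coarsening by ~4x elements per step."""
    finest = finest or MeshDensitySpec()
    out = []
    for k in range(n_levels - 1, -1, -1):
        f = 4 ** k
        out.append(MeshDensitySpec(
            max(2, finest.skin_target_elements // f),
            max(1, finest.subcutis_target_elements // f),
            max(4, finest.mattress_target_elements // f),
            finest.refinement_level,
        ))
    return out


def mesh_convergence_study(base: RunConfig, ladder=None,
                           criterion: float = 0.02) -> ConvergenceReport:
    """Refine the mesh at the worst case (highest COF) until the maximal
    midline skin effective stress changes by less than ``criterion``.

    ``ladder`` is an ascending list of :class:`MeshDensitySpec`.  The study
    stops at the first pair of successive levels within the criterion; the
    finer level of that pair is reported as the converged density.
    """
    if ladder is None:
        ladder = density_ladder()
    if len(ladder) < 2:
        raise ValueError("need at least 2 ladder levels")
    levels = []
    converged = False
    converged_level = None
    prev = None
    for i, density in enumerate(ladder):
        config = replace(base, mu=max(COF_LEVELS), density=density)
        record, arts = run_simulation(config)
        n_skin = len(arts["mesh"].element_sets["skin"])
        s = record.max_skin_effective
        rel = abs(s - prev) / abs(prev) if prev is not None else np.nan
        levels.append({
            "level": i, "skin_elements": n_skin,
            "n_elements": arts["mesh"].n_elements,
            "max_skin_effective": s, "relative_change": rel,
        })
        if prev is not None and rel < criterion:
            converged = True
            converged_level = i
            break
        prev = s
    return ConvergenceReport(levels=levels, converged=converged,
                             converged_level=converged_level)


def factorial_effects(table: pd.DataFrame) -> FactorialReport:
    """Dry-vs-wet reduction of the sweep table.

    For each skin modulus, extracts the maximal interface shear at the dry
    (lowest-COF) and wet (highest-COF) levels and their difference; reports
    whether the wet-dry difference grows with skin stiffness (the
    stiffness-moisture interaction).
    """
    mu_dry, mu_wet = min(COF_LEVELS), max(COF_LEVELS)
    e_levels = sorted(table["E_skin"].unique())
    dry, wet = [], []
    for e in e_levels:
        sel_d = table[(table.E_skin == e) & (table.mu == mu_dry)]
        sel_w = table[(table.E_skin == e) & (table.mu == mu_wet)]
        if sel_d.empty or sel_w.empty:
            raise ValueError(f"table is missing dry/wet rows for E_skin={e}")
        dry.append(float(sel_d["max_interface_shear"].iloc[0]))
        wet.append(float(sel_w["max_interface_shear"].iloc[0]))
    diff = [w - d for w, d in zip(wet, dry)]
    ratio = [w / d if d else np.inf for w, d in zip(wet, dry)]
    grows = all(b >= a - 1e-12 for a, b in zip(diff, diff[1:]))
    return FactorialReport(
        e_skin=list(e_levels), dry_shear=dry, wet_shear=wet,
        wet_dry_difference=diff, wet_dry_ratio=ratio,
        difference_grows_with_stiffness=bool(grows),
    )


# ---------------------------------------------------------------------------
# config file I/O


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(config), f, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    kwargs = {}
    if "mu" in raw:
        kwargs["mu"] = float(raw["mu"])
    if "E_skin" in raw:
        kwargs["E_skin"] = float(raw["E_skin"])
    if "formulation" in raw:
        kwargs["formulation"] = str(raw["formulation"])
    for key, cls in (("geometry", RoiGeometry), ("density", MeshDensitySpec),
                     ("load_case", LoadCase), ("solver", SolverSettings)):
        if key in raw and raw[key] is not None:
            kwargs[key] = cls(**raw[key])
    return RunConfig(**kwargs)
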