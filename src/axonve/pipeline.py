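"""Top-level pipeline: materials -> geometry -> synthesis -> fit -> effective -> damage.

Every stage writes its artifact into the output directory and records an
entry in the manifest; a stage failure marks the manifest and skips the
remaining stages.  All randomness flows from the single global seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import damage as damage_mod
from . import effective as effective_mod
from . import io as io_mod
from . import materials as materials_mod
from . import rve as rve_mod
from .fitting import PronyRelaxationModel, summarize_fits
from .synthetic import SyntheticConfig, generate_case
from .viscoelastic import LOAD_CASES

logger = logging.getLogger("axonve")

__all__ = ["PipelineConfig", "run_pipeline"]

_SECTIONS = {"materials", "geometry", "synthetic", "fit", "effective", "damage",
             "seed", "out_dir"}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested stage configurations plus the global seed."""

    materials: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    effective: dict = field(default_factory=dict)
    damage: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "axonve_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**io_mod.load_yaml_config(path, _SECTIONS))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}

    stages = [
        ("materials", _stage_materials),
        ("geometry", _stage_geometry),
        ("synthetic_fit", _stage_synth_fit),
        ("effective", _stage_effective),
        ("damage", _stage_damage),
    ]
    state: dict = {}
    failed = False
    for name, fn in stages:
        if failed:
            manifest["stages"][name] = "skipped"
            continue
        try:
            logger.info("stage %s", name)
            fn(cfg, out, state, manifest)
            manifest["stages"][name] = "ok"
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = f"failed: {exc}"
            failed = True
    io_mod.write_json(out / "manifest.json", manifest)
    return manifest


def _stage_materials(cfg, out, state, manifest) -> None:
    result = materials_mod.derive_tau_and_matrix(**cfg.materials)
    path = out / "materials.json"
    materials_mod.write_materials_json(path, result)
    state["materials"] = result
    manifest["outputs"]["materials"] = path.name


def _stage_geometry(cfg, out, state, manifest) -> None:
    rve_cfg = rve_mod.RVEConfig(**cfg.geometry)
    summary = rve_mod.summarize(rve_cfg)
    segments = rve_mod.build_rve(rve_cfg, seed=cfg.seed)
    geo = {
        "summary": summary.to_dict(),
        "segments": [
            {"type": s.kind, "p0": list(s.p0), "p1": list(s.p1),
             "r_outer": s.r_outer, "r_inner": s.r_inner}
            for s in segments
        ],
    }
    path = out / "geometry.json"
    io_mod.write_json(path, geo)
    state["rve_summary"] = summary
    manifest["outputs"]["geometry"] = path.name


def _stage_synth_fit(cfg, out, state, manifest) -> None:
    summary = state["rve_summary"]
    box = {"a1": summary.a1, "a2": summary.a2, "a3": summary.a3}
    syn = SyntheticConfig(box=box, seed=cfg.seed, **cfg.synthetic)
    n_obs = int(cfg.fit.get("n_observations", 2))
    n_terms = int(cfg.fit.get("n_terms", 2))
    results: dict[str, list] = {}
    for obs in range(n_obs):
        obs_cfg = syn.with_seed(cfg.seed + obs)
        for case in range(1, 7):
            fld = generate_case(obs_cfg, case)
            if obs == 0:
                path = out / f"case{case}.csv"
                io_mod.write_element_field_csv(
                    path, fld,
                    {"load_case": case,
                     "eps_star": obs_cfg.loading(case).eps_star})
                manifest["outputs"][f"case{case}"] = path.name
            loading = obs_cfg.loading(case)
            for label, comp in LOAD_CASES[case].fitted.items():
                model = PronyRelaxationModel.from_element_field(
                    fld, comp, loading, n_terms=n_terms)
                results.setdefault(label, []).append(
                    model.fit(seed=cfg.seed + obs))
    table = summarize_fits(results)
    path = out / "prony_coefficients.csv"
    table.to_csv(path)
    state["fit_table"] = table
    state["synthetic"] = syn
    manifest["outputs"]["prony_coefficients"] = path.name


def _stage_effective(cfg, out, state, manifest) -> None:
    kwargs = dict(cfg.effective)
    sweep = kwargs.pop("sweep_alpha_i", None)
    target = kwargs.pop("target_Pa", None)
    x = effective_mod.AxonCrossSection(**kwargs)
    result = {
        "fractions": x.fractions,
        "E1_reuss_Pa": effective_mod.reuss_transverse_modulus(x),
        "E1_voigt_Pa": effective_mod.voigt_transverse_modulus(x),
    }
    if sweep is not None:
        import numpy as np

        lo, hi, step = (float(v) for v in str(sweep).split(":"))
        grid = np.arange(lo, hi + step / 2, step)
        swept = effective_mod.sweep_alpha_i(x, grid, target=target)
        result["sweep"] = {"alpha_i": swept["alpha_i"].tolist(),
                           "E1_Pa": swept["E1"].tolist()}
        if "alpha_i_at_target" in swept:
            result["alpha_i_at_target"] = swept["alpha_i_at_target"]
    path = out / "effective.json"
    io_mod.write_json(path, result)
    manifest["outputs"]["effective"] = path.name


def _stage_damage(cfg, out, state, manifest) -> None:
    kwargs = dict(cfg.damage)
    rates = kwargs.pop("rates", damage_mod.DEFAULT_RATES)
    syn = state.get("synthetic") or SyntheticConfig(seed=cfg.seed)
    if kwargs:
        syn = replace(syn, **kwargs)
    table = damage_mod.rate_sweep(syn, rates=rates)
    path = out / "damage.csv"
    table.to_csv(path, index=False)
    manifest["outputs"]["damage"] = path.name
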