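"""End-to-end orchestration from a single structured config.

A run config (YAML or dict) selects stages and carries one parameter block
per module.  Stages execute in dependency order; every output file is
listed in a manifest with its SHA-256 checksum, the seeds used, and the
package version, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import yaml

from . import __version__
from . import leakage as leak_mod
from . import observables as obs_mod
from . import partition as part_mod
from . import pmf as pmf_mod
from . import saxs as saxs_mod
from . import syngen

logger = logging.getLogger("membranekit.workbench")

STAGE_ORDER = ["syngen", "partition", "leakage", "observables", "pmf", "saxs"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration."""

    stages: list
    params: dict
    seed: int
    outdir: str
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        stages = d.get("stages", STAGE_ORDER)
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "observables" in stages and "syngen" not in stages and "trajectory" not in d:
            raise ValueError("observables stage needs syngen or an input trajectory")
        return cls(
            stages=[s for s in STAGE_ORDER if s in stages],
            params={k: d.get(k, {}) or {} for k in STAGE_ORDER},
            seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", "membranekit_out")),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    # stable per-stage stream derived from the global seed
    return int(np.random.SeedSequence([seed, STAGE_ORDER.index(stage)]).generate_state(1)[0] % 2**31)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    artifacts: dict = {}
    marker = os.path.join(config.outdir, ".partial")
    with open(marker, "w") as fh:
        fh.write("run in progress\n")

    for stage in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, stage)
        logger.info("stage=%s seed=%d start", stage, seed)
        try:
            files = _STAGE_FUNCS[stage](config.params[stage], seed, config.outdir, artifacts)
        except Exception as exc:
            logger.error("stage=%s FAILED: %s", stage, exc)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {os.path.basename(f): _sha256(f) for f in files},
        }
        logger.info("stage=%s done files=%d", stage, len(files))

    mpath = os.path.join(config.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    os.remove(marker)
    return manifest


# ----------------------------------------------------------------------
# stage implementations
# ----------------------------------------------------------------------
def _stage_syngen(p: dict, seed: int, outdir: str, artifacts: dict) -> list:
    spec_kwargs = dict(p.get("bilayer", {}))
    spec_kwargs.setdefault("seed", seed)
    if "target_scd" in spec_kwargs:
        spec_kwargs["target_scd"] = tuple(spec_kwargs["target_scd"])
    spec = syngen.BilayerSpec(**spec_kwargs)
    traj = syngen.gen_bilayer_trajectory(spec)
    artifacts["trajectory"] = traj
    artifacts["bilayer_spec"] = spec
    path = os.path.join(outdir, "trajectory.tsv")
    traj.write_table(path)
    return [path]


def _stage_partition(p: dict, seed: int, outdir: str, artifacts: dict) -> list:
    x = p.get("x_values", [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
    data = syngen.gen_partition_data(
        r_sat=p.get("r_sat", 0.30),
        r_50=p.get("r_50", 1.2),
        x_values=x,
        noise_sd=p.get("noise_sd", 0.01),
        n_reps=p.get("n_reps", 3),
        seed=seed,
    )
    iso = part_mod.fit_isotherm(data, weighted=bool(p.get("weighted", False)))
    dpath = os.path.join(outdir, "partition_data.csv")
    data.to_csv(dpath)
    rpath = os.path.join(outdir, "partition_fit.json")
    with open(rpath, "w") as fh:
        json.dump(iso.to_dict(), fh, indent=2)
    artifacts["isotherm"] = iso
    return [dpath, rpath]


def _stage_leakage(p: dict, seed: int, outdir: str, artifacts: dict) -> list:
    t = np.linspace(0.0, p.get("t_max", 1200.0), int(p.get("n_points", 121)))
    files = []
    summaries = {}
    conditions = p.get(
        "conditions",
        {"baseline": 1.0, "anionic_enhanced": 2.0, "pe_protected": 0.5},
    )
    for label, modifier in conditions.items():
        params = syngen.LeakageSimParams(
            plateau_percent=p.get("plateau_percent", 60.0),
            rate_constant=p.get("rate_constant", 0.01),
            composition_modifier=float(modifier),
            noise_sd=p.get("noise_sd", 1.0),
            seed=seed,
            label=label,
        )
        trace = syngen.gen_leakage_trace(params, t)
        path = os.path.join(outdir, f"leakage_{label}.csv")
        trace.to_csv(path)
        files.append(path)
        s = leak_mod.summarize_trace(trace, t_report=p.get("t_report", t[-1] / 2))
        summaries[label] = {
            "extent_percent": s.extent_percent,
            "initial_rate_percent_per_s": s.initial_rate_percent_per_s,
            "plateau_percent": s.plateau_percent,
        }
    spath = os.path.join(outdir, "leakage_summary.json")
    with open(spath, "w") as fh:
        json.dump(summaries, fh, indent=2)
    files.append(spath)
    return files


def _stage_observables(p: dict, seed: int, outdir: str, artifacts: dict) -> list:
    traj = artifacts.get("trajectory")
    if traj is None:
        raise ValueError("no trajectory available; run the syngen stage first")
    spec = artifacts.get("bilayer_spec")
    n_leaf = spec.n_lipids_per_leaflet if spec else int(p.get("n_per_leaflet", 64))
    results = {}
    apl = obs_mod.area_per_lipid(traj, n_leaf)
    results["area_per_lipid_nm2"] = {"mean": apl.mean, "sd": apl.sd}
    th = obs_mod.membrane_thickness(traj)
    results["thickness_nm"] = {"mean": th.mean, "sd": th.sd}
    msd = obs_mod.lateral_diffusion(traj)
    results["diffusion_cm2_s"] = msd.d_coeff
    prof = obs_mod.order_parameters(traj)
    results["s_cd"] = {
        "carbon_index": prof.carbon_index.tolist(),
        "signed": prof.s_cd.tolist(),
        "chain_mean_abs": prof.chain_mean_abs,
    }
    if traj.select(role="SOLUTE").any():
        rep = obs_mod.cluster_stats(traj, cutoff=p.get("cluster_cutoff", 0.30))
        results["percent_monomers"] = rep.percent_monomers
    dens = obs_mod.density_profile(
        traj,
        groups=p.get(
            "density_groups",
            {"phosphate": "P", "carbonyl": "CARBONYL",
             "terminal_ch3": "TERMINAL_CH3", "solute": "SOLUTE"},
        ),
        bin_width=p.get("density_bin_width", 0.1),
        symmetrize=bool(p.get("symmetrize_density", True)),
    )
    dpath = os.path.join(outdir, "density_profile.csv")
    import pandas as pd

    pd.DataFrame({"z_nm": dens.z_centers, **{k: v for k, v in dens.density.items()}}).to_csv(
        dpath, index=False
    )
    rpath = os.path.join(outdir, "observables.json")
    with open(rpath, "w") as fh:
        json.dump(results, fh, indent=2)
    return [rpath, dpath]


def _stage_pmf(p: dict, seed: int, outdir: str, artifacts: dict) -> list:
    from .presets import gaussian_barrier_profile

    files = []
    barriers = {}
    scenarios = p.get("scenarios", {"popc_like": 6.8, "popc_cpt_like": 4.84})
    centers = np.arange(
        p.get("z_start", 0.0), p.get("z_stop", 4.0) + 1e-9, p.get("spacing", 0.1)
    )
    for label, barrier in scenarios.items():
        truth = gaussian_barrier_profile(
            barrier_kcal=float(barrier), width=p.get("width", 0.8)
        )
        windows = syngen.gen_umbrella_samples(
            truth, centers,
            k_spring=p.get("k_spring", 1000.0),
            n_per_window=int(p.get("n_per_window", 5000)),
            temperature=p.get("temperature", 298.0),
            seed=seed,
        )
        profile = pmf_mod.wham(windows, bin_width=p.get("bin_width", 0.05))
        profile = pmf_mod.symmetrize_profile(profile, center=0.0)
        b = pmf_mod.barrier_height(profile)
        barriers[label] = {"barrier_kcal_mol": b.height, "z_at_max_nm": b.z_at_max,
                           "truth_kcal_mol": float(barrier)}
        ppath = os.path.join(outdir, f"pmf_{label}.csv")
        profile.to_csv(ppath)
        files.append(ppath)
    bpath = os.path.join(outdir, "pmf_barriers.json")
    with open(bpath, "w") as fh:
        json.dump(barriers, fh, indent=2)
    files.append(bpath)
    return files


def _stage_saxs(p: dict, seed: int, outdir: str, artifacts: dict) -> list:
    d_true = p.get("d_spacing", 59.6)
    amplitude = p.get("amplitude", 100.0)
    curve = syngen.gen_scattering_curve(
        d=d_true,
        n_orders=int(p.get("n_orders", 3)),
        noise_sd=p.get("noise_frac", 0.02) * amplitude,
        amplitude=amplitude,
        seed=seed,
    )
    peaks = saxs_mod.find_reflections(curve, min_prominence=p.get("min_prominence", 0.05))
    idx = saxs_mod.index_lamellar(peaks)
    cpath = os.path.join(outdir, "scattering_curve.csv")
    curve.to_csv(cpath)
    rpath = os.path.join(outdir, "lamellar_indexing.json")
    with open(rpath, "w") as fh:
        json.dump(
            {
                "d_spacing_A": idx.d_spacing,
                "peak_positions_invA": idx.peak_positions.tolist(),
                "orders": idx.orders.tolist(),
                "ratio_residual": idx.ratio_residual,
                "is_lamellar": idx.is_lamellar,
                "d_true_A": d_true,
            },
            fh,
            indent=2,
        )
    return [cpath, rpath]


_STAGE_FUNCS = {
    "syngen": _stage_syngen,
    "partition": _stage_partition,
    "leakage": _stage_leakage,
    "observables": _stage_observables,
    "pmf": _stage_pmf,
    "saxs": _stage_saxs,
}
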