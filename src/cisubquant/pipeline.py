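"""End-to-end four-scenario phantom study orchestration.

Simulates the complete experiment: calibrated iodinated phantoms are
projected (with transmission Poisson noise), reconstructed with FBP and
SIRT on their own voxel grids, calibrated to HU against a water phantom,
optionally bilateral-filtered (the fFBP / fSIRT scenarios), registered and
subtracted against the session's 0 mg I/ml baseline, converted to C_I with
a per-algorithm calibration, and measured in a world-coordinate insert ROI.
Image quality (NPS, MTF, CNR) and accuracy/precision statistics (bias,
linearity, repeatability, reproducibility) are then computed per scenario.

Simulation is performed on a dedicated finer grid than either
reconstruction grid, so neither algorithm reconstructs onto the grid that
generated the data.

Seeding: every acquisition derives its RNG seed from the master seed via
``SeedSequence([master_seed, session, slot, level_index])`` where ``slot``
is the replicate index (255 for the session baseline scan) and QC scans
use ``SeedSequence([master_seed, 9000 + phantom_index])``.  Replicates are
therefore independent while the whole study reproduces exactly from the
master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .denoise import BilateralParams, bilateral_filter, fwhm_from_mtf50, \
    select_bf_params
from .image_quality import MtfResult, NpsResult, compute_cnr, \
    compute_mtf_edge, compute_nps
from .phantoms import GridSpec, ImageVolume, MaterialModel, \
    make_standard_phantom, voxelize
from .projection import ScanGeometry, Sinogram, add_noise, \
    forward_project, system_matrix
from .recon import FbpParams, SirtParams, fbp_reconstruct, \
    to_hounsfield, _sirt_run
from .subtraction import RoiSpec, fit_ci_calibration, \
    measure_roi, register_affine, subtract
from .quant_metrics import ReplicateSet, assess_linearity, compute_bias, \
    compute_repeatability, compute_reproducibility

logger = logging.getLogger("cisubquant")

__all__ = ["StudyConfig", "StudyReport", "run_qc", "run_phantom_study",
           "export_report"]

SCENARIOS = ("FBP", "fFBP", "SIRT", "fSIRT")
#: Cross-scenario comparisons evaluated for reproducibility.
COMPARISONS = (("FBP", "SIRT"), ("FBP", "fFBP"), ("SIRT", "fSIRT"),
               ("fFBP", "fSIRT"))
_BASELINE_SLOT = 255


@dataclass
class StudyConfig:
    """Study configuration with desk-scale defaults.

    Desk scale keeps the reconstruction grids proportional to the
    full-protocol grids (0.125 mm FBP vs 0.1 mm SIRT pixel pitch becomes
    0.25 vs 0.2 mm) while the full-scale class method restores the
    protocol values (400 projections, 560^2 / 750^2 matrices).
    """

    # phantom levels and replicate design
    ci_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 3.0)
    n_replicates: int = 3
    n_sessions: int = 2
    scenarios: tuple[str, ...] = SCENARIOS
    master_seed: int = 42

    # acquisition geometry; I0=None disables noise (ideal detector)
    n_angles: int = 200
    detector_bins: int = 160
    detector_spacing: float = 0.25
    I0: float | None = 1e5

    # grids (z, y, x)
    sim_shape: tuple[int, int, int] = (8, 200, 200)
    sim_spacing: tuple[float, float, float] = (1.0, 0.16, 0.16)
    fbp_shape: tuple[int, int, int] = (8, 128, 128)
    fbp_spacing: tuple[float, float, float] = (1.0, 0.25, 0.25)
    sirt_shape: tuple[int, int, int] = (8, 160, 160)
    sirt_spacing: tuple[float, float, float] = (1.0, 0.2, 0.2)

    # reconstruction
    sirt_iterations: int = 180
    sirt_relaxation: float = 1.0
    sirt_nonnegativity: bool = False
    fbp_filter: str = "hann"
    fbp_cutoff: float = 1.0

    # bilateral filter constants
    bf_c_range: float = 2.0
    bf_c_spatial: float = 1.0

    # phantom geometry (mm)
    body_radius: float = 12.0
    insert_radius: float = 4.0

    # measurement ROIs (mm, world coordinates)
    insert_roi_radius: float = 3.0
    water_roi_radius: float = 6.0
    nps_roi_size: int = 32
    nps_uniform_radius: float = 9.0
    mtf_roi_radius: float = 5.0

    registration_mode: str = "translation"

    # materials
    mu_water: float = 0.0375
    k_iodine: float = 0.0022
    mu_acrylic: float = 0.044

    def __post_init__(self) -> None:
        bad = [s for s in self.scenarios if s not in SCENARIOS]
        if bad:
            raise ValueError(f"unknown scenarios: {bad}")
        if len(self.ci_levels) < 3:
            raise ValueError("need >= 3 C_I levels for calibration")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        self.ci_levels = tuple(float(c) for c in self.ci_levels)
        self.scenarios = tuple(self.scenarios)

    # -- derived objects ---------------------------------------------------
    @property
    def geometry(self) -> ScanGeometry:
        return ScanGeometry(self.n_angles, self.detector_bins,
                            self.detector_spacing,
                            self.I0 if self.I0 is not None else 1e12)

    @property
    def materials(self) -> MaterialModel:
        return MaterialModel(mu_water=self.mu_water, k_iodine=self.k_iodine,
                             mu_acrylic=self.mu_acrylic)

    @property
    def sim_grid(self) -> GridSpec:
        return GridSpec(self.sim_shape, self.sim_spacing)

    @property
    def fbp_grid(self) -> GridSpec:
        return GridSpec(self.fbp_shape, self.fbp_spacing)

    @property
    def sirt_grid(self) -> GridSpec:
        return GridSpec(self.sirt_shape, self.sirt_spacing)

    @classmethod
    def full_scale(cls, **overrides) -> "StudyConfig":
        """Full-protocol sizes (compute-heavy; desk runs use the default)."""
        base = dict(
            n_angles=400, detector_bins=600, detector_spacing=0.125,
            sim_shape=(16, 700, 700), sim_spacing=(0.5, 0.1, 0.1),
            fbp_shape=(16, 560, 560), fbp_spacing=(0.5, 0.125, 0.125),
            sirt_shape=(16, 750, 750), sirt_spacing=(0.5, 0.1, 0.1),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for k in ("ci_levels", "scenarios", "sim_shape", "sim_spacing",
                  "fbp_shape", "fbp_spacing", "sirt_shape", "sirt_spacing"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _acq_seed(master: int, *tags: int) -> int:
    """Documented counter scheme: derive a 31-bit seed from the master seed
    and integer tags via SeedSequence."""
    ss = np.random.SeedSequence([int(master), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stage(name: str, t0: float) -> None:
    logger.info("stage=%s elapsed=%.1fs", name, time.time() - t0)


def _simulate(config: StudyConfig, spec, seed: int | None) -> Sinogram:
    vol = voxelize(spec, config.sim_grid, config.materials)
    sino = forward_project(vol, config.geometry)
    if config.I0 is None or seed is None:
        return sino
    return add_noise(sino, config.I0, seed)


def _sirt_batch(sinos: list[Sinogram], grid: GridSpec,
                params: SirtParams) -> list[ImageVolume]:
    """Reconstruct several sinograms in one SIRT run (slices stacked as
    right-hand-side columns; mathematically identical to one-by-one runs)."""
    geom = sinos[0].geometry
    nz, ny, nx = grid.shape
    A = system_matrix(geom, ny, nx, grid.spacing[2])
    cols = np.concatenate(
        [s.line_integrals.reshape(nz, -1).T for s in sinos], axis=1)
    sols = _sirt_run(A, cols, params)
    x = sols[params.n_iterations]
    out = []
    for i in range(len(sinos)):
        block = x[:, i * nz:(i + 1) * nz]
        out.append(ImageVolume(block.T.reshape(nz, ny, nx), grid,
                               "attenuation"))
    return out


# ---------------------------------------------------------------------------
# QC: image-quality arm (water + edge phantoms)
# ---------------------------------------------------------------------------

def run_qc(config: StudyConfig) -> dict:
    """Simulate water and edge phantom scans, reconstruct under every
    scenario and compute NPS, MTF and noise SD.

    Also returns the per-algorithm water attenuation (the HU calibration
    anchor) and the bilateral parameters derived from each algorithm's
    measured noise and resolution, which the study arm reuses.
    """
    t0 = time.time()
    water = make_standard_phantom("water", body_radius=config.body_radius)[0]
    edge = make_standard_phantom("edge", body_radius=config.body_radius)[0]
    water_sino = _simulate(config, water, _acq_seed(config.master_seed, 9000))
    edge_sino = _simulate(config, edge, _acq_seed(config.master_seed, 9001))
    _stage("qc_simulate", t0)

    fbp_params = FbpParams(config.fbp_filter, config.fbp_cutoff)
    sirt_params = SirtParams(config.sirt_iterations, config.sirt_relaxation,
                             config.sirt_nonnegativity)
    recons: dict[str, dict[str, ImageVolume]] = {}
    recons["FBP"] = {
        "water": fbp_reconstruct(water_sino, fbp_params, config.fbp_grid),
        "edge": fbp_reconstruct(edge_sino, fbp_params, config.fbp_grid)}
    wat_s, edg_s = _sirt_batch([water_sino, edge_sino], config.sirt_grid,
                               sirt_params)
    recons["SIRT"] = {"water": wat_s, "edge": edg_s}
    _stage("qc_reconstruct", t0)

    water_roi = RoiSpec((0.0, 0.0, 0.0), config.water_roi_radius, "sphere")
    edge_roi = RoiSpec((0.0, 0.0, 0.0), config.mtf_roi_radius, "disk",
                       z_extent=1e9)
    out: dict = {"scenarios": {}, "mu_water": {}, "bf_params": {}}
    hu_vols: dict[str, dict[str, ImageVolume]] = {}
    for algo in ("FBP", "SIRT"):
        mu_w = measure_roi(recons[algo]["water"], water_roi)[0]
        out["mu_water"][algo] = mu_w
        hu_vols[algo] = {k: to_hounsfield(v, mu_w)
                         for k, v in recons[algo].items()}
        noise_sd = measure_roi(hu_vols[algo]["water"], water_roi)[1]
        mtf = compute_mtf_edge(hu_vols[algo]["edge"], edge_roi)
        out["bf_params"][algo] = select_bf_params(
            noise_sd, fwhm_from_mtf50(mtf.mtf50),
            c_range=config.bf_c_range, c_spatial=config.bf_c_spatial)

    for scen in config.scenarios:
        algo = scen.lstrip("f")
        water_hu, edge_hu = hu_vols[algo]["water"], hu_vols[algo]["edge"]
        if scen.startswith("f"):
            bf = out["bf_params"][algo]
            water_hu = bilateral_filter(water_hu, bf)
            edge_hu = bilateral_filter(edge_hu, bf)
        nps = compute_nps([water_hu], roi_size=config.nps_roi_size,
                          uniform_radius_mm=config.nps_uniform_radius)
        mtf = compute_mtf_edge(edge_hu, edge_roi)
        noise_sd = measure_roi(water_hu, water_roi)[1]
        out["scenarios"][scen] = {"nps": nps, "mtf": mtf,
                                  "noise_sd": noise_sd}
    _stage("qc_metrics", t0)
    return out


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Per-scenario image-quality and accuracy/precision results plus
    cross-scenario reproducibility; serialises losslessly to JSON."""

    scenarios: dict
    reproducibility: dict
    measurements: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "scenarios": self.scenarios,
            "reproducibility": self.reproducibility,
            "measurements": self.measurements.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(_round_floats(self.to_dict()), indent=2,
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        d = json.loads(text)
        return cls(scenarios=d["scenarios"],
                   reproducibility=d["reproducibility"],
                   measurements=pd.DataFrame(d["measurements"]),
                   provenance=d["provenance"])


def _round_floats(obj, ndigits: int = 10):
    """Round floats for stable, platform-independent JSON output."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _nps_summary(nps: NpsResult) -> dict:
    return {"mean": float(nps.mean_nps),
            "freq": [float(f) for f in nps.nps1d_freq],
            "profile": [float(v) for v in nps.nps1d],
            "roi_size": nps.roi_size, "n_rois": nps.n_rois}


def _mtf_summary(mtf: MtfResult) -> dict:
    return {"mtf50": float(mtf.mtf50), "mtf10": float(mtf.mtf10)}


# ---------------------------------------------------------------------------
# Study arm
# ---------------------------------------------------------------------------

def run_phantom_study(config: StudyConfig,
                      partial_dir=None) -> StudyReport:
    """Run the full phantom study and return the aggregated report.

    Deterministic given ``config.master_seed``; per-acquisition seeds follow
    the documented SeedSequence counter scheme.  If a stage fails the error
    is re-raised with the stage name; measurements collected so far are
    written to ``partial_dir`` (if given) before the abort.
    """
    state: dict = {"stage": "start", "rows": []}
    try:
        return _run_phantom_study(config, state)
    except Exception as exc:
        if partial_dir is not None:
            from pathlib import Path
            p = Path(partial_dir)
            p.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(state["rows"]).to_csv(
                p / "partial_measurements.csv", index=False)
        raise RuntimeError(
            f"phantom study failed at stage {state['stage']!r}: {exc}"
        ) from exc


def _run_phantom_study(config: StudyConfig, state: dict) -> StudyReport:
    t_start = time.time()
    state["stage"] = "qc"
    qc = run_qc(config)
    fbp_params = FbpParams(config.fbp_filter, config.fbp_cutoff)
    sirt_params = SirtParams(config.sirt_iterations, config.sirt_relaxation,
                             config.sirt_nonnegativity)
    phantoms = make_standard_phantom(
        "iodine_set", ci_levels=list(config.ci_levels),
        body_radius=config.body_radius, insert_radius=config.insert_radius)

    # noiseless sinogram per level (phantoms are deterministic), reused
    # across replicates before adding independent noise
    state["stage"] = "forward_project"
    clean = {}
    for li, spec in enumerate(phantoms):
        vol = voxelize(spec, config.sim_grid, config.materials)
        clean[li] = forward_project(vol, config.geometry)
    _stage("study_forward_project", t_start)

    insert_roi = RoiSpec((0.0, 0.0, 0.0), config.insert_roi_radius, "sphere")
    needs_algo = {a for a in ("FBP", "SIRT")
                  if a in config.scenarios or f"f{a}" in config.scenarios}

    # acquisition bookkeeping: (session, slot, level_index) -> sinogram
    # slot = replicate index, or _BASELINE_SLOT for the session baseline
    records = []
    cnr_subs: dict[str, dict[float, ImageVolume]] = {s: {}
                                                     for s in config.scenarios}
    dhu_means: dict[str, list[dict]] = {s: [] for s in config.scenarios}

    for session in range(config.n_sessions):
        state["stage"] = f"session{session}"
        acq_keys = [(_BASELINE_SLOT, 0)]
        acq_keys += [(rep, li) for rep in range(config.n_replicates)
                     for li in range(len(config.ci_levels))]
        sinos = []
        for slot, li in acq_keys:
            seed = _acq_seed(config.master_seed, session, slot, li)
            s = clean[li]
            if config.I0 is not None:
                s = add_noise(s, config.I0, seed)
            sinos.append(s)
        _stage(f"session{session}_noise", t_start)

        hu: dict[str, list[ImageVolume]] = {}
        if "FBP" in needs_algo:
            vols = [fbp_reconstruct(s, fbp_params, config.fbp_grid)
                    for s in sinos]
            hu["FBP"] = [to_hounsfield(v, qc["mu_water"]["FBP"])
                         for v in vols]
        if "SIRT" in needs_algo:
            vols = _sirt_batch(sinos, config.sirt_grid, sirt_params)
            hu["SIRT"] = [to_hounsfield(v, qc["mu_water"]["SIRT"])
                          for v in vols]
        _stage(f"session{session}_reconstruct", t_start)

        for scen in config.scenarios:
            algo = scen.lstrip("f")
            vols = hu[algo]
            if scen.startswith("f"):
                bf = qc["bf_params"][algo]
                vols = [bilateral_filter(v, bf) for v in vols]
            baseline = vols[0]
            for idx, (slot, li) in enumerate(acq_keys):
                if slot == _BASELINE_SLOT:
                    continue
                ce = vols[idx]
                t = register_affine(baseline, ce,
                                    mode=config.registration_mode)
                sub = subtract(ce, baseline, t)
                mean_dhu = measure_roi(sub, insert_roi)[0]
                row = {"scenario": scen,
                       "session": session, "replicate": slot,
                       "level_index": li,
                       "nominal_ci": config.ci_levels[li],
                       "mean_dhu": mean_dhu}
                dhu_means[scen].append(row)
                state["rows"].append(row)
                if session == 0 and slot == 0:
                    cnr_subs[scen][config.ci_levels[li]] = sub
        _stage(f"session{session}_subtract", t_start)

    state["stage"] = "calibrate"
    # calibration per reconstruction algorithm from session-0 mean ΔHU,
    # shared by the filtered scenario of the same algorithm
    calibrations: dict[str, object] = {}
    for algo in needs_algo:
        src = algo if algo in config.scenarios else f"f{algo}"
        df = pd.DataFrame(dhu_means[src])
        s0 = df[df["session"] == 0]
        pairs = [(grp["mean_dhu"].mean(), level)
                 for level, grp in s0.groupby("nominal_ci")]
        calibrations[algo] = fit_ci_calibration(pairs)

    for scen in config.scenarios:
        fn = calibrations[scen.lstrip("f")]
        for rec in dhu_means[scen]:
            measured = fn.slope * rec["mean_dhu"] + fn.intercept
            records.append({"scenario": scen, "nominal_ci": rec["nominal_ci"],
                            "replicate": int(rec["replicate"]),
                            "session": int(rec["session"]),
                            "mean_dhu": float(rec["mean_dhu"]),
                            "measured_ci": float(measured)})
    measurements = pd.DataFrame(records).sort_values(
        ["scenario", "session", "replicate", "nominal_ci"],
        ignore_index=True)
    reps = ReplicateSet(measurements)
    _stage("study_calibrate", t_start)

    state["stage"] = "metrics"
    scen_blocks = {}
    for scen in config.scenarios:
        algo = scen.lstrip("f")
        fn = calibrations[algo]
        lin = assess_linearity(reps, scen)
        rep_rep = compute_repeatability(reps, scen)
        sub = reps.scenario(scen)
        bias_rows = []
        for level, grp in sub.groupby("nominal_ci"):
            _, mean_bias = compute_bias(
                grp["measured_ci"].to_numpy(), float(level))
            bias_rows.append({"nominal_ci": float(level),
                              "mean_bias": float(mean_bias)})
        try:
            cnr = compute_cnr(cnr_subs[scen], insert_roi)
        except ValueError:
            # ideal-detector (noiseless) runs have a zero 0-level
            # subtracted image; CNR is undefined there
            cnr = []
        qs = qc["scenarios"][scen]
        scen_blocks[scen] = {
            "calibration": {"slope": fn.slope, "intercept": fn.intercept,
                            "r_squared": fn.r_squared},
            "noise_sd": float(qs["noise_sd"]),
            "nps": _nps_summary(qs["nps"]),
            "mtf": _mtf_summary(qs["mtf"]),
            "cnr": [{"nominal_ci": c.nominal_ci, "contrast": c.contrast,
                     "noise": c.noise, "cnr": c.cnr} for c in cnr],
            "linearity": {"beta1": lin.beta1, "beta2": lin.beta2,
                          "r_squared": lin.r_squared, "passes": lin.passes},
            "bias": bias_rows,
            "repeatability": {
                "per_level": rep_rep.per_level.to_dict(orient="records"),
                "pooled_wsd": rep_rep.pooled_wsd,
                "pooled_rc": rep_rep.pooled_rc},
        }

    reproducibility = {}
    for a, b in COMPARISONS:
        if a not in config.scenarios or b not in config.scenarios:
            continue
        key = ["session", "replicate", "nominal_ci"]
        xa = reps.scenario(a).sort_values(key)["measured_ci"].to_numpy()
        xb = reps.scenario(b).sort_values(key)["measured_ci"].to_numpy()
        r, p = compute_reproducibility(xa, xb)
        reproducibility[f"{a}_vs_{b}"] = {"pearson_r": r, "p_value": p}
    _stage("study_metrics", t_start)

    provenance = {"config": config.to_dict(),
                  "config_sha256": config.sha256(),
                  "master_seed": config.master_seed,
                  "package_version": __version__}
    return StudyReport(scenarios=scen_blocks,
                       reproducibility=reproducibility,
                       measurements=measurements, provenance=provenance)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_report(report: StudyReport, out_dir, plots: bool = False) -> list:
    """Write report.json and per-scenario CSV tables; returns file list.

    Output is deterministic: two exports of one report are byte-identical.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    p = out / "report.json"
    p.write_text(report.to_json())
    files.append(p)

    m = out / "measurements.csv"
    report.measurements.to_csv(m, index=False, float_format="%.10g")
    files.append(m)

    rows = []
    for scen, blk in sorted(report.scenarios.items()):
        for lvl in blk["repeatability"]["per_level"]:
            rows.append({"scenario": scen, **lvl})
    rp = out / "repeatability.csv"
    pd.DataFrame(rows).to_csv(rp, index=False, float_format="%.10g")
    files.append(rp)

    rows = []
    for scen, blk in sorted(report.scenarios.items()):
        for rec in blk["cnr"]:
            rows.append({"scenario": scen, **rec})
    cp = out / "cnr.csv"
    pd.DataFrame(rows).to_csv(cp, index=False, float_format="%.10g")
    files.append(cp)

    if plots:
        files.extend(_write_plots(report, out))
    return [str(f) for f in files]


def _write_plots(report: StudyReport, out) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for scen, blk in sorted(report.scenarios.items()):
        ax.plot(blk["nps"]["freq"], blk["nps"]["profile"], label=scen)
    ax.set_xlabel("frequency (mm$^{-1}$)")
    ax.set_ylabel("NPS (HU$^2$ mm$^2$)")
    ax.legend()
    p = out / "nps.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return [p]
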