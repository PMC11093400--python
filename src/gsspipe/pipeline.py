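"""Phantom-study orchestration: simulate -> glm -> parcellate -> extract -> analyze.

Two entry points:

* :func:`run_phantom_study` executes the whole study in memory and returns a
  :class:`StudyResult`; this is what simulations, tests and the worked
  examples use.
* :func:`run_pipeline` executes the same stages against a directory of
  NIfTI/TSV/JSON artifacts with a content-hash manifest, so any contiguous
  suffix of stages can restart from cached results; this is what the command
  line drives.

The default study: two disjoint ellipsoidal networks on a 24^3 grid of 2 mm
voxels, 12 subjects, two blocked dual-localizer runs per subject (condition
``taskA`` drives network A, ``taskB`` network B; localizer contrast
taskA - taskB and its reverse), and one event-related naming run per
critical condition with a 0.07 percent-signal-change condition effect
planted in network A only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bold import NoiseParams, simulate_bold_run
from .firstlevel import build_design_matrix, fit_glm, fixed_effects_combine
from .froi import FROIConfig, define_subject_froi, extract_psc_table
from .grid import VolumeGrid
from .gss import GSSConfig, GSSParcellation, ParcelAtlas
from .io import (file_sha256, load_volume, read_json, read_table, save_labels,
                 save_volume, write_json, write_table)
from .lmm import (DEFAULT_CONDITION_CODES, fit_interaction_lmm, fit_network_lmm,
                  fit_roi_models, network_overlap)
from .phantom import NetworkSpec, make_phantom, sample_subject_topography
from .schedules import (make_localizer_schedule, make_picture_naming_schedule,
                        read_events_tsv, write_events_tsv)

log = logging.getLogger(__name__)

STAGES = ("simulate", "glm", "parcellate", "extract", "analyze")

#: critical naming conditions and their deviation codes
TASK_CONDITIONS = tuple(DEFAULT_CONDITION_CODES)


@dataclass
class PhantomStudyConfig:
    """Declarative description of a full multi-subject phantom study."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_subjects: int = 12
    tr_s: float = 1.4
    seed: int = 0
    # two disjoint networks; condition effect (L1-after-L2 minus L1-after-L1)
    # planted in network A only
    network_centers: tuple = ((7.0, 12.0, 12.0), (17.0, 12.0, 12.0))
    network_radii: tuple = (3.2, 3.2)
    localizer_amplitude_pct: float = 1.0
    task_amplitude_pct: float = 1.0
    planted_effect_pct: float = 0.07
    amplitude_subject_sd: float = 0.1
    n_localizer_runs: int = 2
    localizer_design: str = "language"
    topography_max_shift_vox: int = 2
    topography_grow_prob: float = 0.3
    topography_min_overlap: float = 0.5
    noise_white_sd: float = 0.5
    noise_ar1: float = 0.3
    noise_drift: float = 2.0
    gss: dict = field(default_factory=dict)
    froi: dict = field(default_factory=dict)

    # ----- derived objects ------------------------------------------------
    def grid(self) -> VolumeGrid:
        return VolumeGrid(tuple(self.shape), tuple(self.voxel_size_mm))

    def noise(self) -> NoiseParams:
        return NoiseParams(self.noise_white_sd, self.noise_ar1, self.noise_drift)

    def gss_config(self) -> GSSConfig:
        return GSSConfig(**self.gss)

    def froi_config(self) -> FROIConfig:
        return FROIConfig(**self.froi)

    def subjects(self) -> list[str]:
        return [f"sub{i:02d}" for i in range(self.n_subjects)]

    def network_specs(self) -> list[NetworkSpec]:
        c1, c2 = TASK_CONDITIONS  # (L1_after_L1, L1_after_L2)
        a = self.task_amplitude_pct
        specs = []
        for i, (center, radius) in enumerate(zip(self.network_centers, self.network_radii)):
            name = f"net{chr(ord('A') + i)}"
            planted = self.planted_effect_pct if i == 0 else 0.0
            amps = {"taskA": self.localizer_amplitude_pct if i == 0 else 0.0,
                    "taskB": self.localizer_amplitude_pct if i == 1 else 0.0,
                    c1: a, c2: a + planted}
            specs.append(NetworkSpec(name, tuple(center), radius, amps,
                                     self.amplitude_subject_sd))
        return specs

    def network_contrasts(self) -> dict[str, dict[str, float]]:
        return {"netA": {"taskA": 1.0, "taskB": -1.0},
                "netB": {"taskB": 1.0, "taskA": -1.0}}

    # ----- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomStudyConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomStudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# --------------------------------------------------------------- seed policy

def _study_seeds(cfg: PhantomStudyConfig) -> np.random.SeedSequence:
    return np.random.SeedSequence(cfg.seed)


def _subject_seed(cfg: PhantomStudyConfig, si: int, stream: int) -> int:
    # deterministic per-(study, subject, stream) seeds below 2^31
    return int(np.random.SeedSequence([cfg.seed, si, stream]).generate_state(1)[0] % (2 ** 31))


# ------------------------------------------------------------ in-memory study

@dataclass
class SubjectMaps:
    """Per-subject first-level derivatives on the common grid."""
    subject_id: str
    z_by_network: dict[str, np.ndarray]          # pooled localizer z
    run_z_by_network: dict[str, list[np.ndarray]]  # per localizer run
    task_psc: dict[str, np.ndarray]              # condition -> PSC volume


@dataclass
class StudyResult:
    config: PhantomStudyConfig
    truth_masks: dict[str, np.ndarray]
    atlases: dict[str, ParcelAtlas]
    dice: dict[str, float]
    psc_table: pd.DataFrame
    network_fits: dict[str, object]
    interaction_fit: object
    roi_fits: pd.DataFrame
    overlap: dict


def simulate_subject(cfg: PhantomStudyConfig, truths, si: int) -> SubjectMaps:
    """Simulate and fit all runs of one subject, keeping only statistic maps."""
    grid = cfg.grid()
    sid = cfg.subjects()[si]
    noise = cfg.noise()
    topos = [sample_subject_topography(
        t, sid, seed=_subject_seed(cfg, si, 10 + k),
        max_shift_vox=cfg.topography_max_shift_vox,
        grow_prob=cfg.topography_grow_prob,
        min_overlap=cfg.topography_min_overlap) for k, t in enumerate(truths)]
    contrasts = cfg.network_contrasts()
    eff = {n: [] for n in contrasts}
    var = {n: [] for n in contrasts}
    run_z = {n: [] for n in contrasts}
    for r in range(cfg.n_localizer_runs):
        sched = make_localizer_schedule(cfg.localizer_design,
                                        seed=_subject_seed(cfg, si, 100 + r),
                                        conditions=("taskA", "taskB"))
        run = simulate_bold_run(grid, truths, topos, sched, sid, f"loc{r + 1}",
                                seed=_subject_seed(cfg, si, 200 + r),
                                tr_s=cfg.tr_s, noise=noise)
        glm = fit_glm(run, build_design_matrix(sched, cfg.tr_s, run.n_volumes))
        for net, w in contrasts.items():
            e, v = glm.contrast(w)
            eff[net].append(e)
            var[net].append(v)
            run_z[net].append(glm.contrast_z(w))
    z_by_net = {}
    for net in contrasts:
        if cfg.n_localizer_runs >= 2:
            _, _, z = fixed_effects_combine(eff[net], var[net])
        else:
            z = run_z[net][0]
        z_by_net[net] = z
    task_psc = {}
    for ci, cond in enumerate(TASK_CONDITIONS):
        sched = make_picture_naming_schedule(seed=_subject_seed(cfg, si, 300 + ci),
                                             condition=cond)
        run = simulate_bold_run(grid, truths, topos, sched, sid, cond,
                                seed=_subject_seed(cfg, si, 400 + ci),
                                tr_s=cfg.tr_s, noise=noise)
        glm = fit_glm(run, build_design_matrix(sched, cfg.tr_s, run.n_volumes))
        task_psc[cond] = glm.psc(cond)
    return SubjectMaps(sid, z_by_net, run_z, task_psc)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool); b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else np.nan


def parcellate_study(cfg: PhantomStudyConfig,
                     z_by_network: dict[str, list[np.ndarray]]) -> dict[str, ParcelAtlas]:
    gss_kwargs = dict(cfg.gss)
    atlases = {}
    for net, zmaps in z_by_network.items():
        est = GSSParcellation(voxel_size_mm=tuple(cfg.voxel_size_mm), **gss_kwargs)
        est.fit(zmaps)
        atlases[net] = est.atlas_
    return atlases


def build_psc_table(cfg: PhantomStudyConfig, atlases: dict[str, ParcelAtlas],
                    subject_maps: list[SubjectMaps]) -> tuple[pd.DataFrame, dict[int, str]]:
    """Define fROIs on pooled localizer z and extract the task PSC table.

    Parcel ids are offset per network so ROI identifiers stay unique in the
    combined table (the crossed model requires it).
    """
    fcfg = cfg.froi_config()
    net_of: dict[int, str] = {}
    frois: dict[str, dict] = {m.subject_id: {} for m in subject_maps}
    offset = 0
    for net in sorted(atlases):
        atlas = atlases[net]
        for pid in atlas.parcel_ids():
            net_of[offset + pid] = net
        for m in subject_maps:
            for pid in atlas.parcel_ids():
                frois[m.subject_id][offset + pid] = define_subject_froi(
                    atlas.parcel_mask(pid), m.z_by_network[net],
                    fcfg.top_fraction, fcfg.min_voxels, m.subject_id, offset + pid)
        offset += atlas.n_parcels
    psc_maps = {m.subject_id: m.task_psc for m in subject_maps}
    table = extract_psc_table(frois, psc_maps, net_of, dict(DEFAULT_CONDITION_CODES))
    return table, net_of


def analyze_study(table: pd.DataFrame) -> tuple[dict, object, pd.DataFrame]:
    fits = {}
    for net, sub in table.groupby("network"):
        fits[net] = fit_network_lmm(sub, allow_single_roi=True)
    inter = None
    if table["network"].nunique() == 2 and all(
            table[table.network == n]["roi"].nunique() >= 1 for n in fits):
        inter = fit_interaction_lmm(table)
    roi_fits = fit_roi_models(table)
    return fits, inter, roi_fits


def run_phantom_study(cfg: PhantomStudyConfig | None = None, seed: int | None = None
                      ) -> StudyResult:
    """Execute the full study in memory and analyse it."""
    cfg = cfg or PhantomStudyConfig()
    if seed is not None:
        cfg = PhantomStudyConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    grid = cfg.grid()
    truths = make_phantom(grid, cfg.network_specs(), cfg.subjects(),
                          seed=cfg.seed, disjoint=True)
    subject_maps = [simulate_subject(cfg, truths, si)
                    for si in range(cfg.n_subjects)]
    z_by_net = {net: [m.z_by_network[net] for m in subject_maps]
                for net in cfg.network_contrasts()}
    atlases = parcellate_study(cfg, z_by_net)
    truth_masks = {t.name: t.mask for t in truths}
    dice = {net: _dice(atlases[net].union_mask(), truth_masks[net])
            for net in atlases}
    table, _ = build_psc_table(cfg, atlases, subject_maps)
    fits, inter, roi_fits = analyze_study(table)
    overlap = network_overlap(atlases["netA"].labels, atlases["netB"].labels) \
        if len(atlases) == 2 else {}
    overlap.pop("per_parcel", None)
    return StudyResult(cfg, truth_masks, atlases, dice, table, fits, inter,
                       roi_fits, overlap)


# ------------------------------------------------------------- staged pipeline

def _hash_config(cfg: PhantomStudyConfig) -> str:
    import hashlib
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()


class PipelineError(RuntimeError):
    pass


def _load_manifest(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    return read_json(p) if p.exists() else {"stages": {}}


def _stage_current(manifest: dict, stage: str, cfg_hash: str,
                   inputs: dict[str, str]) -> bool:
    rec = manifest["stages"].get(stage)
    if rec is None or rec["config_hash"] != cfg_hash or rec["inputs"] != inputs:
        return False
    return all(Path(p).exists() and file_sha256(p) == h
               for p, h in rec["outputs"].items())


def _record_stage(manifest: dict, outdir: Path, stage: str, cfg_hash: str,
                  inputs: dict[str, str], outputs: list[Path], t0: float) -> None:
    manifest["stages"][stage] = {
        "config_hash": cfg_hash,
        "inputs": inputs,
        "outputs": {str(p): file_sha256(p) for p in sorted(outputs)},
        "wall_s": round(time.time() - t0, 3),
    }
    write_json(manifest, outdir / "manifest.json")


def _require(paths: list[Path], stage: str, needed_by: str) -> dict[str, str]:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise PipelineError(
            f"stage '{needed_by}' is missing inputs produced by stage '{stage}': "
            f"{missing[:3]}{'...' if len(missing) > 3 else ''}; re-run '{stage}'")
    return {str(p): file_sha256(p) for p in sorted(paths)}


def run_pipeline(cfg: PhantomStudyConfig, outdir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested pipeline stages against ``outdir`` artifacts.

    Stages are cached on (config hash, input hashes, output hashes): re-running
    with unchanged inputs is a no-op.  Returns the manifest.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(cfg.to_dict(), outdir / "config_echo.json")
    cfg_hash = _hash_config(cfg)
    manifest = _load_manifest(outdir)
    grid = cfg.grid()
    subjects = cfg.subjects()
    contrasts = cfg.network_contrasts()
    nets = sorted(contrasts)

    def stage_on(name: str) -> bool:
        return name in stages

    # ---------------- simulate ----------------
    truth_paths = [outdir / "truth" / f"{n}_mask.nii" for n in nets]
    run_specs = []  # (bold path, events path, kind, cond-or-run, si)
    for si, sid in enumerate(subjects):
        for r in range(cfg.n_localizer_runs):
            base = outdir / sid / f"loc_run-{r + 1}"
            run_specs.append((base.with_suffix(".nii"),
                              Path(str(base) + "_events.tsv"), "loc", r, si))
        for ci, cond in enumerate(TASK_CONDITIONS):
            base = outdir / sid / f"task_{cond}"
            run_specs.append((base.with_suffix(".nii"),
                              Path(str(base) + "_events.tsv"), "task", ci, si))
    if stage_on("simulate"):
        if not _stage_current(manifest, "simulate", cfg_hash, {}):
            t0 = time.time()
            log.info("simulate: %d subjects on grid %s, seed %d",
                     cfg.n_subjects, cfg.shape, cfg.seed)
            truths = make_phantom(grid, cfg.network_specs(), subjects,
                                  seed=cfg.seed, disjoint=True)
            outputs = []
            for n, t in zip(nets, truths):
                outputs.append(save_labels(t.mask.astype(np.int16), grid,
                                           outdir / "truth" / f"{n}_mask.nii"))
            amps = {t.name: t.subject_amplitudes for t in truths}
            outputs.append(write_json(amps, outdir / "truth" / "amplitudes.json"))
            for bold_path, ev_path, kind, idx, si in run_specs:
                sid = subjects[si]
                topos = [sample_subject_topography(
                    t, sid, seed=_subject_seed(cfg, si, 10 + k),
                    max_shift_vox=cfg.topography_max_shift_vox,
                    grow_prob=cfg.topography_grow_prob,
                    min_overlap=cfg.topography_min_overlap)
                    for k, t in enumerate(truths)]
                if kind == "loc":
                    sched = make_localizer_schedule(
                        cfg.localizer_design, seed=_subject_seed(cfg, si, 100 + idx),
                        conditions=("taskA", "taskB"))
                    seed = _subject_seed(cfg, si, 200 + idx)
                else:
                    cond = TASK_CONDITIONS[idx]
                    sched = make_picture_naming_schedule(
                        seed=_subject_seed(cfg, si, 300 + idx), condition=cond)
                    seed = _subject_seed(cfg, si, 400 + idx)
                run = simulate_bold_run(grid, truths, topos, sched, sid,
                                        bold_path.stem, seed=seed, tr_s=cfg.tr_s,
                                        noise=cfg.noise())
                outputs.append(save_volume(run.data.astype(np.float32), grid, bold_path))
                write_events_tsv(sched, ev_path)
                outputs.append(ev_path)
            _record_stage(manifest, outdir, "simulate", cfg_hash, {}, outputs, t0)
        else:
            log.info("simulate: cached, skipping")

    # ---------------- glm ----------------
    z_paths = {net: [outdir / "glm" / f"{s}_{net}_z.nii" for s in subjects]
               for net in nets}
    psc_paths = {cond: [outdir / "glm" / f"{s}_task-{cond}_psc.nii" for s in subjects]
                 for cond in TASK_CONDITIONS}
    if stage_on("glm"):
        sim_inputs = _require([p for p, *_ in run_specs], "simulate", "glm")
        if not _stage_current(manifest, "glm", cfg_hash, sim_inputs):
            t0 = time.time()
            log.info("glm: fitting %d runs", len(run_specs))
            outputs = []
            for si, sid in enumerate(subjects):
                eff = {n: [] for n in nets}
                var = {n: [] for n in nets}
                for bold_path, ev_path, kind, idx, si2 in run_specs:
                    if si2 != si:
                        continue
                    data, _ = load_volume(bold_path)
                    kind_ = "blocked" if kind == "loc" else "event_related"
                    sched = read_events_tsv(ev_path, design_kind=kind_)
                    dm = build_design_matrix(sched, cfg.tr_s, data.shape[3])
                    glm = fit_glm(data.astype(np.float64), dm)
                    if kind == "loc":
                        for net, w in contrasts.items():
                            e, v = glm.contrast(w)
                            eff[net].append(e)
                            var[net].append(v)
                    else:
                        cond = TASK_CONDITIONS[idx]
                        outputs.append(save_volume(
                            glm.psc(cond), grid, psc_paths[cond][si]))
                    outputs.append(write_json(
                        {"dof": glm.dof_, "labels": dm.labels,
                         "n_vols": dm.n_volumes},
                        Path(str(bold_path).replace(".nii", "_glm.json"))))
                for net in nets:
                    if cfg.n_localizer_runs >= 2:
                        _, _, z = fixed_effects_combine(eff[net], var[net])
                    else:
                        zd = np.divide(eff[net][0], np.sqrt(var[net][0]),
                                       out=np.zeros_like(eff[net][0]),
                                       where=var[net][0] > 0)
                        z = zd
                    outputs.append(save_volume(z, grid, z_paths[net][si]))
            _record_stage(manifest, outdir, "glm", cfg_hash, sim_inputs, outputs, t0)
        else:
            log.info("glm: cached, skipping")

    # ---------------- parcellate ----------------
    atlas_paths = {net: outdir / "gss" / f"{net}_atlas.nii" for net in nets}
    table_paths = {net: outdir / "gss" / f"{net}_parcels.tsv" for net in nets}
    if stage_on("parcellate"):
        glm_inputs = _require([p for ps in z_paths.values() for p in ps],
                              "glm", "parcellate")
        if not _stage_current(manifest, "parcellate", cfg_hash, glm_inputs):
            t0 = time.time()
            outputs = []
            for net in nets:
                zmaps = [load_volume(p)[0].astype(np.float64) for p in z_paths[net]]
                est = GSSParcellation(voxel_size_mm=tuple(cfg.voxel_size_mm), **cfg.gss)
                est.fit(zmaps)
                log.info("parcellate %s: %d parcels", net, est.atlas_.n_parcels)
                outputs.append(save_labels(est.atlas_.labels, grid, atlas_paths[net]))
                outputs.append(write_table(est.atlas_.table, table_paths[net]))
            outputs.append(write_json(asdict(cfg.gss_config()), outdir / "gss" / "gss_config.json"))
            _record_stage(manifest, outdir, "parcellate", cfg_hash, glm_inputs, outputs, t0)
        else:
            log.info("parcellate: cached, skipping")

    # ---------------- extract ----------------
    psc_table_path = outdir / "extract" / "psc_table.tsv"
    if stage_on("extract"):
        inputs = _require([atlas_paths[n] for n in nets]
                          + [p for ps in z_paths.values() for p in ps]
                          + [p for ps in psc_paths.values() for p in ps],
                          "parcellate", "extract")
        if not _stage_current(manifest, "extract", cfg_hash, inputs):
            t0 = time.time()
            atlases = {}
            for net in nets:
                labels = load_volume(atlas_paths[net])[0].astype(np.int32)
                atlases[net] = ParcelAtlas(labels)
            maps = []
            for si, sid in enumerate(subjects):
                maps.append(SubjectMaps(
                    sid,
                    {net: load_volume(z_paths[net][si])[0].astype(np.float64)
                     for net in nets},
                    {},
                    {cond: load_volume(psc_paths[cond][si])[0].astype(np.float64)
                     for cond in TASK_CONDITIONS}))
            table, _ = build_psc_table(cfg, atlases, maps)
            outputs = [write_table(table, psc_table_path)]
            _record_stage(manifest, outdir, "extract", cfg_hash, inputs, outputs, t0)
        else:
            log.info("extract: cached, skipping")

    # ---------------- analyze ----------------
    analyze_path = outdir / "analyze" / "results.json"
    roi_fits_path = outdir / "analyze" / "roi_fits.tsv"
    if stage_on("analyze"):
        inputs = _require([psc_table_path] + [atlas_paths[n] for n in nets]
                          + truth_paths, "extract", "analyze")
        if not _stage_current(manifest, "analyze", cfg_hash, inputs):
            t0 = time.time()
            table = read_table(psc_table_path)
            fits, inter, roi_fits = analyze_study(table) if len(table) else ({}, None, pd.DataFrame())
            atl = {n: load_volume(atlas_paths[n])[0] for n in nets}
            truth = {n: load_volume(outdir / "truth" / f"{n}_mask.nii")[0] > 0
                     for n in nets}
            results = {
                "dice": {n: _dice(atl[n] > 0, truth[n]) for n in nets},
                "n_parcels": {n: int(atl[n].max()) for n in nets},
                "network_fits": {n: _fit_to_dict(f) for n, f in fits.items()},
                "interaction": _fit_to_dict(inter) if inter is not None else None,
                "overlap": {k: v for k, v in network_overlap(
                    atl[nets[0]], atl[nets[1]]).items() if k != "per_parcel"}
                if len(nets) == 2 else {},
                "n_records": int(len(table)),
            }
            outputs = [write_json(results, analyze_path),
                       write_table(roi_fits, roi_fits_path)]
            _record_stage(manifest, outdir, "analyze", cfg_hash, inputs, outputs, t0)
        else:
            log.info("analyze: cached, skipping")

    return _load_manifest(outdir)


def _fit_to_dict(fit) -> dict:
    return {
        "term": fit.term, "beta": fit.beta, "se": fit.se, "t": fit.t,
        "df": fit.df, "p": fit.p, "ci": [fit.ci_low, fit.ci_high],
        "intercept": fit.intercept, "effect_size": fit.effect_size,
        "effect_size_method": fit.effect_size_method, "vc": fit.vc,
        "converged": fit.converged, "method": fit.method,
        "trace": list(fit.trace), "n_subjects": fit.n_subjects,
        "n_rois": fit.n_rois, "n_obs": fit.n_obs,
    }


def report(outdir: str | Path, make_figures: bool = True) -> str:
    """Summarise a completed analyze stage into text (and optional figures)."""
    outdir = Path(outdir)
    analyze_path = outdir / "analyze" / "results.json"
    if not analyze_path.exists():
        raise PipelineError("no analyze results found; run the analyze stage first")
    res = read_json(analyze_path)
    lines = ["phantom study report", "====================", ""]
    if res["n_records"] == 0:
        lines.append("no records: the PSC table is empty.")
    else:
        for net, f in sorted(res["network_fits"].items()):
            lines.append(
                f"{net}: beta={f['beta']:+.4f} 95% CI [{f['ci'][0]:+.4f}, "
                f"{f['ci'][1]:+.4f}] t({f['df']:.1f})={f['t']:.3f} p={f['p']:.4g} "
                f"effect size ({f['effect_size_method']})={f['effect_size']:.2f}")
        if res.get("interaction"):
            f = res["interaction"]
            lines.append(f"condition x network interaction: beta={f['beta']:+.4f} "
                         f"t({f['df']:.1f})={f['t']:.3f} p={f['p']:.4g}")
        lines.append("")
        for net, d in sorted(res["dice"].items()):
            lines.append(f"{net}: {res['n_parcels'][net]} parcels, "
                         f"Dice vs truth = {d:.3f}")
        ov = res.get("overlap") or {}
        if ov:
            lines.append(f"between-atlas overlap: Dice={ov['dice']:.3f}, "
                         f"shared voxels={ov['shared_voxels']}")
    text = "\n".join(lines) + "\n"
    (outdir / "report").mkdir(exist_ok=True)
    (outdir / "report" / "report.txt").write_text(text)
    if make_figures and res["n_records"]:
        _figures(outdir, res)
    return text


def _figures(outdir: Path, res: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = read_table(outdir / "extract" / "psc_table.tsv")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (net, sub) in zip(axes, table.groupby("network")):
        means = sub.groupby("condition")["psc"].mean()
        sems = sub.groupby("condition")["psc"].sem()
        ax.bar(means.index, means.values, yerr=sems.values, color=["#7799cc", "#334477"])
        ax.set_title(net)
        ax.set_ylabel("percent signal change")
        ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    fig.savefig(outdir / "report" / "psc_by_condition.png", dpi=110)
    plt.close(fig)

    nets = sorted(res["n_parcels"])
    fig, axes = plt.subplots(1, len(nets), figsize=(4 * len(nets), 4))
    axes = np.atleast_1d(axes)
    for ax, net in zip(axes, nets):
        labels, _ = load_volume(outdir / "gss" / f"{net}_atlas.nii")
        mid = labels.shape[2] // 2
        ax.imshow(labels[:, :, mid].T, origin="lower", interpolation="nearest")
        ax.set_title(f"{net} atlas (axial slice {mid})")
    fig.tight_layout()
    fig.savefig(outdir / "report" / "atlas_slices.png", dpi=110)
    plt.close(fig)
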