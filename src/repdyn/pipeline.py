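"""End-to-end orchestration: simulate -> preprocess -> decode -> generalize
-> RSA -> fuse -> stats, from one declarative configuration.

Two scale presets are built in: ``desk`` (10 subjects, 64 channels, 300 Hz,
downsampled to 60 Hz, reduced iteration/permutation counts) runs the full
chain on one CPU in minutes; ``paper`` mirrors a full MEG study's scale
(17 subjects, 272 channels, 1200 Hz -> 120 Hz, 500 decoding iterations,
10,000/5000 permutations, 100,000 bootstrap samples).  Every stochastic
stage draws its seed deterministically from the global seed and the stage
name, so a rerun with the same configuration reproduces identical output
checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .decoding import (DecodingConfig, cross_tasktype_object_decode,
                       decode_timecourse, temporal_generalization)
from .fusion import run_fusion
from .preprocess import (PreprocessConfig, baseline_normalize,
                         drop_low_variance_components, filter_epochs,
                         fit_spatial_pca, smooth_and_downsample)
from .rsa import (RDM, compute_rdm, condition_mean_patterns, model_rdm,
                  rdm_timeseries, task_major_conditions)
from .stats import (bootstrap_peak_ci, cluster_2d, rdm_randomization_cluster,
                    sign_permutation_cluster_1d)
from .synth import (DesignSpec, GroundTruth, RESPONSE_SCREEN_MS,
                    STIMULUS_ONSET_MS, generate_design,
                    generate_roi_pattern_set, generate_subject_epochs)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "load_bundle",
           "STAGES"]

log = logging.getLogger("repdyn")

STAGES = ("simulate", "preprocess", "decode", "tempgen", "rsa", "fuse", "stats")


@dataclass
class SimulateSection:
    n_subjects: int = 10
    n_channels: int = 64
    sampling_rate: float = 300.0
    noise_sd: float = 1.0
    task_onset_ms: float = 100.0
    object_onset_ms: float = 80.0
    task_amplitude: float = 1.0
    object_amplitude: float = 1.0
    tasktype_gain: float = 1.0
    tasktype_gain_onset_ms: float = 0.0


@dataclass
class PreprocessSection:
    # lo = 0 -> low-pass + notch only: the synthetic data carries no drift,
    # and an epoch-level zero-phase high-pass would smear sustained evoked
    # patterns into the baseline window
    band_lo_hz: float = 0.0
    band_hi_hz: float = 100.0
    notch_hz: float = 60.0
    variance_drop_fraction: float = 0.01
    max_drop_fraction: float = 0.5
    smooth_hdhm_ms: float = 15.0
    target_rate_hz: float = 60.0


@dataclass
class DecodeSection:
    n_iterations: int = 30
    supertrial_size: int = 10
    C: float = 1.0
    cross_tasktype: bool = True


@dataclass
class TempgenSection:
    n_iterations: int = 10
    time_step: int = 3


@dataclass
class FusionSection:
    # per-ROI (task_weight, object_weight, noise_sd) mixtures for the
    # synthesized fMRI side; defaults emulate a task-dominated frontoparietal
    # ROI, an object-dominated ventral ROI, and a mixed one
    rois: dict = field(default_factory=lambda: {
        "PFC": [1.0, 0.2, 0.5], "pFS": [0.2, 1.0, 0.5], "EVC": [0.6, 0.6, 0.5]})
    n_units: int = 100


@dataclass
class StatsSection:
    alpha: float = 0.05
    n_perm_2d: int = 1024
    n_perm_rdm: int = 500
    n_boot: int = 2000
    max_exhaustive: int = 2 ** 17
    n_perm_1d: int = 10000


@dataclass
class PipelineConfig:
    seed: int = 0
    preset: str = "desk"
    out_dir: str = "repdyn_out"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    decode: DecodeSection = field(default_factory=DecodeSection)
    tempgen: TempgenSection = field(default_factory=TempgenSection)
    fusion: FusionSection = field(default_factory=FusionSection)
    stats: StatsSection = field(default_factory=StatsSection)

    @classmethod
    def preset_desk(cls, seed: int = 0, out_dir: str = "repdyn_out") -> "PipelineConfig":
        return cls(seed=seed, out_dir=out_dir, preset="desk")

    @classmethod
    def preset_paper(cls, seed: int = 0, out_dir: str = "repdyn_out") -> "PipelineConfig":
        return cls(
            seed=seed, out_dir=out_dir, preset="paper",
            simulate=SimulateSection(n_subjects=17, n_channels=272,
                                     sampling_rate=1200.0),
            preprocess=PreprocessSection(band_hi_hz=300.0, target_rate_hz=120.0),
            decode=DecodeSection(n_iterations=500),
            tempgen=TempgenSection(n_iterations=500, time_step=1),
            stats=StatsSection(n_perm_2d=10000, n_perm_rdm=5000,
                               n_boot=100000))

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0,
                    out_dir: str = "repdyn_out") -> "PipelineConfig":
        if preset == "desk":
            return cls.preset_desk(seed, out_dir)
        if preset == "paper":
            return cls.preset_paper(seed, out_dir)
        raise ValueError(f"unknown preset {preset!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in sections:
                raise ValueError(f"unknown config key {key!r}")
            f = sections[key]
            if dataclasses.is_dataclass(f.type) or f.name in (
                    "simulate", "preprocess", "decode", "tempgen", "fusion",
                    "stats"):
                sub_cls = f.default_factory  # type: ignore[union-attr]
                sub_fields = {sf.name for sf in dataclasses.fields(sub_cls())}
                unknown = set(value) - sub_fields
                if unknown:
                    raise ValueError(
                        f"unknown config key {key}.{sorted(unknown)[0]!r}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage (and per-subject) seed below 2^31."""
        h = zlib.crc32(f"{stage}:{index}".encode())
        return int((self.seed * 1_000_003 + h) % (2 ** 31))


@dataclass
class ResultBundle:
    """Paths + checksums of all stage outputs and the provenance graph
    (which outputs fed which stage)."""

    out_dir: str
    files: dict[str, dict]            # name -> {"path": ..., "sha256": ...}
    provenance: dict[str, list[str]]  # output name -> input names
    timings_s: dict[str, float] = field(default_factory=dict)

    def verify(self) -> None:
        for name, rec in self.files.items():
            p = Path(rec["path"])
            if not p.exists():
                raise FileNotFoundError(f"{name}: missing file {p}")
            if rio.sha256_file(p) != rec["sha256"]:
                raise ValueError(f"{name}: checksum mismatch for {p}")

    def save(self) -> None:
        out = Path(self.out_dir) / "bundle.json"
        out.write_text(json.dumps(
            {"files": self.files, "provenance": self.provenance,
             "timings_s": self.timings_s}, indent=1, sort_keys=True))


def _preproc_config(sec: PreprocessSection) -> PreprocessConfig:
    return PreprocessConfig(band_hz=(sec.band_lo_hz, sec.band_hi_hz),
                            notch_hz=sec.notch_hz,
                            variance_drop_fraction=sec.variance_drop_fraction,
                            max_drop_fraction=sec.max_drop_fraction,
                            smooth_hdhm_ms=sec.smooth_hdhm_ms,
                            target_rate_hz=sec.target_rate_hz)


def _cluster_table(result, time_ms: np.ndarray) -> pd.DataFrame:
    rows = []
    for c in result.clusters:
        idx = [i[0] if isinstance(i, tuple) else i for i in c.indices]
        rows.append((float(time_ms[min(idx)]), float(time_ms[max(idx)]),
                     c.size, c.p_value, c.significant))
    return pd.DataFrame(rows, columns=["start_ms", "end_ms", "size_samples",
                                       "p_value", "significant"])


class _Recorder:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: dict[str, dict] = {}
        self.provenance: dict[str, list[str]] = {}

    def add(self, name: str, path: Path, inputs: list[str]) -> None:
        self.files[name] = {"path": str(path), "sha256": rio.sha256_file(path)}
        self.provenance[name] = inputs


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> ResultBundle:
    """Execute the requested stages in dependency order and write all
    outputs (CSV/JSON) plus a checksummed bundle manifest to
    ``config.out_dir``.  Identical config + seed reproduces identical
    checksums."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    rec = _Recorder(out_dir)
    timings: dict[str, float] = {}
    sim = config.simulate
    pp = _preproc_config(config.preprocess)
    truth = GroundTruth(task_onset_ms=sim.task_onset_ms,
                        object_onset_ms=sim.object_onset_ms,
                        task_amplitude=sim.task_amplitude,
                        object_amplitude=sim.object_amplitude,
                        tasktype_gain=sim.tasktype_gain,
                        tasktype_gain_onset_ms=sim.tasktype_gain_onset_ms,
                        pattern_seed=config.stage_seed("patterns"))

    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True))
    rec.add("config", out_dir / "config.json", [])

    task_curves, cat_curves, within_curves, between_curves = [], [], [], []
    tg_mats, subject_rdm_stacks = [], []
    time_ms = None
    rdm_time_ms = None
    order = task_major_conditions()

    t_all = time.perf_counter()
    try:
        for s in range(sim.n_subjects):
            t0 = time.perf_counter()
            stage = "simulate"
            design_seed = config.stage_seed("design", s)
            epoch_seed = config.stage_seed("epochs", s)
            log.info("subject %d: design seed %d, epoch seed %d",
                     s, design_seed, epoch_seed)
            design = generate_design(DesignSpec(), design_seed)
            epochs = generate_subject_epochs(
                design, truth, n_channels=sim.n_channels,
                sampling_rate=sim.sampling_rate, noise_sd=sim.noise_sd,
                seed=epoch_seed, subject_id=f"S{s:02d}")
            if s == 0:
                rio.save_trial_table(design, out_dir / "trials_S00.csv")
                rec.add("trials_S00", out_dir / "trials_S00.csv", [])

            stage = "preprocess"
            filtered = filter_epochs(epochs, pp)
            del epochs
            model, comp = fit_spatial_pca(filtered)
            del filtered
            comp = drop_low_variance_components(
                comp, model, pp.variance_drop_fraction, pp.max_drop_fraction)

            def finish(factor: str):
                normalized = baseline_normalize(comp, pp.baseline_ms(factor))
                ds = smooth_and_downsample(normalized, pp.smooth_hdhm_ms,
                                           pp.target_rate_hz)
                ds.provenance["baseline_factor"] = factor
                return ds

            comp_task = finish("task")
            comp_cat = finish("category")
            del comp
            time_ms = comp_task.time_ms

            if "decode" in stages:
                stage = "decode"
                dsec = config.decode
                cfg = lambda factor: DecodingConfig(
                    label_factor=factor, supertrial_size=dsec.supertrial_size,
                    n_iterations=dsec.n_iterations, C=dsec.C,
                    seed=config.stage_seed("decode_" + factor, s))
                task_curves.append(decode_timecourse(comp_task, cfg("task")))
                cat_curves.append(decode_timecourse(comp_cat, cfg("category")))
                if dsec.cross_tasktype:
                    w, b = cross_tasktype_object_decode(comp_cat, cfg("category"))
                    within_curves.append(w)
                    between_curves.append(b)

            if "tempgen" in stages:
                stage = "tempgen"
                tsec = config.tempgen
                tg_cfg = DecodingConfig(
                    label_factor="task", supertrial_size=config.decode.supertrial_size,
                    n_iterations=tsec.n_iterations, C=config.decode.C,
                    seed=config.stage_seed("tempgen", s))
                tg_mats.append(temporal_generalization(
                    comp_task, tg_cfg, time_step=tsec.time_step))

            if "rsa" in stages:
                stage = "rsa"
                means, cond_order = condition_mean_patterns(comp_task)
                rdms = rdm_timeseries(means, comp_task.time_ms, cond_order)
                subject_rdm_stacks.append(
                    np.stack([r.values for r in rdms]))
                rdm_time_ms = comp_task.time_ms
                order = cond_order
            timings[f"subject_{s}"] = time.perf_counter() - t0
            log.info("subject %d done in %.1f s", s, timings[f"subject_{s}"])

        stage = "decode"
        if task_curves:
            rio.save_timecourse_csv(task_curves, out_dir / "decoding_task.csv")
            rio.save_timecourse_csv(cat_curves, out_dir / "decoding_category.csv")
            rec.add("decoding_task", out_dir / "decoding_task.csv", ["simulate"])
            rec.add("decoding_category", out_dir / "decoding_category.csv",
                    ["simulate"])
            if within_curves:
                rio.save_timecourse_csv(within_curves,
                                        out_dir / "decoding_within_tasktype.csv")
                rio.save_timecourse_csv(between_curves,
                                        out_dir / "decoding_between_tasktype.csv")
                rec.add("decoding_within_tasktype",
                        out_dir / "decoding_within_tasktype.csv", ["simulate"])
                rec.add("decoding_between_tasktype",
                        out_dir / "decoding_between_tasktype.csv", ["simulate"])

        stage = "tempgen"
        if tg_mats:
            rio.save_tg_matrix_csv(tg_mats, out_dir / "tempgen_task.csv")
            rec.add("tempgen_task", out_dir / "tempgen_task.csv", ["simulate"])

        stage = "fuse"
        fusion_result = None
        group_rdms = None
        fmri_rdms = None
        if subject_rdm_stacks:
            mean_stack = np.mean(subject_rdm_stacks, axis=0)
            group_rdms = [RDM(m, list(order), label=float(tm))
                          for m, tm in zip(mean_stack, rdm_time_ms)]
            rio.save_rdm_csv(group_rdms[len(group_rdms) // 2],
                             out_dir / "group_rdm_mid.csv")
            rec.add("group_rdm_mid", out_dir / "group_rdm_mid.csv",
                    ["simulate"])

            if "fuse" in stages:
                fsec = config.fusion
                roi_set = generate_roi_pattern_set(
                    {k: tuple(v) for k, v in fsec.rois.items()},
                    n_units=fsec.n_units, seed=config.stage_seed("fmri"))
                fmri_rdms = {name: compute_rdm(roi.patterns, order, label=name)
                             for name, roi in roi_set.rois.items()}
                fusion_result = run_fusion(group_rdms, fmri_rdms,
                                           model_rdm("task", order),
                                           model_rdm("category", order))
                rio.save_fusion_csv(fusion_result, out_dir / "fusion.csv")
                rec.add("fusion", out_dir / "fusion.csv", ["group_rdm_mid"])

        stage = "stats"
        if "stats" in stages and task_curves:
            ssec = config.stats
            t0 = time.perf_counter()
            task_stack = np.stack([c.accuracy for c in task_curves])
            cat_stack = np.stack([c.accuracy for c in cat_curves])
            task_mask = (time_ms >= 0) & (time_ms <= RESPONSE_SCREEN_MS)
            cat_mask = (time_ms >= STIMULUS_ONSET_MS) & \
                (time_ms <= RESPONSE_SCREEN_MS)
            res_task = sign_permutation_cluster_1d(
                task_stack, 50.0, alpha=ssec.alpha,
                max_exhaustive=ssec.max_exhaustive, n_perm=ssec.n_perm_1d,
                seed=config.stage_seed("stats_task"), time_mask=task_mask)
            res_cat = sign_permutation_cluster_1d(
                cat_stack, 50.0, alpha=ssec.alpha,
                max_exhaustive=ssec.max_exhaustive, n_perm=ssec.n_perm_1d,
                seed=config.stage_seed("stats_cat"), time_mask=cat_mask)
            _cluster_table(res_task, time_ms).to_csv(
                out_dir / "clusters_task.csv", index=False)
            _cluster_table(res_cat, time_ms).to_csv(
                out_dir / "clusters_category.csv", index=False)
            rec.add("clusters_task", out_dir / "clusters_task.csv",
                    ["decoding_task"])
            rec.add("clusters_category", out_dir / "clusters_category.csv",
                    ["decoding_category"])

            if tg_mats:
                tg_stack = np.stack([m.accuracy for m in tg_mats])
                n_subj = tg_stack.shape[0]
                res_tg = cluster_2d(tg_stack, 50.0,
                                    n_perm=min(ssec.n_perm_2d, 2 ** n_subj),
                                    alpha=ssec.alpha,
                                    seed=config.stage_seed("stats_tg"))
                _cluster_table(res_tg, tg_mats[0].time_ms).to_csv(
                    out_dir / "clusters_tempgen.csv", index=False)
                rec.add("clusters_tempgen", out_dir / "clusters_tempgen.csv",
                        ["tempgen_task"])

            if fusion_result is not None:
                fus_clusters = rdm_randomization_cluster(
                    group_rdms, fmri_rdms, model_rdm("task", order),
                    model_rdm("category", order), statistic="c_task",
                    n_perm=ssec.n_perm_rdm, alpha=ssec.alpha,
                    seed=config.stage_seed("stats_fusion"))
                frames = []
                for roi, resr in fus_clusters.items():
                    tbl = _cluster_table(resr, rdm_time_ms)
                    tbl.insert(0, "roi", roi)
                    frames.append(tbl)
                pd.concat(frames).to_csv(out_dir / "clusters_fusion.csv",
                                         index=False)
                rec.add("clusters_fusion", out_dir / "clusters_fusion.csv",
                        ["fusion"])

            peak_rows = []
            for name, stack, mask in (("task", task_stack, task_mask),
                                      ("category", cat_stack, cat_mask)):
                tw = time_ms[mask]
                ci = bootstrap_peak_ci(stack, time_ms, (tw[0], tw[-1]),
                                       n_boot=ssec.n_boot, mode="peak",
                                       seed=config.stage_seed("boot_" + name))
                peak_rows.append((name, ci.estimate_ms, ci.ci_low_ms,
                                  ci.ci_high_ms, ci.n_boot))
            pd.DataFrame(peak_rows, columns=[
                "factor", "peak_ms", "ci_low_ms", "ci_high_ms",
                "n_boot"]).to_csv(out_dir / "peak_latencies.csv", index=False)
            rec.add("peak_latencies", out_dir / "peak_latencies.csv",
                    ["decoding_task", "decoding_category"])
            timings["stats"] = time.perf_counter() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()

    timings["total"] = time.perf_counter() - t_all
    bundle = ResultBundle(str(out_dir), rec.files, rec.provenance, timings)
    bundle.save()
    return bundle


def load_bundle(out_dir) -> ResultBundle:
    """Load a bundle manifest and verify every checksum."""
    out_dir = Path(out_dir)
    d = json.loads((out_dir / "bundle.json").read_text())
    bundle = ResultBundle(str(out_dir), d["files"], d["provenance"],
                          d.get("timings_s", {}))
    bundle.verify()
    return bundle
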