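"""End-to-end pipeline: generation, cleaning, statistics, modelling, report.

A :class:`RunConfig` describes one reproducible run.  A single master seed
fans out to every stochastic stage through a counter-based derivation
(stage name + index hashed to a 31-bit seed), so adding a stage never
perturbs another stage's random stream.  ``run_pipeline`` executes the
stages in dependency order into a run directory, persisting the config
verbatim plus a manifest of seeds, library versions and output checksums;
``make_report`` condenses a completed run into summary tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    group_bias_test,
    icc_oneway,
    individual_bias,
    percept_time_fractions,
    segment_percepts,
)
from .containers import ChannelInfo, EventLog, Recording
from .granger import (
    Hierarchy,
    asymmetry_spectra,
    asymmetry_test,
    equalize_counts,
    extract_trials,
    group_bias,
    percept_difference_test,
    spectral_cluster_test,
)
from .hpc import HierarchicalPerceptModel, ModelParams
from .preprocess import (
    EnvelopeSeries,
    common_average_reference,
    detect_heartbeats,
    detrend_notch,
    extract_high_gamma,
    lowpass_downsample,
    remove_heartbeat_artifact,
)
from .switch_maintain import build_periods, classify_recording, overlap_test
from .synthetic import (
    ArtifactParams,
    CouplingSpec,
    PerceptScheduleParams,
    gen_event_locked_gamma,
    gen_percept_schedule,
    gen_var_recording,
    inject_artifacts,
)
from .varfit import select_order

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineError",
    "derive_seed",
    "run_pipeline",
    "make_report",
    "STAGES",
]

STAGES = ("gen-data", "preprocess", "behavior", "classify", "granger", "simulate-model")

# demo montage: three occipital, three temporal, two frontal channels with
# switch channels placed dorsally relative to maintain channels
CHANNEL_GROUPS = (
    "occipital", "occipital", "occipital",
    "temporal", "temporal", "temporal",
    "frontal", "frontal",
)
CHANNEL_XYZ = (
    (-20.0, -90.0, 18.0), (-18.0, -88.0, 4.0), (-25.0, -85.0, -6.0),
    (-55.0, -30.0, 12.0), (-60.0, -25.0, -2.0), (-58.0, -20.0, -12.0),
    (-35.0, 40.0, 22.0), (-40.0, 45.0, 8.0),
)
SWITCH_BOOST_CHANNELS = (0, 3, 6)
MAINTAIN_BOOST_CHANNELS = (2, 5)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """31-bit seed derived from the master seed, a stage name and a counter."""
    h = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all stochastic stages seeded)."""

    out_dir: str = "runs/demo"
    master_seed: int = 0
    # behavioral cohort
    images: tuple = ("image1", "image2")
    n_participants: int = 8
    n_presentations: int = 2
    presentation_length_s: float = 60.0
    mean_duration_preferred_s: float = 8.0
    mean_duration_nonpreferred_s: float = 5.0
    p_unsure: float = 0.0
    # synthetic recording (participant 0 of each image)
    fs_raw: float = 512.0
    fs_analysis: float = 256.0
    coupling_gain: float = 0.4
    heart_artifact_scale: float = 2.0
    line_amplitude: float = 2.0
    gamma_boost_factor: float = 2.0
    # directed-flow analysis
    trial_len_s: float = 0.25
    maintain_margin_s: float = 1.0
    max_order: int = 6
    n_perm: int = 200
    freq_resolution_hz: float = 2.0
    # model simulation
    model_steps: int = 200_000
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = tuple(self.images)
        if self.n_perm < 1 or self.model_steps < 1:
            raise ValueError("n_perm and model_steps must be positive")
        if self.fs_analysis > self.fs_raw:
            raise ValueError("fs_analysis must not exceed fs_raw")

    @property
    def run_dir(self) -> Path:
        return Path(self.out_dir)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["images"] = list(self.images)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# file layout helpers
# ---------------------------------------------------------------------------

def _events_path(cfg: RunConfig, image: str, participant: int) -> Path:
    return cfg.run_dir / "events" / f"{image}_p{participant:02d}.csv"


def _raw_path(cfg: RunConfig, image: str) -> Path:
    return cfg.run_dir / "raw" / f"{image}.h5"


def _ecg_path(cfg: RunConfig, image: str) -> Path:
    return cfg.run_dir / "raw" / f"{image}_ecg.csv"


def _clean_path(cfg: RunConfig, image: str) -> Path:
    return cfg.run_dir / "clean" / f"{image}.h5"


def _env_path(cfg: RunConfig, image: str) -> Path:
    return cfg.run_dir / "clean" / f"{image}_envelope.h5"


def _require(stage: str, path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            stage, f"missing input artifact {path} (produced by stage '{producer}')"
        )
    return path


def _load_events(cfg: RunConfig, image: str, participant: int, stage: str) -> EventLog:
    path = _require(stage, _events_path(cfg, image, participant), "gen-data")
    return EventLog.from_csv(path, presentation_length=cfg.presentation_length_s)


def _save_envelope(env: EnvelopeSeries, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("log_amplitude", data=env.log_amplitude)
        f.create_dataset("fs", data=float(env.fs))
        f.create_dataset("block_boundaries", data=env.block_boundaries)


def _load_envelope(path: Path) -> EnvelopeSeries:
    with h5py.File(path, "r") as f:
        return EnvelopeSeries(
            log_amplitude=f["log_amplitude"][()],
            fs=float(f["fs"][()]),
            block_boundaries=f["block_boundaries"][()],
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_gen_data(cfg: RunConfig) -> list[Path]:
    """Generate percept schedules for the cohort and raw recordings."""
    out: list[Path] = []
    (cfg.run_dir / "events").mkdir(parents=True, exist_ok=True)
    (cfg.run_dir / "raw").mkdir(parents=True, exist_ok=True)
    g = cfg.coupling_gain
    for image in cfg.images:
        for p in range(cfg.n_participants):
            params = PerceptScheduleParams(
                presentation_length=cfg.presentation_length_s,
                n_presentations=cfg.n_presentations,
                mean_duration_preferred=cfg.mean_duration_preferred_s,
                mean_duration_nonpreferred=cfg.mean_duration_nonpreferred_s,
                p_unsure=cfg.p_unsure,
                seed=derive_seed(cfg.master_seed, f"events-{image}", p),
            )
            events = gen_percept_schedule(params)
            path = _events_path(cfg, image, p)
            events.to_csv(path)
            out.append(path)

        # recording for participant 0: percept-dependent directed coupling
        events0 = _load_events(cfg, image, 0, "gen-data")
        spec = CouplingSpec(
            n_channels=len(CHANNEL_GROUPS),
            channel_groups=list(CHANNEL_GROUPS),
            directed_gains={
                "baseline": {
                    ("occipital", "temporal"): g / 2,
                    ("temporal", "occipital"): g / 2,
                    ("temporal", "frontal"): g / 2,
                    ("frontal", "temporal"): g / 2,
                },
                # preferred percept: feedback (higher -> lower) dominates
                "A": {
                    ("temporal", "occipital"): g,
                    ("frontal", "temporal"): g,
                    ("occipital", "temporal"): g / 4,
                    ("temporal", "frontal"): g / 4,
                },
                # non-preferred percept: feedforward dominates
                "B": {
                    ("occipital", "temporal"): g,
                    ("temporal", "frontal"): g,
                    ("temporal", "occipital"): g / 4,
                    ("frontal", "temporal"): g / 4,
                },
            },
            fs=cfg.fs_raw,
            seed=derive_seed(cfg.master_seed, f"var-{image}"),
        )
        rec = gen_var_recording(spec, events=events0)
        gamma_sw = gen_event_locked_gamma(
            events0, cfg.fs_raw, rec.n_channels,
            boost_channels=SWITCH_BOOST_CHANNELS, boost_sign="switch",
            boost_factor=cfg.gamma_boost_factor,
            seed=derive_seed(cfg.master_seed, f"gamma-switch-{image}"),
        )
        gamma_mt = gen_event_locked_gamma(
            events0, cfg.fs_raw, rec.n_channels,
            boost_channels=MAINTAIN_BOOST_CHANNELS, boost_sign="maintain",
            boost_factor=cfg.gamma_boost_factor,
            seed=derive_seed(cfg.master_seed, f"gamma-maintain-{image}"),
        )
        n = min(rec.n_samples, gamma_sw.n_samples)
        data = rec.data[:, :n].copy()
        for ch in range(rec.n_channels):
            src = gamma_mt if ch in MAINTAIN_BOOST_CHANNELS else gamma_sw
            data[ch] += src.data[ch, :n]
        channels = [
            ChannelInfo(label=f"ch{i}", group=CHANNEL_GROUPS[i], xyz=CHANNEL_XYZ[i])
            for i in range(rec.n_channels)
        ]
        combined = Recording(data=data, fs=cfg.fs_raw, channels=channels)
        inj = inject_artifacts(combined, ArtifactParams(
            artifact_scale=cfg.heart_artifact_scale,
            line_amplitude=cfg.line_amplitude,
            seed=derive_seed(cfg.master_seed, f"artifacts-{image}"),
        ))
        raw_path = _raw_path(cfg, image)
        inj.recording.to_hdf5(raw_path)
        ecg_path = _ecg_path(cfg, image)
        pd.DataFrame({"ecg": inj.ecg}).to_csv(ecg_path, index=False)
        out += [raw_path, ecg_path]
    return out


def stage_preprocess(cfg: RunConfig) -> list[Path]:
    """Clean each raw recording and extract analysis-ready signals."""
    out: list[Path] = []
    (cfg.run_dir / "clean").mkdir(parents=True, exist_ok=True)
    for image in cfg.images:
        raw = Recording.from_hdf5(_require("preprocess", _raw_path(cfg, image), "gen-data"))
        ecg = pd.read_csv(_require("preprocess", _ecg_path(cfg, image), "gen-data"))["ecg"].to_numpy()
        events = _load_events(cfg, image, 0, "preprocess")
        bounds = np.array(sorted(
            int(round(events.presentation_onsets[pid] * raw.fs))
            for pid in events.presentation_ids
        ))
        rec = detrend_notch(raw, block_boundaries=bounds)
        beats = detect_heartbeats(ecg, raw.fs)
        rec = remove_heartbeat_artifact(rec, beats)
        rec = common_average_reference(rec)
        env = extract_high_gamma(rec, block_boundaries=bounds)
        env_path = _env_path(cfg, image)
        _save_envelope(env, env_path)
        clean = lowpass_downsample(rec, cutoff=50.0, fs_new=cfg.fs_analysis)
        clean_path = _clean_path(cfg, image)
        clean.to_hdf5(clean_path)
        out += [env_path, clean_path]
    return out


def stage_behavior(cfg: RunConfig) -> list[Path]:
    """Percept-time fractions and bias statistics across the cohort."""
    frac_rows, bias_rows = [], []
    for image in cfg.images:
        frac_a, frac_b = [], []
        per_presentation = np.zeros((cfg.n_participants, cfg.n_presentations))
        for p in range(cfg.n_participants):
            events = _load_events(cfg, image, p, "behavior")
            periods = segment_percepts(events)
            fr = percept_time_fractions(periods)
            frac_a.append(fr.get("A", 0.0))
            frac_b.append(fr.get("B", 0.0))
            frac_rows.append({
                "image": image, "participant": p,
                **{f"pct_{k}": v for k, v in sorted(fr.items())},
            })
            for pid in range(cfg.n_presentations):
                sub = [q for q in periods if q.presentation_id == pid]
                fr_pid = percept_time_fractions(sub) if sub else {}
                per_presentation[p, pid] = fr_pid.get("A", 0.0)
        group = group_bias_test(np.array(frac_a), np.array(frac_b))
        events0 = _load_events(cfg, image, 0, "behavior")
        indiv = individual_bias(segment_percepts(events0))
        icc, f_stat, (df_b, df_w), icc_p = icc_oneway(per_presentation)
        bias_rows.append({
            "image": image,
            "group_w": group.statistic, "group_z": group.z, "group_p": group.p,
            "group_preferred": group.preferred_code, "group_n": group.n_pairs,
            "indiv0_z": indiv.z, "indiv0_p": indiv.p, "indiv0_n": indiv.n_pairs,
            "icc": icc, "icc_f": f_stat, "icc_df_b": df_b, "icc_df_w": df_w,
            "icc_p": icc_p,
        })
    bdir = cfg.run_dir / "behavior"
    bdir.mkdir(parents=True, exist_ok=True)
    f1, f2 = bdir / "fractions.csv", bdir / "bias.csv"
    pd.DataFrame(frac_rows).to_csv(f1, index=False)
    pd.DataFrame(bias_rows).to_csv(f2, index=False)
    return [f1, f2]


def stage_classify(cfg: RunConfig) -> list[Path]:
    """Switch/maintain classification of every channel, per image."""
    out: list[Path] = []
    cdir = cfg.run_dir / "classify"
    cdir.mkdir(parents=True, exist_ok=True)
    for image in cfg.images:
        env = _load_envelope(_require("classify", _env_path(cfg, image), "preprocess"))
        events = _load_events(cfg, image, 0, "classify")
        periods = build_periods(events, maintain_margin_s=cfg.maintain_margin_s)
        cls = classify_recording(env, periods)
        df = pd.DataFrame([{
            "channel": c.channel, "group": CHANNEL_GROUPS[c.channel],
            "label": c.label, "t": c.t, "p": c.p, "n_pairs": c.n_pairs,
        } for c in cls])
        path = cdir / f"{image}.csv"
        df.to_csv(path, index=False)
        out.append(path)
    return out


def _maintain_periods_abs(events: EventLog, margin_s: float) -> list[tuple[float, float, str]]:
    """Absolute-time maintain windows (1 s clear of presses), labeled by percept."""
    out = []
    for q in segment_percepts(events):
        onset = events.presentation_onsets[q.presentation_id]
        a, b = onset + q.start_s + margin_s, onset + q.end_s - margin_s
        if b > a and q.percept_code in ("A", "B"):
            out.append((a, b, q.percept_code))
    return out


def stage_granger(cfg: RunConfig) -> list[Path]:
    """Directed-flow analysis: pairwise GC with permutation calls."""
    out: list[Path] = []
    gdir = cfg.run_dir / "granger"
    gdir.mkdir(parents=True, exist_ok=True)
    hier = Hierarchy()
    for image in cfg.images:
        rec = Recording.from_hdf5(_require("granger", _clean_path(cfg, image), "preprocess"))
        events = _load_events(cfg, image, 0, "granger")
        periods = _maintain_periods_abs(events, cfg.maintain_margin_s)
        trials = extract_trials(rec, periods, trial_len_s=cfg.trial_len_s)
        if trials.data.shape[0] < 20:
            raise PipelineError("granger", f"only {trials.data.shape[0]} trials for {image}")
        pairs = [
            (i, j) for i in range(rec.n_channels) for j in range(rec.n_channels)
            if hier.direction(rec.groups[i], rec.groups[j]) == "ff"
        ]
        order, _ = select_order([trials.pair(i, j).data for i, j in pairs], cfg.max_order)
        rng = np.random.default_rng(derive_seed(cfg.master_seed, f"granger-{image}"))
        rows, records, spectra_list = [], [], []
        freqs = None
        for i, j in pairs:
            pt = trials.pair(i, j)
            asym = asymmetry_test(pt.data, order, n_perm=cfg.n_perm, seed=rng)
            freqs, spec = asymmetry_spectra(
                pt.data, order, rec.fs, n_perm=cfg.n_perm, seed=rng,
                resolution=cfg.freq_resolution_hz,
            )
            spectra_list.append(spec)
            a_tr, b_tr = equalize_counts(pt.select("A"), pt.select("B"))
            pd_xy, pd_yx = percept_difference_test(
                a_tr, b_tr, order, n_perm=cfg.n_perm, seed=rng
            )
            group_pair = (rec.groups[i], rec.groups[j])
            records.append((group_pair, asym.call))
            rows.append({
                "image": image, "src": i, "dst": j,
                "src_group": group_pair[0], "dst_group": group_pair[1],
                "order": order, "gc_ff": asym.gc_ff, "gc_fb": asym.gc_fb,
                "asymmetry": asym.asymmetry, "asym_call": asym.call, "asym_p": asym.p,
                "pd_ff_call": pd_xy.call, "pd_ff_p": pd_xy.p,
                "pd_fb_call": pd_yx.call, "pd_fb_p": pd_yx.p,
            })
        pairs_path = gdir / f"{image}_pairs.csv"
        pd.DataFrame(rows).to_csv(pairs_path, index=False)
        bias = group_bias(records)
        bias_path = gdir / f"{image}_group_bias.csv"
        pd.DataFrame([{
            "image": image, "src_group": b.group_pair[0], "dst_group": b.group_pair[1],
            "n_ff": b.n_dir1, "n_fb": b.n_dir2, "z": b.z, "p": b.p,
        } for b in bias]).to_csv(bias_path, index=False)
        clusters = spectral_cluster_test(spectra_list, freqs)
        clus_path = gdir / f"{image}_clusters.csv"
        pd.DataFrame([{
            "image": image, "start_hz": c.start_hz, "end_hz": c.end_hz,
            "sign": c.sign, "size": c.size, "corrected_p": c.corrected_p,
            "significant": c.significant,
        } for c in clusters]).to_csv(clus_path, index=False)
        out += [pairs_path, bias_path, clus_path]
    return out


def stage_simulate_model(cfg: RunConfig) -> list[Path]:
    """Simulate the hierarchical predictive-coding attractor model."""
    mdir = cfg.run_dir / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    params = ModelParams(**cfg.model_params)
    model = HierarchicalPerceptModel(params)
    res = model.simulate(cfg.model_steps, seed=derive_seed(cfg.master_seed, "model"))
    ep_path = mdir / "episodes.csv"
    res.episodes().to_csv(ep_path, index=False)
    flows = res.flow_summary().table
    fl_path = mdir / "flows.csv"
    flows.to_csv(fl_path)
    ds = res.duration_stats()
    stats_path = mdir / "stats.json"
    stats_path.write_text(json.dumps({
        "median_preferred_s": ds["median_preferred_s"],
        "median_nonpreferred_s": ds["median_nonpreferred_s"],
        "ranksum_z": ds["ranksum_z"], "ranksum_p": ds["ranksum_p"],
        "n_preferred": len(ds["preferred_durations"]),
        "n_nonpreferred": len(ds["nonpreferred_durations"]),
    }, indent=2))
    return [ep_path, fl_path, stats_path]


_STAGE_FUNCS = {
    "gen-data": stage_gen_data,
    "preprocess": stage_preprocess,
    "behavior": stage_behavior,
    "classify": stage_classify,
    "granger": stage_granger,
    "simulate-model": stage_simulate_model,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, stages: tuple = STAGES) -> Path:
    """Execute the requested stages in dependency order into the run directory.

    Persists the config verbatim and a manifest (package and library
    versions, per-stage seeds, output checksums).  A stage failure raises a
    stage-tagged :class:`PipelineError`; outputs of completed stages are
    retained.
    """
    import scipy

    run_dir = cfg.run_dir
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    manifest = {
        "versions": {
            "bistableflow": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "master_seed": cfg.master_seed,
        "stages": {},
    }
    for stage in STAGES:  # fixed dependency order regardless of request order
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](cfg)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        manifest["stages"][stage] = {
            "seed": derive_seed(cfg.master_seed, stage),
            "outputs": {
                str(p.relative_to(run_dir)): _sha256(p) for p in outputs
            },
        }
        # write after every stage so partial runs keep a usable manifest
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def make_report(run_dir: str | Path) -> Path:
    """Condense a run directory into summary tables plus a markdown index.

    Missing stage outputs are skipped with a notice.  Regeneration is
    idempotent: the report depends only on the run directory contents.
    """
    run_dir = Path(run_dir)
    rep = run_dir / "report"
    rep.mkdir(parents=True, exist_ok=True)
    sections: list[str] = ["# Run report\n"]

    bias_csv = run_dir / "behavior" / "bias.csv"
    if bias_csv.exists():
        df = pd.read_csv(bias_csv)
        df.to_csv(rep / "behavior_bias.csv", index=False)
        sections.append("## Behavioral bias per image\n\n" + df.to_markdown(index=False) + "\n")
    else:
        logger.warning("behavior outputs missing: bias table skipped")

    cls_files = sorted((run_dir / "classify").glob("*.csv")) if (run_dir / "classify").exists() else []
    if len(cls_files) >= 2:
        l1 = pd.read_csv(cls_files[0])["label"].tolist()
        l2 = pd.read_csv(cls_files[1])["label"].tolist()
        chi2, df_, p, observed, expected = overlap_test(l1, l2)
        labels = ["switch", "maintain", "ns"]
        obs = pd.DataFrame(observed, index=labels, columns=labels)
        exp = pd.DataFrame(expected, index=labels, columns=labels)
        obs.to_csv(rep / "classification_overlap_observed.csv")
        exp.to_csv(rep / "classification_overlap_expected.csv")
        sections.append(
            "## Classification overlap across images\n\n"
            f"chi2 = {chi2:.3f}, df = {df_}, p = {p:.4f}\n\n"
            + obs.to_markdown() + "\n"
        )
    else:
        logger.warning("need classification for two images: overlap table skipped")

    gdir = run_dir / "granger"
    if gdir.exists():
        gb = sorted(gdir.glob("*_group_bias.csv"))
        if gb:
            df = pd.concat([pd.read_csv(f) for f in gb], ignore_index=True)
            df.to_csv(rep / "granger_group_bias.csv", index=False)
            sections.append("## Directed group bias\n\n" + df.to_markdown(index=False) + "\n")
        cl = sorted(gdir.glob("*_clusters.csv"))
        frames = [pd.read_csv(f) for f in cl]
        frames = [f for f in frames if not f.empty]
        if frames:
            df = pd.concat(frames, ignore_index=True)
            df.to_csv(rep / "granger_clusters.csv", index=False)
            sections.append("## Frequency clusters\n\n" + df.to_markdown(index=False) + "\n")
    else:
        logger.warning("granger outputs missing: flow tables skipped")

    stats_json = run_dir / "model" / "stats.json"
    if stats_json.exists():
        stats = json.loads(stats_json.read_text())
        flows = pd.read_csv(run_dir / "model" / "flows.csv", index_col=0)
        pd.DataFrame([stats]).to_csv(rep / "model_durations.csv", index=False)
        flows.to_csv(rep / "model_flows.csv")
        sections.append(
            "## Model simulation\n\n"
            f"median preferred {stats['median_preferred_s']:.2f} s vs "
            f"nonpreferred {stats['median_nonpreferred_s']:.2f} s "
            f"(rank-sum p = {stats['ranksum_p']:.2e})\n\n"
            + flows.to_markdown() + "\n"
        )
    else:
        logger.warning("model outputs missing: model tables skipped")

    (rep / "report.md").write_text("\n".join(sections))
    return rep
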