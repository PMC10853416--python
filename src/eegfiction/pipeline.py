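"""End-to-end orchestration: simulate -> preprocess -> features -> stats
-> SOM -> report, from one config file.

Each stage reads only on-disk artifacts written by its predecessors and
writes only its declared outputs under the run directory, so deleting a
downstream artifact and rerunning just that stage reproduces it
bit-identically.  A run manifest (config hash, per-file digests, seeds,
counts) is written last.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from . import preprocess as pp
from . import som as esom
from . import spectral as spc
from . import stats as est
from .simulate import DesignSpec, EffectSpec, NoiseSpec, generate_design, synthesize_recording
from .io import ContractError

__all__ = ["PipelineConfig", "RunManifest", "run", "report", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "stats", "som", "report")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 1999
    fdr_q: float = 0.05
    unit: str = "stimulus"
    pooling: str = "all"
    exclude_channels: tuple[str, ...] = ("Fp2",)
    seed_offset: int = 3


@dataclass
class PreprocessConfig:
    filter: pp.FilterSpec = field(default_factory=pp.FilterSpec)
    reject_z_threshold: float = 5.0
    ica: bool = True
    artifact_threshold: float = 0.85
    seed_offset: int = 2


@dataclass
class SomStageConfig:
    som: esom.SOMConfig = field(default_factory=esom.SOMConfig)
    train_fraction: float = 0.7
    exclude_channels: tuple[str, ...] = ()
    seed_offset: int = 4


@dataclass
class PipelineConfig:
    """One run: exactly one of simulation mode (a DesignSpec) or real-data
    mode (input recording paths + metadata table) is active."""

    out_dir: Path
    design: DesignSpec | None = None
    input_recordings: tuple[str, ...] = ()
    input_metadata: str | None = None
    window: pp.WindowSpec = field(default_factory=pp.WindowSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    som: SomStageConfig = field(default_factory=SomStageConfig)
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        simulation = self.design is not None
        real = bool(self.input_recordings)
        if simulation == real:
            raise ContractError(
                "exactly one of simulation mode (design) and real-data mode "
                "(input_recordings) must be active"
            )
        if real and not self.input_metadata:
            raise ContractError("real-data mode requires input_metadata")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ContractError(f"unknown stages: {bad}")

    def stage_seed(self, offset: int) -> int:
        return (self.seed * 1009 + offset) % 2**31

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a TOML or JSON config; unknown keys raise a validation
        error naming them."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)

        def build(klass, data: dict):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ContractError(
                    f"unknown config keys for {klass.__name__}: {sorted(unknown)}"
                )
            return klass(**data)

        if "design" in raw and raw["design"] is not None:
            d = dict(raw["design"])
            if "noise" in d:
                d["noise"] = build(NoiseSpec, d["noise"])
            if "effects" in d:
                d["effects"] = tuple(
                    build(EffectSpec, e) for e in d["effects"]
                )
            if "montage" in d:
                d["montage"] = eio.Montage(tuple(d["montage"]))
            if "trial_pattern" in d:
                d["trial_pattern"] = tuple(d["trial_pattern"])
            if "stimulus_duration_s" in d:
                d["stimulus_duration_s"] = tuple(d["stimulus_duration_s"])
            raw["design"] = build(DesignSpec, d)
        if "window" in raw:
            raw["window"] = build(pp.WindowSpec, raw["window"])
        if "preprocess" in raw:
            p = dict(raw["preprocess"])
            if "filter" in p:
                p["filter"] = build(pp.FilterSpec, p["filter"])
            raw["preprocess"] = build(PreprocessConfig, p)
        if "stats" in raw:
            s = dict(raw["stats"])
            if "exclude_channels" in s:
                s["exclude_channels"] = tuple(s["exclude_channels"])
            raw["stats"] = build(StatsConfig, s)
        if "som" in raw:
            s = dict(raw["som"])
            if "som" in s:
                s["som"] = build(esom.SOMConfig, s["som"])
            if "exclude_channels" in s:
                s["exclude_channels"] = tuple(s["exclude_channels"])
            raw["som"] = build(SomStageConfig, s)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "input_recordings" in raw:
            raw["input_recordings"] = tuple(raw["input_recordings"])
        return build(cls, raw)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict
    digests: dict
    counts: dict
    timestamps: dict

    def to_json(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))
        return path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _recording_paths(out: Path) -> list[Path]:
    return sorted((out / "recordings").glob("*.json"))


def _clean_paths(out: Path) -> list[Path]:
    return sorted((out / "clean").glob("*.json"))


def run(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest."""
    from . import __version__

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    counts: dict[str, int] = {}
    timestamps: dict[str, str] = {}
    seeds = {"master": config.seed}

    def done(stage: str, paths: list[Path]) -> None:
        for p in paths:
            digests[str(p.relative_to(out))] = _digest(p)
        timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        logger.info("stage %s complete (%d artifacts)", stage, len(paths))

    if "simulate" in config.stages:
        stage_dir = out / "recordings"
        stage_dir.mkdir(exist_ok=True)
        if config.design is None:
            raise ContractError("simulate stage requires simulation mode")
        design = dataclasses.replace(
            config.design, seed=config.stage_seed(1)
        )
        seeds["simulate"] = design.seed
        paths = []
        metas = []
        n_stimuli = 0
        for meta, schedule in generate_design(design):
            rec = synthesize_recording(meta, schedule, design)
            jp, dp = eio.write_native(rec, stage_dir / meta.participant_id)
            paths += [jp, dp]
            metas.append(meta)
            n_stimuli += len(schedule)
        mpath = eio.write_metadata_table(metas, out / "metadata.tsv")
        counts["participants"] = len(metas)
        counts["stimuli"] = n_stimuli
        done("simulate", paths + [mpath])

    if "preprocess" in config.stages:
        stage_dir = out / "clean"
        stage_dir.mkdir(exist_ok=True)
        pcfg = config.preprocess
        seeds["preprocess"] = config.stage_seed(pcfg.seed_offset)
        if config.design is not None:
            inputs = _recording_paths(out)
        else:
            inputs = [Path(p) for p in config.input_recordings]
        if not inputs:
            raise ContractError("preprocess: no input recordings found")
        paths = []
        log_rows = []
        for p in inputs:
            rec = _read_any(p)
            rec = pp.apply_bandlimit(rec, pcfg.filter)
            rec, rejected = pp.reject_channels(rec, pcfg.reject_z_threshold)
            removed: list[int] = []
            if pcfg.ica:
                decomp = pp.decompose_ica(
                    rec, seed=seeds["preprocess"]
                )
                scores = pp.score_components(decomp)
                flagged = {
                    s.component_index
                    for s in scores
                    if s.artifact_class in ("eye", "muscle")
                    and s.probability >= pcfg.artifact_threshold
                }
                removed = sorted(flagged)
                rec = pp.remove_artifacts(
                    rec, decomp, scores, pcfg.artifact_threshold
                )
            jp, dp = eio.write_native(rec, stage_dir / rec.participant_id)
            paths += [jp, dp]
            log_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "rejected_channels": ",".join(rejected),
                    "removed_components": ",".join(map(str, removed)),
                }
            )
        logp = out / "preprocess_log.tsv"
        pd.DataFrame(log_rows).to_csv(logp, sep="\t", index=False)
        done("preprocess", paths + [logp])

    if "features" in config.stages:
        inputs = _clean_paths(out)
        if not inputs:
            raise ContractError("features: no cleaned recordings found")
        meta_path = (
            out / "metadata.tsv"
            if config.design is not None
            else Path(config.input_metadata)
        )
        metadata = eio.read_metadata_table(meta_path)
        meta_by_id = {m.participant_id: m for m in metadata}
        features = []
        for p in inputs:
            rec = eio.read_native(p.with_suffix(""))
            meta = meta_by_id.get(rec.participant_id)
            levels = (
                {v: meta.level(v) for v in eio.GROUP_VARIABLES} if meta else {}
            )
            segments = pp.segment_windows(rec, wspec=config.window)
            features += spc.extract_features(segments, group_levels=levels)
        fpath = eio.write_features_table(features, out / "features.tsv")
        counts["feature_rows"] = len(features)
        counts["windows"] = int(sum(f.n_windows for f in features))
        done("features", [fpath])

    if "stats" in config.stages or "som" in config.stages:
        features = eio.read_features_table(out / "features.tsv")
        meta_path = (
            out / "metadata.tsv"
            if config.design is not None
            else Path(config.input_metadata)
        )
        metadata = eio.read_metadata_table(meta_path)

    if "stats" in config.stages:
        scfg = config.stats
        seeds["stats"] = config.stage_seed(scfg.seed_offset)
        kept = [
            f for f in features if f.channel not in scfg.exclude_channels
        ]
        grid_table = est.participant_condition_psd(kept)
        grid = est.anova_grid(
            grid_table, alpha=scfg.alpha, n_perm=scfg.n_perm, seed=seeds["stats"]
        )
        gpath = out / "anova_grid.tsv"
        grid.to_csv(gpath, sep="\t", index=False)

        frame = spc.features_frame(kept)
        cascade = est.run_cascade(
            frame,
            metadata,
            q=scfg.fdr_q,
            unit=scfg.unit,
            pooling=scfg.pooling,
        )
        cpath = out / "cascade.tsv"
        cascade.to_csv(cpath, sep="\t", index=False)
        jpath = out / "stats.json"
        jpath.write_text(
            json.dumps(
                {
                    "n_grid_cells": int(grid.attrs.get("n_comparisons", len(grid))),
                    "n_grid_significant": int(grid["significant"].sum()),
                    "n_cascade_tests": int(len(cascade)),
                    "n_cascade_significant": int(
                        cascade["p_passes_fdr"].sum()
                    ) if len(cascade) else 0,
                    "adjusted_alpha": grid.attrs.get("alpha"),
                    "fdr_adjusted_alpha": cascade.attrs.get("adjusted_alpha"),
                },
                indent=1,
            )
        )
        counts["cascade_tests"] = int(len(cascade))
        done("stats", [gpath, cpath, jpath])

    if "som" in config.stages:
        mcfg = config.som
        seeds["som"] = config.stage_seed(mcfg.seed_offset)
        kept = [
            f for f in features if f.channel not in mcfg.exclude_channels
        ]
        rows = _som_rows(kept)
        feature_names = [
            c for c in rows.columns
            if c not in ("participant_id", "stimulus_id", "text_type")
        ]
        train, test = esom.split_participant_holdout(
            rows, mcfg.train_fraction, seed=seeds["som"]
        )
        som_config = dataclasses.replace(mcfg.som, seed=seeds["som"])
        model = esom.train_som(train, feature_names, som_config)
        pred = esom.predict(model, test)
        rep = esom.evaluate(test["text_type"].to_numpy(), pred)
        mpath = model.to_json(out / "som_model.json")
        rpath = out / "som_report.json"
        rpath.write_text(
            json.dumps(
                {
                    "train_rows": int(len(train)),
                    "test_rows": int(len(test)),
                    "labels": list(rep.labels),
                    "confusion": rep.confusion.tolist(),
                    "f1": rep.f1,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "accuracy": rep.accuracy,
                },
                indent=1,
            )
        )
        counts["som_train_rows"] = int(len(train))
        counts["som_test_rows"] = int(len(test))
        done("som", [mpath, rpath])

    manifest = RunManifest(
        config_hash=_config_hash(config),
        version=__version__,
        seeds=seeds,
        digests=digests,
        counts=counts,
        timestamps=timestamps,
    )
    manifest.to_json(out / "manifest.json")

    if "report" in config.stages:
        rpath = out / "report.txt"
        rpath.write_text(report(out))
        timestamps["report"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    return manifest


def _read_any(path: Path) -> eio.Recording:
    if path.suffix == ".json":
        return eio.read_native(path.with_suffix(""))
    if path.suffix == ".vhdr":
        return eio.read_brainvision(path)
    if path.suffix == ".edf":
        return eio.read_edf(path)
    raise ContractError(f"unrecognized recording container: {path}")


def _som_rows(features) -> pd.DataFrame:
    """One row per stimulus: concatenated per-channel band summaries
    (relative powers + brain rate)."""
    frame = spc.features_frame(features)
    cols = [*spc.BAND_NAMES, "brain_rate"]
    wide = frame.pivot_table(
        index=["participant_id", "stimulus_id", "text_type"],
        columns="channel",
        values=cols,
    )
    wide.columns = [f"{m}_{ch}" for m, ch in wide.columns]
    return wide.reset_index()


def report(out_dir: str | Path) -> str:
    """Human-readable run summary: significant grid runs, cascade table,
    confusion matrix and F1 line."""
    out = Path(out_dir)
    lines = ["run summary", "==========="]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        m = json.loads(manifest_path.read_text())
        lines.append(f"counts: {m['counts']}")

    grid_path = out / "anova_grid.tsv"
    if grid_path.exists():
        grid = pd.read_csv(grid_path, sep="\t")
        sig = grid[grid["significant"]]
        lines.append("")
        lines.append(f"text-type ANOVA: {len(sig)}/{len(grid)} significant cells")
        for ch, sub in sig.groupby("channel"):
            freqs = sub["freq_bin_hz"].sort_values().to_numpy()
            runs = []
            start = prev = freqs[0]
            for f in freqs[1:]:
                if f - prev > 1.0001:
                    runs.append((start, prev))
                    start = f
                prev = f
            runs.append((start, prev))
            pretty = ", ".join(
                f"{a:g}" if a == b else f"{a:g}-{b:g}" for a, b in runs
            )
            lines.append(f"  {ch}: {pretty} Hz")

    cascade_path = out / "cascade.tsv"
    if cascade_path.exists():
        cas = pd.read_csv(cascade_path, sep="\t")
        sig = cas[cas["p_passes_fdr"]] if "p_passes_fdr" in cas else cas.iloc[:0]
        lines.append("")
        lines.append(
            f"group cascade: {len(sig)}/{len(cas)} significant after FDR"
        )
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['measure']:>10s} {r['group_a']} vs {r['group_b']} at "
                f"{r['site']}: p={r['p_raw']:.2e}, |d|={abs(r['cohens_d']):.2f}"
            )

    som_path = out / "som_report.json"
    if som_path.exists():
        rep = json.loads(som_path.read_text())
        lines.append("")
        lines.append("SOM confusion matrix (rows true / columns predicted):")
        labs = rep["labels"]
        lines.append("\t" + "\t".join(labs))
        for lab, row in zip(labs, rep["confusion"]):
            lines.append(lab + "\t" + "\t".join(map(str, row)))
        f1s = ", ".join(f"{k} {v:.3f}" for k, v in rep["f1"].items())
        lines.append(f"F1: {f1s}; accuracy {rep['accuracy']:.3f}")
    return "\n".join(lines) + "\n"
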