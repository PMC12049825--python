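"""End-to-end orchestration: ingest -> acoustic space -> call typing ->
moving ESC -> emergence forecasting, with per-stage CSV/JSON artifacts.

Stages communicate exclusively through documented files in the output
directory, so any stage can be re-run in isolation from the saved
intermediates of an earlier run.  The manifest records every artifact
with its SHA-256 hash plus the seed and the methodological switches in
force (normalization base, NMI variant, window convention), making runs
comparable and byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import calltypes, entropy, forecast, io, simulate, space

logger = logging.getLogger(__name__)

STAGES = ("ingest", "space", "cluster", "transitions", "esc", "forecast")


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-loadable, CLI-overridable."""

    outdir: str = "vocseq_out"
    seed: int = 0
    # input
    inputs: list[str] = field(default_factory=list)
    simulate: bool = False
    generator: dict = field(default_factory=dict)
    # acoustic space
    n_bins: int = 10
    n_slices: int = 8
    # clustering
    k_min: int = 2
    k_max: int = 20
    n_repeats: int = 10
    axes: list[str] = field(default_factory=lambda: ["activation", "modulation"])
    # permutation test
    n_perm: int = 10_000
    perm_unit: str = "block"
    block_len: int = 10
    # moving ESC
    l: int = 8
    binning: str = "equal_width_global"
    k_base: str = "log2"
    # forecasting
    models: list[str] = field(default_factory=lambda: list(forecast.MODEL_FAMILIES))
    min_train: int = 8
    run_cv: bool = True
    cv_parameter: str = "entropy_bits"
    extra_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise ValueError("config requires input paths or simulate: true")
        for p in self.inputs:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


def _out(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_sequences(config: PipelineConfig) -> list[io.CallSequence]:
    calls = _out(config) / "calls.csv"
    if not calls.exists():
        raise FileNotFoundError("calls.csv not found; run the ingest stage first")
    return io.read_call_table(calls)


def stage_ingest(config: PipelineConfig) -> list[Path]:
    """Read (or simulate) the call table, validate it, write calls.csv."""
    config.validate()
    out = _out(config)
    written = []
    if config.simulate:
        spec = simulate.GeneratorSpec(seed=config.seed, **config.generator)
        seqs, true_types = simulate.simulate_markov_calls(spec)
        truth = io.sequences_to_frame(seqs)[["subject", "session", "order"]].copy()
        truth["true_type"] = true_types
        truth.to_csv(out / "true_types.csv", index=False)
        written.append(out / "true_types.csv")
    else:
        seqs = []
        for p in config.inputs:
            dialect = "tsv" if str(p).endswith((".tsv", ".txt")) else "csv"
            seqs.extend(io.read_call_table(p, dialect=dialect))
    problems = {f"{s.subject}/{s.session}": io.validate_sequence(s) for s in seqs}
    problems = {k: v for k, v in problems.items() if v}
    if problems:
        raise ValueError(f"invalid input sequences: {problems}")
    io.write_call_table(seqs, out / "calls.csv")
    written.insert(0, out / "calls.csv")
    return written


def stage_space(config: PipelineConfig) -> list[Path]:
    """Change vectors, direction maps and slice summaries for both planes."""
    out = _out(config)
    seqs = _load_sequences(config)
    planes = {
        "activation": space.PlaneSpec(
            "duration_s", "maxfreq_hz", config.n_bins, config.n_bins
        ),
        "modulation": space.PlaneSpec(
            "freqslope_hz", "entropy_bits", config.n_bins, config.n_bins
        ),
    }
    vec_frames, map_frames, slice_frames = [], [], []
    for plane_name, plane in planes.items():
        for mode in ("absolute", "percent"):
            for seq in seqs:
                if len(seq) < 2:
                    continue
                vecs = space.change_vectors(seq, plane, mode)
                vf = space.vectors_to_frame(vecs)
                vf.insert(0, "mode", mode)
                vf.insert(0, "plane", plane_name)
                vf.insert(0, "session", seq.session)
                vf.insert(0, "subject", seq.subject)
                vec_frames.append(vf)
            for by in ("all", "subject", "session"):
                pooled = space.pooled_change_vectors(seqs, plane, mode, by)
                for group, vecs in pooled.items():
                    sl = space.slice_summary(vecs, config.n_slices)
                    sl.insert(0, "group", group)
                    sl.insert(0, "pooling", by)
                    sl.insert(0, "mode", mode)
                    sl.insert(0, "plane", plane_name)
                    slice_frames.append(sl)
        for seq in seqs:
            if len(seq) < 2:
                continue
            dmap = space.grid_direction_map(seq, plane, summary="distance")
            mf = dmap.table.copy()
            mf.insert(0, "plane", plane_name)
            mf.insert(0, "session", seq.session)
            mf.insert(0, "subject", seq.subject)
            map_frames.append(mf)
    pd.concat(vec_frames, ignore_index=True).to_csv(out / "change_vectors.csv", index=False)
    pd.concat(map_frames, ignore_index=True).to_csv(out / "direction_map.csv", index=False)
    pd.concat(slice_frames, ignore_index=True).to_csv(out / "slice_summary.csv", index=False)
    return [out / "change_vectors.csv", out / "direction_map.csv", out / "slice_summary.csv"]


def stage_cluster(config: PipelineConfig) -> list[Path]:
    """Call-type discovery per analysis axis; writes the selection curve
    and the per-call type labels."""
    out = _out(config)
    seqs = _load_sequences(config)
    sel_frames, label_frames = [], []
    n_calls = sum(len(s) for s in seqs)
    k_max = min(config.k_max, n_calls - 1)
    for axis in config.axes:
        features, _ = calltypes.axis_features(seqs, axis)
        selection = calltypes.select_cluster_model(
            features,
            k_range=range(config.k_min, k_max + 1),
            n_repeats=config.n_repeats,
            seed=config.seed,
        )
        tab = selection.table.copy()
        tab.insert(0, "axis", axis)
        tab["chosen"] = tab["k"] == selection.chosen_k
        sel_frames.append(tab)
        per_seq = calltypes.typed_sequences(selection, seqs, axis)
        for seq, labels in zip(seqs, per_seq):
            label_frames.append(
                pd.DataFrame(
                    {
                        "subject": seq.subject,
                        "session": seq.session,
                        "order": [r.order for r in seq.records],
                        "axis": axis,
                        "call_type": labels,
                        "k": selection.chosen_k,
                    }
                )
            )
    pd.concat(sel_frames, ignore_index=True).to_csv(out / "cluster_selection.csv", index=False)
    pd.concat(label_frames, ignore_index=True).to_csv(out / "call_types.csv", index=False)
    return [out / "cluster_selection.csv", out / "call_types.csv"]


def stage_transitions(config: PipelineConfig) -> list[Path]:
    """Per-subject transition tables and the between-subject NMI test."""
    out = _out(config)
    types_df = pd.read_csv(out / "call_types.csv")
    table_frames, tests = [], {}
    for axis, adf in types_df.groupby("axis"):
        k = int(adf["k"].iloc[0])
        subjects = sorted(adf["subject"].unique())
        for subject in subjects:
            sdf = adf[adf["subject"] == subject]
            label_seqs = [
                grp.sort_values("order")["call_type"].to_numpy()
                for _, grp in sdf.groupby("session")
            ]
            table = calltypes.build_transition_table(label_seqs, k)
            tf = table.to_frame()
            tf.insert(0, "subject", subject)
            tf.insert(0, "axis", axis)
            table_frames.append(tf)
        if len(subjects) == 2:
            adf = adf.sort_values(["subject", "session", "order"])
            result = calltypes.permutation_test(
                adf["call_type"].to_numpy(),
                adf["subject"].to_numpy(),
                adf["subject"].astype(str) + "/" + adf["session"].astype(str),
                n_perm=config.n_perm,
                seed=config.seed,
                unit=config.perm_unit,
                block_len=config.block_len,
            )
            tests[axis] = result.to_dict()
        else:
            logger.warning(
                "axis %s: %d subjects; the permutation test needs exactly 2",
                axis, len(subjects),
            )
    pd.concat(table_frames, ignore_index=True).to_csv(out / "transition_table.csv", index=False)
    with open(out / "nmi_test.json", "w") as fh:
        json.dump(tests, fh, indent=2)
    return [out / "transition_table.csv", out / "nmi_test.json"]


def stage_esc(config: PipelineConfig) -> list[Path]:
    """Moving emergence/self-organization/complexity per parameter."""
    out = _out(config)
    seqs = _load_sequences(config)
    spec = entropy.DiscretizationSpec(
        l=config.l, binning=config.binning, k_base=config.k_base
    )
    table = entropy.esc_table(seqs, spec)
    table.to_csv(out / "esc_series.csv", index=False)
    return [out / "esc_series.csv"]


def stage_forecast(config: PipelineConfig) -> list[Path]:
    """Model comparison by rolling-origin CV, ARFIMA fits, forecast paths
    and the depletion report for each session's emergence series."""
    out = _out(config)
    esc = pd.read_csv(out / "esc_series.csv")
    target = esc[esc["parameter"] == config.cv_parameter]
    if target.empty:
        raise ValueError(f"no ESC series for parameter {config.cv_parameter!r}")
    series = {
        (subj, sess): grp.sort_values("t")["mE"].to_numpy()
        for (subj, sess), grp in target.groupby(["subject", "session"])
    }
    written = []

    if config.run_cv:
        # CV on the first session's series; light ARFIMA search per fold
        key = sorted(series)[0]
        x = series[key]
        model_specs = [
            forecast.ForecastModelSpec(
                fam,
                {"config": forecast.ArfimaConfig(max_pq=1)} if fam == "ARFIMA" else {},
            )
            for fam in config.models
        ]
        ev = forecast.rolling_origin_cv(
            x, model_specs, h_max=len(x) // 2, min_train=config.min_train
        )
        tab = ev.table.copy()
        tab.insert(0, "session", key[1])
        tab.insert(0, "subject", key[0])
        tab.to_csv(out / "forecast_eval.csv", index=False)
        written.append(out / "forecast_eval.csv")

    fits, paths, depletion = {}, [], {}
    for (subj, sess), x in series.items():
        name = f"{subj}/{sess}"
        try:
            fit = forecast.fit_arfima(x, forecast.ArfimaConfig(max_pq=1))
        except forecast.DegenerateSeriesError as exc:
            logger.warning("skipping %s: %s", name, exc)
            continue
        path, report = forecast.forecast_emergence(
            fit, x, extra_fraction=config.extra_fraction
        )
        fits[name] = fit.to_dict()
        path = path.copy()
        path.insert(0, "session", sess)
        path.insert(0, "subject", subj)
        paths.append(path)
        depletion[name] = report.to_dict()
    with open(out / "arfima_fit.json", "w") as fh:
        json.dump(fits, fh, indent=2)
    pd.concat(paths, ignore_index=True).to_csv(out / "forecast_path.csv", index=False)
    with open(out / "depletion_report.json", "w") as fh:
        json.dump(depletion, fh, indent=2)
    written += [out / "arfima_fit.json", out / "forecast_path.csv", out / "depletion_report.json"]
    return written


_STAGE_FUNCS = {
    "ingest": stage_ingest,
    "space": stage_space,
    "cluster": stage_cluster,
    "transitions": stage_transitions,
    "esc": stage_esc,
    "forecast": stage_forecast,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = STAGES) -> dict:
    """Execute the requested stages in order and write the manifest."""
    config.validate()
    out = _out(config)
    logger.info(
        "run: seed=%d l=%d k_base=%s nmi=jsd perm_unit=%s window=drop-first(n-l)",
        config.seed, config.l, config.k_base, config.perm_unit,
    )
    artifacts: list[Path] = []
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            artifacts.extend(_STAGE_FUNCS[stage](config))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "switches": {
            "k_base": config.k_base,
            "nmi_variant": "table-identity JSD",
            "window_convention": "drop first window (length n - l)",
            "perm_unit": config.perm_unit,
        },
        "artifacts": {str(p.name): _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
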