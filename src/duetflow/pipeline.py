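"""Study-level orchestration: manifest in, result tables and report out.

A *study manifest* (YAML-serialisable dict) lists, per piece and per
participant, a recording track, a performance track (WAV audio or
precomputed envelope CSV) and the trial boundaries.  The pipeline then
runs, per trial, envelope extraction -> per-trial AIC order selection ->
per-participant maximum order -> Granger causality in both directions ->
lagged cross-correlation; and per piece, the direction test, the
mixed-model trial trends, the linear contrasts and the optimal-lag sign
tally.  The analysis path contains no randomness: rerunning the same
manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lagcorr, trend, vargc
from .envelope import Envelope, extract_envelope, read_envelope_csv, read_wav, segment_trials

__all__ = [
    "AnalysisOptions",
    "ResultsBundle",
    "load_manifest",
    "run_study_analysis",
    "analyse_synthetic_study",
    "write_results",
]

TREND_MEASURES = ("gc_rec_to_perf", "cc_max", "cc_zero_lag")


@dataclass(frozen=True)
class AnalysisOptions:
    p_max: int = 20
    max_lag: int = 10
    window_ms: float = 125.0
    cutoff: float | None = None  # None -> rate/4
    absolute_cc: bool = False
    channel_policy: str = "error_on_multichannel"
    seed: int = 0

    @classmethod
    def from_manifest(cls, manifest: dict) -> "AnalysisOptions":
        opts = dict(manifest.get("options") or {})
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in opts.items() if k in known})

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultsBundle:
    gc: pd.DataFrame
    cc: pd.DataFrame
    trial_table: pd.DataFrame
    report: dict
    log: list[str] = field(default_factory=list)


def load_manifest(path: str | Path) -> dict:
    with Path(path).open() as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "pieces" not in manifest:
        raise ValueError(f"{path}: manifest must be a mapping with a 'pieces' list")
    return manifest


def _load_track(path: Path, opts: AnalysisOptions) -> Envelope:
    """Load a track as an envelope: WAVs go through the extraction
    pipeline, CSVs are read as precomputed envelopes."""
    if path.suffix.lower() == ".wav":
        audio = read_wav(path, channel_policy=opts.channel_policy)
        return extract_envelope(audio, cutoff=opts.cutoff, window=opts.window_ms / 1000.0)
    return read_envelope_csv(path)


def _analyse_participant(
    piece_id: str,
    part: dict,
    base_dir: Path,
    opts: AnalysisOptions,
    gc_rows: list,
    cc_rows: list,
    log: list[str],
) -> None:
    pid = str(part["id"])
    try:
        rec_track = _load_track(base_dir / part["recording"], opts)
        perf_track = _load_track(base_dir / part["performance"], opts)
        boundaries = [(t["start_s"], t["end_s"]) for t in part["trials"]]
        rec_trials = segment_trials(rec_track, boundaries)
        perf_trials = segment_trials(perf_track, boundaries)

        per_trial_orders = [
            vargc.aic_order_search((r.values, p.values), p_max=opts.p_max)
            for r, p in zip(rec_trials, perf_trials)
        ]
        order = vargc.select_participant_order(per_trial_orders)
        log.append(f"{piece_id}/{pid}: per-trial orders {per_trial_orders} -> order {order}")

        for j, (rec, perf, trial_order) in enumerate(
            zip(rec_trials, perf_trials, per_trial_orders), start=1
        ):
            fwd, rev = vargc.gc_pair(rec, perf, order)
            for est, direction in ((fwd, "rec_to_perf"), (rev, "perf_to_rec")):
                gc_rows.append(
                    {
                        "participant": pid,
                        "piece": piece_id,
                        "trial": j,
                        "direction": direction,
                        "order": order,
                        "trial_aic_order": trial_order,
                        "gc_value": est.value,
                        "stationary": est.stationary,
                        "spectral_radius": est.spectral_radius,
                    }
                )
            cc = lagcorr.cc_estimate(
                rec, perf, max_lag=opts.max_lag,
                interval=rec.interval, absolute=opts.absolute_cc,
            )
            cc_rows.append(
                {
                    "participant": pid,
                    "piece": piece_id,
                    "trial": j,
                    "cc_max": cc.max_coefficient,
                    "optimal_lag_points": cc.optimal_lag,
                    "optimal_lag_s": cc.optimal_lag_s,
                    "cc_zero_lag": cc.zero_lag_coefficient,
                }
            )
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"piece {piece_id}, participant {pid}: {exc}") from exc


def _piece_report(piece_id: str, gc: pd.DataFrame, cc: pd.DataFrame, table: pd.DataFrame) -> dict:
    report: dict = {}
    fwd = gc[gc["direction"] == "rec_to_perf"].sort_values(["participant", "trial"])
    rev = gc[gc["direction"] == "perf_to_rec"].sort_values(["participant", "trial"])
    try:
        t_res = trend.paired_direction_test(
            fwd["gc_value"].to_numpy(), rev["gc_value"].to_numpy()
        )
        report["direction_test"] = {
            "t_stat": t_res.t_stat, "df": t_res.df, "p_value": t_res.p_value
        }
    except ValueError as exc:
        report["direction_test"] = {"error": str(exc)}
    report["trends"] = {}
    for measure in TREND_MEASURES:
        fit = trend.trial_trend(table, measure)
        contrast = trend.linear_trend_contrast(table, measure)
        report["trends"][measure] = {
            "slope": fit.slope,
            "r2_semipartial": fit.r2_semipartial,
            "lrt_stat": fit.lrt_stat,
            "lrt_p_value": fit.p_value,
            "sigma_participant2": fit.sigma_participant2,
            "sigma_resid2": fit.sigma_resid2,
            "contrast_F": contrast.F_stat,
            "contrast_df": [contrast.df_num, contrast.df_den],
            "contrast_p_value": contrast.p_value,
        }
    report["optimal_lag_nonneg_proportion"] = lagcorr.classify_optimal_lags(
        cc["optimal_lag_points"].tolist()
    )
    return report


def run_study_analysis(
    manifest: dict, base_dir: str | Path = ".", options: AnalysisOptions | None = None
) -> ResultsBundle:
    """Run the full analysis over a study manifest.

    Returns per-trial GC and CC tables, the long-format trial table, and
    a per-piece statistical report annotated with provenance (seed and
    configuration hash).
    """
    base_dir = Path(base_dir)
    opts = options or AnalysisOptions.from_manifest(manifest)
    log: list[str] = []
    gc_rows: list[dict] = []
    cc_rows: list[dict] = []
    t0 = time.perf_counter()
    for piece in manifest["pieces"]:
        piece_id = str(piece["id"])
        t_piece = time.perf_counter()
        for part in piece["participants"]:
            _analyse_participant(piece_id, part, base_dir, opts, gc_rows, cc_rows, log)
        log.append(f"{piece_id}: analysed in {time.perf_counter() - t_piece:.2f} s")

    gc = pd.DataFrame(
        gc_rows,
        columns=[
            "participant", "piece", "trial", "direction", "order",
            "trial_aic_order", "gc_value", "stationary", "spectral_radius",
        ],
    )
    cc = pd.DataFrame(
        cc_rows,
        columns=[
            "participant", "piece", "trial", "cc_max",
            "optimal_lag_points", "optimal_lag_s", "cc_zero_lag",
        ],
    )

    table_rows: list[dict] = []
    for _, row in gc.iterrows():
        measure = "gc_rec_to_perf" if row["direction"] == "rec_to_perf" else "gc_perf_to_rec"
        table_rows.append(
            {
                "participant": row["participant"], "piece": row["piece"],
                "trial": row["trial"], "measure": measure, "value": row["gc_value"],
            }
        )
    for _, row in cc.iterrows():
        for measure, col in (
            ("cc_max", "cc_max"),
            ("cc_zero_lag", "cc_zero_lag"),
            ("optimal_lag", "optimal_lag_points"),
        ):
            table_rows.append(
                {
                    "participant": row["participant"], "piece": row["piece"],
                    "trial": row["trial"], "measure": measure, "value": row[col],
                }
            )
    trial_table = pd.DataFrame(
        table_rows, columns=["participant", "piece", "trial", "measure", "value"]
    )

    report: dict = {
        "provenance": {"seed": opts.seed, "config_hash": opts.config_hash()},
        "pieces": {},
    }
    for piece in manifest["pieces"]:
        piece_id = str(piece["id"])
        if gc.empty:
            continue
        report["pieces"][piece_id] = _piece_report(
            piece_id,
            gc[gc["piece"] == piece_id],
            cc[cc["piece"] == piece_id],
            trial_table[trial_table["piece"] == piece_id],
        )
    log.append(f"total: {time.perf_counter() - t0:.2f} s")
    return ResultsBundle(gc=gc, cc=cc, trial_table=trial_table, report=report, log=log)


def analyse_synthetic_study(study, options: AnalysisOptions | None = None) -> ResultsBundle:
    """Run the trial-level analysis directly on an in-memory simulated study.

    Mirrors :func:`run_study_analysis` without the file round-trip: per
    participant, AIC order per trial, maximum order, GC both directions
    and the cross-correlation summary; then the per-piece statistics.
    """
    opts = options or AnalysisOptions()
    cfg = study.config
    rec = study.recording
    gc_rows: list[dict] = []
    cc_rows: list[dict] = []
    for p in range(1, cfg.participants + 1):
        pid = f"P{p:02d}"
        trials = [study.performances[(p, j)] for j in range(1, cfg.trials + 1)]
        per_trial_orders = [
            vargc.aic_order_search((rec.values, perf.values), p_max=opts.p_max)
            for perf in trials
        ]
        order = vargc.select_participant_order(per_trial_orders)
        for j, (perf, trial_order) in enumerate(zip(trials, per_trial_orders), start=1):
            fwd, rev = vargc.gc_pair(rec, perf, order)
            for est, direction in ((fwd, "rec_to_perf"), (rev, "perf_to_rec")):
                gc_rows.append(
                    {
                        "participant": pid, "piece": "synthetic_piece", "trial": j,
                        "direction": direction, "order": order,
                        "trial_aic_order": trial_order, "gc_value": est.value,
                        "stationary": est.stationary, "spectral_radius": est.spectral_radius,
                    }
                )
            cc = lagcorr.cc_estimate(
                rec, perf, max_lag=opts.max_lag,
                interval=rec.interval, absolute=opts.absolute_cc,
            )
            cc_rows.append(
                {
                    "participant": pid, "piece": "synthetic_piece", "trial": j,
                    "cc_max": cc.max_coefficient, "optimal_lag_points": cc.optimal_lag,
                    "optimal_lag_s": cc.optimal_lag_s, "cc_zero_lag": cc.zero_lag_coefficient,
                }
            )
    gc = pd.DataFrame(gc_rows)
    cc = pd.DataFrame(cc_rows)
    table_rows: list[dict] = []
    for _, row in gc.iterrows():
        measure = "gc_rec_to_perf" if row["direction"] == "rec_to_perf" else "gc_perf_to_rec"
        table_rows.append(
            {
                "participant": row["participant"], "piece": row["piece"],
                "trial": row["trial"], "measure": measure, "value": row["gc_value"],
            }
        )
    for _, row in cc.iterrows():
        for measure, col in (
            ("cc_max", "cc_max"),
            ("cc_zero_lag", "cc_zero_lag"),
            ("optimal_lag", "optimal_lag_points"),
        ):
            table_rows.append(
                {
                    "participant": row["participant"], "piece": row["piece"],
                    "trial": row["trial"], "measure": measure, "value": row[col],
                }
            )
    trial_table = pd.DataFrame(table_rows)
    report = {
        "provenance": {"seed": cfg.seed, "config_hash": opts.config_hash()},
        "pieces": {"synthetic_piece": _piece_report("synthetic_piece", gc, cc, trial_table)},
    }
    return ResultsBundle(gc=gc, cc=cc, trial_table=trial_table, report=report, log=[])


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as gc.csv, cc.csv, trial_table.csv, report.json, run.log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gc": out_dir / "gc.csv",
        "cc": out_dir / "cc.csv",
        "trial_table": out_dir / "trial_table.csv",
        "report": out_dir / "report.json",
        "log": out_dir / "run.log",
    }
    bundle.gc.to_csv(paths["gc"], index=False)
    bundle.cc.to_csv(paths["cc"], index=False)
    bundle.trial_table.to_csv(paths["trial_table"], index=False)
    with paths["report"].open("w") as fh:
        json.dump(bundle.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["log"].write_text("\n".join(bundle.log) + "\n")
    return paths
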