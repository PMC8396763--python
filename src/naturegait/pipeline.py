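"""End-to-end orchestration: cohort exclusions and the full simulated or
file-driven analysis run with a reproducible output bundle."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import McmcConfig, RunConfig
from .datatypes import ParticipantRecord, TrueTrialParams
from .fractal import fractal_dimension
from .gait import GaitFeatureExtractor
from .io import list_trajectory_files, read_trajectory_tsv
from .model import prepare_design, staged_selection
from .synthetic import (
    generate_fractal_image,
    generate_image_metadata,
    generate_participants,
    generate_trial_table,
    images_to_frame,
    synthesize_trial_trajectory,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

MIN_PROP_VALID = 0.80
MIN_MEMORY_ACCURACY = 0.62


def apply_exclusions(participants: Sequence[ParticipantRecord],
                     gait_table: pd.DataFrame
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply participant-level then trial-level exclusions.

    A participant is excluded when under 80% of their trials carry valid
    marker data, or — in the memory task — when recognition accuracy
    falls below the 62% compliance cut-off. QC-flagged trials of the
    surviving participants are then removed. Returns the filtered table
    and a log listing every exclusion with its rule.
    """
    by_id = {p.participant_id: p for p in participants}
    orphans = set(gait_table["participant_id"]) - set(by_id)
    if orphans:
        raise ValueError(
            f"gait rows reference unknown participants: {sorted(orphans)}")

    log_rows: List[Dict] = []
    excluded_ids = set()
    for p in participants:
        reason = None
        if p.prop_valid_data < MIN_PROP_VALID:
            reason = (f"below 80% of data "
                      f"(prop_valid_data={p.prop_valid_data:.2f})")
        elif (p.task == "memory" and p.memory_accuracy is not None
              and p.memory_accuracy < MIN_MEMORY_ACCURACY):
            reason = (f"memory compliance < 62% "
                      f"(accuracy={p.memory_accuracy:.2f})")
        if reason:
            p.excluded = True
            p.exclusion_reason = reason
            excluded_ids.add(p.participant_id)
            log_rows.append({"level": "participant",
                             "id": p.participant_id, "rule": reason})

    table = gait_table[~gait_table["participant_id"].isin(excluded_ids)]
    if "qc_flags" in table.columns:
        flagged = table["qc_flags"].fillna("").astype(str).str.len() > 0
        for row in table[flagged].itertuples():
            log_rows.append({
                "level": "trial",
                "id": f"{row.participant_id}/T{row.trial_id}",
                "rule": f"QC: {row.qc_flags}",
            })
        table = table[~flagged]
    log = pd.DataFrame(log_rows, columns=["level", "id", "rule"])
    logger.info("exclusions: %d participants, %d trials",
                len(excluded_ids), (log["level"] == "trial").sum())
    return table.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir", None)  # the analysis identity, not its location
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _gait_from_simulation(table: pd.DataFrame,
                          truths: List[TrueTrialParams],
                          config: RunConfig) -> pd.DataFrame:
    """Per-trial gait summaries, either via full trajectory synthesis and
    re-analysis (default) or directly from the latent ground truth."""
    extractor = GaitFeatureExtractor(
        cutoff=config.filter_cutoff, order=config.filter_order,
        start_cut=config.start_cut_m, end_margin=config.end_margin_m,
        window_s=config.stationary_window_s,
        threshold_m=config.stationary_threshold_m,
        min_stationary_s=config.min_stationary_s,
    )
    if config.synthesize_trajectories:
        seq = np.random.SeedSequence([config.seed, 11])
        rng = np.random.default_rng(seq)
        trajectories = [
            synthesize_trial_trajectory(t, config.generator, rng=rng)
            for t in truths
        ]
        gait = extractor.fit(trajectories).transform(trajectories)
    else:
        gait = pd.DataFrame({
            "participant_id": [t.participant_id for t in truths],
            "trial_id": [t.trial_id for t in truths],
            "image_id": [t.image_id for t in truths],
            "mean_velocity": [t.true_velocity for t in truths],
            "mean_step_length": [t.true_step_length for t in truths],
            "mean_stride_time": [t.true_stride_time for t in truths],
            "step_length_sd": 0.0,
            "stride_time_sd": 0.0,
            "n_steps_used": [t.n_steps for t in truths],
            "qc_flags": "",
        })
    extra = table[["participant_id", "trial_id", "environment", "task",
                   "discomfort_rating"]]
    return gait.merge(extra, on=["participant_id", "trial_id"], how="left")


def _gait_from_files(config: RunConfig) -> pd.DataFrame:
    files = list_trajectory_files(config.trajectory_dir)
    if not files:
        raise RuntimeError(
            f"gait stage: no trajectory TSV files in "
            f"{config.trajectory_dir}")
    extractor = GaitFeatureExtractor(
        cutoff=config.filter_cutoff, order=config.filter_order,
        start_cut=config.start_cut_m, end_margin=config.end_margin_m,
        window_s=config.stationary_window_s,
        threshold_m=config.stationary_threshold_m,
        min_stationary_s=config.min_stationary_s,
    )
    trajectories = []
    for path in files:
        try:
            trajectories.append(read_trajectory_tsv(path))
        except Exception as exc:  # noqa: BLE001 - report offending file
            raise RuntimeError(f"gait stage failed on {path}: {exc}") from exc
    gait = extractor.fit(trajectories).transform(trajectories)
    meta = pd.read_csv(config.metadata_csv)
    return gait.drop(columns=["image_id"]).merge(
        meta, on=["participant_id", "trial_id"], how="left")


def _fractal_fixture_table(config: RunConfig) -> pd.DataFrame:
    """Box-counting demonstration on generated rasters of known dimension."""
    depth = config.fractal_fixture_depth
    rows = []
    for kind, d in (("sierpinski_carpet", depth),
                    ("sierpinski_triangle", depth + 3),
                    ("filled_square", depth + 3),
                    ("line", depth + 3)):
        img = generate_fractal_image(kind, d)
        base = 3 if kind == "sierpinski_carpet" else 2
        sizes = [base ** k for k in range(0, max(d - 1, 2))]
        res = fractal_dimension(img, sizes=sizes, already_binary=True)
        rows.append({"image_id": f"{kind}_d{d}", "fd": res.fd,
                     "r_squared": res.r_squared,
                     "n_sizes": len(res.box_sizes)})
    return pd.DataFrame(rows)


def fractal_table_from_dir(image_dir, sizes=None,
                           invert: bool = False) -> pd.DataFrame:
    """Fractal dimensions for every PNG/JPEG in a directory."""
    from .fractal import load_image

    rows = []
    paths = sorted(Path(image_dir).glob("*"))
    for path in paths:
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        res = fractal_dimension(load_image(path), sizes=sizes, invert=invert)
        rows.append({"image_id": path.stem, "fd": res.fd,
                     "r_squared": res.r_squared,
                     "n_sizes": len(res.box_sizes)})
    if not rows:
        raise RuntimeError(f"fractal stage: no images found in {image_dir}")
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute simulate -> gait -> fractal -> design -> staged selection
    and write the reproducible report bundle to ``config.out_dir``.

    Outputs: ``images.csv``, ``participants.csv``, ``gait.csv``,
    ``fd.csv``, ``modelling.csv``, ``model_comparison.csv``,
    ``model_summary.csv``, ``exclusions.csv`` and ``manifest.json``.
    Re-running with an identical config reproduces identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, int] = {}

    gen = config.generator
    if config.simulate:
        stage = "simulate"
        images = generate_image_metadata(gen)
        images_df = images_to_frame(images)
        table, truths = generate_trial_table(gen, images)
        participants = generate_participants(gen)
        gait = _gait_from_simulation(table, truths, config)
    else:
        stage = "ingest"
        if not config.trajectory_dir or not config.metadata_csv:
            raise RuntimeError(
                f"{stage}: trajectory_dir and metadata_csv are required "
                "when simulate=false")
        meta = pd.read_csv(config.metadata_csv)
        images_df = meta.drop_duplicates("image_id")[
            [c for c in ("image_id", "environment", "liking", "pair_id",
                         "fractal_dim", "discomfort_mean")
             if c in meta.columns]
        ]
        participants = [
            ParticipantRecord(
                participant_id=str(r["participant_id"]),
                task=str(r.get("task", "memory")),
                prop_valid_data=float(r.get("prop_valid_data", 1.0)),
                memory_accuracy=(float(r["memory_accuracy"])
                                 if "memory_accuracy" in r
                                 and pd.notna(r["memory_accuracy"])
                                 else None),
            )
            for _, r in meta.drop_duplicates("participant_id").iterrows()
        ]
        gait = _gait_from_files(config)

    counts["trials_in"] = len(gait)
    if config.image_dir:
        fd_table = fractal_table_from_dir(config.image_dir)
    else:
        fd_table = _fractal_fixture_table(config)

    filtered, exclusion_log = apply_exclusions(participants, gait)
    counts["trials_retained"] = len(filtered)
    counts["trials_excluded"] = counts["trials_in"] - len(filtered)

    modelling = prepare_design(filtered, images_df,
                               predictors=tuple(config.candidates))
    counts["modelling_rows"] = len(modelling)

    mcmc = McmcConfig(
        burn_in=config.mcmc.burn_in, chain_length=config.mcmc.chain_length,
        seed=config.seed,
        prior_beta_variance=config.mcmc.prior_beta_variance,
        prior_var_shape=config.mcmc.prior_var_shape,
        prior_var_rate=config.mcmc.prior_var_rate,
    )
    selection = staged_selection(modelling, list(config.candidates), mcmc)

    summary = selection.best
    summary_rows = summary.fixed.reset_index().rename(
        columns={"index": "term"})
    var_rows = summary.random.reset_index()

    images_df.to_csv(out / "images.csv", index=False)
    pd.DataFrame([asdict(p) for p in participants]).to_csv(
        out / "participants.csv", index=False)
    gait.to_csv(out / "gait.csv", index=False)
    fd_table.to_csv(out / "fd.csv", index=False)
    modelling.to_csv(out / "modelling.csv", index=False)
    selection.comparison.to_csv(out / "model_comparison.csv", index=False)
    summary_rows.to_csv(out / "model_summary.csv", index=False)
    var_rows.to_csv(out / "model_variances.csv", index=False)
    exclusion_log.to_csv(out / "exclusions.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "naturegait_version": __version__,
        "python_version": platform.python_version(),
        "counts": counts,
        "best_model": selection.best_label,
        "best_fixed_effects": list(selection.best_fixed_effects),
        "dic": selection.best.dic,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {
        "manifest": manifest,
        "selection": selection,
        "gait": gait,
        "modelling": modelling,
        "images": images_df,
        "exclusions": exclusion_log,
    }
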