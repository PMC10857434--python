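"""End-to-end orchestration: axis → profiles → borders → stats → doublets.

``analyze_sample`` runs one nucleus table through linearization and
profiling; ``run_pipeline`` drives a whole cohort (simulated or loaded from
CSV) and writes per-sample projections/profiles, cohort border calls,
bin-wise group statistics, doublet and phase summaries, a resolved config
and a run log. Outputs are deterministic given config + seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axis import AxisLinearizer
from .borders import BorderDetector, align_samples, region_lengths
from .cells import call_phase, classify_doublet, doublet_summary, \
    pair_doublets, threshold_marker
from .io import RunConfig, intensity_columns, read_objects_csv, \
    write_json, write_objects_csv
from .profiles import BinnedProfile, build_profile
from .stats import per_bin_compare
from .synthetic import CONDITIONS, SynthConfig, generate_cohort

logger = logging.getLogger(__name__)


def analyze_sample(
    table: pd.DataFrame,
    slice_count: int = 30,
    n_bins: int = 100,
    type_col: str | None = None,
    flip: bool = False,
):
    """Linearize and profile one sample.

    Returns ``(axis, projected, profile)``: the fitted axis, the table with
    ``s_um``/``u``/``d_um``/``bin`` columns appended, and the per-bin
    :class:`~midgutlam.profiles.BinnedProfile`.
    """
    lin = AxisLinearizer(slice_count=slice_count, n_bins=n_bins, flip=flip)
    projected = lin.fit_transform(table)
    profile = build_profile(projected, n_bins=n_bins, type_col=type_col)
    return lin.axis_, projected, profile


def _call_markers(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Add boolean ``pos_<marker>`` columns for every intensity channel."""
    out = table.copy()
    for col in intensity_columns(table):
        name = col[len("int_"):]
        try:
            positive, thr = threshold_marker(table[col].to_numpy(), method)
        except ValueError:
            positive, thr = threshold_marker(table[col].to_numpy(),
                                             "quantile:0.75")
        out[f"pos_{name}"] = positive
    return out


def _doublets_for_sample(table: pd.DataFrame, config: RunConfig):
    """Marker calls, progenitor pairing and classification for one sample."""
    called = _call_markers(table, config.marker_threshold_method)
    if "pos_esg" not in called.columns:
        return called, []
    prog = called[called["pos_esg"]].reset_index(drop=True)
    doublets = pair_doublets(prog, config.pairing_radius_um,
                             config.exclusion_radius_um)
    if {"pos_delta", "pos_pros"} <= set(called.columns):
        status = called.set_index("object_id")
        for d in doublets:
            classify_doublet(
                d,
                (bool(status.at[d.id_a, "pos_delta"]),
                 bool(status.at[d.id_b, "pos_delta"])),
                (bool(status.at[d.id_a, "pos_pros"]),
                 bool(status.at[d.id_b, "pos_pros"])),
            )
    return called, doublets


def run_pipeline(config: RunConfig,
                 synth_config: SynthConfig | None = None) -> Path:
    """Run the full analysis and write all outputs under ``config.out_dir``.

    With ``config.simulate`` a synthetic cohort is generated (``n_per_group``
    samples per dietary condition, seeded from ``config.seed``); otherwise
    ``config.input_paths`` name object CSVs whose samples are grouped by a
    ``condition`` column. Any stage failure aborts with the stage and sample
    named in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    log_lines = [f"midgutlam {__version__}", f"seed {config.seed}"]

    # ---- inputs ---------------------------------------------------------
    samples: list[tuple[str, str, pd.DataFrame]] = []  # (group, sid, table)
    if config.simulate:
        synth_config = synth_config or SynthConfig()
        cohort = generate_cohort(synth_config, config.n_per_group,
                                 config.seed)
        for cond in CONDITIONS:
            for table, truth in cohort[cond]:
                samples.append((cond, truth.sample_id, table))
        log_lines.append(f"synthetic config hash {synth_config.config_hash()}")
    else:
        for p in config.input_paths:
            df = read_objects_csv(p)
            for sid, sub in df.groupby("sample_id", sort=True):
                cond = (str(sub["condition"].iloc[0])
                        if "condition" in sub.columns else "all")
                samples.append((cond, str(sid), sub.reset_index(drop=True)))
    if not samples:
        raise ValueError("no input samples")

    # ---- per-sample stages ----------------------------------------------
    type_col = ("true_type"
                if "true_type" in samples[0][2].columns else None)
    profiles: dict[str, list[BinnedProfile]] = {}
    axes: dict[str, list] = {}
    doublet_records = []
    phase_counts = []
    for group, sid, table in samples:
        try:
            axis, projected, profile = analyze_sample(
                table, slice_count=config.slice_count, n_bins=config.n_bins,
                type_col=type_col, flip=config.flip_orientation,
            )
            write_objects_csv(projected, out / f"projected_{sid}.csv")
            profile.table.to_csv(out / f"profile_{sid}.csv")
            called, doublets = _doublets_for_sample(projected, config)
            for d in doublets:
                doublet_records.append((group, sid, d))
            if {"pos_e2f1", "pos_cycb"} <= set(called.columns):
                phases = call_phase(called["pos_e2f1"].to_numpy(),
                                    called["pos_cycb"].to_numpy())
                counts = pd.Series(phases).value_counts()
                counts["sample_id"] = sid
                counts["group"] = group
                phase_counts.append(counts)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage failed for sample {sid!r}: {err}"
            ) from err
        profiles.setdefault(group, []).append(profile)
        axes.setdefault(group, []).append(axis)
        log_lines.append(f"sample {sid} group {group} n={len(table)} "
                         f"L={axis.length:.1f}um")

    # ---- cohort stages ---------------------------------------------------
    all_profiles = [p for group in sorted(profiles) for p in profiles[group]]
    detector = BorderDetector(
        variables=tuple(config.border_variables),
        weights=config.border_weights, window=config.border_window,
        k=config.border_k, min_separation=config.border_min_separation,
    ).fit(all_profiles)
    borders = detector.borders_
    mean_length = float(np.mean([ax.length for group in sorted(axes)
                                 for ax in axes[group]]))
    write_json(
        {
            "borders_bins": borders.bins,
            "borders_u": borders.u,
            "labels": list(borders.labels),
            "region_lengths": region_lengths(borders, mean_length),
            "score": detector.score_.score,
        },
        out / "borders.json",
    )

    # per-sample borders for alignment; a sample whose own score is too
    # flat to yield k separated peaks keeps the cohort borders
    sample_border_sets = []
    flat_profiles = [p for group in sorted(profiles) for p in profiles[group]]
    for profile in flat_profiles:
        try:
            det = BorderDetector(
                variables=tuple(config.border_variables),
                weights=config.border_weights, window=config.border_window,
                k=config.border_k,
                min_separation=config.border_min_separation,
            ).fit([profile])
            sample_border_sets.append(det.borders_)
        except ValueError:
            sample_border_sets.append(borders)
    warps = align_samples(sample_border_sets,
                          [p.sample_id for p in flat_profiles])
    write_json(
        {
            p.sample_id: {"from": w.knots_from, "to": w.knots_to}
            for p, w in zip(flat_profiles, warps)
        },
        out / "alignment.json",
    )
    log_lines.append(f"alignment reference u "
                     f"{np.median([b.u for b in sample_border_sets], axis=0).tolist()}")

    groups = sorted(profiles)
    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        for feature in config.compare_features:
            res = per_bin_compare(profiles[ga], profiles[gb],
                                  feature=feature, alpha=config.alpha)
            res.to_csv(out / f"stats_{feature}_{ga}_vs_{gb}.csv", index=False)

    if doublet_records:
        classified = [d for _, _, d in doublet_records if d.cls is not None]
        if classified:
            summary = doublet_summary(
                classified,
                [g for g, _, d in doublet_records if d.cls is not None],
            )
            summary.to_csv(out / "doublets.csv")
    if phase_counts:
        pd.DataFrame(phase_counts).fillna(0).to_csv(out / "phases.csv",
                                                    index=False)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
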