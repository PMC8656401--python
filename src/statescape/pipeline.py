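"""End-to-end orchestration: cohort -> binarize -> fit -> landscape -> dynamics -> stats.

One energy landscape is estimated per (network, group) from the concatenated
binarized data of that group's participants; each participant's dynamics are
then evaluated against their own group's partition (with a cross-partition
option for sensitivity analysis), and group statistics are computed on the
resulting per-participant metrics.  Everything is driven by a single YAML
config and a seed, and a run manifest records what was produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .dynamics import cohort_dynamics
from .ising import boltzmann_distribution, empirical_distribution, fit_pmem
from .landscape import assign_to_basins, build_dendrogram, saddle_energies
from .preprocess import ParticipantSeries, binarize, concatenate_group, group_roi_means
from .stats import anova_bonferroni, comparison_report, symptom_regression
from .synthetic import CohortSpec, PlantedLandscapeSpec, make_cohort

logger = logging.getLogger("statescape")


@dataclass
class RunConfig:
    """Declarative description of one full analysis run.

    Exactly one of ``cohort_dir`` (pre-existing TSV cohort) or ``simulate``
    (synthetic-cohort recipe) must be given.  ``networks`` maps network name
    to an ordered ROI list; each network is analyzed independently.
    """

    networks: dict[str, list[str]]
    out_dir: str
    cohort_dir: Optional[str] = None
    simulate: Optional[dict] = None
    threshold_mode: str = "participant_mean"
    dynamics_mode: str = "direct"
    fit_tol: float = 1e-6
    fit_max_iter: int = 50_000
    fit_step: float = 0.2
    seed: int = 0
    symptom_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.cohort_dir is None) == (self.simulate is None):
            raise ValueError("give exactly one of cohort_dir or simulate")
        if not self.networks:
            raise ValueError("at least one network required")
        for name, rois in self.networks.items():
            if not rois:
                raise ValueError(f"network {name!r} has an empty ROI list")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data.update(overrides)
        return cls(**data)


def simulate_cohort_from_config(
    sim: dict, seed: int
) -> tuple[list[ParticipantSeries], pd.DataFrame, dict]:
    """Build a synthetic cohort from the ``simulate`` section of a config."""
    base = PlantedLandscapeSpec(
        n_rois=sim["n_rois"],
        pattern=tuple(sim["pattern"]),
        coupling_strength=sim.get("coupling_strength", 1.2),
        field_strength=sim.get("field_strength", 0.1),
        seed=seed,
    )
    spec = CohortSpec(
        groups=[tuple(g) for g in sim["groups"]],
        timepoints_per_participant=sim.get("timepoints_per_participant", 160),
        noise_sd=sim.get("noise_sd", 0.2),
        sampler=sim.get("sampler", "exact"),
        seed=seed,
        n_sites=sim.get("n_sites", 2),
    )
    return make_cohort(spec, base)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow for every network x group; return the manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        participants, metadata, truth = simulate_cohort_from_config(
            config.simulate, config.seed
        )
        io.write_cohort_dir(participants, metadata, out / "cohort", truth)
    else:
        participants, metadata = io.read_cohort_dir(config.cohort_dir)

    # validate every network's ROIs before any fitting
    all_rois = set(participants[0].roi_names)
    for name, rois in config.networks.items():
        missing = [r for r in rois if r not in all_rois]
        if missing:
            raise ValueError(f"network {name!r} names missing ROI(s): {missing}")

    groups = list(dict.fromkeys(p.group for p in participants))
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in vars(config).items()}, sort_keys=True, default=str
            ).encode()
        ).hexdigest(),
        "seed": config.seed,
        "groups": groups,
        "networks": {},
    }

    symptom_cols = config.symptom_columns or [
        c
        for c in metadata.columns
        if c not in ("participant_id", "group", "site")
        and pd.api.types.is_numeric_dtype(metadata[c])
    ]

    for net_name, rois in config.networks.items():
        net_dir = out / net_name
        net_dir.mkdir(exist_ok=True)
        net_entry: dict = {"n_rois": len(rois), "groups": {}}
        all_metrics = []
        for group in groups:
            members = [p.subset(rois) for p in participants if p.group == group]
            t_stage = time.time()
            if config.threshold_mode == "group_mean":
                means = group_roi_means(members)
                binarized = [
                    binarize(p, "group_mean", group_means=means) for p in members
                ]
            else:
                binarized = [binarize(p, "participant_mean") for p in members]
            concatenated = concatenate_group(binarized, label=group)
            emp = empirical_distribution(concatenated)
            model, report = fit_pmem(
                emp,
                tol=config.fit_tol,
                max_iter=config.fit_max_iter,
                step=config.fit_step,
                roi_names=list(rois),
            )
            table = boltzmann_distribution(model)
            partition = assign_to_basins(table)
            saddles = (
                saddle_energies(table, partition.basin_codes)
                if len(partition.basin_codes) >= 2
                else None
            )
            prefix = net_dir / f"{group}"
            io.write_model_json(model, f"{prefix}_model.json")
            io.write_binary_series(concatenated, f"{prefix}_states.tsv")
            io.write_tsv(io.energy_table_frame(table), f"{prefix}_energies.tsv")
            io.write_tsv(io.basin_table_frame(partition), f"{prefix}_basins.tsv")
            if saddles is not None:
                s_df, b_df = io.saddle_frames(saddles)
                io.write_tsv(s_df, f"{prefix}_saddles.tsv", index=True)
                io.write_tsv(b_df, f"{prefix}_barriers.tsv", index=True)
                io.write_dendrogram(
                    build_dendrogram(saddles), net_dir / f"{group}_dendrogram"
                )
            metrics = cohort_dynamics(
                binarized, partition, mode=config.dynamics_mode, metadata=metadata
            )
            metrics.insert(1, "network", net_name)
            all_metrics.append(metrics)
            net_entry["groups"][group] = {
                "n_participants": len(members),
                "T_concatenated": concatenated.T,
                "fit_iterations": report.iterations,
                "fit_moment_gap": report.max_moment_gap,
                "fit_kl": report.kl_divergence,
                "n_basins": len(partition.basin_codes),
                "major_basins": partition.major,
                "major_fraction": sum(
                    partition.fractions[b] for b in partition.major
                ),
                "seconds": round(time.time() - t_stage, 3),
            }
            logger.info(
                "%s/%s: T=%d, %d basins, moment gap %.2e",
                net_name,
                group,
                concatenated.T,
                len(partition.basin_codes),
                report.max_moment_gap,
            )

        metrics = pd.concat(all_metrics, ignore_index=True)
        # per-group partitions differ, so align on the shared score columns
        metrics_path = net_dir / "dynamics_metrics.tsv"
        io.write_tsv(metrics, metrics_path)

        comparisons = []
        for col in ("lingering", "traveling", "sr_major", "tr_major", "major_freq"):
            if col == "major_freq":
                # frequency of each participant's own-group deepest-basin cluster
                series = metrics.apply(_deepest_freq, axis=1, manifest=net_entry)
                metrics["major_freq"] = series
            vals = {
                g: sub[col].dropna().to_numpy()
                for g, sub in metrics.groupby("group", observed=True)
            }
            vals = {g: v for g, v in vals.items() if len(v) >= 2}
            if len(vals) >= 2 and not all(np.ptp(v) == 0 for v in vals.values()):
                comparisons.append(anova_bonferroni(vals, metric=f"{net_name}:{col}"))
        report_text = comparison_report(comparisons)
        (net_dir / "group_stats.txt").write_text(report_text)

        regressions = {}
        for col in symptom_cols:
            if col in metrics.columns and metrics["major_freq"].notna().any():
                try:
                    reg = symptom_regression(
                        metrics.dropna(subset=[col, "major_freq"]),
                        response=col,
                        predictors=["major_freq"],
                    )
                    regressions[col] = {
                        "coef": reg.params.to_dict(),
                        "p": reg.pvalues.to_dict(),
                        "r_squared": reg.r_squared,
                        "n": reg.nobs,
                    }
                except ValueError as exc:
                    regressions[col] = {"error": str(exc)}
        if regressions:
            io.write_json(regressions, net_dir / "symptom_regression.json")
        net_entry["n_comparisons"] = len(comparisons)
        manifest["networks"][net_name] = net_entry

    manifest["seconds_total"] = round(time.time() - t0, 3)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _deepest_freq(row: pd.Series, manifest: dict) -> float:
    """Pull the frequency of the participant's own group's deepest basin."""
    group = row["group"]
    entry = manifest["groups"].get(group)
    if entry is None or not entry["major_basins"]:
        return np.nan
    col = f"freq_basin_{entry['major_basins'][0]}"
    return row.get(col, np.nan)
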