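"""Reading and writing the pipeline's plain-text artifacts.

Participant signals and metadata travel as TSV; models, ground truth, binary
series sidecars and manifests as JSON; dendrograms as Newick + JSON.  Floats
are written with ``repr`` round-trip precision, so identical inputs and seeds
produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import DynamicsMetrics
from .ising import EnergyTable, IsingModel
from .landscape import BasinPartition, DendrogramNode, SaddleMatrix
from .preprocess import BinaryStateSeries, ParticipantSeries, decode_state

FLOAT_FMT = "%.17g"


def write_participant_tsv(series: ParticipantSeries, path: str | Path) -> None:
    """Signals as TSV: columns = ROI names, rows = timepoints."""
    df = pd.DataFrame(series.signals, columns=series.roi_names)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_participant_tsv(
    path: str | Path,
    participant_id: Optional[str] = None,
    group: str = "",
    site: str = "",
    symptom_scores: Optional[dict] = None,
) -> ParticipantSeries:
    df = pd.read_csv(path, sep="\t")
    return ParticipantSeries(
        participant_id=participant_id or Path(path).stem,
        signals=df,
        roi_names=list(df.columns),
        group=group,
        site=site,
        symptom_scores=dict(symptom_scores or {}),
    )


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cohort_dir(directory: str | Path) -> tuple[list[ParticipantSeries], pd.DataFrame]:
    """Load a cohort directory: metadata.tsv + one <participant_id>.tsv each."""
    directory = Path(directory)
    metadata = read_metadata_tsv(directory / "metadata.tsv")
    non_score = {"participant_id", "group", "site"}
    participants = []
    for _, row in metadata.iterrows():
        scores = {
            k: float(v)
            for k, v in row.items()
            if k not in non_score and isinstance(v, (int, float, np.floating))
        }
        participants.append(
            read_participant_tsv(
                directory / f"{row['participant_id']}.tsv",
                participant_id=row["participant_id"],
                group=str(row.get("group", "")),
                site=str(row.get("site", "")),
                symptom_scores=scores,
            )
        )
    return participants, metadata


def write_cohort_dir(
    participants: Sequence[ParticipantSeries],
    metadata: pd.DataFrame,
    directory: str | Path,
    truth: Optional[dict] = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in participants:
        write_participant_tsv(p, directory / f"{p.participant_id}.tsv")
    write_metadata_tsv(metadata, directory / "metadata.tsv")
    if truth is not None:
        write_json(truth, directory / "ground_truth.json")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_model_json(model: IsingModel, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def read_model_json(path: str | Path) -> IsingModel:
    return IsingModel.from_dict(read_json(path))


def write_binary_series(series: BinaryStateSeries, path: str | Path) -> None:
    """State codes as one-column TSV plus a JSON sidecar with n/ROIs/boundaries."""
    path = Path(path)
    pd.DataFrame({"state": series.states}).to_csv(path, sep="\t", index=False)
    sidecar = {
        "n": series.n,
        "roi_names": series.roi_names,
        "origin": series.origin,
        "segment_boundaries": list(series.segment_boundaries),
    }
    write_json(sidecar, path.with_suffix(".json"))


def read_binary_series(path: str | Path) -> BinaryStateSeries:
    path = Path(path)
    states = pd.read_csv(path, sep="\t")["state"].to_numpy()
    sc = read_json(path.with_suffix(".json"))
    return BinaryStateSeries(
        states=states,
        n=sc["n"],
        roi_names=sc.get("roi_names"),
        origin=sc.get("origin", ""),
        segment_boundaries=tuple(sc.get("segment_boundaries", ())),
    )


def energy_table_frame(table: EnergyTable) -> pd.DataFrame:
    """Energy table as a DataFrame: code, bits, energy, probability."""
    codes = np.arange(2**table.n)
    bits = ["".join(str(b) for b in decode_state(int(c), table.n)) for c in codes]
    df = pd.DataFrame({"code": codes, "bits": bits, "energy": table.energies})
    if table.probabilities is not None:
        df["probability"] = table.probabilities
    return df


def basin_table_frame(partition: BasinPartition) -> pd.DataFrame:
    sizes = partition.sizes
    fractions = partition.fractions
    rows = []
    for code, energy in zip(partition.basin_codes, partition.energies):
        rows.append(
            {
                "basin_code": code,
                "bits": "".join(str(b) for b in decode_state(code, partition.n)),
                "energy": energy,
                "size": sizes[code],
                "fraction": fractions[code],
                "major": code in partition.major,
            }
        )
    return pd.DataFrame(rows)


def saddle_frames(saddles: SaddleMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    idx = pd.Index(saddles.basin_codes, name="basin")
    saddle = pd.DataFrame(saddles.saddle, index=idx, columns=idx)
    barrier = pd.DataFrame(saddles.barrier, index=idx, columns=idx)
    return saddle, barrier


def write_dendrogram(node: DendrogramNode, path_prefix: str | Path) -> None:
    """Write <prefix>.nwk (Newick) and <prefix>.json (nested tree)."""
    prefix = Path(path_prefix)
    prefix.with_suffix(".nwk").write_text(node.to_newick() + "\n")
    write_json(node.to_dict(), prefix.with_suffix(".json"))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_network_definitions(path: str | Path) -> dict[str, list[str]]:
    """Network-definition YAML/JSON: mapping network name -> ordered ROI list."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or not all(
        isinstance(v, list) and v for v in data.values()
    ):
        raise ValueError("network definitions must map name -> non-empty ROI list")
    return {str(k): [str(r) for r in v] for k, v in data.items()}
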