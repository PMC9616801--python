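"""Session serialization: HDF5 container and a plain-text CSV fallback.

HDF5 layout (one file per session):
  /spikes/neuron, /spikes/trial, /spikes/time   flat parallel arrays
  /trials                                        table (one row per trial)
  /neurons                                       table (one row per neuron)
  /meta                                          attrs (ids, durations, onsets)

The CSV fallback writes three files next to a common stem:
``<stem>.trials.csv``, ``<stem>.neurons.csv`` and ``<stem>.spikes.csv``
(columns neuron_id, trial_id, t_ms).  All times are ms, stimulus onset 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from commdyn.session import SessionData
from commdyn.simulate import GroundTruth

_TRIAL_COLS = ["stimulus", "condition", "silencing_window", "lick_time", "outcome", "excluded"]
_NEURON_COLS = ["area", "depth", "rf_distance", "mean_rate", "waveform_class"]


def _df_to_h5(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        v = df[col].to_numpy()
        if v.dtype == object or str(v.dtype).startswith("str"):
            group.create_dataset(col, data=np.asarray(v, dtype="S32"))
        else:
            group.create_dataset(col, data=v)


def _df_from_h5(group: h5py.Group) -> pd.DataFrame:
    out = {}
    for col in group:
        v = group[col][()]
        if v.dtype.kind == "S":
            v = v.astype(str)
        out[col] = v
    return pd.DataFrame(out)


def save_session(session: SessionData, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        sp = f.create_group("spikes")
        sp.create_dataset("neuron", data=session.spike_neuron)
        sp.create_dataset("trial", data=session.spike_trial)
        sp.create_dataset("time", data=session.spike_time)
        _df_to_h5(f.create_group("trials"), session.trials)
        _df_to_h5(f.create_group("neurons"), session.neurons)
        meta = f.create_group("meta")
        meta.attrs["animal_id"] = session.animal_id
        meta.attrs["stimulus_duration"] = session.stimulus_duration
        meta.attrs["silencing_duration"] = session.silencing_duration
        meta.attrs["silencing_onsets"] = np.asarray(session.silencing_onsets)
        meta.attrs["recording_span"] = np.asarray(session.recording_span)


def load_session(path: str | Path) -> SessionData:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return SessionData(
            animal_id=str(meta["animal_id"]),
            neurons=_df_from_h5(f["neurons"]),
            trials=_df_from_h5(f["trials"]),
            spike_neuron=f["spikes/neuron"][()],
            spike_trial=f["spikes/trial"][()],
            spike_time=f["spikes/time"][()],
            stimulus_duration=float(meta["stimulus_duration"]),
            silencing_duration=float(meta["silencing_duration"]),
            silencing_onsets=tuple(meta["silencing_onsets"]),
            recording_span=tuple(meta["recording_span"]),
        )


def save_session_csv(session: SessionData, stem: str | Path) -> None:
    stem = Path(stem)
    session.trials.to_csv(stem.with_suffix(".trials.csv"), index=False)
    session.neurons.to_csv(stem.with_suffix(".neurons.csv"), index=False)
    pd.DataFrame(
        dict(neuron_id=session.spike_neuron, trial_id=session.spike_trial, t_ms=session.spike_time)
    ).to_csv(stem.with_suffix(".spikes.csv"), index=False)
    meta = dict(
        animal_id=session.animal_id,
        stimulus_duration=session.stimulus_duration,
        silencing_duration=session.silencing_duration,
        silencing_onsets=list(session.silencing_onsets),
        recording_span=list(session.recording_span),
    )
    stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def load_session_csv(stem: str | Path) -> SessionData:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".meta.json").read_text())
    spikes = pd.read_csv(stem.with_suffix(".spikes.csv"))
    return SessionData(
        animal_id=meta["animal_id"],
        neurons=pd.read_csv(stem.with_suffix(".neurons.csv")),
        trials=pd.read_csv(stem.with_suffix(".trials.csv")),
        spike_neuron=spikes["neuron_id"].to_numpy(),
        spike_trial=spikes["trial_id"].to_numpy(),
        spike_time=spikes["t_ms"].to_numpy(),
        stimulus_duration=float(meta["stimulus_duration"]),
        silencing_duration=float(meta["silencing_duration"]),
        silencing_onsets=tuple(meta["silencing_onsets"]),
        recording_span=tuple(meta["recording_span"]),
    )


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = dict(
        effect_vectors_pct=truth.effect_vectors_pct.tolist(),
        adjacent_effect_cosines=truth.adjacent_effect_cosines.tolist(),
        latent_loadings=truth.latent_loadings.tolist(),
        hit_rate=truth.hit_rate,
        fa_rate=truth.fa_rate,
        config=truth.config,
    )
    Path(path).write_text(json.dumps(payload, indent=2))


def save_directions(ds, path: str | Path) -> None:
    """Serialize a DirectionSet (vectors + neuron index + parameters)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=ds.vectors)
        f.create_dataset("neuron_index", data=np.asarray(ds.neuron_index))
        f.attrs["kind"] = ds.kind
        if ds.gamma is not None:
            f.attrs["gamma"] = ds.gamma
        if ds.delta is not None:
            f.attrs["delta"] = ds.delta
        for k, v in ds.meta.items():
            if v is not None:
                f.attrs[f"meta_{k}"] = v


def load_directions(path: str | Path):
    from commdyn.directions import DirectionSet

    with h5py.File(path, "r") as f:
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return DirectionSet(
            kind=str(f.attrs["kind"]),
            vectors=f["vectors"][()],
            neuron_index=f["neuron_index"][()],
            gamma=float(f.attrs["gamma"]) if "gamma" in f.attrs else None,
            delta=float(f.attrs["delta"]) if "delta" in f.attrs else None,
            meta=meta,
        )


def save_similarity(sm, path: str | Path) -> None:
    """Serialize a SimilarityMatrix with its lag profile alongside."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=sm.values)
        f.create_dataset("lag_profile", data=sm.lag_profile())
        f.attrs["n_splits"] = sm.n_splits
        f.attrs["kind"] = sm.kind


def load_similarity(path: str | Path):
    from commdyn.directions import SimilarityMatrix

    with h5py.File(path, "r") as f:
        return SimilarityMatrix(
            values=f["values"][()],
            n_splits=int(f.attrs["n_splits"]),
            kind=str(f.attrs["kind"]),
        )
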