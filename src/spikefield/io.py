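"""Session and pseudopopulation containers on disk.

Trial tables travel as CSV with the documented column header; arrays live
in HDF5 under the groups ``/spikes``, ``/hga`` and ``/voltage`` with
``sampling_rate``, ``count_window_ms`` and ``seed`` attributes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .pseudopop import Pseudopopulation
from .simulate import SessionData
from .task import TRIAL_COLUMNS

__all__ = [
    "save_trial_table",
    "load_trial_table",
    "save_session",
    "load_session",
    "save_pseudopopulation",
    "load_pseudopopulation",
]


def save_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=True)
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    table["category"] = table["category"].where(table["category"].notna(), None)
    return table[TRIAL_COLUMNS]


def save_session(session: SessionData, h5_path: str | Path, csv_path: str | Path) -> None:
    save_trial_table(session.trial_table, csv_path)
    with h5py.File(h5_path, "w") as f:
        f.attrs["count_window_ms"] = session.count_window_ms
        f.attrs["seed"] = session.seed
        f.attrs["mode"] = session.mode
        f.attrs["session_id"] = session.session_id
        g = f.create_group("spikes")
        g.create_dataset("counts", data=session.spike_counts)
        g.create_dataset("unit_to_channel", data=session.unit_to_channel)
        if session.hga_proxy is not None:
            f.create_group("hga").create_dataset("proxy", data=session.hga_proxy)
        if session.voltage is not None:
            g = f.create_group("voltage")
            g.create_dataset("samples", data=session.voltage)
            g.create_dataset("onsets", data=session.onset_samples)
            g.attrs["sampling_rate"] = session.sampling_rate


def load_session(h5_path: str | Path, csv_path: str | Path) -> SessionData:
    table = load_trial_table(csv_path)
    with h5py.File(h5_path, "r") as f:
        kwargs = dict(
            trial_table=table,
            spike_counts=f["spikes/counts"][()],
            unit_to_channel=f["spikes/unit_to_channel"][()],
            count_window_ms=float(f.attrs["count_window_ms"]),
            seed=int(f.attrs["seed"]),
            mode=str(f.attrs["mode"]),
            session_id=str(f.attrs["session_id"]),
        )
        if "hga" in f:
            kwargs["hga_proxy"] = f["hga/proxy"][()]
        if "voltage" in f:
            kwargs["voltage"] = f["voltage/samples"][()]
            kwargs["onset_samples"] = f["voltage/onsets"][()]
            kwargs["sampling_rate"] = float(f["voltage"].attrs["sampling_rate"])
    return SessionData(**kwargs)


def save_pseudopopulation(
    pseudo: Pseudopopulation, h5_path: str | Path, csv_path: str | Path
) -> None:
    pseudo.images.to_csv(csv_path, index=False)
    with h5py.File(h5_path, "w") as f:
        for name in (
            "spikes_novel",
            "spikes_repeated",
            "channels_novel",
            "channels_repeated",
        ):
            f.create_dataset(name, data=getattr(pseudo, name))
        obs = f.create_group("observations")
        obs.create_dataset(
            "session",
            data=np.array(pseudo.observations["session"], dtype="S"),
        )
        obs.create_dataset("unit", data=pseudo.observations["unit"].to_numpy())
        obs.create_dataset("channel", data=pseudo.observations["channel"].to_numpy())
        if pseudo.analysis_window_ms is not None:
            f.attrs["analysis_window_ms"] = pseudo.analysis_window_ms


def load_pseudopopulation(h5_path: str | Path, csv_path: str | Path) -> Pseudopopulation:
    images = pd.read_csv(csv_path)
    with h5py.File(h5_path, "r") as f:
        mats = {
            name: f[name][()]
            for name in (
                "spikes_novel",
                "spikes_repeated",
                "channels_novel",
                "channels_repeated",
            )
        }
        observations = pd.DataFrame(
            {
                "session": [s.decode() for s in f["observations/session"][()]],
                "unit": f["observations/unit"][()],
                "channel": f["observations/channel"][()],
            }
        )
        window = (
            tuple(f.attrs["analysis_window_ms"])
            if "analysis_window_ms" in f.attrs
            else None
        )
    return Pseudopopulation(
        images=images,
        observations=observations,
        analysis_window_ms=window,
        **mats,
    )
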