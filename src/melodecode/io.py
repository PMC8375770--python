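"""On-disk formats: the trial-set container, model serialisation, EDF import.

A trial set is a directory with ``meta.json`` (rate, channel names, optional
positions, and a trial table) plus one binary matrix file per trial
(row-major float32, time × channels, ``.npy``).  Computation is float64;
storage is float32.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import EEGTrial, TrialSet
from .jd import JDModel
from .mcca import MCCAModel

__all__ = ["write_trialset", "read_trialset", "read_edf",
           "save_jd_model", "load_jd_model", "save_mcca_model", "load_mcca_model"]


def write_trialset(trialset: TrialSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table = []
    for i, t in enumerate(trialset.trials):
        fname = f"trial_{i:04d}.npy"
        np.save(path / fname, np.ascontiguousarray(t.data, dtype=np.float32))
        table.append(
            {
                "file": fname,
                "subject": t.subject,
                "condition": t.condition,
                "melody_id": t.melody_id,
                "repetition": t.repetition,
                "n_samples": t.n_samples,
            }
        )
    meta = {
        "rate": trialset.rate,
        "channels": list(trialset.channel_names),
        "positions": None
        if trialset.positions is None
        else np.asarray(trialset.positions).tolist(),
        "trials": table,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    for key in ("rate", "channels", "trials"):
        if key not in meta:
            raise ValueError(f"trial-set meta.json missing required field {key!r}")
    trials = []
    for row in meta["trials"]:
        for key in ("file", "subject", "condition", "melody_id", "repetition"):
            if key not in row:
                raise ValueError(f"trial table entry missing field {key!r}")
        data = np.load(path / row["file"])
        trials.append(
            EEGTrial(
                data=data,
                rate=meta["rate"],
                subject=row["subject"],
                condition=row["condition"],
                melody_id=row["melody_id"],
                repetition=row["repetition"],
            )
        )
    positions = meta.get("positions")
    return TrialSet(
        trials,
        meta["rate"],
        [str(c) for c in meta["channels"]],
        None if positions is None else np.asarray(positions, float),
    )


def read_edf(
    path: str | Path,
    subject: str = "edf",
    condition: str = "listening",
    melody_id: str = "unknown",
    repetition: int = 0,
) -> EEGTrial:
    """Import an EDF/BDF recording as a single trial (channels from the file)."""
    import mne

    p = Path(path)
    reader = mne.io.read_raw_bdf if p.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(p, preload=True, verbose="error")
    return EEGTrial(
        data=raw.get_data().T,
        rate=float(raw.info["sfreq"]),
        subject=subject,
        condition=condition,
        melody_id=melody_id,
        repetition=repetition,
    )


def _save_arrays(path: Path, meta: dict, arrays: dict[str, np.ndarray | None]) -> None:
    path.mkdir(parents=True, exist_ok=True)
    present = {k: v for k, v in arrays.items() if v is not None}
    np.savez(path / "arrays.npz", **present)
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def save_jd_model(model: JDModel, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "kind": "jd",
        "M": model.M,
        "rejected": list(model.rejected),
        "channel_names": model.channel_names,
    }
    _save_arrays(
        path,
        meta,
        {
            "unmixing": model.unmixing,
            "forward": model.forward,
            "eigenvalues": model.eigenvalues,
            "component_variance": model.component_variance,
            "w_rms": model.w_rms,
            "positions": model.positions,
        },
    )


def load_jd_model(path: str | Path) -> JDModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    arr = np.load(path / "arrays.npz")
    return JDModel(
        unmixing=arr["unmixing"],
        forward=arr["forward"],
        eigenvalues=arr["eigenvalues"],
        component_variance=arr["component_variance"],
        M=meta["M"],
        rejected=list(meta["rejected"]),
        w_rms=arr["w_rms"] if "w_rms" in arr else None,
        channel_names=meta.get("channel_names"),
        positions=arr["positions"] if "positions" in arr else None,
    )


def save_mcca_model(model: MCCAModel, path: str | Path) -> None:
    path = Path(path)
    meta = {"kind": "mcca", "n_sc": model.n_sc, "n_datasets": len(model.transforms)}
    arrays = {"sc_power": model.sc_power}
    for i, (w, m) in enumerate(zip(model.transforms, model.means)):
        arrays[f"transform_{i}"] = w
        arrays[f"mean_{i}"] = m
    _save_arrays(path, meta, arrays)


def load_mcca_model(path: str | Path) -> MCCAModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    arr = np.load(path / "arrays.npz")
    n = meta["n_datasets"]
    return MCCAModel(
        transforms=[arr[f"transform_{i}"] for i in range(n)],
        means=[arr[f"mean_{i}"] for i in range(n)],
        n_sc=meta["n_sc"],
        sc_power=arr["sc_power"],
    )
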