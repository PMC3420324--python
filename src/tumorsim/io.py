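"""Writers for step-record time series, snapshots and rendered images."""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .config import SimulationConfig
from .engine import SimulationFields, SimulationResult, records_frame
from .grid import CellStatus, Field, LatticeState


def write_records_csv(records, path) -> None:
    """Step-record time series as CSV (one row per iteration)."""
    records_frame(records).to_csv(path, index=False)


def write_snapshot(path, state: LatticeState, fields: SimulationFields | None = None,
                   config: SimulationConfig | None = None) -> None:
    """Dump the lattice state (and fields, if given) to a compressed .npz."""
    arrays = {"status": state.status, "age": state.age}
    if fields is not None:
        arrays["u"] = fields.u.values
        arrays["f"] = fields.f.values
        if fields.m is not None:
            arrays["m"] = fields.m.values
    if config is not None:
        arrays["config_json"] = np.array(json.dumps(config.to_dict()))
    np.savez_compressed(path, **arrays)


def read_snapshot(path) -> dict:
    """Load a snapshot; returns a dict with 'state' plus any saved fields."""
    with np.load(path, allow_pickle=False) as data:
        out: dict = {"state": LatticeState(status=data["status"].copy(),
                                           age=data["age"].copy())}
        for key in ("u", "f", "m"):
            if key in data:
                out[key] = Field(values=data[key].copy())
        if "config_json" in data:
            out["config"] = json.loads(str(data["config_json"]))
    return out


def save_result(result: SimulationResult, out_dir) -> pathlib.Path:
    """Write records.csv, final.npz and meta.json for a finished run."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_records_csv(result.records, out / "records.csv")
    write_snapshot(out / "final.npz", result.state, result.fields,
                   result.config)
    meta = {
        "config": result.config.to_dict(),
        "hypoxia_onset_step": result.hypoxia_onset_step,
        "hypoxia_onset_hours": result.hypoxia_onset_hours,
        "final_counts": result.state.counts(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


#: Cell-class colours: black proliferating/migrating, dark grey quiescent,
#: light grey necrotic, white background.
_STATUS_COLOURS = {
    CellStatus.EMPTY: (1.0, 1.0, 1.0),
    CellStatus.TUMOUR: (0.0, 0.0, 0.0),
    CellStatus.QUIESCENT: (0.45, 0.45, 0.45),
    CellStatus.NECROTIC: (0.8, 0.8, 0.8),
}


def render_state(state: LatticeState, path) -> None:
    """PNG of the cell distribution with the conventional grey-scale coding."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = np.ones(state.status.shape + (3,))
    for status, colour in _STATUS_COLOURS.items():
        rgb[state.status == status] = colour
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_field(field: Field, path, label: str = "") -> None:
    """PNG heat map of a continuum field."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(field.values, interpolation="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
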