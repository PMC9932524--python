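"""File I/O: raw scans and volumes in HDF5, map stacks as TIFF + JSON, tables as CSV.

HDF5 (float64) is the canonical round-trip format for every artifact; the
multi-page 32-bit TIFF export of parameter maps is intended for viewers and
carries a JSON sidecar with band labels and units.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from . import config
from .mapping import FLImMapStack
from .phantom import IRFRecord, RawFLImScan


# ---------------------------------------------------------------------------
# Raw scans
# ---------------------------------------------------------------------------

def save_scan(path, scan: RawFLImScan) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("scan")
        g.create_dataset("waveforms", data=scan.waveforms)
        f.create_group("irf").create_dataset("samples", data=scan.irf.samples)
        f["irf"].attrs["dt_ns"] = scan.irf.dt_ns
        f["irf"].attrs["fwhm_ns"] = scan.irf.fwhm_ns
        m = f.create_group("meta")
        m.attrs["dt_ns"] = scan.dt_ns
        m.attrs["offsets_ns"] = scan.offsets_ns
        m.attrs["window_samples"] = scan.window_samples
        m.attrs["pitch_um"] = scan.pitch_um
        m.attrs["channel_bands_nm"] = np.asarray(config.CHANNEL_BANDS_NM)


def load_scan(path) -> RawFLImScan:
    with h5py.File(path, "r") as f:
        irf = IRFRecord(samples=f["irf/samples"][...],
                        dt_ns=float(f["irf"].attrs["dt_ns"]),
                        fwhm_ns=float(f["irf"].attrs["fwhm_ns"]))
        m = f["meta"]
        return RawFLImScan(
            waveforms=f["scan/waveforms"][...],
            irf=irf,
            dt_ns=float(m.attrs["dt_ns"]),
            offsets_ns=tuple(m.attrs["offsets_ns"]),
            window_samples=int(m.attrs["window_samples"]),
            pitch_um=float(m.attrs["pitch_um"]),
        )


# ---------------------------------------------------------------------------
# Map stacks
# ---------------------------------------------------------------------------

_MAP_PAGES = ("LT1", "LT2", "LT3", "LT4", "INTR1", "INTR2", "INTR3", "INTR4")
_MAP_UNITS = {"LT": "ns", "INTR": "fraction"}


def save_map_stack(path, stack: FLImMapStack) -> None:
    """Canonical full-precision HDF5 store of a map stack."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lt_maps", data=stack.lt_maps)
        f.create_dataset("intr_maps", data=stack.intr_maps)
        f.create_dataset("intensity_maps", data=stack.intensity_maps)
        f.create_dataset("snr_maps", data=stack.snr_maps)
        f.create_dataset("foreground_mask", data=stack.foreground_mask)
        f.attrs["pitch_um"] = stack.pitch_um
        f.attrs["meta_json"] = json.dumps(_jsonable(stack.meta))


def load_map_stack(path) -> FLImMapStack:
    with h5py.File(path, "r") as f:
        return FLImMapStack(
            lt_maps=f["lt_maps"][...],
            intr_maps=f["intr_maps"][...],
            intensity_maps=f["intensity_maps"][...],
            snr_maps=f["snr_maps"][...],
            foreground_mask=f["foreground_mask"][...].astype(bool),
            pitch_um=float(f.attrs["pitch_um"]),
            meta=json.loads(f.attrs["meta_json"]),
        )


def export_map_tiff(path, stack: FLImMapStack) -> None:
    """Viewer export: multi-page 32-bit TIFF plus a JSON sidecar."""
    path = Path(path)
    maps = stack.parameter_maps()
    pages = np.stack([maps[k] for k in _MAP_PAGES]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "pages": list(_MAP_PAGES),
        "units": {k: _MAP_UNITS[k.rstrip("1234")] for k in _MAP_PAGES},
        "channel_bands_nm": [list(b) for b in config.CHANNEL_BANDS_NM],
        "pixel_pitch_um": stack.pitch_um,
        "dtype": "float32",
        "note": "float32 export for viewing; HDF5 store is full precision",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def save_volume(path, volume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("log_magnitude", data=volume.log_magnitude)
        f.create_dataset("surface_map", data=volume.surface_map)
        f.attrs["axial_pitch_um"] = volume.axial_pitch_um
        f.attrs["lateral_pitch_um"] = volume.lateral_pitch_um
        f.attrs["meta_json"] = json.dumps(_jsonable(volume.meta))


def load_volume(path):
    from .oct import OCTVolume

    with h5py.File(path, "r") as f:
        return OCTVolume(
            log_magnitude=f["log_magnitude"][...],
            axial_pitch_um=float(f.attrs["axial_pitch_um"]),
            lateral_pitch_um=float(f.attrs["lateral_pitch_um"]),
            surface_map=f["surface_map"][...],
            meta=json.loads(f.attrs["meta_json"]),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
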