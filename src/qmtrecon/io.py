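"""Scan container, protocol serialization, and map/checkpoint I/O.

A scan lives in one HDF5 file: ``/kspace`` (complex64, [meas, coil, kx,
ky, z]), ``/sens`` (complex64, [coil, x, y, z]), ``/mask`` (uint8), the
protocol as a YAML attribute, and optional ``/truth`` and ``/labels``
groups for simulated data.  Quantitative maps are written as one NIfTI
file per parameter (float32, units recorded in the header description).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .encoding import CoilSensitivities, SamplingMask
from .signal import (
    AcquisitionProtocol,
    FixedPoolConstants,
    QMapVolume,
    SaturationPulse,
    fermi_pulse,
)

__all__ = [
    "ScanData",
    "protocol_to_dict",
    "protocol_from_dict",
    "save_scan",
    "load_scan",
    "save_qmaps",
    "load_qmaps",
    "save_checkpoint",
    "load_checkpoint",
]

MAP_UNITS = {"i0": "arbitrary", "t1f": "s", "f": "dimensionless", "kf": "1/s"}


@dataclass
class ScanData:
    """In-memory scan container consumed by the reconstruction."""

    kspace: np.ndarray
    sens: CoilSensitivities
    mask: SamplingMask
    protocol: AcquisitionProtocol
    consts: FixedPoolConstants = field(default_factory=FixedPoolConstants)
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def validate(self):
        k = np.asarray(self.kspace)
        if k.ndim != 5:
            raise ValueError("kspace must be [meas, coil, kx, ky, z]")
        if k.shape[0] != self.protocol.n_measurements:
            raise ValueError("measurement count mismatch with protocol")
        if k.shape[1] != self.sens.n_coils:
            raise ValueError("coil count mismatch")
        if k.shape[2:4] != self.mask.grid.shape[-2:]:
            raise ValueError("mask grid mismatch")
        unsampled = self.mask.broadcast_grid() == 0
        if np.any(k[np.broadcast_to(unsampled, k.shape)] != 0):
            raise ValueError("k-space nonzero at unsampled locations")
        return self


# ---------------------------------------------------------------------------
# protocol serialization
# ---------------------------------------------------------------------------


def protocol_to_dict(protocol: AcquisitionProtocol) -> dict:
    p = protocol.pulse
    return {
        "flip_angles_deg": [float(a) for a, _ in protocol.measurements],
        "saturation_on": [bool(s) for _, s in protocol.measurements],
        "tr_s": float(protocol.tr),
        "te_s": float(protocol.te),
        "tau_exc_s": float(protocol.tau_exc),
        "gamma_rad_s_t": float(protocol.gamma),
        "pulse": {
            "shape": p.shape_name,
            "tau_s": float(p.tau_bts),
            "b1max_uT": float(p.b1_max),
            "delta_off_hz": float(p.delta_off),
            "envelope": [float(v) for v in p.envelope],
        },
    }


def protocol_from_dict(d: dict) -> AcquisitionProtocol:
    pd = d["pulse"]
    if pd.get("envelope"):
        pulse = SaturationPulse(
            shape_name=pd.get("shape", "custom"),
            tau_bts=pd["tau_s"],
            b1_max=pd["b1max_uT"],
            envelope=tuple(pd["envelope"]),
            delta_off=pd["delta_off_hz"],
        )
    else:
        pulse = fermi_pulse(pd["tau_s"], pd["b1max_uT"], pd["delta_off_hz"])
    measurements = tuple(
        (a, bool(s)) for a, s in zip(d["flip_angles_deg"], d["saturation_on"])
    )
    return AcquisitionProtocol(
        measurements=measurements,
        tr=d["tr_s"],
        te=d["te_s"],
        tau_exc=d.get("tau_exc_s", 500e-6),
        pulse=pulse,
        gamma=d.get("gamma_rad_s_t", 2.6752218744e8),
    )


# ---------------------------------------------------------------------------
# HDF5 scan container
# ---------------------------------------------------------------------------


def save_scan(path, scan: ScanData, truth: QMapVolume | None = None, labels=None):
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=np.asarray(scan.kspace, np.complex64))
        h5.create_dataset("sens", data=np.asarray(scan.sens.maps, np.complex64))
        h5.create_dataset("support", data=scan.sens.support.astype(np.uint8))
        h5.create_dataset("mask", data=scan.mask.grid.astype(np.uint8))
        h5.attrs["protocol"] = yaml.safe_dump(protocol_to_dict(scan.protocol))
        h5.attrs["consts"] = yaml.safe_dump(
            {
                "r1r": scan.consts.r1r,
                "t2r": scan.consts.t2r,
                "onres_policy": scan.consts.onres_policy,
            }
        )
        h5.attrs["noise_sigma"] = float(scan.noise_sigma)
        h5.attrs["mask_af"] = float(scan.mask.af_nominal)
        h5.attrs["mask_seed"] = int(scan.mask.seed)
        h5.attrs["mask_calibration"] = list(scan.mask.calibration_extent)
        h5.attrs["meta"] = yaml.safe_dump(_plain(scan.meta))
        if truth is not None:
            g = h5.create_group("truth")
            for name in ("i0", "t1f", "f", "kf"):
                g.create_dataset(name, data=truth[name].astype(np.float32))
        if labels is not None:
            h5.create_dataset("labels", data=np.asarray(labels, np.int16))
    return path


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_scan(path):
    """Load and validate a scan container.

    Returns ``(scan, truth, labels)``; truth/labels are None when absent.
    """
    with h5py.File(path, "r") as h5:
        k = h5["kspace"][()]
        sens = CoilSensitivities(h5["sens"][()], h5["support"][()].astype(bool))
        mask = SamplingMask(
            h5["mask"][()],
            tuple(h5.attrs["mask_calibration"]),
            float(h5.attrs["mask_af"]),
            int(h5.attrs["mask_seed"]),
        )
        protocol = protocol_from_dict(yaml.safe_load(h5.attrs["protocol"]))
        cd = yaml.safe_load(h5.attrs["consts"])
        consts = FixedPoolConstants(**cd)
        scan = ScanData(
            kspace=k,
            sens=sens,
            mask=mask,
            protocol=protocol,
            consts=consts,
            noise_sigma=float(h5.attrs["noise_sigma"]),
            meta=yaml.safe_load(h5.attrs["meta"]) or {},
        )
        truth = labels = None
        if "truth" in h5:
            truth = QMapVolume(*(h5["truth"][n][()] for n in ("i0", "t1f", "f", "kf")))
        if "labels" in h5:
            labels = h5["labels"][()]
    return scan.validate(), truth, labels


# ---------------------------------------------------------------------------
# NIfTI maps
# ---------------------------------------------------------------------------


def save_qmaps(outdir, qmaps: QMapVolume, prefix: str = "", affine=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    paths = {}
    for name in ("i0", "t1f", "f", "kf"):
        img = nib.Nifti1Image(qmaps[name].astype(np.float32), affine)
        img.header["descrip"] = f"{name} [{MAP_UNITS[name]}]".encode()
        p = outdir / f"{prefix}{name}.nii"
        nib.save(img, str(p))
        paths[name] = p
    return paths


def load_qmaps(outdir, prefix: str = "") -> QMapVolume:
    outdir = Path(outdir)
    arrs = []
    for name in ("i0", "t1f", "f", "kf"):
        arrs.append(np.asarray(nib.load(str(outdir / f"{prefix}{name}.nii")).dataobj))
    return QMapVolume(*arrs)


# ---------------------------------------------------------------------------
# reconstruction results
# ---------------------------------------------------------------------------


def save_recon_result(outdir, result, affine=None):
    """Write a ReconResult: final/initial maps as NIfTI, per-phase maps and
    loss traces as HDF5, and a YAML run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_qmaps(outdir, result.qmaps, prefix="recon_", affine=affine)
    save_qmaps(outdir, result.q0, prefix="init_", affine=affine)
    with h5py.File(outdir / "phases.h5", "w") as h5:
        for k, vol in enumerate(result.phases, start=1):
            h5.create_dataset(f"phase_{k}", data=vol.stack().astype(np.float32))
        h5.create_dataset("w0", data=np.asarray(result.w0, np.complex64))
        tg = h5.create_group("traces")
        for stage, trace in result.traces.items():
            sg = tg.create_group(stage)
            for key, vals in trace.items():
                sg.create_dataset(key, data=np.asarray(vals, np.float64))
    manifest = {
        "config": _plain(result.config),
        "seed": int(result.seed),
        "provenance": _plain(result.provenance),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return outdir


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, groups: dict, config: dict | None = None, extra: dict | None = None):
    """Save named parameter groups (modules) into one ``.npz`` archive."""
    arrays = dict(extra or {})
    for gname, module in groups.items():
        for pname, p in module.named_parameters():
            arrays[f"{gname}/{pname}"] = p.data
    arrays["__config__"] = np.frombuffer(
        yaml.safe_dump(_plain(config or {})).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return Path(path)


def load_checkpoint(path, groups: dict) -> dict:
    """Load parameters saved by :func:`save_checkpoint` into modules
    (matched by name); returns the stored config dict."""
    with np.load(path) as z:
        for gname, module in groups.items():
            state = {}
            prefix = f"{gname}/"
            for key in z.files:
                if key.startswith(prefix):
                    state[key[len(prefix):]] = z[key]
            if state:
                module.load_state_dict(state)
        cfg = (
            yaml.safe_load(z["__config__"].tobytes().decode())
            if "__config__" in z.files
            else {}
        )
    return cfg or {}
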