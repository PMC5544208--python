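"""File formats and run configuration.

NIfTI-1 in/out for 4D BOLD, stat maps and masks (nibabel); BIDS-style
events TSV; YAML run configuration with strict key validation. Voxels
are always ordered by ascending linear (C-order) index within the mask
grid, so masks from different sources compare by coordinates, not by
order. Voxel indices are 0-based and all times are in seconds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import HRFModel, TrialTable, DEFAULT_MICROTIME_DT, DEFAULT_DRIFT_CUTOFF_S
from .classify import MVBSettings
from .evaluate import EvalConfig
from .mvb import HyperPriors
from .simulate import BoldDataset, SimConfig

logger = logging.getLogger("mvbdecode")

EVENT_COLUMNS = ("onset", "duration", "trial_type", "is_target")


# ---------------------------------------------------------------------------
# BOLD images
# ---------------------------------------------------------------------------

def load_bold(bold_path, mask_path, tr_override: float | None = None) -> BoldDataset:
    """4D NIfTI + 3D mask -> M x N matrix in ascending-linear-index order."""
    img = nib.load(str(bold_path))
    mimg = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mimg.dataobj) > 0
    if data.ndim != 4:
        raise ValueError("BOLD image must be 4D")
    if mask.shape != data.shape[:3]:
        raise ValueError("mask grid does not match the BOLD grid")
    if not np.allclose(img.affine, mimg.affine, atol=1e-4):
        raise ValueError("BOLD and mask affines differ")
    if not mask.any():
        raise ValueError("empty mask")
    Y = data[mask].T  # (scans, voxels), C-order voxel traversal
    n_bad = int(np.sum(~np.isfinite(Y)))
    if n_bad:
        raise ValueError(f"{n_bad} non-finite values inside the mask")
    TR = tr_override
    if TR is None:
        TR = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if TR <= 0:
        raise ValueError("TR missing from header; pass tr_override")
    coords = np.column_stack(np.nonzero(mask))
    return BoldDataset(data=Y, TR=TR, voxel_coords=coords, grid_shape=mask.shape)


def _default_grid(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    nz = int(np.ceil(n_voxels / (side * side)))
    return (side, side, nz)


def save_bold(dataset: BoldDataset, bold_path, mask_path) -> None:
    """Write the matrix back to a 4D NIfTI plus its 3D mask."""
    grid = dataset.grid_shape or _default_grid(dataset.n_voxels)
    mask = np.zeros(grid, dtype=np.uint8)
    if dataset.voxel_coords is not None:
        idx = tuple(dataset.voxel_coords.T)
        mask[idx] = 1
    else:
        flat = mask.reshape(-1)
        flat[:dataset.n_voxels] = 1
        mask = flat.reshape(grid)
    vol = np.zeros(grid + (dataset.n_scans,))
    vol[mask.astype(bool)] = dataset.data.T
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.TR))
    nib.save(img, str(bold_path))
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))


def save_statmap(values3d: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values3d, dtype=float), np.eye(4)),
             str(path))


def save_mask(mask3d: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask3d, dtype=np.uint8), np.eye(4)),
             str(path))


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def load_events(path, class_whitelist: list[str] | None = None) -> TrialTable:
    """Strict BIDS-style TSV parsing; no silent coercion."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing required columns: {missing}")
    for col in ("onset", "duration"):
        if (df[col].str.lower() == "n/a").any():
            raise ValueError(f"'n/a' not permitted in column {col!r}")
    try:
        onsets = df["onset"].astype(float).to_numpy()
        durations = df["duration"].astype(float).to_numpy()
        flags = df["is_target"].astype(int).to_numpy()
    except ValueError as exc:
        raise ValueError(f"unparseable numeric field in events file: {exc}") from exc
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("is_target must be 0 or 1")
    labels = df["trial_type"].to_numpy(dtype=object)
    if class_whitelist is not None:
        bad = sorted(set(labels) - set(class_whitelist))
        if bad:
            raise ValueError(f"unknown trial_type values: {bad}")
    return TrialTable(onsets=onsets, durations=durations, labels=labels,
                      target_flags=flags.astype(bool))


def save_events(trials: TrialTable, path) -> None:
    pd.DataFrame({
        "onset": trials.onsets,
        "duration": trials.durations,
        "trial_type": trials.labels,
        "is_target": trials.target_flags.astype(int),
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "design": {"hrf", "microtime_dt", "drift_cutoff_s", "ar1_rho"},
    "mvb": {"tol", "max_iter", "m_max", "tau_features",
            "hyperprior_mean", "hyperprior_precision"},
    "sim": {"n_voxels", "n_trials_per_class", "stim_duration_s",
            "jitter_range_s", "TR_s", "pattern_sparsity", "pattern_overlap",
            "amplitude_mean", "amplitude_sd", "snr", "ar1_rho",
            "drift_amplitude", "identical_patterns", "class_names", "seed"},
    "eval": {"svm_C", "rfe_target", "fe_sign", "method"},
}
_TOP_KEYS = set(_SCHEMA) | {"seed", "out_dir", "log_level"}
_HRF_KEYS = {"peak_delay", "undershoot_delay", "peak_dispersion",
             "undershoot_dispersion", "undershoot_ratio", "duration"}


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys, naming the offender."""
    cfg = cfg or {}
    for key in cfg:
        if key not in _TOP_KEYS:
            raise ValueError(f"unknown config key: {key!r}")
    for block, allowed in _SCHEMA.items():
        for key in cfg.get(block) or {}:
            if key not in allowed:
                raise ValueError(f"unknown config key: {block}.{key}")
    for key in (cfg.get("design") or {}).get("hrf") or {}:
        if key not in _HRF_KEYS:
            raise ValueError(f"unknown config key: design.hrf.{key}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_sim_config(cfg: dict, seed: int | None = None) -> SimConfig:
    block = dict(cfg.get("sim") or {})
    if seed is not None:
        block["seed"] = seed
    if "jitter_range_s" in block:
        block["jitter_range_s"] = tuple(block["jitter_range_s"])
    if "class_names" in block:
        block["class_names"] = tuple(block["class_names"])
    return SimConfig(**block)


def build_eval_config(cfg: dict) -> EvalConfig:
    design = cfg.get("design") or {}
    mvb = cfg.get("mvb") or {}
    ev = cfg.get("eval") or {}
    hrf = HRFModel(**(design.get("hrf") or {}))
    settings = MVBSettings(
        tol=mvb.get("tol", MVBSettings.tol),
        max_iter=mvb.get("max_iter", MVBSettings.max_iter),
        m_max=mvb.get("m_max", MVBSettings.m_max),
        hyper=HyperPriors(mean=mvb.get("hyperprior_mean", HyperPriors.mean),
                          precision=mvb.get("hyperprior_precision",
                                            HyperPriors.precision)),
        hrf=hrf,
        microtime_dt=design.get("microtime_dt", DEFAULT_MICROTIME_DT),
    )
    return EvalConfig(
        mvb=settings,
        drift_cutoff_s=design.get("drift_cutoff_s", DEFAULT_DRIFT_CUTOFF_S),
        ar1_rho=design.get("ar1_rho", 0.2),
        svm_C=ev.get("svm_C", 1.0),
        rfe_target=ev.get("rfe_target", 2000),
        fe_sign=ev.get("fe_sign", "true_minus_other"),
    )


def write_json(obj, path, cfg: dict | None = None) -> None:
    """JSON output with the resolved config (and its hash) embedded."""
    payload = dict(obj)
    if cfg is not None:
        payload["config"] = cfg
        payload["config_hash"] = config_hash(cfg)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
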