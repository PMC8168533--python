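"""Reading and writing the package's on-disk formats.

Sessions are stored as NIfTI-1 volumes: one 4-D file per nominal PLD with
pair order [control_1, label_1, control_2, label_2, ...] along the fourth
axis, plus ``m0.nii.gz`` and ``ir.nii.gz``, and a ``protocol.json`` sidecar.
Perfusion/T1 maps are written float32.  Cohort tables are CSV with explicit
empty cells for missing values; configs round-trip through YAML.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .protocol import ASLProtocol
from .quantify import PerfusionMap, T1Map
from .regions import COHORT_COLUMNS
from .simulate import ASLSession

__all__ = [
    "save_session",
    "load_session",
    "save_volume",
    "load_volume",
    "save_perfusion_map",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_yaml",
    "dump_yaml",
]

_AFFINE = np.eye(4)


def save_volume(data: np.ndarray, path: Path, dtype=np.float32) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _AFFINE)
    nib.save(img, str(path))


def load_volume(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several parse-error types
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc


def _pld_filename(pld: float) -> str:
    return f"pld_{int(round(pld)):04d}.nii.gz"


def save_session(session: ASLSession, out_dir: Path) -> Dict[str, str]:
    """Write a session to a directory; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for pld, stack in session.stacks.items():
        name = _pld_filename(pld)
        save_volume(stack, out_dir / name)
        files[f"pld_{int(round(pld))}"] = name
    save_volume(session.m0, out_dir / "m0.nii.gz")
    save_volume(session.ir, out_dir / "ir.nii.gz")
    files["m0"] = "m0.nii.gz"
    files["ir"] = "ir.nii.gz"
    sidecar = {"protocol": session.protocol.to_dict(), "meta": session.meta}
    (out_dir / "protocol.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    files["protocol"] = "protocol.json"
    return files


def load_session(session_dir: Path) -> ASLSession:
    """Read a session directory back into memory, validating shapes."""
    session_dir = Path(session_dir)
    sidecar = json.loads((session_dir / "protocol.json").read_text())
    protocol = ASLProtocol.from_dict(sidecar["protocol"])
    m0 = load_volume(session_dir / "m0.nii.gz")
    ir = load_volume(session_dir / "ir.nii.gz")
    stacks = {}
    for pld in protocol.plds:
        stack = load_volume(session_dir / _pld_filename(pld))
        if stack.shape[:3] != m0.shape:
            raise ValueError(
                f"shape mismatch: {_pld_filename(pld)} grid {stack.shape[:3]} "
                f"vs m0 grid {m0.shape}"
            )
        stacks[float(pld)] = stack
    return ASLSession(
        stacks=stacks, m0=m0, ir=ir, protocol=protocol, meta=sidecar.get("meta", {})
    )


def save_perfusion_map(fmap: PerfusionMap, out_dir: Path, stem: str) -> None:
    out_dir = Path(out_dir)
    save_volume(fmap.f, out_dir / f"{stem}_f.nii.gz")
    save_volume(fmap.valid.astype(np.uint8), out_dir / f"{stem}_valid.nii.gz", dtype=np.uint8)


def write_cohort_csv(table: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)


def read_cohort_csv(path: Path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells parse as missing (NaN), never zero."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in ("patient_id", "mvi") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} lacks required columns {missing}")
    return df


def load_yaml(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
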