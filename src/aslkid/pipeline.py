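"""End-to-end study orchestration: simulate → quantify → ROI → statistics.

Two study designs are provided.  The reproducibility study simulates N
subjects scanned in two back-to-back sessions, quantifies both, and reports
paired-t and ICC per region and PLD — the volunteer arm of the design.  The
MVI study generates (or ingests) a patient cohort table and runs the
group-comparison, ROC, diagnostic-index and logistic layers — the patient
arm.  A single master seed fans out deterministically to per-stage,
per-subject sub-seeds, so identical configs give identical reports.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import CohortSpec, default_cohort_spec, simulate_cohort_table
from .io import read_cohort_csv, write_cohort_csv
from .kinetics import buxton_delta_m
from .phantom import TissueParams, build_phantom, default_phantom_spec
from .protocol import ASLProtocol
from .quantify import quantify_session
from .regions import RegionMask, region_mean
from .simulate import inject_motion, simulate_asl_session

__all__ = [
    "subseed",
    "ReproStudyConfig",
    "run_repro_study",
    "MviStudyConfig",
    "run_mvi_study",
]


def subseed(master: int, *tokens) -> int:
    """Deterministic sub-seed from a master seed and context tokens (< 2^31)."""
    h = hashlib.sha256(("|".join([str(master)] + [str(t) for t in tokens])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Reproducibility study (volunteer arm)


@dataclass
class ReproStudyConfig:
    """Two-session test-retest simulation.

    Subjects differ in their true cortical/medullary perfusion (normal
    between-subject variation); both sessions of a subject share the same
    tissue truth and differ only in acquisition noise, which is what makes
    the between/within variance decomposition of the ICC meaningful.
    ``delta_m_snr`` sets the cortical per-voxel SNR of a single difference
    image; calibration (M0/IR) images are simulated at high SNR.
    """

    n_subjects: int = 16
    grid_shape: Tuple[int, int, int] = (20, 20, 3)
    n_pairs: int = 4
    plds: Tuple[float, ...] = (500.0, 1000.0, 2000.0)
    cortex_f: Tuple[float, float] = (250.0, 25.0)  # between-subject mean, SD
    medulla_f: Tuple[float, float] = (60.0, 6.0)
    delta_m_snr: float = 20.0
    calib_snr: float = 100.0
    motion_fraction: float = 0.0
    motion_shift: int = 2
    seed: int = 0


def _session_rois(
    phantom, protocol, noise_sd, calib_noise_sd, seed, motion_fraction, motion_shift
) -> Dict[Tuple[str, float], float]:
    session = simulate_asl_session(
        phantom, protocol, noise_sd, seed, calib_noise_sd=calib_noise_sd
    )
    if motion_fraction > 0:
        session, _ = inject_motion(
            session, motion_fraction, motion_shift, subseed(seed, "motion")
        )
    maps, _, _ = quantify_session(session)
    out = {}
    for roi in ("cortex", "medulla"):
        mask = RegionMask(phantom.mask(roi), roi, source="phantom_truth")
        for pld, fmap in maps.items():
            out[(roi, pld)] = region_mean(fmap, mask).mean_f
    return out


def run_repro_study(config: ReproStudyConfig, out_dir: Optional[Path] = None) -> dict:
    """Simulate the two-session volunteer study and report paired-t + ICC.

    Returns (and optionally writes as ``repro.json`` with a run manifest) a
    report keyed by region and PLD.  Zero-variance paired differences — the
    degenerate identical-sessions case — are reported as an explicit flag
    instead of aborting the run.
    """
    t0 = time.time()
    protocol = ASLProtocol(
        plds=config.plds, n_pairs=config.n_pairs, n_slices=config.grid_shape[2]
    )
    # reference phantom sets the noise scale from the cortical ΔM at PLD1
    ref = build_phantom(default_phantom_spec(config.grid_shape))
    ref_dm = buxton_delta_m(
        config.cortex_f[0], protocol.constants, 1150.0, config.plds[0], 100.0
    )
    noise_sd = float(ref_dm) / config.delta_m_snr
    calib_noise_sd = 100.0 / config.calib_snr

    per_subject: Dict[Tuple[str, float], List[List[float]]] = {}
    for subj in range(config.n_subjects):
        rng = np.random.default_rng(subseed(config.seed, "tissue", subj))
        cortex = TissueParams(
            f_true=max(float(rng.normal(*config.cortex_f)), 1.0), t1_tissue=1150.0
        )
        medulla = TissueParams(
            f_true=max(float(rng.normal(*config.medulla_f)), 1.0), t1_tissue=1500.0
        )
        phantom = build_phantom(
            default_phantom_spec(
                config.grid_shape, tissue={"cortex": cortex, "medulla": medulla}
            )
        )
        sessions = []
        for ses in (1, 2):
            rois = _session_rois(
                phantom,
                protocol,
                noise_sd,
                calib_noise_sd,
                subseed(config.seed, "acq", subj, ses),
                config.motion_fraction,
                config.motion_shift,
            )
            sessions.append(rois)
        for key in sessions[0]:
            per_subject.setdefault(key, []).append([sessions[0][key], sessions[1][key]])

    report: dict = {"config_hash": _config_hash(asdict(config)), "results": {}}
    for (roi, pld), values in sorted(per_subject.items()):
        mat = np.asarray(values)
        entry: dict = {
            "n_subjects": int(mat.shape[0]),
            "session1_mean": float(mat[:, 0].mean()),
            "session2_mean": float(mat[:, 1].mean()),
        }
        try:
            t, p = st.paired_t(mat[:, 0], mat[:, 1])
            entry["paired_t"] = {"t": t, "p": p}
        except ValueError as exc:
            entry["paired_t"] = {"error": str(exc)}
        try:
            icc = st.icc_two_way(mat)
            entry["icc"] = icc.icc
        except ValueError as exc:
            entry["icc"] = 1.0 if np.allclose(mat[:, 0], mat[:, 1]) else None
            entry["icc_note"] = str(exc)
        report["results"][f"{roi}_pld{int(pld)}"] = entry
    report["elapsed_s"] = round(time.time() - t0, 2)
    if out_dir is not None:
        _write_report(report, Path(out_dir), "repro.json", asdict(config))
    return report


# ---------------------------------------------------------------------------
# MVI diagnostic study (patient arm)


@dataclass
class MviStudyConfig:
    cohort_spec: Optional[CohortSpec] = None
    table_path: Optional[str] = None  # ingest an existing cohort CSV instead
    score_columns: Tuple[str, ...] = (
        "entire_pld1",
        "entire_pld2",
        "entire_pld3",
        "solid_pld1",
        "solid_pld2",
        "solid_pld3",
    )
    predictors: Tuple[str, ...] = ("diameter_cm", "margin", "solid_pld1")
    standardize: bool = True
    seed: int = 0


def _encode_predictors(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    cols = []
    for name in predictors:
        if name not in table.columns:
            raise KeyError(f"predictor column {name!r} missing from cohort table")
        col = table[name]
        if name == "margin":
            col = (col == "ill-defined").astype(float)
        elif name == "shape":
            col = (col == "irregular").astype(float)
        cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols)


def run_mvi_study(config: MviStudyConfig, out_dir: Optional[Path] = None) -> dict:
    """Run the diagnostic arm on a generated or provided cohort table.

    Per score column: pooled-variance Student's t between MVI groups, ROC
    with trapezoidal AUC, and diagnostic indices at the Youden cutoff.
    Then one multivariable logistic fit on the configured predictor set,
    reported as odds ratios.
    """
    t0 = time.time()
    if config.table_path is not None:
        table = read_cohort_csv(config.table_path)
    else:
        spec = config.cohort_spec or default_cohort_spec(seed=subseed(config.seed, "cohort"))
        table = simulate_cohort_table(spec)
    labels = table["mvi"].to_numpy().astype(int)
    report: dict = {
        "n_pos": int(labels.sum()),
        "n_neg": int((1 - labels).sum()),
        "per_score": {},
    }
    for colname in config.score_columns:
        if colname not in table.columns:
            raise KeyError(f"score column {colname!r} missing from cohort table")
        scores = table[colname].to_numpy(dtype=float)
        try:
            t, p = st.student_t(scores[labels == 1], scores[labels == 0])
            ttest_entry = {"t": t, "p": p}
        except ValueError as exc:  # e.g. zero-variance degenerate groups
            ttest_entry = {"error": str(exc)}
        roc = st.roc_auc(scores, labels)
        cm = st.ConfusionMatrix.from_predictions(scores, labels, roc.youden_cutoff)
        idx = st.diagnostic_indices(cm)
        report["per_score"][colname] = {
            "student_t": ttest_entry,
            "auc": roc.auc,
            "youden_cutoff": roc.youden_cutoff,
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "sensitivity": idx.sensitivity,
            "specificity": idx.specificity,
            "ppv": idx.ppv,
            "npv": idx.npv,
        }
    X = _encode_predictors(table, config.predictors)
    model = st.logistic_fit(
        X, labels, names=list(config.predictors), standardize=config.standardize
    )
    report["logistic"] = {
        "names": model.names,
        "coefficients": model.coefficients.tolist(),
        "odds_ratios": model.odds_ratios.tolist(),
        "p_values": [None if not np.isfinite(v) else float(v) for v in model.p_values],
        "converged": model.converged,
        "message": model.message,
    }
    report["elapsed_s"] = round(time.time() - t0, 2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_cohort_csv(table, out_dir / "cohort.csv")
        cfg = asdict(config)
        cfg["cohort_spec"] = None if config.cohort_spec is None else "inline"
        _write_report(report, out_dir, "mvi.json", cfg)
    return report


def _write_report(report: dict, out_dir: Path, name: str, config_dict: dict) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    manifest = {
        "config_hash": _config_hash(config_dict),
        "package_version": _package_version(),
        "outputs": {
            p.name: _file_digest(p)
            for p in sorted(out_dir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _package_version() -> str:
    from importlib.metadata import version, PackageNotFoundError

    try:
        return version("aslkid")
    except PackageNotFoundError:
        return "unknown"
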