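"""Per-animal workflow orchestration with a reproducible run manifest.

Runs the full chain — SUV conversion, MTV segmentation, lesion QC,
QC-gated partial-volume correction and metric extraction on both scans,
then the EORTC-style response classification — and records every stage
output, the effective configuration and input hashes in a manifest, so a
rerun on identical inputs reproduces identical results byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .errors import PipelineStageError
from .imaging_io import (
    AcquisitionMeta,
    LesionMask,
    SUVImage,
    read_volume,
    to_suv,
    write_volume,
)
from .pve import DEFAULT_RC_TABLE, LesionMetrics, RCTable, quantify
from .qc import LesionQCReport, qc_report
from .response import ResponseAssessment, assess
from .segmentation import BBox, SegmentationConfig, segment_mtv

log = logging.getLogger("petquant")


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of a full run (snapshotted in the manifest)."""

    segmentation: SegmentationConfig = SegmentationConfig()
    rc_table: RCTable = DEFAULT_RC_TABLE
    use_corrected_for_tlg: bool = True
    decay_correct: bool = False
    qc_n_bins: int = 16
    qc_min_prominence_frac: float = 0.20


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a TOML config file; sections mirror the config dataclasses."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    seg = SegmentationConfig(**raw.get("segmentation", {}))
    rc_raw = raw.get("rc_table", {})
    table = (
        RCTable(
            diameters_mm=tuple(rc_raw["diameters_mm"]),
            coefficients=tuple(rc_raw["coefficients"]),
            no_correction_above=rc_raw.get("no_correction_above", 5.0),
        )
        if rc_raw
        else DEFAULT_RC_TABLE
    )
    pipe = raw.get("pipeline", {})
    return PipelineConfig(
        segmentation=seg,
        rc_table=table,
        use_corrected_for_tlg=pipe.get("use_corrected_for_tlg", True),
        decay_correct=pipe.get("decay_correct", False),
        qc_n_bins=pipe.get("qc_n_bins", 16),
        qc_min_prominence_frac=pipe.get("qc_min_prominence_frac", 0.20),
    )


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _asdict(obj):
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.generic):
            return v.item()
        return v

    return clean(d)


def _stage(name: str, fn, *args, **kwargs):
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise PipelineStageError(name, exc) from exc
    log.info("stage %s done", name)
    return out


def _quantify_scan(
    scan: Union[SUVImage, str, Path],
    bbox: BBox,
    config: PipelineConfig,
    meta: Optional[AcquisitionMeta],
    label: str,
    manifest: dict,
) -> tuple[SUVImage, LesionMask, LesionQCReport, LesionMetrics]:
    if isinstance(scan, (str, Path)):
        manifest["inputs"][label] = {"path": str(scan), "sha256": _sha256(scan)}
        vol = _stage(f"read[{label}]", read_volume, scan)
        if meta is None:
            raise PipelineStageError(
                f"suv[{label}]", ValueError("acquisition metadata required for activity volumes")
            )
        suv = _stage(f"suv[{label}]", to_suv, vol, meta, config.decay_correct)
    else:
        manifest["inputs"][label] = {
            "shape": list(scan.shape),
            "voxel_sum": float(scan.voxels.sum()),
        }
        suv = scan
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mask = _stage(f"segment[{label}]", segment_mtv, suv, bbox, config.segmentation)
        qc = _stage(f"qc[{label}]", qc_report, suv, mask, config.qc_n_bins, config.qc_min_prominence_frac)
        metrics = _stage(
            f"metrics[{label}]",
            quantify,
            suv,
            mask,
            qc,
            config.rc_table,
            config.use_corrected_for_tlg,
        )
    manifest["warnings"].extend(f"{label}: {w.message}" for w in caught)
    manifest["stages"][f"seed_bbox_{label}"] = [list(r) for r in bbox]
    manifest["stages"][f"mask_{label}"] = {
        "voxel_count": mask.voxel_count,
        "mtv_mm3": metrics.mtv_mm3,
    }
    manifest["stages"][f"qc_{label}"] = _asdict(qc)
    manifest["stages"][f"metrics_{label}"] = _asdict(metrics)
    return suv, mask, qc, metrics


def run_pipeline(
    pre_scan: Union[SUVImage, str, Path],
    post_scan: Union[SUVImage, str, Path],
    bbox_pre: BBox,
    bbox_post: BBox,
    config: PipelineConfig = PipelineConfig(),
    meta_pre: Optional[AcquisitionMeta] = None,
    meta_post: Optional[AcquisitionMeta] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[ResponseAssessment, dict]:
    """Run the full pre/post workflow and return the assessment + manifest.

    Scans may be in-memory :class:`SUVImage` objects or paths to NIfTI
    activity volumes (then per-scan :class:`AcquisitionMeta` is required).
    When ``out_dir`` is given, SUV and mask NIfTIs plus ``qc_*.json``,
    ``metrics_*.json``, ``response.json`` and ``manifest.json`` are
    written there.
    """
    manifest: dict = {
        "software": {"name": "petquant", "version": __version__},
        "config": _asdict(config),
        "inputs": {},
        "stages": {},
        "warnings": [],
    }
    suv_pre, mask_pre, qc_pre, met_pre = _quantify_scan(
        pre_scan, bbox_pre, config, meta_pre, "pre", manifest
    )
    suv_post, mask_post, qc_post, met_post = _quantify_scan(
        post_scan, bbox_post, config, meta_post, "post", manifest
    )
    result = _stage("respond", assess, met_pre, met_post)
    manifest["stages"]["response"] = _asdict(result)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(suv_pre, out / "suv_pre.nii.gz")
        write_volume(suv_post, out / "suv_post.nii.gz")
        write_volume(mask_pre, out / "mask_pre.nii.gz")
        write_volume(mask_post, out / "mask_post.nii.gz")
        for name, payload in (
            ("qc_pre", _asdict(qc_pre)),
            ("qc_post", _asdict(qc_post)),
            ("metrics_pre", _asdict(met_pre)),
            ("metrics_post", _asdict(met_post)),
            ("response", _asdict(result)),
            ("manifest", manifest),
        ):
            with open(out / f"{name}.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
    return result, manifest
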