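"""Lesion metrics and recovery-coefficient partial-volume correction.

Objects small relative to the scanner resolution lose apparent uptake
(the partial-volume effect).  The correction divides measured SUVs by a
tabulated recovery coefficient (RC) indexed by the lesion's
sphere-equivalent diameter ``d = (6 * MTV / pi) ** (1/3)``.  The default
table is a scanner calibration for 1-5 mm spheres; above 5 mm the effect
is considered irrelevant and no correction is applied (RC = 1).

Correction is gated by the lesion QC report: only lesions that are
near-spherical with single-peak uptake — the geometry the calibration
table was built for — are corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .imaging_io import LesionMask, SUVImage
from .qc import LesionQCReport


@dataclass(frozen=True)
class RCTable:
    """Recovery coefficients per sphere-equivalent diameter (mm).

    Diameters and coefficients must both be strictly increasing, with
    coefficients in (0, 1].  Between tabulated diameters the coefficient
    is linearly interpolated; above ``no_correction_above`` mm no
    correction is applied; below the smallest tabulated diameter the
    smallest coefficient is used (with a warning) rather than
    extrapolating toward zero.
    """

    diameters_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    coefficients: tuple[float, ...] = (0.04, 0.19, 0.41, 0.54, 0.70)
    no_correction_above: float = 5.0

    def __post_init__(self):
        d = np.asarray(self.diameters_mm, dtype=float)
        c = np.asarray(self.coefficients, dtype=float)
        if d.size != c.size or d.size < 1:
            raise ValueError("table needs matching diameter/coefficient entries")
        if np.any(np.diff(d) <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("diameters and coefficients must be strictly increasing")
        if np.any(c <= 0) or np.any(c > 1):
            raise ValueError("coefficients must lie in (0, 1]")


DEFAULT_RC_TABLE = RCTable()


@dataclass(frozen=True)
class LesionMetrics:
    """Per-lesion quantification results."""

    mtv_mm3: float
    mtv_ml: float
    suv_mean: float
    suv_max: float
    d_equiv_mm: float
    rc_applied: float
    suv_mean_corrected: float
    suv_max_corrected: float
    tlg: float
    tlg_uses_corrected: bool
    warnings: tuple[str, ...] = ()


def mtv(mask: LesionMask) -> float:
    """Metabolic tumor volume in mm^3: voxel count x voxel volume, exact."""
    n = mask.voxel_count
    if n == 0:
        raise DegenerateInputError("empty mask has no volume")
    return n * mask.voxel_volume_mm3


def sphere_equivalent_diameter(mtv_mm3: float) -> float:
    """Diameter (mm) of the sphere with the same volume."""
    if mtv_mm3 <= 0:
        raise ValueError("volume must be positive")
    return (6.0 * mtv_mm3 / math.pi) ** (1.0 / 3.0)


def rc_lookup(d_mm: float, table: RCTable = DEFAULT_RC_TABLE) -> float:
    """Recovery coefficient for a sphere-equivalent diameter.

    Tabulated diameters return the exact table value; in-between values
    are linearly interpolated; above the no-correction bound the
    coefficient is 1.0; below the table a warning is issued and the
    smallest tabulated coefficient is returned.
    """
    if d_mm <= 0:
        raise ValueError("diameter must be positive")
    if d_mm > table.no_correction_above:
        return 1.0
    if d_mm < table.diameters_mm[0]:
        warnings.warn(
            f"diameter {d_mm:.3g} mm is below the calibrated range; "
            f"clamping to RC({table.diameters_mm[0]:g} mm)",
            stacklevel=2,
        )
        return float(table.coefficients[0])
    return float(np.interp(d_mm, table.diameters_mm, table.coefficients))


def correct_suv(value: float, rc: float) -> float:
    """Partial-volume-correct a SUV statistic by dividing by the RC."""
    if not 0.0 < rc <= 1.0:
        raise ValueError("recovery coefficient must lie in (0, 1]")
    return value / rc


def tlg(suv_mean: float, mtv_mm3: float) -> float:
    """Total lesion glycolysis: SUVmean x MTV (SUV * mm^3), exact product."""
    if not (math.isfinite(suv_mean) and math.isfinite(mtv_mm3)):
        raise ValueError("TLG inputs must be finite")
    if mtv_mm3 <= 0:
        raise ValueError("MTV must be positive")
    return suv_mean * mtv_mm3


def quantify(
    img: SUVImage,
    mask: LesionMask,
    qc: LesionQCReport,
    table: RCTable = DEFAULT_RC_TABLE,
    use_corrected_for_tlg: bool = True,
) -> LesionMetrics:
    """Compute the full lesion metric set with QC-gated PVE correction.

    When the lesion fails QC the correction is skipped (``rc_applied`` is
    1.0) and a warning is recorded: the calibration table only applies to
    near-spherical, uniform lesions.
    """
    notes: list[str] = []
    volume = mtv(mask)
    vals = img.voxels[mask.voxels]
    suv_mean = float(vals.mean())
    suv_max = float(vals.max())
    d_eq = sphere_equivalent_diameter(volume)
    if qc.pve_eligible:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rc = rc_lookup(d_eq, table)
        notes.extend(str(w.message) for w in caught)
    else:
        rc = 1.0
        msg = "lesion failed QC (sphericity/uniformity); PVE correction skipped"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    mean_c = correct_suv(suv_mean, rc)
    max_c = correct_suv(suv_max, rc)
    use_corr = bool(use_corrected_for_tlg and qc.pve_eligible)
    tlg_val = tlg(mean_c if use_corr else suv_mean, volume)
    return LesionMetrics(
        mtv_mm3=volume,
        mtv_ml=volume / 1000.0,
        suv_mean=suv_mean,
        suv_max=suv_max,
        d_equiv_mm=d_eq,
        rc_applied=rc,
        suv_mean_corrected=mean_c,
        suv_max_corrected=max_c,
        tlg=tlg_val,
        tlg_uses_corrected=use_corr,
        warnings=tuple(notes),
    )
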