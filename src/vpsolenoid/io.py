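"""File formats for coil paths, field maps, axis profiles and grid surfaces.

All tabular outputs are plain CSV (RFC-4180, '.' decimal); field maps on a
regular ROI grid can additionally be written as NIfTI-1 volumes with the
grid spacing encoded in the affine (mm units, as is conventional for
NIfTI).  Every CSV has a small JSON sidecar carrying the metadata that the
table itself cannot (closed flag, current, fill value, selection rule), so
a file pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import MM, ConductorPath
from .metrics import MetricsResult, RoiSpec
from .optimize import GridSearchResult, select_optimum
from .solver import AxisProfile, FieldMap

__all__ = [
    "save_path_csv",
    "load_path_csv",
    "save_fieldmap_csv",
    "save_fieldmap_nifti",
    "save_axis_profile_csv",
    "save_grid_csv",
    "load_grid_csv",
    "save_grid_summary_json",
]

_FLOAT_FMT = "%.12e"


def _sidecar(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def save_path_csv(path: ConductorPath, csv_file: str | Path) -> None:
    """Write vertices as ``x_m,y_m,z_m`` CSV plus a JSON sidecar."""
    csv_file = Path(csv_file)
    df = pd.DataFrame(path.vertices, columns=["x_m", "y_m", "z_m"])
    df.to_csv(csv_file, index=False, float_format=_FLOAT_FMT)
    _sidecar(csv_file).write_text(
        json.dumps({"closed": path.closed, "current_A": path.current_a}, indent=1)
        + "\n"
    )


def load_path_csv(csv_file: str | Path) -> ConductorPath:
    """Inverse of :func:`save_path_csv`."""
    csv_file = Path(csv_file)
    df = pd.read_csv(csv_file)
    meta = json.loads(_sidecar(csv_file).read_text())
    return ConductorPath(
        df[["x_m", "y_m", "z_m"]].to_numpy(),
        closed=bool(meta["closed"]),
        current_a=float(meta["current_A"]),
    )


def save_fieldmap_csv(field: FieldMap, csv_file: str | Path) -> None:
    """Long-format field map: ``x_m,y_m,z_m,Bx_T,By_T,Bz_T,B1_T``."""
    df = pd.DataFrame(
        np.column_stack((field.points, field.b_vectors, field.b1)),
        columns=["x_m", "y_m", "z_m", "Bx_T", "By_T", "Bz_T", "B1_T"],
    )
    df.to_csv(Path(csv_file), index=False, float_format=_FLOAT_FMT)


def save_fieldmap_nifti(
    field: FieldMap,
    roi: RoiSpec,
    nii_file: str | Path,
    fill_value: float = np.nan,
) -> nib.Nifti1Image:
    """Render a field map sampled on an ROI grid into a NIfTI-1 volume.

    The volume covers the bounding box of the cylindrical ROI; voxels
    outside the cylinder hold ``fill_value``.  The affine maps voxel
    indices to mm with the ROI grid spacing, origin at the volume corner.
    """
    h = roi.grid_spacing_mm
    nx, ny, nz = roi.grid_shape
    vol = np.full((nx, ny, nz), fill_value, dtype=float)
    # voxel indices from metre coordinates
    idx = np.rint(field.points / MM / h).astype(int)
    ii = idx[:, 0] + (nx - 1) // 2
    jj = idx[:, 1] + (ny - 1) // 2
    kk = idx[:, 2] + (nz - 1) // 2
    if (ii < 0).any() or (ii >= nx).any() or (jj < 0).any() or (kk < 0).any():
        raise ValueError("field points do not lie on the ROI grid")
    vol[ii, jj, kk] = field.b1
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = [-h * (nx - 1) / 2, -h * (ny - 1) / 2, -h * (nz - 1) / 2]
    img = nib.Nifti1Image(vol, affine)
    img.header["descrip"] = f"B1 [T], proxy={field.b1_proxy}".encode()[:79]
    nib.save(img, str(nii_file))
    return img


def save_axis_profile_csv(profile: AxisProfile, csv_file: str | Path) -> None:
    """Axis profile as ``z_m,B1_T,B1_rel`` (``B1_rel`` normalised to z=0)."""
    z = np.asarray(profile.z)
    i0 = int(np.argmin(np.abs(z)))
    df = pd.DataFrame(
        {"z_m": z, "B1_T": profile.b1, "B1_rel": profile.b1 / profile.b1[i0]}
    )
    df.to_csv(Path(csv_file), index=False, float_format=_FLOAT_FMT)


def save_grid_csv(result: GridSearchResult, csv_file: str | Path) -> None:
    """Metric surface as ``alpha_deg,beta_deg,mean_B1_T,std_B1_T,cv,n_points``."""
    df = pd.DataFrame(
        [
            (e.alpha_deg, e.beta_deg, e.mean_b1, e.std_b1, e.cv, e.n_points)
            for e in result.entries
        ],
        columns=["alpha_deg", "beta_deg", "mean_B1_T", "std_B1_T", "cv", "n_points"],
    )
    df.to_csv(Path(csv_file), index=False, float_format=_FLOAT_FMT)


def load_grid_csv(
    csv_file: str | Path, rule: str | None = None
) -> GridSearchResult:
    """Re-load a metric surface and re-apply a selection rule.

    With ``rule=None`` the default rule is used; selection on a re-loaded
    surface reproduces the original optimum (the selection is a pure
    function of the table).
    """
    from .optimize import DEFAULT_RULE

    rule = rule or DEFAULT_RULE
    df = pd.read_csv(Path(csv_file))
    entries = tuple(
        MetricsResult(
            alpha_deg=float(r.alpha_deg),
            beta_deg=float(r.beta_deg),
            mean_b1=float(r.mean_B1_T),
            std_b1=float(r.std_B1_T),
            cv=float(r.cv),
            n_points=int(r.n_points),
        )
        for r in df.itertuples()
    )
    return GridSearchResult(
        entries=entries, selected=select_optimum(entries, rule), selection_rule=rule
    )


def save_grid_summary_json(
    result: GridSearchResult, json_file: str | Path, extra: dict | None = None
) -> None:
    """Selected optimum, rule identifier and any provenance ``extra`` keys."""
    payload = {
        "selected_alpha_deg": result.selected[0],
        "selected_beta_deg": result.selected[1],
        "selection_rule": result.selection_rule,
        "n_entries": len(result.entries),
    }
    payload.update(extra or {})
    Path(json_file).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
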