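"""File formats: the spectral container, DWI volumes, and cohort tables.

The spectral container is a directory holding

* ``manifest.json`` -- schema version, the acquisition protocol, the
  diffusion-condition table, and an index row per stored FID;
* ``fids.h5`` -- an HDF5 file with one float64 dataset of shape
  ``(n_fids, 2, n_points)`` storing the real and imaginary planes of every
  FID, so complex data round-trip bit-exactly;
* optionally ``truth.json`` with simulation ground truth.

DWI data use NIfTI plus FSL-style ``bval``/``bvec`` text files; cohort tables
are delimited text with a header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError
from .preprocess import Transient
from .protocol import AcquisitionProtocol, DiffusionCondition

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "CohortRecord",
    "DWIDataset",
    "write_spectra_container",
    "read_spectra_container",
    "read_dwi",
    "write_dwi",
    "read_cohort_table",
    "write_cohort_table",
    "cohort_records_to_frame",
]

GROUP_LABELS = ("stable", "active", "HV")
_KNOWN_COHORT_COLUMNS = {
    "subject_id", "group", "voi_id", "timepoint", "d_cytosol", "sigma_phi",
    "md", "fa", "lambda_par", "lambda_perp", "pct_icv", "lesion_load_pct_wm",
    "voi_lesion_mm3", "sex", "age", "edss",
}


@dataclass
class CohortRecord:
    """One (subject, VOI, timepoint) row of the longitudinal cohort table."""

    subject_id: str
    group: str  # {"stable", "active", "HV"}
    voi_id: str
    timepoint: str  # {"mo0", "mo3", "mo6"} or scan index for HV
    d_cytosol: float | None = None
    sigma_phi: float | None = None
    md: float | None = None
    fa: float | None = None
    lambda_par: float | None = None
    lambda_perp: float | None = None
    pct_icv: float | None = None
    lesion_load_pct_wm: float | None = None
    voi_lesion_mm3: float | None = None
    sex: str | None = None
    age: float | None = None
    edss: float | None = None
    extra: dict = field(default_factory=dict)  # unknown columns, kept opaque

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}")


@dataclass
class DWIDataset:
    """Diffusion-weighted volumes with their b-values and unit b-vectors."""

    data: np.ndarray  # (x, y, z, n_volumes)
    bvals: np.ndarray  # (n_volumes,)
    bvecs: np.ndarray  # (n_volumes, 3), unit rows (zero rows allowed for b=0)
    affine: np.ndarray  # (4, 4)


# ---------------------------------------------------------------------------
# Spectral container


def _protocol_to_dict(p: AcquisitionProtocol) -> dict:
    d = asdict(p)
    d["conditions"] = [
        {"direction": list(c.direction), "b_value": c.b_value, "role_label": c.role_label}
        for c in p.conditions
    ]
    return d


def _protocol_from_dict(d: dict) -> AcquisitionProtocol:
    d = dict(d)
    conds = []
    for c in d.pop("conditions"):
        vec = np.asarray(c["direction"], dtype=float)
        norm = np.linalg.norm(vec)
        if norm > 0 and abs(norm - 1.0) > 1e-9:
            logger.warning("normalizing non-unit condition direction %s on read", c["direction"])
        conds.append(DiffusionCondition(tuple(vec), float(c["b_value"]), c.get("role_label", "parallel")))
    return AcquisitionProtocol(conditions=tuple(conds), **d)


def write_spectra_container(
    path: str | Path,
    protocol: AcquisitionProtocol,
    transients: list[Transient],
    water_references: list[Transient],
    truth: dict | None = None,
) -> Path:
    """Write a spectral container directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    all_fids = list(transients) + list(water_references)
    index = [
        {
            "condition_index": t.condition_index,
            "transient_index": t.transient_index,
            "is_water_reference": bool(t.is_water_reference),
            "flagged": bool(t.flagged),
        }
        for t in all_fids
    ]
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "protocol": _protocol_to_dict(protocol),
        "transients": index,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with h5py.File(path / "fids.h5", "w") as h5:
        if all_fids:
            arr = np.stack([np.stack([t.data.real, t.data.imag]) for t in all_fids])
        else:
            arr = np.zeros((0, 2, protocol.n_points))
        h5.create_dataset("fids", data=arr.astype(np.float64))
    if truth is not None:
        with open(path / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)
    return path


def read_spectra_container(
    path: str | Path,
) -> tuple[AcquisitionProtocol, list[Transient], list[Transient]]:
    """Read a spectral container; returns (protocol, transients, water references).

    Raises
    ------
    FormatError
        Missing manifest or unsupported schema version.
    ConsistencyError
        A transient references an undeclared condition, or a declared
        condition has no (non-water) transients.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema version {manifest.get('schema_version')}")
    protocol = _protocol_from_dict(manifest["protocol"])

    with h5py.File(path / "fids.h5", "r") as h5:
        arr = h5["fids"][()]
    index = manifest["transients"]
    if arr.shape[0] != len(index):
        raise FormatError(
            f"manifest lists {len(index)} FIDs but data file holds {arr.shape[0]}"
        )

    dwell = 1.0 / protocol.spectral_width_hz
    n_cond = len(protocol.conditions)
    transients: list[Transient] = []
    waters: list[Transient] = []
    for row, planes in zip(index, arr):
        ci = int(row["condition_index"])
        if not (0 <= ci < n_cond):
            raise ConsistencyError(f"transient references undeclared condition {ci}")
        t = Transient(
            data=planes[0] + 1j * planes[1],
            dwell_time_s=dwell,
            condition_index=ci,
            transient_index=int(row["transient_index"]),
            is_water_reference=bool(row["is_water_reference"]),
            flagged=bool(row.get("flagged", False)),
        )
        (waters if t.is_water_reference else transients).append(t)

    seen = {t.condition_index for t in transients}
    missing = sorted(set(range(n_cond)) - seen)
    if missing:
        raise ConsistencyError(f"declared condition(s) {missing} have no transients")
    return protocol, transients, waters


def read_container_truth(path: str | Path) -> dict | None:
    p = Path(path) / "truth.json"
    if not p.exists():
        return None
    with open(p) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# DWI


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIDataset:
    """Read DWI volumes plus FSL-style bval/bvec text.

    b-vectors are unit-normalized on read (zero vectors allowed for b=0);
    the voxel grid and affine are preserved.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    n_vol = data.shape[3]
    if bvals.size != n_vol or bvecs.shape[0] != n_vol:
        raise FormatError(
            f"{n_vol} volumes but {bvals.size} b-values / {bvecs.shape[0]} b-vectors"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = norms > 0
    bvecs = bvecs.copy()
    bvecs[nonzero] /= norms[nonzero, None]
    return DWIDataset(data=data, bvals=bvals, bvecs=bvecs, affine=np.asarray(img.affine))


def write_dwi(dset: DWIDataset, nifti_path, bval_path, bvec_path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(dset.data.astype(np.float32), dset.affine), str(nifti_path))
    np.savetxt(bval_path, dset.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, dset.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# Cohort tables


def read_cohort_table(path: str | Path, sep: str | None = None) -> list[CohortRecord]:
    """Read a delimited cohort table into typed records.

    Unknown columns are preserved per record in ``extra``. Missing optional
    values (e.g. EDSS for healthy volunteers) become ``None``.

    Raises
    ------
    ConsistencyError
        Duplicate (subject, voi, timepoint) key.
    ValueError
        Unknown group label.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "group", "voi_id", "timepoint"}
    if not required.issubset(df.columns):
        raise FormatError(f"cohort table missing required columns {sorted(required - set(df.columns))}")

    keys = list(zip(df["subject_id"], df["voi_id"], df["timepoint"]))
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ConsistencyError(f"duplicate (subject, voi, timepoint) rows: {dupes[:3]}")

    records = []
    for _, row in df.iterrows():
        kwargs = {}
        extra = {}
        for col in df.columns:
            val = row[col]
            if isinstance(val, float) and np.isnan(val):
                val = None
            if col in _KNOWN_COHORT_COLUMNS:
                kwargs[col] = val
            else:
                extra[col] = val
        for key in ("subject_id", "voi_id", "timepoint"):
            kwargs[key] = str(kwargs[key])
        records.append(CohortRecord(extra=extra, **kwargs))

    by_subject: dict[str, set[str]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, set()).add(r.group)
    bad = {s: g for s, g in by_subject.items() if len(g) > 1}
    if bad:
        raise ConsistencyError(f"group label changes within subject(s): {sorted(bad)}")
    return records


def cohort_records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        extra = d.pop("extra")
        d.update(extra)
        rows.append(d)
    return pd.DataFrame(rows)


def write_cohort_table(records: list[CohortRecord], path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    cohort_records_to_frame(records).to_csv(path, sep=sep, index=False)
    return path
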