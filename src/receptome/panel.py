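"""Density-panel assembly: parcellation, multi-study averaging, z-scoring.

The panel is the regions × molecules matrix of PET-derived neurotransmitter
receptor/transporter densities ("receptor fingerprints" along its rows).
Densities arrive in arbitrary tracer units and are z-scored per molecule
before any similarity computation; z-scoring scope (cortical, subcortical,
or joint across compartments) is recorded because subcortical analyses use
within-compartment scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MOLECULES_19",
    "DensityPanel",
    "TracerStudy",
    "parcellate_volume",
    "parcellate_nifti",
    "panel_from_pet_dir",
    "assemble_panel",
    "zscore_panel",
    "read_panel",
    "write_panel",
]

#: The 19 PET-imaged receptor/transporter molecules of the source atlas.
MOLECULES_19 = [
    "5-HTT", "5-HT4", "D1", "GABAa", "VAChT", "NAT", "a4b2", "H3", "MU",
    "CB1", "NMDA", "DAT", "D2", "5-HT1a", "5-HT1b", "5-HT2a", "5-HT6",
    "M1", "mGluR5",
]


@dataclass
class TracerStudy:
    """One tracer study: a molecule's region-value map weighted by its n."""

    molecule: str
    map: np.ndarray
    n_subjects: int = 1

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class DensityPanel:
    """regions × molecules density matrix with metadata.

    ``zscored`` is False for raw tracer units; after :func:`zscore_panel`
    it holds the scope string the scoring was computed over.
    """

    values: np.ndarray
    molecules: list[str]
    region_ids: list[str] = field(default_factory=list)
    compartment: np.ndarray | None = None  # per-region {"cortical","subcortical"}
    zscored: bool | str = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel values must be 2-D")
        n, m = self.values.shape
        if len(self.molecules) != m:
            raise ValueError("molecule names do not match panel width")
        if not self.region_ids:
            self.region_ids = [f"region{i}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError("region ids do not match panel height")
        if self.compartment is None:
            self.compartment = np.array(["cortical"] * n)
        else:
            self.compartment = np.asarray(self.compartment)
        if np.isnan(self.values).any():
            raise ValueError("panel contains NaN after assembly")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.molecules)


def parcellate_volume(
    intensity: np.ndarray,
    intensity_affine: np.ndarray,
    labels: np.ndarray,
    labels_affine: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Average intensity voxels within each atlas label.

    Label 0 is background. NaN voxels are excluded from the mean; labels
    whose voxels are all NaN (or absent) come back flagged missing.

    Returns
    -------
    values : per-label mean, ordered by ascending label value (1-based labels)
    missing : boolean flag per label (True = no usable voxels)
    """
    intensity = np.asarray(intensity, dtype=float)
    labels = np.asarray(labels)
    if intensity.shape != labels.shape:
        raise ValueError("intensity and label volumes have different shapes")
    if not np.allclose(intensity_affine, labels_affine, atol=1e-6):
        raise ValueError("intensity and label volumes have different affines")
    lab_flat = labels.reshape(-1).astype(int)
    int_flat = intensity.reshape(-1)
    label_vals = np.unique(lab_flat)
    label_vals = label_vals[label_vals != 0]
    if label_vals.size == 0:
        raise ValueError("label volume is all background")
    ok = ~np.isnan(int_flat)
    # bincount-based means are invariant to voxel traversal order
    counts = np.bincount(lab_flat[ok], minlength=label_vals.max() + 1)
    sums = np.bincount(lab_flat[ok], weights=int_flat[ok], minlength=label_vals.max() + 1)
    values = np.full(label_vals.size, np.nan)
    missing = np.zeros(label_vals.size, dtype=bool)
    for i, lab in enumerate(label_vals):
        if counts[lab] == 0:
            missing[i] = True
        else:
            values[i] = sums[lab] / counts[lab]
    return values, missing


def parcellate_nifti(intensity_path: str | Path, label_path: str | Path):
    """Parcellate a NIfTI density volume with a NIfTI label volume."""
    import nibabel as nib

    img = nib.load(str(intensity_path))
    lab = nib.load(str(label_path))
    return parcellate_volume(
        np.asarray(img.dataobj, dtype=float), img.affine,
        np.asarray(lab.dataobj), lab.affine,
    )


def panel_from_pet_dir(
    pet_dir: str | Path, atlas_path: str | Path,
    molecule_order: list[str] | None = None,
) -> DensityPanel:
    """Assemble a panel from a directory of per-tracer NIfTI volumes.

    Files are named ``<molecule>.nii[.gz]`` or ``<molecule>__n<K>.nii[.gz]``
    where K is the study sample size (weight); several files per molecule
    are averaged with those weights. Regions whose parcel mean is missing
    in any map are dropped, with their atlas labels recorded.
    """
    pet_dir = Path(pet_dir)
    atlas_resolved = Path(atlas_path).resolve()
    paths = sorted(
        p for p in list(pet_dir.glob("*.nii")) + list(pet_dir.glob("*.nii.gz"))
        if p.resolve() != atlas_resolved
    )
    if not paths:
        raise ValueError(f"no NIfTI volumes found in {pet_dir}")
    studies = []
    missing_any = None
    for p in paths:
        stem = p.name.removesuffix(".gz").removesuffix(".nii")
        if "__n" in stem:
            mol, n = stem.rsplit("__n", 1)
            n_subjects = int(n)
        else:
            mol, n_subjects = stem, 1
        values, missing = parcellate_nifti(p, atlas_path)
        missing_any = missing if missing_any is None else (missing_any | missing)
        studies.append(TracerStudy(mol, values, n_subjects))
    keep = ~missing_any
    if not keep.all():
        dropped = np.where(~keep)[0] + 1
        warnings.warn(f"dropping regions with empty parcels (labels {dropped.tolist()})")
    studies = [TracerStudy(s.molecule, s.map[keep], s.n_subjects) for s in studies]
    region_ids = [f"region{i + 1}" for i in np.where(keep)[0]]
    return assemble_panel(studies, region_ids=region_ids,
                          molecule_order=molecule_order)


def assemble_panel(
    studies: list[TracerStudy],
    region_ids: list[str] | None = None,
    compartment: np.ndarray | None = None,
    molecule_order: list[str] | None = None,
) -> DensityPanel:
    """Combine tracer studies into a panel, n-weighted within molecule.

    Molecules measured by several studies are averaged with weights equal
    to each study's sample size.
    """
    if not studies:
        raise ValueError("no studies supplied")
    n = studies[0].map.shape[0]
    for s in studies:
        if s.map.shape[0] != n:
            raise ValueError(
                f"study map for {s.molecule} has length {s.map.shape[0]}, expected {n}"
            )
    by_mol: dict[str, list[TracerStudy]] = {}
    for s in studies:
        by_mol.setdefault(s.molecule, []).append(s)
    order = molecule_order if molecule_order is not None else list(by_mol)
    missing = set(order) - set(by_mol)
    if missing:
        raise ValueError(f"no study for molecules: {sorted(missing)}")
    cols = []
    for mol in order:
        group = by_mol[mol]
        weights = np.array([s.n_subjects for s in group], dtype=float)
        if weights.sum() <= 0:
            raise ValueError(f"zero total weight for molecule {mol}")
        maps = np.stack([s.map for s in group])
        cols.append(weights @ maps / weights.sum())
    values = np.column_stack(cols)
    return DensityPanel(
        values=values,
        molecules=list(order),
        region_ids=list(region_ids) if region_ids else [],
        compartment=compartment,
    )


def zscore_panel(panel: DensityPanel, scope: str = "joint") -> DensityPanel:
    """Z-score each molecule column (sample sd, ddof=1) over a row scope.

    ``scope`` selects which rows define (and receive) the scoring: a single
    compartment, or "joint" for all rows. Rows outside the scope are left
    untouched so cortical and subcortical normalisations stay independent.
    """
    if scope not in {"cortical", "subcortical", "joint"}:
        raise ValueError(f"unknown scope {scope!r}")
    rows = (
        np.ones(panel.n_regions, dtype=bool)
        if scope == "joint"
        else panel.compartment == scope
    )
    if not rows.any():
        raise ValueError(f"no regions in scope {scope!r}")
    values = panel.values.copy()
    sub = values[rows]
    sd = sub.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(
                f"molecule {panel.molecules[j]!r} has zero variance within scope {scope!r}"
            )
    values[rows] = (sub - sub.mean(axis=0)) / sd
    return DensityPanel(
        values=values,
        molecules=list(panel.molecules),
        region_ids=list(panel.region_ids),
        compartment=panel.compartment.copy(),
        zscored=scope,
    )


def write_panel(panel: DensityPanel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.to_frame().to_csv(path, sep="\t", index_label="region", float_format="%.17g")
    sidecar = {
        "region_ids": list(panel.region_ids),
        "molecules": list(panel.molecules),
        "compartment": [str(c) for c in panel.compartment],
        "zscored": panel.zscored,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_panel(path: str | Path) -> DensityPanel:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        return DensityPanel(
            values=values,
            molecules=list(side["molecules"]),
            region_ids=list(side["region_ids"]),
            compartment=np.array(side["compartment"]),
            zscored=side.get("zscored", False),
        )
    warnings.warn(f"missing sidecar for {path}; ids taken from the TSV header")
    return DensityPanel(
        values=values,
        molecules=[str(c) for c in df.columns],
        region_ids=[str(i) for i in df.index],
    )
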