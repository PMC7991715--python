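"""Synthetic CT phantoms and fixture machines.

Every pipeline stage is testable offline against analytic ground truth: the
phantom is a geometric stand-in for an anthropomorphic quality-assurance
phantom — an elliptical-cylinder torso (soft-tissue HU with Gaussian noise)
on a flat CT couch plate, optionally wrapped in a low-density immobilization
shell (vacuum-bag surrogate), plus a prone-board variant that raises the
torso and reproduces the reduced posterior-oblique gantry clearance of a
prone breast setup.

HU defaults: body 30 +/- 15, shell -650, plate 200, board 150, air -1000 —
chosen so a window/threshold choice cleanly separates the colliders.  Voxels
are integer HU, so a written DICOM series reloads bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contour import CTVolume
from .errors import RTClearError
from .machine import MachineSpec, load_machine_spec

__all__ = [
    "PhantomParams",
    "make_phantom_ct",
    "make_prone_breast_case",
    "fixture_machine",
    "write_dicom_series",
]

FIXTURE_MACHINES = ("machine_a", "machine_b")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of the synthetic torso phantom."""

    body_semi_axes_mm: tuple[float, float] = (170.0, 110.0)  # (lateral a, vertical b)
    body_length_mm: float = 290.0
    body_hu_mean: float = 30.0
    body_hu_sd: float = 15.0
    bag_thickness_mm: float = 0.0  # 0 = no shell
    bag_hu: float = -650.0
    plate_thickness_mm: float = 30.0
    plate_hu: float = 200.0
    plate_height_mm: float = -110.0  # vertical coordinate of the plate top
    board_height_mm: float = 0.0  # 0 = no prone board
    board_half_width_mm: float = 200.0
    board_hu: float = 150.0
    #: air gap between board top and body bottom (a cushion in practice);
    #: wider than the default closing diameter so the two colliders stay
    #: distinct components after smoothing
    board_gap_mm: float = 12.0
    air_hu: float = -1000.0
    n_pixels: int = 256
    n_slices: int = 60
    pixel_spacing_mm: float = 2.0
    slice_thickness_mm: float = 5.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.body_semi_axes_mm
        if min(a, b, self.body_length_mm, self.pixel_spacing_mm, self.slice_thickness_mm) <= 0:
            raise RTClearError("phantom geometric parameters must be > 0")
        fov = self.n_pixels * self.pixel_spacing_mm
        lift = self.board_height_mm + (self.board_gap_mm if self.board_height_mm else 0)
        top = self.plate_height_mm + lift + 2 * b + self.bag_thickness_mm
        if 2 * (a + self.bag_thickness_mm) >= fov or top >= fov / 2:
            raise RTClearError("body (plus shell/board) exceeds the field of view")


def make_phantom_ct(p: PhantomParams = PhantomParams()) -> CTVolume:
    """Rasterize the phantom into a CT volume (deterministic for a seed).

    The returned volume has the plate height set and the isocenter placed at
    the body center — the conventional manual choice for this phantom; both
    remain overridable, mirroring their manual definition in practice.
    """
    n = p.n_pixels
    sp = p.pixel_spacing_mm
    half = (n - 1) / 2.0 * sp
    x = -half + np.arange(n) * sp  # columns, lateral
    v = -half + np.arange(n) * sp  # rows, vertical up
    X, V = np.meshgrid(x, v)  # [row, col]

    nz = p.n_slices
    z0 = -(nz - 1) / 2.0 * p.slice_thickness_mm
    zs = z0 + np.arange(nz) * p.slice_thickness_mm

    a, b = p.body_semi_axes_mm
    lift = p.board_height_mm + (p.board_gap_mm if p.board_height_mm else 0.0)
    cv = p.plate_height_mm + lift + b  # body center height: resting surface + b
    body2d = (X / a) ** 2 + ((V - cv) / b) ** 2 <= 1.0

    plate2d = (V <= p.plate_height_mm) & (V >= p.plate_height_mm - p.plate_thickness_mm)
    board2d = np.zeros_like(plate2d)
    if p.board_height_mm > 0:
        board2d = (
            (np.abs(X) <= p.board_half_width_mm)
            & (V > p.plate_height_mm)
            & (V <= p.plate_height_mm + p.board_height_mm)
        )
    bag2d = np.zeros_like(body2d)
    if p.bag_thickness_mm > 0:
        outer = (X / (a + p.bag_thickness_mm)) ** 2 + (
            (V - cv) / (b + p.bag_thickness_mm)
        ) ** 2 <= 1.0
        bag2d = outer & ~body2d & (V > p.plate_height_mm + lift) & ~board2d

    rng = np.random.default_rng(p.noise_seed)
    vox = np.full((nz, n, n), int(round(p.air_hu)), dtype=np.int16)
    in_body_z = np.abs(zs) <= p.body_length_mm / 2.0
    for k in range(nz):
        sl = vox[k]
        sl[plate2d] = int(round(p.plate_hu))
        if p.board_height_mm > 0:
            sl[board2d] = int(round(p.board_hu))
        if in_body_z[k]:
            if p.bag_thickness_mm > 0:
                sl[bag2d] = int(round(p.bag_hu))
            noise = rng.normal(0.0, p.body_hu_sd, size=int(body2d.sum()))
            sl[body2d] = np.round(p.body_hu_mean + noise).astype(np.int16)

    return CTVolume(
        voxels=vox,
        pixel_spacing=(sp, sp),
        slice_positions=zs,
        origin=(float(x[0]), float(v[0]), float(zs[0])),
        plate_height_mm=p.plate_height_mm,
        isocenter_mm=(0.0, cv, 0.0),
    )


def make_prone_breast_case(seed: int = 0, board_height_mm: float = 120.0) -> CTVolume:
    """Phantom variant on a prone board that raises the torso.

    The board is its own collider above the plate (separated from the body by
    a small air gap so component tracking keeps them distinct); the raised
    torso reduces gantry clearance at posterior-oblique angles.
    """
    return make_phantom_ct(
        PhantomParams(board_height_mm=board_height_mm, noise_seed=seed)
    )


def fixture_machine(name: str) -> MachineSpec:
    """Load one of the shipped generic fixture machines.

    ``machine_b`` has a larger head diameter and a smaller face-to-isocenter
    clearance than ``machine_a``.
    """
    if name not in FIXTURE_MACHINES:
        raise RTClearError(f"unknown fixture machine {name!r} (have {FIXTURE_MACHINES})")
    from importlib import resources

    with resources.as_file(
        resources.files("rtclear.data").joinpath(f"{name}.yaml")
    ) as path:
        return load_machine_spec(path)


# --------------------------------------------------------------------------
# DICOM series output
# --------------------------------------------------------------------------

def write_dicom_series(vol: CTVolume, directory) -> list[Path]:
    """Write the volume as a standard single-series DICOM CT stack.

    Voxels are stored as signed 16-bit HU with identity rescale, so
    ``load_ct_series`` reproduces the volume bit-identically.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    sp_row, sp_col = vol.pixel_spacing
    nrow = vol.voxels.shape[1]
    paths = []
    for k, z in enumerate(vol.slice_positions):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset("", {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # stored rows run top-down; row 0 is the highest vertical coordinate
        top_v = vol.origin[1] + (nrow - 1) * sp_row
        ds.ImagePositionPatient = [vol.origin[0], top_v, float(z)]
        ds.PixelSpacing = [sp_row, sp_col]
        ds.SliceThickness = vol.slice_spacing
        ds.Rows, ds.Columns = vol.voxels.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        sl = np.asarray(vol.voxels[k], dtype=np.int16)[::-1, :]  # flip to top-down
        ds.PixelData = sl.tobytes()
        path = out / f"ct_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
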