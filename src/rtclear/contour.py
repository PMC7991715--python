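"""CT ingestion and external-contour extraction.

The pipeline mirrors clinical practice for collision prediction: a simulation
CT is windowed to grayscale, thresholded, smoothed with a grayscale-morphology
closing, and the per-slice outlines of everything above the couch-plate top
(body, immobilization shell/vacuum bag, accessories) become *colliders*.  The
plate height and the isocenter are user inputs: the isocenter is defined
manually, never auto-detected.

Coordinates: a volume is indexed ``[slice, row, col]``; the in-plane axes are
``x`` (columns, lateral, mm) and ``v`` (rows, vertical up, mm); the slice axis
``z`` is the longitudinal position.  A 3-vector like the isocenter is always
``(x, v, z)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure, morphology

from ._polygon import ensure_ccw, signed_area
from .errors import ContourError, CTSeriesError

__all__ = [
    "CTVolume",
    "SliceContour",
    "ContourStack",
    "load_ct_series",
    "intensity_transform",
    "hu_to_gray",
    "segment_mask",
    "extract_slice_contours",
    "export_contours",
    "import_contours",
    "contour_pipeline",
]

#: default intensity window (HU) and body cut (HU); user-overridable — these
#: are interface defaults of this package, exposed exactly because the method
#: treats them as operator choices.
DEFAULT_WINDOW_HU = (-500.0, 300.0)
DEFAULT_THRESHOLD_HU = -300.0
DEFAULT_CLOSING_RADIUS_PX = 2
DEFAULT_MIN_AREA_MM2 = 400.0


@dataclass
class CTVolume:
    """Calibrated HU voxel grid with geometry and the two manual landmarks."""

    voxels: np.ndarray  # (nz, nrow, ncol) HU
    pixel_spacing: tuple[float, float]  # (row/vertical, col/lateral) mm
    slice_positions: np.ndarray  # (nz,) mm, strictly increasing
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, v, z0) of voxel (0,0,0)
    plate_height_mm: float | None = None
    isocenter_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        zs = np.asarray(self.slice_positions, dtype=float)
        if self.voxels.ndim != 3:
            raise CTSeriesError("voxels must be a 3D [slice, row, col] array")
        if len(zs) != self.voxels.shape[0]:
            raise CTSeriesError("slice_positions length != number of slices")
        if len(zs) > 1:
            dz = np.diff(zs)
            if np.any(dz <= 0):
                raise CTSeriesError("slice positions must be strictly increasing")
            if np.ptp(dz) > 1e-3:
                raise CTSeriesError(
                    f"non-uniform slice spacing (spread {np.ptp(dz):.4f} mm)"
                )
        if min(self.pixel_spacing) <= 0:
            raise CTSeriesError("pixel spacing must be > 0")
        self.slice_positions = zs
        if self.isocenter_mm is not None:
            self.set_isocenter(self.isocenter_mm)

    @property
    def slice_spacing(self) -> float:
        zs = self.slice_positions
        return float(zs[1] - zs[0]) if len(zs) > 1 else 1.0

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.voxels.shape[2]) * self.pixel_spacing[1]

    def v_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.voxels.shape[1]) * self.pixel_spacing[0]

    def set_isocenter(self, isocenter_mm) -> None:
        iso = tuple(float(c) for c in isocenter_mm)
        x, v = self.x_coords(), self.v_coords()
        z = self.slice_positions
        inside = (
            x[0] <= iso[0] <= x[-1]
            and v[0] <= iso[1] <= v[-1]
            and z[0] <= iso[2] <= z[-1]
        )
        if not inside:
            raise ContourError(f"isocenter {iso} outside volume bounds")
        self.isocenter_mm = iso


@dataclass
class SliceContour:
    """One closed, simple, CCW polygon on an axial slice (mm)."""

    z_mm: float
    points: np.ndarray  # (N, 2) of (x, v), first point not repeated
    label: str

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
            raise ContourError("contour needs >= 3 (x, v) points")
        if np.allclose(p[0], p[-1]):
            p = p[:-1]
        if signed_area(p) < 0:
            p = p[::-1].copy()
        self.points = p

    @property
    def area_mm2(self) -> float:
        return signed_area(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ContourStack:
    """Per-slice collider contours plus the isocenter and plate height."""

    contours: dict[str, list[SliceContour]]
    isocenter_mm: tuple[float, float, float]
    plate_height_mm: float

    def labels(self) -> list[str]:
        return sorted(self.contours)

    def for_label(self, label: str) -> list[SliceContour]:
        return sorted(self.contours[label], key=lambda c: c.z_mm)


# --------------------------------------------------------------------------
# DICOM CT series I/O
# --------------------------------------------------------------------------

def load_ct_series(directory) -> CTVolume:
    """Read one DICOM CT series from a directory.

    Slices are ordered by ImagePositionPatient regardless of filename; the HU
    rescale (slope/intercept) is applied.  Mixed series, a missing rescale
    tag, or a non-uniform slice gap are errors.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file()
    )
    if not files:
        raise CTSeriesError(f"no files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise CTSeriesError(f"directory contains {len(uids)} series, expected 1")
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise CTSeriesError("missing HU rescale tags (RescaleSlope/Intercept)")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1 and np.ptp(np.diff(zs)) > 1e-3:
        raise CTSeriesError(
            f"non-uniform slice gap: spacings span {np.ptp(np.diff(zs)):.3f} mm"
        )
    first = datasets[0]
    hu = np.stack(
        [
            ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
            for ds in datasets
        ]
    )
    # stored rows run top-down; flip so row index increases upward (v axis)
    hu = hu[:, ::-1, :].copy()
    spacing = tuple(float(s) for s in first.PixelSpacing)
    ipp = [float(c) for c in first.ImagePositionPatient]
    nrow = hu.shape[1]
    origin_v = ipp[1] - (nrow - 1) * spacing[0]
    return CTVolume(
        voxels=hu,
        pixel_spacing=(spacing[0], spacing[1]),
        slice_positions=zs,
        origin=(ipp[0], origin_v, zs[0]),
    )


# --------------------------------------------------------------------------
# intensity transform / segmentation
# --------------------------------------------------------------------------

def intensity_transform(vol, window_low: float, window_high: float) -> np.ndarray:
    """Linear HU window to 8-bit grayscale, clamped, rounded half-up."""
    if window_low >= window_high:
        raise ContourError("window_low must be < window_high")
    hu = vol.voxels if isinstance(vol, CTVolume) else np.asarray(vol)
    g = (hu.astype(np.float64) - window_low) * 255.0 / (window_high - window_low)
    g = np.clip(np.floor(g + 0.5), 0.0, 255.0)
    return g.astype(np.uint8)


def hu_to_gray(hu: float, window_low: float, window_high: float) -> int:
    """Gray level a given HU maps to under the window (for threshold choice)."""
    return int(intensity_transform(np.array([[[hu]]]), window_low, window_high)[0, 0, 0])


def segment_mask(
    gray: np.ndarray, threshold: int, closing_radius_px: int = DEFAULT_CLOSING_RADIUS_PX
) -> np.ndarray:
    """Threshold then morphologically close each slice.

    The closing (dilation then erosion with an elliptical structuring element)
    is the smoothing step; an empty mask is a legal output.
    """
    if closing_radius_px < 0:
        raise ContourError("closing_radius_px must be >= 0")
    mask = np.asarray(gray) >= threshold
    if closing_radius_px == 0:
        return mask
    footprint = morphology.ellipse(closing_radius_px, closing_radius_px)
    return np.stack(
        [morphology.closing(m.astype(np.uint8), footprint) > 0 for m in mask]
    )


# --------------------------------------------------------------------------
# contour extraction and cross-slice tracking
# --------------------------------------------------------------------------

def _component_contour(comp_mask: np.ndarray) -> np.ndarray | None:
    """Outer boundary of one connected component in (row, col) index units."""
    padded = np.pad(comp_mask, 1).astype(float)
    rings = measure.find_contours(padded, 0.5)
    if not rings:
        return None
    ring = max(rings, key=len) - 1.0  # undo pad
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    return ring if len(ring) >= 3 else None


def extract_slice_contours(
    mask: np.ndarray,
    vol: CTVolume,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> ContourStack:
    """Trace, filter and track per-slice components into labelled colliders.

    Everything at or below the plate top is removed before labelling — the CT
    couch plate is not a collider (the treatment plate replaces it), and a
    body resting on the plate would otherwise merge with it into one
    component.  Components still entirely below the plate top after the clip
    are discarded, as are components whose polygon area is below
    ``min_area_mm2``.  Components are tracked
    across slices by maximal pixel overlap (ties by centroid distance); the
    track with the largest total volume is the ``body``, the others become
    ``accessory_1`` ... in descending volume order.
    """
    if vol.isocenter_mm is None or vol.plate_height_mm is None:
        raise ContourError("isocenter and plate height must be set on the volume")
    ps_row, ps_col = vol.pixel_spacing
    px_area = ps_row * ps_col
    plate = float(vol.plate_height_mm)
    v0 = vol.origin[1]

    # clip away the plate and everything under it before labelling
    vgrid = vol.v_coords()
    mask = np.asarray(mask).copy()
    mask[:, vgrid <= plate, :] = False

    tracks: list[dict] = []  # each: contours [(z, points)], prev slice footprint
    prev: list[tuple[int, np.ndarray, int]] = []  # (track_id, mask, slice_index)
    for k in range(mask.shape[0]):
        labels = measure.label(mask[k], connectivity=2)
        cur: list[tuple[int, np.ndarray, int]] = []
        comps = []
        for region in measure.regionprops(labels):
            comp = labels == region.label
            rows = np.nonzero(comp.any(axis=1))[0]
            top_v = v0 + rows.max() * ps_row
            if top_v <= plate:  # entirely below the plate top
                continue
            if region.area * px_area < min_area_mm2:
                continue
            ring = _component_contour(comp)
            if ring is None:
                continue
            # (row, col) -> (x, v) mm
            pts = np.column_stack(
                [
                    vol.origin[0] + ring[:, 1] * ps_col,
                    v0 + ring[:, 0] * ps_row,
                ]
            )
            comps.append((comp, pts, region.centroid))
        # greedy matching to the previous slice's components by overlap
        used = set()
        for comp, pts, centroid in comps:
            best_tid, best_overlap, best_cdist = None, 0, np.inf
            for tid, pmask, _ in prev:
                if tid in used:
                    continue
                overlap = int(np.count_nonzero(comp & pmask))
                pc = np.argwhere(pmask).mean(axis=0)
                cdist = float(np.hypot(*(np.asarray(centroid) - pc)))
                if overlap > best_overlap or (
                    overlap == best_overlap and overlap > 0 and cdist < best_cdist
                ):
                    best_tid, best_overlap, best_cdist = tid, overlap, cdist
            if best_tid is None or best_overlap == 0:
                tracks.append({"contours": []})
                best_tid = len(tracks) - 1
            used.add(best_tid)
            tracks[best_tid]["contours"].append((float(vol.slice_positions[k]), pts))
            cur.append((best_tid, comp, k))
        prev = cur

    tracks = [t for t in tracks if t["contours"]]
    if not tracks:
        raise ContourError("no collider component survives on any slice")

    def track_volume(t):
        return sum(signed_area(ensure_ccw(p)) for _, p in t["contours"]) * vol.slice_spacing

    tracks.sort(key=track_volume, reverse=True)
    contours: dict[str, list[SliceContour]] = {}
    for i, t in enumerate(tracks):
        name = "body" if i == 0 else f"accessory_{i}"
        contours[name] = [SliceContour(z, pts, name) for z, pts in t["contours"]]
    return ContourStack(
        contours=contours, isocenter_mm=vol.isocenter_mm, plate_height_mm=plate
    )


def contour_pipeline(
    vol: CTVolume,
    window_hu=DEFAULT_WINDOW_HU,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    closing_radius_px: int = DEFAULT_CLOSING_RADIUS_PX,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> ContourStack:
    """Window -> threshold -> close -> trace, with thresholds given in HU."""
    gray = intensity_transform(vol, *window_hu)
    cut = hu_to_gray(threshold_hu, *window_hu)
    mask = segment_mask(gray, cut, closing_radius_px)
    return extract_slice_contours(mask, vol, min_area_mm2)


# --------------------------------------------------------------------------
# DICOM structure-set export / import
# --------------------------------------------------------------------------

_RTSTRUCT_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.3"
_ISO_ROI = "ISOCENTER"
_PLATE_ROI = "CT_PLATE"


def export_contours(stack: ContourStack, path) -> None:
    """Write the stack as an RT-Structure-Set-style DICOM file.

    One CLOSED_PLANAR ROI per collider, a POINT ROI for the isocenter and a
    dedicated CLOSED_PLANAR ROI (a square at plate height) for the CT plate.
    Contour points round-trip within 1e-3 mm.  Exact tag usage is documented
    in docs/rtstruct_dialect.md.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if stack.isocenter_mm is None:
        raise ContourError("stack has no isocenter")
    if stack.plate_height_mm is None:
        raise ContourError("stack has no plate height")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = _RTSTRUCT_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "rtclear"

    def _contour_item(points3d, geom="CLOSED_PLANAR"):
        item = Dataset()
        item.ContourGeometricType = geom
        item.NumberOfContourPoints = len(points3d)
        item.ContourData = [f"{c:.4f}" for p in points3d for c in p]
        return item

    roi_seq, cont_seq = [], []

    def _add_roi(number, name, items):
        r = Dataset()
        r.ROINumber = number
        r.ROIName = name
        roi_seq.append(r)
        c = Dataset()
        c.ReferencedROINumber = number
        c.ContourSequence = items
        cont_seq.append(c)

    num = 1
    for label in stack.labels():
        items = [
            _contour_item([(p[0], p[1], sc.z_mm) for p in sc.points])
            for sc in stack.for_label(label)
        ]
        _add_roi(num, label, items)
        num += 1
    iso = stack.isocenter_mm
    _add_roi(num, _ISO_ROI, [_contour_item([iso], geom="POINT")])
    num += 1
    h = stack.plate_height_mm
    z0 = stack.for_label(stack.labels()[0])[0].z_mm
    square = [(-100.0, h, z0), (100.0, h, z0), (100.0, h, z0 + 1.0), (-100.0, h, z0 + 1.0)]
    _add_roi(num, _PLATE_ROI, [_contour_item(square)])

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = cont_seq
    ds.save_as(str(path), enforce_file_format=True)


def import_contours(path) -> ContourStack:
    """Read a structure file written by :func:`export_contours`."""
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as e:  # pragma: no cover - message path
        raise ContourError(f"cannot parse {path}: {e}") from e
    if getattr(ds, "SOPClassUID", None) != _RTSTRUCT_CLASS_UID:
        raise ContourError(f"{path} is not an RT structure set")

    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    contours: dict[str, list[SliceContour]] = {}
    isocenter = None
    plate_height = None
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        for item in rc.ContourSequence:
            data = np.array([float(v) for v in item.ContourData]).reshape(-1, 3)
            if name == _ISO_ROI:
                isocenter = tuple(data[0])
            elif name == _PLATE_ROI:
                plate_height = float(data[0, 1])
            else:
                contours.setdefault(name, []).append(
                    SliceContour(float(data[0, 2]), data[:, :2], name)
                )
    if isocenter is None:
        raise ContourError("structure file lacks the isocenter point ROI")
    if plate_height is None:
        raise ContourError("structure file lacks the plate-height ROI")
    if not contours:
        raise ContourError("structure file contains no collider ROIs")
    return ContourStack(contours, isocenter, plate_height)
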