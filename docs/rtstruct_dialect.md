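# Structure-file dialect

`export_contours` writes a DICOM RT-Structure-Set-style file
(SOP class `1.2.840.10008.5.1.4.1.1.481.3`) with exactly three kinds of
ROIs, so a collision case round-trips through one file:

| ROI name | geometric type | content |
|---|---|---|
| `body`, `accessory_1`, ... | `CLOSED_PLANAR` | one contour item per slice; `ContourData` triplets are `(x, v, z)` mm in the CT frame (see COORDINATES.md) |
| `ISOCENTER` | `POINT` | the manually defined isocenter `(x, v, z)` |
| `CT_PLATE` | `CLOSED_PLANAR` | a marker square whose `v` coordinate is the CT plate-top height |

Details that make files round-trip stably:

- `StructureSetROISequence` holds `ROINumber`/`ROIName`; `ROIContourSequence`
  references them by `ReferencedROINumber`.
- Contour points are written with 4 decimal places (`%.4f`), so re-imported
  points match within 1e-3 mm.
- The first point is not repeated at the end; polygons are closed
  implicitly and re-oriented counter-clockwise on import.
- Importing a file that lacks the `ISOCENTER` or `CT_PLATE` ROI, or any
  collider ROI, is an error — the three sequences together are the contract.

The dialect deliberately omits the image-reference plumbing of full clinical
RT Structure Sets (referenced frame UIDs per contour, ROI observations):
collision prediction needs geometry only.  Clinical systems can still read
the contours; files produced by other systems import as long as the three
ROI kinds are present.
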