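"""Synthetic SFM images with known ground truth, and tiny fixture-file writers.

Real SFM scans of DNA and protein are not reproducible at desk scale, so the
test bench is built from analytically known surfaces:

* Gaussian blobs — ``h(r) = A exp(-|r-c|^2 / (2 sigma^2))`` with exact volume
  ``2 pi sigma^2 A x pixel_area`` (the continuum integral; the discrete sum
  converges to it for sigma >= 2 px).
* Filaments — ridges of Gaussian cross-section around a centerline (straight
  line, circular arc, or a curvature-limited smooth random walk) with exact
  contour length.  Gaussian broadening of the cross-section stands in for the
  probe's tip-sample convolution: a blunter tip is emulated by a larger sigma.
* Additive plane tilt and seeded Gaussian noise, for robustness tests.

The fixture writers emit minimal, spec-conformant files in every dialect the
readers support (NanoScope v5, JPK TIFF, Igor binary wave v5, ASCII with and
without headers, plain TIFF/JPEG/PNG), so each reader is exercised end-to-end
without any binary assets or downloads.  They are test/dev API only, not an
end-user export path.

All randomness is seeded; the seed is recorded in the GroundTruth.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .io_formats import (
    IBW_BINHEADER5,
    IBW_BINHEADER5_SIZE,
    IBW_DATA_OFFSET,
    IBW_WAVEHEADER5_SIZE,
    JPK_TAG_A_MULT,
    JPK_TAG_A_OFF,
    JPK_TAG_B_MULT,
    JPK_TAG_B_OFF,
    JPK_TAG_SCAN_X,
    JPK_TAG_SCAN_Y,
    HeightMap,
)

logger = logging.getLogger("afmetrics")

DIALECTS = ("nanoscope", "jpk", "ibw", "ascii", "ascii_header", "tiff", "jpeg", "png")


@dataclass
class GroundTruth:
    """What the generator actually drew, for closing the recovery loop."""

    kind: str                               # "blob" | "filament"
    sigma_px: float
    amplitude_nm: float
    pixel_size_nm: float
    analytic_volume_nm3: Optional[float] = None
    contour_length_nm: Optional[float] = None
    centerline: Optional[np.ndarray] = None   # (n, 2) (row, col)
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma_px: float,
    amplitude_nm: float,
    pixel_size_nm: float = 1.0,
) -> tuple[HeightMap, GroundTruth]:
    """Isotropic Gaussian bump; ground truth carries the continuum volume."""
    if sigma_px < 1:
        raise ParameterError(f"sigma_px must be >= 1, got {sigma_px}")
    rows, cols = shape
    cr, cc = center
    margin = 4 * sigma_px
    if not (margin <= cr <= rows - 1 - margin and margin <= cc <= cols - 1 - margin):
        raise ParameterError(
            f"blob at {center} with sigma {sigma_px} px reaches within 4 sigma of a "
            f"border of shape {shape} (it would be suppressed by detection)"
        )
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    heights = amplitude_nm * np.exp(
        -((r - cr) ** 2 + (c - cc) ** 2) / (2.0 * sigma_px**2)
    )
    hmap = HeightMap(
        heights=heights,
        pixel_size_x=pixel_size_nm,
        pixel_size_y=pixel_size_nm,
        source_format="ascii",
        source_path="",
        channel_name="synthetic blob",
    )
    truth = GroundTruth(
        kind="blob",
        sigma_px=sigma_px,
        amplitude_nm=amplitude_nm,
        pixel_size_nm=pixel_size_nm,
        analytic_volume_nm3=2.0 * math.pi * sigma_px**2 * amplitude_nm * pixel_size_nm**2,
        centerline=np.array([[cr, cc]], dtype=float),
    )
    return hmap, truth


def centerline_line(p0: tuple[float, float], p1: tuple[float, float], step_px: float = 0.5) -> np.ndarray:
    """Straight polyline from p0 to p1 at ~step_px spacing."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / step_px)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p0 + t * (p1 - p0)


def centerline_arc(
    center: tuple[float, float],
    radius_px: float,
    theta_start: float,
    theta_end: float,
    step_px: float = 0.25,
) -> np.ndarray:
    """Circular-arc polyline (angles in radians; row = center + R sin, col = center + R cos)."""
    arc = abs(theta_end - theta_start) * radius_px
    n = max(int(np.ceil(arc / step_px)), 2)
    theta = np.linspace(theta_start, theta_end, n + 1)
    cr, cc = center
    return np.column_stack([cr + radius_px * np.sin(theta), cc + radius_px * np.cos(theta)])


def centerline_random_walk(
    shape: tuple[int, int],
    seed: int,
    length_px: float,
    margin_px: float,
    max_turn_rad_per_px: float,
    min_self_distance_px: float = 0.0,
    step_px: float = 1.0,
    max_attempts: int = 200,
) -> tuple[np.ndarray, int]:
    """Curvature-limited smooth random walk inside the margins.

    The heading turns by an AR(1)-smoothed increment clipped to
    ``max_turn_rad_per_px`` (so the curvature radius is >= 1/max_turn), with a
    gentle steer toward the image center when close to the margin.  Walks that
    leave the allowed region or approach themselves closer than
    ``min_self_distance_px`` are regenerated with the next seed (logged).
    Returns the polyline and the seed that finally produced it.
    """
    rows, cols = shape
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    n_steps = int(round(length_px / step_px))
    for attempt in range(max_attempts):
        s = seed + attempt
        rng = np.random.default_rng(s)
        pos = center + rng.uniform(-0.15, 0.15, size=2) * min(rows, cols)
        heading = rng.uniform(0, 2 * math.pi)
        turn = 0.0
        pts = [pos.copy()]
        ok = True
        for _ in range(n_steps):
            turn = 0.9 * turn + 0.1 * rng.normal(0.0, 3.0 * max_turn_rad_per_px)
            turn = float(np.clip(turn, -max_turn_rad_per_px, max_turn_rad_per_px))
            # steer toward center when the border is near (within the turn limit)
            d_border = min(pos[0], pos[1], rows - 1 - pos[0], cols - 1 - pos[1])
            if d_border < 2.5 * margin_px:
                to_center = math.atan2(*(center - pos))
                dev = (to_center - heading + math.pi) % (2 * math.pi) - math.pi
                turn = float(np.clip(turn + 0.3 * dev, -max_turn_rad_per_px, max_turn_rad_per_px))
            heading += turn * step_px
            pos = pos + step_px * np.array([math.sin(heading), math.cos(heading)])
            pts.append(pos.copy())
            if not (margin_px <= pos[0] <= rows - 1 - margin_px
                    and margin_px <= pos[1] <= cols - 1 - margin_px):
                ok = False
                break
        if not ok:
            logger.debug("random walk left margins with seed %d; retrying", s)
            continue
        line = np.asarray(pts)
        if min_self_distance_px > 0:
            tree = cKDTree(line)
            sep = int(np.ceil(2.0 * min_self_distance_px / step_px)) + 2
            close = tree.query_pairs(min_self_distance_px, output_type="ndarray")
            if close.size and np.any(np.abs(close[:, 0] - close[:, 1]) > sep):
                logger.debug("random walk self-intersects with seed %d; retrying", s)
                continue
        return line, s
    raise ParameterError(
        f"could not generate a valid random walk of {length_px} px in shape {shape} "
        f"after {max_attempts} attempts from seed {seed}"
    )


def make_filament(
    shape: tuple[int, int],
    centerline: np.ndarray,
    sigma_px: float,
    amplitude_nm: float,
    pixel_size_nm: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[HeightMap, GroundTruth]:
    """Ridge of Gaussian cross-section around a polyline centerline.

    ``h(p) = A exp(-d(p, centerline)^2 / (2 sigma^2))`` with d the Euclidean
    distance to the (densely resampled) polyline.  Ground truth holds the
    exact centerline length in nm.
    """
    if sigma_px < 1:
        raise ParameterError(f"sigma_px must be >= 1, got {sigma_px}")
    rows, cols = shape
    line = np.asarray(centerline, dtype=float)
    margin = 4 * sigma_px
    if (line[:, 0].min() < margin or line[:, 1].min() < margin
            or line[:, 0].max() > rows - 1 - margin or line[:, 1].max() > cols - 1 - margin):
        raise ParameterError(
            f"centerline reaches within 4 sigma ({margin:.1f} px) of a border"
        )

    # densify so nearest-point distance approximates distance-to-curve
    seg = np.hypot(*np.diff(line, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    dense_t = np.linspace(0.0, t[-1], max(int(t[-1] / 0.1), 2))
    dense = np.column_stack([
        np.interp(dense_t, t, line[:, 0]),
        np.interp(dense_t, t, line[:, 1]),
    ])
    tree = cKDTree(dense)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, _ = tree.query(pix, workers=-1)
    heights = amplitude_nm * np.exp(-(d**2) / (2.0 * sigma_px**2)).reshape(rows, cols)

    contour_nm = float(np.hypot(*np.diff(line, axis=0).T).sum() * pixel_size_nm)
    hmap = HeightMap(
        heights=heights,
        pixel_size_x=pixel_size_nm,
        pixel_size_y=pixel_size_nm,
        source_format="ascii",
        source_path="",
        channel_name="synthetic filament",
    )
    truth = GroundTruth(
        kind="filament",
        sigma_px=sigma_px,
        amplitude_nm=amplitude_nm,
        pixel_size_nm=pixel_size_nm,
        contour_length_nm=contour_nm,
        centerline=line,
        seed=seed,
    )
    return hmap, truth


def add_plane(hmap: HeightMap, slope_row_nm_per_px: float, slope_col_nm_per_px: float) -> HeightMap:
    """Add a deterministic tilt plane (nm per pixel index along each axis)."""
    rows, cols = hmap.shape
    plane = (
        slope_row_nm_per_px * np.arange(rows)[:, None]
        + slope_col_nm_per_px * np.arange(cols)[None, :]
    )
    from dataclasses import replace

    return replace(hmap, heights=hmap.heights + plane)


def add_noise(hmap: HeightMap, sigma_nm: float, seed: int = 0) -> HeightMap:
    """Add seeded i.i.d. Gaussian height noise."""
    from dataclasses import replace

    if sigma_nm == 0:
        return replace(hmap, heights=hmap.heights.copy())
    rng = np.random.default_rng(seed)
    return replace(hmap, heights=hmap.heights + rng.normal(0.0, sigma_nm, hmap.shape))


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def write_nanoscope_fixture(
    hmap: HeightMap,
    path: str | Path,
    quantization_step_nm: Optional[float] = None,
) -> dict:
    """Minimal NanoScope v5 file: text header block + 16-bit LE binary data.

    ``quantization_step_nm`` is the nm value of one raw LSB (encoded in the
    header as Z scale with Z sensitivity 1); defaults to max|h|/32000.
    Returns the reader kwargs (none needed) plus the quantization bound.
    """
    path = Path(path)
    h = hmap.heights
    max_abs = float(np.abs(h).max())
    step = quantization_step_nm if quantization_step_nm else (max_abs / 32000.0 or 1.0)
    raw = np.round(h / step)
    if np.abs(raw).max() > 32767:
        raise ParameterError(
            f"dynamic range {max_abs} nm cannot be represented at step {step} nm in int16"
        )
    rows, cols = h.shape
    offset = 512
    header = (
        "\\*File list\r\n"
        "\\Version: 0x05300002\r\n"
        f"\\Scan size: {cols * hmap.pixel_size_x:.9g} {rows * hmap.pixel_size_y:.9g} nm\r\n"
        f"\\Samps/line: {cols}\r\n"
        f"\\Lines: {rows}\r\n"
        f"\\Data offset: {offset}\r\n"
        f"\\Data length: {rows * cols * 2}\r\n"
        f"\\Z scale: {step * 65536.0:.12g}\r\n"
        "\\Z sensitivity: 1\r\n"
        "\\*File list end\r\n"
    ).encode("latin-1")
    if len(header) > offset:
        raise ParameterError("fixture header exceeds the fixed data offset")
    with open(path, "wb") as fh:
        fh.write(header.ljust(offset, b"\x1a"))
        fh.write(raw.astype("<i2").tobytes())
    return {"quantization_nm": step / 2.0}


def write_jpk_fixture(
    hmap: HeightMap,
    path: str | Path,
    layout: str = "4.2.53",
    multiplier: Optional[float] = None,
    offset: Optional[float] = None,
) -> dict:
    """Two-page JPK TIFF: uint8 thumbnail then calibrated uint16 data page.

    Default calibration: multiplier = range/65535, offset = min, so the
    round-trip error is bounded by one quantization step.  ``layout`` selects
    which private-tag pair carries (multiplier, offset).
    """
    import tifffile

    path = Path(path)
    h = hmap.heights
    if multiplier is None or offset is None:
        rng = float(h.max() - h.min())
        multiplier = rng / 65535.0 if rng > 0 else 1.0
        offset = float(h.min())
    raw = np.clip(np.round((h - offset) / multiplier), 0, 65535).astype(np.uint16)

    if layout == "4.2.53":
        tag_mult, tag_off = JPK_TAG_B_MULT, JPK_TAG_B_OFF
    elif layout == "pre-4.2.53":
        tag_mult, tag_off = JPK_TAG_A_MULT, JPK_TAG_A_OFF
    else:
        raise ParameterError(f"unknown JPK layout {layout!r}")

    rows, cols = h.shape
    thumb = (raw[:: max(rows // 16, 1), :: max(cols // 16, 1)] >> 8).astype(np.uint8)
    extratags = [
        (tag_mult, "d", 1, float(multiplier), True),
        (tag_off, "d", 1, float(offset), True),
        (JPK_TAG_SCAN_X, "d", 1, cols * hmap.pixel_size_x, True),
        (JPK_TAG_SCAN_Y, "d", 1, rows * hmap.pixel_size_y, True),
    ]
    with tifffile.TiffWriter(str(path)) as tif:
        tif.write(thumb)                       # thumbnail page, skipped on read
        tif.write(raw, extratags=extratags)
    return {"quantization_nm": float(multiplier) / 2.0}


def write_ibw_fixture(
    path: str | Path,
    array: np.ndarray,
    delta_x: float,
    delta_y: float,
    data_units: str = "nm",
    dim_units: str = "nm",
    layer_labels: Optional[Sequence[str]] = None,
    name: str = "HeightRetrace",
) -> dict:
    """Igor binary wave v5 with float64 data (2-D, or 3-D with layer labels).

    ``array`` axes are (row, col[, layer]); values and axis deltas are in
    ``data_units`` / ``dim_units`` (the reader converts "m", "um", "nm" to nm).
    The byte layout (BinHeader5 + WaveHeader5 + column-major data + dimension
    labels, checksummed over the first 384 bytes) follows the published v5
    structure.
    """
    path = Path(path)
    arr = np.asarray(array, dtype="<f8")
    if arr.ndim not in (2, 3):
        raise ParameterError("IBW fixture must be 2-D or 3-D")
    data = arr.tobytes(order="F")
    npnts = arr.size

    n_dim = [0, 0, 0, 0]
    for i, d in enumerate(arr.shape):
        n_dim[i] = d
    sf_a = [delta_y, delta_x, 1.0, 1.0]        # dim 0 = rows (y), dim 1 = cols (x)
    sf_b = [0.0, 0.0, 0.0, 0.0]

    dim_labels_chunks = b""
    dim_labels_size = [0, 0, 0, 0]
    if arr.ndim == 3 and layer_labels is not None:
        if len(layer_labels) != arr.shape[2]:
            raise ParameterError("need one label per layer")
        chunk = b"\x00" * 32
        for lbl in layer_labels:
            chunk += lbl.encode("latin-1")[:31].ljust(32, b"\x00")
        dim_labels_size[2] = len(chunk)
        dim_labels_chunks = chunk

    wh = bytearray(IBW_WAVEHEADER5_SIZE)
    struct.pack_into("<i", wh, 12, npnts)
    struct.pack_into("<h", wh, 16, 4)          # NT_FP64
    wh[28:60] = name.encode("latin-1")[:31].ljust(32, b"\x00")
    struct.pack_into("<4i", wh, 68, *n_dim)
    struct.pack_into("<4d", wh, 84, *sf_a)
    struct.pack_into("<4d", wh, 116, *sf_b)
    wh[148:152] = data_units.encode("latin-1")[:4].ljust(4, b"\x00")
    for d in range(4):
        wh[152 + 4 * d:156 + 4 * d] = dim_units.encode("latin-1")[:4].ljust(4, b"\x00")

    bin5 = struct.pack(
        IBW_BINHEADER5,
        5, 0,                                   # version, checksum placeholder
        IBW_WAVEHEADER5_SIZE + len(data),       # wfmSize
        0, 0, 0,                                # formula, note, dataEUnits
        0, 0, 0, 0,                             # dimEUnitsSize
        *dim_labels_size,
        0, 0, 0,
    )
    head = bytearray(bin5 + bytes(wh))
    shorts = struct.unpack(f"<{IBW_DATA_OFFSET // 2}h", bytes(head))
    checksum = (-sum(shorts)) & 0xFFFF
    if checksum >= 0x8000:
        checksum -= 0x10000
    struct.pack_into("<h", head, 2, checksum)

    with open(path, "wb") as fh:
        fh.write(bytes(head))
        fh.write(data)
        fh.write(dim_labels_chunks)
    return {"quantization_nm": 0.0}


def write_ascii_fixture(
    hmap: HeightMap, path: str | Path, header: bool = False, delimiter: str = " "
) -> dict:
    """x-y-z text table at 6 significant digits, optionally with 2 header lines."""
    path = Path(path)
    rows, cols = hmap.shape
    with open(path, "w", encoding="ascii") as fh:
        if header:
            fh.write("# synthetic SFM fixture, columns: x[nm] y[nm] z[nm]\n")
            fh.write("x y z\n")
        for r in range(rows):
            y = r * hmap.pixel_size_y
            for c in range(cols):
                x = c * hmap.pixel_size_x
                fh.write(
                    f"{x:.6g}{delimiter}{y:.6g}{delimiter}{hmap.heights[r, c]:.6g}\n"
                )
    return {"quantization_nm": np.abs(hmap.heights).max() * 1e-5}


def write_raster_fixture(hmap: HeightMap, path: str | Path, kind: str = "png") -> dict:
    """Plain raster fixture; returns the kwargs read_raster needs.

    * tiff: float32, lossless (down to float32 precision), heights as-is.
    * png: 16-bit, heights shifted to min 0 and scaled to the full range.
    * jpeg: 8-bit, lossy — round-trip asserts correlation, not equality.
    """
    import imageio.v3 as iio

    path = Path(path)
    h = hmap.heights
    if kind == "tiff":
        import tifffile

        tifffile.imwrite(str(path), h.astype(np.float32))
        return {
            "height_scale_nm_per_unit": 1.0,
            "pixel_size_nm": hmap.pixel_size_x,
            "quantization_nm": float(np.abs(h).max()) * 2.0**-23,
        }
    rng = float(h.max() - h.min())
    if kind == "png":
        step = rng / 65535.0 if rng > 0 else 1.0
        raw = np.round((h - h.min()) / step).astype(np.uint16)
    elif kind == "jpeg":
        step = rng / 255.0 if rng > 0 else 1.0
        raw = np.round((h - h.min()) / step).astype(np.uint8)
    else:
        raise ParameterError(f"unknown raster kind {kind!r}")
    iio.imwrite(str(path), raw)
    return {
        "height_scale_nm_per_unit": step,
        "pixel_size_nm": hmap.pixel_size_x,
        "quantization_nm": step / 2.0,
        "offset_nm": float(h.min()),
    }


def write_fixture(hmap: HeightMap, dialect: str, path: str | Path) -> dict:
    """Write ``hmap`` in the given dialect; returns reader kwargs / quantization.

    Dialects: nanoscope, jpk, ibw, ascii, ascii_header, tiff, jpeg, png.
    """
    if dialect == "nanoscope":
        return write_nanoscope_fixture(hmap, path)
    if dialect == "jpk":
        return write_jpk_fixture(hmap, path)
    if dialect == "ibw":
        return write_ibw_fixture(
            path, hmap.heights, delta_x=hmap.pixel_size_x, delta_y=hmap.pixel_size_y
        )
    if dialect == "ascii":
        return write_ascii_fixture(hmap, path, header=False)
    if dialect == "ascii_header":
        return write_ascii_fixture(hmap, path, header=True)
    if dialect in ("tiff", "jpeg", "png"):
        return write_raster_fixture(hmap, path, kind=dialect)
    raise ParameterError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
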