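"""Downstream processing of bead logs: parse, normalise, bin, average.

Mirrors the study's analysis chain: the ImageJ macro emits, per bead, an
(area, mean Ras intensity, perimeter) triple followed by the effector
intensity at every timepoint, each measurement comma-terminated on its own
line and each bead closed by a ``!`` marker.  Traces are normalised to the
bead perimeter (the signal lives on the bead surface), zeroed at t0, and
binned by Ras density; bins are averaged pointwise with SEM.  A minimal
particle detector (threshold, connected components, area and circularity
filters, border exclusion) recovers bead ROIs from synthetic images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import (
    DensityCalibration,
    assign_density_bin,
    concentration_to_density,
    intensity_to_concentration,
)
from .features import Timecourse
from .synthetic_data import BeadDataset, BeadRecord

__all__ = [
    "BinnedResponse",
    "ROI",
    "ParseError",
    "parse_bead_log",
    "normalize_trace",
    "bin_and_average",
    "detect_beads",
]

DEFAULT_SAMPLE_DT = 900.0  # s, the 15-min imaging interval


class ParseError(ValueError):
    """Malformed bead-log file; carries the offending line number."""


@dataclass
class BinnedResponse:
    bin: float                 # molecules/um^2
    mean_trace: np.ndarray     # perimeter-normalised, t0-zeroed AU
    sem_trace: np.ndarray | None   # None when n_beads < 2
    n_beads: int
    times_s: np.ndarray


def _parse_number(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: expected a number, got {token!r}") from None


def parse_bead_log(path, sample_dt: float = DEFAULT_SAMPLE_DT) -> BeadDataset:
    """Parse the macro log dialect back into a :class:`BeadDataset`.

    Inverse of :func:`rascycle.synthetic_data.emit_log_format` (lossless to
    float round-trip).  Ragged blocks (differing trace lengths) and blocks
    missing their ``!`` terminator are rejected with the line number.
    """
    beads: list[BeadRecord] = []
    header: tuple[float, float, float] | None = None
    header_line = 0
    trace: list[float] = []
    n_expected: int | None = None
    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "!":
                if header is None:
                    raise ParseError(f"line {lineno}: stop marker with no bead block")
                if n_expected is None:
                    n_expected = len(trace)
                elif len(trace) != n_expected:
                    raise ParseError(
                        f"line {lineno}: bead has {len(trace)} timepoints, "
                        f"expected {n_expected}"
                    )
                area, ras_mean, perim = header
                radius = perim / (2.0 * np.pi)
                beads.append(
                    BeadRecord(
                        bead_id=len(beads),
                        radius_px=radius,
                        ras_intensity=ras_mean,
                        true_density=np.nan,
                        effector_trace=np.asarray(trace),
                    )
                )
                header, trace = None, []
                continue
            tokens = [t for t in line.split(",") if t != ""]
            if header is None:
                if len(tokens) != 3:
                    raise ParseError(
                        f"line {lineno}: bead header must have 3 fields, got {len(tokens)}"
                    )
                header = tuple(_parse_number(t, lineno) for t in tokens)
                header_line = lineno
            else:
                if len(tokens) != 1:
                    raise ParseError(
                        f"line {lineno}: timepoint line must have 1 field, got {len(tokens)}"
                    )
                trace.append(_parse_number(tokens[0], lineno))
    if header is not None:
        raise ParseError(
            f"end of file: bead block starting at line {header_line} "
            "is missing its '!' terminator"
        )
    n_t = n_expected or 0
    times = np.arange(n_t) * sample_dt
    return BeadDataset(beads=beads, times_s=times)


def normalize_trace(
    rec: BeadRecord, times_s: np.ndarray | None = None
) -> Timecourse:
    """Perimeter-normalise and zero a raw bead trace at t0."""
    if rec.effector_trace is None:
        raise ValueError(f"bead {rec.bead_id} has no trace")
    if rec.perimeter_px <= 0:
        raise ValueError(f"bead {rec.bead_id} has non-positive perimeter")
    if times_s is None:
        times_s = np.arange(len(rec.effector_trace)) * DEFAULT_SAMPLE_DT
    values = np.asarray(rec.effector_trace, dtype=float) / rec.perimeter_px
    values = values - values[0]
    return Timecourse(np.asarray(times_s, dtype=float), values)


def bin_and_average(
    ds: BeadDataset, cal: DensityCalibration | None = None
) -> list[BinnedResponse]:
    """Assign beads to density bins and average normalised traces per bin.

    Density is estimated from the Ras-channel intensity through the
    calibration chain; SEM is the per-timepoint sample standard deviation
    over beads divided by sqrt(n).  Bins with no beads are omitted; the
    result does not depend on bead order.
    """
    if not ds.beads:
        raise ValueError("empty dataset")
    cal = cal or ds.calibration or DensityCalibration()
    groups: dict[float, list[np.ndarray]] = {}
    for b in ds.beads:
        density = concentration_to_density(
            intensity_to_concentration(b.ras_intensity, cal), cal
        )
        bin_center = assign_density_bin(density, cal)
        groups.setdefault(bin_center, []).append(
            normalize_trace(b, ds.times_s).values
        )
    out = []
    for center in sorted(groups):
        traces = np.vstack(groups[center])
        n = traces.shape[0]
        sem = traces.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else None
        times = (
            np.asarray(ds.times_s, dtype=float)
            if ds.times_s is not None
            else np.arange(traces.shape[1]) * DEFAULT_SAMPLE_DT
        )
        out.append(
            BinnedResponse(
                bin=center,
                mean_trace=traces.mean(axis=0),
                sem_trace=sem,
                n_beads=n,
                times_s=times,
            )
        )
    return out


@dataclass(frozen=True)
class ROI:
    label: int
    centroid: tuple[float, float]   # (row, col)
    area_px: float
    perimeter_px: float
    circularity: float


def detect_beads(
    image: np.ndarray,
    min_area: float = 400.0,
    max_area: float = 15000.0,
    circ_min: float = 0.60,
    circ_max: float = 1.00,
    threshold: float | None = None,
) -> list[ROI]:
    """Threshold + connected components + area/circularity particle filter.

    Circularity is the ImageJ convention 4*pi*A/P^2 (clipped at 1, where
    digitisation can push the estimate slightly above one); components
    touching the image border are excluded.  ``threshold`` defaults to
    Otsu's method.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops
    from skimage.segmentation import clear_border

    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"detect_beads expects a 2-D image, got shape {image.shape}")
    if threshold is None:
        threshold = threshold_otsu(image)
    mask = clear_border(image > threshold)
    labels = label(mask, connectivity=2)
    rois = []
    for rp in regionprops(labels):
        if not (min_area <= rp.area <= max_area):
            continue
        perim = rp.perimeter
        if perim <= 0:
            continue
        circ = min(4.0 * np.pi * rp.area / perim**2, 1.0)
        if not (circ_min <= circ <= circ_max):
            continue
        rois.append(
            ROI(
                label=rp.label,
                centroid=tuple(rp.centroid),
                area_px=float(rp.area),
                perimeter_px=float(perim),
                circularity=float(circ),
            )
        )
    return rois
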