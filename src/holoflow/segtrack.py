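"""Cell detection, shape filtering, frame-to-frame tracking, and projection
cropping on off-axis hologram videos.

The detection recipe works on the raw holograms: average all frames into a
background image, subtract it from each frame (removing the static fringe
pattern), binarize the residual, dilate with a disk whose diameter matches
the fringe period (bridging fringe-split blobs), fill holes, and measure
connected-component region properties.  Detections are filtered by area,
axes ratio, circularity, eccentricity, and equivalent diameter (with
defaults matched to a 40x magnification recording; all thresholds are
configurable and should be re-tuned once per experiment).  Surviving
detections are greedily associated across frames into per-cell tracks, and
each track is cropped from the raw holograms and zero-padded into a uniform
projection set for the classifier.

Coordinates are 0-based (row, col); the flow axis is the column axis;
bounding boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import dilation, disk

from .reconstruct import SpectralPeak, extract_wavefront, locate_carrier
from .types import ComplexWavefront, HologramFrame

__all__ = [
    "BackgroundModel",
    "DetectionRecord",
    "FilterCriteria",
    "TrackCriteria",
    "CellTrack",
    "ProjectionSet",
    "estimate_background",
    "detect_cells",
    "filter_detections",
    "link_tracks",
    "crop_and_pad",
    "extract_projection_sets",
]


@dataclass
class BackgroundModel:
    """Pixel-wise mean of all video frames, used both for fringe removal in
    detection and as the cell-free hologram for wavefront compensation."""

    mean_frame: np.ndarray

    def background_wavefront(
        self, peak: SpectralPeak | None = None, window_radius: float | None = None
    ) -> ComplexWavefront:
        """Demodulate the mean frame into a background complex wavefront."""
        if peak is None:
            peak = locate_carrier(self.mean_frame)
        return extract_wavefront(self.mean_frame, peak, window_radius)


@dataclass
class DetectionRecord:
    """Region properties of one detected connected component."""

    frame_index: int
    centroid: tuple[float, float]  # (row, col)
    area: float
    eccentricity: float
    major_axis_length: float
    minor_axis_length: float
    circularity: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    equivalent_diameter: float
    fully_in_frame: bool = True

    @property
    def axes_ratio(self) -> float:
        """minor/major axis ratio; 1 for degenerate (sub-pixel) regions."""
        if self.major_axis_length <= 0:
            return 1.0
        return self.minor_axis_length / self.major_axis_length


@dataclass(frozen=True)
class FilterCriteria:
    """Shape gates a detection must pass to count as a cell.

    Range endpoints are inclusive; one-sided bounds are strict, matching the
    convention in which they are quoted ("> 0.62", "< 0.85").
    """

    area_range: tuple[float, float] = (300.0, 7100.0)
    min_axes_ratio: float = 0.62
    min_circularity: float = 0.26
    max_eccentricity: float = 0.85
    size_range: tuple[float, float] = (38.0, 120.0)  # equivalent diameter, px
    require_fully_in_frame: bool = True

    def __post_init__(self) -> None:
        if self.area_range[0] > self.area_range[1] or self.size_range[0] > self.size_range[1]:
            raise ValueError("ranges must be ordered (min, max)")


@dataclass(frozen=True)
class TrackCriteria:
    """Gates for associating a detection with an open track (all strict)."""

    max_perpendicular_gap: float = 21.0
    max_flow_gap: float = 480.0
    max_area_diff: float = 890.0
    max_minor_axis_diff: float = 14.0
    max_major_axis_diff: float = 21.0

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class CellTrack:
    """One physical cell's detections, strictly increasing in frame index."""

    cell_id: int
    detections: list[DetectionRecord] = field(default_factory=list)

    @property
    def last(self) -> DetectionRecord:
        return self.detections[-1]

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class ProjectionSet:
    """Cropped, zero-padded projections of one cell across frames."""

    cell_id: int
    crops: np.ndarray  # (K, pad_size, pad_size)
    frame_indices: list[int]
    pad_size: int
    label: int | None = None

    def __post_init__(self) -> None:
        if self.crops.ndim != 3 or self.crops.shape[1:] != (self.pad_size, self.pad_size):
            raise ValueError("crops must have shape (K, pad_size, pad_size)")


def _frames(video) -> np.ndarray:
    if isinstance(video, np.ndarray):
        if video.ndim != 3:
            raise ValueError("video must be a (frames, rows, cols) array")
        return video
    arr = np.stack([f.intensity if isinstance(f, HologramFrame) else np.asarray(f) for f in video])
    if arr.ndim != 3:
        raise ValueError("video must be a sequence of 2-D frames")
    return arr


def estimate_background(video) -> BackgroundModel:
    """Average all frames of a video into a background hologram."""
    frames = _frames(video)
    if frames.shape[0] < 1:
        raise ValueError("empty video")
    return BackgroundModel(mean_frame=frames.mean(axis=0))


def detect_cells(
    frame,
    background: BackgroundModel,
    fringe_period: float = 4.0,
    threshold: float | None = None,
) -> list[DetectionRecord]:
    """Segment candidate cells in one frame.

    ``threshold`` overrides the default Otsu threshold on the absolute
    background-subtracted image.  A robust noise floor (6 sigma of the
    residual, estimated from the median absolute deviation) guards Otsu
    against cell-free frames, where it would otherwise split pure noise.
    """
    img = frame.intensity if isinstance(frame, HologramFrame) else np.asarray(frame, float)
    frame_index = frame.frame_index if isinstance(frame, HologramFrame) else 0
    if img.shape != background.mean_frame.shape:
        raise ValueError("frame and background shapes differ")
    if fringe_period < 1:
        raise ValueError("fringe_period must be >= 1 pixel")
    diff = np.abs(img - background.mean_frame)
    if diff.max() == 0:
        return []
    if threshold is None:
        med = np.median(diff)
        noise_sigma = 1.4826 * np.median(np.abs(diff - med))
        threshold = max(float(threshold_otsu(diff)), float(med + 6.0 * noise_sigma))
    mask = diff > threshold
    if not mask.any():
        return []
    radius = max(1, int(round(fringe_period / 2.0)))
    mask = dilation(mask, disk(radius))
    mask = ndimage.binary_fill_holes(mask)
    labeled = sk_label(mask)
    h, w = img.shape
    records = []
    for rp in regionprops(labeled):
        perimeter = rp.perimeter
        circularity = 4.0 * np.pi * rp.area / perimeter**2 if perimeter > 0 else 0.0
        r0, c0, r1, c1 = rp.bbox
        records.append(
            DetectionRecord(
                frame_index=frame_index,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=float(rp.area),
                eccentricity=float(rp.eccentricity),
                major_axis_length=float(rp.axis_major_length),
                minor_axis_length=float(rp.axis_minor_length),
                circularity=float(circularity),
                bbox=(r0, c0, r1, c1),
                equivalent_diameter=float(rp.equivalent_diameter_area),
                fully_in_frame=bool(r0 > 0 and c0 > 0 and r1 < h and c1 < w),
            )
        )
    return records


_FILTER_FIELDS = (
    "area",
    "major_axis_length",
    "minor_axis_length",
    "circularity",
    "eccentricity",
    "equivalent_diameter",
    "fully_in_frame",
)


def _get(record, name: str):
    if isinstance(record, dict):
        if name not in record:
            raise ValueError(f"detection record missing field '{name}'")
        return record[name]
    try:
        return getattr(record, name)
    except AttributeError:
        raise ValueError(f"detection record missing field '{name}'") from None


def passes_filter(record, criteria: FilterCriteria) -> bool:
    """Evaluate the five shape gates (and containment) on one record."""
    area = _get(record, "area")
    major = _get(record, "major_axis_length")
    minor = _get(record, "minor_axis_length")
    ratio = minor / major if major > 0 else 1.0
    ok = (
        criteria.area_range[0] <= area <= criteria.area_range[1]
        and ratio > criteria.min_axes_ratio
        and _get(record, "circularity") > criteria.min_circularity
        and _get(record, "eccentricity") < criteria.max_eccentricity
        and criteria.size_range[0] <= _get(record, "equivalent_diameter") <= criteria.size_range[1]
    )
    if criteria.require_fully_in_frame:
        ok = ok and bool(_get(record, "fully_in_frame"))
    return ok


def filter_detections(records, criteria: FilterCriteria = FilterCriteria()) -> list:
    """Keep the records that pass every gate in ``criteria``."""
    return [r for r in records if passes_filter(r, criteria)]


def track_gates_pass(prev, cand, criteria: TrackCriteria, flow_axis: int = 1) -> bool:
    """All association gates between a track's latest detection and a
    candidate: small perpendicular gap, bounded non-negative downstream
    displacement, and similar area and axis lengths (all strict bounds)."""
    perp_axis = 1 - flow_axis
    d_perp = abs(_get(cand, "centroid")[perp_axis] - _get(prev, "centroid")[perp_axis])
    d_flow = _get(cand, "centroid")[flow_axis] - _get(prev, "centroid")[flow_axis]
    return (
        d_perp < criteria.max_perpendicular_gap
        and 0 <= d_flow < criteria.max_flow_gap
        and abs(_get(cand, "area") - _get(prev, "area")) < criteria.max_area_diff
        and abs(_get(cand, "minor_axis_length") - _get(prev, "minor_axis_length"))
        < criteria.max_minor_axis_diff
        and abs(_get(cand, "major_axis_length") - _get(prev, "major_axis_length"))
        < criteria.max_major_axis_diff
    )


def link_tracks(
    detections,
    criteria: TrackCriteria = TrackCriteria(),
    flow_axis: int = 1,
) -> list[CellTrack]:
    """Greedy frame-order association of detections into tracks.

    Within each frame, candidate (detection, track) pairs that pass all gates
    against the track's latest detection are assigned in order of increasing
    centroid distance (ties broken by detection then track index); a track
    accepts at most one detection per frame.  Unmatched detections open new
    tracks.  Every detection ends up in exactly one track.
    """
    by_frame: dict[int, list] = {}
    for det in detections:
        by_frame.setdefault(int(_get(det, "frame_index")), []).append(det)
    tracks: list[CellTrack] = []
    for f in sorted(by_frame):
        dets = by_frame[f]
        pairs = []
        for di, det in enumerate(dets):
            for ti, track in enumerate(tracks):
                if _get(track.last, "frame_index") >= f:
                    continue
                if track_gates_pass(track.last, det, criteria, flow_axis):
                    c0 = _get(track.last, "centroid")
                    c1 = _get(det, "centroid")
                    dist = float(np.hypot(c1[0] - c0[0], c1[1] - c0[1]))
                    pairs.append((dist, di, ti))
        pairs.sort()
        used_d: set[int] = set()
        used_t: set[int] = set()
        for dist, di, ti in pairs:
            if di in used_d or ti in used_t:
                continue
            tracks[ti].detections.append(dets[di])
            used_d.add(di)
            used_t.add(ti)
        for di, det in enumerate(dets):
            if di not in used_d:
                tracks.append(CellTrack(cell_id=len(tracks), detections=[det]))
    return tracks


def crop_and_pad(
    track: CellTrack,
    video,
    pad_size: int = 134,
    max_projections: int = 10,
) -> ProjectionSet:
    """Crop each detection's bounding box from the raw hologram frames and
    zero-pad symmetrically to ``pad_size`` squares (off-by-one padding goes
    to the bottom/right).  At most ``max_projections`` crops are taken, in
    frame order."""
    frames = _frames(video)
    crops = []
    frame_indices = []
    for det in track.detections[:max_projections]:
        r0, c0, r1, c1 = det.bbox
        h, w = r1 - r0, c1 - c0
        if h > pad_size or w > pad_size:
            raise ValueError(
                f"bounding box {h}x{w} exceeds pad_size {pad_size}; increase pad_size"
            )
        crop = frames[det.frame_index, r0:r1, c0:c1]
        top = (pad_size - h) // 2
        left = (pad_size - w) // 2
        padded = np.zeros((pad_size, pad_size), dtype=frames.dtype)
        padded[top : top + h, left : left + w] = crop
        crops.append(padded)
        frame_indices.append(det.frame_index)
    return ProjectionSet(
        cell_id=track.cell_id,
        crops=np.stack(crops),
        frame_indices=frame_indices,
        pad_size=pad_size,
    )


def extract_projection_sets(
    video,
    fringe_period: float = 4.0,
    filter_criteria: FilterCriteria = FilterCriteria(),
    track_criteria: TrackCriteria = TrackCriteria(),
    pad_size: int = 134,
    max_projections: int = 10,
    min_projections: int = 1,
) -> tuple[list[ProjectionSet], BackgroundModel, list[CellTrack]]:
    """Full detection pipeline: background, per-frame detection, filtering,
    tracking, and cropping.  Returns the projection sets (tracks with at
    least ``min_projections`` detections), the background model, and the
    tracks themselves."""
    frames = _frames(video)
    background = estimate_background(frames)
    kept = []
    for i in range(frames.shape[0]):
        records = detect_cells(
            HologramFrame(intensity=frames[i], frame_index=i), background, fringe_period
        )
        kept.extend(filter_detections(records, filter_criteria))
    tracks = link_tracks(kept, track_criteria)
    sets = [
        crop_and_pad(t, frames, pad_size, max_projections)
        for t in tracks
        if len(t) >= min_projections
    ]
    return sets, background, tracks
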