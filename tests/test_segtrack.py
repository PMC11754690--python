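import numpy as np
import pytest

from holoflow import (
    CellTrack,
    DetectionRecord,
    FilterCriteria,
    TrackCriteria,
    crop_and_pad,
    detect_cells,
    estimate_background,
    extract_projection_sets,
    filter_detections,
    link_tracks,
    passes_filter,
    track_gates_pass,
)
from holoflow.types import HologramFrame


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately written from the published
# numbers, not from the library source)
# ---------------------------------------------------------------------------

def oracle_filter(rec) -> bool:
    """Default criteria, spelled out literally: area in [300, 7100],
    minor/major > 0.62, circularity > 0.26, eccentricity < 0.85,
    equivalent diameter in [38, 120], fully inside the frame."""
    get = rec.__getitem__ if isinstance(rec, dict) else lambda n: getattr(rec, n)
    major, minor = get("major_axis_length"), get("minor_axis_length")
    ratio = (minor / major) if major > 0 else 1.0
    if not (300.0 <= get("area") <= 7100.0):
        return False
    if not ratio > 0.62:
        return False
    if not get("circularity") > 0.26:
        return False
    if not get("eccentricity") < 0.85:
        return False
    if not (38.0 <= get("equivalent_diameter") <= 120.0):
        return False
    return bool(get("fully_in_frame"))


def oracle_gates(prev, cand) -> bool:
    """Default association gates: perpendicular (row) gap < 21, downstream
    (column) displacement in [0, 480), area difference < 890, minor-axis
    difference < 14, major-axis difference < 21."""
    d_row = abs(cand.centroid[0] - prev.centroid[0])
    d_col = cand.centroid[1] - prev.centroid[1]
    return (
        d_row < 21.0
        and 0.0 <= d_col < 480.0
        and abs(cand.area - prev.area) < 890.0
        and abs(cand.minor_axis_length - prev.minor_axis_length) < 14.0
        and abs(cand.major_axis_length - prev.major_axis_length) < 21.0
    )


def oracle_link(detections):
    """Reference linker: greedy nearest-first assignment per frame, one
    detection per open track, leftovers start new tracks.  Returns a list of
    lists of detection objects (track order = creation order)."""
    frames = sorted({d.frame_index for d in detections})
    tracks: list[list] = []
    for f in frames:
        dets = [d for d in detections if d.frame_index == f]
        candidates = []
        for di, det in enumerate(dets):
            for ti, tr in enumerate(tracks):
                last = tr[-1]
                if last.frame_index >= f or not oracle_gates(last, det):
                    continue
                dist = np.hypot(
                    det.centroid[0] - last.centroid[0],
                    det.centroid[1] - last.centroid[1],
                )
                candidates.append((float(dist), di, ti))
        taken_d, taken_t = set(), set()
        for dist, di, ti in sorted(candidates):
            if di not in taken_d and ti not in taken_t:
                tracks[ti].append(dets[di])
                taken_d.add(di)
                taken_t.add(ti)
        for di, det in enumerate(dets):
            if di not in taken_d:
                tracks.append([det])
    return tracks


def random_record(rng, as_dict=False):
    """A randomized detection record biased toward the decision boundaries."""

    def draw(lo, hi, boundaries):
        if rng.random() < 0.4:
            b = boundaries[rng.integers(len(boundaries))]
            return float(b + rng.choice([-1e-9, 0.0, 1e-9, -0.5, 0.5]))
        return float(rng.uniform(lo, hi))

    major = draw(0.0, 160.0, [0.0, 38.0, 120.0])
    fields = dict(
        frame_index=int(rng.integers(0, 5)),
        centroid=(float(rng.uniform(0, 300)), float(rng.uniform(0, 500))),
        area=draw(0.0, 9000.0, [300.0, 7100.0]),
        eccentricity=draw(0.0, 1.0, [0.85]),
        major_axis_length=major,
        minor_axis_length=draw(0.0, major if major > 0 else 1.0, [0.62 * major]),
        circularity=draw(0.0, 1.2, [0.26]),
        bbox=(0, 0, 10, 10),
        equivalent_diameter=draw(0.0, 150.0, [38.0, 120.0]),
        fully_in_frame=bool(rng.random() < 0.8),
    )
    if as_dict:
        fields.pop("bbox")
        fields.pop("frame_index")
        fields.pop("centroid")
        return fields
    return DetectionRecord(**fields)


# ---------------------------------------------------------------------------
# filter gates
# ---------------------------------------------------------------------------

def passing_record(**overrides):
    base = dict(
        frame_index=0,
        centroid=(100.0, 100.0),
        area=2000.0,
        eccentricity=0.5,
        major_axis_length=55.0,
        minor_axis_length=45.0,
        circularity=0.9,
        bbox=(75, 75, 125, 125),
        equivalent_diameter=50.0,
        fully_in_frame=True,
    )
    base.update(overrides)
    return DetectionRecord(**base)


def test_documented_examples():
    crit = FilterCriteria()
    assert passes_filter(passing_record(), crit)
    # area 200 px falls below the 300 px floor and is rejected
    assert not passes_filter(passing_record(area=200.0), crit)
    # area 1000 px is inside [300, 7100] and kept
    assert passes_filter(passing_record(area=1000.0), crit)


def test_boundary_semantics():
    crit = FilterCriteria()
    # range endpoints are inclusive
    assert passes_filter(passing_record(area=300.0), crit)
    assert passes_filter(passing_record(area=7100.0), crit)
    assert passes_filter(passing_record(equivalent_diameter=38.0), crit)
    assert passes_filter(passing_record(equivalent_diameter=120.0), crit)
    # one-sided bounds are strict
    assert not passes_filter(
        passing_record(major_axis_length=100.0, minor_axis_length=62.0), crit
    )
    assert not passes_filter(passing_record(circularity=0.26), crit)
    assert not passes_filter(passing_record(eccentricity=0.85), crit)
    assert not passes_filter(passing_record(fully_in_frame=False), crit)
    assert passes_filter(
        passing_record(fully_in_frame=False),
        FilterCriteria(require_fully_in_frame=False),
    )


def test_filter_matches_oracle_on_randomized_records(rng):
    crit = FilterCriteria()
    records = [random_record(rng, as_dict=bool(i % 2)) for i in range(1000)]
    for rec in records:
        assert passes_filter(rec, crit) == oracle_filter(rec), rec
    kept = filter_detections(records, crit)
    assert kept == [r for r in records if oracle_filter(r)]


def test_missing_field_raises():
    with pytest.raises(ValueError, match="missing field 'area'"):
        passes_filter({"major_axis_length": 10.0}, FilterCriteria())

    class Bare:
        major_axis_length = 50.0
        minor_axis_length = 40.0

    with pytest.raises(ValueError, match="missing field"):
        passes_filter(Bare(), FilterCriteria())


def test_criteria_validation():
    with pytest.raises(ValueError, match="ordered"):
        FilterCriteria(area_range=(100.0, 50.0))
    with pytest.raises(ValueError, match="positive"):
        TrackCriteria(max_flow_gap=0.0)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def test_track_gates_direction_and_bounds():
    crit = TrackCriteria()
    prev = passing_record(centroid=(100.0, 100.0))
    assert track_gates_pass(prev, passing_record(centroid=(100.0, 140.0)), crit)
    # backward (upstream) motion is rejected
    assert not track_gates_pass(prev, passing_record(centroid=(100.0, 99.0)), crit)
    # strict bounds
    assert not track_gates_pass(prev, passing_record(centroid=(121.0, 140.0)), crit)
    assert not track_gates_pass(prev, passing_record(centroid=(100.0, 580.0)), crit)
    assert not track_gates_pass(prev, passing_record(centroid=(100.0, 140.0), area=2890.0), crit)
    assert track_gates_pass(prev, passing_record(centroid=(100.0, 140.0), area=2889.0), crit)


def test_link_matches_oracle_on_random_clouds(rng):
    crit = TrackCriteria()
    for trial in range(200):
        n = int(rng.integers(1, 14))
        dets = []
        for i in range(n):
            dets.append(
                passing_record(
                    frame_index=int(rng.integers(0, 5)),
                    centroid=(float(rng.uniform(0, 60)), float(rng.uniform(0, 250))),
                    area=float(rng.uniform(1500, 3500)),
                    major_axis_length=float(rng.uniform(40, 70)),
                    minor_axis_length=float(rng.uniform(35, 45)),
                )
            )
        got = link_tracks(dets, crit)
        want = oracle_link(dets)
        assert [t.detections for t in got] == want, f"trial {trial}"
        # every detection lands in exactly one track
        assert sorted(map(id, (d for t in got for d in t.detections))) == sorted(map(id, dets))


def test_each_track_strictly_increasing_frames(default_scene):
    video = default_scene["video"]
    _, _, tracks = extract_projection_sets(video)
    assert tracks
    for t in tracks:
        frames = [d.frame_index for d in t.detections]
        assert frames == sorted(set(frames))


def match_truth(det, truth, radius=40.0):
    """Ground-truth cell_id nearest to a detection in its frame, or None."""
    best, best_d2 = None, radius**2
    for r in truth:
        if r.frame_index != det.frame_index:
            continue
        d2 = (r.centroid[0] - det.centroid[0]) ** 2 + (r.centroid[1] - det.centroid[1]) ** 2
        if d2 <= best_d2:
            best, best_d2 = r.cell_id, d2
    return best


def test_detection_precision_and_recall(default_scene):
    video, truth = default_scene["video"], default_scene["truth"]
    h, w = video.shape[1:]
    background = estimate_background(video)
    margin = 45.0  # cells closer to an edge are legitimately gated out
    n_truth = n_found = n_kept = n_matched = 0
    for i, frame in enumerate(video):
        dets = detect_cells(HologramFrame(intensity=frame, frame_index=i), background)
        kept = filter_detections(dets, FilterCriteria())
        interior = [
            r for r in truth
            if r.frame_index == i
            and margin <= r.centroid[0] <= h - margin
            and margin <= r.centroid[1] <= w - margin
        ]
        n_truth += len(interior)
        for r in interior:
            if any(
                np.hypot(d.centroid[0] - r.centroid[0], d.centroid[1] - r.centroid[1]) <= 25
                for d in kept
            ):
                n_found += 1
        n_kept += len(kept)
        n_matched += sum(match_truth(d, truth) is not None for d in kept)
    assert n_truth > 10
    assert n_found / n_truth >= 0.9  # recall
    assert n_matched / n_kept >= 0.9  # precision


def test_track_purity_on_default_scene(default_scene):
    video, truth = default_scene["video"], default_scene["truth"]
    _, _, tracks = extract_projection_sets(video)
    agree = total = 0
    for t in tracks:
        ids = [match_truth(d, truth) for d in t.detections]
        ids = [i for i in ids if i is not None]
        if not ids:
            continue
        majority = max(set(ids), key=ids.count)
        agree += ids.count(majority)
        total += len(ids)
    assert total > 0
    assert agree / total >= 0.9


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def test_crop_and_pad_geometry():
    video = np.zeros((2, 60, 80))
    video[1, 10:20, 30:44] = 5.0
    det = passing_record(frame_index=1, bbox=(10, 30, 20, 44))
    track = CellTrack(cell_id=0, detections=[det])
    ps = crop_and_pad(track, video, pad_size=21)
    assert ps.crops.shape == (1, 21, 21)
    # content centered, odd remainder padded bottom/right: h=10 -> top 5,
    # w=14 -> left 3
    assert np.all(ps.crops[0, 5:15, 3:17] == 5.0)
    assert ps.crops[0].sum() == pytest.approx(5.0 * 10 * 14)
    assert ps.frame_indices == [1]


def test_crop_and_pad_limits_projections():
    video = np.ones((12, 64, 64))
    dets = [
        passing_record(frame_index=i, bbox=(20, 20, 40, 40)) for i in range(12)
    ]
    track = CellTrack(cell_id=3, detections=dets)
    ps = crop_and_pad(track, video, pad_size=134, max_projections=10)
    assert ps.crops.shape[0] == 10  # hard cap of 10 projections per cell
    assert ps.frame_indices == list(range(10))
    assert ps.pad_size == 134


def test_crop_and_pad_rejects_oversized_bbox():
    video = np.ones((1, 64, 64))
    det = passing_record(frame_index=0, bbox=(0, 0, 50, 50))
    with pytest.raises(ValueError, match="exceeds pad_size"):
        crop_and_pad(CellTrack(cell_id=0, detections=[det]), video, pad_size=40)


def test_detect_cells_edge_cases():
    bg = estimate_background(np.ones((4, 32, 32)))
    # identical frame: nothing to detect
    assert detect_cells(np.ones((32, 32)), bg) == []
    with pytest.raises(ValueError, match="shapes differ"):
        detect_cells(np.ones((16, 16)), bg)
    with pytest.raises(ValueError, match="fringe_period"):
        detect_cells(np.ones((32, 32)), bg, fringe_period=0.5)
    with pytest.raises(ValueError, match="empty video"):
        estimate_background(np.empty((0, 8, 8)))


def test_extract_projection_sets_on_scene(default_scene):
    video = default_scene["video"]
    sets, background, tracks = extract_projection_sets(video, min_projections=2)
    assert background.mean_frame.shape == video.shape[1:]
    assert sets
    for ps in sets:
        assert ps.pad_size == 134
        assert 2 <= ps.crops.shape[0] <= 10
        assert ps.frame_indices == sorted(ps.frame_indices)
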