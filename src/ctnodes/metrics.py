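"""Lesion-wise detection and segmentation metrics.

The evaluation unit is a connected lesion component, not a voxel.  Reference
nodes are sized by their short-axis diameter (SAD) — clinically, the shorter
in-plane diameter measured on one axial slice — and stratified into *ignored*
(< 3 mm), *small* (3–8 mm) and *large* (>= 8 mm) nodes.  A reference node
counts as detected (TP) when at least one predicted voxel overlaps it;
predicted components overlapping no reference node are false positives,
except components that touch only ignored nodes, which are excluded from the
FP count just as their nodes are excluded from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LesionLabelMap

__all__ = [
    "SizeThresholds",
    "NodeRecord",
    "DetectionCounts",
    "MatchResult",
    "label_components",
    "measure_sad",
    "classify_size",
    "extract_nodes",
    "match_detections",
    "detection_metrics",
    "dsc",
    "hd95",
    "evaluate_volume",
    "VolumeEvaluation",
]

SIZE_CLASSES = ("ignored", "small", "large")


@dataclass(frozen=True)
class SizeThresholds:
    """SAD cut-points in mm; closed on the left (3.0 -> small, 8.0 -> large)."""

    small: float = 3.0
    large: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.small < self.large:
            raise ValueError(f"need 0 < small < large, got {self.small}, {self.large}")


@dataclass(frozen=True)
class NodeRecord:
    node_id: int
    sad_mm: float
    size_class: str
    voxels: int
    centroid_mm: tuple[float, float, float]


def label_components(mask: LesionLabelMap | np.ndarray,
                     connectivity: int = 3) -> LesionLabelMap:
    """Relabel 26-connected (default) components 1..N.

    Label order is deterministic: ascending minimum voxel index in C order
    (lexicographic (z, y, x) of each component's first voxel).
    """
    if isinstance(mask, LesionLabelMap):
        data, spacing = mask.data, mask.spacing
    else:
        data, spacing = np.asarray(mask), (1.0, 1.0, 1.0)
    structure = ndimage.generate_binary_structure(3, connectivity)
    labelled, n = ndimage.label(data > 0, structure=structure)
    if n == 0:
        return LesionLabelMap(labelled, spacing)
    flat = labelled.ravel()
    labels, first = np.unique(flat, return_index=True)
    order = labels[np.argsort(first)]
    order = order[order > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return LesionLabelMap(remap[labelled], spacing)


def measure_sad(component: np.ndarray, spacing) -> float:
    """Short-axis diameter of one lesion component, in mm.

    SAD = twice the maximum over axial slices of the in-plane Euclidean
    distance transform of that slice's cross-section — the diameter of the
    largest inscribed circle on any axial slice.  A single-voxel component
    measures the minimum in-plane spacing by convention.
    """
    component = np.asarray(component).astype(bool)
    if component.ndim != 3:
        raise ValueError("component must be a 3D mask")
    n_vox = int(component.sum())
    if n_vox == 0:
        raise ValueError("cannot measure SAD of an empty component")
    sy, sx = float(spacing[1]), float(spacing[2])
    if n_vox == 1:
        return min(sy, sx)
    best = 0.0
    for z in np.flatnonzero(component.any(axis=(1, 2))):
        padded = np.pad(component[z], 1)  # ensure a background rim for the EDT
        edt = ndimage.distance_transform_edt(padded, sampling=(sy, sx))
        best = max(best, float(edt.max()))
    return 2.0 * best


def classify_size(sad_mm: float, thresholds: SizeThresholds = SizeThresholds()) -> str:
    """Size stratum for a SAD: ignored (< 3 mm), small (3–8 mm), large (>= 8 mm)."""
    if sad_mm < 0:
        raise ValueError(f"SAD must be non-negative, got {sad_mm}")
    if sad_mm < thresholds.small:
        return "ignored"
    if sad_mm < thresholds.large:
        return "small"
    return "large"


def extract_nodes(label_map: LesionLabelMap,
                  thresholds: SizeThresholds = SizeThresholds()) -> list[NodeRecord]:
    """One record (SAD, size class, voxel count, centroid) per labelled node."""
    data = label_map.data
    spacing = label_map.spacing
    records = []
    for obj_slice, node_id in zip(
            ndimage.find_objects(data), range(1, int(data.max()) + 1)):
        if obj_slice is None:
            continue
        component = data[obj_slice] == node_id
        sad = measure_sad(component, spacing)
        com = ndimage.center_of_mass(component)
        centroid = tuple(float((s.start + c) * sp)
                         for s, c, sp in zip(obj_slice, com, spacing))
        records.append(NodeRecord(node_id, sad, classify_size(sad, thresholds),
                                  int(component.sum()), centroid))
    return records


@dataclass
class DetectionCounts:
    """TP/FP/FN with derived precision, sensitivity and F1 (percent).

    A ratio with zero denominator is ``None`` (undefined), never silently 0.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        d = 2 * self.tp + self.fp + self.fn
        return 100.0 * 2 * self.tp / d if d else None

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "sensitivity": self.sensitivity,
                "f1": self.f1}


def detection_metrics(tp: int, fp: int, fn: int) -> DetectionCounts:
    """Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN),
    each as a percentage."""
    return DetectionCounts(tp, fp, fn)


@dataclass
class MatchResult:
    """Outcome of lesion-wise matching between reference and prediction."""

    nodes: pd.DataFrame          # node_id, sad_mm, size_class, voxels, hit
    fp_labels: list[int]         # predicted components matching nothing
    excluded_fp_labels: list[int]  # components touching only ignored nodes
    counts: dict[str, DetectionCounts]  # keys: all, small, large

    @property
    def eligible(self) -> int:
        return int((self.nodes.size_class != "ignored").sum())


def match_detections(ref: LesionLabelMap, pred: LesionLabelMap,
                     thresholds: SizeThresholds = SizeThresholds(),
                     min_iou: float = 0.0) -> MatchResult:
    """Match predicted components to reference nodes by voxel overlap.

    The default hit criterion is any-voxel overlap (``min_iou = 0``); a
    stricter intersection-over-union threshold can be requested.  FP counts
    appear in the "all" stratum only: a false positive has no reference SAD,
    hence no size class.
    """
    if ref.shape != pred.shape:
        raise ValueError(f"shape mismatch: ref {ref.shape} vs pred {pred.shape}")
    ref_lab = label_components(ref)
    pred_lab = label_components(pred)
    nodes = extract_nodes(ref_lab, thresholds)
    n_ref = len(nodes)
    n_pred = int(pred_lab.data.max())

    # overlap matrix via joint histogram of (ref label, pred label)
    joint = np.zeros((n_ref + 1, n_pred + 1), dtype=np.int64)
    np.add.at(joint, (ref_lab.data.ravel(), pred_lab.data.ravel()), 1)
    overlap = joint[1:, 1:]

    if min_iou > 0:
        ref_sizes = joint[1:, :].sum(axis=1, keepdims=True)
        pred_sizes = joint[:, 1:].sum(axis=0, keepdims=True)
        union = ref_sizes + pred_sizes - overlap
        matched = np.divide(overlap, union, out=np.zeros_like(overlap, float),
                            where=union > 0) >= min_iou
    else:
        matched = overlap > 0

    classes = np.array([n.size_class for n in nodes])
    hits = matched.any(axis=1) if n_pred else np.zeros(n_ref, bool)

    touches_any = (overlap > 0).any(axis=0) if n_ref else np.zeros(n_pred, bool)
    touches_eligible = ((overlap > 0) & (classes != "ignored")[:, None]).any(axis=0) \
        if n_ref else np.zeros(n_pred, bool)
    fp_labels = [int(j + 1) for j in np.flatnonzero(~touches_any)]
    excluded = [int(j + 1) for j in np.flatnonzero(touches_any & ~touches_eligible)]

    table = pd.DataFrame({
        "node_id": [n.node_id for n in nodes],
        "sad_mm": [n.sad_mm for n in nodes],
        "size_class": classes if n_ref else np.array([], dtype=str),
        "voxels": [n.voxels for n in nodes],
        "hit": hits,
    })
    counts = {}
    for stratum in ("all", "small", "large"):
        sel = (classes != "ignored") if stratum == "all" else (classes == stratum)
        tp = int(hits[sel].sum()) if n_ref else 0
        fn = int((~hits[sel]).sum()) if n_ref else 0
        fp = len(fp_labels) if stratum == "all" else 0
        counts[stratum] = DetectionCounts(tp, fp, fn)
    return MatchResult(table, fp_labels, excluded, counts)


def dsc(ref: np.ndarray, pred: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``; 1.0 if both empty."""
    ref = np.asarray(ref).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if ref.shape != pred.shape:
        raise ValueError("shape mismatch")
    denom = int(ref.sum()) + int(pred.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ref & pred).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    return mask & ~eroded


def hd95(ref: np.ndarray, pred: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric Hausdorff distance between mask surfaces, mm.

    The 95th percentile of each directed set of boundary-voxel distances is
    taken, then the maximum of the two directions.  Raises on an empty mask:
    the distance is undefined there and the caller excludes it.
    """
    ref = np.asarray(ref).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if ref.shape != pred.shape:
        raise ValueError("shape mismatch")
    if not ref.any() or not pred.any():
        raise ValueError("hd95 undefined for an empty mask")
    b_ref, b_pred = _boundary(ref), _boundary(pred)
    d_to_pred = ndimage.distance_transform_edt(~b_pred, sampling=spacing)
    d_to_ref = ndimage.distance_transform_edt(~b_ref, sampling=spacing)
    forward = np.percentile(d_to_pred[b_ref], 95)
    backward = np.percentile(d_to_ref[b_pred], 95)
    return float(max(forward, backward))


@dataclass
class VolumeEvaluation:
    """Per-volume and per-node scores for one (volume, dose, model) cell."""

    match: MatchResult
    volume_dsc: float
    volume_hd95: float          # NaN when undefined (either union empty)
    per_node: pd.DataFrame      # node_id, sad_mm, size_class, hit, dsc, hd95
    n_undefined_hd: int


def evaluate_volume(ref: LesionLabelMap, pred: LesionLabelMap,
                    thresholds: SizeThresholds = SizeThresholds(),
                    min_iou: float = 0.0) -> VolumeEvaluation:
    """Full lesion-wise evaluation of one prediction against one reference.

    Per-volume DSC/HD95 compare the union of all eligible (>= 3 mm) reference
    nodes against the union of predicted components, excluding components
    that touch only ignored nodes (mirroring their exclusion from FP).
    Per-node DSC/HD95 compare each eligible node with the union of predicted
    components overlapping it; an unmatched node scores DSC 0 with HD95
    undefined (NaN, excluded from aggregation).
    """
    match = match_detections(ref, pred, thresholds, min_iou)
    ref_lab = label_components(ref)
    pred_lab = label_components(pred)
    spacing = ref.spacing

    eligible_ids = match.nodes.loc[match.nodes.size_class != "ignored", "node_id"]
    ref_union = np.isin(ref_lab.data, eligible_ids.to_numpy())
    keep_pred = np.ones(int(pred_lab.data.max()) + 1, dtype=bool)
    for lab in match.excluded_fp_labels:
        keep_pred[lab] = False
    keep_pred[0] = False
    pred_union = keep_pred[pred_lab.data]

    vol_dsc = dsc(ref_union, pred_union)
    n_undef = 0
    try:
        both = ref_union | pred_union
        if both.any():
            bbox = ndimage.find_objects(both.astype(np.int8))[0]
            crop = tuple(slice(max(0, s.start - 1), s.stop + 1) for s in bbox)
            vol_hd = hd95(ref_union[crop], pred_union[crop], spacing)
        else:
            vol_hd = hd95(ref_union, pred_union, spacing)  # raises: both empty
    except ValueError:
        vol_hd, n_undef = float("nan"), 1

    objects = ndimage.find_objects(ref_lab.data)
    pred_objects = ndimage.find_objects(pred_lab.data)
    rows = []
    for rec in match.nodes.itertuples():
        if rec.size_class == "ignored":
            continue
        node_box = objects[rec.node_id - 1]
        overlapping = np.unique(pred_lab.data[node_box][
            ref_lab.data[node_box] == rec.node_id])
        overlapping = overlapping[overlapping > 0]
        # work on the joint bounding box; distances beyond it cannot matter
        boxes = [node_box] + [pred_objects[j - 1] for j in overlapping]
        lo = [min(b[ax].start for b in boxes) for ax in range(3)]
        hi = [max(b[ax].stop for b in boxes) for ax in range(3)]
        crop = tuple(slice(max(0, lo[ax] - 1), hi[ax] + 1) for ax in range(3))
        node_mask = ref_lab.data[crop] == rec.node_id
        pred_mask = np.isin(pred_lab.data[crop], overlapping)
        node_dsc = dsc(node_mask, pred_mask)
        try:
            node_hd = hd95(node_mask, pred_mask, spacing)
        except ValueError:
            node_hd = float("nan")
            n_undef += 1
        rows.append({"node_id": rec.node_id, "sad_mm": rec.sad_mm,
                     "size_class": rec.size_class, "hit": bool(rec.hit),
                     "dsc": node_dsc, "hd95": node_hd})
    per_node = pd.DataFrame(rows, columns=["node_id", "sad_mm", "size_class",
                                           "hit", "dsc", "hd95"])
    return VolumeEvaluation(match, vol_dsc, vol_hd, per_node, n_undef)
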