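"""Probability maps -> binary masks -> lesion boxes -> detection counts.

Coordinate convention, used everywhere: 0-based, row-major (y = row),
half-open on the max side, so a box covers pixels with
x_min <= x < x_max and y_min <= y < y_max.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclasses.dataclass
class DetectionBox:
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    area: int
    matched: bool = False

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box must have positive extent (half-open max)")
        box_area = (self.x_max - self.x_min) * (self.y_max - self.y_min)
        if not 1 <= self.area <= box_area:
            raise ValueError(f"area {self.area} outside [1, {box_area}]")

    def expand(self, margin: float) -> tuple:
        return (self.x_min - margin, self.y_min - margin,
                self.x_max + margin, self.y_max + margin)

    def to_csv_row(self, image_id="") -> str:
        return (f"{image_id},{self.x_min},{self.y_min},{self.x_max},"
                f"{self.y_max},{self.area}")

    CSV_HEADER = "image_id,x_min,y_min,x_max,y_max,area"


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; values equal to the threshold count as
    foreground."""
    prob_map = np.asarray(prob_map)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return (prob_map >= threshold).astype(np.uint8)


def label_components(mask: np.ndarray, connectivity: int = 8):
    """Connected-component labelling; returns (labels, count)."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask) > 0
    return ndimage.label(mask, structure=_STRUCTURES[connectivity])


def mask_to_boxes(mask: np.ndarray, connectivity: int = 8,
                  min_area: int = 0) -> list[DetectionBox]:
    """Tight bounding box per connected component with area >= min_area."""
    labels, n = label_components(mask, connectivity)
    boxes = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ysl, xsl = sl
        area = int((labels[sl] == lab).sum())
        if area < min_area:
            continue
        boxes.append(DetectionBox(x_min=int(xsl.start), y_min=int(ysl.start),
                                  x_max=int(xsl.stop), y_max=int(ysl.stop),
                                  area=area))
    return boxes


def _intersects(a: tuple, b: tuple) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def merge_boxes(boxes: list[DetectionBox], gap: float = 0) -> list[DetectionBox]:
    """Union-merge boxes whose expansions by gap/2 intersect, transitively.

    gap = 0 therefore merges only genuinely overlapping boxes (half-open
    coordinates: boxes that merely touch share no pixel and stay apart).
    Merged area is the sum of member areas.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    n = len(boxes)
    if n <= 1:
        return list(boxes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    expanded = [b.expand(gap / 2.0) for b in boxes]
    for i in range(n):
        for j in range(i + 1, n):
            if _intersects(expanded[i], expanded[j]):
                parent[find(i)] = find(j)

    groups: dict[int, list[DetectionBox]] = {}
    for i, b in enumerate(boxes):
        groups.setdefault(find(i), []).append(b)

    merged = []
    for members in groups.values():
        x_min = min(b.x_min for b in members)
        y_min = min(b.y_min for b in members)
        x_max = max(b.x_max for b in members)
        y_max = max(b.y_max for b in members)
        # member areas sum; capped by the union box for overlapping members
        area = min(sum(b.area for b in members),
                   (x_max - x_min) * (y_max - y_min))
        merged.append(DetectionBox(x_min=x_min, y_min=y_min, x_max=x_max,
                                   y_max=y_max, area=area,
                                   matched=any(b.matched for b in members)))
    merged.sort(key=lambda b: (b.y_min, b.x_min))
    return merged


def match_to_truth(pred_boxes: list[DetectionBox], truth_mask: np.ndarray,
                   min_overlap: float | None = None,
                   connectivity: int = 8) -> tuple[int, int, int]:
    """Greedy one-to-one matching of predicted boxes to truth components.

    A truth component counts as detected when a predicted box covers at
    least `min_overlap` of its pixels (any positive overlap if None).
    Pairs are matched largest-overlap-first; each box and each component
    matches at most once.  Returns (tp, fp, fn); sets box.matched flags.
    """
    if min_overlap is not None and not 0.0 < min_overlap <= 1.0:
        raise ValueError(f"min_overlap must lie in (0,1], got {min_overlap}")
    labels, n_truth = label_components(truth_mask, connectivity)
    for b in pred_boxes:
        b.matched = False
    if n_truth == 0:
        return 0, len(pred_boxes), 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_truth + 1))
    candidates = []
    for bi, box in enumerate(pred_boxes):
        window = labels[box.y_min:box.y_max, box.x_min:box.x_max]
        inside = np.bincount(window.ravel(), minlength=n_truth + 1)[1:]
        for ti in np.nonzero(inside)[0]:
            frac = inside[ti] / sizes[ti]
            if min_overlap is None or frac >= min_overlap:
                candidates.append((frac, bi, ti))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_truth: set[int] = set()
    for frac, bi, ti in candidates:
        if pred_boxes[bi].matched or ti in matched_truth:
            continue
        pred_boxes[bi].matched = True
        matched_truth.add(ti)
    tp = len(matched_truth)
    fp = sum(1 for b in pred_boxes if not b.matched)
    fn = n_truth - tp
    return tp, fp, fn


def boxes_to_csv(boxes_by_image: dict, path) -> None:
    lines = [DetectionBox.CSV_HEADER]
    for image_id, boxes in boxes_by_image.items():
        for b in boxes:
            lines.append(b.to_csv_row(image_id))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def render_overlay(image: np.ndarray, truth_mask: np.ndarray | None,
                   pred_boxes: list[DetectionBox]) -> np.ndarray:
    """RGB overlay: green truth contours, red prediction boxes (uint8)."""
    img = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    rgb = np.stack([img, img, img], axis=-1)
    if truth_mask is not None:
        m = np.asarray(truth_mask) > 0
        edge = m & ~ndimage.binary_erosion(m)
        rgb[edge] = (0.0, 1.0, 0.0)
    for b in pred_boxes:
        y0, y1 = b.y_min, b.y_max - 1
        x0, x1 = b.x_min, b.x_max - 1
        rgb[y0, x0:x1 + 1] = (1.0, 0.0, 0.0)
        rgb[y1, x0:x1 + 1] = (1.0, 0.0, 0.0)
        rgb[y0:y1 + 1, x0] = (1.0, 0.0, 0.0)
        rgb[y0:y1 + 1, x1] = (1.0, 0.0, 0.0)
    return (rgb * 255).astype(np.uint8)
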