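"""Synthetic body-CT phantoms with ground-truth lymph-node masks.

The phantoms emulate the structure that matters for dose-robustness
experiments on body CT: a soft-tissue background (~40 HU) with smooth
low-frequency variation and a few large organ-like blobs, plus many small
quasi-ellipsoidal soft-tissue lesions whose short-axis diameters (SAD) span
roughly 1–30 mm, at ~1 mm spacing.  Mild spatially correlated acquisition
noise mimics the full-dose noise floor a real scanner leaves in the image.
No bone, air or contrast-phase modelling is attempted.

``perturb_mask`` turns a ground-truth mask into a controlled "prediction":
nodes are dropped with per-size-class probabilities, surviving nodes are
eroded or dilated by a per-node signed radius, and spurious blobs are added
in the background.  Every action is logged so that downstream detection
counts can be verified against the log exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import SizeThresholds, classify_size, measure_sad
from .volume import CtVolume, LesionLabelMap

__all__ = ["PhantomSpec", "PerturbationSpec", "generate_phantom", "perturb_mask",
           "PhantomPlacementError"]


class PhantomPlacementError(RuntimeError):
    """Raised when the requested node count cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one phantom reproducibly.

    SADs are drawn from a log-normal distribution (``exp(N(mu, sigma))`` mm)
    truncated to ``sad_range_mm``; node contrast is uniform in
    ``node_contrast_hu`` above the nominal background.  Default geometry is
    64x128x128 voxels at 1 mm isotropic spacing.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = 40.0
    background_variation_hu: float = 10.0
    organ_count: int = 3
    organ_hu_range: tuple[float, float] = (-30.0, 20.0)
    node_count: int = 12
    sad_lognormal_mu: float = 1.70   # median ~5.5 mm
    sad_lognormal_sigma: float = 0.50
    sad_range_mm: tuple[float, float] = (1.0, 30.0)
    node_contrast_hu: tuple[float, float] = (30.0, 60.0)
    axis_ratio_range: tuple[float, float] = (1.0, 1.6)
    noise_sigma_hu: float = 10.0
    noise_correlation_voxels: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("all dimensions must be >= 16 voxels")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        lo, hi = self.sad_range_mm
        if not 0 < lo < hi:
            raise ValueError("SAD truncation bounds must satisfy 0 < lo < hi")
        if self.node_count < 0 or self.organ_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled corruption of a reference mask into a 'prediction'."""

    miss_prob: dict = field(default_factory=lambda: {
        "ignored": 0.5, "small": 0.2, "large": 0.05})
    jitter_voxels: int = 1            # per-node signed radius in [-j, j]
    false_blob_count: int = 3
    false_blob_radius_voxels: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for k, p in self.miss_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"miss probability for {k!r} must be in [0,1]")
        if self.false_blob_radius_voxels[0] < 0.5:
            raise ValueError("false blobs must be at least 1 voxel")
        if self.jitter_voxels < 0 or self.false_blob_count < 0:
            raise ValueError("jitter and blob count must be non-negative")


def _truncated_lognormal(rng, mu, sigma, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled:filled + len(draw)] = draw
        filled += len(draw)
    return out


def _smooth_field(rng, shape, sigma_voxels, amplitude):
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_voxels)
    peak = np.abs(field).max()
    return field / peak * amplitude if peak > 0 else field


def _ellipsoid_mask(shape, spacing, center_vox, semi_axes_mm, phi):
    """Boolean mask of an ellipsoid with in-plane rotation phi (radians)."""
    cz, cy, cx = center_vox
    c_mm, b_mm, a_mm = semi_axes_mm  # z, in-plane minor, in-plane major
    rz = int(np.ceil(c_mm / spacing[0])) + 1
    ry = rx = int(np.ceil(max(a_mm, b_mm) / min(spacing[1], spacing[2]))) + 1
    z0, z1 = max(0, cz - rz), min(shape[0], cz + rz + 1)
    y0, y1 = max(0, cy - ry), min(shape[1], cy + ry + 1)
    x0, x1 = max(0, cx - rx), min(shape[2], cx + rx + 1)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    dz = (zz - cz) * spacing[0]
    dy = (yy - cy) * spacing[1]
    dx = (xx - cx) * spacing[2]
    u = dx * np.cos(phi) + dy * np.sin(phi)     # along in-plane major axis
    v = -dx * np.sin(phi) + dy * np.cos(phi)    # along in-plane minor axis
    inside = (u / a_mm) ** 2 + (v / b_mm) ** 2 + (dz / c_mm) ** 2 <= 1.0
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), inside


def generate_phantom(spec: PhantomSpec,
                     max_retries: int = 100) -> tuple[CtVolume, LesionLabelMap, pd.DataFrame]:
    """Generate a phantom volume, its node label map, and the intent table.

    Nodes are random in-plane-orientation ellipsoids whose middle axial
    cross-section has minor diameter equal to the sampled SAD (the axial SAD
    convention).  Nodes never touch each other (1-voxel separation enforced),
    so each keeps its own 26-connected component.  Placement is by rejection
    sampling; exceeding ``max_retries`` for a node raises
    :class:`PhantomPlacementError` naming the count achieved.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    volume = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    volume += _smooth_field(rng, spec.shape, sigma_voxels=12.0,
                            amplitude=spec.background_variation_hu)

    # large smooth organ-like blobs, clipped to the configured HU range
    for _ in range(spec.organ_count):
        hu = rng.uniform(*spec.organ_hu_range)
        center = (rng.integers(nz // 4, 3 * nz // 4),
                  rng.integers(ny // 4, 3 * ny // 4),
                  rng.integers(nx // 4, 3 * nx // 4))
        axes = (rng.uniform(8, 16) * spec.spacing[0],
                rng.uniform(12, 25), rng.uniform(12, 25))
        region, inside = _ellipsoid_mask(spec.shape, spec.spacing, center,
                                         (axes[0], axes[1], axes[2]), 0.0)
        blob = np.zeros(spec.shape)
        blob[region][inside] = 1.0
        blob = ndimage.gaussian_filter(blob, 2.0)
        volume += (hu - spec.background_hu) * blob

    labels = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)  # nodes dilated by 1 voxel
    sads = _truncated_lognormal(rng, spec.sad_lognormal_mu,
                                spec.sad_lognormal_sigma,
                                *spec.sad_range_mm, spec.node_count)
    rows = []
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    placement_radius = 0.40 * min(ny, nx)  # keep nodes inside the recon circle
    for k in range(spec.node_count):
        sad = float(sads[k])
        b = sad / 2.0
        a = b * rng.uniform(*spec.axis_ratio_range)
        # clip the z semi-axis so the node fits the stack; SAD is in-plane
        c = min(b * rng.uniform(*spec.axis_ratio_range),
                (nz - 4) * spec.spacing[0] / 2.0)
        phi = rng.uniform(0.0, np.pi)
        contrast = rng.uniform(*spec.node_contrast_hu)
        placed = False
        for _ in range(max_retries):
            rz = max(1, int(np.ceil(c / spec.spacing[0])))
            if nz - rz <= rz + 1:
                break
            cz = int(rng.integers(rz + 1, nz - rz))
            r = placement_radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            cy = int(round(cy0 + r * np.sin(ang)))
            cx = int(round(cx0 + r * np.cos(ang)))
            region, inside = _ellipsoid_mask(spec.shape, spec.spacing,
                                             (cz, cy, cx), (c, b, a), phi)
            if not inside.any() or occupied[region][inside].any():
                continue
            labels[region][inside] = k + 1
            grown = ndimage.binary_dilation(
                inside, ndimage.generate_binary_structure(3, 3))
            occupied[region] |= grown
            volume[region][inside] = spec.background_hu + contrast
            rows.append({"node_id": k + 1, "sad_mm": sad, "contrast_hu": contrast,
                         "axis_mm_z": c, "axis_mm_minor": b, "axis_mm_major": a,
                         "center_z": cz, "center_y": cy, "center_x": cx})
            placed = True
            break
        if not placed:
            raise PhantomPlacementError(
                f"placed {k} of {spec.node_count} nodes without overlap "
                f"(retry cap {max_retries} reached)")

    if spec.noise_sigma_hu > 0:
        noise = rng.standard_normal(spec.shape)
        if spec.noise_correlation_voxels > 0:
            noise = np.stack([ndimage.gaussian_filter(s, spec.noise_correlation_voxels)
                              for s in noise])
            noise /= noise.std()
        volume += spec.noise_sigma_hu * noise

    table = pd.DataFrame(rows, columns=["node_id", "sad_mm", "contrast_hu",
                                        "axis_mm_z", "axis_mm_minor",
                                        "axis_mm_major", "center_z", "center_y",
                                        "center_x"])
    return (CtVolume(volume.astype(np.float32), spec.spacing),
            LesionLabelMap(labels, spec.spacing), table)


def perturb_mask(ref: LesionLabelMap,
                 spec: PerturbationSpec,
                 thresholds: SizeThresholds = SizeThresholds(),
                 ) -> tuple[LesionLabelMap, pd.DataFrame]:
    """Corrupt a reference mask into a synthetic prediction, with a full log.

    Guarantees that make the log an exact oracle for lesion-wise matching:
    dropped nodes leave no predicted voxel on their territory, dilation never
    reaches into (or touches) another reference node, erosion falls back to
    the untouched node if it would erase it, and false blobs are disjoint
    from all reference nodes and from each other.  The log has one row per
    reference node (``kind='node'``: dropped flag, applied jitter) and one
    per added blob (``kind='blob'``).

    With an all-zero perturbation the output equals the input.
    """
    rng = np.random.default_rng(spec.seed)
    data = ref.data
    out = np.zeros_like(data)
    node_ids = [int(l) for l in np.unique(data) if l > 0]
    struct = ndimage.generate_binary_structure(3, 3)
    log_rows = []
    for node_id in node_ids:
        mask = data == node_id
        sad = measure_sad(mask, ref.spacing)
        size_class = classify_size(sad, thresholds)
        dropped = bool(rng.uniform() < spec.miss_prob.get(size_class, 0.0))
        jitter = int(rng.integers(-spec.jitter_voxels, spec.jitter_voxels + 1)) \
            if spec.jitter_voxels > 0 else 0
        applied = 0
        if not dropped:
            new = mask
            if jitter < 0:
                eroded = ndimage.binary_erosion(mask, struct, iterations=-jitter)
                if eroded.any():
                    new, applied = eroded, jitter
            elif jitter > 0:
                forbidden = ndimage.binary_dilation(
                    (data > 0) & ~mask, struct)
                new = ndimage.binary_dilation(mask, struct, iterations=jitter,
                                              mask=~forbidden) & ~forbidden
                new |= mask
                applied = jitter
            out[new] = node_id
        log_rows.append({"kind": "node", "node_id": node_id, "sad_mm": sad,
                         "size_class": size_class, "dropped": dropped,
                         "jitter_voxels": applied})

    # spurious blobs: strictly background, disjoint from nodes and each other
    forbidden = ndimage.binary_dilation(
        (data > 0) | (out > 0), struct, iterations=max(2, spec.jitter_voxels + 1))
    next_label = (max(node_ids) if node_ids else 0) + 1
    nz, ny, nx = data.shape
    for _ in range(spec.false_blob_count):
        for _ in range(100):
            radius = rng.uniform(*spec.false_blob_radius_voxels)
            r_int = int(np.ceil(radius))
            cz = int(rng.integers(r_int, max(r_int + 1, nz - r_int)))
            cy = int(rng.integers(r_int, max(r_int + 1, ny - r_int)))
            cx = int(rng.integers(r_int, max(r_int + 1, nx - r_int)))
            region, inside = _ellipsoid_mask(
                data.shape, (1.0, 1.0, 1.0), (cz, cy, cx),
                (radius, radius, radius), 0.0)
            if not inside.any() or forbidden[region][inside].any():
                continue
            out[region][inside] = next_label
            forbidden[region] |= ndimage.binary_dilation(inside, struct,
                                                         iterations=2)
            log_rows.append({"kind": "blob", "node_id": next_label,
                             "sad_mm": float("nan"), "size_class": "",
                             "dropped": False, "jitter_voxels": 0})
            next_label += 1
            break
        else:
            raise PhantomPlacementError(
                "could not place a false-positive blob in free background")
    log = pd.DataFrame(log_rows, columns=["kind", "node_id", "sad_mm",
                                          "size_class", "dropped",
                                          "jitter_voxels"])
    return LesionLabelMap(out, ref.spacing), log
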