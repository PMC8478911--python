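"""Synthetic photoquadrat scenes and simulated cover time-series.

Every downstream stage of the toolkit (frame rectification, color
balancing, point annotation, cover estimation, trend models, ordination)
is testable against known ground truth produced here, with no real imagery
required.

Scenes are composed of spatially coherent Voronoi patches of benthic
classes (real quadrats show contiguous organism patches, not per-pixel
noise), optionally framed by a near-white band emulating a PVC quadrat
frame at a small rotation, then degraded with an additive green/blue
color cast and an overexposure gain.  Class pixel counts over the frame
interior are exact to integer rounding, so ground-truth fractions can be
used as tight oracles.

Cover time-series are drawn from a beta distribution whose mean follows
an inverse-logit linear predictor in year (centered), with independent
Gaussian site effects on the logit scale — the generating model the
beta-GAM trend stage is meant to recover.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree

from .sites import STUDY_REEF_TYPES, STUDY_SITES, STUDY_YEARS

FRAME_INDEX = -1  # sentinel value in label maps for frame-band pixels

# mid-range colors (all channels < 236, below any sensible frame threshold)
_PALETTE: dict[str, tuple[int, int, int]] = {
    "MA": (46, 139, 87),
    "LTA": (107, 142, 35),
    "SC": (210, 105, 97),
    "OCT": (138, 102, 170),
    "SP": (165, 90, 50),
    "SAND": (205, 190, 145),
    "RUB": (160, 158, 150),
    "CS": (125, 115, 100),
}


def _color_for(code: str) -> tuple[int, int, int]:
    if code in _PALETTE:
        return _PALETTE[code]
    h = hashlib.md5(code.encode()).digest()
    return tuple(40 + b % 180 for b in h[:3])  # type: ignore[return-value]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered photoquadrat scene."""

    width_px: int = 360
    height_px: int = 360
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"SC": 0.15, "MA": 0.15, "CS": 0.45, "SAND": 0.25}
    )
    frame_present: bool = True
    frame_rotation_deg: float = 0.0
    frame_inner_margin_px: int | None = None  # default: 15% of min dimension
    frame_band_px: int = 12
    cast_green: int = 0
    cast_blue: int = 0
    overexposure_gain: float = 1.0
    n_patches: int = 60
    noise_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("scene must be at least 64x64 pixels")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1 (got {total})")
        if any(f < 0 or f > 1 for f in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(self.frame_rotation_deg) > 20:
            raise ValueError("frame rotation must lie in [-20, 20] degrees")
        if not (0 <= self.cast_green <= 255 and 0 <= self.cast_blue <= 255):
            raise ValueError("color-cast offsets must lie in [0, 255]")
        if self.overexposure_gain < 1:
            raise ValueError("overexposure gain must be >= 1")
        if self.frame_band_px < 2:
            raise ValueError("frame band must be at least 2 px thick")
        if self.frame_present:
            a = self._outer_half()
            if a - self.frame_band_px < 8:
                raise ValueError("frame interior too small")
            th = np.deg2rad(abs(self.frame_rotation_deg))
            if a * (np.cos(th) + np.sin(th)) > min(self.width_px, self.height_px) / 2:
                raise ValueError("rotated frame would extend beyond the image")

    def _margin(self) -> int:
        if self.frame_inner_margin_px is not None:
            return self.frame_inner_margin_px
        return int(round(0.15 * min(self.width_px, self.height_px)))

    def _outer_half(self) -> float:
        return min(self.width_px, self.height_px) / 2 - self._margin()


@dataclass
class GroundTruth:
    """Per-pixel truth for one rendered scene.

    ``label_map`` holds indices into ``labels`` (``FRAME_INDEX`` marks
    frame-band pixels).  ``inner_bbox`` is the frame-interior rectangle
    (top, left, bottom, right; half-open) in *rectified* coordinates, i.e.
    after undoing ``frame_rotation_deg``.  ``class_fractions_interior`` is
    computed over frame-interior pixels only and sums to 1.
    """

    label_map: np.ndarray
    labels: tuple[str, ...]
    frame_rotation_deg: float
    inner_bbox: tuple[int, int, int, int]
    class_fractions_interior: dict[str, float]

    def label_at(self, row: int, col: int) -> str | None:
        idx = int(self.label_map[row, col])
        return None if idx == FRAME_INDEX else self.labels[idx]

    def to_json(self, path) -> None:
        doc = {
            "labels": list(self.labels),
            "frame_rotation_deg": self.frame_rotation_deg,
            "inner_bbox": list(self.inner_bbox),
            "class_fractions_interior": self.class_fractions_interior,
            "label_map": self.label_map.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            label_map=np.asarray(doc["label_map"], dtype=np.int16),
            labels=tuple(doc["labels"]),
            frame_rotation_deg=float(doc["frame_rotation_deg"]),
            inner_bbox=tuple(doc["inner_bbox"]),
            class_fractions_interior=dict(doc["class_fractions_interior"]),
        )


def _rotated_chebyshev(h: int, w: int, theta_deg: float) -> np.ndarray:
    """Chebyshev radius of every pixel in the frame's (rotated) coordinates.

    The frame band occupies {b <= m <= a} of this radius m; rotating the
    image by ``-theta_deg`` (skimage convention) axis-aligns the band.
    """
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx - cx
    y = yy - cy
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    qx = c * x - s * y
    qy = s * x + c * y
    return np.maximum(np.abs(qx), np.abs(qy))


def render_quadrat(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic photoquadrat and its ground truth.

    Returns an ``(H, W, 3)`` uint8 image and a :class:`GroundTruth` whose
    interior class fractions match ``spec.class_fractions`` to integer
    rounding.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    labels = tuple(spec.class_fractions.keys())

    # Voronoi patch structure
    n_seeds = max(len(labels), spec.n_patches)
    seeds = rng.uniform([0, 0], [h, w], size=(n_seeds, 2))
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist, cell = cKDTree(seeds).query(pix)

    # frame geometry / interior mask
    if spec.frame_present:
        a = spec._outer_half()
        b = a - spec.frame_band_px
        m = _rotated_chebyshev(h, w, spec.frame_rotation_deg)
        band = ((m >= b) & (m <= a)).ravel()
        interior = (m < b).ravel()
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        top = int(np.ceil(cy - b))
        left = int(np.ceil(cx - b))
        bottom = int(np.floor(cy + b)) + 1
        right = int(np.floor(cx + b)) + 1
        inner_bbox = (top, left, bottom, right)
    else:
        band = np.zeros(h * w, dtype=bool)
        interior = np.ones(h * w, dtype=bool)
        inner_bbox = (0, 0, h, w)

    # exact-count class allocation over the interior: order interior pixels
    # by (shuffled cell, distance to seed) and cut at exact per-class counts,
    # so at most one cell per class boundary is split (into a coherent disc).
    int_idx = np.flatnonzero(interior)
    n_int = int_idx.size
    cell_rank = rng.permutation(n_seeds)
    order = np.lexsort((dist[int_idx], cell_rank[cell[int_idx]]))
    fr = np.array([spec.class_fractions[c] for c in labels])
    counts = np.floor(fr * n_int).astype(int)
    rem = n_int - counts.sum()
    extra = np.argsort(-(fr * n_int - counts))[:rem]
    counts[extra] += 1

    label_map = np.full(h * w, FRAME_INDEX, dtype=np.int16)
    pos = 0
    for li, cnt in enumerate(counts):
        label_map[int_idx[order[pos : pos + cnt]]] = li
        pos += cnt

    # exterior pixels inherit the (majority) label of their cell; empty cells
    # copy the nearest allocated seed
    cell_label = np.full(n_seeds, -2, dtype=np.int16)
    for ci in range(n_seeds):
        members = label_map[int_idx[cell[int_idx] == ci]]
        if members.size:
            vals, cts = np.unique(members, return_counts=True)
            cell_label[ci] = vals[np.argmax(cts)]
    have = np.flatnonzero(cell_label != -2)
    if have.size < n_seeds:
        empty = np.flatnonzero(cell_label == -2)
        _, nn = cKDTree(seeds[have]).query(seeds[empty])
        cell_label[empty] = cell_label[have[nn]]
    ext_idx = np.flatnonzero(~interior & ~band)
    label_map[ext_idx] = cell_label[cell[ext_idx]]

    # paint classes, then the frame band, then degradations
    img = np.empty((h * w, 3), dtype=float)
    for li, code in enumerate(labels):
        img[label_map == li] = _color_for(code)
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0, 235, out=img)
    if band.any():
        glow = 248.0 + rng.normal(0.0, 2.0, size=(int(band.sum()), 3))
        img[band] = np.clip(glow, 240, 255)
        label_map[band] = FRAME_INDEX

    img[:, 1] += spec.cast_green
    img[:, 2] += spec.cast_blue
    img *= spec.overexposure_gain
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    interior_counts = {
        code: int(counts[li]) for li, code in enumerate(labels)
    }
    truth = GroundTruth(
        label_map=label_map.reshape(h, w),
        labels=labels,
        frame_rotation_deg=spec.frame_rotation_deg if spec.frame_present else 0.0,
        inner_bbox=inner_bbox,
        class_fractions_interior={
            c: n / n_int for c, n in interior_counts.items()
        },
    )
    return img.reshape(h, w, 3), truth


# --------------------------------------------------------------------------
# dataset writer


def write_scene_dataset(
    out_dir,
    specs: list[SceneSpec],
    metadata: list[dict] | None = None,
) -> pd.DataFrame:
    """Render scenes to PNG files with JSON ground-truth sidecars.

    ``metadata`` supplies per-image manifest fields (site, year, reef_type,
    transect_type, area_m2); missing fields are left empty.  Returns the
    manifest, which is also written to ``manifest.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        img, truth = render_quadrat(spec)
        name = f"quadrat_{i:04d}.png"
        Image.fromarray(img).save(out / name)
        truth.to_json(out / f"quadrat_{i:04d}.truth.json")
        meta = dict(metadata[i]) if metadata else {}
        rows.append(
            {
                "image_path": name,
                "site": meta.get("site", ""),
                "year": meta.get("year", ""),
                "reef_type": meta.get("reef_type", ""),
                "transect_type": meta.get("transect_type", ""),
                "area_m2": meta.get("area_m2", ""),
                "frame_present": spec.frame_present,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# --------------------------------------------------------------------------
# simulated cover time-series


def simulate_cover_series(
    n_sites: int,
    years=STUDY_YEARS,
    trend: dict | None = None,
    reef_types: dict[str, str] | None = None,
    precision: float = 30.0,
    seed: int = 0,
    n_images: int = 1,
    baseline=0.10,
    site_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate per-image proportional cover through time.

    Cover for each label is Beta(mu*phi, (1-mu)*phi) with
    ``logit(mu) = logit(baseline) + slope * (year - mean(years)) + site effect``,
    site effects i.i.d. Normal(0, site_sd) per site and label.  ``trend``
    maps label -> slope on the logit scale per year; a slope may also be a
    ``{reef_type: slope}`` map for reef-type-specific trends.  ``baseline``
    is a scalar or a label -> baseline-cover map.  With the defaults
    (φ=30, site_sd=0.5, the five survey years) the generator emulates
    site-to-site variability typical of reef photoquadrat cover data.

    Returns a tidy frame (site, year, reef_type, label, image, cover) with
    every cover strictly inside (0, 1); identical seeds give identical
    tables.
    """
    years = list(years)
    if len(set(years)) < 2:
        raise ValueError("need at least 2 distinct years")
    if precision <= 0:
        raise ValueError("beta precision must be positive")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    trend = trend or {"SC": 0.0}

    if reef_types is None:
        if n_sites <= len(STUDY_SITES):
            site_names = STUDY_SITES[:n_sites]
            reef_types = {s: STUDY_REEF_TYPES[s] for s in site_names}
        else:
            site_names = [f"site{i + 1:02d}" for i in range(n_sites)]
            reef_types = {
                s: ("patch" if i % 2 == 0 else "forereef")
                for i, s in enumerate(site_names)
            }
    else:
        site_names = list(reef_types.keys())[:n_sites]
        if len(site_names) < n_sites:
            raise ValueError("reef_types must name every site")

    rng = np.random.default_rng(seed)
    yc = np.asarray(years, dtype=float) - float(np.mean(years))
    rows = []
    for label, slope in trend.items():
        base = baseline[label] if isinstance(baseline, dict) else baseline
        eta0 = np.log(base / (1 - base))
        site_eff = rng.normal(0.0, site_sd, size=len(site_names))
        for si, site in enumerate(site_names):
            rt = reef_types[site]
            sl = slope[rt] if isinstance(slope, dict) else slope
            for yi, year in enumerate(years):
                mu = 1.0 / (1.0 + np.exp(-(eta0 + site_eff[si] + sl * yc[yi])))
                cov = rng.beta(mu * precision, (1 - mu) * precision, size=n_images)
                for k in range(n_images):
                    rows.append(
                        {
                            "site": site,
                            "year": year,
                            "reef_type": rt,
                            "label": label,
                            "image": k + 1,
                            "cover": float(cov[k]),
                        }
                    )
    return pd.DataFrame(rows)
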