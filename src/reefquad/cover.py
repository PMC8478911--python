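"""Percent-cover estimation and aggregation from finalized point counts.

Per image, cover of a benthic label is the fraction of finalized points
assigned that label after removing image-quality points (shadow, transect
tape, unidentifiable) and renormalizing, so benthic cover always sums
to 1.  Site-year aggregation averages over images (SE over images, the
replication unit).  Two procedures from survey practice are included:
the oversampled-first-year fix (median of per-label means over repeated
random subsamples of n images) and the image-area bias regression
(per-label OLS of cover on log10 image area for groups above a minimum
mean cover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import PointAnnotation
from .schema import DEFAULT_SCHEMA, LabelSchema
from .sites import FIXED_TRANSECT_SITES, STUDY_REEF_TYPES


class CoverUndefinedError(Exception):
    """An image retained no benthic points after quality-label exclusion."""


@dataclass(frozen=True)
class QuadratRecord:
    """Manifest entry for one photoquadrat."""

    image_id: str
    site: str
    year: int
    reef_type: str | None = None
    transect_type: str | None = None
    area_m2: float | None = None

    def __post_init__(self) -> None:
        rt = self.reef_type or STUDY_REEF_TYPES.get(self.site)
        tt = self.transect_type or (
            "fixed" if self.site in FIXED_TRANSECT_SITES else "random"
        )
        object.__setattr__(self, "reef_type", rt)
        object.__setattr__(self, "transect_type", tt)
        if self.reef_type not in ("patch", "forereef"):
            raise ValueError(f"unknown reef type for site {self.site!r}")
        if self.area_m2 is not None and self.area_m2 <= 0:
            raise ValueError("image area must be positive")


def image_cover(
    points: list[PointAnnotation], schema: LabelSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Per-label cover fractions for one image's finalized points.

    Quality-category points are excluded and the denominator renormalized
    to the remaining (benthic) points.  Raises
    :class:`CoverUndefinedError` if nothing benthic remains.
    """
    if not points:
        raise CoverUndefinedError("no points for this image")
    labels = []
    for p in points:
        if not p.finalized:
            raise ValueError("all points must be finalized")
        labels.append(p.final_label)
    benthic = [l for l in labels if l in schema.benthic_codes]
    if not benthic:
        raise CoverUndefinedError(
            "no benthic points remain after quality-label exclusion"
        )
    n = len(benthic)
    counts = pd.Series(benthic).value_counts()
    return pd.DataFrame(
        {
            "label": counts.index,
            "cover": counts.values / n,
            "n_points_included": n,
        }
    )


def cover_table(
    points_by_image: dict[str, list[PointAnnotation]],
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Long cover table (image_id, label, cover, n_points_included) over
    many images.  Images with undefined cover are flagged in the
    ``undefined`` attribute-style column of the returned frame's
    ``.attrs`` rather than silently dropped."""
    rows, undefined = [], []
    for image_id, pts in points_by_image.items():
        try:
            tab = image_cover(pts, schema)
        except CoverUndefinedError:
            undefined.append(image_id)
            continue
        tab = tab.assign(image_id=image_id)
        rows.append(tab)
    out = (
        pd.concat(rows, ignore_index=True)[
            ["image_id", "label", "cover", "n_points_included"]
        ]
        if rows
        else pd.DataFrame(columns=["image_id", "label", "cover", "n_points_included"])
    )
    out.attrs["undefined_images"] = undefined
    return out


def _wide(cover: pd.DataFrame) -> pd.DataFrame:
    """image x label matrix of cover, absent labels as 0, rows sorted by
    image id (canonical order makes resampling order-invariant)."""
    w = cover.pivot_table(
        index="image_id", columns="label", values="cover", fill_value=0.0
    )
    return w.sort_index()


def resample_median_cover(
    cover: pd.DataFrame,
    n_sub: int = 20,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Median over ``n_iter`` random subsamples of the per-label mean
    cover of ``n_sub`` distinct images — the fix for an oversampled
    survey year.

    ``cover`` is a long table (image_id, label, cover) for one site-year.
    Per-label medians are reported as-is and need not sum exactly to 1.
    """
    w = _wide(cover)
    n_img = len(w)
    if n_img < n_sub:
        raise ValueError(
            f"only {n_img} images (< n_sub={n_sub}); use the plain mean instead"
        )
    rng = np.random.default_rng(seed)
    vals = w.to_numpy()
    means = np.empty((n_iter, vals.shape[1]))
    for i in range(n_iter):
        idx = rng.choice(n_img, size=n_sub, replace=False)
        means[i] = vals[idx].mean(axis=0)
    med = np.median(means, axis=0)
    return pd.Series(med, index=w.columns, name="median_cover")


def site_year_cover(
    cover: pd.DataFrame, manifest: list[QuadratRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-image cover to site-year means with standard errors.

    SE = sd / sqrt(n_images) over images (absent labels count as 0 cover
    in an image); a single-image site-year gets an absent SE.
    """
    if isinstance(manifest, pd.DataFrame):
        meta = manifest.copy()
    else:
        meta = pd.DataFrame(
            {
                "image_id": [m.image_id for m in manifest],
                "site": [m.site for m in manifest],
                "year": [m.year for m in manifest],
                "reef_type": [m.reef_type for m in manifest],
                "transect_type": [m.transect_type for m in manifest],
            }
        )
    w = _wide(cover)
    long = (
        w.reset_index()
        .melt(id_vars="image_id", var_name="label", value_name="cover")
        .merge(meta, on="image_id", how="inner")
    )
    gb = long.groupby(["site", "year", "label"], observed=True)["cover"]
    agg = gb.agg(["mean", "std", "count"]).reset_index()
    agg["se"] = agg["std"] / np.sqrt(agg["count"])
    agg.loc[agg["count"] < 2, "se"] = np.nan
    agg = agg.rename(columns={"mean": "cover", "count": "n_images"}).drop(
        columns="std"
    )
    extra = meta.drop_duplicates("image_id").groupby(["site", "year"]).first()
    agg = agg.merge(
        extra[["reef_type", "transect_type"]].reset_index(),
        on=["site", "year"],
        how="left",
    )
    return agg[
        ["site", "year", "reef_type", "transect_type", "label", "cover", "se", "n_images"]
    ]


def area_bias_check(
    cover: pd.DataFrame,
    areas: dict[str, float],
    min_mean_cover: float = 0.01,
) -> pd.DataFrame:
    """Per-label OLS of cover against log10 image area.

    Labels with mean cover at or below ``min_mean_cover`` are excluded.
    Returns (label, slope, p_value, n).  A significant slope would flag
    systematic bias from varying imaged area; the monitoring design
    expects a null result.
    """
    w = _wide(cover)
    common = [i for i in w.index if i in areas]
    if len(common) < 3:
        raise ValueError("need at least 3 images with a measured area")
    w = w.loc[common]
    a = np.array([areas[i] for i in common], dtype=float)
    if np.allclose(a, a[0]):
        raise ValueError("all image areas identical; slope undefined")
    x = np.log10(a)
    rows = []
    for label in w.columns:
        if w[label].mean() <= min_mean_cover:
            continue
        res = stats.linregress(x, w[label].to_numpy())
        rows.append(
            {
                "label": label,
                "slope": float(res.slope),
                "p_value": float(res.pvalue),
                "n": len(common),
            }
        )
    return pd.DataFrame(rows)
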