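"""Reporter-intensity quantification from segmented-nucleus tables.

Implements the imaging readout used to compare nuclear reporter levels
across a proneural stripe: per-image intensities are rescaled so the
maximal level of each reporter is of order one, nuclei are flagged as
showing detectable expression when the normalized level strictly exceeds a
threshold (0.2 by default), each nucleus is assigned a signed perpendicular
distance to a manually traced stripe centerline, and per-bin statistics
(sum of normalized level minus threshold over detectable nuclei, or mean
normalized level) are aggregated across images as mean +/- SEM.

Input tables are pandas DataFrames with columns ``image_id``,
``nucleus_id``, ``x_um``, ``y_um`` and one column per reporter channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Centerline",
    "ExpressionProfile",
    "normalize_image",
    "normalize_images",
    "flag_detectable",
    "signed_distance",
    "compute_profile",
]

META_COLUMNS = ("image_id", "nucleus_id", "x_um", "y_um")


def channel_columns(df: pd.DataFrame) -> list[str]:
    """Reporter channel columns = everything that is not metadata or derived."""
    return [
        c for c in df.columns
        if c not in META_COLUMNS and not c.endswith(("_norm", "_detectable"))
    ]


# ---------------------------------------------------------------------------
# normalization and detection

def normalize_image(
    df: pd.DataFrame,
    channels: Sequence[str] | None = None,
    mode: str = "percentile",
    percentile: float = 99.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Normalize raw intensities of one image so maxima are of order one.

    ``mode='max'`` divides by the per-channel maximum (the brightest nucleus
    maps exactly to 1); ``mode='percentile'`` divides by the given upper
    percentile, a robust variant under which a few nuclei may exceed 1.
    Channels that are identically zero cannot be scaled; they are left
    without a ``_norm`` column and returned in the skipped list.
    """
    if len(df) == 0:
        raise ValueError("normalize_image requires at least one nucleus")
    if df["image_id"].nunique() > 1:
        raise ValueError("normalize_image expects records from a single image")
    if mode not in ("max", "percentile"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    channels = list(channels) if channels is not None else channel_columns(df)
    out = df.copy()
    skipped: list[str] = []
    for ch in channels:
        raw = out[ch].to_numpy(dtype=float)
        if np.any(raw < 0):
            raise ValueError(f"channel {ch!r} has negative raw intensities")
        scale = float(np.max(raw)) if mode == "max" else float(np.percentile(raw, percentile))
        if scale <= 0:
            skipped.append(ch)
            continue
        out[f"{ch}_norm"] = raw / scale
    return out, skipped


def normalize_images(
    df: pd.DataFrame,
    channels: Sequence[str] | None = None,
    mode: str = "percentile",
    percentile: float = 99.0,
) -> tuple[pd.DataFrame, dict]:
    """Apply :func:`normalize_image` independently to every image."""
    parts, skipped = [], {}
    for image_id, group in df.groupby("image_id", sort=True):
        part, sk = normalize_image(group, channels, mode, percentile)
        parts.append(part)
        if sk:
            skipped[image_id] = sk
    return pd.concat(parts, ignore_index=True), skipped


def flag_detectable(
    df: pd.DataFrame,
    channels: Sequence[str] | None = None,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Flag nuclei whose normalized level strictly exceeds ``threshold``."""
    channels = list(channels) if channels is not None else channel_columns(df)
    out = df.copy()
    for ch in channels:
        col = f"{ch}_norm"
        if col not in out.columns:
            raise ValueError(f"channel {ch!r} has not been normalized yet")
        out[f"{ch}_detectable"] = out[col].to_numpy(dtype=float) > threshold
    return out


# ---------------------------------------------------------------------------
# centerline geometry

@dataclass(frozen=True)
class Centerline:
    """Polyline tracing the stripe center, in image coordinates (um).

    The sign convention follows the traversal direction: points to the left
    of the directed polyline get positive offsets.  For a centerline drawn
    left-to-right along x this makes the +y side positive.
    """

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
            raise ValueError("centerline needs >= 2 two-dimensional vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("centerline has coincident consecutive vertices")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Centerline":
        df = pd.read_csv(path)
        return cls(df[["x_um", "y_um"]].to_numpy(dtype=float))

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        """Signed perpendicular distance of each point to the polyline.

        Magnitude is the Euclidean point-to-polyline distance; the sign
        comes from the side of the nearest segment.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.vertices[:-1]          # (m, 2)
        b = self.vertices[1:]
        ab = b - a
        ab2 = (ab**2).sum(axis=1)
        ap = p[:, None, :] - a[None, :, :]          # (n, m, 2)
        t = np.clip((ap * ab[None]).sum(axis=2) / ab2[None], 0.0, 1.0)
        foot = a[None] + t[..., None] * ab[None]
        diff = p[:, None, :] - foot
        d2 = (diff**2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        cross = (
            ab[nearest, 0] * ap[rows, nearest, 1]
            - ab[nearest, 1] * ap[rows, nearest, 0]
        )
        sign = np.where(cross >= 0, 1.0, -1.0)
        return sign * np.sqrt(d2[rows, nearest])


def signed_distance(x_um: float, y_um: float, line: Centerline) -> float:
    """Signed distance of a single nucleus to the centerline."""
    return float(line.signed_distances(np.array([[x_um, y_um]]))[0])


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class ExpressionProfile:
    """Across-image binned expression profile of one channel."""

    channel: str
    bin_edges: np.ndarray         # signed distance, um
    bin_centers: np.ndarray
    per_image: pd.DataFrame       # images x bins
    mean: np.ndarray
    sem: np.ndarray               # NaN when n_images < 2
    n_images: int
    bin_width: float
    threshold: float
    statistic: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.bin_centers,
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n_images,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_profile(
    records: pd.DataFrame,
    centerlines: "Centerline | Mapping[object, Centerline]",
    channel: str,
    bin_width: float = 2.0,
    profile_range: float = 20.0,
    threshold: float = 0.2,
    statistic: str = "sum_minus_threshold",
    normalization: str = "percentile",
) -> ExpressionProfile:
    """Binned expression profile of ``channel`` versus signed distance.

    Per image: nuclei are normalized, flagged, assigned signed distances to
    that image's centerline and binned over ``[-profile_range,
    +profile_range)``.  ``statistic='sum_minus_threshold'`` sums
    ``normalized - threshold`` over detectable nuclei per bin (an image
    with no detectable nuclei contributes an all-zero profile);
    ``statistic='mean_intensity'`` averages the normalized level of
    detectable nuclei per bin (empty bins contribute 0).  Across images the
    per-bin mean and standard error are reported.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if statistic not in ("sum_minus_threshold", "mean_intensity"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if channel not in records.columns:
        raise ValueError(f"channel column {channel!r} missing from records")

    n_bins = int(round(2 * profile_range / bin_width))
    edges = -profile_range + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    image_ids = sorted(records["image_id"].unique())
    rows = {}
    for image_id in image_ids:
        img = records[records["image_id"] == image_id]
        line = centerlines if isinstance(centerlines, Centerline) else centerlines[image_id]
        if normalization == "none":
            # records already carry normalized levels in the channel column
            img = img.copy()
            img[f"{channel}_norm"] = img[channel].to_numpy(dtype=float)
            skipped = []
        else:
            img, skipped = normalize_image(img, [channel], mode=normalization)
        row = np.zeros(n_bins)
        if channel not in skipped:
            img = flag_detectable(img, [channel], threshold)
            det = img[img[f"{channel}_detectable"]]
            if len(det):
                dist = line.signed_distances(det[["x_um", "y_um"]].to_numpy(dtype=float))
                vals = det[f"{channel}_norm"].to_numpy(dtype=float)
                inside = (dist >= edges[0]) & (dist < edges[-1])
                which = np.digitize(dist[inside], edges) - 1
                if statistic == "sum_minus_threshold":
                    row = np.bincount(
                        which, weights=vals[inside] - threshold, minlength=n_bins
                    )
                else:
                    sums = np.bincount(which, weights=vals[inside], minlength=n_bins)
                    cnts = np.bincount(which, minlength=n_bins)
                    row = np.divide(sums, cnts, out=np.zeros(n_bins), where=cnts > 0)
        rows[image_id] = row

    per_image = pd.DataFrame.from_dict(rows, orient="index", columns=centers)
    mean = per_image.to_numpy().mean(axis=0)
    n = len(per_image)
    sem = (
        per_image.to_numpy().std(axis=0, ddof=1) / np.sqrt(n)
        if n >= 2
        else np.full(n_bins, np.nan)
    )
    return ExpressionProfile(
        channel=channel,
        bin_edges=edges,
        bin_centers=centers,
        per_image=per_image,
        mean=mean,
        sem=sem,
        n_images=n,
        bin_width=bin_width,
        threshold=threshold,
        statistic=statistic,
    )
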