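"""Shell colour phenotyping.

Quantifies hue, saturation and darkness of shell images (darkness is defined
operationally as 1 minus the mean HSV brightness over shell pixels; hue is
the circular mean in degrees) and tests group differences the way the
phenotype analysis does: Shapiro-Wilk normality per group, then pairwise
two-sided Wilcoxon rank-sum tests, exact by enumeration for small tie-free
samples and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ColorMeasurement:
    image_id: str
    mean_hue: float          # degrees in [0, 360)
    mean_saturation: float
    darkness: float          # 1 - mean brightness (HSV value)
    n_pixels: int


@dataclass
class GroupTestResult:
    comparison: str
    test: str                # wilcoxon | shapiro
    statistic: float
    p: float


def _to_rgb_array(image) -> np.ndarray:
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        from PIL import Image

        arr = np.asarray(Image.open(image).convert("RGB"))
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    return arr


def read_pixel_matrix_tsv(path) -> np.ndarray:
    """Plain-text pixel matrix: one row per pixel, columns R G B in 0-255."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    arr = df.to_numpy(dtype=float)[:, :3] / 255.0
    return arr.reshape(-1, 1, 3)


def hsb_stats(image, mask=None, image_id: str = "") -> ColorMeasurement:
    """Mean hue (circular), saturation and darkness of an RGB image.

    Per-pixel RGB->HSV conversion; saturation and brightness are arithmetic
    means over masked pixels, darkness = 1 - mean brightness, and hue is the
    unit-vector average in degrees.
    """
    from skimage.color import rgb2hsv

    arr = _to_rgb_array(image)
    hsv = rgb2hsv(arr)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        hsv = hsv[mask]
    else:
        hsv = hsv.reshape(-1, 3)
    h = hsv[:, 0] * 2 * np.pi
    sin_m, cos_m = np.sin(h).mean(), np.cos(h).mean()
    mean_hue = float(np.degrees(np.arctan2(sin_m, cos_m)) % 360.0)
    mean_sat = float(hsv[:, 1].mean())
    darkness = float(1.0 - hsv[:, 2].mean())
    return ColorMeasurement(image_id, mean_hue, mean_sat, darkness, hsv.shape[0])


def shapiro_test(values, label: str = "") -> GroupTestResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValueError("constant sample; Shapiro-Wilk undefined")
    w, p = stats.shapiro(x)
    return GroupTestResult(label, "shapiro", float(w), float(p))


def wilcoxon_rank_sum(a, b, label: str = "", mode: str = "exact_if_small") -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration of the rank-sum distribution when the combined
    sample has at most 25 values and no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if mode == "exact_if_small":
        method = "exact" if (len(combined) <= 25 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return GroupTestResult(label, "wilcoxon", float(res.statistic), float(min(res.pvalue, 1.0)))


def phenotype_pipeline(image_groups: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group colour measurements and pairwise group tests.

    ``image_groups`` maps a group label to a list of images (arrays or
    paths), at least three per group.  Returns (measurements, tests):
    Shapiro-Wilk on darkness per group, then pairwise Wilcoxon rank-sum on
    darkness and on saturation for every pair of groups; hue is reported
    descriptively in the measurement table only.
    """
    if len(image_groups) < 2:
        raise ValueError("need at least two groups")
    meas_rows = []
    per_group: dict[str, pd.DataFrame] = {}
    for label, images in image_groups.items():
        if len(images) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 images")
        rows = []
        for i, img in enumerate(images):
            m = hsb_stats(img, image_id=f"{label}/{i}")
            rows.append((label, m.image_id, m.mean_hue, m.mean_saturation,
                         m.darkness, m.n_pixels))
        gdf = pd.DataFrame(
            rows, columns=["group", "image_id", "mean_hue", "mean_saturation",
                           "darkness", "n_pixels"]
        )
        per_group[label] = gdf
        meas_rows.append(gdf)
    measurements = pd.concat(meas_rows, ignore_index=True)

    tests = []
    for label, gdf in per_group.items():
        d = gdf["darkness"].to_numpy()
        try:
            r = shapiro_test(d, label)
            tests.append((label, "shapiro", "darkness", r.statistic, r.p))
        except ValueError:
            tests.append((label, "shapiro", "darkness", np.nan, np.nan))
    labels = list(per_group)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            for metric in ("darkness", "mean_saturation"):
                r = wilcoxon_rank_sum(
                    per_group[la][metric], per_group[lb][metric],
                    label=f"{la} vs {lb}",
                )
                tests.append((f"{la} vs {lb}", "wilcoxon", metric, r.statistic, r.p))
    test_df = pd.DataFrame(
        tests, columns=["comparison", "test", "metric", "statistic", "p"]
    )
    return measurements, test_df
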