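"""Immunostain quantification: area fraction and two-way ANOVA statistics.

The staining signal in a single-channel image is thresholded (fixed value or
Otsu's method), binarized, and summarized as the *area fraction* — the
proportion of pixels at or above threshold.  Fractions measured per animal,
per anatomical region (dorsal/ventral grey and white matter: DG, VG, DW, VW)
are compared between SCI and sham groups by a fixed-effects two-way ANOVA
(group, region, interaction) with Holm-Sidak-adjusted per-region contrasts.

Unbalanced designs use Type II sums of squares.  Per-region group contrasts
share the ANOVA residual mean square (the pooled error), as multiple-comparison
procedures following an ANOVA conventionally do.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

REGIONS = ("DG", "VG", "DW", "VW")
GROUPS = ("SCI", "sham")


def area_fraction(image: np.ndarray, threshold: float | str = "otsu") -> float:
    """Fraction of pixels at or above *threshold* in a single-channel image.

    ``threshold="otsu"`` picks the threshold by Otsu's method.  Pixels with
    intensity >= threshold count as foreground.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if img.min() == img.max():
            # constant image: Otsu undefined; nothing exceeds the signal level
            return 0.0
        thr = threshold_otsu(img)
        # skimage's convention is foreground > thr; shift to >= on the next
        # representable level for integer images
        foreground = img > thr
    else:
        foreground = img >= threshold
    return float(foreground.mean())


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment, input order preserved.

    Sorted ascending, adj_(i) = 1 - (1 - p_(i))^(m - i + 1); a running
    maximum enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def two_way_anova_holm_sidak(
    data: pd.DataFrame,
    value: str = "area_fraction",
    group: str = "group",
    region: str = "region",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (group x region) plus Holm-Sidak per-region contrasts.

    Parameters
    ----------
    data : long-format DataFrame
        One measurement per row with group, region, and value columns;
        at least 2 groups, 2 regions, and 2 observations per cell.

    Returns
    -------
    (anova, comparisons) : the Type II ANOVA table (sum_sq, df, F, PR(>F) for
        group, region, interaction, residual) and a per-region table with the
        group means, mean difference, t (on the pooled residual MS), raw and
        Holm-Sidak-adjusted p.
    """
    df = data.copy()
    for col in (value, group, region):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    groups = sorted(df[group].unique())
    regions = sorted(df[region].unique())
    if len(groups) < 2 or len(regions) < 2:
        raise ValueError("need at least 2 groups and 2 regions")
    for g in groups:
        for r in regions:
            n_cell = int(((df[group] == g) & (df[region] == r)).sum())
            if n_cell < 2:
                raise ValueError(
                    f"cell (group={g!r}, region={r!r}) has {n_cell} observation(s); "
                    "need at least 2"
                )

    model = smf.ols(
        f"Q('{value}') ~ C(Q('{group}')) * C(Q('{region}'))", data=df
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = ["group", "region", "interaction", "residual"]

    mse = float(anova.loc["residual", "sum_sq"] / anova.loc["residual", "df"])
    df_err = float(anova.loc["residual", "df"])
    if len(groups) != 2:
        raise ValueError("per-region contrasts are defined for exactly 2 groups")
    g1, g2 = groups
    rows = []
    for r in regions:
        a = df[(df[group] == g1) & (df[region] == r)][value].to_numpy(float)
        b = df[(df[group] == g2) & (df[region] == r)][value].to_numpy(float)
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        t = diff / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df=df_err)
        rows.append(
            {
                "region": r,
                f"mean_{g1}": a.mean(),
                f"mean_{g2}": b.mean(),
                "diff": diff,
                "t": t,
                "p": p,
            }
        )
    comparisons = pd.DataFrame(rows)
    comparisons["p_adj"] = holm_sidak(comparisons["p"].to_numpy())
    return anova, comparisons


def measure_manifest(
    manifest: pd.DataFrame,
    threshold: float | str = "otsu",
    root: str | Path = ".",
) -> pd.DataFrame:
    """Measure area fractions for a manifest of images.

    ``manifest`` columns: path, animal_id, group, region.  Returns a
    RegionMeasurement table (animal_id, group, region, area_fraction).
    """
    import imageio.v3 as iio

    rows = []
    for rec in manifest.itertuples(index=False):
        img = iio.imread(Path(root) / rec.path)
        rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "region": rec.region,
                "area_fraction": area_fraction(img, threshold),
            }
        )
    return pd.DataFrame(rows)
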