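"""Regional plantar-pressure analysis and validation statistics.

A plantar pressure map (uniform grid of cell-centre coordinates in mm with
pressures in kPa) is partitioned into the standard anatomical regions —
seven for barefoot analysis (medial/lateral heel, midfoot, medial/middle/
lateral forefoot, hallux) or eight when the midfoot is split medially/
laterally (orthosis analysis).  Region boundaries are longitudinal bands
by fraction of footprint length along the foot axis and medial-to-lateral
width fractions within the forefoot; the exact fractions are a package
convention and fully configurable.

Per-region peak pressures feed the validation statistics: a
Shapiro-Wilk-gated paired comparison (paired t-test when the differences
are consistent with normality at alpha, Wilcoxon matched-pairs signed-rank
otherwise) and an agreement analysis (Pearson correlation plus
Bland-Altman mean offset with 1.96-SD limits of agreement).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PressureMap",
    "RegionScheme",
    "PairedComparisonResult",
    "AgreementResult",
    "partition_regions",
    "region_peaks",
    "compare_paired",
    "agreement",
]


@dataclass
class PressureMap:
    """Gridded plantar pressure field (kPa) on uniform cell centres (mm).

    ``side`` orients the medial direction: for a right foot with the
    package frame (+y anterior) the medial border is the +x side.
    An explicit ``heel_point``/``toe_direction`` override the automatic
    foot-axis estimate.
    """

    x: np.ndarray          # (nx,) cell-centre x coordinates
    y: np.ndarray          # (ny,) cell-centre y coordinates
    values: np.ndarray     # (ny, nx) pressures, kPa
    side: str = "right"
    heel_point: Optional[np.ndarray] = None
    toe_direction: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.y), len(self.x)):
            raise ValueError("values must have shape (len(y), len(x))")
        if np.any(self.values < 0):
            raise ValueError("pressures must be nonnegative")
        for coords in (self.x, self.y):
            if len(coords) > 1:
                d = np.diff(coords)
                if not np.allclose(d, d[0], rtol=1e-6):
                    raise ValueError("grid spacing must be uniform per axis")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def footprint(self) -> np.ndarray:
        return self.values > 0

    @classmethod
    def from_csv(cls, path, side: str = "right") -> "PressureMap":
        """Read an ``x,y,pressure_kpa`` CSV written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        xs = np.unique(df["x"].to_numpy())
        ys = np.unique(df["y"].to_numpy())
        values = np.zeros((len(ys), len(xs)))
        xi = np.searchsorted(xs, df["x"].to_numpy())
        yi = np.searchsorted(ys, df["y"].to_numpy())
        values[yi, xi] = df["pressure_kpa"].to_numpy()
        return cls(xs, ys, values, side=side)

    def to_csv(self, path) -> Path:
        xx, yy = self.cell_centers()
        df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                           "pressure_kpa": self.values.ravel()})
        df.to_csv(path, index=False)
        return Path(path)


@dataclass(frozen=True)
class RegionScheme:
    """Region naming plus the boundary fractions that delimit them.

    ``long_bounds`` are the heel/midfoot/forefoot/toe cut fractions of the
    footprint length (posterior -> anterior); ``width_bounds`` split the
    forefoot medial-to-lateral; ``hallux_frac`` is the medial fraction of
    the toe band assigned to the hallux.
    """

    name: str
    region_names: tuple
    long_bounds: tuple = (0.30, 0.60, 0.85)
    width_bounds: tuple = (0.40, 0.70)
    hallux_frac: float = 1.0 / 3.0

    @classmethod
    def seven(cls, **kw) -> "RegionScheme":
        return cls("SEVEN", ("medial heel", "lateral heel", "midfoot",
                             "medial forefoot", "middle forefoot",
                             "lateral forefoot", "hallux"), **kw)

    @classmethod
    def eight(cls, **kw) -> "RegionScheme":
        return cls("EIGHT", ("medial heel", "lateral heel",
                             "medial midfoot", "lateral midfoot",
                             "medial forefoot", "middle forefoot",
                             "lateral forefoot", "hallux"), **kw)


def _foot_axis(pmap: PressureMap) -> tuple[np.ndarray, np.ndarray]:
    """Heel point and unit toe direction.

    Default estimate: heel point is the pressure-weighted centroid of the
    posterior 15% band of the footprint (along +y), the direction points
    from it to the centroid of the anterior 15% band.
    """
    if pmap.heel_point is not None and pmap.toe_direction is not None:
        d = np.asarray(pmap.toe_direction, dtype=np.float64)
        return np.asarray(pmap.heel_point, dtype=np.float64), d / np.linalg.norm(d)
    xx, yy = pmap.cell_centers()
    fp = pmap.footprint()
    if not fp.any():
        raise ValueError("empty footprint")
    ys = yy[fp]
    y0, y1 = ys.min(), ys.max()
    length = max(y1 - y0, 1e-9)

    def band_centroid(mask):
        w = pmap.values[mask]
        return np.array([np.average(xx[mask], weights=w),
                         np.average(yy[mask], weights=w)])

    post = fp & (yy <= y0 + 0.15 * length)
    ant = fp & (yy >= y1 - 0.15 * length)
    heel = band_centroid(post)
    toe = band_centroid(ant)
    d = toe - heel
    return heel, d / np.linalg.norm(d)


def partition_regions(pmap: PressureMap, scheme: RegionScheme) -> dict:
    """Disjoint region masks covering every loaded (pressure > 0) cell.

    Longitudinal position is the projection onto the foot axis normalised
    to [0, 1] over the footprint; the lateral coordinate is the signed
    offset from the axis line, oriented so positive = medial.
    """
    fp = pmap.footprint()
    if not fp.any():
        raise ValueError("empty footprint")
    heel, axis = _foot_axis(pmap)
    # medial unit vector: +90 deg rotation of the axis for a left foot,
    # -90 deg for a right foot (medial is +x when the axis is +y, right side)
    if pmap.side == "right":
        medial = np.array([axis[1], -axis[0]])
    else:
        medial = np.array([-axis[1], axis[0]])
    xx, yy = pmap.cell_centers()
    rel = np.stack([xx - heel[0], yy - heel[1]], axis=-1)
    t = rel @ axis
    u = rel @ medial
    tf = t[fp]
    t01 = (t - tf.min()) / max(tf.max() - tf.min(), 1e-9)

    lb = scheme.long_bounds
    heel_band = fp & (t01 < lb[0])
    mid_band = fp & (t01 >= lb[0]) & (t01 < lb[1])
    fore_band = fp & (t01 >= lb[1]) & (t01 < lb[2])
    toe_band = fp & (t01 >= lb[2])

    # medial-to-lateral width fraction over the forefoot + toe bands
    ft = fore_band | toe_band
    masks = {name: np.zeros_like(fp) for name in scheme.region_names}
    if ft.any():
        u_ft = u[ft]
        u_max, u_min = u_ft.max(), u_ft.min()     # most medial, most lateral
        w = (u_max - u) / max(u_max - u_min, 1e-9)
        wb = scheme.width_bounds
        med_col = w < wb[0]
        midl_col = (w >= wb[0]) & (w < wb[1])
        lat_col = w >= wb[1]
        hallux = toe_band & (w < scheme.hallux_frac)
        masks["hallux"] = hallux
        rest = ft & ~hallux
        masks["medial forefoot"] = rest & med_col
        masks["middle forefoot"] = rest & midl_col
        masks["lateral forefoot"] = rest & lat_col
    medial_side = u >= 0
    masks["medial heel"] = heel_band & medial_side
    masks["lateral heel"] = heel_band & ~medial_side
    if scheme.name == "EIGHT":
        masks["medial midfoot"] = mid_band & medial_side
        masks["lateral midfoot"] = mid_band & ~medial_side
    else:
        masks["midfoot"] = mid_band

    total = np.zeros_like(fp, dtype=int)
    for m in masks.values():
        total += m.astype(int)
    if np.any(total[fp] != 1) or np.any(total[~fp] != 0):
        raise AssertionError("region masks are not a disjoint cover of the footprint")
    return masks


def region_peaks(pmap: PressureMap, masks: dict) -> dict:
    """Per-region peak pressure (kPa); empty regions report 0 with a warning."""
    peaks = {}
    for name, mask in masks.items():
        if mask.any():
            peaks[name] = float(pmap.values[mask].max())
        else:
            warnings.warn(f"region {name!r} contains no loaded cells; peak set to 0")
            peaks[name] = 0.0
    return peaks


@dataclass(frozen=True)
class PairedComparisonResult:
    """Outcome of a normality-gated paired comparison."""

    test: str                  # "paired-t" or "wilcoxon"
    statistic: float
    p_value: float
    normality_p: float
    alpha: float
    mean_a: float
    mean_b: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_paired(a, b, alpha: float = 0.05,
                   normality_on: str = "differences") -> PairedComparisonResult:
    """Paired comparison with a Shapiro-Wilk normality gate at ``alpha``.

    The paired t-test is used when normality is not rejected, otherwise the
    Wilcoxon matched-pairs signed-rank test (exact for n <= 25 after
    dropping zero differences, normal approximation with continuity
    correction above).  ``normality_on`` selects whether Shapiro-Wilk is
    applied to the paired differences (default) or to each sample.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("paired comparison needs at least 3 pairs")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return PairedComparisonResult("wilcoxon", 0.0, 1.0, float("nan"),
                                      alpha, float(a.mean()), float(b.mean()), n)
    if normality_on == "differences":
        norm_p = float(stats.shapiro(diffs).pvalue)
    elif normality_on == "samples":
        norm_p = float(min(stats.shapiro(a).pvalue, stats.shapiro(b).pvalue))
    else:
        raise ValueError("normality_on must be 'differences' or 'samples'")
    if norm_p >= alpha:
        res = stats.ttest_rel(a, b)
        return PairedComparisonResult("paired-t", float(res.statistic),
                                      float(res.pvalue), norm_p, alpha,
                                      float(a.mean()), float(b.mean()), n)
    nz = diffs[diffs != 0]
    if len(nz) <= 25:
        res = stats.wilcoxon(nz, method="exact")
    else:
        res = stats.wilcoxon(nz, method="approx", correction=True)
    return PairedComparisonResult("wilcoxon", float(res.statistic),
                                  float(res.pvalue), norm_p, alpha,
                                  float(a.mean()), float(b.mean()), n)


@dataclass(frozen=True)
class AgreementResult:
    """Pearson correlation and Bland-Altman agreement of paired peaks."""

    pearson_r: float
    pearson_p: float
    mean_offset: float          # mean(predicted - measured), kPa
    loa_lower: float            # offset - 1.96 SD
    loa_upper: float            # offset + 1.96 SD

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("correlation out of range")
        if not (self.loa_lower <= self.mean_offset <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean offset")


def agreement(measured, predicted) -> AgreementResult:
    """Association and agreement between measured and predicted peaks.

    Pearson product-moment correlation plus Bland-Altman mean offset
    (predicted minus measured) with 95% limits of agreement
    (offset +- 1.96 x SD of the differences).
    """
    m = np.asarray(measured, dtype=np.float64).ravel()
    p = np.asarray(predicted, dtype=np.float64).ravel()
    if m.shape != p.shape:
        raise ValueError("paired samples must have equal length")
    if len(m) < 3:
        raise ValueError("agreement needs at least 3 pairs")
    if np.std(m) == 0 or np.std(p) == 0:
        raise ValueError("zero variance in one of the samples")
    r, pval = stats.pearsonr(m, p)
    diffs = p - m
    offset = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(float(min(max(r, -1.0), 1.0)), float(pval),
                           offset, offset - 1.96 * sd, offset + 1.96 * sd)
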