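"""Inter-rater reliability: ICC(2,1) with F-based confidence intervals.

The reliability model is the two-way random-effects, absolute-agreement,
single-measures intraclass correlation ("Model 2", ICC(2,1)).  Each of
n subjects is measured by the same k raters, both subjects and raters
being treated as random samples; absolute agreement means a systematic
offset between raters counts against reliability.  From the two-way
ANOVA mean squares (rows = subjects MSR, columns = raters MSC, residual
MSE):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

The 95% confidence interval is the standard F-distribution interval for
this model, using a Satterthwaite approximation for the denominator
degrees of freedom.

Estimates are banded qualitatively: > 0.80 'almost perfect',
> 0.60 'substantial', > 0.40 'moderate', > 0.20 'fair', and 'slight'
otherwise (including negative estimates, which are reported as
computed, not floored at zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, IncompleteDesignError, UndefinedICCError
from .io_space import Mask3D
from .metrics import mask_center_of_mass, mask_volume

__all__ = ["RaterTable", "ICCResult", "icc_2_1", "band_icc", "reliability_report"]

#: banding cut-points (strictly greater than the key -> the band)
_BANDS = [
    (0.80, "almost perfect"),
    (0.60, "substantial"),
    (0.40, "moderate"),
    (0.20, "fair"),
]


@dataclass(frozen=True)
class RaterTable:
    """An n-subjects x k-raters grid of measurements in common units."""

    values: np.ndarray
    measure_name: str = "measure"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise IncompleteDesignError("values must be a 2D subjects-by-raters grid")
        n, k = v.shape
        if n < 2 or k < 2:
            raise IncompleteDesignError(
                f"need at least 2 subjects and 2 raters, got {n}x{k}"
            )
        if not np.all(np.isfinite(v)):
            raise IncompleteDesignError("rater table has missing cells")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    band: str


def band_icc(estimate: float) -> str:
    """Qualitative band for an ICC estimate (boundaries go to the upper band)."""
    if not -1.0 - 1e-12 <= estimate <= 1.0 + 1e-12:
        raise ValueError(f"ICC estimate {estimate} outside [-1, 1]")
    for cut, name in _BANDS:
        if estimate > cut:
            return name
    return "slight"


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2_1(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measures ICC.

    Raises :class:`UndefinedICCError` when the table has no variance at
    all (all cells identical).
    """
    x = table.values
    n, k = x.shape
    if np.allclose(x, x.flat[0], atol=0, rtol=0):
        raise UndefinedICCError("all cells identical: ICC undefined")
    msr, msc, mse = _mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300:
        raise UndefinedICCError("degenerate variance decomposition")
    est = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect agreement: interval collapses
        lo = hi = 1.0
    else:
        # Satterthwaite df for the composite denominator mean square
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
            b = 1.0 + (k * est * (n - 1)) / (n * (1.0 - est)) if est < 1.0 else np.inf
        if not np.isfinite(a) or not np.isfinite(b):
            lo = hi = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else (n - 1) * (k - 1)
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_l * mse)
                  / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_u * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo = min(lo, est)
    hi = max(hi, est)
    return ICCResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n=n,
        k=k,
        band=band_icc(max(min(est, 1.0), -1.0)),
    )


def reliability_report(
    masks_rater1: dict[str, dict[str, Mask3D]],
    masks_rater2: dict[str, dict[str, Mask3D]],
    include_centroids: bool = False,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """ICC(2,1) for left, right and combined habenula volume across subjects.

    ``masks_rater*`` map subject id -> {"left": Mask3D, "right": Mask3D}.
    With ``include_centroids`` the per-side centre-of-mass x/y/z
    coordinates are analysed as well.
    """
    subjects = sorted(masks_rater1)
    if sorted(masks_rater2) != subjects:
        raise AlignmentError("subject lists differ between raters")
    if len(subjects) < 2:
        raise IncompleteDesignError("need at least 2 common subjects")

    def vols(masks):
        return {
            s: {side: mask_volume(masks[s][side]) for side in ("left", "right")}
            for s in subjects
        }

    v1, v2 = vols(masks_rater1), vols(masks_rater2)
    tables: dict[str, RaterTable] = {}
    for side in ("left", "right"):
        tables[f"{side}_volume_mm3"] = RaterTable(
            np.array([[v1[s][side], v2[s][side]] for s in subjects]),
            f"{side}_volume_mm3",
        )
    tables["combined_volume_mm3"] = RaterTable(
        np.array(
            [[v1[s]["left"] + v1[s]["right"], v2[s]["left"] + v2[s]["right"]]
             for s in subjects]
        ),
        "combined_volume_mm3",
    )
    if include_centroids:
        for side in ("left", "right"):
            for ax_i, ax in enumerate("xyz"):
                col = np.array(
                    [
                        [mask_center_of_mass(masks_rater1[s][side])[ax_i],
                         mask_center_of_mass(masks_rater2[s][side])[ax_i]]
                        for s in subjects
                    ]
                )
                tables[f"{side}_com_{ax}"] = RaterTable(col, f"{side}_com_{ax}")

    rows = []
    for name, tab in tables.items():
        r = icc_2_1(tab)
        rows.append(
            {
                "measure": name,
                "icc": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "band": r.band,
                "n_subjects": r.n,
                "n_raters": r.k,
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
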