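"""Bland-Altman agreement between two measurement devices.

Two smartphone cameras photograph the same leaf; let ``x`` be the color
parameter measured by device A and ``y`` the value from device B.  With
``d = y - x``, ``m = mean(d)`` and ``s = sd(d)`` (sample, n-1 denominator):

* 95% limits of agreement (LOA): ``m ± 1.96 s`` — the range individual
  device differences fall in about 95% of the time;
* 95% confidence interval (CI) of the mean difference: ``m ± 1.96 s / √n``
  — excludes zero when one device systematically over- or under-reads
  relative to the other.

The CI half-width is exactly the LOA half-width divided by √n, which also
lets a CI be reconstructed from a published LOA and n
(:func:`reconstruct_ci_from_loa`).

Usage follows the Model/Results convention::

    res = BlandAltman(x, y).fit()
    print(res.summary())
    res.plot()
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

Z_95 = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements of the same targets by two devices.

    ``x`` holds device A's values and ``y`` device B's, aligned by target
    and on a common scale (both intensities, or both proportions).
    """

    x: np.ndarray
    y: np.ndarray
    parameter: str = "value"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InputError(
                f"paired sample needs equal-length 1-d arrays, got {x.shape}, {y.shape}"
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "device_a_value": self.x,
                "device_b_value": self.y,
            }
        )


class BlandAltman:
    """Agreement model for paired measurements of the same targets.

    Parameters
    ----------
    x, y : array-like
        Values of one color parameter for the same targets, measured by
        device A (``x``) and device B (``y``).  Pairs with a missing value
        on either side are dropped (logged).
    parameter : str, optional
        Name of the measured quantity, carried into summaries.
    """

    def __init__(self, x, y, parameter: str = "value") -> None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InputError(
                f"x and y must be 1-d arrays of equal length, got {x.shape} and {y.shape}"
            )
        keep = ~(np.isnan(x) | np.isnan(y))
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d pair(s) with missing values", dropped)
        self.x = x[keep]
        self.y = y[keep]
        self.parameter = parameter
        self.n_dropped = dropped

    @classmethod
    def from_pairs(cls, sample: PairedSample) -> "BlandAltman":
        return cls(sample.x, sample.y, parameter=sample.parameter)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        device_a: str = "device_a_value",
        device_b: str = "device_b_value",
        parameter: str = "value",
    ) -> "BlandAltman":
        missing = {device_a, device_b} - set(df.columns)
        if missing:
            raise InputError(f"paired table lacks columns {sorted(missing)}")
        return cls(df[device_a].to_numpy(), df[device_b].to_numpy(), parameter=parameter)

    def fit(self) -> "BlandAltmanResults":
        n = self.x.size
        if n < 2:
            raise InsufficientDataError(
                f"Bland-Altman needs at least 2 complete pairs, got {n}"
            )
        d = self.y - self.x
        m = float(np.mean(d))
        s = float(np.std(d, ddof=1))
        half_loa = Z_95 * s
        half_ci = half_loa / math.sqrt(n)
        return BlandAltmanResults(
            model=self,
            n=n,
            m=m,
            s=s,
            loa=(m - half_loa, m + half_loa),
            ci=(m - half_ci, m + half_ci),
        )


@dataclass(frozen=True)
class BlandAltmanResults:
    """Fitted agreement summary for one color parameter."""

    model: BlandAltman
    n: int
    m: float
    s: float
    loa: tuple[float, float]
    ci: tuple[float, float]

    @property
    def parameter(self) -> str:
        return self.model.parameter

    @property
    def has_systematic_bias(self) -> bool:
        """True when the 95% CI of the mean difference excludes zero."""
        return self.ci[0] > 0.0 or self.ci[1] < 0.0

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "n": self.n,
            "m": self.m,
            "s": self.s,
            "loa_lower": self.loa[0],
            "loa_upper": self.loa[1],
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
        }

    def summary(self) -> str:
        lines = [
            f"Bland-Altman agreement: {self.parameter}",
            f"  pairs (n)              {self.n:>10d}",
            f"  mean difference (m)    {self.m:>10.4f}",
            f"  sd of differences (s)  {self.s:>10.4f}",
            f"  95% LOA                ({self.loa[0]:.4f}, {self.loa[1]:.4f})",
            f"  95% CI of mean diff    ({self.ci[0]:.4f}, {self.ci[1]:.4f})",
            f"  systematic bias        {'yes' if self.has_systematic_bias else 'no'}",
        ]
        return "\n".join(lines)

    def plot_data(self) -> pd.DataFrame:
        """Per-pair plot coordinates: mean of the pair vs. difference."""
        return pd.DataFrame(
            {
                "mean": (self.model.x + self.model.y) / 2.0,
                "difference": self.model.y - self.model.x,
            }
        )

    def reference_levels(self) -> dict[str, float]:
        """Horizontal guide lines of the agreement plot."""
        return {
            "zero": 0.0,
            "m": self.m,
            "loa_lower": self.loa[0],
            "loa_upper": self.loa[1],
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
        }

    def plot(self, ax=None):
        """Draw the agreement plot (scatter + m, LOA, CI and zero lines)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        pts = self.plot_data()
        ax.scatter(pts["mean"], pts["difference"], s=18, color="tab:green", alpha=0.8)
        ax.axhline(0.0, color="grey", ls=":", lw=1)
        ax.axhline(self.m, color="tab:blue", lw=1.2, label="mean difference")
        for b in self.loa:
            ax.axhline(b, color="black", lw=1.2)
        for b in self.ci:
            ax.axhline(b, color="tab:blue", ls=":", lw=1)
        ax.set_xlabel(f"mean {self.parameter}")
        ax.set_ylabel("difference (B - A)")
        ax.legend(loc="best", fontsize=8)
        return ax


def reconstruct_ci_from_loa(
    loa: tuple[float, float], n: int
) -> tuple[float, float]:
    """Recover the 95% CI of the mean difference from a published 95% LOA.

    The LOA midpoint is ``m`` and its half-width is ``1.96 s``; dividing the
    half-width by √n gives the CI half-width.  Useful to check the internal
    consistency of reported agreement tables when the raw pairs are not
    available.
    """
    lo, hi = float(loa[0]), float(loa[1])
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
        raise InputError(f"malformed LOA interval ({lo}, {hi})")
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    m = (lo + hi) / 2.0
    half = (hi - lo) / 2.0 / math.sqrt(n)
    return (m - half, m + half)


def agreement_table(results: list[BlandAltmanResults]) -> pd.DataFrame:
    """Stack several fitted agreement results into one summary table."""
    return pd.DataFrame([r.as_dict() for r in results])
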