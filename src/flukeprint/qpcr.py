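"""Relative standard curve fitting and Ct-to-concentration conversion.

A dilution series of known target-DNA concentrations gives a regression of
threshold cycle (Ct) on log10 concentration; the fitted slope and intercept
convert the Ct of unknown water samples into DNA concentrations (ng/ul).
Amplification efficiency derives from the slope as 10^(-1/slope) - 1
(slope -3.32 ~ 100%: perfect doubling each cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError

DEFAULT_DETECTION_CUTOFF = 45.0


@dataclass
class StandardCurve:
    """Fitted relative standard curve: Ct = slope*log10(conc) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_standards: int
    valid: bool = True

    def predict_ct(self, concentration: float) -> float:
        return self.slope * math.log10(concentration) + self.intercept

    def concentration(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def summary(self) -> str:
        return "\n".join(
            [
                "Relative standard curve",
                "-" * 40,
                f"  slope      {self.slope:10.4f}  Ct per log10(ng/ul)",
                f"  intercept  {self.intercept:10.4f}  Ct",
                f"  r^2        {self.r_squared:10.4f}",
                f"  efficiency {100 * self.efficiency:9.2f}%",
                f"  standards  {self.n_standards:10d}"
                + ("" if self.valid else "   [INVALID: non-negative slope]"),
            ]
        )

    def plot(self, standards: Sequence[tuple[float, float]] | None = None, ax=None):
        """Plot the fitted line (and optionally the standard points)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        if standards:
            x = [math.log10(c) for c, _ in standards]
            y = [ct for _, ct in standards]
            ax.scatter(x, y, label="standards")
            xs = np.linspace(min(x), max(x), 50)
        else:
            xs = np.linspace(-5, 1, 50)
        ax.plot(xs, self.slope * xs + self.intercept, label="fit")
        ax.set_xlabel("log10 concentration (ng/ul)")
        ax.set_ylabel("Ct")
        ax.legend()
        return ax


@dataclass
class QuantResult:
    sample_id: str
    ct: float | None  # mean of determined replicate Cts, None if undetermined
    concentration: float | None
    detected: bool


def fit_standard_curve(
    standards: Sequence[tuple[float, float]] | pd.DataFrame,
) -> StandardCurve:
    """OLS fit of Ct on log10(concentration) for the dilution series.

    ``standards`` is (concentration, Ct) pairs or a frame with
    ``known_concentration``/``ct`` columns.  Replicate wells at one
    concentration are averaged on the Ct scale before fitting.  Requires at
    least three usable standards at distinct concentrations; a non-negative
    slope flags the curve invalid.
    """
    if isinstance(standards, pd.DataFrame):
        pairs = list(
            zip(standards["known_concentration"].tolist(), standards["ct"].tolist())
        )
    else:
        pairs = list(standards)
    usable = [
        (c, t)
        for c, t in pairs
        if c is not None and t is not None and c > 0 and math.isfinite(t)
    ]
    by_conc: dict[float, list[float]] = {}
    for c, t in usable:
        by_conc.setdefault(float(c), []).append(float(t))
    if len(by_conc) < 3:
        raise FitError(
            f"need >= 3 standards at distinct concentrations, got {len(by_conc)}"
        )
    concs = sorted(by_conc)
    x = np.log10(concs)
    y = np.array([float(np.mean(by_conc[c])) for c in concs])
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope < 0 else math.nan
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency,
        n_standards=len(usable),
        valid=slope < 0,
    )


def quantify(
    ct_table: pd.DataFrame,
    curve: StandardCurve,
    detection_cutoff: float = DEFAULT_DETECTION_CUTOFF,
) -> tuple[list[QuantResult], dict]:
    """Convert unknown-well Cts to concentrations and summarize the cohort.

    ``ct_table`` needs ``sample_id`` and ``ct`` columns (NaN Ct =
    undetermined); replicate wells per sample are averaged on the Ct scale.
    A sample is detected iff its mean determined Ct is <= the cutoff.  The
    summary (median/mean/sd/min/max of concentration) covers detected
    samples only.
    """
    if not curve.valid:
        raise FitError("cannot quantify against an invalid standard curve")
    results: list[QuantResult] = []
    for sid, grp in ct_table.groupby("sample_id", sort=True):
        cts = [c for c in grp["ct"].tolist() if c is not None and math.isfinite(c)]
        if not cts:
            results.append(QuantResult(sid, None, None, False))
            continue
        mean_ct = float(np.mean(cts))
        if mean_ct > detection_cutoff:
            results.append(QuantResult(sid, mean_ct, None, False))
            continue
        results.append(QuantResult(sid, mean_ct, curve.concentration(mean_ct), True))

    detected = [r.concentration for r in results if r.detected]
    summary = {
        "n_samples": len(results),
        "n_detected": len(detected),
        "median": float(np.median(detected)) if detected else math.nan,
        "mean": float(np.mean(detected)) if detected else math.nan,
        "sd": float(np.std(detected, ddof=1)) if len(detected) > 1 else math.nan,
        "min": float(np.min(detected)) if detected else math.nan,
        "max": float(np.max(detected)) if detected else math.nan,
    }
    return results, summary
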