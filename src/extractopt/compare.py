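"""Goodness-of-prediction statistics for comparing regression models.

Four standard metrics between a predicted and an observed vector:

    R2   = 1 - sum (Yp - Ye)^2 / sum (Ym - Ye)^2     (Ym = mean observed)
    RMSE = sqrt(sum (Yp - Ye)^2 / n)
    AAD  = 100 * mean(|Yp - Ye| / Ye)                (percent)
    SEP  = 100 * RMSE / Ym                           (percent)

R2 and AAD are invariant under a common rescaling of both vectors;
RMSE scales linearly and SEP is scale-free. On in-sample least-squares
predictions R2 reduces to the ANOVA 1 - SSE/SST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComparisonMetrics", "comparison_metrics"]


@dataclass
class ComparisonMetrics:
    r2: float
    rmse: float
    aad_percent: float
    sep_percent: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "aad_percent": self.aad_percent,
            "sep_percent": self.sep_percent,
            "n": self.n,
        }


def comparison_metrics(predicted, observed) -> ComparisonMetrics:
    yp = np.asarray(predicted, dtype=float)
    ye = np.asarray(observed, dtype=float)
    if yp.shape != ye.shape or yp.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    n = len(ye)
    if n < 2:
        raise ValueError("need at least 2 points")
    ym = ye.mean()
    if np.isclose(ym, 0.0):
        raise ValueError("SEP undefined: mean observed value is zero")
    if np.any(ye == 0.0):
        raise ValueError("AAD undefined: an observed value is zero")
    sq = np.sum((yp - ye) ** 2)
    rmse = float(np.sqrt(sq / n))
    return ComparisonMetrics(
        r2=float(1.0 - sq / np.sum((ym - ye) ** 2)),
        rmse=rmse,
        aad_percent=float(100.0 * np.mean(np.abs(yp - ye) / ye)),
        sep_percent=float(100.0 * rmse / ym),
        n=n,
    )
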