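"""Cohen's d with a normal-approximation confidence interval.

The dyadic contrasts of the pipeline report d = (mean(x) - mean(y)) / s_p
with the (n-1)-weighted pooled SD and

    SE(d) = sqrt((n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2))).

Dyadic values are treated as independent for the CI, exactly as the
conventional effect-size packages do on such contrasts; the report carries a
nonindependence caveat instead of a correction.  Magnitude labels follow the
conventional 0.2 / 0.5 / 0.8 bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EffectSize", "cohens_d"]

NONINDEPENDENCE_CAVEAT = (
    "dyadic values share individuals and are not independent; the CI treats "
    "them as independent and is therefore approximate"
)


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    ci_level: float
    magnitude: str
    direction: str = "x_minus_y"
    caveat: str = NONINDEPENDENCE_CAVEAT

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n1": self.n1,
            "n2": self.n2,
            "ci_level": self.ci_level,
            "magnitude": self.magnitude,
            "direction": self.direction,
        }


def _magnitude(d: float) -> str:
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def cohens_d(x, y, ci_level: float = 0.95) -> EffectSize:
    """Standardized mean difference (x minus y) with pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per sample")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0.0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    d = float((x.mean() - y.mean()) / np.sqrt(s2))
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return EffectSize(
        d=d,
        ci_low=float(d - z * se),
        ci_high=float(d + z * se),
        n1=n1,
        n2=n2,
        ci_level=ci_level,
        magnitude=_magnitude(d),
    )
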