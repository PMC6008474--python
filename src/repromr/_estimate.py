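"""Shared result container for MR effect estimates."""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

Z95 = 1.96  # normal multiplier for 95% confidence intervals


@dataclass
class MrEstimate:
    """A causal-effect estimate on the log-odds-per-year scale.

    ``beta`` is the log odds ratio per year of exposure, ``or_`` its
    exponential; confidence limits use the normal approximation
    ``exp(beta ± 1.96·se)``.  Egger fits also carry the intercept term, whose
    deviation from zero indicates directional pleiotropy.
    """

    method: str
    beta: float
    se: float
    n_cases: int | None = None
    n_controls: int | None = None
    n_snps: int | None = None
    intercept: float | None = None
    intercept_se: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.beta - Z95 * self.se),
                math.exp(self.beta + Z95 * self.se))

    @property
    def pvalue(self) -> float:
        return 2.0 * float(stats.norm.sf(abs(self.beta / self.se)))

    @property
    def intercept_ci95(self) -> tuple[float, float] | None:
        if self.intercept is None or self.intercept_se is None:
            return None
        return (self.intercept - Z95 * self.intercept_se,
                self.intercept + Z95 * self.intercept_se)

    @property
    def intercept_pvalue(self) -> float | None:
        if self.intercept is None or self.intercept_se is None:
            return None
        return 2.0 * float(stats.norm.sf(abs(self.intercept / self.intercept_se)))

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        out = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.pvalue,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_snps": self.n_snps,
        }
        if self.intercept is not None:
            ilo, ihi = self.intercept_ci95
            out.update({
                "intercept": self.intercept,
                "intercept_se": self.intercept_se,
                "intercept_ci_low": ilo,
                "intercept_ci_high": ihi,
                "intercept_p": self.intercept_pvalue,
            })
        return out
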