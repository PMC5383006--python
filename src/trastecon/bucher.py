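"""Adjusted indirect comparison of hazard ratios via a common comparator.

Given published hazard ratios A-vs-C and B-vs-C, the indirect A-vs-B
estimate is HR_A/HR_B with log-scale standard errors added in quadrature:

    log HR_AB = log HR_AC - log HR_BC,   se^2 = se_AC^2 + se_BC^2.

Standard errors are back-calculated from 95% confidence intervals assuming
log-normality.  Inputs here are the trial teams' modelled hazard ratios
(supplied externally), not crude rate ratios recomputed from event counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "Z95",
    "HazardRatioEstimate",
    "se_from_ci",
    "indirect_hr",
    "indirect_table",
]

#: Exact 97.5% normal quantile; a ``z=1.96`` variant is accepted everywhere a
#: z-value can be passed, since sub-rounding matters when checking 2-d.p.
#: published output.
Z95 = 1.959963984540054


def se_from_ci(hr: float, ci_low: float, ci_high: float, z: float = Z95) -> float:
    """Log-scale standard error implied by a 95% CI of a hazard ratio."""
    if not (hr > 0 and ci_low > 0 and ci_high > 0):
        raise ValueError("hazard ratio and CI limits must be positive")
    if ci_low > ci_high:
        raise ValueError(f"ci_low {ci_low} exceeds ci_high {ci_high}")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


@dataclass(frozen=True)
class HazardRatioEstimate:
    label: str
    hr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.hr > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise ValueError(f"{self.label}: non-positive hazard ratio or CI limit")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(
                f"{self.label}: HR {self.hr} outside CI ({self.ci_low}, {self.ci_high})"
            )

    def se_log(self, z: float = Z95) -> float:
        return se_from_ci(self.hr, self.ci_low, self.ci_high, z=z)


def indirect_hr(
    a_vs_common: HazardRatioEstimate,
    b_vs_common: HazardRatioEstimate,
    label: str | None = None,
    z: float = Z95,
) -> HazardRatioEstimate:
    """Indirect A-vs-B hazard ratio through the shared comparator."""
    log_hr = math.log(a_vs_common.hr) - math.log(b_vs_common.hr)
    se = math.hypot(a_vs_common.se_log(z), b_vs_common.se_log(z))
    return HazardRatioEstimate(
        label=label or f"{a_vs_common.label} vs {b_vs_common.label}",
        hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - z * se),
        ci_high=math.exp(log_hr + z * se),
    )


def load_hr_table(path: str | Path) -> dict[str, HazardRatioEstimate]:
    """Read labelled HR estimates from CSV (label, outcome, hr, ci_low, ci_high)."""
    df = pd.read_csv(path)
    required = {"label", "outcome", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        key = f"{row['label']}:{row['outcome']}"
        out[key] = HazardRatioEstimate(
            label=key,
            hr=float(row["hr"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
        )
    return out


def indirect_table(
    estimates: dict[str, HazardRatioEstimate],
    comparisons: list[tuple[str, str, str, str]],
    z: float = Z95,
) -> pd.DataFrame:
    """Build an indirect-comparison table.

    ``comparisons`` rows are (comparison_name, outcome, key_a, key_b); keys
    index ``estimates``.  Output columns mirror a published HR table:
    comparison, outcome, hr, ci_low, ci_high.
    """
    rows = []
    for name, outcome, key_a, key_b in comparisons:
        res = indirect_hr(estimates[key_a], estimates[key_b], label=name, z=z)
        rows.append(
            {
                "comparison": name,
                "outcome": outcome,
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)
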