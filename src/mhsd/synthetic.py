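"""Synthetic historic series and packaged calibration anchors.

The regional registries behind the historic validation series (population
surveys, hospital and suicide registers) are not public, so this module
generates statistically similar stand-ins: smooth linear yearly trends for
2011-2017 with Poisson noise on count indicators and Gaussian noise on the
logit of the prevalence indicator.  Default trend levels are consistent with
a ~500k-person catchment whose decade forecasts sit near the published
anchors (roughly 1,400 self-harm hospitalizations and 115 suicide deaths a
year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationTargets, Target
from .model import HISTORIC_INDICATORS
from .reported import BASELINE_FORECAST

__all__ = [
    "SyntheticHistoric",
    "DEFAULT_TRENDS",
    "generate_historic",
    "generate_baseline_anchors",
    "write_historic_csv",
    "read_historic_csv",
]

YEARS = tuple(range(2011, 2018))

# (level at 2011, yearly slope); prevalence in percent, counts per year
DEFAULT_TRENDS: dict[str, tuple[float, float]] = {
    "distress_prevalence_pct": (20.9, -0.50),
    "psychiatric_hospitalizations": (1295.0, -25.0),
    "ed_presentations": (10790.0, -210.0),
    "self_harm_hospitalizations": (1605.0, -28.0),
    "suicide_deaths": (124.6, -2.2),
}

_COUNT_INDICATORS = tuple(k for k in DEFAULT_TRENDS if not k.endswith("_pct"))


@dataclass(frozen=True)
class SyntheticHistoric:
    """Yearly 2011-2017 indicator series plus the generating truth."""

    series: pd.DataFrame  # tidy: year, indicator, value
    trends: dict[str, tuple[float, float]]
    noise: bool
    prevalence_logit_sd: float
    seed: int

    def pivot(self) -> pd.DataFrame:
        return self.series.pivot(index="year", columns="indicator", values="value")


def generate_historic(
    trends: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    noise: bool = True,
    prevalence_logit_sd: float = 0.02,
) -> SyntheticHistoric:
    """Draw one synthetic historic dataset.

    Counts are Poisson around the linear trend; the prevalence indicator gets
    Gaussian noise on the logit scale.  ``noise=False`` returns the trends
    exactly.  Identical seeds give bit-identical output.
    """
    trends = dict(trends or DEFAULT_TRENDS)
    unknown = set(trends) - set(HISTORIC_INDICATORS)
    if unknown:
        raise KeyError(f"unknown indicators: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for indicator, (level, slope) in trends.items():
        for i, year in enumerate(YEARS):
            mean = level + slope * i
            if indicator in _COUNT_INDICATORS:
                if mean < 0:
                    raise ValueError(
                        f"{indicator}: trend implies negative expected count in {year}"
                    )
                value = float(rng.poisson(mean)) if noise else float(mean)
            else:
                p = mean / 100.0
                if not 0.0 < p < 1.0:
                    raise ValueError(f"{indicator}: prevalence {mean}% outside (0, 100)")
                if noise:
                    logit = np.log(p / (1 - p)) + rng.normal(0.0, prevalence_logit_sd)
                    value = 100.0 / (1.0 + np.exp(-logit))
                else:
                    value = float(mean)
            rows.append({"year": year, "indicator": indicator, "value": value})
    series = pd.DataFrame(rows)
    return SyntheticHistoric(series, trends, noise, prevalence_logit_sd, seed)


def generate_baseline_anchors(
    seed: int = 0,
    include_historic: bool = True,
    anchor_tolerance: float = 0.01,
    noise: bool = True,
) -> CalibrationTargets:
    """Package the published decade-forecast anchors as calibration targets.

    Anchors carry high weight and a 1% default tolerance; the generated
    historic series (optional) enters with low per-point weight and a 5%
    tolerance, mirroring its synthetic, noisy nature.
    """
    anchors = [
        Target("self_harm_hospitalizations",
               BASELINE_FORECAST["self_harm_hospitalizations"], 1.0, anchor_tolerance),
        Target("suicide_deaths",
               BASELINE_FORECAST["suicide_deaths"], 1.0, anchor_tolerance),
        Target("ed_presentations",
               BASELINE_FORECAST["ed_presentations"], 1.0, anchor_tolerance),
        Target("prevalence_2021_pct",
               BASELINE_FORECAST["prevalence_2021_pct"], 1.0, anchor_tolerance),
        Target("prevalence_2030_pct",
               BASELINE_FORECAST["prevalence_2030_pct"], 1.0, anchor_tolerance),
    ]
    historic = generate_historic(seed=seed, noise=noise).series if include_historic else None
    return CalibrationTargets(anchors=anchors, historic=historic)


def write_historic_csv(historic: SyntheticHistoric, path) -> None:
    """Write the tidy (year, indicator, value) schema."""
    historic.series.to_csv(path, index=False)


def read_historic_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"year", "indicator", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"historic CSV missing columns: {sorted(missing)}")
    return df
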