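"""Published decade forecasts for the modelled regional catchment.

These printed figures serve two roles: they are the calibration anchors the
business-as-usual pre-pandemic run is fitted to, and they back arithmetic
consistency checks (e.g. that the published percentage increases under
post-pandemic conditions follow from the published cumulative counts).
All counts are cumulative over the 2021-2030 reporting window; prevalence is
the high/very-high psychological-distress share in percent.
"""

from __future__ import annotations

__all__ = ["BASELINE_FORECAST", "POST_COVID_FORECAST", "POST_COVID_PRINTED_INCREASES"]

# business as usual, pre-pandemic conditions
BASELINE_FORECAST: dict[str, float] = {
    "self_harm_hospitalizations": 12_274.0,
    "suicide_deaths": 953.0,
    "ed_presentations": 81_263.0,
    "prevalence_2021_pct": 17.60,
    "prevalence_2030_pct": 15.60,
}

# business as usual, post-pandemic conditions
POST_COVID_FORECAST: dict[str, float] = {
    "self_harm_hospitalizations": 14_973.0,
    "suicide_deaths": 1_176.0,
    "ed_presentations": 98_591.0,
    "prevalence_2030_pct": 18.3,
}

# printed rounded increases of the post-pandemic run over baseline
POST_COVID_PRINTED_INCREASES: dict[str, float] = {
    "self_harm_hospitalizations_pct": 22.0,
    "suicide_deaths_pct": 23.0,
    "ed_presentations_pct": 21.0,
    "prevalence_2030_pp": 2.7,
}
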