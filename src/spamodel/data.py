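"""Published pooled two-wave correlation sets used as worked examples.

Each entry holds the six meta-analytically pooled correlations between a
pair of constructs measured at two occasions, together with the association
sign used when fitting the SPAM (negative for construct pairs such as
self-esteem and depression) and the simulation size conventionally used for
the evaluation pipeline (10,000).  The loneliness / social-anxiety set is
available at both the 3-decimal precision of its source meta-analysis and
the 2-decimal precision of the cross-pair summary table.
"""

from __future__ import annotations

from .core_effects import CorrelationSet

__all__ = ["POOLED_CORRELATIONS", "POOLED_SIGNS", "EVALUATION_N", "LON_SA_POOLED_CI"]

EVALUATION_N = 10_000

#: order: r_x1x2, r_x1y1, r_x1y2, r_x2y1, r_x2y2, r_y1y2
POOLED_CORRELATIONS: dict[str, CorrelationSet] = {
    "self_esteem-depression": CorrelationSet(0.70, -0.51, -0.39, -0.41, -0.53, 0.53),
    "self_esteem-social_relations": CorrelationSet(0.57, 0.28, 0.26, 0.24, 0.34, 0.60),
    "social_support-ptsd": CorrelationSet(0.55, -0.26, -0.24, -0.22, -0.26, 0.63),
    "self_concept-achievement": CorrelationSet(0.54, 0.37, 0.34, 0.34, 0.41, 0.70),
    "loneliness-social_anxiety": CorrelationSet(
        0.603, 0.493, 0.379, 0.351, 0.552, 0.568
    ),
    "loneliness-social_anxiety_2dec": CorrelationSet(0.60, 0.49, 0.38, 0.35, 0.55, 0.57),
}

POOLED_SIGNS: dict[str, int] = {
    "self_esteem-depression": -1,
    "self_esteem-social_relations": +1,
    "social_support-ptsd": -1,
    "self_concept-achievement": +1,
    "loneliness-social_anxiety": +1,
    "loneliness-social_anxiety_2dec": +1,
}

#: meta-analytic 95% CIs of the adjusted lagged effects for the loneliness /
#: social-anxiety pair: forward (Lon1 -> SA2 . SA1) and the reverse direction
#: (SA1 -> Lon2 . Lon1)
LON_SA_POOLED_CI: dict[str, tuple[float, float]] = {
    "beta_lag_fwd_xy": (0.047, 0.197),
    "beta_lag_fwd_yx": (0.041, 0.146),
}
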