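"""Worked-example inputs: a published-style single-pollutant summary table.

``NM_SINGLE_POLLUTANT_SUMMARY`` carries the per-IQR effect estimates, 95%
confidence bounds, p-values and exposure IQRs of a small-area analysis of
ten PM2.5 metal components and low birth weight in New Mexico (2012-2016
birth cohorts).  It is used by the examples and acceptance checks to
exercise the multiple-comparison and confidence-interval arithmetic on
realistic printed numbers; it is an *input* table, not something this
package computes.

The mercury p-value was reported only as "<0.001"; the upper bound is
stored, which does not affect any significance call at FDR 0.05.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["NM_SINGLE_POLLUTANT_SUMMARY"]

NM_SINGLE_POLLUTANT_SUMMARY = pd.DataFrame(
    [
        # chemical, effect %/IQR, ci_low, ci_high, p, IQR (x 1e-3)
        ("mercury",   0.43,  0.18, 0.68, 0.001, 0.307),
        ("nickel",    0.35,  0.08, 0.62, 0.011, 0.731),
        ("chromium",  0.63,  0.15, 1.12, 0.011, 1.729),
        ("lead",      0.32,  0.05, 0.60, 0.022, 0.961),
        ("copper",    0.50,  0.07, 0.93, 0.025, 1.390),
        ("zinc",      0.36, -0.06, 0.78, 0.150, 1.673),
        ("cobalt",    0.24, -0.20, 0.68, 0.374, 0.035),
        ("vanadium",  0.24, -0.21, 0.69, 0.388, 0.238),
        ("manganese", 0.12, -0.20, 0.44, 0.530, 0.867),
        ("barium",    0.12, -0.25, 0.49, 0.592, 3.355),
    ],
    columns=["chemical", "effect_pct_per_iqr", "ci_low", "ci_high", "p", "iqr_e3"],
)
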