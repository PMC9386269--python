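"""Published reference values for consistency checks.

Cohort summary statistics from a published 25-patient essential-tremor
surgical cohort measured with this exam protocol (wrist accelerometry of the
dominant arm; mean ± SD per position), plus the matched control group's
loaded-action total power.  These are *inputs* for arithmetic consistency
checks (fold ratios between positions, patient/control contrast); the
package never fits to them.
"""

from __future__ import annotations

import pandas as pd

#: Per-position mean and SD: peak frequency (Hz), peak power (m²/s⁴/Hz),
#: total power in the 1–20 Hz band (m²/s⁴).
_COHORT_ROWS = [
    # position, pf_mean, pf_sd, pp_mean, pp_sd, tp_mean, tp_sd
    ("rest", 4.78, 3.03, 0.02, 0.05, 0.11, 0.31),
    ("posture", 4.78, 1.23, 1.58, 4.33, 1.08, 2.62),
    ("bimanual", 4.89, 1.43, 1.44, 3.47, 0.96, 2.18),
    ("wing", 4.58, 1.35, 8.37, 18.7, 1.90, 3.94),
    ("action", 3.81, 2.02, 1.33, 1.46, 1.88, 3.67),
]

#: Control group (n = 6, no clinically detectable tremor): total power in the
#: loaded-action condition, mean ± SD, m²/s⁴.
CONTROL_ACTION_TOTAL_POWER = (0.09, 0.03)


def published_cohort_summary() -> pd.DataFrame:
    """Reference per-position summary table (mean ± SD), indexed by position."""
    df = pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "position",
            "peak_frequency_hz_mean",
            "peak_frequency_hz_sd",
            "peak_power_mean",
            "peak_power_sd",
            "total_power_mean",
            "total_power_sd",
        ],
    )
    return df.set_index("position")
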