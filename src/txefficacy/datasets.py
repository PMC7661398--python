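"""Small built-in example datasets."""

from __future__ import annotations

import pandas as pd

__all__ = ["example_dose_mortality"]

# dose, cells counted, cells dead, expression of two apoptosis-related genes
_DOSE_ROWS = [
    (0, 3000, 100, 10, 23),
    (50, 2400, 130, 1500, 200),
    (100, 3100, 350, 2000, 500),
    (150, 3000, 500, 2500, 750),
    (200, 2000, 600, 2400, 950),
    (250, 3000, 1500, 1600, 1000),
    (300, 2600, 1700, 1500, 1500),
    (400, 2800, 2450, 200, 1900),
    (500, 2800, 2600, 100, 2000),
]


def example_dose_mortality() -> pd.DataFrame:
    """Illustrative dose-dependent cancer-cell mortality table.

    Nine doses of a disruptive drug with the number of counted and dead
    cells per dose, plus expression of two apoptosis-related genes: *AG2*
    rises monotonically with dose (mechanistically coupled to the drug's
    action) while *AG1* varies without relation to mortality.  The grouped
    binomial logistic fit of mortality on dose gives intercept -3.3827 and
    slope 0.0130; the covariate screen on the propensity scale selects the
    AG2-only model.  Used throughout the documentation and tests.
    """
    return pd.DataFrame(_DOSE_ROWS, columns=["Dose", "N_Cell", "N_Dead", "AG1", "AG2"])
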