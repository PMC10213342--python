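"""Published reference values for the GSE1297 four-gene panel analysis.

These constants are the reported eigenvector tables and leading eigenvalue
fractions of the uncentered Gram analysis of the BAG2/HSC70/STUB1/MAPT panel
on the GSE1297 hippocampus cohort (control and severe-dementia groups).
They serve as fixed external checkpoints: the leading columns of the two
tables point in opposite directions (dot product ≈ -0.944), the reported
sign reversal between health and severe disease.

The gene order of the table rows was reported ambiguously (panel listed both
as BAG2, HSC70, STUB1, MAPT and as BAG2, STUB1, HSC70, MAPT); row order here
follows the tables as printed and comparisons should treat the order as
configurable.  Columns are ordered by descending eigenvalue (leading first).
"""

from __future__ import annotations

import numpy as np

from .spectral import SpectralResult

__all__ = [
    "CONTROL_EIGENVECTORS",
    "SEVERE_EIGENVECTORS",
    "CONTROL_LEADING_FRACTION",
    "SEVERE_LEADING_FRACTION",
    "reference_spectral_results",
]

#: Reported eigenvector table, control group (columns = eigenvectors,
#: leading first; rows = panel genes in reported order).
CONTROL_EIGENVECTORS = np.array(
    [
        [0.1603998, -0.86496189, 0.43869841, 0.18345718],
        [-0.57748234, 0.26959268, 0.49608849, 0.58968648],
        [0.50539008, 0.39466183, 0.71249652, -0.28490634],
        [0.62077928, 0.15297958, -0.23192376, 0.73310415],
    ]
)

#: Reported eigenvector table, severe group.
SEVERE_EIGENVECTORS = np.array(
    [
        [-0.47158612, 0.4301255, 0.75178616, 0.16557825],
        [0.47986946, -0.34906073, 0.61507755, -0.51919314],
        [-0.49541599, 0.15885334, -0.2199049, -0.82520934],
        [-0.54944958, -0.81726022, 0.09021649, 0.14849873],
    ]
)

#: Reported leading eigenvalue fractions (percentage-transformed).
CONTROL_LEADING_FRACTION = 0.56
SEVERE_LEADING_FRACTION = 0.79


def reference_spectral_results() -> tuple[SpectralResult, SpectralResult]:
    """The two reported tables wrapped as :class:`SpectralResult` objects
    (printed orientation preserved), ready for alignment comparison."""
    con = SpectralResult.from_table(
        CONTROL_EIGENVECTORS,
        fractions=[CONTROL_LEADING_FRACTION, np.nan, np.nan, np.nan],
        group="control",
    )
    sev = SpectralResult.from_table(
        SEVERE_EIGENVECTORS,
        fractions=[SEVERE_LEADING_FRACTION, np.nan, np.nan, np.nan],
        group="severe",
    )
    return con, sev
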