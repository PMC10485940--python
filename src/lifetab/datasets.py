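"""Small bundled reference datasets.

``reported_birth_estimates`` carries the published at-birth LE and HALE-NHIS
point estimates (years) for Korean registered disabled people, 2014-2018, by
sex and severity group, with the non-disabled population as reference. These
are reporting-layer numbers (2-decimal precision) used as the worked example
for the between-group difference report; they are inputs, not outputs, of this
package.
"""

from __future__ import annotations

import pandas as pd

_REPORTED_BIRTH = [
    # group_id, sex, ex, hale_nhis  (years at birth / first age)
    ("non_disabled", "male", 81.32, 73.32),
    ("disabled_all", "male", 68.54, 58.98),
    ("disabled_mild", "male", 73.87, 65.43),
    ("disabled_severe", "male", 61.53, 50.48),
    ("non_disabled", "female", 87.38, 75.58),
    ("disabled_all", "female", 71.43, 59.24),
    ("disabled_mild", "female", 78.25, 67.51),
    ("disabled_severe", "female", 62.41, 49.72),
]


def reported_birth_estimates() -> pd.DataFrame:
    """Published at-birth LE / HALE-NHIS (years) by group and sex, Korea 2014-2018."""
    frame = pd.DataFrame(
        _REPORTED_BIRTH, columns=["group_id", "sex", "ex", "hale_NHIS"]
    )
    frame["age"] = 0
    return frame[["group_id", "sex", "age", "ex", "hale_NHIS"]]
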