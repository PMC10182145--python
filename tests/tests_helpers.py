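"""Shared helpers for the test suite."""

import pandas as pd

from survgwas.simulate import with_encoded


def encode_full(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort table joined with its encoded 0/1 design columns."""
    return with_encoded(cohort)
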