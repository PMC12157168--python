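"""Small bundled reference tables."""

from importlib import resources

import pandas as pd

__all__ = ["tg_holdout_validation"]


def tg_holdout_validation() -> pd.DataFrame:
    """Published holdout comparison for a freeze-dried Tg' screen.

    Twenty formulations with experimentally determined Tg' (°C, by DSC) and
    the values predicted for them by a gradient-boosted and a linear
    surrogate that never saw them during training.  Used as a worked example
    for prediction-error summaries: the signed delta of a row is
    predicted − experimental.
    """
    with resources.files("formubo.data").joinpath("tg_holdout_validation.csv").open() as fh:
        return pd.read_csv(fh)
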