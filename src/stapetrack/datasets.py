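"""Bundled count data for the statistics layer.

The per-patient applied/detected counts for the four raters (software,
experienced surgeon, intermediate and unexperienced observer) ship as a
small CSV so the rater-comparison statistics are runnable and testable
without any video input.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_rater_counts() -> pd.DataFrame:
    """Per-patient applied stimuli and detected-reflex counts per rater."""
    ref = resources.files("stapetrack.data") / "table1_counts.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
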