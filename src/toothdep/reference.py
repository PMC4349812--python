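"""Published reference tables shipped with the package.

Currently one table: the annual summary of observed longline sets
interacting with fur seals, sperm whales and orcas in the South Georgia
toothfish fishery, 1997-2012 (counts of interacting sets and of animals,
percentage of observed sets with an interaction, and animals per observed
set, all as printed in the published record).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_annual_interaction_table"]


def load_annual_interaction_table() -> pd.DataFrame:
    """The 16 yearly rows (1997-2012) of the published annual interaction
    summary for the South Georgia longline fishery, one row per year."""
    ref = resources.files("toothdep").joinpath("data/annual_interactions_sg.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
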