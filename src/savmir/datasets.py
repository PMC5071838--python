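"""Bundled datasets.

``winged_wingless_table`` is the published differential-expression table
from a winged-vs-wingless grain-aphid small-RNA comparison: per-miRNA
normalized read counts in the wingless (WL) and winged (W) libraries, the
reported p-value, and the printed fold-change / log2 fold-change columns.
It serves as the reference input for validating the fold-change arithmetic
and significance-calling logic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def winged_wingless_table() -> pd.DataFrame:
    """The 32-row published WL-vs-W normalized-count table."""
    with resources.files("savmir.data").joinpath("winged_wingless_de.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
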