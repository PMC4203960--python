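"""Packaged reference data: cross-species promoter STR motif counts.

A small table of perfect-STR motif-family counts in 2-kb promoter sets
of five amniotes (chicken, duck, zebra finch, mouse, human) plus the
whole chicken genome, used as the default motif-frequency distribution
for the synthetic generator and as worked input for the frequency-table
comparison statistics.  Genome-wide counts come from an external survey
with its own scanning parameters and are treated as a user-supplied
table only, never recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import FrequencyTable

#: promoter set sizes behind the packaged counts (sequences per species)
PROMOTER_SET_SIZES = {
    "chicken_promoter": 13754,
    "duck_promoter": 13583,
    "zebra_finch_promoter": 15633,
    "mouse_promoter": 27046,
    "human_promoter": 38687,
}


def _data_path():
    return resources.files("promoscan") / "data" / "str_motif_reference.tsv"


def load_reference_frame() -> "pd.DataFrame":
    with resources.as_file(_data_path()) as path:
        return pd.read_csv(path, sep="\t")


def reference_table(column: str = "chicken_promoter") -> FrequencyTable:
    """One species' counts as a FrequencyTable (missing entries dropped)."""
    df = load_reference_frame()
    if column not in df.columns:
        raise KeyError(f"no reference column {column!r}")
    sub = df[["motif", column]].dropna()
    return FrequencyTable.from_counts(
        dict(zip(sub["motif"], sub[column].astype(int))),
        n_promoters=PROMOTER_SET_SIZES.get(column),
    )


def chicken_motif_distribution() -> dict[str, float]:
    """Canonical motif -> probability, normalized from the chicken counts."""
    tab = reference_table("chicken_promoter")
    total = tab.total
    return {m: int(c) / total for m, c in tab.counts.items()}
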