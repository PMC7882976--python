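"""Packaged reference tables from the published rat-scavenging study.

Three small TSVs are shipped with the package:

* ``table1`` — diet-assay contingency counts: sample type x bird-in-diet
  status for the 51-rat cohort.
* ``table2`` — decayed-tissue biomarker ASVs matched into rat gut
  microbiomes: biomarker id, first detection day, matched rat ASV id,
  taxonomy, percent similarity and the number of rats carrying the match.
* ``table3`` — per-primer Sanger species assignments for the consumed-bird
  samples, with the carrion flag for rats whose gut carried informative
  decay biomarkers.

These are data transcriptions, used as inputs for the bookkeeping and
summary computations and as ground truth in the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_paper_fixture"]

_FIXTURES = {"table1", "table2", "table3"}


def load_paper_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a DataFrame."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    ref = resources.files("scavtrace") / "tables" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if name == "table1":
        assert int(df["n"].sum()) == 51, "cohort size must total 51"
    if name == "table3":
        df["carrion_flag"] = df["carrion_flag"].astype(bool)
    return df
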