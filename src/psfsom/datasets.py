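"""Bundled reference tables from the lung-disease pathway activity study."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def load_lung_cohort_table() -> pd.DataFrame:
    """The published cohort table: 21 lung-disease groups plus healthy control.

    Columns: ``n``, ``group``, ``name``, ``abbreviation``, ``n_samples``.
    """
    ref = resources.files("psfsom").joinpath("data/lung_cohort_table.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_lung_study_summary() -> dict:
    """Published collection scale: pathway counts and total sink count."""
    ref = resources.files("psfsom").joinpath("data/lung_study_summary.json")
    return json.loads(ref.read_text())
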