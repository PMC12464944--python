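"""Bundled reference tables.

``load_glioma_demographics`` returns the demographic table of a reference
48-patient left-hemisphere glioma cohort (sex, histological diagnosis,
IDH genotype, WHO grade group, age, MNI-space lesion volume in voxels,
number of resting-state runs).  It is used by examples and tests, e.g.
to compare lesion volumes between IDH genotypes with the rank-sum test.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_glioma_demographics"]


def load_glioma_demographics() -> pd.DataFrame:
    with resources.files("contraconn.data").joinpath(
            "glioma_cohort_demographics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
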