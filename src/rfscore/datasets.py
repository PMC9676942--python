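"""Packaged reference data.

The package ships the class-conditional frequency counts of the published
412-patient retrospective derivation cohort (197 central-LNM-positive, 215
negative) — the count data from which the risk-factor score table was
originally derived. Patient-level records of that cohort were never
published; cohorts with individual records are produced synthetically (see
:mod:`rfscore.simulate`).
"""

from __future__ import annotations

import json
from importlib import resources

from .frequency import FrequencyTable

__all__ = ["load_retrospective_counts"]


def load_retrospective_counts() -> FrequencyTable:
    """Frequency table of the retrospective derivation cohort (n = 412)."""
    ref = resources.files("rfscore.data").joinpath("retrospective_counts.json")
    with ref.open() as fh:
        return FrequencyTable.from_dict(json.load(fh))
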