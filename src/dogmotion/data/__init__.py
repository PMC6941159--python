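"""Bundled reference tables from the published clinic cohort study.

``reference_cohort_demographics.csv`` is the demographic roster of the 24
consultation subjects (12 cases with ADHD-like behavior, 12 controls);
``reference_group_summary.csv`` carries the published per-group means and
standard deviations of the 12 movement parameters.  Both are inputs for
worked examples and cross-checks, not outputs of this package.
"""

from importlib import resources

import pandas as pd

from ..trajectory import SubjectMeta

__all__ = ["load_reference_demographics", "load_reference_group_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_demographics() -> list[SubjectMeta]:
    """The 24-subject demographic roster as SubjectMeta records."""
    df = _read("reference_cohort_demographics.csv")
    return [
        SubjectMeta(
            subject_id=r.subject_id,
            group=r.group,
            sex=r.sex,
            age=float(r.age),
            weight=float(r.weight),
            neutered=r.neutered == "y",
        )
        for r in df.itertuples()
    ]


def load_reference_group_summary() -> pd.DataFrame:
    """Published per-group mean/SD of each movement parameter."""
    return _read("reference_group_summary.csv")
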