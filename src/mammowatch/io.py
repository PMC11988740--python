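"""Tabular I/O: headered UTF-8 CSV readers/writers for the data contracts.

studies.csv  — study_id, month, score_left, score_right, study_score,
               n_images_analyzed, output_present, true_label, birads
reviews.csv  — study_id, month, category, localization, interpretation
feedback.csv — user_id, study_id, response
"""

from __future__ import annotations

import pandas as pd

from .simulate import STUDY_COLUMNS

__all__ = [
    "read_studies",
    "write_studies",
    "read_reviews",
    "write_reviews",
    "read_feedback",
    "write_feedback",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.map(lambda v: _BOOL_MAP[str(v).strip().lower()])


def read_studies(path) -> pd.DataFrame:
    """Read a studies table, validating the header contract."""
    df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"studies table is missing columns: {sorted(missing)}")
    df["output_present"] = _coerce_bool(df["output_present"])
    return df


def write_studies(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_reviews(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("study_id", "month", "category"):
        if col not in df.columns:
            raise ValueError(f"reviews table is missing column: {col}")
    return df


def write_reviews(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feedback(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("user_id", "study_id", "response"):
        if col not in df.columns:
            raise ValueError(f"feedback table is missing column: {col}")
    return df


def write_feedback(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
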