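"""Bundled per-patient evaluation tables from the ten-patient reader study.

Four CSV fixtures ship with the package:

* ``table2`` — unfiltered MAPE/NRMSE for 30-, 15- and 10-view images,
* ``table3`` / ``table4`` — the full metric suite (MAPE both ROIs, NRMSE,
  PSNR, NB) for 30- and 15-view images under no filter / Gaussian / NLM,
* ``table5`` — two physicians' 5-point Likert quality scores for the
  30-view Gaussian vs NLM images.

Loaders return tidy DataFrames in the package's unified metrics schema so
the aggregation functions apply to fixtures and simulated runs alike.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import METRICS_COLUMNS


def _read(name: str) -> pd.DataFrame:
    with resources.files("sparsespect.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_unfiltered_view_study() -> pd.DataFrame:
    """Unfiltered 30/15/10-view MAPE and NRMSE per patient (metrics schema)."""
    df = _read("table2.csv")
    df["filter"] = "none"
    df["psnr"] = float("nan")
    df["nb_roi1"] = float("nan")
    return df[METRICS_COLUMNS]


def load_filter_study(n_views: int) -> pd.DataFrame:
    """Full metric suite per patient and filter at 30 or 15 views."""
    if n_views == 30:
        df = _read("table3.csv")
    elif n_views == 15:
        df = _read("table4.csv")
    else:
        raise ValueError("filter-study tables exist for 30 and 15 views only")
    df["n_views"] = n_views
    return df[METRICS_COLUMNS]


def load_reader_scores() -> pd.DataFrame:
    """Physician Likert scores (case_id, filter, rater, score) at 30 views."""
    return _read("table5.csv")
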