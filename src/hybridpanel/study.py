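"""Recomputation of the published panel's headline numbers from its
supplementary tables.

The published raw data (growth parameters per strain x medium x replicate,
and the hybrid table with parental ploidies) is distributed as supplementary
material and is not bundled here. To run these recomputations, convert the
workbook sheets to two TSVs in a directory (default ``data/supplementary``,
overridable via the ``HYBRIDPANEL_STUDY_DATA`` environment variable):

``study_growth.tsv``
    columns: strain_id, medium, replicate, auc, mu — one row per well.
``study_hybrids.tsv``
    columns: hybrid_id, parent_a, parent_b, ploidy_parent_a,
    ploidy_parent_b, ploidy_measured — one row per hybrid.

Strain ids must be consistent between the two files (hybrids reference the
mating-competent parent strains they were crossed from).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .heterosis import best_parent_heterosis, mid_parent_heterosis

__all__ = ["study_data_dir", "load_study_tables", "recompute_study_numbers"]


def study_data_dir() -> Path:
    return Path(os.environ.get("HYBRIDPANEL_STUDY_DATA", "data/supplementary"))


def load_study_tables(directory: Path | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    directory = study_data_dir() if directory is None else Path(directory)
    growth_path = directory / "study_growth.tsv"
    hybrids_path = directory / "study_hybrids.tsv"
    for p in (growth_path, hybrids_path):
        if not p.exists():
            raise FileNotFoundError(
                f"supplementary table {p} not found; see hybridpanel.study docstring "
                "for the expected layout"
            )
    return (
        pd.read_csv(growth_path, sep="\t"),
        pd.read_csv(hybrids_path, sep="\t"),
    )


def recompute_study_numbers(
    growth: pd.DataFrame, hybrids: pd.DataFrame
) -> dict[str, float]:
    """Heterosis counts, ploidy agreement and replicate CV from study tables.

    Returns keys: bph_positive_auc, mph_positive_auc, bph_positive_mu,
    ploidy_r, mean_ploidy, median_cv_auc_pct.
    """
    means = growth.groupby(["strain_id", "medium"])[["auc", "mu"]].mean()

    counts = {"bph_positive_auc": 0, "mph_positive_auc": 0, "bph_positive_mu": 0}
    for hyb in hybrids.itertuples():
        for medium in growth["medium"].unique():
            try:
                h = means.loc[(hyb.hybrid_id, medium)]
                p1 = means.loc[(hyb.parent_a, medium)]
                p2 = means.loc[(hyb.parent_b, medium)]
            except KeyError:
                continue
            for trait, bph_key in (("auc", "bph_positive_auc"), ("mu", "bph_positive_mu")):
                if p1[trait] > 0 and p2[trait] > 0:
                    if best_parent_heterosis(h[trait], p1[trait], p2[trait]) > 0:
                        counts[bph_key] += 1
                    if trait == "auc" and mid_parent_heterosis(h[trait], p1[trait], p2[trait]) > 0:
                        counts["mph_positive_auc"] += 1

    predicted = hybrids["ploidy_parent_a"] + hybrids["ploidy_parent_b"]
    measured = hybrids["ploidy_measured"]
    ok = predicted.notna() & measured.notna()
    r = (
        float(np.corrcoef(predicted[ok], measured[ok])[0, 1])
        if ok.sum() >= 2
        else float("nan")
    )

    cvs = (
        growth.groupby(["strain_id", "medium"])["auc"]
        .agg(lambda v: v.std(ddof=1) / v.mean() if len(v) > 1 and v.mean() != 0 else np.nan)
        .dropna()
    )
    return {
        **{k: float(v) for k, v in counts.items()},
        "ploidy_r": r,
        "mean_ploidy": float(measured[ok].mean()),
        "median_cv_auc_pct": float(cvs.median() * 100.0),
        "n_hybrids": int(len(hybrids)),
        "n_wells": int(len(growth)),
    }
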