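"""Mid-parent and best-parent heterosis statistics over a hybrid panel.

MPH compares the hybrid trait value to the mean of its two parents,
BPH to the better parent:

    MPH = (H1 - (P1 + P2) / 2) / ((P1 + P2) / 2)
    BPH = (H1 - max(P1, P2)) / max(P1, P2)

Records whose parents have non-positive trait values are flagged and
excluded from frequency tallies rather than clamped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "mid_parent_heterosis",
    "best_parent_heterosis",
    "heterosis_table",
    "positive_counts",
    "parent_representation",
]

log = logging.getLogger(__name__)


def mid_parent_heterosis(h1: float, p1: float, p2: float) -> float:
    """Relative gain of the hybrid over the mid-parent value."""
    mid = (p1 + p2) / 2.0
    if mid <= 0:
        raise ValueError(f"non-positive mid-parent value {mid}")
    return (h1 - mid) / mid


def best_parent_heterosis(h1: float, p1: float, p2: float) -> float:
    """Relative gain of the hybrid over its better parent."""
    best = max(p1, p2)
    if best <= 0:
        raise ValueError(f"non-positive best-parent value {best}")
    return (h1 - best) / best


def heterosis_table(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    trait: str = "auc",
    parent_reference: str = "mating_competent",
) -> pd.DataFrame:
    """One heterosis record per hybrid x medium for the chosen trait.

    Parameters
    ----------
    summaries : DataFrame
        Per strain x medium replicate summary with ``mean_auc``/``mean_mu``.
    metadata : DataFrame
        Strain table; hybrid rows reference their two mating-competent
        parents via ``parent_a``/``parent_b``.
    trait : {"auc", "mu"}
    parent_reference : {"mating_competent", "wildtype"}
        Which parental measurements P1/P2 refer to. "wildtype" maps each
        mating-competent parent to the wild-type strain it derives from.

    Hybrids with a missing parent summary are skipped with a warning.
    Records with a non-positive parent value keep NaN statistics and an
    ``excluded`` flag.
    """
    col = {"auc": "mean_auc", "mu": "mean_mu"}.get(trait)
    if col is None:
        raise ValueError(f"unknown trait {trait!r}")
    if parent_reference not in ("mating_competent", "wildtype"):
        raise ValueError(f"unknown parent reference {parent_reference!r}")

    values = summaries.set_index(["strain_id", "medium"])[col]
    wt_of = metadata.set_index("strain_id")["parent_a"].to_dict()
    hybrids = metadata[metadata["role"] == "hybrid"]
    media = sorted(summaries["medium"].unique())

    rows: list[dict] = []
    n_skipped = 0
    for hyb in hybrids.itertuples():
        pa, pb = hyb.parent_a, hyb.parent_b
        if parent_reference == "wildtype":
            pa, pb = wt_of.get(pa, pa), wt_of.get(pb, pb)
        for medium in media:
            try:
                h1 = float(values[(hyb.strain_id, medium)])
                p1 = float(values[(pa, medium)])
                p2 = float(values[(pb, medium)])
            except KeyError as exc:
                n_skipped += 1
                log.warning(
                    "hybrid %s in %s: missing summary for %s — skipped",
                    hyb.strain_id, medium, exc,
                )
                continue
            excluded = p1 <= 0 or p2 <= 0
            rows.append(
                dict(
                    hybrid_id=hyb.strain_id,
                    parent_a=hyb.parent_a,
                    parent_b=hyb.parent_b,
                    medium=medium,
                    trait=trait,
                    h1=h1,
                    p1=p1,
                    p2=p2,
                    mph=np.nan if excluded else mid_parent_heterosis(h1, p1, p2),
                    bph=np.nan if excluded else best_parent_heterosis(h1, p1, p2),
                    excluded=excluded,
                )
            )
    if n_skipped:
        log.warning("%d hybrid x medium records skipped (missing parents)", n_skipped)
    return pd.DataFrame(rows)


def positive_counts(records: pd.DataFrame) -> dict[str, int]:
    """Counts of strictly positive MPH/BPH records (excluded rows ignored)."""
    ok = records[~records["excluded"]]
    return {
        "n_records": int(len(records)),
        "n_excluded": int(records["excluded"].sum()),
        "mph_positive": int((ok["mph"] > 0).sum()),
        "bph_positive": int((ok["bph"] > 0).sum()),
    }


def parent_representation(
    records: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Parent-strain frequencies among BPH-positive vs all heterosis records.

    Each record contributes two parent attributions (mapped from the
    mating-competent strains to the wild-type parents they derive from);
    frequencies are normalized within each tally so they sum to 1.
    """
    if records.empty:
        raise ValueError("empty heterosis record set")
    wt_rows = metadata.set_index("strain_id")
    mc_mask = wt_rows["role"] == "mating_competent"
    wt_of = wt_rows.loc[mc_mask, "parent_a"].to_dict()

    def tally(df: pd.DataFrame) -> pd.Series:
        parents = []
        for pa, pb in zip(df["parent_a"], df["parent_b"]):
            if pa not in wt_of and pa not in wt_rows.index:
                raise KeyError(f"no wild-type mapping for parent {pa}")
            parents.append(wt_of.get(pa, pa))
            parents.append(wt_of.get(pb, pb))
        return pd.Series(parents).value_counts(normalize=True)

    ok = records[~records["excluded"]]
    overall = tally(ok)
    positive = ok[ok["bph"] > 0]
    pos = tally(positive) if len(positive) else pd.Series(dtype=float)

    out = pd.DataFrame(
        {
            "parent_id": overall.index,
            "freq_overall": overall.to_numpy(),
            "freq_in_positive": [float(pos.get(p, 0.0)) for p in overall.index],
        }
    )
    out["excess"] = out["freq_in_positive"] - out["freq_overall"]
    return out.sort_values("parent_id", ignore_index=True)
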