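"""Relative quantification of qPCR CT data by the comparative-threshold
(2^-ddCt) method, with a two-sample t-test between conditions.

Technical replicates are averaged first; dCt = CT(target) - CT(reference)
per biological replicate; ddCt is taken relative to the mean dCt of the
calibrator condition; RQ = 2 ** -ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["target", "condition", "bio_rep", "tech_rep", "ct"]


def _validate(ct: pd.DataFrame, reference: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise ValueError("CT values must be finite and > 0")
    if reference not in set(ct["target"]):
        raise ValueError(f"reference {reference!r} absent from CT table")
    return ct


def ddct(ct: pd.DataFrame, reference: str = "U6",
         calibrator: str = "wingless") -> pd.DataFrame:
    """Per-(target, condition, bio_rep) relative quantities.

    Parameters
    ----------
    ct : DataFrame
        Long-format CT table with columns target, condition, bio_rep,
        tech_rep, ct.
    reference : str
        Endogenous reference assay id (subtracted per biological replicate).
    calibrator : str
        Condition the ddCt is taken relative to.

    Returns
    -------
    DataFrame
        Columns target, condition, bio_rep, dct, ddct, rq.
    """
    ct = _validate(ct, reference)
    if calibrator not in set(ct["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} absent from CT table")
    # technical replicates first
    mean_ct = (ct.groupby(["target", "condition", "bio_rep"], sort=True)["ct"]
                 .mean().reset_index())
    ref = mean_ct[mean_ct["target"] == reference].rename(columns={"ct": "ref_ct"})
    tgt = mean_ct[mean_ct["target"] != reference]
    merged = tgt.merge(ref[["condition", "bio_rep", "ref_ct"]],
                       on=["condition", "bio_rep"], how="left")
    if merged["ref_ct"].isna().any():
        gaps = merged.loc[merged["ref_ct"].isna(), ["target", "condition", "bio_rep"]]
        raise ValueError(
            "missing reference CT for: "
            + "; ".join(f"{r.target}/{r.condition}/bio_rep={r.bio_rep}"
                        for r in gaps.itertuples()))
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    calib = (merged[merged["condition"] == calibrator]
             .groupby("target")["dct"].mean().rename("calib_dct"))
    merged = merged.merge(calib, on="target", how="left")
    if merged["calib_dct"].isna().any():
        bad = sorted(merged.loc[merged["calib_dct"].isna(), "target"].unique())
        raise ValueError(f"no calibrator-condition rows for targets: {bad}")
    merged["ddct"] = merged["dct"] - merged["calib_dct"]
    merged["rq"] = 2.0 ** -merged["ddct"]
    return (merged[["target", "condition", "bio_rep", "dct", "ddct", "rq"]]
            .sort_values(["target", "condition", "bio_rep"])
            .reset_index(drop=True))


def two_sample_t(rq_a, rq_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-replicate RQ values."""
    a = np.asarray(rq_a, dtype=float)
    b = np.asarray(rq_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ConditionContrast:
    target: str
    condition_a: str
    condition_b: str
    mean_rq_a: float
    mean_rq_b: float
    t: float
    p: float


def compare_conditions(rq: pd.DataFrame, condition_a: str, condition_b: str,
                       equal_var: bool = True) -> pd.DataFrame:
    """Per-target t-test of RQ values between two conditions."""
    rows = []
    for target, grp in rq.groupby("target", sort=True):
        va = grp.loc[grp["condition"] == condition_a, "rq"].to_numpy()
        vb = grp.loc[grp["condition"] == condition_b, "rq"].to_numpy()
        t, p = two_sample_t(va, vb, equal_var=equal_var)
        rows.append(ConditionContrast(target, condition_a, condition_b,
                                      float(va.mean()), float(vb.mean()), t, p))
    return pd.DataFrame([r.__dict__ for r in rows])
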