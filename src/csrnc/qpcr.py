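"""Relative qPCR quantitation of sterile transcripts by the ddCt method.

Each target's threshold cycle (Ct) is normalized to a reference gene (HPRT by
default) within the same sample, then to a calibrator condition (resting
enriched B cells in the validation experiments):

    dCt_sample     = Ct_target(sample)     - Ct_ref(sample)
    dCt_calibrator = Ct_target(calibrator) - Ct_ref(calibrator)
    ddCt           = dCt_sample - dCt_calibrator
    fold           = 2 ** (-ddCt)

so one cycle fewer than the calibrator (after reference normalization) is a
two-fold induction and fold = 1 means no change. Amplification efficiency is
fixed at 100% (base 2); technical replicates are averaged on the Ct (log)
scale before differencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import rank_compare

logger = logging.getLogger(__name__)


class QpcrError(ValueError):
    """Invalid Ct input."""


@dataclass(frozen=True)
class FoldChange:
    sample_id: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


def ddct_fold(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
    sample_id: str = "",
    target: str = "",
) -> FoldChange:
    """Fold change of one target in one sample vs the calibrator condition."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if any(not np.isfinite(c) or c <= 0 for c in cts):
        raise QpcrError(
            f"sample {sample_id!r} target {target!r}: Ct values must be finite "
            "and positive"
        )
    d_sample = ct_target_sample - ct_ref_sample
    d_cal = ct_target_calibrator - ct_ref_calibrator
    ddct = d_sample - d_cal
    return FoldChange(
        sample_id=sample_id,
        target=target,
        delta_ct=d_sample,
        delta_delta_ct=ddct,
        fold=float(2.0 ** (-ddct)),
    )


def _mean_ct(records: pd.DataFrame) -> pd.Series:
    """Replicate Ct averaged on the Ct scale per (sample, target)."""
    return records.groupby(["sample_id", "target"])["ct"].mean()


def fold_changes(
    ct_table: pd.DataFrame,
    reference: str = "HPRT",
    calibrator_condition: str = "resting_B",
) -> pd.DataFrame:
    """Per-sample fold changes for every non-reference target.

    ``ct_table`` columns: sample_id, target, condition, replicate, ct. The
    calibrator dCt per target is the mean over samples in the calibrator
    condition. Samples lacking a reference-gene Ct are an error.
    """
    required = {"sample_id", "target", "condition", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    if (ct_table["ct"] <= 0).any():
        raise QpcrError("Ct values must be positive")
    mean_ct = _mean_ct(ct_table).unstack("target")
    if reference not in mean_ct.columns:
        raise QpcrError(f"reference gene {reference!r} absent from Ct table")
    no_ref = list(mean_ct.index[mean_ct[reference].isna()])
    if no_ref:
        raise QpcrError(f"missing reference-gene Ct for sample(s): {no_ref}")
    condition = (
        ct_table.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    )
    cal_samples = condition.index[condition == calibrator_condition]
    if len(cal_samples) == 0:
        raise QpcrError(f"no samples in calibrator condition {calibrator_condition!r}")

    dct = mean_ct.drop(columns=reference).sub(mean_ct[reference], axis=0)
    cal_dct = dct.loc[cal_samples].mean()

    rows = []
    for sample_id, row in dct.iterrows():
        for target, d in row.items():
            if pd.isna(d) or pd.isna(cal_dct[target]):
                continue
            ddct = d - cal_dct[target]
            rows.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "condition": condition[sample_id],
                    "delta_ct": float(d),
                    "delta_delta_ct": float(ddct),
                    "fold": float(2.0 ** (-ddct)),
                }
            )
    return pd.DataFrame(rows)


def summarize_fold(
    folds: pd.DataFrame,
    baseline_condition: str,
) -> pd.DataFrame:
    """Per (target, condition) mean fold, SD and paired signed-rank p vs the
    baseline condition.

    Pairing is by sample order within target/condition groups (suitable for
    per-donor time courses where each donor appears once per condition). With
    a single sample per group the fold is reported and p is absent with a
    warning.
    """
    if baseline_condition not in set(folds["condition"]):
        raise QpcrError(f"baseline condition {baseline_condition!r} not present")
    rows = []
    for (target, cond), grp in folds.groupby(["target", "condition"], observed=True):
        base = folds[
            (folds["target"] == target) & (folds["condition"] == baseline_condition)
        ].sort_values("sample_id")
        grp = grp.sort_values("sample_id")
        p = np.nan
        if cond == baseline_condition:
            p = 1.0
        elif len(grp) < 2 or len(base) < 2:
            logger.warning(
                "target %r condition %r: too few samples for a rank test",
                target, cond,
            )
        else:
            if len(grp) == len(base):
                _, p = rank_compare(
                    grp["fold"].to_numpy(), base["fold"].to_numpy(), paired=True
                )
            else:
                _, p = rank_compare(
                    grp["fold"].to_numpy(), base["fold"].to_numpy(), paired=False
                )
        rows.append(
            {
                "target": target,
                "condition": cond,
                "n": len(grp),
                "mean_fold": float(grp["fold"].mean()),
                "sd_fold": float(grp["fold"].std(ddof=1)) if len(grp) > 1 else np.nan,
                "p_vs_baseline": p,
            }
        )
    return pd.DataFrame(rows)
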