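"""Relative qPCR quantification by the 2^-ddCt method and concordance with
sequencing fold changes.

dCt = mean Ct(target) - mean Ct(reference) within a condition; ddCt is the
difference of dCt between the test condition and the calibrator; the fold
change is 2^-ddCt. The reference gene is assumed expression-stable between
conditions; a shift of its mean Ct above half a cycle triggers a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PHENOTYPES, ValidationError

logger = logging.getLogger(__name__)

REFERENCE_STABILITY_CYCLES = 0.5


@dataclass
class FoldChange:
    feature_id: str
    delta_delta_ct: float
    fold_change: float
    replicate_folds: np.ndarray = field(repr=False)
    reference_shift: float = 0.0


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ["feature_id", "condition", "replicate", "ct"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table is missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or np.any(~np.isfinite(ct)) or np.any(ct <= 0):
        bad = table.loc[~(np.isfinite(ct) & (ct > 0)), "feature_id"].iloc[0]
        raise ValidationError(f"non-finite or non-positive Ct for feature {bad!r}")
    bad_cond = set(table["condition"]) - set(PHENOTYPES)
    if bad_cond:
        raise ValidationError(f"unknown conditions in Ct table: {sorted(bad_cond)}")
    return table


def delta_delta_ct(table: pd.DataFrame, target: str, reference: str,
                   calibrator: str = "sensitive") -> FoldChange:
    """Fold change of ``target`` relative to ``reference``, vs the calibrator
    condition. Per-replicate folds (target Ct paired with the condition's
    mean reference Ct) are reported for spread."""
    table = validate_ct_table(table)
    if calibrator not in PHENOTYPES:
        raise ValidationError(f"unknown calibrator condition {calibrator!r}")
    test = [p for p in PHENOTYPES if p != calibrator][0]

    def mean_ct(fid: str, cond: str) -> float:
        sel = table[(table["feature_id"] == fid) & (table["condition"] == cond)]["ct"]
        if sel.empty:
            raise ValidationError(f"no Ct values for feature {fid!r} in condition {cond!r}")
        return float(sel.mean())

    d_ct = {c: mean_ct(target, c) - mean_ct(reference, c) for c in PHENOTYPES}
    ref_shift = mean_ct(reference, test) - mean_ct(reference, calibrator)
    if abs(ref_shift) >= REFERENCE_STABILITY_CYCLES:
        logger.warning(
            "reference %r shifts %.2f cycles between conditions "
            "(stability assumption questionable)", reference, ref_shift)
    ddct = d_ct[test] - d_ct[calibrator]

    test_cts = table[(table["feature_id"] == target) & (table["condition"] == test)]["ct"]
    rep_ddct = (test_cts.to_numpy() - mean_ct(reference, test)) - d_ct[calibrator]
    return FoldChange(
        feature_id=target,
        delta_delta_ct=float(ddct),
        fold_change=float(2.0 ** -ddct),
        replicate_folds=2.0 ** -rep_ddct,
        reference_shift=float(ref_shift),
    )


def concordance(folds: list[FoldChange], de: pd.DataFrame) -> pd.DataFrame:
    """Sign agreement of qPCR fold changes with sequencing log fold changes.

    Concordant iff sign(log2 fold) equals sign(logFC) and both are non-zero.
    """
    de_idx = de.set_index("feature_id")
    rows = []
    for fc in folds:
        if fc.feature_id not in de_idx.index:
            raise ValidationError(f"feature {fc.feature_id!r} absent from the DE table")
        log_fold = np.log2(fc.fold_change)
        ngs_lfc = float(de_idx.loc[fc.feature_id, "logFC"])
        q_dir = int(np.sign(log_fold))
        n_dir = int(np.sign(ngs_lfc))
        rows.append({
            "feature_id": fc.feature_id,
            "qpcr_log2_fold": log_fold,
            "ngs_logFC": ngs_lfc,
            "qpcr_direction": q_dir,
            "ngs_direction": n_dir,
            "concordant": bool(q_dir == n_dir and q_dir != 0),
        })
    return pd.DataFrame(rows)
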