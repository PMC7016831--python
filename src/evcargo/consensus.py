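"""Cross-contrast integration: Venn partitioning of significant feature sets,
cross-model directional consensus, biotype composition profiling, and a local
miR-to-target join.

The directional consensus mirrors the headline table of this kind of study:
species significant in the sensitive-vs-MDR contrast of *both* tumor models
with the same sign of log2 fold change, labeled up- or down-regulated in the
MDR condition (positive logFC = higher in MDR).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CountMatrix, FeatureAnnotation, ValidationError


@dataclass
class ConsensusTable:
    """Features concordantly altered in both tumor models.

    ``n_one_model_only`` counts features tested in one model but filtered
    out in the other (excluded from consensus, reported for transparency).
    """

    table: pd.DataFrame
    n_one_model_only: int


def venn_partition(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive-region counts for up to four labeled sets.

    Regions are labeled by the sorted member labels joined with ``&``
    (e.g. ``"NSCLC_cell&CML_cell"``). Every feature of the union lands in
    exactly one region; counts over all 2^k - 1 regions sum to the union.
    """
    labels = sorted(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[lb] for lb in combo)) if combo else set()
            outside = set.union(set(), *(sets[lb] for lb in labels if lb not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions


def significant_set(de: pd.DataFrame, alpha: float = 0.05,
                    use_adjusted: bool = False) -> set[str]:
    """Feature ids called significant in one DE table."""
    col = "adjusted_p" if use_adjusted else "p_value"
    mask = de["tested"] & (de[col] < alpha)
    return set(de.loc[mask, "feature_id"])


def directional_consensus(de_model1: pd.DataFrame, de_model2: pd.DataFrame,
                          alpha: float = 0.05, use_adjusted: bool = False) -> ConsensusTable:
    """Features significant in both models with the same logFC sign."""
    col = "adjusted_p" if use_adjusted else "p_value"
    m1 = de_model1.set_index("feature_id")
    m2 = de_model2.set_index("feature_id")
    shared = m1.index.intersection(m2.index)
    t1 = m1.loc[shared, "tested"].astype(bool)
    t2 = m2.loc[shared, "tested"].astype(bool)
    n_one_only = int((t1 ^ t2).sum())
    both = shared[t1 & t2]
    sig = (m1.loc[both, col] < alpha) & (m2.loc[both, col] < alpha)
    concordant = np.sign(m1.loc[both, "logFC"]) == np.sign(m2.loc[both, "logFC"])
    nonzero = (m1.loc[both, "logFC"] != 0) & (m2.loc[both, "logFC"] != 0)
    keep = both[sig & concordant & nonzero]
    table = pd.DataFrame({
        "feature_id": keep,
        "logFC_model1": m1.loc[keep, "logFC"].to_numpy(),
        "p_model1": m1.loc[keep, col].to_numpy(),
        "logFC_model2": m2.loc[keep, "logFC"].to_numpy(),
        "p_model2": m2.loc[keep, col].to_numpy(),
    }).reset_index(drop=True)
    table["direction"] = np.where(table["logFC_model1"] > 0, "up_in_MDR", "down_in_MDR")
    return ConsensusTable(table=table, n_one_model_only=n_one_only)


def biotype_composition(matrix: CountMatrix, annotation: FeatureAnnotation) -> pd.DataFrame:
    """Per-sample fraction of reads per biotype (rows: samples, columns: biotypes)."""
    lib = matrix.library_sizes()
    if np.any(lib == 0):
        j = int(np.argmax(lib == 0))
        raise ValidationError(f"sample {matrix.samples[j].label!r} has zero total counts")
    bmap = annotation.biotype_map()
    biotypes = np.array([bmap.get(f, "other") for f in matrix.feature_ids])
    out = {}
    for bt in sorted(set(biotypes)):
        out[bt] = matrix.counts[biotypes == bt, :].sum(axis=0) / lib
    return pd.DataFrame(out, index=matrix.labels)


def map_targets(consensus: ConsensusTable, mapping: pd.DataFrame
                ) -> tuple[pd.DataFrame, list[str]]:
    """Inner-join consensus miRs against a local miR-to-target table.

    ``mapping`` must have exactly two columns: the miR feature id and the
    target gene. Returns the joined table and the list of consensus features
    without any mapping.
    """
    if mapping.shape[1] != 2:
        raise ValidationError(
            f"mapping table must have exactly 2 columns, got {mapping.shape[1]}")
    mapping = mapping.copy()
    mapping.columns = ["feature_id", "target"]
    joined = consensus.table.merge(mapping, on="feature_id", how="inner")
    unmapped = sorted(set(consensus.table["feature_id"]) - set(mapping["feature_id"]))
    return joined, unmapped
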