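"""Core data model, validation and tab-separated file I/O.

The pipeline operates on integer count matrices (features x samples) from a
paired study design: two tumor models (non-small-cell lung cancer, NSCLC, and
chronic myeloid leukemia, CML), each with a drug-sensitive line and its
multidrug-resistant (MDR) counterpart, profiled both as cells and as the
extracellular vesicles (EVs) they release, in three biological replicates —
24 samples in total.

All on-disk formats are plain UTF-8 TSV with a mandatory header row; counts
files carry the feature identifier in a first column named ``feature_id`` and
sample metadata lives in a separate table keyed by the count-column label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

MODELS = ("NSCLC", "CML")
COMPARTMENTS = ("cell", "EV")
PHENOTYPES = ("sensitive", "MDR")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequencing library."""

    label: str
    model: str
    compartment: str
    phenotype: str
    replicate: int

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValidationError(
                f"sample {self.label!r}: unknown model {self.model!r}; expected one of {MODELS}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"sample {self.label!r}: unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"sample {self.label!r}: unknown phenotype {self.phenotype!r}; "
                f"expected one of {PHENOTYPES}"
            )
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            raise ValidationError(
                f"sample {self.label!r}: replicate must be an integer >= 1, got {self.replicate!r}"
            )

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.model, self.compartment, self.phenotype)


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with typed sample metadata."""

    feature_ids: list[str]
    counts: np.ndarray
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()
        self.counts = self.counts.astype(np.int64)

    def validate(self) -> None:
        n_feat, n_samp = len(self.feature_ids), len(self.samples)
        if self.counts.shape != (n_feat, n_samp):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{n_feat} features x {n_samp} samples"
            )
        dup = _duplicates(self.feature_ids)
        if dup:
            raise ValidationError(f"duplicate feature ids: {sorted(dup)[:5]}")
        dup = _duplicates([s.label for s in self.samples])
        if dup:
            raise ValidationError(f"duplicate sample labels: {sorted(dup)[:5]}")
        keys = [(s.model, s.compartment, s.phenotype, s.replicate) for s in self.samples]
        dup = _duplicates(keys)
        if dup:
            raise ValidationError(f"duplicate (model, compartment, phenotype, replicate): {sorted(dup)[:5]}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = self.counts - np.floor(self.counts)
            bad = np.argwhere(frac != 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count {self.counts[i, j]!r} at feature "
                    f"{self.feature_ids[i]!r}, sample {self.samples[j].label!r}"
                )
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count {self.counts[i, j]} at feature "
                f"{self.feature_ids[i]!r}, sample {self.samples[j].label!r}"
            )

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.labels)

    def subset(self, model: str | None = None, compartment: str | None = None,
               phenotype: str | None = None) -> "CountMatrix":
        return subset(self, model=model, compartment=compartment, phenotype=phenotype)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (self.feature_ids == other.feature_ids
                and self.samples == other.samples
                and np.array_equal(self.counts, other.counts))


@dataclass
class FeatureAnnotation:
    """Per-feature name and transcript biotype (miRNA, pseudogene, rRNA, ...)."""

    table: pd.DataFrame

    REQUIRED = ("feature_id", "name", "biotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation is missing columns: {missing}")
        dup = self.table["feature_id"][self.table["feature_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate feature_id in annotation: {sorted(set(dup))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def biotype_map(self) -> dict[str, str]:
        return dict(zip(self.table["feature_id"], self.table["biotype"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureAnnotation):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class PipelineConfig:
    """Analysis parameters shared by the pipeline stages.

    ``cpm_cutoff``/``min_samples_passing`` define the abundance filter
    (counts-per-million >= cutoff in at least that many samples); ``alpha`` is
    the significance level; the ``grid_*`` fields span the noise-threshold
    grid search on the log2 RPM scale.
    """

    cpm_cutoff: float = 2.0
    min_samples_passing: int = 3
    alpha: float = 0.05
    use_adjusted_p: bool = False
    grid_lo: float = 0.0
    grid_hi: float = 10.0
    grid_step: float = 0.1
    logfc_prior_count: float = 0.5
    threshold_axes: str = "both"   # both | x | y
    r2_ceiling: float = 0.8
    cluster_distance: str = "pearson"
    cluster_linkage: str = "average"
    mds_top_k: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.grid_lo < self.grid_hi):
            raise ValidationError("grid_lo must be < grid_hi")
        if not (self.grid_step > 0):
            raise ValidationError("grid_step must be > 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.threshold_axes not in ("both", "x", "y"):
            raise ValidationError("threshold_axes must be 'both', 'x' or 'y'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers

def read_count_matrix(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column ``feature_id``) and its metadata TSV."""
    counts_df = pd.read_csv(path, sep="\t", dtype={0: str})
    if counts_df.columns[0] != "feature_id":
        raise ValidationError(
            f"{path}: first column must be named 'feature_id', got {counts_df.columns[0]!r}"
        )
    meta = pd.read_csv(metadata_path, sep="\t")
    required = ["label", "model", "compartment", "phenotype", "replicate"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValidationError(f"{metadata_path}: missing metadata columns: {missing}")

    feature_ids = counts_df["feature_id"].tolist()
    labels = list(counts_df.columns[1:])
    meta_by_label = {row.label: row for row in meta.itertuples(index=False)}
    unknown = [lb for lb in labels if lb not in meta_by_label]
    if unknown:
        raise ValidationError(f"count columns with no metadata row: {unknown}")

    raw = counts_df[labels]
    for col in labels:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise ValidationError(
                f"non-numeric count {raw[col].iloc[i]!r} at feature "
                f"{feature_ids[i]!r}, sample {col!r}"
            )
    counts = raw.to_numpy(dtype=float)
    samples = [
        SampleInfo(
            label=lb,
            model=str(meta_by_label[lb].model),
            compartment=str(meta_by_label[lb].compartment),
            phenotype=str(meta_by_label[lb].phenotype),
            replicate=int(meta_by_label[lb].replicate),
        )
        for lb in labels
    ]
    return CountMatrix(feature_ids=feature_ids, counts=counts, samples=samples)


def write_count_matrix(matrix: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    df = matrix.to_frame().reset_index(names="feature_id")
    df.to_csv(path, sep="\t", index=False)
    meta = pd.DataFrame([dataclasses.asdict(s) for s in matrix.samples])
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> FeatureAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return FeatureAnnotation(table=table)


def write_annotation(annotation: FeatureAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def subset(matrix: CountMatrix, model: str | None = None, compartment: str | None = None,
           phenotype: str | None = None) -> CountMatrix:
    """Restrict to samples matching the given design axes; features unchanged."""
    if model is not None and model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    if compartment is not None and compartment not in COMPARTMENTS:
        raise ValidationError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    if phenotype is not None and phenotype not in PHENOTYPES:
        raise ValidationError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    keep = [
        j for j, s in enumerate(matrix.samples)
        if (model is None or s.model == model)
        and (compartment is None or s.compartment == compartment)
        and (phenotype is None or s.phenotype == phenotype)
    ]
    if not keep:
        raise ValidationError(
            f"no samples match model={model!r}, compartment={compartment!r}, phenotype={phenotype!r}"
        )
    return CountMatrix(
        feature_ids=list(matrix.feature_ids),
        counts=matrix.counts[:, keep],
        samples=[matrix.samples[j] for j in keep],
    )


def _duplicates(items: Iterable) -> set:
    seen: set = set()
    dup: set = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup
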