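"""Synthetic data with known truth for the paired cell/EV MDR study design.

The generator emits a 24-sample count matrix (2 tumor models x 2 compartments
x 2 phenotypes x 3 replicates) with negative-binomial counts, a feature
annotation with a realistic biotype mix, and a truth table recording every
planted quantity so downstream stages can be tested for recovery.

Model, in brief:

* each feature gets a shared log2 baseline ~ Normal(mu0, sigma0) plus an
  independent per-tumor-model offset, so the two models differ at baseline;
* a fraction of features carries an MDR effect in cells (log2 fold change,
  random sign); a sub-fraction is "shared", i.e. same sign in both models
  with independently drawn magnitudes;
* EV expected abundance is the donor-cell baseline abundance times a
  per-feature packaging factor (log-normal for a selective subset, 1
  otherwise) times a logistic detection indicator on log2 abundance
  (abundance-dependent dropout), so every EV species also exists in cells;
* a separate, disjoint fraction of features carries an EV-only MDR effect
  (phenotype-dependent packaging), mirroring the observation that the
  species altered in EVs are largely not those altered in cells;
* counts are NB(mean = library-size-scaled expected abundance, variance =
  mu + phi * mu^2); phi = 0 degenerates to Poisson.

Cell-side MDR effects are deliberately not transmitted to EV abundance: in
the study design this emulates, the sets of MDR-altered species in cells and
in EVs were essentially disjoint, which a simple multiplicative pass-through
cannot produce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    MODELS,
    PHENOTYPES,
    CountMatrix,
    FeatureAnnotation,
    SampleInfo,
    ValidationError,
)

DEFAULT_BIOTYPE_PROPORTIONS = {
    "pseudogene": 0.15,
    "miRNA": 0.03,
    "protein_coding": 0.55,
    "rRNA": 0.05,
    "tRNA": 0.07,
    "snRNA": 0.05,
    "other": 0.10,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``biotype_proportions`` are planted read (not feature-count) fractions:
    per tumor model, expected drug-sensitive cell abundance is rescaled per
    biotype so composition profiling should recover these values. The
    dropout parameters act on the log2 abundance scale: detection
    probability = logistic((log2 a - midpoint) * slope).
    """

    n_features: int = 5000
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS))
    log2_mean_baseline: tuple[float, float] = (5.0, 2.0)
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (1_000_000, 5_000_000)
    model_effect_sd: float = 1.0
    de_fraction: float = 0.1
    de_logfc_distribution: tuple[float, float] = (2.0, 0.5)
    shared_de_fraction: float = 0.3
    ev_de_fraction: float = 0.05
    ev_shared_de_fraction: float = 0.3
    de_min_log2_baseline: float | None = None
    packaging_mode: str = "selective"   # selective | proportional
    selective_fraction: float = 0.3
    packaging_log_sd: float = 1.5
    dropout_midpoint: float = 2.0
    dropout_slope: float = 1.0
    enforce_ev_subset: bool = True
    n_replicates: int = 3
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("de_fraction", "shared_de_fraction", "ev_de_fraction",
                     "ev_shared_de_fraction", "selective_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"biotype proportions must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.biotype_proportions.values()):
            raise ValidationError("biotype proportions must be non-negative")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.packaging_mode not in ("selective", "proportional"):
            raise ValidationError("packaging_mode must be 'selective' or 'proportional'")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must satisfy 0 < min <= max")
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class SimTruth:
    """Planted quantities, one row per feature.

    Columns: feature_id, biotype; per model M: baseline_M (log2 expected
    cell abundance after biotype rescaling, drug-sensitive), cell_logfc_M,
    ev_logfc_M, packaging_factor_M, ev_detected_M.
    """

    table: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimTruth):
            return NotImplemented
        return self.table.equals(other.table)


def apply_packaging(cell_abundance: np.ndarray, config: SimConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EV loading model: multiplicative packaging factors plus logistic dropout.

    Returns (ev_abundance, factors, detected_flags). In proportional mode all
    factors are 1; in selective mode a ``selective_fraction`` of features gets
    log-normal(0, packaging_log_sd) factors. Detection probability is
    logistic on log2 abundance; undetected features get EV abundance 0.
    """
    config.validate()
    a = np.asarray(cell_abundance, dtype=float)
    if np.any(a < 0):
        raise ValidationError("cell abundances must be >= 0")
    n = a.size
    factors = np.ones(n)
    if config.packaging_mode == "selective":
        n_sel = int(round(config.selective_fraction * n))
        idx = rng.choice(n, size=n_sel, replace=False)
        factors[idx] = rng.lognormal(mean=0.0, sigma=config.packaging_log_sd, size=n_sel)
    with np.errstate(divide="ignore"):
        log2a = np.where(a > 0, np.log2(np.where(a > 0, a, 1.0)), -np.inf)
    if np.isneginf(config.dropout_midpoint):
        p_detect = np.ones(n)
    else:
        p_detect = expit((log2a - config.dropout_midpoint) * config.dropout_slope)
    detected = rng.random(n) < p_detect
    ev_abundance = a * factors * detected
    return ev_abundance, factors, detected


def generate_dataset(config: SimConfig) -> tuple[CountMatrix, FeatureAnnotation, SimTruth]:
    """Draw one complete synthetic study; deterministic given ``rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_features

    feature_ids = [f"F{i:05d}" for i in range(1, n + 1)]
    biotypes = _assign_biotypes(config, rng)

    mu0, sigma0 = config.log2_mean_baseline
    shared_baseline = rng.normal(mu0, sigma0, size=n)
    baseline = {
        m: shared_baseline + rng.normal(0.0, config.model_effect_sd, size=n)
        for m in MODELS
    }

    cell_logfc = _plant_effects(config, rng, baseline,
                                fraction=config.de_fraction,
                                shared_fraction=config.shared_de_fraction,
                                exclude=np.zeros(n, dtype=bool))
    cell_de_any = (cell_logfc[MODELS[0]] != 0) | (cell_logfc[MODELS[1]] != 0)
    ev_logfc = _plant_effects(config, rng, baseline,
                              fraction=config.ev_de_fraction,
                              shared_fraction=config.ev_shared_de_fraction,
                              exclude=cell_de_any)

    # rescale expected sensitive-cell abundance so per-biotype read fractions
    # match the planted proportions; one factor per feature per model, applied
    # uniformly across phenotypes and compartments so fold changes are intact
    abundance_sens: dict[str, np.ndarray] = {}
    for m in MODELS:
        a = np.power(2.0, baseline[m])
        scale = np.ones(n)
        total = a.sum()
        for bt, prop in config.biotype_proportions.items():
            mask = biotypes == bt
            s = a[mask].sum()
            if s > 0:
                scale[mask] = prop * total / s
        abundance_sens[m] = a * scale
        baseline[m] = np.log2(abundance_sens[m])

    packaging: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for m in MODELS:
        packaging[m] = apply_packaging(abundance_sens[m], config, rng)

    expected: dict[tuple[str, str, str], np.ndarray] = {}
    for m in MODELS:
        ev_base, factors, detected = packaging[m]
        for p in PHENOTYPES:
            mdr = 1.0 if p == "MDR" else 0.0
            expected[(m, "cell", p)] = abundance_sens[m] * np.power(2.0, cell_logfc[m] * mdr)
            expected[(m, "EV", p)] = ev_base * np.power(2.0, ev_logfc[m] * mdr)

    samples: list[SampleInfo] = []
    columns: list[np.ndarray] = []
    lo, hi = config.library_size_range
    phi = config.nb_dispersion
    for m in MODELS:
        for comp in ("cell", "EV"):
            for p in PHENOTYPES:
                a = expected[(m, comp, p)]
                a_total = a.sum()
                if a_total <= 0:
                    raise ValidationError(
                        f"condition {m}/{comp}/{p} has zero total expected abundance")
                for rep in range(1, config.n_replicates + 1):
                    lib = int(rng.integers(lo, hi + 1))
                    mu = lib * a / a_total
                    columns.append(_nb_draw(mu, phi, rng))
                    samples.append(SampleInfo(
                        label=f"{m}_{comp}_{p}_r{rep}",
                        model=m, compartment=comp, phenotype=p, replicate=rep))
    counts = np.column_stack(columns)

    if config.enforce_ev_subset:
        # EV cargo derives from cell RNA: zero out EV counts for species with
        # no observed cell counts in the matching model/phenotype
        for m in MODELS:
            for p in PHENOTYPES:
                cell_cols = [j for j, s in enumerate(samples)
                             if s.model == m and s.phenotype == p and s.compartment == "cell"]
                ev_cols = [j for j, s in enumerate(samples)
                           if s.model == m and s.phenotype == p and s.compartment == "EV"]
                absent = counts[:, cell_cols].sum(axis=1) == 0
                counts[np.ix_(absent, ev_cols)] = 0

    matrix = CountMatrix(feature_ids=feature_ids, counts=counts, samples=samples)
    annotation = FeatureAnnotation(table=pd.DataFrame({
        "feature_id": feature_ids,
        "name": [f"feat-{i:05d}" for i in range(1, n + 1)],
        "biotype": biotypes,
    }))
    truth_cols: dict[str, object] = {"feature_id": feature_ids, "biotype": biotypes}
    for m in MODELS:
        ev_base, factors, detected = packaging[m]
        truth_cols[f"baseline_{m}"] = baseline[m]
        truth_cols[f"cell_logfc_{m}"] = cell_logfc[m]
        truth_cols[f"ev_logfc_{m}"] = ev_logfc[m]
        truth_cols[f"packaging_factor_{m}"] = factors
        truth_cols[f"ev_detected_{m}"] = detected
    truth = SimTruth(table=pd.DataFrame(truth_cols))
    return matrix, annotation, truth


def generate_ct_table(truth: SimTruth, ct_intercept: float, ct_noise_sd: float,
                      reference_feature: str, rng: np.random.Generator,
                      model: str = "NSCLC", features: list[str] | None = None,
                      n_replicates: int = 3) -> pd.DataFrame:
    """Simulate qPCR threshold cycles: Ct = intercept - log2(abundance) + noise.

    The reference feature must be expression-stable (zero planted cell fold
    change in the chosen model), as required of a normalizer.
    """
    t = truth.table.set_index("feature_id")
    if reference_feature not in t.index:
        raise ValidationError(f"reference feature {reference_feature!r} not in truth")
    if t.loc[reference_feature, f"cell_logfc_{model}"] != 0:
        raise ValidationError(
            f"reference feature {reference_feature!r} is not expression-stable "
            f"(planted log2 fold change != 0 in model {model})")
    if features is None:
        features = list(t.index)
    rows = []
    for fid in features:
        if fid not in t.index:
            raise ValidationError(f"feature {fid!r} not in truth")
        base = float(t.loc[fid, f"baseline_{model}"])
        lfc = float(t.loc[fid, f"cell_logfc_{model}"])
        for cond, log2a in (("sensitive", base), ("MDR", base + lfc)):
            for rep in range(1, n_replicates + 1):
                ct = ct_intercept - log2a + rng.normal(0.0, ct_noise_sd)
                rows.append((fid, cond, rep, ct))
    return pd.DataFrame(rows, columns=["feature_id", "condition", "replicate", "ct"])


def write_truth(truth: SimTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path) -> SimTruth:
    return SimTruth(table=pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------

def _assign_biotypes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder apportionment of features to biotypes, then shuffled."""
    n = config.n_features
    names = list(config.biotype_proportions)
    quotas = np.array([config.biotype_proportions[b] * n for b in names])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - np.floor(quotas)))
    for k in range(remainder):
        counts[order[k % len(names)]] += 1
    biotypes = np.repeat(names, counts)
    return biotypes[rng.permutation(n)]


def _plant_effects(config: SimConfig, rng: np.random.Generator,
                   baseline: dict[str, np.ndarray], fraction: float,
                   shared_fraction: float, exclude: np.ndarray) -> dict[str, np.ndarray]:
    """Draw per-model log2 fold changes for a planted-effect feature set."""
    n = config.n_features
    loc, scale = config.de_logfc_distribution
    logfc = {m: np.zeros(n) for m in MODELS}
    n_de = int(round(fraction * n))
    if n_de == 0:
        return logfc
    eligible = ~exclude
    if config.de_min_log2_baseline is not None:
        min_base = np.minimum(baseline[MODELS[0]], baseline[MODELS[1]])
        eligible &= min_base >= config.de_min_log2_baseline
    pool = np.flatnonzero(eligible)
    if pool.size < n_de:
        raise ValidationError(
            f"only {pool.size} features eligible for {n_de} planted effects; "
            "relax de_min_log2_baseline or lower the fraction")
    chosen = rng.choice(pool, size=n_de, replace=False)
    n_shared = int(round(shared_fraction * n_de))
    shared, rest = chosen[:n_shared], chosen[n_shared:]
    signs = rng.choice([-1.0, 1.0], size=n_shared)
    for m in MODELS:
        logfc[m][shared] = signs * np.abs(rng.normal(loc, scale, size=n_shared))
    owner = rng.integers(0, 2, size=rest.size)
    for k, m in enumerate(MODELS):
        idx = rest[owner == k]
        s = rng.choice([-1.0, 1.0], size=idx.size)
        logfc[m][idx] = s * np.abs(rng.normal(loc, scale, size=idx.size))
    return logfc


def _nb_draw(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2); Poisson when phi = 0."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu).astype(np.int64)
    r = 1.0 / phi
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out
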