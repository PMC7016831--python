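"""Normalization, abundance filtering and the negative-binomial exact test.

This is the classic count-based differential-expression path for small
designs: TMM (trimmed mean of M-values) scaling factors, a common NB
dispersion estimated by conditional maximum likelihood on library-equalized
counts, and the conditional exact test comparing two groups of NB counts
given their total. Fold changes are reported as log2(MDR / sensitive).

The exact test exploits the fact that, under a common dispersion phi and
equal per-sample means, the sum of n NB(mu, phi) variables is
NB(n*mu, phi/n), and the conditional law of one group's sum given the total
is negative hypergeometric — free of mu, depending only on the group sizes
and phi. The two-sided p-value sums the probabilities of all splits no more
likely than the observed one. At phi = 0 this reduces to an exact binomial
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, ValidationError

_TIE_REL_TOL = 1e-7  # relative slack when comparing split probabilities for ties


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    library_sizes: np.ndarray
    factors: np.ndarray

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


def cpm(matrix: CountMatrix, factors: NormalizationFactors | None = None) -> np.ndarray:
    """Counts per million against the (TMM-effective) library size."""
    lib = matrix.library_sizes().astype(float)
    if factors is not None:
        lib = factors.effective_sizes
    if np.any(lib <= 0):
        j = int(np.argmax(lib <= 0))
        raise ValidationError(f"sample {matrix.samples[j].label!r} has library size <= 0")
    return matrix.counts / lib * 1e6


def log2_cpm(matrix: CountMatrix, factors: NormalizationFactors | None = None,
             prior_count: float = 0.5) -> np.ndarray:
    """log2 CPM with a small prior count to keep zeros finite."""
    lib = matrix.library_sizes().astype(float)
    if factors is not None:
        lib = factors.effective_sizes
    return np.log2((matrix.counts + prior_count) / lib * 1e6)


def filter_by_cpm(matrix: CountMatrix, cutoff: float = 2.0,
                  min_samples: int = 3,
                  factors: NormalizationFactors | None = None) -> tuple[list[str], list[str]]:
    """Partition features by the CPM abundance filter.

    A feature is kept iff CPM >= cutoff in at least ``min_samples`` samples.
    """
    if min_samples > matrix.n_samples:
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {matrix.n_samples} available samples")
    passing = (cpm(matrix, factors) >= cutoff).sum(axis=1) >= min_samples
    kept = [f for f, ok in zip(matrix.feature_ids, passing) if ok]
    dropped = [f for f, ok in zip(matrix.feature_ids, passing) if not ok]
    return kept, dropped


def tmm_factors(matrix: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> NormalizationFactors:
    """TMM composition-scaling factors.

    The reference column is the one whose upper-quartile relative abundance
    is closest to the mean upper quartile. Each factor is 2 to the
    precision-weighted mean of M-values (log-ratios vs the reference), after
    trimming the most extreme ``trim_m`` of M and ``trim_a`` of A on each
    side. Factors are rescaled to geometric mean 1.
    """
    counts = matrix.counts.astype(float)
    lib = counts.sum(axis=0)
    if matrix.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    if np.any(lib <= 0):
        j = int(np.argmax(lib <= 0))
        raise ValidationError(f"sample {matrix.samples[j].label!r} has zero library size")

    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(matrix.n_samples)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == ref:
            factors[j] = 1.0
            continue
        factors[j] = _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref],
                               trim_m, trim_a,
                               label=matrix.samples[j].label)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(library_sizes=lib, factors=factors)


def _tmm_pair(y: np.ndarray, y_ref: np.ndarray, n: float, n_ref: float,
              trim_m: float, trim_a: float, label: str = "?") -> float:
    keep = (y > 0) & (y_ref > 0)
    if not np.any(keep):
        raise ValidationError(
            f"sample {label!r} shares no positive features with the TMM reference")
    p, p_ref = y[keep] / n, y_ref[keep] / n_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    # asymptotic (delta-method) variance of M, used as inverse weight
    w = (n - y[keep]) / (n * y[keep]) + (n_ref - y_ref[keep]) / (n_ref * y_ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    k = m.size
    lo_m = np.floor(k * trim_m) + 1
    hi_m = k + 1 - lo_m
    lo_a = np.floor(k * trim_a) + 1
    hi_a = k + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    mask = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(mask):
        mask = np.ones(k, dtype=bool)
    f = np.sum(m[mask] / w[mask]) / np.sum(1.0 / w[mask])
    return float(2.0 ** f)


def estimate_common_dispersion(matrix: CountMatrix, groups: list[str] | np.ndarray,
                               factors: NormalizationFactors | None = None) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are first scaled to the geometric mean of the effective library
    sizes; the conditional log-likelihood given each group's per-feature sum
    is then maximized over phi (variance = mu + phi mu^2), summed over all
    groups with >= 2 replicates. Clamped at 0.
    """
    groups = np.asarray(groups)
    if groups.size != matrix.n_samples:
        raise ValidationError("groups must give one label per sample")
    lib = matrix.library_sizes().astype(float)
    if factors is not None:
        lib = factors.effective_sizes
    common = np.exp(np.mean(np.log(lib)))
    pseudo = matrix.counts * (common / lib)

    blocks = []
    for g in np.unique(groups):
        cols = np.flatnonzero(groups == g)
        if cols.size >= 2:
            blocks.append(pseudo[:, cols])
    if not blocks:
        raise ValidationError(
            "no group has >= 2 replicates; supply a dispersion value instead of estimating it")

    def neg_cl(log10_phi: float) -> float:
        r = 1.0 / (10.0 ** log10_phi)
        total = 0.0
        for y in blocks:
            nrep = y.shape[1]
            z = y.sum(axis=1)
            ll = (gammaln(y + r).sum(axis=1) - nrep * gammaln(r)
                  + gammaln(nrep * r) - gammaln(z + nrep * r))
            total += ll.sum()
        return -total

    res = minimize_scalar(neg_cl, bounds=(-8.0, 2.0), method="bounded",
                          options={"xatol": 1e-6})
    phi = float(10.0 ** res.x)
    # likelihood flat or maximized at the lower boundary -> Poisson
    if res.x <= -7.5 or neg_cl(-8.0) <= res.fun + 1e-9:
        return 0.0
    return phi


def exact_nb_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for one feature.

    ``y_a``/``y_b`` are the library-equalized group sums, ``n_a``/``n_b``
    the group sizes. Sums the null probabilities of all splits of the total
    whose probability does not exceed the observed split's.
    """
    t = int(y_a) + int(y_b)
    if t == 0:
        return 1.0
    logp = _log_split_probs(t, n_a, n_b, phi)
    obs = logp[int(y_a)]
    take = logp <= obs + np.log1p(_TIE_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[take]))))


def _log_split_probs(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log null probabilities of y_a = 0..t given total t."""
    a = np.arange(t + 1, dtype=float)
    b = t - a
    if phi == 0:
        p = n_a / (n_a + n_b)
        logp = (gammaln(t + 1) - gammaln(a + 1) - gammaln(b + 1)
                + a * np.log(p) + b * np.log1p(-p))
        return logp - logsumexp(logp)
    r_a, r_b = n_a / phi, n_b / phi
    logp = (gammaln(a + r_a) - gammaln(a + 1)
            + gammaln(b + r_b) - gammaln(b + 1))
    return logp - logsumexp(logp)


def nb_exact_test(matrix: CountMatrix, group_a: list[str], group_b: list[str],
                  dispersion: float, factors: NormalizationFactors | None = None,
                  prior_count: float = 0.5) -> pd.DataFrame:
    """Exact test for every feature; group B relative to group A.

    Counts are scaled to the geometric mean of the effective library sizes,
    group sums are rounded to integers, and the conditional exact p-value is
    computed per feature. logFC = log2((y_b + prior)/(y_a + prior)) adjusted
    for group size; the convention downstream is A = sensitive, B = MDR, so
    positive logFC means higher in MDR.
    """
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    labels = matrix.labels
    idx_a = [labels.index(lb) for lb in group_a]
    idx_b = [labels.index(lb) for lb in group_b]
    if not idx_a or not idx_b:
        raise ValidationError("both groups must be non-empty")
    lib = matrix.library_sizes().astype(float)
    if factors is not None:
        lib = factors.effective_sizes
    common = np.exp(np.mean(np.log(lib[idx_a + idx_b])))
    pseudo = matrix.counts * (common / lib)
    y_a = np.rint(pseudo[:, idx_a].sum(axis=1)).astype(np.int64)
    y_b = np.rint(pseudo[:, idx_b].sum(axis=1)).astype(np.int64)
    n_a, n_b = len(idx_a), len(idx_b)

    logfc = np.log2((y_b + prior_count) / (y_a + prior_count)) - np.log2(n_b / n_a)
    logfc[(y_a == 0) & (y_b == 0)] = 0.0

    # cache p-value vectors by total: features sharing t reuse the split law
    pvals = np.ones(matrix.n_features)
    cache: dict[int, np.ndarray] = {}
    for i in range(matrix.n_features):
        t = int(y_a[i] + y_b[i])
        if t == 0:
            continue
        logp = cache.get(t)
        if logp is None:
            logp = _log_split_probs(t, n_a, n_b, dispersion)
            if t <= 2000:
                cache[t] = logp
        obs = logp[int(y_a[i])]
        take = logp <= obs + np.log1p(_TIE_REL_TOL)
        pvals[i] = min(1.0, float(np.exp(logsumexp(logp[take]))))

    group_cpm = (pseudo[:, idx_a + idx_b] / common * 1e6)
    mean_log2_cpm = np.log2(group_cpm.mean(axis=1) + 0.5)
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "logFC": logfc,
        "p_value": pvals,
        "mean_log2_cpm": mean_log2_cpm,
    })


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValidationError(f"p-value {bad!r} outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_contrast(matrix: CountMatrix, model: str, compartment: str,
                cpm_cutoff: float = 2.0, min_samples: int = 3,
                dispersion: float | None = None,
                prior_count: float = 0.5) -> pd.DataFrame:
    """Full sensitive-vs-MDR contrast for one model and compartment.

    Subsets the matrix, TMM-normalizes, applies the CPM filter, estimates
    the common dispersion (unless given), runs the exact test on the kept
    features and BH-adjusts their p-values. Features failing the filter are
    returned with ``tested = False`` and NaN statistics.
    """
    sub = matrix.subset(model=model, compartment=compartment)
    norm = tmm_factors(sub)
    kept, _ = filter_by_cpm(sub, cutoff=cpm_cutoff, min_samples=min_samples, factors=norm)
    kept_set = set(kept)
    keep_rows = [i for i, f in enumerate(sub.feature_ids) if f in kept_set]
    filtered = CountMatrix(
        feature_ids=[sub.feature_ids[i] for i in keep_rows],
        counts=sub.counts[keep_rows, :],
        samples=sub.samples,
    )
    group_a = [s.label for s in sub.samples if s.phenotype == "sensitive"]
    group_b = [s.label for s in sub.samples if s.phenotype == "MDR"]
    norm_f = NormalizationFactors(library_sizes=norm.library_sizes, factors=norm.factors)
    if dispersion is None:
        groups = [s.phenotype for s in filtered.samples]
        dispersion = estimate_common_dispersion(filtered, groups, factors=norm_f)
    res = nb_exact_test(filtered, group_a, group_b, dispersion,
                        factors=norm_f, prior_count=prior_count)
    res["adjusted_p"] = bh_adjust(res["p_value"].to_numpy())
    res["tested"] = True
    out = pd.DataFrame({"feature_id": matrix.feature_ids})
    out = out.merge(res, on="feature_id", how="left")
    out["tested"] = out["tested"].eq(True)
    out.attrs["dispersion"] = dispersion
    out.attrs["contrast"] = f"{model}_{compartment}"
    return out
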