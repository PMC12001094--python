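"""Dose transformation, count normalization and pathway-level pre-filters.

Counts enter the downstream linear mixed models as precision-weighted
log2-CPM: a per-feature negative-binomial dispersion (Var = mu + phi*mu^2)
is estimated by method of moments with empirical-Bayes shrinkage toward a
mean-dispersion trend, and observation weights are the inverse delta-method
variance of log2 counts under that dispersion. Log-intensity data pass
through with unit weights.

Three optional gene-set filters run before fitting, each a pure function of
the transformed data with configurable thresholds: an invariant-gene filter,
an antagonistic-profile filter and a first-principal-component filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datasets import DoseResponseDataset, GeneSet

__all__ = [
    "DoseScale",
    "FilterConfig",
    "FilterDecision",
    "TransformedDataset",
    "transform_doses",
    "estimate_dispersion",
    "transform_counts",
    "transform_dataset",
    "filter_invariant",
    "filter_antagonistic",
    "filter_pc1",
    "apply_filters",
]


@dataclass(frozen=True)
class DoseScale:
    """Record of the dose-axis transformation applied before modeling."""

    kind: str  # "natural" | "log10"
    pseudo_dose: float | None = None  # value substituted for dose 0 under log10

    def to_model(self, doses: np.ndarray) -> np.ndarray:
        doses = np.asarray(doses, dtype=float)
        if self.kind == "natural":
            return doses
        d = doses
        if self.pseudo_dose is not None:
            d = np.where(doses == 0, self.pseudo_dose, doses)
        return np.log10(d)

    def to_natural(self, model_doses: np.ndarray) -> np.ndarray:
        model_doses = np.asarray(model_doses, dtype=float)
        if self.kind == "natural":
            return model_doses
        return 10.0 ** model_doses


def transform_doses(
    doses: Sequence[float] | np.ndarray, use_log10: bool = False
) -> tuple[np.ndarray, DoseScale]:
    """Optionally log10-transform doses, mapping zero (control) doses to a
    pseudo-dose of one tenth of the smallest positive dose.

    Log10 is recommended when doses span several orders of magnitude. The
    pseudo-dose is recorded in the returned :class:`DoseScale` for
    provenance and back-transformation.
    """
    doses = np.asarray(doses, dtype=float)
    if (doses < 0).any():
        raise ValueError("doses must be non-negative")
    if not use_log10:
        return doses.copy(), DoseScale("natural")
    positive = doses[doses > 0]
    if positive.size == 0:
        raise ValueError("cannot log10-transform doses: all doses are zero")
    pseudo = float(positive.min()) / 10.0 if (doses == 0).any() else None
    scale = DoseScale("log10", pseudo_dose=pseudo)
    return scale.to_model(doses), scale


def estimate_dispersion(
    counts: pd.DataFrame | np.ndarray, shrink: bool = True
) -> np.ndarray:
    """Per-feature negative-binomial dispersion phi with Var = mu + phi*mu^2.

    A two-step estimator: a per-feature method-of-moments phi-hat, then
    empirical-Bayes shrinkage toward a lowess mean-dispersion trend fitted
    across features (the trend pools information over features much like
    dispersion moderation in standard RNA-seq pipelines). Features with
    sub-Poisson moments get phi = 0.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("dispersion estimation needs a matrix with >= 2 samples")
    # Normalize library sizes so between-sample depth does not inflate variance.
    libs = mat.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("sample with zero library size")
    scaled = mat * (libs.mean() / libs)
    mu = scaled.mean(axis=1)
    var = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (var - mu) / mu**2, 0.0)
    raw = np.clip(raw, 0.0, None)
    if not shrink or mat.shape[0] < 10:
        return raw
    # Trend of dispersion vs mean abundance, fit on features with signal.
    ok = mu > 0
    order = np.argsort(mu[ok])
    trend_fit = lowess(
        raw[ok][order], np.log(mu[ok][order]), frac=0.6, return_sorted=False
    )
    trend = np.zeros_like(raw)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    trend[ok] = np.clip(trend_fit[inv], 0.0, None)
    # Moment estimators of phi are noisy at small n; weight the per-feature
    # estimate by its effective degrees of freedom against the trend.
    n = mat.shape[1]
    w = (n - 1) / (n - 1 + 20.0)
    return np.clip(w * raw + (1 - w) * trend, 0.0, None)


@dataclass
class TransformedDataset:
    """Expression on the modeling scale with optional precision weights.

    ``values`` is features x samples on the modeling scale (log2-CPM for
    counts, as-given for log intensities); ``weights`` (same shape) are
    inverse-variance precision weights, present only for counts mode;
    ``model_doses`` is the per-sample dose on the modeling dose scale.
    """

    values: pd.DataFrame
    doses: pd.Series  # natural units, per sample
    model_doses: np.ndarray  # modeling scale, aligned with values.columns
    dose_scale: DoseScale
    omics_type: str
    weights: pd.DataFrame | None = None
    dispersion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite values on the modeling scale")
        if self.weights is not None:
            w = self.weights.to_numpy()
            if (w <= 0).any() or not np.isfinite(w).all():
                raise ValueError("precision weights must be positive and finite")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def subset_samples(self, samples: Sequence[str]) -> "TransformedDataset":
        idx = [self.samples.index(s) for s in samples]
        return TransformedDataset(
            values=self.values[list(samples)],
            doses=self.doses[list(samples)],
            model_doses=self.model_doses[idx],
            dose_scale=self.dose_scale,
            omics_type=self.omics_type,
            weights=None if self.weights is None else self.weights[list(samples)],
            dispersion=self.dispersion,
        )


def transform_counts(
    counts: pd.DataFrame, dispersion: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> (log2(CPM + 0.5) values, precision weights).

    The weight of a cell is the inverse of the delta-method variance of its
    log2 count under the feature's NB dispersion, Var(log2 Y) ~=
    (1/mu + phi) / ln(2)^2 with mu the expected count of the cell predicted
    from the feature's mean CPM and the sample's library size. Deterministic.
    """
    mat = counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if (libs <= 0).any():
        bad = counts.columns[np.argwhere(libs <= 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    cpm = mat / libs * 1e6
    values = np.log2(cpm + 0.5)
    dispersion = np.asarray(dispersion, dtype=float)
    if dispersion.shape != (mat.shape[0],):
        raise ValueError("dispersion must have one entry per feature")
    mean_cpm = np.clip(cpm.mean(axis=1), 1e-8, None)
    mu = mean_cpm[:, None] * libs[None, :] / 1e6  # expected count per cell
    var_log2 = (1.0 / np.clip(mu, 0.25, None) + dispersion[:, None]) / np.log(2) ** 2
    weights = 1.0 / var_log2
    return (
        pd.DataFrame(values, index=counts.index, columns=counts.columns),
        pd.DataFrame(weights, index=counts.index, columns=counts.columns),
    )


def transform_dataset(
    dataset: DoseResponseDataset, use_log10: bool = False
) -> TransformedDataset:
    """Full preprocessing bridge: dose transform plus, for counts, dispersion
    estimation and precision-weighted log2-CPM. Log-intensity data pass
    through with no weights."""
    model_doses, scale = transform_doses(np.asarray(dataset.doses, float), use_log10)
    if dataset.omics_type == "counts":
        phi = estimate_dispersion(dataset.expression)
        values, weights = transform_counts(dataset.expression, phi)
        return TransformedDataset(
            values=values,
            doses=dataset.doses.copy(),
            model_doses=model_doses,
            dose_scale=scale,
            omics_type="counts",
            weights=weights,
            dispersion=phi,
        )
    return TransformedDataset(
        values=dataset.expression.copy(),
        doses=dataset.doses.copy(),
        model_doses=model_doses,
        dose_scale=scale,
        omics_type="log_intensity",
    )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three pathway pre-filters and set-size gates.

    Defaults: a set is dropped when more than half its genes sit in the
    lowest-variance decile of all genes, or when more than half of its gene
    pairs are negatively correlated, or when PC1 of the member submatrix
    explains more than 70% of the variance. All strict inequalities.
    """

    invariant_gene_fraction: float = 0.5
    low_variance_quantile: float = 0.10
    negative_correlation_fraction: float = 0.5
    pc1_variance_fraction: float = 0.70
    min_set_size: int = 3
    max_set_size: int = 500
    enable_invariant: bool = True
    enable_antagonistic: bool = True
    # The PC1 gate drops highly coherent sets (a dominant shared mode is what
    # a clean dose-responsive pathway produces), so it is off unless asked for.
    enable_pc1: bool = False

    def __post_init__(self) -> None:
        for name in (
            "invariant_gene_fraction",
            "low_variance_quantile",
            "negative_correlation_fraction",
            "pc1_variance_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must be <= max_set_size")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be positive")


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of one filter on one gene set; diagnostics determine keep."""

    filter: str
    keep: bool
    statistic: float | None
    reason: str = ""


def _member_matrix(dataset: TransformedDataset, geneset: GeneSet) -> np.ndarray:
    members = geneset.intersect(dataset.features)
    return dataset.values.loc[members].to_numpy(dtype=float)


def filter_invariant(
    dataset: TransformedDataset, geneset: GeneSet, cfg: FilterConfig
) -> FilterDecision:
    """Drop sets dominated by invariant genes.

    The set is dropped when the fraction of member genes whose variance lies
    within the ``low_variance_quantile`` quantile of all-gene variances
    (computed over every feature in the dataset) exceeds
    ``invariant_gene_fraction``.
    """
    sub = _member_matrix(dataset, geneset)
    all_var = dataset.values.to_numpy(dtype=float).var(axis=1, ddof=1)
    cutoff = np.quantile(all_var, cfg.low_variance_quantile)
    member_var = sub.var(axis=1, ddof=1)
    frac = float((member_var <= cutoff).mean())
    return FilterDecision(
        filter="invariant",
        keep=not frac > cfg.invariant_gene_fraction,
        statistic=frac,
        reason=f"{frac:.3f} of members in the lowest {cfg.low_variance_quantile:.0%} variance quantile",
    )


def filter_antagonistic(
    dataset: TransformedDataset, geneset: GeneSet, cfg: FilterConfig
) -> FilterDecision:
    """Drop sets with predominantly opposite gene profiles.

    The statistic is the fraction of gene pairs with negative Pearson
    correlation; pairs involving a zero-variance gene are excluded from both
    numerator and denominator.
    """
    sub = _member_matrix(dataset, geneset)
    if sub.shape[0] < 2:
        return FilterDecision("antagonistic", True, None, "fewer than 2 genes")
    variable = sub[sub.var(axis=1) > 0]
    n = variable.shape[0]
    if n < 2:
        return FilterDecision(
            "antagonistic", True, None, "fewer than 2 variable genes"
        )
    corr = np.corrcoef(variable)
    iu = np.triu_indices(n, k=1)
    frac = float((corr[iu] < 0).mean())
    return FilterDecision(
        filter="antagonistic",
        keep=not frac > cfg.negative_correlation_fraction,
        statistic=frac,
        reason=f"{frac:.3f} of gene pairs negatively correlated",
    )


def filter_pc1(
    dataset: TransformedDataset, geneset: GeneSet, cfg: FilterConfig
) -> FilterDecision:
    """Drop sets whose first principal component explains more than
    ``pc1_variance_fraction`` of the member-submatrix variance (genes as
    variables, centered). Optional and configurable: a high PC1 fraction
    flags a single dominant mode across the set."""
    sub = _member_matrix(dataset, geneset)
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return FilterDecision("pc1", True, None, "submatrix too small for PCA")
    centered = sub.T - sub.T.mean(axis=0)  # samples x genes, genes are variables
    sv = np.linalg.svd(centered, compute_uv=False)
    total = float((sv**2).sum())
    if total == 0:
        return FilterDecision("pc1", False, None, "rank-0 submatrix")
    frac = float(sv[0] ** 2 / total)
    return FilterDecision(
        filter="pc1",
        keep=not frac > cfg.pc1_variance_fraction,
        statistic=frac,
        reason=f"PC1 explains {frac:.3f} of variance",
    )


def apply_filters(
    dataset: TransformedDataset, geneset: GeneSet, cfg: FilterConfig
) -> list[FilterDecision]:
    """Run the size gate plus all enabled filters; the set is kept only if
    every returned decision has ``keep=True``."""
    n_matched = len(geneset.intersect(dataset.features))
    if n_matched < cfg.min_set_size:
        return [FilterDecision("size", False, float(n_matched), "too_small")]
    if n_matched > cfg.max_set_size:
        return [FilterDecision("size", False, float(n_matched), "too_large")]
    decisions = [FilterDecision("size", True, float(n_matched))]
    if cfg.enable_invariant:
        decisions.append(filter_invariant(dataset, geneset, cfg))
    if cfg.enable_antagonistic:
        decisions.append(filter_antagonistic(dataset, geneset, cfg))
    if cfg.enable_pc1:
        decisions.append(filter_pc1(dataset, geneset, cfg))
    return decisions
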