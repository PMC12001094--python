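"""Candidate dose-response models per gene set and model selection.

Four candidates are fitted to every gene set, all sharing a gene-specific
random intercept that absorbs baseline expression differences:

- ``null``: intercept only — no dose effect.
- ``linear_mixed``: shared linear dose effect plus gene-specific random
  slopes.
- ``nonlinear_fixed``: shared cubic-spline dose-response, random intercept
  only.
- ``nonlinear_mixed``: cubic-spline dose-response with gene-specific random
  spline coefficients.

All fits use maximum likelihood so AIC and likelihood-ratio tests against
the null are comparable across fixed-effect structures. The best model is
the lowest-AIC candidate among those whose LRT p-value against the null
clears the significance gate; if none clears it, the pathway is reported
as not dose-responsive (null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .datasets import GeneSet
from .mixedlm import LMMFit, fit_weighted_lmm
from .preprocess import TransformedDataset
from .splines import MIN_SPLINE_DOSES, SplineBasis, build_spline_basis

__all__ = [
    "MODEL_KINDS",
    "CandidateModel",
    "FittedPathwayModel",
    "PathwayCurve",
    "fit_candidate",
    "lrt_against_null",
    "select_best",
    "adjust_pvalues",
    "predict_curves",
    "fit_pathway",
]

MODEL_KINDS = ("null", "linear_mixed", "nonlinear_fixed", "nonlinear_mixed")


@dataclass
class CandidateModel:
    """One fitted candidate for one gene set."""

    kind: str
    genes: list[str]
    fit: LMMFit
    basis: SplineBasis | None = None
    lrt_p: float | None = None

    @property
    def beta0(self) -> float:
        return float(self.fit.beta[0])

    @property
    def fixed_dose_params(self) -> np.ndarray:
        return self.fit.beta[1:]

    @property
    def log_likelihood(self) -> float:
        return self.fit.log_likelihood

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def n_params(self) -> int:
        return self.fit.n_params

    @property
    def sigma_resid(self) -> float:
        return self.fit.sigma_resid

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def random_effects_frame(self) -> pd.DataFrame:
        names = ["b0"] + [f"b{k}" for k in range(1, self.fit.random_effects.shape[1])]
        return pd.DataFrame(self.fit.random_effects, index=self.genes, columns=names)


@dataclass
class PathwayCurve:
    """The fixed-effect dose-response curve of a fitted model on a dense grid.

    ``doses`` are on the modeling dose scale. For spline models ``spline``
    carries the underlying B-spline of the dose part (excluding the
    intercept), from which derivatives are analytic.
    """

    doses: np.ndarray
    response: np.ndarray
    kind: str
    spline: object | None = None   # scipy BSpline of the dose part, if any
    offset: float = 0.0            # intercept added on top of the spline

    def __post_init__(self) -> None:
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("curve dose grid must be strictly increasing")


def _designs(
    kind: str, doses: np.ndarray, basis: SplineBasis | None
) -> tuple[np.ndarray, np.ndarray]:
    ones = np.ones((doses.size, 1))
    if kind == "null":
        return ones, ones
    if kind == "linear_mixed":
        X = np.hstack([ones, doses[:, None]])
        return X, X
    if kind in ("nonlinear_fixed", "nonlinear_mixed"):
        if basis is None:
            raise ValueError(f"{kind} requires a spline basis")
        X = np.hstack([ones, basis.design(doses)])
        Z = ones if kind == "nonlinear_fixed" else X
        return X, Z
    raise ValueError(f"unknown model kind {kind!r}")


def fit_candidate(
    dataset: TransformedDataset,
    geneset: GeneSet,
    kind: str,
    basis: SplineBasis | None = None,
    theta0: np.ndarray | None = None,
    extra_starts: bool = True,
) -> CandidateModel:
    """Fit one candidate model for `geneset` on the transformed data.

    Observations are stacked in (gene, sample) long form internally;
    precision weights are applied when the dataset carries them. Requires
    at least 2 matched genes (random effects need replication across
    genes).
    """
    genes = geneset.intersect(dataset.features)
    if len(genes) < 2:
        raise ValueError(
            f"gene set {geneset.name!r}: {len(genes)} matched genes; "
            "random effects need >= 2"
        )
    Y = dataset.values.loc[genes].to_numpy(dtype=float)
    W = None if dataset.weights is None else dataset.weights.loc[genes].to_numpy(float)
    X, Z = _designs(kind, dataset.model_doses, basis)
    fit = fit_weighted_lmm(Y, X, Z, weights=W, theta0=theta0, extra_starts=extra_starts)
    if kind.startswith("nonlinear") and not basis.identity:
        fit.beta = _smooth_null_space(fit.beta, dataset.model_doses, basis)
    return CandidateModel(kind=kind, genes=genes, fit=fit,
                          basis=basis if kind.startswith("nonlinear") else None)


def _smooth_null_space(
    beta: np.ndarray, doses: np.ndarray, basis: SplineBasis
) -> np.ndarray:
    """Resolve the unidentified part of the spline fixed effects.

    With interior knots at every non-boundary dose level, the basis has more
    functions than the design has dose levels, so the fixed-effect curve is
    pinned down only at the observed doses. Among the coefficient vectors
    producing identical fitted values (hence identical likelihood), pick the
    one minimizing the integrated squared second derivative, so the reported
    curve does not wiggle between dose levels.
    """
    levels = np.unique(doses)
    Xl = np.hstack([np.ones((levels.size, 1)), basis.design(levels)])
    _, s, vh = np.linalg.svd(Xl, full_matrices=True)
    null_dim = Xl.shape[1] - int((s > s[0] * 1e-10).sum())
    if null_dim == 0:
        return beta
    N = vh[-null_dim:].T                      # (p, null_dim)
    P = np.zeros((Xl.shape[1], Xl.shape[1]))
    P[1:, 1:] = basis.penalty_matrix()        # intercept has no curvature
    NPN = N.T @ P @ N
    correction = N @ np.linalg.pinv(NPN, rcond=1e-12) @ (N.T @ (P @ beta))
    return beta - correction


def lrt_against_null(candidate: CandidateModel, null: CandidateModel) -> float:
    """Likelihood-ratio p-value of a candidate against the null model.

    Statistic 2*(l_candidate - l_null), clipped at zero, referred to a
    chi-squared with df = difference in parameter count.
    """
    if null.kind != "null":
        raise ValueError("reference model must be the null model")
    if candidate.fit.data_fingerprint != null.fit.data_fingerprint:
        raise ValueError("candidate and null were fitted on different data")
    stat = max(0.0, 2.0 * (candidate.log_likelihood - null.log_likelihood))
    df = candidate.n_params - null.n_params
    if df <= 0:
        return 1.0
    return float(chi2.sf(stat, df))


def select_best(
    candidates: list[CandidateModel], alpha: float = 0.05
) -> tuple[CandidateModel, list[dict]]:
    """AIC selection gated by the LRT: among converged non-null candidates
    with lrt_p < alpha, pick minimal AIC (ties -> fewer parameters); if none
    passes, the null model is returned (pathway not dose-responsive).

    Returns the winner and a per-candidate decision trace.
    """
    null = next((c for c in candidates if c.kind == "null"), None)
    if null is None:
        raise ValueError("candidate list must include the null model")
    trace = []
    eligible = []
    for c in candidates:
        if c.kind == "null":
            continue
        if c.lrt_p is None:
            c.lrt_p = lrt_against_null(c, null)
        passed = c.converged and c.lrt_p < alpha
        trace.append(
            {
                "kind": c.kind,
                "aic": c.aic,
                "log_likelihood": c.log_likelihood,
                "n_params": c.n_params,
                "lrt_p": c.lrt_p,
                "converged": c.converged,
                "eligible": passed,
            }
        )
        if passed:
            eligible.append(c)
    if not eligible:
        return null, trace
    best = min(eligible, key=lambda c: (round(c.aic, 9), c.n_params))
    return best, trace


def adjust_pvalues(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (step-up); adjusted >= raw."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FittedPathwayModel:
    """Selected model for a gene set with curves and goodness of fit."""

    geneset: GeneSet
    best: CandidateModel
    all_candidates: list[CandidateModel]
    lrt_p: float
    pathway_curve: PathwayCurve
    gene_curves: pd.DataFrame       # genes x grid, EB gene-level curves
    rmse: float
    adjusted_p: float | None = None
    selection_trace: list[dict] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def significant_raw(self) -> bool:
        return self.best.kind != "null"


def predict_curves(
    candidate: CandidateModel,
    dataset: TransformedDataset,
    grid_size: int = 200,
) -> tuple[PathwayCurve, pd.DataFrame, float]:
    """Dense fixed-effect pathway curve, per-gene EB curves, and RMSE.

    The pathway curve is the fixed-effect part beta0 + f(D) on a uniform
    grid over the modeling dose range; gene curves add each gene's
    empirical-Bayes random effects. RMSE compares observed values with
    fitted values (including random effects) at the observed doses.
    """
    if grid_size < 100:
        raise ValueError("curve grid needs >= 100 points")
    d = dataset.model_doses
    grid = np.linspace(d.min(), d.max(), grid_size)
    X, Z = _designs(candidate.kind, grid, candidate.basis)
    path_resp = X @ candidate.fit.beta
    gene_resp = path_resp[None, :] + candidate.fit.random_effects @ Z.T
    spline = None
    offset = candidate.beta0
    if candidate.kind.startswith("nonlinear"):
        spline = candidate.basis.spline(candidate.fixed_dose_params)
    elif candidate.kind == "linear_mixed":
        from .splines import linear_basis

        spline = linear_basis(d).spline(candidate.fixed_dose_params)
    curve = PathwayCurve(
        doses=grid, response=path_resp, kind=candidate.kind,
        spline=spline, offset=offset,
    )
    genes = candidate.genes
    gene_curves = pd.DataFrame(gene_resp, index=genes, columns=grid)
    obs = dataset.values.loc[genes].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((obs - candidate.fit.fitted) ** 2)))
    return curve, gene_curves, rmse


def fit_pathway(
    dataset: TransformedDataset,
    geneset: GeneSet,
    alpha: float = 0.05,
    degree: int = 3,
    manual_knots: np.ndarray | None = None,
    grid_size: int = 200,
) -> FittedPathwayModel:
    """Fit all candidates for one gene set and select the best.

    Spline candidates are skipped (with a recorded reason) when the design
    has fewer than four distinct dose levels.
    """
    skipped: list[str] = []
    candidates: list[CandidateModel] = []
    null = fit_candidate(dataset, geneset, "null")
    candidates.append(null)
    candidates.append(fit_candidate(dataset, geneset, "linear_mixed"))
    n_levels = np.unique(dataset.model_doses).size
    if n_levels >= MIN_SPLINE_DOSES:
        basis = build_spline_basis(dataset.model_doses, degree=degree,
                                   manual_knots=manual_knots)
        candidates.append(fit_candidate(dataset, geneset, "nonlinear_fixed", basis))
        candidates.append(fit_candidate(dataset, geneset, "nonlinear_mixed", basis))
    else:
        skipped.append(
            f"spline candidates skipped: {n_levels} distinct dose levels < "
            f"{MIN_SPLINE_DOSES}"
        )
    best, trace = select_best(candidates, alpha=alpha)
    # The reported p is the strongest evidence against the null among the
    # fitted candidates (the winner's p when one passes the gate).
    if best.kind != "null":
        lrt_p = best.lrt_p
    else:
        ps = [c.lrt_p for c in candidates if c.lrt_p is not None]
        lrt_p = min(ps) if ps else 1.0
    curve, gene_curves, rmse = predict_curves(best, dataset, grid_size=grid_size)
    return FittedPathwayModel(
        geneset=geneset,
        best=best,
        all_candidates=candidates,
        lrt_p=float(lrt_p),
        pathway_curve=curve,
        gene_curves=gene_curves,
        rmse=rmse,
        selection_trace=trace,
        skipped=skipped,
    )
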