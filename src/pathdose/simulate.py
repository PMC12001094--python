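"""Synthetic dose-response data with known pathway-level ground truth.

The generator draws data from exactly the model class the fitting stage
assumes: a shared pathway-level dose-response curve, gene-specific random
intercepts and multiplicative slope perturbations, and Gaussian residual
noise — or negative-binomial counts whose latent log2 mean follows the same
structure. Pathway shapes cover the phenomenology of interest: flat (null),
linear, sigmoid (monotone with an inflection), bell and U (biphasic), and
antagonistic (half the genes respond with opposite sign).

Shapes are parameterized on the normalized position t in [0, 1] along the
modeling dose axis (log10 dose by default, mirroring a multi-decade
concentration design of 8 half-log-spaced doses with 3 replicates), so
their turning and inflection points — and the benchmark-dose crossing for
a given response band — have closed forms, independent of the estimation
code, for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DoseResponseDataset, GeneSet, GeneSetCollection, align_dataset
from .preprocess import transform_doses

__all__ = [
    "SHAPES",
    "GeneSetSim",
    "SimulationSpec",
    "simulate_dataset",
    "simulate_null_suite",
    "shape_value",
    "analytic_bmd",
    "analytic_tcds",
]

SHAPES = ("flat", "linear", "sigmoid", "bell", "u_shape", "antagonistic")

# Shape hyper-parameters on the normalized dose axis t in [0, 1]. Widths are
# chosen so the transition region spans several dose intervals of the default
# 8-level design: a shape narrower than the dose spacing would not be
# identifiable from the design and could not serve as a recovery target.
_SIGMOID_CENTER = 0.5
_SIGMOID_WIDTH = 0.15
_BELL_CENTER = 0.5
_BELL_WIDTH = 0.18


def shape_value(shape: str, t: np.ndarray) -> np.ndarray:
    """Unit-amplitude pathway shape evaluated at normalized doses t."""
    t = np.asarray(t, dtype=float)
    if shape == "flat":
        return np.zeros_like(t)
    if shape in ("linear", "antagonistic"):
        return t
    if shape == "sigmoid":
        return 1.0 / (1.0 + np.exp(-(t - _SIGMOID_CENTER) / _SIGMOID_WIDTH))
    if shape == "bell":
        return np.exp(-((t - _BELL_CENTER) ** 2) / (2.0 * _BELL_WIDTH**2))
    if shape == "u_shape":
        return -np.exp(-((t - _BELL_CENTER) ** 2) / (2.0 * _BELL_WIDTH**2))
    raise ValueError(f"unknown shape {shape!r}")


def analytic_bmd(shape: str, effect_size: float, band: float) -> float | None:
    """Closed-form first crossing of |effect*(shape(t) - shape(0))| = band.

    Returns the crossing on the normalized t axis, or None when the band is
    never exited. Independent of the grid-scanning estimator, so the two
    serve as cross-checks of each other.
    """
    if band <= 0:
        raise ValueError("band must be positive")
    a = abs(effect_size)
    if shape == "flat" or a == 0:
        return None
    delta = band / a
    if shape in ("linear", "antagonistic"):
        return delta if delta <= 1 else None
    if shape == "sigmoid":
        s0 = shape_value("sigmoid", np.array([0.0]))[0]
        target = s0 + delta
        if target >= 1.0:
            return None
        t = _SIGMOID_CENTER + _SIGMOID_WIDTH * math.log(target / (1.0 - target))
        return t if t <= 1 else None
    if shape in ("bell", "u_shape"):
        s0 = math.exp(-(_BELL_CENTER**2) / (2.0 * _BELL_WIDTH**2))
        target = s0 + delta
        if target > 1.0:
            return None
        t = _BELL_CENTER - _BELL_WIDTH * math.sqrt(-2.0 * math.log(target))
        return t if t >= 0 else None
    raise ValueError(f"unknown shape {shape!r}")


def analytic_tcds(shape: str) -> list[tuple[str, float]]:
    """True turning/inflection points of a shape on the t axis, ascending."""
    if shape in ("flat", "linear", "antagonistic"):
        return []
    if shape == "sigmoid":
        return [("inflection", _SIGMOID_CENTER)]
    if shape == "bell":
        return [
            ("inflection", _BELL_CENTER - _BELL_WIDTH),
            ("maximum", _BELL_CENTER),
            ("inflection", _BELL_CENTER + _BELL_WIDTH),
        ]
    if shape == "u_shape":
        return [
            ("inflection", _BELL_CENTER - _BELL_WIDTH),
            ("minimum", _BELL_CENTER),
            ("inflection", _BELL_CENTER + _BELL_WIDTH),
        ]
    raise ValueError(f"unknown shape {shape!r}")


@dataclass(frozen=True)
class GeneSetSim:
    """Specification of one simulated pathway."""

    name: str
    n_genes: int = 15
    shape: str = "linear"
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


def _default_doses() -> tuple[float, ...]:
    # 8 half-log-spaced concentrations spanning 3.5 decades.
    return tuple(np.round(10.0 ** np.linspace(-2.5, 1.0, 8), 6))


@dataclass(frozen=True)
class SimulationSpec:
    """Study design and noise levels for one synthetic dataset.

    Defaults mirror a typical in-vitro concentration series: 8 half-log
    doses, 3 replicates each, log10 dose modeling, gene baseline SD 1.0,
    20% multiplicative slope heterogeneity, residual SD 0.3.
    """

    doses: tuple[float, ...] = field(default_factory=_default_doses)
    reps_per_dose: int = 3
    genesets: tuple[GeneSetSim, ...] = ()
    beta0: float = 8.0
    sd_gene_intercept: float = 1.0
    sd_gene_slope: float = 0.2
    sigma: float = 0.3
    omics_type: str = "log_intensity"
    nb_dispersion: float = 0.05
    use_log10_dose: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.sd_gene_intercept, self.sd_gene_slope, self.sigma):
            if v < 0:
                raise ValueError("noise SDs must be non-negative")
        if len(set(self.doses)) < 2:
            raise ValueError("need at least 2 distinct doses")
        if self.reps_per_dose < 1:
            raise ValueError("reps_per_dose must be >= 1")


def _normalized_positions(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample natural doses and normalized modeling positions t."""
    doses = np.repeat(np.sort(np.asarray(spec.doses, float)), spec.reps_per_dose)
    model, _ = transform_doses(doses, use_log10=spec.use_log10_dose)
    t = (model - model.min()) / (model.max() - model.min())
    return doses, t


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[DoseResponseDataset, GeneSetCollection, dict]:
    """Draw one dataset and the ground-truth record used by recovery tests.

    For gene j of a pathway with shape s and effect size E:

        Y_ij = beta0 + b0j + s_j * E * shape(t_i) + eps_ij

    with b0j ~ N(0, sd_gene_intercept^2), s_j = 1 + N(0, sd_gene_slope^2)
    (antagonistic pathways flip the sign of s_j for half the genes), and
    eps_ij ~ N(0, sigma^2). In counts mode the latent value is taken as a
    log2 mean, scaled by a log-normal library-size factor per sample, and
    counts are drawn negative-binomially with the spec's dispersion.
    """
    rng = np.random.default_rng(spec.seed)
    doses, t = _normalized_positions(spec)
    n = doses.size
    sample_ids = [f"S{i:02d}_r{r}" for i, d in enumerate(sorted(set(doses)))
                  for r in range(1, spec.reps_per_dose + 1)]
    rows, gene_names, collection = [], [], GeneSetCollection()
    truth: dict = {"spec": spec, "pathways": {}}
    for gs in spec.genesets:
        b0 = rng.normal(0.0, spec.sd_gene_intercept, size=gs.n_genes)
        slopes = 1.0 + rng.normal(0.0, spec.sd_gene_slope, size=gs.n_genes)
        if gs.shape == "antagonistic":
            signs = np.where(np.arange(gs.n_genes) % 2 == 0, 1.0, -1.0)
            slopes = slopes * signs
        base = shape_value(gs.shape, t)
        eps = rng.normal(0.0, spec.sigma, size=(gs.n_genes, n))
        latent = (
            spec.beta0 + b0[:, None]
            + slopes[:, None] * gs.effect_size * base[None, :] + eps
        )
        names = [f"{gs.name}_g{j:03d}" for j in range(gs.n_genes)]
        rows.append(latent)
        gene_names.extend(names)
        collection.add(GeneSet(name=gs.name, members=frozenset(names),
                               description=f"simulated {gs.shape} pathway"))
        truth["pathways"][gs.name] = {
            "shape": gs.shape,
            "effect_size": gs.effect_size,
            "b0": b0,
            "slopes": slopes,
            "true_tcds_t": analytic_tcds(gs.shape),
        }
    if not rows:
        raise ValueError("spec contains no gene sets")
    latent = np.vstack(rows)
    if spec.omics_type == "counts":
        lib = np.exp(rng.normal(0.0, 0.1, size=n))
        mu = (2.0**latent) * lib[None, :]
        if spec.nb_dispersion > 0:
            r = 1.0 / spec.nb_dispersion
            expr = rng.negative_binomial(r, r / (r + mu)).astype(float)
        else:
            expr = rng.poisson(mu).astype(float)
    else:
        expr = latent
    matrix = pd.DataFrame(expr, index=gene_names, columns=sample_ids)
    dataset = align_dataset(
        matrix, dict(zip(sample_ids, doses)), omics_type=spec.omics_type,
        feature_id_kind="simulated gene",
    )
    truth["t_positions"] = t
    truth["model_dose_range"] = None  # filled by callers after dose transform
    return dataset, collection, truth


def simulate_null_suite(
    n_pathways: int,
    n_genes: int = 15,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[DoseResponseDataset, GeneSetCollection, dict]:
    """All-flat pathways (gene random intercepts only) for type-I studies."""
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    sets = tuple(
        GeneSetSim(name=f"null{i:03d}", n_genes=n_genes, shape="flat", effect_size=0.0)
        for i in range(n_pathways)
    )
    spec = SimulationSpec(genesets=sets, seed=seed, **spec_kwargs)
    return simulate_dataset(spec)
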