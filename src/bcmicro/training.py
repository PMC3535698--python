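"""Estimation of the fusion model from a labeled score table.

Training has three parts:

1. the twelve class-conditional score densities (one per tool per class),
   fitted by maximum likelihood on the non-missing scores of that class;
2. the per-tool reporting rates p(s_i | y), estimated by counting which
   labeled pairs each tool scored;
3. the class prior p(y=1), taken from the label fractions unless pinned
   by configuration (e.g. to a published genome-wide estimate).

The module also provides the predicate used to build high-confidence
negative pairs from miRNA over-expression microarrays: a gene qualifies
as a negative target when it is up-regulated with differential-expression
p-value strictly below 0.001 and linear fold change strictly above 1.5
(both thresholds configurable, boundaries excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cond_dists import FITTERS
from .errors import ConfigError, FitError, InsufficientDataError
from .fusion import RATE_FLOOR, FusionModel, ReportingRates, ToolModel
from .score_io import ExpressionRecord, ScoreTable

#: Default family assignment per tool and class, following the shapes of
#: the published score histograms: TargetScan context scores are left-
#: skewed (reflected Gamma in both classes); miRanda alignment scores are
#: integer-like (Negative Binomial); PicTar scores are right-skewed
#: positive (Gamma); mirTarget probabilities are bimodal in positives
#: (2-component Gaussian mixture) and decay-shaped in negatives
#: (Exponential); PITA energies are roughly normal; Diana-microT scores
#: are decay-shaped in both classes (Exponential).
DEFAULT_FAMILIES: dict[str, dict[str, dict]] = {
    "TargetScan": {
        "positive": {"family": "gamma_reflected"},
        "negative": {"family": "gamma_reflected"},
    },
    "miRanda": {
        "positive": {"family": "negative_binomial", "scale": 1.0},
        "negative": {"family": "negative_binomial", "scale": 1.0},
    },
    "PicTar": {
        "positive": {"family": "gamma"},
        "negative": {"family": "gamma"},
    },
    "mirTarget": {
        "positive": {"family": "gaussian_mixture_2"},
        "negative": {"family": "exponential_shifted"},
    },
    "PITA": {
        "positive": {"family": "gaussian"},
        "negative": {"family": "gaussian"},
    },
    "Diana-microT": {
        "positive": {"family": "exponential_shifted"},
        "negative": {"family": "exponential_shifted"},
    },
}


@dataclass
class TrainingConfig:
    """Knobs for model estimation and negative-set construction."""

    families: dict[str, dict[str, dict]] = field(
        default_factory=lambda: DEFAULT_FAMILIES
    )
    p_value_threshold: float = 0.001
    fold_change_threshold: float = 1.5
    rate_floor: float = RATE_FLOOR
    prior_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value_threshold < 1.0:
            raise ValueError("p_value_threshold must lie in (0, 1)")
        if not self.fold_change_threshold > 0:
            raise ValueError("fold_change_threshold must be positive")
        if self.prior_override is not None and not 0 < self.prior_override < 1:
            raise ValueError("prior_override must lie in open (0, 1)")


def estimate_reporting_rates(
    table: ScoreTable, floor: float = RATE_FLOOR
) -> list[ReportingRates]:
    """Per-tool reporting rates by counting scored pairs per class.

    tpr_i is the fraction of labeled positives for which tool i reported
    any score; fpr_i likewise over the labeled negatives.
    """
    labels = table.labels
    pos = labels == 1.0
    neg = labels == 0.0
    if not pos.any() or not neg.any():
        raise InsufficientDataError(
            "need at least one labeled positive and one labeled negative"
        )
    x = table.score_matrix
    present = ~np.isnan(x)
    rates = []
    for i in range(len(table.tool_names)):
        tpr = float(present[pos, i].mean())
        fpr = float(present[neg, i].mean())
        rates.append(ReportingRates.from_positive_rates(tpr, fpr))
    return rates


def estimate_prior(n_positive: int, n_total: int) -> float:
    """Fraction of true pairs among all pairs in a reference set."""
    if not 0 < n_positive < n_total:
        raise ValueError(
            f"need 0 < n_positive < n_total, got {n_positive}/{n_total}"
        )
    return n_positive / n_total


def negative_pair_filter(rec: ExpressionRecord, cfg: TrainingConfig) -> bool:
    """True iff the gene qualifies as a high-confidence negative target.

    Requires up-regulation under miRNA over-expression with p-value
    strictly below and fold change strictly above the configured
    thresholds; boundary values are excluded.
    """
    return (
        rec.direction == "up"
        and rec.p_value < cfg.p_value_threshold
        and rec.fold_change > cfg.fold_change_threshold
    )


def _fit_conditional(scores: np.ndarray, spec: dict, seed: int):
    spec = dict(spec)
    family = spec.pop("family")
    if family not in FITTERS:
        raise ConfigError(f"unknown family {family!r}")
    fitter = FITTERS[family]
    if family == "gaussian_mixture_2":
        spec.setdefault("seed", seed)
    return fitter(scores, **spec)


def train_model(
    table: ScoreTable, cfg: TrainingConfig | None = None, seed: int = 0
) -> FusionModel:
    """Fit prior, reporting rates and all per-tool conditionals."""
    cfg = cfg or TrainingConfig()
    labels = table.labels
    pos = labels == 1.0
    neg = labels == 0.0
    rates = estimate_reporting_rates(table, cfg.rate_floor)
    x = table.score_matrix
    tools: list[ToolModel] = []
    for i, name in enumerate(table.tool_names):
        if name not in cfg.families:
            raise ConfigError(f"no family assignment for tool {name!r}")
        fams = cfg.families[name]
        col = x[:, i]
        fitted = {}
        for cls, mask in (("positive", pos), ("negative", neg)):
            scores = col[mask & ~np.isnan(col)]
            try:
                fitted[cls] = _fit_conditional(scores, fams[cls], seed)
            except (InsufficientDataError, FitError) as exc:
                raise type(exc)(f"tool {name!r}, class {cls}: {exc}") from exc
        tools.append(ToolModel(name, fitted["positive"], fitted["negative"], rates[i]))
    if cfg.prior_override is not None:
        prior = cfg.prior_override
    else:
        prior = estimate_prior(int(pos.sum()), int(pos.sum() + neg.sum()))
    return FusionModel(prior=prior, tools=tools)
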