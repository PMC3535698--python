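"""Bayesian-network decision fusion of per-tool prediction scores.

The model: a latent class ``y`` (1 = the mRNA is a true target of the
miRNA) with prior ``p(y=1)``; conditionally on ``y`` the K tools are
independent.  Each tool i either reports a score (indicator ``s_i = 1``,
with class-conditional reporting rates TPR/FPR) or stays silent
(``s_i = 0``, rates FNR/TNR), and a reported score has class-conditional
density ``p(x_i | s_i=1, y)``.  Marginalizing the indicator, the per-tool
likelihood factor is

    p(x_i | y) = density_y(x_i) * p(s_i=1 | y)   if a score is present,
    p(x_i | y) = p(s_i=0 | y)                    if the score is missing,

because a present score is impossible under ``s_i = 0`` and a missing one
impossible under ``s_i = 1``.  The posterior follows from Bayes' rule;
all products are computed as sums of logs with a log-sum-exp guard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .cond_dists import FittedConditional, density
from .errors import ConfigError
from .score_io import ScoreRecord, ScoreTable

#: Reporting rates of exactly 0 or 1 are clamped into this open interval
#: before logs are taken; empirical rates from small references can be
#: degenerate.
RATE_FLOOR = 1e-9


def _clamp(rate: float, floor: float = RATE_FLOOR) -> float:
    return min(max(rate, floor), 1.0 - floor)


@dataclass(frozen=True)
class ReportingRates:
    """Per-tool score-reporting probabilities p(s_i | y).

    tpr = p(s=1|y=1), fnr = p(s=0|y=1), fpr = p(s=1|y=0), tnr = p(s=0|y=0).
    """

    tpr: float
    fpr: float
    tnr: float
    fnr: float

    def __post_init__(self) -> None:
        for name in ("tpr", "fpr", "tnr", "fnr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.tpr + self.fnr - 1.0) > 1e-12:
            raise ValueError("tpr + fnr must equal 1")
        if abs(self.fpr + self.tnr - 1.0) > 1e-12:
            raise ValueError("fpr + tnr must equal 1")

    @classmethod
    def from_positive_rates(cls, tpr: float, fpr: float) -> "ReportingRates":
        return cls(tpr=tpr, fpr=fpr, tnr=1.0 - fpr, fnr=1.0 - tpr)


@dataclass
class ToolModel:
    """One tool's fitted conditionals and reporting rates."""

    name: str
    positive: FittedConditional
    negative: FittedConditional
    rates: ReportingRates


@dataclass
class FusionModel:
    """Prior plus per-tool models, in canonical tool order."""

    prior: float
    tools: list[ToolModel]

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior {self.prior} outside open (0, 1)")

    @property
    def tool_names(self) -> list[str]:
        return [t.name for t in self.tools]


@dataclass
class PosteriorResult:
    """Posterior p(y=1 | x) with its per-class log-likelihoods."""

    posterior: float
    loglik_pos: float
    loglik_neg: float
    tool_log_factors: list[tuple[float, float]]  # (log p(x_i|y=1), log p(x_i|y=0))


def tool_log_factor(
    model: FusionModel, tool_index: int, score: float, y: int
) -> float:
    """log p(x_i | y): one marginalized likelihood factor."""
    tool = model.tools[tool_index]
    r = tool.rates
    if isinstance(score, float) and math.isnan(score):
        absent = r.fnr if y == 1 else r.tnr
        return math.log(_clamp(absent))
    cond = tool.positive if y == 1 else tool.negative
    present = r.tpr if y == 1 else r.fpr
    return float(np.log(density(cond, score))) + math.log(_clamp(present))


def posterior(model: FusionModel, record: ScoreRecord) -> PosteriorResult:
    """Posterior target probability for one record, in log space."""
    if len(record.scores) != len(model.tools):
        raise ValueError(
            f"record has {len(record.scores)} scores for "
            f"{len(model.tools)} tools"
        )
    factors = [
        (
            tool_log_factor(model, i, float(x), 1),
            tool_log_factor(model, i, float(x), 0),
        )
        for i, x in enumerate(record.scores)
    ]
    loglik_pos = sum(f[0] for f in factors)
    loglik_neg = sum(f[1] for f in factors)
    lp = math.log(model.prior) + loglik_pos
    ln = math.log1p(-model.prior) + loglik_neg
    post = math.exp(lp - np.logaddexp(lp, ln))
    return PosteriorResult(post, loglik_pos, loglik_neg, factors)


def posterior_batch(model: FusionModel, table: ScoreTable) -> np.ndarray:
    """Vectorized posteriors for every record, order preserved."""
    if table.tool_names != model.tool_names:
        raise ConfigError(
            f"table tools {table.tool_names} do not match model tools "
            f"{model.tool_names}"
        )
    n = len(table)
    if n == 0:
        return np.empty(0)
    x = table.score_matrix
    loglik_pos = np.zeros(n)
    loglik_neg = np.zeros(n)
    for i, tool in enumerate(model.tools):
        col = x[:, i]
        present = ~np.isnan(col)
        r = tool.rates
        lf1 = np.full(n, math.log(_clamp(r.fnr)))
        lf0 = np.full(n, math.log(_clamp(r.tnr)))
        if present.any():
            xs = col[present]
            lf1[present] = np.log(density(tool.positive, xs)) + math.log(
                _clamp(r.tpr)
            )
            lf0[present] = np.log(density(tool.negative, xs)) + math.log(
                _clamp(r.fpr)
            )
        loglik_pos += lf1
        loglik_neg += lf0
    lp = math.log(model.prior) + loglik_pos
    ln = math.log1p(-model.prior) + loglik_neg
    return np.exp(lp - np.logaddexp(lp, ln))


# ---------------------------------------------------------------------------
# Serialization: human-readable YAML round-trip of a fitted model.

def _py(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, (list, tuple)):
        return [_py(v) for v in value]
    if isinstance(value, dict):
        return {k: _py(v) for k, v in value.items()}
    return value


def _fc_to_dict(fc: FittedConditional) -> dict:
    return {
        "family": fc.family,
        "params": _py(fc.params),
        "transform": _py(fc.transform),
        "n_fit": int(fc.n_fit),
        "floor": float(fc.floor),
    }


def _fc_from_dict(d: dict) -> FittedConditional:
    return FittedConditional(
        d["family"], d["params"], d.get("transform", {}),
        n_fit=d.get("n_fit", 0), floor=d.get("floor", 1e-12),
    )


def model_to_dict(model: FusionModel) -> dict:
    return {
        "prior": float(model.prior),
        "tools": [
            {
                "name": t.name,
                "rates": {
                    "tpr": float(t.rates.tpr),
                    "fpr": float(t.rates.fpr),
                    "tnr": float(t.rates.tnr),
                    "fnr": float(t.rates.fnr),
                },
                "positive": _fc_to_dict(t.positive),
                "negative": _fc_to_dict(t.negative),
            }
            for t in model.tools
        ],
    }


def model_from_dict(d: dict) -> FusionModel:
    tools = [
        ToolModel(
            name=td["name"],
            positive=_fc_from_dict(td["positive"]),
            negative=_fc_from_dict(td["negative"]),
            rates=ReportingRates(**td["rates"]),
        )
        for td in d["tools"]
    ]
    return FusionModel(prior=d["prior"], tools=tools)


def save_model(model: FusionModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> FusionModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
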