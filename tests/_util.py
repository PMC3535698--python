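"""Shared test helpers: random model construction and independent oracles.

The oracles here deliberately avoid the package's log-space code paths:
``naive_posterior`` multiplies plain probabilities, ``mann_whitney_auc``
counts concordant pairs, and ``naive_downfold_area`` is a double loop.
"""

import math

import numpy as np

from bcmicro.cond_dists import FittedConditional, density, sample
from bcmicro.fusion import FusionModel, ReportingRates, ToolModel
from bcmicro.score_io import ScoreRecord

FAMILY_NAMES = (
    "gamma",
    "gamma_reflected",
    "negative_binomial",
    "gaussian",
    "gaussian_mixture_2",
    "exponential_shifted",
)


def random_conditional(rng: np.random.Generator) -> FittedConditional:
    fam = FAMILY_NAMES[rng.integers(len(FAMILY_NAMES))]
    if fam == "gamma":
        return FittedConditional(
            fam,
            {"shape": rng.uniform(0.5, 5), "scale": rng.uniform(0.2, 3)},
            {"shift": rng.uniform(-2, 2)},
        )
    if fam == "gamma_reflected":
        return FittedConditional(
            fam,
            {"shape": rng.uniform(0.5, 5), "scale": rng.uniform(0.2, 3)},
            {"reflection": rng.uniform(-1, 1)},
        )
    if fam == "negative_binomial":
        return FittedConditional(
            fam,
            {"size": rng.uniform(0.5, 10), "prob": rng.uniform(0.1, 0.8)},
            {"shift": rng.uniform(-5, 5), "scale": float(rng.choice([0.5, 1.0, 2.0]))},
        )
    if fam == "gaussian":
        return FittedConditional(
            fam, {"mean": rng.uniform(-5, 5), "sd": rng.uniform(0.3, 3)}
        )
    if fam == "gaussian_mixture_2":
        means = sorted(rng.uniform(-5, 5, 2))
        w = rng.uniform(0.2, 0.8)
        return FittedConditional(
            fam,
            {
                "weights": [w, 1 - w],
                "means": [float(m) for m in means],
                "sds": [rng.uniform(0.3, 2), rng.uniform(0.3, 2)],
            },
        )
    return FittedConditional(
        "exponential_shifted",
        {"rate": rng.uniform(0.2, 4)},
        {"shift": rng.uniform(-2, 2)},
    )


def random_model(rng: np.random.Generator, k: int | None = None) -> FusionModel:
    if k is None:
        k = int(rng.integers(3, 7))
    tools = [
        ToolModel(
            f"tool{i}",
            random_conditional(rng),
            random_conditional(rng),
            ReportingRates.from_positive_rates(
                rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95)
            ),
        )
        for i in range(k)
    ]
    return FusionModel(prior=rng.uniform(0.01, 0.9), tools=tools)


def random_record(
    rng: np.random.Generator, model: FusionModel, missing_p: float = 0.3
) -> ScoreRecord:
    scores = np.empty(len(model.tools))
    for i, tool in enumerate(model.tools):
        if rng.random() < missing_p:
            scores[i] = math.nan
        else:
            cond = tool.positive if rng.random() < 0.5 else tool.negative
            scores[i] = sample(cond, 1, rng)[0]
    return ScoreRecord("miR-x", f"g{rng.integers(10**9)}", scores)


def naive_posterior(model: FusionModel, record: ScoreRecord) -> float:
    """Bayes' rule in direct probabilities (no logs, no log-sum-exp)."""

    def clamp(r):
        return min(max(r, 1e-9), 1 - 1e-9)

    def likelihood(y: int) -> float:
        v = 1.0
        for tool, x in zip(model.tools, record.scores):
            r = tool.rates
            if math.isnan(x):
                v *= clamp(r.fnr) if y else clamp(r.tnr)
            else:
                cond = tool.positive if y else tool.negative
                present = clamp(r.tpr) if y else clamp(r.fpr)
                v *= float(density(cond, x)) * present
        return v

    a = model.prior * likelihood(1)
    b = (1 - model.prior) * likelihood(0)
    return a / (a + b)


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise concordance over all positive-negative pairs (ties = 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_downfold_area(fold_changes, n: int) -> float:
    """A(n) by the literal double sum over ranks."""
    total = 0.0
    for t in range(1, n + 1):
        c_t = 0.0
        for j in range(t):
            c_t += fold_changes[j]
        total += c_t
    return total
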