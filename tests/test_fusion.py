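"""Posterior fusion: oracle equivalence, closed forms, invariances."""

import math

import numpy as np
import pytest

from _util import naive_posterior, random_model, random_record

from bcmicro.cond_dists import FittedConditional
from bcmicro.errors import ConfigError
from bcmicro.fusion import (
    FusionModel,
    ReportingRates,
    ToolModel,
    load_model,
    model_from_dict,
    model_to_dict,
    posterior,
    posterior_batch,
    save_model,
    tool_log_factor,
)
from bcmicro.reference import REFERENCE_PRIOR, reference_rates
from bcmicro.score_io import ScoreRecord, ScoreTable
from bcmicro.synthetic import generate, reference_spec, spec_to_model


def _sym_model(k=3, prior=0.5):
    """Identical positive/negative behavior for every tool."""
    cond = FittedConditional("gaussian", {"mean": 0.0, "sd": 1.0})
    rates = ReportingRates.from_positive_rates(0.6, 0.6)
    tools = [ToolModel(f"t{i}", cond, cond, rates) for i in range(k)]
    return FusionModel(prior=prior, tools=tools)


def test_log_space_posterior_matches_direct_bayes_oracle():
    """1,000 random small models/records: log-space vs plain probability."""
    rng = np.random.default_rng(2024)
    worst = 0.0
    for _ in range(1000):
        model = random_model(rng)
        record = random_record(rng, model)
        got = posterior(model, record).posterior
        want = naive_posterior(model, record)
        worst = max(worst, abs(got - want) / max(want, 1e-300))
    assert worst <= 1e-10


def test_all_missing_record_closed_form():
    """Six missing scores reduce to prior*prod(FNR) vs (1-prior)*prod(TNR)."""
    model = spec_to_model(reference_spec())
    rec = ScoreRecord("miR-124", "G", [math.nan] * 6)
    rates = reference_rates()
    num = REFERENCE_PRIOR * math.prod(r.fnr for r in rates.values())
    den = num + (1 - REFERENCE_PRIOR) * math.prod(r.tnr for r in rates.values())
    expected = num / den
    assert expected == pytest.approx(1.18e-3, abs=2e-5)  # sanity on magnitude
    assert posterior(model, rec).posterior == pytest.approx(expected, abs=1e-12)


def test_tool_log_factor_values():
    model = spec_to_model(reference_spec())
    # missing TargetScan score under y=1 contributes log FNR
    assert tool_log_factor(model, 0, math.nan, 1) == pytest.approx(
        math.log(0.5918), abs=1e-12
    )
    # present score: log(density) + log(reporting rate)
    cond = FittedConditional("exponential_shifted", {"rate": 1.0}, {"shift": 0.0})
    m = FusionModel(
        prior=0.5,
        tools=[ToolModel("t", cond, cond, ReportingRates.from_positive_rates(1.0, 0.5))],
    )
    assert tool_log_factor(m, 0, 0.0, 1) == pytest.approx(0.0, abs=1e-8)
    m2 = FusionModel(
        prior=0.5,
        tools=[ToolModel("t", cond, cond, ReportingRates.from_positive_rates(0.5, 0.5))],
    )
    # density(0.2|exp rate 1) * 0.5 -> log(e^-0.2 * 0.5)
    assert tool_log_factor(m2, 0, 0.2, 1) == pytest.approx(
        math.log(math.exp(-0.2) * 0.5), abs=1e-12
    )


def test_symmetric_model_gives_half():
    model = _sym_model()
    for scores in ([0.3, -1.0, math.nan], [math.nan] * 3, [0.0, 0.0, 0.0]):
        assert posterior(model, ScoreRecord("m", "g", scores)).posterior == (
            pytest.approx(0.5, abs=1e-12)
        )


def test_posterior_normalization_and_determinism():
    rng = np.random.default_rng(7)
    for _ in range(200):
        model = random_model(rng)
        record = random_record(rng, model)
        res = posterior(model, record)
        # complement computed by swapping the class roles
        swapped = FusionModel(
            prior=1 - model.prior,
            tools=[
                ToolModel(t.name, t.negative, t.positive,
                          ReportingRates(t.rates.fpr, t.rates.tpr,
                                         t.rates.fnr, t.rates.tnr))
                for t in model.tools
            ],
        )
        comp = posterior(swapped, record).posterior
        assert res.posterior + comp == pytest.approx(1.0, abs=1e-12)
        assert posterior(model, record).posterior == res.posterior


def test_monotone_in_single_tool_likelihood_ratio():
    """Moving one tool's positive density toward the observed score
    strictly increases the posterior; everything else fixed."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        base = random_model(rng, k=int(rng.integers(2, 5)))
        k = len(base.tools)
        scores = random_record(rng, base, missing_p=0.2).scores
        j = int(rng.integers(k))
        scores[j] = 0.0
        neg = FittedConditional("gaussian", {"mean": 1.0, "sd": 1.0})
        last = None
        for mean in (4.0, 2.0, 1.0, 0.5, 0.0):
            tools = list(base.tools)
            tools[j] = ToolModel(
                tools[j].name,
                FittedConditional("gaussian", {"mean": mean, "sd": 1.0}),
                neg,
                tools[j].rates,
            )
            p = posterior(FusionModel(base.prior, tools),
                          ScoreRecord("m", "g", scores)).posterior
            if last is not None:
                assert p > last
            last = p


def test_prior_limits():
    """With fixed finite log-factors the posterior is driven to 0 / 1 by
    the prior, and is monotone in the prior throughout."""
    model = _sym_model(k=4, prior=0.5)
    record = ScoreRecord("m", "g", [0.3, -1.2, math.nan, 0.8])

    def with_prior(pr):
        return posterior(FusionModel(pr, model.tools), record).posterior

    assert with_prior(1e-12) < 1e-6
    assert with_prior(1 - 1e-12) > 1 - 1e-6
    priors = [1e-6, 1e-3, 0.1, 0.5, 0.9, 0.999]
    values = [with_prior(p) for p in priors]
    assert all(a < b for a, b in zip(values, values[1:]))


def test_uninformative_tool_leaves_posterior_unchanged():
    rng = np.random.default_rng(13)
    model = random_model(rng, k=4)
    cond = FittedConditional("gaussian", {"mean": 0.0, "sd": 2.0})
    flat = ToolModel("flat", cond, cond, ReportingRates.from_positive_rates(0.5, 0.5))
    bigger = FusionModel(model.prior, model.tools + [flat])
    for _ in range(20):
        rec = random_record(rng, model)
        rec_b = ScoreRecord(rec.mirna_id, rec.gene_id,
                            np.r_[rec.scores, rng.normal()], rec.label)
        assert posterior(bigger, rec_b).posterior == pytest.approx(
            posterior(model, rec).posterior, abs=1e-12
        )


def test_batch_equals_loop_and_preserves_order():
    spec = reference_spec(n=1000, seed=5)
    table = generate(spec)
    model = spec_to_model(spec)
    batch = posterior_batch(model, table)
    loop = np.array([posterior(model, r).posterior for r in table.records])
    np.testing.assert_allclose(batch, loop, rtol=1e-12, atol=0)


def test_batch_edge_cases():
    model = _sym_model()
    empty = ScoreTable([t.name for t in model.tools], [])
    assert len(posterior_batch(model, empty)) == 0

    twice = ScoreTable(
        [t.name for t in model.tools],
        [ScoreRecord("m", "g1", [1.0, math.nan, 0.2]),
         ScoreRecord("m", "g2", [1.0, math.nan, 0.2])],
    )
    out = posterior_batch(model, twice)
    assert out[0] == out[1]

    wrong = ScoreTable(["x", "y", "z"], [])
    with pytest.raises(ConfigError):
        posterior_batch(model, wrong)


def test_model_yaml_round_trip(tmp_path):
    model = spec_to_model(reference_spec())
    path = tmp_path / "model.yaml"
    save_model(model, path)
    back = load_model(path)
    assert model_to_dict(back) == model_to_dict(model)
    rec = ScoreRecord("m", "g", [0.0, 150.0, math.nan, 80.0, -8.0, 1.0])
    assert posterior(back, rec).posterior == posterior(model, rec).posterior


def test_extreme_rates_are_clamped_not_crashing():
    cond = FittedConditional("gaussian", {"mean": 0.0, "sd": 1.0})
    tools = [ToolModel("t", cond, cond, ReportingRates.from_positive_rates(1.0, 0.0))]
    model = FusionModel(0.5, tools)
    p_missing = posterior(model, ScoreRecord("m", "g", [math.nan])).posterior
    assert 0.0 < p_missing < 1.0
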