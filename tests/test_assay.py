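"""Reaction norms, plasticity calls, noise estimation, and summaries."""

import math
from dataclasses import dataclass, field

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plastisim.assay import (
    AssayConfig,
    assay_genotype,
    classify_plastic,
    developmental_noise,
    reaction_norm,
    summarize_experiment,
)
from plastisim.development import develop_batch
from plastisim.fixtures import make_fixture
from plastisim.genome import Genotype


def test_classify_plastic_threshold_cases():
    assert classify_plastic(1000.0, 1500.0, 400.0) is True
    assert classify_plastic(1000.0, 1400.0, 400.0) is False  # strict inequality
    assert classify_plastic(1500.0, 1000.0, 400.0) is True   # direction-free
    with pytest.raises(ValueError):
        classify_plastic(0.0, 0.0, 0.0)


@given(
    a=st.floats(-1e5, 1e5),
    b=st.floats(-1e5, 1e5),
    d=st.floats(1e-3, 1e4),
)
@settings(max_examples=200, deadline=None)
def test_classify_plastic_symmetric(a, b, d):
    assert classify_plastic(a, b, d) == classify_plastic(b, a, d)


def test_reaction_norm_no_signal_is_exactly_flat(params):
    g = make_fixture("constitutive")
    ml, mh = reaction_norm(g, "no_signal", AssayConfig(n_redevelop=40), params,
                           np.random.default_rng(0))
    assert ml == mh


def test_reaction_norm_env_toggle_is_plastic(params):
    g = make_fixture("env_toggle")
    cfg = AssayConfig(n_redevelop=800)
    res = assay_genotype(g, "environmental_signal", cfg, params, np.random.default_rng(1))
    assert res.mean_high - res.mean_low > 400.0
    assert res.is_plastic


def test_reaction_norm_minimal_sample(params):
    g = make_fixture("constitutive")
    ml, mh = reaction_norm(g, "no_signal", AssayConfig(n_redevelop=2), params,
                           np.random.default_rng(2))
    assert np.isfinite(ml) and ml == mh


def test_noise_zero_when_development_is_deterministic(params):
    # no phenotype genes: every redevelopment realizes exactly 0
    g = Genotype()
    sd = developmental_noise(g, "no_signal", AssayConfig(n_redevelop=50), params,
                             np.random.default_rng(3))
    assert sd == 0.0


def test_noise_uses_sample_sd_convention(params):
    """developmental_noise reproduces the n-1 sample SD of the same
    development stream (e.g. {900, 1100} -> ~141.42)."""
    assert float(np.std([900.0, 1100.0], ddof=1)) == pytest.approx(141.4213562)
    g = make_fixture("constitutive")
    cfg = AssayConfig(n_redevelop=2)
    sd = developmental_noise(g, "no_signal", cfg, params, np.random.default_rng(7))
    vals = develop_batch(g, "none", 1000.0, 2, params, np.random.default_rng(7))
    assert sd == pytest.approx(float(np.std(vals, ddof=1)))


def test_noise_estimate_consistency(params):
    """The scatter of the SD estimate shrinks like 1/sqrt(n_redevelop)."""
    g = make_fixture("constitutive")
    rng = np.random.default_rng(11)

    def sd_scatter(n, k=12):
        sds = [
            float(np.std(develop_batch(g, "none", 1000.0, n, params, rng), ddof=1))
            for _ in range(k)
        ]
        return np.std(sds, ddof=1)

    s_small, s_big = sd_scatter(150), sd_scatter(600)
    ratio = s_small / s_big  # expected 2 for a 4x sample-size increase
    assert 1.2 < ratio < 3.4


def test_no_signal_misclassification_is_negligible(params):
    """With independent streams per environment, a nonplastic genotype's
    estimated |mean_high - mean_low| is far below the threshold: the normal
    oracle puts the misclassification probability at essentially zero."""
    g = make_fixture("constitutive")
    rng = np.random.default_rng(13)
    n = 200
    diffs = []
    for _ in range(10):
        lo = develop_batch(g, "none", 1000.0, n, params, rng)
        hi = develop_batch(g, "none", 3000.0, n, params, rng)
        diffs.append(abs(hi.mean() - lo.mean()))
    diffs = np.asarray(diffs)
    assert np.all(diffs < 400.0)
    sd_diff = math.sqrt(2) * 45.0 / math.sqrt(n)  # generous per-dev SD bound
    assert stats.norm.sf(400.0, scale=sd_diff) < 1e-9


# ---------------------------------------------------------------------------
# experiment summaries


@dataclass
class FakeRecord:
    treatment: str
    environment_model: str
    founder_plastic: bool
    final_plastic: bool
    final_noise: float
    gene_counts: dict = field(default_factory=dict)


def _cell(treatment, env, plastic_flags, noises, founder_plastic=None):
    founder_plastic = founder_plastic or [False] * len(plastic_flags)
    return [
        FakeRecord(treatment, env, fp, pl, nz)
        for fp, pl, nz in zip(founder_plastic, plastic_flags, noises)
    ]


def test_fisher_exact_against_hypergeometric_enumeration():
    """0/10 vs 10/10 plastic: the two-sided Fisher p equals the exact
    hypergeometric tail, 2/C(20,10) = 1/92378."""
    recs = _cell("no_signal", "constant_low", [False] * 10, np.linspace(30, 40, 10))
    recs += _cell("performance_signal", "constant_low", [True] * 10, np.linspace(35, 45, 10))
    tables = summarize_experiment(recs)
    p = tables["fisher"]["p"].iloc[0]

    # brute-force oracle: P(X <= 0) + P(X >= 10) for X ~ Hypergeom(20, 10, 10)
    oracle = stats.hypergeom.pmf(0, 20, 10, 10) + stats.hypergeom.pmf(10, 20, 10, 10)
    assert p == pytest.approx(oracle, rel=1e-12)
    assert p == pytest.approx(1.0 / 92378.0, rel=1e-9)


def test_welch_on_identical_noise_samples():
    noises = [30.0, 35.0, 40.0, 45.0]
    recs = _cell("no_signal", "constant_low", [False] * 4, noises)
    recs += _cell("environmental_signal", "constant_low", [False] * 4, noises)
    tables = summarize_experiment(recs)
    row = tables["welch"].iloc[0]
    assert row["t"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0)


def test_fractions_reported_including_and_excluding_started_plastic():
    recs = _cell(
        "performance_signal",
        "constant_low",
        plastic_flags=[True, True, False, False, True],
        noises=[50, 60, 30, 35, 55],
        founder_plastic=[True, False, False, False, False],
    )
    tables = summarize_experiment(recs)
    row = tables["summary"].iloc[0]
    assert row["n_replicates"] == 5
    assert row["frac_plastic_all"] == pytest.approx(3 / 5)
    assert row["n_start_nonplastic"] == 4
    assert row["frac_plastic_excl_start_plastic"] == pytest.approx(2 / 4)
    # noise means split by final plasticity
    assert row["noise_plastic_mean"] == pytest.approx(55.0)
    assert row["noise_nonplastic_mean"] == pytest.approx(32.5)


def test_empty_cell_reports_nan_not_dropped():
    recs = _cell("environmental_signal", "constant_low", [False], [40.0])
    expected = [("no_signal", "constant_low"), ("environmental_signal", "constant_low")]
    tables = summarize_experiment(recs, expected_cells=expected)
    # the declared-but-empty cell appears as an explicit all-NaN row
    assert len(tables["summary"]) == 2
    empty_row = tables["summary"].set_index("treatment").loc["no_signal"]
    assert empty_row["n_replicates"] == 0
    assert np.isnan(empty_row["frac_plastic_all"])
    # fisher with an empty side is NaN
    recs_a = _cell("no_signal", "constant_low", [False, False], [40.0, 41.0],
                   founder_plastic=[True, True])  # all started plastic -> excluded
    recs_a += _cell("environmental_signal", "constant_low", [False, True], [40.0, 90.0])
    t2 = summarize_experiment(recs_a)
    assert np.isnan(t2["fisher"]["p"].iloc[0])
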