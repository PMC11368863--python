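"""NB differential expression: dispersion estimation, Wald test, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copath import (
    PlantedPath,
    SimulationConfig,
    bh_adjust,
    estimate_dispersion,
    simulate_counts,
    test_contrast,
)
from copath.design import SampleDesign


def one_group_sim(mu, alpha, n_reps, seed):
    """A single-condition dataset: every sample is baseline-like."""
    config = SimulationConfig(
        n_genes=1,
        n_reps_per_condition=n_reps,
        baseline_mean_range=(mu, mu),
        dispersion=alpha,
        planted_paths=(),
        seed=seed,
    )
    return simulate_counts(config)


# ---------------------------------------------------------------------------
# bh_adjust


def test_bh_hand_computed_step_up():
    # p=[.01,.02,.03], m=3: q_(i) = min over j>=i of p_(j)*m/j = .03 for all
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_edge_cases_and_errors():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.1, np.nan])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


def test_bh_is_order_preserving_and_monotone():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=100)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    # order preserved: permuting inputs permutes outputs identically
    perm = rng.permutation(100)
    assert np.allclose(bh_adjust(p[perm]), q[perm])


# ---------------------------------------------------------------------------
# dispersion estimation


def test_dispersion_poisson_gene_estimates_near_zero():
    counts, design, _ = one_group_sim(mu=200.0, alpha=0.0, n_reps=1000, seed=21)
    disp = estimate_dispersion(counts, design)
    assert disp["alpha_raw"].iloc[0] <= 0.01


def test_dispersion_nb_gene_recovers_alpha():
    counts, design, _ = one_group_sim(mu=100.0, alpha=0.5, n_reps=10_000, seed=22)
    disp = estimate_dispersion(counts, design)
    assert disp["alpha_raw"].iloc[0] == pytest.approx(0.5, rel=0.10)


def test_dispersion_constant_counts_and_all_zero_genes():
    m = pd.DataFrame(
        [[7, 7, 7, 7], [0, 0, 0, 0]],
        index=["const", "zero"],
        columns=["a", "b", "c", "d"],
    )
    design = SampleDesign({s: "baseline" for s in m.columns})
    disp = estimate_dispersion(m, design)
    assert disp.loc["const", "alpha_raw"] == 0.0
    assert disp.loc["zero", "alpha"] == 0.0
    assert bool(disp.loc["zero", "all_zero"])
    assert not bool(disp.loc["const", "all_zero"])


def test_dispersion_requires_replication():
    m = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
    design = SampleDesign({"a": "baseline", "b": "injured_vehicle"})
    with pytest.raises(ValueError, match="replicates"):
        estimate_dispersion(m, design)


# ---------------------------------------------------------------------------
# Wald contrast test


def test_identical_groups_give_zero_lfc_and_p_one():
    rng = np.random.default_rng(23)
    block = rng.poisson(100.0, size=(30, 4))
    m = pd.DataFrame(
        np.hstack([block, block]),
        index=[f"g{i}" for i in range(30)],
        columns=[f"b{j}" for j in range(4)] + [f"c{j}" for j in range(4)],
    )
    design = SampleDesign(
        {f"b{j}": "baseline" for j in range(4)}
        | {f"c{j}": "injured_vehicle" for j in range(4)}
    )
    res = test_contrast(m, design, "IV", pd.Series(0.1, index=m.index))
    assert (res["log2FC"] == 0).all()
    assert (res["pvalue"] == 1.0).all()


def test_unknown_contrast_and_missing_condition_errors(null_run):
    design = null_run["design"]
    m = null_run["normalized"]
    with pytest.raises(ValueError, match="unknown contrast"):
        test_contrast(m, design, "XX", null_run["config"].dispersion)
    partial = SampleDesign(
        {s: c for s, c in design.condition_of.items() if c != "injured_vehicle"}
    )
    with pytest.raises(ValueError):
        test_contrast(m, partial, "IV", pd.Series(0.1, index=m.index))


def test_null_type_one_error_is_calibrated(null_run):
    res = test_contrast(
        null_run["normalized"], null_run["design"], "IV",
        estimate_dispersion(null_run["normalized"], null_run["design"]),
    )
    frac = float((res["pvalue"] <= 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_null_pvalues_are_approximately_uniform(null_run):
    res = test_contrast(
        null_run["normalized"], null_run["design"], "IV",
        estimate_dispersion(null_run["normalized"], null_run["design"]),
    )
    ks = stats.kstest(res["pvalue"], "uniform").statistic
    assert ks < 0.05


def test_power_on_planted_fold_change_exceeds_ninety_percent():
    config = SimulationConfig(
        n_genes=2000,
        baseline_mean_range=(200.0, 200.0),
        dispersion=0.1,
        planted_paths=(PlantedPath(("0", "+", "0"), 500, 2.0),),
        seed=3,
    )
    counts, design, truth = simulate_counts(config)
    res = test_contrast(counts, design, "IV", estimate_dispersion(counts, design))
    planted = truth["state_IV"] == "+"
    power = float((res.loc[planted.to_numpy(), "padj"] <= 0.05).mean())
    assert power > 0.9


def test_contrast_is_invariant_to_sample_column_order(planted_run):
    m, design, disp = (
        planted_run["normalized"],
        planted_run["design"],
        planted_run["dispersions"],
    )
    rng = np.random.default_rng(1)
    shuffled = m[rng.permutation(m.columns)]
    a = test_contrast(m, design, "IC", disp)
    b = test_contrast(shuffled, design, "IC", disp)
    pd.testing.assert_frame_equal(a, b)


def test_wald_agrees_with_poisson_glm_at_zero_dispersion():
    """Independent oracle: statsmodels Poisson GLM on each gene."""
    import statsmodels.api as sm

    config = SimulationConfig(
        n_genes=100,
        baseline_mean_range=(500.0, 5000.0),
        dispersion=0.0,
        planted_paths=(PlantedPath(("0", "+", "0"), 30, 1.0),),
        seed=5,
    )
    counts, design, _ = simulate_counts(config)
    mine = test_contrast(counts, design, "IV", pd.Series(0.0, index=counts.index))
    base = design.samples_for("baseline")
    cond = design.samples_for("injured_vehicle")
    X = sm.add_constant(np.r_[np.zeros(len(base)), np.ones(len(cond))])
    deltas = []
    for gene in counts.index:
        y = np.concatenate([counts.loc[gene, base], counts.loc[gene, cond]])
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        deltas.append(abs(fit.pvalues[1] - mine.loc[gene, "pvalue"]))
    assert max(deltas) < 0.01
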