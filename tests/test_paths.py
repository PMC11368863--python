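"""State calling, the 26-event catalog, path selection and gene assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from copath import (
    StateCallConfig,
    assign_genes,
    call_states,
    enumerate_events,
    mirror_triple,
    select_ligand_paths,
)
from copath.paths import ANCHOR_ALIASES, call_state, summarize_paths


def calls_frame(triples):
    return pd.DataFrame(
        [{"state_NC": a, "state_IV": b, "state_IC": c} for a, b, c in triples],
        index=[f"g{i}" for i in range(len(triples))],
    )


# ---------------------------------------------------------------------------
# catalog enumeration


def test_catalog_has_26_nonnull_events_in_stable_order():
    cat = enumerate_events()
    assert len(cat.events) == 26
    assert ("0", "0", "0") not in cat.events
    assert len(set(cat.events)) == 26
    assert [cat.ids[t] for t in cat.events] == [f"path{i:02d}" for i in range(1, 27)]
    # deterministic across calls
    assert enumerate_events().events == cat.events


def test_two_state_alphabet_hook_gives_seven_events():
    cat = enumerate_events(alphabet=("+", "0"))
    assert len(cat.events) == 7


def test_anchor_triples_carry_their_conventional_aliases():
    cat = enumerate_events()
    assert cat.alias_of(("0", "0", "+")) == "path2"
    assert cat.alias_of(("0", "+", "0")) == "path4"
    assert cat.alias_of(("0", "-", "0")) == "path5"
    assert cat.alias_of(("0", "0", "-")) == "path7"


# ---------------------------------------------------------------------------
# selection rules


def test_default_rule_selects_eight_paths_including_all_anchors():
    cat = select_ligand_paths(enumerate_events())
    assert len(cat.selected) == 8
    assert set(ANCHOR_ALIASES) <= cat.selected


def test_iv_ne_ic_rule_matches_brute_force_enumeration():
    # oracle: count triples with differing IV and IC states over all 27
    expected = {
        t
        for t in itertools.product("+0-", repeat=3)
        if t[1] != t[2] and t != ("0", "0", "0")
    }
    assert len(expected) == 18
    cat = select_ligand_paths(enumerate_events(), "iv_ne_ic")
    assert cat.selected == frozenset(expected)


def test_explicit_triple_list_and_null_rejection():
    cat = select_ligand_paths(enumerate_events(), [("0", "+", "0")])
    assert cat.selected == frozenset({("0", "+", "0")})
    with pytest.raises(ValueError, match="null"):
        select_ligand_paths(enumerate_events(), [("0", "0", "0")])
    with pytest.raises(ValueError, match="unknown selection rule"):
        select_ligand_paths(enumerate_events(), "no_such_rule")


# ---------------------------------------------------------------------------
# state calling


@pytest.mark.parametrize(
    "lfc, q, expected",
    [
        (2.0, 0.01, "+"),
        (-0.2, 0.001, "0"),  # significant but below the effect threshold
        (-1.5, 0.04, "-"),
        (1.5, 0.2, "0"),  # large effect but not significant
        (1.0, 0.05, "+"),  # boundary: thresholds are inclusive
    ],
)
def test_call_state_threshold_rules(lfc, q, expected):
    assert call_state(lfc, q) == expected


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.floats(-5, 5),
    st.floats(0.001, 0.999),
    st.floats(0.1, 3),
)
def test_call_state_monotone_in_effect_size(lfc, q, bump):
    """Increasing |log2FC| at fixed q never moves a +/- call back to 0."""
    cfg = StateCallConfig()
    before = call_state(lfc, q, cfg)
    after = call_state(lfc + np.sign(lfc or 1) * bump, q, cfg)
    if before in "+-":
        assert after == before


def test_call_states_vector_matches_scalar(planted_run):
    calls = call_states(planted_run["de"])
    res = planted_run["de"]["IV"]
    sample = res.sample(50, random_state=0)
    for gene, row in sample.iterrows():
        assert calls.loc[gene, "state_IV"] == call_state(row["log2FC"], row["padj"])


# ---------------------------------------------------------------------------
# assignment


def test_homogeneous_genes_all_land_in_the_alias_path():
    cat = select_ligand_paths(enumerate_events())
    calls = calls_frame([("0", "+", "0")] * 5)
    assign = assign_genes(calls, cat)
    assert (assign["path_id"] == cat.ids[("0", "+", "0")]).all()
    assert (assign["alias"] == "path4").all()
    summary = summarize_paths(assign, cat)
    assert summary.loc[summary["alias"] == "path4", "n_genes"].item() == 5
    assert summary.loc[summary["alias"] != "path4", "n_genes"].sum() == 0


def test_assignment_is_a_partition(planted_run, default_catalog):
    calls = call_states(planted_run["de"])
    assign = assign_genes(calls, default_catalog)
    assert len(assign) == len(calls)
    assert assign["gene_id"].is_unique
    summary = summarize_paths(assign, default_catalog)
    assert summary["n_genes"].sum() == len(calls)


def test_missing_contrast_call_names_the_gene():
    cat = enumerate_events()
    calls = calls_frame([("0", "+", "0"), ("0", "0", "0")])
    calls.loc["g1", "state_IV"] = None
    with pytest.raises(ValueError, match="g1"):
        assign_genes(calls, cat)


def test_sign_mirror_symmetry_of_calls_and_paths(planted_run, default_catalog):
    """Negating every log2FC swaps + and - calls and mirrors path ids."""
    de = planted_run["de"]
    mirrored_de = {
        c: r.assign(log2FC=-r["log2FC"]) for c, r in de.items()
    }
    calls = call_states(de)
    mirrored_calls = call_states(mirrored_de)
    flip = {"+": "-", "-": "+", "0": "0"}
    for col in calls.columns:
        assert (mirrored_calls[col] == calls[col].map(flip)).all()
    a = assign_genes(calls, default_catalog).set_index("gene_id")
    b = assign_genes(mirrored_calls, default_catalog).set_index("gene_id")
    state_cols = ["state_NC", "state_IV", "state_IC"]
    mirrored_states = a[state_cols].apply(lambda col: col.map(flip))
    pd.testing.assert_frame_equal(b.loc[a.index, state_cols], mirrored_states)
    # each path maps to its sign-mirrored path
    mirror_id = {
        default_catalog.ids[t]: default_catalog.ids[mirror_triple(t)]
        for t in default_catalog.events
    } | {"unchanged": "unchanged"}
    assert (b.loc[a.index, "path_id"] == a["path_id"].map(mirror_id)).all()


def test_mirror_triple_is_an_involution():
    for t in enumerate_events().events:
        assert mirror_triple(mirror_triple(t)) == t
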