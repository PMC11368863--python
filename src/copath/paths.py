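"""Combinatorial co-expression paths over discrete expression states.

Each gene is stratified per contrast into one of three states -- induced
(``+``), non-differentially expressed (``0``) or repressed (``-``) -- giving
a state triple over the three treated-vs-baseline contrasts (NC, IV, IC).
Excluding the all-null triple, 3**3 - 1 = 26 combinatorial co-expression
events remain.  A configurable selection rule flags the subset from which an
effect of the drug in injured tissue can be inferred ("ligand-informative"
paths); four of those carry the conventional aliases:

* path2 = (0, 0, +)  drug-specific induction in injured tissue
* path4 = (0, +, 0)  injury-induced genes returned to baseline by the drug
* path5 = (0, -, 0)  injury-repressed genes returned to baseline by the drug
* path7 = (0, 0, -)  drug-specific repression in injured tissue
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from copath.design import CONTRASTS

Triple = tuple[str, ...]

#: enumeration order of states: + < 0 < -
STATE_ORDER: tuple[str, ...] = ("+", "0", "-")

ANCHOR_ALIASES: dict[Triple, str] = {
    ("0", "0", "+"): "path2",
    ("0", "+", "0"): "path4",
    ("0", "-", "0"): "path5",
    ("0", "0", "-"): "path7",
}

UNCHANGED = "unchanged"


@dataclass(frozen=True)
class StateCallConfig:
    """Thresholds for discretising a DE result into a state.

    A gene is called ``+``/``-`` when its BH-adjusted p-value is at most
    ``q_threshold`` and |log2FC| is at least ``lfc_threshold``; otherwise
    ``0``.  The defaults (0.05, 1.0) are conventional choices, surfaced in
    the run configuration.
    """

    q_threshold: float = 0.05
    lfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")


@dataclass(frozen=True)
class PathCatalog:
    """Ordered catalog of non-null state triples with stable path ids."""

    events: tuple[Triple, ...]
    ids: dict[Triple, str] = field(compare=False)
    aliases: dict[Triple, str] = field(compare=False)
    selected: frozenset[Triple] = frozenset()

    def id_of(self, triple: Triple) -> str:
        return self.ids[triple]

    def alias_of(self, triple: Triple) -> str:
        return self.aliases.get(triple, "")

    def selected_events(self) -> list[Triple]:
        return [t for t in self.events if t in self.selected]


def enumerate_events(
    alphabet: Sequence[str] = STATE_ORDER, n_positions: int = 3
) -> PathCatalog:
    """Enumerate all non-null state tuples in stable lexicographic order.

    With the default three-state alphabet over three contrasts this yields
    exactly 26 events with ids ``path01`` ... ``path26``; the all-``0``
    tuple is excluded as the null event.  The alphabet and tuple length are
    exposed as a generic hook (e.g. a two-state alphabet gives 2**3 - 1 = 7
    events).
    """
    if "0" not in alphabet:
        raise ValueError("alphabet must contain the null state '0'")
    null = tuple("0" for _ in range(n_positions))
    events = tuple(
        t for t in itertools.product(alphabet, repeat=n_positions) if t != null
    )
    width = max(2, len(str(len(events))))
    ids = {t: f"path{i + 1:0{width}d}" for i, t in enumerate(events)}
    aliases = {t: a for t, a in ANCHOR_ALIASES.items() if t in ids}
    return PathCatalog(events=events, ids=ids, aliases=aliases)


# ---------------------------------------------------------------------------
# selection rules

SelectionRule = Callable[[Triple], bool]


def _default_rule(t: Triple) -> bool:
    # drug effect inferable in injured tissue: quiet in non-injured+drug and
    # injury response altered by the drug, plus the two consistent
    # injury-independent drug responses
    return (t[0] == "0" and t[1] != t[2]) or t in {("+", "0", "+"), ("-", "0", "-")}


def _iv_ne_ic_rule(t: Triple) -> bool:
    return t[1] != t[2]


NAMED_RULES: dict[str, SelectionRule] = {
    "default": _default_rule,
    "iv_ne_ic": _iv_ne_ic_rule,
}


def select_ligand_paths(
    catalog: PathCatalog,
    rule: str | SelectionRule | Iterable[Triple] = "default",
) -> PathCatalog:
    """Flag the ligand-informative subset of the catalog.

    ``rule`` is a named rule (``"default"`` selects the 8 paths described in
    the module docstring), a predicate over triples, or an explicit iterable
    of triples.  Selecting the null triple is an error.
    """
    if isinstance(rule, str):
        try:
            predicate = NAMED_RULES[rule]
        except KeyError:
            raise ValueError(f"unknown selection rule {rule!r}") from None
        selected = frozenset(t for t in catalog.events if predicate(t))
    elif callable(rule):
        selected = frozenset(t for t in catalog.events if rule(t))
    else:
        selected = frozenset(tuple(t) for t in rule)
        null = tuple("0" for _ in range(len(catalog.events[0])))
        if null in selected:
            raise ValueError("selection rule must not include the null triple")
        unknown = selected - set(catalog.events)
        if unknown:
            raise ValueError(f"selected triples not in catalog: {sorted(unknown)}")
    return replace(catalog, selected=selected)


# ---------------------------------------------------------------------------
# state calling and assignment


def call_state(log2fc: float, q: float, cfg: StateCallConfig = StateCallConfig()) -> str:
    """Discretise one DE result into ``+``, ``0`` or ``-``."""
    if q <= cfg.q_threshold and log2fc >= cfg.lfc_threshold:
        return "+"
    if q <= cfg.q_threshold and log2fc <= -cfg.lfc_threshold:
        return "-"
    return "0"


def call_states(
    de_results: dict[str, pd.DataFrame],
    cfg: StateCallConfig = StateCallConfig(),
) -> pd.DataFrame:
    """Vectorised state calls for all genes over all three contrasts.

    Returns a DataFrame indexed by gene with columns ``state_NC``,
    ``state_IV``, ``state_IC``.
    """
    missing = [c for c in CONTRASTS if c not in de_results]
    if missing:
        raise ValueError(f"missing DE results for contrast(s): {', '.join(missing)}")
    calls = {}
    index = de_results[CONTRASTS[0]].index
    for c in CONTRASTS:
        res = de_results[c]
        if not res.index.equals(index):
            raise ValueError("DE result tables are not aligned on the same genes")
        lfc = res["log2FC"].to_numpy()
        q = res["padj"].to_numpy()
        sig = q <= cfg.q_threshold
        state = np.where(
            sig & (lfc >= cfg.lfc_threshold),
            "+",
            np.where(sig & (lfc <= -cfg.lfc_threshold), "-", "0"),
        )
        calls[f"state_{c}"] = state
    return pd.DataFrame(calls, index=index)


def assign_genes(calls: pd.DataFrame, catalog: PathCatalog) -> pd.DataFrame:
    """Assign each gene to exactly one path (or the ``unchanged`` bucket).

    ``calls`` must hold one complete state triple per gene (columns
    ``state_NC``, ``state_IV``, ``state_IC``).  The output is a partition:
    every gene appears exactly once, null-triple genes under the path id
    ``unchanged``.
    """
    cols = [f"state_{c}" for c in CONTRASTS]
    missing_cols = set(cols) - set(calls.columns)
    if missing_cols:
        raise ValueError(f"calls missing column(s): {', '.join(sorted(missing_cols))}")
    bad = calls[cols].isna().any(axis=1)
    if bad.any():
        examples = ", ".join(map(str, calls.index[bad][:5]))
        raise ValueError(f"gene(s) with missing contrast call: {examples}")

    n_positions = len(cols)
    null = tuple("0" for _ in range(n_positions))
    triples = list(zip(*(calls[c] for c in cols)))
    unknown = {t for t in triples if t != null} - set(catalog.events)
    if unknown:
        raise ValueError(f"state triple(s) outside the catalog: {sorted(unknown)}")

    path_ids = [UNCHANGED if t == null else catalog.ids[t] for t in triples]
    aliases = ["" if t == null else catalog.aliases.get(t, "") for t in triples]
    selected = [t != null and t in catalog.selected for t in triples]
    out = pd.DataFrame(
        {
            "gene_id": calls.index.astype(str),
            **{c: calls[c].to_numpy() for c in cols},
            "path_id": path_ids,
            "alias": aliases,
            "selected": selected,
        },
    )
    # partition identity is a runtime assertion on every call
    assert len(out) == len(calls) and not out["gene_id"].duplicated().any()
    return out


def summarize_paths(assignments: pd.DataFrame, catalog: PathCatalog) -> pd.DataFrame:
    """Per-path gene counts over the full catalog (zero-filled), plus the
    ``unchanged`` bucket last."""
    counts = assignments["path_id"].value_counts()
    rows = []
    for t in catalog.events:
        pid = catalog.ids[t]
        rows.append(
            {
                "path_id": pid,
                "triple": "".join(t),
                "alias": catalog.aliases.get(t, ""),
                "selected": t in catalog.selected,
                "n_genes": int(counts.get(pid, 0)),
            }
        )
    rows.append(
        {
            "path_id": UNCHANGED,
            "triple": "0" * len(catalog.events[0]),
            "alias": "",
            "selected": False,
            "n_genes": int(counts.get(UNCHANGED, 0)),
        }
    )
    summary = pd.DataFrame(rows)
    assert summary["n_genes"].sum() == len(assignments)
    return summary


def mirror_triple(t: Triple) -> Triple:
    """Sign mirror: swap + and -, fix 0."""
    flip = {"+": "-", "-": "+", "0": "0"}
    return tuple(flip[s] for s in t)
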