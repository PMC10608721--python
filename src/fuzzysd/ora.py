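"""Qualitative over-representation analysis of metabolite hit lists.

Given the metabolites named by a set of discovered rules ("hits") and a
collection of metabolite sets (pathways), each set is tested with the
one-tailed hypergeometric test: is the overlap between hits and set
larger than expected when drawing ``|hits|`` metabolites at random from
the universe?  The enrichment ratio is observed/expected overlap, and
p-values are adjusted across sets with Benjamini-Hochberg.

Name matching is exact and case-insensitive; synonym resolution is the
caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import fdrcorrection


@dataclass
class MetaboliteSetCollection:
    sets: dict[str, frozenset[str]]       # lowercased member names
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("no metabolite sets")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"metabolite set {name!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"set {name!r} contains metabolites outside the universe")


def make_collection(
    sets: dict[str, Iterable[str]], universe: Iterable[str] | None = None
) -> MetaboliteSetCollection:
    """Build a collection; universe defaults to the union of all sets."""
    norm = {name: frozenset(m.strip().lower() for m in members) for name, members in sets.items()}
    if universe is None:
        uni = frozenset().union(*norm.values()) if norm else frozenset()
    else:
        uni = frozenset(m.strip().lower() for m in universe)
    return MetaboliteSetCollection(sets=norm, universe=uni)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> MetaboliteSetCollection:
    """GMT format: one set per line, ``name <tab> description <tab> members...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = parts[2:]
    return make_collection(sets, universe)


def read_hits(path: str | Path) -> list[str]:
    """Plain text, one metabolite per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def ora_test(hits: Sequence[str], collection: MetaboliteSetCollection) -> pd.DataFrame:
    """Per-set enrichment: observed, expected, ER, raw p, BH-adjusted p.

    Raw p is the upper-tail hypergeometric ``P(X >= max(observed, 1))``
    so zero-overlap sets report p = 1 instead of spurious significance.
    """
    matched = sorted({h.strip().lower() for h in hits} & collection.universe)
    if not matched:
        raise ValueError("no hits matched the universe")
    M = len(collection.universe)
    k = len(matched)
    rows = []
    for name, members in collection.sets.items():
        m = len(members)
        observed = len(members & set(matched))
        expected = k * m / M
        er = observed / expected if expected > 0 else 0.0
        p = float(hypergeom.sf(max(observed, 1) - 1, M, m, k))
        rows.append({"set": name, "size": m, "observed": observed,
                     "expected": expected, "ER": er, "raw_p": p})
    df = pd.DataFrame(rows)
    _, adj = fdrcorrection(df["raw_p"].to_numpy())
    df["FDR"] = adj
    return df.sort_values("raw_p", kind="stable").reset_index(drop=True)
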