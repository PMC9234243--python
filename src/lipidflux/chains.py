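"""Acyl-chain occurrence and composition analytics, class distributions.

Two distinct counting semantics are implemented deliberately:

* *occurrence* — how many lipid species contain a given chain at least
  once (a TG carrying 18:2 twice still counts once for 18:2), broken
  down by lipid class;
* *composition* — among the lipids increased in cold, what percentage of
  all chain *slots* a given chain occupies (multiplicity counts), with a
  display filter hiding chains below a minimum share.

Sum-composition species (e.g. PC 34:4), whose individual chains are
unknown, never enter per-chain tallies; they are reported in an explicit
``unresolved`` bucket instead of being dropped silently.  Sphingoid
bases count as chains by default (an 18:0 sphingoid base is an 18:0
signature).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

import pandas as pd

from .nomenclature import LipidName, canonical_key, chains_of, parse_lipid_name

__all__ = ["chain_occurrence", "increased_chain_composition", "class_distribution"]

logger = logging.getLogger(__name__)


def _as_names(lipids) -> list[LipidName]:
    names = [l if isinstance(l, LipidName) else parse_lipid_name(str(l)) for l in lipids]
    seen: dict[str, LipidName] = {}
    for n in names:
        seen.setdefault(canonical_key(n), n)
    return list(seen.values())


def chain_occurrence(lipids, include_sphingoid: bool = True) -> pd.DataFrame:
    """Number of lipid species containing each chain, by lipid class.

    Input is deduplicated by canonical key, so the tally is invariant to
    input order and repeated identities.  Rows are chain tokens (e.g.
    ``18:2``) plus an ``unresolved`` row for sum-composition species;
    columns are lipid classes plus a ``total`` column equal to the class
    sum.
    """
    names = _as_names(lipids)
    per_chain: dict[str, Counter] = defaultdict(Counter)
    unresolved = Counter()
    for name in names:
        if not name.resolved:
            unresolved[name.lipid_class] += 1
            continue
        tokens = {
            f"{c.carbons}:{c.double_bonds}"
            for c in chains_of(name, include_sphingoid)
        }
        for tok in tokens:  # containment: once per species per chain
            per_chain[tok][name.lipid_class] += 1

    classes = sorted({cls for ctr in per_chain.values() for cls in ctr} | set(unresolved))
    rows = {}
    for tok in sorted(per_chain, key=lambda s: (int(s.split(":")[0]), int(s.split(":")[1]))):
        rows[tok] = {cls: per_chain[tok].get(cls, 0) for cls in classes}
    if unresolved:
        rows["unresolved"] = {cls: unresolved.get(cls, 0) for cls in classes}
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int).fillna(0).astype(int)
    table["total"] = table.sum(axis=1)
    return table


def increased_chain_composition(
    increased, min_share: float = 0.05, include_sphingoid: bool = True
) -> pd.DataFrame:
    """Percentage chain composition of the cold-increased lipid set.

    Chain *slots* are counted with multiplicity across the resolved
    increased lipids and normalized to 100%.  Rows below ``min_share``
    (fraction, default 5%) are hidden from the headline table but kept in
    the full output: returns a DataFrame with columns ``percent`` and
    ``shown``.  Percentages over all rows always sum to 100.
    """
    names = _as_names(increased)
    slots = Counter()
    for name in names:
        if not name.resolved:
            continue
        for c in chains_of(name, include_sphingoid):
            slots[f"{c.carbons}:{c.double_bonds}"] += 1
    if not slots:
        logger.info("increased_chain_composition: no resolved increased lipids")
        return pd.DataFrame(columns=["percent", "shown"])
    total = sum(slots.values())
    toks = sorted(slots, key=lambda s: (int(s.split(":")[0]), int(s.split(":")[1])))
    out = pd.DataFrame(
        {
            "percent": [100.0 * slots[t] / total for t in toks],
            "shown": [slots[t] / total >= min_share for t in toks],
        },
        index=toks,
    )
    return out


def class_distribution(groups: dict[str, list]) -> pd.DataFrame:
    """Unique species count per lipid class for each named group.

    ``groups`` maps a group label (tissue, extraction method, ...) to its
    lipid list.  Returns classes x groups counts with a ``total`` row;
    each group's total equals its number of unique canonical keys (classes
    partition the lipids, no double counting).
    """
    counts: dict[str, Counter] = {}
    for label, lipids in groups.items():
        ctr = Counter()
        for name in _as_names(lipids):
            ctr[name.lipid_class] += 1
        counts[label] = ctr
    classes = sorted({cls for ctr in counts.values() for cls in ctr})
    table = pd.DataFrame(
        {label: [counts[label].get(cls, 0) for cls in classes] for label in counts},
        index=classes,
        dtype=int,
    )
    table.loc["total"] = table.sum(axis=0)
    return table
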