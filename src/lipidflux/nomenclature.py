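"""Shorthand lipid nomenclature: parsing, canonical keys, chain extraction.

The dialect handled here is the underscore shorthand common in LC-MS
lipidomics exports: ``Class[_subclass] [d|t]C:D[_C:D...]``, e.g.::

    ACar 18:0            one acyl chain, resolved
    Cer_NS d18:1_23:0    sphingoid base d18:1 plus 23:0 N-acyl, resolved
    PC 34:4              sum composition (individual chains unknown)
    TG 18:1_18:2_16:0    three acyl chains, resolved

A name is *resolved* when every constituent chain is known individually;
a single ``C:D`` on a class that carries several chains is a *sum
composition* and is treated as a distinct identity (no chain inference
is ever attempted from a sum).  Sphingoid bases are flagged by the
``d``/``t`` hydroxylation prefix and carry the ``sphingoid`` role.

Ether/oxidized species (``PC O-34:2``, ``PE P-36:4``) are accepted as
opaque identities: the class token is recognized, the chain detail is
kept verbatim and the name is flagged unresolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "AcylChain",
    "LipidName",
    "LipidParseError",
    "parse_lipid_name",
    "canonical_key",
    "chains_of",
    "register_lipid_class",
    "lipid_class_of",
]


class LipidParseError(ValueError):
    """Raised when a shorthand lipid name does not fit the grammar.

    Carries the offending token so callers can report exactly what failed
    instead of silently guessing an identity.
    """

    def __init__(self, raw: str, token: str, reason: str):
        self.raw = raw
        self.token = token
        self.reason = reason
        super().__init__(f"cannot parse lipid name {raw!r}: {reason} (token {token!r})")


# Expected number of chains per recognized class token.  Single-chain
# classes resolve from one C:D token; multi-chain classes read a single
# C:D token as a sum composition.
_CLASS_CHAIN_COUNTS: dict[str, int] = {
    # single chain
    "ACar": 1, "CAR": 1, "FA": 1, "CE": 1, "MG": 1, "SPB": 1,
    "LPC": 1, "LPE": 1, "LPI": 1, "LPS": 1, "LPG": 1, "LPA": 1,
    # two chains
    "PC": 2, "PE": 2, "PI": 2, "PS": 2, "PG": 2, "PA": 2,
    "DG": 2, "SM": 2, "Cer": 2, "HexCer": 2, "Hex2Cer": 2, "DhCer": 2,
    # three / four chains
    "TG": 3, "CL": 4,
}

_SPHINGOLIPID_CLASSES = {"Cer", "HexCer", "Hex2Cer", "DhCer", "SM", "SPB"}

_CHAIN_RE = re.compile(r"^([dt]?)(\d+):(\d+)$")
_ETHER_RE = re.compile(r"^[OP]-\d+:\d+")

_ROLE_ORDER = {"sphingoid": 0, "acyl": 1, "sum": 2}


def register_lipid_class(token: str, n_chains: int) -> None:
    """Extend the class registry (e.g. for a vendor-specific token)."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    _CLASS_CHAIN_COUNTS[token] = n_chains


@dataclass(frozen=True, order=True)
class AcylChain:
    """One fatty-acyl or sphingoid chain, ``carbons:double_bonds``.

    ``hydroxylation`` keeps the shorthand prefix (``d`` = di-hydroxy
    sphingoid base, ``t`` = tri-hydroxy); ``role`` is ``acyl``,
    ``sphingoid`` or ``sum`` (an unresolved total composition).
    """

    carbons: int
    double_bonds: int
    role: str = "acyl"
    hydroxylation: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"double_bonds ({self.double_bonds}) exceeds carbons ({self.carbons})"
            )
        if self.role not in _ROLE_ORDER:
            raise ValueError(f"unknown chain role {self.role!r}")

    @property
    def token(self) -> str:
        return f"{self.hydroxylation or ''}{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


@dataclass(frozen=True)
class LipidName:
    """Parsed identity of a shorthand lipid name."""

    raw: str
    lipid_class: str
    subclass: str | None
    chains: tuple[AcylChain, ...]
    resolved: bool
    unparsed_detail: str | None = None  # ether/oxidized chain text kept verbatim

    @property
    def class_token(self) -> str:
        return self.lipid_class if self.subclass is None else f"{self.lipid_class}_{self.subclass}"

    def render(self) -> str:
        """Re-emit the shorthand form (a fixed point under re-parsing)."""
        if self.unparsed_detail is not None:
            return f"{self.class_token} {self.unparsed_detail}"
        return f"{self.class_token} " + "_".join(c.token for c in self.chains)

    def __str__(self) -> str:
        return self.render()


def _parse_chain(raw: str, token: str) -> AcylChain:
    m = _CHAIN_RE.match(token)
    if m is None:
        raise LipidParseError(raw, token, "chain token is not [d|t]C:D")
    prefix, carbons, dbs = m.group(1), int(m.group(2)), int(m.group(3))
    role = "sphingoid" if prefix else "acyl"
    try:
        return AcylChain(carbons, dbs, role=role, hydroxylation=prefix or None)
    except ValueError as exc:
        raise LipidParseError(raw, token, str(exc)) from exc


def parse_lipid_name(raw: str) -> LipidName:
    """Parse a shorthand lipid name into a structured :class:`LipidName`.

    Unrecognized grammar raises :class:`LipidParseError`; the parser never
    guesses.  See the module docstring for the dialect.
    """
    if not raw or not raw.strip():
        raise LipidParseError(raw, raw, "empty name")
    text = raw.strip()
    head, sep, tail = text.partition(" ")
    if not sep or not tail.strip():
        raise LipidParseError(raw, text, "expected '<class> <chains>'")
    chain_part = tail.strip()

    if "_" in head:
        lipid_class, subclass = head.split("_", 1)
    else:
        lipid_class, subclass = head, None
    if lipid_class not in _CLASS_CHAIN_COUNTS:
        raise LipidParseError(raw, lipid_class, "unknown lipid class token")

    if _ETHER_RE.match(chain_part):
        # ether/plasmalogen detail is kept opaque and unresolved
        return LipidName(raw, lipid_class, subclass, (), False, unparsed_detail=chain_part)

    chains = tuple(_parse_chain(raw, tok) for tok in chain_part.split("_"))
    expected = _CLASS_CHAIN_COUNTS[lipid_class]

    if len(chains) == expected:
        resolved = True
    elif len(chains) == 1 and expected > 1:
        only = chains[0]
        if only.hydroxylation is not None:
            raise LipidParseError(raw, only.token, "sum composition cannot carry a sphingoid prefix")
        chains = (AcylChain(only.carbons, only.double_bonds, role="sum"),)
        resolved = False
    else:
        raise LipidParseError(
            raw, chain_part, f"{lipid_class} expects {expected} chains, found {len(chains)}"
        )

    n_sphingoid = sum(1 for c in chains if c.role == "sphingoid")
    if n_sphingoid and lipid_class not in _SPHINGOLIPID_CLASSES:
        raise LipidParseError(raw, chain_part, f"{lipid_class} cannot carry a sphingoid base")
    if n_sphingoid > 1:
        raise LipidParseError(raw, chain_part, "more than one sphingoid base")

    return LipidName(raw, lipid_class, subclass, chains, resolved)


def canonical_key(name: LipidName, *, ignore_subclass: bool = False) -> str:
    """Canonical identity string; invariant to chain order for resolved species.

    ``ignore_subclass=True`` lets ``Cer d18:1_22:0`` and ``Cer_NS d18:1_22:0``
    share a key when the two spellings are known to denote one annotation
    stream.  Sum and resolved compositions are always distinct identities.
    """
    head = name.lipid_class if ignore_subclass else name.class_token
    if name.unparsed_detail is not None:
        return f"{head} {name.unparsed_detail}"
    ordered = sorted(
        name.chains,
        key=lambda c: (_ROLE_ORDER[c.role], c.carbons, c.double_bonds, c.hydroxylation or ""),
    )
    return f"{head} " + "_".join(c.token for c in ordered)


def chains_of(name: LipidName, include_sphingoid: bool = True) -> tuple[AcylChain, ...]:
    """All chains of a lipid as a multiset (tuple preserves multiplicity).

    Sphingoid bases count by default — an 18:0 sphingoid base tallies as an
    18:0 chain, which is how ceramide chain signatures are read — and can be
    excluded with ``include_sphingoid=False``.  Sum chains are returned with
    role ``sum``.
    """
    if include_sphingoid:
        return name.chains
    return tuple(c for c in name.chains if c.role != "sphingoid")


def lipid_class_of(raw_or_name: str | LipidName) -> str:
    """Class token of a raw shorthand string or parsed name."""
    name = raw_or_name if isinstance(raw_or_name, LipidName) else parse_lipid_name(raw_or_name)
    return name.lipid_class
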