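"""Parsing and classification of lipid shorthand species names.

Targeted lipidomics panels report species under shorthand names such as
``PC 38:4`` (sum composition), ``DG 18:0_18:2`` (two chains, sn-position
unknown), ``Cer d18:1/18:0`` (sphingoid base + N-acyl chain, sn-resolved)
or ``S1P d16:1`` (sphingoid base only).  Every downstream rule in this
package — class grouping, double-bond stratification, ether/plasmalogen
handling — is driven by the structured fields produced here rather than by
string matching.

The class vocabulary is closed by default (the twenty classes covered by
the phospholipid/CE/DG, sphingolipid, S1P and TG panels) but can be
extended per call for non-standard catalogs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Optional, Tuple

__all__ = [
    "LIPID_CLASSES",
    "SPHINGOID_CLASSES",
    "Linkage",
    "ChainSeparator",
    "SaturationGroup",
    "LipidNameError",
    "ParsedLipidName",
    "parse_lipid_name",
    "saturation_group",
]

#: Closed default class vocabulary (extensible via ``extra_classes``).
LIPID_CLASSES: Tuple[str, ...] = (
    "Cer", "Hex1Cer", "Hex2Cer", "GM3", "SM", "S1P",
    "LPC", "LPC-O", "PC", "PC-O", "PC-P",
    "LPE", "PE", "PE-O", "PE-P",
    "PI", "PS", "DG", "TG", "CE",
)

#: Classes built on a sphingoid long-chain base.  SM species are commonly
#: reported as sum compositions without an explicit base; for the other
#: sphingolipid classes the base is part of the name.
SPHINGOID_CLASSES = frozenset({"Cer", "Hex1Cer", "Hex2Cer", "GM3", "SM", "S1P"})

#: Sphingoid classes where the base spec is mandatory in the name.
_BASE_REQUIRED = frozenset({"Cer", "Hex1Cer", "Hex2Cer", "GM3", "S1P"})


class Linkage(str, Enum):
    """Glycerol sn-1 linkage type, encoded in the class token suffix."""

    ACYL = "acyl"
    ETHER = "ether"          # "-O" classes (alkyl ether)
    PLASMALOGEN = "plasmalogen"  # "-P" classes (alkenyl / vinyl ether)


class ChainSeparator(str, Enum):
    SLASH_KNOWN_SN = "slash_known_sn"
    UNDERSCORE_UNKNOWN_SN = "underscore_unknown_sn"
    SUM_COMPOSITION = "sum_composition"


class SaturationGroup(str, Enum):
    """Double-bond stratum of a species within its class."""

    LE3 = "LE3"  # 0-3 total double bonds
    GE4 = "GE4"  # 4 or more


class LipidNameError(ValueError):
    """Raised for names that do not conform to the shorthand grammar."""


_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_BASE_RE = re.compile(r"^d(\d+):(\d+)$")


@dataclass(frozen=True)
class ParsedLipidName:
    """Structured decomposition of a shorthand lipid species name.

    ``total_carbons`` and ``total_double_bonds`` sum over all chains,
    including the sphingoid base when present (so ``Cer d18:1/18:0`` has 36
    carbons and one double bond).  For GM3 the glycan head group is part of
    the class token and contributes no carbons to the totals.
    """

    raw_name: str
    lipid_class: str
    linkage: Linkage
    sphingoid_base: Optional[Tuple[int, int]]
    chains: Tuple[Tuple[int, int], ...]
    chain_separator: ChainSeparator
    total_carbons: int
    total_double_bonds: int

    def format(self) -> str:
        """Re-emit the shorthand name; round-trips ``raw_name`` exactly."""
        parts = []
        if self.sphingoid_base is not None:
            parts.append("d%d:%d" % self.sphingoid_base)
        parts.extend("%d:%d" % chain for chain in self.chains)
        if self.chain_separator is ChainSeparator.SLASH_KNOWN_SN:
            spec = "/".join(parts)
        elif self.chain_separator is ChainSeparator.UNDERSCORE_UNKNOWN_SN:
            spec = "_".join(parts)
        else:
            spec = parts[0]
        return f"{self.lipid_class} {spec}"


def _linkage_of(lipid_class: str) -> Linkage:
    if lipid_class.endswith("-O"):
        return Linkage.ETHER
    if lipid_class.endswith("-P"):
        return Linkage.PLASMALOGEN
    return Linkage.ACYL


@lru_cache(maxsize=4096)
def _parse_cached(name: str, classes: Tuple[str, ...]) -> ParsedLipidName:
    head, sep_char, spec = name.partition(" ")
    if not sep_char or not spec:
        raise LipidNameError(
            f"{name!r}: expected '<class> <chains>' with a single space"
        )
    if head not in classes:
        raise LipidNameError(f"{name!r}: unrecognized lipid class token {head!r}")
    if " " in spec:
        raise LipidNameError(f"{name!r}: malformed chain spec {spec!r}")

    if "/" in spec:
        separator = ChainSeparator.SLASH_KNOWN_SN
        tokens = spec.split("/")
    elif "_" in spec:
        separator = ChainSeparator.UNDERSCORE_UNKNOWN_SN
        tokens = spec.split("_")
    else:
        tokens = [spec]
        separator = ChainSeparator.SUM_COMPOSITION

    base: Optional[Tuple[int, int]] = None
    chains = []
    for i, tok in enumerate(tokens):
        m = _BASE_RE.match(tok)
        if m:
            if head not in SPHINGOID_CLASSES:
                raise LipidNameError(
                    f"{name!r}: sphingoid base {tok!r} not allowed for class {head}"
                )
            if i != 0 or base is not None:
                raise LipidNameError(f"{name!r}: misplaced sphingoid base {tok!r}")
            base = (int(m.group(1)), int(m.group(2)))
            continue
        m = _CHAIN_RE.match(tok)
        if not m:
            raise LipidNameError(f"{name!r}: malformed chain spec fragment {tok!r}")
        chains.append((int(m.group(1)), int(m.group(2))))

    if head in _BASE_REQUIRED and base is None:
        raise LipidNameError(
            f"{name!r}: class {head} requires a sphingoid base (e.g. d18:1)"
        )
    if head == "S1P" and chains:
        raise LipidNameError(f"{name!r}: S1P carries only a sphingoid base")
    if base is not None and len(tokens) == 1:
        # a lone base (S1P d18:1) is structurally fully resolved
        separator = ChainSeparator.SLASH_KNOWN_SN

    total_c = (base[0] if base else 0) + sum(c for c, _ in chains)
    total_db = (base[1] if base else 0) + sum(d for _, d in chains)
    return ParsedLipidName(
        raw_name=name,
        lipid_class=head,
        linkage=_linkage_of(head),
        sphingoid_base=base,
        chains=tuple(chains),
        chain_separator=separator,
        total_carbons=total_c,
        total_double_bonds=total_db,
    )


def parse_lipid_name(name: str, extra_classes: Tuple[str, ...] = ()) -> ParsedLipidName:
    """Parse a shorthand species name into its structured fields.

    Parameters
    ----------
    name
        Species name, e.g. ``"PE-P 18:0/18:2"``.
    extra_classes
        Additional class tokens accepted beyond :data:`LIPID_CLASSES`.

    Raises
    ------
    LipidNameError
        If the class token is unknown or a chain fragment is malformed; the
        message names the offending fragment.
    """
    if not name:
        raise LipidNameError("empty lipid name")
    classes = LIPID_CLASSES + tuple(extra_classes) if extra_classes else LIPID_CLASSES
    return _parse_cached(name, classes)


def saturation_group(
    parsed: ParsedLipidName, cutoff_low: int = 3, cutoff_high: int = 4
) -> SaturationGroup:
    """Assign a species to the ≤``cutoff_low`` or ≥``cutoff_high`` double-bond
    stratum.

    With the default cutoffs (3, 4) every species is assigned; with a gap
    between the cutoffs, species falling in the gap raise ``ValueError``.
    """
    if cutoff_low >= cutoff_high:
        raise ValueError(
            f"cutoff_low ({cutoff_low}) must be below cutoff_high ({cutoff_high})"
        )
    db = parsed.total_double_bonds
    if db <= cutoff_low:
        return SaturationGroup.LE3
    if db >= cutoff_high:
        return SaturationGroup.GE4
    raise ValueError(
        f"{parsed.raw_name}: {db} double bonds falls between cutoffs "
        f"{cutoff_low} and {cutoff_high}"
    )
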