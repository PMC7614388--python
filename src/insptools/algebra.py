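"""Combinatorial algebra of myo-inositol phosphate isomers.

myo-Inositol is a cyclohexane-hexol whose single axial hydroxyl sits at C2;
its internal mirror plane passes through C2 and C5.  Reflection through that
plane exchanges ring positions 1<->3 and 4<->6 while fixing 2 and 5, which is
the enantiomer map acting on 1D position labels.  A phosphorylation state is
therefore just a subset of {1..6} (plus, optionally, which of those positions
carry a diphosphate), and enantiomer/meso questions reduce to set algebra
under that involution.

Names follow the field's 1D convention, e.g. ``Ins(1,4,6)P3`` and, for
pyrophosphates, ``5PP-Ins(1,2,3,4)P4`` where the ``Pn`` suffix counts
monoester positions only.  An isomer and its enantiomer keep their distinct
names; no lowest-locant renaming is applied across mirror images.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass

__all__ = [
    "PhosphoInositol",
    "ENANTIOMER_MAP",
    "RING_POSITIONS",
    "enantiomer",
    "is_meso",
    "parse_name",
    "format_name",
    "enumerate_isomers",
    "isomer_summary",
]

RING_POSITIONS = frozenset({1, 2, 3, 4, 5, 6})

#: The mirror-plane position exchange (sigma): 1<->3, 4<->6, 2 and 5 fixed.
ENANTIOMER_MAP = {1: 3, 2: 2, 3: 1, 4: 6, 5: 5, 6: 4}


@dataclass(frozen=True)
class PhosphoInositol:
    """A phosphorylation state of the myo-inositol ring.

    Parameters
    ----------
    phosphates : frozenset of int
        Ring carbons (1-6) bearing a phosphate group.  May be empty
        (free inositol).
    pyrophosphates : frozenset of int
        Subset of ``phosphates`` whose positions carry a diphosphate
        (pyrophosphate) group, as in 5-InsP7.
    """

    phosphates: frozenset = frozenset()
    pyrophosphates: frozenset = frozenset()

    def __post_init__(self):
        phos = frozenset(self.phosphates)
        pp = frozenset(self.pyrophosphates)
        object.__setattr__(self, "phosphates", phos)
        object.__setattr__(self, "pyrophosphates", pp)
        bad = (phos | pp) - RING_POSITIONS
        if bad:
            raise ValueError(f"ring positions must be in 1-6, got {sorted(bad)}")
        if not pp <= phos:
            raise ValueError(
                "pyrophosphate positions must be a subset of phosphate positions"
            )

    @property
    def n_phosphate_positions(self) -> int:
        """Number of ring positions bearing at least one phosphate."""
        return len(self.phosphates)

    @property
    def n_phosphate_groups(self) -> int:
        """Total phosphate groups counting each diphosphate as two."""
        return len(self.phosphates) + len(self.pyrophosphates)

    @property
    def free_hydroxyls(self) -> frozenset:
        return RING_POSITIONS - self.phosphates

    @property
    def name(self) -> str:
        return format_name(self)

    def __str__(self) -> str:
        return format_name(self)

    def to_json(self) -> str:
        return json.dumps(
            {"positions": sorted(self.phosphates), "pp": sorted(self.pyrophosphates)}
        )

    @classmethod
    def from_json(cls, text: str) -> "PhosphoInositol":
        obj = json.loads(text)
        return cls(frozenset(obj["positions"]), frozenset(obj.get("pp", ())))


def enantiomer(s: PhosphoInositol) -> PhosphoInositol:
    """Mirror image under the C2/C5 plane: positions 1<->3 and 4<->6.

    An involution: ``enantiomer(enantiomer(s)) == s``.
    """
    return PhosphoInositol(
        frozenset(ENANTIOMER_MAP[p] for p in s.phosphates),
        frozenset(ENANTIOMER_MAP[p] for p in s.pyrophosphates),
    )


def is_meso(s: PhosphoInositol) -> bool:
    """True iff the state is its own mirror image (achiral)."""
    return enantiomer(s) == s


_NAME_RE = re.compile(
    r"^(?:(?P<pp>\d+(?:,\d+)*)PP-)?Ins"
    r"(?:\((?P<pos>\d+(?:,\d+)*)\)P(?P<n>\d+)|P(?P<nshort>\d+)|(?P<single>\d)P)?$"
)


def parse_name(name: str) -> PhosphoInositol:
    """Parse a 1D inositol phosphate name into a :class:`PhosphoInositol`.

    Accepted forms: ``Ins`` (free inositol), ``Ins(1,4,6)P3``,
    ``Ins(1,2,3,4,5,6)P6``, the monophosphate shorthand ``Ins1P``, the
    unambiguous shorthands ``InsP6``/``InsP0``, and ``kPP-Ins(p,...)Pn`` for
    pyrophosphates, where the ``Pn`` suffix counts monoester positions only
    (so 5PP-Ins(1,2,3,4)P4 is an InsP7 species).  Subscript markup like
    ``P_3_`` is tolerated.
    """
    cleaned = name.strip().replace("_", "")
    m = _NAME_RE.match(cleaned)
    if not m:
        raise ValueError(f"malformed inositol phosphate name: {name!r}")
    pp_part, pos_part, n_part, n_short = (
        m.group("pp"),
        m.group("pos"),
        m.group("n"),
        m.group("nshort"),
    )
    if m.group("single") is not None:
        if pp_part:
            raise ValueError("pyrophosphate names must use the Ins(p,...)Pn form")
        pos_part, n_part = m.group("single"), "1"
    if n_short is not None:
        n = int(n_short)
        if n == 0:
            positions = []
        elif n == 6:
            positions = [1, 2, 3, 4, 5, 6]
        else:
            raise ValueError(
                f"shorthand InsP{n} is ambiguous; list positions explicitly"
            )
        if pp_part:
            raise ValueError("pyrophosphate names must list monoester positions")
        return PhosphoInositol(frozenset(positions))

    positions = [int(p) for p in pos_part.split(",")] if pos_part else []
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate position in name: {name!r}")
    for p in positions:
        if p not in RING_POSITIONS:
            raise ValueError(f"position {p} outside ring carbons 1-6 in {name!r}")
    if n_part is not None and int(n_part) != len(positions):
        raise ValueError(
            f"Pn suffix ({n_part}) disagrees with listed positions in {name!r}"
        )
    pp = [int(p) for p in pp_part.split(",")] if pp_part else []
    if len(set(pp)) != len(pp):
        raise ValueError(f"duplicate pyrophosphate position in name: {name!r}")
    for p in pp:
        if p not in RING_POSITIONS:
            raise ValueError(f"pyrophosphate position {p} outside 1-6 in {name!r}")
        if p in positions:
            raise ValueError(
                f"position {p} listed both as monoester and pyrophosphate in {name!r}"
            )
    return PhosphoInositol(frozenset(positions) | frozenset(pp), frozenset(pp))


def format_name(s: PhosphoInositol) -> str:
    """Format a state back to its 1D name (inverse of :func:`parse_name`)."""
    mono = sorted(s.phosphates - s.pyrophosphates)
    prefix = ""
    if s.pyrophosphates:
        prefix = ",".join(str(p) for p in sorted(s.pyrophosphates)) + "PP-"
    if not mono and not s.pyrophosphates:
        return "Ins"
    if not mono:
        return f"{prefix}Ins()P0"
    return f"{prefix}Ins({','.join(map(str, mono))})P{len(mono)}"


def enumerate_isomers(n: int) -> list:
    """All C(6, n) positionally distinct InsPn states, lexicographically ordered.

    Only phosphate monoester states are enumerated (no pyrophosphates).
    """
    if not 0 <= n <= 6:
        raise ValueError(f"phosphate count must be 0-6, got {n}")
    return [
        PhosphoInositol(frozenset(combo))
        for combo in itertools.combinations(range(1, 7), n)
    ]


def isomer_summary(n: int) -> dict:
    """Enumerate level-n isomers and count meso states and enantiomeric pairs."""
    isomers = enumerate_isomers(n)
    meso = [s for s in isomers if is_meso(s)]
    n_pairs = (len(isomers) - len(meso)) // 2
    return {
        "n": n,
        "count": len(isomers),
        "meso_count": len(meso),
        "enantiomeric_pairs": n_pairs,
        "isomers": isomers,
        "meso": meso,
    }
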