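"""Hydroxy-kinase and phosphotransfer reaction engine for ITPK enzymes.

ITPK-family enzymes phosphorylate free hydroxyls of inositol phosphates at
the expense of ATP (forward, hydroxy-kinase) and can run the transfer in
reverse, moving a ring phosphate back onto ADP to regenerate ATP.  Each
reaction conserves phosphate: ATP + InsPn <-> ADP + InsPn+1.

The module also ships a machine-readable transcription of the measured
AtITPK4 substrate/product table (23 kinase rows, 4 phosphotransfer rows)
with ordinal activity grades for the two assay formats (ATP-regenerating
and standard).  Blank cells and printed dashes are both encoded as grade
``none``, distinguished only by a provenance note.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .algebra import PhosphoInositol, enantiomer, parse_name

__all__ = [
    "Direction",
    "ReactionSpec",
    "ActivityGrade",
    "EnzymeProfile",
    "ReactionRecord",
    "TableRow",
    "ITPK4_PROFILE",
    "phosphorylate",
    "infer_transfer_position",
    "reverse_transfer",
    "table1_fixture",
    "table1_dataframe",
]


class Direction(enum.Enum):
    FORWARD_KINASE = "forward-kinase"
    REVERSE_TO_ADP = "reverse-to-ADP"


_GRADE_ORDER = {"none": 0, "+": 1, "++": 2, "+++": 3}


@dataclass(frozen=True)
class ActivityGrade:
    """Ordinal activity grades for the two assay formats.

    ``regeneration`` uses the +/++/+++ scale, ``standard`` the */**/*** scale;
    the two columns are independent and their quantitative relation is not
    defined.  ``none`` covers both a printed dash and a blank cell.
    """

    regeneration: str = "none"
    standard: str = "none"
    provenance: str = ""

    def __post_init__(self):
        if self.regeneration not in _GRADE_ORDER:
            raise ValueError(f"bad regeneration grade {self.regeneration!r}")
        if self.standard not in _GRADE_ORDER and set(self.standard) != {"*"}:
            raise ValueError(f"bad standard grade {self.standard!r}")

    @property
    def regeneration_level(self) -> int:
        return _GRADE_ORDER[self.regeneration]

    @property
    def standard_level(self) -> int:
        return 0 if self.standard == "none" else len(self.standard)

    @property
    def any_activity(self) -> bool:
        return self.regeneration_level > 0 or self.standard_level > 0


@dataclass(frozen=True)
class EnzymeProfile:
    """Capability profile restricting which reaction classes an enzyme runs."""

    name: str
    hydroxy_kinase: bool = True
    phosphotransfer_to_adp: bool = True
    phosphate_kinase: bool = False  # pyrophosphorylation


#: AtITPK4: hydroxy-kinase and reverse transfer, no pyrophosphorylation found.
ITPK4_PROFILE = EnzymeProfile("AtITPK4")


@dataclass(frozen=True)
class ReactionSpec:
    substrate: PhosphoInositol
    position: int
    direction: Direction

    def __post_init__(self):
        if self.position not in range(1, 7):
            raise ValueError(f"position {self.position} outside ring carbons 1-6")
        if self.direction is Direction.FORWARD_KINASE:
            if self.position in self.substrate.phosphates:
                raise ValueError(
                    f"forward kinase needs a free hydroxyl; {self.position} of "
                    f"{self.substrate} is phosphorylated"
                )
        else:
            if self.position not in self.substrate.phosphates:
                raise ValueError(
                    f"reverse transfer needs a phosphorylated position; "
                    f"{self.position} of {self.substrate} is free"
                )
            if self.position in self.substrate.pyrophosphates:
                raise ValueError(
                    "reverse transfer from a pyrophosphate position is not modelled"
                )

    @property
    def nucleotide_side(self) -> str:
        return (
            "ATP->ADP" if self.direction is Direction.FORWARD_KINASE else "ADP->ATP"
        )


@dataclass
class ReactionRecord:
    """Outcome of one phosphotransfer with its nucleotide ledger."""

    spec: ReactionSpec
    product: PhosphoInositol
    atp_delta: int
    adp_delta: int

    @property
    def phosphate_balance(self) -> int:
        """(product P + ADP) - (substrate P + ATP); zero when P is conserved."""
        return (
            self.product.n_phosphate_groups
            - self.spec.substrate.n_phosphate_groups
            + self.atp_delta  # ATP carries the transferred gamma-phosphate
        )


def phosphorylate(
    s: PhosphoInositol, position: int, profile: EnzymeProfile = ITPK4_PROFILE
) -> ReactionRecord:
    """Forward hydroxy-kinase step: add a phosphate at a free hydroxyl.

    Consumes one ATP and releases one ADP.
    """
    if not profile.hydroxy_kinase:
        raise ValueError(f"{profile.name} has no hydroxy-kinase activity")
    spec = ReactionSpec(s, position, Direction.FORWARD_KINASE)
    product = PhosphoInositol(s.phosphates | {position}, s.pyrophosphates)
    return ReactionRecord(spec, product, atp_delta=-1, adp_delta=+1)


def infer_transfer_position(
    substrate: PhosphoInositol, product: PhosphoInositol
) -> int:
    """Which ring carbon gained the phosphate between substrate and product.

    Requires the product to be the substrate plus exactly one new phosphate.
    """
    if substrate.pyrophosphates != product.pyrophosphates:
        raise ValueError("pyrophosphate pattern changed; not a single transfer")
    diff = product.phosphates - substrate.phosphates
    if len(diff) != 1 or not substrate.phosphates <= product.phosphates:
        raise ValueError(
            f"{product} is not {substrate} plus a single phosphate addition"
        )
    return next(iter(diff))


def reverse_transfer(
    s: PhosphoInositol,
    candidate_positions,
    profile: EnzymeProfile = ITPK4_PROFILE,
) -> list:
    """Phosphotransfer to ADP from each candidate position.

    Returns one ``(product, flags)`` tuple per candidate.  Products that are
    mutual enantiomers are flagged as a chromatographically unresolvable
    pair; such mixtures are expected to be of unequal amounts because the
    forward direction prefers one enantiomer.
    """
    if not profile.phosphotransfer_to_adp:
        raise ValueError(f"{profile.name} has no phosphotransfer-to-ADP activity")
    candidates = sorted(set(candidate_positions))
    products = []
    for pos in candidates:
        spec = ReactionSpec(s, pos, Direction.REVERSE_TO_ADP)
        product = PhosphoInositol(s.phosphates - {pos}, s.pyrophosphates)
        products.append(
            ReactionRecord(spec, product, atp_delta=+1, adp_delta=-1)
        )
    flagged = []
    for i, rec in enumerate(products):
        flags = {}
        for j, other in enumerate(products):
            if i != j and enantiomer(rec.product) == other.product:
                flags["chromatographically_unresolvable_pair"] = True
                flags["note"] = (
                    "mixture of unequal amounts: the forward direction prefers "
                    "one enantiomer"
                )
        flagged.append((rec, flags))
    return flagged


@dataclass(frozen=True)
class TableRow:
    section: str  # "kinase" or "phosphotransfer"
    substrate: PhosphoInositol
    substrate_name: str
    products: tuple  # PhosphoInositol tuple; racemic rows carry both
    product_name: str
    grade: ActivityGrade
    verified: bool


def _load_rows() -> list:
    text = (
        resources.files("insptools.data")
        .joinpath("itpk4_reaction_table.tsv")
        .read_text()
    )
    rows = []
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        products = ()
        if rec["product"] and rec["product"] != "-":
            products = tuple(parse_name(p) for p in rec["product"].split("/"))
        grade = ActivityGrade(
            regeneration=(
                "none" if rec["regeneration"] in ("", "-") else rec["regeneration"]
            ),
            standard="none" if rec["standard"] in ("", "-") else rec["standard"],
            provenance=rec["provenance"],
        )
        rows.append(
            TableRow(
                section=rec["section"],
                substrate=parse_name(rec["substrate"]),
                substrate_name=rec["substrate"],
                products=products,
                product_name=rec["product"],
                grade=grade,
                verified=rec["verified"] == "yes",
            )
        )
    return rows


def table1_fixture() -> list:
    """The full AtITPK4 substrate/product table as :class:`TableRow` records.

    23 kinase rows followed by 4 phosphotransfer-to-ADP rows.  Every verified
    kinase product is consistent with :func:`phosphorylate` /
    :func:`infer_transfer_position` (enforced by the test suite).
    """
    return _load_rows()


def table1_dataframe() -> pd.DataFrame:
    """Table fixture as a pandas DataFrame (one row per printed table row)."""
    rows = table1_fixture()
    return pd.DataFrame(
        {
            "section": [r.section for r in rows],
            "substrate": [r.substrate_name for r in rows],
            "product": [r.product_name for r in rows],
            "regeneration": [r.grade.regeneration for r in rows],
            "standard": [r.grade.standard for r in rows],
            "verified": [r.verified for r in rows],
        }
    )
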