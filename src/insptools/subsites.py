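"""Specificity subsite assignment (A-F) for inositol phosphate kinase poses.

Subsite A is the catalytic centre, holding the free hydroxyl that accepts
the gamma-phosphate.  From the vantage point of an observer on the
gamma-phosphate looking at the reverse face of the bound ring, the
remaining subsites are labelled B-F clockwise, following increasing carbon
number.  Combinatorially that makes B..F the carbons A+1..A+5 (cyclically
on 1..6) for reverse-face poses; viewing the obverse face mirrors the
apparent rotational sense, so for obverse poses B..F are A-1..A-5.

The same assignment is recomputed from explicit pose coordinates
(:func:`assign_subsites_geometric`) as an independent check, and an
occupancy report carries the B-pocket rationale: a phosphate in subsite B
is favourable, the axial 2-hydroxyl there is unfavourable (poorly
solvated), anything else neutral.  The flag is a partial rationale, not a
predictor: Ins(4,5,6)P3 is inactive despite a B-pocket phosphate in its
3-kinase pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .algebra import PhosphoInositol
from .geometry import BindingPose, ChairGeometry, construct_pose, ring_normal

__all__ = [
    "SubsiteAssignment",
    "PocketProfile",
    "SUBSITES",
    "assign_subsites",
    "assign_subsites_geometric",
    "occupancy_report",
]

SUBSITES = ("A", "B", "C", "D", "E", "F")

OCC_PHOSPHATE = "phosphate"
OCC_EQUATORIAL_OH = "equatorial-hydroxyl"
OCC_AXIAL_OH = "axial-hydroxyl"


@dataclass(frozen=True)
class SubsiteAssignment:
    """Bijection subsite letter -> ring carbon, with per-subsite occupancy."""

    mapping: dict  # subsite -> carbon
    occupancy: dict  # subsite -> occupancy class

    def __post_init__(self):
        if set(self.mapping) != set(SUBSITES):
            raise ValueError("mapping must cover subsites A-F")
        if sorted(self.mapping.values()) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("mapping must be a bijection onto carbons 1-6")

    def carbon(self, subsite: str) -> int:
        return self.mapping[subsite]


@dataclass
class PocketProfile:
    """Per-enzyme annotation of the specificity pockets (free-text notes)."""

    enzyme: str
    residue_notes: dict = field(default_factory=dict)
    b_pocket_prefers_phosphate: bool = True

    def __post_init__(self):
        if not set(self.residue_notes) <= set(SUBSITES):
            raise ValueError("residue note keys must be subsites A-F")


#: AtITPK4 pocket annotations from the structural analysis.
ITPK4_POCKETS = PocketProfile(
    enzyme="AtITPK4",
    residue_notes={
        "B": "Cys320 (central domain); phosphate here H-bonds the thiol "
        "and coordinates Mg2+",
        "C": "tab insertion residues",
        "D": "tab insertion residues",
        "E": "underpopulated (no tether insertion)",
        "F": "underpopulated; Gly437 where plant ITPK1s present an Asn",
    },
)


def _occupancy_of_carbon(isomer: PhosphoInositol, carbon: int) -> str:
    if carbon in isomer.phosphates:
        return OCC_PHOSPHATE
    return OCC_AXIAL_OH if carbon == 2 else OCC_EQUATORIAL_OH


def assign_subsites(pose: BindingPose) -> SubsiteAssignment:
    """Combinatorial subsite assignment for a pose (the clockwise rule)."""
    a = pose.target_position
    step = 1 if pose.face == "reverse" else -1
    mapping = {
        letter: (a - 1 + step * i) % 6 + 1 for i, letter in enumerate(SUBSITES)
    }
    occupancy = {
        letter: _occupancy_of_carbon(pose.isomer, carbon)
        for letter, carbon in mapping.items()
    }
    return SubsiteAssignment(mapping=mapping, occupancy=occupancy)


def assign_subsites_geometric(pose: BindingPose) -> SubsiteAssignment:
    """Subsite assignment recomputed from explicit pose coordinates.

    The observer sits on the +z axis of the enzyme frame.  Carbons are
    projected onto the plane normal to the viewing axis and ordered
    clockwise as the observer sees them (decreasing azimuth), starting from
    the target carbon at subsite A.  Mirrored (reflected) coordinate sets
    are rejected by a ring-circulation handedness check.
    """
    carbons = pose.chair.carbons
    if carbons.shape != (6, 3):
        raise ValueError("pose must carry six ring-carbon coordinates")
    view = np.array([0.0, 0.0, 1.0])
    centered = carbons - carbons.mean(axis=0)
    azimuth = np.arctan2(centered[:, 1], centered[:, 0])

    # handedness of the ring circulation C1->C2->...->C6 as seen by the observer;
    # a reflection of a valid pose reverses it relative to the face on show.
    circ = 0.0
    for i in range(6):
        j = (i + 1) % 6
        circ += centered[i, 0] * centered[j, 1] - centered[j, 0] * centered[i, 1]
    presented_obverse = float(pose.chair.obverse_normal @ view) > 0
    # valid chairs circulate counterclockwise (positive) seen from obverse
    expected_positive = presented_obverse
    if (circ > 0) != expected_positive:
        raise ValueError(
            "mirrored (reflected) coordinates detected; refusing to assign "
            "subsites to an enantiomerized pose"
        )

    a_idx = pose.target_position - 1
    # clockwise from the observer's viewpoint = decreasing azimuth
    rel = (azimuth[a_idx] - azimuth) % (2 * np.pi)
    order = np.argsort(rel)  # starts at A (rel = 0), then clockwise
    mapping = {letter: int(order[i]) + 1 for i, letter in enumerate(SUBSITES)}
    occupancy = {
        letter: _occupancy_of_carbon(pose.isomer, carbon)
        for letter, carbon in mapping.items()
    }
    return SubsiteAssignment(mapping=mapping, occupancy=occupancy)


def occupancy_report(
    isomer: PhosphoInositol,
    target: int,
    profile: PocketProfile = ITPK4_POCKETS,
) -> dict:
    """Per-subsite occupancy for a substrate/target pair plus the B-pocket flag.

    The ``favourability`` entry is a three-level heuristic ("favourable" if
    subsite B holds a phosphate, "unfavourable" if it holds the axial
    2-hydroxyl, "neutral" otherwise) and is explicitly a partial rationale
    rather than an activity predictor.
    """
    pose = construct_pose(isomer, target)
    assignment = assign_subsites(pose)
    b_occ = assignment.occupancy["B"]
    if b_occ == OCC_PHOSPHATE and profile.b_pocket_prefers_phosphate:
        flag = "favourable"
    elif b_occ == OCC_AXIAL_OH:
        flag = "unfavourable"
    else:
        flag = "neutral"
    return {
        "enzyme": profile.enzyme,
        "isomer": str(isomer),
        "target": target,
        "face": pose.face,
        "mapping": assignment.mapping,
        "occupancy": assignment.occupancy,
        "favourability": flag,
        "note": "partial rationale, not a predictor",
        "residue_notes": {
            k: v for k, v in profile.residue_notes.items()
        },
    }
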