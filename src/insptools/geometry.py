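"""Idealized chair geometry of the myo-inositol ring and rigid-body tools.

The ring is built as a perfect cyclohexane chair (C-C 1.54 A, tetrahedral
angles) with carbons C1..C6 placed counterclockwise when viewed from the
obverse face.  "Obverse" is the face carrying the unique axial substituent
at C2; "reverse" is the opposite face.  In the myo configuration the C2
hydroxyl is axial and all others are equatorial.

Two stereochemical facts carried by this geometry drive the substrate
specificity model:

* the equatorial substituents at C1/C3/C5 tilt out of the mean plane toward
  the obverse face while those at C4/C6 tilt toward the reverse face, so a
  phosphoryl-transfer observer positioned *opposite* the target hydroxyl's
  tilt sees the reverse face for targets 1/3/5 and the obverse face for 4/6;
* a 180 degree rotation about the C2-C5 axis exchanges carbons 1<->3 and
  4<->6 in the projected ring ordering, i.e. it realizes the enantiomer
  position map geometrically.

Rigid superposition uses the Kabsch algorithm with reflections excluded by
default (a reflection would silently convert an isomer to its enantiomer).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .algebra import PhosphoInositol

__all__ = [
    "ChairGeometry",
    "BindingPose",
    "RigidTransform",
    "Face",
    "build_ideal_chair",
    "required_face",
    "construct_pose",
    "kabsch_superpose",
    "ring_normal",
    "rotation_about_axis",
    "read_ring_pdb",
    "write_ring_pdb",
]

CC_BOND = 1.54  # A
TET_ANGLE = 109.47122063449069  # degrees, arccos(-1/3)
RING_CLOSURE_TOL = 1e-6  # A

Face = str  # "obverse" | "reverse"


@dataclass
class RigidTransform:
    """Proper rigid-body map x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ChairGeometry:
    """Six ring-carbon coordinates plus O-substituent direction vectors.

    ``carbons`` is a (6, 3) array ordered C1..C6 (angstroms);
    ``substituents`` holds the unit direction of the oxygen substituent at
    each carbon; ``axial`` flags which of those directions is axial.
    """

    carbons: np.ndarray
    substituents: np.ndarray
    axial: np.ndarray  # boolean per carbon

    def carbon(self, position: int) -> np.ndarray:
        return self.carbons[position - 1]

    def substituent(self, position: int) -> np.ndarray:
        return self.substituents[position - 1]

    def is_axial(self, position: int) -> bool:
        return bool(self.axial[position - 1])

    @property
    def obverse_normal(self) -> np.ndarray:
        """Unit normal of the ring plane pointing toward the C2 axial substituent."""
        n = ring_normal(self.carbons)
        if np.dot(n, self.substituent(2)) < 0:
            n = -n
        return n

    def transformed(self, t: RigidTransform) -> "ChairGeometry":
        return ChairGeometry(
            carbons=t.apply(self.carbons),
            substituents=self.substituents @ t.rotation.T,
            axial=self.axial.copy(),
        )

    def ring_closure_deviation(self) -> float:
        d = np.linalg.norm(np.roll(self.carbons, -1, axis=0) - self.carbons, axis=1)
        return float(np.max(np.abs(d - d[0])))


def ring_normal(carbons: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through the six ring carbons."""
    centered = carbons - carbons.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2] / np.linalg.norm(vt[2])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a rotation about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _substituent_directions(carbons: np.ndarray, i: int):
    """The two tetrahedral substituent directions at carbon index i (0-based)."""
    c = carbons[i]
    u = carbons[(i + 1) % 6] - c
    w = carbons[(i - 1) % 6] - c
    u /= np.linalg.norm(u)
    w /= np.linalg.norm(w)
    b = u + w
    b /= np.linalg.norm(b)
    p = np.cross(u, w)
    p /= np.linalg.norm(p)
    d1 = -b / np.sqrt(3) + p * np.sqrt(2.0 / 3.0)
    d2 = -b / np.sqrt(3) - p * np.sqrt(2.0 / 3.0)
    return d1, d2


def build_ideal_chair() -> ChairGeometry:
    """Perfect myo-inositol chair in a canonical frame.

    The ring mean plane is z = 0, the obverse normal is +z (C2 axial points
    up) and C1 sits on the +x azimuth.  Bond length 1.54 A, all bond angles
    tetrahedral.  The oxygen substituent is axial at C2 and equatorial at
    every other position.
    """
    r = CC_BOND * 2.0 * np.sqrt(2.0) / 3.0
    z0 = r / (4.0 * np.sqrt(2.0))
    carbons = np.empty((6, 3))
    for k in range(1, 7):
        ang = np.deg2rad((k - 1) * 60.0)
        # even-numbered carbons puckered toward obverse so the C2 axial is +z
        z = z0 if k % 2 == 0 else -z0
        carbons[k - 1] = (r * np.cos(ang), r * np.sin(ang), z)
    normal = ring_normal(carbons)
    if normal[2] < 0:
        normal = -normal
    substituents = np.empty((6, 3))
    axial = np.zeros(6, dtype=bool)
    for k in range(1, 7):
        d1, d2 = _substituent_directions(carbons, k - 1)
        # axial = the direction nearer the ring normal
        ax, eq = (d1, d2) if abs(d1 @ normal) > abs(d2 @ normal) else (d2, d1)
        if k == 2:
            substituents[k - 1] = ax
            axial[k - 1] = True
        else:
            substituents[k - 1] = eq
    return ChairGeometry(carbons=carbons, substituents=substituents, axial=axial)


def required_face(target_position: int) -> Face:
    """Which ring face must point toward the phosphoryl-transfer observer.

    Reverse for targets 1, 3, 5; obverse for 4 and 6.  Phosphorylation at
    the axial 2-position has no stated stereochemical rule and is rejected.
    """
    if target_position == 2:
        raise ValueError(
            "no face rule exists for the axial 2-position; unsupported target"
        )
    if target_position not in (1, 3, 4, 5, 6):
        raise ValueError(f"target position {target_position} outside ring carbons 1-6")
    return "reverse" if target_position in (1, 3, 5) else "obverse"


def required_face_geometric(
    target_position: int, chair: Optional[ChairGeometry] = None
) -> Face:
    """Face rule derived from coordinates rather than the lookup.

    The transfer observer sits on the face *opposite* the out-of-plane tilt
    of the target's equatorial substituent, so the sign of that tilt against
    the obverse normal decides the presented face.
    """
    if chair is None:
        chair = build_ideal_chair()
    if target_position == 2:
        raise ValueError(
            "no face rule exists for the axial 2-position; unsupported target"
        )
    tilt = float(chair.substituent(target_position) @ chair.obverse_normal)
    return "reverse" if tilt > 0 else "obverse"


@dataclass
class BindingPose:
    """An isomer oriented in the enzyme frame for transfer at one hydroxyl.

    Enzyme-frame convention: the phosphoryl-transfer observer (the
    gamma-phosphate of ATP) sits on the +z axis looking down; subsite A
    (the target carbon) lies on the +x azimuth.
    """

    isomer: PhosphoInositol
    target_position: int
    face: Face
    transform: RigidTransform
    chair: ChairGeometry  # already in the enzyme frame

    def to_json_dict(self) -> dict:
        return {
            "isomer": str(self.isomer),
            "target": self.target_position,
            "face": self.face,
            "rotation": self.transform.rotation.tolist(),
            "translation": self.transform.translation.tolist(),
            "carbons": self.chair.carbons.tolist(),
        }


def construct_pose(
    isomer: PhosphoInositol,
    target: int,
    chair: Optional[ChairGeometry] = None,
) -> BindingPose:
    """Orient an isomer for stereochemically favoured transfer at ``target``.

    Starting from the canonical chair (obverse up), the pose is built by an
    optional 180 degree rotation about the C2-C5 axis (which flips the
    presented face and exchanges carbons 1<->3 and 4<->6 in projection)
    followed by an in-plane rotation about the ring normal bringing the
    target carbon to the subsite-A azimuth (+x).
    """
    if target in isomer.phosphates:
        raise ValueError(f"target {target} of {isomer} is not a free hydroxyl")
    face = required_face(target)
    base = build_ideal_chair() if chair is None else chair
    transform = RigidTransform.identity()
    posed = base
    if face == "reverse":
        axis = base.carbon(5) - base.carbon(2)
        flip = RigidTransform(rotation_about_axis(axis, 180.0), np.zeros(3))
        posed = posed.transformed(flip)
        transform = flip.compose(transform)
    # in-plane rotation about the viewing axis to put the target at +x
    tpos = posed.carbon(target)
    ang = np.degrees(np.arctan2(tpos[1], tpos[0]))
    spin = RigidTransform(rotation_about_axis(np.array([0.0, 0.0, 1.0]), -ang), np.zeros(3))
    posed = posed.transformed(spin)
    transform = spin.compose(transform)
    return BindingPose(
        isomer=isomer,
        target_position=target,
        face=face,
        transform=transform,
        chair=posed,
    )


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray, allow_reflection: bool = False
):
    """Optimal rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(RigidTransform, rmsd)`` where the transform maps the moving
    set onto the fixed set in the least-squares sense and rmsd is in the
    same units as the coordinates.  Only proper rotations (det = +1) are
    returned unless ``allow_reflection`` is set (used by the enantiomer
    mirror check).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # collinearity check: rank of the centered fixed set
    if np.linalg.matrix_rank(b, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.ones(3)
    if not allow_reflection:
        corr[2] = d
    rot = vt.T @ np.diag(corr) @ u.T
    trans = fc - rot @ mc
    t = RigidTransform(rot, trans)
    diff = t.apply(moving) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return t, rmsd


# -- PDB-format I/O for ring-atom fixtures (via gemmi) -----------------------

def write_ring_pdb(chair_or_coords, path) -> None:
    """Write ring-carbon ATOM records (C1..C6, residue INS) to a PDB file."""
    import gemmi

    coords = (
        chair_or_coords.carbons
        if isinstance(chair_or_coords, ChairGeometry)
        else np.asarray(chair_or_coords)
    )
    structure = gemmi.Structure()
    structure.name = "ring"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    residue = gemmi.Residue()
    residue.name = "INS"
    residue.seqid = gemmi.SeqId(1, " ")
    for i, (x, y, z) in enumerate(coords, start=1):
        atom = gemmi.Atom()
        atom.name = f"C{i}"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        residue.add_atom(atom)
    chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_ring_pdb(path) -> np.ndarray:
    """Read ring-carbon coordinates back from a PDB file, ordered C1..C6."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    atoms = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.element.name == "C":
                        atoms.append((atom.name, atom.pos))
    atoms.sort(key=lambda a: int(a[0][1:]) if a[0][1:].isdigit() else 0)
    return np.array([[p.x, p.y, p.z] for _, p in atoms])
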