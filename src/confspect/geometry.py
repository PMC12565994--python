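"""Distances, planar angles, signed dihedrals and conformer classification.

The conformers of the coumarin–cytisine complex are distinguished by the two
marker dihedrals between adjacent carbonyl groups: theta1 = O1-C19-C45-O4
(cytisine/linker) and theta2 = O4-C45-C31-O8 (linker/coumarin).  Rotating
the cytisine part about the linker N-C bond flips theta1 from near 0 to near
130 deg (conformers 1,3 vs 2,4); rotating the coumarin part about the C-C
bond flips the sign of theta2 within each group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import AtomSite, ValidationError, parse_atom_label

__all__ = [
    "GeometryError",
    "distance",
    "planar_angle",
    "dihedral",
    "contact_table",
    "ContactTable",
    "classify_conformer",
    "ConformerClass",
    "normalize_angle",
]

#: |theta1| below this bound (degrees) marks group A (conformers 1 and 3).
GROUP_BOUNDARY_DEG = 90.0

_COLLINEAR_TOL = 1e-10


class GeometryError(ValueError):
    """Raised for missing positions or degenerate (collinear) geometries."""


def _site(geometry: Sequence[AtomSite], label: str | int) -> AtomSite:
    if isinstance(label, str):
        element, index = parse_atom_label(label)
    else:
        element, index = None, int(label)
    for site in geometry:
        if site.index == index:
            if element is not None and site.element != element:
                raise ValidationError(
                    f"label {label!r} names element {element} but atom "
                    f"{index} is {site.element}"
                )
            return site
    raise GeometryError(f"no atom with index {index} in geometry")


def _pos(geometry: Sequence[AtomSite], label: str | int) -> np.ndarray:
    site = _site(geometry, label)
    if site.position is None:
        raise GeometryError(f"atom {site.label} has no position")
    return np.asarray(site.position, dtype=float)


def distance(geometry: Sequence[AtomSite], i: str | int, j: str | int) -> float:
    """Euclidean distance between two atoms in Å."""
    return float(np.linalg.norm(_pos(geometry, i) - _pos(geometry, j)))


def planar_angle(
    geometry: Sequence[AtomSite], i: str | int, j: str | int, k: str | int
) -> float:
    """Planar angle i-j-k in degrees, in [0, 180]."""
    a = _pos(geometry, i) - _pos(geometry, j)
    b = _pos(geometry, k) - _pos(geometry, j)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _COLLINEAR_TOL or nb < _COLLINEAR_TOL:
        raise GeometryError("coincident atoms in planar angle")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(
    geometry: Sequence[AtomSite],
    i: str | int,
    j: str | int,
    k: str | int,
    l: str | int,
) -> float:
    """Signed dihedral i-j-k-l in degrees, in (-180, 180].

    Right-handed (IUPAC) convention about the j->k axis: looking from j to
    k, a positive angle means the far bond k->l is rotated clockwise from
    the near bond j->i.  The torsion is invariant under sequence reversal
    (``dihedral(l,k,j,i) == dihedral(i,j,k,l)``, handedness does not depend
    on traversal direction) and flips sign under mirror reflection.
    """
    p0, p1, p2, p3 = (_pos(geometry, a) for a in (i, j, k, l))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError(
            "three consecutive atoms are collinear; dihedral undefined"
        )
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


@dataclass(frozen=True)
class ContactTable:
    """Oxygen–hydrogen contact distances sorted ascending.

    ``verified`` reports whether a user-supplied expected strict ordering of
    contacts holds; ``diagnostic`` explains a failure ("tie" for equal
    distances, "order" for a genuine violation).
    """

    contacts: tuple[tuple[str, str, float], ...]
    verified: bool | None = None
    diagnostic: str = ""


def contact_table(
    geometry: Sequence[AtomSite],
    pairs: Sequence[tuple[str, str]],
    expected_order: Sequence[tuple[str, str]] | None = None,
) -> ContactTable:
    """All requested O···H distances, ascending.

    Each pair is (oxygen label, hydrogen label); labels resolving to other
    elements raise :class:`~confspect.types.ValidationError`.  When
    ``expected_order`` is given, ``verified`` states whether the measured
    distances follow that ordering with strict ``<``.
    """
    measured = {}
    for o_label, h_label in pairs:
        o_site, h_site = _site(geometry, o_label), _site(geometry, h_label)
        if o_site.element != "O":
            raise ValidationError(f"{o_label} is {o_site.element}, expected O")
        if h_site.element != "H":
            raise ValidationError(f"{h_label} is {h_site.element}, expected H")
        measured[(o_label, h_label)] = distance(geometry, o_label, h_label)

    contacts = tuple(
        (o, h, d) for (o, h), d in sorted(measured.items(), key=lambda kv: kv[1])
    )
    verified: bool | None = None
    diagnostic = ""
    if expected_order is not None:
        verified = True
        for (pa, pb) in zip(expected_order, expected_order[1:]):
            da, db = measured[tuple(pa)], measured[tuple(pb)]
            if da == db:
                verified, diagnostic = False, "tie"
                break
            if da > db:
                verified, diagnostic = False, "order"
                break
    return ContactTable(contacts=contacts, verified=verified, diagnostic=diagnostic)


def normalize_angle(theta: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = math.fmod(theta, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


@dataclass(frozen=True)
class ConformerClass:
    """Classification of a conformer from its two marker dihedrals.

    Group A (|theta1| < 90 deg) holds conformers 1 and 3; group B holds 2
    and 4.  The family within a group follows the sign of theta2; for
    families 3 and 4 this is a stated convention (the study prints marker
    angles only for families 1 and 2), flagged by ``convention_based``.
    """

    theta1: float
    theta2: float
    group: str
    family: int | str
    convention_based: bool = False


def classify_conformer(theta1: float, theta2: float) -> ConformerClass:
    """Classify a conformer by its (theta1, theta2) marker dihedrals.

    Total on valid angles; inputs are first wrapped into (-180, 180].
    theta2 == 0 exactly leaves the family "unclassified" (the group is
    still defined).  |theta1| == 90 exactly falls in group B.
    """
    t1 = normalize_angle(float(theta1))
    t2 = normalize_angle(float(theta2))
    group = "A" if abs(t1) < GROUP_BOUNDARY_DEG else "B"
    family: int | str
    if t2 == 0.0:
        family = "unclassified"
    elif group == "A":
        family = 1 if t2 > 0 else 3
    else:
        family = 2 if t2 < 0 else 4
    return ConformerClass(
        theta1=t1,
        theta2=t2,
        group=group,
        family=family,
        convention_based=family in (3, 4),
    )
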