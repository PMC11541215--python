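"""Torsion measurement and rigid rotations about bond axes.

Dihedrals follow the IUPAC right-handed sign convention with values in
(-180, 180].  All angles at this interface are degrees; Å for lengths.
"""

from __future__ import annotations

import numpy as np

from glycokit.core.model import MolecularModel


class CollinearityError(ValueError):
    """Three consecutive dihedral atoms are collinear; the angle is undefined."""


def dihedral_from_points(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or norm_b1 < 1e-10:
        raise CollinearityError("collinear atoms: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1) / norm_b1
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def measure_dihedral(model: MolecularModel, quartet: tuple[int, int, int, int]) -> float:
    """Dihedral over four distinct atom indices of ``model``, degrees."""
    i, j, k, l = quartet
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires four distinct atoms")
    atoms = model.atoms
    return dihedral_from_points(
        atoms[i].coordinates, atoms[j].coordinates,
        atoms[k].coordinates, atoms[l].coordinates,
    )


def rotation_about_axis(point: np.ndarray, direction: np.ndarray, angle_deg: float):
    """Return a function mapping (M, 3) coords to their rotation about the axis.

    The axis passes through ``point`` along ``direction`` (right-hand rule).
    """
    point = np.asarray(point, float)
    u = np.asarray(direction, float)
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("zero-length rotation axis")
    u = u / norm
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    R = np.eye(3) * c + s * K + (1.0 - c) * np.outer(u, u)

    def apply(coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        return (coords - point) @ R.T + point

    return apply


def rotate_subset(
    model: MolecularModel,
    moving: list[int] | np.ndarray,
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    angle_deg: float,
) -> None:
    """Rotate the listed atoms rigidly about the axis, in place."""
    if not len(moving):
        return
    rot = rotation_about_axis(axis_point, axis_direction, angle_deg)
    coords = np.array([model.atoms[i].coordinates for i in moving])
    for idx, xyz in zip(moving, rot(coords)):
        model.atoms[idx].coordinates = xyz


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond_length: float, bond_angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position of atom d given internal coordinates relative to a-b-c.

    ``bond_length`` is c-d, ``bond_angle_deg`` is b-c-d and ``torsion_deg``
    is the dihedral a-b-c-d (natural-extension-of-reference-frame build).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise CollinearityError("reference atoms a, b, c are collinear")
    n /= n_norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def set_dihedral(
    model: MolecularModel,
    quartet: tuple[int, int, int, int],
    moving: set[int] | frozenset[int],
    target_deg: float,
) -> None:
    """Rotate ``moving`` about the j-k bond so dihedral(i,j,k,l) = target.

    ``moving`` must contain exactly one of i, l (the side being turned)
    and neither j nor k.
    """
    i, j, k, l = quartet
    current = measure_dihedral(model, quartet)
    delta = (target_deg - current + 180.0) % 360.0 - 180.0
    pj = model.atoms[j].coordinates
    pk = model.atoms[k].coordinates
    if l in moving and i not in moving:
        rotate_subset(model, sorted(moving), pj, pk - pj, delta)
    elif i in moving and l not in moving:
        rotate_subset(model, sorted(moving), pk, pj - pk, delta)
    else:
        raise ValueError("moving set must contain exactly one end of the quartet")


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation + bounded translation (test helper)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-50.0, 50.0, size=3)

    def apply(coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ R.T + t

    return apply
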