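"""Internal-coordinate model of the polypeptide backbone.

The sampler works in internal coordinates: backbone dihedrals (phi, psi,
omega), the three backbone bond angles per residue, and side-chain chi
angles.  Bond lengths are held at ideal values and never sampled.  This
module converts between that representation and Cartesian coordinates
(NeRF-style sequential construction), and provides least-squares
superposition (Kabsch) and CA-RMSD.

Conventions
-----------
* Angles are degrees in the public API, IUPAC sign convention for
  dihedrals, range (-180, 180].
* phi of residue 1, psi of the last residue and omega of residue 1 are
  undefined and carried as NaN sentinels.
* Side chains beyond CB are represented only by their chi angles (used as
  predictor features); they are not built as atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, ProteinStructure, CHI_COUNTS

# Ideal backbone bond lengths (Angstrom); fixed, never sampled.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.01
BOND_CA_HA = 1.09
BOND_CA_CB = 1.53

# Ideal backbone bond angles (degrees), used as defaults.
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

_TET = 109.47  # tetrahedral angle, degrees


class GeometryError(ValueError):
    pass


@dataclass
class InternalCoordinates:
    """Backbone dihedrals, backbone bond angles and side-chain chi angles.

    All arrays have one entry per residue; undefined entries (phi[0],
    psi[-1], omega[0], ang_ca_c_n[-1], ang_c_n_ca[-1]) are NaN.
    ``ang_ca_c_n[i]`` is the CA(i)-C(i)-N(i+1) angle and ``ang_c_n_ca[i]``
    the C(i)-N(i+1)-CA(i+1) angle.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    ang_n_ca_c: np.ndarray
    ang_ca_c_n: np.ndarray
    ang_c_n_ca: np.ndarray
    chi: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("phi", "psi", "omega", "ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            finite = arr[np.isfinite(arr)]
            if finite.size and (np.any(finite <= -180.0) or np.any(finite > 180.0)):
                raise GeometryError(f"{name} contains angles outside (-180, 180]")
        self.chi = [np.asarray(c, dtype=float) for c in self.chi]

    @property
    def n_residues(self) -> int:
        return len(self.phi)

    def copy(self) -> "InternalCoordinates":
        return InternalCoordinates(
            self.phi.copy(), self.psi.copy(), self.omega.copy(),
            self.ang_n_ca_c.copy(), self.ang_ca_c_n.copy(), self.ang_c_n_ca.copy(),
            [c.copy() for c in self.chi],
        )

    @classmethod
    def ideal(cls, sequence, phi=-57.0, psi=-47.0) -> "InternalCoordinates":
        """Uniform backbone at the given (phi, psi); ideal bond angles."""
        n = len(sequence)
        mk = lambda v: np.full(n, float(v))
        ic = cls(
            phi=mk(phi), psi=mk(psi), omega=mk(180.0),
            ang_n_ca_c=mk(ANGLE_N_CA_C), ang_ca_c_n=mk(ANGLE_CA_C_N),
            ang_c_n_ca=mk(ANGLE_C_N_CA),
            chi=[np.zeros(CHI_COUNTS.get(r, 0)) for r in sequence],
        )
        ic.phi[0] = np.nan
        ic.psi[-1] = np.nan
        ic.omega[0] = np.nan
        ic.ang_ca_c_n[-1] = np.nan
        ic.ang_c_n_ca[-1] = np.nan
        return ic


@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("degenerate geometry: zero-length bond vector")
    return v / n


def place_atom(a, b, c, length, angle_deg, torsion_deg):
    """Place atom D given A-B-C, |CD|, angle(B,C,D) and torsion(A,B,C,D)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        -length * math.sin(ang) * math.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC convention."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, _unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def bond_angle(a, b, c) -> float:
    u = _unit(a - b)
    v = _unit(c - b)
    return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


def build_backbone_arrays(internal: InternalCoordinates) -> np.ndarray:
    """Backbone N, CA, C coordinates as an (n, 3, 3) array.

    Sequential NeRF construction; residue 1 in the canonical frame (N at
    the origin, CA on +x, C in the xy-plane).
    """
    n = internal.n_residues
    for name in ("phi", "psi", "omega"):
        arr = getattr(internal, name)
        bad = ~np.isfinite(arr)
        expect = np.zeros(n, bool)
        if name in ("phi", "omega"):
            expect[0] = True
        if name == "psi":
            expect[-1] = True
        if np.any(bad & ~expect):
            raise GeometryError(f"undefined {name} at a non-terminal residue")
    bb = np.empty((n, 3, 3))
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (BOND_N_CA, 0.0, 0.0)
    t0 = math.radians(internal.ang_n_ca_c[0])
    bb[0, 2] = bb[0, 1] + BOND_CA_C * np.array([-math.cos(t0), math.sin(t0), 0.0])
    for i in range(n - 1):
        N, CA, C = bb[i]
        Nn = place_atom(N, CA, C, BOND_C_N, internal.ang_ca_c_n[i], internal.psi[i])
        CAn = place_atom(CA, C, Nn, BOND_N_CA, internal.ang_c_n_ca[i], internal.omega[i + 1])
        Cn = place_atom(C, Nn, CAn, BOND_CA_C, internal.ang_n_ca_c[i + 1], internal.phi[i + 1])
        bb[i + 1] = (Nn, CAn, Cn)
    return bb


def derived_atom_positions(bb: np.ndarray, internal: InternalCoordinates, sequence):
    """Vectorized O, H, HA and CB positions from the backbone array.

    Returns a dict of (n, 3) arrays with NaN rows where an atom does not
    exist (O uses psi+180; H needs a preceding residue; CB absent for GLY).
    """
    n = bb.shape[0]
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]
    out = {}

    # carbonyl O: torsion psi + 180 about N-CA-C; last residue gets 180 - psi
    # sentinel replaced by 0 so O points anti to where N(i+1) would sit.
    psi = np.where(np.isfinite(internal.psi), internal.psi, 0.0)
    tor = np.radians(psi + 180.0)
    ang = math.radians(ANGLE_CA_C_O)
    bc = C - CA
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    nv = np.cross(CA - N, bc)
    nv /= np.linalg.norm(nv, axis=1, keepdims=True)
    mv = np.cross(nv, bc)
    out["O"] = (C - BOND_C_O * math.cos(ang) * bc
                + BOND_C_O * math.sin(ang) * (np.cos(tor)[:, None] * mv
                                              - np.sin(tor)[:, None] * nv))

    # amide H: external bisector of C(i-1)-N(i)-CA(i); none on residue 1 or PRO
    H = np.full((n, 3), np.nan)
    if n > 1:
        u = C[:-1] - N[1:]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = CA[1:] - N[1:]
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        w = -(u + v)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        H[1:] = N[1:] + BOND_N_H * w
        for i, res in enumerate(sequence):
            if res == "PRO":
                H[i] = np.nan
    out["H"] = H

    # HA and CB: the two remaining tetrahedral directions at CA
    u = N - CA
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = C - CA
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    c = np.sum(u * v, axis=1)
    bis = u + v
    bis /= np.linalg.norm(bis, axis=1, keepdims=True)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    # choose a so that each new bond makes the tetrahedral angle with N and C
    cos_t = math.cos(math.radians(_TET))
    a = -cos_t / np.sqrt((1.0 + c) / 2.0)
    a = np.clip(a, 0.0, 1.0)
    b = np.sqrt(np.maximum(0.0, 1.0 - a * a))
    # sign chosen to give L-configuration: zeta = dihedral(CA, N, C, CB) ~ +34 deg
    cb_dir = -a[:, None] * bis - b[:, None] * perp
    ha_dir = -a[:, None] * bis + b[:, None] * perp
    CB = CA + BOND_CA_CB * cb_dir
    for i, res in enumerate(sequence):
        if res == "GLY":
            CB[i] = np.nan
    out["CB"] = CB
    out["HA"] = CA + BOND_CA_HA * ha_dir
    return out


def build_backbone(sequence, internal: InternalCoordinates,
                   chain_id: str = "A") -> ProteinStructure:
    """Realize internal coordinates as a ProteinStructure.

    N, CA, C are placed sequentially; O, amide H, HA and CB follow from
    standard geometry.  Chi angles are attached as metadata (side chains
    beyond CB are not built).
    """
    if len(sequence) != internal.n_residues:
        raise GeometryError("internal coordinates do not cover the sequence")
    bb = build_backbone_arrays(internal)
    derived = derived_atom_positions(bb, internal, sequence)
    atoms = []
    for i, res in enumerate(sequence):
        idx = i + 1
        atoms.append(AtomRecord(idx, res, "N", bb[i, 0].copy()))
        atoms.append(AtomRecord(idx, res, "CA", bb[i, 1].copy()))
        atoms.append(AtomRecord(idx, res, "C", bb[i, 2].copy()))
        for name in ("O", "H", "HA", "CB"):
            pos = derived[name][i]
            if np.all(np.isfinite(pos)):
                atoms.append(AtomRecord(idx, res, name, pos.copy()))
    chi = [c.copy() for c in internal.chi] if internal.chi else \
        [np.zeros(CHI_COUNTS.get(r, 0)) for r in sequence]
    return ProteinStructure(sequence=list(sequence), atoms=atoms,
                            chain_id=chain_id, chi=chi)


def extract_dihedrals(structure: ProteinStructure) -> InternalCoordinates:
    """Backbone dihedrals and bond angles from Cartesian coordinates.

    phi of residue 1 and psi of the last residue are NaN sentinels.  Chi
    angles are taken from the structure's metadata (side chains are not
    built as atoms), defaulting to zeros.
    """
    n = len(structure.sequence)
    bb = np.empty((n, 3, 3))
    for i in range(n):
        idx = i + 1
        for k, name in enumerate(("N", "CA", "C")):
            atom = structure.find_atom(idx, name)
            if atom is None:
                raise GeometryError(f"residue {idx} is missing backbone atom {name}")
            bb[i, k] = atom.position
    nan = float("nan")
    phi = np.full(n, nan)
    psi = np.full(n, nan)
    omega = np.full(n, nan)
    a1 = np.full(n, nan)
    a2 = np.full(n, nan)
    a3 = np.full(n, nan)
    for i in range(n):
        N, CA, C = bb[i]
        a1[i] = bond_angle(N, CA, C)
        if i > 0:
            phi[i] = dihedral(bb[i - 1, 2], N, CA, C)
            omega[i] = dihedral(bb[i - 1, 1], bb[i - 1, 2], N, CA)
        if i < n - 1:
            psi[i] = dihedral(N, CA, C, bb[i + 1, 0])
            a2[i] = bond_angle(CA, C, bb[i + 1, 0])
            a3[i] = bond_angle(C, bb[i + 1, 0], bb[i + 1, 1])
    chi = [c.copy() for c in structure.chi] if structure.chi else \
        [np.zeros(CHI_COUNTS.get(r, 0)) for r in structure.sequence]
    return InternalCoordinates(phi, psi, omega, a1, a2, a3, chi)


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of B onto A (proper rotation).

    Returns the rotation R and translation t minimizing
    ||A - (B R^T + t)|| and the resulting RMSD.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise GeometryError(f"point set size mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise GeometryError("need at least 3 points to superpose")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = (B @ R.T) + t
    rmsd = float(np.sqrt(np.mean(np.sum((A - moved) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def ca_rmsd(A: ProteinStructure, B: ProteinStructure,
            residue_selection=None) -> float:
    """CA RMSD (Angstrom) after optimal rigid superposition."""
    if residue_selection is None:
        residue_selection = [i + 1 for i in range(len(A.sequence))]
    residue_selection = list(residue_selection)
    if not residue_selection:
        raise GeometryError("empty residue selection")
    pa, pb = [], []
    for idx in residue_selection:
        atom_a = A.find_atom(idx, "CA")
        atom_b = B.find_atom(idx, "CA")
        if atom_a is None or atom_b is None:
            raise GeometryError(f"residue {idx} has no CA in one of the structures")
        pa.append(atom_a.position)
        pb.append(atom_b.position)
    return kabsch_superpose(np.asarray(pa), np.asarray(pb)).rmsd
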