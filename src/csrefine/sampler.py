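"""Metropolis-Hastings sampling of structure and error scales.

The sampler explores backbone dihedrals (phi, psi), backbone bond
angles, side-chain chi angles and the per-atom-type error scales s_j of
the chemical-shift energy, under the hybrid energy

    E_hybrid = E_FF + E_CS(X, s)

in reduced units of k_B * T_ref (T_ref = 300 K).  The Metropolis
acceptance at simulation temperature T uses exp(-dE * T_ref / T), so
annealing from 300 K to 3 K progressively minimizes the full hybrid
energy.  Two protocols are provided: simulated annealing (geometric
temperature program) returning the lowest-energy structure visited, and
constant-temperature runs returning a snapshot ensemble.

The default move set uses the relative weights 20 (uniform side-chain) :
30 (local side-chain) : 40 (local backbone dihedral) : 10 (backbone bond
angle) : 5 (error scale), normalized internally.  Backbone moves are a
mix of single-angle Gaussian steps and concerted crankshaft rotations
(which leave every CA and the distal chain fixed), standing in for
concerted-rotation move sets behind the same interface.  The force
field is a soft stand-in — steric repulsion, a broad backbone torsion
bias, bond-angle and peptide-planarity restraints, and an elastic
network anchored on the input fold for tertiary cohesion — and is
pluggable at run level.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .structure_io import AtomRecord, ProteinStructure, match_shifts
from . import geometry
from .geometry import InternalCoordinates, build_backbone, derived_atom_positions
from .shift_energy import ShiftEnergyError

T_REF = 300.0

# stand-in force field constants (energies in k_B T_ref units)
REPULSION_RMIN = 2.6      # Angstrom, heavy-atom soft-sphere onset
REPULSION_K = 10.0        # kT / A^2
TORSION_K_PHI = 2.0       # kT, broad well centered at phi = -90
TORSION_K_PSI = 2.0       # kT, double well at psi = -47 / +133
BOND_ANGLE_K = 0.1        # kT / deg^2, harmonic about the ideal backbone angles
BOND_ANGLE_RANGE = (90.0, 135.0)
OMEGA_K = 0.1             # kT / deg^2, peptide-bond planarity restraint
SCALE_RANGE = (0.05, 1e2)  # ppm bounds on sampled error scales (numerical guard)
# fold-cohesion (elastic network) defaults: a molecular-mechanics force
# field keeps a folded protein near its energy minimum; the stand-in
# emulates that with harmonic CA-CA contact restraints taken from the
# input structure.  Without such cohesion a polypeptide's lever arms let
# small per-dihedral adjustments chase shift noise across Angstroms.
ELASTIC_CUTOFF = None     # Angstrom CA-CA contact cutoff; None = all pairs
ELASTIC_K = 0.3           # kT / A^2 per contact pair

_HEAVY_NAMES = ("N", "CA", "C", "O", "CB")


class SamplerError(ValueError):
    pass


@dataclass
class MoveSet:
    """Relative move weights and step-size parameters."""

    w_uniform_chi: float = 20.0
    w_local_chi: float = 30.0
    w_backbone: float = 40.0
    w_bond_angle: float = 10.0
    w_scale: float = 5.0
    chi_step: float = 15.0        # degrees, local chi Gaussian sd
    backbone_step: float = 3.0    # degrees, phi/psi Gaussian sd
    bond_angle_step: float = 1.5  # degrees
    scale_step: float = 0.3       # log-step half-width for s moves
    # fraction of backbone moves that are concerted crankshaft rotations
    # (C_i / N_{i+1} about the CA_i-CA_{i+1} axis; the distal chain stays
    # fixed, standing in for concerted-rotation backbone moves)
    crankshaft_fraction: float = 0.5
    crank_step: float = 15.0      # degrees, crankshaft rotation sd

    MOVE_KINDS = ("uniform_chi", "local_chi", "backbone", "bond_angle", "scale")

    def weights(self) -> np.ndarray:
        w = np.array([self.w_uniform_chi, self.w_local_chi, self.w_backbone,
                      self.w_bond_angle, self.w_scale], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise SamplerError("move weights must be >= 0 with at least one > 0")
        return w / w.sum()

    def cumulative_weights(self):
        cum = getattr(self, "_cum_cache", None)
        if cum is None:
            cum = tuple(np.cumsum(self.weights()))
            self._cum_cache = cum
        return cum


@dataclass
class AnnealingSchedule:
    t_start: float = 300.0
    t_end: float = 3.0
    n_steps: int = 200_000

    def __post_init__(self):
        if not (self.t_start >= self.t_end > 0):
            raise SamplerError("require t_start >= t_end > 0")
        if self.n_steps < 0:
            raise SamplerError("n_steps must be >= 0")


def geometric_temperature(i: int, schedule: AnnealingSchedule,
                          kind: str = "geometric") -> float:
    """Temperature at step i of the annealing program.

    Geometric interpolation T(i) = t_start * (t_end/t_start)^(i/n) by
    default; ``kind='linear'`` selects linear interpolation.
    """
    if not 0 <= i <= schedule.n_steps:
        raise SamplerError(f"step {i} outside [0, {schedule.n_steps}]")
    if schedule.n_steps == 0:
        return schedule.t_end
    x = i / schedule.n_steps
    if kind == "geometric":
        return schedule.t_start * (schedule.t_end / schedule.t_start) ** x
    if kind == "linear":
        return schedule.t_start + (schedule.t_end - schedule.t_start) * x
    raise SamplerError(f"unknown schedule kind {kind!r}")


def metropolis_step(delta_energy: float, temperature: float,
                    rng: np.random.Generator, log_proposal_ratio: float = 0.0,
                    t_ref: float = T_REF) -> bool:
    """Metropolis-Hastings acceptance decision.

    ``delta_energy`` is in reduced k_B T_ref units; the acceptance
    probability is min(1, exp(-dE * t_ref/T + log_proposal_ratio)).
    """
    if math.isnan(delta_energy):
        raise SamplerError("NaN energy in Metropolis step (structure blow-up?)")
    log_p = -delta_energy * t_ref / temperature + log_proposal_ratio
    if log_p >= 0:
        return True
    return rng.random() < math.exp(log_p)


# ---------------------------------------------------------------------------
# Stand-in force field

def _repulsion_energy(coords: np.ndarray, pair_i: np.ndarray,
                      pair_j: np.ndarray) -> float:
    d = coords[pair_i] - coords[pair_j]
    r2 = np.einsum("ij,ij->i", d, d)
    close = r2 < REPULSION_RMIN * REPULSION_RMIN
    if not np.any(close):
        return 0.0
    r = np.sqrt(r2[close])
    return float(REPULSION_K * np.sum((REPULSION_RMIN - r) ** 2))


def _torsion_bias(phi: np.ndarray, psi: np.ndarray) -> float:
    p = np.radians(phi[np.isfinite(phi)])
    q = np.radians(psi[np.isfinite(psi)])
    e = TORSION_K_PHI * np.sum(1.0 - np.cos(p - math.radians(-90.0)))
    e += TORSION_K_PSI * np.sum(1.0 - np.cos(2.0 * (q - math.radians(-47.0))))
    return float(e)


_ANGLE_TARGETS = {"ang_n_ca_c": geometry.ANGLE_N_CA_C,
                  "ang_ca_c_n": geometry.ANGLE_CA_C_N,
                  "ang_c_n_ca": geometry.ANGLE_C_N_CA}


def _bond_angle_energy(internal: InternalCoordinates) -> float:
    e = 0.0
    for name, target in _ANGLE_TARGETS.items():
        arr = getattr(internal, name)
        d = arr[np.isfinite(arr)] - target
        e += 0.5 * BOND_ANGLE_K * float(d @ d)
    return e


def _dihedral_scalar(p0, p1, p2, p3) -> float:
    """Plain-float IUPAC torsion (hot path; mirrors geometry.dihedral)."""
    b1x, b1y, b1z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    b2x, b2y, b2z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b3x, b3y, b3z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    mx = n1y * b2z - n1z * b2y
    my = n1z * b2x - n1x * b2z
    mz = n1x * b2y - n1y * b2x
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = (mx * n2x + my * n2y + mz * n2z) / nb2
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def _bond_angle_scalar(a, b, c) -> float:
    ux, uy, uz = a[0] - b[0], a[1] - b[1], a[2] - b[2]
    vx, vy, vz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    cos = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def _omega_energy(internal: InternalCoordinates) -> float:
    """Harmonic peptide-bond planarity restraint about omega = 180."""
    w = internal.omega[np.isfinite(internal.omega)]
    d = (w - 180.0 + 180.0) % 360.0 - 180.0
    return 0.5 * OMEGA_K * float(d @ d)


@dataclass
class ElasticNetwork:
    """Harmonic CA-CA contact restraints anchored on a reference fold.

    Emulates the tertiary cohesion of a molecular-mechanics force field
    around its minimum: CA pairs (sequence separation >= 2) are
    restrained to their distances in the anchor structure with spring
    constant ``k``.  With ``cutoff=None`` (default) every pair is
    restrained, which also suppresses the hinge motions that a contact
    cutoff cannot see in elongated chains.  Invariant under global
    rotation/translation.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    r0: np.ndarray
    k: float = ELASTIC_K

    @classmethod
    def from_structure(cls, structure: ProteinStructure,
                       cutoff: float | None = ELASTIC_CUTOFF,
                       k: float = ELASTIC_K) -> "ElasticNetwork":
        ca = np.array([structure.find_atom(i + 1, "CA").position
                       for i in range(structure.n_residues)])
        n = len(ca)
        ii, jj = np.triu_indices(n, k=2)
        d = np.linalg.norm(ca[ii] - ca[jj], axis=1)
        keep = d < cutoff if cutoff is not None else np.ones(len(d), bool)
        return cls(pair_i=ii[keep], pair_j=jj[keep], r0=d[keep], k=k)

    def energy(self, ca: np.ndarray) -> float:
        d = ca[self.pair_i] - ca[self.pair_j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        return float(0.5 * self.k * np.sum((r - self.r0) ** 2))


def _heavy_pairs(residue_of: np.ndarray):
    n = len(residue_of)
    ii, jj = np.triu_indices(n, k=1)
    keep = np.abs(residue_of[ii] - residue_of[jj]) >= 2
    return ii[keep], jj[keep]


def simple_force_field(structure: ProteinStructure) -> float:
    """Soft stand-in force field, in k_B T_ref units.

    Soft-sphere repulsion between backbone heavy atoms (N, CA, C) of
    residues at least two apart in sequence, a cosine torsion bias over
    phi/psi favoring the broad alpha/beta basins, harmonic restraints on
    the backbone bond angles and a peptide-bond planarity restraint.
    Deterministic and invariant under global rotation/translation;
    pluggable behind the same contract as any external energy.
    """
    coords, resof = [], []
    for a in structure.atoms:
        if a.atom_name in ("N", "CA", "C"):
            coords.append(a.position)
            resof.append(a.residue_index)
    coords = np.asarray(coords)
    resof = np.asarray(resof)
    pi, pj = _heavy_pairs(resof)
    ic = geometry.extract_dihedrals(structure)
    return (_repulsion_energy(coords, pi, pj) + _torsion_bias(ic.phi, ic.psi)
            + _bond_angle_energy(ic) + _omega_energy(ic))


# ---------------------------------------------------------------------------
# Sampler state with incremental energy bookkeeping

@dataclass
class Proposal:
    kind: str
    residue: int = -1          # 0-based
    angle_index: int = 0       # chi index / bond-angle slot
    which: str = ""            # "phi"/"psi" or bond-angle array name
    delta: float = 0.0
    new_value: float = 0.0
    atom_type: str = ""
    concerted: bool = False    # backbone move realized as a crankshaft
    log_ratio: float = 0.0


@dataclass
class Trajectory:
    steps: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    e_ff: list = field(default_factory=list)
    e_cs: list = field(default_factory=list)
    e_hybrid: list = field(default_factory=list)
    s: list = field(default_factory=list)
    accepted: dict = field(default_factory=dict)
    proposed: dict = field(default_factory=dict)
    best_energy: float = math.inf
    best_s: dict = field(default_factory=dict)

    def acceptance_rate(self, kind: str | None = None) -> float:
        if kind is None:
            acc = sum(self.accepted.values())
            prop = sum(self.proposed.values())
        else:
            acc, prop = self.accepted.get(kind, 0), self.proposed.get(kind, 0)
        return acc / prop if prop else float("nan")

    def to_tsv(self) -> str:
        types = sorted(self.s[0]) if self.s else []
        header = ["step", "temperature_K", "e_ff", "e_cs", "e_hybrid"] + \
            [f"s_{t}" for t in types]
        lines = ["\t".join(header)]
        for k in range(len(self.steps)):
            row = [f"{self.steps[k]}", f"{self.temperature[k]:.4f}",
                   f"{self.e_ff[k]:.6f}", f"{self.e_cs[k]:.6f}",
                   f"{self.e_hybrid[k]:.6f}"] + \
                  [f"{self.s[k][t]:.6f}" for t in types]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


class SamplerState:
    """Joint state (structure internal coordinates, error scales) with
    cached energies and incremental updates.

    The flat backbone array keeps rows N0, CA0, C0, N1, ... ; dihedral
    and bond-angle moves rotate the downstream block rigidly, which
    leaves all other internal coordinates unchanged.  Derived heavy
    atoms (O, CB) are recomputed vectorized from the backbone at each
    evaluation; chi angles live only in the internal coordinates.
    """

    def __init__(self, structure: ProteinStructure, pairs, predictor,
                 s: dict, elastic: ElasticNetwork | None = None):
        self.elastic = elastic
        self.sequence = list(structure.sequence)
        self.n = len(self.sequence)
        self.internal = geometry.extract_dihedrals(structure)
        self.chain_id = structure.chain_id
        self.X = np.empty((3 * self.n, 3))
        for i in range(self.n):
            for k, nm in enumerate(("N", "CA", "C")):
                self.X[3 * i + k] = structure.find_atom(i + 1, nm).position
        self.predictor = predictor
        self.s = dict(s)
        # experimental data grouped by type, aligned with residue lists
        grouped = {}
        for res, at, val in pairs:
            grouped.setdefault(at, []).append((res, val))
        self.delta, self.res_lists, self.pos_in_type = {}, {}, {}
        for at, lst in grouped.items():
            lst.sort()
            self.res_lists[at] = np.array([r for r, _ in lst], dtype=int)
            self.delta[at] = np.array([v for _, v in lst])
            self.pos_in_type[at] = {r: k for k, (r, _) in enumerate(lst)}
        # repulsion pair list over the backbone N/CA/C atoms (O and CB are
        # rigid functions of the local frame and add little steric
        # information at soft-sphere resolution)
        res_bb = np.repeat(np.arange(1, self.n + 1), 3)
        self.cb_rows = np.array([i for i, r in enumerate(self.sequence) if r != "GLY"],
                                dtype=int)
        self._all_pair_i, self._all_pair_j = _heavy_pairs(res_bb)
        # Verlet-style neighbor list with margin, rebuilt periodically
        # (rebuild_coordinates); atoms move far less than the margin
        # between rebuilds at the default rebuild stride
        self._nl_margin = 4.0
        self._pair_i = self._all_pair_i
        self._pair_j = self._all_pair_j
        # movable slots
        self.chi_slots = [(i, k) for i in range(self.n)
                          for k in range(len(self.internal.chi[i]))]
        self.bb_slots = [(i, "phi") for i in range(1, self.n)] + \
                        [(i, "psi") for i in range(self.n - 1)]
        self.ang_slots = [(i, "ang_n_ca_c") for i in range(self.n)] + \
                         [(i, "ang_ca_c_n") for i in range(self.n - 1)] + \
                         [(i, "ang_c_n_ca") for i in range(self.n - 1)]
        # initial sigma and energies
        self.sigma = {}
        smap = self.predictor.evaluate_internal(self.internal, self.sequence)
        for at in self.delta:
            self.sigma[at] = np.array(
                [smap.get((r, at), np.nan) for r in self.res_lists[at]])
            missing = ~np.isfinite(self.sigma[at])
            if np.any(missing):
                keep = ~missing
                self.res_lists[at] = self.res_lists[at][keep]
                self.delta[at] = self.delta[at][keep]
                self.sigma[at] = self.sigma[at][keep]
                self.pos_in_type[at] = {r: k for k, r in enumerate(self.res_lists[at])}
        self.delta = {at: v for at, v in self.delta.items() if len(v) >= 3}
        if not self.delta:
            raise SamplerError("no atom type has enough matched, predictable shifts")
        self.sigma = {at: self.sigma[at] for at in self.delta}
        # regression sums per type: incremental O(1) updates per sigma change
        self._dconst, self._sums, self._e_cs_type = {}, {}, {}
        for at in self.delta:
            self._refresh_cs_sums(at)
        self._rebuild_neighbor_list()
        self.e_rep = self._full_repulsion()
        self.e_tors = _torsion_bias(self.internal.phi, self.internal.psi)
        self.e_ang = _bond_angle_energy(self.internal)
        self.e_om = _omega_energy(self.internal)
        self.e_el = self._elastic_energy()
        self._pending = None

    def _rebuild_neighbor_list(self):
        d = self.X[self._all_pair_i] - self.X[self._all_pair_j]
        r2 = np.einsum("ij,ij->i", d, d)
        cut = (REPULSION_RMIN + self._nl_margin) ** 2
        keep = r2 < cut
        self._pair_i = self._all_pair_i[keep]
        self._pair_j = self._all_pair_j[keep]

    def _elastic_energy(self) -> float:
        if self.elastic is None:
            return 0.0
        return self.elastic.energy(self.X[1::3])

    # -- energy pieces ----------------------------------------------------
    def _full_repulsion(self) -> float:
        return _repulsion_energy(self.X, self._pair_i, self._pair_j)

    def _refresh_cs_sums(self, at: str):
        d, sg = self.delta[at], self.sigma[at]
        nn = len(d)
        d1 = float(d.sum())
        self._dconst[at] = (nn, d1, float(d @ d) - d1 * d1 / nn)
        self._sums[at] = [float(sg.sum()), float(sg @ sg), float(sg @ d)]
        self._e_cs_type[at] = self._cs_type_energy(at)

    def _cs_regression(self, at: str):
        """(a_hat, b_hat, rss, sxx) from the cached sums."""
        nn, d1, dyy = self._dconst[at]
        s1, s2, sy = self._sums[at]
        sxx = s2 - s1 * s1 / nn
        if sxx <= 0:
            raise ShiftEnergyError(f"constant sigma for type {at}")
        sxy = sy - s1 * d1 / nn
        rss = max(0.0, dyy - sxy * sxy / sxx)
        a = sxy / sxx
        return a, (d1 - a * s1) / nn, rss, sxx

    def _cs_type_energy(self, at: str, s: float | None = None) -> float:
        nn, _, _ = self._dconst[at]
        _, _, rss, sxx = self._cs_regression(at)
        if s is None:
            s = self.s[at]
        return ((nn - 1) * math.log(s) + rss / (2.0 * s * s)
                + 0.5 * math.log(nn * sxx)
                + (nn / 2.0 - 1.0) * math.log(2.0 * math.pi))

    @property
    def e_cs(self) -> float:
        return float(sum(self._e_cs_type.values()))

    @property
    def e_ff(self) -> float:
        return self.e_rep + self.e_tors + self.e_ang + self.e_om + self.e_el

    @property
    def e_hybrid(self) -> float:
        return self.e_ff + self.e_cs

    def calibration(self) -> dict:
        """Plug-in (a_hat, b_hat) per type from the cached sums."""
        return {at: self._cs_regression(at)[:2] for at in self._sums}

    # -- move machinery ---------------------------------------------------
    def _rotate_downstream(self, start_row: int, point: np.ndarray,
                           axis: np.ndarray, angle_deg: float):
        u = axis / np.linalg.norm(axis)
        th = math.radians(angle_deg)
        c, si = math.cos(th), math.sin(th)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) * c + si * K + (1 - c) * np.outer(u, u)
        block = self.X[start_row:]
        self.X[start_row:] = (block - point) @ R.T + point

    def _refresh_internal_window(self, i: int):
        """Re-extract the internal coordinates affected by a crankshaft
        at residue i from the rotated Cartesian frame; returns undo info."""
        ic = self.internal
        X = self.X
        n = self.n
        undo = []

        def setv(arr, j, val):
            undo.append((arr, j, arr[j]))
            arr[j] = val

        def row(r, k):
            return X[3 * r + k]

        setv(ic.ang_n_ca_c, i, _bond_angle_scalar(row(i, 0), row(i, 1), row(i, 2)))
        if i >= 1:
            setv(ic.phi, i, _dihedral_scalar(row(i - 1, 2), row(i, 0),
                                             row(i, 1), row(i, 2)))
        if i <= n - 2:
            setv(ic.psi, i, _dihedral_scalar(row(i, 0), row(i, 1),
                                             row(i, 2), row(i + 1, 0)))
            setv(ic.omega, i + 1, _dihedral_scalar(row(i, 1), row(i, 2),
                                                   row(i + 1, 0), row(i + 1, 1)))
            setv(ic.phi, i + 1, _dihedral_scalar(row(i, 2), row(i + 1, 0),
                                                 row(i + 1, 1), row(i + 1, 2)))
            setv(ic.ang_ca_c_n, i, _bond_angle_scalar(row(i, 1), row(i, 2),
                                                      row(i + 1, 0)))
            setv(ic.ang_c_n_ca, i, _bond_angle_scalar(row(i, 2), row(i + 1, 0),
                                                      row(i + 1, 1)))
            setv(ic.ang_n_ca_c, i + 1, _bond_angle_scalar(row(i + 1, 0),
                                                          row(i + 1, 1),
                                                          row(i + 1, 2)))
            if i + 1 <= n - 2:
                setv(ic.psi, i + 1, _dihedral_scalar(row(i + 1, 0), row(i + 1, 1),
                                                     row(i + 1, 2), row(i + 2, 0)))
        return undo

    def _apply_window_energy_deltas(self, window):
        """Incremental torsion/bond-angle/omega energy updates from the
        (array, index, old_value) undo records of a crankshaft window."""
        ic = self.internal
        for arr, j, old in window:
            new = arr[j]
            if not (np.isfinite(old) and np.isfinite(new)):
                continue
            if arr is ic.phi:
                self.e_tors += TORSION_K_PHI * (
                    math.cos(math.radians(old + 90.0))
                    - math.cos(math.radians(new + 90.0)))
            elif arr is ic.psi:
                self.e_tors += TORSION_K_PSI * (
                    math.cos(2.0 * math.radians(old + 47.0))
                    - math.cos(2.0 * math.radians(new + 47.0)))
            elif arr is ic.omega:
                d_old = old % 360.0 - 180.0
                d_new = new % 360.0 - 180.0
                self.e_om += 0.5 * OMEGA_K * (d_new ** 2 - d_old ** 2)
            elif arr is ic.ang_n_ca_c:
                t = _ANGLE_TARGETS["ang_n_ca_c"]
                self.e_ang += 0.5 * BOND_ANGLE_K * ((new - t) ** 2 - (old - t) ** 2)
            elif arr is ic.ang_ca_c_n:
                t = _ANGLE_TARGETS["ang_ca_c_n"]
                self.e_ang += 0.5 * BOND_ANGLE_K * ((new - t) ** 2 - (old - t) ** 2)
            elif arr is ic.ang_c_n_ca:
                t = _ANGLE_TARGETS["ang_c_n_ca"]
                self.e_ang += 0.5 * BOND_ANGLE_K * ((new - t) ** 2 - (old - t) ** 2)

    def _window_angles_ok(self, i: int) -> bool:
        ic = self.internal
        vals = [ic.ang_n_ca_c[i], ic.ang_ca_c_n[i], ic.ang_c_n_ca[i],
                ic.ang_n_ca_c[i + 1]]
        return all(BOND_ANGLE_RANGE[0] <= v <= BOND_ANGLE_RANGE[1]
                   for v in vals if np.isfinite(v))

    def _sigma_snapshot(self, residues):
        """Backup sums, then update sigma; returns (undo, backup, changed)."""
        backup = {at: list(self._sums[at]) for at in self._sums}
        undo, changed = self._sigma_update(residues)
        return undo, backup, changed

    def _sigma_update(self, residues):
        """Recompute sigma for a residue neighborhood, maintaining the
        regression sums incrementally; returns (undo, changed_types)."""
        todo = sorted({r for r in residues if 1 <= r <= self.n})
        smap = self.predictor.evaluate_internal(self.internal, self.sequence,
                                                residues=todo)
        undo = []
        changed = set()
        for at in self.sigma:
            pos = self.pos_in_type[at]
            sums = self._sums[at]
            delta = self.delta[at]
            sig = self.sigma[at]
            for r in todo:
                k = pos.get(r)
                if k is None:
                    continue
                new = smap.get((r, at))
                if new is None:
                    continue
                old = sig[k]
                undo.append((at, k, old))
                sig[k] = new
                sums[0] += new - old
                sums[1] += new * new - old * old
                sums[2] += delta[k] * (new - old)
                changed.add(at)
        return undo, changed

    def trial(self, prop: Proposal) -> float:
        """Apply a proposal provisionally; returns dE_hybrid.

        Exactly one trial may be pending; follow with commit() or
        revert().
        """
        if self._pending is not None:
            raise SamplerError("a trial is already pending")
        old = {"e_rep": self.e_rep, "e_tors": self.e_tors, "e_ang": self.e_ang,
               "e_om": self.e_om, "e_el": self.e_el,
               "e_cs_type": dict(self._e_cs_type)}
        e0 = self.e_hybrid
        ic = self.internal
        if prop.kind in ("uniform_chi", "local_chi"):
            i, k = prop.residue, prop.angle_index
            old["chi"] = (i, k, ic.chi[i][k])
            ic.chi[i][k] = prop.new_value
            old["sigma"], old["sums"], changed = self._sigma_snapshot([i + 1])
            for at in changed:
                self._e_cs_type[at] = self._cs_type_energy(at)
        elif prop.kind == "backbone" and prop.concerted:
            # crankshaft: rotate C_i and N_{i+1} about the CA_i-CA_{i+1}
            # axis; every CA and the distal chain stay fixed, so the move
            # carries no lever arm and no elastic-network cost
            i = prop.residue
            rows = slice(3 * i + 2, 3 * i + 4)
            old["rot"] = (3 * i + 2, self.X[rows].copy())
            point = self.X[3 * i + 1]
            axis = self.X[3 * i + 4] - point
            u = axis / np.linalg.norm(axis)
            th = math.radians(prop.delta)
            c, si = math.cos(th), math.sin(th)
            K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
            R = np.eye(3) * c + si * K + (1 - c) * np.outer(u, u)
            self.X[rows] = (self.X[rows] - point) @ R.T + point
            old["window"] = self._refresh_internal_window(i)
            if not self._window_angles_ok(i):
                # bond angle pushed outside the allowed range: force reject
                old["sigma"], old["sums"], changed = [], dict(self._sums), set()
                self._pending = old
                return math.inf
            old["sigma"], old["sums"], changed = self._sigma_snapshot(
                [i, i + 1, i + 2, i + 3])
            for at in changed:
                self._e_cs_type[at] = self._cs_type_energy(at)
            self.e_rep = self._full_repulsion()
            self._apply_window_energy_deltas(old["window"])
        elif prop.kind == "backbone":
            i = prop.residue
            arr = ic.phi if prop.which == "phi" else ic.psi
            old["angle"] = (arr, i, arr[i])
            if prop.which == "phi":
                start, point, axis = 3 * i + 2, self.X[3 * i + 1], \
                    self.X[3 * i + 1] - self.X[3 * i]
                self.e_tors += TORSION_K_PHI * (
                    math.cos(math.radians(arr[i] + 90.0))
                    - math.cos(math.radians(prop.new_value + 90.0)))
            else:
                start, point, axis = 3 * i + 3, self.X[3 * i + 2], \
                    self.X[3 * i + 2] - self.X[3 * i + 1]
                self.e_tors += TORSION_K_PSI * (
                    math.cos(2.0 * math.radians(arr[i] + 47.0))
                    - math.cos(2.0 * math.radians(prop.new_value + 47.0)))
            old["rot"] = (start, self.X[start:].copy())
            # right-handed rotation about the bond decreases the torsion
            self._rotate_downstream(start, point, axis, -prop.delta)
            arr[i] = prop.new_value
            old["sigma"], old["sums"], changed = self._sigma_snapshot([i, i + 1, i + 2])
            for at in changed:
                self._e_cs_type[at] = self._cs_type_energy(at)
            self.e_rep = self._full_repulsion()
            self.e_el = self._elastic_energy()
        elif prop.kind == "bond_angle":
            i = prop.residue
            arr = getattr(ic, prop.which)
            old["angle"] = (arr, i, arr[i])
            t0 = _ANGLE_TARGETS[prop.which]
            self.e_ang += 0.5 * BOND_ANGLE_K * (
                (prop.new_value - t0) ** 2 - (arr[i] - t0) ** 2)
            if prop.which == "ang_n_ca_c":
                start = 3 * i + 2
                point = self.X[3 * i + 1]
                axis = np.cross(self.X[3 * i] - point, self.X[3 * i + 2] - point)
            elif prop.which == "ang_ca_c_n":
                start = 3 * i + 3
                point = self.X[3 * i + 2]
                axis = np.cross(self.X[3 * i + 1] - point, self.X[3 * i + 3] - point)
            else:  # ang_c_n_ca: vertex N(i+1)
                start = 3 * i + 4
                point = self.X[3 * i + 3]
                axis = np.cross(self.X[3 * i + 2] - point, self.X[3 * i + 4] - point)
            old["rot"] = (start, self.X[start:].copy())
            self._rotate_downstream(start, point, axis, prop.delta)
            arr[i] = prop.new_value
            self.e_rep = self._full_repulsion()
            self.e_el = self._elastic_energy()
        elif prop.kind == "scale":
            at = prop.atom_type
            old["s"] = (at, self.s[at])
            self.s[at] = prop.new_value
            self._e_cs_type[at] = self._cs_type_energy(at, prop.new_value)
        else:
            raise SamplerError(f"unknown move kind {prop.kind!r}")
        self._pending = old
        return self.e_hybrid - e0

    def commit(self):
        if self._pending is None:
            raise SamplerError("no pending trial")
        self._pending = None

    def revert(self):
        old = self._pending
        if old is None:
            raise SamplerError("no pending trial")
        if "chi" in old:
            i, k, v = old["chi"]
            self.internal.chi[i][k] = v
        if "angle" in old:
            arr, i, v = old["angle"]
            arr[i] = v
        if "window" in old:
            for arr, j, v in reversed(old["window"]):
                arr[j] = v
        if "rot" in old:
            start, block = old["rot"]
            self.X[start:start + len(block)] = block
        if "sigma" in old:
            for at, k, v in old["sigma"]:
                self.sigma[at][k] = v
        if "sums" in old:
            self._sums = old["sums"]
        if "s" in old:
            at, v = old["s"]
            self.s[at] = v
        self.e_rep = old["e_rep"]
        self.e_tors = old["e_tors"]
        self.e_ang = old["e_ang"]
        self.e_om = old["e_om"]
        self.e_el = old["e_el"]
        self._e_cs_type = old["e_cs_type"]
        self._pending = None

    # -- consistency and materialization ----------------------------------
    def rebuild_coordinates(self):
        """Recompute the backbone from internal coordinates (kills the
        slow numerical drift of accumulated incremental rotations) and
        refresh cached energies."""
        bb = geometry.build_backbone_arrays(self.internal)
        # re-anchor in the current frame: superpose new backbone onto old
        old = self.X.reshape(self.n, 3, 3)
        sup = geometry.kabsch_superpose(old.reshape(-1, 3), bb.reshape(-1, 3))
        self.X = (bb.reshape(-1, 3) @ sup.rotation.T) + sup.translation
        self._rebuild_neighbor_list()
        self.e_rep = self._full_repulsion()
        self.e_tors = _torsion_bias(self.internal.phi, self.internal.psi)
        self.e_ang = _bond_angle_energy(self.internal)
        self.e_om = _omega_energy(self.internal)
        self.e_el = self._elastic_energy()
        for at in self.sigma:
            self._refresh_cs_sums(at)

    def check_consistency(self, atol: float = 1e-9) -> bool:
        """Re-derive all cached energies from scratch and compare."""
        e_rep = self._full_repulsion()
        e_tors = _torsion_bias(self.internal.phi, self.internal.psi)
        e_ang = _bond_angle_energy(self.internal)
        smap = self.predictor.evaluate_internal(self.internal, self.sequence)
        ok = (abs(e_rep - self.e_rep) < atol and abs(e_tors - self.e_tors) < atol
              and abs(e_ang - self.e_ang) < atol
              and abs(_omega_energy(self.internal) - self.e_om) < atol
              and abs(self._elastic_energy() - self.e_el) < atol)
        for at in self.sigma:
            fresh = np.array([smap[(r, at)] for r in self.res_lists[at]])
            ok = ok and np.allclose(fresh, self.sigma[at], atol=atol)
            sums = self._sums[at]
            sg = self.sigma[at]
            ok = ok and np.allclose(
                [sg.sum(), sg @ sg, sg @ self.delta[at]], sums,
                rtol=1e-9, atol=atol)
        return bool(ok)

    def to_structure(self) -> ProteinStructure:
        bb = self.X.reshape(self.n, 3, 3)
        derived = derived_atom_positions(bb, self.internal, self.sequence)
        atoms = []
        for i, res in enumerate(self.sequence):
            idx = i + 1
            atoms.append(AtomRecord(idx, res, "N", bb[i, 0].copy()))
            atoms.append(AtomRecord(idx, res, "CA", bb[i, 1].copy()))
            atoms.append(AtomRecord(idx, res, "C", bb[i, 2].copy()))
            for nm in ("O", "H", "HA", "CB"):
                pos = derived[nm][i]
                if np.all(np.isfinite(pos)):
                    atoms.append(AtomRecord(idx, res, nm, pos.copy()))
        return ProteinStructure(sequence=list(self.sequence), atoms=atoms,
                                chain_id=self.chain_id,
                                chi=[c.copy() for c in self.internal.chi])

    def snapshot_internal(self) -> InternalCoordinates:
        return self.internal.copy()


def propose_move(state: SamplerState, moveset: MoveSet,
                 rng: np.random.Generator) -> Proposal:
    """Draw one move by normalized weight.

    Side-chain moves redraw if the chain has no rotatable chi angles;
    bond-angle proposals leaving [90, 135] degrees carry log_ratio =
    -inf (rejected outright, which keeps the proposal symmetric inside
    the allowed range).
    """
    cum = moveset.cumulative_weights()
    ic = state.internal
    for _ in range(1000):
        kind = MoveSet.MOVE_KINDS[bisect.bisect_left(cum, rng.random())]
        if kind in ("uniform_chi", "local_chi") and not state.chi_slots:
            continue
        break
    else:
        raise SamplerError("could not draw a feasible move")
    if kind == "uniform_chi":
        i, k = state.chi_slots[rng.integers(len(state.chi_slots))]
        new = float(rng.uniform(-180.0, 180.0))
        return Proposal(kind=kind, residue=i, angle_index=k,
                        new_value=180.0 if new == -180.0 else new)
    if kind == "local_chi":
        i, k = state.chi_slots[rng.integers(len(state.chi_slots))]
        new = _wrap_angle(ic.chi[i][k] + rng.normal(0.0, moveset.chi_step))
        return Proposal(kind=kind, residue=i, angle_index=k, new_value=new)
    if kind == "backbone":
        if rng.random() < moveset.crankshaft_fraction and state.n >= 2:
            i = int(rng.integers(state.n - 1))
            d = float(rng.normal(0.0, moveset.crank_step))
            return Proposal(kind=kind, residue=i, delta=d, concerted=True)
        i, which = state.bb_slots[rng.integers(len(state.bb_slots))]
        d = float(rng.normal(0.0, moveset.backbone_step))
        cur = ic.phi[i] if which == "phi" else ic.psi[i]
        return Proposal(kind=kind, residue=i, which=which, delta=d,
                        new_value=_wrap_angle(cur + d))
    if kind == "bond_angle":
        i, which = state.ang_slots[rng.integers(len(state.ang_slots))]
        d = float(rng.normal(0.0, moveset.bond_angle_step))
        cur = float(getattr(ic, which)[i])
        new = cur + d
        log_ratio = 0.0
        if not BOND_ANGLE_RANGE[0] <= new <= BOND_ANGLE_RANGE[1]:
            log_ratio = -math.inf
        return Proposal(kind=kind, residue=i, which=which, delta=d,
                        new_value=new, log_ratio=log_ratio)
    # scale move: symmetric in ln s; the Jeffreys measure lives in E_CS
    types = sorted(state.s)
    at = types[rng.integers(len(types))]
    u = float(rng.uniform(-moveset.scale_step, moveset.scale_step))
    new = state.s[at] * math.exp(u)
    log_ratio = 0.0
    if not SCALE_RANGE[0] <= new <= SCALE_RANGE[1]:
        log_ratio = -math.inf
    return Proposal(kind="scale", atom_type=at, new_value=new, log_ratio=log_ratio)


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else float(a)


# ---------------------------------------------------------------------------
# Run protocols

DEFAULT_S_INIT = {"CA": 1.0, "CB": 1.0, "C": 1.0, "HA": 0.3, "H": 0.3, "N": 1.0}


def _run(state: SamplerState, schedule_fn, n_steps: int, moveset: MoveSet,
         rng: np.random.Generator, thin: int, rebuild_every: int = 5000,
         snapshot_stride: int = 0, track_best: bool = True):
    traj = Trajectory()
    for k in MoveSet.MOVE_KINDS:
        traj.accepted[k] = 0
        traj.proposed[k] = 0
    best = (state.e_hybrid, state.snapshot_internal(), dict(state.s))
    snapshots = []

    def record(step, temp):
        traj.steps.append(step)
        traj.temperature.append(temp)
        traj.e_ff.append(state.e_ff)
        traj.e_cs.append(state.e_cs)
        traj.e_hybrid.append(state.e_hybrid)
        traj.s.append(dict(state.s))

    record(0, schedule_fn(0))
    for step in range(1, n_steps + 1):
        temp = schedule_fn(step)
        prop = propose_move(state, moveset, rng)
        traj.proposed[prop.kind] += 1
        if prop.log_ratio == -math.inf:
            accepted = False
        else:
            de = state.trial(prop)
            if metropolis_step(de, temp, rng, prop.log_ratio):
                state.commit()
                accepted = True
            else:
                state.revert()
                accepted = False
        if accepted:
            traj.accepted[prop.kind] += 1
            if track_best and state.e_hybrid < best[0]:
                best = (state.e_hybrid, state.snapshot_internal(), dict(state.s))
        if thin and step % thin == 0:
            record(step, temp)
        if snapshot_stride and step % snapshot_stride == 0:
            snapshots.append(state.snapshot_internal())
        if rebuild_every and step % rebuild_every == 0:
            state.rebuild_coordinates()
    traj.best_energy = best[0]
    traj.best_s = dict(best[2])
    if not snapshot_stride:
        return best, traj
    if not snapshots:
        snapshots.append(state.snapshot_internal())
    return best, traj, snapshots


def _internal_to_structure(internal: InternalCoordinates, template: SamplerState):
    return build_backbone(template.sequence, internal, chain_id=template.chain_id)


def _default_elastic(start: ProteinStructure, elastic):
    """True -> network anchored on the start; None/False -> none."""
    if elastic is True:
        return ElasticNetwork.from_structure(start)
    return elastic or None


def run_annealing(start: ProteinStructure, shifts, predictor,
                  schedule: AnnealingSchedule | None = None,
                  moveset: MoveSet | None = None, seed: int = 0,
                  s_init: dict | None = None, thin: int = 1000,
                  schedule_kind: str = "geometric", elastic=True):
    """Simulated annealing of the hybrid energy.

    Returns (refined structure, trajectory).  The refined structure is
    the lowest-hybrid-energy state visited anywhere along the run, not
    the final state; independent repeats differ only by seed.  By
    default the force field includes an elastic network anchored on the
    start structure (``elastic`` may be False or a custom
    ElasticNetwork).
    """
    schedule = schedule or AnnealingSchedule()
    moveset = moveset or MoveSet()
    s_init = dict(DEFAULT_S_INIT if s_init is None else s_init)
    rng = np.random.default_rng(seed)
    pairs = match_shifts(start, shifts)
    state = SamplerState(start, pairs, predictor, s_init,
                         elastic=_default_elastic(start, elastic))
    if schedule.n_steps == 0:
        traj = Trajectory()
        return start.copy(), traj
    sched = lambda i: geometric_temperature(i, schedule, kind=schedule_kind)
    best, traj = _run(state, sched, schedule.n_steps, moveset, rng, thin)
    refined = _internal_to_structure(best[1], state)
    refined = _superpose_onto(refined, start)
    return refined, traj


def run_constant_temperature(start: ProteinStructure, shifts, predictor,
                             temperature: float = 300.0, n_steps: int = 500_000,
                             moveset: MoveSet | None = None, seed: int = 0,
                             s_init: dict | None = None,
                             snapshot_stride: int = 500, thin: int = 1000,
                             elastic=True):
    """Constant-temperature MH run; returns (ensemble, trajectory).

    The snapshots do not form a thermodynamic ensemble (the energy
    contains the data restraint); they feed ensemble shielding
    averaging and cluster-representative extraction.
    """
    moveset = moveset or MoveSet()
    s_init = dict(DEFAULT_S_INIT if s_init is None else s_init)
    rng = np.random.default_rng(seed)
    pairs = match_shifts(start, shifts)
    state = SamplerState(start, pairs, predictor, s_init,
                         elastic=_default_elastic(start, elastic))
    sched = lambda i: temperature
    best, traj, snaps = _run(state, sched, n_steps, moveset, rng, thin,
                             snapshot_stride=snapshot_stride)
    ensemble = [_superpose_onto(_internal_to_structure(ic, state), start)
                for ic in snaps]
    return ensemble, traj


def _superpose_onto(structure: ProteinStructure,
                    reference: ProteinStructure) -> ProteinStructure:
    """Rigid-align a rebuilt structure onto a reference frame via CA atoms."""
    A = np.array([reference.find_atom(i + 1, "CA").position
                  for i in range(reference.n_residues)])
    B = np.array([structure.find_atom(i + 1, "CA").position
                  for i in range(structure.n_residues)])
    if len(A) != len(B):
        return structure
    sup = geometry.kabsch_superpose(A, B)
    out = structure.copy()
    for a in out.atoms:
        a.position = sup.rotation @ a.position + sup.translation
    return out


def cluster_representative(ensemble, threshold: float = 1.0) -> ProteinStructure:
    """Centroid member of the largest cluster of an ensemble.

    Average-linkage agglomerative clustering of the pairwise CA-RMSD
    matrix, cut at ``threshold`` Angstrom; within the largest cluster
    (lowest cluster label breaks ties) the member minimizing the summed
    CA-RMSD to its cluster mates (first by index on ties) is returned.
    """
    if not ensemble:
        raise SamplerError("empty ensemble")
    m = len(ensemble)
    if m == 1:
        return ensemble[0]
    dm = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dm[i, j] = dm[j, i] = geometry.ca_rmsd(ensemble[i], ensemble[j])
    labels = fcluster(average(squareform(dm, checks=False)), t=threshold,
                      criterion="distance")
    sizes = np.bincount(labels)
    biggest = int(np.argmax(sizes))
    members = np.flatnonzero(labels == biggest)
    sums = dm[np.ix_(members, members)].sum(axis=1)
    return ensemble[int(members[int(np.argmin(sums))])]
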