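"""File formats and shift/structure pairing.

Reads a single-chain, single-model PDB subset (via gemmi, with validation
on top), writes fixed-column PDB with optional per-residue B-factors,
reads chemical-shift tables (TSV and a minimal NMR-STAR v3 loop), reads
sequence-corrected random-coil tables, and pairs shifts with a structure.

Only the six evaluated atom types (CA, CB, C, HA, H, N) are modeled;
every parser filters to these.  Residue indexing is 1-based and shifts
are always in ppm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# number of rotatable side-chain chi angles per residue type
CHI_COUNTS = {
    "ALA": 0, "GLY": 0, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "PRO": 2, "ASN": 2, "ASP": 2, "HIS": 2, "ILE": 2, "LEU": 2,
    "PHE": 2, "TRP": 2, "TYR": 2, "GLN": 3, "GLU": 3, "MET": 3,
    "ARG": 4, "LYS": 4,
}

ATOM_TYPES = ("CA", "CB", "C", "HA", "H", "N")


class StructureIOError(ValueError):
    pass


@dataclass
class AtomRecord:
    residue_index: int
    residue_type: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureIOError(
                f"atom {self.atom_name} of residue {self.residue_index}: bad position")
        if not self.atom_name:
            raise StructureIOError("empty atom name")


@dataclass
class ProteinStructure:
    """Residues with named atoms and Cartesian coordinates (Angstrom).

    ``chi`` carries per-residue side-chain dihedral angles (degrees) as
    metadata; side-chain atoms beyond CB are not represented.
    """

    sequence: list
    atoms: list
    chain_id: str = "A"
    chi: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()
        self._index = {(a.residue_index, a.atom_name): a for a in self.atoms}

    def validate(self):
        indices = sorted({a.residue_index for a in self.atoms})
        if indices != list(range(1, len(self.sequence) + 1)):
            raise StructureIOError("residue indices must be 1..n, strictly increasing")
        seen = set()
        for a in self.atoms:
            key = (a.residue_index, a.atom_name)
            if key in seen:
                raise StructureIOError(
                    f"duplicate atom {a.atom_name} in residue {a.residue_index}")
            seen.add(key)
        for i in range(1, len(self.sequence) + 1):
            for name in ("N", "CA", "C"):
                if (i, name) not in seen:
                    raise StructureIOError(
                        f"residue {i} ({self.sequence[i - 1]}) is missing backbone atom {name}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def find_atom(self, residue_index: int, atom_name: str):
        return self._index.get((residue_index, atom_name))

    def coordinates(self, atom_name: str) -> np.ndarray:
        """(n, 3) array for one backbone atom name, NaN where absent."""
        out = np.full((self.n_residues, 3), np.nan)
        for i in range(1, self.n_residues + 1):
            a = self.find_atom(i, atom_name)
            if a is not None:
                out[i - 1] = a.position
        return out

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            sequence=list(self.sequence),
            atoms=[AtomRecord(a.residue_index, a.residue_type, a.atom_name,
                              a.position.copy()) for a in self.atoms],
            chain_id=self.chain_id,
            chi=[np.asarray(c, dtype=float).copy() for c in self.chi],
        )


@dataclass
class ShiftRecord:
    residue_index: int
    residue_type: str
    atom_type: str
    value: float

    def __post_init__(self):
        if self.atom_type not in ATOM_TYPES:
            raise StructureIOError(
                f"atom_type {self.atom_type!r} not supported; allowed: {ATOM_TYPES}")
        if self.residue_type == "GLY" and self.atom_type == "CB":
            raise StructureIOError(f"residue {self.residue_index}: glycine has no CB")
        if not np.isfinite(self.value):
            raise StructureIOError(
                f"non-finite shift for residue {self.residue_index} {self.atom_type}")


@dataclass
class ShiftTable:
    records: list
    source: str = ""

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.residue_index, r.atom_type)
            if key in seen:
                raise StructureIOError(f"duplicate shift for residue {key[0]} {key[1]}")
            seen.add(key)

    def __len__(self):
        return len(self.records)


@dataclass
class RandomCoilTable:
    """Random-coil shifts with optional neighbor-sequence corrections.

    ``base`` maps (residue_type, atom_type) -> ppm.  ``corrections`` maps
    (neighbor_residue_type, offset, atom_type) -> ppm where offset is in
    {-2, -1, +1, +2} relative to the residue of interest.
    """

    base: dict
    corrections: dict = field(default_factory=dict)

    def __post_init__(self):
        for res in STANDARD_RESIDUES:
            for at in ATOM_TYPES:
                if res == "GLY" and at == "CB":
                    continue
                if (res, at) not in self.base:
                    raise StructureIOError(f"random-coil table missing ({res}, {at})")

    def lookup(self, sequence, residue_index: int, atom_type: str) -> float:
        """Sequence-corrected random-coil value for a residue (1-based)."""
        res = sequence[residue_index - 1]
        if (res, atom_type) not in self.base:
            raise StructureIOError(
                f"no random-coil entry for ({res}, {atom_type}) at residue {residue_index}")
        value = self.base[(res, atom_type)]
        for off in (-2, -1, 1, 2):
            j = residue_index - 1 + off
            if 0 <= j < len(sequence):
                value += self.corrections.get((sequence[j], off, atom_type), 0.0)
        return value


# ---------------------------------------------------------------------------
# PDB

def read_pdb(text: str, chain: str | None = None) -> ProteinStructure:
    """Parse PDB content: first model, one chain, ATOM records only.

    Alternate locations resolve to the highest-occupancy (first seen on
    ties) conformer; HETATM records are skipped; insertion codes are
    rejected.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"unparseable PDB content: {exc}") from exc
    if len(st) == 0:
        raise StructureIOError("no protein atoms")
    model = st[0]
    target = None
    for ch in model:
        if chain is None or ch.name == chain:
            target = ch
            break
    if target is None:
        raise StructureIOError(f"chain {chain!r} not found")
    sequence, atoms = [], []
    index = 0
    for res in target:
        if res.het_flag != "A":
            continue
        if res.seqid.icode.strip():
            raise StructureIOError(
                f"insertion code {res.seqid.icode!r} at residue {res.seqid.num}: unsupported")
        if res.name not in STANDARD_RESIDUES:
            continue
        index += 1
        sequence.append(res.name)
        best = {}
        for atom in res:
            name = atom.name
            if name not in best or atom.occ > best[name].occ:
                best[name] = atom
        for name, atom in best.items():
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            atoms.append(AtomRecord(index, res.name, name, pos))
    if not atoms:
        raise StructureIOError("no protein atoms")
    return ProteinStructure(sequence=sequence, atoms=atoms, chain_id=target.name)


_PDB_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4, "H": 5, "HA": 6}


def write_pdb(structure: ProteinStructure, bfactor: dict | None = None) -> str:
    """Fixed-column PDB ATOM records, TER/END terminated.

    If ``bfactor`` maps residue_index -> scalar, every atom of that
    residue carries the value clamped to [0, 99.99]; residues keyed
    outside the structure are an error.
    """
    if bfactor:
        for idx in bfactor:
            if not 1 <= idx <= structure.n_residues:
                raise StructureIOError(f"B-factor for residue {idx} not in structure")
    lines = []
    serial = 0
    atoms = sorted(structure.atoms,
                   key=lambda a: (a.residue_index, _PDB_ORDER.get(a.atom_name, 99)))
    for a in atoms:
        serial += 1
        b = 0.0
        if bfactor and a.residue_index in bfactor:
            b = min(max(float(bfactor[a.residue_index]), 0.0), 99.99)
        element = a.atom_name[0]
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:5d} {name}{'':1s}{a.residue_type:>3s} "
            f"{structure.chain_id:1s}{a.residue_index:4d}{'':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}{'':10s}{element:>2s}"
        )
    last = atoms[-1]
    serial += 1
    lines.append(f"TER   {serial:5d}      {last.residue_type:>3s} "
                 f"{structure.chain_id:1s}{last.residue_index:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Shift tables

def read_shift_tsv(text: str) -> ShiftTable:
    """Read a shift table with columns residue_index, residue_type,
    atom_type, value (tab- or comma-delimited); '.' or empty values skip
    the line."""
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python", dtype=str)
    required = {"residue_index", "residue_type", "atom_type", "value"}
    missing = required - set(df.columns)
    if missing:
        raise StructureIOError(f"shift table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        value = (row.value or "").strip() if isinstance(row.value, str) else row.value
        if value in (".", "", None) or (isinstance(value, float) and np.isnan(value)):
            continue
        records.append(ShiftRecord(
            residue_index=int(row.residue_index),
            residue_type=str(row.residue_type).strip().upper(),
            atom_type=str(row.atom_type).strip(),
            value=float(value),
        ))
    return ShiftTable(records=records, source="tsv")


def read_nmrstar_shifts(text: str) -> ShiftTable:
    """Extract a minimal ``_Atom_chem_shift`` loop from NMR-STAR v3 text.

    Only rows whose atom ID is one of the six supported types are kept.
    No installed package reads NMR-STAR, so this is a small tolerant
    tokenizer covering the chemical-shift loop only.
    """
    lines = text.splitlines()
    i = 0
    n = len(lines)
    records = []
    found = False
    while i < n:
        if lines[i].strip().lower() != "loop_":
            i += 1
            continue
        i += 1
        tags = []
        while i < n and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip())
            i += 1
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        found = True
        cols = {t.split(".", 1)[1].lower(): k for k, t in enumerate(tags)}
        def col(*names):
            for nm in names:
                if nm in cols:
                    return cols[nm]
            raise StructureIOError(f"chemical-shift loop missing tag {names[0]}")
        c_seq = col("seq_id", "comp_index_id")
        c_res = col("comp_id")
        c_atom = col("atom_id")
        c_val = col("val", "value")
        while i < n:
            stripped = lines[i].strip()
            if not stripped or stripped.lower() in ("stop_",) or stripped.startswith("_"):
                break
            fields = stripped.split()
            if len(fields) >= len(tags):
                atom = fields[c_atom]
                val = fields[c_val]
                if atom in ATOM_TYPES and val not in (".", "?"):
                    records.append(ShiftRecord(
                        residue_index=int(fields[c_seq]),
                        residue_type=fields[c_res].upper(),
                        atom_type=atom,
                        value=float(val),
                    ))
            i += 1
    if not found:
        raise StructureIOError("no _Atom_chem_shift loop found")
    return ShiftTable(records=records, source="nmrstar")


def read_random_coil_tsv(text: str) -> RandomCoilTable:
    """Random-coil table: rows residue_type, atom_type, value; correction
    rows additionally carry neighbor_residue_type and offset columns."""
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python", dtype=str)
    required = {"residue_type", "atom_type", "value"}
    if required - set(df.columns):
        raise StructureIOError("random-coil table needs residue_type, atom_type, value")
    has_corr = {"neighbor_residue_type", "offset"} <= set(df.columns)
    base, corrections = {}, {}
    for row in df.itertuples(index=False):
        at = str(row.atom_type).strip()
        value = float(row.value)
        neighbor = getattr(row, "neighbor_residue_type", None) if has_corr else None
        if has_corr and isinstance(neighbor, str) and neighbor.strip():
            corrections[(neighbor.strip().upper(), int(row.offset), at)] = value
        else:
            base[(str(row.residue_type).strip().upper(), at)] = value
    return RandomCoilTable(base=base, corrections=corrections)


def write_random_coil_tsv(table: RandomCoilTable) -> str:
    lines = ["residue_type\tatom_type\tvalue\tneighbor_residue_type\toffset"]
    for (res, at), v in sorted(table.base.items()):
        lines.append(f"{res}\t{at}\t{v:.4f}\t\t")
    for (nb, off, at), v in sorted(table.corrections.items()):
        lines.append(f"\t{at}\t{v:.4f}\t{nb}\t{off:d}")
    return "\n".join(lines) + "\n"


def write_shift_tsv(table: ShiftTable) -> str:
    lines = ["residue_index\tresidue_type\tatom_type\tvalue"]
    for r in sorted(table.records, key=lambda r: (r.residue_index, r.atom_type)):
        lines.append(f"{r.residue_index}\t{r.residue_type}\t{r.atom_type}\t{r.value:.4f}")
    return "\n".join(lines) + "\n"


def match_shifts(structure: ProteinStructure, shifts: ShiftTable):
    """Pair shifts with structure residues.

    Returns (residue_index, atom_type, value) tuples sorted by
    (residue_index, atom_type), restricted to residues present in the
    structure.  A shift record whose residue type disagrees with the
    structure sequence is an error (guards against sequence mismatches
    between the coordinates and the shift deposition).
    """
    pairs = []
    for r in shifts.records:
        if not 1 <= r.residue_index <= structure.n_residues:
            continue
        expected = structure.sequence[r.residue_index - 1]
        if r.residue_type and r.residue_type != expected:
            raise StructureIOError(
                f"residue {r.residue_index}: shift table says {r.residue_type}, "
                f"structure says {expected}")
        pairs.append((r.residue_index, r.atom_type, r.value))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs
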