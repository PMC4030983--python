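"""Cα-trace data model, PDB/FASTA/feature I/O, and virtual-bond geometry.

A protein conformation is represented throughout the package by its Cα trace
only: one 3D point per residue plus the amino-acid sequence and, optionally,
per-residue predicted 1D features (three-state secondary structure and a
two-class solvent-accessibility label).  The internal-coordinate view
(virtual bond lengths, planar bond angles, torsions) supports fragment
replacement: editing a contiguous stretch of internal coordinates moves the
downstream chain rigidly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1

SS3_CLASSES = ("H", "E", "C")
ACC_CLASSES = ("buried", "exposed")

#: letter codes for the two accessibility classes in feature tables
ACC_LETTERS = {"buried": "b", "exposed": "e"}
ACC_FROM_LETTER = {v: k for k, v in ACC_LETTERS.items()}

_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


class PdbFormatError(ValueError):
    """Raised on malformed or unsupported PDB input/output."""


@dataclass
class CaTrace:
    """Sequence plus ordered Cα coordinates, with optional 1D features.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid codes, length L.
    coords : (L, 3) ndarray
        Cα coordinates in Å, chain order.
    ss3 : str or None
        Per-residue secondary-structure class in {H, E, C}.
    acc : tuple of str or None
        Per-residue accessibility class in {buried, exposed}.
    """

    sequence: str
    coords: np.ndarray
    ss3: str | None = None
    acc: tuple | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        L = len(self.sequence)
        if L < 1:
            raise ValueError("CaTrace needs at least one residue")
        if self.coords.shape != (L, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match sequence length {L}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.ss3 is not None:
            if len(self.ss3) != L:
                raise ValueError("ss3 length mismatch")
            bad = set(self.ss3) - set(SS3_CLASSES)
            if bad:
                raise ValueError(f"invalid ss3 classes: {bad}")
        if self.acc is not None:
            self.acc = tuple(self.acc)
            if len(self.acc) != L:
                raise ValueError("acc length mismatch")
            bad = set(self.acc) - set(ACC_CLASSES)
            if bad:
                raise ValueError(f"invalid acc classes: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_features(self) -> bool:
        return self.ss3 is not None and self.acc is not None

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        """Copy of this trace with new coordinates, features preserved."""
        return replace(self, coords=np.array(coords, dtype=float))

    def copy(self) -> "CaTrace":
        return self.with_coords(self.coords.copy())


@dataclass
class InternalCoords:
    """Virtual-bond internal coordinates of a Cα trace of length L.

    bond_lengths : (L-1,) Å; bond_angles : (L-2,) planar angles in [0, π];
    torsions : (L-3,) dihedrals in (−π, π].
    """

    bond_lengths: np.ndarray
    bond_angles: np.ndarray
    torsions: np.ndarray

    def __post_init__(self):
        self.bond_lengths = np.asarray(self.bond_lengths, dtype=float)
        self.bond_angles = np.asarray(self.bond_angles, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        if np.any(self.bond_lengths <= 0):
            raise ValueError("bond lengths must be positive")
        if np.any((self.bond_angles < 0) | (self.bond_angles > np.pi)):
            raise ValueError("bond angles must lie in [0, pi]")

    @property
    def n_residues(self) -> int:
        return len(self.bond_lengths) + 1

    def copy(self) -> "InternalCoords":
        return InternalCoords(
            self.bond_lengths.copy(), self.bond_angles.copy(), self.torsions.copy()
        )


# ---------------------------------------------------------------------------
# PDB I/O.  Cα-only ATOM records; MODEL/ENDMDL blocks for conformation sets.
# Hand-rolled record parsing keeps line-number error reporting and the strict
# "every residue must carry a CA" contract that generic parsers silently relax.
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        altloc = line[16]
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    return name, altloc, resname, chain, resseq, (x, y, z)


def _residues_to_trace(residues: dict) -> CaTrace:
    seq, xyz = [], []
    for (chain, resseq, resname), ca in residues.items():
        if ca is None:
            raise PdbFormatError(
                f"residue {resname} {chain}{resseq} has no CA atom"
            )
        seq.append(protein_letters_3to1.get(resname, "X"))
        xyz.append(ca)
    return CaTrace("".join(seq), np.array(xyz, dtype=float))


def read_ca_pdb_models(path, chain_id: str | None = None) -> list[CaTrace]:
    """Read every MODEL block of a Cα PDB file as a list of traces.

    Only the first chain encountered is used unless ``chain_id`` is given.
    Alternate locations other than blank/'A' are ignored.
    """
    models: list[CaTrace] = []
    residues: dict = {}
    chain_seen: str | None = chain_id
    n_atom_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                residues, chain_seen = {}, chain_id
            elif rec in ("ENDMDL", "END   ") or line.strip() in ("ENDMDL", "END"):
                if residues:
                    models.append(_residues_to_trace(residues))
                    residues = {}
            elif rec in ("ATOM  ", "HETATM"):
                n_atom_lines += 1
                name, altloc, resname, chain, resseq, xyz = _parse_atom_line(line, lineno)
                if chain_seen is None:
                    chain_seen = chain
                if chain != chain_seen or altloc not in (" ", "A"):
                    continue
                key = (chain, resseq, resname)
                if name == "CA":
                    residues[key] = xyz
                else:
                    residues.setdefault(key, None)
    if residues:
        models.append(_residues_to_trace(residues))
    if not models:
        if n_atom_lines == 0:
            raise PdbFormatError(f"{path}: no ATOM records found")
        raise PdbFormatError(f"{path}: no residues found for chain {chain_seen!r}")
    return models


def read_ca_pdb(path, chain_id: str | None = None) -> CaTrace:
    """Read the first model/chain of a PDB file as a :class:`CaTrace`."""
    return read_ca_pdb_models(path, chain_id=chain_id)[0]


def _format_atom(serial: int, resname: str, resseq: int, xyz) -> str:
    for v in xyz:
        if not (-999.999 <= v <= 9999.999):
            raise PdbFormatError(
                f"coordinate {v:.3f} exceeds the 8.3 PDB field width"
            )
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  CA  {resname:<3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
    )


def write_ca_pdb(traces, path) -> None:
    """Write one trace (single block) or several (MODEL/ENDMDL blocks).

    Coordinates outside the fixed 8.3 field raise instead of truncating.
    """
    if isinstance(traces, CaTrace):
        traces = [traces]
        multi = False
    else:
        traces = list(traces)
        multi = True
    with open(path, "w") as fh:
        for imodel, trace in enumerate(traces, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for i, (aa, xyz) in enumerate(zip(trace.sequence, trace.coords), start=1):
                fh.write(_format_atom(i, _1TO3.get(aa, "UNK"), i, xyz))
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# FASTA and feature-table I/O
# ---------------------------------------------------------------------------

def read_fasta_sequence(path) -> str:
    """First sequence of a FASTA file, upper-cased."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        return str(record.seq).upper()
    raise ValueError(f"{path}: no FASTA records")


def write_fasta_sequence(sequence: str, path, name: str = "target") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


def read_feature_table(path) -> tuple[str, str, tuple]:
    """Read a per-residue feature TSV: position (1-based), aa, ss3, acc.

    Returns (sequence, ss3 string, acc tuple).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "position":  # header
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            pos, aa, ss, acc = parts
            if ss not in SS3_CLASSES:
                raise ValueError(f"{path}:{lineno}: invalid ss3 class {ss!r}")
            if acc not in ACC_FROM_LETTER and acc not in ACC_CLASSES:
                raise ValueError(f"{path}:{lineno}: invalid acc class {acc!r}")
            rows.append((int(pos), aa, ss, ACC_FROM_LETTER.get(acc, acc)))
    rows.sort(key=lambda r: r[0])
    if [r[0] for r in rows] != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: positions must be exactly 1..L")
    seq = "".join(r[1] for r in rows)
    ss3 = "".join(r[2] for r in rows)
    acc = tuple(r[3] for r in rows)
    return seq, ss3, acc


def write_feature_table(trace: CaTrace, path) -> None:
    if not trace.has_features:
        raise ValueError("trace has no ss3/acc features to write")
    with open(path, "w") as fh:
        fh.write("position\taa\tss3\tacc\n")
        for i, (aa, ss, acc) in enumerate(zip(trace.sequence, trace.ss3, trace.acc), 1):
            fh.write(f"{i}\t{aa}\t{ss}\t{ACC_LETTERS[acc]}\n")


def attach_features(trace: CaTrace, path) -> CaTrace:
    """Return a copy of ``trace`` with ss3/acc read from a feature TSV."""
    seq, ss3, acc = read_feature_table(path)
    if seq != trace.sequence:
        raise ValueError("feature table sequence does not match trace sequence")
    return replace(trace, ss3=ss3, acc=acc)


# ---------------------------------------------------------------------------
# Internal-coordinate conversion (virtual bonds between consecutive Cαs)
# ---------------------------------------------------------------------------

def bond_vectors(coords: np.ndarray) -> np.ndarray:
    return np.diff(np.asarray(coords, dtype=float), axis=0)


def to_internal(trace_or_coords) -> InternalCoords:
    """Convert Cartesian coordinates to virtual-bond internal coordinates.

    The planar angle at residue k+1 is the angle between (C[k] − C[k+1]) and
    (C[k+2] − C[k+1]); a straight chain therefore has all angles equal to π.
    Torsions at collinear triples are undefined and set to 0 with a warning.
    """
    coords = trace_or_coords.coords if isinstance(trace_or_coords, CaTrace) else trace_or_coords
    coords = np.asarray(coords, dtype=float)
    L = len(coords)
    if L < 2:
        raise ValueError("need at least 2 residues for internal coordinates")
    b = bond_vectors(coords)
    lengths = np.linalg.norm(b, axis=1)
    if np.any(lengths <= 0):
        raise ValueError("coincident consecutive residues")
    u = b / lengths[:, None]

    if L >= 3:
        cosang = np.clip(np.einsum("ij,ij->i", -u[:-1], u[1:]), -1.0, 1.0)
        angles = np.arccos(cosang)
    else:
        angles = np.empty(0)

    if L >= 4:
        b0, b1, b2 = b[:-2], b[1:-1], b[2:]
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1)[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        torsions = np.arctan2(y, x)
        collinear = (np.linalg.norm(n1, axis=1) < 1e-10) | (
            np.linalg.norm(n2, axis=1) < 1e-10
        )
        if np.any(collinear):
            warnings.warn("collinear triple: torsion set to 0", RuntimeWarning)
            torsions = np.where(collinear, 0.0, torsions)
        torsions = np.where(torsions <= -np.pi, np.pi, torsions)
    else:
        torsions = np.empty(0)
    return InternalCoords(lengths, angles, torsions)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9 * np.linalg.norm(v):
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def from_internal(ic: InternalCoords, anchor: np.ndarray, check_anchor: bool = True) -> np.ndarray:
    """Rebuild Cartesian coordinates from internal coordinates.

    ``anchor`` supplies the first min(L, 3) coordinates and fixes the global
    rigid-body frame.  For L ≥ 3 the anchor must be consistent with the first
    bond length and angle (tolerance 10⁻⁴ relative) unless ``check_anchor``
    is disabled.
    """
    anchor = np.asarray(anchor, dtype=float)
    L = ic.n_residues
    n_anchor = min(L, 3)
    if anchor.shape != (n_anchor, 3):
        raise ValueError(f"anchor must have shape ({n_anchor}, 3)")
    if check_anchor:
        a_ic = to_internal(anchor) if n_anchor >= 2 else None
        if a_ic is not None:
            if abs(a_ic.bond_lengths[0] - ic.bond_lengths[0]) > 1e-4 * ic.bond_lengths[0]:
                raise ValueError("anchor inconsistent with first bond length")
            if n_anchor == 3 and abs(a_ic.bond_angles[0] - ic.bond_angles[0]) > 1e-4:
                raise ValueError("anchor inconsistent with first bond angle")
    coords = np.empty((L, 3))
    coords[:n_anchor] = anchor
    for k in range(n_anchor, L):
        coords[k] = _place_next(
            coords[k - 3],
            coords[k - 2],
            coords[k - 1],
            ic.bond_lengths[k - 1],
            ic.bond_angles[k - 2],
            ic.torsions[k - 3],
        )
    return coords


def _place_next(a, b, c, r, theta, phi):
    """NeRF placement of atom d after a, b, c given bond r=|cd|, planar angle
    theta at c and torsion phi of (a, b, c, d).

    Manual 3-vector arithmetic: this sits in the innermost rebuild loop and
    generic ufunc dispatch dominates the run time otherwise.
    """
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    ln = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / ln, bcy / ln, bcz / ln
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        nx, ny, nz = _any_perpendicular(np.array([bcx, bcy, bcz]))
    else:
        nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    st = math.sin(theta)
    d0 = -r * math.cos(theta)
    d1 = r * st * math.cos(phi)
    d2 = -r * st * math.sin(phi)
    return np.array([
        c[0] + d0 * bcx + d1 * mx + d2 * nx,
        c[1] + d0 * bcy + d1 * my + d2 * ny,
        c[2] + d0 * bcz + d1 * mz + d2 * nz,
    ])


def anchor_from_frame(ic: InternalCoords, old_coords: np.ndarray) -> np.ndarray:
    """Anchor for :func:`from_internal` that keeps the frame of ``old_coords``.

    The first atom, the first bond direction and the first bond plane are
    taken from the old coordinates while bond length/angle come from ``ic``;
    when ``ic`` matches the old geometry the anchor reproduces the old first
    three coordinates exactly.
    """
    old_coords = np.asarray(old_coords, dtype=float)
    L = ic.n_residues
    p0 = old_coords[0].copy()
    if L == 1:
        return p0[None, :]
    u = old_coords[1] - old_coords[0]
    nu = np.linalg.norm(u)
    u = u / nu if nu > 1e-12 else np.array([1.0, 0.0, 0.0])
    p1 = p0 + ic.bond_lengths[0] * u
    if L == 2:
        return np.stack([p0, p1])
    # in-plane unit vector orthogonal to u, from the old second bond
    if len(old_coords) >= 3:
        w = old_coords[2] - old_coords[1]
        w_perp = w - np.dot(w, u) * u
        n_wp = np.linalg.norm(w_perp)
        v = w_perp / n_wp if n_wp > 1e-10 else _any_perpendicular(u)
    else:
        v = _any_perpendicular(u)
    theta = ic.bond_angles[0]
    d2 = np.cos(np.pi - theta) * u + np.sin(np.pi - theta) * v
    p2 = p1 + ic.bond_lengths[1] * d2
    return np.stack([p0, p1, p2])


def random_extended_trace(sequence: str, rng) -> CaTrace:
    """Random unfolded chain: first atom at the origin, each successive atom
    in a uniformly random direction at a distance drawn from U[3.73, 3.87] Å.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(rng)
    L = len(sequence)
    coords = np.zeros((L, 3))
    for k in range(1, L):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        coords[k] = coords[k - 1] + rng.uniform(3.73, 3.87) * v
    return CaTrace(sequence, coords)
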