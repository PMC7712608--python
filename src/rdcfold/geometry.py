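"""Backbone construction in torsion space, torsion extraction, internuclear
vectors and backbone RMSD.

A protein backbone is modeled as a chain of rigid trans peptide planes with
idealized covalent geometry (bond lengths/angles from
:mod:`rdcfold.constants`); the only degrees of freedom are the (phi, psi)
torsions.  Six atoms are kept per residue — N, H, CA, HA, C', O — which is
everything the supported dipolar vector types need.  Glycine gets a single
HA; proline carries no amide H.

Torsion conventions
-------------------
* phi(i) = dihedral(C'(i-1), N(i), CA(i), C'(i)); psi(i) = dihedral(N(i),
  CA(i), C'(i), N(i+1)); both in (-180, 180] degrees.
* phi(1) has no geometric role (there is no C'(0)); psi(L) only orients the
  terminal O.  ``None``/NaN entries are replaced by the fixed cap values
  :data:`CAP_PHI`/:data:`CAP_PSI` so that independently built chains agree.
* The peptide omega torsion is fixed at 180 degrees (all-trans).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import math

import numpy as np

from .constants import (
    AMINO_ACIDS_1TO3,
    AMINO_ACIDS_3TO1,
    BACKBONE_ATOMS,
    BOND_ANGLES,
    BOND_LENGTHS,
    HA_BISECTOR_COEF,
    HA_NORMAL_COEF,
    OMEGA_TRANS,
)
from .errors import DataError, FormatError, ValidationError

#: cap values substituted for the undefined terminal torsions.
CAP_PHI = -120.0
CAP_PSI = 140.0

ATOM_INDEX = {name: i for i, name in enumerate(BACKBONE_ATOMS)}

_COLLINEAR_EPS = 1e-8


class TorsionPair(NamedTuple):
    """One residue's (phi, psi) in degrees, each in (-180, 180] or NaN."""

    phi: float
    psi: float


class Structure:
    """Ordered backbone coordinates plus one-letter sequence.

    ``coords`` has shape (n_residues, 6, 3) in angstroms, atom order
    N, H, CA, HA, C', O; missing atoms (proline H, not-yet-built atoms)
    are NaN.  Residue numbering is 1-based at every public interface.
    """

    __slots__ = ("sequence", "coords")

    def __init__(self, sequence: str, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(sequence), 6, 3):
            raise ValidationError(
                f"coords shape {coords.shape} inconsistent with sequence "
                f"length {len(sequence)}")
        self.sequence = sequence
        self.coords = coords

    def __len__(self) -> int:
        return len(self.sequence)

    def atom(self, residue: int, name: str) -> np.ndarray:
        """Coordinates of atom ``name`` in 1-based ``residue``."""
        if name not in ATOM_INDEX:
            raise ValidationError(
                f"unknown backbone atom {name!r}; supported: "
                f"{', '.join(BACKBONE_ATOMS)}")
        if not 1 <= residue <= len(self):
            raise DataError(f"residue {residue} outside chain 1..{len(self)}")
        return self.coords[residue - 1, ATOM_INDEX[name]]

    def has_atom(self, residue: int, name: str) -> bool:
        if name not in ATOM_INDEX or not 1 <= residue <= len(self):
            return False
        return bool(np.all(np.isfinite(self.coords[residue - 1, ATOM_INDEX[name]])))

    def copy(self) -> "Structure":
        return Structure(self.sequence, self.coords.copy())


# ---------------------------------------------------------------------------
# elementary geometry, all broadcastable over leading axes

def place_atom(a, b, c, bond: float, angle_deg, torsion_deg) -> np.ndarray:
    """Position a new atom bonded to ``c`` given reference atoms ``a, b, c``
    (NeRF construction): |new-c| = bond, angle(b, c, new) = angle_deg and
    dihedral(a, b, c, new) = torsion_deg.  Broadcasts over leading axes.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)

    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(np.asarray(chi, dtype=float)),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return (c + d_local[..., 0:1] * bc + d_local[..., 1:2] * m
            + d_local[..., 2:3] * n)


def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Raises :class:`DataError` when the first or last three points are
    collinear (the angle is undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = (p0 - p1) - np.sum((p0 - p1) * b1, axis=-1, keepdims=True) * b1
    w = (p3 - p2) - np.sum((p3 - p2) * b1, axis=-1, keepdims=True) * b1
    nv = np.linalg.norm(v, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    if np.any(nv < _COLLINEAR_EPS) or np.any(nw < _COLLINEAR_EPS):
        raise DataError("dihedral undefined: collinear reference atoms")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang if ang.ndim else float(ang)


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return float(np.degrees(np.arccos(np.clip(np.sum(u * v, axis=-1), -1, 1))))


def ha_position(n, ca, c, bond: float | None = None) -> np.ndarray:
    """HA position from the N, CA, C' coordinates of a residue.

    The HA direction is the fixed L-chirality combination of the in-plane
    bisector and the plane normal of the two heavy-atom bonds at CA
    (coefficients from ideal L-alanine).  Broadcastable.
    """
    if bond is None:
        bond = BOND_LENGTHS[("CA", "HA")]
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    u1 = n - ca
    u1 = u1 / np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = c - ca
    u2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    bis = -(u1 + u2)
    bis = bis / np.linalg.norm(bis, axis=-1, keepdims=True)
    nrm = np.cross(u1, u2)
    nrm = nrm / np.linalg.norm(nrm, axis=-1, keepdims=True)
    u = HA_BISECTOR_COEF * bis + HA_NORMAL_COEF * nrm
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    return ca + bond * u


# ---------------------------------------------------------------------------
# torsion handling helpers

def _norm_pair(tp) -> TorsionPair:
    if tp is None:
        return TorsionPair(math.nan, math.nan)
    phi, psi = tp
    out = []
    for v in (phi, psi):
        if v is None:
            v = math.nan
        v = float(v)
        if not math.isnan(v) and not (-180.0 < v <= 180.0):
            raise ValidationError(
                f"torsion {v} out of range (-180, 180]")
        out.append(v)
    return TorsionPair(*out)


def _cap(value: float, cap: float) -> float:
    return cap if math.isnan(value) else value


def _validate_sequence(sequence: str) -> None:
    bad = sorted(set(sequence) - set(AMINO_ACIDS_1TO3))
    if bad:
        raise FormatError(
            f"unknown residue letter(s) {''.join(bad)!r} in sequence")


# ---------------------------------------------------------------------------
# chain construction

def _seed_first_residue(coords: np.ndarray, sequence: str) -> None:
    """Place N, CA, C', H, HA of residue 1 in a canonical frame."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_LENGTHS[("N", "CA")], 0.0, 0.0])
    theta = math.radians(BOND_ANGLES[("N", "CA", "C")])
    c = ca + BOND_LENGTHS[("CA", "C")] * np.array(
        [-math.cos(theta), math.sin(theta), 0.0])
    coords[0, ATOM_INDEX["N"]] = n
    coords[0, ATOM_INDEX["CA"]] = ca
    coords[0, ATOM_INDEX["C"]] = c
    if sequence[0] != "P":
        coords[0, ATOM_INDEX["H"]] = place_atom(
            c, ca, n, BOND_LENGTHS[("N", "H")],
            BOND_ANGLES[("CA", "N", "H")], 180.0)
    coords[0, ATOM_INDEX["HA"]] = ha_position(n, ca, c)


def _append_residue(coords: np.ndarray, i: int, sequence: str,
                    psi_prev: float, phi_i: float) -> None:
    """Build residue ``i`` (0-based) given residue i-1 is complete except O,
    place O(i-1), and leave O(i) for the caller (it needs psi_i)."""
    n_p = coords[i - 1, ATOM_INDEX["N"]]
    ca_p = coords[i - 1, ATOM_INDEX["CA"]]
    c_p = coords[i - 1, ATOM_INDEX["C"]]

    o_p = place_atom(n_p, ca_p, c_p, BOND_LENGTHS[("C", "O")],
                     BOND_ANGLES[("CA", "C", "O")], psi_prev + 180.0)
    coords[i - 1, ATOM_INDEX["O"]] = o_p

    n_i = place_atom(n_p, ca_p, c_p, BOND_LENGTHS[("C", "N")],
                     BOND_ANGLES[("CA", "C", "N")], psi_prev)
    ca_i = place_atom(ca_p, c_p, n_i, BOND_LENGTHS[("N", "CA")],
                      BOND_ANGLES[("C", "N", "CA")], OMEGA_TRANS)
    coords[i, ATOM_INDEX["N"]] = n_i
    coords[i, ATOM_INDEX["CA"]] = ca_i
    if sequence[i] != "P":
        coords[i, ATOM_INDEX["H"]] = place_atom(
            o_p, c_p, n_i, BOND_LENGTHS[("N", "H")],
            BOND_ANGLES[("C", "N", "H")], 180.0)
    c_i = place_atom(c_p, n_i, ca_i, BOND_LENGTHS[("CA", "C")],
                     BOND_ANGLES[("N", "CA", "C")], phi_i)
    coords[i, ATOM_INDEX["C"]] = c_i
    coords[i, ATOM_INDEX["HA"]] = ha_position(n_i, ca_i, c_i)


def build_chain(sequence: str,
                torsions: Sequence[tuple[float, float] | None]) -> Structure:
    """Build a backbone from per-residue (phi, psi) torsions.

    ``torsions`` must have one entry per residue; phi of the first and psi
    of the last residue (and any ``None``/NaN entry) are replaced by the cap
    values.  Deterministic: identical inputs give identical coordinates.
    """
    _validate_sequence(sequence)
    if len(torsions) != len(sequence):
        raise ValidationError(
            f"{len(torsions)} torsion pairs for {len(sequence)} residues")
    if not sequence:
        raise ValidationError("empty sequence")
    pairs = [_norm_pair(tp) for tp in torsions]

    L = len(sequence)
    coords = np.full((L, 6, 3), np.nan)
    _seed_first_residue(coords, sequence)
    for i in range(1, L):
        psi_prev = _cap(pairs[i - 1].psi, CAP_PSI)
        phi_i = _cap(pairs[i].phi, CAP_PHI)
        _append_residue(coords, i, sequence, psi_prev, phi_i)
    # terminal O
    psi_last = _cap(pairs[-1].psi, CAP_PSI)
    coords[L - 1, ATOM_INDEX["O"]] = place_atom(
        coords[L - 1, ATOM_INDEX["N"]], coords[L - 1, ATOM_INDEX["CA"]],
        coords[L - 1, ATOM_INDEX["C"]], BOND_LENGTHS[("C", "O")],
        BOND_ANGLES[("CA", "C", "O")], psi_last + 180.0)
    return Structure(sequence, coords)


def extend_fragment(fragment: Structure, next_residue: str,
                    tp: tuple[float, float] | None) -> Structure:
    """Append one residue (one peptide plane) to ``fragment``.

    The psi of the current last residue is recovered from its carbonyl O,
    so prefix coordinates are untouched (elongation is append-only).
    """
    if len(fragment) == 0:
        raise ValidationError("cannot extend an empty fragment")
    _validate_sequence(next_residue)
    if len(next_residue) != 1:
        raise ValidationError("next_residue must be a single letter")
    pair = _norm_pair(tp)

    L = len(fragment)
    last = L - 1
    o = fragment.coords[last, ATOM_INDEX["O"]]
    if not np.all(np.isfinite(o)):
        raise DataError("fragment's terminal O is missing; cannot recover psi")
    psi_prev = dihedral(
        fragment.coords[last, ATOM_INDEX["N"]],
        fragment.coords[last, ATOM_INDEX["CA"]],
        fragment.coords[last, ATOM_INDEX["C"]], o) - 180.0
    if psi_prev <= -180.0:
        psi_prev += 360.0

    coords = np.full((L + 1, 6, 3), np.nan)
    coords[:L] = fragment.coords
    seq = fragment.sequence + next_residue
    _append_residue(coords, L, seq, psi_prev, _cap(pair.phi, CAP_PHI))
    coords[L, ATOM_INDEX["O"]] = place_atom(
        coords[L, ATOM_INDEX["N"]], coords[L, ATOM_INDEX["CA"]],
        coords[L, ATOM_INDEX["C"]], BOND_LENGTHS[("C", "O")],
        BOND_ANGLES[("CA", "C", "O")], _cap(pair.psi, CAP_PSI) + 180.0)
    return Structure(seq, coords)


def extract_torsions(s: Structure) -> list[TorsionPair]:
    """Per-residue (phi, psi); phi(1) and psi(L) are NaN."""
    L = len(s)
    if L < 2:
        raise DataError("need at least two residues to extract torsions")
    iN, iCA, iC = ATOM_INDEX["N"], ATOM_INDEX["CA"], ATOM_INDEX["C"]
    for i in range(L):
        for idx, nm in ((iN, "N"), (iCA, "CA"), (iC, "C")):
            if not np.all(np.isfinite(s.coords[i, idx])):
                raise DataError(f"missing backbone atom {nm} in residue {i + 1}")
    out = []
    for i in range(L):
        phi = math.nan
        psi = math.nan
        if i > 0:
            phi = float(dihedral(s.coords[i - 1, iC], s.coords[i, iN],
                                 s.coords[i, iCA], s.coords[i, iC]))
        if i < L - 1:
            psi = float(dihedral(s.coords[i, iN], s.coords[i, iCA],
                                 s.coords[i, iC], s.coords[i + 1, iN]))
        out.append(TorsionPair(phi, psi))
    return out


def internuclear_vector(s: Structure, residue_i: int, atom_i: str,
                        residue_j: int, atom_j: str) -> np.ndarray:
    """Unit vector from atom_i to atom_j (direction is irrelevant for RDCs:
    the coupling is invariant under v -> -v)."""
    a = s.atom(residue_i, atom_i)
    b = s.atom(residue_j, atom_j)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError(
            f"atom missing: {residue_i}.{atom_i} or {residue_j}.{atom_j}")
    v = b - a
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DataError("coincident atoms: internuclear vector undefined")
    return v / n


# ---------------------------------------------------------------------------
# superposition

def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing |p @ R.T - q| for centered
    point sets (reflections forbidden)."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def bb_rmsd(a: Structure, b: Structure) -> float:
    """Backbone RMSD (N, CA, C') in angstrom after optimal rigid
    superposition (Kabsch, rotation + translation, no reflection)."""
    if len(a) != len(b):
        raise ValidationError(
            f"residue counts differ: {len(a)} vs {len(b)}")
    idx = [ATOM_INDEX[nm] for nm in ("N", "CA", "C")]
    p = a.coords[:, idx, :].reshape(-1, 3)
    q = b.coords[:, idx, :].reshape(-1, 3)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise DataError("missing backbone atoms in RMSD computation")
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    r = kabsch_rotation(p, q)
    diff = p @ r.T - q
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


# ---------------------------------------------------------------------------
# PDB I/O (single chain, single model)

def write_pdb(s: Structure, path) -> None:
    """Write the backbone as ATOM records with element columns (gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "rdcfold"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, letter in enumerate(s.sequence):
        res = gemmi.Residue()
        res.name = AMINO_ACIDS_1TO3[letter]
        res.seqid = gemmi.SeqId(i + 1, " ")
        for name in BACKBONE_ATOMS:
            xyz = s.coords[i, ATOM_INDEX[name]]
            if not np.all(np.isfinite(xyz)):
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path, chain: str | None = None,
             rebuild_protons: bool = True) -> Structure:
    """Read backbone atoms of one chain from a PDB file.

    Missing amide H / HA are rebuilt from the idealized geometry when
    ``rebuild_protons`` (positions are approximate for non-ideal covalent
    geometry but adequate for dipolar vectors).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    chains = [ch for ch in model if chain is None or ch.name == chain]
    if not chains:
        raise FormatError(f"{path}: chain {chain!r} not found")
    ch = chains[0]

    residues = [r for r in ch if r.name in AMINO_ACIDS_3TO1]
    if not residues:
        raise FormatError(f"{path}: chain {ch.name} has no amino acids")
    seq = "".join(AMINO_ACIDS_3TO1[r.name] for r in residues)
    coords = np.full((len(residues), 6, 3), np.nan)
    alias = {"HN": "H", "1HA": "HA", "HA2": "HA", "HA3": None, "OXT": None}
    for i, res in enumerate(residues):
        for at in res:
            name = alias.get(at.name, at.name)
            if name in ATOM_INDEX:
                coords[i, ATOM_INDEX[name]] = [at.pos.x, at.pos.y, at.pos.z]

    s = Structure(seq, coords)
    if rebuild_protons:
        _rebuild_protons(s)
    return s


def _rebuild_protons(s: Structure) -> None:
    iN, iH, iCA, iHA = (ATOM_INDEX[x] for x in ("N", "H", "CA", "HA"))
    iC, iO = ATOM_INDEX["C"], ATOM_INDEX["O"]
    for i in range(len(s)):
        n, ca, c = s.coords[i, iN], s.coords[i, iCA], s.coords[i, iC]
        if (not np.all(np.isfinite(s.coords[i, iHA]))
                and np.all(np.isfinite([n, ca, c]))):
            s.coords[i, iHA] = ha_position(n, ca, c)
        if (s.sequence[i] != "P"
                and not np.all(np.isfinite(s.coords[i, iH]))
                and np.all(np.isfinite(n))):
            if i > 0 and np.all(np.isfinite(s.coords[i - 1, iC])) \
                    and np.all(np.isfinite(s.coords[i - 1, iO])):
                s.coords[i, iH] = place_atom(
                    s.coords[i - 1, iO], s.coords[i - 1, iC], n,
                    BOND_LENGTHS[("N", "H")], BOND_ANGLES[("C", "N", "H")],
                    180.0)
            elif np.all(np.isfinite([ca, c])):
                s.coords[i, iH] = place_atom(
                    c, ca, n, BOND_LENGTHS[("N", "H")],
                    BOND_ANGLES[("CA", "N", "H")], 180.0)
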