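"""Physical constants, idealized backbone geometry, and the dipolar
vector-type registry.

All distances are in angstroms, angles in degrees, gyromagnetic ratios in
rad s^-1 T^-1 and couplings in Hz.

The maximal dipolar coupling for a nucleus pair is

    Dmax = -mu0 * gamma_i * gamma_j * h / (2 pi r)^3

with h the Planck constant and r the (fixed) internuclear distance.  With
the values below this gives the field-standard Dmax(N-H) of about -21.6 kHz
magnitude scale (sign from the negative 15N gyromagnetic ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

# ---------------------------------------------------------------------------
# physical constants

MU0 = 4.0e-7 * math.pi          # T^2 m^3 / J  (vacuum permeability)
PLANCK_H = 6.62607015e-34       # J s

#: gyromagnetic ratios by element symbol of backbone nuclei, rad s^-1 T^-1.
#: 17O is included so that the benchmark C'-O vector type is well defined
#: for simulated data (16O is spin-0; see docs/methods.md).
GAMMA = {
    "H": 267.52218744e6,
    "C": 67.2828e6,
    "N": -27.116e6,
    "O": -36.2808e6,
}

# ---------------------------------------------------------------------------
# idealized backbone covalent geometry (Engh & Huber style)

BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond, C'(i)-N(i+1)
    ("N", "H"): 1.02,
    ("CA", "HA"): 1.09,
    ("C", "O"): 1.231,
}

BOND_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,   # CA(i)-C'(i)-N(i+1)
    ("C", "N", "CA"): 121.7,   # C'(i)-N(i+1)-CA(i+1)
    ("CA", "C", "O"): 120.8,
    ("C", "N", "H"): 119.15,   # C'(i)-N(i+1)-H(i+1)
    ("CA", "N", "H"): 118.2,   # used only for the chain's first amide H
}

OMEGA_TRANS = 180.0  # peptide bond torsion, all-trans; cis-Pro not modeled

#: HA unit direction at CA decomposed on the local tetrahedral frame
#: built from the CA->N and CA->C' unit vectors:
#:   u_ha = HA_BISECTOR_COEF * bis + HA_NORMAL_COEF * n
#: with bis = -(u_N + u_C)/|u_N + u_C| and n = (u_N x u_C)/|u_N x u_C|.
#: Coefficients taken from ideal L-alanine; the negative normal component
#: selects the L-chirality side (CB, not built, sits on the + side).
HA_BISECTOR_COEF = 0.57827
HA_NORMAL_COEF = -0.81584

#: effective C'(i-1)...H(i) distance across the rigid peptide plane,
#: from the law of cosines on r(C'N), r(NH) and the C'-N-H angle.
_R_CN = BOND_LENGTHS[("C", "N")]
_R_NH = BOND_LENGTHS[("N", "H")]
R_C_H = math.sqrt(
    _R_CN**2 + _R_NH**2
    - 2.0 * _R_CN * _R_NH * math.cos(math.radians(BOND_ANGLES[("C", "N", "H")]))
)

AMINO_ACIDS_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AMINO_ACIDS_3TO1 = {v: k for k, v in AMINO_ACIDS_1TO3.items()}

BACKBONE_ATOMS = ("N", "H", "CA", "HA", "C", "O")


# ---------------------------------------------------------------------------
# dipolar vector types

@dataclass(frozen=True)
class VectorTypeSpec:
    """One supported internuclear RDC vector type.

    ``seq_delta`` is residue_2 - residue_1 (0 for intra-residue pairs, 1 for
    pairs that bridge the peptide bond).  ``dmax`` follows the cubic dipolar
    law and carries the sign of the gyromagnetic-ratio product.
    """

    atom_1: str
    atom_2: str
    seq_delta: int
    gamma_1: float
    gamma_2: float
    r: float  # angstrom

    @property
    def dmax(self) -> float:
        return dmax(self.gamma_1, self.gamma_2, self.r)

    @property
    def name(self) -> str:
        return f"{self.atom_1}-{self.atom_2}"


def dmax(gamma_1: float, gamma_2: float, r: float) -> float:
    """Maximal dipolar coupling in Hz for gyromagnetic ratios in
    rad s^-1 T^-1 and internuclear distance ``r`` in angstrom."""
    if r <= 0:
        raise ValidationError(f"internuclear distance must be positive, got {r}")
    r_m = r * 1e-10
    return -MU0 * gamma_1 * gamma_2 * PLANCK_H / (2.0 * math.pi * r_m) ** 3


def _spec(a1: str, a2: str, delta: int, r: float) -> VectorTypeSpec:
    return VectorTypeSpec(a1, a2, delta, GAMMA[a1[0]], GAMMA[a2[0]], r)


#: every backbone atom-pair combination the engine accepts, keyed by
#: (atom_1, atom_2, seq_delta).  Lookup is order-insensitive.
VECTOR_TYPES: dict[tuple[str, str, int], VectorTypeSpec] = {}


def _register(spec: VectorTypeSpec) -> None:
    VECTOR_TYPES[(spec.atom_1, spec.atom_2, spec.seq_delta)] = spec


for _s in [
    _spec("N", "H", 0, BOND_LENGTHS[("N", "H")]),
    _spec("CA", "HA", 0, BOND_LENGTHS[("CA", "HA")]),
    _spec("CA", "C", 0, BOND_LENGTHS[("CA", "C")]),
    _spec("N", "CA", 0, BOND_LENGTHS[("N", "CA")]),
    _spec("C", "O", 0, BOND_LENGTHS[("C", "O")]),
    _spec("C", "N", 1, BOND_LENGTHS[("C", "N")]),    # C'(i)-N(i+1)
    _spec("C", "H", 1, R_C_H),                        # C'(i)-H(i+1)
]:
    _register(_s)


def resolve_vector_type(residue_1: int, atom_1: str, residue_2: int,
                        atom_2: str) -> VectorTypeSpec | None:
    """Map an atom pair (with residue numbers) to its :class:`VectorTypeSpec`.

    Returns the spec oriented as registered (atom_1 of the spec belongs to
    the lower/equal residue); ``None`` if the combination is unsupported.
    """
    for (r1, a1), (r2, a2) in (((residue_1, atom_1), (residue_2, atom_2)),
                               ((residue_2, atom_2), (residue_1, atom_1))):
        spec = VECTOR_TYPES.get((a1, a2, r2 - r1))
        if spec is not None:
            return spec
    return None


#: the six per-residue columns of the legacy whitespace RDC table, as seen
#: from residue i.  This layout is a pinned convention (the historical file
#: is only described, never printed); remap columns here if your legacy
#: files differ.  Column 6 (C'-O) is a benchmark-only type: 16O is not
#: magnetically active, the registry uses gamma(17O).
LEGACY_COLUMNS: tuple[tuple[int, str, int, str], ...] = (
    (-1, "C", 0, "N"),    # C'(i-1)-N(i)
    (-1, "C", 0, "H"),    # C'(i-1)-H(i)
    (0, "N", 0, "H"),
    (0, "CA", 0, "C"),
    (0, "CA", 0, "HA"),
    (0, "C", 0, "O"),
)

LEGACY_SENTINEL = 999.0
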