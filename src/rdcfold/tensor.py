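"""Dipolar-coupling math: back-calculation through a Saupe order tensor,
least-squares tensor estimation, and the pooled RMS fitness score.

A residual dipolar coupling between nuclei i and j is modeled as

    D_ij = Dmax * v_ij . S . v_ij^T        (static-structure form)

with ``v_ij`` the unit internuclear vector and ``S`` the 3x3 symmetric
traceless Saupe order matrix of the alignment medium.  Because the engine
mixes vector types (any backbone atom pair), the per-type maximal coupling
Dmax is kept explicit in the design matrix rather than absorbed into S, so
all couplings in one medium share a single dimensionless order tensor.

The fitness of a structure against data from M media is the RMS deviation
(in Hz) between measured couplings and couplings back-calculated through
the per-medium best-fit tensors, pooled over all media and couplings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import VectorTypeSpec, resolve_vector_type
from .errors import DataError, ValidationError
from .geometry import Structure, internuclear_vector

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for the minimum-norm least-squares fit
SV_CUTOFF = 1e-10


@dataclass(frozen=True)
class SaupeTensor:
    """Symmetric traceless order matrix, stored as its five independent
    components (Szz = -Sxx - Syy by construction)."""

    sxx: float
    syy: float
    sxy: float
    sxz: float
    syz: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array([
            [self.sxx, self.sxy, self.sxz],
            [self.sxy, self.syy, self.syz],
            [self.sxz, self.syz, -self.sxx - self.syy],
        ])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SaupeTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError("Saupe matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("Saupe matrix must be symmetric")
        if abs(np.trace(m)) > 1e-9 * max(1.0, float(np.abs(m).max())):
            raise ValidationError("Saupe matrix must be traceless")
        return cls(m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2])

    @classmethod
    def from_components(cls, c: np.ndarray) -> "SaupeTensor":
        return cls(*(float(x) for x in c))

    @property
    def components(self) -> np.ndarray:
        return np.array([self.sxx, self.syy, self.sxy, self.sxz, self.syz])


@dataclass(frozen=True)
class RdcRecord:
    """One dipolar coupling between two named backbone atoms (Hz)."""

    residue_1: int
    atom_1: str
    residue_2: int
    atom_2: str
    medium: int
    value: float
    uncertainty: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValidationError("RDC value must be finite")
        if self.uncertainty < 0:
            raise ValidationError("RDC uncertainty must be >= 0")
        if self.spec is None:
            raise ValidationError(
                f"unsupported atom pair {self.atom_1}({self.residue_1})-"
                f"{self.atom_2}({self.residue_2})")

    @property
    def spec(self) -> VectorTypeSpec | None:
        return resolve_vector_type(self.residue_1, self.atom_1,
                                   self.residue_2, self.atom_2)


@dataclass(frozen=True)
class FitnessScore:
    """Pooled RMS deviation in Hz plus the pooling counts."""

    value: float
    n_rdcs_used: int
    n_media: int
    n_skipped: int = 0

    def __float__(self) -> float:
        return self.value


# ---------------------------------------------------------------------------

def quad_row(v: np.ndarray) -> np.ndarray:
    """Design-matrix row of the traceless quadratic form for unit vector(s):
    D/Dmax = Sxx (x^2 - z^2) + Syy (y^2 - z^2) + 2 Sxy xy + 2 Sxz xz
             + 2 Syz yz.  Broadcasts over leading axes."""
    v = np.asarray(v, dtype=float)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    return np.stack([x * x - z * z, y * y - z * z,
                     2 * x * y, 2 * x * z, 2 * y * z], axis=-1)


def back_calc(v: np.ndarray, s: SaupeTensor, spec: VectorTypeSpec) -> float:
    """Back-calculated coupling Dmax * v S v^T in Hz.  Invariant under
    v -> -v (even quadratic form)."""
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValidationError("internuclear vector must be unit length")
    return float(spec.dmax * (v @ s.matrix @ v))


def fit_tensor(vectors, rdcs, specs) -> SaupeTensor:
    """Least-squares Saupe tensor from unit vectors and couplings (Hz).

    With fewer than five independent rows the minimum-norm solution is
    returned (singular-value pseudo-inverse, relative cutoff 1e-10).
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    rdcs = np.atleast_1d(np.asarray(rdcs, dtype=float))
    if vectors.size == 0 or rdcs.size == 0:
        raise ValidationError("fit_tensor needs at least one coupling")
    if len(vectors) != len(rdcs) or len(specs) != len(rdcs):
        raise ValidationError("vectors, rdcs and specs must have equal length")
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValidationError("all vectors must be unit length")
    dmaxes = np.array([sp.dmax for sp in specs])
    a = dmaxes[:, None] * quad_row(vectors)
    sol, *_ = np.linalg.lstsq(a, rdcs, rcond=SV_CUTOFF)
    return SaupeTensor.from_components(sol)


def pooled_rmsd(deviations, n_media: int = 1, n_per_medium: int | None = None
                ) -> float:
    """RMS pooling of deviations: sqrt(sum d^2 / (M*N)).  With the default
    ``n_per_medium`` the denominator is simply the number of deviations."""
    d = np.asarray(deviations, dtype=float)
    n = n_per_medium if n_per_medium is not None else d.size // n_media
    return float(np.sqrt(np.sum(d * d) / (n_media * n)))


def _resolve_record(structure: Structure, rec: RdcRecord):
    """(unit vector, spec) for a record, or None when either atom is not
    present in the (possibly partial) structure."""
    for res, at in ((rec.residue_1, rec.atom_1), (rec.residue_2, rec.atom_2)):
        if not structure.has_atom(res, at):
            return None
    v = internuclear_vector(structure, rec.residue_1, rec.atom_1,
                            rec.residue_2, rec.atom_2)
    return v, rec.spec


def fitness(structure: Structure, data, weighted: bool = False
            ) -> FitnessScore:
    """RMS fitness (Hz) of a structure against RDCs from one or more media.

    For each medium the best-fit Saupe tensor is estimated from that
    medium's resolvable records, couplings are back-calculated, and squared
    deviations are pooled across media.  Records referencing atoms or
    residues absent from ``structure`` are skipped and counted (needed
    while a fragment is still growing).  ``weighted`` applies 1/sigma^2
    weights in the tensor fit and pooling (off by default; the standard
    score is unweighted).
    """
    by_medium: dict[int, list[RdcRecord]] = {}
    for rec in data:
        by_medium.setdefault(rec.medium, []).append(rec)
    if not by_medium:
        raise ValidationError("fitness needs at least one record")

    sq_sum = 0.0
    w_sum = 0.0
    n_used = 0
    n_skipped = 0
    n_media = 0
    for medium in sorted(by_medium):
        rows = []
        vals = []
        sigmas = []
        for rec in by_medium[medium]:
            resolved = _resolve_record(structure, rec)
            if resolved is None:
                n_skipped += 1
                continue
            v, spec = resolved
            rows.append(spec.dmax * quad_row(v))
            vals.append(rec.value)
            sigmas.append(rec.uncertainty)
        if not rows:
            continue
        a = np.asarray(rows)
        d = np.asarray(vals)
        if weighted:
            w = 1.0 / np.square(np.where(np.asarray(sigmas) > 0,
                                         sigmas, 1.0))
        else:
            w = np.ones(len(d))
        sw = np.sqrt(w)
        sol, *_ = np.linalg.lstsq(sw[:, None] * a, sw * d, rcond=SV_CUTOFF)
        dev = a @ sol - d
        sq_sum += float(np.sum(w * dev * dev))
        w_sum += float(np.sum(w))
        n_used += len(d)
        n_media += 1
    if n_skipped:
        logger.debug("fitness: skipped %d unresolvable records", n_skipped)
    if n_used == 0:
        return FitnessScore(0.0, 0, 0, n_skipped)
    denom = w_sum if weighted else float(n_used)
    return FitnessScore(float(np.sqrt(sq_sum / denom)), n_used, n_media,
                        n_skipped)
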