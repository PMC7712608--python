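"""Vectorized internals shared by the Stage-I ranker and the Stage-II
elongation engine.

The expensive inner loop of both stages is: for many (phi, psi) candidates
at one junction, place the next peptide plane, form the dipolar design rows
of the couplings that the new plane determines, and solve each candidate's
per-medium least-squares tensor problem.  Everything here broadcasts over
arbitrary leading axes (parents x candidates).

The per-candidate tensor solve uses accumulated normal equations
(M = A^T A, b = A^T D, dd = D^T D): the prefix contribution is shared and
only the new plane's few rows differ per candidate, so each solve is a 5x5
pseudo-inverse.  The minimum-norm solution of the normal system equals the
minimum-norm least-squares solution of the raw system (A+ = (A^T A)+ A^T).
"""

from __future__ import annotations

import numpy as np

from .constants import BOND_ANGLES, BOND_LENGTHS
from .geometry import CAP_PHI, CAP_PSI, ha_position, place_atom
from .tensor import quad_row

#: relative eigenvalue cutoff for the normal-matrix pseudo-inverse; the
#: normal matrix squares singular values, hence the squared raw cutoff.
NORMAL_CUTOFF = 1e-12

#: slot order of atoms a junction step determines.  Slots 0..5 belong to
#: every junction j (plane j -> j+1 plus HA/O of residue j); slots 6..8
#: exist only at the final junction, where the terminal residue's C'/HA/O
#: are fixed by the cap torsions.
SLOTS = ("C", "HA", "O", "N_next", "H_next", "CA_next")
SLOTS_TERMINAL = SLOTS + ("C_term", "HA_term", "O_term")


def extend_plane(c_prev, n_j, ca_j, phi, psi, with_h_next: bool = True,
                 terminal: bool = False) -> np.ndarray:
    """Coordinates of the atoms determined by choosing (phi, psi) at a
    junction, stacked along axis -2 in :data:`SLOTS` order.

    ``c_prev, n_j, ca_j`` are the anchor atoms C'(j-1), N(j), CA(j)
    (broadcastable (..., 3)); ``phi, psi`` broadcastable scalars/arrays.
    With ``terminal`` the cap-torsion atoms of the last residue are
    appended.  A proline at j+1 still gets an H slot (callers must not
    reference it in any coupling row).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)

    c_j = place_atom(c_prev, n_j, ca_j, BOND_LENGTHS[("CA", "C")],
                     BOND_ANGLES[("N", "CA", "C")], phi)
    ha_j = ha_position(n_j, ca_j, c_j)
    o_j = place_atom(n_j, ca_j, c_j, BOND_LENGTHS[("C", "O")],
                     BOND_ANGLES[("CA", "C", "O")], psi + 180.0)
    n_n = place_atom(n_j, ca_j, c_j, BOND_LENGTHS[("C", "N")],
                     BOND_ANGLES[("CA", "C", "N")], psi)
    ca_n = place_atom(ca_j, c_j, n_n, BOND_LENGTHS[("N", "CA")],
                      BOND_ANGLES[("C", "N", "CA")], 180.0)
    h_n = place_atom(o_j, c_j, n_n, BOND_LENGTHS[("N", "H")],
                     BOND_ANGLES[("C", "N", "H")], 180.0)
    if not with_h_next:
        h_n = np.full_like(h_n, np.nan)
    atoms = [c_j, ha_j, o_j, n_n, h_n, ca_n]
    if terminal:
        c_t = place_atom(c_j, n_n, ca_n, BOND_LENGTHS[("CA", "C")],
                         BOND_ANGLES[("N", "CA", "C")], CAP_PHI)
        ha_t = ha_position(n_n, ca_n, c_t)
        o_t = place_atom(n_n, ca_n, c_t, BOND_LENGTHS[("C", "O")],
                         BOND_ANGLES[("CA", "C", "O")], CAP_PSI + 180.0)
        atoms += [c_t, ha_t, o_t]
    return np.stack(np.broadcast_arrays(*atoms), axis=-2)


def rdc_rows(pos_1, pos_2, dmax: float) -> np.ndarray:
    """Scaled design row(s) dmax * quad(v) for the unit vector(s) between
    two broadcastable coordinate arrays."""
    v = np.asarray(pos_2, dtype=float) - np.asarray(pos_1, dtype=float)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return dmax * quad_row(v)


def accumulate(m, b, dd, rows, value: float):
    """Add one coupling's contribution to the normal-equation accumulators
    (in place when shapes allow; returns the updated triple)."""
    m = m + rows[..., :, None] * rows[..., None, :]
    b = b + rows * value
    dd = dd + value * value
    return m, b, dd


def solve_ssq(m: np.ndarray, b: np.ndarray, dd) -> np.ndarray:
    """Residual sum of squares of the minimum-norm tensor solution for
    stacked normal equations: m (..., 5, 5), b (..., 5), dd (...).

    Uses a batched eigendecomposition (m is symmetric PSD); eigenvalues
    below ``NORMAL_CUTOFF`` times the largest are treated as null
    directions.  Cancellation can make the result epsilon-negative, so it
    is clamped at zero.
    """
    w, q = np.linalg.eigh(m)
    wmax = w[..., -1:]
    good = w > np.maximum(wmax, 1e-300) * NORMAL_CUTOFF
    winv = np.where(good, 1.0 / np.where(good, w, 1.0), 0.0)
    qt_b = np.einsum("...ij,...i->...j", q, b)
    sol = np.einsum("...ij,...j->...i", q, winv * qt_b)
    ssq = dd - np.einsum("...i,...i->...", sol, b)
    return np.maximum(ssq, 0.0)


def solve_tensor_components(m: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimum-norm tensor components for stacked normal equations."""
    w, q = np.linalg.eigh(m)
    wmax = w[..., -1:]
    good = w > np.maximum(wmax, 1e-300) * NORMAL_CUTOFF
    winv = np.where(good, 1.0 / np.where(good, w, 1.0), 0.0)
    qt_b = np.einsum("...ij,...i->...j", q, b)
    return np.einsum("...ij,...j->...i", q, winv * qt_b)
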