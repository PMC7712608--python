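"""Stage I: per-junction candidate torsion lists.

For every junction (an interior residue whose (phi, psi) joins two
adjoining peptide planes) the full discretized torsion grid is enumerated,
filtered by Ramachandran class, optionally intersected with a mined
dihedral restraint, and ranked by local RDC fitness.  The ranked lists
bound the Stage-II search space.

Local fitness of a candidate (phi, psi) is the RMS fitness over the
couplings whose atoms all lie in the two peptide planes the junction
joins; the relative geometry of those atoms depends on nothing but
(phi, psi), so the score is well defined without the rest of the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import TYPE_CHECKING, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from . import _batch
from .errors import DataError, ValidationError
from .geometry import ATOM_INDEX, TorsionPair, build_chain
from .tensor import RdcRecord

if TYPE_CHECKING:  # pragma: no cover
    from .mining import DihedralRestraint

logger = logging.getLogger(__name__)

RESIDUE_CLASSES = ("general", "GLY", "PRO", "prePRO")

# Allowed Ramachandran regions per residue class, as polygon vertex lists in
# degrees.  Deliberately permissive "allowed" envelopes (helical proteins can
# sample atypical torsion space, and the RDC score does the fine
# discrimination): the general/pre-Pro classes admit the whole negative-phi
# half plane, proline is confined to its ring-compatible phi band, and
# glycine is unrestricted.  Boundaries sit off the 5-degree lattice so grid
# points are never borderline.  The table is data: swap it via the
# ``regions`` argument of :func:`rama_filter` if a stricter set is wanted.
RAMA_REGIONS: dict[str, list[list[tuple[float, float]]]] = {
    "general": [[(-180.5, -180.5), (-17.5, -180.5), (-17.5, 180.5),
                 (-180.5, 180.5)]],
    "prePRO": [[(-180.5, -180.5), (-37.5, -180.5), (-37.5, 180.5),
                (-180.5, 180.5)]],
    "PRO": [[(-112.5, -180.5), (-32.5, -180.5), (-32.5, 180.5),
             (-112.5, 180.5)]],
    "GLY": [[(-180.5, -180.5), (180.5, -180.5), (180.5, 180.5),
             (-180.5, 180.5)]],
}


@dataclass
class CandidateList:
    """Ranked (phi, psi) candidates for one junction residue."""

    residue: int
    entries: list[tuple[TorsionPair, float]] = field(default_factory=list)
    no_local_data: bool = False

    @property
    def pairs(self) -> list[TorsionPair]:
        return [tp for tp, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def enumerate_grid(step_deg: float) -> list[TorsionPair]:
    """Full (360/step)^2 torsion grid over (-180, 180]^2."""
    if step_deg <= 0 or abs(360.0 / step_deg - round(360.0 / step_deg)) > 1e-9:
        raise ValidationError(f"grid step {step_deg} must divide 360")
    n = int(round(360.0 / step_deg))
    vals = -180.0 + step_deg * np.arange(1, n + 1)
    return [TorsionPair(float(p), float(s)) for p in vals for s in vals]


def residue_class(sequence: str, residue: int) -> str:
    """Ramachandran class of 1-based ``residue``: PRO and GLY by identity,
    prePRO for residues immediately preceding a proline, else general."""
    i = residue - 1
    if sequence[i] == "P":
        return "PRO"
    if sequence[i] == "G":
        return "GLY"
    if i + 1 < len(sequence) and sequence[i + 1] == "P":
        return "prePRO"
    return "general"


def rama_filter(pairs: Sequence[TorsionPair], residue_cls: str,
                regions: dict | None = None) -> list[TorsionPair]:
    """Keep the pairs inside the class's allowed polygons.  Idempotent;
    an empty result is allowed (and logged)."""
    if residue_cls not in RESIDUE_CLASSES:
        raise ValidationError(
            f"unknown residue class {residue_cls!r}; one of "
            f"{', '.join(RESIDUE_CLASSES)}")
    table = (regions or RAMA_REGIONS)[residue_cls]
    if not pairs:
        return []
    pts = np.array([[tp.phi, tp.psi] for tp in pairs], dtype=float)
    # fold the periodic boundary: +180 is the same angle as -180
    pts = np.where(pts == 180.0, -180.0, pts)
    keep = np.zeros(len(pts), dtype=bool)
    for poly in table:
        keep |= MplPath(poly).contains_points(pts)
    out = [tp for tp, k in zip(pairs, keep) if k]
    if not out:
        logger.warning("Ramachandran filter removed every candidate "
                       "(class %s)", residue_cls)
    return out


def circular_delta(a, b):
    """Smallest absolute angular difference in degrees."""
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def _wrap(v: float) -> float:
    v = (v + 180.0) % 360.0 - 180.0
    return 180.0 if v == -180.0 else v


def restrict_by_restraint(pairs: Sequence[TorsionPair],
                          restraint: "DihedralRestraint | None"
                          ) -> list[TorsionPair]:
    """Keep pairs within the restraint's +/- half-width window (circular
    distance in both phi and psi); identity when no restraint."""
    if restraint is None:
        return list(pairs)
    return [tp for tp in pairs
            if circular_delta(tp.phi, restraint.phi_hat) <= restraint.half_width
            and circular_delta(tp.psi, restraint.psi_hat) <= restraint.half_width]


def expand_restraint(restraint: "DihedralRestraint") -> list[TorsionPair]:
    """Candidate pairs generated directly from a restraint: the predicted
    angles varied by +/- half_width in ``step`` increments (wrap-aware)."""
    n = int(round(restraint.half_width / restraint.step))
    offs = restraint.step * np.arange(-n, n + 1)
    return [TorsionPair(_wrap(restraint.phi_hat + dp),
                        _wrap(restraint.psi_hat + ds))
            for dp in offs for ds in offs]


# ---------------------------------------------------------------------------
# local RDC ranking

def _local_maps(junction: int, sequence: str):
    """Atom maps of the two peptide planes joined at ``junction``:
    plane-fixed atoms -> local coordinates, candidate-dependent atoms ->
    slot indices of :func:`rdcfold._batch.extend_plane`."""
    j = junction
    L = len(sequence)
    if not 2 <= j <= L - 1:
        raise ValidationError(
            f"junction {j} outside interior residues 2..{L - 1}")
    lc = build_chain(sequence[j - 2:j], [(None, None), (None, None)]).coords
    fixed = {
        (j - 1, "CA"): lc[0, ATOM_INDEX["CA"]],
        (j - 1, "C"): lc[0, ATOM_INDEX["C"]],
        (j - 1, "O"): lc[0, ATOM_INDEX["O"]],
        (j, "N"): lc[1, ATOM_INDEX["N"]],
        (j, "CA"): lc[1, ATOM_INDEX["CA"]],
    }
    if sequence[j - 1] != "P":
        fixed[(j, "H")] = lc[1, ATOM_INDEX["H"]]
    slots = {(j, "C"): 0, (j, "HA"): 1, (j, "O"): 2,
             (j + 1, "N"): 3, (j + 1, "CA"): 5}
    if sequence[j] != "P":
        slots[(j + 1, "H")] = 4
    anchors = (lc[0, ATOM_INDEX["C"]], lc[1, ATOM_INDEX["N"]],
               lc[1, ATOM_INDEX["CA"]])
    return fixed, slots, anchors


def rank_candidates(junction: int, pairs: Sequence[TorsionPair],
                    data: Sequence[RdcRecord], sequence: str
                    ) -> CandidateList:
    """Score every candidate pair by local RDC fitness and sort ascending.

    Ties are broken by ascending (phi, psi); with no local couplings all
    scores are zero, the input order is preserved and the list is flagged.
    Deterministic: the ranking is independent of the input pair order
    (up to the documented tie-break).
    """
    if not pairs:
        raise ValidationError(f"no candidate pairs for junction {junction}")
    fixed, slots, anchors = _local_maps(junction, sequence)

    local = []
    for rec in data:
        key1 = (rec.residue_1, rec.atom_1)
        key2 = (rec.residue_2, rec.atom_2)
        if (key1 in fixed or key1 in slots) and (key2 in fixed or key2 in slots):
            local.append(rec)

    phi = np.array([tp.phi for tp in pairs])
    psi = np.array([tp.psi for tp in pairs])
    if not local:
        logger.info("junction %d: no local couplings; candidates unranked",
                    junction)
        return CandidateList(junction,
                             [(TorsionPair(p, s), 0.0)
                              for p, s in zip(phi, psi)],
                             no_local_data=True)

    new = _batch.extend_plane(*anchors, phi[:, None], psi[:, None],
                              with_h_next=(sequence[junction] != "P"))
    new = new[:, 0, :, :]  # (C, slots, 3)

    media = sorted({rec.medium for rec in local})
    midx = {m: i for i, m in enumerate(media)}
    nc = len(pairs)
    m_acc = np.zeros((nc, len(media), 5, 5))
    b_acc = np.zeros((nc, len(media), 5))
    dd_acc = np.zeros((nc, len(media)))
    for rec in local:
        pos = []
        for key in ((rec.residue_1, rec.atom_1), (rec.residue_2, rec.atom_2)):
            pos.append(fixed[key] if key in fixed else new[:, slots[key], :])
        rows = _batch.rdc_rows(pos[0], pos[1], rec.spec.dmax)
        rows = np.broadcast_to(rows, (nc, 5))
        k = midx[rec.medium]
        m_acc[:, k], b_acc[:, k], dd_acc[:, k] = _batch.accumulate(
            m_acc[:, k], b_acc[:, k], dd_acc[:, k], rows, rec.value)

    ssq = _batch.solve_ssq(m_acc, b_acc, dd_acc).sum(axis=1)
    scores = np.sqrt(ssq / len(local))

    order = np.lexsort((psi, phi, scores))
    entries = [(TorsionPair(float(phi[i]), float(psi[i])), float(scores[i]))
               for i in order]
    return CandidateList(junction, entries)


# ---------------------------------------------------------------------------
# pipeline + candidate files

def run_stage1(sequence: str, data: Sequence[RdcRecord],
               grid_step: float = 10.0,
               restraints: dict[int, "DihedralRestraint"] | None = None,
               regions: dict | None = None) -> dict[int, CandidateList]:
    """Candidate lists for every junction 2..L-1.

    With a dihedral restraint at a junction the candidates come directly
    from the restraint expansion (the mined prediction already reflects
    observed structures, so the Ramachandran filter is not re-applied);
    otherwise from the Ramachandran-filtered grid.
    """
    restraints = restraints or {}
    grid = enumerate_grid(grid_step)
    out: dict[int, CandidateList] = {}
    cache: dict[str, list[TorsionPair]] = {}
    for j in range(2, len(sequence)):
        if j in restraints:
            pairs = expand_restraint(restraints[j])
        else:
            cls = residue_class(sequence, j)
            if cls not in cache:
                cache[cls] = rama_filter(grid, cls, regions)
            pairs = cache[cls]
        out[j] = rank_candidates(j, pairs, data, sequence)
    return out


def write_candidates(clist: CandidateList, path) -> None:
    """One text file per junction: ``residue phi psi score`` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# junction candidate list: residue phi psi score\n")
        for tp, score in clist.entries:
            fh.write(f"{clist.residue} {tp.phi:.4f} {tp.psi:.4f} {score:.6g}\n")


def read_candidates(path) -> CandidateList:
    entries = []
    residue = None
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise DataError(f"{path}:{ln}: expected 4 columns")
            r, phi, psi, score = (float(x) for x in parts)
            residue = int(r) if residue is None else residue
            if int(r) != residue:
                raise DataError(f"{path}:{ln}: mixed residue indices")
            entries.append((TorsionPair(phi, psi), score))
    if residue is None:
        raise DataError(f"{path}: empty candidate file")
    return CandidateList(residue, entries)


def write_candidate_files(lists: dict[int, CandidateList], directory) -> None:
    d = FsPath(directory)
    d.mkdir(parents=True, exist_ok=True)
    for j, clist in lists.items():
        write_candidates(clist, d / f"candidates_{j:04d}.txt")
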