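"""Local dihedral-angle fragment mining.

Emulates, at local scale, the database-mining workflow in which a query
sequence is cut into k-mers with a rolling window, matching fragments are
collected from a structure corpus, and the pooled (phi, psi) observations
per residue yield a predicted dihedral pair.  The corpus here is a list of
structures (e.g. PDB files read with :func:`rdcfold.geometry.read_pdb`),
which keeps the module fully offline and testable; a live mining service
is deliberately out of scope.

Predictions are turned into per-residue restraints that Stage I expands
into candidate lists (default: predicted angles +/- 25 degrees in 5-degree
steps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, ValidationError
from .geometry import Structure, extract_torsions

logger = logging.getLogger(__name__)

#: 2-D histogram bin width (degrees) used for the mode aggregation
HIST_BIN_DEG = 10.0


@dataclass(frozen=True)
class DihedralRestraint:
    """Per-residue predicted (phi, psi) with its expansion parameters."""

    residue: int
    phi_hat: float
    psi_hat: float
    half_width: float = 25.0
    step: float = 5.0

    def __post_init__(self):
        if not (0 < self.step <= self.half_width):
            raise ValidationError(
                f"need 0 < step <= half_width, got step={self.step}, "
                f"half_width={self.half_width}")


@dataclass
class FragmentLibrary:
    """k-mer sequence -> observed (phi, psi) series of length k."""

    window: int
    fragments: dict[str, list[np.ndarray]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.fragments.values())

    def add(self, kmer: str, series: np.ndarray) -> None:
        if len(kmer) != self.window or series.shape != (self.window, 2):
            raise ValidationError("fragment series inconsistent with window")
        self.fragments.setdefault(kmer, []).append(series)


def mine_fragments(corpus, window: int = 6) -> FragmentLibrary:
    """Every length-``window`` subsequence of every corpus chain
    contributes one (phi, psi) series; chains shorter than the window are
    skipped with a log message."""
    if window < 3:
        raise ValidationError("rolling window must be >= 3")
    lib = FragmentLibrary(window)
    for chain in corpus:
        if not isinstance(chain, Structure):
            raise ValidationError("corpus entries must be Structure objects")
        if len(chain) < window:
            logger.info("skipping %d-residue chain shorter than window %d",
                        len(chain), window)
            continue
        tors = np.array(extract_torsions(chain), dtype=float)
        for start in range(len(chain) - window + 1):
            lib.add(chain.sequence[start:start + window],
                    tors[start:start + window])
    return lib


def predict_dihedrals(sequence: str, library: FragmentLibrary
                      ) -> list[DihedralRestraint]:
    """Most-likely (phi, psi) per residue of ``sequence``.

    All library fragments matching any window that covers a residue pool
    their observation at that residue; the prediction is the center of the
    modal bin of the pooled 2-D histogram (:data:`HIST_BIN_DEG` bins,
    ties resolved toward the lexicographically smallest (phi, psi)).
    Residues covered by no matching window yield no restraint.
    """
    if library.size == 0:
        raise ValidationError("empty fragment library")
    k = library.window
    edges = np.arange(-180.0, 180.0 + HIST_BIN_DEG, HIST_BIN_DEG)
    out: list[DihedralRestraint] = []
    for p in range(len(sequence)):
        pooled = []
        for offset in range(k):
            start = p - offset
            if start < 0 or start + k > len(sequence):
                continue
            for series in library.fragments.get(sequence[start:start + k], []):
                obs = series[offset]
                if np.all(np.isfinite(obs)):
                    pooled.append(obs)
        if not pooled:
            continue
        pooled = np.asarray(pooled)
        hist, _, _ = np.histogram2d(pooled[:, 0], pooled[:, 1],
                                    bins=(edges, edges))
        # argmax scans phi-major then psi: first maximum is the
        # lexicographically smallest modal bin
        i, j = np.unravel_index(int(np.argmax(hist)), hist.shape)
        phi_hat = float(edges[i] + HIST_BIN_DEG / 2.0)
        psi_hat = float(edges[j] + HIST_BIN_DEG / 2.0)
        out.append(DihedralRestraint(p + 1, phi_hat, psi_hat))
    return out


def emit_stage1_lists(restraints, directory) -> list[Path]:
    """Write per-residue Stage-I candidate files (restraint expansion at
    the restraint's own step/half-width); empty input writes nothing."""
    from .stage1 import CandidateList, expand_restraint, write_candidates

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for r in restraints:
        pairs = expand_restraint(r)
        clist = CandidateList(r.residue, [(tp, 0.0) for tp in pairs],
                              no_local_data=True)
        path = d / f"candidates_{r.residue:04d}.txt"
        write_candidates(clist, path)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# restraint table I/O (plain text: residue phi psi [half_width step])

def write_restraints(restraints, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# residue phi_hat psi_hat half_width step\n")
        for r in restraints:
            fh.write(f"{r.residue} {r.phi_hat:.4f} {r.psi_hat:.4f} "
                     f"{r.half_width:.1f} {r.step:.1f}\n")


def read_restraints(path) -> list[DihedralRestraint]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 5):
                raise DataError(f"{path}:{ln}: expected 3 or 5 columns")
            res = int(parts[0])
            phi, psi = float(parts[1]), float(parts[2])
            if len(parts) == 5:
                out.append(DihedralRestraint(res, phi, psi,
                                             float(parts[3]), float(parts[4])))
            else:
                out.append(DihedralRestraint(res, phi, psi))
    return out
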