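"""RDC dataset simulation: back-calculate couplings from a structure under
known order tensors, add seeded uniform noise, and build the self-contained
synthetic fixtures used by the test-suite and the acceptance protocol.

The evaluation loop this enables is: simulate couplings from a known
structure -> fold from the couplings alone -> compare the result to the
generating structure (backbone RMSD) and to the data (RMS fitness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import VECTOR_TYPES, VectorTypeSpec
from .errors import ValidationError
from .geometry import Structure, TorsionPair, build_chain, internuclear_vector
from .tensor import RdcRecord, SaupeTensor, back_calc

#: the six vector types of the legacy per-residue table
LEGACY_TYPE_NAMES = ("C-N", "C-H", "N-H", "CA-C", "CA-HA", "C-O")
#: the two additional types highlighted by the flexible-format engine
NEW_TYPE_NAMES = ("HA-CA", "N-CA")


def resolve_type_name(name: str) -> VectorTypeSpec:
    """Resolve a type name like ``"N-H"`` or ``"HA-CA"`` (order-insensitive)
    to its registry spec."""
    parts = name.upper().replace("'", "").split("-")
    if len(parts) != 2:
        raise ValidationError(f"bad vector type name {name!r}")
    a, b = parts
    for (a1, a2, _), spec in VECTOR_TYPES.items():
        if {a1, a2} == {a, b} or (a1, a2) in ((a, b), (b, a)):
            return spec
    raise ValidationError(
        f"unknown vector type {name!r}; supported: "
        f"{', '.join(s.name for s in VECTOR_TYPES.values())}")


def default_tensors() -> list[SaupeTensor]:
    """Two order tensors of typical experimental magnitude (principal
    values in the 1e-4..1e-3 range); medium 2 is rotated by intrinsic ZYZ
    Euler angles (40, 50, 60) degrees so the media are independent."""
    s1 = np.diag([-3e-4, -5e-4, 8e-4])
    r = Rotation.from_euler("ZYZ", [40.0, 50.0, 60.0], degrees=True).as_matrix()
    s2 = r @ np.diag([-4e-4, -6e-4, 1e-3]) @ r.T
    return [SaupeTensor.from_matrix(s1), SaupeTensor.from_matrix(s2)]


@dataclass
class SimulationSpec:
    """What to simulate: one tensor per medium, which vector types, the
    uniform-noise half-width E (Hz) and the RNG seed."""

    tensors: list[SaupeTensor] = field(default_factory=default_tensors)
    vector_types: tuple[str, ...] = LEGACY_TYPE_NAMES
    noise_hz: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_hz < 0:
            raise ValidationError("noise half-width must be >= 0")
        if not self.tensors:
            raise ValidationError("at least one alignment medium required")


def simulate_rdcs(s: Structure, spec: SimulationSpec) -> list[RdcRecord]:
    """Noise-free couplings for every resolvable (residue, type, medium).

    A type is unresolvable at a residue when an atom is missing: the two
    sequential types at residue 1 (no preceding C'), and any N-H on
    proline.  Noise is NOT added here; apply :func:`add_noise`.
    """
    specs = [resolve_type_name(nm) for nm in spec.vector_types]
    records: list[RdcRecord] = []
    for medium, tens in enumerate(spec.tensors, start=1):
        for i in range(1, len(s) + 1):
            for ts in specs:
                r1 = i - ts.seq_delta
                r2 = i
                if not (s.has_atom(r1, ts.atom_1) and s.has_atom(r2, ts.atom_2)):
                    continue
                v = internuclear_vector(s, r1, ts.atom_1, r2, ts.atom_2)
                d = back_calc(v, tens, ts)
                records.append(RdcRecord(r1, ts.atom_1, r2, ts.atom_2,
                                         medium, d, spec.noise_hz))
    return records


def add_noise(records, e_hz: float, seed: int) -> list[RdcRecord]:
    """Add i.i.d. Uniform(-E, +E) noise to every coupling (E=0 is the
    identity); deterministic for a given seed."""
    if e_hz < 0:
        raise ValidationError("noise half-width must be >= 0")
    if e_hz == 0:
        return list(records)
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        delta = float(rng.uniform(-e_hz, e_hz))
        out.append(RdcRecord(rec.residue_1, rec.atom_1, rec.residue_2,
                             rec.atom_2, rec.medium, rec.value + delta,
                             rec.uncertainty))
    return out


# ---------------------------------------------------------------------------
# synthetic fixtures

_HELIX = (-60.0, -45.0)
_STRAND = (-120.0, 120.0)
_CAP = (None, None)

_FIXTURE_TABLES: dict[str, tuple[str, list]] = {
    "helix15": (
        "ADEQKLVSEMRAQLK",
        [_CAP] + [_HELIX] * 13 + [_CAP],
    ),
    "helix_turn_helix20": (
        "ADEQKLVSGGDKAQLEMVRS",
        [_CAP] + [_HELIX] * 7
        + [(55.0, 40.0), (80.0, 5.0), (-90.0, 0.0), (-65.0, -40.0)]
        + [_HELIX] * 7 + [_CAP],
    ),
    "hairpin12": (
        "AVTFEGGTVSKA",
        [_CAP] + [_STRAND] * 4 + [(60.0, 30.0), (90.0, 0.0)]
        + [_STRAND] * 4 + [_CAP],
    ),
}

_FIXTURE_SEEDS = {"helix15": 101, "helix_turn_helix20": 202, "hairpin12": 303}

#: noise half-widths (Hz) at which each fixture ships a dataset
FIXTURE_NOISE_LEVELS = (0.0, 1.0, 2.0, 4.0)


@dataclass
class Fixture:
    """A synthetic study case: ground-truth structure + datasets."""

    name: str
    structure: Structure
    torsions: list[TorsionPair]
    tensors: list[SaupeTensor]
    datasets: dict[float, list[RdcRecord]]


def make_fixture(name: str,
                 vector_types: tuple[str, ...] = LEGACY_TYPE_NAMES) -> Fixture:
    """Deterministic fixture built from a hard-coded torsion table, with
    noise-free and noisy legacy-six-type x two-media datasets."""
    if name not in _FIXTURE_TABLES:
        raise ValidationError(
            f"unknown fixture {name!r}; choose from "
            f"{', '.join(sorted(_FIXTURE_TABLES))}")
    seq, torsions = _FIXTURE_TABLES[name]
    structure = build_chain(seq, torsions)
    tensors = default_tensors()
    base = SimulationSpec(tensors=tensors, vector_types=vector_types)
    clean = simulate_rdcs(structure, base)
    datasets = {}
    for e in FIXTURE_NOISE_LEVELS:
        seed = _FIXTURE_SEEDS[name] * 10 + int(e)
        noisy = add_noise(clean, e, seed)
        datasets[e] = [RdcRecord(r.residue_1, r.atom_1, r.residue_2,
                                 r.atom_2, r.medium, r.value, e)
                       for r in noisy]
    from .geometry import extract_torsions
    return Fixture(name, structure, extract_torsions(structure), tensors,
                   datasets)
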