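"""Restraint and run-file I/O.

Four text formats are handled:

* NEF (NMR Exchange Format, a STAR dialect): ``nef_rdc_restraint_list``
  saveframes with ``_nef_rdc_restraint`` loops listing chain code, sequence
  code, residue name and atom name of both atoms plus value and
  uncertainty.  Any supported backbone atom-pair combination is accepted;
  one saveframe per alignment medium, numbered in order of appearance.
* the legacy six-column per-residue table (residue index, six couplings,
  six uncertainties; 999 marks a missing datum).  The six columns are, in
  order: C'(i-1)-N(i), C'(i-1)-H(i), N(i)-H(i), CA(i)-C'(i), CA(i)-HA(i),
  C'(i)-O(i) — a pinned convention, remappable in
  :data:`rdcfold.constants.LEGACY_COLUMNS`.
* INI run configuration (with ``#``/``;`` comments).
* the Stage-II ``.out`` trace (one block per elongation step, replayable
  by the pdbgen tool).

Parsing is never silently lossy: every skipped row is warned about and
counted.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import (AMINO_ACIDS_1TO3, AMINO_ACIDS_3TO1, LEGACY_COLUMNS,
                        LEGACY_SENTINEL, resolve_vector_type)
from .errors import ConfigError, DataError, FormatError, ValidationError
from .geometry import TorsionPair
from .tensor import RdcRecord

logger = logging.getLogger(__name__)

NEF_CATEGORY = "nef_rdc_restraint_list"
NEF_LOOP_PREFIX = "_nef_rdc_restraint."


# ---------------------------------------------------------------------------
# NEF

def _make_record(res1, atom1, res2, atom2, medium, value, unc,
                 sequence, context) -> RdcRecord | None:
    """Validate one restraint row; None (with a warning) when rejected."""
    if resolve_vector_type(res1, atom1, res2, atom2) is None:
        logger.warning("%s: unsupported atom pair %s(%d)-%s(%d); row skipped",
                       context, atom1, res1, atom2, res2)
        return None
    if sequence is not None:
        for res, atom in ((res1, atom1), (res2, atom2)):
            if not 1 <= res <= len(sequence):
                logger.warning("%s: residue %d outside sequence; row skipped",
                               context, res)
                return None
            if atom == "H" and sequence[res - 1] == "P":
                logger.warning("%s: amide H on proline %d; row skipped",
                               context, res)
                return None
    return RdcRecord(res1, atom1, res2, atom2, medium, value, unc)


def read_nef(path, sequence: str | None = None,
             medium_offset: int = 0) -> list[RdcRecord]:
    """All RDC records of a NEF document; saveframes become media
    ``medium_offset + 1, 2, ...`` in order of appearance.

    Rows with unsupported atom pairs are skipped with a warning; residue
    names are validated against ``sequence`` when given.
    """
    import gemmi.cif as cif

    try:
        doc = cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not a STAR/NEF document: {exc}") from None

    records: list[RdcRecord] = []
    medium = medium_offset
    n_frames = 0
    for block in doc:
        frames = [item.frame for item in block if item.frame is not None]
        for frame in frames:
            cat = frame.find_value(f"_{NEF_CATEGORY}.sf_category")
            if cat is not None and cat != NEF_CATEGORY:
                continue
            tab = frame.find(NEF_LOOP_PREFIX, [
                "sequence_code_1", "residue_name_1", "atom_name_1",
                "sequence_code_2", "residue_name_2", "atom_name_2",
                "value", "value_uncertainty"])
            if len(tab) == 0:
                continue
            n_frames += 1
            medium += 1
            for row in tab:
                context = f"{path} [{frame.name}]"
                try:
                    res1, res2 = int(row[0]), int(row[3])
                    value = float(row[6])
                    unc = 0.0 if row[7] in (".", "?") else float(row[7])
                except ValueError as exc:
                    raise FormatError(
                        f"{context}: malformed restraint row: {exc}") from None
                atom1, atom2 = row[2], row[5]
                for res, name in ((res1, row[1]), (res2, row[4])):
                    if (sequence is not None
                            and name in AMINO_ACIDS_3TO1
                            and 1 <= res <= len(sequence)
                            and AMINO_ACIDS_3TO1[name] != sequence[res - 1]):
                        raise DataError(
                            f"{context}: residue {res} is "
                            f"{sequence[res - 1]} in the sequence but "
                            f"{name} in the restraint file")
                rec = _make_record(res1, atom1, res2, atom2, medium,
                                   value, unc, sequence, context)
                if rec is not None:
                    records.append(rec)
    if n_frames == 0:
        raise FormatError(f"{path}: no {NEF_CATEGORY} saveframe found")
    return records


def write_nef(records, path, sequence: str | None = None,
              name: str = "rdcfold") -> None:
    """One ``nef_rdc_restraint_list`` saveframe per medium, media in
    ascending order.  Round-trips through :func:`read_nef`.  Residue names
    are filled from ``sequence`` when given, else written as ``.``."""
    by_medium: dict[int, list[RdcRecord]] = {}
    for rec in records:
        by_medium.setdefault(rec.medium, []).append(rec)

    def res_name(res: int) -> str:
        if sequence is None or not 1 <= res <= len(sequence):
            return "."
        return AMINO_ACIDS_1TO3[sequence[res - 1]]

    lines = [f"data_{name}", ""]
    for k, medium in enumerate(sorted(by_medium), start=1):
        frame = f"nef_rdc_restraint_list_{k}"
        lines += [
            f"save_{frame}",
            f"   _{NEF_CATEGORY}.sf_category   {NEF_CATEGORY}",
            f"   _{NEF_CATEGORY}.sf_framecode  {frame}",
            "   loop_",
        ]
        cols = ["index"] + [f"{f}_{i}" for i in (1, 2)
                            for f in ("chain_code", "sequence_code",
                                      "residue_name", "atom_name")] \
            + ["value", "value_uncertainty"]
        lines += [f"      {NEF_LOOP_PREFIX}{c}" for c in cols]
        for idx, rec in enumerate(by_medium[medium], start=1):
            lines.append(
                f"      {idx} A {rec.residue_1} {res_name(rec.residue_1)} "
                f"{rec.atom_1} A {rec.residue_2} {res_name(rec.residue_2)} "
                f"{rec.atom_2} {rec.value:.6f} {rec.uncertainty:.6f}")
        lines += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# legacy six-column table

def read_legacy(path, medium: int = 1,
                sequence: str | None = None) -> list[RdcRecord]:
    """Whitespace table: residue index, six couplings, six uncertainties
    per row; the sentinel 999 marks a missing coupling (no record)."""
    records: list[RdcRecord] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 13:
                raise FormatError(
                    f"{path}:{ln}: expected 13 columns "
                    f"(residue + 6 values + 6 errors), got {len(parts)}")
            try:
                res = int(parts[0])
                vals = [float(x) for x in parts[1:7]]
                errs = [float(x) for x in parts[7:13]]
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from None
            for (d1, a1, d2, a2), val, err in zip(LEGACY_COLUMNS, vals, errs):
                if val == LEGACY_SENTINEL:
                    continue
                rec = _make_record(res + d1, a1, res + d2, a2, medium,
                                   val, abs(err), sequence,
                                   f"{path}:{ln}")
                if rec is not None:
                    records.append(rec)
    return records


def write_legacy(records, path, medium: int = 1) -> None:
    """Inverse of :func:`read_legacy` for records expressible in the six
    legacy columns (others are warned about and dropped)."""
    col_of = {(d1, a1, d2, a2): k
              for k, (d1, a1, d2, a2) in enumerate(LEGACY_COLUMNS)}
    table: dict[int, list[tuple[float, float]]] = {}
    dropped = 0
    for rec in records:
        if rec.medium != medium:
            continue
        placed = False
        for (i1, a1, i2, a2) in ((rec.residue_1, rec.atom_1,
                                  rec.residue_2, rec.atom_2),
                                 (rec.residue_2, rec.atom_2,
                                  rec.residue_1, rec.atom_1)):
            for res in (i1, i2):
                key = (i1 - res, a1, i2 - res, a2)
                if key in col_of:
                    row = table.setdefault(
                        res, [(LEGACY_SENTINEL, LEGACY_SENTINEL)] * 6)
                    row[col_of[key]] = (rec.value, rec.uncertainty)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            dropped += 1
    if dropped:
        logger.warning("write_legacy: %d records have no legacy column",
                       dropped)
    with open(path, "w", encoding="utf-8") as fh:
        for res in sorted(table):
            vals = " ".join(f"{v:.6f}" if v != LEGACY_SENTINEL else "999"
                            for v, _ in table[res])
            errs = " ".join(f"{e:.6f}" if v != LEGACY_SENTINEL else "999"
                            for v, e in table[res])
            fh.write(f"{res} {vals} {errs}\n")


def convert_legacy_to_nef(legacy_path, nef_path, medium: int = 1) -> int:
    """Legacy -> NEF conversion; returns the number of records written."""
    records = read_legacy(legacy_path, medium=medium)
    write_nef(records, nef_path)
    return len(records)


# ---------------------------------------------------------------------------
# run configuration (INI)

@dataclass
class RunConfig:
    """Resolved Stage-I/II run parameters."""

    sequence: str
    rdc_files: list[str]
    rdc_format: str = "nef"          # "nef" | "legacy"
    depth: int = 1000
    decimation: str = "dynamic"      # "dynamic" | "static"
    tolerance_pct: float = 20.0
    static_threshold_hz: float = float("inf")
    bucket_deg: float = 0.0
    grid_step: float = 10.0
    restraint_file: str | None = None
    seed: int = 0
    out_file: str = "run.out"
    pdb_file: str = "final.pdb"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError("search depth must be >= 1")
        if self.decimation not in ("dynamic", "static"):
            raise ConfigError(
                f"decimation must be dynamic or static, got {self.decimation}")
        if self.decimation == "dynamic" and self.tolerance_pct <= 0:
            raise ConfigError("tolerance must be > 0 for dynamic decimation")


_KNOWN_KEYS = {
    ("input", "sequence"), ("input", "rdc_files"), ("input", "format"),
    ("input", "restraints"),
    ("search", "depth"), ("search", "decimation"), ("search", "tolerance"),
    ("search", "static_threshold"), ("search", "bucket"),
    ("search", "grid_step"), ("search", "seed"),
    ("output", "out_file"), ("output", "pdb_file"),
}


def read_config(path) -> RunConfig:
    """Parse an INI run configuration (``#``/``;`` comments allowed).

    Mandatory keys: ``[input] sequence`` (file of one-letter codes, or the
    literal sequence) and ``[input] rdc_files`` (comma-separated, one per
    alignment medium).  Unknown keys warn; missing mandatory keys raise a
    :class:`ConfigError` naming the key.  Relative paths are resolved
    against the config file's directory.
    """
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    read = parser.read(str(path))
    if not read:
        raise ConfigError(f"cannot read config file {path}")
    base = Path(path).resolve().parent

    for section in parser.sections():
        for key in parser[section]:
            if (section, key) not in _KNOWN_KEYS:
                logger.warning("%s: unknown key [%s] %s ignored",
                               path, section, key)

    def get(section, key, default=None, required=False):
        if parser.has_option(section, key):
            return parser.get(section, key).strip()
        if required:
            raise ConfigError(f"{path}: missing mandatory key [{section}] {key}")
        return default

    seq_value = get("input", "sequence", required=True)
    seq_path = (base / seq_value)
    if seq_path.is_file():
        sequence = "".join(seq_path.read_text(encoding="utf-8").split())
    else:
        sequence = seq_value
    sequence = sequence.upper()
    bad = set(sequence) - set(AMINO_ACIDS_1TO3)
    if bad:
        raise ConfigError(
            f"{path}: sequence contains unknown letters {''.join(sorted(bad))} "
            f"(is [input] sequence a missing file path?)")

    files_value = get("input", "rdc_files", required=True)
    rdc_files = [str((base / f.strip()))
                 for f in files_value.split(",") if f.strip()]
    if not rdc_files:
        raise ConfigError(f"{path}: [input] rdc_files lists no files")

    restr = get("input", "restraints")
    return RunConfig(
        sequence=sequence,
        rdc_files=rdc_files,
        rdc_format=get("input", "format", "nef").lower(),
        depth=int(get("search", "depth", "1000")),
        decimation=get("search", "decimation", "dynamic").lower(),
        tolerance_pct=float(get("search", "tolerance", "20")),
        static_threshold_hz=float(get("search", "static_threshold", "inf")),
        bucket_deg=float(get("search", "bucket", "0")),
        grid_step=float(get("search", "grid_step", "10")),
        restraint_file=str(base / restr) if restr else None,
        seed=int(get("search", "seed", "0")),
        out_file=str(base / get("output", "out_file", "run.out")),
        pdb_file=str(base / get("output", "pdb_file", "final.pdb")),
    )


def load_rdc_data(config: RunConfig) -> list[RdcRecord]:
    """All media of a run, numbered by file order (NEF files holding
    several saveframes consume several medium indices)."""
    records: list[RdcRecord] = []
    medium = 0
    for f in config.rdc_files:
        if not Path(f).is_file():
            raise ConfigError(f"RDC file not found: {f}")
        if config.rdc_format == "nef":
            batch = read_nef(f, sequence=config.sequence,
                             medium_offset=medium)
        elif config.rdc_format == "legacy":
            batch = read_legacy(f, medium=medium + 1,
                                sequence=config.sequence)
        else:
            raise ConfigError(f"unknown RDC format {config.rdc_format!r}")
        records.extend(batch)
        medium = max((r.medium for r in records), default=medium)
    return records


# ---------------------------------------------------------------------------
# Stage-II .out trace

@dataclass
class OutRecord:
    """Ranked beam snapshot after elongating through one junction."""

    residue: int
    entries: list[tuple[float, list[TorsionPair]]] = field(default_factory=list)

    def __post_init__(self):
        scores = [s for s, _ in self.entries]
        if any(b < a - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValidationError("out entries must be score-sorted")


def write_out(records: list[OutRecord], path) -> None:
    """Line-oriented trace: a ``step`` header per junction, then one line
    per beam member: score + semicolon-joined phi:psi list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# rdcfold stage2 trace\n")
        for rec in records:
            fh.write(f"step {rec.residue}\n")
            for score, torsions in rec.entries:
                angles = ";".join(f"{tp.phi:.4f}:{tp.psi:.4f}"
                                  for tp in torsions)
                fh.write(f"{score:.9g} {angles}\n")


def read_out(path) -> list[OutRecord]:
    records: list[OutRecord] = []
    current: OutRecord | None = None
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("step "):
                current = OutRecord(int(line.split()[1]))
                records.append(current)
                continue
            if current is None:
                raise FormatError(f"{path}:{ln}: entry before step header")
            score_s, angles_s = line.split(None, 1)
            torsions = []
            for pair in angles_s.split(";"):
                phi_s, psi_s = pair.split(":")
                torsions.append(TorsionPair(float(phi_s), float(psi_s)))
            current.entries.append((float(score_s), torsions))
    if not records:
        raise FormatError(f"{path}: empty trace")
    return records
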