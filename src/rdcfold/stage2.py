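"""Stage II: beam-search elongation over peptide planes with static
(legacy) and dynamic decimation.

The chain is assembled junction by junction: starting from the first two
peptide planes, every beam fragment is combined with every Stage-I
candidate (phi, psi) for the next junction, the children are scored by
RMS fitness over all couplings their atoms determine, pruned by the
decimation policy, and the best ``depth`` survivors carry forward.

Dynamic decimation keeps only children scoring below the running best
times (1 + tolerance/100); because early steps are under-determined (a
five-parameter order tensor per medium against few couplings) a small
absolute guard threshold takes over whenever the best score is exactly
zero.  Static decimation — kept for comparison experiments — selects one
representative per terminal-torsion bucket and applies a fixed absolute
score threshold.

Scoring is incremental: each fragment carries per-medium normal-equation
accumulators of its dipolar design rows, so a child's tensor problem is a
5x5 solve regardless of fragment length.  Every step, the winner's score
is audited against a from-scratch recomputation on its rebuilt structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _batch
from .errors import DataError, ValidationError
from .formats import OutRecord, RunConfig
from .geometry import ATOM_INDEX, Structure, TorsionPair, build_chain
from .stage1 import CandidateList
from .tensor import FitnessScore, RdcRecord, fitness

logger = logging.getLogger(__name__)

#: tolerance (Hz) of the per-step batch-vs-reference score audit
AUDIT_TOL = 1e-6

#: target number of (parent, candidate) children scored per chunk
_CHUNK_CHILDREN = 200_000

_IC = ATOM_INDEX["C"]
_IN = ATOM_INDEX["N"]
_ICA = ATOM_INDEX["CA"]


@dataclass
class DecimationPolicy:
    """Pruning parameters for one Stage-II run."""

    mode: str = "dynamic"                 # "dynamic" | "static"
    depth: int = 1000                     # beam width n
    tolerance_pct: float = 20.0           # dynamic: +n% band above the best
    static_threshold_hz: float = float("inf")  # static: absolute cutoff
    bucket_deg: float = 0.0               # static: representative bucket, 0=off
    eps_abs_hz: float = 0.01              # dynamic: guard when best score is 0
    additive: bool = False                # read "+n%" as s0 + n/100 Hz instead

    def __post_init__(self):
        if self.mode not in ("dynamic", "static"):
            raise ValidationError(f"unknown decimation mode {self.mode!r}")
        if self.depth < 1:
            raise ValidationError("search depth must be >= 1")
        if self.mode == "dynamic" and self.tolerance_pct <= 0:
            raise ValidationError("dynamic tolerance must be > 0")

    @classmethod
    def from_config(cls, config: RunConfig) -> "DecimationPolicy":
        return cls(mode=config.decimation, depth=config.depth,
                   tolerance_pct=config.tolerance_pct,
                   static_threshold_hz=config.static_threshold_hz,
                   bucket_deg=config.bucket_deg)


@dataclass
class Fragment:
    """A partial (or complete) structure in the beam: the chosen torsions
    for junctions 2..j, the cached structure (atoms beyond the built
    planes are NaN) and its fitness on the couplings those atoms
    determine."""

    torsions: list[TorsionPair]
    structure: Structure
    score: FitnessScore

    @property
    def last_junction(self) -> int:
        return len(self.torsions) + 1


# ---------------------------------------------------------------------------
# record determination plan

def _det_step(residue: int, atom: str, length: int) -> int:
    """First step at which an atom's position is fixed by chosen torsions:
    1 is the init step (planes 1-2), j in 2..L-1 the junction steps."""
    if atom in ("N", "H", "CA"):
        return 1 if residue <= 2 else residue - 1
    # C', HA, O move with the residue's own (phi, psi)
    if residue == 1:
        return 1
    return min(residue, length - 1)


def _slot_of(residue: int, atom: str, j: int, length: int) -> int:
    """Slot index in :func:`rdcfold._batch.extend_plane` output for an
    atom first determined at junction ``j``."""
    if residue == j:
        return {"C": 0, "HA": 1, "O": 2}[atom]
    if residue == j + 1 and atom in ("N", "H", "CA"):
        return {"N": 3, "H": 4, "CA": 5}[atom]
    # terminal residue's cap-torsion atoms, only at the final junction
    assert j == length - 1 and residue == length
    return {"C": 6, "HA": 7, "O": 8}[atom]


def build_plan(data, sequence: str):
    """Assign every coupling to the elongation step that determines both
    its atoms.

    Returns ``(media, init_records, steps)`` where ``steps[j]`` is a list
    of ``(medium_index, value, dmax, ref1, ref2)`` with each ref either
    ``("slot", k)`` into the new-atom stack or ``("old", res0, atom_idx)``
    into the fragment coordinates.  Couplings that can never be resolved
    (out-of-range residues, amide H on proline) are dropped with a
    warning.
    """
    length = len(sequence)
    media = sorted({rec.medium for rec in data})
    midx = {m: i for i, m in enumerate(media)}
    init: list[RdcRecord] = []
    steps: dict[int, list] = {j: [] for j in range(2, length)}
    dropped = 0
    for rec in data:
        atoms = ((rec.residue_1, rec.atom_1), (rec.residue_2, rec.atom_2))
        ok = True
        for res, atom in atoms:
            if not 1 <= res <= length or (
                    atom == "H" and sequence[res - 1] == "P"):
                ok = False
        if not ok:
            dropped += 1
            continue
        j = max(_det_step(res, atom, length) for res, atom in atoms)
        if j == 1:
            init.append(rec)
            continue
        refs = []
        for res, atom in atoms:
            if _det_step(res, atom, length) == j:
                refs.append(("slot", _slot_of(res, atom, j, length)))
            else:
                refs.append(("old", res - 1, ATOM_INDEX[atom]))
        steps[j].append((midx[rec.medium], rec.value, rec.spec.dmax,
                         refs[0], refs[1]))
    if dropped:
        logger.warning("stage2 plan: dropped %d never-resolvable couplings",
                       dropped)
    return media, init, steps


# ---------------------------------------------------------------------------
# internal beam state

class _BeamState:
    """Array-of-fragments representation of the beam after junction j."""

    __slots__ = ("j", "torsions", "coords", "m", "b", "dd", "n_used",
                 "scores")

    def __init__(self, j, torsions, coords, m, b, dd, n_used, scores):
        self.j = j                  # last junction elongated (1 = init)
        self.torsions = torsions    # (P, j-1, 2)
        self.coords = coords        # (P, L, 6, 3), NaN where undetermined
        self.m = m                  # (P, nmed, 5, 5)
        self.b = b                  # (P, nmed, 5)
        self.dd = dd                # (P, nmed)
        self.n_used = n_used        # couplings accumulated so far
        self.scores = scores        # (P,)

    def __len__(self) -> int:
        return self.torsions.shape[0]


def _accumulate_records(coords, records, midx):
    """Normal-equation accumulators for fully-resolvable records on a
    single coordinate set (used for the init state and public wrappers)."""
    nmed = len(midx)
    m = np.zeros((nmed, 5, 5))
    b = np.zeros((nmed, 5))
    dd = np.zeros(nmed)
    n = 0
    for rec in records:
        p1 = coords[rec.residue_1 - 1, ATOM_INDEX[rec.atom_1]]
        p2 = coords[rec.residue_2 - 1, ATOM_INDEX[rec.atom_2]]
        if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
            continue
        rows = _batch.rdc_rows(p1, p2, rec.spec.dmax)
        k = midx[rec.medium]
        m[k], b[k], dd[k] = _batch.accumulate(m[k], b[k], dd[k], rows,
                                              rec.value)
        n += 1
    return m, b, dd, n


def init_state(sequence: str, media, init_records) -> _BeamState:
    """Single-fragment beam holding the first two peptide planes."""
    length = len(sequence)
    if length < 3:
        raise ValidationError("need at least three residues to assemble")
    s2 = build_chain(sequence[:2], [(None, None), (None, None)])
    coords = np.full((1, length, 6, 3), np.nan)
    coords[0, :2] = s2.coords
    for at in ("C", "HA", "O"):  # junction-2 degrees of freedom
        coords[0, 1, ATOM_INDEX[at]] = np.nan
    midx = {m: i for i, m in enumerate(media)}
    m, b, dd, n = _accumulate_records(coords[0], init_records, midx)
    return _BeamState(1, np.zeros((1, 0, 2)), coords, m[None], b[None],
                      dd[None], n, np.zeros(1))


def _plan_arrays(coords, j, phi, psi, plan_j, nmed, with_h_next, terminal):
    """New-atom stack plus per-medium normal-equation increments for the
    children defined by broadcastable (phi, psi) at junction ``j``."""
    c_prev = coords[..., j - 2, _IC, :]
    n_j = coords[..., j - 1, _IN, :]
    ca_j = coords[..., j - 1, _ICA, :]
    new = _batch.extend_plane(c_prev, n_j, ca_j, phi, psi,
                              with_h_next=with_h_next, terminal=terminal)
    shape = np.broadcast_shapes(np.shape(phi), c_prev.shape[:-1])
    m_add = np.zeros(shape + (nmed, 5, 5))
    b_add = np.zeros(shape + (nmed, 5))
    dd_add = np.zeros(nmed)
    for med, value, dmax, ref1, ref2 in plan_j:
        pos = []
        for kind, *idx in (ref1, ref2):
            if kind == "slot":
                pos.append(new[..., idx[0], :])
            else:
                pos.append(coords[..., idx[0], idx[1], :])
        rows = np.broadcast_to(_batch.rdc_rows(pos[0], pos[1], dmax),
                               shape + (5,))
        m_add[..., med, :, :] += rows[..., :, None] * rows[..., None, :]
        b_add[..., med, :] += rows * value
        dd_add[med] += value * value
    return new, m_add, b_add, dd_add


def _pool_scores(state: _BeamState, j: int, cand: np.ndarray, plan_j,
                 sequence: str, nmed: int) -> np.ndarray:
    """(P, C) child scores, computed in parent chunks to bound memory."""
    length = len(sequence)
    n_par, n_cand = len(state), len(cand)
    n_tot = state.n_used + len(plan_j)
    with_h = sequence[j] != "P"
    terminal = j == length - 1
    phi = cand[None, :, 0]
    psi = cand[None, :, 1]
    scores = np.empty((n_par, n_cand))
    chunk = max(1, _CHUNK_CHILDREN // max(1, n_cand))
    for lo in range(0, n_par, chunk):
        hi = min(n_par, lo + chunk)
        coords = state.coords[lo:hi, None]
        _, m_add, b_add, dd_add = _plan_arrays(
            coords, j, phi, psi, plan_j, nmed, with_h, terminal)
        m_tot = state.m[lo:hi, None] + m_add
        b_tot = state.b[lo:hi, None] + b_add
        dd_tot = state.dd[lo:hi, None] + dd_add
        ssq = _batch.solve_ssq(m_tot, b_tot, dd_tot).sum(axis=-1)
        scores[lo:hi] = np.sqrt(ssq / max(1, n_tot))
    return scores


# ---------------------------------------------------------------------------
# decimation

def _dynamic_threshold(s0: float, policy: DecimationPolicy) -> float:
    if s0 <= 0.0:
        return policy.eps_abs_hz
    if policy.additive:
        return s0 + policy.tolerance_pct / 100.0
    return s0 * (1.0 + policy.tolerance_pct / 100.0)


def decimate_dynamic(pool, tolerance_pct: float, eps_abs_hz: float = 0.01,
                     additive: bool = False):
    """Keep the pool members scoring below best * (1 + tolerance/100)
    (or best + tolerance/100 Hz in additive mode; below ``eps_abs_hz``
    when the best score is zero).  ``pool`` must be sorted ascending by
    score; the best member always survives, so the result is never empty.
    Members may be :class:`Fragment` objects or plain numbers.
    """
    scores = np.array([float(getattr(x, "score", x)) for x in pool])
    if scores.size == 0:
        raise ValidationError("empty decimation pool")
    if np.any(np.diff(scores) < -1e-12):
        raise ValidationError("decimation pool must be sorted ascending")
    policy = DecimationPolicy(tolerance_pct=max(tolerance_pct, 1e-12),
                              eps_abs_hz=eps_abs_hz, additive=additive)
    thr = _dynamic_threshold(float(scores[0]), policy)
    keep = scores < thr
    keep[0] = True
    return [x for x, k in zip(pool, keep) if k]


def decimate_static(pool, policy: DecimationPolicy):
    """Legacy representative pruning: bucket fragments by their terminal
    (phi, psi) rounded to ``bucket_deg`` (0 disables bucketing), keep the
    best of each bucket, then drop everything above the absolute score
    threshold.  May return an empty list (callers fall back to plain
    top-n)."""
    out = []
    seen = set()
    for frag in pool:
        score = float(getattr(frag, "score", frag))
        if policy.bucket_deg > 0:
            tp = frag.torsions[-1]
            key = (round(tp.phi / policy.bucket_deg),
                   round(tp.psi / policy.bucket_deg))
            if key in seen:
                continue
            seen.add(key)
        if score <= policy.static_threshold_hz:
            out.append(frag)
    return out


def _select_children(scores_flat: np.ndarray, state: _BeamState,
                     cand: np.ndarray, policy: DecimationPolicy
                     ) -> np.ndarray:
    """Flat child indices (parent * C + candidate) surviving decimation,
    best-first, at most ``policy.depth`` of them, with exact score ties
    broken lexicographically on the full torsion sequence."""
    n_cand = len(cand)
    order = np.argsort(scores_flat, kind="stable")
    sorted_scores = scores_flat[order]

    if policy.mode == "dynamic":
        thr = _dynamic_threshold(float(sorted_scores[0]), policy)
        n_keep = int(np.searchsorted(sorted_scores, thr, side="left"))
        n_keep = max(1, n_keep)
        survivors = order[:n_keep]
    else:
        kept = []
        seen = set()
        for idx in order:
            if policy.bucket_deg > 0:
                c = idx % n_cand
                key = (round(cand[c, 0] / policy.bucket_deg),
                       round(cand[c, 1] / policy.bucket_deg))
                if key in seen:
                    continue
                seen.add(key)
            if scores_flat[idx] <= policy.static_threshold_hz:
                kept.append(idx)
            if len(kept) >= policy.depth * 4:
                break
        if not kept:
            logger.warning("static decimation emptied the pool; "
                           "falling back to best %d by score", policy.depth)
            kept = list(order[:policy.depth])
        survivors = np.asarray(kept)

    survivors = survivors[:max(policy.depth,
                               _tie_extent(scores_flat, survivors,
                                           policy.depth))]
    survivors = _break_ties(scores_flat, survivors, state, cand)
    return survivors[:policy.depth]


def _tie_extent(scores_flat, survivors, depth) -> int:
    """Extend the cut so a tie group straddling the depth boundary is
    fully included before lexicographic resolution."""
    if len(survivors) <= depth:
        return len(survivors)
    cut_score = scores_flat[survivors[depth - 1]]
    n = depth
    while n < len(survivors) and scores_flat[survivors[n]] == cut_score:
        n += 1
    return n


def _break_ties(scores_flat, survivors, state, cand) -> np.ndarray:
    """Reorder exact-score ties by ascending full torsion sequence."""
    n_cand = len(cand)
    scores = scores_flat[survivors]
    out = []
    i = 0
    while i < len(survivors):
        jx = i + 1
        while jx < len(survivors) and scores[jx] == scores[i]:
            jx += 1
        group = survivors[i:jx]
        if len(group) > 1:
            def key(idx):
                p, c = divmod(int(idx), n_cand)
                return (tuple(state.torsions[p].ravel())
                        + (cand[c, 0], cand[c, 1]))
            group = np.asarray(sorted(group, key=key))
        out.append(group)
        i = jx
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# one elongation step

_SLOT_TARGETS = ((0, "C", 0), (1, "HA", 0), (2, "O", 0),
                 (3, "N", 1), (4, "H", 1), (5, "CA", 1),
                 (6, "C", 1), (7, "HA", 1), (8, "O", 1))


def _step(state: _BeamState, j: int, cand: np.ndarray, plan_j,
          sequence: str, nmed: int, policy: DecimationPolicy
          ) -> _BeamState:
    length = len(sequence)
    n_cand = len(cand)
    scores = _pool_scores(state, j, cand, plan_j, sequence, nmed)
    flat = scores.ravel()
    chosen = _select_children(flat, state, cand, policy)
    p_idx, c_idx = np.divmod(chosen, n_cand)

    logger.info("junction %d: pool %d -> beam %d (best %.4g Hz)",
                j, flat.size, len(chosen), float(flat[chosen[0]]))

    par_coords = state.coords[p_idx]
    phi = cand[c_idx, 0]
    psi = cand[c_idx, 1]
    with_h = sequence[j] != "P"
    terminal = j == length - 1
    new, m_add, b_add, dd_add = _plan_arrays(
        par_coords, j, phi, psi, plan_j, nmed, with_h, terminal)

    coords = par_coords.copy()
    n_slots = new.shape[-2]
    for slot, atom, dres in _SLOT_TARGETS[:n_slots]:
        coords[:, j - 1 + dres, ATOM_INDEX[atom]] = new[:, slot]
    if not with_h:
        coords[:, j, ATOM_INDEX["H"]] = np.nan

    torsions = np.concatenate(
        [state.torsions[p_idx],
         np.stack([phi, psi], axis=1)[:, None, :]], axis=1)
    return _BeamState(j, torsions, coords,
                      state.m[p_idx] + m_add, state.b[p_idx] + b_add,
                      state.dd[p_idx] + dd_add,
                      state.n_used + len(plan_j), flat[chosen])


def _fragment_from_row(state: _BeamState, row: int, sequence: str,
                       data) -> Fragment:
    structure = Structure(sequence, state.coords[row].copy())
    score = fitness(structure, data)
    return Fragment([TorsionPair(float(p), float(s))
                     for p, s in state.torsions[row]], structure, score)


def _audit(state: _BeamState, sequence: str, data) -> float:
    """Cache-coherence audit: the winner's incremental score must equal
    the from-scratch RMS fitness of its rebuilt partial structure."""
    ref = fitness(Structure(sequence, state.coords[0]), data).value
    if abs(ref - float(state.scores[0])) > AUDIT_TOL * max(1.0, ref):
        raise RuntimeError(
            f"score cache incoherent at junction {state.j}: "
            f"incremental {state.scores[0]:.9g} vs recomputed {ref:.9g}")
    return ref


# ---------------------------------------------------------------------------
# public operations

def elongate_step(beam: list[Fragment], candidates: CandidateList,
                  data, policy: DecimationPolicy) -> list[Fragment]:
    """One elongation round on an explicit fragment beam.

    All beam members must cover the same junctions; ``candidates.residue``
    must be the next junction.  Children are scored over every coupling
    their atoms determine, decimated per ``policy``, and returned ranked
    ascending (at most ``policy.depth`` fragments, each with a
    from-scratch recomputed score).
    """
    if not beam:
        raise ValidationError("empty beam")
    if len(candidates) == 0:
        raise ValidationError("empty candidate list")
    sequence = beam[0].structure.sequence
    j = candidates.residue
    for frag in beam:
        if frag.last_junction != j - 1:
            raise ValidationError(
                f"beam fragment at junction {frag.last_junction} cannot "
                f"take candidates for junction {j}")

    media, init_records, steps = build_plan(data, sequence)
    midx = {m: i for i, m in enumerate(media)}
    coords = np.stack([f.structure.coords for f in beam])
    acc = [_accumulate_records(c, data, midx) for c in coords]
    state = _BeamState(
        j - 1,
        np.array([[[tp.phi, tp.psi] for tp in f.torsions] for f in beam],
                 dtype=float).reshape(len(beam), -1, 2),
        coords,
        np.stack([a[0] for a in acc]), np.stack([a[1] for a in acc]),
        np.stack([a[2] for a in acc]), acc[0][3],
        np.array([float(f.score) for f in beam]))

    cand = np.array([[tp.phi, tp.psi] for tp in candidates.pairs])
    state = _step(state, j, cand, steps.get(j, []), sequence, len(media),
                  policy)
    _audit(state, sequence, data)
    return [_fragment_from_row(state, r, sequence, data)
            for r in range(len(state))]


def initial_fragment(sequence: str, data) -> Fragment:
    """The beam seed: the first two peptide planes (no torsions chosen)."""
    media, init_records, _ = build_plan(data, sequence)
    state = init_state(sequence, media, init_records)
    return _fragment_from_row(state, 0, sequence, data)


def run_stage2(config: RunConfig, stage1_lists: dict[int, CandidateList],
               data) -> tuple[Fragment, list[OutRecord]]:
    """Full elongation from the first two peptide planes to the final
    residue.

    Returns the best complete fragment (terminal atoms closed with the
    cap torsions, score recomputed from scratch over all couplings) and
    the per-step ranked trace.  Deterministic for identical inputs.
    """
    sequence = config.sequence
    length = len(sequence)
    policy = DecimationPolicy.from_config(config)
    media, init_records, steps = build_plan(data, sequence)
    state = init_state(sequence, media, init_records)
    trace: list[OutRecord] = []
    for j in range(2, length):
        clist = stage1_lists.get(j)
        if clist is None or len(clist) == 0:
            raise DataError(f"no Stage-I candidates for junction residue {j}")
        cand = np.array([[tp.phi, tp.psi] for tp in clist.pairs])
        state = _step(state, j, cand, steps.get(j, []), sequence,
                      len(media), policy)
        _audit(state, sequence, data)
        entries = [(float(state.scores[r]),
                    [TorsionPair(float(p), float(s))
                     for p, s in state.torsions[r]])
                   for r in range(len(state))]
        trace.append(OutRecord(j, entries))
    best = _fragment_from_row(state, 0, sequence, data)
    return best, trace
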