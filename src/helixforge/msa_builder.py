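"""Blended sequence/structure multiple alignment of 7TM receptors.

The template alignment is built from structure: transmembrane helices are
aligned outward from their most conserved (x.50) residues, with insertions
and deletions placed where a CA deviates from the column consensus along
the helical axis; loops are aligned by CA proximity and CA->CB vector
agreement after global superposition; residues no criterion can place are
parked adjacent to defined secondary structure. A structure-less target is
then threaded into the finished template MSA with knowledge-based rules
(x.50 / motif anchoring, half-split loops, disulfide-anchored ECL2/ECL3).

MSA columns are 0-based array indices; residue positions are 1-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import AlignConfig
from .errors import AlignmentError, ValidationError
from .geometry import ATOM_INDEX, apply_rigid, classify_ss, kabsch
from .io_formats import (
    LOOP_AFTER_TM,
    LOOP_REGIONS,
    REGION_ORDER,
    TM_REGIONS,
    ReceptorEntry,
    regions_from_segments,
)

log = logging.getLogger(__name__)

GAP = "-"


# ---------------------------------------------------------------------------
# MSA container


@dataclass
class MSA:
    """Gapped rows over a shared column space, with region bookkeeping.

    rows : ordered mapping id -> gapped sequence (all equal length)
    region_masks : region name -> set of columns
    anchor_columns : BW anchor label ("1.50".."7.50") -> column
    unaligned : row id -> columns holding residues no structural or motif
        criterion could place (sequence-parked residues)
    defined_columns : columns of defined structure (TM helices, loop
        secondary-structure elements, disulfide cysteines)
    disulfide_columns : bond kind ("TM3-ECL2", "ECL3") -> (column_a, column_b)
    """

    rows: Dict[str, str]
    region_masks: Dict[str, Set[int]] = field(default_factory=dict)
    anchor_columns: Dict[str, int] = field(default_factory=dict)
    unaligned: Dict[str, Set[int]] = field(default_factory=dict)
    defined_columns: Set[int] = field(default_factory=set)
    disulfide_columns: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValidationError(f"ragged MSA rows: widths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungap(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "")

    def pos_to_col(self, row_id: str) -> Dict[int, int]:
        """1-based residue position -> column, for one row."""
        out = {}
        pos = 0
        for col, ch in enumerate(self.rows[row_id]):
            if ch != GAP:
                pos += 1
                out[pos] = col
        return out

    def col_to_pos(self, row_id: str) -> Dict[int, int]:
        return {c: p for p, c in self.pos_to_col(row_id).items()}

    def region_of_column(self, col: int) -> Optional[str]:
        for name, mask in self.region_masks.items():
            if col in mask:
                return name
        return None


# ---------------------------------------------------------------------------
# BW numbering


def assign_bw_numbers(entry: ReceptorEntry) -> Dict[int, str]:
    """Label every TM residue with its Ballesteros-Weinstein number.

    The x.50 anchor of helix h is the most conserved residue; residues at
    anchor +/- k get h.(50 +/- k), within the helix bounds.
    """
    if not entry.tm_segments:
        raise ValidationError(f"{entry.id}: no TM segments annotated")
    labels: Dict[int, str] = {}
    for seg in entry.tm_segments:
        if seg.anchor is None:
            raise ValidationError(
                f"{entry.id}: TM{seg.helix_index} lacks an x.50 anchor"
            )
        for pos in seg.positions():
            labels[pos] = f"{seg.helix_index}.{50 + (pos - seg.anchor)}"
    return labels


# ---------------------------------------------------------------------------
# family superposition


def superpose_family(entries: Sequence[ReceptorEntry]) -> Dict[str, np.ndarray]:
    """Superpose every entry onto the first, pairing TM CA atoms by their
    offset from each helix anchor. Returns id -> transformed (L, 3) CA array."""
    ref = entries[0]
    out: Dict[str, np.ndarray] = {}
    ca_idx = ATOM_INDEX["CA"]
    for entry in entries:
        ca = entry.coords.array[:, ca_idx]
        if entry is ref:
            out[entry.id] = ca.copy()
            continue
        P, Q = [], []
        for h in range(1, 8):
            s_e, s_r = entry.segment(h), ref.segment(h)
            if s_e is None or s_r is None or s_e.anchor is None or s_r.anchor is None:
                continue
            lo = max(s_e.start - s_e.anchor, s_r.start - s_r.anchor)
            hi = min(s_e.end - s_e.anchor, s_r.end - s_r.anchor)
            for k in range(lo, hi + 1):
                P.append(ca[s_e.anchor + k - 1])
                Q.append(ref.coords.array[s_r.anchor + k - 1, ca_idx])
        if len(P) < 3:
            raise AlignmentError(f"{entry.id}: too few TM anchors to superpose")
        R, t, _ = kabsch(np.array(P), np.array(Q))
        out[entry.id] = apply_rigid(ca, R, t)
    return out


def _transformed_cb_vectors(entries, transforms) -> Dict[str, np.ndarray]:
    """Unit CA->CB vectors per entry, rotated into the common frame."""
    out = {}
    for entry in entries:
        arr = entry.coords.array
        ca = arr[:, ATOM_INDEX["CA"]]
        cb = arr[:, ATOM_INDEX["CB"]].copy()
        missing = ~np.isfinite(cb).all(axis=1)
        if missing.any():
            from .geometry import ideal_cb_array

            cb[missing] = ideal_cb_array(
                arr[missing, ATOM_INDEX["N"]], ca[missing],
                arr[missing, ATOM_INDEX["C"]],
            )
        v = cb - ca
        # recover the family rotation from the CA transform
        tca = transforms[entry.id]
        if len(ca) >= 3:
            R, _, _ = kabsch(ca, tca)
            v = v @ R.T
        n = np.linalg.norm(v, axis=1, keepdims=True)
        out[entry.id] = v / np.where(n == 0, 1.0, n)
    return out


# ---------------------------------------------------------------------------
# column blocks (internal build representation)


@dataclass
class _Block:
    """An ordered run of columns for one region. Each column maps row id ->
    1-based residue position."""

    cols: List[Dict[str, int]] = field(default_factory=list)
    anchors: Dict[str, int] = field(default_factory=dict)  # label -> col index
    unaligned: Set[Tuple[str, int]] = field(default_factory=set)  # (row, col idx)
    defined_idx: Set[int] = field(default_factory=set)


def _consensus(points: List[np.ndarray]) -> np.ndarray:
    return np.median(np.stack(points), axis=0)


def _extend_helix(rows, segs, tca, direction: int, cfg: AlignConfig):
    """Greedy outward extension of one helix alignment from its anchors.

    A row whose CA deviates more than ``d_max`` from the column consensus
    receives a gap (deletion) unless its *next* residue matches the current
    consensus, in which case the deviating residue is emitted as a
    row-exclusive bulge column (insertion).
    """
    ptr = {r: segs[r].anchor + direction for r in rows}
    stall = {r: 0 for r in rows}
    cols: List[Dict[str, int]] = []

    def in_range(r):
        return segs[r].start <= ptr[r] <= segs[r].end

    while True:
        active = [r for r in rows if in_range(r)]
        if not active:
            break
        cand = {r: tca[r][ptr[r] - 1] for r in active}
        cons = _consensus(list(cand.values()))
        dev = {r: float(np.linalg.norm(cand[r] - cons)) for r in active}
        ok = [r for r in active if dev[r] <= cfg.d_max or stall[r] > 3]
        if len(ok) == len(active):
            cols.append({r: ptr[r] for r in active})
            for r in active:
                ptr[r] += direction
                stall[r] = 0
            continue
        # insertion test: the deviating row's next residue fits this column
        inserted = False
        for r in sorted(set(active) - set(ok)):
            nxt = ptr[r] + direction
            if segs[r].start <= nxt <= segs[r].end:
                if np.linalg.norm(tca[r][nxt - 1] - cons) <= cfg.d_max:
                    cols.append({r: ptr[r]})  # bulge column, gaps elsewhere
                    ptr[r] = nxt
                    stall[r] = 0
                    inserted = True
                    break
        if inserted:
            continue
        if not ok:  # nothing fits the consensus: fall back to offset pairing
            log.debug("helix extension: no row within d_max; forcing column")
            cols.append({r: ptr[r] for r in active})
            for r in active:
                ptr[r] += direction
            continue
        cols.append({r: ptr[r] for r in ok})
        for r in ok:
            ptr[r] += direction
            stall[r] = 0
        for r in set(active) - set(ok):
            stall[r] += 1  # deletion: this row waits for a later column
    return cols


def _tm_blocks(entries, tca, cfg) -> Dict[int, _Block]:
    blocks: Dict[int, _Block] = {}
    for h in range(1, 8):
        rows = []
        segs = {}
        for e in entries:
            seg = e.segment(h)
            if seg is None or seg.anchor is None:
                log.warning("%s lacks TM%d; gapping that helix", e.id, h)
                continue
            rows.append(e.id)
            segs[e.id] = seg
        if not rows:
            raise AlignmentError(f"no entry provides TM{h}")
        right = _extend_helix(rows, segs, tca, +1, cfg)
        left = _extend_helix(rows, segs, tca, -1, cfg)
        block = _Block()
        block.cols = left[::-1] + [{r: segs[r].anchor for r in rows}] + right
        block.anchors[f"{h}.50"] = len(left)
        block.defined_idx = set(range(len(block.cols)))
        blocks[h] = block
    return blocks


# ---------------------------------------------------------------------------
# loop alignment


def _loop_positions(entries) -> Dict[str, Dict[str, List[int]]]:
    """region -> row id -> loop residue positions (includes termini)."""
    out: Dict[str, Dict[str, List[int]]] = {}
    for e in entries:
        regions = regions_from_segments(e)
        for name in LOOP_REGIONS + ("Nterm", "Cterm"):
            out.setdefault(name, {})[e.id] = regions[name]
    return out


def _compatible(p_ca, q_ca, p_vec, q_vec, cfg) -> bool:
    if np.linalg.norm(p_ca - q_ca) > cfg.d_loop:
        return False
    cosang = float(np.clip(np.dot(p_vec, q_vec), -1.0, 1.0))
    return np.degrees(np.arccos(cosang)) <= cfg.theta_max


def _align_row_to_reference(row_pos, ref_pos, row_id, ref_id, tca, vecs,
                            dscys_row, dscys_ref, cfg):
    """Monotone assignment of one row's loop residues to reference columns.

    Needleman-Wunsch over (row residues) x (reference columns) where only
    structurally compatible pairs may match; disulfide cysteines are
    force-matched (they outrank the vector criterion). Returns a dict
    row position -> reference column index.
    """
    m, n = len(row_pos), len(ref_pos)
    if m == 0 or n == 0:
        return {}
    MATCH, DS, GAP_PEN, NEG = 5.0, 1000.0, -0.01, -1e9
    score = np.full((m, n), NEG)
    for i, p in enumerate(row_pos):
        for j, q in enumerate(ref_pos):
            if p in dscys_row and q in dscys_ref:
                score[i, j] = DS
            elif _compatible(
                tca[row_id][p - 1], tca[ref_id][q - 1],
                vecs[row_id][p - 1], vecs[ref_id][q - 1], cfg,
            ):
                # distance-weighted so register ties resolve toward the
                # geometrically closer pairing
                d = np.linalg.norm(tca[row_id][p - 1] - tca[ref_id][q - 1])
                score[i, j] = MATCH + (1.0 - d / cfg.d_loop)
    F = np.zeros((m + 1, n + 1))
    F[1:, 0] = GAP_PEN * np.arange(1, m + 1)
    F[0, 1:] = GAP_PEN * np.arange(1, n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            F[i, j] = max(
                F[i - 1, j - 1] + score[i - 1, j - 1],
                F[i - 1, j] + GAP_PEN,
                F[i, j - 1] + GAP_PEN,
            )
    out = {}
    i, j = m, n
    while i > 0 and j > 0:
        if np.isclose(F[i, j], F[i - 1, j - 1] + score[i - 1, j - 1]) and \
                score[i - 1, j - 1] > NEG / 2:
            out[row_pos[i - 1]] = j - 1
            i, j = i - 1, j - 1
        elif np.isclose(F[i, j], F[i - 1, j] + GAP_PEN):
            i -= 1
        else:
            j -= 1
    return out


def _ss_runs(ss: str, positions: Sequence[int], offset_map,
             classes: str = "H") -> List[List[int]]:
    """Maximal runs (length >= 3) of identical SS class among ``positions``.

    Only helical runs are protected by default: extended/coil loop
    geometry tolerates register shifts that the vector criterion already
    arbitrates, while breaking up a helical element would leave an
    unbuildable fragment junction.
    """
    runs, cur, cur_cls = [], [], None
    for p in positions:
        cls = ss[offset_map[p]] if offset_map[p] < len(ss) else "L"
        if cls in classes and cls == cur_cls and cur and p == cur[-1] + 1:
            cur.append(p)
        else:
            if len(cur) >= 3:
                runs.append(cur)
            cur, cur_cls = ([p], cls) if cls in classes else ([], None)
    if len(cur) >= 3:
        runs.append(cur)
    return runs


def _enforce_ss_intact(assign, runs):
    """Keep only the longest contiguous (residue- and column-contiguous)
    streak of each secondary-structure run; unassign the rest so the
    element stays gap-free once parked."""
    for run in runs:
        streaks, cur = [], []
        for p in run:
            if p in assign and cur and assign[p] == assign[cur[-1]] + 1 and p == cur[-1] + 1:
                cur.append(p)
            elif p in assign:
                if cur:
                    streaks.append(cur)
                cur = [p]
        if cur:
            streaks.append(cur)
        if not streaks:
            continue
        best = max(streaks, key=len)
        for s in streaks:
            if s is not best:
                for p in s:
                    del assign[p]


def _loop_block(region, loop_pos, entries_by_id, tca, vecs, cfg) -> _Block:
    """Structure-align one loop region across all rows."""
    lengths = {r: len(pos) for r, pos in loop_pos.items()}
    nonempty = [r for r, n in lengths.items() if n > 0]
    block = _Block()
    if not nonempty:
        return block
    # reference row: the medoid — the loop most structurally compatible
    # with all the others (a loop with an atypical conformation would
    # poison the register for every row). Residues the star alignment
    # leaves over are clustered afterwards, so columns absent from the
    # reference can still form.
    ss = {r: classify_ss(tca[r]) for r in loop_pos}
    ds_cys = {
        r: {p for pair in entries_by_id[r].disulfides for p in pair
            if p in set(loop_pos[r])}
        for r in loop_pos
    }
    if len(nonempty) > 2:
        totals = {}
        for r in nonempty:
            n_match = 0
            for r2 in nonempty:
                if r2 == r:
                    continue
                n_match += len(_align_row_to_reference(
                    loop_pos[r2], loop_pos[r], r2, r, tca, vecs,
                    ds_cys[r2], ds_cys[r], cfg,
                ))
            totals[r] = n_match
        ref_id = min(nonempty,
                     key=lambda r: (-totals[r], list(loop_pos).index(r)))
    else:
        ref_id = min(nonempty,
                     key=lambda r: (-lengths[r], list(loop_pos).index(r)))
    ref_pos = loop_pos[ref_id]

    assignments: Dict[str, Dict[int, int]] = {
        ref_id: {p: j for j, p in enumerate(ref_pos)}
    }
    for r in nonempty:
        if r == ref_id:
            continue
        assign = _align_row_to_reference(
            loop_pos[r], ref_pos, r, ref_id, tca, vecs,
            ds_cys[r], ds_cys[ref_id], cfg,
        )
        offset_map = {p: p - 1 for p in loop_pos[r]}
        _enforce_ss_intact(assign, _ss_runs(ss[r], loop_pos[r], offset_map))
        assignments[r] = assign

    # consensus rescue: a residue the star alignment left out joins a
    # reference column when it is within d_loop of the column's median CA
    # and within theta_max of its mean CA->CB vector, order permitting
    for _ in range(2):
        for r in nonempty:
            if r == ref_id:
                continue
            assign = assignments[r]
            for idx_p, p in enumerate(loop_pos[r]):
                if p in assign:
                    continue
                prev_j = max(
                    (assign[q] for q in loop_pos[r][:idx_p] if q in assign),
                    default=-1,
                )
                next_j = min(
                    (assign[q] for q in loop_pos[r][idx_p + 1:] if q in assign),
                    default=len(ref_pos),
                )
                best_j, best_d = None, None
                for j in range(prev_j + 1, next_j):
                    members = [(ref_id, ref_pos[j])] + [
                        (r2, q) for r2 in nonempty if r2 != ref_id
                        for q, jj in assignments[r2].items() if jj == j
                    ]
                    cons_ca = np.median(
                        np.stack([tca[r2][q - 1] for r2, q in members]), axis=0
                    )
                    d = float(np.linalg.norm(tca[r][p - 1] - cons_ca))
                    if d > cfg.d_loop:
                        continue
                    mean_vec = np.mean(
                        np.stack([vecs[r2][q - 1] for r2, q in members]), axis=0
                    )
                    nv = np.linalg.norm(mean_vec)
                    if nv > 1e-9:
                        cosang = float(np.clip(
                            np.dot(vecs[r][p - 1], mean_vec / nv), -1.0, 1.0
                        ))
                        if np.degrees(np.arccos(cosang)) > cfg.theta_max:
                            continue
                    if best_d is None or d < best_d:
                        best_j, best_d = j, d
                if best_j is not None:
                    assign[p] = best_j

    # slots: unassigned runs parked (initially) right after their left anchor
    slot_runs: Dict[int, Dict[str, List[int]]] = {}
    for r in nonempty:
        assign = assignments[r]
        run: List[int] = []
        left_col = -1  # slot index = left reference column + 1 (or 0 at start)
        for p in loop_pos[r]:
            if p in assign:
                if run:
                    slot_runs.setdefault(left_col + 1, {})[r] = run
                    run = []
                left_col = assign[p]
            else:
                run.append(p)
        if run:
            slot_runs.setdefault(left_col + 1, {})[r] = run

    def mark_defined(idx: int, col: Dict[str, int]) -> None:
        if any(p in ds_cys[r] for r, p in col.items()):
            block.defined_idx.add(idx)
            return
        for r, p in col.items():
            if ss[r][p - 1] in "HE":
                block.defined_idx.add(idx)
                break

    n_ref = len(ref_pos)
    for j in range(n_ref + 1):
        runs = slot_runs.get(j, {})
        if runs:
            # residues the star alignment left over: greedily grow columns
            # from mutually compatible front residues, preserving order
            order = [r for r in nonempty if r in runs]
            ptr = {r: 0 for r in order}
            while any(ptr[r] < len(runs[r]) for r in order):
                seed_row = next(r for r in order if ptr[r] < len(runs[r]))
                members = {seed_row: runs[seed_row][ptr[seed_row]]}
                for r in order:
                    if r == seed_row or ptr[r] >= len(runs[r]):
                        continue
                    p = runs[r][ptr[r]]
                    if all(
                        _compatible(
                            tca[r][p - 1], tca[r2][p2 - 1],
                            vecs[r][p - 1], vecs[r2][p2 - 1], cfg,
                        )
                        for r2, p2 in members.items()
                    ):
                        members[r] = p
                idx = len(block.cols)
                block.cols.append(dict(members))
                for r in members:
                    ptr[r] += 1
                if len(members) < 2:
                    block.unaligned.add((seed_row, idx))
                else:
                    mark_defined(idx, members)
        if j < n_ref:
            col = {ref_id: ref_pos[j]}
            for r in nonempty:
                if r == ref_id:
                    continue
                for p, jj in assignments[r].items():
                    if jj == j:
                        col[r] = p
            idx = len(block.cols)
            block.cols.append(col)
            mark_defined(idx, col)
    return block


def _terminus_block(region, pos_by_row) -> _Block:
    """Stack termini without claiming alignment: Nterm right-aligned against
    TM1, Cterm left-aligned after TM7; every cell is 'unaligned'."""
    block = _Block()
    width = max((len(v) for v in pos_by_row.values()), default=0)
    for k in range(width):
        col: Dict[str, int] = {}
        for r, positions in pos_by_row.items():
            n = len(positions)
            if region == "Nterm":
                i = k - (width - n)
            else:
                i = k
            if 0 <= i < n:
                col[r] = positions[i]
                block.unaligned.add((r, len(block.cols)))
        block.cols.append(col)
    return block


# ---------------------------------------------------------------------------
# assembly


def _assemble(entries, region_blocks: List[Tuple[str, _Block]]) -> MSA:
    seqs = {e.id: e.sequence for e in entries}
    ids = [e.id for e in entries]
    rows = {r: [] for r in ids}
    masks: Dict[str, Set[int]] = {}
    anchors: Dict[str, int] = {}
    unaligned: Dict[str, Set[int]] = {r: set() for r in ids}
    defined: Set[int] = set()
    poscol: Dict[str, Dict[int, int]] = {r: {} for r in ids}
    gcol = 0
    for region, block in region_blocks:
        mask = masks.setdefault(region, set())
        for idx, col in enumerate(block.cols):
            for r in ids:
                if r in col:
                    rows[r].append(seqs[r][col[r] - 1])
                    poscol[r][col[r]] = gcol
                else:
                    rows[r].append(GAP)
            mask.add(gcol)
            if idx in block.defined_idx:
                defined.add(gcol)
            gcol += 1
        for label, idx in block.anchors.items():
            anchors[label] = gcol - len(block.cols) + idx
        for r, idx in block.unaligned:
            unaligned[r].add(gcol - len(block.cols) + idx)

    msa = MSA(
        rows={r: "".join(v) for r, v in rows.items()},
        region_masks={k: v for k, v in masks.items() if v},
        anchor_columns=anchors,
        unaligned=unaligned,
        defined_columns=defined,
    )
    # canonical disulfide columns by majority vote over annotated entries
    votes: Dict[str, List[Tuple[int, int]]] = {}
    for e in entries:
        regions = regions_from_segments(e)
        rof = {}
        for name, positions in regions.items():
            for p in positions:
                rof[p] = name
        for a, b in e.disulfides:
            if a not in poscol[e.id] or b not in poscol[e.id]:
                continue  # partial (TM-only / loops-only) alignment
            ra, rb = rof.get(a), rof.get(b)
            if {ra, rb} == {"TM3", "ECL2"}:
                if ra != "TM3":
                    a, b = b, a
                votes.setdefault("TM3-ECL2", []).append(
                    (poscol[e.id][a], poscol[e.id][b])
                )
            elif ra == "ECL3" and rb == "ECL3":
                votes.setdefault("ECL3", []).append(
                    (poscol[e.id][min(a, b)], poscol[e.id][max(a, b)])
                )
    for kind, pairs in votes.items():
        vals, counts = np.unique(np.array(pairs), axis=0, return_counts=True)
        best = vals[int(np.argmax(counts))]
        msa.disulfide_columns[kind] = (int(best[0]), int(best[1]))
        msa.defined_columns.update(msa.disulfide_columns[kind])
    return msa


def _check_inputs(entries):
    if len(entries) < 2:
        raise ValidationError("need at least two entries to align")
    for e in entries:
        if e.coords is None:
            raise ValidationError(f"{e.id}: coordinates required")
        if not e.tm_segments or len(e.tm_segments) != 7:
            raise ValidationError(f"{e.id}: 7 TM segments required")


def align_tm_segments(entries: Sequence[ReceptorEntry],
                      config: Optional[AlignConfig] = None) -> MSA:
    """Anchor-based structural alignment of the seven TM helices only.

    Returns a partial MSA whose rows cover just the TM residues (the loop
    and termini columns are added by the other builders; use
    :func:`build_template_msa` for the full alignment).
    """
    cfg = config or AlignConfig()
    _check_inputs(entries)
    tca = superpose_family(entries)
    blocks = _tm_blocks(entries, tca, cfg)
    return _assemble(entries, [(f"TM{h}", blocks[h]) for h in range(1, 8)])


def align_loops_structural(entries: Sequence[ReceptorEntry],
                           config: Optional[AlignConfig] = None) -> MSA:
    """CA-proximity + CA->CB-vector alignment of the six loops only."""
    cfg = config or AlignConfig()
    _check_inputs(entries)
    tca = superpose_family(entries)
    vecs = _transformed_cb_vectors(entries, tca)
    loop_pos = _loop_positions(entries)
    by_id = {e.id: e for e in entries}
    pairs = [
        (name, _loop_block(name, loop_pos[name], by_id, tca, vecs, cfg))
        for name in LOOP_REGIONS
    ]
    return _assemble(entries, pairs)


def build_template_msa(entries: Sequence[ReceptorEntry],
                       config: Optional[AlignConfig] = None) -> MSA:
    """Full blended template MSA: termini, helices and loops in sequence
    order, unalignable residues parked adjacent to defined structure."""
    cfg = config or AlignConfig()
    _check_inputs(entries)
    tca = superpose_family(entries)
    vecs = _transformed_cb_vectors(entries, tca)
    tm = _tm_blocks(entries, tca, cfg)
    loop_pos = _loop_positions(entries)
    by_id = {e.id: e for e in entries}
    region_blocks: List[Tuple[str, _Block]] = []
    for region in REGION_ORDER:
        if region in ("Nterm", "Cterm"):
            region_blocks.append((region, _terminus_block(region, loop_pos[region])))
        elif region.startswith("TM"):
            region_blocks.append((region, tm[int(region[2:])]))
        else:
            region_blocks.append(
                (region, _loop_block(region, loop_pos[region], by_id, tca, vecs, cfg))
            )
    msa = _assemble(entries, region_blocks)
    return place_unalignable_residues(msa)


# ---------------------------------------------------------------------------
# parking unalignable residues


def place_unalignable_residues(msa: MSA) -> MSA:
    """Shift each run of unaligned residues within its gap span so it abuts
    the side whose nearest defined-structure column is closest (ties toward
    the N-terminus). Idempotent; gap blocks stay contiguous."""
    defined = sorted(msa.defined_columns)
    darr = np.array(defined) if defined else None
    new_rows = {}
    new_unaligned = {}
    for rid, row in msa.rows.items():
        chars = list(row)
        una = set(msa.unaligned.get(rid, set()))
        if not una:
            new_rows[rid] = row
            new_unaligned[rid] = una
            continue
        # maximal runs of columns holding unaligned residues of this row
        cols = sorted(c for c in una if chars[c] != GAP)
        runs: List[List[int]] = []
        for c in cols:
            if runs and c == runs[-1][-1] + 1:
                runs[-1].append(c)
            else:
                runs.append([c])
        out_una: Set[int] = set()
        for run in runs:
            s = run[0]
            e = run[-1]
            # enclosing gap span: extend over gaps and this run only
            lo = s
            while lo - 1 >= 0 and chars[lo - 1] == GAP:
                lo -= 1
            hi = e
            while hi + 1 < len(chars) and chars[hi + 1] == GAP:
                hi += 1
            if darr is not None:
                left_cand = darr[darr < s]
                right_cand = darr[darr > e]
                ldist = s - left_cand[-1] if len(left_cand) else np.inf
                rdist = right_cand[0] - e if len(right_cand) else np.inf
            else:
                ldist, rdist = 0, np.inf
            body = [chars[c] for c in run]
            for c in range(lo, hi + 1):
                chars[c] = GAP
            if ldist <= rdist:
                dest = range(lo, lo + len(body))
            else:
                dest = range(hi - len(body) + 1, hi + 1)
            for c, ch in zip(dest, body):
                chars[c] = ch
                out_una.add(c)
        new_rows[rid] = "".join(chars)
        new_unaligned[rid] = out_una
    return MSA(
        rows=new_rows,
        region_masks=msa.region_masks,
        anchor_columns=msa.anchor_columns,
        unaligned=new_unaligned,
        defined_columns=msa.defined_columns,
        disulfide_columns=msa.disulfide_columns,
    )


# ---------------------------------------------------------------------------
# pairwise identity


def default_identity_mask(msa: MSA, termini_pad: int = 10) -> Set[int]:
    """TM bundle + loops, plus the ``termini_pad`` terminal columns nearest
    TM1/TM7; long termini beyond that are excluded."""
    mask: Set[int] = set()
    for name in TM_REGIONS + LOOP_REGIONS:
        mask |= msa.region_masks.get(name, set())
    nterm = sorted(msa.region_masks.get("Nterm", set()))
    cterm = sorted(msa.region_masks.get("Cterm", set()))
    mask |= set(nterm[-termini_pad:]) if termini_pad else set()
    mask |= set(cterm[:termini_pad]) if termini_pad else set()
    return mask


def pairwise_identity(msa: MSA, region_mask: Optional[Set[int]] = None,
                      config: Optional[AlignConfig] = None) -> pd.DataFrame:
    """Percent identity matrix over masked columns.

    identity(i, j) = 100 * matches / columns where both rows are non-gap
    (within the mask). Zero shared columns gives NaN. The matrix is
    symmetric with diagonal 100.
    """
    cfg = config or AlignConfig()
    if region_mask is None:
        region_mask = default_identity_mask(msa, cfg.termini_pad)
    ids = list(msa.rows)
    cols = sorted(region_mask)
    arr = np.array([[msa.rows[r][c] for c in cols] for r in ids])
    gap = arr == GAP
    n = len(ids)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 100.0
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            denom = int(both.sum()) if cfg.identity_denominator == "shared" else len(cols)
            if denom == 0 or not both.any():
                continue
            matches = int((arr[i][both] == arr[j][both]).sum())
            out[i, j] = out[j, i] = 100.0 * matches / denom
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# recovery metric (fixture evaluation)


def column_cell_sets(msa: MSA, mask: Optional[Set[int]] = None):
    """Frozenset of (row, residue position) per column with >= 2 residues."""
    p2c = {r: msa.col_to_pos(r) for r in msa.rows}
    out = []
    for c in range(msa.width):
        if mask is not None and c not in mask:
            continue
        cells = frozenset(
            (r, p2c[r][c]) for r in msa.rows if c in p2c[r]
        )
        if len(cells) >= 2:
            out.append(cells)
    return out


def recovered_column_fraction(built: MSA, truth: MSA,
                              truth_mask: Optional[Set[int]] = None,
                              row_subset: Optional[Set[str]] = None) -> float:
    """Fraction of ground-truth columns reproduced exactly by the built MSA.

    A truth column counts as recovered when the same set of (row, residue)
    cells appears as one column of the built alignment. ``row_subset``
    restricts both sides to the given rows (used when the built MSA lacks
    some truth rows, e.g. the target)."""
    def restrict(cells):
        if row_subset is None:
            return cells
        return frozenset((r, p) for r, p in cells if r in row_subset)

    built_sets = {restrict(s) for s in column_cell_sets(built)}
    truth_sets = [restrict(s) for s in column_cell_sets(truth, truth_mask)]
    truth_sets = [s for s in truth_sets if len(s) >= 2]
    if not truth_sets:
        raise ValidationError("no ground-truth columns to compare")
    hit = sum(1 for s in truth_sets if s in built_sets)
    return hit / len(truth_sets)


# ---------------------------------------------------------------------------
# target alignment into the template MSA


class _ECol:
    """One editable MSA column: residue chars per row plus metadata."""

    __slots__ = ("cells", "region", "defined", "anchor", "unaligned_rows", "ds")

    def __init__(self, cells=None, region=None, defined=False, anchor=None,
                 unaligned_rows=None, ds=None):
        self.cells = cells or {}
        self.region = region
        self.defined = defined
        self.anchor = anchor
        self.unaligned_rows = unaligned_rows or set()
        self.ds = ds or []  # [(kind, side)] disulfide tags


class _EditableMSA:
    def __init__(self, cols, order):
        self.cols = cols
        self.order = order  # row ids in output order

    @classmethod
    def from_msa(cls, msa: MSA) -> "_EditableMSA":
        cols = []
        ds_by_col = {}
        for kind, (a, b) in msa.disulfide_columns.items():
            ds_by_col.setdefault(a, []).append((kind, 0))
            ds_by_col.setdefault(b, []).append((kind, 1))
        anchors_by_col = {c: lbl for lbl, c in msa.anchor_columns.items()}
        for c in range(msa.width):
            cells = {r: msa.rows[r][c] for r in msa.rows if msa.rows[r][c] != GAP}
            cols.append(
                _ECol(
                    cells=cells,
                    region=msa.region_of_column(c),
                    defined=c in msa.defined_columns,
                    anchor=anchors_by_col.get(c),
                    unaligned_rows={
                        r for r in msa.rows if c in msa.unaligned.get(r, set())
                    },
                    ds=ds_by_col.get(c, []),
                )
            )
        return cls(cols, list(msa.rows))

    def region_cols(self, region):
        return [c for c in self.cols if c.region == region]

    def row_cols(self, row_id, region=None):
        return [
            c for c in self.cols
            if row_id in c.cells and (region is None or c.region == region)
        ]

    def to_msa(self) -> MSA:
        rows = {r: [] for r in self.order}
        masks: Dict[str, Set[int]] = {}
        anchors: Dict[str, int] = {}
        unaligned: Dict[str, Set[int]] = {r: set() for r in self.order}
        defined: Set[int] = set()
        ds_cols: Dict[str, List[int]] = {}
        for i, col in enumerate(self.cols):
            for r in self.order:
                rows[r].append(col.cells.get(r, GAP))
            if col.region:
                masks.setdefault(col.region, set()).add(i)
            if col.anchor:
                anchors[col.anchor] = i
            if col.defined:
                defined.add(i)
            for r in col.unaligned_rows:
                if r in unaligned:
                    unaligned[r].add(i)
            for kind, side in col.ds:
                ds_cols.setdefault(kind, [None, None])[side] = i
        return MSA(
            rows={r: "".join(v) for r, v in rows.items()},
            region_masks=masks,
            anchor_columns=anchors,
            unaligned=unaligned,
            defined_columns=defined,
            disulfide_columns={
                k: tuple(v) for k, v in ds_cols.items() if None not in v
            },
        )


def _segments_from_span(span) -> List:
    from .io_formats import SpanRecord, TMSegment, topology_to_span

    if isinstance(span, str):
        span = topology_to_span(span)
    if not isinstance(span, SpanRecord):
        raise ValidationError("tm_predictions must be a SpanRecord or topology string")
    if len(span.segments) != 7:
        raise AlignmentError(
            f"need 7 predicted membrane segments, got {len(span.segments)}"
        )
    return [
        TMSegment(helix_index=i + 1, start=s, end=e)
        for i, (s, e) in enumerate(span.segments)
    ]


def _motif_regex(pattern: str) -> str:
    return "".join("." if ch == "x" else re.escape(ch) for ch in pattern)


def _find_tm_anchor(sequence: str, seg, cfg: AlignConfig) -> int:
    """Anchor a helix lacking its x.50 annotation via its fallback motif,
    choosing the occurrence nearest the expected (mid-helix) position."""
    entry_cfg = cfg.tm_motifs.get(seg.helix_index)
    if entry_cfg is None:
        raise AlignmentError(
            f"TM{seg.helix_index}: no x.50 anchor and no fallback motif"
        )
    pattern, offset = entry_cfg
    slack = 5
    lo = max(0, seg.start - 1 - slack)
    hi = min(len(sequence), seg.end + slack)
    expected = (seg.start + seg.end) // 2
    hits = [
        m.start() + lo + 1 + offset
        for m in re.finditer(f"(?={_motif_regex(pattern)})", sequence[lo:hi])
    ]
    hits = [h for h in hits if seg.start <= h <= seg.end]
    if not hits:
        raise AlignmentError(
            f"TM{seg.helix_index}: neither x.50 anchor nor motif "
            f"{pattern!r} found"
        )
    return min(hits, key=lambda h: (abs(h - expected), h))


def _insert_cols(em: _EditableMSA, index: int, count: int, region: str):
    for _ in range(count):
        em.cols.insert(index, _ECol(region=region))


def _pack_split(em, tid, seq, residues, left_col, right_col, region,
                n_left=None, aligned=frozenset()):
    """Place ``residues`` between two boundary columns: the first ``n_left``
    immediately after ``left_col``, the rest immediately before
    ``right_col``; columns are inserted when the span is too narrow. Odd
    splits give the extra residue to the N-terminal half."""
    n = len(residues)
    if n == 0:
        return {}
    if n_left is None:
        n_left = (n + 1) // 2
    li = em.cols.index(left_col) if left_col is not None else -1
    ri = em.cols.index(right_col) if right_col is not None else len(em.cols)
    space = ri - li - 1
    if space < n:
        _insert_cols(em, li + 1, n - space, region)
        ri += n - space
    placed = {}
    for k in range(n_left):
        placed[residues[k]] = em.cols[li + 1 + k]
    for k in range(n - n_left):
        placed[residues[n_left + k]] = em.cols[ri - (n - n_left) + k]
    for pos, col in placed.items():
        col.cells[tid] = seq[pos - 1]
        if pos not in aligned:
            col.unaligned_rows.add(tid)
    return placed


def _find_motif_window(em, region, pattern):
    """Best run of consecutive region columns matching a loop motif."""
    cols = em.region_cols(region)
    k = len(pattern)
    best, best_score = None, 0
    col_index = {id(c): i for i, c in enumerate(em.cols)}
    for i in range(len(cols) - k + 1):
        window = cols[i : i + k]
        idxs = [col_index[id(c)] for c in window]
        if idxs != list(range(idxs[0], idxs[0] + k)):
            continue  # not consecutive in the full alignment
        rows = set.intersection(*(set(c.cells) for c in window)) if window else set()
        score = 0
        for r in rows:
            if all(
                pattern[j] == "x" or window[j].cells[r] == pattern[j]
                for j in range(k)
            ):
                score += 1
        if score > best_score:
            best, best_score = window, score
    return best


def align_target_to_msa(target: ReceptorEntry, msa: MSA,
                        tm_predictions=None,
                        config: Optional[AlignConfig] = None):
    """Thread a structure-less target sequence into the template MSA.

    Rules, in order: (1) whenever a region's sequence matches a template
    row's region sequence exactly, that row's placement is copied (family
    propagation); (2) TM helices are anchored at their x.50 columns (motif
    fallback) and extended along the best-matching template row; (3)
    ECL1/ICL1/ICL2 are anchored on loop motifs when available; (4) ICL3 is
    split at its midpoint and the halves adjoined to TM5/TM6; (5) ECL2 is
    split at the conserved cysteine, which is pinned to the TM3-disulfide
    column, each sub-loop halved toward its nearest fixed feature; (6)
    ECL3 cysteines are pinned to disulfide columns when both sides have
    them; (7) all remaining loops and the termini are half-split/packed
    against their flanking helices. Odd splits favour the N-terminal half.

    Returns ``(row, extended_msa)`` where ``row`` is the target's gapped
    row and ``extended_msa`` contains all template rows plus the target
    (columns may have been inserted where the target is longer than the
    template alignment).
    """
    cfg = config or AlignConfig()
    tid = target.id
    if tid in msa.rows:
        raise ValidationError(f"target id {tid!r} already present in MSA")
    seq = target.sequence
    segs = target.tm_segments or _segments_from_span(tm_predictions)
    if len(segs) != 7:
        raise AlignmentError(f"{tid}: need 7 TM segments, got {len(segs)}")
    from .io_formats import TMSegment

    full_segs = []
    for seg in segs:
        anchor = seg.anchor or _find_tm_anchor(seq, seg, cfg)
        full_segs.append(TMSegment(seg.helix_index, seg.start, seg.end, anchor))
    probe = ReceptorEntry(id=tid, sequence=seq, tm_segments=full_segs,
                          disulfides=list(target.disulfides),
                          disulfide_free=target.disulfide_free)
    regions = regions_from_segments(probe)
    region_pos = {p: name for name, pos in regions.items() for p in pos}

    em = _EditableMSA.from_msa(msa)
    placed: Dict[int, _ECol] = {}

    def copy_family_placement(region) -> bool:
        tseq = "".join(seq[p - 1] for p in regions[region])
        for rid in em.order:
            rcols = em.row_cols(rid, region)
            if "".join(c.cells[rid] for c in rcols) == tseq and tseq:
                for p, col in zip(regions[region], rcols):
                    placed[p] = col
                    col.cells[tid] = seq[p - 1]
                    if rid in col.unaligned_rows:
                        col.unaligned_rows.add(tid)
                return True
        return False

    # --- TM helices -------------------------------------------------------
    spill: Dict[str, List[int]] = {name: [] for name in regions}
    for seg in full_segs:
        h = seg.helix_index
        region = f"TM{h}"
        if copy_family_placement(region):
            continue
        anchor_label = f"{h}.50"
        region_cols_h = em.region_cols(region)
        anchor_col = next((c for c in region_cols_h if c.anchor == anchor_label), None)
        if anchor_col is None:
            raise AlignmentError(f"MSA lacks anchor column {anchor_label}")
        # guide row: best sequence agreement when paired by anchor offset
        best_rid, best_score = None, -1.0
        for rid in em.order:
            rcols = [c for c in region_cols_h if rid in c.cells]
            if anchor_col not in rcols:
                continue
            ia = rcols.index(anchor_col)
            hits = tries = 0
            for k in range(seg.start - seg.anchor, seg.end - seg.anchor + 1):
                j = ia + k
                if 0 <= j < len(rcols):
                    tries += 1
                    if rcols[j].cells[rid] == seq[seg.anchor + k - 1]:
                        hits += 1
            score = hits / tries if tries else 0.0
            if score > best_score:
                best_rid, best_score = rid, score
        rcols = [c for c in region_cols_h if best_rid in c.cells]
        ia = rcols.index(anchor_col)
        for k in range(seg.start - seg.anchor, seg.end - seg.anchor + 1):
            pos = seg.anchor + k
            j = ia + k
            if 0 <= j < len(rcols):
                placed[pos] = rcols[j]
                rcols[j].cells[tid] = seq[pos - 1]
            elif j < 0:  # helix longer than the guide: spill to the flanks
                spill[LOOP_AFTER_TM.get(h - 1, "Nterm")].append(pos)
            else:
                spill[LOOP_AFTER_TM.get(h, "Cterm")].append(pos)

    def flank_cols(region):
        """Boundary columns: last placed column of the preceding TM and
        first placed column of the following TM (None at the termini)."""
        idx = REGION_ORDER.index(region)
        left = right = None
        if idx > 0:
            prev_tm = REGION_ORDER[idx - 1]
            pcols = [placed[p] for p in regions[prev_tm] if p in placed]
            left = pcols[-1] if pcols else None
        if idx < len(REGION_ORDER) - 1:
            nxt_tm = REGION_ORDER[idx + 1]
            ncols = [placed[p] for p in regions[nxt_tm] if p in placed]
            right = ncols[0] if ncols else None
        return left, right

    def loop_residues(region):
        return sorted(set(regions[region]) | set(spill[region]))

    def target_ds_pair(kind):
        for a, b in probe.disulfides:
            ra, rb = region_pos.get(a), region_pos.get(b)
            if kind == "TM3-ECL2" and {ra, rb} == {"TM3", "ECL2"}:
                return (a, b) if rb == "ECL2" else (b, a)
            if kind == "ECL3" and ra == rb == "ECL3":
                return (min(a, b), max(a, b))
        return None

    def ds_col(kind, side):
        for c in em.cols:
            if (kind, side) in c.ds:
                return c
        return None

    # --- loops ------------------------------------------------------------
    for region in LOOP_REGIONS:
        residues = loop_residues(region)
        if not residues:
            continue
        if not spill[region] and copy_family_placement(region):
            continue
        left, right = flank_cols(region)
        if region == "ECL2" and not probe.disulfide_free:
            pair = target_ds_pair("TM3-ECL2")
            ccol = ds_col("TM3-ECL2", 1)
            if pair and ccol is not None and left is not None and right is not None:
                li, ci, ri = (em.cols.index(x) for x in (left, ccol, right))
                if li < ci < ri:
                    cys = pair[1]
                    ccol.cells[tid] = seq[cys - 1]
                    placed[cys] = ccol
                    sub_a = [p for p in residues if p < cys]
                    sub_b = [p for p in residues if p > cys]
                    placed.update(_pack_split(em, tid, seq, sub_a, left, ccol, region))
                    placed.update(_pack_split(em, tid, seq, sub_b, ccol, right, region))
                    continue
        if region == "ECL3":
            pair = target_ds_pair("ECL3")
            ca_col, cb_col = ds_col("ECL3", 0), ds_col("ECL3", 1)
            if pair and ca_col is not None and cb_col is not None:
                a, b = pair
                for cys, col in ((a, ca_col), (b, cb_col)):
                    col.cells[tid] = seq[cys - 1]
                    placed[cys] = col
                placed.update(_pack_split(
                    em, tid, seq, [p for p in residues if p < a], left, ca_col, region))
                placed.update(_pack_split(
                    em, tid, seq, [p for p in residues if a < p < b], ca_col, cb_col, region))
                placed.update(_pack_split(
                    em, tid, seq, [p for p in residues if p > b], cb_col, right, region))
                continue
        pattern = cfg.loop_motifs.get(region)
        if pattern:
            tseq = "".join(seq[p - 1] for p in residues)
            m_hits = [m.start() for m in re.finditer(f"(?={_motif_regex(pattern)})", tseq)]
            window = _find_motif_window(em, region, pattern)
            if m_hits and window:
                center = (len(tseq) - len(pattern)) / 2
                start = min(m_hits, key=lambda h: (abs(h - center), h))
                motif_pos = residues[start : start + len(pattern)]
                for p, col in zip(motif_pos, window):
                    col.cells[tid] = seq[p - 1]
                    placed[p] = col
                placed.update(_pack_split(
                    em, tid, seq, residues[:start], left, window[0], region))
                placed.update(_pack_split(
                    em, tid, seq, residues[start + len(pattern):], window[-1],
                    right, region))
                continue
        # default: half-split, halves adjoined to the flanking helices
        placed.update(_pack_split(em, tid, seq, residues, left, right, region))

    # --- termini ----------------------------------------------------------
    nt = loop_residues("Nterm")
    if nt:
        _, right = flank_cols("Nterm")
        placed.update(_pack_split(em, tid, seq, nt, None, right, "Nterm", n_left=0))
    ct = loop_residues("Cterm")
    if ct:
        left, _ = flank_cols("Cterm")
        placed.update(_pack_split(em, tid, seq, ct, left, None, "Cterm",
                                  n_left=len(ct)))

    em.order = em.order + [tid]
    out = em.to_msa()
    return out.rows[tid], out
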