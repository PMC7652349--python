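"""Idealized 7TM receptor families with known ground truth.

The generator builds a geometrically ideal seven-helix bundle (1.5 A rise,
100 deg twist, helix axes on a circle with alternating up/down direction,
loops as smooth arcs, one planted TM3-ECL2 disulfide) and evolves families
from it by point mutation, loop indels and coordinate noise, logging every
edit so the ground-truth alignment and reference coordinates are exact.
These families stand in for a crystallographic benchmark: they exercise
every pipeline stage without downloads, but they are idealized — no
side-chain packing, uniform amino-acid usage, and smooth loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ValidationError
from .geometry import (
    ATOM_INDEX,
    CA_CA,
    arc_points,
    backbone_from_ca,
    ideal_helix_ca,
)
from .io_formats import (
    LOOP_AFTER_TM,
    LOOP_REGIONS,
    BackboneCoords,
    ReceptorEntry,
    TMSegment,
    regions_from_segments,
)
from .msa_builder import GAP, MSA

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_LOOP_LENGTHS = {
    "ICL1": 5, "ECL1": 6, "ICL2": 5, "ECL2": 13, "ICL3": 9, "ECL3": 6,
}


# ---------------------------------------------------------------------------
# ideal bundle


def _helix_frame(angle: float, radius: float, up: bool, n_res: int,
                 rise: float = 1.5):
    """CA trace of one ideal helix placed on the bundle circle."""
    ca = ideal_helix_ca(n_res, rise=rise)
    ca = ca - ca.mean(axis=0)  # center on the axis midpoint
    if not up:  # proper rotation (180 deg about x) keeps right-handedness
        ca = ca @ np.diag([1.0, -1.0, -1.0])
    axis_xy = np.array([np.cos(angle), np.sin(angle), 0.0])
    return ca + radius * axis_xy


def make_ideal_bundle(helix_length: int = 22,
                      loop_lengths: Optional[Dict[str, int]] = None,
                      nterm: int = 4, cterm: int = 4,
                      bundle_radius: float = 11.0,
                      seed: int = 0,
                      entry_id: str = "ancestor") -> ReceptorEntry:
    """Build an idealized 7TM receptor with ideal alpha-helix geometry.

    Helix axes sit on a circle of ``bundle_radius`` A with alternating
    up/down direction (TM1 runs extracellular -> intracellular); loops are
    smooth circular arcs with ~3.8 A CA spacing; x.50 anchors sit at helix
    midpoints; a TM3-ECL2 disulfide is planted with ECL2 routed past the
    TM3 extracellular end so the bond is geometrically satisfied. The
    sequence is random but carries the class-A anchor motifs (DRY, CWxP,
    NPxxY, and the xWxxG ECL1 motif).
    """
    loops = dict(DEFAULT_LOOP_LENGTHS)
    if loop_lengths:
        loops.update(loop_lengths)
    for name, n in loops.items():
        if n < 1:
            raise ValidationError(f"{name}: loop length must be positive")
    rng = np.random.default_rng(seed)

    angles = [2.0 * np.pi * k / 7.0 for k in range(7)]
    helix_ca = [
        _helix_frame(angles[k], bundle_radius, up=(k % 2 == 1), n_res=helix_length)
        for k in range(7)
    ]

    def outward(point):
        v = np.array([point[0], point[1], 0.0])
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

    # layout: Nterm TM1 ICL1 TM2 ECL1 TM3 ICL2 TM4 ECL2 TM5 ICL3 TM6 ECL3 TM7 Cterm
    segs: List[TMSegment] = []
    ca_parts: List[np.ndarray] = []
    pos = 1

    # N terminus: straight run descending onto the TM1 extracellular end
    u_n = (outward(helix_ca[0][0]) + np.array([0, 0, 1.2]))
    u_n /= np.linalg.norm(u_n)
    nterm_ca = np.array(
        [helix_ca[0][0] + (nterm - k) * CA_CA * u_n for k in range(nterm)]
    ).reshape(nterm, 3) if nterm else np.empty((0, 3))
    ca_parts.append(nterm_ca)
    pos += nterm

    tm3_cys_pos = None
    ecl2_cys_pos = None
    tm3_cys_ca = None

    for h in range(1, 8):
        start = pos
        ca_parts.append(helix_ca[h - 1])
        pos += helix_length
        anchor = start + helix_length // 2
        segs.append(TMSegment(h, start, pos - 1, anchor))
        if h == 3:
            tm3_cys_pos = start + 2  # near the extracellular end of TM3
            tm3_cys_ca = helix_ca[2][2]
        if h == 7:
            break
        loop_name = LOOP_AFTER_TM[h]
        n_loop = loops[loop_name]
        p_start = helix_ca[h - 1][-1]
        p_end = helix_ca[h][0]
        mid = (p_start + p_end) / 2.0
        sign_z = 1.0 if mid[2] > 0 else -1.0
        bulge = outward(mid) + np.array([0.0, 0.0, 0.6 * sign_z])
        if loop_name == "ECL2":
            # route past the TM3 extracellular end so the conserved
            # disulfide with TM3 is geometrically satisfied
            way = tm3_cys_ca + 5.0 * outward(tm3_cys_ca) + np.array([0, 0, 2.0])
            d_a = np.linalg.norm(way - p_start)
            d_b = np.linalg.norm(p_end - way)
            n_interior = n_loop - 1
            n_a = int(round(n_interior * d_a / (d_a + d_b)))
            n_a = min(max(n_a, max(1, int(np.ceil(d_a / CA_CA)) - 1)),
                      n_interior - max(1, int(np.ceil(d_b / CA_CA)) - 1))
            n_b = n_interior - n_a
            arc_a = arc_points(p_start, way, n_a, bulge)
            arc_b = arc_points(way, p_end, n_b, bulge)
            loop_ca = np.vstack([arc_a, way[None, :], arc_b])
            ecl2_cys_pos = pos + n_a
        else:
            loop_ca = arc_points(p_start, p_end, n_loop, bulge)
        ca_parts.append(loop_ca)
        pos += n_loop

    # C terminus: TM7 runs top->bottom, so extend below and outward
    u_c = (outward(helix_ca[6][-1]) + np.array([0, 0, -1.2]))
    u_c /= np.linalg.norm(u_c)
    cterm_ca = np.array(
        [helix_ca[6][-1] + (k + 1) * CA_CA * u_c for k in range(cterm)]
    ).reshape(cterm, 3) if cterm else np.empty((0, 3))
    ca_parts.append(cterm_ca)

    ca = np.vstack([p for p in ca_parts if len(p)])
    length = len(ca)

    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    # plant anchors' motifs and the conserved disulfide cysteines
    by_helix = {s.helix_index: s for s in segs}
    for helix, pattern, offset in ((3, "DRY", 1), (6, "CWLP", 3), (7, "NPLLY", 1)):
        a = by_helix[helix].anchor
        start = a - offset
        for i, ch in enumerate(pattern):
            seq[start - 1 + i] = ch
    # ECL1 motif xWxxG
    ecl1_start = by_helix[2].end + 1
    seq[ecl1_start] = "W"          # second loop residue
    seq[ecl1_start + 3] = "G"
    seq[tm3_cys_pos - 1] = "C"
    seq[ecl2_cys_pos - 1] = "C"
    # avoid spurious cysteines in loops/termini (they would confuse the
    # cysteine-anchored loop rules); TM cysteines such as C6.47 are fine
    tm_positions = {p for seg in segs for p in seg.positions()}
    for i, ch in enumerate(seq):
        if ch == "C" and (i + 1) not in (tm3_cys_pos, ecl2_cys_pos) \
                and (i + 1) not in tm_positions:
            seq[i] = "S"

    # relax loop/termini residues so no nonadjacent CA pair sits below
    # 4.2 A (real CA traces do not), keeping helices and the disulfide
    # cysteines fixed and virtual bonds at ~3.8 A
    fixed = np.zeros(length, dtype=bool)
    for seg in segs:
        fixed[seg.start - 1 : seg.end] = True
    fixed[tm3_cys_pos - 1] = True
    fixed[ecl2_cys_pos - 1] = True
    ca = _declash(ca, fixed)

    entry = ReceptorEntry(
        id=entry_id,
        sequence="".join(seq),
        coords=BackboneCoords(backbone_from_ca(ca)),
        tm_segments=segs,
        disulfides=[(tm3_cys_pos, ecl2_cys_pos)],
        class_label="A",
    )
    return entry


def _declash(ca: np.ndarray, fixed: np.ndarray, min_sep: float = 4.2,
             bond: float = CA_CA, n_iter: int = 200) -> np.ndarray:
    """Position-based relaxation: push nonadjacent CA pairs apart to
    ``min_sep`` while keeping consecutive CA distances near ``bond``.
    Residues flagged ``fixed`` never move."""
    ca = ca.copy()
    L = len(ca)
    iu, ju = np.triu_indices(L, k=2)
    for _ in range(n_iter):
        moved = False
        d = np.linalg.norm(ca[iu] - ca[ju], axis=1)
        close = np.nonzero(d < min_sep)[0]
        for k in close:
            a, b = iu[k], ju[k]
            if fixed[a] and fixed[b]:
                continue
            v = ca[b] - ca[a]
            nv = np.linalg.norm(v)
            v = v / nv if nv > 1e-9 else np.array([1.0, 0.0, 0.0])
            push = 0.5 * (min_sep - nv) + 0.05
            if fixed[a]:
                ca[b] += push * 2 * v
            elif fixed[b]:
                ca[a] -= push * 2 * v
            else:
                ca[a] -= push * v
                ca[b] += push * v
            moved = True
        # bond projection
        for _ in range(4):
            steps = ca[1:] - ca[:-1]
            dist = np.linalg.norm(steps, axis=1)
            for i in np.nonzero(np.abs(dist - bond) > 0.05)[0]:
                corr = (dist[i] - bond) * steps[i] / max(dist[i], 1e-9)
                if fixed[i] and fixed[i + 1]:
                    continue
                if fixed[i]:
                    ca[i + 1] -= corr
                elif fixed[i + 1]:
                    ca[i] += corr
                else:
                    ca[i] += 0.5 * corr
                    ca[i + 1] -= 0.5 * corr
        if not moved:
            break
    return ca


# ---------------------------------------------------------------------------
# family evolution


@dataclass
class FixtureFamily:
    """A synthetic receptor family with exact ground truth.

    ``maps[id]`` lists, for each member residue (1-based order), the
    ancestor position it descends from, or None for an insertion.
    """

    ancestor: ReceptorEntry
    members: List[ReceptorEntry]
    maps: Dict[str, List[Optional[int]]]
    truth_alignment: MSA
    params: Dict = field(default_factory=dict)
    edits: Dict[str, List[str]] = field(default_factory=dict)

    def member(self, member_id: str) -> ReceptorEntry:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def displacement(self, member_id: str) -> Dict[int, float]:
        """Per-residue CA displacement (A) from the ancestor position each
        residue descends from; insertions are omitted."""
        m = self.member(member_id)
        anc = self.ancestor.coords
        out = {}
        for i, src in enumerate(self.maps[member_id], start=1):
            if src is not None:
                out[i] = float(np.linalg.norm(m.coords.ca(i) - anc.ca(src)))
        return out

    def structure_conserved_columns(self, max_disp: float = 1.5,
                                    max_angle: float = 30.0) -> Set[int]:
        """Truth columns whose every resident residue kept its ancestral
        geometry: CA within ``max_disp`` A *and* CA->CB orientation within
        ``max_angle`` degrees of the ancestor.

        Both criteria matter because structural loop alignment tests both
        proximity and side-chain direction; a residue flanking an
        insertion bulge barely moves but reorients, and is genuinely no
        longer structurally conserved.
        """
        def unit_cb(entry, pos):
            v = entry.coords.cb(pos) - entry.coords.ca(pos)
            return v / max(np.linalg.norm(v), 1e-12)

        disp = {m.id: self.displacement(m.id) for m in self.members}
        p2c = {m.id: self.truth_alignment.pos_to_col(m.id) for m in self.members}
        bad: Set[int] = set()
        for m in self.members:
            src = self.maps[m.id]
            for pos, col in p2c[m.id].items():
                d = disp[m.id].get(pos)
                if d is None or d > max_disp:
                    bad.add(col)
                    continue
                cosang = float(np.clip(np.dot(
                    unit_cb(m, pos), unit_cb(self.ancestor, src[pos - 1])
                ), -1.0, 1.0))
                if np.degrees(np.arccos(cosang)) > max_angle:
                    bad.add(col)
        return set(range(self.truth_alignment.width)) - bad

    def realized_identity(self) -> "np.ndarray":
        from .msa_builder import pairwise_identity

        return pairwise_identity(self.truth_alignment)


def mutation_rate_for_identity(identity_pct: float) -> float:
    """Per-residue mutation rate so two independently mutated descendants
    share ~``identity_pct`` percent identity (uniform 19-letter choice)."""
    q = identity_pct / 100.0
    a = 20.0 / 19.0
    inner = 1.0 - a * (1.0 - q)
    if inner < 0:
        raise ValidationError(f"identity {identity_pct}% unreachable by mutation")
    return float((1.0 - np.sqrt(inner)) / a)


def _regenerate_loop(ca: List[np.ndarray], idxs: List[int],
                     left: np.ndarray, right: np.ndarray,
                     fixed: Dict[int, np.ndarray]) -> None:
    """Re-lay a loop's CA positions as arcs between its (fixed) flanks,
    keeping any pinned residues (e.g. a disulfide cysteine) in place."""
    center = np.mean([left, right], axis=0)
    sign_z = 1.0 if center[2] > 0 else -1.0
    v = np.array([center[0], center[1], 0.0])
    nv = np.linalg.norm(v)
    bulge = (v / nv if nv > 1e-9 else np.array([1.0, 0, 0])) + \
        np.array([0.0, 0.0, 0.6 * sign_z])
    pins = sorted(k for k in range(len(idxs)) if idxs[k] in fixed)
    bounds = [(-1, left)] + [(k, fixed[idxs[k]]) for k in pins] + [(len(idxs), right)]
    for (k0, p0), (k1, p1) in zip(bounds, bounds[1:]):
        n_int = k1 - k0 - 1
        if n_int <= 0:
            continue
        pts = arc_points(p0, p1, n_int, bulge)
        for j in range(n_int):
            ca[idxs[k0 + 1 + j]] = pts[j]


def evolve_family(ancestor: ReceptorEntry, n_members: int = 10,
                  mutation_rate: float = 0.45, indel_rate: float = 0.3,
                  noise_sigma: float = 0.3, seed: int = 0,
                  tm_indels: bool = False,
                  protected: Optional[Set[int]] = None) -> FixtureFamily:
    """Derive a family of receptors from an ideal ancestor.

    Each member gets: at most one single-residue indel per loop (with
    probability ``indel_rate`` per loop; loops only unless ``tm_indels``),
    point mutations at ``mutation_rate`` per unprotected residue (uniform
    over the 19 alternatives), and per-residue Gaussian coordinate noise
    of RMS ``noise_sigma`` A applied rigidly to each residue's atoms.
    Anchors and disulfide cysteines are protected from mutation. Indel
    loops are re-laid as smooth arcs (pinned at disulfide cysteines), so
    their residues move; the ground-truth bookkeeping records every edit
    and actual displacement.
    """
    if not 0 <= mutation_rate <= 1 or not 0 <= indel_rate <= 1:
        raise ValidationError("rates must lie in [0, 1]")
    if ancestor.coords is None or not ancestor.tm_segments:
        raise ValidationError("ancestor needs coordinates and TM segments")
    base_protect = {s.anchor for s in ancestor.tm_segments}
    base_protect |= {p for pair in ancestor.disulfides for p in pair}
    base_protect |= _motif_positions(ancestor)
    if protected:
        base_protect |= set(protected)
    regions = regions_from_segments(ancestor)
    anc_seq = ancestor.sequence
    anc_ca = ancestor.coords.array[:, ATOM_INDEX["CA"]]
    ds_set = {p for pair in ancestor.disulfides for p in pair}

    members: List[ReceptorEntry] = []
    maps: Dict[str, List[Optional[int]]] = {}
    edits: Dict[str, List[str]] = {}

    for j in range(n_members):
        rng = np.random.default_rng([seed, j])
        mid = f"m{j:02d}"
        log_j: List[str] = []
        # start from the ancestor: lists indexed by current member order
        seq = list(anc_seq)
        src: List[Optional[int]] = list(range(1, len(anc_seq) + 1))
        ca = [anc_ca[i].copy() for i in range(len(anc_seq))]

        # --- indels (loops; optionally TM bulges) -------------------------
        # Indels perturb the structure locally, as in real homologs: an
        # insertion bulges outward between its neighbours, a deletion
        # re-lays only a small window around the excised residue; the rest
        # of the loop keeps its exact ancestral geometry.
        indel_regions = list(LOOP_REGIONS) + (
            [f"TM{h}" for h in range(1, 8)] if tm_indels else []
        )
        for region in indel_regions:
            if rng.random() >= indel_rate:
                continue
            anc_positions = regions[region]
            cand = [
                p for p in anc_positions[1:-1] if p not in ds_set
            ] if len(anc_positions) > 2 else []
            if not cand:
                continue
            at = int(rng.choice(cand))
            k = next(i for i, s in enumerate(src) if s == at)
            region_set = set(anc_positions)
            # helices admit bulge insertions only: a deletion would demand
            # a register shift along the helix axis, not a local repair
            if (rng.random() < 0.5 and len(anc_positions) > 3
                    and not region.startswith("TM")):
                del seq[k], src[k], ca[k]
                log_j.append(f"del {region} anc:{at}")
                _heal_deletion(ca, src, k, region_set, ds_set)
            else:
                seq.insert(k, str(rng.choice(list(AMINO_ACIDS))))
                src.insert(k, None)
                u = ca[k] - ca[k - 1]
                u = u / max(np.linalg.norm(u), 1e-9)
                out = np.array([ca[k][0], ca[k][1], 0.0])
                out = out - np.dot(out, u) * u  # bulge perpendicular to chain
                if np.linalg.norm(out) < 1e-6:
                    out = np.cross(u, np.array([0.0, 0.0, 1.0]))
                out = out / max(np.linalg.norm(out), 1e-9)
                ca.insert(k, (ca[k - 1] + ca[k]) / 2.0 + 2.8 * out)
                log_j.append(f"ins {region} after anc:{at - 1}")

        # --- point mutations ---------------------------------------------
        n_mut = 0
        for i in range(len(seq)):
            if src[i] is None or src[i] in base_protect:
                continue
            if rng.random() < mutation_rate:
                alternatives = [a for a in AMINO_ACIDS if a != seq[i]]
                seq[i] = str(rng.choice(alternatives))
                n_mut += 1
        if n_mut:
            log_j.append(f"{n_mut} point mutations")

        # --- backbone + chain-correlated coordinate noise -----------------
        # White noise on consecutive residues would strain every virtual
        # bond, which no real structural ensemble does; instead a Gaussian
        # random field smoothed along the chain (kernel sd ~2 residues)
        # displaces the backbone in a locally rigid way, rescaled so the
        # per-residue RMS displacement equals noise_sigma.
        ca_arr = np.array(ca)
        if noise_sigma > 0:
            white = rng.normal(0.0, 1.0, size=(len(seq), 3))
            k = np.arange(-6, 7)
            kernel = np.exp(-0.5 * (k / 2.0) ** 2)
            kernel /= kernel.sum()
            smooth = np.stack(
                [np.convolve(white[:, ax], kernel, mode="same")
                 for ax in range(3)], axis=1,
            )
            rms = np.sqrt((smooth ** 2).sum(axis=1).mean())
            ca_arr = ca_arr + smooth * (noise_sigma / max(rms, 1e-9))
            # re-project virtual bonds so connectivity survives any sigma
            for _ in range(8):
                steps = ca_arr[1:] - ca_arr[:-1]
                dist = np.linalg.norm(steps, axis=1, keepdims=True)
                corr = (dist - 3.8) * steps / np.where(dist == 0, 1, dist)
                ca_arr[:-1] += 0.5 * corr
                ca_arr[1:] -= 0.5 * corr
        bb = backbone_from_ca(ca_arr)

        # --- remap annotations --------------------------------------------
        anc_to_mem = {s: i + 1 for i, s in enumerate(src) if s is not None}
        new_segs = []
        for s in ancestor.tm_segments:
            positions = [anc_to_mem[p] for p in s.positions() if p in anc_to_mem]
            new_segs.append(
                TMSegment(s.helix_index, min(positions), max(positions),
                          anc_to_mem[s.anchor])
            )
        new_ds = [
            (anc_to_mem[a], anc_to_mem[b]) for a, b in ancestor.disulfides
            if a in anc_to_mem and b in anc_to_mem
        ]
        members.append(
            ReceptorEntry(
                id=mid, sequence="".join(seq),
                coords=BackboneCoords(bb),
                tm_segments=new_segs, disulfides=new_ds,
                class_label=ancestor.class_label,
            )
        )
        maps[mid] = src
        edits[mid] = log_j

    truth = _truth_alignment(ancestor, members, maps, regions)
    return FixtureFamily(
        ancestor=ancestor, members=members, maps=maps,
        truth_alignment=truth,
        params=dict(n_members=n_members, mutation_rate=mutation_rate,
                    indel_rate=indel_rate, noise_sigma=noise_sigma,
                    seed=seed, tm_indels=tm_indels),
        edits=edits,
    )


def _motif_positions(ancestor: ReceptorEntry) -> Set[int]:
    """Positions of the class-defining motifs (DRY, CWxP, NPxxY, xWxxG),
    located near their expected anchors; protected from mutation because
    these motifs are what 'conserved' means in this family."""
    import re as _re

    from .config import DEFAULT_LOOP_MOTIFS, DEFAULT_TM_MOTIFS

    out: Set[int] = set()
    seq = ancestor.sequence
    for seg in ancestor.tm_segments or []:
        entry = DEFAULT_TM_MOTIFS.get(seg.helix_index)
        if entry is None or seg.anchor is None:
            continue
        pattern, offset = entry
        start = seg.anchor - offset  # 1-based motif start
        window = seq[start - 1 : start - 1 + len(pattern)]
        if len(window) == len(pattern) and all(
            p == "x" or p == w for p, w in zip(pattern, window)
        ):
            out |= set(range(start, start + len(pattern)))
    regions = regions_from_segments(ancestor) if ancestor.tm_segments else {}
    for region, pattern in DEFAULT_LOOP_MOTIFS.items():
        positions = regions.get(region, [])
        if not positions:
            continue
        text = "".join(seq[p - 1] for p in positions)
        regex = "".join("." if ch == "x" else _re.escape(ch) for ch in pattern)
        m = _re.search(regex, text)
        if m:
            out |= {positions[i] for i in range(m.start(), m.end())
                    if pattern[i - m.start()] != "x"}
    return out


def _heal_deletion(ca: List[np.ndarray], src: List[Optional[int]], k: int,
                   region_set: Set[int], ds_set: Set[int],
                   reach: int = 2) -> None:
    """Close the geometric gap a deletion leaves by re-laying a small
    window (up to ``reach`` residues each side) as a fresh arc between
    fixed flanks. Residues outside the window, disulfide cysteines and
    everything beyond the region stay exactly in place."""
    def movable(i):
        return (0 <= i < len(src) and src[i] is not None
                and src[i] in region_set and src[i] not in ds_set)

    lo = k  # first movable index of the window
    while lo - 1 >= 0 and k - (lo - 1) <= reach and movable(lo - 1):
        lo -= 1
    hi = k - 1  # last movable index (k-th residue was just removed)
    while hi + 1 < len(src) and (hi + 1) - k < reach and movable(hi + 1):
        hi += 1
    n_window = hi - lo + 1
    if n_window < 1 or lo - 1 < 0 or hi + 1 >= len(src):
        return
    left, right = ca[lo - 1], ca[hi + 1]
    center = (left + right) / 2.0
    v = np.array([center[0], center[1], 0.0])
    nv = np.linalg.norm(v)
    bulge = (v / nv if nv > 1e-9 else np.array([1.0, 0.0, 0.0])) + \
        np.array([0.0, 0.0, 0.6 * (1.0 if center[2] > 0 else -1.0)])
    try:
        pts = arc_points(left, right, n_window, bulge)
    except ValidationError:
        # window too tight to respan: widen once, else leave the kink
        if reach < 4:
            _heal_deletion(ca, src, k, region_set, ds_set, reach=reach + 2)
        return
    for j in range(n_window):
        ca[lo + j] = pts[j]


def _loop_of(src, i, regions) -> Optional[str]:
    """Region of member residue i, using the nearest mapped neighbour for
    insertions."""
    lookup = {}
    for name, positions in regions.items():
        for p in positions:
            lookup[p] = name
    j = i
    while j >= 0 and src[j] is None:
        j -= 1
    if j >= 0 and src[j] is not None:
        return lookup.get(src[j])
    j = i
    while j < len(src) and src[j] is None:
        j += 1
    return lookup.get(src[j]) if j < len(src) else None


def _truth_alignment(ancestor, members, maps, regions) -> MSA:
    """Assemble the ground-truth MSA from the edit bookkeeping."""
    # column plan: each ancestor position is a column; member insertions get
    # private columns right after the ancestor position they follow
    L = len(ancestor.sequence)
    inserts: Dict[int, List[Tuple[str, int]]] = {}  # after-anchor -> [(mid, mempos)]
    for m in members:
        src = maps[m.id]
        last_anc = 0
        for i, s in enumerate(src):
            if s is None:
                inserts.setdefault(last_anc, []).append((m.id, i + 1))
            else:
                last_anc = s
    col_of_anc: Dict[int, int] = {}
    col_of_ins: Dict[Tuple[str, int], int] = {}
    col = 0
    for a in range(0, L + 1):
        if a >= 1:
            col_of_anc[a] = col
            col += 1
        for key in inserts.get(a, []):
            col_of_ins[key] = col
            col += 1
    width = col

    rows = {}
    unaligned: Dict[str, Set[int]] = {}
    for m in members:
        row = [GAP] * width
        src = maps[m.id]
        una = set()
        for i, s in enumerate(src):
            if s is None:
                c = col_of_ins[(m.id, i + 1)]
                una.add(c)
            else:
                c = col_of_anc[s]
            row[c] = m.sequence[i]
        rows[m.id] = "".join(row)
        unaligned[m.id] = una

    region_masks: Dict[str, Set[int]] = {}
    anc_region = {}
    for name, positions in regions.items():
        mask = {col_of_anc[p] for p in positions}
        region_masks[name] = mask
        for p in positions:
            anc_region[p] = name
    for (mid, mempos), c in col_of_ins.items():
        # insertion columns inherit the region of the preceding position
        src = maps[mid]
        j = mempos - 2
        while j >= 0 and src[j] is None:
            j -= 1
        name = anc_region.get(src[j]) if j >= 0 else "Nterm"
        if name:
            region_masks.setdefault(name, set()).add(c)

    anchors = {
        f"{s.helix_index}.50": col_of_anc[s.anchor]
        for s in ancestor.tm_segments
    }
    msa = MSA(rows=rows, region_masks=region_masks, anchor_columns=anchors,
              unaligned=unaligned)
    tm3, ecl2 = ancestor.disulfides[0]
    msa.disulfide_columns["TM3-ECL2"] = (col_of_anc[tm3], col_of_anc[ecl2])
    msa.defined_columns = set().union(
        *(region_masks[f"TM{h}"] for h in range(1, 8))
    ) | {col_of_anc[tm3], col_of_anc[ecl2]}
    return msa


# ---------------------------------------------------------------------------
# special-purpose fixtures


def make_region_specialists(seed: int = 0, n_templates: int = 5,
                            mutation_rate: float = 0.3,
                            shift: float = 2.5,
                            bad_window: int = 22) -> FixtureFamily:
    """Templates that are each *inaccurate* in one distinct region.

    The chain is cut into ``n_templates`` contiguous chunks; template k
    has a ``bad_window``-residue window centered in chunk k rigidly
    displaced by ``shift`` A (tapered at the edges so the chain stays
    connected) and is accurate elsewhere. Every region is thus correct in
    all but one template, and recombination can beat every individual
    template. The window is kept small enough for one template-segment
    swap to span it.
    """
    ancestor = make_ideal_bundle(seed=seed)
    fam = evolve_family(
        ancestor, n_members=n_templates, mutation_rate=mutation_rate,
        indel_rate=0.0, noise_sigma=0.15, seed=seed,
    )
    L = len(ancestor.sequence)
    bounds = np.linspace(0, L, n_templates + 1).astype(int)
    rng = np.random.default_rng([seed, 7919])
    taper = 3  # residues ramping 0 -> full shift at each window edge
    for k, m in enumerate(fam.members):
        clo, chi = int(bounds[k]), int(bounds[k + 1])
        mid = (clo + chi) // 2
        lo = max(clo, mid - bad_window // 2)
        hi = min(chi, lo + bad_window)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for i in range(lo, hi):
            ramp = min(1.0, (i - lo + 1) / taper, (hi - i) / taper)
            m.coords.array[i] += shift * ramp * direction
        fam.edits[m.id].append(
            f"rigid shift {shift} A on residues {lo + 1}-{hi}"
        )
        fam.params.setdefault("bad_windows", {})[m.id] = (lo + 1, hi)
    return fam


def truth_msa_with_target(family: FixtureFamily,
                          target_id: str = "tgt") -> MSA:
    """The family's ground-truth alignment extended with a target row.

    The target is the (unmutated) ancestor sequence, placed in the
    columns of its ancestor positions. Used to exercise threading and
    hybridization in isolation from the alignment stage.
    """
    truth = family.truth_alignment
    L = len(family.ancestor.sequence)
    # ancestor-position columns: reconstruct from any member's map
    col_of_anc: Dict[int, int] = {}
    for m in family.members:
        p2c = truth.pos_to_col(m.id)
        for pos, src in enumerate(family.maps[m.id], start=1):
            if src is not None and src not in col_of_anc:
                col_of_anc[src] = p2c[pos]
    if len(col_of_anc) < L:
        raise ValidationError(
            "not every ancestor position survives in some member; cannot "
            "place the target row"
        )
    row = [GAP] * truth.width
    for a in range(1, L + 1):
        row[col_of_anc[a]] = family.ancestor.sequence[a - 1]
    rows = dict(truth.rows)
    rows[target_id] = "".join(row)
    return MSA(rows=rows, region_masks=truth.region_masks,
               anchor_columns=truth.anchor_columns,
               unaligned=dict(truth.unaligned),
               defined_columns=truth.defined_columns,
               disulfide_columns=truth.disulfide_columns)


def make_binned_family(seed: int = 0, per_bin: int = 5,
                       bins: Sequence[Tuple[int, int]] = ((30, 39), (25, 29),
                                                          (20, 24), (15, 19)),
                       sigmas: Sequence[float] = (0.6, 1.1, 1.7, 2.5)
                       ) -> Tuple[ReceptorEntry, Dict[str, "FixtureFamily"]]:
    """Template sets binned by identity to the ancestor, with coordinate
    accuracy degrading as identity drops (lower-identity structures are
    farther from the target's true fold, as in a real template pool).

    Returns (target, {bin label: family of per_bin templates}).
    """
    target = make_ideal_bundle(seed=seed)
    out: Dict[str, FixtureFamily] = {}
    for b, ((lo, hi), sigma) in enumerate(zip(bins, sigmas)):
        mid_ident = (lo + hi + 1) / 2.0
        # member identity to the (unmutated) target: 1 - (18/19) m = q
        m_rate = min(0.97, (1.0 - mid_ident / 100.0) * 19.0 / 18.0)
        fam = evolve_family(
            target, n_members=per_bin, mutation_rate=m_rate,
            indel_rate=0.0, noise_sigma=sigma, seed=seed * 101 + b,
        )
        for k, mem in enumerate(fam.members):
            mem.id = f"b{lo}_{hi}_m{k:02d}"
        fam.maps = {m.id: fam.maps[f"m{k:02d}"] for k, m in enumerate(fam.members)}
        fam.truth_alignment = _truth_alignment(
            target, fam.members, fam.maps, regions_from_segments(target)
        )
        out[f"{lo}-{hi}"] = fam
    return target, out
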