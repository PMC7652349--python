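"""Desk-scale multi-template hybridization.

Starting from the best partial thread, a Metropolis Monte Carlo search
recombines backbone segments from the other threads (after local
superposition on the flanking residues, so the global receptor frame is
preserved) with 3/9-residue fragment insertions, under a lightweight
composite score. The score is an explicit stand-in for a full molecular
energy function: its job is to keep the chain connected and clash-free,
respect predicted secondary structure and disulfide restraints, and pull
the model toward the consensus of the superposed templates. Parity with
any particular force field is a non-goal.

Score terms (CA/CB level):

==================  =====================================================
clash               sum over nonadjacent CA pairs of max(0, 4.0 - d)^2
chainbreak          sum of (d(CA_i, CA_i+1) - 3.8)^2
ss_agreement        fraction of residues whose CA-trace geometry class
                    disagrees with the predicted secondary structure
disulfide           sum over restraint pairs of max(0, d(CB, CB) - 5.0)^2
rg                  max(0, Rg - Rg_ref)^2
template_consensus  mean CA deviation from the per-residue median of the
                    superposed templates
==================  =====================================================

total = weighted sum; default weights 1, 10, 5, 10, 0.1, 50
(see :class:`helixforge.config.ScoreWeights` for the rationale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import HybridConfig, ScoreWeights
from .errors import ValidationError
from .geometry import (
    ATOM_INDEX,
    CA_CA,
    apply_rigid,
    backbone_from_ca,
    classify_ss,
    classify_ss_codes,
    ideal_helix_ca,
    kabsch,
    radius_of_gyration,
)
from .threader import ThreadedModel

log = logging.getLogger(__name__)

_CA = ATOM_INDEX["CA"]
_CB = ATOM_INDEX["CB"]


# ---------------------------------------------------------------------------
# annotations consumed by the score


@dataclass
class TargetAnnotations:
    """Everything the composite score needs to know about the target."""

    sequence: str
    predicted_ss: str  # per-residue H/E/L
    disulfides: List[Tuple[int, int]] = field(default_factory=list)
    rg_ref: float = 0.0
    #: per-residue median CA of the superposed templates (NaN where no
    #: template covers the residue)
    consensus_ca: Optional[np.ndarray] = None


def make_target_annotations(threads: Sequence[ThreadedModel],
                            predicted_ss: str,
                            disulfides: Optional[Sequence[Tuple[int, int]]] = None
                            ) -> TargetAnnotations:
    """Superpose all threads onto the first and derive the consensus CA
    positions and the reference radius of gyration."""
    if not threads:
        raise ValidationError("need at least one threaded model")
    L = len(threads[0].sequence)
    if len(predicted_ss) != L:
        raise ValidationError("predicted SS length must match target length")
    ref = threads[0]
    ref_pos = set(ref.coords.modeled_positions())
    stacks = np.full((len(threads), L, 3), np.nan)
    rgs = []
    for k, th in enumerate(threads):
        pos = th.coords.modeled_positions()
        ca = th.coords.ca_array(pos)
        mutual = sorted(ref_pos & set(pos))
        if th is not ref and len(mutual) >= 3:
            R, t, _ = kabsch(
                th.coords.ca_array(mutual), ref.coords.ca_array(mutual)
            )
            ca = apply_rigid(ca, R, t)
        for p, xyz in zip(pos, ca):
            stacks[k, p - 1] = xyz
        rgs.append(radius_of_gyration(ca))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        consensus = np.nanmedian(stacks, axis=0)
    return TargetAnnotations(
        sequence=threads[0].sequence,
        predicted_ss=predicted_ss,
        disulfides=list(disulfides or []),
        rg_ref=float(np.mean(rgs)) + 2.0,  # flat-bottom: only penalize expansion
        consensus_ca=consensus,
    )


# ---------------------------------------------------------------------------
# states and fragments


@dataclass
class HybridState:
    """A complete model under (or after) Monte Carlo assembly."""

    coords: np.ndarray  # (L, 5, 3), complete
    provenance: List[str]  # per-residue source: template id, fragment tag, 'interp'
    score_terms: Dict[str, float] = field(default_factory=dict)
    total: float = float("inf")
    model_index: int = -1
    #: accepted-score trace and running-best trace of the trajectory that
    #: produced this state (first entry = initial score)
    trace_accepted: List[float] = field(default_factory=list)
    trace_best: List[float] = field(default_factory=list)

    def copy(self) -> "HybridState":
        return HybridState(
            coords=self.coords.copy(), provenance=list(self.provenance),
            score_terms=dict(self.score_terms), total=self.total,
            model_index=self.model_index,
        )


class FragmentLibrary:
    """Backbone fragments per (position, length in {3, 9}).

    Fragments are harvested from template windows whose observed
    secondary structure matches the prediction; ideal-geometry fragments
    guarantee total coverage.
    """

    LENGTHS = (3, 9)

    def __init__(self, entries: Dict[Tuple[int, int], List[Tuple[str, np.ndarray]]]):
        self.entries = entries

    def fragments(self, position: int, length: int):
        return self.entries[(position, length)]

    def positions(self, length: int):
        return sorted(p for p, ln in self.entries if ln == length)


def _ideal_fragment(ss_window: str) -> np.ndarray:
    """Ideal-geometry backbone for a window, by majority predicted class."""
    n = len(ss_window)
    counts = {c: ss_window.count(c) for c in "HEL"}
    cls = max("HEL", key=lambda c: counts[c])
    if cls == "H":
        ca = ideal_helix_ca(n)
    elif cls == "E":
        ca = np.stack(
            [np.zeros(n), 0.45 * (-1.0) ** np.arange(n), 3.3 * np.arange(n)],
            axis=1,
        )
    else:  # gentle coil arc
        ang = np.radians(20.0) * np.arange(n)
        ca = np.stack(
            [8.0 * np.sin(ang), 8.0 * (1 - np.cos(ang)), 1.2 * np.arange(n)],
            axis=1,
        )
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1).mean()
        ca *= CA_CA / d
    return backbone_from_ca(ca)


def build_fragment_library(threads: Sequence[ThreadedModel],
                           predicted_ss: str) -> FragmentLibrary:
    """Harvest 3- and 9-mers from the threads; fall back to ideal geometry.

    A template window is accepted when at least two thirds of its
    CA-geometry classes agree with the predicted secondary structure of
    the target window, mirroring how fragment picking conditions on
    predicted SS. Every (position, length) is guaranteed at least one
    (ideal) fragment.
    """
    if not threads:
        raise ValidationError("need at least one thread")
    L = len(threads[0].sequence)
    if len(predicted_ss) != L:
        raise ValidationError("predicted SS length must match target length")
    thread_ss = {}
    for th in threads:
        ca = th.coords.array[:, _CA]
        filled = np.where(np.isfinite(ca).all(axis=1), 0, 1)
        safe = ca.copy()
        safe[filled == 1] = 0.0
        thread_ss[th.template_id] = classify_ss(safe)
    entries: Dict[Tuple[int, int], List[Tuple[str, np.ndarray]]] = {}
    for length in FragmentLibrary.LENGTHS:
        for p in range(1, L - length + 2):
            window = slice(p - 1, p - 1 + length)
            frags: List[Tuple[str, np.ndarray]] = []
            for th in threads:
                block = th.coords.array[window]
                if not np.isfinite(block[:, _CA]).all():
                    continue
                agree = sum(
                    a == b
                    for a, b in zip(thread_ss[th.template_id][window],
                                    predicted_ss[window])
                )
                if agree / length >= 2 / 3:
                    frags.append((f"{th.template_id}:{p}", block.copy()))
            frags.append((f"ideal:{p}", _ideal_fragment(predicted_ss[window])))
            entries[(p, length)] = frags
    return FragmentLibrary(entries)


# ---------------------------------------------------------------------------
# scoring


_PAIR_CACHE: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}


def _nonadjacent_pairs(L: int):
    if L not in _PAIR_CACHE:
        i, j = np.triu_indices(L, k=2)
        _PAIR_CACHE[L] = (i, j)
    return _PAIR_CACHE[L]


def score(state_or_coords, annotations: TargetAnnotations,
          weights: Optional[ScoreWeights] = None) -> Tuple[Dict[str, float], float]:
    """Composite score of a complete backbone; returns (terms, total)."""
    w = weights or ScoreWeights()
    coords = (
        state_or_coords.coords
        if isinstance(state_or_coords, HybridState) else state_or_coords
    )
    ca = coords[:, _CA]
    if not np.isfinite(ca).all():
        raise ValidationError("score requires complete coordinates")
    L = len(ca)
    i, j = _nonadjacent_pairs(L)
    diff = ca[i] - ca[j]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    viol = np.clip(4.0 - d, 0.0, None)
    clash = float((viol * viol).sum())

    step_v = ca[1:] - ca[:-1]
    step = np.sqrt(np.einsum("ij,ij->i", step_v, step_v))
    chainbreak = float(((step - CA_CA) ** 2).sum())

    pred = getattr(annotations, "_ss_codes", None)
    if pred is None or len(pred) != L:
        pred = np.array(list(annotations.predicted_ss), dtype="<U1")
        try:
            annotations._ss_codes = pred
        except AttributeError:
            pass
    obs = classify_ss_codes(ca)
    ss_term = float((obs != pred).mean())

    ds = 0.0
    for a, b in annotations.disulfides:
        cb_a = coords[a - 1, _CB]
        cb_b = coords[b - 1, _CB]
        gap = np.linalg.norm(cb_a - cb_b) - 5.0
        if gap > 0:
            ds += gap * gap
    rg_val = radius_of_gyration(ca)
    rg_term = max(0.0, rg_val - annotations.rg_ref) ** 2

    cons = annotations.consensus_ca
    if cons is not None:
        have = np.isfinite(cons).all(axis=1)
        consensus = float(
            np.linalg.norm(ca[have] - cons[have], axis=1).mean()
        ) if have.any() else 0.0
    else:
        consensus = 0.0

    terms = {
        "clash": clash,
        "chainbreak": chainbreak,
        "ss_agreement": ss_term,
        "disulfide": float(ds),
        "rg": float(rg_term),
        "template_consensus": consensus,
    }
    wd = w.as_dict()
    total = float(sum(wd[_W_KEY[k]] * v for k, v in terms.items()))
    return terms, total


_W_KEY = {
    "clash": "clash",
    "chainbreak": "chainbreak",
    "ss_agreement": "ss_agreement",
    "disulfide": "disulfide",
    "rg": "rg",
    "template_consensus": "template_consensus",
}


# ---------------------------------------------------------------------------
# initialization


def _interpolate_gaps(thread: ThreadedModel) -> Tuple[np.ndarray, List[str]]:
    """Complete a partial thread: unmodeled runs get linearly interpolated
    CA positions (termini extrapolate along the nearest chain direction)
    and a locally rebuilt pseudo-backbone."""
    L = len(thread.sequence)
    coords = thread.coords.array.copy()
    prov = [
        thread.template_id if thread.coords.is_modeled(p) else "interp"
        for p in range(1, L + 1)
    ]
    ca = coords[:, _CA].copy()
    modeled = np.isfinite(ca).all(axis=1)
    if not modeled.any():
        raise ValidationError("thread has no modeled residues")
    idx = np.nonzero(modeled)[0]
    # interior gaps: linear interpolation between flanking modeled residues
    for a, b in zip(idx, idx[1:]):
        if b - a > 1:
            for k in range(1, b - a):
                ca[a + k] = ca[a] + (ca[b] - ca[a]) * (k / (b - a))
    # termini: extend along the first/last chain step
    first, last = idx[0], idx[-1]
    if first > 0:
        step = ca[first] - ca[min(first + 1, last)]
        nstep = np.linalg.norm(step)
        u = step / nstep if nstep > 1e-9 else np.array([0.0, 0.0, 1.0])
        for k in range(1, first + 1):
            ca[first - k] = ca[first] + u * CA_CA * k
    if last < L - 1:
        step = ca[last] - ca[max(last - 1, first)]
        nstep = np.linalg.norm(step)
        u = step / nstep if nstep > 1e-9 else np.array([0.0, 0.0, 1.0])
        for k in range(1, L - last):
            ca[last + k] = ca[last] + u * CA_CA * k
    full_bb = backbone_from_ca(ca)
    out = np.where(np.isfinite(coords), coords, full_bb)
    out[:, _CA] = ca
    return out, prov


# ---------------------------------------------------------------------------
# moves


def _superpose_flanks(donor_ca, state_ca, flank_idx):
    """Rigid transform mapping donor flank CAs onto the current state's."""
    P = donor_ca[flank_idx]
    Q = state_ca[flank_idx]
    if len(flank_idx) < 3:
        # translation-only fallback for very short flanks
        t = (Q - P).mean(axis=0)
        return np.eye(3), t
    R, t, _ = kabsch(P, Q)
    return R, t


def _propose_swap(coords, donors, rng, cfg: HybridConfig):
    donor = donors[rng.integers(len(donors))]
    length = int(rng.integers(cfg.swap_min, cfg.swap_max + 1))
    L = len(coords)
    mask = donor["modeled"]
    starts = donor["starts"].get(length)
    if starts is None:
        ok = np.array([
            mask[s : s + length].all() for s in range(L - length + 1)
        ])
        starts = np.nonzero(ok)[0]
        donor["starts"][length] = starts
    if len(starts) == 0:
        return None
    s = int(starts[rng.integers(len(starts))])
    e = s + length  # python slice end
    f = cfg.flank
    flank_idx = np.array(
        [i for i in range(max(0, s - f), s)] + [i for i in range(e, min(L, e + f))]
    )
    flank_idx = flank_idx[mask[flank_idx]]
    if len(flank_idx) == 0:
        return None
    dca = donor["ca"]
    R, t = _superpose_flanks(dca, coords[:, _CA], flank_idx)
    block = apply_rigid(donor["bb"][s:e], R, t)
    return s, e, block, donor["id"]


def _propose_fragment(coords, library, rng):
    length = 3 if rng.random() < 0.5 else 9
    L = len(coords)
    if L < length:
        return None
    p = int(rng.integers(1, L - length + 2))
    frags = library.fragments(p, length)
    tag, frag = frags[rng.integers(len(frags))]
    s, e = p - 1, p - 1 + length
    # anchor the fragment on the window's two end residues (N, CA, C): the
    # insertion must reproduce the junction geometry at both ends
    sel = [0, length - 1]
    P = frag[sel][:, :3].reshape(-1, 3)
    Q = coords[[s, e - 1]][:, :3].reshape(-1, 3)
    R, t, _ = kabsch(P, Q)
    block = apply_rigid(frag, R, t)
    return s, e, block, f"frag:{tag}"


# ---------------------------------------------------------------------------
# the Monte Carlo driver


def hybridize(threads: Sequence[ThreadedModel],
              fragment_library: FragmentLibrary,
              annotations: TargetAnnotations,
              n_models: int = 100, seed: int = 0,
              config: Optional[HybridConfig] = None) -> List[HybridState]:
    """Assemble ``n_models`` complete models by Metropolis Monte Carlo.

    The first thread (callers pass them identity-ranked) seeds the state;
    moves are template-segment swaps and fragment insertions chosen 50/50,
    with geometric cooling from ``t_start`` to ``t_end``. Each model runs
    an independent trajectory seeded ``seed + model_index``, and the best
    state encountered in the trajectory is returned for each model,
    sorted by total score. Fully deterministic for a fixed seed.
    """
    cfg = config or HybridConfig()
    if not threads:
        raise ValidationError("need at least one threaded model")
    L = len(threads[0].sequence)
    for th in threads:
        if len(th.sequence) != L:
            raise ValidationError("threads disagree on target length")
    init_coords, init_prov = _interpolate_gaps(threads[0])
    donors = []
    for th in threads:
        mask = np.isfinite(th.coords.array[:, _CA]).all(axis=1)
        donors.append({
            "id": th.template_id,
            "bb": th.coords.array,
            "ca": th.coords.array[:, _CA],
            "modeled": mask,
            "starts": {},
        })

    results: List[HybridState] = []
    for m in range(n_models):
        rng = np.random.default_rng(seed + m)
        coords = init_coords.copy()
        prov = list(init_prov)
        terms, total = score(coords, annotations, cfg.weights)
        best = HybridState(coords.copy(), list(prov), dict(terms), total, m)
        accepted = [total]
        best_trace = [total]
        n_steps = cfg.n_steps
        ratio = cfg.t_end / cfg.t_start
        for step in range(n_steps):
            T = cfg.t_start * ratio ** (step / max(1, n_steps - 1))
            if rng.random() < 0.5 and len(donors) > 0:
                prop = _propose_swap(coords, donors, rng, cfg)
            else:
                prop = _propose_fragment(coords, fragment_library, rng)
            if prop is None:
                continue
            s, e, block, tag = prop
            saved = coords[s:e].copy()
            coords[s:e] = block
            new_terms, new_total = score(coords, annotations, cfg.weights)
            delta = new_total - total
            if delta <= 0 or rng.random() < np.exp(-delta / T):
                total, terms = new_total, new_terms
                for i in range(s, e):
                    prov[i] = tag
                accepted.append(total)
                if total < best.total:
                    best = HybridState(coords.copy(), list(prov),
                                       dict(terms), total, m)
            else:
                coords[s:e] = saved
            best_trace.append(min(best_trace[-1], total))
        best.trace_accepted = accepted
        best.trace_best = best_trace
        results.append(best)
    results.sort(key=lambda st: (st.total, st.model_index))
    return results


def select_best(models: Sequence[HybridState]) -> HybridState:
    """The model with the lowest total score; ties go to the lowest index."""
    if not models:
        raise ValidationError("empty model list")
    return min(models, key=lambda st: (st.total, st.model_index))
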