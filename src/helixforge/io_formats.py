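"""External file formats and the residue-indexing conventions.

Everything downstream indexes residues 1-based inclusive; MSA columns are
0-based (they are array indices, not residue numbers). Coordinates are in
Angstrom. The PDB dialect handled here is deliberately narrow: ATOM records
of the first MODEL, first listed altloc, one chain (first encountered
unless selected) — the templates this pipeline consumes are monomeric
receptor chains.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import gemmi
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .geometry import ATOM_INDEX, ATOM_ORDER, ideal_cb

log = logging.getLogger(__name__)

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = {k: v.upper() for k, v in protein_letters_1to3.items()}

#: Canonical order of sequence regions along a 7TM receptor, extracellular
#: N-terminus first. Loops alternate intracellular/extracellular because
#: TM1 crosses the membrane outside -> inside.
REGION_ORDER = (
    "Nterm", "TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4",
    "ECL2", "TM5", "ICL3", "TM6", "ECL3", "TM7", "Cterm",
)
LOOP_AFTER_TM = {1: "ICL1", 2: "ECL1", 3: "ICL2", 4: "ECL2", 5: "ICL3", 6: "ECL3"}
LOOP_REGIONS = tuple(LOOP_AFTER_TM[i] for i in range(1, 7))
TM_REGIONS = tuple(f"TM{i}" for i in range(1, 8))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TMSegment:
    """One transmembrane helix: 1-based inclusive ``[start, end]`` with the
    x.50 anchor residue (the most conserved position of the helix)."""

    helix_index: int
    start: int
    end: int
    anchor: Optional[int] = None

    def __post_init__(self):
        if not 1 <= self.helix_index <= 7:
            raise ValidationError(f"helix_index must be 1..7, got {self.helix_index}")
        if self.start > self.end:
            raise ValidationError(f"TM{self.helix_index}: start > end")
        if self.anchor is not None and not self.start <= self.anchor <= self.end:
            raise ValidationError(
                f"TM{self.helix_index}: anchor {self.anchor} outside "
                f"[{self.start}, {self.end}]"
            )

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class SpanRecord:
    """Membrane-spanning segments of a sequence, 1-based inclusive."""

    segments: list
    total_length: int

    def __post_init__(self):
        prev_end = 0
        for start, end in self.segments:
            if start <= prev_end or end < start or end > self.total_length:
                raise ValidationError(
                    f"span segments must be ordered, non-overlapping and "
                    f"within [1, {self.total_length}]"
                )
            prev_end = end


class BackboneCoords:
    """Per-residue backbone coordinates, (L, 5, 3) in N/CA/C/O/CB order.

    NaN marks atoms that are absent; a residue counts as modeled when its
    CA is present. Positions are 1-based.
    """

    def __init__(self, array: np.ndarray):
        array = np.asarray(array, dtype=float)
        if array.ndim != 3 or array.shape[1:] != (5, 3):
            raise ValidationError("backbone array must have shape (L, 5, 3)")
        self.array = array

    @classmethod
    def empty(cls, length: int) -> "BackboneCoords":
        return cls(np.full((length, 5, 3), np.nan))

    def __len__(self) -> int:
        return len(self.array)

    def is_modeled(self, pos: int) -> bool:
        return bool(np.isfinite(self.array[pos - 1, ATOM_INDEX["CA"]]).all())

    def modeled_positions(self) -> list:
        ok = np.isfinite(self.array[:, ATOM_INDEX["CA"]]).all(axis=1)
        return [int(i) + 1 for i in np.nonzero(ok)[0]]

    def atom(self, pos: int, name: str) -> np.ndarray:
        return self.array[pos - 1, ATOM_INDEX[name]]

    def ca(self, pos: int) -> np.ndarray:
        return self.array[pos - 1, ATOM_INDEX["CA"]]

    def ca_array(self, positions: Sequence[int]) -> np.ndarray:
        idx = np.asarray(list(positions), dtype=int) - 1
        return self.array[idx, ATOM_INDEX["CA"]]

    def cb(self, pos: int) -> np.ndarray:
        """CB position; reconstructed ideally from N/CA/C when absent."""
        v = self.array[pos - 1, ATOM_INDEX["CB"]]
        if np.isfinite(v).all():
            return v
        r = self.array[pos - 1]
        return ideal_cb(r[ATOM_INDEX["N"]], r[ATOM_INDEX["CA"]], r[ATOM_INDEX["C"]])

    def copy(self) -> "BackboneCoords":
        return BackboneCoords(self.array.copy())


@dataclass
class ReceptorEntry:
    """A receptor sequence with optional structure and annotations."""

    id: str
    sequence: str
    coords: Optional[BackboneCoords] = None
    tm_segments: Optional[list] = None
    disulfides: list = field(default_factory=list)
    class_label: str = "unknown"
    #: receptors known to lack the conserved TM3-ECL2 disulfide
    disulfide_free: bool = False

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValidationError("sequence must be non-empty")
        if self.coords is not None and len(self.coords) != len(self.sequence):
            raise ValidationError("coords length must match sequence length")
        if self.class_label not in {"A", "B", "C", "F", "unknown"}:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if self.tm_segments is not None:
            segs = sorted(self.tm_segments, key=lambda s: s.helix_index)
            prev_end = 0
            for seg in segs:
                if seg.start <= prev_end:
                    raise ValidationError("TM segments must be ordered and disjoint")
                if seg.end > len(self.sequence):
                    raise ValidationError("TM segment beyond sequence end")
                prev_end = seg.end
            self.tm_segments = segs
        for a, b in self.disulfides:
            for pos in (a, b):
                if not 1 <= pos <= len(self.sequence):
                    raise ValidationError(f"disulfide residue {pos} out of range")
                if self.sequence[pos - 1] != "C":
                    raise ValidationError(
                        f"disulfide residue {pos} is {self.sequence[pos - 1]}, "
                        "not cysteine"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def segment(self, helix_index: int) -> Optional[TMSegment]:
        if not self.tm_segments:
            return None
        for seg in self.tm_segments:
            if seg.helix_index == helix_index:
                return seg
        return None


def regions_from_segments(entry: ReceptorEntry) -> dict:
    """Map each sequence region to its 1-based residue positions.

    Requires 7 TM segments. Regions with zero residues (e.g. an absent
    terminus) map to empty lists.
    """
    if not entry.tm_segments or len(entry.tm_segments) != 7:
        raise ValidationError(f"{entry.id}: need 7 TM segments to define regions")
    segs = entry.tm_segments
    regions: dict = {}
    regions["Nterm"] = list(range(1, segs[0].start))
    for i, seg in enumerate(segs, start=1):
        regions[f"TM{i}"] = list(seg.positions())
        if i < 7:
            nxt = segs[i]
            regions[LOOP_AFTER_TM[i]] = list(range(seg.end + 1, nxt.start))
    regions["Cterm"] = list(range(segs[-1].end + 1, len(entry.sequence) + 1))
    return regions


# ---------------------------------------------------------------------------
# PDB subset


def read_pdb(path, chain: Optional[str] = None,
             keep_numbering: bool = False) -> ReceptorEntry:
    """Read one protein chain from a PDB file into a :class:`ReceptorEntry`.

    Only ATOM records of the first model are considered; for duplicated
    atom names (altlocs) the first listed position is retained. Residues
    lacking a CA atom are dropped (and logged). HETATM records are ignored.

    With ``keep_numbering=True`` the residue numbers in the file become
    1-based sequence positions: numbering gaps (e.g. unmodeled residues a
    partial thread omitted) yield 'X' residues with NaN coordinates, so
    the entry stays comparable residue-by-residue with a full-length
    reference.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # gemmi raises RuntimeError on garbage
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    picked = None
    for ch in model:
        if chain is None or ch.name == chain:
            picked = ch
            break
    if picked is None:
        raise FormatError(f"{path}: chain {chain!r} not found")

    seq_letters = []
    rows = []
    numbers = []
    for res in picked:
        if res.het_flag != "A":
            continue
        atoms = {}
        for atom in res:
            if atom.name in ATOM_INDEX and atom.name not in atoms:
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
        if "CA" not in atoms:
            log.warning(
                "%s: dropping residue %s %s (no CA atom)", path.name,
                res.name, res.seqid.num,
            )
            continue
        seq_letters.append(_THREE_TO_ONE.get(res.name.upper(), "X"))
        row = np.full((5, 3), np.nan)
        for name, xyz in atoms.items():
            row[ATOM_INDEX[name]] = xyz
        rows.append(row)
        numbers.append(int(res.seqid.num))
    if not rows:
        raise FormatError(f"{path}: no CA atoms found in chain {picked.name!r}")
    if keep_numbering:
        if min(numbers) < 1 or len(set(numbers)) != len(numbers):
            raise FormatError(
                f"{path}: keep_numbering requires positive, unique residue "
                "numbers"
            )
        length = max(numbers)
        seq = ["X"] * length
        arr = np.full((length, 5, 3), np.nan)
        for letter, row, num in zip(seq_letters, rows, numbers):
            seq[num - 1] = letter
            arr[num - 1] = row
        return ReceptorEntry(id=path.stem, sequence="".join(seq),
                             coords=BackboneCoords(arr))
    return ReceptorEntry(
        id=path.stem, sequence="".join(seq_letters),
        coords=BackboneCoords(np.stack(rows)),
    )


def write_pdb(entry: ReceptorEntry, path) -> None:
    """Write the modeled backbone of ``entry`` as a single-chain PDB file.

    Unmodeled residues are omitted entirely (never written with dummy
    coordinates). Residue numbers are the 1-based sequence positions, so
    gaps remain visible in the numbering.
    """
    if entry.coords is None:
        raise ValidationError(f"{entry.id}: no coordinates to write")
    st = gemmi.Structure()
    st.name = entry.id[:4] if entry.id else "MODL"
    model = gemmi.Model(1)
    ch = gemmi.Chain("A")
    for pos in entry.coords.modeled_positions():
        aa = entry.sequence[pos - 1]
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "UNK")
        res.seqid = gemmi.SeqId(pos, " ")
        for name in ATOM_ORDER:
            xyz = entry.coords.atom(pos, name)
            if not np.isfinite(xyz).all():
                continue
            if name == "CB" and aa == "G":
                continue  # glycine has no real CB; reconstructed on read if needed
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_entry_meta(entry: ReceptorEntry, path) -> None:
    """Sidecar JSON with the annotations a PDB file cannot carry:
    TM segments (with x.50 anchors), disulfides, class label."""
    payload = {
        "tm_segments": [
            [s.helix_index, s.start, s.end, s.anchor]
            for s in (entry.tm_segments or [])
        ],
        "disulfides": [list(p) for p in entry.disulfides],
        "class_label": entry.class_label,
        "disulfide_free": entry.disulfide_free,
    }
    Path(path).write_text(json.dumps(payload, indent=0))


def read_entry_meta(entry: ReceptorEntry, path) -> ReceptorEntry:
    """Return a copy of ``entry`` carrying the sidecar annotations."""
    meta = json.loads(Path(path).read_text())
    return ReceptorEntry(
        id=entry.id, sequence=entry.sequence, coords=entry.coords,
        tm_segments=[TMSegment(*row) for row in meta.get("tm_segments", [])]
        or None,
        disulfides=[tuple(p) for p in meta.get("disulfides", [])],
        class_label=meta.get("class_label", "unknown"),
        disulfide_free=meta.get("disulfide_free", False),
    )


def read_annotated_pdb(path, chain=None) -> ReceptorEntry:
    """:func:`read_pdb` plus the ``<path>.meta.json`` sidecar if present."""
    entry = read_pdb(path, chain=chain)
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        entry = read_entry_meta(entry, meta_path)
    return entry


# ---------------------------------------------------------------------------
# topology / span files


def topology_to_span(topology: str) -> SpanRecord:
    """Convert a per-residue membrane topology string to a span record.

    The string uses the alphabet {M, i, o} (membrane / inside / outside);
    maximal runs of ``M`` become membrane-spanning segments, in order.
    """
    bad = set(topology) - {"M", "i", "o"}
    if bad:
        raise FormatError(f"illegal topology characters: {sorted(bad)}")
    segments = []
    pos = 1
    for char, run in groupby(topology):
        n = len(list(run))
        if char == "M":
            segments.append((pos, pos + n - 1))
        pos += n
    if not segments:
        raise FormatError("topology contains no membrane segments")
    return SpanRecord(segments=segments, total_length=len(topology))


def read_topology(path) -> str:
    text = Path(path).read_text().split()
    if not text:
        raise FormatError(f"{path}: empty topology file")
    return "".join(text)


def write_span(span: SpanRecord, path, rosetta: bool = False) -> None:
    """Write a span file.

    Default dialect: a header line ``<n_segments> <total_length>`` then one
    ``start end`` pair per line. With ``rosetta=True`` a Rosetta-style file
    (title line, counts, ``antiparallel``, ``n2C``, doubled ranges) is
    produced instead.
    """
    lines = []
    if rosetta:
        lines.append("TM region prediction")
        lines.append(f"{len(span.segments)} {span.total_length}")
        lines.append("antiparallel")
        lines.append("n2C")
        for s, e in span.segments:
            lines.append(f"{s:>5d}{e:>6d}{s:>6d}{e:>6d}")
    else:
        lines.append(f"{len(span.segments)} {span.total_length}")
        for s, e in span.segments:
            lines.append(f"{s} {e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_span(path) -> SpanRecord:
    """Read the default span dialect written by :func:`write_span`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty span file")
    try:
        n, total = (int(x) for x in lines[0].split())
        segments = [tuple(int(x) for x in ln.split()) for ln in lines[1 : n + 1]]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed span file: {exc}") from exc
    if len(segments) != n:
        raise FormatError(f"{path}: expected {n} segments, found {len(segments)}")
    return SpanRecord(segments=segments, total_length=total)


# ---------------------------------------------------------------------------
# disulfide constraint files


def write_disulfide_pairs(pairs: Sequence, path) -> None:
    """One ``resi_a resi_b`` line per disulfide, sorted by first index."""
    lines = [f"{a} {b}" for a, b in sorted(pairs)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_disulfide_pairs(path) -> list:
    pairs = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        try:
            a, b = (int(x) for x in ln.split())
        except ValueError as exc:
            raise FormatError(f"{path}: bad disulfide line {ln!r}") from exc
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# FASTA sequences and MSAs


def read_fasta(path) -> list:
    """Read (id, sequence) pairs from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [(rec.id, str(rec.seq)) for rec in records]


def write_fasta(records: Sequence, path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def _msa_format(path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower()
    return "clustal" if suffix in {".aln", ".clustal", ".clw"} else "fasta"


def read_msa(path, fmt: Optional[str] = None):
    """Read an MSA (FASTA or Clustal) into an :class:`~helixforge.msa_builder.MSA`.

    A sidecar ``<path>.meta.json`` (written by :func:`write_msa`) restores
    region masks, anchor columns and unaligned-residue bookkeeping when
    present; without it the MSA carries rows only.
    """
    from .msa_builder import MSA  # local import to avoid a module cycle

    path = Path(path)
    fmt = _msa_format(path, fmt)
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot read {fmt} MSA: {exc}") from exc
    rows = {rec.id: str(rec.seq) for rec in aln}
    widths = {len(r) for r in rows.values()}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged alignment rows (widths {sorted(widths)})")
    msa = MSA(rows=rows)
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        msa.region_masks = {k: set(v) for k, v in meta.get("region_masks", {}).items()}
        msa.anchor_columns = dict(meta.get("anchor_columns", {}))
        msa.unaligned = {k: set(v) for k, v in meta.get("unaligned", {}).items()}
        msa.defined_columns = set(meta.get("defined_columns", []))
        msa.disulfide_columns = {
            k: tuple(v) for k, v in meta.get("disulfide_columns", {}).items()
        }
    return msa


def write_msa(msa, path, fmt: Optional[str] = None, meta: bool = True) -> None:
    """Write an MSA as FASTA (default) or Clustal, plus a metadata sidecar."""
    path = Path(path)
    fmt = _msa_format(path, fmt)
    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=name, description="") for name, row in msa.rows.items()]
    )
    AlignIO.write(aln, str(path), fmt)
    if meta:
        payload = {
            "region_masks": {k: sorted(v) for k, v in msa.region_masks.items()},
            "anchor_columns": msa.anchor_columns,
            "unaligned": {k: sorted(v) for k, v in msa.unaligned.items()},
            "defined_columns": sorted(msa.defined_columns),
            "disulfide_columns": {k: list(v) for k, v in msa.disulfide_columns.items()},
        }
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(payload, indent=0)
        )
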