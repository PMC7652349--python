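import numpy as np
import pytest

from helixforge import (
    MSA,
    ReceptorEntry,
    align_loops_structural,
    align_target_to_msa,
    align_tm_segments,
    assign_bw_numbers,
    build_template_msa,
    evolve_family,
    pairwise_identity,
    place_unalignable_residues,
    recovered_column_fraction,
)
from helixforge.errors import AlignmentError, ValidationError
from helixforge.io_formats import LOOP_REGIONS, TMSegment, regions_from_segments
from helixforge.msa_builder import default_identity_mask


class TestBWNumbers:
    def test_anchor_gets_x50(self, ancestor):
        labels = assign_bw_numbers(ancestor)
        seg3 = ancestor.segment(3)
        assert labels[seg3.anchor] == "3.50"

    def test_offsets_count_from_anchor(self, ancestor):
        labels = assign_bw_numbers(ancestor)
        seg3 = ancestor.segment(3)
        assert labels[seg3.anchor + 1] == "3.51"
        assert labels[seg3.anchor - 2] == "3.48"

    def test_labels_distinct_and_increasing(self, ancestor):
        labels = assign_bw_numbers(ancestor)
        for seg in ancestor.tm_segments:
            seen = [labels[p] for p in seg.positions()]
            assert len(set(seen)) == len(seen)
            numbers = [int(s.split(".")[1]) for s in seen]
            assert numbers == sorted(numbers)

    def test_missing_anchor_raises(self, ancestor):
        segs = [TMSegment(s.helix_index, s.start, s.end, None)
                for s in ancestor.tm_segments]
        entry = ReceptorEntry(id="x", sequence=ancestor.sequence,
                              tm_segments=segs)
        with pytest.raises(ValidationError):
            assign_bw_numbers(entry)


class TestTMAlignment:
    def test_identical_entries_no_gaps(self, ancestor):
        twin = ReceptorEntry(id="twin", sequence=ancestor.sequence,
                             coords=ancestor.coords.copy(),
                             tm_segments=ancestor.tm_segments,
                             disulfides=ancestor.disulfides)
        msa = align_tm_segments([ancestor, twin])
        assert "-" not in msa.rows["ancestor"]
        assert "-" not in msa.rows["twin"]
        assert msa.rows["ancestor"] == msa.rows["twin"]

    def test_anchors_share_columns(self, small_family):
        msa = build_template_msa(small_family.members)
        for label, col in msa.anchor_columns.items():
            for rid in msa.rows:
                assert msa.rows[rid][col] != "-", (label, rid)

    def test_tm_bulge_insertion_recovered(self, ancestor):
        """A one-residue mid-helix insertion in one member must surface as
        a row-exclusive bulge column, with anchors still co-columnar."""
        fam = evolve_family(ancestor, n_members=5, mutation_rate=0.2,
                            indel_rate=0.35, noise_sigma=0.15, seed=9,
                            tm_indels=True)
        has_tm_indel = any(
            any(e.startswith(("ins TM", "del TM")) for e in fam.edits[m.id])
            for m in fam.members
        )
        assert has_tm_indel, "fixture must contain at least one TM indel"
        msa = build_template_msa(fam.members)
        truth = fam.truth_alignment
        tm_mask = set().union(*(truth.region_masks[f"TM{h}"]
                                for h in range(1, 8)))
        assert recovered_column_fraction(msa, truth, tm_mask) >= 0.95

    def test_rows_ungap_to_sequences(self, small_family):
        msa = build_template_msa(small_family.members)
        for m in small_family.members:
            assert msa.ungap(m.id) == m.sequence


class TestLoopAlignment:
    def test_self_alignment_gapless(self, ancestor):
        twin = ReceptorEntry(id="twin", sequence=ancestor.sequence,
                             coords=ancestor.coords.copy(),
                             tm_segments=ancestor.tm_segments,
                             disulfides=ancestor.disulfides)
        msa = align_loops_structural([ancestor, twin])
        assert msa.rows["ancestor"] == msa.rows["twin"]
        assert "-" not in msa.rows["ancestor"]

    def test_antiparallel_vectors_not_aligned(self, ancestor):
        """Mirroring loop CB directions breaks the angle criterion, so the
        flipped rows may not share loop columns with the original."""
        flipped = ancestor.coords.copy()
        ca = flipped.array[:, 1]
        cb = flipped.array[:, 4]
        flipped.array[:, 4] = ca - (cb - ca)  # invert CA->CB
        twin = ReceptorEntry(id="flip", sequence=ancestor.sequence,
                             coords=flipped, tm_segments=ancestor.tm_segments)
        msa = align_loops_structural([ancestor, twin])
        regions = regions_from_segments(ancestor)
        p2c_a = msa.pos_to_col("ancestor")
        p2c_b = msa.pos_to_col("flip")
        shared = 0
        for name in LOOP_REGIONS:
            for p in regions[name]:
                if p2c_a.get(p) is not None and p2c_a.get(p) == p2c_b.get(p):
                    # disulfide cysteines are force-pinned; skip them
                    if p in {x for pair in ancestor.disulfides for x in pair}:
                        continue
                    shared += 1
        assert shared == 0

    def test_family_recovery(self, recovery_family):
        fam = recovery_family
        msa = build_template_msa(fam.members)
        truth = fam.truth_alignment
        cons = fam.structure_conserved_columns()
        loop_mask = set().union(*(truth.region_masks[r] for r in LOOP_REGIONS))
        frac = recovered_column_fraction(msa, truth, loop_mask & cons)
        assert frac >= 0.90


class TestPlaceUnalignable:
    def _msa(self, row, unaligned_cols, defined_cols):
        return MSA(rows={"r": row}, unaligned={"r": set(unaligned_cols)},
                   defined_columns=set(defined_cols),
                   region_masks={"ECL1": set(range(len(row)))})

    def test_run_shifts_to_nearer_flank(self):
        # "H...xx..H": gap of 3 left, 2 right -> pack right
        msa = self._msa("H---AA--H", {4, 5}, {0, 8})
        out = place_unalignable_residues(msa)
        assert out.rows["r"] == "H-----AAH"

    def test_tie_goes_left(self):
        msa = self._msa("H--AA--H", {3, 4}, {0, 7})
        out = place_unalignable_residues(msa)
        assert out.rows["r"] == "HAA----H"

    def test_no_unaligned_is_identity(self):
        msa = self._msa("HAAH", set(), {0, 3})
        assert place_unalignable_residues(msa).rows == msa.rows

    def test_idempotent_on_family(self, small_family):
        msa = build_template_msa(small_family.members)
        again = place_unalignable_residues(msa)
        assert again.rows == msa.rows
        assert again.unaligned == msa.unaligned

    def test_property_runs_abut_structure(self, recovery_family):
        msa = build_template_msa(recovery_family.members)
        defined = msa.defined_columns
        for rid, row in msa.rows.items():
            for c in msa.unaligned.get(rid, set()):
                # walk toward the nearest defined column: no gap directly
                # between the run and the side it was packed against
                left_ok = c - 1 < 0 or row[c - 1] != "-" or (c - 1) in msa.unaligned[rid]
                right_ok = c + 1 >= len(row) or row[c + 1] != "-" or (c + 1) in msa.unaligned[rid]
                assert left_ok or right_ok


class TestPairwiseIdentity:
    def test_identical_rows_100(self):
        msa = MSA(rows={"a": "ACDEF", "b": "ACDEF"})
        ident = pairwise_identity(msa, region_mask=set(range(5)))
        assert ident.loc["a", "b"] == 100.0

    def test_four_of_five(self):
        msa = MSA(rows={"a": "ACDEF", "b": "ACDFF"})
        ident = pairwise_identity(msa, region_mask=set(range(5)))
        assert ident.loc["a", "b"] == pytest.approx(80.0)

    def test_matrix_invariants(self, small_family):
        msa = build_template_msa(small_family.members)
        ident = pairwise_identity(msa)
        arr = ident.values
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 100.0)
        off = arr[~np.eye(len(arr), dtype=bool)]
        assert np.nanmin(off) >= 0.0 and np.nanmax(off) <= 100.0

    def test_against_counting_oracle(self):
        rng = np.random.default_rng(12)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(50):
            width = int(rng.integers(8, 60))
            rows = {
                "a": "".join(rng.choice(alphabet, size=width)),
                "b": "".join(rng.choice(alphabet, size=width)),
            }
            if rows["a"].replace("-", "") == "":
                rows["a"] = "A" + rows["a"][1:]
            if rows["b"].replace("-", "") == "":
                rows["b"] = "A" + rows["b"][1:]
            msa = MSA(rows=rows)
            mask = set(rng.choice(width, size=max(2, width // 2),
                                  replace=False).tolist())
            got = pairwise_identity(msa, region_mask=mask).loc["a", "b"]
            shared = [c for c in mask
                      if rows["a"][c] != "-" and rows["b"][c] != "-"]
            if not shared:
                assert np.isnan(got)
            else:
                matches = sum(rows["a"][c] == rows["b"][c] for c in shared)
                assert got == pytest.approx(100.0 * matches / len(shared))

    def test_zero_shared_columns_nan(self):
        msa = MSA(rows={"a": "AC--", "b": "--AC"})
        ident = pairwise_identity(msa, region_mask=set(range(4)))
        assert np.isnan(ident.loc["a", "b"])

    def test_termini_excluded_by_default_mask(self, small_family):
        msa = build_template_msa(small_family.members)
        mask = default_identity_mask(msa, termini_pad=0)
        assert not (mask & msa.region_masks.get("Nterm", set()))
        assert not (mask & msa.region_masks.get("Cterm", set()))


class TestTargetAlignment:
    def test_identical_target_reproduces_member_row(self, small_family):
        msa = build_template_msa(small_family.members)
        member = small_family.members[2]
        target = ReceptorEntry(id="tgt", sequence=member.sequence,
                               tm_segments=member.tm_segments,
                               disulfides=member.disulfides)
        row, full = align_target_to_msa(target, msa)
        assert row == full.rows[member.id]
        assert full.width == msa.width

    def test_icl3_odd_split(self, small_family):
        """An ICL3 of length 9 adjoins 5 residues to TM5 and 4 to TM6."""
        msa = build_template_msa(small_family.members)
        member = small_family.members[0]
        regions = regions_from_segments(member)
        icl3 = regions["ICL3"]
        # build a target with a distinct 9-residue ICL3 (no family row match)
        seq = list(member.sequence)
        start = icl3[0] - 1
        new_seq = (member.sequence[:icl3[0] - 1] + "WYWYWYWYW"
                   + member.sequence[icl3[-1]:])
        # adjust segments after ICL3 by the length difference
        delta = 9 - len(icl3)
        segs = []
        for s in member.tm_segments:
            if s.start > icl3[-1]:
                segs.append(TMSegment(s.helix_index, s.start + delta,
                                      s.end + delta, s.anchor + delta))
            else:
                segs.append(s)
        ds = [(a + (delta if a > icl3[-1] else 0),
               b + (delta if b > icl3[-1] else 0))
              for a, b in member.disulfides]
        target = ReceptorEntry(id="tgt", sequence=new_seq, tm_segments=segs,
                               disulfides=ds)
        row, full = align_target_to_msa(target, msa)
        p2c = full.pos_to_col("tgt")
        new_regions = regions_from_segments(target)
        icl3_new = new_regions["ICL3"]
        tm5_last = p2c[new_regions["TM5"][-1]]
        tm6_first = p2c[new_regions["TM6"][0]]
        first_half = [p2c[p] for p in icl3_new[:5]]
        second_half = [p2c[p] for p in icl3_new[5:]]
        assert first_half == list(range(tm5_last + 1, tm5_last + 6))
        assert second_half == list(range(tm6_first - 4, tm6_first))

    def test_mutated_target_tm_recovery(self, ancestor):
        fam = evolve_family(ancestor, n_members=7, mutation_rate=0.4,
                            indel_rate=0.3, noise_sigma=0.3, seed=6)
        held_out = fam.members[-1]
        templates = fam.members[:-1]
        msa = build_template_msa(templates)
        target = ReceptorEntry(id=held_out.id, sequence=held_out.sequence,
                               tm_segments=held_out.tm_segments,
                               disulfides=held_out.disulfides)
        _, full = align_target_to_msa(target, msa)
        truth = fam.truth_alignment
        ids = [t.id for t in templates] + [held_out.id]
        tm_cols = set().union(*(truth.region_masks[f"TM{h}"]
                                for h in range(1, 8)))
        tc2p = {mid: truth.col_to_pos(mid) for mid in ids}
        bc2p = {mid: full.col_to_pos(mid) for mid in ids}

        def cells(c2p, col):
            return frozenset(
                (mid, c2p[mid][col]) for mid in ids if col in c2p[mid]
            )

        built = {cells(bc2p, c) for c in range(full.width)}
        hit = tot = 0
        for c in sorted(tm_cols):
            s = cells(tc2p, c)
            if len(s) >= 2 and any(mid == held_out.id for mid, _ in s):
                tot += 1
                hit += s in built
        assert hit / tot >= 0.95

    def test_motif_fallback_anchors_helices(self, small_family, ancestor):
        """Without x.50 annotations the DRY/CWxP/NPxxY motifs must anchor
        TM3/6/7; helices with neither anchor nor motif raise."""
        msa = build_template_msa(small_family.members)
        member = small_family.members[2]
        segs = []
        for s in member.tm_segments:
            anchor = None if s.helix_index in (3, 6, 7) else s.anchor
            segs.append(TMSegment(s.helix_index, s.start, s.end, anchor))
        target = ReceptorEntry(id="tgt", sequence=member.sequence,
                               tm_segments=segs,
                               disulfides=member.disulfides)
        row, full = align_target_to_msa(target, msa)
        assert row == full.rows[member.id]
        # now strip an anchor from a helix with no fallback motif
        segs2 = [TMSegment(s.helix_index, s.start, s.end,
                           None if s.helix_index == 2 else s.anchor)
                 for s in member.tm_segments]
        bad = ReceptorEntry(id="t2", sequence=member.sequence,
                            tm_segments=segs2)
        with pytest.raises(AlignmentError, match="TM2"):
            align_target_to_msa(bad, msa)

    def test_ecl2_cysteine_pinned_to_disulfide_column(self, small_family):
        msa = build_template_msa(small_family.members)
        member = small_family.members[1]
        # mutate ECL2 around the cysteine so family propagation cannot fire
        regions = regions_from_segments(member)
        seq = list(member.sequence)
        for p in regions["ECL2"]:
            if member.sequence[p - 1] != "C":
                seq[p - 1] = "A"
        target = ReceptorEntry(id="tgt", sequence="".join(seq),
                               tm_segments=member.tm_segments,
                               disulfides=member.disulfides)
        row, full = align_target_to_msa(target, msa)
        cys_col = full.disulfide_columns["TM3-ECL2"][1]
        assert full.rows["tgt"][cys_col] == "C"
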