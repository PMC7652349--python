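import numpy as np
import pytest

from helixforge import (
    evolve_family,
    make_binned_family,
    make_ideal_bundle,
    make_region_specialists,
    mutation_rate_for_identity,
    pairwise_identity,
)
from helixforge.errors import ValidationError
from helixforge.io_formats import LOOP_REGIONS, regions_from_segments
from helixforge.synthetic_fixtures import truth_msa_with_target


class TestIdealBundle:
    def test_seven_annotated_segments(self, ancestor):
        assert len(ancestor.tm_segments) == 7
        assert [s.helix_index for s in ancestor.tm_segments] == list(range(1, 8))
        for seg in ancestor.tm_segments:
            assert seg.start <= seg.anchor <= seg.end

    def test_chain_spacing(self, ancestor):
        ca = ancestor.coords.array[:, 1]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert d.min() > 3.8 - 0.2
        assert d.max() < 3.8 + 0.2

    def test_same_seed_identical(self):
        a = make_ideal_bundle(seed=42)
        b = make_ideal_bundle(seed=42)
        assert a.sequence == b.sequence
        assert np.array_equal(a.coords.array, b.coords.array)

    def test_helix_rise_by_axis_regression(self, ancestor):
        """CA positions of each helix fit a straight axis with ~1.5 A rise
        per residue (principal-component projection)."""
        for seg in ancestor.tm_segments:
            ca = ancestor.coords.array[seg.start - 1 : seg.end, 1]
            centered = ca - ca.mean(axis=0)
            axis = np.linalg.svd(centered)[2][0]
            proj = centered @ axis
            rise = np.abs(np.polyfit(np.arange(len(proj)), proj, 1)[0])
            assert rise == pytest.approx(1.5, abs=0.1)

    def test_planted_disulfide_geometry(self, ancestor):
        a, b = ancestor.disulfides[0]
        assert ancestor.sequence[a - 1] == "C"
        assert ancestor.sequence[b - 1] == "C"
        cb_dist = np.linalg.norm(ancestor.coords.cb(a) - ancestor.coords.cb(b))
        assert cb_dist <= 5.0  # chemically plausible for a disulfide

    def test_no_close_nonadjacent_contacts(self, ancestor):
        ca = ancestor.coords.array[:, 1]
        i, j = np.triu_indices(len(ca), k=2)
        d = np.linalg.norm(ca[i] - ca[j], axis=1)
        assert d.min() >= 4.0

    def test_impossible_loop_raises(self):
        with pytest.raises(ValidationError):
            make_ideal_bundle(loop_lengths={"ICL1": 0})


class TestEvolveFamily:
    def test_zero_mutation_rate_identity(self, ancestor):
        fam = evolve_family(ancestor, n_members=3, mutation_rate=0.0,
                            indel_rate=0.0, noise_sigma=0.0, seed=0)
        for m in fam.members:
            assert m.sequence == ancestor.sequence
        assert all("-" not in r for r in fam.truth_alignment.rows.values())

    def test_indels_restricted_to_loops(self, recovery_family):
        truth = recovery_family.truth_alignment
        tm_cols = set().union(*(truth.region_masks[f"TM{h}"]
                                for h in range(1, 8)))
        for rid, row in truth.rows.items():
            for c in tm_cols:
                assert row[c] != "-", (rid, c)

    def test_deterministic_under_seed(self, ancestor):
        a = evolve_family(ancestor, n_members=3, mutation_rate=0.3,
                          indel_rate=0.3, noise_sigma=0.3, seed=8)
        b = evolve_family(ancestor, n_members=3, mutation_rate=0.3,
                          indel_rate=0.3, noise_sigma=0.3, seed=8)
        for x, y in zip(a.members, b.members):
            assert x.sequence == y.sequence
            assert np.array_equal(x.coords.array, y.coords.array)

    def test_truth_rows_ungap_to_member_sequences(self, recovery_family):
        truth = recovery_family.truth_alignment
        for m in recovery_family.members:
            assert truth.ungap(m.id) == m.sequence

    def test_chain_connectivity_after_noise(self, recovery_family):
        for m in recovery_family.members:
            ca = m.coords.array[:, 1]
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            assert d.min() >= 2.8
            assert d.max() <= 4.8

    def test_identity_calibration(self, ancestor):
        """Ten members at the rate tuned for ~30% identity must realize a
        mean pairwise identity within +/-10 points of the request."""
        fam = evolve_family(ancestor, n_members=10,
                            mutation_rate=mutation_rate_for_identity(30.0),
                            indel_rate=0.0, noise_sigma=0.1, seed=21)
        ident = pairwise_identity(fam.truth_alignment,
                                  region_mask=set(range(fam.truth_alignment.width)))
        off_diag = ident.values[np.triu_indices(len(ident), 1)]
        assert abs(np.nanmean(off_diag) - 30.0) <= 10.0

    def test_anchors_and_disulfides_remapped(self, recovery_family):
        for m in recovery_family.members:
            assert len(m.tm_segments) == 7
            for seg in m.tm_segments:
                assert seg.start <= seg.anchor <= seg.end
            for a, b in m.disulfides:
                assert m.sequence[a - 1] == "C"
                assert m.sequence[b - 1] == "C"

    def test_rates_validated(self, ancestor):
        with pytest.raises(ValidationError):
            evolve_family(ancestor, mutation_rate=1.5)


class TestSpecialFixtures:
    def test_region_specialists_distinct_windows(self):
        fam = make_region_specialists(seed=4)
        windows = fam.params["bad_windows"]
        spans = sorted(windows.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2  # disjoint

    def test_truth_msa_with_target_row(self, small_family):
        msa = truth_msa_with_target(small_family, target_id="tgt")
        assert msa.ungap("tgt") == small_family.ancestor.sequence
        assert msa.width == small_family.truth_alignment.width

    def test_binned_family_noise_gradient(self):
        target, bins = make_binned_family(seed=7, per_bin=2)
        labels = ["30-39", "25-29", "20-24", "15-19"]
        assert list(bins) == labels
        mean_disp = []
        for label in labels:
            fam = bins[label]
            disp = [np.mean(list(fam.displacement(m.id).values()))
                    for m in fam.members]
            mean_disp.append(np.mean(disp))
        assert all(a < b for a, b in zip(mean_disp, mean_disp[1:]))
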