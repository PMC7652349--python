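import numpy as np
import pytest

from helixforge import (
    ReceptorEntry,
    experiment_harness,
    fold_change,
    kabsch_superpose,
    region_rmsd,
)
from helixforge.errors import ValidationError
from helixforge.io_formats import BackboneCoords, regions_from_segments


def random_rigid(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=15.0, size=3)


class TestKabschSuperpose:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        assert kabsch_superpose(P, P).rmsd < 1e-12

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        P = rng.normal(scale=10, size=(25, 3))
        R, t = random_rigid(rng)
        res = kabsch_superpose(P @ R.T + t, P)
        assert res.rmsd < 1e-8
        assert not res.degenerate

    def test_collinear_flagged_but_scored(self):
        P = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        Q = P + 0.1
        res = kabsch_superpose(P, Q)
        assert res.degenerate
        assert np.isfinite(res.rmsd)

    def test_quaternion_agreement(self, quaternion_rmsd):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            P = rng.normal(scale=12, size=(n, 3))
            Q = P @ random_rigid(rng)[0].T + rng.normal(scale=1.0, size=(n, 3))
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                quaternion_rmsd(P, Q), abs=1e-8
            )


class TestRegionRMSD:
    def test_self_is_zero(self, ancestor):
        report = region_rmsd(ancestor, ancestor)
        for region in ("TM", "ECL2", "FullModel"):
            assert report.rmsd[region] == pytest.approx(0.0, abs=1e-9)
            assert report.n_atoms[region] > 0

    def test_rigidly_displaced_ecl2(self, ancestor):
        """Displacing ECL2 rigidly leaves per-region TM and ECL2 RMSD at
        zero (each region superposes on itself) but shows in FullModel."""
        moved = ancestor.coords.copy()
        regions = regions_from_segments(ancestor)
        idx = [p - 1 for p in regions["ECL2"]]
        moved.array[idx] += np.array([2.0, 0.0, 0.0])
        model = ReceptorEntry(id="m", sequence=ancestor.sequence,
                              coords=moved, tm_segments=ancestor.tm_segments,
                              disulfides=ancestor.disulfides)
        report = region_rmsd(model, ancestor)
        assert report.rmsd["TM"] == pytest.approx(0.0, abs=1e-9)
        assert report.rmsd["ECL2"] == pytest.approx(0.0, abs=1e-9)
        assert report.rmsd["FullModel"] > 0.1

    def test_global_fit_sees_displaced_ecl2(self, ancestor):
        moved = ancestor.coords.copy()
        regions = regions_from_segments(ancestor)
        idx = [p - 1 for p in regions["ECL2"]]
        moved.array[idx] += np.array([2.0, 0.0, 0.0])
        model = ReceptorEntry(id="m", sequence=ancestor.sequence,
                              coords=moved, tm_segments=ancestor.tm_segments,
                              disulfides=ancestor.disulfides)
        report = region_rmsd(model, ancestor, fit="global")
        assert report.rmsd["TM"] == pytest.approx(0.0, abs=1e-6)
        assert report.rmsd["ECL2"] == pytest.approx(2.0, abs=0.05)

    def test_gaussian_noise_closed_form(self, ancestor):
        """Isotropic per-atom noise of RMS sigma gives RMSD ~ sigma (the
        full-model fit absorbs a vanishing fraction at this size)."""
        sigma = 0.5
        rng = np.random.default_rng(3)
        reps = []
        for _ in range(8):
            noisy = ancestor.coords.copy()
            noisy.array += rng.normal(scale=sigma / np.sqrt(3),
                                      size=noisy.array.shape)
            model = ReceptorEntry(id="m", sequence=ancestor.sequence,
                                  coords=noisy,
                                  tm_segments=ancestor.tm_segments,
                                  disulfides=ancestor.disulfides)
            reps.append(region_rmsd(model, ancestor).rmsd["FullModel"])
        n = len(ancestor.sequence)
        se = sigma / np.sqrt(2 * n * len(reps))
        assert np.mean(reps) == pytest.approx(sigma, abs=3 * se + 0.02)

    def test_unmodeled_residues_excluded_pairwise(self, ancestor):
        partial = ancestor.coords.copy()
        partial.array[10:20] = np.nan
        model = ReceptorEntry(id="m", sequence=ancestor.sequence,
                              coords=partial,
                              tm_segments=ancestor.tm_segments,
                              disulfides=ancestor.disulfides)
        report = region_rmsd(model, ancestor)
        assert report.n_atoms["FullModel"] == len(ancestor.sequence) - 10

    def test_length_mismatch_raises(self, ancestor):
        other = ReceptorEntry(id="o", sequence="ACDE",
                              coords=BackboneCoords(np.zeros((4, 5, 3))))
        with pytest.raises(ValidationError):
            region_rmsd(other, ancestor)


class TestFoldChange:
    def test_reference_against_itself_exactly_one(self):
        runs = {"t1": [1.0, 2.0], "t2": [0.5, 1.5, 2.5]}
        table = fold_change(runs, runs)
        assert (table.per_target["method"] == 1.0).all()
        assert table.summary["method"] == 1.0

    def test_doubling_doubles_ratios(self):
        ref = {"t1": [1.0, 2.0], "t2": [3.0]}
        doubled = {t: [2 * v for v in vs] for t, vs in ref.items()}
        table = fold_change({"double": doubled, "same": ref}, ref)
        assert np.allclose(table.per_target["double"], 2.0)
        assert table.summary["double"] == pytest.approx(2.0)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            targets = [f"t{i}" for i in range(int(rng.integers(2, 8)))]
            ref = {t: rng.uniform(0.5, 5.0, rng.integers(1, 6)).tolist()
                   for t in targets}
            method = {t: rng.uniform(0.5, 5.0, rng.integers(1, 6)).tolist()
                      for t in targets}
            table = fold_change(method, ref)
            for t in targets:
                oracle = np.mean(method[t]) / np.mean(ref[t])
                assert table.per_target.loc[t, "method"] == pytest.approx(oracle)

    def test_zero_reference_flagged(self):
        table = fold_change({"t1": [1.0]}, {"t1": [0.0]})
        assert "t1" in table.flagged
        assert np.isnan(table.per_target.loc["t1", "method"])


@pytest.fixture(scope="module")
def harness_result(family_with_target):
    fam, target, templates = family_with_target
    reference = fam.member(target.id)
    return experiment_harness(
        target, reference, templates=templates,
        template_counts=[1, 3], n_models=2, n_steps=300, seed=0,
    )


class TestExperimentHarness:
    def test_shape_two_conditions_three_regions(self, harness_result):
        assert set(harness_result["condition"]) == {"1", "3"}
        assert set(harness_result["region"]) == {"TM", "ECL2", "FullModel"}
        assert len(harness_result) == 6

    def test_summary_statistics_ordered(self, harness_result):
        for _, row in harness_result.iterrows():
            assert (row["min"] <= row["q1"] <= row["median"]
                    <= row["q3"] <= row["max"])
            assert row["min"] <= row["mean"] <= row["max"]

    def test_rerun_identical(self, family_with_target):
        fam, target, templates = family_with_target
        reference = fam.member(target.id)
        kwargs = dict(templates=templates, template_counts=[1],
                      n_models=2, n_steps=200, seed=3)
        a = experiment_harness(target, reference, **kwargs)
        b = experiment_harness(target, reference, **kwargs)
        assert a.equals(b)

    def test_both_modes_rejected(self, family_with_target):
        fam, target, templates = family_with_target
        with pytest.raises(ValidationError):
            experiment_harness(target, fam.member(target.id),
                               templates=templates, template_counts=[1],
                               identity_bins={"x": templates})

    def test_empty_condition_skipped(self, family_with_target):
        fam, target, _ = family_with_target
        table = experiment_harness(
            target, fam.member(target.id),
            identity_bins={"empty": []}, n_models=1, n_steps=100, seed=0,
        )
        assert len(table) == 0
        assert table.attrs["skipped"][0][0] == "empty"
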