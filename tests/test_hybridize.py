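import numpy as np
import pytest

from helixforge import (
    HybridConfig,
    ReceptorEntry,
    ScoreWeights,
    build_fragment_library,
    build_template_msa,
    hybridize,
    make_target_annotations,
    partial_thread,
    region_rmsd,
    score,
    select_best,
)
from helixforge.errors import ValidationError
from helixforge.geometry import backbone_from_ca, ideal_helix_ca
from helixforge.hybridize_lite import HybridState, _interpolate_gaps
from helixforge.io_formats import BackboneCoords, regions_from_segments


def predicted_ss_for(entry):
    regions = regions_from_segments(entry)
    ss = ["L"] * len(entry.sequence)
    for h in range(1, 8):
        for p in regions[f"TM{h}"]:
            ss[p - 1] = "H"
    return "".join(ss)


@pytest.fixture(scope="module")
def threads_and_annotations(family_with_target):
    fam, target, templates = family_with_target
    msa = build_template_msa(templates)
    from helixforge import align_target_to_msa

    _, full = align_target_to_msa(target, msa)
    threads = [
        partial_thread(full.rows[target.id], full.rows[t.id], t,
                       target_id=target.id)
        for t in templates[:3]
    ]
    ss = predicted_ss_for(target)
    ann = make_target_annotations(threads, ss, target.disulfides)
    lib = build_fragment_library(threads, ss)
    return threads, ann, lib, target


class TestScore:
    def test_clean_helix_near_zero_strain(self):
        ca = ideal_helix_ca(30)
        bb = backbone_from_ca(ca)
        from helixforge.hybridize_lite import TargetAnnotations

        ann = TargetAnnotations(sequence="A" * 30, predicted_ss="H" * 30,
                                rg_ref=100.0)
        terms, _ = score(bb, ann)
        assert terms["clash"] == 0.0
        assert terms["chainbreak"] < 0.1
        assert terms["disulfide"] == 0.0

    def test_forced_two_angstrom_clash(self):
        ca = ideal_helix_ca(10)
        ca[5] = ca[2] + (ca[5] - ca[2]) * (2.0 / np.linalg.norm(ca[5] - ca[2]))
        bb = backbone_from_ca(ca)
        from helixforge.hybridize_lite import TargetAnnotations

        ann = TargetAnnotations(sequence="A" * 10, predicted_ss="L" * 10,
                                rg_ref=100.0)
        terms, _ = score(bb, ann)
        # the planted 2.0 A pair contributes (4.0 - 2.0)^2 = 4.0
        assert terms["clash"] >= 4.0 - 1e-6

    def test_total_is_weighted_resummation(self, threads_and_annotations):
        threads, ann, _, _ = threads_and_annotations
        coords, _ = _interpolate_gaps(threads[0])
        rng = np.random.default_rng(0)
        weights = ScoreWeights()
        wd = weights.as_dict()
        for _ in range(10):
            jitter = coords + rng.normal(scale=0.2, size=coords.shape)
            terms, total = score(jitter, ann, weights)
            oracle = sum(wd[k] * v for k, v in terms.items())
            assert total == pytest.approx(oracle, rel=1e-12)

    def test_incomplete_coordinates_rejected(self, threads_and_annotations):
        threads, ann, _, _ = threads_and_annotations
        coords = threads[0].coords.array
        if np.isfinite(coords[:, 1]).all():
            coords = coords.copy()
            coords[3] = np.nan
        with pytest.raises(ValidationError):
            score(coords, ann)


class TestFragmentLibrary:
    def test_total_coverage(self, threads_and_annotations):
        _, _, lib, target = threads_and_annotations
        L = len(target.sequence)
        for length in (3, 9):
            for p in range(1, L - length + 2):
                assert len(lib.fragments(p, length)) >= 1

    def test_ideal_fallback_always_present(self, threads_and_annotations):
        _, _, lib, target = threads_and_annotations
        for (p, ln), frags in lib.entries.items():
            assert any(tag.startswith("ideal:") for tag, _ in frags)

    def test_template_fragments_on_helices(self, threads_and_annotations):
        threads, ann, lib, target = threads_and_annotations
        regions = regions_from_segments(target)
        mid_tm1 = regions["TM3"][5]
        frags = lib.fragments(mid_tm1, 9)
        assert any(not tag.startswith("ideal:") for tag, _ in frags)


class TestHybridize:
    def test_single_template_full_coverage_stays_put(self, family_with_target):
        """One template, zero unmodeled residues, near-zero temperature:
        there is nothing to recombine, so the best model stays within
        0.5 A of the input thread."""
        fam, target, templates = family_with_target
        template = templates[0]
        msa = build_template_msa(templates)
        one = [partial_thread(msa.rows[template.id], msa.rows[template.id],
                              template, target_id="self")]
        assert one[0].coverage == 1.0
        ss = predicted_ss_for(template)
        ann = make_target_annotations(one, ss, template.disulfides)
        lib = build_fragment_library(one, ss)
        cfg = HybridConfig(n_models=1, n_steps=400, t_start=0.05, t_end=0.01)
        models = hybridize(one, lib, ann, n_models=1, seed=0, config=cfg)
        entry_a = ReceptorEntry(id="a", sequence=template.sequence,
                                coords=BackboneCoords(models[0].coords))
        masks = {"FullModel": range(1, len(template.sequence) + 1)}
        rep = region_rmsd(entry_a, template, region_masks=masks)
        assert rep.rmsd["FullModel"] < 0.5

    def test_deterministic_under_seed(self, threads_and_annotations):
        threads, ann, lib, _ = threads_and_annotations
        cfg = HybridConfig(n_models=2, n_steps=300)
        a = hybridize(threads, lib, ann, n_models=2, seed=5, config=cfg)
        b = hybridize(threads, lib, ann, n_models=2, seed=5, config=cfg)
        for x, y in zip(a, b):
            assert x.coords.tobytes() == y.coords.tobytes()
            assert x.total == y.total
            assert x.provenance == y.provenance

    def test_trace_best_non_increasing_and_final_leq_initial(
            self, threads_and_annotations):
        threads, ann, lib, _ = threads_and_annotations
        cfg = HybridConfig(n_models=3, n_steps=400)
        models = hybridize(threads, lib, ann, n_models=3, seed=2, config=cfg)
        for st in models:
            trace = np.array(st.trace_best)
            assert (np.diff(trace) <= 1e-9).all()
            assert st.total <= st.trace_accepted[0] + 1e-9
            assert st.total == pytest.approx(min(st.trace_accepted))

    def test_provenance_conservation(self, threads_and_annotations):
        threads, ann, lib, _ = threads_and_annotations
        cfg = HybridConfig(n_models=1, n_steps=300)
        models = hybridize(threads, lib, ann, n_models=1, seed=1, config=cfg)
        valid_ids = {th.template_id for th in threads}
        for tag in models[0].provenance:
            assert (tag in valid_ids or tag == "interp"
                    or tag.startswith("frag:"))

    def test_zero_templates_rejected(self, threads_and_annotations):
        _, ann, lib, _ = threads_and_annotations
        with pytest.raises(ValidationError):
            hybridize([], lib, ann)


class TestSelectBest:
    def _state(self, total, idx):
        return HybridState(coords=np.zeros((2, 5, 3)), provenance=[],
                           total=total, model_index=idx)

    def test_argmin(self):
        models = [self._state(t, i) for i, t in enumerate([3.2, 1.1, 7.0])]
        assert select_best(models).model_index == 1

    def test_tie_goes_to_lowest_index(self):
        models = [self._state(2.0, i) for i in range(4)]
        assert select_best(models).model_index == 0

    def test_random_argmin_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            totals = rng.normal(size=int(rng.integers(1, 30)))
            models = [self._state(t, i) for i, t in enumerate(totals)]
            assert select_best(models).model_index == int(np.argmin(totals))

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            select_best([])
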