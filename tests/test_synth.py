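"""Synthetic cohort generator: determinism, label bookkeeping, declines."""

import numpy as np
import pytest

from fltrad.features import suv_statistics
from fltrad.io import DegenerateVoiError, VoiMask
from fltrad.response import background_correct, percent_change
from fltrad.synth import (
    CohortConfig,
    generate_cohort,
    generate_lesion_texture,
    write_cohort,
)


@pytest.fixture()
def small_mask():
    data = np.zeros((16, 16, 16), dtype=bool)
    data[5:11, 5:11, 5:11] = True
    return VoiMask(data, (1.0, 1.0, 1.0))


class TestLesionTexture:
    def test_zero_amplitude_constant_at_max(self, small_mask):
        vol = generate_lesion_texture(small_mask, (5.0, 0.0), (1.0, 6.0), seed=1)
        np.testing.assert_allclose(vol.data[small_mask.data], 6.0)

    def test_same_seed_bit_identical(self, small_mask):
        a = generate_lesion_texture(small_mask, (5.0, 0.5), (1.0, 6.0), seed=7)
        b = generate_lesion_texture(small_mask, (5.0, 0.5), (1.0, 6.0), seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seeds_differ_but_share_max(self, small_mask):
        a = generate_lesion_texture(small_mask, (5.0, 0.5), (1.0, 6.0), seed=1)
        b = generate_lesion_texture(small_mask, (5.0, 0.5), (1.0, 6.0), seed=2)
        assert not np.array_equal(a.data, b.data)
        assert a.data.max() == pytest.approx(6.0)
        assert b.data.max() == pytest.approx(6.0)
        assert a.data[small_mask.data].min() == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        empty = VoiMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(DegenerateVoiError):
            generate_lesion_texture(empty, (5.0, 0.5), (1.0, 6.0), seed=0)


class TestCohort:
    def test_label_counts_match_config(self):
        pats, truth = generate_cohort(CohortConfig(n_patients=10, responder_fraction=0.5, seed=4))
        assert (truth["true_label"] == "responder").sum() == 5
        assert len(pats) == 10

    def test_cohort_reproducible_for_fixed_seed(self):
        cfg = CohortConfig(n_patients=3, seed=11)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(cfg)
        assert ta.equals(tb)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.flt1.data, pb.flt1.data)
            np.testing.assert_array_equal(pa.flt2.data, pb.flt2.data)

    def test_masks_disjoint_and_grids_shared(self):
        pats, _ = generate_cohort(CohortConfig(n_patients=4, seed=2))
        for p in pats:
            assert p.flt1.shape == p.flt2.shape == p.lesion_mask.shape
            assert p.flt1.spacing == p.flt2.spacing
            assert not (p.lesion_mask.data & p.contralateral_mask.data).any()
            assert p.lesion_mask.n_voxels > 0

    def test_rcb_consistent_with_label(self):
        _, truth = generate_cohort(CohortConfig(n_patients=40, seed=5))
        resp = truth[truth.true_label == "responder"]
        nonresp = truth[truth.true_label == "nonresponder"]
        assert set(resp.rcb_category) <= {"RCB-0", "RCB-I"}
        assert set(nonresp.rcb_category) <= {"RCB-II", "RCB-III"}

    def test_half_decline_halves_corrected_suv_max(self):
        cfg = CohortConfig(
            n_patients=2,
            responder_fraction=1.0,
            responder_decline=(0.5, 0.5),
            responder_complete_fraction=0.0,
            lesion_noise_sd=0.0,
            background_noise_sd=0.0,
            seed=8,
        )
        pats, truth = generate_cohort(cfg)
        for p in pats:
            s1 = background_correct(
                suv_statistics(p.flt1, p.lesion_mask),
                suv_statistics(p.flt1, p.contralateral_mask),
            )
            s2 = background_correct(
                suv_statistics(p.flt2, p.lesion_mask),
                suv_statistics(p.flt2, p.contralateral_mask),
            )
            raw1 = p.flt1.data[p.lesion_mask.data].max()
            raw2 = p.flt2.data[p.lesion_mask.data].max()
            assert raw2 == pytest.approx(0.5 * raw1, rel=1e-9)
            assert s2[0] < s1[0]

    def test_realized_responder_decline_within_configured_range(self):
        cfg = CohortConfig(
            n_patients=30,
            responder_fraction=1.0,
            responder_complete_fraction=0.0,
            lesion_noise_sd=0.0,
            background_noise_sd=0.0,
            seed=21,
        )
        pats, truth = generate_cohort(cfg)
        pcts = []
        for p in pats:
            raw1 = p.flt1.data[p.lesion_mask.data].max()
            raw2 = p.flt2.data[p.lesion_mask.data].max()
            pcts.append(percent_change(raw1, raw2))
        lo, hi = cfg.responder_decline
        assert lo * 100 <= np.mean(pcts) <= hi * 100

    def test_label_separation_of_suv_max_percent_change(self):
        """Responder and non-responder percent changes of the raw lesion
        SUV_max separate with < 5% overlap across seeds."""
        overlaps = 0
        total = 0
        for seed in range(10):
            cfg = CohortConfig(
                n_patients=10,
                responder_fraction=0.5,
                responder_complete_fraction=0.0,
                seed=seed,
            )
            pats, truth = generate_cohort(cfg)
            pcts = {}
            for p in pats:
                raw1 = p.flt1.data[p.lesion_mask.data].max()
                raw2 = p.flt2.data[p.lesion_mask.data].max()
                pcts[p.patient_id] = percent_change(raw1, raw2)
            labels = truth.set_index("patient_id")["true_label"]
            resp = [v for k, v in pcts.items() if labels[k] == "responder"]
            nonresp = [v for k, v in pcts.items() if labels[k] == "nonresponder"]
            cut = (min(resp) + max(nonresp)) / 2
            misclassified = sum(v < cut for v in resp) + sum(v >= cut for v in nonresp)
            overlaps += misclassified
            total += len(pats)
        assert overlaps / total < 0.05

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            CohortConfig(responder_fraction=1.2)
        with pytest.raises(ValueError):
            CohortConfig(responder_decline=(0.7, 0.4))


def test_write_cohort_roundtrip(tmp_path):
    from fltrad.io import read_mask, read_volume

    pats, truth = generate_cohort(CohortConfig(n_patients=2, seed=6))
    outdir = write_cohort(pats, truth, tmp_path / "cohort")
    assert (outdir / "manifest.csv").exists()
    back = read_volume(outdir / "P001" / "flt1.nii.gz")
    np.testing.assert_allclose(back.data, pats[0].flt1.data, rtol=1e-6)
    mask = read_mask(outdir / "P001" / "lesion.nii.gz")
    np.testing.assert_array_equal(mask.data, pats[0].lesion_mask.data)
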