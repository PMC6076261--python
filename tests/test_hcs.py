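"""HCS pipeline: segmentation, regions, viability, puncta, endpoints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from punctaflux import hcs, synthgen
from punctaflux.hcs import HcsConfig
from punctaflux.types import CellRecord, LabeledField


def field_from(nuclear=None, viability=None, gfp=None, fill=0.0, shape=None):
    given = [np.asarray(a) for a in (nuclear, viability, gfp) if a is not None]
    if shape is None:
        shape = given[0].shape if given else (32, 32)
    base = {name: np.full(shape, fill, dtype=float)
            for name in ("nuclear", "viability", "gfp")}
    for name, arr in (("nuclear", nuclear), ("viability", viability),
                      ("gfp", gfp)):
        if arr is not None:
            base[name] = np.asarray(arr, dtype=float)
    return LabeledField(channels=base)


class TestFormFactor:
    # frozen expected values from per-pixel edge counting:
    # 1 px: A=1 P=4; 3x3: A=9 P=12; 1x10 line: A=10 P=22
    @pytest.mark.parametrize("pixels, expected", [
        ([(0, 0)], 4 * math.pi / 16),
        ([(r, c) for r in range(3) for c in range(3)], 4 * math.pi * 9 / 144),
        ([(0, c) for c in range(10)], 4 * math.pi * 10 / 484),
    ])
    def test_reference_shapes(self, pixels, expected):
        assert hcs.form_factor(np.array(pixels)) == pytest.approx(expected)

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError):
            hcs.form_factor(np.empty((0, 2)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_bruteforce_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(12, 12)) < 0.35
        for comp in oracles.flood_fill_components(mask):
            px = np.array(sorted(comp))
            assert hcs.form_factor(px) == pytest.approx(
                oracles.form_factor_bruteforce(comp))

    def test_ff_bounded_by_pi_over_4(self, rng):
        for _ in range(20):
            mask = rng.uniform(size=(10, 10)) < 0.4
            for comp in oracles.flood_fill_components(mask):
                ff = hcs.form_factor(np.array(sorted(comp)))
                assert 0.0 < ff <= math.pi / 4 + 1e-12


class TestSegmentNuclei:
    def test_constant_image_warns_and_returns_empty(self):
        field = field_from(fill=5.0)
        with pytest.warns(UserWarning, match="constant"):
            labels = hcs.segment_nuclei(field)
        assert labels.max() == 0

    def test_two_discs_match_thresholded_mask(self):
        img = np.zeros((40, 40))
        rr, cc = np.mgrid[0:40, 0:40]
        d1 = np.hypot(rr - 10, cc - 10) <= 4
        d2 = np.hypot(rr - 30, cc - 30) <= 4
        img[d1] = 100.0
        img[d2] = 100.0
        field = field_from(nuclear=img)
        labels = hcs.segment_nuclei(field, HcsConfig(nuclear_threshold=50.0))
        assert labels.max() == 2
        comps = oracles.flood_fill_components(img > 50.0)
        got = [set(map(tuple, np.argwhere(labels == k))) for k in (1, 2)]
        assert {frozenset(c) for c in comps} == {frozenset(g) for g in got}

    def test_counts_generated_nuclei(self, hcs_field_clean):
        (field, gt), spec = hcs_field_clean
        labels = hcs.segment_nuclei(field)
        assert labels.max() == len(gt.cells)

    def test_missing_channel_raises(self):
        field = LabeledField(channels={"gfp": np.zeros((8, 8))})
        with pytest.raises(KeyError):
            hcs.segment_nuclei(field)


class TestCellRegions:
    def test_single_nucleus_full_clipped_disc(self):
        labels = np.zeros((21, 21), dtype=int)
        labels[10, 10] = 1
        cells = hcs.define_cell_regions(labels, radius_px=6.0)
        expected = oracles.nearest_centroid_regions((21, 21), [(10, 10)], 6.0)
        assert set(map(tuple, cells[0].cell_region)) == \
            set(map(tuple, np.argwhere(expected == 0)))

    def test_two_nuclei_split_along_bisector(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[15, 8] = 1
        labels[15, 22] = 2
        cells = hcs.define_cell_regions(labels, radius_px=10.0)
        expected = oracles.nearest_centroid_regions(
            (30, 30), [(15, 8), (15, 22)], 10.0)
        for k, cell in enumerate(cells):
            assert set(map(tuple, cell.cell_region)) == \
                set(map(tuple, np.argwhere(expected == k)))
        # pairwise disjoint
        a = set(map(tuple, cells[0].cell_region))
        b = set(map(tuple, cells[1].cell_region))
        assert not (a & b)

    def test_corner_nucleus_clipped_to_bounds(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[0, 0] = 1
        cells = hcs.define_cell_regions(labels, radius_px=5.0)
        region = cells[0].cell_region
        assert region.min() >= 0
        assert region.max() < 16

    def test_nucleus_pixels_inside_own_region(self, hcs_field_clean):
        (field, _), spec = hcs_field_clean
        labels = hcs.segment_nuclei(field)
        cells = hcs.define_cell_regions(labels, spec.cell_radius_px)
        for cell in cells[:10]:
            region = set(map(tuple, cell.cell_region))
            assert set(map(tuple, cell.nucleus_pixels)) <= region

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            hcs.define_cell_regions(np.zeros((4, 4), dtype=int), 0.0)


def _square_cell(label=1, origin=(0, 0), size=10):
    r0, c0 = origin
    region = np.array([(r, c) for r in range(r0, r0 + size)
                       for c in range(c0, c0 + size)])
    return CellRecord(nucleus_label=label, center=(r0 + size / 2, c0 + size / 2),
                      nucleus_pixels=region[:4], cell_region=region)


class TestViability:
    def test_exact_half_overlap_is_dead(self):
        """The 50% rule is inclusive: overlap exactly 0.50 classifies dead."""
        cell = _square_cell()
        via = np.zeros((12, 12))
        via[0:5, 0:10] = 10.0  # 50 of 100 region pixels
        field = field_from(viability=via, shape=(12, 12))
        hcs.classify_viability([cell], field, cfg=HcsConfig(viability_threshold=5.0))
        assert cell.ethd1_overlap == pytest.approx(0.5)
        assert cell.viability == "dead"

    def test_no_signal_all_live(self):
        cell = _square_cell()
        field = field_from(shape=(12, 12))
        hcs.classify_viability([cell], field, cfg=HcsConfig(viability_threshold=5.0))
        assert cell.viability == "live"

    def test_37_of_100_pixels_is_live(self):
        cell = _square_cell()
        via = np.zeros((12, 12))
        flat = [(r, c) for r in range(10) for c in range(10)][:37]
        for r, c in flat:
            via[r, c] = 10.0
        field = field_from(viability=via, shape=(12, 12))
        hcs.classify_viability([cell], field, cfg=HcsConfig(viability_threshold=5.0))
        assert cell.ethd1_overlap == pytest.approx(0.37)
        assert cell.viability == "live"

    def test_raising_threshold_never_increases_dead_count(self, hcs_field_noisy):
        (field, _), spec = hcs_field_noisy
        labels = hcs.segment_nuclei(field)
        cells = hcs.define_cell_regions(labels, spec.cell_radius_px)
        dead_counts = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            hcs.classify_viability(cells, field, dead_overlap_threshold=thr)
            dead_counts.append(sum(c.viability == "dead" for c in cells))
        assert dead_counts == sorted(dead_counts, reverse=True)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            hcs.classify_viability([], field_from(), dead_overlap_threshold=0.0)


class TestDetectPuncta:
    def test_empty_channel_no_puncta(self):
        cells = [_square_cell()]
        field = field_from(shape=(16, 16))
        puncta = hcs.detect_puncta(field, cells,
                                   HcsConfig(gfp_threshold=5.0))
        assert puncta == []

    def test_square_kept_line_rejected(self):
        """3x3 square (FF≈0.785) passes the 0.4 cutoff; a 1x10 line
        (FF≈0.26) is rejected."""
        gfp = np.zeros((16, 16))
        gfp[2:5, 2:5] = 10.0
        gfp[10, 3:13] = 10.0
        cells = [_square_cell(size=16)]
        field = field_from(gfp=gfp, shape=(16, 16))
        puncta = hcs.detect_puncta(field, cells, HcsConfig(gfp_threshold=5.0))
        assert len(puncta) == 1
        comp = {(r, c) for r in range(2, 5) for c in range(2, 5)}
        assert set(map(tuple, puncta[0].pixels)) == comp
        assert puncta[0].form_factor == pytest.approx(
            oracles.form_factor_bruteforce(comp))

    def test_counts_match_ground_truth_noiseless(self, hcs_field_clean):
        (field, gt), spec = hcs_field_clean
        cfg = HcsConfig(cell_radius_px=spec.cell_radius_px)
        cells, _, _ = hcs.quantify_field(field, cfg)
        from punctaflux import metrics
        mapping = metrics.match_cells(gt, cells)
        assert len(mapping) == len(gt.cells)
        truth = gt.per_cell_counts
        for gi, ci in mapping.items():
            assert cells[ci].n_puncta == truth[gi]

    def test_raising_min_ff_never_increases_count(self, rng):
        gfp = (rng.uniform(size=(48, 48)) < 0.15) * 10.0
        cells = [_square_cell(size=48)]
        field = field_from(gfp=gfp, shape=(48, 48))
        counts = []
        for ff_min in (0.1, 0.3, 0.5, 0.7):
            n = len(hcs.detect_puncta(field, cells,
                                      HcsConfig(gfp_threshold=5.0,
                                                min_form_factor=ff_min)))
            counts.append(n)
        assert counts == sorted(counts, reverse=True)

    def test_raising_min_area_never_increases_count(self, rng):
        gfp = (rng.uniform(size=(48, 48)) < 0.2) * 10.0
        cells = [_square_cell(size=48)]
        field = field_from(gfp=gfp, shape=(48, 48))
        counts = [len(hcs.detect_puncta(field, cells,
                                        HcsConfig(gfp_threshold=5.0,
                                                  min_punctum_area=a)))
                  for a in (1, 2, 4, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cfg_rejected(self):
        field = field_from(shape=(8, 8))
        with pytest.raises(ValueError):
            hcs.detect_puncta(field, [], HcsConfig(min_punctum_area=0))
        with pytest.raises(ValueError):
            hcs.detect_puncta(field, [], HcsConfig(min_form_factor=0.9))


class TestSummarize:
    def _cells_with_counts(self, counts, viability="live"):
        cells = []
        for k, n in enumerate(counts):
            cell = _square_cell(label=k + 1)
            cell.viability = viability
            cell.puncta = [object()] * n
            cells.append(cell)
        return cells

    def test_fraction_with_min_puncta(self):
        cells = self._cells_with_counts([0, 1, 5, 5, 6, 2, 0, 7, 3, 5])
        s = hcs.summarize_field(cells, min_puncta=5)
        assert s.frac_live_with_min_puncta == pytest.approx(0.5)
        assert s.n_live == 10 and s.n_dead == 0

    def test_all_dead_flagged_undefined(self):
        cells = self._cells_with_counts([1, 2], viability="dead")
        s = hcs.summarize_field(cells)
        assert s.undefined and s.frac_live_with_min_puncta is None

    def test_identity_normalization(self):
        cells = self._cells_with_counts([5, 5, 0, 0])
        base = hcs.summarize_field(cells, min_puncta=5)
        s = hcs.summarize_field(cells, min_puncta=5, control_summaries=[base])
        assert s.normalized_value == pytest.approx(1.0)

    def test_unassigned_viability_rejected(self):
        with pytest.raises(ValueError):
            hcs.summarize_field([_square_cell()])


def test_end_to_end_determinism(hcs_field_noisy):
    (field, _), spec = hcs_field_noisy
    cfg = HcsConfig(cell_radius_px=spec.cell_radius_px)
    _, _, s1 = hcs.quantify_field(field, cfg)
    _, _, s2 = hcs.quantify_field(field, cfg)
    assert s1 == s2
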