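"""Marker scoring over fibres, cells and tissue region classes."""

import numpy as np
import pytest

from mdxquant import markers
from mdxquant.centronucleation import NucleusRecord
from mdxquant.io_core import ChannelImage, FiberLabelMap, RegionClassMap


def _square_fibers(n=4, size=10, gap=4, ps=1.0):
    side = n * (size + gap) + gap
    labels = np.zeros((side, side), np.int32)
    lid = 0
    for i in range(n):
        for j in range(n):
            lid += 1
            r = gap + i * (size + gap)
            c = gap + j * (size + gap)
            labels[r : r + size, c : c + size] = lid
    return FiberLabelMap(labels, ps)


class TestPositiveFiberFraction:
    def test_zero_channel_gives_zero(self):
        fibers = _square_fibers()
        img = ChannelImage(np.zeros(fibers.labels.shape), 1.0, "IgM")
        score = markers.positive_fiber_fraction(img, fibers)
        assert score.value == 0.0

    def test_saturated_channel_gives_one(self):
        fibers = _square_fibers()
        img = ChannelImage(np.full(fibers.labels.shape, 100.0), 1.0, "IgM")
        score = markers.positive_fiber_fraction(
            img, fibers, threshold_method="fixed", fixed_threshold=50.0,
            min_positive_area_fraction=0.0,
        )
        assert score.value == 1.0

    def test_exact_positive_subset_recovered(self):
        fibers = _square_fibers()
        img = np.zeros(fibers.labels.shape)
        img[np.isin(fibers.labels, [1, 5, 9])] = 150.0
        score = markers.positive_fiber_fraction(
            ChannelImage(img, 1.0, "IgM"), fibers
        )
        assert score.positive_ids == frozenset({1, 5, 9})
        assert score.value == pytest.approx(3 / 16)

    def test_empty_fiber_set_raises(self):
        fibers = _square_fibers()
        img = ChannelImage(np.zeros(fibers.labels.shape), 1.0, "IgM")
        with pytest.raises(ValueError):
            markers.positive_fiber_fraction(img, fibers, retained_ids=set())

    def test_phantom_igm_recovery(self, small_phantom):
        _, channels, _, truth = small_phantom
        fibers = truth.fiber_labels
        score = markers.positive_fiber_fraction(channels["IgM"], fibers)
        true_frac = len(truth.igm_fiber_ids) / len(truth.fiber_ids)
        assert score.value == pytest.approx(true_frac, abs=0.03)


class TestPositiveFiberDensity:
    def test_twelve_fibers_per_mm2(self):
        # 100x100 px at 10 µm/px = exactly 1 mm² of tissue
        labels = np.zeros((100, 100), np.int32)
        for k in range(12):
            r, c = divmod(k, 4)
            labels[5 + r * 30 : 10 + r * 30, 5 + c * 20 : 10 + c * 20] = k + 1
        fibers = FiberLabelMap(labels, 10.0)
        img = ChannelImage((labels > 0) * 200.0, 10.0, "eMyHC")
        score = markers.positive_fiber_density(
            img, fibers, np.ones((100, 100), bool),
            threshold_method="fixed", fixed_threshold=100.0,
        )
        assert score.value == pytest.approx(12.0)

    def test_no_positive_fibers_zero_density(self):
        fibers = _square_fibers()
        img = ChannelImage(np.zeros(fibers.labels.shape), 1.0, "eMyHC")
        score = markers.positive_fiber_density(
            img, fibers, np.ones(fibers.labels.shape, bool)
        )
        assert score.value == 0.0

    def test_zero_tissue_raises(self):
        fibers = _square_fibers()
        img = ChannelImage(np.zeros(fibers.labels.shape), 1.0, "eMyHC")
        with pytest.raises(ValueError, match="tissue"):
            markers.positive_fiber_density(
                img, fibers, np.zeros(fibers.labels.shape, bool)
            )

    def test_density_scales_with_calibration(self):
        labels = _square_fibers(ps=1.0).labels
        img_mask = (labels > 0) * 200.0
        tissue = np.ones(labels.shape, bool)
        kwargs = dict(threshold_method="fixed", fixed_threshold=100.0)
        d1 = markers.positive_fiber_density(
            ChannelImage(img_mask, 1.0), FiberLabelMap(labels, 1.0), tissue, **kwargs
        ).value
        d2 = markers.positive_fiber_density(
            ChannelImage(img_mask, 2.0), FiberLabelMap(labels, 2.0), tissue, **kwargs
        ).value
        assert d2 == pytest.approx(d1 / 4.0)


class TestPositiveCellFraction:
    def _cells(self, n, shape=(60, 200)):
        return [
            NucleusRecord(i + 1, 0, (30.0, 15.0 + 18.0 * i), 20.0) for i in range(n)
        ]

    def test_zero_channel_zero_fraction(self):
        img = ChannelImage(np.zeros((60, 200)), 1.0, "PDGFRA")
        score = markers.positive_cell_fraction(img, self._cells(5))
        assert score.value == 0.0

    def test_all_above_fixed_threshold(self):
        img = ChannelImage(np.full((60, 200), 120.0), 1.0, "PDGFRA")
        score = markers.positive_cell_fraction(
            img, self._cells(5), threshold_method="fixed", fixed_threshold=50.0
        )
        assert score.value == 1.0

    def test_no_cells_raises(self):
        img = ChannelImage(np.zeros((10, 10)), 1.0, "PDGFRA")
        with pytest.raises(ValueError):
            markers.positive_cell_fraction(img, [])

    def test_phantom_fap_fraction_recovery(self, clean_phantom):
        """The generated PDGFRA⁺ fraction of all cells is recovered ± 0.05."""
        _, channels, _, truth = clean_phantom
        df = truth.nucleus_dataframe()
        from mdxquant import centronucleation as cn

        recs = cn.assign_nuclei(
            df[["nucleus_id", "centroid_row", "centroid_col", "area_um2"]],
            truth.fiber_labels,
        )
        score = markers.positive_cell_fraction(channels["PDGFRA"], recs)
        true_frac = len(truth.pdgfra_cell_ids) / len(truth.nucleus_table)
        assert score.value == pytest.approx(true_frac, abs=0.05)


class TestClassifyRegions:
    def test_blank_channels_all_healthy(self):
        tissue = np.zeros((50, 50), bool)
        tissue[5:45, 5:45] = True
        rm = markers.classify_regions(
            ChannelImage(np.zeros((50, 50)), 1.0, "F4-80"),
            ChannelImage(np.zeros((50, 50)), 1.0, "eMyHC"),
            tissue,
        )
        assert np.array_equal(rm.mask("healthy"), tissue)

    def test_classes_partition_tissue(self, small_phantom):
        _, channels, _, truth = small_phantom
        tissue = truth.tissue_mask
        rm = markers.classify_regions(channels["F4-80"], channels["eMyHC"], tissue)
        total = rm.mask("damage") | rm.mask("repair") | rm.mask("healthy")
        assert np.array_equal(total, tissue)
        assert not (rm.mask("damage") & rm.mask("repair")).any()

    def test_phantom_region_accuracy(self, small_phantom):
        """Per-pixel region recovery >= 90% against the generated truth."""
        _, channels, _, truth = small_phantom
        rm = markers.classify_regions(
            channels["F4-80"], channels["eMyHC"], truth.tissue_mask
        )
        t = truth.tissue_mask
        acc = (rm.classes[t] == truth.region_class_map.classes[t]).mean()
        assert acc >= 0.90


class TestRegionNormalizedScore:
    def _regions(self):
        classes = np.zeros((60, 90), np.uint8)
        classes[:, :30] = RegionClassMap.CODES["damage"]
        classes[:, 30:60] = RegionClassMap.CODES["repair"]
        classes[:, 60:] = RegionClassMap.CODES["healthy"]
        return RegionClassMap(classes, 1.0)

    def test_half_damage_coverage(self):
        regions = self._regions()
        img = np.zeros((60, 90))
        img[:30, :30] = 200.0  # exactly half of the damage class
        scores = markers.region_normalized_score(
            ChannelImage(img, 1.0, "p-SMAD2"), regions,
            threshold_method="fixed", fixed_threshold=100.0,
        )
        assert scores == {"damage": 0.5, "repair": 0.0, "healthy": 0.0}

    def test_uniform_saturation_scores_one_everywhere(self):
        scores = markers.region_normalized_score(
            ChannelImage(np.full((60, 90), 250.0), 1.0), self._regions(),
            threshold_method="fixed", fixed_threshold=100.0,
        )
        assert scores == {"damage": 1.0, "repair": 1.0, "healthy": 1.0}

    def test_empty_class_reported_missing(self):
        classes = np.zeros((20, 20), np.uint8)
        classes[5:15, 5:15] = RegionClassMap.CODES["healthy"]
        scores = markers.region_normalized_score(
            ChannelImage(np.zeros((20, 20)), 1.0), RegionClassMap(classes, 1.0)
        )
        assert scores["damage"] is None and scores["repair"] is None
        assert scores["healthy"] == 0.0

    def test_all_background_raises(self):
        with pytest.raises(ValueError):
            markers.region_normalized_score(
                ChannelImage(np.zeros((10, 10)), 1.0),
                RegionClassMap(np.zeros((10, 10), np.uint8), 1.0),
            )

    def test_phantom_per_class_positivity(self, small_phantom):
        """Generated per-class p-SMAD2 rates are recovered ± 0.05."""
        spec, channels, _, truth = small_phantom
        scores = markers.region_normalized_score(
            channels["p-SMAD2"], truth.region_class_map
        )
        for name, rate in zip(("damage", "repair", "healthy"), spec.psmad2_positivity):
            if scores[name] is not None:
                assert scores[name] == pytest.approx(rate, abs=0.05)
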