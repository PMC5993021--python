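"""Inclusive-mask construction and barcode-based population assignment."""

import itertools

import numpy as np
import pytest

from _oracles import border_flood_background
from conftest import small_spec
from wellcyto.populations import (
    MULTI_POSITIVE,
    NEGATIVE,
    PopulationDef,
    absolute_counts,
    assign_barcodes,
    filter_nuclei_by_mask,
    make_population_mask,
    relative_counts,
)
from wellcyto.segment import NucleiParams, count_objects, segment_nuclei
from wellcyto.synthetic import render_well


def annulus_image(shape=(60, 60), center=(30, 30), r_out=15, r_in=10, value=2000.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    img = np.zeros(shape)
    img[(d2 <= r_out**2) & (d2 >= r_in**2)] = value
    return img


class TestMakePopulationMask:
    def test_blank_stain_gives_empty_mask(self):
        params = PopulationDef(name="a", stain_channel="cytoplasmic")
        mask = make_population_mask(np.zeros((50, 50)), params)
        assert mask.dtype == bool and not mask.any()

    def test_surface_ring_fills_to_disk_identified_by_flood_fill_oracle(self):
        """Hole filling turns the surface-stain annulus into a full disk:
        exactly the pixels a border flood fill cannot reach."""
        img = annulus_image()
        params = PopulationDef(name="a", stain_channel="surface")
        mask = make_population_mask(img, params)
        ring = img > 0
        hole = ~ring & ~border_flood_background(ring)
        assert hole.sum() > 0
        assert np.array_equal(mask, ring | hole)

    def test_mask_is_inclusive_on_noise_free_cytoplasm(self):
        """On clean input the mask covers at least 99 % of true cell-body
        pixels of the population."""
        spec = small_spec(
            n_cells=20, seed=13, stains=("nuclear", "cytoplasmic"),
            stain_inhomogeneity=0.2,
        )
        wellset, _ = render_well(spec)
        cyto = wellset.channel("cytoplasmic")
        params = PopulationDef(name="a", stain_channel="cytoplasmic")
        mask = make_population_mask(cyto, params)
        true_body = cyto > 0
        assert mask[true_body].mean() >= 0.99


class TestFilterNucleiByMask:
    def _three_nuclei(self):
        nuclei = np.zeros((30, 30), dtype=np.int32)
        nuclei[2:12, 2:12] = 1   # 100 px
        nuclei[2:12, 15:25] = 2  # 100 px
        nuclei[20:30, 2:12] = 3  # 100 px
        return nuclei

    def test_overlap_fractions_against_pixel_intersection_oracle(self):
        nuclei = self._three_nuclei()
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:12, 2:12] = True       # nucleus 1 fully covered
        mask[2:12, 15:21] = True      # nucleus 2: 60 of 100 px
        mask[20:21, 2:12] = True      # nucleus 3: 10 of 100 px
        # oracle: brute-force per-pixel intersection counts
        for lbl, expected in ((1, 1.0), (2, 0.6), (3, 0.1)):
            inter = sum(
                1
                for i, j in itertools.product(range(30), range(30))
                if nuclei[i, j] == lbl and mask[i, j]
            )
            assert inter / 100 == expected
        out = filter_nuclei_by_mask(nuclei, mask, min_overlap_fraction=0.5)
        assert count_objects(out) == 2
        # retained pixel sets unchanged, labels contiguous
        assert np.array_equal(out > 0, (nuclei == 1) | (nuclei == 2))
        assert sorted(np.unique(out).tolist()) == [0, 1, 2]

    def test_full_mask_is_identity_on_counts(self):
        nuclei = self._three_nuclei()
        out = filter_nuclei_by_mask(nuclei, np.ones((30, 30), dtype=bool), 0.5)
        assert count_objects(out) == 3

    def test_empty_mask_removes_everything(self):
        nuclei = self._three_nuclei()
        out = filter_nuclei_by_mask(nuclei, np.zeros((30, 30), dtype=bool), 0.5)
        assert count_objects(out) == 0

    def test_enlarging_mask_never_decreases_retained_count(self, rng):
        nuclei = self._three_nuclei()
        mask = rng.random((30, 30)) > 0.6
        grown = mask | (rng.random((30, 30)) > 0.5)
        n_small = count_objects(filter_nuclei_by_mask(nuclei, mask, 0.5))
        n_large = count_objects(filter_nuclei_by_mask(nuclei, grown, 0.5))
        assert n_large >= n_small


class TestBarcodes:
    def _nuclei_and_masks(self):
        nuclei = np.zeros((20, 40), dtype=np.int32)
        nuclei[5:10, 2:7] = 1
        nuclei[5:10, 15:20] = 2
        nuclei[5:10, 30:35] = 3
        mask_a = np.zeros((20, 40), dtype=bool)
        mask_a[:, :12] = True        # covers nucleus 1
        mask_b = np.zeros((20, 40), dtype=bool)
        mask_b[:, 13:22] = True      # covers nucleus 2
        mask_b[:, :12] = True        # ... and also nucleus 1 (double)
        pops = [
            PopulationDef(name="A", stain_channel="cytoplasmic"),
            PopulationDef(name="B", stain_channel="surface"),
        ]
        return nuclei, pops, [mask_a, mask_b]

    def test_single_double_and_negative_classes(self):
        nuclei, pops, masks = self._nuclei_and_masks()
        table = assign_barcodes(nuclei, pops, masks, 0.5)
        assert table["barcode"].tolist() == ["A+B+", "A-B+", "A-B-"]
        assert table["population_class"].tolist() == [MULTI_POSITIVE, "B", NEGATIVE]

    def test_counts_conserve_total_nuclei(self):
        nuclei, pops, masks = self._nuclei_and_masks()
        table = assign_barcodes(nuclei, pops, masks, 0.5)
        counts = absolute_counts(table, pops)
        assert sum(counts.values()) == 3
        assert counts == {"A": 0, "B": 1, MULTI_POSITIVE: 1, NEGATIVE: 1}

    def test_population_order_has_no_effect_on_memberships(self):
        nuclei, pops, masks = self._nuclei_and_masks()
        fwd = assign_barcodes(nuclei, pops, masks, 0.5)
        rev = assign_barcodes(nuclei, pops[::-1], masks[::-1], 0.5)
        assert fwd["population_class"].tolist() == rev["population_class"].tolist()

    def test_mask_population_mismatch_rejected(self):
        nuclei, pops, masks = self._nuclei_and_masks()
        with pytest.raises(ValueError, match="masks"):
            assign_barcodes(nuclei, pops, masks[:1], 0.5)

    def test_synthetic_disjoint_populations_recover_truth_counts(self):
        """Noise-free 50:50-ish two-population well with disjoint stains:
        barcode class counts equal the rendered population sizes."""
        from wellcyto.synthetic import SyntheticPopulation, SyntheticWellSpec

        spec = SyntheticWellSpec(
            well_diameter_px=400,
            tile_size_px=400,
            populations=(
                SyntheticPopulation(
                    name="A", n_cells=25, stain_channels=("nuclear", "cytoplasmic")
                ),
                SyntheticPopulation(
                    name="B", n_cells=25, stain_channels=("nuclear", "surface")
                ),
            ),
            vignette_strength=0.0,
            edge_ring_amplitude=0.0,
            gaussian_sd=0.0,
            rng_seed=17,
            spacing="cell",
        )
        wellset, truth = render_well(spec)
        nuclei = segment_nuclei(wellset.channel("nuclear"), NucleiParams())
        pops = [
            PopulationDef(name="A", stain_channel="cytoplasmic"),
            PopulationDef(name="B", stain_channel="surface"),
        ]
        masks = [
            make_population_mask(wellset.channel(p.stain_channel), p) for p in pops
        ]
        counts = absolute_counts(assign_barcodes(nuclei, pops, masks, 0.5), pops)
        assert counts["A"] == 25
        assert counts["B"] == 25
        assert sum(counts.values()) == len(truth)


class TestRelativeCounts:
    def test_percentages(self):
        rel = relative_counts({"A": 200, "B": 800})
        assert rel == {"A": 20.0, "B": 80.0}

    def test_single_class_is_all(self):
        assert relative_counts({"A": 7}) == {"A": 100.0}

    def test_sum_is_hundred(self, rng):
        counts = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1, 50, 5))}
        assert sum(relative_counts(counts).values()) == pytest.approx(100.0)

    def test_empty_total_is_explicit_error(self):
        with pytest.raises(ValueError, match="total = 0"):
            relative_counts({"A": 0, "B": 0})

    def test_relative_share_can_rise_while_absolute_count_falls(self):
        """The ordering inversion: between two conditions population A's
        absolute count drops yet its relative share grows because B falls
        faster — the trap of percentage-only readouts."""
        cond1 = {"A": 200, "B": 800}
        cond2 = {"A": 180, "B": 220}
        assert cond2["A"] < cond1["A"]  # absolute count falls
        rel1, rel2 = relative_counts(cond1), relative_counts(cond2)
        assert rel2["A"] > rel1["A"]  # relative share rises
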