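"""Colocalization, mother/daughter asymmetry, inheritance and statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimquant.detection import CellROI, FocusRecord
from slimquant.population import (colocalize, compare_conditions, fold_changes,
                                  inheritance_score, mother_daughter_stats)
from slimquant.simulate import disk_mask


def _focus(cell_id, row, col, area=1.0, intensity=100.0, fid=0):
    return FocusRecord(focus_id=fid, cell_id=cell_id, frame=0,
                       centroid=(row, col), area_px=4, area_um2=area,
                       integrated_intensity=intensity, mean_intensity=intensity / 4,
                       background_intensity=0.0)


class TestColocalize:
    def test_centroid_inside_mask_is_colocalized(self):
        mask = disk_mask((40, 40), (20, 20), 5)
        res = colocalize([(20.0, 20.0)], mask, pixel_size_nm=120.0)
        assert res.n_colocalized == 1 and res.fraction == 100.0

    def test_one_micron_away_is_not(self):
        mask = disk_mask((60, 60), (30, 30), 5)
        # 5 px radius + 1 µm  (~8.3 px at 120 nm/px) away from the edge
        res = colocalize([(30.0, 30 + 5 + 8.4)], mask, pixel_size_nm=120.0,
                         max_distance=250.0)
        assert res.n_colocalized == 0

    def test_zero_foci_rejected(self):
        with pytest.raises(ValueError):
            colocalize([], disk_mask((10, 10), (5, 5), 2), 120.0)

    def test_random_placement_matches_geometric_null(self):
        # uniform foci in a cell: expected colocalized fraction equals the
        # area fraction of the (dilated) organelle within the cell
        rng = np.random.default_rng(0)
        px = 120.0
        cell = disk_mask((100, 100), (50, 50), 40)
        org = disk_mask((100, 100), (40, 55), 10)
        from scipy.ndimage import distance_transform_edt
        dil = distance_transform_edt(~org) * px <= 250.0
        p_true = (dil & cell).sum() / cell.sum()
        rows, cols = np.nonzero(cell)
        idx = rng.integers(0, rows.size, 1000)
        pts = list(zip(rows[idx].astype(float), cols[idx].astype(float)))
        res = colocalize(pts, org, pixel_size_nm=px, max_distance=250.0)
        se = np.sqrt(p_true * (1 - p_true) / 1000)
        assert abs(res.fraction / 100 - p_true) < 3 * se

    def test_fraction_monotone_in_distance(self):
        rng = np.random.default_rng(1)
        org = disk_mask((80, 80), (40, 40), 6)
        pts = [(rng.uniform(0, 79), rng.uniform(0, 79)) for _ in range(200)]
        fracs = [colocalize(pts, org, 120.0, max_distance=d).fraction
                 for d in (0, 100, 250, 500, 1000, 2000)]
        assert fracs == sorted(fracs)


class TestMotherDaughter:
    def _rois(self):
        m = CellROI(1, np.zeros((4, 4), bool), role="mother")
        d = CellROI(2, np.zeros((4, 4), bool), role="daughter")
        return [m, d]

    def test_trivial_means(self):
        foci = [_focus(1, 0, 0, area=1.0, fid=1), _focus(1, 1, 1, area=1.0, fid=2),
                _focus(2, 2, 2, area=0.4, fid=3)]
        df = mother_daughter_stats(foci, self._rois())
        assert df.set_index("role").loc["mother", "mean_area"] == pytest.approx(1.0)
        assert df.set_index("role").loc["daughter", "mean_area"] == pytest.approx(0.4)

    def test_role_without_foci_flagged_empty(self):
        foci = [_focus(1, 0, 0, fid=1)]
        df = mother_daughter_stats(foci, self._rois())
        row = df.set_index("role").loc["daughter"]
        assert bool(row["empty"]) and np.isnan(row["mean_area"])

    def test_generator_area_ratio_recovered(self):
        # mothers carry foci ~2.5x the daughters' area
        rng = np.random.default_rng(2)
        foci = [_focus(1, 0, 0, area=a, fid=i)
                for i, a in enumerate(rng.normal(1.0, 0.08, 60))]
        foci += [_focus(2, 0, 0, area=a, fid=100 + i)
                 for i, a in enumerate(rng.normal(0.4, 0.05, 40))]
        df = mother_daughter_stats(foci, self._rois()).set_index("role")
        ratio = df.loc["mother", "mean_area"] / df.loc["daughter", "mean_area"]
        assert ratio == pytest.approx(2.5, rel=0.15)


class TestInheritance:
    def test_retain_fixture_scores_zero(self, vacuole_timelapse):
        stack = vacuole_timelapse
        lin = stack.lineage
        px = stack.config.pixel_size_um
        foci = {t: [(tr.trajectory[t][1] / px, tr.trajectory[t][0] / px)
                    for tr in stack.truths]
                for t in range(stack.config.n_frames)}
        masks = dict(enumerate(lin["cell_masks_per_frame"]))
        orgs = dict(enumerate(lin["organelle_masks_per_frame"]))
        res = inheritance_score(foci, masks, orgs)
        assert res.inherited_fraction == 0.0
        # conservation: mother + bud = total at every timepoint
        for m, b in zip(res.mother_counts, res.bud_counts):
            assert m + b == len(stack.truths)
        # organelle (vacuole) first reaches the bud at the 20-min frame
        first = next(i for i, f in enumerate(res.organelle_in_bud) if f)
        assert res.frames[first] * lin["frame_interval_min"] == pytest.approx(20.0)

    def test_single_transfer_gives_one_over_n(self):
        masks = {0: np.ones((10, 10), np.uint16)}
        masks[0][:, 6:] = 2
        foci = {0: [(2.0, 2.0), (3.0, 3.0), (5.0, 8.0)]}
        res = inheritance_score(foci, masks)
        assert res.inherited_fraction == pytest.approx(1 / 3)

    def test_missing_mask_skipped_with_warning(self):
        masks = {0: np.ones((5, 5), np.uint16)}
        foci = {0: [(1.0, 1.0)], 1: [(1.0, 1.0)]}
        with pytest.warns(UserWarning):
            res = inheritance_score(foci, masks)
        assert res.frames == [0]


def _brute_force_U(a, b):
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


class TestCompareConditions:
    def test_identical_samples_t(self):
        stat, p = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "student_t")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_degenerate_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            stat, p = compare_conditions([5.0] * 4, [5.0] * 4, "student_t")
        assert (stat, p) == (0.0, 1.0)

    def test_fully_separated_small_U_exact(self):
        # n=m=3 fully separated: smallest attainable two-sided p = 2/20
        stat, p = compare_conditions([1, 2, 3], [10, 11, 12], "mann_whitney")
        assert p == pytest.approx(0.1)

    def test_u_statistic_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n, m = rng.integers(1, 9, 2)
            a = rng.normal(0, 1, n).round(2)
            b = rng.normal(0.5, 1, m).round(2)
            stat, _ = compare_conditions(a, b, "mann_whitney")
            assert stat == pytest.approx(_brute_force_U(a, b))

    def test_two_sided_p_symmetric(self):
        rng = np.random.default_rng(4)
        for test in ("student_t", "mann_whitney"):
            a = rng.normal(0, 1, 8)
            b = rng.normal(1, 2, 6)
            _, p_ab = compare_conditions(a, b, test)
            _, p_ba = compare_conditions(b, a, test)
            assert p_ab == pytest.approx(p_ba)

    def test_exact_small_sample_p_against_enumeration(self):
        # two-sided exact p by enumerating all C(7,3) label assignments
        a, b = [1.2, 3.4, 5.6], [0.1, 2.3, 4.5, 6.7]
        stat, p = compare_conditions(a, b, "mann_whitney")
        pooled = a + b
        n = len(a)
        u_obs = _brute_force_U(a, b)
        m_u = len(a) * len(b) / 2
        count = 0
        total = 0
        for comb in itertools.combinations(range(7), n):
            aa = [pooled[i] for i in comb]
            bb = [pooled[i] for i in range(7) if i not in comb]
            u = _brute_force_U(aa, bb)
            total += 1
            if abs(u - m_u) >= abs(u_obs - m_u) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)


class TestFoldChanges:
    def test_printed_stoichiometry_increase(self):
        fc = fold_changes(157.0, 290.0)
        assert fc["percent_increase"] == pytest.approx(84.7, abs=0.05)

    def test_printed_positive_fraction_factor(self):
        fc = fold_changes(19.0, 47.0)
        assert fc["factor"] == pytest.approx(2.47, abs=0.005)

    def test_no_change(self):
        fc = fold_changes(3.0, 3.0)
        assert fc["percent_increase"] == 0.0 and fc["factor"] == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_changes(0.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 1e6), st.floats(0.0, 1e6))
    def test_conventions_consistent(self, a, b):
        fc = fold_changes(a, b)
        assert fc["percent_decrease"] == pytest.approx(100.0 - fc["remaining_percent"], abs=1e-6)
        assert fc["factor"] * 100.0 == pytest.approx(fc["remaining_percent"], rel=1e-9)
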