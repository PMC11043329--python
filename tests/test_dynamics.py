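"""Normalization, delta-profiles, per-bp paired tests, region calling
and classification, nucleosome counting, and group ANOVA."""

import numpy as np
import pytest
from scipy import stats

from qmnase.annotation import WINDOW_LENGTH
from qmnase.dynamics import (
    CoverageProfile,
    DeltaResult,
    DynamicsError,
    OFFSET_MIN,
    RegionCall,
    avg_spacing,
    call_regions,
    classify_regions,
    count_nucleosomes,
    delta_profile,
    group_anova,
    normalize_profile,
    per_bp_paired_test,
    promoter_summary,
)


def padded(values, fill=0.0):
    out = np.full(WINDOW_LENGTH, fill)
    out[:len(values)] = values
    return out


def profile(values, gene="g", cond="control", normalized=False):
    return CoverageProfile(gene, cond, values, normalized=normalized)


def make_delta(mean, mask, alpha=0.05):
    n = WINDOW_LENGTH
    return DeltaResult(group="t", mean=np.asarray(mean, float),
                       se=np.zeros(n), p=np.where(mask, 0.01, 0.5),
                       mask=np.asarray(mask, bool), alpha=alpha, n_genes=3)


class TestNormalize:
    def test_division_by_sum(self):
        p = normalize_profile(profile(padded([1, 2, 3, 4])))
        assert np.allclose(p.values[:4], [0.1, 0.2, 0.3, 0.4])
        assert p.values[4:].sum() == 0

    def test_idempotent(self):
        p1 = normalize_profile(profile(padded([1, 2, 3, 4])))
        p2 = normalize_profile(p1)
        assert np.allclose(p1.values, p2.values)

    def test_random_profile_sums_to_one(self, rng):
        p = normalize_profile(profile(rng.random(WINDOW_LENGTH)))
        assert abs(p.values.sum() - 1.0) < 1e-9

    def test_zero_profile_flagged_degenerate(self):
        p = normalize_profile(profile(np.zeros(WINDOW_LENGTH)))
        assert p.degenerate and p.normalized
        assert p.values.sum() == 0


class TestDeltaProfile:
    def test_identical_profiles_give_zero(self, rng):
        a = normalize_profile(profile(rng.random(WINDOW_LENGTH)))
        d = delta_profile(a, profile(a.values, cond="myotube", normalized=True))
        assert np.allclose(d, 0)

    def test_mass_moved_upstream_to_downstream(self):
        base = padded([], fill=1.0)
        moved = base.copy()
        moved[2500] -= 0.5   # offset -500
        moved[2700] += 0.5   # offset -300
        ctrl = normalize_profile(profile(base))
        myo = normalize_profile(profile(moved, cond="myotube"))
        d = delta_profile(ctrl, myo)
        assert d[2500] < 0 and d[2700] > 0
        assert abs(d.sum()) < 1e-12

    def test_delta_sums_to_zero(self, rng):
        ctrl = normalize_profile(profile(rng.random(WINDOW_LENGTH)))
        myo = normalize_profile(profile(rng.random(WINDOW_LENGTH), cond="m"))
        assert abs(delta_profile(ctrl, myo).sum()) < 1e-9

    def test_raw_profiles_rejected(self, rng):
        raw = profile(rng.random(WINDOW_LENGTH))
        with pytest.raises(DynamicsError, match="normalized"):
            delta_profile(raw, raw)


class TestPairedTest:
    def test_null_gives_no_confident_rejections(self):
        m = np.tile(np.linspace(1, 2, WINDOW_LENGTH), (4, 1))
        m = m / m.sum(axis=1, keepdims=True)
        d = per_bp_paired_test(m, m.copy())
        assert (d.p[~np.isnan(d.p)] == 1.0).all()
        assert not (d.mask & ~d.degenerate).any()

    def test_matches_textbook_closed_form(self):
        """Three genes with differences 0.01/0.02/0.03 at one offset:
        t = dbar / (sd/sqrt(3)), df = 2."""
        ctrl = np.zeros((3, WINDOW_LENGTH))
        myo = np.zeros((3, WINDOW_LENGTH))
        myo[:, 0] = [0.01, 0.02, 0.03]
        d = per_bp_paired_test(ctrl, myo)
        dbar, sd = 0.02, 0.01
        t_exp = dbar / (sd / np.sqrt(3))
        p_exp = 2 * stats.t.sf(t_exp, df=2)
        assert np.isclose(d.mean[0], dbar)
        assert np.isclose(d.se[0], sd / np.sqrt(3))
        assert np.isclose(d.p[0], p_exp)

    def test_matches_brute_force_oracle_everywhere(self, rng):
        n = 6
        ctrl = rng.random((n, WINDOW_LENGTH))
        myo = rng.random((n, WINDOW_LENGTH))
        d = per_bp_paired_test(ctrl, myo)
        idx = rng.integers(0, WINDOW_LENGTH, size=50)
        for i in idx:
            t_ref, p_ref = stats.ttest_rel(myo[:, i], ctrl[:, i])
            assert np.isclose(d.p[i], p_ref)
            assert np.isclose(d.mean[i], (myo[:, i] - ctrl[:, i]).mean())

    def test_zero_variance_nonzero_diff_flagged(self):
        ctrl = np.zeros((3, WINDOW_LENGTH))
        myo = np.zeros((3, WINDOW_LENGTH))
        myo[:, 5] = 0.01  # identical non-zero differences
        d = per_bp_paired_test(ctrl, myo)
        assert d.degenerate[5] and d.mask[5] and np.isnan(d.p[5])

    def test_single_gene_rejected(self):
        m = np.zeros((1, WINDOW_LENGTH))
        with pytest.raises(DynamicsError, match=">= 2 genes"):
            per_bp_paired_test(m, m)

    def test_bh_correction_is_more_conservative(self, rng):
        n = 8
        ctrl = rng.random((n, WINDOW_LENGTH))
        myo = ctrl + rng.normal(0, 0.01, ctrl.shape)
        raw = per_bp_paired_test(ctrl, myo)
        bh = per_bp_paired_test(ctrl, myo, bh=True)
        assert bh.mask.sum() <= raw.mask.sum()


def brute_force_regions(mask, mean, max_gap, min_width):
    """Naive run scanner over significant offsets, one sign at a time."""
    offsets = np.arange(OFFSET_MIN, OFFSET_MIN + WINDOW_LENGTH)
    out = []
    for sign, direction in ((1, "gain"), (-1, "loss")):
        pos = [int(o) for o, m, v in zip(offsets, mask, mean)
               if m and np.sign(v) == sign]
        runs = []
        for p in pos:
            if runs and p - runs[-1][1] - 1 <= max_gap:
                runs[-1][1] = p
            else:
                runs.append([p, p])
        for s, e in runs:
            if e - s + 1 >= min_width:
                out.append((s, e, direction))
    return sorted(out)


class TestCallRegions:
    def test_empty_mask(self):
        d = make_delta(np.zeros(WINDOW_LENGTH), np.zeros(WINDOW_LENGTH, bool))
        assert call_regions(d) == []

    def test_narrow_tss_loss_region_survives_defaults(self):
        """A 16-bp loss region at +5..+20 must not be discarded by the
        default min_width."""
        mean = np.zeros(WINDOW_LENGTH)
        mask = np.zeros(WINDOW_LENGTH, bool)
        sl = slice(3000 + 5, 3000 + 21)
        mean[sl] = -1.0
        mask[sl] = True
        (r,) = call_regions(d := make_delta(mean, mask))
        assert (r.start, r.end, r.width, r.direction) == (5, 20, 16, "loss")

    def test_sign_split_lobes(self):
        mean = np.zeros(WINDOW_LENGTH)
        mask = np.zeros(WINDOW_LENGTH, bool)
        mask[3000 - 650:3000 - 500] = True
        mean[3000 - 650:3000 - 500] = -1
        mask[3000 - 499:3000 - 400] = True
        mean[3000 - 499:3000 - 400] = +1
        regions = call_regions(make_delta(mean, mask))
        assert [(r.start, r.end, r.direction) for r in regions] == [
            (-650, -501, "loss"), (-499, -401, "gain")]

    def test_matches_naive_scanner_on_random_masks(self, rng):
        for _ in range(200):
            mask = rng.random(WINDOW_LENGTH) < 0.03
            mean = rng.normal(size=WINDOW_LENGTH)
            max_gap = int(rng.integers(0, 40))
            min_width = int(rng.integers(1, 30))
            d = make_delta(mean, mask)
            got = sorted((r.start, r.end, r.direction)
                         for r in call_regions(d, max_gap, min_width))
            assert got == brute_force_regions(mask, mean, max_gap, min_width)

    def test_labels_in_genomic_order(self, rng):
        mask = rng.random(WINDOW_LENGTH) < 0.02
        mean = rng.normal(size=WINDOW_LENGTH)
        regions = call_regions(make_delta(mean, mask))
        starts = [r.start for r in regions]
        assert starts == sorted(starts)
        assert [r.label for r in regions][:3] == ["A", "B", "C"][:len(regions)]


class TestClassifyRegions:
    def mk(self, start, end, direction, amp=1.0):
        delta = amp if direction == "gain" else -amp
        return RegionCall(start=start, end=end, direction=direction,
                          mean_delta=delta)

    def test_loss_then_gain_is_downstream_shift(self):
        out = classify_regions([self.mk(-650, -550, "loss"),
                                self.mk(-500, -400, "gain")])
        assert all(r.classification == "downstream_shift" for r in out)

    def test_gain_then_loss_is_upstream_shift(self):
        out = classify_regions([self.mk(-650, -550, "gain"),
                                self.mk(-500, -400, "loss")])
        assert all(r.classification == "upstream_shift" for r in out)

    def test_isolated_gain_is_buildup(self):
        (r,) = classify_regions([self.mk(-2100, -2000, "gain")])
        assert r.classification == "buildup"

    def test_isolated_loss_is_loss(self):
        (r,) = classify_regions([self.mk(5, 20, "loss")])
        assert r.classification == "loss"

    def test_distant_opposite_lobes_not_paired(self):
        out = classify_regions([self.mk(-2500, -2400, "loss"),
                                self.mk(-500, -400, "gain")])
        assert [r.classification for r in out] == ["loss", "buildup"]

    def test_unbalanced_lobes_not_paired(self):
        """Mass conservation: a gain lobe carrying far less material than
        the adjacent loss is a side effect, not the displaced nucleosome."""
        out = classify_regions([self.mk(-650, -550, "loss", amp=1.0),
                                self.mk(-500, -450, "gain", amp=0.5)])
        assert [r.classification for r in out] == ["loss", "buildup"]

    def test_fragmented_lobe_clusters_before_pairing(self):
        """Two nearby same-sign fragments act as one lobe: their combined
        mass balances the loss even though each alone would not."""
        out = classify_regions([self.mk(-650, -550, "loss", amp=1.0),
                                self.mk(-500, -461, "gain", amp=1.1),
                                self.mk(-440, -391, "gain", amp=1.1)])
        assert all(r.classification == "downstream_shift" for r in out)

    def test_best_balanced_pair_wins(self):
        """With one loss between two candidate gains at equal gaps, the
        gain whose mass matches the loss is chosen."""
        out = classify_regions([self.mk(-800, -701, "gain", amp=0.3),
                                self.mk(-650, -551, "loss", amp=1.0),
                                self.mk(-500, -401, "gain", amp=1.0)])
        assert [r.classification for r in out] == [
            "buildup", "downstream_shift", "downstream_shift"]


class TestNucleosomeCounting:
    def test_planted_peak_count(self, rng):
        x = np.arange(WINDOW_LENGTH, dtype=float)
        centers = np.arange(100, WINDOW_LENGTH - 100, 210)  # 18 peaks
        y = sum(np.exp(-0.5 * ((x - c) / 30) ** 2) for c in centers)
        y += rng.normal(0, 0.02, WINDOW_LENGTH)
        assert count_nucleosomes(y) == len(centers)

    def test_single_peak(self):
        x = np.arange(WINDOW_LENGTH, dtype=float)
        y = np.exp(-0.5 * ((x - 2000) / 40) ** 2)
        assert count_nucleosomes(y) == 1

    def test_flat_profile(self):
        assert count_nucleosomes(np.zeros(WINDOW_LENGTH)) == 0

    def test_spacing_arithmetic(self):
        assert avg_spacing(20) == 200.0
        assert np.isnan(avg_spacing(0))

    def test_summary_deltas_zero_for_identical_conditions(self, rng):
        vals = rng.random(WINDOW_LENGTH)
        s = promoter_summary(profile(vals), profile(vals, cond="myotube"))
        assert s["delta_read_sum"] == 0
        assert s["delta_spacing"] == 0


class TestGroupAnova:
    def test_matches_hand_computed_f(self):
        """Three-group toy table; F from between/within mean squares."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                  "c": [5.0, 6.0, 7.0]}
        res = group_anova(groups)
        data = [np.array(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in data)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in data)
        f_hand = (ssb / 2) / (ssw / 6)
        assert np.isclose(res["F"], f_hand)
        assert len(res["pairwise"]) == 3
        assert (res["pairwise"]["p_bonferroni"] <= 1).all()

    def test_identical_groups_flagged_degenerate(self):
        res = group_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res["degenerate"] and np.isnan(res["F"])

    def test_null_simulation_f_near_one(self, rng):
        fs = []
        for _ in range(200):
            groups = {k: rng.normal(size=10) for k in "abc"}
            fs.append(group_anova(groups)["F"])
        # E[F] = dfw/(dfw-2) = 27/25 under the null
        assert abs(np.mean(fs) - 27 / 25) < 0.15

    def test_bonferroni_capped_and_scaled(self):
        res = group_anova({"a": [1.0, 2.0], "b": [1.1, 2.1], "c": [0.9, 1.9]})
        pw = res["pairwise"]
        assert np.allclose(pw["p_bonferroni"],
                           np.minimum(1.0, pw["p_raw"] * 3))
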