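"""Input-subtracted binding values and the mean + 4-sigma site caller,
including an exact single-spike oracle and a large-sample Gaussian null
calibration of the seed rule."""

import numpy as np
import pytest
from scipy import stats

from qmnase.annotation import WINDOW_LENGTH
from qmnase.chip import (
    BindingSite,
    BindingValueProfile,
    ChipError,
    binding_value,
    call_4sigma,
    nucleosome_change_at_sites,
    sigma_confidence,
    site_census,
    site_region_overlap,
    site_retention,
    validated_sites,
)
from qmnase.dynamics import OFFSET_MIN, CoverageProfile, RegionCall


def profile(values, gene="Neb", cond="myotube", normalized=True):
    return CoverageProfile(gene_id=gene, condition=cond, values=values,
                           normalized=normalized)


def bprofile(values, gene="Neb", cond="myotube"):
    return BindingValueProfile(gene_id=gene, condition=cond, values=values)


def site(gene, start, end, cond="myotube"):
    return BindingSite(gene_id=gene, condition=cond, start=start, end=end,
                       peak_value=1.0, sigma_multiple=5.0)


class TestSigmaConfidence:
    def test_four_sigma_exceeds_99_8(self):
        assert sigma_confidence(4.0) >= 99.8

    def test_matches_gaussian_cdf(self):
        for k in (1.0, 2.0, 3.0):
            assert sigma_confidence(k) == pytest.approx(
                stats.norm.cdf(k) * 100.0)

    def test_monotone_in_k(self):
        ks = np.linspace(0, 6, 13)
        vals = [sigma_confidence(k) for k in ks]
        assert np.all(np.diff(vals) > 0)


class TestBindingValue:
    def test_identical_profiles_give_zeros(self):
        v = np.full(WINDOW_LENGTH, 1 / WINDOW_LENGTH)
        b = binding_value(profile(v), profile(v))
        assert np.array_equal(b.values, np.zeros(WINDOW_LENGTH))

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a = rng.random(WINDOW_LENGTH)
        a /= a.sum()
        c = rng.random(WINDOW_LENGTH)
        c /= c.sum()
        b1 = binding_value(profile(a), profile(c))
        b2 = binding_value(profile(c), profile(a))
        assert np.allclose(b1.values, -b2.values)

    def test_values_sum_to_zero(self):
        rng = np.random.default_rng(8)
        a = rng.random(WINDOW_LENGTH)
        a /= a.sum()
        c = rng.random(WINDOW_LENGTH)
        c /= c.sum()
        b = binding_value(profile(a), profile(c))
        assert abs(b.values.sum()) < 1e-12

    def test_planted_box_is_positive_inside(self):
        base = np.full(WINDOW_LENGTH, 1.0)
        ip = base.copy()
        ip[1000:1200] *= 5.0
        b = binding_value(profile(ip / ip.sum()), profile(base / base.sum()))
        assert b.values[1000:1200].min() > 0
        assert b.values[:1000].max() < 0

    def test_unnormalized_rejected(self):
        v = np.ones(WINDOW_LENGTH)
        with pytest.raises(ChipError, match="normalized"):
            binding_value(profile(v, normalized=False), profile(v))

    def test_gene_mismatch_rejected(self):
        v = np.full(WINDOW_LENGTH, 1 / WINDOW_LENGTH)
        with pytest.raises(ChipError, match="different genes"):
            binding_value(profile(v, gene="Neb"), profile(v, gene="Ttn"))


class TestCall4Sigma:
    def test_single_spike_oracle(self):
        """4000 zeros with one 1: mu = 1/4000, population SD =
        sqrt(1/4000 - 1/4000^2) ~ 0.01581, spike sits ~63 SDs above the
        mean, every other base sits below it -> exactly one 1-bp site."""
        v = np.zeros(WINDOW_LENGTH)
        v[2500] = 1.0
        mu = 1 / WINDOW_LENGTH
        sd = np.sqrt(mu - mu ** 2)
        sites = call_4sigma(bprofile(v))
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end) == (2500 + OFFSET_MIN, 2500 + OFFSET_MIN)
        assert s.peak_value == 1.0
        assert s.sigma_multiple == pytest.approx((1.0 - mu) / sd)
        assert s.sigma_multiple > 60

    def test_constant_profile_has_no_sites(self):
        assert call_4sigma(bprofile(np.full(WINDOW_LENGTH, 0.25))) == []

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=WINDOW_LENGTH)
        v[100:140] += 8.0
        base = call_4sigma(bprofile(v))
        shifted = call_4sigma(bprofile(3.5 * v - 42.0))
        assert [(s.start, s.end) for s in shifted] == \
               [(s.start, s.end) for s in base]
        assert np.allclose([s.sigma_multiple for s in shifted],
                           [s.sigma_multiple for s in base])

    def test_extension_to_one_sigma_contains_seed(self):
        """A plateau above 1 sigma around a 4-sigma seed is reported as
        one contiguous site covering the plateau."""
        v = np.zeros(WINDOW_LENGTH)
        v[1000:1100] = 1.0   # above mean + 1 SD
        v[1050] = 10.0       # the seed
        sites = call_4sigma(bprofile(v))
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (1000 + OFFSET_MIN,
                                                  1099 + OFFSET_MIN)

    def test_above_one_sigma_without_seed_not_called(self):
        v = np.zeros(WINDOW_LENGTH)
        v[1000:1100] = 1.0
        v[1050] = 10.0       # seed run
        v[3000:3050] = 1.0   # above 1 sigma but seedless
        sites = call_4sigma(bprofile(v))
        assert len(sites) == 1
        assert sites[0].start == 1000 + OFFSET_MIN

    def test_null_seed_rate_matches_gaussian_tail(self):
        """Per-offset seed exceedance rate on i.i.d. Gaussian noise.

        mu-hat and SD-hat over 4000 values are essentially exact, so the
        per-base exceedance probability is the 4-sigma upper tail
        p = 1 - Phi(4) ~ 3.167e-5.  Checked over >= 10^7 offsets within
        3 binomial SEs, in chunks to bound memory."""
        p_tail = float(stats.norm.sf(4.0))
        n_profiles = 2600            # 2600 * 4000 = 1.04e7 offsets
        chunk = 250
        rng = np.random.default_rng(20240)
        exceed = 0
        total = 0
        for start in range(0, n_profiles, chunk):
            k = min(chunk, n_profiles - start)
            mat = rng.normal(size=(k, WINDOW_LENGTH))
            mu = mat.mean(axis=1, keepdims=True)
            sd = mat.std(axis=1, keepdims=True)
            exceed += int((mat > mu + 4.0 * sd).sum())
            total += k * WINDOW_LENGTH
        se = np.sqrt(p_tail * (1 - p_tail) / total)
        assert total >= 10_000_000
        assert abs(exceed / total - p_tail) <= 3 * se


class TestValidation:
    def test_overlap_required_same_gene(self):
        r1 = [site("Neb", -2700, -2600), site("Neb", 500, 600)]
        r2 = [site("Neb", -2650, -2500), site("Ttn", 500, 600)]
        kept = validated_sites(r1, r2)
        assert [(s.start, s.end) for s in kept] == [(-2700, -2600)]

    def test_one_bp_touch_counts(self):
        assert validated_sites([site("Neb", 0, 10)],
                               [site("Neb", 10, 20)]) != []
        assert validated_sites([site("Neb", 0, 10)],
                               [site("Neb", 11, 20)]) == []

    def test_empty_other_replicate(self):
        assert validated_sites([site("Neb", 0, 10)], []) == []


class TestCensusAndRetention:
    GROUPS = {"skeletal": ["Neb", "Ttn"], "nonmuscle": ["Vwf"]}

    def test_gene_counted_once(self):
        sites = [site("Neb", -2700, -2600), site("Neb", 100, 200),
                 site("Vwf", 0, 50, cond="control")]
        table = site_census(sites, self.GROUPS)
        row = table[(table["group"] == "skeletal")
                    & (table["condition"] == "myotube")]
        assert row["genes_with_site"].item() == 1
        assert row["n_genes"].item() == 2
        row = table[(table["group"] == "nonmuscle")
                    & (table["condition"] == "control")]
        assert row["genes_with_site"].item() == 1

    def test_unknown_gene_ignored(self):
        table = site_census([site("NotAGene", 0, 10)], self.GROUPS)
        assert (table["genes_with_site"] == 0).all()

    def test_retention_oracle(self):
        control = [site("Vwf", 0, 100, cond="control"),
                   site("Vwf", 900, 950, cond="control")]
        myotube = [site("Vwf", 80, 200),          # overlaps the first
                   site("Neb", -2700, -2600)]     # gained elsewhere
        out = site_retention(control, myotube)
        assert out["n_retained"] == 1 and out["retained"][0].start == 0
        assert out["n_lost"] == 1 and out["lost"][0].start == 900
        assert out["n_gained"] == 1 and out["gained"][0].gene_id == "Neb"


class TestDeltaContentAndOverlap:
    def test_delta_content_sums_interval(self):
        d = np.zeros(WINDOW_LENGTH)
        d[0:10] = 0.5          # offsets -3000..-2991
        table = nucleosome_change_at_sites(
            [site("Neb", -3000, -2996)], {"Neb": d})
        assert table["delta_content"].item() == pytest.approx(0.5 * 5)

    def test_missing_gene_skipped(self):
        table = nucleosome_change_at_sites([site("Neb", 0, 10)], {})
        assert len(table) == 0

    def test_overlap_flags_and_distances(self):
        regions = [RegionCall(start=-650, end=-400, direction="loss",
                              label="C"),
                   RegionCall(start=5, end=20, direction="loss", label="D")]
        out = site_region_overlap(
            [site("Neb", -500, -450),    # inside C
             site("Neb", -900, -800),    # 150 bp upstream of C
             site("Neb", 100, 150)],     # 80 bp downstream of D
            regions)
        t = out["sites"]
        assert t["overlaps_C"].tolist() == [True, False, False]
        assert t["overlaps_any"].tolist() == [True, False, False]
        assert t["nearest_region_distance"].tolist() == [0, -150, 80]

    def test_histogram_counts_midpoints(self):
        out = site_region_overlap(
            [site("Neb", -2700, -2600), site("Ttn", -2680, -2620)], [])
        h = out["histogram"]
        assert h["n_sites"].sum() == 2
        row = h[(h["bin_start"] <= -2650) & (h["bin_end"] > -2650)]
        assert row["n_sites"].item() == 2
        assert h["bin_start"].iloc[0] == OFFSET_MIN
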