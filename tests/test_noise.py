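"""Noise metrics: conservation labels/profiles, periodicity, error rates,
covariate trends, residual correction, polymorphism profiles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicenoise.annotation import Annotation, junction_sites
from splicenoise.config import SimConfig
from splicenoise import noise
from splicenoise.noise import (bin_and_trend, conservation_profile,
                               expression_level, intron_error_rate,
                               label_conservation, label_junction_sites,
                               per_gene_missplice, periodicity_profile,
                               polymorphism_profile, residual_correction)
from splicenoise.synthetic import simulate_dataset, simulate_junction_counts
from splicenoise.synthetic.conservation import ConservationTrack


class TestConservationLabel:
    @pytest.mark.parametrize("scores,expected", [
        ((2.0, 1.8), "conserved"),       # mean 1.9 >= 1.5
        ((0.1, 0.3), "unconserved"),     # mean 0.2 <= 0.5
        ((0.6, 0.8), "intermediate"),    # mean 0.7 between thresholds
    ])
    def test_threshold_partition(self, scores, expected):
        arr = np.zeros(300, dtype=np.float32)
        arr[100], arr[101] = scores
        track = ConservationTrack({"chr1": arr})
        site = ("chr1", "+", "5", 100)  # donor: canonical bases 100, 101
        assert label_conservation(site, track, 1.5, 0.5) == expected

    def test_site_outside_track_is_intermediate(self):
        track = ConservationTrack({"chr1": np.zeros(50, dtype=np.float32)})
        assert label_conservation(("chr1", "+", "3", 49), track) != "conserved"

    def test_acceptor_uses_intron_end_bases(self):
        arr = np.zeros(300, dtype=np.float32)
        arr[198], arr[199] = 2.0, 2.0  # intron [., 200): canonical bases 198,199
        track = ConservationTrack({"chr1": arr})
        assert label_conservation(("chr1", "+", "3", 200), track) == "conserved"


class TestConservationProfile:
    def test_flat_track_gives_constant_profile(self):
        track = ConservationTrack({"chr1": np.full(1000, 0.7, dtype=np.float32)})
        prof = conservation_profile([("chr1", "+", "5", 500)], track, window=50)
        assert np.allclose(prof["mean_score"], 0.7, atol=1e-6)

    def test_annotated_donors_step_exon_high_intron_background(self, default_data,
                                                               default_annotation):
        sites = sorted(default_annotation.donor_sites)
        prof = conservation_profile(sites, default_data.track, window=60)
        exonic = prof[prof["offset"] < -5]["mean_score"].mean()
        deep_intronic = prof[prof["offset"] > 40]["mean_score"].mean()
        canonical = prof[prof["offset"].isin([1, 2])]["mean_score"].mean()
        assert exonic > 1.5
        assert canonical > 1.5
        assert abs(deep_intronic) < 0.3

    def test_cryptic_sites_are_flat_background(self, default_data, default_counts):
        d = default_data
        sites = []
        for key, (gid, ii, side, off) in list(d.truth.error_junctions.items())[:300]:
            donor, acceptor = junction_sites(*key)
            sites.append(donor if side == "D" else acceptor)
        prof = conservation_profile(sites, d.track, window=30)
        assert prof[prof["offset"].isin([1, 2])]["mean_score"].mean() < 0.5


class TestPeriodicity:
    def test_offset_six_is_frame_preserving(self):
        assert 6 % 3 == 0  # definitional, kept with the profile contract below

    def test_profile_marks_frames_and_excludes_center(self, default_junctions,
                                                      default_annotation,
                                                      default_data):
        res = periodicity_profile(default_junctions, default_annotation,
                                  default_data.genome, side="3")
        prof = res.profile
        assert set(prof.loc[prof["offset"] % 3 == 0, "in_frame"]) == {True}
        assert not set(range(-2, 3)) & set(prof["offset"])
        zero_minor = prof[(prof["minor_sites"] == 0) & (prof["opportunities"] > 0)]
        assert (zero_minor["ratio"] == 0).all()

    def test_binomial_pvalue_matches_exact_tail_sum(self):
        # 126 in-frame of 300: compare to direct tail summation
        k, n, p = 126, 300, 1 / 3
        direct = sum(math.comb(n, i) * p**i * (1 - p)**(n - i)
                     for i in range(k, n + 1))
        got = stats.binomtest(k, n, p, alternative="greater").pvalue
        assert got == pytest.approx(direct, rel=1e-10)
        assert k / n == pytest.approx(0.42)

    def test_frame_bias_elevates_in_frame_fraction(self):
        cfg = SimConfig(n_genes=80, frame_bias=0.5, per_intron_error_rate=0.02,
                        seed=29)
        d = simulate_dataset(cfg)
        counts = simulate_junction_counts(d.genome, d.truth, cfg, 91,
                                          total_reads=400_000)
        jt = counts[["chrom", "strand", "start", "end", "reads"]]
        ann = Annotation(genes=d.truth.genes)
        n_if = n_tot = 0
        for side in ("3", "5"):
            res = periodicity_profile(jt, ann, d.genome, side=side)
            n_if += res.n_in_frame
            n_tot += res.n_minor
        frac = n_if / n_tot
        # NMD thinning doubles the per-read usage of in-frame cryptic sites;
        # at the distinct-site level the excess is diluted by saturation but
        # must remain well above 1/3 and statistically unambiguous
        assert frac > 1 / 3
        p = stats.binomtest(n_if, n_tot, 1 / 3, alternative="greater").pvalue
        assert p < 1e-3

    def test_depth_scaling_leaves_ratio_invariant(self, default_junctions,
                                                  default_annotation,
                                                  default_data):
        res1 = periodicity_profile(default_junctions, default_annotation,
                                   default_data.genome, side="3")
        scaled = default_junctions.assign(reads=default_junctions["reads"] * 10)
        res2 = periodicity_profile(scaled, default_annotation,
                                   default_data.genome, side="3")
        pd.testing.assert_frame_equal(res1.profile, res2.profile)


class TestIntronErrorRate:
    def test_simple_fraction(self):
        ann = Annotation(genes=[])
        ann.introns = {("chr1", "+", 100, 400)}
        jt = pd.DataFrame([
            dict(chrom="chr1", strand="+", start=100, end=400, reads=995),
            dict(chrom="chr1", strand="+", start=100, end=350, reads=5),
        ])
        labels = {
            ("chr1", "+", "5", 100): "conserved",
            ("chr1", "+", "3", 400): "conserved",
            ("chr1", "+", "3", 350): "unconserved",
        }
        table, summary = intron_error_rate(jt, labels, ann)
        assert len(table) == 1
        assert table["error_rate"].iloc[0] == pytest.approx(0.005)
        assert summary["global_error_rate"] == pytest.approx(0.005)

    def test_no_unconserved_partners_gives_zero(self):
        ann = Annotation(genes=[])
        ann.introns = {("chr1", "+", 100, 400)}
        jt = pd.DataFrame([dict(chrom="chr1", strand="+", start=100, end=400,
                                reads=100)])
        labels = {("chr1", "+", "5", 100): "conserved",
                  ("chr1", "+", "3", 400): "conserved"}
        table, summary = intron_error_rate(jt, labels, ann)
        assert summary["global_error_rate"] == 0.0

    def test_recovers_generator_rate(self, default_junctions, default_data,
                                     default_annotation):
        labels = label_junction_sites(default_junctions, default_data.track)
        _, summary = intron_error_rate(default_junctions, labels,
                                       default_annotation)
        eps = default_data.config.per_intron_error_rate
        total = default_junctions["reads"].sum()
        se = math.sqrt(eps * (1 - eps) / total)
        assert abs(summary["global_error_rate"] - eps) < 3 * se

    @pytest.mark.parametrize("rate,n,expected", [
        (0.007, 3, 0.020854), (0.0, 5, 0.0), (0.3, 1, 0.3)])
    def test_per_gene_missplice(self, rate, n, expected):
        assert per_gene_missplice(rate, n) == pytest.approx(expected, abs=1e-6)


class TestExpression:
    def test_reads_per_exonic_base(self):
        exons = [(0, 1000), (2000, 3000)]
        starts = np.concatenate([np.linspace(0, 999, 600),
                                 np.linspace(2000, 2999, 400)]).astype(int)
        assert expression_level(exons, [starts]) == pytest.approx(0.5)

    def test_max_across_samples(self):
        exons = [(0, 100)]
        s1 = np.arange(0, 50)   # 0.5
        s2 = np.arange(0, 100)  # 1.0 reads per exonic base
        assert expression_level(exons, [s1, s2]) == pytest.approx(1.0)

    def test_zero_exon_length_raises(self):
        with pytest.raises(ValueError):
            expression_level([], [np.array([1, 2])])


class TestTrends:
    def _error_table(self, cfg, seed, depth_reads=600_000):
        d = simulate_dataset(cfg)
        counts = simulate_junction_counts(d.genome, d.truth, cfg, seed,
                                          total_reads=depth_reads)
        jt = counts[["chrom", "strand", "start", "end", "reads"]]
        ann = Annotation(genes=d.truth.genes)
        labels = label_junction_sites(jt, d.track)
        table, _ = intron_error_rate(jt, labels, ann)
        expr = {g.gene_id: d.truth.expression[g.gene_id] for g in d.truth.genes}
        key2gene = {k: gid for gid, g in d.truth.gene_by_id.items()
                    for k in g.intron_keys()}
        table["expression"] = [
            expr[key2gene[(r.chrom, r.strand, r.start, r.end)]]
            for r in table.itertuples(index=False)]
        return table

    def test_constant_rate_gives_no_trend(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(dict(
            chrom="chr1", start=np.arange(500), end=np.arange(500) + 100,
            length=rng.integers(100, 10_000, 500),
            error_rate=0.01 + rng.normal(0, 1e-4, 500)))
        binned, trend = bin_and_trend(table, "length", n_bins=50)
        assert abs(trend["spearman_rho"]) < 0.35
        assert trend["spearman_p"] > 0.01
        assert binned["n"].sum() == 500

    def test_recovers_length_slope(self):
        cfg = SimConfig(n_genes=400, per_intron_error_rate=-0.011,
                        error_length_slope=0.007, seed=31)
        table = self._error_table(cfg, 93)
        assert len(table) >= 100
        binned, trend = bin_and_trend(table, "length", n_bins=100)
        assert trend["spearman_rho"] > 0.5
        # slope of binned means recovers the generator slope
        slope, _ = np.polyfit(binned["mean_length"], binned["mean_error_rate"], 1)
        assert slope == pytest.approx(0.007, rel=0.25)

    def test_requires_enough_introns(self):
        table = pd.DataFrame(dict(length=[100, 200], error_rate=[0.1, 0.2]))
        with pytest.raises(ValueError):
            bin_and_trend(table, "length", n_bins=100)

    def test_residuals_sum_to_zero_and_constant_covariate_raises(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(dict(
            chrom="chr1", start=np.arange(300), end=np.arange(300) + 50,
            length=rng.integers(100, 5000, 300),
            expression=rng.lognormal(0, 1, 300),
            error_rate=rng.uniform(0, 0.02, 300)))
        res = residual_correction(table, "length", "expression", n_bins=30)
        assert res["residual_mean"] == pytest.approx(0.0, abs=1e-12)
        bad = table.assign(expression=1.0)
        with pytest.raises(ValueError):
            residual_correction(bad, "length", "expression")

    def test_confounded_expression_association_vanishes_after_correction(self):
        cfg = SimConfig(n_genes=400, per_intron_error_rate=-0.011,
                        error_length_slope=0.007,
                        expression_length_coupling=1.5, seed=33)
        table = self._error_table(cfg, 95)
        res = residual_correction(table, "length", "expression",
                                  n_bins=min(100, len(table) // 4))
        # error depends on length only; expression anti-correlates with length,
        # so the raw association is negative and correction removes most of it
        assert res["raw_rho"] < -0.3
        assert abs(res["corrected_rho"]) < abs(res["raw_rho"]) / 2


class TestPolymorphism:
    def test_no_variants_all_zero(self):
        prof = polymorphism_profile([("chr1", "+", "5", 100)], {"chr1":
                                    np.array([], dtype=int)}, window=10)
        assert (prof["fraction"] == 0).all()

    def test_dip_at_protected_canonical_bases(self, default_data,
                                              default_annotation):
        d = default_data
        ann_sites = sorted(default_annotation.donor_sites
                           | default_annotation.acceptor_sites)
        prof = polymorphism_profile(ann_sites, d.variant_positions, window=10)
        core = prof[prof["offset"].isin([1, 2])]["fraction"]
        flank = prof[prof["offset"].abs() > 4]["fraction"]
        assert (core == 0).all()  # true splice-site dinucleotides monomorphic
        assert flank.mean() > 0
        assert prof["fraction"].between(0, 1).all()

    def test_cryptic_sites_have_no_dip(self, default_data, default_counts):
        d = default_data
        sites = []
        for key, (gid, ii, side, off) in d.truth.error_junctions.items():
            donor, acceptor = junction_sites(*key)
            sites.append(donor if side == "D" else acceptor)
        if len(sites) < 50:
            pytest.skip("too few cryptic sites in fixture")
        prof = polymorphism_profile(sites, d.variant_positions, window=10)
        core = prof[prof["offset"].isin([1, 2])]["fraction"].mean()
        flank = prof[prof["offset"].abs() > 4]["fraction"].mean()
        # no protection at cryptic sites: similar rates at core and flank
        assert core > 0
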