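"""Marker-scan model, RP(EE), FDR classes and QTL merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abqtl import ValidationError, compute_rp, fdr_classify, merge_qtl, \
    scan_genome
from abqtl.scan import MarkerScanResult, MarkerSkipped, fit_marker_model
from conftest import balanced_dataset, simulated_dataset
from oracles import balanced_anova_p, bh_qvalues


def _fit(ds, marker="mk"):
    return fit_marker_model(ds.phenotypes, ds.genotypes.column(marker))


class TestFitMarkerModel:
    def test_identical_class_distributions_give_p_one(self):
        ds = balanced_dataset(shift=0.0, noise_sd=0.0)
        p, lsm_cc, lsm_ee, lod, n_cc, n_ee = _fit(ds)
        assert p == 1.0 and lod == 0.0
        assert lsm_cc == lsm_ee
        assert compute_rp(lsm_cc, lsm_ee) == 0.0

    def test_noise_free_shift_recovered_exactly(self):
        ds = balanced_dataset(n_per_class=4, n_env=2, shift=2.0)
        p, lsm_cc, lsm_ee, *_ = _fit(ds)
        assert lsm_ee - lsm_cc == pytest.approx(2.0)
        assert p < 1e-300  # noise-free: below any threshold

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_raw_sums_of_squares_anova(self, seed):
        # balanced toy: p-value equals the independently coded two-way
        # ANOVA F-test (class MS over class-x-environment MS)
        n, b = 6, 5
        ds = balanced_dataset(n_per_class=n, n_env=b, shift=1.0,
                              noise_sd=2.0, seed=seed)
        p, *_ = _fit(ds)
        wide = ds.phenotypes.to_matrix()
        codes = ds.genotypes.codes["mk"].reindex(wide.index)
        # oracle expects (class, environment, replicate-line)
        y = np.stack([wide[codes == 1].to_numpy().T,
                      wide[codes == 3].to_numpy().T])
        p_oracle, _ = balanced_anova_p(y)
        assert p == pytest.approx(p_oracle, rel=1e-6)

    def test_replicated_records_match_raw_anova(self):
        # with n_reps > 1 the cell-mean F still equals the raw MS ratio
        from abqtl import CrossingScheme, TrialDesign, make_map, \
            simulate_ab_population, simulate_phenotypes

        gmap = make_map(n_markers=21)
        pop = simulate_ab_population(gmap, CrossingScheme(n_lines=60, seed=8))
        marker = pop.markers[3]
        ph = simulate_phenotypes(pop, [], TrialDesign(n_reps=2, seed=5))
        codes = pop.codes[marker]
        p, *_ = fit_marker_model(ph, codes)
        # oracle: pool plots per class x env cell from the long table
        df = ph.frame.merge(codes.rename("code"), left_on="line_id",
                            right_index=True)
        hom = df[df["code"].isin([1, 3])]
        counts = hom.groupby("code")["line_id"].nunique()
        cells = hom.groupby(["code", "env_id"])["yield_dt_ha"].mean()
        y_cc = cells.loc[1].to_numpy()
        y_ee = cells.loc[3].to_numpy()
        # unreplicated two-way ANOVA on the 2 x B cell means
        cellm = np.vstack([y_cc, y_ee])
        bnum = cellm.shape[1]
        gm = cellm.mean()
        ss_m = bnum * ((cellm.mean(axis=1) - gm) ** 2).sum()
        resid = cellm - cellm.mean(axis=1, keepdims=True) \
            - cellm.mean(axis=0, keepdims=True) + gm
        from scipy import stats as sps
        f = ss_m / (resid ** 2).sum() * (bnum - 1)
        assert p == pytest.approx(float(sps.f.sf(f, 1, bnum - 1)), rel=1e-9)
        assert counts.min() >= 2

    def test_small_class_skipped_with_reason(self):
        ds = balanced_dataset(n_per_class=4)
        codes = ds.genotypes.codes["mk"].copy()
        codes.iloc[-3:] = 2  # leaves one EE line
        with pytest.raises(MarkerSkipped, match="EE=1"):
            fit_marker_model(ds.phenotypes, codes)


class TestComputeRp:
    @pytest.mark.parametrize(
        "cc,ee,shown",
        [(74.5, 76.6, 2.8), (74.3, 80.4, 8.2), (74.4, 76.7, 3.1)],
    )
    def test_published_style_rows_round_to_one_decimal(self, cc, ee, shown):
        assert round(compute_rp(cc, ee), 1) == shown

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, derandomize=True)
    def test_equal_means_give_zero(self, x):
        assert compute_rp(x, x) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_rp(0.0, 75.0)


class TestFdrClassify:
    def test_step_up_by_hand(self):
        q, classes = fdr_classify([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)
        assert classes == ["ns"] * 4

    def test_all_ones(self):
        q, classes = fdr_classify([1.0, 1.0, 1.0])
        assert (q == 1.0).all()
        assert classes == ["ns"] * 3

    def test_single_small_p_gets_three_stars(self):
        q, classes = fdr_classify([0.0005])
        assert q[0] == pytest.approx(0.0005)
        assert classes == ["***"]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fdr_classify([])

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_matches_hand_coded_bh_and_stays_in_unit_interval(self, p):
        q, _ = fdr_classify(p)
        assert np.allclose(q, bh_qvalues(p))
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _res(marker, chrom, pos, p=1e-5, q=1e-4, cls="***", rp=2.0):
    lsm_cc = 74.0
    lsm_ee = lsm_cc * (1 + rp / 100)
    return MarkerScanResult(
        marker_id=marker, chromosome=chrom, position_cM=pos, p_value=p,
        fdr_q=q, fdr_class=cls, lsm_cc=lsm_cc, lsm_ee=lsm_ee, rp_ee=rp,
        lod=-np.log10(p), n_cc=100, n_ee=15,
    )


class TestMergeQtl:
    def test_markers_within_rule_merge(self):
        regions = merge_qtl([_res("a", "1D", 0.0), _res("b", "1D", 15.0)])
        assert len(regions) == 1
        assert regions[0].member_markers == ("a", "b")
        assert regions[0].start_cM == 0.0 and regions[0].end_cM == 15.0

    def test_markers_beyond_rule_split(self):
        regions = merge_qtl([_res("a", "1D", 0.0), _res("b", "1D", 25.0)])
        assert len(regions) == 2

    def test_gap_exactly_at_rule_merges(self):
        regions = merge_qtl([_res("a", "1D", 0.0), _res("b", "1D", 20.0)])
        assert len(regions) == 1

    def test_opposite_sign_breaks_chain(self):
        regions = merge_qtl(
            [_res("a", "1D", 0.0, rp=2.0), _res("b", "1D", 5.0, rp=-2.0)]
        )
        assert len(regions) == 2
        assert {r.direction for r in regions} == {
            "exotic_favorable", "exotic_unfavorable",
        }

    def test_nonsignificant_marker_breaks_chain(self):
        regions = merge_qtl(
            [
                _res("a", "1D", 0.0),
                _res("mid", "1D", 5.0, p=0.5, q=0.8, cls="ns"),
                _res("b", "1D", 10.0),
            ]
        )
        assert len(regions) == 2

    def test_never_merges_across_chromosomes(self):
        regions = merge_qtl([_res("a", "1D", 149.0), _res("b", "2D", 1.0)])
        assert len(regions) == 2

    def test_peak_is_smallest_p(self):
        regions = merge_qtl(
            [_res("a", "1D", 0.0, p=1e-4), _res("b", "1D", 10.0, p=1e-8)]
        )
        assert regions[0].peak_marker == "b"

    def test_idempotent_on_region_members(self):
        results = [
            _res("a", "1D", 0.0), _res("b", "1D", 15.0),
            _res("c", "1D", 60.0), _res("d", "2D", 3.0, rp=-1.0),
        ]
        regions = merge_qtl(results)
        for region in regions:
            members = [r for r in results
                       if r.marker_id in region.member_markers]
            assert merge_qtl(members) == [region]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValidationError):
            merge_qtl([_res("a", "1D", 10.0), _res("b", "1D", 0.0)])


class TestScanGenome:
    def test_deterministic_for_identical_input(self):
        ds = simulated_dataset(n_lines=60, n_markers=42, seed=7)
        assert scan_genome(ds).results == scan_genome(ds).results

    def test_scale_equivariance(self):
        # yields in other units: p and RP unchanged, means scaled
        ds = simulated_dataset(n_lines=80, n_markers=42, seed=9,
                               effects=(("1D_m001", 2.0),))
        scaled = simulated_dataset(n_lines=80, n_markers=42, seed=9,
                                   effects=(("1D_m001", 2.0),))
        scaled.phenotypes.frame["yield_dt_ha"] *= 10.0
        a, b = scan_genome(ds), scan_genome(scaled)
        for ra, rb in zip(a, b):
            assert rb.p_value == pytest.approx(ra.p_value, rel=1e-9)
            assert rb.rp_ee == pytest.approx(ra.rp_ee, rel=1e-9)
            assert rb.lsm_cc == pytest.approx(10 * ra.lsm_cc, rel=1e-9)

    def test_environment_shift_invariance(self):
        ds = simulated_dataset(n_lines=80, n_markers=42, seed=13)
        shifted = simulated_dataset(n_lines=80, n_markers=42, seed=13)
        frame = shifted.phenotypes.frame
        frame.loc[frame["env_id"] == "E02", "yield_dt_ha"] += 50.0
        a, b = scan_genome(ds), scan_genome(shifted)
        for ra, rb in zip(a, b):
            assert rb.p_value == pytest.approx(ra.p_value, rel=1e-9)

    def test_skipped_markers_carry_reasons(self):
        from abqtl import mask_missing

        ds = simulated_dataset(n_lines=12, n_markers=42, seed=2)
        outcome = scan_genome(ds)
        # at 12 lines some markers lack 2 EE lines; reasons are recorded
        assert len(outcome) + len(outcome.skipped) == 42
        assert all("class too small" in why
                   for why in outcome.skipped.values())

    def test_injected_qtl_detected_with_positive_rp(self):
        ds = simulated_dataset(n_lines=150, n_markers=200, seed=17,
                               effects=(("3D_m005", 3.0),))
        outcome = scan_genome(ds)
        sig = [r for r in outcome if r.significant]
        assert sig, "injected QTL not detected"
        peak = min(sig, key=lambda r: r.p_value)
        assert peak.chromosome == "3D"
        assert peak.rp_ee > 0
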