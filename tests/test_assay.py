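"""Assay simulator: template sampling, ct model, markers, mislabeling."""

import math

import numpy as np
import pytest

from rhdnipt.assay import (
    AssayParams,
    AssayResult,
    apply_mislabel,
    fetal_fraction,
    read_calls_csv,
    simulate_markers,
    simulate_rhd_matrix,
    simulate_assays,
    write_calls_csv,
)
from rhdnipt.cohort import (
    CohortConfig,
    GestationalAge,
    Pregnancy,
    RhdClass,
    Sex,
    generate_cohort,
    make_fetus,
)

GA12 = GestationalAge(12, 6)


def singleton(rhd=RhdClass.RHD_POSITIVE, sex=Sex.FEMALE, maternal_variant=False, **kw):
    return Pregnancy(
        id="P1",
        ga_at_sampling=GA12,
        maternal_age=30,
        n_fetuses=1,
        fetuses=(make_fetus(rhd, sex, **kw),),
        maternal_rhd_variant=maternal_variant,
    )


class TestFetalFraction:
    def test_degenerate_constant(self, rng):
        p = AssayParams(ff_sd=0.0, ff_slope=0.0, ff_intercept=math.log(0.05))
        assert fetal_fraction(GA12, p, rng) == pytest.approx(0.05)

    def test_median_calibration_at_booking(self, rng):
        p = AssayParams()
        draws = [fetal_fraction(GA12, p, rng) for _ in range(10_000)]
        assert abs(np.median(draws) - 0.04) < 0.2 * 0.04

    def test_median_increases_with_gestation(self, rng):
        p = AssayParams()
        early = np.median([fetal_fraction(GA12, p, rng) for _ in range(4000)])
        late = np.median(
            [fetal_fraction(GestationalAge(25, 5), p, rng) for _ in range(4000)]
        )
        assert late > early


class TestRhdMatrix:
    def test_negative_fetus_no_noise_is_silent(self, rng):
        p = AssayParams(spurious_call_prob=0.0)
        preg = singleton(RhdClass.RHD_NEGATIVE)
        for _ in range(20):
            assert simulate_rhd_matrix(preg, 0.04, p, rng).n_calls == 0

    def test_saturation_gives_nine_calls(self, rng):
        p = AssayParams(detection_prob_per_copy=1.0, total_cfdna_copies_per_ml=1e5)
        m = simulate_rhd_matrix(singleton(), 0.29, p, rng)
        assert m.n_calls == 9

    def test_partial_variant_amplifies_present_exons_only(self, rng):
        p = AssayParams(
            detection_prob_per_copy=1.0, total_cfdna_copies_per_ml=1e5,
            spurious_call_prob=0.0,
        )
        preg = singleton(RhdClass.D_VARIANT_PARTIAL, present_exons=(5, 10))
        m = simulate_rhd_matrix(preg, 0.29, p, rng)
        assert (m.exon_calls(5), m.exon_calls(7), m.exon_calls(10)) == (3, 0, 3)

    def test_ff_out_of_range(self, rng):
        with pytest.raises(ValueError):
            simulate_rhd_matrix(singleton(), 1.5, AssayParams(), rng)

    def test_maternal_variant_lowers_ct(self, rng):
        # maternal template is ~1/ff times the fetal template, so the mean
        # positive-well ct drops by at least ct_slope*log10(1/ff)
        p = AssayParams(ct_noise_sd=0.0, spurious_call_prob=0.0)
        ff = 0.04
        fetal, maternal = [], []
        for _ in range(2000):
            fetal += list(simulate_rhd_matrix(singleton(), ff, p, rng).ct.values())
            maternal += list(
                simulate_rhd_matrix(
                    singleton(maternal_variant=True), ff, p, rng
                ).ct.values()
            )
        shift = np.mean(fetal) - np.mean(maternal)
        assert shift >= p.ct_slope * math.log10(1.0 / ff)

    def test_ct_standard_curve_doubling(self, rng):
        # doubling the template lowers the expected ct by ct_slope*log10(2)
        p = AssayParams(ct_noise_sd=0.0, spurious_call_prob=0.0,
                        detection_prob_per_copy=1.0)
        cts = {}
        for ff in (0.02, 0.04):
            vals = []
            for _ in range(3000):
                vals += list(simulate_rhd_matrix(singleton(), ff, p, rng).ct.values())
            cts[ff] = np.mean(vals)
        expected = p.ct_slope * math.log10(2)
        lam = p.total_cfdna_copies_per_ml * p.plasma_ml_per_replicate * 0.02
        mc_tol = 3 * p.ct_slope / math.sqrt(lam * 3000)  # delta-method spread
        assert cts[0.02] - cts[0.04] == pytest.approx(expected, abs=3 * mc_tol)

    def test_vanished_fetus_contributes_signal(self, rng):
        p = AssayParams(detection_prob_per_copy=1.0, total_cfdna_copies_per_ml=1e5,
                        spurious_call_prob=0.0)
        preg = Pregnancy(
            id="P1", ga_at_sampling=GA12, maternal_age=30, n_fetuses=2,
            fetuses=(
                make_fetus(RhdClass.RHD_NEGATIVE),
                make_fetus(RhdClass.RHD_POSITIVE, vanished=True),
            ),
        )
        m = simulate_rhd_matrix(preg, 0.29, p, rng)
        assert m.n_calls == 9  # demised co-fetus still sheds cfDNA


class TestMarkers:
    def test_all_female_pregnancy_has_no_sry(self, rng):
        p = AssayParams()
        for _ in range(50):
            panel = simulate_markers(singleton(sex=Sex.FEMALE), 0.1, p, rng)
            assert panel.sry_calls == 0

    def test_male_saturation(self, rng):
        p = AssayParams(detection_prob_per_copy=1.0, total_cfdna_copies_per_ml=1e5)
        panel = simulate_markers(singleton(sex=Sex.MALE), 0.29, p, rng)
        assert panel.sry_calls == 3

    def test_rassf1a_failure_increases_at_low_ff(self, rng):
        p = AssayParams()
        def fail_rate(ff, n=4000):
            return np.mean(
                [simulate_markers(singleton(), ff, p, rng).rassf1a_calls < 2
                 for _ in range(n)]
            )
        assert fail_rate(0.003) > fail_rate(0.03)


class TestMislabel:
    def _results(self, n, rng):
        cohort = generate_cohort(CohortConfig(n_pregnancies=n, seed=17))
        return simulate_assays(cohort, AssayParams(), rng, mislabel_prob=0.0)

    def test_zero_prob_identity(self, rng):
        res = self._results(10, rng)
        assert apply_mislabel(res, rng, 0.0) == res

    def test_forced_swap_of_two(self, rng):
        res = self._results(2, rng)
        swapped = apply_mislabel(res, rng, 1.0)
        assert swapped[0].id == res[0].id
        assert swapped[0].matrix == res[1].matrix
        assert swapped[1].matrix == res[0].matrix
        assert all(r.mislabeled for r in swapped)

    def test_single_record_warns_and_noop(self, rng):
        res = self._results(1, rng)
        with pytest.warns(UserWarning):
            out = apply_mislabel(res, rng, 0.5)
        assert out == res

    def test_permutation_conservation(self, rng):
        # the multiset of observations is unchanged, ids keep their order
        res = self._results(60, rng)
        out = apply_mislabel(res, rng, 0.3)
        assert [r.id for r in out] == [r.id for r in res]
        key = lambda r: (r.matrix.n_calls, sorted(r.matrix.ct.values()))
        assert sorted(map(key, out)) == sorted(map(key, res))

    def test_swap_rate_scale(self, rng):
        # ~2 swap-affected records per 1000 at the default rate of 1/1000
        n, prob, reps = 2244, 1e-3, 5
        res = self._results(n, rng)
        flagged = sum(
            sum(r.mislabeled for r in apply_mislabel(res, rng, prob))
            for _ in range(reps)
        ) / reps
        assert 0 < flagged < 5 * (2 * n * prob)


class TestStochasticMonotonicity:
    def test_positive_band_rate_nondecreasing_in_ff(self, rng):
        p = AssayParams()
        preg = singleton()
        rates = []
        for ff in (0.005, 0.02, 0.08):
            hits = sum(
                simulate_rhd_matrix(preg, ff, p, rng).n_calls >= 7
                for _ in range(3000)
            )
            rates.append(hits / 3000)
        assert rates == sorted(rates)


def test_calls_csv_roundtrip(tmp_path, rng):
    cohort = generate_cohort(CohortConfig(n_pregnancies=80, seed=23))
    results = simulate_assays(cohort, AssayParams(), rng, mislabel_prob=0.01)
    path = tmp_path / "calls.csv"
    write_calls_csv(results, path)
    back = read_calls_csv(path)
    assert [r.id for r in back] == [r.id for r in results]
    for a, b in zip(results, back):
        assert a.matrix.calls == b.matrix.calls
        assert a.markers == b.markers
        assert a.mislabeled == b.mislabeled
        for well, ct in a.matrix.ct.items():
            assert b.matrix.ct[well] == pytest.approx(ct, abs=1e-3)
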