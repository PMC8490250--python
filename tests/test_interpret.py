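"""Interpretation rules: call bands, guards, and oracle equivalence."""

import itertools

import numpy as np
import pytest

from conftest import make_markers, make_matrix
from rhdnipt.assay import FetalMarkerPanel, ReplicateCallMatrix
from rhdnipt.cohort import ASSAY_EXONS
from rhdnipt.interpret import (
    Category,
    Flag,
    InterpretConfig,
    MarkerStatus,
    classify,
    count_calls,
    detect_d_variant_pattern,
    detect_maternal_variant,
    marker_status,
)

CFG = InterpretConfig()


def matrix_from_wells(wells: tuple[bool, ...], ct: float) -> ReplicateCallMatrix:
    """Build a matrix from a flat 9-tuple of well states (exon-major)."""
    calls, cts = {}, {}
    for i, (exon, rep) in enumerate(
        (e, r) for e in ASSAY_EXONS for r in range(1, 4)
    ):
        calls[(exon, rep)] = wells[i]
        if wells[i]:
            cts[(exon, rep)] = ct
    return ReplicateCallMatrix(calls=calls, ct=cts)


class TestCountCalls:
    @pytest.mark.parametrize(
        "per_exon,expected", [((0, 0, 0), 0), ((3, 3, 3), 9), ((3, 3, 0), 6)]
    )
    def test_counts(self, per_exon, expected):
        assert count_calls(make_matrix(per_exon)) == expected


class TestMaternalVariantFlag:
    def test_full_positive_low_ct(self):
        assert detect_maternal_variant(make_matrix((3, 3, 3), ct=28.0), CFG)

    def test_full_positive_normal_ct(self):
        assert not detect_maternal_variant(make_matrix((3, 3, 3), ct=38.0), CFG)

    def test_no_calls_is_vacuously_false(self):
        assert not detect_maternal_variant(make_matrix((0, 0, 0)), CFG)

    def test_requires_positive_band(self):
        # low ct alone is not enough below 7 calls
        assert not detect_maternal_variant(make_matrix((3, 3, 0), ct=28.0), CFG)


class TestDVariantPattern:
    @pytest.mark.parametrize("per_exon", [(3, 3, 0), (3, 0, 0), (0, 0, 3)])
    def test_all_or_none_patterns(self, per_exon):
        assert detect_d_variant_pattern(make_matrix(per_exon))

    @pytest.mark.parametrize("per_exon", [(2, 2, 1), (3, 2, 0), (1, 1, 1)])
    def test_scattered_dropout_rejected(self, per_exon):
        assert not detect_d_variant_pattern(make_matrix(per_exon))

    def test_bands_outside_3_6_rejected(self):
        assert not detect_d_variant_pattern(make_matrix((3, 3, 3)))
        assert not detect_d_variant_pattern(make_matrix((0, 0, 0)))


class TestMarkerStatus:
    @pytest.mark.parametrize(
        "calls,status",
        [
            (3, MarkerStatus.POSITIVE),
            (2, MarkerStatus.POSITIVE),
            (1, MarkerStatus.INCONCLUSIVE),
            (0, MarkerStatus.NEGATIVE),
        ],
    )
    def test_thresholds(self, calls, status):
        assert marker_status(calls, CFG) is status

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            marker_status(4, CFG)


class TestClassify:
    def test_positive_band(self):
        rep = classify(make_matrix((3, 3, 3), ct=38.0), make_markers())
        assert rep.category is Category.POSITIVE and rep.call_count == 9

    def test_negative_band_with_marker(self):
        rep = classify(make_matrix((1, 1, 0)), make_markers(sry=3, rassf1a=0))
        assert rep.category is Category.NEGATIVE

    def test_negative_band_marker_failure(self):
        # 2 of 9 calls, SRY negative, RASSF1A inconclusive: the fetal-DNA
        # gate withholds the negative report
        rep = classify(make_matrix((1, 1, 0)), make_markers(sry=0, rassf1a=1))
        assert rep.category is Category.INC_FETAL_MARKER
        assert Flag.MARKER_FAIL in rep.flags

    def test_marker_gate_disabled(self):
        cfg = InterpretConfig(require_marker_for_negative=False)
        rep = classify(make_matrix((0, 0, 0)), make_markers(sry=0, rassf1a=0), cfg)
        assert rep.category is Category.NEGATIVE

    def test_scattered_mid_band(self):
        rep = classify(make_matrix((2, 2, 1)), make_markers())
        assert rep.category is Category.INC_CALLS

    def test_d_variant_mid_band(self):
        rep = classify(make_matrix((3, 3, 0)), make_markers())
        assert rep.category is Category.INC_D_VARIANT

    def test_maternal_precedence_over_positive(self):
        rep = classify(make_matrix((3, 3, 3), ct=28.0), make_markers())
        assert rep.category is Category.INC_MATERNAL_VARIANT
        assert Flag.LOW_CT in rep.flags


# ---------------------------------------------------------------------------
# truth-table oracle: an independent flat enumeration of the rules
# ---------------------------------------------------------------------------

def oracle_category(
    wells: tuple[bool, ...], ct: float, sry: int, rassf1a: int, cfg: InterpretConfig
) -> Category:
    n = sum(wells)
    per_exon = [sum(wells[0:3]), sum(wells[3:6]), sum(wells[6:9])]
    maternal = n >= 7 and n > 0 and ct < cfg.maternal_ct_threshold
    d_variant = (
        3 <= n <= 6
        and all(c in (0, 3) for c in per_exon)
        and 3 in per_exon
        and 0 in per_exon
    )
    def mstat(c):
        if c >= cfg.marker_positive_min_calls:
            return "POS"
        return "NEG" if c == 0 else "INC"
    marker_ok = mstat(sry) == "POS" or mstat(rassf1a) == "POS"
    if maternal:
        return Category.INC_MATERNAL_VARIANT
    if 7 <= n <= 9:
        return Category.POSITIVE
    if 3 <= n <= 6:
        return Category.INC_D_VARIANT if d_variant else Category.INC_CALLS
    if marker_ok or not cfg.require_marker_for_negative:
        return Category.NEGATIVE
    return Category.INC_FETAL_MARKER


def enumerate_classify_vs_oracle(cfg: InterpretConfig):
    """Yield (report, oracle category) over all 512 matrices x ct x markers."""
    marker_states = [(s, r) for s in range(4) for r in range(4)]
    for wells in itertools.product([False, True], repeat=9):
        for ct in (28.0, 38.0):
            matrix = matrix_from_wells(wells, ct)
            for sry, rassf1a in marker_states:
                rep = classify(matrix, FetalMarkerPanel(sry, rassf1a), cfg)
                yield rep, oracle_category(wells, ct, sry, rassf1a, cfg)


class TestOracleEquivalence:
    def test_full_enumeration_agreement_and_band_consistency(self):
        cfg = InterpretConfig()
        n_seen = 0
        for rep, expected in enumerate_classify_vs_oracle(cfg):
            n_seen += 1
            assert rep.category is expected
            # band consistency invariants
            if rep.category is Category.POSITIVE:
                assert 7 <= rep.call_count <= 9
            if rep.category in (Category.NEGATIVE, Category.INC_FETAL_MARKER):
                assert rep.call_count <= 2
            if rep.category in (Category.INC_D_VARIANT, Category.INC_CALLS):
                assert 3 <= rep.call_count <= 6
        assert n_seen == 512 * 2 * 16
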