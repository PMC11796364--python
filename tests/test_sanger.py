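"""Colony enumeration from composite traces: construction oracles and the
round-trip against the analytic 10N accuracy."""

import numpy as np
import pytest

from plasmux.barcode_model import BarcodeScheme, tenn_enumeration_accuracy
from plasmux.sanger import (
    FLAG_DEGRADED,
    FLAG_EMPTY,
    FLAG_LOW_CONFIDENCE,
    FLAG_SATURATED,
    TraceProfile,
    call_colony,
    call_snp_count,
    call_tenn_count,
    combine_calls,
    detect_degradation,
)
from plasmux.simulate import (
    DEFECT_INTACT,
    DEFECT_SMALL_DELETION,
    DualBarcode,
    SimConfig,
    make_library,
    render_trace,
    sample_colonies,
)


def _molecule(ref, snp_position, alt, random_region, defect=DEFECT_INTACT, emitted=None):
    snp_region = (
        ref.snp_region_reference[:snp_position]
        + alt
        + ref.snp_region_reference[snp_position + 1 :]
    )
    intact = snp_region + random_region
    return DualBarcode(
        snp_position=snp_position,
        snp_alt_base=alt,
        random_region=random_region,
        defect_class=defect,
        emitted_barcode=intact if emitted is None else emitted,
    )


class TestTraceProfile:
    def test_rejects_bad_row_sum(self):
        rows = np.full((3, 4), 0.2)
        with pytest.raises(ValueError, match="sum"):
            TraceProfile(rows)

    def test_rejects_fraction_outside_unit_interval(self):
        rows = np.array([[1.2, -0.2, 0.0, 0.0]])
        with pytest.raises(ValueError):
            TraceProfile(rows)

    def test_from_intensities_normalises(self):
        trace = TraceProfile.from_intensities(np.array([[100.0, 100.0, 0.0, 0.0]]))
        assert trace.fractions[0, 0] == pytest.approx(0.5)

    def test_from_sequence_expands_iupac(self):
        trace = TraceProfile.from_sequence("AN")
        assert trace.fractions[0, 0] == 1.0
        assert np.allclose(trace.fractions[1], 0.25)

    def test_from_sequence_rejects_invalid_code(self):
        with pytest.raises(ValueError, match="position 1"):
            TraceProfile.from_sequence("AXA")


class TestSnpCall:
    def test_single_molecule_has_one_snp(self, ref, scheme):
        mol = _molecule(ref, 5, "A" if ref.snp_region_reference[5] != "A" else "C", "ACGTACGTAC")
        call = call_snp_count(render_trace([mol], ref), ref, scheme)
        assert call.count == 1
        assert call.detections[0].position == 5

    def test_reference_trace_has_zero_snps(self, ref, scheme):
        seq = ref.upstream_anchor + ref.snp_region_reference + "ACGTACGTAC" + ref.downstream_anchor
        trace = TraceProfile.from_sequence(seq)
        assert call_snp_count(trace, ref, scheme).count == 0

    def test_two_molecule_mixture_gives_two_snps(self, ref, scheme):
        alt2 = "A" if ref.snp_region_reference[2] != "A" else "C"
        alt7 = "A" if ref.snp_region_reference[7] != "A" else "C"
        mols = [_molecule(ref, 2, alt2, "AAAAAAAAAA"), _molecule(ref, 7, alt7, "CCCCCCCCCC")]
        assert call_snp_count(render_trace(mols, ref), ref, scheme).count == 2

    def test_count_capped_at_detection_ceiling(self, ref):
        # 10 variants at 10% each with a permissive threshold still cap at
        # floor(1/threshold)
        scheme = BarcodeScheme(sanger_call_threshold=0.05)
        alts = []
        for pos in range(10):
            alt = "A" if ref.snp_region_reference[pos] != "A" else "C"
            alts.append(_molecule(ref, pos, alt, "ACGTACGTAC"))
        call = call_snp_count(render_trace(alts, ref), ref, scheme)
        assert call.count == 10  # ceiling at threshold 0.05 is 20, so uncapped here
        assert len(call.detections) == 10

    def test_trace_too_short_rejected(self, ref, scheme):
        trace = TraceProfile.from_sequence(ref.upstream_anchor)
        with pytest.raises(ValueError, match="cover"):
            call_snp_count(trace, ref, scheme)


class TestTenNCall:
    def test_single_molecule(self, ref, scheme):
        mol = _molecule(ref, 0, "A" if ref.snp_region_reference[0] != "A" else "C", "ACGTACGTAC")
        assert call_tenn_count(render_trace([mol], ref), ref, scheme) == 1

    def test_three_molecule_mixture(self, ref, scheme):
        regions = ["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"]
        mols = [
            _molecule(ref, i, "A" if ref.snp_region_reference[i] != "A" else "C", r)
            for i, r in enumerate(regions)
        ]
        assert call_tenn_count(render_trace(mols, ref), ref, scheme) == 3

    def test_all_four_bases_saturates(self, ref, scheme):
        regions = ["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG", "TTTTTTTTTT"]
        mols = [
            _molecule(ref, i, "A" if ref.snp_region_reference[i] != "A" else "C", r)
            for i, r in enumerate(regions)
        ]
        trace = render_trace(mols, ref)
        assert call_tenn_count(trace, ref, scheme) == 4
        assert FLAG_SATURATED in call_colony(trace, ref, scheme).flags

    def test_calls_invariant_to_uniform_rescaling(self, ref, scheme):
        mols = [
            _molecule(ref, 1, "A" if ref.snp_region_reference[1] != "A" else "C", "AAAAACCCCC"),
            _molecule(ref, 3, "A" if ref.snp_region_reference[3] != "A" else "C", "CCCCCAAAAA"),
        ]
        base = render_trace(mols, ref)
        for scale in (0.5, 7.0, 1234.5):
            rescaled = TraceProfile.from_intensities(base.fractions * scale)
            assert call_tenn_count(rescaled, ref, scheme) == call_tenn_count(base, ref, scheme)
            assert (
                call_snp_count(rescaled, ref, scheme).count
                == call_snp_count(base, ref, scheme).count
            )


class TestCombineCalls:
    @pytest.mark.parametrize(
        "snp,tenn,final,flags",
        [
            (1, 1, 1, frozenset()),
            (2, 2, 2, frozenset()),
            (2, 3, 3, frozenset()),  # within-1 disagreement: 10N wins in 1-3
            (5, 4, 5, frozenset({FLAG_SATURATED})),
            (3, 4, 4, frozenset({FLAG_SATURATED})),
            (0, 2, 2, frozenset({FLAG_EMPTY})),
            (0, 4, 4, frozenset({FLAG_EMPTY, FLAG_SATURATED})),
            (3, 1, 1, frozenset({FLAG_LOW_CONFIDENCE})),
            (4, 3, 4, frozenset({FLAG_LOW_CONFIDENCE})),
        ],
    )
    def test_combination_logic(self, snp, tenn, final, flags):
        call = combine_calls(snp, tenn)
        assert call.final_count == final
        assert call.flags == flags

    def test_saturated_label(self):
        assert combine_calls(5, 4).tenn_label == ">=4"
        assert combine_calls(2, 2).tenn_label == "2"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            combine_calls(-1, 1)
        with pytest.raises(ValueError):
            combine_calls(1, 0)


class TestDegradation:
    def test_clean_single_molecule(self, ref, scheme):
        mol = _molecule(ref, 4, "A" if ref.snp_region_reference[4] != "A" else "C", "ACGTACGTAC")
        degraded, affected = detect_degradation(render_trace([mol], ref), ref, scheme)
        assert not degraded
        assert affected == 0.0

    def test_intact_mixture_is_clean(self, ref, scheme):
        mols = [
            _molecule(ref, i, "A" if ref.snp_region_reference[i] != "A" else "C", r)
            for i, r in enumerate(["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"])
        ]
        degraded, _ = detect_degradation(render_trace(mols, ref), ref, scheme)
        assert not degraded

    def test_deletion_member_corrupts_anchor(self, ref, scheme):
        intact = _molecule(ref, 1, "A" if ref.snp_region_reference[1] != "A" else "C", "ACGTACGTAC")
        snp_region = ref.snp_region_reference[:6] + (
            "A" if ref.snp_region_reference[6] != "A" else "C"
        ) + ref.snp_region_reference[7:]
        full = snp_region + "TTGGCCAATT"
        shifted = _molecule(
            ref, 6, "A" if ref.snp_region_reference[6] != "A" else "C", "TTGGCCAATT",
            defect=DEFECT_SMALL_DELETION, emitted=full[:8] + full[10:],  # 2-nt deletion
        )
        trace = render_trace([intact, shifted], ref)
        degraded, affected = detect_degradation(trace, ref, scheme)
        assert degraded
        assert affected == pytest.approx(0.5, abs=0.25)  # ~1/k of the signal off-anchor
        assert FLAG_DEGRADED in call_colony(trace, ref, scheme).flags

    def test_insufficient_anchor_coverage_rejected(self, ref, scheme):
        start, _ = ref.downstream_anchor_interval
        trace = TraceProfile(np.tile([1.0, 0, 0, 0], (start + 2, 1)))
        with pytest.raises(ValueError, match="anchor"):
            detect_degradation(trace, ref, scheme)


class TestRoundTrip:
    def test_noise_free_mixtures_called_exactly(self, ref, scheme):
        # three intact molecules whose random regions expose 3 distinct
        # bases at one position: the combined call must equal the truth
        regions = ["AAAAAAAAAA", "CAAAAAAAAA", "GAAAAAAAAA"]
        mols = [
            _molecule(ref, i, "A" if ref.snp_region_reference[i] != "A" else "C", r)
            for i, r in enumerate(regions)
        ]
        for m in range(1, 4):
            call = call_colony(render_trace(mols[:m], ref), ref, scheme)
            assert call.final_count == m

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_tenn_recovery_matches_analytic(self, k, ref, scheme):
        # 10N-rule accuracy over simulated colonies reproduces the closed
        # form within 3 binomial SE.  Each colony gets its own disjoint
        # slice of a large library so random regions are iid across
        # colonies.
        n = 10_000
        config = SimConfig(
            n_library_molecules=n * k,
            large_deletion_fraction=0.0,
            small_deletion_fraction=0.0,
            seed=900 + k,
        )
        library = make_library(config, ref, np.random.default_rng(900 + k))
        hits = 0
        for i in range(n):
            members = library[i * k : (i + 1) * k]
            hits += call_tenn_count(render_trace(members, ref), ref, scheme) == k
        analytic = tenn_enumeration_accuracy(k, scheme)
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(hits / n - analytic) <= 3 * max(se, 1e-4)
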