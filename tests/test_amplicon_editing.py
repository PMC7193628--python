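import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdrscreen.amplicon_editing import (
    AMBIGUOUS,
    DEFAULT_SCORING,
    HDR,
    MIXED,
    NHEJ,
    UNEDITED,
    AlignScoring,
    classify_read,
    infer_cut_index,
    merge_pair,
    needleman_wunsch,
    quantify_editing,
    rescore,
    summarize_rates,
    trim_adapter,
)
from hdrscreen.io_formats import AmpliconSpec, SequenceRead, ValidationError, revcomp
from hdrscreen.synthetic_data import (
    AmpliconSimParams,
    build_template,
    simulate_amplicon_reads,
)

from conftest import make_read
from oracles import brute_force_alignment_score

# ---------------------------------------------------------------------------
# Needleman-Wunsch
# ---------------------------------------------------------------------------

def test_identity_alignment():
    aln = needleman_wunsch("ACGT", "ACGT")
    assert aln.score == 20
    assert [op.kind for op in aln.operations] == ["match"]
    assert aln.operations[0].length == 4


def test_pure_gap_costs_affine():
    # gap of length 2 costs open + extend
    aln = needleman_wunsch("AC", "")
    assert aln.score == -10.5
    assert aln.aligned_b == "--"


def test_empty_vs_empty():
    aln = needleman_wunsch("", "")
    assert aln.score == 0 and aln.aligned_a == ""


def test_single_deletion_alignment():
    aln = needleman_wunsch("GATTACA", "GATACA")
    assert aln.score == brute_force_alignment_score("GATTACA", "GATACA", DEFAULT_SCORING)
    assert aln.aligned_a.replace("-", "") == "GATTACA"
    assert aln.aligned_b.replace("-", "") == "GATACA"


def test_n_scores_as_mismatch():
    assert needleman_wunsch("N", "N").score == DEFAULT_SCORING.mismatch
    assert needleman_wunsch("AN", "AA").score == 5 - 4


@pytest.mark.parametrize("seed", [0, 1])
def test_alignment_matches_bruteforce_enumeration(seed, rng):
    """DP optimum equals exhaustive enumeration over all global alignments."""
    local = np.random.default_rng(seed)
    for _ in range(60):
        a = "".join(local.choice(list("ACGT"), local.integers(0, 7)))
        b = "".join(local.choice(list("ACGT"), local.integers(0, 7)))
        aln = needleman_wunsch(a, b)
        assert aln.score == brute_force_alignment_score(a, b, DEFAULT_SCORING), (a, b)
        # invariants: ungapping recovers inputs; ops re-score to the optimum
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b
        assert rescore(aln) == aln.score


def test_alignment_score_symmetry(rng):
    for _ in range(40):
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 12)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 12)))
        assert needleman_wunsch(a, b).score == needleman_wunsch(b, a).score


def test_reference_covered_exactly_once_by_non_insertions(rng):
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), rng.integers(0, 15)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(0, 15)))
        aln = needleman_wunsch(a, b)
        covered = sum(
            op.length for op in aln.operations if op.kind != "insertion"
        )
        assert covered == len(b)


def test_score_agrees_with_biopython_on_long_pairs(rng):
    """Independent affine-gap cross-check at realistic lengths."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    for _ in range(15):
        a = "".join(rng.choice(list("ACGT"), 40))
        b = "".join(rng.choice(list("ACGT"), rng.integers(30, 50)))
        assert needleman_wunsch(a, b).score == aligner.score(a, b)


def test_deterministic_traceback():
    a, b = "ACGTACGT", "AGGTACCT"
    first = needleman_wunsch(a, b)
    for _ in range(3):
        again = needleman_wunsch(a, b)
        assert (again.aligned_a, again.aligned_b) == (first.aligned_a, first.aligned_b)


# ---------------------------------------------------------------------------
# trimming and merging
# ---------------------------------------------------------------------------

ADAPTER = "AGATCGGAAGAGC"


def test_trim_full_adapter():
    insert = "ACGTACGTAC"
    read = make_read(insert + ADAPTER)
    out = trim_adapter(read, ADAPTER)
    assert out.bases == insert
    assert len(out.qualities) == len(insert)


def test_trim_no_adapter_content_unchanged():
    read = make_read("ACGTACGTACGTACG")
    assert trim_adapter(read, "TTGGCCAATTGGCC").bases == read.bases


def test_trim_partial_adapter_prefix():
    insert = "ACGTACGTAC"
    read = make_read(insert + ADAPTER[:5])
    assert trim_adapter(read, ADAPTER).bases == insert


def test_trim_read_shorter_than_min_match_unchanged():
    read = make_read("AC")
    assert trim_adapter(read, ADAPTER).bases == "AC"


def test_merge_reconstructs_amplicon():
    amplicon = "ACGTTGCAGGTCAGCT"
    r1 = make_read(amplicon[0:12], "m")
    r2 = make_read(revcomp(amplicon[4:16]), "m")
    merged = merge_pair(r1, r2, min_overlap=4)
    assert merged is not None and merged.bases == amplicon


def test_merge_disjoint_reads_fails():
    assert merge_pair(make_read("ACGTACGTACGT"), make_read("TTTTGGGGCCCC")) is None


def test_merge_conflict_resolved_to_higher_quality():
    amplicon = "ACGTTGCAGGTCAGCT"
    r1b = list(amplicon[0:12])
    r1b[6] = "A" if r1b[6] != "A" else "C"  # plant a disagreement
    r1 = SequenceRead("m", "".join(r1b), (40,) * 12)
    r2 = SequenceRead("m", revcomp(amplicon[4:16]), (10,) * 12)
    merged = merge_pair(r1, r2, min_overlap=4)
    assert merged.bases[6] == r1.bases[6]  # r1 wins on quality
    # now flip the qualities: the true amplicon base wins
    r1 = SequenceRead("m", "".join(r1b), (10,) * 12)
    r2 = SequenceRead("m", revcomp(amplicon[4:16]), (40,) * 12)
    merged = merge_pair(r1, r2, min_overlap=4)
    assert merged.bases == amplicon


# ---------------------------------------------------------------------------
# cut-site inference
# ---------------------------------------------------------------------------

def _spec_with(reference, protospacer, **kw):
    return AmpliconSpec(
        name="t", reference=reference, donor=reference, cut_index=0,
        protospacer=protospacer, **kw,
    )


def test_infer_cut_forward():
    proto = "GACGCATAAAGATGAGACGC"
    ref = "CCCCC" + proto + "TGG" + "AAAA"
    assert infer_cut_index(_spec_with(ref, proto)) == 5 + 17


def test_infer_cut_reverse_strand_is_mirrored():
    proto = "GACGCATAAAGATGAGACGC"
    fwd = "CCCCC" + proto + "TGG" + "AAAA"
    rev = revcomp(fwd)
    # manual placement: in fwd coordinates the cut is at 22, i.e. 22 bases
    # 5' of the cut; mirrored, len - 22 bases remain 5' of it
    assert infer_cut_index(_spec_with(rev, proto)) == len(fwd) - 22


def test_infer_cut_requires_unique_occurrence():
    proto = "GACGCATAAAGATGAGACGC"
    ref = proto + "TGGAA" + proto + "TGG"
    with pytest.raises(ValidationError, match="occurs"):
        infer_cut_index(_spec_with(ref, proto))


def test_infer_cut_requires_pam():
    proto = "GACGCATAAAGATGAGACGC"
    ref = "CCCCC" + proto + "TAA" + "AAAA"
    with pytest.raises(ValidationError, match="PAM"):
        infer_cut_index(_spec_with(ref, proto))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_canonical_reads_classify(amplicon_spec):
    ref, donor = amplicon_spec.reference, amplicon_spec.donor
    cut = amplicon_spec.cut_index
    assert classify_read(make_read(ref), amplicon_spec).category == UNEDITED
    assert classify_read(make_read(donor), amplicon_spec).category == HDR
    ins1 = ref[:cut] + "A" + ref[cut:]
    assert classify_read(make_read(ins1), amplicon_spec).category == NHEJ
    del2 = donor[: cut - 1] + donor[cut + 1:]
    assert classify_read(make_read(del2), amplicon_spec).category == MIXED


def test_fast_path_equals_full_alignment_route(amplicon_spec):
    from hdrscreen.amplicon_editing import _categorize, _flag_states

    for bases, template in [
        (amplicon_spec.reference, "reference"),
        (amplicon_spec.donor, "donor"),
    ]:
        fast = classify_read(make_read(bases), amplicon_spec)
        aln = needleman_wunsch(
            bases,
            amplicon_spec.donor if template == "donor" else amplicon_spec.reference,
        )
        flags = _flag_states(aln, amplicon_spec, template)
        assert fast.flags_converted == flags
        assert fast.category == _categorize(amplicon_spec, flags, False, template)
        assert fast.alignment_score == aln.score


def test_short_read_is_ambiguous(amplicon_spec):
    short = amplicon_spec.reference[: len(amplicon_spec.reference) // 3]
    assert classify_read(make_read(short), amplicon_spec).category == AMBIGUOUS


def test_partial_flag_conversion_is_ambiguous(amplicon_spec):
    partial = build_template(amplicon_spec, "partial@0")
    c = classify_read(make_read(partial), amplicon_spec)
    assert c.category == AMBIGUOUS
    assert c.flags_converted == (True, False)


def test_indel_outside_window_with_reference_bases_is_not_nhej(amplicon_spec):
    ref = amplicon_spec.reference
    distant = ref[:5] + ref[7:]  # 2-nt deletion far from the cut
    c = classify_read(make_read(distant), amplicon_spec)
    assert c.category == UNEDITED
    assert not c.indel_in_window


def test_substitution_read_keeps_unedited(amplicon_spec):
    ref = amplicon_spec.reference
    mutated = "T" + ref[1:] if ref[0] != "T" else "A" + ref[1:]
    c = classify_read(make_read(mutated), amplicon_spec)
    assert c.category == UNEDITED
    assert c.chosen_template == "reference"


def test_window_halfwidth_controls_nhej_call(amplicon_spec):
    from hdrscreen.synthetic_data import example_amplicon_spec

    ref = amplicon_spec.reference
    cut = amplicon_spec.cut_index
    # 1-nt deletion 5 bases from the cut: outside +/-3, inside +/-6
    edge = ref[: cut + 4] + ref[cut + 5:]
    assert classify_read(make_read(edge), amplicon_spec).category == UNEDITED
    wide = example_amplicon_spec(window_halfwidth=6)
    assert classify_read(make_read(edge), wide).category == NHEJ


# ---------------------------------------------------------------------------
# rate summaries
# ---------------------------------------------------------------------------

def _cls(category, read_id="r", flags=(False, False)):
    from hdrscreen.amplicon_editing import ReadClassification

    return ReadClassification(read_id, category, category in (NHEJ, MIXED),
                              flags, "reference", 0.0)


def test_rates_denominator_excludes_merge_failures():
    cls = [_cls(HDR)] * 9 + [_cls(UNEDITED)] * 81
    rates = summarize_rates(cls, n_merge_failures=10)
    assert rates.aligned_reads == 90
    assert rates.hdr_rate == pytest.approx(9 / 90)


def test_all_unedited_rates():
    rates = summarize_rates([_cls(UNEDITED)] * 5)
    assert rates.hdr_rate == 0 and rates.nhej_rate == 0
    assert rates.unedited_rate == 1


def test_mixed_counts_in_nhej_numerator():
    cls = (
        [_cls(HDR)] * 30 + [_cls(NHEJ)] * 45 + [_cls(MIXED)] * 5 + [_cls(UNEDITED)] * 20
    )
    rates = summarize_rates(cls)
    assert rates.hdr_rate == pytest.approx(0.30)
    assert rates.nhej_rate == pytest.approx(0.50)
    assert rates.mixed_rate == pytest.approx(0.05)
    assert rates.unedited_rate == pytest.approx(0.20)
    # category fractions partition the aligned reads
    assert (
        rates.hdr_rate + (rates.nhej_rate - rates.mixed_rate)
        + rates.mixed_rate + rates.unedited_rate
    ) == pytest.approx(1.0)


def test_zero_aligned_reads_reports_nan():
    rates = summarize_rates([], n_merge_failures=4)
    assert np.isnan(rates.hdr_rate)


def test_every_read_gets_exactly_one_category(amplicon_spec, rng):
    params = AmpliconSimParams(
        mixture={"unedited": 0.4, "hdr": 0.3, "del2@cut": 0.2, "ins1@cut": 0.1},
        n_reads=300,
        seed=5,
    )
    r1, r2, truth = simulate_amplicon_reads(amplicon_spec, params)
    rates, cls = quantify_editing(amplicon_spec, r1, r2, adapter=params.adapter)
    assert len(cls) + rates.merge_failures == 300
    assert (
        rates.n_hdr + rates.n_nhej + rates.n_mixed + rates.n_unedited
        == rates.aligned_reads
    )


def test_hdr_rate_monotone_in_programmed_fraction(amplicon_spec):
    estimates = []
    for frac in (0.1, 0.3, 0.5):
        params = AmpliconSimParams(
            mixture={"hdr": frac, "del2@cut": 0.2, "unedited": 0.8 - frac},
            n_reads=600,
            seed=77,
        )
        r1, r2, _ = simulate_amplicon_reads(amplicon_spec, params)
        rates, _ = quantify_editing(amplicon_spec, r1, r2, adapter=params.adapter)
        estimates.append(rates.hdr_rate)
    assert estimates[0] < estimates[1] < estimates[2]
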