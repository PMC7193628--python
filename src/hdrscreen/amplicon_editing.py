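"""Amplicon editing-outcome quantification: HDR / NHEJ / SSTR rates.

The pipeline mirrors the standard amplicon deep-sequencing workflow for
scoring Cas9 editing outcomes: paired reads are adapter trimmed and merged,
each merged read is globally aligned (Needleman-Wunsch, affine gaps) to the
unedited reference amplicon and to the donor sequence, and the read is
classified by (a) whether every programmed donor edit ("flag") is converted
and (b) whether any insertion or deletion falls inside a window around the
Cas9 cut site:

* HDR       -- all flags converted, no indel in the cut window;
* NHEJ      -- an indel in the cut window, flags not all converted;
* MIXED     -- all flags converted but also an indel in the window
               (donor conversion plus imperfect repair; excluded from HDR
               and counted with NHEJ, whose definition is "any read with a
               window indel");
* UNEDITED  -- no flag converted, no indel in the window;
* AMBIGUOUS -- merge/alignment failures, reads shorter than half the
               amplicon, alignments below the score floor, and partial
               (some-but-not-all) flag conversion without a window indel.

Rates are reported over aligned reads (total minus merge failures and
AMBIGUOUS reads).  Per-flag conversion frequencies are reported separately,
which is how single-nucleotide SSTR conversion is scored.

Coordinates are 0-based; the cut falls between ``cut_index - 1`` and
``cut_index`` of the reference.  The default indel window is +/-3 bases
around the cut (a six-base-pair window, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    AmpliconSpec,
    SequenceRead,
    ValidationError,
    pam_matches,
    revcomp,
)

__all__ = [
    "AlignScoring",
    "AlignOp",
    "Alignment",
    "ReadClassification",
    "EditingRates",
    "DEFAULT_SCORING",
    "needleman_wunsch",
    "trim_adapter",
    "merge_pair",
    "infer_cut_index",
    "classify_read",
    "classify_pool",
    "summarize_rates",
    "quantify_editing",
]

_NEG = -1.0e30  # effective -infinity for the DP matrices


@dataclass(frozen=True)
class AlignScoring:
    """Global-alignment scoring; a gap of length L costs open + extend*(L-1).

    Defaults mirror the classic EDNAFULL global-alignment convention
    (match +5, mismatch -4, gap open -10, gap extend -0.5, end gaps
    penalized).
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


DEFAULT_SCORING = AlignScoring()


@dataclass(frozen=True)
class AlignOp:
    """Run-length alignment operation in reference (sequence ``b``) coordinates.

    ``insertion`` = bases present in the query ``a`` but not in ``b``
    (placed before reference position ``ref_start``); ``deletion`` = bases
    of ``b`` absent from ``a`` covering ``[ref_start, ref_start + length)``.
    """

    kind: str  # match | mismatch | insertion | deletion
    ref_start: int
    length: int


@dataclass(frozen=True)
class Alignment:
    """A global alignment of query ``a`` against reference ``b``."""

    aligned_a: str
    aligned_b: str
    score: float
    operations: tuple[AlignOp, ...]


# ---------------------------------------------------------------------------
# Needleman-Wunsch with affine gaps (Gotoh three-state DP)
# ---------------------------------------------------------------------------

def _argpriority(m_val: float, x_val: float, y_val: float) -> int:
    """Index of the max of (M, X, Y); ties resolved in that priority order
    (diagonal, then gap-in-b, then gap-in-a)."""
    best = m_val
    idx = 0
    if x_val > best:
        best, idx = x_val, 1
    if y_val > best:
        idx = 2
    return idx


def needleman_wunsch(
    a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING
) -> Alignment:
    """Optimal global alignment of ``a`` (query) to ``b`` (reference).

    Affine gaps: a run of L gap columns costs gap_open + gap_extend*(L-1);
    end gaps are penalized.  ``N`` scores as a mismatch against every base
    (including another N).  Traceback is deterministic: on ties the
    diagonal move wins, then a gap in ``b``, then a gap in ``a``.
    """
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    match, mismatch = scoring.match, scoring.mismatch
    open_, ext = scoring.gap_open, scoring.gap_extend

    # Three-state DP: M = a[i-1] aligned to b[j-1]; X = gap in b (consumes
    # a); Y = gap in a (consumes b).  Rows depend only on the previous row
    # except Y's within-row recurrence, solved in closed form by a running
    # maximum (exact for scores on a half-integer grid).
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = open_ + ext * np.arange(n)
    if m:
        Y[0, 1:] = open_ + ext * np.arange(m)

    a_arr = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    b_is_n = b_arr == ord("N")
    j_idx = np.arange(m)

    for i in range(1, n + 1):
        ai = a_arr[i - 1]
        if ai == ord("N"):
            sub = np.full(m, mismatch)
        else:
            sub = np.where((b_arr == ai) & ~b_is_n, match, mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + open_, X[i - 1, 1:] + ext),
            Y[i - 1, 1:] + open_,
        )
        if m:
            B = np.maximum(M[i], X[i])
            t = B[:-1] + open_ - ext * j_idx
            Y[i, 1:] = np.maximum.accumulate(t) + ext * j_idx

    score = max(M[n, m], X[n, m], Y[n, m])
    state = _argpriority(M[n, m], X[n, m], Y[n, m])

    # Traceback by recomputing each cell's best predecessor.
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # M: diagonal
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            state = _argpriority(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i -= 1
            j -= 1
        elif state == 1:  # X: gap in b, consume a[i-1]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            state = _argpriority(
                M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_
            )
            i -= 1
        else:  # Y: gap in a, consume b[j-1]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            state = _argpriority(
                M[i, j - 1] + open_, X[i, j - 1] + open_, Y[i, j - 1] + ext
            )
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    aligned_a = "".join(cols_a)
    aligned_b = "".join(cols_b)

    ops: list[AlignOp] = []
    ref_pos = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if cb == "-":
            kind = "insertion"
        elif ca == "-":
            kind = "deletion"
        elif ca == cb and ca != "N":
            kind = "match"
        else:
            kind = "mismatch"
        if ops and ops[-1].kind == kind and kind != "insertion":
            ops[-1] = AlignOp(kind, ops[-1].ref_start, ops[-1].length + 1)
        elif ops and ops[-1].kind == kind == "insertion" and ops[-1].ref_start == ref_pos:
            ops[-1] = AlignOp(kind, ops[-1].ref_start, ops[-1].length + 1)
        else:
            ops.append(AlignOp(kind, ref_pos, 1))
        if cb != "-":
            ref_pos += 1

    return Alignment(aligned_a, aligned_b, float(score), tuple(ops))


def rescore(alignment: Alignment, scoring: AlignScoring = DEFAULT_SCORING) -> float:
    """Re-apply the scoring parameters to an alignment's operations."""
    total = 0.0
    for op in alignment.operations:
        if op.kind == "match":
            total += scoring.match * op.length
        elif op.kind == "mismatch":
            total += scoring.mismatch * op.length
        else:
            total += scoring.gap_open + scoring.gap_extend * (op.length - 1)
    return total


# ---------------------------------------------------------------------------
# Adapter trimming and pair merging
# ---------------------------------------------------------------------------

def trim_adapter(
    read: SequenceRead, adapter: str, min_match: int = 3
) -> SequenceRead:
    """Remove the longest read suffix matching a prefix of ``adapter``.

    A candidate suffix of length L must match adapter[:L] with at most
    floor(L / 10) mismatches (one mismatch allowed per 10 nt) and L >=
    ``min_match``.  Qualities are trimmed in step; reads shorter than
    ``min_match`` are returned unchanged.
    """
    if not adapter:
        raise ValidationError("adapter must be non-empty")
    adapter = adapter.upper()
    bases = read.bases.upper()
    L_read = len(bases)
    for start in range(0, L_read - min_match + 1):
        span = min(L_read - start, len(adapter))
        if span < min_match:
            break
        allowed = span // 10
        mismatches = 0
        ok = True
        for k in range(span):
            if bases[start + k] != adapter[k]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return SequenceRead(
                read.read_id, read.bases[:start], read.qualities[:start]
            )
    return read


def merge_pair(
    r1: SequenceRead,
    r2: SequenceRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.2,
) -> SequenceRead | None:
    """Merge a read pair into one fragment sequence, or None on failure.

    ``r2`` is the reverse-strand mate and is reverse-complemented
    internally.  The overlap maximizing the number of matching bases is
    consumed (ties favor the longer overlap); candidate overlaps must be at
    least ``min_overlap`` long with a mismatch fraction at most
    ``max_mismatch_frac``.  Overlap disagreements are resolved to the
    higher-quality base (ties favor mate 1).
    """
    s1 = r1.bases.upper()
    q1 = r1.qualities
    s2 = revcomp(r2.bases.upper())
    q2 = r2.qualities[::-1]
    l1, l2 = len(s1), len(s2)

    best_o = 0
    best_matches = -1
    for o in range(min(l1, l2), min_overlap - 1, -1):
        if o <= best_matches:
            break  # no shorter overlap can match more bases
        mismatches = sum(1 for x, y in zip(s1[l1 - o:], s2[:o]) if x != y)
        if mismatches / o > max_mismatch_frac:
            continue
        matches = o - mismatches
        if matches > best_matches:
            best_matches = matches
            best_o = o
    if best_matches < 0:
        return None

    o = best_o
    head_b, head_q = s1[: l1 - o], list(q1[: l1 - o])
    tail_b, tail_q = s2[o:], list(q2[o:])
    mid_b: list[str] = []
    mid_q: list[int] = []
    for k in range(o):
        b1, b2 = s1[l1 - o + k], s2[k]
        p1, p2 = q1[l1 - o + k], q2[k]
        if b1 == b2:
            mid_b.append(b1)
            mid_q.append(max(p1, p2))
        elif p2 > p1:
            mid_b.append(b2)
            mid_q.append(p2)
        else:
            mid_b.append(b1)
            mid_q.append(p1)
    return SequenceRead(
        r1.read_id,
        head_b + "".join(mid_b) + tail_b,
        tuple(head_q + mid_q + tail_q),
    )


# ---------------------------------------------------------------------------
# Cut-site inference
# ---------------------------------------------------------------------------

def infer_cut_index(spec: AmpliconSpec) -> int:
    """Place the blunt Cas9 cut from the protospacer/PAM position.

    SpCas9 cuts between protospacer positions 17 and 18 (3 nt 5' of the
    PAM).  The protospacer must occur exactly once in the reference, on
    either strand, with an adjacent PAM; the result is strand-symmetric.
    """
    if spec.protospacer is None:
        raise ValidationError(f"amplicon {spec.name!r}: no protospacer given")
    ref = spec.reference
    proto = spec.protospacer
    pam = spec.pam
    k = len(proto)
    hits: list[int] = []  # candidate cut indices
    occurrences = 0

    # forward strand: proto at [s, s+k), PAM at [s+k, s+k+|pam|)
    s = ref.find(proto)
    while s != -1:
        occurrences += 1
        if pam_matches(pam, ref[s + k: s + k + len(pam)]):
            hits.append(s + k - 3)
        s = ref.find(proto, s + 1)

    # reverse strand: revcomp(proto) at [s, s+k), PAM revcomp at [s-|pam|, s)
    rc = revcomp(proto)
    s = ref.find(rc)
    while s != -1:
        occurrences += 1
        if pam_matches(pam, revcomp(ref[max(s - len(pam), 0): s])):
            hits.append(s + 3)
        s = ref.find(rc, s + 1)

    if occurrences == 0:
        raise ValidationError(
            f"amplicon {spec.name!r}: protospacer not found in reference"
        )
    if occurrences > 1:
        raise ValidationError(
            f"amplicon {spec.name!r}: protospacer occurs {occurrences} times "
            "in the reference"
        )
    if not hits:
        raise ValidationError(
            f"amplicon {spec.name!r}: protospacer found but no adjacent "
            f"{spec.pam} PAM"
        )
    cut = hits[0]
    if not 0 <= cut <= len(ref):
        raise ValidationError(
            f"amplicon {spec.name!r}: inferred cut index {cut} falls outside "
            "the reference"
        )
    return cut


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------

#: Classification categories.
UNEDITED, HDR, NHEJ, MIXED, AMBIGUOUS = (
    "UNEDITED", "HDR", "NHEJ", "MIXED", "AMBIGUOUS",
)


@dataclass(frozen=True)
class ReadClassification:
    """Editing-outcome call for one merged read."""

    read_id: str
    category: str
    indel_in_window: bool
    flags_converted: tuple[bool, ...]
    chosen_template: str  # "reference" | "donor"
    alignment_score: float

    @property
    def n_flags_converted(self) -> int:
        return sum(self.flags_converted)


def _window_interval(spec: AmpliconSpec, template: str) -> tuple[int, int]:
    """Indel window [lo, hi) in the chosen template's coordinates."""
    w = spec.window_halfwidth
    lo = spec.cut_index - w
    hi = spec.cut_index + w
    if template == "donor":
        lo = spec.donor_pos(lo) if lo >= 0 else lo
        hi = spec.donor_pos(hi)
    return lo, hi


def _indel_in_window(alignment: Alignment, lo: int, hi: int) -> bool:
    for op in alignment.operations:
        if op.kind == "insertion":
            # inserted before template position ref_start
            if lo <= op.ref_start <= hi:
                return True
        elif op.kind == "deletion":
            if op.ref_start < hi and op.ref_start + op.length > lo:
                return True
    return False


def _flag_states(
    alignment: Alignment, spec: AmpliconSpec, template: str
) -> tuple[bool, ...]:
    """Per-flag conversion: the read base aligned at each flag position.

    Read from the chosen template's alignment (positions mapped to donor
    coordinates when the donor template won): around the cut, indels and
    flag substitutions can make reference-alignment placement ambiguous,
    while the best-scoring template pins the flag columns down.
    """
    if template == "donor":
        positions = {spec.donor_pos(f.ref_pos): f for f in spec.flags}
    else:
        positions = {f.ref_pos: f for f in spec.flags}
    bases: dict[int, str] = {}
    pos = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if cb != "-":
            if pos in positions:
                bases[pos] = ca  # '-' when the read deletes this base
            pos += 1
    return tuple(
        bases.get(p, "-") == f.alt_base for p, f in sorted(positions.items())
    )


def _categorize(
    spec: AmpliconSpec,
    flags_converted: Sequence[bool],
    indel_in_window: bool,
    chosen_template: str,
) -> str:
    if spec.flags:
        all_conv = all(flags_converted)
        none_conv = not any(flags_converted)
    elif spec.insert_pos is not None:
        # insertion-cassette donor with no SNP flags: donor conversion is
        # carried by the cassette itself
        all_conv = chosen_template == "donor"
        none_conv = not all_conv
    else:
        all_conv, none_conv = False, True
    if indel_in_window:
        return MIXED if all_conv else NHEJ
    if all_conv:
        return HDR
    if none_conv:
        return UNEDITED
    return AMBIGUOUS  # partial flag conversion without a window indel


def classify_read(
    merged: SequenceRead,
    spec: AmpliconSpec,
    scoring: AlignScoring = DEFAULT_SCORING,
    min_length_frac: float = 0.5,
    score_floor_frac: float = 0.6,
) -> ReadClassification:
    """Classify one merged read against the reference and donor templates.

    The read is aligned globally to both templates; the higher-scoring
    template is kept (ties go to the reference).  Reads shorter than
    ``min_length_frac`` of the reference, or whose best alignment scores
    below ``score_floor_frac`` of the maximum attainable score for the
    chosen template, are AMBIGUOUS.
    """
    read = merged.bases.upper()
    n_flags = len(spec.flags)
    if len(read) < min_length_frac * len(spec.reference):
        return ReadClassification(
            merged.read_id, AMBIGUOUS, False, (False,) * n_flags, "reference", 0.0
        )

    # exact-template fast paths (equivalent to the full alignment route;
    # asserted equivalent in the test suite)
    if read == spec.reference:
        return ReadClassification(
            merged.read_id,
            _categorize(spec, (False,) * n_flags, False, "reference"),
            False,
            (False,) * n_flags,
            "reference",
            scoring.match * len(read),
        )
    if read == spec.donor and spec.donor != spec.reference:
        return ReadClassification(
            merged.read_id,
            _categorize(spec, (True,) * n_flags, False, "donor"),
            False,
            (True,) * n_flags,
            "donor",
            scoring.match * len(read),
        )

    aln_ref = needleman_wunsch(read, spec.reference, scoring)
    if spec.donor != spec.reference:
        aln_donor = needleman_wunsch(read, spec.donor, scoring)
    else:
        aln_donor = aln_ref
    if aln_donor.score > aln_ref.score:
        chosen, aln = "donor", aln_donor
        template = spec.donor
    else:
        chosen, aln = "reference", aln_ref
        template = spec.reference

    flags_converted = _flag_states(aln, spec, chosen)
    if aln.score < score_floor_frac * scoring.match * len(template):
        return ReadClassification(
            merged.read_id, AMBIGUOUS, False, flags_converted, chosen, aln.score
        )
    lo, hi = _window_interval(spec, chosen)
    indel = _indel_in_window(aln, lo, hi)
    return ReadClassification(
        merged.read_id,
        _categorize(spec, flags_converted, indel, chosen),
        indel,
        flags_converted,
        chosen,
        aln.score,
    )


def classify_pool(
    merged_reads: Iterable[SequenceRead],
    spec: AmpliconSpec,
    scoring: AlignScoring = DEFAULT_SCORING,
    **kwargs,
) -> list[ReadClassification]:
    """Classify many merged reads, memoizing identical sequences."""
    cache: dict[str, ReadClassification] = {}
    out: list[ReadClassification] = []
    for read in merged_reads:
        hit = cache.get(read.bases)
        if hit is None:
            hit = classify_read(read, spec, scoring, **kwargs)
            cache[read.bases] = hit
        if hit.read_id != read.read_id:
            hit = ReadClassification(
                read.read_id,
                hit.category,
                hit.indel_in_window,
                hit.flags_converted,
                hit.chosen_template,
                hit.alignment_score,
            )
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# Rate summaries
# ---------------------------------------------------------------------------

@dataclass
class EditingRates:
    """HDR/NHEJ/unedited fractions over aligned reads.

    ``aligned_reads`` = total - merge failures - AMBIGUOUS.  ``nhej_rate``
    counts every read with a window indel (NHEJ + MIXED); ``mixed_rate`` is
    reported separately so either accounting can be reconstructed, and the
    category fractions hdr + (nhej - mixed) + mixed + unedited partition
    the aligned reads exactly.  ``ambiguous_rate`` is over total reads.
    Rates are NaN when no read aligns.
    """

    total_reads: int
    merge_failures: int
    aligned_reads: int
    n_hdr: int
    n_nhej: int  # window-indel reads without full conversion
    n_mixed: int
    n_unedited: int
    n_ambiguous: int
    hdr_rate: float
    nhej_rate: float
    mixed_rate: float
    unedited_rate: float
    ambiguous_rate: float
    per_flag_conversion: dict[str, float] = field(default_factory=dict)


def summarize_rates(
    classifications: Sequence[ReadClassification],
    spec: AmpliconSpec | None = None,
    n_merge_failures: int = 0,
) -> EditingRates:
    """Aggregate per-read calls into editing rates.

    HDR rate = #HDR / aligned; NHEJ rate = (#NHEJ + #MIXED) / aligned
    (every read with a window indel); per-flag conversion = reads carrying
    that flag's alt base / aligned.
    """
    counts = {UNEDITED: 0, HDR: 0, NHEJ: 0, MIXED: 0, AMBIGUOUS: 0}
    for c in classifications:
        counts[c.category] += 1
    total = len(classifications) + n_merge_failures
    aligned = total - n_merge_failures - counts[AMBIGUOUS]

    if spec is not None:
        labels = [f.label for f in spec.flags]
    elif classifications:
        labels = [f"flag_{i}" for i in range(len(classifications[0].flags_converted))]
    else:
        labels = []
    flag_counts = [0] * len(labels)
    for c in classifications:
        if c.category == AMBIGUOUS:
            continue
        for i, converted in enumerate(c.flags_converted):
            if converted:
                flag_counts[i] += 1

    if aligned > 0:
        hdr = counts[HDR] / aligned
        nhej = (counts[NHEJ] + counts[MIXED]) / aligned
        mixed = counts[MIXED] / aligned
        unedited = counts[UNEDITED] / aligned
        per_flag = {lab: c / aligned for lab, c in zip(labels, flag_counts)}
    else:
        hdr = nhej = mixed = unedited = float("nan")
        per_flag = {lab: float("nan") for lab in labels}
    ambiguous = counts[AMBIGUOUS] / total if total else float("nan")

    return EditingRates(
        total_reads=total,
        merge_failures=n_merge_failures,
        aligned_reads=aligned,
        n_hdr=counts[HDR],
        n_nhej=counts[NHEJ],
        n_mixed=counts[MIXED],
        n_unedited=counts[UNEDITED],
        n_ambiguous=counts[AMBIGUOUS],
        hdr_rate=hdr,
        nhej_rate=nhej,
        mixed_rate=mixed,
        unedited_rate=unedited,
        ambiguous_rate=ambiguous,
        per_flag_conversion=per_flag,
    )


def quantify_editing(
    spec: AmpliconSpec,
    reads1: Iterable[SequenceRead],
    reads2: Iterable[SequenceRead] | None = None,
    adapter: str | None = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.2,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[EditingRates, list[ReadClassification]]:
    """Full pipeline: trim, merge (if paired), classify, summarize.

    ``reads2 is None`` treats ``reads1`` as already-merged single reads.
    Merging is memoized on read sequences+qualities, which collapses the
    deep identical-read pools typical of amplicon data.
    """
    merged: list[SequenceRead] = []
    failures = 0
    if reads2 is None:
        for r in reads1:
            merged.append(trim_adapter(r, adapter) if adapter else r)
    else:
        merge_cache: dict[tuple, SequenceRead | None] = {}
        for r1, r2 in zip(reads1, reads2):
            key = (r1.bases, r1.qualities, r2.bases, r2.qualities)
            if key in merge_cache:
                result = merge_cache[key]
            else:
                t1 = trim_adapter(r1, adapter) if adapter else r1
                t2 = trim_adapter(r2, adapter) if adapter else r2
                result = merge_pair(t1, t2, min_overlap, max_mismatch_frac)
                merge_cache[key] = result
            if result is None:
                failures += 1
            else:
                merged.append(SequenceRead(r1.read_id, result.bases, result.qualities))
    classifications = classify_pool(merged, spec, scoring)
    rates = summarize_rates(classifications, spec, n_merge_failures=failures)
    return rates, classifications
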