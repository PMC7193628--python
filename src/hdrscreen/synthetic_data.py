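"""Synthetic screen counts and amplicon read pools with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage is testable without any sequencing download:

* a CRISPRi guide library (~2000 genes at five guides per TSS plus
  non-targeting controls);
* screen count data from a generative sorting model: each guide g carries
  an HDR probability p_g = clamp(base_hdr * multiplier(gene) * 2**eps_g, 0, 1)
  with eps_g ~ Normal(0, guide_noise_sd) for guides whose gene has an
  effect (multiplier != 1).  The noise models guide-to-guide knockdown
  efficacy, which can only express itself through an effect, so guides of
  no-effect genes -- like the non-targeting controls -- sit exactly at
  base_hdr; that is also what makes true-null genes exchangeable with the
  control null the screen test relies on.  Cells are distributed
  over guides by a multinomial; HDR cells sort into the GFP+ bin with
  probability ``sorting_purity`` while non-HDR cells contaminate it at
  1 - sorting_purity; sequencing reads per population are multinomial over
  that population's cell composition at a fixed total depth;
* screen cassette FASTQ reads (fixed flanks around each protospacer) whose
  recount reproduces the input counts exactly;
* paired amplicon reads drawn from a programmed mixture of outcome
  templates (unedited / hdr / named indels such as ``del2@cut`` /
  partial-conversion templates) with a per-base substitution error rate,
  split into overlapping mates with adapter read-through when the fragment
  is shorter than the read length.

All outputs are deterministic under the seed: one seed fans out to
per-component child seeds via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .guide_quant import CountMatrix
from .io_formats import (
    CONTROL_GENE,
    AmpliconFlag,
    AmpliconSpec,
    GuideEntry,
    GuideLibrary,
    SequenceRead,
    ValidationError,
    revcomp,
    write_fastq,
)

__all__ = [
    "ScreenSimParams",
    "AmpliconSimParams",
    "make_library",
    "simulate_screen_counts",
    "simulate_screen_reads",
    "simulate_amplicon_reads",
    "example_amplicon_spec",
    "expected_guide_enrichment",
    "expected_collapsed_score",
    "CASSETTE_FLANK5",
    "CASSETTE_FLANK3",
    "DEFAULT_ADAPTER",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed cassette flanks around the protospacer in simulated screen reads.
#: The real read structure depends on the screening vector; these flanks
#: are a fixture definition, constant so recounting is exact.
CASSETTE_FLANK5 = "TTGTGGAAAGGACGAAACACCG"
CASSETTE_FLANK3 = "GTTTTAGAGCTAGAAATAGCA"

#: Illumina TruSeq universal adapter prefix used for read-through.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"

_READ_QUAL = 37  # constant Phred score for simulated bases


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Guide library generation
# ---------------------------------------------------------------------------

def make_library(
    n_genes: int,
    guides_per_gene: int = 5,
    n_controls: int = 250,
    seed: int = 0,
    protospacer_length: int = 20,
) -> GuideLibrary:
    """Generate a guide library with unique ids and unique protospacers.

    Produces ``n_genes * guides_per_gene`` targeting guides (genes named
    G0001, G0002, ...) plus ``n_controls`` non-targeting controls, with
    random distinct protospacers; deterministic under the seed.
    """
    if min(n_genes, guides_per_gene, n_controls) < 0:
        raise ValidationError("library counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_total = n_genes * guides_per_gene + n_controls
    seen: set[str] = set()
    protos: list[str] = []
    attempts = 0
    max_attempts = 50 * max(n_total, 1)
    while len(protos) < n_total:
        if attempts >= max_attempts:
            raise ValidationError(
                "could not generate distinct protospacers within the retry bound"
            )
        attempts += 1
        p = bytes(_BASES[rng.integers(0, 4, protospacer_length)]).decode()
        if p not in seen:
            seen.add(p)
            protos.append(p)
    entries: list[GuideEntry] = []
    it = iter(protos)
    width = max(4, len(str(n_genes)))
    for g in range(n_genes):
        gene = f"G{g + 1:0{width}d}"
        for j in range(guides_per_gene):
            entries.append(GuideEntry(f"{gene}_g{j + 1}", gene, next(it), False))
    for c in range(n_controls):
        entries.append(GuideEntry(f"CTRL_{c + 1:05d}", CONTROL_GENE, next(it), True))
    return GuideLibrary(entries)


# ---------------------------------------------------------------------------
# Screen count simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Study conditions of the simulated sorting screen.

    Defaults reflect the screen design the analysis targets: ~2000 genes
    at five guides per TSS plus non-targeting controls, a low baseline HDR
    probability, log-normal guide-level efficacy spread, and high but
    imperfect FACS purity.  ``n_cells`` defaults to 500 cells per guide;
    ``reads_per_guide_depth`` fixes each population's total sequencing
    depth at depth * n_guides reads.
    """

    n_genes: int = 2000
    guides_per_gene: int = 5
    n_controls: int = 250
    base_hdr: float = 0.05
    effect_multipliers: Mapping[str, float] = field(default_factory=dict)
    guide_noise_sd: float = 0.25
    n_cells: int | None = None
    reads_per_guide_depth: int = 500
    sorting_purity: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.base_hdr <= 1:
            raise ValidationError("base_hdr must be in (0, 1]")
        if self.guide_noise_sd < 0:
            raise ValidationError("guide_noise_sd must be >= 0")
        if not 0 <= self.sorting_purity <= 1:
            raise ValidationError("sorting_purity must be in [0, 1]")
        if self.reads_per_guide_depth <= 0:
            raise ValidationError("sequencing depth must be positive")
        if any(m <= 0 for m in self.effect_multipliers.values()):
            raise ValidationError("effect multipliers must be positive")
        if self.effect_multipliers:
            if self.base_hdr * max(self.effect_multipliers.values()) > 1:
                raise ValidationError(
                    "base_hdr * max multiplier exceeds 1: HDR probabilities "
                    "would saturate"
                )


def simulate_screen_counts(
    library: GuideLibrary, params: ScreenSimParams
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate PRESORT/GFP/NON count columns plus the per-guide truth table.

    Returns ``(counts, truth)`` where truth records each guide's gene,
    multiplier and realized HDR probability p_g.  Column sums equal
    depth * n_guides exactly (multinomial construction).
    """
    n = len(library)
    if n == 0:
        raise ValidationError("empty guide library")
    genes = set(library.genes())
    for g in params.effect_multipliers:
        if g not in genes:
            raise ValidationError(f"effect multiplier for unknown gene {g!r}")

    is_ctrl = np.array([e.is_control for e in library])
    mult = np.array(
        [
            1.0 if e.is_control else params.effect_multipliers.get(e.gene, 1.0)
            for e in library
        ]
    )
    rng_noise, rng_cells, rng_hdr, rng_sort, rng_seq = _child_rngs(params.seed, 5)

    eps = rng_noise.normal(0.0, params.guide_noise_sd, n)
    eps[mult == 1.0] = 0.0  # efficacy noise expresses only through an effect
    p = np.clip(params.base_hdr * mult * np.exp2(eps), 0.0, 1.0)
    p[is_ctrl] = params.base_hdr

    n_cells = params.n_cells if params.n_cells is not None else 500 * n
    cells = rng_cells.multinomial(n_cells, np.full(n, 1.0 / n))
    hdr_cells = rng_hdr.binomial(cells, p)
    gfp_cells = rng_sort.binomial(hdr_cells, params.sorting_purity)
    gfp_cells = gfp_cells + rng_sort.binomial(
        cells - hdr_cells, 1.0 - params.sorting_purity
    )
    non_cells = cells - gfp_cells

    depth_total = params.reads_per_guide_depth * n
    columns = {}
    for label, comp in (("PRESORT", cells), ("GFP", gfp_cells), ("NON", non_cells)):
        total = comp.sum()
        if total == 0:
            raise ValidationError(f"population {label} contains no cells")
        columns[label] = rng_seq.multinomial(depth_total, comp / total)

    counts = CountMatrix(
        guide_ids=library.guide_ids,
        samples=["PRESORT", "GFP", "NON"],
        counts=np.stack([columns["PRESORT"], columns["GFP"], columns["NON"]], axis=1),
    )
    truth = pd.DataFrame(
        {
            "guide_id": library.guide_ids,
            "gene": [e.gene for e in library],
            "is_control": is_ctrl,
            "multiplier": mult,
            "p_hdr": p,
            "cells": cells,
        }
    )
    return counts, truth


def simulate_screen_reads(
    counts: Mapping[str, int],
    library: GuideLibrary,
    seed: int = 0,
    path=None,
) -> tuple[list[SequenceRead], dict[str, int]]:
    """Emit one cassette read per counted guide occurrence.

    Reads are ``flank5 + protospacer + flank3`` with constant qualities,
    shuffled deterministically under the seed.  Returns the reads and the
    truth counts (equal to the input multiplicities); if ``path`` is given
    the reads are also written as FASTQ.
    """
    proto = {e.guide_id: e.protospacer for e in library}
    unknown = set(counts) - set(proto)
    if unknown:
        raise ValidationError(f"counts for unknown guide(s): {sorted(unknown)}")
    guide_ids = [g for g in proto if counts.get(g, 0) > 0]
    expanded = np.repeat(
        np.array(guide_ids, dtype=object),
        [counts[g] for g in guide_ids],
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    expanded = expanded[rng.permutation(len(expanded))]
    reads = [
        SequenceRead(
            f"screenread_{i:07d}",
            CASSETTE_FLANK5 + proto[g] + CASSETTE_FLANK3,
            (_READ_QUAL,) * (len(CASSETTE_FLANK5) + len(proto[g]) + len(CASSETTE_FLANK3)),
        )
        for i, g in enumerate(expanded)
    ]
    if path is not None:
        write_fastq(reads, path)
    truth = {g: int(counts[g]) for g in guide_ids}
    return reads, truth


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

@dataclass
class AmpliconSimParams:
    """Study conditions for one simulated amplicon sequencing sample.

    ``mixture`` maps outcome-template names to probabilities (sum 1 within
    1e-9).  Recognized names: ``unedited``, ``hdr``, ``insN@cut`` /
    ``insN@<pos>``, ``delN@cut`` / ``delN@<pos>`` (deletions of N bases
    centered on the position; insertions of N random bases before it) and
    ``partial@<i>`` (only flag i converted).  The default depth of 10,000
    reads matches the sequencing depth floor of the assay the generator
    emulates.
    """

    mixture: Mapping[str, float] = field(
        default_factory=lambda: {"unedited": 0.25, "hdr": 0.30, "del2@cut": 0.45}
    )
    n_reads: int = 10_000
    substitution_error_rate: float = 0.001
    read_length: int = 100
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValidationError("substitution_error_rate must be in [0, 1)")
        if self.read_length <= 0:
            raise ValidationError("read_length must be positive")
        probs = list(self.mixture.values())
        if any(p < 0 for p in probs):
            raise ValidationError("mixture probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("mixture probabilities must sum to 1")


_TEMPLATE_RE = re.compile(r"^(ins|del)(\d+)@(cut|\d+)$")
_PARTIAL_RE = re.compile(r"^partial@(\d+)$")


def build_template(
    spec: AmpliconSpec, name: str, rng: np.random.Generator | None = None
) -> str:
    """Construct the full amplicon sequence for a named outcome template."""
    if name == "unedited":
        return spec.reference
    if name == "hdr":
        return spec.donor
    m = _PARTIAL_RE.match(name)
    if m:
        i = int(m.group(1))
        if i >= len(spec.flags):
            raise ValidationError(f"template {name!r}: no flag index {i}")
        f = spec.flags[i]
        return spec.reference[: f.ref_pos] + f.alt_base + spec.reference[f.ref_pos + 1:]
    m = _TEMPLATE_RE.match(name)
    if not m:
        raise ValidationError(f"unrecognized outcome template {name!r}")
    kind, size, at = m.group(1), int(m.group(2)), m.group(3)
    pos = spec.cut_index if at == "cut" else int(at)
    ref = spec.reference
    if kind == "del":
        start = pos - size // 2
        if start < 0 or start + size > len(ref):
            raise ValidationError(f"template {name!r}: deletion outside reference")
        return ref[:start] + ref[start + size:]
    if not 0 <= pos <= len(ref):
        raise ValidationError(f"template {name!r}: insertion outside reference")
    if rng is None:
        rng = np.random.default_rng(0)
    ins = bytes(_BASES[rng.integers(0, 4, size)]).decode()
    return ref[:pos] + ins + ref[pos:]


def simulate_amplicon_reads(
    spec: AmpliconSpec,
    params: AmpliconSimParams,
    r1_path=None,
    r2_path=None,
) -> tuple[list[SequenceRead], list[SequenceRead], pd.DataFrame]:
    """Draw an amplicon read pool from the programmed outcome mixture.

    Per read: a template is drawn (one seeded multinomial over the
    mixture), per-base substitution errors are applied to the fragment,
    and the fragment is split into overlapping mates (mate 2 reverse-
    complemented) with the adapter appended when the fragment is shorter
    than the read length.  Returns ``(reads1, reads2, truth)`` where the
    truth table records each read's template; template counts in the truth
    table equal the seeded multinomial draw exactly.
    """
    rng_tmpl, rng_draw, rng_err = _child_rngs(params.seed, 3)
    names = sorted(params.mixture)
    templates = {n: build_template(spec, n, rng_tmpl) for n in names}
    probs = np.array([params.mixture[n] for n in names], dtype=float)

    counts = rng_draw.multinomial(params.n_reads, probs / probs.sum())
    assignment = np.repeat(np.array(names, dtype=object), counts)
    assignment = assignment[rng_draw.permutation(len(assignment))]

    L = params.read_length
    reads1: list[SequenceRead] = []
    reads2: list[SequenceRead] = []
    rows = []
    for i, name in enumerate(assignment):
        frag = templates[name]
        if params.substitution_error_rate > 0:
            arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
            hits = np.nonzero(rng_err.random(arr.size) < params.substitution_error_rate)[0]
            for h in hits:
                choices = _BASES[_BASES != arr[h]]
                arr[h] = choices[rng_err.integers(0, len(choices))]
            frag = arr.tobytes().decode()
        b1 = (frag + params.adapter)[:L] if len(frag) < L else frag[:L]
        rc = revcomp(frag)
        b2 = (rc + params.adapter)[:L] if len(rc) < L else rc[:L]
        rid = f"amp_{i:06d}"
        reads1.append(SequenceRead(rid, b1, (_READ_QUAL,) * len(b1)))
        reads2.append(SequenceRead(rid, b2, (_READ_QUAL,) * len(b2)))
        rows.append({"read_id": rid, "template": name})
    truth = pd.DataFrame(rows, columns=["read_id", "template"])
    if r1_path is not None:
        write_fastq(reads1, r1_path)
    if r2_path is not None:
        write_fastq(reads2, r2_path)
    return reads1, reads2, truth


# ---------------------------------------------------------------------------
# Canonical amplicon fixture
# ---------------------------------------------------------------------------

_EX_LEFT = "ATCGGACTTCAGGTCCAGTTACAAC"
_EX_PROTO = "GACGCATAAAGATGAGACGC"
_EX_RIGHT = "CTTAGGTACCAGATCCGTGCAAGT"


def example_amplicon_spec(window_halfwidth: int = 3) -> AmpliconSpec:
    """A synthetic 72-nt amplicon used as the canonical fixture.

    The protospacer sits at offset 25 with a TGG PAM, so the blunt cut
    falls at reference position 42 (3 nt 5' of the PAM).  The donor
    carries two SNP flags: one inside the protospacer (position 40) and
    one destroying the PAM (position 46), the classic recut-blocking
    design.
    """
    reference = _EX_LEFT + _EX_PROTO + "TGG" + _EX_RIGHT
    flags = [
        AmpliconFlag(ref_pos=40, ref_base=reference[40], alt_base="T"),
        AmpliconFlag(ref_pos=46, ref_base=reference[46], alt_base="C"),
    ]
    donor = list(reference)
    for f in flags:
        donor[f.ref_pos] = f.alt_base
    return AmpliconSpec(
        name="synthetic-bfp-amplicon",
        reference=reference,
        donor="".join(donor),
        protospacer=_EX_PROTO,
        cut_index=42,
        flags=flags,
        window_halfwidth=window_halfwidth,
    )


# ---------------------------------------------------------------------------
# Model expectations (for power / recovery checks)
# ---------------------------------------------------------------------------

def _mean_gfp_weight(params: ScreenSimParams) -> float:
    """Expected per-cell GFP-bin weight averaged over the whole library."""
    e2 = float(np.exp((params.guide_noise_sd * np.log(2)) ** 2 / 2))
    pur = params.sorting_purity

    def w(p: float) -> float:
        return pur * p + (1 - pur) * (1 - p)

    n_target = params.n_genes * params.guides_per_gene
    n_total = n_target + params.n_controls
    # efficacy noise (hence the log-normal mean factor e2) applies only to
    # guides whose gene has an effect
    boosted = sum(
        params.guides_per_gene for m in params.effect_multipliers.values() if m != 1.0
    )
    total_w = (n_target - boosted) * w(params.base_hdr)
    for m in params.effect_multipliers.values():
        if m != 1.0:
            total_w += params.guides_per_gene * w(min(params.base_hdr * m * e2, 1.0))
    total_w += params.n_controls * w(params.base_hdr)
    return total_w / n_total


def expected_guide_enrichment(
    params: ScreenSimParams, multiplier: float, pseudocount: float = 1.0
) -> float:
    """Expected log2 GFP-vs-PRESORT enrichment for a guide at ``multiplier``.

    Evaluated at the guide-noise median (eps = 0), with the CPM pseudocount
    included; the library-wide mean GFP weight accounts for the log-normal
    noise and the sorting purity.
    """
    n_total = params.n_genes * params.guides_per_gene + params.n_controls
    w_bar = _mean_gfp_weight(params)
    p = min(params.base_hdr * multiplier, 1.0)
    pur = params.sorting_purity
    w = pur * p + (1 - pur) * (1 - p)
    cpm_pre = 1e6 / n_total
    cpm_gfp = 1e6 * w / (n_total * w_bar)
    return float(np.log2((cpm_gfp + pseudocount) / (cpm_pre + pseudocount)))


def _mean_top_k_order_stat(n: int, k: int) -> float:
    """Mean of the k largest of n standard normal order statistics."""
    total = 0.0
    for r in range(n - k + 1, n + 1):
        coef = n * special.comb(n - 1, r - 1)
        val, _ = integrate.quad(
            lambda x, r=r: coef
            * x
            * stats.norm.cdf(x) ** (r - 1)
            * stats.norm.sf(x) ** (n - r)
            * stats.norm.pdf(x),
            -np.inf,
            np.inf,
        )
        total += val
    return total / k


def expected_collapsed_score(
    params: ScreenSimParams, multiplier: float, k: int = 3, pseudocount: float = 1.0
) -> float:
    """Expected gene phenotype score for a gene at ``multiplier``.

    The collapse keeps the k most extreme of ``guides_per_gene`` guide
    enrichments; for effects well above the guide noise all enrichments
    share one sign, so the expectation is the eps = 0 enrichment plus the
    guide noise scaled by the mean of the top-k normal order statistics.
    """
    e0 = expected_guide_enrichment(params, multiplier, pseudocount)
    shift = params.guide_noise_sd * _mean_top_k_order_stat(params.guides_per_gene, k)
    return e0 + shift if e0 >= 0 else e0 - shift
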