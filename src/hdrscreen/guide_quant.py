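"""Guide cassette counting, CPM normalization and per-guide enrichment.

Reads from each screen population (unsorted baseline PRESORT, sorted GFP+,
non-fluorescent NON) are assigned to the unique guide whose protospacer
occurs exactly (forward orientation) within the read; anything else counts
as unassigned.  Exact matching is deterministic and is the tested default;
no mismatch tolerance is applied.

Counts are normalized to counts-per-million (CPM) over the assigned reads
of each sample, and guide-level phenotypes are log2 ratios of sorted over
baseline CPM with a pseudocount (default 1.0 on the CPM scale) so every
enrichment is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GuideLibrary, SequenceRead, ValidationError

__all__ = [
    "CountMatrix",
    "count_guides",
    "normalize_cpm",
    "guide_enrichment",
    "average_replicates",
]

#: Columns of the guide-phenotype table produced by :func:`guide_enrichment`.
GUIDE_PHENOTYPE_COLUMNS = [
    "guide_id", "gene", "is_control",
    "baseline_cpm", "sorted_cpm", "log2_enrichment", "passes_qc",
]


@dataclass
class CountMatrix:
    """Per-guide read counts across screen populations.

    ``counts`` is an integer array of shape (n_guides, n_samples) in
    library order; ``unassigned`` records, per sample, reads matching no
    guide (or more than one), so assigned + unassigned equals the reads
    processed.
    """

    guide_ids: list[str]
    samples: list[str]
    counts: np.ndarray
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.guide_ids), len(self.samples)):
            raise ValidationError(
                f"count array shape {self.counts.shape} inconsistent with "
                f"{len(self.guide_ids)} guides x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        for s in self.samples:
            self.unassigned.setdefault(s, 0)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "guide_id", self.guide_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c != "guide_id"]
        return cls(
            guide_ids=list(df["guide_id"].astype(str)),
            samples=samples,
            counts=df[samples].to_numpy(dtype=np.int64),
        )

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        if self.guide_ids != other.guide_ids:
            raise ValidationError("guide universes differ between count matrices")
        return CountMatrix(
            guide_ids=self.guide_ids,
            samples=self.samples + other.samples,
            counts=np.hstack([self.counts, other.counts]),
            unassigned={**self.unassigned, **other.unassigned},
        )


def count_guides(
    reads: Iterable[SequenceRead],
    library: GuideLibrary,
    sample: str = "sample",
) -> CountMatrix:
    """Count cassette reads against the library by exact protospacer match.

    Each read is assigned to the single guide whose protospacer occurs as
    an exact forward-orientation substring.  Reads matching no guide, or
    containing the protospacers of two different guides, increment the
    unassigned tally.
    """
    if not len(library):
        raise ValidationError("empty guide library")
    k = library.protospacer_length
    proto_to_idx: dict[str, int] = {}
    for idx, e in enumerate(library):
        if e.protospacer in proto_to_idx:
            raise ValidationError(
                f"protospacer of {e.guide_id!r} duplicates another guide's"
            )
        proto_to_idx[e.protospacer] = idx

    counts = np.zeros(len(library), dtype=np.int64)
    unassigned = 0
    for read in reads:
        bases = read.bases.upper()
        hit: int | None = None
        ambiguous = False
        for start in range(0, len(bases) - k + 1):
            idx = proto_to_idx.get(bases[start:start + k])
            if idx is not None:
                if hit is not None and idx != hit:
                    ambiguous = True
                    break
                hit = idx
        if hit is None or ambiguous:
            unassigned += 1
        else:
            counts[hit] += 1
    return CountMatrix(
        guide_ids=library.guide_ids,
        samples=[sample],
        counts=counts[:, None],
        unassigned={sample: unassigned},
    )


def normalize_cpm(counts: CountMatrix) -> np.ndarray:
    """Counts-per-million over assigned reads, per sample.

    Returns a float array shaped like ``counts.counts``; each sample's CPM
    column sums to 1e6.  A sample with zero assigned reads is an error.
    """
    totals = counts.counts.sum(axis=0)
    for s, t in zip(counts.samples, totals):
        if t == 0:
            raise ValidationError(f"sample {s!r} has zero assigned reads")
    return counts.counts / totals * 1e6


def guide_enrichment(
    library: GuideLibrary,
    sorted_cpm: Sequence[float],
    baseline_cpm: Sequence[float],
    pseudocount: float = 1.0,
    qc_min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2 enrichment of the sorted over the baseline population.

    log2_enrichment = log2((sorted_cpm + pseudocount) /
    (baseline_cpm + pseudocount)); the pseudocount keeps every value
    finite.  ``passes_qc`` is False when baseline CPM < ``qc_min_cpm``
    (guides too poorly represented in the baseline to score).

    Returns a guide-phenotype table with columns
    ``GUIDE_PHENOTYPE_COLUMNS``, in library order.
    """
    sorted_cpm = np.asarray(sorted_cpm, dtype=float)
    baseline_cpm = np.asarray(baseline_cpm, dtype=float)
    if sorted_cpm.shape != baseline_cpm.shape or len(sorted_cpm) != len(library):
        raise ValidationError("CPM vectors must match the guide universe")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    enrich = np.log2(sorted_cpm + pseudocount) - np.log2(baseline_cpm + pseudocount)
    return pd.DataFrame(
        {
            "guide_id": library.guide_ids,
            "gene": [e.gene for e in library],
            "is_control": [e.is_control for e in library],
            "baseline_cpm": baseline_cpm,
            "sorted_cpm": sorted_cpm,
            "log2_enrichment": enrich,
            "passes_qc": baseline_cpm >= qc_min_cpm,
        }
    )


def average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine replicate guide-phenotype tables by averaging enrichments.

    Replicates are processed independently upstream; enrichments are
    averaged per guide here, before any gene-level statistics.  A guide
    passes QC only if it passed in every replicate.
    """
    if not tables:
        raise ValidationError("no replicate tables given")
    first = tables[0]
    for t in tables[1:]:
        if list(t["guide_id"]) != list(first["guide_id"]):
            raise ValidationError("replicate tables have different guide universes")
    out = first.copy()
    for col in ("baseline_cpm", "sorted_cpm", "log2_enrichment"):
        out[col] = np.mean([t[col].to_numpy() for t in tables], axis=0)
    qc = np.logical_and.reduce([t["passes_qc"].to_numpy() for t in tables])
    out["passes_qc"] = qc
    return out
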