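"""Readers and writers for the plain-text formats the pipeline touches.

Three kinds of input are handled here, each with strict, typed validation:

* a guide-library table (TSV: guide_id, gene, protospacer, is_control)
  describing the CRISPRi library, including the non-targeting control
  guides that define the null enrichment distribution;
* an amplicon specification (YAML key-value document) giving the reference
  amplicon, the donor sequence carrying the programmed edits, the Cas9 cut
  site, and the "flag" positions (donor SNPs) whose conversion is scored;
* FASTQ sequencing reads (plain or gzip, Sanger quality offset 33).

Coordinates are 0-based, half-open throughout.  ``cut_index`` counts the
reference bases 5' of the blunt cut, i.e. the cut falls between positions
``cut_index - 1`` and ``cut_index``.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "GuideEntry",
    "GuideLibrary",
    "AmpliconFlag",
    "AmpliconSpec",
    "SequenceRead",
    "CONTROL_GENE",
    "read_guide_library",
    "write_guide_library",
    "read_amplicon_spec",
    "write_amplicon_spec",
    "stream_fastq",
    "write_fastq",
    "revcomp",
]

DNA_BASES = frozenset("ACGT")
DNA_BASES_N = frozenset("ACGTN")

#: Sentinel gene label carried by non-targeting control guides.
CONTROL_GENE = "non-targeting"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC wildcard expansion used for PAM patterns (NGG by default).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, *, what: str, allow_n: bool = False) -> None:
    alphabet = DNA_BASES_N if allow_n else DNA_BASES
    bad = set(seq) - alphabet
    if bad:
        raise ValidationError(
            f"{what} contains non-DNA characters: {sorted(bad)!r}"
        )


# ---------------------------------------------------------------------------
# Guide library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideEntry:
    """One library member: a protospacer targeting a gene TSS, or a control."""

    guide_id: str
    gene: str
    protospacer: str
    is_control: bool


@dataclass
class GuideLibrary:
    """The targeting/control guide catalogue.

    Invariants (checked on construction): guide ids unique; protospacers
    uppercase over {A,C,G,T} and of a single common length; every
    non-control entry carries a non-empty gene; no protospacer is a
    substring of another (which would make exact-match counting ambiguous).
    """

    entries: list[GuideEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        lengths: set[int] = set()
        for i, e in enumerate(self.entries):
            if e.guide_id in seen:
                raise ValidationError(f"duplicate guide_id {e.guide_id!r}")
            seen.add(e.guide_id)
            _check_dna(e.protospacer, what=f"protospacer of {e.guide_id!r} (row {i + 1})")
            lengths.add(len(e.protospacer))
            if not e.is_control and not e.gene:
                raise ValidationError(
                    f"targeting guide {e.guide_id!r} has an empty gene"
                )
        if len(lengths) > 1:
            # Mixed lengths would allow one protospacer to contain another,
            # making read assignment ambiguous.
            protos = sorted((e.protospacer for e in self.entries), key=len)
            for i, p in enumerate(protos):
                for q in protos[i + 1:]:
                    if len(q) > len(p) and p in q:
                        raise ValidationError(
                            f"protospacer {p!r} is contained in {q!r}; "
                            "exact-match counting would be ambiguous"
                        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GuideEntry]:
        return iter(self.entries)

    @property
    def guide_ids(self) -> list[str]:
        return [e.guide_id for e in self.entries]

    @property
    def controls(self) -> list[GuideEntry]:
        return [e for e in self.entries if e.is_control]

    @property
    def targeting(self) -> list[GuideEntry]:
        return [e for e in self.entries if not e.is_control]

    @property
    def protospacer_length(self) -> int:
        if not self.entries:
            raise ValidationError("empty guide library")
        return len(self.entries[0].protospacer)

    def genes(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for e in self.entries:
            if not e.is_control and e.gene not in seen:
                seen.add(e.gene)
                out.append(e.gene)
        return out


_LIBRARY_COLUMNS = ["guide_id", "gene", "protospacer", "is_control"]

_BOOL_STRINGS = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s not in _BOOL_STRINGS:
        raise FormatError(f"row {row}: is_control value {value!r} is not boolean")
    return _BOOL_STRINGS[s]


def read_guide_library(path: str | os.PathLike) -> GuideLibrary:
    """Read a tab-separated guide library table.

    The file must carry a header with columns guide_id, gene, protospacer,
    is_control.  Lowercase protospacer bases are normalized to uppercase.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"guide library {path}: missing column(s) {missing}")
    entries = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        proto = str(rec.protospacer).strip().upper()
        try:
            _check_dna(proto, what="protospacer")
        except ValidationError as exc:
            raise ValidationError(f"row {row}: {exc}") from None
        entries.append(
            GuideEntry(
                guide_id=str(rec.guide_id).strip(),
                gene=str(rec.gene).strip(),
                protospacer=proto,
                is_control=_parse_bool(rec.is_control, row),
            )
        )
    return GuideLibrary(entries)


def write_guide_library(library: GuideLibrary, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "guide_id": [e.guide_id for e in library],
            "gene": [e.gene for e in library],
            "protospacer": [e.protospacer for e in library],
            "is_control": [e.is_control for e in library],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Amplicon specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconFlag:
    """A programmed donor edit (SNP) tracked per aligned read.

    ``ref_pos`` is 0-based on the reference; the reference carries
    ``ref_base`` there and the donor carries ``alt_base`` at the homologous
    position.
    """

    ref_pos: int
    ref_base: str
    alt_base: str

    @property
    def label(self) -> str:
        return f"{self.ref_base}{self.ref_pos}{self.alt_base}"


@dataclass
class AmpliconSpec:
    """Reference + donor sequences and the coordinate frame for classification.

    ``cut_index`` is the number of reference bases 5' of the blunt Cas9 cut
    (0-based; cut between ``cut_index - 1`` and ``cut_index``).  The donor
    must equal the reference with every flag substitution applied and,
    optionally, one declared insertion cassette (``insert_pos``/``insert_seq``,
    inserted before reference position ``insert_pos``).
    ``window_halfwidth`` sets the indel scoring window around the cut.
    """

    name: str
    reference: str
    donor: str
    cut_index: int | None = None
    protospacer: str | None = None
    pam: str = "NGG"
    flags: list[AmpliconFlag] = field(default_factory=list)
    window_halfwidth: int = 3
    insert_pos: int | None = None
    insert_seq: str | None = None

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        self.donor = self.donor.upper()
        _check_dna(self.reference, what="reference")
        _check_dna(self.donor, what="donor")
        if self.protospacer is not None:
            self.protospacer = self.protospacer.upper()
            _check_dna(self.protospacer, what="protospacer")
        if self.window_halfwidth < 0:
            raise ValidationError("window_halfwidth must be >= 0")
        if self.cut_index is None:
            if self.protospacer is None:
                raise ValidationError(
                    f"amplicon {self.name!r}: need cut_index or a protospacer "
                    "to place the cut"
                )
            from .amplicon_editing import infer_cut_index  # deferred: avoids cycle
            self.cut_index = infer_cut_index(self)
        if not 0 <= self.cut_index <= len(self.reference):
            raise ValidationError(
                f"cut_index {self.cut_index} outside reference of length "
                f"{len(self.reference)}"
            )
        if (self.insert_pos is None) != (self.insert_seq is None):
            raise ValidationError("insert_pos and insert_seq must be given together")
        self.flags = sorted(self.flags, key=lambda f: f.ref_pos)
        self._validate_donor()

    # donor position homologous to a reference position
    def donor_pos(self, ref_pos: int) -> int:
        if self.insert_pos is not None and ref_pos >= self.insert_pos:
            return ref_pos + len(self.insert_seq)
        return ref_pos

    def _validate_donor(self) -> None:
        ref, donor = self.reference, self.donor
        if self.insert_pos is None:
            if len(donor) != len(ref):
                raise ValidationError(
                    f"amplicon {self.name!r}: donor length {len(donor)} != "
                    f"reference length {len(ref)} and no insertion declared"
                )
        else:
            if not 0 <= self.insert_pos <= len(ref):
                raise ValidationError("insert_pos outside reference")
            _check_dna(self.insert_seq, what="insert_seq")
            if len(donor) != len(ref) + len(self.insert_seq):
                raise ValidationError(
                    "donor length inconsistent with declared insertion cassette"
                )
        flag_positions = set()
        for f in self.flags:
            if not 0 <= f.ref_pos < len(ref):
                raise ValidationError(f"flag position {f.ref_pos} outside reference")
            if ref[f.ref_pos] != f.ref_base.upper():
                raise ValidationError(
                    f"flag at position {f.ref_pos}: declared ref_base "
                    f"{f.ref_base!r} but reference has {ref[f.ref_pos]!r}"
                )
            if donor[self.donor_pos(f.ref_pos)] != f.alt_base.upper():
                raise ValidationError(
                    f"flag at position {f.ref_pos}: declared alt_base "
                    f"{f.alt_base!r} but donor has "
                    f"{donor[self.donor_pos(f.ref_pos)]!r}"
                )
            flag_positions.add(f.ref_pos)
        # Donor may differ from the reference only at flag positions (plus
        # the declared insertion cassette).
        expected = list(ref)
        for f in self.flags:
            expected[f.ref_pos] = f.alt_base.upper()
        if self.insert_pos is not None:
            expected[self.insert_pos:self.insert_pos] = list(self.insert_seq)
        expected_donor = "".join(expected)
        if donor != expected_donor:
            for i, (d, e) in enumerate(zip(donor, expected_donor)):
                if d != e:
                    raise ValidationError(
                        f"amplicon {self.name!r}: donor differs from reference "
                        f"at undeclared position {i} ({e!r} -> {d!r})"
                    )


def pam_matches(pattern: str, seq: str) -> bool:
    """True when ``seq`` matches the IUPAC PAM ``pattern`` (same length)."""
    if len(pattern) != len(seq):
        return False
    return all(b in _IUPAC[p.upper()] for p, b in zip(pattern, seq))


def read_amplicon_spec(path: str | os.PathLike) -> AmpliconSpec:
    """Read one amplicon specification from a YAML key-value document.

    If ``cut_index`` is absent but a protospacer is given, the cut is
    placed from the protospacer/PAM position (blunt cut 3 nt 5' of the PAM).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"amplicon spec {path}: expected a key-value document")
    for key in ("name", "reference", "donor"):
        if key not in doc:
            raise FormatError(f"amplicon spec {path}: missing key {key!r}")
    flags = [
        AmpliconFlag(
            ref_pos=int(f["ref_pos"]),
            ref_base=str(f["ref_base"]).upper(),
            alt_base=str(f["alt_base"]).upper(),
        )
        for f in doc.get("flags", []) or []
    ]
    return AmpliconSpec(
        name=str(doc["name"]),
        reference=str(doc["reference"]),
        donor=str(doc["donor"]),
        cut_index=doc.get("cut_index"),
        protospacer=doc.get("protospacer"),
        pam=str(doc.get("pam", "NGG")),
        flags=flags,
        window_halfwidth=int(doc.get("window_halfwidth", 3)),
        insert_pos=doc.get("insert_pos"),
        insert_seq=doc.get("insert_seq"),
    )


def write_amplicon_spec(spec: AmpliconSpec, path: str | os.PathLike) -> None:
    doc: dict = {
        "name": spec.name,
        "reference": spec.reference,
        "donor": spec.donor,
        "cut_index": spec.cut_index,
        "pam": spec.pam,
        "window_halfwidth": spec.window_halfwidth,
        "flags": [
            {"ref_pos": f.ref_pos, "ref_base": f.ref_base, "alt_base": f.alt_base}
            for f in spec.flags
        ],
    }
    if spec.protospacer is not None:
        doc["protospacer"] = spec.protospacer
    if spec.insert_pos is not None:
        doc["insert_pos"] = spec.insert_pos
        doc["insert_seq"] = spec.insert_seq
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRead:
    """A sequencing read: id, bases (may include N), per-base Phred scores."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.bases):
            raise ValidationError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValidationError(f"read {self.read_id!r}: negative quality score")
        _check_dna(self.bases.upper(), what=f"read {self.read_id!r}", allow_n=True)

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(path, mode: str):
    path = os.fspath(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt")
        return open(path, "rt")
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "wt")


def stream_fastq(path: str | os.PathLike) -> Iterator[SequenceRead]:
    """Lazily yield reads from a 4-line-record FASTQ file (plain or gzip)."""
    with _open_maybe_gzip(path, "r") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if header.strip() == "" :
                # permit trailing blank lines only at EOF
                if fh.read().strip():
                    raise FormatError(f"record {record + 1}: blank line inside FASTQ")
                return
            record += 1
            bases = fh.readline()
            plus = fh.readline()
            quals = fh.readline()
            if not quals:
                raise FormatError(f"record {record}: truncated FASTQ record")
            if not header.startswith("@"):
                raise FormatError(f"record {record}: header does not start with '@'")
            if not plus.startswith("+"):
                raise FormatError(f"record {record}: separator line missing '+'")
            bases = bases.strip()
            quals = quals.strip()
            if len(bases) != len(quals):
                raise FormatError(
                    f"record {record}: {len(bases)} bases but "
                    f"{len(quals)} quality characters"
                )
            yield SequenceRead(
                read_id=header[1:].strip(),
                bases=bases,
                qualities=tuple(ord(c) - 33 for c in quals),
            )


def write_fastq(reads: Iterable[SequenceRead], path: str | os.PathLike) -> int:
    """Write reads as 4-line FASTQ records (Sanger offset 33). Returns count."""
    n = 0
    with _open_maybe_gzip(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id}\n{read.bases}\n+\n"
                + "".join(chr(q + 33) for q in read.qualities)
                + "\n"
            )
            n += 1
    return n
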