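"""Three-step NGS curation of amplicon barcode libraries.

Given per-condition (per-library) FASTQ files of the dual-barcode
amplicon, the pipeline

1. removes reads whose mean Phred quality is below Q35,
2. extracts the barcode between the two flanking anchors, counts
   distinct sequences, and drops those below 200x coverage (rare
   PCR/sequencing artefacts),
3. flags as "uncertain" any sequence found identically — or within one
   nucleotide — in another library: such sequences are attributable to
   index hopping, cross-well contamination, or PCR/sequencing error,
   and cannot be assigned to a library with confidence.

Subtracting the uncertain count from a library's total gives the range
(total - uncertain, total) of the most probable number of distinct
plasmids in that library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import FastqRead, phred_scores
from .sanger import BASES, BASE_INDEX, BarcodeReference, DEFAULT_REFERENCE

CATEGORY_IDENTICAL = "identical"
CATEGORY_NEAR_IDENTICAL = "near_identical"
CATEGORY_UNIQUE = "unique"

REJECT_NO_UPSTREAM = "upstream_anchor_not_found"
REJECT_NO_DOWNSTREAM = "downstream_anchor_not_found"
REJECT_BAD_LENGTH = "unexpected_barcode_length"


@dataclass(frozen=True)
class FilterStats:
    reads_in: int
    reads_passing: int

    @property
    def fraction_removed(self) -> float:
        return 0.0 if self.reads_in == 0 else 1.0 - self.reads_passing / self.reads_in


def mean_quality(quality: str) -> float:
    """Arithmetic mean of the Phred scores of a read (Phred+33)."""
    return float(phred_scores(quality).mean())


def filter_by_mean_quality(
    reads: Iterable[FastqRead], min_mean_q: int = 35
) -> tuple[list[FastqRead], FilterStats]:
    """Keep reads whose mean Phred score reaches ``min_mean_q``."""
    passing = []
    n_in = 0
    for read in reads:
        n_in += 1
        if mean_quality(read.quality) >= min_mean_q:
            passing.append(read)
    return passing, FilterStats(reads_in=n_in, reads_passing=len(passing))


@dataclass(frozen=True)
class ExtractionResult:
    barcode: str | None
    reason: str | None  # rejection reason code, None on success

    @property
    def accepted(self) -> bool:
        return self.barcode is not None


def _find_approximate(sequence: str, anchor: str, start: int, max_mismatch: int) -> int:
    """Leftmost occurrence of ``anchor`` in ``sequence`` allowing mismatches."""
    pos = sequence.find(anchor, start)
    if pos >= 0 or max_mismatch == 0:
        return pos
    n, m = len(sequence), len(anchor)
    for pos in range(start, n - m + 1):
        mismatches = 0
        for a, b in zip(sequence[pos : pos + m], anchor):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            return pos
    return -1


def extract_barcode(
    sequence: str,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    max_deletion: int = 3,
    anchor_mismatch: int = 1,
) -> ExtractionResult:
    """Extract the barcode between the two anchors of a read.

    Anchors are located by exact match first, then with a one-mismatch
    fallback.  The intervening sequence is accepted if its length is
    within ``max_deletion`` nt below the designed barcode length
    (tolerating the library's small 1-3 nt deletions).
    """
    sequence = sequence.upper()
    up = _find_approximate(sequence, ref.upstream_anchor, 0, anchor_mismatch)
    if up < 0:
        return ExtractionResult(None, REJECT_NO_UPSTREAM)
    barcode_start = up + len(ref.upstream_anchor)
    down = _find_approximate(sequence, ref.downstream_anchor, barcode_start, anchor_mismatch)
    if down < 0:
        return ExtractionResult(None, REJECT_NO_DOWNSTREAM)
    barcode = sequence[barcode_start:down]
    expected = ref.barcode_length
    if not expected - max_deletion <= len(barcode) <= expected:
        return ExtractionResult(None, REJECT_BAD_LENGTH)
    return ExtractionResult(barcode, None)


@dataclass(frozen=True)
class LibraryCounts:
    """Per-library barcode counts after the stated filters."""

    library_id: str
    counts: Mapping[str, int]
    reads_in: int = 0
    reads_passing_quality: int = 0

    def __post_init__(self) -> None:
        for seq, count in self.counts.items():
            if not seq or seq != seq.upper() or any(b not in BASE_INDEX for b in seq):
                raise ValueError(f"barcode {seq!r} is not an uppercase DNA string")
            if count < 1:
                raise ValueError(f"barcode {seq!r} has non-positive count {count}")
        if self.reads_passing_quality > self.reads_in:
            raise ValueError("reads_passing_quality cannot exceed reads_in")

    @property
    def total_barcodes(self) -> int:
        return len(self.counts)


def count_barcodes(
    reads: Iterable[FastqRead],
    ref: BarcodeReference = DEFAULT_REFERENCE,
    library_id: str = "library",
    reads_in: int = 0,
    reads_passing_quality: int = 0,
    max_deletion: int = 3,
) -> tuple[LibraryCounts, Counter]:
    """Extract and tally barcodes; returns the counts and rejection tallies."""
    counts: Counter = Counter()
    rejections: Counter = Counter()
    for read in reads:
        result = extract_barcode(read.sequence, ref, max_deletion=max_deletion)
        if result.accepted:
            counts[result.barcode] += 1
        else:
            rejections[result.reason] += 1
    return (
        LibraryCounts(
            library_id=library_id,
            counts=dict(counts),
            reads_in=reads_in,
            reads_passing_quality=reads_passing_quality,
        ),
        rejections,
    )


def coverage_filter(library: LibraryCounts, min_coverage: int = 200) -> LibraryCounts:
    """Drop barcodes below ``min_coverage`` reads; other entries unchanged."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    return LibraryCounts(
        library_id=library.library_id,
        counts={s: c for s, c in library.counts.items() if c >= min_coverage},
        reads_in=library.reads_in,
        reads_passing_quality=library.reads_passing_quality,
    )


def probable_range(total: int, uncertain: int) -> tuple[int, int]:
    """Most probable number of distinct plasmids: (total - uncertain, total)."""
    if not 0 <= uncertain <= total:
        raise ValueError(f"uncertain ({uncertain}) must lie in [0, total={total}]")
    return total - uncertain, total


def _within_distance(a: str, b: str, max_mismatch: int) -> bool:
    """Unit-cost edit distance <= max_mismatch.

    For equal lengths and max_mismatch 1 this is exactly Hamming <= 1;
    for lengths differing by one it is exactly a single indel.
    """
    if abs(len(a) - len(b)) > max_mismatch:
        return False
    return edlib.align(a, b, mode="NW", task="distance", k=max_mismatch)["editDistance"] != -1


@dataclass(frozen=True)
class LibraryCuration:
    library_id: str
    total: int
    identical: int
    near_identical: int
    uncertain: int
    probable_range: tuple[int, int]
    categories: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CurationResult:
    per_library: tuple[LibraryCuration, ...]

    @property
    def total(self) -> int:
        return sum(lib.total for lib in self.per_library)

    @property
    def identical(self) -> int:
        return sum(lib.identical for lib in self.per_library)

    @property
    def near_identical(self) -> int:
        return sum(lib.near_identical for lib in self.per_library)

    @property
    def uncertain(self) -> int:
        return sum(lib.uncertain for lib in self.per_library)

    @property
    def probable_range_total(self) -> tuple[int, int]:
        return self.total - self.uncertain, self.total


def cross_library_curation(
    libraries: Sequence[LibraryCounts], max_mismatch: int = 1
) -> CurationResult:
    """Flag sequences shared (exactly or within 1 nt) across libraries.

    Per sequence and library: ``identical`` if the same sequence occurs
    in at least one other library; otherwise ``near_identical`` if some
    other library holds a sequence within ``max_mismatch`` edits
    (substitution or indel); otherwise ``unique``.  Identical takes
    precedence, so the categories are disjoint and uncertain =
    identical + near_identical, additive per library and overall.
    """
    if len(libraries) < 2:
        raise ValueError("cross-library curation needs at least 2 libraries")
    ids = [lib.library_id for lib in libraries]
    if len(set(ids)) != len(ids):
        raise ValueError("library_id values must be distinct")
    keysets = {lib.library_id: set(lib.counts) for lib in libraries}
    per_library = []
    for lib in libraries:
        other_exact: set[str] = set()
        for other in libraries:
            if other.library_id != lib.library_id:
                other_exact |= keysets[other.library_id]
        categories = {}
        for seq in lib.counts:
            if seq in other_exact:
                categories[seq] = CATEGORY_IDENTICAL
            elif any(_within_distance(seq, other, max_mismatch) for other in other_exact):
                categories[seq] = CATEGORY_NEAR_IDENTICAL
            else:
                categories[seq] = CATEGORY_UNIQUE
        n_identical = sum(1 for c in categories.values() if c == CATEGORY_IDENTICAL)
        n_near = sum(1 for c in categories.values() if c == CATEGORY_NEAR_IDENTICAL)
        uncertain = n_identical + n_near
        per_library.append(
            LibraryCuration(
                library_id=lib.library_id,
                total=lib.total_barcodes,
                identical=n_identical,
                near_identical=n_near,
                uncertain=uncertain,
                probable_range=probable_range(lib.total_barcodes, uncertain),
                categories=categories,
            )
        )
    return CurationResult(per_library=tuple(per_library))


def curate_libraries(
    reads_by_library: Mapping[str, Iterable[FastqRead]],
    ref: BarcodeReference = DEFAULT_REFERENCE,
    min_mean_q: int = 35,
    min_coverage: int = 200,
    max_mismatch: int = 1,
) -> tuple[CurationResult, dict[str, LibraryCounts]]:
    """Full pipeline: quality filter -> extract/count -> coverage filter ->
    cross-library curation.  Returns the curation and the filtered counts."""
    filtered: dict[str, LibraryCounts] = {}
    for library_id in sorted(reads_by_library):
        passing, stats = filter_by_mean_quality(reads_by_library[library_id], min_mean_q)
        counts, _ = count_barcodes(
            passing,
            ref,
            library_id=library_id,
            reads_in=stats.reads_in,
            reads_passing_quality=stats.reads_passing,
        )
        filtered[library_id] = coverage_filter(counts, min_coverage)
    result = cross_library_curation(list(filtered.values()), max_mismatch)
    return result, filtered


@dataclass(frozen=True)
class FrequencyAudit:
    """Per-position nucleotide composition of a barcode set."""

    random_region: pd.DataFrame  # positions x ACGT frequencies
    snp_region: pd.DataFrame  # positions x ACGT frequencies
    reference_fraction: pd.Series  # per SNP position, fraction matching reference
    observed_snps: frozenset[tuple[int, str]]
    n_barcodes: int


def nucleotide_frequency_audit(
    barcodes: Iterable[str], ref: BarcodeReference = DEFAULT_REFERENCE
) -> FrequencyAudit:
    """Audit sequence bias over the barcode region (full-length barcodes only).

    Over the random region each base should appear at ~25% per position;
    over the SNP region each position should be dominated by the
    reference base with all three alternatives present at low frequency
    (~1/33 per (position, alternative) for a uniform single-SNP library).
    """
    snp_len = len(ref.snp_region_reference)
    barcode_list = []
    for barcode in barcodes:
        if len(barcode) != ref.barcode_length:
            raise ValueError(
                f"barcode {barcode!r} is not full length ({ref.barcode_length} nt)"
            )
        barcode_list.append(barcode.upper())
    if not barcode_list:
        raise ValueError("no barcodes supplied")
    arr = np.array([[BASE_INDEX[b] for b in bc] for bc in barcode_list])
    n = len(barcode_list)

    def freq_table(sub: np.ndarray) -> pd.DataFrame:
        table = np.zeros((sub.shape[1], len(BASES)))
        for idx in range(len(BASES)):
            table[:, idx] = (sub == idx).sum(axis=0) / n
        return pd.DataFrame(table, columns=list(BASES))

    snp_part = arr[:, :snp_len]
    random_part = arr[:, snp_len:]
    snp_freq = freq_table(snp_part)
    ref_idx = np.array([BASE_INDEX[b] for b in ref.snp_region_reference])
    reference_fraction = pd.Series(
        [(snp_part[:, j] == ref_idx[j]).mean() for j in range(snp_len)], name="reference_fraction"
    )
    observed = set()
    for j in range(snp_len):
        for base, idx in BASE_INDEX.items():
            if base != ref.snp_region_reference[j] and (snp_part[:, j] == idx).any():
                observed.add((j, base))
    return FrequencyAudit(
        random_region=freq_table(random_part),
        snp_region=snp_freq,
        reference_fraction=reference_fraction,
        observed_snps=frozenset(observed),
        n_barcodes=n,
    )
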