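"""Colony-level plasmid enumeration from composite Sanger traces.

A single-cell-derived colony carrying several barcoded plasmids yields a
colony-PCR Sanger trace in which every member contributes equally, so
each position shows a mixture of peaks.  Enumeration uses both halves of
the dual barcode:

* **SNP rule** — count the distinct (position, alternative-base) pairs in
  the 11-nt SNP region whose fractional intensity reaches the calling
  threshold; each intact plasmid carries exactly one SNP, so on clean
  traces this is a lower bound on the multiplicity, reliable up to the
  Sanger ceiling (~6 variants at a 15% threshold).
* **10N rule** — over the ten random-region positions, take the maximum
  number of bases above threshold; exact for 1-3 plasmids (probability
  > 99%) and correct ~63% of the time for 4, where it saturates.

The two calls are then combined: the 10N call decides the 1-3 range,
the SNP call resolves colonies in which the 10N rule saturates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np

from .barcode_model import BarcodeScheme, DEFAULT_SCHEME, max_detectable_snps

BASES = "ACGT"
BASE_INDEX = {base: i for i, base in enumerate(BASES)}

#: IUPAC ambiguity codes expanded to the bases they denote.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

FLAG_EMPTY = "empty_or_deleted_barcode"
FLAG_DEGRADED = "degraded_frameshift"
FLAG_SATURATED = "saturated"
FLAG_LOW_CONFIDENCE = "low_confidence"

# Documented defaults; the real sequences are experiment-specific
# configuration.  Anchors are the M13 universal primer pair.
DEFAULT_UPSTREAM_ANCHOR = "TGTAAAACGACGGCCAGT"
DEFAULT_DOWNSTREAM_ANCHOR = "CAGGAAACAGCTATGACC"
DEFAULT_SNP_REGION_REFERENCE = "GCTAGACCTGA"


def _check_dna(seq: str, what: str) -> None:
    if not seq or any(b not in BASE_INDEX for b in seq):
        raise ValueError(f"{what} must be a non-empty string over A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class BarcodeReference:
    """Layout of the dual-barcode amplicon on the sequencing strand.

    The amplicon is upstream anchor + 11-nt SNP region + 10N region +
    downstream anchor, contiguous, 0-based; trace position 0 is the first
    base of the upstream anchor.  Intervals are derived from this layout,
    so they can never overlap or disagree with the reference length.
    """

    snp_region_reference: str = DEFAULT_SNP_REGION_REFERENCE
    upstream_anchor: str = DEFAULT_UPSTREAM_ANCHOR
    downstream_anchor: str = DEFAULT_DOWNSTREAM_ANCHOR
    random_region_length: int = 10

    def __post_init__(self) -> None:
        _check_dna(self.snp_region_reference, "snp_region_reference")
        _check_dna(self.upstream_anchor, "upstream_anchor")
        _check_dna(self.downstream_anchor, "downstream_anchor")
        if len(self.upstream_anchor) < 10 or len(self.downstream_anchor) < 10:
            raise ValueError("anchors must be at least 10 nt")
        if self.random_region_length < 1:
            raise ValueError("random_region_length must be >= 1")

    @property
    def snp_region_interval(self) -> tuple[int, int]:
        start = len(self.upstream_anchor)
        return start, start + len(self.snp_region_reference)

    @property
    def random_region_interval(self) -> tuple[int, int]:
        _, snp_end = self.snp_region_interval
        return snp_end, snp_end + self.random_region_length

    @property
    def downstream_anchor_interval(self) -> tuple[int, int]:
        _, random_end = self.random_region_interval
        return random_end, random_end + len(self.downstream_anchor)

    @property
    def barcode_length(self) -> int:
        """Full dual-barcode length (SNP region + random region)."""
        return len(self.snp_region_reference) + self.random_region_length

    @property
    def amplicon_length(self) -> int:
        return self.downstream_anchor_interval[1]


DEFAULT_REFERENCE = BarcodeReference()


class TraceProfile:
    """A colony's composite Sanger signal as per-position base fractions.

    Rows are trace positions, columns are (A, C, G, T) fractional
    intensities summing to 1 within ``atol``.  Only fractions matter to
    the callers, so :meth:`from_intensities` accepts raw peak heights and
    normalises them — calls are invariant to uniform rescaling.
    """

    def __init__(self, fractions: np.ndarray, *, atol: float = 0.01) -> None:
        arr = np.asarray(fractions, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(BASES):
            raise ValueError("trace profile must be an (n_positions, 4) array")
        if (arr < -1e-9).any() or (arr > 1.0 + 1e-9).any():
            pos = int(np.argwhere((arr < -1e-9) | (arr > 1.0 + 1e-9))[0, 0])
            raise ValueError(f"fraction outside [0, 1] at position {pos}")
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 1.0) > atol
        if bad.any():
            pos = int(np.argmax(bad))
            raise ValueError(
                f"fractions at position {pos} sum to {sums[pos]:.3f}, not 1±{atol}"
            )
        self.fractions = arr

    def __len__(self) -> int:
        return self.fractions.shape[0]

    @classmethod
    def from_intensities(cls, intensities: np.ndarray) -> "TraceProfile":
        arr = np.asarray(intensities, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(BASES):
            raise ValueError("intensities must be an (n_positions, 4) array")
        if (arr < 0).any():
            raise ValueError("intensities must be non-negative")
        sums = arr.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValueError("every position needs positive total intensity")
        return cls(arr / sums)

    @classmethod
    def from_sequence(cls, sequence: str) -> "TraceProfile":
        """Expand an IUPAC ambiguity-coded string to equal base fractions."""
        rows = np.zeros((len(sequence), len(BASES)))
        for i, code in enumerate(sequence.upper()):
            try:
                bases = IUPAC_CODES[code]
            except KeyError:
                raise ValueError(f"invalid IUPAC code {code!r} at position {i}") from None
            for base in bases:
                rows[i, BASE_INDEX[base]] = 1.0 / len(bases)
        return cls(rows)


class SnpDetection(NamedTuple):
    position: int  # 0-based within the SNP region
    base: str  # alternative base called present
    fraction: float


@dataclass(frozen=True)
class SnpCall:
    count: int
    detections: tuple[SnpDetection, ...]


@dataclass(frozen=True)
class ColonyCall:
    """Combined enumeration result for one colony."""

    snp_count: int
    tenn_count: int
    final_count: int
    flags: frozenset[str]
    colony_id: str | None = None

    @property
    def tenn_label(self) -> str:
        """The 10N rule saturates at 4, so a 4 means 'four or more'."""
        return ">=4" if self.tenn_count >= 4 else str(self.tenn_count)


def call_snp_count(
    trace: TraceProfile,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    scheme: BarcodeScheme = DEFAULT_SCHEME,
) -> SnpCall:
    """Count distinct SNPs (non-reference bases above threshold) in the SNP region.

    The count is capped at the Sanger resolution ceiling
    (:func:`plasmux.barcode_model.max_detectable_snps`); the full
    detection list is returned uncapped.
    """
    start, end = ref.snp_region_interval
    if len(trace) < end:
        raise ValueError(
            f"trace of length {len(trace)} does not cover the SNP region [{start}, {end})"
        )
    threshold = scheme.sanger_call_threshold
    detections = []
    for offset, pos in enumerate(range(start, end)):
        ref_base = ref.snp_region_reference[offset]
        for base, idx in BASE_INDEX.items():
            if base == ref_base:
                continue
            fraction = float(trace.fractions[pos, idx])
            if fraction >= threshold:
                detections.append(SnpDetection(offset, base, fraction))
    count = min(len(detections), max_detectable_snps(scheme))
    return SnpCall(count=count, detections=tuple(detections))


def call_tenn_count(
    trace: TraceProfile,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    scheme: BarcodeScheme = DEFAULT_SCHEME,
) -> int:
    """Max-distinct-bases call over the random region, capped at 4."""
    start, end = ref.random_region_interval
    if len(trace) < end:
        raise ValueError(
            f"trace of length {len(trace)} does not cover the random region [{start}, {end})"
        )
    above = trace.fractions[start:end] >= scheme.sanger_call_threshold
    per_position = above.sum(axis=1)
    return int(min(per_position.max(initial=0), 4))


def combine_calls(snp_count: int, tenn_count: int) -> ColonyCall:
    """Merge the SNP and 10N calls into the final multiplicity.

    * 10N saturated (>=4): final = max(4, snp_count) — the SNP call
      resolves the 4-6 range; flagged ``saturated``.
    * SNP region silent (0 detections): the barcode is empty or deleted;
      the 10N call stands alone, flagged ``empty_or_deleted_barcode``.
    * SNP >= 4 while 10N <= 3: the SNP count (a lower bound on clean
      traces) wins, flagged ``low_confidence``.
    * Both in 1-3: the 10N call wins; disagreement of more than one adds
      ``low_confidence``.
    """
    if snp_count < 0 or tenn_count < 1:
        raise ValueError("snp_count must be >= 0 and tenn_count >= 1")
    flags: set[str] = set()
    if snp_count == 0:
        flags.add(FLAG_EMPTY)
    if tenn_count >= 4:
        flags.add(FLAG_SATURATED)
        final = max(4, snp_count)
    elif snp_count == 0:
        final = tenn_count
    elif snp_count >= 4:
        flags.add(FLAG_LOW_CONFIDENCE)
        final = snp_count
    elif abs(snp_count - tenn_count) > 1:
        flags.add(FLAG_LOW_CONFIDENCE)
        final = tenn_count
    else:
        final = tenn_count
    return ColonyCall(
        snp_count=snp_count,
        tenn_count=tenn_count,
        final_count=final,
        flags=frozenset(flags),
    )


def detect_degradation(
    trace: TraceProfile,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    scheme: BarcodeScheme = DEFAULT_SCHEME,
) -> tuple[bool, float]:
    """Detect frame-shifted (deletion-carrying) members from the anchor.

    A colony member with a deletion in the barcode shifts every
    downstream base, so the normally invariant downstream-anchor
    positions acquire secondary peaks.  Returns (degraded, affected
    fraction), where the affected fraction is the mean non-anchor-base
    intensity over the covered anchor positions — an estimate of the
    frame-shifted share of the mixture.
    """
    start, end = ref.downstream_anchor_interval
    covered_end = min(len(trace), end)
    if covered_end - start < 5:
        raise ValueError("trace must cover at least 5 nt of the downstream anchor")
    threshold = scheme.sanger_call_threshold
    degraded = False
    off_fractions = []
    for offset, pos in enumerate(range(start, covered_end)):
        expected_idx = BASE_INDEX[ref.downstream_anchor[offset]]
        secondary = np.delete(trace.fractions[pos], expected_idx)
        if (secondary >= threshold).any():
            degraded = True
        off_fractions.append(float(secondary.sum()))
    return degraded, float(np.mean(off_fractions))


def call_colony(
    trace: TraceProfile,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    scheme: BarcodeScheme = DEFAULT_SCHEME,
    colony_id: str | None = None,
) -> ColonyCall:
    """Full per-colony pipeline: SNP call, 10N call, combination, QC flags."""
    snp = call_snp_count(trace, ref, scheme)
    tenn = call_tenn_count(trace, ref, scheme)
    call = combine_calls(snp.count, tenn)
    degraded, _ = detect_degradation(trace, ref, scheme)
    flags = set(call.flags)
    if degraded:
        flags.add(FLAG_DEGRADED)
    return replace(call, flags=frozenset(flags), colony_id=colony_id)


def call_colonies(
    traces: Iterable[tuple[str, TraceProfile]],
    ref: BarcodeReference = DEFAULT_REFERENCE,
    scheme: BarcodeScheme = DEFAULT_SCHEME,
) -> list[ColonyCall]:
    return [call_colony(trace, ref, scheme, colony_id=cid) for cid, trace in traces]
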