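"""Probability model of the dual-barcode design.

The dual barcode pairs a low-diversity SNP barcode — an 11-nt region that
carries exactly one substitution relative to a fixed reference, giving
11 positions x 3 alternative bases = 33 possible sequences — with a
high-diversity, fully random 10-nt region ("10N").  The SNP half is read
out from a composite Sanger trace by counting secondary peaks above a
calling threshold; the 10N half by taking, over its ten positions, the
maximum number of distinct bases observed.

This module provides the closed-form design statistics of that scheme:

* barcode-space sizes (SNP space, full dual-barcode space, and the
  collapsed space in which one random position is allowed to match),
* the birthday-collision probability that k plasmids drawn uniformly
  from the SNP space share a barcode,
* the probability that the 10N max-distinct-bases rule enumerates a
  k-plasmid colony exactly,
* the ceiling on how many equally abundant variants a Sanger trace can
  resolve at a given calling threshold,

together with a Monte-Carlo estimator that serves as an independent
cross-check of the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "BarcodeScheme",
    "DEFAULT_SCHEME",
    "EstimatorSaturationError",
    "MonteCarloEstimate",
    "dual_barcode_space_size",
    "max_detectable_snps",
    "monte_carlo_accuracy",
    "snp_collision_probability",
    "snp_space_size",
    "tenn_enumeration_accuracy",
]


class EstimatorSaturationError(ValueError):
    """The 10N max-distinct-bases rule cannot resolve this many plasmids.

    With a 4-letter alphabet the estimator saturates at 4: five or more
    molecules can never be distinguished from four by counting distinct
    bases per position.
    """


@dataclass(frozen=True)
class BarcodeScheme:
    """Parameters of the dual-barcode design.

    Attributes
    ----------
    snp_region_length:
        Length in nt of the SNP-carrying region (default 11).
    alternatives_per_position:
        Number of alternative bases a single substitution can introduce
        at one position (default 3, i.e. any non-reference base).
    random_region_length:
        Length in nt of the fully random region (default 10; may be 0,
        which degenerates to a pure SNP barcode).
    alphabet_size:
        Nucleotide alphabet size (default 4).
    sanger_call_threshold:
        Minimum fractional peak intensity at which a base is called
        present in a mixed Sanger trace (default 0.15).
    """

    snp_region_length: int = 11
    alternatives_per_position: int = 3
    random_region_length: int = 10
    alphabet_size: int = 4
    sanger_call_threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.snp_region_length < 1:
            raise ValueError("snp_region_length must be >= 1")
        if self.alternatives_per_position < 1:
            raise ValueError("alternatives_per_position must be >= 1")
        if self.random_region_length < 0:
            raise ValueError("random_region_length must be >= 0")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if not 0.0 < self.sanger_call_threshold <= 0.5:
            raise ValueError("sanger_call_threshold must lie in (0, 0.5]")


DEFAULT_SCHEME = BarcodeScheme()


def snp_space_size(scheme: BarcodeScheme = DEFAULT_SCHEME) -> int:
    """Number of distinct single-SNP barcodes (positions x alternatives)."""
    return scheme.snp_region_length * scheme.alternatives_per_position


def dual_barcode_space_size(
    scheme: BarcodeScheme = DEFAULT_SCHEME, collapse_one_position: bool = False
) -> int:
    """Number of distinct dual barcodes.

    With ``collapse_one_position=True`` one random-region position is
    allowed to be identical between two barcodes, i.e. the random region
    contributes only ``random_region_length - 1`` informative positions.
    This is the lower bound on the space within which two barcodes still
    differ by more than one random-region nucleotide.
    """
    exponent = scheme.random_region_length - (1 if collapse_one_position else 0)
    if exponent < 0:
        raise ValueError("cannot collapse a position of an empty random region")
    return scheme.alphabet_size**exponent * snp_space_size(scheme)


def snp_collision_probability(k: int, scheme: BarcodeScheme = DEFAULT_SCHEME) -> float:
    """Probability that at least two of k plasmids share a SNP barcode.

    The k barcodes are drawn independently and uniformly from the
    ``snp_space_size`` possible sequences; this is the classical
    birthday-collision probability 1 - prod_{i=0}^{k-1} (S - i) / S.
    Returns 1.0 whenever k exceeds the space size (pigeonhole).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    space = snp_space_size(scheme)
    if k > space:
        return 1.0
    p_all_distinct = 1.0
    for i in range(k):
        p_all_distinct *= (space - i) / space
    return 1.0 - p_all_distinct


def tenn_enumeration_accuracy(k: int, scheme: BarcodeScheme = DEFAULT_SCHEME) -> float:
    """Probability that the 10N rule counts a k-plasmid colony exactly.

    The estimator reports, over the random-region positions, the maximum
    number of distinct bases.  For k iid uniform random regions it equals
    k exactly when at least one position shows all k sequences with k
    different bases.  The per-position probability of that event is
    d(k) / A^k with d(k) = A! / (A - k)! (ordered k-tuples with all
    values distinct), so the accuracy over L independent positions is

        1 - (1 - d(k) / A**k) ** L.

    A colony with a single plasmid is always counted correctly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = scheme.alphabet_size
    if k > alphabet:
        raise EstimatorSaturationError(
            f"{k} plasmids exceed the {alphabet}-base ceiling of the "
            "max-distinct-bases estimator"
        )
    p_position = math.perm(alphabet, k) / alphabet**k
    return 1.0 - (1.0 - p_position) ** scheme.random_region_length


def max_detectable_snps(scheme: BarcodeScheme = DEFAULT_SCHEME) -> int:
    """Ceiling on equally abundant variants resolvable in one Sanger trace.

    A secondary peak is callable only if it carries at least
    ``sanger_call_threshold`` of the signal, so at most
    floor(1 / threshold) equally represented sequences can each stay
    above it (6 at the default 15% threshold).
    """
    # guard against float artefacts such as 1/0.1 -> 9.999...
    return int(math.floor(1.0 / scheme.sanger_call_threshold + 1e-9))


class MonteCarloEstimate(NamedTuple):
    """Hit fraction of a simulated estimator with its binomial standard error."""

    estimate: float
    standard_error: float
    replicates: int


def monte_carlo_accuracy(
    k: int,
    scheme: BarcodeScheme = DEFAULT_SCHEME,
    replicates: int = 100_000,
    seed: int = 0,
    statistic: str = "tenn",
) -> MonteCarloEstimate:
    """Simulation cross-check of the closed-form design statistics.

    Parameters
    ----------
    statistic:
        ``"tenn"`` simulates k iid uniform random regions and scores the
        fraction of replicates in which the max-distinct-bases estimator
        returns exactly k (cross-check of
        :func:`tenn_enumeration_accuracy`); ``"snp_collision"`` simulates
        k uniform SNP draws and scores the fraction with at least one
        shared barcode (cross-check of :func:`snp_collision_probability`).
    seed:
        One fresh ``numpy.random.default_rng(seed)`` stream per call;
        the same seed always yields the same estimate.
    """
    if replicates < 1000:
        raise ValueError("replicates must be >= 1000")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if statistic == "tenn":
        alphabet = scheme.alphabet_size
        if k > alphabet:
            raise EstimatorSaturationError(f"k={k} saturates the estimator")
        draws = rng.integers(
            0, alphabet, size=(replicates, k, scheme.random_region_length)
        )
        present = np.zeros(
            (replicates, alphabet, scheme.random_region_length), dtype=bool
        )
        for base in range(alphabet):
            present[:, base, :] = (draws == base).any(axis=1)
        max_distinct = present.sum(axis=1).max(axis=1)
        hits = max_distinct == k
    elif statistic == "snp_collision":
        space = snp_space_size(scheme)
        draws = np.sort(rng.integers(0, space, size=(replicates, k)), axis=1)
        if k == 1:
            hits = np.zeros(replicates, dtype=bool)
        else:
            hits = (np.diff(draws, axis=1) == 0).any(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    estimate = float(hits.mean())
    standard_error = float(math.sqrt(estimate * (1.0 - estimate) / replicates))
    return MonteCarloEstimate(estimate, standard_error, replicates)
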