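"""Synthetic dual-barcode experiments.

Generates the study's experimental objects in silico: a plasmid library
in which every molecule carries one SNP (uniform over the 33
possibilities) plus an iid uniform 10-nt random region; single-cell
colonies holding 1..k distinct library members; composite Sanger-style
trace profiles (equal-weight mixtures, optional noise, frameshifts from
deletion-carrying members); and per-condition amplicon FASTQ reads with
PCR substitutions, per-base sequencing error, a two-class read-quality
mixture, index hopping between conditions, and cross-well contamination.

Every generator takes or derives a ``numpy.random.Generator``; a fixed
seed reproduces output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import FastqRead, PHRED_OFFSET
from .sanger import BASES, BASE_INDEX, BarcodeReference, DEFAULT_REFERENCE, TraceProfile

DEFECT_INTACT = "intact"
DEFECT_SMALL_DELETION = "small_deletion_1_3nt"
DEFECT_LARGE_DELETION = "large_deletion_gt3nt"

# Constant filler downstream of the amplicon (plasmid backbone context);
# members with deletions pull these bases into the rendered window.
VECTOR_CONTEXT = "GAGTCGACCTGCAGGCATGCAAGCTTGGCACTGGCCGTCGTTTTAC"


@dataclass(frozen=True)
class DualBarcode:
    """One library molecule's genotype and its physically emitted barcode."""

    snp_position: int  # 0-based within the SNP region
    snp_alt_base: str
    random_region: str
    defect_class: str = DEFECT_INTACT
    emitted_barcode: str = ""  # barcode sequence with any deletion applied

    @property
    def snp(self) -> tuple[int, str]:
        return self.snp_position, self.snp_alt_base


@dataclass(frozen=True)
class Colony:
    colony_id: str
    members: tuple[DualBarcode, ...]

    @property
    def true_multiplicity(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults follow the source experiment where it states a value:
    defect fractions 0.20 (large, >3 nt lost) and 0.125 (small, 1-3 nt),
    PCR error 8e-6 substitutions/bp/duplication, sequencing error inside
    the quoted 0.2%-1.2% per-base window, index hopping inside the
    quoted 0.2%-6% window, and a 37 °C-heat-shock-like multiplicity
    profile (~65% mono-transformed).  Amplicon read length and PCR cycle
    count are package defaults, not measured quantities.
    """

    n_library_molecules: int = 1000
    multiplicity_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.65, 2: 0.20, 3: 0.10, 4: 0.05}
    )
    large_deletion_fraction: float = 0.20
    small_deletion_fraction: float = 0.125
    sequencing_error_rate: float = 0.007
    pcr_error_rate: float = 8e-6
    pcr_cycles: int = 30
    index_hop_rate: float = 0.01
    cross_well_contamination_rate: float = 0.01
    mean_depth: float = 500.0
    depth_model: str = "poisson"  # "poisson" or "fixed"
    read_length: int = 70
    low_quality_fraction: float = 0.40
    q_low: float = 30.0
    q_high: float = 40.0
    q_sd: float = 2.0
    trace_noise_sd: float = 0.0
    n_colonies: int = 93
    n_conditions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_library_molecules < 1:
            raise ValueError("n_library_molecules must be >= 1")
        total = sum(self.multiplicity_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("multiplicity_distribution must sum to 1")
        if any(k < 1 or p < 0 for k, p in self.multiplicity_distribution.items()):
            raise ValueError("multiplicities must be >= 1 with probabilities >= 0")
        if not 0 <= self.large_deletion_fraction + self.small_deletion_fraction <= 1:
            raise ValueError("defect fractions must sum to at most 1")
        for name in (
            "sequencing_error_rate",
            "pcr_error_rate",
            "index_hop_rate",
            "cross_well_contamination_rate",
            "trace_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError("depth_model must be 'poisson' or 'fixed'")


def _random_string(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _apply_deletion(sequence: str, defect_class: str, rng: np.random.Generator) -> str:
    if defect_class == DEFECT_INTACT:
        return sequence
    if defect_class == DEFECT_SMALL_DELETION:
        length = int(rng.integers(1, 4))
    elif defect_class == DEFECT_LARGE_DELETION:
        length = int(rng.integers(4, min(12, len(sequence)) + 1))
    else:
        raise ValueError(f"unknown defect class {defect_class!r}")
    start = int(rng.integers(0, len(sequence) - length + 1))
    return sequence[:start] + sequence[start + length :]


def make_library(
    config: SimConfig,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    rng: np.random.Generator | None = None,
) -> list[DualBarcode]:
    """Draw a barcoded plasmid library.

    SNPs are uniform over the (position, alternative base) space;
    random regions are iid uniform; deletion classes are assigned at the
    configured fractions and applied to the emitted barcode sequence
    (the genotype record keeps the intact design).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_library_molecules
    snp_len = len(ref.snp_region_reference)
    positions = rng.integers(0, snp_len, size=n)
    alt_choices = rng.integers(0, 3, size=n)
    class_draws = rng.random(n)
    molecules = []
    for i in range(n):
        pos = int(positions[i])
        ref_base = ref.snp_region_reference[pos]
        alt = [b for b in BASES if b != ref_base][alt_choices[i]]
        random_region = _random_string(rng, ref.random_region_length)
        u = class_draws[i]
        if u < config.large_deletion_fraction:
            defect = DEFECT_LARGE_DELETION
        elif u < config.large_deletion_fraction + config.small_deletion_fraction:
            defect = DEFECT_SMALL_DELETION
        else:
            defect = DEFECT_INTACT
        snp_region = ref.snp_region_reference[:pos] + alt + ref.snp_region_reference[pos + 1 :]
        intact = snp_region + random_region
        molecules.append(
            DualBarcode(
                snp_position=pos,
                snp_alt_base=alt,
                random_region=random_region,
                defect_class=defect,
                emitted_barcode=_apply_deletion(intact, defect, rng),
            )
        )
    return molecules


def sample_colonies(
    library: Sequence[DualBarcode],
    n_colonies: int,
    multiplicity_distribution: Mapping[int, float],
    rng: np.random.Generator,
    id_prefix: str = "colony",
) -> list[Colony]:
    """Draw colonies: k from the multiplicity distribution, then k distinct
    library members uniformly without replacement."""
    ks = sorted(multiplicity_distribution)
    probs = np.array([multiplicity_distribution[k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    if max(ks) > len(library):
        raise ValueError("multiplicity exceeds library size")
    draws = rng.choice(ks, size=n_colonies, p=probs)
    colonies = []
    for i, k in enumerate(draws):
        idx = rng.choice(len(library), size=int(k), replace=False)
        colonies.append(
            Colony(
                colony_id=f"{id_prefix}{i:05d}",
                members=tuple(library[j] for j in idx),
            )
        )
    return colonies


def member_amplicon(member: DualBarcode, ref: BarcodeReference, length: int) -> str:
    """The sequence a colony member contributes, padded with backbone context."""
    seq = ref.upstream_anchor + member.emitted_barcode + ref.downstream_anchor
    context = VECTOR_CONTEXT * (1 + max(0, length - len(seq)) // len(VECTOR_CONTEXT) + 1)
    return (seq + context)[:length]


def render_trace(
    colony: Colony | Sequence[DualBarcode],
    ref: BarcodeReference = DEFAULT_REFERENCE,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    weights: Sequence[float] | None = None,
) -> TraceProfile:
    """Render the composite Sanger trace of a colony.

    Per-position fractions are the weighted average (equal weights by
    default) of member base indicators; members with deletions shift all
    downstream bases, which is what corrupts the anchor positions.
    Truncated Gaussian noise of scale ``noise_sd`` is added and each
    position renormalised to sum 1.
    """
    members = colony.members if isinstance(colony, Colony) else tuple(colony)
    if not members:
        raise ValueError("colony has no members")
    if weights is None:
        w = np.full(len(members), 1.0 / len(members))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(members),) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative, one per member")
        w = w / w.sum()
    length = ref.amplicon_length
    intensities = np.zeros((length, len(BASES)))
    for member, weight in zip(members, w):
        for pos, base in enumerate(member_amplicon(member, ref, length)):
            intensities[pos, BASE_INDEX[base]] += weight
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        intensities = np.clip(intensities + rng.normal(0.0, noise_sd, intensities.shape), 0.0, None)
    return TraceProfile.from_intensities(intensities)


def _substitute(sequence: str, n_sub: int, rng: np.random.Generator) -> str:
    if n_sub == 0:
        return sequence
    n_sub = min(n_sub, len(sequence))
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    seq = list(sequence)
    for pos in positions:
        current = seq[pos]
        choices = [b for b in BASES if b != current]
        seq[pos] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def _quality_string(length: int, mean_q: float, sd: float, rng: np.random.Generator) -> str:
    scores = np.clip(np.rint(rng.normal(mean_q, sd, size=length)), 2, 41).astype(int)
    return "".join(chr(q + PHRED_OFFSET) for q in scores)


def _reads_for_template(
    template: str,
    read_id_prefix: str,
    depth: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[FastqRead]:
    # PCR error approximated per final molecule: Binomial(cycles * length, rate)
    # substitutions, matching the expected variant load of a branching
    # lineage at these tiny rates.
    p_pcr = config.pcr_error_rate
    n_pcr_trials = config.pcr_cycles * len(template)
    reads = []
    for i in range(depth):
        seq = _substitute(template, int(rng.binomial(n_pcr_trials, p_pcr)), rng)
        seq = _substitute(seq, int(rng.binomial(len(seq), config.sequencing_error_rate)), rng)
        mean_q = (
            config.q_low if rng.random() < config.low_quality_fraction else config.q_high
        )
        reads.append(
            FastqRead(
                id=f"{read_id_prefix}.{i}",
                sequence=seq,
                quality=_quality_string(len(seq), mean_q, config.q_sd, rng),
            )
        )
    return reads


def render_reads(
    pools: Mapping[str, Sequence[DualBarcode]],
    config: SimConfig,
    ref: BarcodeReference = DEFAULT_REFERENCE,
    rng: np.random.Generator | None = None,
) -> dict[str, list[FastqRead]]:
    """Emit per-condition amplicon FASTQ reads.

    Each pool molecule is amplified to a Poisson(mean_depth) read count;
    every read carries PCR substitutions, sequencing substitutions and a
    two-class quality string.  Index hopping reassigns single reads to a
    uniformly chosen other condition.  Cross-well contamination injects
    whole foreign templates (amplified to full depth) at a per-pool
    Poisson rate, mimicking a contaminating well that entered the PCR
    early — such sequences survive a coverage cutoff, unlike hopped
    single reads.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lib_ids = sorted(pools)
    out: dict[str, list[FastqRead]] = {lid: [] for lid in lib_ids}
    def draw_depth() -> int:
        if config.depth_model == "fixed":
            return int(round(config.mean_depth))
        return int(rng.poisson(config.mean_depth))

    for lid in lib_ids:
        for bi, member in enumerate(pools[lid]):
            template = member_amplicon(member, ref, config.read_length)
            depth = draw_depth()
            for read in _reads_for_template(template, f"{lid}:{bi}", depth, config, rng):
                dest = lid
                if len(lib_ids) > 1 and rng.random() < config.index_hop_rate:
                    others = [x for x in lib_ids if x != lid]
                    dest = others[rng.integers(0, len(others))]
                out[dest].append(read)
    if len(lib_ids) > 1 and config.cross_well_contamination_rate > 0:
        for lid in lib_ids:
            n_events = int(
                rng.poisson(config.cross_well_contamination_rate * len(pools[lid]))
            )
            for event in range(n_events):
                others = [x for x in lib_ids if x != lid and len(pools[x]) > 0]
                if not others:
                    break
                src = others[rng.integers(0, len(others))]
                member = pools[src][rng.integers(0, len(pools[src]))]
                template = member_amplicon(member, ref, config.read_length)
                depth = draw_depth()
                out[lid].extend(
                    _reads_for_template(
                        template, f"{lid}:contam{event}:{src}", depth, config, rng
                    )
                )
    return out


def partition_pools(
    colonies: Sequence[Colony], n_conditions: int
) -> dict[str, list[DualBarcode]]:
    """Split colonies round-robin into per-condition pools of their members.

    Each pool holds the distinct molecules found in its colonies — the
    material one condition's colony PCRs contribute to the sequencing run.
    """
    pools: dict[str, list[DualBarcode]] = {f"cond{c + 1}": [] for c in range(n_conditions)}
    for i, colony in enumerate(colonies):
        key = f"cond{(i % n_conditions) + 1}"
        for member in colony.members:
            if member not in pools[key]:
                pools[key].append(member)
    return pools
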