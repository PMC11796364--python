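"""Readers, writers and run configuration.

Formats: FASTQ (Phred+33) and FASTA via Biopython; tab-delimited tables
(header row, UTF-8, '.' decimal) via pandas; YAML/JSON run configuration.
All readers validate their input and fail with the offending record or
row identified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .barcode_model import BarcodeScheme
from .sanger import BarcodeReference, TraceProfile

logger = logging.getLogger("plasmux")

PHRED_OFFSET = 33

TRACE_COLUMNS = ["colony_id", "position", "frac_A", "frac_C", "frac_G", "frac_T"]


class FastqRead(NamedTuple):
    id: str
    sequence: str
    quality: str  # Phred+33


def phred_scores(quality: str) -> np.ndarray:
    """Decode a Phred+33 quality string to integer scores."""
    return np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream reads from a Phred+33 FASTQ file (constant memory).

    Malformed records (truncated record, sequence/quality length
    mismatch) raise ``ValueError`` naming the 0-based record index.
    """
    index = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, sequence, quality = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
            yield FastqRead(id=title, sequence=sequence.upper(), quality=quality)
            index += 1


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            if len(read.sequence) != len(read.quality):
                raise ValueError(f"read {read.id!r}: sequence/quality length mismatch")
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")
            n += 1
    return n


def read_traces(path: str | Path, *, atol: float = 0.01) -> dict[str, TraceProfile]:
    """Load per-colony trace profiles from a tidy TSV.

    Required columns: colony_id, position (0-based), frac_A, frac_C,
    frac_G, frac_T.  Unknown columns are ignored with a warning; a
    fraction outside [0, 1] or a per-position sum off 1 by more than
    ``atol`` fails with the 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table is missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in TRACE_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown trace column(s): %s", ", ".join(unknown))
    frac = df[["frac_A", "frac_C", "frac_G", "frac_T"]].to_numpy(dtype=float)
    out_of_range = (frac < 0) | (frac > 1)
    if out_of_range.any():
        row = int(np.argwhere(out_of_range.any(axis=1))[0, 0])
        raise ValueError(f"row {row + 1}: fraction outside [0, 1]")
    sums = frac.sum(axis=1)
    bad_sum = np.abs(sums - 1.0) > atol
    if bad_sum.any():
        row = int(np.argmax(bad_sum))
        raise ValueError(f"row {row + 1}: fractions sum to {sums[row]:.3f}, not 1±{atol}")
    traces: dict[str, TraceProfile] = {}
    for colony_id, group in df.groupby("colony_id", sort=False):
        group = group.sort_values("position")
        positions = group["position"].to_numpy()
        if not np.array_equal(positions, np.arange(len(positions))):
            raise ValueError(f"colony {colony_id!r}: positions must be contiguous from 0")
        traces[str(colony_id)] = TraceProfile(
            group[["frac_A", "frac_C", "frac_G", "frac_T"]].to_numpy(dtype=float), atol=atol
        )
    return traces


def write_traces(traces: dict[str, TraceProfile], path: str | Path) -> None:
    rows = []
    for colony_id, trace in traces.items():
        for pos, (a, c, g, t) in enumerate(trace.fractions):
            rows.append((colony_id, pos, a, c, g, t))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    min_mean_q: int = 35
    min_coverage: int = 200
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.min_mean_q <= 0 or self.min_coverage <= 0 or self.max_mismatch < 0:
            raise ConfigError("thresholds must be positive (max_mismatch >= 0)")


@dataclass(frozen=True)
class RunConfig:
    scheme: BarcodeScheme = field(default_factory=BarcodeScheme)
    reference: BarcodeReference = field(default_factory=BarcodeReference)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0


def _build(section_name: str, cls, data: dict):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid key in config section {section_name!r}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"invalid value in config section {section_name!r}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration.

    Sections ``scheme``, ``reference`` and ``thresholds`` are each
    optional; omitted fields fall back to the documented defaults.  A
    ``reference`` section, when present, must name its
    ``snp_region_reference`` — there is no universal barcode sequence.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {"scheme", "reference", "thresholds", "seed", "simulation"}
    for key in data:
        if key not in known:
            logger.warning("ignoring unknown config section %r", key)
    if "reference" in data:
        if "snp_region_reference" not in data["reference"]:
            raise ConfigError("missing required config key: reference.snp_region_reference")
        reference = _build("reference", BarcodeReference, data["reference"])
    else:
        reference = BarcodeReference()
    scheme = _build("scheme", BarcodeScheme, data.get("scheme", {}))
    thresholds = _build("thresholds", Thresholds, data.get("thresholds", {}))
    return RunConfig(
        scheme=scheme,
        reference=reference,
        thresholds=thresholds,
        seed=int(data.get("seed", 0)),
    )


def write_run_log(path: str | Path, command: str, parameters: dict) -> None:
    """Machine-readable provenance log (no timestamp: reruns stay byte-identical)."""
    payload = {
        "tool": "plasmux",
        "version": __version__,
        "command": command,
        "parameters": parameters,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def reference_to_dict(ref: BarcodeReference) -> dict:
    return asdict(ref)
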