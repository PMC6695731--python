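"""Read decoding: raw sequences -> gene-level count tables.

Each read is sliced into its variable segments by the design's layout;
every segment is matched to the nearest codon of its cycle (across both
lineages) under a per-codon mismatch budget, and the cycle-1..3 lineage
assignments must agree.  Every failure is a typed rejection, never a
silent drop, so assigned + rejected always equals total reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import Gene, LibraryDesign

REV = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(REV)[::-1]


@dataclass(frozen=True)
class DecodeSettings:
    max_mismatch: int = 2
    require_unique_best: bool = True
    try_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")

    def validate_against(self, design: LibraryDesign) -> None:
        # 2*max_mismatch < d_min guarantees a unique nearest codon
        if not self.max_mismatch < design.d_min / 2:
            raise ValueError(
                f"max_mismatch={self.max_mismatch} must be < d_min/2 = "
                f"{design.d_min / 2} for unambiguous assignment"
            )


@dataclass(frozen=True)
class Rejection:
    reason: str
    detail: str = ""


class CodonMatcher:
    """Vectorised nearest-codon lookup for one cycle (all lineages pooled)."""

    def __init__(self, design: LibraryDesign, cycle: int):
        labels: list[tuple[str, int]] = []
        rows: list[np.ndarray] = []
        for (c, lin), table in sorted(design.codon_tables.items()):
            if c != cycle:
                continue
            for bid, seq in sorted(table.entries.items()):
                labels.append((lin, bid))
                rows.append(np.frombuffer(seq.encode(), dtype=np.uint8))
        self.cycle = cycle
        self.labels = labels
        self.matrix = np.stack(rows)
        self.length = self.matrix.shape[1]

    def match(self, segment: str, settings: DecodeSettings
              ) -> Union[tuple[str, int], Rejection]:
        if len(segment) != self.length:
            raise ValueError(
                f"segment length {len(segment)} != codon length {self.length}"
            )
        seg = np.frombuffer(segment.encode(), dtype=np.uint8)
        dists = (self.matrix != seg).sum(axis=1)
        best = int(dists.min())
        if best > settings.max_mismatch:
            return Rejection("no_match", f"cycle{self.cycle}:best_distance={best}")
        hits = np.nonzero(dists == best)[0]
        if settings.require_unique_best and len(hits) > 1:
            return Rejection("ambiguous", f"cycle{self.cycle}:tie_at_distance={best}")
        return self.labels[int(hits[0])]


def match_codon(segment: str, design: LibraryDesign, cycle: int,
                settings: DecodeSettings | None = None
                ) -> Union[tuple[str, int], Rejection]:
    """Match one variable segment to (lineage, codon id) or reject.

    Rejection reasons: ``no_match`` (nearest codon beyond the mismatch
    budget) and ``ambiguous`` (tie at the best distance under
    require_unique_best).
    """
    settings = settings or DecodeSettings()
    return CodonMatcher(design, cycle).match(segment, settings)


def _build_matchers(design: LibraryDesign) -> dict[int, CodonMatcher]:
    return {cycle: CodonMatcher(design, cycle) for cycle in (1, 2, 3, 4)}


def _decode_oriented(seq: str, design: LibraryDesign, settings: DecodeSettings,
                     matchers: dict[int, CodonMatcher]) -> Union[Gene, Rejection]:
    codons: list[int] = []
    lineages: list[str] = []
    for cycle, start, stop in design.layout.variable_slices():
        res = matchers[cycle].match(seq[start:stop], settings)
        if isinstance(res, Rejection):
            return Rejection(f"codon_reject_cycle{cycle}", res.reason)
        lin, bid = res
        codons.append(bid)
        if cycle != 4:
            lineages.append(lin)
    if len(set(lineages)) > 1:
        return Rejection("lineage_conflict", "/".join(lineages))
    return Gene(lineages[0], tuple(codons))


def decode_read(read: str, design: LibraryDesign,
                settings: DecodeSettings | None = None,
                matchers: dict[int, CodonMatcher] | None = None
                ) -> Union[Gene, Rejection]:
    """Decode one read to a Gene, or return a typed rejection.

    All failures are rejections (``bad_length``, ``codon_reject_cycle<c>``,
    ``lineage_conflict``); reverse-complement orientation is tried when
    the forward decode fails and try_reverse_complement is set.
    """
    settings = settings or DecodeSettings()
    settings.validate_against(design)
    if matchers is None:
        matchers = _build_matchers(design)
    if len(read) != design.layout.total_length:
        return Rejection("bad_length", f"length={len(read)}")
    read = read.upper()
    fwd = _decode_oriented(read, design, settings, matchers)
    if isinstance(fwd, Gene) or not settings.try_reverse_complement:
        return fwd
    rev = _decode_oriented(reverse_complement(read), design, settings, matchers)
    return rev if isinstance(rev, Gene) else fwd


@dataclass
class CountTable:
    """Reads per gene for one sample, with explicit rejection accounting."""

    sample_id: str
    counts: dict[Gene, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def total_reads(self) -> int:
        return self.total_assigned + self.total_rejected

    def check_conservation(self, expected_total: int) -> None:
        if self.total_reads != expected_total:
            raise AssertionError(
                f"conservation violated: {self.total_assigned} assigned + "
                f"{self.total_rejected} rejected != {expected_total} reads"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lineage": g.lineage,
                "c1": g.codons[0], "c2": g.codons[1],
                "c3": g.codons[2], "c4": g.codons[3],
                "count": n,
            }
            for g, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["lineage", "c1", "c2", "c3", "c4", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        counts = {
            Gene(row.lineage, (int(row.c1), int(row.c2), int(row.c3), int(row.c4))): int(row.count)
            for row in df.itertuples()
        }
        return cls(sample_id=sample_id or str(path), counts=counts)

    @classmethod
    def from_vector(cls, genes: Iterable[Gene], counts: Iterable[int],
                    sample_id: str) -> "CountTable":
        table: dict[Gene, int] = {}
        for g, n in zip(genes, counts):
            n = int(n)
            if n < 0:
                raise ValueError("counts must be non-negative")
            if n:
                table[g] = table.get(g, 0) + n
        return cls(sample_id=sample_id, counts=table)


def _iter_sequences(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
        return
    for item in reads:
        yield str(getattr(item, "seq", item))


def count_genes(reads, design: LibraryDesign,
                settings: DecodeSettings | None = None,
                sample_id: str = "sample") -> CountTable:
    """Aggregate decode_read over a FASTQ path / record stream into counts."""
    settings = settings or DecodeSettings()
    settings.validate_against(design)
    matchers = _build_matchers(design)
    table = CountTable(sample_id=sample_id)
    total = 0
    for seq in _iter_sequences(reads):
        total += 1
        res = decode_read(seq, design, settings, matchers)
        if isinstance(res, Gene):
            table.counts[res] = table.counts.get(res, 0) + 1
        else:
            table.rejected[res.reason] = table.rejected.get(res.reason, 0) + 1
    table.check_conservation(total)
    return table


def qc_summary(table: CountTable) -> dict:
    return {
        "sample_id": table.sample_id,
        "total_reads": table.total_reads,
        "assigned": table.total_assigned,
        "rejected": dict(sorted(table.rejected.items())),
        "distinct_genes": len(table.counts),
    }
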