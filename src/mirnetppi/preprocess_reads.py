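"""Adapter trimming and length filtering for paired-end FASTQ.

Illumina 3' adapters are located allowing a fixed mismatch budget
(default 2), the read is cut at the match start, and pairs whose either
mate shrinks to the minimum length or below (default: 18 bp or shorter
discarded) are dropped as a pair so mates stay synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io_formats import FastqRead

# Illumina TruSeq-style paired-end adapters used by default.
READ1_ADAPTER = "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
READ2_ADAPTER = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATT"


@dataclass
class TrimPolicy:
    """Adapter-trimming parameters.

    ``min_length_exclusive`` is the exclusive keep bound: a mate trimmed
    to this length or shorter discards its pair (18 means "18 bp or
    shorter discarded").  ``min_overlap`` is the minimum number of
    adapter bases that must align when only an adapter prefix overhangs
    the 3' end; 8 keeps the chance of a random partial hit near
    4^-8 per position.  ``pair_mode`` discards the whole pair when one
    mate fails the length rule; ``single`` drops only the failing mate.
    """

    adapter_read1: str = READ1_ADAPTER
    adapter_read2: str = READ2_ADAPTER
    max_mismatches: int = 2
    min_length_exclusive: int = 18
    min_overlap: int = 8
    pair_mode: str = "pair"  # "pair" | "single"

    def __post_init__(self) -> None:
        for ad in (self.adapter_read1, self.adapter_read2):
            if not ad or set(ad) - set("ACGT"):
                raise ValueError(f"adapter must be non-empty over ACGT, got {ad!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_mismatches >= min(len(self.adapter_read1), len(self.adapter_read2)):
            raise ValueError("max_mismatches must be smaller than the adapter length")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.pair_mode not in ("pair", "single"):
            raise ValueError("pair_mode must be 'pair' or 'single'")


@dataclass
class TrimStats:
    """Bookkeeping for one trimming run; kept + discarded == input."""

    pairs_in: int = 0
    mates_trimmed: int = 0
    pairs_discarded: int = 0
    pairs_kept: int = 0
    mates_discarded: int = 0  # only populated in single-mate mode
    record_errors: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "mates_trimmed": self.mates_trimmed,
            "pairs_discarded": self.pairs_discarded,
            "pairs_kept": self.pairs_kept,
            "mates_discarded": self.mates_discarded,
            "record_errors": list(self.record_errors),
        }


def find_adapter(sequence: str, adapter: str, policy: TrimPolicy) -> int | None:
    """Leftmost adapter match start in ``sequence``, or None.

    Scans every start position left to right.  At interior positions the
    full adapter must fit with at most ``max_mismatches`` substitutions
    (N always counts as a mismatch); at 3'-end positions an adapter
    prefix of at least ``min_overlap`` bases may overhang, with the same
    mismatch budget over the aligned bases.
    """
    n, m = len(sequence), len(adapter)
    budget = policy.max_mismatches
    for start in range(n):
        aligned = min(m, n - start)
        if aligned < m and aligned < policy.min_overlap:
            break  # remaining positions only get shorter
        mism = 0
        ok = True
        for i in range(aligned):
            base = sequence[start + i]
            if base != adapter[i] or base == "N":
                mism += 1
                if mism > budget:
                    ok = False
                    break
        if ok:
            return start
    return None


def trim_read(read: FastqRead, adapter: str, policy: TrimPolicy) -> tuple[FastqRead, bool]:
    """Cut ``read`` at its adapter match (if any); returns (read, trimmed?)."""
    pos = find_adapter(read.sequence, adapter, policy)
    if pos is None:
        return read, False
    return FastqRead(read.read_id, read.sequence[:pos], read.quality[:pos]), True


def trim_and_filter(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    policy: TrimPolicy | None = None,
) -> tuple[list[tuple[FastqRead, FastqRead]], TrimStats]:
    """Trim both mates of each pair and apply the length filter.

    In ``pair`` mode a pair is discarded when either trimmed mate is
    ``min_length_exclusive`` bases or shorter.  Records whose sequence
    and quality lengths disagree are skipped and reported in the stats
    rather than aborting the stream.
    """
    policy = policy or TrimPolicy()
    stats = TrimStats()
    kept: list[tuple[FastqRead, FastqRead]] = []
    for r1, r2 in pairs:
        stats.pairs_in += 1
        try:
            t1, did1 = trim_read(r1, policy.adapter_read1, policy)
            t2, did2 = trim_read(r2, policy.adapter_read2, policy)
        except ValueError as exc:  # length-mismatch record
            stats.record_errors.append(str(exc))
            stats.pairs_discarded += 1
            continue
        stats.mates_trimmed += int(did1) + int(did2)
        short1 = len(t1.sequence) <= policy.min_length_exclusive
        short2 = len(t2.sequence) <= policy.min_length_exclusive
        if policy.pair_mode == "pair":
            if short1 or short2:
                stats.pairs_discarded += 1
            else:
                stats.pairs_kept += 1
                kept.append((t1, t2))
        else:
            if short1 and short2:
                stats.pairs_discarded += 1
            else:
                stats.mates_discarded += int(short1) + int(short2)
                stats.pairs_kept += 1
                kept.append((t1 if not short1 else None, t2 if not short2 else None))  # type: ignore[arg-type]
    return kept, stats
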