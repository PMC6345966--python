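"""Read trimming, size/quality filtering and hierarchical classification.

Raw single-end small-RNA reads are adapter-trimmed, quality- and
size-filtered (18-28 nt), collapsed to unique tags with per-library counts,
and then classified sequentially: genome -> contaminant class pools (in a
fixed, explicit order) -> mature miRNAs -> clean unassigned.  A tag
matching an earlier class is removed from all later ones, mirroring the
sequential mapping convention of small-RNA workbenches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import approx_occurrences, hamming, revcomp, unify
from .annotation import AnnotationIndex, ReferencePools

LABEL_UNMAPPED = "unmapped_genome"
LABEL_MIRNA = "miRNA"
LABEL_CLEAN = "clean_unassigned"

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 28
DEFAULT_MIN_QUAL = 20.0
ADAPTER_SEED = 8
ADAPTER_MAX_MISMATCH = 1


@dataclass
class TrimStats:
    """Per-library read accounting; raw is conserved across the categories."""

    library: str
    raw: int = 0
    no_adapter: int = 0
    empty_insert: int = 0
    low_quality: int = 0
    out_of_size: int = 0
    kept_reads: int = 0

    def check_conservation(self) -> bool:
        return self.raw == (
            self.no_adapter + self.empty_insert + self.low_quality + self.out_of_size + self.kept_reads
        )


@dataclass
class TagTable:
    """Unique tag sequences with per-library counts."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    libraries: list[str] = field(default_factory=list)

    def add(self, seq: str, library: str, n: int = 1) -> None:
        if library not in self.libraries:
            self.libraries.append(library)
        per_lib = self.counts.setdefault(seq, {})
        per_lib[library] = per_lib.get(library, 0) + n

    def count(self, seq: str, library: str) -> int:
        return self.counts.get(seq, {}).get(library, 0)

    def total(self, library: str) -> int:
        return sum(per.get(library, 0) for per in self.counts.values())

    def subset(self, seqs: Iterable[str]) -> "TagTable":
        t = TagTable(libraries=list(self.libraries))
        keep = set(seqs)
        t.counts = {s: dict(c) for s, c in self.counts.items() if s in keep}
        return t


def locate_adapter(
    read: str,
    adapter: str,
    seed: int = ADAPTER_SEED,
    max_mismatch: int = ADAPTER_MAX_MISMATCH,
) -> int:
    """Start offset of the 3' adapter in *read*, or -1 if not found.

    The adapter is located by its longest prefix occurring in the read with
    at most *max_mismatch* substitutions, requiring at least *seed* matched
    columns; among equally long matches the leftmost wins.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(read)
    # fast path: exact full-length (or exact truncated-at-end) occurrence
    pos = read.find(adapter)
    if pos == -1 and len(adapter) < n:
        pos = read.find(adapter[: max(seed, 1)])
        # verify the remainder up to read end matches exactly
        while pos != -1:
            overlap = min(n - pos, len(adapter))
            if read[pos : pos + overlap] == adapter[:overlap] and overlap >= seed:
                break
            pos = read.find(adapter[: max(seed, 1)], pos + 1)
    if pos != -1:
        return pos
    if max_mismatch <= 0:
        return -1
    best = (-1, -1)  # (overlap, -pos) to maximise
    for i in range(0, n - seed + 1):
        overlap = min(n - i, len(adapter))
        if overlap < seed:
            break
        if hamming(read[i : i + overlap], adapter[:overlap]) <= max_mismatch:
            key = (overlap, -i)
            if key > best:
                best = key
    return -best[1] if best[0] != -1 else -1


def trim_and_filter(
    fastq: str | Path | Iterator[tuple[str, str, str]],
    library: str,
    adapter: str,
    tags: TagTable | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_qual: float = DEFAULT_MIN_QUAL,
) -> tuple[TagTable, TrimStats]:
    """Trim one library's FASTQ, collapse surviving inserts to unique tags.

    *fastq* may be a path or an iterator of (title, sequence, quality)
    triples.  Pass an existing *tags* table to accumulate several libraries
    into one collection.
    """
    if tags is None:
        tags = TagTable()
    stats = TrimStats(library=library)
    if library not in tags.libraries:
        tags.libraries.append(library)

    if isinstance(fastq, (str, Path)):
        if str(fastq).endswith(".gz"):
            import gzip

            handle = gzip.open(fastq, "rt")
        else:
            handle = open(fastq)
        records: Iterator[tuple[str, str, str]] = FastqGeneralIterator(handle)
    else:
        handle = None
        records = fastq
    try:
        for _title, seq, qual in records:
            stats.raw += 1
            seq = seq.upper()
            pos = locate_adapter(seq, adapter)
            if pos == -1:
                stats.no_adapter += 1
                continue
            if pos == 0:
                stats.empty_insert += 1
                continue
            insert = seq[:pos]
            q = qual[:pos]
            mean_q = sum(ord(c) - 33 for c in q) / len(q)
            if mean_q < min_qual:
                stats.low_quality += 1
                continue
            if not (min_len <= len(insert) <= max_len):
                stats.out_of_size += 1
                continue
            stats.kept_reads += 1
            tags.add(unify(insert), library)
    finally:
        if handle is not None:
            handle.close()
    return tags, stats


@dataclass
class ClassificationResult:
    tag: str
    counts: dict[str, int]
    label: str
    assigned_units: list[str] = field(default_factory=list)
    ambiguous: bool = False


def _matches_unit(tag: str, mature_seq: str, max_mismatch: int) -> bool:
    """A tag maps to a mature if one contains the other (ungapped)."""
    if max_mismatch <= 0:
        return tag in mature_seq or mature_seq in tag
    short, long_ = (tag, mature_seq) if len(tag) <= len(mature_seq) else (mature_seq, tag)
    return bool(approx_occurrences(short, long_, max_mismatch))


def classify_hierarchical(
    tags: TagTable,
    pools: ReferencePools,
    index: AnnotationIndex,
    max_mismatch: int = 0,
) -> list[ClassificationResult]:
    """Sequentially classify tags: genome, contaminant pools, miRNA, clean.

    Genome matching considers both strands; class pools and matures are
    matched on the sense strand only.  The first matching contaminant class
    wins and the tag takes that class's label.  Tags matching several
    distinct collapsed matures are assigned to all of them and flagged
    ambiguous (counted once in totals).
    """
    if not pools.class_pools or not pools.genome:
        raise ValueError("reference pools must contain a genome and at least one class pool")
    genome_fwd = "#".join(pools.genome.values())
    genome_rev = revcomp(genome_fwd)
    pool_texts = [(name, "#".join(p.values())) for name, p in pools.class_pools]
    unit_seqs = sorted(index.unit_sequence.items())

    def in_text(tag: str, text: str) -> bool:
        if max_mismatch <= 0:
            return tag in text
        return bool(approx_occurrences(tag, text, max_mismatch))

    results: list[ClassificationResult] = []
    for tag, counts in tags.counts.items():
        if not (in_text(tag, genome_fwd) or in_text(tag, genome_rev)):
            results.append(ClassificationResult(tag, counts, LABEL_UNMAPPED))
            continue
        pool_label = None
        for name, text in pool_texts:
            if in_text(tag, text):
                pool_label = name
                break
        if pool_label is not None:
            results.append(ClassificationResult(tag, counts, pool_label))
            continue
        assigned = [u for u, seq in unit_seqs if _matches_unit(tag, seq, max_mismatch)]
        if assigned:
            results.append(
                ClassificationResult(tag, counts, LABEL_MIRNA, assigned, ambiguous=len(assigned) > 1)
            )
        else:
            results.append(ClassificationResult(tag, counts, LABEL_CLEAN))
    return results


def cleaned_totals(results: list[ClassificationResult]) -> dict[str, int]:
    """Per-library cleaned-read totals: genome-mapped minus contaminant classes.

    Ambiguous miRNA tags contribute once (per read), never once per matched
    mature, so totals are not inflated.
    """
    totals: dict[str, int] = {}
    for r in results:
        if r.label in (LABEL_MIRNA, LABEL_CLEAN):
            for lib, n in r.counts.items():
                totals[lib] = totals.get(lib, 0) + n
    return totals


def mirna_totals(results: list[ClassificationResult]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for r in results:
        if r.label == LABEL_MIRNA:
            for lib, n in r.counts.items():
                totals[lib] = totals.get(lib, 0) + n
    return totals


def length_distribution(
    tags: TagTable, library: str, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> dict[int, int]:
    """Read-length histogram for one library; sums to its kept-read total."""
    hist = {n: 0 for n in range(min_len, max_len + 1)}
    for seq, counts in tags.counts.items():
        n = counts.get(library, 0)
        if n:
            hist[len(seq)] += n
    return hist
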