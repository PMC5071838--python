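"""Raw small-RNA read cleaning, collapsing and library summaries.

The cascade is: 3' adapter trimming -> length filter -> mean-quality filter
-> sequence-composition filter.  Every removal is attributed to exactly one
stage in a ledger so that input reads = removed + survivors, exactly.
Survivors are collapsed to unique tags with per-library counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO

from savmir._seq import check_alphabet

MIN_TAG_LEN = 15
MAX_TAG_LEN = 30

# composition rules, in firing order; (reason, predicate builder) pairs
HOMOPOLYMER_THRESHOLDS = {"A": 7, "C": 8, "G": 6, "T": 7}
TANDEM_THRESHOLDS = {2: 10, 3: 6, 4: 5}  # unit length -> min unit repeats


@dataclass(frozen=True)
class RawRead:
    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")


@dataclass
class CleanTag:
    """A unique collapsed read sequence with per-library counts."""

    seq: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class FilterLedger:
    """Reads removed per cascade stage, plus survivors."""

    input_reads: int = 0
    removed: Counter = field(default_factory=Counter)
    survivors: int = 0

    def conserved(self) -> bool:
        return self.input_reads == sum(self.removed.values()) + self.survivors


@dataclass
class LibrarySummary:
    length_histogram: dict[int, int]
    first_base_freq: dict[str, float]
    last_base_freq: dict[str, float]
    per_position_freq: "np.ndarray"  # 4 x maxlen, columns sum to 1
    read_count_frequency: dict[int, int]
    filter_ledger: Optional[FilterLedger] = None


def read_fastq(path) -> Iterator[RawRead]:
    """Stream a Phred+33 FASTQ file as RawRead records."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(rec.id, str(rec.seq).upper(),
                      tuple(rec.letter_annotations["phred_quality"]))


def trim_adapter(read: RawRead, adapter3: str, min_overlap: int = 6
                 ) -> Optional[RawRead]:
    """Trim the 3' adapter off a read.

    Returns the insert 5' of the left-most adapter match (prefix match of at
    least ``min_overlap`` bases with at most one mismatch in the matched
    region), or ``None`` when no adapter is found.
    """
    if not adapter3:
        raise ValueError("empty 3' adapter")
    if min_overlap < 6:
        raise ValueError("min_overlap must be >= 6 to avoid spurious trims")
    adapter3 = check_alphabet(adapter3, allow_n=False)
    seq = read.seq
    n, m = len(seq), len(adapter3)
    for i in range(0, n - min_overlap + 1):
        matched = min(m, n - i)
        mismatches = 0
        for k in range(matched):
            if seq[i + k] != adapter3[k]:
                mismatches += 1
                if mismatches > 1:
                    break
        else:
            return RawRead(read.id, seq[:i], read.qual[:i])
    return None


def filter_length(seq_or_read, min_len: int = MIN_TAG_LEN,
                  max_len: int = MAX_TAG_LEN) -> bool:
    """Keep iff min_len <= length <= max_len."""
    seq = seq_or_read.seq if isinstance(seq_or_read, RawRead) else seq_or_read
    return min_len <= len(seq) <= max_len


def filter_quality(read: RawRead, threshold: float = 20.0) -> bool:
    """Keep iff mean Phred quality >= threshold (boundary inclusive)."""
    if not read.qual:
        return False
    return float(np.mean(read.qual)) >= threshold


def _max_tandem_repeats(seq: str, k: int) -> int:
    best = 0
    n = len(seq)
    for i in range(n - k + 1):
        unit = seq[i:i + k]
        r = 1
        while seq[i + k * r: i + k * (r + 1)] == unit:
            r += 1
        if r > best:
            best = r
    return best


def filter_composition(seq: str) -> tuple[bool, Optional[str]]:
    """Degenerate-sequence filter.

    Removes a sequence when any rule fires: >=2 N in total; a homopolymer run
    of A>=7, C>=8, G>=6 or T>=7; or a tandem repeat of a 2-mer unit >=10
    times, a 3-mer >=6 times, or a 4-mer >=5 times.  Returns
    ``(keep, reason)`` where reason names the first rule fired.
    """
    s = check_alphabet(seq)
    if s.count("N") >= 2:
        return False, "N"
    for base, threshold in HOMOPOLYMER_THRESHOLDS.items():
        if base * threshold in s:
            return False, f"poly{base}"
    for k, threshold in TANDEM_THRESHOLDS.items():
        if len(s) >= k * threshold and _max_tandem_repeats(s, k) >= threshold:
            return False, {2: "dimer", 3: "trimer", 4: "tetramer"}[k]
    return True, None


def clean_library(reads: Iterable[RawRead], adapter3: str, *,
                  min_overlap: int = 6, min_len: int = MIN_TAG_LEN,
                  max_len: int = MAX_TAG_LEN, min_qual: float = 20.0
                  ) -> tuple[list[RawRead], FilterLedger]:
    """Run the full cleaning cascade over one library."""
    ledger = FilterLedger()
    kept: list[RawRead] = []
    for read in reads:
        ledger.input_reads += 1
        trimmed = trim_adapter(read, adapter3, min_overlap)
        if trimmed is None:
            ledger.removed["3adt_not_found"] += 1
            continue
        if not filter_length(trimmed, min_len, max_len):
            ledger.removed["length"] += 1
            continue
        if not filter_quality(trimmed, min_qual):
            ledger.removed["quality"] += 1
            continue
        keep, reason = filter_composition(trimmed.seq)
        if not keep:
            ledger.removed[f"composition:{reason}"] += 1
            continue
        ledger.survivors += 1
        kept.append(trimmed)
    return kept, ledger


def collapse(reads_by_library: dict[str, Sequence[RawRead | str]]
             ) -> list[CleanTag]:
    """Collapse cleaned reads into unique tags with per-library counts.

    Output is ordered by descending total count, then sequence, so repeated
    runs are byte-identical.
    """
    libs = list(reads_by_library)
    per_seq: dict[str, Counter] = {}
    for lib, reads in reads_by_library.items():
        for r in reads:
            seq = r.seq if isinstance(r, RawRead) else str(r)
            per_seq.setdefault(seq, Counter())[lib] += 1
    tags = [CleanTag(seq, {lib: cnt.get(lib, 0) for lib in libs})
            for seq, cnt in per_seq.items()]
    tags.sort(key=lambda t: (-t.total, t.seq))
    return tags


def summarize(tags: Sequence[CleanTag],
              ledger: Optional[FilterLedger] = None) -> LibrarySummary:
    """Length/base-composition/copy-number summaries over a tag set."""
    lengths = Counter(len(t.seq) for t in tags)
    copy_numbers = Counter(t.total for t in tags)
    first = Counter(t.seq[0] for t in tags if t.seq)
    last = Counter(t.seq[-1] for t in tags if t.seq)
    n = sum(first.values())
    bases = "ACGT"
    maxlen = max((len(t.seq) for t in tags), default=0)
    mat = np.zeros((4, maxlen))
    for t in tags:
        for pos, b in enumerate(t.seq):
            if b in bases:
                mat[bases.index(b), pos] += 1
    col = mat.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mat = np.where(col > 0, mat / col, 0.0)
    return LibrarySummary(
        length_histogram=dict(sorted(lengths.items())),
        first_base_freq={b: first.get(b, 0) / n if n else 0.0 for b in bases},
        last_base_freq={b: last.get(b, 0) / n if n else 0.0 for b in bases},
        per_position_freq=mat,
        read_count_frequency=dict(sorted(copy_numbers.items())),
        filter_ledger=ledger,
    )


def write_tags_fasta(tags: Sequence[CleanTag], path) -> None:
    """Write collapsed tags as FASTA with ``>tag{n}_x{total}`` headers."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{t.total}\n{t.seq}\n")


def write_count_matrix(tags: Sequence[CleanTag], path) -> None:
    libs = sorted({lib for t in tags for lib in t.counts})
    with open(path, "w") as fh:
        fh.write("tag\t" + "\t".join(libs) + "\n")
        for t in tags:
            fh.write(t.seq + "\t" + "\t".join(str(t.counts.get(l, 0)) for l in libs) + "\n")
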