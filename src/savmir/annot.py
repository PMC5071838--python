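"""Tag annotation: reference mapping, decoy subtraction, miRNA classification.

Mapping is ungapped and full-length with at most one substitution, on both
strands for genome references.  Classification follows the joint-mapping
rule: known-miRNA hit AND genome hit -> conserved; known-miRNA hit only ->
semi-conserved; genome hit only -> novel, provided the flanking genomic
locus folds into a valid hairpin (otherwise semi-conserved); no hit ->
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from savmir._fold import HairpinFold, fold_hairpin
from savmir._seq import check_alphabet, encode, revcomp

__all__ = [
    "ReferenceIndex", "Hit", "MirnaAnnotation", "HairpinFold",
    "match_le1", "subtract", "classify", "extract_seed", "assign_families",
    "fold_hairpin", "validate_hairpin",
]

REFERENCE_KINDS = {"ncrna", "repeat", "mature", "precursor", "genome"}

# precursor candidate windows around a genome hit: (upstream, downstream)
FLANK_WINDOWS = ((15, 60), (60, 15))


class ReferenceIndex:
    """A named set of reference sequences of one kind, scannable for tags."""

    def __init__(self, name: str, sequences: dict[str, str], kind: str):
        if kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference kind {kind!r}")
        if not sequences:
            raise ValueError(f"reference index {name!r} is empty")
        self.name = name
        self.kind = kind
        self.sequences = {rid: check_alphabet(s) for rid, s in sequences.items()}
        self._encoded = {rid: encode(s) for rid, s in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class Hit:
    ref_id: str
    start: int        # 0-based on the forward reference strand
    strand: str       # '+' or '-'
    mismatches: int


@dataclass
class MirnaAnnotation:
    id: str
    mature_seq: str
    klass: str                      # conserved | semi-conserved | novel
    family_seed: str
    precursor_id: Optional[str] = None
    genome_hits: list = field(default_factory=list)
    mirbase_hit: Optional[tuple[str, int]] = None


def _scan_encoded(tag_arr: np.ndarray, ref_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of ``tag_arr`` at every offset of ``ref_arr``."""
    L, N = len(tag_arr), len(ref_arr)
    if N < L:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(ref_arr, L)
    return (win != tag_arr).sum(axis=1)


def match_le1(tag: str, index: ReferenceIndex, max_mismatches: int = 1
              ) -> list[Hit]:
    """All ungapped full-length hits of ``tag`` with Hamming distance <= 1.

    Genome-kind references are scanned on both strands; a '-' hit at start s
    means the reverse complement of the reference window [s, s+len) matches
    the tag.  Hits are ordered by (ref id, start, strand).
    """
    tag = check_alphabet(tag)
    if len(tag) < 15:
        raise ValueError("tag shorter than 15 nt")
    tag_arr = encode(tag)
    tag_arr = np.where(tag_arr == 255, 254, tag_arr)  # tag N never matches ref N
    queries = [(tag_arr, "+")]
    if index.kind == "genome":
        rc = encode(revcomp(tag))
        queries.append((np.where(rc == 255, 254, rc), "-"))
    hits: list[Hit] = []
    for rid, ref_arr in index._encoded.items():
        for arr, strand in queries:
            mm = _scan_encoded(arr, ref_arr)
            for start in np.nonzero(mm <= max_mismatches)[0]:
                hits.append(Hit(rid, int(start), strand, int(mm[start])))
    hits.sort(key=lambda h: (h.ref_id, h.start, h.strand))
    return hits


def subtract(tags: Sequence, index: ReferenceIndex):
    """Partition tags into (kept, removed) by decoy-reference matching.

    A tag is removed iff it has at least one <=1-mismatch hit in the index.
    Only ncRNA and repeat indexes may be used for subtraction.
    """
    if index.kind not in {"ncrna", "repeat"}:
        raise ValueError(f"subtract requires an ncrna/repeat index, got {index.kind!r}")
    kept, removed = [], []
    for tag in tags:
        seq = getattr(tag, "seq", tag)
        (removed if match_le1(seq, index) else kept).append(tag)
    return kept, removed


def extract_seed(mature: str) -> str:
    """Seed region: positions 2-8 from the 5' end, 1-based inclusive."""
    mature = check_alphabet(mature)
    if len(mature) < 8:
        raise ValueError(f"mature sequence too short for a seed: {len(mature)} nt")
    return mature[1:8]


def assign_families(annotations: Iterable[MirnaAnnotation]) -> pd.DataFrame:
    """Group miRNAs into families by identical seed.

    Families are named after the lexicographically smallest member id.
    Returns a DataFrame with columns family, seed, size, members.
    """
    groups: dict[str, list[str]] = {}
    for a in annotations:
        groups.setdefault(a.family_seed, []).append(a.id)
    rows = []
    for seed, members in groups.items():
        members = sorted(members)
        rows.append({"family": members[0], "seed": seed,
                     "size": len(members), "members": ",".join(members)})
    rows.sort(key=lambda r: (-r["size"], r["family"]))
    return pd.DataFrame(rows, columns=["family", "seed", "size", "members"])


@dataclass
class HairpinCheck:
    passed: bool
    reasons: list[str]
    mature_arm: str  # 5p | 3p | spanning | none


def validate_hairpin(fold: HairpinFold, mature_interval: tuple[int, int], *,
                     max_mfe: float = -18.0, min_stem_pairs: int = 16,
                     max_loop_overlap: int = 4,
                     max_unpaired_frac: float = 0.5) -> HairpinCheck:
    """Check a folded precursor against miRNA-precursor criteria.

    Pass requires: MFE <= ``max_mfe`` kcal/mol, at least ``min_stem_pairs``
    stem pairs, the mature on a single arm with at most ``max_loop_overlap``
    nt reaching into the loop, and at most ``max_unpaired_frac`` of mature
    bases unpaired.
    """
    s, e = mature_interval
    n = len(fold.sequence)
    if not (0 <= s < e <= n):
        raise ValueError(f"mature interval {mature_interval} outside precursor [0, {n})")
    reasons: list[str] = []
    if fold.mfe > max_mfe:
        reasons.append(f"mfe {fold.mfe} > {max_mfe}")
    if fold.stem_pairs < min_stem_pairs:
        reasons.append(f"stem_pairs {fold.stem_pairs} < {min_stem_pairs}")

    pairs = fold.pairs
    arm = "none"
    if not pairs:
        reasons.append("no base pairs")
    else:
        li, lj = max(pairs)  # innermost pair
        positions = range(s, e)
        in_loop = sum(li < p < lj for p in positions)
        in_5p = sum(p <= li for p in positions)
        in_3p = sum(p >= lj for p in positions)
        if in_5p and in_3p:
            arm = "spanning"
        elif in_5p:
            arm = "5p"
        elif in_3p:
            arm = "3p"
        else:
            arm = "spanning"  # entirely inside the loop
        if arm == "spanning" or in_loop > max_loop_overlap:
            reasons.append(f"mature placement: arm={arm}, loop_overlap={in_loop}")
        unpaired = sum(fold.structure[p] == "." for p in positions)
        if unpaired / (e - s) > max_unpaired_frac:
            reasons.append(f"unpaired fraction {unpaired / (e - s):.2f} > {max_unpaired_frac}")
    return HairpinCheck(not reasons, reasons, arm)


@dataclass
class Classification:
    label: str  # conserved | semi-conserved | novel | unclassified
    mirbase_hit: Optional[tuple[str, int]]
    genome_hits: list[Hit]
    hairpin_valid: Optional[bool] = None


def _precursor_candidates(genome_seq: str, hit: Hit, tag_len: int):
    """Candidate (precursor, mature interval) windows flanking a genome hit."""
    n = len(genome_seq)
    for up, down in FLANK_WINDOWS:
        a = max(0, hit.start - up)
        b = min(n, hit.start + tag_len + down)
        if b - a < 40:
            continue
        window = genome_seq[a:b]
        if hit.strand == "+":
            yield window, (hit.start - a, hit.start - a + tag_len)
        else:
            ms = b - (hit.start + tag_len)
            yield revcomp(window), (ms, ms + tag_len)


def classify(tag: str, mirbase: ReferenceIndex, genome: ReferenceIndex,
             fold_check: bool = True, *, validate_kwargs: Optional[dict] = None
             ) -> Classification:
    """Classify a subtracted tag as conserved / semi-conserved / novel.

    ``mirbase`` stands in for the known-miRNA reference (mature and/or
    precursor sequences merged into one index).  For genome-only tags, the
    hairpin formed by the flanking locus of each genome hit is folded and
    validated; a valid hairpin makes the tag novel, otherwise it falls back
    to semi-conserved (single-reference mapping).  With ``fold_check`` off
    every genome-only tag is novel.
    """
    tag = check_alphabet(tag)
    mb_hits = match_le1(tag, mirbase)
    g_hits = match_le1(tag, genome)
    mb_best = (mb_hits[0].ref_id, mb_hits[0].mismatches) if mb_hits else None
    if mb_hits and g_hits:
        return Classification("conserved", mb_best, g_hits)
    if mb_hits:
        return Classification("semi-conserved", mb_best, g_hits)
    if g_hits:
        if not fold_check:
            return Classification("novel", None, g_hits, hairpin_valid=None)
        kwargs = validate_kwargs or {}
        for hit in g_hits:
            for prec, interval in _precursor_candidates(
                    genome.sequences[hit.ref_id], hit, len(tag)):
                fold = fold_hairpin(prec)
                if validate_hairpin(fold, interval, **kwargs).passed:
                    return Classification("novel", None, g_hits, hairpin_valid=True)
        return Classification("semi-conserved", None, g_hits, hairpin_valid=False)
    return Classification("unclassified", None, [])
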