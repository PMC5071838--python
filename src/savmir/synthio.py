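"""Ground-truthed synthetic references and two-condition FASTQ libraries.

Everything is driven by ``numpy.random.default_rng`` seeded explicitly, so
identical inputs produce byte-identical outputs.  The generator plants:

* mature miRNAs (18-26 nt, peaked at 22 nt, 5'-T bias) inside hairpin
  precursors that the default folding backend accepts;
* precursors verbatim in a background genome;
* rRNA/tRNA-like and repeat decoys guaranteed not to cross-match matures;
* reads = mature insert + 3' adapter truncated/padded to a fixed read
  length, with per-mature condition fold changes, plus decoy contamination,
  composition-rule-violating degenerate reads, a 27-28 nt genomic length
  class and adapterless junk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from savmir._fold import fold_hairpin
from savmir._seq import check_alphabet, revcomp
from savmir.annot import validate_hairpin

BASES = np.array(list("ACGT"))
READ_LENGTH = 36          # fixed pre-trim read length
POST_ADAPTER_FILL = "GAATTCCACCACGTTCCCGTGG"  # downstream construct sequence

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    precursors: dict[str, str]
    matures: dict[str, str]
    mature_precursor: dict[str, str]     # mature id -> precursor id
    conserved: dict[str, bool]           # mature id -> conservation flag
    ncrna_decoys: dict[str, str]
    repeat_decoys: dict[str, str]
    truth: pd.DataFrame                  # mirna_id, abundance


@dataclass
class LibrarySpec:
    seed: int
    depth: int
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    contamination_fraction: float = 0.05
    degenerate_fraction: float = 0.02
    pirna_fraction: float = 0.05         # 27-28 nt genomic length class
    no_adapter_fraction: float = 0.01
    quality_mean: float = 34.0
    quality_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        fracs = (self.contamination_fraction, self.degenerate_fraction,
                 self.pirna_fraction, self.no_adapter_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("non-insert fractions must be >= 0 and sum to < 1")
        if len(self.adapter3) < 6:
            raise ValueError("3' adapter shorter than 6 nt makes trimming ambiguous")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _random_mature(rng: np.random.Generator) -> str:
    lengths = np.arange(18, 27)
    weights = np.array([1, 2, 3, 6, 14, 6, 3, 2, 1], dtype=float)
    length = int(rng.choice(lengths, p=weights / weights.sum()))
    seq = _random_seq(rng, length)
    if rng.random() < 0.4:  # 5'-U bias
        seq = "T" + seq[1:]
    return seq


def embed_hairpin(mature: str, seed: int, arm: str = "5p") -> str:
    """Build a precursor hosting ``mature`` on one arm of a stem-loop.

    The opposite arm is the reverse complement of the mature with at most
    two substitutions (at least 16 bases stay exactly complementary); the
    arms are separated by an 8-15 nt loop and padded with short random
    flanks.  The result folds into a hairpin accepted by
    :func:`savmir.annot.validate_hairpin` under default settings.
    """
    mature = check_alphabet(mature, allow_n=False)
    if not 18 <= len(mature) <= 26:
        raise ValueError(f"mature length {len(mature)} outside 18-26")
    rng = np.random.default_rng(seed)
    partner = list(revcomp(mature))
    n_mut = int(rng.integers(0, min(2, len(mature) - 16) + 1))
    # mutate interior positions only, keeping terminal stacks intact
    for pos in rng.choice(np.arange(2, len(partner) - 2), size=n_mut, replace=False):
        alternatives = [b for b in "ACGT" if b != partner[pos]]
        partner[pos] = str(rng.choice(alternatives))
    loop = _random_seq(rng, int(rng.integers(8, 16)))
    flank5 = _random_seq(rng, int(rng.integers(4, 9)))
    flank3 = _random_seq(rng, int(rng.integers(4, 9)))
    if arm == "5p":
        return flank5 + mature + loop + "".join(partner) + flank3
    return flank5 + "".join(partner) + loop + mature + flank3


def make_reference(seed: int, n_mirnas: int, genome_length: int = 50_000, *,
                   conserved_fraction: float = 0.5, n_ncrna: int = 8,
                   n_repeats: int = 5) -> ReferenceBundle:
    """Generate a self-consistent reference bundle.

    Deterministic for a fixed seed.  Raises ``ValueError`` when the genome
    cannot host all precursors without overlap.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    rng = np.random.default_rng(seed)

    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    mature_precursor: dict[str, str] = {}
    conserved: dict[str, bool] = {}
    for i in range(n_mirnas):
        mid = f"syn-miR-{i + 1}"
        pid = f"syn-mir-{i + 1}"
        while True:
            mature = _random_mature(rng)
            if mature not in matures.values():
                break
        arm = "5p" if i % 2 == 0 else "3p"
        prec = embed_hairpin(mature, int(rng.integers(0, 2**31)), arm=arm)
        matures[mid] = mature
        precursors[pid] = prec
        mature_precursor[mid] = pid
        conserved[mid] = rng.random() < conserved_fraction

    # place precursors non-overlapping in a random background genome
    total_prec = sum(len(p) for p in precursors.values())
    gap = 20
    if total_prec + gap * (n_mirnas + 1) > genome_length:
        raise ValueError(
            f"genome_length {genome_length} too small for {n_mirnas} precursors")
    genome = list(_random_seq(rng, genome_length))
    cursor = gap
    for pid, prec in precursors.items():
        genome[cursor:cursor + len(prec)] = list(prec)
        cursor += len(prec) + gap
    genome_seq = "".join(genome)
    genome_d = {"chr1": genome_seq}

    # decoys, rejected until no 18-26 nt window sits within 1 mismatch of a mature
    def _clean_decoy(length: int) -> str:
        for _ in range(50):
            cand = _random_seq(rng, length)
            if not _decoy_clashes(cand, matures.values()):
                return cand
        raise RuntimeError("could not generate a clash-free decoy")

    ncrna = {f"ncrna-{i + 1}": _clean_decoy(int(rng.integers(70, 160)))
             for i in range(n_ncrna)}
    repeats = {f"repeat-{i + 1}": _clean_decoy(int(rng.integers(100, 300)))
               for i in range(n_repeats)}

    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n_mirnas)
    truth = pd.DataFrame({"mirna_id": list(matures), "abundance": abundance})
    return ReferenceBundle(genome_d, precursors, matures, mature_precursor,
                           conserved, ncrna, repeats, truth)


def _decoy_clashes(decoy: str, matures) -> bool:
    for mature in matures:
        L = len(mature)
        for i in range(len(decoy) - L + 1):
            window = decoy[i:i + L]
            if sum(a != b for a, b in zip(window, mature)) <= 1:
                return True
    return False


def _quality_string(rng: np.random.Generator, length: int, mean: float,
                    sd: float) -> str:
    q = np.clip(np.rint(rng.normal(mean, sd, size=length)), 2, 41).astype(int)
    return "".join(chr(33 + v) for v in q)


_DEGENERATE_TEMPLATES = (
    "ACACACACACACACACACAC",      # dimer x10
    "GTCGTCGTCGTCGTCGTC",        # trimer x6
    "ACGTACGTACGTACGTACGT",      # tetramer x5
    "TGCAAAAAAATCGATCGATCG",     # A run of 7
    "TGCACCCCCCCCTAGATCGAT",     # C run of 8
    "ATCGGGGGGCATTAGCATCGA",     # G run of 6
    "AGCTTTTTTTACGATCGATCA",     # T run of 7
    "ANCGTNACGTACGTACGTAC",      # two N
)


def _make_read(rng: np.random.Generator, insert: str, adapter3: str,
               mean: float, sd: float, with_adapter: bool = True
               ) -> tuple[str, str]:
    if with_adapter:
        full = insert + adapter3 + POST_ADAPTER_FILL * 2
    else:
        full = insert + _random_seq(rng, READ_LENGTH)
    seq = full[:READ_LENGTH]
    return seq, _quality_string(rng, len(seq), mean, sd)


def simulate_libraries(ref: ReferenceBundle, spec: LibrarySpec,
                       fc_map: Mapping[str, float],
                       outdir: Optional[Path] = None,
                       condition_names: tuple[str, str] = ("cond1", "cond2"),
                       ) -> tuple[pd.DataFrame, Optional[tuple[Path, Path, Path]]]:
    """Simulate two FASTQ libraries with per-mature fold changes.

    ``fc_map`` gives the condition-2 / condition-1 expected-count ratio per
    mature id (missing ids default to 1.0; all values must be > 0).  Both
    libraries draw their mature counts from a multinomial scaled so that the
    expected count ratio equals the requested fold change exactly; the
    probability mass freed in the lower-mass library is emitted as extra
    background genomic reads (labelled ``slack``), keeping the record count
    at ``depth`` exactly.  Returns the realized truth table and, when
    ``outdir`` is given, the paths of the two FASTQ files and the truth TSV.
    """
    for mid, fc in fc_map.items():
        if fc <= 0:
            raise ValueError(f"fold change for {mid} must be > 0")
        if mid not in ref.matures:
            raise ValueError(f"fc_map id {mid} not in reference bundle")
    rng = np.random.default_rng(spec.seed)
    ids = list(ref.matures)
    base = ref.truth.set_index("mirna_id").loc[ids, "abundance"].to_numpy()
    fcs = np.array([float(fc_map.get(mid, 1.0)) for mid in ids])

    n_contam = int(round(spec.depth * spec.contamination_fraction))
    n_degen = int(round(spec.depth * spec.degenerate_fraction))
    n_pirna = int(round(spec.depth * spec.pirna_fraction))
    n_junk = int(round(spec.depth * spec.no_adapter_fraction))
    n_real = spec.depth - n_contam - n_degen - n_pirna - n_junk

    genome_seq = next(iter(ref.genome.values()))
    decoy_pool = list(ref.ncrna_decoys.values()) + list(ref.repeat_decoys.values())

    # scale both conditions by the larger total mass so expected count
    # ratios equal fc exactly; the shortfall becomes background slack reads
    w1 = base / base.sum()
    w2 = base * fcs / base.sum()
    scale = 1.0 / max(w1.sum(), w2.sum())
    realized = {}
    fastq: dict[str, list[str]] = {}
    for cond, weights in zip(condition_names, (w1, w2)):
        probs = weights * scale
        if n_real > 0:
            pvals = np.append(probs, max(0.0, 1.0 - probs.sum()))
            counts = rng.multinomial(n_real, pvals / pvals.sum())
            counts, n_slack = counts[:-1], int(counts[-1])
        else:
            counts, n_slack = np.zeros(len(ids), int), 0
        realized[cond] = counts
        records: list[tuple[str, str, str]] = []
        for _ in range(n_slack):
            ln = int(rng.integers(27, 29))
            start = int(rng.integers(0, len(genome_seq) - ln + 1))
            seq, qual = _make_read(rng, genome_seq[start:start + ln],
                                   spec.adapter3, spec.quality_mean, spec.quality_sd)
            records.append(("slack", seq, qual))
        for mid, c in zip(ids, counts):
            insert = ref.matures[mid]
            for _ in range(c):
                seq, qual = _make_read(rng, insert, spec.adapter3,
                                       spec.quality_mean, spec.quality_sd)
                records.append((mid, seq, qual))
        for k in range(n_contam):
            decoy = decoy_pool[int(rng.integers(len(decoy_pool)))]
            ln = int(rng.integers(16, min(31, len(decoy) + 1)))
            start = int(rng.integers(0, len(decoy) - ln + 1))
            seq, qual = _make_read(rng, decoy[start:start + ln], spec.adapter3,
                                   spec.quality_mean, spec.quality_sd)
            records.append(("contam", seq, qual))
        for k in range(n_degen):
            insert = _DEGENERATE_TEMPLATES[k % len(_DEGENERATE_TEMPLATES)]
            seq, qual = _make_read(rng, insert, spec.adapter3,
                                   spec.quality_mean, spec.quality_sd)
            records.append(("degen", seq, qual))
        for _ in range(n_pirna):
            ln = int(rng.integers(27, 29))
            start = int(rng.integers(0, len(genome_seq) - ln + 1))
            seq, qual = _make_read(rng, genome_seq[start:start + ln],
                                   spec.adapter3, spec.quality_mean, spec.quality_sd)
            records.append(("pirna", seq, qual))
        for _ in range(n_junk):
            seq, qual = _make_read(rng, "", spec.adapter3, spec.quality_mean,
                                   spec.quality_sd, with_adapter=False)
            records.append(("junk", seq, qual))
        order = rng.permutation(len(records))
        fastq[cond] = [
            f"@{cond}_{i + 1} src={records[j][0]}\n{records[j][1]}\n+\n{records[j][2]}\n"
            for i, j in enumerate(order)]

    c1, c2 = condition_names
    truth = pd.DataFrame({
        "mirna_id": ids,
        "cond1_count": realized[c1],
        "cond2_count": realized[c2],
        "true_fc": fcs,
    })
    paths = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p1, p2 = outdir / f"{c1}.fastq", outdir / f"{c2}.fastq"
        p1.write_text("".join(fastq[c1]))
        p2.write_text("".join(fastq[c2]))
        pt = outdir / "truth.tsv"
        truth.to_csv(pt, sep="\t", index=False)
        paths = (p1, p2, pt)
    return truth, paths


def write_reference_fastas(ref: ReferenceBundle, outdir: Path) -> dict[str, Path]:
    """Write the bundle's sequence sets as FASTA files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, seqs in [("genome", ref.genome), ("precursors", ref.precursors),
                       ("matures", ref.matures), ("ncrna", ref.ncrna_decoys),
                       ("repeats", ref.repeat_decoys)]:
        path = outdir / f"{name}.fa"
        with open(path, "w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n{seq}\n")
        paths[name] = path
    return paths


# self-check used by tests: every generated precursor must validate
def check_bundle(ref: ReferenceBundle) -> bool:
    for mid, mature in ref.matures.items():
        prec = ref.precursors[ref.mature_precursor[mid]]
        start = prec.find(mature)
        if start < 0:
            return False
        fold = fold_hairpin(prec)
        if not validate_hairpin(fold, (start, start + len(mature))).passed:
            return False
    return True
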