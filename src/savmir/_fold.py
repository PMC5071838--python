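"""Single-hairpin secondary-structure engine.

A deliberately small nearest-neighbour model: Watson-Crick and GU pairs
with a stacking bonus, a hairpin-loop penalty linear in loop length, and a
per-nucleotide penalty for interior loops / bulges.  The dynamic program is
restricted to single stem-loops (no multiloops), which is the only structure
class the precursor-validation step reasons about.  The backend is pluggable
at the :mod:`savmir.annot` level; this module is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from savmir._seq import check_alphabet

# kcal/mol; negative = stabilising
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}
STACK_BONUS = -0.5          # contiguous helix extension
HAIRPIN_LOOP_BASE = 1.5     # closing penalty
HAIRPIN_LOOP_PER_NT = 0.1
INTERIOR_PER_NT = 0.4       # bulge / interior loop, per unpaired nt
MIN_LOOP = 3                # steric minimum for a hairpin loop
MAX_INTERIOR = 6            # max unpaired nt per side between stacked pairs


@dataclass(frozen=True)
class HairpinFold:
    """MFE single-hairpin structure of a precursor candidate."""

    sequence: str
    structure: str          # dot-bracket, same length as sequence
    mfe: float              # kcal/mol, <= 0
    stem_pairs: int
    loop_length: int        # unpaired span inside the innermost pair (0 if unpaired)

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as (i, j) index tuples, outermost first."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for k, c in enumerate(self.structure):
            if c == "(":
                stack.append(k)
            elif c == ")":
                out.append((stack.pop(), k))
        return sorted(out)


def _pair_energy(a: str, b: str) -> Optional[float]:
    return PAIR_ENERGY.get((a, b))


def fold_hairpin(precursor: str) -> HairpinFold:
    """Minimum-free-energy single stem-loop structure of ``precursor``.

    Parameters
    ----------
    precursor : str
        Nucleotide sequence, 40-200 nt, ACGT/ACGU alphabet.

    Returns
    -------
    HairpinFold
        Dot-bracket structure, MFE (0 for a structure with no pairs),
        stem pair count and loop length.
    """
    seq = check_alphabet(precursor, allow_n=False)
    n = len(seq)
    if not 40 <= n <= 200:
        raise ValueError(f"precursor length {n} outside supported range 40-200")

    INF = float("inf")
    # H[(i, j)] = best energy of a single hairpin on [i, j] with i.j paired
    H: dict[tuple[int, int], float] = {}
    # traceback: inner pair (p, q) or None for the closing hairpin loop
    back: dict[tuple[int, int], Optional[tuple[int, int]]] = {}

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pe = _pair_energy(seq[i], seq[j])
            if pe is None:
                continue
            best = pe + HAIRPIN_LOOP_BASE + HAIRPIN_LOOP_PER_NT * (j - i - 1)
            choice: Optional[tuple[int, int]] = None
            for p in range(i + 1, min(i + 2 + MAX_INTERIOR, j)):
                for q in range(max(p + MIN_LOOP + 1, j - 1 - MAX_INTERIOR), j):
                    inner = H.get((p, q))
                    if inner is None:
                        continue
                    gap = (p - i - 1) + (j - q - 1)
                    e = pe + inner + (STACK_BONUS if gap == 0 else INTERIOR_PER_NT * gap)
                    if e < best:
                        best, choice = e, (p, q)
            if best < INF:
                H[(i, j)] = best
                back[(i, j)] = choice

    if not H:
        return HairpinFold(seq, "." * n, 0.0, 0, 0)

    (i0, j0), mfe = min(H.items(), key=lambda kv: (kv[1], kv[0]))
    if mfe >= 0.0:
        return HairpinFold(seq, "." * n, 0.0, 0, 0)

    struct = ["."] * n
    pairs = 0
    node: Optional[tuple[int, int]] = (i0, j0)
    loop_len = 0
    while node is not None:
        i, j = node
        struct[i], struct[j] = "(", ")"
        pairs += 1
        loop_len = j - i - 1
        node = back[node]
    return HairpinFold(seq, "".join(struct), round(mfe, 2), pairs, loop_len)
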