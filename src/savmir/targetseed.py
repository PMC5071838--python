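"""Canonical seed-match target prediction and term over-representation.

Site classes on the mRNA (5'->3'), for a miRNA with 1-based positions:

* 7mer-m8: exact Watson-Crick complement of miRNA positions 2-8.
* 7mer-A1: complement of positions 2-7 followed by an A on the mRNA
  (opposite miRNA position 1, regardless of that base's identity).
* 8mer: both at once - the position 2-8 complement followed by an A.

Each genomic position is reported once at its strongest class
(8mer > 7mer-m8 > 7mer-A1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from savmir._seq import check_alphabet, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int      # 0-based on the mRNA
    site_type: str


def site_scan(mirna_id: str, mature: str, transcript_id: str, utr: str
              ) -> list[TargetSite]:
    """All canonical seed sites of one miRNA in one UTR.

    ``start`` is the 0-based position of the site's 5'-most base on the
    mRNA: the m8-complement base for 8mer/7mer-m8 sites, the seed(2-7)
    complement for 7mer-A1 sites.
    """
    mature = check_alphabet(mature, allow_n=False)
    if len(mature) < 8:
        raise ValueError("mature sequence shorter than 8 nt")
    utr = check_alphabet(utr)
    match_m8 = revcomp(mature[1:8])   # 7 nt, complement of positions 2-8
    match_a1 = revcomp(mature[1:7])   # 6 nt, complement of positions 2-7
    comp_m8 = match_m8[0]             # complement of miRNA position 8
    sites: list[TargetSite] = []
    # 7mer-m8 frame: 7-mer complement at i, A-check at i+7
    i = utr.find(match_m8)
    while i != -1:
        stype = "8mer" if i + 7 < len(utr) and utr[i + 7] == "A" else "7mer-m8"
        sites.append(TargetSite(mirna_id, transcript_id, i, stype))
        i = utr.find(match_m8, i + 1)
    # 7mer-A1 frame: 6-mer complement at i with A at i+6, not already an 8mer
    i = utr.find(match_a1)
    while i != -1:
        if i + 6 < len(utr) and utr[i + 6] == "A":
            if not (i > 0 and utr[i - 1] == comp_m8):
                sites.append(TargetSite(mirna_id, transcript_id, i, "7mer-A1"))
        i = utr.find(match_a1, i + 1)
    sites.sort(key=lambda s: (s.start, s.site_type))
    return sites


def scan_all(matures: dict[str, str], utrs: dict[str, str]) -> list[TargetSite]:
    """Cross-scan every miRNA against every UTR."""
    out: list[TargetSite] = []
    for mid in sorted(matures):
        for tid in sorted(utrs):
            out.extend(site_scan(mid, matures[mid], tid, utrs[tid]))
    return out


def aggregate_targets(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """Unique (miRNA, transcript) pairs with per-class site tallies."""
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for s in sites:
        tally = rows.setdefault((s.mirna_id, s.transcript_id),
                                {t: 0 for t in SITE_TYPES})
        tally[s.site_type] += 1
    records = [{"mirna_id": m, "transcript_id": t, **tally,
                "n_sites": sum(tally.values())}
               for (m, t), tally in sorted(rows.items())]
    return pd.DataFrame(records, columns=["mirna_id", "transcript_id",
                                          *SITE_TYPES, "n_sites"])


def hypergeom_enrich(target_genes: Sequence[str], universe: Sequence[str],
                     term_map: dict[str, Sequence[str]], alpha: float = 0.001,
                     method: str = "bonferroni") -> pd.DataFrame:
    """Per-term one-sided hypergeometric over-representation test.

    ``term_map`` maps term id -> annotated gene ids.  P-values are the
    upper-tail probability of drawing at least the observed number of
    annotated genes when sampling ``len(target_genes)`` genes from the
    universe without replacement, corrected over the tested terms by
    Bonferroni (default) or Benjamini-Hochberg (``method="bh"``).
    """
    universe_set = set(universe)
    targets = set(target_genes)
    stray = targets - universe_set
    if stray:
        raise ValueError(f"target genes absent from universe: {sorted(stray)[:5]}")
    M, n = len(universe_set), len(targets)
    rows = []
    for term in sorted(term_map):
        annotated = set(term_map[term]) & universe_set
        K = len(annotated)
        k = len(annotated & targets)
        if K == 0 or n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "universe_count": K, "target_count": k, "p": p})
    table = pd.DataFrame(rows, columns=["term", "universe_count", "target_count", "p"])
    m = len(table)
    if m == 0:
        table["p_adj"] = []
        table["significant"] = []
        return table
    if method == "bonferroni":
        table["p_adj"] = (table["p"] * m).clip(upper=1.0)
    elif method == "bh":
        order = table["p"].rank(method="first")
        adj = (table["p"] * m / order).to_numpy()
        # enforce monotonicity from the largest p downward
        idx = table["p"].to_numpy().argsort()[::-1]
        running = 1.0
        for i in idx:
            running = min(running, adj[i])
            adj[i] = running
        table["p_adj"] = adj
    else:
        raise ValueError(f"unknown correction method {method!r}")
    table["significant"] = table["p_adj"] <= alpha
    return table
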