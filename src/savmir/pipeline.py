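"""End-to-end orchestration: simulate -> clean -> annotate -> diffexp -> targets.

A run is driven by a single :class:`RunConfig`, writes every intermediate
artifact under the output directory, and emits a JSON manifest with file
hashes, parameters and the per-stage read ledger.  Re-running an identical
config reproduces identical non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from savmir import annot, diffexp, readproc, synthio, targetseed

log = logging.getLogger("savmir")


@dataclass
class RunConfig:
    outdir: str = "savmir_run"
    seed: int = 1

    # simulation (used when no input FASTQs are given)
    n_mirnas: int = 100
    depth: int = 50_000
    genome_length: int = 80_000
    n_de: int = 20
    de_fc: float = 4.0
    contamination_fraction: float = 0.05
    degenerate_fraction: float = 0.02
    pirna_fraction: float = 0.05
    no_adapter_fraction: float = 0.01

    # alternatively: user-supplied inputs
    fastq_wl: Optional[str] = None
    fastq_w: Optional[str] = None
    mature_fasta: Optional[str] = None
    precursor_fasta: Optional[str] = None
    genome_fasta: Optional[str] = None
    ncrna_fasta: Optional[str] = None
    repeat_fasta: Optional[str] = None
    utr_fasta: Optional[str] = None
    term_map_tsv: Optional[str] = None

    # thresholds
    adapter3: str = synthio.DEFAULT_ADAPTER3
    min_overlap: int = 6
    min_len: int = 15
    max_len: int = 30
    min_qual: float = 20.0
    min_tag_count: int = 5
    fold_check: bool = True
    alpha: float = 0.05
    fc_min: float = 1.5
    enrich_alpha: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if not 0 <= self.alpha <= 1 or not 0 <= self.enrich_alpha <= 1:
            raise ValueError("alpha thresholds must be in [0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": [], "files": {}}

    def register(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    # ---- stage 1: inputs (simulated or user-supplied) -------------------
    simulated = config.fastq_wl is None
    if simulated:
        log.info("simulating references and libraries (seed=%d)", config.seed)
        ref = synthio.make_reference(config.seed, config.n_mirnas,
                                     config.genome_length)
        mature_ids = list(ref.matures)
        fc_map = {mid: (config.de_fc if i % 2 == 0 else 1.0 / config.de_fc)
                  for i, mid in enumerate(mature_ids[:config.n_de])}
        spec = synthio.LibrarySpec(
            seed=config.seed + 1, depth=config.depth, adapter3=config.adapter3,
            contamination_fraction=config.contamination_fraction,
            degenerate_fraction=config.degenerate_fraction,
            pirna_fraction=config.pirna_fraction,
            no_adapter_fraction=config.no_adapter_fraction)
        truth, paths = synthio.simulate_libraries(
            ref, spec, fc_map, out / "sim", condition_names=("wl", "w"))
        ref_paths = synthio.write_reference_fastas(ref, out / "sim" / "ref")
        fastq_wl, fastq_w = paths[0], paths[1]
        for p in [*paths, *ref_paths.values()]:
            register(Path(p))
        matures, precursors = ref.matures, ref.precursors
        genome, ncrna, repeats = ref.genome, ref.ncrna_decoys, ref.repeat_decoys
        manifest["stages"].append({"stage": "simulate", "depth": config.depth,
                                   "n_mirnas": config.n_mirnas,
                                   "n_spiked": len(fc_map)})
    else:
        for name in ("fastq_w", "mature_fasta", "genome_fasta"):
            if getattr(config, name) is None:
                raise ValueError(f"config.{name} is required when fastq_wl is set")
        fastq_wl, fastq_w = Path(config.fastq_wl), Path(config.fastq_w)
        matures = _read_fasta(config.mature_fasta)
        precursors = _read_fasta(config.precursor_fasta) if config.precursor_fasta else {}
        genome = _read_fasta(config.genome_fasta)
        ncrna = _read_fasta(config.ncrna_fasta) if config.ncrna_fasta else {}
        repeats = _read_fasta(config.repeat_fasta) if config.repeat_fasta else {}

    # ---- stage 2: cleaning ---------------------------------------------
    clean = {}
    ledgers = {}
    for lib, path in (("wl", fastq_wl), ("w", fastq_w)):
        reads = readproc.read_fastq(path)
        clean[lib], ledgers[lib] = readproc.clean_library(
            reads, config.adapter3, min_overlap=config.min_overlap,
            min_len=config.min_len, max_len=config.max_len,
            min_qual=config.min_qual)
        if not ledgers[lib].conserved():
            raise RuntimeError(f"clean stage ledger not conserved for library {lib}")
        log.info("library %s: %d reads in, %d survivors", lib,
                 ledgers[lib].input_reads, ledgers[lib].survivors)
    manifest["stages"].append({
        "stage": "clean",
        "ledger": {lib: {"input_reads": lg.input_reads,
                         "removed": dict(sorted(lg.removed.items())),
                         "survivors": lg.survivors}
                   for lib, lg in ledgers.items()}})

    # ---- stage 3: collapse + decoy subtraction --------------------------
    tags = readproc.collapse(clean)
    n_collapsed = sum(t.total for t in tags)
    removed_decoy = {}
    for kind, seqs in (("ncrna", ncrna), ("repeat", repeats)):
        if not seqs:
            continue
        index = annot.ReferenceIndex(kind, seqs, kind)
        tags, removed = annot.subtract(tags, index)
        removed_decoy[kind] = sum(t.total for t in removed)
    readproc.write_tags_fasta(tags, out / "tags.fa")
    readproc.write_count_matrix(tags, out / "tag_counts.tsv")
    register(out / "tags.fa")
    register(out / "tag_counts.tsv")
    manifest["stages"].append({"stage": "subtract", "collapsed_reads": n_collapsed,
                               "removed": removed_decoy,
                               "surviving_reads": sum(t.total for t in tags)})

    # ---- stage 4: annotation / per-miRNA counting -----------------------
    mirbase_seqs = {f"mat:{k}": v for k, v in matures.items()}
    mirbase_seqs.update({f"pre:{k}": v for k, v in precursors.items()})
    mirbase = annot.ReferenceIndex("mirbase", mirbase_seqs, "mature")
    genome_idx = annot.ReferenceIndex("genome", genome, "genome")
    exact = {seq: mid for mid, seq in matures.items()}

    counts: dict[str, list[int]] = {}
    annotations: list[annot.MirnaAnnotation] = []
    class_tally = {"conserved": 0, "semi-conserved": 0, "novel": 0,
                   "unclassified": 0, "low_count": 0}
    novel_i = 0
    for tag in tags:
        mid = exact.get(tag.seq)
        if mid is None:
            hits = annot.match_le1(tag.seq, mirbase)
            mat_hits = [h for h in hits if h.ref_id.startswith("mat:")]
            if mat_hits:
                mid = mat_hits[0].ref_id[4:]
        if mid is not None:
            row = counts.setdefault(mid, [0, 0])
            row[0] += tag.counts.get("wl", 0)
            row[1] += tag.counts.get("w", 0)
            continue
        if tag.total < config.min_tag_count:
            class_tally["low_count"] += 1
            continue
        cls = annot.classify(tag.seq, mirbase, genome_idx,
                             fold_check=config.fold_check)
        class_tally[cls.label] += 1
        if cls.label == "novel":
            novel_i += 1
            nid = f"PC-{novel_i}"
            counts.setdefault(nid, [0, 0])
            counts[nid][0] += tag.counts.get("wl", 0)
            counts[nid][1] += tag.counts.get("w", 0)
            annotations.append(annot.MirnaAnnotation(
                nid, tag.seq, "novel", annot.extract_seed(tag.seq),
                genome_hits=cls.genome_hits))
    for mid, seq in matures.items():
        if mid in counts:
            annotations.append(annot.MirnaAnnotation(
                mid, seq, "conserved", annot.extract_seed(seq),
                precursor_id=f"pre:{mid}"))
    families = annot.assign_families(annotations)
    families.to_csv(out / "families.tsv", sep="\t", index=False)
    register(out / "families.tsv")
    manifest["stages"].append({"stage": "annotate", "classes": class_tally,
                               "n_quantified": len(counts)})

    # ---- stage 5: differential expression -------------------------------
    matrix = pd.DataFrame(
        [(mid, c[0], c[1]) for mid, c in sorted(counts.items())],
        columns=["mirna_id", "count_wl", "count_w"])
    totals = (sum(t.counts.get("wl", 0) for t in tags),
              sum(t.counts.get("w", 0) for t in tags))
    matrix.to_csv(out / "mirna_counts.tsv", sep="\t", index=False)
    register(out / "mirna_counts.tsv")
    de = diffexp.run(matrix, totals, alpha=config.alpha, fc_min=config.fc_min)
    de.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    register(out / "de_results.tsv")
    called = de[de["call"] != "ns"]
    manifest["stages"].append({
        "stage": "diffexp", "totals": list(totals), "n_tested": len(de),
        "n_called": int(len(called)),
        "n_up": int((called["call"] == "up").sum()),
        "n_down": int((called["call"] == "down").sum())})

    # ---- stage 6: target prediction (optional) --------------------------
    if config.utr_fasta:
        utrs = _read_fasta(config.utr_fasta)
        de_matures = {a.id: a.mature_seq for a in annotations
                      if a.id in set(called["mirna_id"])}
        sites = targetseed.scan_all(de_matures, utrs)
        targets = targetseed.aggregate_targets(sites)
        targets.to_csv(out / "targets.tsv", sep="\t", index=False)
        register(out / "targets.tsv")
        stage: dict = {"stage": "targets", "n_sites": len(sites),
                       "n_pairs": len(targets)}
        if config.term_map_tsv:
            terms_df = pd.read_csv(config.term_map_tsv, sep="\t")
            term_map: dict[str, list[str]] = {}
            for term, gene in zip(terms_df.iloc[:, 0], terms_df.iloc[:, 1]):
                term_map.setdefault(str(term), []).append(str(gene))
            enrich = targetseed.hypergeom_enrich(
                sorted(set(targets["transcript_id"])), sorted(utrs),
                term_map, alpha=config.enrich_alpha)
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            register(out / "enrichment.tsv")
            stage["n_terms"] = len(enrich)
        manifest["stages"].append(stage)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", manifest_path)
    return manifest
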