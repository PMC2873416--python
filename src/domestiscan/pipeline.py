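"""End-to-end domestication-selection scan.

Chains the per-module analyses into one reproducible report: per-locus
per-population diversity statistics, a sliding-window scan, the HKA test
of a candidate locus against a neutral reference, Ka/Ks with molecular-
clock dating for a paralog pair, haplotype typing, a near-fixed-difference
scan between cultivars and wild accessions, and gene-tree vs genome-tree
incongruence.  Any stage failure is recorded and the remaining stages are
still attempted; the report is deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .diversity import (fixed_differences, haplotype_classify, locus_stats,
                        sliding_windows)
from .kaks import duplication_time, kaks_pair
from .neutrality import hka_test, polymorphism_divergence_counts
from .phylo import (distance_matrix, monophyly_check, neighbor_joining,
                    robinson_foulds)
from .seqio import (GenotypeMatrix, LocusAlignment, PopulationMap,
                    read_fasta_alignment, write_tsv_report)

log = logging.getLogger("domestiscan.pipeline")

CULTIVATED = ("japonica", "indica")


@dataclass
class ScanConfig:
    """Inputs and thresholds for one full scan."""

    loci: list[str]                 # FASTA alignment paths
    popmap: str
    out_dir: str
    seed: int = 0
    candidate_locus: str | None = None   # defaults to first locus
    reference_locus: str | None = None   # HKA reference; defaults to last
    window: int = 500
    step: int = 100
    fixed_diff_threshold: float = 0.95
    homolog_min_identity: float = 0.6
    clock_rate: float = 6.5e-9
    kaks_pair_fasta: str | None = None   # 2-record in-frame FASTA
    genotype_matrix: str | None = None   # TSV for the genome tree

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScanReport:
    config_digest: str
    seed: int
    version: str
    stats: list = field(default_factory=list)          # LocusStats
    windows: dict = field(default_factory=dict)        # locus -> WindowTrack
    hka: dict = field(default_factory=dict)            # method -> HkaResult
    kaks: object | None = None                         # CodonPair
    clock: object | None = None                        # ClockEstimate
    haplotypes: dict = field(default_factory=dict)     # locus -> types table
    fixed_diffs: dict = field(default_factory=dict)    # locus -> list
    trees: dict = field(default_factory=dict)          # name -> newick str
    rf_distance: int | None = None
    monophyly: dict = field(default_factory=dict)      # tree -> bool
    failures: dict = field(default_factory=dict)       # stage -> message


def _stage(report: ScanReport, name: str):
    """Run a stage, recording failure without aborting the scan."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.warning("stage %s failed after %.2fs: %s", name, dt, exc)
                report.failures[name] = f"{exc_type.__name__}: {exc}"
                return True
            log.info("stage %s done in %.2fs", name, dt)
            return False
    return _Ctx()


def run_scan(cfg: ScanConfig) -> ScanReport:
    """Execute the full scan and write report.json, stats.tsv, windows.tsv
    and trees/*.nwk under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    popmap = PopulationMap.read_tsv(cfg.popmap)
    alignments = {
        aln.locus_id: aln
        for aln in (read_fasta_alignment(p, popmap) for p in cfg.loci)
    }
    report = ScanReport(config_digest=cfg.digest(), seed=cfg.seed,
                        version=__version__)
    candidate = cfg.candidate_locus or list(alignments)[0]
    reference = cfg.reference_locus or list(alignments)[-1]

    populations = sorted({p for p in popmap.assignments.values()
                          if p != "outgroup"})

    with _stage(report, "diversity"):
        for locus_id, aln in alignments.items():
            for pop in populations:
                try:
                    report.stats.append(locus_stats(aln, pop))
                except Exception as exc:
                    report.failures[f"diversity:{locus_id}:{pop}"] = str(exc)

    with _stage(report, "windows"):
        aln = alignments[candidate]
        for pop in populations:
            track = sliding_windows(aln, pop, cfg.window, cfg.step)
            report.windows[f"{candidate}:{pop}"] = track

    with _stage(report, "hka"):
        # cultivar polymorphism vs outgroup divergence, per convention
        def _cultivated_plus_outgroup(aln):
            keep = [s for s in aln.samples
                    if aln.populations[s] in CULTIVATED + ("outgroup",)]
            return aln.subset(samples=keep)

        cand_counts = polymorphism_divergence_counts(
            _cultivated_plus_outgroup(alignments[candidate]))
        ref_counts = polymorphism_divergence_counts(
            _cultivated_plus_outgroup(alignments[reference]))
        for method in ("hka1987", "contingency"):
            report.hka[method] = hka_test(cand_counts, ref_counts,
                                          method=method)

    if cfg.kaks_pair_fasta:
        with _stage(report, "kaks"):
            from Bio import SeqIO
            recs = list(SeqIO.parse(cfg.kaks_pair_fasta, "fasta"))
            pair = kaks_pair(str(recs[0].seq), str(recs[1].seq))
            report.kaks = pair
            if pair.Ks not in (0.0, float("inf")):
                report.clock = duplication_time(pair.Ks, cfg.clock_rate)

    with _stage(report, "haplotypes"):
        for locus_id, aln in alignments.items():
            sub = aln.subset(populations)
            types, hap_div = haplotype_classify(sub)
            report.haplotypes[locus_id] = {
                "n_types": len(types), "hap_div": hap_div,
                "types": {str(k): v for k, v in types.items()},
            }

    with _stage(report, "fixed_differences"):
        for locus_id, aln in alignments.items():
            pops = set(aln.populations.values())
            if not set(CULTIVATED) & pops or "wild" not in pops:
                continue
            merged = LocusAlignment(
                locus_id=aln.locus_id,
                samples=list(aln.samples),
                populations={s: ("cultivated" if p in CULTIVATED else p)
                             for s, p in aln.populations.items()},
                sequences=list(aln.sequences),
                coordinate_offset=aln.coordinate_offset)
            report.fixed_diffs[locus_id] = fixed_differences(
                merged, "cultivated", "wild", cfg.fixed_diff_threshold)

    with _stage(report, "trees"):
        aln = alignments[candidate].subset(populations)
        gene_tree = neighbor_joining(distance_matrix(aln, "jc"))
        report.trees["gene"] = str(gene_tree).strip()
        cultivars = {s for s, p in aln.populations.items()
                     if p in CULTIVATED}
        report.monophyly["gene"] = monophyly_check(gene_tree, cultivars)
        if cfg.genotype_matrix:
            gm = GenotypeMatrix.read_tsv(cfg.genotype_matrix)
            genome_tree = neighbor_joining(
                distance_matrix(gm, "allele_sharing"))
            report.trees["genome"] = str(genome_tree).strip()
            report.monophyly["genome"] = monophyly_check(
                genome_tree, cultivars & set(gm.samples))
            report.rf_distance = robinson_foulds(
                gene_tree.shear(sorted(set(gm.samples))), genome_tree)

    _write_outputs(report, out)
    return report


def _write_outputs(report: ScanReport, out: Path) -> None:
    write_tsv_report(report.stats, out / "stats.tsv")
    with open(out / "windows.tsv", "w") as fh:
        fh.write("locus\tpopulation\tstart\tend\tpi\ttheta_w\ttajima_d\tS\n")
        for key, track in report.windows.items():
            for start, end, st in track.windows:
                d = "NA" if st.tajima_d is None else f"{st.tajima_d:.6f}"
                fh.write(f"{track.locus_id}\t{track.population}\t{start}\t"
                         f"{end}\t{st.pi:.6f}\t{st.theta_w:.6f}\t{d}\t"
                         f"{st.S}\n")
    trees_dir = out / "trees"
    trees_dir.mkdir(exist_ok=True)
    for name, newick in report.trees.items():
        (trees_dir / f"{name}.nwk").write_text(newick + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    """Recursively convert dataclasses / numpy scalars for JSON output."""
    import numpy as np
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and obj in (float("inf"), float("-inf")):
        return "saturated"
    return obj
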