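"""End-to-end orchestration: bait -> recruit -> bin -> assemble -> decode.

Stages run in order, each writing its artifacts to the output directory
and recording completion in ``status.json``; a rerun with an identical
configuration resumes after the last completed stage.  The final report
mirrors the summary-table shape of targeted minisatellite assembly:
reference and assembly copy numbers, assembly-to-reference identity, and
in-silico PCR product sizes, plus read accounting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .align import AlignScoring, align_pair
from .array_decoder import (VariantTable, compare_alleles,
                            decode_allele, render_comparison)
from .assembler import Contig, assemble_and_select
from .insilico_pcr import (Bait, PrimerPair, detect_and_mask_tandem_repeats,
                           extract_bait, write_annotations_bed,
                           write_bait_fasta)
from .recruitment import build_score_bins, classify_read, recruit
from . import io as mio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters (serializable to YAML)."""

    reference: str = ""
    reads: str = ""
    variant_table: str = ""
    outdir: str = "mvrasm_out"
    primers: str = ""            # TSV path; or give primer sequences
    primer_name: str | None = None
    forward_primer: str = ""
    reverse_primer: str = ""
    reference_record: str | None = None

    flank_length: int = 5000
    max_product: int = 50_000
    max_mismatches: int = 2
    three_prime_exact: int = 5

    min_period: int = 4
    max_period: int = 200
    min_copies: float = 3.0
    min_unit_identity: float = 75.0

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    seed_length: int = 13
    band_width: int = 100

    n_bins: int = 5
    min_anchor: int = 500
    min_overlap: int = 500
    min_overlap_identity: float = 70.0
    rounds: int = 2
    end_window: int = 10

    seed: int = 0
    resume: bool = True
    verbosity: str = "info"

    def scoring(self) -> AlignScoring:
        return AlignScoring(match=self.match, mismatch=self.mismatch,
                            gap_open=self.gap_open,
                            gap_extend=self.gap_extend,
                            seed_length=self.seed_length,
                            band_width=self.band_width)

    def primer_pair(self) -> PrimerPair:
        if self.forward_primer and self.reverse_primer:
            return PrimerPair(forward=self.forward_primer.upper(),
                              reverse=self.reverse_primer.upper(),
                              max_mismatches=self.max_mismatches,
                              three_prime_exact=self.three_prime_exact,
                              name=self.primer_name or "locus")
        if self.primers:
            return mio.read_primer_tsv(
                self.primers, self.primer_name,
                max_mismatches=self.max_mismatches,
                three_prime_exact=self.three_prime_exact)
        raise ValueError("no primers configured")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("resume", "verbosity")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Summary-table row plus read accounting and provenance."""

    locus: str
    copy_number_ref: float
    copy_number_assembly: float
    complete_units_assembly: int
    identity_assembly_vs_reference: float
    product_size_ref_kb: float
    product_size_assembly_kb: float | None
    n_recruited: int
    n_spanning: int
    n_contributing: int
    selected_bin: str
    code_string_assembly: str
    code_string_ref: str
    comparison: dict = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0
    version: str = __version__

    COLUMNS = ["locus", "copy_number_ref", "copy_number_assembly",
               "identity_assembly_vs_reference", "product_size_ref_kb",
               "product_size_assembly_kb", "n_recruited", "n_spanning",
               "n_contributing"]

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path, fmt: str = "json") -> None:
        fmt = fmt.lower()
        if fmt == "json":
            with open(path, "w") as fh:
                json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
        elif fmt == "tsv":
            vals = [str(getattr(self, c)) for c in self.COLUMNS]
            with open(path, "w") as fh:
                fh.write("\t".join(self.COLUMNS) + "\n")
                fh.write("\t".join(vals) + "\n")
        elif fmt == "text":
            widths = [max(len(c), len(str(getattr(self, c)))) + 2
                      for c in self.COLUMNS]
            with open(path, "w") as fh:
                fh.write("".join(c.ljust(w)
                                 for c, w in zip(self.COLUMNS, widths)) + "\n")
                fh.write("".join(str(getattr(self, c)).ljust(w)
                                 for c, w in zip(self.COLUMNS, widths)) + "\n")
        else:
            raise ValueError(f"unknown report format {fmt!r}")


def _bait_to_dict(bait: Bait) -> dict:
    return {
        "id": bait.id,
        "sequence": bait.sequence,
        "source_interval": list(bait.source_interval),
        "amplicon_interval": list(bait.amplicon_interval),
        "flank_length": bait.flank_length,
        "mask_intervals": [list(iv) for iv in bait.mask_intervals],
        "roi_interval": list(bait.roi_interval) if bait.roi_interval else None,
    }


def _bait_from_dict(d: dict) -> Bait:
    return Bait(id=d["id"], sequence=d["sequence"],
                source_interval=tuple(d["source_interval"]),
                amplicon_interval=tuple(d["amplicon_interval"]),
                flank_length=d["flank_length"],
                mask_intervals=[tuple(iv) for iv in d["mask_intervals"]],
                roi_interval=tuple(d["roi_interval"])
                if d["roi_interval"] else None)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute (or resume) the full pipeline; returns the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    status_path = out / "status.json"
    chash = config.config_hash()
    status = {"config_hash": chash, "stages": [], "failed": None}
    if config.resume and status_path.exists():
        try:
            prev = json.loads(status_path.read_text())
            if prev.get("config_hash") == chash:
                status["stages"] = [s for s in prev.get("stages", [])]
        except (json.JSONDecodeError, KeyError):
            pass
    config.to_yaml(out / "config.yaml")

    def done(stage: str) -> bool:
        return stage in status["stages"]

    def mark(stage: str) -> None:
        if stage not in status["stages"]:
            status["stages"].append(stage)
        status_path.write_text(json.dumps(status, indent=1) + "\n")

    def fail(stage: str, exc: Exception):
        status["failed"] = {"stage": stage, "error": str(exc)}
        status_path.write_text(json.dumps(status, indent=1) + "\n")
        return PipelineError(stage, str(exc))

    scoring = config.scoring()
    table = VariantTable.load_tsv(config.variant_table)

    # ---- stage: bait -----------------------------------------------------
    stage = "bait"
    bait_json = out / "bait.json"
    try:
        if done(stage) and bait_json.exists():
            bait = _bait_from_dict(json.loads(bait_json.read_text()))
        else:
            ref_id, reference = mio.read_reference(config.reference,
                                                   config.reference_record)
            pair = config.primer_pair()
            bait = extract_bait(reference, pair, config.flank_length,
                                config.max_product, reference_id=ref_id)
            bait, _ = detect_and_mask_tandem_repeats(
                bait, config.min_period, config.max_period,
                config.min_copies, config.min_unit_identity)
            write_bait_fasta(bait, out / "bait.fasta")
            write_annotations_bed(bait, out / "bait.bed")
            bait_json.write_text(json.dumps(_bait_to_dict(bait)) + "\n")
            logger.info("stage bait: amplicon %s, roi %s",
                        bait.amplicon_interval, bait.roi_interval)
            mark(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- stage: recruit --------------------------------------------------
    stage = "recruit"
    rec_json = out / "recruited.json"
    try:
        reads = mio.read_long_reads(config.reads)
        if done(stage) and rec_json.exists():
            payload = json.loads(rec_json.read_text())
            from .recruitment import LocalAlignment
            alignments = [LocalAlignment(
                read_id=r["read_id"],
                bait_interval=tuple(r["bait_interval"]),
                read_interval=tuple(r["read_interval"]),
                strand=r["strand"], score=r["score"],
                identity=r["identity"], edit_path=r["edit_path"])
                for r in payload]
            from .align import revcomp
            by_id = {rd.id: rd for rd in reads}
            oriented = {a.read_id: (by_id[a.read_id].sequence
                                    if a.strand == "+"
                                    else revcomp(by_id[a.read_id].sequence))
                        for a in alignments}
        else:
            alignments, oriented = recruit(bait, reads, scoring)
            if not alignments:
                raise ValueError("nothing recruited")
            rec_json.write_text(json.dumps([{
                "read_id": a.read_id,
                "bait_interval": list(a.bait_interval),
                "read_interval": list(a.read_interval),
                "strand": a.strand, "score": a.score,
                "identity": a.identity, "edit_path": a.edit_path}
                for a in alignments]) + "\n")
            logger.info("stage recruit: %d/%d reads recruited",
                        len(alignments), len(reads))
            mark(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- stage: bins -----------------------------------------------------
    stage = "bins"
    try:
        classes = {a.read_id: classify_read(a, bait, config.min_anchor)
                   for a in alignments}
        bins = build_score_bins(alignments, n_bins=config.n_bins)
        by_id_aln = {a.read_id: a for a in alignments}
        bin_of = {rid: i for i, b in enumerate(bins) for rid in b.read_ids}
        with open(out / "recruited.tsv", "w") as fh:
            fh.write("read_id\tscore\tidentity\tclass\tbin\n")
            for a in sorted(alignments, key=lambda a: a.read_id):
                fh.write(f"{a.read_id}\t{a.score}\t{a.identity:.2f}\t"
                         f"{classes[a.read_id]}\t{bin_of[a.read_id]}\n")
        for i, b in enumerate(bins):
            mio.write_fasta(((rid, oriented[rid]) for rid in b.read_ids),
                            out / f"bin{i}.fasta")
        logger.info("stage bins: %d bins over %d reads", len(bins),
                    len(alignments))
        mark(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- stage: assemble -------------------------------------------------
    stage = "assemble"
    asm_json = out / "assembly.json"
    contigs_fasta = out / "contigs.fasta"
    try:
        if done(stage) and asm_json.exists() and contigs_fasta.exists():
            meta = json.loads(asm_json.read_text())
            seqs = mio.read_fasta_dict(contigs_fasta)
            sel = meta["selected_bin"]
            contig = Contig(sequence=seqs[sel],
                            support=np.asarray(meta["support"],
                                               dtype=np.int32),
                            contributing_reads=meta["contributing_reads"],
                            bin_id=sel)
            contig_aln = align_pair(contig.sequence, bait.unmasked_sequence,
                                    scoring)
            asm_table = meta["table"]
        else:
            contig, contig_aln, asm_table = assemble_and_select(
                bins, oriented, bait, scoring, config.min_overlap,
                config.min_overlap_identity, config.rounds)
            mio.write_fasta([(contig.bin_id, contig.sequence)],
                            contigs_fasta)
            with open(out / "assembly.tsv", "w") as fh:
                cols = ["bin", "n_reads", "contig_len", "score_vs_bait",
                        "identity_vs_bait", "selected"]
                fh.write("\t".join(cols) + "\n")
                for row in asm_table:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
            asm_json.write_text(json.dumps({
                "selected_bin": contig.bin_id,
                "contributing_reads": contig.contributing_reads,
                "support": [int(x) for x in contig.support],
                "table": asm_table}) + "\n")
            logger.info("stage assemble: selected %s (%d bp, %d reads)",
                        contig.bin_id, len(contig.sequence),
                        len(contig.contributing_reads))
            mark(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- stage: decode ---------------------------------------------------
    stage = "decode"
    dec_json = out / "decoding.json"
    try:
        decoding = decode_allele(contig.sequence, bait, table, scoring,
                                 config.min_anchor, alignment=contig_aln)
        ref_decoding = decode_allele(bait.unmasked_sequence, bait, table,
                                     scoring, config.min_anchor)
        comparison = compare_alleles(ref_decoding.code_string,
                                     decoding.code_string,
                                     config.end_window)
        dec_json.write_text(json.dumps({
            "assembly": decoding.to_dict(),
            "reference": ref_decoding.to_dict()}, indent=1) + "\n")
        (out / "allele.txt").write_text(decoding.code_string + "\n")
        with open(out / "array.bed", "w") as fh:
            s, e = decoding.array_interval
            fh.write(f"{contig.bin_id}\t{s}\t{e}\tarray\t"
                     f"{int(decoding.copy_number)}\t+\n")
        (out / "comparison.txt").write_text(render_comparison(comparison))
        logger.info("stage decode: %.1f copies, %d complete units",
                    decoding.copy_number, decoding.complete_units)
        mark(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- stage: report ---------------------------------------------------
    stage = "report"
    try:
        # in-silico PCR size on the assembly: run primer matching on the
        # contig itself, as done for the reference
        pair = config.primer_pair()
        asm_size_kb = None
        try:
            asm_bait = extract_bait(contig.sequence, pair, flank_length=0,
                                    max_product=config.max_product)
            asm_size_kb = round(asm_bait.amplicon_length / 1000.0, 1)
        except Exception:
            logger.warning("in-silico PCR on the assembly found no product")
        n_span = sum(1 for c in classes.values() if c == "spanning")
        report = RunReport(
            locus=config.primer_name or pair.name,
            copy_number_ref=ref_decoding.copy_number,
            copy_number_assembly=decoding.copy_number,
            complete_units_assembly=decoding.complete_units,
            identity_assembly_vs_reference=round(contig_aln.identity, 1)
            if contig_aln else 0.0,
            product_size_ref_kb=round(bait.amplicon_length / 1000.0, 1),
            product_size_assembly_kb=asm_size_kb,
            n_recruited=len(alignments),
            n_spanning=n_span,
            n_contributing=len(contig.contributing_reads),
            selected_bin=contig.bin_id,
            code_string_assembly=decoding.code_string,
            code_string_ref=ref_decoding.code_string,
            comparison={"n_match": comparison.n_match,
                        "n_mismatch": comparison.n_mismatch,
                        "n_indel": comparison.n_indel,
                        "five_prime_consistent":
                            comparison.five_prime_consistent,
                        "three_prime_consistent":
                            comparison.three_prime_consistent},
            config_hash=chash,
            seed=config.seed,
        )
        report.write(out / "report.json", "json")
        report.write(out / "report.tsv", "tsv")
        report.write(out / "report.txt", "text")
        mark(stage)
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc
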