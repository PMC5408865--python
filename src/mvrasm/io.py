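"""File-format helpers: FASTA/FASTQ (optionally gzipped), primer TSV."""

from __future__ import annotations

import gzip

from Bio import SeqIO

from .insilico_pcr import PrimerPair
from .recruitment import LongRead


def open_maybe_gzip(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path) -> str:
    """'fasta' or 'fastq' from the first non-empty character."""
    with open_maybe_gzip(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    raise ValueError(f"empty sequence file {path}")


def read_reference(path, record_id: str | None = None) -> tuple[str, str]:
    """One record (id, sequence) from a multi-FASTA."""
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if record_id is None or rec.id == record_id:
                return rec.id, str(rec.seq)
    raise ValueError(f"record {record_id!r} not found in {path}")


def read_long_reads(path) -> list[LongRead]:
    fmt = sniff_format(path)
    reads = []
    seen = set()
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            if rec.id in seen:
                raise ValueError(f"duplicate read id {rec.id!r}")
            seen.add(rec.id)
            quals = None
            if fmt == "fastq":
                quals = "".join(chr(q + 33)
                                for q in rec.letter_annotations["phred_quality"])
            reads.append(LongRead(id=rec.id, sequence=str(rec.seq).upper(),
                                  qualities=quals))
    if not reads:
        raise ValueError(f"no reads in {path}")
    return reads


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta_dict(path) -> dict[str, str]:
    with open_maybe_gzip(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def read_primer_tsv(path, name: str | None = None, **kwargs) -> PrimerPair:
    """3-column TSV (name, forward, reverse); picks ``name`` or the first."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"bad primer line: {line!r}")
            if name is None or fields[0] == name:
                return PrimerPair(forward=fields[1].upper(),
                                  reverse=fields[2].upper(),
                                  name=fields[0], **kwargs)
    raise ValueError(f"primer pair {name!r} not found in {path}")


def write_primer_tsv(pair: PrimerPair, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{pair.name}\t{pair.forward}\t{pair.reverse}\n")
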