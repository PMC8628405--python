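"""File IO helpers: FASTA, TSV reports, provenance records."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .align import MSA

log = logging.getLogger(__name__)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read sequences; ids are the first whitespace-delimited token of the
    header and ``*`` stop symbols are stripped with a logged warning."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            log.warning("%s: stripping %d '*' stop symbol(s)", rec.id, seq.count("*"))
            seq = seq.replace("*", "")
        records.append((rec.id, seq))
    return records


def write_fasta(seqs: Sequence[tuple[str, str]], path) -> None:
    """Write FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_alignment_fasta(path) -> MSA:
    return MSA(rows=read_fasta(path))


def write_alignment_fasta(msa: MSA, path) -> None:
    write_fasta(msa.rows, path)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_dir, subcommand: str, inputs: dict[str, str], params: dict
) -> Path:
    """Machine-readable run record: input hashes, parameters, tool version."""
    record = {
        "tool": "opsinsites",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": {name: sha256_of(p) for name, p in inputs.items()},
        "parameters": params,
    }
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
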