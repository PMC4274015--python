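"""FASTA I/O and shipped reference sequences.

The founding hairpin and both qPCR primers are shipped as package data; all
other sequence I/O goes through Biopython's SeqIO.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ancestor_sequence",
    "primer_sequences",
    "read_fasta",
    "write_fasta",
]


def _data_path(name: str):
    return resources.files("olisim.data").joinpath(name)


@lru_cache(maxsize=None)
def ancestor_sequence() -> str:
    """The printed 107-nt founding Oli sequence."""
    with resources.as_file(_data_path("ancestor.fasta")) as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    return str(rec.seq).upper()


@lru_cache(maxsize=None)
def primer_sequences() -> tuple[str, str]:
    """(forward, reverse) printed qPCR primer sequences, 5'->3'."""
    with resources.as_file(_data_path("primers.fasta")) as p:
        recs = list(SeqIO.parse(str(p), "fasta"))
    fwd = next(str(r.seq).upper() for r in recs if r.id.startswith("fwd"))
    rev = next(str(r.seq).upper() for r in recs if r.id.startswith("rev"))
    return fwd, rev


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> int:
    """Write records (SeqRecords or (id, sequence) pairs) as FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        else:
            rid, seq = rec
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    return SeqIO.write(out, str(path), "fasta")
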