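"""Shared file I/O: FASTA, paired FASTQ(.gz), and run manifests."""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import dataclass
from typing import Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .demux import ReadPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq_paired",
    "RunManifest",
]

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    """Open plain or gzipped text, sniffing by magic bytes, not extension."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "r")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence); sequences are uppercased."""
    records = []
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            records.append((title.split()[0], seq.upper()))
    return records


def write_fasta(records, path, width: int = 80) -> None:
    """Write (id, sequence) records, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _core_id(raw: str) -> str:
    """Strip mate suffixes: whitespace comment and trailing /1 or /2."""
    rid = raw.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def read_fastq_paired(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two FASTQ(.gz) files.

    Raises at the first pair whose ids disagree (after stripping /1, /2 or
    space-comment suffixes) and when one file runs out before the other.
    """
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            index += 1
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                longer = r2_path if rec1 is None else r1_path
                raise ValueError(
                    f"paired FASTQ desynchronized: extra record {index} in {longer}"
                )
            id1, id2 = _core_id(rec1[0]), _core_id(rec2[0])
            if id1 != id2:
                raise ValueError(
                    f"paired FASTQ id mismatch at record {index}: {id1!r} vs {id2!r}"
                )
            yield ReadPair(read_id=id1, r1_seq=rec1[1].upper(), r1_qual=rec1[2],
                           r2_seq=rec2[1].upper(), r2_qual=rec2[2])


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    subcommand: str
    config: dict
    input_paths: list
    seed: int | None = None
    warnings: list = None

    def write(self, path) -> None:
        doc = {
            "tool": "amplitrace",
            "version": __version__,
            "subcommand": self.subcommand,
            "config": self.config,
            "inputs": {str(p): _digest(p) for p in self.input_paths},
            "seed": self.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "warnings": self.warnings or [],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
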