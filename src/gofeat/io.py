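"""Readers and writers for the flat-file formats the pipeline exchanges."""

from __future__ import annotations

import io as _io
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .features import FeatureRegistry, FeatureVector


def read_fasta(text: str) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines allowed) -> id -> sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out and text.strip():
        raise ParseError("no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], width: int = 60) -> str:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    buf = _io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def feature_table_to_tsv(
    vectors: Sequence[FeatureVector], registry: FeatureRegistry
) -> str:
    """Tab-separated feature table; header is "id" plus group.index columns."""
    header = ["id"] + registry.column_names()
    lines = ["\t".join(header)]
    names = registry.group_names
    for vec in vectors:
        row = vec.to_array(names)
        lines.append(vec.sequence_id + "\t" +
                     "\t".join(f"{x:.6g}" for x in row))
    return "\n".join(lines) + "\n"


def feature_table_from_tsv(
    text: str, registry: FeatureRegistry
) -> list[FeatureVector]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty feature table")
    header = lines[0].split("\t")
    expected = ["id"] + registry.column_names()
    if header != expected:
        raise ParseError("feature table header does not match registry")
    out = []
    sizes = [(g.name, g.size) for g in registry.groups]
    for ln in lines[1:]:
        parts = ln.split("\t")
        sid, vals = parts[0], np.array([float(x) for x in parts[1:]])
        values, off = {}, 0
        for name, size in sizes:
            values[name] = vals[off:off + size]
            off += size
        out.append(FeatureVector(sequence_id=sid, values=values))
    return out
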