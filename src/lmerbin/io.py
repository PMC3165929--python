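"""Reading and writing the package's on-disk formats.

FASTA in/out goes through Biopython; labels and assignments are plain
two-column TSV (fragment_id, value), header optional on input.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .kmer import Fragment


def read_fasta(path, labels: Mapping[str, str] | None = None) -> list[Fragment]:
    """Read a multi-FASTA into Fragment objects.

    The fragment id is the header token up to the first whitespace.  When a
    label map is given, labels are attached where available.
    """
    if not os.path.exists(path):
        raise InputError(f"FASTA file not found: {path}")
    fragments = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            lab = labels.get(rec.id) if labels else None
            fragments.append(Fragment(id=rec.id, sequence=str(rec.seq),
                                      label=lab))
    except (ValueError, UnicodeDecodeError) as exc:
        raise InputError(f"malformed FASTA {path}: {exc}") from exc
    if not fragments:
        raise InputError(f"no sequences found in {path}")
    return fragments


def write_fasta(fragments: Iterable[Fragment], path) -> None:
    records = [SeqRecord(Seq(f.sequence), id=f.id, description="")
               for f in fragments]
    SeqIO.write(records, str(path), "fasta")


def _read_two_column_tsv(path, value_name: str) -> pd.Series:
    if not os.path.exists(path):
        raise InputError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise InputError(f"{path} must have two tab-separated columns")
    # tolerate a header row: drop it if the first row repeats column names
    first = df.iloc[0, 0].lower()
    if first in ("fragment_id", "id", "fragment"):
        df = df.iloc[1:]
    if df.empty:
        raise InputError(f"{path} contains no data rows")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        raise InputError(f"{path} has duplicate fragment ids")
    return pd.Series(df.iloc[:, 1].values, index=ids.values, name=value_name)


def read_labels(path) -> dict[str, str]:
    """Read a (fragment_id, species_label) TSV into a dict."""
    return _read_two_column_tsv(path, "label").to_dict()


def write_labels(fragments: Iterable[Fragment], path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tlabel\n")
        for f in fragments:
            fh.write(f"{f.id}\t{f.label if f.label is not None else ''}\n")


def read_assignments(path) -> dict[str, int]:
    """Read a (fragment_id, cluster_id) TSV into a dict."""
    series = _read_two_column_tsv(path, "cluster")
    try:
        return {fid: int(c) for fid, c in series.items()}
    except ValueError as exc:
        raise InputError(f"{path}: cluster ids must be integers") from exc
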