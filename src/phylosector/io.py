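"""Readers and writers for binary spin alignments.

Spin states are encoded in FASTA as characters: -1 -> 'A', +1 -> 'B'
(the mapping is recorded in each record description).  The lossless
matrix format is a plain CSV of -1/+1 integers, one row per sequence.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPIN_TO_CHAR = {-1: "A", 1: "B"}
CHAR_TO_SPIN = {"A": -1, "B": 1}
_MAPPING_NOTE = "spin_encoding A=-1 B=+1"


def write_binary_fasta(msa, path, ids: Optional[Sequence[str]] = None) -> None:
    from .seqsim import BinaryMSA

    seqs = msa.sequences if isinstance(msa, BinaryMSA) else np.asarray(msa, dtype=np.int8)
    if ids is None:
        ids = [f"seq{m}" for m in range(seqs.shape[0])]
    lut = np.array(["A", "B"])
    records = [
        SeqRecord(Seq("".join(lut[(row + 1) // 2])), id=str(name), description=_MAPPING_NOTE)
        for name, row in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_binary_fasta(path):
    from .seqsim import BinaryMSA

    rows, ids = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            rows.append([CHAR_TO_SPIN[c] for c in str(rec.seq)])
        except KeyError as err:
            raise ValueError(f"unexpected character in {rec.id}: {err}") from None
        ids.append(rec.id)
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return BinaryMSA(np.array(rows, dtype=np.int8)), ids


def write_binary_csv(msa, path) -> None:
    from .seqsim import BinaryMSA

    seqs = msa.sequences if isinstance(msa, BinaryMSA) else np.asarray(msa, dtype=np.int8)
    np.savetxt(str(path), seqs, fmt="%d", delimiter=",")


def read_binary_csv(path):
    from .seqsim import BinaryMSA

    return BinaryMSA(np.loadtxt(str(path), delimiter=",", dtype=np.int8, ndmin=2))


def write_site_vector(values, path, header: str = "component") -> None:
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"site,{header}\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{float(v)!r}\n")


def write_matrix_csv(matrix, path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    L = matrix.shape[0]
    with open(path, "w") as fh:
        fh.write("site," + ",".join(str(j) for j in range(L)) + "\n")
        for i in range(L):
            fh.write(str(i) + "," + ",".join(repr(float(v)) for v in matrix[i]) + "\n")


def read_matrix_csv(path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(Path(path), index_col=0).to_numpy(dtype=float)
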