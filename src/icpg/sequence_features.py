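"""Sequence-based baseline encoders: one-hot and n-gram frequencies.

These are the comparison encoders against which positional features are
benchmarked.  Both operate on a window of genomic sequence centered on the
CpG cytosine.

The one-hot row order is A, T, G, C (a documented convention of this
encoder); the n-gram vocabulary is lexicographic over A < C < G < T — two
independent conventions, kept distinct on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np

_ONE_HOT = {
    "A": (1, 0, 0, 0),
    "T": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "C": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}

_BASES = "ACGT"
#: fixed 84-entry vocabulary: 4 unigrams + 16 bigrams + 64 trigrams,
#: each block lexicographic
NGRAM_VOCAB: tuple[str, ...] = tuple(
    "".join(g) for n in (1, 2, 3) for g in product(_BASES, repeat=n)
)


@dataclass(frozen=True)
class SequenceWindow:
    """A sequence window of length M centered on a CpG cytosine."""

    seq: str
    center: int
    left_clip: int = 0
    right_clip: int = 0

    @property
    def M(self) -> int:
        return len(self.seq)


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a sequence as one 4-bit row per base.

    A→[1,0,0,0], T→[0,1,0,0], G→[0,0,1,0], C→[0,0,0,1]; N→ all zeros.
    """
    rows = []
    for i, base in enumerate(seq.upper()):
        try:
            rows.append(_ONE_HOT[base])
        except KeyError:
            raise ValueError(
                f"cannot one-hot encode {base!r} at index {i}") from None
    return np.array(rows, dtype=np.int8).reshape(len(rows), 4)


def ngram_features(seq: str, orders: tuple[int, ...] = (1, 2, 3)) -> np.ndarray:
    """n-gram frequency vector of fixed length 84.

    Each entry is t_i = N(o_i) / (M - (n-1)) — the count of gram o_i over
    the number of length-n windows in a sequence of length M.  Grams that
    contain an ambiguous base (N) are excluded from the counts; the
    denominator is unchanged, so all entries stay in [0, 1] and an N-free
    sequence's order-n block sums to exactly 1.
    """
    seq = seq.upper()
    M = len(seq)
    if M < max(orders):
        raise ValueError(f"sequence length {M} < max n-gram order {max(orders)}")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    values = np.zeros(len(NGRAM_VOCAB), dtype=np.float64)
    offset = 0
    for n in (1, 2, 3):
        block = 4 ** n
        if n in orders:
            denom = M - (n - 1)
            counts: dict[str, int] = {}
            for i in range(denom):
                gram = seq[i:i + n]
                if "N" not in gram:
                    counts[gram] = counts.get(gram, 0) + 1
            for j, gram in enumerate(NGRAM_VOCAB[offset:offset + block]):
                values[offset + j] = counts.get(gram, 0) / denom
        offset += block
    return values


def extract_window(fasta: Mapping[str, object], chrom: str, pos: int,
                   flank: int = 50) -> SequenceWindow:
    """Extract an uppercase window of 2*flank+1 bases centered on ``pos``.

    ``fasta`` is anything mapping chromosome name to a sliceable sequence
    (a ``pyfaidx.Fasta``, a ``dict`` of strings, ...); ``pos`` is 1-based.
    Windows running past a chromosome end are N-padded, with the clip
    lengths recorded on the returned :class:`SequenceWindow`.
    """
    try:
        ref = fasta[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} absent from the sequence source")
    chrom_len = len(ref)
    if not 1 <= pos <= chrom_len:
        raise ValueError(f"{chrom}:{pos} outside chromosome (len {chrom_len})")
    lo = max(0, pos - 1 - flank)
    hi = min(chrom_len, pos + flank)
    seq = str(ref[lo:hi]).upper()
    left_clip = flank - (pos - 1 - lo)
    right_clip = flank - (hi - pos)
    seq = "N" * left_clip + seq + "N" * right_clip
    return SequenceWindow(seq=seq, center=flank,
                          left_clip=left_clip, right_clip=right_clip)


def assemble_sequence_matrix(cell, fasta: Mapping[str, object],
                             chroms: list[str] | None = None,
                             encoding: str = "ngram", flank: int = 50):
    """Sequence-encoder design matrix for one cell's sites.

    One row per site of ``cell`` on the chromosome subset: n-gram
    frequencies (84 columns) or a flattened one-hot window
    (4*(2*flank+1) columns).  Returns (X, labels, site index) in the same
    shape as the positional assembler.
    """
    import pandas as pd

    if encoding not in ("ngram", "onehot"):
        raise ValueError(f"unknown sequence encoding {encoding!r}")
    use_chroms = sorted(set(cell.sites) if chroms is None
                        else set(chroms) & set(cell.sites))
    rows, labels, idx = [], [], []
    for chrom in use_chroms:
        cs = cell.sites[chrom]
        for pos, state in zip(cs.pos, cs.state):
            win = extract_window(fasta, chrom, int(pos), flank=flank)
            if encoding == "ngram":
                rows.append(ngram_features(win.seq))
            else:
                rows.append(one_hot_encode(win.seq).ravel())
            labels.append(int(state))
            idx.append((chrom, int(pos)))
    if encoding == "ngram":
        cols = [f"ngram_{g}" for g in NGRAM_VOCAB]
    else:
        cols = [f"onehot_{i}_{b}" for i in range(2 * flank + 1)
                for b in "ATGC"]
    X = pd.DataFrame(np.asarray(rows, dtype=np.float64).reshape(
        len(rows), len(cols)), columns=cols)
    index = pd.DataFrame(idx, columns=["chrom", "pos"])
    return X, np.asarray(labels, dtype=np.int8), index
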