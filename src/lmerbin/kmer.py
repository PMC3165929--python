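"""Canonical l-mer composition features for DNA fragments.

DNA fragments are summarised by the occurrence frequencies of their
length-``l`` substrings (l-mers), counted with a sliding window.  Because a
fragment may have been sequenced from either strand, an l-mer and its
reverse complement are collapsed into a single canonical class, so both
strands of the same locus produce identical feature vectors.  For even
``l`` some l-mers are their own reverse complement (palindromes) and form
singleton classes; the number of classes is ``4**l / 2`` for odd ``l`` and
``(4**l + 4**(l//2)) / 2`` for even ``l`` — 136 for the default ``l = 4``.

Counts are normalised by the number of counted windows so fragments of
different lengths are comparable.  Windows containing any non-ACGT symbol
(e.g. ``N``) are skipped rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFragmentError, InputError, ParameterError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: map ASCII byte -> 2-bit base code, 255 for anything that is not A/C/G/T
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BYTE_CODE[_b] = _i


def reverse_complement(sequence: str) -> str:
    """Return the reverse complement of a DNA string (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """One input DNA fragment.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    sequence : str
        DNA sequence over the alphabet {A, C, G, T, N}; lowercase accepted.
    label : str, optional
        True species label, when known (used only for evaluation).
    """

    id: str
    sequence: str
    label: str | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class CanonicalIndex:
    """Bijection between reverse-complement l-mer classes and vector columns.

    ``classes`` lists the canonical representative (the lexicographically
    smaller of an l-mer and its reverse complement) of every class in sorted
    order; ``lookup`` maps all ``4**l`` l-mer strings to their column.
    """

    l: int
    classes: tuple[str, ...]
    lookup: dict[str, int] = field(repr=False)
    _code_to_class: np.ndarray = field(repr=False)  # len 4**l, int32

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def build_canonical_index(l: int) -> CanonicalIndex:
    """Build the canonical l-mer index for mer length ``l`` (1..8).

    The number of classes is ``4**l / 2`` for odd ``l`` and
    ``(4**l + 4**(l//2)) / 2`` for even ``l`` (palindromic l-mers are their
    own class); 136 classes for ``l = 4``.
    """
    if not isinstance(l, (int, np.integer)) or isinstance(l, bool):
        raise ParameterError(f"l must be an integer, got {l!r}")
    if not 1 <= l <= 8:
        raise ParameterError(f"l must be in 1..8, got {l}")
    mers = ["".join(p) for p in product("ACGT", repeat=l)]
    canon = {m: min(m, reverse_complement(m)) for m in mers}
    classes = tuple(sorted(set(canon.values())))
    col = {c: i for i, c in enumerate(classes)}
    lookup = {m: col[canon[m]] for m in mers}
    code_to_class = np.array([lookup[m] for m in mers], dtype=np.int32)
    return CanonicalIndex(l=int(l), classes=classes, lookup=lookup,
                          _code_to_class=code_to_class)


@dataclass(frozen=True)
class CountVector:
    """Raw canonical l-mer counts for one fragment.

    ``total`` is the number of valid (ambiguity-free) windows counted and
    equals ``counts.sum()``.
    """

    counts: np.ndarray
    total: int


def _window_codes(sequence: str, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid) for every window: base-4 code and validity mask."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    base = _BYTE_CODE[raw]
    windows = np.lib.stride_tricks.sliding_window_view(base, l)
    valid = (windows != 255).all(axis=1)
    powers = (4 ** np.arange(l - 1, -1, -1)).astype(np.int64)
    codes = windows.astype(np.int64) @ powers
    return codes, valid


def count_lmers(fragment: Fragment, index: CanonicalIndex) -> CountVector:
    """Count canonical l-mers in ``fragment`` with a sliding window.

    Every length-``l`` window consisting solely of A/C/G/T increments the
    count of its reverse-complement class; windows containing any other
    symbol are skipped.  A fragment of length ``L`` has ``L - l + 1``
    windows in total (497 four-mers in 500 bp, 1997 in 2000 bp).
    """
    l = index.l
    seq = fragment.sequence
    if len(seq) == 0:
        raise InputError(f"fragment {fragment.id!r} has an empty sequence")
    if len(seq) < l:
        raise InputError(
            f"fragment {fragment.id!r} is shorter ({len(seq)}) than l={l}")
    try:
        codes, valid = _window_codes(seq, l)
    except UnicodeEncodeError as exc:
        raise InputError(
            f"fragment {fragment.id!r} contains non-ASCII characters") from exc
    cls = index._code_to_class[codes[valid]]
    counts = np.bincount(cls, minlength=index.n_classes).astype(np.int64)
    return CountVector(counts=counts, total=int(valid.sum()))


def normalize_counts(counts: CountVector) -> np.ndarray:
    """Divide counts by the number of counted windows; rows sum to 1."""
    if counts.total <= 0:
        raise DegenerateFragmentError(
            "cannot normalize a count vector with zero valid windows")
    return counts.counts / counts.total


@dataclass(frozen=True)
class FeatureMatrix:
    """n x N(l) matrix of normalised canonical l-mer frequencies.

    Rows follow the input fragment order; fragments with zero valid windows
    are excluded and recorded in ``dropped_ids``.
    """

    values: np.ndarray
    fragment_ids: tuple[str, ...]
    index: CanonicalIndex
    dropped_ids: tuple[str, ...] = ()

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.fragment_ids),
                            columns=list(self.index.classes))

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "fragment_id"
        df.to_csv(path, sep="\t", float_format="%.10g")


def build_feature_matrix(fragments: Sequence[Fragment] | Iterable[Fragment],
                         l: int = 4) -> FeatureMatrix:
    """Convert fragments to the n x N(l) normalised frequency matrix.

    Row order matches fragment order.  Fragments without a single valid
    window (all windows ambiguous) have no defined normalisation; they are
    dropped with a warning and listed in ``FeatureMatrix.dropped_ids``.
    """
    fragments = list(fragments)
    if not fragments:
        raise InputError("fragment list is empty")
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        raise InputError("fragment ids are not unique")
    index = build_canonical_index(l)
    rows, kept, dropped = [], [], []
    for frag in fragments:
        cv = count_lmers(frag, index)
        if cv.total == 0:
            dropped.append(frag.id)
            continue
        rows.append(normalize_counts(cv))
        kept.append(frag.id)
    if dropped:
        logger.warning("dropped %d fragment(s) with no valid %d-mer windows: %s",
                       len(dropped), l, ", ".join(dropped[:10]))
    if not rows:
        raise InputError("no fragment yields a valid window; nothing to bin")
    return FeatureMatrix(values=np.vstack(rows), fragment_ids=tuple(kept),
                         index=index, dropped_ids=tuple(dropped))


def corrupted_window_count(original: str, mutated: str, l: int = 4) -> int:
    """Number of length-``l`` windows whose content differs between two
    equal-length sequences.

    A single substitution corrupts at most ``l`` windows, so ``e`` isolated
    substitutions (each at least ``l`` correct bases apart and away from the
    ends) corrupt exactly ``e * l`` windows.  Useful for reasoning about
    sequencing-error propagation into l-mer counts.
    """
    if len(original) != len(mutated):
        raise InputError("sequences must have equal length")
    if len(original) < l:
        raise InputError("sequences shorter than l")
    a = np.frombuffer(original.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(mutated.encode("ascii"), dtype=np.uint8)
    diff = a != b
    win = np.lib.stride_tricks.sliding_window_view(diff, l)
    return int(win.any(axis=1).sum())
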