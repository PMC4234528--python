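"""Compositional spectra by mismatch-tolerant probe-word counting.

A compositional spectrum characterizes a sequence S by a fixed probe set W
of n words of length L.  For each word w_i the count m_i is the number of
sliding windows of S within Hamming distance r of w_i (every window is
tested independently, so overlapping occurrences all count).  With
M = sum_i m_i, the spectrum is the frequency vector f_i = m_i / M.

Two alphabets are supported: the standard four-letter {A,C,G,T} and the
two-letter purine/pyrimidine recoding {R,Y} (A,G -> R; C,T -> Y), in which
longer words compensate for the smaller alphabet.  An N never matches any
probe letter, so masked or ambiguous stretches contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALPHABETS = {"ACGT": "ACGT", "RY": "RY"}
DEFAULT_N_WORDS = 100
DEFAULT_WORD_LEN = {"ACGT": 10, "RY": 20}
DEFAULT_R = {"ACGT": 2, "RY": 4}

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# In the two-letter alphabet the complement of a purine is a pyrimidine;
# this is a derived convention, not part of the four-letter definition.
_RY_COMPLEMENT = str.maketrans("RY", "YR")
_TO_RY = str.maketrans("AGCT", "RRYY")

# Residue encoders: probe letters map to 0..(sigma-1); N and any stray
# symbol map to a sentinel that mismatches every probe letter.
_SENTINEL = 255


def _make_encoder(alphabet: str) -> np.ndarray:
    table = np.full(256, _SENTINEL, dtype=np.uint8)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
    return table


_ENCODERS = {name: _make_encoder(letters) for name, letters in ALPHABETS.items()}


def encode_residues(residues: str, alphabet: str = "ACGT") -> np.ndarray:
    """Encode a residue string as a uint8 array for the counting kernel."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODERS[alphabet][raw]


@dataclass(frozen=True)
class WordSet:
    """An ordered probe set of n distinct length-L words over one alphabet."""

    words: tuple[str, ...]
    alphabet: str
    seed: int

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        letters = set(ALPHABETS[self.alphabet])
        if len(set(self.words)) != len(self.words):
            raise ValueError("probe words must be distinct")
        lengths = {len(w) for w in self.words}
        if len(lengths) != 1:
            raise ValueError("probe words must share one length")
        for w in self.words:
            if not set(w) <= letters:
                raise ValueError(f"word {w!r} not over alphabet {self.alphabet}")

    @property
    def n(self) -> int:
        return len(self.words)

    @property
    def L(self) -> int:
        return len(self.words[0])

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix of the words."""
        return np.vstack([encode_residues(w, self.alphabet) for w in self.words])


@dataclass(frozen=True)
class SpectrumParams:
    """Counting parameters: Hamming tolerance r and complementary-set usage.

    With ``use_complementary`` the reverse-complement probe set W' is
    counted as well and merged per word, making spectra strand-symmetric.
    """

    r: int = 2
    use_complementary: bool = True

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")


@dataclass(frozen=True)
class CompositionalSpectrum:
    """Match counts and normalized frequencies of one segment."""

    segment_id: str
    counts: np.ndarray
    total: int
    frequencies: np.ndarray | None

    @property
    def defined(self) -> bool:
        """False when no window matched any probe (M = 0)."""
        return self.total > 0


def _index_to_word(index: int, L: int, letters: str) -> str:
    sigma = len(letters)
    chars = []
    for _ in range(L):
        index, rem = divmod(index, sigma)
        chars.append(letters[rem])
    return "".join(reversed(chars))


def generate_word_set(
    n: int = DEFAULT_N_WORDS,
    L: int | None = None,
    alphabet: str = "ACGT",
    seed: int = 0,
) -> WordSet:
    """Draw n distinct length-L words uniformly without replacement.

    Deterministic for identical (n, L, alphabet, seed).  ``L`` defaults to
    10 for the four-letter alphabet and 20 for the RY alphabet.
    """
    if alphabet not in ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    letters = ALPHABETS[alphabet]
    if L is None:
        L = DEFAULT_WORD_LEN[alphabet]
    if L < 1:
        raise ValueError("L must be >= 1")
    total = len(letters) ** L
    if not 2 <= n <= total:
        raise ValueError(f"need 2 <= n <= {len(letters)}^{L} = {total}, got n={n}")
    rng = np.random.default_rng(seed)
    if total <= 2**24:
        indices = rng.choice(total, size=n, replace=False)
        words = tuple(_index_to_word(int(i), L, letters) for i in indices)
    else:
        # Word space too large to enumerate; rejection-sample distinct words.
        seen: dict[str, None] = {}
        while len(seen) < n:
            draw = rng.integers(0, len(letters), size=L)
            seen.setdefault("".join(letters[int(i)] for i in draw), None)
        words = tuple(seen)
    return WordSet(words=words, alphabet=alphabet, seed=seed)


def complement_word_set(ws: WordSet) -> WordSet:
    """Reverse-complement every word, preserving order (an involution)."""
    table = _DNA_COMPLEMENT if ws.alphabet == "ACGT" else _RY_COMPLEMENT
    if ws.alphabet == "RY":
        logger.debug("reverse-complementing an RY word set (derived R<->Y convention)")
    return WordSet(
        words=tuple(w.translate(table)[::-1] for w in ws.words),
        alphabet=ws.alphabet,
        seed=ws.seed,
    )


def to_ry(residues: str) -> str:
    """Recode to the purine/pyrimidine alphabet: A,G -> R; C,T -> Y; N -> N."""
    return residues.translate(_TO_RY)


def _count_all(encoded: np.ndarray, words_mat: np.ndarray, r: int) -> np.ndarray:
    """Count, for each row of ``words_mat``, the windows of ``encoded``
    within Hamming distance r.  Vectorized over windows and words in
    memory-bounded chunks."""
    n_words, L = words_mat.shape
    counts = np.zeros(n_words, dtype=np.int64)
    if encoded.size < L:
        return counts
    n_win = encoded.size - L + 1
    # Accumulate per-position mismatches into an (windows, words) tally,
    # chunked over windows to bound the intermediate at ~64 MB.
    chunk = max(1, 64_000_000 // n_words)
    for lo in range(0, n_win, chunk):
        hi = min(lo + chunk, n_win)
        mism = np.zeros((hi - lo, n_words), dtype=np.uint8 if L <= 255 else np.uint16)
        for j in range(L):
            mism += encoded[lo + j : hi + j, None] != words_mat[None, :, j]
        counts += (mism <= r).sum(axis=0)
    return counts


def count_matches(residues: str, word: str, r: int, alphabet: str = "ACGT") -> int:
    """Number of sliding windows of ``residues`` within Hamming distance r
    of ``word``.  An N in a window mismatches every probe letter.  A word
    longer than the sequence yields 0."""
    if not word:
        raise ValueError("empty probe word")
    if r >= len(word):
        raise ValueError(f"r ({r}) must be < word length ({len(word)})")
    encoded = encode_residues(residues, alphabet)
    word_mat = encode_residues(word, alphabet)[None, :]
    return int(_count_all(encoded, word_mat, r)[0])


def compute_spectrum(
    segment_residues: str,
    ws: WordSet,
    params: SpectrumParams = SpectrumParams(),
    segment_id: str = "",
) -> CompositionalSpectrum:
    """Count every probe word (optionally merged with its reverse
    complement) in one segment and normalize to frequencies.

    A segment in which no window matches any probe (M = 0) yields an
    undefined spectrum (``frequencies is None``); callers exclude it from
    distance computations.
    """
    if not segment_residues:
        raise ValueError("empty segment residues")
    if params.r >= ws.L:
        raise ValueError(f"r ({params.r}) must be < word length ({ws.L})")
    residue_letters = set(segment_residues)
    allowed = set(ALPHABETS[ws.alphabet]) | {"N"}
    if not residue_letters <= allowed:
        raise ValueError(
            f"residues contain {sorted(residue_letters - allowed)}; "
            f"expected the {ws.alphabet} alphabet (use to_ry for RY probes)"
        )
    encoded = encode_residues(segment_residues, ws.alphabet)
    counts = _count_all(encoded, ws.encoded(), params.r)
    if params.use_complementary:
        counts = counts + _count_all(encoded, complement_word_set(ws).encoded(), params.r)
    total = int(counts.sum())
    if total == 0:
        logger.warning("segment %s: spectrum undefined (no probe matches)", segment_id)
        return CompositionalSpectrum(segment_id, counts, 0, None)
    return CompositionalSpectrum(segment_id, counts, total, counts / total)


def compute_spectra(
    segments: Iterable[tuple[str, str]],
    ws: WordSet,
    params: SpectrumParams = SpectrumParams(),
) -> list[CompositionalSpectrum]:
    """Spectra for (segment_id, residues) pairs, excluding none (undefined
    spectra are returned flagged; filter on ``.defined`` downstream)."""
    residue_source = list(segments)
    out = []
    for seg_id, residues in residue_source:
        seq = to_ry(residues) if ws.alphabet == "RY" else residues
        out.append(compute_spectrum(seq, ws, params, segment_id=seg_id))
    return out


def spectra_to_frame(spectra: Sequence[CompositionalSpectrum], ws: WordSet) -> pd.DataFrame:
    """Frequency matrix: rows = segments, columns = probe words."""
    defined = [s for s in spectra if s.defined]
    return pd.DataFrame(
        [s.frequencies for s in defined],
        index=pd.Index([s.segment_id for s in defined], name="segment_id"),
        columns=list(ws.words),
    )


def word_set_manifest(ws: WordSet, params: SpectrumParams) -> pd.DataFrame:
    """Word-set bookkeeping table (word, reverse complement, parameters)."""
    comp = complement_word_set(ws)
    return pd.DataFrame(
        {
            "index": range(ws.n),
            "word": list(ws.words),
            "complement": list(comp.words),
            "alphabet": ws.alphabet,
            "n": ws.n,
            "L": ws.L,
            "r": params.r,
            "use_complementary": params.use_complementary,
            "seed": ws.seed,
        }
    )
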