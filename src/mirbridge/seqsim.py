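"""Length-normalized Smith-Waterman sequence similarity.

For two sequences u, v the similarity is e(u, v) = w(u, v) / (|u| + |v|)
with w the best local-alignment score.  With the default nucleotide
scoring (match +2) this puts e in [0, 1], reaching 1 only for identical
sequences.

Alignment is computed with Bio.Align.PairwiseAligner; a gap of length g
costs gap_open + (g - 1) * gap_extend.  The ambiguity sentinel written
by dataio scores a large negative value against everything (including
itself), so ambiguous positions can never support an alignment.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .dataio import AMBIGUOUS_SENTINEL, AMINO_ACIDS, NUCLEOTIDES, Alphabet, SequenceStore
from .matrices import SimilarityMatrix

log = logging.getLogger(__name__)

_SENTINEL_SCORE = -1.0e4


@dataclass(frozen=True)
class AlignmentScheme:
    """Local-alignment scoring scheme.

    ``gap_open``/``gap_extend`` are penalties (non-negative); a length-g
    gap costs gap_open + (g-1)*gap_extend.  For proteins the
    ``substitution`` named matrix replaces match/mismatch.
    """

    alphabet: Alphabet = Alphabet.NUCLEOTIDE
    match: float = 2.0
    mismatch: float = -1.0
    substitution: str = "BLOSUM62"
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.alphabet is Alphabet.NUCLEOTIDE and self.match <= 0:
            raise ValueError("match score must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @classmethod
    def nucleotide(cls, **kw) -> "AlignmentScheme":
        return cls(alphabet=Alphabet.NUCLEOTIDE, **kw)

    @classmethod
    def protein(cls, **kw) -> "AlignmentScheme":
        kw.setdefault("gap_open", 11.0)
        kw.setdefault("gap_extend", 1.0)
        return cls(alphabet=Alphabet.AMINO_ACID, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alphabet"] = self.alphabet.value
        return d


def _substitution_matrix(scheme: AlignmentScheme):
    if scheme.alphabet is Alphabet.NUCLEOTIDE:
        letters = NUCLEOTIDES + AMBIGUOUS_SENTINEL
        m = substitution_matrices.Array(alphabet=letters, dims=2)
        for a in NUCLEOTIDES:
            for b in NUCLEOTIDES:
                m[a, b] = scheme.match if a == b else scheme.mismatch
    else:
        base = substitution_matrices.load(scheme.substitution)
        letters = AMINO_ACIDS + AMBIGUOUS_SENTINEL
        m = substitution_matrices.Array(alphabet=letters, dims=2)
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                m[a, b] = base[a, b]
    for a in letters:
        m[a, AMBIGUOUS_SENTINEL] = _SENTINEL_SCORE
        m[AMBIGUOUS_SENTINEL, a] = _SENTINEL_SCORE
    return m


def make_aligner(scheme: AlignmentScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _substitution_matrix(scheme)
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _check_alphabet(seq: str, scheme: AlignmentScheme, name: str) -> None:
    allowed = set(
        (NUCLEOTIDES if scheme.alphabet is Alphabet.NUCLEOTIDE else AMINO_ACIDS)
        + AMBIGUOUS_SENTINEL
    )
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"sequence {name} contains characters {sorted(bad)} outside the "
            f"{scheme.alphabet.value} alphabet"
        )


def sw_score(
    a: str,
    b: str,
    scheme: AlignmentScheme,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Best Smith-Waterman local-alignment score (>= 0)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    _check_alphabet(a, scheme, "a")
    _check_alphabet(b, scheme, "b")
    if aligner is None:
        aligner = make_aligner(scheme)
    return float(aligner.score(a, b))


def sequence_similarity(
    store: SequenceStore,
    ids: list[str],
    scheme: AlignmentScheme | None = None,
) -> SimilarityMatrix:
    """All-pairs e(u, v) = w(u, v) / (|u| + |v|) over ``ids``.

    Pairs are computed once (upper triangle) and mirrored; the result is
    independent of computation order.
    """
    if scheme is None:
        scheme = (
            AlignmentScheme.nucleotide()
            if store.alphabet is Alphabet.NUCLEOTIDE
            else AlignmentScheme.protein()
        )
    if scheme.alphabet is not store.alphabet:
        raise ValueError(
            f"scheme alphabet {scheme.alphabet.value} does not match store "
            f"alphabet {store.alphabet.value}"
        )
    missing = [i for i in ids if i not in store]
    if missing:
        raise KeyError(f"sequences missing for ids: {missing}")
    aligner = make_aligner(scheme)
    n = len(ids)
    seqs = [store[i] for i in ids]
    lengths = np.array([len(s) for s in seqs], dtype=float)
    values = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations_with_replacement(range(n), 2):
        w = sw_score(seqs[i], seqs[j], scheme, aligner=aligner)
        e = w / (lengths[i] + lengths[j])
        values[i, j] = values[j, i] = e
    return SimilarityMatrix(
        ids=list(ids), values=values, method="sequence", meta=scheme.to_dict()
    )
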