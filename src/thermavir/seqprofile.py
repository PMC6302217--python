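"""Sequence-composition primitives.

GC content, tetranucleotide-frequency (TNF) vectors, Pearson correlation
matrices between TNF profiles, and the composite feature distance
(TNF + standardized log-coverage + GC) that drives contig binning.

Conventions: 4-mers are counted on the given strand only, in lexicographic
order over {A,C,G,T}; windows containing an ambiguous base are skipped.
Coverage enters distances as log10(coverage + 1): the log already places
coverage on a scale comparable to GC (a 2-fold coverage change is ~0.3),
and the default weights down-weight it to 0.25 so that coverage noise
cannot drown the compositional signal when coverage is uninformative.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .contig import Contig
from .errors import CompositionError, DegenerateVarianceError, InsufficientSequenceError

#: all 256 tetranucleotides, lexicographic
KMERS_4 = ["".join(p) for p in product("ACGT", repeat=4)]

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _codes(sequence: str) -> np.ndarray:
    """Map a nucleotide string to integer codes; non-ACGT -> -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _seq_of(contig: Contig | str) -> str:
    return contig.sequence if isinstance(contig, Contig) else contig


def gc_content(contig: Contig | str) -> float:
    """(G+C)/(A+C+G+T); N positions are excluded from the denominator."""
    seq = _seq_of(contig)
    if not seq:
        raise CompositionError("empty sequence")
    codes = _codes(seq)
    unamb = int((codes >= 0).sum())
    if unamb == 0:
        raise CompositionError("sequence contains no unambiguous bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / unamb


def tnf_vector(contig: Contig | str) -> np.ndarray:
    """256-vector of overlapping 4-mer frequencies (single strand).

    Windows containing any ambiguous base are skipped; frequencies are
    normalized by the number of counted windows and sum to 1.
    """
    seq = _seq_of(contig)
    codes = _codes(seq)
    n = len(codes)
    if n < 4:
        raise InsufficientSequenceError("no 4-mer window of unambiguous bases")
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    total = int(valid.sum())
    if total == 0:
        raise InsufficientSequenceError("no 4-mer window of unambiguous bases")
    idx = (c0[valid] << 6) | (c1[valid] << 4) | (c2[valid] << 2) | c3[valid]
    counts = np.bincount(idx, minlength=256).astype(float)
    return counts / total


def correlation_matrix(vectors: Sequence[np.ndarray],
                       ids: Sequence[str] | None = None) -> np.ndarray:
    """Symmetric Pearson correlation matrix between profile vectors."""
    if len(vectors) < 2:
        raise InsufficientSequenceError("need at least two vectors")
    mat = np.asarray(vectors, dtype=float)
    sd = mat.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            name = ids[i] if ids is not None else f"vector {i}"
            raise DegenerateVarianceError(f"constant profile for {name}")
    corr = np.corrcoef(mat)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


DEFAULT_FEATURE_WEIGHTS = (1.0, 0.25, 1.0)


def feature_matrix(contigs: Sequence[Contig],
                   weights: tuple[float, float, float] = DEFAULT_FEATURE_WEIGHTS,
                   ) -> np.ndarray:
    """Stacked per-contig features: 256 TNF dims, log10(coverage+1), GC.

    Each feature block is scaled by sqrt(weight) so that plain Euclidean
    distance on the rows equals the weighted distance.
    """
    w_tnf, w_cov, w_gc = weights
    tnf = np.vstack([tnf_vector(c) for c in contigs])
    logcov = np.log10(np.array([c.coverage for c in contigs], dtype=float) + 1.0)
    gc = np.array([gc_content(c) for c in contigs], dtype=float)
    return np.hstack([
        tnf * np.sqrt(w_tnf),
        (logcov * np.sqrt(w_cov))[:, None],
        (gc * np.sqrt(w_gc))[:, None],
    ])


def feature_distance_matrix(contigs: Sequence[Contig],
                            weights: tuple[float, float, float] = DEFAULT_FEATURE_WEIGHTS,
                            ) -> np.ndarray:
    """Weighted Euclidean distance over (TNF, log10-coverage, GC)."""
    if len(contigs) < 2:
        raise InsufficientSequenceError("need at least two contigs")
    feats = feature_matrix(contigs, weights)
    return squareform(pdist(feats, metric="euclidean"))


def matrix_to_tsv(matrix: np.ndarray, ids: Sequence[str], path) -> None:
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def matrix_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
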