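"""CRISPR repeat-spacer array detection and repeat-type characterization.

Two independent detectors mirror the common two-predictor design used to
suppress false positives in environmental data:

* :func:`detect_arrays_seed` — seed-and-extend: exact k-mer seeds recurring
  at offsets compatible with one repeat+spacer period are chained into
  candidate regions, boundaries are refined by per-column consensus
  agreement across copies, and additional copies (whose seed was destroyed
  by mutation) are recovered by stepping a consensus probe along the array.
* :func:`detect_arrays_periodic` — autocorrelation: the sequence is scored
  for self-similarity against its translate at every lag in the
  repeat+spacer range; windows of high periodic self-match seed the same
  refinement machinery.

Arrays found by both detectors (reciprocal interval overlap) are retained
by :func:`consensus_arrays`; consensus repeats are clustered into unique
repeat types and matched against a motif-consensus database.

Coordinates are 0-based half-open throughout; the GFF3 writer converts to
1-based inclusive.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd
from Bio import Align

from .contig import Contig, reverse_complement
from .errors import ParameterError
from .seqprofile import _codes

_TIE_ORDER = "ACGT"  # consensus ties broken by fixed base order A<C<G<T


@dataclass
class CrisprParams:
    """Detection parameters; defaults bracket the ~35 nt repeat / ~34 nt
    spacer geometry observed in hot-spring CRISPR cassettes."""

    repeat_min: int = 21
    repeat_max: int = 48
    spacer_min: int = 20
    spacer_max: int = 60
    min_copies: int = 3
    seed_k: int = 8
    max_divergence: float = 0.3     # per-copy Hamming fraction vs consensus
    agree_frac: float = 0.7         # column agreement for boundary extension
    window_score: float = 0.75      # periodic detector: smoothed match score

    @property
    def period_min(self) -> int:
        return self.repeat_min + self.spacer_min

    @property
    def period_max(self) -> int:
        return self.repeat_max + self.spacer_max


DEFAULT_PARAMS = CrisprParams()


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus (0-based half-open interval)."""

    contig_id: str
    start: int
    end: int
    repeat_starts: list[int]
    consensus_repeat: str
    spacers: list[str]
    detector: str = ""

    @property
    def copies(self) -> int:
        return len(self.repeat_starts)

    @property
    def locus_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"

    def check(self, params: CrisprParams = DEFAULT_PARAMS) -> None:
        """Raise AssertionError on any structural invariant violation."""
        L = len(self.consensus_repeat)
        assert self.copies >= params.min_copies, "too few copies"
        assert len(self.spacers) == self.copies - 1, "spacer count"
        assert params.repeat_min <= L <= params.repeat_max, "repeat length"
        assert all(s1 < s2 for s1, s2 in zip(self.repeat_starts,
                                             self.repeat_starts[1:])), \
            "repeat starts not strictly increasing"
        for sp in self.spacers:
            assert params.spacer_min <= len(sp) <= params.spacer_max, \
                "spacer length"
        assert self.start <= self.repeat_starts[0]
        assert self.repeat_starts[-1] + L <= self.end


@dataclass
class RepeatType:
    type_id: str
    representative: str
    member_ids: list[str]
    member_consensi: list[str] = field(default_factory=list)
    per_sample_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class MotifAssignment:
    repeat_type_id: str
    motif_id: str          # "1".."33" or "novel"
    identity: float


# ---------------------------------------------------------------------------
# shared refinement machinery

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _column_stats(seq: str, anchors: Sequence[int], offset: int,
                  ) -> tuple[int, int, str]:
    """(modal count, n valid copies, modal base) at anchor+offset columns."""
    counts: Counter = Counter()
    for a in anchors:
        i = a + offset
        if 0 <= i < len(seq):
            counts[seq[i]] += 1
    if not counts:
        return 0, 0, "N"
    best = min(counts.items(), key=lambda kv: (-kv[1], _TIE_ORDER.find(kv[0])))
    return best[1], sum(counts.values()), best[0]


def _col_ok(modal: int, n: int, agree_frac: float) -> bool:
    if n < 2:
        return False
    if n == 2:
        return modal == 2
    if n <= 4:
        return modal >= n - 1
    return modal / n >= agree_frac


def _refine_boundaries(seq: str, anchors: Sequence[int], init_len: int,
                       params: CrisprParams) -> tuple[int, int]:
    """Extend/trim the repeat window around aligned anchors by column
    consensus agreement. Returns (left, right) offsets relative to the
    anchor positions, half-open."""
    max_len = params.repeat_max
    left, right = 0, min(init_len, max_len)
    # trim the initial window wherever its edge columns disagree
    while right - left > 1:
        modal, n, _ = _column_stats(seq, anchors, right - 1)
        if _col_ok(modal, n, params.agree_frac):
            break
        right -= 1
    while right - left > 1:
        modal, n, _ = _column_stats(seq, anchors, left)
        if _col_ok(modal, n, params.agree_frac):
            break
        left += 1
    # extend
    while right - left < max_len:
        modal, n, _ = _column_stats(seq, anchors, left - 1)
        if _col_ok(modal, n, params.agree_frac):
            left -= 1
            continue
        modal, n, _ = _column_stats(seq, anchors, right)
        if _col_ok(modal, n, params.agree_frac):
            right += 1
            continue
        break
    return left, right


def _consensus_of(seq: str, starts: Sequence[int], length: int) -> str:
    cols = []
    for o in range(length):
        _, _, base = _column_stats(seq, starts, o)
        cols.append(base)
    return "".join(cols)


def _step_copies(seq: str, consensus: str, start0: int,
                 params: CrisprParams) -> list[int]:
    """Collect all repeat starts by probing the consensus left and right of
    a known copy; each step searches the allowed spacer window and accepts
    the minimum-Hamming placement under the divergence cap."""
    L = len(consensus)
    max_mm = int(params.max_divergence * L)

    def best_in(lo: int, hi: int) -> int | None:
        best = None
        for c in range(max(0, lo), min(hi, len(seq) - L) + 1):
            mm = _hamming(seq[c:c + L], consensus)
            if mm <= max_mm and (best is None or mm < best[1]):
                best = (c, mm)
        return None if best is None else best[0]

    starts = [start0]
    cur = start0
    while True:
        nxt = best_in(cur + L + params.spacer_min, cur + L + params.spacer_max)
        if nxt is None:
            break
        starts.append(nxt)
        cur = nxt
    cur = start0
    while True:
        prv = best_in(cur - L - params.spacer_max, cur - L - params.spacer_min)
        if prv is None:
            break
        starts.append(prv)
        cur = prv
    return sorted(starts)


def _low_complexity(consensus: str, spacers: Sequence[str]) -> bool:
    """Suppress degenerate periodicity: near-homopolymer repeats, or
    'spacers' that are themselves copies of the repeat (tandem repeats)."""
    if len(set(consensus)) < 3:
        return True
    top = Counter(consensus).most_common(1)[0][1]
    if top / len(consensus) >= 0.9:
        return True
    if spacers:
        sims = [1 - _hamming(sp[:len(consensus)].ljust(len(consensus), "N"),
                             consensus) / len(consensus) for sp in spacers]
        if float(np.mean(sims)) >= 0.8:
            return True
    return False


def _build_array(contig: Contig, anchors0: Sequence[int], init_len: int,
                 params: CrisprParams, detector: str) -> CrisprArray | None:
    """Refine candidate anchors into a validated CrisprArray (or None)."""
    seq = contig.sequence.upper()
    anchors0 = sorted(set(anchors0))
    # two anchors within one period cannot both be true copy positions
    # (spacer can coincidentally contain the seed k-mer): keep the first
    filtered = []
    for a in anchors0:
        if not filtered or a - filtered[-1] >= params.period_min:
            filtered.append(a)
    anchors0 = filtered
    if len(anchors0) >= 3:
        left, right = _refine_boundaries(seq, anchors0, init_len, params)
        if right - left < max(params.seed_k, 8):
            return None
        probe = _consensus_of(seq, [a + left for a in anchors0], right - left)
        # re-anchor at the copy best matching the consensus probe, in case
        # an off-phase anchor survived the spacing filter; candidates must
        # lie fully inside the contig
        candidates = [a + left for a in anchors0
                      if 0 <= a + left <= len(seq) - (right - left)]
        if not candidates:
            return None
        start0 = min(candidates,
                     key=lambda s: _hamming(seq[s:s + len(probe)], probe))
    else:
        # too few anchors for a trustworthy column profile; phase-align the
        # probe window by maximizing pairwise matches between the two
        # anchored copies, then let stepping + a second refinement fix
        # boundaries
        a0 = anchors0[0]
        lag = anchors0[-1] - a0 if len(anchors0) > 1 else 0
        best_s = 0
        if lag > 0:
            best_m = -1
            for s in range(init_len):
                w1 = seq[a0 + s:a0 + s + init_len]
                w2 = seq[a0 + lag + s:a0 + lag + s + init_len]
                if len(w1) < init_len or len(w2) < init_len:
                    break
                m = sum(c1 == c2 for c1, c2 in zip(w1, w2))
                if m > best_m:
                    best_m, best_s = m, s
        probe = seq[a0 + best_s:a0 + best_s + init_len]
        start0 = a0 + best_s
    if len(probe) < 8:
        return None
    starts = _step_copies(seq, probe, start0, params)
    if len(starts) < params.min_copies:
        return None
    # second refinement with the full copy set
    left, right = _refine_boundaries(seq, starts, len(probe), params)
    L = right - left
    if not params.repeat_min <= L <= params.repeat_max:
        return None
    starts = [s + left for s in starts]
    # partial copies hanging over a contig edge are not countable copies
    starts = [s for s in starts if 0 <= s <= len(seq) - L]
    if len(starts) < params.min_copies:
        return None
    # drop terminal copies whose spacers fall outside the allowed range
    while len(starts) > 1 and not (
            params.spacer_min <= starts[1] - (starts[0] + L) <= params.spacer_max):
        starts.pop(0)
    while len(starts) > 1 and not (
            params.spacer_min <= starts[-1] - (starts[-2] + L) <= params.spacer_max):
        starts.pop()
    if len(starts) < params.min_copies:
        return None
    consensus = _consensus_of(seq, starts, L)
    spacers = [seq[a + L:b] for a, b in zip(starts, starts[1:])]
    if any(not (params.spacer_min <= len(sp) <= params.spacer_max)
           for sp in spacers):
        return None
    if _low_complexity(consensus, spacers):
        return None
    arr = CrisprArray(contig_id=contig.id, start=starts[0], end=starts[-1] + L,
                      repeat_starts=starts, consensus_repeat=consensus,
                      spacers=spacers, detector=detector)
    # per-copy divergence sanity: every copy within the cap of the consensus
    if any(_hamming(seq[s:s + L], consensus) > params.max_divergence * L
           for s in starts):
        return None
    return arr


def _dedupe(arrays: list[CrisprArray]) -> list[CrisprArray]:
    """Collapse overlapping detections on one contig, keeping more copies."""
    out: list[CrisprArray] = []
    for arr in sorted(arrays, key=lambda a: (-a.copies, a.start)):
        if all(_overlap(arr, kept) == 0 for kept in out):
            out.append(arr)
    return sorted(out, key=lambda a: a.start)


def _overlap(a: CrisprArray, b: CrisprArray) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


# ---------------------------------------------------------------------------
# detector 1: seed-and-extend

def detect_arrays_seed(contig: Contig,
                       params: CrisprParams = DEFAULT_PARAMS) -> list[CrisprArray]:
    """Seed-and-extend CRISPR detector (see module docstring)."""
    seq = contig.sequence.upper()
    k = params.seed_k
    if len(seq) < 2 * params.repeat_min + params.spacer_min:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer or len(set(kmer)) < 2:
            continue
        index[kmer].append(i)
    # anchor pairs at array-compatible offsets
    pairs: list[tuple[int, int, str]] = []
    for kmer, pos in index.items():
        if len(pos) < 2:
            continue
        for i, p in enumerate(pos):
            for q in pos[i + 1:]:
                d = q - p
                if d > params.period_max:
                    break
                if d >= params.period_min:
                    pairs.append((p, q, kmer))
    if not pairs:
        return []
    # merge anchor pairs into candidate regions
    pairs.sort()
    regions: list[list[tuple[int, int, str]]] = []
    cur: list[tuple[int, int, str]] = [pairs[0]]
    cur_end = pairs[0][1] + k
    for p, q, kmer in pairs[1:]:
        if p <= cur_end + params.period_max:
            cur.append((p, q, kmer))
            cur_end = max(cur_end, q + k)
        else:
            regions.append(cur)
            cur = [(p, q, kmer)]
            cur_end = q + k
    regions.append(cur)

    arrays: list[CrisprArray] = []
    for region in regions:
        lo = min(p for p, _, _ in region)
        hi = max(q for _, q, _ in region) + k
        # the k-mer with the most occurrences in the region anchors all
        # copies at one fixed offset within the repeat
        counts: Counter = Counter()
        for _, _, kmer in region:
            counts[kmer] += 0  # ensure key
        for kmer in counts:
            counts[kmer] = sum(1 for i in index[kmer] if lo <= i <= hi)
        best_kmer = min(counts, key=lambda km: (-counts[km], km))
        anchors0 = [i for i in index[best_kmer] if lo <= i <= hi]
        arr = _build_array(contig, anchors0, k, params, detector="seed")
        if arr is not None:
            arrays.append(arr)
    return _dedupe(arrays)


# ---------------------------------------------------------------------------
# detector 2: periodic self-similarity

def detect_arrays_periodic(contig: Contig,
                           params: CrisprParams = DEFAULT_PARAMS,
                           ) -> list[CrisprArray]:
    """Autocorrelation-style CRISPR detector (see module docstring)."""
    seq = contig.sequence.upper()
    n = len(seq)
    if n < 2 * params.repeat_min + params.spacer_min:
        return []
    x = _codes(seq)
    w = params.repeat_min
    kernel = np.ones(w) / w
    candidates: list[tuple[int, int, int]] = []  # (run_start, run_len, lag)
    for lag in range(params.period_min, min(params.period_max, n - w) + 1):
        m = ((x[:-lag] == x[lag:]) & (x[:-lag] >= 0)).astype(float)
        if len(m) < w:
            continue
        score = np.convolve(m, kernel, mode="valid")  # score[i]: window [i, i+w)
        hit = score >= params.window_score
        if not hit.any():
            continue
        idx = np.flatnonzero(hit)
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i > prev + 1:
                candidates.append((int(run_start), int(prev - run_start + 1), lag))
                run_start = i
            prev = i
        candidates.append((int(run_start), int(prev - run_start + 1), lag))
    if not candidates:
        return []
    # cluster candidate runs (any lag) that fall within one array's span
    candidates.sort()
    clusters: list[list[tuple[int, int, int]]] = []
    cur = [candidates[0]]
    cur_end = candidates[0][0] + candidates[0][1] + candidates[0][2]
    for c in candidates[1:]:
        if c[0] <= cur_end + params.period_max:
            cur.append(c)
            cur_end = max(cur_end, c[0] + c[1] + c[2])
        else:
            clusters.append(cur)
            cur = [c]
            cur_end = c[0] + c[1] + c[2]
    clusters.append(cur)

    arrays: list[CrisprArray] = []
    for cluster in clusters:
        # the dominant lag (largest total run length) estimates the period
        by_lag: Counter = Counter()
        for start, length, lag in cluster:
            by_lag[lag] += length
        lag = min(by_lag, key=lambda l: (-by_lag[l], l))
        runs = [c for c in cluster if c[2] == lag]
        anchor = min(r[0] for r in runs)
        arr = _build_array(contig, [anchor, anchor + lag], w, params,
                           detector="periodic")
        if arr is not None:
            arrays.append(arr)
    return _dedupe(arrays)


# ---------------------------------------------------------------------------
# consensus retention and characterization

def consensus_arrays(a: list[CrisprArray], b: list[CrisprArray],
                     overlap_frac: float = 0.5) -> list[CrisprArray]:
    """Retain arrays found by both detectors.

    An array from `a` is kept iff some array in `b` on the same contig
    overlaps it reciprocally by >= overlap_frac of each interval; the
    merged record takes the union interval and keeps the seed detector's
    repeat structure.
    """
    retained: list[CrisprArray] = []
    for arr in a:
        for other in b:
            if other.contig_id != arr.contig_id:
                continue
            ov = _overlap(arr, other)
            if ov >= overlap_frac * (arr.end - arr.start) and \
               ov >= overlap_frac * (other.end - other.start):
                retained.append(CrisprArray(
                    contig_id=arr.contig_id,
                    start=min(arr.start, other.start),
                    end=max(arr.end, other.end),
                    repeat_starts=list(arr.repeat_starts),
                    consensus_repeat=arr.consensus_repeat,
                    spacers=list(arr.spacers),
                    detector="consensus"))
                break
    return retained


def detect_consensus(contig: Contig,
                     params: CrisprParams = DEFAULT_PARAMS) -> list[CrisprArray]:
    """Run both detectors and keep the consistent arrays."""
    return consensus_arrays(detect_arrays_seed(contig, params),
                            detect_arrays_periodic(contig, params))


def consensus_repeat(array: CrisprArray, contig: Contig) -> str:
    """Per-column majority base over gapless, position-aligned repeat
    copies; ties broken by fixed base order A<C<G<T."""
    seq = contig.sequence.upper()
    L = len(array.consensus_repeat) if array.consensus_repeat else \
        array.end - array.repeat_starts[-1]
    return _consensus_of(seq, array.repeat_starts, L)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


def sequence_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Global-alignment identity (matches / alignment columns); optionally
    the better of forward and reverse-complement orientation."""
    def one(x: str, y: str) -> float:
        aln = _aligner.align(x, y)[0]
        counts = aln.counts()
        total = counts.identities + counts.mismatches + counts.gaps
        return counts.identities / total if total else 0.0

    ident = one(a, b)
    if both_strands:
        ident = max(ident, one(a, reverse_complement(b)))
    return ident


def cluster_repeat_types(arrays: Sequence[CrisprArray],
                         identity_threshold: float = 0.9,
                         samples: Mapping[str, str] | None = None,
                         ) -> list[RepeatType]:
    """Single-linkage clustering of arrays by consensus-repeat identity
    (best of forward and reverse complement)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(arrays)))
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if sequence_identity(arrays[i].consensus_repeat,
                                 arrays[j].consensus_repeat) >= identity_threshold:
                g.add_edge(i, j)
    types: list[RepeatType] = []
    comps = sorted(nx.connected_components(g), key=min)
    for t, comp in enumerate(comps, start=1):
        members = sorted(comp)
        consensi = [arrays[i].consensus_repeat for i in members]
        # medoid representative: max mean identity to the other members
        if len(members) == 1:
            rep = consensi[0]
        else:
            means = [np.mean([sequence_identity(c, d) for d in consensi])
                     for c in consensi]
            rep = consensi[int(np.argmax(means))]
        counts: Counter = Counter()
        for i in members:
            cid = arrays[i].contig_id
            counts[(samples or {}).get(cid, "NA")] += 1
        types.append(RepeatType(
            type_id=f"RT_{t:03d}", representative=rep,
            member_ids=[arrays[i].locus_id for i in members],
            member_consensi=consensi,
            per_sample_counts=dict(counts)))
    return types


def assign_motif(rt: RepeatType, motif_db: Sequence[tuple[str, str]],
                 threshold: float = 0.8) -> MotifAssignment:
    """Best global-alignment identity over the motif database (both
    orientations); assigned iff identity >= threshold, else "novel".
    Ties go to the lowest motif id."""
    if not motif_db:
        raise ParameterError("motif_db must be non-empty")

    def sort_key(mid: str):
        return (0, int(mid)) if str(mid).isdigit() else (1, str(mid))

    best_id, best_ident = None, -1.0
    for mid, consensus in sorted(motif_db, key=lambda e: sort_key(e[0])):
        ident = sequence_identity(rt.representative, consensus)
        if ident > best_ident:
            best_id, best_ident = str(mid), ident
    if best_ident >= threshold:
        return MotifAssignment(rt.type_id, best_id, best_ident)
    return MotifAssignment(rt.type_id, "novel", best_ident)


def read_motif_db(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return [(str(r[cols[0]]), str(r[cols[1]])) for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# writers

def write_gff3(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    """repeat_region feature per array, direct_repeat children (1-based)."""
    lines = ["##gff-version 3"]
    for n, arr in enumerate(arrays, start=1):
        rid = f"crispr{n}"
        L = len(arr.consensus_repeat)
        lines.append("\t".join([
            arr.contig_id, "thermavir", "repeat_region",
            str(arr.start + 1), str(arr.end), ".", ".", ".",
            f"ID={rid};copies={arr.copies};consensus={arr.consensus_repeat};"
            f"detector={arr.detector}"]))
        for i, s in enumerate(arr.repeat_starts, start=1):
            lines.append("\t".join([
                arr.contig_id, "thermavir", "direct_repeat",
                str(s + 1), str(s + L), ".", ".", ".",
                f"ID={rid}.r{i};Parent={rid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_spacer_fasta(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    recs = []
    for n, arr in enumerate(arrays, start=1):
        for i, sp in enumerate(arr.spacers, start=1):
            recs.append(f">crispr{n}_spacer{i} {arr.locus_id}\n{sp}")
    Path(path).write_text("\n".join(recs) + ("\n" if recs else ""))


def write_repeat_types(types: Sequence[RepeatType],
                       assignments: Sequence[MotifAssignment] | None,
                       path: str | Path) -> None:
    amap = {a.repeat_type_id: a for a in assignments or []}
    rows = []
    for rt in types:
        a = amap.get(rt.type_id)
        rows.append({
            "type_id": rt.type_id, "representative": rt.representative,
            "n_arrays": len(rt.member_ids),
            "members": ";".join(rt.member_ids),
            "per_sample": ";".join(f"{k}={v}" for k, v in
                                   sorted(rt.per_sample_counts.items())),
            "motif": a.motif_id if a else "",
            "motif_identity": round(a.identity, 4) if a else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
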