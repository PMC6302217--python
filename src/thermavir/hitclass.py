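"""Classification of queries from ranked homology-hit tables.

Implements the taxonomy voting rule used for environmental CRISPR arrays
(phylum assigned only when the top 10 hits are unanimous; class/family/
genus assigned when a strict majority of the top 30 hits agree) and the
best-hit screen used against the archaeal-virus database (best hit by bit
score after an 80% query-coverage cutoff), plus per-reference summaries.

Hits are rows of a 12-column blast-tabular file joined to a subject->
lineage table; query coverage is computed from the alignment span and the
query length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError, MappingError
from .synth import BLAST_COLUMNS, RANKS

VOTABLE_RANKS = ("class", "family", "genus")  # order is deliberately not votable


@dataclass
class Hit:
    query: str
    subject: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    coverage: float
    lineage: dict[str, str | None] = field(default_factory=dict)


@dataclass
class TaxonomyCall:
    query: str
    rank: str | None          # None => unassigned
    taxon: str                # taxon name or "unassigned"
    n_considered: int
    n_agreeing: int


@dataclass
class BBHRecord:
    query: str
    subject: str
    pident: float
    evalue: float
    bitscore: float


def _single_query(hits: Sequence[Hit]) -> str:
    queries = {h.query for h in hits}
    if len(queries) != 1:
        raise InputError(f"hits span {len(queries)} queries, expected one")
    return next(iter(queries))


def rank_hits(hits: Sequence[Hit]) -> list[Hit]:
    """Total order: bit score desc, then E-value asc, then subject id."""
    if hits:
        _single_query(hits)
    return sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject))


def vote_taxonomy(ranked: Sequence[Hit], phylum_window: int = 10,
                  deep_window: int = 30, min_hits: int = 10) -> TaxonomyCall:
    """Voting rule over ranked hits.

    Phylum: assigned iff the top min(phylum_window, n) hits carry one
    identical, non-missing phylum and n >= min_hits. Class/family/genus:
    assigned iff one taxon strictly exceeds 50% of the top
    min(deep_window, n) hits and n >= min_hits. The deepest assignable
    rank is reported; queries with fewer than min_hits hits (or a diverse
    top list) are unassigned. Missing labels never vote.
    """
    if not ranked:
        raise InputError("empty hit list")
    query = _single_query(ranked)
    n = len(ranked)
    best: TaxonomyCall | None = None
    if n >= min_hits:
        top = ranked[:min(phylum_window, n)]
        phyla = {h.lineage.get("phylum") for h in top}
        if len(phyla) == 1:
            (phylum,) = phyla
            if phylum:
                best = TaxonomyCall(query, "phylum", phylum, len(top), len(top))
        for rank in VOTABLE_RANKS:
            top = ranked[:min(deep_window, n)]
            counts: dict[str, int] = {}
            for h in top:
                taxon = h.lineage.get(rank)
                if taxon:
                    counts[taxon] = counts.get(taxon, 0) + 1
            if not counts:
                continue
            taxon, c = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            if c > len(top) / 2:
                best = TaxonomyCall(query, rank, taxon, len(top), c)
    if best is None:
        return TaxonomyCall(query, None, "unassigned", min(n, deep_window), 0)
    return best


def best_hit(hits: Sequence[Hit], coverage_cutoff: float = 80.0,
             ) -> BBHRecord | None:
    """Best hit after the query-coverage screen (cutoff is inclusive)."""
    if not hits:
        return None
    _single_query(hits)
    surviving = [h for h in hits if h.coverage >= coverage_cutoff]
    if not surviving:
        return None
    top = rank_hits(surviving)[0]
    return BBHRecord(top.query, top.subject, top.pident, top.evalue, top.bitscore)


def bbh_summary(records: Sequence[BBHRecord],
                subject_to_reference: Mapping[str, str],
                references: Sequence[str] | None = None) -> pd.DataFrame:
    """Per reference genome: number of queries whose BBH maps to it and the
    unweighted mean percent identity rounded to integer. References with no
    records get an empty identity cell."""
    for r in records:
        if r.subject not in subject_to_reference:
            raise MappingError(f"subject {r.subject!r} has no reference mapping")
    refs = list(references) if references is not None else \
        sorted(set(subject_to_reference.values()))
    by_ref: dict[str, list[float]] = {ref: [] for ref in refs}
    for r in records:
        by_ref.setdefault(subject_to_reference[r.subject], []).append(r.pident)
    rows = []
    for ref in refs:
        idents = by_ref[ref]
        rows.append({
            "reference": ref,
            "n_queries": len(idents),
            "mean_identity": int(round(sum(idents) / len(idents))) if idents
            else pd.NA,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

def load_hits(blast_path: str | Path, lineage_path: str | Path | None = None,
              query_lengths: Mapping[str, int] | None = None) -> list[Hit]:
    """Read a 12-column blast-tabular file (plus optional lineage TSV).

    Query coverage = 100*(qend-qstart+1)/query length; queries without a
    known length get coverage 0 (they then never pass the BBH screen).
    """
    df = pd.read_csv(blast_path, sep="\t", names=BLAST_COLUMNS, dtype={0: str, 1: str})
    return hits_from_frames(df, None if lineage_path is None
                            else pd.read_csv(lineage_path, sep="\t", dtype=str),
                            query_lengths)


def hits_from_frames(blast: pd.DataFrame, lineage: pd.DataFrame | None = None,
                     query_lengths: Mapping[str, int] | None = None) -> list[Hit]:
    lmap: dict[str, dict] = {}
    if lineage is not None:
        for _, row in lineage.iterrows():
            lmap[str(row["sseqid"])] = {
                r: (str(row[r]) if r in lineage.columns and pd.notna(row[r])
                    and str(row[r]) != "" else None)
                for r in RANKS}
    hits = []
    for _, row in blast.iterrows():
        q = str(row["qseqid"])
        qlen = (query_lengths or {}).get(q)
        span = int(row["qend"]) - int(row["qstart"]) + 1
        cov = 100.0 * span / qlen if qlen else 0.0
        hits.append(Hit(
            query=q, subject=str(row["sseqid"]), pident=float(row["pident"]),
            length=int(row["length"]), evalue=float(row["evalue"]),
            bitscore=float(row["bitscore"]), coverage=cov,
            lineage=lmap.get(str(row["sseqid"]), {})))
    return hits


def calls_to_frame(calls: Sequence[TaxonomyCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {"query": c.query, "rank": c.rank or "unassigned", "taxon": c.taxon,
         "n_considered": c.n_considered, "n_agreeing": c.n_agreeing}
        for c in calls])
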