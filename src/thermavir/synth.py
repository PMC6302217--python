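"""Synthetic metagenome generator with a full ground-truth manifest.

Emulates the statistical structure the downstream analysis assumes: host
genomes with distinct GC / tetranucleotide signatures, planted CRISPR
arrays (near-identical direct repeats separated by random spacers) and
prophage segments, phage genomes in the 24-200 kb size range, fragmentation
into coverage-annotated contigs, and ranked, lineage-labelled homology-hit
tables with controllable label noise. Every planted feature is recorded in
a :class:`GroundTruthManifest`, the oracle for all recovery tests.

Seeding contract: one master seed; each stage derives its own generator
from ``(seed, crc32(label))`` so adding a stage never perturbs the draws
of earlier stages.

Model choices (deliberately simple so oracles stay trivial): bases are
i.i.d. at the target GC, spacers are i.i.d. uniform over {A,C,G,T}, and
coverage follows a normal distribution truncated at zero.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .contig import Contig
from .errors import CapacityError, ManifestError, ParameterError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"

RANKS = ("phylum", "class", "order", "family", "genus")

#: small pool of realistic host lineages (phyla the study's CRISPR types map to)
LINEAGE_POOL: list[dict] = [
    {"phylum": "Proteobacteria", "class": "Betaproteobacteria",
     "order": "Burkholderiales", "family": "Burkholderiaceae", "genus": "Ralstonia"},
    {"phylum": "Proteobacteria", "class": "Gammaproteobacteria",
     "order": "Xanthomonadales", "family": "Xanthomonadaceae",
     "genus": "Pseudoxanthomonas"},
    {"phylum": "Proteobacteria", "class": "Betaproteobacteria",
     "order": "Rhodocyclales", "family": "Azonexaceae", "genus": "Dechloromonas"},
    {"phylum": "Firmicutes", "class": "Clostridia",
     "order": "Clostridiales", "family": "Clostridiaceae", "genus": "Clostridium"},
    {"phylum": "Chloroflexi", "class": "Chloroflexia",
     "order": "Chloroflexales", "family": "Oscillochloridaceae",
     "genus": "Oscillochloris"},
]

DECOY_POOL: list[dict] = [
    {"phylum": "Actinobacteria", "class": "Actinomycetia",
     "order": "Streptomycetales", "family": "Streptomycetaceae",
     "genus": "Streptomyces"},
    {"phylum": "Bacteroidetes", "class": "Bacteroidia",
     "order": "Bacteroidales", "family": "Bacteroidaceae", "genus": "Bacteroides"},
    {"phylum": "Euryarchaeota", "class": "Methanobacteria",
     "order": "Methanobacteriales", "family": "Methanobacteriaceae",
     "genus": "Methanobacterium"},
]


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Stage-local generator derived from the master seed and a stable label."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class GeneratorParams:
    """Knobs of the synthetic world.

    Defaults follow the study's stated geometry where it states one
    (repeat ~35 nt, spacer ~34 nt); GC/coverage defaults are chosen for
    testability since the study reports no such distributions.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_target: float = 0.5
    contig_length_mean: int = 10_000
    contig_length_sd: int = 2_000
    coverage_mean: float = 20.0
    coverage_sd: float = 5.0
    repeat_length: int = 35
    spacer_length: int = 34
    array_copies: int = 20
    repeat_mutation_rate: float = 0.01
    hit_noise_rate: float = 0.1

    def validate(self) -> None:
        for name in ("genome_length", "contig_length_mean", "contig_length_sd",
                     "repeat_length", "spacer_length", "array_copies"):
            v = getattr(self, name)
            if name == "contig_length_sd":
                if v < 0:
                    raise ParameterError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        for name in ("gc_target", "repeat_mutation_rate", "hit_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("coverage_mean", "coverage_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.array_footprint >= self.genome_length:
            raise ParameterError(
                "array_copies: array footprint "
                f"({self.array_footprint}) must be < genome_length "
                f"({self.genome_length})")

    @property
    def array_footprint(self) -> int:
        c, r, s = self.array_copies, self.repeat_length, self.spacer_length
        return c * r + (c - 1) * s


@dataclass
class PlantedArray:
    contig_id: str
    start: int
    end: int
    consensus: str
    copies: int
    repeat_starts: list[int] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    """Machine-readable record of every planted feature."""

    planted_arrays: list[PlantedArray] = field(default_factory=list)
    planted_prophages: list[dict] = field(default_factory=list)
    genome_origin: dict[str, dict] = field(default_factory=dict)
    true_orthologs: list[list[str]] = field(default_factory=list)

    def merge(self, other: "GroundTruthManifest") -> "GroundTruthManifest":
        return GroundTruthManifest(
            planted_arrays=self.planted_arrays + other.planted_arrays,
            planted_prophages=self.planted_prophages + other.planted_prophages,
            genome_origin={**self.genome_origin, **other.genome_origin},
            true_orthologs=self.true_orthologs + other.true_orthologs,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "planted_arrays": [asdict(a) for a in self.planted_arrays],
            "planted_prophages": self.planted_prophages,
            "genome_origin": self.genome_origin,
            "true_orthologs": self.true_orthologs,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "GroundTruthManifest":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            planted_arrays=[PlantedArray(**a) for a in d["planted_arrays"]],
            planted_prophages=d["planted_prophages"],
            genome_origin=d["genome_origin"],
            true_orthologs=[list(p) for p in d["true_orthologs"]],
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return bytes(_BASES[codes]).decode("ascii")


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-base substitution to a different base at `rate`."""
    if rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        base_code = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=len(idx))
        arr[idx] = _BASES[(base_code + shift) % 4]
    return bytes(arr).decode("ascii")


def generate_host_genome(params: GeneratorParams, genome_id: str = "host_1",
                         sample: str = "", lineage: Mapping[str, str] | None = None,
                         ) -> tuple[Contig, GroundTruthManifest]:
    """i.i.d.-base genome at the target GC, with its manifest entry."""
    params.validate()
    rng = stage_rng(params.seed, f"host:{genome_id}")
    seq = _random_sequence(rng, params.genome_length, params.gc_target)
    contig = Contig(genome_id, seq, sample=sample, coverage=params.coverage_mean)
    manifest = GroundTruthManifest(genome_origin={
        genome_id: {"genome": genome_id, "lineage": dict(lineage or {})}})
    return contig, manifest


def plant_crispr_array(genome: Contig, params: GeneratorParams, label: str = "array0",
                       ) -> tuple[Contig, GroundTruthManifest]:
    """Overwrite a seeded-random locus with a repeat-spacer array.

    `array_copies` copies of one consensus repeat (each independently
    point-mutated at `repeat_mutation_rate`) separated by independent
    uniform-random spacers of `spacer_length`. Genome length is unchanged.
    """
    params.validate()
    footprint = params.array_footprint
    if footprint > genome.length:
        raise CapacityError(
            f"array footprint {footprint} exceeds genome length {genome.length}")
    rng = stage_rng(params.seed, f"crispr:{genome.id}:{label}")
    pos = int(rng.integers(0, genome.length - footprint + 1))
    consensus = _random_sequence(rng, params.repeat_length, 0.5)
    parts: list[str] = []
    starts: list[int] = []
    cur = pos
    for i in range(params.array_copies):
        copy = _mutate(consensus, params.repeat_mutation_rate, rng)
        parts.append(copy)
        starts.append(cur)
        cur += params.repeat_length
        if i < params.array_copies - 1:
            parts.append(_random_sequence(rng, params.spacer_length, 0.5))
            cur += params.spacer_length
    segment = "".join(parts)
    seq = genome.sequence[:pos] + segment + genome.sequence[pos + footprint:]
    out = Contig(genome.id, seq, sample=genome.sample, coverage=genome.coverage)
    manifest = GroundTruthManifest(planted_arrays=[PlantedArray(
        contig_id=genome.id, start=pos, end=pos + footprint,
        consensus=consensus, copies=params.array_copies, repeat_starts=starts)])
    return out, manifest


def plant_prophage(host: Contig, phage_sequence: str, seed: int,
                   label: str = "prophage0",
                   ) -> tuple[Contig, GroundTruthManifest]:
    """Overwrite a seeded-random host locus with a phage-derived segment."""
    if len(phage_sequence) > host.length:
        raise CapacityError("prophage longer than host genome")
    rng = stage_rng(seed, f"prophage:{host.id}:{label}")
    pos = int(rng.integers(0, host.length - len(phage_sequence) + 1))
    seq = (host.sequence[:pos] + phage_sequence
           + host.sequence[pos + len(phage_sequence):])
    out = Contig(host.id, seq, sample=host.sample, coverage=host.coverage)
    manifest = GroundTruthManifest(planted_prophages=[
        {"contig_id": host.id, "start": pos, "end": pos + len(phage_sequence)}])
    return out, manifest


def generate_phage_set(n: int, gc_targets: Sequence[float],
                       length_range: tuple[int, int] = (24_000, 200_000),
                       seed: int = 0, sample: str = "",
                       ) -> tuple[list[Contig], GroundTruthManifest]:
    """n phage genomes, round-robin over gc_targets, lengths uniform in range.

    The default length range follows the observed genome sizes of the
    reconstructed bacteriophages (24-200 kb).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not gc_targets:
        raise ParameterError("gc_targets must be non-empty")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ParameterError(f"length_range invalid: {length_range}")
    phages: list[Contig] = []
    manifest = GroundTruthManifest()
    for i in range(n):
        gc = float(gc_targets[i % len(gc_targets)])
        if not 0 <= gc <= 1:
            raise ParameterError(f"gc_targets[{i % len(gc_targets)}] not in [0,1]")
        rng = stage_rng(seed, f"phage:{i}")
        length = int(rng.integers(lo, hi + 1))
        pid = f"phage_{i + 1:03d}"
        phages.append(Contig(pid, _random_sequence(rng, length, gc), sample=sample))
        manifest.genome_origin[pid] = {
            "genome": pid, "lineage": {}, "gc_target": gc}
    return phages, manifest


def fragment_to_contigs(genome: Contig, params: GeneratorParams,
                        lineage: Mapping[str, str] | None = None,
                        ) -> tuple[list[Contig], GroundTruthManifest]:
    """Tile the genome with non-overlapping fragments.

    Schedule (relied on by the replay oracle in tests): fragments are cut
    left to right; for each fragment first its length is drawn
    (round(N(mean, sd)), floored at 1, truncated at the genome end), then
    its coverage (normal truncated at 0; exactly `coverage_mean` if sd=0).
    """
    params.validate()
    if params.contig_length_mean >= genome.length:
        raise ParameterError("contig_length_mean must be < genome length")
    rng = stage_rng(params.seed, f"frag:{genome.id}")
    contigs: list[Contig] = []
    manifest = GroundTruthManifest()
    pos, i = 0, 0
    while pos < genome.length:
        if params.contig_length_sd > 0:
            length = max(1, int(round(rng.normal(params.contig_length_mean,
                                                 params.contig_length_sd))))
        else:
            length = params.contig_length_mean
        length = min(length, genome.length - pos)
        if params.coverage_sd > 0:
            a = (0.0 - params.coverage_mean) / params.coverage_sd
            cov = float(truncnorm.rvs(a, np.inf, loc=params.coverage_mean,
                                      scale=params.coverage_sd, random_state=rng))
        else:
            cov = params.coverage_mean
        i += 1
        cid = f"{genome.id}_c{i:03d}"
        contigs.append(Contig(cid, genome.sequence[pos:pos + length],
                              sample=genome.sample, coverage=cov))
        manifest.genome_origin[cid] = {
            "genome": genome.id, "lineage": dict(lineage or {}),
            "start": pos, "end": pos + length}
        pos += length
    return contigs, manifest


BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

LINEAGE_COLUMNS = ["sseqid"] + list(RANKS)


def synthesize_hit_table(truth: GroundTruthManifest, n_hits_per_query: int,
                         params: GeneratorParams,
                         queries: Sequence[str] | None = None,
                         query_lengths: Mapping[str, int] | None = None,
                         decoy_pool: Sequence[Mapping[str, str]] | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked 12-column blast-tabular hits plus a subject->lineage table.

    Per query: strictly decreasing bit scores, non-decreasing E-values,
    identities in [30,100], query coverage in [50,100]. Each hit's lineage
    is the query's true lineage except with probability `hit_noise_rate`,
    when it is resampled from the decoy pool.
    """
    params.validate()
    if n_hits_per_query < 1:
        raise ParameterError("n_hits_per_query must be >= 1")
    decoys = list(decoy_pool) if decoy_pool is not None else list(DECOY_POOL)
    if queries is None:
        queries = sorted(truth.genome_origin)
    rows: list[dict] = []
    lineage_rows: list[dict] = []
    for q in queries:
        if q not in truth.genome_origin:
            raise ManifestError(f"query {q!r} not in manifest")
        rng = stage_rng(params.seed, f"hits:{q}")
        true_lin = truth.genome_origin[q].get("lineage", {}) or {}
        qlen = int((query_lengths or {}).get(q, 1000))
        bits = float(rng.uniform(150, 400))
        for r in range(n_hits_per_query):
            sid = f"subj_{q}_{r + 1:03d}"
            noisy = bool(rng.random() < params.hit_noise_rate)
            lin = dict(decoys[int(rng.integers(0, len(decoys)))]) if noisy \
                else dict(true_lin)
            pident = float(rng.uniform(30, 100))
            cov = float(rng.uniform(50, 100))
            qstart = 1
            qend = max(1, int(round(cov / 100 * qlen)))
            alen = qend - qstart + 1
            rows.append({
                "qseqid": q, "sseqid": sid, "pident": round(pident, 2),
                "length": alen,
                "mismatch": int(round(alen * (1 - pident / 100))),
                "gapopen": 0, "qstart": qstart, "qend": qend,
                "sstart": 1, "send": alen,
                "evalue": float(f"{10 ** (-bits / 10):.3e}"),
                "bitscore": round(bits, 1),
            })
            lineage_rows.append({"sseqid": sid, **{k: lin.get(k, "") for k in RANKS},
                                 "_noisy": noisy})
            bits -= float(rng.uniform(0.5, 5.0))
    hits = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    lineage = pd.DataFrame(lineage_rows, columns=LINEAGE_COLUMNS + ["_noisy"])
    return hits, lineage


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def write_lineage(lineage: pd.DataFrame, path: str | Path) -> None:
    lineage[LINEAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def generate_proteome_pair(n_shared: int, n_unique: int, length: int,
                           mutation_rate: float, seed: int = 0,
                           prefix_a: str = "A", prefix_b: str = "B",
                           ) -> tuple[dict[str, str], dict[str, str],
                                      GroundTruthManifest]:
    """Two protein sets sharing `n_shared` point-mutated ortholog pairs.

    Shared proteins in set B are per-residue mutated copies of their A
    counterparts at `mutation_rate`; `n_unique` unrelated random proteins
    are added to each set. True pairs go to the manifest.
    """
    if n_shared < 0 or n_unique < 0 or length <= 0:
        raise ParameterError("n_shared/n_unique must be >= 0, length > 0")
    rng = stage_rng(seed, "proteome")
    aa = np.frombuffer(_AA.encode(), dtype=np.uint8)

    def rand_protein(n: int) -> str:
        return bytes(aa[rng.integers(0, len(aa), size=n)]).decode()

    def mutate_protein(p: str) -> str:
        out = list(p)
        for i in range(len(out)):
            if rng.random() < mutation_rate:
                out[i] = _AA[int(rng.integers(0, len(_AA)))]
        return "".join(out)

    a: dict[str, str] = {}
    b: dict[str, str] = {}
    manifest = GroundTruthManifest()
    for i in range(n_shared):
        pa, pb = f"{prefix_a}_orth{i + 1:03d}", f"{prefix_b}_orth{i + 1:03d}"
        seq = rand_protein(length)
        a[pa] = seq
        b[pb] = mutate_protein(seq)
        manifest.true_orthologs.append([pa, pb])
    for i in range(n_unique):
        a[f"{prefix_a}_uniq{i + 1:03d}"] = rand_protein(length)
        b[f"{prefix_b}_uniq{i + 1:03d}"] = rand_protein(length)
    return a, b, manifest
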