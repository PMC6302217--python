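"""End-to-end orchestration: simulate -> profile -> bin -> crispr ->
classify -> compare.

Configuration is a single YAML file with per-stage blocks and toggles;
every effective parameter and seed is echoed to the run log so the many
scattered cutoffs (>10 kb, 80% coverage, 1e-15/0.5, word 10, p<0.05) are
auditable in one place. Runs are deterministic under a fixed master seed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import binning, compare, crispr, hitclass, seqprofile, synth
from .contig import Contig, write_fasta, write_metadata
from .errors import ParameterError

log = logging.getLogger("thermavir")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "thermavir_run",
    "stages": {"simulate": True, "profile": True, "bin": True,
               "crispr": True, "classify": True, "compare": True},
    "simulate": {
        "samples": ["MM", "MnS"],
        "hosts_per_sample": 2,
        "host_gc": [0.35, 0.65],
        "genome_length": 60_000,
        "contig_length_mean": 12_000,
        "contig_length_sd": 1_500,
        "coverage_mean": 20.0,
        "coverage_sd": 5.0,
        "arrays_per_host": 1,
        "repeat_length": 35,
        "spacer_length": 34,
        "array_copies": 10,
        "repeat_mutation_rate": 0.01,
        "phages_per_sample": 3,
        "phage_gc": [0.35, 0.65],
        # subset of the observed 24-200 kb phage size range, kept small so a
        # full run stays cheap; widen for realism
        "phage_length_range": [24_000, 48_000],
        "n_hits_per_query": 30,
        "hit_noise_rate": 0.1,
    },
    "bin": {"min_length": 10_000, "k": "auto"},
    "crispr": {"min_copies": 3, "repeat_min": 21, "repeat_max": 48,
               "spacer_min": 20, "spacer_max": 60, "type_identity": 0.9},
    "classify": {"coverage_cutoff": 80.0},
    "compare": {"edge_threshold": 0.5, "run_similarity": False,
                "word": 10},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict[str, Any]) -> "RunConfig":
        data = copy.deepcopy(DEFAULT_CONFIG)
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(data.get(key), dict):
                data[key].update(value)
            else:
                data[key] = value
        cfg = cls(data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        sim = self.data["simulate"]
        if not sim["samples"]:
            raise ParameterError("simulate.samples must be non-empty")
        synth.GeneratorParams(
            seed=int(self.data["seed"]),
            genome_length=int(sim["genome_length"]),
            contig_length_mean=int(sim["contig_length_mean"]),
            contig_length_sd=int(sim["contig_length_sd"]),
            coverage_mean=float(sim["coverage_mean"]),
            coverage_sd=float(sim["coverage_sd"]),
            repeat_length=int(sim["repeat_length"]),
            spacer_length=int(sim["spacer_length"]),
            array_copies=int(sim["array_copies"]),
            repeat_mutation_rate=float(sim["repeat_mutation_rate"]),
            hit_noise_rate=float(sim["hit_noise_rate"]),
        ).validate()

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


@dataclass
class CommunityData:
    contigs: list[Contig]
    phages: list[Contig]
    manifest: synth.GroundTruthManifest
    hits: pd.DataFrame
    lineage: pd.DataFrame


def simulate_community(config: RunConfig) -> CommunityData:
    """Build the synthetic community the downstream stages consume."""
    sim = config["simulate"]
    seed = int(config["seed"])
    manifest = synth.GroundTruthManifest()
    contigs: list[Contig] = []
    phages: list[Contig] = []
    for s_idx, sample in enumerate(sim["samples"]):
        for h_idx in range(int(sim["hosts_per_sample"])):
            gc = float(sim["host_gc"][h_idx % len(sim["host_gc"])])
            lineage = synth.LINEAGE_POOL[
                (s_idx * int(sim["hosts_per_sample"]) + h_idx)
                % len(synth.LINEAGE_POOL)]
            params = synth.GeneratorParams(
                seed=seed,
                genome_length=int(sim["genome_length"]),
                gc_target=gc,
                contig_length_mean=int(sim["contig_length_mean"]),
                contig_length_sd=int(sim["contig_length_sd"]),
                coverage_mean=float(sim["coverage_mean"]),
                coverage_sd=float(sim["coverage_sd"]),
                repeat_length=int(sim["repeat_length"]),
                spacer_length=int(sim["spacer_length"]),
                array_copies=int(sim["array_copies"]),
                repeat_mutation_rate=float(sim["repeat_mutation_rate"]),
                hit_noise_rate=float(sim["hit_noise_rate"]),
            )
            gid = f"{sample}_host{h_idx + 1}"
            genome, _ = synth.generate_host_genome(params, gid, sample=sample,
                                                   lineage=lineage)
            genome_manifest = synth.GroundTruthManifest()
            for a_idx in range(int(sim["arrays_per_host"])):
                genome, m = synth.plant_crispr_array(genome, params,
                                                     label=f"array{a_idx}")
                genome_manifest = genome_manifest.merge(m)
            frags, m = synth.fragment_to_contigs(genome, params, lineage=lineage)
            # planted-array coordinates refer to the unfragmented genome;
            # remap onto the fragment carrying each array
            manifest = manifest.merge(_remap_arrays(m, genome_manifest, gid))
            contigs.extend(frags)
            manifest.genome_origin.update(m.genome_origin)
        sample_phages, m = synth.generate_phage_set(
            n=int(sim["phages_per_sample"]),
            gc_targets=[float(x) for x in sim["phage_gc"]],
            length_range=tuple(int(x) for x in sim["phage_length_range"]),
            seed=seed + s_idx + 1, sample=sample)
        renamed = []
        for ph in sample_phages:
            pid = f"{sample}_{ph.id}"
            manifest.genome_origin[pid] = m.genome_origin[ph.id]
            manifest.genome_origin[pid]["genome"] = pid
            renamed.append(Contig(pid, ph.sequence, sample=sample,
                                  coverage=ph.coverage))
        phages.extend(renamed)
    params = synth.GeneratorParams(seed=seed,
                                   hit_noise_rate=float(sim["hit_noise_rate"]))
    qlens = {c.id: c.length for c in contigs}
    hits, lineage = synth.synthesize_hit_table(
        manifest, int(sim["n_hits_per_query"]), params,
        queries=sorted(qlens), query_lengths=qlens)
    return CommunityData(contigs, phages, manifest, hits, lineage)


def _remap_arrays(frag_manifest: synth.GroundTruthManifest,
                  manifest: synth.GroundTruthManifest,
                  genome_id: str, min_copies: int = 3,
                  ) -> synth.GroundTruthManifest:
    """Translate whole-genome planted-array coordinates to fragment-local
    ones. An array split across a fragment boundary is recorded for every
    fragment that retains at least `min_copies` complete repeat copies
    (those remnants are still detectable arrays); remnants below that are
    dropped — they are not recoverable from any single contig."""
    out = synth.GroundTruthManifest()
    frags = [(cid, o["start"], o["end"])
             for cid, o in frag_manifest.genome_origin.items()
             if o["genome"] == genome_id]
    for arr in manifest.planted_arrays:
        if arr.contig_id != genome_id:
            continue
        rep_len = len(arr.consensus)
        for cid, fs, fe in frags:
            kept = [s for s in arr.repeat_starts
                    if s >= fs and s + rep_len <= fe]
            if len(kept) < min_copies:
                continue
            out.planted_arrays.append(synth.PlantedArray(
                contig_id=cid, start=kept[0] - fs,
                end=kept[-1] + rep_len - fs,
                consensus=arr.consensus, copies=len(kept),
                repeat_starts=[s - fs for s in kept]))
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "FAILED").unlink(missing_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stages = config["stages"]
    report: dict[str, Any] = {"seed": config["seed"], "stages_run": []}
    try:
        log.info("effective config: %s", config.data)
        community = simulate_community(config)
        if stages.get("simulate", True):
            write_fasta(community.contigs, outdir / "contigs.fasta")
            write_fasta(community.phages, outdir / "phages.fasta")
            write_metadata(community.contigs + community.phages,
                           outdir / "contigs.tsv")
            synth.write_hit_table(community.hits, outdir / "hits.tsv")
            synth.write_lineage(community.lineage, outdir / "lineage.tsv")
            community.manifest.to_json(outdir / "manifest.json")
            report["stages_run"].append("simulate")

        if stages.get("profile", True):
            ids = [c.id for c in community.phages]
            corr = seqprofile.correlation_matrix(
                [seqprofile.tnf_vector(c) for c in community.phages], ids=ids)
            seqprofile.matrix_to_tsv(corr, ids, outdir / "phage_tnf_corr.tsv")
            report["stages_run"].append("profile")

        if stages.get("bin", True):
            bcfg = config["bin"]
            assignment = binning.bin_contigs(
                community.contigs, min_length=int(bcfg["min_length"]),
                k=bcfg["k"])
            binning.assignment_to_frame(assignment).to_csv(
                outdir / "bins.tsv", sep="\t", index=False)
            assignment.summary.to_csv(outdir / "bin_summary.tsv", sep="\t",
                                      index=False)
            report["n_bins"] = len(assignment.summary)
            report["stages_run"].append("bin")

        arrays_by_sample: dict[str, int] = {}
        if stages.get("crispr", True):
            ccfg = config["crispr"]
            params = crispr.CrisprParams(
                repeat_min=int(ccfg["repeat_min"]),
                repeat_max=int(ccfg["repeat_max"]),
                spacer_min=int(ccfg["spacer_min"]),
                spacer_max=int(ccfg["spacer_max"]),
                min_copies=int(ccfg["min_copies"]))
            retained: list[crispr.CrisprArray] = []
            samples: dict[str, str] = {}
            for c in community.contigs:
                retained.extend(crispr.detect_consensus(c, params))
                samples[c.id] = c.sample
            crispr.write_gff3(retained, outdir / "crispr.gff3")
            crispr.write_spacer_fasta(retained, outdir / "spacers.fasta")
            types = crispr.cluster_repeat_types(
                retained, identity_threshold=float(ccfg["type_identity"]),
                samples=samples)
            crispr.write_repeat_types(types, None, outdir / "repeat_types.tsv")
            for arr in retained:
                arrays_by_sample[samples[arr.contig_id]] = \
                    arrays_by_sample.get(samples[arr.contig_id], 0) + 1
            report["n_crispr_arrays"] = len(retained)
            report["n_repeat_types"] = len(types)
            report["stages_run"].append("crispr")

        if stages.get("classify", True):
            kcfg = config["classify"]
            qlens = {c.id: c.length for c in community.contigs}
            hits = hitclass.hits_from_frames(community.hits, community.lineage,
                                             query_lengths=qlens)
            by_query: dict[str, list[hitclass.Hit]] = {}
            for h in hits:
                by_query.setdefault(h.query, []).append(h)
            calls, bbhs = [], []
            for q in sorted(by_query):
                ranked = hitclass.rank_hits(by_query[q])
                calls.append(hitclass.vote_taxonomy(ranked))
                bbh = hitclass.best_hit(ranked,
                                        float(kcfg["coverage_cutoff"]))
                if bbh is not None:
                    bbhs.append(bbh)
            hitclass.calls_to_frame(calls).to_csv(
                outdir / "taxonomy_calls.tsv", sep="\t", index=False)
            ref_map = {r.subject: r.subject.rsplit("_", 1)[0] for r in bbhs}
            hitclass.bbh_summary(bbhs, ref_map).to_csv(
                outdir / "bbh_summary.tsv", sep="\t", index=False)
            report["n_taxonomy_calls"] = sum(1 for c in calls if c.rank)
            report["stages_run"].append("classify")

        if stages.get("compare", True):
            mcfg = config["compare"]
            net = compare.tnf_network(community.phages,
                                      edge_threshold=float(mcfg["edge_threshold"]))
            compare.network_to_edge_frame(net).to_csv(
                outdir / "phage_network_edges.tsv", sep="\t", index=False)
            if mcfg.get("run_similarity", False):
                groups = {c.id: c.sample for c in community.phages}
                compare.group_similarity(community.phages, groups).to_csv(
                    outdir / "group_similarity.tsv", sep="\t", index=False)
            report["n_network_edges"] = net.number_of_edges()
            report["stages_run"].append("compare")

        # Table-1-shaped summary: per sample, contig / cassette / phage counts
        rows = []
        for sample in config["simulate"]["samples"]:
            rows.append({
                "sample": sample,
                "n_contigs": sum(1 for c in community.contigs
                                 if c.sample == sample),
                "crispr_cassettes": arrays_by_sample.get(sample, 0),
                "phage_genomes": sum(1 for p in community.phages
                                     if p.sample == sample),
            })
        summary = pd.DataFrame(rows)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        report["summary"] = summary
        log.info("pipeline complete: %s", report["stages_run"])
        return report
    except Exception as exc:  # pragma: no cover - failure path
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
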