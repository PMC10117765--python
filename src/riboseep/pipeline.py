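"""Stage orchestration: simulate -> coverage -> quantify -> metagene ->
call-sorfs -> build-db -> classify-peptides -> accept.

Each stage reads its inputs from and writes plain-text outputs (TSV,
FASTA, GFF3, bedGraph, JSON) into one output directory, so stages can be
re-run individually or chained with ``run_all``.  A manifest (config
echo, seed, output hashes) makes every run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import coverage as cov
from . import iptgxdb, metagene, peptide_evidence, quantify, sorf_call
from . import synthetic_data as sim
from .genome_io import FeatureRecord, read_fasta, write_fasta, write_gff

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]


@dataclass
class PipelineConfig:
    out_dir: str = "riboseep_out"
    seed: int = 0
    simulation: sim.SimConfig = None
    thresholds: sorf_call.Thresholds = None
    curation: sorf_call.CurationParams = None
    proteases: tuple[str, ...] = ("trypsin", "lysC", "none")
    max_missed_cleavages: int = 2

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = sim.SimConfig(seed=self.seed)
        if self.thresholds is None:
            self.thresholds = sorf_call.Thresholds()
        if self.curation is None:
            self.curation = sorf_call.CurationParams()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in ("out_dir", "seed", "proteases", "max_missed_cleavages"):
            if key in raw:
                kwargs[key] = raw[key]
        if "simulation" in raw:
            kwargs["simulation"] = sim.SimConfig(**raw["simulation"])
        if "thresholds" in raw:
            kwargs["thresholds"] = sorf_call.Thresholds(**raw["thresholds"])
        if "curation" in raw:
            kwargs["curation"] = sorf_call.CurationParams(**raw["curation"])
        config = cls(**kwargs)
        if "simulation" not in raw:
            config.simulation = sim.SimConfig(seed=config.seed)
        return config

    def echo(self) -> dict:
        d = asdict(self)
        return d


class _Ctx:
    """Lazy access to stage inputs living in the output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # cached loaders -------------------------------------------------------
    def replicons(self):
        return read_fasta(self.out / "genome.fasta")

    def replicon_lengths(self):
        return {r.id: r.length for r in self.replicons()}

    def truth(self):
        return pd.read_csv(self.out / "truth.tsv", sep="\t",
                           keep_default_na=False)

    def reads(self):
        return sim.read_reads_tsv(self.out / "reads.tsv")

    def quants(self):
        return pd.read_csv(self.out / "quant.tsv", sep="\t")

    def sample_pairs(self):
        n = self.config.simulation.n_replicates
        return [(f"ribo_{i}", f"rna_{i}") for i in range(1, n + 1)]

    def truth_features(self):
        truth = self.truth()
        feats = []
        for row in truth.itertuples():
            fclass = sim._TRUTH_TO_ANNOT.get(row.feature_class, "other")
            feats.append(FeatureRecord(
                feature_id=row.feature_id, replicon_id=row.replicon_id,
                strand=row.strand, start=row.start, end=row.end,
                feature_class=fclass if row.feature_class != "decoy_sORF"
                else "other",
            ))
        return feats


def stage_simulate(ctx: _Ctx) -> None:
    cfg = ctx.config.simulation
    replicons, annotation, truth = sim.make_genome(cfg)
    write_fasta(replicons, ctx.out / "genome.fasta")
    write_gff(annotation, ctx.out / "truth_annotation.gff3")
    truth.to_csv(ctx.out / "truth.tsv", sep="\t", index=False)
    reads = sim.simulate_reads(truth, cfg,
                               {r.id: r.length for r in replicons})
    sim.write_reads_tsv(reads, ctx.out / "reads.tsv")
    candidates = sim.make_candidate_table(truth, cfg)
    candidates.to_csv(ctx.out / "candidates.tsv", sep="\t", index=False)
    for source in sim.split_annotation_sources(truth, replicons, cfg):
        write_gff(source, ctx.out / f"{source.source_name}.gff3")
    for protease in ctx.config.proteases:
        psms = sim.simulate_psms(truth, protease, cfg)
        psms.to_csv(ctx.out / f"psms_{protease}.tsv", sep="\t", index=False)


def stage_coverage(ctx: _Ctx) -> None:
    reads = ctx.reads()
    lengths = ctx.replicon_lengths()
    tracks = []
    for sample in sorted(reads["sample_id"].unique()):
        library = reads.loc[reads["sample_id"] == sample, "library"].iloc[0]
        tracks.append(cov.build_coverage(reads, lengths, "global",
                                         sample_id=sample, library=library))
    for track in cov.normalize_min(tracks):
        cov.write_bedgraph(track, ctx.out / "coverage")


def stage_quantify(ctx: _Ctx) -> None:
    table = quantify.quantify_features(
        ctx.truth_features(), ctx.reads(), ctx.sample_pairs())
    table.to_csv(ctx.out / "quant.tsv", sep="\t", index=False)
    summary = quantify.class_te_summary(table)
    summary.rename("mean_te").to_csv(ctx.out / "class_te.tsv", sep="\t")


def stage_metagene(ctx: _Ctx) -> None:
    reads = ctx.reads()
    lengths = ctx.replicon_lengths()
    cds = [f for f in ctx.truth_features() if f.feature_class == "CDS"]
    ribo = reads[reads["library"] == "RIBO"]
    for mode in ("five_prime", "three_prime"):
        track = cov.build_coverage(ribo, lengths, mode)
        profile = metagene.metagene_profile(track, cds)
        metagene.profile_table(profile).to_csv(
            ctx.out / f"metagene_{mode}.tsv", sep="\t", index=False)
    scores = metagene.length_stratified_enrichment(ribo, cds, lengths)
    scores.rename_axis("footprint_length").rename("enrichment").to_csv(
        ctx.out / "metagene_length_enrichment.tsv", sep="\t")


def stage_call_sorfs(ctx: _Ctx) -> None:
    config = ctx.config
    truth = ctx.truth()
    quants = ctx.quants()
    reads = ctx.reads()
    lengths = ctx.replicon_lengths()

    annotated = truth[truth["feature_class"] == "sORF"]["feature_id"]
    annotated_calls = sorf_call.filter_annotated_sorfs(
        quants, annotated, config.thresholds)

    candidates = pd.read_csv(ctx.out / "candidates.tsv", sep="\t")
    candidates = candidates.rename(columns={"truth_id": "quant_id"})
    candidates = sorf_call.select_primary_candidates(candidates)
    active = candidates[~candidates["shadowed"]]
    novel_calls = sorf_call.filter_novel_candidates(
        quants, active, config.thresholds)

    ribo_tracks = [cov.build_coverage(reads, lengths, "global", sample_id=s,
                                      library="RIBO")
                   for s, _ in ctx.sample_pairs()]
    rna_tracks = [cov.build_coverage(reads, lengths, "global", sample_id=s,
                                     library="RNA")
                  for _, s in ctx.sample_pairs()]
    normalized = cov.normalize_min(ribo_tracks + rna_tracks)
    ribo = _merge_tracks(normalized[: len(ribo_tracks)])
    rna = _merge_tracks(normalized[len(ribo_tracks):])

    features = {}
    transcripts = {}
    exclusions = {}
    # annotated coding intervals per (replicon, strand): a curator
    # discounts neighbouring genes when judging an operon-internal sORF
    coding = {}
    for f in ctx.truth_features():
        if f.feature_class in ("CDS", "sORF"):
            coding.setdefault((f.replicon_id, f.strand), []).append(
                (f.start, f.end))
    by_truth = truth.set_index("feature_id")
    for cand in active.itertuples():
        row = by_truth.loc[cand.quant_id]
        features[cand.candidate_id] = FeatureRecord(
            feature_id=cand.candidate_id, replicon_id=cand.replicon_id,
            strand=cand.strand, start=cand.start, end=cand.end,
            feature_class="sORF")
        t_lo, t_hi = int(row["transcript_start"]), int(row["transcript_end"])
        transcripts[cand.candidate_id] = (t_lo, t_hi)
        exclusions[cand.candidate_id] = [
            (lo, hi) for lo, hi in coding.get(
                (cand.replicon_id, cand.strand), [])
            if lo < t_hi and hi > t_lo and (lo, hi) != (cand.start, cand.end)
        ]
    novel_calls = sorf_call.apply_curation(
        novel_calls, features, ribo, rna, config.curation, transcripts,
        exclusions)

    annotated_calls.to_csv(ctx.out / "annotated_sorf_calls.tsv", sep="\t",
                           index=False)
    novel_calls.to_csv(ctx.out / "novel_sorf_calls.tsv", sep="\t", index=False)

    passing_ids = set(novel_calls.loc[
        novel_calls["verdict"] == "translated_high_confidence", "candidate_id"])
    passing = [features[cid] for cid in sorted(passing_ids)]
    if passing:
        summaries = sorf_call.summarize_sorfs(passing, ctx.replicons())
        for name, series in summaries.items():
            series.to_csv(ctx.out / f"summary_{name}.tsv", sep="\t")
    passing_df = active[active["candidate_id"].isin(passing_ids)]
    passing_df.to_csv(ctx.out / "passing_candidates.tsv", sep="\t", index=False)


def _merge_tracks(tracks):
    """Sum replicate tracks position-wise (after min normalization)."""
    merged = tracks[0]
    for other in tracks[1:]:
        for key in merged.arrays:
            merged.arrays[key] = merged.arrays[key] + other.arrays[key]
    return merged


def _load_sources(ctx: _Ctx):
    from .genome_io import read_gff

    lengths = ctx.replicon_lengths()
    sources = []
    for name, rank in (("genbank_sim", 1), ("refseq_sim", 2)):
        path = ctx.out / f"{name}.gff3"
        if path.exists():
            sources.append(read_gff(path, name, rank,
                                    replicon_lengths=lengths))
    return sources


def _riboseq_set(ctx: _Ctx):
    from .genome_io import AnnotationSet

    path = ctx.out / "passing_candidates.tsv"
    passing = pd.read_csv(path, sep="\t")
    features = [
        FeatureRecord(
            feature_id=row.candidate_id, replicon_id=row.replicon_id,
            strand=row.strand, start=row.start, end=row.end,
            feature_class="sORF", source="riboseq")
        for row in passing.itertuples()
    ]
    return AnnotationSet("riboseq", rank=50, features=features,
                         category="riboseq")


def stage_build_db(ctx: _Ctx) -> None:
    replicons = ctx.replicons()
    sources = _load_sources(ctx)
    insilico = iptgxdb.predict_insilico_orfs(replicons)
    standard = iptgxdb.integrate_annotations(sources, insilico, replicons)
    custom = iptgxdb.integrate_annotations(
        sources, _riboseq_set(ctx), replicons)
    db_dir = ctx.out / "db"
    db_dir.mkdir(exist_ok=True)
    counts = {}
    for protease in ctx.config.proteases:
        for tag, clusters in (("standard", standard), ("custom", custom)):
            n = iptgxdb.write_iptgxdb(
                clusters, protease,
                db_dir / f"{tag}_{protease}.fasta",
                db_dir / f"{tag}_{protease}.gff3",
                ctx.config.max_missed_cleavages)
            counts[f"{tag}_{protease}_entries"] = n
    iptgxdb.cluster_summary(standard).to_csv(
        db_dir / "standard_clusters.tsv", sep="\t", index=False)
    iptgxdb.cluster_summary(custom).to_csv(
        db_dir / "custom_clusters.tsv", sep="\t", index=False)
    with open(db_dir / "db_stats.json", "w") as handle:
        json.dump({**counts,
                   "standard_clusters": len(standard),
                   "custom_clusters": len(custom)}, handle, indent=2)


def _custom_clusters(ctx: _Ctx):
    replicons = ctx.replicons()
    return iptgxdb.integrate_annotations(
        _load_sources(ctx), _riboseq_set(ctx), replicons)


def stage_classify_peptides(ctx: _Ctx) -> None:
    clusters = _custom_clusters(ctx)
    rows = []
    for protease in ctx.config.proteases:
        psms = pd.read_csv(ctx.out / f"psms_{protease}.tsv", sep="\t")
        classes = peptide_evidence.classify_peptides(
            psms["peptide"], clusters)
        for pep, cls in sorted(classes.items()):
            rows.append(dict(protease=protease, peptide=pep,
                             peptide_class=cls))
    pd.DataFrame(rows).to_csv(ctx.out / "peptide_classes.tsv", sep="\t",
                              index=False)


def stage_accept(ctx: _Ctx) -> None:
    clusters = _custom_clusters(ctx)
    class_table = pd.read_csv(ctx.out / "peptide_classes.tsv", sep="\t")
    frames = []
    for protease in ctx.config.proteases:
        psms = pd.read_csv(ctx.out / f"psms_{protease}.tsv", sep="\t")
        psms["protease"] = protease
        frames.append(psms)
    psms = pd.concat(frames, ignore_index=True)
    classes = dict(zip(class_table["peptide"], class_table["peptide_class"]))
    rows = []
    for cluster in clusters:
        decision = peptide_evidence.accept_protein(
            cluster, psms, classes,
            n_replicates_required=ctx.config.simulation.n_ms_replicates)
        rows.append(dict(
            cluster=decision.cluster_id, category=decision.category,
            mass_kda=round(decision.mass_kda, 3),
            unique_peptides=decision.unique_peptides,
            total_psms=decision.total_psms,
            n_replicates=len(decision.replicates_observed),
            accepted=decision.accepted, rule=decision.rule_applied))
    pd.DataFrame(rows).to_csv(ctx.out / "acceptance_decisions.tsv", sep="\t",
                              index=False)


STAGES = {
    "simulate": stage_simulate,
    "coverage": stage_coverage,
    "quantify": stage_quantify,
    "metagene": stage_metagene,
    "call-sorfs": stage_call_sorfs,
    "build-db": stage_build_db,
    "classify-peptides": stage_classify_peptides,
    "accept": stage_accept,
}


def _hash_outputs(out: Path) -> dict:
    hashes = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return hashes


def run_stage(name: str, config: PipelineConfig) -> None:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    ctx = _Ctx(config)
    t0 = time.time()
    STAGES[name](ctx)
    _write_manifest(ctx, [name], time.time() - t0)


def run_all(config: PipelineConfig) -> None:
    ctx = _Ctx(config)
    t0 = time.time()
    for name, stage in STAGES.items():
        stage(ctx)
    _write_manifest(ctx, list(STAGES), time.time() - t0)


def _write_manifest(ctx: _Ctx, stages: list, elapsed: float) -> None:
    manifest = {
        "stages": stages,
        "seed": ctx.config.seed,
        "config": ctx.config.echo(),
        "elapsed_seconds": round(elapsed, 2),
        "output_sha256": _hash_outputs(ctx.out),
    }
    with open(ctx.out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
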