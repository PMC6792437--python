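"""End-to-end orchestration of the analysis stages on one artifact directory.

Stage order: synth -> recruit -> profile -> mag-stats -> derep ->
screen-nifh -> primer-check -> enrich -> report. Every stage reads its
inputs from, and writes its outputs to, the same artifact directory, so
each is idempotent given identical inputs and seed. One global seed
fans out to per-stage seeds derived by stable hashing of stage names,
so stage-level reruns reproduce bit-for-bit. The report stage writes a
manifest listing every output with a checksum.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dereplication, enrichment, io, mag_stats, markers, primers, recruitment, synth

STAGES = [
    "synth",
    "recruit",
    "profile",
    "mag-stats",
    "derep",
    "screen-nifh",
    "primer-check",
    "enrich",
    "report",
]


@dataclass
class RunConfig:
    """Every tunable parameter of the pipeline, with pinned defaults."""

    # dereplication rule
    ani_min: float = 99.0
    align_frac_min: float = 0.75
    r_min: float = 0.9
    # marker screen
    evalue_max: float = 1e-50
    label_keyword: str = "nitrogenase"
    ka_lambda: float = 0.3176
    ka_k: float = 0.134
    min_align_len: int = 100
    # MAG definition
    completeness_min: float = 70.0
    length_min: float = 2e6
    # recruitment
    mapper_k: int = 21
    min_identity: float = 0.95
    min_aligned_fraction: float = 0.9
    min_cov: int = 1
    # abundance scaling
    cell_density: float = 5e8
    # primers
    max_mismatch: int = 0
    # synthetic community
    n_genomes: int = 8
    genome_length: int = 30000
    gc: float = 0.5
    n_samples: int = 4
    reads_per_sample: int = 50000
    read_length: int = 120
    error_rate: float = 0.005
    variant_sub_rate: float = 0.002
    n_variant_pairs: int = 3
    profile_noise_sd: float = 0.05
    scg_collection_size: int = 20
    n_ref_proteins: int = 20
    # plumbing
    seed: int = 1
    derep_enabled: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        overrides = io.load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(overrides) - known
        if unknown:
            raise io.ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def bundled_motif() -> markers.PrositePattern:
    """The bundled synthetic [4Fe-4S]-site pattern (PROSITE syntax)."""
    text = (
        resources.files("diazoscan.data")
        .joinpath("synthetic_nifh_4fe4s.prosite")
        .read_text()
        .strip()
    )
    return markers.prosite_parse(text)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# stages


def run_synth(cfg: RunConfig, outdir: Path) -> None:
    """Generate the community with known truth and write all its artifacts."""
    rng = np.random.default_rng(stage_seed(cfg.seed, "synth"))
    motif = bundled_motif()
    refdb = synth.make_reference_proteins(cfg.n_ref_proteins, motif, seed=rng)
    io.write_fasta(refdb, outdir / "refdb.fasta")

    # genomes: n_variant_pairs redundant pairs + singletons; genome 0 carries
    # the planted nifH gene (back-translated from the first reference protein)
    nifh_gene = synth.reverse_translate(refdb[0].residues, rng)
    n_base = cfg.n_genomes - cfg.n_variant_pairs
    bases = []
    for i in range(n_base):
        planted = []
        if i == 0:
            offset = int(rng.integers(1000, cfg.genome_length - len(nifh_gene) - 1000))
            planted = [("nifH_planted", nifh_gene, offset)]
        spec = synth.GenomeSpec(
            id=f"MAG{i:02d}", length=cfg.genome_length, gc=cfg.gc, planted_genes=planted
        )
        bases.append(synth.build_genome(spec, rng))
    genomes = list(bases)
    pair_rows = []
    redundant_pairs = []
    for p in range(cfg.n_variant_pairs):
        variant, divergence = synth.mutate_genome(bases[p], cfg.variant_sub_rate, rng)
        variant.id = f"MAG{n_base + p:02d}"
        redundant_pairs.append((p, n_base + p))
        pair_rows.append((bases[p].id, variant.id, divergence))
        genomes.append(variant)
    io.write_fasta(genomes, outdir / "genomes.fasta")
    pd.DataFrame(pair_rows, columns=["mag_a", "mag_b", "true_divergence"]).pipe(
        _write_tsv, outdir / "truth_pairs.tsv"
    )

    # abundances: redundant pairs correlated; last singleton enriched in region A
    ab = synth.simulate_abundances(
        len(genomes),
        cfg.n_samples,
        redundant_pairs=redundant_pairs,
        correlated_noise_sd=cfg.profile_noise_sd,
        seed=rng,
    )
    groups = ["pacific" if s < cfg.n_samples // 2 else "other" for s in range(cfg.n_samples)]
    enriched = n_base - 1  # last non-variant genome
    ab[enriched, [g == "pacific" for g in groups]] *= 10
    ab = ab / ab.sum(axis=0, keepdims=True)
    samples = [f"S{j:02d}" for j in range(cfg.n_samples)]
    pd.DataFrame(ab, index=[g.id for g in genomes], columns=samples).rename_axis(
        "mag_id"
    ).reset_index().pipe(_write_tsv, outdir / "truth_abundance.tsv")
    pd.DataFrame({"sample_id": samples, "region": groups}).pipe(
        _write_tsv, outdir / "sample_groups.tsv"
    )

    # single-copy-gene truth: variants miss a few families so the
    # completion-minus-redundancy rule has something to decide
    scg_rows = []
    for gi, g in enumerate(genomes):
        missing = int(rng.integers(0, 4)) if gi >= n_base else int(rng.integers(0, 2))
        dup = int(rng.integers(0, 2))
        for fam in range(cfg.scg_collection_size):
            count = 1
            if fam < missing:
                count = 0
            elif fam == cfg.scg_collection_size - 1 and dup:
                count = 2
            scg_rows.append((g.id, f"scg{fam:03d}", count))
    pd.DataFrame(scg_rows, columns=["mag_id", "family_id", "count"]).pipe(
        _write_tsv, outdir / "scg_counts.tsv"
    )

    # reads + truth alignments
    community = synth.CommunitySpec(
        genomes=genomes,
        samples=[(s, cfg.reads_per_sample, ab[:, j]) for j, s in enumerate(samples)],
        read_length=cfg.read_length,
        error_rate=cfg.error_rate,
        seed=int(rng.integers(2**31)),
    )
    reads, truth_aln, truthset = synth.simulate_reads(community)
    ref_lengths = {g.id: len(g) for g in genomes}
    for s in samples:
        io.write_fastq(reads[s], outdir / f"reads_{s}.fastq")
        io.write_alignments(truth_aln[s], ref_lengths, outdir / f"truth_{s}.sam")

    # candidate genes for the marker screen: the planted nifH gene and a
    # composition-matched shuffled decoy
    genes = [
        io.SequenceRecord(id="gene_nifH", residues=nifh_gene, description="planted nifH"),
        io.SequenceRecord(
            id="gene_decoy",
            residues=synth.shuffle_sequence(nifh_gene, rng),
            description="shuffled decoy",
        ),
    ]
    io.write_fasta(genes, outdir / "genes.fasta")

    # primers with known truth against the planted gene: one exact site,
    # one degenerate-but-compatible site, one single-mismatch primer
    site = nifh_gene[60:80]
    degenerate = "".join(
        c if i % 5 else {"A": "R", "C": "Y", "G": "R", "T": "Y"}[c] for i, c in enumerate(site)
    )
    mismatched = list(site)
    mismatched[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mismatched[10]]
    primer_rows = [
        ("synth_exact", site, "forward"),
        ("synth_degenerate", degenerate, "forward"),
        ("synth_mismatch", "".join(mismatched), "forward"),
    ]
    pd.DataFrame(primer_rows, columns=["name", "sequence", "orientation"]).pipe(
        _write_tsv, outdir / "primers.tsv"
    )


def _samples(outdir: Path) -> list[str]:
    df = pd.read_csv(outdir / "sample_groups.tsv", sep="\t")
    return df["sample_id"].tolist()


def run_recruit(cfg: RunConfig, outdir: Path) -> None:
    """Competitively map each sample's reads against the genome collection."""
    genomes = io.read_fasta(outdir / "genomes.fasta")
    index = recruitment.ReferenceIndex(genomes, k=cfg.mapper_k)
    ref_lengths = {g.id: len(g) for g in genomes}
    seed = stage_seed(cfg.seed, "recruit")
    for i, s in enumerate(_samples(outdir)):
        reads = io.read_fastq(outdir / f"reads_{s}.fastq")
        alns = recruitment.map_reads(
            reads,
            index,
            min_identity=cfg.min_identity,
            min_aligned_fraction=cfg.min_aligned_fraction,
            seed=seed + i,
        )
        io.write_alignments(alns, ref_lengths, outdir / f"mapped_{s}.sam")


def run_profile(cfg: RunConfig, outdir: Path) -> None:
    """Coverage/detection/abundance summaries per genome per sample."""
    genomes = io.read_fasta(outdir / "genomes.fasta")
    samples = _samples(outdir)
    rows = []
    for s in samples:
        alns = io.read_alignments(outdir / f"mapped_{s}.sam")
        total = sum(1 for _ in open(outdir / f"reads_{s}.fastq")) // 4
        for summ in recruitment.summarize_sample(alns, genomes, s, total, min_cov=cfg.min_cov):
            rows.append(
                (
                    summ.ref_id,
                    summ.sample_id,
                    summ.mean_coverage,
                    summ.q2q3_mean_coverage,
                    summ.detection,
                    summ.reads_recruited,
                    recruitment.relative_abundance(summ.reads_recruited, total),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mag_id",
            "sample_id",
            "mean_coverage",
            "q2q3_mean_coverage",
            "detection",
            "reads_recruited",
            "relative_abundance",
        ],
    )
    _write_tsv(df, outdir / "profile.tsv")
    ab = df.pivot(index="mag_id", columns="sample_id", values="relative_abundance")
    _write_tsv(ab.reset_index(), outdir / "abundance.tsv")
    cells = ab.map(lambda x: recruitment.cells_per_litre(x, cfg.cell_density))
    _write_tsv(cells.reset_index(), outdir / "cells_per_litre.tsv")


def _load_mag_records(cfg: RunConfig, outdir: Path) -> dict[str, mag_stats.MagRecord]:
    genomes = io.read_fasta(outdir / "genomes.fasta")
    scg = pd.read_csv(outdir / "scg_counts.tsv", sep="\t")
    records = {}
    for g in genomes:
        counts = dict(
            zip(
                scg.loc[scg.mag_id == g.id, "family_id"],
                scg.loc[scg.mag_id == g.id, "count"].astype(int),
            )
        )
        profile = mag_stats.ScgProfile(g.id, counts, cfg.scg_collection_size)
        records[g.id] = mag_stats.mag_record(g.id, [g], scg=profile)
    return records


def run_mag_stats(cfg: RunConfig, outdir: Path) -> None:
    """Table-shaped per-MAG statistics (length, N50, GC, completion/redundancy)."""
    records = _load_mag_records(cfg, outdir)
    rows = [
        (
            r.mag_id,
            r.total_length,
            r.n_contigs,
            r.n50,
            round(r.gc, 2),
            round(r.completion, 1),
            round(r.redundancy, 1),
            mag_stats.is_mag(r.completion, r.total_length),
        )
        for r in records.values()
    ]
    pd.DataFrame(
        rows,
        columns=["mag_id", "length_bp", "n_contigs", "n50", "gc_pct", "completion", "redundancy", "is_mag"],
    ).pipe(_write_tsv, outdir / "mag_table.tsv")


def run_derep(cfg: RunConfig, outdir: Path) -> None:
    """ANI + distribution-correlation dereplication with representatives."""
    genomes = {g.id: g for g in io.read_fasta(outdir / "genomes.fasta")}
    records = _load_mag_records(cfg, outdir)
    ab = pd.read_csv(outdir / "abundance.tsv", sep="\t").set_index("mag_id")
    matrix = ab.to_numpy()
    index = {m: i for i, m in enumerate(ab.index)}
    if cfg.derep_enabled:
        groups = dereplication.dereplicate(
            records,
            genomes,
            matrix,
            index,
            ani_min=cfg.ani_min,
            align_frac_min=cfg.align_frac_min,
            r_min=cfg.r_min,
        )
    else:
        groups = [
            dereplication.RedundancyGroup(members=[m], representative=m) for m in sorted(genomes)
        ]
    rows = []
    for gi, grp in enumerate(groups):
        for m in grp.members:
            rows.append((f"group{gi:03d}", m, "Reference" if m == grp.representative else "Redundant"))
    pd.DataFrame(rows, columns=["group_id", "mag_id", "status"]).pipe(
        _write_tsv, outdir / "derep_groups.tsv"
    )


def run_screen(cfg: RunConfig, outdir: Path) -> None:
    """Three-part nifH screen over the candidate genes."""
    genes = io.read_fasta(outdir / "genes.fasta")
    refdb = io.read_fasta(outdir / "refdb.fasta", alphabet="protein")
    motif = bundled_motif()
    rows = []
    for gene in genes:
        hit = markers.screen_gene(
            gene,
            refdb,
            motif,
            evalue_max=cfg.evalue_max,
            label_keyword=cfg.label_keyword,
            lam=cfg.ka_lambda,
            k=cfg.ka_k,
        )
        rows.append(
            (
                hit.gene_id,
                hit.frame,
                hit.best_ref_id,
                hit.score,
                hit.evalue,
                hit.top_hit_label_ok,
                hit.motif_ok,
                hit.verdict,
            )
        )
    pd.DataFrame(
        rows,
        columns=["gene_id", "frame", "best_ref", "score", "evalue", "label_ok", "motif_ok", "verdict"],
    ).pipe(_write_tsv, outdir / "nifh_verdicts.tsv")


def run_primer_check(cfg: RunConfig, outdir: Path) -> None:
    """Degenerate-primer compatibility table over the candidate genes."""
    genes = io.read_fasta(outdir / "genes.fasta")
    primer_list = primers.read_primer_tsv(outdir / "primers.tsv")
    rows = [
        (m.primer, m.gene_id, m.strand, m.position, m.mismatches, m.compatible)
        for m in primers.compatibility_report(primer_list, genes, max_mismatch=cfg.max_mismatch)
    ]
    pd.DataFrame(
        rows, columns=["primer", "gene_id", "strand", "position", "mismatches", "compatible"]
    ).pipe(_write_tsv, outdir / "primer_compatibility.tsv")


def run_enrich(cfg: RunConfig, outdir: Path) -> None:
    """Welch's test: first region vs the rest, per population."""
    ab = pd.read_csv(outdir / "abundance.tsv", sep="\t").set_index("mag_id")
    groups = pd.read_csv(outdir / "sample_groups.tsv", sep="\t")
    labels = [groups.set_index("sample_id").loc[s, "region"] for s in ab.columns]
    rows = enrichment.enrichment_table(
        ab.to_numpy(), list(ab.index), labels, group_a=labels[0], adjust="bh"
    )
    pd.DataFrame(
        [
            (
                r.population,
                r.group_a,
                r.mean_a,
                r.mean_b,
                r.t_statistic,
                r.degrees_of_freedom,
                r.p_two_sided,
                r.adjusted_p,
            )
            for r in rows
        ],
        columns=["mag_id", "group_a", "mean_a", "mean_b", "t", "df", "p", "p_bh"],
    ).pipe(_write_tsv, outdir / "enrichment.tsv")


def run_report(cfg: RunConfig, outdir: Path) -> None:
    """Manifest of every artifact with a sha256 checksum."""
    rows = []
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.tsv" or path.is_dir():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        rows.append((path.name, path.stat().st_size, digest))
    note = "dereplicated" if cfg.derep_enabled else "redundant MAG set (derep disabled)"
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write(f"# collection: {note}\n")
        pd.DataFrame(rows, columns=["file", "bytes", "sha256"]).to_csv(fh, sep="\t", index=False)


_STAGE_FUNCS = {
    "synth": run_synth,
    "recruit": run_recruit,
    "profile": run_profile,
    "mag-stats": run_mag_stats,
    "derep": run_derep,
    "screen-nifh": run_screen,
    "primer-check": run_primer_check,
    "enrich": run_enrich,
    "report": run_report,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig, outdir, stages: list[str] | None = None) -> Path:
    """Execute the stages in order, echoing the resolved config next to outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    for stage in stages or STAGES:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:  # halt with the failing stage named
            raise StageError(stage, exc) from exc
    return outdir
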