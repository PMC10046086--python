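"""File formats: minimal VCF 4.2, BED, GFF3, depth and result tables.

The simulator writes and the curation stage reads plain-text formats only:
VCF 4.2 with a DP INFO field, 3-column BED (0-based half-open), GFF3
gene/CDS features, and TSV tables for depth tracks, curated variants,
rates, spectra and signature refits.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .curation import ExclusionSet
from .variants import VariantCall


def write_vcf(calls, path, genome=None, source: str = "malspectra") -> None:
    """Write calls as minimal VCF 4.2 (DP carried in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if genome is not None:
            for name, length in genome.lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda v: (v.chromosome, v.position, v.alt_allele)):
            info = f"DP={c.depth}" if c.depth is not None else "."
            fh.write(
                f"{c.chromosome}\t{c.position}\t.\t{c.ref_allele}\t"
                f"{c.alt_allele}\t.\tPASS\t{info}\n"
            )


def read_vcf(path, replicate_id: str = "", caller: str | None = None):
    """Read a VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one bi-allelic call per ALT; the
    DP INFO field populates depth when present.
    """
    import pysam

    flags = frozenset({caller}) if caller else frozenset()
    calls = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                dp = rec.info.get("DP") if "DP" in rec.info else None
                if dp is None and rec.samples:
                    sample = next(iter(rec.samples.values()))
                    dp = sample.get("DP")
                for alt in rec.alts or ():
                    calls.append(
                        VariantCall(
                            chromosome=rec.chrom,
                            position=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=alt,
                            depth=int(dp) if dp is not None else None,
                            replicate_id=replicate_id,
                            caller_flags=flags,
                        )
                    )
    return calls


def write_bed(intervals, path) -> None:
    """Write (chromosome, start, end[, label]) intervals as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path, label: str = "excluded") -> ExclusionSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return ExclusionSet(intervals, label=label)


def write_gff3(models, path) -> None:
    """Write gene models as GFF3 gene + CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            start, end = g.span
            fh.write(
                f"{g.chromosome}\tmalspectra\tgene\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for cstart, cend in g.cds_intervals:
                fh.write(
                    f"{g.chromosome}\tmalspectra\tCDS\t{cstart + 1}\t{cend}\t.\t"
                    f"{g.strand}\t0\tID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )


def read_gene_models(path):
    """Read gene/CDS features from GFF3 into :class:`GeneModel` records."""
    import gffutils

    from .annotation import GeneModel

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")
        )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(cds),
                gene_start=gene.start - 1,
                gene_end=gene.end,
            )
        )
    return models


def write_depth_tsv(tracks, path) -> None:
    """Depth tracks as TSV: chrom, start, end, depth (0-based half-open)."""
    frames = [
        pd.DataFrame(
            {
                "chrom": t.chromosome,
                "start": t.starts,
                "end": t.ends,
                "depth": t.depths,
            }
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depth_tracks(path):
    from .cnv import DepthTrack

    df = pd.read_csv(path, sep="\t")
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        window = int((sub["end"] - sub["start"]).max()) if len(sub) else 0
        tracks.append(
            DepthTrack(
                str(chrom),
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["depth"].to_numpy(),
                window_size=window,
            )
        )
    return tracks


def variants_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chromosome for c in calls],
            "pos": [c.position for c in calls],
            "ref": [c.ref_allele for c in calls],
            "alt": [c.alt_allele for c in calls],
            "class": [c.var_class for c in calls],
            "depth": [c.depth for c in calls],
            "replicate": [c.replicate_id for c in calls],
        }
    )


def write_variants_tsv(calls, path) -> None:
    variants_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [
        VariantCall(
            chromosome=str(row.chrom),
            position=int(row.pos),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            depth=None if pd.isna(row.depth) else int(row.depth),
            replicate_id="" if pd.isna(row.replicate) else str(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_design_table(designs, path) -> None:
    """Experiment design TSV: one row per strain."""
    pd.DataFrame(
        {
            "strain": [d.strain_id for d in designs],
            "replicates": [d.replicate_count for d in designs],
            "bottlenecks": [d.bottleneck_count for d in designs],
            "generations": [d.generations_total for d in designs],
            "ploidy": [d.ploidy for d in designs],
            "mito_present": [d.mito_present for d in designs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_experiment(experiment, genome, outdir, depth_tracks=None) -> dict:
    """Write a simulated experiment as the file bundle the curation CLI
    consumes: reference FASTA, per-replicate caller VCFs, ancestor VCF,
    design table, and optionally a depth TSV. Returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    design = experiment.truth.design
    paths = {"fasta": os.path.join(outdir, "reference.fa")}
    genome.to_fasta(paths["fasta"])
    paths["ancestor"] = os.path.join(outdir, "ancestor.vcf")
    write_vcf(experiment.ancestor_calls, paths["ancestor"], genome)
    paths["design"] = os.path.join(outdir, "design.tsv")
    write_design_table([design], paths["design"])
    paths["callers"] = {}
    for rep, callers in experiment.caller_calls.items():
        for caller, calls in callers.items():
            p = os.path.join(outdir, f"{rep}.{caller}.vcf")
            write_vcf(calls, p, genome)
            paths["callers"][(rep, caller)] = p
    if depth_tracks is not None:
        paths["depth"] = os.path.join(outdir, "depth.tsv")
        write_depth_tsv(depth_tracks, paths["depth"])
    return paths
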