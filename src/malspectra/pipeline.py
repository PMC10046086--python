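"""End-to-end pipeline: simulate -> curate -> annotate -> rates/spectra ->
signatures -> neutrality -> copy number, from one YAML-serialisable config.

Every stage's numeric output lands in one JSON summary keyed by strain;
thresholds and derived quantities (callable lengths, seeds per strain) are
echoed into a run log so each number can be reproduced by calling the
underlying module operation directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io
from .annotation import annotate_variants, effect_fractions
from .cnv import call_aneuploidy, detect_segmental_cnv, mtdna_copy_number
from .curation import curate_replicate, detect_cross_contamination
from .genome import Genome, random_genome
from .neutrality import (
    EXPECTED_GENIC_FRACTION,
    EXPECTED_NONSYN_FRACTION,
    chromosome_length_regression,
    neutral_fraction_test,
)
from .rates import MutationRateModel, compare_rates
from .simulate import (
    MALDesign,
    SimParams,
    random_gene_models,
    simulate_depth_tracks,
    simulate_mal_experiment,
)
from .spectra import MutationSpectrum, spectrum_summary, trinucleotide_profile

logger = logging.getLogger(__name__)


@dataclass
class StrainConfig:
    """Simulation settings for one strain."""

    strain_id: str
    generations: int
    replicates: int = 4
    bottlenecks: int | None = None
    snv_rate: float = 1.15e-9
    indel_rate: float = 0.0
    mito_snv_rate: float = 0.0
    mito_indel_rate: float = 0.0
    ts_tv: float = 0.5
    gc_at_bias: float = 1.0
    mito_copy_ratio: float = 14.0
    caller_fp_rate: float = 0.0
    caller_fn_rate: float = 0.0
    ancestor_variant_count: int = 0
    ploidy_events: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Whole-run configuration; round-trips through YAML unchanged."""

    seed: int = 0
    chromosomes: dict = field(
        default_factory=lambda: {"chrI": 200_000, "chrII": 300_000, "chrIII": 400_000}
    )
    mito_id: str | None = "chrM"
    mito_length: int = 75_000
    gc_content: float = 0.38
    strains: list = field(default_factory=list)
    control_strain: str | None = None
    min_depth: int = 11
    contamination_threshold: float = 0.2
    exact_test_method: str = "binomial"
    expected_nonsyn: float = EXPECTED_NONSYN_FRACTION
    #: None -> use the annotation's genic coverage of the nuclear genome
    #: (the right null for a toy annotation); set a number to override,
    #: e.g. the yeast constant EXPECTED_GENIC_FRACTION.
    expected_genic: float | None = None
    mean_depth: float = 88.0
    depth_dispersion: float = 2.0
    window_size: int = 1000
    signature_matrix: str | None = None
    signature_max_delta: float = 0.004
    genic_fraction: float = 0.7

    def __post_init__(self):
        self.strains = [
            s if isinstance(s, StrainConfig) else StrainConfig(**s)
            for s in self.strains
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _strain_seed(base_seed: int, index: int) -> int:
    """Deterministic per-strain child seed below 2^31."""
    state = np.random.SeedSequence(base_seed).generate_state(index + 1)
    return int(state[index]) % (2**31)


def _compartment_of(call, mito_id):
    return "mito" if mito_id is not None and call.chromosome == mito_id else "nuclear"


def run_strain(config: PipelineConfig, strain: StrainConfig, genome: Genome,
               gene_models, signature_matrix=None, seed: int | None = None) -> dict:
    """Run every stage for one strain; returns its summary block."""
    design = MALDesign(
        strain_id=strain.strain_id,
        generations_total=strain.generations,
        replicate_count=strain.replicates,
        bottleneck_count=strain.bottlenecks,
        mito_present=strain.mito_copy_ratio > 0,
    )
    params = SimParams(
        snv_rate=strain.snv_rate,
        indel_rate=strain.indel_rate,
        mito_snv_rate=strain.mito_snv_rate,
        mito_indel_rate=strain.mito_indel_rate,
        spectrum=MutationSpectrum.from_ts_tv(strain.ts_tv, strain.gc_at_bias),
        caller_fp_rate=strain.caller_fp_rate,
        caller_fn_rate=strain.caller_fn_rate,
        ancestor_variant_count=strain.ancestor_variant_count,
        mean_depth=config.mean_depth,
        depth_dispersion=config.depth_dispersion,
        mito_copy_ratio=strain.mito_copy_ratio,
        ploidy_events=tuple(tuple(e) for e in strain.ploidy_events),
        seed=seed if seed is not None else config.seed,
    )
    experiment = simulate_mal_experiment(genome, design, params)

    # --- curation ---
    curated = {}
    filter_logs = {}
    for rep in design.replicate_ids:
        calls, log = curate_replicate(
            experiment.caller_calls[rep]["callerA"],
            experiment.caller_calls[rep]["callerB"],
            ancestor=experiment.ancestor_calls,
            min_depth=config.min_depth,
        )
        curated[rep] = calls
        filter_logs[rep] = log.as_dict()
    contamination = (
        detect_cross_contamination(curated, config.contamination_threshold)
        if len(curated) >= 2
        else []
    )
    retained = {
        rep: calls
        for rep, calls in curated.items()
        if not any(
            f.flagged and rep in (f.replicate_a, f.replicate_b) for f in contamination
        )
    }
    if not retained:  # all pairs flagged (pathological); keep everything, note it
        retained = curated

    mito_id = genome.mito_id
    pooled = [c for calls in retained.values() for c in calls]
    pooled_snvs = [c for c in pooled if c.var_class == "SNV"
                   and _compartment_of(c, mito_id) == "nuclear"]

    # --- rates ---
    L_nuc = genome.compartment_length("nuclear")
    L_mito = genome.compartment_length("mito")
    rates = {}
    estimates = {}
    for var_class in ("SNV", "INDEL"):
        for compartment, L in (("nuclear", L_nuc), ("mito", L_mito)):
            if compartment == "mito" and (mito_id is None or not design.mito_present):
                continue
            counts = [
                sum(
                    1
                    for c in retained[rep]
                    if c.var_class == var_class
                    and _compartment_of(c, mito_id) == compartment
                )
                for rep in retained
            ]
            est = MutationRateModel(
                counts, L, design.generations_total,
                strain_id=strain.strain_id, var_class=var_class,
                compartment=compartment, replicate_ids=list(retained),
            ).fit()
            estimates[(var_class, compartment)] = est
            rates[f"{compartment}_{var_class.lower()}"] = {
                "mean_rate": est.mean_rate,
                "standard_error": est.standard_error,
                "pooled_rate": est.pooled_rate,
                "counts": list(est.counts),
                "callable_length": est.callable_length,
            }

    # --- spectra ---
    summary = spectrum_summary(pooled_snvs)
    profile = trinucleotide_profile(pooled_snvs, genome)
    per_rep_ts_tv = {
        rep: spectrum_summary(
            [
                c
                for c in calls
                if c.var_class == "SNV" and _compartment_of(c, mito_id) == "nuclear"
            ]
        ).ts_tv
        for rep, calls in retained.items()
    }
    spectra_block = {
        "n_snv": summary.n,
        "class_counts": summary.class_counts,
        "ts_tv": summary.ts_tv,  # pooled over retained replicates
        "ts_tv_per_replicate": per_rep_ts_tv,
        "gc_to_at": summary.gc_to_at,
        "profile_96": profile.context_counts.tolist(),
    }

    # --- signature refit ---
    signatures_block = None
    if signature_matrix is not None and profile.total > 0:
        from .signatures import SignatureRefitModel

        refit = SignatureRefitModel(profile, signature_matrix).fit(
            config.signature_max_delta
        )
        signatures_block = {
            "contributions": {k: float(v) for k, v in refit.contributions.items()},
            "dropped": list(refit.dropped),
            "reconstruction_similarity": refit.reconstruction_similarity,
        }

    # --- effect annotation + neutrality ---
    annotations = annotate_variants(pooled_snvs, gene_models, genome)
    fractions = effect_fractions(annotations)
    neutrality_block = {
        "nonsyn_fraction": fractions.nonsyn_fraction,
        "genic_fraction": fractions.genic_fraction,
        "coding_count": fractions.coding_count,
        "total_snvs": fractions.total,
    }
    if fractions.coding_count > 0:
        neutrality_block["nonsyn_p"] = neutral_fraction_test(
            fractions.nonsyn_count, fractions.coding_count,
            config.expected_nonsyn, config.exact_test_method,
        ).p_value
    expected_genic = config.expected_genic
    if expected_genic is None:
        genic_bases = sum(g.span[1] - g.span[0] for g in gene_models)
        expected_genic = genic_bases / genome.compartment_length("nuclear")
    neutrality_block["expected_genic"] = expected_genic
    if fractions.total > 0:
        neutrality_block["genic_p"] = neutral_fraction_test(
            fractions.genic_count, fractions.total,
            expected_genic, config.exact_test_method,
        ).p_value

    nuclear_ids = genome.nuclear_ids
    counts_by_chrom = {c: 0 for c in nuclear_ids}
    for c in pooled_snvs:
        counts_by_chrom[c.chromosome] += 1
    if len(nuclear_ids) >= 3:
        reg = chromosome_length_regression(
            [counts_by_chrom[c] for c in nuclear_ids],
            [genome.lengths[c] for c in nuclear_ids],
            nuclear_ids,
        )
        neutrality_block["chrom_regression"] = {
            "slope": reg.slope,
            "r_squared": reg.r_squared,
            "p_value": reg.p_value,
        }

    # --- depth / copy number ---
    tracks = simulate_depth_tracks(
        genome, params, window_size=config.window_size, ploidy=design.ploidy
    )
    cnv_block = {}
    if mito_id is not None:
        cnv_block["mito_copy_number"] = mtdna_copy_number(
            tracks, mito_id, ploidy=design.ploidy
        )
    aneuploidies = call_aneuploidy(tracks, ploidy=design.ploidy, mito_id=mito_id)
    cnv_block["chromosome_copies"] = {
        a.chromosome: {"estimated": a.estimated_copy, "integer": a.integer_copy}
        for a in aneuploidies
    }
    segments = []
    for a in aneuploidies:
        track = next(t for t in tracks if t.chromosome == a.chromosome)
        if len(track) >= 5:
            baseline = a.baseline_depth * a.integer_copy / design.ploidy
            for seg in detect_segmental_cnv(
                track, ploidy=design.ploidy, baseline_depth=baseline
            ):
                segments.append(
                    {
                        "chromosome": seg.chromosome,
                        "start": seg.start,
                        "end": seg.end,
                        "estimated_copy": seg.estimated_copy,
                        "integer_copy": seg.integer_copy,
                    }
                )
    cnv_block["segments"] = segments

    return {
        "design": {
            "replicates": design.replicate_count,
            "generations": design.generations_total,
            "bottlenecks": design.bottleneck_count,
        },
        "seed": params.seed,
        "filters": filter_logs,
        "contamination": [
            {
                "pair": [f.replicate_a, f.replicate_b],
                "shared_fraction": f.shared_fraction,
                "flagged": f.flagged,
            }
            for f in contamination
        ],
        "replicates_retained": list(retained),
        "rates": rates,
        "spectra": spectra_block,
        "signatures": signatures_block,
        "neutrality": neutrality_block,
        "cnv": cnv_block,
        "_estimates": estimates,  # stripped before JSON serialisation
    }


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Run the full pipeline for every configured strain.

    Returns the JSON-serialisable summary; when ``outdir`` is given the
    summary, per-strain variant tables and the run log are written there.
    Deterministic given config + seed.
    """
    if not config.strains:
        raise ValueError("config lists no strains")
    signature_matrix = None
    if config.signature_matrix:
        from .signatures import SignatureMatrix

        if not os.path.exists(config.signature_matrix):
            raise FileNotFoundError(
                f"signature matrix not found: {config.signature_matrix}"
            )
        signature_matrix = SignatureMatrix.from_tsv(config.signature_matrix)

    lengths = dict(config.chromosomes)
    if config.mito_id:
        lengths[config.mito_id] = config.mito_length
    genome = random_genome(
        lengths, gc=config.gc_content, seed=config.seed, mito_id=config.mito_id
    )
    gene_models = random_gene_models(
        genome, genic_fraction=config.genic_fraction, seed=config.seed
    )

    summary = {"seed": config.seed, "strains": {}}
    estimates = {}
    for i, strain in enumerate(config.strains):
        block = run_strain(
            config, strain, genome, gene_models, signature_matrix,
            seed=_strain_seed(config.seed, i),
        )
        estimates[strain.strain_id] = block.pop("_estimates")
        summary["strains"][strain.strain_id] = block
        logger.info("strain %s done", strain.strain_id)

    control = config.control_strain or config.strains[0].strain_id
    comparisons = []
    for strain in config.strains:
        if strain.strain_id == control:
            continue
        key = ("SNV", "nuclear")
        if key in estimates[strain.strain_id] and key in estimates[control]:
            cmp_res = compare_rates(
                estimates[strain.strain_id][key], estimates[control][key]
            )
            comparisons.append(
                {
                    "strain": strain.strain_id,
                    "control": control,
                    "fold_change": cmp_res.fold_change,
                    "t_statistic": cmp_res.t_statistic,
                    "p_value": cmp_res.p_value,
                }
            )
    summary["rate_comparisons"] = comparisons

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        config.to_yaml(os.path.join(outdir, "config_used.yaml"))
    return summary
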