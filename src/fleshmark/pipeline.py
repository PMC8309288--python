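"""End-to-end orchestration: simulate -> call variants -> phylogeny -> design ->
genotype, with deterministic, provenance-stamped artifacts.

The flow mirrors a marker-development study: polymorphisms are discovered and
classified on a small sequenced discovery panel (one accession per skin/flesh
subtype), markers are designed from those diagnostic sites, and the markers are
then scored on a wider validation panel containing heterozygous cultivars (and,
optionally, an accession carrying the Rf-length microsatellite on a white-flesh
background — the homoplasy that defeats the SSR marker).  Primer windows are
required to be conserved across the union of both panels.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .insilico_genotyping import (
    BindingModel,
    ConcordanceReport,
    MarkerCall,
    calls_to_frame,
    genotype_panel,
)
from .io_core import AccessionMeta, AlleleRecord, group_of, write_gene_model, write_panel
from .marker_design import (
    DesignFailure,
    PrimerConstraints,
    PrimerSet,
    design_marker_suite,
    markers_to_frame,
)
from .phylogeny import build_nj_tree, check_group_split, distance_matrix
from .synthetic_panel import Experiment, GeneratorConfig, simulate_experiment
from .variant_analysis import (
    PanelAlignment,
    Variant,
    call_variants,
    summarize_matrix,
    variants_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    experiment: Experiment
    discovery_variants: list[Variant]
    union_variants: list[Variant]
    matrix: pd.DataFrame
    markers: list[PrimerSet]
    failures: list[DesignFailure]
    calls: list[MarkerCall]
    concordance: ConcordanceReport
    tree_newick: str
    group_split: bool
    artifacts: list[Path] = field(default_factory=list)


def provenance_header(seed: int, config_repr: str) -> str:
    digest = hashlib.md5(config_repr.encode()).hexdigest()[:12]
    return f"# fleshmark {__version__} seed={seed} config={digest}\n"


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(
    seed: int,
    outdir: str | Path | None = None,
    chengwoo: bool = False,
    phenotype_rule: str = "dominant",
    config: GeneratorConfig | None = None,
    constraints: PrimerConstraints | None = None,
    binding: BindingModel | None = None,
    anchor: str = "atg",
) -> PipelineResult:
    config = config or GeneratorConfig(seed=seed)
    header = provenance_header(seed, repr(config) + repr(constraints) + phenotype_rule)

    exp = simulate_experiment(config, chengwoo=chengwoo)
    model = exp.model
    ref_id = exp.reference_id

    pa_disc = PanelAlignment(exp.discovery.alleles, reference_id=ref_id)
    disc_variants = call_variants(pa_disc, model, anchor=anchor)
    union = list(exp.discovery.alleles) + list(exp.validation.alleles)
    pa_union = PanelAlignment(union, reference_id=ref_id)
    union_variants = call_variants(pa_union, model, anchor=anchor)
    matrix = summarize_matrix(disc_variants)

    dm = distance_matrix(pa_disc)
    tree = build_nj_tree(dm)
    groups = {a.allele_id: group_of(a) for a in exp.discovery.alleles}
    split, _ = check_group_split(tree, groups)
    newick = str(tree).strip()

    markers, failures = design_marker_suite(
        disc_variants, pa_union, model, constraints, mask_variants=union_variants
    )
    calls, concordance = genotype_panel(
        markers,
        exp.validation.alleles,
        exp.validation.accessions,
        phenotype_rule=phenotype_rule,
        model=binding,
    )

    result = PipelineResult(
        experiment=exp,
        discovery_variants=disc_variants,
        union_variants=union_variants,
        matrix=matrix,
        markers=markers,
        failures=failures,
        calls=calls,
        concordance=concordance,
        tree_newick=newick,
        group_split=split,
    )
    if outdir is not None:
        result.artifacts = write_artifacts(result, Path(outdir), header, dm)
    return result


def write_artifacts(result: PipelineResult, outdir: Path, header: str, dm=None) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    exp = result.experiment
    paths: list[Path] = []

    def keep(p: Path) -> Path:
        paths.append(p)
        return p

    write_panel(
        exp.discovery.alleles,
        exp.discovery.accessions,
        keep(outdir / "discovery.fasta"),
        keep(outdir / "discovery_meta.tsv"),
    )
    write_panel(
        exp.validation.alleles,
        exp.validation.accessions,
        keep(outdir / "validation.fasta"),
        keep(outdir / "validation_meta.tsv"),
    )
    write_gene_model(exp.model, keep(outdir / "gene_model.gff3"))
    _write_tsv(exp.discovery.truth, keep(outdir / "truth_discovery.tsv"), header)
    _write_tsv(exp.validation.truth, keep(outdir / "truth_validation.tsv"), header)
    _write_tsv(
        variants_to_frame(result.discovery_variants), keep(outdir / "variants.tsv"), header
    )
    _write_tsv(
        result.matrix, keep(outdir / "polymorphism_matrix.tsv"), header, index=True
    )
    if dm is not None:
        _write_tsv(dm.to_data_frame(), keep(outdir / "distances.tsv"), header, index=True)
    (keep(outdir / "alleles.nwk")).write_text(result.tree_newick + "\n")
    _write_tsv(
        markers_to_frame(result.markers, result.failures),
        keep(outdir / "markers.tsv"),
        header,
    )
    _write_tsv(calls_to_frame(result.calls), keep(outdir / "marker_calls.tsv"), header)
    _write_tsv(
        result.concordance.per_marker, keep(outdir / "concordance.tsv"), header
    )
    return paths
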