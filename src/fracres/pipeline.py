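"""End-to-end orchestration: ontology -> retention -> expression ->
design -> ANOVA / Tukey, with stage logging and CSV outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .anova import AnovaResult, anova_type2, build_design, tukey_from_design
from .errors import ConfigError, FracresError, InputError, ValidationError
from .expression import assemble_gene_records, read_expression_matrix
from .ontology import (
    FunctionalScheme,
    annotate_genes,
    load_annotations,
    load_obo,
    load_scheme,
)
from .retention import (
    read_family_table,
    retention_records,
    tabulate_retention,
    write_retention_csv,
)
from .synthetic import SimResult

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on.

    ``median_split_level`` ('low'/'high') picks the category within which
    expression medians are taken; ``gof_levels`` (3/4) selects whether
    the regulation and response halves of Z3 are one factor level or two;
    ``propagate_part_of`` additionally rolls annotations up over part_of
    edges (default: is_a only).
    """

    families: str
    obo: str
    annotations: str
    expression: str
    out_dir: str
    scheme: str | None = None  # None -> packaged default scheme
    species: Sequence[str] = ("grape", "peach", "cacao")
    expression_species: str | None = None  # defaults to species[0]
    duplicate_threshold: int = 2
    median_split_level: str = "low"
    gof_levels: int = 3
    include_singleton_genes: bool = True
    annotation_format: str = "auto"
    propagate_part_of: bool = False
    conf_level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        for name in ("families", "obo", "annotations", "expression"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise InputError(f"{name} file not found: {p}")
        if self.scheme is not None and not Path(self.scheme).exists():
            raise InputError(f"scheme file not found: {self.scheme}")
        if len(self.species) < 1:
            raise ConfigError("species list is empty")
        sp = self.expression_species or self.species[0]
        if sp not in self.species:
            raise ConfigError(
                f"expression_species {sp!r} is not in the species list {list(self.species)}"
            )
        if self.median_split_level not in {"low", "high"}:
            raise ConfigError("median_split_level must be 'low' or 'high'")
        if self.gof_levels not in {3, 4}:
            raise ConfigError("gof_levels must be 3 or 4")


@dataclass
class PipelineResult:
    retention: pd.DataFrame
    records: pd.DataFrame
    design: pd.DataFrame
    anova: AnovaResult
    tukey: pd.DataFrame
    term_counts: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write the output bundle.

    Outputs under ``config.out_dir``: retention.csv, gene_records.csv,
    design.csv, anova.csv, tukey.csv, term_counts.csv, manifest.yaml.
    Any stage error aborts with the stage name; no partial outputs are
    written.
    """
    config.validate()
    expr_species = config.expression_species or config.species[0]
    relations = ("is_a", "part_of") if config.propagate_part_of else ("is_a",)

    try:
        _stage("ontology")
        dag = load_obo(config.obo)
        scheme = (
            load_scheme(config.scheme) if config.scheme else FunctionalScheme.default()
        )
        annotations = load_annotations(config.annotations, fmt=config.annotation_format)
        logger.info("%d annotated genes", len(annotations))
        categories = annotate_genes(dag, scheme, annotations, relations=relations)
        logger.info("%d (gene, category) assignments", len(categories))

        _stage("retention")
        families = read_family_table(config.families)
        recs = retention_records(
            families, config.duplicate_threshold, list(config.species)
        )
        tab = tabulate_retention(
            families, config.duplicate_threshold, list(config.species)
        )
        logger.info("retention tabulation: %s", tab.to_dict())

        _stage("expression")
        matrix = read_expression_matrix(config.expression)
        records = assemble_gene_records(
            families,
            categories,
            matrix,
            species=expr_species,
            clade_species=list(config.species),
            duplicate_threshold=config.duplicate_threshold,
            include_singleton_genes=config.include_singleton_genes,
            median_split_level=config.median_split_level,
        )

        _stage("design")
        design = build_design(records, scheme=scheme)

        _stage("anova")
        anova = anova_type2(design, gof_levels=config.gof_levels)
        tukey = tukey_from_design(
            design, conf_level=config.conf_level, gof_levels=config.gof_levels
        )

        _stage("report")
        gene_species = pd.DataFrame(
            [
                (g, sp, fam.family_id)
                for fam in families
                for sp, genes in fam.members.items()
                for g in genes
            ],
            columns=["gene_id", "species", "family_id"],
        )
        term_counts = (
            gene_species.merge(categories, on="gene_id", how="inner")
            .groupby(["high_code", "low_code", "species"], sort=True)
            .size()
            .rename("n_genes")
            .reset_index()
            .pivot_table(
                index=["high_code", "low_code"],
                columns="species",
                values="n_genes",
                fill_value=0,
            )
            .reset_index()
        )
        term_counts.columns.name = None
    except FracresError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise FracresError(f"pipeline failed: {exc}") from exc

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "retention": out / "retention.csv",
        "records": out / "gene_records.csv",
        "design": out / "design.csv",
        "anova": out / "anova.csv",
        "tukey": out / "tukey.csv",
        "term_counts": out / "term_counts.csv",
        "manifest": out / "manifest.yaml",
    }
    write_retention_csv(recs, paths["retention"])
    records.to_csv(paths["records"], index=False)
    design.to_csv(paths["design"], index=False)
    anova.table.rename_axis("term").to_csv(paths["anova"])
    tukey.to_csv(paths["tukey"], index=False)
    term_counts.to_csv(paths["term_counts"], index=False)

    cfg = dataclasses.asdict(config)
    cfg["species"] = list(config.species)
    digest = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "fracres_version": __version__,
        "config": cfg,
        "config_sha256": digest,
        "n_families": int(len(recs)),
        "n_gene_records": int(len(records)),
        "n_design_rows": int(len(design)),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    retention_df = pd.read_csv(paths["retention"])
    return PipelineResult(
        retention=retention_df,
        records=records,
        design=design,
        anova=anova,
        tukey=tukey,
        term_counts=term_counts,
        paths={k: str(v) for k, v in paths.items()},
    )


def records_from_simulation(
    sim: SimResult,
    include_singleton_genes: bool = True,
    median_split_level: str = "low",
    duplicate_threshold: int = 2,
) -> pd.DataFrame:
    """Gene records straight from a :class:`~fracres.synthetic.SimResult`.

    Skips the file round-trip and the ontology rollup by using the
    simulator's per-family truth for category membership; scoring,
    binning, retention and design construction are the same code paths
    the file-based pipeline uses.  Intended for simulation studies
    (calibration loops) where the rollup is not under test.
    """
    fam_cat = sim.truth.set_index("family_id")[["high_code", "low_code"]]
    expr_species = sim.config.expression_species or sim.config.species[0]
    gene_rows = [
        (g, fam.family_id)
        for fam in sim.families
        for g in fam.members.get(expr_species, ())
    ]
    categories = pd.DataFrame(gene_rows, columns=["gene_id", "family_id"]).join(
        fam_cat, on="family_id"
    )[["gene_id", "high_code", "low_code"]]
    return assemble_gene_records(
        sim.families,
        categories,
        sim.expression,
        species=expr_species,
        clade_species=list(sim.config.species),
        duplicate_threshold=duplicate_threshold,
        include_singleton_genes=include_singleton_genes,
        median_split_level=median_split_level,
    )


def analyze_simulation(
    sim: SimResult,
    gof_levels: int = 3,
    include_singleton_genes: bool = True,
    median_split_level: str = "low",
) -> tuple[pd.DataFrame, AnovaResult, pd.DataFrame]:
    """Design, ANOVA and Tukey tables for a simulation in one call."""
    records = records_from_simulation(
        sim,
        include_singleton_genes=include_singleton_genes,
        median_split_level=median_split_level,
    )
    design = build_design(records, scheme=sim.config.scheme)
    return design, anova_type2(design, gof_levels=gof_levels), tukey_from_design(
        design, gof_levels=gof_levels
    )
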