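"""Synthetic post-polyploidy fractionation data.

Generates gene families, GO annotations, an organ-level expression
matrix, and a miniature ontology with the statistical structure the
analysis assumes, so every pipeline stage is testable without genome
downloads.

Generative model, per family:

* a low-level functional category is drawn uniformly from the scheme;
* a latent expression level ``e ~ LogNormal(mu_expr[term], sigma_expr)``
  is drawn, with ``z`` the within-category standardized log expression;
* each species independently keeps the family in duplicate with
  probability ``inverse_logit(alpha + beta[Z] + (gamma + delta[Z]) * z)``
  — ``beta`` carries the Gene Balance-style category effect, ``gamma``
  the Gene Dosage-style expression effect, ``delta`` their interaction;
* duplicate-retaining species get 2 gene copies, the rest 1;
* measured organ expression is ``e`` scaled by per-organ factors (max 1)
  with multiplicative log-normal noise, so the organ max estimates ``e``;
* every gene is annotated with its family's scheme term, or with a
  synthetic child of it (exercising the ontology rollup), plus optional
  extra random scheme terms.

Default effect sizes mirror the reported biology: Z1 (metabolic) most
fractionation-prone with Z2 (enzymes) close behind, Z3 (regulation and
response) resistant — a category log-odds spread of 2.0 — plus a weak
positive expression effect and no interaction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigError
from .ontology import FunctionalScheme, GeneAnnotation
from .retention import GeneFamily

logger = logging.getLogger(__name__)

DEFAULT_BETA = {"Z1": -1.0, "Z2": -0.8, "Z3": 1.0}


def _default_scheme() -> FunctionalScheme:
    return FunctionalScheme.default()


@dataclass
class SimConfig:
    """Parameters of the fractionation simulator.

    Log-odds parameters act on the per-species probability of keeping a
    family in duplicate; ``mu_expr``/``sigma_expr`` are on the natural-log
    expression scale (``mu_expr`` may be a per-low-level-term mapping).
    The same seed and config reproduce the output exactly.
    """

    n_families: int = 2000
    species: tuple = ("grape", "peach", "cacao")
    expression_species: str | None = None  # defaults to species[0]
    scheme: FunctionalScheme = field(default_factory=_default_scheme)
    alpha: float = 0.0
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    gamma: float = 0.2
    delta: Mapping[str, float] = field(default_factory=dict)
    mu_expr: float | Mapping[str, float] = 3.0
    sigma_expr: float = 1.0
    n_organs: int = 6
    organ_noise_sd: float = 0.25
    child_annotation_prob: float = 0.5
    extra_term_rate: float = 0.0
    max_copies: int = 2
    seed: int = 0

    @property
    def n_species(self) -> int:
        return len(self.species)

    def _high_param(self, mapping: Mapping[str, float], high_code: str) -> float:
        return float(mapping.get(high_code, 0.0))

    def _mu(self, low_code: str) -> float:
        if isinstance(self.mu_expr, Mapping):
            return float(self.mu_expr.get(low_code, 0.0))
        return float(self.mu_expr)

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.sigma_expr <= 0:
            raise ConfigError("sigma_expr must be > 0")
        if self.n_organs < 1:
            raise ConfigError("need at least one organ")
        if self.organ_noise_sd < 0:
            raise ConfigError("organ_noise_sd must be >= 0")
        if self.max_copies < 2:
            raise ConfigError("max_copies must be >= 2")
        if not 0.0 <= self.child_annotation_prob <= 1.0:
            raise ConfigError("child_annotation_prob must be in [0, 1]")
        if self.expression_species is not None and self.expression_species not in self.species:
            raise ConfigError("expression_species must be one of the simulated species")
        params = [self.alpha, self.gamma, *self.beta.values(), *self.delta.values()]
        if not np.all(np.isfinite(params)):
            raise ConfigError("linear-predictor parameters must be finite")


def expected_mean_retention(config: SimConfig, category: str, z: float) -> float:
    """Closed-form conditional mean retention index.

    ``n_species * inverse_logit(alpha + beta[Z] + (gamma + delta[Z]) z)``
    for a family of the given category (low- or high-level code) at
    standardized log expression ``z``.
    """
    high = category if len(category) == 2 else None
    if high is None:
        entry = config.scheme.by_low_code().get(category)
        if entry is None:
            raise ConfigError(f"unknown category code: {category}")
        high = entry.high_code
    eta = (
        config.alpha
        + config._high_param(config.beta, high)
        + (config.gamma + config._high_param(config.delta, high)) * z
    )
    return config.n_species * float(expit(eta))


@dataclass
class SimResult:
    """Simulated bundle plus the per-family generating truth."""

    families: list
    annotations: list
    expression: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def simulate(config: SimConfig) -> SimResult:
    """Run the generative model (deterministic given config + seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    entries = scheme.entries
    n = config.n_families
    n_sp = config.n_species
    expr_species = config.expression_species or config.species[0]

    term_idx = rng.integers(0, len(entries), size=n)
    z = rng.standard_normal(n)
    mu = np.array([config._mu(e.low_code) for e in entries])[term_idx]
    latent = np.exp(mu + config.sigma_expr * z)

    beta = np.array([config._high_param(config.beta, e.high_code) for e in entries])
    delta = np.array([config._high_param(config.delta, e.high_code) for e in entries])
    eta = config.alpha + beta[term_idx] + (config.gamma + delta[term_idx]) * z
    p_retain = expit(eta)
    if not np.all((p_retain > 0) & (p_retain < 1)):
        raise ConfigError("retention probabilities must lie strictly in (0, 1)")

    retained = rng.random((n, n_sp)) < p_retain[:, None]
    copies = retained.astype(int) + 1
    if config.max_copies > 2:
        copies += retained * rng.binomial(config.max_copies - 2, 0.25, size=(n, n_sp))

    fam_ids = np.array([f"F{i:05d}" for i in range(n)])
    families = []
    gene_rows: list[tuple[str, str, str]] = []  # gene_id, species, family index
    for i in range(n):
        members = {}
        for s, sp in enumerate(config.species):
            genes = tuple(f"{fam_ids[i]}_{sp}_{c + 1}" for c in range(copies[i, s]))
            members[sp] = genes
            for g in genes:
                gene_rows.append((g, sp, i))
        families.append(GeneFamily(family_id=fam_ids[i], members=members))

    # annotations: the family's scheme term, or its synthetic child
    child_ids = synthetic_child_ids(scheme)
    go_ids = np.array([e.go_id for e in entries])
    annotations = []
    n_genes = len(gene_rows)
    use_child = rng.random(n_genes) < config.child_annotation_prob
    n_extra = (
        rng.poisson(config.extra_term_rate, size=n_genes)
        if config.extra_term_rate > 0
        else np.zeros(n_genes, dtype=int)
    )
    for j, (gene, sp, i) in enumerate(gene_rows):
        t = term_idx[i]
        terms = {child_ids[t] if use_child[j] else go_ids[t]}
        for _ in range(n_extra[j]):
            terms.add(go_ids[rng.integers(0, len(entries))])
        annotations.append(GeneAnnotation(gene, frozenset(terms)))

    # organ expression for the designated species' genes
    organ_names = [f"organ{o + 1}" for o in range(config.n_organs)]
    profile = 0.8 ** np.arange(config.n_organs)
    expr_genes = [(g, i) for g, sp, i in gene_rows if sp == expr_species]
    factors = rng.permuted(
        np.tile(profile, (len(expr_genes), 1)), axis=1
    ) * np.exp(rng.normal(0.0, config.organ_noise_sd, size=(len(expr_genes), config.n_organs)))
    values = latent[[i for _, i in expr_genes]][:, None] * factors
    expression = pd.DataFrame(
        values, index=pd.Index([g for g, _ in expr_genes], name="gene_id"), columns=organ_names
    )

    truth = pd.DataFrame(
        {
            "family_id": fam_ids,
            "low_code": [entries[t].low_code for t in term_idx],
            "high_code": [entries[t].high_code for t in term_idx],
            "latent_expression": latent,
            "z": z,
            "p_retain": p_retain,
            "retention_index": retained.sum(axis=1),
        }
    )
    logger.info(
        "simulated %d families, %d genes (%d in %s expression matrix)",
        n,
        n_genes,
        len(expr_genes),
        expr_species,
    )
    return SimResult(
        families=families,
        annotations=annotations,
        expression=expression,
        truth=truth,
        config=config,
    )


def rosid_like(**overrides) -> SimConfig:
    """Preset with low baseline retention: most families end up singletons
    in all species, as in the long-diverged rosid clade."""
    overrides.setdefault("alpha", -1.5)
    overrides.setdefault("species", ("grape", "peach", "cacao"))
    return SimConfig(**overrides)


def asterid_like(**overrides) -> SimConfig:
    """Preset with higher baseline retention giving a flatter retention
    distribution, as in the asterid clade with its extra duplications."""
    overrides.setdefault("alpha", -0.6)
    overrides.setdefault("species", ("tomato", "mimulus", "utricularia"))
    return SimConfig(**overrides)


# ---------------------------------------------------------------------------
# Writers: the exact dialects the pipeline readers consume
# ---------------------------------------------------------------------------

def synthetic_child_ids(scheme: FunctionalScheme) -> list[str]:
    """Synthetic child-term id for each scheme entry (GO:9xxxxxx range)."""
    return [f"GO:9{i:06d}" for i in range(len(scheme.entries))]


_MINI_ROOTS = (
    ("GO:0008150", "biological_process", "biological_process"),
    ("GO:0003674", "molecular_function", "molecular_function"),
    ("GO:0005575", "cellular_component", "cellular_component"),
)

# intermediate layer: scheme terms attach here, never directly to a root,
# so the rollup has to walk at least two levels
_MINI_INTERMEDIATES = (
    ("GO:0008152", "metabolic process", "biological_process", "GO:0008150"),
    ("GO:0003824", "catalytic activity", "molecular_function", "GO:0003674"),
    ("GO:0065007", "biological regulation", "biological_process", "GO:0008150"),
    ("GO:0050896", "response to stimulus", "biological_process", "GO:0008150"),
    ("GO:0140110", "transcription regulator activity", "molecular_function", "GO:0003674"),
    ("GO:0023052", "signaling", "biological_process", "GO:0008150"),
)

_PARENT_BY_LOW = {
    "Z31": "GO:0065007",
    "Z32": "GO:0140110",
    "Z33": "GO:0023052",
    "Z34": "GO:0050896",
    "Z35": "GO:0050896",
    "Z36": "GO:0050896",
}


def build_mini_obo(scheme: FunctionalScheme) -> str:
    """A miniature OBO ontology containing the scheme terms, nested
    intermediates, the three roots, one synthetic child per scheme term,
    and one obsolete decoy term."""
    lines = ["format-version: 1.2", "ontology: fracres-mini", ""]

    def stanza(go_id, name, namespace, parents=(), obsolete=False):
        lines.append("[Term]")
        lines.append(f"id: {go_id}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {namespace}")
        for p in parents:
            lines.append(f"is_a: {p}")
        if obsolete:
            lines.append("is_obsolete: true")
        lines.append("")

    for go_id, name, ns in _MINI_ROOTS:
        stanza(go_id, name, ns)
    for go_id, name, ns, parent in _MINI_INTERMEDIATES:
        stanza(go_id, name, ns, [parent])
    child_ids = synthetic_child_ids(scheme)
    for i, e in enumerate(scheme.entries):
        if e.high_code == "Z1":
            parent, ns = "GO:0008152", "biological_process"
        elif e.high_code == "Z2":
            parent, ns = "GO:0003824", "molecular_function"
        else:
            parent = _PARENT_BY_LOW.get(e.low_code, "GO:0008150")
            ns = "molecular_function" if parent == "GO:0140110" else "biological_process"
        stanza(e.go_id, e.label, ns, [parent])
        stanza(child_ids[i], f"synthetic subtype of {e.label}", ns, [e.go_id])
    stanza("GO:8000000", "synthetic obsolete decoy", "biological_process", obsolete=True)
    return "\n".join(lines)


def write_bundle(result: SimResult, outdir: str | Path) -> dict:
    """Write the simulated data in the pipeline's input formats.

    Emits families.tsv (long form), annotations.gaf, expression.tsv,
    ontology.obo, scheme.tsv, and manifest.yaml; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = result.config
    paths = {
        "families": outdir / "families.tsv",
        "annotations": outdir / "annotations.gaf",
        "expression": outdir / "expression.tsv",
        "obo": outdir / "ontology.obo",
        "scheme": outdir / "scheme.tsv",
        "manifest": outdir / "manifest.yaml",
    }

    rows = [
        (fam.family_id, sp, g)
        for fam in result.families
        for sp in config.species
        for g in fam.members.get(sp, ())
    ]
    pd.DataFrame(rows, columns=["family_id", "species", "gene_id"]).to_csv(
        paths["families"], sep="\t", index=False
    )

    with open(paths["annotations"], "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for ann in result.annotations:
            for term in sorted(ann.direct_terms):
                fh.write(
                    "\t".join(
                        [
                            "fracres",  # DB
                            ann.gene_id,  # DB object id
                            ann.gene_id,  # symbol
                            "",  # qualifier
                            term,  # GO id
                            "fracres:sim",  # reference
                            "IEA",  # evidence
                            "",  # with/from
                            "P",  # aspect
                            "",
                            "",
                            "gene",
                            "taxon:0",
                            "20260101",
                            "fracres",
                        ]
                    )
                    + "\n"
                )

    result.expression.to_csv(paths["expression"], sep="\t")
    paths["obo"].write_text(build_mini_obo(config.scheme))
    scheme_df = pd.DataFrame(
        [dataclasses.astuple(e) for e in config.scheme.entries],
        columns=["low_code", "go_id", "label", "high_code"],
    )
    scheme_df.to_csv(paths["scheme"], sep="\t", index=False)

    cfg = dataclasses.asdict(config)
    cfg.pop("scheme")
    cfg["species"] = list(config.species)
    cfg["beta"] = dict(config.beta)
    cfg["delta"] = dict(config.delta)
    if isinstance(config.mu_expr, Mapping):
        cfg["mu_expr"] = dict(config.mu_expr)
    manifest = {
        "generator": "fracres.synthetic.simulate",
        "config": cfg,
        "n_genes": int(sum(len(g) for f in result.families for g in f.members.values())),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
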