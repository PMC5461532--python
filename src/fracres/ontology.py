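"""Gene Ontology DAG handling and functional-category rollup.

Genes are assigned to high-level functional categories (Z1 metabolic
process, Z2 enzyme class, Z3 regulation-and-response) through a fixed
scheme of 18 low-level GO terms (6 per high-level category).  A gene
matches a low-level term when that term appears in the reflexive
transitive closure (over propagating relations, ``is_a`` by default) of
any of the gene's direct annotations.

The DAG is parsed from OBO with :mod:`obonet`; GAF 2.x and two-column
TSV annotation files are supported.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .errors import ConfigError, FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: The three ontology roots ("biological process", "cellular component",
#: "molecular function") by stable identifier.
GO_ROOT_IDS = frozenset({"GO:0008150", "GO:0005575", "GO:0003674"})
GO_ROOT_NAMES = frozenset(
    {
        "biological process",
        "biological_process",
        "cellular component",
        "cellular_component",
        "molecular function",
        "molecular_function",
    }
)

#: Relations over which annotations propagate towards the roots.
DEFAULT_RELATIONS = ("is_a",)


@dataclass
class GODag:
    """A Gene Ontology DAG.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose edges point from
    child to parent and carry the relation kind as their key (``is_a``,
    ``part_of``, ...).  ``roots`` is the set of terms the DAG bottoms out
    in; every other term must reach at least one root.
    """

    graph: nx.MultiDiGraph
    roots: frozenset = field(default_factory=frozenset)
    _closure_cache: dict = field(default_factory=dict, repr=False)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> set:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
        terms: Iterable[str] = (),
        names: Mapping[str, str] | None = None,
        validate: bool = True,
    ) -> "GODag":
        """Build a DAG from ``(child, parent[, relation])`` tuples.

        Terms with no outgoing propagating edge become the roots.  Mainly
        useful for tests and for programmatically generated ontologies.
        """
        g = nx.MultiDiGraph()
        for t in terms:
            g.add_node(t)
        for e in edges:
            child, parent = e[0], e[1]
            rel = e[2] if len(e) > 2 else "is_a"
            g.add_edge(child, parent, key=rel)
        if names:
            for t, n in names.items():
                if t in g:
                    g.nodes[t]["name"] = n
        dag = cls(graph=g)
        dag.roots = frozenset(n for n in g.nodes if g.out_degree(n) == 0)
        if validate:
            dag.validate()
        return dag

    def validate(self, require_named_roots: bool = False) -> None:
        """Check acyclicity and that every term reaches a root."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join(str(edge[0]) for edge in cycle) + f" -> {cycle[-1][1]}"
            raise FormatError(f"ontology contains a cycle: {path}")
        if require_named_roots:
            bad = [
                n
                for n in self.roots
                if n not in GO_ROOT_IDS
                and self.graph.nodes[n].get("name", "").lower() not in GO_ROOT_NAMES
            ]
            if bad:
                raise FormatError(
                    "term(s) with no path to any ontology root: " + ", ".join(sorted(bad))
                )
        # reachability: in a finite acyclic graph every node reaches a sink,
        # so with sink-derived roots this only fails for explicit root sets
        for n in self.graph.nodes:
            if n in self.roots:
                continue
            if not any(r in self.ancestors(n, relations=None) for r in self.roots):
                raise FormatError(f"term {n} has no path to any ontology root")

    def _propagation_graph(self, relations: Sequence[str] | None) -> nx.DiGraph:
        key = tuple(sorted(relations)) if relations is not None else None
        cached = self._closure_cache.get(("graph", key))
        if cached is not None:
            return cached
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for child, parent, rel in self.graph.edges(keys=True):
            if relations is None or rel in relations:
                g.add_edge(child, parent)
        self._closure_cache[("graph", key)] = g
        return g

    def ancestors(self, term: str, relations: Sequence[str] | None = DEFAULT_RELATIONS) -> set:
        """Reflexive transitive closure of ``term`` over propagating edges.

        Returns the term itself plus every term reachable by following
        child-to-parent edges of the given relation kinds (all kinds when
        ``relations`` is None).
        """
        if term not in self.graph:
            raise KeyError(f"unknown GO term: {term}")
        key = ("closure", tuple(sorted(relations)) if relations is not None else None, term)
        cached = self._closure_cache.get(key)
        if cached is None:
            pg = self._propagation_graph(relations)
            cached = frozenset(nx.descendants(pg, term)) | {term}
            self._closure_cache[key] = cached
        return set(cached)


def load_obo(
    path: str | Path,
    validate_roots: bool = True,
) -> GODag:
    """Parse an OBO 1.2/1.4 file into a :class:`GODag`.

    Obsolete terms are excluded.  Raises :class:`InputError` for an
    unreadable file and :class:`FormatError` for a cyclic ontology or a
    term without a path to one of the three roots.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"ontology file not found: {path}")
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except FormatError:
        raise
    except Exception as exc:  # malformed OBO surfaces as ValueError from obonet
        raise FormatError(f"could not parse OBO file {path}: {exc}") from exc
    # obonet orients edges child -> parent already
    dag = GODag(graph=nx.MultiDiGraph(graph))
    named_roots = {
        n
        for n in dag.graph.nodes
        if n in GO_ROOT_IDS or dag.graph.nodes[n].get("name", "").lower() in GO_ROOT_NAMES
    }
    sinks = {n for n in dag.graph.nodes if dag.graph.out_degree(n) == 0}
    dag.roots = frozenset(named_roots or sinks)
    if not nx.is_directed_acyclic_graph(dag.graph):
        cycle = nx.find_cycle(dag.graph)
        path_s = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
        raise FormatError(f"ontology contains a cycle: {path_s}")
    if validate_roots and named_roots:
        stranded = sorted(sinks - named_roots)
        if stranded:
            raise FormatError(
                "term(s) with no path to any ontology root: " + ", ".join(stranded)
            )
    logger.info("loaded ontology %s: %d terms, %d edges", path.name, len(dag), dag.graph.number_of_edges())
    return dag


# ---------------------------------------------------------------------------
# Functional scheme
# ---------------------------------------------------------------------------

_LOW_CODE_RE = re.compile(r"^Z[1-9][0-9]$")
_HIGH_CODE_RE = re.compile(r"^Z[1-9]$")


@dataclass(frozen=True)
class SchemeEntry:
    low_code: str
    go_id: str
    label: str
    high_code: str


@dataclass
class FunctionalScheme:
    """The mapping of low-level GO terms to high-level categories.

    The shipped default has 18 entries, six per high-level code (Z1
    metabolic process, Z2 enzyme class, Z3 regulation and response); user
    schemes may differ in size but codes and GO ids must be unique.
    """

    entries: tuple[SchemeEntry, ...]

    def __post_init__(self):
        go_ids = [e.go_id for e in self.entries]
        low_codes = [e.low_code for e in self.entries]
        if len(set(go_ids)) != len(go_ids):
            raise ConfigError("scheme GO identifiers must be unique")
        if len(set(low_codes)) != len(low_codes):
            raise ConfigError("scheme low-level codes must be unique")
        for e in self.entries:
            if not _LOW_CODE_RE.match(e.low_code) or not _HIGH_CODE_RE.match(e.high_code):
                raise ConfigError(f"malformed scheme codes: {e.low_code}/{e.high_code}")
            if not e.low_code.startswith(e.high_code):
                raise ConfigError(
                    f"low-level code {e.low_code} does not belong to high-level {e.high_code}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def high_codes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.high_code, None)
        return tuple(seen)

    @property
    def go_ids(self) -> tuple[str, ...]:
        return tuple(e.go_id for e in self.entries)

    def by_go_id(self) -> dict[str, SchemeEntry]:
        return {e.go_id: e for e in self.entries}

    def by_low_code(self) -> dict[str, SchemeEntry]:
        return {e.low_code: e for e in self.entries}

    @classmethod
    def default(cls) -> "FunctionalScheme":
        """The packaged 18-term scheme (6 terms per high-level category)."""
        with resources.files("fracres.data").joinpath("default_scheme.tsv").open() as fh:
            scheme = _parse_scheme(fh)
        if len(scheme) != 18 or any(
            sum(e.high_code == h for e in scheme.entries) != 6 for h in scheme.high_codes
        ):
            raise ConfigError("packaged scheme must have 18 entries, 6 per high-level code")
        return scheme


def _parse_scheme(fh) -> FunctionalScheme:
    reader = csv.DictReader(fh, delimiter="\t")
    required = {"low_code", "go_id", "label", "high_code"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise FormatError(f"scheme file must have columns {sorted(required)}")
    entries = tuple(
        SchemeEntry(row["low_code"], row["go_id"], row["label"], row["high_code"])
        for row in reader
    )
    return FunctionalScheme(entries=entries)


def load_scheme(path: str | Path) -> FunctionalScheme:
    """Read a functional scheme from a TSV with columns
    low_code, go_id, label, high_code."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"scheme file not found: {path}")
    with open(path) as fh:
        return _parse_scheme(fh)


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """Direct GO annotations of one gene (possibly empty)."""

    gene_id: str
    direct_terms: frozenset


def load_gaf(
    path: str | Path,
    evidence_codes: Iterable[str] | None = None,
) -> list[GeneAnnotation]:
    """Read a GAF 2.x file (columns 2 and 5: object id, GO id).

    Lines beginning with ``!`` are comments; rows whose qualifier contains
    ``NOT`` are skipped.  ``evidence_codes`` optionally restricts to an
    include-list of evidence codes (column 7).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    evidence = set(evidence_codes) if evidence_codes is not None else None
    terms: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: GAF row has {len(fields)} columns, needs >=7")
            gene_id, qualifier, go_id, code = fields[1], fields[3], fields[4], fields[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence is not None and code not in evidence:
                continue
            terms.setdefault(gene_id, set()).add(go_id)
    return [GeneAnnotation(g, frozenset(t)) for g, t in terms.items()]


def load_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read the two-column fallback format: gene_id <TAB> go_id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    terms: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            if lineno == 1 and fields[1].lower() in {"go_id", "goid", "term"}:
                continue
            terms.setdefault(fields[0], set()).add(fields[1])
    return [GeneAnnotation(g, frozenset(t)) for g, t in terms.items()]


def load_annotations(path: str | Path, fmt: str = "auto", **kwargs) -> list[GeneAnnotation]:
    """Dispatch to :func:`load_gaf` or :func:`load_annotation_tsv`.

    ``fmt='auto'`` decides by file suffix (``.gaf`` vs anything else).
    """
    if fmt == "auto":
        fmt = "gaf" if str(path).endswith(".gaf") else "tsv"
    if fmt == "gaf":
        return load_gaf(path, **kwargs)
    if fmt == "tsv":
        return load_annotation_tsv(path)
    raise ConfigError(f"unknown annotation format: {fmt!r}")


# ---------------------------------------------------------------------------
# Category assignment (GO rollup)
# ---------------------------------------------------------------------------

def ancestors(
    dag: GODag, term: str, relations: Sequence[str] | None = DEFAULT_RELATIONS
) -> set:
    """Module-level alias of :meth:`GODag.ancestors`."""
    return dag.ancestors(term, relations=relations)


def assign_categories(
    dag: GODag,
    scheme: FunctionalScheme,
    annotation: GeneAnnotation,
    relations: Sequence[str] | None = DEFAULT_RELATIONS,
    strict: bool = False,
) -> set:
    """Assign a gene to every (high_code, low_code) whose scheme GO term
    lies in the ancestor closure of one of its direct annotations.

    Multiple assignments are retained, including across high-level codes.
    Direct terms absent from the DAG are skipped with a warning (raised
    instead when ``strict``).
    """
    missing = [e.go_id for e in scheme.entries if e.go_id not in dag]
    if missing:
        raise ConfigError(
            "scheme GO term(s) missing from the ontology: " + ", ".join(missing)
        )
    by_go = scheme.by_go_id()
    assigned: set = set()
    for term in annotation.direct_terms:
        if term not in dag:
            msg = f"gene {annotation.gene_id}: direct term {term} not in ontology"
            if strict:
                raise ValidationError(msg)
            logger.warning("%s; skipped", msg)
            continue
        for anc in dag.ancestors(term, relations=relations):
            entry = by_go.get(anc)
            if entry is not None:
                assigned.add((entry.high_code, entry.low_code))
    return assigned


def annotate_genes(
    dag: GODag,
    scheme: FunctionalScheme,
    annotations: Iterable[GeneAnnotation],
    relations: Sequence[str] | None = DEFAULT_RELATIONS,
):
    """Roll up a collection of gene annotations to scheme categories.

    Returns a pandas DataFrame with one row per (gene_id, high_code,
    low_code); genes matching no scheme term are absent.
    """
    import pandas as pd

    rows = []
    for ann in annotations:
        for high, low in sorted(assign_categories(dag, scheme, ann, relations=relations)):
            rows.append((ann.gene_id, high, low))
    return pd.DataFrame(rows, columns=["gene_id", "high_code", "low_code"])
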