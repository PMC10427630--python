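"""Rule-based histopathology spot classification and category DGE.

Spots are labelled ``affected`` / ``unaffected`` / ``excluded`` by boolean
rules over raw gene counts, scoped to named clusters.  Three rule sets ship
built in, matching the published selections for muscle regeneration (mdx),
fibrosis and calcification (D2-mdx):

* ``regeneration`` — affected: regenerated-fiber clusters with
  (Myog>0 AND Igfbp7>0) OR (Myh3>0 AND Igfbp7>0); unaffected: muscle fibers
  without centralized nuclei and none of the three markers detected.
* ``fibrosis`` — affected: Cd34 detected in the three eligible clusters
  (with or without Lox), or connective-tissue spots with Lox>3 AND Col1a1>3;
  unaffected: muscle-fiber spots with Cd34=0, Lox=0 and Col1a1<2.
* ``calcification`` — affected: inflamed/calcified-fiber spots with Mgp>0;
  unaffected: muscle-fiber spots with Mgp=0.

Differential expression between the affected and unaffected categories uses
a one-sided (greater-in-affected) Wilcoxon rank-sum test with the same
filtering and Bonferroni contract as cluster marker detection, sorted by
fold change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .preprocess import wilcoxon_de

_TOKEN = re.compile(r"\s*(\(|\)|AND\b|OR\b|>=|<=|==|>|<|-?\d+|[A-Za-z0-9_.\-]+)")

_OPS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
}


class Expr:
    """Boolean expression over integer gene counts."""

    def evaluate(self, counts) -> np.ndarray:  # counts: gene -> count vector
        raise NotImplementedError

    def genes(self) -> set[str]:
        raise NotImplementedError


@dataclass
class Atom(Expr):
    gene: str
    op: str
    value: int

    def evaluate(self, counts):
        if self.gene not in counts:
            raise ConfigurationError(f"rule references unknown gene {self.gene!r}")
        return _OPS[self.op](counts[self.gene], self.value)

    def genes(self):
        return {self.gene}

    def __str__(self):
        return f"{self.gene} {self.op} {self.value}"


@dataclass
class BoolOp(Expr):
    op: str  # "AND" | "OR"
    terms: list

    def evaluate(self, counts):
        vals = [t.evaluate(counts) for t in self.terms]
        out = vals[0]
        for v in vals[1:]:
            out = (out & v) if self.op == "AND" else (out | v)
        return out

    def genes(self):
        return set().union(*(t.genes() for t in self.terms))

    def __str__(self):
        sep = f" {self.op} "
        return "(" + sep.join(str(t) for t in self.terms) + ")"


def parse_rule(text: str) -> Expr:
    """Parse ``gene OP integer`` atoms combined with AND / OR / parentheses."""
    tokens = _TOKEN.findall(text)
    if "".join(tokens).replace(" ", "") != text.replace(" ", ""):
        raise ConfigurationError(f"cannot tokenize rule: {text!r}")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() == "OR":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else BoolOp("OR", terms)

    def parse_and():
        terms = [parse_factor()]
        while peek() == "AND":
            take()
            terms.append(parse_factor())
        return terms[0] if len(terms) == 1 else BoolOp("AND", terms)

    def parse_factor():
        if peek() == "(":
            take()
            node = parse_or()
            if take() != ")":
                raise ConfigurationError(f"unbalanced parentheses in rule: {text!r}")
            return node
        gene = take()
        op = take()
        if op not in _OPS:
            raise ConfigurationError(f"unknown operator {op!r} in rule: {text!r}")
        return Atom(gene, op, int(take()))

    try:
        node = parse_or()
    except ConfigurationError:
        raise
    except (IndexError, ValueError) as exc:
        raise ConfigurationError(f"malformed rule {text!r}: {exc}") from exc
    if pos != len(tokens):
        raise ConfigurationError(f"trailing tokens in rule: {text!r}")
    return node


@dataclass
class Clause:
    """A predicate applied only to spots of the listed clusters."""

    clusters: frozenset
    predicate: Expr

    @classmethod
    def make(cls, clusters, rule: str) -> "Clause":
        return cls(frozenset(clusters), parse_rule(rule))


@dataclass
class RuleSet:
    name: str
    affected: list = field(default_factory=list)
    unaffected: list = field(default_factory=list)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for cl in self.affected + self.unaffected:
            out |= cl.predicate.genes()
        return out

    def cluster_names(self) -> set[str]:
        out: set[str] = set()
        for cl in self.affected + self.unaffected:
            out |= set(cl.clusters)
        return out

    @classmethod
    def from_config(cls, cfg: dict) -> "RuleSet":
        def clauses(entries):
            return [Clause.make(e["clusters"], e["rule"]) for e in entries]

        return cls(cfg["name"], clauses(cfg["affected"]), clauses(cfg["unaffected"]))


REGENERATION = RuleSet(
    "regeneration",
    affected=[
        Clause.make(
            ["regenerated fibers", "regenerating fibers and inflamed patches"],
            "(Myog > 0 AND Igfbp7 > 0) OR (Myh3 > 0 AND Igfbp7 > 0)",
        )
    ],
    unaffected=[
        Clause.make(
            ["muscle fibers without CN"],
            "Myog == 0 AND Igfbp7 == 0 AND Myh3 == 0",
        )
    ],
)

FIBROSIS = RuleSet(
    "fibrosis",
    affected=[
        # "solely Cd34, or Cd34 and Lox" jointly reduce to Cd34 detected
        Clause.make(
            ["inflamed and/or calcified fibers", "muscle fibers", "connective tissue"],
            "Cd34 > 0",
        ),
        Clause.make(["connective tissue"], "Lox > 3 AND Col1a1 > 3"),
    ],
    unaffected=[
        Clause.make(["muscle fibers"], "Cd34 == 0 AND Lox == 0 AND Col1a1 < 2")
    ],
)

CALCIFICATION = RuleSet(
    "calcification",
    affected=[Clause.make(["inflamed and/or calcified fibers"], "Mgp > 0")],
    unaffected=[Clause.make(["muscle fibers"], "Mgp == 0")],
)

RULESETS = {rs.name: rs for rs in (REGENERATION, FIBROSIS, CALCIFICATION)}


def classify_spots(counts, gene_names, cluster_names, ruleset: RuleSet,
                   known_clusters=None) -> pd.Series:
    """Label each spot ``affected`` / ``unaffected`` / ``excluded``.

    ``counts`` are raw (pre-normalization, post-QC) spot x gene counts;
    ``cluster_names`` is the per-spot annotated cluster name.  A spot is
    affected (unaffected) when any affected (unaffected) clause whose
    cluster scope contains the spot's cluster evaluates true; anything else
    is excluded.  Rule sets referencing a cluster name outside the
    annotation vocabulary (``known_clusters``, defaulting to the names
    observed on the spots) raise an error listing the available names.
    """
    gene_names = pd.Index(gene_names)
    cluster_names = pd.Series(np.asarray(cluster_names, dtype=object))
    available = set(known_clusters) if known_clusters is not None else set(
        cluster_names.unique())
    missing = ruleset.cluster_names() - available
    if missing:
        raise ConfigurationError(
            f"rule set {ruleset.name!r} references clusters {sorted(missing)} "
            f"not present in the data; available: {sorted(available)}"
        )
    X = np.asarray(counts.todense() if sp.issparse(counts) else counts)
    lookup = {}
    for g in ruleset.genes():
        pos = gene_names.get_indexer([g])[0]
        if pos < 0:
            raise ConfigurationError(f"rule set {ruleset.name!r} references unknown gene {g!r}")
        lookup[g] = X[:, pos]

    n = X.shape[0]
    affected = np.zeros(n, dtype=bool)
    unaffected = np.zeros(n, dtype=bool)
    clusters = cluster_names.to_numpy()
    for cl in ruleset.affected:
        scope = np.isin(clusters, list(cl.clusters))
        affected |= scope & cl.predicate.evaluate(lookup)
    for cl in ruleset.unaffected:
        scope = np.isin(clusters, list(cl.clusters))
        unaffected |= scope & cl.predicate.evaluate(lookup)
    labels = np.where(affected, "affected", np.where(unaffected, "unaffected", "excluded"))
    out = pd.Series(labels, name=ruleset.name)
    out.attrs["ruleset"] = ruleset.name
    return out


def dge_categories(Xnorm, gene_names, labels: pd.Series, min_pct: float = 0.1,
                   logfc_min: float = 0.25, min_cells_feature: int = 5,
                   alternative: str = "greater") -> pd.DataFrame:
    """Upregulated genes in affected vs unaffected spots.

    One-sided (greater-in-affected) Wilcoxon rank-sum by default, Bonferroni
    over genes tested; the table is sorted by decreasing fold change.
    """
    labels = np.asarray(labels)
    X = np.asarray(Xnorm.todense() if sp.issparse(Xnorm) else Xnorm, dtype=np.float64)
    in_mask = labels == "affected"
    out_mask = labels == "unaffected"
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise ConfigurationError(
            f"need at least 3 spots per category; got {int(in_mask.sum())} affected "
            f"and {int(out_mask.sum())} unaffected"
        )
    table = wilcoxon_de(X[in_mask], X[out_mask], pd.Index(gene_names),
                        min_pct=min_pct, logfc_min=logfc_min,
                        min_cells_feature=min_cells_feature, alternative=alternative)
    return table.sort_values("log2_fold_change", ascending=False,
                             kind="stable").reset_index(drop=True)
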