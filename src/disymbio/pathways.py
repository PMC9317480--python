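"""Biosynthetic-pathway completeness with alternative-enzyme logic.

A pathway is an ordered list of enzymatic steps; each step carries a set of
alternative genes, any one of which performs the reaction (e.g. the
riboflavin phosphatase step satisfied by yigB, ybjI, or yigL). A step is
satisfied in a genome set when any alternative is intact in any member; a
pathway is complete only when every step is satisfied — completeness is
strictly all-steps, with no partial score. Evaluating steps over the union
of two symbiont genomes captures metabolic complementarity: a consortium
can be complete where neither member alone is, and each step's providers
record which member covers it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd
import yaml

from .gene_status import INTACT, MISSING, PSEUDOGENE, StatusTable

__all__ = [
    "SATISFIED",
    "PSEUDOGENIZED",
    "STEP_MISSING",
    "PathwayStep",
    "Pathway",
    "PathwayCatalog",
    "StepStatus",
    "PathwayVerdict",
    "ConsortiumVerdict",
    "CatalogError",
    "load_default_catalog",
    "step_status",
    "pathway_completeness",
    "consortium_completeness",
    "complementarity_matrix",
]

SATISFIED = "SATISFIED"
PSEUDOGENIZED = "PSEUDOGENIZED"
STEP_MISSING = "MISSING"


class CatalogError(ValueError):
    """A pathway catalog inconsistent with the status tables or panel."""


@dataclass(frozen=True)
class PathwayStep:
    name: str
    alternatives: tuple[str, ...]
    enzyme: str = ""

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise CatalogError(f"step {self.name}: no alternative genes")


@dataclass(frozen=True)
class Pathway:
    name: str
    steps: tuple[PathwayStep, ...]

    @property
    def gene_names(self) -> list[str]:
        return [g for s in self.steps for g in s.alternatives]


@dataclass
class PathwayCatalog:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        self._by_name = {p.name: p for p in self.pathways}

    def __getitem__(self, name: str) -> Pathway:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.pathways)

    @property
    def gene_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pathways:
            for g in p.gene_names:
                seen.setdefault(g)
        return list(seen)

    def subset(self, names: Sequence[str]) -> "PathwayCatalog":
        return PathwayCatalog([self._by_name[n] for n in names])

    @classmethod
    def from_dict(cls, data: dict) -> "PathwayCatalog":
        pathways = []
        for pname, steps in data["pathways"].items():
            parsed = []
            for step in steps:
                alts = step["alternatives"]
                if isinstance(alts, str):
                    alts = [alts]
                parsed.append(PathwayStep(step["step"], tuple(alts), step.get("enzyme", "")))
            pathways.append(Pathway(pname, tuple(parsed)))
        return cls(pathways)

    @classmethod
    def from_yaml(cls, path: str) -> "PathwayCatalog":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_default_catalog() -> PathwayCatalog:
    """Bundled catalog: riboflavin (with phosphatase alternatives
    yigB/ybjI/yigL), biotin, and the ten host-essential amino acids, with
    the standard enterobacterial biosynthesis gene sets. Fully overridable
    via a user YAML of the same schema."""
    text = resources.files("disymbio.data").joinpath("pathways.yaml").read_text()
    return PathwayCatalog.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class StepStatus:
    """Verdict for one step over a set of genomes.

    SATISFIED when some alternative is intact somewhere (providers lists
    the genomes holding one); otherwise PSEUDOGENIZED dominates MISSING —
    any pseudogenized alternative anywhere makes the step Ψ.
    """

    value: str
    providers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.value == SATISFIED) != bool(self.providers):
            raise ValueError("SATISFIED if and only if providers non-empty")


@dataclass(frozen=True)
class PathwayVerdict:
    pathway_name: str
    genomes: tuple[str, ...]
    per_step: tuple[StepStatus, ...]

    @property
    def complete(self) -> bool:
        return all(s.value == SATISFIED for s in self.per_step)


@dataclass(frozen=True)
class ConsortiumVerdict(PathwayVerdict):
    """Pathway verdict over a genome union, with provider attribution.

    ``unique_providers`` names the complementarity signal: steps covered by
    exactly one member; ``redundant_steps`` those covered by several.
    """

    unique_providers: tuple[tuple[str, str], ...] = ()  # (step_name, genome)
    redundant_steps: frozenset[str] = frozenset()


def step_status(step: PathwayStep, tables: Sequence[StatusTable]) -> StepStatus:
    """Evaluate one step over one or more genomes' status tables."""
    if not tables:
        raise ValueError("at least one status table required")
    providers = set()
    any_pseudo = False
    for table in tables:
        for gene in step.alternatives:
            if gene not in table:
                raise CatalogError(
                    f"step {step.name}: alternative {gene!r} absent from "
                    f"status table for {table.genome!r}"
                )
            status = table.status_of(gene)
            if status == INTACT:
                providers.add(table.genome)
            elif status == PSEUDOGENE:
                any_pseudo = True
    if providers:
        return StepStatus(SATISFIED, frozenset(providers))
    return StepStatus(PSEUDOGENIZED if any_pseudo else STEP_MISSING)


def pathway_completeness(pathway: Pathway, table: StatusTable) -> PathwayVerdict:
    """Per-genome pathway verdict (one genome's column of the matrix)."""
    per_step = tuple(step_status(s, [table]) for s in pathway.steps)
    return PathwayVerdict(pathway.name, (table.genome,), per_step)


def consortium_completeness(pathway: Pathway, tables: Sequence[StatusTable]) -> ConsortiumVerdict:
    """Pathway verdict over the union of genomes.

    Monotone in the genome set: adding a table never un-satisfies a step.
    """
    per_step = tuple(step_status(s, tables) for s in pathway.steps)
    unique = tuple(
        (step.name, next(iter(st.providers)))
        for step, st in zip(pathway.steps, per_step)
        if len(st.providers) == 1
    )
    redundant = frozenset(
        step.name for step, st in zip(pathway.steps, per_step) if len(st.providers) > 1
    )
    return ConsortiumVerdict(
        pathway.name,
        tuple(t.genome for t in tables),
        per_step,
        unique_providers=unique,
        redundant_steps=redundant,
    )


def complementarity_matrix(
    catalog: PathwayCatalog,
    tables: Sequence[StatusTable],
    consortium_column: bool = True,
) -> pd.DataFrame:
    """Assemble the per-gene, per-genome status matrix.

    One row per (pathway, step, gene) in catalog order (pathway order, then
    step index, then gene name within a step); one column per genome with
    the gene's own status; optionally a consortium column with the step
    verdict over the union.
    """
    rows = []
    for pathway in catalog:
        for idx, step in enumerate(pathway.steps):
            consortium = step_status(step, tables) if consortium_column else None
            for gene in sorted(step.alternatives):
                row = {
                    "pathway": pathway.name,
                    "step": step.name,
                    "step_index": idx,
                    "gene": gene,
                }
                for table in tables:
                    row[table.genome] = table.status_of(gene)
                if consortium is not None:
                    row["consortium_step"] = consortium.value
                rows.append(row)
    return pd.DataFrame(rows)
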