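"""Co-expression path classification and restoration-set extraction.

A gene's co-expression path is the ordered tuple of its trinary calls
(up / down / unchanged, always against the fixed reference condition)
over the path conditions. Genes sharing a tuple form one path; with k
path conditions at most 3**k paths exist and the non-empty ones
partition the analyzed gene universe. Paths are call-tuples, not
correlation clusters.

Restoration sets project each path label onto two named positions: the
injured-untreated condition and the injured-treated condition. A gene
"restored to baseline" is up (or down) in the former and *unchanged vs
the never-injured reference* in the latter; "persistent" genes stay
altered under treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ExperimentDesign
from .errors import DesignError, IncompletenessError

PATH_SEPARATOR = "|"


@dataclass(frozen=True)
class CoexpressionPath:
    """One path: a call tuple and the genes assigned to it."""

    label: tuple[str, ...]
    genes: frozenset[str]

    @property
    def label_str(self) -> str:
        return PATH_SEPARATOR.join(self.label)

    @property
    def is_flat(self) -> bool:
        """True for the all-unchanged path (kept as background, non-DE)."""
        return all(c == "unchanged" for c in self.label)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RestorationSets:
    """Genes grouped by their injury response and its fate under drug."""

    up_restored: frozenset[str]
    down_restored: frozenset[str]
    up_persistent: frozenset[str]
    down_persistent: frozenset[str]

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "up_restored": self.up_restored,
            "down_restored": self.down_restored,
            "up_persistent": self.up_persistent,
            "down_persistent": self.down_persistent,
        }


def classify_paths(
    de: pd.DataFrame, design: ExperimentDesign
) -> list[CoexpressionPath]:
    """Partition the DE table's genes into co-expression paths.

    Requires one (gene, contrast) row for every path condition; a gene
    with missing contrasts raises :class:`IncompletenessError`. Empty
    paths are omitted. The result is ordered by size (largest first),
    ties broken by label.
    """
    missing_conds = set(design.path_conditions) - set(de["contrast"])
    if missing_conds:
        raise DesignError(
            f"DE table has no rows for conditions {sorted(missing_conds)}"
        )
    calls = de.pivot_table(
        index="gene", columns="contrast", values="call", aggfunc="first"
    )
    sub = calls.reindex(columns=list(design.path_conditions))
    incomplete = sub.isna().any(axis=1)
    if incomplete.any():
        gene = sub.index[incomplete][0]
        raise IncompletenessError(
            f"gene {gene!r} is missing a call for at least one path condition"
        )
    grouped: dict[tuple[str, ...], set[str]] = {}
    for gene, row in zip(sub.index, sub.to_numpy()):
        grouped.setdefault(tuple(row), set()).add(gene)
    paths = [
        CoexpressionPath(label=label, genes=frozenset(genes))
        for label, genes in grouped.items()
    ]
    paths.sort(key=lambda p: (-len(p.genes), p.label))
    return paths


def path_table(paths: list[CoexpressionPath]) -> pd.DataFrame:
    """Long-form (gene, path_label) table, genes sorted within path."""
    rows = [
        {"gene": gene, "path_label": path.label_str}
        for path in paths
        for gene in sorted(path.genes)
    ]
    return pd.DataFrame(rows, columns=["gene", "path_label"])


def extract_restoration_sets(
    paths: list[CoexpressionPath],
    design: ExperimentDesign,
    injury_condition: str,
    treated_condition: str,
) -> RestorationSets:
    """Project path labels onto the injury and treated positions.

    up_restored collects genes called up in the injured-untreated
    condition and unchanged in the injured-treated one; up_persistent
    those up in both; down variants symmetric. Calls at any other path
    position are ignored, so each set is a union of whole paths.
    """
    positions = {}
    for name, cond in (("injury", injury_condition), ("treated", treated_condition)):
        if cond not in design.path_conditions:
            raise DesignError(
                f"{name} condition {cond!r} is not one of the path "
                f"conditions {list(design.path_conditions)}"
            )
        positions[name] = design.path_conditions.index(cond)

    buckets: dict[str, set[str]] = {
        "up_restored": set(),
        "down_restored": set(),
        "up_persistent": set(),
        "down_persistent": set(),
    }
    for path in paths:
        at_injury = path.label[positions["injury"]]
        at_treated = path.label[positions["treated"]]
        if at_injury == "up":
            key = "up_restored" if at_treated == "unchanged" else None
            if at_treated == "up":
                key = "up_persistent"
        elif at_injury == "down":
            key = "down_restored" if at_treated == "unchanged" else None
            if at_treated == "down":
                key = "down_persistent"
        else:
            key = None
        if key is not None:
            buckets[key] |= path.genes
    return RestorationSets(
        up_restored=frozenset(buckets["up_restored"]),
        down_restored=frozenset(buckets["down_restored"]),
        up_persistent=frozenset(buckets["up_persistent"]),
        down_persistent=frozenset(buckets["down_persistent"]),
    )


def restoration_table(sets: RestorationSets) -> pd.DataFrame:
    """Long-form (gene, set_name) table in stable order."""
    rows = [
        {"gene": gene, "set_name": name}
        for name, genes in sets.as_dict().items()
        for gene in sorted(genes)
    ]
    return pd.DataFrame(rows, columns=["gene", "set_name"])
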