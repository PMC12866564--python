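"""Pangenome partition: soft core and source-combination set algebra.

Orthogroups are first split off into a soft core (present in at least a
fraction tau of isolates, default 0.95). Each remaining orthogroup is
assigned to the unique non-empty subset C of group labels (isolation
sources or genera) in which it occurs: present in at least one isolate
of every group in C and absent from every isolate outside C. A strict
within-group occupancy requirement (default 0.95 of each member group's
isolates) sends partially penetrant orthogroups to an ``unclassified``
pool instead — the reading under which a large fraction of accessory
orthogroups ends up unplaced, as observed in real panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io_formats import MetadataTable, OrthogroupMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionConfig:
    #: soft-core occupancy fraction tau (inclusive)
    core_occupancy: float = 0.95
    #: occupancy counted over isolates or over distinct group labels
    core_unit: str = "isolate"
    #: within-group occupancy a combination member must reach; 0 gives
    #: the plain any-presence rule
    strict_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.core_occupancy <= 1:
            raise ValueError("core occupancy must be in (0, 1]")
        if self.core_unit not in ("isolate", "group"):
            raise ValueError(f"unknown core unit {self.core_unit!r}")
        if not 0 <= self.strict_fraction <= 1:
            raise ValueError("strict fraction must be in [0, 1]")


@dataclass
class PartitionResult:
    core: set[str]
    combos: dict[frozenset[str], set[str]]
    unclassified: set[str]

    def category_of(self) -> dict[str, str]:
        """Flat orthogroup -> category-label map for serialization."""
        out = {og: "core" for og in self.core}
        for combo, ogs in self.combos.items():
            label = "+".join(sorted(combo))
            out.update({og: label for og in ogs})
        out.update({og: "unclassified" for og in self.unclassified})
        return out

    def check_disjoint_union(self, all_orthogroups: set[str]) -> None:
        parts = [self.core, self.unclassified, *self.combos.values()]
        total = sum(len(p) for p in parts)
        union = set().union(*parts) if parts else set()
        if total != len(union) or union != set(all_orthogroups):
            raise AssertionError("partition is not a disjoint cover of the orthogroups")


@dataclass
class SummaryStats:
    """Orthogroup-assignment arithmetic for a gene catalogue."""

    total_genes: int
    assigned_genes: int
    unassigned_genes: int
    n_orthogroups: int

    def __post_init__(self) -> None:
        if self.total_genes != self.assigned_genes + self.unassigned_genes:
            raise ValueError("total != assigned + unassigned")
        if self.n_orthogroups == 0 and self.assigned_genes > 0:
            raise ValueError("assigned genes without any orthogroup")

    @property
    def pct_assigned(self) -> float:
        return 100.0 * self.assigned_genes / self.total_genes if self.total_genes else 0.0

    @property
    def mean_og_size(self) -> float:
        return self.assigned_genes / self.n_orthogroups if self.n_orthogroups else 0.0

    def rounded(self) -> dict[str, float]:
        """Reporting view: percentages and means half-up to one decimal."""
        return {
            "total_genes": self.total_genes,
            "assigned_genes": self.assigned_genes,
            "unassigned_genes": self.unassigned_genes,
            "n_orthogroups": self.n_orthogroups,
            "pct_assigned": round_half_up(self.pct_assigned, 1),
            "mean_og_size": round_half_up(self.mean_og_size, 1),
        }


def round_half_up(value: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def presence_from_counts(matrix: OrthogroupMatrix) -> pd.DataFrame:
    """Binary presence (count > 0) with the same axes as the counts."""
    return (matrix.counts > 0).astype(int)


def soft_core(presence: pd.DataFrame, cfg: PartitionConfig | None = None,
              groups: pd.Series | None = None) -> set[str]:
    """Orthogroups whose occupancy fraction is >= tau (inclusive).

    With ``core_unit='group'``, occupancy is the fraction of distinct
    group labels containing at least one presence; ``groups`` maps
    isolate -> label and is then required.
    """
    cfg = cfg or PartitionConfig()
    if presence.shape[0] == 0:
        raise ValueError("need at least one isolate")
    if cfg.core_unit == "group":
        if groups is None:
            raise ValueError("core_unit='group' needs a group label per isolate")
        groups = groups.reindex(presence.index)
        per_group = (presence.groupby(groups).sum() > 0)
        occupancy = per_group.mean(axis=0)
    else:
        occupancy = presence.mean(axis=0)
    return set(occupancy.index[occupancy >= cfg.core_occupancy])


def partition_by_group(presence: pd.DataFrame, metadata: MetadataTable,
                       group_key: str = "source",
                       cfg: PartitionConfig | None = None) -> PartitionResult:
    """Partition orthogroups into {core} | {group combinations} | {unclassified}.

    The soft core (isolate-level unless configured otherwise) is removed
    first; remaining orthogroups are matched to the subset of groups
    they occur in, subject to the strict within-group occupancy rule.
    """
    cfg = cfg or PartitionConfig()
    if group_key not in ("source", "genus"):
        raise ValueError(f"unknown group key {group_key!r}")
    labels = metadata.table[group_key].reindex(presence.index)
    missing = presence.index[labels.isna()]
    if len(missing):
        logger.warning("dropping %d isolate(s) without metadata: %s",
                       len(missing), list(missing))
        presence = presence.drop(index=missing)
        labels = labels.drop(index=missing)
    counts_per_group = labels.value_counts()
    if (counts_per_group == 0).any() or presence.shape[0] == 0:
        raise ValueError("every group needs at least one isolate")

    core = soft_core(presence, cfg, groups=labels)
    remaining = [og for og in presence.columns if og not in core]

    # fraction of each group's isolates containing the orthogroup
    group_frac = presence[remaining].groupby(labels).mean()
    combos: dict[frozenset[str], set[str]] = {}
    unclassified: set[str] = set()
    for og in remaining:
        frac = group_frac[og]
        present_groups = frozenset(frac.index[frac > 0])
        if not present_groups:
            unclassified.add(og)
            continue
        if all(frac[g] >= cfg.strict_fraction for g in present_groups):
            combos.setdefault(present_groups, set()).add(og)
        else:
            unclassified.add(og)

    result = PartitionResult(core=core, combos=combos, unclassified=unclassified)
    result.check_disjoint_union(set(presence.columns))
    return result


def pangenome_summary(matrix: OrthogroupMatrix) -> SummaryStats:
    return SummaryStats(
        total_genes=matrix.total_genes,
        assigned_genes=matrix.assigned_genes,
        unassigned_genes=int(matrix.unassigned.sum()),
        n_orthogroups=len(matrix.orthogroup_ids),
    )


def combo_sizes(result: PartitionResult) -> pd.DataFrame:
    """Upset-style combination-size table, largest first."""
    rows = [{"combination": "core", "n_orthogroups": len(result.core)}]
    rows += [
        {"combination": "+".join(sorted(c)), "n_orthogroups": len(ogs)}
        for c, ogs in result.combos.items()
    ]
    rows.append({"combination": "unclassified",
                 "n_orthogroups": len(result.unclassified)})
    df = pd.DataFrame(rows)
    return df.sort_values("n_orthogroups", ascending=False, kind="stable",
                          ignore_index=True)
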