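"""Per-genus differential orthogroups and grouped metric comparisons.

Within one genus, per-isolate gene counts of every orthogroup are
compared between a target isolation source (typically leaf) and all
other sources with the Mann–Whitney U test, Benjamini–Hochberg
corrected across the tested orthogroups. Whole-genome metrics (genome
size, glycoside-hydrolase counts, ...) are compared across all source
groups pairwise with Bonferroni correction and summarized as a compact
letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .io_formats import MetadataTable, OrthogroupMatrix

logger = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    orthogroup_id: str
    genus: str
    mean_count_target: float
    mean_count_other: float
    direction: str | None  # enriched | depleted | None when means tie
    U: float
    p: float
    p_adj: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adj < alpha


def differential_orthogroups(matrix: OrthogroupMatrix, metadata: MetadataTable,
                             genus: str, target_source: str = "leaf",
                             alpha: float = 0.05, test_all: bool = False,
                             mwu_mode: str = "auto") -> list[DifferentialResult]:
    """Leaf-vs-other orthogroup count comparison within one genus.

    Orthogroups with no gene in the genus at all are skipped before the
    BH correction (``test_all`` keeps them). Needs at least two isolates
    on each side of the split.
    """
    meta = metadata.table
    in_genus = meta.index[(meta["genus"] == genus)]
    in_genus = [i for i in in_genus if i in matrix.counts.index]
    if not in_genus:
        raise ValueError(f"no isolates of genus {genus!r} in the matrix")
    sources = meta.loc[in_genus, "source"]
    target_ids = [i for i in in_genus if sources[i] == target_source]
    other_ids = [i for i in in_genus if sources[i] != target_source]
    if len(target_ids) < 2 or len(other_ids) < 2:
        raise ValueError(
            f"genus {genus!r} needs >=2 isolates per side; got "
            f"{len(target_ids)} {target_source} vs {len(other_ids)} other"
        )

    sub = matrix.counts.loc[in_genus]
    if test_all:
        tested = list(sub.columns)
    else:
        nonzero = sub.sum(axis=0) > 0
        skipped = int((~nonzero).sum())
        if skipped:
            logger.debug("genus %s: skipping %d all-zero orthogroup(s)",
                         genus, skipped)
        tested = list(sub.columns[nonzero])

    target_block = sub.loc[target_ids, tested].to_numpy()
    other_block = sub.loc[other_ids, tested].to_numpy()
    results: list[DifferentialResult] = []
    pvals: list[float] = []
    for k, og in enumerate(tested):
        res = stats.mann_whitney_u(target_block[:, k], other_block[:, k],
                                   mode=mwu_mode)
        m_t = float(target_block[:, k].mean())
        m_o = float(other_block[:, k].mean())
        if m_t > m_o:
            direction = "enriched"
        elif m_t < m_o:
            direction = "depleted"
        else:
            direction = None
        results.append(DifferentialResult(
            orthogroup_id=og, genus=genus,
            mean_count_target=m_t, mean_count_other=m_o,
            direction=direction, U=res.statistic, p=res.p_value, p_adj=np.nan,
        ))
        pvals.append(res.p_value)
    for res, p_adj in zip(results, stats.bh_adjust(pvals)):
        res.p_adj = float(p_adj)
    return results


def differential_table(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def compare_group_metric(values: pd.Series, groups: pd.Series,
                         alpha: float = 0.05, mwu_mode: str = "auto"
                         ) -> tuple[pd.DataFrame, dict[str, str]]:
    """All-pairwise Mann–Whitney comparisons of a per-isolate metric.

    Bonferroni correction over the number of pairs; group order follows
    first appearance in ``groups``. Singleton groups are excluded with a
    warning. Returns the pairwise table and a compact letter display in
    which two groups share a letter iff their adjusted p >= alpha.
    """
    groups = groups.reindex(values.index)
    ordered = list(dict.fromkeys(groups))
    sizes = groups.value_counts()
    usable = [g for g in ordered if sizes.get(g, 0) >= 2]
    dropped = [g for g in ordered if g not in usable]
    if dropped:
        logger.warning("excluding singleton group(s) %s", dropped)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >=2 members")

    rows = []
    for i, g1 in enumerate(usable):
        for g2 in usable[i + 1:]:
            res = stats.mann_whitney_u(values[groups == g1].to_numpy(),
                                       values[groups == g2].to_numpy(),
                                       mode=mwu_mode)
            rows.append({"group1": g1, "group2": g2,
                         "U": res.statistic, "p": res.p_value})
    table = pd.DataFrame(rows)
    table["p_adj"] = stats.bonferroni_adjust(table["p"].to_numpy())

    significant = {
        frozenset((r.group1, r.group2))
        for r in table.itertuples() if r.p_adj < alpha
    }
    letters = compact_letter_display(usable, significant)
    return table, letters


def compact_letter_display(groups: list[str],
                           significant_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are exactly those not significantly
    different; ties are broken by the given group order.
    """
    columns: list[set[str]] = [set(groups)]
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if frozenset((g1, g2)) not in significant_pairs:
                continue
            for col in [c for c in columns if g1 in c and g2 in c]:
                columns.remove(col)
                left, right = col - {g2}, col - {g1}
                for new in (left, right):
                    if not any(new <= other for other in columns):
                        columns.append(new)
                # absorb columns made redundant by the split
                columns = [c for c in columns
                           if not any(c < other for other in columns)]
    # letter order follows the first group appearing in each column
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                display[g] += letter
    return display
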