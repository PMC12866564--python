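"""COG functional-category enrichment of orthogroup sets against the core.

Expected category frequencies come from the genes of the soft-core
orthogroups; each target set (a source-unique or combination set from
the partition) is compared category by category with Fisher's exact
test, Benjamini–Hochberg correction across the categories of that set,
and a percent-deviation summary. Counting is at the gene level: a gene
carrying several COG letters contributes once to each letter; genes
with no COG annotation count only toward the set total.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from . import stats
from .stats import ContingencyTable2x2

logger = logging.getLogger(__name__)

#: the 23 single-letter functional categories of the COG scheme
COG_LETTERS = tuple("JAKLBDYVTMNZWUOCGEFHIPQ")
COG_LETTER_SET = frozenset(COG_LETTERS)


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.05
    #: |percent deviation from core frequency| needed to call a category
    #: over/under-represented
    deviation_threshold_pct: float = 50.0
    #: categories supported by fewer genes than this (target + core) are
    #: reported but flagged low-support
    min_gene_support: int = 200
    #: BH scope: across the categories of each target set, or across all
    adjust_scope: str = "per-set"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.deviation_threshold_pct <= 0:
            raise ValueError("deviation threshold must be positive")
        if self.adjust_scope not in ("per-set", "global"):
            raise ValueError(f"unknown adjust scope {self.adjust_scope!r}")


@dataclass
class EnrichmentRecord:
    set_label: str
    cog_category: str
    a: int  # target genes in category
    b: int  # target genes outside category
    c: int  # core genes in category
    d: int  # core genes outside category
    odds_ratio: float
    log_odds_ratio: float
    lor_haldane_corrected: bool
    p: float
    p_adj: float
    deviation_pct: float      # D = 100 * (p_obs / p_core - 1)
    representation_pct: float  # R = 100 * p_obs / p_core = D + 100
    n_genes: int
    classification: str  # over | under | ns | low-support


def category_gene_counts(og_set: set[str], ann: pd.DataFrame
                         ) -> tuple[Counter, int]:
    """Per-COG-letter gene counts and the total gene count of a set.

    A gene with k category letters adds 1 to each of the k letters; a
    gene with an empty COG set is counted in the total only.
    """
    subset = ann[ann["orthogroup_id"].isin(og_set)]
    counts: Counter = Counter()
    for letters in subset["cog"]:
        counts.update(letters)
    return counts, int(subset.shape[0])


def enrich_vs_core(target: set[str], core: set[str], ann: pd.DataFrame,
                   cfg: EnrichmentConfig | None = None,
                   set_label: str = "target") -> list[EnrichmentRecord]:
    """Observed-vs-expected COG representation of ``target`` against ``core``.

    Returns one record per COG letter observed in either set, with
    Fisher p, BH-adjusted p (across this set's categories by default),
    deviation and representation percentages, and the over/under/ns/
    low-support classification.
    """
    cfg = cfg or EnrichmentConfig()
    overlap = target & core
    if overlap:
        logger.warning("target and core share %d orthogroup(s); the comparison "
                       "assumes disjoint sets", len(overlap))
    target_counts, target_total = category_gene_counts(target, ann)
    core_counts, core_total = category_gene_counts(core, ann)
    if core_total == 0:
        raise ValueError("core has no annotated genes")
    if target_total == 0:
        return []

    letters = sorted(set(target_counts) | set(core_counts))
    records: list[EnrichmentRecord] = []
    pvals: list[float] = []
    for letter in letters:
        a = target_counts.get(letter, 0)
        c = core_counts.get(letter, 0)
        table = ContingencyTable2x2(a, target_total - a, c, core_total - c)
        odds_ratio, p = stats.fisher_exact(table)
        lor, corrected = stats.log_odds_ratio(table)
        p_obs = a / target_total
        p_core = c / core_total
        if p_core > 0:
            representation = 100.0 * p_obs / p_core
            deviation = representation - 100.0
        else:
            representation = math.inf if p_obs > 0 else math.nan
            deviation = math.inf if p_obs > 0 else math.nan
        records.append(EnrichmentRecord(
            set_label=set_label, cog_category=letter,
            a=a, b=target_total - a, c=c, d=core_total - c,
            odds_ratio=odds_ratio, log_odds_ratio=lor,
            lor_haldane_corrected=corrected,
            p=p, p_adj=math.nan,
            deviation_pct=deviation, representation_pct=representation,
            n_genes=a, classification="ns",
        ))
        pvals.append(p)

    adjusted = stats.bh_adjust(pvals)
    for rec, p_adj in zip(records, adjusted):
        rec.p_adj = float(p_adj)
        rec.classification = _classify(rec, cfg)
    return records


def _classify(rec: EnrichmentRecord, cfg: EnrichmentConfig) -> str:
    if rec.a + rec.c < cfg.min_gene_support:
        return "low-support"
    if rec.p_adj < cfg.alpha and rec.deviation_pct > cfg.deviation_threshold_pct:
        return "over"
    if rec.p_adj < cfg.alpha and rec.deviation_pct < -cfg.deviation_threshold_pct:
        return "under"
    return "ns"


def enrich_partition(partition_categories: dict[str, set[str]], core: set[str],
                     ann: pd.DataFrame, cfg: EnrichmentConfig | None = None
                     ) -> pd.DataFrame:
    """Run :func:`enrich_vs_core` for every partition category and
    return one tidy table. With ``adjust_scope='global'`` the BH
    correction is re-applied across all (set, category) pairs."""
    cfg = cfg or EnrichmentConfig()
    records: list[EnrichmentRecord] = []
    for label, og_set in partition_categories.items():
        records.extend(enrich_vs_core(og_set, core, ann, cfg, set_label=label))
    if cfg.adjust_scope == "global" and records:
        adjusted = stats.bh_adjust([r.p for r in records])
        for rec, p_adj in zip(records, adjusted):
            rec.p_adj = float(p_adj)
            rec.classification = _classify(rec, cfg)
    return pd.DataFrame([vars(r) for r in records])
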