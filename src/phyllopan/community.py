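"""Amplicon-side decision rules for the leaf community.

Relative abundance per sample, the both-years low-abundance exclusion
rule, prevalence-based core-mycobiome membership, and culture-collection
recovery estimates against the amplicon-detected genus set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import AbundanceTable


@dataclass(frozen=True)
class CommunityConfig:
    #: taxa below this mean relative abundance (percent) in *every* year
    #: are excluded
    abundance_threshold_pct: float = 0.1
    #: fraction of a year's samples a taxon must appear in to be core
    prevalence_threshold: float = 0.80
    #: "mean" averages per-sample relative abundances within a year;
    #: "pooled" sums raw counts first
    abundance_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.abundance_threshold_pct <= 0 and self.abundance_threshold_pct != 0:
            raise ValueError("abundance threshold must be positive (or 0 to disable)")
        if not 0 < self.prevalence_threshold <= 1:
            raise ValueError("prevalence threshold must be in (0, 1]")
        if self.abundance_mode not in ("mean", "pooled"):
            raise ValueError(f"unknown abundance mode {self.abundance_mode!r}")


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample relative abundance in percent; each row sums to 100."""
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero)}")
    return table.counts.div(totals, axis=0) * 100.0


def _yearly_mean_ra(ra: pd.DataFrame, years: pd.Series,
                    cfg: CommunityConfig) -> pd.DataFrame:
    """Per-(year, taxon) abundance summary on the percent scale."""
    years = years.reindex(ra.index)
    if years.isna().any():
        raise ValueError("every sample needs a year label")
    if cfg.abundance_mode == "mean":
        return ra.groupby(years).mean()
    pooled = ra.groupby(years).sum()
    return pooled.div(pooled.sum(axis=1), axis=0) * 100.0


def filter_low_abundance(ra: pd.DataFrame, years: pd.Series,
                         cfg: CommunityConfig | None = None) -> set[str]:
    """Taxa retained unless below the abundance threshold in every year.

    A taxon survives iff its mean relative abundance reaches
    ``abundance_threshold_pct`` (inclusive) in at least one year.
    """
    cfg = cfg or CommunityConfig()
    if ra.shape[0] == 0:
        raise ValueError("no samples")
    yearly = _yearly_mean_ra(ra, years, cfg)
    keep = (yearly >= cfg.abundance_threshold_pct).any(axis=0)
    return set(yearly.columns[keep])


def core_taxa(table: AbundanceTable, cfg: CommunityConfig | None = None
              ) -> dict[int, set[str]]:
    """Per-year core taxon sets by prevalence.

    A taxon is core for a year iff it is present (count > 0) in at least
    ``prevalence_threshold`` of that year's samples (inclusive).
    """
    cfg = cfg or CommunityConfig()
    presence = table.counts > 0
    cores: dict[int, set[str]] = {}
    for year, block in presence.groupby(table.sample_year):
        if block.shape[0] == 0:
            raise ValueError(f"year {year} has no samples")
        prevalence = block.mean(axis=0)
        cores[year] = set(prevalence.index[prevalence >= cfg.prevalence_threshold])
    return cores


def detected_taxa_by_year(table: AbundanceTable,
                          cfg: CommunityConfig | None = None) -> dict[int, set[str]]:
    """Amplicon-detected taxa per year after the abundance filter."""
    cfg = cfg or CommunityConfig()
    ra = relative_abundance(table)
    yearly = _yearly_mean_ra(ra, table.sample_year, cfg)
    return {
        int(year): set(yearly.columns[yearly.loc[year] >= cfg.abundance_threshold_pct])
        for year in yearly.index
    }


def recovery_estimate(cultured_genera: set[str], detected: set[str]) -> float:
    """Percent of amplicon-detected genera recovered in culture:
    100 * |cultured & detected| / |detected|."""
    if not detected:
        raise ValueError("empty detected genus set")
    return 100.0 * len(set(cultured_genera) & detected) / len(detected)


def recovery_by_year(cultured_genera: set[str], table: AbundanceTable,
                     cfg: CommunityConfig | None = None) -> dict[int, float]:
    """Recovery estimate per year, denominators filtered at the
    abundance threshold for that year."""
    detected = detected_taxa_by_year(table, cfg)
    return {year: recovery_estimate(cultured_genera, taxa)
            for year, taxa in detected.items()}
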