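"""Seeded synthetic studies emulating a multi-genus yeast genome panel.

The generator produces the same input dialects the readers consume — an
orthogroup gene-count matrix, eggNOG-style gene annotations, isolate
metadata, pathway definitions and an ASV table — together with a ground
truth of everything planted, so recovery experiments can score
sensitivity and false-discovery rates.

Statistical structure mirrors the design of real phyllosphere panels:

* a shared soft core present in (nearly) every isolate;
* genus-specific orthogroup backbones, making taxonomy the dominant
  axis of variation (the reason cross-genus classifiers overfit);
* source-unique orthogroups confined to one isolation source;
* planted source-enriched orthogroups whose gene counts are shifted by
  an additive Poisson effect in the target source;
* per-gene COG letters with a planted category bias in the target
  source's unique orthogroups;
* KO grants making one designated pathway complete only in the target
  source.

Counts are Poisson with optional dropout; every non-core orthogroup's
occupancy is capped strictly below the core threshold by construction,
so with dropout zero the soft core is recovered exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    UNASSIGNED,
    AbundanceTable,
    MetadataTable,
    OrthogroupMatrix,
    write_abundance_table,
    write_annotations,
    write_genecount_table,
    write_metadata,
)

_COG_LETTERS = tuple("JAKLBDYVTMNZWUOCGEFHIPQ")

#: per-genus isolate counts per source for the default panel (~60
#: isolates over 4 genera and 5 sources, leaf most represented —
#: proportions follow a typical leaf-focused genome panel)
DEFAULT_GENERA: tuple[tuple[str, dict[str, int]], ...] = (
    ("Aureobasidium", {"leaf": 5, "flower": 3, "soil": 3, "human": 2, "water": 2}),
    ("Candida", {"leaf": 5, "flower": 3, "soil": 3, "human": 2, "water": 2}),
    ("Metschnikowia", {"leaf": 5, "flower": 3, "soil": 3, "human": 2, "water": 2}),
    ("Rhodotorula", {"leaf": 5, "flower": 3, "soil": 3, "human": 2, "water": 2}),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genera: tuple[tuple[str, dict[str, int]], ...] = DEFAULT_GENERA
    target_source: str = "leaf"
    n_core_ogs: int = 1200
    n_genus_ogs: int = 800
    n_shared_accessory: int = 400
    n_planted_source_ogs: int = 50
    n_source_unique_ogs: int = 60
    #: additive count shift in target-source isolates of planted OGs
    planted_effect: float = 5.0
    #: baseline Poisson mean for gene counts of present orthogroups
    baseline_count_mean: float = 2.0
    #: probability a present (isolate, orthogroup) cell is zeroed
    dropout: float = 0.0
    core_occupancy: float = 0.95
    #: fraction of genes receiving a COG annotation
    annotation_rate: float = 0.8
    #: probability an annotated gene carries a second COG letter
    multi_letter_rate: float = 0.15
    #: (COG letter, fold enrichment) planted in the target source's
    #: unique orthogroups
    planted_cog_bias: tuple[tuple[str, float], ...] = (("Q", 3.0),)
    n_pathways: int = 8
    #: mean unassigned genes per isolate
    unassigned_mean: float = 50.0

    def __post_init__(self) -> None:
        n_background = self.total_orthogroups() - self.n_planted_source_ogs
        if self.n_planted_source_ogs > 0 and self.n_planted_source_ogs > n_background:
            raise ValueError(
                "more planted orthogroups than background orthogroups; a "
                "recovery experiment needs null orthogroups"
            )
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.baseline_count_mean <= 0 or self.planted_effect < 0:
            raise ValueError("count parameters must be positive")
        sources = self.source_labels()
        if self.target_source not in sources:
            raise ValueError(
                f"target source {self.target_source!r} absent from the panel"
            )

    def source_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, per_source in self.genera:
            for s in per_source:
                seen.setdefault(s)
        return list(seen)

    def total_orthogroups(self) -> int:
        return (self.n_core_ogs
                + self.n_genus_ogs * len(self.genera)
                + self.n_shared_accessory
                + self.n_planted_source_ogs
                + self.n_source_unique_ogs * len(self.source_labels()))


@dataclass
class GroundTruth:
    core_ogs: set[str]
    genus_backbones: dict[str, set[str]]
    shared_accessory: set[str]
    planted_source_ogs: set[str]
    source_unique: dict[str, set[str]]
    planted_cog_categories: set[str]
    planted_pathway_id: str | None = None

    def to_json(self) -> str:
        payload = {
            "core_ogs": sorted(self.core_ogs),
            "genus_backbones": {g: sorted(v) for g, v in self.genus_backbones.items()},
            "shared_accessory": sorted(self.shared_accessory),
            "planted_source_ogs": sorted(self.planted_source_ogs),
            "source_unique": {s: sorted(v) for s, v in self.source_unique.items()},
            "planted_cog_categories": sorted(self.planted_cog_categories),
            "planted_pathway_id": self.planted_pathway_id,
        }
        return json.dumps(payload, indent=2)


@dataclass
class SimulatedStudy:
    matrix: OrthogroupMatrix
    metadata: MetadataTable
    annotations: pd.DataFrame
    pathway_table: pd.DataFrame
    ground_truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = f"phyllopan simulate seed={self.config.seed}"
        write_genecount_table(self.matrix, outdir / "Orthogroups.GeneCount.tsv",
                              provenance=stamp)
        write_annotations(self.annotations, outdir / "genes.emapper.annotations",
                          provenance=stamp)
        write_metadata(self.metadata, outdir / "metadata.tsv", provenance=stamp)
        self.pathway_table.to_csv(outdir / "pathways.tsv", sep="\t", index=False)
        unassigned = self.matrix.unassigned.rename("unassigned")
        unassigned.index.name = "isolate_id"
        unassigned.to_csv(outdir / "unassigned.tsv", sep="\t")
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())


def _positive_counts(rng: np.random.Generator, shape, mean: float) -> np.ndarray:
    """Counts of present cells: at least one gene, Poisson-shaped tail."""
    return 1 + rng.poisson(max(mean - 1.0, 0.0), size=shape)


def _cap_occupancy(rng: np.random.Generator, block: np.ndarray, tau: float,
                   protect: np.ndarray | None = None) -> None:
    """Zero random rows of any column whose occupancy reaches tau, so no
    accessory orthogroup drifts into the soft core (in place).

    Rows flagged in ``protect`` (the target-source isolates of planted
    orthogroups) are zeroed only when no other row is available, so the
    planted count shift survives the cap.
    """
    n = block.shape[0]
    max_present = int(np.ceil(tau * n)) - 1
    for j in np.where((block > 0).sum(axis=0) > max_present)[0]:
        present = np.where(block[:, j] > 0)[0]
        n_drop = len(present) - max_present
        if protect is not None:
            unprotected = present[~protect[present]]
            if len(unprotected) >= n_drop:
                present = unprotected
        drop = rng.choice(present, size=n_drop, replace=False)
        block[drop, j] = 0


def simulate_study(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full synthetic study; deterministic per seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- isolates & metadata -------------------------------------------------
    rows = []
    for genus, per_source in cfg.genera:
        k = 0
        for source, n in per_source.items():
            for _ in range(n):
                k += 1
                rows.append({
                    "isolate_id": f"{genus[:3].upper()}{k:02d}",
                    "genus": genus, "species": f"{genus} sp.",
                    "source": source, "year": "2020", "cluster": "-",
                })
    meta_df = pd.DataFrame(rows).set_index("isolate_id")
    metadata = MetadataTable(meta_df)
    isolates = list(meta_df.index)
    n_iso = len(isolates)
    genus_arr = meta_df["genus"].to_numpy()
    source_arr = meta_df["source"].to_numpy()
    target_mask = source_arr == cfg.target_source
    mu = cfg.baseline_count_mean

    # --- orthogroup blocks ---------------------------------------------------
    og_ids: list[str] = []
    blocks: list[np.ndarray] = []
    truth = GroundTruth(core_ogs=set(), genus_backbones={}, shared_accessory=set(),
                        planted_source_ogs=set(), source_unique={},
                        planted_cog_categories={c for c, _ in cfg.planted_cog_bias})

    def add_block(prefix: str, counts: np.ndarray) -> list[str]:
        ids = [f"{prefix}{i:05d}" for i in range(len(og_ids),
                                                 len(og_ids) + counts.shape[1])]
        og_ids.extend(ids)
        blocks.append(counts)
        return ids

    # core: present everywhere before dropout
    core_block = _positive_counts(rng, (n_iso, cfg.n_core_ogs), mu)
    if cfg.dropout > 0:
        core_block[rng.random(core_block.shape) < cfg.dropout] = 0
    truth.core_ogs = set(add_block("OGCORE", core_block))

    # genus backbones: confined to one genus
    for genus, _ in cfg.genera:
        block = np.zeros((n_iso, cfg.n_genus_ogs), dtype=int)
        members = genus_arr == genus
        present = rng.random((int(members.sum()), cfg.n_genus_ogs)) < 0.9
        block[members] = present * _positive_counts(
            rng, (int(members.sum()), cfg.n_genus_ogs), mu)
        _cap_occupancy(rng, block, cfg.core_occupancy)
        truth.genus_backbones[genus] = set(add_block(f"OG{genus[:3].upper()}", block))

    # shared accessory: random >=2-genus subsets
    genera_names = [g for g, _ in cfg.genera]
    if cfg.n_shared_accessory and len(genera_names) >= 2:
        block = np.zeros((n_iso, cfg.n_shared_accessory), dtype=int)
        for j in range(cfg.n_shared_accessory):
            size = int(rng.integers(2, len(genera_names) + 1))
            chosen = rng.choice(genera_names, size=size, replace=False)
            members = np.isin(genus_arr, chosen)
            present = rng.random(int(members.sum())) < 0.7
            block[members, j] = present * _positive_counts(
                rng, int(members.sum()), mu)
        _cap_occupancy(rng, block, cfg.core_occupancy)
        truth.shared_accessory = set(add_block("OGACC", block))

    # planted source-enriched: additive count shift +lambda in the
    # target source on top of the Poisson(mu) baseline (mean mu+lambda)
    if cfg.n_planted_source_ogs:
        block = rng.poisson(mu, size=(n_iso, cfg.n_planted_source_ogs))
        block[target_mask] += int(round(cfg.planted_effect))
        _cap_occupancy(rng, block, cfg.core_occupancy, protect=target_mask)
        truth.planted_source_ogs = set(add_block("OGPLNT", block))

    # source-unique orthogroups
    for source in cfg.source_labels():
        block = np.zeros((n_iso, cfg.n_source_unique_ogs), dtype=int)
        members = source_arr == source
        present = rng.random((int(members.sum()), cfg.n_source_unique_ogs)) < 0.9
        block[members] = present * _positive_counts(
            rng, (int(members.sum()), cfg.n_source_unique_ogs), mu)
        _cap_occupancy(rng, block, cfg.core_occupancy)
        truth.source_unique[source] = set(
            add_block(f"OGU{source[:3].upper()}", block))

    counts = np.hstack(blocks) if blocks else np.zeros((n_iso, 0), dtype=int)
    if cfg.dropout > 0:
        # dropout for non-core blocks (core handled above)
        noncore = np.zeros(counts.shape[1], dtype=bool)
        noncore[cfg.n_core_ogs:] = True
        mask = rng.random(counts.shape) < cfg.dropout
        counts[:, noncore] *= ~mask[:, noncore]

    unassigned = pd.Series(rng.poisson(cfg.unassigned_mean, size=n_iso),
                           index=isolates, dtype=int)
    matrix = OrthogroupMatrix(
        counts=pd.DataFrame(counts, index=isolates, columns=og_ids),
        unassigned=unassigned,
    )

    # --- pathways & per-isolate KO grants ------------------------------------
    pathway_table, pathway_kos = _make_pathways(rng, cfg)
    planted_pw = pathway_table["pathway_id"].iloc[0] if len(pathway_table) else None
    truth.planted_pathway_id = planted_pw
    isolate_kos: list[set[str]] = [set() for _ in range(n_iso)]
    for p_idx, (pw_id, kos) in enumerate(pathway_kos.items()):
        kos = sorted(kos)
        for i in range(n_iso):
            if pw_id == planted_pw:
                if target_mask[i]:
                    granted = set(kos)
                else:
                    # strictly partial: never all of the planted pathway
                    n_grant = int(rng.integers(0, max(len(kos) - 1, 1)))
                    granted = set(rng.choice(kos, size=n_grant, replace=False))
            else:
                granted = {k for k in kos if rng.random() < 0.7}
            isolate_kos[i] |= granted

    # --- gene-level annotations ----------------------------------------------
    annotations = _make_annotations(rng, cfg, matrix, truth, isolate_kos)

    return SimulatedStudy(matrix=matrix, metadata=metadata,
                          annotations=annotations,
                          pathway_table=pathway_table,
                          ground_truth=truth, config=cfg)


def _make_pathways(rng: np.random.Generator, cfg: SimulationConfig
                   ) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Random pathway definitions over a disjoint KO pool.

    Each pathway is 3-6 required steps; a step is a single KO, an OR of
    two alternatives, or a two-subunit complex. The first pathway is the
    planted one (complete only in the target source).
    """
    rows = []
    kos_per_pathway: dict[str, set[str]] = {}
    next_ko = 1
    for p in range(cfg.n_pathways):
        pw_id = f"pw{p + 1:03d}"
        steps = []
        used: set[str] = set()
        for _ in range(int(rng.integers(3, 7))):
            kind = rng.random()
            if kind < 0.5:
                ko = f"K{next_ko:05d}"; next_ko += 1
                steps.append(ko); used.add(ko)
            elif kind < 0.8:
                k1, k2 = f"K{next_ko:05d}", f"K{next_ko + 1:05d}"; next_ko += 2
                steps.append(f"{k1},{k2}"); used |= {k1, k2}
            else:
                k1, k2 = f"K{next_ko:05d}", f"K{next_ko + 1:05d}"; next_ko += 2
                steps.append(f"{k1}+{k2}"); used |= {k1, k2}
        rows.append({"pathway_id": pw_id, "name": f"synthetic pathway {p + 1}",
                     "definition": " ".join(steps)})
        kos_per_pathway[pw_id] = used
    return pd.DataFrame(rows), kos_per_pathway


def _make_annotations(rng: np.random.Generator, cfg: SimulationConfig,
                      matrix: OrthogroupMatrix, truth: GroundTruth,
                      isolate_kos: list[set[str]]) -> pd.DataFrame:
    letters = np.array(_COG_LETTERS)
    baseline = np.full(len(letters), 1.0 / len(letters))
    biased = baseline.copy()
    for letter, fold in cfg.planted_cog_bias:
        biased[letters == letter] *= fold
    biased /= biased.sum()

    counts = matrix.counts.to_numpy()
    isolates = np.array(matrix.isolate_ids)
    ogs = np.array(matrix.orthogroup_ids)
    iso_idx, og_idx = np.nonzero(counts)
    reps = counts[iso_idx, og_idx]
    gene_iso = np.repeat(iso_idx, reps)
    gene_og = np.repeat(og_idx, reps)

    # unassigned genes appended per isolate
    ua = matrix.unassigned.to_numpy()
    gene_iso = np.concatenate([gene_iso, np.repeat(np.arange(len(isolates)), ua)])
    gene_og = np.concatenate([gene_og, np.full(int(ua.sum()), -1)])

    order = np.argsort(gene_iso, kind="stable")
    gene_iso, gene_og = gene_iso[order], gene_og[order]
    n_genes = len(gene_iso)

    # stable per-isolate gene numbering
    gene_ids = np.empty(n_genes, dtype=object)
    start = 0
    for i in range(len(isolates)):
        end = start + int((gene_iso == i).sum())
        gene_ids[start:end] = [f"{isolates[i]}_g{j:06d}" for j in range(end - start)]
        start = end

    biased_og_mask = np.isin(
        ogs, sorted(truth.source_unique.get(cfg.target_source, set())))
    gene_biased = np.zeros(n_genes, dtype=bool)
    assigned = gene_og >= 0
    gene_biased[assigned] = biased_og_mask[gene_og[assigned]]

    annotated = rng.random(n_genes) < cfg.annotation_rate
    primary = rng.choice(letters, size=n_genes, p=baseline)
    n_biased = int(gene_biased.sum())
    if n_biased:
        primary[gene_biased] = rng.choice(letters, size=n_biased, p=biased)
    second = rng.choice(letters, size=n_genes, p=baseline)
    has_second = rng.random(n_genes) < cfg.multi_letter_rate

    cogs = [
        frozenset((primary[g], second[g])) if has_second[g] else frozenset((primary[g],))
        for g in range(n_genes)
    ]
    cogs = [c if annotated[g] else frozenset() for g, c in enumerate(cogs)]

    # spread each isolate's KO grants over its genes
    kos_col: list[frozenset] = [frozenset()] * n_genes
    start = 0
    for i in range(len(isolates)):
        end = start + int((gene_iso == i).sum())
        grants = sorted(isolate_kos[i])
        if grants and end > start:
            targets = rng.integers(start, end, size=len(grants))
            per_gene: dict[int, set[str]] = {}
            for t, ko in zip(targets, grants):
                per_gene.setdefault(int(t), set()).add(ko)
            for t, s in per_gene.items():
                kos_col[t] = frozenset(s)
        start = end

    og_col = np.where(assigned, ogs[np.clip(gene_og, 0, None)], UNASSIGNED)
    return pd.DataFrame({
        "gene_id": gene_ids,
        "isolate_id": isolates[gene_iso],
        "orthogroup_id": og_col,
        "cog": cogs,
        "kos": kos_col,
    })


# --------------------------------------------------------------------------
# ASV community table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AsvConfig:
    seed: int = 0
    years: tuple[int, ...] = (2020, 2021)
    n_samples_per_year: int = 12
    n_taxa: int = 40
    n_core_taxa: int = 6
    n_low_abundance: int = 8
    core_prevalence: float = 0.8


@dataclass
class SimulatedCommunity:
    table: AbundanceTable
    core_taxa: dict[int, set[str]]
    low_abundance_taxa: set[str]

    def write(self, counts_path: str | Path, years_path: str | Path) -> None:
        write_abundance_table(self.table, counts_path, years_path)


def simulate_asv_table(cfg: AsvConfig | None = None) -> SimulatedCommunity:
    """ASV/genus table with designated core and low-abundance taxa.

    Core taxa are present in every sample (prevalence 1 >= threshold);
    non-core taxa are held strictly below the prevalence threshold per
    year; low-abundance taxa keep mean relative abundance well under
    0.1% in both years.
    """
    cfg = cfg or AsvConfig()
    rng = np.random.default_rng(cfg.seed)
    taxa = [f"Genus{t:03d}" for t in range(cfg.n_taxa)]
    core = set(taxa[:cfg.n_core_taxa])
    low = set(taxa[cfg.n_core_taxa:cfg.n_core_taxa + cfg.n_low_abundance])
    mid = [t for t in taxa if t not in core and t not in low]

    samples, years_list = [], []
    for year in cfg.years:
        for s in range(cfg.n_samples_per_year):
            samples.append(f"y{year}_s{s:02d}")
            years_list.append(year)
    n = cfg.n_samples_per_year
    # strictly-below-threshold presence cap for non-core taxa
    max_present = int(np.ceil(cfg.core_prevalence * n)) - 1

    counts = pd.DataFrame(0, index=samples, columns=taxa, dtype=int)
    for year in cfg.years:
        year_samples = [s for s, y in zip(samples, years_list) if y == year]
        for t in core:
            counts.loc[year_samples, t] = 200 + rng.poisson(300, size=n)
        for t in mid:
            k = int(rng.integers(1, max_present + 1))
            chosen = rng.choice(year_samples, size=k, replace=False)
            counts.loc[chosen, t] = 50 + rng.poisson(100, size=k)
        for t in low:
            k = int(rng.integers(0, min(3, max_present) + 1))
            if k:
                chosen = rng.choice(year_samples, size=k, replace=False)
                counts.loc[chosen, t] = 1
    table = AbundanceTable(counts=counts,
                           sample_year=pd.Series(years_list, index=samples))
    return SimulatedCommunity(
        table=table,
        core_taxa={year: set(core) for year in cfg.years},
        low_abundance_taxa=low,
    )


# --------------------------------------------------------------------------
# Classifier fixtures
# --------------------------------------------------------------------------

def make_separable_panel(seed: int = 0, n_genera: int = 4,
                         n_per_genus: int = 16, n_signal_ogs: int = 10,
                         n_noise_ogs: int = 150
                         ) -> tuple[OrthogroupMatrix, MetadataTable]:
    """Panel with a block of orthogroups present iff leaf, identically
    across genera — every classifier and every LOGO fold can separate
    it. The signal block is wide enough that feature-subsampling
    ensembles see it in every tree."""
    rng = np.random.default_rng(seed)
    rows, leaf_flags = [], []
    for g in range(n_genera):
        genus = f"Genus{g}"
        for k in range(n_per_genus):
            source = "leaf" if k < n_per_genus // 2 else "soil"
            rows.append({"isolate_id": f"G{g}I{k:02d}", "genus": genus,
                         "species": "-", "source": source, "year": "-",
                         "cluster": "-"})
            leaf_flags.append(source == "leaf")
    meta = MetadataTable(pd.DataFrame(rows).set_index("isolate_id"))
    n = len(rows)
    counts = rng.poisson(2.0, size=(n, n_noise_ogs))
    signal = np.repeat(np.where(leaf_flags, 5, 0)[:, None], n_signal_ogs, axis=1)
    counts = np.hstack([signal, counts])
    og_ids = [f"OGSIG{i:03d}" for i in range(n_signal_ogs)] + [
        f"OGN{i:05d}" for i in range(n_noise_ogs)]
    matrix = OrthogroupMatrix(pd.DataFrame(counts, index=meta.isolate_ids,
                                           columns=og_ids))
    return matrix, meta


def make_confounded_panel(seed: int = 0, n_genera: int = 4,
                          n_per_genus: int = 16, n_noise_ogs: int = 300,
                          confounded_genus: str = "Genus0",
                          leaf_fraction_confounded: float = 0.875
                          ) -> tuple[OrthogroupMatrix, MetadataTable]:
    """Panel whose only informative orthogroups track one genus that is
    mostly leaf-derived: a classifier learns the genus backbone as a
    proxy for the habitat and fails on the held-out genus."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genera):
        genus = f"Genus{g}"
        leaf_frac = leaf_fraction_confounded if genus == confounded_genus else 0.25
        n_leaf = int(round(leaf_frac * n_per_genus))
        for k in range(n_per_genus):
            source = "leaf" if k < n_leaf else "soil"
            rows.append({"isolate_id": f"G{g}I{k:02d}", "genus": genus,
                         "species": "-", "source": source, "year": "-",
                         "cluster": "-"})
    meta = MetadataTable(pd.DataFrame(rows).set_index("isolate_id"))
    genus_arr = meta.table["genus"].to_numpy()
    n = len(rows)
    counts = rng.poisson(2.0, size=(n, n_noise_ogs))
    # genus backbone of the confounded genus doubles as the only signal
    backbone = np.where(genus_arr == confounded_genus, 6, 0)[:, None]
    backbone = np.repeat(backbone, 10, axis=1) + rng.poisson(0.2, size=(n, 10))
    counts = np.hstack([backbone, counts])
    og_ids = [f"OGBB{i:03d}" for i in range(10)] + [
        f"OGN{i:05d}" for i in range(n_noise_ogs)]
    matrix = OrthogroupMatrix(pd.DataFrame(counts, index=meta.isolate_ids,
                                           columns=og_ids))
    return matrix, meta
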