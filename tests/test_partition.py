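"""Soft core, combination partition and summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from _oracles import partition_oracle
from phyllopan import partition as part
from phyllopan.io_formats import MetadataTable, OrthogroupMatrix
from phyllopan.partition import PartitionConfig, SummaryStats


def matrix_from(array, isolates=None, ogs=None):
    array = np.asarray(array)
    isolates = isolates or [f"i{k}" for k in range(array.shape[0])]
    ogs = ogs or [f"OG{k}" for k in range(array.shape[1])]
    return OrthogroupMatrix(pd.DataFrame(array, index=isolates, columns=ogs))


def meta_from(genus_source_pairs):
    rows = [{"isolate_id": f"i{k}", "genus": g, "species": "-", "source": s,
             "year": "-", "cluster": "-"}
            for k, (g, s) in enumerate(genus_source_pairs)]
    return MetadataTable(pd.DataFrame(rows).set_index("isolate_id"))


class TestPresence:
    def test_binarization_and_idempotence(self, tiny_matrix):
        presence = part.presence_from_counts(tiny_matrix)
        assert presence.loc["A", "OG1"] == 1
        assert presence.loc["A", "OG2"] == 0
        again = part.presence_from_counts(OrthogroupMatrix(presence))
        pd.testing.assert_frame_equal(again, presence)

    def test_column_sums_are_occupancy_counts(self, tiny_matrix):
        presence = part.presence_from_counts(tiny_matrix)
        assert list(presence.sum(axis=0)) == [2, 2, 2]


class TestSoftCore:
    def test_inclusive_122_of_128_boundary(self):
        counts = np.zeros((128, 2), dtype=int)
        counts[:122, 0] = 1  # 122/128 = 0.953 -> core
        counts[:121, 1] = 1  # 121/128 = 0.945 -> not core
        presence = part.presence_from_counts(matrix_from(counts))
        core = part.soft_core(presence, PartitionConfig(core_occupancy=0.95))
        assert core == {"OG0"}

    def test_ubiquitous_orthogroup_core_at_any_tau(self):
        presence = part.presence_from_counts(matrix_from(np.ones((5, 1), int)))
        for tau in (0.5, 0.95, 1.0):
            assert part.soft_core(presence, PartitionConfig(core_occupancy=tau)) \
                == {"OG0"}

    def test_tau_one_is_strict_core(self):
        counts = np.array([[1, 1], [1, 0], [1, 1]])
        presence = part.presence_from_counts(matrix_from(counts))
        assert part.soft_core(presence, PartitionConfig(core_occupancy=1.0)) \
            == {"OG0"}

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(0)
        presence = part.presence_from_counts(
            matrix_from(rng.integers(0, 2, size=(30, 40))))
        previous = None
        for tau in (0.3, 0.5, 0.8, 0.95, 1.0):
            core = part.soft_core(presence, PartitionConfig(core_occupancy=tau))
            if previous is not None:
                assert core <= previous
            previous = core

    def test_group_unit_counts_distinct_labels(self):
        # present in 1 of 2 isolates of each of 3 genera: isolate
        # occupancy 0.5 but group occupancy 1.0
        counts = np.array([[1], [0], [1], [0], [1], [0]])
        presence = part.presence_from_counts(matrix_from(counts))
        groups = pd.Series(["a", "a", "b", "b", "c", "c"],
                           index=presence.index)
        cfg = PartitionConfig(core_occupancy=0.95, core_unit="group")
        assert part.soft_core(presence, cfg, groups=groups) == {"OG0"}
        cfg_iso = PartitionConfig(core_occupancy=0.95)
        assert part.soft_core(presence, cfg_iso) == set()


class TestPartitionByGroup:
    def three_group_meta(self):
        return meta_from([("g", "A")] * 2 + [("g", "B")] * 2 + [("g", "C")] * 2)

    def test_unique_and_shared_combos(self):
        # OG0 only in i0 (group A); OG1 in i0 and i2 (groups A and B)
        counts = np.zeros((6, 2), dtype=int)
        counts[0, 0] = 1
        counts[0, 1] = 1
        counts[2, 1] = 1
        meta = meta_from([("g", s) for s in ["A", "A", "B", "B", "C", "C"]])
        presence = part.presence_from_counts(matrix_from(counts))
        cfg = PartitionConfig(strict_fraction=0.0)
        result = part.partition_by_group(presence, meta, "source", cfg)
        assert result.combos[frozenset({"A"})] == {"OG0"}
        assert result.combos[frozenset({"A", "B"})] == {"OG1"}

    @pytest.mark.parametrize("strict", [0.0, 0.5, 0.95])
    def test_matches_bruteforce_oracle(self, strict):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 2, size=(10, 50)) * rng.integers(1, 4, (10, 50))
        sources = ["A", "A", "B", "B", "C", "C", "D", "D", "E", "E"]
        meta = meta_from([("g", s) for s in sources])
        matrix = matrix_from(counts)
        presence = part.presence_from_counts(matrix)
        cfg = PartitionConfig(strict_fraction=strict)
        result = part.partition_by_group(presence, meta, "source", cfg)
        labels = dict(zip(presence.index, sources))
        core_o, combos_o, unclassified_o = partition_oracle(
            presence, labels, cfg.core_occupancy, strict)
        assert result.core == core_o
        assert result.combos == combos_o
        assert result.unclassified == unclassified_o
        result.check_disjoint_union(set(presence.columns))

    def test_isolate_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 2, size=(8, 30))
        sources = ["A", "A", "B", "B", "A", "B", "A", "B"]
        meta = meta_from([("g", s) for s in sources])
        presence = part.presence_from_counts(matrix_from(counts))
        result = part.partition_by_group(presence, meta, "source")
        perm = rng.permutation(presence.index)
        result_perm = part.partition_by_group(presence.loc[perm], meta, "source")
        assert result.core == result_perm.core
        assert result.combos == result_perm.combos
        assert result.unclassified == result_perm.unclassified

    def test_missing_metadata_isolates_dropped_with_warning(self, caplog):
        counts = np.ones((3, 2), dtype=int)
        matrix = matrix_from(counts)
        meta = meta_from([("g", "A"), ("g", "B")])  # i2 missing
        presence = part.presence_from_counts(matrix)
        with caplog.at_level("WARNING"):
            result = part.partition_by_group(presence, meta, "source")
        assert any("without metadata" in r.message for r in caplog.records)
        result.check_disjoint_union(set(presence.columns))


class TestSummaryStats:
    def test_genus_panel_arithmetic(self):
        stats = SummaryStats(total_genes=690_814, assigned_genes=682_566,
                             unassigned_genes=8_248, n_orthogroups=25_903)
        rounded = stats.rounded()
        assert rounded["pct_assigned"] == 98.8
        assert rounded["mean_og_size"] == 26.4

    def test_source_panel_arithmetic(self):
        stats = SummaryStats(total_genes=858_025, assigned_genes=853_022,
                             unassigned_genes=5_003, n_orthogroups=18_563)
        assert stats.rounded()["pct_assigned"] == 99.4

    def test_single_orthogroup_degenerate(self):
        stats = SummaryStats(total_genes=7, assigned_genes=7,
                             unassigned_genes=0, n_orthogroups=1)
        assert stats.pct_assigned == 100.0
        assert stats.mean_og_size == 7.0

    def test_impossible_assignment_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(total_genes=5, assigned_genes=5, unassigned_genes=0,
                         n_orthogroups=0)

    def test_from_matrix(self, tiny_matrix):
        summary = part.pangenome_summary(tiny_matrix)
        assert summary.assigned_genes == 9
        assert summary.n_orthogroups == 3

    def test_half_up_rounding(self):
        assert part.round_half_up(26.35, 1) == 26.4
        assert part.round_half_up(98.84, 1) == 98.8
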