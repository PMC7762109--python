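"""FDR filtering, search merging, parsimony grouping and EC abundance."""

import numpy as np
import pytest

from dietomics import (
    DataError,
    PsmRecord,
    Source,
    SynthConfig,
    ec_abundance,
    filter_fdr,
    generate_psm_tables,
    infer_protein_groups,
    merge_searches,
    summarize_profile,
)
from dietomics.pipeline import process_psm_sample
from dietomics.proteomics import ProteinGroup


def psm(spectrum, peptide="PEP", proteins=("P1",), source=Source.METAGENOME,
        score=50.0, q=0.001, sample="A"):
    return PsmRecord(spectrum, sample, peptide, tuple(proteins), source, score, q)


class TestFilterFdr:
    def test_strictly_below_threshold(self):
        records = [psm("s1", q=0.005), psm("s2", q=0.01), psm("s3", q=0.02)]
        kept = filter_fdr(records, 0.01)
        assert [r.spectrum_id for r in kept] == ["s1"]

    def test_empty_input(self):
        assert filter_fdr([], 0.01) == []

    def test_vacuous_threshold_keeps_all(self):
        records = [psm("s1", q=0.5), psm("s2", q=0.99)]
        assert filter_fdr(records, 1.0) == records


class TestMergeSearches:
    def test_singleton_passes_through(self):
        (m,) = merge_searches([psm("s1")], [])
        assert m.chosen_source is Source.METAGENOME

    def test_higher_score_wins(self):
        merged = merge_searches(
            [psm("s2", score=42)], [psm("s2", source=Source.HUMAN, score=57)]
        )
        assert merged[0].chosen_source is Source.HUMAN

    def test_tie_goes_to_metagenome(self):
        merged = merge_searches(
            [psm("s3", score=50)], [psm("s3", source=Source.HUMAN, score=50)]
        )
        assert merged[0].chosen_source is Source.METAGENOME

    def test_duplicate_spectrum_in_one_source_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            merge_searches([psm("s1"), psm("s1")], [])

    def test_output_is_union_of_spectra(self):
        mg = [psm(f"s{i}") for i in range(5)]
        hu = [psm(f"s{i}", source=Source.HUMAN, score=90) for i in range(3, 8)]
        merged = merge_searches(mg, hu)
        assert {m.spectrum_id for m in merged} == {f"s{i}" for i in range(8)}
        assert len(merged) == 8


class TestProteinGroups:
    def test_shared_peptide_maps_to_representative(self):
        ids = merge_searches(
            [psm("s1", peptide="pep1", proteins=("P1", "P2")),
             psm("s2", peptide="pep2", proteins=("P1",))],
            [],
        )
        (group,) = infer_protein_groups(ids, {}, min_peptides=2)
        assert group.representative == "P1"
        assert group.unique_peptides == {"pep1", "pep2"}
        assert group.psm_count == 2
        assert "P2" in group.members

    def test_single_peptide_protein_dropped(self):
        ids = merge_searches([psm("s1", peptide="pep1", proteins=("P3",))], [])
        assert infer_protein_groups(ids, {}, min_peptides=2) == []

    def test_disjoint_proteins_stay_separate(self):
        ids = merge_searches(
            [psm("s1", peptide="a1", proteins=("PA",)),
             psm("s2", peptide="a2", proteins=("PA",)),
             psm("s3", peptide="b1", proteins=("PB",)),
             psm("s4", peptide="b2", proteins=("PB",))],
            [],
        )
        groups = infer_protein_groups(ids, {}, min_peptides=2)
        assert sorted(g.representative for g in groups) == ["PA", "PB"]
        assert all(g.psm_count == 2 for g in groups)

    def test_psm_count_bounds_unique_peptides(self):
        ids = merge_searches(
            [psm("s1", peptide="a1"), psm("s2", peptide="a1"),
             psm("s3", peptide="a2")],
            [],
        )
        (g,) = infer_protein_groups(ids, {}, min_peptides=2)
        assert g.psm_count == 3 >= len(g.unique_peptides) == 2

    def test_raising_min_peptides_never_increases_totals(self):
        cfg = SynthConfig(seed=4, n_ecs=15, n_taxa=5, n_metabolites=5)
        tables, _, ec_map = generate_psm_tables(cfg)
        mg, hu = next(iter(tables.values()))
        merged = merge_searches(filter_fdr(mg), filter_fdr(hu))
        totals = []
        for k in (1, 2, 3, 5):
            groups = infer_protein_groups(merged, ec_map, min_peptides=k)
            totals.append(sum(g.psm_count for g in groups))
        assert totals == sorted(totals, reverse=True)


class TestEcAbundance:
    def test_two_feature_normalization(self):
        groups = {
            "A": [
                ProteinGroup("P1", {"P1"}, {"x", "y"}, 30, frozenset({"1.1.1.1"})),
                ProteinGroup("P2", {"P2"}, {"u", "v"}, 10, frozenset({"2.7.1.1"})),
            ]
        }
        m = ec_abundance(groups)
        assert m.values.loc["1.1.1.1", "A"] == pytest.approx(0.75)
        assert m.values.loc["2.7.1.1", "A"] == pytest.approx(0.25)

    def test_multi_ec_group_contributes_full_count_to_each(self):
        groups = {
            "A": [ProteinGroup("P1", {"P1"}, {"x", "y"}, 10,
                               frozenset({"1.1.1.1", "2.7.1.1"}))]
        }
        m = ec_abundance(groups)
        assert m.values.loc["1.1.1.1", "A"] == pytest.approx(0.5)
        assert m.values.loc["2.7.1.1", "A"] == pytest.approx(0.5)

    def test_absent_ec_is_zero_not_missing(self):
        groups = {
            "A": [ProteinGroup("P1", {"P1"}, {"x", "y"}, 5, frozenset({"1.1.1.1"}))],
            "B": [ProteinGroup("P2", {"P2"}, {"u", "v"}, 5, frozenset({"2.7.1.1"}))],
        }
        m = ec_abundance(groups)
        assert m.values.loc["1.1.1.1", "B"] == 0.0

    def test_sample_without_ec_assignments_is_an_error(self):
        groups = {"A": [ProteinGroup("P1", {"P1"}, {"x", "y"}, 5)]}
        with pytest.raises(DataError, match="A"):
            ec_abundance(groups)

    def test_group_order_permutation_invariant(self):
        base = [
            ProteinGroup("P1", {"P1"}, {"x", "y"}, 7, frozenset({"1.1.1.1"})),
            ProteinGroup("P2", {"P2"}, {"u", "v"}, 3, frozenset({"2.7.1.1"})),
            ProteinGroup("P3", {"P3"}, {"q", "r"}, 5, frozenset({"3.2.1.1"})),
        ]
        m1 = ec_abundance({"A": base})
        m2 = ec_abundance({"A": base[::-1]})
        assert m1.equals(m2)

    def test_columns_sum_to_one_on_synthetic_run(self):
        cfg = SynthConfig(seed=9, n_ecs=20, n_taxa=5, n_metabolites=5)
        tables, _, ec_map = generate_psm_tables(cfg)
        groups = {sid: process_psm_sample(mg, hu, ec_map)[2]
                  for sid, (mg, hu) in tables.items()}
        m = ec_abundance(groups)
        np.testing.assert_allclose(m.values.sum(axis=0).to_numpy(), 1.0, atol=1e-12)

    def test_oracle_equivalence_without_shared_peptides(self):
        """With no shared peptides and one protein per EC, EC abundance is
        just each protein's share of EC-assigned PSMs."""
        rng = np.random.default_rng(0)
        records, expected = [], {}
        counts = {f"PROT{i}": int(rng.integers(2, 30)) for i in range(8)}
        ec_map = {f"PROT{i}": {f"9.9.9.{i}"} for i in range(8)}
        n = 0
        for prot, c in counts.items():
            for j in range(c):
                records.append(psm(f"s{n}", peptide=f"{prot}_pep{j % 2}",
                                   proteins=(prot,)))
                n += 1
        merged = merge_searches(records, [])
        groups = infer_protein_groups(merged, ec_map, min_peptides=2)
        m = ec_abundance({"A": groups})
        total = sum(counts.values())
        for i, (prot, c) in enumerate(counts.items()):
            assert m.values.loc[f"9.9.9.{i}", "A"] == pytest.approx(c / total)


class TestSummary:
    def _matrix(self, ecs, shares):
        groups = {
            "A": [ProteinGroup(f"P{i}", {f"P{i}"}, {f"p{i}a", f"p{i}b"},
                               share, frozenset({ec}))
                  for i, (ec, share) in enumerate(zip(ecs, shares))]
        }
        return groups, ec_abundance(groups)

    def test_uniform_ecs_give_integer_diversity(self):
        groups, m = self._matrix(["1.1", "2.2", "3.3", "4.4"], [5, 5, 5, 5])
        s = summarize_profile([], groups["A"], m, "A")
        assert s.ec_inv_simpson == pytest.approx(4.0)
        assert s.ec_families == 4

    def test_single_ec_degenerate(self):
        groups, m = self._matrix(["1.1"], [9])
        s = summarize_profile([], groups["A"], m, "A")
        assert s.ec_inv_simpson == pytest.approx(1.0)
        assert s.ec_families == 1

    def test_pct_nonhuman_with_ec(self):
        groups = [
            ProteinGroup(f"N{i}", {f"N{i}"}, {f"n{i}a", f"n{i}b"}, 3,
                         frozenset({"1.1.1.1"}) if i < 4 else frozenset())
            for i in range(10)
        ]
        m = ec_abundance({"A": groups})
        s = summarize_profile([], groups, m, "A")
        assert s.pct_nonhuman_with_ec == pytest.approx(40.0)

    def test_unknown_sample_is_an_error(self):
        groups, m = self._matrix(["1.1"], [9])
        with pytest.raises(DataError, match="nope"):
            summarize_profile([], groups["A"], m, "nope")
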