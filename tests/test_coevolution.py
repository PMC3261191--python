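"""Scoring scans, ranking, curves, subsets, distributions and clusters."""

import itertools

import numpy as np
import pytest

from tripletmi.alignments import PairedAlignment
from tripletmi.coevolution import (
    PairScore,
    TripletScore,
    attach_contacts,
    conditional_distributions,
    contact_fraction_curve,
    polar_subset,
    rank_scores,
    score_all_pairs,
    score_all_triplets,
    scores_from_frame,
    scores_to_frame,
    top_cluster_report,
)
from tripletmi.infotheory import mi_pair, mi_triplet
from tripletmi.structure import Residue, StructureModel
from tripletmi.synthetic import (
    PlantedTriplet,
    SyntheticSpec,
    generate_paired_msa,
)


def random_paired(rng, n_rows=60, rna_len=3, prot_len=4, gap_rate=0.05):
    rna = rng.choice(list("ACGU-"), p=[0.24, 0.24, 0.24, 0.23, 0.05],
                     size=(n_rows, rna_len))
    prot = rng.choice(list("RDKLNE-"),
                      p=[0.16, 0.16, 0.16, 0.16, 0.16, 0.15, 0.05],
                      size=(n_rows, prot_len))
    rows = tuple((f"s{i:03d}", "".join(rna[i]), "".join(prot[i]))
                 for i in range(n_rows))
    return PairedAlignment(rows=rows, rna_length=rna_len,
                           protein_length=prot_len)


class TestScoringScans:
    def test_pair_combinatorics(self, fig3_bundle):
        _, paired, _, _ = fig3_bundle
        scores, skipped = score_all_pairs(paired, [1, 2], [1, 2, 3], min_rows=1)
        assert len(scores) == 6 and not skipped

    def test_triplet_combinatorics(self, fig3_bundle):
        _, paired, _, _ = fig3_bundle
        scores, skipped = score_all_triplets(paired, [1], [1, 2, 3, 4],
                                             min_rows=1)
        assert len(scores) == 6 and not skipped
        assert all(s.aa_position_1 < s.aa_position_2 for s in scores)

    def test_triplet_count_identity(self):
        rng = np.random.default_rng(0)
        paired = random_paired(rng, n_rows=200)
        q, p = 3, 4
        scores, skipped = score_all_triplets(
            paired, range(1, q + 1), range(1, p + 1), min_rows=190)
        assert len(scores) + len(skipped) == q * p * (p - 1) // 2

    def test_low_n_scores_skipped_and_logged(self):
        rng = np.random.default_rng(1)
        paired = random_paired(rng, n_rows=30, gap_rate=0.3)
        scores, skipped = score_all_pairs(paired, [1], [1], min_rows=29)
        assert len(scores) + len(skipped) == 1
        if skipped:
            (positions, n), = skipped
            assert positions == (1, 1) and n < 29

    def test_engine_agrees_with_reference_implementation(self):
        """Vectorized scan vs the readable Counter-based estimators."""
        from tripletmi.alignments import extract_columns
        rng = np.random.default_rng(42)
        paired = random_paired(rng, n_rows=80)
        triplets, _ = score_all_triplets(paired, [1, 2, 3], [1, 2, 3, 4],
                                         min_rows=1)
        for s in triplets:
            tuples = extract_columns(paired, s.rna_position,
                                     list(s.aa_positions))
            z, x, y = zip(*tuples)
            ref = mi_triplet(x, y, z)
            assert s.mi == pytest.approx(ref.mi, abs=1e-12)
            assert s.joint_entropy == pytest.approx(ref.joint_entropy,
                                                    abs=1e-12)
            assert s.n_used == ref.n_used
        pairs, _ = score_all_pairs(paired, [1, 2, 3], [1, 2, 3, 4], min_rows=1)
        for s in pairs:
            tuples = extract_columns(paired, s.rna_position,
                                     [s.aa_position])
            z, x = zip(*tuples)
            ref = mi_pair(z, x)
            assert s.mi == pytest.approx(ref.mi, abs=1e-12)

    def test_planted_pairless_triplet_tops_pairs_nowhere(self):
        """An xor-planted triplet has near-zero pairwise MI by design."""
        spec = SyntheticSpec(
            n_species=2000, rna_length=2, protein_length=4,
            planted_triplets=(PlantedTriplet(1, 1, 2, "xor", 1.0),),
            gap_rate=0.0, seed=3)
        paired, _ = generate_paired_msa(spec)
        pairs, _ = score_all_pairs(paired, [1], [1, 2], min_rows=1)
        assert all(p.mi < 0.02 for p in pairs)
        triplets, _ = score_all_triplets(paired, [1], [1, 2], min_rows=1)
        assert triplets[0].mi > 0.9


def make_score(mi_over_h, mi=None, positions=(1, 2, 3), in_contact=None):
    return TripletScore(
        rna_position=positions[0], aa_position_1=positions[1],
        aa_position_2=positions[2], mi=mi if mi is not None else mi_over_h,
        joint_entropy=1.0, mi_over_h=mi_over_h, n_used=200,
        in_contact=in_contact,
        distance=None if in_contact is None else (5.0 if in_contact else 40.0))


class TestRanking:
    def test_descending_order(self):
        scores = [make_score(v, positions=(i, 1, 2))
                  for i, v in enumerate([0.3, 0.1, 0.2], start=1)]
        ranked = rank_scores(scores)
        assert [s.mi_over_h for s in ranked] == [0.3, 0.2, 0.1]

    def test_ties_broken_by_positions(self):
        scores = [make_score(0.2, positions=(2, 1, 2)),
                  make_score(0.2, positions=(1, 1, 2))]
        ranked = rank_scores(scores)
        assert [s.rna_position for s in ranked] == [1, 2]

    def test_positive_only_filter(self):
        scores = [make_score(-0.1, positions=(1, 1, 2)),
                  make_score(0.1, positions=(2, 1, 2))]
        assert len(rank_scores(scores)) == 1
        assert len(rank_scores(scores, positive_only=False)) == 2

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(17)
        scores = [make_score(float(v), positions=(i, 1, 2))
                  for i, v in enumerate(rng.random(500), start=1)]
        ranked = rank_scores(scores)
        expected = sorted((s.mi_over_h for s in scores), reverse=True)
        assert [s.mi_over_h for s in ranked] == expected


class TestContactCurve:
    def test_forty_percent_of_top_five(self):
        flags = [True, False, True, False, False]
        ranked = [make_score(0.9 - 0.1 * i, positions=(i + 1, 1, 2),
                             in_contact=f) for i, f in enumerate(flags)]
        curve = contact_fraction_curve(ranked, max_rank=5)
        assert curve.contact_fraction[4] == pytest.approx(0.4)
        assert curve.contact_fraction[0] == 1.0

    @pytest.mark.parametrize("flag,value", [(True, 1.0), (False, 0.0)])
    def test_constant_curves(self, flag, value):
        ranked = [make_score(0.5, positions=(i, 1, 2), in_contact=flag)
                  for i in range(1, 8)]
        curve = contact_fraction_curve(ranked)
        assert set(curve.contact_fraction) == {value}

    def test_missing_contact_call_is_an_error(self):
        ranked = [make_score(0.5, in_contact=None)]
        with pytest.raises(ValueError, match="contact call"):
            contact_fraction_curve(ranked)

    def test_fraction_equals_exact_count(self):
        rng = np.random.default_rng(23)
        flags = rng.random(60) < 0.3
        ranked = [make_score(1.0 - i * 0.01, positions=(i + 1, 1, 2),
                             in_contact=bool(f))
                  for i, f in enumerate(flags)]
        curve = contact_fraction_curve(ranked, max_rank=60)
        for r, frac in zip(curve.ranks, curve.contact_fraction):
            assert frac == pytest.approx(flags[:r].sum() / r)
            assert 0.0 <= frac <= 1.0


class TestPolarSubset:
    @staticmethod
    def paired_with_protein_columns(cols):
        n = len(cols[0])
        rows = tuple((f"s{i:03d}", "A", "".join(c[i] for c in cols))
                     for i in range(n))
        return PairedAlignment(rows=rows, rna_length=1,
                               protein_length=len(cols))

    def test_polar_dominated_columns_retained(self):
        paired = self.paired_with_protein_columns(
            [["R"] * 6 + ["L"] * 4, ["D"] * 7 + ["V"] * 3,
             ["L"] * 8 + ["R"] * 2, ["V"] * 9 + ["D"] * 1])
        scores = [make_score(0.5, positions=(1, 1, 2)),
                  make_score(0.4, positions=(1, 3, 4)),
                  make_score(0.3, positions=(1, 1, 3))]
        kept = polar_subset(scores, paired)
        assert [s.positions for s in kept] == [(1, 1, 2)]

    def test_empty_input(self):
        paired = self.paired_with_protein_columns([["R"] * 5])
        assert polar_subset([], paired) == []

    def test_mean_fraction_mode(self):
        # 50% polar rows: mean-fraction keeps it, majority rule depends on top
        paired = self.paired_with_protein_columns(
            [["R"] * 5 + ["L"] * 4 + ["V"] * 1])
        pair = PairScore(rna_position=1, aa_position=1, mi=0.1,
                         joint_entropy=1.0, mi_over_h=0.1, n_used=10)
        assert polar_subset([pair], paired, mode="mean_fraction") == [pair]


class TestConditionalDistributions:
    def test_pyrimidine_pairing_at_full_coupling(self):
        spec = SyntheticSpec(
            n_species=400, rna_length=2, protein_length=3,
            planted_triplets=(PlantedTriplet(1, 1, 2, "fig3", 1.0),),
            gap_rate=0.0, seed=5)
        paired, _ = generate_paired_msa(spec)
        dist = conditional_distributions(paired, 1, 1, 2)
        pyr = dist.tables["pyrimidine"]
        assert pyr.loc["R", "D"] + pyr.loc["N", "E"] == pytest.approx(1.0)
        assert pyr.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)

    def test_tables_normalized_and_classes_flagged(self, fig3_bundle):
        _, paired, _, _ = fig3_bundle
        dist = conditional_distributions(paired, 1, 1, 2)
        for label, table in dist.tables.items():
            if table is None:
                assert dist.row_counts[label] == 0
            else:
                assert table.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)

    def test_nucleotide_frequencies_match_construction(self):
        rows = tuple((f"s{i:03d}",
                      "A" * 5 + "C" * 10 + "G" * 15 + "U" * 70, "RD")
                     for i in range(1))
        # one species, 100 rna columns is awkward; instead build 100 rows
        rows = tuple(
            (f"s{i:03d}", ("A" * 5 + "C" * 10 + "G" * 15 + "U" * 70)[i], "RD")
            for i in range(100))
        paired = PairedAlignment(rows=rows, rna_length=1, protein_length=2)
        dist = conditional_distributions(paired, 1, 1, 2)
        assert dist.nucleotide_frequencies == pytest.approx(
            {"A": 0.05, "C": 0.10, "G": 0.15, "U": 0.70})

    def test_uniform_amino_acids_given_nucleotide(self):
        rng = np.random.default_rng(13)
        n = 4000
        rows = tuple(
            (f"s{i:05d}", "A", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                                  2)))
            for i in range(n))
        paired = PairedAlignment(rows=rows, rna_length=1, protein_length=2)
        table = conditional_distributions(paired, 1, 1, 2).tables["A"]
        # max over the 400 cells of a near-uniform multinomial
        assert table.to_numpy().max() < 3 / 400 + 3 * np.sqrt(
            (1 / 400) * (1 - 1 / 400) / n) + 1e-9


def line_model(n_protein, spacing, extra=()):
    residues = [Residue("P", str(i + 1), "amino_acid", (spacing * i, 0.0, 0.0))
                for i in range(n_protein)]
    residues += list(extra)
    residues.append(Residue("R", "1", "nucleotide", (0.0, 100.0, 0.0)))
    return StructureModel(residues=residues)


class TestClusterReport:
    @staticmethod
    def ranked_for(nuc, aa_pairs):
        return [make_score(0.9 - 0.05 * i, positions=(nuc, a, b))
                for i, (a, b) in enumerate(aa_pairs)]

    def test_line_at_five_angstrom_is_one_component(self):
        model = line_model(6, 5.0)
        ranked = self.ranked_for(1, [(1, 2), (3, 4), (5, 6)])
        report = top_cluster_report(ranked, 1, model, "P", k=3, edge_cutoff=8.0)
        assert report["single_spanning_component"]
        assert report["components"] == [[1, 2, 3, 4, 5, 6]]

    def test_two_distant_groups_are_two_components(self):
        residues = [Residue("P", "1", "amino_acid", (0.0, 0.0, 0.0)),
                    Residue("P", "2", "amino_acid", (5.0, 0.0, 0.0)),
                    Residue("P", "3", "amino_acid", (55.0, 0.0, 0.0)),
                    Residue("P", "4", "amino_acid", (60.0, 0.0, 0.0)),
                    Residue("R", "1", "nucleotide", (0.0, 100.0, 0.0))]
        model = StructureModel(residues=residues)
        ranked = self.ranked_for(1, [(1, 2), (3, 4)])
        report = top_cluster_report(ranked, 1, model, "P", k=2, edge_cutoff=8.0)
        assert not report["single_spanning_component"]
        assert report["components"] == [[1, 2], [3, 4]]

    def test_missing_nucleotide_raises(self):
        model = line_model(4, 5.0)
        ranked = self.ranked_for(1, [(1, 2)])
        with pytest.raises(KeyError):
            top_cluster_report(ranked, 99, model, "P")


class TestContactsAndSerialization:
    def test_attach_and_round_trip(self, fig3_bundle):
        _, paired, truth, model = fig3_bundle
        triplets, _ = score_all_triplets(paired, range(1, 7), range(1, 11),
                                         min_rows=125)
        annotated, unmapped = attach_contacts(triplets, model, "R", "P")
        assert not unmapped
        planted = truth.triplets[0]
        by_pos = {s.positions: s for s in annotated}
        assert by_pos[planted.positions].in_contact is True
        frame = scores_to_frame(annotated)
        back = scores_from_frame(frame)
        assert [s.positions for s in back] == [s.positions for s in annotated]
        assert [s.in_contact for s in back] == [s.in_contact for s in annotated]

    def test_unmapped_positions_flagged(self, fig3_bundle):
        _, paired, _, model = fig3_bundle
        score = make_score(0.5, positions=(999, 1, 2))
        annotated, unmapped = attach_contacts([score], model, "R", "P")
        assert unmapped == [score]
        assert annotated[0].distance is None
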