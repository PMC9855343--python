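"""Distance-gated backbone averaging and the merge report."""

import numpy as np
import pytest

from proligand import (
    MergeParams,
    MergeReport,
    apply_transform,
    average_backbone,
    ca_distance,
    nearest_predicted_ca,
    report_summary,
    superpose_structures,
)
from proligand.backbone_merge import MergeError
from proligand.structure_io import Atom, Chain, Residue, Structure

from conftest import polymer_keys


def single_ca_structure(positions_by_chain):
    """{chain_id: [(resnum, xyz), ...]} -> Structure of lone-CA residues."""
    chains = []
    for cid, entries in positions_by_chain.items():
        chain = Chain(id=cid)
        for num, xyz in entries:
            chain.residues.append(Residue(
                name="ALA", number=num,
                atoms=[Atom(name="CA", element="C", position=xyz)],
            ))
        chains.append(chain)
    return Structure(chains=chains)


class TestCaDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 0), (0, 0, 0), 0.0),
        ((0, 0, 0), (1, 0, 0), 1.0),
        ((0, 0, 0), (1, 2, 2), 3.0),
    ])
    def test_euclidean(self, a, b, expected):
        assert ca_distance(np.array(a, float), np.array(b, float)) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ca_distance(np.array([np.nan, 0, 0]), np.zeros(3))


class TestNearestPredictedCa:
    def test_single_candidate(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        pred = single_ca_structure({"A": [(1, (0.4, 0, 0))]})
        key, dist = nearest_predicted_ca(ref.chains[0].residues[0], pred)
        assert key == ("A", 1, "") and dist == pytest.approx(0.4)

    def test_closest_of_two_wins(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        pred = single_ca_structure({"A": [(1, (0.6, 0, 0)), (2, (0.4, 0, 0))]})
        key, dist = nearest_predicted_ca(ref.chains[0].residues[0], pred)
        assert key == ("A", 2, "") and dist == pytest.approx(0.4)

    def test_search_spans_all_predicted_chains(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        pred = single_ca_structure({"A": [(1, (5, 0, 0))], "B": [(9, (0.3, 0, 0))]})
        key, _ = nearest_predicted_ca(ref.chains[0].residues[0], pred)
        assert key == ("B", 9, "")

    def test_exact_tie_broken_by_lowest_key(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        pred = single_ca_structure({
            "B": [(7, (0.5, 0, 0))],
            "A": [(3, (-0.5, 0, 0))],
        })
        key, dist = nearest_predicted_ca(ref.chains[0].residues[0], pred)
        assert key == ("A", 3, "") and dist == pytest.approx(0.5)

    def test_no_ca_returns_none(self):
        res = Residue(name="ALA", number=1,
                      atoms=[Atom(name="CB", element="C", position=(0, 0, 0))])
        pred = single_ca_structure({"A": [(1, (0, 0, 0))]})
        assert nearest_predicted_ca(res, pred) is None


class TestAverageBackbone:
    def test_midpoint_averaging_inside_threshold(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        pred = single_ca_structure({"A": [(1, (0.5, 0, 0))]})
        merged, report = average_backbone(ref, pred, MergeParams(default_threshold=1.0))
        ca = merged.structure.chains[0].residues[0].atom("CA")
        assert np.allclose(ca.position, [0.25, 0, 0])
        assert merged.provenance[("A", 1, "")] == "averaged"
        assert report.chains[0].averaged_residues == 1

    def test_boundary_distance_keeps_reference(self):
        """distance == threshold is not averaged (strict inequality)."""
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        pred = single_ca_structure({"A": [(1, (1.0, 0, 0))]})
        merged, report = average_backbone(ref, pred, MergeParams(default_threshold=1.0))
        assert np.allclose(merged.structure.chains[0].residues[0].atom("CA").position, 0.0)
        assert merged.provenance[("A", 1, "")] == "reference_only"
        assert report.chains[0].averaged_residues == 0

    def test_identical_structures_average_to_reference(self, helix_pair):
        ref, _, _ = helix_pair
        merged, report = average_backbone(ref, ref.copy())
        assert all(c.percent_averaged == 100.0 for c in report.chains)
        ref_polymer = [r for c in ref.chains for r in c.polymer_residues()]
        merged_res = [r for _, r in merged.structure.residues()]
        for res, res0 in zip(merged_res, ref_polymer, strict=True):
            for a, b in zip(res.atoms, res0.atoms):
                assert np.allclose(a.position, b.position, atol=1e-12)

    def test_backbone_atom_only_averaged_when_present_in_both(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        ref.chains[0].residues[0].atoms.append(
            Atom(name="O", element="O", position=(2.0, 0, 0)))
        pred = single_ca_structure({"A": [(1, (0.5, 0, 0))]})  # no O atom
        merged, _ = average_backbone(ref, pred)
        res = merged.structure.chains[0].residues[0]
        assert np.allclose(res.atom("CA").position, [0.25, 0, 0])
        assert np.allclose(res.atom("O").position, [2.0, 0, 0])  # untouched

    def test_merged_coordinates_are_exact_midpoints(self, helix_pair):
        ref, pred, _ = helix_pair
        t = superpose_structures(ref, pred)
        pred_fit = apply_transform(pred, t)
        merged, _ = average_backbone(ref, pred_fit)
        pred_res = {(c.id, r.number, r.insertion_code): r
                    for c in pred_fit.chains for r in c.residues}
        for chain in merged.structure.chains:
            for res in chain.residues:
                key = (chain.id, res.number, res.insertion_code)
                ref_res = next(
                    r for r in ref.chain(chain.id).residues
                    if (r.number, r.insertion_code) == key[1:])
                if merged.provenance[key] == "reference_only":
                    for a in res.atoms:
                        assert np.allclose(a.position, ref_res.atom(a.name).position)

    def test_hetero_residues_never_averaged_and_not_counted(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))]})
        lig = Residue(name="PTQ", number=2,
                      atoms=[Atom(name="C1", element="C", position=(0.1, 0, 0),
                                  is_hetero=True)])
        ref.chains[0].residues.append(lig)
        pred = single_ca_structure({"A": [(1, (0.1, 0, 0))]})
        merged, report = average_backbone(ref, pred)
        assert report.chains[0].total_residues == 1
        # the hetero residue is left for the ligand-transfer stage
        assert all(not r.is_hetero for _, r in merged.structure.residues())

    def test_ground_truth_recovery(self, helix_pair, helix_spec):
        ref, pred, truth = helix_pair
        t = superpose_structures(ref, pred)
        merged, report = average_backbone(ref, apply_transform(pred, t))
        averaged = {k for k, v in merged.provenance.items() if v == "averaged"}
        assert averaged == polymer_keys(ref) - truth.displaced

    def test_threshold_monotonicity(self, helix_pair):
        ref, pred, _ = helix_pair
        t = superpose_structures(ref, pred)
        pred_fit = apply_transform(pred, t)
        counts = []
        for thr in (0.05, 0.3, 1.0, 4.0):
            _, report = average_backbone(ref, pred_fit, MergeParams(default_threshold=thr))
            counts.append([c.averaged_residues for c in report.chains])
        for lo, hi in zip(counts, counts[1:]):
            assert all(a <= b for a, b in zip(lo, hi))

    def test_vanishing_threshold_reproduces_reference(self, helix_pair):
        ref, pred, _ = helix_pair
        t = superpose_structures(ref, pred)
        merged, report = average_backbone(
            ref, apply_transform(pred, t), MergeParams(default_threshold=1e-9))
        assert all(c.averaged_residues == 0 for c in report.chains)

    def test_reference_labels_and_order_preserved(self, helix_pair):
        ref, pred, _ = helix_pair
        t = superpose_structures(ref, pred)
        merged, _ = average_backbone(ref, apply_transform(pred, t))
        assert [c.id for c in merged.structure.chains] == [c.id for c in ref.chains]
        for mc, rc in zip(merged.structure.chains, ref.chains):
            assert [r.key for r in mc.residues] == [r.key for r in rc.residues if not r.is_hetero]

    def test_conservation_of_residue_counts(self, helix_pair, helix_spec):
        ref, pred, _ = helix_pair
        t = superpose_structures(ref, pred)
        _, report = average_backbone(ref, apply_transform(pred, t))
        for c in report.chains:
            assert c.total_residues == helix_spec.residues_per_chain
        n_ref_only = sum(
            c.total_residues - c.averaged_residues for c in report.chains)
        n_avg = sum(c.averaged_residues for c in report.chains)
        assert n_avg + n_ref_only == 2 * helix_spec.residues_per_chain

    def test_per_chain_threshold_override(self):
        ref = single_ca_structure({"A": [(1, (0, 0, 0))], "C": [(1, (10, 0, 0))]})
        pred = single_ca_structure({"A": [(1, (0.4, 0, 0))], "C": [(1, (10.4, 0, 0))]})
        params = MergeParams(default_threshold=1.0, per_chain_threshold={"C": 0.3})
        _, report = average_backbone(ref, pred, params)
        by_chain = {c.chain_id: c.averaged_residues for c in report.chains}
        assert by_chain == {"A": 1, "C": 0}

    def test_empty_reference_errors(self):
        with pytest.raises(MergeError):
            average_backbone(Structure(chains=[]), single_ca_structure({"A": [(1, (0, 0, 0))]}))


class TestReport:
    def test_published_per_chain_percentages(self):
        """Per-chain percentages recomputed from the challenge tallies."""
        report = MergeReport.from_counts([
            ("A", 1021, 845), ("B", 1021, 845), ("C", 1021, 461), ("D", 1021, 852),
        ])
        assert [c.percent_averaged for c in report.chains] == [82.8, 82.8, 45.2, 83.4]
        assert report.overall_percent == 73.55

    def test_overall_from_percent_rows(self):
        report = MergeReport.from_counts([
            ("A", 193, 184), ("B", 193, 0), ("C", 31, 20), ("D", 31, 22),
        ])
        assert [c.percent_averaged for c in report.chains] == [95.3, 0.0, 64.5, 71.0]
        assert report.overall_percent == 57.70

    def test_single_chain_overall(self):
        report = MergeReport.from_counts([("A", 10, 5)])
        assert report.overall_percent == 50.00

    def test_summary_format(self):
        text = report_summary(MergeReport.from_counts([("A", 10, 5)]))
        lines = text.splitlines()
        assert lines[0] == "chain\ttotal\taveraged\tpercent"
        assert lines[1] == "A\t10\t5\t50.0"
        assert lines[-1] == "#overall\t\t\t50.00"
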