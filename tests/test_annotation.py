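"""Fragment annotation: subformula assignment, losses, trees, Cl inference."""

import itertools

import numpy as np
import pytest

from tpscreen.annotation import (
    annotate_loss,
    assign_confidence_level,
    assign_subformulas,
    build_tree,
    infer_cl_count,
)
from tpscreen.formula import (
    ELEMENTS,
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ElementalComposition,
    IonSpecies,
    MassMeasurement,
    NotASubformulaError,
    format_ppm,
    ion_mz,
    parse_formula,
    rdbe,
)
from tpscreen.synthetic import generate_msn_spectra


def brute_force_subformulas(precursor, observed_mz, tol_ppm, allow_radical=False):
    """Independent oracle: plain nested-loop enumeration and filtering.

    Mirrors the documented ranking contract (mass error, RDBE plausibility,
    heteroatom parsimony, Hill string) with none of the vectorized machinery.
    """
    hits = []
    ranges = [range(precursor[el] + 1) for el in ELEMENTS]
    prec_rdbe = rdbe(precursor)
    for counts in itertools.product(*ranges):
        if sum(counts) == 0:
            continue
        comp = ElementalComposition(counts)
        mz = sum(
            c * MONOISOTOPIC_MASS[el] for el, c in zip(ELEMENTS, counts)
        ) - ELECTRON_MASS
        err = (observed_mz - mz) / mz * 1e6
        if abs(err) > tol_ppm:
            continue
        loss = precursor - comp
        radical = (loss["H"] + loss["Cl"] + loss["F"] + loss["N"]) % 2 == 1
        if radical and not allow_radical:
            continue
        plausible = -0.5 <= rdbe(comp) <= prec_rdbe + 1
        removals = sum(
            precursor[el] - comp[el] for el in ELEMENTS if el not in ("C", "H")
        )
        hits.append(((abs(err), radical, not plausible, removals, comp.hill()), comp))
    hits.sort(key=lambda t: t[0])
    return [c for _, c in hits]


class TestAssignSubformulas:
    def test_haloperidol_base_peak(self):
        prec = parse_formula("C21H24ClFNO2")
        hits = assign_subformulas(prec, MassMeasurement(165.0712), 10.0)
        assert hits[0].formula == parse_formula("C10H10FO")
        assert format_ppm(hits[0].ppm) == 1.1

    def test_precursor_assigns_to_itself(self):
        prec = parse_formula("C14H19Cl2N2")
        hits = assign_subformulas(prec, ion_mz(IonSpecies(prec)), 10.0)
        assert hits[0].formula == prec and hits[0].ppm == pytest.approx(0.0)

    @pytest.mark.parametrize("drug", ["haloperidol", "aripiprazole"])
    def test_equals_brute_force_oracle_on_all_table_rows(
        self, drug, haloperidol_template, aripiprazole_template
    ):
        template = (
            haloperidol_template if drug == "haloperidol" else aripiprazole_template
        )
        for row in template.rows:
            ours = [
                a.formula
                for a in assign_subformulas(
                    row.precursor, MassMeasurement(row.observed_mz), 10.0
                )
            ]
            oracle = brute_force_subformulas(row.precursor, row.observed_mz, 10.0)
            assert ours == oracle
            assert ours[0] == row.fragment, row.observed_mz

    def test_published_formulas_top_ranked_with_printed_error(
        self, haloperidol_template, aripiprazole_template
    ):
        for template in (haloperidol_template, aripiprazole_template):
            for row in template.rows:
                top = assign_subformulas(
                    row.precursor, MassMeasurement(row.observed_mz), 10.0
                )[0]
                assert top.formula == row.fragment
                assert format_ppm(top.ppm) == row.printed_dppm

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            assign_subformulas(parse_formula("C6H6"), 79.0542, 0.0)


class TestAnnotateLoss:
    def test_table_loss(self):
        loss, radical = annotate_loss(
            parse_formula("C21H22ClFNO"), parse_formula("C11H13ClN")
        )
        assert loss == parse_formula("C10H9FO") and not radical

    def test_parent_to_parent_empty(self):
        loss, radical = annotate_loss(parse_formula("C6H6"), parse_formula("C6H6"))
        assert loss.is_empty and not radical

    def test_radical_chlorine_loss_flagged(self):
        # dehydro-piperazine TP chain: losing a lone Cl atom flips parity
        loss, radical = annotate_loss(
            parse_formula("C10H13Cl2N2"), parse_formula("C10H13ClN2")
        )
        assert loss == parse_formula("Cl") and radical

    def test_inconsistent_child_rejected(self):
        with pytest.raises(NotASubformulaError):
            annotate_loss(parse_formula("H2O"), parse_formula("C6H6"))


class TestBuildTree:
    def test_aripiprazole_ms3_chain(self, aripiprazole_template):
        spectra = generate_msn_spectra(aripiprazole_template)
        tree = build_tree(spectra, aripiprazole_template.precursor_formula)
        nodes = {n.assignment.formula.hill(): n for n in tree.nodes}
        ms3 = nodes["C6H12N"]
        assert ms3.ms_level == 3
        assert ms3.assignment.loss == parse_formula("C8H7Cl2N")
        anchor = tree.nodes[ms3.parent]
        assert anchor.assignment.formula == parse_formula("C14H19Cl2N2")

    def test_losses_telescope_along_haloperidol_path(self, haloperidol_template):
        spectra = generate_msn_spectra(haloperidol_template)
        tree = build_tree(spectra, haloperidol_template.precursor_formula)
        root = haloperidol_template.precursor_formula
        for path in tree.paths():
            leaf = path[-1].assignment.formula
            total_loss = root - leaf
            summed = root - root
            node_chain = [path[0]] if len(path) == 1 else path
            # MS2 loss + MS3 loss must equal root - leaf
            acc = path[0].assignment.loss
            for node in path[1:]:
                acc = acc + node.assignment.loss
            assert acc == total_loss

    def test_tree_monotone_in_mass_and_nested_in_formula(self, haloperidol_template):
        spectra = generate_msn_spectra(haloperidol_template)
        tree = build_tree(spectra, haloperidol_template.precursor_formula)
        root = haloperidol_template.precursor_formula
        for node in tree.nodes:
            assert root.contains(node.assignment.formula)
            if node.parent is not None:
                parent = tree.nodes[node.parent].assignment.formula
                assert parent.contains(node.assignment.formula)
                assert ion_mz(IonSpecies(parent)) > ion_mz(
                    IonSpecies(node.assignment.formula)
                )

    def test_specific_loss_376_358_165(self):
        prec = parse_formula("C21H24ClFNO2")
        ms2_hit = assign_subformulas(prec, 358.1363, 10.0)[0]
        ms3_hit = assign_subformulas(ms2_hit.formula, 165.0712, 10.0)[0]
        total = (prec - ms2_hit.formula) + (ms2_hit.formula - ms3_hit.formula)
        assert total == prec - parse_formula("C10H10FO")


class TestInferClCount:
    def test_noise_free_patterns(self):
        assert infer_cl_count(100.0, 64.0)[0] == 2
        assert infer_cl_count(100.0, 32.0)[0] == 1
        assert infer_cl_count(100.0, 0.3)[0] == 0

    def test_zero_monoisotopic_undetermined(self):
        with pytest.raises(ValueError):
            infer_cl_count(0.0, 10.0)

    def test_classification_accuracy_under_pattern_noise(self):
        """>=95% correct 0/1/2-Cl calls at 10% multiplicative noise."""
        rng = np.random.default_rng(2024)
        ref = {0: (1.0, 0.0032), 1: (1.0, 0.3198), 2: (1.0, 0.6396)}
        n_draws, correct = 1000, 0
        for i in range(n_draws):
            truth = i % 3
            m, m2 = ref[truth]
            m_obs = m * (1 + 0.10 * rng.standard_normal())
            m2_obs = max(0.0, m2 * (1 + 0.10 * rng.standard_normal()))
            if infer_cl_count(m_obs, m2_obs)[0] == truth:
                correct += 1
        assert correct / n_draws >= 0.95


class TestScreening:
    def test_haloperidol_headline_counts(self, haloperidol_screening):
        detections, _, coverage = haloperidol_screening
        assert len(detections) == 14
        assert sum(tp.n_isomers for tp in detections) == 32
        assert all(ok for ok, _ in coverage.values())

    def test_aripiprazole_headline_counts(self, aripiprazole_screening):
        detections, _, _ = aripiprazole_screening
        assert len(detections) == 12
        assert sum(tp.n_isomers for tp in detections) == 13

    def test_isomer_letters_in_elution_order(self, haloperidol_screening):
        detections, _, _ = haloperidol_screening
        for tp in detections:
            rts = [iso.rt for iso in tp.isomers]
            letters = [iso.letter for iso in tp.isomers]
            assert rts == sorted(rts)
            assert letters == [chr(ord("A") + i) for i in range(len(letters))]

    def test_shoulder_isomer_resolved(self, haloperidol_screening):
        detections, _, _ = haloperidol_screening
        tp392 = next(t for t in detections if t.name == "TP_ha_392")
        a, b = tp392.isomers[0], tp392.isomers[1]
        assert a.rt == pytest.approx(18.45, abs=0.03)
        assert b.rt - a.rt == pytest.approx(0.2, abs=0.05)
        assert b.apex_intensity < a.apex_intensity

    def test_chlorine_counts_match_formulas(self, aripiprazole_screening):
        detections, _, _ = aripiprazole_screening
        for tp in detections:
            assert tp.cl_count == min(tp.cation_formula["Cl"], 2), tp.name

    def test_all_detections_are_level3_without_standards(
        self, haloperidol_screening
    ):
        detections, _, _ = haloperidol_screening
        assert {tp.confidence_level for tp in detections} == {3}

    def test_detections_match_generator_ledger(self, haloperidol_screening):
        """Recovered isomer retention times equal the ledger ground truth."""
        detections, ledger, _ = haloperidol_screening
        truth = ledger[ledger.species != "haloperidol"]
        got = {
            (tp.name, iso.letter): iso.rt
            for tp in detections
            for iso in tp.isomers
        }
        for row in truth.itertuples():
            assert got[(row.species, row.isomer)] == pytest.approx(
                row.rt_min, abs=0.03
            )

    def test_empty_suspect_list(self, haloperidol_screening):
        from tpscreen.annotation import screen_suspects

        assert screen_suspects([], []) == []


class TestConfidence:
    def test_ms2_without_standard_is_level3(self):
        assert assign_confidence_level(has_ms2_evidence=True) == 3

    def test_standard_match_is_level1(self):
        assert assign_confidence_level(True, standard_match=True) == 1

    def test_formula_only_is_level4_or_5(self):
        assert assign_confidence_level(False) == 4
        assert assign_confidence_level(False, formula_unique=False) == 5
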