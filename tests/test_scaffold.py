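"""Scaffold model: charge states, region profiles and isoelectric points."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from ocrevolve import (Artifact, ChargeState, IonizableComposition, PkaSet,
                       ScaffoldError, charge_profile, charge_state,
                       isoelectric_point, load_scaffold, net_charge,
                       state_composition, state_isoelectric_point)
from ocrevolve.io import write_scaffold
from ocrevolve.scaffold import scaffold_to_config, scaffold_from_config


# ---------------------------------------------------------------------------
# independent pI oracle: 0.001-step grid scan of the net-charge function
# ---------------------------------------------------------------------------

def grid_scan_pi(comp, pka=PkaSet(), step=0.001):
    """Locate the net-charge zero crossing by brute-force scan."""
    ph = np.arange(0.0, 14.0 + step, step)
    neg = sum(n / (1.0 + 10.0 ** (pk - ph)) for n, pk in
              [(comp.n_asp, pka.asp), (comp.n_glu, pka.glu),
               (comp.n_cys, pka.cys), (comp.n_tyr, pka.tyr),
               (comp.c_termini, pka.c_term)])
    pos = sum(n / (1.0 + 10.0 ** (ph - pk)) for n, pk in
              [(comp.n_his, pka.his), (comp.n_lys, pka.lys),
               (comp.n_arg, pka.arg), (comp.n_termini, pka.n_term)])
    charge = pos - neg
    idx = np.argmax(charge <= 0.0)
    return float(ph[idx])


# ---------------------------------------------------------------------------
# scaffold loading and validation
# ---------------------------------------------------------------------------

class TestScaffold:
    def test_canonical_architecture(self, scaffold):
        assert scaffold.length == 116
        assert scaffold.n_chargeable == 34
        assert scaffold.basic_count == 6
        rm = scaffold.region_map
        assert len(rm.central) == 9
        assert len(rm.specific) == 10
        assert len(rm.flanking) == 15
        assert len(rm.loop1) == 5 and rm.loop1 <= rm.specific
        assert len(rm.loop2) == 7 and rm.loop2 <= rm.central
        assert 88 in scaffold.position_index
        assert scaffold.acidic_identity[88] == "D"

    def test_roundtrip_through_fasta_and_config(self, scaffold, tmp_path):
        fa, cfg = tmp_path / "s.fasta", tmp_path / "s.yaml"
        write_scaffold(scaffold, fa, cfg)
        loaded = load_scaffold(fa, cfg)
        assert loaded.sequence == scaffold.sequence
        assert loaded.chargeable_positions == scaffold.chargeable_positions
        assert loaded.region_map == scaffold.region_map

    def test_all_neutral_record_has_no_chargeable_positions(self):
        config = {"scaffold": {"length": 116, "chargeable": []},
                  "regions": {}, "position88": 88}
        sc = scaffold_from_config("A" * 116, config)
        assert sc.n_chargeable == 0

    def test_out_of_range_position_is_rejected_by_name(self, scaffold):
        config = scaffold_to_config(scaffold)
        config["scaffold"]["chargeable"].append(120)
        config["regions"]["flanking"].append(120)
        with pytest.raises(ScaffoldError, match="120"):
            scaffold_from_config(scaffold.sequence, config)

    def test_region_map_must_partition_chargeable(self, scaffold):
        config = scaffold_to_config(scaffold)
        config["regions"]["central"].remove(56)
        with pytest.raises(ScaffoldError, match="partition"):
            scaffold_from_config(scaffold.sequence, config)

    def test_declared_length_must_match(self, scaffold):
        config = scaffold_to_config(scaffold)
        config["scaffold"]["length"] = 100
        with pytest.raises(ScaffoldError, match="length"):
            scaffold_from_config(scaffold.sequence, config)


# ---------------------------------------------------------------------------
# charge_state
# ---------------------------------------------------------------------------

class TestChargeState:
    def test_wild_type_is_fully_acidic(self, scaffold):
        st_ = charge_state(scaffold.sequence, scaffold)
        assert st_.artifact is Artifact.INTACT
        assert st_.total == 34

    def test_pocr_is_fully_neutral(self, scaffold):
        st_ = charge_state(scaffold.pocr_sequence, scaffold)
        assert st_.artifact is Artifact.INTACT
        assert st_.total == 0

    def test_truncated_sequence_is_frameshift(self, scaffold):
        st_ = charge_state(scaffold.sequence[:90], scaffold)
        assert st_.artifact is Artifact.FRAMESHIFT_DELETION

    def test_internal_stop_is_frameshift(self, scaffold):
        seq = scaffold.sequence[:50] + "*" + scaffold.sequence[51:]
        assert charge_state(seq, scaffold).artifact is \
            Artifact.FRAMESHIFT_DELETION

    def test_empty_sequence_is_empty_vector(self, scaffold):
        assert charge_state("", scaffold).artifact is Artifact.EMPTY_VECTOR

    def test_non_isogenic_residue_at_chargeable_position_errors(self,
                                                                scaffold):
        p = scaffold.chargeable_positions[0]
        seq = list(scaffold.sequence)
        seq[p - 1] = "A"
        with pytest.raises(ScaffoldError, match=str(p)):
            charge_state("".join(seq), scaffold)

    def test_lowercase_accepted(self, scaffold):
        st_ = charge_state(scaffold.sequence.lower(), scaffold)
        assert st_.total == 34

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(min_value=0, max_value=33)))
    def test_toggle_roundtrip(self, toggles):
        """Writing a toggled pocr sequence and re-reading it reproduces the
        toggle set exactly."""
        from ocrevolve import canonical_scaffold
        sc = canonical_scaffold()
        acidic = np.zeros(34, dtype=bool)
        acidic[list(toggles)] = True
        seq = sc.sequence_for(acidic)
        back = charge_state(seq, sc)
        assert np.array_equal(back.acidic, acidic)


# ---------------------------------------------------------------------------
# charge_profile
# ---------------------------------------------------------------------------

class TestChargeProfile:
    def test_wild_type_counts(self, fixtures):
        p = charge_profile(fixtures["wt"])
        assert (p.total, p.central, p.loop1, p.loop2) == (34, 9, 5, 7)
        assert p.central + p.specific + p.flanking == p.total
        assert p.pos88_acidic

    def test_pocr_counts_and_undefined_percentage(self, fixtures):
        p = charge_profile(fixtures["pocr"])
        assert (p.total, p.central, p.specific, p.flanking) == (0, 0, 0, 0)
        assert p.flanking_pct is None

    def test_central_only_state(self, scaffold):
        """Acidic only at the 9 central positions: counts follow from set
        intersection with the region map."""
        acidic = scaffold.central_vector.copy()
        p = charge_profile(ChargeState(scaffold, acidic))
        assert (p.total, p.central, p.specific, p.flanking) == (9, 9, 0, 0)
        assert p.flanking_pct == 0.0

    def test_artifact_clone_rejected(self, scaffold):
        st_ = charge_state("", scaffold)
        with pytest.raises(ScaffoldError, match="filter"):
            charge_profile(st_)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=34, max_size=34))
    def test_partition_conservation(self, bits):
        """central + specific + flanking == total for every state."""
        from ocrevolve import canonical_scaffold
        sc = canonical_scaffold()
        p = charge_profile(ChargeState(sc, np.array(bits)))
        assert p.central + p.specific + p.flanking == p.total


# ---------------------------------------------------------------------------
# isoelectric point
# ---------------------------------------------------------------------------

class TestIsoelectricPoint:
    def test_two_group_symmetry(self):
        """One acid + one base with pKa a and b titrate to pI=(a+b)/2."""
        comp = IonizableComposition(n_asp=1, n_lys=1, n_termini=0,
                                    c_termini=0)
        pka = PkaSet()
        assert isoelectric_point(comp, tol=1e-4) == pytest.approx(
            (pka.asp + pka.lys) / 2, abs=1e-3)

    def test_ocr_composition_is_very_acidic(self, scaffold, fixtures):
        """34 acidic vs 6 basic residues pull the pI to 4.5 or below."""
        pi = state_isoelectric_point(fixtures["wt"])
        assert pi <= 4.5

    def test_bisection_agrees_with_grid_scan(self, scaffold, fixtures):
        for name in ("wt", "pocr", "M1.9-like", "M2.8-like"):
            comp = state_composition(fixtures[name])
            assert state_isoelectric_point(fixtures[name]) == pytest.approx(
                grid_scan_pi(comp), abs=0.01)

    def test_pocr_pi_exceeds_ocr_pi(self, fixtures):
        """Removing all 34 acidic side chains must raise the pI (checked
        against the grid-scan oracle for both states)."""
        pi_wt = grid_scan_pi(state_composition(fixtures["wt"]))
        pi_pocr = grid_scan_pi(state_composition(fixtures["pocr"]))
        assert pi_pocr > pi_wt
        assert state_isoelectric_point(fixtures["pocr"]) > \
            state_isoelectric_point(fixtures["wt"])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 8),
           st.integers(0, 3))
    def test_monotonicity_in_composition(self, nd, ne, nk, nh):
        """Adding an acidic group never raises the pI; adding a basic group
        never lowers it."""
        base = IonizableComposition(n_asp=nd, n_glu=ne, n_lys=nk, n_his=nh)
        pi0 = isoelectric_point(base)
        more_acid = IonizableComposition(n_asp=nd + 1, n_glu=ne, n_lys=nk,
                                         n_his=nh)
        more_base = IonizableComposition(n_asp=nd, n_glu=ne, n_lys=nk + 1,
                                         n_his=nh)
        assert isoelectric_point(more_acid) <= pi0 + 2e-3
        assert isoelectric_point(more_base) >= pi0 - 2e-3

    def test_no_ionisable_group_errors(self):
        comp = IonizableComposition(n_termini=0, c_termini=0)
        with pytest.raises(ValueError, match="ionisable"):
            isoelectric_point(comp)

    def test_net_charge_decreases_with_ph(self, fixtures):
        comp = state_composition(fixtures["wt"])
        values = [net_charge(comp, ph) for ph in (2.0, 4.0, 7.0, 10.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_biopython_cross_check(self, scaffold, fixtures):
        """Independent implementation sanity check on compositions whose pI
        lies inside biopython's search window [4.05, 12] (loose tolerance:
        biopython's N-terminal pKa depends on the first residue)."""
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint as BioIP
        for name in ("pocr", "M1.9-like"):
            seq = fixtures[name].sequence()
            ours = isoelectric_point(
                IonizableComposition.from_sequence(seq))
            theirs = BioIP(seq).pi()
            assert ours == pytest.approx(theirs, abs=0.3), name

    def test_pka_values_must_be_physical(self):
        with pytest.raises(ValueError):
            PkaSet(asp=-1.0)
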