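"""Elemental compositions and isotopologue envelopes against independent oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnover15n.isotope_model import (
    ElementalComposition,
    EnrichmentModel,
    IsotopeEnvelope,
    PeptideIon,
    composition_from_sequence,
    isotopologue_distribution,
    mixture_envelope,
    peptide_envelopes,
)

AA = "GASPVTCLINDQKEMHFRYW"


def enumerate_envelope(comp: ElementalComposition, p15N: float) -> np.ndarray:
    """Exact-rational polynomial-expansion oracle: convolve one atom at a time.

    Builds the generating polynomial of the extra-neutron count by multiplying
    the single-atom polynomial of every atom individually, with Fraction
    coefficients, so there is no floating-point error or tail truncation.
    """
    atom_polys = {
        "C": [Fraction(9893, 10000), Fraction(107, 10000)],
        "H": [Fraction(999885, 1000000), Fraction(115, 1000000)],
        "O": [Fraction(99757, 100000), Fraction(38, 100000), Fraction(205, 100000)],
        "S": [Fraction(9499, 10000), Fraction(75, 10000), Fraction(425, 10000),
              Fraction(0), Fraction(1, 10000)],
        "N": [1 - Fraction(p15N).limit_denominator(10**9),
              Fraction(p15N).limit_denominator(10**9)],
    }
    poly = [Fraction(1)]
    for el in "CHNOS":
        single = atom_polys[el]
        for _ in range(getattr(comp, el)):
            new = [Fraction(0)] * (len(poly) + len(single) - 1)
            for i, a in enumerate(poly):
                for j, b in enumerate(single):
                    new[i + j] += a * b
            poly = new
    return np.array([float(c) for c in poly])


class TestComposition:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("G", ElementalComposition(C=2, H=5, N=1, O=2)),
            ("PEPTIDE", ElementalComposition(C=34, H=53, N=7, O=15)),
        ],
    )
    def test_known_molecules(self, seq, expected):
        assert composition_from_sequence(PeptideIon(seq)) == expected

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="unknown residue 'X' at position 2"):
            PeptideIon("PXP")

    def test_carbamidomethyl_adds_c2h3no_per_cys(self):
        plain = composition_from_sequence(PeptideIon("ACCK", carbamidomethyl_cys=False))
        fixed = composition_from_sequence(PeptideIon("ACCK"))
        assert (fixed.C - plain.C, fixed.H - plain.H, fixed.N - plain.N,
                fixed.O - plain.O, fixed.S - plain.S) == (4, 6, 2, 2, 0)

    def test_matches_pyteomics_composition(self, rng):
        """Shipped residue table agrees with the pyteomics amino-acid table."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for _ in range(25):
            seq = "".join(rng.choice(list(AA), size=rng.integers(5, 20)))
            ours = composition_from_sequence(PeptideIon(seq, carbamidomethyl_cys=False))
            ref = pyteomics_mass.Composition(sequence=seq)
            assert (ours.C, ours.H, ours.N, ours.O, ours.S) == (
                ref.get("C", 0), ref.get("H", 0), ref.get("N", 0),
                ref.get("O", 0), ref.get("S", 0))

    def test_nitrogen_at_least_residue_count(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list(AA), size=rng.integers(5, 20)))
            comp = composition_from_sequence(PeptideIon(seq))
            assert comp.N >= len(seq)

    def test_invalid_peptides_rejected(self):
        with pytest.raises(ValueError):
            PeptideIon("")
        with pytest.raises(ValueError):
            PeptideIon("PEPTIDEK", charge=0)


class TestIsotopologueDistribution:
    def test_single_nitrogen_binomial(self):
        env = isotopologue_distribution(ElementalComposition(N=1), 0.00364)
        assert np.allclose(env.probabilities, [0.99636, 0.00364], atol=1e-12)

    def test_monoisotopic_delta(self):
        """All-light abundances and p15N = 0 collapse to a delta at k = 0."""
        mono = EnrichmentModel(
            p_natural=0.0, p_label=0.5,
            abundances={"C": (1.0,), "H": (1.0,), "O": (1.0,), "S": (1.0,)})
        env = isotopologue_distribution(
            ElementalComposition(C=10, H=20, N=5, O=3, S=1), 0.0, mono)
        assert len(env) == 1 and env.probabilities[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seq", ["PEPTIDE", "GCK", "MWNR"])
    @pytest.mark.parametrize("p15N", [0.00364, 0.5, 0.98])
    def test_matches_exact_enumeration(self, seq, p15N):
        """Envelope equals exhaustive isotope-assignment expansion to < 1e-10."""
        comp = composition_from_sequence(PeptideIon(seq, carbamidomethyl_cys=False))
        env = isotopologue_distribution(comp, p15N).probabilities
        exact = enumerate_envelope(comp, p15N)
        k = min(len(env), len(exact))
        assert np.max(np.abs(env[:k] - exact[:k])) < 1e-10
        assert np.sum(exact[k:]) < 1e-10

    def test_envelope_sums_to_one(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list(AA), size=rng.integers(7, 26)))
            comp = composition_from_sequence(PeptideIon(seq))
            env = isotopologue_distribution(comp, rng.random())
            assert abs(env.probabilities.sum() - 1.0) < 1e-9

    @given(st.floats(0.01, 0.97), st.floats(0.001, 0.02))
    @settings(max_examples=25, deadline=None)
    def test_mean_neutrons_increases_with_enrichment(self, p, dp):
        comp = composition_from_sequence(PeptideIon("PEPTIDEK"))
        lo = isotopologue_distribution(comp, p).mean_neutrons()
        hi = isotopologue_distribution(comp, p + dp).mean_neutrons()
        assert hi > lo

    def test_p15n_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            isotopologue_distribution(ElementalComposition(N=1), 1.5)


@pytest.fixture(scope="module")
def pair():
    nat, lab = peptide_envelopes(PeptideIon("ELVISLIVESK"))
    return IsotopeEnvelope(nat), IsotopeEnvelope(lab)


class TestMixture:
    def test_endpoints_return_components(self, pair):
        nat, lab = pair
        assert np.allclose(mixture_envelope(nat, lab, 0.0).probabilities,
                           nat.probabilities)
        assert np.allclose(mixture_envelope(nat, lab, 1.0).probabilities,
                           lab.probabilities)

    def test_half_mixture_is_elementwise_average(self, pair):
        nat, lab = pair
        mix = mixture_envelope(nat, lab, 0.5).probabilities
        assert np.allclose(mix, 0.5 * (nat.probabilities + lab.probabilities))

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_mean_neutrons_linear_in_lpf(self, pair, lpf):
        nat, lab = pair
        mix = mixture_envelope(nat, lab, lpf)
        expected = (1 - lpf) * nat.mean_neutrons() + lpf * lab.mean_neutrons()
        assert mix.mean_neutrons() == pytest.approx(expected, abs=1e-9)

    def test_lpf_out_of_range_rejected(self, pair):
        nat, lab = pair
        with pytest.raises(ValueError):
            mixture_envelope(nat, lab, 1.2)
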