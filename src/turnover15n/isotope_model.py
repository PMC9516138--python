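"""Peptide elemental compositions and isotopologue envelopes at arbitrary 15N enrichment.

The measured quantity in a progressive-labeling experiment is the shape of a
peptide's isotopologue envelope: a probability vector over the number of extra
neutrons relative to the all-light monoisotopic species.  Pre-existing protein
carries nitrogen at natural 15N abundance; protein synthesized after the medium
switch carries nitrogen at the enrichment of the label.  The observed envelope
is a two-population mixture of those envelopes, and the mixing weight is the
labeled peptide fraction (LPF).

Envelopes are indexed on a unit extra-neutron grid of the neutral molecule;
charge only matters when reading or simulating m/z peak tables, because the
envelope intensity pattern, not exact mass, carries the LPF signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "PeptideIon",
    "ElementalComposition",
    "EnrichmentModel",
    "IsotopeEnvelope",
    "composition_from_sequence",
    "isotopologue_distribution",
    "mixture_envelope",
]

#: mass of the truncated envelope tail; chosen far below the 1e-9 guarantee so
#: envelopes match exact rational-arithmetic enumeration to <1e-10 per entry
TAIL_TOL = 1e-13

_ELEMENTS = ("C", "H", "N", "O", "S")

# Natural isotope abundances indexed by extra neutrons (IUPAC representative
# values).  S-35 does not occur naturally; the zero keeps S-36 at offset 4.
_NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: natural abundance of 15N
P15N_NATURAL = 0.00364


def _load_residue_table() -> dict[str, tuple[int, int, int, int, int]]:
    table: dict[str, tuple[int, int, int, int, int]] = {}
    text = (
        resources.files("turnover15n.data")
        .joinpath("residue_composition.tsv")
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        parts = line.split("\t")
        table[parts[0]] = tuple(int(x) for x in parts[1:6])  # type: ignore[assignment]
    return table


_RESIDUES = _load_residue_table()

# carbamidomethylation of cysteine (iodoacetamide alkylation): +C2H3NO per Cys
_CARBAMIDOMETHYL = (2, 3, 1, 1, 0)


@dataclass(frozen=True)
class PeptideIon:
    """An identified peptide species whose envelope is modeled.

    Parameters
    ----------
    sequence
        Amino-acid sequence over the 20 standard one-letter codes.
    charge
        Positive integer charge state.
    carbamidomethyl_cys
        Apply the fixed carbamidomethyl modification to every cysteine
        (iodoacetamide alkylation during sample preparation). Default on.
    """

    sequence: str
    charge: int = 1
    carbamidomethyl_cys: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in _RESIDUES:
                raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a neutral molecule (C, H, N, O, S)."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative atom count for {el}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            *(getattr(self, el) + getattr(other, el) for el in _ELEMENTS)
        )


@dataclass(frozen=True)
class EnrichmentModel:
    """Isotope abundances for the two nitrogen populations.

    ``p_natural`` is the 15N fraction under natural abundance; ``p_label`` the
    15N fraction incorporated into protein synthesized during labeling.  The
    label enrichment is below the nominal purity of the nitrogen salts because
    amino-acid recycling dilutes the label; 0.98 is the default and the value
    may be fitted from data instead (see ``envelope_quant.estimate_lpf``).
    """

    p_natural: float = P15N_NATURAL
    p_label: float = 0.98
    abundances: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_NATURAL_ABUNDANCE)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_natural <= 1.0:
            raise ValueError("p_natural must lie in [0, 1]")
        if not 0.0 <= self.p_label <= 1.0:
            raise ValueError("p_label must lie in [0, 1]")
        if self.p_label <= self.p_natural:
            raise ValueError("p_label must exceed p_natural")
        for el, probs in self.abundances.items():
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"abundances for {el} outside [0, 1]")


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Normalized isotopologue probabilities indexed by extra-neutron count k."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("envelope must be a non-empty 1-D vector")
        if np.any(p < 0):
            raise ValueError("envelope entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("envelope must sum to 1 within 1e-9")
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return len(self.probabilities)

    def mean_neutrons(self) -> float:
        """Expected number of extra neutrons (envelope centroid)."""
        p = self.probabilities
        return float(np.dot(np.arange(len(p)), p))


def composition_from_sequence(pep: PeptideIon) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum + one water + fixed mods."""
    counts = np.zeros(5, dtype=int)
    for aa in pep.sequence:
        counts += _RESIDUES[aa]
    counts += (0, 2, 0, 1, 0)  # H2O
    if pep.carbamidomethyl_cys:
        n_cys = pep.sequence.count("C")
        counts += np.asarray(_CARBAMIDOMETHYL) * n_cys
    return ElementalComposition(*counts.tolist())


def _truncate(p: np.ndarray, tol: float) -> np.ndarray:
    """Drop the trailing tail whose total mass is below ``tol``."""
    tail = np.cumsum(p[::-1])[::-1]
    keep = np.nonzero(tail >= tol)[0]
    if len(keep) == 0:
        return p[:1]
    return p[: keep[-1] + 1]

def _element_distribution(single: np.ndarray, n: int, tol: float) -> np.ndarray:
    """Extra-neutron pmf of ``n`` iid atoms, by binary-exponentiation convolution."""
    result = np.ones(1)
    base = single
    while n:
        if n & 1:
            result = _truncate(np.convolve(result, base), tol)
        n >>= 1
        if n:
            base = _truncate(np.convolve(base, base), tol)
    return result


def isotopologue_distribution(
    comp: ElementalComposition,
    p15N: float,
    model: EnrichmentModel | None = None,
) -> IsotopeEnvelope:
    """Theoretical envelope of a molecule whose nitrogen is 15N at fraction ``p15N``.

    Per-element extra-neutron distributions (binomial for two-isotope elements,
    multinomial otherwise) are convolved directly, with tail truncation; the
    nitrogen channel uses ``p15N`` while C, H, O, S use natural abundances from
    ``model``.
    """
    if not 0.0 <= p15N <= 1.0:
        raise ValueError(f"p15N must lie in [0, 1], got {p15N}")
    model = model or EnrichmentModel()
    envelope = np.ones(1)
    for el in ("C", "H", "O", "S"):
        n = getattr(comp, el)
        if n:
            single = np.asarray(model.abundances[el], dtype=float)
            single = single / single.sum()
            envelope = _truncate(
                np.convolve(envelope, _element_distribution(single, n, TAIL_TOL)),
                TAIL_TOL,
            )
    if comp.N:
        single = np.array([1.0 - p15N, p15N])
        envelope = _truncate(
            np.convolve(envelope, _element_distribution(single, comp.N, TAIL_TOL)),
            TAIL_TOL,
        )
    return IsotopeEnvelope(envelope / envelope.sum())


def peptide_envelopes(
    pep: PeptideIon, model: EnrichmentModel | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural and fully labeled envelopes of a peptide, padded to equal length."""
    model = model or EnrichmentModel()
    comp = composition_from_sequence(pep)
    nat = isotopologue_distribution(comp, model.p_natural, model).probabilities
    lab = isotopologue_distribution(comp, model.p_label, model).probabilities
    k = max(len(nat), len(lab))
    return _pad(nat, k), _pad(lab, k)


def _pad(p: np.ndarray, k: int) -> np.ndarray:
    return np.pad(p, (0, k - len(p))) if len(p) < k else p


def mixture_envelope(
    natural: IsotopeEnvelope, labeled: IsotopeEnvelope, lpf: float
) -> IsotopeEnvelope:
    """Two-population mixture ``(1 - lpf) * natural + lpf * labeled``.

    ``lpf`` is the labeled peptide fraction: the fraction of the peptide's
    population synthesized during the labeling window.
    """
    if not 0.0 <= lpf <= 1.0:
        raise ValueError(f"lpf must lie in [0, 1], got {lpf}")
    k = max(len(natural), len(labeled))
    mix = (1.0 - lpf) * _pad(natural.probabilities, k) + lpf * _pad(
        labeled.probabilities, k
    )
    return IsotopeEnvelope(mix / mix.sum())
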