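"""Tryptic peptides and theoretical isotope envelopes under 15N metabolic labeling.

Metabolic labeling with 15N-substituted growth media shifts every nitrogen
atom of a peptide from the natural isotope ratio to the enrichment of the
medium.  The isotope envelope of a peptide at a given enrichment is the
probability distribution of its isotopologues, aggregated at nominal-mass
resolution: peaks one "extra neutron" apart, each positioned at the
probability-weighted exact mass of the isotopologues it contains.

The enrichment parameter ``e`` is the fraction of nitrogen that is 15N.
``e = 0.00364`` reproduces natural nitrogen; ``e = 0.5`` models growth in
50% 15N media; ``e = 1.0`` models the fully labeled reference spike.
Carbon, hydrogen, oxygen and sulfur always use IUPAC natural abundances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pt_mass

__all__ = [
    "ElementalComposition",
    "Envelope",
    "InvalidSequenceError",
    "UnknownModificationError",
    "EmptyCompositionError",
    "tryptic_digest",
    "elemental_composition",
    "isotope_distribution",
    "NATURAL_N15_ABUNDANCE",
    "PROTON_MASS",
    "NEUTRON_MASS",
    "N15_N14_DELTA",
]


class InvalidSequenceError(ValueError):
    """Peptide or protein sequence contains a non-standard residue."""


class UnknownModificationError(ValueError):
    """A fixed modification name is not recognised."""


class EmptyCompositionError(ValueError):
    """Isotope distribution requested for a composition with no atoms."""


PROTON_MASS = 1.007276466621
NEUTRON_MASS = 1.00866491595

NATURAL_N15_ABUNDANCE = 0.00364

# (exact mass, natural abundance) indexed by neutron-number offset from the
# lightest isotope; zero-abundance slots pad skipped offsets (e.g. 35S).
_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 1.0 - NATURAL_N15_ABUNDANCE), (15.0001088989, NATURAL_N15_ABUNDANCE)],
    "O": [(15.99491461956, 0.99757), (16.99913170, 0.00038), (17.9991610, 0.00205)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (0.0, 0.0),
        (35.96708076, 0.0001),
    ],
}

_N14_MASS = _ISOTOPES["N"][0][0]
_N15_MASS = _ISOTOPES["N"][1][0]
N15_N14_DELTA = _N15_MASS - _N14_MASS

_ELEMENTS = ("C", "H", "N", "O", "S")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Elemental deltas of supported fixed modifications.
_MODIFICATIONS: dict[str, dict[str, int]] = {
    # iodoacetamide alkylation of cysteine: +C2H3NO
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
}

_WATER = {"H": 2, "O": 1}


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a (modified) peptide, restricted to C/H/N/O/S."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    @property
    def total_atoms(self) -> int:
        return sum(getattr(self, el) for el in _ELEMENTS)

    def monoisotopic_mass(self) -> float:
        return sum(_ISOTOPES[el][0][0] * getattr(self, el) for el in _ELEMENTS)

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in _ELEMENTS if getattr(self, el)}


@dataclass(frozen=True)
class Envelope:
    """Aggregated isotope distribution of one peptide species at one charge.

    ``mz`` is strictly increasing; ``intensity`` sums to one before any
    truncation-renormalization.  ``enrichment`` is the 15N fraction that
    generated the distribution.
    """

    peptide_id: str
    charge: int
    enrichment: float
    mz: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def max_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def centroid_neutral_mass(self) -> float:
        """Intensity-weighted mean neutral mass of the envelope."""
        neutral = self.mz * self.charge - self.charge * PROTON_MASS
        return float(np.sum(neutral * self.intensity) / np.sum(self.intensity))


def tryptic_digest(protein_sequence: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico trypsin digest: cleave C-terminal to K/R except before P.

    Returns every peptide with at most ``missed_cleavages`` internal K/R
    cleavage sites, ordered by position then by span.  The zero-missed-
    cleavage peptides partition the protein.
    """
    seq = protein_sequence.strip().upper()
    if not seq:
        return []
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise InvalidSequenceError(
            f"non-standard residue(s) {sorted(bad)} in protein sequence"
        )
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    # fully tryptic fragments: split after K or R unless followed by P
    fragments = [f for f in re.split(r"(?<=[KR])(?!P)", seq) if f]
    peptides: list[str] = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            peptides.append("".join(fragments[i : j + 1]))
    return peptides


def elemental_composition(
    peptide: str, fixed_modifications: frozenset[str] | set[str] = frozenset({"carbamidomethyl"})
) -> ElementalComposition:
    """C/H/N/O/S atom counts of a peptide: residue formulas + one water +
    fixed-modification deltas (carbamidomethyl adds C2H3NO per cysteine).
    """
    seq = peptide.strip().upper()
    if not seq:
        raise InvalidSequenceError("empty peptide")
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise InvalidSequenceError(f"non-standard residue(s) {sorted(bad)} in peptide")
    unknown = set(fixed_modifications) - set(_MODIFICATIONS)
    if unknown:
        raise UnknownModificationError(f"unknown modification(s) {sorted(unknown)}")

    counts = dict.fromkeys(_ELEMENTS, 0)
    for aa in seq:
        residue = _pt_mass.std_aa_comp[aa]
        for el, n in residue.items():
            if el not in counts:
                raise InvalidSequenceError(f"residue {aa} contains unsupported element {el}")
            counts[el] += n
    for el, n in _WATER.items():
        counts[el] += n
    if "carbamidomethyl" in fixed_modifications:
        n_cys = seq.count("C")
        for el, n in _MODIFICATIONS["carbamidomethyl"].items():
            counts[el] += n * n_cys
    return ElementalComposition(**counts)


def _single_atom_arrays(element: str, n15_enrichment: float | None) -> tuple[np.ndarray, np.ndarray]:
    """(probability, probability*mass) arrays over neutron offsets for one atom."""
    if element == "N" and n15_enrichment is not None:
        iso = [(_N14_MASS, 1.0 - n15_enrichment), (_N15_MASS, n15_enrichment)]
    else:
        iso = _ISOTOPES[element]
    p = np.array([a for _, a in iso], dtype=float)
    pm = np.array([m * a for m, a in iso], dtype=float)
    return p, pm


def _convolve_pm(
    p1: np.ndarray, pm1: np.ndarray, p2: np.ndarray, pm2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # probabilities convolve; first mass moments follow the product rule
    return np.convolve(p1, p2), np.convolve(pm1, p2) + np.convolve(p1, pm2)


def _element_power(
    p: np.ndarray, pm: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n i.i.d. atoms by binary exponentiation."""
    rp, rpm = np.array([1.0]), np.array([0.0])
    bp, bpm = p, pm
    while n:
        if n & 1:
            rp, rpm = _convolve_pm(rp, rpm, bp, bpm)
        n >>= 1
        if n:
            bp, bpm = _convolve_pm(bp, bpm, bp, bpm)
    return rp, rpm


def isotope_distribution(
    composition: ElementalComposition,
    n15_enrichment: float = NATURAL_N15_ABUNDANCE,
    charge: int = 1,
    truncation: float = 1e-4,
    peptide_id: str = "",
) -> Envelope:
    """Theoretical isotope envelope of a composition at a given 15N enrichment.

    The distribution is the convolution over elements of per-element
    isotope distributions.  Nitrogen's two-isotope probabilities are
    ``(1 - e, e)``; all other elements use natural abundances.  Peaks are
    aggregated by neutron number and positioned at the probability-weighted
    exact mass, so the envelope centroid equals the expected neutral mass —
    linear in ``e`` with slope ``nN * (m(15N) - m(14N))``.

    Parameters
    ----------
    truncation
        Peaks below this relative intensity (relative to the summed
        distribution) are dropped and the remainder renormalized; pass 0
        to keep the full distribution.
    """
    if not 0.0 <= n15_enrichment <= 1.0:
        raise ValueError("n15_enrichment must be in [0, 1]")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if composition.total_atoms == 0:
        raise EmptyCompositionError("cannot compute an envelope for an empty composition")

    p, pm = np.array([1.0]), np.array([0.0])
    for el in _ELEMENTS:
        n = getattr(composition, el)
        if n == 0:
            continue
        ep, epm = _single_atom_arrays(el, n15_enrichment if el == "N" else None)
        ep_n, epm_n = _element_power(ep, epm, n)
        p, pm = _convolve_pm(p, pm, ep_n, epm_n)

    keep = p > 0
    p, pm = p[keep], pm[keep]
    masses = pm / p
    if truncation > 0:
        sel = p >= truncation * p.sum()
        p, masses = p[sel], masses[sel]
    p = p / p.sum()
    mz = (masses + charge * PROTON_MASS) / charge
    order = np.argsort(mz)
    return Envelope(
        peptide_id=peptide_id,
        charge=charge,
        enrichment=n15_enrichment,
        mz=mz[order],
        intensity=p[order],
    )
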