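"""Oligo-directed RNase H accessibility quantitation.

A DNA oligonucleotide annealed to an exposed region of 16S rRNA directs
RNase H cleavage of the RNA strand of the hybrid, splitting the 16S into a
5' and a 3' product whose sizes report where the oligo bound.  The degree
of cleavage across strains measures how accessible the targeted region
(e.g. the central pseudoknot, 16S positions 906-920) is in accumulated
assembly intermediates.  Gel band volumes are background-corrected with a
mock (no-oligo) lane and reduced to a fraction cleaved per replicate.

All rRNA coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "DEFAULT_16S_LENGTH",
    "OligoTarget",
    "FragmentSizes",
    "CleavageResult",
    "TargetIntervalError",
    "expected_products",
    "antisense_match",
    "fraction_cleaved",
    "ANTI_PK",
    "ANTI_H21",
]

DEFAULT_16S_LENGTH = 1542  # mature E. coli 16S rRNA


class TargetIntervalError(ValueError):
    """Oligo target interval inconsistent with the rRNA sequence."""


@dataclass(frozen=True)
class OligoTarget:
    """A DNA oligo and the 1-based inclusive rRNA interval it anneals to."""

    name: str
    start: int
    end: int
    sequence: str  # DNA, 5'->3'

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise TargetIntervalError(f"{self.name}: invalid interval ({self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start + 1:
            raise TargetIntervalError(
                f"{self.name}: oligo length {len(self.sequence)} != interval "
                f"length {self.end - self.start + 1}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


# The two assay oligos: anti-PK probes the central pseudoknot (h2/h27
# region); anti-h21 targets a buried helix as a negative control.
ANTI_PK = OligoTarget("anti-PK", 906, 920, "ATTCATTTGAGTTTT")
ANTI_H21 = OligoTarget("anti-h21", 589, 603, "ATCTGACTTAACAAA")


@dataclass(frozen=True)
class FragmentSizes:
    """Expected cleavage-product lengths for one oligo target.

    Nominal sizes assume complete excision of the DNA:RNA hybrid; the
    ranges cover a single cut anywhere within the hybrid.
    """

    nominal_5p: int
    nominal_3p: int
    range_5p: tuple[int, int]
    range_3p: tuple[int, int]


def expected_products(target: OligoTarget, rna_length: int = DEFAULT_16S_LENGTH) -> FragmentSizes:
    """Product sizes from RNase H cleavage directed by ``target``.

    Complete excision of the hybrid leaves a 5' product of ``start - 1`` nt
    and a 3' product of ``rna_length - end`` nt.  A single cut at any
    position within the hybrid instead yields a 5' product in
    ``[start - 1, end - 1]`` and a 3' product in
    ``[rna_length - end, rna_length - start]``.
    """
    if target.end > rna_length:
        raise TargetIntervalError(
            f"{target.name}: interval ({target.start}, {target.end}) exceeds "
            f"rRNA length {rna_length}"
        )
    return FragmentSizes(
        nominal_5p=target.start - 1,
        nominal_3p=rna_length - target.end,
        range_5p=(target.start - 1, target.end - 1),
        range_3p=(rna_length - target.end, rna_length - target.start),
    )


def antisense_match(target: OligoTarget, rna_sequence: str) -> int:
    """Mismatches between the oligo's reverse complement and its target site.

    The DNA oligo is reverse-complemented and transcribed (T -> U), then
    compared position-by-position with ``rna_sequence[start-1:end]``.
    Zero means the oligo is perfectly antisense to its site.
    """
    rna = rna_sequence.strip().upper().replace("T", "U")
    if len(rna) < target.end:
        raise TargetIntervalError(
            f"rna_sequence (length {len(rna)}) does not cover interval end {target.end}"
        )
    site = rna[target.start - 1 : target.end]
    expected = str(Seq(target.sequence.upper()).reverse_complement_rna())
    if len(expected) != len(site):
        raise TargetIntervalError("oligo length does not match interval length")
    return sum(a != b for a, b in zip(expected, site))


@dataclass(frozen=True)
class CleavageResult:
    """Background-subtracted fraction cleaved for one strain."""

    strain_id: str
    fractions: tuple[float, ...]
    mean: float
    sd: float
    missing_reason: str | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.fractions)


def _one_lane(intact: float, products: float, mock_products: float) -> float | None:
    if min(intact, products, mock_products) < 0:
        raise ValueError("band intensities must be >= 0")
    corrected = max(products - mock_products, 0.0)
    total = corrected + intact
    if total == 0:
        return None
    return corrected / total


def fraction_cleaved(
    replicates: list[dict[str, float]],
    strain_id: str = "",
) -> CleavageResult:
    """Mean and standard deviation of background-corrected fraction cleaved.

    Each replicate is a dict with keys ``intact``, ``products`` and
    ``mock_products`` (band volumes of the cleavage reaction and the
    mock/no-oligo control).  Per lane:

        corrected = max(products - mock_products, 0)
        fraction  = corrected / (corrected + intact)

    The standard deviation is the sample SD (ddof=1); lanes with zero
    total signal are dropped, and a result with no usable lane carries a
    ``missing_reason`` instead of numbers.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    vals: list[float] = []
    for rep in replicates:
        f = _one_lane(rep["intact"], rep["products"], rep.get("mock_products", 0.0))
        if f is not None:
            vals.append(f)
    if not vals:
        return CleavageResult(
            strain_id=strain_id, fractions=(), mean=float("nan"), sd=float("nan"),
            missing_reason="no lane with nonzero corrected signal",
        )
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CleavageResult(
        strain_id=strain_id,
        fractions=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        sd=sd,
    )
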