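"""Species-amplitude fitting and reference-normalized protein abundance matrices.

Each peptide in a labeling experiment appears as up to three co-eluting
isotope envelopes: material synthesized pre-pulse (natural 14N), material
synthesized post-pulse (fractionally 15N-enriched), and the fully
15N-labeled reference spike added in equimolar amount to every sample.
The amplitudes of the three species are recovered by non-negative least
squares against the theoretical envelope designs; peptide-level ratios of
those amplitudes are rolled up per protein (median) and normalized to a
reference protein (the primary binder S4 in the original experiments) per
sucrose-gradient fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .isotope import (
    NATURAL_N15_ABUNDANCE,
    Envelope,
    elemental_composition,
    isotope_distribution,
    tryptic_digest,
)

__all__ = [
    "PeptideDesign",
    "species_envelopes",
    "build_designs",
    "quantify_peaklists",
    "PeakList",
    "EnvelopeMixtureModel",
    "EnvelopeFitResult",
    "RatioMode",
    "MissingValue",
    "fit_envelope_amplitudes",
    "peptide_ratio",
    "AbundanceMatrix",
    "protein_abundance_matrix",
    "DEFAULT_MZ_WINDOW",
    "DEFAULT_MZ_TOL_PPM",
    "DEFAULT_SNR_MIN",
]

DEFAULT_MZ_WINDOW = (250.0, 1300.0)
DEFAULT_MZ_TOL_PPM = 15.0
DEFAULT_SNR_MIN = 5.0

SPECIES = ("pre", "post", "ref")


@dataclass
class PeakList:
    """Centroided peaks of one sample (sucrose-gradient fraction)."""

    fraction_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def windowed(self, lo: float, hi: float) -> "PeakList":
        keep = (self.mz >= lo) & (self.mz <= hi)
        return PeakList(self.fraction_id, self.mz[keep], self.intensity[keep])


@dataclass(frozen=True)
class EnvelopeFitResult:
    """Fitted species amplitudes for one peptide/charge.

    ``snr`` is (largest amplitude x that species' envelope maximum
    intensity) / residual RMS; infinite for a perfect fit, zero when no
    species is present.
    """

    peptide_id: str
    charge: int
    a_pre: float
    a_post: float
    a_ref: float
    residual_rms: float
    snr: float
    overlap_collapsed: bool = False
    n_matched_peaks: int = 0

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.a_pre, self.a_post, self.a_ref)


class EnvelopeMixtureModel:
    """Non-negative linear mixture of three envelope designs fitted to a peak list.

    Design peaks of the three species are merged into shared m/z columns
    when closer than the ppm tolerance (flagged, since the species then
    share signal); observed peaks are matched to the nearest column within
    tolerance, and design columns with no observed match count as observed
    zero.  ``fit()`` solves the NNLS problem and returns an
    :class:`EnvelopeFitResult`.
    """

    def __init__(
        self,
        peaklist: PeakList,
        envelopes: dict[str, Envelope],
        mz_tolerance_ppm: float = DEFAULT_MZ_TOL_PPM,
        mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    ) -> None:
        if set(envelopes) != set(SPECIES):
            raise ValueError(f"envelopes must be keyed by {SPECIES}")
        charges = {env.charge for env in envelopes.values()}
        pids = {env.peptide_id for env in envelopes.values()}
        if len(charges) != 1 or len(pids) != 1:
            raise ValueError("the three envelopes must share peptide id and charge")
        if mz_tolerance_ppm <= 0:
            raise ValueError("mz tolerance must be positive")
        self.peaklist = peaklist.windowed(*mz_window)
        self.envelopes = envelopes
        self.tol_ppm = mz_tolerance_ppm
        self.peptide_id = pids.pop()
        self.charge = charges.pop()
        self._build_design()

    def _build_design(self) -> None:
        # pool all design peaks, then cluster into columns by ppm proximity
        mzs, species_idx, inten = [], [], []
        for s_i, sp in enumerate(SPECIES):
            env = self.envelopes[sp]
            mzs.extend(env.mz.tolist())
            inten.extend(env.intensity.tolist())
            species_idx.extend([s_i] * len(env))
        mzs = np.asarray(mzs)
        inten = np.asarray(inten)
        species_idx = np.asarray(species_idx)
        order = np.argsort(mzs)
        mzs, inten, species_idx = mzs[order], inten[order], species_idx[order]

        columns: list[list[int]] = []
        for i in range(len(mzs)):
            if columns and (mzs[i] - mzs[columns[-1][0]]) <= self._tol(mzs[i]):
                columns[-1].append(i)
            else:
                columns.append([i])

        n_cols = len(columns)
        design = np.zeros((n_cols, 3))
        col_mz = np.zeros(n_cols)
        collapsed = False
        for c, members in enumerate(columns):
            col_mz[c] = float(np.mean(mzs[members]))
            present = set()
            for m in members:
                design[c, species_idx[m]] += inten[m]
                present.add(species_idx[m])
            if len(present) > 1:
                collapsed = True
        self.design_ = design
        self.column_mz_ = col_mz
        self.overlap_collapsed_ = collapsed

    def _tol(self, mz: float) -> float:
        return mz * self.tol_ppm * 1e-6

    def _observed_vector(self) -> tuple[np.ndarray, int]:
        y = np.zeros(len(self.column_mz_))
        n_matched = 0
        if len(self.peaklist) == 0:
            return y, 0
        for mz, intensity in zip(self.peaklist.mz, self.peaklist.intensity):
            diffs = np.abs(self.column_mz_ - mz)
            c = int(np.argmin(diffs))
            if diffs[c] <= self._tol(mz):
                y[c] += intensity
                n_matched += 1
        return y, n_matched

    def fit(self) -> EnvelopeFitResult:
        y, n_matched = self._observed_vector()
        if n_matched == 0:
            return EnvelopeFitResult(
                self.peptide_id, self.charge, 0.0, 0.0, 0.0,
                residual_rms=0.0, snr=0.0,
                overlap_collapsed=self.overlap_collapsed_, n_matched_peaks=0,
            )
        amps, rnorm = nnls(self.design_, y)
        residual_rms = float(rnorm / np.sqrt(len(y)))
        peak_heights = [
            amps[i] * self.envelopes[sp].max_intensity for i, sp in enumerate(SPECIES)
        ]
        top = max(peak_heights)
        if top == 0.0:
            snr = 0.0
        elif residual_rms == 0.0:
            snr = float("inf")
        else:
            snr = top / residual_rms
        return EnvelopeFitResult(
            self.peptide_id, self.charge,
            float(amps[0]), float(amps[1]), float(amps[2]),
            residual_rms=residual_rms, snr=snr,
            overlap_collapsed=self.overlap_collapsed_, n_matched_peaks=n_matched,
        )


def fit_envelope_amplitudes(
    peaklist: PeakList,
    envelopes: dict[str, Envelope],
    mz_tolerance_ppm: float = DEFAULT_MZ_TOL_PPM,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
) -> EnvelopeFitResult:
    """Convenience wrapper: build an :class:`EnvelopeMixtureModel` and fit it."""
    return EnvelopeMixtureModel(peaklist, envelopes, mz_tolerance_ppm, mz_window).fit()


def species_envelopes(
    peptide: str,
    charge: int,
    e_pre: float = NATURAL_N15_ABUNDANCE,
    e_post: float = 0.5,
    e_ref: float = 1.0,
    truncation: float = 1e-4,
    peptide_id: str | None = None,
) -> dict[str, Envelope]:
    """Theoretical envelopes of the three labeling species of one peptide.

    ``pre`` is material made before the pulse (natural nitrogen), ``post``
    is material made in the fractionally enriched media, ``ref`` is the
    fully 15N-labeled reference spike.
    """
    comp = elemental_composition(peptide)
    pid = peptide_id if peptide_id is not None else f"{peptide}/{charge}"
    return {
        "pre": isotope_distribution(comp, e_pre, charge, truncation, peptide_id=pid),
        "post": isotope_distribution(comp, e_post, charge, truncation, peptide_id=pid),
        "ref": isotope_distribution(comp, e_ref, charge, truncation, peptide_id=pid),
    }


@dataclass(frozen=True)
class PeptideDesign:
    """One peptide/charge of one protein with its three species envelopes."""

    protein: str
    peptide: str
    charge: int
    envelopes: dict[str, Envelope]

    @property
    def peptide_id(self) -> str:
        return f"{self.protein}:{self.peptide}/{self.charge}"


def build_designs(
    proteome: dict[str, str],
    charges: tuple[int, ...] = (1, 2),
    e_post: float = 0.5,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    min_length: int = 6,
    max_peptides_per_protein: int = 4,
    truncation: float = 1e-4,
) -> list[PeptideDesign]:
    """In-silico digest each protein and keep peptide/charge pairs whose
    envelopes fall entirely inside the detection window."""
    designs: list[PeptideDesign] = []
    for protein, seq in proteome.items():
        kept = 0
        for pep in tryptic_digest(seq, missed_cleavages=0):
            if len(pep) < min_length:
                continue
            if kept >= max_peptides_per_protein:
                break
            for z in charges:
                envs = species_envelopes(
                    pep, z, e_post=e_post, truncation=truncation,
                    peptide_id=f"{protein}:{pep}/{z}",
                )
                lo = min(e.mz.min() for e in envs.values())
                hi = max(e.mz.max() for e in envs.values())
                if lo >= mz_window[0] and hi <= mz_window[1]:
                    designs.append(PeptideDesign(protein, pep, z, envs))
                    kept += 1
                    break
    return designs


def quantify_peaklists(
    peaklists: list[PeakList],
    designs: list[PeptideDesign],
    mode: "RatioMode | str" = "relative_abundance",
    mz_tolerance_ppm: float = DEFAULT_MZ_TOL_PPM,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
) -> pd.DataFrame:
    """Fit every design against every fraction's peak list.

    Returns the long-format peptide ratio table consumed by
    :func:`protein_abundance_matrix` (columns protein, fraction, peptide,
    charge, ratio, snr); undefined ratios appear as NaN.
    """
    rows = []
    for pl in peaklists:
        for d in designs:
            fit = fit_envelope_amplitudes(pl, d.envelopes, mz_tolerance_ppm, mz_window)
            r = peptide_ratio(fit, mode)
            rows.append(
                {
                    "protein": d.protein,
                    "fraction": pl.fraction_id,
                    "peptide": d.peptide,
                    "charge": d.charge,
                    "ratio": r if not isinstance(r, MissingValue) else np.nan,
                    "snr": fit.snr,
                }
            )
    return pd.DataFrame(rows)


class RatioMode(str, Enum):
    """Which pair of species amplitudes forms the reported fraction.

    relative_abundance
        14N experimental vs 15N reference spike: ``a_pre / (a_pre + a_ref)``.
    fraction_labeled
        post-pulse vs total newly+previously synthesized:
        ``a_post / (a_pre + a_post)``.
    strain_ratio
        50% 15N experimental strain vs 100% 15N reference:
        ``a_post / (a_post + a_ref)``.
    """

    relative_abundance = "relative_abundance"
    fraction_labeled = "fraction_labeled"
    strain_ratio = "strain_ratio"


@dataclass(frozen=True)
class MissingValue:
    """Sentinel for an undefined ratio, carrying the reason."""

    reason: str

    def __bool__(self) -> bool:  # missing is falsy
        return False


_RATIO_PAIRS = {
    RatioMode.relative_abundance: ("a_pre", "a_ref"),
    RatioMode.fraction_labeled: ("a_post", "a_pre"),
    RatioMode.strain_ratio: ("a_post", "a_ref"),
}


def peptide_ratio(
    fit: EnvelopeFitResult, mode: RatioMode | str
) -> float | MissingValue:
    """Fraction ``num / (num + other)`` of the species pair selected by ``mode``.

    Returns a :class:`MissingValue` when both amplitudes in the pair are zero.
    """
    mode = RatioMode(mode)
    num_name, other_name = _RATIO_PAIRS[mode]
    num = getattr(fit, num_name)
    other = getattr(fit, other_name)
    denom = num + other
    if denom == 0:
        return MissingValue(reason=f"zero denominator for {mode.value}")
    return float(num / denom)


@dataclass
class AbundanceMatrix:
    """Protein x fraction relative abundances, reference-normalized.

    ``values`` holds NaN where no peptide survived filtering ("gray box"
    entries); ``n_peptides`` and ``mad`` carry the per-cell rollup
    diagnostics; ``unnormalizable_fractions`` lists columns where the
    reference protein itself was missing.
    """

    values: pd.DataFrame
    n_peptides: pd.DataFrame
    mad: pd.DataFrame
    reference_protein: str
    unnormalizable_fractions: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def fractions(self) -> list[str]:
        return list(self.values.columns)

    def is_missing(self, protein: str, fraction: str) -> bool:
        return bool(pd.isna(self.values.loc[protein, fraction]))


def protein_abundance_matrix(
    peptide_ratios: pd.DataFrame,
    snr_min: float = DEFAULT_SNR_MIN,
    reference_protein: str = "S4",
    exclude_proteins: set[str] | frozenset[str] = frozenset(),
) -> AbundanceMatrix:
    """Roll peptide-level ratios up to a reference-normalized protein matrix.

    Parameters
    ----------
    peptide_ratios
        Long-format table with columns ``protein``, ``fraction``, ``ratio``,
        ``snr``.  Rows with ``snr < snr_min`` or NaN ratios are discarded.
    reference_protein
        Each fraction's column is divided by this protein's value; fractions
        where it is missing are flagged unnormalizable (left NaN).
    exclude_proteins
        Proteins whose isotope fits are known-poor (the original analysis
        excluded S17 this way); dropped before rollup.

    The per-cell statistic is the median of surviving peptide ratios, with
    the count and the median absolute deviation retained as diagnostics.
    """
    required = {"protein", "fraction", "ratio", "snr"}
    if not required.issubset(peptide_ratios.columns):
        raise ValueError(f"peptide_ratios needs columns {sorted(required)}")
    df = peptide_ratios.copy()
    df = df[~df["protein"].isin(exclude_proteins)]
    proteins = sorted(df["protein"].unique())
    fractions = sorted(df["fraction"].unique())
    df = df[df["snr"] >= snr_min].dropna(subset=["ratio"])

    grouped = df.groupby(["protein", "fraction"])["ratio"]
    med = grouped.median()
    count = grouped.size()
    madev = grouped.apply(lambda s: float((s - s.median()).abs().median()))

    values = pd.DataFrame(np.nan, index=proteins, columns=fractions)
    n_pep = pd.DataFrame(0, index=proteins, columns=fractions, dtype=int)
    mad = pd.DataFrame(np.nan, index=proteins, columns=fractions)
    for (prot, frac), v in med.items():
        values.loc[prot, frac] = v
        n_pep.loc[prot, frac] = int(count.loc[(prot, frac)])
        mad.loc[prot, frac] = madev.loc[(prot, frac)]

    unnormalizable: list[str] = []
    for frac in fractions:
        ref = values.loc[reference_protein, frac] if reference_protein in values.index else np.nan
        if pd.isna(ref) or ref == 0:
            unnormalizable.append(frac)
            values[frac] = np.nan
        else:
            values[frac] = values[frac] / ref
    return AbundanceMatrix(
        values=values,
        n_peptides=n_pep,
        mad=mad,
        reference_protein=reference_protein,
        unnormalizable_fractions=unnormalizable,
    )
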