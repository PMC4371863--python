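"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of a 30S-assembly
quantitative-MS study without any raw data: three-envelope peptide spectra
across sucrose-gradient fractions, r-protein occupancy profiles tiered by
Nomura binding order, pulse-labeling time courses, RNase H gel lanes with
background cleavage, and noisy class-average image stacks.  Every
generator is a pure function of its parameters and a seed, and every
generator also returns a machine-readable truth table so downstream
recovery can be asserted without re-deriving the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .isotope import NATURAL_N15_ABUNDANCE
from .kinetics import DEFAULT_GROWTH_RATE, TimeCourse, f_l_model
from .quantitation import (
    DEFAULT_MZ_WINDOW,
    PeakList,
    PeptideDesign,
    build_designs,
)

__all__ = [
    "BINDING_CLASSES",
    "NOMURA_CLASS",
    "AssemblyTruth",
    "default_assembly_truth",
    "default_proteome",
    "simulate_proteome_spectra",
    "simulate_timecourses",
    "simulate_gel_lanes",
    "simulate_class_averages",
    "default_class_templates",
    "ImageStack",
]

BINDING_CLASSES = ("primary", "secondary", "tertiary-early", "tertiary-late")

# Binding-dependency tiers of the 20 small-subunit r-proteins (Nomura map),
# with the tertiary tier split by assembly timing.
NOMURA_CLASS: dict[str, str] = {
    **{p: "primary" for p in ("S4", "S7", "S8", "S15", "S17", "S20")},
    **{p: "secondary" for p in ("S5", "S6", "S9", "S11", "S12", "S13", "S16", "S18", "S19")},
    **{p: "tertiary-early" for p in ("S3", "S10", "S14")},
    **{p: "tertiary-late" for p in ("S2", "S21")},
}

# logistic-onset midpoints (fraction index) per class: earlier binders
# reach full occupancy in earlier gradient fractions
_CLASS_MIDPOINT = {
    "primary": 1.0,
    "secondary": 3.0,
    "tertiary-early": 5.0,
    "tertiary-late": 7.0,
}
_ONSET_WIDTH = 0.7

# default true precursor pool sizes per class: abundant early binders carry
# large pools (S4-like, 12%), depleted late binders have essentially none
_CLASS_POOL = {
    "primary": 0.12,
    "secondary": 0.06,
    "tertiary-early": 0.02,
    "tertiary-late": 0.005,
}


@dataclass
class AssemblyTruth:
    """Ground truth of a synthetic assembly-intermediate experiment."""

    binding_class: dict[str, str]
    abundance: pd.DataFrame  # protein x fraction, values in [0, 1]
    pool_size: dict[str, float]

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def fractions(self) -> list[str]:
        return list(self.abundance.columns)

    def expected_ratio_matrix(
        self, reference_protein: str = "S4", reference_amplitude: float = 1.0
    ) -> pd.DataFrame:
        """The reference-normalized matrix the quantitation pipeline reports.

        With an equimolar 15N spike of amplitude ``a_ref``, a protein of
        molar abundance ``a`` measures as the compressed ratio
        ``a / (a + a_ref)``; the pipeline then divides by the reference
        protein's ratio per fraction.  This is the truth to compare
        pipeline output against.
        """
        r = self.abundance / (self.abundance + reference_amplitude)
        return r.div(r.loc[reference_protein], axis=1)

    def as_table(self, reference_protein: str = "S4") -> pd.DataFrame:
        """Long-format truth table (protein, class, pool size, per-fraction
        molar abundance and expected pipeline readouts)."""
        expected = self.expected_ratio_matrix(reference_protein)
        rows = []
        for prot in self.proteins:
            for frac in self.fractions:
                a = self.abundance.loc[prot, frac]
                rows.append(
                    {
                        "protein": prot,
                        "binding_class": self.binding_class[prot],
                        "pool_size": self.pool_size[prot],
                        "fraction": frac,
                        "abundance": a,
                        "expected_ratio": a / (a + 1.0),
                        "expected_normalized": expected.loc[prot, frac],
                    }
                )
        return pd.DataFrame(rows)


def default_assembly_truth(n_fractions: int = 10) -> AssemblyTruth:
    """Occupancy truth with logistic onsets ordered by binding class.

    abundance(protein, fraction f) = 1 / (1 + exp(-(f - mu_class) / w))
    with midpoints mu ordered primary < secondary < tertiary-early <
    tertiary-late, reproducing the tiered occupancy structure of early
    gradient fractions.  The reference protein S4 (primary) is present
    everywhere.
    """
    proteins = sorted(NOMURA_CLASS, key=lambda p: int(p[1:]))
    fractions = [f"F{i + 1}" for i in range(n_fractions)]
    f_idx = np.arange(n_fractions, dtype=float)
    values = {}
    for prot in proteins:
        mu = _CLASS_MIDPOINT[NOMURA_CLASS[prot]]
        values[prot] = 1.0 / (1.0 + np.exp(-(f_idx - mu) / _ONSET_WIDTH))
    abundance = pd.DataFrame(values, index=fractions).T
    pool = {p: _CLASS_POOL[NOMURA_CLASS[p]] for p in proteins}
    return AssemblyTruth(binding_class=dict(NOMURA_CLASS), abundance=abundance, pool_size=pool)


# ---------------------------------------------------------------------------
# toy proteome

_INTERIOR_AA = "ACDEFGHILMNQSTVWY"  # no K/R (cleavage sites) and no P


def _random_tryptic_peptide(
    rng: np.random.Generator, mz_lo: float, mz_hi: float, max_attempts: int = 5000
) -> str:
    """A random fully tryptic peptide whose singly protonated monoisotopic
    m/z falls in [mz_lo, mz_hi], with a bounded nitrogen count so the fully
    15N-labeled envelope stays close to its slot."""
    from .isotope import PROTON_MASS, elemental_composition

    from .isotope import _ISOTOPES  # residue-mass ordering helper below

    def mz1(pep: str) -> float:
        return elemental_composition(pep).monoisotopic_mass() + PROTON_MASS

    by_mass = sorted(_INTERIOR_AA, key=lambda aa: mz1(aa))
    target = 0.5 * (mz_lo + mz_hi)
    for _ in range(max_attempts):
        length = max(6, min(10, int(round((target - 150.0) / 115.0)) + 1))
        body = list(rng.choice(list(_INTERIOR_AA), size=length - 1))
        tail = str(rng.choice(["K", "R"]))
        # repair: swap single residues lighter/heavier until m/z enters the slot
        for _ in range(200):
            pep = "".join(body) + tail
            m = mz1(pep)
            if mz_lo <= m <= mz_hi:
                if elemental_composition(pep).N <= 14:
                    return pep
                break
            i = int(rng.integers(len(body)))
            cur = by_mass.index(body[i])
            if m < mz_lo and cur < len(by_mass) - 1:
                body[i] = by_mass[int(rng.integers(cur + 1, len(by_mass)))]
            elif m > mz_hi and cur > 0:
                body[i] = by_mass[int(rng.integers(0, cur))]
    raise RuntimeError(f"no tryptic peptide found for m/z slot [{mz_lo}, {mz_hi}]")


def _short_flank(rng: np.random.Generator) -> str:
    # below the min design length, so it never enters the fit designs
    body = "".join(rng.choice(list(_INTERIOR_AA), size=int(rng.integers(2, 5))))
    return body + str(rng.choice(["K", "R"]))


def _has_cross_peptide_collision(designs: list[PeptideDesign], tol_ppm: float) -> bool:
    mzs, pids = [], []
    for d in designs:
        for env in d.envelopes.values():
            mzs.extend(env.mz.tolist())
            pids.extend([d.peptide_id] * len(env))
    order = np.argsort(mzs)
    mzs_arr = np.asarray(mzs)[order]
    pids_arr = np.asarray(pids)[order]
    gaps = np.diff(mzs_arr)
    tol = 2.0 * mzs_arr[1:] * tol_ppm * 1e-6
    close = gaps <= tol
    return bool(np.any(close & (pids_arr[1:] != pids_arr[:-1])))


@lru_cache(maxsize=4)
def default_proteome(n_proteins: int = 20, tol_ppm: float = 15.0) -> dict[str, str]:
    """Deterministic toy proteome of short synthetic sequences named S2..S21.

    These are toy sequences, not real r-protein sequences.  Each protein
    carries one quantifiable tryptic peptide (flanked by sub-design-length
    fragments) whose isotope envelopes occupy a private ~38 Th slot of the
    detection window, so that per-peptide amplitude fits against a combined
    fraction spectrum are free of cross-peptide interference — standing in
    for the chromatographic separation that is not modeled.  Construction
    is pure (fixed internal seed) and verified collision-free at twice the
    matching tolerance.
    """
    names = [f"S{i}" for i in range(2, 2 + n_proteins)]
    rng = np.random.default_rng(778491)
    slot_width = (1260.0 - 520.0) / max(n_proteins - 1, 1)
    proteome: dict[str, str] = {}
    for i, name in enumerate(names):
        lo = 520.0 + i * slot_width
        pep = _random_tryptic_peptide(rng, lo, lo + 10.0)
        proteome[name] = _short_flank(rng) + pep + _short_flank(rng)
    designs = build_designs(proteome, charges=(1, 2))
    if {d.protein for d in designs} != set(names):
        raise RuntimeError("toy proteome construction lost a protein design")
    if _has_cross_peptide_collision(designs, tol_ppm):
        raise RuntimeError("toy proteome construction produced colliding designs")
    return proteome


# ---------------------------------------------------------------------------
# spectra

def simulate_proteome_spectra(
    truth: AssemblyTruth,
    proteome: dict[str, str] | None = None,
    e_post: float = 0.5,
    post_amplitude: float | dict[str, float] = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    charges: tuple[int, ...] = (1, 2),
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
) -> tuple[list[PeakList], list[PeptideDesign], pd.DataFrame]:
    """Three-envelope peptide spectra for every gradient fraction.

    Per protein and fraction the species amplitudes are (true abundance,
    ``post_amplitude``, 1.0): the reference spike is equimolar everywhere.
    Gaussian noise of ``noise_sigma`` times the fraction's maximum peak
    intensity is added to every peak (clipped at zero) and peaks outside
    the detection window are dropped.  Returns the peak lists, the peptide
    designs used, and the long-format truth table.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if proteome is None:
        proteome = default_proteome()
    designs = build_designs(proteome, charges=charges, e_post=e_post, mz_window=mz_window)
    rng = np.random.default_rng(seed)
    peaklists: list[PeakList] = []
    for frac in truth.fractions:
        mzs: list[float] = []
        intens: list[float] = []
        for d in designs:
            a_pre = float(truth.abundance.loc[d.protein, frac])
            a_post = (
                post_amplitude.get(d.protein, 0.0)
                if isinstance(post_amplitude, dict)
                else post_amplitude
            )
            for sp, amp in (("pre", a_pre), ("post", a_post), ("ref", 1.0)):
                if amp == 0.0:
                    continue
                env = d.envelopes[sp]
                mzs.extend(env.mz.tolist())
                intens.extend((amp * env.intensity).tolist())
        mz_arr = np.asarray(mzs)
        int_arr = np.asarray(intens)
        keep = (mz_arr >= mz_window[0]) & (mz_arr <= mz_window[1])
        mz_arr, int_arr = mz_arr[keep], int_arr[keep]
        if noise_sigma > 0 and len(int_arr):
            int_arr = int_arr + rng.normal(0.0, noise_sigma * int_arr.max(), size=len(int_arr))
            int_arr = np.clip(int_arr, 0.0, None)
        peaklists.append(PeakList(frac, mz_arr, int_arr))
    return peaklists, designs, truth.as_table()


# ---------------------------------------------------------------------------
# time courses

DEFAULT_PULSE_TIMES = (15.0, 20.0, 30.0, 45.0)  # minutes


def simulate_timecourses(
    pool_sizes: dict[str, float],
    k: float = DEFAULT_GROWTH_RATE,
    times: tuple[float, ...] = DEFAULT_PULSE_TIMES,
    noise_sigma: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[list[TimeCourse], pd.DataFrame]:
    """Fraction-labeled time courses drawn around the pool-dilution curve.

    fL is the model value plus N(0, sigma^2) noise, clipped to [0, 1].
    Returns one TimeCourse per (protein, replicate) and a truth table.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if any(t <= 0 for t in times):
        raise ValueError("pulse times must be positive")
    rng = np.random.default_rng(seed)
    t_arr = np.asarray(times, dtype=float)
    courses: list[TimeCourse] = []
    truth_rows = []
    for protein, P in pool_sizes.items():
        clean = f_l_model(t_arr, P, k)
        truth_rows.append({"protein": protein, "P": P, "k": k})
        for rep in range(n_replicates):
            noisy = clean + rng.normal(0.0, noise_sigma, size=len(t_arr)) if noise_sigma else clean
            noisy = np.clip(noisy, 0.0, 1.0)
            pid = protein if n_replicates == 1 else f"{protein}#r{rep + 1}"
            courses.append(TimeCourse(pid, t_arr.copy(), noisy, k=k))
    return courses, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# gel lanes

def simulate_gel_lanes(
    true_fractions: dict[str, float],
    background: float = 0.05,
    noise_sigma: float = 0.0,
    n_replicates: int = 3,
    total_intensity: float = 1000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gel band intensities whose corrected fraction cleaved matches truth.

    Each replicate lane carries ``intact = (1 - f) * T`` and
    ``products = (f + background) * T``; the mock (no-oligo) lane carries
    ``mock_products = background * T``.  Gaussian noise of
    ``noise_sigma * T`` is added per band and clipped at zero.  Returns the
    long-format lane table (strain, replicate, band, intensity) and the
    truth table.
    """
    if not all(0.0 <= f <= 1.0 for f in true_fractions.values()):
        raise ValueError("true fractions must lie in [0, 1]")
    if noise_sigma < 0 or background < 0:
        raise ValueError("noise and background must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for strain, f_true in true_fractions.items():
        for rep in range(1, n_replicates + 1):
            bands = {
                "intact": (1.0 - f_true) * total_intensity,
                "products": (f_true + background) * total_intensity,
                "mock_products": background * total_intensity,
            }
            for band, value in bands.items():
                if noise_sigma:
                    value += rng.normal(0.0, noise_sigma * total_intensity)
                rows.append(
                    {
                        "strain": strain,
                        "replicate": rep,
                        "band": band,
                        "intensity": max(value, 0.0),
                    }
                )
    lanes = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [{"strain": s, "fraction_cleaved": f} for s, f in true_fractions.items()]
    )
    return lanes, truth


# ---------------------------------------------------------------------------
# class averages

@dataclass
class ImageStack:
    """A stack of equal-shape grayscale images with per-image metadata."""

    images: np.ndarray  # (n, h, w)
    labels: list[str]
    dataset_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be an (n, h, w) array")
        if len(self.labels) != len(self.images):
            raise ValueError("labels must match image count")

    def __len__(self) -> int:
        return len(self.images)

    def flattened(self) -> np.ndarray:
        return self.images.reshape(len(self), -1)


def _disc(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).astype(float)


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0).astype(float)


def default_class_templates(size: int = 32) -> dict[str, np.ndarray]:
    """Five assembly-state archetypes (max intensity 1) on a ``size`` grid:
    body only, detached head, angled head, near-mature, and mature
    (body + docked head + beak)."""
    h = w = size
    body = _ellipse(h, w, 0.68 * h, 0.50 * w, 0.26 * h, 0.38 * w)
    head_detached = _disc(h, w, 0.18 * h, 0.50 * w, 0.13 * h)
    head_angled = _disc(h, w, 0.26 * h, 0.72 * w, 0.14 * h)
    head_docked = _disc(h, w, 0.33 * h, 0.50 * w, 0.15 * h)
    beak = _ellipse(h, w, 0.30 * h, 0.24 * w, 0.07 * h, 0.12 * w)
    templates = {
        "body-only": body,
        "detached-head": body + head_detached,
        "angled-head": body + head_angled,
        "near-mature": body + head_docked,
        "mature": body + head_docked + beak,
    }
    return {name: np.clip(img, 0.0, 1.0) for name, img in templates.items()}


def simulate_class_averages(
    counts: dict[str, dict[str, int]],
    templates: dict[str, np.ndarray] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Noisy copies of group archetype images with truth labels.

    ``counts`` maps dataset id -> {template name: image count}.  Each image
    is its template plus i.i.d. pixel Gaussian noise of ``noise_sigma``
    (templates have max intensity 1, so sigma is relative to signal).
    Returns the stack and a truth table (image index, dataset, template).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if templates is None:
        templates = default_class_templates()
    shapes = {t.shape for t in templates.values()}
    if len(shapes) != 1:
        raise ValueError("all templates must share one shape")
    rng = np.random.default_rng(seed)
    images, labels, ds_ids, rows = [], [], [], []
    idx = 0
    for dataset in sorted(counts):
        for tmpl_name in sorted(counts[dataset]):
            if tmpl_name not in templates:
                raise KeyError(f"unknown template {tmpl_name!r}")
            for _ in range(counts[dataset][tmpl_name]):
                img = templates[tmpl_name]
                if noise_sigma:
                    img = img + rng.normal(0.0, noise_sigma, size=img.shape)
                images.append(img)
                labels.append(tmpl_name)
                ds_ids.append(dataset)
                rows.append({"index": idx, "dataset": dataset, "template": tmpl_name})
                idx += 1
    stack = ImageStack(np.stack(images), labels, ds_ids)
    return stack, pd.DataFrame(rows)
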