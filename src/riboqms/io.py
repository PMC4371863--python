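"""Configuration, format readers/writers, and small lab-math utilities.

File conventions
----------------
* All tabular formats are plain TSV/CSV with a header row; writers prepend
  comment lines (``# riboqms <version>``, ``# config_hash=<sha1>``) naming
  the tool version and the configuration that produced the file.
* Sequence coordinates in every interval are 1-based inclusive, matching
  the convention of rRNA position numbering (e.g. "positions 906-920").
* Image stacks use a versioned on-disk layout: a directory holding
  ``header.json`` (format version, shape, dtype) and ``data.npy``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .isotope import NATURAL_N15_ABUNDANCE
from .kinetics import DEFAULT_GROWTH_RATE, TimeCourse
from .quantitation import (
    DEFAULT_MZ_TOL_PPM,
    DEFAULT_MZ_WINDOW,
    DEFAULT_SNR_MIN,
    AbundanceMatrix,
    PeakList,
)
from .synthetic import ImageStack

__all__ = [
    "RunConfig",
    "ConfigError",
    "beer_lambert_concentration",
    "read_fasta",
    "read_peaklists",
    "write_peaklists",
    "read_timecourses",
    "write_timecourses",
    "read_lane_table",
    "write_abundance_matrix",
    "read_abundance_matrix",
    "write_table",
    "read_table",
    "write_image_stack",
    "read_image_stack",
]

try:
    __version__ = metadata.version("riboqms")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "0.0.0"


class ConfigError(ValueError):
    """Configuration failed validation."""


@dataclass
class RunConfig:
    """Validated run parameters shared by all pipeline stages.

    enrichment_post
        15N fraction of the post-pulse / experimental-strain species
        (growth in 50% 15N media -> 0.5 by default; true incorporation is
        configurable).
    growth_rate_k
        Culture growth rate in min^-1 (default: 60-min doubling time).
    """

    enrichment_post: float = 0.5
    mz_tolerance_ppm: float = DEFAULT_MZ_TOL_PPM
    mz_window_lo: float = DEFAULT_MZ_WINDOW[0]
    mz_window_hi: float = DEFAULT_MZ_WINDOW[1]
    snr_min: float = DEFAULT_SNR_MIN
    reference_protein: str = "S4"
    exclude_proteins: tuple[str, ...] = ()
    growth_rate_k: float = DEFAULT_GROWTH_RATE
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    cluster_n_groups: int | None = None
    cluster_height: float | None = None
    rrna_length: int = 1542
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment_post <= 1.0:
            raise ConfigError("enrichment_post must be in [0, 1]")
        if self.mz_tolerance_ppm <= 0:
            raise ConfigError("mz_tolerance_ppm must be positive")
        if not 0 < self.mz_window_lo < self.mz_window_hi:
            raise ConfigError("mz window must satisfy 0 < lo < hi")
        if self.snr_min < 0:
            raise ConfigError("snr_min must be >= 0")
        if self.growth_rate_k <= 0:
            raise ConfigError("growth_rate_k must be positive")
        if self.cluster_metric not in ("euclidean", "correlation"):
            raise ConfigError("cluster_metric must be euclidean or correlation")
        if self.cluster_linkage != "average":
            raise ConfigError("only average linkage is supported")
        if self.rrna_length < 1:
            raise ConfigError("rrna_length must be >= 1")

    @property
    def mz_window(self) -> tuple[float, float]:
        return (self.mz_window_lo, self.mz_window_hi)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` text file (``#`` comments allowed)."""
        kwargs: dict = {}
        field_types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in field_types:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(key, value)
        return cls(**kwargs)


def _coerce(key: str, value: str):
    if key in ("reference_protein", "cluster_metric", "cluster_linkage"):
        return value
    if key == "exclude_proteins":
        return tuple(v.strip() for v in value.split(",") if v.strip())
    if key in ("cluster_n_groups", "cluster_height"):
        if value.lower() in ("none", ""):
            return None
        return int(value) if key == "cluster_n_groups" else float(value)
    if key in ("rrna_length", "seed"):
        return int(value)
    return float(value)


def beer_lambert_concentration(
    absorbance: float, extinction: float, path_cm: float = 1.0
) -> float:
    """Molar concentration from absorbance: c = A / (epsilon * l).

    With a 30S extinction coefficient of 12.8e6 M^-1 cm^-1, an A260 of
    0.13 corresponds to ~10 nM particles.
    """
    if extinction <= 0:
        raise ValueError("extinction coefficient must be positive")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return absorbance / (extinction * path_cm)


# ---------------------------------------------------------------------------
# headers

def _header_lines(config: RunConfig | None) -> str:
    chash = config.config_hash() if config is not None else "none"
    return f"# riboqms {__version__}\n# config_hash={chash}\n"


def write_table(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None, sep: str = "\t",
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV/CSV with the standard provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path: str | Path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein (or RNA) sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# peak lists

def write_peaklists(
    peaklists: list[PeakList], path: str | Path, config: RunConfig | None = None
) -> None:
    rows = []
    for pl in peaklists:
        for mz, intensity in zip(pl.mz, pl.intensity):
            rows.append({"fraction": pl.fraction_id, "mz": mz, "intensity": intensity})
    write_table(pd.DataFrame(rows, columns=["fraction", "mz", "intensity"]), path, config)


def read_peaklists(path: str | Path) -> list[PeakList]:
    df = read_table(path)
    required = {"fraction", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak list file needs columns {sorted(required)}")
    out = []
    for frac, sub in df.groupby("fraction", sort=True):
        out.append(PeakList(str(frac), sub["mz"].to_numpy(), sub["intensity"].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# time courses

def write_timecourses(
    courses: list[TimeCourse], path: str | Path, config: RunConfig | None = None
) -> None:
    rows = []
    for tc in courses:
        for t, fl in zip(tc.t, tc.f_labeled):
            rows.append({"protein": tc.protein_id, "t_min": t, "fL": fl, "k": tc.k})
    write_table(pd.DataFrame(rows, columns=["protein", "t_min", "fL", "k"]), path, config)


def read_timecourses(path: str | Path, k: float | None = None) -> list[TimeCourse]:
    """Read (protein, t_min, fL[, k]) rows; ``k`` overrides any file value."""
    df = read_table(path)
    required = {"protein", "t_min", "fL"}
    if not required.issubset(df.columns):
        raise ValueError(f"time-course file needs columns {sorted(required)}")
    out = []
    for prot, sub in df.groupby("protein", sort=True):
        k_val = k if k is not None else float(sub["k"].iloc[0]) if "k" in sub else DEFAULT_GROWTH_RATE
        out.append(TimeCourse(str(prot), sub["t_min"].to_numpy(), sub["fL"].to_numpy(), k=k_val))
    return out


# ---------------------------------------------------------------------------
# gel lanes

def read_lane_table(path: str | Path) -> pd.DataFrame:
    """Lane intensity CSV with columns strain, replicate, band, intensity."""
    df = read_table(path, sep=",")
    required = {"strain", "replicate", "band", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"lane table needs columns {sorted(required)}")
    return df


def lanes_to_replicates(lane_table: pd.DataFrame, strain: str) -> list[dict[str, float]]:
    """Pivot one strain's lanes into the replicate dicts fraction_cleaved expects."""
    sub = lane_table[lane_table["strain"] == strain]
    reps = []
    for _, grp in sub.groupby("replicate", sort=True):
        bands = dict(zip(grp["band"], grp["intensity"]))
        reps.append(
            {
                "intact": float(bands.get("intact", 0.0)),
                "products": float(bands.get("products", 0.0)),
                "mock_products": float(bands.get("mock_products", 0.0)),
            }
        )
    return reps


# ---------------------------------------------------------------------------
# abundance matrices

def write_abundance_matrix(
    matrix: AbundanceMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    """Proteins as rows, fractions as columns, NA for missing entries."""
    df = matrix.values.copy()
    df.index.name = "protein"
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        fh.write(f"# reference_protein={matrix.reference_protein}\n")
        if matrix.unnormalizable_fractions:
            fh.write(
                "# unnormalizable_fractions=" + ",".join(matrix.unnormalizable_fractions) + "\n"
            )
        df.to_csv(fh, sep="\t", na_rep="NA")


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])


# ---------------------------------------------------------------------------
# image stacks

_STACK_FORMAT_VERSION = 1


def write_image_stack(stack: ImageStack, directory: str | Path) -> None:
    """Versioned stack layout: header.json + data.npy + labels.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": _STACK_FORMAT_VERSION,
        "n_images": len(stack),
        "shape": list(stack.images.shape[1:]),
        "dtype": str(stack.images.dtype),
    }
    (directory / "header.json").write_text(json.dumps(header, indent=1))
    np.save(directory / "data.npy", stack.images)
    meta = pd.DataFrame(
        {
            "index": range(len(stack)),
            "label": stack.labels,
            "dataset": stack.dataset_ids or [""] * len(stack),
        }
    )
    meta.to_csv(directory / "labels.tsv", sep="\t", index=False)


def read_image_stack(directory: str | Path) -> ImageStack:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    if header["format_version"] != _STACK_FORMAT_VERSION:
        raise ValueError(f"unsupported stack format version {header['format_version']}")
    images = np.load(directory / "data.npy")
    meta = pd.read_csv(directory / "labels.tsv", sep="\t")
    return ImageStack(
        images,
        labels=[str(v) for v in meta["label"]],
        dataset_ids=[str(v) if pd.notna(v) else "" for v in meta["dataset"]],
    )
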