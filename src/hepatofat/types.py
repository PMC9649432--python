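"""Shared domain types for the liver fat-fraction pipeline.

Conventions used throughout the package:

* echo times are stored in **seconds** internally; configuration files and
  constructors that mirror scanner protocols take milliseconds,
* the fat chemical shift ``fat_shift_hz`` enters the signal model through
  ``exp(-1j * 2 * pi * fat_shift * t)``,
* images are 2-D ``numpy`` arrays (height x width); multi-echo stacks are
  ``height x width x n_echo`` complex arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "ParameterMaps",
    "MultiEchoImage",
    "FitResult",
    "PDFFMap",
    "ROI",
    "ROIStats",
    "PDFFReport",
    "IronCalibration",
    "Cohort",
    "ProteinPanel",
    "AssocResult",
    "InteractionResult",
    "MetaResult",
    "MRResult",
    "GRSWeights",
    "CVReport",
    "StagingModel",
]


@dataclass(frozen=True)
class Protocol:
    """Multi-echo acquisition protocol.

    Parameters
    ----------
    echo_times_s:
        Strictly increasing echo times in seconds.
    fat_shift_hz:
        Chemical shift of fat relative to water in Hz (magnitude ~217 Hz for
        a single-peak fat model at 1.5 T); the model uses
        ``exp(-1j*2*pi*fat_shift_hz*t)``.
    name:
        Acquisition label, e.g. ``"GRE"`` or ``"IDEAL"``.
    noise_sd:
        Standard deviation of the complex Gaussian noise per real/imaginary
        channel, in the same arbitrary units as the amplitudes.
    """

    echo_times_s: tuple
    fat_shift_hz: float = 217.0
    name: str = "custom"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.echo_times_s, dtype=float)
        if times.ndim != 1 or times.size < 3:
            raise ValueError("protocol needs at least 3 echo times")
        if not np.all(np.diff(times) > 0):
            raise ValueError("echo times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "echo_times_s", tuple(float(t) for t in times))

    @classmethod
    def from_ms(
        cls,
        echo_times_ms: Sequence[float],
        fat_shift_hz: float = 217.0,
        name: str = "custom",
        noise_sd: float = 0.0,
    ) -> "Protocol":
        """Build a protocol from echo times given in milliseconds."""
        return cls(
            echo_times_s=tuple(t * 1e-3 for t in echo_times_ms),
            fat_shift_hz=fat_shift_hz,
            name=name,
            noise_sd=noise_sd,
        )

    @property
    def echo_times_ms(self) -> tuple:
        return tuple(t * 1e3 for t in self.echo_times_s)

    @property
    def n_echo(self) -> int:
        return len(self.echo_times_s)

    def to_sidecar(self) -> dict:
        return {
            "echo_times_ms": list(self.echo_times_ms),
            "fat_shift_hz": self.fat_shift_hz,
            "noise_sd": self.noise_sd,
            "name": self.name,
        }

    @classmethod
    def from_sidecar(cls, sidecar: dict) -> "Protocol":
        required = {"echo_times_ms", "fat_shift_hz", "noise_sd", "name"}
        missing = required - set(sidecar)
        if missing:
            raise ValueError(f"sidecar missing keys: {sorted(missing)}")
        return cls.from_ms(
            sidecar["echo_times_ms"],
            fat_shift_hz=float(sidecar["fat_shift_hz"]),
            name=str(sidecar["name"]),
            noise_sd=float(sidecar["noise_sd"]),
        )


@dataclass
class ParameterMaps:
    """Ground-truth voxel maps for a 2-D slice phantom.

    ``rho_w``/``rho_f`` are water/fat amplitudes (a.u.), ``field_map`` the
    off-resonance frequency in Hz, ``r2star`` the effective transverse
    relaxation rate in 1/s, and ``mask`` the liver region.
    """

    rho_w: np.ndarray
    rho_f: np.ndarray
    field_map: np.ndarray
    r2star: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.rho_w.shape
        for name in ("rho_f", "field_map", "r2star", "mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")
        if np.any(self.r2star < 0):
            raise ValueError("r2star must be non-negative")
        if np.any(self.rho_w < 0) or np.any(self.rho_f < 0):
            raise ValueError("amplitudes must be non-negative")
        self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple:
        return self.rho_w.shape

    def pdff(self) -> np.ndarray:
        """True proton-density fat fraction, 0 where both amplitudes vanish."""
        total = self.rho_w + self.rho_f
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, self.rho_f / np.where(total > 0, total, 1.0), 0.0)
        return out


@dataclass
class MultiEchoImage:
    """Observed complex echo stack ``y_i`` with its protocol.

    ``data`` has shape (height, width, n_echo); ``truth`` optionally embeds
    the generating parameter maps for testing.
    """

    data: np.ndarray
    protocol: Protocol
    truth: Optional[ParameterMaps] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be height x width x n_echo")
        if self.data.shape[2] != self.protocol.n_echo:
            raise ValueError(
                f"echo count mismatch: data has {self.data.shape[2]}, "
                f"protocol has {self.protocol.n_echo}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in echo stack")
        if self.truth is not None and self.truth.shape != self.data.shape[:2]:
            raise ValueError("truth maps do not match image shape")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:2]


@dataclass
class FitResult:
    """Per-voxel signal-model fit (amplitudes reported as magnitudes)."""

    rho_w: float
    rho_f: float
    field_map_hz: float
    r2star: float
    residual: float
    iterations: int = 0
    converged: bool = True
    degenerate: bool = False

    @property
    def pdff(self) -> float:
        total = self.rho_w + self.rho_f
        return self.rho_f / total if total > 0 else 0.0


@dataclass
class PDFFMap:
    """Voxelwise PDFF (fraction in [0, 1]) with optional R2* map."""

    pdff: np.ndarray
    r2star: Optional[np.ndarray] = None
    convergence_mask: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    field_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any((self.pdff < -1e-12) | (self.pdff > 1 + 1e-12)):
            raise ValueError("pdff outside [0, 1]")


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; ``row``/``col`` are top-left corner."""

    row: int
    col: int
    height: int = 5
    width: int = 5

    @property
    def n_voxels(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple:
        return (slice(self.row, self.row + self.height), slice(self.col, self.col + self.width))


@dataclass(frozen=True)
class ROIStats:
    roi: ROI
    mean: float
    sd: float
    excluded: bool = False


@dataclass
class PDFFReport:
    """Eight candidate ROIs and the reported (lowest-s.d.) PDFF in percent."""

    rois: list
    selected_index: int  # 1-based
    reported_pdff: float  # percent
    iron_mg_per_g: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "rois": [
                {
                    "row": s.roi.row,
                    "col": s.roi.col,
                    "height": s.roi.height,
                    "width": s.roi.width,
                    "mean_pdff_percent": 100.0 * s.mean,
                    "sd_pdff_percent": 100.0 * s.sd,
                    "excluded": s.excluded,
                }
                for s in self.rois
            ],
            "selected_index": self.selected_index,
            "reported_pdff_percent": self.reported_pdff,
            "iron_mg_per_g": self.iron_mg_per_g,
        }


@dataclass(frozen=True)
class IronCalibration:
    """Linear R2*-to-iron calibration: iron = intercept + slope * R2*.

    Units: mg iron per g dry tissue, with R2* in 1/s.
    """

    intercept: float = 0.202
    slope: float = 0.0254


@dataclass
class Cohort:
    """Simulated genotype/phenotype cohort.

    ``genotypes``: DataFrame of minor-allele counts in {0,1,2}
    (individuals x variants); ``covariates``: sex/age/year_of_birth/bmi;
    ``traits``: quantitative traits; ``diagnoses``: boolean disease columns.
    """

    genotypes: pd.DataFrame
    mafs: pd.Series
    covariates: pd.DataFrame
    traits: pd.DataFrame
    diagnoses: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.genotypes.to_numpy()
        valid = np.isin(values[~pd.isna(values)], [0, 1, 2])
        if not valid.all():
            raise ValueError("genotypes must be in {0, 1, 2}")
        n = len(self.genotypes)
        for name in ("covariates", "traits", "diagnoses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} row count differs from genotypes")

    @property
    def n(self) -> int:
        return len(self.genotypes)


@dataclass
class ProteinPanel:
    """Samples x analytes protein panel with planted disease shifts."""

    levels: pd.DataFrame
    informative_ids: list
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.labels):
            raise ValueError("levels and labels have different sample counts")
        unknown = set(self.informative_ids) - set(self.levels.columns)
        if unknown:
            raise ValueError(f"informative ids not in panel: {sorted(unknown)}")


@dataclass(frozen=True)
class AssocResult:
    """Additive association result (beta in s.d. units, or log-OR)."""

    beta: float
    se: float
    p_value: float
    n: int
    separation: bool = False


@dataclass(frozen=True)
class InteractionResult:
    """Genotype-group interaction fit: beta_g = b + gamma * g_p, df=1 LRT."""

    group_betas: tuple
    group_ses: tuple
    group_ns: tuple
    b: float
    gamma: float
    gamma_se: float
    lrt_stat: float
    p_value: float


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects inverse-variance meta-analysis result."""

    effect: float
    se: float
    p_value: float
    q_stat: float
    p_het: float
    k: int


@dataclass(frozen=True)
class MRResult:
    """Mendelian-randomization estimates (IVW and, with >=3 instruments, Egger)."""

    ivw_estimate: float
    ivw_se: float
    ivw_p: float
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    egger_slope: Optional[float] = None
    egger_slope_se: Optional[float] = None
    egger_slope_p: Optional[float] = None


@dataclass
class GRSWeights:
    """Per-variant genetic-risk-score weights with explicit effect alleles."""

    variants: list
    effect_alleles: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.variants) == len(self.effect_alleles) == len(self.weights)):
            raise ValueError("variants, effect_alleles and weights must align")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class CVReport:
    """Repeated stratified cross-validation summary (ROC AUC)."""

    mean_auc: float
    sem_auc: float
    n_repeats: int
    n_folds: int
    per_repeat_aucs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sem_auc": self.sem_auc,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "per_repeat_aucs": list(self.per_repeat_aucs),
        }


@dataclass
class StagingModel:
    """Fitted elastic-net staging classifier with its preprocessing state."""

    selected_features: list
    transform_params: dict
    coefficients: pd.Series
    intercept: float
    tuning: dict
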