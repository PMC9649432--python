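"""Pipeline configuration and orchestration.

``run_pipeline`` executes simulate -> fit (both acquisitions) -> ROI report
-> cohort statistics on synthetic inputs and returns a JSON-serializable
summary; every stage seed is derived deterministically from the config
seed, and the summary records the package version and a config hash for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .dixon import DixonConfig, dixon_pdff_map
from .genetic_stats import additive_assoc, interaction_lrt, inverse_normal_transform, ivw_meta
from .ideal import ideal_pdff_map
from .io import write_json, write_multiecho, write_nifti
from .roi_report import report_pdff
from .synthetic import (
    gre_protocol,
    ideal_protocol,
    simulate_cohort,
    simulate_multiecho,
    simulate_parameter_maps,
)

log = logging.getLogger("hepatofat")

__all__ = ["PipelineConfig", "run_pipeline", "config_hash"]


@dataclass
class PhantomConfig:
    shape: tuple = (64, 64)
    pdff_dist: tuple = ("normal", 0.10, 0.005)
    r2star_range: tuple = (30.0, 50.0)
    field_poly: tuple = (10.0, 5.0, -4.0)
    noise_sd: float = 0.0005
    fat_shift_hz: float = 217.0


@dataclass
class CohortConfig:
    n: int = 2000
    mafs: tuple = (0.3, 0.25, 0.2)
    beta: tuple = (0.15, 0.1, 0.0)
    gamma: float = 0.0
    noise_sd: float = 1.0


@dataclass
class PipelineConfig:
    """Serializable configuration of the end-to-end synthetic pipeline."""

    seed: int = 0
    methods: tuple = ("dixon", "ideal")
    dixon_echoes: tuple = (2, 4, 6)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        phantom = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.pop("phantom", {}).items()})
        cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.pop("cohort", {}).items()})
        for key in ("methods", "dixon_echoes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(phantom=phantom, cohort=cohort, **d)

    def validate(self) -> None:
        gre = gre_protocol(fat_shift_hz=self.phantom.fat_shift_hz)
        ideal = ideal_protocol(fat_shift_hz=self.phantom.fat_shift_hz)
        if "dixon" in self.methods and max(self.dixon_echoes) > gre.n_echo:
            raise ValueError(
                f"dixon echo index {max(self.dixon_echoes)} exceeds the "
                f"{gre.n_echo}-echo GRE protocol"
            )
        if "ideal" in self.methods and ideal.n_echo < 4:
            raise ValueError("IDEAL protocol must have at least 4 echoes")
        for m in self.methods:
            if m not in ("dixon", "ideal"):
                raise ValueError(f"unknown method {m!r}")
        if self.cohort.n < 50:
            raise ValueError("cohort n must be at least 50")


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured synthetic pipeline and return the summary dict.

    When ``config.out_dir`` is set, the echo stacks, PDFF maps and the JSON
    summary are written there.
    """
    config.validate()
    chash = config_hash(config)
    summary = {"version": __version__, "config_hash": chash, "seed": config.seed}
    out_dir = Path(config.out_dir) if config.out_dir else None

    log.info("stage=phantom seed=%d", _stage_seed(config.seed, "phantom"))
    ph = config.phantom
    try:
        maps = simulate_parameter_maps(
            shape=ph.shape,
            pdff_dist=ph.pdff_dist,
            r2star_range=ph.r2star_range,
            field_poly=ph.field_poly,
            seed=_stage_seed(config.seed, "phantom"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'phantom' failed: {exc}") from exc

    truth_pdff = float(maps.pdff()[maps.mask].mean())
    summary["phantom"] = {"true_mean_pdff_percent": 100.0 * truth_pdff}

    for method in config.methods:
        stage = f"fit-{method}"
        seed = _stage_seed(config.seed, stage)
        log.info("stage=%s seed=%d", stage, seed)
        try:
            if method == "dixon":
                protocol = gre_protocol(noise_sd=ph.noise_sd, fat_shift_hz=ph.fat_shift_hz)
                image = simulate_multiecho(maps, protocol, seed=seed)
                pdff_map = dixon_pdff_map(image, DixonConfig(echo_indices=config.dixon_echoes))
            else:
                protocol = ideal_protocol(noise_sd=ph.noise_sd, fat_shift_hz=ph.fat_shift_hz)
                image = simulate_multiecho(maps, protocol, seed=seed)
                pdff_map = ideal_pdff_map(image)
            report = report_pdff(pdff_map)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        entry = report.to_dict()
        summary[method] = {
            "reported_pdff_percent": entry["reported_pdff_percent"],
            "selected_roi": entry["selected_index"],
            "iron_mg_per_g": entry["iron_mg_per_g"],
        }
        if out_dir is not None:
            write_multiecho(image, out_dir / f"echoes_{method}")
            write_nifti(out_dir / f"pdff_{method}.nii.gz", pdff_map.pdff)

    co = config.cohort
    seed = _stage_seed(config.seed, "cohort")
    log.info("stage=cohort seed=%d", seed)
    try:
        cohort = simulate_cohort(
            n=co.n, mafs=co.mafs, beta=co.beta, gamma=co.gamma, noise_sd=co.noise_sd, seed=seed
        )
        trait = inverse_normal_transform(
            cohort.traits["trait"].to_numpy(),
            cohort.covariates[["sex", "age", "bmi"]],
        )
        assoc = additive_assoc(cohort.genotypes.iloc[:, 0].to_numpy(), trait)
        inter = interaction_lrt(
            cohort.genotypes.iloc[:, 0].to_numpy(),
            cohort.genotypes.iloc[:, 1].to_numpy(),
            trait,
        )
        # two half-cohort "studies" meta-analyzed for the smoke summary
        half = co.n // 2
        a1 = additive_assoc(cohort.genotypes.iloc[:half, 0].to_numpy(), trait[:half])
        a2 = additive_assoc(cohort.genotypes.iloc[half:, 0].to_numpy(), trait[half:])
        meta = ivw_meta([a1.beta, a2.beta], [a1.se, a2.se])
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    summary["cohort"] = {
        "assoc_beta": assoc.beta,
        "assoc_p": assoc.p_value,
        "interaction_gamma": inter.gamma,
        "interaction_p": inter.p_value,
        "meta_effect": meta.effect,
        "meta_se": meta.se,
    }

    if out_dir is not None:
        write_json(out_dir / "summary.json", summary)
    return summary
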