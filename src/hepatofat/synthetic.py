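"""Synthetic-data generators: MR phantoms, cohorts and protein panels.

Every generator takes an explicit integer seed and is bit-reproducible.
The MR phantom emulates a single 2-D liver slice: an elliptical "liver"
mask with voxelwise water/fat amplitudes, a smooth polynomial B0 field
map, R2* decay and i.i.d. circular complex Gaussian noise. Anatomical
realism is deliberately absent — the downstream estimators are voxelwise.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import Cohort, MultiEchoImage, ParameterMaps, ProteinPanel, Protocol

__all__ = [
    "GRE_ECHO_TIMES_MS",
    "IDEAL_ECHO_TIMES_MS",
    "DEFAULT_FAT_SHIFT_HZ",
    "gre_protocol",
    "ideal_protocol",
    "forward_signal",
    "simulate_parameter_maps",
    "simulate_multiecho",
    "inject_swap_region",
    "simulate_cohort",
    "simulate_proteome",
    "simulate_staging_dataset",
]

# 10-echo gradient-echo train and 6-echo IDEAL acquisition (ms).
GRE_ECHO_TIMES_MS = (2.38, 4.76, 7.15, 9.53, 11.91, 14.29, 16.67, 19.06, 21.44, 23.82)
IDEAL_ECHO_TIMES_MS = (1.2, 3.2, 5.2, 7.2, 9.2, 11.2)

# Single-peak fat chemical shift, ~-3.4 ppm at 1.5 T.
DEFAULT_FAT_SHIFT_HZ = 217.0


def gre_protocol(noise_sd: float = 0.0, fat_shift_hz: float = DEFAULT_FAT_SHIFT_HZ) -> Protocol:
    """The 10-echo GRE protocol (TE 2.38..23.82 ms)."""
    return Protocol.from_ms(GRE_ECHO_TIMES_MS, fat_shift_hz=fat_shift_hz, name="GRE", noise_sd=noise_sd)


def ideal_protocol(noise_sd: float = 0.0, fat_shift_hz: float = DEFAULT_FAT_SHIFT_HZ) -> Protocol:
    """The 6-echo IDEAL protocol (TE 1.2..11.2 ms)."""
    return Protocol.from_ms(IDEAL_ECHO_TIMES_MS, fat_shift_hz=fat_shift_hz, name="IDEAL", noise_sd=noise_sd)


def forward_signal(maps: ParameterMaps, protocol: Protocol) -> np.ndarray:
    """Noise-free signal model evaluated at every voxel and echo.

    ``y_i = (rho_w + rho_f e^{-j2pi df t_i}) e^{-j2pi phi t_i} e^{-R2* t_i}``
    """
    t = np.asarray(protocol.echo_times_s)  # (n_echo,)
    fat = np.exp(-1j * 2 * np.pi * protocol.fat_shift_hz * t)  # (n_echo,)
    amp = maps.rho_w[..., None] + maps.rho_f[..., None] * fat
    phase = np.exp(
        (-1j * 2 * np.pi * maps.field_map[..., None] - maps.r2star[..., None]) * t
    )
    return amp * phase


def _parse_pdff_dist(pdff_dist) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Accept a constant, an ('name', args...) tuple or a callable(rng, n)."""
    if callable(pdff_dist):
        return pdff_dist
    if np.isscalar(pdff_dist):
        value = float(pdff_dist)
        if not 0.0 <= value <= 1.0:
            raise ValueError("constant PDFF must lie in [0, 1]")
        return lambda rng, n: np.full(n, value)
    name, *args = pdff_dist
    if name == "uniform":
        lo, hi = args
        return lambda rng, n: rng.uniform(lo, hi, n)
    if name == "normal":
        mu, sd = args
        return lambda rng, n: np.clip(rng.normal(mu, sd, n), 0.0, 1.0)
    if name == "point":
        (value,) = args
        return lambda rng, n: np.full(n, float(value))
    raise ValueError(f"unknown pdff distribution: {name!r}")


def simulate_parameter_maps(
    shape: Sequence[int] = (64, 64),
    pdff_dist=("uniform", 0.0, 0.4),
    r2star_range: Sequence[float] = (30.0, 50.0),
    field_poly: Sequence[float] = (0.0,),
    seed: int = 0,
    total_amplitude: float = 1.0,
) -> ParameterMaps:
    """Simulate ground-truth parameter maps for an elliptical liver phantom.

    Parameters
    ----------
    shape:
        Image extent, at least 32 x 32.
    pdff_dist:
        Per-voxel PDFF distribution inside the mask: a constant, a tuple like
        ``("uniform", lo, hi)`` / ``("normal", mu, sd)`` / ``("point", v)``,
        or a callable ``f(rng, n) -> array``.
    r2star_range:
        Uniform range of R2* inside the mask, within [0, 500] 1/s.
    field_poly:
        2-D polynomial coefficients for the field map in Hz, ordered as
        ``(c0, cx, cy, cxx, cxy, cyy, ...)`` over normalized coordinates
        x, y in [-1, 1]; truncated/extended by degree as provided.
    seed:
        RNG seed.
    total_amplitude:
        Water + fat amplitude inside the mask (a.u.).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) < 32:
        raise ValueError("shape must be 2-D and at least 32 x 32")
    lo, hi = float(r2star_range[0]), float(r2star_range[1])
    if not (0.0 <= lo <= hi <= 500.0):
        raise ValueError("r2star_range must lie within [0, 500] 1/s")

    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # normalized coordinates in [-1, 1]
    xn = (xx - (w - 1) / 2) / ((w - 1) / 2)
    yn = (yy - (h - 1) / 2) / ((h - 1) / 2)

    # filled ellipse covering ~70% of each axis, inset from the frame
    mask = (xn / 0.78) ** 2 + (yn / 0.72) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("empty liver mask")

    # polynomial field map over normalized coordinates
    basis = [np.ones_like(xn), xn, yn, xn * xn, xn * yn, yn * yn, xn**3, xn * xn * yn, xn * yn * yn, yn**3]
    coeffs = list(field_poly)
    if len(coeffs) > len(basis):
        raise ValueError("field_poly supports up to cubic terms (10 coefficients)")
    field = np.zeros(shape, dtype=float)
    for c, b in zip(coeffs, basis):
        field += float(c) * b

    n_in = int(mask.sum())
    pdff = np.zeros(shape, dtype=float)
    pdff[mask] = _parse_pdff_dist(pdff_dist)(rng, n_in)
    if np.any((pdff < 0) | (pdff > 1)):
        raise ValueError("pdff_dist produced values outside [0, 1]")

    rho_w = np.zeros(shape, dtype=float)
    rho_f = np.zeros(shape, dtype=float)
    rho_w[mask] = total_amplitude * (1.0 - pdff[mask])
    rho_f[mask] = total_amplitude * pdff[mask]

    r2star = np.zeros(shape, dtype=float)
    r2star[mask] = rng.uniform(lo, hi, n_in)

    return ParameterMaps(rho_w=rho_w, rho_f=rho_f, field_map=field, r2star=r2star, mask=mask)


def simulate_multiecho(maps: ParameterMaps, protocol: Protocol, seed: int = 0) -> MultiEchoImage:
    """Evaluate the signal model and add complex Gaussian noise.

    Noise is i.i.d. circular complex Gaussian with standard deviation
    ``protocol.noise_sd`` per real/imaginary channel, added everywhere
    (mask included) so background voxels are noise-only.
    """
    clean = forward_signal(maps, protocol)
    rng = np.random.default_rng(seed)
    if protocol.noise_sd > 0:
        noise = rng.normal(0.0, protocol.noise_sd, clean.shape) + 1j * rng.normal(
            0.0, protocol.noise_sd, clean.shape
        )
        data = clean + noise
    else:
        data = clean
    return MultiEchoImage(data=data, protocol=protocol, truth=maps)


def inject_swap_region(
    maps: ParameterMaps,
    region: Union[tuple, "np.ndarray", None],
    fat_shift_hz: float = DEFAULT_FAT_SHIFT_HZ,
    seed: int = 0,
) -> ParameterMaps:
    """Shift the field map by half the fat-shift frequency inside ``region``.

    This plants the classic water-fat ambiguity: inside the region the
    off-resonance sits half a chemical shift away, so a fitter whose field
    search is confined to the principal interval lands on the swapped
    (fat-for-water) solution. ``region`` is ``(row, col, height, width)``
    or ``None``/empty for the identity. ``seed`` is accepted for interface
    uniformity; the operation is deterministic.
    """
    if region is None:
        return ParameterMaps(
            rho_w=maps.rho_w.copy(),
            rho_f=maps.rho_f.copy(),
            field_map=maps.field_map.copy(),
            r2star=maps.r2star.copy(),
            mask=maps.mask.copy(),
        )
    r, c, hgt, wid = (int(v) for v in region)
    h, w = maps.shape
    if r < 0 or c < 0 or r + hgt > h or c + wid > w:
        raise ValueError("region lies outside the image")
    if hgt == 0 or wid == 0:
        return inject_swap_region(maps, None, fat_shift_hz)
    sub = maps.mask[r : r + hgt, c : c + wid]
    if not sub.any():
        raise ValueError("region does not intersect the liver mask")
    field = maps.field_map.copy()
    field[r : r + hgt, c : c + wid] += fat_shift_hz / 2.0
    return ParameterMaps(
        rho_w=maps.rho_w.copy(),
        rho_f=maps.rho_f.copy(),
        field_map=field,
        r2star=maps.r2star.copy(),
        mask=maps.mask.copy(),
    )


# ---------------------------------------------------------------------------
# cohorts and protein panels
# ---------------------------------------------------------------------------


def simulate_cohort(
    n: int,
    mafs: Sequence[float],
    beta: Optional[Sequence[float]] = None,
    gamma: float = 0.0,
    interaction_pair: tuple = (0, 1),
    noise_sd: float = 1.0,
    disease_model: Optional[dict] = None,
    covariate_effects: Optional[dict] = None,
    seed: int = 0,
) -> Cohort:
    """Simulate genotypes under Hardy-Weinberg plus an additive trait model.

    The quantitative trait is
    ``sum_k beta_k g_k + gamma * g_p * g_s + covariate effects + N(0, noise_sd)``
    where ``(p, s)`` is ``interaction_pair``. A binary diagnosis is drawn
    from ``Bernoulli(logistic(intercept + sum slopes_k g_k))`` when
    ``disease_model={"intercept": ..., "slopes": [...]}`` is given.
    """
    if n < 50:
        raise ValueError("n must be at least 50")
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("mafs must lie in (0, 0.5]")
    m = mafs.size
    beta_arr = np.zeros(m) if beta is None else np.asarray(beta, dtype=float)
    if beta_arr.size != m:
        raise ValueError("beta length must match mafs")
    if not (np.all(np.isfinite(beta_arr)) and np.isfinite(gamma)):
        raise ValueError("effects must be finite")

    rng = np.random.default_rng(seed)
    genotypes = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int64)

    sex = rng.integers(0, 2, n)
    age = rng.uniform(40, 70, n)
    year_of_birth = 2018 - np.round(age).astype(int)
    bmi = rng.normal(27.0, 4.0, n)
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "year_of_birth": year_of_birth, "bmi": bmi}
    )

    effects = covariate_effects or {}
    cov_term = (
        effects.get("sex", 0.0) * sex
        + effects.get("age", 0.0) * (age - age.mean())
        + effects.get("bmi", 0.0) * (bmi - bmi.mean())
    )
    p_idx, s_idx = interaction_pair
    if gamma != 0.0:
        if max(p_idx, s_idx) >= m:
            raise ValueError("interaction_pair indices exceed the variant count")
        inter_term = gamma * genotypes[:, p_idx] * genotypes[:, s_idx]
    else:
        inter_term = 0.0
    trait = genotypes @ beta_arr + inter_term + cov_term + rng.normal(0.0, noise_sd, n)
    traits = pd.DataFrame({"trait": trait})

    if disease_model is not None:
        intercept = float(disease_model.get("intercept", -2.0))
        slopes = np.asarray(disease_model.get("slopes", np.zeros(m)), dtype=float)
        if slopes.size != m:
            raise ValueError("disease_model slopes must match variant count")
        logit = intercept + genotypes @ slopes
        prob = 1.0 / (1.0 + np.exp(-logit))
        dx = rng.random(n) < prob
    else:
        dx = np.zeros(n, dtype=bool)
    diagnoses = pd.DataFrame({"disease": dx})

    sample_index = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    variant_ids = [f"rs{i + 1:04d}" for i in range(m)]
    return Cohort(
        genotypes=pd.DataFrame(genotypes, index=sample_index, columns=variant_ids),
        mafs=pd.Series(mafs, index=variant_ids, name="maf"),
        covariates=covariates.set_index(sample_index),
        traits=traits.set_index(sample_index),
        diagnoses=diagnoses.set_index(sample_index),
    )


def simulate_proteome(
    cohort: Cohort,
    n_proteins: int = 500,
    n_informative: int = 20,
    effect: float = 0.8,
    confound: Optional[dict] = None,
    seed: int = 0,
) -> ProteinPanel:
    """Simulate a protein panel with case shifts on a subset of analytes.

    Informative analytes are shifted by ``effect`` standard deviations in
    cases (first diagnosis column of the cohort); all analytes are unit-s.d.
    Gaussian noise otherwise. ``confound={"age": a, "sex": s, "bmi": b}``
    adds linear covariate terms to every analyte.
    """
    if n_informative > n_proteins:
        raise ValueError("n_informative cannot exceed n_proteins")
    labels = cohort.diagnoses.iloc[:, 0].astype(bool)
    n = len(labels)
    rng = np.random.default_rng(seed)
    levels = rng.normal(0.0, 1.0, (n, n_proteins))
    levels[labels.to_numpy(), :n_informative] += effect
    if confound:
        cov = cohort.covariates
        term = (
            confound.get("age", 0.0) * (cov["age"] - cov["age"].mean()).to_numpy()
            + confound.get("sex", 0.0) * cov["sex"].to_numpy()
            + confound.get("bmi", 0.0) * (cov["bmi"] - cov["bmi"].mean()).to_numpy()
        )
        levels += term[:, None]
    analyte_ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    informative = analyte_ids[:n_informative]
    return ProteinPanel(
        levels=pd.DataFrame(levels, index=cohort.genotypes.index, columns=analyte_ids),
        informative_ids=informative,
        labels=labels,
    )


def simulate_staging_dataset(
    n_cases: int = 300,
    n_controls: int = 300,
    n_proteins: int = 500,
    n_informative: int = 20,
    protein_effect: float = 0.8,
    enzyme_effect: float = 0.3,
    seed: int = 0,
) -> tuple:
    """Case/control protein panel plus the six baseline covariates.

    Returns ``(panel, covariates)`` where ``covariates`` holds age, sex, bmi,
    alt, ast, ggt; the three enzymes (and bmi, weakly) carry a planted case
    shift of ``enzyme_effect`` s.d., emulating a disease stage in which
    circulating proteins are more informative than liver enzymes.
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    labels = np.zeros(n, dtype=bool)
    labels[:n_cases] = True
    perm = rng.permutation(n)
    labels = labels[perm]

    levels = rng.normal(0.0, 1.0, (n, n_proteins))
    levels[labels, :n_informative] += protein_effect
    analyte_ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    sample_ids = [f"S{i:06d}" for i in range(n)]
    panel = ProteinPanel(
        levels=pd.DataFrame(levels, index=sample_ids, columns=analyte_ids),
        informative_ids=analyte_ids[:n_informative],
        labels=pd.Series(labels, index=sample_ids, name="case"),
    )

    age = rng.uniform(40, 70, n)
    sex = rng.integers(0, 2, n)
    bmi = rng.normal(27.0, 4.0, n) + 0.5 * enzyme_effect * labels
    enzymes = {
        name: rng.normal(0.0, 1.0, n) + enzyme_effect * labels
        for name in ("alt", "ast", "ggt")
    }
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "bmi": bmi, **enzymes}, index=sample_ids
    )
    return panel, covariates
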