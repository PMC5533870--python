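"""Seeded two-group synthetic urine-spectrum cohorts with known ground truth.

Emulates 500 MHz CPMG urine spectra at the level the downstream pipeline
needs: area-parameterized Lorentzian multiplets for a library of urinary
metabolites, log-normal inter-subject concentration variation, group-specific
fold changes on the discriminant metabolites, per-sample dilution factors,
per-sample/per-metabolite chemical-shift jitter, a slowly varying baseline
and additive Gaussian noise.  Every draw comes from one seeded generator, so
a cohort is bit-reproducible from its config.

The generator is the stand-in for the study's (non-deposited) patient
spectra; its :class:`GroundTruth` output is the oracle used by recovery
tests (dilution recovery by PQN, effect-size realization, alignment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Spectrum
from .regions import BPH_MEAN_INTENSITY, PCA_VS_BPH_FOLD_CHANGE

PPM_MIN = 0.15
PPM_MAX = 9.50

#: Lorentzians are evaluated only within this many linewidths of the center.
TRUNCATION_LINEWIDTHS = 50.0


@dataclass(frozen=True)
class MetaboliteSignature:
    """One metabolite's resonances.

    ``peaks`` holds ``(center_ppm, relative_intensity, linewidth_ppm)``
    triples; relative intensities are the fractions of the metabolite's
    total spectral area carried by each resonance (they need not sum to 1,
    only their ratios matter within a metabolite).
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    base_concentration: float
    shift_jitter_sd: float = 0.003

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"{self.name}: needs at least one peak")
        for center, rel, lw in self.peaks:
            if rel <= 0 or lw <= 0:
                raise ValueError(f"{self.name}: relative intensities and linewidths must be > 0")
            if not PPM_MIN <= center <= PPM_MAX:
                raise ValueError(f"{self.name}: peak center {center} outside {PPM_MIN}-{PPM_MAX} ppm")
        if self.base_concentration <= 0:
            raise ValueError(f"{self.name}: base concentration must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Group A is the reference (BPH-like) group; group B (PCa-like) has the
    ``effect_map`` fold changes applied to its metabolite concentrations.
    """

    n_group_a: int = 51
    n_group_b: int = 64
    effect_map: dict[str, float] = field(
        default_factory=lambda: dict(PCA_VS_BPH_FOLD_CHANGE)
    )
    dilution_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 2.0
    baseline_amplitude: float = 5.0
    ppm_grid: tuple[float, float, float] = (PPM_MIN, PPM_MAX, 0.001)
    log_concentration_sd: float = 0.2
    jitter_scale: float = 1.0
    group_a_label: str = "BPH"
    group_b_label: str = "PCa"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 3 or self.n_group_b < 3:
            raise ValueError("group sizes must be >= 3")
        lo, hi = self.dilution_range
        if lo <= 0 or hi < lo:
            raise ValueError("dilution_range must satisfy 0 < low <= high")
        gmin, gmax, step = self.ppm_grid
        if gmin >= gmax:
            raise ValueError("degenerate ppm grid: min must be < max")
        if step <= 0:
            raise ValueError("ppm grid step must be > 0")
        if any(f <= 0 for f in self.effect_map.values()):
            raise ValueError("effect fold changes must be > 0")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ValueError("noise_sd and baseline_amplitude must be >= 0")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")


@dataclass
class GroundTruth:
    """Per-sample latent variables of a simulated cohort (oracle for tests).

    Row order matches the emitted spectra exactly.
    """

    sample_ids: list[str]
    groups: list[str]
    dilutions: np.ndarray
    concentrations: pd.DataFrame
    shifts: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sample_ids": self.sample_ids,
                    "groups": self.groups,
                    "dilutions": self.dilutions.tolist(),
                    "concentrations": self.concentrations.to_dict(orient="list"),
                    "shifts": self.shifts.to_dict(orient="list"),
                }
            )
        )


def default_metabolite_library() -> list[MetaboliteSignature]:
    """Urinary metabolite signatures for the simulator.

    The eight discriminant metabolites carry peaks inside their integration
    windows (base concentrations on the scale of the reported BPH group
    means); the dominant background metabolites of urine (creatinine,
    citrate, hippurate, TMAO, dimethylamine, urea, lactate, alanine,
    creatine, formate) fill out the rest of the spectrum.  Linewidths are
    typical of well-shimmed 500 MHz CPMG urine spectra (~0.0015 ppm full
    width at half maximum for small metabolites).
    """
    lw = 0.0015
    c = BPH_MEAN_INTENSITY
    return [
        # discriminant metabolites (peaks inside their integration windows)
        MetaboliteSignature(
            "BCAA",
            (
                (0.858, 0.17, lw), (0.864, 0.17, lw),      # leucine CH3 doublet
                (0.893, 0.16, lw), (0.899, 0.16, lw),      # isoleucine CH3
                (0.918, 0.17, lw), (0.924, 0.17, lw),      # valine CH3 doublet
            ),
            c["BCAA"],
        ),
        MetaboliteSignature(
            "glutamate",
            (
                (2.090, 0.2, lw), (2.098, 0.25, lw), (2.106, 0.2, lw),  # beta-CH2
                (2.340, 0.35, lw),                                       # gamma-CH2
            ),
            c["glutamate"],
        ),
        MetaboliteSignature("dimethylglycine", ((2.933, 1.0, lw),), c["dimethylglycine"]),
        MetaboliteSignature("glycine", ((3.574, 1.0, lw),), c["glycine"]),
        MetaboliteSignature("pseudouridine", ((4.290, 1.0, lw),), c["pseudouridine"]),
        MetaboliteSignature("U1", ((6.487, 1.0, lw),), c["U1"]),
        MetaboliteSignature("fumarate", ((6.520, 1.0, lw),), c["fumarate"]),
        MetaboliteSignature(
            "4-imidazole-acetate",
            ((8.540, 0.5, lw), (7.310, 0.5, lw)),
            c["4-imidazole-acetate"],
        ),
        # dominant background metabolites of urine
        MetaboliteSignature(
            "creatinine", ((3.045, 0.6, lw), (4.060, 0.4, lw)), 100.0
        ),
        MetaboliteSignature(
            "citrate",
            ((2.545, 0.25, lw), (2.565, 0.25, lw), (2.655, 0.25, lw), (2.675, 0.25, lw)),
            30.0,
        ),
        MetaboliteSignature(
            "hippurate",
            ((3.970, 0.3, lw), (7.555, 0.15, lw), (7.640, 0.25, lw), (7.840, 0.3, lw)),
            40.0,
        ),
        MetaboliteSignature("TMAO", ((3.270, 1.0, lw),), 25.0),
        MetaboliteSignature("dimethylamine", ((2.720, 1.0, lw),), 15.0),
        # broad urea resonance sits inside the excluded 5.52-6.10 region
        MetaboliteSignature("urea", ((5.780, 1.0, 0.03),), 60.0, shift_jitter_sd=0.005),
        MetaboliteSignature("lactate", ((1.330, 0.35, lw), (1.345, 0.35, lw), (4.115, 0.3, lw)), 12.0),
        MetaboliteSignature("alanine", ((1.480, 0.5, lw), (1.495, 0.5, lw)), 8.0),
        MetaboliteSignature("creatine", ((3.030, 0.6, lw), (3.930, 0.4, lw)), 10.0),
        MetaboliteSignature("formate", ((8.460, 1.0, lw),), 3.0),
    ]


def _lorentzian_add(
    out: np.ndarray, grid: np.ndarray, center: float, area: float, linewidth: float
) -> None:
    """Accumulate an area-parameterized Lorentzian, truncated in the tails."""
    gamma = linewidth / 2.0  # half width at half maximum
    half = TRUNCATION_LINEWIDTHS * linewidth
    i0, i1 = np.searchsorted(grid, [center - half, center + half])
    if i1 <= i0:
        return
    x = grid[i0:i1] - center
    out[i0:i1] += (area / np.pi) * gamma / (x * x + gamma * gamma)


def simulate_cohort(
    config: CohortConfig,
    library: list[MetaboliteSignature] | None = None,
) -> tuple[list[Spectrum], GroundTruth]:
    """Draw one cohort of spectra plus its latent ground truth.

    Per sample: dilution log-uniform over ``dilution_range``; metabolite
    concentrations log-normal around ``base_concentration`` (times the
    group-B fold change where applicable); per-metabolite Gaussian shift
    jitter capped at +/-0.01 ppm; intensity = dilution * sum of scaled
    Lorentzians, plus an undiluted sinusoidal baseline and Gaussian noise.
    """
    if library is None:
        library = default_metabolite_library()
    if not library:
        raise ValueError("empty metabolite library")

    gmin, gmax, step = config.ppm_grid
    n_points = int(round((gmax - gmin) / step))
    grid = gmin + step * np.arange(n_points)

    rng = np.random.default_rng(config.seed)
    n_total = config.n_group_a + config.n_group_b
    groups = [config.group_a_label] * config.n_group_a + [config.group_b_label] * config.n_group_b
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]

    lo, hi = config.dilution_range
    dilutions = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_total))

    names = [m.name for m in library]
    conc = np.empty((n_total, len(library)))
    shifts = np.empty((n_total, len(library)))
    for j, met in enumerate(library):
        fold = config.effect_map.get(met.name, 1.0)
        log_noise = rng.normal(0.0, config.log_concentration_sd, size=n_total)
        per_sample_fold = np.where(
            np.asarray(groups) == config.group_b_label, fold, 1.0
        )
        conc[:, j] = met.base_concentration * per_sample_fold * np.exp(log_noise)
        shifts[:, j] = np.clip(
            rng.normal(0.0, met.shift_jitter_sd * config.jitter_scale, size=n_total),
            -0.01,
            0.01,
        )

    spectra: list[Spectrum] = []
    for i in range(n_total):
        signal = np.zeros(n_points)
        for j, met in enumerate(library):
            rel_total = sum(p[1] for p in met.peaks)
            for center, rel, lw in met.peaks:
                _lorentzian_add(
                    signal, grid, center + shifts[i, j], conc[i, j] * rel / rel_total, lw
                )
        intensity = dilutions[i] * signal
        if config.baseline_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            intensity = intensity + config.baseline_amplitude * (
                0.5 + 0.5 * np.sin(2 * np.pi * grid / 3.0 + phase)
            )
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, size=n_points)
        spectra.append(Spectrum(sample_ids[i], grid, intensity, group=groups[i]))

    truth = GroundTruth(
        sample_ids,
        groups,
        dilutions,
        pd.DataFrame(conc, index=sample_ids, columns=names),
        pd.DataFrame(shifts, index=sample_ids, columns=names),
    )
    return spectra, truth


def write_cohort(
    spectra: list[Spectrum], truth: GroundTruth, outdir: str | Path
) -> None:
    """Write spectra (long CSV), metadata CSV and ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"sample_id": sp.sample_id, "ppm": sp.ppm, "intensity": sp.intensity}
        )
        for sp in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(outdir / "spectra.csv", index=False)
    pd.DataFrame(
        {"sample_id": [sp.sample_id for sp in spectra], "group": [sp.group for sp in spectra]}
    ).to_csv(outdir / "metadata.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")


def read_cohort(indir: str | Path) -> list[Spectrum]:
    """Read spectra written by :func:`write_cohort` (long CSV + metadata)."""
    indir = Path(indir)
    long_df = pd.read_csv(indir / "spectra.csv")
    meta = pd.read_csv(indir / "metadata.csv").set_index("sample_id")["group"]
    spectra = []
    for sid, sub in long_df.groupby("sample_id", sort=False):
        spectra.append(
            Spectrum(str(sid), sub["ppm"].to_numpy(), sub["intensity"].to_numpy(),
                     group=str(meta.loc[sid]))
        )
    return spectra
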