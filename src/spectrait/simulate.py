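"""Synthetic multi-environment RIL trial generator with a trait->spectrum
forward model.

The generator emulates a wheat recombinant-inbred-line irrigation trial:
32 genotypes (30 RILs + 2 parents) x 2 irrigation treatments (FL = full,
LM = limited) x 2 years x 3 replicates, i.e. 384 plots.  Plot-level values
of three agronomic traits -- shoot dry weight (DW, kg m-2), biomass water
content (WC, %, fresh basis) and grain yield (GY, t ha-1) -- are drawn from
the additive model

    y = treatment mean + genotype effect + GxE effect + residual

with genotype effects multivariate normal across the three traits
(covariance diag(sg) * C * diag(sg), C the genetic correlation matrix),
independent GxE effects per treatment-by-year environment, and independent
plot residuals.  All realized draws are retained as ground truth so that
downstream estimators (variance components, H2, rg) have a known target.

Each plot's reflectance spectrum is a deterministic, phenomenological
function of its traits plus additive sensor noise:

* visible pigment absorption wells near 490 and 670 nm deepening with GY,
* a red-edge sigmoid (inflection near 722 nm) whose amplitude grows and
  whose inflection shifts to longer wavelengths with DW,
* an NIR plateau (760-1300 nm) whose level rises with DW,
* Gaussian water-absorption wells at 970, 1200, 1450 and 1900 nm deepening
  with WC,
* a SWIR dry-matter slope beyond 1300 nm tied to DW.

Trait-to-spectrum coupling is multiplied by a per-treatment gain, defaulting
to a weaker coupling under FL than under LM: under full irrigation a closed,
saturated canopy expresses genotypic trait differences only weakly in its
reflectance, which is the regime contrast the pipeline is meant to resolve.
This is a feature-planting model, not a radiative-transfer one: it puts
recoverable band-trait associations at physiologically named regions and
nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import GRID, SpectraSet

TRAITS = ("DW", "WC", "GY")

#: red-edge sigmoid inflection (nm) at reference trait values
RED_EDGE_INFLECTION_NM = 722.0
#: centres of the planted water-absorption wells (nm)
WATER_WELLS_NM = (970.0, 1200.0, 1450.0, 1900.0)
#: centres of the planted visible pigment wells (nm)
PIGMENT_WELLS_NM = (490.0, 670.0)

# reference values and scales that turn raw traits into dimensionless
# deviations for the forward model
_TRAIT_REF = {"DW": 1.7, "WC": 69.0, "GY": 5.0}
_TRAIT_SCALE = {"DW": 1.0, "WC": 20.0, "GY": 3.0}


class ConfigurationError(ValueError):
    pass


def _default_trait_means() -> dict[str, tuple[float, float, float]]:
    return {"FL": (2.0, 74.0, 6.4), "LM": (1.3, 64.0, 3.5)}


def _default_var_components() -> dict[str, tuple[float, float, float]]:
    # (sigma2_G, sigma2_GE, sigma2_e) per trait, squared trait units;
    # chosen to give broad-sense heritabilities near 0.85 at e=2, r=3
    return {"DW": (0.04, 0.008, 0.01), "WC": (9.0, 1.8, 2.5), "GY": (0.5, 0.1, 0.15)}


def _default_genetic_corr() -> np.ndarray:
    # order (DW, WC, GY); moderate DW-WC and WC-GY, strong DW-GY
    return np.array([[1.0, 0.6, 0.8], [0.6, 1.0, 0.6], [0.8, 0.6, 1.0]])


def _default_gain() -> dict[str, float]:
    return {"FL": 0.35, "LM": 1.0}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic split-plot RIL trial."""

    n_genotypes: int = 32
    treatments: tuple[str, ...] = ("FL", "LM")
    n_years: int = 2
    n_reps: int = 3
    trait_means: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_trait_means
    )
    var_components: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_var_components
    )
    genetic_corr: np.ndarray = field(default_factory=_default_genetic_corr)
    spectral_noise_sd: float = 0.01
    trait_spectrum_gain: dict[str, float] = field(default_factory=_default_gain)
    seed: int = 0

    def __post_init__(self) -> None:
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.n_years < 1 or self.n_reps < 1:
            raise ConfigurationError("counts must be positive")
        c = self.genetic_corr
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
            raise ConfigurationError("genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ConfigurationError("genetic_corr is not positive semidefinite")
        for t in self.treatments:
            if t not in self.trait_means:
                raise ConfigurationError(f"no trait means for treatment {t!r}")
            dw, wc, gy = self.trait_means[t]
            if dw <= 0 or gy <= 0 or not (0 < wc < 100):
                raise ConfigurationError(f"invalid trait means for {t!r}")
            if t not in self.trait_spectrum_gain:
                raise ConfigurationError(f"no spectral gain for treatment {t!r}")
            if not (0 < self.trait_spectrum_gain[t] <= 1):
                raise ConfigurationError("trait_spectrum_gain must lie in (0, 1]")
        for t in TRAITS:
            if any(v < 0 for v in self.var_components[t]):
                raise ConfigurationError("variances must be nonnegative")
        if self.spectral_noise_sd < 0:
            raise ConfigurationError("spectral_noise_sd must be nonnegative")

    @property
    def environments(self) -> list[tuple[str, str]]:
        """Treatment x year combinations, the G x E environments."""
        years = [f"Y{i + 1}" for i in range(self.n_years)]
        return [(t, y) for t in self.treatments for y in years]

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * len(self.treatments) * self.n_years * self.n_reps

    # ------------------------------------------------------------- YAML I/O

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "treatments" in raw:
            raw["treatments"] = tuple(raw["treatments"])
        for key in ("trait_means", "var_components"):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        if "genetic_corr" in raw:
            raw["genetic_corr"] = np.asarray(raw["genetic_corr"], dtype=float)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_genotypes": self.n_genotypes,
            "treatments": list(self.treatments),
            "n_years": self.n_years,
            "n_reps": self.n_reps,
            "trait_means": {k: list(v) for k, v in self.trait_means.items()},
            "var_components": {k: list(v) for k, v in self.var_components.items()},
            "genetic_corr": self.genetic_corr.tolist(),
            "spectral_noise_sd": self.spectral_noise_sd,
            "trait_spectrum_gain": dict(self.trait_spectrum_gain),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class SyntheticExperiment:
    """A realized trial: design, plot traits, spectra, and the truth draws."""

    config: SimulationConfig
    traits: pd.DataFrame
    spectra: SpectraSet | None
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        if self.spectra is not None:
            self.spectra.write_csv(outdir / "spectra.csv", dialect="long")
        truth_json = {
            "genotype_effects": {
                t: self.truth["genotype_effects"][t].tolist() for t in TRAITS
            },
            "ge_effects": {t: self.truth["ge_effects"][t].tolist() for t in TRAITS},
            "residuals": {t: self.truth["residuals"][t].tolist() for t in TRAITS},
            "genotypes": self.truth["genotypes"],
            "environments": self.truth["environments"],
        }
        (outdir / "truth.json").write_text(json.dumps(truth_json))
        self.config.to_yaml(outdir / "config.yaml")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Named substream so each stochastic stage is independently replayable."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_genetic_effects(config: SimulationConfig) -> dict:
    """Draw genotype and GxE effects for the three traits.

    Genotype effects: zero-mean multivariate normal across traits with
    covariance diag(sg) C diag(sg).  GxE effects: independent zero-mean
    normal per trait per treatment-by-year environment.
    """
    sg = np.array([np.sqrt(config.var_components[t][0]) for t in TRAITS])
    cov = np.diag(sg) @ config.genetic_corr @ np.diag(sg)
    rng_g = _rng(config, 0)
    g_draws = rng_g.multivariate_normal(
        np.zeros(3), cov, size=config.n_genotypes, method="svd"
    )
    rng_ge = _rng(config, 1)
    n_env = len(config.environments)
    ge = {
        t: rng_ge.normal(
            0.0,
            np.sqrt(config.var_components[t][1]),
            size=(config.n_genotypes, n_env),
        )
        for t in TRAITS
    }
    return {
        "genotype_effects": {t: g_draws[:, i] for i, t in enumerate(TRAITS)},
        "ge_effects": ge,
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def traits_to_spectrum(
    dw: float,
    wc: float,
    gy: float,
    treatment: str,
    config: SimulationConfig,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic forward model from traits to canonical reflectance.

    ``noise`` is an optional pre-drawn additive perturbation (same length as
    the grid); pass None for the noiseless spectrum.  Output is clipped to
    [0.001, 0.999].
    """
    if dw <= 0 or gy <= 0 or not (0 < wc < 100):
        raise ValueError(f"trait out of range: DW={dw}, WC={wc}, GY={gy}")
    gain = config.trait_spectrum_gain[treatment]
    d = gain * (dw - _TRAIT_REF["DW"]) / _TRAIT_SCALE["DW"]
    w = gain * (wc - _TRAIT_REF["WC"]) / _TRAIT_SCALE["WC"]
    g = gain * (gy - _TRAIT_REF["GY"]) / _TRAIT_SCALE["GY"]

    wl = GRID.astype(float)
    vis_level = 0.10
    nir_level = 0.45 + 0.10 * d
    # red edge: amplitude and inflection position both increase with DW; the
    # positional shift dominates near the inflection, making the 700-740 nm
    # region the most DW-sensitive part of the spectrum (the classic
    # red-edge shift with biomass/chlorophyll)
    center = RED_EDGE_INFLECTION_NM + 25.0 * d
    edge = _sigmoid((wl - center) / 10.0)
    r = vis_level + (nir_level - vis_level) * edge
    # pigment wells (blue, red) deepen with GY
    r -= (0.040 + 0.020 * g) * _gauss(wl, PIGMENT_WELLS_NM[0], 22.0)
    r -= (0.055 + 0.030 * g) * _gauss(wl, PIGMENT_WELLS_NM[1], 18.0)
    # water wells deepen with WC; the 970 nm well gets the strongest
    # coupling so the canonical NIR water feature is recoverable against
    # sensor noise
    r -= (0.050 + 0.080 * w) * _gauss(wl, WATER_WELLS_NM[0], 30.0)
    r -= (0.080 + 0.050 * w) * _gauss(wl, WATER_WELLS_NM[1], 40.0)
    r -= (0.200 + 0.100 * w) * _gauss(wl, WATER_WELLS_NM[2], 55.0)
    r -= (0.260 + 0.120 * w) * _gauss(wl, WATER_WELLS_NM[3], 75.0)
    # SWIR dry-matter slope tied to DW
    r -= (0.120 + 0.050 * d) * np.clip((wl - 1300.0) / 1200.0, 0.0, 1.0)
    if noise is not None:
        r = r + noise
    return np.clip(r, 0.001, 0.999)


def generate_experiment(
    config: SimulationConfig, with_spectra: bool = True
) -> SyntheticExperiment:
    """Realize a full factorial trial: design, traits, spectra, truth."""
    effects = simulate_genetic_effects(config)
    genotypes = [f"G{i + 1:02d}" for i in range(config.n_genotypes)]
    envs = config.environments
    env_labels = [f"{t}:{y}" for t, y in envs]

    rows = []
    for gi, geno in enumerate(genotypes):
        for ei, (treatment, year) in enumerate(envs):
            for rep in range(1, config.n_reps + 1):
                rows.append((gi, geno, ei, treatment, year, rep))
    design = pd.DataFrame(
        rows, columns=["gi", "genotype", "ei", "treatment", "year", "replicate"]
    )
    design["plot_id"] = (
        design["genotype"]
        + "_"
        + design["treatment"]
        + "_"
        + design["year"]
        + "_R"
        + design["replicate"].astype(str)
    )

    rng_res = _rng(config, 2)
    n = len(design)
    residuals = {
        t: rng_res.normal(0.0, np.sqrt(config.var_components[t][2]), size=n)
        for t in TRAITS
    }
    # physical bounds; rare extreme draws are truncated and the truncation
    # is absorbed into the stored residual so that the additive identity
    # (value = mean + genotype + GxE + residual) stays exact
    bounds = {"DW": (0.05, np.inf), "WC": (1.0, 99.0), "GY": (0.05, np.inf)}
    trait_values: dict[str, np.ndarray] = {}
    for i, t in enumerate(TRAITS):
        means = np.array(
            [config.trait_means[tr][i] for tr in design["treatment"]], dtype=float
        )
        structural = (
            means
            + effects["genotype_effects"][t][design["gi"]]
            + effects["ge_effects"][t][design["gi"], design["ei"]]
        )
        vals = np.clip(structural + residuals[t], *bounds[t])
        residuals[t] = vals - structural
        trait_values[t] = vals
    traits = design[["plot_id", "genotype", "treatment", "year", "replicate"]].copy()
    for t in TRAITS:
        traits[t] = trait_values[t]
    # fresh weight implied by the fresh-basis water-content convention
    traits["FW"] = traits["DW"] / (1.0 - traits["WC"] / 100.0)

    spectra = None
    if with_spectra:
        rng_noise = _rng(config, 3)
        values = np.empty((n, GRID.size))
        for k in range(n):
            noise = (
                rng_noise.normal(0.0, config.spectral_noise_sd, size=GRID.size)
                if config.spectral_noise_sd > 0
                else None
            )
            values[k] = traits_to_spectrum(
                trait_values["DW"][k],
                trait_values["WC"][k],
                trait_values["GY"][k],
                str(design["treatment"].iloc[k]),
                config,
                noise=noise,
            )
        spectra = SpectraSet(
            meta=traits[["plot_id", "genotype", "treatment", "year", "replicate"]].copy(),
            values=values,
            provenance=f"synthetic seed={config.seed}",
        )

    truth = {
        "genotype_effects": effects["genotype_effects"],
        "ge_effects": effects["ge_effects"],
        "residuals": residuals,
        "genotypes": genotypes,
        "environments": env_labels,
    }
    return SyntheticExperiment(config=config, traits=traits, spectra=spectra, truth=truth)
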