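"""Quantitative-genetic screening: variance components, heritability, rg.

Variance components are estimated by the method of moments from the expected
mean squares of the balanced two-way genotype x environment ANOVA with r
replicates per cell, environments being treatment-by-year combinations:

    MS_G   = sigma2_e + r * sigma2_GE + r * e * sigma2_G
    MS_GE  = sigma2_e + r * sigma2_GE
    MS_err = sigma2_e

so sigma2_G = (MS_G - MS_GE)/(r e) and sigma2_GE = (MS_GE - MS_err)/r.
The phenotypic variance on a genotype-mean basis is

    sigma2_P = sigma2_G + sigma2_GE / e + sigma2_e / (r e)

and broad-sense heritability H2 = sigma2_G / sigma2_P.  Genetic covariance
between two variables measured on the same plots uses the identical
decomposition applied to mean cross-products, giving the genetic correlation
rg = Cov_G(x, y) / sqrt(Var_G(x) * Var_G(y)).

Negative moment estimates are truncated at zero and flagged; rg values that
fall outside [-1, 1] (possible with moment estimators) are clipped and
flagged.  Split-plot error strata are deliberately collapsed into a single
residual term, matching the single-residual phenotypic-variance formula
above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised for unbalanced or otherwise unusable experimental layouts."""


def water_content(fw: float, dw: float, basis: str = "fresh") -> float:
    """Biomass water content, percent.

    Fresh basis (default): 100 * (FW - DW) / FW, bounded in (0, 100).
    Dry basis: 100 * (FW - DW) / DW, unbounded above.
    """
    fw = float(fw)
    dw = float(dw)
    if not (fw > dw > 0):
        raise ValueError(f"need FW > DW > 0, got FW={fw}, DW={dw}")
    if basis == "fresh":
        return 100.0 * (fw - dw) / fw
    if basis == "dry":
        return 100.0 * (fw - dw) / dw
    raise ValueError(f"unknown basis {basis!r}")


@dataclass
class VarianceComponents:
    """Moment estimates of genetic, GxE, and residual variance."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    e: int
    r: int
    truncated: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_ge / self.e + self.sigma2_e / (self.r * self.e)


@dataclass
class HeritabilityEstimate:
    name: str
    scope: str
    h2: float
    components: VarianceComponents


@dataclass
class GeneticCorrelationEstimate:
    x_name: str
    y_name: str
    rg: float
    cov_g: float
    var_x: float
    var_y: float
    clipped: bool = False
    undefined: bool = False


def _design_arrays(
    values: np.ndarray, genotype: np.ndarray, environment: np.ndarray
) -> tuple[np.ndarray, int, int, int]:
    """Reshape plot observations into a (g, e, r) cell array; enforce balance."""
    frame = pd.DataFrame(
        {"g": genotype, "env": environment, "y": np.asarray(values, dtype=float)}
    )
    counts = frame.groupby(["g", "env"], sort=True).size()
    g_levels = frame["g"].nunique()
    e_levels = frame["env"].nunique()
    if len(counts) != g_levels * e_levels or counts.nunique() != 1:
        raise DesignError("layout is not a balanced genotype x environment table")
    r = int(counts.iloc[0])
    frame = frame.sort_values(["g", "env"]).reset_index(drop=True)
    cells = frame["y"].to_numpy().reshape(g_levels, e_levels, r)
    return cells, g_levels, e_levels, r


def _mean_squares(cells: np.ndarray) -> tuple[float, float, float]:
    """(MS_G, MS_GE, MS_err) from the balanced (g, e, r) cell array."""
    g, e, r = cells.shape
    cell_means = cells.mean(axis=2)
    g_means = cell_means.mean(axis=1)
    e_means = cell_means.mean(axis=0)
    grand = cell_means.mean()
    ss_g = r * e * float(((g_means - grand) ** 2).sum())
    interaction = cell_means - g_means[:, None] - e_means[None, :] + grand
    ss_ge = r * float((interaction**2).sum())
    ss_err = float(((cells - cell_means[:, :, None]) ** 2).sum())
    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1)) if e > 1 else np.nan
    ms_err = ss_err / (g * e * (r - 1)) if r > 1 else 0.0
    return ms_g, ms_ge, ms_err


def variance_components(
    values: np.ndarray, genotype: np.ndarray, environment: np.ndarray
) -> VarianceComponents:
    """Method-of-moments variance components for one variable."""
    cells, g, e, r = _design_arrays(values, genotype, environment)
    if g < 2:
        raise DesignError("need at least two genotypes")
    ms_g, ms_ge, ms_err = _mean_squares(cells)
    flags: list[str] = []
    truncated: list[str] = []
    if r == 1:
        flags.append("single replicate: residual variance not estimable, set to 0")
    if e < 2:
        flags.append("single environment: GxE not estimable, set to 0")
        sigma2_ge = 0.0
        sigma2_g = (ms_g - ms_err) / (r * e)
    else:
        sigma2_ge = (ms_ge - ms_err) / r
        sigma2_g = (ms_g - ms_ge) / (r * e)
    sigma2_e = ms_err
    if sigma2_ge < 0:
        truncated.append("sigma2_ge")
        sigma2_ge = 0.0
    if sigma2_g < 0:
        truncated.append("sigma2_g")
        sigma2_g = 0.0
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_ge=sigma2_ge,
        sigma2_e=sigma2_e,
        e=e,
        r=r,
        truncated=truncated,
        flags=flags,
    )


def heritability(
    vc: VarianceComponents, name: str = "", scope: str = ""
) -> HeritabilityEstimate:
    """Broad-sense heritability H2 = sigma2_G / sigma2_P on a mean basis."""
    sp = vc.sigma2_p
    if sp == 0:
        raise ValueError("phenotypic variance is zero; H2 undefined")
    return HeritabilityEstimate(name=name, scope=scope, h2=vc.sigma2_g / sp, components=vc)


def _cross_products(cells_x: np.ndarray, cells_y: np.ndarray) -> tuple[float, float, float]:
    """Mean cross-products (MCP_G, MCP_GE, MCP_err), the MS analogues."""
    g, e, r = cells_x.shape
    cmx = cells_x.mean(axis=2)
    cmy = cells_y.mean(axis=2)
    gx, gy = cmx.mean(axis=1), cmy.mean(axis=1)
    ex, ey = cmx.mean(axis=0), cmy.mean(axis=0)
    grx, gry = cmx.mean(), cmy.mean()
    cp_g = r * e * float(((gx - grx) * (gy - gry)).sum())
    ix = cmx - gx[:, None] - ex[None, :] + grx
    iy = cmy - gy[:, None] - ey[None, :] + gry
    cp_ge = r * float((ix * iy).sum())
    cp_err = float(((cells_x - cmx[:, :, None]) * (cells_y - cmy[:, :, None])).sum())
    mcp_g = cp_g / (g - 1)
    mcp_ge = cp_ge / ((g - 1) * (e - 1)) if e > 1 else np.nan
    mcp_err = cp_err / (g * e * (r - 1)) if r > 1 else 0.0
    return mcp_g, mcp_ge, mcp_err


def genetic_correlation(
    values_x: np.ndarray,
    values_y: np.ndarray,
    genotype: np.ndarray,
    environment: np.ndarray,
) -> GeneticCorrelationEstimate:
    """Genetic correlation between two variables on the same balanced design."""
    cells_x, g, e, r = _design_arrays(values_x, genotype, environment)
    cells_y, g2, e2, r2 = _design_arrays(values_y, genotype, environment)
    if (g, e, r) != (g2, e2, r2):
        raise DesignError("the two variables are on different layouts")
    vcx = variance_components(values_x, genotype, environment)
    vcy = variance_components(values_y, genotype, environment)
    mcp_g, mcp_ge, _ = _cross_products(cells_x, cells_y)
    if e < 2:
        cov_g = mcp_g / (r * e)
    else:
        cov_g = (mcp_g - mcp_ge) / (r * e)
    if vcx.sigma2_g <= 0 or vcy.sigma2_g <= 0:
        return GeneticCorrelationEstimate(
            x_name="x", y_name="y", rg=np.nan, cov_g=cov_g,
            var_x=vcx.sigma2_g, var_y=vcy.sigma2_g, undefined=True,
        )
    rg = cov_g / np.sqrt(vcx.sigma2_g * vcy.sigma2_g)
    clipped = False
    if abs(rg) > 1:
        rg = float(np.clip(rg, -1.0, 1.0))
        clipped = True
    return GeneticCorrelationEstimate(
        x_name="x", y_name="y", rg=float(rg), cov_g=cov_g,
        var_x=vcx.sigma2_g, var_y=vcy.sigma2_g, clipped=clipped,
    )


def screen_indices(
    sri_table: pd.DataFrame,
    traits: pd.DataFrame,
    trait_names: list[str] | None = None,
    scope: str = "",
) -> pd.DataFrame:
    """Genetic correlations and heritabilities for all indices and traits.

    ``traits`` must carry plot_id, genotype, treatment, year plus the trait
    columns, aligned with the rows of ``sri_table`` by plot_id.  Returns a
    tidy frame: one row per (variable, trait) pair with rg, plus one row per
    variable with its H2 (trait column empty).
    """
    if trait_names is None:
        trait_names = ["DW", "WC", "GY"]
    meta = traits.set_index("plot_id").loc[sri_table.index]
    genotype = meta["genotype"].to_numpy()
    environment = (meta["treatment"].astype(str) + ":" + meta["year"].astype(str)).to_numpy()

    rows = []
    variables: dict[str, np.ndarray] = {
        name: sri_table[name].to_numpy(dtype=float) for name in sri_table.columns
    }
    for t in trait_names:
        variables[t] = meta[t].to_numpy(dtype=float)

    for name, vals in variables.items():
        vc = variance_components(vals, genotype, environment)
        h2 = heritability(vc, name=name, scope=scope)
        rows.append(
            {
                "variable": name, "trait": "", "scope": scope, "rg": np.nan,
                "H2": h2.h2, "sigma2_g": vc.sigma2_g, "sigma2_ge": vc.sigma2_ge,
                "sigma2_e": vc.sigma2_e, "flags": ";".join(vc.truncated + vc.flags),
            }
        )
    for name in sri_table.columns:
        for t in trait_names:
            est = genetic_correlation(variables[t], variables[name], genotype, environment)
            flags = []
            if est.clipped:
                flags.append("rg_clipped")
            if est.undefined:
                flags.append("rg_undefined")
            rows.append(
                {
                    "variable": name, "trait": t, "scope": scope, "rg": est.rg,
                    "H2": np.nan, "sigma2_g": np.nan, "sigma2_ge": np.nan,
                    "sigma2_e": np.nan, "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(rows)
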