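"""Per-band and per-index narrow-sense / genomic heritability profiles.

Each wavelength band (or each spectral index) is fitted separately as the
response of a mixed model with fixed covariates and one relationship-matrix
random effect (pedigree A or genomic G, entered through its eigen-loadings),
and heritability is summarized as the posterior mean of

    h2 = var_genetic / (var_genetic + var_residual)

exactly the printed formulas: the fixed-covariate (structure, provenance,
block) variance is omitted from the denominator. Bands are fitted
independently with seeds keyed to the wavelength, so the profile is
invariant to band processing order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes
from .relmat import FactorLoadings

VISIBLE = (400.0, 700.0)
SWIR = (1400.0, 2400.0)


def h2_from_varcomps(var_g: float, var_e: float) -> float:
    """var_g / (var_g + var_e)."""
    if var_g < 0 or var_e < 0:
        raise ValueError("variance components must be non-negative")
    if var_g + var_e == 0:
        raise ValueError("both variance components are zero")
    return var_g / (var_g + var_e)


def _band_seed(base_seed: int, key: float) -> int:
    return (int(base_seed) * 1_000_003 + int(round(key * 16))) % (2 ** 31)


def _fit_band(y: np.ndarray, loadings: FactorLoadings, covariates,
              mcmc: bayes.MCMCSettings) -> tuple[float, float]:
    """One band fit; returns (posterior mean h2, posterior sd h2).

    Variance components carry flat reference priors (df = -2) rather than
    the informative scaled-inverse-chi-squared defaults used for prediction:
    half-sib designs identify the additive/residual ratio weakly, and an
    informative prior scale would dominate the heritability estimate.
    """
    blocks = []
    if covariates is not None and np.shape(covariates)[1] > 0:
        blocks.append(bayes.EffectBlock("covariates", np.asarray(covariates, float),
                                        prior="fixed"))
    blocks.append(bayes.EffectBlock("genetic", loadings.loadings, prior="brr",
                                    df=-2.0))
    result = bayes.fit(y, blocks, mcmc=mcmc, residual_df=-2.0)
    draws = result.h2("genetic")
    return float(draws.mean()), float(draws.std())


def wavelength_h2_profile(values: np.ndarray, wavelengths: np.ndarray,
                          loadings: FactorLoadings, covariates=None,
                          kind: str = "genomic", preset: str = "fast",
                          seed: int = 0) -> pd.DataFrame:
    """Heritability profile along the reflectance curve.

    ``values`` is the (n, w) band matrix aligned with ``loadings`` rows;
    ``covariates`` the fixed design (block / structure or provenance terms of
    the per-band models). Bands with zero variance get NaN with a flag.
    Returns a frame with columns wavelength, h2, sd, kind, flag.
    """
    values = np.asarray(values, dtype=float)
    rows = []
    for k, wl in enumerate(np.asarray(wavelengths, dtype=float)):
        y = values[:, k]
        if np.var(y) <= 0:
            rows.append((wl, np.nan, np.nan, kind, "zero-variance"))
            continue
        mcmc = bayes.settings(preset, seed=_band_seed(seed, wl))
        h2, sd = _fit_band(y, loadings, covariates, mcmc)
        rows.append((wl, h2, sd, kind, ""))
    return pd.DataFrame(rows, columns=["wavelength", "h2", "sd", "kind", "flag"])


def sri_h2(sri: pd.DataFrame, loadings: FactorLoadings, covariates=None,
           kind: str = "genomic", preset: str = "desk", seed: int = 0) -> pd.DataFrame:
    """Heritability of each spectral index column (same machinery per index)."""
    import zlib

    rows = []
    for name in sri.columns:
        y = sri[name].to_numpy(dtype=float)
        if np.var(y) <= 0 or not np.all(np.isfinite(y)):
            rows.append((name, np.nan, np.nan, kind, "degenerate"))
            continue
        # seed keyed to the column content: identical indices (duplicated
        # columns) get identical chains regardless of name or position
        key = zlib.crc32(y.tobytes()) % 65_536
        mcmc = bayes.settings(preset, seed=_band_seed(seed, float(key)))
        h2, sd = _fit_band(y, loadings, covariates, mcmc)
        rows.append((name, h2, sd, kind, ""))
    return pd.DataFrame(rows, columns=["index", "h2", "sd", "kind", "flag"])


def region_means(profile: pd.DataFrame) -> dict[str, float]:
    """Mean h2 in the visible and SWIR regions (profile-shape summary)."""
    wl = profile["wavelength"]
    out = {}
    for name, (lo, hi) in {"visible": VISIBLE, "swir": SWIR}.items():
        sel = profile[(wl >= lo) & (wl <= hi)]["h2"]
        out[name] = float(sel.mean())
    return out


def plot_profile(profiles: list[pd.DataFrame], path=None):
    """h2 vs wavelength with visible/NIR/SWIR annotations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for prof in profiles:
        ax.plot(prof["wavelength"], prof["h2"], label=prof["kind"].iloc[0])
    for x in (700, 1400):
        ax.axvline(x, color="grey", lw=0.6, ls="--")
    for label, x in (("visible", 550), ("NIR", 1050), ("SWIR", 1900)):
        ax.text(x, ax.get_ylim()[1] * 0.95, label, ha="center", fontsize=9)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("heritability")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
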