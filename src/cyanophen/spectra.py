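"""Spectral preprocessing, reflectance indices, stepwise selection.

Preprocessing follows the chemometrics convention for reflectance curves:
per-band centering/scaling, then a Savitzky-Golay first derivative along the
wavelength axis (window of 37 grid points by default), with the edge bands
lacking a full window dropped. Spectral reflectance indices (SRIs) are
evaluated on the raw reflectance, their published definitions; the two
derivative-based indices use the Savitzky-Golay first derivative of the raw
curve. Candidate SRIs are screened for a trait by bidirectional stepwise
ordinary least squares under AIC, with variance-inflation-factor reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .syndata import SpectraMatrix


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ProcessedSpectra:
    values: np.ndarray          # (n, w') preprocessed band values
    wavelengths: np.ndarray     # (w',) grid after edge trimming
    ids: list[str]
    descriptor: dict


def preprocess(spectra: SpectraMatrix, window: int = 37, polyorder: int = 2,
               derivative: int = 1, center: bool = True,
               scale: bool = True) -> ProcessedSpectra:
    """Center/scale per band, then Savitzky-Golay derivative per individual.

    The window must be odd with ``window > polyorder >= derivative`` and the
    wavelength grid uniform. Half a window is lost at each edge, so the
    output has ``w - (window - 1)`` bands.
    """
    wl = spectra.wavelengths
    step = np.diff(wl)
    if wl.size < 2 or not np.allclose(step, step[0]):
        raise ValueError("wavelength grid must be uniform")
    if window % 2 == 0 or window >= wl.size:
        raise ValueError("window must be odd and smaller than the grid")
    if not (window > polyorder >= derivative):
        raise ValueError("require window > polyorder >= derivative")
    X = spectra.values.astype(float).copy()
    if center:
        X -= X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X /= np.where(sd > 0, sd, 1.0)
    out = savgol_filter(X, window_length=window, polyorder=polyorder,
                        deriv=derivative, delta=float(step[0]), axis=1,
                        mode="interp")
    half = (window - 1) // 2
    sl = slice(half, wl.size - half)
    return ProcessedSpectra(out[:, sl], wl[sl], list(spectra.ids),
                            {"window": window, "polyorder": polyorder,
                             "derivative": derivative, "center": center,
                             "scale": scale})


# ---------------------------------------------------------------------------
# SRI registry
# ---------------------------------------------------------------------------

class _BandAccessor:
    """Nearest-band reflectance lookup with a +-2 nm tolerance.

    With ``interpolate=True`` an off-grid wavelength inside the grid range is
    linearly interpolated instead of raising — appropriate for strided grids,
    since reflectance curves are smooth at the 10-nm scale.
    """

    def __init__(self, values: np.ndarray, wavelengths: np.ndarray,
                 tol: float = 2.0, context: str = "",
                 interpolate: bool = False) -> None:
        self.values = values
        self.wl = wavelengths
        self.tol = tol
        self.context = context
        self.interpolate = interpolate

    def __call__(self, nm: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.wl - nm)))
        if abs(self.wl[k] - nm) <= self.tol:
            return self.values[:, k]
        if self.interpolate and self.wl[0] <= nm <= self.wl[-1]:
            hi = int(np.searchsorted(self.wl, nm))
            lo = hi - 1
            t = (nm - self.wl[lo]) / (self.wl[hi] - self.wl[lo])
            return (1 - t) * self.values[:, lo] + t * self.values[:, hi]
        raise ValueError(f"{self.context}: no band within "
                         f"{self.tol} nm of {nm} nm")

    def deriv_max(self, lo: float, hi: float) -> np.ndarray:
        """Max of the first derivative of raw reflectance over [lo, hi] nm."""
        mask = (self.wl >= lo) & (self.wl <= hi)
        if not mask.any():
            raise ValueError(f"{self.context}: empty derivative range {lo}-{hi}")
        step = float(self.wl[1] - self.wl[0])
        window = min(37, (mask.sum() // 2) * 2 + 1, (self.wl.size // 2) * 2 - 1)
        window = max(window, 5)
        d = savgol_filter(self.values, window_length=window, polyorder=2,
                          deriv=1, delta=step, axis=1, mode="interp")
        return d[:, mask].max(axis=1)


#: name -> (callable(bands) -> values, human-readable formula)
SRI_REGISTRY: dict[str, tuple] = {}


def register_sri(name: str, formula: str):
    def deco(fn):
        SRI_REGISTRY[name] = (fn, formula)
        return fn
    return deco


register_sri("LRDSI1", "6.9*(R605/R455) - 1.2")(lambda R: 6.9 * (R(605) / R(455)) - 1.2)
register_sri("ARI", "1/R550 - 1/R700")(lambda R: 1.0 / R(550) - 1.0 / R(700))
register_sri("BRI", "R450/R690")(lambda R: R(450) / R(690))
register_sri("SR7", "R440/R690")(lambda R: R(440) / R(690))
register_sri("BGI", "R450/R550")(lambda R: R(450) / R(550))
register_sri("GMI1", "R750/R550")(lambda R: R(750) / R(550))
register_sri("SR3", "R750/R550")(lambda R: R(750) / R(550))
register_sri("SR10", "R685/R655")(lambda R: R(685) / R(655))
register_sri("NPCI", "(R680-R430)/(R680+R430)")(
    lambda R: (R(680) - R(430)) / (R(680) + R(430)))


@register_sri("NDLI", "(log(1/R1754)-log(1/R1680))/(log(1/R1754)+log(1/R1680))")
def _ndli(R):
    a, b = np.log(1.0 / R(1754)), np.log(1.0 / R(1680))
    return (a - b) / (a + b)


@register_sri("NDNI", "(log(1/R1510)-log(1/R1680))/(log(1/R1510)+log(1/R1680))")
def _ndni(R):
    a, b = np.log(1.0 / R(1510)), np.log(1.0 / R(1680))
    return (a - b) / (a + b)


@register_sri("EGFN", "(maxD650:750 - maxD500:550)/(maxD650:750 + maxD500:550)")
def _egfn(R):
    red, green = R.deriv_max(650, 750), R.deriv_max(500, 550)
    return (red - green) / (red + green)


@register_sri("EGFNR", "maxD650:750 / maxD500:550")
def _egfnr(R):
    return R.deriv_max(650, 750) / R.deriv_max(500, 550)


def compute_sri(spectra: SpectraMatrix, names: list[str] | None = None,
                interpolate: bool = False) -> pd.DataFrame:
    """Evaluate named registry indices on raw reflectance; rows = individuals.

    Division by a zero denominator yields NaN (with a warning) rather than an
    error, so a single degenerate spectrum does not abort a batch. Set
    ``interpolate`` on strided grids whose bands miss an index's wavelengths
    by more than the +-2 nm tolerance.
    """
    if names is None:
        names = list(SRI_REGISTRY)
    out = {}
    for name in names:
        if name not in SRI_REGISTRY:
            raise KeyError(f"unknown SRI {name!r}; registered: {sorted(SRI_REGISTRY)}")
        fn, _ = SRI_REGISTRY[name]
        R = _BandAccessor(spectra.values, spectra.wavelengths, context=name,
                          interpolate=interpolate)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.asarray(fn(R), dtype=float)
        if not np.all(np.isfinite(vals)):
            warnings.warn(f"SRI {name}: {np.sum(~np.isfinite(vals))} non-finite values")
        out[name] = vals
    return pd.DataFrame(out, index=spectra.ids)


# ---------------------------------------------------------------------------
# stepwise selection and collinearity
# ---------------------------------------------------------------------------

def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R2_j) per column; +inf on exact
    collinearity. Interpretation bands: <10 none, 10-100 strong, >=100
    severe multicollinearity."""
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two columns")
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_class(v: float) -> str:
    if v >= 100:
        return "severe"
    if v >= 10:
        return "strong"
    return "none"


@dataclass
class SelectionReport:
    selected: list[str]
    aic_trajectory: list[float]
    vif: pd.Series
    partial_r2: pd.Series
    r_squared: float
    p_values: pd.Series
    coefficients: pd.Series

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "aic_trajectory": self.aic_trajectory,
            "vif": self.vif.to_dict(),
            "partial_r2": self.partial_r2.to_dict(),
            "r_squared": self.r_squared,
            "p_values": self.p_values.to_dict(),
            "coefficients": self.coefficients.to_dict(),
        }


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def stepwise_select(sri: pd.DataFrame, trait: np.ndarray | pd.Series,
                    max_steps: int = 100) -> SelectionReport:
    """Bidirectional stepwise OLS from the intercept-only model under
    AIC = n log(RSS/n) + 2k.

    Candidates are standardized (AIC is invariant to affine rescaling, the
    standardization only conditions the linear algebra); constant columns
    are excluded with a warning. Selection stops when neither adding nor
    dropping an index lowers the AIC. Coefficient p-values, per-index
    partial R2 and VIFs of the selected set are reported post hoc.
    """
    import statsmodels.api as sm

    y = np.asarray(trait, dtype=float)
    n = y.size
    X = sri.copy().astype(float)
    sds = X.std(axis=0, ddof=0)
    const = sds <= 0
    if const.any():
        warnings.warn(f"dropping constant candidates: {list(X.columns[const])}")
        X = X.loc[:, ~const]
        sds = sds[~const]
    X = (X - X.mean(axis=0)) / sds

    def aic(cols: list[str]) -> float:
        M = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
        return n * np.log(max(_ols_rss(y, M), 1e-300) / n) + 2 * (len(cols) + 1)

    selected: list[str] = []
    trajectory = [aic(selected)]
    for _ in range(max_steps):
        current = trajectory[-1]
        moves: list[tuple[float, str, str]] = []
        for c in X.columns:
            if c not in selected:
                moves.append((aic(selected + [c]), "add", c))
        for c in selected:
            moves.append((aic([s for s in selected if s != c]), "drop", c))
        if not moves:
            break
        best_aic, action, col = min(moves, key=lambda t: t[0])
        if best_aic >= current - 1e-10:
            break
        selected = (selected + [col]) if action == "add" else \
            [s for s in selected if s != col]
        trajectory.append(best_aic)

    if selected:
        M = sm.add_constant(X[selected])
        fit = sm.OLS(y, M).fit()
        r2 = float(fit.rsquared)
        pvals = fit.pvalues.drop("const")
        coefs = fit.params.drop("const")
        partial = {}
        full_rss = float(fit.ssr)
        tss = float(np.sum((y - y.mean()) ** 2))
        for c in selected:
            rest = [s for s in selected if s != c]
            Mr = np.column_stack([np.ones(n)] + [X[s].to_numpy() for s in rest])
            partial[c] = (_ols_rss(y, Mr) - full_rss) / tss
        vifs = vif(X[selected]) if len(selected) > 1 else pd.Series({selected[0]: 1.0})
    else:
        r2 = 0.0
        pvals = pd.Series(dtype=float)
        coefs = pd.Series(dtype=float)
        partial = {}
        vifs = pd.Series(dtype=float)
    return SelectionReport(selected, trajectory, vifs, pd.Series(partial), r2,
                           pvals, coefs)
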