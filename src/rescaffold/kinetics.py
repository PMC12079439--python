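"""Michaelis–Menten fitting for enzyme characterization.

Initial-rate data v(S) are fitted to v = Vmax·S/(Km + S) by nonlinear least
squares on the untransformed model (linearizations such as Lineweaver–Burk
bias the estimates and are deliberately avoided).  Substrate load is in
g/L: for a polymeric substrate like PET, molarity is undefined, so Km
carries mass-concentration units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit, OptimizeWarning

__all__ = [
    "KineticsDataset",
    "MMFit",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "read_kinetics_csv",
]


@dataclass
class KineticsDataset:
    """Initial-rate measurements: substrate in g/L, rate in µM/min."""

    substrate: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate.shape != self.rate.shape:
            raise ValueError("substrate and rate must have equal length")
        if self.substrate.size < 4:
            raise ValueError("need at least 4 data points")
        if np.any(self.substrate < 0) or np.any(self.rate < 0):
            raise ValueError("substrate and rate must be non-negative")
        if not np.all(np.diff(self.substrate) >= 0):
            order = np.argsort(self.substrate, kind="stable")
            self.substrate = self.substrate[order]
            self.rate = self.rate[order]


@dataclass
class MMFit:
    """Fitted Michaelis–Menten parameters with Jacobian-based standard errors."""

    vmax: float        # µM/min
    km: float          # g/L
    se_vmax: float
    se_km: float
    rss: float
    converged: bool
    identifiability_warning: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _mm(S: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * S / (km + S)


def fit_michaelis_menten(data: KineticsDataset,
                         init: tuple[float, float] | None = None) -> MMFit:
    """Least-squares Michaelis–Menten fit.

    The default initialization takes Vmax₀ as the largest observed rate and
    Km₀ as the substrate load closest to half-maximal rate.  Standard
    errors come from the Jacobian at the optimum.  If the substrate grid
    does not bracket the fitted Km, an identifiability warning is attached
    (the fit is still returned).
    """
    S, v = data.substrate, data.rate
    if init is None:
        vmax0 = float(v.max())
        half_idx = int(np.argmin(np.abs(v - vmax0 / 2.0)))
        km0 = float(S[half_idx]) if S[half_idx] > 0 else float(np.median(S[S > 0]))
        init = (vmax0, km0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(_mm, S, v, p0=init, maxfev=10000)
    except RuntimeError as exc:
        return MMFit(vmax=float("nan"), km=float("nan"),
                     se_vmax=float("nan"), se_km=float("nan"),
                     rss=float("nan"), converged=False,
                     identifiability_warning=str(exc))
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    rss = float(((v - _mm(S, *popt)) ** 2).sum())
    converged = np.isfinite(vmax) and np.isfinite(km) and vmax > 0 and km > 0
    warn = None
    if converged and not (S.min() < km < S.max()):
        warn = (f"fitted Km = {km:.3g} g/L lies outside the substrate range "
                f"[{S.min():.3g}, {S.max():.3g}]; Km poorly identified")
    elif not converged:
        warn = "non-physical estimates (Vmax or Km not positive)"
    return MMFit(vmax=vmax, km=km, se_vmax=float(se[0]), se_km=float(se[1]),
                 rss=rss, converged=converged, identifiability_warning=warn)


def catalytic_efficiency(fit: MMFit) -> float:
    """Vmax/Km in (µM/min)/(g/L).

    Defined strictly as the ratio of the fitted parameters; no
    enzyme-concentration normalization is applied, so values are comparable
    only across assays run at the same enzyme load.
    """
    if not fit.converged:
        raise ValueError("cannot compute efficiency from a non-converged fit")
    return fit.vmax / fit.km


def read_kinetics_csv(path: str | Path) -> KineticsDataset:
    """Read (substrate, rate) columns from a CSV/TSV file with a header."""
    import pandas as pd
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().split("_")[0]: c for c in df.columns}
    try:
        s_col = cols["substrate"]
        r_col = cols["rate"]
    except KeyError as exc:
        raise ValueError(f"{path}: expected 'substrate' and 'rate' columns, "
                         f"found {list(df.columns)}") from exc
    return KineticsDataset(substrate=df[s_col].to_numpy(),
                           rate=df[r_col].to_numpy())
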