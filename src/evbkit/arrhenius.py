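"""Arrhenius decomposition of activation free energies.

Over a narrow temperature span the Gibbs relation dG_act(T) = dH_act -
T*dS_act is linear in T, so plotting dG_act/T against 1/T gives a line with
slope dH_act and intercept -dS_act.  The regression runs on per-temperature
replicate means (matching how simulation campaigns report mean +/- SEM per
temperature); parameter standard errors come from a nonparametric bootstrap
over replicates within each temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .evb_core import EVBError
from .synthetic import TemperatureSeries

DEFAULT_REF_T = 298.0
DEFAULT_BOOTSTRAP = 1000


class FitError(EVBError):
    pass


@dataclass
class ArrheniusFit:
    """Result of the dG_act/T vs 1/T regression.

    ``dH_act`` (kcal/mol) is the slope, ``dS_act`` (kcal/mol/K) minus the
    intercept, and ``TdS_at_ref = ref_T * dS_act``.  The identity
    dG_act(T) = dH_act - T*dS_act reproduces the fitted line exactly.
    """

    dH_act: float
    dS_act: float
    TdS_at_ref: float
    ref_T: float
    se_dH: float
    se_dS: float
    se_TdS: float
    r_squared: float
    temperatures: np.ndarray
    mean_dG_act: np.ndarray
    label: str = ""

    @classmethod
    def from_parameters(cls, dH_act: float, TdS_at_ref: float,
                        ref_T: float = DEFAULT_REF_T,
                        label: str = "") -> "ArrheniusFit":
        """Build a fit object directly from (dH_act, T*dS_act at ref_T),
        e.g. from published activation parameters."""
        dS = TdS_at_ref / ref_T
        return cls(dH_act=dH_act, dS_act=dS, TdS_at_ref=TdS_at_ref,
                   ref_T=ref_T, se_dH=0.0, se_dS=0.0, se_TdS=0.0,
                   r_squared=1.0, temperatures=np.array([]),
                   mean_dG_act=np.array([]), label=label)

    def as_dict(self) -> dict:
        return {
            "label": self.label, "ref_T": self.ref_T,
            "dH_act": self.dH_act, "dS_act": self.dS_act,
            "TdS_at_ref": self.TdS_at_ref,
            "se_dH": self.se_dH, "se_dS": self.se_dS, "se_TdS": self.se_TdS,
            "r_squared": self.r_squared,
            "temperatures": self.temperatures.tolist(),
            "mean_dG_act": self.mean_dG_act.tolist(),
        }


def fit_arrhenius(series: TemperatureSeries, ref_T: float = DEFAULT_REF_T,
                  n_bootstrap: int = DEFAULT_BOOTSTRAP,
                  seed: int = 0) -> ArrheniusFit:
    """Ordinary least squares of mean dG_act(T)/T against 1/T.

    Bootstrap SEs resample replicates within each temperature (seeded,
    ``n_bootstrap`` resamples); with a single replicate everywhere the SEs
    are zero.  Raises on fewer than 3 distinct temperatures.
    """
    entries = sorted(((t, np.asarray(v, dtype=float))
                      for t, v in series.entries), key=lambda e: e[0])
    T = np.array([t for t, _ in entries])
    if np.unique(T).size < 3:
        raise FitError("need at least 3 distinct temperatures")
    if np.ptp(1.0 / T) <= 0:
        raise FitError("zero variance in 1/T")
    means = np.array([v.mean() for _, v in entries])
    x = 1.0 / T
    y = means / T

    def _ols(yv):
        slope, intercept = np.polyfit(x, yv, 1)
        return slope, intercept

    slope, intercept = _ols(y)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    if n_bootstrap > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_bootstrap, 2))
        for b in range(n_bootstrap):
            ym = np.array([v[rng.integers(0, v.size, v.size)].mean()
                           for _, v in entries])
            boots[b] = _ols(ym / T)
        se_dH = float(np.std(boots[:, 0], ddof=1))
        se_dS = float(np.std(boots[:, 1], ddof=1))  # intercept = -dS
    else:
        se_dH = se_dS = 0.0
    dS = -intercept
    return ArrheniusFit(
        dH_act=float(slope), dS_act=float(dS), TdS_at_ref=float(ref_T * dS),
        ref_T=ref_T, se_dH=se_dH, se_dS=se_dS, se_TdS=float(ref_T * se_dS),
        r_squared=r2, temperatures=T, mean_dG_act=means, label=series.label)


def thermo_at_temperature(fit: ArrheniusFit, T: float
                          ) -> tuple[float, float, float]:
    """(dG_act, dH_act, T*dS_act) at temperature T from a fitted model,
    via the Gibbs identity dG_act = dH_act - T*dS_act."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    TdS = T * fit.dS_act
    return fit.dH_act - TdS, fit.dH_act, TdS


def series_from_frame(df, label: str | None = None) -> TemperatureSeries:
    """Build a TemperatureSeries from a DataFrame with columns
    ``system, T, replicate, dG_act`` (single system unless ``label`` given)."""
    if label is not None:
        df = df[df["system"] == label]
    if df.empty:
        raise FitError(f"no rows for system {label!r}")
    entries = [(float(t), g["dG_act"].to_numpy())
               for t, g in df.groupby("T")]
    return TemperatureSeries(entries=entries,
                             label=label or str(df["system"].iloc[0]))
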