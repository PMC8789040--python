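"""1:1 Langmuir binding kinetics for surface plasmon resonance (SPR).

The model: an immobilized ligand and a single analyte at concentration C
associate with rate constant k_on (1/(M s)) and dissociate with k_off (1/s).
During analyte injection the response follows

    R(t) = R_max * C k_on / (C k_on + k_off) * (1 - exp(-(C k_on + k_off) t))

and after the injection ends at t0 it decays as R(t) = R(t0) exp(-k_off (t - t0)).
The equilibrium dissociation constant is always the ratio K_D = k_off / k_on.

:class:`LangmuirModel` fits a single (k_on, k_off, R_max) globally across a
multi-concentration sensorgram series, association and dissociation phases
jointly, by bounded nonlinear least squares in log-parameter space with a
data-driven initialization (log-linear dissociation tails for k_off, a
coarse k_on grid with the conditionally-linear R_max solved in closed form).
:class:`KineticFitResults` carries the estimates, their uncertainties, fit
diagnostics, a no-binding call, and plotting/summary helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "KineticFitResults",
    "LangmuirModel",
    "LangmuirParams",
    "ReplicateSummary",
    "Sensorgram",
    "aggregate_replicates",
    "double_reference",
    "kd_from_rates",
    "langmuir_association",
    "langmuir_dissociation",
    "orthogonality_matrix",
    "selectivity",
    "simulate_sensorgrams",
]

KON_BOUNDS = (1e3, 1e10)
KOFF_BOUNDS = (1e-6, 1.0)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def langmuir_association(t, conc: float, k_on: float, k_off: float, r_max: float):
    """Association-phase response of the 1:1 Langmuir model."""
    t = np.asarray(t, dtype=float)
    k_obs = conc * k_on + k_off
    req = r_max * conc * k_on / k_obs
    return req * (1.0 - np.exp(-k_obs * t))


def langmuir_dissociation(t, r0: float, k_off: float, t0: float = 0.0):
    """Exponential decay from response ``r0`` at the end of injection ``t0``."""
    t = np.asarray(t, dtype=float)
    return r0 * np.exp(-k_off * (t - t0))


def kd_from_rates(k_on: float, k_off: float) -> float:
    """K_D = k_off / k_on (exact quotient)."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be strictly positive")
    return k_off / k_on


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LangmuirParams:
    k_on: float  # 1/(M s)
    k_off: float  # 1/s
    r_max: float  # RU

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0 or self.r_max <= 0:
            raise ValueError("Langmuir parameters must be strictly positive")

    @property
    def k_d(self) -> float:
        return kd_from_rates(self.k_on, self.k_off)


@dataclass
class Sensorgram:
    """One analyte concentration's time-resolved response.

    Time is in seconds with the injection starting at t = 0; points with
    t < 0 form the pre-injection baseline window.  ``t_assoc_end`` marks
    the end of the association phase (= start of dissociation).
    """

    concentration: float
    time: np.ndarray
    response: np.ndarray
    t_assoc_end: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")

    def phases(self) -> np.ndarray:
        out = np.where(
            self.time < 0,
            "baseline",
            np.where(self.time <= self.t_assoc_end, "association", "dissociation"),
        )
        return out

    def predict(self, k_on: float, k_off: float, r_max: float) -> np.ndarray:
        """Model response on this sensorgram's grid (baseline = 0)."""
        t = self.time
        out = np.zeros_like(t)
        assoc = (t >= 0) & (t <= self.t_assoc_end)
        diss = t > self.t_assoc_end
        out[assoc] = langmuir_association(
            t[assoc], self.concentration, k_on, k_off, r_max
        )
        r_end = float(
            langmuir_association(
                self.t_assoc_end, self.concentration, k_on, k_off, r_max
            )
        )
        out[diss] = langmuir_dissociation(t[diss], r_end, k_off, self.t_assoc_end)
        return out


def simulate_sensorgrams(
    params: LangmuirParams,
    concentrations,
    t_assoc: float = 100.0,
    t_diss: float = 420.0,
    dt: float = 1.0,
    baseline: float = 10.0,
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Sensorgram]:
    """Closed-form curves plus Gaussian noise and linear baseline drift.

    Phase durations default to the shorter of the two standard injection
    programmes (100 s association, 420 s dissociation); slow-dissociating
    analytes warrant the longer 200 s / 1500 s programme.
    """
    if noise_sd > 0 and rng is None:
        raise ValueError("noise requires an rng")
    out = []
    t = np.arange(-baseline, t_assoc + t_diss + dt / 2, dt)
    for conc in concentrations:
        sg = Sensorgram(conc, t, np.zeros_like(t), t_assoc_end=t_assoc)
        r = sg.predict(params.k_on, params.k_off, params.r_max)
        r = r + drift_slope * (t - t[0])
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=t.shape)
        out.append(Sensorgram(conc, t, r, t_assoc_end=t_assoc))
    return out


def double_reference(
    sample: Sensorgram,
    reference_cell: Sensorgram,
    blank_sample: Sensorgram,
    blank_reference: Sensorgram,
) -> Sensorgram:
    """Double referencing: (sample - reference) - (blank - blank reference)."""
    grids = [reference_cell, blank_sample, blank_reference]
    for other in grids:
        if other.time.shape != sample.time.shape or np.any(
            other.time != sample.time
        ):
            raise ValueError("all four sensorgrams must share one time grid")
    corrected = (sample.response - reference_cell.response) - (
        blank_sample.response - blank_reference.response
    )
    return Sensorgram(
        sample.concentration, sample.time.copy(), corrected, sample.t_assoc_end
    )


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------


class LangmuirModel:
    """Global 1:1 Langmuir fit over a multi-concentration sensorgram set.

    One (k_on, k_off, R_max) triple is shared across all curves and both
    phases, matching a single-interaction reading of the data; per-curve
    fitting for diagnostics is available via ``fit(global_fit=False)``.
    """

    def __init__(self, sensorgrams: list[Sensorgram]):
        if len(sensorgrams) == 0:
            raise ValueError("at least one sensorgram is required")
        self.sensorgrams = list(sensorgrams)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LangmuirModel":
        """Build from a tidy frame with columns time, response,
        concentration and optionally phase."""
        required = {"time", "response", "concentration"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        sgs = []
        for conc, group in df.groupby("concentration", sort=True):
            group = group.sort_values("time")
            t = group["time"].to_numpy(float)
            if "phase" in group.columns:
                assoc = group["phase"].to_numpy() == "association"
                t_assoc_end = float(t[assoc].max()) if assoc.any() else float(t.max())
            else:
                t_assoc_end = float(t.max())
            sgs.append(
                Sensorgram(float(conc), t, group["response"].to_numpy(float),
                           t_assoc_end)
            )
        return cls(sgs)

    # -- initialization helpers -------------------------------------------

    def _estimate_noise_sd(self) -> float:
        baseline = np.concatenate(
            [sg.response[sg.time < 0] for sg in self.sensorgrams]
        )
        if baseline.size >= 4:
            return float(baseline.std())
        return 0.0

    def _init_koff(self) -> float:
        slopes = []
        for sg in self.sensorgrams:
            diss = sg.time > sg.t_assoc_end
            t, r = sg.time[diss], sg.response[diss]
            floor = 0.05 * max(abs(r).max() if r.size else 0.0, 1e-12)
            keep = r > floor
            if keep.sum() >= 3:
                slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
                if slope < 0:
                    slopes.append(-slope)
        if slopes:
            return float(np.clip(np.median(slopes), *KOFF_BOUNDS))
        return 1e-3

    def _rmax_given(self, k_on: float, k_off: float) -> float:
        num = den = 0.0
        for sg in self.sensorgrams:
            fit_mask = sg.time >= 0
            shape = sg.predict(k_on, k_off, 1.0)  # model is linear in r_max
            num += float(shape[fit_mask] @ sg.response[fit_mask])
            den += float(shape[fit_mask] @ shape[fit_mask])
        if den <= 0 or num <= 0:
            return max(1e-6, max(abs(sg.response).max() for sg in self.sensorgrams))
        return num / den

    def _initial_guess(self) -> tuple[float, float, float]:
        koff0 = self._init_koff()
        best = None
        for koff in (koff0, koff0 / 10, koff0 * 10):
            if not KOFF_BOUNDS[0] <= koff <= KOFF_BOUNDS[1]:
                continue
            for log_kon in np.arange(3.0, 10.01, 0.25):
                kon = 10.0**log_kon
                rmax = self._rmax_given(kon, koff)
                sse = self._sse(kon, koff, rmax)
                if best is None or sse < best[0]:
                    best = (sse, kon, koff, rmax)
        _, kon, koff, rmax = best
        return kon, koff, max(rmax, 1e-6)

    def _sse(self, k_on: float, k_off: float, r_max: float) -> float:
        sse = 0.0
        for sg in self.sensorgrams:
            mask = sg.time >= 0
            resid = sg.response[mask] - sg.predict(k_on, k_off, r_max)[mask]
            sse += float(resid @ resid)
        return sse

    @staticmethod
    def _smoothed_max(sg: Sensorgram, window: int = 9) -> float:
        r = sg.response[sg.time >= 0]
        if r.size == 0:
            return 0.0
        if r.size < window:
            return float(np.abs(r).mean())
        kernel = np.ones(window) / window
        return float(np.abs(np.convolve(r, kernel, mode="valid")).max())

    # -- fitting -----------------------------------------------------------

    def _residuals(self, params: lmfit.Parameters) -> np.ndarray:
        k_on = 10.0 ** params["log10_kon"].value
        k_off = 10.0 ** params["log10_koff"].value
        r_max = 10.0 ** params["log10_rmax"].value
        parts = []
        for sg in self.sensorgrams:
            mask = sg.time >= 0
            parts.append(sg.response[mask] - sg.predict(k_on, k_off, r_max)[mask])
        return np.concatenate(parts)

    def fit(self, global_fit: bool = True, noise_sd: float | None = None):
        """Fit and return :class:`KineticFitResults`.

        ``noise_sd`` overrides the baseline-window noise estimate used for
        the no-binding call.  ``global_fit=False`` fits each concentration
        separately and returns a list of results (diagnostic mode).
        """
        if not global_fit:
            return [
                LangmuirModel([sg]).fit(global_fit=True, noise_sd=noise_sd)
                for sg in self.sensorgrams
            ]
        kon0, koff0, rmax0 = self._initial_guess()
        params = lmfit.Parameters()
        params.add("log10_kon", value=math.log10(kon0),
                   min=math.log10(KON_BOUNDS[0]), max=math.log10(KON_BOUNDS[1]))
        params.add("log10_koff", value=math.log10(koff0),
                   min=math.log10(KOFF_BOUNDS[0]), max=math.log10(KOFF_BOUNDS[1]))
        params.add("log10_rmax", value=math.log10(rmax0), min=-6.0, max=6.0)
        minimizer = lmfit.Minimizer(self._residuals, params)
        import warnings as _warnings

        with _warnings.catch_warnings():
            # a perfect (zero-residual) fit makes the covariance singular,
            # which lmfit reports via a harmless RuntimeWarning
            _warnings.simplefilter("ignore", RuntimeWarning)
            out = minimizer.minimize(
                method="least_squares", xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        k_on = 10.0 ** out.params["log10_kon"].value
        k_off = 10.0 ** out.params["log10_koff"].value
        r_max = 10.0 ** out.params["log10_rmax"].value
        stderr = {}
        param_names = {"k_on": "log10_kon", "k_off": "log10_koff",
                       "r_max": "log10_rmax"}
        for name, value in (("k_on", k_on), ("k_off", k_off), ("r_max", r_max)):
            p = out.params[param_names[name]]
            stderr[name] = (
                value * math.log(10.0) * p.stderr if p.stderr is not None else None
            )
        rss = float(np.sum(out.residual**2))
        est_noise = noise_sd if noise_sd is not None else self._estimate_noise_sd()
        # the no-binding call compares the maximum corrected response against
        # the noise floor; the response is lightly smoothed first so the call
        # reflects signal amplitude rather than pointwise noise excursions
        max_resp = max(self._smoothed_max(sg) for sg in self.sensorgrams)
        threshold = max(3.0 * est_noise, 0.01 * r_max)
        return KineticFitResults(
            model=self,
            params=LangmuirParams(k_on, k_off, r_max),
            stderr=stderr,
            rss=rss,
            converged=bool(out.success),
            no_binding=bool(max_resp < threshold),
            noise_sd=est_noise,
            nfev=int(out.nfev),
            message=str(out.message),
        )


@dataclass
class KineticFitResults:
    """Fitted 1:1 Langmuir parameters with uncertainties and diagnostics."""

    model: LangmuirModel
    params: LangmuirParams
    stderr: dict
    rss: float
    converged: bool
    no_binding: bool
    noise_sd: float
    nfev: int
    message: str = ""

    @property
    def k_on(self) -> float:
        return self.params.k_on

    @property
    def k_off(self) -> float:
        return self.params.k_off

    @property
    def r_max(self) -> float:
        return self.params.r_max

    @property
    def k_d(self) -> float:
        """Always the exact quotient k_off / k_on of this same fit."""
        return kd_from_rates(self.params.k_on, self.params.k_off)

    def to_dict(self) -> dict:
        return {
            "k_on": self.k_on,
            "k_off": self.k_off,
            "r_max": self.r_max,
            "k_d": self.k_d,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "no_binding": self.no_binding,
            "noise_sd": self.noise_sd,
            "nfev": self.nfev,
        }

    def summary(self) -> str:
        rows = [
            ("k_on [1/(M s)]", self.k_on, self.stderr.get("k_on")),
            ("k_off [1/s]", self.k_off, self.stderr.get("k_off")),
            ("R_max [RU]", self.r_max, self.stderr.get("r_max")),
            ("K_D [M]", self.k_d, None),
        ]
        lines = [
            "1:1 Langmuir global fit",
            f"  curves: {len(self.model.sensorgrams)}   "
            f"RSS: {self.rss:.4g}   converged: {self.converged}   "
            f"no binding: {self.no_binding}",
            f"  {'parameter':<16}{'estimate':>14}{'std err':>14}",
        ]
        for name, value, err in rows:
            err_s = f"{err:>14.4g}" if err is not None else f"{'-':>14}"
            lines.append(f"  {name:<16}{value:>14.4g}{err_s}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay measured sensorgrams and the fitted curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sg in self.model.sensorgrams:
            ax.plot(sg.time, sg.response, lw=1,
                    label=f"{sg.concentration:.3g} M")
            ax.plot(sg.time, sg.predict(self.k_on, self.k_off, self.r_max),
                    color="black", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        ax.legend(fontsize="small")
        return ax


# ---------------------------------------------------------------------------
# replicate aggregation, selectivity, orthogonality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-parameter mean and SD over independent replicate fits.

    K_D is aggregated as the mean of per-replicate K_D ratios, not the
    ratio of the mean rates — the two differ whenever rates co-vary.
    """

    n: int
    k_on_mean: float
    k_on_sd: float
    k_off_mean: float
    k_off_sd: float
    r_max_mean: float
    r_max_sd: float
    k_d_mean: float
    k_d_sd: float


def aggregate_replicates(fits: list[KineticFitResults]) -> ReplicateSummary:
    if len(fits) < 2:
        raise ValueError("at least two replicate fits are required")
    if any(not f.converged for f in fits):
        raise ValueError("all replicate fits must have converged")
    if any(f.no_binding for f in fits):
        raise ValueError(
            "replicates include no-binding fits; aggregate only binding fits"
        )
    k_on = np.array([f.k_on for f in fits])
    k_off = np.array([f.k_off for f in fits])
    r_max = np.array([f.r_max for f in fits])
    k_d = np.array([f.k_d for f in fits])
    sd = lambda x: float(x.std(ddof=1))
    return ReplicateSummary(
        len(fits),
        float(k_on.mean()), sd(k_on),
        float(k_off.mean()), sd(k_off),
        float(r_max.mean()), sd(r_max),
        float(k_d.mean()), sd(k_d),
    )


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def selectivity(k_d_offtarget: float, k_d_cognate: float) -> float:
    """Fold selectivity = K_D(off-target) / K_D(cognate), to 3 significant
    figures."""
    if k_d_offtarget <= 0 or k_d_cognate <= 0:
        raise ValueError("K_D values must be positive")
    return _round_sig(k_d_offtarget / k_d_cognate, 3)


def orthogonality_matrix(
    kd_table: pd.DataFrame,
    cognate: dict[str, str],
    selectivity_min: float = 4000.0,
    nb_floor_kd: float = 1e-6,
):
    """All pairwise selectivity folds plus mutually-orthogonal proposals.

    ``kd_table`` is RNA x protein with K_D in M; NaN entries mean no
    binding detected and are treated as selectivity-infinite with a floor
    at ``nb_floor_kd`` (the concentration-limit bound).  ``cognate`` names
    each RNA's cognate protein.  Entries are oriented off-target/cognate,
    so every entry is >= 1 when the cognate is each RNA's best binder.
    Two pairs (r_i, p_i), (r_j, p_j) are proposed as mutually orthogonal
    when both cross-selectivities meet ``selectivity_min``.
    """
    sel = pd.DataFrame(index=kd_table.index, columns=kd_table.columns, dtype=float)
    for rna in kd_table.index:
        kd_cog = kd_table.loc[rna, cognate[rna]]
        if not np.isfinite(kd_cog):
            raise ValueError(f"cognate K_D for {rna!r} is not measurable")
        for prot in kd_table.columns:
            kd_off = kd_table.loc[rna, prot]
            if not np.isfinite(kd_off):
                kd_off = nb_floor_kd
            sel.loc[rna, prot] = _round_sig(kd_off / kd_cog, 3)
    pairs = [(rna, cognate[rna]) for rna in kd_table.index]
    proposals = []
    for i, (r_i, p_i) in enumerate(pairs):
        for r_j, p_j in pairs[i + 1 :]:
            if p_i == p_j:
                continue
            cross_ij = sel.loc[r_i, p_j]
            cross_ji = sel.loc[r_j, p_i]
            if cross_ij >= selectivity_min and cross_ji >= selectivity_min:
                proposals.append(((r_i, p_i), (r_j, p_j)))
    return sel, proposals
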