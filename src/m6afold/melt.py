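"""Two-state UV-melting thermodynamics for RNA hairpins and duplexes.

The folded fraction of a self-complementary two-state duplex is

    f_duplex(T) = 4e / (1 + 4e + sqrt(1 + 8e)),   e = exp[(1/Tm - 1/T) ΔH / R]

(an algebraically stable rearrangement of the textbook root expression),
and for a unimolecular hairpin

    f_hairpin(T) = e / (1 + e),

so that f(Tm) = 1/2 exactly in both cases. Nonlinear least squares recovers
(Tm, ΔH) from a melting curve; van't Hoff analysis then derives

    duplex:   ΔS = ΔH/Tm − R ln(CT/2)
    hairpin:  ΔS = ΔH/Tm
    both:     ΔG(T) = ΔH − T ΔS

with CT the total strand concentration. Methylation effects are reported as
signed differences ΔΔX = X(methylated) − X(unmodified); negative ΔΔG means
the modification stabilizes folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import FitError, ValidationError

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 0.0019872

#: default evaluation temperature: 37 °C
T37_K = 310.15


# -- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class MeltingCurve:
    """A melting curve: temperature (K, strictly increasing) vs signal.

    ``signal_kind`` is 'fraction' (folded fraction, approximately in [0, 1])
    or 'absorbance' (raw A260, fitted with joint linear baselines).
    ``ct`` is the total strand concentration in mol/L, required for the
    bimolecular duplex model.
    """

    temperature: np.ndarray
    signal: np.ndarray
    signal_kind: str = "fraction"
    ct: float | None = None

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValidationError("temperature and signal must be equal-length 1-D arrays")
        if len(t) < 8:
            raise ValidationError("melting curve needs at least 8 points")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if np.any(t <= 0):
            raise ValidationError("temperatures must be positive kelvin")
        if self.signal_kind not in ("fraction", "absorbance"):
            raise ValidationError(f"unknown signal_kind {self.signal_kind!r}")
        if self.ct is not None and self.ct <= 0:
            raise ValidationError("ct must be positive")


@dataclass(frozen=True)
class MeltModelParams:
    """Fitted/derived two-state parameters. Energies kcal/mol, Tm kelvin."""

    model: str                      # 'duplex' or 'hairpin'
    tm: float
    dh: float
    ds: float | None = None         # kcal mol^-1 K^-1
    dg: float | None = None         # kcal/mol at t_eval
    t_eval: float | None = None
    ct: float | None = None
    residual_norm: float | None = None
    baseline: tuple | None = None   # (b_f, m_f, b_u, m_u) for absorbance fits
    uncertainty: dict = field(default_factory=dict)  # per-parameter std dev


@dataclass(frozen=True)
class DeltaDeltaResult:
    """Signed methylation differences (methylated − unmodified)."""

    ddg: float
    ddh: float
    dds: float
    t_eval: float
    uncertainty: dict = field(default_factory=dict)


# -- model functions -------------------------------------------------------

def _vant_hoff_exponent(T, tm: float, dh: float):
    if tm <= 0 or np.any(np.asarray(T) <= 0):
        raise ValidationError("temperatures must be positive kelvin")
    x = (1.0 / tm - 1.0 / np.asarray(T, dtype=float)) * dh / R_KCAL
    return np.clip(x, -500.0, 500.0)


def fraction_folded_duplex(T, tm: float, dh: float):
    """Folded fraction of a two-state duplex; scalar or array in [0, 1]."""
    e = np.exp(_vant_hoff_exponent(T, tm, dh))
    return 4.0 * e / (1.0 + 4.0 * e + np.sqrt(1.0 + 8.0 * e))


def fraction_folded_hairpin(T, tm: float, dh: float):
    """Folded fraction of a two-state hairpin; overflow-safe logistic."""
    return expit(_vant_hoff_exponent(T, tm, dh))


_MODEL_FN = {"duplex": fraction_folded_duplex, "hairpin": fraction_folded_hairpin}


# -- fitting ---------------------------------------------------------------

def _fit_once(curve: MeltingCurve, model: str, baseline: bool,
              tm0: float, dh0: float):
    T, y = curve.temperature, curve.signal
    fn = _MODEL_FN[model]
    if baseline:
        # absorbance trace: folded/unfolded linear baselines fitted jointly;
        # A(T) = (b_f + m_f T) f + (b_u + m_u T)(1 - f)
        lo, hi = float(np.min(y)), float(np.max(y))

        def resid(p):
            tm, dh, bf, mf, bu, mu = p
            f = fn(T, tm, dh)
            return (bf + mf * T) * f + (bu + mu * T) * (1.0 - f) - y

        p0 = [tm0, dh0, lo, 0.0, hi, 0.0]
        bounds = ([T[0] - 50, -400, -np.inf, -np.inf, -np.inf, -np.inf],
                  [T[-1] + 50, -0.1, np.inf, np.inf, np.inf, np.inf])
    else:
        def resid(p):
            tm, dh = p
            return fn(T, tm, dh) - y

        p0 = [tm0, dh0]
        bounds = ([T[0] - 50, -400], [T[-1] + 50, -0.1])
    p0 = np.clip(p0, bounds[0], bounds[1])
    sol = least_squares(resid, p0, bounds=bounds, method="trf")
    return sol


def _initial_tm(curve: MeltingCurve) -> float:
    """Temperature where the signal crosses its midpoint."""
    y = curve.signal
    mid = 0.5 * (np.min(y) + np.max(y))
    idx = int(np.argmin(np.abs(y - mid)))
    return float(curve.temperature[idx])


def fit_melting(curve: MeltingCurve, model: str = "hairpin",
                baseline_mode: str = "none",
                t_eval: float = T37_K,
                n_bootstrap: int = 0, seed: int | None = None) -> MeltModelParams:
    """Least-squares fit of a two-state melting model to one curve.

    Multi-start and deterministic: Tm starts at the observed signal midpoint
    (±5 K), ΔH at −40 kcal/mol (×0.5, 1, 2); the lowest residual wins, ties
    broken by start order. With ``n_bootstrap`` > 0 a seeded parametric
    bootstrap provides per-parameter standard deviations.
    """
    if model not in _MODEL_FN:
        raise ValidationError(f"unknown model {model!r}")
    if model == "duplex" and curve.ct is None:
        raise ValidationError("duplex model requires curve.ct")
    if baseline_mode not in ("none", "linear"):
        raise ValidationError(f"unknown baseline_mode {baseline_mode!r}")
    if curve.signal_kind == "absorbance" and baseline_mode != "linear":
        raise ValidationError("absorbance curves require baseline_mode='linear' "
                              "or pre-normalized signal")
    if curve.signal_kind == "fraction":
        if np.any(curve.signal < -0.05) or np.any(curve.signal > 1.05):
            raise ValidationError("folded fraction outside [-0.05, 1.05]")
    use_baseline = baseline_mode == "linear"

    tm0 = _initial_tm(curve)
    best = None
    for dtm in (0.0, -5.0, 5.0):
        for scale in (1.0, 0.5, 2.0):
            sol = _fit_once(curve, model, use_baseline, tm0 + dtm, -40.0 * scale)
            if sol.success and (best is None or sol.cost < best.cost - 1e-15):
                best = sol
    if best is None:
        raise FitError("melting fit failed to converge from all starts")

    tm, dh = float(best.x[0]), float(best.x[1])
    baseline = tuple(float(v) for v in best.x[2:]) if use_baseline else None
    params = derive_thermo({"tm": tm, "dh": dh}, model=model, ct=curve.ct,
                           t_eval=t_eval)
    params = replace(params, residual_norm=float(np.sqrt(2 * best.cost)),
                     baseline=baseline)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        resid = best.fun
        sigma = float(np.std(resid, ddof=min(len(best.x), len(resid) - 1)))
        yhat = curve.signal - resid
        samples = []
        for _ in range(n_bootstrap):
            yb = yhat + rng.normal(0.0, sigma, size=yhat.shape)
            cb = MeltingCurve(curve.temperature, yb,
                              signal_kind="absorbance" if use_baseline else "fraction",
                              ct=curve.ct)
            try:
                pb = fit_melting(cb, model=model, baseline_mode=baseline_mode,
                                 t_eval=t_eval)
                samples.append((pb.tm, pb.dh, pb.ds, pb.dg))
            except (FitError, ValidationError):
                continue
        if len(samples) >= 10:
            arr = np.array(samples, dtype=float)
            unc = dict(zip(("tm", "dh", "ds", "dg"), np.std(arr, axis=0, ddof=1)))
            params = replace(params, uncertainty={k: float(v) for k, v in unc.items()})
    return params


def fit_melting_replicates(curves: Sequence[MeltingCurve], model: str = "hairpin",
                           baseline_mode: str = "none",
                           t_eval: float = T37_K,
                           seed: int | None = None) -> MeltModelParams:
    """Fit each replicate curve and pool: mean parameters, std-dev uncertainty.

    With fewer than 3 replicates the uncertainty falls back to a seeded
    parametric bootstrap (500 resamples) on the first curve.
    """
    if not curves:
        raise ValidationError("no curves given")
    fits = [fit_melting(c, model=model, baseline_mode=baseline_mode, t_eval=t_eval)
            for c in curves]
    vals = np.array([[f.tm, f.dh, f.ds, f.dg] for f in fits], dtype=float)
    mean = vals.mean(axis=0)
    if len(fits) >= 3:
        sd = vals.std(axis=0, ddof=1)
        unc = {k: float(v) for k, v in zip(("tm", "dh", "ds", "dg"), sd)}
    else:
        boot = fit_melting(curves[0], model=model, baseline_mode=baseline_mode,
                           t_eval=t_eval, n_bootstrap=500, seed=seed)
        unc = boot.uncertainty
    return MeltModelParams(model=model, tm=float(mean[0]), dh=float(mean[1]),
                           ds=float(mean[2]), dg=float(mean[3]), t_eval=t_eval,
                           ct=curves[0].ct,
                           residual_norm=float(np.mean([f.residual_norm for f in fits])),
                           uncertainty=unc)


# -- van't Hoff derivation and methylation differences ---------------------

def derive_thermo(params, model: str, ct: float | None = None,
                  t_eval: float = T37_K) -> MeltModelParams:
    """Derive ΔS and ΔG(t_eval) from (Tm, ΔH).

    ``params`` may be a MeltModelParams or a {'tm':, 'dh':} mapping.
    ``ct`` (total strand concentration, mol/L) is required for the duplex
    model and ignored for the hairpin model.
    """
    if isinstance(params, MeltModelParams):
        tm, dh = params.tm, params.dh
        ct = ct if ct is not None else params.ct
        unc = params.uncertainty
    else:
        tm, dh = float(params["tm"]), float(params["dh"])
        unc = {}
    if tm <= 0:
        raise ValidationError("Tm must be positive kelvin")
    if model == "duplex":
        if ct is None:
            raise ValidationError("duplex model requires the total strand "
                                  "concentration ct")
        ds = dh / tm - R_KCAL * np.log(ct / 2.0)
    elif model == "hairpin":
        ds = dh / tm
    else:
        raise ValidationError(f"unknown model {model!r}")
    dg = dh - t_eval * ds
    return MeltModelParams(model=model, tm=tm, dh=dh, ds=float(ds), dg=float(dg),
                           t_eval=t_eval, ct=ct, uncertainty=dict(unc))


def delta_delta(methylated: MeltModelParams,
                unmodified: MeltModelParams) -> DeltaDeltaResult:
    """Signed methylation differences, uncertainties combined in quadrature.

    Negative ΔΔG = methylation stabilizes folding.
    """
    if methylated.model != unmodified.model:
        raise ValidationError("delta_delta requires matching models")
    if methylated.t_eval is None or unmodified.t_eval is None:
        raise ValidationError("both inputs need a derived ΔG (run derive_thermo)")
    if abs(methylated.t_eval - unmodified.t_eval) > 1e-9:
        raise ValidationError("delta_delta requires matching evaluation temperatures")
    unc = {}
    for key, name in (("dg", "ddg"), ("dh", "ddh"), ("ds", "dds")):
        a = methylated.uncertainty.get(key)
        b = unmodified.uncertainty.get(key)
        if a is not None and b is not None:
            unc[name] = float(np.hypot(a, b))
    return DeltaDeltaResult(ddg=methylated.dg - unmodified.dg,
                            ddh=methylated.dh - unmodified.dh,
                            dds=methylated.ds - unmodified.ds,
                            t_eval=methylated.t_eval, uncertainty=unc)
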