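"""Lifetime extraction from energy-integrated photoelectron yield traces.

Pathway yields are fitted to independent monoexponentials A*exp(-t/tau),
since mechanistically distinct relaxation routes are treated as independent;
several traces can also be fitted globally to a shared set of exponential
time constants with free per-trace amplitudes (negative amplitudes express
rise terms, so sequential cascades A -> B -> ground are covered).

Traces that passed through the instrument-response convolution can instead
be fitted with the Gaussian x exponential model (exponentially modified
Gaussian, EMG), evaluated in the erfcx-stabilised form
    f(t) = (A/2) * erfcx(u) * exp(-t^2 / (2 sigma^2)),
    u = (sigma/tau - t/sigma) / sqrt(2),
which shares the tail exp(-t/tau) of the plain exponential.

All fits are deterministic: multi-start over 8 log-spaced tau
initialisations, least squares via lmfit, lowest chi-square wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.special import erfcx

from .spectra import FWHM_TO_SIGMA

#: a best-fit tau beyond this multiple of the trace span flags a non-decay
NON_DECAYING_SPAN_FACTOR = 100.0

_N_STARTS = 8


@dataclass
class DecayFitResult:
    """Result of a mono- or multi-exponential yield fit."""

    taus: list[float]  # fs
    tau_stderrs: list[float | None]
    amplitudes: dict[str, list[float]]  # trace label -> amplitude per component
    offset: float
    model: str  # "mono" | "global"
    non_decaying: bool
    redchi: float
    diagnostics: dict = field(default_factory=dict)


def exponential_decay(t: np.ndarray, amplitude: float, tau: float) -> np.ndarray:
    """A * exp(-t / tau)."""
    return amplitude * np.exp(-np.asarray(t, dtype=float) / tau)


def emg(t: np.ndarray, amplitude: float, tau: float, sigma: float) -> np.ndarray:
    """Exponential decay starting at t=0 convolved with a unit-area Gaussian.

    Overflow-safe via the scaled complementary error function.
    """
    t = np.asarray(t, dtype=float)
    u = (sigma / tau - t / sigma) / math.sqrt(2.0)
    return 0.5 * amplitude * erfcx(u) * np.exp(-0.5 * (t / sigma) ** 2)


def _tau_starts(span: float) -> np.ndarray:
    return np.geomspace(span / 50.0, span * 5.0, _N_STARTS)


def fit_monoexponential(
    times: np.ndarray,
    values: np.ndarray,
    t_start: float = 0.0,
    t_end: float | None = None,
    with_offset: bool = False,
    convolution_fwhm: float | None = None,
) -> DecayFitResult:
    """Least-squares monoexponential fit of a yield trace.

    ``convolution_fwhm`` switches the model from A*exp(-t/tau) to the EMG
    with the corresponding fixed Gaussian sigma, for traces that were
    convolved with the instrument response.  Traces whose best tau exceeds
    100x the fitted span are flagged ``non_decaying`` (no exception).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    mask = t >= t_start
    if t_end is not None:
        mask &= t <= t_end
    t, y = t[mask], y[mask]
    if len(t) < 5:
        raise ValueError("need at least 5 points after t_start")
    span = float(t[-1] - t[0]) or 1.0
    sigma = convolution_fwhm * FWHM_TO_SIGMA if convolution_fwhm else None
    scale = float(np.max(np.abs(y))) or 1.0

    def model(params: Parameters) -> np.ndarray:
        a = params["amplitude"].value
        tau = params["tau"].value
        c = params["offset"].value if with_offset else 0.0
        base = emg(t, a, tau, sigma) if sigma else exponential_decay(t, a, tau)
        return base + c

    best = None
    for tau0 in _tau_starts(span):
        params = Parameters()
        params.add("amplitude", value=scale, min=0.0)
        params.add("tau", value=float(tau0), min=1e-6)
        if with_offset:
            params.add("offset", value=0.0)
        try:
            res = minimize(lambda p: model(p) - y, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    tau = float(best.params["tau"].value)
    stderr = best.params["tau"].stderr
    return DecayFitResult(
        taus=[tau],
        tau_stderrs=[float(stderr) if stderr is not None else None],
        amplitudes={"trace": [float(best.params["amplitude"].value)]},
        offset=float(best.params["offset"].value) if with_offset else 0.0,
        model="mono",
        non_decaying=tau > NON_DECAYING_SPAN_FACTOR * span,
        redchi=float(best.redchi),
        diagnostics={
            "n_points": len(t),
            "t_start": t_start,
            "convolution_fwhm": convolution_fwhm,
            "n_starts": _N_STARTS,
        },
    )


def fit_global(
    traces: dict[str, tuple[np.ndarray, np.ndarray]],
    n_components: int = 2,
    components_per_trace: dict[str, list[int]] | None = None,
    convolution_fwhm: float | None = None,
) -> DecayFitResult:
    """Simultaneous fit of several traces to shared exponential constants.

    Every trace is modelled as a linear combination of exponential basis
    functions exp(-t/tau_k) (or their Gaussian-convolved EMG counterparts)
    with the tau_k shared across traces and per-trace amplitudes free;
    negative amplitudes encode rise terms, so sequential cascades are
    expressible.  ``components_per_trace`` restricts which components enter
    which trace.  An identifiability warning (with a Jacobian condition
    number) is attached when there are at least as many shared constants as
    informative traces.
    """
    if not traces:
        raise ValueError("no traces given")
    labels = sorted(traces)
    data = {k: (np.asarray(t, float), np.asarray(y, float)) for k, (t, y) in traces.items()}
    if components_per_trace is None:
        components_per_trace = {k: list(range(n_components)) for k in labels}
    span = max(float(t[-1] - t[0]) for t, _ in data.values()) or 1.0
    sigma = convolution_fwhm * FWHM_TO_SIGMA if convolution_fwhm else None

    def basis(t: np.ndarray, tau: float) -> np.ndarray:
        return emg(t, 1.0, tau, sigma) if sigma else np.exp(-t / tau)

    def residual(params: Parameters) -> np.ndarray:
        taus = [params[f"tau_{k}"].value for k in range(n_components)]
        out = []
        for lab in labels:
            t, y = data[lab]
            model = np.zeros_like(t)
            for k in components_per_trace[lab]:
                model += params[f"amp_{lab}_{k}"].value * basis(t, taus[k])
            out.append(model - y)
        return np.concatenate(out)

    starts = _tau_starts(span)
    best = None
    for m in range(_N_STARTS):
        params = Parameters()
        for k in range(n_components):
            # staggered deterministic assignment of log-spaced starts
            tau0 = starts[(m + k * (_N_STARTS // max(1, n_components))) % _N_STARTS]
            params.add(f"tau_{k}", value=float(tau0), min=1e-6)
        for lab in labels:
            scale = float(np.max(np.abs(data[lab][1]))) or 1.0
            for k in components_per_trace[lab]:
                params.add(f"amp_{lab}_{k}", value=scale / len(components_per_trace[lab]))
        try:
            res = minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    taus = sorted(
        (float(best.params[f"tau_{k}"].value), k) for k in range(n_components)
    )
    order = [k for _, k in taus]
    tau_vals = [tv for tv, _ in taus]
    stderrs = [
        float(best.params[f"tau_{k}"].stderr)
        if best.params[f"tau_{k}"].stderr is not None
        else None
        for k in order
    ]
    amplitudes = {
        lab: [
            float(best.params[f"amp_{lab}_{k}"].value)
            if k in components_per_trace[lab]
            else 0.0
            for k in order
        ]
        for lab in labels
    }

    diagnostics: dict = {"n_traces": len(labels), "n_components": n_components}
    n_informative = sum(1 for lab in labels if np.ptp(data[lab][1]) > 0)
    if n_components >= n_informative:
        try:
            from scipy.optimize import approx_fprime  # noqa: F401

            jac = _numeric_jacobian(residual, best.params)
            cond = float(np.linalg.cond(jac))
        except Exception:
            cond = float("inf")
        diagnostics["identifiability_warning"] = (
            f"{n_components} shared constants for {n_informative} informative "
            f"traces; Jacobian condition number {cond:.3g}"
        )
        diagnostics["jacobian_condition"] = cond

    return DecayFitResult(
        taus=tau_vals,
        tau_stderrs=stderrs,
        amplitudes=amplitudes,
        offset=0.0,
        model="global",
        non_decaying=min(tau_vals) > NON_DECAYING_SPAN_FACTOR * span,
        redchi=float(best.redchi),
        diagnostics=diagnostics,
    )


def _numeric_jacobian(residual, params: Parameters, eps: float = 1e-6) -> np.ndarray:
    """Forward-difference Jacobian of the residual w.r.t. varying parameters."""
    names = [n for n in params if params[n].vary]
    r0 = residual(params)
    jac = np.empty((len(r0), len(names)))
    for j, name in enumerate(names):
        p = params.copy()
        step = eps * max(1.0, abs(p[name].value))
        p[name].value = p[name].value + step
        jac[:, j] = (residual(p) - r0) / step
    return jac
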